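{
 "name": "partial_mix",
 "spec": {
  "image_shape": [
   512,
   512
  ],
  "pixel_size_nm": 30.0,
  "n_paths": 8,
  "path_model": "random_walk",
  "path_length_um": 12.0,
  "base_intensity_ch1": 2000.0,
  "base_intensity_ch2": 2000.0,
  "psf_sigma_nm": 80.0,
  "noise_model": "poisson_gaussian",
  "gaussian_noise_sd": 2.0,
  "background_level": 20.0,
  "seed": 31
 },
 "planted": [
  {
   "path_id": 0,
   "start_um": 1.5,
   "end_um": 4.0,
   "mode": "enrich_ch1",
   "fold": 1.4
  },
  {
   "path_id": 0,
   "start_um": 6.5,
   "end_um": 9.0,
   "mode": "enrich_ch2",
   "fold": 1.4
  },
  {
   "path_id": 1,
   "start_um": 1.5,
   "end_um": 4.0,
   "mode": "enrich_ch1",
   "fold": 1.4
  },
  {
   "path_id": 1,
   "start_um": 6.5,
   "end_um": 9.0,
   "mode": "enrich_ch2",
   "fold": 1.4
  },
  {
   "path_id": 2,
   "start_um": 1.5,
   "end_um": 4.0,
   "mode": "enrich_ch1",
   "fold": 1.4
  },
  {
   "path_id": 2,
   "start_um": 6.5,
   "end_um": 9.0,
   "mode": "enrich_ch2",
   "fold": 1.4
  },
  {
   "path_id": 3,
   "start_um": 1.5,
   "end_um": 4.0,
   "mode": "enrich_ch1",
   "fold": 1.4
  },
  {
   "path_id": 3,
   "start_um": 6.5,
   "end_um": 9.0,
   "mode": "enrich_ch2",
   "fold": 1.4
  },
  {
   "path_id": 4,
   "start_um": 1.5,
   "end_um": 4.0,
   "mode": "enrich_ch1",
   "fold": 1.4
  },
  {
   "path_id": 4,
   "start_um": 6.5,
   "end_um": 9.0,
   "mode": "enrich_ch2",
   "fold": 1.4
  },
  {
   "path_id": 5,
   "start_um": 1.5,
   "end_um": 4.0,
   "mode": "enrich_ch1",
   "fold": 1.4
  },
  {
   "path_id": 5,
   "start_um": 6.5,
   "end_um": 9.0,
   "mode": "enrich_ch2",
   "fold": 1.4
  },
  {
   "path_id": 6,
   "start_um": 1.5,
   "end_um": 4.0,
   "mode": "enrich_ch1",
   "fold": 1.4
  },
  {
   "path_id": 6,
   "start_um": 6.5,
   "end_um": 9.0,
   "mode": "enrich_ch2",
   "fold": 1.4
  },
  {
   "path_id": 7,
   "start_um": 1.5,
   "end_um": 4.0,
   "mode": "enrich_ch1",
   "fold": 1.4
  },
  {
   "path_id": 7,
   "start_um": 6.5,
   "end_um": 9.0,
   "mode": "enrich_ch2",
   "fold": 1.4
  }
 ],
 "expected": {
  "compartment_class": "many",
  "enrichment_class": "median < 50%"
 }
}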