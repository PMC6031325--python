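{
 "name": "reduced_self",
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
  "seed": 41
 },
 "planted": [
  {
   "path_id": 0,
   "start_um": 4.0,
   "end_um": 6.0,
   "mode": "deplete_ch2",
   "fold": 1.8
  },
  {
   "path_id": 1,
   "start_um": 4.0,
   "end_um": 6.0,
   "mode": "deplete_ch2",
   "fold": 1.8
  },
  {
   "path_id": 2,
   "start_um": 4.0,
   "end_um": 6.0,
   "mode": "deplete_ch2",
   "fold": 1.8
  },
  {
   "path_id": 3,
   "start_um": 4.0,
   "end_um": 6.0,
   "mode": "deplete_ch2",
   "fold": 1.8
  }
 ],
 "expected": {
  "compartment_class": "sparse",
  "enrichment_class": "mostly exclusion-attributed"
 }
}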