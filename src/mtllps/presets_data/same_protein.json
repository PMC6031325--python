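{
 "name": "same_protein",
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
  "seed": 11
 },
 "planted": [],
 "expected": {
  "compartment_class": "none",
  "enrichment_class": "n/a"
 }
}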