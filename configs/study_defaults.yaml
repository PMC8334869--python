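# Default study configuration: cohort scale and analysis constants.
n_subjects: 37
torsion_mean: 16.2
torsion_sd: 10.0
torsion_support: [-20.0, 50.0]
baseline_torsion: 5.5
inclination: 45.0
anteversion: 20.0
hemisphere_diameter: 54.0
alpha: 0.05
min_cluster_extent: 2.0
seed: 0
write_figures: false
effects:
  slope_rotation: 0.3
  window_rotation: [57.0, 63.0]
  slope_foot_progression: 0.2
  window_foot_progression: [39.0, 56.0]
  noise_fwhm: 20.0
  noise_sd: 2.0
  taper: 3.0
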