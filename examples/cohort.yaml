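# Demo pipeline configuration.  Every modelling assumption that the
# acquisition protocol leaves open is an explicit key here.
out_dir: pipeline_demo
seed: 0

cohort:
  n_oa: 4
  n_hv: 2
  visits: [baseline, month1, month6]
  mean_oa: 0.039          # whole-joint Ktrans, min^-1
  mean_hv: 0.025
  between_subject_sd: 0.01449   # sqrt(2.1e-4)
  within_subject_sd: 0.004899   # sqrt(2.4e-5)
  haematocrit_mean: 0.42
  haematocrit_sd: 0.03

phantom:
  grid_shape: [32, 32, 8]
  voxel_size: [5.0, 5.0, 4.0]
  enhancing_fraction: 0.7

acquisition:
  grid_shape: [32, 32, 8]
  voxel_size: [5.0, 5.0, 4.0]
  repetition_time: 0.004
  flip_angles_vfa: [2, 6, 14]
  dynamic_flip_angle: 14
  n_phases: 35
  phase_interval: 10.0    # seconds per dynamic frame (assumption)
  baseline_frames: 5      # bolus arrives after these frames (assumption)
  noise_sd: 0.5
  noise_model: gaussian

aif:
  bolus_arrival_offset: 0.8333   # minutes = 5 frames x 10 s
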