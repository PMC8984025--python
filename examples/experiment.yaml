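# Full experiment grid on a synthetic field.
#
#   paddy all --config examples/experiment.yaml --out results/ --seed 42
#
# field: the synthetic study system (see docs/methods.md for defaults)
field:
  height_px: 400
  width_px: 400
  yield_mean: 9.06        # Mg/ha
  yield_sd: 0.9           # Mg/ha
  correlation_length: 15.0  # meters
  n_dates: 5
  stage_labels: [tillering, panicle-initiation, booting, flowering, grain-fill]
  sensor_noise_sd: 0.01   # reflectance units
  label_noise:
    amplitude: 0.3        # Mg/ha, harvester-track artifact
    spacing: 17.0         # cells (8.5 m header at 50 cm)
  buffer_cells: 20        # 10 m edge buffer
  seed: 42

models: [null, linear, xgboost, cnn2d, cnn3d]
folds: [A, B, C, D]
# dates_2d: null -> every date gets its own single-date models
# dates_3d: null -> the last five dates feed the spatio-temporal network
seed: 42
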