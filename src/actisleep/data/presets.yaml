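# Versioned coefficient presets for the legacy count-based sleep algorithms.
# Each preset cites the publication its constants were taken from. Values are
# overridable per run; the pipeline logs the preset version it used.
version: 1

cole_kripke:
  # Cole R.J., Kripke D.F., Gruen W., Mullaney D.J., Gillin J.C. (1992).
  # Automatic sleep/wake identification from wrist activity. Sleep 15(5):461-469.
  # 1-minute epochs; D = 0.001 * (106 A-4 + 54 A-3 + 58 A-2 + 76 A-1
  #                               + 230 A0 + 74 A+1 + 67 A+2); sleep if D < 1.
  scale: 0.001
  weights: {-4: 106, -3: 54, -2: 58, -1: 76, 0: 230, 1: 74, 2: 67}
  threshold: 1.0
  sleep_when: score_below
  epoch_basis_s: 60

oakley:
  # Oakley N.R. (1997). Validation with polysomnography of the Sleepwatch
  # sleep/wake scoring algorithm used by the Actiwatch activity monitoring
  # system. Mini-Mitter technical report. Symmetric window weights with a
  # device threshold; the medium-sensitivity threshold 40 is the default.
  scale: 1.0
  weights: {-2: 0.04, -1: 0.2, 0: 1.0, 1: 0.2, 2: 0.04}
  threshold: 40.0
  sleep_when: score_at_or_below
  epoch_basis_s: 60

sadeh:
  # Sadeh A., Sharkey K.M., Carskadon M.A. (1994). Activity-based sleep-wake
  # identification: an empirical test of methodological issues.
  # Sleep 17(3):201-207. PS = 7.601 - 0.065 MW5 - 1.08 NAT - 0.056 SD6
  #                          - 0.703 LG; sleep if PS >= 0.
  intercept: 7.601
  w_mean: -0.065
  w_nat: -1.08
  w_sd: -0.056
  w_log: -0.703
  nat_low: 50
  nat_high: 100
  window_epochs_each_side: 5
  sd_window_epochs: 6
  sleep_threshold: 0.0
  # Documented alternative threshold in circulation: -4.
  epoch_basis_s: 60

sazonov:
  # Sazonov E. et al. (2004). Activity-based sleep-wake identification in
  # infants. Physiol Meas 25:1291-1304, as propagated by the Palotti et al.
  # (2019) benchmark implementation. Logistic model on trailing-window
  # maxima of counts; sleep when P >= 0.5.
  intercept: 1.727
  window_weights: {1: -0.256, 2: -0.154, 3: -0.136, 4: -0.140, 5: -0.176}
  probability_threshold: 0.5

vanhees:
  # van Hees V.T. et al. (2015). A novel, open access method to assess sleep
  # duration using a wrist-worn accelerometer. PLoS ONE 10(11):e0142533.
  median_window_s: 5.0
  angle_block_s: 5.0
  angle_change_threshold_deg: 5.0
  min_still_duration_min: 5.0
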