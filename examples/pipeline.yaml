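# Example pipeline configuration for `rpt-uptake run-all --config ...`.
# Every key is optional; omitted keys take the defaults shown here.

seed: 0                 # global seed; each stage derives its own from it
out_dir: pipeline_out
overwrite: false

# Synthetic cohort design (ignored when external_* paths are given).
cohort:
  n_participants: 1000
  uptake_base_rate: 0.7264     # expected fraction fully vaccinated
  mediation_strength: 0.4      # corr(latent judgment factor, age/income/education)
  noise_sd: 1.0                # overall rating-noise scale
  # category_valence:          # mean-rating target per picture category
  #   sports: 0.8
  #   disasters: -2.4
  #   cute_animals: 2.4
  #   aggressive_animals: -1.4
  #   nature: 1.5
  #   people: -0.7
  # judgment_effects:          # logistic coefficients (standardized scale)
  #   loss_aversion: -0.6
  #   peak_positive_risk: -0.4
  #   tradeoff_range: 0.3
  # demo_effects:
  #   age: 0.8
  #   income: 0.5
  #   education: 0.5
  #   sex: -0.15
  #   marital: -0.1
  #   employment: 0.1

# To analyze your own tables instead of simulating, point at two CSVs with
# the documented headers (see README):
# external_participants: data/participants.csv
# external_ratings: data/ratings.csv

# Quality assurance thresholds.
qa_enabled: true
qa_r2_min: 0.8               # minimum R^2 for value and limit fits
qa_outlier_threshold: 4.0    # modified-z cutoff for feature outliers
qa_speeder_min_seconds: 800  # applied only when a completion-time column exists

# Prediction stage: repeats of stratified 10-fold CV, and the model grid.
cv_repeats: 10
# model_specs:
#   - {model: brf, n_estimators: 100, max_depth: 10, feature_set: judgment+demo}
#   - {model: brf, n_estimators: 300, max_depth: 15, feature_set: judgment+demo+covid_beh}
#   - {model: rf, n_estimators: 100, max_depth: 10, feature_set: judgment+demo}
#   - {model: logistic, feature_set: judgment+demo}

# Mediation/moderation sweep (15 judgment x 3 demographics x 3 analyses).
run_mediation: true
mediation_n_boot: 1000
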