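"""Predict a binarized behavior trait from microbiome features.

Builds a 120-dog cohort where two species carry a 2-latent-SD motivation
effect, binarizes motivation at the median rule (puppies under 1 year
excluded), and evaluates an XGBoost classifier in stratified 3-fold
cross-validation.
"""

import dogbiome as db

cfg = db.CommunityConfig(n_sgbs=30, genome_length_bp=500, seed=2)
catalog, _ = db.generate_reference_catalog(cfg)
effect = db.EffectSpec("motivation", ["SGB_0003", "SGB_0007"], 2.0, threshold=3)
meta, truths = db.generate_cohort(120, catalog, effects=[effect], seed=2, config=cfg)
features = db.assemble_feature_table(db.truth_table(truths), catalog.taxonomy_frame())

report = db.predict_trait(features, meta, "motivation", k=3, seed=0)
print(f"trait: {report.trait}  (threshold {report.rule.threshold}, "
      f"groups low/high = {report.rule.group_sizes})")
print(f"n = {report.n_used} dogs used, {report.n_excluded_puppies} puppies excluded")
print(f"features: {report.n_features} (13 summary + species abundances)")
print(f"ROC AUC  : {report.mean_auc:.3f} +/- {report.std_auc:.3f} over {report.k_folds} folds")
print(f"accuracy : {report.mean_accuracy:.3f} +/- {report.std_accuracy:.3f}")
print("\nAUC near 1 means held-out dogs' motivation group is recoverable from the "
      "microbiome; a null cohort would sit near 0.5.")
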