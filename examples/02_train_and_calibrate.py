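"""Train the SVM meta-classifier and calibrate confidences.

Labels a simulated pool against its reference LDO set, runs nested
cross-validation for both query->target directions, and prints the held-out
performance of the weighted (SVM) score next to plain voting, plus the
calibration anchors that pin F-beta-optimal raw thresholds to fixed
confidences (the balanced-F threshold lands exactly at confidence 0.5).
"""

import warnings

warnings.filterwarnings("ignore")

import ldometa as lm
from ldometa.pool import Label
from ldometa.scaling import DEFAULT_BETAS

cfg = lm.heterogeneous17_config(seed=0, n_query_genes=1200, n_target_genes=1200)
pool, reference, truth = lm.simulate(cfg)
trained = lm.train_meta(pool, reference, seed=0)

for direction in ("forward", "reverse"):
    agg = trained.reports[direction].aggregate()
    print(
        f"{direction:8s}: held-out F = {agg.loc['f', 'mean']:.3f} "
        f"+/- {agg.loc['f', 'sem']:.3f} | max-F {agg.loc['max_f', 'mean']:.3f} "
        f"(voting max-F {agg.loc['vote_max_f', 'mean']:.3f})"
    )

report = trained.reports["forward"]
label_map = {
    p: trained.labeled.labels[p] is Label.KNOWN_LDO for p in report.oof_scores
}
total = sum(label_map.values()) + trained.labeled.n_reference_unpooled
print("\ncalibration anchors (out-of-fold raw score -> confidence):")
for beta in DEFAULT_BETAS:
    t = lm.find_fbeta_threshold(report.oof_scores, label_map, total, beta)
    conf = trained.scalers["forward"].scale(t)
    print(f"  beta={beta:<6} threshold={t:+.3f}  confidence={conf:.4f}")
print(
    "\nThe SVM separates known LDOs from known non-LDOs better than voting,\n"
    "and thresholding the calibrated score at 0.5 maximizes balanced F."
)
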