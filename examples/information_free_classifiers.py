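"""Near-perfect classifiers trained on an information-free raw matrix.

Creates a raw count matrix that is identically zero, normalizes it with the
class-offset leak, extracts the (entire) all-zero submatrix, populates it
with normalized values, and trains one-vs-all gradient-boosted classifiers
with stratified cross-validation. For contrast, the same pipeline runs with
honest normalization.

Run:  python examples/information_free_classifiers.py   (~30 s)
"""

from leakforensics.experiments import leakage_experiment
from leakforensics.pipeline import EvalConfig

cfg = EvalConfig(n_folds=5, n_estimators=60, seed=0)

for mode in ("class_offsets", "none"):
    evaluation, provenance = leakage_experiment(
        seed=11, n_classes=8, n_per_class=40, n_features=20,
        leak_mode=mode, config=cfg,
    )
    print(f"leak_mode={mode!r}  "
          f"({provenance['n_samples']} samples x {provenance['n_features']} "
          f"features, raw all zero: {provenance['raw_submatrix_all_zero']})")
    print(evaluation.per_class[["auc", "sensitivity", "specificity", "ppv", "npv"]]
          .round(3).to_string())
    med = evaluation.medians
    print(f"  medians: AUC {med['auc']:.3f}, sensitivity {med['sensitivity']:.3f}, "
          f"specificity {med['specificity']:.3f}\n")

print(
    "Reading this: the raw data underlying both runs is a matrix of zeros.\n"
    "With the leaky normalization the models look outstanding — every bit of\n"
    "that accuracy is the class label smuggled in by the transform. With\n"
    "honest normalization the same pipeline sits at chance (AUC ~ 0.5),\n"
    "which is the only defensible result on information-free data."
)
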