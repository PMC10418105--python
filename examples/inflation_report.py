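"""Entry-level inflation between two count matrices for the same samples.

Simulates a "true" raw matrix, then a corrupted copy in which a fraction of
entries is inflated by orders of magnitude (the effect of host reads being
mis-assigned to microbial genera), and summarizes the disagreement.

Run:  python examples/inflation_report.py
"""

import numpy as np

from leakforensics.forensics import inflation_report
from leakforensics.simulate import simulate_count_matrix

truth = simulate_count_matrix(
    ["BLCA", "HNSC", "BRCA"], 50, n_common_features=30, n_rare_features=10,
    n_zero_features=10, nb_mean=20, seed=1,
)
rng = np.random.default_rng(2)
inflated = truth.counts.copy()
mask = rng.random(inflated.shape) < 0.6  # 60% of entries corrupted
inflated = inflated.where(~mask, inflated * 1000 + 500)

report = inflation_report(inflated, truth.counts)
for label, entry in report.to_dict().items():
    print(f"entries with inflated count {label}:")
    print(f"  pairs considered : {entry['n_pairs']}")
    frac = entry["tenfold_fraction"]
    print(f"  >=10x too high   : {entry['n_tenfold']} ({100 * frac:.1f}%)")
    if "n_within50" in entry:
        w = entry["within50_fraction"]
        print(f"  within 50%       : {entry['n_within50']} ({100 * w:.1f}%)")

print(
    "\nReading this: when most entries of a published matrix are >=10 times\n"
    "larger than a careful re-analysis, and almost none agree to within 50%,\n"
    "the matrix is not noisy — it is systematically wrong."
)
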