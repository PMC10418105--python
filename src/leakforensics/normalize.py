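"""Count normalization, including deliberately leaky misuse modes.

:func:`voom_logcpm` is the standard log2 counts-per-million transform with a
0.5 pseudo-count. :func:`supervised_normalize` is a per-feature regression
normalization that removes an adjustment covariate while retaining a
biological one — plus two explicitly named misuse modes that imprint the
biological (class) label onto features carrying no information in the raw
counts. The misuse modes exist so the forensics and pipeline modules have a
controlled generator of the class-tagging artifact; neither is claimed to be
the exact mechanism of any particular published analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .containers import CountMatrix, NormalizedMatrix

__all__ = ["voom_logcpm", "supervised_normalize", "LEAK_MODES"]

LEAK_MODES = ("none", "class_offsets", "libsize_coupling")


def voom_logcpm(matrix: CountMatrix) -> NormalizedMatrix:
    """log2((count + 0.5) / (library_size + 1) * 1e6), per cell.

    A zero count at library size 999,999 maps exactly to -1. Strictly
    monotone in the count for fixed library size; for an all-zero feature
    the value is a pure function of library size — the hinge on which the
    leakage phenomena turn.
    """
    lib = matrix.metadata["library_size"].to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library_size must be positive for every sample")
    counts = matrix.counts.to_numpy(dtype=float)
    vals = np.log2((counts + 0.5) / (lib[:, None] + 1.0) * 1e6)
    return NormalizedMatrix(
        values=pd.DataFrame(
            vals, index=matrix.counts.index, columns=matrix.counts.columns
        ),
        provenance={
            "transform": "voom_logcpm",
            "all_zero_features": matrix.zero_features(),
        },
    )


def _onehot_drop_first(cov: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    levels = pd.unique(cov)
    cols = [f"{name}[{lv}]" for lv in levels[1:]]
    mat = np.column_stack([(cov == lv).to_numpy(float) for lv in levels[1:]]) if len(
        levels
    ) > 1 else np.empty((len(cov), 0))
    return mat, cols


def supervised_normalize(
    matrix: NormalizedMatrix,
    biological: pd.Series,
    adjustment: pd.Series,
    leak_mode: str = "none",
    offset_sd: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    zero_features: list[str] | None = None,
) -> NormalizedMatrix:
    """Remove adjustment-covariate effects per feature; optionally leak.

    leak_mode="none"
        Ordinary least squares of each feature on
        [intercept | biological | adjustment] (reference-level one-hot);
        the fitted adjustment component is subtracted, everything else —
        intercept, biological effects, residuals — is retained. With a
        constant adjustment covariate this is the identity.
    leak_mode="class_offsets"
        Additionally overwrites each raw-all-zero feature with a per-class
        constant tag: its fitted class mean plus a per-(class, feature)
        offset ~ Normal(0, offset_sd), plus optional within-class noise
        ~ Normal(0, noise_sd). With the default noise_sd=0 every class gets
        exactly one distinct value — the duplicate-value artifact.
    leak_mode="libsize_coupling"
        Replaces each raw-all-zero feature with the zero-count log-CPM value
        computed under a class-dependent library size, so the pseudo-count
        anchor alone separates the classes.

    Which features count as raw-all-zero comes from ``zero_features`` or,
    by default, the input's provenance (as recorded by :func:`voom_logcpm`).
    """
    if leak_mode not in LEAK_MODES:
        raise ValueError(f"leak_mode must be one of {LEAK_MODES}, got {leak_mode!r}")
    values = matrix.values
    for cov, cname in [(biological, "biological"), (adjustment, "adjustment")]:
        if not values.index.isin(cov.index).all():
            raise ValueError(f"{cname} covariate missing for some samples")
    bio = biological.loc[values.index]
    adj = adjustment.loc[values.index]

    x_bio, bio_cols = _onehot_drop_first(bio, "biological")
    x_adj, adj_cols = _onehot_drop_first(adj, "adjustment")
    n = len(values)
    design = np.hstack([np.ones((n, 1)), x_bio, x_adj])
    col_names = ["intercept"] + bio_cols + adj_cols
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient design: collinear covariates among " + ", ".join(col_names)
        )

    y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    n_adj = x_adj.shape[1]
    out = y - (x_adj @ beta[-n_adj:] if n_adj else 0.0)

    if zero_features is None:
        zero_features = matrix.provenance.get("all_zero_features", [])
    zcols = [values.columns.get_loc(f) for f in zero_features if f in values.columns]

    if leak_mode == "class_offsets" and zcols:
        rng = stage_rng(seed, "class_offsets")
        levels = list(pd.unique(bio))
        offsets = rng.normal(0.0, offset_sd, size=(len(levels), len(zcols)))
        class_idx = bio.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
        # fitted class means of the leak-free output serve as the base level
        base = np.zeros((len(levels), len(zcols)))
        for i, lv in enumerate(levels):
            base[i] = out[np.asarray(bio == lv), :][:, zcols].mean(axis=0)
        tags = base[class_idx] + offsets[class_idx]
        if noise_sd > 0:
            tags = tags + rng.normal(0.0, noise_sd, size=tags.shape)
        out[:, zcols] = tags
    elif leak_mode == "libsize_coupling" and zcols:
        rng = stage_rng(seed, "libsize_coupling")
        levels = list(pd.unique(bio))
        # class-dependent library sizes: the -1-anchored zero-count value
        # log2(0.5/(L_c+1)*1e6) becomes a per-class constant
        lib_c = rng.lognormal(mean=np.log(1e6), sigma=0.5, size=len(levels))
        zero_vals = np.log2(0.5 / (lib_c + 1.0) * 1e6)
        class_idx = bio.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
        out[:, zcols] = zero_vals[class_idx][:, None]

    prov = dict(matrix.provenance)
    prov.update(
        {
            "transform": prov.get("transform", "?") + "+supervised_normalize",
            "leak_mode": leak_mode,
            "offset_sd": offset_sd,
            "noise_sd": noise_sd,
            "seed": seed,
            "biological_levels": int(pd.unique(bio).size),
            "adjustment_levels": int(pd.unique(adj).size),
            "all_zero_features": list(zero_features),
        }
    )
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=values.index, columns=values.columns),
        provenance=prov,
    )
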