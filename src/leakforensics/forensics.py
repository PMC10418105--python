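"""Diagnostics for count matrices and suspicious normalized values.

Three families of evidence that a published matrix has gone wrong:

* entry-level inflation between two raw matrices claiming to describe the
  same samples (how many entries are >= 10x larger, how many are even
  within 50%);
* duplicate-value tags — many samples of one group sharing a bit-identical
  normalized value, a fingerprint of fitted values being written back into
  the data;
* single-feature threshold rules — if one genus alone nearly separates a
  class while its raw column is all zeros, the "signal" was created by the
  transformation, not the biology.

Rule metrics are computed in exact rational arithmetic; rounding only ever
happens at display time.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "InflationReport",
    "inflation_report",
    "duplicate_value_clusters",
    "ThresholdRuleResult",
    "threshold_rule_eval",
    "best_threshold_rule",
    "FeatureDiagnostics",
    "discordance_scan",
]


@dataclass(frozen=True)
class InflationEntry:
    """Comparison restricted to entries where A >= threshold."""

    threshold: int
    n_pairs: int
    n_tenfold: int
    n_within50: int | None  # reported at the lowest threshold only

    @property
    def tenfold_fraction(self) -> Fraction | None:
        return Fraction(self.n_tenfold, self.n_pairs) if self.n_pairs else None

    @property
    def within50_fraction(self) -> Fraction | None:
        if self.n_within50 is None or not self.n_pairs:
            return None
        return Fraction(self.n_within50, self.n_pairs)


@dataclass
class InflationReport:
    entries: list[InflationEntry]

    def at(self, threshold: int) -> InflationEntry:
        for e in self.entries:
            if e.threshold == threshold:
                return e
        raise KeyError(f"no entry for threshold {threshold}")

    def to_dict(self) -> dict:
        out = {}
        for e in self.entries:
            d = {
                "n_pairs": e.n_pairs,
                "n_tenfold": e.n_tenfold,
                "tenfold_fraction": float(e.tenfold_fraction)
                if e.tenfold_fraction is not None
                else None,
            }
            if e.n_within50 is not None:
                d["n_within50"] = e.n_within50
                d["within50_fraction"] = (
                    float(e.within50_fraction)
                    if e.within50_fraction is not None
                    else None
                )
            out[f"A>={e.threshold}"] = d
        return out


def _aligned(a: CountMatrix | pd.DataFrame, b: CountMatrix | pd.DataFrame):
    da = a.counts if isinstance(a, CountMatrix) else a
    db = b.counts if isinstance(b, CountMatrix) else b
    if not (da.index.equals(db.index) and da.columns.equals(db.columns)):
        samp = da.index.symmetric_difference(db.index).tolist()
        gen = da.columns.symmetric_difference(db.columns).tolist()
        raise ValueError(
            f"matrices disagree on ids: samples {samp[:5]}, genera {gen[:5]}"
        )
    return da.to_numpy(), db.to_numpy()


def inflation_report(
    A: CountMatrix | pd.DataFrame,
    B: CountMatrix | pd.DataFrame,
    thresholds: Sequence[int] = (10, 100),
) -> InflationReport:
    """Entry-level inflation of matrix A relative to re-analysis matrix B.

    For each threshold T, considers entries with A >= T. An entry is
    "tenfold" when A >= 10*B (B = 0 always satisfies this); "within 50%"
    (evaluated at the lowest threshold) when B >= 1 and 0.5*B <= A <= 1.5*B.
    """
    a, b = _aligned(A, B)
    a = a.ravel().astype(np.int64)
    b = b.ravel().astype(np.int64)
    lowest = min(thresholds)
    entries = []
    for t in sorted(thresholds):
        mask = a >= t
        tenfold = int((mask & (a >= 10 * b)).sum())
        within50 = None
        if t == lowest:
            within50 = int((mask & (b >= 1) & (2 * a >= b) & (2 * a <= 3 * b)).sum())
        entries.append(InflationEntry(t, int(mask.sum()), tenfold, within50))
    return InflationReport(entries)


def _round_sig(x: float, sig: int) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, sig - 1 - int(np.floor(np.log10(abs(x)))))


def duplicate_value_clusters(
    values: pd.Series | np.ndarray,
    group: Sequence | np.ndarray | None = None,
    sig_digits: int = 9,
) -> list[tuple[float, int]]:
    """Clusters of identical values (after rounding) within a sample group.

    Values equal after rounding to ``sig_digits`` significant digits form a
    cluster; singletons are omitted; the result is sorted by size
    descending (value ascending on ties). The default precision matches
    9-10 significant digits typical of printed normalized values.
    """
    arr = np.asarray(values, dtype=float)
    if group is not None:
        arr = arr[np.asarray(group)]
    if arr.size == 0:
        raise ValueError("group is empty")
    rounded = [_round_sig(float(v), sig_digits) for v in arr]
    counts: dict[float, int] = {}
    for v in rounded:
        counts[v] = counts.get(v, 0) + 1
    clusters = [(v, c) for v, c in counts.items() if c >= 2]
    clusters.sort(key=lambda vc: (-vc[1], vc[0]))
    return clusters


@dataclass(frozen=True)
class ThresholdRuleResult:
    """Confusion-matrix summary of a one-feature threshold rule."""

    threshold: float
    direction: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> Fraction:
        return Fraction(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Fraction:
        return Fraction(self.tn, self.tn + self.fp)

    @property
    def error_rate(self) -> Fraction:
        return Fraction(self.fp + self.fn, self.tp + self.fp + self.tn + self.fn)

    @property
    def n_errors(self) -> int:
        return self.fp + self.fn

    @property
    def balanced_accuracy(self) -> Fraction:
        return (self.sensitivity + self.specificity) / 2


_DIRECTIONS = {
    "ge": np.greater_equal,
    "gt": np.greater,
    "le": np.less_equal,
    "lt": np.less,
}


def threshold_rule_eval(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[bool] | np.ndarray,
    threshold: float,
    direction: str = "ge",
) -> ThresholdRuleResult:
    """Evaluate "predict positive when value <direction> threshold" exactly.

    ``labels`` is boolean (True = positive class) and must contain both
    classes. Sensitivity, specificity and error rate are exact fractions.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(_DIRECTIONS)}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    pred = _DIRECTIONS[direction](v, threshold)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    return ThresholdRuleResult(float(threshold), direction, tp, fp, tn, fn)


def best_threshold_rule(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[bool] | np.ndarray,
) -> tuple[float, str, float]:
    """Best single-feature rule by balanced accuracy, scanning midpoints.

    Candidate thresholds are midpoints of consecutive sorted unique values;
    both orientations are tried: ge (positive when high) and le (positive
    when low). Ties prefer the smallest threshold, then direction ge. The
    optimum is always >= 0.5 (a rule and its mirrored complement have
    balanced accuracies summing to 1).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    pos_total = int(ys.sum())
    neg_total = len(ys) - pos_total
    uniq, first_idx = np.unique(vs, return_index=True)
    if len(uniq) == 1:
        # no midpoint exists; the degenerate all-positive rule scores 0.5
        return float(uniq[0]), "ge", 0.5
    cum_pos = np.concatenate([[0], np.cumsum(ys)])
    # cut i sits between uniq[i] and uniq[i+1]: `below` counts values < midpoint
    best_num = -1  # balanced accuracy numerator over denominator 2*P*N
    best: tuple[float, str] | None = None
    denom = 2 * pos_total * neg_total
    for i in range(len(uniq) - 1):
        cut = int(first_idx[i + 1])
        pos_below = int(cum_pos[cut])
        neg_below = cut - pos_below
        tp_ge = pos_total - pos_below
        tn_ge = neg_below
        num_ge = tp_ge * neg_total + tn_ge * pos_total
        num_le = denom - num_ge
        mid = float((uniq[i] + uniq[i + 1]) / 2)
        for num, direction in ((num_ge, "ge"), (num_le, "le")):
            if num > best_num:
                best_num, best = num, (mid, direction)
    assert best is not None
    return best[0], best[1], best_num / denom


@dataclass
class FeatureDiagnostics:
    """Per-feature leakage diagnostics against a normalized matrix."""

    feature: str
    raw_nonzero_samples: int
    near_zero_raw: bool
    largest_cluster_per_group: dict[str, int]
    best_rule_class: str
    best_rule_threshold: float
    best_rule_direction: str
    best_rule_balanced_accuracy: float
    best_rule_sensitivity: float
    best_rule_specificity: float
    flagged: bool

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "raw_nonzero_samples": self.raw_nonzero_samples,
            "near_zero_raw": self.near_zero_raw,
            "largest_cluster_per_group": self.largest_cluster_per_group,
            "best_rule_class": self.best_rule_class,
            "best_rule_threshold": self.best_rule_threshold,
            "best_rule_direction": self.best_rule_direction,
            "best_rule_balanced_accuracy": self.best_rule_balanced_accuracy,
            "best_rule_sensitivity": self.best_rule_sensitivity,
            "best_rule_specificity": self.best_rule_specificity,
            "flagged": self.flagged,
        }


def discordance_scan(
    raw: CountMatrix,
    normalized: NormalizedMatrix,
    labels: pd.Series,
    near_zero_fraction: float = 0.01,
    flag_balanced_accuracy: float = 0.75,
) -> list[FeatureDiagnostics]:
    """Flag features that discriminate classes despite empty raw columns.

    A feature is flagged when its raw column is all-zero (or nonzero in
    fewer than ``near_zero_fraction`` of samples) yet its best one-vs-rest
    threshold rule exceeds ``flag_balanced_accuracy``. Also reports, per
    class group, the largest identical-value cluster — the tag signature.
    """
    if raw.counts.shape != normalized.values.shape:
        raise ValueError("raw and normalized shapes differ")
    lab = labels.loc[raw.counts.index]
    classes = list(pd.unique(lab))
    if len(classes) < 2:
        raise ValueError("labels must contain at least two classes")
    n = len(lab)
    out: list[FeatureDiagnostics] = []
    for feature in raw.counts.columns:
        col_raw = raw.counts[feature].to_numpy()
        col_val = normalized.values[feature].to_numpy()
        nnz = int((col_raw != 0).sum())
        near_zero = nnz == 0 or nnz < near_zero_fraction * n
        clusters: dict[str, int] = {}
        best = (None, 0.0, "ge", 0.5)  # class, threshold, direction, bacc
        for cls in classes:
            mask = (lab == cls).to_numpy()
            cl = duplicate_value_clusters(col_val, group=mask)
            clusters[str(cls)] = cl[0][1] if cl else 0
            thr, direction, bacc = best_threshold_rule(col_val, mask)
            if bacc > best[3]:
                best = (cls, thr, direction, bacc)
        if best[0] is None:
            best = (classes[0], float(np.median(col_val)), "ge", 0.5)
        rule = threshold_rule_eval(
            col_val, (lab == best[0]).to_numpy(), best[1], best[2]
        )
        out.append(
            FeatureDiagnostics(
                feature=str(feature),
                raw_nonzero_samples=nnz,
                near_zero_raw=bool(near_zero),
                largest_cluster_per_group=clusters,
                best_rule_class=str(best[0]),
                best_rule_threshold=float(best[1]),
                best_rule_direction=best[2],
                best_rule_balanced_accuracy=float(best[3]),
                best_rule_sensitivity=float(rule.sensitivity),
                best_rule_specificity=float(rule.specificity),
                flagged=bool(near_zero and best[3] > flag_balanced_accuracy),
            )
        )
    return out
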