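"""Designed end-to-end simulations of the two failure mechanisms.

:func:`contamination_experiment` — a host genome, a panel of microbial
genomes of which one draft carries a mislabeled host-derived contig, and a
read set dominated by host reads; classification against microbes-only vs
microbes+host databases quantifies the false-positive collapse.

:func:`leakage_experiment` — a raw count matrix that is identically zero,
normalized with an explicitly leaky transform, fed to one-vs-all
classifiers; the measured accuracy is purely the leaked label.

Default parameters ARE the study conditions; change them only to explore.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import stage_rng, stage_seed
from .classifier import HostInclusionReport, host_inclusion_experiment
from .containers import CountMatrix, NormalizedMatrix
from .normalize import supervised_normalize, voom_logcpm
from .pipeline import ClassifierEvaluation, EvalConfig, run_fig6_experiment
from .simulate import contaminate_draft, simulate_genome, simulate_reads

__all__ = ["contamination_experiment", "leakage_experiment"]


def contamination_experiment(
    seed: int = 0,
    host_length: int = 1_000_000,
    n_microbes: int = 10,
    microbe_length: int = 200_000,
    contig_length: int = 100_000,
    n_host_reads: int = 100_000,
    n_microbe_reads: int = 50,
    read_length: int = 150,
    error_rate: float = 0.0,
    k: int = 31,
) -> HostInclusionReport:
    """Simulate host reads soaked up by a contaminated draft genome.

    Ten microbial genomes in distinct genera; the first is augmented with a
    host contig while keeping its microbial label. Reads: ``n_host_reads``
    error-free reads uniform over the host plus ``n_microbe_reads`` from
    the clean portion of the contaminated microbe. Returns the two-database
    report (fold decline of the contaminated genus, host-origin fraction).
    """
    host = simulate_genome(
        host_length,
        gc=0.41,
        seed=stage_seed(seed, "host_genome"),
        id="host",
        taxon_path=("root", "Eukaryota", "Homo", "host"),
    )
    microbes = [
        simulate_genome(
            microbe_length,
            gc=0.5,
            seed=stage_seed(seed, f"microbe_{i}"),
            id=f"microbe{i}",
            taxon_path=("root", "Bacteria", f"Genus{i:02d}", f"microbe{i}"),
        )
        for i in range(n_microbes)
    ]
    clean_draft = microbes[0]
    microbes[0] = contaminate_draft(
        clean_draft, host, contig_length, seed=stage_seed(seed, "contig")
    )
    # microbe reads are drawn from the pre-contamination record: same id and
    # sequence as the draft's clean portion, so provenance stays exact
    reads = simulate_reads(
        [(host, n_host_reads), (clean_draft, n_microbe_reads)],
        read_length=read_length,
        error_rate=error_rate,
        seed=stage_seed(seed, "reads"),
    )
    return host_inclusion_experiment(reads, microbes, host, k=k)


def zero_raw_matrix(
    n_classes: int = 32,
    n_per_class: int = 100,
    n_features: int = 66,
    library_sigma: float = 0.2,
    seed: int = 0,
) -> CountMatrix:
    """All-zero raw counts with class labels and class-independent depths."""
    rng = stage_rng(seed, "zero_raw")
    n = n_classes * n_per_class
    classes = [f"C{i + 1:02d}" for i in range(n_classes)]
    sample_ids = [f"s{i:05d}" for i in range(n)]
    lib = np.round(rng.lognormal(np.log(1e6), library_sigma, size=n)).astype(np.int64)
    meta = pd.DataFrame(
        {
            "class_label": np.repeat(classes, n_per_class),
            "sample_type": "tumor",
            "library_size": lib,
        },
        index=sample_ids,
    )
    counts = pd.DataFrame(
        np.zeros((n, n_features), dtype=np.int64),
        index=sample_ids,
        columns=[f"genus{j:03d}" for j in range(n_features)],
    )
    return CountMatrix(counts, meta)


def leakage_experiment(
    seed: int = 0,
    n_classes: int = 32,
    n_per_class: int = 100,
    n_features: int = 66,
    leak_mode: str = "class_offsets",
    offset_sd: float = 1.0,
    noise_sd: float = 0.05,
    config: EvalConfig | None = None,
) -> tuple[ClassifierEvaluation, dict]:
    """Train one-vs-all classifiers on an information-free raw matrix.

    Raw counts are identically zero; log-CPM then supervised normalization
    under the chosen leak mode produce the feature values. With
    ``leak_mode="none"`` the classifiers can only reach chance; with
    ``class_offsets`` they recover the injected per-class tags.
    """
    raw = zero_raw_matrix(n_classes, n_per_class, n_features, seed=seed)
    logcpm = voom_logcpm(raw)
    bio = raw.metadata["class_label"]
    rng = stage_rng(seed, "batches")
    adj = pd.Series(
        rng.choice(["batch1", "batch2"], size=len(raw.sample_ids)),
        index=raw.counts.index,
        name="batch",
    )
    normalized: NormalizedMatrix = supervised_normalize(
        logcpm,
        biological=bio,
        adjustment=adj,
        leak_mode=leak_mode,
        offset_sd=offset_sd,
        noise_sd=noise_sd,
        seed=stage_seed(seed, "leak"),
    )
    cfg = config or EvalConfig(seed=stage_seed(seed, "eval"))
    evaluation, provenance = run_fig6_experiment(raw, normalized, cfg)
    provenance["leak_mode"] = leak_mode
    provenance["offset_sd"] = offset_sd
    provenance["noise_sd"] = noise_sd
    return evaluation, provenance
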