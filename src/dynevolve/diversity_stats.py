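"""Selection-strength statistics of an evolving barcoded population.

Three summaries describe how strongly selection reshapes the lineage
frequency distribution: the Shannon-Wiener diversity index, the abundance
share of the N most abundant lineages, and a sampled-clone statistic that
emulates picking a fixed number of colonies at the end of an experiment and
asking how many distinct barcodes (and how many non-neutral ones) come up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineage_data import LineageTrackingDataset, to_frequencies

__all__ = [
    "shannon_index",
    "top_n_share",
    "sample_uniqueness",
    "diversity_trajectory",
    "SampleUniquenessResult",
]


def shannon_index(frequencies, atol: float = 1e-9) -> float:
    """Shannon-Wiener index ``-sum(f ln f)`` in nats.

    Zero frequencies contribute exactly 0 (the ``x ln x -> 0`` limit). The
    index of a uniform distribution over N lineages is ``ln N``; a
    single-lineage population scores 0.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    tot = f.sum()
    if abs(tot - 1.0) > atol:
        raise ValueError(f"frequencies must sum to 1 (got {tot!r})")
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum())


def top_n_share(counts, n: int) -> float:
    """Fraction of all reads held by the ``n`` most abundant lineages."""
    if n < 1:
        raise ValueError("n must be >= 1")
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot compute a top-N share of an all-zero vector")
    if n >= c.size:
        return 1.0
    top = np.partition(c, c.size - n)[c.size - n:]
    return float(top.sum() / total)


@dataclass
class SampleUniquenessResult:
    """Colony-sampling summary with counting-statistics errors."""

    mean_unique: float
    mean_nonneutral_fraction: float
    se_unique: float
    se_nonneutral_fraction: float
    k: int
    n_reps: int


def sample_uniqueness(
    counts,
    k: int,
    adaptive_flags,
    n_reps: int = 100,
    seed: int | None = None,
    replace: bool = True,
) -> SampleUniquenessResult:
    """Pick ``k`` clones by lineage frequency and summarize the draw.

    Reports the mean number of distinct barcodes among the ``k`` picked
    clones and the mean fraction flagged adaptive (non-neutral), each with
    a counting-statistics standard error (Poisson for the unique-barcode
    count, binomial for the fraction). ``replace=True`` draws clones
    multinomially; ``replace=False`` samples colonies without replacement
    from the discrete population of reads.
    """
    c = np.asarray(counts, dtype=np.int64)
    flags = np.asarray(adaptive_flags, dtype=bool)
    if flags.shape != c.shape:
        raise ValueError("adaptive_flags must align with counts")
    if k < 1:
        raise ValueError("k must be >= 1")
    total = int(c.sum())
    if total <= 0 or (not replace and k > total):
        raise ValueError(f"cannot draw {k} clones from {total} total counts")
    rng = np.random.default_rng(seed)
    freqs = c / total
    uniques = np.empty(n_reps)
    fracs = np.empty(n_reps)
    for r in range(n_reps):
        if replace:
            draw = rng.multinomial(k, freqs)
        else:
            picked = rng.choice(total, size=k, replace=False)
            edges = np.cumsum(c)
            idx = np.searchsorted(edges, picked, side="right")
            draw = np.bincount(idx, minlength=c.size)
        hit = draw > 0
        uniques[r] = hit.sum()
        fracs[r] = draw[flags].sum() / k
    mean_u = float(uniques.mean())
    mean_f = float(fracs.mean())
    return SampleUniquenessResult(
        mean_unique=mean_u,
        mean_nonneutral_fraction=mean_f,
        se_unique=float(np.sqrt(max(mean_u, 1.0))),
        se_nonneutral_fraction=float(np.sqrt(max(mean_f * (1 - mean_f), 0.0) / k)),
        k=k,
        n_reps=n_reps,
    )


def diversity_trajectory(
    dataset: LineageTrackingDataset, top_n: int = 100
) -> pd.DataFrame:
    """Per-timepoint Shannon index, richness, and top-N abundance share."""
    freqs = to_frequencies(dataset, pseudocount=0.0)
    rows = []
    for j, g in enumerate(dataset.generations):
        col = dataset.counts[:, j]
        rows.append(
            {
                "generation": int(g),
                "shannon": shannon_index(freqs[:, j]),
                "richness": int((col > 0).sum()),
                "top_n_share": top_n_share(col, top_n),
            }
        )
    return pd.DataFrame(rows)
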