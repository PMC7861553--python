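"""Per-cycle fitness estimation from pooled bulk-assay barcode trajectories.

A lineage's fitness is estimated from the slopes of its log-frequency
trajectory between sampled timepoints, corrected for the rising population
mean fitness (measured from the decay of flagged neutral lineages) and
combined across measured intervals by inverse-variance weighting. Fitness
is reported per 8-generation growth-and-dilution cycle.

For fitness remeasurement inside a switching assay (the 1:1 and 1:3
designs), an estimate can be restricted to intervals spent in one
environment block: only slopes (and the neutral-based noise parameter)
from the matching intervals contribute. This is the block-restricted
modification that makes "fitness in fluconazole, measured between
glycerol/ethanol residences" a well-defined quantity.

The per-interval noise model is counting-dominated:
``var(slope) ~ kappa * (1/n_t1 + 1/n_t2)`` with read counts ``n`` at the
interval endpoints and ``kappa`` a variance-inflation constant fitted from
the flagged neutral lineages by method of moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .env_schedule import EnvironmentSchedule
from .lineage_data import LineageTrackingDataset

__all__ = [
    "AssayDesign",
    "FitnessEstimate",
    "mean_fitness_reference",
    "fit_kappa",
    "estimate_fitness",
    "lineage_fitness_table",
    "block_restricted_fitness",
    "fitness_correlation",
    "combine_replicates",
]

GENS_PER_CYCLE = 8


@dataclass(frozen=True)
class AssayDesign:
    """A fitness-remeasurement condition.

    ``measured_block_label`` restricts which inter-timepoint intervals
    contribute to the estimate (``None`` = all intervals).
    """

    name: str
    schedule: EnvironmentSchedule | None = None
    measured_block_label: str | None = None


@dataclass
class FitnessEstimate:
    """One lineage's per-cycle fitness with its standard error."""

    fitness_per_cycle: float
    std_error: float
    kappa: float
    n_intervals_used: int
    reliable: bool
    is_neutral_call: bool


def _interval_mask(dataset: LineageTrackingDataset, label: str | None) -> np.ndarray:
    if label is None:
        return np.ones(dataset.n_timepoints - 1, dtype=bool)
    mask = np.array([e == label for e in dataset.env_labels])
    if not mask.any():
        raise ValueError(f"no interval of the assay runs in environment {label!r}")
    return mask


def mean_fitness_reference(
    dataset: LineageTrackingDataset,
    neutral_flags=None,
    pseudocount: float = 0.5,
    min_neutral: int = 10,
) -> np.ndarray:
    """Per-interval mean-fitness increments from decaying neutral lineages.

    Neutral lineages decline in frequency at the population mean fitness,
    so the increment over interval i is ``-delta ln(total neutral
    frequency)``. Returns one increment per interval (in per-interval
    units, i.e. already integrated over the interval's generations); an
    interval where the neutral set is extinct is returned as NaN.
    """
    flags = dataset.neutral_flags if neutral_flags is None else np.asarray(neutral_flags, bool)
    if flags is None:
        raise ValueError("dataset has no neutral flags and none were supplied")
    nz = (dataset.counts[flags].sum(axis=1) > 0).sum()
    if nz < min_neutral:
        raise ValueError(
            f"need >= {min_neutral} flagged neutral lineages with reads (got {nz})"
        )
    c = dataset.counts.astype(float) + pseudocount
    tot = c.sum(axis=0)
    neut = dataset.counts[flags].astype(float).sum(axis=0)
    with np.errstate(divide="ignore"):
        logf = np.where(neut > 0, np.log(np.maximum(neut, 1e-300) / tot), np.nan)
    return -np.diff(logf)


def fit_kappa(
    dataset: LineageTrackingDataset,
    reference: np.ndarray,
    neutral_flags=None,
    interval_mask: np.ndarray | None = None,
    min_reads: int = 20,
    pseudocount: float = 0.5,
) -> float:
    """Method-of-moments noise parameter from flagged neutral lineages.

    For a neutral lineage the mean-fitness-corrected interval slope has
    expectation 0, so ``kappa`` is the mean of ``slope^2 / (1/n1 + 1/n2)``
    over neutral interval slopes with adequate reads. ``kappa = 1``
    corresponds to pure Poisson counting noise.
    """
    flags = dataset.neutral_flags if neutral_flags is None else np.asarray(neutral_flags, bool)
    if flags is None:
        raise ValueError("kappa requires flagged neutral lineages")
    mask = (
        np.ones(dataset.n_timepoints - 1, dtype=bool)
        if interval_mask is None
        else interval_mask
    )
    c = dataset.counts[flags].astype(float)
    tot = dataset.counts.sum(axis=0) + pseudocount * dataset.n_lineages
    logf = np.log((c + pseudocount) / tot)
    slopes = np.diff(logf, axis=1) + reference[None, :]
    n1 = c[:, :-1]
    n2 = c[:, 1:]
    ok = (n1 + n2 >= min_reads) & mask[None, :] & np.isfinite(slopes)
    if not ok.any():
        return 1.0
    var_scale = 1.0 / np.maximum(n1, 0.5) + 1.0 / np.maximum(n2, 0.5)
    return float(np.mean(slopes[ok] ** 2 / var_scale[ok]))


def lineage_fitness_table(
    dataset: LineageTrackingDataset,
    reference: np.ndarray,
    design: AssayDesign | None = None,
    neutral_flags=None,
    min_reads: int = 20,
    pseudocount: float = 0.5,
    kappa: float | None = None,
) -> pd.DataFrame:
    """Per-cycle fitness of every lineage (vectorized over the table).

    Each usable interval contributes a slope ``delta ln f + reference``
    rescaled to one 8-generation cycle; intervals outside the design's
    measured block, or whose endpoint reads sum below ``min_reads``, are
    skipped. Slopes are combined by inverse-variance weighting under the
    kappa-inflated counting-noise model. Lineages with no usable interval
    are flagged unreliable (fitness reported as NaN).
    """
    design = design or AssayDesign(name="all")
    mask = _interval_mask(dataset, design.measured_block_label)
    if kappa is None:
        kappa = fit_kappa(
            dataset, reference, neutral_flags, interval_mask=mask,
            min_reads=min_reads, pseudocount=pseudocount,
        )
    c = dataset.counts.astype(float)
    tot = c.sum(axis=0) + pseudocount * dataset.n_lineages
    logf = np.log((c + pseudocount) / tot)
    raw = np.diff(logf, axis=1) + reference[None, :]
    gens = dataset.interval_generations.astype(float)
    scale = GENS_PER_CYCLE / gens
    slopes = raw * scale[None, :]
    n1, n2 = c[:, :-1], c[:, 1:]
    var = kappa * (1.0 / np.maximum(n1, 0.5) + 1.0 / np.maximum(n2, 0.5)) * scale[None, :] ** 2
    usable = (n1 + n2 >= min_reads) & mask[None, :] & np.isfinite(slopes)
    w = np.where(usable, 1.0 / var, 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = (w * np.where(usable, slopes, 0.0)).sum(axis=1) / wsum
        se = np.sqrt(1.0 / wsum)
    n_used = usable.sum(axis=1)
    reliable = n_used > 0
    fit = np.where(reliable, fit, np.nan)
    se = np.where(reliable, se, np.nan)
    neutral_call = reliable & (np.abs(fit) < 2 * se)
    return pd.DataFrame(
        {
            "barcode": dataset.barcode_ids,
            "fitness_per_cycle": fit,
            "std_error": se,
            "kappa": kappa,
            "n_intervals": n_used,
            "reliable": reliable,
            "neutral_call": neutral_call,
        }
    )


def estimate_fitness(
    trajectory_counts,
    total_counts,
    generations,
    reference: np.ndarray,
    design: AssayDesign | None = None,
    env_labels: list[str] | None = None,
    min_reads: int = 20,
    pseudocount: float = 0.5,
    kappa: float = 1.0,
) -> FitnessEstimate:
    """Fitness of a single lineage trajectory (see ``lineage_fitness_table``).

    ``trajectory_counts`` are the lineage's reads per timepoint and
    ``total_counts`` the per-timepoint totals of the pool it lives in.
    """
    c = np.asarray(trajectory_counts, float)
    tot = np.asarray(total_counts, float)
    gens = np.diff(np.asarray(generations, float))
    design = design or AssayDesign(name="single")
    if design.measured_block_label is not None:
        if env_labels is None:
            raise ValueError("block restriction needs per-interval env labels")
        mask = np.array([e == design.measured_block_label for e in env_labels])
        if not mask.any():
            raise ValueError(
                f"no interval in environment {design.measured_block_label!r}"
            )
    else:
        mask = np.ones(c.size - 1, dtype=bool)
    logf = np.log((c + pseudocount) / tot)
    raw = np.diff(logf) + np.asarray(reference, float)
    scale = GENS_PER_CYCLE / gens
    slopes = raw * scale
    var = kappa * (1.0 / np.maximum(c[:-1], 0.5) + 1.0 / np.maximum(c[1:], 0.5)) * scale**2
    usable = (c[:-1] + c[1:] >= min_reads) & mask & np.isfinite(slopes)
    if not usable.any():
        return FitnessEstimate(np.nan, np.nan, kappa, 0, False, False)
    w = 1.0 / var[usable]
    fit = float((w * slopes[usable]).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    return FitnessEstimate(fit, se, kappa, int(usable.sum()), True, abs(fit) < 2 * se)


def block_restricted_fitness(
    dataset: LineageTrackingDataset,
    reference: np.ndarray,
    schedule: EnvironmentSchedule | None,
    label: str,
    neutral_flags=None,
    min_reads: int = 20,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-lineage fitness measured only over intervals in one environment.

    Identical to :func:`lineage_fitness_table` with the slope average and
    the neutral noise parameter both restricted to intervals whose
    environment label matches.
    """
    design = AssayDesign(name=f"restricted:{label}", schedule=schedule,
                         measured_block_label=label)
    return lineage_fitness_table(
        dataset, reference, design, neutral_flags,
        min_reads=min_reads, pseudocount=pseudocount,
    )


def fitness_correlation(fits_a: pd.DataFrame, fits_b: pd.DataFrame):
    """Pearson r (and p) between two fitness tables over jointly reliable lineages."""
    a = fits_a.set_index("barcode")
    b = fits_b.set_index("barcode")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    ok = a["reliable"].to_numpy() & b["reliable"].to_numpy()
    if ok.sum() < 3:
        raise ValueError("need >= 3 lineages reliable in both conditions")
    r, p = stats.pearsonr(
        a["fitness_per_cycle"].to_numpy()[ok], b["fitness_per_cycle"].to_numpy()[ok]
    )
    return float(r), float(p)


def combine_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance average of per-lineage fitness across replicates."""
    if not tables:
        raise ValueError("no replicate tables given")
    base = tables[0][["barcode"]].copy()
    w_sum = np.zeros(len(base))
    ws_sum = np.zeros(len(base))
    n_used = np.zeros(len(base), dtype=int)
    for t in tables:
        ok = t["reliable"].to_numpy() & np.isfinite(t["std_error"].to_numpy())
        w = np.where(ok, 1.0 / t["std_error"].to_numpy() ** 2, 0.0)
        w_sum += w
        ws_sum += w * np.where(ok, t["fitness_per_cycle"].to_numpy(), 0.0)
        n_used += t["n_intervals"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = ws_sum / w_sum
        se = np.sqrt(1.0 / w_sum)
    reliable = w_sum > 0
    base["fitness_per_cycle"] = np.where(reliable, fit, np.nan)
    base["std_error"] = np.where(reliable, se, np.nan)
    base["kappa"] = float(np.mean([t["kappa"].iloc[0] for t in tables]))
    base["n_intervals"] = n_used
    base["reliable"] = reliable
    base["neutral_call"] = reliable & (np.abs(base["fitness_per_cycle"]) < 2 * base["std_error"])
    return base
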