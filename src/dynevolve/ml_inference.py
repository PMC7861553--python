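"""Maximum-likelihood inference of lineage composition across environments.

Each well-read lineage trajectory within a single environment segment is
explained by one of four generative models, all deterministic in expectation
with Poisson read noise:

* ``ONE_PARAM`` — a single clone of fitness ``s``;
* ``TWO_PARAM`` — a neutral background plus a mutant of fitness ``s``
  establishing at generation ``tau``;
* ``THREE_PARAM_RISING`` — a background of fitness ``s0`` plus a mutant of
  (total) fitness ``s`` establishing at ``tau``;
* ``THREE_PARAM_MIX`` — two founder clones of fitnesses ``s1``/``s2``
  present from the segment start, with initial fraction ``mix_fraction``
  of the second.

Clones grow as ``n(t+dt) = n(t) exp((s - s_bar) dt)`` against the
population mean fitness ``s_bar(t)``; an establishing mutant enters at the
branching-process establishment size ``1/s`` at time ``tau`` (``tau`` may
precede the segment: the mutant then pre-exists). Expected reads are
``frequency x depth`` and the likelihood is Poisson over timepoints.

Model selection uses AIC (``2k - 2 lnL``) by default, or the parsimony
rule that picks the lowest-parameter model whose implied average lineage
fitness matches the measured log-slope within two counting-noise standard
errors. An inferred ``tau`` is flagged infeasible when it is earlier than
the segment start by more than ``ln(Ns s)/s`` generations — a mutant that
old would already have swept the population.

The population mean fitness can be estimated four ways: from a thread of
similarly behaving (presumed neutral) lineages, from the bulk of lineage
slopes, from the decay of flagged neutral lineages, or from lineages of
known fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import gammaln

from .fitness_assay import mean_fitness_reference
from .lineage_data import LineageTrackingDataset

__all__ = [
    "ModelId",
    "MutantModelFit",
    "MeanFitnessTrajectory",
    "mean_fitness_thread",
    "mean_fitness_slopes",
    "mean_fitness_decaying_neutrals",
    "mean_fitness_known_lineages",
    "lineage_log_likelihood",
    "simulate_model_counts",
    "fit_lineage",
    "second_environment_fit",
    "segment_bounds",
    "select_top_lineages",
]


class ModelId(str, Enum):
    ONE_PARAM = "ONE_PARAM"
    TWO_PARAM = "TWO_PARAM"
    THREE_PARAM_RISING = "THREE_PARAM_RISING"
    THREE_PARAM_MIX = "THREE_PARAM_MIX"


N_PARAMS = {
    ModelId.ONE_PARAM: 1,
    ModelId.TWO_PARAM: 2,
    ModelId.THREE_PARAM_RISING: 3,
    ModelId.THREE_PARAM_MIX: 3,
}

_EXP_CLIP = 500.0


@dataclass
class MutantModelFit:
    """A fitted lineage model for one environment segment."""

    model: ModelId
    params: dict
    log_likelihood: float
    aic: float
    feasible_tau: bool = True
    converged: bool = True

    @property
    def s_background(self):
        return self.params.get("s0", self.params.get("s1"))

    @property
    def s_mutant(self):
        return self.params.get("s", self.params.get("s2"))

    @property
    def tau(self):
        return self.params.get("tau")

    @property
    def mix_fraction(self):
        return self.params.get("mix_fraction")


@dataclass
class MeanFitnessTrajectory:
    """Per-interval population mean fitness, per generation.

    ``generations`` are the sampled timepoints; ``per_generation[i]`` is
    the mean fitness over interval ``[generations[i], generations[i+1])``.
    NaN marks intervals where the method could not produce an estimate.
    """

    generations: np.ndarray
    per_generation: np.ndarray
    method: str

    def __post_init__(self):
        self.generations = np.asarray(self.generations, float)
        self.per_generation = np.asarray(self.per_generation, float)
        if self.per_generation.size != self.generations.size - 1:
            raise ValueError("need one mean-fitness value per interval")

    def increments(self) -> np.ndarray:
        """Per-interval integrated mean-fitness increments."""
        return self.per_generation * np.diff(self.generations)

    def cumulative(self) -> np.ndarray:
        """Integral of the mean fitness at each timepoint (0 at the first)."""
        inc = np.nan_to_num(self.increments())
        return np.concatenate([[0.0], np.cumsum(inc)])

    def cumulative_at(self, t) -> np.ndarray:
        """Integral of the mean fitness from the first timepoint to ``t``.

        Mean fitness is taken as 0 before the first timepoint and held at
        its last interval value after the last.
        """
        cum = self.cumulative()
        t = np.asarray(t, float)
        out = np.interp(t, self.generations, cum)
        after = t > self.generations[-1]
        if np.any(after) and self.per_generation.size:
            last = np.nan_to_num(self.per_generation[-1])
            out = np.where(after, cum[-1] + last * (t - self.generations[-1]), out)
        return out

    def restrict(self, lo_idx: int, hi_idx: int) -> "MeanFitnessTrajectory":
        """Sub-trajectory over timepoints ``[lo_idx, hi_idx]``."""
        return MeanFitnessTrajectory(
            self.generations[lo_idx : hi_idx + 1],
            self.per_generation[lo_idx:hi_idx],
            self.method,
        )


# ----------------------------------------------------- mean-fitness methods


def segment_bounds(dataset: LineageTrackingDataset) -> list[tuple[str, int, int]]:
    """Environment segments as ``(label, first timepoint idx, last idx)``.

    A segment is a maximal run of intervals sharing one environment label;
    the boundary timepoint belongs to both adjacent segments.
    """
    labels = dataset.env_labels
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((labels[start], start, i))
            start = i
    return out


def _log_frequencies(dataset, pseudocount=0.5):
    c = dataset.counts.astype(float)
    tot = c.sum(axis=0) + pseudocount * dataset.n_lineages
    return np.log((c + pseudocount) / tot)


def mean_fitness_thread(
    dataset: LineageTrackingDataset,
    n_threads: int = 10,
    max_lineages: int = 2000,
    min_reads: int = 20,
    monotone_tol: float = 0.02,
) -> MeanFitnessTrajectory:
    """Mean fitness from a thread of similarly behaving lineages.

    Lineages with adequate reads are grouped by the shape of their
    standardized log-frequency trajectories (average-linkage agglomerative
    clustering on correlation distance). The largest group whose mean
    log-frequency trajectory decays monotonically is taken as the
    presumptive-neutral cohort; minus its mean per-generation log-slope is
    the mean-fitness estimate. Raises if no decaying thread exists (use the
    decaying-neutrals method then).
    """
    if dataset.n_lineages < 100:
        raise ValueError("thread mean fitness needs >= 100 lineages")
    ok = dataset.counts.min(axis=1) >= min_reads
    idx = np.flatnonzero(ok)
    if idx.size < n_threads:
        raise ValueError(
            "no decaying thread found (too few well-read lineages); "
            "use the decaying-neutrals method"
        )
    if idx.size > max_lineages:
        order = np.argsort(-dataset.counts[idx].mean(axis=1))
        idx = idx[order[:max_lineages]]
    logf = _log_frequencies(dataset)[idx]
    z = logf - logf.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    z = z / np.where(sd > 0, sd, 1.0)[:, None]
    d = pdist(z, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)
    link = hierarchy.linkage(d, method="average")
    groups = hierarchy.fcluster(link, t=n_threads, criterion="maxclust")
    order = sorted(np.unique(groups), key=lambda g: -(groups == g).sum())
    gens = dataset.generations.astype(float)
    for g in order:
        members = groups == g
        mean_traj = logf[members].mean(axis=0)
        if np.all(np.diff(mean_traj) < monotone_tol):
            sbar = -np.diff(mean_traj) / np.diff(gens)
            return MeanFitnessTrajectory(gens, sbar, method="thread")
    raise ValueError(
        "no monotonically decaying thread found; use the decaying-neutrals method"
    )


def mean_fitness_slopes(
    dataset: LineageTrackingDataset, min_reads: int = 20
) -> MeanFitnessTrajectory:
    """Mean fitness as minus the median per-generation lineage log-slope.

    Assumes the typical well-read lineage is neutral; biased upward once
    most surviving lineages carry beneficial mutations.
    """
    logf = _log_frequencies(dataset)
    gens = dataset.generations.astype(float)
    slopes = np.diff(logf, axis=1) / np.diff(gens)[None, :]
    ok = (dataset.counts[:, :-1] + dataset.counts[:, 1:]) >= min_reads
    sbar = np.array(
        [
            -np.median(slopes[ok[:, j], j]) if ok[:, j].any() else np.nan
            for j in range(slopes.shape[1])
        ]
    )
    return MeanFitnessTrajectory(gens, sbar, method="slopes")


def mean_fitness_decaying_neutrals(
    dataset: LineageTrackingDataset, neutral_flags=None, **kw
) -> MeanFitnessTrajectory:
    """Mean fitness from the frequency decay of flagged neutral lineages."""
    inc = mean_fitness_reference(dataset, neutral_flags, **kw)
    gens = dataset.generations.astype(float)
    return MeanFitnessTrajectory(gens, inc / np.diff(gens), method="decaying_neutrals")


def mean_fitness_known_lineages(
    dataset: LineageTrackingDataset, known_fitness, pseudocount: float = 0.5
) -> MeanFitnessTrajectory:
    """Mean fitness from lineages of known per-generation fitness.

    ``known_fitness`` holds one fitness per lineage (NaN = unknown); the
    interval mean fitness is the read-frequency-weighted average over known
    lineages at the interval midpoint (average of the endpoint weights).
    """
    s = np.asarray(known_fitness, float)
    known = np.isfinite(s)
    if known.sum() < 1:
        raise ValueError("no lineages of known fitness")
    c = dataset.counts.astype(float) + pseudocount
    f = c / c.sum(axis=0, keepdims=True)
    w = 0.5 * (f[:, :-1] + f[:, 1:])
    w = w[known]
    sbar = (w * s[known, None]).sum(axis=0) / w.sum(axis=0)
    gens = dataset.generations.astype(float)
    return MeanFitnessTrajectory(gens, sbar, method="known_lineages")


# ----------------------------------------------------------- model library


def _expected_counts(model, params, gens, sbar_cum, n0, depth, n_ref):
    """Expected reads per timepoint under a lineage model.

    ``n0`` is the observed lineage size at the segment start in
    reference-population units (``count/depth * n_ref``); ``sbar_cum`` the
    integrated mean fitness at each timepoint (0 at the first).
    """
    t = gens - gens[0]
    if model is ModelId.ONE_PARAM:
        n = n0 * np.exp(np.clip(params["s"] * t - sbar_cum, -_EXP_CLIP, _EXP_CLIP))
    elif model in (ModelId.TWO_PARAM, ModelId.THREE_PARAM_RISING):
        s0 = params.get("s0", 0.0)
        s = params["s"]
        tau = params["tau"] - gens[0]
        adv = max(s - s0, 1e-4)
        # integrated mean fitness at tau; 0 before the observed window
        sbar_tau = np.interp(tau, t, sbar_cum) if tau > 0 else 0.0
        grown = np.where(t >= tau, s * (t - tau) - (sbar_cum - sbar_tau), -np.inf)
        nm = (1.0 / adv) * np.exp(np.clip(grown, -_EXP_CLIP, _EXP_CLIP))
        nb0 = max(n0 - nm[0], 0.0)
        nb = nb0 * np.exp(np.clip(s0 * t - sbar_cum, -_EXP_CLIP, _EXP_CLIP))
        n = nb + nm
    elif model is ModelId.THREE_PARAM_MIX:
        s1, s2, phi = params["s1"], params["s2"], params["mix_fraction"]
        n = n0 * (
            (1 - phi) * np.exp(np.clip(s1 * t - sbar_cum, -_EXP_CLIP, _EXP_CLIP))
            + phi * np.exp(np.clip(s2 * t - sbar_cum, -_EXP_CLIP, _EXP_CLIP))
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown model {model}")
    lam = n / n_ref * depth
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError("non-finite expected counts (overflow guard)")
    return np.maximum(lam, 1e-12)


def _model_components(model, params, gens, sbar_cum):
    """Per-timepoint (background shape, absolute mutant size) in cell units.

    The background scales with the lineage's initial size (a nuisance
    profiled out of the likelihood); an establishing mutant has an absolute
    size set by the ``1/s`` establishment convention.
    """
    t = gens - gens[0]
    if model is ModelId.ONE_PARAM:
        b = np.exp(np.clip(params["s"] * t - sbar_cum, -_EXP_CLIP, _EXP_CLIP))
        m = np.zeros_like(b)
    elif model in (ModelId.TWO_PARAM, ModelId.THREE_PARAM_RISING):
        s0 = params.get("s0", 0.0)
        s = params["s"]
        tau = params["tau"] - gens[0]
        adv = max(s - s0, 1e-4)
        sbar_tau = np.interp(tau, t, sbar_cum) if tau > 0 else 0.0
        grown = np.where(t >= tau, s * (t - tau) - (sbar_cum - sbar_tau), -np.inf)
        m = (1.0 / adv) * np.exp(np.clip(grown, -_EXP_CLIP, _EXP_CLIP))
        b = np.exp(np.clip(s0 * t - sbar_cum, -_EXP_CLIP, _EXP_CLIP))
    elif model is ModelId.THREE_PARAM_MIX:
        s1, s2, phi = params["s1"], params["s2"], params["mix_fraction"]
        b = (1 - phi) * np.exp(np.clip(s1 * t - sbar_cum, -_EXP_CLIP, _EXP_CLIP)) + (
            phi
        ) * np.exp(np.clip(s2 * t - sbar_cum, -_EXP_CLIP, _EXP_CLIP))
        m = np.zeros_like(b)
    else:  # pragma: no cover
        raise ValueError(f"unknown model {model}")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(m))):
        raise FloatingPointError("non-finite expected counts (overflow guard)")
    return b, m


def _profile_background(counts, b_reads, m_reads):
    """ML initial background size given fixed shapes, by Newton iteration.

    The Poisson log-likelihood is concave in the background scale ``x``
    (``lambda = x b + m``); with no fixed mutant term the maximizer is
    closed-form.
    """
    c = counts
    if not m_reads.any():
        tot_b = b_reads.sum()
        return float(max(c.sum() / max(tot_b, 1e-300), 0.0))
    x = max((c.sum() - m_reads.sum()) / max(b_reads.sum(), 1e-300), 0.0)
    for _ in range(30):
        lam = x * b_reads + m_reads + 1e-12
        score = float((c * b_reads / lam).sum() - b_reads.sum())
        if x == 0.0 and score <= 0:
            break
        curv = float((c * b_reads**2 / lam**2).sum())
        if curv <= 0:
            break
        step = score / curv
        x_new = max(x + step, 0.0)
        if abs(x_new - x) <= 1e-9 * (1.0 + x):
            x = x_new
            break
        x = x_new
    return x


def _profiled_lambda(model, params, gens, sbar_cum, counts, depth, n_ref):
    """Expected reads with the initial background size profiled out."""
    b, m = _model_components(model, params, gens, sbar_cum)
    k = depth / n_ref
    b_reads, m_reads = b * k, m * k
    x = _profile_background(counts, b_reads, m_reads)
    lam = np.maximum(x * b_reads + m_reads, 1e-12)
    return lam, x


def lineage_log_likelihood(
    counts,
    generations,
    model: ModelId,
    params: dict,
    mean_fitness: MeanFitnessTrajectory,
    depth: float,
    n_ref: float = 5e7,
) -> float:
    """Poisson log-likelihood of a lineage segment under one model (nats).

    The lineage's initial (background) size is a nuisance parameter common
    to every model and is profiled out at each evaluation, so the named
    parameter counts compare like for like under AIC.
    """
    c = np.asarray(counts, float)
    gens = np.asarray(generations, float)
    sbar_cum = mean_fitness.cumulative_at(gens) - mean_fitness.cumulative_at(gens[0])
    lam, _ = _profiled_lambda(model, params, gens, sbar_cum, c, depth, n_ref)
    return float(np.sum(c * np.log(lam) - lam - gammaln(c + 1)))


def simulate_model_counts(
    model: ModelId,
    params: dict,
    generations,
    mean_fitness: MeanFitnessTrajectory,
    depth: float,
    n_ref: float = 5e7,
    n0_cells: float = 5e3,
    rng=None,
    noiseless: bool = False,
) -> np.ndarray:
    """Draw a read-count trajectory from a lineage model (Poisson noise).

    Generates the data the likelihood assumes: expected counts from the
    model's deterministic clone dynamics, then Poisson sampling (or the
    exact expectations with ``noiseless=True``). Used by recovery studies
    and fixtures.
    """
    gens = np.asarray(generations, float)
    sbar_cum = mean_fitness.cumulative_at(gens) - mean_fitness.cumulative_at(gens[0])
    lam = _expected_counts(model, params, gens, sbar_cum, n0_cells, depth, n_ref)
    if noiseless:
        return lam
    rng = np.random.default_rng(rng)
    return rng.poisson(lam).astype(np.int64)


def _pack(model, x, t0):
    if model is ModelId.ONE_PARAM:
        return {"s": x[0]}
    if model is ModelId.TWO_PARAM:
        return {"s": x[0], "tau": x[1]}
    if model is ModelId.THREE_PARAM_RISING:
        return {"s0": x[0], "s": x[1], "tau": x[2]}
    return {"s1": x[0], "s2": x[1], "mix_fraction": x[2]}


def _starts_and_bounds(model, t0, t1, seeds, n0):
    span = t1 - t0
    s_lo, s_hi = -0.5, 0.6
    if model is ModelId.ONE_PARAM:
        bounds = [(s_lo, s_hi)]
        starts = [[-0.05], [0.0], [0.05], [0.15]]
    elif model is ModelId.TWO_PARAM:
        bounds = [(1e-3, s_hi), (t0 - 3 * span, t1)]
        starts = [
            [s, tau]
            for s in (0.05, 0.15)
            for tau in (t0 - span / 2, t0 + span / 4, t0 + span / 2, t0 + 3 * span / 4)
        ]
    elif model is ModelId.THREE_PARAM_RISING:
        bounds = [(s_lo, 0.5), (1e-3, s_hi), (t0 - 3 * span, t1)]
        starts = [
            [0.0, 0.1, t0 + span / 3],
            [0.05, 0.2, t0 + span / 2],
            [-0.05, 0.1, t0 + span / 4],
            [0.02, 0.05, t0],
        ]
    else:
        # a founder clone is at least one cell of the lineage's n0
        phi_lo = min(0.4, max(1e-6, 1.0 / max(n0, 2.0)))
        bounds = [(s_lo, s_hi), (s_lo, s_hi), (phi_lo, 0.5)]
        starts = [
            [0.0, 0.1, 0.1],
            [0.0, 0.2, 0.05],
            [0.05, 0.15, 0.2],
            [-0.05, 0.1, 0.1],
        ]
    starts = starts + seeds.get(model, [])
    return starts, bounds


_PARAM_STEP = {"s": 1e-6, "tau": 1e-3}


def _fd_steps(model):
    """Finite-difference steps matched to each parameter's scale.

    Establishment times live on a generations scale where the default
    derivative step would vanish into float noise.
    """
    if model is ModelId.ONE_PARAM:
        return np.array([1e-6])
    if model is ModelId.TWO_PARAM:
        return np.array([1e-6, 1e-3])
    if model is ModelId.THREE_PARAM_RISING:
        return np.array([1e-6, 1e-6, 1e-3])
    return np.array([1e-6, 1e-6, 1e-6])


def _grid_seed(model, nll, t0, t1):
    """Coarse likelihood grid over (s, tau) to seed the local optimizer."""
    if model is not ModelId.TWO_PARAM:
        return []
    span = t1 - t0
    s_grid = np.geomspace(0.02, 0.4, 8)
    tau_grid = np.linspace(t0 - span, t1, 13)
    scored = [
        (nll([s, tau]), [s, tau]) for s in s_grid for tau in tau_grid
    ]
    scored.sort(key=lambda p: p[0])
    return [x for _, x in scored[:2]]


def _fit_one_model(model, counts, gens, mean_fitness, depth, n_ref, seeds):
    t0, t1 = gens[0], gens[-1]
    n0 = max(counts[0], 0.5) / depth * n_ref
    starts, bounds = _starts_and_bounds(model, t0, t1, seeds, n0)

    def nll(x):
        try:
            return -lineage_log_likelihood(
                counts, gens, model, _pack(model, x, t0), mean_fitness, depth, n_ref
            )
        except FloatingPointError:
            return 1e12

    starts = starts + _grid_seed(model, nll, t0, t1)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"eps": _fd_steps(model), "maxfun": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = _pack(model, best.x, t0)
    lnl = -float(best.fun)
    return MutantModelFit(
        model=model,
        params=params,
        log_likelihood=lnl,
        aic=2 * N_PARAMS[model] - 2 * lnl,
        converged=bool(best.success),
    )


def _tau_feasible(
    fit: MutantModelFit, t0: float, sat_size: float, tau_floor: float | None
) -> bool:
    """Can the inferred establishment time be real?

    Two constraints: a mutant establishing more than ``ln(Ns s)/s``
    generations before the segment would already have swept the
    population; and ``tau_floor``, when given, marks the generation before
    which the lineage did not exist (e.g. the start of library prep), so
    an earlier establishment means the trajectory is really an initial mix
    of founder clones.
    """
    tau = fit.tau
    if tau is None:
        return True
    s_adv = max((fit.params.get("s", 0.0)) - fit.params.get("s0", 0.0), 1e-4)
    bound = t0 - math.log(max(sat_size * s_adv, math.e)) / s_adv
    if tau_floor is not None:
        bound = max(bound, tau_floor)
    return tau >= bound


def _measured_slope(counts, gens, sbar_total):
    c0, c1 = max(counts[0], 0.5), max(counts[-1], 0.5)
    span = gens[-1] - gens[0]
    slope = (math.log(c1 / c0) + sbar_total) / span
    se = math.sqrt(1.0 / c0 + 1.0 / c1) / span
    return slope, se


def _implied_slope(fit, counts, gens, mean_fitness, depth, n_ref):
    gens = np.asarray(gens, float)
    sbar_cum = mean_fitness.cumulative_at(gens) - mean_fitness.cumulative_at(gens[0])
    lam, _ = _profiled_lambda(
        fit.model, fit.params, gens, sbar_cum, np.asarray(counts, float), depth, n_ref
    )
    span = gens[-1] - gens[0]
    return (math.log(lam[-1] / lam[0]) + sbar_cum[-1]) / span


def fit_lineage(
    counts,
    generations,
    mean_fitness: MeanFitnessTrajectory,
    depth: float,
    n_ref: float = 5e7,
    saturation_size: float = 256 * 5e7,
    selection_criterion: str = "aic",
    models: tuple[ModelId, ...] = tuple(ModelId),
    tau_floor: float | None = None,
) -> dict:
    """Fit the four lineage models to one environment segment and select.

    Returns ``{"best": MutantModelFit, "fits": {model: fit}}``. Fitting is
    bounded L-BFGS-B from deterministic multi-starts, with nested models'
    optima used to seed the richer ones so the maximized log-likelihood is
    monotone non-decreasing in parameter count. Selection prefers fits
    with a feasible establishment time (``tau_floor`` optionally marks
    when the lineage came into existence); fits whose ``tau`` cannot be
    real lose to feasible ones regardless of score.
    """
    c = np.asarray(counts, float)
    gens = np.asarray(generations, float)
    if c.size < 3:
        raise ValueError("need >= 3 timepoints in the segment")
    t0, t1 = gens[0], gens[-1]
    fits: dict[ModelId, MutantModelFit] = {}
    seeds: dict[ModelId, list] = {}
    for model in (
        ModelId.ONE_PARAM,
        ModelId.TWO_PARAM,
        ModelId.THREE_PARAM_RISING,
        ModelId.THREE_PARAM_MIX,
    ):
        if model not in models:
            continue
        fit = _fit_one_model(model, c, gens, mean_fitness, depth, n_ref, seeds)
        # nested-model floor: a richer model can always emulate a simpler one
        floor = _nested_floor(model, fits, c, gens, mean_fitness, depth, n_ref, t1)
        if floor is not None and floor[1] > fit.log_likelihood:
            fit = MutantModelFit(
                model=model,
                params=floor[0],
                log_likelihood=floor[1],
                aic=2 * N_PARAMS[model] - 2 * floor[1],
                converged=True,
            )
        fit.feasible_tau = _tau_feasible(fit, t0, saturation_size, tau_floor)
        fits[model] = fit
        if model is ModelId.ONE_PARAM:
            s1 = fit.params["s"]
            seeds[ModelId.THREE_PARAM_RISING] = [[s1, s1 + 0.05, t1]]
            seeds[ModelId.THREE_PARAM_MIX] = [[s1, s1, 0.25], [s1, s1 + 0.1, 0.1]]
        if model is ModelId.TWO_PARAM:
            seeds.setdefault(ModelId.THREE_PARAM_RISING, []).append(
                [0.0, fit.params["s"], fit.params["tau"]]
            )
            # a founder-mix clone at the equivalent initial fraction mimics
            # a mutant establishing at tau
            s2, tau2 = fit.params["s"], fit.params["tau"]
            n0 = max(c[0], 0.5) / depth * n_ref
            phi_eq = float(
                np.clip((1.0 / s2) * math.exp(-min(s2 * (tau2 - t0), _EXP_CLIP)) / n0,
                        1e-6, 0.5)
            )
            seeds.setdefault(ModelId.THREE_PARAM_MIX, []).append([0.0, s2, phi_eq])
    best = _select(fits, selection_criterion, c, gens, mean_fitness, depth, n_ref)
    return {"best": best, "fits": fits}


def _nested_floor(model, fits, c, gens, mean_fitness, depth, n_ref, t1):
    """Parameters emulating the best simpler model inside a richer one."""
    cands = []
    if model is ModelId.THREE_PARAM_RISING:
        if ModelId.TWO_PARAM in fits:
            f = fits[ModelId.TWO_PARAM]
            cands.append({"s0": 0.0, "s": f.params["s"], "tau": f.params["tau"]})
        if ModelId.ONE_PARAM in fits:
            s = fits[ModelId.ONE_PARAM].params["s"]
            cands.append({"s0": s, "s": s + 1e-3, "tau": t1})
    elif model is ModelId.THREE_PARAM_MIX and ModelId.ONE_PARAM in fits:
        s = fits[ModelId.ONE_PARAM].params["s"]
        cands.append({"s1": s, "s2": s, "mix_fraction": 0.5})
    best = None
    for p in cands:
        try:
            lnl = lineage_log_likelihood(c, gens, model, p, mean_fitness, depth, n_ref)
        except FloatingPointError:
            continue
        if best is None or lnl > best[1]:
            best = (p, lnl)
    return best


def _select(fits, criterion, c, gens, mean_fitness, depth, n_ref):
    pool = [f for f in fits.values() if f.feasible_tau] or list(fits.values())
    if criterion == "aic":
        return min(pool, key=lambda f: f.aic)
    if criterion != "lineage_fitness":
        raise ValueError(f"unknown selection criterion {criterion!r}")
    sbar_total = float(
        mean_fitness.cumulative_at(gens[-1]) - mean_fitness.cumulative_at(gens[0])
    )
    slope, se = _measured_slope(c, gens, sbar_total)
    for fit in sorted(pool, key=lambda f: (N_PARAMS[f.model], f.model.value)):
        implied = _implied_slope(fit, c, gens, mean_fitness, depth, n_ref)
        if abs(implied - slope) <= 2 * se:
            return fit
    return min(pool, key=lambda f: f.aic)


def select_top_lineages(
    dataset: LineageTrackingDataset, end_timepoint: int, n: int = 1000
) -> np.ndarray:
    """Indices of the N largest lineages at the end of a segment."""
    col = dataset.counts[:, end_timepoint]
    order = np.argsort(-col, kind="stable")
    return order[: min(n, order.size)]


def _boundary_composition(fit: MutantModelFit, counts, gens, mean_fitness, depth, n_ref):
    """Clone mix (background fraction, mutant fraction) at the segment end."""
    gens = np.asarray(gens, float)
    sbar_cum = mean_fitness.cumulative_at(gens) - mean_fitness.cumulative_at(gens[0])
    t = gens - gens[0]
    if fit.model is ModelId.ONE_PARAM:
        return 1.0, 0.0
    if fit.model is ModelId.THREE_PARAM_MIX:
        s1, s2, phi = fit.params["s1"], fit.params["s2"], fit.params["mix_fraction"]
        a = (1 - phi) * math.exp(min(s1 * t[-1] - sbar_cum[-1], _EXP_CLIP))
        b = phi * math.exp(min(s2 * t[-1] - sbar_cum[-1], _EXP_CLIP))
        return a / (a + b), b / (a + b)
    b, m = _model_components(fit.model, fit.params, gens, sbar_cum)
    k = depth / n_ref
    nb0 = _profile_background(np.asarray(counts, float), b * k, m * k)
    nb_end = nb0 * b[-1]
    nm_end = m[-1]
    tot = nb_end + nm_end
    if tot <= 0:
        return 1.0, 0.0
    return nb_end / tot, nm_end / tot


def second_environment_fit(
    fit_env1: MutantModelFit,
    counts_env1,
    gens_env1,
    mean_fitness_env1: MeanFitnessTrajectory,
    counts_env2,
    gens_env2,
    mean_fitness_env2: MeanFitnessTrajectory,
    depth: float,
    n_ref: float = 5e7,
    neutral_threshold: float = 0.005,
) -> dict:
    """Refit a lineage in the following environment with founders fixed.

    The clone composition at the environment boundary is taken from the
    environment-1 maximum-likelihood state; segment 2 is then fitted with
    that founder mix frozen and only the clones' fitnesses in the new
    environment free. Returns the refit plus the cross-environment class
    (``neutral``/``adaptive``/``deleterious`` per environment, from the
    dominant fitted coefficients against ``neutral_threshold`` per
    generation).
    """
    c2 = np.asarray(counts_env2, float)
    g2 = np.asarray(gens_env2, float)
    fb, fm = _boundary_composition(
        fit_env1, np.asarray(counts_env1, float), gens_env1, mean_fitness_env1, depth, n_ref
    )
    if fm < 1e-6:
        res = fit_lineage(
            c2, g2, mean_fitness_env2, depth, n_ref,
            models=(ModelId.ONE_PARAM,),
        )
        fit2 = res["best"]
    else:
        def nll(x):
            p = {"s1": x[0], "s2": x[1], "mix_fraction": fm}
            try:
                return -lineage_log_likelihood(
                    c2, g2, ModelId.THREE_PARAM_MIX, p, mean_fitness_env2, depth, n_ref
                )
            except FloatingPointError:
                return 1e12

        best = None
        for x0 in ([0.0, 0.0], [0.0, 0.1], [0.05, -0.05], [0.1, 0.2]):
            r = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=[(-0.5, 0.6), (-0.5, 0.6)]
            )
            if best is None or r.fun < best.fun:
                best = r
        lnl = -float(best.fun)
        fit2 = MutantModelFit(
            model=ModelId.THREE_PARAM_MIX,
            params={"s1": best.x[0], "s2": best.x[1], "mix_fraction": fm},
            log_likelihood=lnl,
            aic=2 * 2 - 2 * lnl,
            converged=bool(best.success),
        )

    def classify(fit, mutant_weight):
        if fit.model is ModelId.ONE_PARAM:
            s = fit.params["s"]
        elif fit.model is ModelId.THREE_PARAM_MIX:
            s = fit.params["s2"] if mutant_weight else max(
                fit.params["s1"], fit.params["s2"], key=abs
            )
        else:
            s = fit.params["s"]
        if s > neutral_threshold:
            return "adaptive"
        if s < -neutral_threshold:
            return "deleterious"
        return "neutral"

    cls1 = classify(fit_env1, mutant_weight=True)
    cls2 = classify(fit2, mutant_weight=fm >= 1e-6)
    return {"fit": fit2, "class": f"{cls1}/{cls2}", "boundary_mutant_fraction": fm}
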