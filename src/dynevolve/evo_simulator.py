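"""Poisson branching-process simulator of barcoded serial-transfer evolution.

The model follows a pool of uniquely barcoded lineages through a schedule of
growth environments. Within an environment, every clone (a set of cells
sharing the same mutations) grows each generation by a Poisson draw centred
on its size times its growth multiplier ``2 * exp(s)``: a neutral clone
(``s = 0``) doubles in expectation, so eight generations of growth exactly
offset the 1/256 transfer bottleneck and neutral lineage frequencies are
martingales. ``s`` is an additive per-generation selection coefficient in
natural-log units, so a clone's log-frequency drifts at ``s - s_bar`` per
generation relative to the population mean fitness ``s_bar``.

New beneficial mutations arrive by Poisson mutation supply at rate
``mu_env`` per cell per generation, with effects drawn from a uniform DFE
specific to the current environment. Within a lineage that already carries
mutants, new mutations arise only on the background of the clone that was
most frequent in the lineage at the beginning of the current environment
period. When the environment switches, every carried mutation that has
never been exposed to the new environment is independently assigned a sign
(neutral / deleterious / beneficial with probabilities Pn / Pd / Pb) and a
magnitude from the new environment's DFE — fitnesses in the two
environments are uncorrelated by construction.

Every passage (8 generations), the population is rescaled to its saturation
size and put through the transfer bottleneck, both by Poisson sampling, and
extinct clones are pruned. Read sampling at a timepoint draws each
lineage's count from Poisson(frequency x depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_schedule import ENV_CODES, EnvironmentSchedule
from .lineage_data import LineageTrackingDataset

__all__ = [
    "SimulatorParams",
    "SimulatorParameterError",
    "Clone",
    "SimulatedPopulation",
    "SimulationResult",
    "init_library",
    "step_generation",
    "passage",
    "assign_env_fitness",
    "sample_reads",
    "run_experiment",
]


class SimulatorParameterError(ValueError):
    """Raised for invalid simulator parameter combinations."""


def _default_dfe():
    return {"F": (0.0, 0.125), "G": (0.0, 0.125), "P": (0.0, 0.125)}


@dataclass
class SimulatorParams:
    """Configuration of one simulated evolution experiment.

    Attributes
    ----------
    n_barcodes
        Number of uniquely barcoded founder lineages.
    prep_generations, prep_mutation_rate
        Length of the simulated library-construction growth and the
        per-cell, per-generation probability of acquiring a beneficial
        mutation during it. Prep mutants carry an effect drawn from the
        DFE of the first environment encountered.
    mu_env
        Per-cell, per-generation beneficial mutation rate during the
        evolution; either a single float or a per-environment mapping.
    dfe_bounds
        Per-environment ``(low, high)`` bounds of the uniform distribution
        of fitness effects, in per-generation units.
    p_neutral, p_deleterious, p_beneficial
        Sign probabilities applied to a carried mutation on first exposure
        to a new environment; must sum to 1.
    saturation_size
        Cells at saturation (Ns). The default corresponds to transferring
        ~5e7 cells that then double 8 times.
    bottleneck_factor
        Fraction of the saturated culture transferred at each passage.
    gens_per_passage
        Generations of growth between passages.
    read_depth
        Sequencing reads per sampled timepoint.
    seed
        Seed of the single generator driving every stochastic draw.
    planted_fitness
        Optional ``{lineage index: {env: s}}`` engineered founder fitness,
        used to seed lineages of known fitness for recovery studies.
    prune
        Drop extinct clones from the active set at each passage. Output
        distributions are unaffected; this is a memory/time optimization.
    """

    n_barcodes: int = 500_000
    prep_generations: int = 16
    prep_mutation_rate: float = 1e-5
    mu_env: float | dict = 1e-5
    dfe_bounds: dict = field(default_factory=_default_dfe)
    p_neutral: float = 1.0 / 3.0
    p_deleterious: float = 1.0 / 3.0
    p_beneficial: float = 1.0 / 3.0
    saturation_size: float = 256 * 5e7
    bottleneck_factor: float = 1.0 / 256.0
    gens_per_passage: int = 8
    read_depth: float = 3e7
    seed: int | None = None
    planted_fitness: dict | None = None
    prune: bool = True

    def __post_init__(self):
        psum = self.p_neutral + self.p_deleterious + self.p_beneficial
        if abs(psum - 1.0) > 1e-9:
            raise SimulatorParameterError(
                f"sign probabilities Pn+Pd+Pb must sum to 1 (got {psum})"
            )
        if min(self.p_neutral, self.p_deleterious, self.p_beneficial) < 0:
            raise SimulatorParameterError("sign probabilities must be >= 0")
        if not (0 < self.bottleneck_factor <= 1):
            raise SimulatorParameterError("bottleneck_factor must be in (0, 1]")
        if self.saturation_size <= 0:
            raise SimulatorParameterError("saturation_size must be > 0")
        if self.n_barcodes < 1 or self.gens_per_passage < 1:
            raise SimulatorParameterError("n_barcodes and gens_per_passage must be >= 1")
        if self.prep_mutation_rate < 0 or any(
            m < 0 for m in self._mu_map().values()
        ):
            raise SimulatorParameterError("mutation rates must be >= 0")
        for env, (lo, hi) in self.dfe_bounds.items():
            if lo > hi:
                raise SimulatorParameterError(
                    f"DFE bounds for {env!r} must satisfy low <= high"
                )

    def _mu_map(self) -> dict:
        if isinstance(self.mu_env, dict):
            return dict(self.mu_env)
        return {env: float(self.mu_env) for env in self.dfe_bounds}

    def mu_for(self, env: str) -> float:
        mu = self._mu_map()
        if env not in mu:
            raise SimulatorParameterError(f"no mutation rate configured for {env!r}")
        return mu[env]

    @property
    def transfer_size(self) -> float:
        """Expected cells transferred at each passage (post-bottleneck)."""
        return self.saturation_size * self.bottleneck_factor


@dataclass
class Clone:
    """Read-only view of one clone inside a lineage."""

    size: int
    fitness_by_env: dict
    mutation_ids: list


_CHUNK = 1 << 16


class SimulatedPopulation:
    """Array-backed state of a simulated barcoded population.

    Clones live in an append-only table (a clone's row index is its
    mutation id); ``size == 0`` marks extinction and the ``active`` index
    array tracks living clones. Per-environment fitness is resolved
    lazily: a mutation's effect in an environment is drawn on the clone's
    first exposure, and additive totals are propagated from the parent
    clone, whose effects are always resolved first (parents predate their
    children by at least one environment period).
    """

    def __init__(self, params: SimulatorParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.envs = sorted(params.dfe_bounds)
        n0 = max(params.n_barcodes, _CHUNK)
        self._cap = n0
        self.n_rows = 0
        self.parent = np.empty(n0, dtype=np.int64)
        self.lineage = np.empty(n0, dtype=np.int64)
        self.size = np.zeros(n0, dtype=np.int64)
        self.own = {e: np.empty(n0) for e in self.envs}
        self.tot = {e: np.empty(n0) for e in self.envs}
        self.batches: list[tuple[int, int]] = []
        self.active = np.empty(0, dtype=np.int64)
        self.current_generation = 0
        self.current_env: str | None = None
        self.feeder_rows = np.full(params.n_barcodes, -1, dtype=np.int64)
        self._mean_fitness_log: list[tuple[int, str, float]] = []

    # ---------------------------------------------------------------- table

    def _grow(self, k: int) -> None:
        need = self.n_rows + k
        if need <= self._cap:
            return
        new_cap = self._cap
        while new_cap < need:
            new_cap *= 2
        for name in ("parent", "lineage", "size"):
            arr = getattr(self, name)
            out = np.zeros(new_cap, dtype=arr.dtype)
            out[: self.n_rows] = arr[: self.n_rows]
            setattr(self, name, out)
        for d in (self.own, self.tot):
            for e in self.envs:
                out = np.empty(new_cap)
                out[: self.n_rows] = d[e][: self.n_rows]
                d[e] = out
        self._cap = new_cap

    def _append_mutants(self, parents: np.ndarray, env: str) -> np.ndarray:
        """Found new size-1 mutant clones on the given parent rows."""
        k = parents.size
        self._grow(k)
        rows = np.arange(self.n_rows, self.n_rows + k)
        self.parent[rows] = parents
        self.lineage[rows] = self.lineage[parents]
        self.size[rows] = 1
        lo, hi = self.params.dfe_bounds[env]
        eff = self.rng.uniform(lo, hi, k)
        for e in self.envs:
            if e == env:
                self.own[e][rows] = eff
                self.tot[e][rows] = self.tot[e][parents] + eff
            else:
                self.own[e][rows] = np.nan
                self.tot[e][rows] = self.tot[e][parents]
        self.batches.append((self.n_rows, self.n_rows + k))
        self.n_rows += k
        self.active = np.concatenate([self.active, rows])
        return rows

    # ------------------------------------------------------------ accessors

    def lineage_sizes(self) -> np.ndarray:
        """Cells per lineage (sum of clone sizes), length ``n_barcodes``."""
        act = self.active
        return np.bincount(
            self.lineage[act],
            weights=self.size[act].astype(float),
            minlength=self.params.n_barcodes,
        ).astype(np.int64)

    def total_size(self) -> int:
        return int(self.size[self.active].sum())

    def lineage_clones(self, lineage_id: int) -> list[Clone]:
        """Living clones of one lineage, as introspection-friendly views."""
        rows = self.active[self.lineage[self.active] == lineage_id]
        out = []
        for r in rows:
            chain = []
            node = int(r)
            while node >= 0 and self.parent[node] >= 0:
                chain.append(node)
                node = int(self.parent[node])
            out.append(
                Clone(
                    size=int(self.size[r]),
                    fitness_by_env={e: float(self.tot[e][r]) for e in self.envs},
                    mutation_ids=chain[::-1],
                )
            )
        return out

    def mean_fitness(self, env: str) -> float:
        """Size-weighted population mean fitness in ``env`` (per generation)."""
        act = self.active
        tot_size = self.size[act].sum()
        if tot_size == 0:
            return float("nan")
        w = self.size[act].astype(float)
        return float((w * self.tot[env][act]).sum() / tot_size)

    def mean_fitness_log(self) -> pd.DataFrame:
        """Recorded per-generation population mean fitness trajectory."""
        return pd.DataFrame(
            self._mean_fitness_log, columns=["generation", "env", "mean_fitness"]
        )

    # ------------------------------------------------------------- dynamics

    def begin_environment(self, env: str) -> None:
        """Resolve fitnesses for ``env`` and fix per-lineage mutation feeders.

        Called at the start of every contiguous same-environment period.
        Mutations without an effect in ``env`` draw sign and magnitude;
        additive totals propagate parent-first (append batches are in
        chronological order, and a parent always predates its children's
        batch). The feeder of each lineage — the clone on whose background
        new mutations arise — is the currently largest clone.
        """
        if env not in self.params.dfe_bounds:
            raise SimulatorParameterError(f"no DFE configured for environment {env!r}")
        p = self.params
        lo, hi = p.dfe_bounds[env]
        own, tot, par = self.own[env], self.tot[env], self.parent
        for start, end in self.batches:
            mask = np.isnan(own[start:end])
            if not mask.any():
                continue
            idx = start + np.flatnonzero(mask)
            u = self.rng.random(idx.size)
            sign = np.where(u < p.p_neutral, 0.0, np.where(u < p.p_neutral + p.p_deleterious, -1.0, 1.0))
            mag = self.rng.uniform(lo, hi, idx.size)
            own[idx] = sign * mag
            tot[idx] = tot[par[idx]] + own[idx]
        self.current_env = env
        self._fix_feeders()

    def _fix_feeders(self) -> None:
        act = self.active
        self.feeder_rows = np.full(self.params.n_barcodes, -1, dtype=np.int64)
        if act.size == 0:
            return
        lin = self.lineage[act]
        order = np.lexsort((-self.size[act], lin))
        lin_sorted = lin[order]
        uniq, first = np.unique(lin_sorted, return_index=True)
        self.feeder_rows[uniq] = act[order[first]]

    def step_generation(self, env: str) -> None:
        """One generation: Poisson growth of every clone, then mutation supply."""
        if env != self.current_env:
            raise RuntimeError(
                f"environment {env!r} not initialized; call assign_env_fitness "
                f"(current: {self.current_env!r})"
            )
        act = self.active
        rng = self.rng
        if act.size:
            lam = self.size[act] * (2.0 * np.exp(self.tot[env][act]))
            self.size[act] = rng.poisson(lam)
        mu = self.params.mu_for(env)
        if mu > 0:
            feeders = self.feeder_rows[self.feeder_rows >= 0]
            if feeders.size:
                n_new = rng.poisson(self.size[feeders] * mu)
                hit = n_new > 0
                if hit.any():
                    parents = np.repeat(feeders[hit], n_new[hit])
                    self._append_mutants(parents, env)
        self.current_generation += 1
        self._mean_fitness_log.append(
            (self.current_generation, env, self.mean_fitness(env))
        )

    def rescale_to_saturation(self) -> None:
        """Poisson rescale of every clone to the saturated culture size Ns."""
        act = self.active
        tot_size = self.size[act].sum()
        if tot_size > 0:
            freq = self.size[act] / tot_size
            self.size[act] = self.rng.poisson(freq * self.params.saturation_size)

    def bottleneck(self) -> None:
        """Poisson transfer bottleneck (1/256 by default); prunes extinct clones."""
        act = self.active
        self.size[act] = self.rng.poisson(self.size[act] * self.params.bottleneck_factor)
        if self.params.prune:
            self.active = act[self.size[act] > 0]

    def passage(self) -> None:
        """Saturation rescale then transfer bottleneck, both Poisson draws.

        The saturated state between the two halves is the culture an
        experimenter harvests; ``run_experiment`` samples reads there.
        """
        self.rescale_to_saturation()
        self.bottleneck()

    def sample_reads(self, depth: float | None = None) -> np.ndarray:
        """Per-lineage read counts, Poisson(lineage frequency x depth)."""
        depth = self.params.read_depth if depth is None else depth
        if depth <= 0:
            raise ValueError("sequencing depth must be > 0")
        sizes = self.lineage_sizes().astype(float)
        tot = sizes.sum()
        if tot == 0:
            return np.zeros(self.params.n_barcodes, dtype=np.int64)
        return self.rng.poisson(sizes / tot * depth).astype(np.int64)

    def richness(self) -> int:
        """Number of lineages with at least one living cell."""
        return int((self.lineage_sizes() > 0).sum())


# --------------------------------------------------------------- operations


def init_library(params: SimulatorParams, first_env: str | None = None) -> SimulatedPopulation:
    """Build the barcoded founder pool and run library-prep mutagenesis.

    Founder lineage sizes are Poisson draws around the post-bottleneck mean
    ``saturation_size x bottleneck_factor / n_barcodes`` and are held
    constant through the ``prep_generations`` of simulated library
    construction, during which each lineage acquires beneficial mutations
    by Poisson supply at ``prep_mutation_rate`` per cell per generation,
    with effects from the DFE of ``first_env`` (the first environment the
    pool will encounter). Prep mutants are founded at one cell.
    """
    pop = SimulatedPopulation(params)
    n = params.n_barcodes
    pop._grow(n)
    rows = np.arange(n)
    pop.parent[rows] = -1
    pop.lineage[rows] = rows
    mean0 = params.transfer_size / n
    pop.size[rows] = pop.rng.poisson(mean0, n)
    for e in pop.envs:
        pop.own[e][rows] = 0.0
        pop.tot[e][rows] = 0.0
    if params.planted_fitness:
        for lid, by_env in params.planted_fitness.items():
            for e, s in by_env.items():
                pop.own[e][lid] = s
                pop.tot[e][lid] = s
    pop.batches.append((0, n))
    pop.n_rows = n
    pop.active = rows[pop.size[rows] > 0]
    if params.prep_mutation_rate > 0 and params.prep_generations > 0:
        if first_env is None:
            raise SimulatorParameterError(
                "first_env is required when prep mutagenesis is enabled"
            )
        if first_env not in params.dfe_bounds:
            raise SimulatorParameterError(f"no DFE configured for {first_env!r}")
        founder_sizes = pop.size[rows]
        for _ in range(params.prep_generations):
            n_new = pop.rng.poisson(founder_sizes * params.prep_mutation_rate)
            hit = n_new > 0
            if hit.any():
                parents = np.repeat(rows[hit], n_new[hit])
                pop._append_mutants(parents, first_env)
    return pop


def assign_env_fitness(pop: SimulatedPopulation, new_env: str) -> SimulatedPopulation:
    """Expose the population to ``new_env`` (see ``begin_environment``)."""
    pop.begin_environment(new_env)
    return pop


def step_generation(pop: SimulatedPopulation, env: str) -> SimulatedPopulation:
    pop.step_generation(env)
    return pop


def passage(pop: SimulatedPopulation) -> SimulatedPopulation:
    pop.passage()
    return pop


def sample_reads(pop: SimulatedPopulation, depth: float | None = None) -> np.ndarray:
    return pop.sample_reads(depth)


@dataclass
class SimulationResult:
    """Counts plus the hidden truth of one simulated experiment."""

    dataset: LineageTrackingDataset
    mean_fitness: pd.DataFrame
    lineage_truth: pd.DataFrame
    initial_richness: int
    final_richness: int
    population: SimulatedPopulation
    schedule_string: str
    seed: int | None

    @property
    def diversity_fold_loss(self) -> float:
        """Initial over final barcode richness."""
        return self.initial_richness / max(self.final_richness, 1)


def _lineage_truth(pop: SimulatedPopulation) -> pd.DataFrame:
    """End-state per-lineage summary: size, clone count, best fitness per env.

    A lineage is flagged neutral if every living clone has zero fitness in
    every environment (extinct, unplanted lineages also count as neutral);
    this emulates the role of spiked-in known-neutral barcodes as an oracle
    for the estimators.
    """
    n = pop.params.n_barcodes
    act = pop.active
    lin = pop.lineage[act]
    sizes = pop.lineage_sizes()
    n_clones = np.bincount(lin, minlength=n)
    out = {"barcode": [f"bc{i}" for i in range(n)], "final_size": sizes, "n_clones": n_clones}
    neutral = np.ones(n, dtype=bool)
    w = pop.size[act].astype(float)
    for e in pop.envs:
        best = np.zeros(n)
        if act.size:
            np.maximum.at(best, lin, pop.tot[e][act])
        out[f"max_fitness_{e}"] = best
        mean = np.zeros(n)
        if act.size:
            np.add.at(mean, lin, w * pop.tot[e][act])
            with np.errstate(invalid="ignore"):
                mean = np.where(sizes > 0, mean / np.maximum(sizes, 1), 0.0)
        out[f"mean_fitness_{e}"] = mean
        nonzero = np.zeros(n, dtype=bool)
        if act.size:
            np.logical_or.at(nonzero, lin, pop.tot[e][act] != 0.0)
        neutral &= ~nonzero
    if pop.params.planted_fitness:
        for lid, by_env in pop.params.planted_fitness.items():
            if any(s != 0 for s in by_env.values()):
                neutral[lid] = False
    out["neutral"] = neutral
    return pd.DataFrame(out)


def run_experiment(
    schedule: EnvironmentSchedule,
    params: SimulatorParams,
    sample_every: int | None = None,
) -> SimulationResult:
    """Simulate a full lineage-tracking experiment over a schedule.

    Orchestrates library prep, per-generation growth and mutation, passages
    every ``gens_per_passage`` generations, fitness reassignment and feeder
    selection at every environment-period boundary, and read sampling every
    ``sample_every`` generations (which must be a multiple of the passage
    length). Returns the count dataset plus the hidden truth used by
    closed-loop recovery tests.
    """
    p = params
    sample_every = p.gens_per_passage if sample_every is None else sample_every
    if sample_every % p.gens_per_passage != 0:
        raise ValueError("sample_every must be a multiple of gens_per_passage")
    first_env = schedule.blocks[0].label
    pop = init_library(p, first_env=first_env)
    initial_richness = pop.richness()
    counts = [pop.sample_reads()]
    gens = [0]
    env_labels: list[str] = []
    final_richness = initial_richness
    for label, start, end in schedule.periods():
        pop.begin_environment(label)
        for g in range(start, end):
            pop.step_generation(label)
            at_passage = (g + 1) % p.gens_per_passage == 0
            if at_passage:
                pop.rescale_to_saturation()
            if (g + 1) % sample_every == 0:
                # reads and richness are measured on the saturated culture,
                # before the transfer bottleneck that starts the next cycle
                counts.append(pop.sample_reads())
                env_labels.append(label)
                gens.append(g + 1)
                final_richness = pop.richness()
            if at_passage:
                pop.bottleneck()
    truth = _lineage_truth(pop)
    dataset = LineageTrackingDataset(
        counts=np.column_stack(counts),
        generations=np.array(gens),
        env_labels=env_labels,
        barcode_ids=truth["barcode"].tolist(),
        neutral_flags=truth["neutral"].to_numpy(),
    )
    return SimulationResult(
        dataset=dataset,
        mean_fitness=pop.mean_fitness_log(),
        lineage_truth=truth,
        initial_richness=initial_richness,
        final_richness=final_richness,
        population=pop,
        schedule_string=schedule.to_string(),
        seed=p.seed,
    )
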