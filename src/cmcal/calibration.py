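"""Genetic-algorithm estimation of conductance multipliers from traces.

Individuals are vectors of log2 multipliers for the free parameters.  Each
candidate is evaluated by simulating the calibration protocol and scoring
the summed per-segment mean squared error between its (optionally
normalized) V/Ca segments and the target's, after beat alignment.  Failed
or non-beating candidates receive a sentinel fitness.  Selection is by
tournament, recombination by uniform crossover, variation by Gaussian
mutation in log2 space, and the best individuals are carried over
unchanged (elitism), which makes the best fitness non-increasing across
generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .features import _upstroke_indices
from .protocol import Protocol, TraceSet, normalize_traces, run_protocol
from .simulation import derive_initial_state
from .types import CONDUCTANCE_NAMES, ConductanceSet

__all__ = ["GAConfig", "CalibrationRun", "CalibrationEnsemble", "fitness",
           "ga_run", "calibrate_ensemble", "SENTINEL_FITNESS"]

SENTINEL_FITNESS = 1.0e6


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm search settings (package defaults, configurable)."""

    population_size: int = 200
    generations: int = 20
    retention_fraction: float = 0.5      # lowest-error cells kept each round
    tournament_size: int = 2
    crossover: str = "blend"             # blend (BLX-0.25) | uniform
    crossover_rate: float = 0.5          # per-gene probability (uniform mode)
    mutation_rate: float = 0.3           # per-gene mutation probability
    mutation_sigma: float = 0.5          # log2 units, at generation 0
    mutation_sigma_final: float = 0.03   # annealed geometrically to this
    bounds_log2: tuple[float, float] = (-3.32, 3.32)   # ~0.1x .. 10x
    init: str = "lognormal"              # lognormal (around baseline) | uniform
    init_sigma: float = 0.5              # log2 SD of the lognormal init
    sentinel: float = SENTINEL_FITNESS
    seed: int = 0
    free_parameters: tuple[str, ...] = CONDUCTANCE_NAMES
    # none | first-upstroke | cross-correlation | per-beat
    alignment: str = "per-beat"
    n_jobs: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.bounds_log2
        if not lo <= 0.0 <= hi:
            raise ValueError("search bounds must contain the baseline (log2 = 0)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        unknown = set(self.free_parameters) - set(CONDUCTANCE_NAMES)
        if unknown:
            raise KeyError(f"unknown free parameters: {sorted(unknown)}")

    @property
    def n_retained(self) -> int:
        return min(self.population_size - 1,
                   max(1, int(round(self.retention_fraction
                                    * self.population_size))))


def _align_shift(candidate_v: np.ndarray, target_v: np.ndarray,
                 mode: str) -> int | None:
    """Sample shift to apply (circularly) to the candidate, or None if the
    candidate has no detectable upstroke."""
    if mode == "none":
        return 0
    if mode == "cross-correlation":
        c = candidate_v - candidate_v.mean()
        t = target_v - target_v.mean()
        xc = np.fft.irfft(np.fft.rfft(t) * np.conj(np.fft.rfft(c)), n=len(c))
        return int(np.argmax(xc))
    if mode == "first-upstroke":
        n = len(candidate_v)
        grid = np.arange(n, dtype=float)
        ups_t = _upstroke_indices(grid, target_v)
        if len(ups_t) == 0:
            # quiescent target segment: compare unshifted
            return 0
        ups_c = _upstroke_indices(grid, candidate_v)
        if len(ups_c) == 0:
            # non-beating candidate against a beating target
            return None
        return int(ups_t[0] - ups_c[0])
    raise ValueError(f"unknown alignment mode {mode!r}")


def _per_beat_mse(tr_c, tr_t) -> tuple[float, float] | None:
    """(V, Ca) mean squared errors with beat-by-beat correspondence.

    The k-th candidate beat is aligned to the k-th target beat before the
    pointwise comparison over that beat's span, so a small spontaneous-rate
    mismatch degrades the score gradually instead of catastrophically.  A
    beat-count mismatch adds a relative penalty to the V term.  Returns
    None for a non-beating candidate facing a beating target.
    """
    grid = np.arange(len(tr_t.V), dtype=float)
    ups_t = _upstroke_indices(grid, tr_t.V)
    if len(ups_t) == 0:
        return (float(np.mean((tr_c.V - tr_t.V) ** 2)),
                float(np.mean((tr_c.Ca - tr_t.Ca) ** 2)))
    ups_c = _upstroke_indices(grid, tr_c.V)
    if len(ups_c) == 0:
        return None
    n = len(tr_t.V)
    m = min(len(ups_t), len(ups_c))
    acc_v = acc_ca = 0.0
    count = 0
    for k in range(m):
        start_t = ups_t[k]
        end_t = ups_t[k + 1] if k + 1 < len(ups_t) else n
        shift = ups_t[k] - ups_c[k]
        lo = max(start_t, shift)
        hi = min(end_t, n + shift)
        if hi <= lo:
            continue
        v_c = tr_c.V[lo - shift:hi - shift]
        ca_c = tr_c.Ca[lo - shift:hi - shift]
        acc_v += float(np.sum((v_c - tr_t.V[lo:hi]) ** 2))
        acc_ca += float(np.sum((ca_c - tr_t.Ca[lo:hi]) ** 2))
        count += hi - lo
    if count == 0:
        return None
    amp_t = float(np.max(tr_t.V) - np.min(tr_t.V))
    count_penalty = (abs(len(ups_c) - len(ups_t)) / len(ups_t)) ** 2 \
        * amp_t ** 2
    return acc_v / count + count_penalty, acc_ca / count


def fitness(candidate: TraceSet, target: TraceSet,
            alignment: str = "per-beat",
            sentinel: float = SENTINEL_FITNESS) -> float:
    """Summed per-segment MSE between beat-aligned candidate and target.

    Voltage and calcium segments contribute with equal weight.  A failed
    candidate, or a non-beating candidate facing a beating target, scores
    the sentinel value.  Candidate and target must share the protocol grid
    and normalization state.

    Alignment modes: ``per-beat`` (default for calibration) establishes
    point correspondence beat by beat; ``first-upstroke`` and
    ``cross-correlation`` apply one circular shift per segment; ``none``
    compares in place.
    """
    if candidate.normalized != target.normalized:
        raise ValueError("candidate and target normalization flags differ")
    if len(candidate) != len(target):
        raise ValueError("candidate and target have different segment counts")
    if candidate.failed:
        return sentinel
    total = 0.0
    for tr_c, tr_t in zip(candidate.traces, target.traces):
        if len(tr_c.t) != len(tr_t.t) or \
                abs(tr_c.dt - tr_t.dt) > 1e-6 * tr_t.dt:
            raise ValueError("candidate and target grids differ")
        if alignment == "per-beat":
            pair = _per_beat_mse(tr_c, tr_t)
            if pair is None:
                return sentinel
            total += pair[0] + pair[1]
            continue
        shift = _align_shift(tr_c.V, tr_t.V, alignment)
        if shift is None:
            return sentinel
        v = np.roll(tr_c.V, shift)
        ca = np.roll(tr_c.Ca, shift)
        total += float(np.mean((v - tr_t.V) ** 2))
        total += float(np.mean((ca - tr_t.Ca) ** 2))
    return min(total, sentinel)


@dataclass
class CalibrationRun:
    """Result of one GA run."""

    best: ConductanceSet
    best_fitness: float
    history_best: list[float]
    history_mean: list[float]
    seed: int
    config: GAConfig

    def __post_init__(self) -> None:
        hb = np.asarray(self.history_best)
        if np.any(np.diff(hb) > 1e-12):
            raise AssertionError("best fitness increased across generations")


@dataclass
class CalibrationEnsemble:
    """Repeated GA runs (different seeds) against one target."""

    runs: list[CalibrationRun] = field(default_factory=list)

    @property
    def best_sets(self) -> list[ConductanceSet]:
        return [r.best for r in self.runs]

    def __len__(self) -> int:
        return len(self.runs)


def _genes_to_conductances(genes: np.ndarray, free_idx: np.ndarray) -> ConductanceSet:
    mult = np.ones(len(CONDUCTANCE_NAMES))
    mult[free_idx] = np.exp2(genes)
    return ConductanceSet(tuple(mult))


def _evaluate(genes: np.ndarray, free_idx: np.ndarray, target: TraceSet,
              protocol: Protocol, x0: np.ndarray, cfg: GAConfig) -> float:
    c = _genes_to_conductances(genes, free_idx)
    ts = run_protocol(c, protocol, x0)
    if ts.failed:
        return cfg.sentinel
    if target.normalized:
        try:
            ts = normalize_traces(ts)
        except ValueError:
            return cfg.sentinel
    return fitness(ts, target, alignment=cfg.alignment, sentinel=cfg.sentinel)


def ga_run(target: TraceSet, protocol: Protocol, cfg: GAConfig,
           x0: np.ndarray | None = None,
           seed_population: list[ConductanceSet] | None = None
           ) -> CalibrationRun:
    """Evolve a population of multiplier sets against one target TraceSet.

    ``seed_population`` lets callers plant known individuals into the
    initial population (the rest is drawn uniformly inside the log2 search
    bounds).  The run is fully reproducible from ``cfg.seed``.
    """
    x0 = derive_initial_state() if x0 is None else np.asarray(x0, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    free_idx = np.array([CONDUCTANCE_NAMES.index(p)
                         for p in cfg.free_parameters])
    n_genes = len(free_idx)
    lo, hi = cfg.bounds_log2

    if cfg.init == "lognormal":
        # population-of-models prior: multipliers log-normal around the
        # baseline cell, truncated to the search bounds
        pop = np.clip(rng.normal(0.0, cfg.init_sigma,
                                 size=(cfg.population_size, n_genes)), lo, hi)
    else:
        pop = rng.uniform(lo, hi, size=(cfg.population_size, n_genes))
    if seed_population:
        for i, c in enumerate(seed_population[: cfg.population_size]):
            pop[i] = np.log2(c.as_array()[free_idx])

    cache: dict[tuple, float] = {}

    def evaluate_all(pop: np.ndarray) -> np.ndarray:
        keys = [tuple(np.round(ind, 12)) for ind in pop]
        todo = [i for i, k in enumerate(keys) if k not in cache]
        if todo:
            if cfg.n_jobs != 1:
                vals = Parallel(n_jobs=cfg.n_jobs)(
                    delayed(_evaluate)(pop[i], free_idx, target, protocol,
                                       x0, cfg) for i in todo)
            else:
                vals = [_evaluate(pop[i], free_idx, target, protocol, x0, cfg)
                        for i in todo]
            for i, v in zip(todo, vals):
                cache[keys[i]] = v
        return np.array([cache[k] for k in keys])

    fit = evaluate_all(pop)
    history_best = [float(fit.min())]
    history_mean = [float(fit.mean())]

    for gen in range(cfg.generations):
        # geometric annealing of the mutation scale
        if cfg.generations > 1 and cfg.mutation_sigma_final:
            frac = gen / (cfg.generations - 1)
            sigma = cfg.mutation_sigma * \
                (cfg.mutation_sigma_final / cfg.mutation_sigma) ** frac
        else:
            sigma = cfg.mutation_sigma
        # retain the lowest-error cells; replace the rest with offspring of
        # the retained cells
        order = np.argsort(fit, kind="stable")
        keep = order[: cfg.n_retained]
        retained = pop[keep].copy()
        retained_fit = fit[keep].copy()
        children = []
        while len(children) < cfg.population_size - len(retained):
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(retained),
                                          size=cfg.tournament_size)
                parents.append(
                    retained[contenders[np.argmin(retained_fit[contenders])]])
            if cfg.crossover == "blend":
                # BLX-0.25: per-gene blend sampled slightly outside the span
                alpha = rng.uniform(-0.25, 1.25, size=n_genes)
                child = alpha * parents[0] + (1.0 - alpha) * parents[1]
            else:
                mask = rng.random(n_genes) < cfg.crossover_rate
                child = np.where(mask, parents[1], parents[0])
            # Gaussian mutation in log2 space
            mmask = rng.random(n_genes) < cfg.mutation_rate
            child = child + mmask * rng.normal(0.0, sigma, size=n_genes)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([retained, np.asarray(children)])
        fit = evaluate_all(pop)
        history_best.append(float(fit.min()))
        history_mean.append(float(fit.mean()))

    i_best = int(np.argmin(fit))
    return CalibrationRun(
        best=_genes_to_conductances(pop[i_best], free_idx),
        best_fitness=float(fit[i_best]),
        history_best=history_best,
        history_mean=history_mean,
        seed=cfg.seed,
        config=cfg,
    )


def calibrate_ensemble(target: TraceSet, protocol: Protocol, cfg: GAConfig,
                       n_runs: int = 10,
                       x0: np.ndarray | None = None) -> CalibrationEnsemble:
    """Repeat the GA ``n_runs`` times with independent seeds/initial
    populations against the same target."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    x0 = derive_initial_state() if x0 is None else x0
    runs = [ga_run(target, protocol, replace(cfg, seed=cfg.seed + 1000 * i),
                   x0=x0) for i in range(n_runs)]
    return CalibrationEnsemble(runs)
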