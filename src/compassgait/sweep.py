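"""Parameter sweeps and measure-robustness rank correlations.

A sweep walks an ordered grid of walker configurations, locates the
period-one gait for each (continuation-seeded Newton shooting), filters
for stability, and computes the phase-dependent stability measures, the
local divergence exponent and the gait robustness for every stable gait.
Kendall's rank correlation (tau-b, tie corrected) between each measure and
robustness summarizes how well a measure predicts robustness; |tau| > 0.7
is flagged as a strong correlation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import limit_cycle as lc
from . import phase_stability as ps
from . import simulate as sim
from .walkers import WalkerParams, make_model

__all__ = [
    "GridSpec",
    "SweepConfig",
    "SweepRecord",
    "CorrelationTable",
    "kendall_tau",
    "paper_point_grid",
    "paper_circular_grid",
    "run_sweep",
    "records_to_dataframe",
    "correlation_table",
    "STRONG_TAU",
    "MEASURE_NAMES",
]

#: |tau| above this counts as a strong correlation
STRONG_TAU = 0.7
MEASURE_NAMES = ("lde", "i", "ii", "iii", "iv", "v")


def kendall_tau(x, y):
    """Kendall rank correlation, tau-b (tie-corrected), in [-1, 1].

    Raises ``ValueError`` for arrays of unequal length, length < 2, or an
    all-constant input for which the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("kendall tau undefined for constant input")
    return float(stats.kendalltau(x, y, variant="b").statistic)


@dataclass(frozen=True)
class GridSpec:
    """An inclusive arithmetic grid {start, start+step, ..., <= stop}."""

    start: float
    stop: float
    step: float

    def values(self):
        n = int(round((self.stop - self.start) / self.step)) + 1
        vals = self.start + self.step * np.arange(n)
        return vals[vals <= self.stop + 1e-12 * max(1.0, abs(self.stop))]


#: grids printed in the study: 56 slopes x 50 mass ratios (point feet)
POINT_GAMMA_GRID = GridSpec(1e-3, 1.2e-2, 2e-4)
POINT_BETA_GRID = GridSpec(2e-3, 1e-1, 2e-3)
#: 13 foot radii x 56 slopes (circular feet)
CIRCULAR_R_GRID = GridSpec(0.01, 0.49, 0.04)
CIRCULAR_GAMMA_GRID = POINT_GAMMA_GRID


def _snake(outer_vals, inner_vals):
    combos = []
    for i, a in enumerate(outer_vals):
        inner = inner_vals if i % 2 == 0 else inner_vals[::-1]
        combos.extend((a, b) for b in inner)
    return combos


def paper_point_grid(beta_grid=POINT_BETA_GRID, gamma_grid=POINT_GAMMA_GRID):
    """The full point-feet study grid (2800 parameter combinations),
    snake-ordered for continuation (adjacent combos differ in one value)."""
    return [WalkerParams(beta=b, gamma=g)
            for b, g in _snake(beta_grid.values(), gamma_grid.values())]


def paper_circular_grid(r_grid=CIRCULAR_R_GRID,
                        gamma_grid=CIRCULAR_GAMMA_GRID, beta=0.01):
    """The full circular-feet study grid (728 parameter combinations)."""
    return [WalkerParams(beta=beta, gamma=g, r=r)
            for r, g in _snake(r_grid.values(), gamma_grid.values())]


@dataclass
class SweepConfig:
    """Everything needed to reproduce a sweep deterministically."""

    model: str = "point_el"
    params_list: list = field(default_factory=list)
    robustness_kinds: tuple = ("step_height",)
    precisions: dict = field(default_factory=dict)
    n_samples: int = 1000
    lde: dict | None = field(default_factory=dict)  # {} = defaults, None = skip
    seed: int = 0
    rtol: float | None = None
    atol: float | None = None
    walk_steps: int = 30

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        model = d.pop("model", "point_el")
        grids = d.pop("grid", {})
        if "params_list" not in d and grids:
            def spec(key, default):
                g = grids.get(key)
                if g is None:
                    return default
                if isinstance(g, dict):
                    return GridSpec(g["start"], g["stop"], g["step"]).values()
                return np.atleast_1d(np.asarray(g, dtype=float))

            gammas = spec("gamma", POINT_GAMMA_GRID.values())
            if model == "circular":
                rs = spec("r", CIRCULAR_R_GRID.values())
                beta = float(grids.get("beta", 0.01)) \
                    if np.isscalar(grids.get("beta", 0.01)) else 0.01
                d["params_list"] = [
                    WalkerParams(beta=beta, gamma=g, r=r)
                    for r, g in _snake(rs, gammas)]
            else:
                betas = spec("beta", POINT_BETA_GRID.values())
                d["params_list"] = [
                    WalkerParams(beta=b, gamma=g)
                    for b, g in _snake(betas, gammas)]
        kinds = d.pop("robustness_kinds", ("step_height",))
        return cls(model=model, robustness_kinds=tuple(kinds), **d)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SweepRecord:
    """Outcome for one parameter combination."""

    model: str
    beta: float
    gamma: float
    r: float
    found: bool
    stable: bool
    measures: ps.MeasureSet | None = None
    robustness: sim.RobustnessResult | None = None
    period: float | None = None
    max_multiplier: float | None = None
    fixed_state: list | None = None
    newton_iterations: int | None = None
    seed: int | None = None

    def to_dict(self):
        d = {
            "model": self.model, "beta": self.beta, "gamma": self.gamma,
            "r": self.r, "found": self.found, "stable": self.stable,
            "period": self.period, "max_multiplier": self.max_multiplier,
            "fixed_state": self.fixed_state,
            "newton_iterations": self.newton_iterations, "seed": self.seed,
        }
        if self.measures is not None:
            for k, v in self.measures.to_dict().items():
                d[f"measure_{k}"] = v
        if self.robustness is not None:
            d.update(self.robustness.to_dict())
        return d


def run_sweep(config: SweepConfig, progress=False, cache_path=None):
    """Execute a sweep; returns one :class:`SweepRecord` per combination.

    Continuation: each located gait seeds the Newton shot of the next
    combination.  Per-combination failures (no solution, falls during
    search) are recorded and never abort the sweep.  Deterministic for a
    fixed config (the LDE noise seed is derived from ``config.seed`` and
    the combination index).  ``cache_path`` (JSON) makes the sweep
    resumable: already-computed combinations are loaded, new ones appended.
    """
    cache = {}
    if cache_path is not None:
        try:
            with open(cache_path) as fh:
                for d in json.load(fh):
                    cache[(d["model"], d["beta"], d["gamma"], d["r"])] = d
        except (OSError, ValueError):
            cache = {}

    records = []
    prev_state = None
    iterator = enumerate(config.params_list)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc=f"sweep {config.model}")
    for idx, params in iterator:
        key = (config.model, params.beta, params.gamma, params.r)
        if key in cache:
            records.append(_record_from_dict(cache[key]))
            if records[-1].fixed_state is not None:
                prev_state = np.array(records[-1].fixed_state)
            continue
        rec, prev_state = _run_combo(config, params, idx, prev_state)
        records.append(rec)
        if cache_path is not None:
            cache[key] = rec.to_dict()
            with open(cache_path, "w") as fh:
                json.dump([r.to_dict() for r in records], fh)
    return records


def _run_combo(config, params, idx, prev_state):
    model = make_model(config.model, params)
    combo_seed = int(config.seed) + idx
    rec = SweepRecord(model=config.model, beta=params.beta,
                      gamma=params.gamma, r=params.r, found=False,
                      stable=False, seed=combo_seed)
    guesses = []
    if prev_state is not None:
        guesses.append(prev_state)
    guesses.append(lc.cold_start_guess(config.model, params))
    sol = None
    for guess in guesses:
        sol = lc.find_period_one(model, guess, rtol=config.rtol,
                                 atol=config.atol)
        if sol is not None:
            break
    if sol is None:
        return rec, prev_state
    rec.found = True
    rec.stable = sol.stable
    rec.period = sol.period
    rec.max_multiplier = sol.max_multiplier
    rec.fixed_state = [float(x) for x in sol.fixed_state]
    rec.newton_iterations = sol.newton_iterations
    if not sol.stable:
        return rec, sol.fixed_state
    try:
        lde_kwargs = None
        compute_lde = config.lde is not None
        if compute_lde:
            lde_kwargs = dict(config.lde)
            lde_kwargs.setdefault("seed", combo_seed)
        rec.measures = ps.measure_set(
            model, sol, n_samples=config.n_samples, lde_kwargs=lde_kwargs,
            rtol=config.rtol, atol=config.atol, compute_lde=compute_lde)
        rec.robustness = sim.robustness(
            model, sol.fixed_state, kinds=config.robustness_kinds,
            precisions=config.precisions or None, n_steps=config.walk_steps,
            rtol=config.rtol, atol=config.atol)
    except (sim.FallError, ValueError):
        rec.measures = None
        rec.robustness = None
    return rec, sol.fixed_state


def _record_from_dict(d):
    rec = SweepRecord(model=d["model"], beta=d["beta"], gamma=d["gamma"],
                      r=d["r"], found=d["found"], stable=d["stable"],
                      period=d.get("period"),
                      max_multiplier=d.get("max_multiplier"),
                      fixed_state=d.get("fixed_state"),
                      newton_iterations=d.get("newton_iterations"),
                      seed=d.get("seed"))
    if "measure_i" in d:
        rec.measures = ps.MeasureSet(
            lde=d.get("measure_lde"), i=d["measure_i"], ii=d["measure_ii"],
            iii=d["measure_iii"], iv=d["measure_iv"], v=d["measure_v"])
    if "max_step_up" in d and d["max_step_up"] is not None:
        rec.robustness = sim.RobustnessResult(
            max_step_up=d.get("max_step_up"),
            max_step_down=d.get("max_step_down"),
            max_push=d.get("max_push"), max_pull=d.get("max_pull"))
    return rec


def records_to_dataframe(records):
    """Flatten sweep records into a pandas DataFrame."""
    return pd.DataFrame([r.to_dict() for r in records])


@dataclass
class CorrelationTable:
    """Kendall tau of every measure against a robustness sum."""

    model: str
    robustness_kind: str
    n: int
    taus: dict            # measure name -> tau (or None if undefined)

    def strong(self, name):
        tau = self.taus.get(name)
        return tau is not None and abs(tau) > STRONG_TAU

    def to_dataframe(self):
        rows = [{"measure": k, "tau": v, "n": self.n,
                 "strong": self.strong(k)} for k, v in self.taus.items()]
        return pd.DataFrame(rows)


def correlation_table(records, robustness_kind="step_height",
                      min_records=10):
    """Correlate each stability measure with gait robustness.

    Pools every stable record that carries both a measure set and the
    requested robustness sum; unstable and failed combinations are
    excluded.  Requires at least ``min_records`` usable records.
    """
    col = ("robustness_height" if robustness_kind == "step_height"
           else "robustness_force")
    usable = [r for r in records
              if r.stable and r.measures is not None
              and r.robustness is not None
              and getattr(r.robustness, col) is not None]
    if len(usable) < min_records:
        raise ValueError(
            f"only {len(usable)} stable records with {col}; "
            f"need >= {min_records}")
    rob = np.array([getattr(r.robustness, col) for r in usable])
    taus = {}
    for name in MEASURE_NAMES:
        vals = [getattr(r.measures, name) for r in usable]
        if any(v is None for v in vals):
            taus[name] = None
            continue
        try:
            taus[name] = kendall_tau(np.array(vals, dtype=float), rob)
        except ValueError:
            taus[name] = None
    model = usable[0].model if usable else "?"
    return CorrelationTable(model=model, robustness_kind=robustness_kind,
                            n=len(usable), taus=taus)
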