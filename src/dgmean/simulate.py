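"""Monte-Carlo coverage / expected-length study for the five interval methods.

Each replicate draws a fresh delta-gamma sample (or an independent pair), builds
the requested intervals from ``ndraws`` posterior or fiducial draws, and records
whether the true mean ``tau = (1 - delta) alpha / beta`` (or the true difference
``psi``) lies in ``[L, U]`` together with the width ``U - L``.  Aggregates are

    CP = #{L <= theta <= U} / #{usable replicates}
    EL = mean(U - L)            over usable replicates

with the binomial Monte-Carlo standard error ``sqrt(CP (1 - CP) / reps)``.

Replicates whose sample violates a method's preconditions (no positives, zero
spread, or fewer than 4 positives for the uniform prior) are excluded from that
method's CP/EL and counted in ``n_failed`` — at the study's settings this is a
negligible-probability event, but it is never silently dropped.

The engine is vectorized: replicates are processed in fixed-size chunks of
summary statistics, with one random stream per draw family derived from the
master seed, so results are a pure, order-independent function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd

from .core import DeltaGammaParams, _summarize_matrix
from .fiducial import _fiducial_matrices
from .intervals import METHODS, _equal_tailed_rows, _hpd_rows
from .posterior import _posterior_matrices
from .core import gamma_mean_wh

__all__ = [
    "ScenarioSpec",
    "MethodResult",
    "SimulationResult",
    "run_scenario",
    "run_grid",
    "wide_table",
]

_CHUNK = 1024  # replicates per vectorized block (fixed: part of the seed contract)

# draw family -> (method tags it serves, minimum positive count per sample)
_FAMILIES = {
    "jeffreys": (("jeffreys_credible", "jeffreys_hpd"), 2),
    "uniform": (("uniform_credible", "uniform_hpd"), 4),
    "fq": (("fq",), 2),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell: a design, its true parameters, and run sizes."""

    design: str  # "single" | "two_sample"
    n: int
    params: DeltaGammaParams
    m: Optional[int] = None
    params2: Optional[DeltaGammaParams] = None
    gamma: float = 0.05
    reps: int = 15_000
    ndraws: int = 5_000
    methods: tuple = METHODS
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("single", "two_sample"):
            raise ValueError("design must be 'single' or 'two_sample'")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.ndraws < 2:
            raise ValueError("ndraws must be >= 2")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.design == "two_sample":
            if self.m is None or self.params2 is None:
                raise ValueError("two_sample design needs m and params2")
            if self.m < 1:
                raise ValueError("m must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must be in (0, 1)")

    @property
    def true_value(self) -> float:
        """True tau (single) or true psi (two_sample)."""
        if self.design == "single":
            return self.params.mean
        return self.params.mean - self.params2.mean


@dataclass(frozen=True)
class MethodResult:
    """Coverage and expected length for one method in one scenario."""

    method: str
    coverage: float
    expected_length: float
    mc_se_coverage: float
    n_failed: int
    n_used: int


@dataclass(frozen=True)
class SimulationResult:
    spec: ScenarioSpec
    true_value: float
    methods: dict = field(default_factory=dict)  # tag -> MethodResult

    def to_frame(self) -> pd.DataFrame:
        spec = self.spec
        rows = []
        for tag in spec.methods:
            r = self.methods[tag]
            rows.append(
                {
                    "design": spec.design,
                    "n": spec.n,
                    "m": spec.m,
                    "alpha": spec.params.alpha,
                    "beta": spec.params.beta,
                    "delta": spec.params.delta,
                    "alpha2": spec.params2.alpha if spec.params2 else None,
                    "beta2": spec.params2.beta if spec.params2 else None,
                    "delta2": spec.params2.delta if spec.params2 else None,
                    "gamma": spec.gamma,
                    "reps": spec.reps,
                    "ndraws": spec.ndraws,
                    "master_seed": spec.master_seed,
                    "true_value": self.true_value,
                    "method": tag,
                    "coverage": r.coverage,
                    "expected_length": r.expected_length,
                    "mc_se_coverage": r.mc_se_coverage,
                    "n_failed": r.n_failed,
                    "n_used": r.n_used,
                }
            )
        return pd.DataFrame(rows)


def _gen_summaries(params: DeltaGammaParams, n: int, reps: int, rng) -> dict:
    """Summary statistics of ``reps`` independent samples of size ``n``."""
    zero = rng.random((reps, n)) < params.delta
    g = rng.standard_gamma(params.alpha, size=(reps, n)) / params.beta
    obs = np.where(zero, 0.0, g)
    n_zero, n_pos, ybar, ss = _summarize_matrix(obs)
    return {"n_zero": n_zero, "n_pos": n_pos, "cube_mean": ybar, "cube_ss": ss}


def _valid_mask(sums: dict, min_pos: int) -> np.ndarray:
    return (sums["n_pos"] >= min_pos) & (sums["cube_ss"] > 0)


def _tau_chunk(family: str, sums: dict, idx: np.ndarray, ndraws: int, rng):
    """(len(idx), ndraws) mean draws for one family over selected replicates."""
    args = (
        sums["n_zero"][idx],
        sums["n_pos"][idx],
        sums["cube_mean"][idx],
        sums["cube_ss"][idx],
    )
    if family == "fq":
        fmu, fsigma2, f1md = _fiducial_matrices(*args, ndraws, rng)
        return f1md * gamma_mean_wh(fmu, fsigma2)
    mu, sigma2, delta = _posterior_matrices(*args, family, ndraws, rng)
    return (1.0 - delta) * gamma_mean_wh(mu, sigma2)


def _family_bounds(family, tags, spec, sums, sums2, rng):
    """Per-replicate interval bounds for every requested method of one family."""
    _, min_pos = _FAMILIES[family]
    valid = _valid_mask(sums, min_pos)
    if sums2 is not None:
        valid &= _valid_mask(sums2, min_pos)
    idx = np.flatnonzero(valid)

    bounds = {t: (np.full(spec.reps, np.nan), np.full(spec.reps, np.nan)) for t in tags}
    need_hpd = any(t.endswith("_hpd") for t in tags)
    need_eq = any(not t.endswith("_hpd") for t in tags)

    for start in range(0, idx.size, _CHUNK):
        sel = idx[start : start + _CHUNK]
        draws = _tau_chunk(family, sums, sel, spec.ndraws, rng)
        if sums2 is not None:
            draws = draws - _tau_chunk(family, sums2, sel, spec.ndraws, rng)
        draws.sort(axis=1)
        if need_eq:
            lo, hi = _equal_tailed_rows(draws, spec.gamma)
            for t in tags:
                if not t.endswith("_hpd"):
                    bounds[t][0][sel] = lo
                    bounds[t][1][sel] = hi
        if need_hpd:
            lo, hi = _hpd_rows(draws, spec.gamma)
            for t in tags:
                if t.endswith("_hpd"):
                    bounds[t][0][sel] = lo
                    bounds[t][1][sel] = hi
    return bounds, valid


def run_scenario(spec: ScenarioSpec) -> SimulationResult:
    """Run one simulation cell; deterministic given ``spec.master_seed``."""
    root = np.random.SeedSequence(spec.master_seed)
    data_ss, jeff_ss, unif_ss, fq_ss = root.spawn(4)
    family_seeds = {"jeffreys": jeff_ss, "uniform": unif_ss, "fq": fq_ss}

    data_rng = np.random.default_rng(data_ss)
    sums = _gen_summaries(spec.params, spec.n, spec.reps, data_rng)
    sums2 = None
    if spec.design == "two_sample":
        sums2 = _gen_summaries(spec.params2, spec.m, spec.reps, data_rng)

    theta = spec.true_value
    results: dict = {}
    for family, (family_tags, _) in _FAMILIES.items():
        tags = tuple(t for t in family_tags if t in spec.methods)
        if not tags:
            continue
        rng = np.random.default_rng(family_seeds[family])
        bounds, valid = _family_bounds(family, tags, spec, sums, sums2, rng)
        n_used = int(valid.sum())
        n_failed = spec.reps - n_used
        for t in tags:
            lo, hi = bounds[t]
            if n_used == 0:
                results[t] = MethodResult(t, np.nan, np.nan, np.nan, n_failed, 0)
                continue
            contained = (lo[valid] <= theta) & (theta <= hi[valid])
            cp = float(contained.mean())
            el = float((hi[valid] - lo[valid]).mean())
            se = float(np.sqrt(cp * (1.0 - cp) / n_used))
            results[t] = MethodResult(t, cp, el, se, n_failed, n_used)
    return SimulationResult(spec=spec, true_value=theta, methods=results)


# ---------------------------------------------------------------------------
# scenario grids

_AXIS_KEYS = ("n", "m", "alpha", "beta", "delta", "alpha2", "beta2", "delta2", "gamma")
_SCALAR_KEYS = ("design", "reps", "ndraws", "methods", "master_seed")


def _as_list(v):
    return list(v) if isinstance(v, (list, tuple)) else [v]


def _grid_scenarios(block: dict, master_seed: int, offset: int):
    unknown = set(block) - set(_AXIS_KEYS) - set(_SCALAR_KEYS)
    if unknown:
        raise ValueError(f"unknown grid config keys: {sorted(unknown)}")
    missing = {"design", "n", "alpha", "beta", "delta"} - set(block)
    if missing:
        raise ValueError(f"grid config is missing keys: {sorted(missing)}")

    design = block["design"]
    methods = tuple(block.get("methods", METHODS))
    reps = int(block.get("reps", 15_000))
    ndraws = int(block.get("ndraws", 5_000))

    axes = {k: _as_list(block[k]) for k in _AXIS_KEYS if k in block}
    if design == "two_sample":
        axes.setdefault("m", axes["n"])
        axes.setdefault("alpha2", axes["alpha"])
        axes.setdefault("beta2", axes["beta"])
        axes.setdefault("delta2", axes["delta"])
    axes.setdefault("gamma", [0.05])

    keys = list(axes)
    scenarios = []
    for i, combo in enumerate(product(*(axes[k] for k in keys))):
        cell = dict(zip(keys, combo))
        params = DeltaGammaParams(cell["alpha"], cell["beta"], cell["delta"])
        params2 = None
        m = None
        if design == "two_sample":
            params2 = DeltaGammaParams(cell["alpha2"], cell["beta2"], cell["delta2"])
            m = int(cell["m"])
        seed = int(
            np.random.SeedSequence(
                entropy=master_seed, spawn_key=(offset + i,)
            ).generate_state(1)[0]
            % (2**31)
        )
        scenarios.append(
            ScenarioSpec(
                design=design,
                n=int(cell["n"]),
                params=params,
                m=m,
                params2=params2,
                gamma=float(cell["gamma"]),
                reps=reps,
                ndraws=ndraws,
                methods=methods,
                master_seed=seed,
            )
        )
    return scenarios


def run_grid(config: dict) -> pd.DataFrame:
    """Run a cross-product of scenario axes; one tidy row per scenario x method.

    ``config`` is a mapping with the keys of :class:`ScenarioSpec` where any of
    n, m, alpha, beta, delta (and their second-population counterparts) and
    gamma may be lists, meaning cross-product axes.  Several independent grids
    may be given under a top-level ``grids`` list (they share ``master_seed``).
    """
    if not isinstance(config, dict):
        raise ValueError("grid config must be a mapping")
    master_seed = int(config.get("master_seed", 0))
    blocks = config["grids"] if "grids" in config else [config]
    scenarios = []
    for block in blocks:
        block = {k: v for k, v in dict(block).items() if k != "master_seed"}
        scenarios.extend(_grid_scenarios(block, master_seed, offset=len(scenarios)))
    frames = [run_scenario(s).to_frame() for s in scenarios]
    return pd.concat(frames, ignore_index=True)


def wide_table(results: pd.DataFrame) -> pd.DataFrame:
    """Printed-table layout: a CP row and a parenthesized (EL) row per scenario."""
    scenario_cols = [
        c
        for c in ("design", "n", "m", "delta", "alpha", "beta", "delta2", "alpha2", "beta2")
        if c in results.columns and results[c].notna().any()
    ]
    rows = []
    for key, grp in results.groupby(scenario_cols, dropna=False, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        base = dict(zip(scenario_cols, key))
        cp_row = dict(base)
        el_row = {c: "" for c in scenario_cols}
        for _, r in grp.iterrows():
            cp_row[r["method"]] = f"{r['coverage']:.4f}"
            el_row[r["method"]] = f"({r['expected_length']:.4f})"
        rows.append(cp_row)
        rows.append(el_row)
    return pd.DataFrame(rows)
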