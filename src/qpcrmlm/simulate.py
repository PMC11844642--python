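"""Monte-Carlo comparison of ANCOVA (MLM), ddCT and dCT for qPCR.

Each simulated experiment is a two-gene, two-group design: ``n_per_group``
treated and control samples (independent donors), a target and a reference
gene on the CT scale with unit variances. Target and reference share a
controllable Pearson correlation ``rho`` — the degree to which the
reference actually captures sample-quality variation — via linear mixing
of two independent unit-variance margins:

    reference = z_R,    target = rho * z_R + sqrt(1 - rho^2) * z_e

which yields correlation exactly ``rho`` for any margin shape. Margins are
standard Gaussian or standardised (left/right) exponential (skewness -2 or
+2). Treatment effects are mean shifts in SD units: ``target_effect`` on
the target (0 under the null) and ``reference_effect`` on the reference
(a contaminated housekeeping gene that itself responds to treatment).

Three methods are scored per experiment at two-sided level ``alpha``:

* ``mlm``  — ANCOVA ``target ~ treatment + reference``, treatment-term t;
* ``ddct`` — pooled two-sample t on per-sample target - reference;
* ``dct``  — pooled two-sample t on raw target CT (reference-free).

Replicates are seeded by a counter-based substream derivation from the
scenario seed, so results are reproducible and independent of execution
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classic import two_sample_pooled_t
from .ct_data import CTTable
from .mlm import DesignMatrix, coefficient_test, fit_ols

SHAPES = ("gaussian", "right_skewed", "left_skewed")
METHODS = ("mlm", "ddct", "dct")

_SHAPE_DIRECTION = {"gaussian": "none", "right_skewed": "right", "left_skewed": "left"}


@dataclass(frozen=True)
class Scenario:
    """Full parameterisation of one simulation cell."""

    rho: float
    shape: str = "gaussian"
    n_per_group: int = 5
    target_effect: float = 0.0
    reference_effect: float = 0.0
    alpha: float = 0.05
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho) or abs(self.rho) > 1:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for name in ("target_effect", "reference_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def skewed_margin(rng: np.random.Generator, direction: str, size: int) -> np.ndarray:
    """I.i.d. draws with mean 0 and variance 1 of controllable skew.

    ``none`` is standard Gaussian; ``right`` is the standardised
    exponential (skewness +2); ``left`` is its negation (skewness -2,
    identical draws reflected under the same random stream).
    """
    if direction == "none":
        return rng.standard_normal(size)
    if direction in ("right", "left"):
        draws = rng.standard_exponential(size) - 1.0
        return draws if direction == "right" else -draws
    raise ValueError(f"direction must be 'none', 'right' or 'left', got {direction!r}")


@dataclass
class SimulatedExperiment:
    """One synthetic two-gene experiment (arrays ordered control then treated)."""

    target: np.ndarray
    reference: np.ndarray
    treated: np.ndarray  # boolean

    def to_ct_table(self, offset: float = 20.0) -> CTTable:
        """Render as a CTTable (CT values shifted by ``offset`` to stay >= 0)."""
        n = len(self.target)
        rows = []
        for i in range(n):
            trt = "treated" if self.treated[i] else "control"
            sid = f"s{i:02d}"
            rows.append((sid, sid, trt, "TARGET", self.target[i] + offset))
            rows.append((sid, sid, trt, "REF", self.reference[i] + offset))
        return CTTable(pd.DataFrame(
            rows, columns=["sample", "subject", "treatment", "gene", "ct"]))


def generate_experiment(scenario: Scenario, rng: np.random.Generator) -> SimulatedExperiment:
    """Draw one experiment under the scenario's correlation, shape and effects."""
    direction = _SHAPE_DIRECTION[scenario.shape]
    n = 2 * scenario.n_per_group
    z_r = skewed_margin(rng, direction, n)
    z_e = skewed_margin(rng, direction, n)
    rho = scenario.rho
    reference = z_r.copy()
    target = rho * z_r + np.sqrt(1.0 - rho * rho) * z_e
    treated = np.zeros(n, dtype=bool)
    treated[scenario.n_per_group:] = True
    target[treated] += scenario.target_effect
    reference[treated] += scenario.reference_effect
    return SimulatedExperiment(target=target, reference=reference, treated=treated)


@dataclass(frozen=True)
class MethodOutcome:
    p_value: float
    reject: bool


def run_methods(dataset: SimulatedExperiment, alpha: float) -> dict[str, MethodOutcome]:
    """Score the MLM, ddCT and dCT methods on one simulated experiment."""
    tgt, ref, treated = dataset.target, dataset.reference, dataset.treated
    n = len(tgt)
    design = DesignMatrix(
        np.column_stack([np.ones(n), treated.astype(float), ref]),
        ["(Intercept)", "treatment-treated", "reference"],
        {"treatment": "control"},
    )
    mlm_p = coefficient_test(fit_ols(design, tgt), "treatment-treated").p_value
    diff = tgt - ref
    ddct_p = two_sample_pooled_t(diff[treated], diff[~treated]).p_value
    dct_p = two_sample_pooled_t(tgt[treated], tgt[~treated]).p_value
    return {
        "mlm": MethodOutcome(mlm_p, mlm_p < alpha),
        "ddct": MethodOutcome(ddct_p, ddct_p < alpha),
        "dct": MethodOutcome(dct_p, dct_p < alpha),
    }


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    # counter-based substream: reproducible regardless of execution order
    return np.random.default_rng(np.random.SeedSequence((seed, rep)))


@dataclass(frozen=True)
class RejectionRates:
    """Per-method empirical rejection rates with Monte-Carlo standard errors."""

    rates: dict[str, float]
    mc_se: dict[str, float]
    n_reps: int
    scenario: Scenario


def rejection_rates(scenario: Scenario) -> RejectionRates:
    """Empirical rejection rate of each method over n_reps experiments.

    Deterministic given ``scenario.seed``. The Monte-Carlo standard error
    is sqrt(rate * (1 - rate) / n_reps).
    """
    if scenario.n_reps < 100:
        warnings.warn(
            f"n_reps = {scenario.n_reps} < 100: Monte-Carlo error will be large",
            stacklevel=2,
        )
    counts = dict.fromkeys(METHODS, 0)
    for rep in range(scenario.n_reps):
        rng = _replicate_rng(scenario.seed, rep)
        outcome = run_methods(generate_experiment(scenario, rng), scenario.alpha)
        for m in METHODS:
            counts[m] += outcome[m].reject
    rates = {m: counts[m] / scenario.n_reps for m in METHODS}
    mc_se = {m: float(np.sqrt(r * (1 - r) / scenario.n_reps)) for m, r in rates.items()}
    return RejectionRates(rates=rates, mc_se=mc_se, n_reps=scenario.n_reps,
                          scenario=scenario)


def _row_seed(base_seed: int, row: int, block: int) -> int:
    state = np.random.SeedSequence((base_seed, row, block)).generate_state(1)[0]
    return int(state % (2**31))


@dataclass
class RejectionTable:
    """Scenario-grid results: one row per (rho, shape), type I error then power."""

    table: pd.DataFrame
    n_reps: int
    alpha: float
    target_effect: float
    base_seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def scenario_grid(rhos, shapes, base: Scenario) -> RejectionTable:
    """Run the full (rho x shape) grid, null and alternative blocks.

    For each cell two runs are made: ``target_effect = 0`` for the type I
    error block and ``target_effect = base.target_effect`` for the power
    block. Per-row seeds derive deterministically from ``base.seed``, so
    identical bases give bit-identical tables.
    """
    rhos = list(rhos)
    shapes = list(shapes)
    if not rhos or not shapes:
        raise ValueError("rhos and shapes must be non-empty")
    rows = []
    idx = 0
    for rho in rhos:
        for shape in shapes:
            null = rejection_rates(replace(
                base, rho=rho, shape=shape, target_effect=0.0,
                seed=_row_seed(base.seed, idx, 0)))
            power = rejection_rates(replace(
                base, rho=rho, shape=shape, target_effect=base.target_effect,
                seed=_row_seed(base.seed, idx, 1)))
            row = {"correlation": rho, "distribution": shape}
            for m in METHODS:
                row[f"{m}_type1"] = null.rates[m]
            for m in METHODS:
                row[f"{m}_power"] = power.rates[m]
            for m in METHODS:
                row[f"{m}_type1_se"] = null.mc_se[m]
                row[f"{m}_power_se"] = power.mc_se[m]
            rows.append(row)
            idx += 1
    return RejectionTable(table=pd.DataFrame(rows), n_reps=base.n_reps,
                          alpha=base.alpha, target_effect=base.target_effect,
                          base_seed=base.seed)


_GRID_KEYS = {"rhos", "shapes"}
_SCENARIO_KEYS = {"n_per_group", "target_effect", "reference_effect",
                  "alpha", "n_reps", "seed"}


def load_scenario_config(path) -> dict:
    """Load a scenario-grid configuration from YAML (or JSON) .

    Recognised keys: ``rhos``, ``shapes`` plus the Scenario fields
    ``n_per_group``, ``target_effect``, ``reference_effect``, ``alpha``,
    ``n_reps``, ``seed``. Unknown keys are an error.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    unknown = set(cfg) - _GRID_KEYS - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    missing = _GRID_KEYS - set(cfg)
    if missing:
        raise ValueError(f"scenario file missing keys: {sorted(missing)}")
    return cfg


def grid_from_config(cfg: dict, seed: int | None = None) -> RejectionTable:
    """Run :func:`scenario_grid` from a loaded configuration dict."""
    base_kwargs = {k: cfg[k] for k in _SCENARIO_KEYS if k in cfg}
    if seed is not None:
        base_kwargs["seed"] = seed
    base = Scenario(rho=0.0, shape="gaussian", **base_kwargs)
    return scenario_grid(cfg["rhos"], cfg["shapes"], base)
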