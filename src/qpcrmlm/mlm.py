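"""ANCOVA (multivariable linear model) analysis of CT tables.

The model regresses the target gene's CT on the treatment factor, any
nuisance factors (typically the donor), and the reference gene's CT as a
numeric covariate. Where the classic ddCT approach subtracts the reference
CT outright — implicitly assuming sample-quality variation hits target and
reference one-for-one — the regression *estimates* that weight. If the
reference carries no information about the target, its coefficient shrinks
toward zero and the model effectively ignores it; a weight different from
one also absorbs amplification-efficiency differences between the genes,
which is why the treatment p-value is invariant to rescaling any CT
column.

Fitting is ordinary least squares via an orthogonal (SVD) decomposition,
with classical standard errors sigma^2 (X'X)^-1 and two-sided Student-t
p-values on n - p residual degrees of freedom. Rank deficiency is a hard
error rather than silent column dropping: at qPCR sample sizes, aliasing
silently changes what every term means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import stdtr

from .ct_data import CTTable, QPCRError

logger = logging.getLogger("qpcrmlm")

#: model-formula factor names accepted for the annotation columns
FACTOR_ALIASES = {"subject": "subject", "donor": "subject", "treatment": "treatment"}


class RankDeficiencyError(QPCRError):
    """Design matrix is not of full column rank."""


class InsufficientDataError(QPCRError):
    """Fewer observations than parameters (hard floor n > p).

    Rule of thumb for reliable p-values: at least two observations per
    estimated parameter.
    """


class TermLookupError(QPCRError, KeyError):
    """A requested coefficient term is not in the fitted model."""


class ModelSpecError(QPCRError):
    """The model specification does not match the table."""


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of an ANCOVA model for a CT table.

    ``treatment``/``nuisance_factors`` name annotation factors (``donor``
    is accepted as a synonym for ``subject``); ``reference_genes`` enter as
    numeric CT covariates. ``control_level`` fixes the treatment baseline;
    every other factor uses its lexicographically first level as baseline.
    """

    response: str
    treatment: str = "treatment"
    control_level: str | None = None
    nuisance_factors: tuple[str, ...] = ()
    reference_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuisance_factors", tuple(self.nuisance_factors))
        object.__setattr__(self, "reference_genes", tuple(self.reference_genes))
        if self.response in self.reference_genes:
            raise ModelSpecError(
                f"response {self.response!r} cannot also be a reference gene"
            )


@dataclass
class DesignMatrix:
    """Fixed-effects design: intercept, factor dummies, numeric covariates."""

    matrix: np.ndarray
    column_names: list[str]
    baseline_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n, p = self.matrix.shape
        if p != len(self.column_names):
            raise ValueError("column_names length does not match matrix width")
        if n <= p:
            raise InsufficientDataError(
                f"{n} observations for {p} parameters; need n > p "
                f"(and preferably n >= {2 * p})"
            )
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < p:
            raise RankDeficiencyError(
                f"design matrix rank {rank} < {p} columns; collinear columns: "
                f"{self._collinear_columns()}"
            )

    def _collinear_columns(self) -> list[str]:
        """Columns linearly dependent on their predecessors (incremental rank)."""
        bad = []
        for j in range(1, self.matrix.shape[1]):
            if (np.linalg.matrix_rank(self.matrix[:, : j + 1])
                    == np.linalg.matrix_rank(self.matrix[:, :j])):
                bad.append(self.column_names[j])
        return bad

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FitResult:
    """OLS coefficients with classical (homoscedastic) inference."""

    column_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    residual_df: int
    sigma: float
    r_squared: float
    fitted: np.ndarray
    residuals: np.ndarray

    def __getitem__(self, term: str):
        if term not in self.column_names:
            raise TermLookupError(
                f"unknown term {term!r}; available terms: {self.column_names}"
            )
        i = self.column_names.index(term)
        return (self.coefficients[i], self.standard_errors[i],
                self.t_statistics[i], self.p_values[i])


def _resolve_factor(name: str) -> str:
    key = name.lower()
    if key not in FACTOR_ALIASES:
        raise ModelSpecError(
            f"unknown factor {name!r}; annotation factors are "
            f"{sorted(set(FACTOR_ALIASES))}"
        )
    return FACTOR_ALIASES[key]


def _dummy_columns(values: pd.Series, factor_label: str, baseline: str | None):
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise ModelSpecError(
            f"factor {factor_label!r} has a single observed level {levels}"
        )
    base = baseline if baseline is not None else levels[0]
    if base not in levels:
        raise ModelSpecError(
            f"baseline level {base!r} of factor {factor_label!r} not among {levels}"
        )
    cols, names = [], []
    for level in levels:
        if level == base:
            continue
        cols.append((values == level).to_numpy(float))
        names.append(f"{factor_label}-{level}")
    return cols, names, base


def build_design(table: CTTable, spec: ModelSpec):
    """Build the ANCOVA design matrix and response vector from a CT table.

    Samples missing the response, any reference-gene CT, or an annotation
    are dropped (count logged). Returns ``(DesignMatrix, response, samples)``
    where ``samples`` are the retained sample ids in table order.
    """
    wide = table.wide()
    for g in (spec.response, *spec.reference_genes):
        if g not in wide.columns:
            raise ModelSpecError(f"gene {g!r} not in table (available: {table.genes})")
    needed = wide[[spec.response, *spec.reference_genes]]
    keep = needed.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("build_design: dropped %d sample(s) with missing cells", n_drop)
    samples = [s for s in table.samples if keep[s]]
    ann = table.annotations.loc[samples]

    cols = [np.ones(len(samples))]
    names = ["(Intercept)"]
    baselines: dict[str, str] = {}
    for factor in spec.nuisance_factors:
        vals = ann[_resolve_factor(factor)]
        c, nm, base = _dummy_columns(vals, factor, None)
        cols += c
        names += nm
        baselines[factor] = base
    trt_vals = ann[_resolve_factor(spec.treatment)]
    c, nm, base = _dummy_columns(trt_vals, spec.treatment, spec.control_level)
    cols += c
    names += nm
    baselines[spec.treatment] = base
    for g in spec.reference_genes:
        cols.append(wide.loc[samples, g].to_numpy())
        names.append(g)

    design = DesignMatrix(np.column_stack(cols), names, baselines)
    y = wide.loc[samples, spec.response].to_numpy()
    return design, y, samples


def fit_ols(design: DesignMatrix, response: np.ndarray) -> FitResult:
    """Ordinary least squares with classical t inference.

    Coefficients minimise the residual sum of squares (SVD-based solve);
    standard errors come from sigma^2 (X'X)^-1; p-values are two-sided
    Student t on n - p degrees of freedom.
    """
    X = design.matrix
    y = np.asarray(response, float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response length does not match design")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    df = n - p
    rss = float(resid @ resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    pvals = 2.0 * stdtr(df, -np.abs(t))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    return FitResult(
        column_names=list(design.column_names),
        coefficients=coef, standard_errors=se, t_statistics=t, p_values=pvals,
        residual_df=df, sigma=float(np.sqrt(sigma2)), r_squared=r2,
        fitted=fitted, residuals=resid,
    )


def coefficient_test(fit: FitResult, term: str):
    """Extract one coefficient as a TestResult (estimate, t, df, p)."""
    from .classic import TestResult

    est, _, t, p = fit[term]
    return TestResult(float(est), float(t), float(fit.residual_df), float(p),
                      method=f"ANCOVA coefficient {term}")


@dataclass
class AncovaResult:
    """ANCOVA coefficient summary: factors first, then covariates."""

    summary: pd.DataFrame  # term, estimate, std_error, t, p_value (non-intercept)
    intercept: tuple[float, float, float, float]  # estimate, se, t, p
    fit: FitResult
    n_used: int
    n_dropped: int

    def term(self, name: str):
        return coefficient_test(self.fit, name)


def analyze_ancova(table: CTTable, spec: ModelSpec) -> AncovaResult:
    """Fit the ANCOVA and tabulate per-term estimates and p-values.

    One summary row per non-intercept term, factor dummies before
    reference-gene covariates (the intercept is reported separately).
    """
    design, y, samples = build_design(table, spec)
    fit = fit_ols(design, y)
    rows = []
    for name in fit.column_names:
        if name == "(Intercept)":
            continue
        est, se, t, p = fit[name]
        rows.append({"term": name, "estimate": est, "std_error": se,
                     "t": t, "p_value": p})
    summary = pd.DataFrame(rows)
    return AncovaResult(
        summary=summary,
        intercept=tuple(float(v) for v in fit["(Intercept)"]),
        fit=fit,
        n_used=len(samples),
        n_dropped=len(table.samples) - len(samples),
    )


def parse_model_string(formula: str, table: CTTable,
                       control_level: str | None = None) -> ModelSpec:
    """Parse ``response ~ factor1 + factor2 + refgene`` into a ModelSpec.

    Right-hand-side terms that name genes in the table become reference
    covariates; the rest must resolve to annotation factors (``Donor`` /
    ``Subject`` / ``Treatment``, case-insensitive). Exactly one treatment
    factor is required.
    """
    if formula.count("~") != 1:
        raise ModelSpecError(f"model string must contain one '~': {formula!r}")
    lhs, rhs = (side.strip() for side in formula.split("~"))
    if lhs not in table.genes:
        raise ModelSpecError(f"response {lhs!r} not a gene in the table ({table.genes})")
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    if not terms:
        raise ModelSpecError("model right-hand side is empty")
    treatment = None
    nuisance: list[str] = []
    refs: list[str] = []
    for term in terms:
        if term in table.genes:
            refs.append(term)
        elif term.lower() in FACTOR_ALIASES:
            if FACTOR_ALIASES[term.lower()] == "treatment":
                if treatment is not None:
                    raise ModelSpecError("treatment factor listed twice")
                treatment = term
            else:
                nuisance.append(term)
        else:
            raise ModelSpecError(
                f"term {term!r} is neither a gene in the table nor an "
                f"annotation factor ({sorted(set(FACTOR_ALIASES))})"
            )
    if treatment is None:
        raise ModelSpecError("model must include the treatment factor")
    return ModelSpec(response=lhs, treatment=treatment, control_level=control_level,
                     nuisance_factors=tuple(nuisance), reference_genes=tuple(refs))
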