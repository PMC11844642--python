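"""Classic qPCR quantification: dCT, ddCT, 2^-ddCT, and their t-tests.

All analysis stays on the CT (log) scale; the fold-change back-transform
2^-ddCT is a separate, explicitly requested step. Because CT falls as
transcript abundance rises, a positive ddCT (treated minus control) means
down-regulation and a fold change below 1.

The two-sample tests use the pooled-variance (Student) t by default, which
is exact under Gaussian errors at these tiny group sizes; Welch is
available behind a flag. Degenerate inputs (zero variance in both groups)
follow a fixed convention: equal means give statistic 0 / p = 1, unequal
means give p = 0 with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import stdtr
from scipy.stats import ranksums

from .ct_data import CTTable, QPCRError

logger = logging.getLogger("qpcrmlm")


class PairingError(QPCRError):
    """Subjects cannot be matched one-to-one across treatment levels."""


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome on the CT scale."""

    estimate: float
    statistic: float
    df: float
    p_value: float
    method: str


@dataclass(frozen=True)
class Efficiency:
    """Fractional per-cycle amplification efficiency, in (0, 1].

    e = 1 means perfect doubling, making raw CT a base-2 logarithm of
    starting abundance; e < 1 makes CT a base-(1+e) logarithm.
    """

    e: float

    def __post_init__(self) -> None:
        if not (0.0 < self.e <= 1.0):
            raise ValueError(f"efficiency must be in (0, 1], got {self.e}")


def _t_pvalue(t: float, df: float) -> float:
    return float(2.0 * stdtr(df, -abs(t)))


def two_sample_pooled_t(a: np.ndarray, b: np.ndarray, *, welch: bool = False,
                        method: str = "pooled t") -> TestResult:
    """Two-sample t-test of mean(a) - mean(b).

    Pooled-variance (Student) by default; Welch on request. Implements the
    degenerate zero-variance convention described in the module docstring.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    est = float(a.mean() - b.mean())
    ssa = float(((a - a.mean()) ** 2).sum())
    ssb = float(((b - b.mean()) ** 2).sum())
    if welch:
        va, vb = ssa / (na - 1), ssb / (nb - 1)
        se2 = va / na + vb / nb
        df = (se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
              if se2 > 0 else float(na + nb - 2))
    else:
        df = float(na + nb - 2)
        sp2 = (ssa + ssb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    if se2 == 0.0:
        if est == 0.0:
            return TestResult(0.0, 0.0, df, 1.0, method)
        logger.warning("zero variance with unequal means; reporting p = 0")
        return TestResult(est, math.copysign(math.inf, est), df, 0.0, method)
    t = est / math.sqrt(se2)
    return TestResult(est, t, df, _t_pvalue(t, df), method)


def one_sample_t(x: np.ndarray, method: str = "paired t") -> TestResult:
    """One-sample t-test of mean(x) against zero (used for paired designs)."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    est = float(x.mean())
    sd = float(x.std(ddof=1))
    df = float(n - 1)
    if sd == 0.0:
        if est == 0.0:
            return TestResult(0.0, 0.0, df, 1.0, method)
        logger.warning("zero variance with nonzero mean; reporting p = 0")
        return TestResult(est, math.copysign(math.inf, est), df, 0.0, method)
    t = est / (sd / math.sqrt(n))
    return TestResult(est, t, df, _t_pvalue(t, df), method)


def _two_levels(treatment: pd.Series, control_level: str) -> str:
    levels = sorted(pd.Series(treatment).astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"exactly two treatment levels required, got {levels}; "
            "analyze one contrast at a time"
        )
    if control_level not in levels:
        raise ValueError(f"control level {control_level!r} not among {levels}")
    treated = next(l for l in levels if l != control_level)
    counts = pd.Series(treatment).value_counts()
    if counts.min() == 0:  # pragma: no cover - unique() precludes this
        raise ValueError("a treatment level has zero samples")
    return treated


def delta_ct(table: CTTable, target: str, reference: str) -> pd.Series:
    """Per-sample dCT = target CT - reference CT.

    Samples with either cell missing are excluded (a note is logged);
    sample order is preserved.
    """
    t = table.gene_values(target)
    r = table.gene_values(reference)
    d = t - r
    n_drop = int(d.isna().sum())
    if n_drop:
        logger.info("delta_ct: dropped %d sample(s) with missing CT", n_drop)
    return d.dropna()


def delta_delta_ct(deltas: pd.Series, treatment: pd.Series, control_level: str) -> float:
    """ddCT = mean(dCT | treated) - mean(dCT | control)."""
    deltas = pd.Series(deltas, dtype=float)
    treatment = pd.Series(treatment).astype(str)
    treatment = treatment.loc[deltas.index] if deltas.index.equals(
        treatment.index) or set(deltas.index) <= set(treatment.index) else treatment
    treated = _two_levels(treatment, control_level)
    return float(deltas[treatment == treated].mean() - deltas[treatment == control_level].mean())


def fold_change(ddct: float) -> float:
    """Back-transform a ddCT to a fold change, 2^-ddCT (perfect doubling)."""
    return float(2.0 ** (-ddct))


def ddct_test(deltas: pd.Series, treatment: pd.Series, control_level: str,
              paired_by: pd.Series | None = None, *, welch: bool = False) -> TestResult:
    """Test ddCT against zero.

    Unpaired: pooled-variance two-sample t on dCT between groups. With
    ``paired_by`` (subject labels), a one-sample t on the within-subject
    treated-minus-control dCT differences. The estimate equals
    :func:`delta_delta_ct` on the same inputs in both cases.
    """
    deltas = pd.Series(deltas, dtype=float)
    treatment = pd.Series(treatment).astype(str).loc[deltas.index] \
        if set(deltas.index) <= set(pd.Series(treatment).index) else pd.Series(treatment).astype(str)
    treated = _two_levels(treatment, control_level)
    if paired_by is None:
        return two_sample_pooled_t(
            deltas[treatment == treated], deltas[treatment == control_level],
            welch=welch, method="ddCT unpaired t" + (" (Welch)" if welch else ""),
        )
    subjects = pd.Series(paired_by).astype(str)
    subjects = subjects.loc[deltas.index] if set(deltas.index) <= set(subjects.index) else subjects
    frame = pd.DataFrame({"d": deltas.values, "trt": treatment.values, "subj": subjects.values})
    pivot = frame.pivot_table(index="subj", columns="trt", values="d", aggfunc="count")
    bad = pivot.index[(pivot != 1).any(axis=1) | pivot.isna().any(axis=1)].tolist()
    if bad:
        raise PairingError(
            f"subjects without exactly one sample per treatment level: {bad}"
        )
    by = frame.pivot(index="subj", columns="trt", values="d")
    diffs = (by[treated] - by[control_level]).to_numpy()
    return one_sample_t(diffs, method="ddCT paired t")


def ddct_rank_test(deltas: pd.Series, treatment: pd.Series, control_level: str) -> TestResult:
    """Rank-based (Wilcoxon rank-sum) comparison of dCT distributions."""
    deltas = pd.Series(deltas, dtype=float)
    treatment = pd.Series(treatment).astype(str)
    treated = _two_levels(treatment, control_level)
    a = deltas[treatment.values == treated]
    b = deltas[treatment.values == control_level]
    res = ranksums(a, b)
    return TestResult(float(a.mean() - b.mean()), float(res.statistic),
                      float("nan"), float(res.pvalue), "ddCT rank-sum")


def dct_test(table: CTTable, target: str, control_level: str, *,
             welch: bool = False) -> TestResult:
    """Reference-free test: pooled two-sample t on raw target CT.

    This is the "dCT" method of the simulation comparisons — it ignores the
    reference gene entirely.
    """
    ct = table.gene_values(target).dropna()
    treatment = table.annotations["treatment"].loc[ct.index]
    treated = _two_levels(treatment, control_level)
    return two_sample_pooled_t(
        ct[treatment == treated], ct[treatment == control_level],
        welch=welch, method="dCT t" + (" (Welch)" if welch else ""),
    )


def efficiency_scaled_ct(ct, eff: Efficiency):
    """Rescale CT from base-(1+e) cycles to the log2 abundance scale.

    With per-cycle efficiency e, one observed cycle corresponds to a
    log2(1+e)-fold doubling, so the rescaled value is ct * log2(1+e);
    e = 1 is the identity.
    """
    if not isinstance(eff, Efficiency):
        eff = Efficiency(float(eff))
    factor = math.log2(1.0 + eff.e)
    out = np.asarray(ct, float) * factor
    return float(out) if np.isscalar(ct) or np.ndim(ct) == 0 else out


def scale_gene_efficiency(table: CTTable, gene: str, eff: Efficiency) -> CTTable:
    """Return a copy of ``table`` with one gene's CT column efficiency-rescaled."""
    table.gene_values(gene)  # raises GeneLookupError if absent
    df = table.data.copy()
    mask = df["gene"] == gene
    df.loc[mask, "ct"] = efficiency_scaled_ct(df.loc[mask, "ct"].to_numpy(), eff)
    return CTTable(df)
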