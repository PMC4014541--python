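"""Repeatability and group-comparison statistics for tracer-bolus studies.

Covers the statistics the method's validation studies rely on: coefficients
of variation (analytical and between-visit repeatability), paired t-tests for
replicate visits and pre/post designs, and one-way ANOVA followed by Dunnett
many-to-one comparisons against a named control group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, InputError

__all__ = [
    "RepeatedMeasure",
    "cv_percent",
    "within_subject_cv",
    "paired_t",
    "anova_dunnett",
    "PairedTResult",
    "DunnettResult",
    "summarize_groups",
]


@dataclass(frozen=True)
class RepeatedMeasure:
    """One subject's endoRa values across repeated study occasions."""

    subject_id: str
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) < 2:
            raise InputError(
                f"subject {self.subject_id!r} needs >= 2 occasions for repeatability"
            )


def cv_percent(values) -> float:
    """Coefficient of variation, 100 * sample SD / mean (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InputError("CV needs >= 2 values")
    mean = float(x.mean())
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return 100.0 * float(x.std(ddof=1)) / mean


def within_subject_cv(measures) -> float:
    """Pooled within-subject CV: root-mean-square of the per-subject CVs.

    This is the standard repeatability summary for designs where each subject
    is studied on a small number of occasions.
    """
    cvs = []
    for m in measures:
        values = m.values if isinstance(m, RepeatedMeasure) else m
        cvs.append(cv_percent(values))
    if not cvs:
        raise InputError("no subjects supplied")
    return float(np.sqrt(np.mean(np.square(cvs))))


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_value: float
    mean_diff: float
    degenerate: bool = False  # all pairwise differences identical


def paired_t(pre, post) -> PairedTResult:
    """Two-sided Student's t-test for paired samples.

    A zero-variance difference vector is flagged degenerate: identical lists
    give t = 0, p = 1; a constant nonzero shift gives an infinite t, p = 0.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired samples must be 1-D and of equal length")
    if a.size < 2:
        raise InputError("paired t-test needs >= 2 pairs")
    d = b - a
    df = a.size - 1
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return PairedTResult(0.0, df, 1.0, 0.0, degenerate=True)
        t = np.inf if d[0] > 0 else -np.inf
        return PairedTResult(float(t), df, 0.0, float(d.mean()), degenerate=True)
    res = sps.ttest_rel(b, a)
    return PairedTResult(float(res.statistic), df, float(res.pvalue), float(d.mean()))


@dataclass(frozen=True)
class DunnettResult:
    f_statistic: float
    p_anova: float
    control: str
    comparisons: tuple[str, ...]          # non-control group labels, input order
    statistics: tuple[float, ...]         # Dunnett t statistics vs control
    p_adjusted: tuple[float, ...]         # many-to-one adjusted p-values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.comparisons,
                "statistic": self.statistics,
                "p_adjusted": self.p_adjusted,
            }
        )


def anova_dunnett(groups: dict, control_label: str, *, rng=None) -> DunnettResult:
    """One-way ANOVA followed by Dunnett many-to-one comparisons vs a control.

    ``groups`` maps label -> samples.  Adjusted p-values come from the
    multivariate-t formulation of the Dunnett procedure (exact correlation
    1/2 for balanced groups, the unbalanced generalisation otherwise); the
    underlying rectangle probabilities are evaluated by randomised
    quasi-Monte-Carlo, so ``rng`` may be fixed for bitwise reproducibility.
    """
    if control_label not in groups:
        raise InputError(f"control label {control_label!r} not among {list(groups)}")
    labels = [k for k in groups if k != control_label]
    if not labels:
        raise InputError("need at least one non-control group")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InputError(f"group {k!r} needs n >= 2")
    f_stat, p_anova = sps.f_oneway(*arrays.values())
    dn = sps.dunnett(
        *(arrays[k] for k in labels),
        control=arrays[control_label],
        random_state=np.random.default_rng(0) if rng is None else rng,
    )
    return DunnettResult(
        f_statistic=float(f_stat),
        p_anova=float(p_anova),
        control=control_label,
        comparisons=tuple(labels),
        statistics=tuple(float(s) for s in np.atleast_1d(dn.statistic)),
        p_adjusted=tuple(float(p) for p in np.atleast_1d(dn.pvalue)),
    )


def dunnett_critical_value(
    n_comparisons: int, df: int, alpha: float = 0.05, *, seed: int = 0
) -> float:
    """Two-sided Dunnett critical point for balanced many-to-one comparisons.

    Root-finds c such that P(max_i |T_i| <= c) = 1 - alpha under the
    equicorrelated (rho = 1/2) multivariate t with ``df`` degrees of freedom.
    Useful for vectorised simulation studies where calling the full Dunnett
    procedure per dataset would dominate the runtime.
    """
    from scipy.optimize import brentq
    from scipy.stats import multivariate_t

    shape = np.full((n_comparisons, n_comparisons), 0.5)
    np.fill_diagonal(shape, 1.0)
    dist = multivariate_t(shape=shape, df=df, allow_singular=True)

    def fwer(c):
        lo = np.full(n_comparisons, -c)
        hi = np.full(n_comparisons, c)
        return 1.0 - dist.cdf(hi, lower_limit=lo, random_state=np.random.default_rng(seed))

    return float(brentq(lambda c: fwer(c) - alpha, 1.0, 6.0, xtol=1e-4))


def summarize_groups(
    table: pd.DataFrame,
    *,
    value_col: str = "endo_ra",
    group_col: str = "group",
    control: str | None = None,
) -> pd.DataFrame:
    """Group mean/SD/n summary of a tidy results table, with optional Dunnett tests.

    When ``control`` is given, each non-control group's Dunnett-adjusted
    p-value against it is appended.
    """
    if value_col not in table or group_col not in table:
        raise InputError(f"table needs columns {value_col!r} and {group_col!r}")
    summary = (
        table.groupby(group_col, sort=True)[value_col]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    if control is not None:
        groups = {g: sub[value_col].to_numpy() for g, sub in table.groupby(group_col)}
        res = anova_dunnett(groups, control)
        pmap = dict(zip(res.comparisons, res.p_adjusted))
        summary["p_vs_control"] = [pmap.get(g, float("nan")) for g in summary[group_col]]
    return summary
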