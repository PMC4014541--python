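"""Atom-percent-excess (APE) curves from raw GC-MS ion-intensity ratios.

A bolus tracer experiment yields, per blood sample, the ion-intensity ratio
of the labelled to the unlabelled isotopomer (for [1-13C]glutamine as its
TBDMS derivative: m/z 432 over m/z 431).  Pre-bolus samples measure the
natural-abundance background; enrichment above that background, expressed in
percent, is the APE curve that the kinetics module integrates.

Two APE conventions are supported:

``mole_fraction`` (default)
    APE = 100 * [r_t/(1+r_t) - r_b/(1+r_b)], the difference of isotopomer
    mole fractions.  This is the exact tracer arithmetic; at the ~2 % peak
    enrichments of a 3 mg/kg glutamine bolus it differs from the raw-ratio
    difference by < 0.05 % absolute, and the difference grows with enrichment.

``ratio``
    APE = 100 * (r_t - r_b), the tracer/tracee ratio difference.  Simpler,
    common in older tracer literature, adequate at trace enrichments.

Concentrations come from single-point isotope dilution against a uniformly
labelled internal standard ([13C5]glutamine, m/z 436).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, InputError

__all__ = [
    "RawSample",
    "EnrichmentCurve",
    "ratio_to_mole_fraction",
    "mole_fraction_to_ratio",
    "compute_ape",
    "concentration_from_is",
    "flag_below_loq",
    "curves_from_frame",
]

APE_CONVENTIONS = ("mole_fraction", "ratio")

#: Default limit of quantification, % APE.  The 3 mg/kg bolus curve becomes
#: unquantifiable towards the end of the 90-min window; a finite LOQ delimits
#: which points may enter the terminal tail fit.
DEFAULT_LOQ_APE = 0.01


@dataclass(frozen=True)
class RawSample:
    """One blood sample: time relative to the end of the bolus plus measured ratios.

    Negative ``time_min`` marks a pre-bolus (baseline) sample.
    """

    time_min: float
    ratio_tracer: float
    ratio_is: float | None = None

    def __post_init__(self):
        if self.ratio_tracer < 0:
            raise DomainError(f"ratio_tracer must be >= 0, got {self.ratio_tracer}")
        if self.ratio_is is not None and self.ratio_is < 0:
            raise DomainError(f"ratio_is must be >= 0, got {self.ratio_is}")


@dataclass(frozen=True)
class EnrichmentCurve:
    """Time-ordered post-bolus APE samples for one bolus experiment.

    ``quantifiable`` is all-True until :func:`flag_below_loq` is applied.
    Flagged points stay in the record (and in non-extrapolated AUCs) but are
    excluded from terminal tail fitting.
    """

    time_min: np.ndarray
    ape_percent: np.ndarray
    baseline_ratio: float
    subject_id: str = ""
    quantifiable: np.ndarray = field(default=None)  # type: ignore[assignment]
    convention: str = "mole_fraction"

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        a = np.asarray(self.ape_percent, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise InputError("time_min and ape_percent must be 1-D arrays of equal length")
        if t.size < 3:
            raise InputError(f"an enrichment curve needs >= 3 points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise InputError("sample times must be strictly increasing")
        q = self.quantifiable
        q = np.ones(t.size, dtype=bool) if q is None else np.asarray(q, dtype=bool)
        if q.shape != t.shape:
            raise InputError("quantifiable flags must match the number of points")
        if self.convention not in APE_CONVENTIONS:
            raise InputError(f"unknown APE convention {self.convention!r}")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "ape_percent", a)
        object.__setattr__(self, "quantifiable", q)

    def __len__(self) -> int:
        return self.time_min.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "time_min": self.time_min,
                "ape_percent": self.ape_percent,
                "quantifiable": self.quantifiable,
            }
        )


def ratio_to_mole_fraction(ratio):
    """Labelled-isotopomer mole fraction from a labelled/unlabelled ion ratio.

    f = r / (1 + r); strictly increasing, bounded in [0, 1).
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise DomainError("ion-intensity ratio must be >= 0")
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def mole_fraction_to_ratio(fraction):
    """Inverse of :func:`ratio_to_mole_fraction`: r = f / (1 - f), f in [0, 1)."""
    f = np.asarray(fraction, dtype=float)
    if np.any((f < 0) | (f >= 1)):
        raise DomainError("mole fraction must lie in [0, 1)")
    out = f / (1.0 - f)
    return out if out.ndim else float(out)


def compute_ape(
    samples,
    *,
    subject_id: str = "",
    convention: str = "mole_fraction",
) -> EnrichmentCurve:
    """Baseline-correct raw ratio samples into an APE curve.

    Parameters
    ----------
    samples
        Sequence of :class:`RawSample`, or a DataFrame with columns
        ``time_min`` and ``ratio_tracer``.  Samples with ``time_min < 0`` are
        baseline; their mean ratio defines the natural-abundance background.
    convention
        ``"mole_fraction"`` or ``"ratio"`` (see module docstring).

    Requires at least one baseline sample and three post-bolus samples.
    """
    if isinstance(samples, pd.DataFrame):
        t = samples["time_min"].to_numpy(dtype=float)
        r = samples["ratio_tracer"].to_numpy(dtype=float)
    else:
        t = np.array([s.time_min for s in samples], dtype=float)
        r = np.array([s.ratio_tracer for s in samples], dtype=float)
    if np.any(r < 0):
        raise DomainError("ion-intensity ratios must be >= 0")
    if np.any(np.diff(t) <= 0):
        raise InputError(f"sample times must be strictly increasing (subject {subject_id!r})")
    pre = t < 0
    post = ~pre
    if not pre.any():
        raise ConfigurationError(
            f"no pre-bolus baseline sample (time_min < 0) for subject {subject_id!r}"
        )
    if pre.sum() == 1:
        warnings.warn(
            f"only one baseline sample for subject {subject_id!r}; "
            "two pre-bolus samples are recommended",
            stacklevel=2,
        )
    if post.sum() < 3:
        raise InputError(
            f"need >= 3 post-bolus samples, got {int(post.sum())} (subject {subject_id!r})"
        )
    baseline_ratio = float(np.mean(r[pre]))
    if convention == "mole_fraction":
        ape = 100.0 * (ratio_to_mole_fraction(r[post]) - ratio_to_mole_fraction(baseline_ratio))
    elif convention == "ratio":
        ape = 100.0 * (r[post] - baseline_ratio)
    else:
        raise InputError(f"unknown APE convention {convention!r}")
    return EnrichmentCurve(
        time_min=t[post],
        ape_percent=ape,
        baseline_ratio=baseline_ratio,
        subject_id=subject_id,
        convention=convention,
    )


def concentration_from_is(ratio_is, is_concentration, *, zero_ok: bool = False):
    """Analyte concentration by single-point isotope dilution.

    concentration = (analyte / internal standard ion ratio) * added IS
    concentration.  Linear in both arguments.  ``zero_ok`` lets a zero ratio
    map to 0 instead of raising.
    """
    r = np.asarray(ratio_is, dtype=float)
    if is_concentration <= 0:
        raise DomainError("internal-standard concentration must be > 0")
    if np.any(r < 0) or (not zero_ok and np.any(r == 0)):
        raise DomainError("analyte/IS ratio must be > 0 (or set zero_ok=True)")
    out = r * float(is_concentration)
    return out if out.ndim else float(out)


def flag_below_loq(curve: EnrichmentCurve, loq_ape: float = DEFAULT_LOQ_APE) -> EnrichmentCurve:
    """Mark points with APE below the limit of quantification.

    Flagged points are retained in the record (and in non-extrapolated AUC)
    but excluded from terminal tail fitting.  Returns a new curve.
    """
    if loq_ape < 0:
        raise DomainError("LOQ must be >= 0")
    return replace(curve, quantifiable=curve.ape_percent >= loq_ape)


def curves_from_frame(
    frame: pd.DataFrame,
    *,
    convention: str = "mole_fraction",
) -> dict[str, EnrichmentCurve]:
    """Split a long-format sample table into per-subject enrichment curves.

    Accepts either raw-ratio input (columns ``subject_id, time_min,
    ratio_tracer``) or pre-computed APE input (``subject_id, time_min,
    ape_percent``); in the latter case baseline rows are optional and
    ``baseline_ratio`` is recorded as NaN.
    """
    cols = set(frame.columns)
    if not {"subject_id", "time_min"} <= cols:
        raise InputError("input table needs 'subject_id' and 'time_min' columns")
    has_ratio = "ratio_tracer" in cols
    has_ape = "ape_percent" in cols
    if not (has_ratio or has_ape):
        raise InputError("input table needs a 'ratio_tracer' or an 'ape_percent' column")
    curves: dict[str, EnrichmentCurve] = {}
    for sid, sub in frame.groupby("subject_id", sort=True):
        sub = sub.sort_values("time_min")
        if has_ratio:
            curves[str(sid)] = compute_ape(sub, subject_id=str(sid), convention=convention)
        else:
            post = sub[sub["time_min"] >= 0]
            curves[str(sid)] = EnrichmentCurve(
                time_min=post["time_min"].to_numpy(dtype=float),
                ape_percent=post["ape_percent"].to_numpy(dtype=float),
                baseline_ratio=float("nan"),
                subject_id=str(sid),
                convention=convention,
            )
    return curves
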