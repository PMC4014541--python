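"""Single-pool bolus kinetics: from an APE decay curve to endogenous Ra.

After an intravenous bolus of Dose (µmol/kg) of labelled glutamine, the
single-pool model gives the whole-body rate of appearance as

    Ra (µmol/kg/min) = Dose / AUC

where AUC is the area under the enrichment-versus-time curve with APE
expressed as a *fraction* (percent / 100).  When labelled glutamine is also
delivered by a continuous infusion (e.g. the alanyl-glutamine dipeptide),
the known exogenous delivery rate is subtracted:

    endoRa = Ra - exogenous rate.

AUC handling is explicit and auditable:

* observed area by linear (default) or log-linear trapezoids between the
  first and last usable samples;
* optionally, a terminal mono-exponential tail fitted by OLS on ln(APE) over
  the last ``n_tail`` quantifiable points, adding area C_last / k beyond the
  last quantifiable sample;
* no area is added before the first post-bolus sample.  The bolus peak can
  never be sampled exactly, so the measured AUC slightly underestimates the
  complete area and Ra is a small, systematic *over*estimate — a documented
  property of the method, not corrected by default.  A triangular
  leading-edge correction is available for sensitivity analyses only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .enrichment import EnrichmentCurve, compute_ape, flag_below_loq
from .errors import DomainError, InputError, NoValidTailError

__all__ = [
    "TracerDose",
    "InfusionRegimen",
    "TailFit",
    "KineticsResult",
    "dose_to_micromol",
    "auc_observed",
    "fit_tail",
    "auc_total",
    "exogenous_glutamine_rate",
    "ra_single_pool",
    "analyze_curve",
    "analyze_cohort",
    "MOLAR_MASS_GLN_1_13C",
    "MOLAR_MASS_ALA_GLN",
    "MOLAR_MASS_ALA",
]

# Built-in molar masses (g/mol), overridable in the dataclasses below.
MOLAR_MASS_GLN_1_13C = 147.14   # [1-13C]glutamine: 146.145 + ~1 for the 13C
MOLAR_MASS_ALA_GLN = 217.22    # alanyl-glutamine dipeptide (Ala + Gln - H2O)
MOLAR_MASS_ALA = 89.09


@dataclass(frozen=True)
class TracerDose:
    """The injected tracer bolus — numerator of the Ra equation."""

    amount_mg_per_kg: float = 3.0
    tracer_name: str = "[1-13C]glutamine"
    molar_mass_g_per_mol: float = MOLAR_MASS_GLN_1_13C
    isotopic_purity: float = 1.0

    def __post_init__(self):
        if self.amount_mg_per_kg <= 0:
            raise DomainError("tracer dose must be > 0 mg/kg")
        if self.molar_mass_g_per_mol <= 0:
            raise DomainError("molar mass must be > 0")
        if not 0 < self.isotopic_purity <= 1:
            raise DomainError("isotopic purity must lie in (0, 1]")


@dataclass(frozen=True)
class InfusionRegimen:
    """Continuous exogenous glutamine delivery — the subtraction term for endoRa.

    ``moles_glutamine_per_mole_compound`` carries the stoichiometry: 1 for
    alanyl-glutamine (one mole of dipeptide delivers one mole of glutamine),
    0 for alanine or saline (no glutamine delivered directly).
    """

    compound: str = "saline"
    rate_mg_per_kg_per_h: float = 0.0
    compound_molar_mass_g_per_mol: float = MOLAR_MASS_ALA_GLN
    moles_glutamine_per_mole_compound: float = 0.0

    def __post_init__(self):
        if self.rate_mg_per_kg_per_h < 0:
            raise DomainError("infusion rate must be >= 0")
        if self.compound_molar_mass_g_per_mol <= 0:
            raise DomainError("compound molar mass must be > 0")
        if self.moles_glutamine_per_mole_compound < 0:
            raise DomainError("stoichiometry must be >= 0")

    @classmethod
    def dipeptiven(cls, rate_mg_per_kg_per_h: float = 25.0) -> "InfusionRegimen":
        """The alanyl-glutamine regimen: 25 mg/kg/h Dipeptiven by default."""
        return cls(
            compound="alanyl-glutamine",
            rate_mg_per_kg_per_h=rate_mg_per_kg_per_h,
            compound_molar_mass_g_per_mol=MOLAR_MASS_ALA_GLN,
            moles_glutamine_per_mole_compound=1.0,
        )

    @classmethod
    def none(cls) -> "InfusionRegimen":
        return cls()


@dataclass(frozen=True)
class TailFit:
    """Terminal mono-exponential fit ln(APE) ~ a - k*t over the tail window."""

    amplitude_ape: float       # predicted APE (%) at the last quantifiable time
    k_per_min: float           # terminal rate constant (1/min)
    n_points_used: int
    r_squared: float
    t_ref_min: float           # time the amplitude refers to


@dataclass(frozen=True)
class KineticsResult:
    """Full AUC decomposition and flux estimates for one curve."""

    subject_id: str
    n_points: int
    auc_observed: float        # %*min over the integrated span
    auc_tail: float            # %*min extrapolated beyond the last quantifiable point
    auc_total: float           # %*min, = auc_observed + auc_tail
    dose_umol_per_kg: float
    ra: float                  # µmol/kg/min
    exo_rate: float            # µmol/kg/min
    endo_ra: float             # µmol/kg/min, = ra - exo_rate
    tail_fit: TailFit | None = None
    warnings: tuple[str, ...] = field(default=())

    def to_row(self) -> dict:
        tf = self.tail_fit
        return {
            "subject_id": self.subject_id,
            "n_points": self.n_points,
            "auc_observed": self.auc_observed,
            "auc_tail": self.auc_tail,
            "auc_total": self.auc_total,
            "dose_umol_per_kg": self.dose_umol_per_kg,
            "ra": self.ra,
            "exo_rate": self.exo_rate,
            "endo_ra": self.endo_ra,
            "tail_k_per_min": tf.k_per_min if tf else float("nan"),
            "tail_amplitude_ape": tf.amplitude_ape if tf else float("nan"),
            "tail_n_points": tf.n_points_used if tf else 0,
            "tail_r_squared": tf.r_squared if tf else float("nan"),
        }


def dose_to_micromol(dose: TracerDose) -> float:
    """Convert a mg/kg tracer bolus to µmol/kg of labelled glutamine."""
    return dose.amount_mg_per_kg / dose.molar_mass_g_per_mol * 1000.0 * dose.isotopic_purity


def auc_observed(
    curve: EnrichmentCurve,
    method: str = "linear",
    *,
    quantifiable_only: bool = False,
) -> float:
    """Area under the APE curve (%*min) between its first and last usable samples.

    ``method`` is ``"linear"`` (trapezoid) or ``"log"`` (log-trapezoid with
    per-segment fallback to linear wherever an endpoint is <= 0 or the two
    endpoints are equal).  ``quantifiable_only`` restricts the integration to
    points not flagged below the LOQ — used when a fitted tail will cover the
    remainder.
    """
    t = curve.time_min
    y = curve.ape_percent
    if quantifiable_only:
        t, y = t[curve.quantifiable], y[curve.quantifiable]
    if t.size < 2:
        raise InputError("AUC needs at least 2 points")
    if method == "linear":
        return float(np.trapezoid(y, t))
    if method != "log":
        raise InputError(f"unknown AUC method {method!r}")
    dt = np.diff(t)
    y1, y2 = y[:-1], y[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ok = (y1 > 0) & (y2 > 0) & (y1 != y2)
        seg = np.where(log_ok, (y1 - y2) / np.log(np.where(log_ok, y1 / y2, 1.0)), (y1 + y2) / 2.0)
    return float(np.sum(seg * dt))


def fit_tail(curve: EnrichmentCurve, n_tail: int = 10) -> TailFit:
    """OLS log-linear fit over the last ``n_tail`` quantifiable points.

    Points with APE <= 0 inside the window are dropped with a warning (the
    window shrinks; at least 3 usable points must remain).  Raises
    :class:`NoValidTailError` when the fitted slope is not a decay.
    """
    if n_tail < 3:
        raise InputError("n_tail must be >= 3")
    mask = curve.quantifiable & (curve.ape_percent > 0)
    t = curve.time_min[mask]
    y = curve.ape_percent[mask]
    if t.size < 3:
        raise NoValidTailError(
            f"only {t.size} quantifiable positive point(s); need >= 3 for a tail fit"
        )
    if t.size < n_tail:
        warnings.warn(
            f"tail window shrunk to {t.size} points (requested {n_tail})", stacklevel=2
        )
    t_win = t[-n_tail:]
    y_win = y[-n_tail:]
    slope, intercept = np.polyfit(t_win, np.log(y_win), 1)
    k = -float(slope)
    if k <= 0:
        raise NoValidTailError(f"terminal slope is not a decay (k = {k:.4g}/min)")
    pred = intercept + slope * t_win
    resid = np.log(y_win) - pred
    ss_tot = float(np.sum((np.log(y_win) - np.log(y_win).mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    t_ref = float(t_win[-1])
    amplitude = float(math.exp(intercept + slope * t_ref))
    return TailFit(
        amplitude_ape=amplitude,
        k_per_min=k,
        n_points_used=int(t_win.size),
        r_squared=r2,
        t_ref_min=t_ref,
    )


def auc_total(
    curve: EnrichmentCurve,
    tail: TailFit | None = None,
    *,
    extrapolate: bool = True,
    method: str = "linear",
) -> float:
    """Total AUC (%*min): observed area plus, optionally, the fitted tail C/k.

    With extrapolation the observed part runs to the last quantifiable point
    and the tail adds amplitude/k beyond it; without it the observed area over
    all retained points stands alone.  No leading-edge area is added before
    the first sample.
    """
    if not extrapolate:
        return auc_observed(curve, method)
    if tail is None:
        raise NoValidTailError("tail extrapolation requested but no tail fit supplied")
    return auc_observed(curve, method, quantifiable_only=True) + tail.amplitude_ape / tail.k_per_min


def exogenous_glutamine_rate(infusion: InfusionRegimen) -> float:
    """Glutamine delivery rate (µmol/kg/min) implied by a continuous infusion."""
    return (
        infusion.rate_mg_per_kg_per_h
        / infusion.compound_molar_mass_g_per_mol
        * 1000.0
        / 60.0
        * infusion.moles_glutamine_per_mole_compound
    )


def ra_single_pool(dose_umol_per_kg: float, auc_percent_min: float) -> float:
    """Ra = Dose / AUC with APE converted from percent to fraction."""
    if dose_umol_per_kg <= 0:
        raise DomainError("dose must be > 0")
    if auc_percent_min <= 0:
        raise DomainError(f"AUC must be > 0, got {auc_percent_min:.4g} %*min")
    return dose_umol_per_kg / (auc_percent_min / 100.0)


def analyze_curve(
    data,
    dose: TracerDose,
    infusion: InfusionRegimen | None = None,
    config: AnalysisConfig | None = None,
) -> KineticsResult:
    """Run the full single-pool analysis on one experiment.

    ``data`` is either raw samples (anything :func:`~bolusflux.enrichment.compute_ape`
    accepts) or an already-built :class:`~bolusflux.enrichment.EnrichmentCurve`.
    The deterministic pipeline is: APE -> LOQ flags -> tail fit -> AUC ->
    Ra -> endoRa, with every intermediate kept on the result for audit.
    """
    cfg = config or AnalysisConfig()
    infusion = infusion or InfusionRegimen.none()
    notes: list[str] = []

    if isinstance(data, EnrichmentCurve):
        curve = data
    else:
        curve = compute_ape(data, convention=cfg.ape_convention)
    curve = flag_below_loq(curve, cfg.loq_ape)

    tail: TailFit | None = None
    if cfg.extrapolate:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            tail = fit_tail(curve, cfg.n_tail)
        notes.extend(str(w.message) for w in caught)
        auc_obs = auc_observed(curve, cfg.auc_method, quantifiable_only=True)
        auc_ext = tail.amplitude_ape / tail.k_per_min
    else:
        auc_obs = auc_observed(curve, cfg.auc_method)
        auc_ext = 0.0

    if cfg.head_correction:
        # Sensitivity-analysis option: triangular area from (0, 0) to the
        # first sample.  Off by default — see module docstring.
        auc_obs += 0.5 * curve.time_min[0] * curve.ape_percent[0]
        notes.append("triangular leading-edge correction applied")

    total = auc_obs + auc_ext
    dose_umol = dose_to_micromol(dose)
    ra = ra_single_pool(dose_umol, total)
    exo = exogenous_glutamine_rate(infusion)
    endo = ra - exo
    if endo < 0:
        notes.append(
            f"endoRa is negative ({endo:.3g} µmol/kg/min): the declared exogenous "
            "rate exceeds the measured Ra — check dose, infusion and units"
        )
    return KineticsResult(
        subject_id=curve.subject_id,
        n_points=len(curve),
        auc_observed=auc_obs,
        auc_tail=auc_ext,
        auc_total=total,
        dose_umol_per_kg=dose_umol,
        ra=ra,
        exo_rate=exo,
        endo_ra=endo,
        tail_fit=tail,
        warnings=tuple(notes),
    )


def analyze_cohort(
    curves: dict[str, EnrichmentCurve],
    dose: TracerDose,
    infusion: InfusionRegimen | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Analyze several subjects; one result row per subject, sorted by id."""
    rows = []
    for sid in sorted(curves):
        res = analyze_curve(curves[sid], dose, infusion, config)
        rows.append(res.to_row())
    return pd.DataFrame(rows)
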