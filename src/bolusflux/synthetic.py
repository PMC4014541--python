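"""Synthetic bolus decay curves with known ground truth.

Generates the tracer curves a bolus experiment would measure, so that the
enrichment -> kinetics -> statistics pipeline can be validated end to end
without access to subject data.

Two generative models:

* **one_pool** — the exact counterpart of the single-pool estimator.  A dose
  injected into a well-stirred pool of size ``q_pool`` turning over at
  ``ra_true`` gives the tracer/tracee ratio

      r(t) = (dose / q_pool) * exp(-(ra_true / q_pool) * t)

  whose complete time integral is dose / ra_true, so Dose/AUC recovers
  ``ra_true`` exactly up to sampling-window effects.  The default pool
  (200 µmol/kg) is the effective rapidly exchangeable glutamine distribution
  space; it yields a terminal rate constant of ~0.03/min, enrichment
  quantifiable across the whole 90-min window, and a pre-first-sample area
  of ~1.5 % of the total — the "small, acknowledged overestimation" regime
  of the bolus method.

* **two_pool** — plasma pool exchanging bidirectionally with a larger, slower
  tissue pool (skeletal muscle holds most of the free glutamine).  Endogenous
  appearance and irreversible loss both act on the plasma pool, so the
  plasma enrichment decays bi-exponentially: a fast mixing phase as tracer
  distributes into tissue, then a slow terminal phase.  Its complete plasma
  AUC still equals dose / ra_true (all tracer ultimately leaves via plasma),
  which makes this model the test bed for what a *finite* sampling window
  does to the single-pool estimate.  The default plasma pool (20.7 µmol/kg)
  makes a 3 mg/kg bolus roughly double the plasma glutamine concentration,
  matching dose-finding observations.

Enrichment output convention ("ratio" = tracer/tracee ratio excess, or
"mole_fraction") is a single switch shared with the enrichment module; the
ratio convention is the one for which Dose/AUC is exact and is the default
for simulation work.

Measurement noise is multiplicative lognormal with median 1, parameterised
by the analytical CV (default 4.1 %, the duplicate GC-MS figure).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .enrichment import EnrichmentCurve
from .errors import DomainError, InputError
from .kinetics import TracerDose, dose_to_micromol
from .protocol import SamplingSchedule, default_schedule

__all__ = [
    "PoolModelParams",
    "NoiseModel",
    "simulate_single_pool",
    "simulate_two_pool",
    "two_pool_masses",
    "add_noise",
    "simulate_cohort",
    "DEFAULT_ANALYTICAL_CV",
]

#: Duplicate GC-MS analysis coefficient of variation (fraction).
DEFAULT_ANALYTICAL_CV = 0.041

#: 3 mg/kg of [1-13C]glutamine in µmol/kg.
DEFAULT_DOSE_UMOL_PER_KG = dose_to_micromol(TracerDose())

#: Effective rapidly exchangeable glutamine pool for the one-pool model, µmol/kg.
DEFAULT_Q_ONE_POOL = 200.0

#: Natural-abundance background of the m/z 432/431 ion ratio used when
#: emitting raw-ratio cohort files (illustrative; instrument dependent).
DEFAULT_BASELINE_RATIO = 0.04


@dataclass(frozen=True)
class PoolModelParams:
    """Ground-truth kinetics for the generator.

    ``q_plasma`` is the accessible (sampled) pool; ``q_tissue`` and
    ``k_exchange`` (fractional plasma->tissue rate, 1/min) exist only for the
    two-pool model.  The tissue->plasma rate follows from tracee steady
    state: k_tissue_to_plasma = k_exchange * q_plasma / q_tissue.
    """

    model: str = "one_pool"
    ra_true: float = 6.1
    q_plasma: float = DEFAULT_Q_ONE_POOL
    dose_umol_per_kg: float = DEFAULT_DOSE_UMOL_PER_KG
    q_tissue: float | None = None
    k_exchange: float | None = None

    def __post_init__(self):
        if self.model not in ("one_pool", "two_pool"):
            raise DomainError(f"unknown model {self.model!r}")
        for name in ("ra_true", "q_plasma", "dose_umol_per_kg"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.model == "two_pool":
            if self.q_tissue is None or self.k_exchange is None:
                raise DomainError("two_pool requires q_tissue and k_exchange")
            if self.q_tissue <= 0 or self.k_exchange < 0:
                raise DomainError("q_tissue must be > 0 and k_exchange >= 0")

    @classmethod
    def two_pool_default(cls, ra_true: float = 6.1) -> "PoolModelParams":
        """Illustrative two-pool defaults: plasma 20.7 µmol/kg (bolus doubles the
        plasma concentration), a 300 µmol/kg slow tissue pool, exchange 0.3/min."""
        return cls(
            model="two_pool",
            ra_true=ra_true,
            q_plasma=20.7,
            q_tissue=300.0,
            k_exchange=0.3,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise, median 1, given CV."""

    cv_fraction: float = DEFAULT_ANALYTICAL_CV
    seed: int = 0

    def __post_init__(self):
        if self.cv_fraction < 0:
            raise DomainError("noise CV must be >= 0")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv_fraction**2)))

    def factors(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = np.random.default_rng(self.seed) if rng is None else rng
        if self.cv_fraction == 0:
            return np.ones(n)
        return np.exp(self.sigma * rng.standard_normal(n))


def _ratio_to_ape(r: np.ndarray, convention: str) -> np.ndarray:
    if convention == "ratio":
        return 100.0 * r
    if convention == "mole_fraction":
        return 100.0 * r / (1.0 + r)
    raise InputError(f"unknown APE convention {convention!r}")


def simulate_single_pool(
    params: PoolModelParams,
    schedule: SamplingSchedule | None = None,
    *,
    convention: str = "ratio",
    subject_id: str = "sim",
) -> tuple[EnrichmentCurve, dict]:
    """Noiseless mono-exponential bolus curve plus its ground truth.

    Truth keys: ``ra_true``, ``k_per_min`` (= ra/q), ``peak_ratio``
    (= dose/q, the t=0+ tracer/tracee ratio) and ``auc_infinite`` —
    the complete %*min ratio-form area 100*dose/ra that the ideal estimator
    divides into the dose.
    """
    if params.model != "one_pool":
        raise DomainError("simulate_single_pool requires model='one_pool'")
    schedule = schedule or default_schedule()
    t = schedule.times()
    k = params.ra_true / params.q_plasma
    r = (params.dose_umol_per_kg / params.q_plasma) * np.exp(-k * t)
    curve = EnrichmentCurve(
        time_min=t,
        ape_percent=_ratio_to_ape(r, convention),
        baseline_ratio=0.0,
        subject_id=subject_id,
        convention=convention,
    )
    truth = {
        "ra_true": params.ra_true,
        "k_per_min": k,
        "peak_ratio": params.dose_umol_per_kg / params.q_plasma,
        "auc_infinite": 100.0 * params.dose_umol_per_kg / params.ra_true,
    }
    return curve, truth


def _two_pool_rates(params: PoolModelParams) -> tuple[float, float, float]:
    k10 = params.ra_true / params.q_plasma              # irreversible loss
    k12 = float(params.k_exchange)                      # plasma -> tissue
    k21 = k12 * params.q_plasma / float(params.q_tissue)  # tissue -> plasma
    return k10, k12, k21


def _two_pool_eigen(params: PoolModelParams) -> tuple[float, float, float, float, float]:
    k10, k12, k21 = _two_pool_rates(params)
    tr = -(k10 + k12 + k21)
    det = k10 * k21
    disc = tr * tr - 4.0 * det
    if disc <= 0:
        raise DomainError("degenerate two-pool configuration (repeated eigenvalues)")
    root = np.sqrt(disc)
    lam1 = (tr + root) / 2.0   # slow
    lam2 = (tr - root) / 2.0   # fast
    if lam1 >= 0 and k21 > 0:
        raise DomainError("two-pool eigenvalues must be negative")
    return k10, k12, k21, lam1, lam2


def two_pool_masses(params: PoolModelParams, t) -> pd.DataFrame:
    """Closed-form tracer masses: plasma, tissue and cumulative loss (µmol/kg).

    Bi-exponential solution of the linear two-compartment tracer system for a
    plasma bolus; at every t, plasma + tissue + loss equals the dose.
    """
    k10, k12, k21, lam1, lam2 = _two_pool_eigen(params)
    t = np.asarray(t, dtype=float)
    d = params.dose_umol_per_kg
    e1, e2 = np.exp(lam1 * t), np.exp(lam2 * t)
    denom = lam1 - lam2
    m_plasma = d * ((lam1 + k21) * e1 - (lam2 + k21) * e2) / denom
    m_tissue = d * k12 * (e1 - e2) / denom
    if k21 > 0 or k12 > 0:
        loss = (
            d
            * k10
            * ((lam1 + k21) * (e1 - 1.0) / lam1 - (lam2 + k21) * (e2 - 1.0) / lam2)
            / denom
        )
    else:
        loss = d * (1.0 - e2)
    return pd.DataFrame(
        {"time_min": t, "plasma": m_plasma, "tissue": m_tissue, "loss": loss}
    )


def simulate_two_pool(
    params: PoolModelParams,
    schedule: SamplingSchedule | None = None,
    *,
    convention: str = "ratio",
    subject_id: str = "sim",
) -> tuple[EnrichmentCurve, dict]:
    """Noiseless bi-exponential plasma enrichment curve plus its ground truth.

    With ``k_exchange = 0`` this reduces exactly to the single-pool output.
    """
    if params.model != "two_pool":
        raise DomainError("simulate_two_pool requires model='two_pool'")
    schedule = schedule or default_schedule()
    t = schedule.times()
    masses = two_pool_masses(params, t)
    r = masses["plasma"].to_numpy() / params.q_plasma
    _, _, _, lam1, _ = _two_pool_eigen(params)
    curve = EnrichmentCurve(
        time_min=t,
        ape_percent=_ratio_to_ape(r, convention),
        baseline_ratio=0.0,
        subject_id=subject_id,
        convention=convention,
    )
    truth = {
        "ra_true": params.ra_true,
        "lambda_slow_per_min": lam1,
        "peak_ratio": params.dose_umol_per_kg / params.q_plasma,
        "auc_infinite": 100.0 * params.dose_umol_per_kg / params.ra_true,
    }
    return curve, truth


def add_noise(
    curve: EnrichmentCurve,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> EnrichmentCurve:
    """Multiply each APE value by an independent lognormal factor (median 1)."""
    factors = noise.factors(len(curve), rng)
    return replace(curve, ape_percent=curve.ape_percent * factors)


def simulate_cohort(
    n_subjects: int,
    *,
    ra_distribution: tuple = ("normal", 6.1, 0.9),
    schedule: SamplingSchedule | None = None,
    noise: NoiseModel | None = None,
    n_visits: int = 1,
    between_visit_cv: float = 0.05,
    q_pool: float = DEFAULT_Q_ONE_POOL,
    dose_umol_per_kg: float = DEFAULT_DOSE_UMOL_PER_KG,
    baseline_ratio: float = DEFAULT_BASELINE_RATIO,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of bolus experiments in the raw-ratio input format.

    Per-subject true Ra is drawn from ``ra_distribution`` — ``("normal",
    mean, sd)`` (truncated at 0.5 µmol/kg/min) or ``("uniform", low, high)``;
    a degenerate value can be forced with ``("constant", value)``.  With
    ``n_visits > 1`` each visit's realised Ra is the subject's value times a
    lognormal day-to-day factor of CV ``between_visit_cv``, emulating
    repeated-measurement (variation-study) designs.

    Returns ``(samples, truth)``: a long table with columns ``subject_id,
    time_min, ratio_tracer`` (baseline rows included) ready for the
    enrichment reader, and the per-record ground truth.  Fully reproducible
    for a fixed ``seed``.
    """
    if n_subjects < 1:
        raise InputError("need n_subjects >= 1")
    schedule = schedule or default_schedule()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    kind = ra_distribution[0]
    if kind == "normal":
        draw = lambda: max(0.5, rng.normal(ra_distribution[1], ra_distribution[2]))
    elif kind == "uniform":
        draw = lambda: rng.uniform(ra_distribution[1], ra_distribution[2])
    elif kind == "constant":
        draw = lambda: float(ra_distribution[1])
    else:
        raise InputError(f"unknown distribution {kind!r}")

    sigma_visit = float(np.sqrt(np.log1p(between_visit_cv**2)))
    sample_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for i in range(1, n_subjects + 1):
        ra_subject = draw()
        for v in range(1, n_visits + 1):
            ra_visit = ra_subject
            if n_visits > 1 and between_visit_cv > 0:
                ra_visit *= float(np.exp(sigma_visit * rng.standard_normal()))
            record_id = f"S{i:02d}" if n_visits == 1 else f"S{i:02d}v{v}"
            params = PoolModelParams(
                ra_true=ra_visit, q_plasma=q_pool, dose_umol_per_kg=dose_umol_per_kg
            )
            curve, _ = simulate_single_pool(params, schedule, convention="ratio")
            noisy = add_noise(curve, noise, rng)
            # Measurement noise acts on the enrichment excess (the stated noise
            # model); baseline rows carry the calibrated natural background.
            n_base = len(schedule.baseline_times)
            t_all = np.concatenate([np.asarray(schedule.baseline_times), noisy.time_min])
            r_all = np.concatenate(
                [np.full(n_base, baseline_ratio), baseline_ratio + noisy.ape_percent / 100.0]
            )
            sample_rows.append(
                pd.DataFrame(
                    {"subject_id": record_id, "time_min": t_all, "ratio_tracer": r_all}
                )
            )
            truth_rows.append(
                {
                    "subject_id": record_id,
                    "subject": f"S{i:02d}",
                    "visit": v,
                    "ra_true": ra_visit,
                    "ra_subject": ra_subject,
                    "k_per_min": ra_visit / q_pool,
                    "q_pool": q_pool,
                    "dose_umol_per_kg": dose_umol_per_kg,
                }
            )
    samples = pd.concat(sample_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return samples, truth
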