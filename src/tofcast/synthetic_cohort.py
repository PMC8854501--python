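"""Synthetic cohorts of virtual patients recovering from neuromuscular block.

Real TOFR (train-of-four ratio) recordings from acceleromyography are not
redistributable, so analyses are developed against virtual cohorts whose
recovery curves carry the statistical structure the downstream experiments
rely on: demographics (age, BMI) shift the recovery timing, so patients with
similar demographics have similar curves.

The latent curve is a logistic sigmoid on the 0-100 percent TOFR scale,

    TOFR(t) = t_max / (1 + exp(-(t - t50) / slope)),

with ``t50`` the time of half-maximal recovery (minutes) and ``slope`` the
sigmoid time scale (minutes).  The generator inverts the curve analytically
(:func:`solve_t50`) so that every virtual patient ends the recording with a
noiseless TOFR of at least 90 percent -- mirroring the clinical exclusion of
cases that had not recovered to TOFR >= 90 by the end of surgery.  Samples
sit on a fixed 15-second grid (four points per minute).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.special import expit

from .errors import ConfigError, DomainError

__all__ = [
    "GeneratorConfig",
    "LatentCurveParams",
    "TOFRSeries",
    "PatientRecord",
    "tofr_curve",
    "solve_t50",
    "generate_patient",
    "generate_cohort",
]

SAMPLE_INTERVAL_S = 15.0
#: Samples per minute on the fixed acquisition grid.
SAMPLES_PER_MINUTE = 60.0 / SAMPLE_INTERVAL_S


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the virtual cohort.

    Defaults emulate the clinical cohort the analysis targets: 83 patients,
    series lengths of 119-228 samples at 15-s spacing, ages 18-75 years,
    BMI 18 to <35 kg/m^2, and end-of-recording TOFR of at least 90 percent.

    Parameters
    ----------
    n_patients:
        Cohort size (>= 2; pairwise and leave-one-out experiments need at
        least two patients).
    length_range:
        Inclusive (low, high) bounds on series length in samples.
    sample_interval:
        Seconds between samples; fixed at 15 by the acquisition protocol.
    age_range, bmi_range:
        Uniform sampling ranges for demographics.  Ages within 18-75 years;
        BMI upper bound at most 35 kg/m^2 (inclusion criteria).
    end_value_range:
        Uniform range of the noiseless TOFR at the final sample, in percent;
        must lie in [90, t_max).
    beta_age, beta_bmi:
        Minutes of t50 shift per year of age (centred at 50 y) and per
        kg/m^2 of BMI (centred at 25).  Positive values prolong recovery,
        matching the reported direction of slower block resolution in the
        elderly.
    slope_base:
        Baseline sigmoid time scale in minutes.
    slope_sd:
        Log-scale standard deviation of the per-patient slope effect.
    patient_sd:
        Standard deviation (minutes) of the patient-level random effect on
        t50, on top of the demographic shift.
    noise_sd:
        Standard deviation of additive observation noise, TOFR percent.
    missing_rate:
        Independent probability that a sample is missing (device artefact);
        the final sample is always observed so the end-value rule can be
        checked.
    seed:
        Cohort-level random seed.
    """

    n_patients: int = 83
    length_range: Tuple[int, int] = (119, 228)
    sample_interval: float = SAMPLE_INTERVAL_S
    age_range: Tuple[float, float] = (18.0, 75.0)
    bmi_range: Tuple[float, float] = (18.0, 35.0)
    end_value_range: Tuple[float, float] = (90.0, 100.0)
    beta_age: float = 0.15
    beta_bmi: float = 0.25
    slope_base: float = 9.0
    slope_sd: float = 0.10
    patient_sd: float = 2.0
    t_max: float = 100.0
    noise_sd: float = 1.5
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.length_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ConfigError("length_range bounds must be integers")
        if not (0 < lo <= hi):
            raise ConfigError(f"length_range must satisfy 0 < low <= high, got {self.length_range}")
        if self.sample_interval != SAMPLE_INTERVAL_S:
            raise ConfigError("sample_interval is fixed at 15 s by the acquisition protocol")
        a_lo, a_hi = self.age_range
        if not (18.0 <= a_lo <= a_hi <= 75.0):
            raise ConfigError(f"age_range must lie within [18, 75] years, got {self.age_range}")
        b_lo, b_hi = self.bmi_range
        if not (0 < b_lo <= b_hi <= 35.0):
            raise ConfigError(f"bmi_range upper bound must be <= 35 kg/m^2, got {self.bmi_range}")
        e_lo, e_hi = self.end_value_range
        if not (90.0 <= e_lo <= e_hi <= self.t_max) or e_lo >= self.t_max:
            raise ConfigError(
                f"end_value_range must lie in [90, t_max] with its lower bound below "
                f"t_max={self.t_max}, got {self.end_value_range}"
            )
        if not (0 < self.t_max <= 110.0):
            raise ConfigError(f"t_max must be in (0, 110], got {self.t_max}")
        if not (0 <= self.missing_rate < 0.5):
            raise ConfigError(f"missing_rate must be in [0, 0.5), got {self.missing_rate}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.patient_sd < 0 or self.slope_sd < 0:
            raise ConfigError("patient_sd and slope_sd must be >= 0")
        if self.slope_base <= 0:
            raise ConfigError(f"slope_base must be > 0, got {self.slope_base}")
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2 (pairwise/LOOCV experiments need >= 2)")


@dataclass(frozen=True)
class LatentCurveParams:
    """Parameters of the noiseless logistic recovery curve."""

    t50: float
    slope: float
    t_max: float = 100.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigError(f"slope must be > 0, got {self.slope}")
        if not (0 < self.t_max <= 110.0):
            raise ConfigError(f"t_max must be in (0, 110], got {self.t_max}")


@dataclass(frozen=True)
class TOFRSeries:
    """A TOFR sequence on the 15-s grid with a missingness mask.

    ``values[i]`` is the TOFR in percent at sample index ``i`` (time
    ``i * 15`` seconds); unobserved samples hold NaN and have
    ``observed[i] == False``.
    """

    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        observed = np.asarray(self.observed, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "observed", observed)
        if values.ndim != 1 or observed.shape != values.shape:
            raise ConfigError("values and observed must be parallel 1-D arrays")
        obs_vals = values[observed]
        if obs_vals.size and (not np.all(np.isfinite(obs_vals)) or np.any(obs_vals < 0)):
            raise ConfigError("observed TOFR values must be finite and >= 0")

    def __len__(self) -> int:
        return int(self.values.shape[0])

    @property
    def n(self) -> int:
        return len(self)

    @property
    def t_index(self) -> np.ndarray:
        return np.arange(len(self))

    def times_minutes(self) -> np.ndarray:
        """Sample times in minutes on the 15-s grid."""
        return self.t_index * (SAMPLE_INTERVAL_S / 60.0)


@dataclass(frozen=True)
class PatientRecord:
    """Demographics plus one TOFR series; the unit of training and transfer."""

    patient_id: str
    age: float
    bmi: float
    series: TOFRSeries
    latent: Optional[LatentCurveParams] = field(default=None, compare=False)


def tofr_curve(t, params: LatentCurveParams):
    """Noiseless logistic recovery curve, in TOFR percent.

    ``t`` is time in minutes (scalar or array).  Total function,
    nondecreasing in ``t``; tends to 0 for early times and to ``t_max``
    late in recovery.
    """
    t = np.asarray(t, dtype=float)
    out = params.t_max * expit((t - params.t50) / params.slope)
    return float(out) if out.ndim == 0 else out


def solve_t50(end_time: float, end_value: float, slope: float, t_max: float = 100.0) -> float:
    """Invert the logistic curve: the t50 for which TOFR(end_time) == end_value.

    Closed form: ``t50 = end_time + slope * log(t_max / end_value - 1)``.
    Raises :class:`DomainError` unless ``0 < end_value < t_max``.
    """
    if slope <= 0:
        raise DomainError(f"slope must be > 0, got {slope}")
    if not (0.0 < end_value < t_max):
        raise DomainError(
            f"end_value must be strictly between 0 and t_max={t_max}, got {end_value}"
        )
    return end_time + slope * math.log(t_max / end_value - 1.0)


def _draw_latent(
    config: GeneratorConfig, rng: np.random.Generator
) -> Tuple[float, float, int, LatentCurveParams]:
    """Sample demographics, series length and latent curve for one patient."""
    age = rng.uniform(*config.age_range)
    bmi = rng.uniform(*config.bmi_range)
    lo, hi = config.length_range
    n = int(rng.integers(lo, hi + 1))
    slope = config.slope_base * math.exp(rng.normal(0.0, config.slope_sd))
    target_end = rng.uniform(*config.end_value_range)
    if target_end >= config.t_max:  # guard the open upper edge of the uniform draw
        target_end = np.nextafter(config.t_max, 0.0)
    # time of the final sample on the 0-based 15-s grid, in minutes
    end_time = (n - 1) * config.sample_interval / 60.0

    t50_base = solve_t50(end_time, target_end, slope, config.t_max)
    shift = (
        config.beta_age * (age - 50.0)
        + config.beta_bmi * (bmi - 25.0)
        + rng.normal(0.0, config.patient_sd)
    )
    # Demographics shift t50 BEFORE the end-value clamp: similar (age, bmi)
    # must give correlated dynamics, which the transfer experiments test.
    t50 = t50_base + shift
    # Largest t50 still compatible with a noiseless end value >= 90.
    t50_cap = solve_t50(end_time, 90.0, slope, config.t_max)
    t50 = min(t50, t50_cap)
    return age, bmi, n, LatentCurveParams(t50=t50, slope=slope, t_max=config.t_max)


def generate_patient(
    config: GeneratorConfig, rng: np.random.Generator, patient_id: str = "p001"
) -> PatientRecord:
    """Draw one virtual patient from the configured cohort distribution.

    Demographics are uniform over their ranges; the recovery midpoint t50 is
    solved so the noiseless end value lands in ``end_value_range``, then
    shifted by the demographic terms and a patient-level random effect, and
    finally capped so the noiseless final TOFR stays >= 90.  Observed values
    add Gaussian noise (clipped at 0; acceleromyography may read above 100,
    so no upper clip).  Each sample is missing independently with
    ``missing_rate`` except the final one, which is always observed.
    """
    config.validate()
    age, bmi, n, latent = _draw_latent(config, rng)

    t = np.arange(n) * (config.sample_interval / 60.0)
    clean = tofr_curve(t, latent)
    values = clean + rng.normal(0.0, config.noise_sd, size=n)
    values = np.maximum(values, 0.0)

    observed = rng.random(n) >= config.missing_rate
    observed[-1] = True
    values = np.where(observed, values, np.nan)

    series = TOFRSeries(values=values, observed=observed)
    return PatientRecord(patient_id=patient_id, age=age, bmi=bmi, series=series, latent=latent)


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` virtual patients, ids ``p001``, ``p002``, ...

    Fully reproducible from ``config.seed``: each patient gets an
    independent child stream spawned from the cohort seed, so the cohort is
    identical regardless of how the records are later consumed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    width = max(3, len(str(config.n_patients)))
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        pid = f"p{i + 1:0{width}d}"
        cohort.append(generate_patient(config, rng, patient_id=pid))
    return cohort


def noiseless_series(record: PatientRecord, config: GeneratorConfig) -> np.ndarray:
    """Reconstruct the latent noise-free curve of a generated patient."""
    if record.latent is None:
        raise ConfigError(f"patient {record.patient_id} carries no latent curve parameters")
    t = np.arange(len(record.series)) * (config.sample_interval / 60.0)
    return tofr_curve(t, record.latent)


def strong_covariate_config(**overrides) -> GeneratorConfig:
    """A cohort configuration with a strong demographic effect on dynamics.

    Used by the transfer-learning direction-of-effect experiments: large
    beta_age/beta_bmi, small patient-level random effect and low noise, so
    demographic similarity translates into curve similarity.
    """
    base = dict(
        beta_age=0.8,
        beta_bmi=1.2,
        patient_sd=0.5,
        slope_sd=0.05,
        noise_sd=0.5,
        missing_rate=0.02,
    )
    base.update(overrides)
    return GeneratorConfig(**base)
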