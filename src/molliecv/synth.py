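"""Synthetic inputs: phantom fixtures and contrast-kinetics scan series.

The generator states a simple world for end-to-end testing:

* blood-pool ΔR1 follows the injection protocol — a monoexponential
  clearance after a bolus (default half-life 90 min, slow relative to the
  12-50 min observation window) or a saturating rise to a plateau during a
  constant infusion (99% of plateau by 25 min);
* myocardial ΔR1 is ``λ × blood ΔR1`` at every instant, i.e. the tissues
  are in exchange equilibrium with a constant true partition coefficient;
* measured T1 is ``1 / (1/T1_pre + ΔR1)`` perturbed multiplicatively by
  independent Gaussian noise (default 1.4% of T1, which makes the median
  absolute within-scan repeat difference about 1.3%).

What this world leaves out: two-compartment exchange transients, renal
function covariates, correlated blood/myocardium errors within one
acquisition (a correlation knob is exposed for sensitivity tests), and any
readout-dependent T1 bias.  A green recovery test therefore establishes
that the pipeline inverts its own stated kinetics, not that a scanner
would behave this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .ecv import ScanSeries, TissueT1Point
from .errors import InvalidParameterError

__all__ = [
    "PhantomSpec",
    "phantom_set",
    "KineticsConfig",
    "generate_scan",
    "CohortSubject",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """A CuSO4-agar phantom role with its reference T1/T2 values."""

    label: str
    t1_msec: float
    t2_msec: float

    def __post_init__(self):
        if self.t1_msec <= 0 or self.t2_msec <= 0:
            raise InvalidParameterError("phantom T1 and T2 must be positive")


def phantom_set() -> list[PhantomSpec]:
    """The seven reference phantoms spanning pre/post-contrast blood and
    myocardium T1/T2 values."""
    return [
        PhantomSpec("blood-pre", 1535.0, 172.0),
        PhantomSpec("myo-pre-1", 909.0, 44.0),
        PhantomSpec("myo-pre-2", 887.0, 38.0),
        PhantomSpec("blood-post-1", 309.0, 187.0),
        PhantomSpec("blood-post-2", 251.0, 171.0),
        PhantomSpec("myo-post-1", 342.0, 53.0),
        PhantomSpec("myo-post-2", 260.0, 53.0),
    ]


_DEFAULT_BOLUS_TIMES = tuple(np.arange(12.0, 50.1, 4.0))
_DEFAULT_INFUSION_TIMES = tuple(np.arange(3.0, 58.1, 5.0))

#: default multiplicative T1 noise; |N(0,s)-N(0,s)| has median
#: 0.6745*s*sqrt(2), so s = 0.0136 reproduces ~1.3% within-scan repeats
DEFAULT_NOISE_FRAC = 0.0136


@dataclass(frozen=True)
class KineticsConfig:
    """Stated world for one synthetic subject-scan."""

    protocol: str  # "bolus" | "infusion"
    true_lambda: float = 0.45
    hematocrit: float = 0.40
    pre_blood_t1_msec: float = 1500.0
    pre_myo_t1_msec: float = 950.0
    peak_blood_dr1: float = 0.002  # 1/msec at t=0 (bolus)
    clearance_halflife_min: float = 90.0  # bolus renal clearance
    plateau_time_min: float = 25.0  # infusion: 99% of plateau reached here
    plateau_level: float = 0.0018  # infusion plateau blood ΔR1, 1/msec
    sample_times_min: Optional[tuple[float, ...]] = None
    noise_frac: float = DEFAULT_NOISE_FRAC
    noise_corr: float = 0.0  # blood/myo error correlation within a timepoint
    equilibration_lag_min: float = 0.0  # >0 delays myocardial uptake
    seed: int = 0

    def __post_init__(self):
        if self.protocol not in ("bolus", "infusion"):
            raise InvalidParameterError(f"protocol must be bolus|infusion, got {self.protocol!r}")
        if not (0.2 < self.true_lambda < 0.7):
            raise InvalidParameterError("true_lambda must lie in (0.2, 0.7)")
        if self.noise_frac < 0:
            raise InvalidParameterError("noise_frac must be >= 0")
        if not (-1.0 < self.noise_corr < 1.0):
            raise InvalidParameterError("noise_corr must lie in (-1, 1)")
        if self.sample_times_min is not None:
            t = tuple(float(v) for v in self.sample_times_min)
            if list(t) != sorted(t):
                raise InvalidParameterError("sample_times_min must be sorted")
            object.__setattr__(self, "sample_times_min", t)

    @property
    def times(self) -> np.ndarray:
        if self.sample_times_min is not None:
            return np.asarray(self.sample_times_min, dtype=float)
        default = _DEFAULT_BOLUS_TIMES if self.protocol == "bolus" else _DEFAULT_INFUSION_TIMES
        return np.asarray(default, dtype=float)


def _blood_dr1(config: KineticsConfig, t_min: np.ndarray) -> np.ndarray:
    if config.protocol == "bolus":
        return config.peak_blood_dr1 * np.power(2.0, -t_min / config.clearance_halflife_min)
    # saturating rise hitting 99% of plateau at plateau_time
    k = np.log(100.0) / config.plateau_time_min
    return config.plateau_level * (1.0 - np.exp(-k * t_min))


def generate_scan(config: KineticsConfig, subject_id: str = "synthetic") -> ScanSeries:
    """Simulate one subject-scan under the configured kinetics.

    Deterministic given ``config.seed``.  Raises when the kinetics would
    produce a non-positive T1.
    """
    t = config.times
    dr1_b = _blood_dr1(config, t)
    lam_eff = config.true_lambda * np.ones_like(t)
    if config.equilibration_lag_min > 0:
        lam_eff = lam_eff * (1.0 - np.exp(-t / config.equilibration_lag_min))
    dr1_m = lam_eff * dr1_b

    t1_b = 1.0 / (1.0 / config.pre_blood_t1_msec + dr1_b)
    t1_m = 1.0 / (1.0 / config.pre_myo_t1_msec + dr1_m)
    if np.any(t1_b <= 0) or np.any(t1_m <= 0):
        raise InvalidParameterError("kinetics produced non-positive T1")

    rng = np.random.default_rng(config.seed)
    eps_b = rng.standard_normal(t.size)
    eps_i = rng.standard_normal(t.size)
    rho = config.noise_corr
    eps_m = rho * eps_b + np.sqrt(1.0 - rho * rho) * eps_i
    t1_b = t1_b * (1.0 + config.noise_frac * eps_b)
    t1_m = t1_m * (1.0 + config.noise_frac * eps_m)

    points = []
    for ti, b, m in zip(t, t1_b, t1_m):
        points.append(TissueT1Point(time_min=float(ti), tissue="blood", t1_msec=float(b)))
        points.append(TissueT1Point(time_min=float(ti), tissue="myocardium", t1_msec=float(m)))
    return ScanSeries(
        subject_id=subject_id,
        protocol=config.protocol,
        hematocrit=config.hematocrit,
        pre_blood_t1_msec=config.pre_blood_t1_msec,
        pre_myo_t1_msec=config.pre_myo_t1_msec,
        points=points,
    )


@dataclass(frozen=True)
class CohortSubject:
    """One synthetic subject with paired bolus and infusion scans and the
    true parameters needed for recovery scoring."""

    subject_id: str
    age_group: str  # "young" | "old"
    true_lambda: float
    hematocrit_bolus: float
    hematocrit_infusion: float
    bolus: ScanSeries
    infusion: ScanSeries

    def manifest(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "age_group": self.age_group,
            "true_lambda": self.true_lambda,
            "hematocrit_bolus": self.hematocrit_bolus,
            "hematocrit_infusion": self.hematocrit_infusion,
        }


# Age-group parameter distributions bracketing a healthy-young vs
# older-with-comorbidity cohort: older subjects have a higher, tighter λ
# and a lower, more variable hematocrit.
_LAMBDA_DIST = {"young": (0.42, 0.02), "old": (0.46, 0.01)}
_HCT_DIST = {"young": (0.42, 0.025), "old": (0.38, 0.05)}
_HCT_SESSION_SD = 0.01  # hematocrit is re-measured at each session


def generate_cohort(
    n_young: int = 6,
    n_old: int = 4,
    seed: int = 0,
    noise_frac: float = DEFAULT_NOISE_FRAC,
    hct_session_sd: float = _HCT_SESSION_SD,
) -> list[CohortSubject]:
    """Paired bolus/infusion scans for a two-age-group cohort.

    Each subject has a single true λ shared by both protocols and a
    per-session hematocrit; scans are generated with independent noise.
    Setting ``hct_session_sd=0`` makes the two sessions share the same true
    hematocrit (and hence the same true Ve) — the strict
    technique-equivalent null used in agreement simulations.
    """
    if n_young + n_old < 1:
        raise InvalidParameterError("cohort must contain at least one subject")
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    groups = ["young"] * n_young + ["old"] * n_old
    for i, group in enumerate(groups):
        lam_mu, lam_sd = _LAMBDA_DIST[group]
        hct_mu, hct_sd = _HCT_DIST[group]
        lam = float(np.clip(rng.normal(lam_mu, lam_sd), 0.25, 0.65))
        hct_base = float(np.clip(rng.normal(hct_mu, hct_sd), 0.2, 0.55))
        hct_b = float(np.clip(hct_base + rng.normal(0, 1.0) * hct_session_sd, 0.15, 0.6))
        hct_i = float(np.clip(hct_base + rng.normal(0, 1.0) * hct_session_sd, 0.15, 0.6))
        seed_b, seed_i = rng.integers(0, 2**31 - 1, size=2)
        sid = f"S{i + 1:02d}"
        bolus = generate_scan(
            KineticsConfig(
                protocol="bolus",
                true_lambda=lam,
                hematocrit=hct_b,
                noise_frac=noise_frac,
                seed=int(seed_b),
            ),
            subject_id=sid,
        )
        infusion = generate_scan(
            KineticsConfig(
                protocol="infusion",
                true_lambda=lam,
                hematocrit=hct_i,
                noise_frac=noise_frac,
                seed=int(seed_i),
            ),
            subject_id=sid,
        )
        subjects.append(
            CohortSubject(
                subject_id=sid,
                age_group=group,
                true_lambda=lam,
                hematocrit_bolus=hct_b,
                hematocrit_infusion=hct_i,
                bolus=bolus,
                infusion=infusion,
            )
        )
    return subjects
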