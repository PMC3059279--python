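"""Partition coefficient and extracellular volume fraction (ECV / Ve).

Gadolinium contrast distributes in plasma and the myocardial interstitium
but not inside cells, and the change in longitudinal relaxation rate
``ΔR1 = 1/T1_post - 1/T1_pre`` is proportional to its local concentration.
At plasma-interstitium equilibrium the myocardium-to-blood ratio

    λ = ΔR1_myocardium / ΔR1_blood

is the tissue-blood partition coefficient, and the extravascular
extracellular volume fraction follows as

    Ve = λ · ρ · (1 - hematocrit) - Vp

with ρ = 1.05 (myocardial specific density) and Vp = 0.045 (plasma volume
fraction).  Because λ is a ratio of concentrations, Ve is insensitive to
the slow renal clearance of contrast: serial Ve measures stay flat both
during a constant infusion and in the 12-50 min window after a bolus.

Serial measurements are carried in :class:`ScanSeries`; :func:`ve_series`
computes λ and Ve per paired timepoint, restricting infusion scans to the
detected steady-state window and bolus scans to times at least 12 min
after contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "ECVConstants",
    "TissueT1Point",
    "ScanSeries",
    "ECVResult",
    "delta_r1",
    "partition_coefficient",
    "ve_from_lambda",
    "lambda_from_ve",
    "steady_state_window",
    "ve_series",
    "read_scan_csv",
    "write_scan_csv",
]

#: bolus measurements before this delay are discarded (contrast not yet
#: fully dispersed between tissues)
BOLUS_DELAY_MIN = 12.0
_LAMBDA_PHYSIOLOGIC = (0.3, 0.6)
_T1_RANGE_MSEC = (1.0, 10_000.0)


@dataclass(frozen=True)
class ECVConstants:
    """Fixed tissue constants of the Ve equation."""

    rho: float = 1.05  # myocardial specific density, g/mL
    vp: float = 0.045  # myocardial plasma volume fraction


DEFAULT_CONSTANTS = ECVConstants()


@dataclass(frozen=True)
class TissueT1Point:
    """One post-contrast T1 measurement of blood or myocardium."""

    time_min: float
    tissue: str  # "blood" | "myocardium"
    t1_msec: float

    def __post_init__(self):
        if self.tissue not in ("blood", "myocardium"):
            raise InvalidParameterError(f"tissue must be blood|myocardium, got {self.tissue!r}")
        if not (_T1_RANGE_MSEC[0] < self.t1_msec < _T1_RANGE_MSEC[1]):
            raise InvalidParameterError(f"t1_msec {self.t1_msec} outside {_T1_RANGE_MSEC}")
        if self.time_min < 0:
            raise InvalidParameterError("time_min must be >= 0")


def _normalize_hct(hct: float) -> float:
    if hct > 1.0:
        warnings.warn(
            f"hematocrit {hct} looks like a percentage; converting to fraction",
            stacklevel=3,
        )
        hct = hct / 100.0
    if not (0.1 < hct < 0.65):
        raise InvalidParameterError(f"hematocrit fraction {hct} outside plausible (0.1, 0.65)")
    return hct


@dataclass
class ScanSeries:
    """Serial blood/myocardium T1 measurements of one subject-scan."""

    subject_id: str
    protocol: str  # "bolus" | "infusion"
    hematocrit: float
    pre_blood_t1_msec: float
    pre_myo_t1_msec: float
    points: list[TissueT1Point] = field(default_factory=list)

    def __post_init__(self):
        if self.protocol not in ("bolus", "infusion"):
            raise InvalidParameterError(f"protocol must be bolus|infusion, got {self.protocol!r}")
        self.hematocrit = _normalize_hct(self.hematocrit)
        if not self.points:
            raise InsufficientDataError("ScanSeries needs at least one post-contrast timepoint")
        for pre, tissue in (
            (self.pre_blood_t1_msec, "blood"),
            (self.pre_myo_t1_msec, "myocardium"),
        ):
            post_max = max(
                (p.t1_msec for p in self.points if p.tissue == tissue), default=None
            )
            if post_max is not None and post_max >= pre:
                raise InvalidParameterError(
                    f"pre-contrast {tissue} T1 ({pre}) must exceed all post-contrast values"
                )

    def paired(self) -> pd.DataFrame:
        """Blood/myocardium T1 pairs sharing an acquisition time.

        Unpaired timepoints are dropped with a warning.
        """
        df = pd.DataFrame(
            [(p.time_min, p.tissue, p.t1_msec) for p in self.points],
            columns=["time_min", "tissue", "t1_msec"],
        )
        wide = df.pivot_table(index="time_min", columns="tissue", values="t1_msec")
        for col in ("blood", "myocardium"):
            if col not in wide:
                wide[col] = np.nan
        n_unpaired = int(wide.isna().any(axis=1).sum())
        if n_unpaired:
            warnings.warn(f"dropping {n_unpaired} unpaired timepoint(s)", stacklevel=2)
        out = wide.dropna().reset_index()
        out.columns.name = None
        return out[["time_min", "blood", "myocardium"]]


def delta_r1(t1_pre_msec: float, t1_post_msec: float):
    """Relaxation-rate change ``1/T1_post - 1/T1_pre`` in 1/msec.

    Positive whenever contrast shortens T1.
    """
    pre = np.asarray(t1_pre_msec, dtype=float)
    post = np.asarray(t1_post_msec, dtype=float)
    if np.any(pre <= 0) or np.any(post <= 0):
        raise InvalidParameterError("T1 values must be positive")
    out = 1.0 / post - 1.0 / pre
    return float(out) if out.ndim == 0 else out


def partition_coefficient(dr1_myo, dr1_blood, warn: bool = True):
    """λ = ΔR1_myocardium / ΔR1_blood; warns outside ~0.3-0.6."""
    myo = np.asarray(dr1_myo, dtype=float)
    blood = np.asarray(dr1_blood, dtype=float)
    if np.any(blood <= 0):
        raise InvalidParameterError("dr1_blood must be positive (no contrast effect in blood)")
    lam = myo / blood
    if warn and np.any((lam < _LAMBDA_PHYSIOLOGIC[0]) | (lam > _LAMBDA_PHYSIOLOGIC[1])):
        warnings.warn(
            f"partition coefficient outside physiologic range {_LAMBDA_PHYSIOLOGIC}",
            stacklevel=2,
        )
    return float(lam) if lam.ndim == 0 else lam


def ve_from_lambda(lambda_, hematocrit, constants: ECVConstants = DEFAULT_CONSTANTS):
    """Ve = λ·ρ·(1 - hematocrit) - Vp, as a fraction."""
    lam = np.asarray(lambda_, dtype=float)
    hct = np.asarray(hematocrit, dtype=float)
    if np.any(lam <= 0):
        raise InvalidParameterError("lambda must be positive")
    if np.any((hct <= 0) | (hct >= 1)):
        raise InvalidParameterError("hematocrit must be a fraction in (0, 1)")
    out = lam * constants.rho * (1.0 - hct) - constants.vp
    return float(out) if out.ndim == 0 else out


def lambda_from_ve(ve, hematocrit, constants: ECVConstants = DEFAULT_CONSTANTS):
    """Exact inverse of :func:`ve_from_lambda`: λ = (Ve + Vp) / (ρ·(1 - hct))."""
    v = np.asarray(ve, dtype=float)
    hct = np.asarray(hematocrit, dtype=float)
    if np.any(hct >= 1) or np.any(hct <= 0):
        raise InvalidParameterError("hematocrit must be a fraction in (0, 1)")
    out = (v + constants.vp) / (constants.rho * (1.0 - hct))
    return float(out) if out.ndim == 0 else out


def steady_state_window(
    series: ScanSeries, tolerance: float = 0.05
) -> Optional[tuple[float, float]]:
    """Longest suffix of timepoints with both tissues' T1 stable.

    Stability means (max T1 - min T1) / mean T1 < ``tolerance`` within the
    window, for blood and myocardium simultaneously.  Returns the (start,
    end) times in minutes, or None when no window of at least two points
    qualifies.
    """
    paired = series.paired()
    n = len(paired)
    if n < 2:
        raise InsufficientDataError("steady-state detection needs >= 2 paired timepoints")

    def stable(values: np.ndarray) -> bool:
        return (values.max() - values.min()) / values.mean() < tolerance

    # Dropping leading points only shrinks the range, so qualifying
    # suffixes are nested: the first qualifying start gives the longest.
    for start in range(0, n - 1):
        window = paired.iloc[start:]
        if stable(window["blood"].to_numpy()) and stable(window["myocardium"].to_numpy()):
            return (float(window["time_min"].iloc[0]), float(window["time_min"].iloc[-1]))
    return None


@dataclass
class ECVResult:
    """λ and Ve per paired timepoint plus per-scan summaries."""

    subject_id: str
    protocol: str
    time_min: np.ndarray
    lambda_: np.ndarray
    ve: np.ndarray
    steady_state: Optional[tuple[float, float]]
    mean_ve: float
    sd_ve: float
    sem_ve: float
    mean_lambda: float
    sem_lambda: float

    @property
    def n_points(self) -> int:
        return int(self.time_min.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.time_min, "lambda": self.lambda_, "ve": self.ve}
        )

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "protocol": self.protocol,
            "n_points": self.n_points,
            "steady_state_window": list(self.steady_state) if self.steady_state else None,
            "mean_ve": self.mean_ve,
            "sd_ve": self.sd_ve,
            "sem_ve": self.sem_ve,
            "mean_lambda": self.mean_lambda,
            "sem_lambda": self.sem_lambda,
        }


def ve_series(
    series: ScanSeries,
    constants: ECVConstants = DEFAULT_CONSTANTS,
    tolerance: float = 0.05,
) -> ECVResult:
    """λ and Ve over the qualifying timepoints of one scan.

    Infusion scans are restricted to the detected steady-state window (all
    points are used, with a warning, when none is found); bolus scans use
    every point at or after the 12-minute dispersion delay.
    """
    paired = series.paired()
    window = None
    if series.protocol == "infusion":
        if len(paired) >= 2:
            window = steady_state_window(series, tolerance=tolerance)
        if window is not None:
            sel = paired[paired["time_min"] >= window[0]]
        else:
            warnings.warn(
                "no steady-state window found; using all infusion timepoints",
                stacklevel=2,
            )
            sel = paired
    else:  # bolus
        sel = paired[paired["time_min"] >= BOLUS_DELAY_MIN]
    if sel.empty:
        raise InsufficientDataError(
            f"no qualifying timepoints for {series.protocol} scan {series.subject_id!r}"
        )

    dr1_b = delta_r1(series.pre_blood_t1_msec, sel["blood"].to_numpy())
    dr1_m = delta_r1(series.pre_myo_t1_msec, sel["myocardium"].to_numpy())
    lam = partition_coefficient(dr1_m, dr1_b, warn=False)
    ve = ve_from_lambda(lam, series.hematocrit, constants)
    n = lam.size
    sd = float(np.std(ve, ddof=1)) if n > 1 else 0.0
    sd_lam = float(np.std(lam, ddof=1)) if n > 1 else 0.0
    return ECVResult(
        subject_id=series.subject_id,
        protocol=series.protocol,
        time_min=sel["time_min"].to_numpy(),
        lambda_=np.atleast_1d(lam),
        ve=np.atleast_1d(ve),
        steady_state=window,
        mean_ve=float(np.mean(ve)),
        sd_ve=sd,
        sem_ve=sd / np.sqrt(n),
        mean_lambda=float(np.mean(lam)),
        sem_lambda=sd_lam / np.sqrt(n),
    )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["subject_id", "protocol", "hematocrit", "phase", "time_min", "tissue", "t1_msec"]


def write_scan_csv(series: ScanSeries, path) -> None:
    """Tidy CSV: one row per (phase, time, tissue) T1 measurement."""
    rows = [
        (series.subject_id, series.protocol, series.hematocrit, "pre", -1.0, "blood",
         series.pre_blood_t1_msec),
        (series.subject_id, series.protocol, series.hematocrit, "pre", -1.0, "myocardium",
         series.pre_myo_t1_msec),
    ]
    rows += [
        (series.subject_id, series.protocol, series.hematocrit, "post", p.time_min, p.tissue,
         p.t1_msec)
        for p in series.points
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_scan_csv(path) -> ScanSeries:
    """Read a scan written by :func:`write_scan_csv`.

    A missing ``phase`` column is tolerated: rows with ``time_min < 0`` are
    treated as pre-contrast.
    """
    df = pd.read_csv(path)
    if "phase" not in df.columns:
        df["phase"] = np.where(df["time_min"] < 0, "pre", "post")
    pre = df[df["phase"] == "pre"].set_index("tissue")["t1_msec"]
    post = df[df["phase"] == "post"]
    points = [
        TissueT1Point(time_min=float(r.time_min), tissue=str(r.tissue), t1_msec=float(r.t1_msec))
        for r in post.itertuples()
    ]
    first = df.iloc[0]
    return ScanSeries(
        subject_id=str(first["subject_id"]),
        protocol=str(first["protocol"]),
        hematocrit=float(first["hematocrit"]),
        pre_blood_t1_msec=float(pre["blood"]),
        pre_myo_t1_msec=float(pre["myocardium"]),
        points=points,
    )
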