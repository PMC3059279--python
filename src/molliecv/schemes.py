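"""Cardiac-gated Look-Locker (MOLLI) sampling schemes.

A scheme is an ordered list of inversion groups; within a group one image
is acquired per heart beat, so the effective inversion time (TIeff) of
successive images grows by one R-R interval.  The base TIeff of group g is
``TI0 + g * dTI`` (TI0 = 90 msec, dTI = 80 msec here), and inversion
pulses are separated by dummy recovery beats.

Three named schemes are provided:

* ``classic``      3+3+5 sampling, 11 images — the conventional scheme;
* ``hybrid_pre``   5+1, 6 images — shortened scheme for long pre-contrast T1;
* ``hybrid_post``  4+2+1, 7 images — shortened scheme that samples the fast
  early recovery of short post-contrast T1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "SamplingScheme",
    "TISchedule",
    "make_scheme",
    "ti_schedule",
    "breath_hold_beats",
    "rr_from_heart_rate",
]

RR_RANGE_MSEC = (300.0, 2000.0)


@dataclass(frozen=True)
class SamplingScheme:
    name: str
    samples_per_inversion: tuple[int, ...]
    dummy_beats_between: int = 3
    ti0_msec: float = 90.0
    dti_msec: float = 80.0

    def __post_init__(self):
        spi = tuple(int(k) for k in self.samples_per_inversion)
        object.__setattr__(self, "samples_per_inversion", spi)
        if len(spi) < 1 or any(k < 1 for k in spi):
            raise InvalidParameterError("samples_per_inversion must be positive counts")
        if self.dummy_beats_between < 0:
            raise InvalidParameterError("dummy_beats_between must be >= 0")
        if self.ti0_msec <= 0 or self.dti_msec < 0:
            raise InvalidParameterError("require ti0_msec > 0 and dti_msec >= 0")

    @property
    def total_images(self) -> int:
        return sum(self.samples_per_inversion)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "samples_per_inversion": list(self.samples_per_inversion),
            "dummy_beats_between": self.dummy_beats_between,
            "ti0_msec": self.ti0_msec,
            "dti_msec": self.dti_msec,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingScheme":
        return cls(
            name=d["name"],
            samples_per_inversion=tuple(d["samples_per_inversion"]),
            dummy_beats_between=int(d.get("dummy_beats_between", 3)),
            ti0_msec=float(d.get("ti0_msec", 90.0)),
            dti_msec=float(d.get("dti_msec", 80.0)),
        )

    @classmethod
    def from_json(cls, path) -> "SamplingScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class TISchedule:
    """Effective-inversion-time schedule of a scheme at one cardiac period.

    ``entries`` holds (inversion_index, beat_index_within_group, ti_eff_msec)
    in acquisition order; within a group the TIeffs step by exactly one R-R.
    """

    entries: tuple[tuple[int, int, float], ...]
    rr_msec: float

    @property
    def ti_msec(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


_KINDS = {
    "classic": (3, 3, 5),
    "hybrid_pre": (5, 1),
    "hybrid_post": (4, 2, 1),
}


def make_scheme(kind: str) -> SamplingScheme:
    """Build one of the named schemes: classic (3+3+5), hybrid_pre (5+1),
    hybrid_post (4+2+1), all with TI0 = 90 msec, dTI = 80 msec and 3 dummy
    beats between inversions."""
    if kind not in _KINDS:
        raise InvalidParameterError(
            f"unknown scheme kind {kind!r}; expected one of {sorted(_KINDS)}"
        )
    return SamplingScheme(name=kind, samples_per_inversion=_KINDS[kind])


def rr_from_heart_rate(hr_bpm: float) -> float:
    """Cardiac period in msec from heart rate in beats per minute."""
    if hr_bpm <= 0:
        raise InvalidParameterError("heart rate must be positive")
    return 60_000.0 / float(hr_bpm)


def ti_schedule(scheme: SamplingScheme, rr_msec: float) -> TISchedule:
    """TIeff schedule at cardiac period ``rr_msec``.

    Image k (0-based) of inversion group g is acquired at
    ``TI0 + g*dTI + k*RR``.
    """
    if not (RR_RANGE_MSEC[0] <= rr_msec <= RR_RANGE_MSEC[1]):
        raise InvalidParameterError(
            f"rr_msec {rr_msec} outside supported range {RR_RANGE_MSEC}"
        )
    entries = []
    for g, n_images in enumerate(scheme.samples_per_inversion):
        base = scheme.ti0_msec + g * scheme.dti_msec
        for k in range(n_images):
            entries.append((g, k, base + k * rr_msec))
    return TISchedule(entries=tuple(entries), rr_msec=float(rr_msec))


def breath_hold_beats(scheme: SamplingScheme) -> int:
    """Heart beats needed for one acquisition: one beat per image plus the
    dummy recovery beats between inversion groups."""
    n_groups = len(scheme.samples_per_inversion)
    return scheme.total_images + scheme.dummy_beats_between * (n_groups - 1)
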