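"""Crop-stress-coefficient interpolation and seasonal ET integration.

Per flight date the stress coefficient Ks = ETa/ETp summarises how far the
canopy's actual water use falls below its potential.  Early in the season
(0–100 days after sowing) water needs are assumed fully met, Ks = 1.
Between flights Ks is held piecewise-constant: each flight's value applies
from the midpoint with the previous flight (DAS 101 for the first) through
the midpoint with the next (floor division), and the last value holds to
maturity.  Daily ETa = Ks·ETp is then integrated over the whole season and
split at heading into vegetative and grain-filling totals; water
productivity converts grain yield per cumulative ETa into kg·m⁻³.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Phenology",
    "KsPoint",
    "StageIntegrals",
    "crop_stress_coefficient",
    "interpolate_ks",
    "daily_eta_series",
    "stage_integrals",
    "water_productivity",
    "KS_UNITY_UNTIL_DAS",
]

KS_UNITY_UNTIL_DAS = 100


@dataclass(frozen=True)
class Phenology:
    """Key growth-stage dates of one variety (days after sowing).

    heading = GS55, physiological maturity = GS87.
    """

    variety: str
    heading_das: int
    maturity_das: int

    def __post_init__(self) -> None:
        if not 0 < self.heading_das < self.maturity_das:
            raise ValueError(
                f"need 0 < heading ({self.heading_das}) < maturity "
                f"({self.maturity_das})"
            )


@dataclass(frozen=True)
class KsPoint:
    """Stress coefficient observed at one flight date."""

    das: int
    ks: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ks) or self.ks < 0:
            raise ValueError(f"Ks must be finite and >= 0, got {self.ks}")


@dataclass(frozen=True)
class StageIntegrals:
    """Cumulative ETa totals (mm): whole season, vegetative, grain filling."""

    eta_total: float
    eta_veg: float
    eta_gf: float


def crop_stress_coefficient(
    eta_day: float, etp_day: float, cap: float | None = None
) -> float:
    """Ks = ETa/ETp for one day (dimensionless, >= 0).

    Not clamped above 1 by default — measured daily ETa can exceed the
    modelled potential — but an optional cap is available.
    """
    if etp_day <= 0:
        raise ValueError("ETp must be positive to form Ks")
    if eta_day < 0:
        raise ValueError("ETa must be >= 0")
    ks = eta_day / etp_day
    if cap is not None:
        ks = min(ks, cap)
    return ks


def interpolate_ks(
    points: list[KsPoint],
    maturity_das: int,
    scheme: str = "step",
) -> np.ndarray:
    """Daily Ks sequence over [0, maturity_das] from per-flight values.

    Ks = 1 through DAS 100.  ``scheme="step"`` (default) assigns each
    flight's Ks piecewise-constant between inter-flight midpoints (floor);
    ``scheme="linear"`` interpolates linearly between flights, holding the
    first value back to DAS 101 and the last value to maturity.  Flights
    at or before DAS 100 are rejected; an empty flight list returns an
    all-ones series with a warning.
    """
    if maturity_das < 1:
        raise ValueError("maturity must be >= 1 DAS")
    das = np.arange(0, maturity_das + 1)
    ks = np.ones(maturity_das + 1)
    if not points:
        warnings.warn(
            "no flight Ks points: assuming an unstressed season (Ks = 1)",
            stacklevel=2,
        )
        return ks

    flights = sorted(points, key=lambda p: p.das)
    d = [p.das for p in flights]
    if any(b <= a for a, b in zip(d, d[1:])):
        raise ValueError("flight DAS must be strictly increasing")
    if d[0] <= KS_UNITY_UNTIL_DAS:
        raise ValueError(
            f"flights at or before DAS {KS_UNITY_UNTIL_DAS} conflict with the "
            "early-season Ks = 1 assumption"
        )

    if scheme == "step":
        for i, p in enumerate(flights):
            start = (
                KS_UNITY_UNTIL_DAS + 1
                if i == 0
                else (flights[i - 1].das + p.das) // 2 + 1
            )
            end = (
                maturity_das
                if i == len(flights) - 1
                else (p.das + flights[i + 1].das) // 2
            )
            sel = (das >= start) & (das <= end)
            ks[sel] = p.ks
    elif scheme == "linear":
        xp = [KS_UNITY_UNTIL_DAS + 1] + d + [maturity_das]
        fp = [flights[0].ks] + [p.ks for p in flights] + [flights[-1].ks]
        # np.interp requires increasing xp; drop duplicates at the ends
        xp_arr, idx = np.unique(xp, return_index=True)
        fp_arr = np.asarray(fp)[idx]
        tail = das > KS_UNITY_UNTIL_DAS
        ks[tail] = np.interp(das[tail], xp_arr, fp_arr)
    else:
        raise ValueError(f"unknown interpolation scheme {scheme!r}")
    return ks


def daily_eta_series(
    ks: np.ndarray, etp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Daily ETa = Ks·ETp and its running cumulative sum (mm)."""
    ks = np.asarray(ks, dtype=float)
    etp = np.asarray(etp, dtype=float)
    if ks.shape != etp.shape:
        raise ValueError(f"length mismatch: Ks {ks.shape} vs ETp {etp.shape}")
    eta = ks * etp
    return eta, np.cumsum(eta)


def stage_integrals(eta: np.ndarray, phenology: Phenology) -> StageIntegrals:
    """Split cumulative ETa at heading.

    The series must cover [0, maturity].  The heading day itself belongs
    to the vegetative integral (closed at heading); grain filling runs
    from heading+1 through maturity.  The two stages partition the total
    exactly.
    """
    eta = np.asarray(eta, dtype=float)
    if len(eta) < phenology.maturity_das + 1:
        raise ValueError(
            f"series of length {len(eta)} does not cover maturity DAS "
            f"{phenology.maturity_das}"
        )
    veg = float(eta[: phenology.heading_das + 1].sum())
    gf = float(eta[phenology.heading_das + 1 : phenology.maturity_das + 1].sum())
    return StageIntegrals(eta_total=veg + gf, eta_veg=veg, eta_gf=gf)


def water_productivity(gy_kg_ha: float, cum_eta_mm: float) -> float:
    """Water productivity WP = GY / (10·ETa) in kg·m⁻³.

    1 mm of water over 1 ha is 10 m³, hence the factor 10 converting
    kg·ha⁻¹ per mm into kg per m³.
    """
    if cum_eta_mm <= 0:
        raise ValueError("cumulative ETa must be positive")
    if gy_kg_ha < 0:
        raise ValueError("grain yield must be >= 0")
    return gy_kg_ha / (10.0 * cum_eta_mm)
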