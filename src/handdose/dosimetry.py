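"""Tally -> dose -> slope -> scenario dose -> Hp(0.07) pipeline.

Absorbed dose per region is deposited energy over region mass. Doses at
each decay-count level (replicates averaged) are fitted with an
ordinary-least-squares line against the number of decays; the slope
(Gy/decay) multiplied by the scenario decay count gives the handling
dose, converted to personal dose equivalent Hp(0.07) with the photon
quality factor Q = 1, and optionally normalised per unit activity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import constants
from .geometry import SceneGeometry, region_mass
from .scene import FINGERS
from .transport import DoseTally

__all__ = [
    "DosePoint",
    "SlopeFit",
    "DoseReport",
    "dose_from_tally",
    "average_replicates",
    "fit_dose_response",
    "extrapolate_dose_mgy",
    "hp007_msv",
    "normalized_stats",
    "build_report",
]


@dataclass(frozen=True)
class DosePoint:
    """Absorbed dose for one region at one decay-count level."""

    n_decays: float
    region: str
    dose_gy: float
    sigma_gy: float

    def __post_init__(self):
        if self.dose_gy < 0 or self.sigma_gy < 0:
            raise ValueError("dose and sigma must be >= 0")


@dataclass(frozen=True)
class SlopeFit:
    """OLS line of dose against decay count for one region."""

    region: str
    slope_gy_per_decay: float
    intercept_gy: float
    r_squared: float

    def __post_init__(self):
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def dose_from_tally(
    tally: DoseTally, scene: SceneGeometry, n_decays: Optional[float] = None
) -> list[DosePoint]:
    """Convert a tally to absorbed-dose points for all scoring regions.

    ``dose = E_dep [J] / mass [kg]``; the uncertainty propagates the
    history-by-history standard error of the mean deposit.
    """
    n = tally.histories if n_decays is None else n_decays
    points = []
    sigma = tally.sigma_mev()
    for region in scene.scoring_regions:
        i = tally.index(region.name)
        mass = region_mass(region)
        dose = tally.edep_mev[i] * constants.MEV_TO_J / mass
        sig = (
            sigma[i] * tally.histories * constants.MEV_TO_J / mass
            if tally.histories >= 2
            else 0.0
        )
        points.append(DosePoint(n, region.name, dose, sig))
    return points


def average_replicates(points: Iterable[DosePoint]) -> list[DosePoint]:
    """Average dose points sharing (region, n_decays) across replicates."""
    groups: dict[tuple, list[DosePoint]] = {}
    for p in points:
        groups.setdefault((p.region, p.n_decays), []).append(p)
    out = []
    for (region, n), grp in sorted(groups.items()):
        doses = np.array([p.dose_gy for p in grp])
        sigs = np.array([p.sigma_gy for p in grp])
        out.append(
            DosePoint(
                n,
                region,
                float(doses.mean()),
                float(np.sqrt((sigs**2).sum()) / len(grp)),
            )
        )
    return out


def fit_dose_response(
    points: Sequence[DosePoint], weighted: bool = False
) -> SlopeFit:
    """Fit dose against n_decays for a single region's points.

    Unweighted ordinary least squares by default (inverse-variance
    weighting available). Requires at least three distinct decay-count
    levels.
    """
    regions = {p.region for p in points}
    if len(regions) != 1:
        raise ValueError(f"points span several regions: {sorted(regions)}")
    pts = average_replicates(points)
    x = np.array([p.n_decays for p in pts])
    y = np.array([p.dose_gy for p in pts])
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct decay-count levels to fit")
    if np.all(y == y[0]):
        # constant response (e.g. an all-zero starved region): the flat
        # line reproduces every point exactly
        return SlopeFit(pts[0].region, 0.0, float(y[0]), 1.0)
    if weighted:
        w = np.array([1.0 / max(p.sigma_gy, 1e-300) ** 2 for p in pts])
        sw = w.sum()
        xb, yb = (w * x).sum() / sw, (w * y).sum() / sw
        slope = (w * (x - xb) * (y - yb)).sum() / (w * (x - xb) ** 2).sum()
        intercept = yb - slope * xb
        resid = y - (intercept + slope * x)
        ss_res = (w * resid**2).sum()
        ss_tot = (w * (y - yb) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
    return SlopeFit(pts[0].region, float(slope), float(intercept), min(r2, 1.0))


def extrapolate_dose_mgy(fit: SlopeFit, n_decays: float) -> float:
    """Scenario absorbed dose, mGy: ``slope x n_decays`` (Gy -> mGy)."""
    if n_decays < 0:
        raise ValueError("n_decays must be >= 0")
    return fit.slope_gy_per_decay * n_decays * 1e3


def hp007_msv(absorbed_dose_mgy: float, quality_factor: float = 1.0) -> float:
    """Personal dose equivalent Hp(0.07), mSv: absorbed dose x Q.

    For photons Q = 1, so the value equals the absorbed dose in mGy.
    """
    if absorbed_dose_mgy < 0:
        raise ValueError("absorbed dose must be >= 0")
    if quality_factor <= 0:
        raise ValueError("quality factor must be positive")
    return absorbed_dose_mgy * quality_factor


def normalized_stats(values_msv: Sequence[float], activity_gbq: float):
    """Per-activity dose statistics: ((min, max), mean, median) mSv/GBq."""
    vals = np.asarray(list(values_msv), dtype=float)
    if vals.size == 0:
        raise ValueError("values must be non-empty")
    if activity_gbq <= 0:
        raise ValueError("activity must be positive")
    norm = vals / activity_gbq
    return (
        (float(norm.min()), float(norm.max())),
        float(norm.mean()),
        float(np.median(norm)),
    )


@dataclass
class DoseReport:
    """Per-finger scenario dose summary (fingertip = distal phalanx)."""

    activity_bq: float
    handling_time_s: float
    n_decays: float
    fingers: Mapping[str, dict]  # finger -> {slope, r_squared, dose_mgy,
    #                                         hp007_msv, norm_msv_per_gbq}
    quality_factor: float = 1.0

    def hp007(self, finger: str) -> float:
        return self.fingers[finger]["hp007_msv"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"finger": f, **vals} for f, vals in self.fingers.items()
        ]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "activity_bq": self.activity_bq,
            "handling_time_s": self.handling_time_s,
            "n_decays": self.n_decays,
            "quality_factor": self.quality_factor,
            "fingers": {k: dict(v) for k, v in self.fingers.items()},
        }

    def write(self, csv_path=None, json_path=None, provenance=None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            payload = self.to_json_dict()
            if provenance:
                payload["provenance"] = provenance
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def build_report(
    fits: Mapping[str, SlopeFit],
    activity_bq: float,
    handling_time_s: float,
    n_decays: float,
    quality_factor: float = 1.0,
) -> DoseReport:
    """Assemble a :class:`DoseReport` from per-finger slope fits.

    ``fits`` maps finger labels (or their distal-region names) to fits;
    doses are rounded to 3 decimals only at serialisation, not here.
    """
    fingers = {}
    for label, fit in fits.items():
        finger = label.replace("_distal", "")
        if finger not in FINGERS:
            raise ValueError(f"unknown finger label {label!r}")
        dose = extrapolate_dose_mgy(fit, n_decays)
        hp = hp007_msv(dose, quality_factor)
        fingers[finger] = {
            "slope_gy_per_decay": fit.slope_gy_per_decay,
            "r_squared": fit.r_squared,
            "dose_mgy": dose,
            "hp007_msv": hp,
            "norm_msv_per_gbq": hp / (activity_bq / 1e9)
            if activity_bq > 0
            else float("nan"),
        }
    return DoseReport(
        activity_bq=activity_bq,
        handling_time_s=handling_time_s,
        n_decays=n_decays,
        fingers=fingers,
        quality_factor=quality_factor,
    )
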