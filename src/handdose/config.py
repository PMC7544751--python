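"""Run configuration, provenance bookkeeping, and the run orchestrator.

A :class:`RunConfig` collects everything a simulation campaign needs:
scene dimensions, nuclide, exposure scenario, decay-count levels,
replicate count, transport settings and the master seed. Configs load
from a nested-key YAML file; CLI flags override file values (flag >
file > default). Every output directory gets a ``provenance.json``
with the canonical config hash, seed and package version, and the
numeric outputs depend only on (config, seed) — not on where they are
written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dosimetry import (
    DosePoint,
    build_report,
    dose_from_tally,
    fit_dose_response,
)
from .scene import SceneConfig, build_scene
from .source import ExposureScenario, NuclideSpec, F18, decays_from_activity
from .transport import TransportSettings, run_histories

__all__ = [
    "RunConfig",
    "ConfigError",
    "simulate_campaign",
    "fits_from_dose_points",
    "report_from_dose_points",
    "load_dose_points",
]

DEFAULT_N_LEVELS = (100, 1000, 10_000, 100_000)


class ConfigError(ValueError):
    """A configuration field failed validation; the message names it."""


@dataclass
class RunConfig:
    """Full description of a simulation campaign."""

    seed: int = 12345
    output_dir: str = "runs/default"
    n_levels: tuple = DEFAULT_N_LEVELS
    replicates: int = 20
    scene: SceneConfig = field(default_factory=SceneConfig)
    nuclide: NuclideSpec = F18
    scenario: ExposureScenario = field(
        default_factory=lambda: ExposureScenario(300e6, 120.0)
    )
    transport: TransportSettings = field(default_factory=TransportSettings)

    def __post_init__(self):
        levels = tuple(int(n) for n in self.n_levels)
        if not levels or any(n <= 0 for n in levels):
            raise ConfigError("n_levels: must be non-empty and positive")
        if list(levels) != sorted(levels):
            raise ConfigError("n_levels: must be ascending")
        self.n_levels = levels
        if self.replicates < 1:
            raise ConfigError("replicates: must be >= 1")

    # -- serialisation ----------------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        kwargs = {}
        try:
            if "scene" in raw:
                kwargs["scene"] = SceneConfig(**raw.pop("scene"))
            if "nuclide" in raw:
                kwargs["nuclide"] = NuclideSpec(**raw.pop("nuclide"))
            if "scenario" in raw:
                kwargs["scenario"] = ExposureScenario(**raw.pop("scenario"))
            if "transport" in raw:
                kwargs["transport"] = TransportSettings(
                    **raw.pop("transport")
                )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        try:
            return cls(**kwargs, **raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "n_levels": list(self.n_levels),
            "replicates": self.replicates,
            "scene": self.scene.to_dict(),
            "nuclide": dataclasses.asdict(self.nuclide),
            "scenario": dataclasses.asdict(self.scenario),
            "transport": dataclasses.asdict(self.transport),
        }

    def config_hash(self) -> str:
        """Hash of the numeric-relevant config (output path excluded)."""
        payload = self.to_dict()
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "version": __version__,
        }


# -- campaign runner ------------------------------------------------------


def _run_seed(master: int, level_idx: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master, level_idx, replicate])
    )


def simulate_campaign(
    config: RunConfig,
    write: bool = True,
    progress=None,
) -> pd.DataFrame:
    """Run replicates x levels; return (and optionally write) dose points.

    The returned frame has one row per (level, replicate, scoring
    region). With ``write`` the frame, per-run tallies and a provenance
    block are written under ``config.output_dir``.
    """
    scene = build_scene(config.scene)
    rows = []
    tally_frames = []
    for li, n in enumerate(config.n_levels):
        for rep in range(config.replicates):
            rng = _run_seed(config.seed, li, rep)
            tally = run_histories(
                n,
                scene,
                settings=config.transport,
                nuclide=config.nuclide,
                rng=rng,
            )
            for p in dose_from_tally(tally, scene):
                rows.append(
                    {
                        "n_decays": n,
                        "replicate": rep,
                        "region": p.region,
                        "dose_gy": p.dose_gy,
                        "sigma_gy": p.sigma_gy,
                    }
                )
            sig = tally.sigma_mev()
            tally_frames.append(
                pd.DataFrame(
                    {
                        "n_decays": n,
                        "replicate": rep,
                        "region": tally.region_names,
                        "energy_mev": tally.edep_mev,
                        "sigma_mev": sig * tally.histories,
                        "histories": tally.histories,
                    }
                )
            )
        if progress is not None:
            progress(n)
    points = pd.DataFrame(rows)
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        points.to_csv(out / "dose_points.csv", index=False)
        pd.concat(tally_frames, ignore_index=True).to_csv(
            out / "tallies.csv", index=False
        )
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {**config.provenance(), "config": config.to_dict()},
                fh,
                indent=2,
            )
    return points


def load_dose_points(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"n_decays", "region", "dose_gy", "sigma_gy"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"dose-point file lacks columns {sorted(missing)}")
    return df


def fits_from_dose_points(points: pd.DataFrame, fingertips_only=True):
    """Per-region slope fits from a dose-point frame.

    With ``fingertips_only`` the per-finger fit uses the distal-phalanx
    (fingertip) region, the reported quantity of the pipeline.
    """
    fits = {}
    for region, grp in points.groupby("region"):
        if fingertips_only and not region.endswith("_distal"):
            continue
        pts = [
            DosePoint(r.n_decays, region, r.dose_gy, r.sigma_gy)
            for r in grp.itertuples()
        ]
        fits[region] = fit_dose_response(pts)
    return fits


def report_from_dose_points(
    points: pd.DataFrame,
    scenario: ExposureScenario,
    nuclide: NuclideSpec = F18,
    quality_factor: float = 1.0,
):
    """Fit fingertip dose responses and extrapolate to the scenario."""
    fits = fits_from_dose_points(points)
    n = decays_from_activity(scenario, nuclide)
    return build_report(
        fits,
        activity_bq=scenario.activity_bq,
        handling_time_s=scenario.handling_time_s,
        n_decays=n,
        quality_factor=quality_factor,
    )
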