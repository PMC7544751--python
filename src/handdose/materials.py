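"""Material definitions and photon interaction-coefficient lookup.

Materials (air, water, ICRP-type soft tissue/skin, tungsten) carry a
density, an elemental mass-fraction composition, and an
:class:`AttenuationTable` of mass interaction coefficients on a fixed
10 keV - 1 MeV energy grid. Lookups interpolate log-log between grid
nodes, the standard convention for attenuation data (exact for
power-law segments and at the nodes themselves).

The numeric tables live in the generated constants module
``_attenuation_data`` so that results are bit-stable across releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _attenuation_data as _data

__all__ = [
    "Material",
    "AttenuationTable",
    "CHANNELS",
    "get_material",
    "material_names",
    "lookup_mu",
    "lookup_mu_over_rho",
    "EnergyOutOfRangeError",
    "UnknownChannelError",
]

#: Recognized interaction channels. ``total`` excludes coherent scattering.
CHANNELS = ("photoelectric", "incoherent", "coherent", "total", "mu_en")


class EnergyOutOfRangeError(ValueError):
    """Requested energy lies outside the tabulated grid span."""


class UnknownChannelError(KeyError):
    """Requested interaction channel is not tabulated."""


@dataclass(frozen=True)
class AttenuationTable:
    """Mass interaction coefficients (cm^2/g) on an ascending energy grid."""

    energy_grid: np.ndarray  # MeV, strictly ascending
    channels: Mapping[str, np.ndarray]  # cm^2/g per channel

    def __post_init__(self) -> None:
        grid = np.asarray(self.energy_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2:
            raise ValueError("energy grid must be a 1-D array of >= 2 nodes")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("energy grid must be strictly ascending")
        for name, vals in self.channels.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != grid.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            if not np.all(vals > 0):
                raise ValueError(f"channel {name!r} has non-positive values")

    @property
    def e_min(self) -> float:
        return float(self.energy_grid[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_grid[-1])

    def mu_over_rho(self, energy, channel: str = "total"):
        """Interpolate a mass coefficient (cm^2/g) at ``energy`` (MeV).

        Log-log linear between bracketing nodes; exact at nodes. Accepts
        scalars or arrays. Raises :class:`EnergyOutOfRangeError` if any
        energy falls outside the grid span.
        """
        if channel not in self.channels:
            raise UnknownChannelError(channel)
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise EnergyOutOfRangeError(
                f"energy outside tabulated span "
                f"[{self.e_min}, {self.e_max}] MeV"
            )
        log_mu = np.interp(
            np.log(e), np.log(self.energy_grid), np.log(self.channels[channel])
        )
        out = np.exp(log_mu)
        return float(out) if np.isscalar(energy) else out


@dataclass(frozen=True)
class Material:
    """A homogeneous material: density, composition, interaction table."""

    name: str
    density: float  # g/cm^3
    composition: Mapping[str, float]  # element symbol -> mass fraction
    table: AttenuationTable = field(repr=False)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not self.composition:
            raise ValueError("composition must be non-empty")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions sum to {total!r}, expected 1 within 1e-6"
            )

    def mu(self, energy, channel: str = "total"):
        """Linear attenuation coefficient mu (1/cm) at ``energy`` (MeV)."""
        return self.table.mu_over_rho(energy, channel) * self.density


def _build_registry() -> dict[str, Material]:
    registry = {}
    for name, chans in _data.TABLES.items():
        table = AttenuationTable(
            energy_grid=_data.ENERGY_GRID_MEV, channels=dict(chans)
        )
        registry[name] = Material(
            name=name,
            density=_data.DENSITIES_G_CM3[name],
            composition=dict(_data.COMPOSITIONS[name]),
            table=table,
        )
    return registry


_REGISTRY = _build_registry()


def material_names() -> list[str]:
    """Names of the embedded materials."""
    return sorted(_REGISTRY)


def get_material(name: str) -> Material:
    """Return an embedded material by name.

    Raises ``KeyError`` listing available names if unknown.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {material_names()}"
        ) from None


def lookup_mu_over_rho(material: Material | str, energy, channel="total"):
    """Mass attenuation coefficient (cm^2/g) for a material at an energy."""
    mat = get_material(material) if isinstance(material, str) else material
    return mat.table.mu_over_rho(energy, channel)


def lookup_mu(material: Material | str, energy, channel: str = "total"):
    """Linear attenuation coefficient mu (1/cm) for a material at an energy.

    ``mu = (mu/rho) * rho`` with log-log interpolation between grid nodes;
    exact at the nodes. ``channel`` is one of :data:`CHANNELS`.
    """
    mat = get_material(material) if isinstance(material, str) else material
    return mat.mu(energy, channel)
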