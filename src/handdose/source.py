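"""Radionuclide decay sampling inside the syringe.

Samples fluorine-18 decays: a decay position in the liquid column, a
beta-plus kinetic energy from the allowed-shape spectrum, and the two
back-to-back 511 keV annihilation photons. The neutrino is dropped —
it deposits nothing. Positrons are terminated locally by default (their
range is small against every region in the scene), with an optional
straight-line displacement by the continuous-slowing-down range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .geometry import SceneGeometry

__all__ = [
    "NuclideSpec",
    "F18",
    "ExposureScenario",
    "DecaySample",
    "decays_from_activity",
    "sample_decay_positions",
    "sample_beta_energies",
    "sample_isotropic",
    "annihilation_pairs",
    "sample_decays",
]

_ME = constants.ELECTRON_REST_MEV

# CSDA range of electrons in water, (MeV kinetic, g/cm^2); used only by
# the optional positron-displacement mode.
_CSDA_E_MEV = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
_CSDA_G_CM2 = np.array(
    [0.0042, 0.0140, 0.0449, 0.0840, 0.1280, 0.1760, 0.2220, 0.2700]
)


@dataclass(frozen=True)
class NuclideSpec:
    """Beta-plus emitter parameters."""

    name: str
    half_life_s: float
    beta_plus_fraction: float
    beta_endpoint_mev: float

    def __post_init__(self):
        if self.half_life_s <= 0:
            raise ValueError("half-life must be positive")
        if not 0.0 <= self.beta_plus_fraction <= 1.0:
            raise ValueError("branching fraction must lie in [0, 1]")
        if self.beta_endpoint_mev <= 0:
            raise ValueError("endpoint energy must be positive")

    @property
    def decay_constant(self) -> float:
        """lambda = ln 2 / T_1/2, per second."""
        return np.log(2.0) / self.half_life_s


F18 = NuclideSpec(
    name="F18",
    half_life_s=constants.F18_HALF_LIFE_S,
    beta_plus_fraction=constants.F18_BETA_PLUS_FRACTION,
    beta_endpoint_mev=constants.F18_BETA_ENDPOINT_MEV,
)


@dataclass(frozen=True)
class ExposureScenario:
    """Handled activity and contact time."""

    activity_bq: float
    handling_time_s: float
    decay_correction: bool = False

    def __post_init__(self):
        if self.activity_bq < 0:
            raise ValueError("activity must be >= 0")
        if self.handling_time_s < 0:
            raise ValueError("handling time must be >= 0")


def decays_from_activity(
    scenario: ExposureScenario, nuclide: NuclideSpec = F18
) -> float:
    """Number of decays over the handling interval.

    Constant-activity mode returns ``A * t`` (the convention that maps
    300 MBq over 120 s to 3.6e10 decays). With ``decay_correction``
    the initial-activity decay integral ``(A/lambda)(1 - exp(-lambda t))``
    is used instead.
    """
    a, t = scenario.activity_bq, scenario.handling_time_s
    if not scenario.decay_correction:
        return a * t
    lam = nuclide.decay_constant
    return (a / lam) * -np.expm1(-lam * t)


def _interior_cylinder(scene: SceneGeometry):
    region = scene.region("syringe_interior")
    shape = region.shape
    return shape.center, shape.r_outer, shape.length


def sample_decay_positions(
    rng: np.random.Generator,
    scene: SceneGeometry,
    n: int,
    deterministic_first: bool = False,
    fill_fraction: float = 1.0,
) -> np.ndarray:
    """Uniform decay positions in the liquid column, shape (n, 3).

    With ``deterministic_first`` the first point is the exact column
    centre (the seeding convention of the reproduced study).
    ``fill_fraction`` shortens the occupied column from the needle end.
    """
    if not 0 < fill_fraction <= 1.0:
        raise ValueError("fill fraction must be in (0, 1]")
    center, radius, length = _interior_cylinder(scene)
    length = length * fill_fraction
    r = radius * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    z = center[2] + length * (rng.random(n) - 0.5)
    pts = np.column_stack(
        [center[0] + r * np.cos(phi), center[1] + r * np.sin(phi), z]
    )
    if deterministic_first and n > 0:
        pts[0] = center
    return pts


def beta_spectrum_density(e_kin, endpoint: float) -> np.ndarray:
    """Unnormalised allowed beta shape ``p * E_tot * (Q - E)^2``.

    Fermi function approximated as 1; zero outside (0, Q).
    """
    e = np.asarray(e_kin, dtype=float)
    etot = e + _ME
    p = np.sqrt(np.maximum(etot**2 - _ME**2, 0.0))
    out = p * etot * (endpoint - e) ** 2
    return np.where((e > 0) & (e < endpoint), out, 0.0)


def _beta_density_max(endpoint: float) -> float:
    grid = np.linspace(0.0, endpoint, 4001)
    return float(beta_spectrum_density(grid, endpoint).max()) * 1.001


def sample_beta_energies(
    rng: np.random.Generator, nuclide: NuclideSpec, n: int
) -> np.ndarray:
    """Rejection-sample ``n`` beta-plus kinetic energies (MeV)."""
    q = nuclide.beta_endpoint_mev
    fmax = _beta_density_max(q)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        e = rng.random(m) * q
        keep = rng.random(m) * fmax < beta_spectrum_density(e, q)
        take = e[keep][: n - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    return out


def sample_isotropic(rng: np.random.Generator, n: int) -> np.ndarray:
    """``n`` isotropic unit vectors, shape (n, 3)."""
    mu = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    s = np.sqrt(1.0 - mu * mu)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])


def annihilation_pairs(rng: np.random.Generator, positions: np.ndarray):
    """Two 511 keV photons per position, back to back, isotropic.

    Returns ``(origins, directions, energies)`` with ``2n`` rows; rows
    ``2i`` and ``2i+1`` belong to decay ``i``.
    """
    n = len(positions)
    d = sample_isotropic(rng, n)
    origins = np.repeat(positions, 2, axis=0)
    directions = np.empty((2 * n, 3))
    directions[0::2] = d
    directions[1::2] = -d
    energies = np.full(2 * n, constants.ANNIHILATION_PHOTON_MEV)
    return origins, directions, energies


@dataclass
class DecaySample:
    """One batch of sampled decays and their annihilation photons."""

    positions: np.ndarray  # (n, 3) decay/termination points, cm
    is_beta: np.ndarray  # (n,) bool, beta-plus branch
    positron_energies: np.ndarray  # (n,) MeV, zero on the EC branch
    photon_origins: np.ndarray  # (2*n_beta, 3)
    photon_directions: np.ndarray  # (2*n_beta, 3)
    photon_energies: np.ndarray  # (2*n_beta,)
    photon_history: np.ndarray  # (2*n_beta,) decay index of each photon

    @property
    def n(self) -> int:
        return len(self.positions)


def _csda_range_cm(e_kin: np.ndarray, density: float) -> np.ndarray:
    return np.interp(e_kin, _CSDA_E_MEV, _CSDA_G_CM2) / density


def sample_decays(
    rng: np.random.Generator,
    scene: SceneGeometry,
    nuclide: NuclideSpec,
    n: int,
    deterministic_first: bool = False,
    positron_displacement: bool = False,
    fill_fraction: float = 1.0,
) -> DecaySample:
    """Sample ``n`` decays: positions, branches, positrons, photons.

    EC-branch decays produce no photons and deposit nothing. By default
    the positron annihilates where it is created; with
    ``positron_displacement`` it is moved by its CSDA range along an
    isotropic direction first (clipped to stay inside the world).
    """
    positions = sample_decay_positions(
        rng, scene, n, deterministic_first, fill_fraction
    )
    is_beta = rng.random(n) < nuclide.beta_plus_fraction
    e_pos = np.zeros(n)
    nb = int(is_beta.sum())
    e_pos[is_beta] = sample_beta_energies(rng, nuclide, nb)

    term = positions.copy()
    if positron_displacement and nb:
        density = scene.region("syringe_interior").material.density
        step = _csda_range_cm(e_pos[is_beta], density)
        term[is_beta] += step[:, None] * sample_isotropic(rng, nb)

    origins, directions, energies = annihilation_pairs(rng, term[is_beta])
    history = np.repeat(np.flatnonzero(is_beta), 2)
    return DecaySample(
        positions=term,
        is_beta=is_beta,
        positron_energies=e_pos,
        photon_origins=origins,
        photon_directions=directions,
        photon_energies=energies,
        photon_history=history,
    )
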