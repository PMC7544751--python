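"""Photon transport with per-region energy-deposition tallies.

Analog random walk: free paths are exponential in the local linear
attenuation coefficient and are interrupted at region boundaries;
interactions are photoelectric absorption (full local deposit) or
Compton scattering with the angle/energy pair rejection-sampled from
the Klein-Nishina differential cross-section. Secondary electrons are
not transported: energy transferred to them is deposited at the
interaction point (kerma approximation — electron ranges are small
against every scoring region here). Coherent scattering is available
behind a flag and defaults off.

Tallies are history-by-history: per scoring region the engine keeps the
summed deposit and the sum of squared per-history deposits, which gives
the standard Monte Carlo uncertainty estimate.

The batch kernels (:func:`sample_compton`, :func:`transport_batch`)
drive production runs; the scalar :func:`step_interaction` and
:func:`transport_photon` expose the same physics one photon at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import constants
from .geometry import PUSH, SceneGeometry
from .source import NuclideSpec, F18, sample_decays

__all__ = [
    "TransportSettings",
    "Photon",
    "DoseTally",
    "sample_compton",
    "compton_scattered_energy",
    "rotate_directions",
    "step_interaction",
    "transport_photon",
    "transport_batch",
    "run_histories",
]

_ME = constants.ELECTRON_REST_MEV


@dataclass(frozen=True)
class TransportSettings:
    """Knobs of the photon random walk."""

    energy_cutoff_mev: float = 0.010
    max_crossings: int = 1000
    rayleigh_enabled: bool = False
    interactions_enabled: bool = True  # False -> pure streaming (tests)
    chunk_size: int = 20000  # decays per vectorized batch

    def __post_init__(self):
        if not 0.001 <= self.energy_cutoff_mev <= 0.1:
            raise ValueError("cutoff must lie in [0.001, 0.1] MeV")
        if self.max_crossings <= 0:
            raise ValueError("max_crossings must be positive")


@dataclass
class Photon:
    """A single tracked photon (scalar API)."""

    position: np.ndarray
    direction: np.ndarray
    energy_mev: float
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be unit length")
        if self.alive and self.energy_mev <= 0:
            raise ValueError("live photon needs positive energy")


@dataclass
class DoseTally:
    """Per-region deposited energy with history-by-history statistics."""

    region_names: tuple
    edep_mev: np.ndarray  # summed deposits per region
    edep_sq_mev2: np.ndarray  # sum of squared per-history deposits
    histories: int = 0
    escaped_mev: float = 0.0
    aborted_histories: int = 0

    @classmethod
    def empty(cls, region_names) -> "DoseTally":
        names = tuple(region_names)
        return cls(
            region_names=names,
            edep_mev=np.zeros(len(names)),
            edep_sq_mev2=np.zeros(len(names)),
        )

    def add_history_block(self, deposits: np.ndarray) -> None:
        """Fold a (histories, regions) per-history deposit block in."""
        if deposits.shape[1] != len(self.region_names):
            raise ValueError("region count mismatch")
        self.edep_mev += deposits.sum(axis=0)
        self.edep_sq_mev2 += (deposits**2).sum(axis=0)
        self.histories += deposits.shape[0]

    def merge(self, other: "DoseTally") -> "DoseTally":
        if self.region_names != other.region_names:
            raise ValueError("cannot merge tallies over different regions")
        return DoseTally(
            region_names=self.region_names,
            edep_mev=self.edep_mev + other.edep_mev,
            edep_sq_mev2=self.edep_sq_mev2 + other.edep_sq_mev2,
            histories=self.histories + other.histories,
            escaped_mev=self.escaped_mev + other.escaped_mev,
            aborted_histories=self.aborted_histories
            + other.aborted_histories,
        )

    def mean_mev(self) -> np.ndarray:
        """Mean deposit per history and region."""
        n = max(self.histories, 1)
        return self.edep_mev / n

    def sigma_mev(self) -> np.ndarray:
        """Standard error of the per-region mean deposit (MeV/history)."""
        n = self.histories
        if n < 2:
            return np.full(len(self.region_names), np.nan)
        mean = self.edep_mev / n
        var = (self.edep_sq_mev2 / n - mean**2) / (n - 1)
        return np.sqrt(np.maximum(var, 0.0))

    def index(self, name: str) -> int:
        return self.region_names.index(name)


# ---------------------------------------------------------------------------
# Compton kinematics and Klein-Nishina sampling


def compton_scattered_energy(energy_mev, cos_theta):
    """Scattered photon energy E' = E / (1 + (E/m_e c^2)(1 - cos theta))."""
    e = np.asarray(energy_mev, dtype=float)
    return e / (1.0 + (e / _ME) * (1.0 - np.asarray(cos_theta, dtype=float)))


def _kn_weight(k, cos_theta):
    """Klein-Nishina dsigma/dcos(theta) up to constants; bounded by 2."""
    r = 1.0 / (1.0 + k * (1.0 - cos_theta))
    return r * r * (r + 1.0 / r - (1.0 - cos_theta**2))


def sample_compton(rng: np.random.Generator, energies: np.ndarray):
    """Sample (E_scattered, cos_theta) from Klein-Nishina by rejection.

    The proposal is uniform in cos(theta) with envelope 2, which bounds
    the differential cross-section at all energies.
    """
    e = np.atleast_1d(np.asarray(energies, dtype=float))
    k = e / _ME
    n = e.size
    cos_t = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        c = 2.0 * rng.random(m) - 1.0
        accept = 2.0 * rng.random(m) < _kn_weight(k[todo], c)
        idx = np.flatnonzero(todo)[accept]
        cos_t[idx] = c[accept]
        todo[idx] = False
    e_sc = compton_scattered_energy(e, cos_t)
    if np.isscalar(energies) or np.ndim(energies) == 0:
        return float(e_sc[0]), float(cos_t[0])
    return e_sc, cos_t


def rotate_directions(
    directions: np.ndarray, cos_theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Rotate unit vectors by polar angle theta about a random azimuth."""
    d = np.atleast_2d(directions)
    ct = np.atleast_1d(cos_theta)
    ph = np.atleast_1d(phi)
    st = np.sqrt(np.maximum(1.0 - ct**2, 0.0))
    # build an orthonormal frame (u, v, d); guard the polar singularity
    dz = d[:, 2]
    near_pole = np.abs(dz) > 0.999999
    a = np.where(
        near_pole[:, None],
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
    )
    u = np.cross(a, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (
        st[:, None] * np.cos(ph)[:, None] * u
        + st[:, None] * np.sin(ph)[:, None] * v
        + ct[:, None] * d
    )
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Scalar contracts


def step_interaction(photon: Photon, material, rng, settings=None):
    """Resolve one interaction in ``material``; returns (photon, deposit).

    The channel is chosen proportionally to the channel attenuation
    coefficients at the photon energy. Photoelectric kills the photon
    and deposits everything; Compton deposits the electron share and
    continues the photon with the Klein-Nishina-sampled energy and a
    rotated direction; a scattered photon below the cutoff is absorbed
    on the spot.
    """
    settings = settings or TransportSettings()
    if not photon.alive:
        raise ValueError("step_interaction needs a live photon")
    e = photon.energy_mev
    mu_pe = material.mu(e, "photoelectric")
    mu_in = material.mu(e, "incoherent")
    mu_coh = material.mu(e, "coherent") if settings.rayleigh_enabled else 0.0
    total = mu_pe + mu_in + mu_coh
    u = rng.random() * total
    if u < mu_pe:
        return replace(photon, alive=False, energy_mev=0.0), e
    if u < mu_pe + mu_in:
        e_sc, cos_t = sample_compton(rng, e)
        deposit = e - e_sc
        if e_sc < settings.energy_cutoff_mev:
            return replace(photon, alive=False, energy_mev=0.0), e
        new_dir = rotate_directions(
            photon.direction, np.array([cos_t]), rng.random(1) * 2 * np.pi
        )[0]
        return (
            replace(photon, direction=new_dir, energy_mev=e_sc),
            deposit,
        )
    # coherent: direction change only (Thomson-like angular shape)
    cos_t = _sample_thomson(rng, 1)[0]
    new_dir = rotate_directions(
        photon.direction, np.array([cos_t]), rng.random(1) * 2 * np.pi
    )[0]
    return replace(photon, direction=new_dir), 0.0


def _sample_thomson(rng, n):
    # density ∝ (1 + cos^2) on [-1, 1]; rejection with envelope 2
    out = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        c = 2.0 * rng.random(m) - 1.0
        acc = 2.0 * rng.random(m) < 1.0 + c * c
        idx = np.flatnonzero(todo)[acc]
        out[idx] = c[acc]
        todo[idx] = False
    return out


def transport_photon(
    photon: Photon,
    scene: SceneGeometry,
    settings: TransportSettings,
    rng: np.random.Generator,
    tally: Optional[DoseTally] = None,
) -> DoseTally:
    """Track one photon to absorption or world escape; update the tally."""
    if tally is None:
        tally = DoseTally.empty([r.name for r in scene.regions])
    deposits = np.zeros((1, len(scene.regions)))
    escaped, aborted = transport_batch(
        origins=photon.position[None, :],
        directions=photon.direction[None, :],
        energies=np.array([photon.energy_mev]),
        history_ids=np.array([0]),
        scene=scene,
        settings=settings,
        rng=rng,
        deposits=deposits,
        escaped=np.zeros(1),
    )
    tally.add_history_block(deposits)
    tally.escaped_mev += float(escaped)
    tally.aborted_histories += int(aborted)
    return tally


# ---------------------------------------------------------------------------
# Batch engine


def transport_batch(
    origins: np.ndarray,
    directions: np.ndarray,
    energies: np.ndarray,
    history_ids: np.ndarray,
    scene: SceneGeometry,
    settings: TransportSettings,
    rng: np.random.Generator,
    deposits: np.ndarray,
    escaped: np.ndarray,
) -> tuple[float, int]:
    """Transport a photon batch, crediting ``deposits[history, region]``.

    ``escaped`` accumulates per-history energy leaving the world.
    Returns ``(total escaped energy, aborted history count)``. Histories
    whose crossing count exceeds ``settings.max_crossings`` are aborted
    (a geometry-leak signal) and their in-flight energy is dropped from
    the balance.
    """
    pos = np.array(origins, dtype=float)
    dirs = np.array(directions, dtype=float)
    e = np.array(energies, dtype=float)
    hist = np.asarray(history_ids)
    mats = [r.material for r in scene.regions]
    region = scene.locate_many(pos)
    if np.any(region < 0):
        raise ValueError("photon batch contains out-of-world origins")
    alive = np.ones(len(e), dtype=bool)
    crossings = np.zeros(len(e), dtype=np.int64)
    aborted = 0

    while alive.any():
        ai = np.flatnonzero(alive)
        p = pos[ai]
        d = dirs[ai]
        en = e[ai]
        reg = region[ai]

        mu_pe = np.empty(len(ai))
        mu_in = np.empty(len(ai))
        mu_coh = np.zeros(len(ai))
        for ridx in np.unique(reg):
            sel = reg == ridx
            mat = mats[ridx]
            mu_pe[sel] = mat.mu(en[sel], "photoelectric")
            mu_in[sel] = mat.mu(en[sel], "incoherent")
            if settings.rayleigh_enabled:
                mu_coh[sel] = mat.mu(en[sel], "coherent")
        mu_tot = mu_pe + mu_in + mu_coh

        if settings.interactions_enabled:
            s = rng.exponential(1.0, size=len(ai)) / mu_tot
        else:
            s = np.full(len(ai), np.inf)
        d_bound = scene.first_crossing(p, d)
        interacts = s < d_bound

        # --- boundary crossings
        ci = ai[~interacts]
        if ci.size:
            step = d_bound[~interacts] + PUSH
            pos[ci] += step[:, None] * dirs[ci]
            new_reg = scene.locate_many(pos[ci])
            out = new_reg < 0
            esc = ci[out]
            np.add.at(escaped, hist[esc], e[esc])
            alive[esc] = False
            stay = ci[~out]
            region[stay] = new_reg[~out]
            crossings[ci] += 1
            over = stay[crossings[stay] > settings.max_crossings]
            if over.size:
                alive[over] = False
                aborted += over.size

        # --- interactions
        ii = ai[interacts]
        if ii.size:
            pos[ii] += s[interacts][:, None] * dirs[ii]
            en_i = e[ii]
            pe_i = mu_pe[interacts]
            in_i = mu_in[interacts]
            coh_i = mu_coh[interacts]
            u = rng.random(ii.size) * (pe_i + in_i + coh_i)
            photo = u < pe_i
            compton = (~photo) & (u < pe_i + in_i)
            rayleigh = ~photo & ~compton

            dep = np.zeros(ii.size)
            dep[photo] = en_i[photo]
            alive[ii[photo]] = False
            e[ii[photo]] = 0.0

            if compton.any():
                ci2 = ii[compton]
                e_sc, cos_t = sample_compton(rng, en_i[compton])
                below = e_sc < settings.energy_cutoff_mev
                dep[compton] = np.where(
                    below, en_i[compton], en_i[compton] - e_sc
                )
                kill = ci2[below]
                alive[kill] = False
                e[kill] = 0.0
                keep = ci2[~below]
                if keep.size:
                    e[keep] = e_sc[~below]
                    phi = 2.0 * np.pi * rng.random(keep.size)
                    dirs[keep] = rotate_directions(
                        dirs[keep], cos_t[~below], phi
                    )
            if rayleigh.any():
                ri = ii[rayleigh]
                cos_t = _sample_thomson(rng, ri.size)
                phi = 2.0 * np.pi * rng.random(ri.size)
                dirs[ri] = rotate_directions(dirs[ri], cos_t, phi)

            np.add.at(deposits, (hist[ii], region[ii]), dep)

    return float(escaped.sum()), aborted


def run_histories(
    n_decays: int,
    scene: SceneGeometry,
    settings: Optional[TransportSettings] = None,
    nuclide: NuclideSpec = F18,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    deterministic_first: bool = False,
    positron_displacement: bool = False,
    return_history_detail: bool = False,
):
    """Simulate ``n_decays`` decays and return the merged :class:`DoseTally`.

    One history is one decay: its positron kinetic energy is deposited
    at the termination point (kerma approximation) and both annihilation
    photons are transported. With ``return_history_detail`` the
    per-history (deposit matrix, escaped, emitted) arrays of the final
    chunk are also returned for diagnostic use at small ``n``.
    """
    if n_decays < 0:
        raise ValueError("n_decays must be >= 0")
    settings = settings or TransportSettings()
    if rng is None:
        rng = np.random.default_rng(seed)
    names = [r.name for r in scene.regions]
    tally = DoseTally.empty(names)
    detail = None

    done = 0
    first = deterministic_first
    while done < n_decays:
        m = min(settings.chunk_size, n_decays - done)
        sample = sample_decays(
            rng,
            scene,
            nuclide,
            m,
            deterministic_first=first,
            positron_displacement=positron_displacement,
        )
        first = False
        deposits = np.zeros((m, len(names)))
        escaped = np.zeros(m)

        # positron kinetic energy, deposited where the positron stops
        beta_idx = np.flatnonzero(sample.is_beta)
        if beta_idx.size:
            reg = scene.locate_many(sample.positions[beta_idx])
            inside = reg >= 0
            np.add.at(
                deposits,
                (beta_idx[inside], reg[inside]),
                sample.positron_energies[beta_idx[inside]],
            )

        esc_total, aborted = transport_batch(
            origins=sample.photon_origins,
            directions=sample.photon_directions,
            energies=sample.photon_energies,
            history_ids=sample.photon_history,
            scene=scene,
            settings=settings,
            rng=rng,
            deposits=deposits,
            escaped=escaped,
        )
        tally.add_history_block(deposits)
        tally.escaped_mev += esc_total
        tally.aborted_histories += aborted
        if return_history_detail:
            emitted = sample.positron_energies + np.where(
                sample.is_beta, 2.0 * constants.ANNIHILATION_PHOTON_MEV, 0.0
            )
            detail = (deposits, escaped, emitted)
        done += m

    if return_history_detail:
        return tally, detail
    return tally
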