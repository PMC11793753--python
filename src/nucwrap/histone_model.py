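"""Histone core: geometry, DNA adsorption, rigid-body Langevin dynamics.

The histone octamer is a sphere of radius |a| = 4.5 nm carrying 22 discrete
binding sites on a left-handed helical path (axial extent 5.5 nm, about two
turns, end diameters about 8 nm).  DNA charge sites adsorb onto the binding
sites through a Morse well of depth eps (4-8 kBT) and inverse range
alpha = 1.26 nm^-1 with minimum at delta = 1 nm; a half-harmonic shell of
stiffness k = 8 kBT/nm^2 keeps DNA outside |a| + r0 = 5.5 nm of the center.

The rigid body translates with Stokes friction zeta = 6 pi eta |a| and
rotates with zeta_rot = 8 pi eta |a|^3.  Orientation is carried as a full
body-frame rotation matrix; the helical-path axis A is its third column and
the spin angle Psi about A is tracked as an accumulated angle, so the update
splits exactly into axis tipping (torque component perpendicular to A) and
spinning (component along A) without any spherical-coordinate singularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .dna_model import KB_PN_NM

N_BINDING_SITES = 22
HELIX_HEIGHT = 5.5        # axial extent of the binding path [nm]
HELIX_TURNS = 2.0         # left-handed turns
HELIX_END_DIAMETER = 8.0  # diameter of the apical/basal termini [nm]


@dataclass
class HistoneParams:
    """Adsorption and friction constants of the histone core."""

    epsilon_kbt: float = 5.0     # Morse well depth [kBT]
    morse_alpha: float = 1.26    # inverse decay length [1/nm]
    morse_delta: float = 1.0     # well minimum distance [nm]
    exclusion_k_kbt: float = 8.0  # half-harmonic stiffness [kBT/nm^2]
    dna_radius: float = 1.0      # DNA radius r0 [nm]
    core_radius: float = 4.5     # |a| [nm]
    eta: float = 1.0e-9          # viscosity [pN*s/nm^2]
    temperature: float = 298.0   # [K]

    @property
    def kbt(self) -> float:
        return KB_PN_NM * self.temperature

    @property
    def epsilon(self) -> float:
        """Well depth in pN*nm."""
        return self.epsilon_kbt * self.kbt

    @property
    def exclusion_k(self) -> float:
        """Stiffness in pN/nm."""
        return self.exclusion_k_kbt * self.kbt

    @property
    def morse_cutoff(self) -> float:
        """Truncation at delta + 6/alpha (well tail < 0.6% of eps)."""
        return self.morse_delta + 6.0 / self.morse_alpha

    @property
    def zeta(self) -> float:
        """Translational Stokes friction 6 pi eta |a| [pN*s/nm]."""
        return 6.0 * np.pi * self.eta * self.core_radius

    @property
    def zeta_rot(self) -> float:
        """Rotational Stokes friction 8 pi eta |a|^3 [pN*nm*s]."""
        return 8.0 * np.pi * self.eta * self.core_radius ** 3


@dataclass
class BindingGeometry:
    """Body-frame coordinates of the 22 binding sites and helix dimensions."""

    body_sites: np.ndarray        # (22, 3) [nm]
    core_radius: float
    helix_height: float
    helix_turns: float
    end_diameter: float

    @property
    def n_sites(self) -> int:
        return self.body_sites.shape[0]


def build_binding_geometry(core_radius: float = 4.5) -> BindingGeometry:
    """22 sites equally spaced in phase on a left-handed helix about the
    body z axis: axial span 5.5 nm, two turns, end diameters 8 nm.

    The sites lie on the sphere of radius sqrt(4^2 + 2.75^2) = 4.854 nm
    (slightly proud of the 4.5 nm core), so a DNA site at the Morse minimum
    1 nm outside a binding site is already clear of the |a| + r0 = 5.5 nm
    exclusion shell: adsorption and excluded volume never fight."""
    if core_radius <= 0:
        raise ValueError("core_radius must be positive")
    site_sphere = np.hypot(HELIX_END_DIAMETER / 2.0, HELIX_HEIGHT / 2.0)
    k = np.arange(N_BINDING_SITES)
    t = k / (N_BINDING_SITES - 1.0)
    # left-handed: azimuth decreases along the path
    phi = -2.0 * np.pi * HELIX_TURNS * t
    z = HELIX_HEIGHT * (t - 0.5)
    rho = np.sqrt(site_sphere ** 2 - z ** 2)
    body = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return BindingGeometry(body, core_radius, HELIX_HEIGHT, HELIX_TURNS,
                           HELIX_END_DIAMETER)


def _axis_to_matrix(axis: np.ndarray, psi: float) -> np.ndarray:
    """Body->world rotation with body z mapped to ``axis`` (minimal rotation
    from z) composed with a spin of ``psi`` about the axis."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(np.dot(z, a))
    if np.linalg.norm(v) < 1.0e-12:
        Q = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0.0, -v[2], v[1]],
                       [v[2], 0.0, -v[0]],
                       [-v[1], v[0], 0.0]])
        Q = np.eye(3) + vx + vx @ vx / (1.0 + c)
    cp, sp = np.cos(psi), np.sin(psi)
    Rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return Q @ Rz


@dataclass
class HistoneState:
    """Histone center, orientation and binding geometry."""

    center: np.ndarray                       # (3,) [nm]
    orientation: np.ndarray                  # (3,3) body->world rotation
    psi: float = 0.0                         # accumulated spin angle [rad]
    geometry: BindingGeometry = field(default_factory=build_binding_geometry)

    @classmethod
    def from_axis(cls, center, axis=(0.0, 0.0, 1.0), psi: float = 0.0,
                  geometry: BindingGeometry | None = None) -> "HistoneState":
        Q = _axis_to_matrix(np.asarray(axis, float), psi)
        return cls(np.asarray(center, float).copy(), Q, psi,
                   geometry or build_binding_geometry())

    @property
    def axis(self) -> np.ndarray:
        """Unit axial vector A of the helical path (world frame)."""
        return self.orientation[:, 2].copy()

    @property
    def psi_wrapped(self) -> float:
        """Spin angle wrapped to (-pi, pi]."""
        w = (self.psi + np.pi) % (2.0 * np.pi) - np.pi
        return np.pi if w == -np.pi else w

    def copy(self) -> "HistoneState":
        return HistoneState(self.center.copy(), self.orientation.copy(),
                            self.psi, self.geometry)


def world_sites(h: HistoneState) -> np.ndarray:
    """Binding sites in the world frame: center + Q @ body_site."""
    out = np.empty_like(h.geometry.body_sites)
    K.world_sites_kernel(h.center, h.orientation, h.geometry.body_sites, out)
    return out


def _histone_phys(params: HistoneParams) -> np.ndarray:
    phys = np.zeros(K.NPHYS)
    phys[K.IEPS] = params.epsilon
    phys[K.IMALPHA] = params.morse_alpha
    phys[K.IMDELTA] = params.morse_delta
    phys[K.IMCUT] = params.morse_cutoff
    phys[K.IKEXCL] = params.exclusion_k
    phys[K.IREXCL] = params.core_radius + params.dna_radius
    phys[K.IRHH] = 2.0 * params.core_radius
    phys[K.IKHH] = params.exclusion_k
    phys[K.IKBT] = params.kbt
    return phys


def morse_energy_forces(h: HistoneState, dna_sites: np.ndarray,
                        params: HistoneParams):
    """Morse adsorption over all (binding site, DNA site) pairs within the
    cutoff.  Returns (energy, DNA-site forces, histone force, histone torque
    about the center)."""
    phys = _histone_phys(params)
    phys[K.IKEXCL] = 0.0  # Morse only
    return _histone_terms(h, dna_sites, phys)


def histone_dna_exclusion(h: HistoneState, dna_sites: np.ndarray,
                          params: HistoneParams):
    """Half-harmonic shell on the center-to-site distance below |a| + r0.
    Returns (energy, DNA-site forces, histone force)."""
    phys = _histone_phys(params)
    phys[K.IEPS] = 0.0  # exclusion only
    E, Fs, hF, _ = _histone_terms(h, dna_sites, phys)
    return E, Fs, hF


def _histone_terms(h: HistoneState, dna_sites: np.ndarray, phys: np.ndarray):
    dna_sites = np.ascontiguousarray(dna_sites, float)
    M = dna_sites.shape[0]
    W = world_sites(h)
    Fs = np.zeros((M, 3))
    hF = np.zeros(3)
    hT = np.zeros(3)
    hl = np.arange(M, dtype=np.int64)
    Em, Ex = K.histone_dna_forces(dna_sites, h.center, W, hl, M, phys,
                                  Fs, hF, hT)
    return Em + Ex, Fs, hF, hT


def histone_histone_exclusion(h1: HistoneState, h2: HistoneState,
                              params: HistoneParams):
    """Half-harmonic center repulsion below 2|a|.  Returns (energy, force on
    h1, force on h2)."""
    phys = _histone_phys(params)
    hc = np.vstack([h1.center, h2.center])
    hF = np.zeros((2, 3))
    E = K.histone_histone_forces(hc, phys, hF)
    return E, hF[0], hF[1]


def histone_translate_step(h: HistoneState, total_force: np.ndarray,
                           dt: float, params: HistoneParams,
                           rng: np.random.Generator | None = None) -> HistoneState:
    """Overdamped center update: drift F dt/zeta plus thermal noise of
    per-axis variance 2 (kBT/zeta) dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    total_force = np.asarray(total_force, float)
    if not np.all(np.isfinite(total_force)):
        raise FloatingPointError("non-finite force on histone")
    out = h.copy()
    out.center = h.center + total_force * dt / params.zeta
    if rng is not None:
        out.center += rng.normal(0.0, np.sqrt(2.0 * params.kbt / params.zeta * dt),
                                 size=3)
    return out


def histone_rotate_step(h: HistoneState, torque: np.ndarray, dt: float,
                        params: HistoneParams,
                        rng: np.random.Generator | None = None) -> HistoneState:
    """Rigid-body rotational update.

    The torque component along A spins the body (Psi advances by
    T_par dt/zeta_rot); the perpendicular component tips the axis.  Noise is
    an isotropic rotation vector of per-axis variance 2 (kBT/zeta_rot) dt,
    whose axial/tangential components play the roles of the three unit
    Gaussian noises of the angular Langevin equations.  A stays unit-norm
    exactly (rotation-matrix update)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    torque = np.asarray(torque, float)
    rho = torque * dt / params.zeta_rot
    if rng is not None:
        rho = rho + rng.normal(
            0.0, np.sqrt(2.0 * params.kbt / params.zeta_rot * dt), size=3)
    out = h.copy()
    A = h.axis
    K.apply_rotation(out.orientation, rho[0], rho[1], rho[2])
    K.orthonormalize(out.orientation)
    out.psi = h.psi + float(np.dot(rho, A))
    return out
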