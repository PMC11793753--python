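"""Discrete twistable worm-like chain: geometry, energies, forces.

The DNA is N jointed segments of equilibrium length l0 = 3.4 nm (10 bp).
Each segment i carries a right-handed orthonormal material frame
{f_i, g_i, e_i} with e_i the unit tangent.  Bending at joint i is
beta_i = arccos(e_{i-1}.e_i); twist is theta_i = alpha_i + gamma_i measured
through the auxiliary vector p_i = e_{i-1} x e_i (parallel-transport
convention, wrapped to (-pi, pi]).  The chain energy is

    E = sum kBT/(2 (l0 a_s)^2) (l0 - s_i)^2          stretching
      + sum kBT a_b beta_i^2                          bending
      + sum a_t/(2 l0) theta_i^2                      twisting
      + sum_{pairs} A q^2 exp(-kappa r)/r             Debye-Hueckel

with lam point charges per segment and a constant 15 pN repulsion between
non-bonded charge sites closer than 2 nm (DNA impenetrability).  The
Debye-Hueckel amplitude is a single folded constant A = kBT * lB
(lB = 0.714 nm, water at 298 K) so that two unit charges in 150 mM salt
reproduce the standard screened-Coulomb energy.

Units throughout: pN, nm, s, rad; energies in pN*nm; kBT(298 K) = 4.114 pN*nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

KB_PN_NM = 0.0138065  # Boltzmann constant [pN*nm/K]
BJERRUM_NM = 0.714    # Bjerrum length of water at 298 K [nm]


@dataclass
class DNAParams:
    """Mechanical, electrostatic and hydrodynamic DNA constants.

    Defaults are the standard parameter set for coarse-grained supercoiled
    DNA at 10 bp/segment in 150 mM monovalent salt.
    """

    l0: float = 3.4              # segment equilibrium length [nm]
    alpha_s: float = 0.1         # fractional stretch scale (dimensionless)
    alpha_b: float = 7.32        # bending stiffness (dimensionless)
    alpha_t: float = 400.0       # torsional stiffness [pN*nm^2]
    temperature: float = 298.0   # [K]
    rho_e: float = 8.01          # effective charge density [e/nm]
    lam: int = 5                 # point charges per segment
    kappa: float = 1.261         # inverse Debye length [1/nm]
    r_cutoff: float = 8.0        # electrostatic cutoff [nm]
    dh_prefactor: float = field(default=None)  # folded DH constant [pN*nm*nm/e^2]
    n_near: int = field(default=None)          # bonded-exclusion count (site indices)
    f_ex: float = 15.0           # DNA-DNA excluded-volume force [pN]
    overlap_distance: float = 2.0  # excluded-volume onset [nm]
    r_hydro: float = 1.3         # hydrodynamic radius for translation [nm]
    r_d: float = 1.2             # hydrodynamic radius for segment rotation [nm]
    eta: float = 1.0e-9          # viscosity [pN*s/nm^2] (= 0.001 kg/(m*s))

    def __post_init__(self):
        if self.dh_prefactor is None:
            self.dh_prefactor = self.kbt * BJERRUM_NM
        if self.n_near is None:
            # same or adjacent segment -> represented by bonded elastic terms
            self.n_near = 2 * self.lam
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        for name in ("l0", "alpha_s", "alpha_b", "alpha_t", "temperature",
                     "kappa", "r_cutoff", "f_ex", "r_hydro", "r_d", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.overlap_distance < self.l0:
            raise ValueError("overlap_distance must lie in (0, l0)")

    @property
    def kbt(self) -> float:
        return KB_PN_NM * self.temperature

    @property
    def site_charge(self) -> float:
        """Charge per point-like site [e]: rho_e*l0 split over lam sites."""
        return self.rho_e * self.l0 / self.lam

    @property
    def diffusion(self) -> float:
        """Per-vertex translational diffusion constant kBT/(6 pi eta R_H)."""
        return self.kbt / (6.0 * np.pi * self.eta * self.r_hydro)

    @property
    def diffusion_rot(self) -> float:
        """Segment twist diffusion constant kBT/(4 pi eta R_d^2 l0)."""
        return self.kbt / (4.0 * np.pi * self.eta * self.r_d ** 2 * self.l0)


@dataclass
class ChainConformation:
    """N+1 vertex positions [nm] and N orthonormal segment frames.

    ``frames[i]`` rows are (f_i, g_i, e_i); e_i must equal the unit vector
    along segment i after every geometry update.
    """

    vertices: np.ndarray   # (N+1, 3)
    frames: np.ndarray     # (N, 3, 3)

    @property
    def n_segments(self) -> int:
        return self.frames.shape[0]

    def copy(self) -> "ChainConformation":
        return ChainConformation(self.vertices.copy(), self.frames.copy())


@dataclass
class ChainGeometryDerived:
    """Derived joint geometry; entry 0 of the joint arrays is unused (zero)."""

    bend_angles: np.ndarray    # beta_i [rad], index i = joint between segs i-1, i
    twist_angles: np.ndarray   # theta_i [rad], wrapped to (-pi, pi]
    aux_vectors: np.ndarray    # p_i unit vectors (zero where beta_i = 0)
    segment_lengths: np.ndarray  # s_i [nm]


def build_straight_chain(n_segments: int, params: DNAParams,
                         axis=(0.0, 0.0, 1.0)) -> ChainConformation:
    """Straight untwisted chain along ``axis`` at spacing l0.

    All frames are identical: e along the axis, f an arbitrary fixed unit
    vector perpendicular to it, g = e x f.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    vertices = np.outer(np.arange(n_segments + 1), a * params.l0)
    # pick f perpendicular to the axis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, a)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    f = trial - np.dot(trial, a) * a
    f /= np.linalg.norm(f)
    g = np.cross(a, f)
    frames = np.empty((n_segments, 3, 3))
    frames[:, 0] = f
    frames[:, 1] = g
    frames[:, 2] = a
    return ChainConformation(vertices, frames)


def update_geometry(chain: ChainConformation) -> ChainGeometryDerived:
    """Bend/twist angles, auxiliary vectors and segment lengths for the
    current conformation.  Raises on zero-length segments."""
    n = chain.n_segments
    r = chain.vertices
    s = np.empty((n, 3))
    slen = np.empty(n)
    e = np.empty((n, 3))
    lmin = K.chain_tangents(r, s, slen, e)
    if lmin <= 1.0e-12:
        raise ValueError("degenerate geometry: zero-length segment")
    if not np.allclose(e, chain.frames[:, 2], atol=1.0e-9):
        raise ValueError("frame e-vectors inconsistent with vertices; "
                         "transport frames before computing geometry")
    beta = np.empty(n)
    theta = np.empty(n)
    K.joint_angles(chain.frames, beta, theta)
    p = np.zeros((n, 3))
    cr = np.cross(e[:-1], e[1:])
    nrm = np.linalg.norm(cr, axis=1)
    mask = nrm > 1.0e-12
    p[1:][mask] = cr[mask] / nrm[mask][:, None]
    return ChainGeometryDerived(beta, theta, p, slen)


def elastic_energy(chain: ChainConformation, geom: ChainGeometryDerived,
                   params: DNAParams):
    """(stretch, bend, twist) energies in pN*nm."""
    kbt = params.kbt
    ks = kbt / (params.l0 * params.alpha_s) ** 2
    stretch = 0.5 * ks * np.sum((params.l0 - geom.segment_lengths) ** 2)
    bend = kbt * params.alpha_b * np.sum(geom.bend_angles[1:] ** 2)
    twist = params.alpha_t / (2.0 * params.l0) * np.sum(geom.twist_angles[1:] ** 2)
    return stretch, bend, twist


def _phys_vector(params: DNAParams, fz: float = 0.0, k_align: float = 0.0,
                 skin: float = 2.5) -> np.ndarray:
    """Pack DNA constants into the kernel physics vector (histone entries
    zeroed; dynamics fills them)."""
    phys = np.zeros(K.NPHYS)
    kbt = params.kbt
    phys[K.IL0] = params.l0
    phys[K.IKS] = kbt / (params.l0 * params.alpha_s) ** 2
    phys[K.IKB] = kbt * params.alpha_b
    phys[K.IKT] = params.alpha_t / params.l0
    phys[K.IQQ] = params.dh_prefactor * params.site_charge ** 2
    phys[K.IKAPPA] = params.kappa
    phys[K.IRC] = params.r_cutoff
    phys[K.IFEX] = params.f_ex
    phys[K.IREX] = params.overlap_distance
    phys[K.IKBT] = kbt
    phys[K.ID] = params.diffusion
    phys[K.IDROT] = params.diffusion_rot
    phys[K.IFZ] = fz
    phys[K.IKALIGN] = k_align
    phys[K.ISKIN] = skin
    return phys


def elastic_forces_torques(chain: ChainConformation, geom: ChainGeometryDerived,
                           params: DNAParams):
    """Analytic elastic forces on vertices [pN] and twist torques about each
    segment axis [pN*nm] (T_i = -dE/dphi_i)."""
    n = chain.n_segments
    phys = _phys_vector(params)
    e = chain.frames[:, 2].copy()
    F = np.zeros((n + 1, 3))
    T = np.zeros(n)
    K.elastic_forces(e, geom.segment_lengths, geom.bend_angles,
                     geom.twist_angles, phys, F, T)
    return F, T


def place_point_charges(chain: ChainConformation, params: DNAParams) -> np.ndarray:
    """lam equally spaced charge sites per segment (lam*N, 3), each carrying
    charge rho_e*l0/lam."""
    M = chain.n_segments * params.lam
    sites = np.empty((M, 3))
    K.fill_sites(chain.vertices, params.lam, sites)
    return sites


def _site_pairs(chain: ChainConformation, params: DNAParams, rlist: float):
    sites = place_point_charges(chain, params)
    M = sites.shape[0]
    pi = np.empty(M * M // 2 + 8, np.int64)
    pj = np.empty(M * M // 2 + 8, np.int64)
    npair = K.build_pairs(sites, chain.vertices, params.lam, rlist, pi, pj)
    return sites, pi[:npair], pj[:npair]


def electrostatic_energy_forces(chain: ChainConformation, params: DNAParams):
    """Screened-Coulomb energy [pN*nm] and the resulting vertex forces [pN]
    (charge-site forces transferred by the lever rule)."""
    sites, pi, pj = _site_pairs(chain, params, params.r_cutoff)
    phys = _phys_vector(params)
    phys[K.IFEX] = 0.0  # electrostatics only
    Fs = np.zeros_like(sites)
    Ee, _ = K.pair_forces(sites, pi, pj, len(pi), phys, Fs)
    F = np.zeros((chain.n_segments + 1, 3))
    K.scatter_site_forces(Fs, params.lam, F)
    return Ee, F

def dna_self_exclusion(chain: ChainConformation, params: DNAParams) -> np.ndarray:
    """Vertex forces from the constant-magnitude 15 pN repulsion between
    non-bonded charge-site pairs closer than the overlap distance (2 nm)."""
    sites, pi, pj = _site_pairs(chain, params, params.overlap_distance)
    phys = _phys_vector(params)
    phys[K.IQQ] = 0.0  # excluded volume only
    Fs = np.zeros_like(sites)
    K.pair_forces(sites, pi, pj, len(pi), phys, Fs)
    F = np.zeros((chain.n_segments + 1, 3))
    K.scatter_site_forces(Fs, params.lam, F)
    return F
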