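"""Twist, writhe and linking-number bookkeeping for the open stretched chain.

For a torsionally clamped chain held extended between its ends,
DLk = DTw + Wr is conserved.  Excess twist is the sum of the joint twist
angles, DTw = (1/2 pi) sum_i theta_i; writhe is the discrete Gauss double
integral over non-adjacent segment pairs, evaluated exactly per pair by the
solid-angle (Klenin-Langowski) construction.  The relaxed B-DNA reference is
Lk0 = N_bp / 10.5.

The wrapped/unconstrained partition assigns a segment to the wrapped set when
its midpoint lies inside the histone contact shell and one of its charge
sites is Morse-bound; DTw^un and Wr^un are then the same sums restricted to
the unconstrained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

BP_PER_TURN = 10.5


@dataclass
class TopologyReport:
    """Twist/writhe/linking-number bookkeeping, optionally restricted to the
    unconstrained (non-wrapped) sub-chain."""

    delta_Tw: float              # turns
    Wr: float                    # turns
    delta_Lk: float              # turns (= delta_Tw + Wr by construction)
    wrapped_segments: np.ndarray = field(default_factory=lambda: np.array([], int))
    delta_Tw_un: float = None
    Wr_un: float = None

    @property
    def delta_Lk_un(self):
        if self.delta_Tw_un is None:
            return None
        return self.delta_Tw_un + self.Wr_un


def delta_twist(chain, subset=None) -> float:
    """Excess twist (turns): (1/2 pi) sum of joint twist angles.

    ``subset`` restricts the sum to joints i whose segment i is in the
    subset (joint i sits between segments i-1 and i); joints are assigned to
    the higher-indexed segment so a partition's parts sum exactly to the
    total."""
    from .dna_model import update_geometry
    geom = update_geometry(chain)
    theta = geom.twist_angles
    n = chain.n_segments
    if subset is None:
        return float(np.sum(theta[1:]) / (2.0 * np.pi))
    subset = np.asarray(subset, int)
    mask = np.zeros(n, bool)
    mask[subset] = True
    mask[0] = False  # joint 0 does not exist
    return float(np.sum(theta[mask]) / (2.0 * np.pi))


@njit(cache=True)
def _writhe_pair(p1x, p1y, p1z, p2x, p2y, p2z, p3x, p3y, p3z, p4x, p4y, p4z):
    """Exact Gauss-integral contribution (in turns multiplied by 2 pi ...)
    of the directed segment pair (p1->p2, p3->p4): signed solid angle."""
    r13x, r13y, r13z = p3x - p1x, p3y - p1y, p3z - p1z
    r14x, r14y, r14z = p4x - p1x, p4y - p1y, p4z - p1z
    r23x, r23y, r23z = p3x - p2x, p3y - p2y, p3z - p2z
    r24x, r24y, r24z = p4x - p2x, p4y - p2y, p4z - p2z

    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x

    a1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    a2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    a3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    a4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if a1 < 1.0e-12 or a2 < 1.0e-12 or a3 < 1.0e-12 or a4 < 1.0e-12:
        return 0.0
    n1x, n1y, n1z = n1x / a1, n1y / a1, n1z / a1
    n2x, n2y, n2z = n2x / a2, n2y / a2, n2z / a2
    n3x, n3y, n3z = n3x / a3, n3y / a3, n3z / a3
    n4x, n4y, n4z = n4x / a4, n4y / a4, n4z / a4

    d12 = n1x * n2x + n1y * n2y + n1z * n2z
    d23 = n2x * n3x + n2y * n3y + n2z * n3z
    d34 = n3x * n4x + n3y * n4y + n3z * n4z
    d41 = n4x * n1x + n4y * n1y + n4z * n1z
    for_clamp = (d12, d23, d34, d41)
    tot = 0.0
    for d in for_clamp:
        if d > 1.0:
            d = 1.0
        elif d < -1.0:
            d = -1.0
        tot += np.arcsin(d)

    # sign of (r34 x r12) . r13
    r12x, r12y, r12z = p2x - p1x, p2y - p1y, p2z - p1z
    r34x, r34y, r34z = p4x - p3x, p4y - p3y, p4z - p3z
    cx = r34y * r12z - r34z * r12y
    cy = r34z * r12x - r34x * r12z
    cz = r34x * r12y - r34y * r12x
    sgn = cx * r13x + cy * r13y + cz * r13z
    if sgn > 0.0:
        return tot
    elif sgn < 0.0:
        return -tot
    return 0.0


@njit(cache=True)
def _writhe_sum(r, imask, jmask):
    """Sum of pair solid angles over non-adjacent segment pairs with
    segment i in imask and j in jmask (or the reverse); returns turns."""
    n = r.shape[0] - 1
    tot = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if not ((imask[i] and jmask[j]) or (imask[j] and jmask[i])):
                continue
            tot += _writhe_pair(r[i, 0], r[i, 1], r[i, 2],
                                r[i + 1, 0], r[i + 1, 1], r[i + 1, 2],
                                r[j, 0], r[j, 1], r[j, 2],
                                r[j + 1, 0], r[j + 1, 1], r[j + 1, 2])
    return tot / (2.0 * np.pi)


def writhe(chain_or_vertices, subset=None, closed: bool = False,
           method: str = "fast") -> float:
    """Writhe (turns) by the exact discrete Gauss double sum.

    Parameters
    ----------
    chain_or_vertices : ChainConformation or (N+1, 3) array of vertices.
    subset : optional segment-index set; only pairs with at least one member
        in the subset and the partner also in the subset are counted when
        given as a single set.  (Used for the unconstrained-sub-chain writhe:
        pass the unconstrained set; pairs must have both segments in it.)
    closed : include the closing segment from the last vertex to the first.
    method : "fast" (compiled) or "reference" (pure-Python loop); both
        evaluate the identical formula and agree to 1e-9.
    """
    r = np.asarray(getattr(chain_or_vertices, "vertices", chain_or_vertices),
                   float)
    if closed:
        r = np.vstack([r, r[:1]])
    n = r.shape[0] - 1
    seg = np.diff(r, axis=0)
    # near-singular pair guard: distinct vertices too close
    if n >= 2:
        dmin = _min_vertex_gap(r)
        if dmin < 0.1:
            raise ValueError(
                f"near-singular vertex pair (separation {dmin:.2} nm)")
    if subset is None:
        mask = np.ones(n, bool)
    else:
        mask = np.zeros(n, bool)
        mask[np.asarray(subset, int)] = True
    # pairs sharing a vertex (including the closure against segment 0)
    # contribute exactly zero through the degenerate-normal guard
    if method == "fast":
        return float(_writhe_sum(r, mask, mask))
    # reference path: plain loops in Python, identical formula
    tot = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if not (mask[i] and mask[j]):
                continue
            tot += _writhe_pair(*r[i], *r[i + 1], *r[j], *r[j + 1])
    return float(tot / (2.0 * np.pi))


@njit(cache=True)
def _min_vertex_gap(r):
    m = r.shape[0]
    dmin = 1.0e30
    for i in range(m):
        for j in range(i + 1, m):
            dx = r[i, 0] - r[j, 0]
            dy = r[i, 1] - r[j, 1]
            dz = r[i, 2] - r[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < dmin and d > 1.0e-12:
                dmin = d
    return dmin


@njit(cache=True)
def _ray_pair(p1x, p1y, p1z, p2x, p2y, p2z, ax, ay, az):
    """Gauss-integral contribution of the directed segment p1->p2 against a
    semi-infinite vertical ray from point a upward (+z), as the analytic
    H->infinity limit of the four-point solid-angle formula."""
    r13x, r13y, r13z = ax - p1x, ay - p1y, az - p1z
    r23x, r23y, r23z = ax - p2x, ay - p2y, az - p2z
    r12x, r12y, r12z = p2x - p1x, p2y - p1y, p2z - p1z

    # n1 = r13 x z ; n2 = r12 x z ; n3 = z x r23 ; n4 = r23 x r13
    n1x, n1y, n1z = r13y, -r13x, 0.0
    n2x, n2y, n2z = r12y, -r12x, 0.0
    n3x, n3y, n3z = -r23y, r23x, 0.0
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x

    a1 = np.sqrt(n1x * n1x + n1y * n1y)
    a2 = np.sqrt(n2x * n2x + n2y * n2y)
    a3 = np.sqrt(n3x * n3x + n3y * n3y)
    a4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if a1 < 1.0e-12 or a2 < 1.0e-12 or a3 < 1.0e-12 or a4 < 1.0e-12:
        return 0.0
    n1x, n1y = n1x / a1, n1y / a1
    n2x, n2y = n2x / a2, n2y / a2
    n3x, n3y = n3x / a3, n3y / a3
    n4x, n4y, n4z = n4x / a4, n4y / a4, n4z / a4

    tot = 0.0
    for d in (n1x * n2x + n1y * n2y,
              n2x * n3x + n2y * n3y,
              n3x * n4x + n3y * n4y,
              n4x * n1x + n4y * n1y):
        if d > 1.0:
            d = 1.0
        elif d < -1.0:
            d = -1.0
        tot += np.arcsin(d)
    # sign of ((z x r12) . r13)
    sgn = -r12y * r13x + r12x * r13y
    if sgn > 0.0:
        return tot
    elif sgn < 0.0:
        return -tot
    return 0.0


@njit(cache=True)
def _ray_pair_below(p1x, p1y, p1z, p2x, p2y, p2z, ax, ay, az):
    """Gauss-integral contribution of the directed segment p1->p2 against a
    semi-infinite vertical ray rising from z = -infinity to its endpoint a
    (H->infinity limit of the four-point formula with p3 = a - Hz, p4 = a)."""
    r14x, r14y, r14z = ax - p1x, ay - p1y, az - p1z
    r24x, r24y, r24z = ax - p2x, ay - p2y, az - p2z
    r12x, r12y, r12z = p2x - p1x, p2y - p1y, p2z - p1z

    # n1 = r14 x z ; n2 = r14 x r24 ; n3 = z x r24 ; n4 = r12 x z
    n1x, n1y = r14y, -r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x, n3y = -r24y, r24x
    n4x, n4y = r12y, -r12x

    a1 = np.sqrt(n1x * n1x + n1y * n1y)
    a2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    a3 = np.sqrt(n3x * n3x + n3y * n3y)
    a4 = np.sqrt(n4x * n4x + n4y * n4y)
    if a1 < 1.0e-12 or a2 < 1.0e-12 or a3 < 1.0e-12 or a4 < 1.0e-12:
        return 0.0
    n1x, n1y = n1x / a1, n1y / a1
    n2x, n2y, n2z = n2x / a2, n2y / a2, n2z / a2
    n3x, n3y = n3x / a3, n3y / a3
    n4x, n4y = n4x / a4, n4y / a4

    tot = 0.0
    for d in (n1x * n2x + n1y * n2y,
              n2x * n3x + n2y * n3y,
              n3x * n4x + n3y * n4y,
              n4x * n1x + n4y * n1y):
        if d > 1.0:
            d = 1.0
        elif d < -1.0:
            d = -1.0
        tot += np.arcsin(d)
    # sign of ((z x r12) . r14)
    sgn = -r12y * r14x + r12x * r14y
    if sgn > 0.0:
        return tot
    elif sgn < 0.0:
        return -tot
    return 0.0


@njit(cache=True)
def _closure_cross(r):
    """Cross-writhe (turns) between the open chain and its tweezers closure:
    an upward ray leaving the last vertex (through the bead plane) and a ray
    arriving at the first vertex from below the anchoring surface.  The
    connectors at infinity contribute nothing and the two parallel rays are
    mutually coplanar.  Segments sharing a ray endpoint contribute zero
    (coplanar) and are skipped."""
    n = r.shape[0] - 1
    tot = 0.0
    for i in range(n):
        if i < n - 1:
            tot += _ray_pair(r[i, 0], r[i, 1], r[i, 2],
                             r[i + 1, 0], r[i + 1, 1], r[i + 1, 2],
                             r[n, 0], r[n, 1], r[n, 2])
        if i > 0:
            tot += _ray_pair_below(r[i, 0], r[i, 1], r[i, 2],
                                   r[i + 1, 0], r[i + 1, 1], r[i + 1, 2],
                                   r[0, 0], r[0, 1], r[0, 2])
    # each cross pair appears once per ordering; the Gauss double sum counts
    # both orderings
    return 2.0 * tot / (4.0 * np.pi)


def writhe_tweezers(chain_or_vertices) -> float:
    """Writhe of the tweezers circuit (turns): the open-chain Gauss sum plus
    the cross terms with the two vertical closure rays -- upward through the
    bead plane from the held end, and upward from below the anchoring
    surface into the clamped end.

    For a chain held torsionally clamped between a surface and a bead,
    DTw + Wr of the *open* curve fluctuates as the coil moves relative to
    the anchoring verticals; DTw plus this closed-circuit writhe is the
    linking number that clamped dynamics conserves (the chain can cross
    neither the bead plane nor the surface, so the circuit is topologically
    closed)."""
    r = np.asarray(getattr(chain_or_vertices, "vertices", chain_or_vertices),
                   float)
    return writhe(r) + float(_closure_cross(r))


def linking_difference(chain, conserved: bool = False) -> TopologyReport:
    """Full-chain report: DTw, Wr and DLk = DTw + Wr (turns).

    With ``conserved=True`` the writhe is that of the closed tweezers
    circuit (see :func:`writhe_tweezers`), giving the linking number that
    clamped dynamics actually conserves."""
    dtw = delta_twist(chain)
    wr = writhe_tweezers(chain) if conserved else writhe(chain)
    return TopologyReport(dtw, wr, dtw + wr)


def lk0(n_bp: int) -> float:
    """Relaxed B-DNA linking number N_bp / 10.5."""
    return n_bp / BP_PER_TURN


def partition_unconstrained(chain, histones, hist_params,
                            shell_margin: float = 0.5,
                            bound_margin: float = None) -> TopologyReport:
    """Report with DTw/Wr restricted to the unconstrained (non-wrapped) DNA.

    A segment is *wrapped* when its midpoint lies within |a| + r0 +
    shell_margin of any histone center and at least one of its charge sites
    sits within the Morse-bound distance (delta + 1/alpha by default) of a
    binding site of that histone.
    """
    from .dna_model import DNAParams, place_point_charges
    from .histone_model import world_sites

    if bound_margin is None:
        bound_radius = hist_params.morse_delta + 1.0 / hist_params.morse_alpha
    else:
        bound_radius = bound_margin
    n = chain.n_segments
    full = linking_difference(chain)
    if not histones:
        full.delta_Tw_un = full.delta_Tw
        full.Wr_un = full.Wr
        return full

    params = DNAParams()
    sites = place_point_charges(chain, params)
    lam = params.lam
    mid = 0.5 * (chain.vertices[:-1] + chain.vertices[1:])
    shell = hist_params.core_radius + hist_params.dna_radius + shell_margin
    wrapped = np.zeros(n, bool)
    for h in histones:
        W = world_sites(h)
        near = np.linalg.norm(mid - h.center, axis=1) < shell
        if not near.any():
            continue
        # charge sites of near segments vs binding sites
        d = np.linalg.norm(sites[:, None, :] - W[None, :, :], axis=2)
        site_bound = (d < bound_radius).any(axis=1)
        seg_bound = site_bound.reshape(n, lam).any(axis=1)
        wrapped |= near & seg_bound
    un = np.nonzero(~wrapped)[0]
    full.wrapped_segments = np.nonzero(wrapped)[0]
    full.delta_Tw_un = delta_twist(chain, subset=un)
    full.Wr_un = writhe(chain, subset=un)
    return full
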