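"""Second-order Brownian-dynamics driver for the DNA-histone system.

Each step is a two-stage predictor-corrector: a tentative first-order move
with the forces F(t) and the thermal noise, then a final move from the
original state with the average of F(t) and F(t+dt) and the *same* noise
realisation (the corrector adjusts drift only).  Vertex positions and
segment twist angles advance identically; histone centers and orientations
advance through the equivalent overdamped rigid-body scheme.

Boundary conditions emulate a torsionally constrained stretching experiment:
vertex 0 and its frame are clamped, a constant force f pulls the last vertex
along +z, terminal tangents are restrained toward +z by a stiff harmonic,
and supercoils are injected by rotating the end frame about its tangent at a
slow scheduled rate until the accumulated turns reach the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .dna_model import (ChainConformation, DNAParams, build_straight_chain,
                        _phys_vector)
from .histone_model import (HistoneParams, HistoneState,
                            build_binding_geometry)
from . import topology as topo


@dataclass
class IntegratorParams:
    """Time step, diffusion constants and run control.

    ``diffusion``/``diffusion_rot`` default to the values implied by the DNA
    constants (kBT/6 pi eta R_H and kBT/4 pi eta R_d^2 l0)."""

    dt: float = 25.0e-12          # [s]
    seed: int = 0
    max_steps: int = 0
    diffusion: float = None       # [nm^2/s]
    diffusion_rot: float = None   # [rad^2/s]
    skin: float = 2.5             # neighbour-list skin [nm]

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class BoundaryCondition:
    """Clamps, stretching force and the supercoil-injection schedule."""

    clamp_vertex_0: bool = True
    end_force: float = 0.0            # [pN], applied to vertex N along +z
    torsional_clamp_end: bool = True  # last frame twist follows the schedule
    torsional_clamp_0: bool = True
    align_ends: bool = True           # restrain e_0, e_{N-1} toward +z
    k_align_kbt: float = 50.0         # alignment stiffness [kBT]
    delta_lk_target: float = 0.0      # injection target [turns]
    turns_per_step: float = 1.0e-5    # injection rate [turns/step]
    bead_radius: float = 16.0         # tweezers bead on the free end [nm]
    wall_k_kbt: float = 24.0          # bead/surface stiffness [kBT/nm^2]

    def __post_init__(self):
        if self.end_force < 0:
            raise ValueError("end_force must be >= 0")
        if abs(self.turns_per_step) * 2.0 * np.pi > 0.5:
            raise ValueError("per-step injected twist must be << pi")


@dataclass
class SystemState:
    """Chain + histones + boundary conditions: the unit the integrator
    advances."""

    chain: ChainConformation
    histones: list = field(default_factory=list)
    time: float = 0.0
    bc: BoundaryCondition = field(default_factory=BoundaryCondition)
    n_bp: int = None

    def __post_init__(self):
        if self.n_bp is None:
            self.n_bp = 10 * self.chain.n_segments

    def copy(self) -> "SystemState":
        return SystemState(self.chain.copy(),
                           [h.copy() for h in self.histones],
                           self.time, self.bc, self.n_bp)


def _mix_seed(seed: int, chunk: int) -> int:
    return int((seed * 2654435761 + chunk * 40503 + 1013904223) % (2 ** 31 - 1))


def build_phys(dna: DNAParams, hist: HistoneParams, bc: BoundaryCondition,
               integ: IntegratorParams) -> np.ndarray:
    """Packed physics vector for the kernels."""
    phys = _phys_vector(dna, fz=bc.end_force,
                        k_align=bc.k_align_kbt * dna.kbt if bc.align_ends else 0.0,
                        skin=integ.skin)
    phys[K.IEPS] = hist.epsilon
    phys[K.IMALPHA] = hist.morse_alpha
    phys[K.IMDELTA] = hist.morse_delta
    phys[K.IMCUT] = hist.morse_cutoff
    phys[K.IKEXCL] = hist.exclusion_k
    phys[K.IREXCL] = hist.core_radius + hist.dna_radius
    phys[K.IRHH] = 2.0 * hist.core_radius
    phys[K.IKHH] = hist.exclusion_k
    phys[K.IZETAH] = hist.zeta
    phys[K.IZETAROT] = hist.zeta_rot
    if integ.diffusion is not None:
        phys[K.ID] = integ.diffusion
    if integ.diffusion_rot is not None:
        phys[K.IDROT] = integ.diffusion_rot
    phys[K.IDT] = integ.dt
    phys[K.IRBEAD] = bc.bead_radius
    phys[K.IKWALL] = bc.wall_k_kbt * dna.kbt
    return phys


def _build_flags(bc: BoundaryCondition, lam: int) -> np.ndarray:
    flags = np.zeros(K.NFLAG, np.int64)
    flags[K.FCLAMP0] = 1 if bc.clamp_vertex_0 else 0
    flags[K.FTWIST0] = 1 if bc.torsional_clamp_0 else 0
    flags[K.FTWISTN] = 1 if bc.torsional_clamp_end else 0
    flags[K.FALIGN0] = 1 if bc.align_ends else 0
    flags[K.FALIGNN] = 1 if bc.align_ends else 0
    flags[K.FLAM] = lam
    return flags


class Simulator:
    """Owns the packed state arrays and advances them with the compiled
    integration loop.  All randomness flows from ``integ.seed``: each call to
    :meth:`run` seeds the kernel stream from (seed, chunk counter), so a
    trajectory is reproducible from the configuration alone regardless of
    how the steps are chunked -- provided the chunking is part of the
    protocol (run_simulation always chunks by the frame stride)."""

    def __init__(self, sys: SystemState, dna: DNAParams = None,
                 hist: HistoneParams = None, integ: IntegratorParams = None):
        self.dna = dna or DNAParams()
        self.hist = hist or HistoneParams()
        self.integ = integ or IntegratorParams()
        self.bc = sys.bc
        self.n_bp = sys.n_bp
        # own copies: stepping must never mutate the caller's state
        self.r = np.array(sys.chain.vertices, float, order="C")
        self.fr = np.array(sys.chain.frames, float, order="C")
        H = len(sys.histones)
        self.hc = np.zeros((H, 3))
        self.hQ = np.zeros((H, 3, 3))
        self.hpsi = np.zeros(H)
        for i, h in enumerate(sys.histones):
            self.hc[i] = h.center
            self.hQ[i] = h.orientation
            self.hpsi[i] = h.psi
        self.geometry = (sys.histones[0].geometry if H
                         else build_binding_geometry(self.hist.core_radius))
        self.body = np.ascontiguousarray(self.geometry.body_sites, float)
        self.phys = build_phys(self.dna, self.hist, self.bc, self.integ)
        self.flags = _build_flags(self.bc, self.dna.lam)
        self.inj = np.zeros(2)
        sign = 1.0 if self.bc.delta_lk_target >= 0 else -1.0
        self.inj[0] = sign * abs(self.bc.turns_per_step) * 2.0 * np.pi
        self.inj[1] = self.bc.delta_lk_target * 2.0 * np.pi
        # lab-fixed reference f-vectors of the torsionally clamped end frames
        n = self.fr.shape[0]
        self.fref = np.vstack([self.fr[0, 0], self.fr[n - 1, 0]])
        self.time = sys.time
        self.chunk = 0
        self.rejections = 0

    # -- stepping ----------------------------------------------------------
    def run(self, n_steps: int) -> None:
        if n_steps <= 0:
            return
        seed = _mix_seed(self.integ.seed, self.chunk)
        self.chunk += 1
        rej, t_adv = K.run_core(self.r, self.fr, self.hc, self.hQ, self.hpsi,
                                self.body, self.phys, self.flags, self.inj,
                                self.fref, n_steps, seed)
        if rej < 0:
            raise FloatingPointError(
                "integration failed: no stable sub-step found "
                f"(t = {self.time:.3e} s)")
        self.rejections += rej
        self.time += t_adv

    # -- views -------------------------------------------------------------
    @property
    def injected_remaining_turns(self) -> float:
        return self.inj[1] / (2.0 * np.pi)

    def state(self) -> SystemState:
        chain = ChainConformation(self.r.copy(), self.fr.copy())
        histones = [
            HistoneState(self.hc[i].copy(), self.hQ[i].copy(),
                         float(self.hpsi[i]), self.geometry)
            for i in range(self.hc.shape[0])
        ]
        return SystemState(chain, histones, self.time, self.bc, self.n_bp)

    def extension(self) -> float:
        return float(self.r[-1, 2] - self.r[0, 2])

    def delta_twist(self) -> float:
        n = self.fr.shape[0]
        beta = np.empty(n)
        theta = np.empty(n)
        K.joint_angles(self.fr, beta, theta)
        return float(np.sum(theta[1:]) / (2.0 * np.pi))

    def writhe(self) -> float:
        return topo.writhe(self.r)


def total_forces(sys: SystemState, dna: DNAParams = None,
                 hist: HistoneParams = None, integ: IntegratorParams = None):
    """Aggregate forces/torques for the current state.

    Returns (vertex forces (N+1,3) [pN], segment torques (N,) [pN*nm],
    per-histone forces (H,3), per-histone torques (H,3), energies dict).
    Raises on non-finite output."""
    sim = Simulator(sys, dna, hist, integ)
    n = sim.fr.shape[0]
    H = max(sim.hc.shape[0], 1)
    lam = sim.dna.lam
    M = n * lam
    sites = np.empty((M, 3))
    K.fill_sites(sim.r, lam, sites)
    pi = np.empty(M * M // 2 + 8, np.int64)
    pj = np.empty(M * M // 2 + 8, np.int64)
    npair = K.build_pairs(sites, sim.r, lam, sim.dna.r_cutoff, pi, pj)
    hl = np.empty((H, M), np.int64)
    hlcnt = np.zeros(H, np.int64)
    rmax = (float(np.max(np.linalg.norm(sim.body, axis=1)))
            if sim.body.size else 0.0)
    hrad = max(rmax + sim.hist.morse_cutoff,
               sim.hist.core_radius + sim.hist.dna_radius) + 0.1
    for h in range(sim.hc.shape[0]):
        hlcnt[h] = K.build_hlist(sites, sim.hc[h], hrad, hl[h])
    F = np.zeros((n + 1, 3))
    T = np.zeros(n)
    Fs = np.zeros((M, 3))
    hF = np.zeros((H, 3))
    hT = np.zeros((H, 3))
    Wbuf = np.empty((sim.body.shape[0], 3))
    energies = np.zeros(9)
    K.total_forces_kernel(sim.r, sim.fr, sim.hc, sim.hQ, sim.body, sim.phys,
                          sim.flags, pi, pj, npair, hl, hlcnt, sites, Fs,
                          F, T, hF, hT, Wbuf, energies)
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(hF))):
        raise FloatingPointError("non-finite force encountered")
    Hn = sim.hc.shape[0]
    keys = ("stretch", "bend", "twist", "electrostatic", "dna_excluded",
            "morse", "histone_exclusion", "histone_histone", "alignment")
    return F, T, hF[:Hn], hT[:Hn], dict(zip(keys, energies))


def bd_step(sys: SystemState, dna: DNAParams = None, hist: HistoneParams = None,
            integ: IntegratorParams = None) -> SystemState:
    """Advance one two-stage BD step and return the new state."""
    sim = Simulator(sys, dna, hist, integ)
    sim.run(1)
    return sim.state()


def apply_boundary(sys: SystemState, clamp_position=None,
                   clamp_frame=None) -> SystemState:
    """Restore the clamped vertex/frame to their reference values (the
    integrator never moves them; this enforces the invariant on externally
    edited states)."""
    out = sys.copy()
    if sys.bc.clamp_vertex_0:
        if clamp_position is not None:
            out.chain.vertices[0] = clamp_position
        if clamp_frame is not None:
            out.chain.frames[0] = clamp_frame
    return out


def inject_supercoils(sys: SystemState, delta_lk_target: float,
                      dna: DNAParams = None, hist: HistoneParams = None,
                      integ: IntegratorParams = None,
                      turns_per_step: float = 1.0e-5,
                      relax_steps: int = 100000) -> SystemState:
    """Rotate the end frame about its tangent at ``turns_per_step`` until the
    accumulated injected turns reach the target, then freeze the rotation
    and relax.  The chain must be torsionally clamped at both ends."""
    bc = sys.bc
    if not (bc.torsional_clamp_end and bc.torsional_clamp_0):
        raise ValueError("supercoil injection requires torsional clamps")
    n_joints = sys.chain.n_segments - 1
    if abs(delta_lk_target) * 2.0 * np.pi / max(n_joints, 1) > 2.0:
        raise ValueError("requested DLk implies unstable per-joint twist; "
                         "use a longer chain")
    bc.delta_lk_target = delta_lk_target
    bc.turns_per_step = turns_per_step
    sim = Simulator(sys, dna, hist, integ)
    n_inj = (int(np.ceil(abs(delta_lk_target) / abs(turns_per_step)))
             if delta_lk_target else 0)
    chunk = 20000
    done = 0
    while done < n_inj:
        todo = min(chunk, n_inj - done)
        sim.run(todo)
        done += todo
    if abs(sim.injected_remaining_turns) > 1.0e-9:
        raise RuntimeError("injection schedule did not complete")
    sim.run(relax_steps)
    # the injected turns now live in the chain: disarm the schedule so a
    # fresh Simulator built on this state does not inject again
    bc.delta_lk_target = 0.0
    return sim.state()


# ---------------------------------------------------------------------------
# trajectory driver
# ---------------------------------------------------------------------------

def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perp_offset(tangent, rng):
    u = np.cross(tangent, _random_unit(rng))
    while np.linalg.norm(u) < 1.0e-6:
        u = np.cross(tangent, _random_unit(rng))
    return u / np.linalg.norm(u)


def place_single_histone(sys: SystemState, offset: float, rng,
                         geometry=None) -> None:
    """One histone at ``offset`` nm from the chain midpoint vertex,
    perpendicular to the local tangent, randomly oriented."""
    geometry = geometry or build_binding_geometry()
    n = sys.chain.n_segments
    mid = sys.chain.vertices[n // 2]
    t = sys.chain.frames[min(n // 2, n - 1), 2]
    center = mid + offset * _perp_offset(t, rng)
    sys.histones.append(
        HistoneState.from_axis(center, _random_unit(rng),
                               rng.uniform(-np.pi, np.pi), geometry))


def place_histones_random(sys: SystemState, n_histones: int, rng,
                          radial=(10.0, 20.0), min_sep: float = 11.0,
                          geometry=None) -> None:
    """Histones scattered around the chain: random vertex, random
    perpendicular direction, radial distance in ``radial``; resampled until
    centers are mutually separated by ``min_sep``."""
    geometry = geometry or build_binding_geometry()
    n = sys.chain.n_segments
    centers = []
    for _ in range(n_histones):
        for _attempt in range(200):
            iv = int(rng.integers(2, n - 1))
            t = sys.chain.frames[min(iv, n - 1), 2]
            c = (sys.chain.vertices[iv]
                 + rng.uniform(*radial) * _perp_offset(t, rng))
            if all(np.linalg.norm(c - c0) >= min_sep for c0 in centers):
                break
        centers.append(c)
        sys.histones.append(
            HistoneState.from_axis(c, _random_unit(rng),
                                   rng.uniform(-np.pi, np.pi), geometry))


def run_simulation(config):
    """Run one protocol described by a RunConfig and return its Trajectory.

    The protocol: build a straight clamped chain, inject the target excess
    linking number and relax, place histones per the experiment, then
    advance in frame_stride chunks recording (DTw, Wr, DLk, z, per-histone
    bound-site counts and state labels) until max_steps or, when
    stop_on_complete applies, until the designated histone has stayed
    complete through the sustain window plus a post-completion window.
    Identical (config, seed) reproduce the trajectory bit for bit.
    """
    import pandas as pd
    from .cli_io import Trajectory, run_header
    from .wrapping_analysis import StateThresholds, detect_first_passage
    from . import wrapping_analysis as wa

    dna = DNAParams()
    hist = HistoneParams(epsilon_kbt=config.epsilon_kbt)
    thr = StateThresholds(touch_radius=config.touch_radius,
                          bound_radius=config.bound_radius,
                          partial_min=config.partial_min,
                          complete_min=config.complete_min,
                          sustain_steps=config.sustain_steps,
                          min_wrap_turns=config.min_wrap_turns)
    bound_radius = thr.resolve_bound_radius(hist)
    rng = np.random.default_rng(config.seed)

    chain = build_straight_chain(config.n_segments, dna)
    bc = BoundaryCondition(end_force=config.force,
                           turns_per_step=config.turns_per_step)
    sys = SystemState(chain, [], bc=bc, n_bp=config.n_bp)
    integ = IntegratorParams(dt=config.dt, seed=config.seed)
    if config.delta_lk != 0.0:
        sys = inject_supercoils(sys, config.delta_lk, dna, hist, integ,
                                turns_per_step=config.turns_per_step,
                                relax_steps=config.relax_steps)
    else:
        sim0 = Simulator(sys, dna, hist, integ)
        sim0.run(config.relax_steps)
        sys = sim0.state()

    if config.experiment in ("single_wrap", "mfpt_scan", "force_scan"):
        place_single_histone(sys, config.placement_offset, rng)
    elif config.experiment == "multi_nucleosome":
        place_histones_random(sys, config.n_histones, rng,
                              radial=config.placement_radial)

    prod = IntegratorParams(dt=config.dt, seed=_mix_seed(config.seed, 99991))
    sim = Simulator(sys, dna, hist, prod)
    H = sim.hc.shape[0]
    lam = dna.lam
    M = sim.fr.shape[0] * lam
    sites = np.empty((M, 3))

    rows = {k: [] for k in ("time", "dTw", "Wr", "dLk", "z")}
    for h in range(H):
        rows[f"nbound_h{h}"] = []
        rows[f"label_h{h}"] = []
        rows[f"wrapped_h{h}"] = []
    if H > 1:
        rows["n_complete"] = []
    coords = []

    def record(iframe):
        K.fill_sites(sim.r, lam, sites)
        dtw = sim.delta_twist()
        wr = sim.writhe()
        rows["time"].append(sim.time)
        rows["dTw"].append(dtw)
        rows["Wr"].append(wr)
        rows["dLk"].append(dtw + wr)
        rows["z"].append(sim.extension())
        ncomp = 0
        for h in range(H):
            W = sim.hc[h] + sim.body @ sim.hQ[h].T
            label, nb, winding = wa._label_from_arrays(
                sites, W, sim.hc[h], sim.hQ[h], thr, bound_radius)
            assembled = (nb >= thr.complete_min
                         and winding <= -thr.min_wrap_turns)
            rows[f"nbound_h{h}"].append(nb)
            rows[f"label_h{h}"].append(label)
            rows[f"wrapped_h{h}"].append(assembled)
            if assembled:
                ncomp += 1
        if H > 1:
            rows["n_complete"].append(ncomp)
        if config.coord_stride and iframe % config.coord_stride == 0:
            coords.append({"time": sim.time,
                           "vertices": sim.r.copy(),
                           "hc": sim.hc.copy(),
                           "hQ": sim.hQ.copy()})

    record(0)
    n_frames = config.max_steps // config.frame_stride
    stop_after = None
    for iframe in range(1, n_frames + 1):
        sim.run(config.frame_stride)
        record(iframe)
        if config.stop_on_complete and H >= 1 and stop_after is None:
            mask = (rows["wrapped_h0"] if config.completion == "assembled"
                    else None)
            ev = detect_first_passage(rows["time"], rows["label_h0"],
                                      config.dt, config.sustain_steps,
                                      complete_mask=mask)
            if ev.complete_time is not None:
                stop_after = (sim.time
                              + config.post_complete_steps * config.dt)
        if stop_after is not None and sim.time >= stop_after:
            break

    header = run_header(config, dna, hist)
    header["rejected_steps"] = sim.rejections
    return Trajectory(header, pd.DataFrame(rows), coords)


# ---------------------------------------------------------------------------
# ensemble experiment drivers
# ---------------------------------------------------------------------------

def single_wrap_ensemble(epsilon_kbt: float, delta_lk: float, force: float,
                         n_seeds: int = 5, base_seed: int = 1,
                         n_bp: int = 500, cap_steps: int = 800_000,
                         check_stride: int = 2_000, settle_steps: int = 40_000,
                         thresholds=None):
    """Pre-placed single-histone wrapping runs sharing one equilibrated
    chain, with the topology of the unconstrained DNA measured before touch
    and after completion.

    The chain (torsionally clamped, stretched by ``force``) is injected to
    ``delta_lk`` and relaxed once; each replicate then places a randomly
    oriented histone in contact range of the chain midpoint and advances
    until the wrap completes (assembly criterion sustained over three
    checks) or ``cap_steps`` is reached.  After completion the system
    settles for ``settle_steps`` and the report averages five snapshots.

    Returns a list of per-seed dicts with keys: completed, t_assembled [s],
    dd_lk_un, dd_tw_un, d_wr_un (changes of DTw^un + Wr^un and components,
    turns).
    """
    from .wrapping_analysis import StateThresholds, _label_from_arrays

    dna = DNAParams()
    hist = HistoneParams(epsilon_kbt=epsilon_kbt)
    thr = thresholds or StateThresholds()
    brad = thr.resolve_bound_radius(hist)

    chain = build_straight_chain(n_bp // 10, dna)
    base = SystemState(chain, [], bc=BoundaryCondition(end_force=force))
    if delta_lk != 0.0:
        base = inject_supercoils(base, delta_lk, dna, hist,
                                 IntegratorParams(seed=_mix_seed(base_seed,
                                                                 555)))
    else:
        sim0 = Simulator(base, dna, hist,
                         IntegratorParams(seed=_mix_seed(base_seed, 555)))
        sim0.run(100_000)
        base = sim0.state()

    results = []
    for i in range(n_seeds):
        s = base.copy()
        rng = np.random.default_rng(_mix_seed(base_seed, 1000 + i))
        place_single_histone(s, 6.0, rng)
        pre = topo.partition_unconstrained(s.chain, s.histones, hist,
                                           )
        sim = Simulator(s, dna, hist,
                        IntegratorParams(seed=_mix_seed(base_seed, 2000 + i)))
        n = sim.fr.shape[0]
        M = n * dna.lam
        sites = np.empty((M, 3))
        consecutive = 0
        t_assembled = None
        steps = 0
        while steps < cap_steps:
            sim.run(check_stride)
            steps += check_stride
            K.fill_sites(sim.r, dna.lam, sites)
            W = sim.hc[0] + sim.body @ sim.hQ[0].T
            _, nb, winding = _label_from_arrays(sites, W, sim.hc[0],
                                                sim.hQ[0], thr, brad)
            if nb >= thr.complete_min and winding <= -thr.min_wrap_turns:
                consecutive += 1
                if consecutive >= 3:
                    t_assembled = sim.time
                    break
            else:
                consecutive = 0
        completed = t_assembled is not None
        if completed:
            sim.run(settle_steps)
        # average the partition over five snapshots to tame the open-chain
        # writhe fluctuation
        dtw_un = []
        wr_un = []
        for k in range(5):
            if k:
                sim.run(5_000)
            st = sim.state()
            rep = topo.partition_unconstrained(st.chain, st.histones, hist)
            dtw_un.append(rep.delta_Tw_un)
            wr_un.append(rep.Wr_un)
        dtw_un = float(np.mean(dtw_un))
        wr_un = float(np.mean(wr_un))
        results.append({
            "completed": completed,
            "t_assembled": t_assembled,
            "dd_lk_un": (dtw_un + wr_un) - (pre.delta_Tw_un + pre.Wr_un),
            "dd_tw_un": dtw_un - pre.delta_Tw_un,
            "d_wr_un": wr_un - pre.Wr_un,
        })
    return results


def multi_nucleosome_ensemble(n_seeds: int = 5, base_seed: int = 1,
                              n_bp: int = 1000, delta_lk: float = -5.0,
                              epsilon_kbt: float = 6.0, force: float = 1.0,
                              n_histones: int = 6, horizon: float = 10.0e-6,
                              check_stride: int = 5_000, thresholds=None):
    """Nucleosome-assembly census: an initially naked supercoiled chain with
    several free histone cores, advanced to the time horizon.

    Returns (final_counts, pair_distances): the assembled-nucleosome count
    at the horizon per seed, and center-center distances among assembled
    pairs pooled over the second half of every trajectory.
    """
    from .wrapping_analysis import StateThresholds, _label_from_arrays

    dna = DNAParams()
    hist = HistoneParams(epsilon_kbt=epsilon_kbt)
    thr = thresholds or StateThresholds()
    brad = thr.resolve_bound_radius(hist)

    chain = build_straight_chain(n_bp // 10, dna)
    base = SystemState(chain, [], bc=BoundaryCondition(end_force=force))
    if delta_lk != 0.0:
        base = inject_supercoils(base, delta_lk, dna, hist,
                                 IntegratorParams(seed=_mix_seed(base_seed,
                                                                 777)))
    else:
        sim0 = Simulator(base, dna, hist,
                         IntegratorParams(seed=_mix_seed(base_seed, 777)))
        sim0.run(100_000)
        base = sim0.state()
    t0 = base.time

    counts = []
    distances = []
    for i in range(n_seeds):
        s = base.copy()
        rng = np.random.default_rng(_mix_seed(base_seed, 3000 + i))
        place_histones_random(s, n_histones, rng)
        sim = Simulator(s, dna, hist,
                        IntegratorParams(seed=_mix_seed(base_seed, 4000 + i)))
        n = sim.fr.shape[0]
        M = n * dna.lam
        sites = np.empty((M, 3))
        count = 0
        while sim.time - t0 < horizon:
            sim.run(check_stride)
            K.fill_sites(sim.r, dna.lam, sites)
            flags = []
            for h in range(n_histones):
                W = sim.hc[h] + sim.body @ sim.hQ[h].T
                _, nb, winding = _label_from_arrays(sites, W, sim.hc[h],
                                                    sim.hQ[h], thr, brad)
                flags.append(nb >= thr.complete_min
                             and winding <= -thr.min_wrap_turns)
            count = sum(flags)
            if sim.time - t0 > 0.5 * horizon:
                done = [h for h, f in enumerate(flags) if f]
                for a in range(len(done)):
                    for b in range(a + 1, len(done)):
                        distances.append(float(np.linalg.norm(
                            sim.hc[done[a]] - sim.hc[done[b]])))
        counts.append(count)
    return counts, distances
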