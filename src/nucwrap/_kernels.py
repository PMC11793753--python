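"""Compiled kernels for the DNA-histone Brownian dynamics engine.

Everything the integrator touches per step lives here as numba ``njit``
functions operating on plain arrays: chain geometry, elastic / electrostatic /
excluded-volume forces, histone Morse adsorption and rigid-body updates, and
the two-stage (predictor-corrector) BD step loop.  The public modules wrap
these kernels with typed containers; the kernels are the single source of
truth for the physics, so the wrappers never re-implement a force.

Physical constants arrive packed in one float64 vector whose layout is frozen
below (units: pN, nm, s, rad; energies in pN*nm).
"""

import numpy as np
from numba import njit

NPHYS = 28
(
    IL0,       # segment equilibrium length [nm]
    IKS,       # stretch spring constant kBT/(l0*alpha_s)^2 [pN/nm]
    IKB,       # bend prefactor kBT*alpha_b [pN*nm] (energy = IKB*beta^2)
    IKT,       # twist scale alpha_t/l0 [pN*nm]   (energy = IKT*theta^2/2)
    IQQ,       # folded DH prefactor * q^2 [pN*nm^2] (pair energy IQQ*exp(-kr)/r)
    IKAPPA,    # inverse Debye length [1/nm]
    IRC,       # electrostatic cutoff [nm]
    IFEX,      # DNA-DNA excluded-volume force [pN]
    IREX,      # DNA-DNA excluded-volume onset distance [nm]
    IKBT,      # kBT [pN*nm]
    IEPS,      # Morse well depth [pN*nm]
    IMALPHA,   # Morse inverse decay length [1/nm]
    IMDELTA,   # Morse minimum distance [nm]
    IMCUT,     # Morse interaction cutoff [nm]
    IKEXCL,    # histone-DNA half-harmonic stiffness [pN/nm]
    IREXCL,    # histone-DNA exclusion radius |a|+r0 [nm]
    IRHH,      # histone-histone exclusion onset 2|a| [nm]
    IKHH,      # histone-histone half-harmonic stiffness [pN/nm]
    IZETAH,    # histone translational friction [pN*s/nm]
    IZETAROT,  # histone rotational friction [pN*nm*s]
    ID,        # DNA vertex diffusion constant [nm^2/s]
    IDROT,     # DNA segment twist diffusion constant [rad^2/s]
    IDT,       # time step [s]
    IFZ,       # stretching force on the last vertex, +z [pN]
    IKALIGN,   # terminal tangent alignment stiffness [pN*nm]
    ISKIN,     # neighbour-list skin [nm]
    IRBEAD,    # tweezers-bead radius on the free end [nm] (0 = no bead)
    IKWALL,    # bead/surface repulsion stiffness [pN/nm] (0 = no wall)
) = range(NPHYS)

# integer flag-vector layout for run_core
NFLAG = 6
(
    FCLAMP0,      # vertex 0 position + frame clamped
    FTWIST0,      # segment 0 twist clamped (no torque/noise on phi_0)
    FTWISTN,      # last segment twist clamped (injection only)
    FALIGN0,      # restrain e_0 toward +z
    FALIGNN,      # restrain e_{N-1} toward +z
    FLAM,         # charges per segment
) = range(NFLAG)


# ----------------------------------------------------------------------------
# chain geometry
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def chain_tangents(r, s, slen, e):
    """Fill segment vectors, lengths and unit tangents; return min length."""
    n = r.shape[0] - 1
    lmin = 1.0e30
    for i in range(n):
        sx = r[i + 1, 0] - r[i, 0]
        sy = r[i + 1, 1] - r[i, 1]
        sz = r[i + 1, 2] - r[i, 2]
        L = np.sqrt(sx * sx + sy * sy + sz * sz)
        s[i, 0] = sx
        s[i, 1] = sy
        s[i, 2] = sz
        slen[i] = L
        if L < lmin:
            lmin = L
        if L > 0.0:
            e[i, 0] = sx / L
            e[i, 1] = sy / L
            e[i, 2] = sz / L
    return lmin


@njit(cache=True, fastmath=True)
def transport_frames(fr, e_new):
    """Rotate each frame by the minimal rotation taking its old tangent onto
    ``e_new[i]`` (parallel transport of the material frame), then store the
    new tangent as the frame's e-vector."""
    n = fr.shape[0]
    for i in range(n):
        ex, ey, ez = fr[i, 2, 0], fr[i, 2, 1], fr[i, 2, 2]
        tx, ty, tz = e_new[i, 0], e_new[i, 1], e_new[i, 2]
        ax = ey * tz - ez * ty
        ay = ez * tx - ex * tz
        az = ex * ty - ey * tx
        s2 = ax * ax + ay * ay + az * az
        c = ex * tx + ey * ty + ez * tz
        if s2 > 1.0e-28:
            sn = np.sqrt(s2)
            ux, uy, uz = ax / sn, ay / sn, az / sn
            # Rodrigues for f and g rows
            for row in range(2):
                vx, vy, vz = fr[i, row, 0], fr[i, row, 1], fr[i, row, 2]
                dot = ux * vx + uy * vy + uz * vz
                cx = uy * vz - uz * vy
                cy = uz * vx - ux * vz
                cz = ux * vy - uy * vx
                fr[i, row, 0] = vx * c + cx * sn + ux * dot * (1.0 - c)
                fr[i, row, 1] = vy * c + cy * sn + uy * dot * (1.0 - c)
                fr[i, row, 2] = vz * c + cz * sn + uz * dot * (1.0 - c)
        fr[i, 2, 0] = tx
        fr[i, 2, 1] = ty
        fr[i, 2, 2] = tz
        # re-orthonormalise f,g against e (drift control)
        fx, fy, fz = fr[i, 0, 0], fr[i, 0, 1], fr[i, 0, 2]
        d = fx * tx + fy * ty + fz * tz
        fx -= d * tx
        fy -= d * ty
        fz -= d * tz
        nf = np.sqrt(fx * fx + fy * fy + fz * fz)
        fr[i, 0, 0] = fx / nf
        fr[i, 0, 1] = fy / nf
        fr[i, 0, 2] = fz / nf
        # g = e x f
        fr[i, 1, 0] = ty * fr[i, 0, 2] - tz * fr[i, 0, 1]
        fr[i, 1, 1] = tz * fr[i, 0, 0] - tx * fr[i, 0, 2]
        fr[i, 1, 2] = tx * fr[i, 0, 1] - ty * fr[i, 0, 0]


@njit(cache=True, fastmath=True)
def rotate_frame_about_e(fr, i, dphi):
    """Spin frame i about its own tangent by dphi (material twist update)."""
    c = np.cos(dphi)
    s = np.sin(dphi)
    fx = c * fr[i, 0, 0] + s * fr[i, 1, 0]
    fy = c * fr[i, 0, 1] + s * fr[i, 1, 1]
    fz = c * fr[i, 0, 2] + s * fr[i, 1, 2]
    gx = -s * fr[i, 0, 0] + c * fr[i, 1, 0]
    gy = -s * fr[i, 0, 1] + c * fr[i, 1, 1]
    gz = -s * fr[i, 0, 2] + c * fr[i, 1, 2]
    fr[i, 0, 0], fr[i, 0, 1], fr[i, 0, 2] = fx, fy, fz
    fr[i, 1, 0], fr[i, 1, 1], fr[i, 1, 2] = gx, gy, gz


@njit(cache=True, fastmath=True)
def pin_frame(fr, i, fref):
    """Clamp the material frame of segment i to a lab-fixed reference: f is
    the projection of ``fref`` onto the plane normal to the tangent, g = e x f.
    This is the torsional constraint of a tweezers-held end -- unlike
    parallel transport it pumps no geometric phase while the end tangent
    fluctuates about its restrained direction."""
    tx, ty, tz = fr[i, 2, 0], fr[i, 2, 1], fr[i, 2, 2]
    d = fref[0] * tx + fref[1] * ty + fref[2] * tz
    fx = fref[0] - d * tx
    fy = fref[1] - d * ty
    fz = fref[2] - d * tz
    nf = np.sqrt(fx * fx + fy * fy + fz * fz)
    fr[i, 0, 0] = fx / nf
    fr[i, 0, 1] = fy / nf
    fr[i, 0, 2] = fz / nf
    fr[i, 1, 0] = ty * fr[i, 0, 2] - tz * fr[i, 0, 1]
    fr[i, 1, 1] = tz * fr[i, 0, 0] - tx * fr[i, 0, 2]
    fr[i, 1, 2] = tx * fr[i, 0, 1] - ty * fr[i, 0, 0]


@njit(cache=True, fastmath=True)
def joint_angles(fr, beta, theta):
    """Bend angle beta_i = arccos(e_{i-1}.e_i) and twist theta_i = alpha_i +
    gamma_i (via the auxiliary vector p_i = e_{i-1} x e_i), wrapped to
    (-pi, pi].  Entry 0 of both arrays is unused and set to zero."""
    n = fr.shape[0]
    beta[0] = 0.0
    theta[0] = 0.0
    for i in range(1, n):
        e1x, e1y, e1z = fr[i - 1, 2, 0], fr[i - 1, 2, 1], fr[i - 1, 2, 2]
        e2x, e2y, e2z = fr[i, 2, 0], fr[i, 2, 1], fr[i, 2, 2]
        c = e1x * e2x + e1y * e2y + e1z * e2z
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        beta[i] = np.arccos(c)
        px = e1y * e2z - e1z * e2y
        py = e1z * e2x - e1x * e2z
        pz = e1x * e2y - e1y * e2x
        pn = np.sqrt(px * px + py * py + pz * pz)
        f1x, f1y, f1z = fr[i - 1, 0, 0], fr[i - 1, 0, 1], fr[i - 1, 0, 2]
        g1x, g1y, g1z = fr[i - 1, 1, 0], fr[i - 1, 1, 1], fr[i - 1, 1, 2]
        f2x, f2y, f2z = fr[i, 0, 0], fr[i, 0, 1], fr[i, 0, 2]
        if pn < 1.0e-12:
            # collinear tangents: angle from f1 to f2 about the shared axis
            th = np.arctan2(
                f2x * g1x + f2y * g1y + f2z * g1z,
                f2x * f1x + f2y * f1y + f2z * f1z,
            )
        else:
            px /= pn
            py /= pn
            pz /= pn
            alpha = np.arctan2(
                px * g1x + py * g1y + pz * g1z,
                px * f1x + py * f1y + pz * f1z,
            )
            # sin(gamma) = (p x f2).e2, cos(gamma) = p.f2
            cxx = py * f2z - pz * f2y
            cyy = pz * f2x - px * f2z
            czz = px * f2y - py * f2x
            gamma = np.arctan2(
                cxx * e2x + cyy * e2y + czz * e2z,
                px * f2x + py * f2y + pz * f2z,
            )
            th = alpha + gamma
        if th > np.pi:
            th -= 2.0 * np.pi
        elif th <= -np.pi:
            th += 2.0 * np.pi
        theta[i] = th


# ----------------------------------------------------------------------------
# elastic forces and torques
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def elastic_forces(e, slen, beta, theta, phys, F, T):
    """Stretch + bend + twist forces on vertices and twist torques on segment
    frames.  The twist-angle gradient with respect to vertex positions uses
    the curvature binormal kb = 2 e1 x e2 / (1 + e1.e2) of the
    parallel-transport convention.  Returns (E_stretch, E_bend, E_twist)."""
    n = e.shape[0]
    l0 = phys[IL0]
    ks = phys[IKS]
    kb = phys[IKB]
    kt = phys[IKT]
    Es = 0.0
    Eb = 0.0
    Et = 0.0
    # stretching
    for i in range(n):
        d = l0 - slen[i]
        Es += 0.5 * ks * d * d
        # dE/ds = -ks*(l0-L)*t ; F[i] += dE/ds, F[i+1] -= dE/ds
        gx = -ks * d * e[i, 0]
        gy = -ks * d * e[i, 1]
        gz = -ks * d * e[i, 2]
        F[i, 0] += gx
        F[i, 1] += gy
        F[i, 2] += gz
        F[i + 1, 0] -= gx
        F[i + 1, 1] -= gy
        F[i + 1, 2] -= gz
    # bending + twist positional forces, per joint
    for i in range(1, n):
        t1x, t1y, t1z = e[i - 1, 0], e[i - 1, 1], e[i - 1, 2]
        t2x, t2y, t2z = e[i, 0], e[i, 1], e[i, 2]
        l1 = slen[i - 1]
        l2 = slen[i]
        b = beta[i]
        cb = np.cos(b)
        Eb += kb * b * b
        Et += 0.5 * kt * theta[i] * theta[i]
        # bending: dE/dcos(beta) = -2*kb*beta/sin(beta)  (-> -2*kb as beta->0)
        if b > 1.0e-8:
            gbend = 2.0 * kb * b / np.sin(b)
        else:
            gbend = 2.0 * kb
        # dcos/ds1 = (t2 - cb*t1)/l1 ; dcos/ds2 = (t1 - cb*t2)/l2
        g1x = -gbend * (t2x - cb * t1x) / l1
        g1y = -gbend * (t2y - cb * t1y) / l1
        g1z = -gbend * (t2z - cb * t1z) / l1
        g2x = -gbend * (t1x - cb * t2x) / l2
        g2y = -gbend * (t1y - cb * t2y) / l2
        g2z = -gbend * (t1z - cb * t2z) / l2
        # twist: dtheta = kbv . (ds1/(2 l1) + ds2/(2 l2)),
        # kbv = 2 t1 x t2 / (1 + t1.t2)
        chi = 1.0 + t1x * t2x + t1y * t2y + t1z * t2z
        if chi > 1.0e-12:
            gt = kt * theta[i]
            kbx = 2.0 * (t1y * t2z - t1z * t2y) / chi
            kby = 2.0 * (t1z * t2x - t1x * t2z) / chi
            kbz = 2.0 * (t1x * t2y - t1y * t2x) / chi
            g1x += gt * kbx / (2.0 * l1)
            g1y += gt * kby / (2.0 * l1)
            g1z += gt * kbz / (2.0 * l1)
            g2x += gt * kbx / (2.0 * l2)
            g2y += gt * kby / (2.0 * l2)
            g2z += gt * kbz / (2.0 * l2)
        # scatter: F[i-1] += G1 ; F[i] += -G1 + G2 ; F[i+1] -= G2
        F[i - 1, 0] += g1x
        F[i - 1, 1] += g1y
        F[i - 1, 2] += g1z
        F[i, 0] += g2x - g1x
        F[i, 1] += g2y - g1y
        F[i, 2] += g2z - g1z
        F[i + 1, 0] -= g2x
        F[i + 1, 1] -= g2y
        F[i + 1, 2] -= g2z
    # twist torques about each segment axis: T_i = -dE/dphi_i
    for i in range(n):
        t = 0.0
        if i >= 1:
            t -= kt * theta[i]          # dtheta_i/dphi_i = +1
        if i + 1 < n:
            t += kt * theta[i + 1]      # dtheta_{i+1}/dphi_i = -1
        T[i] += t
    return Es, Eb, Et


@njit(cache=True, fastmath=True)
def boundary_forces(e, slen, phys, flags, F):
    """External stretching force on the last vertex and the terminal tangent
    alignment restraints E = k_align*(1 - e.z).  Returns alignment energy."""
    n = e.shape[0]
    Ea = 0.0
    F[n, 2] += phys[IFZ]
    ka = phys[IKALIGN]
    if ka > 0.0:
        for which in range(2):
            if which == 0:
                if flags[FALIGN0] == 0:
                    continue
                i = 0
            else:
                if flags[FALIGNN] == 0:
                    continue
                i = n - 1
            ez = e[i, 2]
            Ea += ka * (1.0 - ez)
            L = slen[i]
            # dE/ds = -ka * (z_hat - ez*e)/L
            gx = ka * ez * e[i, 0] / L
            gy = ka * ez * e[i, 1] / L
            gz = -ka * (1.0 - ez * e[i, 2]) / L
            F[i, 0] += gx
            F[i, 1] += gy
            F[i, 2] += gz
            F[i + 1, 0] -= gx
            F[i + 1, 1] -= gy
            F[i + 1, 2] -= gz
    return Ea


@njit(cache=True, fastmath=True)
def tweezer_boundaries(r, sites, hc, phys, flags, Fs, F, hF):
    """Magnetic-tweezers boundaries that make the open chain's linking
    number conserved: an impenetrable bead (radius IRBEAD) rigidly attached
    just above the last vertex, and a repulsive surface plane just below the
    clamped vertex.  Half-harmonic with stiffness IKWALL on DNA charge sites
    and histone centers (with the core radius added).  The bead's reaction
    force acts on the last vertex; the surface is external.  Returns the
    boundary energy."""
    n = r.shape[0] - 1
    kw = phys[IKWALL]
    rb = phys[IRBEAD]
    E = 0.0
    if kw <= 0.0:
        return E
    M = sites.shape[0]
    H = hc.shape[0]
    hcore = phys[IREXCL]  # |a| + r0: keep histones clear by their size
    if flags[FCLAMP0] == 1:
        zw = r[0, 2]
        for m in range(M):
            d = zw - sites[m, 2]
            if d > 0.0:
                E += 0.5 * kw * d * d
                Fs[m, 2] += kw * d
        for h in range(H):
            d = zw + hcore - hc[h, 2]
            if d > 0.0:
                E += 0.5 * kw * d * d
                hF[h, 2] += kw * d
    if rb > 0.0 and flags[FTWISTN] == 1:
        # the bead is micron-scale in the experiment this emulates: treat it
        # as a plane riding on the last vertex; its reaction acts there
        zb = r[n, 2]
        for m in range(M):
            d = sites[m, 2] - zb
            if d > 0.0:
                E += 0.5 * kw * d * d
                Fs[m, 2] -= kw * d
                F[n, 2] += kw * d
        for h in range(H):
            d = hc[h, 2] - (zb - hcore)
            if d > 0.0:
                E += 0.5 * kw * d * d
                hF[h, 2] -= kw * d
                F[n, 2] += kw * d
    return E


# ----------------------------------------------------------------------------
# point charges: electrostatics + DNA-DNA excluded volume
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def fill_sites(r, lam, sites):
    """lam equally spaced charge sites per segment at fractions (j+0.5)/lam."""
    n = r.shape[0] - 1
    m = 0
    for i in range(n):
        for j in range(lam):
            t = (j + 0.5) / lam
            sites[m, 0] = r[i, 0] + t * (r[i + 1, 0] - r[i, 0])
            sites[m, 1] = r[i, 1] + t * (r[i + 1, 1] - r[i, 1])
            sites[m, 2] = r[i, 2] + t * (r[i + 1, 2] - r[i, 2])
            m += 1


@njit(cache=True, fastmath=True)
def build_pairs(sites, r, lam, rlist, pi, pj):
    """Non-bonded site pair list within rlist; pairs on the same or adjacent
    segments are excluded (their interaction is carried by the bonded elastic
    terms).  Segment midpoints prefilter the O(M^2) site scan.  Returns the
    pair count."""
    n = r.shape[0] - 1
    r2 = rlist * rlist
    cnt = 0
    # segment midpoints and a conservative per-segment bounding radius
    mx = np.empty(n)
    my = np.empty(n)
    mz = np.empty(n)
    rad = np.empty(n)
    for i in range(n):
        mx[i] = 0.5 * (r[i, 0] + r[i + 1, 0])
        my[i] = 0.5 * (r[i, 1] + r[i + 1, 1])
        mz[i] = 0.5 * (r[i, 2] + r[i + 1, 2])
        dx = r[i + 1, 0] - r[i, 0]
        dy = r[i + 1, 1] - r[i, 1]
        dz = r[i + 1, 2] - r[i, 2]
        rad[i] = 0.5 * np.sqrt(dx * dx + dy * dy + dz * dz)
    for i in range(n):
        for j in range(i + 2, n):
            dx = mx[i] - mx[j]
            dy = my[i] - my[j]
            dz = mz[i] - mz[j]
            lim = rlist + rad[i] + rad[j]
            if dx * dx + dy * dy + dz * dz >= lim * lim:
                continue
            for a in range(i * lam, (i + 1) * lam):
                for b in range(j * lam, (j + 1) * lam):
                    dx = sites[a, 0] - sites[b, 0]
                    dy = sites[a, 1] - sites[b, 1]
                    dz = sites[a, 2] - sites[b, 2]
                    if dx * dx + dy * dy + dz * dz < r2:
                        pi[cnt] = a
                        pj[cnt] = b
                        cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def pair_forces(sites, pi, pj, npair, phys, Fs):
    """Screened-Coulomb + constant-force excluded volume on the site pair
    list.  Returns (E_elec, E_ev)."""
    qq = phys[IQQ]
    kap = phys[IKAPPA]
    rc2 = phys[IRC] * phys[IRC]
    fex = phys[IFEX]
    rex = phys[IREX]
    Ee = 0.0
    Ev = 0.0
    for p in range(npair):
        a = pi[p]
        b = pj[p]
        dx = sites[a, 0] - sites[b, 0]
        dy = sites[a, 1] - sites[b, 1]
        dz = sites[a, 2] - sites[b, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= rc2:
            continue
        r = np.sqrt(d2)
        if r < 1.0e-9:
            # coincident sites: push along a fixed fallback direction
            dx, dy, dz = 1.0, 0.0, 0.0
            r = 1.0e-9
        fscale = 0.0
        w = qq * np.exp(-kap * r) / r
        Ee += w
        fscale += w * (kap + 1.0 / r) / r
        if r < rex:
            Ev += fex * (rex - r)
            fscale += fex / r
        fx = fscale * dx
        fy = fscale * dy
        fz = fscale * dz
        Fs[a, 0] += fx
        Fs[a, 1] += fy
        Fs[a, 2] += fz
        Fs[b, 0] -= fx
        Fs[b, 1] -= fy
        Fs[b, 2] -= fz
    return Ee, Ev


@njit(cache=True, fastmath=True)
def scatter_site_forces(Fs, lam, F):
    """Lever-rule transfer of charge-site forces to the flanking vertices."""
    M = Fs.shape[0]
    for m in range(M):
        i = m // lam
        j = m - i * lam
        t = (j + 0.5) / lam
        w0 = 1.0 - t
        F[i, 0] += w0 * Fs[m, 0]
        F[i, 1] += w0 * Fs[m, 1]
        F[i, 2] += w0 * Fs[m, 2]
        F[i + 1, 0] += t * Fs[m, 0]
        F[i + 1, 1] += t * Fs[m, 1]
        F[i + 1, 2] += t * Fs[m, 2]


# ----------------------------------------------------------------------------
# histone: world sites, Morse adsorption, exclusions
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def world_sites_kernel(hc, hQ, body, out):
    """out[k] = hc + Q @ body[k] (columns of Q are body axes in the world)."""
    for k in range(body.shape[0]):
        bx, by, bz = body[k, 0], body[k, 1], body[k, 2]
        out[k, 0] = hc[0] + hQ[0, 0] * bx + hQ[0, 1] * by + hQ[0, 2] * bz
        out[k, 1] = hc[1] + hQ[1, 0] * bx + hQ[1, 1] * by + hQ[1, 2] * bz
        out[k, 2] = hc[2] + hQ[2, 0] * bx + hQ[2, 1] * by + hQ[2, 2] * bz


@njit(cache=True, fastmath=True)
def build_hlist(sites, hc, radius, hl):
    """Indices of DNA sites within radius of a histone center."""
    M = sites.shape[0]
    r2 = radius * radius
    cnt = 0
    for m in range(M):
        dx = sites[m, 0] - hc[0]
        dy = sites[m, 1] - hc[1]
        dz = sites[m, 2] - hc[2]
        if dx * dx + dy * dy + dz * dz < r2:
            hl[cnt] = m
            cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def histone_dna_forces(sites, hc, W, hl, nl, phys, Fs, hF, hT):
    """Morse adsorption (each DNA site against its *nearest* binding site of
    this histone -- adsorption saturates per DNA site) plus the half-harmonic
    histone-DNA exclusion on the center distance.  Adds DNA-site forces into
    Fs and the histone net force/torque into hF/hT (torque about the histone
    center).  Returns (E_morse, E_excl)."""
    eps = phys[IEPS]
    mal = phys[IMALPHA]
    mde = phys[IMDELTA]
    mcut = phys[IMCUT]
    kex = phys[IKEXCL]
    rex = phys[IREXCL]
    Em = 0.0
    Ex = 0.0
    for q in range(nl):
        m = hl[q]
        sx, sy, sz = sites[m, 0], sites[m, 1], sites[m, 2]
        # center exclusion
        dx = sx - hc[0]
        dy = sy - hc[1]
        dz = sz - hc[2]
        R = np.sqrt(dx * dx + dy * dy + dz * dz)
        if R < rex:
            if R < 1.0e-9:
                dx, dy, dz, R = 1.0, 0.0, 0.0, 1.0e-9
            over = rex - R
            Ex += 0.5 * kex * over * over
            fs = kex * over / R
            fx = fs * dx
            fy = fs * dy
            fz = fs * dz
            Fs[m, 0] += fx
            Fs[m, 1] += fy
            Fs[m, 2] += fz
            hF[0] -= fx
            hF[1] -= fy
            hF[2] -= fz
            # central force: no torque about the center
        # Morse against the nearest binding site (saturating adsorption);
        # per-axis early exits prune most of the 22-site search
        kbest = -1
        best = mcut * mcut
        for k in range(W.shape[0]):
            dz = sz - W[k, 2]
            if dz * dz >= best:
                continue
            dx = sx - W[k, 0]
            d2 = dz * dz + dx * dx
            if d2 >= best:
                continue
            dy = sy - W[k, 1]
            r2 = d2 + dy * dy
            if r2 < best:
                best = r2
                kbest = k
        if kbest >= 0:
            k = kbest
            dx = sx - W[k, 0]
            dy = sy - W[k, 1]
            dz = sz - W[k, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 0.05:
                # capped core force: evaluate at the cap distance
                r = 0.05
                if dx * dx + dy * dy + dz * dz < 1.0e-18:
                    dx, dy, dz = 1.0, 0.0, 0.0
            x = np.exp(-mal * (r - mde))
            Em += eps * ((x - 1.0) * (x - 1.0) - 1.0)
            # -dU/dr = 2 eps mal x (x-1): repulsive inside, attractive outside
            fs = 2.0 * eps * mal * x * (x - 1.0) / r
            fx = fs * dx
            fy = fs * dy
            fz = fs * dz
            Fs[m, 0] += fx
            Fs[m, 1] += fy
            Fs[m, 2] += fz
            hF[0] -= fx
            hF[1] -= fy
            hF[2] -= fz
            ax = W[k, 0] - hc[0]
            ay = W[k, 1] - hc[1]
            az = W[k, 2] - hc[2]
            hT[0] += ay * (-fz) - az * (-fy)
            hT[1] += az * (-fx) - ax * (-fz)
            hT[2] += ax * (-fy) - ay * (-fx)
    return Em, Ex


@njit(cache=True, fastmath=True)
def histone_histone_forces(hc, phys, hF):
    """Half-harmonic repulsion between histone centers below 2|a|."""
    H = hc.shape[0]
    rhh = phys[IRHH]
    khh = phys[IKHH]
    E = 0.0
    for a in range(H):
        for b in range(a + 1, H):
            dx = hc[a, 0] - hc[b, 0]
            dy = hc[a, 1] - hc[b, 1]
            dz = hc[a, 2] - hc[b, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r >= rhh:
                continue
            if r < 1.0e-9:
                dx, dy, dz, r = 1.0, 0.0, 0.0, 1.0e-9
            over = rhh - r
            E += 0.5 * khh * over * over
            fs = khh * over / r
            hF[a, 0] += fs * dx
            hF[a, 1] += fs * dy
            hF[a, 2] += fs * dz
            hF[b, 0] -= fs * dx
            hF[b, 1] -= fs * dy
            hF[b, 2] -= fs * dz
    return E


# ----------------------------------------------------------------------------
# total force evaluation
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def total_forces_kernel(r, fr, hc, hQ, body, phys, flags,
                        pi, pj, npair, hl, hlcnt,
                        sites, Fs, F, T, hF, hT, Wbuf, energies):
    """Aggregate all forces/torques for one conformation.

    Outputs are overwritten.  ``energies`` receives
    [stretch, bend, twist, elec, dna_ev, morse, h_excl, hh_excl, align]."""
    n = r.shape[0] - 1
    H = hc.shape[0]
    lam = flags[FLAM]
    F[:] = 0.0
    T[:] = 0.0
    Fs[:] = 0.0
    hF[:] = 0.0
    hT[:] = 0.0
    s = np.empty((n, 3))
    slen = np.empty(n)
    e = np.empty((n, 3))
    chain_tangents(r, s, slen, e)
    beta = np.empty(n)
    theta = np.empty(n)
    joint_angles(fr, beta, theta)
    Es, Eb, Et = elastic_forces(e, slen, beta, theta, phys, F, T)
    Ea = boundary_forces(e, slen, phys, flags, F)
    fill_sites(r, lam, sites)
    Ee, Ev = pair_forces(sites, pi, pj, npair, phys, Fs)
    Ea += tweezer_boundaries(r, sites, hc, phys, flags, Fs, F, hF)
    Em = 0.0
    Ex = 0.0
    Eh = 0.0
    for h in range(H):
        world_sites_kernel(hc[h], hQ[h], body, Wbuf)
        em, ex = histone_dna_forces(sites, hc[h], Wbuf, hl[h], hlcnt[h],
                                    phys, Fs, hF[h], hT[h])
        Em += em
        Ex += ex
    if H > 1:
        Eh = histone_histone_forces(hc, phys, hF)
    scatter_site_forces(Fs, lam, F)
    energies[0] = Es
    energies[1] = Eb
    energies[2] = Et
    energies[3] = Ee
    energies[4] = Ev
    energies[5] = Em
    energies[6] = Ex
    energies[7] = Eh
    energies[8] = Ea


# ----------------------------------------------------------------------------
# rigid-body helpers
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def apply_rotation(Q, wx, wy, wz):
    """Left-multiply Q by the rotation with rotation vector (wx,wy,wz)."""
    ang = np.sqrt(wx * wx + wy * wy + wz * wz)
    if ang < 1.0e-14:
        return
    ux, uy, uz = wx / ang, wy / ang, wz / ang
    c = np.cos(ang)
    s = np.sin(ang)
    for col in range(3):
        vx, vy, vz = Q[0, col], Q[1, col], Q[2, col]
        dot = ux * vx + uy * vy + uz * vz
        cx = uy * vz - uz * vy
        cy = uz * vx - ux * vz
        cz = ux * vy - uy * vx
        Q[0, col] = vx * c + cx * s + ux * dot * (1.0 - c)
        Q[1, col] = vy * c + cy * s + uy * dot * (1.0 - c)
        Q[2, col] = vz * c + cz * s + uz * dot * (1.0 - c)


@njit(cache=True, fastmath=True)
def orthonormalize(Q):
    """Gram-Schmidt on the columns of Q (drift control)."""
    n0 = np.sqrt(Q[0, 0] ** 2 + Q[1, 0] ** 2 + Q[2, 0] ** 2)
    Q[0, 0] /= n0
    Q[1, 0] /= n0
    Q[2, 0] /= n0
    d = Q[0, 0] * Q[0, 1] + Q[1, 0] * Q[1, 1] + Q[2, 0] * Q[2, 1]
    Q[0, 1] -= d * Q[0, 0]
    Q[1, 1] -= d * Q[1, 0]
    Q[2, 1] -= d * Q[2, 0]
    n1 = np.sqrt(Q[0, 1] ** 2 + Q[1, 1] ** 2 + Q[2, 1] ** 2)
    Q[0, 1] /= n1
    Q[1, 1] /= n1
    Q[2, 1] /= n1
    Q[0, 2] = Q[1, 0] * Q[2, 1] - Q[2, 0] * Q[1, 1]
    Q[1, 2] = Q[2, 0] * Q[0, 1] - Q[0, 0] * Q[2, 1]
    Q[2, 2] = Q[0, 0] * Q[1, 1] - Q[1, 0] * Q[0, 1]


# ----------------------------------------------------------------------------
# the integration loop
# ----------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_core(r, fr, hc, hQ, hpsi, body, phys, flags, inj, fref,
             n_steps, seed):
    """Advance the system ``n_steps`` two-stage BD steps in place.

    ``inj`` is [rad_per_step, remaining_rad] for supercoil injection (both
    signed consistently; mutated).  ``fref`` holds the lab-fixed reference
    f-vectors of the torsionally clamped end frames (rows: segment 0, segment
    N-1); injection rotates row 1 about +z.  Returns (n_rejected,
    time_advanced).
    """
    np.random.seed(seed)
    n = r.shape[0] - 1
    H = hc.shape[0]
    lam = flags[FLAM]
    M = n * lam
    DT = phys[IDT]
    kbt = phys[IKBT]
    D = phys[ID]
    Drot = phys[IDROT]
    zeta_h = phys[IZETAH]
    zeta_rot = phys[IZETAROT]
    skin = phys[ISKIN]
    rlist = phys[IRC] + skin

    # histone list radius: max body-site radius + Morse cutoff + skin
    rmax = 0.0
    for k in range(body.shape[0]):
        d = np.sqrt(body[k, 0] ** 2 + body[k, 1] ** 2 + body[k, 2] ** 2)
        if d > rmax:
            rmax = d
    hrad = rmax + phys[IMCUT] + skin
    if hrad < phys[IREXCL] + skin:
        hrad = phys[IREXCL] + skin

    maxpair = M * (M - 1) // 2 + 64   # worst case: every pair listed
    pi = np.empty(maxpair, np.int64)
    pj = np.empty(maxpair, np.int64)
    hl = np.empty((max(H, 1), M), np.int64)
    hlcnt = np.zeros(max(H, 1), np.int64)

    sites = np.empty((M, 3))
    Fs = np.empty((M, 3))
    F1 = np.zeros((n + 1, 3))
    T1 = np.zeros(n)
    F2 = np.zeros((n + 1, 3))
    T2 = np.zeros(n)
    hF1 = np.zeros((max(H, 1), 3))
    hT1 = np.zeros((max(H, 1), 3))
    hF2 = np.zeros((max(H, 1), 3))
    hT2 = np.zeros((max(H, 1), 3))
    Wbuf = np.empty((body.shape[0], 3))
    energies = np.zeros(9)

    rp = np.empty_like(r)
    frp = np.empty_like(fr)
    hcp = np.empty_like(hc)
    hQp = np.empty_like(hQ)
    e_new = np.empty((n, 3))
    sbuf = np.empty((n, 3))
    slenb = np.empty(n)

    r_ref = r.copy()
    hc_ref = hc.copy()
    fill_sites(r, lam, sites)
    npair = build_pairs(sites, r, lam, rlist, pi, pj)
    for h in range(H):
        hlcnt[h] = build_hlist(sites, hc[h], hrad, hl[h])

    guard = 0.5 * phys[IL0]
    rej = 0
    t_adv = 0.0

    for istep in range(n_steps):
        # neighbour-list freshness
        dmax = 0.0
        for i in range(n + 1):
            dx = r[i, 0] - r_ref[i, 0]
            dy = r[i, 1] - r_ref[i, 1]
            dz = r[i, 2] - r_ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > dmax:
                dmax = d2
        for h in range(H):
            dx = hc[h, 0] - hc_ref[h, 0]
            dy = hc[h, 1] - hc_ref[h, 1]
            dz = hc[h, 2] - hc_ref[h, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > dmax:
                dmax = d2
        if dmax > 0.16 * skin * skin:        # moved > skin*0.4
            fill_sites(r, lam, sites)
            npair = build_pairs(sites, r, lam, rlist, pi, pj)
            for h in range(H):
                hlcnt[h] = build_hlist(sites, hc[h], hrad, hl[h])
            r_ref[:] = r
            hc_ref[:] = hc

        # stage A forces at the current state
        total_forces_kernel(r, fr, hc, hQ, body, phys, flags,
                            pi, pj, npair, hl, hlcnt,
                            sites, Fs, F1, T1, hF1, hT1, Wbuf, energies)

        dt = DT
        success = False
        for attempt in range(24):
            if success:
                break
            sig_r = np.sqrt(2.0 * D * dt)
            sig_p = np.sqrt(2.0 * Drot * dt)
            sig_h = np.sqrt(2.0 * kbt / zeta_h * dt)
            sig_q = np.sqrt(2.0 * kbt / zeta_rot * dt)
            cr = D * dt / kbt
            cp = Drot * dt / kbt
            ch = dt / zeta_h
            cq = dt / zeta_rot
            R = np.random.standard_normal((n + 1) * 3).reshape(n + 1, 3) * sig_r
            Phi = np.random.standard_normal(n) * sig_p
            hR = np.random.standard_normal(max(H, 1) * 3).reshape(max(H, 1), 3) * sig_h
            hW = np.random.standard_normal(max(H, 1) * 3).reshape(max(H, 1), 3) * sig_q
            frac = dt / DT
            dinj = inj[0] * frac
            if dinj > 0.0 and dinj > inj[1]:
                dinj = inj[1]
            elif dinj < 0.0 and dinj < inj[1]:
                dinj = inj[1]

            # ---------------- predictor ----------------
            for i in range(n + 1):
                if i == 0 and flags[FCLAMP0] == 1:
                    rp[0, 0] = r[0, 0]
                    rp[0, 1] = r[0, 1]
                    rp[0, 2] = r[0, 2]
                else:
                    rp[i, 0] = r[i, 0] + cr * F1[i, 0] + R[i, 0]
                    rp[i, 1] = r[i, 1] + cr * F1[i, 1] + R[i, 1]
                    rp[i, 2] = r[i, 2] + cr * F1[i, 2] + R[i, 2]
            frp[:] = fr
            lmin = chain_tangents(rp, sbuf, slenb, e_new)
            if lmin < 0.05 * phys[IL0]:
                rej += 1
                dt *= 0.5
                continue
            transport_frames(frp, e_new)
            ci = np.cos(dinj)
            si = np.sin(dinj)
            frx = ci * fref[1, 0] - si * fref[1, 1]
            fry = si * fref[1, 0] + ci * fref[1, 1]
            for i in range(n):
                if i == 0 and flags[FTWIST0] == 1:
                    pin_frame(frp, 0, fref[0])
                    continue
                if i == n - 1 and flags[FTWISTN] == 1:
                    frefN = np.array([frx, fry, fref[1, 2]])
                    pin_frame(frp, n - 1, frefN)
                    continue
                dphi = cp * T1[i] + Phi[i]
                rotate_frame_about_e(frp, i, dphi)
            for h in range(H):
                hcp[h, 0] = hc[h, 0] + ch * hF1[h, 0] + hR[h, 0]
                hcp[h, 1] = hc[h, 1] + ch * hF1[h, 1] + hR[h, 1]
                hcp[h, 2] = hc[h, 2] + ch * hF1[h, 2] + hR[h, 2]
                hQp[h] = hQ[h]
                apply_rotation(hQp[h],
                               cq * hT1[h, 0] + hW[h, 0],
                               cq * hT1[h, 1] + hW[h, 1],
                               cq * hT1[h, 2] + hW[h, 2])

            # stage B forces at the predicted state (same neighbour lists)
            total_forces_kernel(rp, frp, hcp, hQp, body, phys, flags,
                                pi, pj, npair, hl, hlcnt,
                                sites, Fs, F2, T2, hF2, hT2, Wbuf, energies)
            ok = True
            for i in range(n + 1):
                for d3 in range(3):
                    if not np.isfinite(F2[i, d3]):
                        ok = False
            if not ok:
                rej += 1
                dt *= 0.5
                continue

            # ---------------- corrector ----------------
            dispmax = 0.0
            for i in range(n + 1):
                if i == 0 and flags[FCLAMP0] == 1:
                    continue
                ddx = cr * 0.5 * (F1[i, 0] + F2[i, 0]) + R[i, 0]
                ddy = cr * 0.5 * (F1[i, 1] + F2[i, 1]) + R[i, 1]
                ddz = cr * 0.5 * (F1[i, 2] + F2[i, 2]) + R[i, 2]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 > dispmax:
                    dispmax = d2
                rp[i, 0] = r[i, 0] + ddx
                rp[i, 1] = r[i, 1] + ddy
                rp[i, 2] = r[i, 2] + ddz
            if flags[FCLAMP0] == 1:
                rp[0, 0] = r[0, 0]
                rp[0, 1] = r[0, 1]
                rp[0, 2] = r[0, 2]
            lmin = chain_tangents(rp, sbuf, slenb, e_new)
            if dispmax > guard * guard or lmin < 0.05 * phys[IL0]:
                rej += 1
                dt *= 0.5
                continue

            r[:] = rp
            transport_frames(fr, e_new)
            for i in range(n):
                if i == 0 and flags[FTWIST0] == 1:
                    pin_frame(fr, 0, fref[0])
                    continue
                if i == n - 1 and flags[FTWISTN] == 1:
                    frefN = np.array([frx, fry, fref[1, 2]])
                    pin_frame(fr, n - 1, frefN)
                    continue
                dphi = cp * 0.5 * (T1[i] + T2[i]) + Phi[i]
                rotate_frame_about_e(fr, i, dphi)
            if flags[FTWISTN] == 1:
                fref[1, 0] = frx
                fref[1, 1] = fry
            for h in range(H):
                hc[h, 0] += ch * 0.5 * (hF1[h, 0] + hF2[h, 0]) + hR[h, 0]
                hc[h, 1] += ch * 0.5 * (hF1[h, 1] + hF2[h, 1]) + hR[h, 1]
                hc[h, 2] += ch * 0.5 * (hF1[h, 2] + hF2[h, 2]) + hR[h, 2]
                Ax = hQ[h, 0, 2]
                Ay = hQ[h, 1, 2]
                Az = hQ[h, 2, 2]
                wx = cq * 0.5 * (hT1[h, 0] + hT2[h, 0]) + hW[h, 0]
                wy = cq * 0.5 * (hT1[h, 1] + hT2[h, 1]) + hW[h, 1]
                wz = cq * 0.5 * (hT1[h, 2] + hT2[h, 2]) + hW[h, 2]
                apply_rotation(hQ[h], wx, wy, wz)
                orthonormalize(hQ[h])
                hpsi[h] += wx * Ax + wy * Ay + wz * Az
            inj[1] -= dinj
            t_adv += dt
            success = True
        if not success:
            # could not find a stable sub-step; give up loudly
            return -1, t_adv

    return rej, t_adv
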