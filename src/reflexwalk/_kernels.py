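"""Numba kernels: the hot path of the walker simulation.

Everything here operates on flat float64 arrays packed by
:mod:`reflexwalk.params`. The public modules (multibody, mtu, contact,
reflexes, simulate) are thin wrappers over these kernels, so there is a
single implementation of each physical law.

State vector layout (46 entries):
    y[0:9]   q      generalized coordinates
    y[9:18]  qd     generalized velocities
    y[18:32] a      muscle activations (14)
    y[32:46] l_ce   contractile-element lengths (14)

Muscle order: SOL, TA, GAS, VAS, HAM, GLU, HFL for the left leg (0-6),
then the right leg (7-13).
"""

import math

import numpy as np
from numba import njit

# muscle indices within a leg
M_SOL, M_TA, M_GAS, M_VAS, M_HAM, M_GLU, M_HFL = 0, 1, 2, 3, 4, 5, 6

# gains-array indices (must match ReflexGains.as_array)
(GI_SOL, GI_TA, GI_LOFF_TA, GI_SOLTA, GI_GAS, GI_VAS, GI_KPHI, GI_PHIOFF,
 GI_VASDS, GI_THREF, GI_KP, GI_KD, GI_CGLU, GI_CHAM, GI_CHFL, GI_DSHFL,
 GI_DSHAM, GI_GHFL, GI_LOFF_HFL, GI_GHAMHFL, GI_LOFF_HAMHFL, GI_KLEAN,
 GI_GGLUSW, GI_GHAMSW) = range(24)

NQ = 9
NM = 14
NY = 46


# ----------------------------------------------------------------------
# kinematics
# ----------------------------------------------------------------------

@njit(cache=True)
def leg_abs_angles(q, leg):
    """Absolute orientation angles (thigh, shank, foot) of one leg.

    thigh angle a_t: 0 = straight down, positive = knee forward;
    shank likewise; foot angle g_f: 0 = sole flat, positive = toes up.
    """
    b = 3 + 3 * leg
    a_t = math.pi - q[b] - q[2]
    a_s = a_t - math.pi + q[b + 1]
    g_f = a_s + 0.5 * math.pi - q[b + 2]
    return a_t, a_s, g_f


@njit(cache=True)
def leg_abs_rates(qd, leg):
    b = 3 + 3 * leg
    ad_t = -qd[b] - qd[2]
    ad_s = ad_t + qd[b + 1]
    gd_f = ad_s - qd[b + 2]
    return ad_t, ad_s, gd_f


@njit(cache=True)
def kin_points(q, qd, seg):
    """World positions and velocities of the walker's key points.

    Returns (pts, ptv, coms, comv):
      pts  (8,2): kneeL, ankleL, heelL, ballL, kneeR, ankleR, heelR, ballR
      coms (7,2): HAT, thighL, shankL, footL, thighR, shankR, footR
    """
    pts = np.zeros((8, 2))
    ptv = np.zeros((8, 2))
    coms = np.zeros((7, 2))
    comv = np.zeros((7, 2))

    x, y = q[0], q[1]
    vx, vy = qd[0], qd[1]
    psi = q[2]
    psid = qd[2]

    d_T = seg[0]
    l_t, d_t = seg[3], seg[4]
    l_s, d_s = seg[7], seg[8]
    hx, hy = seg[13], seg[14]
    bx, by = seg[15], seg[16]
    cx, cy = seg[17], seg[18]

    # HAT: com above hip along trunk axis
    coms[0, 0] = x + d_T * math.sin(psi)
    coms[0, 1] = y + d_T * math.cos(psi)
    comv[0, 0] = vx + d_T * math.cos(psi) * psid
    comv[0, 1] = vy - d_T * math.sin(psi) * psid

    for leg in range(2):
        a_t, a_s, g_f = leg_abs_angles(q, leg)
        ad_t, ad_s, gd_f = leg_abs_rates(qd, leg)
        st, ct = math.sin(a_t), math.cos(a_t)
        ss, cs = math.sin(a_s), math.cos(a_s)
        sg, cg = math.sin(g_f), math.cos(g_f)

        kx = x + l_t * st
        ky = y - l_t * ct
        kvx = vx + l_t * ct * ad_t
        kvy = vy + l_t * st * ad_t
        ax = kx + l_s * ss
        ay = ky - l_s * cs
        avx = kvx + l_s * cs * ad_s
        avy = kvy + l_s * ss * ad_s

        o = 4 * leg
        pts[o, 0], pts[o, 1] = kx, ky
        ptv[o, 0], ptv[o, 1] = kvx, kvy
        pts[o + 1, 0], pts[o + 1, 1] = ax, ay
        ptv[o + 1, 0], ptv[o + 1, 1] = avx, avy
        # heel / ball: ankle + R(g_f) p
        for k in range(2):
            px = hx if k == 0 else bx
            py = hy if k == 0 else by
            rx = cg * px - sg * py
            ry = sg * px + cg * py
            pts[o + 2 + k, 0] = ax + rx
            pts[o + 2 + k, 1] = ay + ry
            ptv[o + 2 + k, 0] = avx - ry * gd_f
            ptv[o + 2 + k, 1] = avy + rx * gd_f

        co = 1 + 3 * leg
        coms[co, 0] = x + d_t * st
        coms[co, 1] = y - d_t * ct
        comv[co, 0] = vx + d_t * ct * ad_t
        comv[co, 1] = vy + d_t * st * ad_t
        coms[co + 1, 0] = kx + d_s * ss
        coms[co + 1, 1] = ky - d_s * cs
        comv[co + 1, 0] = kvx + d_s * cs * ad_s
        comv[co + 1, 1] = kvy + d_s * ss * ad_s
        rcx = cg * cx - sg * cy
        rcy = sg * cx + cg * cy
        coms[co + 2, 0] = ax + rcx
        coms[co + 2, 1] = ay + rcy
        comv[co + 2, 0] = avx - rcy * gd_f
        comv[co + 2, 1] = avy + rcx * gd_f

    return pts, ptv, coms, comv


@njit(cache=True)
def _add_chain_jacobian(J, col_lean, col_hip, col_knee, col_ankle,
                        ex, ey, coef):
    """Add the column contributions of one rotated lever (ex,ey)*coef whose
    angle depends on (lean, hip, knee, ankle) with signs (-1,-1,+1,-1)."""
    # derivative of coef*e(a) wrt a is coef*e'(a); e=(sin,-cos) => e'=(cos,sin)
    # passed in as (ex, ey) already = coef * e'(a)
    J[0, 2] += -ex
    J[1, 2] += -ey
    J[0, col_hip] += -ex
    J[1, col_hip] += -ey
    if col_knee >= 0:
        J[0, col_knee] += ex
        J[1, col_knee] += ey
    if col_ankle >= 0:
        J[0, col_ankle] += -ex
        J[1, col_ankle] += -ey
    return


@njit(cache=True)
def point_jacobian(q, seg, leg, point):
    """2x9 Jacobian of a foot/leg point. point: 0 knee, 1 ankle, 2 heel, 3 ball."""
    J = np.zeros((2, NQ))
    J[0, 0] = 1.0
    J[1, 1] = 1.0
    b = 3 + 3 * leg
    a_t, a_s, g_f = leg_abs_angles(q, leg)
    l_t, l_s = seg[3], seg[7]
    _add_chain_jacobian(J, 2, b, -1, -1,
                        l_t * math.cos(a_t), l_t * math.sin(a_t), 1.0)
    if point >= 1:
        _add_chain_jacobian(J, 2, b, b + 1, -1,
                            l_s * math.cos(a_s), l_s * math.sin(a_s), 1.0)
    if point >= 2:
        px = seg[13] if point == 2 else seg[15]
        py = seg[14] if point == 2 else seg[16]
        sg, cg = math.sin(g_f), math.cos(g_f)
        rx = cg * px - sg * py
        ry = sg * px + cg * py
        # d/dgamma of R(g)p = perp(Rp) = (-ry, rx)
        _add_chain_jacobian(J, 2, b, b + 1, b + 2, -ry, rx, 1.0)
    return J


@njit(cache=True)
def mass_matrix_bias(q, qd, seg, g):
    """Mass matrix M(q) and bias vector h so that M qdd = Q_applied + h.

    h collects gravity and velocity-product (centrifugal/Coriolis) terms.
    Assembled from per-body COM Jacobians: M = sum m J^T J + I w^T w.
    """
    M = np.zeros((NQ, NQ))
    h = np.zeros(NQ)

    d_T, m_T, I_T = seg[0], seg[1], seg[2]
    l_t, d_t, m_t, I_t = seg[3], seg[4], seg[5], seg[6]
    l_s, d_s, m_s, I_s = seg[7], seg[8], seg[9], seg[10]
    m_f, I_f = seg[11], seg[12]
    cx, cy = seg[17], seg[18]

    psi = q[2]
    psid = qd[2]

    J = np.zeros((2, NQ))
    w = np.zeros(NQ)

    # ---- HAT ----
    J[:] = 0.0
    J[0, 0] = 1.0
    J[1, 1] = 1.0
    J[0, 2] = d_T * math.cos(psi)
    J[1, 2] = -d_T * math.sin(psi)
    w[:] = 0.0
    w[2] = -1.0
    bias_x = -d_T * math.sin(psi) * psid * psid
    bias_y = -d_T * math.cos(psi) * psid * psid
    for i in range(NQ):
        ji0 = J[0, i]
        ji1 = J[1, i]
        wi = w[i]
        if ji0 != 0.0 or ji1 != 0.0 or wi != 0.0:
            for jj in range(NQ):
                M[i, jj] += m_T * (ji0 * J[0, jj] + ji1 * J[1, jj]) \
                    + I_T * wi * w[jj]
            h[i] += ji1 * (-m_T * g) - m_T * (ji0 * bias_x + ji1 * bias_y)

    # ---- legs ----
    for leg in range(2):
        b = 3 + 3 * leg
        a_t, a_s, g_f = leg_abs_angles(q, leg)
        ad_t, ad_s, gd_f = leg_abs_rates(qd, leg)
        st, ct = math.sin(a_t), math.cos(a_t)
        ss, cs = math.sin(a_s), math.cos(a_s)
        sg, cg = math.sin(g_f), math.cos(g_f)

        # thigh COM
        J[:] = 0.0
        J[0, 0] = 1.0
        J[1, 1] = 1.0
        _add_chain_jacobian(J, 2, b, -1, -1, d_t * ct, d_t * st, 1.0)
        w[:] = 0.0
        w[2] = -1.0
        w[b] = -1.0
        bx_ = -d_t * st * ad_t * ad_t
        by_ = d_t * ct * ad_t * ad_t
        _accumulate(M, h, J, w, m_t, I_t, g, bx_, by_)

        # shank COM
        J[:] = 0.0
        J[0, 0] = 1.0
        J[1, 1] = 1.0
        _add_chain_jacobian(J, 2, b, -1, -1, l_t * ct, l_t * st, 1.0)
        _add_chain_jacobian(J, 2, b, b + 1, -1, d_s * cs, d_s * ss, 1.0)
        w[:] = 0.0
        w[2] = -1.0
        w[b] = -1.0
        w[b + 1] = 1.0
        bx_ = -l_t * st * ad_t * ad_t - d_s * ss * ad_s * ad_s
        by_ = l_t * ct * ad_t * ad_t + d_s * cs * ad_s * ad_s
        _accumulate(M, h, J, w, m_s, I_s, g, bx_, by_)

        # foot COM
        J[:] = 0.0
        J[0, 0] = 1.0
        J[1, 1] = 1.0
        _add_chain_jacobian(J, 2, b, -1, -1, l_t * ct, l_t * st, 1.0)
        _add_chain_jacobian(J, 2, b, b + 1, -1, l_s * cs, l_s * ss, 1.0)
        rcx = cg * cx - sg * cy
        rcy = sg * cx + cg * cy
        _add_chain_jacobian(J, 2, b, b + 1, b + 2, -rcy, rcx, 1.0)
        w[:] = 0.0
        w[2] = -1.0
        w[b] = -1.0
        w[b + 1] = 1.0
        w[b + 2] = -1.0
        bx_ = -l_t * st * ad_t * ad_t - l_s * ss * ad_s * ad_s \
            - rcx * gd_f * gd_f
        by_ = l_t * ct * ad_t * ad_t + l_s * cs * ad_s * ad_s \
            - rcy * gd_f * gd_f
        _accumulate(M, h, J, w, m_f, I_f, g, bx_, by_)

    return M, h


@njit(cache=True)
def _accumulate(M, h, J, w, m, I, g, bias_x, bias_y):
    for i in range(NQ):
        ji0 = J[0, i]
        ji1 = J[1, i]
        wi = w[i]
        if ji0 != 0.0 or ji1 != 0.0 or wi != 0.0:
            for jj in range(NQ):
                M[i, jj] += m * (ji0 * J[0, jj] + ji1 * J[1, jj]) + I * wi * w[jj]
            h[i] += ji1 * (-m * g) - m * (ji0 * bias_x + ji1 * bias_y)
    return


@njit(cache=True)
def forward_dynamics_qdd(q, qd, tau6, f_ext, seg, g):
    """Generalized accelerations of the walker.

    tau6: joint torques (hipL, kneeL, ankleL, hipR, kneeR, ankleR),
    positive driving the inner joint angle up.
    f_ext: (4,2) world forces at (heelL, ballL, heelR, ballR).
    """
    M, rhs = mass_matrix_bias(q, qd, seg, g)
    for j in range(6):
        rhs[3 + j] += tau6[j]
    for p in range(4):
        fx = f_ext[p, 0]
        fy = f_ext[p, 1]
        if fx != 0.0 or fy != 0.0:
            leg = p // 2
            point = 2 + (p % 2)
            Jp = point_jacobian(q, seg, leg, point)
            for i in range(NQ):
                rhs[i] += Jp[0, i] * fx + Jp[1, i] * fy
    return np.linalg.solve(M, rhs)


# ----------------------------------------------------------------------
# joint limits
# ----------------------------------------------------------------------

@njit(cache=True)
def joint_limit_torque(angle, vel, lo, hi, k, c):
    """One-sided spring-damper stop; never attracts toward the stop."""
    if angle > hi:
        t = -k * (angle - hi) - c * vel
        return t if t < 0.0 else 0.0
    if angle < lo:
        t = -k * (angle - lo) - c * vel
        return t if t > 0.0 else 0.0
    return 0.0


# ----------------------------------------------------------------------
# muscle-tendon unit
# ----------------------------------------------------------------------

@njit(cache=True)
def mtu_geometry(phi_hip, phi_knee, phi_ankle, musrow):
    """MTU length and signed lever arms (hip, knee, ankle) at given angles.

    Lever arm == d l_mtu / d phi exactly (constant for hip attachments,
    cosine-scaled for knee/ankle)."""
    l = musrow[1] + musrow[2]       # l_opt + l_slack at reference posture
    arm_h = 0.0
    arm_k = 0.0
    arm_a = 0.0
    n_att = int(musrow[6])
    for k in range(n_att):
        base = 7 + 4 * k
        j = int(musrow[base])
        r = musrow[base + 1]
        phimax = musrow[base + 2]
        phiref = musrow[base + 3]
        phi = phi_hip if j == 0 else (phi_knee if j == 1 else phi_ankle)
        if math.isnan(phimax):
            l += r * (phi - phiref)
            arm = r
        else:
            l += r * (math.sin(phi - phimax) - math.sin(phiref - phimax))
            arm = r * math.cos(phi - phimax)
        if j == 0:
            arm_h += arm
        elif j == 1:
            arm_k += arm
        else:
            arm_a += arm
    return l, arm_h, arm_k, arm_a


@njit(cache=True)
def force_length(l_ce, l_opt, w, c):
    x = (l_ce - l_opt) / (l_opt * w)
    return math.exp(c * abs(x) ** 3)


@njit(cache=True)
def force_velocity(v_ce, l_opt, v_max, K, N):
    """Hill force-velocity factor; v_ce in m/s, positive = lengthening."""
    vm = v_max * l_opt
    v = -v_ce            # shortening positive
    if v >= 0.0:
        if v >= vm:
            return 0.0
        return (vm - v) / (vm + K * v)
    f = N + (N - 1.0) * (vm + v) / (7.56 * K * v - vm)
    return f if f < N else N


@njit(cache=True)
def force_velocity_inv(f, l_opt, v_max, K, N):
    """Inverse of the force-velocity factor; returns v_ce (m/s, + lengthening)."""
    vm = v_max * l_opt
    if f < 0.0:
        f = 0.0
    fmax_ecc = N * (1.0 - 1e-4)
    if f > fmax_ecc:
        f = fmax_ecc
    if f <= 1.0:
        v = vm * (1.0 - f) / (1.0 + K * f)   # shortening speed
        return -v
    # eccentric branch
    v = vm * (f - 1.0) / (7.56 * K * (f - N) - (N - 1.0))
    return -v


@njit(cache=True)
def see_force(l_se, l_slack, eps_ref, F_max):
    eps = (l_se - l_slack) / l_slack
    if eps <= 0.0:
        return 0.0
    r = eps / eps_ref
    return F_max * r * r


@njit(cache=True)
def pe_force(l_ce, l_opt, w, F_max):
    if l_ce <= l_opt:
        return 0.0
    r = (l_ce - l_opt) / (l_opt * w)
    return F_max * r * r


@njit(cache=True)
def be_force(l_ce, l_opt, rel_min, bw, F_max):
    l_min = rel_min * l_opt
    if l_ce >= l_min:
        return 0.0
    r = (l_min - l_ce) / (l_opt * bw)
    return F_max * r * r


@njit(cache=True)
def mtu_force_rate(a, l_ce, l_mtu, musrow, hill):
    """MTU force and CE velocity from the CE-SEE force balance.

    The parallel elasticity scales with the force-velocity factor together
    with the CE (shared damping), the buffer elasticity opposes compression
    below the nominal range; both vanish in the nominal working range.
    Returns (F_mtu, dl_ce/dt)."""
    F_max, l_opt, l_slack, v_max = musrow[0], musrow[1], musrow[2], musrow[3]
    w, c, N, K = hill[0], hill[1], hill[2], hill[3]
    eps_ref, pe_w, be_rel, be_w = hill[4], hill[5], hill[6], hill[7]

    l_se = l_mtu - l_ce
    F_se = see_force(l_se, l_slack, eps_ref, F_max)
    F_be = be_force(l_ce, l_opt, be_rel, be_w, F_max)
    F_pe = pe_force(l_ce, l_opt, pe_w, F_max)
    denom = a * F_max * force_length(l_ce, l_opt, w, c) + F_pe + 1e-6 * F_max
    f_v_req = (F_se + F_be) / denom
    v_ce = force_velocity_inv(f_v_req, l_opt, v_max, K, N)
    return F_se, v_ce


# ----------------------------------------------------------------------
# ground contact
# ----------------------------------------------------------------------

@njit(cache=True)
def contact_point_force(px, py, vx, vy, anchor_x, sliding, con):
    """Spring-damper point contact; returns (fx, fy, in_contact)."""
    k_v, expo, v_damp = con[0], con[1], con[2]
    mu_st, mu_sl = con[3], con[4]
    k_h, d_h, v_ref = con[5], con[6], con[7]
    if py >= 0.0:
        return 0.0, 0.0, False
    d = -py
    fy = k_v * d ** expo * (1.0 + (-vy) / v_damp)
    if fy < 0.0:
        fy = 0.0
    if sliding:
        fx = -mu_sl * fy * math.tanh(vx / v_ref)
    else:
        fx = -k_h * (px - anchor_x) - d_h * vx
        lim = mu_st * fy
        if fx > lim:
            fx = lim
        elif fx < -lim:
            fx = -lim
    return fx, fy, True


# ----------------------------------------------------------------------
# reflex controller
# ----------------------------------------------------------------------

@njit(cache=True)
def stimulations(phase, alpha, trailing, theta, thetad, lean_at_to,
                 F_del, lce_del, knee_del, kneed_del, mus, gains):
    """All 14 muscle stimulations from (delayed) sensor data; clipped [0,1].

    phase: per leg, 0 = stance, 1 = swing; alpha: per-leg load share;
    trailing: per leg, True while in double support with the contralateral
    leg touched down later; knee_del/kneed_del: delayed knee angle/rate.
    """
    S = np.zeros(NM)
    for leg in range(2):
        o = 7 * leg
        other = 1 - leg
        for m in range(7):
            i = o + m
            S0 = mus[m, 4]
            F_max = mus[m, 0]
            l_opt = mus[m, 1]
            s = S0
            if phase[leg] == 0:
                if m == M_SOL:
                    s = S0 + gains[GI_SOL] * F_del[i] / F_max
                elif m == M_TA:
                    stretch = lce_del[i] / l_opt - gains[GI_LOFF_TA]
                    if stretch < 0.0:
                        stretch = 0.0
                    s = S0 + gains[GI_TA] * stretch \
                        - gains[GI_SOLTA] * F_del[o + M_SOL] / mus[M_SOL, 0]
                elif m == M_GAS:
                    s = S0 + gains[GI_GAS] * F_del[i] / F_max
                elif m == M_VAS:
                    s = S0 + gains[GI_VAS] * F_del[i] / F_max
                    if knee_del[leg] > gains[GI_PHIOFF] and kneed_del[leg] > 0.0:
                        s -= gains[GI_KPHI] * (knee_del[leg] - gains[GI_PHIOFF])
                    if trailing[leg]:
                        s -= gains[GI_VASDS] * alpha[other]
                else:
                    # trunk-balance PD shared by HAM, GLU, HFL
                    pd = gains[GI_KP] * (theta - gains[GI_THREF]) \
                        + gains[GI_KD] * thetad
                    pos = pd if pd > 0.0 else 0.0
                    neg = -pd if pd < 0.0 else 0.0
                    if m == M_GLU:
                        s = S0 + gains[GI_CGLU] * alpha[leg] * pos
                    elif m == M_HAM:
                        s = S0 + gains[GI_CHAM] * alpha[leg] * pos
                        if trailing[leg]:
                            s -= gains[GI_DSHAM] * alpha[other]
                    elif m == M_HFL:
                        s = S0 + gains[GI_CHFL] * alpha[leg] * neg
                        if trailing[leg]:
                            s += gains[GI_DSHFL] * alpha[other]
            else:
                # swing
                if m == M_TA:
                    stretch = lce_del[i] / l_opt - gains[GI_LOFF_TA]
                    if stretch < 0.0:
                        stretch = 0.0
                    s = S0 + gains[GI_TA] * stretch
                elif m == M_HFL:
                    stretch = lce_del[i] / l_opt - gains[GI_LOFF_HFL]
                    if stretch < 0.0:
                        stretch = 0.0
                    ham_stretch = lce_del[o + M_HAM] / mus[M_HAM, 1] \
                        - gains[GI_LOFF_HAMHFL]
                    if ham_stretch < 0.0:
                        ham_stretch = 0.0
                    s = S0 + gains[GI_GHFL] * stretch \
                        - gains[GI_GHAMHFL] * ham_stretch \
                        + gains[GI_KLEAN] * (lean_at_to[leg] - gains[GI_THREF])
                elif m == M_GLU:
                    s = S0 + gains[GI_GGLUSW] * F_del[i] / F_max
                elif m == M_HAM:
                    s = S0 + gains[GI_GHAMSW] * F_del[i] / F_max
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
            S[i] = s
    return S


# ----------------------------------------------------------------------
# closed-loop right-hand side
# ----------------------------------------------------------------------

@njit(cache=True)
def _leg_joint_angles(q, leg):
    b = 3 + 3 * leg
    return q[b], q[b + 1], q[b + 2]


@njit(cache=True)
def closed_loop_rhs(y, S, anchors, sliding, seg, mus, hill, jlim, con,
                    g, tau_act, out_forces, out_tau, out_fext):
    """Time derivative of the 46-entry state with stimulation held.

    Also fills out_forces (14 MTU forces), out_tau (6 joint torques) and
    out_fext (4x2 contact forces) for sampling/diagnostics."""
    dy = np.zeros(NY)
    for i in range(NY):
        if not math.isfinite(y[i]) or abs(y[i]) > 1e8:
            # poisoned or absurd state: propagate NaN so the driver
            # records a solver failure instead of raising from the solve
            for k in range(NY):
                dy[k] = math.nan
            return dy
    q = y[0:9]
    qd = y[9:18]

    # activation dynamics
    for i in range(NM):
        dy[18 + i] = (S[i] - y[18 + i]) / tau_act

    # muscle forces and joint torques
    tau6 = np.zeros(6)
    for leg in range(2):
        b = 3 * leg
        phi_h, phi_k, phi_a = _leg_joint_angles(q, leg)
        for m in range(7):
            i = 7 * leg + m
            l_mtu, arm_h, arm_k, arm_a = mtu_geometry(phi_h, phi_k, phi_a,
                                                      mus[m])
            F, v_ce = mtu_force_rate(y[18 + i], y[32 + i], l_mtu, mus[m], hill)
            dy[32 + i] = v_ce
            out_forces[i] = F
            tau6[b] += -F * arm_h
            tau6[b + 1] += -F * arm_k
            tau6[b + 2] += -F * arm_a
        # joint limits
        bq = 3 + 3 * leg
        for j in range(3):
            tau6[b + j] += joint_limit_torque(q[bq + j], qd[bq + j],
                                              jlim[j, 0], jlim[j, 1],
                                              jlim[j, 2], jlim[j, 3])

    # contact forces
    pts, ptv, _, _ = kin_points(q, qd, seg)
    f_ext = np.zeros((4, 2))
    for p in range(4):
        src = (2 + p % 2) + 4 * (p // 2)
        fx, fy, _ = contact_point_force(pts[src, 0], pts[src, 1],
                                        ptv[src, 0], ptv[src, 1],
                                        anchors[p], sliding[p], con)
        f_ext[p, 0] = fx
        f_ext[p, 1] = fy

    bad = False
    for j in range(6):
        if not math.isfinite(tau6[j]):
            bad = True
    for p in range(4):
        if not (math.isfinite(f_ext[p, 0]) and math.isfinite(f_ext[p, 1])):
            bad = True
    for i in range(NM):
        if not math.isfinite(dy[32 + i]):
            bad = True
    if bad:
        for k in range(NY):
            dy[k] = math.nan
        return dy
    qdd = forward_dynamics_qdd(q, qd, tau6, f_ext, seg, g)
    for i in range(NQ):
        dy[i] = qd[i]
        dy[9 + i] = qdd[i]
    for j in range(6):
        out_tau[j] = tau6[j]
    for p in range(4):
        out_fext[p, 0] = f_ext[p, 0]
        out_fext[p, 1] = f_ext[p, 1]
    return dy


@njit(cache=True)
def rk4_step(y, dt, S, anchors, sliding, seg, mus, hill, jlim, con, g,
             tau_act, scratch_f, scratch_t, scratch_e, imp_acc):
    """One RK4 step; accumulates the RK4-consistent per-leg contact
    impulse (N s) into imp_acc (2, 2)."""
    k1 = closed_loop_rhs(y, S, anchors, sliding, seg, mus, hill, jlim, con,
                         g, tau_act, scratch_f, scratch_t, scratch_e)
    _acc_impulse(imp_acc, scratch_e, dt / 6.0)
    k2 = closed_loop_rhs(y + 0.5 * dt * k1, S, anchors, sliding, seg, mus,
                         hill, jlim, con, g, tau_act, scratch_f, scratch_t,
                         scratch_e)
    _acc_impulse(imp_acc, scratch_e, dt / 3.0)
    k3 = closed_loop_rhs(y + 0.5 * dt * k2, S, anchors, sliding, seg, mus,
                         hill, jlim, con, g, tau_act, scratch_f, scratch_t,
                         scratch_e)
    _acc_impulse(imp_acc, scratch_e, dt / 3.0)
    k4 = closed_loop_rhs(y + dt * k3, S, anchors, sliding, seg, mus, hill,
                         jlim, con, g, tau_act, scratch_f, scratch_t,
                         scratch_e)
    _acc_impulse(imp_acc, scratch_e, dt / 6.0)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def _acc_impulse(imp_acc, f_ext, w):
    for p in range(4):
        leg = p // 2
        imp_acc[leg, 0] += w * f_ext[p, 0]
        imp_acc[leg, 1] += w * f_ext[p, 1]
    return


# ----------------------------------------------------------------------
# full trial loop
# ----------------------------------------------------------------------

@njit(cache=True)
def simulate_loop(y0, seg, mus, hill, jlim, con, gains, g, tau_act,
                  dt, substeps, n_ctrl,
                  deact_muscle, gc_off, t_off, start_stride, tstride_seed,
                  min_height, max_lean, stand_height,
                  out_q, out_qd, out_tau, out_S, out_a, out_lce, out_F,
                  out_grf, out_cop, out_flags, out_alpha, out_mask,
                  out_imp):
    """Integrate the closed loop for up to n_ctrl control steps (1 per ms).

    Returns (n_done, term_cause, t_stride6, td_count_L, td_count_R).
    term_cause: 0 completed, 1 fell, 2 non-finite state.
    """
    dt_ctrl = dt * substeps
    y = y0.copy()

    # delay bookkeeping (control-rate ring buffers)
    max_delay = 0
    delay_steps = np.zeros(NM, dtype=np.int64)
    for leg in range(2):
        for m in range(7):
            ds = int(round(mus[m, 5] / dt_ctrl))
            delay_steps[7 * leg + m] = ds
            if ds > max_delay:
                max_delay = ds
    buflen = max_delay + 1
    F_hist = np.zeros((buflen, NM))
    lce_hist = np.zeros((buflen, NM))
    knee_hist = np.zeros((buflen, 2))
    kneed_hist = np.zeros((buflen, 2))
    # pre-fill with initial values
    scratch_f = np.zeros(NM)
    scratch_t = np.zeros(6)
    scratch_e = np.zeros((4, 2))
    closed_loop_rhs(y, np.zeros(NM), np.zeros(4),
                    np.zeros(4, dtype=np.bool_), seg, mus, hill, jlim, con,
                    g, tau_act, scratch_f, scratch_t, scratch_e)
    for k in range(buflen):
        for i in range(NM):
            F_hist[k, i] = scratch_f[i]
            lce_hist[k, i] = y[32 + i]
        for leg in range(2):
            knee_hist[k, leg] = y[3 + 3 * leg + 1]
            kneed_hist[k, leg] = y[9 + 3 + 3 * leg + 1]

    # contact / gait state
    anchors = np.zeros(4)
    sliding = np.zeros(4, dtype=np.bool_)
    pts, ptv, _, _ = kin_points(y[0:9], y[9:18], seg)
    for p in range(4):
        src = (2 + p % 2) + 4 * (p // 2)
        anchors[p] = pts[src, 0]

    phase = np.zeros(2, dtype=np.int64)       # 0 stance, 1 swing
    phase[0] = 0
    phase[1] = 0
    lean_at_to = np.zeros(2)
    lean_at_to[0] = y[2]
    lean_at_to[1] = y[2]
    last_td = np.zeros(2)
    last_td[0] = -1.0
    last_td[1] = -1.0
    td_count = np.zeros(2, dtype=np.int64)
    tstride_est = np.zeros(2)
    tstride_est[0] = tstride_seed
    tstride_est[1] = tstride_seed
    # pending deactivation triggers, absolute times (fixed-size queue)
    pend = np.full((2, 4), -1.0)
    window_until = np.zeros(2)
    window_until[0] = -1.0
    window_until[1] = -1.0
    t_stride6 = -1.0

    # initial contact state determines initial phase
    for leg in range(2):
        o = 4 * leg
        in_c = pts[o + 2, 1] < 0.0 or pts[o + 3, 1] < 0.0
        phase[leg] = 0 if in_c else 1

    S = np.zeros(NM)
    alpha = np.zeros(2)
    trailing = np.zeros(2, dtype=np.bool_)
    term_cause = 0
    n_done = 0

    for step in range(n_ctrl):
        t = step * dt_ctrl
        q = y[0:9]
        qd = y[9:18]

        # --- sensors at control rate ---
        pts, ptv, _, _ = kin_points(q, qd, seg)
        fy_leg = np.zeros(2)
        fx_leg = np.zeros(2)
        copx = np.zeros(2)
        flags = np.zeros(4, dtype=np.bool_)
        fpt = np.zeros((4, 2))
        for p in range(4):
            src = (2 + p % 2) + 4 * (p // 2)
            fx, fy, inc = contact_point_force(pts[src, 0], pts[src, 1],
                                              ptv[src, 0], ptv[src, 1],
                                              anchors[p], sliding[p], con)
            fpt[p, 0] = fx
            fpt[p, 1] = fy
            flags[p] = inc
            leg = p // 2
            fx_leg[leg] += fx
            fy_leg[leg] += fy
            copx[leg] += pts[src, 0] * fy
        for leg in range(2):
            if fy_leg[leg] > 0.0:
                copx[leg] /= fy_leg[leg]
            else:
                copx[leg] = math.nan
        tot = fy_leg[0] + fy_leg[1]
        if tot > 0.0:
            alpha[0] = fy_leg[0] / tot
            alpha[1] = fy_leg[1] / tot
        else:
            alpha[0] = 0.0
            alpha[1] = 0.0

        # --- phase transitions, stride clock ---
        for leg in range(2):
            in_c = flags[2 * leg] or flags[2 * leg + 1]
            if phase[leg] == 1 and in_c:
                # touchdown
                phase[leg] = 0
                if last_td[leg] >= 0.0:
                    tstride_est[leg] = t - last_td[leg]
                last_td[leg] = t
                td_count[leg] += 1
                if td_count[leg] == start_stride and t_stride6 < 0.0:
                    t_stride6 = t
                if deact_muscle >= 0 and td_count[leg] >= start_stride:
                    trig = t + gc_off * tstride_est[leg]
                    for s in range(4):
                        if pend[leg, s] < 0.0:
                            pend[leg, s] = trig
                            break
            elif phase[leg] == 0 and not in_c:
                phase[leg] = 1
                lean_at_to[leg] = q[2]
        # trailing-leg flag (double support, other leg touched down later)
        for leg in range(2):
            other = 1 - leg
            trailing[leg] = (phase[leg] == 0 and phase[other] == 0
                             and last_td[other] > last_td[leg])

        # --- deactivation windows ---
        mask_on = np.zeros(2, dtype=np.bool_)
        if deact_muscle >= 0:
            for leg in range(2):
                for s in range(4):
                    if 0.0 <= pend[leg, s] <= t:
                        until = pend[leg, s] + t_off
                        if until > window_until[leg]:
                            window_until[leg] = until
                        pend[leg, s] = -1.0
                mask_on[leg] = t < window_until[leg]

        # --- delayed sensor reads ---
        idx = step % buflen
        F_del = np.zeros(NM)
        lce_del = np.zeros(NM)
        for i in range(NM):
            j = (step - delay_steps[i]) % buflen
            if step < delay_steps[i]:
                j = (0) % buflen
                # pre-history: buffers were pre-filled with initial values,
                # any slot not yet overwritten holds them; reading the oldest
                # valid slot is handled by the modulo into prefilled data
                j = (step - delay_steps[i]) % buflen
            F_del[i] = F_hist[j, i]
            lce_del[i] = lce_hist[j, i]
        knee_del = np.zeros(2)
        kneed_del = np.zeros(2)
        dvas = delay_steps[M_VAS]
        for leg in range(2):
            j = (step - dvas) % buflen
            knee_del[leg] = knee_hist[j, leg]
            kneed_del[leg] = kneed_hist[j, leg]

        # --- stimulations ---
        S = stimulations(phase, alpha, trailing, q[2], qd[2], lean_at_to,
                         F_del, lce_del, knee_del, kneed_del, mus, gains)
        if deact_muscle >= 0:
            for leg in range(2):
                if mask_on[leg]:
                    S[7 * leg + deact_muscle] = 0.0

        # --- sample outputs ---
        for i in range(NQ):
            out_q[step, i] = q[i]
            out_qd[step, i] = qd[i]
        for i in range(NM):
            out_S[step, i] = S[i]
            out_a[step, i] = y[18 + i]
            out_lce[step, i] = y[32 + i]
        for leg in range(2):
            out_grf[step, leg, 0] = fx_leg[leg]
            out_grf[step, leg, 1] = fy_leg[leg]
            out_cop[step, leg] = copx[leg]
            out_alpha[step, leg] = alpha[leg]
            out_mask[step, leg] = mask_on[leg]
        for p in range(4):
            out_flags[step, p] = flags[p]

        # --- integrate one control interval ---
        imp_acc = np.zeros((2, 2))
        for _ in range(substeps):
            y = rk4_step(y, dt, S, anchors, sliding, seg, mus, hill, jlim,
                         con, g, tau_act, scratch_f, scratch_t, scratch_e,
                         imp_acc)
        for leg in range(2):
            out_imp[step, leg, 0] = imp_acc[leg, 0]
            out_imp[step, leg, 1] = imp_acc[leg, 1]
        # forces/torques sampled from the last RK4 stage evaluation are
        # recomputed cleanly at the new state for output
        closed_loop_rhs(y, S, anchors, sliding, seg, mus, hill, jlim, con,
                        g, tau_act, scratch_f, scratch_t, scratch_e)
        for i in range(NM):
            out_F[step, i] = scratch_f[i]
        for j in range(6):
            out_tau[step, j] = scratch_t[j]

        # --- write delay buffers for this step ---
        for i in range(NM):
            F_hist[idx, i] = scratch_f[i]
            lce_hist[idx, i] = y[32 + i]
        for leg in range(2):
            knee_hist[idx, leg] = y[3 + 3 * leg + 1]
            kneed_hist[idx, leg] = y[9 + 3 + 3 * leg + 1]

        # --- friction mode update ---
        pts2, ptv2, _, _ = kin_points(y[0:9], y[9:18], seg)
        for p in range(4):
            src = (2 + p % 2) + 4 * (p // 2)
            px = pts2[src, 0]
            py = pts2[src, 1]
            vx = ptv2[src, 0]
            if py >= 0.0:
                anchors[p] = px
                sliding[p] = False
            else:
                fy = scratch_e[p, 1]
                if sliding[p]:
                    if abs(vx) < con[8]:
                        sliding[p] = False
                        anchors[p] = px
                else:
                    fspring = -con[5] * (px - anchors[p]) - con[6] * vx
                    if abs(fspring) > con[3] * fy:
                        sliding[p] = True

        n_done = step + 1

        # --- failure checks ---
        ok = True
        for i in range(NY):
            if not math.isfinite(y[i]):
                ok = False
        if not ok:
            term_cause = 2
            break
        if y[1] < min_height * stand_height or abs(y[2]) > max_lean:
            term_cause = 1
            break

    return n_done, term_cause, t_stride6, td_count[0], td_count[1]
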