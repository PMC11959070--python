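"""Compiled core of the 1-D pulse-wave solver.

State variables are cross-sectional area A (m^2) and volumetric flow Q
(m^3/s) on a node-centred grid per segment. The interior update is a
two-step Lax-Wendroff (MacCormack) predictor-corrector on

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx = -k_f pi nu Q/A

with the algebraic wall law P(A, x) evaluated pointwise. Inlet,
bifurcation and Windkessel-terminal nodes are closed with linearized
characteristic compatibility relations written in (u, P) variables,
du +- dP/(rho c) = 0 along dx/dt = u +- c; formulating them in pressure
rather than area keeps tapered segments well-posed, because in a taper
the pressure is smooth along the axis while the area is not.
Bifurcations additionally enforce static-pressure continuity and flow
conservation through a small Newton solve.

Everything here is SI. The Python-facing wrapper lives in ``solver.py``.
"""

import numpy as np
from numba import njit

# error codes returned by run_simulation
OK = 0
ERR_NAN = 1
ERR_NEWTON = 2


@njit(cache=True)
def _pressure(A, Aref, Dsi, b, Pref):
    a = A / Aref
    if b == 0.0:
        return Pref + (a - 1.0) / Dsi
    return Pref + (np.exp(b * (a - 1.0)) - 1.0) / (b * Dsi)


@njit(cache=True)
def _dpda(A, Aref, Dsi, b):
    if b == 0.0:
        return 1.0 / (Dsi * Aref)
    a = A / Aref
    return np.exp(b * (a - 1.0)) / (Dsi * Aref)


@njit(cache=True)
def _wave_speed(A, Aref, Dsi, b, rho):
    return np.sqrt(A * _dpda(A, Aref, Dsi, b) / rho)


@njit(cache=True)
def _gauss_solve(M, r, n):
    """In-place Gaussian elimination with partial pivoting for n<=4."""
    for col in range(n):
        piv = col
        big = abs(M[col, col])
        for row in range(col + 1, n):
            if abs(M[row, col]) > big:
                big = abs(M[row, col])
                piv = row
        if big == 0.0:
            return False
        if piv != col:
            for k in range(n):
                tmp = M[col, k]
                M[col, k] = M[piv, k]
                M[piv, k] = tmp
            tmp = r[col]
            r[col] = r[piv]
            r[piv] = tmp
        for row in range(col + 1, n):
            fac = M[row, col] / M[col, col]
            for k in range(col, n):
                M[row, k] -= fac * M[col, k]
            r[row] -= fac * r[col]
    for col in range(n - 1, -1, -1):
        s = r[col]
        for k in range(col + 1, n):
            s -= M[col, k] * r[k]
        r[col] = s / M[col, col]
    return True


@njit(cache=True)
def _char_foot(A, Q, P, i_bnd, i_int, dx, dt, Aref, dAref_dx, Dsi, b, rho,
               nu, kf, outgoing):
    """Linearized characteristic quantities at the foot of the
    characteristic reaching a boundary node.

    Returns (u_eff, P_f, rc) with rc = rho*c_f the characteristic
    impedance per unit area. ``outgoing`` selects the characteristic
    travelling toward the boundary from the interior side: +1 for a
    segment outlet (forward characteristic), -1 for an inlet.

    The compatibility relation along dx/dt = u +- c in (u, P) variables,
        d(u +- P/(rho c)) = (f_visc -+ u c A'_ref/A_ref) dt,
    carries a geometric source on tapered vessels; it is integrated over
    one step and folded into the returned effective foot velocity
    ``u_eff`` so that the boundary closures read
    u_b -+ (P_b - P_f)/(rho c) = u_eff.
    """
    u_b = Q[i_bnd] / A[i_bnd]
    c_b = _wave_speed(A[i_bnd], Aref[i_bnd], Dsi[i_bnd], b[i_bnd], rho)
    if outgoing > 0:
        speed = u_b + c_b
    else:
        speed = c_b - u_b
    frac = speed * dt / dx
    if frac < 0.0:
        frac = 0.0
    if frac > 1.0:
        frac = 1.0
    u_i = Q[i_int] / A[i_int]
    c_i = _wave_speed(A[i_int], Aref[i_int], Dsi[i_int], b[i_int], rho)
    u_f = u_b + frac * (u_i - u_b)
    A_f = A[i_bnd] + frac * (A[i_int] - A[i_bnd])
    P_f = P[i_bnd] + frac * (P[i_int] - P[i_bnd])
    c_f = c_b + frac * (c_i - c_b)
    taper = u_f * c_f * dAref_dx[i_bnd] / Aref[i_bnd]
    fric = -kf * np.pi * nu * u_f / A_f
    if outgoing > 0:
        src = fric - taper
    else:
        src = fric + taper
    return u_f + dt * src, P_f, rho * c_f


@njit(cache=True)
def _seg_of(seg_first, seg_n, node):
    for s in range(seg_first.shape[0]):
        if seg_first[s] <= node < seg_first[s] + seg_n[s]:
            return s
    return -1


@njit(cache=True)
def run_simulation(
    # grid layout
    seg_first, seg_n, seg_dx,
    # per-node wall/geometry arrays
    Aref, dAref_dx, Dsi, bcoef,
    # scalars
    Pref, rho, nu, kf, dt, nsteps,
    # root inflow over one cycle (m^3/s), at step edges
    qin,
    # junctions
    jparent_end, jnchild, jchild_start, jchild_seg,
    # terminals: boundary node index and WK parameters
    term_node, term_r1, term_r2, term_c, term_pout,
    # recording
    rec_nodes,
    # control
    max_cycles, tol,
):
    """Integrate the network until cycle-periodicity or max_cycles.

    Returns (P_rec, Q_rec, root_P, cycles_used, converged, err_code,
    vol_in, vol_out, d_storage, term_Pc) where the recorded arrays hold
    the last completed cycle.
    """
    nnode = Aref.shape[0]
    nseg = seg_first.shape[0]
    njun = jparent_end.shape[0]
    nterm = term_node.shape[0]
    nrec = rec_nodes.shape[0]

    A = Aref.copy()
    Q = np.zeros(nnode)
    P = np.empty(nnode)
    for i in range(nnode):
        P[i] = _pressure(A[i], Aref[i], Dsi[i], bcoef[i], Pref)

    As = np.empty(nnode)
    Qs = np.empty(nnode)
    Ps = np.empty(nnode)
    An = np.empty(nnode)
    Qn = np.empty(nnode)

    term_Pc = np.full(nterm, Pref)

    P_rec = np.zeros((nrec, nsteps))
    Q_rec = np.zeros((nrec, nsteps))
    root_P = np.zeros(nsteps)
    root_P_prev = np.zeros(nsteps)

    vol_in = 0.0
    vol_out = 0.0
    d_storage = 0.0

    cycles_used = 0
    converged = 0
    err_code = OK

    # junction Newton workspace (1 parent + up to 3 children)
    M = np.zeros((4, 4))
    r = np.zeros(4)
    x = np.zeros(4)

    for cycle in range(max_cycles):
        vol_in = 0.0
        vol_out = 0.0
        # total blood volume at cycle start (trapezoid over each segment
        # plus Windkessel charge)
        v_start = 0.0
        for s in range(nseg):
            i0 = seg_first[s]
            n = seg_n[s]
            acc = 0.5 * (A[i0] + A[i0 + n - 1])
            for i in range(i0 + 1, i0 + n - 1):
                acc += A[i]
            v_start += acc * seg_dx[s]
        for t in range(nterm):
            v_start += term_c[t] * term_Pc[t]

        for step in range(nsteps):
            # ---- predictor (forward differences) ----
            for s in range(nseg):
                i0 = seg_first[s]
                n = seg_n[s]
                lam_t = dt / seg_dx[s]
                for i in range(i0, i0 + n - 1):
                    fr_i = Q[i] * Q[i] / A[i]
                    fr_ip = Q[i + 1] * Q[i + 1] / A[i + 1]
                    As[i] = A[i] - lam_t * (Q[i + 1] - Q[i])
                    Qs[i] = (
                        Q[i]
                        - lam_t * (fr_ip - fr_i)
                        - lam_t * (A[i] / rho) * (P[i + 1] - P[i])
                        - dt * kf * np.pi * nu * Q[i] / A[i]
                    )
                i_last = i0 + n - 1
                As[i_last] = A[i_last]
                Qs[i_last] = Q[i_last]
            for i in range(nnode):
                if As[i] <= 0.0 or not np.isfinite(As[i]):
                    return (P_rec, Q_rec, root_P, cycle, 0, ERR_NAN,
                            vol_in, vol_out, d_storage, term_Pc)
                Ps[i] = _pressure(As[i], Aref[i], Dsi[i], bcoef[i], Pref)

            # ---- corrector (backward differences on predicted state) ----
            for s in range(nseg):
                i0 = seg_first[s]
                n = seg_n[s]
                lam_t = dt / seg_dx[s]
                for i in range(i0 + 1, i0 + n - 1):
                    fr_i = Qs[i] * Qs[i] / As[i]
                    fr_im = Qs[i - 1] * Qs[i - 1] / As[i - 1]
                    An[i] = 0.5 * (A[i] + As[i] - lam_t * (Qs[i] - Qs[i - 1]))
                    Qn[i] = 0.5 * (
                        Q[i]
                        + Qs[i]
                        - lam_t * (fr_i - fr_im)
                        - lam_t * (As[i] / rho) * (Ps[i] - Ps[i - 1])
                        - dt * kf * np.pi * nu * Qs[i] / As[i]
                    )

            # ---- root inlet: prescribed Q, backward characteristic ----
            i0 = seg_first[0]
            u_f, P_f, rc = _char_foot(
                A, Q, P, i0, i0 + 1, seg_dx[0], dt, Aref, dAref_dx, Dsi,
                bcoef, rho, nu, kf, -1,
            )
            q_new = qin[(step + 1) % nsteps]
            # u(A) = u_f + (P(A) - P_f)/rc with u = Q/A: Newton on A
            a_cur = A[i0]
            ok = False
            for _ in range(40):
                p_a = _pressure(a_cur, Aref[i0], Dsi[i0], bcoef[i0], Pref)
                g = q_new / a_cur - u_f - (p_a - P_f) / rc
                gp = (
                    -q_new / (a_cur * a_cur)
                    - _dpda(a_cur, Aref[i0], Dsi[i0], bcoef[i0]) / rc
                )
                da = g / gp
                a_cur -= da
                if a_cur <= 0.0 or not np.isfinite(a_cur):
                    return (P_rec, Q_rec, root_P, cycle, 0, ERR_NEWTON,
                            vol_in, vol_out, d_storage, term_Pc)
                if abs(da) < 1e-12 * Aref[i0]:
                    ok = True
                    break
            if not ok:
                return (P_rec, Q_rec, root_P, cycle, 0, ERR_NEWTON,
                        vol_in, vol_out, d_storage, term_Pc)
            An[i0] = a_cur
            Qn[i0] = q_new

            # ---- Windkessel terminals ----
            for t in range(nterm):
                ib = term_node[t]
                sb = _seg_of(seg_first, seg_n, ib)
                u_f, P_f, rc = _char_foot(
                    A, Q, P, ib, ib - 1, seg_dx[sb], dt, Aref, dAref_dx,
                    Dsi, bcoef, rho, nu, kf, 1,
                )
                r1 = term_r1[t]
                r2 = term_r2[t]
                cwk = term_c[t]
                pout = term_pout[t]
                pc = term_Pc[t]
                denom = 1.0 + dt / (r2 * cwk)
                dpc_dq = (dt / cwk) / denom
                a_cur = A[ib]
                ok = False
                for _ in range(40):
                    p_a = _pressure(a_cur, Aref[ib], Dsi[ib], bcoef[ib], Pref)
                    dpda = _dpda(a_cur, Aref[ib], Dsi[ib], bcoef[ib])
                    u_b = u_f - (p_a - P_f) / rc
                    q_b = a_cur * u_b
                    pc_new = (pc + (dt / cwk) * (q_b + pout / r2)) / denom
                    g = p_a - r1 * q_b - pc_new
                    dq_da = u_b - a_cur * dpda / rc
                    gp = dpda - (r1 + dpc_dq) * dq_da
                    da = g / gp
                    a_cur -= da
                    if a_cur <= 0.0 or not np.isfinite(a_cur):
                        return (P_rec, Q_rec, root_P, cycle, 0, ERR_NEWTON,
                                vol_in, vol_out, d_storage, term_Pc)
                    if abs(da) < 1e-12 * Aref[ib]:
                        ok = True
                        break
                if not ok:
                    return (P_rec, Q_rec, root_P, cycle, 0, ERR_NEWTON,
                            vol_in, vol_out, d_storage, term_Pc)
                p_a = _pressure(a_cur, Aref[ib], Dsi[ib], bcoef[ib], Pref)
                u_b = u_f - (p_a - P_f) / rc
                q_b = a_cur * u_b
                term_Pc[t] = (pc + (dt / cwk) * (q_b + pout / r2)) / denom
                An[ib] = a_cur
                Qn[ib] = q_b
                vol_out += q_b * dt

            # ---- junctions ----
            for j in range(njun):
                ip = jparent_end[j]
                k = jnchild[j]
                sp = _seg_of(seg_first, seg_n, ip)
                uf_p, Pf_p, rc_p = _char_foot(
                    A, Q, P, ip, ip - 1, seg_dx[sp], dt, Aref, dAref_dx,
                    Dsi, bcoef, rho, nu, kf, 1,
                )
                uf_c = np.zeros(3)
                Pf_c = np.zeros(3)
                rc_c = np.zeros(3)
                for cidx in range(k):
                    ic = jchild_start[j, cidx]
                    sc = jchild_seg[j, cidx]
                    uf, pf, rc = _char_foot(
                        A, Q, P, ic, ic + 1, seg_dx[sc], dt, Aref, dAref_dx,
                        Dsi, bcoef, rho, nu, kf, -1,
                    )
                    uf_c[cidx] = uf
                    Pf_c[cidx] = pf
                    rc_c[cidx] = rc
                # Newton on [A_p, A_c1..A_ck]
                x[0] = A[ip]
                for cidx in range(k):
                    x[1 + cidx] = A[jchild_start[j, cidx]]
                nunk = k + 1
                ok = False
                for _ in range(40):
                    ap = x[0]
                    pp = _pressure(ap, Aref[ip], Dsi[ip], bcoef[ip], Pref)
                    dpda_p = _dpda(ap, Aref[ip], Dsi[ip], bcoef[ip])
                    up = uf_p - (pp - Pf_p) / rc_p
                    f0 = ap * up
                    for row in range(nunk):
                        for col in range(nunk):
                            M[row, col] = 0.0
                    M[0, 0] = up - ap * dpda_p / rc_p
                    for cidx in range(k):
                        ac = x[1 + cidx]
                        ic = jchild_start[j, cidx]
                        pc_ = _pressure(ac, Aref[ic], Dsi[ic], bcoef[ic], Pref)
                        dpda_c = _dpda(ac, Aref[ic], Dsi[ic], bcoef[ic])
                        uc = uf_c[cidx] + (pc_ - Pf_c[cidx]) / rc_c[cidx]
                        f0 -= ac * uc
                        M[0, 1 + cidx] = -(uc + ac * dpda_c / rc_c[cidx])
                        r[1 + cidx] = -(pp - pc_)
                        M[1 + cidx, 0] = dpda_p
                        M[1 + cidx, 1 + cidx] = -dpda_c
                    r[0] = -f0
                    if not _gauss_solve(M, r, nunk):
                        return (P_rec, Q_rec, root_P, cycle, 0, ERR_NEWTON,
                                vol_in, vol_out, d_storage, term_Pc)
                    maxrel = 0.0
                    for u_i in range(nunk):
                        x[u_i] += r[u_i]
                        if x[u_i] <= 0.0 or not np.isfinite(x[u_i]):
                            return (P_rec, Q_rec, root_P, cycle, 0,
                                    ERR_NEWTON, vol_in, vol_out, d_storage,
                                    term_Pc)
                        rel = abs(r[u_i]) / x[u_i]
                        if rel > maxrel:
                            maxrel = rel
                    if maxrel < 1e-12:
                        ok = True
                        break
                if not ok:
                    return (P_rec, Q_rec, root_P, cycle, 0, ERR_NEWTON,
                            vol_in, vol_out, d_storage, term_Pc)
                ap = x[0]
                pp = _pressure(ap, Aref[ip], Dsi[ip], bcoef[ip], Pref)
                up = uf_p - (pp - Pf_p) / rc_p
                An[ip] = ap
                Qn[ip] = ap * up
                for cidx in range(k):
                    ac = x[1 + cidx]
                    ic = jchild_start[j, cidx]
                    pc_ = _pressure(ac, Aref[ic], Dsi[ic], bcoef[ic], Pref)
                    uc = uf_c[cidx] + (pc_ - Pf_c[cidx]) / rc_c[cidx]
                    An[ic] = ac
                    Qn[ic] = ac * uc

            # ---- commit step ----
            for i in range(nnode):
                A[i] = An[i]
                Q[i] = Qn[i]
                P[i] = _pressure(A[i], Aref[i], Dsi[i], bcoef[i], Pref)

            vol_in += Qn[seg_first[0]] * dt
            root_P[step] = P[seg_first[0]]
            for rr in range(nrec):
                P_rec[rr, step] = P[rec_nodes[rr]]
                Q_rec[rr, step] = Q[rec_nodes[rr]]

        cycles_used = cycle + 1

        for step in range(nsteps):
            if not np.isfinite(root_P[step]):
                return (P_rec, Q_rec, root_P, cycles_used, 0, ERR_NAN,
                        vol_in, vol_out, d_storage, term_Pc)

        v_end = 0.0
        for s in range(nseg):
            i0 = seg_first[s]
            n = seg_n[s]
            acc = 0.5 * (A[i0] + A[i0 + n - 1])
            for i in range(i0 + 1, i0 + n - 1):
                acc += A[i]
            v_end += acc * seg_dx[s]
        for t in range(nterm):
            v_end += term_c[t] * term_Pc[t]
        d_storage = v_end - v_start

        if cycle > 0:
            pmax = root_P[0]
            dmax = 0.0
            for step in range(nsteps):
                if root_P[step] > pmax:
                    pmax = root_P[step]
                d = abs(root_P[step] - root_P_prev[step])
                if d > dmax:
                    dmax = d
            scale = pmax if pmax > 0.0 else 1.0
            if dmax / scale < tol:
                converged = 1
                break
        for step in range(nsteps):
            root_P_prev[step] = root_P[step]

    return (P_rec, Q_rec, root_P, cycles_used, converged, err_code,
            vol_in, vol_out, d_storage, term_Pc)
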