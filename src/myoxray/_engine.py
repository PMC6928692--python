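"""Compiled kernels: strain-dependent rates, spring-network relaxation and
the fixed-step Monte Carlo loop.

Everything here operates on flat numpy arrays; the public modules wrap these
kernels with the typed containers.  Layout conventions:

* ``u_thin`` (F, M) / ``u_thick`` (T, C): axial node displacements from the
  relaxed rest positions ``z0_thin`` (M,) / ``z0_crown`` (C,).  Thin node 0
  is the Z-disc anchor (always 0); the thick chain is anchored to the M-band
  through a bare-zone segment.
* heads are numbered ``hid = t*HPT + crown*HPC + h``; ``head_state`` is 1
  (detached), 2 (weakly attached) or 3 (post-stroke); bound heads carry their
  site in ``head_f``/``head_j`` and occupy ``occ[f, j]``.
* crossbridge strain of a bound head: x = z_crown - z_site (+ d in state 3);
  the spring applies +kappa*strain to the actin node (toward the M-band when
  positive) and the opposite to the crown.

The mechanics re-solve after each event is a residual-driven front of exact
tridiagonal chain solves (block Gauss-Seidel): the crossbridge coupling
(~1.3 pN/nm) is four orders of magnitude softer than the filament segments,
so the front decays within two shells of the event.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# transition codes written to the event log
EV_BIND = 0        # 1 -> 2
EV_UNBIND = 1      # 2 -> 1
EV_STROKE = 2      # 2 -> 3
EV_REVERSE = 3     # 3 -> 2
EV_RELEASE = 4     # 3 -> 1 (ADP release / detachment)


# ---------------------------------------------------------------------------
# rate kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _safe_exp(a):
    if a > 700.0:
        a = 700.0
    elif a < -700.0:
        a = -700.0
    return np.exp(a)


@njit(cache=True)
def rates_bound(state, x, kappa, dGb, dGs, kbind, kadp0, d, delta2,
                cap23, cap32, cap31, kBT):
    """Outgoing rates of a bound head: returns (to-detached, lateral).

    state 2 -> (k21, k23); state 3 -> (k31, k32).  Caps keep the forward
    rates finite; whenever a cap engages, its detailed-balance partner is
    recomputed from the equilibrium constant so kij/kji = exp(-dGij) holds
    for every strain.
    """
    if state == 2:
        k21 = kbind * _safe_exp(dGb)
        dG23 = dGs + kappa * ((x + d) * (x + d) - x * x) / (2.0 * kBT)
        e = _safe_exp(dG23)
        k23 = cap23 / (1.0 + e)
        k32 = k23 * e
        if k32 > cap32:
            k23 = cap32 / e
        return k21, k23
    else:
        s3 = x + d
        if s3 <= 0.0:
            k31 = kadp0 * _safe_exp(-(kappa * delta2 * s3 + kappa * delta2 * delta2 / 2.0) / kBT)
            if k31 > cap31:
                k31 = cap31
        else:
            k31 = kadp0
        dG23 = dGs + kappa * ((x + d) * (x + d) - x * x) / (2.0 * kBT)
        e = _safe_exp(dG23)
        k23 = cap23 / (1.0 + e)
        k32 = k23 * e
        if k32 > cap32:
            k32 = cap32
        return k31, k32


@njit(cache=True)
def _binding_scan(zc, z0_thin, u_row, occ_row, s0, reach,
                  kbind, kappa, kBT, pick_r):
    """Sum of binding rates over free sites within reach of a crown at zc.

    With pick_r < 0 returns (total, -1); with 0 <= pick_r (a rate coordinate
    in [0, total)) returns the selected monomer index.
    """
    M = z0_thin.shape[0]
    j_lo = int(np.floor((zc - reach) / s0)) - 2
    j_hi = int(np.ceil((zc + reach) / s0)) + 2
    if j_lo < 0:
        j_lo = 0
    if j_hi > M - 1:
        j_hi = M - 1
    total = 0.0
    for j in range(j_lo, j_hi + 1):
        if occ_row[j] >= 0:
            continue
        x = zc - (z0_thin[j] + u_row[j])
        if x < -reach or x > reach:
            continue
        w = kbind * _safe_exp(-kappa * x * x / (2.0 * kBT))
        total += w
        if pick_r >= 0.0 and total > pick_r:
            return total, j
    return total, -1


@njit(cache=True)
def _head_rate(hid, head_state, head_f, head_j, head_crown, HPT,
               u_thin, u_thick, z0_thin, z0_crown, occ, head_target,
               s0, reach, kappa, dGb, dGs, kbind, kadp0, d, delta2,
               cap23, cap32, cap31, kBT):
    """Total outgoing rate of one head in the current configuration."""
    t = hid // HPT
    c = head_crown[hid]
    zc = z0_crown[c] + u_thick[t, c]
    st = head_state[hid]
    if st == 1:
        f = head_target[hid]
        total, _ = _binding_scan(zc, z0_thin, u_thin[f], occ[f], s0, reach,
                                 kbind, kappa, kBT, -1.0)
        return total
    f = head_f[hid]
    j = head_j[hid]
    x = zc - (z0_thin[j] + u_thin[f, j])
    ra, rb = rates_bound(st, x, kappa, dGb, dGs, kbind, kadp0, d, delta2,
                         cap23, cap32, cap31, kBT)
    return ra + rb


# ---------------------------------------------------------------------------
# diffraction: coherent per-filament lattice sums on a uniform Z grid
# ---------------------------------------------------------------------------

@njit(cache=True)
def intensity_on_uniform_grid(positions, Z0, dZ, nZ):
    """Incoherent-ensemble meridional intensity sum_f |sum_j e^{2 pi i Z z_fj}|^2
    on the uniform grid Z0 + k*dZ.

    Uses a per-monomer phasor-rotation recurrence (one exp per monomer, one
    complex multiply per grid point) — exact to rounding, ~10x faster than
    evaluating the exponential at every (Z, z) pair.
    """
    n_fil, M = positions.shape
    I = np.zeros(nZ)
    Ar = np.empty(nZ)
    Ai = np.empty(nZ)
    two_pi = 2.0 * np.pi
    for fi in range(n_fil):
        for k in range(nZ):
            Ar[k] = 0.0
            Ai[k] = 0.0
        for j in range(M):
            z = positions[fi, j]
            th0 = two_pi * Z0 * z
            dth = two_pi * dZ * z
            cr = np.cos(th0)
            ci = np.sin(th0)
            wc = np.cos(dth)
            ws = np.sin(dth)
            for k in range(nZ):
                Ar[k] += cr
                Ai[k] += ci
                tr = cr * wc - ci * ws
                ci = cr * ws + ci * wc
                cr = tr
        for k in range(nZ):
            I[k] += Ar[k] * Ar[k] + Ai[k] * Ai[k]
    return I


# ---------------------------------------------------------------------------
# mechanics: exact tridiagonal chain solves with a residual-driven front
# ---------------------------------------------------------------------------

@njit(cache=True)
def _solve_thin_chain(f, u_thin, u_thick, z0_thin, z0_crown,
                      att_count, att_heads, head_state, head_j, head_crown,
                      HPT, ka_seg, kappa, stroke_d, work_b, work_r, work_c):
    """Exact equilibrium of thin chain f holding all other chains fixed.

    Returns the max node displacement change.  Node 0 is fixed at the
    Z-disc; nodes 1..M-1 are free.  work_* are scratch arrays of length M.
    """
    M = z0_thin.shape[0]
    for j in range(1, M):
        work_b[j] = 2.0 * ka_seg if j < M - 1 else ka_seg
        work_r[j] = 0.0
    n_att = att_count[f]
    for a in range(n_att):
        hid = att_heads[f, a]
        j = head_j[hid]
        if j == 0:
            continue  # site on the fixed Z-disc node: force goes to ground
        t = hid // HPT
        c = head_crown[hid]
        shift = stroke_d if head_state[hid] == 3 else 0.0
        work_b[j] += kappa
        work_r[j] += kappa * (z0_crown[c] + u_thick[t, c] - z0_thin[j] + shift)
    # Thomas forward sweep (sub/super diagonals are -ka_seg)
    work_c[1] = -ka_seg / work_b[1]
    work_r[1] = work_r[1] / work_b[1]
    for j in range(2, M):
        m = work_b[j] + ka_seg * work_c[j - 1]
        work_c[j] = -ka_seg / m
        work_r[j] = (work_r[j] + ka_seg * work_r[j - 1]) / m
    dmax = 0.0
    prev = work_r[M - 1]
    dd = abs(prev - u_thin[f, M - 1])
    if dd > dmax:
        dmax = dd
    u_thin[f, M - 1] = prev
    for j in range(M - 2, 0, -1):
        val = work_r[j] - work_c[j] * prev
        dd = abs(val - u_thin[f, j])
        if dd > dmax:
            dmax = dd
        u_thin[f, j] = val
        prev = val
    return dmax


@njit(cache=True)
def _solve_thick_chain(t, u_thin, u_thick, z0_thin, z0_crown,
                       head_state, head_f, head_j, head_crown, HPT,
                       km_seg, k_anchor, titin_k, kappa, stroke_d,
                       work_b, work_r, work_c):
    """Exact equilibrium of thick chain t holding all other chains fixed."""
    C = z0_crown.shape[0]
    for c in range(C):
        nb = 2.0 * km_seg if 0 < c < C - 1 else km_seg
        if c == C - 1:
            nb += k_anchor          # bare-zone link to the fixed M-band
        if c == 0:
            nb += titin_k           # optional titin spring to the Z-disc
        work_b[c] = nb
        work_r[c] = 0.0
    for hid in range(t * HPT, (t + 1) * HPT):
        st = head_state[hid]
        if st < 2:
            continue
        c = head_crown[hid]
        f = head_f[hid]
        j = head_j[hid]
        shift = stroke_d if st == 3 else 0.0
        work_b[c] += kappa
        work_r[c] += kappa * (z0_thin[j] + u_thin[f, j] - z0_crown[c] - shift)
    work_c[0] = -km_seg / work_b[0]
    work_r[0] = work_r[0] / work_b[0]
    for c in range(1, C):
        m = work_b[c] + km_seg * work_c[c - 1]
        work_c[c] = -km_seg / m
        work_r[c] = (work_r[c] + km_seg * work_r[c - 1]) / m
    dmax = 0.0
    prev = work_r[C - 1]
    dd = abs(prev - u_thick[t, C - 1])
    if dd > dmax:
        dmax = dd
    u_thick[t, C - 1] = prev
    for c in range(C - 2, -1, -1):
        val = work_r[c] - work_c[c] * prev
        dd = abs(val - u_thick[t, c])
        if dd > dmax:
            dmax = dd
        u_thick[t, c] = val
        prev = val
    return dmax


@njit(cache=True)
def _relax_front(init_chains, n_init,
                 u_thin, u_thick, z0_thin, z0_crown,
                 att_count, att_heads, head_state, head_f, head_j, head_crown,
                 HPT, ka_seg, km_seg, k_anchor, titin_k, kappa, stroke_d,
                 stack, in_stack, moved_acc, touched,
                 d_act, max_pops,
                 work_b, work_r, work_c):
    """Relax chains starting from ``init_chains`` until every chain whose
    neighbours moved more than ``d_act`` has been re-solved.

    Chain ids: thin f in [0, F); thick t as F + t.  Returns (n_touched, ok);
    ``touched[:n_touched]`` lists chains visited (with accumulated movement
    in ``moved_acc``) so the caller can refresh rate caches and reset state.
    """
    F = u_thin.shape[0]
    top = 0
    n_touched = 0
    for i in range(n_init):
        ch = init_chains[i]
        if in_stack[ch] == 0:
            in_stack[ch] = 1
            stack[top] = ch
            top += 1
    pops = 0
    while top > 0:
        pops += 1
        if pops > max_pops:
            return n_touched, False
        top -= 1
        ch = stack[top]
        in_stack[ch] = 0
        if moved_acc[ch] == 0.0:
            touched[n_touched] = ch
            n_touched += 1
            moved_acc[ch] = 1e-300   # mark as visited
        if ch < F:
            dmax = _solve_thin_chain(ch, u_thin, u_thick, z0_thin, z0_crown,
                                     att_count, att_heads, head_state, head_j,
                                     head_crown, HPT, ka_seg, kappa, stroke_d,
                                     work_b, work_r, work_c)
            moved_acc[ch] += dmax
            if dmax > d_act:
                for a in range(att_count[ch]):
                    hid = att_heads[ch, a]
                    nb = F + hid // HPT
                    if in_stack[nb] == 0:
                        in_stack[nb] = 1
                        stack[top] = nb
                        top += 1
        else:
            t = ch - F
            dmax = _solve_thick_chain(t, u_thin, u_thick, z0_thin, z0_crown,
                                      head_state, head_f, head_j, head_crown,
                                      HPT, km_seg, k_anchor, titin_k, kappa,
                                      stroke_d, work_b, work_r, work_c)
            moved_acc[ch] += dmax
            if dmax > d_act:
                for hid in range(t * HPT, (t + 1) * HPT):
                    if head_state[hid] >= 2:
                        nb = head_f[hid]
                        if in_stack[nb] == 0:
                            in_stack[nb] = 1
                            stack[top] = nb
                            top += 1
    return n_touched, True


@njit(cache=True)
def _relax_rounds(u_thin, u_thick, z0_thin, z0_crown,
                  att_count, att_heads, head_state, head_f, head_j, head_crown,
                  HPT, ka_seg, km_seg, k_anchor, titin_k, kappa, stroke_d,
                  d_act, max_rounds, work_b, work_r, work_c):
    """Global Gauss-Seidel polish: ordered sweeps of exact chain solves
    until a whole round moves no node by more than ``d_act``.

    Exact per-chain solves make each round a block Gauss-Seidel iteration of
    an SPD system, so the sweep contracts geometrically; the aggregate
    thin<->thick force-exchange mode sets the contraction factor, hence the
    round-based (not stack-based) ordering.
    """
    F = u_thin.shape[0]
    T = u_thick.shape[0]
    for r in range(max_rounds):
        maxmove = 0.0
        for f in range(F):
            dm = _solve_thin_chain(f, u_thin, u_thick, z0_thin, z0_crown,
                                   att_count, att_heads, head_state, head_j,
                                   head_crown, HPT, ka_seg, kappa, stroke_d,
                                   work_b, work_r, work_c)
            if dm > maxmove:
                maxmove = dm
        for t in range(T):
            dm = _solve_thick_chain(t, u_thin, u_thick, z0_thin, z0_crown,
                                    head_state, head_f, head_j, head_crown,
                                    HPT, km_seg, k_anchor, titin_k, kappa,
                                    stroke_d, work_b, work_r, work_c)
            if dm > maxmove:
                maxmove = dm
        if maxmove <= d_act:
            return True
    return False


@njit(cache=True)
def relax_all(u_thin, u_thick, z0_thin, z0_crown,
              att_count, att_heads, head_state, head_f, head_j, head_crown,
              HPT, ka_seg, km_seg, k_anchor, titin_k, kappa, stroke_d,
              d_act, max_rounds):
    """Full equilibrium solve (used by the public API and the in-run
    polish).  Returns True on convergence."""
    M = z0_thin.shape[0]
    C = z0_crown.shape[0]
    nw = max(M, C)
    work_b = np.empty(nw, dtype=np.float64)
    work_r = np.empty(nw, dtype=np.float64)
    work_c = np.empty(nw, dtype=np.float64)
    return _relax_rounds(u_thin, u_thick, z0_thin, z0_crown,
                         att_count, att_heads, head_state, head_f, head_j,
                         head_crown, HPT, ka_seg, km_seg, k_anchor, titin_k,
                         kappa, stroke_d, d_act, max_rounds,
                         work_b, work_r, work_c)


# ---------------------------------------------------------------------------
# main Monte Carlo loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_mc(seed, n_steps, dt,
           # geometry / wiring
           z0_thin, z0_crown, head_target, head_crown, heads_of_thin_idx,
           heads_of_thin, HPT,
           # elastic
           ka_seg, km_seg, k_anchor, titin_k, kappa,
           # rates
           dGb, dGs, kbind, kadp0, stroke_d, delta2, cap23, cap32, cap31, kBT,
           reach, s0,
           # numerics
           d_act, d_act_mid, d_act_local, dx_refresh, polish_every, max_pops,
           max_rounds,
           # initial state (mutated in place)
           u_thin, u_thick, head_state, head_f, head_j, occ,
           att_count, att_heads, att_slot,
           # recording
           record_every, snap_start, snap_every,
           rec_t, rec_fthin, rec_n2, rec_n3, rec_xbF, rec_xbN,
           snap_t, snaps,
           events, max_events):
    """Fixed-step Monte Carlo with event-driven mechanics.

    Each 1 us step the number of transitions is drawn from the aggregate
    rate (rates frozen at the step start, first-order probabilities), the
    firing heads are chosen proportionally to their rates, all transitions
    are applied atomically, and the spring network is re-equilibrated only
    if something fired.  The per-event re-solve is local (front threshold
    ``d_act_local``); every ``polish_every`` steps a global sweep polishes
    the network to ``d_act_mid`` and all rate caches are rebuilt; before a
    record or snapshot (and at the final step) the polish runs to the full
    ``d_act``, so every reported configuration satisfies the force-balance
    tolerance.  Returns (n_events, status) with status 0 = ok,
    1 = mechanics non-convergence, 2 = event log overflow (simulation still
    completes; the log is truncated).
    """
    np.random.seed(seed)
    F = u_thin.shape[0]
    T = u_thick.shape[0]
    M = z0_thin.shape[0]
    C = z0_crown.shape[0]
    Nh = head_state.shape[0]
    n_ch = F + T

    rate = np.zeros(Nh, dtype=np.float64)
    for hid in range(Nh):
        rate[hid] = _head_rate(hid, head_state, head_f, head_j, head_crown,
                               HPT, u_thin, u_thick, z0_thin, z0_crown, occ,
                               head_target, s0, reach, kappa, dGb, dGs, kbind,
                               kadp0, stroke_d, delta2, cap23, cap32, cap31, kBT)
    R_tot = rate.sum()

    stack = np.empty(n_ch, dtype=np.int64)
    in_stack = np.zeros(n_ch, dtype=np.uint8)
    moved_acc = np.zeros(n_ch, dtype=np.float64)
    touched = np.empty(n_ch, dtype=np.int64)
    init_chains = np.empty(2 * Nh + 8, dtype=np.int64)
    nw = max(M, C)
    work_b = np.empty(nw, dtype=np.float64)
    work_r = np.empty(nw, dtype=np.float64)
    work_c = np.empty(nw, dtype=np.float64)
    head_dirty = np.zeros(Nh, dtype=np.uint8)
    dirty_list = np.empty(Nh, dtype=np.int64)
    fired = np.zeros(Nh, dtype=np.uint8)
    fired_list = np.empty(Nh, dtype=np.int64)

    n_events = 0
    status = 0
    n_rec = 0
    n_snap = 0
    overflow = False
    dirty_mid = False      # events since the last polish of any level
    dirty_tight = False    # events since the last full-tolerance polish

    for step in range(n_steps):
        lam = R_tot * dt
        K = 0
        if lam > 0.0:
            # Knuth Poisson sampler (lam is O(0.3))
            L = np.exp(-lam)
            p = np.random.random()
            while p > L:
                K += 1
                p *= np.random.random()
        if K > 0:
            n_init = 0
            n_fired = 0
            for _ev in range(K):
                r = np.random.random() * R_tot
                acc = 0.0
                pick = -1
                for hid in range(Nh):
                    acc += rate[hid]
                    if acc > r:
                        pick = hid
                        break
                if pick < 0:
                    continue
                if fired[pick] == 1:
                    continue
                st = head_state[pick]
                t = pick // HPT
                c = head_crown[pick]
                zc = z0_crown[c] + u_thick[t, c]
                code = -1
                f_ev = -1
                j_ev = -1
                if st == 1:
                    f = head_target[pick]
                    total, _ = _binding_scan(zc, z0_thin, u_thin[f], occ[f],
                                             s0, reach, kbind, kappa, kBT, -1.0)
                    if total <= 0.0:
                        continue
                    r2 = np.random.random() * total
                    _, j = _binding_scan(zc, z0_thin, u_thin[f], occ[f],
                                         s0, reach, kbind, kappa, kBT, r2)
                    if j < 0:
                        continue
                    head_state[pick] = 2
                    head_f[pick] = f
                    head_j[pick] = j
                    occ[f, j] = pick
                    slot = att_count[f]
                    att_heads[f, slot] = pick
                    att_slot[pick] = slot
                    att_count[f] = slot + 1
                    code = EV_BIND
                    f_ev = f
                    j_ev = j
                else:
                    f = head_f[pick]
                    j = head_j[pick]
                    x = zc - (z0_thin[j] + u_thin[f, j])
                    ra, rb = rates_bound(st, x, kappa, dGb, dGs, kbind, kadp0,
                                         stroke_d, delta2, cap23, cap32, cap31, kBT)
                    r2 = np.random.random() * (ra + rb)
                    f_ev = f
                    j_ev = j
                    if st == 2:
                        if r2 < ra:   # unbind
                            head_state[pick] = 1
                            occ[f, j] = -1
                            slot = att_slot[pick]
                            last = att_count[f] - 1
                            moved = att_heads[f, last]
                            att_heads[f, slot] = moved
                            att_slot[moved] = slot
                            att_count[f] = last
                            head_f[pick] = -1
                            head_j[pick] = -1
                            code = EV_UNBIND
                        else:         # power stroke
                            head_state[pick] = 3
                            code = EV_STROKE
                    else:
                        if r2 < ra:   # ADP release -> detached
                            head_state[pick] = 1
                            occ[f, j] = -1
                            slot = att_slot[pick]
                            last = att_count[f] - 1
                            moved = att_heads[f, last]
                            att_heads[f, slot] = moved
                            att_slot[moved] = slot
                            att_count[f] = last
                            head_f[pick] = -1
                            head_j[pick] = -1
                            code = EV_RELEASE
                        else:         # stroke reversal
                            head_state[pick] = 2
                            code = EV_REVERSE
                    # occupancy changed or state changed on chain f / thick t
                fired[pick] = 1
                fired_list[n_fired] = pick
                n_fired += 1
                init_chains[n_init] = f_ev
                init_chains[n_init + 1] = F + t
                n_init += 2
                if n_events < max_events:
                    events[n_events, 0] = step
                    events[n_events, 1] = pick
                    events[n_events, 2] = code
                    events[n_events, 3] = f_ev
                    events[n_events, 4] = j_ev
                    n_events += 1
                else:
                    overflow = True
            if n_init > 0:
                dirty_mid = True
                dirty_tight = True
                n_t, ok = _relax_front(init_chains, n_init,
                                       u_thin, u_thick, z0_thin, z0_crown,
                                       att_count, att_heads, head_state,
                                       head_f, head_j, head_crown, HPT,
                                       ka_seg, km_seg, k_anchor, titin_k,
                                       kappa, stroke_d,
                                       stack, in_stack, moved_acc, touched,
                                       d_act_local, max_pops,
                                       work_b, work_r, work_c)
                if not ok:
                    status = 1
                    return n_events, status
                # refresh rate caches: heads on chains that moved appreciably
                # plus every head able to bind a filament whose occupancy
                # changed (the event chains are always in the touched set)
                n_dirty = 0
                for i in range(n_t):
                    ch = touched[i]
                    big = moved_acc[ch] > dx_refresh
                    moved_acc[ch] = 0.0
                    if ch < F:
                        ff = ch
                        ev_chain = False
                        for k in range(n_init):
                            if init_chains[k] == ch:
                                ev_chain = True
                                break
                        if big or ev_chain:
                            for p in range(heads_of_thin_idx[ff], heads_of_thin_idx[ff + 1]):
                                hid = heads_of_thin[p]
                                if head_dirty[hid] == 0:
                                    head_dirty[hid] = 1
                                    dirty_list[n_dirty] = hid
                                    n_dirty += 1
                    else:
                        if big:
                            tt = ch - F
                            for hid in range(tt * HPT, (tt + 1) * HPT):
                                if head_dirty[hid] == 0:
                                    head_dirty[hid] = 1
                                    dirty_list[n_dirty] = hid
                                    n_dirty += 1
                for i in range(n_fired):
                    hid = fired_list[i]
                    if head_dirty[hid] == 0:
                        head_dirty[hid] = 1
                        dirty_list[n_dirty] = hid
                        n_dirty += 1
                for i in range(n_dirty):
                    hid = dirty_list[i]
                    head_dirty[hid] = 0
                    old = rate[hid]
                    new = _head_rate(hid, head_state, head_f, head_j,
                                     head_crown, HPT, u_thin, u_thick,
                                     z0_thin, z0_crown, occ, head_target,
                                     s0, reach, kappa, dGb, dGs, kbind, kadp0,
                                     stroke_d, delta2, cap23, cap32, cap31, kBT)
                    rate[hid] = new
                    R_tot += new - old
                for i in range(n_fired):
                    fired[fired_list[i]] = 0

        s1 = step + 1
        want_record = record_every > 0 and s1 % record_every == 0 and n_rec < rec_t.shape[0]
        want_snap = (snap_every > 0 and s1 >= snap_start
                     and (s1 - snap_start) % snap_every == 0
                     and n_snap < snap_t.shape[0])
        want_tight = dirty_tight and (want_record or want_snap or s1 == n_steps)
        want_mid = dirty_mid and polish_every > 0 and s1 % polish_every == 0
        if want_tight or want_mid:
            thr = d_act if want_tight else d_act_mid
            ok = _relax_rounds(u_thin, u_thick, z0_thin, z0_crown,
                               att_count, att_heads, head_state, head_f,
                               head_j, head_crown, HPT, ka_seg, km_seg,
                               k_anchor, titin_k, kappa, stroke_d,
                               thr, max_rounds, work_b, work_r, work_c)
            if not ok:
                status = 1
                return n_events, status
            R_tot = 0.0
            for hid in range(Nh):
                rate[hid] = _head_rate(hid, head_state, head_f, head_j,
                                       head_crown, HPT, u_thin, u_thick,
                                       z0_thin, z0_crown, occ, head_target,
                                       s0, reach, kappa, dGb, dGs, kbind,
                                       kadp0, stroke_d, delta2, cap23, cap32,
                                       cap31, kBT)
                R_tot += rate[hid]
            dirty_mid = False
            if want_tight:
                dirty_tight = False
        if record_every > 0 and s1 % record_every == 0 and n_rec < rec_t.shape[0]:
            rec_t[n_rec] = s1 * dt
            for f in range(F):
                rec_fthin[n_rec, f] = ka_seg * u_thin[f, 1]
            xbF = 0.0
            xbN = 0
            for t in range(T):
                n2 = 0
                n3 = 0
                for hid in range(t * HPT, (t + 1) * HPT):
                    st = head_state[hid]
                    if st >= 2:
                        c = head_crown[hid]
                        f = head_f[hid]
                        j = head_j[hid]
                        x = (z0_crown[c] + u_thick[t, c]) - (z0_thin[j] + u_thin[f, j])
                        if st == 2:
                            n2 += 1
                            xbF += kappa * x
                        else:
                            n3 += 1
                            xbF += kappa * (x + stroke_d)
                        xbN += 1
                rec_n2[n_rec, t] = n2
                rec_n3[n_rec, t] = n3
            rec_xbF[n_rec] = xbF
            rec_xbN[n_rec] = xbN
            n_rec += 1
        if snap_every > 0 and s1 >= snap_start and (s1 - snap_start) % snap_every == 0 \
                and n_snap < snap_t.shape[0]:
            snap_t[n_snap] = s1 * dt
            for f in range(F):
                for j in range(M):
                    snaps[n_snap, f, j] = z0_thin[j] + u_thin[f, j]
            n_snap += 1

    if overflow:
        status = 2
    return n_events, status
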