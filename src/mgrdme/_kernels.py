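"""Numba kernels for the Gillespie SSA and the Brownian-dynamics stepper.

These are performance back-ends; the readable reference implementations of
the event table and of a single BD step live in :mod:`mgrdme.ssa` and
:mod:`mgrdme.brownian` and are cross-checked against the kernels in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event-count slots shared between the kernel and ssa.Trajectory
EV_PRODUCE = 0
EV_CONVERT = 1
EV_DEGRADE = 2
EV_DIFF_A = 3
EV_DIFF_B = 4
N_EVENT_KINDS = 5


@njit(cache=True)
def _poisson_small(rng, mu):
    """Knuth Poisson sampler; adequate for the small means used per BD step."""
    if mu <= 0.0:
        return 0
    limit = np.exp(-mu)
    k = 0
    p = rng.random()
    while p > limit:
        k += 1
        p *= rng.random()
    return k


@njit(cache=True)
def ssa_kernel(
    n,
    m,
    t0,
    t_end,
    burn_in,
    k1,
    k2_eff,
    k3,
    d_A,
    d_B,
    w_indptr,
    w_rows,
    w_vals,
    order2,
    rec_times,
    rec_n,
    rec_m,
    sum_n,
    sum_n2,
    sum_m,
    sum_m2,
    counts,
    rng,
):
    """Direct-method SSA on the dual lattice.

    ``k2_eff`` is the conversion rate k2 for the first-order network and
    k2/h_A for the dimerization network (applied to n_j (n_j - 1)).
    ``rec_times`` must be increasing and lie in (t0, t_end]; the state in
    force at each recording time is written to ``rec_n`` / ``rec_m``.
    Time-weighted first and second moments over [burn_in, t_end] are
    accumulated into ``sum_n`` .. ``sum_m2``.  Returns the final time.
    """
    K_A = n.size
    K_B = m.size
    nA_tot = 0
    for j in range(K_A):
        nA_tot += n[j]
    mB_tot = 0
    for i in range(K_B):
        mB_tot += m[i]
    q2 = 0  # sum of n_j (n_j - 1), maintained incrementally for order2
    if order2:
        for j in range(K_A):
            q2 += n[j] * (n[j] - 1)

    t = t0
    rec_idx = 0
    n_rec = rec_times.size

    while t < t_end:
        if order2:
            conv_tot = k2_eff * q2
        else:
            conv_tot = k2_eff * nA_tot
        diffA_tot = d_A * (2.0 * nA_tot - n[0] - n[K_A - 1])
        diffB_tot = d_B * (2.0 * mB_tot - m[0] - m[K_B - 1])
        total = k1 + diffA_tot + diffB_tot + conv_tot + k3 * mB_tot

        if total <= 0.0:
            t_new = t_end
        else:
            u = rng.random()
            while u <= 0.0:
                u = rng.random()
            t_new = t + (-np.log(u) / total)

        # accumulate time-weighted moments over [t, min(t_new, t_end))
        seg_hi = t_new if t_new < t_end else t_end
        seg_lo = t if t > burn_in else burn_in
        if seg_hi > seg_lo:
            w = seg_hi - seg_lo
            for j in range(K_A):
                sum_n[j] += w * n[j]
                sum_n2[j] += w * n[j] * n[j]
            for i in range(K_B):
                sum_m[i] += w * m[i]
                sum_m2[i] += w * m[i] * m[i]
        while rec_idx < n_rec and rec_times[rec_idx] <= seg_hi:
            for j in range(K_A):
                rec_n[rec_idx, j] = n[j]
            for i in range(K_B):
                rec_m[rec_idx, i] = m[i]
            rec_idx += 1

        if total <= 0.0 or t_new >= t_end:
            t = t_end
            break
        t = t_new

        # select and fire the event
        r = rng.random() * total
        if r < k1:
            n[0] += 1
            nA_tot += 1
            if order2:
                q2 += 2 * n[0] - 2
            counts[EV_PRODUCE] += 1
            continue
        r -= k1

        if r < diffA_tot:
            fired = False
            for j in range(K_A):
                if n[j] == 0:
                    continue
                rate = d_A * n[j]
                if j > 0:  # jump left
                    if r < rate:
                        n[j] -= 1
                        n[j - 1] += 1
                        fired = True
                        counts[EV_DIFF_A] += 1
                        break
                    r -= rate
                if j < K_A - 1:  # jump right
                    if r < rate:
                        n[j] -= 1
                        n[j + 1] += 1
                        fired = True
                        counts[EV_DIFF_A] += 1
                        break
                    r -= rate
            if not fired:
                # numerical fall-through: fire a jump from the last occupied
                for j in range(K_A - 1, -1, -1):
                    if n[j] > 0:
                        n[j] -= 1
                        n[j - 1 if j > 0 else j + 1] += 1
                        counts[EV_DIFF_A] += 1
                        break
            if order2:
                q2 = 0
                for j in range(K_A):
                    q2 += n[j] * (n[j] - 1)
            continue
        r -= diffA_tot

        if r < conv_tot:
            j_sel = -1
            for j in range(K_A):
                if order2:
                    block = k2_eff * n[j] * (n[j] - 1)
                else:
                    block = k2_eff * n[j]
                if r < block:
                    j_sel = j
                    break
                r -= block
            if j_sel < 0:
                # numerical fall-through: last compartment with positive weight
                for j in range(K_A - 1, -1, -1):
                    if (order2 and n[j] >= 2) or ((not order2) and n[j] >= 1):
                        j_sel = j
                        break
            # pick the target B-compartment from the overlap weights
            if order2:
                denom = k2_eff * n[j_sel] * (n[j_sel] - 1)
            else:
                denom = k2_eff * n[j_sel]
            u2 = r / denom if denom > 0.0 else rng.random()
            i_sel = w_rows[w_indptr[j_sel + 1] - 1]
            acc = 0.0
            for p in range(w_indptr[j_sel], w_indptr[j_sel + 1]):
                acc += w_vals[p]
                if u2 < acc:
                    i_sel = w_rows[p]
                    break
            if order2:
                q2 -= n[j_sel] * (n[j_sel] - 1)
                n[j_sel] -= 2
                nA_tot -= 2
                q2 += n[j_sel] * (n[j_sel] - 1)
            else:
                n[j_sel] -= 1
                nA_tot -= 1
            m[i_sel] += 1
            mB_tot += 1
            counts[EV_CONVERT] += 1
            continue
        r -= conv_tot

        if r < diffB_tot:
            fired = False
            for i in range(K_B):
                if m[i] == 0:
                    continue
                rate = d_B * m[i]
                if i > 0:
                    if r < rate:
                        m[i] -= 1
                        m[i - 1] += 1
                        fired = True
                        counts[EV_DIFF_B] += 1
                        break
                    r -= rate
                if i < K_B - 1:
                    if r < rate:
                        m[i] -= 1
                        m[i + 1] += 1
                        fired = True
                        counts[EV_DIFF_B] += 1
                        break
                    r -= rate
            if not fired:
                for i in range(K_B - 1, -1, -1):
                    if m[i] > 0:
                        m[i] -= 1
                        m[i - 1 if i > 0 else i + 1] += 1
                        counts[EV_DIFF_B] += 1
                        break
            continue
        r -= diffB_tot

        # degradation of B
        i_sel = K_B - 1
        for i in range(K_B):
            block = k3 * m[i]
            if r < block:
                i_sel = i
                break
            r -= block
        if m[i_sel] == 0:
            # numerical fall-through onto an empty compartment: pick any
            # occupied one (total propensity guaranteed mB_tot > 0 here)
            for i in range(K_B):
                if m[i] > 0:
                    i_sel = i
                    break
        m[i_sel] -= 1
        mB_tot -= 1
        counts[EV_DEGRADE] += 1

    return t


@njit(cache=True)
def _reflect(x, L):
    # fold a position back into [0, L] (triangle map, period 2L)
    while x < 0.0 or x > L:
        if x < 0.0:
            x = -x
        if x > L:
            x = 2.0 * L - x
    return x


@njit(cache=True)
def bd_kernel(
    xA_init,
    xB_init,
    L,
    D_A,
    D_B,
    k1,
    k2,
    k3,
    lam,
    rho,
    first_order,
    dt,
    n_steps,
    burn_steps,
    source_at_origin,
    source_width,
    product_midpoint,
    K_A,
    K_B,
    n_batches,
    batch_histA,
    batch_histB,
    batch_totA,
    batch_totB,
    batch_steps,
    rng,
):
    """Fixed-timestep Brownian dynamics with Doi-model dimerization.

    Per step: Gaussian displacements reflected at 0 and L; Poisson(k1 dt)
    production at the source; conversion (first-order) or pairwise Doi
    firing within radius rho (dimerization); exponential B removal.  After
    ``burn_steps`` the per-compartment occupancies and totals are
    accumulated into per-batch sums for batch-means standard errors.
    Returns the final particle positions ``(xA, xB)``.
    """
    capA = max(4 * (xA_init.size + 16), 1024)
    capB = max(4 * (xB_init.size + 16), 1024)
    xA = np.empty(capA)
    xB = np.empty(capB)
    nA = xA_init.size
    nB = xB_init.size
    xA[:nA] = xA_init
    xB[:nB] = xB_init

    sdA = np.sqrt(2.0 * D_A * dt)
    sdB = np.sqrt(2.0 * D_B * dt)
    p_conv = 1.0 - np.exp(-k2 * dt)
    p_doi = 1.0 - np.exp(-lam * dt)
    p_degr = 1.0 - np.exp(-k3 * dt)
    hA_bin = L / K_A
    hB_bin = L / K_B

    for step in range(n_steps):
        # (i) diffusion with reflection
        for p in range(nA):
            xA[p] = _reflect(xA[p] + sdA * rng.standard_normal(), L)
        for p in range(nB):
            xB[p] = _reflect(xB[p] + sdB * rng.standard_normal(), L)

        # (ii) production of A at the source
        n_new = _poisson_small(rng, k1 * dt)
        for _ in range(n_new):
            if nA >= capA:
                capA *= 2
                tmp = np.empty(capA)
                tmp[:nA] = xA[:nA]
                xA = tmp
            if source_at_origin:
                xA[nA] = 0.0
            else:
                xA[nA] = source_width * rng.random()
            nA += 1

        # (iii) reaction
        if first_order:
            keep = 0
            for p in range(nA):
                if rng.random() < p_conv:
                    if nB >= capB:
                        capB *= 2
                        tmp = np.empty(capB)
                        tmp[:nB] = xB[:nB]
                        xB = tmp
                    xB[nB] = xA[p]
                    nB += 1
                else:
                    xA[keep] = xA[p]
                    keep += 1
            nA = keep
        else:
            if nA >= 2:
                xs = np.sort(xA[:nA])
                # candidate pairs by sorted sweep
                max_pairs = 0
                for a in range(nA - 1):
                    b = a + 1
                    while b < nA and xs[b] - xs[a] <= rho:
                        max_pairs += 1
                        b += 1
                if max_pairs > 0:
                    pi_arr = np.empty(max_pairs, dtype=np.int64)
                    pj_arr = np.empty(max_pairs, dtype=np.int64)
                    cnt = 0
                    for a in range(nA - 1):
                        b = a + 1
                        while b < nA and xs[b] - xs[a] <= rho:
                            pi_arr[cnt] = a
                            pj_arr[cnt] = b
                            cnt += 1
                            b += 1
                    # random processing order (Fisher-Yates)
                    for a in range(cnt - 1, 0, -1):
                        b = rng.integers(0, a + 1)
                        pi_arr[a], pi_arr[b] = pi_arr[b], pi_arr[a]
                        pj_arr[a], pj_arr[b] = pj_arr[b], pj_arr[a]
                    alive = np.ones(nA, dtype=np.bool_)
                    for q in range(cnt):
                        a = pi_arr[q]
                        b = pj_arr[q]
                        if alive[a] and alive[b] and rng.random() < p_doi:
                            alive[a] = False
                            alive[b] = False
                            if nB >= capB:
                                capB *= 2
                                tmp = np.empty(capB)
                                tmp[:nB] = xB[:nB]
                                xB = tmp
                            if product_midpoint:
                                xB[nB] = 0.5 * (xs[a] + xs[b])
                            else:
                                xB[nB] = xs[a]
                            nB += 1
                    keep = 0
                    for p in range(nA):
                        if alive[p]:
                            xs[keep] = xs[p]
                            keep += 1
                    nA = keep
                    xA[:nA] = xs[:nA]

        # (iv) degradation of B
        keep = 0
        for p in range(nB):
            if rng.random() >= p_degr:
                xB[keep] = xB[p]
                keep += 1
        nB = keep

        # accumulation after burn-in
        if step >= burn_steps:
            bi = (step - burn_steps) * n_batches // (n_steps - burn_steps)
            for p in range(nA):
                b = int(xA[p] / hA_bin)
                if b >= K_A:
                    b = K_A - 1
                batch_histA[bi, b] += 1.0
            for p in range(nB):
                b = int(xB[p] / hB_bin)
                if b >= K_B:
                    b = K_B - 1
                batch_histB[bi, b] += 1.0
            batch_totA[bi] += nA
            batch_totB[bi] += nB
            batch_steps[bi] += 1

    return xA[:nA].copy(), xB[:nB].copy()
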