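"""Numba-accelerated SSA kernel for the whole-cell model.

The kernel advances the exact stochastic simulation (direct method) over
all reaction channels — transcription, mRNA decay, ribosome binding,
per-site elongation hops, nutrient import, catabolism and growth
dilution — while maintaining every ribosome-bearing transcript as a row
of an occupancy matrix.  Per-lattice hop weights (the sum of codon
efficiencies over unblocked ribosomes, i.e. the transition vector without
the shared ``gamma(a)`` factor) are kept incrementally so each event
costs O(active lattices + transcript length).

State layout (mutated in place):

``counts`` (int64[15])
    0 s_i, 1 a, 2 r_free, 3-7 m_free per class, 8-11 p for ET/EM/Q/H
    (the ribosome count is implicit: ``p_R = r_free + bound``),
    12 cumulative H proteins made, 13 cumulative R proteins made,
    14 bound ribosomes.
``occ`` (int8[CAP, Lmax])
    one row per lattice slot; ``lat_class[r] == -1`` marks a free slot.

Gene classes are indexed R=0, ET=1, EM=2, Q=3, H=4.

Observable rows written to ``obs`` (one per sample time):
    0 t, 1 s_i, 2 a, 3 r_free, 4-8 m_free, 9 p_R, 10-13 p ET/EM/Q/H,
    14 bound, 15 H made, 16 R made, 17 Grate (1/min), 18-22 lattice
    count per class.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NCOL = 23
N_CLASSES = 5

# counts indices
I_SI, I_A, I_RFREE = 0, 1, 2
I_MFREE = 3          # .. 3+4
I_P = 8              # ET, EM, Q, H -> 8..11
I_HPROD, I_RPROD, I_BOUND = 12, 13, 14

STATUS_OK = 0
STATUS_CAPACITY = 1
STATUS_STALLED = 2


@njit(cache=True)
def _row_stats(occ_row, eff_row, L):
    """(hop weight, site-1-free flag) of one lattice row.

    The hop weight sums, over ribosomes whose next site is free, the
    efficiency of the codon being decoded — the site ahead (entry-gating
    convention); the ribosome on the last site contributes the
    termination weight ``eff[L-1]``.
    """
    w = 0.0
    for j in range(L):
        if occ_row[j] == 1:
            if j == L - 1:
                w += eff_row[L - 1]
            elif occ_row[j + 1] == 0:
                w += eff_row[j + 1]
    s1 = 1 if occ_row[0] == 0 else 0
    return w, s1


@njit(cache=True)
def run_segment(counts, occ, lat_class, lat_n, lat_w,
                active, slot, free_stack, meta,
                s1free, nlat,
                w_eff, theta, binit, lengths, eff,
                d_m, K_q, h_q, gamma_max, K_gamma, M_rf,
                imp_per_enzyme, v_m, K_m, n_energy,
                init_on_occupied,
                t_start, sample_times, obs, hocc, seed):
    """Advance the SSA from ``t_start`` past the last sample time.

    ``meta`` = int64[3]: [n_active, n_free, status]; mutated in place.
    Returns the reached time.
    """
    np.random.seed(seed)
    n_active = meta[0]
    n_free = meta[1]
    L_H = lengths[4]
    n_samples = sample_times.shape[0]
    t_end = sample_times[n_samples - 1]
    t = t_start
    si = 0
    # exact refresh of the global hop weight at segment start
    W_total = 0.0
    for k in range(n_active):
        W_total += lat_w[active[k]]
    prop = np.zeros(19)
    events = 0
    while True:
        a = float(counts[I_A])
        g_elong = gamma_max * a / (K_gamma + a)
        grate = g_elong * counts[I_BOUND] / M_rf
        # transcription (0-4)
        for c in range(N_CLASSES):
            r = w_eff[c] * a / (theta[c] + a)
            if c == 3:
                r *= 1.0 / (1.0 + (counts[I_P + 2] / K_q) ** h_q)
            prop[c] = r
        # degradation (5-9)
        for c in range(N_CLASSES):
            prop[5 + c] = d_m * counts[I_MFREE + c]
        # initiation (10-14)
        for c in range(N_CLASSES):
            targets = counts[I_MFREE + c]
            if init_on_occupied == 1:
                targets += s1free[c]
            prop[10 + c] = binit[c] * counts[I_RFREE] * targets
        # elongation hop (15)
        if W_total < 0.0:
            W_total = 0.0
        prop[15] = g_elong * W_total if counts[I_A] >= 1 else 0.0
        # import (16), catabolism (17)
        prop[16] = counts[I_P + 0] * imp_per_enzyme
        si_count = float(counts[I_SI])
        prop[17] = counts[I_P + 1] * v_m * si_count / (K_m + si_count)
        # dilution (18): grouped over all targets
        dil_targets = (counts[I_SI] + counts[I_A] + counts[I_RFREE])
        for c in range(N_CLASSES):
            dil_targets += counts[I_MFREE + c]
        for c in range(4):
            dil_targets += counts[I_P + c]
        dil_targets += n_active
        prop[18] = grate * dil_targets

        total = 0.0
        for k in range(19):
            total += prop[k]
        if total <= 0.0:
            meta[2] = STATUS_STALLED
            break
        dt = -np.log(1.0 - np.random.random()) / total
        t_next = t + dt
        # record samples passed by this jump (state is constant on [t, t_next))
        while si < n_samples and sample_times[si] <= t_next:
            obs[si, 0] = sample_times[si]
            obs[si, 1] = counts[I_SI]
            obs[si, 2] = counts[I_A]
            obs[si, 3] = counts[I_RFREE]
            for c in range(N_CLASSES):
                obs[si, 4 + c] = counts[I_MFREE + c]
            obs[si, 9] = counts[I_RFREE] + counts[I_BOUND]
            for c in range(4):
                obs[si, 10 + c] = counts[I_P + c]
            obs[si, 14] = counts[I_BOUND]
            obs[si, 15] = counts[I_HPROD]
            obs[si, 16] = counts[I_RPROD]
            obs[si, 17] = grate
            for c in range(N_CLASSES):
                obs[si, 18 + c] = nlat[c]
            for k in range(n_active):
                r = active[k]
                if lat_class[r] == 4:
                    for j in range(L_H):
                        hocc[si, j] += occ[r, j]
            si += 1
        if si >= n_samples:
            t = t_end
            break
        t = t_next
        events += 1
        if events % 65536 == 0:
            # periodic exact refresh against float drift
            W_total = 0.0
            for k in range(n_active):
                W_total += lat_w[active[k]]

        # ---- choose and apply one reaction ---------------------------
        u = np.random.random() * total
        ch = 0
        acc = prop[0]
        while acc < u and ch < 18:
            ch += 1
            acc += prop[ch]

        if ch < 5:  # transcription
            counts[I_MFREE + ch] += 1
        elif ch < 10:  # degradation of a free mRNA
            counts[I_MFREE + (ch - 5)] -= 1
        elif ch < 15:  # initiation
            c = ch - 10
            n_elig = counts[I_MFREE + c]
            if init_on_occupied == 1:
                n_elig += s1free[c]
            pick = int(np.random.random() * n_elig)
            if pick >= n_elig:
                pick = n_elig - 1
            if pick < counts[I_MFREE + c]:
                # activate a free mRNA as a new lattice
                if n_free == 0:
                    meta[2] = STATUS_CAPACITY
                    break
                n_free -= 1
                r = free_stack[n_free]
                lat_class[r] = c
                occ[r, 0] = 1
                lat_n[r] = 1
                w, s1 = _row_stats(occ[r], eff[c], lengths[c])
                lat_w[r] = w
                W_total += w
                s1free[c] += s1
                active[n_active] = r
                slot[r] = n_active
                n_active += 1
                nlat[c] += 1
                counts[I_MFREE + c] -= 1
            else:
                # place on the k-th occupied lattice of class c with site 1 free
                k_target = pick - counts[I_MFREE + c]
                r = -1
                seen = 0
                for k in range(n_active):
                    rr = active[k]
                    if lat_class[rr] == c and occ[rr, 0] == 0:
                        if seen == k_target:
                            r = rr
                            break
                        seen += 1
                if r < 0:
                    # bookkeeping said an eligible row exists; scan must find one
                    meta[2] = STATUS_CAPACITY
                    break
                W_total -= lat_w[r]
                s1free[c] -= 1
                occ[r, 0] = 1
                lat_n[r] += 1
                w, s1 = _row_stats(occ[r], eff[c], lengths[c])
                lat_w[r] = w
                W_total += w
                s1free[c] += s1
            counts[I_RFREE] -= 1
            counts[I_BOUND] += 1
        elif ch == 15:  # elongation hop
            target = np.random.random() * W_total
            r = -1
            acc_w = 0.0
            last_pos = -1
            for k in range(n_active):
                rr = active[k]
                if lat_w[rr] > 0.0:
                    last_pos = rr
                    acc_w += lat_w[rr]
                    if acc_w >= target:
                        r = rr
                        break
            if r < 0:
                r = last_pos
            if r < 0:
                # no movable ribosome anywhere (drifted weight); skip
                continue
            c = lat_class[r]
            L = lengths[c]
            # choose the unblocked ribosome within the row
            sub = np.random.random() * lat_w[r]
            jsel = -1
            acc_w = 0.0
            for j in range(L):
                if occ[r, j] == 1 and (j == L - 1 or occ[r, j + 1] == 0):
                    jsel = j
                    acc_w += eff[c, j + 1] if j < L - 1 else eff[c, L - 1]
                    if acc_w >= sub:
                        break
            W_total -= lat_w[r]
            s1free[c] -= 1 if occ[r, 0] == 0 else 0
            counts[I_A] -= 1
            if jsel == L - 1:
                # termination: release ribosome, make one protein
                occ[r, jsel] = 0
                lat_n[r] -= 1
                counts[I_BOUND] -= 1
                counts[I_RFREE] += 1
                if c == 0:
                    counts[I_RFREE] += 1   # the new protein is a ribosome
                    counts[I_RPROD] += 1
                else:
                    counts[I_P + (c - 1)] += 1
                    if c == 4:
                        counts[I_HPROD] += 1
                if lat_n[r] == 0:
                    # lattice emptied: back to the degradable free pool
                    counts[I_MFREE + c] += 1
                    nlat[c] -= 1
                    lat_class[r] = -1
                    lat_w[r] = 0.0
                    free_stack[n_free] = r
                    n_free += 1
                    ks = slot[r]
                    n_active -= 1
                    moved = active[n_active]
                    active[ks] = moved
                    slot[moved] = ks
                    continue
            else:
                occ[r, jsel] = 0
                occ[r, jsel + 1] = 1
            w, s1 = _row_stats(occ[r], eff[c], L)
            lat_w[r] = w
            W_total += w
            s1free[c] += s1
        elif ch == 16:  # nutrient import
            counts[I_SI] += 1
        elif ch == 17:  # catabolism
            counts[I_SI] -= 1
            counts[I_A] += n_energy
        else:  # dilution: pick one target proportional to its count
            u2 = np.random.random() * dil_targets
            if u2 < counts[I_SI]:
                counts[I_SI] -= 1
                continue
            u2 -= counts[I_SI]
            if u2 < counts[I_A]:
                counts[I_A] -= 1
                continue
            u2 -= counts[I_A]
            if u2 < counts[I_RFREE]:
                counts[I_RFREE] -= 1
                continue
            u2 -= counts[I_RFREE]
            done = False
            for c in range(N_CLASSES):
                if u2 < counts[I_MFREE + c]:
                    counts[I_MFREE + c] -= 1
                    done = True
                    break
                u2 -= counts[I_MFREE + c]
            if done:
                continue
            for c in range(4):
                if u2 < counts[I_P + c]:
                    counts[I_P + c] -= 1
                    done = True
                    break
                u2 -= counts[I_P + c]
            if done:
                continue
            if n_active > 0:
                k = int(u2)
                if k >= n_active:
                    k = n_active - 1
                r = active[k]
                c = lat_class[r]
                counts[I_BOUND] -= lat_n[r]
                W_total -= lat_w[r]
                if occ[r, 0] == 0:
                    s1free[c] -= 1
                for j in range(lengths[c]):
                    occ[r, j] = 0
                lat_n[r] = 0
                lat_w[r] = 0.0
                lat_class[r] = -1
                nlat[c] -= 1
                free_stack[n_free] = r
                n_free += 1
                ks = slot[r]
                n_active -= 1
                moved = active[n_active]
                active[ks] = moved
                slot[moved] = ks

    meta[0] = n_active
    meta[1] = n_free
    if meta[2] == STATUS_STALLED and si < n_samples:
        # state is frozen; fill the remaining grid with the final state
        a = float(counts[I_A])
        g_elong = gamma_max * a / (K_gamma + a)
        grate = g_elong * counts[I_BOUND] / M_rf
        while si < n_samples:
            obs[si, 0] = sample_times[si]
            obs[si, 1] = counts[I_SI]
            obs[si, 2] = counts[I_A]
            obs[si, 3] = counts[I_RFREE]
            for c in range(N_CLASSES):
                obs[si, 4 + c] = counts[I_MFREE + c]
            obs[si, 9] = counts[I_RFREE] + counts[I_BOUND]
            for c in range(4):
                obs[si, 10 + c] = counts[I_P + c]
            obs[si, 14] = counts[I_BOUND]
            obs[si, 15] = counts[I_HPROD]
            obs[si, 16] = counts[I_RPROD]
            obs[si, 17] = grate
            for c in range(N_CLASSES):
                obs[si, 18 + c] = nlat[c]
            for k in range(meta[0]):
                r = active[k]
                if lat_class[r] == 4:
                    for j in range(L_H):
                        hocc[si, j] += occ[r, j]
            si += 1
        t = t_end
    return t
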