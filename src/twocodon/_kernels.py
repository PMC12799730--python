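"""Numba cores for the stochastic simulators.

Both kernels implement the direct-method SSA: per event a single pair
of uniforms determines the waiting time and the elementary channel;
where a channel needs a secondary choice (which transcript, which
ribosome) the fractional remainder of the channel draw is reused, so
trajectories are bit-reproducible from the seed alone.

Counts are int64 throughout.  State vector order matches
``core_model.STATE_FIELDS``: (T_c1, T_c2, T_u1, T_u2, R_f, R_b1, R_b2).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def meanfield_kernel(seed, t_max, rec_dt, L, k_charge, k_speed, k_bind_eff,
                     f_op, n_sites, init):
    """Mean-field SSA over ten elementary channels.

    Channels: charging (x2), initiation landing on an optimal /
    non-optimal codon, and for each codon class elongation that
    terminates (prob 1/L), re-lands optimal, or re-lands non-optimal.
    Returns (times, states[n_rec, 7], protein[n_rec]).
    """
    np.random.seed(seed)
    n_rec = int(t_max / rec_dt) + 1
    times = np.empty(n_rec)
    for k in range(n_rec):
        times[k] = k * rec_dt
    states = np.zeros((n_rec, 7), dtype=np.int64)
    protein_rec = np.zeros(n_rec, dtype=np.int64)

    Tc1, Tc2, Tu1, Tu2, Rf, Rb1, Rb2 = (init[0], init[1], init[2], init[3],
                                        init[4], init[5], init[6])
    protein = 0
    t = 0.0
    rec = 0
    inv_L = 1.0 / L
    stay = 1.0 - inv_L
    a = np.empty(10)
    while True:
        e1 = k_speed * Rb1 * Tc1
        e2 = k_speed * Rb2 * Tc2
        binding = k_bind_eff * n_sites * Rf
        a[0] = k_charge * Tu1
        a[1] = k_charge * Tu2
        a[2] = binding * f_op
        a[3] = binding * (1.0 - f_op)
        a[4] = e1 * inv_L
        a[5] = e1 * stay * f_op
        a[6] = e1 * stay * (1.0 - f_op)
        a[7] = e2 * inv_L
        a[8] = e2 * stay * f_op
        a[9] = e2 * stay * (1.0 - f_op)
        atot = (a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7]
                + a[8] + a[9])
        if atot <= 0.0:
            break
        u1 = np.random.random()
        u2 = np.random.random()
        dt = -np.log(u1) / atot
        t_next = t + dt
        while rec < n_rec and times[rec] < t_next:
            states[rec, 0] = Tc1
            states[rec, 1] = Tc2
            states[rec, 2] = Tu1
            states[rec, 3] = Tu2
            states[rec, 4] = Rf
            states[rec, 5] = Rb1
            states[rec, 6] = Rb2
            protein_rec[rec] = protein
            rec += 1
        if t_next > t_max:
            break
        t = t_next
        target = u2 * atot
        cum = 0.0
        ch = 9
        for k in range(10):
            cum += a[k]
            if target < cum:
                ch = k
                break
        if ch == 0:
            Tu1 -= 1
            Tc1 += 1
        elif ch == 1:
            Tu2 -= 1
            Tc2 += 1
        elif ch == 2:
            Rf -= 1
            Rb1 += 1
        elif ch == 3:
            Rf -= 1
            Rb2 += 1
        elif ch == 4:  # elongate on optimal codon, terminate
            Tc1 -= 1
            Tu1 += 1
            Rb1 -= 1
            Rf += 1
            protein += 1
        elif ch == 5:  # elongate optimal, re-land optimal
            Tc1 -= 1
            Tu1 += 1
        elif ch == 6:  # elongate optimal, re-land non-optimal
            Tc1 -= 1
            Tu1 += 1
            Rb1 -= 1
            Rb2 += 1
        elif ch == 7:
            Tc2 -= 1
            Tu2 += 1
            Rb2 -= 1
            Rf += 1
            protein += 1
        elif ch == 8:
            Tc2 -= 1
            Tu2 += 1
            Rb2 -= 1
            Rb1 += 1
        else:
            Tc2 -= 1
            Tu2 += 1
    # flush remaining grid points with the final state
    while rec < n_rec:
        states[rec, 0] = Tc1
        states[rec, 1] = Tc2
        states[rec, 2] = Tu1
        states[rec, 3] = Tu2
        states[rec, 4] = Rf
        states[rec, 5] = Rb1
        states[rec, 6] = Rb2
        protein_rec[rec] = protein
        rec += 1
    return times, states, protein_rec


@njit(cache=True)
def _blocked(occ, tx, pos, footprint, L):
    """True if any anchor occupies [pos, pos+footprint-1] on ``tx``.

    Placing (or moving) an anchor at ``pos`` requires the next anchor
    downstream to be at least ``footprint`` codons away.
    """
    hi = pos + footprint
    if hi > L:
        hi = L
    for q in range(pos, hi):
        if occ[tx, q] >= 0:
            return True
    return False


@njit(cache=True)
def _count_class(rib_cls, cls):
    n = 0
    for i in range(rib_cls.shape[0]):
        if rib_cls[i] == cls:
            n += 1
    return n


@njit(cache=True)
def codon_resolved_kernel(seed, t_max, rec_dt, seqs, k_charge, k_speed,
                          k_bind_eff, footprint, R_tot, init):
    """Codon-resolved SSA: each ribosome tracks transcript and position.

    ``seqs`` is an int8 array (N, L); 1 marks an optimal codon.  The
    elongation propensity of a ribosome is k_speed * T_c(class of its
    codon); termination occurs on stepping past codon L-1.  With
    ``footprint`` > 0, two anchors on one transcript must sit at least
    ``footprint`` codons apart and initiation requires codons
    [0, footprint-1] clear; propensities count only unblocked ribosomes
    and clear transcripts, so the process remains an exact SSA.

    All ribosomes must start free (their positions would otherwise be
    undefined).  Returns (times, states[n_rec, 7], protein[n_rec]);
    the recorded R_b1/R_b2 count all bound ribosomes on optimal /
    non-optimal codons, blocked or not.
    """
    np.random.seed(seed)
    N, L = seqs.shape
    n_rec = int(t_max / rec_dt) + 1
    times = np.empty(n_rec)
    for k in range(n_rec):
        times[k] = k * rec_dt
    states = np.zeros((n_rec, 7), dtype=np.int64)
    protein_rec = np.zeros(n_rec, dtype=np.int64)

    Tc1, Tc2, Tu1, Tu2 = init[0], init[1], init[2], init[3]
    Rf = R_tot
    protein = 0

    rib_tx = np.full(R_tot, -1, dtype=np.int64)
    rib_pos = np.full(R_tot, -1, dtype=np.int64)
    rib_cls = np.full(R_tot, -1, dtype=np.int64)  # 1 optimal, 0 non-optimal
    rib_slot = np.full(R_tot, -1, dtype=np.int64)  # slot in class array
    rib_free = np.empty(R_tot, dtype=np.int64)  # stack of free ribosome ids
    for i in range(R_tot):
        rib_free[i] = i
    n_free = R_tot

    # membership arrays of *unblocked* bound ribosomes per codon class
    mem_opt = np.empty(R_tot, dtype=np.int64)
    mem_non = np.empty(R_tot, dtype=np.int64)
    n_opt = 0
    n_non = 0

    occ = np.full((N, L), -1, dtype=np.int64)  # anchor grid: ribosome id

    # transcripts whose start region is clear (binding possible)
    avail = np.empty(N, dtype=np.int64)
    avail_slot = np.empty(N, dtype=np.int64)
    avail_flag = np.ones(N, dtype=np.int8)
    for j in range(N):
        avail[j] = j
        avail_slot[j] = j
    n_avail = N

    t = 0.0
    rec = 0
    while True:
        e_opt = k_speed * Tc1 * n_opt
        e_non = k_speed * Tc2 * n_non
        if footprint > 0:
            binding = k_bind_eff * n_avail * Rf
        else:
            binding = k_bind_eff * N * Rf
        a0 = k_charge * Tu1
        a1 = k_charge * Tu2
        atot = a0 + a1 + binding + e_opt + e_non
        if atot <= 0.0:
            break
        u1 = np.random.random()
        u2 = np.random.random()
        dt = -np.log(u1) / atot
        t_next = t + dt
        while rec < n_rec and times[rec] < t_next:
            states[rec, 0] = Tc1
            states[rec, 1] = Tc2
            states[rec, 2] = Tu1
            states[rec, 3] = Tu2
            states[rec, 4] = Rf
            states[rec, 5] = _count_class(rib_cls, 1)
            states[rec, 6] = _count_class(rib_cls, 0)
            protein_rec[rec] = protein
            rec += 1
        if t_next > t_max:
            break
        t = t_next
        target = u2 * atot
        if target < a0:
            Tu1 -= 1
            Tc1 += 1
            continue
        target -= a0
        if target < a1:
            Tu2 -= 1
            Tc2 += 1
            continue
        target -= a1
        if target < binding:
            # initiation at codon 0 of a transcript with a clear start
            frac = target / binding
            if footprint > 0:
                idx = int(frac * n_avail)
                if idx >= n_avail:
                    idx = n_avail - 1
                tx = avail[idx]
            else:
                tx = int(frac * N)
                if tx >= N:
                    tx = N - 1
            n_free -= 1
            rib = rib_free[n_free]
            Rf -= 1
            rib_tx[rib] = tx
            rib_pos[rib] = 0
            occ[tx, 0] = rib
            cls = seqs[tx, 0]
            rib_cls[rib] = cls
            if footprint > 0 and _blocked(occ, tx, 1, footprint, L):
                rib_slot[rib] = -1  # blocked: cannot elongate yet
            elif cls == 1:
                mem_opt[n_opt] = rib
                rib_slot[rib] = n_opt
                n_opt += 1
            else:
                mem_non[n_non] = rib
                rib_slot[rib] = n_non
                n_non += 1
            if footprint > 0:
                slot = avail_slot[tx]
                last = avail[n_avail - 1]
                avail[slot] = last
                avail_slot[last] = slot
                avail_flag[tx] = 0
                n_avail -= 1
            continue
        target -= binding
        if target < e_opt:
            frac = target / e_opt
            idx = int(frac * n_opt)
            if idx >= n_opt:
                idx = n_opt - 1
            rib = mem_opt[idx]
            Tc1 -= 1
            Tu1 += 1
        else:
            frac = (target - e_opt) / e_non
            idx = int(frac * n_non)
            if idx >= n_non:
                idx = n_non - 1
            rib = mem_non[idx]
            Tc2 -= 1
            Tu2 += 1
        # --- move ribosome `rib` one codon forward (it is unblocked) ---
        tx = rib_tx[rib]
        p = rib_pos[rib]
        cls = rib_cls[rib]
        slot = rib_slot[rib]
        if cls == 1:
            last = mem_opt[n_opt - 1]
            mem_opt[slot] = last
            rib_slot[last] = slot
            n_opt -= 1
        else:
            last = mem_non[n_non - 1]
            mem_non[slot] = last
            rib_slot[last] = slot
            n_non -= 1
        rib_slot[rib] = -1
        occ[tx, p] = -1
        if p + 1 >= L:
            # termination: free the ribosome, count one protein
            rib_tx[rib] = -1
            rib_pos[rib] = -1
            rib_cls[rib] = -1
            rib_free[n_free] = rib
            n_free += 1
            Rf += 1
            protein += 1
        else:
            pn = p + 1
            rib_pos[rib] = pn
            occ[tx, pn] = rib
            cls = seqs[tx, pn]
            rib_cls[rib] = cls
            if footprint > 0 and _blocked(occ, tx, pn + 1, footprint, L):
                rib_slot[rib] = -1
            elif cls == 1:
                mem_opt[n_opt] = rib
                rib_slot[rib] = n_opt
                n_opt += 1
            else:
                mem_non[n_non] = rib
                rib_slot[rib] = n_non
                n_non += 1
        if footprint > 0:
            # the nearest trailing anchor behind the vacated codon p may
            # have been blocked by it; re-check now
            lo = p - footprint
            if lo < 0:
                lo = 0
            q = p - 1
            while q >= lo:
                r2 = occ[tx, q]
                if r2 >= 0:
                    if (rib_slot[r2] == -1
                            and not _blocked(occ, tx, q + 1, footprint, L)):
                        c2 = rib_cls[r2]
                        if c2 == 1:
                            mem_opt[n_opt] = r2
                            rib_slot[r2] = n_opt
                            n_opt += 1
                        else:
                            mem_non[n_non] = r2
                            rib_slot[r2] = n_non
                            n_non += 1
                    break
                q -= 1
            # the start region may have become clear
            if p < footprint and avail_flag[tx] == 0:
                if not _blocked(occ, tx, 0, footprint, L):
                    avail[n_avail] = tx
                    avail_slot[tx] = n_avail
                    avail_flag[tx] = 1
                    n_avail += 1
    while rec < n_rec:
        states[rec, 0] = Tc1
        states[rec, 1] = Tc2
        states[rec, 2] = Tu1
        states[rec, 3] = Tu2
        states[rec, 4] = Rf
        states[rec, 5] = _count_class(rib_cls, 1)
        states[rec, 6] = _count_class(rib_cls, 0)
        protein_rec[rec] = protein
        rec += 1
    return times, states, protein_rec
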