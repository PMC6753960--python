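"""Compiled inner loops for the contribution/migration annealer.

The plan is held as per-offspring arrays (natal deme, sire, dam, destination
deme); the objective is recomputed from scratch at every step, which at the
study's problem sizes (<= 200 offspring, <= 32 alleles, tens of loci) costs
a few tens of microseconds and keeps the move/undo logic trivial.

Method codes: 0 = maxHT, 1 = maxAT, 2 = maxK.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=False)
def score_kernel(sire, dam, dest, xhalf, het, hom, method, lam, n_dest):
    """Objective value of the plan encoded by (sire, dam, dest).

    xhalf[k, l, a] = allelic dosage of parent k at locus l for allele a,
    divided by 2 (0, 0.5 or 1); het/hom are the corresponding carrier flags.
    """
    P, K, A = xhalf.shape
    D = n_dest.shape[0]
    T = sire.shape[0]
    g = np.zeros((P, D))
    for t in range(T):
        g[sire[t], dest[t]] += 1.0
        g[dam[t], dest[t]] += 1.0

    if method == 0:  # maxHT: D_G + lam * H_S on expected progeny frequencies
        p = np.zeros((D, K, A))
        for k in range(P):
            for d in range(D):
                w = g[k, d]
                if w > 0.0:
                    for l in range(K):
                        for a in range(A):
                            p[d, l, a] += w * xhalf[k, l, a]
        for d in range(D):
            denom = 2.0 * n_dest[d]
            for l in range(K):
                for a in range(A):
                    p[d, l, a] /= denom
        hs = 0.0
        ht = 0.0
        for l in range(K):
            hs_l = 0.0
            for d in range(D):
                s2 = 0.0
                for a in range(A):
                    s2 += p[d, l, a] * p[d, l, a]
                hs_l += 1.0 - s2
            hs_l /= D
            s2b = 0.0
            for a in range(A):
                pb = 0.0
                for d in range(D):
                    pb += p[d, l, a]
                pb /= D
                s2b += pb * pb
            hs += hs_l
            ht += 1.0 - s2b
        hs /= K
        ht /= K
        return (ht - hs) + lam * hs

    # allelic objectives need per-deme retention probabilities
    S = np.zeros((D, K, A))
    homf = np.zeros((D, K, A), np.uint8)
    for k in range(P):
        for d in range(D):
            w = g[k, d]
            if w > 0.0:
                for l in range(K):
                    for a in range(A):
                        if het[k, l, a]:
                            S[d, l, a] += w
                        if hom[k, l, a]:
                            homf[d, l, a] = 1
    R = np.zeros((D, K, A))
    for d in range(D):
        for l in range(K):
            for a in range(A):
                if homf[d, l, a]:
                    R[d, l, a] = 1.0
                elif S[d, l, a] > 0.0:
                    R[d, l, a] = 1.0 - 0.5 ** S[d, l, a]

    if method == 1:  # maxAT: D_A + lam * A_S on expected allele counts
        a_s = R.sum() / (D * K) - 1.0
        d_a = 0.0
        if D >= 2:
            acc = 0.0
            for i in range(D):
                for j in range(i + 1, D):
                    for l in range(K):
                        for a in range(A):
                            acc += 0.5 * (
                                R[i, l, a] * (1.0 - R[j, l, a])
                                + R[j, l, a] * (1.0 - R[i, l, a])
                            )
            d_a = acc / (K * D * (D - 1) / 2.0)
        return d_a + lam * a_s

    # maxK: expected number of alleles retained anywhere (mean per locus);
    # maximizing it minimizes the summed global loss probabilities.
    acc = 0.0
    for l in range(K):
        for a in range(A):
            prod = 1.0
            for d in range(D):
                prod *= 1.0 - R[d, l, a]
            acc += 1.0 - prod
    return acc / K


@njit
def anneal_kernel(
    natal,
    sire,
    dam,
    dest,
    xhalf,
    het,
    hom,
    pool_f,
    pool_m,
    method,
    lam,
    n_dest,
    t0,
    cooling,
    per_temp,
    iters,
    n_probe,
    seed,
):
    """Simulated annealing over contribution/migration plans.

    Moves (chosen uniformly): 0 reassign one offspring's parents (origin
    deme re-drawn for migrants); 1 replace the sire or dam of a whole
    mating; 2 swap the destinations of two offspring from different natal
    demes; 3 relocate a migration (a migrant becomes a resident of its
    destination while a resident elsewhere becomes a migrant).  Every move
    preserves per-destination totals and the exact total migrant count.

    When ``t0 <= 0`` the first ``n_probe`` iterations are probe moves
    (always undone) whose mean |delta| sets the initial temperature so that
    a typical worsening move starts with ~50% acceptance.
    """
    np.random.seed(seed)
    T = natal.shape[0]
    D = n_dest.shape[0]
    nf = pool_f.shape[1]
    nm = pool_m.shape[1]

    cur = score_kernel(sire, dam, dest, xhalf, het, hom, method, lam, n_dest)
    best = cur
    b_natal = natal.copy()
    b_sire = sire.copy()
    b_dam = dam.copy()
    b_dest = dest.copy()

    calibrate = t0 <= 0.0
    n_cal = n_probe if calibrate else 0
    temp = t0 if t0 > 0.0 else 1.0
    cal_sum = 0.0
    cal_n = 0

    idx_buf = np.empty(T, np.int64)

    for it in range(n_cal + iters):
        mtype = np.random.randint(0, 4)
        ok = False
        nchanged = 0
        rep_sire = False
        o1 = np.int64(0)
        o2 = np.int64(0)
        o3 = np.int64(0)
        o4 = np.int64(0)
        o5 = np.int64(0)
        o6 = np.int64(0)
        t1 = np.int64(0)
        t2 = np.int64(0)
        oldp = np.int64(0)

        if mtype == 0:
            t1 = np.random.randint(T)
            d = dest[t1]
            o1 = natal[t1]
            o2 = sire[t1]
            o3 = dam[t1]
            if o1 == d:
                j = d
            elif D >= 2:
                j = np.random.randint(D - 1)
                if j >= d:
                    j += 1
            else:
                j = o1
            natal[t1] = j
            sire[t1] = pool_m[j, np.random.randint(nm)]
            dam[t1] = pool_f[j, np.random.randint(nf)]
            ok = True
        elif mtype == 1:
            t = np.random.randint(T)
            mn = natal[t]
            ms = sire[t]
            md = dam[t]
            mdst = dest[t]
            if np.random.random() < 0.5:
                rep_sire = True
                newp = pool_m[mn, np.random.randint(nm)]
                oldp = ms
                if newp != ms:
                    for u in range(T):
                        if (
                            natal[u] == mn
                            and sire[u] == ms
                            and dam[u] == md
                            and dest[u] == mdst
                        ):
                            sire[u] = newp
                            idx_buf[nchanged] = u
                            nchanged += 1
                    ok = nchanged > 0
            else:
                rep_sire = False
                newp = pool_f[mn, np.random.randint(nf)]
                oldp = md
                if newp != md:
                    for u in range(T):
                        if (
                            natal[u] == mn
                            and sire[u] == ms
                            and dam[u] == md
                            and dest[u] == mdst
                        ):
                            dam[u] = newp
                            idx_buf[nchanged] = u
                            nchanged += 1
                    ok = nchanged > 0
        elif mtype == 2:
            t1 = np.random.randint(T)
            t2 = np.random.randint(T)
            if (
                t1 != t2
                and natal[t1] != natal[t2]
                and dest[t1] != dest[t2]
            ):
                m_before = int(natal[t1] != dest[t1]) + int(natal[t2] != dest[t2])
                m_after = int(natal[t1] != dest[t2]) + int(natal[t2] != dest[t1])
                if m_before == m_after:
                    tmp = dest[t1]
                    dest[t1] = dest[t2]
                    dest[t2] = tmp
                    ok = True
        else:
            if D >= 2:
                n_mig = 0
                for u in range(T):
                    if natal[u] != dest[u]:
                        n_mig += 1
                if 0 < n_mig < T:
                    r = np.random.randint(n_mig)
                    t1 = -1
                    c = 0
                    for u in range(T):
                        if natal[u] != dest[u]:
                            if c == r:
                                t1 = u
                                break
                            c += 1
                    r = np.random.randint(T - n_mig)
                    t2 = -1
                    c = 0
                    for u in range(T):
                        if natal[u] == dest[u]:
                            if c == r:
                                t2 = u
                                break
                            c += 1
                    o1 = natal[t1]
                    o2 = sire[t1]
                    o3 = dam[t1]
                    o4 = natal[t2]
                    o5 = sire[t2]
                    o6 = dam[t2]
                    # migrant t1 becomes a resident of its destination
                    j1 = dest[t1]
                    natal[t1] = j1
                    sire[t1] = pool_m[j1, np.random.randint(nm)]
                    dam[t1] = pool_f[j1, np.random.randint(nf)]
                    # resident t2 becomes a migrant from a random other deme
                    j2 = np.random.randint(D - 1)
                    if j2 >= dest[t2]:
                        j2 += 1
                    natal[t2] = j2
                    sire[t2] = pool_m[j2, np.random.randint(nm)]
                    dam[t2] = pool_f[j2, np.random.randint(nf)]
                    ok = True

        if not ok:
            if it >= n_cal and (it - n_cal + 1) % per_temp == 0:
                temp *= cooling
            continue

        s = score_kernel(sire, dam, dest, xhalf, het, hom, method, lam, n_dest)
        delta = s - cur

        if it < n_cal:
            cal_sum += abs(delta)
            cal_n += 1
            accept = False
            if it == n_cal - 1:
                mean_d = cal_sum / cal_n if cal_n > 0 else 0.0
                temp = mean_d / np.log(2.0) if mean_d > 0.0 else 1e-9
        else:
            accept = delta >= 0.0 or np.random.random() < np.exp(delta / temp)

        if accept:
            cur = s
            if s > best:
                best = s
                b_natal[:] = natal
                b_sire[:] = sire
                b_dam[:] = dam
                b_dest[:] = dest
        else:
            # undo
            if mtype == 0:
                natal[t1] = o1
                sire[t1] = o2
                dam[t1] = o3
            elif mtype == 1:
                if rep_sire:
                    for c in range(nchanged):
                        sire[idx_buf[c]] = oldp
                else:
                    for c in range(nchanged):
                        dam[idx_buf[c]] = oldp
            elif mtype == 2:
                tmp = dest[t1]
                dest[t1] = dest[t2]
                dest[t2] = tmp
            else:
                natal[t1] = o1
                sire[t1] = o2
                dam[t1] = o3
                natal[t2] = o4
                sire[t2] = o5
                dam[t2] = o6

        if it >= n_cal and (it - n_cal + 1) % per_temp == 0:
            temp *= cooling

    return b_natal, b_sire, b_dam, b_dest, best
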