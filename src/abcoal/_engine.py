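"""Numba kernels: two-deme structured coalescent and per-locus statistics.

Time convention: rates are {pair coalescence 1/nu_d, per-lineage
migration M_into_d/2, mutation theta/2 per unit branch length}, i.e.
the physical process with time measured in units of 2*Nref generations
while theta = 4*Nref*mu*L and M = 4*Nref*m keep their conventional
scaling.  Under this set E[S] = theta * a_{n-1} and E[pi] = theta in a
single deme of size Nref.

Haplotypes are bit positions in a uint64 (so nA + nB <= 64): a
segregating site is the bitmask of haplotypes carrying the derived
allele.  Kernels draw from numba's internal np.random state, seeded
explicitly per simulation for reproducibility.
"""

import numpy as np
from numba import njit

MAX_EPOCHS = 4
N_LOCUS_STATS = 16
N_SUMSTATS = 39

# indices into the 16-element per-locus stat vector
(I_BIAL, I_SF, I_SXA, I_SXB, I_SS, I_PIA, I_PIB, I_THWA, I_THWB,
 I_DA, I_DB, I_DIV, I_NETDIV, I_MINDIV, I_MAXDIV, I_FST) = range(16)

# (x, y) index pairs for the 7 across-locus Pearson correlations
CORR_PAIRS = np.array([
    (I_PIA, I_PIB),
    (I_THWA, I_THWB),
    (I_DA, I_DB),
    (I_DIV, I_NETDIV),
    (I_FST, I_DIV),
    (I_PIA, I_DIV),
    (I_PIB, I_DIV),
], dtype=np.int64)


@njit(cache=True)
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + \
        ((x >> np.uint64(2)) & np.uint64(0x3333333333333333))
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=True)
def _sim_masks(n1, n2, n_epochs, t_end, e_nu1, e_nu2, e_m1, e_m2, e_ndem,
               fne, fm, theta):
    """Simulate one locus; return derived-allele bitmasks sorted by position.

    Epoch arrays describe consecutive backwards-time intervals; e_m1 is
    the per-lineage jump rate deme0->deme1 (= M12/2) before scaling by
    the per-locus migration multiplier fm; e_nu* are deme sizes relative
    to Nref before scaling by fne.  Returns (masks, positions).
    """
    n = n1 + n2
    mask = np.empty(n, dtype=np.uint64)
    deme = np.empty(n, dtype=np.int64)
    blen = np.zeros(n, dtype=np.float64)
    for i in range(n):
        mask[i] = np.uint64(1) << np.uint64(i)
        deme[i] = 0 if i < n1 else 1
    k = n
    # every coalescence finalises two branches -> at most 2n-2 branches
    bmask = np.empty(2 * n, dtype=np.uint64)
    blens = np.empty(2 * n, dtype=np.float64)
    nb = 0
    t = 0.0
    e = 0
    while k > 1:
        single = e_ndem[e] == 1
        if single:
            for i in range(k):
                deme[i] = 0
        nu0 = e_nu1[e] * fne
        nu1_ = e_nu2[e] * fne
        mr0 = e_m1[e] * fm
        mr1 = e_m2[e] * fm
        tend = t_end[e]
        while k > 1:
            k0 = 0
            for i in range(k):
                if deme[i] == 0:
                    k0 += 1
            k1 = k - k0
            rc0 = 0.5 * k0 * (k0 - 1) / nu0
            if single:
                rc1 = 0.0
                rm0 = 0.0
                rm1 = 0.0
            else:
                rc1 = 0.5 * k1 * (k1 - 1) / nu1_
                rm0 = k0 * mr0
                rm1 = k1 * mr1
            rtot = rc0 + rc1 + rm0 + rm1
            if rtot <= 0.0:
                dt = np.inf
            else:
                dt = np.random.exponential(1.0 / rtot)
            if t + dt >= tend:
                span = tend - t
                for i in range(k):
                    blen[i] += span
                t = tend
                e += 1
                break
            for i in range(k):
                blen[i] += dt
            t += dt
            u = np.random.random() * rtot
            if u < rc0 + rc1:
                d = 0 if u < rc0 else 1
                kd = k0 if d == 0 else k1
                # pick an ordered pair of distinct lineages in deme d
                r1 = int(np.random.random() * kd)
                r2 = int(np.random.random() * (kd - 1))
                if r2 >= r1:
                    r2 += 1
                a = -1
                b = -1
                c = 0
                for i in range(k):
                    if deme[i] == d:
                        if c == r1:
                            a = i
                        if c == r2:
                            b = i
                        c += 1
                bmask[nb] = mask[a]
                blens[nb] = blen[a]
                nb += 1
                bmask[nb] = mask[b]
                blens[nb] = blen[b]
                nb += 1
                mask[a] = mask[a] | mask[b]
                blen[a] = 0.0
                k -= 1
                mask[b] = mask[k]
                blen[b] = blen[k]
                deme[b] = deme[k]
            else:
                d = 0 if u < rc0 + rc1 + rm0 else 1
                kd = k0 if d == 0 else k1
                r1 = int(np.random.random() * kd)
                c = 0
                for i in range(k):
                    if deme[i] == d:
                        if c == r1:
                            deme[i] = 1 - d
                            break
                        c += 1
    total_len = 0.0
    for i in range(nb):
        total_len += blens[i]
    if theta <= 0.0 or total_len <= 0.0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.float64))
    S = np.random.poisson(0.5 * theta * total_len)
    out_mask = np.empty(S, dtype=np.uint64)
    pos = np.empty(S, dtype=np.float64)
    for s in range(S):
        r = np.random.random() * total_len
        acc = 0.0
        j = nb - 1
        for i in range(nb):
            acc += blens[i]
            if r < acc:
                j = i
                break
        out_mask[s] = bmask[j]
        pos[s] = np.random.random()
    order = np.argsort(pos)
    return (out_mask[order], pos[order])


@njit(cache=True)
def _sim_locus_seeded(seed, n1, n2, n_epochs, t_end, e_nu1, e_nu2, e_m1,
                      e_m2, e_ndem, fne, fm, theta):
    np.random.seed(seed)
    return _sim_masks(n1, n2, n_epochs, t_end, e_nu1, e_nu2, e_m1, e_m2,
                      e_ndem, fne, fm, theta)


@njit(cache=True)
def _tajima_consts(n):
    a1 = 0.0
    a2 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
        a2 += 1.0 / (i * i)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, e1, e2


@njit(cache=True)
def _tajima_d(S, pi, a1, e1, e2):
    if S <= 0:
        return 0.0
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0.0:
        return 0.0
    return (pi - S / a1) / np.sqrt(var)


@njit(cache=True)
def _stats16(masks, n1, n2, out):
    """16 per-locus statistics from derived-allele bitmasks.

    Pop A = bits [0, n1), pop B = bits [n1, n1+n2).  pi and dxy are
    per-locus sums over sites; FST is Hudson's 1 - piS/piT with mean
    within-population diversity over dxy.  Undefined values (FST with
    dxy = 0, Tajima's D with S = 0) are recorded as 0.
    """
    S = masks.shape[0]
    for i in range(N_LOCUS_STATS):
        out[i] = 0.0
    if S == 0:
        return
    maskA = (np.uint64(1) << np.uint64(n1)) - np.uint64(1)
    sf = 0
    sxA = 0
    sxB = 0
    ss = 0
    SA = 0
    SB = 0
    piA = 0.0
    piB = 0.0
    div = 0.0
    for s in range(S):
        m = masks[s]
        dA = int(_popcount64(m & maskA))
        dB = int(_popcount64(m >> np.uint64(n1)))
        polyA = 0 < dA < n1
        polyB = 0 < dB < n2
        if polyA and polyB:
            ss += 1
        elif polyA:
            sxA += 1
        elif polyB:
            sxB += 1
        else:
            # monomorphic in both -> fixed for different alleles
            sf += 1
        if polyA:
            SA += 1
        if polyB:
            SB += 1
        piA += dA * (n1 - dA) * 2.0 / (n1 * (n1 - 1.0))
        piB += dB * (n2 - dB) * 2.0 / (n2 * (n2 - 1.0))
        pA = dA / n1
        pB = dB / n2
        div += pA * (1.0 - pB) + pB * (1.0 - pA)
    a1A, e1A, e2A = _tajima_consts(n1)
    a1B, e1B, e2B = _tajima_consts(n2)
    # min/max pairwise cross-population difference counts via bitset rows
    nwords = (S + 63) // 64
    n = n1 + n2
    hap = np.zeros((n, nwords), dtype=np.uint64)
    for s in range(S):
        m = masks[s]
        w = s >> 6
        bit = np.uint64(1) << np.uint64(s & 63)
        for i in range(n):
            if (m >> np.uint64(i)) & np.uint64(1):
                hap[i, w] |= bit
    mind = S + 1
    maxd = -1
    for a in range(n1):
        for b in range(n1, n):
            d = 0
            for w in range(nwords):
                d += int(_popcount64(hap[a, w] ^ hap[b, w]))
            if d < mind:
                mind = d
            if d > maxd:
                maxd = d
    out[I_BIAL] = S
    out[I_SF] = sf
    out[I_SXA] = sxA
    out[I_SXB] = sxB
    out[I_SS] = ss
    out[I_PIA] = piA
    out[I_PIB] = piB
    out[I_THWA] = SA / a1A
    out[I_THWB] = SB / a1B
    out[I_DA] = _tajima_d(SA, piA, a1A, e1A, e2A)
    out[I_DB] = _tajima_d(SB, piB, a1B, e1B, e2B)
    out[I_DIV] = div
    out[I_NETDIV] = div - 0.5 * (piA + piB)
    out[I_MINDIV] = mind
    out[I_MAXDIV] = maxd
    out[I_FST] = 1.0 - 0.5 * (piA + piB) / div if div > 0.0 else 0.0


@njit(cache=True)
def _aggregate39(st, out):
    """Means, SDs (ddof=1) and the 7 correlations of per-locus stats."""
    nl = st.shape[0]
    means = np.empty(N_LOCUS_STATS)
    sds = np.empty(N_LOCUS_STATS)
    for j in range(N_LOCUS_STATS):
        m = 0.0
        for l in range(nl):
            m += st[l, j]
        m /= nl
        v = 0.0
        for l in range(nl):
            d = st[l, j] - m
            v += d * d
        means[j] = m
        sds[j] = np.sqrt(v / (nl - 1)) if nl > 1 else 0.0
        out[j] = m
        out[N_LOCUS_STATS + j] = sds[j]
    for c in range(CORR_PAIRS.shape[0]):
        x = CORR_PAIRS[c, 0]
        y = CORR_PAIRS[c, 1]
        if sds[x] == 0.0 or sds[y] == 0.0:
            out[2 * N_LOCUS_STATS + c] = 0.0
            continue
        cov = 0.0
        for l in range(nl):
            cov += (st[l, x] - means[x]) * (st[l, y] - means[y])
        cov /= (nl - 1)
        out[2 * N_LOCUS_STATS + c] = cov / (sds[x] * sds[y])


@njit(cache=True)
def _build_epochs(code, nu1, nu2, nuanc, tsc, tnc, tdiv, mh1, mh2,
                  mhsc1, mhsc2, t_end, e_nu1, e_nu2, e_m1, e_m2, e_ndem):
    """Fill epoch arrays for scenario `code`; returns the epoch count.

    codes: 0 pan, 1 div, 2 im, 3 divAGF, 4 divSC, 5 divAGFSC.  mh1/mh2
    are the per-lineage jump rates M12/2 and M21/2 for ancient/ongoing
    flow; mhsc1/mhsc2 the same for the recent secondary-contact epoch.
    Times already in coalescent units.
    """
    for i in range(MAX_EPOCHS):
        e_m1[i] = 0.0
        e_m2[i] = 0.0
        e_nu1[i] = nu1
        e_nu2[i] = nu2
        e_ndem[i] = 2
    if code == 0:
        t_end[0] = np.inf
        e_ndem[0] = 1
        return 1
    if code == 1 or code == 2:
        t_end[0] = tdiv
        if code == 2:
            e_m1[0] = mh1
            e_m2[0] = mh2
        t_end[1] = np.inf
        e_nu1[1] = nuanc
        e_ndem[1] = 1
        return 2
    if code == 3:  # divAGF: isolation [0,tnc), migration [tnc,tdiv)
        t_end[0] = tnc
        t_end[1] = tdiv
        e_m1[1] = mh1
        e_m2[1] = mh2
        t_end[2] = np.inf
        e_nu1[2] = nuanc
        e_ndem[2] = 1
        return 3
    if code == 4:  # divSC: migration [0,tsc), isolation [tsc,tdiv)
        t_end[0] = tsc
        e_m1[0] = mhsc1
        e_m2[0] = mhsc2
        t_end[1] = tdiv
        t_end[2] = np.inf
        e_nu1[2] = nuanc
        e_ndem[2] = 1
        return 3
    # divAGFSC
    t_end[0] = tsc
    e_m1[0] = mhsc1
    e_m2[0] = mhsc2
    t_end[1] = tnc
    t_end[2] = tdiv
    e_m1[2] = mh1
    e_m2[2] = mh2
    t_end[3] = np.inf
    e_nu1[3] = nuanc
    e_ndem[3] = 1
    return 4


@njit(cache=True)
def _bulk_tables(seeds, code, sp, fne, fm, theta, n1, n2, out):
    """One 39-statistic row per simulation.

    sp columns: [nu1, nu2, nuanc, tsc, tnc, tdiv, mh1, mh2, mhsc1,
    mhsc2] (times in coalescent units, mh = M/2).  fne/fm are
    (n_sims, n_loci) per-locus multipliers; theta is (n_loci,).
    """
    n_sims = seeds.shape[0]
    n_loci = fne.shape[1]
    st = np.empty((n_loci, N_LOCUS_STATS))
    t_end = np.empty(MAX_EPOCHS)
    e_nu1 = np.empty(MAX_EPOCHS)
    e_nu2 = np.empty(MAX_EPOCHS)
    e_m1 = np.empty(MAX_EPOCHS)
    e_m2 = np.empty(MAX_EPOCHS)
    e_ndem = np.empty(MAX_EPOCHS, dtype=np.int64)
    for s in range(n_sims):
        np.random.seed(seeds[s])
        ne = _build_epochs(code, sp[s, 0], sp[s, 1], sp[s, 2], sp[s, 3],
                           sp[s, 4], sp[s, 5], sp[s, 6], sp[s, 7],
                           sp[s, 8], sp[s, 9],
                           t_end, e_nu1, e_nu2, e_m1, e_m2, e_ndem)
        for l in range(n_loci):
            masks, _pos = _sim_masks(n1, n2, ne, t_end, e_nu1, e_nu2,
                                     e_m1, e_m2, e_ndem,
                                     fne[s, l], fm[s, l], theta[l])
            _stats16(masks, n1, n2, st[l])
        _aggregate39(st, out[s])
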