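"""Numba hot loops: the two Gibbs samplers and gametic transmission.

These kernels carry the package's Monte-Carlo workload.  They take plain
arrays, hold no Python objects, and are deterministic given the seed passed
in (numba maintains its own RNG state, seeded inside each kernel).
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _chisq(df):
    return 2.0 * np.random.gamma(0.5 * df, 1.0)


# ---------------------------------------------------------------------------
# BayesR-style mixture Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def bayesr_gibbs(
    Wt,          # (m, n) centred genotypes, SNP-major
    y,           # (n,)
    gamma,       # (4,) component variance fractions, gamma[0] == 0
    alpha,       # (4,) Dirichlet pseudo-counts
    ref_mode,    # 0: fixed reference variance, 1: current genetic variance
    ref_fixed,   # reference variance value when ref_mode == 0
    s0_g, nu_g,  # scaled-inv-chi2 prior for the genetic variance
    s0_e, nu_e,  # scaled-inv-chi2 prior for the residual variance
    n_iter,
    keep,        # (S,) sorted iteration indices to store
    seed,
):
    np.random.seed(seed)
    m, n = Wt.shape
    S = keep.shape[0]
    K = gamma.shape[0]

    wtw = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Wt[j, i] * Wt[j, i]
        wtw[j] = s

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    r = np.empty(n)
    vy = 0.0
    for i in range(n):
        r[i] = y[i] - mu
        vy += r[i] * r[i]
    vy /= max(n - 1, 1)

    beta = np.zeros(m)
    klass = np.zeros(m, dtype=np.int8)
    pi = np.full(K, 1.0 / K)
    s2e = 0.5 * vy
    s2g = 0.5 * vy

    beta_s = np.zeros((S, m))
    class_s = np.zeros((S, m), dtype=np.int8)
    s2g_s = np.zeros(S)
    s2e_s = np.zeros(S)
    pi_s = np.zeros((S, K))
    mu_s = np.zeros(S)

    logl = np.empty(K)
    ptr = 0
    for it in range(n_iter):
        # intercept
        rsum = 0.0
        for i in range(n):
            rsum += r[i]
        mu_new = mu + rsum / n + np.sqrt(s2e / n) * np.random.normal(0.0, 1.0)
        d = mu_new - mu
        for i in range(n):
            r[i] -= d
        mu = mu_new

        ref = s2g if ref_mode == 1 else ref_fixed
        counts = np.zeros(K)
        ssb = 0.0
        m_nz = 0
        for j in range(m):
            old = beta[j]
            rhs = wtw[j] * old
            for i in range(n):
                rhs += Wt[j, i] * r[i]
            # component log-likelihoods (marginal over the effect)
            logl[0] = np.log(pi[0] + 1e-300)
            for k in range(1, K):
                v = gamma[k] * ref
                c = v * wtw[j] + s2e
                logl[k] = (np.log(pi[k] + 1e-300)
                           - 0.5 * np.log(c / s2e)
                           + 0.5 * rhs * rhs * v / (s2e * c))
            top = logl[0]
            for k in range(1, K):
                if logl[k] > top:
                    top = logl[k]
            tot = 0.0
            for k in range(K):
                logl[k] = np.exp(logl[k] - top)
                tot += logl[k]
            u = np.random.random() * tot
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += logl[k]
                if u <= acc:
                    k_new = k
                    break
            if k_new == 0:
                b_new = 0.0
            else:
                v = gamma[k_new] * ref
                c = v * wtw[j] + s2e
                post_var = v * s2e / c
                post_mean = v * rhs / c
                b_new = post_mean + np.sqrt(post_var) * np.random.normal(0.0, 1.0)
                ssb += b_new * b_new / gamma[k_new]
                m_nz += 1
            if b_new != old:
                diff = old - b_new
                for i in range(n):
                    r[i] += Wt[j, i] * diff
            beta[j] = b_new
            klass[j] = np.int8(k_new)
            counts[k_new] += 1.0

        # mixture proportions
        tot = 0.0
        for k in range(K):
            pi[k] = np.random.gamma(alpha[k] + counts[k], 1.0)
            tot += pi[k]
        for k in range(K):
            pi[k] /= tot

        # variances
        s2g = (nu_g * s0_g + ssb) / _chisq(nu_g + m_nz)
        rss = 0.0
        for i in range(n):
            rss += r[i] * r[i]
        s2e = (nu_e * s0_e + rss) / _chisq(nu_e + n)

        if ptr < S and it == keep[ptr]:
            for j in range(m):
                beta_s[ptr, j] = beta[j]
                class_s[ptr, j] = klass[j]
            s2g_s[ptr] = s2g
            s2e_s[ptr] = s2e
            for k in range(K):
                pi_s[ptr, k] = pi[k]
            mu_s[ptr] = mu
            ptr += 1

    return beta_s, class_s, s2g_s, s2e_s, pi_s, mu_s


# ---------------------------------------------------------------------------
# Animal-model single-site Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def animal_gibbs(
    y,                 # (n_rec,)
    X,                 # (n_rec, p) fixed-effect design
    rec_a,             # (n_rec,) pedigree index per record
    rec_pe,            # (n_rec,) permanent-environment level per record
    rec_by, rec_cy,    # (n_rec,) birth-year / capture-year levels
    n_ped, n_pe, n_by, n_cy,
    ai_indptr, ai_indices, ai_data,   # CSR of A^-1
    a_rec_off, a_rec_list,            # records grouped by animal
    nu0, s0,           # (5,) priors for (A, PE, BY, CY, E)
    n_iter,
    keep,              # (S,) sorted stored iterations
    store_idx,         # pedigree indices whose breeding values are stored
    seed,
):
    np.random.seed(seed)
    n_rec = y.shape[0]
    p = X.shape[1]
    S = keep.shape[0]

    sxx = np.zeros(p)
    for c in range(p):
        s = 0.0
        for i in range(n_rec):
            s += X[i, c] * X[i, c]
        sxx[c] = s

    b = np.zeros(p)
    a = np.zeros(n_ped)
    pe = np.zeros(n_pe)
    uby = np.zeros(n_by)
    ucy = np.zeros(n_cy)
    s2 = s0.copy()          # (A, PE, BY, CY, E) current variances

    r = y.copy()
    ybar = 0.0
    for i in range(n_rec):
        ybar += y[i]
    ybar /= n_rec
    b[0] = ybar
    for i in range(n_rec):
        r[i] -= X[i, 0] * ybar

    a_s = np.zeros((S, store_idx.shape[0]))
    s2_s = np.zeros((S, 5))
    b_s = np.zeros((S, p))

    lvl_sum = np.zeros(max(max(n_pe, n_by), max(n_cy, 1)))
    lvl_n = np.zeros(lvl_sum.shape[0])

    ptr = 0
    for it in range(n_iter):
        s2a, s2pe, s2by, s2cy, s2e = s2[0], s2[1], s2[2], s2[3], s2[4]

        # fixed effects, flat prior, one column at a time
        for c in range(p):
            if sxx[c] <= 0.0:
                continue
            sxr = 0.0
            for i in range(n_rec):
                sxr += X[i, c] * r[i]
            mean = (sxr + sxx[c] * b[c]) / sxx[c]
            new = mean + np.sqrt(s2e / sxx[c]) * np.random.normal(0.0, 1.0)
            d = new - b[c]
            if d != 0.0:
                for i in range(n_rec):
                    r[i] -= X[i, c] * d
            b[c] = new

        # iid random intercept factors: levels are conditionally independent
        for f in range(3):
            if f == 0:
                idx, eff, nl, s2f = rec_pe, pe, n_pe, s2pe
            elif f == 1:
                idx, eff, nl, s2f = rec_by, uby, n_by, s2by
            else:
                idx, eff, nl, s2f = rec_cy, ucy, n_cy, s2cy
            if nl == 0 or s2f <= 0.0:
                continue
            for l in range(nl):
                lvl_sum[l] = 0.0
                lvl_n[l] = 0.0
            for i in range(n_rec):
                l = idx[i]
                lvl_sum[l] += r[i]
                lvl_n[l] += 1.0
            for l in range(nl):
                prec = lvl_n[l] / s2e + 1.0 / s2f
                mean = (lvl_sum[l] + lvl_n[l] * eff[l]) / s2e / prec
                new = mean + np.sqrt(1.0 / prec) * np.random.normal(0.0, 1.0)
                lvl_sum[l] = new - eff[l]   # reuse as delta
                eff[l] = new
            for i in range(n_rec):
                r[i] -= lvl_sum[idx[i]]

        # breeding values: true single-site sweep (prior couples animals)
        for i in range(n_ped):
            aii = 0.0
            off = 0.0
            for k in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[k]
                if j == i:
                    aii += ai_data[k]
                else:
                    off += ai_data[k] * a[j]
            nrec_i = a_rec_off[i + 1] - a_rec_off[i]
            sres = 0.0
            for k in range(a_rec_off[i], a_rec_off[i + 1]):
                sres += r[a_rec_list[k]]
            prec = nrec_i / s2e + aii / s2a
            rhs = (sres + nrec_i * a[i]) / s2e - off / s2a
            mean = rhs / prec
            new = mean + np.sqrt(1.0 / prec) * np.random.normal(0.0, 1.0)
            d = new - a[i]
            if d != 0.0:
                for k in range(a_rec_off[i], a_rec_off[i + 1]):
                    r[a_rec_list[k]] -= d
            a[i] = new

        # variances: scaled-inv-chi2 full conditionals
        quad = 0.0
        for i in range(n_ped):
            for k in range(ai_indptr[i], ai_indptr[i + 1]):
                quad += a[i] * ai_data[k] * a[ai_indices[k]]
        s2[0] = (nu0[0] * s0[0] + quad) / _chisq(nu0[0] + n_ped)
        q = 0.0
        for l in range(n_pe):
            q += pe[l] * pe[l]
        s2[1] = (nu0[1] * s0[1] + q) / _chisq(nu0[1] + n_pe)
        q = 0.0
        for l in range(n_by):
            q += uby[l] * uby[l]
        s2[2] = (nu0[2] * s0[2] + q) / _chisq(nu0[2] + n_by)
        q = 0.0
        for l in range(n_cy):
            q += ucy[l] * ucy[l]
        s2[3] = (nu0[3] * s0[3] + q) / _chisq(nu0[3] + n_cy)
        rss = 0.0
        for i in range(n_rec):
            rss += r[i] * r[i]
        s2[4] = (nu0[4] * s0[4] + rss) / _chisq(nu0[4] + n_rec)

        if ptr < S and it == keep[ptr]:
            for k in range(store_idx.shape[0]):
                a_s[ptr, k] = a[store_idx[k]]
            for k in range(5):
                s2_s[ptr, k] = s2[k]
            for c in range(p):
                b_s[ptr, c] = b[c]
            ptr += 1

    return a_s, s2_s, b_s


# ---------------------------------------------------------------------------
# Gametic transmission and gene dropping
# ---------------------------------------------------------------------------

@njit(cache=True)
def _meiosis(hap_pair, rec, out):
    """One recombinant gamete: walk the SNP order copying from one of the two
    parental haplotypes, switching template between adjacent SNPs with the
    interval's recombination fraction."""
    m = rec.shape[0]
    t = np.random.randint(0, 2)
    for j in range(m):
        out[j] = hap_pair[t, j]
        if j < m - 1 and np.random.random() < rec[j]:
            t = 1 - t
    return out


@njit(cache=True)
def gene_drop_kernel(
    order,        # (n,) processing order, parents before offspring
    sire, dam,    # (n,) parent indices, -1 unknown
    is_founder,   # (n,) treat as pool founder (birth year before cutoff)
    pool,         # (H, m) phased founder haplotypes
    rec,          # (m,) recombination fraction to the next SNP
    donor_off,    # (2n+1,) candidate-list offsets; slot 2i sire, 2i+1 dam
    donor_list,   # concatenated donor candidate indices
    seed,
    permute_pool, # True: founders consume a random permutation of the pool
                  # (each haplotype used once per pass); False: sample with
                  # replacement
):
    np.random.seed(seed)
    n = order.shape[0]
    H, m = pool.shape
    hap = np.zeros((n, 2, m), dtype=np.int8)
    gam = np.zeros(m, dtype=np.int8)
    perm = np.arange(H)
    if permute_pool:
        for a in range(H - 1, 0, -1):
            b = np.random.randint(0, a + 1)
            t = perm[a]
            perm[a] = perm[b]
            perm[b] = t
    next_hap = 0
    for k in range(n):
        i = order[k]
        if is_founder[i]:
            for slot in range(2):
                if permute_pool:
                    if next_hap == H:   # pool exhausted: reshuffle and reuse
                        for a in range(H - 1, 0, -1):
                            b = np.random.randint(0, a + 1)
                            t = perm[a]
                            perm[a] = perm[b]
                            perm[b] = t
                        next_hap = 0
                    hap[i, slot] = pool[perm[next_hap]]
                    next_hap += 1
                else:
                    hap[i, slot] = pool[np.random.randint(0, H)]
            continue
        for slot in range(2):
            par = sire[i] if slot == 0 else dam[i]
            if par >= 0:
                _meiosis(hap[par], rec, gam)
                hap[i, slot] = gam
            else:
                lo = donor_off[2 * i + slot]
                hi = donor_off[2 * i + slot + 1]
                if hi > lo:
                    donor = donor_list[lo + np.random.randint(0, hi - lo)]
                    hap[i, slot] = hap[donor, np.random.randint(0, 2)]
                else:
                    hap[i, slot] = pool[np.random.randint(0, H)]
    return hap


@njit(cache=True)
def transmit_gamete(hap_pair, rec, seed=-1):
    """Standalone meiosis for the forward simulator (seed < 0: do not reseed)."""
    if seed >= 0:
        np.random.seed(seed)
    out = np.zeros(rec.shape[0], dtype=np.int8)
    _meiosis(hap_pair, rec, out)
    return out
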