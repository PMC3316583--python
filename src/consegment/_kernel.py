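"""Numba kernel for the change-point Gibbs sampler.

The state is a vector of boundary indicators over the N-1 positions between
adjacent characters, a class label per segment, the mixture weights ``pi``,
the per-class Dirichlet parameters ``alpha`` and the boundary probability
``rho``.  Each sweep performs a collapsed Gibbs update at every boundary
(class labels of the two affected segments are marginalised analytically and
then redrawn from their exact conditional), followed by conjugate updates of
``pi`` and ``rho`` and a log-space random-walk Metropolis update of each
``alpha`` component.

Dirichlet-multinomial segment marginals are evaluated through per-iteration
lookup tables ``lgamma(alpha + n)`` for n = 0..N, built by the recurrence
``lgamma(a+n+1) = lgamma(a+n) + log(a+n)`` re-anchored with an exact
``lgamma`` every 1024 entries to stop error accumulation.
"""

import math

import numpy as np
from numba import njit

__all__ = ["run_chain", "marginal_loglik"]

_ANCHOR = 1024


@njit(cache=True)
def _fill_lgamma_table(a, out):
    """out[n] = lgamma(a + n) for n = 0..len(out)-1."""
    L = out.shape[0]
    acc = math.lgamma(a)
    out[0] = acc
    for n in range(1, L):
        if n % _ANCHOR == 0:
            acc = math.lgamma(a + n)
        else:
            acc += math.log(a + n - 1.0)
        out[n] = acc


@njit(cache=True, inline="always")
def _dm_from_tables(Tlg, TA, g, counts, C):
    """Log Dirichlet-multinomial marginal of one segment under class g."""
    n = 0
    s = 0.0
    for c in range(C):
        nc = counts[c]
        n += nc
        s += Tlg[g, c, nc] - Tlg[g, c, 0]
    return TA[g, 0] - TA[g, n] + s


@njit(cache=True)
def _dm_direct(alpha_row, counts, C):
    A = 0.0
    n = 0
    s = 0.0
    for c in range(C):
        A += alpha_row[c]
        nc = counts[c]
        n += nc
        s += math.lgamma(alpha_row[c] + nc) - math.lgamma(alpha_row[c])
    return math.lgamma(A) - math.lgamma(A + n) + s


@njit(cache=True, inline="always")
def _class_posterior(Tlg, TA, log_pi, counts, C, k, work):
    """work[g] = log pi_g + DM(counts; alpha_g); returns logsumexp(work)."""
    m = -1.0e308
    for g in range(k):
        v = log_pi[g] + _dm_from_tables(Tlg, TA, g, counts, C)
        work[g] = v
        if v > m:
            m = v
    s = 0.0
    for g in range(k):
        s += math.exp(work[g] - m)
    return m + math.log(s)


@njit(cache=True, inline="always")
def _sample_class(work, k, lse):
    u = np.random.random()
    acc = 0.0
    for g in range(k):
        acc += math.exp(work[g] - lse)
        if u <= acc:
            return g
    return k - 1


@njit(cache=True)
def _dirichlet(params, out):
    k = params.shape[0]
    s = 0.0
    for g in range(k):
        v = np.random.gamma(params[g], 1.0)
        if v <= 0.0:
            v = 1e-300
        out[g] = v
        s += v
    for g in range(k):
        out[g] /= s


@njit(cache=True)
def marginal_loglik(codes, C, log_pi, alpha, rho, max_segment):
    """Log P(data | pi, alpha, rho): segmentations and labels marginalised
    by forward dynamic programming.

    F[i] = logsumexp_j { F[j] + seg(j, i) + (i-j-1) log(1-rho)
                         + [j > 0] log rho },
    seg(j, i) = logsumexp_g { log pi_g + DM(counts of codes[j:i]; alpha_g) },
    with the Dirichlet-multinomial term grown incrementally as the segment
    extends leftward (Polya-urn update, O(1) per character per class).

    ``max_segment <= 0`` sums over all segmentations exactly; a positive
    value restricts segments to that length (an O(N * max_segment * k)
    approximation, negligible when max_segment covers the prior's segment
    length distribution).
    """
    N = codes.shape[0]
    k = log_pi.shape[0]
    L = max_segment if max_segment > 0 else N
    A = np.empty(k)
    for g in range(k):
        s = 0.0
        for c in range(C):
            s += alpha[g, c]
        A[g] = s
    log_rho = math.log(rho)
    log_1m = math.log1p(-rho)
    F = np.empty(N + 1)
    F[0] = 0.0
    vals = np.empty(N)
    counts = np.zeros(C, np.int64)
    dm = np.empty(k)
    for i in range(1, N + 1):
        for c in range(C):
            counts[c] = 0
        for g in range(k):
            dm[g] = 0.0
        j_lo = i - L if i - L > 0 else 0
        for j in range(i - 1, j_lo - 1, -1):
            c = codes[j]
            n = i - 1 - j  # segment size before adding codes[j]
            for g in range(k):
                dm[g] += math.log((alpha[g, c] + counts[c]) / (A[g] + n))
            counts[c] += 1
            m = -1.0e308
            for g in range(k):
                v = log_pi[g] + dm[g]
                if v > m:
                    m = v
            s = 0.0
            for g in range(k):
                s += math.exp(log_pi[g] + dm[g] - m)
            seg = m + math.log(s)
            v = F[j] + seg + (i - 1 - j) * log_1m
            if j > 0:
                v += log_rho
            vals[j] = v
        m = -1.0e308
        for j in range(j_lo, i):
            if vals[j] > m:
                m = vals[j]
        s = 0.0
        for j in range(j_lo, i):
            s += math.exp(vals[j] - m)
        F[i] = m + math.log(s)
    return F[N]


@njit(cache=True)
def _log_dirichlet_pdf(m, a, C):
    """log Dirichlet(m; a) on the C-simplex."""
    A = 0.0
    s = 0.0
    for c in range(C):
        A += a[c]
        s += (a[c] - 1.0) * math.log(m[c]) - math.lgamma(a[c])
    return math.lgamma(A) + s


@njit(cache=True)
def _anchor_log_q(alpha_row, seg_counts_g, n_g, C, log_s_lo, log_s_hi,
                  log_lo, log_hi, w_anchor):
    """Log density of the anchored independence proposal at alpha_row.

    Mixture: w_anchor * [segment-anchored Dirichlet on the mean direction x
    log-uniform concentration] + (1 - w_anchor) * independent log-uniform
    per component.
    """
    s = 0.0
    for c in range(C):
        s += alpha_row[c]
    m = np.empty(C)
    for c in range(C):
        m[c] = alpha_row[c] / s
    # anchored component (log-sum-exp over segment anchors)
    log_anchor = -1.0e308
    ls = math.log(s)
    if log_s_lo <= ls <= log_s_hi:
        a_work = np.empty(C)
        lps = np.empty(n_g)
        mx = -1.0e308
        for j in range(n_g):
            for c in range(C):
                a_work[c] = seg_counts_g[j, c] + 1.0
            v = _log_dirichlet_pdf(m, a_work, C)
            lps[j] = v
            if v > mx:
                mx = v
        acc = 0.0
        for j in range(n_g):
            acc += math.exp(lps[j] - mx)
        # q_s(s) = 1 / (s * range);  Jacobian (m, s) -> alpha: s^(C-1)
        log_anchor = (
            mx + math.log(acc / n_g)
            - ls - math.log(log_s_hi - log_s_lo)
            - (C - 1.0) * ls
        )
    # diffuse log-uniform component
    log_diffuse = 0.0
    rng = log_hi - log_lo
    for c in range(C):
        la = math.log(alpha_row[c])
        if la < log_lo or la > log_hi:
            log_diffuse = -1.0e308
            break
        log_diffuse += -la - math.log(rng)
    ma = log_anchor if log_anchor > log_diffuse else log_diffuse
    if ma <= -1.0e307:
        return -1.0e308
    return ma + math.log(
        w_anchor * math.exp(log_anchor - ma)
        + (1.0 - w_anchor) * math.exp(log_diffuse - ma)
    )


@njit(cache=True)
def run_chain(
    codes,
    C,
    k,
    n_iter,
    seed,
    pi0,
    alpha0,
    rho0,
    update_pi,
    update_rho,
    update_alpha,
    alpha_step0,
    adapt_until,
    log_lo,
    log_hi,
    pi_prior,
    rho_a,
    rho_b,
    alpha_inner,
):
    np.random.seed(seed)
    N = codes.shape[0]

    # prefix[i, c] = number of code-c characters in codes[:i]
    prefix = np.zeros((N + 1, C), np.int64)
    for i in range(N):
        for c in range(C):
            prefix[i + 1, c] = prefix[i, c]
        prefix[i + 1, codes[i]] += 1

    cp = np.zeros(N + 1, np.bool_)
    cp[0] = True
    cp[N] = True
    lab_start = np.zeros(N, np.int32)  # valid at segment starts only

    pi = pi0.copy()
    alpha = alpha0.copy()
    rho = rho0
    log_pi = np.empty(k)
    for g in range(k):
        log_pi[g] = math.log(pi[g])

    Tlg = np.empty((k, C, N + 1))
    TA = np.empty((k, N + 1))
    for g in range(k):
        A = 0.0
        for c in range(C):
            _fill_lgamma_table(alpha[g, c], Tlg[g, c])
            A += alpha[g, c]
        _fill_lgamma_table(A, TA[g])

    # traces
    loglik_tr = np.empty(n_iter)
    data_ll_tr = np.empty(n_iter)
    ncp_tr = np.empty(n_iter, np.int64)
    rho_tr = np.empty(n_iter)
    pi_tr = np.empty((n_iter, k))
    alpha_tr = np.empty((n_iter, k, C))

    # per-iteration segmentations, flat storage with offsets
    cap = 1024
    cp_flat = np.empty(cap, np.int64)
    lab_flat = np.empty(cap + n_iter, np.int32)
    cp_off = np.zeros(n_iter + 1, np.int64)
    lab_off = np.zeros(n_iter + 1, np.int64)

    work = np.empty(k)
    work_m = np.empty(k)
    counts = np.empty(C, np.int64)
    counts_l = np.empty(C, np.int64)
    counts_r = np.empty(C, np.int64)
    seg_starts = np.empty(N + 1, np.int64)

    alpha_step = np.empty((k, C))
    for g in range(k):
        for c in range(C):
            alpha_step[g, c] = alpha_step0
    n_prop = 0
    n_acc = 0

    for it in range(n_iter):
        # ---- collapsed Gibbs sweep over boundaries ----
        if N > 1:
            s = 0  # last changepoint < b
            e = 1  # first changepoint > b (found below)
            for b in range(1, N):
                if e <= b:
                    e = b + 1
                    while not cp[e]:
                        e += 1
                for c in range(C):
                    counts[c] = prefix[e, c] - prefix[s, c]
                    counts_l[c] = prefix[b, c] - prefix[s, c]
                    counts_r[c] = prefix[e, c] - prefix[b, c]
                lse_w = _class_posterior(Tlg, TA, log_pi, counts, C, k, work_m)
                w_merge = math.log1p(-rho) + lse_w
                lse_l = _class_posterior(Tlg, TA, log_pi, counts_l, C, k, work)
                g_left = _sample_class(work, k, lse_l)
                lse_r = _class_posterior(Tlg, TA, log_pi, counts_r, C, k, work)
                g_right = _sample_class(work, k, lse_r)
                w_split = math.log(rho) + lse_l + lse_r
                m = w_merge if w_merge > w_split else w_split
                p_split = math.exp(w_split - m) / (
                    math.exp(w_split - m) + math.exp(w_merge - m)
                )
                if np.random.random() < p_split:
                    cp[b] = True
                    lab_start[s] = g_left
                    lab_start[b] = g_right
                else:
                    cp[b] = False
                    lab_start[s] = _sample_class(work_m, k, lse_w)
                if cp[b]:
                    s = b

        # ---- collect segments ----
        n_seg = 0
        for i in range(N):
            if cp[i]:
                seg_starts[n_seg] = i
                n_seg += 1
        seg_starts[n_seg] = N
        seg_counts = np.empty((n_seg, C), np.int64)
        for j in range(n_seg):
            a0 = seg_starts[j]
            a1 = seg_starts[j + 1]
            for c in range(C):
                seg_counts[j, c] = prefix[a1, c] - prefix[a0, c]

        # ---- Gibbs labels per segment (also refreshes after sweep) ----
        lab_counts = np.zeros(k, np.int64)
        seg_labels = np.empty(n_seg, np.int32)
        for j in range(n_seg):
            lse = _class_posterior(Tlg, TA, log_pi, seg_counts[j], C, k, work)
            g = _sample_class(work, k, lse)
            lab_start[seg_starts[j]] = g
            seg_labels[j] = g
            lab_counts[g] += 1

        # ---- conjugate updates ----
        n_cp = n_seg - 1
        if update_rho and N > 1:
            a = rho_a + n_cp
            b_ = rho_b + (N - 1 - n_cp)
            rho = np.random.beta(a, b_)
            if rho <= 0.0:
                rho = 1e-12
            if rho >= 1.0:
                rho = 1.0 - 1e-12
        if update_pi:
            params = np.empty(k)
            for g in range(k):
                params[g] = pi_prior + lab_counts[g]
            _dirichlet(params, pi)
            for g in range(k):
                if pi[g] < 1e-300:
                    pi[g] = 1e-300
                log_pi[g] = math.log(pi[g])

        # ---- alpha updates: random-walk MH plus an anchored independence
        # ---- move (proposals centred on a random segment's composition,
        # ---- mixed with a diffuse log-uniform component; exact Hastings
        # ---- correction). The anchored move lets a starved class jump onto
        # ---- an occupied region of composition space.
        if update_alpha:
            log_s_lo = 0.0           # proposal concentration range (log)
            log_s_hi = math.log(1.0e5)
            w_anchor = 0.8
            prop = np.empty(C)
            m_work = np.empty(C)
            for g in range(k):
                ll_cur = 0.0
                for j in range(n_seg):
                    if seg_labels[j] == g:
                        ll_cur += _dm_direct(alpha[g], seg_counts[j], C)
                changed = False
                for rep in range(alpha_inner):
                    for c in range(C):
                        theta = math.log(alpha[g, c])
                        theta_p = theta + alpha_step[g, c] * np.random.normal()
                        n_prop += 1
                        if theta_p < log_lo or theta_p > log_hi:
                            accepted = False
                        else:
                            old = alpha[g, c]
                            alpha[g, c] = math.exp(theta_p)
                            ll_new = 0.0
                            for j in range(n_seg):
                                if seg_labels[j] == g:
                                    ll_new += _dm_direct(
                                        alpha[g], seg_counts[j], C
                                    )
                            if math.log(np.random.random()) < ll_new - ll_cur:
                                accepted = True
                                ll_cur = ll_new
                            else:
                                accepted = False
                                alpha[g, c] = old
                        if accepted:
                            n_acc += 1
                            changed = True
                        if it < adapt_until:
                            d = 0.56 if accepted else -0.44
                            alpha_step[g, c] *= math.exp(0.05 * d)
                            if alpha_step[g, c] < 1e-3:
                                alpha_step[g, c] = 1e-3
                            if alpha_step[g, c] > 5.0:
                                alpha_step[g, c] = 5.0

                # anchored independence proposal
                if np.random.random() < w_anchor:
                    j = int(np.random.random() * n_seg)
                    if j >= n_seg:
                        j = n_seg - 1
                    s_m = 0.0
                    for c in range(C):
                        v = np.random.gamma(seg_counts[j, c] + 1.0, 1.0)
                        if v <= 0.0:
                            v = 1e-300
                        m_work[c] = v
                        s_m += v
                    s_new = math.exp(
                        log_s_lo + np.random.random() * (log_s_hi - log_s_lo)
                    )
                    for c in range(C):
                        prop[c] = s_new * m_work[c] / s_m
                else:
                    for c in range(C):
                        prop[c] = math.exp(
                            log_lo + np.random.random() * (log_hi - log_lo)
                        )
                ok = True
                lp_new = 0.0
                lp_cur = 0.0
                for c in range(C):
                    la = math.log(prop[c])
                    if la < log_lo or la > log_hi:
                        ok = False
                        break
                    lp_new -= la
                    lp_cur -= math.log(alpha[g, c])
                if ok:
                    ll_new = 0.0
                    for j2 in range(n_seg):
                        if seg_labels[j2] == g:
                            ll_new += _dm_direct(prop, seg_counts[j2], C)
                    lq_new = _anchor_log_q(
                        prop, seg_counts, n_seg, C,
                        log_s_lo, log_s_hi, log_lo, log_hi, w_anchor,
                    )
                    lq_cur = _anchor_log_q(
                        alpha[g], seg_counts, n_seg, C,
                        log_s_lo, log_s_hi, log_lo, log_hi, w_anchor,
                    )
                    log_r = (ll_new + lp_new + lq_cur) - (
                        ll_cur + lp_cur + lq_new
                    )
                    if math.log(np.random.random()) < log_r:
                        for c in range(C):
                            alpha[g, c] = prop[c]
                        ll_cur = ll_new
                        changed = True
                if changed:
                    A = 0.0
                    for c in range(C):
                        _fill_lgamma_table(alpha[g, c], Tlg[g, c])
                        A += alpha[g, c]
                    _fill_lgamma_table(A, TA[g])

        # ---- log probabilities: data likelihood (sum of segment marginals
        # ---- given labels/alphas) and the joint over (data, segmentation,
        # ---- labels | params) ----
        data_ll = 0.0
        ll = 0.0
        for j in range(n_seg):
            g = seg_labels[j]
            dm = _dm_from_tables(Tlg, TA, g, seg_counts[j], C)
            data_ll += dm
            ll += log_pi[g] + dm
        if N > 1:
            ll += n_cp * math.log(rho) + (N - 1 - n_cp) * math.log1p(-rho)

        data_ll_tr[it] = data_ll
        loglik_tr[it] = ll
        ncp_tr[it] = n_cp
        rho_tr[it] = rho
        for g in range(k):
            pi_tr[it, g] = pi[g]
            for c in range(C):
                alpha_tr[it, g, c] = alpha[g, c]

        # ---- store segmentation ----
        need = cp_off[it] + n_cp
        while need > cp_flat.shape[0]:
            new = np.empty(cp_flat.shape[0] * 2, np.int64)
            new[: cp_flat.shape[0]] = cp_flat
            cp_flat = new
        need_l = lab_off[it] + n_seg
        while need_l > lab_flat.shape[0]:
            new2 = np.empty(lab_flat.shape[0] * 2, np.int32)
            new2[: lab_flat.shape[0]] = lab_flat
            lab_flat = new2
        pos = cp_off[it]
        for j in range(1, n_seg):
            cp_flat[pos] = seg_starts[j]
            pos += 1
        cp_off[it + 1] = pos
        posl = lab_off[it]
        for j in range(n_seg):
            lab_flat[posl] = lab_start[seg_starts[j]]
            posl += 1
        lab_off[it + 1] = posl

    acc_rate = n_acc / n_prop if n_prop > 0 else 0.0
    return (
        loglik_tr,
        data_ll_tr,
        ncp_tr,
        rho_tr,
        pi_tr,
        alpha_tr,
        cp_flat[: cp_off[n_iter]],
        cp_off,
        lab_flat[: lab_off[n_iter]],
        lab_off,
        acc_rate,
    )
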