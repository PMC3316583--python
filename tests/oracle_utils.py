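"""Independent brute-force oracles used by the model tests.

These deliberately avoid the package's samplers and DP code paths: the
posterior is enumerated over every boundary configuration, with segment
marginals computed through scipy's gammaln.
"""

from itertools import product

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln, logsumexp


def dm_log(counts, alpha):
    counts = np.asarray(counts, float)
    alpha = np.asarray(alpha, float)
    return (gammaln(alpha.sum()) - gammaln(alpha.sum() + counts.sum())
            + np.sum(gammaln(alpha + counts) - gammaln(alpha)))


def enumerate_posterior(codes, pi, alphas, rho, n_codes=3):
    """Exact posterior by enumeration over all 2^(N-1) boundary configs.

    Returns (boundary_probs[N-1], position_class_probs[N, k], log_evidence).
    """
    codes = np.asarray(codes)
    N = len(codes)
    k = len(pi)
    log_pi = np.log(pi)
    log_w = []
    configs = list(product([0, 1], repeat=N - 1))
    seg_post = []  # per config: list of (start, end, class posterior)
    for mask in configs:
        cps = [i + 1 for i, b in enumerate(mask) if b]
        starts = [0] + cps
        ends = cps + [N]
        lw = sum(mask) * np.log(rho) + (N - 1 - sum(mask)) * np.log1p(-rho)
        post = []
        for a, b in zip(starts, ends):
            counts = np.bincount(codes[a:b], minlength=n_codes)
            seg = np.array([log_pi[g] + dm_log(counts, alphas[g])
                            for g in range(k)])
            lse = logsumexp(seg)
            lw += lse
            post.append((a, b, np.exp(seg - lse)))
        log_w.append(lw)
        seg_post.append(post)
    log_w = np.array(log_w)
    log_z = logsumexp(log_w)
    w = np.exp(log_w - log_z)
    boundary = np.zeros(N - 1)
    pos_class = np.zeros((N, k))
    for wi, mask, post in zip(w, configs, seg_post):
        boundary += wi * np.array(mask)
        for a, b, pc in post:
            pos_class[a:b] += wi * pc
    return boundary, pos_class, log_z


def batch_mean_se(x, n_batches=20):
    """Monte-Carlo standard error of the mean via batch means."""
    x = np.asarray(x, float)
    n = (len(x) // n_batches) * n_batches
    batches = x[:n].reshape(n_batches, -1).mean(axis=1)
    return batches.std(ddof=1) / np.sqrt(n_batches)


def permutation_accuracy(true_labels, pred_labels, k):
    """Positionwise accuracy under the best class permutation."""
    conf = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            conf[a, b] = np.sum((true_labels == a + 1) & (pred_labels == b + 1))
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / len(true_labels)
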