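"""Bayesian multiple change-point mixture model for categorical code sequences.

The model: unknown changepoints partition a sequence of conservation codes
into segments; each segment carries a latent class label ``g`` drawn from
mixture weights ``pi``; within a segment the codes are i.i.d. categorical
with proportions drawn from a class-specific ``Dirichlet(alpha_g)`` (the
proportions are integrated out analytically, leaving a Dirichlet-multinomial
segment marginal).  Boundaries between adjacent characters are independently
changepoints with probability ``rho``.

Priors: ``rho ~ Beta(1, 1)``, ``pi ~ Dirichlet(1, .., 1)``, each ``alpha``
component log-uniform on (1e-3, 1e6).

Posterior inference is by MCMC (:class:`ChangepointModel` / ``fit``), a
collapsed Gibbs sweep over boundaries plus conjugate ``pi``/``rho`` updates
and Metropolis moves on ``alpha`` (log-space random walk plus an anchored
independence proposal).  Per-position class-membership profiles are
averaged over post-burn-in samples after canonical relabelling by
conservation level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .alignment import CodeSequence, GenomicRegion
from . import _kernel

__all__ = [
    "Segmentation",
    "ClassParams",
    "Sample",
    "SampleChain",
    "ProfileMatrix",
    "segment_log_marginal",
    "joint_log_prob",
    "mcmc_run",
    "compute_profiles",
    "information_criteria",
    "marginal_log_likelihood",
    "select_k_aic",
    "convergence_diagnostics",
    "ConvergenceReport",
    "write_wiggle",
    "read_wiggle",
    "ChangepointModel",
    "ChangepointResults",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Segmentation:
    """Interior changepoints (between-character indices in 1..N-1, strictly
    increasing) and a 1-based class label per segment."""

    changepoints: np.ndarray
    labels: np.ndarray
    n_positions: int

    def __post_init__(self) -> None:
        self.changepoints = np.asarray(self.changepoints, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        cps = self.changepoints
        if len(cps) and not (
            np.all(np.diff(cps) > 0)
            and cps[0] >= 1
            and cps[-1] <= self.n_positions - 1
        ):
            raise ValueError("changepoints must be strictly increasing in "
                             "1..N-1")
        if len(self.labels) != len(cps) + 1:
            raise ValueError("need exactly one more label than changepoints")
        if len(self.labels) and self.labels.min() < 1:
            raise ValueError("labels are 1-based")

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate(([0], self.changepoints))

    @property
    def ends(self) -> np.ndarray:
        return np.concatenate((self.changepoints, [self.n_positions]))

    def position_labels(self) -> np.ndarray:
        """1-based class label at every position."""
        return np.repeat(self.labels, self.ends - self.starts)


@dataclass
class ClassParams:
    """alpha: (k, C) Dirichlet parameters; pi: mixture weights; rho:
    per-boundary changepoint probability."""

    alpha: np.ndarray
    pi: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be positive")
        if self.pi.shape[0] != self.alpha.shape[0]:
            raise ValueError("pi and alpha disagree on the class count")
        if abs(self.pi.sum() - 1.0) > 1e-8 or np.any(self.pi < 0):
            raise ValueError("pi must lie on the simplex")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must be in (0, 1)")

    @property
    def k(self) -> int:
        return self.alpha.shape[0]


@dataclass
class Sample:
    segmentation: Segmentation
    params: ClassParams
    log_likelihood: float


@dataclass
class SampleChain:
    """Ordered MCMC samples plus flat per-iteration traces."""

    k: int
    n_positions: int
    n_symbols: int
    seed: int
    codes: np.ndarray
    log_likelihood: np.ndarray
    data_log_likelihood: np.ndarray
    n_changepoints: np.ndarray
    rho_trace: np.ndarray
    pi_trace: np.ndarray          # (n_iter, k)
    alpha_trace: np.ndarray       # (n_iter, k, C)
    _cp_flat: np.ndarray = field(repr=False, default=None)
    _cp_off: np.ndarray = field(repr=False, default=None)
    _lab_flat: np.ndarray = field(repr=False, default=None)
    _lab_off: np.ndarray = field(repr=False, default=None)
    alpha_acceptance: float = float("nan")
    region: GenomicRegion | None = None

    def __len__(self) -> int:
        return len(self.log_likelihood)

    def segmentation(self, it: int) -> Segmentation:
        cps = self._cp_flat[self._cp_off[it]:self._cp_off[it + 1]]
        labs = self._lab_flat[self._lab_off[it]:self._lab_off[it + 1]]
        return Segmentation(cps.copy(), labs.astype(np.int64) + 1,
                            self.n_positions)

    def sample(self, it: int) -> Sample:
        params = ClassParams(
            self.alpha_trace[it].copy(), self.pi_trace[it].copy(),
            float(self.rho_trace[it]),
        )
        return Sample(self.segmentation(it), params,
                      float(self.log_likelihood[it]))

    def __iter__(self):
        return (self.sample(i) for i in range(len(self)))


@dataclass
class ProfileMatrix:
    """Per-position posterior class-membership probabilities (rows sum to 1)."""

    values: np.ndarray  # (N, k)
    region: GenomicRegion | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("profile must be 2-D (positions x classes)")
        rs = self.values.sum(axis=1)
        if len(rs) and np.max(np.abs(rs - 1.0)) > 1e-9:
            raise ValueError("profile rows must sum to 1")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def class_profile(self, class_index: int) -> np.ndarray:
        """1-based class column."""
        if not 1 <= class_index <= self.k:
            raise ValueError(f"class_index must be in 1..{self.k}")
        return self.values[:, class_index - 1]

    def argmax_classes(self) -> np.ndarray:
        """1-based argmax class per position (ties -> lowest class index)."""
        return self.values.argmax(axis=1) + 1


# ---------------------------------------------------------------------------
# reference (non-kernel) probability functions


def segment_log_marginal(counts, alpha) -> float:
    """Log marginal probability of one segment's ordered codes, with the
    segment's categorical proportions integrated out against Dirichlet(alpha).

    ``log Gamma(A)/Gamma(A+n) + sum_c log Gamma(alpha_c+n_c)/Gamma(alpha_c)``
    """
    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    A = alpha.sum()
    n = counts.sum()
    return float(
        gammaln(A) - gammaln(A + n)
        + np.sum(gammaln(alpha + counts) - gammaln(alpha))
    )


def _segment_counts(codes: np.ndarray, seg: Segmentation,
                    C: int) -> np.ndarray:
    out = np.zeros((len(seg.labels), C), dtype=np.int64)
    for j, (a, b) in enumerate(zip(seg.starts, seg.ends)):
        out[j] = np.bincount(codes[a:b], minlength=C)
    return out


def joint_log_prob(seq, seg: Segmentation, params: ClassParams) -> float:
    """Log P(codes, segmentation, labels | pi, alpha, rho).

    Sum over segments of ``log pi_label + segment_log_marginal`` plus the
    Bernoulli(rho) boundary terms.  Hyperprior terms on (pi, rho, alpha) are
    constant in the quantities compared here and are omitted.
    """
    codes = seq.codes if isinstance(seq, CodeSequence) else np.asarray(seq)
    N = len(codes)
    k = params.k
    C = params.alpha.shape[1]
    if seg.n_positions != N:
        raise ValueError("segmentation does not match the sequence length")
    if seg.labels.max(initial=1) > k:
        raise ValueError(f"segment label outside 1..{k}")
    counts = _segment_counts(codes, seg, C)
    ll = 0.0
    for j, g in enumerate(seg.labels):
        ll += np.log(params.pi[g - 1])
        ll += segment_log_marginal(counts[j], params.alpha[g - 1])
    ncp = len(seg.changepoints)
    if N > 1:
        ll += ncp * np.log(params.rho) + (N - 1 - ncp) * np.log1p(-params.rho)
    return float(ll)


# ---------------------------------------------------------------------------
# sampler front end


def _default_init(k: int, C: int, concentration: float = 10.0) -> np.ndarray:
    """Deterministic staggered initial alpha: class means spread along the
    code-0 axis, the remainder split evenly over the other codes."""
    alpha = np.empty((k, C))
    for g in range(k):
        m0 = (g + 1.0) / (k + 1.0)
        alpha[g, 0] = m0 * concentration
        for c in range(1, C):
            alpha[g, c] = (1.0 - m0) / (C - 1) * concentration
    return alpha


def _moment_init(codes: np.ndarray, k: int, C: int, seed: int,
                 window: int = 100,
                 concentration: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matching initialisation: k-means on windowed code proportions.

    Clusters fixed non-overlapping windows of the sequence by their code
    composition and seeds each class's alpha at its cluster centre (scaled
    by a moderate concentration) and pi at the cluster shares.  Falls back
    to the staggered grid when the sequence is too short.
    """
    n_win = len(codes) // window
    if n_win < k:
        return _default_init(k, C), np.full(k, 1.0 / k)
    props = np.empty((n_win, C))
    for w in range(n_win):
        chunk = codes[w * window:(w + 1) * window]
        props[w] = np.bincount(chunk, minlength=C) / window
    from scipy.cluster.vq import kmeans2
    best = None
    for trial in range(10):
        with np.errstate(all="ignore"):
            c, a = kmeans2(props, k, minit="++",
                           seed=(seed + 101 * trial) % (2**31))
        inertia = float(np.sum((props - c[a]) ** 2))
        if best is None or inertia < best[0]:
            best = (inertia, c, a)
    _, centers, assign = best
    shares = np.bincount(assign, minlength=k).astype(float)
    # replace empty clusters by staggered defaults
    fallback = _default_init(k, C, concentration)
    alpha = np.empty((k, C))
    for g in range(k):
        if shares[g] == 0 or not np.all(np.isfinite(centers[g])):
            alpha[g] = fallback[g]
            shares[g] = 1.0
        else:
            m = np.clip(centers[g], 0.01, None)
            alpha[g] = m / m.sum() * concentration
    pi = shares / shares.sum()
    return alpha, np.clip(pi, 0.01, None) / np.clip(pi, 0.01, None).sum()


def mcmc_run(
    seq,
    k: int,
    n_iter: int = 1000,
    seed: int = 0,
    *,
    fixed_params: ClassParams | None = None,
    init_params: ClassParams | None = None,
    alpha_step: float = 0.3,
    adapt_frac: float = 0.5,
    alpha_bounds: tuple[float, float] = (1e-3, 1e6),
    pi_prior: float = 1.0,
    rho_prior: tuple[float, float] = (1.0, 1.0),
    rho_init: float = 0.01,
    alpha_inner: int = 2,
    n_symbols: int | None = None,
) -> SampleChain:
    """Run the sampler and return the chain of posterior samples.

    With ``fixed_params`` the hyperparameters (pi, alpha, rho) are held at
    the given values and only the segmentation and labels are sampled —
    the configuration used for exact small-N validation.
    """
    if isinstance(seq, CodeSequence):
        codes = seq.codes
        C = n_symbols or seq.n_symbols
        region = seq.region
    else:
        codes = np.asarray(seq, dtype=np.int8)
        C = n_symbols or max(3, int(codes.max(initial=0)) + 1)
        region = None
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(codes) == 0:
        raise ValueError("empty code sequence")
    seed = int(seed) % (2**31)

    if fixed_params is not None:
        init = fixed_params
        update = False
    elif init_params is not None:
        init = init_params
        update = True
    else:
        alpha0, pi0 = _moment_init(codes, k, C, seed)
        init = ClassParams(alpha0, pi0, rho_init)
        update = True
    if init.k != k or init.alpha.shape[1] != C:
        raise ValueError("initial/fixed params do not match k or code count")

    out = _kernel.run_chain(
        codes.astype(np.int8),
        C,
        k,
        n_iter,
        seed,
        init.pi.astype(float),
        init.alpha.astype(float),
        float(init.rho),
        update,
        update,
        update,
        alpha_step,
        int(adapt_frac * n_iter) if update else 0,
        np.log(alpha_bounds[0]),
        np.log(alpha_bounds[1]),
        pi_prior,
        rho_prior[0],
        rho_prior[1],
        alpha_inner,
    )
    (loglik, data_ll, ncp, rho_tr, pi_tr, alpha_tr,
     cp_flat, cp_off, lab_flat, lab_off, acc) = out
    if update and k > 1:
        _canonical_relabel(pi_tr, alpha_tr, lab_flat, lab_off)
    return SampleChain(
        k=k, n_positions=len(codes), n_symbols=C, seed=seed,
        codes=codes.astype(np.int8),
        log_likelihood=loglik, data_log_likelihood=data_ll,
        n_changepoints=ncp, rho_trace=rho_tr,
        pi_trace=pi_tr, alpha_trace=alpha_tr,
        _cp_flat=cp_flat, _cp_off=cp_off,
        _lab_flat=lab_flat, _lab_off=lab_off,
        alpha_acceptance=float(acc), region=region,
    )


def _canonical_relabel(pi_tr, alpha_tr, lab_flat, lab_off) -> None:
    """Resolve label switching: relabel every sample so classes are ordered
    by decreasing code-0 mean proportion (alpha_0 / sum alpha), ties broken
    by total concentration.  Class 1 is then always the most conserved.

    Operates in place on the traces and the flat label storage.
    """
    n_iter = pi_tr.shape[0]
    k = pi_tr.shape[1]
    for it in range(n_iter):
        a = alpha_tr[it]
        m0 = a[:, 0] / a.sum(axis=1)
        order = np.lexsort((a.sum(axis=1), -m0))
        if np.array_equal(order, np.arange(k)):
            continue
        inv = np.empty(k, dtype=np.int32)
        inv[order] = np.arange(k, dtype=np.int32)
        pi_tr[it] = pi_tr[it][order]
        alpha_tr[it] = a[order]
        sl = slice(lab_off[it], lab_off[it + 1])
        lab_flat[sl] = inv[lab_flat[sl]]


def compute_profiles(chain: SampleChain, burn_in: int) -> ProfileMatrix:
    """profile(i, g) = fraction of post-burn-in samples in which position i
    lies in a segment labelled g."""
    if burn_in >= len(chain):
        raise ValueError(
            f"burn_in {burn_in} >= chain length {len(chain)}"
        )
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    N, k = chain.n_positions, chain.k
    acc = np.zeros((N, k), dtype=np.int64)
    n_used = 0
    for it in range(burn_in, len(chain)):
        cps = chain._cp_flat[chain._cp_off[it]:chain._cp_off[it + 1]]
        labs = chain._lab_flat[chain._lab_off[it]:chain._lab_off[it + 1]]
        starts = np.concatenate(([0], cps))
        ends = np.concatenate((cps, [N]))
        for a, b, g in zip(starts, ends, labs):
            acc[a:b, g] += 1
        n_used += 1
    return ProfileMatrix(acc / n_used, region=chain.region)


def marginal_log_likelihood(seq, params: ClassParams,
                            max_segment: int | None = None) -> float:
    """Log P(codes | pi, alpha, rho), with segmentations and labels
    marginalised by dynamic programming (O(N^2 k) exact, or
    O(N * max_segment * k) when segments are capped at ``max_segment``)."""
    codes = seq.codes if isinstance(seq, CodeSequence) else \
        np.asarray(seq, dtype=np.int8)
    return float(_kernel.marginal_loglik(
        codes.astype(np.int8), params.alpha.shape[1],
        np.log(params.pi), params.alpha.astype(float), float(params.rho),
        0 if max_segment is None else int(max_segment),
    ))


def _chain_param_candidates(chain: SampleChain, burn_in: int,
                            n_candidates: int = 2):
    """Candidate hyperparameter estimates: the posterior mean and,
    optionally, the retained sample with the highest data
    log-likelihood."""
    sl = slice(burn_in, len(chain))
    pi_m = chain.pi_trace[sl].mean(axis=0)
    cands = [ClassParams(
        chain.alpha_trace[sl].mean(axis=0), pi_m / pi_m.sum(),
        float(chain.rho_trace[sl].mean()),
    )]
    if n_candidates > 1:
        best = burn_in + int(np.argmax(chain.data_log_likelihood[sl]))
        pi_b = chain.pi_trace[best]
        cands.append(ClassParams(
            chain.alpha_trace[best].copy(), pi_b / pi_b.sum(),
            float(chain.rho_trace[best]),
        ))
    return cands


def information_criteria(
    chains, burn_in: int = 500, dic_draws: int = 8,
    max_segment: int | None = None, candidates: int = 2,
) -> pd.DataFrame:
    """AIC / BIC / DIC per class count, from the integrated likelihood.

    For each chain the likelihood is log P(data | pi, alpha, rho) with the
    segmentation and labels marginalised exactly (dynamic programming),
    maximised over two candidate estimates (posterior mean and the best
    retained sample).  The parameter count is ``C*k + (k-1) + 1`` (alphas,
    mixture weights, rho).  DIC uses the marginal deviance at ``dic_draws``
    thinned posterior draws (variance/2 flavour); pass ``dic_draws=0`` to
    skip the (comparatively slow) DIC column.
    """
    if isinstance(chains, dict):
        chains = [chains[kk] for kk in sorted(chains)]
    rows = []
    for chain in chains:
        if burn_in >= len(chain):
            raise ValueError("empty post-burn-in window")
        k = chain.k
        p = chain.n_symbols * k + (k - 1) + 1
        ll = max(
            marginal_log_likelihood(chain.codes, params, max_segment)
            for params in _chain_param_candidates(chain, burn_in,
                                                  candidates)
        )
        row = {
            "k": k,
            "n_params": p,
            "log_likelihood": ll,
            "AIC": -2.0 * ll + 2.0 * p,
            "BIC": -2.0 * ll + p * np.log(chain.n_positions),
            "DIC": np.nan,
        }
        if dic_draws > 0:
            idx = np.linspace(burn_in, len(chain) - 1, dic_draws).astype(int)
            devs = []
            for it in idx:
                pi = chain.pi_trace[it]
                params = ClassParams(chain.alpha_trace[it].copy(),
                                     pi / pi.sum(),
                                     float(chain.rho_trace[it]))
                devs.append(-2.0 * marginal_log_likelihood(
                    chain.codes, params, max_segment))
            devs = np.asarray(devs)
            row["DIC"] = float(devs.mean() + devs.var(ddof=1) / 2.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")


def select_k_aic(ic_table: pd.DataFrame) -> int:
    """Class count at the AIC minimum (lowest k on ties)."""
    return int(ic_table["AIC"].idxmin())


@dataclass
class ConvergenceReport:
    traces: pd.DataFrame
    drift_flag: bool
    drift_z: float

    def to_tsv(self, path) -> None:
        self.traces.to_csv(path, sep="\t", index=False)


def convergence_diagnostics(chain: SampleChain) -> ConvergenceReport:
    """Per-iteration traces (log-likelihood, changepoint count, pi, alpha)
    plus a first-half/second-half drift flag on the log-likelihood.

    The flag is raised when the two half-means differ by more than three
    pooled standard errors.
    """
    n = len(chain)
    cols = {
        "iteration": np.arange(n),
        "log_likelihood": chain.log_likelihood,
        "data_log_likelihood": chain.data_log_likelihood,
        "n_changepoints": chain.n_changepoints,
        "rho": chain.rho_trace,
    }
    for g in range(chain.k):
        cols[f"pi_{g + 1}"] = chain.pi_trace[:, g]
    for g in range(chain.k):
        for c in range(chain.n_symbols):
            cols[f"alpha_{g + 1}_{c}"] = chain.alpha_trace[:, g, c]
    traces = pd.DataFrame(cols)
    half = n // 2
    z = 0.0
    if half >= 2:
        a = chain.log_likelihood[:half]
        b = chain.log_likelihood[n - half:]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        z = abs(a.mean() - b.mean()) / se if se > 0 else 0.0
    return ConvergenceReport(traces, bool(z > 3.0), float(z))


# ---------------------------------------------------------------------------
# wiggle export


def write_wiggle(profile: ProfileMatrix, class_index: int, chrom: str,
                 start: int | None = None, precision: int = 6) -> str:
    """fixedStep WIG text for one class profile (browser 1-based start).

    ``start`` is the 0-based reference start; defaults to the profile's
    region start (or 0).
    """
    if start is None:
        start = profile.region.start if profile.region is not None else 0
    vals = profile.class_profile(class_index)
    lines = [f"fixedStep chrom={chrom} start={start + 1} step=1 span=1"]
    lines.extend(f"{v:.{precision}f}" for v in vals)
    return "\n".join(lines) + "\n"


def read_wiggle(text: str) -> tuple[str, int, np.ndarray]:
    """Parse fixedStep WIG text -> (chrom, 0-based start, values)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0]
    if not header.startswith("fixedStep"):
        raise ValueError("only fixedStep WIG is supported")
    fields = dict(tok.split("=") for tok in header.split()[1:])
    chrom = fields["chrom"]
    start = int(fields["start"]) - 1
    vals = np.array([float(x) for x in lines[1:]])
    return chrom, start, vals


# ---------------------------------------------------------------------------
# statsmodels-style front end


class ChangepointModel:
    """Change-point mixture model bound to a code sequence.

    Parameters
    ----------
    data
        CodeSequence or integer array of codes.
    k
        Number of latent conservation classes.

    Examples
    --------
    >>> from consegment import simulate, ChangepointModel
    >>> truth = simulate.simulate_codes(length=2000, seed=1)
    >>> res = ChangepointModel(truth.codes, k=4).fit(seed=1)
    >>> res.profiles.values.shape
    (2000, 4)
    """

    def __init__(self, data, k: int = 4, *, n_symbols: int | None = None,
                 pi_prior: float = 1.0,
                 rho_prior: tuple[float, float] = (1.0, 1.0),
                 alpha_bounds: tuple[float, float] = (1e-3, 1e6)):
        if isinstance(data, CodeSequence):
            self.data = data
        else:
            self.data = CodeSequence(np.asarray(data, dtype=np.int8),
                                     n_symbols=n_symbols or 3)
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.n_symbols = n_symbols or self.data.n_symbols
        self.pi_prior = pi_prior
        self.rho_prior = rho_prior
        self.alpha_bounds = alpha_bounds

    @classmethod
    def from_code_sequence(cls, codeseq: CodeSequence, k: int = 4, **kw):
        return cls(codeseq, k=k, **kw)

    @classmethod
    def from_alignment(cls, columns, k: int = 4,
                       region: GenomicRegion | None = None, **kw):
        from .alignment import encode_region
        return cls(encode_region(columns, region=region), k=k, **kw)

    def fit(self, n_iter: int = 1000, burn_in: int = 500, seed: int = 0,
            **sampler_kw) -> "ChangepointResults":
        if burn_in >= n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        chain = mcmc_run(
            self.data, self.k, n_iter=n_iter, seed=seed,
            pi_prior=self.pi_prior, rho_prior=self.rho_prior,
            alpha_bounds=self.alpha_bounds, n_symbols=self.n_symbols,
            **sampler_kw,
        )
        return ChangepointResults(self, chain, burn_in)


class ChangepointResults:
    """Posterior summaries of a fitted change-point model."""

    def __init__(self, model: ChangepointModel, chain: SampleChain,
                 burn_in: int):
        self.model = model
        self.chain = chain
        self.burn_in = burn_in
        self._profiles: ProfileMatrix | None = None

    @property
    def profiles(self) -> ProfileMatrix:
        if self._profiles is None:
            self._profiles = compute_profiles(self.chain, self.burn_in)
        return self._profiles

    @property
    def n_retained(self) -> int:
        return len(self.chain) - self.burn_in

    @property
    def posterior_mean_n_changepoints(self) -> float:
        return float(self.chain.n_changepoints[self.burn_in:].mean())

    @property
    def posterior_mean_pi(self) -> np.ndarray:
        return self.chain.pi_trace[self.burn_in:].mean(axis=0)

    @property
    def posterior_mean_alpha(self) -> np.ndarray:
        return self.chain.alpha_trace[self.burn_in:].mean(axis=0)

    @property
    def posterior_mean_rho(self) -> float:
        return float(self.chain.rho_trace[self.burn_in:].mean())

    def class_code_proportions(self) -> np.ndarray:
        """Posterior-mean code proportions per class, alpha_g / sum(alpha_g)."""
        a = self.posterior_mean_alpha
        return a / a.sum(axis=1, keepdims=True)

    def most_conserved_class(self) -> int:
        """1-based index of the class with the highest mean code-0 proportion
        (the class tracking protein-coding-style conservation)."""
        return int(np.argmax(self.class_code_proportions()[:, 0])) + 1

    def convergence_diagnostics(self) -> ConvergenceReport:
        return convergence_diagnostics(self.chain)

    def to_wig(self, class_index: int, chrom: str | None = None,
               start: int | None = None) -> str:
        region = self.chain.region
        if chrom is None:
            chrom = region.chrom if region is not None else "chrN"
        return write_wiggle(self.profiles, class_index, chrom, start)

    def summary(self) -> str:
        lines = [
            "Change-point mixture model (MCMC)",
            "=" * 44,
            f"positions            {self.chain.n_positions}",
            f"classes (k)          {self.chain.k}",
            f"iterations           {len(self.chain)} "
            f"(burn-in {self.burn_in})",
            f"seed                 {self.chain.seed}",
            f"mean changepoints    {self.posterior_mean_n_changepoints:.1f}",
            f"mean rho             {self.posterior_mean_rho:.3g}",
            f"alpha MH acceptance  {self.chain.alpha_acceptance:.2f}",
            "",
            "class   pi      code proportions (alpha / sum alpha)",
        ]
        props = self.class_code_proportions()
        pi = self.posterior_mean_pi
        for g in range(self.chain.k):
            pr = " ".join(f"{p:.3f}" for p in props[g])
            lines.append(f"  {g + 1}    {pi[g]:.3f}   {pr}")
        rep = self.convergence_diagnostics()
        lines.append("")
        lines.append(
            f"log-likelihood drift z = {rep.drift_z:.2f} "
            f"({'FLAGGED' if rep.drift_flag else 'ok'})"
        )
        return "\n".join(lines)
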