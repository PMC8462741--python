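"""Continuous-state Bayesian change-point segmentation of binomial site counts.

The model: converted counts X_t ~ Binomial(n, theta_t) at informative sites
tau_1 < ... < tau_N, with theta piecewise constant.  Latent indicators
I_t ~ Bernoulli(p_t) mark sites where theta changes (I_1 = 1 by convention);
on a change, the new theta is drawn from a Beta(mu0, nu0) prior in mean /
sample-size form.  Change priors follow a Poisson boundary process along the
base-pair axis, p_t = 1 - exp(-lambda * (tau_t - tau_{t-1})), so irregular
C spacing is handled naturally.

Exact posteriors are computed by forward/backward dynamic programming over
segment hypotheses.  For a segment i..j of m sites the conjugate update is

    nu_{i:j} = nu0 + m n,   mu_{i:j} = (nu0 mu0 + X_{i:j}) / (nu0 + m n)

and the segment's normalizing constant is c_{i,j} = 1 / B(mu_{i:j} nu_{i:j},
(1 - mu_{i:j}) nu_{i:j}); c_0 is the analogous prior constant, so the ratio
c_0 / c_{i,j} is the segment's Beta-binomial marginal likelihood up to
binomial coefficients.  All recursions run in log space.

An exact enumeration oracle over all 2^(N-1) change configurations
(:func:`enumerate_posterior_oracle`) provides an independent check of every
posterior quantity on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

from .io import SiteCounts

EPS_MU = 1e-6

# lambda (changes per bp) grid for the empirical-Bayes marginal-likelihood search
DEFAULT_LAMBDA_GRID = np.logspace(-4, 0, 40)


@dataclass
class Hyperparams:
    """Prior specification: Beta(mu0, nu0) on new rates, Poisson(lam) boundaries.

    ``p`` holds the per-site change priors p_t (p_1 = 1); ``n`` is the
    binomial size shared by all sites.
    """

    mu0: float
    nu0: float
    lam: float
    p: np.ndarray
    n: float

    def __post_init__(self) -> None:
        if not 0 < self.mu0 < 1:
            raise ValueError("mu0 must lie in (0, 1)")
        if self.nu0 <= 0 or self.lam <= 0 or self.n <= 0:
            raise ValueError("nu0, lam and n must be positive")
        self.p = np.asarray(self.p, dtype=float)
        if self.p[0] != 1.0:
            raise ValueError("p_1 must be 1 (a change at the first site is certain)")

    @classmethod
    def from_counts(
        cls,
        counts: SiteCounts,
        lam: float,
        mu0: float | None = None,
        nu0: float | None = None,
    ) -> "Hyperparams":
        """Empirical-Bayes hyperparameters: nu0 = n, mu0 = sample mean."""
        est_mu0, est_nu0 = estimate_mu0_nu0(counts)
        return cls(
            mu0=est_mu0 if mu0 is None else mu0,
            nu0=est_nu0 if nu0 is None else nu0,
            lam=lam,
            p=change_priors(counts.positions, lam),
            n=counts.n,
        )


@dataclass
class SegmentPosterior:
    """Conjugate Beta posterior for one candidate segment i..j (1-based, inclusive)."""

    i: int
    j: int
    X_ij: float
    mu_ij: float
    nu_ij: float
    log_c_ij: float


@dataclass
class SegmentationResult:
    """Posterior summaries of one segmentation run.

    ``p_fwd[t-1, i-1]`` is p_{i,t} (Eq: most recent change at tau_i given
    x_{1:t}); ``q_bwd[t-1, j-1]`` is q_{j,t+1} with the diagonal holding the
    'segment ends at t' mass p_{t+1}.  Rows of both sum to one.  Segment
    weights w_{i,j,t} are recomputed on demand by :meth:`segment_weights`.
    """

    positions: np.ndarray
    p_fwd: np.ndarray
    q_bwd: np.ndarray
    theta_mean: np.ndarray
    change_prob: np.ndarray
    log_marginal: float
    hyper: Hyperparams
    counts: SiteCounts

    def segment_weights(self, t: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Posterior weights w_{i,j,t} over segments covering site t (1-based).

        Returns (i_idx, j_idx, w) arrays of equal length; w sums to 1.
        """
        i_idx, j_idx, w, _ = _segment_weights_at(
            t, self.p_fwd, self.q_bwd, _log_c_table(self.counts, self.hyper),
            _log_c0(self.hyper), self.hyper,
        )
        return i_idx, j_idx, w


def estimate_mu0_nu0(counts: SiteCounts) -> tuple[float, float]:
    """Empirical-Bayes prior: nu0 = n and mu0 = sample mean sum(x)/(N n)."""
    if counts.n <= 0:
        raise ValueError("n must be positive")
    mu0 = float(counts.x.sum() / (counts.n_sites * counts.n))
    mu0 = min(max(mu0, EPS_MU), 1.0 - EPS_MU)
    return mu0, float(counts.n)


def change_priors(positions: np.ndarray, lam: float) -> np.ndarray:
    """p_1 = 1; p_t = 1 - exp(-lam * (tau_t - tau_{t-1})) for t > 1."""
    positions = np.asarray(positions, dtype=float)
    p = np.empty(positions.size)
    p[0] = 1.0
    p[1:] = -np.expm1(-lam * np.diff(positions))
    return p


def scale_counts(counts: SiteCounts, target_n: float) -> SiteCounts:
    """Rescale (x, n) to a common n; posterior means are invariant, variances not."""
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    f = target_n / counts.n
    return SiteCounts(positions=counts.positions, x=counts.x * f, n=target_n)


def segment_posterior(counts: SiteCounts, i: int, j: int, hyper: Hyperparams) -> SegmentPosterior:
    """Conjugate posterior parameters of the segment spanning sites i..j."""
    N = counts.n_sites
    if not (1 <= i <= j <= N):
        raise ValueError(f"invalid segment ({i}, {j}) for N={N}")
    X = float(counts.x[i - 1 : j].sum())
    m = j - i + 1
    nu = hyper.nu0 + m * hyper.n
    mu = (hyper.nu0 * hyper.mu0 + X) / nu
    return SegmentPosterior(
        i=i, j=j, X_ij=X, mu_ij=mu, nu_ij=nu,
        log_c_ij=-betaln(mu * nu, (1.0 - mu) * nu),
    )


def segment_variance(counts: SiteCounts, i: int, j: int, hyper: Hyperparams) -> float:
    """Posterior variance of theta on segment i..j (mean/size Beta form)."""
    sp = segment_posterior(counts, i, j, hyper)
    return sp.mu_ij * (1.0 - sp.mu_ij) / (sp.nu_ij + 1.0)


def _log_c0(hyper: Hyperparams) -> float:
    return -betaln(hyper.mu0 * hyper.nu0, (1.0 - hyper.mu0) * hyper.nu0)


def _log_c_table(counts: SiteCounts, hyper: Hyperparams) -> np.ndarray:
    """log c_{i,j} for all 1 <= i <= j <= N, stored at [i-1, j-1].

    c_{i,j} is the reciprocal Beta-function normalizer of the segment's
    posterior Beta, so that log(c_0) - log(c_{i,j}) is the segment's
    Beta-binomial log marginal likelihood without binomial coefficients.
    """
    N = counts.n_sites
    a0 = hyper.mu0 * hyper.nu0
    b0 = (1.0 - hyper.mu0) * hyper.nu0
    csum = np.concatenate([[0.0], np.cumsum(counts.x)])
    logc = np.full((N, N), np.nan)
    for i in range(N):
        X = csum[i + 1 :] - csum[i]  # X_{i+1 : j+1} for j >= i (0-based)
        m = np.arange(1, N - i + 1, dtype=float)
        logc[i, i:] = -betaln(a0 + X, b0 + m * hyper.n - X)
    return logc


def _log_binom_coeffs(counts: SiteCounts) -> float:
    """Sum over sites of log C(n, x_t), via gamma for real-valued counts."""
    n, x = counts.n, counts.x
    return float(np.sum(gammaln(n + 1.0) - gammaln(x + 1.0) - gammaln(n - x + 1.0)))


def forward(counts: SiteCounts, hyper: Hyperparams):
    """Forward filtering: p_{i,t} = Pr(most recent change at tau_i | x_{1:t}).

    Returns (p_fwd, log_norms) where p_fwd[t-1, i-1] = p_{i,t} and
    log_norms[t-1] = log sum_i p*_{i,t}, the per-site contribution to the
    marginal likelihood.
    """
    N = counts.n_sites
    logc = _log_c_table(counts, hyper)
    lc0 = _log_c0(hyper)
    p = hyper.p
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_1mp = np.log1p(-p)

    lp = np.full((N, N), -np.inf)  # lp[t-1, i-1] = log p_{i,t}
    log_norms = np.empty(N)
    prev = None  # log p_{i,t-1} for i-1 in 0..t-2
    for t in range(N):  # 0-based site index
        lstar = np.empty(t + 1)
        lstar[t] = log_p[t] + lc0 - logc[t, t]
        if t > 0:
            lstar[:t] = log_1mp[t] + prev + logc[:t, t - 1] - logc[:t, t]
        ln = logsumexp(lstar)
        if not np.isfinite(ln) or np.any(np.isnan(lstar)):
            raise FloatingPointError(f"non-finite forward weights at site {t + 1}")
        log_norms[t] = ln
        prev = lstar - ln
        lp[t, : t + 1] = prev
    return np.exp(lp), log_norms


def backward(counts: SiteCounts, hyper: Hyperparams) -> np.ndarray:
    """Backward recursion: q_{j,t+1} over j >= t, rows summing to one.

    q_bwd[t-1, t-1] holds the 'change at t+1' mass p_{t+1} (p_{N+1} := 1 at
    the sequence end); q_bwd[t-1, j-1] for j > t is the probability that the
    segment containing tau_t extends through tau_j, given x_{t+1:N}.
    """
    N = counts.n_sites
    logc = _log_c_table(counts, hyper)
    lc0 = _log_c0(hyper)
    p_ext = np.append(hyper.p, 1.0)  # p_{N+1} = 1: the end is a certain boundary
    with np.errstate(divide="ignore"):
        log_p_ext = np.log(p_ext)
        log_1mp_ext = np.log1p(-np.clip(p_ext, 0.0, 1.0))

    lq = np.full((N, N), -np.inf)  # lq[t-1, j-1] = log q_{j,t+1}
    lq[N - 1, N - 1] = 0.0  # q_{N,N+1} = p_{N+1} = 1
    for t in range(N - 2, -1, -1):  # 0-based; distribution q_{., t+1}
        # continuation segments: columns t+1..N-1; next row already holds
        # q_{j,t+2} including its diagonal 'immediate change' mass
        lq_next = lq[t + 1, t + 1 :]
        # empty leading segment (j = t+1) has normalizer c0
        log_c_tail = np.empty(N - t - 1)
        log_c_tail[0] = lc0
        if N - t - 1 > 1:
            log_c_tail[1:] = logc[t + 2, t + 2 : N]
        lstar = log_1mp_ext[t + 1] + lq_next + log_c_tail - logc[t + 1, t + 1 :]
        if p_ext[t + 1] >= 1.0:
            lq[t, t] = 0.0  # all mass on an immediate change
            continue
        ln = logsumexp(lstar)
        if not np.isfinite(ln) or np.any(np.isnan(lstar)):
            raise FloatingPointError(f"non-finite backward weights at site {t + 1}")
        lq[t, t] = log_p_ext[t + 1]
        lq[t, t + 1 :] = log_1mp_ext[t + 1] + (lstar - ln)
    return np.exp(lq)


def _segment_weights_at(t, p_fwd, q_bwd, logc, lc0, hyper):
    """Normalized w_{i,j,t} over {(i,j): i <= t <= j}; t is 1-based."""
    N = p_fwd.shape[0]
    t0 = t - 1
    with np.errstate(divide="ignore"):
        lp = np.log(p_fwd[t0, : t0 + 1])
        lq = np.log(q_bwd[t0, t0:])
    # lw[a, b]: segment from i = a+1 to j = t+b (1-based)
    lw = np.full((t0 + 1, N - t0), -np.inf)
    lw[:, 0] = lp + lq[0]  # j = t: ends exactly at t, no correction factor
    if N - t0 > 1:
        corr = (
            logc[: t0 + 1, [t0]]              # c_{i,t}
            + logc[t0 + 1, t0 + 1 :][None, :]  # c_{t+1,j}
            - logc[: t0 + 1, t0 + 1 :]        # c_{i,j}
            - lc0
        )
        lw[:, 1:] = lp[:, None] + lq[None, 1:] + corr
    log_norm = logsumexp(lw)
    w = np.exp(lw - log_norm)
    i_idx, j_idx = np.meshgrid(
        np.arange(1, t + 1), np.arange(t, N + 1), indexing="ij"
    )
    return i_idx.ravel(), j_idx.ravel(), w.ravel(), log_norm


def combine_weights(p_fwd, q_bwd, counts: SiteCounts, hyper: Hyperparams):
    """Posterior segment weights and theta means (smoothing step).

    Returns (theta_mean, log_w_norms) with log_w_norms[t-1] the per-site
    log normalizer of the raw weights w*_{i,j,t}, reused for the change
    probabilities.
    """
    N = counts.n_sites
    logc = _log_c_table(counts, hyper)
    lc0 = _log_c0(hyper)
    csum = np.concatenate([[0.0], np.cumsum(counts.x)])
    theta_mean = np.empty(N)
    log_w_norms = np.empty(N)
    for t in range(1, N + 1):
        i_idx, j_idx, w, log_norm = _segment_weights_at(t, p_fwd, q_bwd, logc, lc0, hyper)
        X = csum[j_idx] - csum[i_idx - 1]
        m = (j_idx - i_idx + 1).astype(float)
        mu = (hyper.nu0 * hyper.mu0 + X) / (hyper.nu0 + m * hyper.n)
        theta_mean[t - 1] = float(w @ mu)
        log_w_norms[t - 1] = log_norm
        if not np.isfinite(log_norm):
            raise FloatingPointError(f"zero segment-weight normalizer at site {t}")
    return theta_mean, log_w_norms


def change_probability(hyper: Hyperparams, log_w_norms: np.ndarray) -> np.ndarray:
    """Pr(I_{tau_t} = 1 | X) per site; 1 at t = 1 by convention.

    Pr(I_{t+1}=1 | X) = p_{t+1} / sum_{i<=t<=j} w*_{i,j,t}: with normalized
    weights this is sum_i w_{i,t,t}, the posterior mass on segments ending
    exactly at t.
    """
    N = log_w_norms.size
    cp = np.empty(N)
    cp[0] = 1.0
    if N > 1:
        cp[1:] = hyper.p[1:] * np.exp(-log_w_norms[:-1])
    return np.clip(cp, 0.0, 1.0)


def log_marginal_likelihood(counts: SiteCounts, hyper: Hyperparams) -> float:
    """log f(x_{tau_1..tau_N}): product over sites of forward normalizers,
    plus the binomial coefficients (constant in lambda)."""
    _, log_norms = forward(counts, hyper)
    return float(log_norms.sum() + _log_binom_coeffs(counts))


def fit_lambda(
    counts: SiteCounts,
    grid: np.ndarray | None = None,
    mu0: float | None = None,
    nu0: float | None = None,
):
    """Empirical-Bayes grid search for the Poisson change rate.

    Returns (lambda_hat, log_marginal_curve); ties resolve to the smallest
    grid value.
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    curve = np.array([
        log_marginal_likelihood(counts, Hyperparams.from_counts(counts, lam, mu0, nu0))
        for lam in grid
    ])
    return float(grid[int(np.argmax(curve))]), curve


def segment(
    counts: SiteCounts,
    lam: float | str = "auto",
    mu0: float | None = None,
    nu0: float | None = None,
    grid: np.ndarray | None = None,
) -> SegmentationResult:
    """Full segmentation: hyperparameters, forward/backward, posteriors."""
    if lam == "auto":
        lam, _ = fit_lambda(counts, grid=grid, mu0=mu0, nu0=nu0)
    hyper = Hyperparams.from_counts(counts, float(lam), mu0, nu0)
    p_fwd, log_norms = forward(counts, hyper)
    q_bwd = backward(counts, hyper)
    theta_mean, log_w_norms = combine_weights(p_fwd, q_bwd, counts, hyper)
    return SegmentationResult(
        positions=counts.positions,
        p_fwd=p_fwd,
        q_bwd=q_bwd,
        theta_mean=theta_mean,
        change_prob=change_probability(hyper, log_w_norms),
        log_marginal=float(log_norms.sum() + _log_binom_coeffs(counts)),
        hyper=hyper,
        counts=counts,
    )


def enumerate_posterior_oracle(counts: SiteCounts, hyper: Hyperparams):
    """Exact posterior by brute-force enumeration of change configurations.

    Sums over all 2^(N-1) settings of (I_2, ..., I_N); each configuration's
    weight is its Bernoulli prior times the product of Beta-binomial segment
    marginals.  Independent of the dynamic-programming path; N <= 14 only.

    Returns (theta_mean, change_prob, log_marginal).
    """
    N = counts.n_sites
    if N > 14:
        raise ValueError("oracle enumeration limited to N <= 14")
    a0 = hyper.mu0 * hyper.nu0
    b0 = (1.0 - hyper.mu0) * hyper.nu0
    lb0 = betaln(a0, b0)
    p = hyper.p
    x = counts.x
    n = hyper.n

    log_weights = []
    config_mu = []  # per-config vector of mu_{seg(t)} per site
    configs = list(itertools.product([0, 1], repeat=N - 1))
    for tail in configs:
        ind = (1,) + tail
        starts = [t for t in range(N) if ind[t] == 1]
        bounds = starts + [N]
        log_prior = sum(
            np.log(p[t]) if ind[t] else np.log1p(-p[t]) for t in range(1, N)
        )
        log_lik = 0.0
        mu_sites = np.empty(N)
        for s, e in zip(bounds[:-1], bounds[1:]):
            X = x[s:e].sum()
            m = e - s
            log_lik += betaln(a0 + X, b0 + m * n - X) - lb0
            mu_sites[s:e] = (hyper.nu0 * hyper.mu0 + X) / (hyper.nu0 + m * n)
        log_weights.append(log_prior + log_lik)
        config_mu.append(mu_sites)

    log_weights = np.asarray(log_weights)
    log_Z = logsumexp(log_weights)
    post = np.exp(log_weights - log_Z)
    theta_mean = post @ np.vstack(config_mu)
    change_prob = np.empty(N)
    change_prob[0] = 1.0
    ind_matrix = np.array([tail for tail in configs], dtype=float)
    if N > 1:
        change_prob[1:] = post @ ind_matrix
    log_marginal = float(log_Z + _log_binom_coeffs(counts))
    return theta_mean, change_prob, log_marginal
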