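"""Bayesian models of the trial features and sampling-based Bayes factors.

Three models are used throughout the analyses, all operating on
standardised log-features (natural log, centred, scaled to unit pooled
sample SD):

* a hierarchical normal model for RMS error / trajectory peak time, with a
  congruence-group mean ``mu_c ~ Normal(0, 0.75)``, cell means
  ``mu_{p,s,d} ~ Normal(mu_c[p], 0.75)`` and cell SDs
  ``sigma_{p,s,d} ~ HalfNormal(1)`` per participant x scale x day cell;
* a simpler per-cell model for single-channel peak amplitude / peak time
  with ``mu_{p,s,d} ~ Normal(0, 1)`` and the same SD prior;
* a bivariate normal model for the (first, second) channel peak-time pairs
  with ``mu ~ Normal(0, 0.1)``, ``sigma ~ Exponential(0.5)`` and a
  uniform (LKJ shape 1) prior on the correlation.

Posteriors are sampled with the affine-invariant ensemble MCMC sampler
(emcee) over explicit log-posteriors; walkers are treated as chains for the
R-hat diagnostic.  Bayes factors are posterior-odds ratios estimated from
prior and posterior draw proportions: for a reduction from ``x_a`` to
``x_b``,

    BF10 = [Pr(x_b < x_a | X) / Pr(x_b >= x_a | X)]
         / [Pr(x_b < x_a)     / Pr(x_b >= x_a)].

Zero counts are replaced by 1/(N+1) and flagged, so reported values are
finite bounds rather than infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd

MIN_DRAWS = 4000
_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# feature transform

@dataclass(frozen=True)
class TransformedFeature:
    """Standardised log-feature values with an invertible transform record."""

    values: np.ndarray
    centre: float  # mean of the log values
    scale: float   # sample SD (ddof=1) of the centred log values

    def inverse(self, v: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(v) * self.scale + self.centre)


def standardize_feature(raw: np.ndarray) -> TransformedFeature:
    """log -> centre -> scale to unit pooled sample SD.

    The log is taken first so that only strictly positive inputs are
    accepted; centring before the log would make the transform undefined.
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("feature values must be strictly positive and finite")
    if np.ptp(x) == 0:
        raise ValueError("feature values have zero variance")
    logs = np.log(x)
    centre = float(logs.mean())
    scale = float(logs.std(ddof=1))
    if scale == 0.0:
        raise ValueError("feature values have zero variance")
    return TransformedFeature((logs - centre) / scale, centre, scale)


# ---------------------------------------------------------------------------
# ensemble sampling machinery

@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    ``draws`` is the total number of kept posterior draws pooled across
    walkers (at least 4000 by default); ``burn`` is the number of discarded
    adaptation steps.
    """

    draws: int = MIN_DRAWS
    burn: int = 2000
    min_kept_steps: int = 300
    nwalkers: int | None = None
    seed: int = 0

    def walker_count(self, ndim: int) -> int:
        n = self.nwalkers or max(2 * ndim + 2, 64)
        return n + n % 2


@dataclass
class Diagnostics:
    rhat_max: float
    acceptance_mean: float
    n_draws: int
    converged: bool
    empty_cells: list = field(default_factory=list)


def _run_ensemble(
    log_prob, ndim: int, init: np.ndarray, config: SamplerConfig
) -> tuple[np.ndarray, Diagnostics]:
    """Run emcee with a vectorised log-posterior.

    Returns the flattened kept draws ``(n_draws, ndim)`` and diagnostics
    (max split-R-hat over parameters, walkers treated as chains).
    """
    nwalkers = config.walker_count(ndim)
    rng = np.random.default_rng(config.seed)
    p0 = init[None, :] + 0.1 * rng.standard_normal((nwalkers, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True,
                                    moves=moves)
    kept_steps = max(math.ceil(config.draws / nwalkers), config.min_kept_steps)
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed))
    state = sampler.run_mcmc(state, config.burn + kept_steps, progress=False)
    chain = sampler.get_chain(discard=config.burn)  # (steps, walkers, ndim)
    # pool walker groups into four pseudo-chains for the split-R-hat
    # diagnostic (individual walkers hold too few draws each)
    g = (nwalkers // 4) * 4
    pooled = (
        np.swapaxes(chain[:, :g, :], 0, 1)
        .reshape(4, g // 4 * chain.shape[0], ndim)
    )
    rhat_ds = az.rhat(az.convert_to_dataset(pooled))
    rhat_max = float(rhat_ds["x"].max())
    diag = Diagnostics(
        rhat_max=rhat_max,
        acceptance_mean=float(np.mean(sampler.acceptance_fraction)),
        n_draws=int(chain.shape[0] * chain.shape[1]),
        converged=rhat_max <= 1.05,
    )
    return chain.reshape(-1, ndim), diag


def _norm_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI


# ---------------------------------------------------------------------------
# cell bookkeeping shared by the hierarchical and channel-feature models

def _cell_stats(
    data: pd.DataFrame, value_col: str
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Sufficient statistics (n, sum, sum of squares) per
    participant x scale x day cell."""
    grouped = data.groupby(["participant", "scale", "day"], sort=True)
    cells = grouped[value_col].agg(n="count", total="sum",
                                   ssq=lambda v: float((v**2).sum()))
    cells = cells.reset_index()
    return (
        cells,
        cells["n"].to_numpy(float),
        cells["total"].to_numpy(float),
        cells["ssq"].to_numpy(float),
    )


def _empty_cells(data: pd.DataFrame) -> list[tuple]:
    """Expected participant x scale x day combinations with no trials."""
    participants = data["participant"].unique()
    scales = data["scale"].unique()
    days = data["day"].unique()
    have = set(map(tuple, data[["participant", "scale", "day"]].itertuples(
        index=False, name=None)))
    return [
        (p, s, d)
        for p in participants for s in scales for d in days
        if (p, s, d) not in have
    ]


def _cell_inits(n, total, ssq):
    """Empirical per-cell means and log-SDs for walker initialisation."""
    n = np.asarray(n, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), 0.0)
        var = np.where(
            n > 1, (ssq - n * mean**2) / np.maximum(n - 1, 1), 1.0
        )
    log_sd = 0.5 * np.log(np.clip(var, 1e-3, 1e3))
    return mean, log_sd


def _marginal_cell_loglik(prior_mean, log_sigma, tau, n, ybar, S):
    """Cell log-likelihood with the cell mean integrated out.

    Each cell's mean has a Normal(prior_mean, tau) prior, so the marginal
    of the data is Gaussian with covariance sigma^2 I + tau^2 J; in terms
    of the per-cell count n, sample mean ybar and centred sum of squares S:

        -1/2 [ (n-1) log sigma^2 + log(sigma^2 + n tau^2)
               + S / sigma^2 + n (ybar - prior_mean)^2 / (sigma^2 + n tau^2)
               + n log 2 pi ].

    ``prior_mean``/``log_sigma`` have shape (walkers, cells).
    """
    var = np.exp(2.0 * log_sigma)
    vb = var + n * tau**2
    return np.sum(
        -0.5 * (
            (n - 1) * 2.0 * log_sigma + np.log(vb)
            + S / var + n * (ybar - prior_mean) ** 2 / vb
            + n * _LOG_2PI
        ),
        axis=-1,
    )


def _conditional_cell_means(prior_mean, sigma, tau, n, ybar, rng):
    """Exact conjugate draws of the cell means given (prior mean, sigma).

    Precision n/sigma^2 + 1/tau^2; one independent Gaussian draw per kept
    posterior draw and cell.
    """
    prec = n / sigma**2 + 1.0 / tau**2
    mean = (n * ybar / sigma**2 + prior_mean / tau**2) / prec
    return mean + rng.standard_normal(sigma.shape) / np.sqrt(prec)


def _prepare_model_data(
    data: pd.DataFrame, feature: str, transform: str = "log-standard"
) -> tuple[pd.DataFrame, TransformedFeature]:
    """Filter to valid, order-correct, no-feedback trials and standardise.

    ``transform``: "log-standard" (the default log / centre / unit-SD
    pipeline), "standard" (centre and scale without the log, for signed
    features) or "none" (observations used as-is, e.g. when the data are
    already on the model scale).
    """
    required = {"participant", "scale", "day", "order_correct", "feedback",
                feature}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns {sorted(missing)}")
    sel = data[
        data["order_correct"].astype(bool)
        & ~data["feedback"].astype(bool)
        & np.isfinite(data[feature])
    ].copy()
    if sel.empty:
        raise ValueError("no usable trials after order/feedback filtering")
    if transform == "log-standard":
        record = standardize_feature(sel[feature].to_numpy())
    elif transform == "standard":
        x = sel[feature].to_numpy(float)
        centre, scale = float(x.mean()), float(x.std(ddof=1))
        record = TransformedFeature((x - centre) / scale, centre, scale)
    elif transform == "none":
        x = sel[feature].to_numpy(float)
        record = TransformedFeature(x, 0.0, 1.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    sel["y"] = record.values
    return sel, record


# ---------------------------------------------------------------------------
# posterior containers

@dataclass
class HierarchicalPosterior:
    """Draws from the hierarchical (or per-cell) normal model.

    ``mu_c`` is None for the channel-feature model, which has no group
    level.  ``cells`` maps each column of ``mu``/``sigma`` to its
    (participant, scale, day) identity.
    """

    mu: np.ndarray            # (draws, n_cells)
    sigma: np.ndarray         # (draws, n_cells)
    cells: pd.DataFrame
    transform: TransformedFeature | None
    diagnostics: Diagnostics
    mu_c: np.ndarray | None = None   # (draws, n_groups)
    groups: list[str] | None = None

    def _select(self, participant=None, scale=None, day=None,
                participants=None) -> np.ndarray:
        mask = np.ones(len(self.cells), dtype=bool)
        if participant is not None:
            mask &= (self.cells["participant"] == participant).to_numpy()
        if participants is not None:
            mask &= self.cells["participant"].isin(participants).to_numpy()
        if scale is not None:
            mask &= (self.cells["scale"] == scale).to_numpy()
        if day is not None:
            mask &= (self.cells["day"] == day).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError("no cells match the requested selection")
        return idx

    def cell_mu(self, participant, scale, day) -> np.ndarray:
        return self.mu[:, self._select(participant, scale, day)[0]]

    def cell_sigma(self, participant, scale, day) -> np.ndarray:
        return self.sigma[:, self._select(participant, scale, day)[0]]

    def marginal_mean(self, scale=None, day=None,
                      participants=None) -> np.ndarray:
        """Across-participant marginal mean: a pure average of the matching
        cell-mean draws, draw by draw."""
        idx = self._select(scale=scale, day=day, participants=participants)
        return self.mu[:, idx].mean(axis=1)

    def marginal_sigma(self, scale=None, day=None,
                       participants=None) -> np.ndarray:
        idx = self._select(scale=scale, day=day, participants=participants)
        return self.sigma[:, idx].mean(axis=1)


# ---------------------------------------------------------------------------
# model 1: hierarchical RMS / peak-time model

GROUP_MU_SD = 0.75


def fit_hierarchical_model(
    data: pd.DataFrame,
    feature: str = "epsilon",
    config: SamplerConfig | None = None,
    group_col: str = "congruence",
    transform: str = "log-standard",
) -> HierarchicalPosterior:
    """Fit the hierarchical normal model to order-correct no-feedback trials.

    ``data`` is a tidy feature table with columns participant, scale, day,
    congruence, order_correct, feedback and the feature column.  The
    feature is log-standardised across all included trials by default.
    """
    config = config or SamplerConfig()
    sel, transform = _prepare_model_data(data, feature, transform)
    if group_col not in sel.columns:
        raise ValueError(f"data is missing the group column {group_col!r}")
    cells, n, total, ssq = _cell_stats(sel, "y")
    groups = sorted(sel[group_col].unique())
    p2g = (
        sel.drop_duplicates("participant")
        .set_index("participant")[group_col]
        .map({g: i for i, g in enumerate(groups)})
    )
    group_of_cell = p2g.loc[cells["participant"]].to_numpy()
    G, C = len(groups), len(cells)
    # the cell means are marginalised analytically (linear-Gaussian
    # hierarchy): the ensemble samples only (mu_c, log sigma) and each
    # mu_{p,s,d} is then drawn exactly from its Gaussian conditional
    ndim = G + C
    ybar = total / n
    S = ssq - n * ybar**2

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        mu_c = theta[:, :G]
        log_sigma = theta[:, G:]
        lp = _norm_logpdf(mu_c, GROUP_MU_SD).sum(axis=1)
        # HalfNormal(1) on sigma, sampled as log_sigma (Jacobian: +log_sigma)
        sigma = np.exp(log_sigma)
        lp += np.sum(-0.5 * sigma**2 + log_sigma, axis=1)
        lp += _marginal_cell_loglik(
            mu_c[:, group_of_cell], log_sigma, GROUP_MU_SD, n, ybar, S
        )
        return lp

    mu0, log_sd0 = _cell_inits(n, total, ssq)
    mu_c0 = np.array([
        mu0[group_of_cell == g].mean() if np.any(group_of_cell == g) else 0.0
        for g in range(G)
    ])
    init = np.concatenate([mu_c0, log_sd0])
    draws, diag = _run_ensemble(log_prob, ndim, init, config)
    diag.empty_cells = _empty_cells(sel)
    sigma = np.exp(draws[:, G:])
    mu = _conditional_cell_means(
        draws[:, :G][:, group_of_cell], sigma, GROUP_MU_SD, n, ybar,
        np.random.default_rng(config.seed + 1),
    )
    return HierarchicalPosterior(
        mu=mu,
        sigma=sigma,
        cells=cells,
        transform=transform,
        diagnostics=diag,
        mu_c=draws[:, :G],
        groups=groups,
    )


def sample_prior_hierarchical(
    cells: pd.DataFrame,
    groups: list[str],
    group_of_cell: np.ndarray,
    n_draws: int = MIN_DRAWS,
    seed: int = 0,
) -> HierarchicalPosterior:
    """Exact draws from the hierarchical model's joint prior, in the same
    container as a posterior (for Bayes-factor denominators)."""
    rng = np.random.default_rng(seed)
    G, C = len(groups), len(cells)
    mu_c = rng.normal(0.0, GROUP_MU_SD, size=(n_draws, G))
    mu = mu_c[:, group_of_cell] + rng.normal(0.0, GROUP_MU_SD, size=(n_draws, C))
    sigma = np.abs(rng.standard_normal((n_draws, C)))
    diag = Diagnostics(rhat_max=1.0, acceptance_mean=1.0,
                       n_draws=n_draws, converged=True)
    return HierarchicalPosterior(mu=mu, sigma=sigma, cells=cells,
                                 transform=None, diagnostics=diag,
                                 mu_c=mu_c, groups=list(groups))


# ---------------------------------------------------------------------------
# model 2: per-channel peak feature model

CHANNEL_MU_SD = 1.0


def fit_channel_feature_model(
    data: pd.DataFrame,
    feature: str,
    config: SamplerConfig | None = None,
    transform: str = "log-standard",
) -> HierarchicalPosterior:
    """Fit the per-cell normal model (no group level) to one channel's peak
    amplitude or peak time."""
    config = config or SamplerConfig()
    sel, transform = _prepare_model_data(data, feature, transform)
    cells, n, total, ssq = _cell_stats(sel, "y")
    C = len(cells)
    # cell means marginalised analytically as in the hierarchical model,
    # with a fixed Normal(0, 1) prior in place of the group mean
    ndim = C
    ybar = total / n
    S = ssq - n * ybar**2

    def log_prob(theta):
        log_sigma = np.atleast_2d(theta)
        lp = np.sum(-0.5 * np.exp(log_sigma) ** 2 + log_sigma, axis=1)
        lp += _marginal_cell_loglik(
            np.zeros_like(log_sigma), log_sigma, CHANNEL_MU_SD, n, ybar, S
        )
        return lp

    _, log_sd0 = _cell_inits(n, total, ssq)
    draws, diag = _run_ensemble(log_prob, ndim, log_sd0, config)
    diag.empty_cells = _empty_cells(sel)
    sigma = np.exp(draws)
    mu = _conditional_cell_means(
        np.zeros_like(sigma), sigma, CHANNEL_MU_SD, n, ybar,
        np.random.default_rng(config.seed + 1),
    )
    return HierarchicalPosterior(
        mu=mu,
        sigma=sigma,
        cells=cells,
        transform=transform,
        diagnostics=diag,
    )


def sample_prior_channel(
    cells: pd.DataFrame, n_draws: int = MIN_DRAWS, seed: int = 0
) -> HierarchicalPosterior:
    """Exact draws from the channel-feature model's prior."""
    rng = np.random.default_rng(seed)
    C = len(cells)
    mu = rng.normal(0.0, CHANNEL_MU_SD, size=(n_draws, C))
    sigma = np.abs(rng.standard_normal((n_draws, C)))
    diag = Diagnostics(rhat_max=1.0, acceptance_mean=1.0,
                       n_draws=n_draws, converged=True)
    return HierarchicalPosterior(mu=mu, sigma=sigma, cells=cells,
                                 transform=None, diagnostics=diag)


# ---------------------------------------------------------------------------
# model 3: channel peak-time correlation model

CORR_MU_SD = 0.1
CORR_SIGMA_RATE = 0.5


@dataclass
class CorrelationPosterior:
    mu: np.ndarray      # (draws, 2)
    sigma: np.ndarray   # (draws, 2)
    r: np.ndarray       # (draws,) off-diagonal correlation
    pairs: np.ndarray   # the observed (re-centred) pairs
    diagnostics: Diagnostics

    def covariance(self) -> np.ndarray:
        """S = diag(sigma) R diag(sigma) per draw, shape (draws, 2, 2)."""
        s1, s2 = self.sigma[:, 0], self.sigma[:, 1]
        S = np.empty((self.r.size, 2, 2))
        S[:, 0, 0] = s1**2
        S[:, 1, 1] = s2**2
        S[:, 0, 1] = S[:, 1, 0] = self.r * s1 * s2
        return S


def prepare_peak_time_pairs(
    first_peak: np.ndarray,
    second_peak: np.ndarray,
    first_initiation: np.ndarray,
) -> np.ndarray:
    """Subtract the first channel's initiation time from both peak times
    and re-centre each column to sample mean zero."""
    p = np.column_stack([
        np.asarray(first_peak, float) - np.asarray(first_initiation, float),
        np.asarray(second_peak, float) - np.asarray(first_initiation, float),
    ])
    return p - p.mean(axis=0, keepdims=True)


def fit_correlation_model(
    pairs: np.ndarray, config: SamplerConfig | None = None,
    min_pairs: int = 10,
) -> CorrelationPosterior:
    """Fit the bivariate-normal model to (first, second) peak-time pairs.

    The correlation is sampled as an unconstrained atanh-transformed
    parameter; the LKJ(1) prior is uniform on the correlation, so only the
    transform Jacobian enters the log-posterior.
    """
    config = config or SamplerConfig()
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must have shape (n, 2)")
    n = pairs.shape[0]
    if n < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs, got {n}")
    s1_obs = pairs[:, 0]
    s2_obs = pairs[:, 1]
    ssum = pairs.sum(axis=0)
    s11 = float((s1_obs**2).sum())
    s22 = float((s2_obs**2).sum())
    s12 = float((s1_obs * s2_obs).sum())

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        mu1, mu2 = theta[:, 0], theta[:, 1]
        log_s1, log_s2, z = theta[:, 2], theta[:, 3], theta[:, 4]
        r = np.tanh(z)
        # hard bound |r| < tanh(8): keeps the posterior proper when the
        # observed pairs are exactly collinear
        out_of_range = np.abs(z) > 8.0
        z = np.clip(z, -8.0, 8.0)
        r = np.tanh(z)
        lp = _norm_logpdf(mu1, CORR_MU_SD) + _norm_logpdf(mu2, CORR_MU_SD)
        # Exponential(0.5) on sigma with log-Jacobian
        for ls in (log_s1, log_s2):
            lp += math.log(CORR_SIGMA_RATE) - CORR_SIGMA_RATE * np.exp(ls) + ls
        # uniform prior on r in (-1, 1); tanh Jacobian
        lp += np.log1p(-(r**2))
        # bivariate normal likelihood from sufficient statistics
        v1, v2 = np.exp(2 * log_s1), np.exp(2 * log_s2)
        one_m_r2 = 1.0 - r**2
        q = (
            (s11 - 2 * mu1 * ssum[0] + n * mu1**2) / v1
            + (s22 - 2 * mu2 * ssum[1] + n * mu2**2) / v2
            - 2 * r * (s12 - mu1 * ssum[1] - mu2 * ssum[0] + n * mu1 * mu2)
            / np.sqrt(v1 * v2)
        )
        lp += (
            -n * (log_s1 + log_s2)
            - 0.5 * n * np.log(one_m_r2)
            - 0.5 * q / one_m_r2
            - n * _LOG_2PI
        )
        return np.where(out_of_range, -np.inf, lp)

    init = np.array([0.0, 0.0, math.log(max(s1_obs.std(), 1e-3)),
                     math.log(max(s2_obs.std(), 1e-3)), 0.0])
    draws, diag = _run_ensemble(log_prob, 5, init, config)
    return CorrelationPosterior(
        mu=draws[:, :2],
        sigma=np.exp(draws[:, 2:4]),
        r=np.tanh(draws[:, 4]),
        pairs=pairs,
        diagnostics=diag,
    )


def sample_prior_correlation(
    n_draws: int = MIN_DRAWS, seed: int = 0
) -> CorrelationPosterior:
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, CORR_MU_SD, size=(n_draws, 2))
    sigma = rng.exponential(1.0 / CORR_SIGMA_RATE, size=(n_draws, 2))
    r = rng.uniform(-1.0, 1.0, size=n_draws)
    diag = Diagnostics(rhat_max=1.0, acceptance_mean=1.0,
                       n_draws=n_draws, converged=True)
    return CorrelationPosterior(mu=mu, sigma=sigma, r=r,
                                pairs=np.empty((0, 2)), diagnostics=diag)


# ---------------------------------------------------------------------------
# Bayes factors

@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    hypothesis: str
    posterior_count: int
    posterior_total: int
    prior_count: int
    prior_total: int
    bounded: bool  # a zero count was replaced by 1/(N+1)

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _odds(count: int, total: int) -> tuple[float, bool]:
    if count == 0:
        return (1.0 / (total + 1)) / (1.0 - 1.0 / (total + 1)), True
    if count == total:
        p = 1.0 - 1.0 / (total + 1)
        return p / (1.0 - p), True
    p = count / total
    return p / (1.0 - p), False


def bayes_factor(
    posterior_a: np.ndarray,
    posterior_b: np.ndarray,
    prior_a: np.ndarray,
    prior_b: np.ndarray,
    hypothesis: str = "x_b < x_a",
    min_draws: int = MIN_DRAWS,
) -> BayesFactorResult:
    """Sampling-based Bayes factor for the reduction hypothesis x_b < x_a.

    All four inputs are draw vectors; the prior pair must be drawn from the
    same joint prior (pushed through the same marginalisation) as the
    posterior pair.
    """
    post_a, post_b = np.asarray(posterior_a), np.asarray(posterior_b)
    pri_a, pri_b = np.asarray(prior_a), np.asarray(prior_b)
    if post_a.shape != post_b.shape or pri_a.shape != pri_b.shape:
        raise ValueError("draw vectors must come in equal-length pairs")
    if post_a.size < min_draws or pri_a.size < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got "
                         f"{post_a.size} posterior / {pri_a.size} prior")
    post_count = int(np.sum(post_b < post_a))
    pri_count = int(np.sum(pri_b < pri_a))
    post_odds, post_bound = _odds(post_count, post_a.size)
    pri_odds, pri_bound = _odds(pri_count, pri_a.size)
    return BayesFactorResult(
        bf10=post_odds / pri_odds,
        hypothesis=hypothesis,
        posterior_count=post_count,
        posterior_total=post_a.size,
        prior_count=pri_count,
        prior_total=pri_a.size,
        bounded=post_bound or pri_bound,
    )


IMPROVER_BF_THRESHOLD = 3.0


def classify_improver(bf10: float) -> str:
    """Improver iff the Bayes factor in favour of a session-1-to-5
    reduction in posterior mean RMS strictly exceeds 3."""
    return "improver" if bf10 > IMPROVER_BF_THRESHOLD else "non-improver"
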