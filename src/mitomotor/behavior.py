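"""Censored lognormal mixture model for motor-test latencies.

Motor tests (beam traversal, pole descent) are scored as the time to
complete the task, with a ceiling of 60 s: a mouse that does not finish
is scored 60. Observed latencies therefore mix two regimes — outright
task failure and lognormally distributed completion times right-censored
at the ceiling:

    y' ~ omega * LogNormal(mu, sigma) + (1 - omega) * delta_60
    y  = y'  if y' < 60, else 60

``omega`` is the probability that a mouse completes the task at all;
``mu`` and ``sigma`` are the location and scale of the completion-time
distribution on the log scale. Because a score of 60 is produced both by
failure and by slow completion, the two are indistinguishable in the data
and the likelihood treats them jointly.

This module provides the likelihood, maximum-likelihood fitting with a
constrained-to-unconstrained reparameterization and deterministic
multi-starts, parametric-bootstrap confidence intervals, graphical model
assessment (predictive ECDF envelopes and Q-Q point sets), and the
per-animal median summary used for rank-based group comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

DEFAULT_CENSOR_POINT = 60.0

#: logit(omega) beyond which the estimate is reported as the boundary value.
_BOUNDARY_LOGIT = 12.0


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial: latency in seconds, censored at the ceiling."""

    animal_id: str
    genotype: str
    condition: str
    test: str
    trial_index: int
    latency_s: float
    censored: bool

    def __post_init__(self) -> None:
        if not self.latency_s > 0:
            raise ValueError(f"latency must be positive, got {self.latency_s}")
        if self.censored and not math.isclose(self.latency_s, DEFAULT_CENSOR_POINT):
            # Callers using a non-default ceiling construct records directly;
            # the invariant censored <=> latency == censor_point is enforced
            # at model entry where the censor point is known.
            pass


@dataclass(frozen=True)
class MixtureParams:
    """Parameters (omega, mu, sigma) of the censored lognormal mixture."""

    omega: float
    mu: float
    sigma: float
    censor_point: float = DEFAULT_CENSOR_POINT

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.censor_point > 0:
            raise ValueError("censor_point must be positive")


@dataclass
class MixtureFit:
    """Result of maximum-likelihood fitting.

    ``boundary`` flags estimates pinned at the edge of the parameter
    space: ``omega_at_1`` (no failure mass needed) or
    ``omega_at_0_degenerate`` (no completion ever observed, in which case
    mu and sigma are undefined and reported as NaN).
    """

    params: MixtureParams
    loglik: float
    converged: bool
    boundary: str  # none | omega_at_1 | omega_at_0_degenerate
    n_obs: int
    n_censored: int


@dataclass
class BootstrapResult:
    """Percentile confidence interval for one parameter."""

    parameter: str
    level: float
    lower: float
    upper: float
    n_replicates: int
    seed: int
    estimates: np.ndarray
    n_failed: int = 0


def _split_latencies(
    data: Sequence[TrialRecord] | np.ndarray, censor_point: float
) -> tuple[np.ndarray, int]:
    """Return (uncensored latencies, number censored)."""
    if isinstance(data, np.ndarray):
        y = np.asarray(data, dtype=float)
    else:
        y = np.array([t.latency_s for t in data], dtype=float)
    if y.size == 0:
        raise ValueError("no observations")
    if np.any(y <= 0) or np.any(y > censor_point):
        raise ValueError(f"latencies must lie in (0, {censor_point}]")
    censored = y >= censor_point
    return y[~censored], int(censored.sum())


def neg_log_likelihood(
    data: Sequence[TrialRecord] | np.ndarray,
    params: MixtureParams,
) -> float:
    """Negative log-likelihood of the censored mixture.

    Uncensored trials contribute ``omega * f_LN(y)``; trials at the
    ceiling contribute ``omega * (1 - F_LN(c)) + (1 - omega)``, i.e. a
    slow completer censored at ``c`` or an outright failure. The censored
    branch is accumulated with log-sum-exp for numerical stability.
    Returns ``+inf`` (zero likelihood), not an exception, when
    ``omega == 0`` coexists with uncensored trials.
    """
    y_unc, n_cens = _split_latencies(data, params.censor_point)
    omega, mu, sigma, c = params.omega, params.mu, params.sigma, params.censor_point

    nll = 0.0
    if y_unc.size:
        if omega == 0.0:
            return math.inf
        logf = stats.lognorm.logpdf(y_unc, s=sigma, scale=math.exp(mu))
        nll -= y_unc.size * math.log(omega) + float(logf.sum())
    if n_cens:
        log_sf = stats.lognorm.logsf(c, s=sigma, scale=math.exp(mu))
        if omega == 1.0:
            log_branch = log_sf
        elif omega == 0.0:
            log_branch = 0.0  # all mass on delta_60
        else:
            log_branch = float(
                special.logsumexp(
                    [math.log(omega) + log_sf, math.log1p(-omega)]
                )
            )
        nll -= n_cens * log_branch
    return nll


def _nll_unconstrained(
    theta: np.ndarray, log_y: np.ndarray, n_cens: int, log_c: float
) -> tuple[float, np.ndarray]:
    """NLL and gradient over (logit omega, mu, log sigma).

    The analytic gradient keeps bootstrap refits cheap; log-space
    softplus identities keep omega near the boundaries stable.
    """
    logit_w, mu, log_sigma = theta
    sigma = math.exp(log_sigma)
    w = special.expit(logit_w)
    # log omega = -softplus(-logit), log(1-omega) = -softplus(logit)
    log_w = -np.logaddexp(0.0, -logit_w)
    log_1mw = -np.logaddexp(0.0, logit_w)
    n_unc = log_y.size
    nll = 0.0
    grad = np.zeros(3)
    if n_unc:
        z = (log_y - mu) / sigma
        logf = -0.5 * z**2 - log_y - log_sigma - 0.5 * math.log(2 * math.pi)
        nll -= n_unc * log_w + float(logf.sum())
        grad[0] -= n_unc * (1.0 - w)
        grad[1] -= float(z.sum()) / sigma
        grad[2] -= float((z**2).sum()) - n_unc
    if n_cens:
        zc = (log_c - mu) / sigma
        log_sf = stats.norm.logsf(zc)
        log_b = float(np.logaddexp(log_w + log_sf, log_1mw))
        nll -= n_cens * log_b
        b = math.exp(log_b)
        sf = math.exp(log_sf)
        phi = math.exp(-0.5 * zc**2) / math.sqrt(2 * math.pi)
        grad[0] -= n_cens * w * (1.0 - w) * (sf - 1.0) / b
        grad[1] -= n_cens * w * phi / (sigma * b)
        grad[2] -= n_cens * w * phi * zc / b
    return nll, grad


def fit_mle(
    data: Sequence[TrialRecord] | np.ndarray,
    censor_point: float = DEFAULT_CENSOR_POINT,
    init: MixtureParams | None = None,
) -> MixtureFit:
    """Maximum-likelihood fit of (omega, mu, sigma).

    Fully uncensored data admit the closed-form lognormal MLE with
    ``omega`` pinned at 1. All-censored data are degenerate: completion
    is never observed, so (mu, sigma) are unidentifiable and the fit is
    flagged rather than invented. Otherwise the NLL is minimized over
    (logit omega, mu, log sigma) by L-BFGS-B from five deterministic
    starting points, keeping the best optimum; this guards against the
    multimodality typical of mixture likelihoods. Passing ``init``
    (e.g. the parameters a bootstrap replicate was simulated from)
    replaces the multi-start with a single warm start.
    """
    y_unc, n_cens = _split_latencies(data, censor_point)
    n_obs = y_unc.size + n_cens

    if y_unc.size == 0:
        # never saw a completion
        return MixtureFit(
            params=_degenerate_params(censor_point),
            loglik=0.0,  # all trials on delta_60 have likelihood 1
            converged=True,
            boundary="omega_at_0_degenerate",
            n_obs=n_obs,
            n_censored=n_cens,
        )

    if n_cens == 0:
        # closed-form lognormal MLE; omega = 1 is the boundary maximizer
        logs = np.log(y_unc)
        mu_hat = float(logs.mean())
        sigma_hat = float(np.sqrt(np.mean((logs - mu_hat) ** 2)))
        if sigma_hat <= 0:
            raise ValueError("insufficient data to identify (mu, sigma)")
        params = MixtureParams(1.0, mu_hat, sigma_hat, censor_point)
        return MixtureFit(
            params=params,
            loglik=-neg_log_likelihood(np.asarray(y_unc), params),
            converged=True,
            boundary="omega_at_1",
            n_obs=n_obs,
            n_censored=0,
        )

    if np.unique(y_unc).size < 2:
        raise ValueError("insufficient data to identify (mu, sigma)")

    logs = np.log(y_unc)
    if init is not None:
        w0 = min(max(init.omega, 1e-4), 1 - 1e-4)
        starts = [(w0, init.mu, max(init.sigma, 1e-6))]
    else:
        mu0 = float(np.log(np.median(y_unc)))
        sd0 = float(logs.std(ddof=0))
        if sd0 <= 0:
            sd0 = 0.25
        starts = [
            (0.25, mu0, sd0),
            (0.5, mu0, sd0),
            (0.9, mu0, sd0),
            (0.5, mu0, 2 * sd0),
            (0.9, mu0, 2 * sd0),
        ]

    log_c = math.log(censor_point)
    best = None
    any_converged = False
    for w0, m0, s0 in starts:
        theta0 = np.array([special.logit(w0), m0, math.log(s0)])
        res = optimize.minimize(
            _nll_unconstrained,
            theta0,
            args=(logs, n_cens, log_c),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)

    logit_w, mu_hat, log_sigma = best.x
    boundary = "none"
    if logit_w > _BOUNDARY_LOGIT:
        omega_hat, boundary = 1.0, "omega_at_1"
    elif logit_w < -_BOUNDARY_LOGIT:
        omega_hat, boundary = 0.0, "omega_at_0_degenerate"
    else:
        omega_hat = float(special.expit(logit_w))
    params = MixtureParams(omega_hat, float(mu_hat), float(math.exp(log_sigma)), censor_point)
    return MixtureFit(
        params=params,
        loglik=-float(best.fun),
        converged=any_converged,
        boundary=boundary,
        n_obs=n_obs,
        n_censored=n_cens,
    )


def _degenerate_params(censor_point: float) -> MixtureParams:
    """omega=0 with undefined (mu, sigma); sigma placeholder keeps validity."""
    p = MixtureParams.__new__(MixtureParams)
    object.__setattr__(p, "omega", 0.0)
    object.__setattr__(p, "mu", math.nan)
    object.__setattr__(p, "sigma", math.nan)
    object.__setattr__(p, "censor_point", censor_point)
    return p


def simulate_from_params(
    params: MixtureParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Forward-simulate n trial latencies from the generative model."""
    complete = rng.random(n) < params.omega
    y = np.full(n, params.censor_point, dtype=float)
    n_c = int(complete.sum())
    if n_c:
        draws = rng.lognormal(mean=params.mu, sigma=params.sigma, size=n_c)
        y[complete] = np.minimum(draws, params.censor_point)
    return y


def parametric_bootstrap(
    fit: MixtureFit,
    n_replicates: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> list[BootstrapResult]:
    """Percentile bootstrap CIs for (omega, mu, sigma).

    Each replicate simulates a dataset of the original size from the
    fitted parameters (Bernoulli(omega) completion; completers draw
    LogNormal(mu, sigma) censored at the ceiling; failures score the
    ceiling) and refits by ``fit_mle``. Per-replicate RNG streams derive
    from ``(seed, replicate index)`` so runs are reproducible and
    order-independent. Replicates whose refit raises are dropped and
    counted.
    """
    if fit.boundary == "omega_at_0_degenerate":
        raise ValueError("cannot bootstrap degenerate fit")
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")

    est = {"omega": [], "mu": [], "sigma": []}
    n_failed = 0
    for i in range(n_replicates):
        rng = np.random.default_rng([seed, i])
        y = simulate_from_params(fit.params, fit.n_obs, rng)
        try:
            refit = fit_mle(y, fit.params.censor_point, init=fit.params)
        except ValueError:
            n_failed += 1
            continue
        est["omega"].append(refit.params.omega)
        est["mu"].append(refit.params.mu)
        est["sigma"].append(refit.params.sigma)

    alpha = 1.0 - level
    results = []
    for name, values in est.items():
        arr = np.asarray(values, dtype=float)
        ok = arr[np.isfinite(arr)]
        if ok.size == 0:
            lower = upper = math.nan
        else:
            lower, upper = np.percentile(ok, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        results.append(
            BootstrapResult(
                parameter=name,
                level=level,
                lower=float(lower),
                upper=float(upper),
                n_replicates=len(values),
                seed=seed,
                estimates=arr,
                n_failed=n_failed,
            )
        )
    return results


def predictive_ecdf_envelope(
    fit: MixtureFit,
    data: Sequence[TrialRecord] | np.ndarray,
    n_draws: int = 1000,
    band_level: float = 0.95,
    seed: int = 0,
    n_grid: int = 121,
) -> dict:
    """Graphical model assessment: predictive ECDF band and Q-Q points.

    Simulates ``n_draws`` datasets of the observed size from the fit,
    computes each ECDF on a common latency grid, and returns pointwise
    lower/upper band quantiles together with the observed ECDF and the
    fraction of grid points where the observed ECDF lies inside the band.
    Q-Q points pair the sorted uncensored latencies with quantiles of the
    fitted completion distribution truncated at the censor point;
    censored observations do not enter the Q-Q set (their true times are
    unobserved).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    y_unc, n_cens = _split_latencies(data, fit.params.censor_point)
    n_obs = y_unc.size + n_cens
    y_obs = np.concatenate([y_unc, np.full(n_cens, fit.params.censor_point)])

    c = fit.params.censor_point
    grid = np.linspace(0.0, c, n_grid)
    rng = np.random.default_rng([seed, 0])
    sims = np.empty((n_draws, n_grid))
    for d in range(n_draws):
        y_sim = simulate_from_params(fit.params, n_obs, rng)
        sims[d] = np.searchsorted(np.sort(y_sim), grid, side="right") / n_obs

    alpha = 1.0 - band_level
    lower = np.quantile(sims, alpha / 2, axis=0)
    upper = np.quantile(sims, 1 - alpha / 2, axis=0)
    observed = np.searchsorted(np.sort(y_obs), grid, side="right") / n_obs
    inside = (observed >= lower) & (observed <= upper)

    # Q-Q: truncated completion distribution, plotting positions (i-1/2)/m
    qq_obs = np.sort(y_unc)
    m = qq_obs.size
    if m:
        p = (np.arange(1, m + 1) - 0.5) / m
        ln = stats.lognorm(s=fit.params.sigma, scale=math.exp(fit.params.mu))
        qq_theo = ln.ppf(p * ln.cdf(c))
    else:
        qq_theo = np.array([])

    return {
        "grid": grid,
        "lower": lower,
        "upper": upper,
        "observed_ecdf": observed,
        "fraction_inside": float(inside.mean()),
        "qq_observed": qq_obs,
        "qq_theoretical": qq_theo,
    }


def median_summary(trials: Iterable[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-animal median latency across trials, keeping group labels.

    Censoring makes trial means biologically uninformative (a 60 stands
    for an unobserved, arbitrarily long time), so the median — robust to
    the ceiling — is the per-animal summary used for group comparisons.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "animal_id": t.animal_id,
                    "genotype": t.genotype,
                    "condition": t.condition,
                    "test": t.test,
                    "latency_s": t.latency_s,
                }
                for t in trials
            ]
        )
    if df.empty:
        raise ValueError("no trials provided")
    labels = [c for c in ("genotype", "condition", "test") if c in df.columns]
    out = (
        df.groupby(["animal_id", *labels], sort=True, observed=True)["latency_s"]
        .median()
        .reset_index()
        .rename(columns={"latency_s": "median_latency_s"})
    )
    return out
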