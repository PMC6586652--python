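"""Bayesian state-space ("Kalman") filter for drift-rate time series.

The model treats a seal's observed drift rates r_k at times t_k as noisy
readings of a slowly varying buoyancy trajectory driven by mass (blubber)
accretion:

    rho_k = (m0 + delta_k) / (v0 + V * delta_k)        relative body density
    mu_k  = alpha * sign(rho_k - 1) * sqrt(|rho_k - 1|)   buoyancy (m/s)
    delta_k = delta_{k-1} + eta_k,  eta_k ~ N(0, tau_delta * (t_k - t_{k-1}))
    z_k ~ Bernoulli(p)                       dive k is inside the trajectory
    r_k ~ N(mu_k, tau_r_in)  if z_k = 1,  else  N(mu_k, tau_r_out)

Water density is the constant 1 (relative units), so rho_k - 1 is the
density difference that drives drifting; alpha is negative under the
positive-down depth convention (a denser-than-water seal sinks, r < 0).
The mass-increment random walk has a variance *rate* tau_delta, so the
variance of an increment grows linearly with the elapsed time between
dives (time is measured in days).

Inference is a Rao-Blackwellized MCMC: the binary inclusion variables z_k
are marginalized analytically in the two-component observation mixture,
the latent path delta_1..n is sampled with vectorized odd-even single-site
Metropolis sweeps plus a global shift move, and the hyperparameters
(alpha, tau_delta, tau_r_in, tau_r_out, p) with an adaptive joint
random-walk Metropolis step.  Multiple chains run in parallel (batched in
numpy) and convergence is monitored with split-R-hat.  The per-dive
posterior inclusion probability P(z_k = 1) is the Rao-Blackwellized
average of the Bernoulli posterior over retained draws.

Dives are accepted as final drift dives when P(z_k = 1) > 0.95 (strictly),
and the *observed* drift rates of accepted dives are retained, never the
smoothed posterior means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BuoyancyModel",
    "FitConfig",
    "FilteredTrajectory",
    "fit_trajectory_filter",
    "select_final_drift_dives",
    "simulate_series",
    "posterior_inclusion_probability",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class BuoyancyModel:
    """Parameters (and prior settings) of the buoyancy state-space model.

    Variances are true variances; ``tau_delta`` is a variance *rate* per
    day.  ``alpha`` maps the signed square-root density difference to a
    drift rate in m/s and is negative for positive-down depths.  ``m0`` is
    fixed at 1 (mass units are arbitrary); ``v0`` defaults to a
    moment-based calibration from the first observations so that m0/v0
    matches the seal's apparent initial relative density.  ``V`` — the
    volume added per unit mass added (inverse density of accreted tissue,
    approximately 1/0.9 for blubber) — is fixed: it is jointly
    non-identifiable with alpha from drift rates alone.
    """

    m0: float = 1.0
    v0: float | None = None  # None: calibrate from the first observations
    V: float = 1.1
    alpha: float = -1.5
    tau_delta: float = 1e-4
    tau_r_in: float = 4e-4  # (0.02 m/s)^2
    tau_r_out: float = 9e-2  # (0.30 m/s)^2
    p: float = 0.9

    # prior scales (half-normal on SDs, normal on log(-alpha), Beta on p)
    prior_log_neg_alpha_mean: float = float(np.log(1.5))
    prior_log_neg_alpha_sd: float = 0.5
    prior_sd_delta_scale: float = 0.2
    prior_sd_in_scale: float = 0.1
    prior_sd_out_extra_scale: float = 0.5
    prior_p_a: float = 9.0
    prior_p_b: float = 1.0
    prior_delta1_sd: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must be in (0, 1)")
        for name in ("tau_delta", "tau_r_in", "tau_r_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tau_r_out <= self.tau_r_in:
            raise ValueError("tau_r_out must exceed tau_r_in")
        if self.v0 is not None and self.v0 <= 0:
            raise ValueError("v0 must be > 0")


@dataclass
class FitConfig:
    """Sampler settings."""

    n_chains: int = 4
    n_warmup: int = 2000
    n_samples: int = 2000
    thin: int = 4
    rhat_max: float = 1.05
    acceptance_threshold: float = 0.95


@dataclass
class FilteredTrajectory:
    """Posterior summary of the trajectory filter for one seal.

    ``table`` has one row per dive: t (days), r (observed m/s), p_inside
    (posterior P(z_k = 1)), mu_post (posterior mean buoyancy, m/s) and
    ``accepted`` (p_inside strictly above the acceptance threshold).
    """

    table: pd.DataFrame
    posterior: dict[str, float]
    diagnostics: dict[str, float | bool]
    threshold: float = 0.95

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))


def _mu_from_delta(delta, m0, v0, V, alpha):
    vol = v0 + V * delta
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (m0 + delta) / vol
    diff = rho - 1.0
    mu = alpha * np.sign(diff) * np.sqrt(np.abs(diff))
    return np.where(vol > 0, mu, np.nan)


def posterior_inclusion_probability(r, mu, tau_r_in, tau_r_out, p):
    """P(z = 1 | r, mu, parameters) for the two-component mixture.

    Degenerates to p as tau_r_out -> tau_r_in, and to 0 as the residual
    grows with tau_r_out finite and well above tau_r_in.
    """
    resid2 = (np.asarray(r, dtype=float) - np.asarray(mu, dtype=float)) ** 2
    log_in = -0.5 * (resid2 / tau_r_in + np.log(tau_r_in))
    log_out = -0.5 * (resid2 / tau_r_out + np.log(tau_r_out))
    # numerically stable Bernoulli posterior
    a = np.log(p) + log_in
    b = np.log1p(-p) + log_out
    m = np.maximum(a, b)
    return np.exp(a - m) / (np.exp(a - m) + np.exp(b - m))


def _mixture_loglik(r, mu, tau_in, tau_out, p):
    resid2 = (r - mu) ** 2
    a = np.log(p) - 0.5 * (resid2 / tau_in + np.log(tau_in) + _LOG2PI)
    b = np.log1p(-p) - 0.5 * (resid2 / tau_out + np.log(tau_out) + _LOG2PI)
    m = np.maximum(a, b)
    return m + np.log(np.exp(a - m) + np.exp(b - m))


def simulate_series(
    model: BuoyancyModel,
    times: np.ndarray,
    seed: int | None = None,
    outlier_shift: float | None = None,
) -> pd.DataFrame:
    """Simulate (t_k, r_k, z_k, mu_k, delta_k) from the generative model.

    ``v0`` must be set on the model.  With ``outlier_shift`` given,
    out-of-trajectory observations (z_k = 0) are the in-trajectory value
    displaced by that constant instead of draws from the wide component —
    a convenient worst-case for testing outlier rejection.
    """
    if model.v0 is None:
        raise ValueError("simulate_series needs an explicit v0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be 1-D and strictly increasing")
    n = t.size
    gaps = np.diff(t, prepend=t[0])
    delta = np.empty(n)
    delta[0] = 0.0
    for k in range(1, n):
        delta[k] = delta[k - 1] + rng.normal(0.0, np.sqrt(model.tau_delta * gaps[k]))
    mu = _mu_from_delta(delta, model.m0, model.v0, model.V, model.alpha)
    z = rng.random(n) < model.p
    r = mu + rng.normal(0.0, np.sqrt(model.tau_r_in), n)
    if outlier_shift is None:
        r_out = mu + rng.normal(0.0, np.sqrt(model.tau_r_out), n)
    else:
        r_out = r + outlier_shift
    r = np.where(z, r, r_out)
    return pd.DataFrame({"t": t, "r": r, "z": z.astype(int), "mu": mu, "delta": delta})


# ---------------------------------------------------------------------------
# Sampler internals.  All state arrays are (n_chains, ...) so the chains
# advance in lock-step through vectorized numpy operations.
# ---------------------------------------------------------------------------


def _log_prior_hyper(a, log_sd_d, log_sd_in, log_extra, logit_p, model):
    # a = log(-alpha); half-normal priors on the SDs include the log-scale
    # Jacobian (exp terms); Beta prior on p includes the logit Jacobian.
    lp = -0.5 * ((a - model.prior_log_neg_alpha_mean) / model.prior_log_neg_alpha_sd) ** 2
    for log_s, scale in (
        (log_sd_d, model.prior_sd_delta_scale),
        (log_sd_in, model.prior_sd_in_scale),
        (log_extra, model.prior_sd_out_extra_scale),
    ):
        s = np.exp(log_s)
        lp += -0.5 * (s / scale) ** 2 + log_s
    # Beta(a, b) kernel plus the logit-transform Jacobian p(1-p)
    p = 1.0 / (1.0 + np.exp(-logit_p))
    lp += model.prior_p_a * np.log(p) + model.prior_p_b * np.log1p(-p)
    return lp


def _path_logdens(delta, gaps, tau_d, prior1_sd):
    # random-walk prior over the path, per chain
    inc = np.diff(delta, axis=1)
    var = tau_d[:, None] * gaps[None, 1:]
    lp = -0.5 * np.sum(inc**2 / var + np.log(var), axis=1)
    lp += -0.5 * (delta[:, 0] / prior1_sd) ** 2
    return lp


def fit_trajectory_filter(
    times,
    rates,
    model: BuoyancyModel | None = None,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> FilteredTrajectory:
    """Fit the trajectory filter to one seal's drift-rate series.

    Parameters
    ----------
    times : array of float
        Observation times in days, strictly increasing.
    rates : array of float
        Observed drift rates (m/s), one per dive.
    model, config
        Model priors/initial values and sampler settings.
    seed : int
        Seed for the (reproducible) sampler.

    Returns
    -------
    FilteredTrajectory with per-dive P(z_k = 1), posterior mean buoyancy,
    hyperparameter posterior means and convergence diagnostics.  A
    non-converged fit is returned flagged (``converged`` False) with a
    warning, never silently.
    """
    model = model or BuoyancyModel()
    config = config or FitConfig()
    t = np.asarray(times, dtype=float)
    r = np.asarray(rates, dtype=float)
    if t.ndim != 1 or t.size != r.size or t.size < 1:
        raise ValueError("times and rates must be equal-length 1-D arrays")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    n = t.size
    C = config.n_chains
    rng = np.random.default_rng(seed)

    # --- moment-based v0 calibration from the first observations ---------
    if model.v0 is None:
        # sinking (r0 < 0, alpha < 0) => rho0 > 1
        r0 = float(np.median(r[: min(10, n)]))
        rho0 = 1.0 + (r0 / model.alpha) ** 2 * (1.0 if r0 < 0 else -1.0)
        rho0 = float(np.clip(rho0, 0.9, 1.1))
        v0 = model.m0 / rho0
    else:
        v0 = model.v0
    m0, V = model.m0, model.V

    gaps = np.diff(t, prepend=t[0] - 1.0) if n > 1 else np.array([1.0])
    gaps = np.maximum(gaps, 1e-9)

    # --- initial state ---------------------------------------------------
    a0 = np.log(-model.alpha) if model.alpha < 0 else np.log(1.5)
    hyper = np.empty((C, 5))
    hyper[:, 0] = a0 + 0.05 * rng.standard_normal(C)
    hyper[:, 1] = 0.5 * np.log(model.tau_delta) + 0.1 * rng.standard_normal(C)
    hyper[:, 2] = 0.5 * np.log(model.tau_r_in) + 0.1 * rng.standard_normal(C)
    extra0 = max(np.sqrt(model.tau_r_out) - np.sqrt(model.tau_r_in), 1e-3)
    hyper[:, 3] = np.log(extra0) + 0.1 * rng.standard_normal(C)
    hyper[:, 4] = np.log(model.p / (1 - model.p)) + 0.1 * rng.standard_normal(C)

    # initialize the latent path from a rolling median of the observed
    # rates (inverting the buoyancy map), so the chains start near the
    # trajectory instead of inflating the in-component variance to cover a
    # flat path
    alpha_init = -np.exp(a0)
    win = min(11, n)
    mu_init = (
        pd.Series(r).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    q = mu_init / alpha_init
    rho_init = np.clip(1.0 + np.sign(q) * q**2, 0.85, 1.15)
    denom = 1.0 - rho_init * V
    denom = np.where(np.abs(denom) < 1e-3, -1e-3, denom)
    delta_init = (rho_init * v0 - m0) / denom
    delta = delta_init[None, :] + 0.001 * rng.standard_normal((C, n))

    def unpack(h):
        alpha = -np.exp(h[:, 0])
        tau_d = np.exp(2.0 * h[:, 1])
        tau_in = np.exp(2.0 * h[:, 2])
        sd_out = np.exp(h[:, 2]) + np.exp(h[:, 3])
        tau_out = sd_out**2
        p = 1.0 / (1.0 + np.exp(-h[:, 4]))
        return alpha, tau_d, tau_in, tau_out, p

    def obs_loglik_path(delta_, h):
        alpha, _, tau_in, tau_out, p = unpack(h)
        mu = _mu_from_delta(delta_, m0, v0, V, alpha[:, None])
        ll = _mixture_loglik(r[None, :], mu, tau_in[:, None], tau_out[:, None], p[:, None])
        return np.where(np.isnan(ll), -np.inf, ll)

    site_scale = np.full(C, 0.02)
    hyper_scale = np.full((C, 5), 0.15)
    shift_scale = np.full(C, 0.01)

    odd = np.arange(1, n, 2)
    even = np.arange(0, n, 2)

    n_keep = config.n_samples // config.thin
    keep_pz = np.zeros((C, n))
    keep_mu = np.zeros((C, n))
    keep_mu2 = np.zeros((C, n))
    kept = 0
    trace_scalar = {name: np.zeros((C, n_keep)) for name in
                    ("alpha", "tau_delta", "tau_r_in", "tau_r_out", "p", "mu_mean")}

    obs_ll = obs_loglik_path(delta, hyper)  # (C, n)

    def site_update(idx, accept_counter):
        nonlocal delta, obs_ll
        prop = delta.copy()
        prop[:, idx] += site_scale[:, None] * rng.standard_normal((C, idx.size))
        # local random-walk prior terms around each updated site
        def local_prior(d):
            _, tau_d, _, _, _ = unpack(hyper)
            lp = np.zeros((C, idx.size))
            left = idx - 1
            has_left = idx > 0
            if np.any(has_left):
                ii = idx[has_left]
                var = tau_d[:, None] * gaps[None, ii]
                lp[:, has_left] += -0.5 * (d[:, ii] - delta_ref[:, ii - 1]) ** 2 / var
            lp[:, ~has_left] += -0.5 * (d[:, idx[~has_left]] / model.prior_delta1_sd) ** 2
            has_right = idx < n - 1
            if np.any(has_right):
                ii = idx[has_right]
                var = tau_d[:, None] * gaps[None, ii + 1]
                lp[:, has_right] += -0.5 * (delta_ref[:, ii + 1] - d[:, ii]) ** 2 / var
            return lp

        delta_ref = delta  # neighbours fixed during a half-sweep
        cur_lp = local_prior(delta) + obs_ll[:, idx]
        prop_ll = obs_loglik_path(prop, hyper)
        new_lp = local_prior(prop) + prop_ll[:, idx]
        accept = np.log(rng.random((C, idx.size))) < (new_lp - cur_lp)
        delta[:, idx] = np.where(accept, prop[:, idx], delta[:, idx])
        obs_ll[:, idx] = np.where(accept, prop_ll[:, idx], obs_ll[:, idx])
        accept_counter += accept.mean()
        return accept_counter

    total_iters = config.n_warmup + config.n_samples
    site_acc = 0.0
    hyper_acc_coord = np.zeros((C, 5))
    check_every = 100

    for it in range(total_iters):
        site_acc = site_update(even, site_acc)
        if odd.size:
            site_acc = site_update(odd, site_acc)

        # global shift move (translates the whole path)
        shift = shift_scale * rng.standard_normal(C)
        prop = delta + shift[:, None]
        prop_ll = obs_loglik_path(prop, hyper)
        _, tau_d, _, _, _ = unpack(hyper)
        cur_lp = -0.5 * (delta[:, 0] / model.prior_delta1_sd) ** 2 + obs_ll.sum(axis=1)
        new_lp = -0.5 * (prop[:, 0] / model.prior_delta1_sd) ** 2 + prop_ll.sum(axis=1)
        acc = np.log(rng.random(C)) < (new_lp - cur_lp)
        delta = np.where(acc[:, None], prop, delta)
        obs_ll = np.where(acc[:, None], prop_ll, obs_ll)

        # hyperparameters: per-coordinate adaptive random-walk Metropolis
        cur = (
            _log_prior_hyper(hyper[:, 0], hyper[:, 1], hyper[:, 2], hyper[:, 3], hyper[:, 4], model)
            + _path_logdens(delta, gaps, unpack(hyper)[1], model.prior_delta1_sd)
            + obs_ll.sum(axis=1)
        )
        for j in range(5):
            prop_h = hyper.copy()
            prop_h[:, j] += hyper_scale[:, j] * rng.standard_normal(C)
            prop_ll = obs_loglik_path(delta, prop_h)
            new = (
                _log_prior_hyper(prop_h[:, 0], prop_h[:, 1], prop_h[:, 2], prop_h[:, 3], prop_h[:, 4], model)
                + _path_logdens(delta, gaps, unpack(prop_h)[1], model.prior_delta1_sd)
                + prop_ll.sum(axis=1)
            )
            acc = np.log(rng.random(C)) < (new - cur)
            hyper = np.where(acc[:, None], prop_h, hyper)
            obs_ll = np.where(acc[:, None], prop_ll, obs_ll)
            cur = np.where(acc, new, cur)
            hyper_acc_coord[:, j] += acc

        # adaptation during warmup
        if it < config.n_warmup and (it + 1) % check_every == 0:
            site_rate = site_acc / (2 * check_every)
            site_scale *= np.exp(np.clip(site_rate - 0.4, -0.5, 0.5))
            site_acc = 0.0
            hyper_rate = hyper_acc_coord / check_every
            hyper_scale *= np.exp(np.clip(hyper_rate - 0.44, -0.5, 0.5))
            hyper_acc_coord[:] = 0.0

        # accumulation after warmup
        if it >= config.n_warmup and (it - config.n_warmup) % config.thin == 0 and kept < n_keep:
            alpha, tau_d, tau_in, tau_out, p = unpack(hyper)
            mu = _mu_from_delta(delta, m0, v0, V, alpha[:, None])
            pz = posterior_inclusion_probability(
                r[None, :], mu, tau_in[:, None], tau_out[:, None], p[:, None]
            )
            keep_pz += pz
            keep_mu += mu
            keep_mu2 += mu**2
            trace_scalar["alpha"][:, kept] = alpha
            trace_scalar["tau_delta"][:, kept] = tau_d
            trace_scalar["tau_r_in"][:, kept] = tau_in
            trace_scalar["tau_r_out"][:, kept] = tau_out
            trace_scalar["p"][:, kept] = p
            trace_scalar["mu_mean"][:, kept] = mu.mean(axis=1)
            kept += 1

    keep_pz /= kept
    keep_mu /= kept

    # --- diagnostics: split-R-hat across chains --------------------------
    # The convergence gate uses the identified posterior functionals (mean
    # buoyancy, p and the observation variances).  alpha and tau_delta are
    # reported but not gated: they are only weakly identified when the
    # trajectory is nearly constant (they trade off against the latent
    # path), which is a property of the model, not of the sampler.
    diagnostics: dict[str, float | bool] = {}

    def _rhat(name: str) -> float:
        arr = trace_scalar[name][:, :kept]
        try:
            import arviz as az

            return float(az.rhat(az.convert_to_dataset(arr))["x"])
        except Exception:  # pragma: no cover - arviz is a declared dependency
            return _split_rhat(arr)

    for name in ("alpha", "tau_delta", "p", "tau_r_in", "tau_r_out", "mu_mean"):
        diagnostics[f"rhat_{name}"] = _rhat(name)
    gated = [diagnostics[f"rhat_{n}"] for n in ("mu_mean", "p", "tau_r_in", "tau_r_out")]
    gated = [g for g in gated if np.isfinite(g)]
    max_rhat = float(max(gated)) if gated else float("nan")
    diagnostics["max_rhat"] = max_rhat
    diagnostics["n_kept_draws"] = int(kept * C)
    diagnostics["converged"] = bool(C < 2 or kept < 4 or max_rhat < config.rhat_max)
    if not diagnostics["converged"]:
        warnings.warn(
            f"trajectory filter did not converge (max split-R-hat {max_rhat:.3f})",
            stacklevel=2,
        )

    p_inside = keep_pz.mean(axis=0)
    mu_post = keep_mu.mean(axis=0)
    table = pd.DataFrame(
        {
            "t": t,
            "r": r,
            "p_inside": p_inside,
            "mu_post": mu_post,
            "accepted": p_inside > config.acceptance_threshold,
        }
    )
    posterior = {
        name: float(trace_scalar[name][:, :kept].mean())
        for name in ("alpha", "tau_delta", "tau_r_in", "tau_r_out", "p")
    }
    posterior["v0"] = float(v0)
    return FilteredTrajectory(
        table=table,
        posterior=posterior,
        diagnostics=diagnostics,
        threshold=config.acceptance_threshold,
    )


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat for a (n_chains, n_draws) scalar trace."""
    C, N = chains.shape
    if N < 4:
        return np.nan
    half = N // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, nn = splits.shape
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = nn * means.var(ddof=1)
    if W <= 0:
        return np.nan
    var_hat = (nn - 1) / nn * W + B / nn
    return float(np.sqrt(var_hat / W))


def select_final_drift_dives(
    traj: FilteredTrajectory, threshold: float = 0.95
) -> pd.DataFrame:
    """Final drift dives: rows with P(z_k = 1) strictly above ``threshold``.

    The returned frame carries the *observed* drift rates ``r`` (the
    posterior means stay in ``mu_post`` for reference but are never
    substituted for the observations).  A dive at exactly the threshold is
    rejected.  The result may be empty.
    """
    tab = traj.table
    return tab.loc[tab["p_inside"] > threshold].reset_index(drop=True)
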