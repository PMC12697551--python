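"""Alternative calibration strategies to compare against conformal ReForm.

Three families, mirroring common practice in multi-site neuroimaging:

* **Refit** — discard the reference chart and fit a fresh naive interval in
  the calibration set alone (the fallback recommended by clinical reference
  interval guidelines when verification fails).
* **Harmonization** — location-scale adjustment of measurements across
  batches around a shared covariate model.  The ``scalar_scale`` variant
  (one variance ratio per batch, ComBat-GAM style) and the
  ``covariate_scale`` variant (per-batch offsets around a covariate-dependent
  log-scale model, ComBatLS style) are single-outcome implementations without
  empirical-Bayes pooling across outcomes.
* **Batch-adjusted location-scale-shape model** — the pooled BCT regression
  with per-batch offsets in both location and log-scale, shrunk toward zero
  by a ridge penalty as a deterministic stand-in for Gaussian random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from ._splines import SplineBasis, make_basis
from .bct import bct_loglik
from .errors import ConfigError, FitError
from .naive_models import (
    FitConfig,
    LSSModel,
    _design,
    fit_additive_quantile,
    fit_location_scale_shape,
    interval_from_model,
)
from .tabular_io import ReferenceInterval, records_to_frame

__all__ = [
    "HarmonizerConfig",
    "HarmonizationModel",
    "BatchAdjustedLSS",
    "refit_interval",
    "fit_harmonizer",
    "apply_harmonizer",
    "fit_batch_adjusted_lss",
]


def refit_interval(calibration_records, alpha: float,
                   model: str = "bct_lss",
                   config: FitConfig = FitConfig()) -> ReferenceInterval:
    """Fit a naive interval entirely in the calibration set.

    Fit failures (too few records, non-convergence) surface as
    :class:`FitError` so an experiment sweep can record them as failed
    trials rather than crash.
    """
    records = list(calibration_records)
    if model == "bct_lss":
        fitted = fit_location_scale_shape(records, config)
        interval = interval_from_model(fitted, alpha)
    elif model == "additive_qr":
        lo = fit_additive_quantile(records, alpha / 2, config)
        hi = fit_additive_quantile(records, 1 - alpha / 2, config)
        interval = interval_from_model((lo, hi), alpha)
    else:
        raise ConfigError(f"unknown naive model {model!r}")
    interval.provenance = "refit | " + interval.provenance
    return interval


# ---------------------------------------------------------------------------
# Location-scale harmonization


@dataclass(frozen=True)
class HarmonizerConfig:
    n_interior_knots: int = 6
    penalty: float = 1.0
    min_n_per_batch: int = 30
    reference_batch: str | None = None  # None -> pooled reference convention


@dataclass
class HarmonizationModel:
    """Fitted location-scale batch harmonizer.

    The shared mean model is ``m(x) = B(age) beta + beta_sex [sex=M]``; batch
    ``b`` observes ``m(x) + shift_b`` with scale either a scalar factor
    (``scalar_scale``) or ``exp(logscale(x) + log_gamma_b)``
    (``covariate_scale``).  Batch shifts/log-factors are centred so the
    sample-weighted mean batch is the pooled reference; a designated
    reference batch overrides that convention.
    """

    variant: str
    basis: SplineBasis
    beta_mean: np.ndarray
    batch_shifts: dict
    # scalar_scale: batch -> sd; covariate_scale: shared log-scale coefs + batch log offsets
    batch_scales: dict
    logscale_coefs: np.ndarray | None = None
    reference_batch: str | None = None
    pooled_scale: float = 1.0
    diagnostics: dict = field(default_factory=dict)

    def mean_for(self, ages, sexes, batch: str | None):
        m = _design(self.basis, ages, sexes) @ self.beta_mean
        if batch is None:  # pooled reference
            if self.reference_batch is not None:
                return m + self.batch_shifts[self.reference_batch]
            return m
        if batch not in self.batch_shifts:
            raise ConfigError(f"batch {batch!r} was not seen during harmonizer fitting")
        return m + self.batch_shifts[batch]

    def scale_for(self, ages, sexes, batch: str | None):
        n = len(np.atleast_1d(ages))
        if self.variant == "scalar_scale":
            if batch is None:
                base = (self.batch_scales[self.reference_batch]
                        if self.reference_batch is not None else self.pooled_scale)
                return np.full(n, base)
            if batch not in self.batch_scales:
                raise ConfigError(f"batch {batch!r} was not seen during harmonizer fitting")
            return np.full(n, self.batch_scales[batch])
        shared = _design(self.basis, ages, sexes) @ self.logscale_coefs
        if batch is None:
            off = (self.batch_scales[self.reference_batch]
                   if self.reference_batch is not None else 0.0)
            return np.exp(shared + off)
        if batch not in self.batch_scales:
            raise ConfigError(f"batch {batch!r} was not seen during harmonizer fitting")
        return np.exp(shared + self.batch_scales[batch])


def fit_harmonizer(records, variant: str = "covariate_scale",
                   config: HarmonizerConfig = HarmonizerConfig()) -> HarmonizationModel:
    """Estimate the shared covariate model and per-batch location/scale effects."""
    if variant not in ("scalar_scale", "covariate_scale"):
        raise ConfigError(f"unknown harmonizer variant {variant!r}")
    records = list(records)
    df = records_to_frame(records)
    batches = list(dict.fromkeys(df["batch"]))
    if len(batches) < 2:
        raise ConfigError("harmonization requires at least two batches")
    counts = df["batch"].value_counts()
    for b in batches:
        if counts[b] < config.min_n_per_batch:
            raise ConfigError(
                f"batch {b!r} has {counts[b]} records, below the minimum "
                f"{config.min_n_per_batch}"
            )
    if config.reference_batch is not None and config.reference_batch not in batches:
        raise ConfigError(f"reference batch {config.reference_batch!r} not in data")

    ages = df["age"].to_numpy()
    sexes = df["sex"].to_numpy(dtype=object)
    y = df["value"].to_numpy()
    try:
        basis = make_basis(ages, config.n_interior_knots)
    except ValueError as exc:
        raise FitError(str(exc)) from exc
    X = _design(basis, ages, sexes)
    m = basis.n_basis
    # batch dummies reference-coded to the first batch, recentred after the fit
    D = np.column_stack([(df["batch"] == b).to_numpy(float) for b in batches[1:]]) \
        if len(batches) > 1 else np.empty((len(df), 0))
    Z = np.hstack([X, D])
    P = np.zeros((Z.shape[1], Z.shape[1]))
    P[:m, :m] = basis.penalty()
    A = Z.T @ Z + config.penalty * P + 1e-8 * np.eye(Z.shape[1])
    coef = np.linalg.solve(A, Z.T @ y)
    beta = coef[: m + 1].copy()
    raw_shifts = {batches[0]: 0.0}
    raw_shifts.update({b: float(coef[m + 1 + j]) for j, b in enumerate(batches[1:])})
    weights = {b: counts[b] / len(df) for b in batches}
    grand = sum(weights[b] * raw_shifts[b] for b in batches)
    shifts = {b: raw_shifts[b] - grand for b in batches}
    beta[:m] += grand  # absorb the weighted-mean shift into the shared curve

    resid = y - (X @ beta + np.array([shifts[b] for b in df["batch"]]))
    batch_arr = df["batch"].to_numpy(dtype=object)

    if variant == "scalar_scale":
        scales = {
            b: float(np.std(resid[batch_arr == b], ddof=1)) for b in batches
        }
        pooled = float(np.sqrt(sum(weights[b] * scales[b] ** 2 for b in batches)))
        return HarmonizationModel(
            variant=variant, basis=basis, beta_mean=beta,
            batch_shifts=shifts, batch_scales=scales, pooled_scale=pooled,
            reference_batch=config.reference_batch,
            diagnostics={"n_obs": len(df), "batches": batches},
        )

    # covariate_scale: Gaussian ML for log sigma(x) = B g + g_sex M + log_gamma_b
    Zs = np.hstack([X, D])
    theta0 = np.zeros(Zs.shape[1])
    theta0[:m] = np.log(max(float(np.std(resid)), 1e-6))

    def fun_grad(theta):
        eta = np.clip(Zs @ theta, -20, 10)
        inv_var = np.exp(-2 * eta)
        nll = float(np.sum(eta + 0.5 * resid**2 * inv_var))
        pen_vec = config.penalty * (P @ theta)
        nll += 0.5 * float(theta @ pen_vec)
        grad = Zs.T @ (1.0 - resid**2 * inv_var) + pen_vec
        return nll, grad

    res = optimize.minimize(fun_grad, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12})
    if not np.isfinite(res.fun):
        raise FitError("log-scale model failed to converge", trace=[float(res.fun)])
    g = res.x[: m + 1].copy()
    raw_off = {batches[0]: 0.0}
    raw_off.update({b: float(res.x[m + 1 + j]) for j, b in enumerate(batches[1:])})
    grand_s = sum(weights[b] * raw_off[b] for b in batches)
    offs = {b: raw_off[b] - grand_s for b in batches}
    g[:m] += grand_s
    return HarmonizationModel(
        variant=variant, basis=basis, beta_mean=beta,
        batch_shifts=shifts, batch_scales=offs, logscale_coefs=g,
        reference_batch=config.reference_batch,
        diagnostics={"n_obs": len(df), "batches": batches,
                     "logscale_nll": float(res.fun)},
    )


def apply_harmonizer(model: HarmonizationModel, records):
    """Map records onto the harmonizer's reference scale.

    y* = m_ref(x) + (y - m_b(x)) / s_b(x) * s_ref(x); covariates, batch and
    group labels are unchanged.  Records from an unseen batch raise
    :class:`ConfigError`.
    """
    records = list(records)
    df = records_to_frame(records)
    ages = df["age"].to_numpy()
    sexes = df["sex"].to_numpy(dtype=object)
    y = df["value"].to_numpy()
    out = np.empty_like(y)
    m_ref = model.mean_for(ages, sexes, None)
    s_ref = model.scale_for(ages, sexes, None)
    for b in dict.fromkeys(df["batch"]):
        mask = (df["batch"] == b).to_numpy()
        m_b = model.mean_for(ages[mask], sexes[mask], b)
        s_b = model.scale_for(ages[mask], sexes[mask], b)
        out[mask] = m_ref[mask] + (y[mask] - m_b) / s_b * s_ref[mask]
    return [replace(r, value=float(v)) for r, v in zip(records, out)]


# ---------------------------------------------------------------------------
# Batch-adjusted BCT location-scale-shape model


@dataclass
class BatchAdjustedLSS:
    """Pooled BCT regression with ridge-shrunk batch offsets.

    Offsets enter the location (phenotype units) and the log-scale; the
    ridge weight corresponds to a Gaussian prior with standard deviation
    ``prior_sd`` on each offset, approximating a random batch effect.
    """

    base: LSSModel
    batches: list
    mu_offsets: dict
    logsigma_offsets: dict
    prior_sd: float

    def model_for_batch(self, batch: str) -> LSSModel:
        if batch not in self.mu_offsets:
            raise ConfigError(f"batch {batch!r} was not in the pooled fit")
        m = self.base.basis.n_basis
        beta_mu = self.base.beta_mu.copy()
        beta_mu[:m] += self.mu_offsets[batch]
        beta_sigma = self.base.beta_sigma.copy()
        beta_sigma[:m] += self.logsigma_offsets[batch]
        return replace(self.base, beta_mu=beta_mu, beta_sigma=beta_sigma)

    def interval_for_batch(self, batch: str, alpha: float) -> ReferenceInterval:
        interval = interval_from_model(self.model_for_batch(batch), alpha)
        interval.provenance = f"batch_adjusted_lss[{batch}] | " + interval.provenance
        return interval


def fit_batch_adjusted_lss(records, config: FitConfig = FitConfig(),
                           prior_sd: float = 0.1,
                           prior_sd_logsigma: float = 0.2) -> BatchAdjustedLSS:
    """Fit the pooled BCT model with shrunk per-batch location/scale offsets.

    ``prior_sd`` (phenotype units) and ``prior_sd_logsigma`` set the ridge
    weights 1/sd^2 on the location and log-scale offsets.  With a single
    batch the offsets shrink to zero and the fit reduces to
    :func:`fit_location_scale_shape`.
    """
    records = list(records)
    if len(records) < config.min_n:
        raise FitError(f"need at least {config.min_n} records (got {len(records)})")
    df = records_to_frame(records)
    batches = list(dict.fromkeys(df["batch"]))
    ages = df["age"].to_numpy()
    sexes = df["sex"].to_numpy(dtype=object)
    y = df["value"].to_numpy()
    if np.any(y <= 0):
        raise FitError("BCT regression requires strictly positive values")
    try:
        from .naive_models import _effective_knots
        basis = make_basis(ages, _effective_knots(len(records), config.n_interior_knots))
    except ValueError as exc:
        raise FitError(str(exc)) from exc
    X = _design(basis, ages, sexes)
    D = np.column_stack([(df["batch"] == b).to_numpy(float) for b in batches])
    m = basis.n_basis
    P = basis.penalty()
    lam = config.penalty
    K = len(batches)
    w_mu = 1.0 / prior_sd**2
    w_sig = 1.0 / prior_sd_logsigma**2
    nb = m + 1

    base_init = fit_location_scale_shape(records, config)
    theta0 = np.concatenate([
        base_init.beta_mu, np.zeros(K),
        base_init.beta_sigma, np.zeros(K),
        [base_init.nu, base_init.log_tau],
    ])
    trace = []

    def fun(theta):
        bmu, dmu = theta[:nb], theta[nb:nb + K]
        bsig, dsig = theta[nb + K:2 * nb + K], theta[2 * nb + K:2 * nb + 2 * K]
        nu, log_tau = theta[-2], theta[-1]
        mu = X @ bmu + D @ dmu
        if np.any(mu <= 0):
            return 1e10 + float(np.sum(np.minimum(mu, 0) ** 2))
        sigma = np.exp(np.clip(X @ bsig + D @ dsig, -20, 10))
        tau = np.exp(np.clip(log_tau, np.log(0.5), 16))
        try:
            ll = bct_loglik(y, mu, sigma, nu, tau)
        except FloatingPointError:
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        pen = 0.5 * lam * (bmu[:m] @ P @ bmu[:m] + bsig[:m] @ P @ bsig[:m])
        pen += 0.5 * w_mu * float(dmu @ dmu) + 0.5 * w_sig * float(dsig @ dsig)
        val = -ll + pen
        trace.append(val)
        return val

    with np.errstate(over="ignore", invalid="ignore"):
        res = optimize.minimize(
            fun, theta0, method="L-BFGS-B",
            options={"maxiter": config.max_iter * 2, "ftol": config.tol, "maxls": 50},
        )
    if not np.isfinite(res.fun) or res.fun >= 1e9 or res.status not in (0, 1):
        raise FitError(f"batch-adjusted BCT fit failed: {res.message}", trace=trace)
    bmu, dmu = res.x[:nb], res.x[nb:nb + K]
    bsig, dsig = res.x[nb + K:2 * nb + K], res.x[2 * nb + K:2 * nb + 2 * K]
    base = LSSModel(
        basis=basis, beta_mu=bmu, beta_sigma=bsig,
        nu=float(res.x[-2]), log_tau=float(np.clip(res.x[-1], np.log(0.5), 16)),
        penalty=lam,
        diagnostics={"penalized_loglik": -float(res.fun),
                     "n_iter": int(res.nit), "converged": bool(res.status == 0),
                     "n_obs": len(records), "n_batches": K},
    )
    return BatchAdjustedLSS(
        base=base, batches=batches,
        mu_offsets={b: float(dmu[j]) for j, b in enumerate(batches)},
        logsigma_offsets={b: float(dsig[j]) for j, b in enumerate(batches)},
        prior_sd=prior_sd,
    )
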