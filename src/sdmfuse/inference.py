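"""Model fitting (empirical-Bayes MAP + Laplace) and prediction maps.

The latent state (α, β, γ, z, b) is Gaussian given the Matérn
hyperparameters θ = (log ρ, log σ) per field, and every observation model
is log-concave in the linear predictor, so the inner problem is solved by
a damped Newton iteration with analytic gradient and Hessian.  The outer
problem optimizes θ on the log scale against the Laplace-approximated
marginal posterior

    log p(θ | y) ≈ log p(y, x̂(θ), θ) − ½ log det H(x̂(θ)) + const,

where H is the Hessian of the negative log posterior at the inner mode —
the same Gaussian approximation whose inverse Hessian provides the
posterior covariance used for uncertainty maps.  This reproduces the
model of the INLA-based reference workflow while staying plain
quasi-Newton numerics.

Prediction maps propagate seeded draws from N(x̂, H⁻¹) through the linear
predictor cell by cell, on the log, intensity (exp) or probability
(cloglog) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import linalg, optimize

from .errors import SDMFuseError
from .fields import MaternParams
from .geometry import Grid
from .model import JointModel, ModelState

__all__ = [
    "FitOptions",
    "FitResult",
    "PredictionMap",
    "fit",
    "laplace_covariance",
    "predict_intensity",
    "predict_bias",
]


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 100
    tol: float = 1e-8  # relative objective change
    hyper_mode: str = "optimize"  # or "fixed"
    outer_maxfev: int = 80
    seed: int = 0
    n_draws: int = 500

    def __post_init__(self):
        if not self.tol > 0:
            raise SDMFuseError("bad-hyperparameter", "tolerance must be > 0")
        if self.n_draws < 2:
            raise SDMFuseError("bad-hyperparameter", "need at least 2 draws")
        if self.hyper_mode not in ("optimize", "fixed"):
            raise SDMFuseError("bad-hyperparameter", f"unknown mode {self.hyper_mode!r}")


@dataclass
class FitResult:
    """MAP estimate with its Gaussian (Laplace) approximation."""

    state: ModelState
    covariance: np.ndarray
    theta_shared: MaternParams | None
    theta_bias: MaternParams | None
    objective: float
    converged: bool
    n_iter: int
    model: JointModel = dc_field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def stderr(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def fixed_effect_summary(self):
        """Fixed-effect estimates with Laplace standard deviations."""
        import pandas as pd

        jm = self.model
        names = ["alpha"]
        names += [f"beta_{n}" for n in jm.spec.process_covariates]
        names += [f"gamma_{n}" for n in jm.spec.bias_covariates]
        x = jm.pack(self.state)
        nf = len(names)
        return pd.DataFrame(
            {"parameter": names, "estimate": x[:nf], "sd": self.stderr[:nf]}
        )


def _newton(jm: JointModel, x0: np.ndarray, max_iter: int, tol: float):
    """Damped Newton with Cholesky solves and a backtracking line search."""
    x = x0.copy()
    f, g = jm.neg_log_posterior(x, want_grad=True)
    if not np.isfinite(f):
        raise SDMFuseError("diverged", "objective not finite at the initial state")
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        H = jm.hessian(x)
        ridge = 0.0
        scale = np.mean(np.diag(H)) if jm.dim else 1.0
        for _ in range(12):
            try:
                L = linalg.cholesky(H + ridge * np.eye(jm.dim), lower=True)
                break
            except linalg.LinAlgError:
                ridge = max(2 * ridge, 1e-8 * abs(scale), 1e-12)
        else:
            raise SDMFuseError("saddle-point", "Hessian could not be regularized")
        step = linalg.cho_solve((L, True), g)
        t = 1.0
        for _ in range(40):
            xn = x - t * step
            fn = jm.neg_log_posterior(xn)
            if np.isfinite(fn) and fn <= f - 1e-4 * t * (g @ step):
                break
            t *= 0.5
        else:
            converged = True  # no descent possible: at (numerical) optimum
            break
        rel = abs(f - fn) / max(abs(f), 1.0)
        x = xn
        f, g = jm.neg_log_posterior(x, want_grad=True)
        if not np.isfinite(f):
            raise SDMFuseError("diverged", "objective became NaN")
        if rel < tol:
            converged = True
            break
    return x, f, g, converged, n_iter


def _log_det_hessian(jm: JointModel, x: np.ndarray) -> float:
    H = jm.hessian(x)
    ridge = 0.0
    for _ in range(12):
        try:
            L = linalg.cholesky(H + ridge * np.eye(jm.dim), lower=True)
            return 2.0 * float(np.log(np.diag(L)).sum())
        except linalg.LinAlgError:
            ridge = max(2 * ridge, 1e-10 * abs(np.mean(np.diag(H))), 1e-12)
    raise SDMFuseError("saddle-point", "Hessian indefinite at the mode")


def _theta_bounds(jm: JointModel) -> list[tuple[float, float]]:
    """log ρ ∈ [cell size, 10 × domain diameter], log σ ∈ [1e-3, 10]."""
    pts = jm.scheme.points if jm.scheme is not None else np.vstack(
        [ds.xy for ds in jm.datasets if len(ds)]
    )
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    diam = float(np.hypot(*(hi - lo))) or 1.0
    if jm.scheme is not None and len(jm.scheme.weights):
        cell = float(np.sqrt(np.median(jm.scheme.weights)))
    else:
        cell = diam / 100.0
    bounds = []
    n_fields = (jm.shared_field is not None) + (jm.bias_field is not None)
    for _ in range(n_fields):
        bounds.append((np.log(cell), np.log(10.0 * diam)))
        bounds.append((np.log(1e-3), np.log(10.0)))
    return bounds


def fit(
    spec,
    datasets,
    priors,
    scheme,
    covariates,
    options: FitOptions = FitOptions(),
    shared_field=None,
    bias_field=None,
    domain_area: float | None = None,
) -> FitResult:
    """Fit the joint model: inner Newton on the latent state, optional
    outer optimization of the Matérn hyperparameters, Laplace covariance.

    Deterministic given the options (the seed only affects later map
    draws).  Non-convergence within ``max_iter`` flags the result rather
    than raising.
    """
    jm = JointModel(
        spec, datasets, covariates, scheme,
        shared_field=shared_field, bias_field=bias_field, priors=priors,
    )
    if domain_area is None:
        domain_area = float(scheme.total_weight) if scheme is not None else 1.0
    x0 = jm.pack(jm.initial_state(domain_area))

    def theta_vec():
        v = []
        if jm.shared_field is not None:
            v += [np.log(jm.shared_field.params.rho), np.log(jm.shared_field.params.sigma)]
        if jm.bias_field is not None:
            v += [np.log(jm.bias_field.params.rho), np.log(jm.bias_field.params.sigma)]
        return np.array(v)

    def apply_theta(v):
        i = 0
        shared = bias = None
        if jm.shared_field is not None:
            shared = MaternParams(rho=float(np.exp(v[i])), sigma=float(np.exp(v[i + 1])))
            i += 2
        if jm.bias_field is not None:
            bias = MaternParams(rho=float(np.exp(v[i])), sigma=float(np.exp(v[i + 1])))
        jm.set_hyperparameters(shared, bias)

    n_hyper = (jm.shared_field is not None) * 2 + (jm.bias_field is not None) * 2
    warm = {"x": x0}

    if options.hyper_mode == "optimize" and n_hyper:
        bounds = _theta_bounds(jm)

        def outer(v):
            apply_theta(np.clip(v, [b[0] for b in bounds], [b[1] for b in bounds]))
            x, f, _, _, _ = _newton(jm, warm["x"], options.max_iter, options.tol)
            warm["x"] = x
            # negative Laplace log marginal (constants dropped)
            return f + 0.5 * _log_det_hessian(jm, x)

        res = optimize.minimize(
            outer,
            theta_vec(),
            method="Powell",
            bounds=bounds,
            options={"maxfev": options.outer_maxfev, "xtol": 1e-3, "ftol": 1e-6},
        )
        apply_theta(np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds]))

    x, f, g, converged, n_iter = _newton(jm, warm["x"], options.max_iter, options.tol)
    cov = laplace_covariance(jm, x)
    return FitResult(
        state=jm.unpack(x),
        covariance=cov,
        theta_shared=jm.shared_field.params if jm.shared_field else None,
        theta_bias=jm.bias_field.params if jm.bias_field else None,
        objective=float(f),
        converged=bool(converged),
        n_iter=n_iter,
        model=jm,
    )


def laplace_covariance(jm: JointModel, x: np.ndarray) -> np.ndarray:
    """Inverse Hessian of the negative log posterior at the mode,
    symmetrized; indefiniteness is an error (the mode is a saddle)."""
    H = jm.hessian(np.asarray(x, dtype=float))
    try:
        L = linalg.cholesky(H, lower=True)
    except linalg.LinAlgError:
        raise SDMFuseError(
            "saddle-point",
            "Hessian indefinite at the mode; coarsen the knot lattice or raise the nugget",
        ) from None
    cov = linalg.cho_solve((L, True), np.eye(jm.dim))
    return 0.5 * (cov + cov.T)


@dataclass
class PredictionMap:
    """Per-cell posterior mean and sd of a predictor on a grid."""

    grid: Grid
    mean: np.ndarray  # (nx*ny,), NaN outside the domain
    sd: np.ndarray
    scale: str  # "log" | "intensity" | "probability"
    species: str = ""
    n_draws: int = 0

    def __post_init__(self):
        valid = ~np.isnan(self.sd)
        if np.any(self.sd[valid] < 0):
            raise SDMFuseError("bad-hyperparameter", "negative sd in prediction map")


def _draw_eta(fit: FitResult, locations, with_bias: bool, n_draws: int, seed: int):
    jm = fit.model
    A = jm.design_matrix(locations, with_bias=with_bias)
    x_hat = jm.pack(fit.state)
    rng = np.random.default_rng(seed)
    L = linalg.cholesky(
        fit.covariance + 1e-12 * np.eye(jm.dim) * max(np.trace(fit.covariance) / jm.dim, 1.0),
        lower=True,
    )
    eps = rng.standard_normal((n_draws, jm.dim))
    draws = x_hat[None, :] + eps @ L.T
    return draws @ A.T  # (n_draws, n_cells)


def _cells_for_grid(fit: FitResult, grid: Grid):
    cx, cy = grid.centers
    keep = grid.inside.copy()
    jm = fit.model
    for nm in jm.spec.process_covariates + jm.spec.bias_covariates:
        r = jm.covariates[nm]
        ok = r.grid.in_extent(cx, cy)
        if not np.all(ok[keep]):
            raise SDMFuseError("covariate-gap", f"grid extends beyond covariate {nm!r}")
    return cx, cy, keep


def predict_intensity(
    fit: FitResult,
    grid: Grid,
    scale: str = "log",
    with_bias: bool = False,
    n_draws: int | None = None,
    seed: int = 0,
    species: str = "",
) -> PredictionMap:
    """Posterior mean/sd map of the linear predictor (``scale="log"``),
    the intensity λ = e^η (``"intensity"``) or the cloglog occurrence
    probability 1 − exp(−e^η) (``"probability"``)."""
    if scale not in ("log", "intensity", "probability"):
        raise SDMFuseError("bad-hyperparameter", f"unknown scale {scale!r}")
    if not fit.converged:
        raise SDMFuseError("diverged", "cannot predict from a non-converged fit")
    n_draws = n_draws or 500
    cx, cy, keep = _cells_for_grid(fit, grid)
    locs = np.column_stack([cx[keep], cy[keep]])
    etas = _draw_eta(fit, locs, with_bias, n_draws, seed)
    if scale == "intensity":
        vals = np.exp(etas)
    elif scale == "probability":
        vals = -np.expm1(-np.exp(etas))
    else:
        vals = etas
    mean = np.full(grid.n_cells, np.nan)
    sd = np.full(grid.n_cells, np.nan)
    mean[keep] = vals.mean(axis=0)
    sd[keep] = vals.std(axis=0, ddof=1)
    return PredictionMap(
        grid=grid, mean=mean, sd=sd, scale=scale, species=species, n_draws=n_draws
    )


def predict_bias(
    fit: FitResult,
    grid: Grid,
    n_draws: int | None = None,
    seed: int = 0,
    species: str = "",
) -> PredictionMap:
    """Posterior mean/sd map of the bias predictor Σ γ_v W_v(s) + b(s) only."""
    jm = fit.model
    if not jm.spec.bias_covariates and jm.bias_field is None:
        raise SDMFuseError("no-bias-model", "model has no bias terms")
    if not fit.converged:
        raise SDMFuseError("diverged", "cannot predict from a non-converged fit")
    n_draws = n_draws or 500
    cx, cy, keep = _cells_for_grid(fit, grid)
    locs = np.column_stack([cx[keep], cy[keep]])
    eta_full = _draw_eta(fit, locs, True, n_draws, seed)
    eta_plain = _draw_eta(fit, locs, False, n_draws, seed)
    vals = eta_full - eta_plain  # same draws: exact bias contribution
    mean = np.full(grid.n_cells, np.nan)
    sd = np.full(grid.n_cells, np.nan)
    mean[keep] = vals.mean(axis=0)
    sd[keep] = vals.std(axis=0, ddof=1)
    return PredictionMap(
        grid=grid, mean=mean, sd=sd, scale="log", species=species, n_draws=n_draws
    )
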