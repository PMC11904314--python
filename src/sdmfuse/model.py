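"""Joint likelihood of the integrated species distribution model.

One latent log-intensity surface

    η(s) = α + Σ_u β_u X_u(s) + c·ζ(s)

(intercept, environmental covariates, shared Matérn field ζ scaled by a
fixed sharing constant c, default 1) drives every dataset, each through its
own observation model:

* presence-only — a thinned Poisson point process with observed intensity
  λ(s) q(s).  The log-thinning log q(s) = Σ_v γ_v W_v(s) + b(s) (bias
  covariates and/or a bias field) is added to η for these likelihoods only;
  the point-process log likelihood uses the quadrature scheme for the
  intensity integral.
* presence-absence — Bernoulli with the cloglog link
  p(s) = 1 − exp(−E e^{η(s)}), the exact detection probability of at least
  one point of the process in a site of measure E.
* count — Poisson with mean E e^{η(s)}, the integrated intensity over the
  sampling site approximated by the exposure offset E.

The joint objective is the negative log posterior: the sum of all dataset
log likelihoods, the Gaussian field priors, the PC hyperpriors, and an
optional Normal(0, sd²) prior on the fixed effects.  Everything is linear
in the latent state, so each likelihood contributes through a design
matrix A: value g(Aθ), gradient Aᵀg′, Hessian Aᵀdiag(g″)A — used by the
Newton solver and the Laplace approximation in :mod:`sdmfuse.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import linalg
from scipy.stats import poisson as poisson_dist

from .data_io import CovariateRaster, OccurrenceDataset
from .errors import SDMFuseError
from .fields import (
    MaternParams,
    PCPrior,
    SpatialField,
    bilinear_weights,
    knot_covariance,
    pc_prior_logdensity,
)
from .geometry import IntegrationScheme

PROB_CLAMP = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the process model and the presence-only bias model."""

    process_covariates: tuple = ()
    bias_covariates: tuple = ()
    shared_field: bool = True
    bias_field: bool = False
    field_scale: float = 1.0  # fixed inter-likelihood sharing constant


@dataclass(frozen=True)
class Priors:
    """Hyperpriors and fixed-effect prior for the joint posterior.

    ``fixed_effect_sd=None`` selects flat priors on (α, β, γ) for
    maximum-likelihood-style fits.
    """

    pc_shared: PCPrior | None = None
    pc_bias: PCPrior | None = None
    fixed_effect_sd: float | None = 10.0


@dataclass
class ModelState:
    """Latent state: intercept, covariate effects, bias terms, field knots."""

    alpha: float = 0.0
    beta: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    gamma: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    z: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    b: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    theta_shared: MaternParams | None = None
    theta_bias: MaternParams | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.b = np.asarray(self.b, dtype=float)


class JointModel:
    """Assembled design matrices + priors for one model specification.

    Parameters
    ----------
    spec : ModelSpec
    datasets : list of OccurrenceDataset
    covariates : mapping name -> CovariateRaster (standardized or not)
    scheme : IntegrationScheme for the presence-only intensity integral
    shared_field, bias_field : SpatialField templates carrying the knot
        lattice, hyperparameters and PC prior (coefficients are taken from
        the state, not the template)
    priors : Priors
    """

    def __init__(
        self,
        spec: ModelSpec,
        datasets: list[OccurrenceDataset],
        covariates: dict[str, CovariateRaster],
        scheme: IntegrationScheme | None,
        shared_field: SpatialField | None = None,
        bias_field: SpatialField | None = None,
        priors: Priors = Priors(),
    ):
        if not datasets:
            raise SDMFuseError("no-data", "at least one dataset is required")
        for nm in spec.process_covariates + spec.bias_covariates:
            if nm not in covariates:
                raise SDMFuseError("covariate-gap", f"unknown covariate {nm!r}")
        if spec.shared_field and shared_field is None:
            raise SDMFuseError("no-data", "spec requests a shared field but none given")
        if spec.bias_field and bias_field is None:
            raise SDMFuseError("no-bias-model", "spec requests a bias field but none given")
        has_po = any(d.process == "presence_only" for d in datasets)
        if has_po and scheme is None:
            raise SDMFuseError("no-data", "presence-only data require a quadrature scheme")

        self.spec = spec
        self.datasets = datasets
        self.covariates = covariates
        self.scheme = scheme
        self.shared_field = shared_field if spec.shared_field else None
        self.bias_field = bias_field if spec.bias_field else None
        self.priors = priors

        p = len(spec.process_covariates)
        q = len(spec.bias_covariates)
        K = self.shared_field.knots.n_knots if self.shared_field else 0
        Kb = self.bias_field.knots.n_knots if self.bias_field else 0
        self._p, self._q, self._K, self._Kb = p, q, K, Kb
        self.dim = 1 + p + q + K + Kb
        self._sl_alpha = slice(0, 1)
        self._sl_beta = slice(1, 1 + p)
        self._sl_gamma = slice(1 + p, 1 + p + q)
        self._sl_z = slice(1 + p + q, 1 + p + q + K)
        self._sl_b = slice(1 + p + q + K, self.dim)

        # per-dataset design matrices
        self._blocks = []
        for ds in datasets:
            xy = ds.xy
            if ds.process == "presence_only":
                A_pts = self.design_matrix(xy, with_bias=True)
                A_quad = self.design_matrix(self.scheme.points, with_bias=True)
                self._blocks.append(("po", ds, A_pts, A_quad, self.scheme.weights))
            elif ds.process == "presence_absence":
                A = self.design_matrix(xy, with_bias=False)
                y = (ds.records["status"] == "present").to_numpy(dtype=float)
                self._blocks.append(("pa", ds, A, y, ds.exposure))
            else:
                A = self.design_matrix(xy, with_bias=False)
                y = ds.records["count"].to_numpy(dtype=float)
                if np.any(y < 0) or np.any(y != np.round(y)):
                    raise SDMFuseError("bad-count", "counts must be nonnegative integers")
                self._blocks.append(("count", ds, A, y, ds.exposure))

        self.set_hyperparameters(
            self.shared_field.params if self.shared_field else None,
            self.bias_field.params if self.bias_field else None,
        )

    # -- state packing ------------------------------------------------------

    def pack(self, state: ModelState) -> np.ndarray:
        x = np.empty(self.dim)
        x[self._sl_alpha] = state.alpha
        x[self._sl_beta] = state.beta
        x[self._sl_gamma] = state.gamma
        x[self._sl_z] = state.z if self._K else []
        x[self._sl_b] = state.b if self._Kb else []
        return x

    def unpack(self, x: np.ndarray) -> ModelState:
        return ModelState(
            alpha=float(x[0]),
            beta=x[self._sl_beta].copy(),
            gamma=x[self._sl_gamma].copy(),
            z=x[self._sl_z].copy(),
            b=x[self._sl_b].copy(),
            theta_shared=self.shared_field.params if self.shared_field else None,
            theta_bias=self.bias_field.params if self.bias_field else None,
        )

    def initial_state(self, domain_area: float) -> ModelState:
        """Intercept at the homogeneous-Poisson solution, all else zero."""
        n = 0
        for ds in self.datasets:
            if ds.process == "presence_only":
                n += len(ds)
            elif ds.process == "presence_absence":
                n += int((ds.records["status"] == "present").sum())
            else:
                n += int(ds.records["count"].sum())
        return ModelState(
            alpha=float(np.log(max(n, 1) / domain_area)),
            beta=np.zeros(self._p),
            gamma=np.zeros(self._q),
            z=np.zeros(self._K),
            b=np.zeros(self._Kb),
            theta_shared=self.shared_field.params if self.shared_field else None,
            theta_bias=self.bias_field.params if self.bias_field else None,
        )

    # -- hyperparameters ----------------------------------------------------

    def set_hyperparameters(
        self, shared: MaternParams | None, bias: MaternParams | None
    ) -> None:
        """Fix (ρ, σ) per field and refresh the knot precision factors."""
        self._prior_terms = []  # (slice, precision Q, log-det const)
        if self.shared_field is not None and shared is not None:
            self.shared_field = self.shared_field.with_params(shared)
        if self.bias_field is not None and bias is not None:
            self.bias_field = self.bias_field.with_params(bias)
        for fld, sl in ((self.shared_field, self._sl_z), (self.bias_field, self._sl_b)):
            if fld is None:
                continue
            cov = knot_covariance(fld.knots.locations, fld.params, fld.nugget)
            L = linalg.cholesky(cov, lower=True)
            Q = linalg.cho_solve((L, True), np.eye(L.shape[0]))
            const = -np.log(np.diag(L)).sum() - 0.5 * L.shape[0] * np.log(2 * np.pi)
            self._prior_terms.append((sl, Q, const))

    def hyper_log_prior(self) -> float:
        """PC-prior log density of the current (ρ, σ) per field."""
        total = 0.0
        if self.shared_field is not None and self.priors.pc_shared is not None:
            total += pc_prior_logdensity(self.shared_field.params, self.priors.pc_shared)
        if self.bias_field is not None and self.priors.pc_bias is not None:
            total += pc_prior_logdensity(self.bias_field.params, self.priors.pc_bias)
        return total

    # -- design -------------------------------------------------------------

    def design_matrix(self, locations, with_bias: bool) -> np.ndarray:
        """(n, dim) matrix A with η = A x for the packed state x.

        Bias columns (γ, b) are zero when ``with_bias`` is false, so one
        packing serves all observation models.
        """
        locations = np.atleast_2d(np.asarray(locations, dtype=float))
        x, y = locations[:, 0], locations[:, 1]
        A = np.zeros((len(x), self.dim))
        A[:, 0] = 1.0
        for j, nm in enumerate(self.spec.process_covariates):
            A[:, 1 + j] = self.covariates[nm].value_at(x, y)
        if self.shared_field is not None:
            A[:, self._sl_z] = self.spec.field_scale * bilinear_weights(
                self.shared_field.knots, x, y
            )
        if with_bias:
            for j, nm in enumerate(self.spec.bias_covariates):
                A[:, self._sl_gamma][:, j] = self.covariates[nm].value_at(x, y)
            if self.bias_field is not None:
                A[:, self._sl_b] = bilinear_weights(self.bias_field.knots, x, y)
        return A

    def linear_predictor(self, state: ModelState, locations, with_bias: bool) -> np.ndarray:
        return self.design_matrix(locations, with_bias) @ self.pack(state)

    # -- log likelihood pieces ---------------------------------------------

    def _block_loglik(self, block, x, want_derivs: bool):
        """Return (ℓ, per-row dℓ/dη, d²ℓ/dη², A) for one dataset block."""
        kind = block[0]
        if kind == "po":
            _, ds, A_pts, A_quad, w = block
            eta_p = A_pts @ x
            eta_q = A_quad @ x
            lam = w * np.exp(eta_q)
            ll = float(eta_p.sum() - lam.sum())
            if not want_derivs:
                return ll, None
            g = A_pts.sum(axis=0) - A_quad.T @ lam
            return ll, (g, A_quad, -lam)
        _, ds, A, y, E = block
        eta = A @ x
        mu = E * np.exp(eta)
        if kind == "count":
            ll = float(poisson_dist.logpmf(y.astype(int), mu).sum())
            if not want_derivs:
                return ll, None
            d1 = y - mu
            d2 = -mu
        else:  # presence-absence, cloglog
            p = -np.expm1(-mu)
            p = np.clip(p, PROB_CLAMP, 1 - PROB_CLAMP)
            ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
            if not want_derivs:
                return ll, None
            with np.errstate(over="ignore"):
                u = mu * np.exp(-mu) / np.clip(-np.expm1(-mu), PROB_CLAMP, None)
            d1 = np.where(y > 0, u, -mu)
            d2 = np.where(y > 0, u * (1.0 - mu - u), -mu)
        g = A.T @ d1
        return ll, (g, A, d2)

    # -- joint objective ----------------------------------------------------

    def neg_log_posterior(self, x: np.ndarray, want_grad: bool = False):
        """−log posterior of the latent state (hyperpriors included as
        constants at the current (ρ, σ))."""
        val = 0.0
        grad = np.zeros(self.dim) if want_grad else None
        for block in self._blocks:
            ll, derivs = self._block_loglik(x=x, block=block, want_derivs=want_grad)
            val += ll
            if want_grad:
                grad += derivs[0]
        for sl, Q, const in self._prior_terms:
            zz = x[sl]
            val += -0.5 * zz @ Q @ zz + const
            if want_grad:
                grad[sl] += -Q @ zz
        s = self.priors.fixed_effect_sd
        if s is not None:
            fx = x[: 1 + self._p + self._q]
            val += float(-0.5 * fx @ fx / s**2 - fx.size * np.log(s * np.sqrt(2 * np.pi)))
            if want_grad:
                grad[: 1 + self._p + self._q] += -fx / s**2
        val += self.hyper_log_prior()
        if want_grad:
            return -val, -grad
        return -val

    def hessian(self, x: np.ndarray) -> np.ndarray:
        """Hessian of the negative log posterior in the latent state."""
        H = np.zeros((self.dim, self.dim))
        for block in self._blocks:
            _, derivs = self._block_loglik(x=x, block=block, want_derivs=True)
            _, A, d2 = derivs
            H -= (A * d2[:, None]).T @ A
        for sl, Q, _ in self._prior_terms:
            H[sl, sl] += Q
        s = self.priors.fixed_effect_sd
        if s is not None:
            nf = 1 + self._p + self._q
            H[np.arange(nf), np.arange(nf)] += 1.0 / s**2
        return H


# ---------------------------------------------------------------------------
# functional surface (thin wrappers used by tests and scripts)


def _single(spec, ds, covariates, scheme, shared_field, bias_field, priors=None):
    return JointModel(
        spec,
        [ds],
        covariates,
        scheme,
        shared_field=shared_field,
        bias_field=bias_field,
        priors=priors or Priors(pc_shared=None, pc_bias=None, fixed_effect_sd=None),
    )


def linear_predictor(
    state: ModelState,
    spec: ModelSpec,
    locations,
    covariates: dict,
    with_bias: bool = False,
    shared_field: SpatialField | None = None,
    bias_field: SpatialField | None = None,
) -> np.ndarray:
    """η(s) = α + Σ β_u X_u(s) + c·ζ(s) (+ bias terms when requested)."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    x, y = locations[:, 0], locations[:, 1]
    eta = np.full(len(x), state.alpha)
    for j, nm in enumerate(spec.process_covariates):
        eta += state.beta[j] * covariates[nm].value_at(x, y)
    if spec.shared_field and shared_field is not None:
        B = bilinear_weights(shared_field.knots, x, y)
        eta += spec.field_scale * (B @ state.z)
    if with_bias:
        for j, nm in enumerate(spec.bias_covariates):
            eta += state.gamma[j] * covariates[nm].value_at(x, y)
        if spec.bias_field and bias_field is not None:
            Bb = bilinear_weights(bias_field.knots, x, y)
            eta += Bb @ state.b
    return eta


def po_loglik(
    ds: OccurrenceDataset,
    state: ModelState,
    spec: ModelSpec,
    scheme: IntegrationScheme,
    covariates: dict,
    shared_field: SpatialField | None = None,
    bias_field: SpatialField | None = None,
) -> float:
    """Thinned inhomogeneous-Poisson log likelihood
    Σ_i η*(s_i) − Σ_j w_j exp(η*(s_j)) with η* including the bias terms."""
    if ds.process != "presence_only":
        raise SDMFuseError("schema-error", "po_loglik needs a presence_only dataset")
    eta_pts = linear_predictor(
        state, spec, ds.xy, covariates, True, shared_field, bias_field
    ) if len(ds) else np.zeros(0)
    eta_quad = linear_predictor(
        state, spec, scheme.points, covariates, True, shared_field, bias_field
    )
    return float(eta_pts.sum() - scheme.weights @ np.exp(eta_quad))


def pa_loglik(
    ds: OccurrenceDataset,
    state: ModelState,
    spec: ModelSpec,
    covariates: dict,
    shared_field: SpatialField | None = None,
) -> float:
    """Bernoulli log likelihood under the cloglog link
    p = 1 − exp(−E e^η); bias terms never enter."""
    if ds.process != "presence_absence":
        raise SDMFuseError("schema-error", "pa_loglik needs a presence_absence dataset")
    eta = linear_predictor(state, spec, ds.xy, covariates, False, shared_field)
    y = (ds.records["status"] == "present").to_numpy(dtype=float)
    p = np.clip(-np.expm1(-ds.exposure * np.exp(eta)), PROB_CLAMP, 1 - PROB_CLAMP)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def count_loglik(
    ds: OccurrenceDataset,
    state: ModelState,
    spec: ModelSpec,
    covariates: dict,
    shared_field: SpatialField | None = None,
) -> float:
    """Poisson log likelihood with mean E e^η (exposure-offset counts)."""
    if ds.process != "count":
        raise SDMFuseError("schema-error", "count_loglik needs a count dataset")
    y = ds.records["count"].to_numpy(dtype=float)
    if np.any(y < 0):
        raise SDMFuseError("bad-count", "negative count")
    eta = linear_predictor(state, spec, ds.xy, covariates, False, shared_field)
    return float(poisson_dist.logpmf(y.astype(int), ds.exposure * np.exp(eta)).sum())


def joint_objective(
    state: ModelState,
    spec: ModelSpec,
    datasets: list[OccurrenceDataset],
    priors: Priors,
    scheme: IntegrationScheme | None,
    covariates: dict,
    shared_field: SpatialField | None = None,
    bias_field: SpatialField | None = None,
) -> float:
    """Negative log posterior of the full integrated model."""
    jm = JointModel(
        spec, datasets, covariates, scheme,
        shared_field=shared_field, bias_field=bias_field, priors=priors,
    )
    return float(jm.neg_log_posterior(jm.pack(state)))
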