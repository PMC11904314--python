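"""Matérn Gaussian random fields on a regular knot lattice, with PC priors.

The latent spatial effect ζ(s) (and the presence-only bias field) is a
zero-mean Gaussian process with Matérn covariance, represented exactly on a
modest set of knots and projected to arbitrary locations by bilinear
interpolation.  Smoothness is fixed at ν = 1 (the 2-D default of the SPDE
family this construction stands in for), with the range convention
κ = √(8ν)/ρ so that the correlation drops to ≈ 0.1 at distance ρ — the
convention under which the "P(range < 200 km) = 20%" prior statement is
meaningful.

Hyperparameter priors are penalized-complexity (PC) priors: ρ has the
inverse-exponential density λ_ρ ρ⁻² exp(−λ_ρ/ρ) with λ_ρ = −log(α_ρ)·ρ0,
and σ is exponential with rate λ_σ = −log(α_σ)/σ0, which makes the tail
statements P(ρ < ρ0) = α_ρ and P(σ > σ0) = α_σ exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, special

from .errors import SDMFuseError

NU = 1.0  # fixed Matérn smoothness
KAPPA_FACTOR = np.sqrt(8.0 * NU)  # κ = √(8ν)/ρ


@dataclass(frozen=True)
class MaternParams:
    """Matérn hyperparameters: range ρ (km) and marginal sd σ, ν fixed at 1."""

    rho: float
    sigma: float

    def __post_init__(self):
        if not (self.rho > 0 and self.sigma > 0):
            raise SDMFuseError(
                "bad-hyperparameter", f"rho={self.rho}, sigma={self.sigma} must be > 0"
            )


@dataclass(frozen=True)
class PCPrior:
    """PC prior calibrated by P(ρ < ρ0) = α_ρ and P(σ > σ0) = α_σ."""

    rho0: float
    alpha_rho: float
    sigma0: float
    alpha_sigma: float

    def __post_init__(self):
        ok = (
            self.rho0 > 0
            and self.sigma0 > 0
            and 0 < self.alpha_rho < 1
            and 0 < self.alpha_sigma < 1
        )
        if not ok:
            raise SDMFuseError("bad-hyperparameter", "invalid PC prior calibration")

    @property
    def lam_rho(self) -> float:
        return -np.log(self.alpha_rho) * self.rho0

    @property
    def lam_sigma(self) -> float:
        return -np.log(self.alpha_sigma) / self.sigma0


def matern_cov(d, p: MaternParams) -> np.ndarray:
    """Matérn ν=1 covariance C(d) = σ² (κd) K₁(κd), C(0) = σ².

    ``d`` is distance in km, scalar or array.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise SDMFuseError("bad-hyperparameter", "negative distance")
    kd = KAPPA_FACTOR / p.rho * d
    with np.errstate(invalid="ignore", over="ignore"):
        c = np.where(kd > 0, kd * special.kv(1.0, kd), 1.0)
        c = np.nan_to_num(c, nan=0.0, posinf=1.0)  # (kd)K1(kd) -> 1 as kd -> 0
        return p.sigma**2 * c


def pc_prior_logdensity(p: MaternParams, prior: PCPrior) -> float:
    """Joint PC-prior log density log π(ρ, σ) (independent factors)."""
    lr, ls = prior.lam_rho, prior.lam_sigma
    return float(
        np.log(lr) - 2.0 * np.log(p.rho) - lr / p.rho + np.log(ls) - ls * p.sigma
    )


def pc_prior_range_cdf(rho0: float, prior: PCPrior) -> float:
    """P(ρ < rho0) in closed form (inverse-exponential tail)."""
    return float(np.exp(-prior.lam_rho / rho0))


def pc_prior_sigma_tail(sigma0: float, prior: PCPrior) -> float:
    """P(σ > sigma0) in closed form (exponential tail)."""
    return float(np.exp(-prior.lam_sigma * sigma0))


@dataclass(frozen=True)
class KnotGrid:
    """Regular kx × ky knot lattice spanning a rectangle (inclusive edges)."""

    xs: np.ndarray  # (kx,) ascending
    ys: np.ndarray  # (ky,) ascending

    @property
    def n_knots(self) -> int:
        return self.xs.size * self.ys.size

    @property
    def locations(self) -> np.ndarray:
        """(K, 2) knot coordinates, x fastest (row-major in y)."""
        gx, gy = np.meshgrid(self.xs, self.ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    @classmethod
    def over_bounds(cls, bounds, kx: int, ky: int) -> "KnotGrid":
        xmin, ymin, xmax, ymax = bounds
        return cls(xs=np.linspace(xmin, xmax, kx), ys=np.linspace(ymin, ymax, ky))


def bilinear_weights(kg: KnotGrid, x, y) -> np.ndarray:
    """Dense (n, K) matrix B with (B z)(i) = bilinear interpolation of knot
    coefficients z at location i.  Exact at knots; rows sum to 1.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    xs, ys = kg.xs, kg.ys
    eps = 1e-9 * max(xs[-1] - xs[0], ys[-1] - ys[0], 1.0)
    out = (
        (x < xs[0] - eps) | (x > xs[-1] + eps) | (y < ys[0] - eps) | (y > ys[-1] + eps)
    )
    if np.any(out):
        raise SDMFuseError("out-of-extent", f"{int(out.sum())} locations outside knot extent")
    ix = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, xs.size - 2)
    iy = np.clip(np.searchsorted(ys, y, side="right") - 1, 0, ys.size - 2)
    tx = np.clip((x - xs[ix]) / (xs[ix + 1] - xs[ix]), 0.0, 1.0)
    ty = np.clip((y - ys[iy]) / (ys[iy + 1] - ys[iy]), 0.0, 1.0)
    n, kx = x.size, xs.size
    B = np.zeros((n, kg.n_knots))
    rows = np.arange(n)
    B[rows, iy * kx + ix] = (1 - tx) * (1 - ty)
    B[rows, iy * kx + ix + 1] += tx * (1 - ty)
    B[rows, (iy + 1) * kx + ix] += (1 - tx) * ty
    B[rows, (iy + 1) * kx + ix + 1] += tx * ty
    return B


@dataclass
class SpatialField:
    """A Matérn GP on knots: coefficients + hyperparameters + PC prior.

    ``role`` is "shared" for the process field ζ(s) common to all datasets,
    or "bias" for the extra field entering presence-only likelihoods only.
    """

    knots: KnotGrid
    params: MaternParams
    prior: PCPrior
    role: str = "shared"
    coefficients: np.ndarray = None  # type: ignore[assignment]
    nugget: float | None = None

    def __post_init__(self):
        if self.coefficients is None:
            self.coefficients = np.zeros(self.knots.n_knots)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != self.knots.n_knots:
            raise SDMFuseError(
                "bad-hyperparameter",
                f"{self.coefficients.size} coefficients for {self.knots.n_knots} knots",
            )

    def with_params(self, params: MaternParams) -> "SpatialField":
        return replace(self, params=params)


def knot_covariance(
    knots: np.ndarray, p: MaternParams, nugget: float | None = None
) -> np.ndarray:
    """Dense Matérn covariance of knot locations plus a jitter nugget.

    ``nugget`` defaults to 1e-8 σ²; raise it if factorization fails.
    """
    knots = np.asarray(knots, dtype=float)
    if nugget is None:
        nugget = 1e-8 * p.sigma**2
    if nugget < 0:
        raise SDMFuseError("bad-hyperparameter", "negative nugget")
    diff = knots[:, None, :] - knots[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    k = knots.shape[0]
    if k > 1 and np.any(d[~np.eye(k, dtype=bool)] == 0):
        raise SDMFuseError("duplicate-knots", "knot locations must be distinct")
    cov = matern_cov(d, p) + nugget * np.eye(k)
    try:
        linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise SDMFuseError(
            "not-PD", "knot covariance not positive definite; raise the nugget"
        ) from exc
    return cov


def project_field(f: SpatialField, locations) -> np.ndarray:
    """Evaluate the field at (n, 2) planar locations by bilinear interpolation."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    B = bilinear_weights(f.knots, locations[:, 0], locations[:, 1])
    return B @ f.coefficients


def field_prior_logdensity(f: SpatialField) -> float:
    """Gaussian log prior of the knot coefficients given (ρ, σ)."""
    cov = knot_covariance(f.knots.locations, f.params, f.nugget)
    L = linalg.cholesky(cov, lower=True)
    z = f.coefficients
    alpha = linalg.solve_triangular(L, z, lower=True)
    k = z.size
    return float(
        -0.5 * alpha @ alpha - np.log(np.diag(L)).sum() - 0.5 * k * np.log(2 * np.pi)
    )
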