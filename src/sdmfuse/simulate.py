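"""Synthetic data with the statistical structure the model assumes.

The generator draws a Matérn Gaussian field on a grid, turns it into a
log-Gaussian Cox process (per-cell Poisson counts, uniform placement
within cells), applies location-dependent Bernoulli thinning to emulate
citizen-science sampling bias, and samples cross-list presence-absence
and count surveys from the same latent intensity — so every observation
model sees data generated under exactly the process it assumes.

:func:`make_scenario` bundles named study designs.  The ``standard``
scenario mirrors the reference case study's structure at desk scale: a
100 × 100 km square domain, one standardized environmental covariate,
one presence-only dataset with south-heavy thinning, and two cross-list
presence-absence surveys; ``po_only`` drops the surveys and ``rich`` adds
a count survey.  Scenario defaults (intensity level, field range and sd,
survey sizes, exposure) are fixed here and used unchanged by the test
suite; see docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import linalg

from .data_io import (
    CovariateRaster,
    OccurrenceDataset,
    read_ascii_grid,
    read_occurrences,
    standardize_covariate,
    write_ascii_grid,
)
from .errors import SDMFuseError
from .fields import MaternParams, PCPrior, matern_cov
from .geometry import Grid, SpatialDomain, make_grid

MAX_SIM_CELLS = 10_000

SPECIES = "Arnica synthetica"  # synthetic stand-in taxon


def simulate_gaussian_field(grid: Grid, p: MaternParams, seed: int) -> np.ndarray:
    """One zero-mean Matérn GP draw on the grid's cell centers (dense
    Cholesky; grids above 10,000 cells are refused)."""
    if grid.n_cells > MAX_SIM_CELLS:
        raise SDMFuseError("grid-too-large", f"{grid.n_cells} cells > {MAX_SIM_CELLS}")
    cx, cy = grid.centers
    pts = np.column_stack([cx, cy])
    diff = pts[:, None, :] - pts[None, :, :]
    cov = matern_cov(np.sqrt((diff**2).sum(-1)), p) + 1e-8 * p.sigma**2 * np.eye(
        grid.n_cells
    )
    L = linalg.cholesky(cov, lower=True)
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal(grid.n_cells)


def simulate_lgcp(intensity: np.ndarray, grid: Grid, seed: int) -> np.ndarray:
    """Sample an inhomogeneous Poisson process: per cell a Poisson count
    with mean λ_cell · clipped area, points uniform within the cell.
    Returns an (n, 2) array of locations."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise SDMFuseError("bad-intensity", "negative intensity")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(intensity * grid.clipped_area)
    idx = np.repeat(np.arange(grid.n_cells), counts)
    if idx.size == 0:
        return np.zeros((0, 2))
    ix = idx % grid.nx
    iy = idx // grid.nx
    u = rng.random((idx.size, 2))
    x = grid.x0 + (ix + u[:, 0]) * grid.dx
    y = grid.y0 + (iy + u[:, 1]) * grid.dy
    # for boundary cells, resample uniformly until inside the domain
    if grid.domain is not None:
        inside = grid.domain.contains(x, y)
        tries = 0
        while not inside.all() and tries < 200:
            bad = ~inside
            u = rng.random((int(bad.sum()), 2))
            x[bad] = grid.x0 + (ix[bad] + u[:, 0]) * grid.dx
            y[bad] = grid.y0 + (iy[bad] + u[:, 1]) * grid.dy
            inside[bad] = grid.domain.contains(x[bad], y[bad])
            tries += 1
        x, y = x[inside], y[inside]
    return np.column_stack([x, y])


def thin_points(points: np.ndarray, q, seed: int) -> np.ndarray:
    """Independent Bernoulli(q(s)) retention of each point; ``q`` is a
    callable (x, y) -> probability or a scalar."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        return points
    qs = q(points[:, 0], points[:, 1]) if callable(q) else np.full(len(points), float(q))
    qs = np.asarray(qs, dtype=float)
    if np.any((qs < 0) | (qs > 1)):
        raise SDMFuseError("bad-thinning", "thinning probability outside [0, 1]")
    rng = np.random.default_rng(seed)
    return points[rng.random(len(points)) < qs]


def simulate_pa(
    sites: np.ndarray, eta: np.ndarray, exposure, seed: int, name: str = "pa"
) -> OccurrenceDataset:
    """Bernoulli cloglog detections: y ~ Bern(1 − exp(−E e^η)) per site."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    eta = np.asarray(eta, dtype=float)
    E = np.broadcast_to(np.asarray(exposure, dtype=float), eta.shape)
    p = -np.expm1(-E * np.exp(eta))
    rng = np.random.default_rng(seed)
    y = rng.random(eta.shape) < p
    df = pd.DataFrame(
        {
            "species": SPECIES,
            "x": sites[:, 0],
            "y": sites[:, 1],
            "uncertainty_m": np.nan,
            "status": np.where(y, "present", "absent"),
            "count": np.nan,
        }
    )
    return OccurrenceDataset(name=name, process="presence_absence", records=df, exposure=E.copy())


def simulate_counts(
    sites: np.ndarray, eta: np.ndarray, exposure, seed: int, name: str = "counts"
) -> OccurrenceDataset:
    """Poisson counts y ~ Pois(E e^η) per sampling site."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    eta = np.asarray(eta, dtype=float)
    E = np.broadcast_to(np.asarray(exposure, dtype=float), eta.shape)
    rng = np.random.default_rng(seed)
    y = rng.poisson(E * np.exp(eta))
    df = pd.DataFrame(
        {
            "species": SPECIES,
            "x": sites[:, 0],
            "y": sites[:, 1],
            "uncertainty_m": np.nan,
            "status": "present",
            "count": y.astype(float),
        }
    )
    return OccurrenceDataset(name=name, process="count", records=df, exposure=E.copy())


# ---------------------------------------------------------------------------
# named scenarios


@dataclass
class Scenario:
    """A complete synthetic study: domain, covariate, truth, datasets."""

    name: str
    seed: int
    domain: SpatialDomain
    grid: Grid
    covariate: CovariateRaster
    true_alpha: float
    true_beta: float
    field_params: MaternParams
    pc_prior: PCPrior
    field_values: np.ndarray  # true ζ per grid cell
    datasets: list[OccurrenceDataset] = dc_field(default_factory=list)
    thinning_rate: float = 1.5  # log q(s) = −rate · y / L

    @property
    def po(self) -> OccurrenceDataset:
        return next(d for d in self.datasets if d.process == "presence_only")

    def write(self, outdir) -> Path:
        """Write the bundle in the formats data_io reads (GeoJSON, ESRI
        ASCII grid, Darwin-Core CSV with planar km coordinates)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.domain.to_geojson(out / "domain.geojson")
        write_ascii_grid(self.covariate, None, out / f"{self.covariate.name}.asc")
        for ds in self.datasets:
            df = ds.records.rename(
                columns={
                    "x": "decimalLongitude",
                    "y": "decimalLatitude",
                    "uncertainty_m": "coordinateUncertaintyInMeters",
                    "status": "occurrenceStatus",
                    "count": "individualCount",
                }
            )
            df["datasetName"] = ds.name
            df.to_csv(out / f"{ds.name}.csv", index=False)
        meta = {
            "name": self.name,
            "seed": self.seed,
            "species": SPECIES,
            "true_alpha": self.true_alpha,
            "true_beta": self.true_beta,
            "field_rho_km": self.field_params.rho,
            "field_sigma": self.field_params.sigma,
            "thinning_rate": self.thinning_rate,
            "datasets": {d.name: d.process for d in self.datasets},
            "covariate": self.covariate.name,
        }
        with open(out / "scenario.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        return out

    def read_back(self, outdir) -> dict:
        """Re-read the written fixture files through data_io."""
        out = Path(outdir)
        loaded = {
            "domain": SpatialDomain.from_geojson(out / "domain.geojson"),
            "covariate": read_ascii_grid(
                out / f"{self.covariate.name}.asc", name=self.covariate.name
            ),
            "datasets": [],
        }
        for ds in self.datasets:
            loaded["datasets"].append(
                read_occurrences(out / f"{ds.name}.csv", process=ds.process, name=ds.name)
            )
        return loaded


# frozen study conditions of the named scenarios (see docs/methods.md)
_STANDARD = dict(
    side_km=100.0,
    sim_nx=40,
    true_alpha=-4.0,
    true_beta=1.5,
    rho=40.0,
    sigma=0.6,
    thinning_rate=1.5,
    n_pa_sites=80,
    pa_exposure=15.0,
    n_count_sites=40,
    count_exposure=15.0,
)


def make_scenario(name: str, seed: int, outdir=None) -> Scenario:
    """Build a named scenario (``standard`` | ``po_only`` | ``rich``).

    All randomness derives from ``seed``; the same (name, seed) pair
    always reproduces the identical bundle.  If ``outdir`` is given the
    fixture files are also written there.
    """
    if name not in ("standard", "po_only", "rich"):
        raise SDMFuseError("unknown-scenario", f"unknown scenario {name!r}")
    c = _STANDARD
    L = c["side_km"]
    import shapely

    domain = SpatialDomain(shapely.box(0.0, 0.0, L, L))
    grid = make_grid(domain, c["sim_nx"], c["sim_nx"])
    cx, cy = grid.centers

    # smooth environmental gradient, then z-standardized
    raw = (cx + 0.5 * cy) / L + 0.25 * np.sin(2 * np.pi * cy / L)
    cov = standardize_covariate(
        CovariateRaster(grid=grid, values=raw, name="temperature")
    )

    p = MaternParams(rho=c["rho"], sigma=c["sigma"])
    prior = PCPrior(rho0=200.0, alpha_rho=0.2, sigma0=1.0, alpha_sigma=0.01)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    zeta = simulate_gaussian_field(grid, p, seed=sub())
    eta_cells = c["true_alpha"] + c["true_beta"] * cov.values + zeta
    lam = np.exp(eta_cells)

    rate = c["thinning_rate"]
    q = lambda x, y: np.exp(-rate * y / L)  # noqa: E731  south-heavy effort

    pts = simulate_lgcp(lam, grid, seed=sub())
    obs = thin_points(pts, q, seed=sub())
    po = OccurrenceDataset(
        name="po_citizen",
        process="presence_only",
        records=pd.DataFrame(
            {
                "species": SPECIES,
                "x": obs[:, 0],
                "y": obs[:, 1],
                "uncertainty_m": np.nan,
                "status": "present",
                "count": np.nan,
            }
        ),
    )
    datasets = [po]

    def eta_at(sites):
        idx = grid.cell_index(sites[:, 0], sites[:, 1])
        return c["true_alpha"] + c["true_beta"] * cov.values[idx] + zeta[idx]

    if name in ("standard", "rich"):
        for label in ("pa_museum_a", "pa_museum_b"):
            sites = rng.random((c["n_pa_sites"], 2)) * L
            datasets.append(
                simulate_pa(sites, eta_at(sites), c["pa_exposure"], seed=sub(), name=label)
            )
    if name == "rich":
        sites = rng.random((c["n_count_sites"], 2)) * L
        datasets.append(
            simulate_counts(
                sites, eta_at(sites), c["count_exposure"], seed=sub(), name="counts_survey"
            )
        )

    scen = Scenario(
        name=name,
        seed=seed,
        domain=domain,
        grid=grid,
        covariate=cov,
        true_alpha=c["true_alpha"],
        true_beta=c["true_beta"],
        field_params=p,
        pc_prior=prior,
        field_values=zeta,
        datasets=datasets,
        thinning_rate=rate,
    )
    if outdir is not None:
        scen.write(outdir)
    return scen


def fit_scenario(
    scen: Scenario,
    datasets=None,
    quad_nx: int = 40,
    knots: int = 9,
    hyper_mode: str = "optimize",
    outer_maxfev: int = 150,
    bias_field: bool = True,
):
    """Fit the standard integrated model to a scenario's datasets.

    The default protocol — 40 × 40 quadrature, a 9 × 9 knot lattice for
    each field, the case-study PC priors, Normal(0, 10²) fixed-effect
    priors, and empirical-Bayes hyperparameter optimization — is the
    package's reference configuration for the 100 km scenarios (see
    docs/methods.md for the resolution choices).
    """
    from .fields import KnotGrid, SpatialField
    from .geometry import build_integration_scheme, make_grid
    from .inference import FitOptions, fit
    from .model import ModelSpec, Priors

    datasets = scen.datasets if datasets is None else datasets
    grid = make_grid(scen.domain, quad_nx, quad_nx)
    scheme = build_integration_scheme(grid)
    kg = KnotGrid.over_bounds(scen.domain.bounds, knots, knots)
    init = MaternParams(rho=35.0, sigma=0.5)
    shared = SpatialField(knots=kg, params=init, prior=scen.pc_prior, role="shared")
    bias = (
        SpatialField(knots=kg, params=init, prior=scen.pc_prior, role="bias")
        if bias_field
        else None
    )
    spec_ = ModelSpec(
        process_covariates=(scen.covariate.name,),
        shared_field=True,
        bias_field=bias_field,
    )
    priors = Priors(
        pc_shared=scen.pc_prior,
        pc_bias=scen.pc_prior if bias_field else None,
        fixed_effect_sd=10.0,
    )
    return fit(
        spec_,
        datasets,
        priors,
        scheme,
        {scen.covariate.name: scen.covariate},
        FitOptions(hyper_mode=hyper_mode, outer_maxfev=outer_maxfev),
        shared_field=shared,
        bias_field=bias,
        domain_area=scen.domain.area,
    )
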