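"""Occurrence and covariate input, cleaning rules, and provenance.

Occurrence tables are delimited text with Darwin-Core column names by
default (``species``, ``decimalLongitude``, ``decimalLatitude``,
``coordinateUncertaintyInMeters``, ``occurrenceStatus``,
``individualCount``, ``datasetName``); a ``column_map`` overrides any of
them.  Cleaning implements the standard pre-modelling steps for aggregated
biodiversity records: dropping observations whose stated coordinate
uncertainty exceeds a threshold (100 m in the reference workflow),
inferring absences from cross-list surveys (a species not recorded at a
visited site is an absence), and z-standardizing covariate rasters.

Rasters are ESRI ASCII grids (plain text).  A provenance ledger records
every dataset and covariate together with its source, citation and the
filters applied, so a fitted model can be traced back to its inputs.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SDMFuseError
from .geometry import Grid, SpatialDomain

EARTH_RADIUS_KM = 6371.0

PROCESSES = ("presence_only", "presence_absence", "count")

DARWIN_CORE = {
    "species": "species",
    "x": "decimalLongitude",
    "y": "decimalLatitude",
    "uncertainty": "coordinateUncertaintyInMeters",
    "status": "occurrenceStatus",
    "count": "individualCount",
    "dataset": "datasetName",
}

#: canonical internal columns of an occurrence table
RECORD_COLUMNS = ["species", "x", "y", "uncertainty_m", "status", "count"]


@dataclass
class OccurrenceDataset:
    """One dataset with its observation process and records.

    ``records`` is a DataFrame with columns ``species, x, y, uncertainty_m,
    status, count``; ``exposure`` is a positive per-record scalar (survey
    effort / site measure, default 1) used by the presence-absence and
    count likelihoods.
    """

    name: str
    process: str
    records: pd.DataFrame
    exposure: np.ndarray = None  # type: ignore[assignment]
    n_rejected: int = 0

    def __post_init__(self):
        if self.process not in PROCESSES:
            raise SDMFuseError("schema-error", f"unknown process {self.process!r}")
        if self.exposure is None:
            self.exposure = np.ones(len(self.records))
        self.exposure = np.asarray(self.exposure, dtype=float)
        if len(self.exposure) != len(self.records):
            raise SDMFuseError("schema-error", "exposure length mismatch")
        if np.any(self.exposure <= 0) and self.process != "count":
            raise SDMFuseError("schema-error", "exposure must be positive")
        if self.process != "presence_absence":
            if (self.records["status"] == "absent").any():
                raise SDMFuseError(
                    "schema-error", "absences only allowed in presence_absence datasets"
                )
        if self.process != "count" and self.records["count"].notna().any():
            raise SDMFuseError("schema-error", "counts only allowed in count datasets")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)

    def subset(self, mask) -> "OccurrenceDataset":
        mask = np.asarray(mask)
        return replace(
            self,
            records=self.records.loc[mask].reset_index(drop=True),
            exposure=self.exposure[mask],
        )


def read_occurrences(
    path,
    process: str,
    column_map: dict | None = None,
    name: str | None = None,
    species: str | None = None,
) -> OccurrenceDataset:
    """Parse a delimited occurrence file into a typed dataset.

    Rows with unparseable coordinates are rejected (their number is kept in
    ``n_rejected``).  In a count dataset, a record marked present without an
    ``individualCount`` is treated as a count of 1.
    """
    cols = dict(DARWIN_CORE)
    if column_map:
        cols.update(column_map)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SDMFuseError("empty-dataset", f"{path} is empty") from None
    if raw.empty:
        raise SDMFuseError("empty-dataset", f"{path} has no rows")
    for key in ("species", "x", "y"):
        if cols[key] not in raw.columns:
            raise SDMFuseError("schema-error", f"missing mandatory column {cols[key]!r}")

    def opt(key):
        c = cols[key]
        return raw[c] if c in raw.columns else pd.Series(np.nan, index=raw.index)

    df = pd.DataFrame(
        {
            "species": raw[cols["species"]].astype(str),
            "x": pd.to_numeric(raw[cols["x"]], errors="coerce"),
            "y": pd.to_numeric(raw[cols["y"]], errors="coerce"),
            "uncertainty_m": pd.to_numeric(opt("uncertainty"), errors="coerce"),
            "status": opt("status")
            .fillna("present")
            .astype(str)
            .str.strip()
            .str.lower(),
            "count": pd.to_numeric(opt("count"), errors="coerce"),
        }
    )
    ok = df["x"].notna() & df["y"].notna()
    n_rejected = int((~ok).sum())
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise SDMFuseError("empty-dataset", "no record had parseable coordinates")
    if species is not None:
        df = df[df["species"] == species].reset_index(drop=True)
    bad = ~df["status"].isin(["present", "absent"])
    if bad.any():
        raise SDMFuseError("schema-error", f"unknown occurrenceStatus {df.loc[bad, 'status'].iloc[0]!r}")
    if process != "count":
        df["count"] = np.nan
    else:
        missing = (df["status"] == "present") & df["count"].isna()
        df.loc[missing, "count"] = 1.0
        df.loc[df["status"] == "absent", "count"] = 0.0
        if (df["count"] < 0).any():
            raise SDMFuseError("bad-count", "negative individualCount")
        df["status"] = "present"
    if name is None:
        dn = raw[cols["dataset"]] if cols["dataset"] in raw.columns else None
        name = str(dn.iloc[0]) if dn is not None else str(path)
    return OccurrenceDataset(name=name, process=process, records=df, n_rejected=n_rejected)


def filter_by_uncertainty(
    ds: OccurrenceDataset,
    max_m: float,
    strict: bool = False,
    ledger: "ProvenanceLedger | None" = None,
) -> OccurrenceDataset:
    """Drop records whose coordinate uncertainty exceeds ``max_m`` metres.

    Records with *missing* uncertainty are retained by default (aggregated
    occurrence data frequently omit the field); ``strict=True`` drops them.
    """
    if not max_m > 0:
        raise SDMFuseError("schema-error", "max_m must be positive")
    u = ds.records["uncertainty_m"]
    keep = (u <= max_m) | (u.isna() & (not strict))
    out = ds.subset(keep.to_numpy())
    if ledger is not None:
        ledger.log_filter(
            ds.name,
            f"coordinate uncertainty <= {max_m} m ({'strict' if strict else 'keep missing'}): "
            f"{len(ds) - len(out)} of {len(ds)} removed",
        )
    return out


def clip_to_domain(
    ds: OccurrenceDataset, domain: SpatialDomain, ledger: "ProvenanceLedger | None" = None
) -> OccurrenceDataset:
    """Drop records falling outside the study domain."""
    keep = domain.contains(ds.records["x"], ds.records["y"])
    out = ds.subset(keep)
    if ledger is not None:
        ledger.log_filter(ds.name, f"clipped to domain: {len(ds) - len(out)} removed")
    return out


def infer_absences(
    presence_lists: list[OccurrenceDataset],
    site_tolerance_km: float = 0.001,
    name: str = "inferred-pa",
) -> OccurrenceDataset:
    """Build a presence-absence dataset from cross-list survey records.

    Sampling sites are the union of distinct record locations (coordinates
    snapped to a ``site_tolerance_km`` lattice); the species pool is the
    union of recorded species.  Each (site, species) pair becomes one
    record: present if the species was recorded there, absent otherwise —
    the standard absence-inference rule for checklist surveys.
    """
    if site_tolerance_km < 0:
        raise SDMFuseError("schema-error", "tolerance must be >= 0")
    frames = [ds.records for ds in presence_lists if len(ds)]
    if not frames:
        raise SDMFuseError("empty-dataset", "no presence records supplied")
    allrec = pd.concat(frames, ignore_index=True)
    tol = max(site_tolerance_km, 1e-12)
    key = list(zip((allrec["x"] / tol).round().astype(np.int64),
                   (allrec["y"] / tol).round().astype(np.int64)))
    allrec = allrec.assign(_site=key)
    sites = allrec.groupby("_site", sort=True)[["x", "y"]].first()
    species = sorted(allrec["species"].unique())
    present = set(zip(allrec["_site"], allrec["species"]))
    rows = []
    for site_key, srow in sites.iterrows():
        for sp in species:
            rows.append(
                {
                    "species": sp,
                    "x": srow["x"],
                    "y": srow["y"],
                    "uncertainty_m": np.nan,
                    "status": "present" if (site_key, sp) in present else "absent",
                    "count": np.nan,
                }
            )
    return OccurrenceDataset(
        name=name, process="presence_absence", records=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# covariate rasters


@dataclass
class CovariateRaster:
    """A gridded covariate X(s) with optional z-standardization metadata."""

    grid: Grid
    values: np.ndarray  # (nx*ny,), NaN = missing
    name: str
    standardization: tuple[float, float] | None = None  # (mean, sd)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_cells:
            raise SDMFuseError("schema-error", "raster size does not match grid")

    def value_at(self, x, y) -> np.ndarray:
        """Nearest-cell lookup; missing or out-of-grid cells are an error."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inext = self.grid.in_extent(x, y)
        if not inext.all():
            raise SDMFuseError("covariate-gap", f"{self.name}: location outside raster extent")
        v = self.values[self.grid.cell_index(x, y)]
        if np.any(np.isnan(v)):
            i = int(np.flatnonzero(np.isnan(v))[0])
            raise SDMFuseError(
                "covariate-gap",
                f"{self.name}: no value at cell containing ({x[i]:.3f}, {y[i]:.3f})",
            )
        return v


def standardize_covariate(r: CovariateRaster) -> CovariateRaster:
    """Center and scale to mean 0, sd 1 over in-domain non-missing cells."""
    mask = r.grid.inside & ~np.isnan(r.values)
    if mask.sum() < 2:
        raise SDMFuseError("constant-covariate", "fewer than 2 in-domain cells")
    mean = float(r.values[mask].mean())
    sd = float(r.values[mask].std(ddof=0))
    if sd == 0:
        raise SDMFuseError("constant-covariate", f"{r.name} has zero variance")
    return replace(r, values=(r.values - mean) / sd, standardization=(mean, sd))


def read_ascii_grid(path, name: str | None = None) -> CovariateRaster:
    """Read an ESRI ASCII grid (square cells) into a raster."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split() and not _is_number(lines[i].split()[0]):
        k, v = lines[i].split()[:2]
        header[k.lower()] = float(v)
        i += 1
    try:
        nx, ny = int(header["ncols"]), int(header["nrows"])
        dx = header["cellsize"]
        x0 = header.get("xllcorner", header.get("xllcenter", 0.0) - dx / 2)
        y0 = header.get("yllcorner", header.get("yllcenter", 0.0) - dx / 2)
    except KeyError as exc:
        raise SDMFuseError("schema-error", f"ASCII grid header missing {exc}") from None
    nodata = header.get("nodata_value")
    data = np.loadtxt(io.StringIO("".join(lines[i:])))
    data = np.atleast_2d(data)
    if data.shape != (ny, nx):
        raise SDMFuseError("schema-error", f"grid body {data.shape} != ({ny}, {nx})")
    vals = data[::-1].ravel()  # ASCII grids store the top row first
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    grid = Grid(
        nx=nx, ny=ny, x0=x0, y0=y0, dx=dx, dy=dx,
        inside=~np.isnan(vals), clipped_area=np.full(nx * ny, dx * dx),
    )
    return CovariateRaster(grid=grid, values=vals, name=name or str(path))


def write_ascii_grid(r_or_grid, values, path, nodata: float = -9999.0) -> None:
    """Write per-cell values on a grid as an ESRI ASCII grid (square cells)."""
    grid = r_or_grid.grid if isinstance(r_or_grid, CovariateRaster) else r_or_grid
    if values is None and isinstance(r_or_grid, CovariateRaster):
        values = r_or_grid.values
    if abs(grid.dx - grid.dy) > 1e-9 * grid.dx:
        raise SDMFuseError("schema-error", "ASCII grids require square cells")
    vals = np.asarray(values, dtype=float).reshape(grid.ny, grid.nx)
    body = np.where(np.isnan(vals), nodata, vals)[::-1]
    with open(path, "w") as fh:
        fh.write(
            f"NCOLS {grid.nx}\nNROWS {grid.ny}\n"
            f"XLLCORNER {grid.x0:.10g}\nYLLCORNER {grid.y0:.10g}\n"
            f"CELLSIZE {grid.dx:.10g}\nNODATA_value {nodata:.10g}\n"
        )
        for row in body:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# projection


def project_lonlat(lon, lat, ref_lon: float, ref_lat: float):
    """Equirectangular projection about a reference point, in km.

    x = R cos(lat0) Δlon, y = R Δlat (radians).  Adequate at regional
    scale; not a substitute for a proper projected CRS at continental
    extents.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if (
        np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90)
        or abs(ref_lon) > 180 or abs(ref_lat) > 90
    ):
        raise SDMFuseError("bad-coordinates", "lon/lat out of range")
    x = EARTH_RADIUS_KM * math.cos(math.radians(ref_lat)) * np.radians(lon - ref_lon)
    y = EARTH_RADIUS_KM * np.radians(lat - ref_lat)
    return x, y


def inverse_project_lonlat(x, y, ref_lon: float, ref_lat: float):
    """Inverse of :func:`project_lonlat`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = ref_lon + np.degrees(x / (EARTH_RADIUS_KM * math.cos(math.radians(ref_lat))))
    lat = ref_lat + np.degrees(y / EARTH_RADIUS_KM)
    return lon, lat


# ---------------------------------------------------------------------------
# provenance


@dataclass
class ProvenanceLedger:
    """Free-text record of every data source and the filters applied to it."""

    datasets: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)

    def add_dataset(self, name: str, source: str = "", citation: str = "") -> None:
        self.datasets.setdefault(
            name, {"source": source, "citation": citation, "filters": []}
        )

    def add_covariate(self, name: str, source: str = "", citation: str = "") -> None:
        self.covariates.setdefault(name, {"source": source, "citation": citation})

    def log_filter(self, dataset: str, message: str) -> None:
        self.add_dataset(dataset)
        self.datasets[dataset]["filters"].append(message)

    @property
    def names(self) -> set:
        return set(self.datasets) | set(self.covariates)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, e in sorted(self.datasets.items()):
                fh.write(f"dataset: {name}\n  source: {e['source']}\n  citation: {e['citation']}\n")
                for msg in e["filters"]:
                    fh.write(f"  filter: {msg}\n")
            for name, e in sorted(self.covariates.items()):
                fh.write(f"covariate: {name}\n  source: {e['source']}\n  citation: {e['citation']}\n")
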