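"""Occurrence parsing, cleaning rules, rasters, projection, provenance."""

import numpy as np
import pandas as pd
import pytest

from sdmfuse import (
    CovariateRaster,
    ProvenanceLedger,
    SpatialDomain,
    filter_by_uncertainty,
    infer_absences,
    make_grid,
    project_lonlat,
    read_occurrences,
    standardize_covariate,
)
from sdmfuse.data_io import (
    inverse_project_lonlat,
    read_ascii_grid,
    write_ascii_grid,
)
from sdmfuse.errors import SDMFuseError

from conftest import make_po


def _write(tmp_path, text, name="occ.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


CSV_OK = (
    "species,decimalLongitude,decimalLatitude,coordinateUncertaintyInMeters,"
    "occurrenceStatus,individualCount,datasetName\n"
    "A,1.0,2.0,50,PRESENT,,gbif\n"
    "A,1.5,2.5,150,present,,gbif\n"
    "B,0.5,0.5,,present,,gbif\n"
)


class TestReadOccurrences:
    def test_parses_valid_rows(self, tmp_path):
        ds = read_occurrences(_write(tmp_path, CSV_OK), process="presence_only")
        assert len(ds) == 3
        assert ds.name == "gbif"
        assert ds.n_rejected == 0
        assert (ds.records["status"] == "present").all()

    def test_missing_species_column_is_schema_error(self, tmp_path):
        bad = CSV_OK.replace("species", "taxon")
        with pytest.raises(SDMFuseError) as exc:
            read_occurrences(_write(tmp_path, bad), process="presence_only")
        assert exc.value.code == "schema-error"

    def test_malformed_coordinate_row_rejected_and_counted(self, tmp_path):
        bad = CSV_OK + "C,not-a-number,3.0,,present,,gbif\n"
        ds = read_occurrences(_write(tmp_path, bad), process="presence_only")
        assert len(ds) == 3
        assert ds.n_rejected == 1

    def test_empty_file_is_empty_dataset(self, tmp_path):
        with pytest.raises(SDMFuseError) as exc:
            read_occurrences(_write(tmp_path, ""), process="presence_only")
        assert exc.value.code == "empty-dataset"

    def test_count_dataset_defaults_missing_count_to_one(self, tmp_path):
        ds = read_occurrences(_write(tmp_path, CSV_OK), process="count")
        assert (ds.records["count"] == 1.0).all()

    def test_custom_column_map(self, tmp_path):
        txt = "sp,x_km,y_km\nA,1,2\n"
        ds = read_occurrences(
            _write(tmp_path, txt),
            process="presence_only",
            column_map={"species": "sp", "x": "x_km", "y": "y_km"},
            name="planar",
        )
        assert ds.records.loc[0, "x"] == 1.0


class TestUncertaintyFilter:
    @pytest.fixture
    def ds(self, tmp_path):
        return read_occurrences(_write(tmp_path, CSV_OK), process="presence_only")

    def test_default_keeps_missing(self, ds):
        out = filter_by_uncertainty(ds, 100.0)
        assert len(out) == 2  # 50 kept, 150 dropped, missing kept

    def test_strict_drops_missing(self, ds):
        out = filter_by_uncertainty(ds, 100.0, strict=True)
        assert len(out) == 1

    def test_infinite_threshold_is_identity(self, ds):
        out = filter_by_uncertainty(ds, np.inf)
        pd.testing.assert_frame_equal(out.records, ds.records)

    def test_idempotent(self, ds):
        once = filter_by_uncertainty(ds, 100.0)
        twice = filter_by_uncertainty(once, 100.0)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_filter_logged_to_ledger(self, ds):
        ledger = ProvenanceLedger()
        filter_by_uncertainty(ds, 100.0, ledger=ledger)
        assert any("100" in m for m in ledger.datasets["gbif"]["filters"])


class TestInferAbsences:
    def test_site_without_species_becomes_absence(self):
        lists = [make_po([[0.0, 0.0]], name="l1"), make_po([[1.0, 1.0]], name="l2")]
        lists[0].records["species"] = "X"
        lists[1].records["species"] = "Y"
        pa = infer_absences(lists)
        assert len(pa) == 4  # 2 sites x 2 species
        tbl = pa.records.set_index(["species", "x"])["status"]
        assert tbl.loc[("X", 0.0)] == "present"
        assert tbl.loc[("X", 1.0)] == "absent"

    def test_species_at_every_site_yields_no_absence(self):
        ds = make_po([[0, 0], [1, 1]])
        pa = infer_absences([ds])
        assert (pa.records["status"] == "present").all()

    def test_matches_bruteforce_site_by_species_table(self):
        # 2 species x 3 sites, fixed recording pattern
        sites = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        recs = {("X", 0), ("X", 2), ("Y", 1)}
        frames = []
        for sp, i in recs:
            d = make_po(sites[[i]])
            d.records["species"] = sp
            frames.append(d)
        pa = infer_absences(frames)
        assert len(pa) == 6
        n_absent = (pa.records["status"] == "absent").sum()
        assert n_absent == 6 - len(recs)  # brute-force enumeration
        # presences never converted to absences
        for sp, i in recs:
            row = pa.records[(pa.records["species"] == sp) & (pa.records["x"] == sites[i, 0])]
            assert (row["status"] == "present").all()

    def test_snapping_merges_nearby_sites(self):
        lists = [make_po([[0.0, 0.0], [0.0004, 0.0]])]  # 0.4 m apart
        pa = infer_absences(lists, site_tolerance_km=0.001)
        assert len(pa) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(SDMFuseError) as exc:
            infer_absences([])
        assert exc.value.code == "empty-dataset"


class TestCovariateRaster:
    def _raster(self, unit_square, values):
        grid = make_grid(unit_square, 2, 2)
        return CovariateRaster(grid=grid, values=np.asarray(values, float), name="v")

    def test_standardize_values(self, unit_square):
        r = standardize_covariate(self._raster(unit_square, [1, 2, 3, 2]))
        assert abs(r.values.mean()) < 1e-12
        assert abs(r.values.std() - 1) < 1e-9
        assert r.standardization is not None

    def test_standardize_is_idempotent_on_standardized_input(self, unit_square):
        r1 = standardize_covariate(self._raster(unit_square, [1, 2, 3, 2]))
        r2 = standardize_covariate(r1)
        assert np.allclose(r1.values, r2.values, atol=1e-12)

    def test_constant_raster_rejected(self, unit_square):
        with pytest.raises(SDMFuseError) as exc:
            standardize_covariate(self._raster(unit_square, [2, 2, 2, 2]))
        assert exc.value.code == "constant-covariate"

    def test_lookup_outside_extent_is_covariate_gap(self, unit_square):
        r = self._raster(unit_square, [1, 2, 3, 4])
        with pytest.raises(SDMFuseError) as exc:
            r.value_at(5.0, 5.0)
        assert exc.value.code == "covariate-gap"

    def test_ascii_grid_round_trip(self, unit_square, tmp_path):
        r = self._raster(unit_square, [1.25, 2.5, np.nan, 4.0])
        path = tmp_path / "cov.asc"
        write_ascii_grid(r, None, path)
        back = read_ascii_grid(path, name="v")
        assert np.allclose(back.values, r.values, equal_nan=True)
        assert back.grid.nx == 2 and np.isclose(back.grid.dx, 0.5)


class TestProjection:
    def test_reference_point_maps_to_origin(self):
        x, y = project_lonlat(10.0, 60.0, 10.0, 60.0)
        assert x == 0.0 and y == 0.0

    def test_one_degree_north_is_arc_length(self):
        # oracle: spherical arc, R = 6371 km -> R * pi/180
        _, y = project_lonlat(10.0, 61.0, 10.0, 60.0)
        assert np.isclose(y, 6371.0 * np.pi / 180.0, rtol=1e-9)
        assert np.isclose(y, 111.1949, atol=1e-3)

    def test_round_trip_identity(self):
        lon = np.array([5.0, 10.0, 12.3])
        lat = np.array([58.0, 60.0, 64.9])
        x, y = project_lonlat(lon, lat, 10.0, 61.0)
        lon2, lat2 = inverse_project_lonlat(x, y, 10.0, 61.0)
        assert np.allclose(lon, lon2, atol=1e-9)
        assert np.allclose(lat, lat2, atol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(SDMFuseError) as exc:
            project_lonlat(200.0, 0.0, 0.0, 0.0)
        assert exc.value.code == "bad-coordinates"


def test_ledger_completeness_matches_sources_used(tmp_path):
    ledger = ProvenanceLedger()
    ledger.add_dataset("gbif", source="fixture", citation="c1")
    ledger.add_covariate("temperature", source="fixture", citation="c2")
    assert ledger.names == {"gbif", "temperature"}
    out = tmp_path / "ledger.txt"
    ledger.write(out)
    text = out.read_text()
    assert "gbif" in text and "temperature" in text


def test_absence_only_allowed_in_presence_absence(tmp_path):
    bad = CSV_OK.replace("B,0.5,0.5,,present", "B,0.5,0.5,,absent")
    with pytest.raises(SDMFuseError) as exc:
        read_occurrences(_write(tmp_path, bad), process="presence_only")
    assert exc.value.code == "schema-error"
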