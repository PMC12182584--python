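"""Coordinate obfuscation: truncation arithmetic, uncertainty
propagation, jitter bounds and distribution, haversine oracle."""

import copy
import math

import numpy as np
import pytest
from scipy import stats

from wdds import displacement_m, jitter_coordinates, truncate_coordinates
from wdds.io import Dataset
from wdds.obfuscation import (M_PER_DEG, has_obfuscation_provenance,
                              truncation_uncertainty_m)
from helpers import make_record


def grid_dataset(n: int, seed: int, lat_band=(-60.0, 60.0)) -> Dataset:
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        records.append(make_record(
            sample_id=f"S{i}", animal_id=f"A{i}",
            latitude=float(rng.uniform(*lat_band)),
            longitude=float(rng.uniform(-180.0, 180.0)),
            source_row=i + 2))
    return Dataset(records=records)


class TestTruncation:
    @pytest.mark.parametrize("value,decimals,expected", [
        (17.7643, 2, 17.76),
        (-88.6521, 0, -88.0),
        (0.29, 2, 0.29),        # binary-float edge case
        (-0.199, 2, -0.19),     # toward zero, not floor
        (17.7643, 6, 17.7643),
    ])
    def test_toward_zero_arithmetic(self, value, decimals, expected):
        ds = Dataset(records=[make_record(latitude=value)])
        out, findings = truncate_coordinates(ds, decimals)
        assert findings == []
        assert out.records[0].latitude == expected

    def test_uncertainty_matches_half_cell_formula(self, fixture_dataset):
        out, _ = truncate_coordinates(fixture_dataset, 2)
        # independent evaluation of the stated formula at the truncated
        # latitude
        phi = out.records[0].latitude
        delta = 0.5 * 10 ** -2
        expected = math.sqrt((delta * 111320) ** 2 +
                             (delta * 111320 * math.cos(
                                 math.radians(phi))) ** 2)
        got = out.records[0].spatial_uncertainty
        assert abs(got - expected) / expected < 1e-6

    def test_uncertainty_at_equator(self):
        # closed form: sqrt(2) * 0.005 * 111320 at zero latitude
        expected = math.sqrt(2) * 0.005 * 111320
        got = truncation_uncertainty_m(2, 0.0)
        assert abs(got - expected) / expected < 1e-12

    def test_uncertainty_never_decreases(self):
        rec = make_record(spatial_uncertainty=1e6)
        out, _ = truncate_coordinates(Dataset(records=[rec]), 0)
        assert out.records[0].spatial_uncertainty == 1e6

    def test_invalid_decimals_rejected(self, fixture_dataset):
        with pytest.raises(ValueError):
            truncate_coordinates(fixture_dataset, 7)

    def test_provenance_appended_and_input_untouched(self, fixture_dataset):
        before = copy.deepcopy(fixture_dataset.records[0].latitude)
        out, _ = truncate_coordinates(fixture_dataset, 1)
        assert len(out.provenance) == 1
        assert out.provenance[0].method == "truncate_coordinates"
        assert fixture_dataset.records[0].latitude == before
        assert not has_obfuscation_provenance(fixture_dataset)
        assert has_obfuscation_provenance(out)

    def test_non_numeric_coordinates_skipped_with_finding(self):
        ds = Dataset(records=[make_record(latitude=None)])
        out, findings = truncate_coordinates(ds, 2)
        assert len(findings) == 1
        assert out.records[0].longitude == -60.0  # untouched


class TestJitter:
    def test_same_seed_identical_output(self, fixture_dataset):
        a, _ = jitter_coordinates(fixture_dataset, 500.0, seed=42)
        b, _ = jitter_coordinates(fixture_dataset, 500.0, seed=42)
        assert [(r.latitude, r.longitude) for r in a.records] == \
            [(r.latitude, r.longitude) for r in b.records]

    def test_different_seed_differs(self, fixture_dataset):
        a, _ = jitter_coordinates(fixture_dataset, 500.0, seed=42)
        b, _ = jitter_coordinates(fixture_dataset, 500.0, seed=43)
        assert a.records[0].latitude != b.records[0].latitude

    def test_tiny_radius_tiny_displacement(self, fixture_dataset):
        out, _ = jitter_coordinates(fixture_dataset, 0.001, seed=1)
        for before, after in zip(fixture_dataset.records, out.records):
            assert displacement_m(before, after) <= 0.0011

    def test_displacement_bounded_by_radius_on_10k_records(self):
        radius = 1000.0
        ds = grid_dataset(10_000, seed=77)
        out, findings = jitter_coordinates(ds, radius, seed=78)
        assert findings == []
        tol = radius * 1.005  # local-approximation slack at |lat| <= 60
        for before, after in zip(ds.records, out.records):
            assert displacement_m(before, after) <= tol

    def test_radial_distribution_is_uniform_on_disk(self):
        # displacements of one point, 10^4 replicates: radial CDF r^2/R^2
        radius = 1000.0
        base = Dataset(records=[make_record() for _ in range(10_000)])
        for i, rec in enumerate(base.records):
            rec.source_row = i + 2
        out, _ = jitter_coordinates(base, radius, seed=5)
        r = np.array([displacement_m(a, b)
                      for a, b in zip(base.records, out.records)])
        stat = stats.kstest(r, lambda x: (x / radius) ** 2)
        assert stat.pvalue > 0.01

    def test_uncertainty_raised_to_radius(self, fixture_dataset):
        out, _ = jitter_coordinates(fixture_dataset, 750.0, seed=2)
        assert all(r.spatial_uncertainty == 750.0 for r in out.records)

    def test_polar_records_skipped(self):
        ds = Dataset(records=[make_record(latitude=89.95)])
        out, findings = jitter_coordinates(ds, 100.0, seed=3)
        assert len(findings) == 1
        assert out.records[0].latitude == 89.95

    def test_longitude_wrapped_at_antimeridian(self):
        ds = Dataset(records=[make_record(latitude=0.0,
                                          longitude=179.99999)])
        out, _ = jitter_coordinates(ds, 5000.0, seed=11)
        assert -180.0 < out.records[0].longitude <= 180.0

    def test_seed_withheld_from_provenance_by_default(self, fixture_dataset):
        out, _ = jitter_coordinates(fixture_dataset, 100.0, seed=9)
        assert out.provenance[0].parameters["seed"] == "withheld"
        recorded, _ = jitter_coordinates(fixture_dataset, 100.0, seed=9,
                                         record_seed=True)
        assert recorded.provenance[0].parameters["seed"] == 9

    def test_radius_and_seed_mandatory(self, fixture_dataset):
        with pytest.raises(ValueError):
            jitter_coordinates(fixture_dataset, 0.0, seed=1)
        with pytest.raises(ValueError):
            jitter_coordinates(fixture_dataset, 100.0, seed=None)


class TestDisplacement:
    def test_identical_points_zero(self):
        assert displacement_m((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_one_degree_of_longitude_at_equator(self):
        # haversine closed form: R * pi/180 for R = 6,371,000
        expected = 6_371_000 * math.pi / 180
        assert abs(displacement_m((0, 0), (0, 1)) - expected) < 0.5

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a = (float(rng.uniform(-90, 90)),
                 float(rng.uniform(-180, 180)))
            b = (float(rng.uniform(-90, 90)),
                 float(rng.uniform(-180, 180)))
            assert displacement_m(a, b) == pytest.approx(
                displacement_m(b, a))
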