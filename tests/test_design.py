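"""Material design: stiffness requirement, power-law calibration, pore
diameters and the staggered hole layout."""

import math

import numpy as np
import pytest

from pillowfit import (
    ContourNodes,
    ElasticCalibration,
    IdealMatrix,
    PressureMatrix,
    compressed_geometry,
    fit_power_law,
    partition_force,
    pore_diameter,
    pore_layout,
    required_stiffness,
)
from pillowfit import reference
from pillowfit.design import staggered_lattice
from pillowfit.segmentation import PartitionMap


class TestRequiredStiffness:
    def test_hand_example(self):
        assert required_stiffness(10.0, 20.0) == pytest.approx(0.5)

    def test_linearity_in_force(self):
        assert required_stiffness(20.0, 8.0) == pytest.approx(2 * required_stiffness(10.0, 8.0))

    def test_nonpositive_height_change_rejected(self):
        with pytest.raises(ValueError):
            required_stiffness(10.0, 0.0)


class TestPartitionForce:
    def test_unit_identity(self):
        m = PressureMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]), pitch_cm=1.0)
        pm = PartitionMap(np.array([[1, 0], [0, 0]]), {1: "a"})
        assert partition_force(m, pm)["a"] == pytest.approx(0.1)  # 1 kPa cm^2 = 0.1 N

    def test_constant_region(self):
        m = PressureMatrix(np.full((5, 10), 2.0), pitch_cm=1.0)
        pm = PartitionMap(np.ones((5, 10), dtype=int), {1: "a"})
        assert partition_force(m, pm)["a"] == pytest.approx(10.0)

    def test_conservation_over_partitions(self, rng):
        vals = rng.random((8, 8)) * 4
        m = PressureMatrix(vals, pitch_cm=1.1)
        labels = 1 + (np.indices((8, 8))[0] >= 4).astype(int)
        pm = PartitionMap(labels, {1: "a", 2: "b"})
        forces = partition_force(m, pm)
        whole = float(vals.sum()) * 1.1**2 * 0.1
        assert sum(forces.values()) == pytest.approx(whole, rel=1e-9)


class TestPowerLaw:
    def test_reference_calibration_coefficients(self):
        a, b, r2 = fit_power_law(reference.ELASTIC_CALIBRATION_PAIRS)
        assert round(a, 3) == 3.613
        assert round(b, 3) == -0.769
        assert r2 > 0.97

    def test_noiseless_recovery(self):
        k = np.array([0.1, 0.2, 0.5, 1.0, 2.0])
        pairs = list(zip(2.0 * k**-0.5, k))
        a, b, _ = fit_power_law(pairs)
        assert a == pytest.approx(2.0, abs=1e-9)
        assert b == pytest.approx(-0.5, abs=1e-9)

    def test_exponent_matches_hand_slope_oracle(self):
        d = np.array([p[0] for p in reference.ELASTIC_CALIBRATION_PAIRS])
        k = np.array([p[1] for p in reference.ELASTIC_CALIBRATION_PAIRS])
        lk, ld = np.log(k), np.log(d)
        slope = ((lk - lk.mean()) * (ld - ld.mean())).sum() / ((lk - lk.mean()) ** 2).sum()
        _, b, _ = fit_power_law(reference.ELASTIC_CALIBRATION_PAIRS)
        assert b == pytest.approx(slope, abs=1e-12)

    def test_too_few_or_nonpositive_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(6, 0.5), (9, 0.3)])
        with pytest.raises(ValueError):
            fit_power_law([(6, 0.5), (9, 0.3), (12, -0.1)])

    def test_calibration_requires_monotone_pairs(self):
        with pytest.raises(ValueError):
            ElasticCalibration.fit([(6, 0.5), (9, 0.6), (12, 0.2)])


class TestPoreDiameter:
    @pytest.fixture
    def cal(self):
        return ElasticCalibration.from_reference()

    def test_clamped_at_lower_bound(self, cal):
        d, clamped = pore_diameter(0.541, cal)
        raw = cal.a * 0.541**cal.b
        assert raw == pytest.approx(5.80, abs=0.01)
        assert d == 6.0 and clamped

    def test_k_one_gives_coefficient(self, cal):
        d, clamped = pore_diameter(1.0, cal)
        assert clamped and d == 6.0  # a ~ 3.61 < valid range
        wide = ElasticCalibration.fit(cal.pairs, valid_d_range_mm=(1.0, 30.0))
        d2, clamped2 = pore_diameter(1.0, wide)
        assert not clamped2
        assert d2 == pytest.approx(wide.a)

    def test_monotone_softer_means_larger_pores(self, cal):
        d_soft, _ = pore_diameter(0.12, cal)
        d_stiff, _ = pore_diameter(0.5, cal)
        assert d_soft > d_stiff

    def test_round_trip_within_fit_residuals(self, cal):
        for d_ref, k in cal.pairs:
            d_pred, _ = pore_diameter(k, cal)
            assert d_pred == pytest.approx(d_ref, rel=0.12)


def square_design(k_values):
    """A simple two-band partition map with an ideal matrix scaled to yield
    the requested required_k per band (at 55 mm node depth)."""
    rows, cols = 10, 10
    labels = np.zeros((rows, cols), dtype=int)
    labels[1:5, 1:9] = 1
    labels[6:9, 1:9] = 2
    vals = np.zeros((rows, cols))
    depth = 55.0
    for lab, k in zip((1, 2), k_values):
        n_cells = (labels == lab).sum()
        total_force = k * depth
        vals[labels == lab] = total_force / (n_cells * 1.0 * 0.1)  # pitch 1 cm
    m = PressureMatrix(vals, pitch_cm=1.0, contact_threshold_kpa=0.0)
    pm = PartitionMap(labels, {1: "top", 2: "bottom"})
    ideal = IdealMatrix(m, "supine", ("T/1",), 1.0)
    nodes = ContourNodes("MS", {"top": ("n1", 10.0, depth), "bottom": ("n2", 20.0, depth)})
    return ideal, pm, nodes


class TestCompressedGeometry:
    def test_depth_and_force_combine(self):
        ideal, pm, nodes = square_design([0.3, 0.15])
        geo = compressed_geometry(nodes, ideal, pm)
        assert geo.entries["top"].compressed_height_mm == pytest.approx(55.0)
        assert geo.entries["top"].required_k == pytest.approx(0.3, rel=1e-9)
        assert geo.entries["bottom"].required_k == pytest.approx(0.15, rel=1e-9)

    def test_zero_depth_rejected(self):
        ideal, pm, _ = square_design([0.3, 0.15])
        nodes = ContourNodes("MS", {"top": ("n1", 10.0, 0.0), "bottom": ("n2", 20.0, 55.0)})
        with pytest.raises(ValueError, match="top"):
            compressed_geometry(nodes, ideal, pm)

    def test_missing_node_rejected(self):
        ideal, pm, _ = square_design([0.3, 0.15])
        nodes = ContourNodes("MS", {"top": ("n1", 10.0, 55.0)})
        with pytest.raises(ValueError, match="bottom"):
            compressed_geometry(nodes, ideal, pm)

    def test_reference_verification_rows_are_self_consistent(self):
        # printed relative errors agree with |calc-actual|/actual to the
        # nearest percent for most partitions (the table rounds k to 2 dp)
        close = 0
        for part, (k_calc, k_act, err) in reference.STIFFNESS_VERIFICATION_MS.items():
            close += abs(abs(k_calc - k_act) / k_act - err) < 0.03
        assert close >= 5


class TestPoreLayout:
    def test_staggered_lattice_spacing(self):
        pts = staggered_lattice(100, 100, 30.0)
        arr = np.array(pts)
        for i in range(len(arr)):
            d = np.hypot(*(arr - arr[i]).T)
            nn = np.min(d[d > 0])
            assert nn >= 30.0 - 1e-9

    def test_uniform_k_gives_single_diameter(self):
        ideal, pm, nodes = square_design([0.3, 0.3])
        geo = compressed_geometry(nodes, ideal, pm)
        layout = pore_layout(geo, pm, ElasticCalibration.from_reference(), pitch_cm=1.0)
        assert len({round(h.diameter_mm, 9) for h in layout.holes}) == 1

    def test_softer_partition_gets_larger_pores(self):
        ideal, pm, nodes = square_design([0.5, 0.12])
        geo = compressed_geometry(nodes, ideal, pm)
        layout = pore_layout(geo, pm, ElasticCalibration.from_reference(), pitch_cm=1.0)
        diam = layout.diameters
        assert diam["bottom"] > diam["top"]
        assert all(6.0 <= h.diameter_mm <= 21.0 for h in layout.holes)

    def test_hole_count_matches_brute_force_scan(self):
        ideal, pm, nodes = square_design([0.4, 0.2])
        geo = compressed_geometry(nodes, ideal, pm)
        cal = ElasticCalibration.from_reference()
        layout = pore_layout(geo, pm, cal, pitch_cm=1.0)
        # independent enumeration: walk the staggered lattice and test
        # point-in-region against the label grid
        cell_mm = 10.0
        count = 0
        dy = cal.pitch_mm * math.sqrt(3) / 2
        j = 0
        while j * dy <= pm.labels.shape[0] * cell_mm + 1e-9:
            x = cal.pitch_mm / 2 if j % 2 else 0.0
            while x <= pm.labels.shape[1] * cell_mm + 1e-9:
                r = min(pm.labels.shape[0] - 1, int(j * dy // cell_mm))
                c = min(pm.labels.shape[1] - 1, int(x // cell_mm))
                count += pm.labels[r, c] > 0
                x += cal.pitch_mm
            j += 1
        assert len(layout.holes) == count

    def test_overlapping_holes_rejected(self):
        ideal, pm, nodes = square_design([0.4, 0.2])
        geo = compressed_geometry(nodes, ideal, pm)
        tight = ElasticCalibration.fit(
            reference.ELASTIC_CALIBRATION_PAIRS, pitch_mm=5.0
        )
        with pytest.raises(ValueError, match="overlap"):
            pore_layout(geo, pm, tight, pitch_cm=1.0)
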