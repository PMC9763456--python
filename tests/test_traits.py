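"""Trait extraction: geometric primitives and the two registries."""

import itertools

import numpy as np
import pytest

from cocoscan import phantom as ph
from cocoscan.recon import Volume
from cocoscan.traits import (
    AGRONOMIC_KEYS,
    DIGITAL_KEYS,
    WeightConfig,
    agronomic_traits,
    average_thickness,
    bounding_box,
    classify_shape,
    ct_integral,
    digital_traits,
    max_inscribed_sphere,
    max_sections,
    min_enclosing_sphere,
)


# -- independent brute-force oracle for the minimal enclosing sphere --------

def _oracle_circumcenter(q):
    """Classic geometric circumcentre formulas (independent derivation)."""
    if len(q) == 2:
        return (q[0] + q[1]) / 2.0
    if len(q) == 3:
        a, b, c = q
        ab, ac = b - a, c - a
        e1 = ab / np.linalg.norm(ab)
        e2 = ac - (ac @ e1) * e1
        if np.linalg.norm(e2) < 1e-12:
            return None  # collinear
        e2 = e2 / np.linalg.norm(e2)
        x2 = np.linalg.norm(ab)
        x3, y3 = ac @ e1, ac @ e2
        cx = x2 / 2.0
        cy = (x3**2 + y3**2 - x3 * x2) / (2.0 * y3)
        return a + cx * e1 + cy * e2
    # 4 points: intersect the three bisector planes
    a = q[0]
    M = 2.0 * (q[1:] - a)
    rhs = np.einsum("ij,ij->i", q[1:], q[1:]) - a @ a
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return None


def _oracle_min_ball(pts):
    """Enumerate all support subsets of size <= 4; smallest valid ball."""
    best = (None, np.inf)
    for k in range(1, 5):
        for sub in itertools.combinations(range(len(pts)), k):
            q = pts[list(sub)]
            if k == 1:
                c = q[0]
            else:
                c = _oracle_circumcenter(q)
                if c is None:
                    continue
            r = float(np.linalg.norm(q[0] - c))
            if np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-9) and r < best[1]:
                best = (c, r)
    return best


class TestMinEnclosingSphere:
    def test_single_point(self):
        c, r = min_enclosing_sphere(np.array([[1.0, 2.0, 3.0]]))
        assert r == 0.0
        assert np.allclose(c, [1, 2, 3])

    def test_two_points(self):
        c, r = min_enclosing_sphere(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
        assert r == pytest.approx(1.0)
        assert np.allclose(c, [1, 0, 0])

    def test_matches_oracle_on_small_clouds(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 13)
            pts = rng.uniform(-10, 10, size=(n, 3))
            _, r = min_enclosing_sphere(pts)
            _, r_oracle = _oracle_min_ball(pts)
            assert r == pytest.approx(r_oracle, abs=1e-9)

    def test_large_cloud_contains_all_points(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5000, 3))
        c, r = min_enclosing_sphere(pts)
        assert np.all(np.linalg.norm(pts - c, axis=1) <= r * (1 + 1e-9) + 1e-9)


class TestMaxInscribedSphere:
    def test_digital_ball(self, digital_ball):
        _, r = max_inscribed_sphere(digital_ball, 1.0)
        assert r == pytest.approx(15.0, abs=0.9)

    def test_single_voxel_convention(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        _, r = max_inscribed_sphere(mask, 1.0)
        assert r == pytest.approx(0.5)

    def test_torus_tube_radius(self):
        n = 64
        z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
        c = (n - 1) / 2.0
        R, a = 20.0, 7.0  # ring radius, tube radius
        rho = np.hypot(np.hypot(y - c, x - c) - R, z - c)
        _, r = max_inscribed_sphere(rho <= a, 1.0)
        assert r == pytest.approx(a, abs=1.0)


class TestBoundingBox:
    def test_cuboid_exact(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[5:15, 10:30, 2:32]
        mask[5:15, 10:30, 2:32] = True  # 10 x 20 x 30 voxels
        bb = bounding_box(mask, 1.0)
        assert (bb["L"], bb["W"], bb["H"]) == (10.0, 20.0, 30.0)
        assert bb["BBVolR"] == pytest.approx(1.0)

    def test_ball_ratio_pi_over_6(self, digital_ball):
        bb = bounding_box(digital_ball, 1.0)
        assert bb["L"] == bb["W"] == bb["H"]
        # voxel-cube extents quantize the diameter to 2r+1 cells
        expected = (4.0 / 3.0 * np.pi * 15.0**3) / 31.0**3
        assert bb["BBVolR"] == pytest.approx(expected, rel=0.02)
        # the continuous limit is pi/6
        assert abs(bb["BBVolR"] - np.pi / 6.0) / (np.pi / 6.0) < 3.0 / 15.0

    def test_ellipsoid_ratio_independent_of_axes(self):
        """BBVolR tends to pi/6 for any ellipsoid axes (up to voxel
        quantization of the box extents, ~1 cell per axis)."""
        n = 73
        z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
        c = (n - 1) / 2.0
        mask = ((x - c) / 30) ** 2 + ((y - c) / 25) ** 2 + ((z - c) / 20) ** 2 <= 1
        bb = bounding_box(mask, 1.0)
        quant = 1.0 / 60 + 1.0 / 50 + 1.0 / 40 + 0.02
        assert abs(bb["BBVolR"] - np.pi / 6.0) / (np.pi / 6.0) < quant


class TestMaxSections:
    def test_ball_sections(self, digital_ball):
        s = max_sections(digital_ball, 1.0, angle_step_deg=5.0)
        area = np.pi * 15.0**2
        assert s["MCSA"] == pytest.approx(area, rel=0.02)
        assert s["MLSA"] == pytest.approx(area, rel=0.02)
        assert s["LSAR"] == pytest.approx(1.0, rel=0.05)

    def test_prolate_ellipsoid_sections(self):
        n = 80
        z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
        cc = (n - 1) / 2.0
        a, c = 15.0, 30.0  # transverse, polar semi-axes (z is polar)
        mask = ((x - cc) / a) ** 2 + ((y - cc) / a) ** 2 + ((z - cc) / c) ** 2 <= 1
        s = max_sections(mask, 1.0, angle_step_deg=5.0)
        assert s["MCSA"] == pytest.approx(np.pi * a * a, rel=0.02)
        assert s["MLSA"] == pytest.approx(np.pi * a * c, rel=0.02)
        assert s["LSAR"] == pytest.approx(c / a, rel=0.05)

    def test_single_slice_mask(self):
        mask = np.zeros((10, 20, 20), bool)
        mask[4, 5:15, 5:15] = True
        s = max_sections(mask, 1.0, angle_step_deg=15.0)
        assert s["MCSA"] == pytest.approx(100.0)


class TestCTIntegralAndThickness:
    def test_uniform_ct_integral(self):
        vol = np.full((10, 10, 10), 200.0)
        mask = np.zeros((10, 10, 10), bool)
        mask[2:5, 2:5, 2:5] = True
        assert ct_integral(vol, mask, 2.0) == pytest.approx(200.0 * 27 * 8.0)

    def test_empty_mask_zero(self):
        assert ct_integral(np.ones((4, 4, 4)), np.zeros((4, 4, 4), bool)) == 0.0

    def test_spherical_shell_thickness(self):
        n = 64
        z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
        c = (n - 1) / 2.0
        r = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
        shell = (r > 20.0) & (r <= 25.0)
        assert average_thickness(shell, 1.0) == pytest.approx(5.0, abs=0.5)

    def test_slab_thickness(self):
        mask = np.zeros((30, 30, 30), bool)
        mask[10:17, 5:25, 5:25] = True  # 7-voxel slab
        assert average_thickness(mask, 1.0) == pytest.approx(7.0, abs=1.0)

    def test_hemispherical_layer_thickness(self):
        n = 72
        z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
        c = (n - 1) / 2.0
        r = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
        layer = (r > 18.0) & (r <= 24.0) & (z < c)
        assert average_thickness(layer, 1.0) == pytest.approx(6.0, rel=0.10)


class TestClassifyShape:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(1.0, "round"), (1.15, "oval"), (1.5, "oblong"), (1.25, "oblong")],
    )
    def test_default_thresholds(self, ratio, expected):
        assert classify_shape(ratio * 10.0, 10.0) == expected

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            classify_shape(1.0, 0.0)


@pytest.fixture(scope="module")
def phantom_tables():
    """Both trait registries on a 1 mm reference fruit (true labels)."""
    # odd grid: the phantom centre falls on a voxel centre
    spec = ph.fruit_spec(grid_shape=(129, 129, 129), voxel_size_mm=1.0)
    mu, labels, gt = ph.make_fruit_phantom(spec)
    ct = Volume(200.0 * mu / spec.mu_water, 1.0, units="ct")
    digi = digital_traits(labels, ct, 1.0, angle_step_deg=3.0)
    agro = agronomic_traits(labels, ct, 1.0, angle_step_deg=3.0)
    return spec, labels, gt, agro, digi


class TestRegistries:
    def test_agronomic_has_21_entries(self, phantom_tables):
        *_, agro, _ = phantom_tables
        assert len(agro) == 21
        assert tuple(agro.entries) == AGRONOMIC_KEYS

    def test_digital_has_47_entries(self, phantom_tables):
        *_, digi = phantom_tables
        assert len(digi) == 47
        assert tuple(digi.entries) == DIGITAL_KEYS

    def test_fruit_length_width_match_phantom(self, phantom_tables):
        spec, _, _, agro, _ = phantom_tables
        outer = spec.compartments[0].semi_axes_mm
        assert agro.value("FL") == pytest.approx(2 * outer[2], abs=2.0)
        assert agro.value("FW") == pytest.approx(2 * outer[0], abs=2.0)

    def test_shape_categories_are_strings(self, phantom_tables):
        *_, agro, _ = phantom_tables
        for key in ("FS", "FLS", "SP", "SLS"):
            assert agro.value(key) in {"round", "oval", "oblong"}

    def test_liquid_weight_identity_at_unit_density(self, phantom_tables):
        _, labels, _, agro, digi = phantom_tables
        assert agro.value("LAW") == pytest.approx(digi.value("MVol") / 1000.0)

    def test_sphere_inclusion_chain(self, phantom_tables):
        *_, digi = phantom_tables
        assert digi.value("ISVol") <= digi.value("Vol") <= digi.value("CSVol")
        assert digi.value("ISVol") <= digi.value("BBVol")
        assert 0 < digi.value("ISVolR") <= 1
        assert 0 < digi.value("CSVolR") <= 1
        assert 0 < digi.value("BBVolR") <= 1

    def test_compartment_volumes_sum_to_fruit(self, phantom_tables):
        _, labels, _, _, digi = phantom_tables
        parts = sum((labels == lid).sum() for lid in range(1, 7))
        assert digi.value("Vol") == pytest.approx(float(parts) * 1.0)

    def test_geometric_digital_traits_within_5pct_of_closed_form(
        self, phantom_tables
    ):
        spec, _, gt, _, digi = phantom_tables
        ax, ay, az = spec.compartments[0].semi_axes_mm
        checks = {
            "Vol": gt.total_volume_mm3,
            "BBVol": 8.0 * ax * ay * az,
            "BBL": 2 * az,
            "BBW": 2 * ay,
            "BBH": 2 * ax,
            "MCSA": np.pi * ax * ay,
            "MLSA": np.pi * ax * az,
            "CSVol": 4.0 / 3.0 * np.pi * az**3,
            # inscribed-sphere radius convention: half a voxel inside the
            # outermost fitting voxel cube
            "ISVol": 4.0 / 3.0 * np.pi * (ax - 0.5) ** 3,
            "Sa": gt.surface_area_mm2["epicarp"],
        }
        for key, expected in checks.items():
            assert digi.value(key) == pytest.approx(expected, rel=0.05), key

    def test_ball_volume_surface_ratio(self, digital_ball):
        ct = Volume(np.full(digital_ball.shape, 200.0), 1.0, units="ct")
        digi = digital_traits(
            digital_ball.astype(np.uint8) * 3, ct, 1.0, angle_step_deg=15.0
        )
        # shell-labelled ball: VolSaR -> r/3 for a sphere
        assert digi.value("SVol") / digi.value("SSa") == pytest.approx(
            15.0 / 3.0, rel=0.03
        )

    def test_missing_compartments_reported_missing(self):
        """A seed (no husk) leaves husk-derived traits empty, not zero."""
        labels = np.zeros((40, 40, 40), np.uint8)
        z, y, x = np.mgrid[0:40, 0:40, 0:40].astype(float)
        r = np.sqrt((z - 19.5) ** 2 + (y - 19.5) ** 2 + (x - 19.5) ** 2)
        labels[r <= 15] = 3  # shell only
        ct = Volume(np.full((40, 40, 40), 300.0), 1.0, units="ct")
        digi = digital_traits(labels, ct, 1.0, angle_step_deg=15.0)
        agro = agronomic_traits(labels, ct, 1.0, angle_step_deg=15.0)
        assert digi.value("CVol") is None
        assert digi.value("MVol") is None
        assert agro.value("SAT") is None
        assert agro.value("CW") is None

    def test_dry_biomass_requires_drying_model(self, phantom_tables):
        spec, labels, _, agro, _ = phantom_tables
        assert agro.value("FDB") is None
        ct = Volume(np.zeros(labels.shape), 1.0, units="ct")
        with_model = agronomic_traits(
            labels, ct, 1.0,
            weights=WeightConfig(dry_matter_fraction=0.45),
            angle_step_deg=15.0,
        )
        assert with_model.value("FDB") == pytest.approx(
            with_model.value("CW") * 0.45
        )

    def test_csv_roundtrip_preserves_order(self, phantom_tables, tmp_path):
        import pandas as pd

        *_, digi = phantom_tables
        digi.to_csv(tmp_path / "digital.csv")
        df = pd.read_csv(tmp_path / "digital.csv")
        assert tuple(df["trait"]) == DIGITAL_KEYS
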