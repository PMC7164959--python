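import numpy as np
import pytest

from mcart.io_formats.particles import ParticleRecord, ParticleSet
from mcart.lateral_analysis import (
    ConcentrationTable,
    OverlayResult,
    class_concentrations,
    nearest_neighbor_distances,
    overlay_em_density,
    overlay_models,
    psii_psi_stoichiometry,
)
from mcart.membranogram import BinaryDensityMap
from mcart.structure_models import MembraneModel, Placement


def bmap(fg, valid=None):
    fg = np.asarray(fg, bool)
    return BinaryDensityMap(
        fg, np.ones_like(fg) if valid is None else valid, 0.5, 0, 1.0
    )


class TestConcentrations:
    def test_zero_particles_all_zero(self):
        table = class_concentrations(ParticleSet(), 0.5)
        assert table.total("all") == 0.0

    def test_simple_arithmetic(self):
        ps = ParticleSet(
            [ParticleRecord("PSII", (float(i), 0, 0), 0.0, "M1") for i in range(56)]
        )
        table = class_concentrations(ps, 0.05)
        assert table.concentration("all", "PSII") == pytest.approx(1120.0)

    def test_reference_row_sums(self):
        table = ConcentrationTable.reference()
        assert table.total("non_appressed") == pytest.approx(
            24 + 501 + 1049 + 1652 + 113 + 1568
        )
        assert table.total("non_appressed") == 4907
        assert table.total("appressed") == 1925

    def test_region_mapping(self):
        ps = ParticleSet(
            [
                ParticleRecord("PSII", (0, 0, 0), 0.0, "M1"),
                ParticleRecord("PSI", (0, 0, 0), 0.0, "M2"),
            ]
        )
        table = class_concentrations(
            ps,
            {"appressed": 0.5, "non_appressed": 0.25},
            {"M1": "appressed", "M2": "non_appressed"},
        )
        assert table.concentration("appressed", "PSII") == pytest.approx(2.0)
        assert table.concentration("non_appressed", "PSI") == pytest.approx(4.0)

    def test_zero_area_errors(self):
        with pytest.raises(ValueError, match="area"):
            class_concentrations(ParticleSet(), 0.0)

    def test_totals_are_row_sums(self):
        table = ConcentrationTable.reference()
        for region in table.regions:
            row = table.table.loc[region]
            assert row["TOTAL"] == pytest.approx(
                sum(row[c] for c in row.index if c != "TOTAL")
            )


class TestStoichiometry:
    def test_single_region(self):
        t = ConcentrationTable.from_concentrations({"r": {"PSII": 1.0, "PSI": 2.0}})
        assert psii_psi_stoichiometry(t) == pytest.approx(1.0)

    def test_reference_equal_areas(self):
        # dimer factor 2: 2 * (24 + 1122) / (1049 + 2) ~ 2.18 at equal weights
        t = ConcentrationTable.reference()
        assert psii_psi_stoichiometry(t) == pytest.approx(
            2 * (24 + 1122) / (1049 + 2), abs=1e-9
        )
        assert psii_psi_stoichiometry(t) == pytest.approx(2.18, abs=0.01)

    def test_area_scale_invariance(self):
        t = ConcentrationTable.reference()
        r1 = psii_psi_stoichiometry(t, {"appressed": 1.0, "non_appressed": 2.0})
        r2 = psii_psi_stoichiometry(t, {"appressed": 2.0, "non_appressed": 4.0})
        assert r1 == pytest.approx(r2)

    def test_zero_psi_errors(self):
        t = ConcentrationTable.from_concentrations({"r": {"PSII": 1.0}})
        with pytest.raises(ValueError, match="PSI"):
            psii_psi_stoichiometry(t)


class TestNearestNeighbor:
    def test_two_particles(self):
        df = nearest_neighbor_distances(np.array([[0.0, 0.0], [30.0, 0.0]]))
        assert np.allclose(df["nn_distance_nm"], [30.0, 30.0])

    def test_square_grid_matches_exhaustive_oracle(self):
        s = 17.0
        gx, gy = np.meshgrid(np.arange(5) * s, np.arange(5) * s, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        df = nearest_neighbor_distances(pts)
        assert np.allclose(df["nn_distance_nm"], s)
        # exhaustive O(n^2) oracle on random instances
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = rng.integers(2, 15)
            pts = rng.uniform(0, 100, size=(n, 2))
            df = nearest_neighbor_distances(pts)
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert np.allclose(np.sort(df["nn_distance_nm"]), np.sort(d.min(axis=1)))

    def test_exclusion_mask_removes_particles(self):
        pts = np.array([[5.0, 5.0], [50.0, 50.0], [52.0, 50.0], [90.0, 90.0]])
        mask = np.zeros((100, 100), bool)
        mask[:10, :10] = True  # excludes the particle at (5, 5)
        df = nearest_neighbor_distances(pts, exclusion_mask=mask)
        assert len(df) == 3
        assert not ((df["u"] == 5.0) & (df["v"] == 5.0)).any()

    def test_within_class_grouping(self):
        pts = np.array([[0.0, 0], [10.0, 0], [1.0, 0], [11.0, 0]])
        classes = np.array(["PSII", "PSII", "ATPS", "ATPS"])
        df = nearest_neighbor_distances(pts, classes)
        assert np.allclose(df["nn_distance_nm"], 10.0)

    def test_fewer_than_two_warns(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            df = nearest_neighbor_distances(np.array([[0.0, 0.0]]))
        assert len(df) == 0


class TestOverlayEMDensity:
    def test_identical_maps_100(self):
        rng = np.random.default_rng(1)
        fg = rng.random((30, 30)) > 0.6
        r = overlay_em_density(bmap(fg), bmap(fg.copy()))
        assert r.percentage == pytest.approx(100.0)

    def test_disjoint_zero(self):
        fg1 = np.zeros((20, 20), bool)
        fg1[:5] = True
        fg2 = np.zeros((20, 20), bool)
        fg2[10:] = True
        assert overlay_em_density(bmap(fg1), bmap(fg2)).percentage == 0.0

    def test_half_middle_quarter_intersection(self):
        # map1 left half, map2 middle half: white = 1/4, green = 1/4,
        # magenta = 1/4 of the grid -> 33.3%
        fg1 = np.zeros((20, 40), bool)
        fg1[:, :20] = True
        fg2 = np.zeros((20, 40), bool)
        fg2[:, 10:30] = True
        r = overlay_em_density(bmap(fg1), bmap(fg2))
        assert (r.white, r.green, r.magenta) == (200, 200, 200)
        assert r.percentage == pytest.approx(100.0 / 3.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            f1 = rng.random((15, 15)) > 0.5
            f2 = rng.random((15, 15)) > 0.5
            r12 = overlay_em_density(bmap(f1), bmap(f2))
            r21 = overlay_em_density(bmap(f2), bmap(f1))
            assert r12.percentage == pytest.approx(r21.percentage)
            assert r12.white == r21.white

    def test_brute_force_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            f1 = rng.random((8, 8)) > 0.5
            f2 = rng.random((8, 8)) > 0.5
            r = overlay_em_density(bmap(f1), bmap(f2))
            w = g = m = 0
            for i in range(8):
                for j in range(8):
                    if f1[i, j] and f2[i, j]:
                        w += 1
                    elif f1[i, j]:
                        g += 1
                    elif f2[i, j]:
                        m += 1
            assert (r.white, r.green, r.magenta) == (w, g, m)

    def test_misregistration_errors(self):
        from mcart.errors import SamplingError

        v1 = np.zeros((20, 20), bool)
        v1[:10] = True
        v2 = np.zeros((20, 20), bool)
        v2[15:] = True
        with pytest.raises(SamplingError, match="mis-registered"):
            overlay_em_density(
                bmap(np.ones((20, 20), bool), v1), bmap(np.ones((20, 20), bool), v2)
            )

    def test_independent_maps_expectation(self):
        """Random independent maps at coverage p: overlap -> 100 p / (2 - p)."""
        rng = np.random.default_rng(5)
        for p in (0.1, 0.3, 0.5):
            vals = []
            for _ in range(60):
                f1 = rng.random((60, 60)) < p
                f2 = rng.random((60, 60)) < p
                vals.append(overlay_em_density(bmap(f1), bmap(f2)).percentage)
            closed = 100 * p / (2 - p)
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - closed) < 3 * se


class TestOverlayModels:
    def _model(self, centers, fp=None, shape=(30, 30)):
        model = MembraneModel(np.ones(shape, bool), 1.0)
        fp = np.ones((2, 2), bool) if fp is None else fp
        for c in centers:
            model.placements.append(Placement(c, 0.0, {"FULL": fp}))
        return model

    def test_copy_on_parallel_plane_100(self):
        m1 = self._model([(5, 5), (20, 20)])
        m2 = self._model([(5, 5), (20, 20)])
        assert overlay_models(m1, m2).percentage == pytest.approx(100.0)

    def test_laterally_separated_zero(self):
        m1 = self._model([(5, 5)])
        m2 = self._model([(25, 25)])
        assert overlay_models(m1, m2).percentage == 0.0

    def test_one_voxel_shift_direct_count(self):
        # 2x2 footprints offset by 1 voxel: white=2, green=2, magenta=2
        m1 = self._model([(10, 10)])
        m2 = self._model([(11, 10)])
        r = overlay_models(m1, m2)
        assert (r.white, r.green, r.magenta) == (2, 2, 2)
        assert r.percentage == pytest.approx(100.0 / 3.0)

    def test_symmetry(self):
        m1 = self._model([(5, 5), (12, 20)])
        m2 = self._model([(6, 5), (20, 12)])
        assert overlay_models(m1, m2).percentage == pytest.approx(
            overlay_models(m2, m1).percentage
        )


class TestOverlayResult:
    def test_percentage_formula(self):
        r = OverlayResult(white=10, green=20, magenta=10)
        assert r.percentage == pytest.approx(25.0)

    def test_empty(self):
        assert OverlayResult(0, 0, 0).percentage == 0.0
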