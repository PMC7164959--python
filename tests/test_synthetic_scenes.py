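import math
from dataclasses import replace

import numpy as np
import pytest

from mcart.errors import PackingError
from mcart.io_formats.particles import ParticleRecord, ParticleSet
from mcart.lateral_analysis import class_concentrations
from mcart.synthetic_scenes import (
    ATPS,
    CYTB6F_APPRESSED,
    PSI,
    PSII,
    RIBO,
    ClassSpec,
    SceneSpec,
    SheetSpec,
    detect_protrusions,
    free_space_nm,
    generate_scene,
    measure_scene,
    recovery_report,
    sweep_for,
    table1_scene,
    visible_templates,
)


@pytest.fixture(scope="module")
def small_table1():
    spec = table1_scene(extent_nm=(250.0, 200.0), seed=3)
    return spec, *generate_scene(spec)


class TestGenerateScene:
    def test_empty_scene_flat_membranogram(self):
        spec = SceneSpec(
            extent_nm=(100.0, 100.0),
            sheets=(SheetSpec("M1", 0.0, "non_appressed", +1),),
            seed=1,
        )
        vol, truth = generate_scene(spec)
        assert len(truth.particles) == 0
        from mcart.membranogram import sample_density

        m = sample_density(vol, truth.surface("M1", "stromal"), 2.0)
        vals = m.values[m.valid]
        assert np.ptp(vals) < 1e-3  # flat: membrane slab only

    def test_expected_counts_rounding(self):
        # 1122 per um^2 on 0.2 um^2 -> exactly 224 dimers
        spec = SceneSpec(
            extent_nm=(500.0, 400.0),
            sheets=(SheetSpec("M1", 0.0, "appressed", +1, (PSII,)),),
            seed=2,
        )
        vol, truth = generate_scene(spec)
        assert truth.expected_counts[("M1", "PSII")] == 224
        assert len(truth.particles.filter(particle_class="PSII")) == 224

    def test_fixed_seed_identical_volume(self):
        spec = table1_scene(extent_nm=(150.0, 120.0), seed=9)
        v1, t1 = generate_scene(spec)
        v2, t2 = generate_scene(spec)
        assert np.array_equal(v1.data, v2.data)
        assert t1.particles.positions_nm().tolist() == t2.particles.positions_nm().tolist()

    def test_infeasible_concentration_errors(self):
        dense = replace(RIBO, concentration_um2=5000.0)
        spec = SceneSpec(
            extent_nm=(200.0, 200.0),
            sheets=(SheetSpec("M1", 0.0, "non_appressed", +1, (dense,)),),
            seed=0,
        )
        with pytest.raises(PackingError):
            generate_scene(spec)

    def test_voxel_size_guard(self):
        with pytest.raises(ValueError, match="half the smallest footprint"):
            SceneSpec(
                sheets=(
                    SheetSpec(
                        "M1", 0.0, "appressed", +1,
                        (ClassSpec("PSI", 10.0, 3.0, 2.0, False, "stromal"),),
                    ),
                ),
                voxel_size_A=13.68,
            )

    def test_particles_lie_on_their_membranes(self, small_table1):
        _, vol, truth = small_table1
        for rec in truth.particles:
            sheet = truth.sheet(rec.membrane_id)
            assert rec.position_nm[2] == pytest.approx(sheet.z_nm)


class TestFreeSpace:
    def test_appressed_stromal_blocked(self, small_table1):
        _, vol, truth = small_table1
        # stromal gap is 3 nm; with 4 nm membranes nothing stromal fits
        assert free_space_nm(truth, "M2", "stromal") <= 0.0
        assert visible_templates(truth, "M2", "stromal") == []

    def test_open_side_unbounded(self, small_table1):
        _, vol, truth = small_table1
        assert free_space_nm(truth, "M1", "stromal") == math.inf

    def test_luminal_fits_psii(self, small_table1):
        _, vol, truth = small_table1
        vis = visible_templates(truth, "M2", "luminal")
        assert {t.name for t in vis} == {"PSII", "CYTB6F"}


class TestDetect:
    def test_noise_free_sparse_psii(self):
        psii = replace(PSII, concentration_um2=200.0)
        spec = SceneSpec(
            extent_nm=(250.0, 200.0),
            sheets=(SheetSpec("M1", 0.0, "appressed", +1, (psii,)),),
            seed=5,
        )
        vol, truth = generate_scene(spec)
        picked = measure_scene(vol, truth, templates=(psii,))
        rep = recovery_report(truth, picked, tolerance_nm=6.0).set_index("class")
        assert rep.loc["PSII", "precision"] == 1.0
        assert rep.loc["PSII", "recall"] == 1.0
        assert rep.loc["PSII", "rmse_nm"] < 1.368  # within one voxel

    def test_dimer_angle_within_5_degrees(self):
        psii = replace(PSII, concentration_um2=200.0)
        spec = SceneSpec(
            extent_nm=(250.0, 200.0),
            sheets=(SheetSpec("M1", 0.0, "appressed", +1, (psii,)),),
            seed=6,
        )
        vol, truth = generate_scene(spec)
        picked = measure_scene(vol, truth, templates=(psii,))
        tpos = truth.particles.positions_nm()
        ppos = picked.positions_nm()
        errs = []
        for i in range(len(tpos)):
            d = np.linalg.norm(ppos - tpos[i], axis=1)
            j = int(np.argmin(d))
            assert d[j] < 6.0
            da = (truth.particles[i].angle - picked[j].angle) % math.pi
            errs.append(min(da, math.pi - da))
        assert np.degrees(np.max(errs)) < 5.0

    def test_empty_scene_empty_set(self):
        # pad the volume so the sweep spanning the PSI height stays in bounds
        spec = SceneSpec(
            extent_nm=(100.0, 100.0),
            sheets=(SheetSpec("M1", 0.0, "non_appressed", +1),),
            seed=1,
            z_pad_nm=8.0,
        )
        vol, truth = generate_scene(spec)
        stack = sweep_for(vol, truth, "M1", "stromal", templates=(PSI,))
        picked = detect_protrusions(stack, templates=(PSI,), side="stromal")
        assert len(picked) == 0

    def test_sweep_must_span_heights(self, small_table1):
        _, vol, truth = small_table1
        stack = sweep_for(vol, truth, "M1", "stromal", templates=(PSI,))
        with pytest.raises(ValueError, match="span template heights"):
            detect_protrusions(stack, templates=(PSI, ATPS, RIBO), side="stromal")


class TestRecoveryReport:
    def test_perfect_pick(self, particle_set):
        rep = recovery_report(particle_set, particle_set, 5.0).set_index("class")
        assert (rep["precision"] == 1.0).all()
        assert (rep["recall"] == 1.0).all()
        assert (rep["rmse_nm"] == 0.0).all()

    def test_empty_pick_zero_recall(self, particle_set):
        rep = recovery_report(particle_set, ParticleSet(), 5.0).set_index("class")
        assert (rep["recall"] == 0.0).all()

    def test_partial_recall(self):
        truth = ParticleSet(
            [ParticleRecord("PSI", (10.0 * i, 0, 0), 0.0, "M") for i in range(4)]
        )
        picked = ParticleSet(
            [ParticleRecord("PSI", (10.0 * i, 0.5, 0), 0.0, "M") for i in range(2)]
        )
        rep = recovery_report(truth, picked, 2.0).set_index("class")
        assert rep.loc["PSI", "recall"] == pytest.approx(0.5)
        assert rep.loc["PSI", "precision"] == pytest.approx(1.0)

    def test_tolerance_guard(self, particle_set):
        with pytest.raises(ValueError, match="positive"):
            recovery_report(particle_set, particle_set, 0.0)


class TestEndToEnd:
    def test_table1_recovery_within_3se(self, small_table1):
        spec, vol, truth = small_table1
        picked = measure_scene(vol, truth)
        region_of = truth.region_of_membrane()
        areas = truth.region_areas_um2()
        table = class_concentrations(picked, areas, region_of)
        for region, classes in (
            ("appressed", (PSII, CYTB6F_APPRESSED)),
            ("non_appressed", (PSI, ATPS, RIBO)),
        ):
            for cspec in classes:
                n_true = sum(
                    truth.expected_counts.get((s.membrane_id, cspec.name), 0)
                    for s in truth.sheets
                    if s.region_class == region
                )
                se = max(math.sqrt(n_true), 1.0) / areas[region]
                got = table.concentration(region, cspec.name)
                want = n_true / areas[region]
                assert abs(got - want) <= 3 * se, (region, cspec.name, got, want)

    def test_lateral_heterogeneity_preserved(self, small_table1):
        spec, vol, truth = small_table1
        picked = measure_scene(vol, truth)
        table = class_concentrations(
            picked, truth.region_areas_um2(), truth.region_of_membrane()
        )
        assert table.concentration("appressed", "PSI") == 0.0
        assert table.concentration("appressed", "ATPS") == 0.0
        assert table.concentration("appressed", "RIBO") == 0.0

    def test_double_resolution_stability(self):
        # measured concentrations change < 2% of the input at half voxel size
        psii = replace(PSII, concentration_um2=400.0)
        results = {}
        for voxel in (13.68, 6.84):
            spec = SceneSpec(
                extent_nm=(250.0, 200.0),
                sheets=(SheetSpec("M1", 0.0, "appressed", +1, (psii,)),),
                voxel_size_A=voxel,
                seed=8,
            )
            vol, truth = generate_scene(spec)
            picked = measure_scene(vol, truth, templates=(psii,))
            results[voxel] = len(picked.filter(particle_class="PSII"))
        n_true = round(400.0 * 0.05)
        assert abs(results[13.68] - results[6.84]) <= 0.02 * n_true + 1
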