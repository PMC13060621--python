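import numpy as np
import pytest

from sxalign.cell import UnitCell
from sxalign.config import SimConfig
from sxalign.localfit import MilleRecord, build_mille_record, local_fit, truth_pairing
from sxalign.millepede import (
    ConstraintSet,
    GlobalParamRegistry,
    NormalSystem,
    accumulate,
    full_matrix_solve,
    hierarchy_constraints,
    local_updates,
    reject_outliers,
    solve,
    weak_mode_report,
)
from sxalign.sketch import simulate_dataset


def random_record(rng, n_pairs, n_local, labels, crystal_id=0):
    """A synthetic converged-looking record with dense derivatives."""
    m = 3 * n_pairs
    A = rng.normal(size=(m, n_local))
    G = rng.normal(size=(m, len(labels)))
    G[2::3, :] = 0.0  # excitation rows never depend on geometry
    return MilleRecord(
        values=rng.normal(scale=0.1, size=m),
        sigmas=np.tile([0.3, 0.3, 0.2], n_pairs),
        local_derivs=A,
        global_labels=np.asarray(labels, dtype=int),
        global_derivs=G,
        crystal_id=crystal_id,
    )


class TestRegistry:
    def test_level_one_stock_detector(self, geometry4):
        reg = GlobalParamRegistry.from_hierarchy(geometry4, level=1)
        assert len(reg) == 30  # root + 4 panels, 6 kinds each
        assert reg.params[0] == ("all", "tx")
        assert ("q2", "ry") in reg.labels

    def test_level_zero_and_kind_selection(self, geometry4):
        reg = GlobalParamRegistry.from_hierarchy(geometry4, level=0,
                                                 kinds=("tx", "ty", "rz"))
        assert reg.params == [("all", "tx"), ("all", "ty"), ("all", "rz")]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            GlobalParamRegistry([("a", "tx"), ("a", "tx")])

    def test_empty_kinds_rejected(self, geometry4):
        with pytest.raises(ValueError):
            GlobalParamRegistry.from_hierarchy(geometry4, kinds=())


class TestHierarchyConstraints:
    def test_stock_detector_rows(self, geometry4):
        reg = GlobalParamRegistry.from_hierarchy(geometry4, level=1)
        cons = hierarchy_constraints(reg, geometry4)
        # 6 sibling sum rows + 1 beam-rotation gauge row
        assert cons.n_constraints == 7
        assert any("gauge" in d for d in cons.descriptions)
        # each sibling row sums exactly the four panels of one kind
        for row, desc in zip(cons.matrix, cons.descriptions):
            if "gauge" not in desc:
                assert row.sum() == 4

    def test_single_child_forced_to_zero(self, geometry4):
        from sxalign.geometry import DetectorGeometry, PanelGroup
        geom = DetectorGeometry(dict(geometry4.panels),
                                PanelGroup("top", [PanelGroup("only", ["q0"])]))
        reg = GlobalParamRegistry.from_hierarchy(geom, level=2, kinds=("tx",))
        cons = hierarchy_constraints(reg, geom)
        sol_rows = [r for r, d in zip(cons.matrix, cons.descriptions)
                    if "only.children" in d]
        assert len(sol_rows) == 1
        assert np.count_nonzero(sol_rows[0]) == 1  # q0.tx alone must vanish

    def test_two_level_tree_hand_enumeration(self, geometry4):
        from sxalign.geometry import DetectorGeometry, PanelGroup
        tree = PanelGroup("top", [PanelGroup("left", ["q0", "q1"]),
                                  PanelGroup("right", ["q2", "q3"])])
        geom = DetectorGeometry(dict(geometry4.panels), tree)
        reg = GlobalParamRegistry.from_hierarchy(geom, level=2, kinds=("tx", "ty"))
        cons = hierarchy_constraints(reg, geom)
        # top: 2 kinds; left: 2; right: 2; no gauge (rz inactive) = 6 rows
        assert cons.n_constraints == 6

    def test_dependent_rows_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(matrix=np.array([[1.0, 1.0], [2.0, 2.0]]))


class TestAccumulate:
    def test_zero_residuals_leave_rhs_zero(self, rng):
        reg = GlobalParamRegistry([("all", "tx"), ("all", "ty")])
        rec = random_record(rng, 6, 4, [0, 1])
        rec.values[:] = 0.0
        system = NormalSystem.empty(reg)
        accumulate(rec, system, reg)
        assert np.allclose(system.rhs, 0.0)
        assert not np.allclose(system.matrix, 0.0)

    def test_single_crystal_matches_dense_schur_formula(self, rng):
        """Oracle: evaluate C - G Gamma^-1 G^T and the reduced rhs directly."""
        reg = GlobalParamRegistry([("all", "tx"), ("q0", "tx"), ("q0", "ty")])
        rec = random_record(rng, 8, 5, [0, 1, 2])
        system = NormalSystem.empty(reg)
        accumulate(rec, system, reg)
        w = 1.0 / rec.sigmas ** 2
        B, A, r = rec.global_derivs, rec.local_derivs, rec.values
        C = (B * w[:, None]).T @ B
        G = (B * w[:, None]).T @ A
        Gam = (A * w[:, None]).T @ A
        want_C = C - G @ np.linalg.inv(Gam) @ G.T
        want_rhs = -(B.T @ (w * r)) + G @ np.linalg.inv(Gam) @ (A.T @ (w * r))
        assert np.allclose(system.matrix, want_C, atol=1e-10)
        assert np.allclose(system.rhs, want_rhs, atol=1e-10)

    def test_order_invariance(self, rng):
        reg = GlobalParamRegistry([("all", "tx"), ("q0", "tx")])
        records = [random_record(rng, 5, 4, [0, 1], i) for i in range(20)]
        s1 = NormalSystem.empty(reg)
        for r in records:
            accumulate(r, s1, reg)
        s2 = NormalSystem.empty(reg)
        for r in reversed(records):
            accumulate(r, s2, reg)
        scale = np.abs(s1.matrix).max()
        assert np.allclose(s1.matrix, s2.matrix, atol=1e-10 * scale)
        assert np.allclose(s1.rhs, s2.rhs, atol=1e-10 * max(1, np.abs(s1.rhs).max()))

    def test_singular_local_block_skipped(self, rng):
        reg = GlobalParamRegistry([("all", "tx")])
        rec = random_record(rng, 5, 4, [0])
        rec.local_derivs[:] = 0.0
        system = NormalSystem.empty(reg)
        with pytest.warns(UserWarning, match="singular"):
            accumulate(rec, system, reg)
        assert system.n_skipped == 1
        assert system.n_crystals == 0


class TestSolveEquivalence:
    @pytest.mark.parametrize("n_crystals", [1, 3, 5, 10])
    def test_schur_equals_full_matrix(self, n_crystals):
        """The Schur-reduced solve must agree with the dense joint solve."""
        rng = np.random.default_rng(100 + n_crystals)
        reg = GlobalParamRegistry([("all", "tx"), ("q0", "tx"), ("q1", "tx")])
        cons = ConstraintSet(matrix=np.array([[0.0, 1.0, 1.0]]))
        records = [random_record(rng, 10, 4, [0, 1, 2], i) for i in range(n_crystals)]
        system = NormalSystem.empty(reg)
        for r in records:
            accumulate(r, system, reg)
        sol = solve(system, cons, reg)
        dg_full, da_full = full_matrix_solve(records, reg, cons)
        scale = max(1.0, np.abs(sol.shifts).max())
        assert np.max(np.abs(sol.shifts - dg_full)) <= 1e-8 * scale
        # back-substituted local updates match the joint solve
        das = local_updates(records, sol.shifts, reg)
        for da, da_joint in zip(das, da_full):
            assert np.allclose(da, da_joint, atol=1e-8)

    def test_constraints_satisfied(self, fitted_records):
        registry, constraints, records, _ = fitted_records
        system = NormalSystem.empty(registry)
        for r in records:
            accumulate(r, system, registry)
        sol = solve(system, constraints, registry)
        assert np.max(np.abs(constraints.matrix @ sol.shifts)) <= 1e-9
        assert sol.constraint_residual <= 1e-9

    def test_real_records_schur_vs_full(self, fitted_records):
        registry, constraints, records, _ = fitted_records
        system = NormalSystem.empty(registry)
        for r in records[:5]:
            accumulate(r, system, registry)
        sol = solve(system, constraints, registry)
        dg_full, _ = full_matrix_solve(records[:5], registry, constraints)
        assert np.max(np.abs(sol.shifts - dg_full)) <= 1e-8 * max(1, np.abs(dg_full).max())

    def test_recovers_injected_shift_direction(self, fitted_records):
        """With q0's model shifted +50 um in x, the solved correction moves the
        q0 corner back by about -50 um."""
        from sxalign.align import report_corner_motions
        registry, constraints, records, model = fitted_records
        system = NormalSystem.empty(registry)
        for r in records:
            accumulate(r, system, registry)
        sol = solve(system, constraints, registry)
        report = report_corner_motions(sol.to_correction_set(), model)
        assert report.loc["q0", "x"] == pytest.approx(-0.05, abs=0.01)

    def test_zero_rhs_gives_zero_shifts(self, rng):
        reg = GlobalParamRegistry([("all", "tx"), ("q0", "tx")])
        rec = random_record(rng, 8, 4, [0, 1])
        rec.values[:] = 0.0
        system = NormalSystem.empty(reg)
        accumulate(rec, system, reg)
        sol = solve(system, ConstraintSet(np.zeros((0, 2))), reg)
        assert np.allclose(sol.shifts, 0.0, atol=1e-12)

    def test_empty_system_errors(self):
        reg = GlobalParamRegistry([("all", "tx")])
        with pytest.raises(ValueError):
            solve(NormalSystem.empty(reg), ConstraintSet(np.zeros((0, 1))), reg)

    def test_decoupled_records_give_zero_globals(self, rng):
        """With all global derivatives zero the joint solve decouples: dg = 0
        and each local update equals its own local solve."""
        reg = GlobalParamRegistry([("all", "tx")])
        records = [random_record(rng, 6, 4, [0], i) for i in range(3)]
        for r in records:
            r.global_derivs[:] = 0.0
        dg, das = full_matrix_solve(records, reg,
                                    ConstraintSet(np.array([[1.0]])))
        assert np.allclose(dg, 0.0, atol=1e-12)
        for r, da in zip(records, das):
            w = 1.0 / r.sigmas ** 2
            A = r.local_derivs
            want = np.linalg.solve((A * w[:, None]).T @ A, -(A.T @ (w * r.values)))
            assert np.allclose(da, want, atol=1e-10)


class TestOutlierRejection:
    def test_clean_records_mostly_survive(self, fitted_records):
        _, _, records, _ = fitted_records
        kept, report = reject_outliers(records, cutoff=4.0)
        assert len(kept) >= 0.95 * len(records)

    def test_constructed_outlier_rejected(self, fitted_records):
        import copy
        _, _, records, _ = fitted_records
        bad = copy.deepcopy(records[0])
        bad.values *= 100.0
        bad.crystal_id = 999
        kept, report = reject_outliers(records + [bad], cutoff=4.0)
        assert 999 in set(report.crystal_id)
        assert len(kept) == len(records)

    def test_infinite_cutoff_is_identity(self, fitted_records):
        _, _, records, _ = fitted_records
        kept, report = reject_outliers(records, cutoff=np.inf)
        assert kept == list(records)
        assert len(report) == 0


class TestWeakModes:
    def test_tilt_squeeze_degeneracy_without_excitation(self, triclinic_systems):
        """Tilting the detector about x mimics squeezing a triclinic cell along
        y (and y/x): without excitation-error rows the constrained normal
        matrix is rank deficient and the tilts are flagged as weak modes."""
        reg, cons, systems = triclinic_systems
        vals, modes = weak_mode_report(systems[False], cons, reg)
        assert len(modes) >= 1
        flagged_params = {p for _, combo in modes for p in combo}
        assert any(p in flagged_params for p in ("all.rx", "all.ry"))
        from sxalign.millepede import WeakModeError
        with pytest.raises(WeakModeError):
            solve(systems[False], cons, reg)

    def test_excitation_terms_mitigate_degeneracy(self, triclinic_systems):
        reg, cons, systems = triclinic_systems
        vals, modes = weak_mode_report(systems[True], cons, reg)
        assert modes == []
        sol = solve(systems[True], cons, reg)  # solvable without difficulty
        assert np.all(np.isfinite(sol.shifts))

    def test_stock_monoclinic_configuration_has_no_weak_modes(self, fitted_records):
        registry, constraints, records, _ = fitted_records
        system = NormalSystem.empty(registry)
        for r in records:
            accumulate(r, system, registry)
        _, modes = weak_mode_report(system, constraints, registry)
        assert modes == []


class TestScaling:
    def test_system_size_independent_of_crystal_count(self, rng):
        """Accumulation is one bounded-cost update per record and the reduced
        system never grows: solve cost is independent of the crystal count."""
        reg = GlobalParamRegistry([("all", "tx"), ("q0", "tx")])
        sizes = []
        for n in (5, 50):
            system = NormalSystem.empty(reg)
            for i in range(n):
                accumulate(random_record(rng, 5, 4, [0, 1], i), system, reg)
            sizes.append(system.matrix.shape)
            assert system.n_crystals == n
        assert sizes[0] == sizes[1] == (2, 2)
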