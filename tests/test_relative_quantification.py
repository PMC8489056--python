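"""2^-ΔΔCq fold changes, multi-gene references, between-run correction."""

import numpy as np
import pandas as pd
import pytest

import refstab as rs
from refstab.cq_data import CqValidationError


def _matrix(values, genes, meta=None):
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=genes,
        columns=[f"s{j}" for j in range(np.asarray(values).shape[1])],
    )
    return rs.CqMatrix(values=df, meta=meta)


class TestReferenceCq:
    def test_mean_of_two_references(self):
        m = _matrix([[16.0, 17.0], [18.0, 19.0]], ["r1", "r2"])
        ref = rs.reference_cq(m, ["r1", "r2"])
        assert ref.tolist() == pytest.approx([17.0, 18.0])

    def test_single_reference_is_identity(self):
        m = _matrix([[16.0, 17.0], [18.0, 19.0]], ["r1", "r2"])
        ref = rs.reference_cq(m, ["r1"])
        assert ref.tolist() == pytest.approx([16.0, 17.0])

    def test_empty_reference_set_rejected(self):
        m = _matrix([[16.0, 17.0]], ["r1"])
        with pytest.raises(CqValidationError):
            rs.reference_cq(m, [])


class TestDdcq:
    def test_calibrator_fold_is_one(self):
        target = pd.Series([20.0, 19.0, 21.0], index=["s0", "s1", "s2"])
        ref = pd.Series([17.0, 17.0, 17.0], index=["s0", "s1", "s2"])
        tab = rs.ddcq_fold_change(target, ref, calibrator="s0")
        folds = dict(zip(tab.table["sample"], tab.table["fold_change"]))
        assert folds["s0"] == pytest.approx(1.0)
        assert folds["s1"] == pytest.approx(2.0)  # one cycle below calibrator
        assert folds["s2"] == pytest.approx(0.5)

    def test_group_calibrator_uses_group_mean(self):
        target = pd.Series([20.0, 21.0, 18.0], index=["s0", "s1", "s2"])
        ref = pd.Series([17.0] * 3, index=["s0", "s1", "s2"])
        groups = pd.Series(["N1", "N1", "N3"], index=["s0", "s1", "s2"])
        tab = rs.ddcq_fold_change(target, ref, calibrator="N1", groups=groups)
        folds = dict(zip(tab.table["sample"], tab.table["fold_change"]))
        # calibrator dCq = mean(3.0, 4.0) = 3.5
        assert folds["s2"] == pytest.approx(2.0**2.5)

    def test_reference_equal_to_target_gives_unit_folds(self):
        x = pd.Series([20.0, 23.0, 18.5], index=["s0", "s1", "s2"])
        tab = rs.ddcq_fold_change(x, x, calibrator="s0")
        assert tab.table["fold_change"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_loading_shift_invariance(self):
        rng = np.random.default_rng(0)
        target = pd.Series(rng.uniform(18, 25, 6), index=[f"s{i}" for i in range(6)])
        ref = pd.Series(rng.uniform(15, 18, 6), index=target.index)
        shift = pd.Series(rng.normal(0, 2, 6), index=target.index)
        base = rs.ddcq_fold_change(target, ref, calibrator="s0").table["fold_change"]
        moved = rs.ddcq_fold_change(target + shift, ref + shift, calibrator="s0").table[
            "fold_change"
        ]
        assert moved.tolist() == pytest.approx(base.tolist(), rel=1e-10)

    def test_missing_calibrator_rejected(self):
        x = pd.Series([20.0, 21.0, 22.0], index=["s0", "s1", "s2"])
        with pytest.raises(CqValidationError, match="calibrator"):
            rs.ddcq_fold_change(x, x, calibrator="nope")

    def test_shared_calibrator_mode(self):
        """An explicit baseline ΔCq scales a second target to the first's."""
        t2 = pd.Series([22.0, 21.0], index=["s0", "s1"])
        ref = pd.Series([17.0, 17.0], index=["s0", "s1"])
        tab = rs.ddcq_fold_change(t2, ref, calibrator="shared", calibrator_delta_cq=3.0)
        folds = dict(zip(tab.table["sample"], tab.table["fold_change"]))
        assert folds["s0"] == pytest.approx(2.0**-2)  # dCq 5 vs baseline 3


class TestSimulatedRecovery:
    def test_fourfold_upregulation_recovered(self):
        """Mean estimated fold for a true 4x group lands in [3.5, 4.5]."""
        folds = []
        for seed in range(100):
            cfg = rs.SimConfig(
                genes=[
                    rs.GeneSpec("ref1", 17.0, 0.05, 0.05),
                    rs.GeneSpec("ref2", 18.0, 0.05, 0.05),
                    rs.GeneSpec("filler", 19.0, 0.1, 0.1),
                ],
                seed=seed,
            )
            ds = rs.generate_cq_dataset(cfg)
            ds = rs.inject_target_gene(
                ds, "far", {"N3m": 4.0, "N3f": 4.0}, base_cq=24.0
            )
            m = rs.collapse_replicates(ds.records, meta=ds.meta)
            ref = rs.reference_cq(m, ["ref1", "ref2"])
            tab = rs.ddcq_fold_change(
                m.values.loc["far"], ref, calibrator="N1", groups=m.groups()
            )
            grp = tab.table.groupby("group")["fold_change"].mean()
            folds.append((grp["N3m"] + grp["N3f"]) / 2)
        assert 3.5 < float(np.mean(folds)) < 4.5

    def test_two_gene_reference_beats_single_noisy_reference(self):
        """RMSE of fold estimates falls when a clean gene joins a noisy one."""
        rmse_single, rmse_combo = [], []
        for seed in range(100):
            cfg = rs.SimConfig(
                genes=[
                    rs.GeneSpec("noisyref", 17.0, 0.0, 0.6),
                    rs.GeneSpec("cleanref", 18.0, 0.0, 0.05),
                    rs.GeneSpec("filler", 19.0, 0.1, 0.1),
                ],
                seed=seed,
            )
            ds = rs.generate_cq_dataset(cfg)
            true_folds = {"N3m": 4.0, "N3f": 2.0}
            ds = rs.inject_target_gene(ds, "far", true_folds, base_cq=24.0)
            m = rs.collapse_replicates(ds.records, meta=ds.meta)
            for refs, store in (
                (["noisyref"], rmse_single),
                (["noisyref", "cleanref"], rmse_combo),
            ):
                ref = rs.reference_cq(m, refs)
                tab = rs.ddcq_fold_change(
                    m.values.loc["far"], ref, calibrator="N1", groups=m.groups()
                )
                grp = tab.table.groupby("group")["fold_change"].mean()
                errs = [
                    grp[g] - f for g, f in true_folds.items()
                ] + [grp["N1"] - 1.0]
                store.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert np.mean(rmse_combo) < np.mean(rmse_single)


class TestBetweenRunCorrection:
    def test_doubled_plate_gets_sqrt2_factors(self):
        q = pd.Series(
            [1.0, 2.0, 4.0, 2.0, 4.0, 8.0],
            index=["c1", "c2", "x1", "c1", "c2", "x1"],
        )
        plates = pd.Series(
            ["p1", "p1", "p1", "p2", "p2", "p2"], index=q.index
        )
        runs, corrected = rs.between_run_correction(q, plates, ["c1", "c2"])
        factors = {r.plate: r.factor for r in runs}
        assert factors["p1"] == pytest.approx(2.0**-0.5, rel=1e-12)
        assert factors["p2"] == pytest.approx(2.0**0.5, rel=1e-12)
        # corrected values identical across plates
        np.testing.assert_allclose(
            corrected.to_numpy()[:3] , corrected.to_numpy()[3:], rtol=1e-12
        )

    def test_single_plate_is_noop(self):
        q = pd.Series([1.0, 2.0, 3.0], index=["c1", "x1", "x2"])
        plates = pd.Series(["p1"] * 3, index=q.index)
        runs, corrected = rs.between_run_correction(q, plates, ["c1"])
        assert runs[0].factor == pytest.approx(1.0)
        assert corrected.tolist() == pytest.approx(q.tolist())

    def test_identical_calibrators_give_unit_factors(self):
        q = pd.Series([2.0, 5.0, 2.0, 7.0], index=["c1", "x1", "c1", "x2"])
        plates = pd.Series(["p1", "p1", "p2", "p2"], index=q.index)
        runs, _ = rs.between_run_correction(q, plates, ["c1"])
        assert all(r.factor == pytest.approx(1.0) for r in runs)

    def test_factors_have_unit_geometric_mean(self):
        rng = np.random.default_rng(4)
        q = pd.Series(
            rng.lognormal(0, 1, 9),
            index=["c1", "c2", "x"] * 3,
        )
        plates = pd.Series(["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3, index=q.index)
        runs, _ = rs.between_run_correction(q, plates, ["c1", "c2"])
        log_gm = np.mean([np.log(r.factor) for r in runs])
        assert log_gm == pytest.approx(0.0, abs=1e-12)

    def test_plate_relabeling_invariance(self):
        q = pd.Series([1.0, 3.0, 2.0, 5.0], index=["c1", "x1", "c1", "x2"])
        plates_a = pd.Series(["p1", "p1", "p2", "p2"], index=q.index)
        plates_b = pd.Series(["east", "east", "west", "west"], index=q.index)
        _, corr_a = rs.between_run_correction(q, plates_a, ["c1"])
        _, corr_b = rs.between_run_correction(q, plates_b, ["c1"])
        assert corr_a.tolist() == pytest.approx(corr_b.tolist())

    def test_plate_missing_calibrator_rejected(self):
        q = pd.Series([1.0, 2.0], index=["c1", "x1"])
        plates = pd.Series(["p1", "p2"], index=q.index)
        with pytest.raises(CqValidationError, match="missing calibrator"):
            rs.between_run_correction(q, plates, ["c1"])
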