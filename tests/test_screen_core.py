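"""Unit and property tests for the plate data model and scoring engine."""

import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pharmacoscopy import screen_core as sc
from pharmacoscopy import synthetic_data as sd

from conftest import make_well
from oracles import rbf_brute_force

VALID_CSV = """patient_id,plate_id,well,drug,concentration_um,replicate,marker,n_viable_marker_pos,n_viable_marker_neg,n_total_cells
P1,pl1,A01,DMSO,0.0,1,CD34,40,60,110
P1,pl1,A02,drugA,1.0,1,CD34,20,80,105
P1,pl1,A03,drugB,1.0,1,CD34,35,65,102
"""


class TestReadWellTable:
    def test_valid_fixture(self, tmp_path):
        path = tmp_path / "wells.csv"
        path.write_text(VALID_CSV)
        records = sc.read_well_table(path)
        assert len(records) == 3
        assert sum(r.is_control for r in records) == 1
        assert records[0].n_viable_marker_pos["CD34"] == 40

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "wells.csv"
        path.write_text(VALID_CSV.replace("n_total_cells", "totals"))
        with pytest.raises(sc.SchemaError, match="n_total_cells"):
            sc.read_well_table(path)

    def test_negative_count_reports_row(self, tmp_path):
        path = tmp_path / "wells.csv"
        path.write_text(VALID_CSV.replace("20,80,105", "-1,80,105"))
        with pytest.raises(sc.ValidationError, match="row 3"):
            sc.read_well_table(path)

    def test_missing_controls(self, tmp_path):
        path = tmp_path / "wells.csv"
        path.write_text(VALID_CSV.replace("DMSO", "drugC"))
        with pytest.raises(sc.ControlMissingError, match="P1"):
            sc.read_well_table(path)

    def test_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "wells.csv"
        lines = VALID_CSV.strip().splitlines()
        path.write_text("\n".join(lines + [lines[-1]]))
        with pytest.raises(sc.ValidationError, match="duplicate"):
            sc.read_well_table(path)

    def test_round_trip(self, tmp_path, small_screen):
        _, wells, _ = small_screen
        path = tmp_path / "wells.csv"
        sc.write_well_table(wells, path)
        back = sc.read_well_table(path)
        assert len(back) == len(wells)

    @pytest.mark.parametrize("well", ["Q01", "A25", "A0x", ""])
    def test_well_coordinate_grid(self, well):
        with pytest.raises(sc.ValidationError):
            sc.parse_well_coordinate(well)

    def test_viable_exceeding_total_rejected(self):
        with pytest.raises(sc.ValidationError, match="exceeds"):
            make_well("drugA", 80, 40, total=100)


class TestComputeRbf:
    def test_worked_example(self):
        # control fractions average 0.40; drug well 20 pos of 80 viable
        wells = [
            make_well("DMSO", 35, 65, well="A01"),
            make_well("DMSO", 45, 55, well="A02"),
            make_well("drugA", 20, 60, well="B01"),
        ]
        res = sc.compute_rbf(wells, "drugA", "CD34")
        assert res.rbf_mean == pytest.approx(0.625)

    def test_proportional_killing_identity(self):
        # drug kills 50% of both populations: fractions unchanged, RBF 1
        wells = [
            make_well("DMSO", 400, 600, well="A01"),
            make_well("drugA", 200, 300, well="B01"),
        ]
        assert sc.compute_rbf(wells, "drugA", "CD34").rbf_mean == pytest.approx(1.0)

    def test_zero_viable_well_excluded_with_warning(self, caplog):
        wells = [
            make_well("DMSO", 40, 60, well="A01"),
            make_well("drugA", 0, 0, well="B01", total=50),
            make_well("drugA", 30, 70, well="B02", replicate=2),
        ]
        with caplog.at_level(logging.WARNING, logger="pharmacoscopy.screen_core"):
            res = sc.compute_rbf(wells, "drugA", "CD34")
        assert res.n_excluded == 1
        assert "excluded" in caplog.text
        assert res.rbf_mean == pytest.approx(0.75)

    def test_all_wells_excluded_gives_missing(self):
        wells = [
            make_well("DMSO", 40, 60, well="A01"),
            make_well("drugA", 0, 0, well="B01", total=50),
        ]
        assert np.isnan(sc.compute_rbf(wells, "drugA", "CD34").rbf_mean)

    def test_control_mean_is_one(self, rng):
        # normalization identity: mean over control-well RBFs == 1 exactly
        for _ in range(20):
            wells = [
                make_well("DMSO", int(p), int(n), well=f"A{i + 1:02d}", replicate=i + 1)
                for i, (p, n) in enumerate(
                    zip(rng.integers(10, 500, 6), rng.integers(10, 500, 6))
                )
            ]
            assert np.mean(sc.control_rbfs(wells, "CD34")) == pytest.approx(1.0)

    def test_scale_invariance(self, small_screen):
        _, wells, _ = small_screen
        scaled = [
            sc.WellRecord(
                w.patient_id, w.plate_id, w.well, w.drug, w.concentration_um,
                w.replicate,
                {m: 3 * v for m, v in w.n_viable_marker_pos.items()},
                {m: 3 * v for m, v in w.n_viable_marker_neg.items()},
                3 * w.n_total_cells,
            )
            for w in wells
        ]
        for drug in ("drug_001", "drug_003"):
            assert sc.compute_rbf(scaled, drug, "CD34").rbf_mean == pytest.approx(
                sc.compute_rbf(wells, drug, "CD34").rbf_mean
            )

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        # 1,000 random small fixtures, implementation vs raw-count oracle
        for _ in range(1000):
            n_ctrl = int(rng.integers(2, 5))
            n_drug = int(rng.integers(1, 5))
            wells = []
            for i in range(n_ctrl):
                wells.append(
                    make_well("DMSO", int(rng.integers(1, 300)), int(rng.integers(1, 300)),
                              well=f"A{i + 1:02d}", replicate=i + 1)
                )
            for i in range(n_drug):
                wells.append(
                    make_well("drugX", int(rng.integers(1, 300)), int(rng.integers(1, 300)),
                              well=f"B{i + 1:02d}", conc=float(rng.choice([1.0, 10.0])),
                              replicate=i + 1)
                )
            expected = rbf_brute_force(wells, "drugX", "CD34")
            assert sc.compute_rbf(wells, "drugX", "CD34").rbf_mean == pytest.approx(expected)


class TestDrugSignificance:
    def test_identical_samples_not_significant(self):
        p, sig = sc.drug_significance([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(1.0)
        assert not sig

    def test_strong_separation(self):
        p, sig = sc.drug_significance(
            [0.30, 0.31, 0.29, 0.30, 0.31], [1.0, 0.99, 1.01, 1.0, 0.98, 1.02]
        )
        assert p < 1e-4
        assert sig

    def test_too_few_replicates(self):
        p, sig = sc.drug_significance([0.5], [1.0, 1.0])
        assert np.isnan(p)
        assert not sig

    def test_simulated_screen_flags_strong_drug(self, small_screen):
        _, wells, _ = small_screen
        table = sc.build_drug_response_table(wells)
        strong = table[table["drug"] == "drug_003"].iloc[0]
        assert strong["significant"]
        assert strong["rank"] == 1
        # null drugs: few false flags at alpha=0.05
        assert table[table["drug"] != "drug_003"]["significant"].mean() < 0.3


class TestPcyScores:
    def test_forced_by_formula(self):
        scores = sc.pcy_scores({"a": 0.6, "b": 1.0, "c": 1.4})
        assert scores == pytest.approx({"a": 1.0, "b": 0.0, "c": -1.0})

    def test_degenerate_all_ones(self, caplog):
        with caplog.at_level(logging.WARNING, logger="pharmacoscopy.screen_core"):
            scores = sc.pcy_scores({"a": 1.0, "b": 1.0})
        assert scores == {"a": 0.0, "b": 0.0}
        assert "no drug beats control" in caplog.text

    def test_best_drug_always_scores_one(self, rng):
        for _ in range(100):
            rbfs = {f"d{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 1.5, 12))}
            if min(rbfs.values()) >= 1:
                continue
            scores = sc.pcy_scores(rbfs)
            best = min(rbfs, key=rbfs.get)
            assert scores[best] == pytest.approx(1.0)
            assert max(scores.values()) == pytest.approx(1.0)

    def test_invariant_under_neutral_drug(self, rng):
        rbfs = {f"d{i}": float(v) for i, v in enumerate(rng.uniform(0.3, 1.4, 8))}
        before = sc.pcy_scores(rbfs)
        rbfs["neutral"] = 1.0
        after = sc.pcy_scores(rbfs)
        for d in before:
            assert after[d] == pytest.approx(before[d])
        assert after["neutral"] == pytest.approx(0.0)


class TestRankDrugs:
    def test_ascending_rbf(self):
        tab = pd.DataFrame({"drug": ["B", "A"], "rbf_mean": [0.9, 0.5]})
        out = sc.rank_drugs(tab)
        assert list(out["drug"]) == ["A", "B"]
        assert list(out["rank"]) == [1, 2]

    def test_tie_break_lexicographic(self):
        tab = pd.DataFrame({"drug": ["B", "A"], "rbf_mean": [0.7, 0.7]})
        assert list(sc.rank_drugs(tab)["drug"]) == ["A", "B"]

    def test_true_best_drug_wins_rank_one(self):
        # Monte-Carlo: uniquely strongest drug attains rank 1 in >= 95% of runs
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            cfg = sd.ScreenSimConfig(
                n_drugs=6, n_concentrations=1, n_replicates=5,
                n_control_wells=8, cells_per_well=800,
                on_target_effect={"drug_004": 0.5, "drug_001": 0.1},
                concentration_range_um=(10.0, 10.0), seed=seed,
            )
            wells, _ = sd.simulate_screen(cfg)
            df = sc.wells_to_frame(wells)
            ctrl = df[df.drug == "DMSO"]
            ctrl_frac = (ctrl.n_viable_marker_pos / (ctrl.n_viable_marker_pos + ctrl.n_viable_marker_neg)).mean()
            drugs = df[df.drug != "DMSO"].copy()
            drugs["rbf"] = (
                drugs.n_viable_marker_pos / (drugs.n_viable_marker_pos + drugs.n_viable_marker_neg)
            ) / ctrl_frac
            means = drugs.groupby("drug")["rbf"].mean().reset_index()
            means = means.rename(columns={"rbf": "rbf_mean"})
            if sc.rank_drugs(means).iloc[0]["drug"] == "drug_004":
                hits += 1
        assert hits / n_runs >= 0.95


class TestIntegrateIpcy:
    def test_single_component(self):
        comp = pd.DataFrame({"CD34": [0.8]}, index=["bortezomib"])
        res = sc.integrate_ipcy(comp, ["bortezomib"], patient_id="P1")
        assert res.i_pcy == pytest.approx(0.8)

    def test_two_by_two_sum(self):
        comp = pd.DataFrame(
            {"CD34": [1.0, 0.2], "CD117": [0.5, -0.2]}, index=["d1", "d2"]
        )
        assert sc.integrate_ipcy(comp, ["d1", "d2"]).i_pcy == pytest.approx(1.5)

    def test_missing_combination_listed(self):
        comp = pd.DataFrame({"CD34": [0.8]}, index=["d1"])
        with pytest.raises(KeyError, match="d2"):
            sc.integrate_ipcy(comp, ["d1", "d2"])

    def test_all_negative_scores_give_negative_ipcy(self, rng):
        # ex-vivo resistant regimens land in the negative range
        for _ in range(20):
            comp = pd.DataFrame(
                rng.uniform(-1.5, -0.05, size=(3, 2)),
                index=["d1", "d2", "d3"], columns=["m1", "m2"],
            )
            assert sc.integrate_ipcy(comp, ["d1", "d2", "d3"]).i_pcy < 0

    def test_additive_over_disjoint_regimens(self, rng):
        comp = pd.DataFrame(
            rng.normal(0, 0.5, size=(6, 2)),
            index=[f"d{i}" for i in range(6)], columns=["m1", "m2"],
        )
        total = sc.integrate_ipcy(comp, [f"d{i}" for i in range(6)]).i_pcy
        part1 = sc.integrate_ipcy(comp, ["d0", "d1", "d2"]).i_pcy
        part2 = sc.integrate_ipcy(comp, ["d3", "d4", "d5"]).i_pcy
        assert total == pytest.approx(part1 + part2)


class TestChemoresistanceFraction:
    def test_worked_example(self):
        scores = dict(zip("abcd", [-0.5, 0.0, 0.5, 1.0]))
        assert sc.chemoresistance_fraction(scores) == pytest.approx(0.25)

    def test_no_resistance(self):
        assert sc.chemoresistance_fraction({"a": 0.0, "b": 0.4}) == 0.0

    def test_fraction_tracks_prior_lines(self, rng):
        # resistance probability rising with prior treatment lines gives r > 0
        lines = rng.integers(0, 8, 60)
        fracs = []
        for ln in lines:
            p_resist = 0.05 + 0.03 * ln
            scores = {
                f"d{i}": float(-0.5 if rng.random() < p_resist else rng.uniform(-0.05, 1))
                for i in range(40)
            }
            fracs.append(sc.chemoresistance_fraction(scores))
        r = np.corrcoef(lines, fracs)[0, 1]
        assert r > 0.2


class TestClusterProfiles:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 10)
        tab = pd.DataFrame({"a": base, "b": base, "c": rng.normal(0, 1, 10)})
        res = sc.cluster_profiles(tab, axis="columns")
        first_merge = res.linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_drug_trivial_tree(self):
        tab = pd.DataFrame({"only": [0.1, 0.2]})
        res = sc.cluster_profiles(tab, axis="columns")
        assert res.linkage is None
        assert res.leaf_order == ["only"]

    def test_drug_classes_co_cluster(self):
        # three simulated drug classes with shared within-class effect vectors
        from scipy.cluster.hierarchy import fcluster

        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_patients, per_class = 30, 4
            truth, cols = [], {}
            for cls in range(3):
                shared = rng.normal(0, 1.0, n_patients)
                for j in range(per_class):
                    cols[f"c{cls}_d{j}"] = shared + rng.normal(0, 0.35, n_patients)
                    truth.append(cls)
            res = sc.cluster_profiles(pd.DataFrame(cols), axis="columns")
            labels = fcluster(res.linkage, t=3, criterion="maxclust")
            aris.append(adjusted_rand_score(truth, labels))
        assert np.mean(aris) >= 0.9

    def test_missing_values_masked(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(rng.normal(0, 1, (12, 4)), columns=list("abcd"))
        tab.loc[0, "a"] = np.nan
        res = sc.cluster_profiles(tab, axis="columns")
        assert np.isfinite(res.linkage[:, 2]).all()
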