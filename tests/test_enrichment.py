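import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from minidriver import (
    Partition,
    PatientMutationProfile,
    bh_adjust,
    cohort_enrichment_summary,
    cohort_overrepresentation,
    e_status,
    geneset_enrichment,
    module_overrepresentation,
    read_gmt,
    union_enrichment_fraction,
)

from _oracles import hypergeom_upper_tail


def partition_of(sizes: dict) -> Partition:
    assignment = {}
    i = 0
    for module, size in sizes.items():
        for _ in range(size):
            assignment[f"G{i}"] = module
            i += 1
    return Partition(assignment)


class TestModuleOverrepresentation:
    def test_worked_hypergeometric_example(self):
        # N=10, K=4, n=3, k=3 -> C(4,3)/C(10,3) = 1/30
        partition = partition_of({1: 4, 2: 6})
        profile = PatientMutationProfile(
            "P1", frozenset({"G0", "G1", "G2"})  # all three in module 1
        )
        results = {
            r.module: r
            for r in module_overrepresentation(profile, partition,
                                               min_module_size=1)
        }
        assert results[1].k == 3
        assert results[1].p_value == pytest.approx(1 / 30)

    def test_zero_overlap_gives_p_one(self):
        partition = partition_of({1: 4, 2: 6})
        profile = PatientMutationProfile("P1", frozenset({"G5", "G6"}))
        results = {
            r.module: r
            for r in module_overrepresentation(profile, partition,
                                               min_module_size=1)
        }
        assert results[1].p_value == pytest.approx(1.0)

    def test_fully_mutated_network_degenerate_tail(self):
        partition = partition_of({1: 4, 2: 6})
        profile = PatientMutationProfile(
            "P1", frozenset(partition.assignment)
        )
        for r in module_overrepresentation(profile, partition,
                                           min_module_size=1):
            assert r.k == r.K
            assert r.p_value == pytest.approx(1.0)

    def test_untestable_patient_flagged(self):
        partition = partition_of({1: 5, 2: 5})
        profile = PatientMutationProfile("P1", frozenset({"ZZZ"}))
        results = module_overrepresentation(profile, partition)
        assert all(not r.testable and r.p_value == 1.0 for r in results)

    def test_genes_outside_network_dropped_before_testing(self):
        partition = partition_of({1: 4, 2: 6})
        profile = PatientMutationProfile(
            "P1", frozenset({"G0", "G1", "G2", "NOT_IN_NET"})
        )
        r = module_overrepresentation(profile, partition, min_module_size=1)
        assert all(res.n == 3 for res in r)

    def test_small_modules_skipped_by_default(self):
        partition = partition_of({1: 3, 2: 10})
        profile = PatientMutationProfile("P1", frozenset({"G0"}))
        tested = {r.module for r in module_overrepresentation(profile,
                                                              partition)}
        assert tested == {2}

    def test_matches_exhaustive_tail_on_small_tables(self):
        for N in range(4, 16):
            for K in range(1, N):
                partition = Partition(
                    {f"G{i}": (1 if i < K else 2) for i in range(N)}
                )
                for n in range(1, N + 1):
                    profile = PatientMutationProfile(
                        "P", frozenset(f"G{i}" for i in range(n))
                    )
                    res = {
                        r.module: r
                        for r in module_overrepresentation(
                            profile, partition, min_module_size=1
                        )
                    }
                    k = res[1].k
                    assert res[1].p_value == pytest.approx(
                        hypergeom_upper_tail(k, N, K, n)
                    )


class TestBHAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_two_value_example(self):
        np.testing.assert_allclose(bh_adjust([0.005, 0.5]), [0.01, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(seed=st.integers(0, 300), m=st.integers(1, 40))
    def test_matches_reference_step_up(self, seed, m):
        p = np.random.default_rng(seed).random(m)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref)

    @given(seed=st.integers(0, 300))
    def test_monotone_and_dominating(self, seed):
        p = np.random.default_rng(seed).random(20)
        q = bh_adjust(p)
        assert np.all(q >= p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestEStatus:
    def frame(self):
        return pd.DataFrame({
            "patient": ["P1", "P2", "P3"],
            "module": [8, 8, 8],
            "q_value": [0.04, 0.05, 1.0],
            "enriched": [True, False, False],
            "testable": [True, True, False],
        })

    def test_strict_threshold(self):
        status = e_status(self.frame(), 8)
        assert bool(status["P1"]) is True
        assert bool(status["P2"]) is False  # q exactly at alpha

    def test_untestable_patient_is_false(self):
        assert bool(e_status(self.frame(), 8)["P3"]) is False

    def test_absent_module_rejected(self):
        with pytest.raises(ValueError):
            e_status(self.frame(), 99)


class TestCohortSummary:
    def cohort(self):
        partition = partition_of({1: 6, 2: 6})
        profiles = {
            "P1": PatientMutationProfile(
                "P1", frozenset({"G0", "G1", "G2", "G3"})
            ),
            "P2": PatientMutationProfile(
                "P2", frozenset({"G0", "G1", "G2", "G4"})
            ),
            "P3": PatientMutationProfile("P3", frozenset({"G6", "G11"})),
            "P4": PatientMutationProfile("P4", frozenset({"G7"})),
        }
        return cohort_overrepresentation(profiles, partition, alpha=0.2)

    def test_fraction_of_patients_enriched(self):
        results = self.cohort()
        summary = cohort_enrichment_summary(results).set_index("module")
        manual = (
            results[results["module"] == 1]["enriched"].sum() / 4
        )
        assert summary.loc[1, "fraction_enriched"] == pytest.approx(manual)

    def test_module_enriched_in_none_scores_zero(self):
        summary = cohort_enrichment_summary(self.cohort()).set_index("module")
        assert summary.loc[2, "fraction_enriched"] == pytest.approx(0.0)

    def test_union_fraction_at_least_max_single(self):
        results = self.cohort()
        summary = cohort_enrichment_summary(results)
        union = union_enrichment_fraction(results, [1, 2])
        assert union >= summary["fraction_enriched"].max() - 1e-12

    def test_global_family_adjusts_across_cohort(self):
        partition = partition_of({1: 6, 2: 6})
        profiles = {
            "P1": PatientMutationProfile("P1", frozenset({"G0", "G1"})),
            "P2": PatientMutationProfile("P2", frozenset({"G6", "G7"})),
        }
        res = cohort_overrepresentation(profiles, partition, family="global")
        testable = res[res["testable"]]
        _, q_ref, _, _ = multipletests(testable["p_value"], method="fdr_bh")
        np.testing.assert_allclose(testable["q_value"], q_ref)


class TestGeneSets:
    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "SET_A\tdesc\tG1\tG2\tG2\tG3\n"
            "SET_B\tdesc\tG4\tG5\n"
        )
        collection = read_gmt(path)
        assert set(collection) == {"SET_A", "SET_B"}
        assert collection["SET_A"] == {"G1", "G2", "G3"}  # de-duplicated

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SET_A\tdesc\n")
        with pytest.raises(ValueError, match="3 fields"):
            read_gmt(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        with pytest.raises(ValueError):
            read_gmt(path)

    def test_worked_enrichment_example(self):
        # background 20, set 5, module 6, overlap 4:
        # p = (C(5,4)C(15,2) + C(5,5)C(15,1)) / C(20,6) = 540/38760
        background = {f"G{i}" for i in range(20)}
        module = {"G0", "G1", "G2", "G3", "G10", "G11"}
        collection = {"SET": {"G0", "G1", "G2", "G3", "G4"}}
        df = geneset_enrichment(module, background, collection)
        assert df.iloc[0]["overlap"] == 4
        assert df.iloc[0]["p_value"] == pytest.approx(540 / 38760)

    def test_zero_overlap_gives_p_one(self):
        background = {f"G{i}" for i in range(10)}
        df = geneset_enrichment(
            {"G0"}, background, {"SET": {"G5", "G6"}}
        )
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_disjoint_geneset_skipped(self, caplog):
        background = {f"G{i}" for i in range(10)}
        with caplog.at_level("INFO"):
            df = geneset_enrichment(
                {"G0"}, background, {"SET": {"X1", "X2"}}
            )
        assert df.empty

    def test_module_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            geneset_enrichment({"Z"}, {"G0"}, {"SET": {"G0"}})
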