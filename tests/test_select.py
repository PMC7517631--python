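import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irsom.select import (
    CLUSTER_LABELS,
    apply_criterion,
    assemble_clusters,
    cluster_trajectory_report,
    summarize_modules,
)


def profiles_of(linear_tpm):
    """Build a profile frame from linear-scale (p, i, r) TPM triples."""
    rows = [
        (f"T{k+1}", *np.log2(np.asarray(triple, dtype=float)))
        for k, triple in enumerate(linear_tpm)
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "p_med", "i_med", "r_med"])


def summary_row(p, i, r, module_id=1):
    return pd.Series(
        {"module_id": module_id, "n_transcripts": 10, "p_bar": p, "i_bar": i, "r_bar": r}
    )


class TestSummarizeModules:
    def test_linear_scale_arithmetic_means(self):
        prof = profiles_of([(10, 20, 15), (30, 60, 45)])
        summ = summarize_modules(
            {"T1": 1, "T2": 1}, prof, n_modules=2, scale="linear"
        )
        assert summ.loc[0, ["p_bar", "i_bar", "r_bar"]].tolist() == pytest.approx(
            [20.0, 40.0, 30.0]
        )

    def test_log2_scale_is_geometric_mean(self):
        prof = profiles_of([(10, 10, 10), (40, 40, 40)])
        summ = summarize_modules({"T1": 1, "T2": 1}, prof, n_modules=1, scale="log2")
        assert summ.loc[0, "p_bar"] == pytest.approx(20.0)  # sqrt(10*40)

    def test_single_transcript_module_passthrough(self):
        prof = profiles_of([(10, 40, 25)])
        summ = summarize_modules({"T1": 3}, prof, n_modules=4, scale="linear")
        row = summ.set_index("module_id").loc[3]
        assert row[["p_bar", "i_bar", "r_bar"]].tolist() == pytest.approx([10, 40, 25])

    def test_empty_module_has_nan_means(self):
        prof = profiles_of([(10, 40, 25)])
        summ = summarize_modules({"T1": 1}, prof, n_modules=2)
        assert summ.loc[1, "n_transcripts"] == 0
        assert np.isnan(summ.loc[1, "p_bar"])


class TestApplyCriterion:
    def test_worked_examples(self):
        # log2(40/10)=2 and log2(25/10)=1.32: ischemia-up fires
        assert apply_criterion(summary_row(10, 40, 25), "ischemia", "up")
        # flat profile fires nothing
        flat = summary_row(10, 10, 10)
        for effect in ("ischemia", "reperfusion"):
            for direction in ("up", "down"):
                assert not apply_criterion(flat, effect, direction)
        # log2(10/40) = -2 twice: ischemia-down fires
        assert apply_criterion(summary_row(40, 10, 10), "ischemia", "down")

    def test_reperfusion_rules(self):
        assert apply_criterion(summary_row(10, 12, 48), "reperfusion", "up")
        assert apply_criterion(summary_row(40, 40, 10), "reperfusion", "down")
        assert not apply_criterion(summary_row(10, 12, 48), "ischemia", "up")

    def test_literal_printed_down_rule_is_near_vacuous(self):
        # the as-printed "<= +1" accepts even a mildly rising module
        rising = summary_row(10, 15, 15)
        assert not apply_criterion(rising, "ischemia", "down")
        assert apply_criterion(rising, "ischemia", "down", literal_table1=True)

    def test_nonpositive_mean_excludes_module(self, caplog):
        assert not apply_criterion(summary_row(0.0, 10, 10), "ischemia", "up")
        assert any("non-positive" in r.message for r in caplog.records)

    @given(
        st.tuples(
            st.floats(0.1, 1e4), st.floats(0.1, 1e4), st.floats(0.1, 1e4)
        ),
        st.floats(0.1, 4.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_up_down_mutually_exclusive(self, bars, threshold):
        row = summary_row(*bars)
        for effect in ("ischemia", "reperfusion"):
            up = apply_criterion(row, effect, "up", threshold)
            down = apply_criterion(row, effect, "down", threshold)
            assert not (up and down)


class TestAssembleClusters:
    def test_no_passing_module_gives_empty_clusters(self):
        prof = profiles_of([(10, 10, 10), (20, 20, 20)])
        assignment = {"T1": 1, "T2": 2}
        summ = summarize_modules(assignment, prof, n_modules=2)
        clusters = assemble_clusters(summ, assignment)
        assert set(clusters) == set(CLUSTER_LABELS)
        assert all(c.n_genes == 0 for c in clusters.values())

    def test_union_of_passing_modules(self):
        prof = profiles_of(
            [(10, 40, 40), (10, 44, 40), (10, 40, 44), (10, 10, 10)]
        )
        assignment = {"T1": 42, "T2": 42, "T3": 44, "T4": 7}
        summ = summarize_modules(assignment, prof, n_modules=49)
        clusters = assemble_clusters(summ, assignment)
        c1 = clusters["C1_ischemia_up"]
        assert c1.module_ids == {42, 44}
        assert c1.transcript_ids == {"T1", "T2", "T3"}
        assert c1.n_genes == 3

    def test_same_effect_up_down_disjoint(self):
        rng = np.random.default_rng(0)
        prof = profiles_of(2.0 ** rng.normal(4, 2, size=(60, 3)))
        assignment = {f"T{k+1}": (k % 12) + 1 for k in range(60)}
        summ = summarize_modules(assignment, prof, n_modules=12)
        clusters = assemble_clusters(summ, assignment)
        assert not clusters["C1_ischemia_up"].module_ids & clusters[
            "C2_ischemia_down"
        ].module_ids
        assert not clusters["C3_reperfusion_up"].module_ids & clusters[
            "C4_reperfusion_down"
        ].module_ids

    def test_selection_invariant_to_module_renumbering(self):
        prof = profiles_of([(10, 40, 40), (10, 10, 10), (40, 10, 10)])
        a = {"T1": 1, "T2": 2, "T3": 3}
        b = {"T1": 9, "T2": 5, "T3": 2}
        ca = assemble_clusters(summarize_modules(a, prof, 10), a)
        cb = assemble_clusters(summarize_modules(b, prof, 10), b)
        for label in CLUSTER_LABELS:
            assert ca[label].transcript_ids == cb[label].transcript_ids


class TestTrajectoryReport:
    def test_relative_to_baseline(self):
        prof = profiles_of([(10, 40, 20)])
        assignment = {"T1": 1}
        summ = summarize_modules(assignment, prof, 1)
        clusters = assemble_clusters(summ, assignment)
        report = cluster_trajectory_report(clusters, prof)
        row = report.set_index("cluster").loc["C1_ischemia_up"]
        assert row.tolist() == pytest.approx([1.0, 4.0, 2.0])

    def test_flat_members_give_unit_trajectory_and_empty_omitted(self):
        prof = profiles_of([(10, 40, 40), (30, 120, 120)])
        assignment = {"T1": 1, "T2": 1}
        clusters = assemble_clusters(summarize_modules(assignment, prof, 1), assignment)
        report = cluster_trajectory_report(clusters, prof)
        assert list(report["cluster"]) == ["C1_ischemia_up"]
        row = report.iloc[0]
        assert row["ischemia"] == pytest.approx(4.0)
        assert row["ischemia"] >= 2.0  # guaranteed by the selection rule

    def test_c1_ischemia_value_at_least_twofold(self, small_sim):
        """The selection rule forces the C1 mean trajectory above 2 in ischemia."""
        import math
        from irsom.pipeline import PipelineConfig, stage_normalize, stage_som
        from irsom.select import summarize_modules as sm

        matrix, design, _ = small_sim
        _, retained = stage_normalize(matrix, design, math.log2(3))
        model, assignment = stage_som(retained, PipelineConfig(), seed=1)
        clusters = assemble_clusters(sm(assignment, retained, 49), assignment)
        report = cluster_trajectory_report(clusters, retained).set_index("cluster")
        if "C1_ischemia_up" in report.index:
            assert report.loc["C1_ischemia_up", "ischemia"] >= 2.0
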