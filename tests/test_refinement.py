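"""Differential-expression refinement: Welch test, cutoffs, recurrence,
specificity, consistency scoring and candidate-table parsing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dili_netminer import datasets
from dili_netminer.refinement import (
    ExperimentDesign,
    ExpressionStudy,
    RefinementConfig,
    consistency_score,
    differential_expression,
    export_curation_views,
    flag_deregulated,
    group_specific_genes,
    log2_fold_change,
    parse_candidate_table,
    positive_specificity_filter,
    refine_disease_genes,
    welch_t_test,
)
from dili_netminer.simulate import gen_expression_studies


def de_row(gene, chem, fc, p=0.01, time="3 h", dose="high", cfg=None):
    dereg, direction = flag_deregulated(fc, p, cfg or RefinementConfig())
    return {
        "gene": gene, "chemical_id": chem, "time": time, "dose": dose,
        "log2fc": fc, "p_value": p, "deregulated": dereg, "direction": direction,
    }


class TestWelch:
    def test_identical_samples_give_t_zero_p_one(self):
        t, _df, p = welch_t_test([1, 1, 2], [1, 1, 2])
        assert t == 0.0 and p == 1.0

    def test_hand_traced_unequal_variance_example(self):
        # a=[2,3,4], b=[0,1]: t = 2.5/sqrt(1/3 + 1/4), Welch–Satterthwaite df
        t, df, p = welch_t_test([2, 3, 4], [0, 1])
        assert t == pytest.approx(3.2733, abs=1e-4)
        assert df == pytest.approx(2.8823, abs=1e-4)
        assert 0.0 <= p <= 1.0

    def test_requires_two_replicates_per_group(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_degenerate_constant_groups(self):
        _t, _df, p_equal = welch_t_test([2, 2, 2], [2, 2])
        assert p_equal == 1.0
        _t, _df, p_diff = welch_t_test([2, 2, 2], [3, 3])
        assert p_diff == 0.0  # infinite t by convention

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            na, nb = rng.integers(2, 8, size=2)
            a = rng.normal(0, rng.uniform(0.2, 2.0), na)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.2, 2.0), nb)
            t, _df, p = welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert abs(p - ref.pvalue) < 1e-10


class TestFoldChangeAndFlags:
    def test_log2_fold_change_is_difference_of_means(self):
        assert log2_fold_change([3, 3], [1, 1]) == 2.0
        assert log2_fold_change([1.5, 2.5], [1.5, 2.5]) == 0.0
        assert log2_fold_change([2.5, 3.5], [1.0, 2.0]) == 1.5

    def test_empty_vector_is_an_error(self):
        with pytest.raises(ValueError):
            log2_fold_change([], [1.0])

    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.5, 0.01, (True, "up")),
            (-1.5, 0.01, (True, "down")),
            (0.9, 0.001, (False, "none")),  # below fold-change cutoff
            (1.0, 0.0, (False, "none")),    # strict boundary on |log2FC|
            (2.0, 0.05, (False, "none")),   # strict boundary on p
        ],
    )
    def test_strict_deregulation_cutoffs(self, fc, p, expected):
        assert flag_deregulated(fc, p) == expected


class TestGroupRules:
    def test_recurrence_threshold_inclusive_at_three_chemicals(self):
        # deregulation across exactly three chemicals satisfies the cutoff
        frame = pd.DataFrame(
            [de_row("G1", c, 2.0) for c in ("A", "B", "C")]
            + [de_row("G2", c, 2.0) for c in ("A", "B")]
            + [de_row("G3", c, 0.2) for c in ("A", "B", "C")]
        )
        cells = group_specific_genes(frame, {"A", "B", "C"})
        assert cells == {("3 h", "high"): {"G1"}}

    def test_counts_are_per_cell(self):
        frame = pd.DataFrame(
            [de_row("G1", "A", 2.0, time="3 h"), de_row("G1", "B", 2.0, time="3 h"),
             de_row("G1", "C", 2.0, time="6 h")]
        )
        assert group_specific_genes(frame, {"A", "B", "C"}) == {}

    def test_specificity_keeps_positive_only_genes(self):
        pos = {("3 h", "high"): {"G1", "G2"}}
        neg = {("3 h", "high"): {"G2"}}
        assert positive_specificity_filter(pos, neg) == {("3 h", "high"): {"G1"}}

    def test_specificity_with_missing_negative_cell(self):
        pos = {("6 h", "low"): {"G1"}}
        assert positive_specificity_filter(pos, {}) == {("6 h", "low"): {"G1"}}

    def test_raising_fc_threshold_never_adds_genes(self):
        rng = np.random.default_rng(5)
        rows = [
            de_row(f"G{g}", f"C{c}", float(rng.normal(0, 1.5)), float(rng.uniform(0, 0.2)))
            for g in range(10) for c in range(5)
        ]
        chems = {f"C{c}" for c in range(5)}
        for loose, tight in [
            (RefinementConfig(), RefinementConfig(fc_threshold=1.5)),
            (RefinementConfig(), RefinementConfig(p_threshold=0.01)),
        ]:
            def cells_at(cfg):
                frame = pd.DataFrame(
                    [de_row(r["gene"], r["chemical_id"], r["log2fc"], r["p_value"], cfg=cfg)
                     for r in rows]
                )
                return group_specific_genes(frame, chems, cfg)
            loose_cells, tight_cells = cells_at(loose), cells_at(tight)
            for cell, genes in tight_cells.items():
                assert genes <= loose_cells.get(cell, set())


class TestConsistencyScore:
    def test_uniform_positive_response_with_flat_negatives_scores_one(self):
        pos = pd.DataFrame([de_row("G1", c, 1.8) for c in ("P1", "P2", "P3")])
        neg = pd.DataFrame([de_row("G1", c, 0.1) for c in ("N1", "N2")])
        score, direction = consistency_score("G1", pos, neg)
        assert score == 1.0 and direction == "up"

    def test_split_positive_directions_halve_the_sign_fraction(self):
        pos = pd.DataFrame(
            [de_row("G1", "P1", 1.8), de_row("G1", "P2", -1.8)]
        )
        neg = pd.DataFrame([de_row("G1", "N1", 0.0)])
        score, _ = consistency_score("G1", pos, neg)
        assert score == pytest.approx(0.5)

    def test_shared_deregulation_with_negatives_is_rejected(self):
        # both groups up ≥ 1.2: chemical-specific, not disease-specific
        cfg = RefinementConfig()
        pos = pd.DataFrame([de_row("G1", c, 1.5) for c in ("P1", "P2", "P3")])
        neg = pd.DataFrame([de_row("G1", c, 1.2) for c in ("N1", "N2")])
        score, _ = consistency_score("G1", pos, neg, cfg)
        assert score == 0.0  # f_neg = 0
        assert score < cfg.pos_fraction_min

    def test_opposing_negative_response_still_counts_as_divergent(self):
        pos = pd.DataFrame([de_row("G1", c, 1.5) for c in ("P1", "P2", "P3")])
        neg = pd.DataFrame([de_row("G1", "N1", -1.4)])
        score, _ = consistency_score("G1", pos, neg)
        assert score == 1.0

    def test_gene_absent_from_positives_is_an_error(self):
        neg = pd.DataFrame([de_row("G1", "N1", 0.0)])
        with pytest.raises(ValueError, match="absent"):
            consistency_score("G9", neg.iloc[0:0], neg)


class TestRefineDiseaseGenes:
    def test_planted_genes_recovered_exactly(self, fast_sim_config):
        studies, truth = gen_expression_studies(fast_sim_config)
        pos = [s for s in studies if s.chemical_id in truth.positives]
        neg = [s for s in studies if s.chemical_id in truth.negatives]
        selection = refine_disease_genes(
            pos, neg, candidate_genes=[g for g in studies[0].genes], disease_id="d"
        )
        assert set(selection.refined_gene_names) == set(truth.planted_genes)
        directions = {g: d for g, d, _ in selection.refined_genes}
        assert directions == truth.planted_genes

    def test_candidates_disjoint_from_deregulation_yield_empty_selection(self, fast_sim_config):
        studies, truth = gen_expression_studies(fast_sim_config)
        pos = [s for s in studies if s.chemical_id in truth.positives]
        neg = [s for s in studies if s.chemical_id in truth.negatives]
        unplanted = [g for g in studies[0].genes if g not in truth.planted_genes][:10]
        selection = refine_disease_genes(pos, neg, unplanted, disease_id="d")
        assert selection.refined_genes == []

    def test_requires_enough_positive_studies(self, fast_sim_config):
        studies, truth = gen_expression_studies(fast_sim_config)
        pos = [s for s in studies if s.chemical_id in truth.positives]
        with pytest.raises(ValueError):
            refine_disease_genes(pos[:2], [], ["G0001"], disease_id="d")
        with pytest.raises(ValueError):
            refine_disease_genes([], [], ["G0001"], disease_id="d")


class TestCandidateTables:
    # unique gene counts of the packaged transcriptions
    @pytest.mark.parametrize(
        "disease,expected",
        [("cholestasis", 32), ("steatosis", 20), ("hepatitis", 25), ("cirrhosis", 36)],
    )
    def test_fixture_tables_parse_to_transcribed_unique_counts(self, disease, expected):
        per_time, unique = parse_candidate_table(datasets.candidate_table(disease))
        assert unique == expected
        assert set().union(*per_time.values())  # non-empty union

    def test_hepatitis_table_has_seven_time_points(self):
        per_time, _ = parse_candidate_table(datasets.candidate_table("hepatitis"))
        assert len(per_time) == 7 and "3 h" not in per_time

    def test_parse_invariant_to_row_order(self):
        frame = datasets.candidate_table("steatosis")
        shuffled = frame.sample(frac=1.0, random_state=1)
        assert parse_candidate_table(frame) == parse_candidate_table(shuffled)

    def test_malformed_symbol_is_named_with_row(self):
        frame = pd.DataFrame({"time_point": ["3 h"], "gene": ["BAD-GENE!"]})
        with pytest.raises(ValueError, match="row 1"):
            parse_candidate_table(frame)

    def test_empty_table_counts_zero(self):
        assert parse_candidate_table(pd.DataFrame(columns=["time_point", "gene"])) == ({}, 0)


class TestCurationViews:
    def _tiny_study(self, chem, rng):
        design = ExperimentDesign(
            time_points=("3 h", "6 h", "9 h"), dose_levels=("high",), replicates_per_cell=2
        )
        genes = ("G1",)
        shape = (3, 1, 2)
        return ExpressionStudy(
            chem, design, genes,
            treated=8 + rng.normal(0, 0.3, shape),
            control=8 + rng.normal(0, 0.3, shape),
        )

    def test_heatmap_cardinality_and_group_labels(self):
        rng = np.random.default_rng(2)
        from dili_netminer.refinement import GeneSelection

        selection = GeneSelection("d", {("3 h", "high"): {"G1"}}, [("G1", "up", 1.0)])
        pos = [self._tiny_study("P1", rng)]
        neg = [self._tiny_study("N1", rng)]
        heatmap, timeseries = export_curation_views(selection, pos, neg)
        assert len(heatmap) == 6  # 1 gene × 2 chemicals × 3 times × 1 dose
        assert set(heatmap["group"]) == {"PC", "NC"}
        # verbatim pass-through of the DE fold changes
        de = differential_expression(pos[0], genes=["G1"])
        merged = heatmap[heatmap["chemical_id"] == "P1"].merge(
            de, on=["gene", "chemical_id", "time", "dose"], suffixes=("_view", "_de")
        )
        assert np.allclose(merged["log2fc_view"], merged["log2fc_de"])
        assert set(timeseries.columns) == {"gene", "group", "time", "mean_log2fc", "sd_log2fc"}
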