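"""FRR arithmetic, selection-call aggregation, external-table adapters."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stasis_scan.redundancy import (
    TableSchemaError,
    annotation_coverage,
    classify_gene_selection,
    compare_frr,
    functional_redundancy_ratio,
    parse_cfml_table,
    parse_fel_table,
    recombination_summary,
    selection_summary,
)


class TestFRR:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["K1", "K2", "K3"], 0.0),
            (["K1", "K1", "K2", "K2"], 0.5),
            (["K1", "K1", "K1", "K1"], 0.75),
        ],
    )
    def test_closed_form(self, labels, expected):
        assert functional_redundancy_ratio(labels) == pytest.approx(expected)

    def test_unannotated_rows_excluded_first(self):
        assert functional_redundancy_ratio(["K1", "K1", None, float("nan"), ""]) == 0.5

    def test_no_annotations_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(functional_redundancy_ratio([None, ""]))

    def test_annotation_coverage(self):
        assert annotation_coverage(["K1", None, "K2", ""]) == 0.5

    @given(st.lists(st.sampled_from(["K1", "K2", "K3", "K4"]), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_zero_iff_unique(self, labels):
        frr = functional_redundancy_ratio(labels)
        assert 0.0 <= frr < 1.0
        assert (frr == 0.0) == (len(set(labels)) == len(labels))

    @given(st.lists(st.sampled_from(["K1", "K2", "K3"]), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_under_duplication(self, labels):
        """Duplicating any existing annotation can only raise the FRR."""
        before = functional_redundancy_ratio(labels)
        after = functional_redundancy_ratio(labels + [labels[0]])
        assert after >= before - 1e-12

    def test_planted_duplication_recovered_from_truth(self):
        from stasis_scan.config import SimulationConfig
        from stasis_scan.simulate import generate_ancestor

        for d in (0.0, 0.2, 0.5):
            errs = []
            for seed in range(20):
                anc = generate_ancestor(
                    SimulationConfig(
                        seed=seed, n_species=1, members_per_species=2,
                        n_genes=40, duplication_rate=d,
                        contamination_range=(0, 0),
                    )
                )
                for comp in ("SP", "CP"):
                    kos = [g.ko for g in anc.genes if g.compartment == comp]
                    if len(kos) >= 5:
                        errs.append(functional_redundancy_ratio(kos) - d)
            assert max(abs(e) for e in errs) <= 0.05


class TestCompareFRR:
    def _table(self, rng, large_d, small_d, n=12):
        rows = []
        for i in range(n):
            rows.append({"mag_id": f"L{i}", "size_class": "large", "compartment": "SP",
                         "frr": np.clip(rng.normal(large_d, 0.03), 0, 1)})
            rows.append({"mag_id": f"S{i}", "size_class": "small", "compartment": "SP",
                         "frr": np.clip(rng.normal(small_d, 0.03), 0, 1)})
        return pd.DataFrame(rows)

    def test_planted_sp_redundancy_gap_detected(self, rng):
        report = compare_frr(self._table(rng, 0.4, 0.05))
        row = report[(report["compartment"] == "SP") & (report["test"] == "wilcoxon_rank_sum")]
        assert row["p_value"].iloc[0] < 0.01

    def test_identical_groups_not_significant(self, rng):
        vals = list(rng.uniform(0.1, 0.3, 10))
        table = pd.DataFrame(
            [{"mag_id": f"L{i}", "size_class": "large", "compartment": "SP", "frr": v}
             for i, v in enumerate(vals)]
            + [{"mag_id": f"S{i}", "size_class": "small", "compartment": "SP", "frr": v}
               for i, v in enumerate(vals)]
        )
        report = compare_frr(table)
        assert report["p_value"].iloc[0] > 0.5


class TestGeneSelection:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "direction", "p_value"])

    def test_no_significant_sites_is_none(self):
        sites = self._sites([("g", "negative", 0.5), ("g", "positive", 0.9)])
        assert classify_gene_selection(sites) == "none"

    def test_positive_precedence_over_negative(self):
        sites = self._sites(
            [("g", "positive", 0.01)] + [("g", "negative", 0.001)] * 3
        )
        assert classify_gene_selection(sites) == "positive"

    def test_invariant_flag_wins(self):
        assert classify_gene_selection(self._sites([]), invariant=True) == "invariant"

    def test_negative_call(self):
        sites = self._sites([("g", "negative", 0.01)])
        assert classify_gene_selection(sites) == "negative"


class TestSelectionSummary:
    def _inputs(self):
        sites = pd.DataFrame(
            [
                {"species_id": "s", "gene_id": g, "compartment": c, "site_index": 1,
                 "direction": d, "p_value": p}
                for g, c, d, p in [
                    ("g1", "SP", "negative", 0.01),
                    ("g2", "SP", "negative", 0.30),
                    ("g3", "CP", "negative", 0.001),
                    ("g4", "CP", "positive", 0.02),
                ]
            ]
        )
        meta = pd.DataFrame(
            [
                {"gene_id": "g1", "size_class": "large", "compartment": "SP"},
                {"gene_id": "g2", "size_class": "large", "compartment": "SP"},
                {"gene_id": "g3", "size_class": "large", "compartment": "CP"},
                {"gene_id": "g4", "size_class": "large", "compartment": "CP"},
            ]
        )
        return sites, meta

    def test_proportions(self):
        props, per_gene, _ = selection_summary(*self._inputs())
        sp = props[(props["compartment"] == "SP")].iloc[0]
        assert sp["pct_negative"] == 50.0
        cp = props[(props["compartment"] == "CP")].iloc[0]
        assert cp["pct_positive"] == 50.0
        assert per_gene.set_index("gene_id").loc["g3", "n_negative_sites"] == 1

    def test_homogeneous_table_chi_square_zero(self):
        meta = pd.DataFrame(
            [{"gene_id": f"g{i}{c}", "size_class": "large", "compartment": c}
             for c in ("SP", "CP") for i in range(6)]
        )
        sites = pd.DataFrame(
            [{"species_id": "s", "gene_id": f"g{i}{c}", "compartment": c,
              "site_index": 1, "direction": "negative",
              "p_value": 0.01 if i < 2 else 0.9}
             for c in ("SP", "CP") for i in range(6)]
        )
        _, _, chisq = selection_summary(sites, meta)
        assert chisq["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_chi_square_matches_hand_computed_pearson(self):
        """Planted SP depletion of negative genes; chi2 checked against the
        hand-expanded Pearson sum over the 2x3 table."""
        rows = []
        # SP: 2 positive, 2 negative, 16 other; CP: 2 positive, 14 negative, 4 other
        for comp, calls in {
            "SP": ["positive"] * 2 + ["negative"] * 2 + ["none"] * 16,
            "CP": ["positive"] * 2 + ["negative"] * 14 + ["none"] * 4,
        }.items():
            for i, call in enumerate(calls):
                gid = f"{comp}{i}"
                rows.append((gid, comp, call))
        meta = pd.DataFrame(
            [{"gene_id": g, "size_class": "small", "compartment": c} for g, c, _ in rows]
        )
        sites = pd.DataFrame(
            [
                {"species_id": "s", "gene_id": g, "compartment": c, "site_index": 1,
                 "direction": call if call != "none" else "negative",
                 "p_value": 0.01 if call != "none" else 0.99}
                for g, c, call in rows
            ]
        )
        _, _, chisq = selection_summary(sites, meta)
        observed = np.array([[2, 2, 16], [2, 14, 4]], dtype=float)
        expected = observed.sum(1, keepdims=True) * observed.sum(0) / observed.sum()
        pearson = float(((observed - expected) ** 2 / expected).sum())
        assert chisq["chi2"].iloc[0] == pytest.approx(pearson, abs=1e-9)
        assert chisq["df"].iloc[0] == 2
        assert chisq["p_value"].iloc[0] < 0.05


class TestRecombinationSummary:
    def _estimates(self, rows):
        return pd.DataFrame(
            rows, columns=["species_id", "size_class", "compartment", "r_over_m", "nu", "delta"]
        )

    def test_unity_flags(self):
        est = self._estimates(
            [("s1", "small", "SP", 1.0, 0.01, 100), ("s2", "small", "SP", 1.0, 0.01, 100)]
        )
        med, tests = recombination_summary(est)
        assert (med["fraction_rm_above_unity"] == 0.0).all()
        assert tests.empty  # single size class: tests skipped

    def test_planted_nu_contrast_detected(self, rng):
        rows = []
        for i in range(16):
            rows.append((f"L{i}", "large", "SP", 0.8, rng.normal(0.08, 0.01), 300))
        for i in range(14):
            rows.append((f"S{i}", "small", "SP", 0.8, rng.normal(0.04, 0.01), 300))
        med, tests = recombination_summary(self._estimates(rows))
        nu_test = tests[tests["statistic"] == "nu"]
        assert nu_test["p_value"].iloc[0] < 0.05
        large_nu = med[(med["size_class"] == "large")]["nu"].iloc[0]
        small_nu = med[(med["size_class"] == "small")]["nu"].iloc[0]
        assert large_nu > small_nu

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            recombination_summary(pd.DataFrame())


FEL_TEXT = """\
species_id\tgene_id\tcompartment\tsite_index\tdirection\tp_value
s1\tg1\tSP\t3\tnegative\t0.01
s1\tg1\tSP\t9\tpositive\t0.20
s1\tg2\tCP\t1\tnegative\t1.5
"""

CFML_TEXT = """\
species_id\tcompartment\tr_over_m\tnu\tdelta
s1\tSP\t0.8\t0.04\t220.5
s1\tCP\t1.3\t0.06\t310.0
"""


class TestAdapters:
    def test_fel_fixture_row_count_and_validation(self):
        table = parse_fel_table(io.StringIO(FEL_TEXT))
        assert len(table) == 2  # p=1.5 row dropped
        assert set(table["direction"]) == {"negative", "positive"}

    def test_fel_unknown_direction_is_schema_error(self):
        bad = FEL_TEXT.replace("positive", "diversifying")
        with pytest.raises(TableSchemaError, match="direction"):
            parse_fel_table(io.StringIO(bad))

    def test_fel_missing_column_named(self):
        bad = FEL_TEXT.replace("p_value", "pval")
        with pytest.raises(TableSchemaError, match="p_value"):
            parse_fel_table(io.StringIO(bad))

    def test_fel_empty_stream(self):
        assert parse_fel_table(io.StringIO("")).empty

    def test_cfml_fixture(self):
        table = parse_cfml_table(io.StringIO(CFML_TEXT))
        assert len(table) == 2
        assert table.loc[0, "delta"] == 220.5

    def test_cfml_negative_value_rejected(self):
        bad = CFML_TEXT.replace("0.8", "-0.8")
        with pytest.raises(TableSchemaError, match="r_over_m"):
            parse_cfml_table(io.StringIO(bad))
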