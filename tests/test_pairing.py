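import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taudiv import (
    AgeCalibration,
    FormatError,
    attach_outgroups,
    select_ortholog_pairs,
    select_youngest_paralog_pairs,
)
from taudiv.io_tables import HOMOLOGY_COLUMNS


def hom_frame(rows):
    return pd.DataFrame(rows, columns=list(HOMOLOGY_COLUMNS))


def tau_frame(max_expr: dict, tau: dict | None = None):
    genes = list(max_expr)
    return pd.DataFrame(
        {
            "tau": [0.5 if tau is None else tau[g] for g in genes],
            "max_tissue": "brain",
            "max_expression": [max_expr[g] for g in genes],
            "defined": True,
        },
        index=pd.Index(genes, name="gene_id"),
    )


CAL = AgeCalibration({"Euarchontoglires": 90, "Eutheria": 105, "Theria": 160, "Old": 300})


class TestOrthologPairs:
    def test_direct_construction(self):
        hom = hom_frame(
            [
                (f"h{i}", "human", f"m{i}", "mouse", "one2one_ortholog",
                 "Euarchontoglires", f"f{i}")
                for i in range(5)
            ]
        )
        pairs = select_ortholog_pairs(hom, "human", "mouse", CAL)
        assert len(pairs) == 5
        assert (pairs["age_my"] == 90).all()
        assert (pairs["pair_class"] == "ortholog").all()
        assert pairs.loc[0, "gene_ref"].startswith("h")

    def test_reversed_orientation_in_table(self):
        hom = hom_frame(
            [("m1", "mouse", "h1", "human", "one2one_ortholog", "Euarchontoglires", "f1")]
        )
        pairs = select_ortholog_pairs(hom, "human", "mouse", CAL)
        assert pairs.loc[0, "gene_ref"] == "h1" and pairs.loc[0, "gene_alt"] == "m1"

    def test_duplicate_partner_is_data_error(self):
        hom = hom_frame(
            [
                ("h1", "human", "m1", "mouse", "one2one_ortholog", "Euarchontoglires", "f1"),
                ("h1", "human", "m2", "mouse", "one2one_ortholog", "Euarchontoglires", "f2"),
            ]
        )
        with pytest.raises(FormatError):
            select_ortholog_pairs(hom, "human", "mouse", CAL)

    def test_absent_species_pair_gives_empty(self):
        hom = hom_frame(
            [("h1", "human", "m1", "mouse", "one2one_ortholog", "Euarchontoglires", "f1")]
        )
        pairs = select_ortholog_pairs(hom, "human", "frog", CAL)
        assert pairs.empty


class TestYoungestParalogPairs:
    FAMILY = [
        # family {A, B, C}: A split from (B, C) at 300 My, B-C split at 90 My
        ("A", "human", "B", "human", "within_species_paralog", "Old", "fam1"),
        ("A", "human", "C", "human", "within_species_paralog", "Old", "fam1"),
        ("B", "human", "C", "human", "within_species_paralog", "Euarchontoglires", "fam1"),
    ]

    def test_youngest_couple_per_gene(self):
        tau = tau_frame({"A": 10.0, "B": 50.0, "C": 5.0})
        pairs = select_youngest_paralog_pairs(hom_frame(self.FAMILY), "human", CAL, tau)
        by_age = {row.age_my: row for row in pairs.itertuples()}
        assert set(by_age) == {90.0, 300.0}
        # B-C retained at 90 My, oriented by expression (B higher)
        assert (by_age[90.0].gene_ref, by_age[90.0].gene_alt) == ("B", "C")
        # A paired with its youngest partner at 300 My; B has higher expression
        assert (by_age[300.0].gene_ref, by_age[300.0].gene_alt) == ("B", "A")

    def test_orientation_by_max_expression(self):
        hom = hom_frame(
            [("A", "human", "B", "human", "within_species_paralog", "Eutheria", "f1")]
        )
        pairs = select_youngest_paralog_pairs(
            hom, "human", CAL, tau_frame({"A": 10.0, "B": 50.0})
        )
        assert pairs.loc[0, "gene_ref"] == "B"

    def test_equal_expression_tie_breaks_lexicographically(self):
        hom = hom_frame(
            [("Z", "human", "A", "human", "within_species_paralog", "Eutheria", "f1")]
        )
        pairs = select_youngest_paralog_pairs(
            hom, "human", CAL, tau_frame({"Z": 7.0, "A": 7.0})
        )
        assert pairs.loc[0, "gene_ref"] == "A"

    def test_missing_gene_dropped(self):
        hom = hom_frame(
            [
                ("A", "human", "B", "human", "within_species_paralog", "Eutheria", "f1"),
                ("C", "human", "D", "human", "within_species_paralog", "Eutheria", "f2"),
            ]
        )
        pairs = select_youngest_paralog_pairs(
            hom, "human", CAL, tau_frame({"A": 1.0, "B": 2.0})
        )
        assert len(pairs) == 1

    def test_genes_unique_within_age_class(self):
        tau = tau_frame({"A": 10.0, "B": 50.0, "C": 5.0, "D": 3.0})
        hom = hom_frame(
            self.FAMILY
            + [("B", "human", "D", "human", "within_species_paralog", "Euarchontoglires", "fam1")]
        )
        pairs = select_youngest_paralog_pairs(hom, "human", CAL, tau)
        for _, grp in pairs.groupby("node_label"):
            members = list(grp["gene_ref"]) + list(grp["gene_alt"])
            assert len(members) == len(set(members))

    def test_reference_orientation_invariant(self):
        tau = tau_frame({c: float(i + 1) for i, c in enumerate("ABCDEF")})
        hom = hom_frame(
            [
                ("A", "human", "B", "human", "within_species_paralog", "Eutheria", "f1"),
                ("C", "human", "D", "human", "within_species_paralog", "Theria", "f2"),
                ("E", "human", "F", "human", "within_species_paralog", "Old", "f3"),
            ]
        )
        pairs = select_youngest_paralog_pairs(hom, "human", CAL, tau)
        me = tau["max_expression"]
        assert all(me[r.gene_ref] >= me[r.gene_alt] for r in pairs.itertuples())

    def test_expression_orientation_beats_random(self, rng):
        """On simulated paralogs with asymmetric loss, the highest-expression
        orientation yields a cross-pair tau correlation at least as high as
        the mean over 100 random orientations."""
        from taudiv import (
            DuplicationScenario,
            SimulationConfig,
            build_tau_table,
            simulate_study,
        )

        config = SimulationConfig(
            n_genes=50,
            scenarios=[DuplicationScenario("Eutheria", 90.0, n_families=300)],
        )
        bundle = simulate_study(config, seed=7)
        tau = build_tau_table(bundle.expression["human"])
        pairs = select_youngest_paralog_pairs(
            bundle.homology, "human", bundle.calibration, tau
        )
        x = pairs["gene_ref"].map(tau["tau"]).to_numpy()
        y = pairs["gene_alt"].map(tau["tau"]).to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        r_oriented = stats.pearsonr(x, y).statistic
        rs = []
        for _ in range(100):
            flip = rng.random(len(x)) < 0.5
            a, b = np.where(flip, y, x), np.where(flip, x, y)
            rs.append(stats.pearsonr(a, b).statistic)
        assert r_oriented >= np.mean(rs)


class TestAttachOutgroups:
    PAIRS = pd.DataFrame(
        [("P1", "P2", "paralog", 105.0, "Eutheria")],
        columns=["gene_ref", "gene_alt", "pair_class", "age_my", "node_label"],
    )

    @staticmethod
    def og_rows(node="Theria", out_gene="O1", out_sp="opossum"):
        return [
            ("P1", "human", out_gene, out_sp, "one2two_outgroup", node, "fam1"),
            ("P2", "human", out_gene, out_sp, "one2two_outgroup", node, "fam1"),
        ]

    def test_valid_triplet(self):
        trip = attach_outgroups(self.PAIRS, hom_frame(self.og_rows()), CAL)
        assert len(trip) == 1
        row = trip.iloc[0]
        assert row["outgroup_gene"] == "O1" and row["outgroup_age_my"] == 160.0

    def test_outgroup_younger_than_duplication_skipped(self):
        trip = attach_outgroups(
            self.PAIRS, hom_frame(self.og_rows(node="Euarchontoglires")), CAL
        )
        assert trip.empty

    def test_closest_of_two_candidates_chosen(self):
        hom = hom_frame(
            self.og_rows(node="Theria", out_gene="O1", out_sp="opossum")
            + self.og_rows(node="Old", out_gene="O2", out_sp="chicken")
        )
        trip = attach_outgroups(self.PAIRS, hom, CAL)
        assert trip.iloc[0]["outgroup_gene"] == "O1"

    def test_duplicated_outgroup_skipped(self):
        hom = hom_frame(
            self.og_rows()
            + [("O1", "opossum", "O1b", "opossum", "within_species_paralog", "Theria", "fam9")]
        )
        trip = attach_outgroups(self.PAIRS, hom, CAL)
        assert trip.empty

    def test_one_sided_link_not_enough(self):
        hom = hom_frame(self.og_rows()[:1])  # only P1 linked to O1
        trip = attach_outgroups(self.PAIRS, hom, CAL)
        assert trip.empty
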