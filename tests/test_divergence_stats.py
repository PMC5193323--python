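import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taudiv import (
    DimensionError,
    DivergencePoint,
    TissueMap,
    UndefinedCorrelationError,
    compare_groups,
    estimate_pi0,
    fit_decay,
    outgroup_asymmetry,
    qvalues,
    same_tissue_counts,
    tau_correlation,
)


def make_pairs(n, age=90.0, cls="ortholog"):
    return pd.DataFrame(
        {
            "gene_ref": [f"r{i}" for i in range(n)],
            "gene_alt": [f"a{i}" for i in range(n)],
            "pair_class": cls,
            "age_my": age,
            "node_label": "node",
        }
    )


def tau_table(values, prefix, extra=None):
    genes = [f"{prefix}{i}" for i in range(len(values))]
    df = pd.DataFrame(
        {
            "tau": values,
            "max_tissue": (extra or {}).get("max_tissue", ["brain"] * len(values)),
            "max_expression": 10.0,
            "defined": np.isfinite(values),
            "testis_forced": False,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return df


class TestTauCorrelation:
    def test_identity_gives_one(self, rng):
        v = rng.random(100)
        point = tau_correlation(make_pairs(100), tau_table(v, "r"), tau_table(v, "a"))
        assert point.r == pytest.approx(1.0)
        assert point.n_pairs == 100

    def test_anticorrelation_gives_minus_one(self, rng):
        v = rng.random(50)
        point = tau_correlation(make_pairs(50), tau_table(v, "r"), tau_table(1 - v, "a"))
        assert point.r == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        x = np.array([0.1, 0.5, 0.9, 0.3])
        y = np.array([0.2, 0.4, 0.9, 0.5])
        # textbook closed form
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        point = tau_correlation(make_pairs(4), tau_table(x, "r"), tau_table(y, "a"))
        assert point.r == pytest.approx(expected, abs=1e-12)

    def test_spearman_matches_rank_pearson(self, rng):
        x, y = rng.random(30), rng.random(30)
        point = tau_correlation(
            make_pairs(30), tau_table(x, "r"), tau_table(y, "a"), method="spearman"
        )
        ranks = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert point.r == pytest.approx(ranks, abs=1e-12)

    def test_undefined_tau_dropped(self, rng):
        v = rng.random(10)
        v_alt = v.copy()
        v_alt[:3] = np.nan
        point = tau_correlation(make_pairs(10), tau_table(v, "r"), tau_table(v_alt, "a"))
        assert point.n_pairs == 7

    def test_too_few_pairs_returns_none(self):
        assert tau_correlation(make_pairs(2), tau_table([0.1, 0.2], "r"),
                               tau_table([0.1, 0.2], "a")) is None

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            tau_correlation(
                make_pairs(5),
                tau_table(np.full(5, 0.5), "r"),
                tau_table(np.arange(5) / 5, "a"),
            )


class TestFitDecay:
    def test_exact_linear_fit(self):
        ages = [10.0, 50.0, 120.0, 200.0, 300.0]
        pts = [DivergencePoint(a, 1 - 0.001 * a, 100, "ortholog") for a in ages]
        fit = fit_decay(pts)
        assert fit["linear"].slope == pytest.approx(-0.001, abs=1e-12)
        assert fit["linear"].rss == pytest.approx(0.0, abs=1e-20)
        assert fit["comparison"].preferred == "linear"

    def test_flat_points_have_nonsignificant_slope(self, rng):
        hits = 0
        for _ in range(500):
            pts = [
                DivergencePoint(a, 0.7 + rng.normal(0, 0.05), 100, "ortholog")
                for a in [10.0, 50.0, 120.0, 200.0, 300.0, 361.0]
            ]
            hits += fit_decay(pts)["linear"].slope_p > 0.05
        assert hits / 500 >= 0.90  # ~95% expected at the 5% level

    def test_too_few_points(self):
        with pytest.raises(DimensionError):
            fit_decay([DivergencePoint(10, 0.9, 10, "o")] * 3)

    def test_degenerate_ages(self):
        from taudiv import DegenerateDesignError

        with pytest.raises(DegenerateDesignError):
            fit_decay([DivergencePoint(10, 0.9, 10, "o")] * 5)


class TestCompareGroups:
    def ages(self):
        return [10.0, 50.0, 120.0, 200.0, 300.0]

    def test_identical_groups_p_near_one(self):
        pts = [DivergencePoint(a, 1 - 0.001 * a, 50, "o") for a in self.ages()]
        cmp_ = compare_groups(pts, list(pts))
        assert cmp_.extra["group_effect"] == pytest.approx(0.0, abs=1e-10)
        assert cmp_.p_value > 0.9

    def test_clear_offset_detected(self, rng):
        a = [DivergencePoint(t, 0.9 - 0.0005 * t + rng.normal(0, 1e-4), 50, "o")
             for t in self.ages()]
        b = [DivergencePoint(t, 0.6 - 0.0005 * t + rng.normal(0, 1e-4), 50, "p")
             for t in self.ages()]
        cmp_ = compare_groups(a, b, "ortholog", "paralog")
        assert cmp_.p_value < 1e-6
        assert cmp_.extra["group_effect"] == pytest.approx(-0.3, abs=0.01)

    def test_null_group_labels_p_uniform(self, rng):
        """With group labels carrying no signal the F-test p-value is
        uniform over replicates (KS)."""
        ages = np.array(self.ages() + [361.0])
        pvals = []
        for _ in range(500):
            r = 0.8 - 0.0004 * ages + rng.normal(0, 0.03, len(ages))
            pts = [DivergencePoint(a, v, 50, "x") for a, v in zip(ages, r)]
            labels = rng.permutation([0, 0, 0, 1, 1, 1])
            a = [p for p, l in zip(pts, labels) if l == 0]
            b = [p for p, l in zip(pts, labels) if l == 1]
            pvals.append(compare_groups(a, b).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestQvalues:
    def test_all_zero(self):
        np.testing.assert_allclose(qvalues(np.zeros(10)), np.zeros(10))

    def test_hand_oracle_two_values(self):
        # Storey with lambda = 0.5: pi0 = #{p > .5}/(m * .5); BH on (0.01, 0.5)
        p = np.array([0.01, 0.5])
        pi0 = min(1.0, (p > 0.5).sum() / (2 * 0.5))
        bh = np.array([min(0.01 * 2 / 1, 0.5 * 2 / 2), 0.5 * 2 / 2])
        np.testing.assert_allclose(qvalues(p), pi0 * bh, atol=1e-15)

    def test_equals_pi0_times_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(200) ** rng.uniform(0.5, 2)
            q = qvalues(p)
            bh = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, estimate_pi0(p) * bh, atol=1e-12)
            # monotone in sorted p
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
            assert (q <= 1 + 1e-12).all()

    def test_pi0_near_one_on_uniform(self, rng):
        pi0s = [estimate_pi0(rng.random(1000)) for _ in range(100)]
        assert min(pi0s) >= 0.85 and max(pi0s) <= 1.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestSameTissueCounts:
    def test_direct_counting(self):
        pairs = make_pairs(3, cls="paralog")
        t_ref = tau_table(
            [0.9, 0.95, 0.85], "r",
            {"max_tissue": ["liver", "brain", "testis"]},
        )
        t_alt = tau_table(
            [0.9, 0.95, 0.85], "a",
            {"max_tissue": ["liver", "heart", "testis"]},
        )
        counts = same_tissue_counts(pairs, t_ref, t_alt)
        row = counts.iloc[0]
        assert (row.n_same, row.n_different, row.n_excluded) == (2, 1, 0)

    def test_nonspecific_member_excluded(self):
        pairs = make_pairs(2)
        t_ref = tau_table([0.9, 0.5], "r")
        t_alt = tau_table([0.9, 0.9], "a")
        counts = same_tissue_counts(pairs, t_ref, t_alt)
        assert counts.iloc[0].n_same + counts.iloc[0].n_different == 1

    def test_cross_species_mapping(self):
        pairs = make_pairs(1)
        t_ref = tau_table([0.9], "r", {"max_tissue": ["cerebral cortex"]})
        t_alt = tau_table([0.9], "a", {"max_tissue": ["brain"]})
        tmap = TissueMap(
            {("human", "cerebral cortex"): "brain", ("mouse", "brain"): "brain"}
        )
        counts = same_tissue_counts(
            pairs, t_ref, t_alt, tmap, species_ref="human", species_alt="mouse"
        )
        assert counts.iloc[0].n_same == 1

    def test_unmapped_tissue_counted_as_excluded(self):
        pairs = make_pairs(1)
        t_ref = tau_table([0.9], "r", {"max_tissue": ["antenna"]})
        t_alt = tau_table([0.9], "a")
        tmap = TissueMap({("mouse", "brain"): "brain"})
        counts = same_tissue_counts(
            pairs, t_ref, t_alt, tmap, species_ref="fly", species_alt="mouse"
        )
        row = counts.iloc[0]
        assert row.n_excluded == 1 and row.n_same + row.n_different == 0

    def test_conservation_identity(self, rng):
        n = 50
        pairs = make_pairs(n)
        t_ref = tau_table(rng.random(n), "r")
        t_alt = tau_table(rng.random(n), "a")
        counts = same_tissue_counts(pairs, t_ref, t_alt, threshold=0.3)
        n_specific = int(
            (
                (t_ref["tau"].to_numpy() >= 0.3) & (t_alt["tau"].to_numpy() >= 0.3)
            ).sum()
        )
        row = counts.iloc[0]
        assert row.n_same + row.n_different + row.n_excluded == n_specific


class TestOutgroupAsymmetry:
    def make_triplets(self, n):
        return pd.DataFrame(
            {
                "gene_ref": [f"hi{i}" for i in range(n)],
                "gene_alt": [f"lo{i}" for i in range(n)],
                "pair_class": "paralog",
                "age_my": 105.0,
                "node_label": "Eutheria",
                "outgroup_gene": [f"o{i}" for i in range(n)],
                "outgroup_species": "opossum",
                "outgroup_age_my": 160.0,
            }
        )

    def test_constructed_asymmetry(self, rng):
        n = 60
        v = rng.random(n)
        focal = pd.concat(
            [tau_table(v, "hi"), tau_table(rng.permutation(v), "lo")]
        )
        out = {"opossum": tau_table(v, "o")}
        result = outgroup_asymmetry(self.make_triplets(n), focal, out)
        r_major = result[result.role == "major"].r.iloc[0]
        r_minor = result[result.role == "minor"].r.iloc[0]
        assert r_major == pytest.approx(1.0)
        assert abs(r_minor) < 0.5

    def test_identical_paralogs_symmetric(self, rng):
        n = 30
        v = rng.random(n)
        focal = pd.concat([tau_table(v, "hi"), tau_table(v, "lo")])
        out = {"opossum": tau_table(rng.random(n), "o")}
        result = outgroup_asymmetry(self.make_triplets(n), focal, out)
        r = result.set_index("role")["r"]
        assert r["major"] == pytest.approx(r["minor"])

    def test_single_triplet_dropped(self, rng):
        focal = pd.concat([tau_table([0.4], "hi"), tau_table([0.6], "lo")])
        out = {"opossum": tau_table([0.5], "o")}
        assert outgroup_asymmetry(self.make_triplets(1), focal, out).empty
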