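import numpy as np
import pandas as pd
import pytest

from crckit import clinical


def make_pathways():
    return [
        clinical.PathwayDefinition("cell_cycle", {"RB1": "tumor_suppressor", "CCND1": "oncogene"}),
        clinical.PathwayDefinition("tgf_beta", {"SMAD2": "tumor_suppressor", "SMAD4": "tumor_suppressor"}),
    ]


def alt(sample, gene, onc="unknown"):
    return {"sample_id": sample, "gene": gene, "oncogenicity": onc}


class TestPathwayRollup:
    def test_oncogenic_beats_vus(self):
        alts = pd.DataFrame(
            [alt("S1", "RB1", "oncogenic")] + [alt("S1", "CCND1", "vus")] * 3
        )
        out = clinical.rollup_pathway_status(alts, make_pathways())
        assert out.loc["S1", "cell_cycle"] == "oncogenic"

    def test_only_vus_gives_vus(self):
        alts = pd.DataFrame([alt("S1", "SMAD2", "vus"), alt("S1", "SMAD4", "unknown")])
        out = clinical.rollup_pathway_status(alts, make_pathways())
        assert out.loc["S1", "tgf_beta"] == "vus"

    def test_unaltered_pathway_is_wt(self):
        alts = pd.DataFrame([alt("S1", "RB1", "vus")])
        out = clinical.rollup_pathway_status(alts, make_pathways())
        assert out.loc["S1", "tgf_beta"] == "wt"

    def test_non_member_gene_ignored(self):
        alts = pd.DataFrame([alt("S1", "NOTAGENE", "oncogenic")])
        out = clinical.rollup_pathway_status(alts, make_pathways(), samples=["S1"])
        assert (out.loc["S1"] == "wt").all()

    def test_monotone_upgrade_only(self, rng):
        """Appending an oncogenic alteration never downgrades any status."""
        base_alts = pd.DataFrame(
            [alt("S1", g, o) for g, o in [("RB1", "vus"), ("SMAD2", "oncogenic")]]
        )
        before = clinical.rollup_pathway_status(base_alts, make_pathways())
        more = pd.concat(
            [base_alts, pd.DataFrame([alt("S1", "CCND1", "oncogenic")])], ignore_index=True
        )
        after = clinical.rollup_pathway_status(more, make_pathways())
        rank = {"wt": 0, "vus": 1, "oncogenic": 2}
        for pw in before.columns:
            assert rank[after.loc["S1", pw]] >= rank[before.loc["S1", pw]]


class TestSmgConsensus:
    def test_two_tool_gene_kept(self):
        lists = {"t1": ["TP53", "APC"], "t2": ["TP53"], "t3": [], "t4": [], "t5": []}
        out = clinical.smg_consensus(lists)
        assert list(out["gene"]) == ["TP53"]
        assert out.loc[0, "n_tools"] == 2

    def test_single_tool_gene_dropped(self):
        out = clinical.smg_consensus({"t1": ["KRAS"], "t2": ["TP53"]})
        assert out.empty

    def test_matches_brute_force(self, rng):
        genes = [f"G{i}" for i in range(30)]
        lists = {
            f"t{j}": list(rng.choice(genes, size=rng.integers(5, 15), replace=False))
            for j in range(5)
        }
        out = clinical.smg_consensus(lists)
        counts = {}
        for tool, gl in lists.items():
            for g in set(gl):
                counts[g] = counts.get(g, 0) + 1
        expected = sorted(g for g, n in counts.items() if n >= 2)
        assert list(out["gene"]) == expected

    def test_invariant_to_order_and_duplication(self):
        a = clinical.smg_consensus({"t1": ["A", "B"], "t2": ["B", "A", "A"]})
        b = clinical.smg_consensus({"t1": ["B", "A"], "t2": ["A", "B"]})
        pd.testing.assert_frame_equal(a, b)


class TestSurvival:
    def test_single_group_errors(self):
        t = pd.Series([1.0, 2.0])
        e = pd.Series([True, True])
        with pytest.raises(ValueError):
            clinical.km_logrank(t, e, pd.Series(["a", "a"]))

    def test_logrank_matches_hand_computation(self):
        """Two fully-observed groups vs the textbook log-rank formula."""
        times = pd.Series([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        events = pd.Series([True] * 6)
        groups = pd.Series(["A", "A", "A", "B", "B", "B"])
        res = clinical.km_logrank(times, events, groups)
        # independent hand computation of the log-rank chi-square
        order = np.argsort(times.to_numpy())
        at_risk_a = 3
        at_risk_b = 3
        o_minus_e = 0.0
        var = 0.0
        for i in order:
            n = at_risk_a + at_risk_b
            e_a = at_risk_a / n
            o_a = 1.0 if groups[i] == "A" else 0.0
            o_minus_e += o_a - e_a
            var += e_a * (1 - e_a)  # single event per time, no ties
            if groups[i] == "A":
                at_risk_a -= 1
            else:
                at_risk_b -= 1
        expected = o_minus_e**2 / var
        assert res["logrank_stat"] == pytest.approx(expected, rel=1e-6)

    def test_km_medians_and_counts(self):
        times = pd.Series([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        events = pd.Series([True, True, True, False, False, False])
        groups = pd.Series(["dead"] * 3 + ["alive"] * 3)
        res = clinical.km_logrank(times, events, groups)
        assert res["groups"]["dead"]["median"] == 2.0
        assert res["groups"]["alive"]["all_censored"]
        assert np.isinf(res["groups"]["alive"]["median"])

    def test_cox_recovers_planted_hazard(self, rng):
        """True HR of 2 for a binary exposure, n = 1000."""
        n = 1000
        x = rng.random(n) < 0.5
        hazard = 0.02 * np.exp(np.log(2.0) * x)
        t = rng.exponential(1 / hazard)
        c = rng.exponential(80, n)
        df = pd.DataFrame(
            {
                "os_months": np.minimum(t, c),
                "os_event": t <= c,
                "exposure": x.astype(float),
            }
        )
        out = clinical.cox_adjusted(df, "exposure", covariates=())
        hr = out.loc["exposure", "hr"]
        assert 1.7 <= hr <= 2.3
        assert out.loc["exposure", "ci_lower"] < hr < out.loc["exposure", "ci_upper"]

    def test_cox_constant_exposure_errors(self):
        df = pd.DataFrame(
            {"os_months": [1.0, 2.0, 3.0], "os_event": [True, True, False], "x": 1.0}
        )
        with pytest.raises(ValueError):
            clinical.cox_adjusted(df, "x", covariates=())

    def test_cox_adjusts_for_categorical_covariates(self, rng):
        n = 400
        stage = rng.choice(["II", "III"], n)
        x = rng.random(n) < 0.5
        hazard = 0.02 * np.exp(0.7 * x + 0.3 * (stage == "III"))
        t = rng.exponential(1 / hazard)
        df = pd.DataFrame(
            {"os_months": t, "os_event": True, "exposure": x.astype(float), "stage": stage}
        )
        out = clinical.cox_adjusted(df, "exposure", covariates=("stage",))
        assert "exposure" in out.index
        assert any(ix.startswith("stage") for ix in out.index)


class TestAssociationNetwork:
    def test_perfect_binary_association(self):
        df = pd.DataFrame({"a": [0, 1] * 50, "b": [0, 1] * 50})
        out = clinical.association_network(df, categorical=["a", "b"])
        assert out.loc[0, "p"] < 1e-10

    def test_small_expected_cell_uses_fisher(self):
        a = [0] * 6 + [1] * 6
        b = [0, 0, 0, 0, 0, 1] + [1, 1, 1, 1, 1, 0]
        out = clinical.association_network(
            pd.DataFrame({"a": a, "b": b}), categorical=["a", "b"]
        )
        assert out.loc[0, "test"] == "fisher"

    def test_constant_variable_skipped(self):
        df = pd.DataFrame({"a": [1] * 10, "b": [0, 1] * 5})
        out = clinical.association_network(df, categorical=["a", "b"])
        assert out.loc[0, "test"] == "skipped"
        assert np.isnan(out.loc[0, "p"])

    def test_continuous_binary_uses_ttest(self, rng):
        df = pd.DataFrame({"grp": [0, 1] * 30, "val": rng.normal(0, 1, 60)})
        out = clinical.association_network(df, categorical=["grp"], continuous=["val"])
        assert out.loc[0, "test"] == "t-test"

    def test_bh_false_positive_control(self, rng):
        """Independent binary pairs: BH keeps the discovery rate near zero."""
        n_pairs, n = 200, 60
        ps = []
        for _ in range(n_pairs):
            df = pd.DataFrame(
                {"a": rng.integers(0, 2, n), "b": rng.integers(0, 2, n)}
            )
            out = clinical.association_network(df, categorical=["a", "b"])
            ps.append(out.loc[0, "p"])
        from statsmodels.stats.multitest import multipletests

        rejected = multipletests(ps, alpha=0.05, method="fdr_bh")[0]
        assert rejected.mean() <= 0.05
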