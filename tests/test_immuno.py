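import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crckit import immuno
from conftest import make_mutation_table

CTX_A = {"trinuc_context": "ACG", "ref": "C", "alt": "T"}  # A[C>T]G
CTX_B = {"trinuc_context": "TCA", "ref": "C", "alt": "A"}  # T[C>A]A


def eligible_sample(sample_id="S1", n_extra=10):
    """Padding rows so the sample passes the >=10 non-silent floor."""
    return [
        {**CTX_B, "sample_id": sample_id, "pos": 9000 + i, "is_silent": False}
        for i in range(n_extra)
    ]


class TestContextRates:
    def test_direct_ratios(self):
        """4 non-silent (2 immunogenic) and 2 silent in one context."""
        rows = (
            [{**CTX_A, "pos": i, "n_neoantigens": 1} for i in range(2)]
            + [{**CTX_A, "pos": 10 + i} for i in range(2)]
            + [{**CTX_A, "pos": 20 + i, "is_silent": True, "func_class": "Silent"} for i in range(2)]
            + eligible_sample()
        )
        rates = immuno.estimate_context_rates(make_mutation_table(rows))
        assert rates.b_bar["A[C>T]G"] == 0.5
        assert rates.n_bar["A[C>T]G"] == 2.0

    def test_ineligible_sample_excluded(self):
        """A sample with 9 non-silent mutations contributes nothing."""
        rows = [
            {**CTX_A, "sample_id": "small", "pos": i, "n_neoantigens": 1}
            for i in range(9)
        ] + eligible_sample("big")
        rates = immuno.estimate_context_rates(make_mutation_table(rows))
        assert "A[C>T]G" not in rates.b_bar.index or rates.b_bar.get("A[C>T]G", 0) == 0
        assert rates.n_eligible_samples == 1

    def test_no_eligible_samples_errors(self):
        rows = [{**CTX_A, "pos": i} for i in range(5)]
        with pytest.raises(ValueError):
            immuno.estimate_context_rates(make_mutation_table(rows))

    def test_brute_force_tally(self, rng):
        """Rates equal an independent per-mutation tally on a 50-row table."""
        contexts = [CTX_A, CTX_B, {"trinuc_context": "GTC", "ref": "T", "alt": "G"}]
        rows = []
        for i in range(50):
            c = contexts[int(rng.integers(3))]
            rows.append(
                {
                    **c,
                    "pos": i + 1,
                    "is_silent": bool(rng.random() < 0.3),
                    "n_neoantigens": int(rng.integers(0, 3)),
                }
            )
        table = make_mutation_table(rows)
        rates = immuno.estimate_context_rates(table, min_nonsilent=10)
        # independent tally
        from crckit.reference import classify_substitution

        tally: dict[str, list[int]] = {}
        for r in rows:
            ctx = classify_substitution(r["trinuc_context"], r["ref"], r["alt"])
            ns, si, im = tally.setdefault(ctx, [0, 0, 0])
            if r.get("is_silent"):
                tally[ctx][1] += 1
            else:
                tally[ctx][0] += 1
                tally[ctx][2] += int(r.get("n_neoantigens", 0) >= 1)
        for ctx, (ns, si, im) in tally.items():
            if ns:
                assert rates.b_bar[ctx] == pytest.approx(im / ns)
            assert rates.n_bar[ctx] == pytest.approx(ns / max(si, 1))


class TestExpectedCounts:
    def _rates(self):
        idx = pd.Index(["A[C>T]G", "T[C>A]A"])
        return immuno.ContextRates(
            b_bar=pd.Series([0.5, 0.25], index=idx),
            n_bar=pd.Series([2.0, 4.0], index=idx),
            n_eligible_samples=1,
        )

    def test_single_silent_mutation(self):
        n_pred, b_pred = immuno.expected_counts(["A[C>T]G"], self._rates())
        assert n_pred == 2.0 and b_pred == 1.0

    def test_matches_manual_sum(self):
        silent = ["A[C>T]G", "T[C>A]A", "T[C>A]A"]
        n_pred, b_pred = immuno.expected_counts(silent, self._rates())
        assert n_pred == 2.0 + 4.0 + 4.0
        assert b_pred == 2.0 * 0.5 + 4.0 * 0.25 + 4.0 * 0.25

    def test_zero_silent_not_assessable(self):
        assert immuno.expected_counts([], self._rates()) is None


class TestImmunoeditingScore:
    def test_consistent_rates_give_unit_score(self):
        """When observed rates equal cohort rates, I = 1 for everyone."""
        rows = []
        for s in ("S1", "S2"):
            rows += [
                {**CTX_A, "sample_id": s, "pos": i, "n_neoantigens": int(i < 5)}
                for i in range(10)
            ]
            rows += [
                {**CTX_A, "sample_id": s, "pos": 100 + i, "is_silent": True,
                 "func_class": "Silent"}
                for i in range(5)
            ]
        out = immuno.immunoediting_score(make_mutation_table(rows))
        np.testing.assert_allclose(out["i_score"], 1.0)
        assert not out["immunoedited"].any()

    def test_zero_observed_immunogenic_gives_zero(self):
        rows = [
            {**CTX_A, "sample_id": "S1", "pos": i, "n_neoantigens": 1} for i in range(5)
        ]
        rows += [{**CTX_A, "sample_id": "S1", "pos": 50 + i} for i in range(5)]
        rows += [
            {**CTX_A, "sample_id": "S1", "pos": 100, "is_silent": True, "func_class": "Silent"}
        ]
        rows += [
            {**CTX_A, "sample_id": "S2", "pos": i} for i in range(10)
        ] + [
            {**CTX_A, "sample_id": "S2", "pos": 200, "is_silent": True, "func_class": "Silent"}
        ]
        out = immuno.immunoediting_score(make_mutation_table(rows))
        assert out.loc["S2", "i_score"] == 0.0

    def test_zscore_standardization(self, rng):
        scores = pd.Series(rng.normal(1.0, 0.3, 500))
        z, flags = immuno.zscore_gate(scores)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_gate_flags_five_percent_of_normal(self, rng):
        """Z < -1.645 flags ~5% of 10,000 i.i.d. normal scores."""
        scores = pd.Series(rng.normal(0.0, 1.0, 10_000))
        _, flags = immuno.zscore_gate(scores)
        assert flags.mean() == pytest.approx(0.05, abs=0.007)


class TestHlaLoh:
    def _calls(self, p, cn, ci):
        rows = [("S1", "A", "a1", p, cn, ci)]
        rows += [("S1", l, "x", 0.5, 1.0, 1.3) for l in ("B", "C")]
        return pd.DataFrame(
            rows, columns=["sample_id", "locus", "allele", "ai_pvalue", "cn_estimate", "ci_upper"]
        )

    @pytest.mark.parametrize(
        "p,cn,ci,status",
        [
            (0.005, 0.3, 0.6, "LOH"),
            (0.005, 0.6, 0.65, "AI"),
            (0.02, 0.1, 0.2, "neither"),
            (0.005, 0.3, 0.75, "AI"),  # CI bound not strictly below 0.7
        ],
    )
    def test_decision_rule(self, p, cn, ci, status):
        out = immuno.classify_hla_loh(self._calls(p, cn, ci))
        assert out.loc["S1", "status"] == status

    def test_missing_locus_not_assessable(self):
        calls = self._calls(0.005, 0.3, 0.6).iloc[:2]
        out = immuno.classify_hla_loh(calls)
        assert out.loc["S1", "status"] == "not-assessable"
        assert not out.loc["S1", "hla_loh"]

    @given(
        p=st.floats(1e-6, 1.0),
        cn=st.floats(0.0, 2.0),
        ci_pad=st.floats(0.0, 0.5),
        dp=st.floats(0.0, 0.5),
        dcn=st.floats(0.0, 0.3),
    )
    def test_monotone_in_all_three_inputs(self, p, cn, ci_pad, dp, dcn):
        """Decreasing p, cn or ci_upper never removes an LOH call."""
        base = immuno.classify_hla_loh(self._calls(p, cn, cn + ci_pad))
        tighter = immuno.classify_hla_loh(
            self._calls(max(p - dp, 0.0), max(cn - dcn, 0.0), max(cn + ci_pad - dcn, 0.0))
        )
        if base.loc["S1", "hla_loh"]:
            assert tighter.loc["S1", "hla_loh"]


class TestIrComposite:
    def test_or_truth_table_exhaustive(self):
        """IR status is the OR of the three escape mechanisms."""
        idx = pd.Index([f"S{i}" for i in range(8)])
        combos = list(itertools.product([False, True], repeat=3))
        npg = pd.Series([c[0] for c in combos], idx)
        loh = pd.Series([c[1] for c in combos], idx)
        ie = pd.Series([c[2] for c in combos], idx)
        out = immuno.classify_immunogenicity_reduction(npg, loh, ie)
        for i, c in enumerate(combos):
            assert out.iloc[i] == ("IR" if any(c) else "nIR")

    def test_not_assessable_counts_as_false(self):
        idx = pd.Index(["A", "B"])
        out = immuno.classify_immunogenicity_reduction(
            pd.Series([np.nan, True], idx),
            pd.Series([np.nan, np.nan], idx),
            pd.Series([False, False], idx),
        )
        assert list(out) == ["nIR", "IR"]


class TestTnbGroups:
    def test_partition(self):
        tnb = pd.Series([0, 1, 5, 10], index=list("ABCD"))
        ir = pd.Series(["IR", "nIR", "IR", "nIR"], index=list("ABCD"))
        groups = immuno.group_by_tnb_ir(tnb, ir)
        assert len(groups) == 4
        assert set(groups) <= {
            "TNB-high/IR", "TNB-high/nIR", "TNB-low/IR", "TNB-low/nIR"
        }

    def test_all_below_cut_empties_high(self):
        tnb = pd.Series([1, 2], index=list("AB"))
        ir = pd.Series(["IR", "nIR"], index=list("AB"))
        groups = immuno.group_by_tnb_ir(tnb, ir, tnb_cut=100)
        assert not groups.str.startswith("TNB-high").any()

    def test_counts_match_crosstab(self, rng):
        idx = pd.Index([f"S{i}" for i in range(60)])
        tnb = pd.Series(rng.integers(0, 20, 60), idx)
        ir = pd.Series(np.where(rng.random(60) < 0.4, "IR", "nIR"), idx)
        groups = immuno.group_by_tnb_ir(tnb, ir, tnb_cut=10)
        ct = pd.crosstab(tnb > 10, ir)
        for (high, status), n in ct.stack().items():
            label = f"TNB-{'high' if high else 'low'}/{status}"
            assert (groups == label).sum() == n
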