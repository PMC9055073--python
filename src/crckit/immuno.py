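"""Neoantigen immunoediting score and immunogenicity-reduction calls.

The immunoediting framework asks whether a tumor carries fewer
immunogenic (neoantigen-bearing) non-silent mutations than its silent
mutations predict.  Cohort-level per-context rates are estimated first:
for each trinucleotide substitution context ``s``, ``B̄_s`` is the average
number of immunogenic mutations per non-silent mutation and ``N̄_s`` the
expected number of non-silent mutations per silent mutation (samples
with >= 10 non-silent mutations only).  A sample's silent mutations then
give expectations

    N_pred = Σ_m N̄_s(m)         B_pred = Σ_m N̄_s(m) · B̄_s(m)

and the immunoediting score is the observed-to-expected ratio of
immunogenic mutations per non-silent mutation,

    I = (B_obs / N_obs) / (B_pred / N_pred).

After Z-scoring I across assessable samples, tumors with Z < -1.645 are
called immunoedited.  Immunogenicity-reduced (IR) tumors have at least
one of: an antigen-presenting-gene (NPG) mutation, HLA loss of
heterozygosity, or immunoediting; tumors with none are nIR.

An "immunogenic mutation" is operationalized as a non-silent mutation
with at least one predicted neoantigen, so B counts mutations, matching
the per-mutation denominators of the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .reference import classify_substitution


@dataclass
class ContextRates:
    """Cohort per-context rates (index: 96-class context labels)."""

    b_bar: pd.Series  # immunogenic mutations per non-silent mutation
    n_bar: pd.Series  # non-silent mutations per silent mutation
    n_eligible_samples: int


def _context_column(table: pd.DataFrame) -> pd.Series:
    ctx = []
    for trinuc, ref, alt in zip(table["trinuc_context"], table["ref"], table["alt"]):
        try:
            ctx.append(classify_substitution(trinuc, ref, alt))
        except ValueError:
            ctx.append(None)
    return pd.Series(ctx, index=table.index)


def estimate_context_rates(
    table: pd.DataFrame, min_nonsilent: int = 10
) -> ContextRates:
    """Estimate B̄_s and N̄_s pooled over eligible samples.

    Only samples with >= ``min_nonsilent`` non-silent mutations enter the
    estimate.  Contexts with zero silent mutations get N̄_s by add-one
    smoothing of the silent denominator.
    """
    snv = table.loc[(table["ref"].str.len() == 1) & (table["alt"].str.len() == 1)].copy()
    snv["context"] = _context_column(snv)
    snv = snv.dropna(subset=["context"])
    nonsilent_per_sample = snv.loc[~snv["is_silent"], "sample_id"].value_counts()
    eligible = set(nonsilent_per_sample.index[nonsilent_per_sample >= min_nonsilent])
    if not eligible:
        raise ValueError("no samples with enough non-silent mutations to estimate rates")
    pool = snv.loc[snv["sample_id"].isin(eligible)]
    ns = pool.loc[~pool["is_silent"]]
    si = pool.loc[pool["is_silent"]]
    ns_count = ns.groupby("context").size()
    si_count = si.groupby("context").size()
    immuno = ns.assign(immunogenic=(ns["n_neoantigens"] >= 1).astype(int))
    b_sum = immuno.groupby("context")["immunogenic"].sum()
    contexts = sorted(set(ns_count.index) | set(si_count.index))
    b_bar = (b_sum.reindex(contexts).fillna(0) / ns_count.reindex(contexts)).fillna(0.0)
    si_n = si_count.reindex(contexts).fillna(0)
    smoothed = si_n.where(si_n > 0, 1.0)  # add-one smoothing for empty silent bins
    n_bar = ns_count.reindex(contexts).fillna(0) / smoothed
    return ContextRates(
        b_bar=b_bar.astype(float),
        n_bar=n_bar.astype(float),
        n_eligible_samples=len(eligible),
    )


def expected_counts(
    silent_contexts: list[str] | pd.Series, rates: ContextRates
) -> tuple[float, float] | None:
    """(N_pred, B_pred) from a sample's silent-mutation contexts.

    Returns None when the sample has no silent mutations (the score is
    then not assessable).
    """
    contexts = list(silent_contexts)
    if not contexts:
        return None
    n_pred = float(sum(rates.n_bar.get(c, 0.0) for c in contexts))
    b_pred = float(
        sum(rates.n_bar.get(c, 0.0) * rates.b_bar.get(c, 0.0) for c in contexts)
    )
    return n_pred, b_pred


class ImmunoeditingScorer(BaseEstimator):
    """Cohort immunoediting scoring with the Z < -1.645 gate.

    ``fit`` estimates the per-context rates from the cohort mutation
    table; ``score_samples`` computes per-sample observed/expected
    counts, the score I, its cohort Z-score, and the immunoedited flag.

    Parameters
    ----------
    min_nonsilent : int, default 10
        Eligibility floor for the rate estimate.
    z_cut : float, default -1.645
        Strict lower gate on the Z-scored I (the one-sided normal 5%
        point).
    """

    def __init__(self, min_nonsilent: int = 10, z_cut: float = -1.645) -> None:
        self.min_nonsilent = min_nonsilent
        self.z_cut = z_cut

    def fit(self, X: pd.DataFrame, y=None) -> "ImmunoeditingScorer":
        self.rates_ = estimate_context_rates(X, self.min_nonsilent)
        return self

    def score_samples(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-sample profile: B_obs, N_obs, N_pred, B_pred, I, z, flag."""
        snv = X.loc[(X["ref"].str.len() == 1) & (X["alt"].str.len() == 1)].copy()
        snv["context"] = _context_column(snv)
        snv = snv.dropna(subset=["context"])
        rows = []
        for sample, grp in snv.groupby("sample_id"):
            ns = grp.loc[~grp["is_silent"]]
            si = grp.loc[grp["is_silent"]]
            b_obs = int((ns["n_neoantigens"] >= 1).sum())
            n_obs = int(len(ns))
            exp = expected_counts(si["context"], self.rates_)
            tnb = int(ns["n_neoantigens"].sum())
            if exp is None or n_obs == 0 or exp[1] == 0 or exp[0] == 0:
                rows.append((sample, b_obs, n_obs, np.nan, np.nan, np.nan, tnb, False))
                continue
            n_pred, b_pred = exp
            score = (b_obs / n_obs) / (b_pred / n_pred)
            rows.append((sample, b_obs, n_obs, n_pred, b_pred, score, tnb, True))
        out = pd.DataFrame(
            rows,
            columns=[
                "sample_id", "b_obs", "n_obs", "n_pred", "b_pred",
                "i_score", "tnb", "assessable",
            ],
        ).set_index("sample_id")
        out["z"], out["immunoedited"] = zscore_gate(out["i_score"], self.z_cut)
        return out


def zscore_gate(scores: pd.Series, z_cut: float = -1.645) -> tuple[pd.Series, pd.Series]:
    """Z-score the defined scores; flag z < z_cut (strict)."""
    vals = scores.dropna()
    z = pd.Series(np.nan, index=scores.index)
    if len(vals) >= 2 and vals.std(ddof=1) > 0:
        z.loc[vals.index] = (vals - vals.mean()) / vals.std(ddof=1)
    flags = z < z_cut
    return z, flags.fillna(False).astype(bool)


def immunoediting_score(
    table: pd.DataFrame, min_nonsilent: int = 10, z_cut: float = -1.645
) -> pd.DataFrame:
    """One-call wrapper: fit rates on the cohort and score every sample."""
    return ImmunoeditingScorer(min_nonsilent, z_cut).fit(table).score_samples(table)


def classify_hla_loh(
    calls: pd.DataFrame,
    p_cut: float = 0.01,
    cn_cut: float = 0.5,
    ci_cut: float = 0.7,
) -> pd.DataFrame:
    """Per-sample HLA allelic-imbalance / LOH classification.

    ``calls`` columns: sample_id, locus (A/B/C), ai_pvalue, cn_estimate,
    ci_upper.  A sample is assessable only with calls at all three
    class-I loci.  Per locus: AI iff p < 0.01; LOH iff AI and allele copy
    number < 0.5 with the CI upper bound strictly below 0.7.  The sample
    is LOH if any locus is.
    """
    rows = []
    for sample, grp in calls.groupby("sample_id"):
        loci = set(grp["locus"])
        if not {"A", "B", "C"} <= loci:
            rows.append((sample, "not-assessable", False, False))
            continue
        ai = grp["ai_pvalue"] < p_cut
        loh = ai & (grp["cn_estimate"] < cn_cut) & (grp["ci_upper"] < ci_cut)
        status = "LOH" if loh.any() else ("AI" if ai.any() else "neither")
        rows.append((sample, status, bool(ai.any()), bool(loh.any())))
    return pd.DataFrame(
        rows, columns=["sample_id", "status", "any_ai", "hla_loh"]
    ).set_index("sample_id")


def classify_immunogenicity_reduction(
    npg_mutated: pd.Series, hla_loh: pd.Series, immunoedited: pd.Series
) -> pd.Series:
    """IR iff any escape mechanism present; nIR iff none.

    Not-assessable inputs (NaN) count as False rather than excluding the
    sample.
    """
    idx = npg_mutated.index

    def as_bool(s: pd.Series) -> pd.Series:
        s = s.reindex(idx)
        return pd.Series(np.where(s.isna(), False, s).astype(bool), index=idx)

    any_flag = as_bool(npg_mutated) | as_bool(hla_loh) | as_bool(immunoedited)
    return any_flag.map({True: "IR", False: "nIR"}).rename("ir_status")


def group_by_tnb_ir(
    tnb: pd.Series, ir_status: pd.Series, tnb_cut: float | None = None
) -> pd.Series:
    """Four-way grouping TNB-high/low x IR/nIR (cut defaults to median)."""
    cut = float(tnb.median()) if tnb_cut is None else tnb_cut
    high = tnb > cut
    return pd.Series(
        np.where(high, "TNB-high", "TNB-low"), index=tnb.index
    ) + "/" + ir_status.reindex(tnb.index).astype(str)
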