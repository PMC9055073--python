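"""Variant hard filters, tumor mutational burden, and hypermutation gating.

TMB is the number of qualifying somatic mutations per megabase of
interrogated exome.  Qualifying mutations are restricted to eight
functional classes (frameshift/in-frame indels, missense, nonsense,
nonstop, splice site), with common variants removed when either the
1000 Genomes or ExAC population allele frequency exceeds 0.05 (strictly).
Samples at TMB >= 10 muts/Mb are flagged hypermutated; hypermutation is
then attributed to MSI-H and/or POLE proofreading mutations, leaving an
unexplained remainder.

Comparison operators mirror the published wording exactly: the hard
filters and the hypermutation gate are inclusive (>=); the population-MAF
removal is strict (>).
"""

from __future__ import annotations

import pandas as pd

from .config import AnalysisConfig

#: Functional classes counted toward TMB (exact, case-sensitive spellings).
TMB_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
    }
)


def apply_variant_filters(
    table: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Keep variants with VAF >= 8%, depth >= 8 and >= 2 supporting reads.

    All three boundaries are inclusive.  Row order is preserved; the
    filter is idempotent.
    """
    cfg = config or AnalysisConfig()
    keep = (
        (table["vaf"] >= cfg.vaf_min)
        & (table["depth"] >= cfg.depth_min)
        & (table["alt_reads"] >= cfg.altreads_min)
    )
    return table.loc[keep]


def qualifying_mask(table: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.Series:
    """Boolean mask of TMB-qualifying mutations (class list + rarity)."""
    cfg = config or AnalysisConfig()
    common = (table["pop_af_1000g"] > cfg.pop_af_max) | (
        table["pop_af_exac"] > cfg.pop_af_max
    )
    return table["func_class"].isin(TMB_CLASSES) & ~common


def compute_tmb(
    table: pd.DataFrame,
    panel_size_mb: float | None = None,
    config: AnalysisConfig | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample TMB from a hard-filtered mutation table.

    Parameters
    ----------
    table
        Mutation table (already hard-filtered).
    panel_size_mb
        Interrogated exome size in Mb (the TMB denominator); defaults to
        the config value.
    samples
        Optional full sample list so that samples without any qualifying
        mutation appear with TMB 0.

    Returns
    -------
    DataFrame with columns ``sample_id, n_qualifying, tmb, hypermutated``.
    """
    cfg = config or AnalysisConfig()
    mb = panel_size_mb if panel_size_mb is not None else cfg.panel_size_mb
    if mb <= 0:
        raise ValueError("panel size must be positive")
    counts = (
        table.loc[qualifying_mask(table, cfg), "sample_id"]
        .value_counts()
        .rename("n_qualifying")
    )
    index = pd.Index(
        samples if samples is not None else sorted(table["sample_id"].unique()),
        name="sample_id",
    )
    out = counts.reindex(index, fill_value=0).reset_index()
    out["tmb"] = out["n_qualifying"] / mb
    out["hypermutated"] = classify_hypermutated(out["tmb"], cfg.tmb_threshold)
    return out


def classify_hypermutated(tmb: pd.Series, threshold: float = 10.0) -> pd.Series:
    """Hypermutated iff TMB >= threshold (inclusive boundary)."""
    return tmb >= threshold


def explain_hypermutation(
    hm_flags: pd.Series, msi_flags: pd.Series, pole_flags: pd.Series
) -> dict[str, int]:
    """Partition hypermutated samples by MSI-H / POLE attribution.

    All three series must share a sample_id index.  Returns disjoint
    counts ``{msi_only, pole_only, both, unexplained}`` summing to the
    number of hypermutated samples.
    """
    hm = hm_flags.astype(bool)
    msi = msi_flags.reindex(hm.index).astype(bool)
    pole = pole_flags.reindex(hm.index).astype(bool)
    return {
        "msi_only": int((hm & msi & ~pole).sum()),
        "pole_only": int((hm & ~msi & pole).sum()),
        "both": int((hm & msi & pole).sum()),
        "unexplained": int((hm & ~msi & ~pole).sum()),
    }


def summarize_cohort(
    clinical: pd.DataFrame,
    flags: pd.Series,
    variables: list[str] = ("stage", "grade", "site", "msi_high"),
) -> pd.DataFrame:
    """Stratified count/percentage table (overall plus flag strata).

    Percentages are rounded half-up to one decimal, matching the usual
    cohort-table presentation.
    """
    clin = clinical.set_index("sample_id")
    strata = {
        "all": clin,
        "flagged": clin.loc[flags.reindex(clin.index).fillna(False).astype(bool)],
        "unflagged": clin.loc[~flags.reindex(clin.index).fillna(False).astype(bool)],
    }
    rows = []
    for stratum, sub in strata.items():
        for var in variables:
            counts = sub[var].value_counts()
            total = int(counts.sum())
            for level, n in counts.items():
                pct = _round_half_up(100.0 * n / total, 1) if total else 0.0
                rows.append((stratum, var, str(level), int(n), pct))
    return pd.DataFrame(
        rows, columns=["stratum", "variable", "level", "count", "percent"]
    )


def _round_half_up(x: float, digits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
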