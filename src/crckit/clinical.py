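"""Pathway rollups, driver-gene consensus, survival and association tests.

Covers the cohort-level statistics around the genomic pipeline: rolling
per-gene alterations up to pathway oncogenic/VUS/wild-type status,
aggregating significantly-mutated-gene calls across tools (high
confidence = found by at least two tools), Kaplan-Meier / log-rank
comparisons, covariate-adjusted Cox proportional hazards, and the
pairwise clinical-molecular association matrix with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests


@dataclass
class PathwayDefinition:
    name: str
    genes: dict[str, str] = field(default_factory=dict)  # gene -> role

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no member genes")


def rollup_pathway_status(
    alterations: pd.DataFrame,
    pathways: list[PathwayDefinition],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per sample x pathway status with precedence oncogenic > vus > wt.

    ``alterations`` needs columns sample_id, gene, oncogenicity (in
    {oncogenic, vus, unknown}); both mutations and CNV events qualify.
    ``unknown`` oncogenicity counts as VUS.  Genes outside every pathway
    are ignored.  Adding an oncogenic alteration can only upgrade a
    status (monotone).
    """
    if samples is None:
        samples = sorted(alterations["sample_id"].unique())
    gene_to_pathways: dict[str, list[str]] = {}
    for pw in pathways:
        for g in pw.genes:
            gene_to_pathways.setdefault(g, []).append(pw.name)
    rows = {}
    for s in samples:
        rows[s] = {pw.name: "wt" for pw in pathways}
    rank = {"wt": 0, "vus": 1, "oncogenic": 2}
    for _, rec in alterations.iterrows():
        hit = gene_to_pathways.get(rec["gene"])
        if hit is None or rec["sample_id"] not in rows:
            continue
        level = "oncogenic" if rec["oncogenicity"] == "oncogenic" else "vus"
        for pw_name in hit:
            if rank[level] > rank[rows[rec["sample_id"]][pw_name]]:
                rows[rec["sample_id"]][pw_name] = level
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")
    return out


def smg_consensus(
    tool_lists: dict[str, list[str]], min_tools: int = 2
) -> pd.DataFrame:
    """High-confidence significantly mutated genes by multi-tool consensus.

    A gene is kept when at least ``min_tools`` distinct tools report it
    (duplicates within one tool's list are ignored).  Returns a frame
    with gene, n_tools and the supporting tool names.
    """
    if len(tool_lists) < 2:
        raise ValueError("need lists from at least 2 tools")
    support: dict[str, set[str]] = {}
    for tool, genes in tool_lists.items():
        for g in set(genes):
            support.setdefault(g, set()).add(tool)
    rows = [
        (g, len(tools), ",".join(sorted(tools)))
        for g, tools in sorted(support.items())
        if len(tools) >= min_tools
    ]
    return pd.DataFrame(rows, columns=["gene", "n_tools", "tools"])


def km_logrank(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> dict:
    """Kaplan-Meier per group plus the multivariate log-rank test.

    Returns per-group n / events / median survival, the log-rank
    chi-square statistic and its p-value, and the fitted KM estimators.
    All-censored groups get a NaN median (flagged).
    """
    groups = groups.astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("log-rank comparison needs at least 2 groups")
    per_group = {}
    fitters = {}
    for g in levels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=g)
        per_group[g] = {
            "n": int(mask.sum()),
            "events": int(events[mask].sum()),
            "median": float(kmf.median_survival_time_),
            "all_censored": bool(events[mask].sum() == 0),
        }
        fitters[g] = kmf
    res = multivariate_logrank_test(times, groups, events)
    return {
        "groups": per_group,
        "logrank_stat": float(res.test_statistic),
        "logrank_p": float(res.p_value),
        "fitters": fitters,
    }


def cox_adjusted(
    df: pd.DataFrame,
    exposure: str,
    covariates: tuple[str, ...] = ("tmb", "stage", "grade"),
    time_col: str = "os_months",
    event_col: str = "os_event",
) -> pd.DataFrame:
    """Covariate-adjusted Cox proportional-hazards fit (Efron ties).

    Categorical covariates (object/category dtype) are expanded to
    indicator terms against their first level.  Rows with missing values
    are dropped (count reported in ``df.attrs['n_dropped']``).  Returns
    the per-term table: hazard ratio, 95% Wald CI, p.
    """
    cols = [time_col, event_col, exposure, *covariates]
    data = df[cols].copy()
    n0 = len(data)
    data = data.dropna()
    if data[exposure].nunique() <= 1:
        raise ValueError(f"exposure {exposure!r} is constant; HR undefined")
    model_df = pd.get_dummies(
        data, columns=[c for c in data.columns if data[c].dtype == object or str(data[c].dtype) == "category"],
        drop_first=True, dtype=float,
    )
    model_df[event_col] = model_df[event_col].astype(bool)
    cph = CoxPHFitter()
    cph.fit(model_df, duration_col=time_col, event_col=event_col)
    out = cph.summary[["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]].copy()
    out.columns = ["hr", "ci_lower", "ci_upper", "p"]
    out.attrs["n_dropped"] = n0 - len(data)
    out.attrs["n_used"] = len(data)
    return out


def association_network(
    table: pd.DataFrame,
    categorical: list[str],
    continuous: list[str] = (),
) -> pd.DataFrame:
    """Pairwise association tests across clinical/molecular variables.

    Categorical x categorical: chi-square (Yates-corrected for 2x2), or
    Fisher's exact when any expected cell of a 2x2 is below 5.
    Continuous x binary categorical: two-sided t-test.  Constant
    variables are skipped (flagged rows with NaN p).  BH-adjusted
    p-values and -log10 p are reported alongside.
    """
    rows = []
    vars_all = [(v, "cat") for v in categorical] + [(v, "cont") for v in continuous]
    for i, (v1, t1) in enumerate(vars_all):
        for v2, t2 in vars_all[i + 1:]:
            sub = table[[v1, v2]].dropna()
            if sub[v1].nunique() <= 1 or sub[v2].nunique() <= 1:
                rows.append((v1, v2, "skipped", np.nan, np.nan))
                continue
            if t1 == "cat" and t2 == "cat":
                test, stat, p = _cat_cat_test(sub[v1], sub[v2])
            elif t1 == "cont" and t2 == "cont":
                res = scipy.stats.pearsonr(sub[v1], sub[v2])
                test, stat, p = "pearson", float(res.statistic), float(res.pvalue)
            else:
                cont_v, cat_v = (v1, v2) if t1 == "cont" else (v2, v1)
                levels = sub[cat_v].unique()
                if len(levels) != 2:
                    rows.append((v1, v2, "skipped", np.nan, np.nan))
                    continue
                a = sub.loc[sub[cat_v] == levels[0], cont_v]
                b = sub.loc[sub[cat_v] == levels[1], cont_v]
                res = scipy.stats.ttest_ind(a, b)
                test, stat, p = "t-test", float(res.statistic), float(res.pvalue)
            rows.append((v1, v2, test, stat, p))
    out = pd.DataFrame(rows, columns=["var1", "var2", "test", "statistic", "p"])
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["neglog10_p"] = -np.log10(out["p"].clip(lower=1e-300))
    return out


def _cat_cat_test(a: pd.Series, b: pd.Series) -> tuple[str, float, float]:
    ct = pd.crosstab(a, b).to_numpy()
    if ct.shape == (2, 2):
        expected = scipy.stats.contingency.expected_freq(ct)
        if (expected < 5).any():
            stat, p = scipy.stats.fisher_exact(ct)
            return "fisher", float(stat), float(p)
        chi2, p, _, _ = scipy.stats.chi2_contingency(ct, correction=True)
        return "chi2_yates", float(chi2), float(p)
    chi2, p, _, _ = scipy.stats.chi2_contingency(ct, correction=False)
    return "chi2", float(chi2), float(p)
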