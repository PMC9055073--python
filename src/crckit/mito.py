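"""Mitochondrial DNA copy-number proxy (mScore) and qPCR validation path.

The mScore corrects the mitochondrial-to-nuclear mapped-read ratio for
tumor purity and average ploidy:

    R = (purity * ploidy + (1 - purity) * 2) / 2
    m = (r_m / r_n) * R

so that, for identically processed samples, a higher m means more mtDNA
copies.  Somatic MT variants are filtered against the rCRS blacklist
{310, 523, 524, 3107} (homopolymer/placeholder positions prone to
misalignment).  The cohort is split into mScore-high (top 10% by rank)
versus mScore-low; an optional log-rank scan over decile candidates
implements an explicit best-cutoff strategy.  qPCR measurements are
converted with the 2^-ΔΔCt method and the WES-scale cutoff is
transferred to the qPCR scale by ordinary least squares on paired
samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from lifelines.statistics import multivariate_logrank_test

MT_BLACKLIST = frozenset({310, 523, 524, 3107})
MT_GENOME_LENGTH = 16569


def purity_ploidy_factor(purity, ploidy):
    """Corrective factor R = (purity*ploidy + (1-purity)*2) / 2.

    Accepts scalars or arrays.  R = 1 for any purity when ploidy = 2,
    and R -> 1 as purity -> 0.
    """
    purity = np.asarray(purity, dtype=float)
    ploidy = np.asarray(ploidy, dtype=float)
    if np.any((purity <= 0) | (purity > 1)):
        raise ValueError("purity must lie in (0, 1]")
    if np.any(ploidy <= 0):
        raise ValueError("ploidy must be positive")
    r = (purity * ploidy + (1.0 - purity) * 2.0) / 2.0
    return float(r) if r.ndim == 0 else r


def compute_mscore(r_m, r_n, R):
    """m = (r_m / r_n) * R; invariant to uniform read-count scaling."""
    r_m = np.asarray(r_m, dtype=float)
    r_n = np.asarray(r_n, dtype=float)
    if np.any(r_n <= 0):
        raise ValueError("nuclear read count must be positive")
    if np.any(r_m < 0):
        raise ValueError("MT read count must be non-negative")
    m = (r_m / r_n) * np.asarray(R, dtype=float)
    return float(m) if m.ndim == 0 else m


def mito_profiles(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorized R and mScore computation over a counts table.

    ``counts`` columns: sample_id, r_m, r_n, purity, ploidy.  Returns the
    table with added ``R`` and ``mscore`` columns.
    """
    out = counts.copy()
    out["R"] = purity_ploidy_factor(out["purity"].to_numpy(), out["ploidy"].to_numpy())
    out["mscore"] = compute_mscore(out["r_m"].to_numpy(), out["r_n"].to_numpy(), out["R"].to_numpy())
    return out


def filter_mt_blacklist(
    variants: pd.DataFrame, blacklist: frozenset[int] = MT_BLACKLIST
) -> pd.DataFrame:
    """Drop MT variants at the blacklisted rCRS positions; keep the rest."""
    if variants.empty:
        return variants
    pos = variants["pos"].astype(int)
    if ((pos < 1) | (pos > MT_GENOME_LENGTH)).any():
        raise ValueError(f"MT positions must lie in [1, {MT_GENOME_LENGTH}] (rCRS)")
    return variants.loc[~pos.isin(blacklist)]


def split_by_mscore(
    mscores: pd.Series,
    survival: pd.DataFrame | None = None,
    top_fraction: float = 0.10,
    strategy: str = "top_fraction",
) -> tuple[pd.Series, float]:
    """Split the cohort into mScore-high vs mScore-low.

    Default strategy: high = the top ``top_fraction`` of samples by rank
    (ties broken by sample id, descending score first), i.e. strictly
    above the empirical (1 - top_fraction) quantile when scores are
    distinct.  Strategy ``"scan"`` instead picks the decile-candidate
    cutoff maximizing the log-rank statistic of high vs low overall
    survival, requiring each group to hold at least 10% of the cohort
    (``survival`` must then provide os_months/os_event indexed like
    ``mscores``).

    Returns (groups, cutoff) where groups maps sample -> "high"/"low"
    and the cutoff is the smallest high-group score (NaN when no split).
    """
    if len(mscores) < 20:
        raise ValueError("need at least 20 samples to split")
    if mscores.nunique() == 1:
        warnings.warn("all mScores equal; no split possible")
        return pd.Series("low", index=mscores.index, name="risk_group"), float("nan")
    if strategy == "top_fraction":
        n_high = int(round(len(mscores) * top_fraction))
        order = sorted(mscores.items(), key=lambda kv: (-kv[1], kv[0]))
        high_ids = {k for k, _ in order[:n_high]}
        cutoff = min(mscores[s] for s in high_ids) if high_ids else float("nan")
    elif strategy == "scan":
        if survival is None:
            raise ValueError("'scan' strategy needs survival data")
        candidates = mscores.quantile(np.arange(0.1, 1.0, 0.1)).unique()
        best_stat, cutoff, high_ids = -np.inf, float("nan"), set()
        for cand in candidates:
            hi = mscores > cand
            frac = hi.mean()
            if not (0.1 <= frac <= 0.9):
                continue
            res = multivariate_logrank_test(
                survival.loc[mscores.index, "os_months"],
                hi.astype(int),
                survival.loc[mscores.index, "os_event"],
            )
            if res.test_statistic > best_stat:
                best_stat = res.test_statistic
                cutoff = float(mscores[hi].min())
                high_ids = set(mscores.index[hi])
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    groups = pd.Series(
        ["high" if s in high_ids else "low" for s in mscores.index],
        index=mscores.index,
        name="risk_group",
    )
    return groups, float(cutoff)


def qpcr_relative_copies(
    ct: pd.DataFrame, reference_sample: str | None = None
) -> pd.DataFrame:
    """2^-ΔΔCt relative quantification.

    ΔCt = ct_dloop - ct_control per sample; ΔΔCt relative to the
    reference sample (default: the sample with the median ΔCt, a neutral
    calibrator).  Adds ``delta_ct`` and ``relative_copies`` columns.
    """
    out = ct.copy().set_index("sample_id") if "sample_id" in ct.columns else ct.copy()
    if not np.isfinite(out[["ct_control", "ct_dloop"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    out["delta_ct"] = out["ct_dloop"] - out["ct_control"]
    if reference_sample is None:
        med = out["delta_ct"].sort_values()
        reference_sample = med.index[(len(med) - 1) // 2]
    if reference_sample not in out.index:
        raise ValueError(f"reference sample {reference_sample!r} not in Ct table")
    ddct = out["delta_ct"] - out.loc[reference_sample, "delta_ct"]
    out["relative_copies"] = 2.0 ** (-ddct)
    return out.reset_index()


def transfer_cutoff(
    wes_mscores: pd.Series, qpcr_values: pd.Series, wes_cutoff: float
) -> dict[str, float]:
    """Map a WES-scale mScore cutoff onto the qPCR scale by OLS.

    Regresses the paired qPCR values on the WES mScores; the transferred
    cutoff is the fitted value at ``wes_cutoff``.  Returns slope,
    intercept, Pearson r and the qPCR cutoff.
    """
    paired = pd.concat([wes_mscores.rename("wes"), qpcr_values.rename("qpcr")], axis=1).dropna()
    if len(paired) < 10:
        raise ValueError("need at least 10 paired samples")
    if paired["wes"].nunique() == 1:
        raise ValueError("WES mScores have zero variance")
    res = scipy.stats.linregress(paired["wes"], paired["qpcr"])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "pearson_r": float(res.rvalue),
        "qpcr_cutoff": float(res.intercept + res.slope * wes_cutoff),
        "n_pairs": int(len(paired)),
    }
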