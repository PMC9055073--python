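"""End-to-end orchestration of the analysis stages.

Runs hard filtering, TMB/hypermutation gating, signature refitting,
consensus-NMF subtyping, immunoediting/IR calling and mScore computation
on one cohort's input tables, returning a bundle of per-sample result
frames suitable for :func:`crckit.io.write_results`.
"""

from __future__ import annotations

import pandas as pd

from . import burden, immuno, mito, signatures, subtyping
from .config import AnalysisConfig
from .simulate import SimulatedCohort


def run_pipeline(
    cohort: SimulatedCohort,
    reference: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Full genomic-subtyping pipeline on in-memory cohort tables."""
    cfg = config or AnalysisConfig()
    samples = cohort.samples

    filtered = burden.apply_variant_filters(cohort.mutations, cfg)
    tmb = burden.compute_tmb(filtered, config=cfg, samples=samples)
    hm = tmb.set_index("sample_id")["hypermutated"]

    catalog, _ = signatures.tabulate_contexts(filtered, samples=samples)
    exposures, status = signatures.fit_exposures_lasso(
        catalog,
        reference,
        min_snvs=cfg.min_snvs_signature,
        random_state=cfg.random_seed,
    )
    fractions = signatures.exposure_fractions(exposures)

    feature = subtyping.build_feature_matrix(fractions, cohort.lesions, hm)
    est = subtyping.consensus_nmf(
        feature,
        k_range=range(cfg.nmf_k_min, cfg.nmf_k_max + 1),
        n_runs=cfg.nmf_runs,
        seed=cfg.random_seed,
        k_override=cfg.nmf_k_override,
    )
    labels = est.labels_per_k_[3 if 3 in est.labels_per_k_ else est.k_]
    subtypes = subtyping.assign_subtypes(labels, hm, cohort.lesions, feature_matrix=feature)

    profiles = immuno.immunoediting_score(
        filtered, min_nonsilent=cfg.min_nonsilent_rates, z_cut=cfg.immunoedit_z_cut
    )
    loh = immuno.classify_hla_loh(
        cohort.hla_calls, cfg.hla_p_cut, cfg.hla_cn_cut, cfg.hla_ci_cut
    )
    npg = (
        cohort.truth.set_index("sample_id")["npg_mutated"]
        if "npg_mutated" in getattr(cohort.truth, "columns", [])
        else pd.Series(False, index=profiles.index)
    )
    profiles["hla_loh"] = loh["hla_loh"].reindex(profiles.index)
    profiles["ir_status"] = immuno.classify_immunogenicity_reduction(
        npg.reindex(profiles.index), profiles["hla_loh"], profiles["immunoedited"]
    )

    mscores = mito.mito_profiles(cohort.mito_counts)
    groups, cutoff = mito.split_by_mscore(
        mscores.set_index("sample_id")["mscore"],
        top_fraction=cfg.mscore_top_fraction,
    )
    mscores["risk_group"] = groups.reindex(mscores["sample_id"]).to_numpy()
    mscores.attrs["mscore_cutoff"] = cutoff

    return {
        "tmb": tmb,
        "exposures": exposures.reset_index(),
        "signature_status": status.reset_index().rename(columns={"index": "sample_id"}),
        "subtypes": subtypes,
        "immuno": profiles.reset_index(),
        "mito": mscores,
    }
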