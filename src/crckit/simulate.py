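"""Synthetic CRC-like cohort generator.

Builds cohorts with the statistical structure the analysis pipeline
assumes — per-sample mutation catalogs drawn from subtype-specific
signature mixtures, cluster-structured copy-number lesion matrices,
purity/ploidy, mitochondrial read counts, HLA allele calls, neoantigen
flags, and subtype-dependent exponential survival — so every downstream
stage can be exercised and validated without access to patient data.

Randomness is hierarchical: one global seed spawns an independent
substream per sample, so enlarging a cohort never perturbs the samples
already generated.

``fixture_from_counts`` is the deterministic counterpart: it emits a
minimal cohort whose boolean flag marginals (hypermutated, MSI-H, POLE,
right-sided, MT-variant-bearing) match a requested count specification
exactly, with numeric fields filled deterministically consistent with
the flags (e.g. TMB spread over [10, 50] iff hypermutated).  Printed
cohort tables from a publication can thereby be replayed as inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import CONTEXTS_96, synthetic_signature_reference

SUBTYPE_ORDER = ("HM", "CIN-HR", "CIN-LR", "GS")

_DEFAULT_MIXTURES = {
    # weights over the 6 synthetic reference signatures
    "HM": (0.35, 0.05, 0.0, 0.0, 0.6, 0.0),
    "CIN-HR": (0.3, 0.7, 0.0, 0.0, 0.0, 0.0),
    "CIN-LR": (0.3, 0.0, 0.7, 0.0, 0.0, 0.0),
    "GS": (0.3, 0.0, 0.0, 0.7, 0.0, 0.0),
}

_DEFAULT_MUTS = {  # log-normal (median, sigma) of mutation counts
    "HM": (600.0, 0.25),
    "CIN-HR": (150.0, 0.35),
    "CIN-LR": (120.0, 0.35),
    "GS": (80.0, 0.35),
}

_DEFAULT_AMP10Q = {"HM": 0.10, "CIN-HR": 0.70, "CIN-LR": 0.08, "GS": 0.05}
# Recurrent lesions are differentially altered between clusters: the two
# CIN clusters are each enriched for a distinct half of the background
# lesions, the genome-stable cluster carries almost none.
_DEFAULT_BG_LESION = {
    "HM": [0.15] * 10,
    "CIN-HR": [0.75] * 5 + [0.15] * 5,
    "CIN-LR": [0.15] * 5 + [0.75] * 5,
    "GS": [0.06] * 10,
}
_DEFAULT_SURV_LOGHR = {"HM": -0.69, "CIN-HR": 0.69, "CIN-LR": 0.0, "GS": 0.0}

_BACKGROUND_LESIONS = [
    ("amp", "8q24.21"), ("amp", "13q12.2"), ("amp", "20q13.12"),
    ("del", "17p12"), ("del", "18q21.2"), ("del", "8p21.2"),
    ("amp", "7p11.2"), ("del", "4q22.1"), ("amp", "6p21.1"), ("del", "1p36.11"),
]

_GENES = [
    "APC", "TP53", "KRAS", "PIK3CA", "SMAD4", "FBXW7", "BRAF", "CTNNB1",
    "RB1", "CCND1", "SMAD2", "ACVR2A", "MYC", "PTEN", "ERBB2", "POLE",
]


@dataclass
class CohortSimConfig:
    """Study-condition parameters of the simulator.

    Defaults emulate the cohort structure the pipeline targets: ~7%
    hypermutated samples, three non-hypermutated genomic clusters with
    distinct signature mixtures and lesion profiles, 10q11.21
    amplification enriched in the high-risk CIN cluster, mtDNA score
    with a log-HR of log(1.84) for the top decile, and exponential
    survival with independent censoring.
    """

    n_samples: int = 300
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: {"HM": 0.07, "CIN-HR": 0.31, "CIN-LR": 0.31, "GS": 0.31}
    )
    reference: pd.DataFrame | None = None  # default: synthetic 96x6
    signature_mixtures: dict[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURES)
    )
    mutations_per_sample: dict[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_MUTS)
    )
    lesion_amp10q_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMP10Q)
    )
    lesion_background_probs: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_BG_LESION.items()}
    )
    silent_fraction: float = 0.25  # 1:3 silent:non-silent odds
    neoantigen_rate_per_nonsilent: float = 0.15
    oncogenic_fraction: float = 0.1
    common_variant_fraction: float = 0.01
    purity_beta: tuple[float, float] = (6.0, 2.5)
    ploidy_weights: dict[float, float] = field(
        default_factory=lambda: {1.5: 0.05, 2.0: 0.45, 2.5: 0.15, 3.0: 0.2, 3.5: 0.1, 4.0: 0.05}
    )
    mean_depth: float = 200.0
    nuclear_reads: float = 5e7
    mscore_log_mean: float = np.log(0.01)
    mscore_log_sd: float = 0.5
    mscore_loghr: float = float(np.log(1.84))
    mt_variant_rate: float = 1.2
    hla_loh_prob: float = 0.10
    hla_missing_prob: float = 0.05
    npg_mut_prob: float = 0.05
    baseline_hazard: float = 0.012  # events per month
    covariate_stage_loghr: float = 0.25
    survival_log_hazards: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SURV_LOGHR)
    )
    censor_rate: float = 0.010  # censoring hazard per month
    admin_censor_months: float = 120.0
    panel_size_mb: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("clustering needs at least 4 samples")
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if self.reference is None:
            self.reference = synthetic_signature_reference(6)
        for name, probs in (
            ("lesion_amp10q_probs", self.lesion_amp10q_probs),
        ):
            for v in probs.values():
                if not 0 <= v <= 1:
                    raise ValueError(f"{name} entries must be probabilities")
        for v in self.lesion_background_probs.values():
            if not all(0 <= p <= 1 for p in v):
                raise ValueError("lesion_background_probs entries must be probabilities")


@dataclass
class SimulatedCohort:
    """All pipeline inputs plus ground truth for one simulated cohort."""

    mutations: pd.DataFrame
    lesions: pd.DataFrame
    clinical: pd.DataFrame
    hla_calls: pd.DataFrame
    mito_counts: pd.DataFrame
    mt_variants: pd.DataFrame
    truth: pd.DataFrame
    config: CohortSimConfig | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.truth["sample_id"])


def _sample_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(i)])


_STAGES = ["I", "II", "III", "IV"]
_SITES = ["ascending", "transverse", "descending", "rectum"]
_GRADES = ["high", "moderately", "low"]


def simulate_cohort(config: CohortSimConfig | None = None) -> SimulatedCohort:
    """Draw a full cohort under ``config`` (deterministic given the seed)."""
    cfg = config or CohortSimConfig()
    ref = cfg.reference
    n = cfg.n_samples
    subtypes = list(cfg.subtype_proportions)
    probs = np.array([cfg.subtype_proportions[s] for s in subtypes])
    head = np.random.default_rng([cfg.seed, 999_999_937])
    assigned = head.choice(len(subtypes), size=n, p=probs)

    mut_rows, lesion_rows, clin_rows, hla_rows = [], [], [], []
    mito_rows, mtvar_rows, truth_rows = [], [], []

    for i in range(n):
        rng = _sample_rng(cfg.seed, i)
        sid = f"S{i:04d}"
        subtype = subtypes[assigned[i]]
        mix = np.asarray(cfg.signature_mixtures[subtype], dtype=float)
        mix = mix / mix.sum()
        context_probs = ref.to_numpy() @ mix

        median, sigma = cfg.mutations_per_sample[subtype]
        n_mut = max(1, int(np.round(rng.lognormal(np.log(median), sigma))))
        purity = float(rng.beta(*cfg.purity_beta))
        purity = min(max(purity, 0.05), 1.0)
        ploidies = np.array(list(cfg.ploidy_weights))
        ploidy = float(rng.choice(ploidies, p=np.array(list(cfg.ploidy_weights.values()))
                                  / sum(cfg.ploidy_weights.values())))

        mut_rows.append(_draw_mutations(rng, sid, n_mut, context_probs, purity, cfg))

        # lesions
        if rng.random() < cfg.lesion_amp10q_probs[subtype]:
            lesion_rows.append((sid, "10q11.21", "amp"))
        p_bg = cfg.lesion_background_probs[subtype]
        for (direction, lesion), p in zip(_BACKGROUND_LESIONS, p_bg):
            if rng.random() < p:
                lesion_rows.append((sid, lesion, direction))

        # mitochondria
        true_m = float(rng.lognormal(cfg.mscore_log_mean, cfg.mscore_log_sd))
        R = (purity * ploidy + (1 - purity) * 2.0) / 2.0
        r_n = float(rng.normal(cfg.nuclear_reads, cfg.nuclear_reads * 0.05))
        r_m = true_m / R * r_n
        mito_rows.append((sid, r_m, r_n, purity, ploidy, true_m))
        for _ in range(rng.poisson(cfg.mt_variant_rate)):
            if rng.random() < 0.15:
                pos = int(rng.choice([310, 523, 524, 3107]))
            else:
                pos = int(rng.integers(1, 16570))
                while pos in (310, 523, 524, 3107):
                    pos = int(rng.integers(1, 16570))
            refb, altb = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
            mtvar_rows.append((sid, pos, refb, altb))

        # HLA
        has_loh = rng.random() < cfg.hla_loh_prob
        loh_locus = rng.choice(["A", "B", "C"]) if has_loh else None
        missing_locus = (
            rng.choice(["A", "B", "C"]) if rng.random() < cfg.hla_missing_prob else None
        )
        for locus in ("A", "B", "C"):
            if locus == missing_locus:
                continue
            if locus == loh_locus:
                p = float(rng.uniform(1e-6, 0.009))
                cn = float(rng.uniform(0.05, 0.45))
                ci = cn + float(rng.uniform(0.01, 0.2))
            else:
                p = float(rng.uniform(0.02, 1.0))
                cn = float(rng.uniform(0.8, 1.3))
                ci = cn + float(rng.uniform(0.1, 0.4))
            hla_rows.append((sid, locus, f"hla_{locus.lower()}_01_01", p, cn, ci))
        npg = rng.random() < cfg.npg_mut_prob

        # clinical + survival
        stage = _STAGES[int(rng.choice(4, p=[0.1, 0.35, 0.3, 0.25]))]
        grade = _GRADES[int(rng.choice(3, p=[0.2, 0.6, 0.2]))]
        site = _SITES[int(rng.choice(4, p=[0.3, 0.1, 0.15, 0.45]))]
        msi_high = subtype == "HM" and rng.random() < 0.64
        pole_mut = subtype == "HM" and rng.random() < 0.37
        loghr = (
            cfg.survival_log_hazards[subtype]
            + cfg.covariate_stage_loghr * (_STAGES.index(stage) - 1)
        )
        # mScore hazard applies to the extreme-copy tail (top decile of
        # the generative log-normal)
        top_cut = float(np.exp(cfg.mscore_log_mean + 1.2816 * cfg.mscore_log_sd))
        if true_m > top_cut:
            loghr += cfg.mscore_loghr
        hazard = cfg.baseline_hazard * np.exp(loghr)
        event_t = float(rng.exponential(1.0 / hazard))
        censor_t = float(rng.exponential(1.0 / cfg.censor_rate)) if cfg.censor_rate > 0 else np.inf
        censor_t = min(censor_t, cfg.admin_censor_months)
        os_months = min(event_t, censor_t)
        os_event = event_t <= censor_t
        clin_rows.append(
            (sid, stage, grade, site, msi_high, pole_mut, os_months, os_event)
        )
        truth_rows.append((sid, subtype, n_mut, purity, ploidy, true_m, npg, has_loh, loghr))

    cohort = SimulatedCohort(
        mutations=pd.concat(mut_rows, ignore_index=True),
        lesions=pd.DataFrame(
            lesion_rows, columns=["sample_id", "lesion_id", "direction"]
        ).assign(called=True),
        clinical=pd.DataFrame(
            clin_rows,
            columns=[
                "sample_id", "stage", "grade", "site", "msi_high",
                "pole_mutant", "os_months", "os_event",
            ],
        ),
        hla_calls=pd.DataFrame(
            hla_rows,
            columns=["sample_id", "locus", "allele", "ai_pvalue", "cn_estimate", "ci_upper"],
        ),
        mito_counts=pd.DataFrame(
            mito_rows, columns=["sample_id", "r_m", "r_n", "purity", "ploidy", "true_mscore"]
        ),
        mt_variants=pd.DataFrame(mtvar_rows, columns=["sample_id", "pos", "ref", "alt"]),
        truth=pd.DataFrame(
            truth_rows,
            columns=[
                "sample_id", "subtype", "n_mutations", "purity", "ploidy",
                "true_mscore", "npg_mutated", "hla_loh", "true_loghr",
            ],
        ),
        config=cfg,
    )
    return cohort


def _draw_mutations(
    rng: np.random.Generator,
    sid: str,
    n_mut: int,
    context_probs: np.ndarray,
    purity: float,
    cfg: CohortSimConfig,
) -> pd.DataFrame:
    ctx_idx = rng.choice(96, size=n_mut, p=context_probs / context_probs.sum())
    contexts = [CONTEXTS_96[j] for j in ctx_idx]
    trinuc = [c[0] + c[2] + c[6] for c in contexts]
    ref = [c[2] for c in contexts]
    alt = [c[4] for c in contexts]
    silent = rng.random(n_mut) < cfg.silent_fraction
    func = np.where(
        silent,
        "Silent",
        np.where(rng.random(n_mut) < 0.9, "Missense_Mutation", "Nonsense_Mutation"),
    )
    neo = np.where(
        ~silent, rng.binomial(1, cfg.neoantigen_rate_per_nonsilent, n_mut), 0
    )
    vaf_true = np.clip(rng.beta(8, 8, n_mut) * purity / 2 * 2, 0.02, 0.95)
    depth = rng.poisson(cfg.mean_depth, n_mut) + 1
    alt_reads = rng.binomial(depth, vaf_true)
    vaf = alt_reads / depth
    common = rng.random(n_mut) < cfg.common_variant_fraction
    onco = np.where(
        rng.random(n_mut) < cfg.oncogenic_fraction, "oncogenic",
        np.where(rng.random(n_mut) < 0.3, "vus", "unknown"),
    )
    return pd.DataFrame(
        {
            "sample_id": sid,
            "gene": rng.choice(_GENES, n_mut),
            "chrom": rng.choice([str(c) for c in range(1, 23)], n_mut),
            "pos": rng.integers(1, 2_000_000, n_mut),
            "ref": ref,
            "alt": alt,
            "func_class": func,
            "vaf": vaf,
            "depth": depth,
            "alt_reads": alt_reads,
            "trinuc_context": trinuc,
            "pop_af_1000g": np.where(common, 0.2, 0.0),
            "pop_af_exac": 0.0,
            "oncogenicity": onco,
            "n_neoantigens": neo,
            "is_silent": silent,
        }
    )


def fixture_from_counts(group_spec: dict[str, int], panel_size_mb: float = 35.0) -> SimulatedCohort:
    """Deterministic minimal cohort with exact flag marginals.

    ``group_spec`` keys (all optional except ``n``):

    - ``n``: group size
    - ``hm``: number of hypermutated samples (TMB spread over [10, 50];
      the rest over [0.5, 9])
    - ``msi``, ``pole``, ``both``: MSI-H / POLE flag counts with their
      overlap (assigned to the earliest samples, overlap first)
    - ``right_sided``: samples with an ascending-colon site (rest rectum)
    - ``mt_variant``: samples retaining >= 1 MT variant after blacklist
      filtering (all other samples carry only blacklisted variants)

    Mutation counts are realized as actual qualifying mutation rows so
    the burden stage reproduces the requested TMB exactly.
    """
    n = int(group_spec.get("n", 0))
    if n == 0:
        empty = pd.DataFrame()
        return SimulatedCohort(*(empty.copy() for _ in range(7)))
    n_hm = int(group_spec.get("hm", 0))
    n_msi = int(group_spec.get("msi", 0))
    n_pole = int(group_spec.get("pole", 0))
    n_both = int(group_spec.get("both", 0))
    for count, name in ((n_hm, "hm"), (n_msi, "msi"), (n_pole, "pole")):
        if count > n or count < 0:
            raise ValueError(f"count {name}={count} outside group size {n}")
    if n_both > min(n_msi, n_pole) or n_msi + n_pole - n_both > n:
        raise ValueError("overlapping counts exceed group size")

    samples = [f"F{i:04d}" for i in range(n)]
    hm = np.zeros(n, dtype=bool)
    hm[:n_hm] = True
    tmb = np.empty(n)
    tmb[:n_hm] = np.linspace(10.0, 50.0, n_hm) if n_hm else []
    tmb[n_hm:] = np.linspace(0.5, 9.0, n - n_hm) if n - n_hm else []

    msi = np.zeros(n, dtype=bool)
    pole = np.zeros(n, dtype=bool)
    msi[:n_both] = True
    pole[:n_both] = True
    msi[n_both : n_both + (n_msi - n_both)] = True
    start = n_both + (n_msi - n_both)
    pole[start : start + (n_pole - n_both)] = True

    n_right = int(group_spec.get("right_sided", 0))
    site = np.where(np.arange(n) < n_right, "ascending", "rectum")

    # qualifying mutation rows realizing the per-sample TMB exactly
    n_mut = np.round(tmb * panel_size_mb).astype(int)
    sid_col = np.repeat(samples, n_mut)
    total = int(n_mut.sum())
    mutations = pd.DataFrame(
        {
            "sample_id": sid_col,
            "gene": "APC",
            "chrom": "5",
            "pos": np.arange(1, total + 1),
            "ref": "C",
            "alt": "T",
            "func_class": "Missense_Mutation",
            "vaf": 0.3,
            "depth": 100,
            "alt_reads": 30,
            "trinuc_context": "ACG",
            "pop_af_1000g": 0.0,
            "pop_af_exac": 0.0,
            "oncogenicity": "unknown",
            "n_neoantigens": 0,
            "is_silent": False,
        }
    )

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "stage": "II",
            "grade": "moderately",
            "site": site,
            "msi_high": msi,
            "pole_mutant": pole,
            "os_months": np.linspace(6.0, 60.0, n),
            "os_event": (np.arange(n) % 2) == 0,
        }
    )

    n_mt = int(group_spec.get("mt_variant", 0))
    mt_rows = []
    for i, sid in enumerate(samples):
        if i < n_mt:
            mt_rows.append((sid, 1000 + i, "A", "G"))
            mt_rows.append((sid, 523, "A", "C"))  # removed by the blacklist
        else:
            mt_rows.append((sid, 310, "T", "C"))
            mt_rows.append((sid, 3107, "G", "A"))
    mt_variants = pd.DataFrame(mt_rows, columns=["sample_id", "pos", "ref", "alt"])

    truth = pd.DataFrame(
        {
            "sample_id": samples,
            "hypermutated": hm,
            "tmb": tmb,
            "msi_high": msi,
            "pole_mutant": pole,
        }
    )
    empty = pd.DataFrame()
    return SimulatedCohort(
        mutations=mutations,
        lesions=empty.copy(),
        clinical=clinical,
        hla_calls=empty.copy(),
        mito_counts=empty.copy(),
        mt_variants=mt_variants,
        truth=truth,
    )


def simulate_qpcr(
    mito_profiles: pd.DataFrame,
    noise_sd: float = 0.0,
    scale: float = 100.0,
    ct_control: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table emulating D-loop quantification of the mScore.

    ΔCt = -log2(mscore * scale) plus Gaussian noise of ``noise_sd``
    cycles; the endogenous-control Ct is fixed, so
    ct_dloop = ct_control + ΔCt.  At zero noise the 2^-ΔΔCt method
    recovers relative mScores exactly, and doubling the mScore lowers
    the D-loop Ct by one cycle.
    """
    m = mito_profiles["mscore"].to_numpy(float)
    if (m <= 0).any():
        raise ValueError("mScores must be positive for qPCR simulation")
    rng = np.random.default_rng(seed)
    delta_ct = -np.log2(m * scale) + rng.normal(0.0, noise_sd, len(m))
    return pd.DataFrame(
        {
            "sample_id": mito_profiles["sample_id"].to_numpy(),
            "ct_control": ct_control,
            "ct_dloop": ct_control + delta_ct,
        }
    )
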