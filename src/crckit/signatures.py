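"""Mutational-signature refitting against a fixed reference catalog.

Per-sample catalogs of the 96 trinucleotide substitution classes are
decomposed as non-negative weighted combinations of known reference
signatures (refitting — no de novo extraction).  The decomposition is an
L1-penalized non-negative least squares on the sample's 96-class
fraction vector, with the penalty chosen by cross-validation over the
contexts; sparsity gives a crisp notion of a signature being "active" in
a sample, which feeds the cohort prevalence rule (keep signatures active
in strictly more than 1% of fitted samples).

Catalogs from exome data can be rescaled to genome-wide trinucleotide
abundances before fitting ("exome2genome" normalization) so exposures are
comparable to genome-derived reference signatures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .reference import CONTEXTS_96, classify_substitution, context_to_trinuc

#: Functional classes whose SNVs enter the 96-context tabulation.
SIGNATURE_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "RNA",
        "Silent",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


def tabulate_contexts(
    table: pd.DataFrame, samples: list[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Count each sample's SNVs into the 96 substitution classes.

    Only single-nucleotide variants in the signature-eligible functional
    classes are tabulated; purine-centered substitutions are folded onto
    the pyrimidine strand.  Records whose context contains a non-ACGT
    base are skipped and counted.

    Returns
    -------
    (catalog, n_skipped)
        ``catalog`` is a samples x 96 integer DataFrame (columns in the
        conventional order); ``n_skipped`` the number of unusable records.
    """
    is_snv = (table["ref"].str.len() == 1) & (table["alt"].str.len() == 1)
    eligible = table.loc[is_snv & table["func_class"].isin(SIGNATURE_CLASSES)]
    skipped = 0
    labels: dict[tuple[str, str], int] = {}
    for sample, trinuc, ref, alt in zip(
        eligible["sample_id"], eligible["trinuc_context"], eligible["ref"], eligible["alt"]
    ):
        try:
            ctx = classify_substitution(trinuc, ref, alt)
        except ValueError:
            skipped += 1
            continue
        labels[(sample, ctx)] = labels.get((sample, ctx), 0) + 1
    index = pd.Index(
        samples if samples is not None else sorted(table["sample_id"].unique()),
        name="sample_id",
    )
    catalog = pd.DataFrame(0, index=index, columns=CONTEXTS_96, dtype=np.int64)
    for (sample, ctx), n in labels.items():
        if sample in catalog.index:
            catalog.loc[sample, ctx] = n
    return catalog, skipped


def normalize_exome2genome(
    catalog: pd.DataFrame, trinuc_abundance_ratio: pd.Series
) -> pd.DataFrame:
    """Rescale a 96-class catalog by genome/exome trinucleotide abundance.

    ``trinuc_abundance_ratio`` maps each of the 32 pyrimidine-centered
    trinucleotides to (genome abundance) / (exome abundance); each of the
    96 bins is multiplied by the ratio of its flanking-context class.
    """
    ratios = trinuc_abundance_ratio.astype(float)
    if (ratios <= 0).any() or not np.isfinite(ratios).all():
        raise ValueError("abundance ratios must be positive and finite")
    per_bin = np.array([ratios[context_to_trinuc(c)] for c in catalog.columns])
    return catalog * per_bin


class LassoSignatureRefitter(TransformerMixin, BaseEstimator):
    """Sparse non-negative refitting of signature exposures.

    For each sample the 96-class fraction vector ``p`` is approximated by
    ``R @ w`` with reference matrix ``R`` (columns sum to 1) and
    non-negative weights ``w``, minimizing
    ``0.5/96 * ||p - R w||^2 + alpha * ||w||_1``.  The penalty ``alpha``
    is selected per sample by K-fold cross-validation over the 96
    contexts on a log-spaced grid, with the one-standard-error rule
    (largest alpha within one SE of the minimum CV error).  Weights are
    rescaled to mutation counts and values below
    ``activity_floor * total`` are set to exactly 0.

    Parameters
    ----------
    reference : DataFrame (96 x K)
        Reference signature matrix; columns are renormalized to sum to 1.
    min_snvs : int, default 20
        Samples with fewer tabulated SNVs are excluded from fitting and
        flagged in ``status_``.
    cv : int, default 5
        Cross-validation folds over contexts.
    n_alphas : int, default 30
        Size of the log-spaced penalty grid.
    alpha_min_ratio : float, default 1e-4
        Smallest grid alpha as a fraction of the data-derived maximum.
    one_se : bool, default True
        Apply the one-standard-error rule (else pick the CV minimum).
    activity_floor : float, default 1e-6
        Exposure floor as a fraction of the sample's total mutations;
        defines "active" for the prevalence rule.
    random_state : int or None
        Seeds the CV fold shuffling.

    Attributes
    ----------
    reference_ : DataFrame
        Column-normalized reference used for fitting.
    status_ : DataFrame
        Per-input-sample fitting status after :meth:`transform`
        (``fitted`` flag and reason).
    alphas_ : Series
        Selected penalty per fitted sample.
    """

    def __init__(
        self,
        reference: pd.DataFrame,
        *,
        min_snvs: int = 20,
        cv: int = 5,
        n_alphas: int = 30,
        alpha_min_ratio: float = 1e-4,
        one_se: bool = True,
        activity_floor: float = 1e-6,
        random_state: int | None = None,
    ) -> None:
        self.reference = reference
        self.min_snvs = min_snvs
        self.cv = cv
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.one_se = one_se
        self.activity_floor = activity_floor
        self.random_state = random_state

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "LassoSignatureRefitter":
        ref = self.reference.astype(float)
        if ref.shape[0] != 96:
            raise ValueError("reference must have 96 context rows")
        sums = ref.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("reference columns must have positive sums")
        self.reference_ = ref / sums
        return self

    def _fit_sample(self, fractions: np.ndarray, rng: np.random.Generator):
        R = self.reference_.to_numpy()
        n = R.shape[0]
        alpha_max = float(np.max(R.T @ fractions) / n)
        alphas = np.geomspace(alpha_max, alpha_max * self.alpha_min_ratio, self.n_alphas)
        folds = KFold(self.cv, shuffle=True, random_state=int(rng.integers(2**31)))
        errs = np.zeros((self.cv, self.n_alphas))
        for f, (tr, te) in enumerate(folds.split(R)):
            for a, alpha in enumerate(alphas):
                w = _nn_lasso(R[tr], fractions[tr], alpha)
                errs[f, a] = np.mean((fractions[te] - R[te] @ w) ** 2)
        mean = errs.mean(axis=0)
        best = int(np.argmin(mean))
        if self.one_se:
            se = errs.std(axis=0, ddof=1)[best] / np.sqrt(self.cv)
            # grid is ordered from strongest to weakest penalty
            best = int(np.nonzero(mean <= mean[best] + se)[0][0])
        alpha = float(alphas[best])
        return _nn_lasso(R, fractions, alpha), alpha

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Fit exposures for each catalog row; returns fitted samples x K."""
        check_is_fitted(self, "reference_")
        rng = np.random.default_rng(self.random_state)
        totals = X.sum(axis=1)
        status = pd.DataFrame(
            {"n_snvs": totals.astype(int), "fitted": False, "reason": ""},
            index=X.index,
        )
        rows = {}
        alphas = {}
        for sample in X.index:
            total = float(totals[sample])
            if total < self.min_snvs:
                status.loc[sample, "reason"] = (
                    "all_zero" if total == 0 else "below_min_snvs"
                )
                continue
            fractions = X.loc[sample].to_numpy(float) / total
            w, alpha = self._fit_sample(fractions, rng)
            exposures = w * total
            exposures[exposures < self.activity_floor * total] = 0.0
            rows[sample] = exposures
            alphas[sample] = alpha
            status.loc[sample, "fitted"] = True
        self.status_ = status
        self.alphas_ = pd.Series(alphas, dtype=float)
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=self.reference_.columns
        ).rename_axis("sample_id")


def _nn_lasso(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    model = Lasso(
        alpha=alpha, positive=True, fit_intercept=False, max_iter=10000, tol=1e-8
    )
    model.fit(X, y)
    return model.coef_


def fit_exposures_lasso(
    catalogs: pd.DataFrame,
    reference: pd.DataFrame,
    *,
    min_snvs: int = 20,
    trinuc_ratio: pd.Series | None = None,
    random_state: int | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper: catalogs -> (exposures, status).

    Applies exome2genome normalization first when ``trinuc_ratio`` is
    given.  The eligibility rule (``min_snvs``) is evaluated on the raw
    SNV counts, before normalization.
    """
    est = LassoSignatureRefitter(
        reference, min_snvs=0 if trinuc_ratio is not None else min_snvs,
        random_state=random_state, **kwargs
    )
    est.fit()
    X = catalogs
    if trinuc_ratio is not None:
        raw_totals = catalogs.sum(axis=1)
        keep = raw_totals >= min_snvs
        X = normalize_exome2genome(catalogs, trinuc_ratio)
        # rescale back to the raw totals so exposures stay on the count scale
        adj_totals = X.sum(axis=1)
        X = X.mul(
            np.where(adj_totals > 0, raw_totals / adj_totals.replace(0, 1), 0.0),
            axis=0,
        )
        X = X.loc[keep]
    exposures = est.transform(X)
    status = est.status_
    if trinuc_ratio is not None:
        status = status.reindex(catalogs.index)
        status["n_snvs"] = catalogs.sum(axis=1).astype(int)
        status["fitted"] = status["fitted"].fillna(False).astype(bool)
        status["reason"] = status["reason"].fillna("below_min_snvs")
    return exposures, status


def exposure_fractions(exposures: pd.DataFrame) -> pd.DataFrame:
    """Per-sample signature contribution fractions (rows sum to 1).

    The compositional view of an exposure matrix — the usual input for
    clustering on signature activity, insensitive to mutation burden.
    All-zero rows stay zero.
    """
    totals = exposures.sum(axis=1)
    return exposures.div(totals.where(totals > 0, 1.0), axis=0)


def filter_signature_prevalence(
    exposures: pd.DataFrame, min_prevalence: float = 0.01
) -> list[str]:
    """Signatures active (> 0 exposure) in strictly more than
    ``min_prevalence`` of fitted samples."""
    if exposures.empty:
        return []
    prevalence = (exposures > 0).mean(axis=0)
    return [s for s in exposures.columns if prevalence[s] > min_prevalence]
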