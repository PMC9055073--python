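"""Consensus-NMF genomic subtyping of non-hypermutated samples.

Hypermutated samples are gated out first (their mutation load would
dominate any factorization) and labelled HM directly.  The remaining
samples are clustered by consensus non-negative matrix factorization of
a concatenated feature matrix — min-max scaled signature exposures plus
binary recurrent-lesion indicators — over a range of ranks K with
repeated random initializations; the co-clustering frequency matrix is
hierarchically clustered to produce final labels, and the cophenetic
correlation of that matrix guides the choice of K.

At K = 3 the three non-HM clusters are named by their genomic character:
the cluster with the lowest overall alteration load is genome-stable
(GS); of the two chromosomal-instability clusters, the one enriched for
10q11.21 amplification is high-risk (CIN-HR) and the other low-risk
(CIN-LR).  External cohorts with predefined GS/CIN/HM labels are mapped
onto the same scheme by splitting CIN on 10q11.21 amplification alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import NMF
from sklearn.utils.validation import check_is_fitted

SUBTYPES = ("HM", "CIN-HR", "CIN-LR", "GS")
AMP_LESION = "10q11.21"


def build_feature_matrix(
    exposures: pd.DataFrame,
    lesion_calls: pd.DataFrame,
    hm_flags: pd.Series,
) -> pd.DataFrame:
    """Concatenate scaled exposures with binary lesion indicators.

    Hypermutated samples are excluded.  Continuous exposure columns are
    min-max scaled to [0, 1]; lesion indicators (one column per
    direction_lesion) pass through as 0/1.  Zero-variance columns are
    dropped.  Samples must appear in the exposure matrix; missing lesion
    data is treated as no calls.
    """
    hm = hm_flags.astype(bool)
    keep = [s for s in exposures.index if not hm.get(s, False)]
    if not keep:
        raise ValueError("no non-hypermutated samples to cluster")
    cont = exposures.loc[keep].astype(float)
    rng_ = cont.max() - cont.min()
    nonconst = rng_ > 0
    cont = (cont.loc[:, nonconst] - cont.loc[:, nonconst].min()) / rng_[nonconst]

    wide = lesion_to_indicator(lesion_calls).reindex(keep).fillna(0).astype(float)
    wide = wide.loc[:, wide.std() > 0]
    mat = pd.concat([cont, wide], axis=1)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 samples for clustering")
    return mat


def lesion_to_indicator(lesion_calls: pd.DataFrame) -> pd.DataFrame:
    """Long lesion calls -> samples x lesion 0/1 indicator matrix."""
    if lesion_calls.empty:
        return pd.DataFrame()
    called = lesion_calls.loc[lesion_calls.get("called", True).astype(bool)].copy()
    called["feature"] = called["direction"] + "_" + called["lesion_id"]
    return (
        called.pivot_table(
            index="sample_id", columns="feature", values="called",
            aggfunc="any", fill_value=False,
        )
        .astype(int)
        .rename_axis(index="sample_id", columns=None)
    )


class ConsensusNMF(ClusterMixin, BaseEstimator):
    """Consensus clustering by repeated non-negative matrix factorization.

    For each rank K in ``k_range``, ``n_runs`` NMF factorizations are run
    from distinct random non-negative initializations (generalized
    Kullback-Leibler loss with multiplicative updates by default, the
    classic consensus-NMF objective; Frobenius available via
    ``beta_loss``).  Each run assigns every sample to its
    dominant basis component; the consensus matrix holds the fraction of
    runs in which two samples co-cluster.  Final labels come from
    average-linkage hierarchical clustering of 1 - consensus cut at K,
    and the cophenetic correlation coefficient of that dendrogram against
    1 - consensus scores each K.

    Attributes (after :meth:`fit`)
    ------------------------------
    consensus_ : dict[int, DataFrame]
        Symmetric consensus matrix per K (diagonal 1, entries i/n_runs).
    labels_per_k_ : dict[int, Series]
        Final integer labels per K.
    cophenetic_ : dict[int, float]
    k_ : int
        Selected rank (argmax cophenetic, ties to the smaller K, or the
        ``k_override`` parameter).
    labels_ : ndarray
        Labels at ``k_``.
    """

    def __init__(
        self,
        k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
        n_runs: int = 10,
        beta_loss: str = "kullback-leibler",
        max_iter: int = 2000,
        tol: float = 1e-6,
        k_override: int | None = None,
        random_state: int | None = None,
    ) -> None:
        self.k_range = k_range
        self.n_runs = n_runs
        self.beta_loss = beta_loss
        self.max_iter = max_iter
        self.tol = tol
        self.k_override = k_override
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "ConsensusNMF":
        mat = np.asarray(X, dtype=float)
        if (mat < 0).any():
            raise ValueError("feature matrix must be non-negative")
        n = mat.shape[0]
        if n < max(self.k_range):
            raise ValueError("fewer samples than the largest K")
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
        rng = np.random.default_rng(self.random_state)
        self.consensus_ = {}
        self.labels_per_k_ = {}
        self.cophenetic_ = {}
        self.n_iter_exhausted_ = 0
        for k in self.k_range:
            co = np.zeros((n, n))
            for _ in range(self.n_runs):
                labels = self._single_run(mat, k, rng)
                co += (labels[:, None] == labels[None, :]).astype(float)
            co /= self.n_runs
            np.fill_diagonal(co, 1.0)
            cons = pd.DataFrame(co, index=index, columns=index)
            dist = ssd.squareform(1.0 - co, checks=False)
            link = sch.linkage(dist, method="average")
            final = sch.fcluster(link, t=k, criterion="maxclust") - 1
            coph = sch.cophenet(link, dist)[0] if n > 2 else 1.0
            self.consensus_[k] = cons
            self.labels_per_k_[k] = pd.Series(final, index=index, name="cluster")
            self.cophenetic_[k] = float(coph) if np.isfinite(coph) else 1.0
        self.k_ = self.select_k()
        self.labels_ = self.labels_per_k_[self.k_].to_numpy()
        return self

    def _single_run(self, mat: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss=self.beta_loss,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=int(rng.integers(2**31)),
        )
        import warnings

        with warnings.catch_warnings():
            # non-convergent runs are still used, per protocol
            warnings.simplefilter("ignore")
            model.fit(mat)
        if model.n_iter_ >= self.max_iter:
            self.n_iter_exhausted_ += 1
        # dominant basis component by cosine similarity: a deterministic
        # function of the sample's own profile, so identical samples
        # always co-cluster even when the factorization is degenerate
        H = model.components_
        Hn = H / np.maximum(np.linalg.norm(H, axis=1, keepdims=True), 1e-12)
        Xn = mat / np.maximum(np.linalg.norm(mat, axis=1, keepdims=True), 1e-12)
        return np.argmax(Xn @ Hn.T, axis=1)

    def select_k(self) -> int:
        """Rank with the highest cophenetic coefficient; ties break low."""
        check_is_fitted(self, "cophenetic_")
        if self.k_override is not None:
            return int(self.k_override)
        best = max(sorted(self.cophenetic_), key=lambda k: (self.cophenetic_[k], -k))
        return int(best)


def consensus_nmf(
    matrix: pd.DataFrame,
    k_range=(2, 3, 4, 5, 6),
    n_runs: int = 10,
    seed: int | None = None,
    k_override: int | None = None,
) -> ConsensusNMF:
    """Fit consensus NMF over ``k_range`` and return the fitted estimator."""
    return ConsensusNMF(
        k_range=tuple(k_range), n_runs=n_runs, k_override=k_override,
        random_state=seed,
    ).fit(matrix)


def select_k(est: ConsensusNMF) -> int:
    return est.select_k()


def assign_subtypes(
    cluster_labels: pd.Series,
    hm_flags: pd.Series,
    lesion_calls: pd.DataFrame,
    feature_matrix: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Name the K=3 non-HM clusters and produce per-sample subtype labels.

    Hypermutated samples get HM.  Among the three clusters: lowest mean
    alteration load (feature-matrix row sums) -> GS; of the remaining
    two, the higher 10q11.21-amplification fraction -> CIN-HR, the other
    CIN-LR.  Naming depends only on these statistics, never on cluster
    indices, so it is invariant to sample order and index permutation.
    """
    clusters = sorted(cluster_labels.unique())
    if len(clusters) != 3:
        raise ValueError(f"expected 3 non-HM clusters, got {len(clusters)}")
    if feature_matrix is None:
        raise ValueError("feature_matrix is required for load-based naming")
    load = feature_matrix.sum(axis=1)
    mean_load = {c: load[cluster_labels.index[cluster_labels == c]].mean() for c in clusters}
    gs = min(clusters, key=lambda c: (mean_load[c], c))
    cin = [c for c in clusters if c != gs]

    amp = amp_10q_flags(lesion_calls)
    frac = {}
    for c in cin:
        members = cluster_labels.index[cluster_labels == c]
        frac[c] = amp.reindex(members, fill_value=False).astype(bool).mean()
    hr = max(cin, key=lambda c: (frac[c], -c))
    names = {gs: "GS", hr: "CIN-HR", [c for c in cin if c != hr][0]: "CIN-LR"}

    hm = hm_flags.astype(bool)
    rows = []
    for s in hm.index:
        if hm[s]:
            rows.append((s, "HM"))
        elif s in cluster_labels.index:
            rows.append((s, names[cluster_labels[s]]))
    return pd.DataFrame(rows, columns=["sample_id", "subtype"])


def amp_10q_flags(lesion_calls: pd.DataFrame, lesion_id: str = AMP_LESION) -> pd.Series:
    """Per-sample flag: carries an amplification call at 10q11.21."""
    if lesion_calls.empty:
        return pd.Series(dtype=bool)
    hit = (
        (lesion_calls["direction"] == "amp")
        & (lesion_calls["lesion_id"].str.startswith(lesion_id))
        & lesion_calls.get("called", True).astype(bool)
    )
    return lesion_calls.loc[hit].groupby("sample_id").size() > 0


def map_external_cohort(
    predefined: pd.Series, amp_flags: pd.Series
) -> pd.DataFrame:
    """Refine external GS/CIN/HM labels with the 10q11.21 rule.

    CIN with amplification -> CIN-HR; CIN without -> CIN-LR; GS and HM
    pass through unchanged.
    """
    out = []
    amp = amp_flags.astype(bool)
    for s, label in predefined.items():
        if label == "CIN":
            out.append((s, "CIN-HR" if amp.get(s, False) else "CIN-LR"))
        elif label in ("GS", "HM"):
            out.append((s, label))
        else:
            raise ValueError(f"unknown predefined label {label!r} for sample {s}")
    return pd.DataFrame(out, columns=["sample_id", "subtype"])
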