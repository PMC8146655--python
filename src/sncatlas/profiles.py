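"""Spatiotemporal expression profiling.

Features (typically the union of differentially expressed sncRNAs) are
reduced to five-point region profiles — replicates averaged per region,
each row centered and scaled — and clustered with multi-start Lloyd
K-means.  The number of clusters is chosen with the elbow statistic
betweenss/totss ("information retained"): the smallest k that retains
at least the information threshold with a marginal gain below the gain
threshold.  Between-class analysis (BCA) of samples quantifies how much
expression inertia the region labels explain; it is computed directly
from the inertia definitions (between-class inertia over total inertia
after feature-wise centering) so the ratio is testable in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .pirna import length_distribution, mtdna_perfect_matches, u1_a10_summary
from .references import REGIONS


def average_and_standardize(
    cm, feature_subset: pd.Index | Sequence[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Region-profile matrix: replicate means, then per-row z-scores.

    Rows with zero variance across regions carry no profile shape and
    are dropped; returns ``(profile_matrix, dropped_features)``.
    """
    means = cm.region_means()
    if feature_subset is not None:
        means = means.loc[list(feature_subset)]
    sd = means.std(axis=1, ddof=0)
    dropped = list(means.index[sd == 0])
    kept = means[sd > 0]
    X = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return X, dropped


@dataclass
class ClusterModel:
    """A fitted K-means solution with its sum-of-squares decomposition."""

    k: int
    assignments: pd.Series
    centroids: pd.DataFrame
    totss: float
    withinss: float
    betweenss: float
    n_starts: int
    max_iter: int
    seed: int

    @property
    def ratio(self) -> float:
        """betweenss/totss, the elbow 'information retained'; defined as
        0 for degenerate data with zero total sum of squares."""
        return self.betweenss / self.totss if self.totss > 0 else 0.0


def kmeans_lloyd(
    X: pd.DataFrame,
    k: int,
    n_starts: int = 100,
    max_iter: int = 1000,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-``n_starts`` Lloyd K-means with random initialization.

    Deterministic for fixed (data, k, n_starts, seed).  Centroids are
    recomputed as the means of the final assignments, so the Huygens
    identity betweenss + withinss = totss holds exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of rows ({len(X)})")
    A = np.ascontiguousarray(X.to_numpy(dtype=float))
    grand = A.mean(axis=0)
    totss = float(((A - grand) ** 2).sum())
    if totss == 0.0 or k == 1:
        labels = np.zeros(len(A), dtype=int)
        centroids = grand[None, :].repeat(1, axis=0)
        withinss = totss
    else:
        km = KMeans(
            n_clusters=k, init="random", n_init=n_starts, max_iter=max_iter,
            algorithm="lloyd", random_state=seed % (2**32),
        ).fit(A)
        labels = km.labels_.astype(int)
        centroids = np.vstack([A[labels == g].mean(axis=0) for g in range(k)])
        withinss = float(
            sum(((A[labels == g] - centroids[g]) ** 2).sum() for g in range(k))
        )
    betweenss = totss - withinss
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=X.index, name="cluster"),
        centroids=pd.DataFrame(centroids, columns=X.columns),
        totss=totss, withinss=withinss, betweenss=betweenss,
        n_starts=n_starts, max_iter=max_iter, seed=seed,
    )


def select_k_elbow(
    X: pd.DataFrame,
    k_range: Sequence[int] = range(2, 26),
    info_threshold: float = 0.90,
    gain_threshold: float = 0.01,
    n_starts: int = 100,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.Series, int | None, dict[int, ClusterModel]]:
    """Elbow scan: ratio trace over k plus the chosen k.

    Chosen k is the smallest k with ratio >= ``info_threshold`` whose
    marginal gain to k+1 is below ``gain_threshold`` ("no significant
    improvement"); ``None`` when no k qualifies.  Returns
    (ratio trace, chosen k, fitted models).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[-1] > len(X):
        raise ValueError("k_range must be non-empty and within the row count")
    models = {k: kmeans_lloyd(X, k, n_starts=n_starts, max_iter=max_iter, seed=seed)
              for k in ks}
    ratios = pd.Series({k: models[k].ratio for k in ks}, name="ratio")
    ratios.index.name = "k"
    chosen = None
    for k in ks:
        if k + 1 not in models:
            break
        if ratios[k] >= info_threshold and ratios[k + 1] - ratios[k] < gain_threshold:
            chosen = k
            break
    return ratios, chosen, models


def peak_region(centroid: pd.Series) -> str:
    """Region of a centroid's maximum (cluster grouping label)."""
    return str(centroid.idxmax())


def cluster_composition(
    model: ClusterModel,
    cm,
    mt_genome: str = "",
    mt_features: Sequence = (),
) -> dict:
    """Per-cluster content summaries.

    For each cluster: the region its centroid peaks at; expression
    shares per sncRNA class; tsRNA subtype and isoacceptor shares; rRNA
    species shares; piRNA U1/A10 signature; weighted length histogram;
    and (when the mt genome is given) the share of piRNA expression
    perfectly matching mtDNA.  Expression is total normalized counts
    over all samples for the features assigned to the cluster.
    """
    norm_total = cm.normalized.sum(axis=1)
    feats = cm.features
    out: dict[int, dict] = {}
    for g in sorted(model.assignments.unique()):
        members = model.assignments.index[model.assignments == g]
        fsub = feats.loc[members]
        w = norm_total.loc[members]
        entry: dict = {"n_features": len(members),
                       "peak_region": peak_region(model.centroids.iloc[g])}
        cls_share = w.groupby(fsub["assigned_class"].to_numpy()).sum()
        entry["class_shares"] = 100.0 * cls_share / cls_share.sum()
        for level, mask_cls, col in (
            ("tsrna_subtype_shares", "tsRNA", "subtype"),
            ("isoacceptor_shares", "tsRNA", "isoacceptor"),
            ("rrna_species_shares", "rsRNA", "subtype"),
        ):
            mask = fsub["assigned_class"] == mask_cls
            if mask.any():
                share = w[mask.to_numpy()].groupby(fsub.loc[mask, col].to_numpy()).sum()
                entry[level] = 100.0 * share / share.sum()
            else:
                entry[level] = pd.Series(dtype=float)
        pi_mask = (fsub["assigned_class"] == "piRNA").to_numpy()
        pi_seqs = list(members[pi_mask])
        pi_w = w[pi_mask].to_numpy()
        if pi_seqs and pi_w.sum() > 0:
            entry["u1_a10"] = u1_a10_summary(pi_seqs, pi_w).to_dict()
            if mt_genome:
                mt_seqs = {m.sequence for m in
                           mtdna_perfect_matches(pi_seqs, mt_genome, mt_features)}
                mt_w = sum(wt for s, wt in zip(pi_seqs, pi_w) if s in mt_seqs)
                entry["mt_pirna_share"] = 100.0 * mt_w / pi_w.sum()
        lengths = length_distribution(list(members), w.to_numpy())["all"]
        entry["length_histogram"] = lengths["histogram"]
        entry["length_modes"] = lengths["modes"]
        out[int(g)] = entry
    return out


@dataclass
class BCAResult:
    """Between-class analysis of samples.

    ``ratio`` is between-class inertia / total inertia (samples
    centered feature-wise); ``axes`` are the eigenvectors of the
    class-weighted covariance of class means, ``scores`` the sample
    projections on them.
    """

    ratio: float
    class_means: pd.DataFrame
    scores: pd.DataFrame
    axes: pd.DataFrame


def between_class_analysis(
    X: pd.DataFrame, class_labels: Sequence[str]
) -> BCAResult:
    """BCA from the inertia definitions.

    ``X`` is samples x features (e.g. normalized counts, samples as
    rows); ``class_labels`` assigns each sample to a class (here: its
    region).  After feature-wise centering, between-class inertia is
    sum over classes of n_g * ||class mean||^2 and total inertia is the
    sum of squared sample norms; their ratio is the variance fraction
    the class structure explains.
    """
    labels = np.asarray(class_labels)
    if len(labels) != len(X):
        raise ValueError("one class label per sample is required")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("BCA needs at least two classes")
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    total = float((A**2).sum())
    means = np.vstack([A[labels == c].mean(axis=0) for c in classes])
    n_g = np.array([(labels == c).sum() for c in classes], dtype=float)
    between = float((n_g[:, None] * means**2).sum())
    ratio = between / total if total > 0 else 0.0

    # axes: eigenvectors of the class-weighted covariance of class means,
    # via SVD of the sqrt(n_g)-weighted class-mean matrix
    M = np.sqrt(n_g)[:, None] * means
    _, svals, vt = np.linalg.svd(M, full_matrices=False)
    n_axes = min(len(classes) - 1, vt.shape[0])
    axes = vt[:n_axes]
    axis_names = [f"BCA{i + 1}" for i in range(n_axes)]
    return BCAResult(
        ratio=ratio,
        class_means=pd.DataFrame(means, index=classes, columns=X.columns),
        scores=pd.DataFrame(A @ axes.T, index=X.index, columns=axis_names),
        axes=pd.DataFrame(axes, index=axis_names, columns=X.columns),
    )


def bca_per_family(cm) -> pd.Series:
    """Between-class inertia ratio per sncRNA family plus overall,
    regions as classes, computed on log1p normalized counts."""
    norm = np.log1p(cm.normalized)
    labels = cm.samples["region"].to_numpy()
    ratios = {}
    ratios["all"] = between_class_analysis(norm.T, labels).ratio
    for cls in ("miRNA", "piRNA", "tsRNA", "rsRNA"):
        mask = (cm.features["assigned_class"] == cls).to_numpy()
        if mask.sum() >= 2:
            ratios[cls] = between_class_analysis(norm[mask].T, labels).ratio
    return pd.Series(ratios, name="bca_ratio")
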