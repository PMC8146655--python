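"""Count matrix, normalization, composition and differential screening.

Library sizes are equalized with the median-of-ratios (relative log
expression) estimator: the size factor of sample j is the median, over
features with a positive geometric mean across samples, of the ratio of
the feature's count in j to its geometric mean.  Per-region class and
subtype compositions are computed on normalized counts with replicates
averaged per region.  Differential expression between two regions is
screened with a deliberately simple negative-binomial Wald test
(method-of-moments dispersion pooled over both groups) with
Benjamini-Hochberg correction and a fold-change threshold; it is a
documented lightweight stand-in for a full shrinkage-based NB engine,
sufficient to rank and screen features in the synthetic studies this
package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .references import REGIONS


@dataclass
class CountMatrix:
    """Annotated features x samples counts with sample metadata.

    ``counts``: integer counts, features (sequences) x samples.
    ``features``: annotation frame aligned with ``counts.index``
    (``assigned_class``, ``subtype``, ``isoacceptor`` ...).
    ``samples``: per-sample metadata indexed by sample id with
    ``region`` and ``replicate`` columns.
    ``size_factors``: positive per-sample scale, set by ``normalize``.
    """

    counts: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.features.index):
            raise ValueError("counts and features must share the same index")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and samples index must match")

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("call normalize() first")
        return self.counts / self.size_factors

    def normalize(self) -> "CountMatrix":
        self.size_factors = rle_size_factors(self.counts)
        return self

    def region_means(self) -> pd.DataFrame:
        """Normalized counts averaged over replicates, one column per
        region in anatomical order."""
        norm = self.normalized
        regions = [r for r in REGIONS if r in set(self.samples["region"])]
        extra = [r for r in self.samples["region"].unique() if r not in regions]
        cols = {}
        for region in regions + sorted(extra):
            members = self.samples.index[self.samples["region"] == region]
            cols[region] = norm[members].mean(axis=1)
        return pd.DataFrame(cols)


def build_count_matrix(
    tag_table: pd.DataFrame,
    annotations: pd.DataFrame,
    manifest: pd.DataFrame,
) -> CountMatrix:
    """Join a tag table with its annotations and sample metadata.

    Column sums are preserved from the tag table; every sequence must
    be annotated (unannotated sequences carry class 'unannotated').
    """
    if tag_table.empty:
        raise ValueError("empty tag table")
    missing = tag_table.index.difference(annotations.index)
    if len(missing):
        raise ValueError(f"{len(missing)} sequences lack annotations")
    unknown = set(tag_table.columns) - set(manifest["sample"])
    if unknown:
        raise ValueError(f"samples absent from manifest: {sorted(unknown)}")
    samples = (
        manifest.set_index("sample")[["region", "replicate"]]
        .loc[list(tag_table.columns)]
    )
    features = annotations.loc[tag_table.index]
    return CountMatrix(tag_table.copy(), features, samples)


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with all-positive counts, the log-scale geometric
    mean across samples is a pseudo-reference; the size factor of a
    sample is the median ratio of its counts to that reference.
    Features containing any zero are excluded from the median.
    """
    X = counts.to_numpy(dtype=float)
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "median-of-ratios needs at least one (filter samples or features)"
        )
    logx = np.log(X[positive])
    log_geomean = logx.mean(axis=1)
    ratios = np.exp(logx - log_geomean[:, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


_LEVEL_COLUMN = {
    "class": "assigned_class",
    "tsrna_subtype": "subtype",
    "isoacceptor": "isoacceptor",
    "rrna_species": "subtype",
}
_LEVEL_CLASS = {"tsrna_subtype": "tsRNA", "isoacceptor": "tsRNA", "rrna_species": "rsRNA"}


def class_proportions(
    cm: CountMatrix, level: str = "class"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composition shares at a given level.

    Returns ``(within_region, across_region)`` in percent:
    ``within_region[label, region]`` is the label's share of the
    region's total expression (columns sum to 100);
    ``across_region[label, region]`` is the region's share of the
    label's total expression (rows sum to 100).  Levels: ``class``,
    ``tsrna_subtype``, ``isoacceptor``, ``rrna_species``.
    Replicates are averaged (normalized counts) per region first.
    """
    if level not in _LEVEL_COLUMN:
        raise ValueError(f"unknown level {level!r}")
    means = cm.region_means()
    feats = cm.features
    if level in _LEVEL_CLASS:
        keep = feats["assigned_class"] == _LEVEL_CLASS[level]
        means, feats = means[keep.to_numpy()], feats[keep.to_numpy()]
    labels = feats[_LEVEL_COLUMN[level]]
    totals = means.groupby(labels.to_numpy()).sum()
    totals.index.name = level
    within = 100.0 * totals / totals.sum(axis=0)
    across = (100.0 * totals.T / totals.sum(axis=1)).T
    return within, across


def nb_differential_test(
    cm: CountMatrix,
    region_a: str,
    region_b: str,
    alpha: float = 0.05,
    fold_threshold: float = 2.5,
    pseudocount: float = 0.5,
    min_dispersion: float = 1e-8,
) -> pd.DataFrame:
    """Per-feature NB Wald screen between two regions.

    For each feature, group means of normalized counts are compared on
    the log scale; the Wald variance uses a method-of-moments
    dispersion pooled over both groups (floored at ``min_dispersion``).
    P values are Benjamini-Hochberg adjusted across features; a feature
    is significant when adjusted p < ``alpha`` and |fold| >
    ``fold_threshold`` (fold computed on pseudocounted means).
    """
    for region in (region_a, region_b):
        if (cm.samples["region"] == region).sum() < 1:
            raise ValueError(f"region {region!r} has no replicates")
    norm = cm.normalized
    A = norm[cm.samples.index[cm.samples["region"] == region_a]].to_numpy()
    B = norm[cm.samples.index[cm.samples["region"] == region_b]].to_numpy()
    n_a, n_b = A.shape[1], B.shape[1]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    mu_a_ps, mu_b_ps = mu_a + pseudocount, mu_b + pseudocount

    var_a = A.var(axis=1, ddof=1) if n_a > 1 else np.zeros_like(mu_a)
    var_b = B.var(axis=1, ddof=1) if n_b > 1 else np.zeros_like(mu_b)
    # method-of-moments NB dispersion (var = mu + alpha mu^2), pooled
    disp = 0.5 * ((var_a - mu_a) / mu_a_ps**2 + (var_b - mu_b) / mu_b_ps**2)
    disp = np.maximum(disp, min_dispersion)

    log_fc = np.log(mu_a_ps / mu_b_ps)
    # pseudocounted means in the Wald variance too: a group observed at
    # zero then behaves as "< pseudocount", so presence/absence changes
    # (the dominant signal along the tract) remain callable
    se = np.sqrt((1.0 / mu_a_ps + disp) / n_a + (1.0 / mu_b_ps + disp) / n_b)
    z = log_fc / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")

    lfc2 = log_fc / np.log(2.0)
    fold = np.exp(np.abs(log_fc))
    significant = (padj < alpha) & (np.abs(lfc2) > np.log2(fold_threshold))
    out = pd.DataFrame(
        {
            "assigned_class": cm.features["assigned_class"].to_numpy(),
            "mean_a": mu_a, "mean_b": mu_b,
            "log2_fold_change": lfc2, "fold_change": fold,
            "dispersion": disp, "p_value": pvals, "p_adjusted": padj,
            "significant": significant,
        },
        index=cm.counts.index,
    )
    out.attrs["regions"] = (region_a, region_b)
    return out


def pairwise_de_summary(
    cm: CountMatrix, alpha: float = 0.05, fold_threshold: float = 2.5
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Run the screen for every region pair.

    Returns (upper-triangular table of significant-feature counts,
    per-pair result frames).
    """
    regions = [r for r in REGIONS if r in set(cm.samples["region"])]
    table = pd.DataFrame(pd.NA, index=regions, columns=regions, dtype="Int64")
    results = {}
    for a, b in combinations(regions, 2):
        res = nb_differential_test(cm, a, b, alpha=alpha, fold_threshold=fold_threshold)
        results[(a, b)] = res
        table.loc[a, b] = int(res["significant"].sum())
    return table, results


def de_union(results: dict[tuple[str, str], pd.DataFrame]) -> pd.Index:
    """Features significant in at least one region pair."""
    idx: pd.Index | None = None
    for res in results.values():
        sig = res.index[res["significant"]]
        idx = sig if idx is None else idx.union(sig)
    return idx if idx is not None else pd.Index([])
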