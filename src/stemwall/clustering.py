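"""Temporal clustering of DE genes and tissue-specificity selection.

DE genes are expressed relative to the IN2 reference (per-internode
replicate means divided by the IN2 mean), then clustered agglomeratively
with distance 1 - Pearson correlation of the log2 relative profiles
(average linkage) and cut into exactly k = 10 groups. Groups are labeled
1..10 by greedy best-correlation matching of group centroids to the ten
canonical archetypes, so cluster numbers are reproducible rather than
dendrogram-order accidents. Clusters 5, 8 and 10 — the shapes that peak at
internode 5, when secondary-wall deposition is most active — are the wall
clusters carried into TF analysis.

Tissue-specificity selection clusters TFs across the 18-tissue atlas with
the same metric/linkage, cuts the dendrogram at a correlation-distance
height, and keeps sub-clades whose centroid is at least ``ratio_min``-fold
higher in the wall-forming tissues (petiole, stem, root, pod) than in the
remaining tissues.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import config
from .containers import ExpressionMatrix


def relative_profile(matrix: ExpressionMatrix, de_genes: Iterable[str]) -> pd.DataFrame:
    """Per-internode replicate means divided by the IN2 mean (gene x internode).

    The reference column is exactly 1 by construction.
    """
    de_genes = list(de_genes)
    missing = [g for g in de_genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"probes absent from matrix: {missing[:10]}")
    means = matrix.internode_means().loc[de_genes]
    ref = config.REFERENCE_INTERNODE if config.REFERENCE_INTERNODE in means.columns else means.columns[0]
    if (means[ref] <= 0).any():
        raise ValueError("non-positive reference-internode mean")
    return means.div(means[ref], axis=0)


@dataclasses.dataclass
class ClusterAssignment:
    """Probe -> cluster label (1..k) with per-cluster centroids.

    ``labels`` is a Series indexed by probe; ``centroids`` a label x
    internode table of geometric-mean relative profiles; ``archetype_corr``
    maps each label to the Pearson correlation between its centroid and the
    archetype it was matched to.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    archetype_corr: pd.Series
    linkage_matrix: Optional[np.ndarray] = None

    def members(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _corr_distance(log2_profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance matrix; rows must have variance."""
    r = np.corrcoef(log2_profiles)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return squareform(d, checks=False)


def _greedy_archetype_match(centroids_log2: pd.DataFrame) -> dict[int, int]:
    """Bijective group -> archetype labeling by greedy best correlation.

    Repeatedly assigns the (group, archetype) pair with the highest centroid
    correlation, ties broken toward the lower archetype index.
    """
    arch_log2 = np.log2(config.archetype_matrix())
    groups = list(centroids_log2.index)
    corr = pd.DataFrame(index=groups, columns=range(1, 11), dtype=float)
    for g in groups:
        c = centroids_log2.loc[g].to_numpy()
        for a in range(10):
            v = arch_log2[a]
            if np.std(c) == 0 or np.std(v) == 0:
                corr.loc[g, a + 1] = -np.inf
            else:
                corr.loc[g, a + 1] = np.corrcoef(c, v)[0, 1]
    mapping: dict[int, int] = {}
    free_groups, free_arch = set(groups), set(range(1, 11))
    while free_groups and free_arch:
        best = (-np.inf, None, None)
        for g in sorted(free_groups):
            for a in sorted(free_arch):
                val = corr.loc[g, a]
                if val > best[0]:
                    best = (val, g, a)
        _, g, a = best
        mapping[g] = a
        free_groups.discard(g)
        free_arch.discard(a)
    # More groups than archetypes (k > 10): leftover groups keep an
    # arbitrary-but-stable numbering past 10.
    for extra, g in enumerate(sorted(free_groups), start=11):
        mapping[g] = extra
    return mapping


def hierarchical_cluster(
    profiles: pd.DataFrame,
    k: int = 10,
    linkage: str = "average",
) -> ClusterAssignment:
    """Average-linkage agglomerative clustering of relative profiles.

    Distance is 1 - Pearson correlation of log2 profiles. Flat (zero log2
    variance) profiles, for which correlation is undefined, are held out of
    the dendrogram and attached afterwards to the nearest centroid in log2
    Euclidean distance. Groups are labeled by archetype matching.
    """
    if (profiles.to_numpy() <= 0).any():
        raise ValueError("relative profiles must be strictly positive")
    log2p = np.log2(profiles.to_numpy(dtype=float))
    variable = log2p.std(axis=1) > 0
    var_idx = profiles.index[variable]
    if variable.sum() < k:
        raise ValueError(f"need at least k={k} non-flat profiles, got {int(variable.sum())}")

    z = hierarchy.linkage(_corr_distance(log2p[variable]), method=linkage)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        raise ValueError(f"dendrogram yields fewer than k={k} distinct groups")

    labels = pd.Series(raw, index=var_idx)
    cent_log2 = pd.DataFrame(
        {g: log2p[variable][labels.to_numpy() == g].mean(axis=0) for g in np.unique(raw)}
    ).T
    cent_log2.columns = profiles.columns
    mapping = _greedy_archetype_match(cent_log2)
    labels = labels.map(mapping)
    cent_log2.index = [mapping[g] for g in cent_log2.index]
    cent_log2 = cent_log2.sort_index()

    # Flat profiles: nearest centroid by Euclidean distance in log2 space.
    if (~variable).any():
        flat_idx = profiles.index[~variable]
        d = np.linalg.norm(
            log2p[~variable][:, None, :] - cent_log2.to_numpy()[None, :, :], axis=2
        )
        nearest = cent_log2.index.to_numpy()[d.argmin(axis=1)]
        labels = pd.concat([labels, pd.Series(nearest, index=flat_idx)])
        labels = labels.loc[profiles.index]

    arch_log2 = np.log2(config.archetype_matrix())
    corr = {}
    for lab in cent_log2.index:
        if lab <= 10:
            c, v = cent_log2.loc[lab].to_numpy(), arch_log2[lab - 1]
            corr[lab] = float(np.corrcoef(c, v)[0, 1]) if np.std(c) > 0 else np.nan
        else:
            corr[lab] = np.nan
    centroids = 2.0**cent_log2

    return ClusterAssignment(
        labels=labels.astype(int),
        centroids=centroids,
        archetype_corr=pd.Series(corr),
        linkage_matrix=z,
    )


def select_wall_clusters(
    assignment: ClusterAssignment,
    wall_labels: Sequence[int] = tuple(sorted(config.WALL_CLUSTERS)),
    tf_annotation: Optional[pd.Series] = None,
) -> pd.Index:
    """Union of the members of the named clusters.

    With ``tf_annotation`` (probe -> bool) the returned set is restricted to
    annotated TFs.
    """
    known = set(assignment.labels.unique())
    unknown = [w for w in wall_labels if w not in known and w in range(1, 11)]
    bad = [w for w in wall_labels if not 1 <= w <= max(10, max(known, default=10))]
    if bad:
        raise ValueError(f"unknown cluster labels: {bad}")
    if unknown:
        raise ValueError(f"clusters absent from assignment: {unknown}")
    pooled = assignment.labels.index[assignment.labels.isin(set(wall_labels))]
    if tf_annotation is not None:
        keep = tf_annotation.reindex(pooled, fill_value=False).astype(bool)
        pooled = pooled[keep.to_numpy()]
    return pooled


def tissue_specificity_select(
    atlas: ExpressionMatrix,
    tf_set: Iterable[str],
    wall_tissues: frozenset[str] = config.WALL_TISSUES,
    ratio_min: float = 2.0,
    linkage: str = "average",
    clade_height: float = 0.5,
) -> pd.Index:
    """TF sub-clades specifically expressed in wall-forming tissues.

    Clusters the TFs across atlas tissues (1 - Pearson of log2, average
    linkage), cuts the dendrogram at correlation distance ``clade_height``,
    and returns members of clades whose centroid mean over ``wall_tissues``
    is at least ``ratio_min`` times its mean over the remaining tissues.
    Flat TFs are never selected (no tissue preference).
    """
    tf_set = list(tf_set)
    missing_cols = wall_tissues - set(atlas.design.loc[atlas.values.columns, "tissue"])
    if missing_cols:
        raise ValueError(f"atlas lacks wall tissue columns: {sorted(missing_cols)}")
    sub = atlas.subset(tf_set)
    tissues = sub.design.loc[sub.values.columns, "tissue"]
    wall_cols = [s for s in sub.values.columns if tissues[s] in wall_tissues]
    other_cols = [s for s in sub.values.columns if tissues[s] not in wall_tissues]

    log2v = np.log2(sub.values.to_numpy(dtype=float))
    variable = log2v.std(axis=1) > 0
    if variable.sum() == 0:
        return pd.Index([])
    idx = sub.values.index[variable]
    if variable.sum() == 1:
        clades = np.array([1])
    else:
        z = hierarchy.linkage(_corr_distance(log2v[variable]), method=linkage)
        clades = hierarchy.fcluster(z, t=clade_height, criterion="distance")

    selected: list[str] = []
    values = sub.values.loc[idx]
    for clade in np.unique(clades):
        members = idx[clades == clade]
        centroid = values.loc[members].mean(axis=0)
        wall_mean = centroid[wall_cols].mean()
        other_mean = centroid[other_cols].mean()
        if other_mean > 0 and wall_mean / other_mean >= ratio_min:
            selected.extend(members)
    return pd.Index([t for t in tf_set if t in set(selected)])
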