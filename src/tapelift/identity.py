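"""Tissue-identity validation.

Checks that a set of methylomes looks like the tissue it claims to be:

* :func:`pca_embed` — joint principal-component embedding of several
  datasets over their shared probes, with a deterministic sign convention
  (the largest-magnitude loading of each component is positive);
* :func:`marker_correlation_cluster` — hierarchical clustering of samples by
  Pearson correlation over cell-type-specific marker probes (distance
  1 − r, average linkage), with a Newick serialization of the dendrogram;
* :func:`compartment_distribution` — chromatin-state composition of a probe
  subset against the full annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .datasets import MethylationDataset, ProbeAnnotation, ValidationError

__all__ = [
    "EmbeddingResult",
    "pca_embed",
    "ClusterResult",
    "marker_correlation_cluster",
    "compartment_distribution",
]

MIN_SHARED_PROBES = 10
MIN_CORR_OVERLAP = 10


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame          # samples × components
    explained_variance_ratio: np.ndarray
    shared_probes: list[str]
    tissue_labels: pd.Series


def _concat_over_shared(
    datasets: Sequence[MethylationDataset], probe_set: Sequence[str] | None
) -> tuple[pd.DataFrame, pd.Series]:
    if not datasets:
        raise ValidationError("need at least one dataset")
    shared = datasets[0].probe_ids
    for ds in datasets[1:]:
        shared = shared.intersection(ds.probe_ids)
    if probe_set is not None:
        shared = shared.intersection(pd.Index([str(p) for p in probe_set]))
    if len(shared) == 0:
        raise ValidationError("no shared probes across datasets")
    mats, labels = [], []
    for ds in datasets:
        mats.append(ds.betas.loc[shared])
        lab = ds.samples.get("tissue_label", pd.Series("unknown", index=ds.sample_ids))
        labels.append(lab.astype(str))
    combined = pd.concat(mats, axis=1)
    if combined.columns.has_duplicates:
        raise ValidationError("duplicate sample ids across datasets")
    return combined, pd.concat(labels)


def pca_embed(
    datasets: Sequence[MethylationDataset],
    probe_set: Sequence[str] | None = None,
    n_components: int = 2,
) -> EmbeddingResult:
    """PCA of concatenated samples over the probes shared by all datasets.

    β values are centered per probe (no variance scaling, matching direct
    PCA of methylation levels); probes with any missing value across the
    combined samples are dropped.  Component signs follow the convention
    that the largest-|loading| probe has a positive loading.
    """
    combined, labels = _concat_over_shared(datasets, probe_set)
    combined = combined.dropna(axis=0, how="any")
    if combined.shape[0] < MIN_SHARED_PROBES:
        raise ValidationError(
            f"only {combined.shape[0]} complete shared probes (< {MIN_SHARED_PROBES})"
        )
    n_samples = combined.shape[1]
    if n_samples < 2:
        raise ValidationError("need at least 2 samples")
    X = combined.to_numpy(dtype=float).T  # samples × probes
    Xc = X - X.mean(axis=0)
    k = min(n_components, n_samples - 1, Xc.shape[1])
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate positive per component
    for comp in range(k):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0
    scores = U[:, :k] * S[:k]
    total_var = float((S**2).sum())
    evr = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    coords = pd.DataFrame(
        scores, index=combined.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return EmbeddingResult(
        coordinates=coords,
        explained_variance_ratio=evr,
        shared_probes=combined.index.tolist(),
        tissue_labels=labels,
    )


@dataclass
class ClusterResult:
    correlation: pd.DataFrame
    linkage_matrix: np.ndarray
    sample_ids: list[str]
    tissue_labels: pd.Series
    newick: str

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")


def _to_newick(tree, leaf_names: list[str]) -> str:
    def rec(node) -> str:
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{node.dist:.10g}"
        left = rec(node.get_left())
        right = rec(node.get_right())
        return f"({left},{right}):{node.dist:.10g}"

    root = rec(tree)
    # root distance is the merge height; terminate the tree
    return root.rsplit(":", 1)[0] + ";"


def marker_correlation_cluster(
    datasets: Sequence[MethylationDataset],
    ann: ProbeAnnotation,
    top_n: int = 25,
    linkage_method: str = "average",
) -> ClusterResult:
    """Cluster samples by Pearson correlation over atlas marker probes.

    The probe set is the union over cell types of each type's ``top_n``
    highest-ranked marker probes, intersected with the probes shared by all
    datasets.  Correlations are pairwise-complete with a minimum overlap of
    10 probes; samples whose marker β are entirely missing are excluded with
    a warning.  Distance is 1 − r under the requested linkage (average by
    default); the dendrogram is also returned in Newick form.
    """
    ms = ann.marker_sets
    chosen = ms[ms["rank"] <= top_n]["probe_id"].unique().tolist()
    combined, labels = _concat_over_shared(datasets, chosen)
    if combined.shape[0] < 2:
        raise ValidationError("fewer than 2 usable marker probes")
    all_missing = combined.isna().all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"excluding samples with all-missing marker betas: "
            f"{combined.columns[all_missing].tolist()}"
        )
        combined = combined.loc[:, ~all_missing]
        labels = labels[combined.columns]
    corr = combined.corr(method="pearson", min_periods=MIN_CORR_OVERLAP)
    np.fill_diagonal(corr.values, 1.0)
    if corr.isna().any().any():
        raise ValidationError("undefined correlations (insufficient probe overlap)")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage_method)
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, corr.columns.tolist())
    return ClusterResult(
        correlation=corr,
        linkage_matrix=Z,
        sample_ids=corr.columns.tolist(),
        tissue_labels=labels,
        newick=newick,
    )


def compartment_distribution(
    probe_ids: Sequence[str], ann: ProbeAnnotation
) -> pd.DataFrame:
    """Chromatin-state fractions for a probe subset and the full annotation.

    Probes without a state count under ``unassigned``.  Each fraction column
    sums to 1 (within numerical precision).
    """
    ids = pd.Index([str(p) for p in probe_ids])
    unknown = ids.difference(ann.probe_ids).tolist()
    if unknown:
        raise ValidationError(f"probes not in annotation: {unknown[:5]}")
    states_all = ann.table["chromatin_state"].fillna("unassigned").astype(str)
    states_sub = states_all.loc[ids]

    def fractions(s: pd.Series) -> pd.Series:
        counts = s.value_counts()
        return counts / counts.sum()

    sub = fractions(states_sub)
    full = fractions(states_all)
    out = pd.DataFrame({"subset_fraction": sub, "overall_fraction": full}).fillna(0.0)
    out.index.name = "chromatin_state"
    return out.sort_index()
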