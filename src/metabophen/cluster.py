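"""Clustering biomarkers into metabolic phenotypes.

Biomarkers that tend to identify the same participants are grouped by
complete-linkage hierarchical clustering of the Jaccard distance between
their positive-participant sets (computed over participants identified by
at least one biomarker). The cluster count is chosen by maximizing the
average silhouette width over a configurable range (default 5–50). Each
cluster is then characterized by per-metabolite fold changes between
cluster-positive and cluster-negative participants, clusters with similar
fold-change patterns are grouped via a |1−r| Pearson distance, and each
identified participant is assigned a primary cluster (the cluster holding
the most of their positive biomarkers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .screen import BiomarkerProfile, _case_indicator

logger = logging.getLogger(__name__)


def jaccard_distance_matrix(
    profile: BiomarkerProfile, restrict_to_identified: bool = True
) -> pd.DataFrame:
    """Pairwise Jaccard distance 1 − |A∩B|/|A∪B| between the
    positive-participant sets of all biomarkers.

    By default the profile is restricted to participants identified by at
    least one biomarker before distances are computed. A biomarker with no
    positives has distance 1 to everything (logged)."""
    M = profile.matrix
    if restrict_to_identified:
        M = M.loc[profile.identified]
    X = M.to_numpy(dtype=np.float64).T  # biomarkers × participants
    b = X.shape[0]
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    empty = sizes == 0
    if empty.any():
        logger.warning("%d biomarker(s) with zero positives: distance 1 by convention",
                       int(empty.sum()))
        D[empty, :] = 1.0
        D[:, empty] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return pd.DataFrame(D, index=M.columns, columns=M.columns)


@dataclass
class ClusterModel:
    assignments: pd.Series  # biomarker_id -> cluster_id (1..k)
    k: int
    linkage_tree: np.ndarray
    silhouette_by_k: dict[int, float]
    distance: pd.DataFrame = field(repr=False, default=None)

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for bid, cid in self.assignments.items():
            out.setdefault(int(cid), []).append(bid)
        return out

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "k": self.k,
            "assignments": {str(b): int(c) for b, c in self.assignments.items()},
            "silhouette_by_k": {str(k): (None if np.isnan(v) else float(v))
                                for k, v in self.silhouette_by_k.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def cluster_biomarkers(
    distance: pd.DataFrame, k_range: tuple[int, int] = (5, 50)
) -> ClusterModel:
    """Complete-linkage tree on the Jaccard distances, cut at the k (in
    ``k_range``) maximizing the average silhouette width; silhouette ties
    and fully degenerate silhouettes resolve to the smallest k."""
    from sklearn.metrics import silhouette_score

    n = distance.shape[0]
    if n < 2:
        raise ValueError("need at least 2 biomarkers to cluster")
    lo, hi = k_range
    if n <= lo:
        lo, hi = 2, max(2, n - 1)
        logger.warning("k_range truncated to (%d, %d) for %d biomarkers", lo, hi, n)
    hi = min(hi, n - 1)
    lo = max(2, min(lo, hi))
    if hi < lo:  # n == 2: only the all-singletons cut is available
        hi = lo

    D = distance.to_numpy(dtype=float)
    Z = linkage(squareform(D, checks=False), method="complete")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(lo, hi + 1):
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        n_found = np.unique(lab).size
        if n_found < 2 or n_found >= n:
            sil[k] = np.nan
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            s = silhouette_score(D, lab, metric="precomputed")
        sil[k] = float(s) if np.isfinite(s) else np.nan
    finite = {k: v for k, v in sil.items() if not np.isnan(v)}
    if finite:
        best_val = max(finite.values())
        k_star = min(k for k, v in finite.items() if v == best_val)
    else:
        k_star = lo
        logger.warning("silhouette degenerate for every k; returning smallest k=%d", k_star)
    lab = labels_by_k[k_star]
    # renumber clusters 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    newlab = np.empty_like(lab)
    for i, c in enumerate(lab):
        if c not in remap:
            remap[c] = len(remap) + 1
        newlab[i] = remap[c]
    assignments = pd.Series(newlab, index=distance.index, name="cluster_id")
    return ClusterModel(assignments=assignments, k=int(np.unique(newlab).size),
                        linkage_tree=Z, silhouette_by_k=sil, distance=distance)


def _cluster_positive(model: ClusterModel, profile: BiomarkerProfile) -> pd.DataFrame:
    """Participants × clusters indicator: positive for ≥1 member biomarker."""
    out = pd.DataFrame(index=profile.matrix.index)
    for cid, members in sorted(model.clusters.items()):
        out[cid] = (profile.matrix[members].sum(axis=1) > 0).astype(np.int8)
    return out


def cluster_summaries(
    model: ClusterModel, profile: BiomarkerProfile, labels
) -> pd.DataFrame:
    """Per-cluster subpopulation size and purity.

    ``pct_asd`` is the fraction of all case participants positive for at
    least one member biomarker; ``pmp_asd`` is the case fraction among all
    participants positive for at least one member."""
    y = _case_indicator(np.asarray(labels))
    pos = _cluster_positive(model, profile)
    rows = []
    for cid in sorted(model.clusters):
        p = pos[cid].to_numpy(dtype=bool)
        n_pos = int(p.sum())
        rows.append({
            "cluster_id": cid,
            "n_biomarkers": len(model.clusters[cid]),
            "pct_asd": float((p & y).sum() / max(int(y.sum()), 1)),
            "pmp_asd": float(y[p].mean()) if n_pos else np.nan,
            "n_positive": n_pos,
        })
    return pd.DataFrame(rows).set_index("cluster_id")


def fold_changes(
    model: ClusterModel, quant, labels, profile: BiomarkerProfile,
    scope: str = "asd_only",
) -> pd.DataFrame:
    """Cluster × metabolite fold changes of mean raw concentration,
    cluster-positive over cluster-negative participants.

    ``scope`` restricts the comparison to cases (``asd_only``, default) or
    uses the whole cohort (``all``). Cells whose positive or negative group
    mean is unavailable are missing, not 1."""
    if scope not in ("asd_only", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    conc = quant.values if hasattr(quant, "values") else quant
    y = _case_indicator(np.asarray(labels))
    pos = _cluster_positive(model, profile)
    mask = y if scope == "asd_only" else np.ones(len(conc), dtype=bool)
    rows = {}
    for cid in sorted(model.clusters):
        p = pos[cid].to_numpy(dtype=bool) & mask
        q = ~pos[cid].to_numpy(dtype=bool) & mask
        fc = {}
        for m in conc.columns:
            num = conc.loc[p, m].mean()
            den = conc.loc[q, m].mean()
            if not np.isfinite(num) or not np.isfinite(den) or den == 0:
                fc[m] = np.nan
                if not p.any() or not np.isfinite(num):
                    logger.warning("cluster %d: no positive-group mean for %s", cid, m)
            else:
                fc[m] = float(num / den)
        rows[cid] = fc
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("cluster_id")


def group_clusters(fold_change_table: pd.DataFrame, n_groups: int = 7) -> pd.Series:
    """Group clusters by similarity of their (log2) fold-change patterns.

    Distance = |1 − r| on pairwise-complete Pearson correlations of the
    log2 fold-change vectors; complete-linkage tree cut into ``n_groups``.
    A constant fold-change vector has undefined correlation and gets
    distance 1 to everything (logged)."""
    n = fold_change_table.shape[0]
    if n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds number of clusters {n}")
    logfc = np.log2(fold_change_table)
    corr = logfc.T.corr(min_periods=2)  # pairwise-complete over metabolites
    D = np.abs(1.0 - corr.to_numpy(dtype=float))
    undef = np.isnan(D)
    if undef.any():
        logger.warning("undefined fold-change correlations: distance 1 by convention")
        D[undef] = 1.0
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="complete")
    lab = fcluster(Z, t=n_groups, criterion="maxclust")
    return pd.Series(lab, index=fold_change_table.index, name="group_id")


def assign_primary_cluster(
    profile: BiomarkerProfile, model: ClusterModel, labels
) -> pd.DataFrame:
    """Per-participant primary cluster and cluster count.

    The primary cluster is the one holding the most of the participant's
    positive biomarkers; ties break to the cluster with higher %ASD, then
    the lowest cluster id. Participants with no positive biomarker are
    excluded. ``cluster_count`` is the number of clusters in which the
    participant has at least one positive biomarker."""
    counts = pd.DataFrame(index=profile.matrix.index)
    for cid, members in sorted(model.clusters.items()):
        counts[cid] = profile.matrix[members].sum(axis=1)
    summaries = cluster_summaries(model, profile, labels)
    # order clusters by (pct_asd desc, cluster_id asc) so that argmax over
    # the reordered columns applies the tie-break automatically
    order = sorted(counts.columns, key=lambda c: (-summaries.loc[c, "pct_asd"], c))
    C = counts[order].to_numpy()
    identified = C.sum(axis=1) > 0
    best = np.argmax(C, axis=1)
    primary = np.array(order)[best]
    cluster_count = (C > 0).sum(axis=1)
    out = pd.DataFrame({
        "primary_cluster": primary,
        "cluster_count": cluster_count,
    }, index=profile.matrix.index)
    return out.loc[identified]


def name_clusters(
    model: ClusterModel, fold_change_table: pd.DataFrame, top: int = 2
) -> dict[int, str]:
    """Auto-generate display names from the largest-|log2 FC| metabolites,
    with ↑/↓ direction arrows (overridable downstream)."""
    names = {}
    logfc = np.log2(fold_change_table)
    for cid in fold_change_table.index:
        row = logfc.loc[cid].dropna()
        if row.empty:
            names[int(cid)] = f"cluster{cid}"
            continue
        top_mets = row.abs().sort_values(ascending=False).index[:top]
        parts = [("↑" if row[m] > 0 else "↓") + str(m) for m in top_mets]
        names[int(cid)] = "".join(parts)
    return names
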