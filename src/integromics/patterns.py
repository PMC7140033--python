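"""Progression-profile templates and K-means template assignment.

Eight canonical stage-wise shapes describe when a feature changes (early,
delayed, late) and in which direction, over a four-stage progression:

====  ==============  ================================
id    shape           label
====  ==============  ================================
G1    (0, 1, 2, 3)    early and continuous increase
G2    (0, 1, 1, 1)    early increase, sustained
G3    (0, 0, 1, 1)    delayed increase
G4    (0, 0, 0, 1)    late increase
G5    (0, 0, 0, -1)   late decrease
G6    (0, 0, -1, -1)  delayed decrease
G7    (0, -1, -1, -1) early decrease, sustained
G8    (0, -1, -2, -3) early and continuous decrease
====  ==============  ================================

Gk and G(9-k) are sign mirrors. Features are summarized to standardized
(z-scored) per-stage mean vectors, clustered by K-means, and each cluster is
matched to the template maximizing the Pearson correlation of its centroid
with the template shape; clusters matching no template well enough (or
ambiguously) leave their members unassigned. mRNA and pathway profiles use
the same group ids with reversed direction semantics (a "G1 gene" decreases
continuously, mirroring the increase of a G1 miRNA that represses it).

Silhouette scores quantify cluster cohesion vs separation per item; a strict
cutoff (default 0.5 for pathways) removes improperly clustered items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .model import ExpressionMatrix, PatternAssignment, StageDesign, transition_name

_FLAT_TOL = 1e-12

TEMPLATE_IDS = ("G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8")

_SHAPES: dict[str, tuple[float, ...]] = {
    "G1": (0, 1, 2, 3),
    "G2": (0, 1, 1, 1),
    "G3": (0, 0, 1, 1),
    "G4": (0, 0, 0, 1),
    "G5": (0, 0, 0, -1),
    "G6": (0, 0, -1, -1),
    "G7": (0, -1, -1, -1),
    "G8": (0, -1, -2, -3),
}

_LABELS: dict[str, str] = {
    "G1": "early and continuous increase",
    "G2": "early increase, sustained",
    "G3": "delayed increase",
    "G4": "late increase",
    "G5": "late decrease",
    "G6": "delayed decrease",
    "G7": "early decrease, sustained",
    "G8": "early and continuous decrease",
}

#: transition index (0-based, adjacent pairs) at which each template first moves
FIRST_CHANGE_STEP: dict[str, int] = {
    "G1": 0, "G2": 0, "G7": 0, "G8": 0,
    "G3": 1, "G6": 1,
    "G4": 2, "G5": 2,
}


@dataclass(frozen=True)
class ProgressionTemplate:
    id: str
    shape: tuple[float, ...]
    label: str

    @property
    def direction(self) -> str:
        return "up" if sum(self.shape) > 0 else "down"

    def first_transition(self, design: StageDesign) -> str:
        return transition_name(design.transitions()[FIRST_CHANGE_STEP[self.id]])


def progression_templates() -> list[ProgressionTemplate]:
    """The eight canonical templates, in id order."""
    return [ProgressionTemplate(t, _SHAPES[t], _LABELS[t]) for t in TEMPLATE_IDS]


def template_direction(template_id: str, reversed_semantics: bool = False) -> str:
    """'up'/'down' direction of a feature carrying this group id.

    With ``reversed_semantics`` (mRNA/pathway side) the direction flips:
    a G1 gene decreases while a G1 miRNA increases.
    """
    up = sum(_SHAPES[template_id]) > 0
    if reversed_semantics:
        up = not up
    return "up" if up else "down"


def stage_mean_profiles(matrix: ExpressionMatrix, design: StageDesign) -> pd.DataFrame:
    """Per-feature mean expression per stage (features x stages, stage order)."""
    labels = design.stage_labels(matrix.sample_ids)
    values = matrix.values
    cols = {}
    for stage in design.stages:
        mask = labels == stage
        if mask.any():
            cols[stage] = values[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(matrix.feature_ids, name="feature"))


def standardize_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each row; rows with (near-)zero SD are dropped and returned
    separately as flat features that cannot carry a pattern."""
    values = profiles.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] <= _FLAT_TOL
    z = np.where(flat[:, None], 0.0, (values - mean) / np.where(flat[:, None], 1.0, sd))
    out = pd.DataFrame(z[~flat], index=profiles.index[~flat], columns=profiles.columns)
    return out, profiles.index[flat]


@dataclass
class ClusterResult:
    labels: pd.Series  # feature -> cluster index
    centroids: np.ndarray  # (k, n_stages)
    inertia: float
    seed: int
    k: int


def kmeans_cluster(
    profiles: pd.DataFrame, k: int, seed: int, n_restarts: int = 25
) -> ClusterResult:
    """K-means (k-means++ seeding, best of ``n_restarts`` by inertia) on
    standardized stage-mean profiles; deterministic given ``seed``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of features ({len(profiles)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy(dtype=float))
    return ClusterResult(
        labels=pd.Series(labels, index=profiles.index),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        k=k,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd, yd = x - x.mean(), y - y.mean()
    nx, ny = np.sqrt((xd**2).sum()), np.sqrt((yd**2).sum())
    if nx <= _FLAT_TOL or ny <= _FLAT_TOL:
        return np.nan
    return float((xd * yd).sum() / (nx * ny))


def assign_clusters_to_templates(
    clusters: ClusterResult,
    templates: list[ProgressionTemplate] | None = None,
    min_match: float = 0.9,
    reversed_semantics: bool = False,
) -> PatternAssignment:
    """Match each cluster centroid to the template maximizing Pearson r.

    Clusters whose best correlation falls below ``min_match``, ties at the
    top, or flat centroids leave all member features unassigned with a
    reason code. With ``reversed_semantics`` centroids are matched against
    the sign-mirrored shapes but keep the unmirrored group id (mRNA/pathway
    convention).
    """
    if templates is None:
        templates = progression_templates()
    cluster_template: dict[int, tuple[str, float, str]] = {}
    for ci, centroid in enumerate(clusters.centroids):
        scores = {}
        for t in templates:
            shape = np.array(t.shape, dtype=float)
            if reversed_semantics:
                shape = -shape
            r = _pearson(centroid, shape)
            if not np.isnan(r):
                scores[t.id] = r
        if not scores:
            cluster_template[ci] = ("unassigned", np.nan, "flat_centroid")
            continue
        best_id = max(scores, key=lambda t: scores[t])
        best = scores[best_id]
        tied = [t for t, r in scores.items() if abs(r - best) <= 1e-9]
        if len(tied) > 1:
            cluster_template[ci] = ("unassigned", best, "ambiguous_match")
        elif best < min_match:
            cluster_template[ci] = ("unassigned", best, "low_match")
        else:
            cluster_template[ci] = (best_id, best, "")
    rows = []
    for feature, ci in clusters.labels.items():
        template, score, reason = cluster_template[int(ci)]
        rows.append(
            {
                "feature": feature,
                "template": template,
                "cluster": int(ci),
                "match_score": score,
                "silhouette": np.nan,
                "reason": reason,
            }
        )
    table = pd.DataFrame(rows).set_index("feature")
    return PatternAssignment(table=table, reversed_semantics=reversed_semantics)


def silhouette_scores(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-item silhouette s(i) = (b - a) / max(a, b) with Euclidean distance.

    a(i): mean distance to the other members of i's cluster; b(i): the
    smallest mean distance to any other cluster. Items in singleton clusters
    score 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = X.shape[0]
    dist = cdist(X, X)
    s = np.zeros(n)
    sizes = {c: int((labels == c).sum()) for c in uniq}
    mean_to_cluster = np.stack(
        [dist[:, labels == c].sum(axis=1) / sizes[c] for c in uniq], axis=1
    )
    for i in range(n):
        ci = np.where(uniq == labels[i])[0][0]
        size = sizes[labels[i]]
        if size == 1:
            s[i] = 0.0
            continue
        a = mean_to_cluster[i, ci] * size / (size - 1)  # exclude self
        b = np.min(np.delete(mean_to_cluster[i], ci))
        denom = max(a, b)
        s[i] = 0.0 if denom <= _FLAT_TOL else (b - a) / denom
    return s


def filter_by_silhouette(
    assignment: PatternAssignment, threshold: float = 0.5
) -> PatternAssignment:
    """Unassign items whose silhouette falls below ``threshold``."""
    table = assignment.table.copy()
    low = (table["silhouette"] < threshold) & (table["template"] != "unassigned")
    table.loc[low, "template"] = "unassigned"
    table.loc[low, "reason"] = "low_silhouette"
    return PatternAssignment(table=table, reversed_semantics=assignment.reversed_semantics)


def assign_patterns(
    matrix: ExpressionMatrix,
    design: StageDesign,
    k: int = 8,
    seed: int = 0,
    n_restarts: int = 25,
    min_match: float = 0.9,
    reversed_semantics: bool = False,
    silhouette_threshold: float | None = None,
) -> PatternAssignment:
    """Full template-assignment pipeline for one matrix.

    Stage means -> z-score (flat features unassigned) -> K-means ->
    cluster-to-template matching -> silhouette scoring -> optional
    silhouette cutoff.
    """
    profiles = stage_mean_profiles(matrix, design)
    z, flat = standardize_profiles(profiles)
    parts = []
    if len(z) >= 2 and k <= len(z):
        clusters = kmeans_cluster(z, k=k, seed=seed, n_restarts=n_restarts)
        assignment = assign_clusters_to_templates(
            clusters, min_match=min_match, reversed_semantics=reversed_semantics
        )
        table = assignment.table
        if clusters.labels.nunique() >= 2:
            table = table.copy()
            table["silhouette"] = silhouette_scores(
                z.to_numpy(), clusters.labels.to_numpy()
            )
        parts.append(table)
    elif len(z):
        parts.append(
            pd.DataFrame(
                {
                    "template": "unassigned",
                    "cluster": -1,
                    "match_score": np.nan,
                    "silhouette": np.nan,
                    "reason": "too_few_features",
                },
                index=z.index,
            )
        )
    if len(flat):
        parts.append(
            pd.DataFrame(
                {
                    "template": "unassigned",
                    "cluster": -1,
                    "match_score": np.nan,
                    "silhouette": np.nan,
                    "reason": "flat_profile",
                },
                index=flat,
            )
        )
    table = pd.concat(parts) if parts else pd.DataFrame(
        columns=["template", "cluster", "match_score", "silhouette", "reason"]
    )
    table = table.reindex(matrix.feature_ids)
    table.index.name = "feature"
    assignment = PatternAssignment(table=table, reversed_semantics=reversed_semantics)
    if silhouette_threshold is not None:
        assignment = filter_by_silhouette(assignment, silhouette_threshold)
    return assignment


class TemplateAssigner(BaseEstimator, ClusterMixin):
    """Sklearn-style wrapper: cluster stage-mean profiles and label each row
    with a progression template.

    ``fit(X)`` takes X of shape (n_items, n_stages) (stage-mean vectors, raw
    scale; z-scoring happens internally). Fitted attributes: ``labels_``
    (template id or 'unassigned'), ``cluster_labels_``, ``match_score_``,
    ``silhouette_``.
    """

    def __init__(
        self,
        k: int = 8,
        random_state: int = 0,
        n_restarts: int = 25,
        min_match: float = 0.9,
        reversed_semantics: bool = False,
        silhouette_threshold: float | None = None,
    ):
        self.k = k
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.min_match = min_match
        self.reversed_semantics = reversed_semantics
        self.silhouette_threshold = silhouette_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_items, n_stages = X.shape
        stages = tuple(f"S{i}" for i in range(n_stages))
        profiles = pd.DataFrame(
            X, index=[f"item{i}" for i in range(n_items)], columns=stages
        )
        z, flat = standardize_profiles(profiles)
        table_parts = []
        if len(z) >= 2 and self.k <= len(z):
            clusters = kmeans_cluster(
                z, k=self.k, seed=self.random_state, n_restarts=self.n_restarts
            )
            assignment = assign_clusters_to_templates(
                clusters,
                min_match=self.min_match,
                reversed_semantics=self.reversed_semantics,
            )
            table = assignment.table.copy()
            if clusters.labels.nunique() >= 2:
                table["silhouette"] = silhouette_scores(
                    z.to_numpy(), clusters.labels.to_numpy()
                )
            table_parts.append(table)
        if len(flat):
            table_parts.append(
                pd.DataFrame(
                    {
                        "template": "unassigned",
                        "cluster": -1,
                        "match_score": np.nan,
                        "silhouette": np.nan,
                        "reason": "flat_profile",
                    },
                    index=flat,
                )
            )
        table = pd.concat(table_parts).reindex(profiles.index)
        assignment = PatternAssignment(table, self.reversed_semantics)
        if self.silhouette_threshold is not None:
            assignment = filter_by_silhouette(assignment, self.silhouette_threshold)
        self.assignment_ = assignment
        self.labels_ = assignment.table["template"].to_numpy()
        self.cluster_labels_ = assignment.table["cluster"].to_numpy()
        self.match_score_ = assignment.table["match_score"].to_numpy()
        self.silhouette_ = assignment.table["silhouette"].to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
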