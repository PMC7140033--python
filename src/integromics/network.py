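"""miRNA-gene-pathway correlation networks and heat-map leaf ordering.

Edges carry the Pearson correlation of the two entities' per-sample
profiles; 'targets' edges run miRNA -> gene and 'member_of' edges run
gene -> pathway. Hierarchical leaf ordering uses Ward linkage on the
1 - r correlation dissimilarity.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .model import ExpressionMatrix, PatternAssignment, StageDesign
from .patterns import template_direction

_CONST_TOL = 1e-12


def _pearson_profiles(x: np.ndarray, y: np.ndarray) -> float | None:
    xd, yd = x - x.mean(), y - y.mean()
    nx_, ny_ = np.sqrt((xd**2).sum()), np.sqrt((yd**2).sum())
    if nx_ <= _CONST_TOL or ny_ <= _CONST_TOL:
        return None
    return float((xd * yd).sum() / (nx_ * ny_))


def build_network(
    triples: pd.DataFrame,
    mirna_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    pathway_scores: ExpressionMatrix,
    mirna_assignment: PatternAssignment | None = None,
    min_abs_r: float = 0.7,
) -> nx.DiGraph:
    """Build the directed miRNA->gene->pathway correlation graph.

    Nodes are the distinct entities in ``triples`` with type/group/direction
    attributes; node direction comes from the group template's sign (gene
    and pathway sides reversed). Edge weight is the Pearson r of the two
    12-sample profiles; edges with |r| < ``min_abs_r`` are dropped and
    constant profiles are skipped with a warning.
    """
    samples = [s for s in mirna_matrix.sample_ids if s in gene_matrix.sample_ids]
    graph = nx.DiGraph()

    def profile(matrix: ExpressionMatrix, feature: str) -> np.ndarray | None:
        if feature not in matrix.data.index:
            return None
        cols = [s for s in samples if s in matrix.sample_ids]
        return matrix.data.loc[feature, cols].to_numpy(dtype=float)

    def ensure_node(name: str, node_type: str, group: str):
        if name in graph:
            return
        reversed_side = node_type in ("gene", "pathway")
        graph.add_node(
            name,
            type=node_type,
            group=group,
            direction=template_direction(group, reversed_semantics=reversed_side),
        )

    def add_edge(u, v, xu, xv, relation):
        r = _pearson_profiles(xu, xv)
        if r is None:
            warnings.warn(
                f"constant profile on edge {u} -> {v}; edge omitted",
                RuntimeWarning,
                stacklevel=3,
            )
            return
        if abs(r) < min_abs_r:
            return
        graph.add_edge(u, v, weight=r, sign=int(np.sign(r)), relation=relation)

    seen_pairs: set[tuple[str, str]] = set()
    for _, row in triples.iterrows():
        mirna, gene, group = row["mirna"], row["gene"], row["group"]
        pathway = row.get("pathway", np.nan)
        xm, xg = profile(mirna_matrix, mirna), profile(gene_matrix, gene)
        if xm is None or xg is None:
            continue
        ensure_node(mirna, "miRNA", group)
        ensure_node(gene, "gene", group)
        if (mirna, gene) not in seen_pairs:
            seen_pairs.add((mirna, gene))
            add_edge(mirna, gene, xm, xg, "targets")
        if isinstance(pathway, str) and pathway:
            xp = profile(pathway_scores, pathway)
            if xp is None:
                continue
            ensure_node(pathway, "pathway", group)
            if (gene, pathway) not in seen_pairs:
                seen_pairs.add((gene, pathway))
                common = [
                    s
                    for s in samples
                    if s in gene_matrix.sample_ids and s in pathway_scores.sample_ids
                ]
                xg2 = gene_matrix.data.loc[gene, common].to_numpy(dtype=float)
                xp2 = pathway_scores.data.loc[pathway, common].to_numpy(dtype=float)
                add_edge(gene, pathway, xg2, xp2, "member_of")
    return graph


def correlation_dissimilarity(matrix: ExpressionMatrix) -> np.ndarray:
    """Pairwise d = 1 - Pearson r over rows; rows with constant profiles get
    d = 1 against everything (with a warning)."""
    values = matrix.values
    sd = values.std(axis=1, ddof=0)
    constant = sd <= _CONST_TOL
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s); their correlation is "
            "undefined and dissimilarity set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    d = 1.0 - r
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return d


def hierarchical_order(
    matrix: ExpressionMatrix, axis: str = "features"
) -> tuple[list[str], np.ndarray]:
    """Ward-linkage leaf order on the 1 - r dissimilarity, for heat maps.

    ``axis`` is 'features' (rows) or 'samples' (columns). Returns the
    ordered labels and the linkage matrix (for dendrogram rendering).
    """
    if axis not in ("features", "samples"):
        raise ValueError("axis must be 'features' or 'samples'")
    work = matrix if axis == "features" else ExpressionMatrix(
        matrix.data.T, matrix.kind, raw=matrix.raw
    )
    labels = work.feature_ids
    if len(labels) < 2:
        raise ValueError("need at least 2 items to order")
    d = correlation_dissimilarity(work)
    # Ward update applied directly to the provided dissimilarities
    Z = linkage(squareform(d, checks=False), method="ward")
    order = leaves_list(Z)
    return [labels[i] for i in order], Z
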