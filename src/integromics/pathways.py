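"""Parametric analysis of gene set enrichment (PAGE).

For each sample column, with mu and delta the mean and (n-1) SD of all gene
values in that column and Sm the mean over a set's m matched members, the
pathway score is the Z statistic

    Z = (Sm - mu) * sqrt(m) / delta.

Scores are computed per sample on the normalized log2 matrix, yielding a
pathway x sample matrix that downstream is clustered and template-assigned
exactly like the gene matrix. Z is invariant to shifting a column and to
positive rescaling, and is approximately standard Normal for random sets
drawn from an i.i.d. column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .model import ExpressionMatrix, FilterReport, GeneSet


def page_scores(
    matrix: ExpressionMatrix,
    gene_sets: list[GeneSet],
    min_members: int = 3,
) -> tuple[ExpressionMatrix, FilterReport]:
    """PAGE Z-score matrix (pathways x samples) for ``gene_sets``.

    Genes absent from the matrix are excluded from a set's member count m;
    sets with m < ``min_members`` are dropped (reported). A column with zero
    SD raises, naming the sample.
    """
    matrix.require_complete("PAGE scoring")
    values = matrix.values
    mu = values.mean(axis=0)
    delta = values.std(axis=0, ddof=1)
    for j, d in enumerate(delta):
        if not d > 0:
            raise ValueError(
                f"sample {matrix.sample_ids[j]!r} has zero expression SD; "
                "PAGE scores are undefined"
            )
    index = {g: i for i, g in enumerate(matrix.feature_ids)}
    rows, names, dropped = [], [], 0
    for gs in gene_sets:
        members = [index[g] for g in gs.members if g in index]
        m = len(members)
        if m < min_members:
            dropped += 1
            continue
        sm = values[members].mean(axis=0)
        rows.append((sm - mu) * np.sqrt(m) / delta)
        names.append(gs.name)
    data = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, matrix.shape[1])),
        index=pd.Index(names, name="pathway"),
        columns=matrix.sample_ids,
    )
    report = FilterReport(
        n_input=len(gene_sets),
        n_removed=dropped,
        n_retained=len(names),
        rule=f"min_members(>={min_members})",
        threshold=float(min_members),
    )
    return ExpressionMatrix(data, kind="pathway"), report


class PAGEScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping a samples x genes matrix to samples x pathways
    PAGE Z-scores.

    Parameters
    ----------
    gene_sets : list of GeneSet
    min_members : int
        Sets with fewer matched members are dropped at fit.
    """

    def __init__(self, gene_sets: list[GeneSet], min_members: int = 3):
        self.gene_sets = gene_sets
        self.min_members = min_members

    def fit(self, X, y=None, feature_names=None):
        X = self._to_frame(X, feature_names)
        index = {g: i for i, g in enumerate(X.columns)}
        self.members_: dict[str, list[int]] = {}
        for gs in self.gene_sets:
            members = [index[g] for g in gs.members if g in index]
            if len(members) >= self.min_members:
                self.members_[gs.name] = members
        self.pathway_names_ = list(self.members_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, feature_names=None):
        check_is_fitted(self, "members_")
        X = self._to_frame(X, feature_names)
        values = X.to_numpy(dtype=float).T  # genes x samples
        mu = values.mean(axis=0)
        delta = values.std(axis=0, ddof=1)
        if (delta <= 0).any():
            j = int(np.argmax(delta <= 0))
            raise ValueError(f"sample index {j} has zero expression SD")
        out = np.empty((X.shape[0], len(self.pathway_names_)))
        for p, name in enumerate(self.pathway_names_):
            members = self.members_[name]
            sm = values[members].mean(axis=0)
            out[:, p] = (sm - mu) * np.sqrt(len(members)) / delta
        return pd.DataFrame(out, index=X.index, columns=self.pathway_names_)

    @staticmethod
    def _to_frame(X, feature_names):
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"g{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=feature_names)
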