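"""miRNA-target integration and target-pathway derivation.

Predicted (miRNA, gene) pairs are first tightened with the per-miRNA lower
5%-quantile context-score cutoff, then intersected with the pattern
assignments: a pair survives only when the miRNA and the gene carry the
same group id (the gene side's template semantics are already direction-
reversed, so identical ids mean "repressor up, target down" with matching
timing). Pathways become target pathways when their own PAGE-score pattern
assignment matches the group and they share at least one member with that
group's integrated gene list. A final ranking orders pathways per adjacent
transition by score change and Tukey-adjusted p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import tukey_hsd
from .model import (
    ExpressionMatrix,
    GeneSet,
    PatternAssignment,
    StageDesign,
    TargetPrediction,
    transition_name,
)
from .patterns import FIRST_CHANGE_STEP


def filter_targets_by_context_score(
    predictions: list[TargetPrediction],
    quantile: float = 0.05,
    per_mirna: bool = True,
) -> list[TargetPrediction]:
    """Keep the most reliable predictions: total context score at or below
    the lower ``quantile`` cutoff (most negative tail).

    By default the cutoff is computed per miRNA, applying only to miRNAs
    with more than one prediction; single-hit miRNAs are kept as-is. Ties at
    the cutoff are retained. ``per_mirna=False`` applies one global cutoff.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    if not predictions:
        return []
    if not per_mirna:
        cutoff = float(
            np.quantile([p.total_context_score for p in predictions], quantile)
        )
        return [p for p in predictions if p.total_context_score <= cutoff]
    by_mirna: dict[str, list[TargetPrediction]] = {}
    for p in predictions:
        by_mirna.setdefault(p.mirna, []).append(p)
    kept: list[TargetPrediction] = []
    for plist in by_mirna.values():
        if len(plist) == 1:
            kept.extend(plist)
            continue
        cutoff = float(np.quantile([p.total_context_score for p in plist], quantile))
        kept.extend(p for p in plist if p.total_context_score <= cutoff)
    return kept


def representative_mirna_per_family(
    predictions: list[TargetPrediction],
) -> dict[str, str]:
    """Per family, the miRNA whose best (lowest) total context score is the
    most favorable; exact ties break to the lexicographically first id."""
    best_per_mirna: dict[tuple[str, str], float] = {}
    for p in predictions:
        key = (p.family, p.mirna)
        if key not in best_per_mirna or p.total_context_score < best_per_mirna[key]:
            best_per_mirna[key] = p.total_context_score
    representative: dict[str, tuple[float, str]] = {}
    for (family, mirna), score in sorted(best_per_mirna.items()):
        if family not in representative or (score, mirna) < representative[family]:
            representative[family] = (score, mirna)
    return {family: mirna for family, (_, mirna) in representative.items()}


def integrate_mirna_mrna(
    mirna_assignment: PatternAssignment,
    gene_assignment: PatternAssignment,
    predictions: list[TargetPrediction],
    design: StageDesign | None = None,
) -> pd.DataFrame:
    """Integrated (miRNA, gene) pairs: predicted, both assigned, same group.

    Returns a DataFrame with columns mirna, gene, group, pathway (NaN at
    this step) and transition_of_first_change (when ``design`` is given).
    """
    mirna_groups = mirna_assignment.group_of()
    gene_groups = gene_assignment.group_of()
    rows = []
    for p in predictions:
        group = mirna_groups.get(p.mirna)
        if group is None or gene_groups.get(p.gene) != group:
            continue
        first = (
            transition_name(design.transitions()[FIRST_CHANGE_STEP[group]])
            if design is not None
            else ""
        )
        rows.append(
            {
                "mirna": p.mirna,
                "gene": p.gene,
                "group": group,
                "pathway": np.nan,
                "transition_of_first_change": first,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mirna", "gene", "group", "pathway", "transition_of_first_change"],
    ).drop_duplicates(subset=["mirna", "gene"], ignore_index=True)


def derive_target_pathways(
    triples: pd.DataFrame,
    pathway_assignment: PatternAssignment,
    gene_sets: list[GeneSet],
) -> pd.DataFrame:
    """Expand integrated pairs with their target pathways.

    A pathway qualifies for a group when its PAGE-score pattern assignment
    carries that group id and its membership overlaps the group's integrated
    gene list; each overlapping (miRNA, gene) pair gains a row per pathway.
    Pairs whose gene belongs to no qualifying pathway keep a single row with
    pathway = NaN.
    """
    members = {gs.name: gs.members for gs in gene_sets}
    pathway_groups = pathway_assignment.group_of()
    genes_by_group: dict[str, set[str]] = {}
    for _, row in triples.iterrows():
        genes_by_group.setdefault(row["group"], set()).add(row["gene"])
    qualifying: dict[str, list[str]] = {}
    for pathway, group in pathway_groups.items():
        overlap = members.get(pathway, frozenset()) & genes_by_group.get(group, set())
        if overlap:
            qualifying.setdefault(group, []).append(pathway)
    rows = []
    for _, row in triples.iterrows():
        matched = [
            p
            for p in qualifying.get(row["group"], [])
            if row["gene"] in members[p]
        ]
        if not matched:
            rows.append(dict(row))
            continue
        for pathway in sorted(matched):
            new = dict(row)
            new["pathway"] = pathway
            rows.append(new)
    return pd.DataFrame(rows, columns=triples.columns)


def target_pathway_names(expanded: pd.DataFrame) -> set[str]:
    return set(expanded["pathway"].dropna())


def rank_top_pathways(
    pathway_scores: ExpressionMatrix,
    design: StageDesign,
    transition: tuple[str, str],
    n_top: int = 2,
    lfc: float = 2.0,
    alpha: float = 0.01,
    pathways: list[str] | None = None,
) -> pd.DataFrame:
    """Top pathways most altered across one adjacent transition.

    Reuses the Tukey machinery on the pathway-score matrix: pathways passing
    |score change| >= ``lfc`` and Tukey p_adj < ``alpha`` for the transition
    pair are ranked by |change| (then p_adj); the best ``n_top`` are
    returned with columns pathway, transition, delta_score, p_adj, rank.
    An empty frame means no pathway met the cutoffs.
    """
    matrix = pathway_scores if pathways is None else pathway_scores.subset(
        features=[p for p in pathways if p in pathway_scores.feature_ids]
    )
    empty = pd.DataFrame(
        columns=["pathway", "transition", "delta_score", "p_adj", "rank"]
    )
    if matrix.shape[0] == 0:
        return empty
    pairwise = tukey_hsd(matrix, design)
    a, b = transition
    sub = pairwise[(pairwise["stage_a"] == a) & (pairwise["stage_b"] == b)].copy()
    if sub.empty:
        raise ValueError(f"transition {transition!r} not found in the design")
    passing = sub[(sub["mean_diff"].abs() >= lfc) & (sub["p_adj"] < alpha)].copy()
    if passing.empty:
        return empty
    passing["abs_change"] = passing["mean_diff"].abs()
    passing = passing.sort_values(
        ["abs_change", "p_adj", "feature"], ascending=[False, True, True]
    ).head(n_top)
    return pd.DataFrame(
        {
            "pathway": passing["feature"].to_numpy(),
            "transition": transition_name(transition),
            "delta_score": passing["mean_diff"].to_numpy(),
            "p_adj": passing["p_adj"].to_numpy(),
            "rank": np.arange(1, len(passing) + 1),
        }
    )
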