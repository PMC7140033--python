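"""Shared data model for the staged-progression integromics pipeline.

The pipeline operates on log2-scale feature-by-sample expression matrices
collected over an ordered series of histologic stages (default: the MCF10A
progression panel P -> AT1 -> DCIS -> CA1D, three replicates per stage),
MSigDB-style gene-set collections, TargetScan-style miRNA target prediction
tables, and clinical survival tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_STAGES: tuple[str, ...] = ("P", "AT1", "DCIS", "CA1D")

STAGE_ORDINALS: dict[str, int] = {"I": 1, "II": 2, "III": 3, "IV": 4}

VALID_KINDS = ("miRNA", "gene", "pathway")


def transitions(stages: tuple[str, ...] | list[str] = DEFAULT_STAGES) -> list[tuple[str, str]]:
    """Adjacent-stage transitions of an ordered stage list."""
    stages = list(stages)
    return [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]


def transition_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}->{pair[1]}"


class ExpressionMatrix:
    """Features x samples log2-scale abundance matrix with a kind tag.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns.
    kind
        One of ``"miRNA"``, ``"gene"`` or ``"pathway"``.
    raw
        If True, values are on the raw (non-log) scale.
    """

    def __init__(self, data: pd.DataFrame, kind: str, raw: bool = False):
        if kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {kind!r}")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = data.to_numpy()
        if values.size and np.isinf(values.astype(float, copy=False)).any():
            raise ValueError("expression values must be finite (or NaN-flagged missing)")
        self.data = data.astype(float)
        self.kind = kind
        self.raw = bool(raw)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def require_complete(self, context: str = "this operation") -> None:
        """Raise if any cell is missing; inferential steps demand complete triplicates."""
        if self.has_missing:
            na = self.data.isna()
            row = na.any(axis=1).idxmax()
            col = na.loc[row].idxmax()
            raise ValueError(
                f"missing expression value at feature {row!r}, sample {col!r}; "
                f"{context} requires a complete matrix"
            )

    def subset(self, features=None, samples=None) -> "ExpressionMatrix":
        data = self.data
        if features is not None:
            data = data.loc[list(features)]
        if samples is not None:
            data = data[list(samples)]
        return ExpressionMatrix(data, self.kind, raw=self.raw)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"ExpressionMatrix(kind={self.kind!r}, shape={self.shape})"


class StageDesign:
    """Sample -> (stage, replicate) mapping over an ordered stage list."""

    def __init__(
        self,
        assignments: dict[str, tuple[str, int]],
        stages: tuple[str, ...] | list[str] = DEFAULT_STAGES,
    ):
        self.stages = tuple(stages)
        if len(self.stages) < 2:
            raise ValueError("a stage design needs at least 2 ordered stages")
        for sample, (stage, rep) in assignments.items():
            if stage not in self.stages:
                raise ValueError(f"sample {sample!r} has unknown stage {stage!r}")
            if not (isinstance(rep, (int, np.integer)) and rep > 0):
                raise ValueError(f"sample {sample!r} has non-positive replicate {rep!r}")
        self.assignments = dict(assignments)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def stage_of(self, sample: str) -> str:
        return self.assignments[sample][0]

    def samples_of(self, stage: str) -> list[str]:
        return [s for s, (st, _) in self.assignments.items() if st == stage]

    def stage_labels(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without a design entry: {missing[:3]}")
        return np.array([self.assignments[s][0] for s in sample_ids])

    def transitions(self) -> list[tuple[str, str]]:
        return transitions(self.stages)

    def validate_for_inference(self, matrix: ExpressionMatrix) -> None:
        """Every sample covered, >=2 stages present, >=2 replicates per stage."""
        labels = self.stage_labels(matrix.sample_ids)
        present = [s for s in self.stages if (labels == s).sum() > 0]
        if len(present) < 2:
            raise ValueError("inferential operations need >=2 stages with samples")
        for s in present:
            if (labels == s).sum() < 2:
                raise ValueError(f"stage {s!r} has <2 replicates")
        matrix.require_complete("inference")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "stage": st, "replicate": rep}
            for s, (st, rep) in self.assignments.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, stages=None) -> "StageDesign":
        if stages is None:
            seen = list(dict.fromkeys(frame["stage"]))
            stages = tuple(seen)
        assignments = {
            str(r["sample"]): (str(r["stage"]), int(r["replicate"]))
            for _, r in frame.iterrows()
        }
        return cls(assignments, stages=stages)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (MSigDB-style), e.g. from the C2/C3/C4/C6 collections."""

    name: str
    members: frozenset[str]
    collection: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class TargetPrediction:
    """One (miRNA, gene) prediction with its summed (total) context score.

    More negative total context score = stronger predicted repression.
    """

    mirna: str
    family: str
    gene: str
    total_context_score: float

    def __post_init__(self):
        if not math.isfinite(self.total_context_score):
            raise ValueError(
                f"non-finite context score for ({self.mirna}, {self.gene})"
            )


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject of a survival cohort (time in months)."""

    subject_id: str
    time: float
    event: int
    age: float
    stage: int
    marker: float

    def __post_init__(self):
        if not self.time > 0:
            raise ValueError(f"subject {self.subject_id!r}: time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.subject_id!r}: event must be 0 or 1")
        if self.stage not in (1, 2, 3, 4):
            raise ValueError(f"subject {self.subject_id!r}: stage must be ordinal 1-4")


def survival_records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "time": r.time,
                "event": r.event,
                "age": r.age,
                "stage": r.stage,
                "marker": r.marker,
            }
            for r in records
        ]
    )


@dataclass
class FilterReport:
    """Bookkeeping for a row filter: n_input = n_removed + n_retained."""

    n_input: int
    n_removed: int
    n_retained: int
    rule: str
    threshold: float | None = None

    def __post_init__(self):
        if self.n_input != self.n_removed + self.n_retained:
            raise ValueError("inconsistent filter report counts")


@dataclass
class PatternAssignment:
    """Feature -> progression-template assignment with quality scores.

    ``table`` columns: template ('G1'..'G8' or 'unassigned'), cluster,
    match_score (Pearson r of the feature's cluster centroid vs the template
    shape), silhouette, reason (empty for assigned features).
    """

    table: pd.DataFrame
    reversed_semantics: bool = False

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["template"] != "unassigned"]

    def group_of(self) -> dict[str, str]:
        return dict(self.assigned["template"])

    def counts(self) -> dict[str, int]:
        return self.table["template"].value_counts().to_dict()
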