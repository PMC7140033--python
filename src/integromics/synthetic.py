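"""Synthetic study-design generator with known planted truth.

Emulates the four-stage, triplicate progression design the pipeline was
built for: log2-scale miRNA and gene matrices in which a chosen number of
features follow each of the eight progression templates (genes with the
sign-mirrored shapes, since a repressed target moves opposite to its
miRNA), a fraction of exactly constant (zero-variance) features, flat
noise-only background features, a TargetScan-style target map linking
planted miRNAs to reversed-pattern genes of the same group (plus weak-score
decoys against background genes), gene sets enriched for planted genes
(plus null sets drawn from the background pool), and a survival cohort with
a proportional-hazards effect of a median-split marker.

Every generated object is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_STAGES,
    ExpressionMatrix,
    GeneSet,
    StageDesign,
    SurvivalRecord,
    TargetPrediction,
)
from .patterns import TEMPLATE_IDS, _SHAPES


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the printed design of the motivating study: 1,983
    annotated miRNAs of which 1,533 are constant across all samples; 17,708
    genes; 213 patterned miRNAs (83% in the increasing groups, none in G8)
    and the published per-group gene counts; 4 stages x 3 replicates.
    Step sizes are equal across a template's active transitions (the
    templates fix shapes, not magnitudes): effect_size log2 units per step,
    with additive Gaussian replicate noise of noise_sd log2 units.
    """

    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_replicates: int = 3
    n_mirna: int = 1983
    n_gene: int = 17708
    mirna_n_zero_variance: int = 1533
    gene_n_zero_variance: int = 0
    mirna_per_template: tuple[int, ...] = (50, 70, 35, 22, 6, 8, 22, 0)
    gene_per_template: tuple[int, ...] = (946, 1751, 452, 166, 248, 299, 1126, 413)
    effect_size: float = 3.0
    noise_sd: float = 0.3
    baseline_low: float = 4.0
    baseline_high: float = 12.0
    # target map
    targets_per_mirna: int = 2
    decoys_per_mirna: int = 30
    planted_score_low: float = -1.0
    planted_score_high: float = -0.6
    decoy_score_low: float = -0.2
    decoy_score_high: float = 0.0
    family_size: int = 2
    # gene sets
    n_gene_sets: int = 60
    n_enriched_sets: int = 16
    set_size: int = 20
    enriched_purity: float = 0.9

    def __post_init__(self):
        if len(self.mirna_per_template) != 8 or len(self.gene_per_template) != 8:
            raise ValueError("per-template counts must have 8 entries (G1..G8)")
        if sum(self.mirna_per_template) + self.mirna_n_zero_variance > self.n_mirna:
            raise ValueError("miRNA template + zero-variance counts exceed n_mirna")
        if sum(self.gene_per_template) + self.gene_n_zero_variance > self.n_gene:
            raise ValueError("gene template + zero-variance counts exceed n_gene")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be non-negative")
        if self.set_size > self.n_gene:
            raise ValueError("set_size exceeds n_gene")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generator."""

    mirna_pattern: dict[str, str] = field(default_factory=dict)
    gene_pattern: dict[str, str] = field(default_factory=dict)
    planted_effect: dict[str, float] = field(default_factory=dict)
    planted_targets: set[tuple[str, str]] = field(default_factory=set)
    planted_enriched_sets: dict[str, str] = field(default_factory=dict)
    survival_beta: float | None = None

    def planted_features(self, side: str) -> dict[str, str]:
        pattern = self.mirna_pattern if side == "miRNA" else self.gene_pattern
        return {f: g for f, g in pattern.items() if g in TEMPLATE_IDS}

    def genes_of_group(self, group: str) -> list[str]:
        return [g for g, grp in self.gene_pattern.items() if grp == group]

    def mirnas_of_group(self, group: str) -> list[str]:
        return [m for m, grp in self.mirna_pattern.items() if grp == group]


def _sample_ids(config: GeneratorConfig) -> tuple[list[str], StageDesign]:
    ids, assignments = [], {}
    for stage in config.stages:
        for rep in range(1, config.n_replicates + 1):
            sid = f"{stage}_{rep}"
            ids.append(sid)
            assignments[sid] = (stage, rep)
    return ids, StageDesign(assignments, stages=config.stages)


def _make_matrix(
    rng: np.random.Generator,
    config: GeneratorConfig,
    prefix: str,
    n_features: int,
    per_template: tuple[int, ...],
    n_zero_variance: int,
    reversed_shapes: bool,
    pattern_out: dict[str, str],
) -> pd.DataFrame:
    sample_ids, design = _sample_ids(config)
    n_samples = len(sample_ids)
    stage_idx = np.array(
        [list(config.stages).index(design.stage_of(s)) for s in sample_ids]
    )
    width = len(str(n_features))
    feature_ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n_features)]
    baselines = rng.uniform(config.baseline_low, config.baseline_high, n_features)
    values = np.empty((n_features, n_samples))
    row = 0
    for tid, count in zip(TEMPLATE_IDS, per_template):
        shape = np.array(_SHAPES[tid], dtype=float)
        if reversed_shapes:
            shape = -shape
        for _ in range(count):
            means = baselines[row] + config.effect_size * shape
            values[row] = means[stage_idx]
            pattern_out[feature_ids[row]] = tid
            row += 1
    n_flat = n_features - n_zero_variance - row
    for _ in range(n_flat):
        values[row] = baselines[row]
        pattern_out[feature_ids[row]] = "flat"
        row += 1
    noise = rng.normal(0.0, config.noise_sd, (row, n_samples)) if config.noise_sd > 0 else 0.0
    values[:row] += noise
    for _ in range(n_zero_variance):
        values[row] = baselines[row]  # exactly constant: no replicate noise
        pattern_out[feature_ids[row]] = "zero_variance"
        row += 1
    return pd.DataFrame(values, index=feature_ids, columns=sample_ids)


def generate_progression_dataset(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, StageDesign, SyntheticTruth]:
    """Generate the paired miRNA/gene matrices, design and planted truth."""
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()
    mirna_data = _make_matrix(
        rng, config, "miR-", config.n_mirna, config.mirna_per_template,
        config.mirna_n_zero_variance, reversed_shapes=False,
        pattern_out=truth.mirna_pattern,
    )
    gene_data = _make_matrix(
        rng, config, "GENE", config.n_gene, config.gene_per_template,
        config.gene_n_zero_variance, reversed_shapes=True,
        pattern_out=truth.gene_pattern,
    )
    for f, g in list(truth.mirna_pattern.items()) + list(truth.gene_pattern.items()):
        if g in TEMPLATE_IDS:
            truth.planted_effect[f] = config.effect_size
    _, design = _sample_ids(config)
    return (
        ExpressionMatrix(mirna_data, kind="miRNA"),
        ExpressionMatrix(gene_data, kind="gene"),
        design,
        truth,
    )


def generate_target_map(
    truth: SyntheticTruth, config: GeneratorConfig
) -> list[TargetPrediction]:
    """TargetScan-style predictions: planted same-group (direction-reversed)
    pairs with strong scores, decoy pairs against background genes with weak
    near-zero scores. Planted pairs are recorded in ``truth.planted_targets``."""
    rng = np.random.default_rng(config.seed + 1)
    background = [g for g, grp in truth.gene_pattern.items() if grp == "flat"]
    predictions: list[TargetPrediction] = []
    for group in TEMPLATE_IDS:
        mirnas = truth.mirnas_of_group(group)
        genes = truth.genes_of_group(group)
        for i, mirna in enumerate(mirnas):
            family = f"fam-{group}-{i // max(config.family_size, 1)}"
            if genes:
                for t in range(config.targets_per_mirna):
                    gene = genes[(i * config.targets_per_mirna + t) % len(genes)]
                    if (mirna, gene) in truth.planted_targets:
                        continue
                    score = rng.uniform(
                        config.planted_score_low, config.planted_score_high
                    )
                    predictions.append(
                        TargetPrediction(mirna, family, gene, float(score))
                    )
                    truth.planted_targets.add((mirna, gene))
            if background and config.decoys_per_mirna:
                n_decoys = min(config.decoys_per_mirna, len(background))
                decoy_genes = rng.choice(background, size=n_decoys, replace=False)
                scores = rng.uniform(
                    config.decoy_score_low, config.decoy_score_high, n_decoys
                )
                predictions.extend(
                    TargetPrediction(mirna, family, str(g), float(s))
                    for g, s in zip(decoy_genes, scores)
                )
    return predictions


def generate_gene_sets(
    truth: SyntheticTruth, config: GeneratorConfig
) -> list[GeneSet]:
    """Gene-set collection: enriched sets drawn (mostly) from one planted
    group's genes; null sets reference unmeasured gene ids (as real pathway
    collections largely do for any single assay), so they carry no
    progression signal at all. Per-sample standardization of the pathway
    score couples any set of measured genes to the stage structure, so sets
    meant to be null must stay outside the assay to remain truly null; see
    the methods note. Enriched membership is recorded in
    ``truth.planted_enriched_sets``."""
    rng = np.random.default_rng(config.seed + 2)
    if config.set_size > len(truth.gene_pattern):
        raise ValueError("set_size exceeds the number of generated genes")
    background = [g for g, grp in truth.gene_pattern.items() if grp == "flat"]
    groups_with_genes = [g for g in TEMPLATE_IDS if truth.genes_of_group(g)]
    sets: list[GeneSet] = []
    n_enriched = min(config.n_enriched_sets, config.n_gene_sets)
    for i in range(n_enriched):
        group = groups_with_genes[i % len(groups_with_genes)]
        pool = truth.genes_of_group(group)
        n_core = min(
            max(int(round(config.enriched_purity * config.set_size)), 1), len(pool)
        )
        members = list(rng.choice(pool, size=n_core, replace=False))
        n_fill = config.set_size - n_core
        if n_fill and background:
            members += list(
                rng.choice(background, size=min(n_fill, len(background)), replace=False)
            )
        name = f"SET_{group}_{i:02d}"
        sets.append(GeneSet(name=name, members=frozenset(members), collection="SYN"))
        truth.planted_enriched_sets[name] = group
    n_external = max(4 * config.set_size, 1)
    for i in range(config.n_gene_sets - n_enriched):
        members = rng.integers(0, n_external, size=config.set_size)
        sets.append(
            GeneSet(
                name=f"NULL_{i:03d}",
                members=frozenset(f"EXT{int(m):05d}" for m in members),
                collection="SYN",
            )
        )
    return sets


def _censor_horizon(rates: np.ndarray, target: float) -> float:
    """Solve for the Uniform(0, u) censoring horizon giving the requested
    expected censored fraction under exponential event times."""

    def frac(u: float) -> float:
        lu = rates * u
        return float(np.mean((1.0 - np.exp(-lu)) / lu))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target and hi < 1e9:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival_cohort(
    n: int,
    beta: float,
    censor_rate: float,
    seed: int,
    baseline_hazard: float = 1.0 / 60.0,
) -> list[SurvivalRecord]:
    """Survival cohort with a proportional-hazards marker effect.

    Event times are exponential with hazard ``baseline_hazard`` for subjects
    whose marker lies above the cohort median and
    ``baseline_hazard * exp(beta)`` for those at or below it, so the true
    log hazard ratio of the Low-vs-High median split equals ``beta``.
    Censoring times are independent Uniform(0, u) with u solved to hit the
    requested expected censored fraction. Age and tumor stage are drawn
    independently of survival (Uniform(30, 85); stages I-IV with
    probabilities 0.4/0.3/0.2/0.1).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 <= censor_rate <= 1.0):
        raise ValueError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    marker = rng.normal(5.0, 1.0, n)
    low = marker <= np.median(marker)
    rates = np.where(low, baseline_hazard * np.exp(beta), baseline_hazard)
    event_times = rng.exponential(1.0 / rates)
    age = rng.uniform(30.0, 85.0, n)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.4, 0.3, 0.2, 0.1])
    if censor_rate <= 0.0:
        times, events = event_times, np.ones(n, dtype=int)
    elif censor_rate >= 1.0:
        times = rng.uniform(1e-6, 1.0 / baseline_hazard, n)
        events = np.zeros(n, dtype=int)
    else:
        u = _censor_horizon(rates, censor_rate)
        censor_times = rng.uniform(1e-9, u, n)
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    times = np.maximum(times, 1e-9)
    return [
        SurvivalRecord(
            subject_id=f"S{i:05d}",
            time=float(times[i]),
            event=int(events[i]),
            age=float(age[i]),
            stage=int(stage[i]),
            marker=float(marker[i]),
        )
        for i in range(n)
    ]


def small_config(seed: int = 0, noise_sd: float = 0.3, **overrides) -> GeneratorConfig:
    """A reduced configuration (same structure, desk-scale sizes) used by
    tests and examples: 8 planted miRNAs/genes per template, 40 background
    and 40 zero-variance miRNAs, a 600-gene background pool (so planted
    signal does not dominate the per-sample score standardization), and 36
    gene sets with three enriched per group."""
    base = dict(
        seed=seed,
        noise_sd=noise_sd,
        n_mirna=8 * 8 + 40 + 40,
        mirna_n_zero_variance=40,
        mirna_per_template=(8,) * 8,
        n_gene=8 * 8 + 600,
        gene_n_zero_variance=0,
        gene_per_template=(8,) * 8,
        n_gene_sets=36,
        n_enriched_sets=24,
        set_size=10,
        decoys_per_mirna=38,
    )
    base.update(overrides)
    return GeneratorConfig(**base)
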