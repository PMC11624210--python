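"""Synthetic cohorts with the statistical structure the classifier assumes.

Per abnormal junction and sample, location coverage n is drawn from a
negative-binomial-shaped distribution (expression variation is not part of
the classifier's model, only the conditional k | n is); the abnormal read
count k is then beta-binomial with a class-dependent mean fraction: the
Active-class mean is ``effect`` times the Inactive mean at matched
concentration. Every abnormal junction has an annotated partner junction
sharing its donor coordinate and carrying the remaining n - k reads, so
junction pairing recovers (k, n) exactly. Decoy unannotated junctions are
drawn identically for both classes; Ambiguous samples are a stated mixture
of Active-like and Inactive-like generators so the reclassification rule
has a recoverable ground truth. Mutation and segment tables are emitted
consistently with the intended labels (Active samples carry an oncogenic
KEAP1 record; Ambiguous samples a CUL3 record or an NFE2L2 amplification
segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    JunctionRecord,
    MutationRecord,
    SegmentRecord,
    write_count_matrix,
    write_junction_table,
    write_labels,
    write_mutations,
    write_segments,
)
from .labeling import SkippingConfig, label_samples
from .regions import NFE2L2_REGION


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults give a clearly separable two-class problem: 60 Active vs 600
    Inactive samples (a 1:10 imbalance, echoing the rarity of pathway
    activation), 40 true features with Inactive-class abnormal fractions of
    1-4% at concentration 50 and a threefold Active-class enrichment, 20
    decoy junctions with no class effect, and Ambiguous samples drawn from
    the Active-like generator with probability 0.8.
    """

    seed: int  # mandatory; no implicit randomness
    n_active: int = 60
    n_inactive: int = 600
    n_ambiguous: int = 30
    n_features: int = 40
    n_decoy_junctions: int = 20
    n_annotated: int = 30
    coverage_mean: float = 200.0
    coverage_shape: float = 5.0
    feature_mean_low: float = 0.01
    feature_mean_high: float = 0.04
    concentration: float = 50.0
    effect: float = 3.0
    ambiguous_active_fraction: float = 0.8
    n_cohorts: int = 2

    def __post_init__(self):
        for name in ("n_active", "n_inactive", "n_features", "n_cohorts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_ambiguous < 0 or self.n_decoy_junctions < 0 or self.n_annotated < 0:
            raise ValueError("counts must be nonnegative")
        if self.effect < 1:
            raise ValueError("effect must be >= 1")
        if self.effect * self.feature_mean_high >= 1:
            raise ValueError(
                "effect * feature_mean_high must stay below 1 (mean fraction >= 1 is impossible)"
            )
        if not 0 <= self.ambiguous_active_fraction <= 1:
            raise ValueError("ambiguous_active_fraction must lie in [0, 1]")


@dataclass
class SimulatedCohort:
    junctions: list[JunctionRecord]
    counts: CountMatrix
    labels: pd.DataFrame  # sample_id, top_mutation_class, label, cohort
    mutations: list[MutationRecord]
    segments: list[SegmentRecord]
    cohort_map: dict[str, str]
    truth: dict
    config: SimConfig | None = None


def _betabin_draws(rng, n, alpha, beta):
    p = rng.beta(alpha, beta, size=np.shape(n))
    return rng.binomial(n, p)


def _nb_counts(rng, mean, shape, size):
    # negative binomial parameterized by mean and shape (size) parameter
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate junction table, count matrix, labels, mutation table and
    segment table for one synthetic cohort. Deterministic in ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    sample_ids = (
        [f"A{i:04d}" for i in range(cfg.n_active)]
        + [f"I{i:04d}" for i in range(cfg.n_inactive)]
        + [f"U{i:04d}" for i in range(cfg.n_ambiguous)]
    )
    n_samples = len(sample_ids)
    is_active_like = np.zeros(n_samples, dtype=bool)
    is_active_like[: cfg.n_active] = True
    amb_start = cfg.n_active + cfg.n_inactive
    amb_active = rng.random(cfg.n_ambiguous) < cfg.ambiguous_active_fraction
    is_active_like[amb_start:] = amb_active

    # per-feature Inactive-class mean fraction and beta parameters
    mu = rng.uniform(cfg.feature_mean_low, cfg.feature_mean_high, size=cfg.n_features)
    s = cfg.concentration
    a_in, b_in = mu * s, (1 - mu) * s
    mu_act = cfg.effect * mu
    a_ac, b_ac = mu_act * s, (1 - mu_act) * s

    junctions: list[JunctionRecord] = []
    rows: list[np.ndarray] = []
    row_ids: list[str] = []

    def add_row(rec: JunctionRecord, values: np.ndarray):
        junctions.append(rec)
        rows.append(values.astype(np.int64))
        row_ids.append(rec.junction_id)

    # true features: abnormal junction + annotated partner sharing its donor
    for j in range(cfg.n_features):
        base = 10_000 * (j + 1)
        n = _nb_counts(rng, cfg.coverage_mean, cfg.coverage_shape, n_samples)
        k = np.where(
            is_active_like,
            _betabin_draws(rng, n, a_ac[j], b_ac[j]),
            _betabin_draws(rng, n, a_in[j], b_in[j]),
        )
        add_row(JunctionRecord(f"abn{j}", "chr1", base + 100, base + 900, "+", False), k)
        add_row(JunctionRecord(f"nrm{j}", "chr1", base + 100, base + 1500, "+", True), n - k)

    # decoys: same generator for every sample, no class effect
    for j in range(cfg.n_decoy_junctions):
        base = 10_000 * (j + 1)
        n = _nb_counts(rng, cfg.coverage_mean, cfg.coverage_shape, n_samples)
        mu_d = rng.uniform(cfg.feature_mean_low, cfg.feature_mean_high)
        k = _betabin_draws(rng, n, mu_d * s, (1 - mu_d) * s)
        add_row(JunctionRecord(f"dec{j}", "chr3", base + 100, base + 900, "+", False), k)
        add_row(JunctionRecord(f"decn{j}", "chr3", base + 100, base + 1500, "+", True), n - k)

    # annotated background junctions (contribute to per-sample totals only)
    for j in range(cfg.n_annotated):
        base = 10_000 * (j + 1)
        n = _nb_counts(rng, 500.0, cfg.coverage_shape, n_samples)
        add_row(JunctionRecord(f"bg{j}", "chr5", base + 100, base + 900, "+", True), n)

    counts = CountMatrix(row_ids, sample_ids, np.vstack(rows))

    # alteration tables consistent with the intended labels
    mutations: list[MutationRecord] = []
    segments: list[SegmentRecord] = []
    for i in range(cfg.n_active):
        mutations.append(
            MutationRecord(f"A{i:04d}", "KEAP1", "Missense_Mutation", None, "Oncogenic", "p.R320Q")
        )
    for i in range(min(3, cfg.n_inactive)):  # a few harmless silent records
        mutations.append(MutationRecord(f"I{i:04d}", "KEAP1", "Silent", None, "Unannotated", None))
    for i in range(cfg.n_ambiguous):
        sid = f"U{i:04d}"
        if i % 2 == 0:
            mutations.append(
                MutationRecord(sid, "CUL3", "Missense_Mutation", None, "Unannotated", None)
            )
        else:
            segments.append(
                SegmentRecord(
                    sid,
                    NFE2L2_REGION.chrom,
                    NFE2L2_REGION.start - 50_000,
                    NFE2L2_REGION.end + 50_000,
                    0.7,
                )
            )

    labels = label_samples(
        sample_ids, mutations, counts, junctions, segments, map_version="initial"
    )
    cohort_map = {
        s: f"COHORT{i % cfg.n_cohorts}" for i, s in enumerate(sample_ids)
    }
    labels["cohort"] = [cohort_map[s] for s in labels["sample_id"]]

    truth = {
        "inactive_alpha": a_in,
        "inactive_beta": b_in,
        "active_alpha": a_ac,
        "active_beta": b_ac,
        "feature_mean_inactive": mu,
        "ambiguous_active_like": {f"U{i:04d}": bool(v) for i, v in enumerate(amb_active)},
    }
    return SimulatedCohort(junctions, counts, labels, mutations, segments, cohort_map, truth, cfg)


def make_worked_example() -> SimulatedCohort:
    """A tiny fixed dataset (7 junctions, 10 samples) with hand-checkable
    counts: one differential abnormal junction fully separating 4 Active
    from 4 Inactive samples (exact one-sided rank p = 1/70), one
    low-coverage decoy below the 10-read candidate filter, an NFE2L2
    exon-2-skipping junction supported by 2 reads in one Ambiguous sample,
    and an NFE2L2 amplification segment for the other."""
    junctions = [
        JunctionRecord("abn_diff", "chr1", 1000, 2000, "+", False),
        JunctionRecord("nrm_diff", "chr1", 1000, 3000, "+", True),
        JunctionRecord("dec_low", "chr1", 5000, 6000, "+", False),
        JunctionRecord("nrm_dec", "chr1", 5000, 7000, "+", True),
        JunctionRecord("skip", "chr2", 177233340, 177264531, "-", False),
        JunctionRecord("hk1", "chr1", 8000, 9000, "+", True),
        JunctionRecord("hk2", "chr1", 12000, 13000, "+", True),
    ]
    sample_ids = ["A1", "A2", "A3", "A4", "I1", "I2", "I3", "I4", "U1", "U2"]
    counts = CountMatrix(
        [j.junction_id for j in junctions],
        sample_ids,
        np.array(
            [
                #  A1   A2   A3   A4   I1   I2   I3   I4   U1   U2
                [30, 25, 28, 22, 1, 0, 2, 1, 20, 0],  # abn_diff
                [100, 100, 100, 100, 100, 100, 100, 100, 100, 100],  # nrm_diff
                [2, 0, 0, 0, 2, 0, 0, 0, 2, 0],  # dec_low
                [50, 50, 50, 50, 50, 50, 50, 50, 50, 50],  # nrm_dec
                [0, 0, 0, 0, 0, 0, 0, 0, 2, 0],  # skip
                [1000, 1000, 1000, 1000, 1000, 1000, 1000, 1000, 1000, 1000],  # hk1
                [800, 800, 800, 800, 800, 800, 800, 800, 800, 800],  # hk2
            ]
        ),
    )
    mutations = [
        MutationRecord(s, "KEAP1", "Missense_Mutation", None, "Oncogenic", "p.G333C")
        for s in ["A1", "A2", "A3", "A4"]
    ] + [
        MutationRecord("U1", "CUL3", "Missense_Mutation", None, "Unannotated", None),
        MutationRecord("I1", "KEAP1", "Silent", None, "Unannotated", None),
    ]
    segments = [
        SegmentRecord("U2", NFE2L2_REGION.chrom, NFE2L2_REGION.start - 50_000, NFE2L2_REGION.end + 50_000, 0.7),
        SegmentRecord("I2", "chr19", 10_400_000, 10_600_000, -0.9),
    ]
    labels = label_samples(sample_ids, mutations, counts, junctions, segments, map_version="initial")
    cohort_map = {s: "TOY" for s in sample_ids}
    labels["cohort"] = "TOY"
    return SimulatedCohort(junctions, counts, labels, mutations, segments, cohort_map, {}, None)


def write_dataset(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write the five input files (junctions, counts, labels, mutations,
    segments) in the formats the readers accept; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "junctions": str(outdir / "junctions.tsv"),
        "counts": str(outdir / "counts.tsv"),
        "labels": str(outdir / "labels.tsv"),
        "mutations": str(outdir / "mutations.tsv"),
        "segments": str(outdir / "segments.seg"),
    }
    write_junction_table(cohort.junctions, paths["junctions"])
    write_count_matrix(cohort.counts, paths["counts"])
    write_labels(cohort.labels, paths["labels"])
    write_mutations(cohort.mutations, paths["mutations"])
    write_segments(cohort.segments, paths["segments"])
    return paths
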