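"""Mapping of somatic alterations to mutation functionality classes and of
samples to Active / Ambiguous / Inactive.

Eight mutation classes are recognized, ranked by a fixed hierarchy (the
highest-ranked class present becomes a sample's representative class):

1. oncogenic KEAP1 mutations
2. NFE2L2 exon-2 hotspot mutations
3. KEAP1 mutations not annotated oncogenic
4. NFE2L2 exon-2 non-hotspot mutations
5. NFE2L2 exon-2 (or 2+3) skipping, called from junction reads
6. CUL3 mutations
7. NFE2L2 copy-number amplification, called from SEG segments
8. NFE2L2 mutations in other exons

Each class carries a functionality label (Functional / Uncertain /
Non-Functional) under a given map version. The "initial" map is the prior
literature-based assignment; "post_evaluation" is the assignment after
score-based reintegration of the Uncertain classes. A sample is Active if
any of its classes is Functional, Ambiguous if none is Functional but at
least one is Uncertain, Inactive otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CountMatrix, JunctionRecord, MutationRecord, SegmentRecord
from .regions import KEAP1_REGION, NFE2L2_REGION, GeneRegion

logger = logging.getLogger(__name__)

#: log2 copy-ratio above which a segment covering NFE2L2 is called amplified
CNA_SEGMENT_MEAN_THRESHOLD = math.log2(3 / 2)

#: samples with more than this many somatic mutations are excluded
HYPERMUTATION_LIMIT = 20_000


class Functionality(Enum):
    FUNCTIONAL = "Functional"
    UNCERTAIN = "Uncertain"
    NON_FUNCTIONAL = "NonFunctional"


class MutationClass(Enum):
    KEAP1_ONCOGENIC = "KEAP1_Oncogenic"
    NFE2L2_EXON2_HOTSPOT = "NFE2L2_Exon2_Hotspot"
    KEAP1_NONONCOGENIC = "KEAP1_nonOncogenic"
    NFE2L2_EXON2_NONHOTSPOT = "NFE2L2_Exon2_nonHotspot"
    NFE2L2_EXON2_SKIPPING = "NFE2L2_Exon2_Skipping"
    CUL3_MUT = "CUL3_Mut"
    NFE2L2_CNA = "NFE2L2_CNA"
    NFE2L2_OTHEREXON = "NFE2L2_OtherExon"
    NONE = "None"


#: ranking used when a sample carries several classes (highest first)
HIERARCHY: tuple[MutationClass, ...] = (
    MutationClass.KEAP1_ONCOGENIC,
    MutationClass.NFE2L2_EXON2_HOTSPOT,
    MutationClass.KEAP1_NONONCOGENIC,
    MutationClass.NFE2L2_EXON2_NONHOTSPOT,
    MutationClass.NFE2L2_EXON2_SKIPPING,
    MutationClass.CUL3_MUT,
    MutationClass.NFE2L2_CNA,
    MutationClass.NFE2L2_OTHEREXON,
)
_RANK = {c: i for i, c in enumerate(HIERARCHY)}

_F, _U, _N = Functionality.FUNCTIONAL, Functionality.UNCERTAIN, Functionality.NON_FUNCTIONAL

FUNCTIONALITY_MAPS: dict[str, dict[MutationClass, Functionality]] = {
    # prior, literature-based assignment
    "initial": {
        MutationClass.KEAP1_ONCOGENIC: _F,
        MutationClass.NFE2L2_EXON2_HOTSPOT: _F,
        MutationClass.KEAP1_NONONCOGENIC: _U,
        MutationClass.NFE2L2_EXON2_NONHOTSPOT: _U,
        MutationClass.NFE2L2_EXON2_SKIPPING: _U,
        MutationClass.CUL3_MUT: _U,
        MutationClass.NFE2L2_CNA: _U,
        MutationClass.NFE2L2_OTHEREXON: _U,
        MutationClass.NONE: _N,
    },
    # after score-based reintegration of the Uncertain classes: non-oncogenic
    # KEAP1 and exon-2 skipping promoted to Functional, other-exon NFE2L2
    # demoted to Non-Functional, the rest stay Uncertain
    "post_evaluation": {
        MutationClass.KEAP1_ONCOGENIC: _F,
        MutationClass.NFE2L2_EXON2_HOTSPOT: _F,
        MutationClass.KEAP1_NONONCOGENIC: _F,
        MutationClass.NFE2L2_EXON2_NONHOTSPOT: _U,
        MutationClass.NFE2L2_EXON2_SKIPPING: _F,
        MutationClass.CUL3_MUT: _U,
        MutationClass.NFE2L2_CNA: _U,
        MutationClass.NFE2L2_OTHEREXON: _N,
        MutationClass.NONE: _N,
    },
    # alternative reading in which exon-2 non-hotspot mutations are demoted
    # and other-exon mutations stay Uncertain
    "post_evaluation_table1": {
        MutationClass.KEAP1_ONCOGENIC: _F,
        MutationClass.NFE2L2_EXON2_HOTSPOT: _F,
        MutationClass.KEAP1_NONONCOGENIC: _F,
        MutationClass.NFE2L2_EXON2_NONHOTSPOT: _N,
        MutationClass.NFE2L2_EXON2_SKIPPING: _F,
        MutationClass.CUL3_MUT: _U,
        MutationClass.NFE2L2_CNA: _U,
        MutationClass.NFE2L2_OTHEREXON: _U,
        MutationClass.NONE: _N,
    },
}

_ONCOGENIC_VALUES = {"oncogenic", "likelyoncogenic", "likely oncogenic", "likely_oncogenic"}
_HOTSPOT_VALUES = _ONCOGENIC_VALUES | {"hotspot"}

# alterations with no protein consequence relevant here
_NONCODING_CLASSES = {
    "silent",
    "3'utr",
    "5'utr",
    "intron",
    "3'flank",
    "5'flank",
    "igr",
    "rna",
}


@dataclass(frozen=True)
class SkippingConfig:
    """Junction coordinates defining NFE2L2 exon-2 (and exon-2+3) skipping:
    a junction joining an exon-1 end directly to an exon-3 or exon-4 start,
    supported by at least ``min_reads`` raw reads."""

    chrom: str = "chr2"
    exon1_end_coords: frozenset = frozenset({177264531, 177263402, 177263436, 177263528})
    exon34_start_coords: frozenset = frozenset({177233340, 177232584, 177232563})
    min_reads: int = 2


@dataclass(frozen=True)
class SampleLabel:
    value: str  # Active | Ambiguous | Inactive
    top_mutation_class: MutationClass


def _functionality_map(map_version) -> dict[MutationClass, Functionality]:
    if isinstance(map_version, str):
        try:
            return FUNCTIONALITY_MAPS[map_version]
        except KeyError:
            raise ValueError(f"unknown map version {map_version!r}") from None
    return dict(map_version)


def classify_mutation(record: MutationRecord) -> MutationClass:
    """Assign a single somatic alteration to its mutation class.

    Noncoding alterations (silent, UTR, intron, flank) and genes outside the
    system map to ``MutationClass.NONE``. NFE2L2 records lacking exon
    information fall back to the other-exon class (logged).
    """
    if record.gene not in ("KEAP1", "NFE2L2", "CUL3"):
        return MutationClass.NONE
    vclass = record.variant_class.strip().lower().replace("_", "").replace(" ", "")
    if vclass in _NONCODING_CLASSES:
        return MutationClass.NONE
    if record.gene == "KEAP1":
        if record.oncogenicity.strip().lower() in _ONCOGENIC_VALUES:
            return MutationClass.KEAP1_ONCOGENIC
        return MutationClass.KEAP1_NONONCOGENIC
    if record.gene == "CUL3":
        return MutationClass.CUL3_MUT
    # NFE2L2
    if record.exon is None:
        logger.warning(
            "NFE2L2 mutation in %s lacks exon information; treated as other-exon",
            record.sample_id,
        )
        return MutationClass.NFE2L2_OTHEREXON
    if record.exon == 2:
        if record.oncogenicity.strip().lower() in _HOTSPOT_VALUES:
            return MutationClass.NFE2L2_EXON2_HOTSPOT
        return MutationClass.NFE2L2_EXON2_NONHOTSPOT
    return MutationClass.NFE2L2_OTHEREXON


def detect_exon2_skipping(
    counts: CountMatrix,
    junctions: Sequence[JunctionRecord],
    sample_id: str,
    cfg: SkippingConfig = SkippingConfig(),
) -> bool:
    """True iff the sample has >= ``cfg.min_reads`` raw reads on any junction
    joining an NFE2L2 exon-1 end coordinate to an exon-3/4 start coordinate."""
    skip_pairs = {
        frozenset((e1, e34))
        for e1 in cfg.exon1_end_coords
        for e34 in cfg.exon34_start_coords
    }
    for j in junctions:
        if j.chrom != cfg.chrom:
            continue
        if frozenset((j.start, j.end)) in skip_pairs:
            if j.junction_id in counts._jidx and counts.value(j.junction_id, sample_id) >= cfg.min_reads:
                return True
    return False


def detect_nfe2l2_cna(
    segments: Iterable[SegmentRecord],
    gene_region: GeneRegion = NFE2L2_REGION,
    threshold: float = CNA_SEGMENT_MEAN_THRESHOLD,
) -> bool:
    """True iff some segment contains the gene region in its entirety with
    Segment_Mean exceeding log2(3/2). Each segment is evaluated on its own;
    any qualifying segment suffices."""
    for seg in segments:
        if seg.chrom != gene_region.chrom:
            continue
        if seg.start <= gene_region.start and seg.end >= gene_region.end and seg.segment_mean > threshold:
            return True
    return False


def resolve_sample_label(classes: Iterable[MutationClass], map_version="initial") -> SampleLabel:
    """Collapse a sample's mutation classes to its label.

    The representative class is the highest-ranked one present; the label is
    Active if any class is Functional, Ambiguous if any is Uncertain (and
    none Functional), Inactive otherwise. Order of the input is irrelevant.
    """
    fmap = _functionality_map(map_version)
    present = [c for c in classes if c is not MutationClass.NONE]
    if not present:
        return SampleLabel("Inactive", MutationClass.NONE)
    top = min(present, key=lambda c: _RANK[c])
    functionalities = {fmap[c] for c in present}
    if Functionality.FUNCTIONAL in functionalities:
        value = "Active"
    elif Functionality.UNCERTAIN in functionalities:
        value = "Ambiguous"
    else:
        value = "Inactive"
    return SampleLabel(value, top)


def filter_hypermutated(
    per_sample_mutation_counts: Mapping[str, int],
    limit: int = HYPERMUTATION_LIMIT,
) -> list[str]:
    """Return sample ids with at most ``limit`` mutations (strict exclusion
    above the limit; a sample at exactly the limit is retained)."""
    removed = sorted(s for s, n in per_sample_mutation_counts.items() if n > limit)
    if removed:
        logger.info("excluding %d hypermutated sample(s): %s", len(removed), ", ".join(removed))
    return sorted(s for s, n in per_sample_mutation_counts.items() if n <= limit)


def collect_sample_classes(
    sample_ids: Sequence[str],
    mutations: Sequence[MutationRecord],
    counts: CountMatrix | None = None,
    junctions: Sequence[JunctionRecord] | None = None,
    segments: Sequence[SegmentRecord] | None = None,
    skipping_cfg: SkippingConfig = SkippingConfig(),
    nfe2l2_region: GeneRegion = NFE2L2_REGION,
) -> dict[str, list[MutationClass]]:
    """Build the per-sample mutation-class multiset from all alteration
    sources: the mutation table, junction-based exon-2 skipping, and
    segment-based NFE2L2 amplification."""
    classes: dict[str, list[MutationClass]] = {s: [] for s in sample_ids}
    for rec in mutations:
        if rec.sample_id in classes:
            classes[rec.sample_id].append(classify_mutation(rec))
    if counts is not None and junctions is not None:
        for s in sample_ids:
            if s in counts._sidx and detect_exon2_skipping(counts, junctions, s, skipping_cfg):
                classes[s].append(MutationClass.NFE2L2_EXON2_SKIPPING)
    if segments is not None:
        segs_by_sample: dict[str, list[SegmentRecord]] = {}
        for seg in segments:
            segs_by_sample.setdefault(seg.sample_id, []).append(seg)
        for s in sample_ids:
            if s in segs_by_sample and detect_nfe2l2_cna(segs_by_sample[s], nfe2l2_region):
                classes[s].append(MutationClass.NFE2L2_CNA)
    return classes


def label_samples(
    sample_ids: Sequence[str],
    mutations: Sequence[MutationRecord],
    counts: CountMatrix | None = None,
    junctions: Sequence[JunctionRecord] | None = None,
    segments: Sequence[SegmentRecord] | None = None,
    map_version="initial",
    skipping_cfg: SkippingConfig = SkippingConfig(),
    nfe2l2_region: GeneRegion = NFE2L2_REGION,
) -> pd.DataFrame:
    """Label every sample; returns a DataFrame with columns
    (sample_id, top_mutation_class, label)."""
    classes = collect_sample_classes(
        sample_ids, mutations, counts, junctions, segments, skipping_cfg, nfe2l2_region
    )
    rows = []
    for s in sample_ids:
        lab = resolve_sample_label(classes[s], map_version)
        rows.append(
            {"sample_id": s, "top_mutation_class": lab.top_mutation_class.value, "label": lab.value}
        )
    return pd.DataFrame(rows, columns=["sample_id", "top_mutation_class", "label"])


def cn_candidate_filter(
    segments: Sequence[SegmentRecord],
    scores: Mapping[str, float],
    labels: Mapping[str, str],
    keap1_region: GeneRegion = KEAP1_REGION,
    nfe2l2_region: GeneRegion = NFE2L2_REGION,
    threshold: float = 10.0,
    pad: int = 15_000,
    keap1_cut: float = -0.8,
    nfe2l2_cut: float = 0.5,
) -> list[str]:
    """Among Inactive samples with NRF2 score at or above the classifier
    threshold, return those with a copy-number segment overlapping the
    padded KEAP1 region at Segment_Mean <= ``keap1_cut`` (deletion) or the
    padded NFE2L2 region at Segment_Mean >= ``nfe2l2_cut`` (amplification).
    Regions are extended by ``pad`` bp upstream and downstream."""
    keap1 = keap1_region.padded(pad)
    nfe2l2 = nfe2l2_region.padded(pad)
    high = {
        s for s, sc in scores.items() if sc >= threshold and labels.get(s) == "Inactive"
    }
    hits: set[str] = set()
    for seg in segments:
        if seg.sample_id not in high:
            continue
        if keap1.overlaps(seg.chrom, seg.start, seg.end) and seg.segment_mean <= keap1_cut:
            hits.add(seg.sample_id)
        elif nfe2l2.overlaps(seg.chrom, seg.start, seg.end) and seg.segment_mean >= nfe2l2_cut:
            hits.add(seg.sample_id)
    return sorted(hits)
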