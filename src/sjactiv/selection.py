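"""Selection of abnormal splice-junction pairs.

Abnormal junctions are junctions absent from reference annotation; under
pathway-driven overexpression the splicing machinery is overwhelmed and
these junctions gain reads. Per cancer-type cohort the pipeline is:

1. keep unannotated junctions with a summed raw count >= 10 in the cohort;
2. normalize: counts-per-million per sample (totals over ALL junctions),
   then divide each junction's CPM by its cohort-mean CPM — used only here,
   never in scoring;
3. one-sided rank test (Active > Inactive) per candidate junction, exact by
   enumeration for small groups, Bonferroni-corrected within the cohort;
4. union the selections over cohorts and bind each abnormal junction to the
   annotated junctions sharing one of its boundary coordinates (the same
   splice site), giving per-sample counts k (abnormal) and n (abnormal +
   normal reads at that location).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, JunctionRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Tuning of the abnormal-junction selection.

    min_total_count: minimum summed raw count of an unannotated junction in
        the cohort ("observed in the samples at least 10 times").
    alpha: Bonferroni-adjusted p-value cutoff.
    min_active_per_cohort: cohorts with fewer mutated (Active) cases skip
        selection entirely.
    count_filter_mode: "total" (default, summed over cohort) or
        "per_sample_max" (alternative reading: some sample has >= the cutoff).
    """

    min_total_count: int = 10
    alpha: float = 0.001
    min_active_per_cohort: int = 2
    count_filter_mode: str = "total"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_total_count <= 0 or self.min_active_per_cohort <= 0:
            raise ValueError("count thresholds must be positive")
        if self.count_filter_mode not in ("total", "per_sample_max"):
            raise ValueError(f"unknown count_filter_mode {self.count_filter_mode!r}")


@dataclass(frozen=True)
class SJPair:
    """An abnormal (unannotated) junction bound to the annotated junctions
    sharing a boundary coordinate with it. Per sample, k is the abnormal
    junction's count and n = k + the summed counts of the normal partners."""

    abnormal_id: str
    chrom: str
    start: int
    end: int
    normal_ids: tuple[str, ...]
    cohorts: tuple[str, ...] = ()
    adj_p: float = float("nan")

    def counts(self, cm: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample (k, n) aligned with ``cm.sample_ids``. Junctions absent
        from the matrix contribute zero reads."""
        nsamp = len(cm.sample_ids)
        k = cm.row(self.abnormal_id).copy() if self.abnormal_id in cm._jidx else np.zeros(nsamp, dtype=np.int64)
        n = k.copy()
        for nid in self.normal_ids:
            if nid in cm._jidx:
                n = n + cm.row(nid)
        return k, n


def find_abnormal_junctions(
    junctions: Sequence[JunctionRecord],
    counts: CountMatrix,
    cfg: SelectionConfig = SelectionConfig(),
    sample_ids: Sequence[str] | None = None,
) -> list[str]:
    """Unannotated junctions whose raw count over ``sample_ids`` (default:
    all samples) passes the minimum-count filter. Order follows the
    junction table."""
    if sample_ids is None:
        cols = slice(None)
    else:
        cols = [counts.sample_index(s) for s in sample_ids]
    out = []
    for j in junctions:
        if j.annotated or j.junction_id not in counts._jidx:
            continue
        row = counts.row(j.junction_id)[cols]
        ok = row.max(initial=0) >= cfg.min_total_count if cfg.count_filter_mode == "per_sample_max" else row.sum() >= cfg.min_total_count
        if ok:
            out.append(j.junction_id)
    return out


def pair_normal_junctions(
    abnormal: JunctionRecord, junctions: Sequence[JunctionRecord]
) -> SJPair | None:
    """Bind an abnormal junction to every annotated junction on the same
    chromosome sharing its donor or acceptor coordinate (same-side boundary
    equality). Returns None — with a logged reason — when no annotated
    junction shares a splice site."""
    normals = [
        j.junction_id
        for j in junctions
        if j.annotated
        and j.chrom == abnormal.chrom
        and (j.start == abnormal.start or j.end == abnormal.end)
    ]
    if not normals:
        logger.info(
            "abnormal junction %s has no coordinate-sharing annotated junction; dropped",
            abnormal.junction_id,
        )
        return None
    return SJPair(
        abnormal_id=abnormal.junction_id,
        chrom=abnormal.chrom,
        start=abnormal.start,
        end=abnormal.end,
        normal_ids=tuple(normals),
    )


def normalize_counts(
    counts: CountMatrix,
    junction_ids: Sequence[str],
    cohort_sample_ids: Sequence[str],
) -> np.ndarray:
    """Two-stage selection-time normalization of the given junctions over a
    cohort: CPM per sample (denominator = the sample's total count over ALL
    junctions), then each junction divided by its cohort-mean CPM. Junctions
    with zero cohort mean (all-zero rows) are returned as zeros."""
    totals = counts.sample_totals
    scol = np.array([counts.sample_index(s) for s in cohort_sample_ids])
    if np.any(totals[scol] <= 0):
        raise ValueError("normalization requires positive per-sample totals")
    rows = np.array([counts.junction_index(j) for j in junction_ids])
    cpm = counts.counts[np.ix_(rows, scol)] / totals[scol] * 1e6
    means = cpm.mean(axis=1)
    norm = np.zeros_like(cpm)
    nonzero = means > 0
    norm[nonzero] = cpm[nonzero] / means[nonzero, None]
    return norm


# enumeration is used when the number of group assignments is at most this
_EXACT_ENUMERATION_LIMIT = 20_000


def rank_test_pvalue(active_values, inactive_values) -> float:
    """One-sided two-sample rank test, alternative "Active > Inactive".

    For small groups (C(n1+n2, n1) assignments within the enumeration limit)
    the p-value is exact: the fraction of group assignments whose Active
    midrank sum is at least the observed one. Larger groups use the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(active_values, dtype=float)
    y = np.asarray(inactive_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    if comb(n1 + n2, n1) <= _EXACT_ENUMERATION_LIMIT:
        ranks = stats.rankdata(np.concatenate([x, y]))
        observed = ranks[:n1].sum()
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if ranks[list(idx)].sum() >= observed - 1e-9:
                hits += 1
        return hits / total
    return float(stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue)


def rank_test_select(
    junctions: Sequence[JunctionRecord],
    counts: CountMatrix,
    labels: pd.DataFrame,
    cohort_map: Mapping[str, str],
    cfg: SelectionConfig = SelectionConfig(),
) -> dict[str, pd.DataFrame]:
    """Per-cohort candidate filtering, normalization, rank testing and
    Bonferroni correction.

    ``labels`` has columns (sample_id, label); only Active and Inactive
    samples take part. Cohorts with fewer than ``cfg.min_active_per_cohort``
    Active samples are skipped. Returns, per cohort, a DataFrame with
    columns (junction_id, p_raw, p_adj, selected); the Bonferroni factor is
    the number of candidates tested in that cohort.
    """
    lab = dict(zip(labels["sample_id"], labels["label"]))
    cohorts: dict[str, list[str]] = {}
    for s in counts.sample_ids:
        if lab.get(s) in ("Active", "Inactive") and s in cohort_map:
            cohorts.setdefault(cohort_map[s], []).append(s)
    results: dict[str, pd.DataFrame] = {}
    for cohort, samples in sorted(cohorts.items()):
        active = [s for s in samples if lab[s] == "Active"]
        inactive = [s for s in samples if lab[s] == "Inactive"]
        if len(active) < cfg.min_active_per_cohort:
            logger.info("cohort %s skipped: %d Active sample(s)", cohort, len(active))
            continue
        if not inactive:
            logger.info("cohort %s skipped: no Inactive samples", cohort)
            continue
        candidates = find_abnormal_junctions(junctions, counts, cfg, samples)
        if not candidates:
            results[cohort] = pd.DataFrame(columns=["junction_id", "p_raw", "p_adj", "selected"])
            continue
        norm = normalize_counts(counts, candidates, samples)
        a_idx = [samples.index(s) for s in active]
        i_idx = [samples.index(s) for s in inactive]
        m = len(candidates)
        rows = []
        for r, jid in enumerate(candidates):
            p = rank_test_pvalue(norm[r, a_idx], norm[r, i_idx])
            p_adj = min(1.0, p * m)
            rows.append({"junction_id": jid, "p_raw": p, "p_adj": p_adj, "selected": p_adj <= cfg.alpha})
        results[cohort] = pd.DataFrame(rows)
    return results


def union_features(
    per_cohort: Mapping[str, pd.DataFrame],
    junctions: Sequence[JunctionRecord],
) -> list[SJPair]:
    """Union of per-cohort selections, keyed by abnormal-junction identity,
    each bound to its coordinate-sharing annotated junctions. Features are
    ordered deterministically by (chrom, start, end); cohort provenance and
    the smallest adjusted p are recorded. Abnormal junctions with no
    annotated partner are dropped (logged)."""
    by_id = {j.junction_id: j for j in junctions}
    provenance: dict[str, list[str]] = {}
    best_p: dict[str, float] = {}
    for cohort in sorted(per_cohort):
        df = per_cohort[cohort]
        for _, row in df[df["selected"]].iterrows():
            jid = row["junction_id"]
            provenance.setdefault(jid, []).append(cohort)
            best_p[jid] = min(best_p.get(jid, np.inf), float(row["p_adj"]))
    pairs = []
    for jid, cohorts in provenance.items():
        pair = pair_normal_junctions(by_id[jid], junctions)
        if pair is None:
            continue
        pairs.append(
            SJPair(
                abnormal_id=pair.abnormal_id,
                chrom=pair.chrom,
                start=pair.start,
                end=pair.end,
                normal_ids=pair.normal_ids,
                cohorts=tuple(cohorts),
                adj_p=best_p[jid],
            )
        )
    pairs.sort(key=lambda p: (p.chrom, p.start, p.end, p.abnormal_id))
    return pairs


def select_features(
    junctions: Sequence[JunctionRecord],
    counts: CountMatrix,
    labels: pd.DataFrame,
    cohort_map: Mapping[str, str],
    cfg: SelectionConfig = SelectionConfig(),
) -> list[SJPair]:
    """The full selection pipeline: per-cohort rank-test selection followed
    by the cross-cohort union and normal-junction pairing."""
    per_cohort = rank_test_select(junctions, counts, labels, cohort_map, cfg)
    return union_features(per_cohort, junctions)
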