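"""Score-based reintegration of Uncertain mutation classes.

Ambiguous samples (no Functional mutation, at least one Uncertain one) are
held out of model construction. Once a model exists, each Ambiguous sample
is scored and grouped by its representative mutation class; the fraction of
samples at or above the decision threshold decides the class's fate:

* over 40%  -> the class becomes Functional (its samples turn Active);
* under 10% -> the class becomes Non-Functional (it stops conferring
  Ambiguous status);
* 10% to 40% inclusive -> the class stays Uncertain and its samples remain
  excluded from further analysis.

After relabeling, junction-pair selection and model fitting are rerun on
the updated Active/Inactive sets (one round by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classifier import ClassifierModel, fit_model, score_matrix
from .errors import FitError
from .io import CountMatrix
from .labeling import Functionality, MutationClass, _functionality_map, resolve_sample_label
from .selection import SelectionConfig, SJPair, select_features

logger = logging.getLogger(__name__)


def fraction_percent(numerator: int, denominator: int) -> float:
    """A count fraction as a percentage rounded to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 2)


def apply_reclassification_rule(n_above: int, n_total: int) -> Functionality:
    """Map a class's (samples above threshold, total samples) to its new
    functionality. Boundaries are strict: exactly 40% or exactly 10% both
    keep the class Uncertain."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_above <= n_total:
        raise ValueError("n_above must lie in [0, n_total]")
    fraction = 100.0 * n_above / n_total
    if fraction > 40.0:
        return Functionality.FUNCTIONAL
    if fraction < 10.0:
        return Functionality.NON_FUNCTIONAL
    return Functionality.UNCERTAIN


def evaluate_ambiguous(
    model: ClassifierModel,
    counts: CountMatrix,
    labels: pd.DataFrame,
) -> dict[MutationClass, tuple[int, int]]:
    """Score every Ambiguous sample and tally, per representative mutation
    class, how many reach the model threshold. ``labels`` must carry
    (sample_id, top_mutation_class, label). Classes without Ambiguous
    samples are omitted (logged)."""
    amb = labels[labels["label"] == "Ambiguous"]
    amb = amb[amb["sample_id"].isin(counts.sample_ids)]
    if amb.empty:
        logger.info("no Ambiguous samples to evaluate")
        return {}
    scores = score_matrix(model, counts).set_index("sample_id")["nrf2_score"]
    out: dict[MutationClass, tuple[int, int]] = {}
    for cls_name, group in amb.groupby("top_mutation_class"):
        cls = MutationClass(cls_name)
        vals = scores.loc[group["sample_id"]].to_numpy()
        out[cls] = (int((vals >= model.threshold).sum()), len(vals))
    for cls in MutationClass:
        if cls not in out and cls is not MutationClass.NONE:
            logger.debug("mutation class %s has no Ambiguous samples; omitted", cls.value)
    return out


def build_reclass_report(per_class: Mapping[MutationClass, tuple[int, int]]) -> pd.DataFrame:
    """Tabulate per-class counts, fractions (percent, 2 decimals) and the
    rule's new functionality label."""
    rows = []
    for cls, (above, total) in per_class.items():
        rows.append(
            {
                "mutation_class": cls.value,
                "n_samples": total,
                "n_above_threshold": above,
                "fraction_pct": fraction_percent(above, total),
                "new_functionality": apply_reclassification_rule(above, total).value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mutation_class", "n_samples", "n_above_threshold", "fraction_pct", "new_functionality"],
    )


def updated_functionality_map(
    base_map, per_class: Mapping[MutationClass, tuple[int, int]]
) -> dict[MutationClass, Functionality]:
    """The base functionality map with every evaluated class replaced by the
    rule's verdict."""
    fmap = dict(_functionality_map(base_map))
    for cls, (above, total) in per_class.items():
        fmap[cls] = apply_reclassification_rule(above, total)
    return fmap


@dataclass
class ReclassResult:
    report: pd.DataFrame
    functionality_map: dict[MutationClass, Functionality]
    labels: pd.DataFrame  # relabeled (sample_id, top_mutation_class, label)
    features: list[SJPair]
    model: ClassifierModel


def relabel_and_refit(
    junctions,
    counts: CountMatrix,
    sample_classes: Mapping[str, Sequence[MutationClass]],
    cohort_map: Mapping[str, str],
    model: ClassifierModel,
    selection_cfg: SelectionConfig = SelectionConfig(),
    base_map="initial",
    priors_mode: str = "equal",
) -> ReclassResult:
    """One reintegration round: evaluate Ambiguous samples under ``model``,
    update the functionality map by the rule, re-resolve every sample's
    label through the mutation hierarchy (so a sample of a dissolved class
    falls back to its next-ranked class), and rerun selection and fitting
    on the updated Active/Inactive sets."""
    sample_ids = list(sample_classes)
    labels = _labels_from_classes(sample_classes, base_map)
    per_class = evaluate_ambiguous(model, counts, labels)
    report = build_reclass_report(per_class)
    new_map = updated_functionality_map(base_map, per_class)
    new_labels = _labels_from_classes(sample_classes, new_map)
    n_active = int((new_labels["label"] == "Active").sum())
    if n_active < 2:
        raise FitError(f"relabeling left {n_active} Active sample(s); cannot refit")
    features = select_features(junctions, counts, new_labels, cohort_map, selection_cfg)
    if not features:
        raise FitError("selection after relabeling returned no features")
    new_model = fit_model(
        counts,
        new_labels,
        features,
        priors_mode=priors_mode,
        clip_bound=model.clip_bound,
        threshold=model.threshold,
    )
    return ReclassResult(
        report=report,
        functionality_map=new_map,
        labels=new_labels,
        features=features,
        model=new_model,
    )


def _labels_from_classes(sample_classes: Mapping[str, Sequence[MutationClass]], fmap) -> pd.DataFrame:
    rows = []
    for s, classes in sample_classes.items():
        lab = resolve_sample_label(classes, fmap)
        rows.append(
            {"sample_id": s, "top_mutation_class": lab.top_mutation_class.value, "label": lab.value}
        )
    return pd.DataFrame(rows, columns=["sample_id", "top_mutation_class", "label"])
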