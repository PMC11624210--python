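"""Beta-binomial naive-Bayes classifier and the NRF2 score.

Per selected junction pair and per class (Active / Inactive), the abnormal
read count k out of the location total n is modeled as beta-binomial,

    f(k | n, a, b) = C(n, k) * B(k + a, n - k + b) / B(a, b),

which is a binomial whose success probability is Beta(a, b)-distributed;
the beta parameters absorb the overdispersion of junction fractions beyond
sampling noise. (a, b) are fitted per feature and class by maximum
likelihood on the log-parameter scale.

A sample's NRF2 score is the log-likelihood ratio of its junction counts
under the Active versus the Inactive model, plus the prior log-ratio, with
each feature's log-ratio contribution truncated to +/- clip_bound (10 by
default) to control outlier junctions. A sample is called Active when the
score reaches the decision threshold (10 by default; zero is the natural
threshold of the log-ratio, 10 is the stricter operating point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import FitError
from .io import CountMatrix
from .selection import SelectionConfig, SJPair, select_features

logger = logging.getLogger(__name__)

PARAM_FLOOR = 1e-6
PARAM_CAP = 1e6

DEFAULT_CLIP_BOUND = 10.0
DEFAULT_THRESHOLD = 10.0


def betabin_logpmf(k, n, alpha: float, beta: float):
    """Log pmf of the beta-binomial distribution, via log-gamma throughout.

    ln f = ln C(n, k) + ln B(k + alpha, n - k + beta) - ln B(alpha, beta).
    Accepts scalars or arrays for k and n (broadcast); k must lie in [0, n]
    elementwise and both parameters must be positive.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError(f"alpha and beta must be positive (got {alpha}, {beta})")
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k must satisfy 0 <= k <= n")
    out = (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + special.betaln(k + alpha, n - k + beta)
        - special.betaln(alpha, beta)
    )
    return out if out.shape else float(out)


@dataclass(frozen=True)
class BetaBinParams:
    """Fitted beta parameters for one feature in one class. ``converged``
    is False when the optimizer failed and the method-of-moments fallback
    was kept."""

    alpha: float
    beta: float
    n_obs: int = 0
    converged: bool = True

    def __post_init__(self):
        if not (0 < self.alpha <= PARAM_CAP and 0 < self.beta <= PARAM_CAP):
            raise ValueError(f"parameters out of range: alpha={self.alpha}, beta={self.beta}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def concentration(self) -> float:
        return self.alpha + self.beta


def _moment_init(ks: np.ndarray, ns: np.ndarray) -> tuple[float, float]:
    """Method-of-moments starting point (and non-convergence fallback)."""
    m = float(np.clip(ks.sum() / ns.sum(), PARAM_FLOOR, 1 - PARAM_FLOOR))
    p = ks / ns
    var_p = float(np.var(p))
    mean_inv_n = float(np.mean(1.0 / ns))
    binom_var = m * (1 - m) * mean_inv_n
    excess = var_p - binom_var
    if excess <= 0 or mean_inv_n >= 1:
        s = 1e4  # little or no overdispersion: start near the binomial limit
    else:
        rho = float(np.clip(excess / (m * (1 - m) * (1 - mean_inv_n)), 1e-6, 0.999))
        s = np.clip(1.0 / rho - 1.0, 1e-3, 1e5)
    a = float(np.clip(m * s, PARAM_FLOOR, PARAM_CAP))
    b = float(np.clip((1 - m) * s, PARAM_FLOOR, PARAM_CAP))
    return a, b


def fit_betabin(ks, ns) -> BetaBinParams:
    """Maximum-likelihood beta-binomial fit of aligned count vectors.

    Samples with n = 0 carry no information (the pmf is 1 on an empty
    trial) and are dropped. Optimization runs over (ln a, ln b) with an
    analytic gradient, bounded to [1e-6, 1e6]; the bound encodes the
    near-binomial limit at the top and the all-zero floor at the bottom.
    On optimizer failure the method-of-moments estimate is returned with
    ``converged=False``.
    """
    ks = np.asarray(ks, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if ks.shape != ns.shape:
        raise ValueError("k and n vectors must be aligned")
    if np.any(ks < 0) or np.any(ks > ns):
        raise ValueError("k must satisfy 0 <= k <= n")
    use = ns > 0
    if not np.any(use):
        raise FitError("no sample with n > 0; cannot fit")
    k, n = ks[use], ns[use]
    a0, b0 = _moment_init(k, n)

    def negloglik_and_grad(theta):
        a, b = np.exp(theta)
        ll = np.sum(
            special.betaln(k + a, n - k + b) - special.betaln(a, b)
        )  # the C(n,k) term is parameter-free
        psi_ab = special.psi(a + b)
        psi_nab = special.psi(n + a + b)
        da = np.sum(special.psi(k + a) - psi_nab + psi_ab - special.psi(a))
        db = np.sum(special.psi(n - k + b) - psi_nab + psi_ab - special.psi(b))
        return -ll, -np.array([da * a, db * b])

    bounds = [(np.log(PARAM_FLOOR), np.log(PARAM_CAP))] * 2
    res = optimize.minimize(
        negloglik_and_grad,
        x0=np.log([a0, b0]),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
    )
    if res.success:
        a, b = (float(v) for v in np.exp(res.x))
        converged = True
        nll = float(res.fun)
    else:
        logger.warning("beta-binomial MLE did not converge (%s); using moment estimates", res.message)
        a, b, converged = a0, b0, False
        nll = negloglik_and_grad(np.log([a0, b0]))[0]
    # Boundary tie-break: with under- or exactly-binomially dispersed data the
    # likelihood is flat in the concentration a+b and its supremum sits at the
    # cap (the binomial limit). If the cap is not worse than the interior
    # point found, report the fit at the cap rather than wherever the
    # optimizer's gradient test happened to stop.
    m_hat = a / (a + b)
    a_cap = float(np.clip(m_hat * PARAM_CAP, PARAM_FLOOR, PARAM_CAP))
    b_cap = float(np.clip((1 - m_hat) * PARAM_CAP, PARAM_FLOOR, PARAM_CAP))
    nll_cap = negloglik_and_grad(np.log([a_cap, b_cap]))[0]
    if nll_cap <= nll + 1e-6:
        a, b = a_cap, b_cap
    return BetaBinParams(a, b, n_obs=int(use.sum()), converged=converged)


@dataclass
class ClassifierModel:
    """Fitted two-class model: per-feature beta-binomial parameters for the
    Active and Inactive classes, class log-priors, the per-feature clip
    bound and the decision threshold."""

    features: list[SJPair]
    params_active: list[BetaBinParams]
    params_inactive: list[BetaBinParams]
    log_prior_active: float = np.log(0.5)
    log_prior_inactive: float = np.log(0.5)
    clip_bound: float = DEFAULT_CLIP_BOUND
    threshold: float = DEFAULT_THRESHOLD
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.params_active) != len(self.features) or len(self.params_inactive) != len(self.features):
            raise ValueError("parameter lists must align with the feature list")
        if self.clip_bound <= 0:
            raise ValueError("clip_bound must be positive")

    @property
    def prior_log_ratio(self) -> float:
        return self.log_prior_active - self.log_prior_inactive

    def to_dict(self) -> dict:
        return {
            "features": [
                {
                    "abnormal_id": f.abnormal_id,
                    "chrom": f.chrom,
                    "start": f.start,
                    "end": f.end,
                    "normal_ids": list(f.normal_ids),
                    "cohorts": list(f.cohorts),
                    "adj_p": None if np.isnan(f.adj_p) else f.adj_p,
                }
                for f in self.features
            ],
            "params_active": [
                {"alpha": p.alpha, "beta": p.beta, "n_obs": p.n_obs, "converged": p.converged}
                for p in self.params_active
            ],
            "params_inactive": [
                {"alpha": p.alpha, "beta": p.beta, "n_obs": p.n_obs, "converged": p.converged}
                for p in self.params_inactive
            ],
            "log_prior_active": self.log_prior_active,
            "log_prior_inactive": self.log_prior_inactive,
            "clip_bound": self.clip_bound,
            "threshold": self.threshold,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        features = [
            SJPair(
                abnormal_id=f["abnormal_id"],
                chrom=f["chrom"],
                start=f["start"],
                end=f["end"],
                normal_ids=tuple(f["normal_ids"]),
                cohorts=tuple(f.get("cohorts", ())),
                adj_p=float("nan") if f.get("adj_p") is None else f["adj_p"],
            )
            for f in d["features"]
        ]
        mk = lambda p: BetaBinParams(p["alpha"], p["beta"], p.get("n_obs", 0), p.get("converged", True))
        return cls(
            features=features,
            params_active=[mk(p) for p in d["params_active"]],
            params_inactive=[mk(p) for p in d["params_inactive"]],
            log_prior_active=d["log_prior_active"],
            log_prior_inactive=d["log_prior_inactive"],
            clip_bound=d["clip_bound"],
            threshold=d["threshold"],
            metadata=d.get("metadata", {}),
        )


@dataclass(frozen=True)
class ScoreReport:
    """Per-sample NRF2 score with its per-feature clipped contributions."""

    sample_id: str
    nrf2_score: float
    per_feature_contributions: np.ndarray
    n_features_informative: int
    predicted: str  # Active | Inactive


def fit_model(
    counts: CountMatrix,
    labels: pd.DataFrame,
    features: Sequence[SJPair],
    priors_mode: str = "equal",
    clip_bound: float = DEFAULT_CLIP_BOUND,
    threshold: float = DEFAULT_THRESHOLD,
) -> ClassifierModel:
    """Fit the per-feature Active and Inactive beta-binomial models.

    ``labels`` (sample_id, label) restricts which samples train each class;
    Ambiguous samples are ignored. Features with no informative sample
    (n > 0) in one of the classes are dropped with a log line. Priors are
    "equal" (log-ratio 0; score 0 is then the natural threshold) or
    "empirical" (training label frequencies).
    """
    if not features:
        raise FitError("feature list is empty; nothing to fit")
    lab = dict(zip(labels["sample_id"], labels["label"]))
    active = [s for s in counts.sample_ids if lab.get(s) == "Active"]
    inactive = [s for s in counts.sample_ids if lab.get(s) == "Inactive"]
    if not active or not inactive:
        raise FitError(
            f"both classes required for fitting (Active={len(active)}, Inactive={len(inactive)})"
        )
    a_idx = [counts.sample_index(s) for s in active]
    i_idx = [counts.sample_index(s) for s in inactive]
    kept, pa, pi = [], [], []
    for feat in features:
        k, n = feat.counts(counts)
        try:
            fa = fit_betabin(k[a_idx], n[a_idx])
            fi = fit_betabin(k[i_idx], n[i_idx])
        except FitError:
            logger.info("feature %s dropped: no informative samples in one class", feat.abnormal_id)
            continue
        kept.append(feat)
        pa.append(fa)
        pi.append(fi)
    if not kept:
        raise FitError("every feature was dropped; cannot build a model")
    if priors_mode == "equal":
        lpa = lpi = float(np.log(0.5))
    elif priors_mode == "empirical":
        total = len(active) + len(inactive)
        lpa = float(np.log(len(active) / total))
        lpi = float(np.log(len(inactive) / total))
    else:
        raise ValueError(f"unknown priors mode {priors_mode!r}")
    return ClassifierModel(
        features=kept,
        params_active=pa,
        params_inactive=pi,
        log_prior_active=lpa,
        log_prior_inactive=lpi,
        clip_bound=clip_bound,
        threshold=threshold,
        metadata={"priors_mode": priors_mode, "n_active_train": len(active), "n_inactive_train": len(inactive)},
    )


def score_sample(model: ClassifierModel, k_vector, n_vector, sample_id: str = "sample") -> ScoreReport:
    """NRF2 score of one sample from its per-feature (k, n) counts.

    contribution_i = clip(ln f(k_i, n_i | Active) - ln f(k_i, n_i | Inactive),
    -clip_bound, +clip_bound); the score is the contribution sum plus the
    prior log-ratio; the call is Active when score >= threshold. Features
    with n = 0 contribute exactly 0 (the pmf of an empty trial is 1 under
    both classes).
    """
    k = np.asarray(k_vector, dtype=float)
    n = np.asarray(n_vector, dtype=float)
    if k.shape != n.shape or k.shape != (len(model.features),):
        raise ValueError("count vectors must align with the model's feature list")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k must satisfy 0 <= k <= n")
    contrib = np.zeros(len(model.features))
    for i, (pa, pi) in enumerate(zip(model.params_active, model.params_inactive)):
        if n[i] <= 0:
            continue
        lr = betabin_logpmf(k[i], n[i], pa.alpha, pa.beta) - betabin_logpmf(
            k[i], n[i], pi.alpha, pi.beta
        )
        contrib[i] = np.clip(lr, -model.clip_bound, model.clip_bound)
    score = float(contrib.sum() + model.prior_log_ratio)
    return ScoreReport(
        sample_id=sample_id,
        nrf2_score=score,
        per_feature_contributions=contrib,
        n_features_informative=int((n > 0).sum()),
        predicted="Active" if score >= model.threshold else "Inactive",
    )


def score_matrix(model: ClassifierModel, counts: CountMatrix) -> pd.DataFrame:
    """Score every sample of a count matrix. Returns a DataFrame with
    columns (sample_id, nrf2_score, predicted, n_features_informative)."""
    nsamp = len(counts.sample_ids)
    total = np.full(nsamp, model.prior_log_ratio)
    informative = np.zeros(nsamp, dtype=int)
    for feat, pa, pi in zip(model.features, model.params_active, model.params_inactive):
        k, n = feat.counts(counts)
        pos = n > 0
        if not np.any(pos):
            continue
        lr = betabin_logpmf(k[pos], n[pos], pa.alpha, pa.beta) - betabin_logpmf(
            k[pos], n[pos], pi.alpha, pi.beta
        )
        total[pos] += np.clip(lr, -model.clip_bound, model.clip_bound)
        informative += pos
    return pd.DataFrame(
        {
            "sample_id": counts.sample_ids,
            "nrf2_score": total,
            "predicted": np.where(total >= model.threshold, "Active", "Inactive"),
            "n_features_informative": informative,
        }
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts with Active as the positive class. Derived
    ratios with a zero denominator are NaN, never silently 0."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Specificity, precision and recall as percentages rounded to two
    decimals (NaN where undefined)."""
    return {
        "specificity_pct": round(100 * c.specificity, 2),
        "precision_pct": round(100 * c.precision, 2),
        "recall_pct": round(100 * c.recall, 2),
    }


def confusion_from_scores(scores: pd.DataFrame, labels: Mapping[str, str], threshold: float) -> ConfusionCounts:
    """Tally TP/FP/TN/FN of score >= threshold against Active/Inactive labels."""
    tp = fp = tn = fn = 0
    for sid, sc in zip(scores["sample_id"], scores["nrf2_score"]):
        truth = labels.get(sid)
        if truth not in ("Active", "Inactive"):
            continue
        called = sc >= threshold
        if truth == "Active":
            tp, fn = tp + called, fn + (not called)
        else:
            fp, tn = fp + called, tn + (not called)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class CVResult:
    confusion: ConfusionCounts
    scores: pd.DataFrame  # sample_id, nrf2_score, predicted, fold, label
    features_per_fold: list[list[SJPair]]


def cross_validate(
    junctions,
    counts: CountMatrix,
    labels: pd.DataFrame,
    cohort_map: Mapping[str, str],
    selection_cfg: SelectionConfig = SelectionConfig(),
    seed: int = 0,
    features: Sequence[SJPair] | None = None,
    priors_mode: str = "equal",
    clip_bound: float = DEFAULT_CLIP_BOUND,
    threshold: float = DEFAULT_THRESHOLD,
) -> CVResult:
    """Two-fold class-stratified cross-validation.

    Active and Inactive samples are each split in half from the given seed;
    each half trains a model that scores the other half, so every sample is
    scored exactly once. By default feature selection is rerun inside each
    training half (leakage-free); passing ``features`` reuses a fixed
    feature list across folds instead.
    """
    lab = dict(zip(labels["sample_id"], labels["label"]))
    active = [s for s in counts.sample_ids if lab.get(s) == "Active"]
    inactive = [s for s in counts.sample_ids if lab.get(s) == "Inactive"]
    if len(active) < 2 or len(inactive) < 2:
        raise FitError("cross-validation requires at least 2 samples per class")
    rng = np.random.default_rng(seed)
    active = list(rng.permutation(active))
    inactive = list(rng.permutation(inactive))
    halves = [
        active[: len(active) // 2] + inactive[: len(inactive) // 2],
        active[len(active) // 2 :] + inactive[len(inactive) // 2 :],
    ]
    all_scores = []
    fold_features: list[list[SJPair]] = []
    for fold, (train, test) in enumerate([(halves[0], halves[1]), (halves[1], halves[0])]):
        train_labels = labels[labels["sample_id"].isin(train)]
        if features is None:
            feats = select_features(junctions, counts, train_labels, cohort_map, selection_cfg)
            if not feats:
                raise FitError(f"fold {fold}: feature selection returned nothing")
        else:
            feats = list(features)
        fold_features.append(feats)
        model = fit_model(counts, train_labels, feats, priors_mode, clip_bound, threshold)
        sc = score_matrix(model, counts)
        sc = sc[sc["sample_id"].isin(test)].copy()
        sc["fold"] = fold
        sc["label"] = [lab[s] for s in sc["sample_id"]]
        all_scores.append(sc)
    scores = pd.concat(all_scores, ignore_index=True)
    confusion = confusion_from_scores(scores, lab, threshold)
    return CVResult(confusion=confusion, scores=scores, features_per_fold=fold_features)


def pr_curve(scores, labels) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve with Active as the positive class.

    Points are placed at every distinct score threshold (descending). The
    area is computed with nonlinear precision-recall interpolation: between
    consecutive operating points false positives are interpolated linearly
    in true positives and the resulting precision is integrated exactly over
    recall (the continuous interpolation convention for PR curves).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([l == "Active" if isinstance(l, str) else bool(l) for l in labels])
    if scores.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    npos = int(y.sum())
    if npos == 0 or npos == y.size:
        raise ValueError("precision-recall requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp_d, fp_d = tp[distinct], fp[distinct]
    points = pd.DataFrame(
        {
            "threshold": s_sorted[distinct],
            "recall": tp_d / npos,
            "precision": tp_d / (tp_d + fp_d),
        }
    )
    area = 0.0
    tp_a, fp_a = 0.0, 0.0
    for tp_b, fp_b in zip(tp_d, fp_d):
        dtp = tp_b - tp_a
        if dtp > 0:
            m = 1.0 + (fp_b - fp_a) / dtp
            c = tp_a + fp_a
            if c == 0:
                area += dtp / m
            else:
                area += dtp / m + (tp_a - c / m) / m * np.log((c + m * dtp) / c)
        tp_a, fp_a = tp_b, fp_b
    return points, float(area / npos)
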