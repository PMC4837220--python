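"""Class-balanced evaluation: LOSO CV, normalized confusion metrics,
bootstrap confidence intervals and hypnogram statistics.

A raw confusion matrix weights each stage by its prevalence, which is
undesirable for sleep staging where rare stages (N1) matter as much as
frequent ones (N2).  All metrics here therefore derive from the
row-normalized ("class-balanced") confusion matrix M, whose row i is the
distribution of the algorithm's output over expert-stage-i epochs.

Each stage is scored one-vs-all with the negative class built as the
*average* of the other stages' rows (so every stage contributes equally
to the negative class):

    sensitivity  s_i = M[i, i]
    false-pos    f_i = mean_{j != i} M[j, i]
    precision    p_i = s_i / (s_i + f_i)
    F1_i         = 2 p_i s_i / (p_i + s_i)
    accuracy a_i = (s_i + (1 - f_i)) / 2
    overall accuracy = mean_i s_i

Summary metrics can either pool the per-fold confusion counts before
normalizing (as a summed cross-validation matrix) or average
per-recording metrics; both are provided.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from . import STAGES
from .data_io import in_bed_segment
from .ensemble import ensemble_predict, train_ensemble
from .ssae import SSAEHyper

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "LosoResult",
    "evaluate_fold",
    "normalize_confusion",
    "stage_metrics",
    "metrics_from_counts",
    "loso_cv",
    "bootstrap_ci",
    "sleep_efficiency",
    "transitional_pct",
    "performance_correlation",
    "round_percent",
]


def round_percent(x: float) -> int:
    """Round a [0, 1] metric to integer percent, half away from zero."""
    return int(np.floor(100 * x + 0.5))


@dataclass
class MetricsReport:
    """Per-stage and summary classification metrics.

    All values are fractions in [0, 1]; ``per_stage`` maps metric name →
    {stage: value}.
    """

    classes: tuple[str, ...]
    per_stage: dict[str, dict[str, float]]
    mean: dict[str, float]
    worst: dict[str, float]
    overall_accuracy: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "per_stage": self.per_stage,
            "mean": self.mean,
            "worst": self.worst,
            "overall_accuracy": self.overall_accuracy,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.as_dict(), indent=2, **kw)

    def as_text(self) -> str:
        """Aligned text table of per-stage metrics plus the summary row."""
        metrics = list(self.per_stage)
        lines = ["stage  " + "".join(f"{m:>13}" for m in metrics)]
        for s in self.classes:
            row = "".join(f"{self.per_stage[m][s]:>13.3f}" for m in metrics)
            lines.append(f"{s:<7}" + row)
        lines.append(
            "mean   " + "".join(f"{self.mean[m]:>13.3f}" for m in metrics)
        )
        lines.append(f"overall accuracy: {self.overall_accuracy:.3f}")
        return "\n".join(lines)


def evaluate_fold(true_stages, predicted_stages, classes=STAGES) -> np.ndarray:
    """Confusion-count matrix, rows = expert stage, cols = algorithm stage."""
    true_stages = list(true_stages)
    predicted_stages = list(predicted_stages)
    if len(true_stages) != len(predicted_stages):
        raise ValueError("true and predicted stage lists differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_stages, predicted_stages):
        if t not in index or p not in index:
            raise ValueError(f"unknown stage label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return counts


def normalize_confusion(counts: np.ndarray, classes=STAGES) -> np.ndarray:
    """Row-normalize confusion counts; errors on a stage with no epochs."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1)
    empty = np.nonzero(sums == 0)[0]
    if empty.size:
        names = [classes[i] for i in empty]
        raise ValueError(f"no expert epochs for stage(s) {names}")
    return counts / sums[:, None]


def stage_metrics(M: np.ndarray, classes=STAGES) -> MetricsReport:
    """One-vs-all metrics from a row-stochastic confusion matrix.

    The negative class of each binary problem is the average of the
    other stages' normalized rows, giving every stage equal weight.
    """
    M = np.asarray(M, dtype=float)
    s_count = M.shape[0]
    if M.shape != (s_count, s_count) or np.any(
        np.abs(M.sum(axis=1) - 1.0) > 1e-9
    ):
        raise ValueError("M must be a square row-stochastic matrix")
    per: dict[str, dict[str, float]] = {
        k: {} for k in ("precision", "sensitivity", "specificity", "f1", "accuracy")
    }
    for i, stage in enumerate(classes[:s_count]):
        s = M[i, i]
        f = float(np.sum(np.delete(M[:, i], i))) / (s_count - 1)
        p = s / (s + f) if (s + f) > 0 else 0.0
        if (s + f) == 0:
            logger.warning("stage %s never predicted; precision set to 0", stage)
        f1 = 2 * p * s / (p + s) if (p + s) > 0 else 0.0
        per["sensitivity"][stage] = s
        per["precision"][stage] = p
        per["specificity"][stage] = 1 - f
        per["f1"][stage] = f1
        per["accuracy"][stage] = (s + (1 - f)) / 2
    mean = {k: float(np.mean(list(v.values()))) for k, v in per.items()}
    worst = {k: float(np.min(list(v.values()))) for k, v in per.items()}
    overall = mean["sensitivity"]
    return MetricsReport(
        classes=tuple(classes[:s_count]),
        per_stage=per,
        mean=mean,
        worst=worst,
        overall_accuracy=overall,
    )


def metrics_from_counts(counts: np.ndarray, classes=STAGES) -> MetricsReport:
    """Full metrics report straight from a confusion-count matrix."""
    return stage_metrics(normalize_confusion(counts, classes), classes)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class LosoResult:
    """Outcome of leave-one-subject-out cross-validation."""

    fold_subjects: list[str]
    recording_ids: list[str]
    per_recording_counts: dict[str, np.ndarray]
    pooled_counts: np.ndarray
    pooled_report: MetricsReport
    mean_report: MetricsReport

    def per_recording_metric(self, metric: str, summary: str = "mean") -> np.ndarray:
        """One value per recording: mean or worst of a per-stage metric."""
        vals = []
        for rid in self.recording_ids:
            rep = _present_stage_metrics(self.per_recording_counts[rid])
            vals.append(rep.mean[metric] if summary == "mean" else rep.worst[metric])
        return np.array(vals)


def _present_stage_metrics(counts: np.ndarray) -> MetricsReport:
    """Metrics over the stages actually present in a recording."""
    counts = np.asarray(counts, dtype=float)
    present = np.nonzero(counts.sum(axis=1) > 0)[0]
    classes = tuple(STAGES[i] for i in present)
    per: dict[str, dict[str, float]] = {
        k: {} for k in ("precision", "sensitivity", "specificity", "f1", "accuracy")
    }
    for i, stage in zip(present, classes):
        s = float(counts[i, i] / counts[i].sum())
        others = [j for j in present if j != i]
        f = float(np.mean([counts[j, i] / counts[j].sum() for j in others])) if others else 0.0
        p = s / (s + f) if (s + f) > 0 else 0.0
        f1 = 2 * p * s / (p + s) if (p + s) > 0 else 0.0
        per["sensitivity"][stage] = s
        per["precision"][stage] = p
        per["specificity"][stage] = 1 - f
        per["f1"][stage] = f1
        per["accuracy"][stage] = (s + (1 - f)) / 2
    mean = {k: float(np.mean(list(v.values()))) for k, v in per.items()}
    worst = {k: float(np.min(list(v.values()))) for k, v in per.items()}
    return MetricsReport(
        classes=classes,
        per_stage=per,
        mean=mean,
        worst=worst,
        overall_accuracy=mean["sensitivity"],
    )


def loso_cv(
    X: np.ndarray,
    stages,
    subject_ids,
    recording_ids,
    hyper: SSAEHyper | None = None,
    n_members: int = 20,
    seed: int = 0,
    stage_weights=None,
    train_predict=None,
) -> LosoResult:
    """Leave-one-subject-out cross-validation of the full classifier.

    One fold per unique subject: all of that subject's recordings are
    held out, an ensemble is trained on everything else, and the held-out
    epochs are scored.  Per-recording confusion counts are retained for
    bootstrap and covariate analyses.

    ``train_predict(X_train, y_train, rids_train, X_test, fold_seed)``
    may replace the default ensemble train/predict (used for testing the
    CV bookkeeping in isolation).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    stages = np.asarray(stages)
    subject_ids = np.asarray(subject_ids)
    recording_ids = np.asarray(recording_ids)
    subjects = _unique_in_order(subject_ids)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")

    if train_predict is None:

        def train_predict(Xtr, ytr, rtr, Xte, fold_seed):
            model = train_ensemble(
                Xtr, ytr, rtr, hyper=hyper, n_members=n_members, seed=fold_seed
            )
            labels, _ = ensemble_predict(model, Xte, stage_weights)
            return labels

    per_recording: dict[str, np.ndarray] = {}
    rec_order: list[str] = [str(r) for r in _unique_in_order(recording_ids)]
    for fold, subj in enumerate(subjects):
        test_mask = subject_ids == subj
        train_mask = ~test_mask
        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % 2**31)
        logger.info(
            "LOSO fold %d: subject %s, %d test / %d train epochs",
            fold, subj, int(test_mask.sum()), int(train_mask.sum()),
        )
        pred = train_predict(
            X[train_mask],
            stages[train_mask],
            recording_ids[train_mask],
            X[test_mask],
            fold_seed,
        )
        pred = np.asarray(pred)
        for rid in _unique_in_order(recording_ids[test_mask]):
            rmask = test_mask & (recording_ids == rid)
            counts = evaluate_fold(
                stages[rmask], pred[recording_ids[test_mask] == rid]
            )
            per_recording[str(rid)] = counts

    pooled = np.sum([per_recording[r] for r in rec_order], axis=0)
    pooled_report = metrics_from_counts(pooled)
    reports = [_present_stage_metrics(per_recording[r]) for r in rec_order]
    mean_report = _average_reports(reports)
    return LosoResult(
        fold_subjects=[str(s) for s in subjects],
        recording_ids=rec_order,
        per_recording_counts=per_recording,
        pooled_counts=pooled,
        pooled_report=pooled_report,
        mean_report=mean_report,
    )


def _average_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Average per-recording summary metrics (paper-style reporting)."""
    metric_names = list(reports[0].per_stage)
    per: dict[str, dict[str, float]] = {m: {} for m in metric_names}
    for m in metric_names:
        for s in STAGES:
            vals = [r.per_stage[m][s] for r in reports if s in r.per_stage[m]]
            if vals:
                per[m][s] = float(np.mean(vals))
    mean = {m: float(np.mean([r.mean[m] for r in reports])) for m in metric_names}
    worst = {m: float(np.mean([r.worst[m] for r in reports])) for m in metric_names}
    return MetricsReport(
        classes=STAGES,
        per_stage=per,
        mean=mean,
        worst=worst,
        overall_accuracy=float(np.mean([r.overall_accuracy for r in reports])),
    )


# ---------------------------------------------------------------------------
# Bootstrap and hypnogram statistics


def bootstrap_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of per-recording values.

    Recordings are resampled with replacement ``n_boot`` times; the
    interval is the (alpha/2, 1 - alpha/2) percentile of resample means.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 recordings")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def sleep_efficiency(stages, lights_out_epoch: int = 0) -> float:
    """Percentage of time in bed spent asleep (non-W), in [0, 100].

    Time in bed runs from lights out through the last sleep epoch
    (:func:`wavesleep.data_io.in_bed_segment`).
    """
    seg = in_bed_segment(list(stages), lights_out_epoch)
    window = list(stages)[seg.start : seg.end + 1]
    asleep = sum(1 for s in window if s != "W")
    return 100.0 * asleep / seg.time_in_bed


def transitional_pct(stages, start: int = 0, end: int | None = None) -> float:
    """Percentage of time-in-bed epochs that are transitional.

    An epoch is transitional iff its previous or next epoch (within the
    recording) carries a different stage; boundary epochs compare only
    their existing neighbor.  The percentage is over epochs in
    ``[start, end]`` inclusive (default: the whole hypnogram).
    """
    stages = list(stages)
    if end is None:
        end = len(stages) - 1
    if not 0 <= start <= end < len(stages):
        raise ValueError("invalid time-in-bed range")
    n_trans = 0
    for i in range(start, end + 1):
        prev_diff = i > 0 and stages[i - 1] != stages[i]
        next_diff = i < len(stages) - 1 and stages[i + 1] != stages[i]
        if prev_diff or next_diff:
            n_trans += 1
    return 100.0 * n_trans / (end - start + 1)


def performance_correlation(covariate, metric) -> tuple[float, float]:
    """R^2 and two-sided slope p-value of metric ~ covariate.

    Simple linear regression over recordings; requires >= 3 points and a
    non-constant covariate.  (For simple regression the slope t-test and
    the overall F-test give the same p-value.)
    """
    covariate = np.asarray(covariate, dtype=float)
    metric = np.asarray(metric, dtype=float)
    if covariate.size != metric.size:
        raise ValueError("covariate and metric lengths differ")
    if covariate.size < 3:
        raise ValueError("need at least 3 recordings for regression")
    if np.ptp(covariate) == 0:
        raise ValueError("covariate has zero variance")
    res = _stats.linregress(covariate, metric)
    return float(res.rvalue**2), float(res.pvalue)


def _unique_in_order(values) -> list:
    out, seen = [], set()
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
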