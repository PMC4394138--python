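"""Evaluation machinery: epoch/event metrics and the two AUC orderings.

Detector performance is quantified at three levels: *epoch* (temporal
precision of detected onsets/offsets, i.e. seizure burden), *event* (whether
each annotated seizure was caught, and how many detections were false), and
*patient* (summaries across records). Sweeping a threshold grid over each
patient's probability trace yields sensitivity and specificity matrices
``SE, SP ∈ R^{N x M}`` (N thresholds, M patients) from which the area under
the ROC curve can be computed in two distinct orders:

* **per-patient mean** — a trapezoidal AUC per patient, then the mean across
  patients: summarises the discriminability of the probabilistic output and
  is the right summary when the probability trace (or colormap) is what is
  displayed;
* **pooled thresholds** — SE/SP averaged across patients at each threshold
  first, then one trapezoidal AUC: summarises what a fixed shared threshold
  achieves and is the right summary for a binary display.

When patients' probability traces discriminate perfectly but sit at shifted
operating levels, the pooled-threshold AUC is strictly lower than the mean
per-patient AUC — the ordering effect that makes the choice of computation
order part of the display choice.

The ROC sweep is augmented with the forced endpoints (SE=1, SP=0) and (SE=0,
SP=1) so the trapezoid spans the full unit square; ``endpoints=False``
reproduces the literal truncated-grid sums.

Epoch-level confusion is computed from exact interval intersections on the
4 s decision grid (equivalent to fractionally-weighted epochs), so detections
and annotations need not align to the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotationTrack, total_duration, total_overlap
from .detector import DecisionTrace, ProbabilityTrace, binarize

__all__ = [
    "ThresholdGrid",
    "MetricsTable",
    "EventScore",
    "default_threshold_grid",
    "epoch_confusion",
    "event_metrics",
    "bootstrap_upper95",
    "compute_metrics_table",
    "auc_per_patient_mean",
    "auc_pooled_thresholds",
    "threshold_guide",
]


def bootstrap_upper95(values: np.ndarray, n_boot: int = 2000, rng=None) -> float:
    """Percentile-bootstrap upper bound of the 95% CI of the mean.

    Resamples patients with replacement and takes the 97.5th percentile of
    the resampled means.
    """
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    return float(np.percentile(values[idx].mean(axis=1), 97.5))


def default_threshold_grid() -> np.ndarray:
    """Thresholds 0.00, 0.01, …, 1.00."""
    return np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass
class ThresholdGrid:
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 2 or np.any(np.diff(v) <= 0):
            raise ValueError("thresholds must be strictly increasing, N >= 2")
        if v[0] < 0 or v[-1] > 1:
            raise ValueError("thresholds must lie in [0, 1]")
        self.values = v


@dataclass
class MetricsTable:
    """SE/SP as N x M matrices (N thresholds, M patients), proportions in [0,1].

    Cells may be NaN where a metric is undefined (a patient with no seizure
    epochs has no sensitivity); the AUC computations reject such tables.
    """

    thresholds: np.ndarray
    SE: np.ndarray
    SP: np.ndarray
    patient_ids: list
    level: str = "epoch"


@dataclass
class EventScore:
    """Event-level score for one patient."""

    gdr_pct: float  # % of true seizures overlapped by >= 1 detection
    fd_per_h: float  # detections overlapping no true seizure, per hour
    duration_h: float
    n_true: int
    n_detected: int
    n_false: int


def epoch_confusion(
    decisions: DecisionTrace,
    truth: AnnotationTrack,
    duration_s: float | None = None,
) -> tuple[float | None, float | None]:
    """Sensitivity and specificity of the detected time against annotations.

    TP is the total detected∩annotated duration; SE = TP / annotated time,
    SP = TN / non-annotated time. A metric whose denominator is empty (no
    seizure time, or seizure covering the whole record) is returned as None,
    not 0.
    """
    if duration_s is None:
        duration_s = decisions.duration_s
    # score only the decided span: the first/last 4 s half-epochs of a hop-
    # aligned trace are covered by no decision interval
    if decisions.times_s.size:
        span = (float(decisions.times_s[0]), float(decisions.times_s[-1]) + 4.0)
    else:
        span = (0.0, float(duration_s))

    def clip(evs):
        return [
            (max(a, span[0]), min(b, span[1]))
            for a, b in evs
            if b > span[0] and a < span[1]
        ]

    det = clip(decisions.events.events)
    tru = clip(truth.events)
    tp = total_overlap(det, tru)
    pos = total_duration(tru)
    neg = (span[1] - span[0]) - pos
    fp = total_duration(det) - tp
    se = tp / pos if pos > 0 else None
    sp = (neg - fp) / neg if neg > 0 else None
    return se, sp


def event_metrics(
    decisions: DecisionTrace,
    truth: AnnotationTrack,
    duration_s: float | None = None,
) -> EventScore:
    """Good detection rate and false detections per hour (any-overlap rule).

    A true seizure counts as detected iff some detected event overlaps it; a
    detected event is false iff it overlaps no true seizure.
    """
    if duration_s is None:
        duration_s = decisions.duration_s
    if duration_s <= 0:
        raise ValueError("record duration must be positive")
    det = decisions.events.events
    tru = truth.events

    def overlaps(a, b) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    n_detected = sum(any(overlaps(t, d) for d in det) for t in tru)
    n_false = sum(not any(overlaps(d, t) for t in tru) for d in det)
    hours = duration_s / 3600.0
    gdr = 100.0 * n_detected / len(tru) if tru else np.nan
    return EventScore(
        gdr_pct=gdr,
        fd_per_h=n_false / hours,
        duration_h=hours,
        n_true=len(tru),
        n_detected=n_detected,
        n_false=n_false,
    )


def compute_metrics_table(
    traces: list[ProbabilityTrace],
    truths: list[AnnotationTrack],
    thresholds: np.ndarray | None = None,
    collar_s: float = 0.0,
    level: str = "epoch",
) -> MetricsTable:
    """Sweep the threshold grid over every patient's fused trace.

    Fills SE/SP with epoch (burden) level confusion, pre-collar by default.
    Event-level threshold curves have no bounded specificity (false
    detections are a rate per hour, not a proportion), so they live in
    :func:`threshold_guide` instead.
    """
    if level != "epoch":
        raise ValueError("compute_metrics_table supports level='epoch'; use threshold_guide for events")
    grid = ThresholdGrid(thresholds if thresholds is not None else default_threshold_grid())
    N = grid.values.size
    M = len(traces)
    SE = np.full((N, M), np.nan)
    SP = np.full((N, M), np.nan)
    for j, (trace, truth) in enumerate(zip(traces, truths)):
        for i, th in enumerate(grid.values):
            dec = binarize(trace, threshold=th, collar_s=collar_s)
            se, sp = epoch_confusion(dec, truth)
            SE[i, j] = np.nan if se is None else se
            SP[i, j] = np.nan if sp is None else sp
    return MetricsTable(
        thresholds=grid.values, SE=SE, SP=SP, patient_ids=list(range(M)), level="epoch"
    )


def _roc_trapezoid(se: np.ndarray, sp: np.ndarray, endpoints: bool) -> float:
    """Trapezoidal AUC over the (SP, SE) curve, thresholds ascending."""
    if endpoints:
        sp = np.concatenate(([0.0], sp, [1.0]))
        se = np.concatenate(([1.0], se, [0.0]))
    return float(np.sum((sp[1:] - sp[:-1]) * (se[1:] + se[:-1]) / 2.0))


def _check_complete(table: MetricsTable) -> None:
    if np.isnan(table.SE).any() or np.isnan(table.SP).any():
        raise ValueError("metrics table has undefined cells; AUC requires a complete table")


def auc_per_patient_mean(table: MetricsTable, endpoints: bool = True) -> float:
    """AUC computed per patient, then averaged across patients."""
    _check_complete(table)
    aucs = [
        _roc_trapezoid(table.SE[:, j], table.SP[:, j], endpoints)
        for j in range(table.SE.shape[1])
    ]
    return float(np.mean(aucs))


def auc_pooled_thresholds(table: MetricsTable, endpoints: bool = True) -> float:
    """SE/SP averaged across patients per threshold, then one AUC."""
    _check_complete(table)
    se_bar = table.SE.mean(axis=1)
    sp_bar = table.SP.mean(axis=1)
    return _roc_trapezoid(se_bar, sp_bar, endpoints)


def threshold_guide(
    traces: list[ProbabilityTrace],
    truths: list[AnnotationTrack],
    thresholds: np.ndarray | None = None,
    collar_s: float = 32.0,
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> pd.DataFrame:
    """Threshold-selection curve: mean GDR and the upper 95% CI of FD/h.

    For each threshold, events are detected per patient (with the collar),
    the good detection rate is averaged across patients, and the upper bound
    of the 95% confidence interval of the mean false-detection rate per hour
    is estimated by a seeded percentile bootstrap over patients (or a normal
    approximation with ``ci_method='normal'``). With a single patient the CI
    is reported as NaN.
    """
    grid = ThresholdGrid(thresholds if thresholds is not None else default_threshold_grid())
    rng = np.random.default_rng(seed)
    M = len(traces)
    rows = []
    for th in grid.values:
        gdrs, fdhs = [], []
        for trace, truth in zip(traces, truths):
            score = event_metrics(binarize(trace, threshold=th, collar_s=collar_s), truth)
            if not np.isnan(score.gdr_pct):
                gdrs.append(score.gdr_pct)
            fdhs.append(score.fd_per_h)
        fdhs = np.asarray(fdhs)
        if M < 2:
            upper = np.nan
        elif ci_method == "bootstrap":
            upper = bootstrap_upper95(fdhs, n_boot=n_boot, rng=rng)
        elif ci_method == "normal":
            upper = float(fdhs.mean() + 1.959964 * fdhs.std(ddof=1) / np.sqrt(M))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        rows.append(
            {
                "threshold": float(th),
                "gdr_mean_pct": float(np.mean(gdrs)) if gdrs else np.nan,
                "fd_per_h_mean": float(fdhs.mean()),
                "fd_per_h_upper95": upper,
            }
        )
    return pd.DataFrame(rows)
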