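"""Temporal microstate parameters: duration, occurrence, contribution,
and the segment-wise transition-probability matrix.

A microstate segment is a maximal run of identically labeled samples.
Duration is the mean run length of a class (ms); occurrence is the
number of runs of that class per second of recording; contribution
(coverage) is the fraction of total samples carrying the class.
Transition probabilities are conditional: entry (X, Y) is the
probability that a segment of class X is immediately followed by one of
class Y, so the diagonal is structurally zero and each observed row
sums to one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microstates import CLASS_NAMES, Segmentation

# Fixed 24-feature layout used by the group statistics and the
# response-prediction model.
FEATURE_NAMES = (
    [f"Duration_{c}" for c in CLASS_NAMES]
    + [f"Occurrence_{c}" for c in CLASS_NAMES]
    + [f"Contribution_{c}" for c in CLASS_NAMES]
    + [f"OrgTM_{a}>{b}" for a in CLASS_NAMES for b in CLASS_NAMES if a != b]
)


def segments_of(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of identical labels as (class, start, length) triples."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


@dataclass
class MicrostateMetrics:
    """Per-class duration (ms), occurrence (1/s) and contribution (fraction).

    ``observed`` flags classes that appear at least once; for absent
    classes duration is reported as 0 and flagged rather than undefined,
    so downstream feature vectors stay complete.
    """

    duration_ms: np.ndarray
    occurrence_hz: np.ndarray
    contribution: np.ndarray
    observed: np.ndarray
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))


@dataclass
class TransitionMatrix:
    """Row-stochastic k x k matrix of segment-to-segment switch probabilities."""

    probabilities: np.ndarray
    row_observed: np.ndarray
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))


def _metrics_from_runs(run_classes: np.ndarray, run_lengths: np.ndarray,
                       n_samples: int, sampling_rate: float, k: int
                       ) -> MicrostateMetrics:
    duration = np.zeros(k)
    occurrence = np.zeros(k)
    contribution = np.zeros(k)
    observed = np.zeros(k, dtype=bool)
    total_s = n_samples / sampling_rate
    for c in range(k):
        mask = run_classes == c
        count = int(mask.sum())
        if count:
            observed[c] = True
            duration[c] = run_lengths[mask].mean() * 1000.0 / sampling_rate
            occurrence[c] = count / total_s
            contribution[c] = run_lengths[mask].sum() / n_samples
    names = CLASS_NAMES[:k] if k <= len(CLASS_NAMES) else [str(i) for i in range(k)]
    return MicrostateMetrics(duration, occurrence, contribution, observed, names)


def compute_metrics(labels: np.ndarray | Segmentation, sampling_rate: float | None = None,
                    k: int = 4) -> MicrostateMetrics:
    """Temporal parameters of a label sequence (or a :class:`Segmentation`).

    Edge runs (possibly truncated by the recording window) are included
    in the duration averages.
    """
    if isinstance(labels, Segmentation):
        sampling_rate = labels.sampling_rate
        labels = labels.labels
    if sampling_rate is None:
        raise ValueError("sampling_rate required with a raw label array")
    runs = segments_of(labels)
    classes = np.array([r[0] for r in runs])
    lengths = np.array([r[2] for r in runs])
    return _metrics_from_runs(classes, lengths, int(np.asarray(labels).size),
                              float(sampling_rate), k)


def compute_transitions(labels: np.ndarray | Segmentation, k: int = 4) -> TransitionMatrix:
    """Segment-wise transition probabilities (self-transitions impossible).

    With fewer than two segments there is nothing to count: an all-zero
    matrix is returned with every row flagged unobserved.
    """
    if isinstance(labels, Segmentation):
        labels = labels.labels
    runs = segments_of(labels)
    seq = np.array([r[0] for r in runs])
    counts = np.zeros((k, k))
    if seq.size >= 2:
        np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    np.fill_diagonal(counts, 0.0)
    row_sums = counts.sum(axis=1)
    row_observed = row_sums > 0
    probs = np.divide(counts, row_sums[:, None],
                      out=np.zeros_like(counts), where=row_sums[:, None] > 0)
    names = CLASS_NAMES[:k] if k <= len(CLASS_NAMES) else [str(i) for i in range(k)]
    return TransitionMatrix(probs, row_observed, names)


def feature_vector(metrics: MicrostateMetrics,
                   transitions: TransitionMatrix) -> pd.Series:
    """The fixed 24-element feature vector (durations, occurrences,
    contributions, then the 12 off-diagonal transition probabilities).

    Unobserved classes and unobserved transition rows are encoded as 0.
    """
    if len(metrics.duration_ms) != 4 or transitions.probabilities.shape != (4, 4):
        raise ValueError("feature vector requires the canonical 4-class layout")
    if metrics.class_names[:4] != CLASS_NAMES:
        raise ValueError("feature vector requires canonical A-D class labels")
    values = np.concatenate([
        metrics.duration_ms, metrics.occurrence_hz, metrics.contribution,
        [transitions.probabilities[a, b]
         for a in range(4) for b in range(4) if a != b],
    ])
    return pd.Series(values, index=FEATURE_NAMES)


def features_from_labels(labels: np.ndarray, sampling_rate: float) -> pd.Series:
    """Convenience: label path -> 24-feature vector."""
    return feature_vector(compute_metrics(labels, sampling_rate),
                          compute_transitions(labels))


def cohort_feature_table(subject_features: dict[str, pd.Series],
                         metadata: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: id, group, 24 features, HAMD scores."""
    rows = []
    meta = metadata.set_index("subject_id")
    for subject_id, feats in subject_features.items():
        row = {"subject_id": subject_id, "group": meta.loc[subject_id, "group"]}
        row.update(feats.to_dict())
        row["hamd_baseline"] = float(meta.loc[subject_id, "hamd_baseline"])
        row["hamd_post"] = float(meta.loc[subject_id, "hamd_post"])
        rows.append(row)
    return pd.DataFrame(rows)
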