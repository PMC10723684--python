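"""Per-subject dynamic state measures from state-label sequences.

Given the per-timepoint state assignments produced by clustering, this
module computes the standard dynamic summary measures: mean dwell time
per state (mean duration of a maximal run, in seconds), fraction of
time spent per state (fractional occupancy), number of state visits
(count of maximal runs), number of state transitions, and the empirical
transition-probability matrix P{X_next | X_prev} including
self-transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StateSequence",
    "StateMetrics",
    "TransitionMatrix",
    "occupancy_metrics",
    "transition_probabilities",
    "cohort_state_summary",
]


@dataclass
class StateSequence:
    """A subject's per-timepoint state labels (values ``1..k``)."""

    subject_id: str
    labels: np.ndarray
    tr_seconds: float = 1.6

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D vector")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class StateMetrics:
    """Dynamic measures for one subject.

    Per-state arrays are indexed ``state - 1``.  ``mean_dwell_seconds``
    is NaN for states never visited.  Boundary runs (truncated by the
    start or end of the scan) count toward visits and dwell.
    """

    subject_id: str
    k: int
    mean_dwell_seconds: np.ndarray
    fraction_of_time: np.ndarray
    n_visits: np.ndarray
    n_transitions: int
    tr_seconds: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-state table."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "state": np.arange(1, self.k + 1),
                "mean_dwell_seconds": self.mean_dwell_seconds,
                "fraction_of_time": self.fraction_of_time,
                "n_visits": self.n_visits,
                "n_transitions": self.n_transitions,
            }
        )


@dataclass
class TransitionMatrix:
    """Row-stochastic estimate of P{X_next | X_prev}.

    Rows of states that never occur before the final timepoint have no
    outgoing pairs; they are marked undefined (NaN rows) rather than
    zero-filled.  ``counts`` holds the raw pair counts.
    """

    subject_id: str
    k: int
    probabilities: np.ndarray
    counts: np.ndarray
    defined: np.ndarray  # boolean per row

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.k):
            for j in range(self.k):
                rows.append(
                    {
                        "subject_id": self.subject_id,
                        "from_state": i + 1,
                        "to_state": j + 1,
                        "probability": self.probabilities[i, j],
                        "count": int(self.counts[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal constant segments as (state, length) arrays."""
    change = np.nonzero(np.diff(labels))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    return labels[starts], ends - starts


def _check_labels(labels: np.ndarray, k: int) -> None:
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")


def occupancy_metrics(seq: StateSequence, k: int) -> StateMetrics:
    """Dwell, occupancy, visit and transition counts for one subject."""
    labels = seq.labels
    _check_labels(labels, k)
    states, lengths = _runs(labels)
    visits = np.bincount(states - 1, minlength=k)
    total_per_state = np.bincount(states - 1, weights=lengths, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dwell = np.where(
            visits > 0, total_per_state / np.maximum(visits, 1), np.nan
        )
    return StateMetrics(
        subject_id=seq.subject_id,
        k=k,
        mean_dwell_seconds=mean_dwell * seq.tr_seconds,
        fraction_of_time=total_per_state / labels.size,
        n_visits=visits,
        n_transitions=int(np.count_nonzero(np.diff(labels))),
        tr_seconds=seq.tr_seconds,
    )


def transition_probabilities(seq: StateSequence, k: int) -> TransitionMatrix:
    """Empirical P{X_next | X_prev} over all consecutive pairs.

    Self-transitions are included; rows are normalised by their
    outgoing pair count.
    """
    labels = seq.labels
    if labels.size < 2:
        raise ValueError("need at least 2 timepoints to estimate transitions")
    _check_labels(labels, k)
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1.0)
    out = counts.sum(axis=1)
    defined = out > 0
    probabilities = np.full((k, k), np.nan)
    probabilities[defined] = counts[defined] / out[defined, None]
    return TransitionMatrix(
        subject_id=seq.subject_id,
        k=k,
        probabilities=probabilities,
        counts=counts,
        defined=defined,
    )


def cohort_state_summary(
    sequences: list[StateSequence], k: int
) -> tuple[pd.Series, pd.DataFrame, bool]:
    """Pooled occupancy and per-subject metric table for a cohort.

    Returns the pooled fraction of timepoints per state (across all
    subjects and timepoints), the tidy per-subject-per-state metrics
    table ready for the inferential stage, and a flag that is True when
    every subject visited every state at least once.
    """
    if not sequences:
        raise ValueError("need at least one subject")
    frames = []
    pooled_counts = np.zeros(k)
    total = 0
    all_visited = True
    for seq in sequences:
        metrics = occupancy_metrics(seq, k)
        frames.append(metrics.to_frame())
        pooled_counts += np.bincount(seq.labels - 1, minlength=k)
        total += seq.labels.size
        if np.any(metrics.n_visits == 0):
            all_visited = False
    pooled = pd.Series(
        pooled_counts / total,
        index=pd.Index(np.arange(1, k + 1), name="state"),
        name="pooled_fraction",
    )
    return pooled, pd.concat(frames, ignore_index=True), all_visited
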