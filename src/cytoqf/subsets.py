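"""Cluster (subset) summaries shared by the matching and display stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError

__all__ = ["Subset", "subsets_from_labels"]


@dataclass
class Subset:
    """One identified cell population within a sample."""

    label: int
    event_indices: np.ndarray
    median: np.ndarray  # per-channel
    sd: np.ndarray  # per-channel
    frequency: float  # member count / total sample events
    sample_id: str = ""

    @property
    def n_events(self) -> int:
        return len(self.event_indices)


def subsets_from_labels(
    values: np.ndarray, labels: np.ndarray, sample_id: str = ""
) -> list[Subset]:
    """Summarize a label vector (labels >= 1; 0 = unassigned, ignored)."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise EmptyInputError(
            f"{labels.shape[0]} labels for {values.shape[0]} events"
        )
    uniq = [int(u) for u in np.unique(labels) if u >= 1]
    if not uniq:
        raise EmptyInputError("no assigned events (all labels < 1)")
    total = values.shape[0]
    out = []
    for u in uniq:
        idx = np.flatnonzero(labels == u)
        member = values[idx]
        out.append(
            Subset(
                label=u,
                event_indices=idx,
                median=np.median(member, axis=0),
                sd=member.std(axis=0, ddof=1) if len(idx) > 1 else np.zeros(values.shape[1]),
                frequency=len(idx) / total,
                sample_id=sample_id,
            )
        )
    return out
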