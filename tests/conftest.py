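"""Shared fixtures: the canonical simulated sample pair and its clustering."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from cytoqf import canonical_fixture, epp_cluster
from cytoqf.epp import epp_labels


@pytest.fixture(scope="session")
def canonical_pair():
    """Full-scale canonical A/B pair (seed 1): 3 vs 4 Gaussian components."""
    return canonical_fixture(seed=1)


@pytest.fixture(scope="session")
def epp_results(canonical_pair):
    """EPP clustering of both canonical samples (computed once per session)."""
    out = {}
    for tag, em in (("A", canonical_pair.events_a), ("B", canonical_pair.events_b)):
        tree, subsets = epp_cluster(em)
        out[tag] = {
            "tree": tree,
            "subsets": subsets,
            "labels": epp_labels(tree, em.n_events),
        }
    return out


def agreement(labels: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of events agreeing under the optimal leaf<->group assignment."""
    ks, gs = np.unique(labels), np.unique(truth)
    cost = np.zeros((len(ks), len(gs)))
    for i, k in enumerate(ks):
        for j, g in enumerate(gs):
            cost[i, j] = np.sum((labels == k) & (truth == g))
    ri, ci = linear_sum_assignment(-cost)
    return float(cost[ri, ci].sum() / len(truth))


def leaf_to_group(labels: np.ndarray, truth: np.ndarray) -> dict[int, int]:
    """Majority-vote mapping from clustering labels to ground-truth groups."""
    return {
        int(k): int(np.bincount(truth[labels == k]).argmax())
        for k in np.unique(labels)
        if k >= 1
    }


def matches_as_groups(result, map_a, map_b):
    """Final matches translated to ground-truth group ids for comparison."""
    return {
        (
            tuple(sorted(map_a[l] for l in m.a_labels)),
            tuple(sorted(map_b[l] for l in m.b_labels)),
            m.kind,
        )
        for m in result.matches
    }
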