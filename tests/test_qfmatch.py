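"""Cluster matching, merging and split/missing decisions."""

import numpy as np
import pytest

from cytoqf import (
    MatchConfig,
    canonical_fixture,
    match,
    match_and_resolve,
    median_gate,
    resolve_merging,
    subsets_from_labels,
)
from cytoqf.errors import EmptyInputError
from cytoqf.subsets import Subset
from conftest import leaf_to_group, matches_as_groups


def make_subset(median, sd, label=1, n=100):
    return Subset(
        label=label,
        event_indices=np.arange(n),
        median=np.asarray(median, dtype=float),
        sd=np.asarray(sd, dtype=float),
        frequency=1.0,
    )


class TestMedianGate:
    def test_identical_subsets_pass(self):
        s = make_subset([0, 0, 0], [1, 1, 1])
        assert median_gate(s, s)

    def test_five_sd_apart_fails(self):
        a = make_subset([0, 0, 0], [1, 1, 1])
        b = make_subset([5, 0, 0], [1, 1, 1], label=2)
        assert not median_gate(a, b)
        assert median_gate(a, make_subset([4, 0, 0], [1, 1, 1], label=3))

    def test_uses_larger_sd(self):
        a = make_subset([0, 0], [0.1, 1])
        b = make_subset([3, 0], [1, 1], label=2)
        assert median_gate(a, b)  # 3 <= 4*max(0.1, 1)

    def test_zero_sd_dimension_requires_equality(self):
        a = make_subset([0, 5], [1, 0])
        assert median_gate(a, make_subset([0, 5], [1, 0], label=2))
        assert not median_gate(a, make_subset([0, 5.01], [1, 0], label=3))

    def test_channel_mismatch(self):
        with pytest.raises(ValueError):
            median_gate(make_subset([0], [1]), make_subset([0, 0], [1, 1]))


@pytest.fixture(scope="module")
def truth_matched():
    """QFMatch on the canonical pair using ground-truth cluster labels."""
    pair = canonical_fixture(seed=1)
    subs_a = subsets_from_labels(pair.events_a.values, pair.labels_a, "A")
    subs_b = subsets_from_labels(pair.events_b.values, pair.labels_b, "B")
    pre = match(subs_a, subs_b, pair.events_a.values, pair.events_b.values)
    return pair, pre


class TestMatch:
    def test_canonical_structure(self, truth_matched):
        """Three one-to-one matches; one B-side subset left as a merging
        candidate (the other half of the split population)."""
        _, pre = truth_matched
        assert len(pre.matches) == 3
        assert all(m.kind == "match" for m in pre.matches)
        assert len(pre.unmatched_candidates) == 1
        (tag, label) = pre.unmatched_candidates[0]
        assert tag == "B" and label in (3, 4)
        # the cross-sample gate excludes distant population pairs
        assert len(pre.candidate_table.gated_out) > 0

    def test_stable_match_scores_far_below_split_scores(self, truth_matched):
        """Populations present unchanged in both samples (groups 1, 2) score
        an order of magnitude below any pairing that involves the split
        region (group 3 vs either half)."""
        _, pre = truth_matched
        scores = pre.candidate_table.scores
        stable = [scores[(1, 1)], scores[(2, 2)]]
        split_related = [s for (a, b), s in scores.items() if a == 3]
        assert split_related
        assert max(stable) * 10 < min(split_related)

    def test_self_match_identity(self, truth_matched):
        pair, _ = truth_matched
        subs = subsets_from_labels(pair.events_a.values, pair.labels_a, "A")
        res = match_and_resolve(
            subs, subs, pair.events_a.values, pair.events_a.values
        )
        assert len(res.matches) == len(subs) and not res.missing
        for m in res.matches:
            assert m.a_labels == m.b_labels
            assert m.score < 1e-9

    def test_label_permutation_invariance(self, truth_matched):
        pair, pre = truth_matched
        relabel = {1: 3, 2: 1, 3: 4, 4: 2}
        lab_b = np.vectorize(relabel.get)(pair.labels_b)
        subs_a = subsets_from_labels(pair.events_a.values, pair.labels_a, "A")
        subs_b = subsets_from_labels(pair.events_b.values, lab_b, "B")
        res = match(subs_a, subs_b, pair.events_a.values, pair.events_b.values)
        orig = {(m.a_labels[0], relabel[m.b_labels[0]]) for m in pre.matches}
        new = {(m.a_labels[0], m.b_labels[0]) for m in res.matches}
        assert orig == new

    def test_score_symmetry(self, truth_matched):
        pair, pre = truth_matched
        subs_a = subsets_from_labels(pair.events_a.values, pair.labels_a, "A")
        subs_b = subsets_from_labels(pair.events_b.values, pair.labels_b, "B")
        swapped = match(
            subs_b, subs_a, pair.events_b.values, pair.events_a.values
        )
        for (la, lb), s in pre.candidate_table.scores.items():
            assert swapped.candidate_table.scores[(lb, la)] == pytest.approx(
                s, abs=1e-12
            )

    def test_empty_subset_list_rejected(self, truth_matched):
        pair, _ = truth_matched
        subs = subsets_from_labels(pair.events_a.values, pair.labels_a, "A")
        with pytest.raises(EmptyInputError):
            match(subs, [], pair.events_a.values, pair.events_b.values)


class TestResolveMerging:
    def test_split_detected(self, truth_matched):
        """Pooling the leftover B cluster with its neighbor lowers the score
        below the initial one, so the A population is recorded as split."""
        pair, pre = truth_matched
        final = resolve_merging(pre)
        assert not final.missing
        split = [m for m in final.matches if m.kind == "split"]
        assert len(split) == 1
        assert split[0].a_labels == (3,)
        assert split[0].b_labels == (3, 4)
        (tag, cand_label) = pre.unmatched_candidates[0]
        initial = pre.candidate_table.scores[(3, cand_label)]
        assert split[0].score < initial

    def test_no_candidates_is_noop(self, truth_matched):
        pair, _ = truth_matched
        subs = subsets_from_labels(pair.events_a.values, pair.labels_a, "A")
        pre = match(subs, subs, pair.events_a.values, pair.events_a.values)
        final = resolve_merging(pre)
        assert [m.kind for m in final.matches] == ["match"] * len(subs)

    def test_far_outlier_reported_missing(self):
        """A cluster 50 SD away from everything has no counterpart."""
        pair = canonical_fixture(seed=2, scale=0.25)
        vb = pair.events_b.values.copy()
        lab_b = pair.labels_b.copy()
        extra = np.random.default_rng(0).normal([50.0, 50.0, 50.0], 1.0, (400, 3))
        vb = np.vstack([vb, extra])
        lab_b = np.concatenate([lab_b, np.full(400, 5)])
        subs_a = subsets_from_labels(pair.events_a.values, pair.labels_a, "A")
        subs_b = subsets_from_labels(vb, lab_b, "B")
        final = match_and_resolve(subs_a, subs_b, pair.events_a.values, vb)
        assert ("B", 5) in final.missing

    def test_coverage(self, truth_matched):
        pair, pre = truth_matched
        final = resolve_merging(pre)
        seen_a = sorted(l for m in final.matches for l in m.a_labels)
        seen_b = sorted(l for m in final.matches for l in m.b_labels) + sorted(
            l for (t, l) in final.missing if t == "B"
        )
        assert seen_a == [1, 2, 3]
        assert seen_b == [1, 2, 3, 4]

    def test_ground_truth_recovery_across_seeds(self):
        """The generator-expected match set is recovered in >= 90% of 20
        seeded replicates of the canonical fixture."""
        hits = 0
        for seed in range(20):
            pair = canonical_fixture(seed=seed, scale=0.5)
            subs_a = subsets_from_labels(pair.events_a.values, pair.labels_a, "A")
            subs_b = subsets_from_labels(pair.events_b.values, pair.labels_b, "B")
            final = match_and_resolve(
                subs_a, subs_b, pair.events_a.values, pair.events_b.values
            )
            ident = {i: i for i in range(1, 5)}
            got = matches_as_groups(final, ident, ident)
            want = {
                (tuple(m.a_groups), tuple(m.b_groups), m.kind)
                for m in pair.expected_matches
            }
            hits += got == want
        assert hits >= 18
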