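"""Cluster matching across two samples with split/missing resolution.

Candidate cluster pairs whose medians lie within 4 SD of each other in every
dimension are scored with the quadratic-form dissimilarity over one shared
adaptive binning of the full sample pair.  Pairs are accepted greedily by
globally smallest score, one-to-one.  Each leftover cluster is then tested
by exhaustive merging: it is pooled with combinations of clusters from its
own sample (its counterpart's matched partner and any other leftover
candidates) and re-scored against the counterpart; if some merged pooling
scores strictly below the candidate's initial pairwise score the counterpart
is declared *split* across the merged group, otherwise the candidate is
*missing* from the other sample.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .qf_core import Binning, adaptive_bin, bin_cluster, qf_distance, similarity_matrix
from .subsets import Subset

logger = logging.getLogger(__name__)

__all__ = [
    "MatchConfig",
    "CandidateTable",
    "Match",
    "MatchResult",
    "median_gate",
    "match",
    "resolve_merging",
    "match_and_resolve",
    "write_match_report",
]


@dataclass(frozen=True)
class MatchConfig:
    gate_multiplier: float = 4.0
    merge_combination_cap: int = 1024


@dataclass
class CandidateTable:
    """Scored pairs and gate-excluded pairs, keyed by (a_label, b_label)."""

    scores: dict[tuple[int, int], float] = field(default_factory=dict)
    gated_out: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Match:
    a_labels: tuple[int, ...]
    b_labels: tuple[int, ...]
    score: float
    kind: str  # "match" or "split"


@dataclass
class MatchResult:
    matches: list[Match]
    missing: list[tuple[str, int]]  # (sample tag "A"/"B", subset label)
    candidate_table: CandidateTable
    # context carried from match() to resolve_merging()
    _ctx: dict = field(default_factory=dict, repr=False)

    @property
    def unmatched_candidates(self) -> list[tuple[str, int]]:
        return list(self._ctx.get("candidates", []))


def median_gate(a: Subset, b: Subset, multiplier: float = 4.0) -> bool:
    """True iff medians are within ``multiplier`` SDs in every dimension.

    The per-dimension scale is the larger of the two subsets' SDs; when both
    SDs are zero the medians must agree exactly in that dimension.
    """
    if a.median.shape != b.median.shape:
        raise ValueError("subsets do not share channel space")
    delta = np.abs(a.median - b.median)
    scale = np.maximum(a.sd, b.sd)
    zero = scale == 0
    if np.any(delta[zero] != 0):
        return False
    return bool(np.all(delta[~zero] <= multiplier * scale[~zero]))


def _pooled_subset(subsets: list[Subset], values: np.ndarray) -> Subset:
    idx = np.concatenate([s.event_indices for s in subsets])
    member = values[idx]
    return Subset(
        label=min(s.label for s in subsets),
        event_indices=idx,
        median=np.median(member, axis=0),
        sd=member.std(axis=0, ddof=1) if len(idx) > 1 else np.zeros(values.shape[1]),
        frequency=sum(s.frequency for s in subsets),
        sample_id=subsets[0].sample_id,
    )


def match(
    subsets_a: list[Subset],
    subsets_b: list[Subset],
    events_a: np.ndarray,
    events_b: np.ndarray,
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Greedy one-to-one matching by smallest quadratic-form score.

    Builds one shared binning over the full samples, scores every
    gate-passing pair, and repeatedly accepts the globally smallest
    remaining score (ties broken by the lexicographically lower label
    pair).  Unpaired subsets become merging candidates for
    :func:`resolve_merging`.
    """
    if not subsets_a or not subsets_b:
        raise EmptyInputError("both samples must have at least one subset")
    events_a = np.asarray(events_a, dtype=np.float64)
    events_b = np.asarray(events_b, dtype=np.float64)

    binning = adaptive_bin(events_a, events_b)
    sim = similarity_matrix(binning)
    if binning.B == 1:
        logger.warning(
            "degenerate single-bin binning: QF scores are all zero; "
            "matching will be driven by median distances"
        )

    dist_a = {
        s.label: bin_cluster(binning, events_a, s.event_indices, f"A:{s.label}")
        for s in subsets_a
    }
    dist_b = {
        s.label: bin_cluster(binning, events_b, s.event_indices, f"B:{s.label}")
        for s in subsets_b
    }

    table = CandidateTable()
    by_label_a = {s.label: s for s in subsets_a}
    by_label_b = {s.label: s for s in subsets_b}
    for sa in subsets_a:
        for sb in subsets_b:
            if median_gate(sa, sb, config.gate_multiplier):
                table.scores[(sa.label, sb.label)] = qf_distance(
                    dist_a[sa.label], dist_b[sb.label], sim
                )
            else:
                table.gated_out.append((sa.label, sb.label))

    ordered = sorted(table.scores.items(), key=lambda kv: (kv[1], kv[0]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[Match] = []
    for (la, lb), score in ordered:
        if la in used_a or lb in used_b:
            continue
        if binning.B == 1:
            # fall back to median-distance ordering within the degenerate case
            score = float(
                np.linalg.norm(by_label_a[la].median - by_label_b[lb].median)
            )
        matches.append(Match((la,), (lb,), score, "match"))
        used_a.add(la)
        used_b.add(lb)

    candidates = [("A", s.label) for s in subsets_a if s.label not in used_a]
    candidates += [("B", s.label) for s in subsets_b if s.label not in used_b]

    return MatchResult(
        matches=matches,
        missing=[],
        candidate_table=table,
        _ctx={
            "binning": binning,
            "sim": sim,
            "subsets_a": by_label_a,
            "subsets_b": by_label_b,
            "events_a": events_a,
            "events_b": events_b,
            "dist_a": dist_a,
            "dist_b": dist_b,
            "candidates": candidates,
            "config": config,
        },
    )


def resolve_merging(result: MatchResult) -> MatchResult:
    """Decide split vs missing for every unmatched merging candidate.

    For a candidate c in sample S and each counterpart x in the other
    sample whose pair (x, c) passed the median gate, all non-empty
    combinations of c with x's matched partner and S's other candidates are
    pooled, gated against x, and re-scored on the original binning.  The
    best pooled score is compared with the candidate's initial pairwise
    score against x: strictly lower means x is split across the pooled
    group; no improving combination anywhere means c is missing.
    """
    ctx = result._ctx
    if not ctx:
        raise EmptyInputError("resolve_merging needs the context from match()")
    config: MatchConfig = ctx["config"]
    binning: Binning = ctx["binning"]
    sim = ctx["sim"]
    candidates: list[tuple[str, int]] = list(ctx["candidates"])
    if not candidates:
        result.missing = []
        return result

    matches = list(result.matches)
    missing: list[tuple[str, int]] = []
    resolved: set[tuple[str, int]] = set()

    def side_data(tag: str):
        if tag == "A":
            return ctx["subsets_a"], ctx["events_a"], ctx["dist_a"]
        return ctx["subsets_b"], ctx["events_b"], ctx["dist_b"]

    for cand in candidates:
        if cand in resolved:
            continue
        tag, c_label = cand
        other_tag = "B" if tag == "A" else "A"
        own_subsets, own_events, own_dists = side_data(tag)
        other_subsets, other_events, other_dists = side_data(other_tag)
        c_sub = own_subsets[c_label]

        best: tuple[float, int, tuple[int, ...], Match | None] | None = None
        for x_label, x_sub in sorted(other_subsets.items()):
            pair_key = (c_label, x_label) if tag == "A" else (x_label, c_label)
            if pair_key not in result.candidate_table.scores:
                continue
            initial = result.candidate_table.scores[pair_key]
            # pool: x's current partner(s) on our side, plus other candidates
            partner_match = next(
                (
                    m
                    for m in matches
                    if x_label in (m.a_labels if other_tag == "A" else m.b_labels)
                ),
                None,
            )
            mandatory: list[int] = []
            if partner_match is not None:
                mandatory = list(
                    partner_match.b_labels if tag == "B" else partner_match.a_labels
                )
            optional = [
                lab
                for (t, lab) in candidates
                if t == tag and lab != c_label and (t, lab) not in resolved
            ]
            combos = []
            for r in range(len(optional) + 1):
                for extra in itertools.combinations(optional, r):
                    if not mandatory and not extra:
                        continue  # need at least one other cluster to pool with
                    combos.append(tuple(extra))
                    if len(combos) >= config.merge_combination_cap:
                        break
                if len(combos) >= config.merge_combination_cap:
                    break
            for extra in combos:
                group_labels = tuple(sorted({c_label, *mandatory, *extra}))
                group = _pooled_subset(
                    [own_subsets[g] for g in group_labels], own_events
                )
                if not median_gate(x_sub, group, config.gate_multiplier):
                    continue
                pooled_dist = bin_cluster(
                    binning, own_events, group.event_indices,
                    f"{tag}:{'+'.join(map(str, group_labels))}",
                )
                merged_score = qf_distance(other_dists[x_label], pooled_dist, sim)
                if merged_score < initial and (
                    best is None
                    or (merged_score, x_label, group_labels)
                    < (best[0], best[1], best[2])
                ):
                    best = (merged_score, x_label, group_labels, partner_match)

        if best is None:
            missing.append(cand)
            resolved.add(cand)
            continue

        merged_score, x_label, group_labels, partner_match = best
        if partner_match is not None:
            matches.remove(partner_match)
        if tag == "B":
            new = Match((x_label,), group_labels, merged_score, "split")
        else:
            new = Match(group_labels, (x_label,), merged_score, "split")
        matches.append(new)
        for g in group_labels:
            resolved.add((tag, g))

    # coverage check: every subset appears exactly once
    seen_a = [l for m in matches for l in m.a_labels] + [
        l for (t, l) in missing if t == "A"
    ]
    seen_b = [l for m in matches for l in m.b_labels] + [
        l for (t, l) in missing if t == "B"
    ]
    assert sorted(seen_a) == sorted(ctx["subsets_a"]), "A-side coverage violated"
    assert sorted(seen_b) == sorted(ctx["subsets_b"]), "B-side coverage violated"

    final = MatchResult(
        matches=matches,
        missing=missing,
        candidate_table=result.candidate_table,
        _ctx=ctx,
    )
    return final


def match_and_resolve(
    subsets_a: list[Subset],
    subsets_b: list[Subset],
    events_a: np.ndarray,
    events_b: np.ndarray,
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Full QFMatch: greedy matching followed by split/missing resolution."""
    return resolve_merging(match(subsets_a, subsets_b, events_a, events_b, config))


def write_match_report(result: MatchResult, path) -> Path:
    """Write the final matching as CSV (a_labels, b_labels, score, kind)."""
    rows = [
        {
            "a_labels": "+".join(map(str, m.a_labels)),
            "b_labels": "+".join(map(str, m.b_labels)),
            "score": m.score,
            "kind": m.kind,
        }
        for m in result.matches
    ]
    rows += [
        {
            "a_labels": str(l) if t == "A" else "",
            "b_labels": str(l) if t == "B" else "",
            "score": float("nan"),
            "kind": "missing",
        }
        for (t, l) in result.missing
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["a_labels", "b_labels", "score", "kind"]).to_csv(
        path, index=False
    )
    return path
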