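"""Paired Gaussian-mixture samples for end-to-end pipeline testing.

The canonical scenario is two comparable stained samples where one cell
population of Sample A appears split into two subpopulations in Sample B
(e.g. an activation marker separating a formerly homogeneous subset).  The
generator draws events from diagonal-covariance Gaussian mixtures, carries
ground-truth component labels, and records the cluster correspondence that a
matching algorithm should recover — so downstream tests assert against the
construction rather than magic numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_fcs import EventMatrix, write_csv_events, write_labels

__all__ = [
    "Component",
    "MixtureSpec",
    "ExpectedMatch",
    "SimulatedPair",
    "simulate_pair",
    "default_paper_like_specs",
    "canonical_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class Component:
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    n: int
    group_id: int


@dataclass(frozen=True)
class MixtureSpec:
    """A diagonal-covariance Gaussian mixture in ``dims`` dimensions."""

    dims: int
    components: tuple[Component, ...]
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.dims < 2:
            raise ValidationError("dims must be >= 2")
        ids = [c.group_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValidationError("group ids must be unique within a sample")
        for c in self.components:
            if len(c.mean) != self.dims or len(c.sd) != self.dims:
                raise ValidationError("component mean/sd must match dims")
            if any(s <= 0 for s in c.sd):
                raise ValidationError("all SDs must be > 0")
            if c.n < 1:
                raise ValidationError("all component counts must be >= 1")

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.components)

    def scaled(self, factor: float) -> "MixtureSpec":
        """Same mixture with component counts scaled (min 1 event each)."""
        comps = tuple(
            Component(c.mean, c.sd, max(1, round(c.n * factor)), c.group_id)
            for c in self.components
        )
        return MixtureSpec(self.dims, comps, self.sample_id)


@dataclass(frozen=True)
class ExpectedMatch:
    """Ground-truth correspondence between component groups of A and B."""

    a_groups: tuple[int, ...]
    b_groups: tuple[int, ...]
    kind: str  # "match" or "split"


@dataclass
class SimulatedPair:
    events_a: EventMatrix
    labels_a: np.ndarray
    events_b: EventMatrix
    labels_b: np.ndarray
    expected_matches: list[ExpectedMatch] = field(default_factory=list)


def _simulate_one(spec: MixtureSpec, rng: np.random.Generator) -> tuple[EventMatrix, np.ndarray]:
    blocks, labels = [], []
    for c in spec.components:
        x = rng.normal(loc=c.mean, scale=c.sd, size=(c.n, spec.dims))
        blocks.append(x)
        labels.append(np.full(c.n, c.group_id, dtype=np.int64))
    values = np.vstack(blocks)
    em = EventMatrix(
        values=values,
        channel_names=[f"M{k + 1}" for k in range(spec.dims)],
        sample_id=spec.sample_id,
    )
    return em, np.concatenate(labels)


def simulate_pair(
    spec_a: MixtureSpec, spec_b: MixtureSpec, seed: int
) -> tuple[EventMatrix, np.ndarray, EventMatrix, np.ndarray]:
    """Draw both samples; identical (specs, seed) give bit-identical output.

    Each sample uses its own PCG64 stream keyed by (seed, sample index), so
    changing one spec never perturbs the other sample's draws.
    """
    em_a, lab_a = _simulate_one(spec_a, np.random.default_rng([seed, 0]))
    em_b, lab_b = _simulate_one(spec_b, np.random.default_rng([seed, 1]))
    return em_a, lab_a, em_b, lab_b


def default_paper_like_specs() -> tuple[MixtureSpec, MixtureSpec]:
    """Canonical 3D two-sample scenario with one split population.

    Sample A has 3 well-separated unit-SD components (pairwise mean
    separation 12 SD).  Sample B repeats A's first two components and
    replaces the third with two half-size components whose joint mean equals
    A3's mean and whose centers are 4 SD apart along the third channel —
    far enough apart that the split is statistically detectable (two equal
    unit-SD Gaussians 4 SD apart overlap with Bayes error Phi(-2) ~ 2.3%),
    yet jointly occupying A3's region so that a matcher must recognise the
    pair as a split of A3 rather than two unrelated populations.
    """
    sd = (1.0, 1.0, 1.0)
    spec_a = MixtureSpec(
        dims=3,
        components=(
            Component((0.0, 0.0, 0.0), sd, 8000, 1),
            Component((12.0, 0.0, 0.0), sd, 6000, 2),
            Component((0.0, 12.0, 0.0), sd, 6000, 3),
        ),
        sample_id="A",
    )
    spec_b = MixtureSpec(
        dims=3,
        components=(
            Component((0.0, 0.0, 0.0), sd, 8000, 1),
            Component((12.0, 0.0, 0.0), sd, 6000, 2),
            Component((0.0, 12.0, -2.0), sd, 3000, 3),
            Component((0.0, 12.0, 2.0), sd, 3000, 4),
        ),
        sample_id="B",
    )
    return spec_a, spec_b


_CANONICAL_EXPECTED = [
    ExpectedMatch((1,), (1,), "match"),
    ExpectedMatch((2,), (2,), "match"),
    ExpectedMatch((3,), (3, 4), "split"),
]


def canonical_fixture(seed: int = 0, scale: float = 1.0) -> SimulatedPair:
    """The canonical A/B pair plus its expected matching, ready to use.

    ``scale`` multiplies component event counts (used to run the same
    scenario at reduced size in repeated-seed property checks).
    """
    spec_a, spec_b = default_paper_like_specs()
    if scale != 1.0:
        spec_a, spec_b = spec_a.scaled(scale), spec_b.scaled(scale)
    em_a, lab_a, em_b, lab_b = simulate_pair(spec_a, spec_b, seed)
    return SimulatedPair(em_a, lab_a, em_b, lab_b, list(_CANONICAL_EXPECTED))


def write_fixture(pair: SimulatedPair, out_dir) -> dict[str, Path]:
    """Write events, ground-truth labels and expected matches to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, em, lab in (
        ("a", pair.events_a, pair.labels_a),
        ("b", pair.events_b, pair.labels_b),
    ):
        paths[f"events_{tag}"] = write_csv_events(em, out / f"sample_{tag}.csv")
        paths[f"labels_{tag}"] = write_labels(lab, out / f"labels_{tag}.csv")
    meta = {
        "expected_matches": [
            {"a_groups": list(m.a_groups), "b_groups": list(m.b_groups), "kind": m.kind}
            for m in pair.expected_matches
        ]
    }
    p = out / "expected_matches.json"
    p.write_text(json.dumps(meta, indent=2))
    paths["expected"] = p
    return paths
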