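"""Combinatorics of arm-location patterns under pericentric inversions.

A pericentric inversion spans the centromere, so it carries one breakpoint
on each arm; every gene closer to the centromere than the breakpoint on its
arm is relocated to the opposite arm.  Given an inversion on some subset of
the three homoeologues (A, B, D) of one group, with per-arm breakpoint
depths, each gene's homoeologous triplet becomes a deterministic function
of its ancestral arm and its distance from the centromere.

Only comparisons between a gene's depth and the breakpoint depths matter,
so breakpoints are modelled as small integer ranks and probe genes as
half-integer depths: this finite space exhausts the behaviour of the
continuous model.  Exhaustive search over every configuration (all subsets
of inverted homoeologues x all rank assignments with ties on each arm)
shows that a single genotype can display at most FOUR distinct nonstandard
arm-location triplets; genes encompassed by inversions on all three
homoeologues appear standard.  Observed pattern sets exceeding that bound
(five patterns on the wheat group 4, 6 and 7 chromosomes) are therefore
infeasible for a single genotype with at most one pericentric inversion
per chromosome.

The engine works in "homoeologous set" space (short set vs long set) and
renders physical arm letters through an ExpectedHomoeologyTable, so the
group-4 arm swap changes labels but never the combinatorics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .errors import DegenerateInputError, ValidationError
from .homoeology import (
    ARMS,
    DEFAULT_TABLE,
    SUBGENOMES,
    ExpectedHomoeologyTable,
    other_arm,
)


@dataclass(frozen=True)
class InversionConfiguration:
    """Per-homoeologue pericentric inversion breakpoints.

    ``depths[sg] = (s, l)`` gives the breakpoint depth (distance from the
    centromere, arbitrary units) on the short-set and long-set side of
    subgenome ``sg``.  An inversion is present iff both depths are
    positive; a pericentric inversion necessarily breaks both arms.
    """

    depths: tuple[tuple[str, float, float], ...]

    @classmethod
    def from_mapping(
        cls, depths: Mapping[str, tuple[float, float]]
    ) -> "InversionConfiguration":
        rows = []
        for sg in SUBGENOMES:
            s, l = depths.get(sg, (0.0, 0.0))
            if (s > 0) != (l > 0):
                raise ValidationError(
                    f"subgenome {sg}: a pericentric inversion needs breakpoints on "
                    f"both arms (got s={s}, l={l})"
                )
            if s < 0 or l < 0:
                raise ValidationError(f"subgenome {sg}: negative breakpoint depth")
            rows.append((sg, float(s), float(l)))
        unknown = set(depths) - set(SUBGENOMES)
        if unknown:
            raise ValidationError(f"unknown subgenomes: {sorted(unknown)}")
        return cls(tuple(rows))

    def present(self, subgenome: str) -> bool:
        return self._depth(subgenome, "S") > 0

    def breakpoint(self, subgenome: str, side: str) -> float:
        if side not in ARMS:
            raise ValidationError(f"side must be 'S' or 'L', got {side!r}")
        return self._depth(subgenome, side)

    def _depth(self, subgenome: str, side: str) -> float:
        for sg, s, l in self.depths:
            if sg == subgenome:
                return s if side == "S" else l
        raise ValidationError(f"unknown subgenome {subgenome!r}")

    @property
    def n_inverted(self) -> int:
        return sum(self.present(sg) for sg in SUBGENOMES)

    def to_mapping(self) -> dict[str, tuple[float, float]]:
        return {sg: (s, l) for sg, s, l in self.depths}


NO_INVERSIONS = InversionConfiguration.from_mapping({})


@dataclass(frozen=True)
class ProbeGene:
    """A marker gene with an ancestral side and a depth from the centromere."""

    ancestral_arm: str  # 'S' (short set) or 'L' (long set)
    depth: float

    def __post_init__(self) -> None:
        if self.ancestral_arm not in ARMS:
            raise ValidationError(f"ancestral arm must be 'S' or 'L', got {self.ancestral_arm!r}")
        if self.depth <= 0:
            raise ValidationError(f"probe depth must be positive, got {self.depth}")


def _render(sets_by_sg: Mapping[str, str], group: int, table: ExpectedHomoeologyTable) -> str:
    return "/".join(
        f"{group}{sg}{table.set_arm(group, sg, sets_by_sg[sg])}" for sg in SUBGENOMES
    )


def derive_pattern(
    config: InversionConfiguration,
    probe: ProbeGene,
    group: int = 6,
    table: ExpectedHomoeologyTable = DEFAULT_TABLE,
) -> str:
    """Arm-location triplet of one probe gene under a configuration.

    On each subgenome the probe moves to the opposite set iff an inversion
    is present there and the probe is shallower than the breakpoint on the
    probe's ancestral side.  Probe depths equal to a breakpoint are
    degenerate (general position is required) and raise an error.
    """
    side = probe.ancestral_arm
    sets = {}
    for sg in SUBGENOMES:
        bp = config.breakpoint(sg, side)
        if config.present(sg) and probe.depth == bp:
            raise DegenerateInputError(
                f"probe depth {probe.depth} coincides with the {side}-side "
                f"breakpoint of subgenome {sg}"
            )
        moved = config.present(sg) and probe.depth < bp
        sets[sg] = other_arm(side) if moved else side
    return _render(sets, group, table)


def _interval_probes(depths: list[float]) -> list[float]:
    """Probe depths covering every interval delimited by the breakpoints."""
    bounds = sorted(set(d for d in depths if d > 0))
    probes = []
    prev = 0.0
    for b in bounds:
        probes.append((prev + b) / 2.0)
        prev = b
    probes.append(prev + 1.0)
    return probes


def enumerate_patterns(
    config: InversionConfiguration,
    group: int = 6,
    table: ExpectedHomoeologyTable = DEFAULT_TABLE,
) -> frozenset[str]:
    """All distinct *nonstandard* triplets achievable under a configuration.

    Probes are placed in every depth interval on both ancestral sides;
    triplets where all three copies end on mutually homoeologous arms
    (including genes inverted on all three homoeologues) are standard in
    appearance and excluded.
    """
    patterns: set[str] = set()
    for side in ARMS:
        depths = [config.breakpoint(sg, side) for sg in SUBGENOMES if config.present(sg)]
        for depth in _interval_probes(depths):
            sets = {
                sg: (
                    other_arm(side)
                    if config.present(sg) and depth < config.breakpoint(sg, side)
                    else side
                )
                for sg in SUBGENOMES
            }
            if len(set(sets.values())) > 1:  # mixed sets = nonstandard
                patterns.add(_render(sets, group, table))
    return frozenset(patterns)


def canonical_configurations(
    k: int | None = None, max_rank: int = 3
) -> Iterator[InversionConfiguration]:
    """Exhaustive rank-discretized configuration space.

    Yields every subset of inverted homoeologues (optionally restricted to
    exactly ``k`` inversions) crossed with every assignment of short- and
    long-side breakpoint ranks in 1..max_rank, ties included.  Ranks
    exhaust the behaviour space because pattern derivation depends only on
    depth comparisons.
    """
    for r in range(len(SUBGENOMES) + 1):
        if k is not None and r != k:
            continue
        for subset in itertools.combinations(SUBGENOMES, r):
            if not subset:
                yield NO_INVERSIONS
                continue
            ranks = range(1, max_rank + 1)
            for s_ranks in itertools.product(ranks, repeat=r):
                for l_ranks in itertools.product(ranks, repeat=r):
                    yield InversionConfiguration.from_mapping(
                        {
                            sg: (float(s), float(l))
                            for sg, s, l in zip(subset, s_ranks, l_ranks)
                        }
                    )


def max_nonstandard_patterns(
    k: int | None = None,
    group: int = 6,
    table: ExpectedHomoeologyTable = DEFAULT_TABLE,
    max_rank: int = 3,
) -> int:
    """Brute-force maximum of |enumerate_patterns| over the canonical space.

    With all three homoeologues allowed the answer is four: each ancestral
    side contributes at most two nonstandard nested probe classes, and the
    class moved by every present inversion appears standard.
    """
    return max(
        len(enumerate_patterns(cfg, group, table))
        for cfg in canonical_configurations(k=k, max_rank=max_rank)
    )


def closed_form_max(k: int) -> int:
    """Analytic maximum of distinct nonstandard patterns for k inversions.

    Each ancestral side yields min(k, 2) nonstandard patterns (the nested
    proper subsets of moved homoeologues, the full subset being standard in
    appearance), and the two sides never coincide at the maximum, giving
    0, 2, 4, 4 for k = 0..3.
    """
    if k not in (0, 1, 2, 3):
        raise ValidationError(f"k must be in 0..3, got {k}")
    return 2 * min(k, 2)


@dataclass(frozen=True)
class FeasibilityVerdict:
    feasible: bool
    witness: InversionConfiguration | None

    def __bool__(self) -> bool:
        return self.feasible


def parse_triplet(text: str) -> tuple[int, dict[str, str]]:
    """Parse '6AS/6BS/6DL' into (group, {subgenome: arm})."""
    parts = text.split("/")
    if len(parts) != 3:
        raise ValidationError(f"triplet must have three arms: {text!r}")
    groups = set()
    arms: dict[str, str] = {}
    for p in parts:
        if len(p) != 3 or not p[0].isdigit() or p[1] not in SUBGENOMES or p[2] not in ARMS:
            raise ValidationError(f"not an arm name: {p!r} in {text!r}")
        groups.add(int(p[0]))
        if p[1] in arms:
            raise ValidationError(f"duplicate subgenome in triplet: {text!r}")
        arms[p[1]] = p[2]
    if len(groups) != 1:
        raise ValidationError(f"triplet mixes homoeologous groups: {text!r}")
    return groups.pop(), arms


def feasibility_check(
    observed: Iterable[str],
    table: ExpectedHomoeologyTable = DEFAULT_TABLE,
    max_rank: int = 3,
) -> FeasibilityVerdict:
    """Can one genotype produce every observed nonstandard triplet?

    Searches the canonical configuration space for a witness whose
    achievable nonstandard pattern set is a superset of the observed set
    (standard-appearing observed triplets are always achievable and are
    ignored).  Five or more distinct nonstandard triplets in one group are
    always infeasible.
    """
    observed = list(observed)
    if not observed:
        return FeasibilityVerdict(True, NO_INVERSIONS)
    group = None
    wanted: set[str] = set()
    for text in observed:
        g, arms = parse_triplet(text)
        if group is None:
            group = g
        elif g != group:
            raise ValidationError("observed triplets span multiple groups")
        # drop standard-appearing triplets
        sets = {sg: ("S" if arms[sg] == table.set_arm(g, sg, "S") else "L")
                for sg in SUBGENOMES}
        if len(set(sets.values())) > 1:
            wanted.add(_render(sets, g, table))
    if not wanted:
        return FeasibilityVerdict(True, NO_INVERSIONS)
    assert group is not None
    for cfg in canonical_configurations(max_rank=max_rank):
        if wanted <= enumerate_patterns(cfg, group, table):
            return FeasibilityVerdict(True, cfg)
    return FeasibilityVerdict(False, None)
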