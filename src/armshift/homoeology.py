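"""Structural model of the allohexaploid (AABBDD) wheat genome.

This module encodes the fixed structural knowledge every downstream stage
relies on:

* arm identities ("1AL" = homoeologous group 1, subgenome A, long arm);
* the expected homoeologous arm relationships between the A, B and D
  subgenomes, including the group-4 exception: the ancient 4A/5A/7B cyclic
  translocation reversed the arm ratio of chromosome 4A, so loci on the
  *modern* 4AL are homoeologous to 4BS/4DS and loci on the modern 4AS to
  4BL/4DL;
* an ordinal ten-segment model of the modern chromosome 4A, whose segments
  originate from four distinct ancestral arms (original 4AS, original 4AL,
  5AL and 7BS);
* the coordinate rule that assigns genes located on the chromosome-3B
  pseudomolecule to 3BS or 3BL relative to the centromere interval
  (265-387 Mb by default).

Everything here is a pure constant or a pure function of its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import FormatError, ValidationError

GROUPS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
SUBGENOMES: tuple[str, ...] = ("A", "B", "D")
ARMS: tuple[str, ...] = ("S", "L")

#: The 21 chromosomes of hexaploid wheat, e.g. "1A" ... "7D".
CHROMOSOMES: tuple[str, ...] = tuple(
    f"{g}{s}" for g in GROUPS for s in SUBGENOMES
)

#: The 42 chromosome-arm names, e.g. "1AS" ... "7DL".
ARM_NAMES: tuple[str, ...] = tuple(f"{c}{a}" for c in CHROMOSOMES for a in ARMS)


def other_arm(arm: str) -> str:
    """Return the opposite arm letter ('S' <-> 'L')."""
    if arm == "S":
        return "L"
    if arm == "L":
        return "S"
    raise FormatError(f"unknown arm letter: {arm!r}")


@dataclass(frozen=True, order=True)
class ArmID:
    """A chromosome arm, e.g. 1AL = group 1, subgenome A, long arm."""

    group: int
    subgenome: str
    arm: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"homoeologous group must be in 1..7, got {self.group}"
            )
        if self.subgenome not in SUBGENOMES:
            raise ValidationError(f"subgenome must be A, B or D, got {self.subgenome!r}")
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be S or L, got {self.arm!r}")

    @property
    def chromosome(self) -> str:
        return f"{self.group}{self.subgenome}"

    def opposite(self) -> "ArmID":
        return ArmID(self.group, self.subgenome, other_arm(self.arm))

    def __str__(self) -> str:
        return f"{self.group}{self.subgenome}{self.arm}"

    @classmethod
    def parse(cls, text: str) -> "ArmID":
        """Parse the canonical three-character form, e.g. '4AL'."""
        if len(text) != 3 or not text[0].isdigit():
            raise FormatError(f"not a chromosome-arm name: {text!r}")
        try:
            return cls(int(text[0]), text[1], text[2])
        except ValidationError as exc:
            raise FormatError(f"not a chromosome-arm name: {text!r} ({exc})") from exc


def split_chromosome(chrom: str) -> tuple[int, str]:
    """Split '4A' into (4, 'A'); raises FormatError on anything else."""
    if len(chrom) != 2 or not chrom[0].isdigit() or chrom[1] not in SUBGENOMES:
        raise FormatError(f"not a chromosome name: {chrom!r}")
    group = int(chrom[0])
    if group not in GROUPS:
        raise FormatError(f"not a chromosome name: {chrom!r}")
    return group, chrom[1]


Triplet = tuple[ArmID, ArmID, ArmID]


def _triplet(group: int, arms: Mapping[str, str]) -> Triplet:
    return tuple(ArmID(group, s, arms[s]) for s in SUBGENOMES)  # type: ignore[return-value]


class ExpectedHomoeologyTable:
    """Expected mutually homoeologous arm triplets per group.

    For every group each of the six arms belongs to exactly one of two
    triplets: the *short set* (homoeologous to the B/D short arms) and the
    *long set*.  For groups 1,2,3,5,6,7 these are simply (xAS,xBS,xDS) and
    (xAL,xBL,xDL).  For group 4 the 4A/5A/7B translocation swapped the 4A
    arms: the short set is (4AL,4BS,4DS) and the long set (4AS,4BL,4DL).
    """

    def __init__(self, swapped_arms: Mapping[int, tuple[str, ...]] | None = None):
        # swapped_arms: per group, the subgenomes whose physical arm letter
        # is reversed relative to its homoeologous set.  Default: 4A only.
        self._swapped: dict[int, frozenset[str]] = {g: frozenset() for g in GROUPS}
        if swapped_arms is None:
            swapped_arms = {4: ("A",)}
        for g, subs in swapped_arms.items():
            if g not in GROUPS:
                raise ValidationError(f"homoeologous group must be in 1..7, got {g}")
            bad = set(subs) - set(SUBGENOMES)
            if bad:
                raise ValidationError(f"unknown subgenomes in swap table: {sorted(bad)}")
            self._swapped[g] = frozenset(subs)

    def set_arm(self, group: int, subgenome: str, which: str) -> str:
        """Physical arm letter carried by `subgenome` for the given set.

        `which` is 'S' for the short set, 'L' for the long set.
        """
        if group not in GROUPS:
            raise ValidationError(f"homoeologous group must be in 1..7, got {group}")
        if which not in ARMS:
            raise ValidationError(f"set selector must be 'S' or 'L', got {which!r}")
        if subgenome in self._swapped[group]:
            return other_arm(which)
        return which

    def expected_triplets(self, group: int) -> tuple[Triplet, Triplet]:
        """The (short-set, long-set) expected triplets of a group."""
        short = _triplet(group, {s: self.set_arm(group, s, "S") for s in SUBGENOMES})
        long = _triplet(group, {s: self.set_arm(group, s, "L") for s in SUBGENOMES})
        return short, long

    def swapped_subgenomes(self, group: int) -> frozenset[str]:
        return self._swapped[group]

    def to_dict(self) -> dict:
        return {
            "swapped_arms": {
                g: sorted(subs) for g, subs in self._swapped.items() if subs
            }
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ExpectedHomoeologyTable":
        raw = data.get("swapped_arms", {})
        return cls({int(g): tuple(subs) for g, subs in raw.items()})


#: Default table for hexaploid wheat (group-4 swap on the A subgenome).
DEFAULT_TABLE = ExpectedHomoeologyTable()


def expected_triplets(group: int) -> tuple[Triplet, Triplet]:
    """Expected homoeologous arm triplets of a group (wheat defaults)."""
    return DEFAULT_TABLE.expected_triplets(group)


# ---------------------------------------------------------------------------
# Chromosome 3B: arm assignment from pseudomolecule coordinates
# ---------------------------------------------------------------------------

#: Returned when a position falls inside the centromere interval and cannot
#: be assigned to either arm.
CENTROMERIC_AMBIGUOUS = "centromeric-ambiguous"

MB = 1_000_000


@dataclass(frozen=True)
class CentromereInterval:
    """Physical extent of a centromere on a whole-chromosome pseudomolecule."""

    chromosome: str
    start_bp: float
    end_bp: float

    def __post_init__(self) -> None:
        if not (0 < self.start_bp < self.end_bp):
            raise ValidationError(
                "centromere interval requires 0 < start < end, got "
                f"[{self.start_bp}, {self.end_bp}]"
            )


#: The 3B centromere sits between 265 and 387 Mb on the 774 Mb pseudomolecule.
DEFAULT_3B_CENTROMERE = CentromereInterval("3B", 265 * MB, 387 * MB)


def assign_3B_arm(
    position_bp: float,
    centromere: CentromereInterval = DEFAULT_3B_CENTROMERE,
) -> str:
    """Assign a 1-based pseudomolecule position to an arm of 3B.

    Positions strictly below the centromere interval map to the short arm,
    strictly above to the long arm.  Positions inside the interval
    (boundaries included, the conservative choice) return
    ``CENTROMERIC_AMBIGUOUS`` and are excluded downstream.
    """
    if position_bp <= 0:
        raise ValidationError(f"position must be positive, got {position_bp}")
    if position_bp < centromere.start_bp:
        return f"{centromere.chromosome}S"
    if position_bp > centromere.end_bp:
        return f"{centromere.chromosome}L"
    return CENTROMERIC_AMBIGUOUS


# ---------------------------------------------------------------------------
# Ten-segment model of the modern chromosome 4A
# ---------------------------------------------------------------------------

ORIGIN_4AS = "original 4AS"
ORIGIN_4AL = "original 4AL"
ORIGIN_5AL = "5AL"
ORIGIN_7BS = "7BS"


@dataclass(frozen=True)
class Chromosome4ASegment:
    """One ordinal segment of modern 4A.

    Segment extents in base pairs are unknown; only the order along the
    chromosome (index 0 = modern 4AS telomere), the ancestral origin arm and
    the homoeologous matching arms are modelled.
    """

    index: int
    origin: str
    modern_arm: str  # "4AS" or "4AL"
    matching_arms: tuple[str, str]


_4A_SEGMENTS: tuple[Chromosome4ASegment, ...] = (
    # modern 4AS, telomere -> centromere
    Chromosome4ASegment(0, ORIGIN_4AS, "4AS", ("4BS", "4DS")),
    Chromosome4ASegment(1, ORIGIN_4AL, "4AS", ("4BL", "4DL")),
    Chromosome4ASegment(2, ORIGIN_4AS, "4AS", ("4BS", "4DS")),
    Chromosome4ASegment(3, ORIGIN_4AL, "4AS", ("4BL", "4DL")),
    # modern 4AL, centromere -> telomere
    Chromosome4ASegment(4, ORIGIN_4AS, "4AL", ("4BS", "4DS")),
    Chromosome4ASegment(5, ORIGIN_4AL, "4AL", ("4BL", "4DL")),
    Chromosome4ASegment(6, ORIGIN_4AS, "4AL", ("4BS", "4DS")),
    Chromosome4ASegment(7, ORIGIN_5AL, "4AL", ("5BL", "5DL")),
    Chromosome4ASegment(8, ORIGIN_7BS, "4AL", ("7AS", "7DS")),
    Chromosome4ASegment(9, ORIGIN_5AL, "4AL", ("5BL", "5DL")),
)


@dataclass(frozen=True)
class Chromosome4AModel:
    """The modern configuration of chromosome 4A as an ordered segment list."""

    segments: tuple[Chromosome4ASegment, ...] = field(default=_4A_SEGMENTS)

    def __post_init__(self) -> None:
        if len(self.segments) != 10:
            raise ValidationError(
                f"modern 4A consists of ten segments, got {len(self.segments)}"
            )
        origins = {s.origin for s in self.segments}
        if len(origins) != 4:
            raise ValidationError(
                f"segments must originate from four distinct arms, got {sorted(origins)}"
            )
        terminal = self.segments[0]
        if terminal.origin != ORIGIN_4AS or terminal.matching_arms != ("4BS", "4DS"):
            raise ValidationError(
                "the terminal modern-4AS segment must originate from the original "
                "4AS and match 4BS/4DS"
            )

    def __iter__(self) -> Iterator[Chromosome4ASegment]:
        return iter(self.segments)

    @property
    def origin_arms(self) -> frozenset[str]:
        return frozenset(s.origin for s in self.segments)

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "index": s.index,
                    "origin": s.origin,
                    "modern_arm": s.modern_arm,
                    "matching_arms": list(s.matching_arms),
                }
                for s in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Chromosome4AModel":
        segs = tuple(
            Chromosome4ASegment(
                index=int(d["index"]),
                origin=str(d["origin"]),
                modern_arm=str(d["modern_arm"]),
                matching_arms=tuple(d["matching_arms"]),  # type: ignore[arg-type]
            )
            for d in data["segments"]
        )
        return cls(segments=segs)


def build_4A_model() -> Chromosome4AModel:
    """The fixed ten-segment model of modern chromosome 4A."""
    return Chromosome4AModel()
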