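"""Per-chromosome pericentric inversion calls from nonstandard arm patterns.

A chromosome shows *strong* evidence for a pericentric inversion when

1. at least six genes were transferred to its opposite arm,
2. the transfers involve both arms, with at least three genes per arm, and
3. the inversion encompasses the centromere, demonstrated by short- and
   long-arm genes that co-locate (within a small cM tolerance) on the
   genetic map.

Chromosomes carrying 11 or more nonstandard genes where one direction
dominates (fewer than three genes in the minority direction) are called
*putative* pericentric inversions; everything else is called *none*.

Chromosome 3B is callable but flagged with a data-quality warning: its arm
assignments derive from pseudomolecule coordinates rather than flow-sorted
arm libraries, and scaffold misplacement can mimic nonstandard locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .classify import ACCEPTED_STATUSES, STATUS_ACCEPTED
from .homoeology import CHROMOSOMES

#: Frozen column order of the calls TSV.
CALL_COLUMNS = [
    "chromosome", "class", "n_short_to_long", "n_long_to_short",
    "comap_satisfied", "data_quality_warning", "supporting_genes",
]

#: Frozen column order of the per-chromosome report TSV.
REPORT_COLUMNS = ["chromosome", "short_to_long", "long_to_short", "class"]

CLASS_STRONG = "strong"
CLASS_PUTATIVE = "putative"
CLASS_NONE = "none"

DEFAULT_THRESHOLDS = {"min_total": 6, "min_per_arm": 3, "putative_total": 11}


@dataclass
class InversionCall:
    chromosome: str
    klass: str
    n_short_to_long: int
    n_long_to_short: int
    comap_satisfied: bool
    supporting_genes: list[str] = field(default_factory=list)
    data_quality_warning: bool = False

    def __post_init__(self) -> None:
        total = self.n_short_to_long + self.n_long_to_short
        low = min(self.n_short_to_long, self.n_long_to_short)
        if self.klass == CLASS_STRONG:
            assert total >= 6 and low >= 3 and self.comap_satisfied
        elif self.klass == CLASS_PUTATIVE:
            assert total >= 11 and low < 3


def read_map(path) -> pd.DataFrame:
    """Genetic map TSV with columns gene, chromosome, cM."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    missing = [c for c in ("gene", "chromosome", "cM") if c not in df.columns]
    if missing:
        raise ValidationError(f"map table lacks columns: {missing}")
    return df


def _nonstandard(patterns: pd.DataFrame, strict: bool) -> pd.DataFrame:
    statuses = (STATUS_ACCEPTED,) if strict else ACCEPTED_STATUSES
    return patterns[
        patterns["status"].isin(statuses)
        & (patterns["classification"] == "nonstandard")
    ]


def _direction(transfer: str) -> str:
    # "1AL->1AS" -> long arm lost a segment to the short arm
    src_arm = transfer.split("->")[0][-1]
    return "long_to_short" if src_arm == "L" else "short_to_long"


def direction_counts(
    patterns: pd.DataFrame, chromosome: str, strict: bool = False
) -> tuple[int, int]:
    """Count nonstandard genes per transfer direction on one chromosome.

    Each nonstandard gene increments exactly one direction of the
    chromosome carrying its minority arm: a 1AS/1BL/1DL triplet implies the
    transfer 1AL->1AS and counts toward long_to_short of 1A.
    """
    sub = _nonstandard(patterns, strict)
    sub = sub[sub["chromosome"] == chromosome]
    if sub.empty:
        return 0, 0
    directions = sub["transfer"].map(_direction)
    return (
        int((directions == "short_to_long").sum()),
        int((directions == "long_to_short").sum()),
    )


def comap_test(
    short_origin_cm: np.ndarray | list[float],
    long_origin_cm: np.ndarray | list[float],
    epsilon: float = 2.0,
) -> bool:
    """Do some short- and long-arm transfer genes co-locate on the map?

    True iff at least one gene of each direction is mapped and some pair
    lies within ``epsilon`` centimorgans.  Pericentromeric recombination
    suppression makes genes inside an inversion that spans the centromere
    collapse to nearly one map position.
    """
    a = np.asarray(short_origin_cm, dtype=float)
    b = np.asarray(long_origin_cm, dtype=float)
    if a.size == 0 or b.size == 0:
        return False
    return bool(np.min(np.abs(a[:, None] - b[None, :])) <= epsilon)


def call_inversion(
    n_short_to_long: int,
    n_long_to_short: int,
    comap: bool,
    thresholds: dict | None = None,
) -> str:
    """Apply the strong/putative/none decision rule to direction counts."""
    if n_short_to_long < 0 or n_long_to_short < 0:
        raise ValidationError("direction counts must be non-negative")
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    total = n_short_to_long + n_long_to_short
    low = min(n_short_to_long, n_long_to_short)
    if total >= t["min_total"] and low >= t["min_per_arm"] and comap:
        return CLASS_STRONG
    if total >= t["putative_total"] and low < t["min_per_arm"]:
        return CLASS_PUTATIVE
    return CLASS_NONE


def call_all(
    patterns: pd.DataFrame,
    map_positions: pd.DataFrame | None = None,
    *,
    epsilon: float = 2.0,
    strict: bool = False,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Produce one InversionCall row per chromosome (21 rows).

    `map_positions` supplies per-(gene, chromosome) cM positions for the
    co-mapping criterion; chromosomes without positions for both directions
    fail that criterion.
    """
    sub = _nonstandard(patterns, strict).copy()
    if not sub.empty:
        sub["direction"] = sub["transfer"].map(_direction)
    if map_positions is not None and not sub.empty:
        positions = map_positions.drop_duplicates(subset=["gene", "chromosome"])
        merged = sub.merge(positions, on=["gene", "chromosome"], how="left")
    else:
        merged = sub.assign(cM=np.nan) if not sub.empty else sub

    rows = []
    for chrom in CHROMOSOMES:
        if sub.empty:
            n_s2l = n_l2s = 0
            genes: list[str] = []
            comap = False
        else:
            here = merged[merged["chromosome"] == chrom]
            n_s2l = int((here["direction"] == "short_to_long").sum())
            n_l2s = int((here["direction"] == "long_to_short").sum())
            genes = sorted(here["gene"].unique())
            if "cM" in here.columns:
                mapped = here.dropna(subset=["cM"])
                comap = comap_test(
                    mapped.loc[mapped["direction"] == "short_to_long", "cM"].to_numpy(),
                    mapped.loc[mapped["direction"] == "long_to_short", "cM"].to_numpy(),
                    epsilon,
                )
            else:
                comap = False
        klass = call_inversion(n_s2l, n_l2s, comap, thresholds)
        rows.append(
            {
                "chromosome": chrom,
                "class": klass,
                "n_short_to_long": n_s2l,
                "n_long_to_short": n_l2s,
                "comap_satisfied": comap,
                "data_quality_warning": chrom == "3B",
                "supporting_genes": ";".join(genes),
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def report_table(calls: pd.DataFrame, patterns: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-chromosome direction counts with class annotation plus a total row.

    When `patterns` is given, the grand total is checked against the number
    of accepted nonstandard genes (each such gene counts on exactly one
    chromosome).
    """
    table = calls[["chromosome", "n_short_to_long", "n_long_to_short", "class"]].rename(
        columns={"n_short_to_long": "short_to_long", "n_long_to_short": "long_to_short"}
    )[REPORT_COLUMNS]
    grand = int(table["short_to_long"].sum() + table["long_to_short"].sum())
    if patterns is not None:
        n_nonstandard = len(_nonstandard(patterns, strict=False))
        if grand != n_nonstandard:
            raise ValidationError(
                f"report total {grand} does not match the {n_nonstandard} accepted "
                "nonstandard genes"
            )
    total_row = pd.DataFrame(
        [{"chromosome": "Total", "short_to_long": grand, "long_to_short": "",
          "class": ""}]
    )
    return pd.concat([table, total_row], ignore_index=True)
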