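"""Packaged report-path fixtures.

The per-chromosome counts of genes with nonstandard arm locations in the
Chinese Spring chromosome-arm shotgun survey (21 chromosomes, two transfer
directions, 551 genes in total) are shipped as a fixture so the reporting
path can be exercised without the original shotgun data.  The
``reported_class`` column records the published evidence class per
chromosome (strong, putative or none).
"""

from __future__ import annotations

import pandas as pd

from .classify import (
    PATTERN_COLUMNS,
    STATUS_ACCEPTED,
    classify_triplet,
    format_triplet,
)
from .homoeology import DEFAULT_TABLE, SUBGENOMES, split_chromosome

#: (chromosome, short_to_long, long_to_short, reported evidence class)
TABLE1_COUNTS: tuple[tuple[str, int, int, str], ...] = (
    ("1A", 8, 20, "strong"),
    ("1B", 3, 3, "none"),
    ("1D", 1, 3, "none"),
    ("2A", 2, 1, "none"),
    ("2B", 5, 16, "strong"),
    ("2D", 15, 3, "strong"),
    ("3A", 0, 0, "none"),
    ("3B", 55, 94, "strong"),
    ("3D", 0, 0, "none"),
    ("4A", 108, 25, "strong"),
    ("4B", 3, 38, "strong"),
    ("4D", 20, 0, "putative"),
    ("5A", 12, 1, "putative"),
    ("5B", 1, 1, "none"),
    ("5D", 1, 0, "none"),
    ("6A", 6, 15, "strong"),
    ("6B", 17, 6, "strong"),
    ("6D", 1, 13, "putative"),
    ("7A", 6, 6, "strong"),
    ("7B", 24, 7, "strong"),
    ("7D", 2, 9, "putative"),
)


def emit_fixture_table1() -> pd.DataFrame:
    """The packaged per-chromosome direction-count table (grand total 551)."""
    return pd.DataFrame(
        list(TABLE1_COUNTS),
        columns=["chromosome", "short_to_long", "long_to_short", "reported_class"],
    )


def _triplet_for_transfer(chromosome: str, src_arm: str) -> tuple[str, str, str]:
    """Build the (triplet, transfer, classification) of one moved gene."""
    group, sg = split_chromosome(chromosome)
    dst_arm = "L" if src_arm == "S" else "S"
    # the majority sits in whichever homoeologous set the source arm belongs to
    majority_set = "S" if DEFAULT_TABLE.set_arm(group, sg, "S") == src_arm else "L"
    arms = {
        other: DEFAULT_TABLE.set_arm(group, other, majority_set)
        for other in SUBGENOMES
    }
    arms[sg] = dst_arm
    classification, transfer = classify_triplet(arms, group, DEFAULT_TABLE)
    assert classification == "nonstandard" and transfer == (
        f"{chromosome}{src_arm}->{chromosome}{dst_arm}"
    )
    return format_triplet(arms, group), transfer, classification


def synthetic_patterns_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand a direction-count table into synthetic ArmPattern rows.

    Gene ids are synthetic placeholders; triplets and transfers are the
    unique nonstandard triplets implied by each chromosome and direction,
    so the rows flow through the genuine counting and reporting path.
    """
    rows = []
    for rec in counts.itertuples(index=False):
        group, _ = split_chromosome(rec.chromosome)
        for src_arm, n in (("S", rec.short_to_long), ("L", rec.long_to_short)):
            if n == 0:
                continue
            triplet, transfer, classification = _triplet_for_transfer(
                rec.chromosome, src_arm
            )
            for i in range(int(n)):
                rows.append(
                    {
                        "gene": f"fx_{rec.chromosome}{src_arm}_{i:03d}",
                        "group": group,
                        "triplet": triplet,
                        "classification": classification,
                        "transfer": transfer,
                        "chromosome": rec.chromosome,
                        "status": STATUS_ACCEPTED,
                    }
                )
    patterns = pd.DataFrame(rows, columns=PATTERN_COLUMNS)
    patterns["group"] = patterns["group"].astype("Int64")
    return patterns
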