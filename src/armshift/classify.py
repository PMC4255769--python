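"""Classification of per-gene BLAST hits into homoeologous arm patterns.

The pipeline mirrors the study design for locating genes on the flow-sorted
chromosome-arm shotgun libraries of hexaploid wheat:

1. assemble a nonredundant ortholog set by reciprocal best hits across the
   source gene sets (Brachypodium as the basis, then *T. urartu*,
   *Ae. tauschii* and wheat ESTs);
2. filter tabular BLASTn hits at an e-value threshold (1e-5 by default);
3. resolve hits against the whole-chromosome 3B library to 3BS/3BL via the
   centromere interval; hits inside the interval are dropped;
4. exclude genes detected on both arms of any one chromosome (a minute part
   of the centromeric region can be present in both telosomes, so such
   genes cannot be assigned an arm of origin);
5. rank the remaining hits (best HSP per arm library) and take the top
   three; if they fall on the three chromosomes of one homoeologous group,
   one per subgenome, the gene yields an arm-pattern triplet, classified
   standard or nonstandard against the group's expected triplets;
6. for nonstandard genes, inspect hits ranked 4-10 and flag the gene if an
   opposite-arm hit scores within a configurable bitscore window of the
   rank-3 hit (an automated stand-in for visual re-inspection).

A nonstandard triplet names the inferred transfer, e.g. hits on
1AS/1BL/1DL imply a transfer 1AL->1AS (pericentric movement on 1A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .homoeology import (
    ARM_NAMES,
    CENTROMERIC_AMBIGUOUS,
    DEFAULT_3B_CENTROMERE,
    DEFAULT_TABLE,
    SUBGENOMES,
    CentromereInterval,
    ExpectedHomoeologyTable,
    assign_3B_arm,
)

#: Standard 12-column tabular BLAST output (outfmt 6).
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: Frozen column order of the ArmPattern TSV.
PATTERN_COLUMNS = [
    "gene", "group", "triplet", "classification", "transfer",
    "chromosome", "status",
]

STATUS_ACCEPTED = "accepted"
STATUS_FLAGGED = "flagged_ambiguous_secondary"
STATUS_BOTH_ARMS = "excluded_both_arms"
STATUS_NOT_HOMOEOLOGOUS = "excluded_top3_not_homoeologous"
STATUS_INCOMPLETE = "excluded_incomplete"

ALL_STATUSES = (
    STATUS_ACCEPTED, STATUS_FLAGGED, STATUS_BOTH_ARMS,
    STATUS_NOT_HOMOEOLOGOUS, STATUS_INCOMPLETE,
)

#: Statuses whose patterns carry a usable triplet.
ACCEPTED_STATUSES = (STATUS_ACCEPTED, STATUS_FLAGGED)

_VALID_LIBRARIES = frozenset(ARM_NAMES) | {"3B"}


def read_hits(path) -> pd.DataFrame:
    """Read a headerless 12-column tabular BLAST file."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, header=None)


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, columns=BLAST6_COLUMNS)


def read_patterns(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str})


def write_patterns(patterns: pd.DataFrame, path) -> None:
    patterns.to_csv(path, sep="\t", index=False, columns=PATTERN_COLUMNS)


# ---------------------------------------------------------------------------
# Ortholog-set assembly
# ---------------------------------------------------------------------------

#: Source priority for choosing the representative of an RBH cluster.
SOURCE_PRIORITY = ("Brachypodium", "T_urartu", "Ae_tauschii", "wheat_EST")


@dataclass(frozen=True)
class GeneRecord:
    """A nonredundant query gene with its source set."""

    gene_id: str
    source: str
    copy_class: str | None = None  # "single_copy" | "multi_copy" | None


def build_ortholog_set(
    gene_lists: Mapping[str, Sequence[str]],
    rbh_pairs: Iterable[tuple[str, str]],
) -> list[GeneRecord]:
    """Collapse reciprocal-best-hit clusters to one representative each.

    `gene_lists` maps a source name (see SOURCE_PRIORITY) to its gene ids;
    `rbh_pairs` are cross-source reciprocal best-hit pairs.  Clusters are
    represented by their highest-priority member (Brachypodium first), so a
    *T. urartu* gene is retained only when it has no Brachypodium partner,
    and so on down the priority chain.  Reciprocal pairs within one source
    are ill-formed input and raise ValidationError.
    """
    for source in gene_lists:
        if source not in SOURCE_PRIORITY:
            raise ValidationError(
                f"unknown gene source {source!r}; expected one of {SOURCE_PRIORITY}"
            )
    source_of: dict[str, str] = {}
    for source, ids in gene_lists.items():
        for gid in ids:
            if gid in source_of:
                raise ValidationError(f"duplicate gene id across sources: {gid!r}")
            source_of[gid] = source

    parent: dict[str, str] = {g: g for g in source_of}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in rbh_pairs:
        for g in (a, b):
            if g not in source_of:
                raise ValidationError(f"best-hit pair names unknown gene {g!r}")
        if source_of[a] == source_of[b]:
            raise ValidationError(
                f"reciprocal best-hit pair within one source ({source_of[a]}): "
                f"{a!r} <-> {b!r}"
            )
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    clusters: dict[str, list[str]] = {}
    for g in source_of:
        clusters.setdefault(find(g), []).append(g)

    records = []
    for members in clusters.values():
        rep = min(members, key=lambda g: (SOURCE_PRIORITY.index(source_of[g]), g))
        records.append(GeneRecord(rep, source_of[rep]))
    records.sort(key=lambda r: (SOURCE_PRIORITY.index(r.source), r.gene_id))
    return records


# ---------------------------------------------------------------------------
# Hit ranking and exclusions
# ---------------------------------------------------------------------------

def _sort_hits(hits: pd.DataFrame, library_col: str) -> pd.DataFrame:
    """Total ordering: bitscore desc, e-value asc, identity desc, library asc."""
    return hits.sort_values(
        by=["bitscore", "evalue", "pident", library_col],
        ascending=[False, True, False, True],
        kind="mergesort",
    )


def top_hits(hits: pd.DataFrame, k: int, library_col: str = "sseqid") -> pd.DataFrame:
    """Rank one gene's (already e-value-filtered) hits and return the best k.

    Ties in bitscore are broken by ascending e-value, then descending
    percent identity, then lexicographic library id, so the ranking is a
    total order and the result deterministic.
    """
    if hits.empty:
        return hits
    return _sort_hits(hits, library_col).head(k)


def exclude_both_arms(libraries: Iterable[str]) -> bool:
    """True when any one chromosome is hit on both its S and L arm.

    Operates on resolved arm-library names for one gene.  Such genes are
    dropped: the arm of origin cannot be determined because pericentromeric
    sequence can be carried by both telosomes of a chromosome.
    """
    seen: dict[str, set[str]] = {}
    for lib in libraries:
        if lib == "3B" or lib == CENTROMERIC_AMBIGUOUS:
            continue
        chrom, arm = lib[:2], lib[2]
        arms = seen.setdefault(chrom, set())
        arms.add(arm)
        if len(arms) == 2:
            return True
    return False


# ---------------------------------------------------------------------------
# Triplet classification
# ---------------------------------------------------------------------------

def classify_triplet(
    arms_by_subgenome: Mapping[str, str],
    group: int,
    table: ExpectedHomoeologyTable = DEFAULT_TABLE,
) -> tuple[str, str | None]:
    """Classify a complete arm triplet of one group.

    Returns ("standard", None) when the triplet equals one of the group's
    expected triplets, else ("nonstandard", transfer) where the transfer
    names the minority subgenome's movement relative to the majority's
    expected triplet, e.g. "1DL->1DS".
    """
    in_short = {
        sg: arms_by_subgenome[sg] == table.set_arm(group, sg, "S")
        for sg in SUBGENOMES
    }
    n_short = sum(in_short.values())
    if n_short in (0, 3):
        return "standard", None
    if n_short == 2:
        # one subgenome sits in the long set while the majority is short
        (sg,) = [s for s, v in in_short.items() if not v]
        src = table.set_arm(group, sg, "S")
        dst = table.set_arm(group, sg, "L")
    else:
        (sg,) = [s for s, v in in_short.items() if v]
        src = table.set_arm(group, sg, "L")
        dst = table.set_arm(group, sg, "S")
    return "nonstandard", f"{group}{sg}{src}->{group}{sg}{dst}"


def format_triplet(arms_by_subgenome: Mapping[str, str], group: int) -> str:
    """Canonical triplet string in A/B/D order, e.g. '1AS/1BL/1DL'."""
    return "/".join(f"{group}{sg}{arms_by_subgenome[sg]}" for sg in SUBGENOMES)


@dataclass
class ArmPattern:
    """Per-gene classification outcome."""

    gene: str
    status: str
    group: int | None = None
    triplet: str | None = None
    classification: str | None = None
    transfer: str | None = None
    chromosome: str | None = None  # minority chromosome when nonstandard


def classify_gene(
    top3_libraries: Sequence[str],
    table: ExpectedHomoeologyTable = DEFAULT_TABLE,
    gene: str = "",
) -> ArmPattern:
    """Classify one gene from its three best resolved arm libraries.

    The libraries must already be resolved (no whole-chromosome '3B' ids).
    Fewer than three hits yield excluded_incomplete; three hits that do not
    cover the three subgenomes of a single group yield
    excluded_top3_not_homoeologous.
    """
    for lib in top3_libraries:
        if lib not in ARM_NAMES:
            raise ValidationError(f"unknown arm library: {lib!r}")
    if len(top3_libraries) < 3:
        return ArmPattern(gene=gene, status=STATUS_INCOMPLETE)
    groups = {int(lib[0]) for lib in top3_libraries}
    subs = {lib[1] for lib in top3_libraries}
    if len(groups) != 1 or len(subs) != 3:
        return ArmPattern(gene=gene, status=STATUS_NOT_HOMOEOLOGOUS)
    group = groups.pop()
    arms = {lib[1]: lib[2] for lib in top3_libraries}
    classification, transfer = classify_triplet(arms, group, table)
    return ArmPattern(
        gene=gene,
        status=STATUS_ACCEPTED,
        group=group,
        triplet=format_triplet(arms, group),
        classification=classification,
        transfer=transfer,
        chromosome=transfer[:2] if transfer else None,
    )


def secondary_hit_check(
    secondary: pd.DataFrame,
    triplet_arms: Mapping[str, str],
    group: int,
    rank3_bitscore: float,
    delta: float = 0.10,
    library_col: str = "library",
) -> bool:
    """Inspect hits ranked 4-10 of a nonstandard gene.

    Returns True (flag the gene as ambiguous) when any secondary hit lies
    on the opposite arm of a triplet chromosome and scores within a window
    of ``delta * rank3_bitscore`` of the rank-3 hit.  The flag surfaces
    ambiguity; it never excludes the gene on its own.
    """
    if secondary.empty:
        return False
    floor = rank3_bitscore * (1.0 - delta)
    for lib, score in zip(secondary[library_col], secondary["bitscore"]):
        if lib not in ARM_NAMES:
            continue
        g, sg, arm = int(lib[0]), lib[1], lib[2]
        if g == group and triplet_arms.get(sg) not in (None, arm) and score >= floor:
            return True
    return False


# ---------------------------------------------------------------------------
# Whole-table driver
# ---------------------------------------------------------------------------

@dataclass
class ClassifyResult:
    patterns: pd.DataFrame
    summary: dict = field(default_factory=dict)


def classify_all(
    hits: pd.DataFrame,
    *,
    evalue_threshold: float = 1e-5,
    delta: float = 0.10,
    centromere: CentromereInterval = DEFAULT_3B_CENTROMERE,
    table: ExpectedHomoeologyTable = DEFAULT_TABLE,
    genes: Sequence[str] | None = None,
) -> ClassifyResult:
    """Run the per-gene classification pipeline over a full hit table.

    Every gene receives exactly one ArmPattern row; the summary's status
    counts sum to the number of genes.  Hits on the whole-chromosome 3B
    library are resolved to 3BS/3BL by the midpoint of the subject
    coordinates; midpoints inside the centromere interval are dropped
    before triplet formation.
    """
    missing = [c for c in BLAST6_COLUMNS if c not in hits.columns]
    if missing:
        raise ValidationError(f"hit table lacks columns: {missing}")

    if genes is not None:
        genes = list(genes)
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        unknown = set(hits["qseqid"]) - set(genes)
        if unknown:
            raise ValidationError(
                f"hit table names genes absent from the gene list: {sorted(unknown)[:5]}"
            )
        all_genes = sorted(genes)
    else:
        all_genes = sorted(hits["qseqid"].unique())

    bad_libs = sorted(set(hits["sseqid"]) - _VALID_LIBRARIES)
    if bad_libs:
        raise ValidationError(f"unknown subject libraries: {bad_libs}")

    kept = hits[hits["evalue"] <= evalue_threshold].copy()

    # resolve the whole-chromosome 3B library by hit midpoint
    n_dropped_3b = 0
    if not kept.empty:
        is_3b = kept["sseqid"] == "3B"
        library = kept["sseqid"].astype(str).copy()
        if is_3b.any():
            mids = (kept.loc[is_3b, "sstart"] + kept.loc[is_3b, "send"]) / 2.0
            resolved = mids.map(lambda p: assign_3B_arm(p, centromere))
            library.loc[is_3b] = resolved
            ambiguous = library == CENTROMERIC_AMBIGUOUS
            n_dropped_3b = int(ambiguous.sum())
            kept = kept[~ambiguous]
            library = library[~ambiguous]
        kept["library"] = library

    rows: list[ArmPattern] = []
    flagged_genes = 0

    if kept.empty:
        grouped: dict[str, pd.DataFrame] = {}
    else:
        # best HSP per (gene, library), then rank within gene
        kept = _sort_hits(kept, "library")
        kept = kept.drop_duplicates(subset=["qseqid", "library"], keep="first")
        kept = kept.sort_values(
            by=["qseqid", "bitscore", "evalue", "pident", "library"],
            ascending=[True, False, True, False, True],
            kind="mergesort",
        )
        grouped = {g: df for g, df in kept.groupby("qseqid", sort=False)}

    for gene in all_genes:
        gdf = grouped.get(gene)
        if gdf is None or len(gdf) == 0:
            rows.append(ArmPattern(gene=gene, status=STATUS_INCOMPLETE))
            continue
        if exclude_both_arms(gdf["library"]):
            rows.append(ArmPattern(gene=gene, status=STATUS_BOTH_ARMS))
            continue
        pattern = classify_gene(list(gdf["library"].head(3)), table, gene=gene)
        if pattern.classification == "nonstandard" and len(gdf) > 3:
            arms = {lib[1]: lib[2] for lib in gdf["library"].head(3)}
            flagged = secondary_hit_check(
                gdf.iloc[3:10],
                arms,
                pattern.group,  # type: ignore[arg-type]
                rank3_bitscore=float(gdf["bitscore"].iloc[2]),
                delta=delta,
            )
            if flagged:
                pattern.status = STATUS_FLAGGED
                flagged_genes += 1
        rows.append(pattern)

    patterns = pd.DataFrame(
        [
            {
                "gene": p.gene,
                "group": p.group,
                "triplet": p.triplet,
                "classification": p.classification,
                "transfer": p.transfer,
                "chromosome": p.chromosome,
                "status": p.status,
            }
            for p in rows
        ],
        columns=PATTERN_COLUMNS,
    )
    patterns["group"] = patterns["group"].astype("Int64")

    status_counts = {s: 0 for s in ALL_STATUSES}
    status_counts.update(patterns["status"].value_counts().to_dict())
    summary = {
        "n_genes": len(all_genes),
        "status_counts": status_counts,
        "n_accepted": int(patterns["status"].isin(ACCEPTED_STATUSES).sum()),
        "n_standard": int((patterns["classification"] == "standard").sum()),
        "n_nonstandard": int((patterns["classification"] == "nonstandard").sum()),
        "n_flagged_ambiguous_secondary": flagged_genes,
        "n_3b_hits_dropped_centromeric": n_dropped_3b,
        "evalue_threshold": evalue_threshold,
        "delta": delta,
    }
    return ClassifyResult(patterns=patterns, summary=summary)
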