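"""Synthetic allohexaploid genome simulator with truth labels.

Generates a stand-in for chromosome-arm shotgun hit data: homoeologous gene
triplets across seven groups and three subgenomes, the group-4 arm swap with
an ordinal terminal original-4AS segment and 5AL/7BS translocation
residents on modern 4A, configurable euploid pericentric inversions,
per-arm-library aneuploid artifacts (inversions arising during telosome
production), gene loss and duplication, decoy hits, a genetic map with
pericentromeric recombination suppression, and a 12-column tabular hit file
whose 3B subject is a whole-chromosome pseudomolecule.

Geometry and noise model
------------------------
Each chromosome is ``chromosome_length_mb`` long with the centromere at a
fixed fraction; gene depths are uniform fractions of the arm length,
shared across the three homoeologous copies.  A euploid inversion on a
chromosome relocates every copy shallower than the per-arm breakpoint to
the opposite arm at the same depth.  An aneuploid artifact attached to an
arm library applies a further pericentric inversion *within the line that
was flow-sorted for that library*: genes can thereby appear in both arm
libraries of a chromosome or in neither, exactly the ambiguity that
motivates excluding both-arm genes downstream.  Applying the same artifact
to both libraries of a chromosome acts as a clean second inversion and can
push the number of distinct nonstandard patterns past the single-inversion
bound of four.

Hit bitscores derive from per-copy percent identities (homoeologues higher
than cross-group paralogs); only the rank order matters downstream.  All
randomness flows from the mandatory seed; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .classify import BLAST6_COLUMNS, classify_triplet, format_triplet
from .fixtures import emit_fixture_table1  # re-exported report-path fixture
from .homoeology import (
    ARM_NAMES,
    CHROMOSOMES,
    DEFAULT_3B_CENTROMERE,
    DEFAULT_TABLE,
    GROUPS,
    MB,
    SUBGENOMES,
    other_arm,
    split_chromosome,
)

__all__ = [
    "RecombinationProfile",
    "SimulationConfig",
    "GenomeModel",
    "simulate_genome",
    "genetic_map",
    "emit_hits",
    "emit_fixture_table1",
    "default_scenario",
    "fig3a_scenario",
    "aneuploid_demo_scenario",
    "TRUTH_COLUMNS",
]

#: Frozen column order of the truth TSV.
TRUTH_COLUMNS = [
    "gene", "group", "lib_A", "lib_B", "lib_D", "pattern", "classification",
    "transfer", "moved_by_euploid_inversion", "moved_by_aneuploid_artifact",
    "nonstandard", "lost_any", "duplicated", "has_decoy", "translocated",
    "structural_4A", "both_arms", "incomplete",
]

_3B_LENGTH_BP = 774 * MB  # pseudomolecule scale used for 3B hit coordinates


@dataclass(frozen=True)
class RecombinationProfile:
    """Recombination density along an arm, relative to the distal rate.

    The pericentromeric ``suppressed_fraction`` of each arm (adjacent to
    the centromere) recombines at ``suppressed_density`` relative to the
    distal ``distal_density``; wheat proximal regions recombine at a tiny
    fraction of distal rates, which is what collapses pericentromeric genes
    onto nearly a single map position.
    """

    suppressed_fraction: float = 0.30
    suppressed_density: float = 0.02
    distal_density: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.suppressed_fraction <= 1):
            raise ValidationError("suppressed_fraction must lie in [0, 1]")
        if self.suppressed_density < 0 or self.distal_density < 0:
            raise ValidationError("recombination densities must be non-negative")
        if self.distal_density == 0 and self.suppressed_density == 0:
            raise ValidationError("recombination profile is identically zero")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated genome.  ``seed`` is mandatory."""

    seed: int
    genes_per_group: int = 200
    chromosome_length_mb: float = 800.0
    centromere_fraction: float = 0.45
    genetic_length_cm: float = 150.0
    recombination: RecombinationProfile = field(default_factory=RecombinationProfile)
    #: chromosome -> (short-arm, long-arm) breakpoint depths as arm fractions
    euploid_inversions: dict = field(default_factory=dict)
    #: arm library (e.g. "6AS") -> (short, long) artifact breakpoint fractions
    aneuploid_artifacts: dict = field(default_factory=dict)
    loss_rate: float = 0.05
    duplication_rate: float = 0.10
    decoy_rate: float = 0.05
    homoeologue_identity: tuple = (96.5, 1.2)
    paralog_identity: tuple = (89.0, 5.0)
    terminal_4AS_genes: int = 12
    translocated_genes_per_donor: int = 8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for any stochastic emission")
        for name in ("loss_rate", "duplication_rate", "decoy_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.genes_per_group <= 0:
            raise ValidationError("genes_per_group must be positive")
        if not (0 < self.centromere_fraction < 1):
            raise ValidationError("centromere_fraction must lie in (0, 1)")
        for chrom, (s, l) in dict(self.euploid_inversions).items():
            if chrom not in CHROMOSOMES:
                raise ValidationError(f"inversion on unknown chromosome {chrom!r}")
            if not (0 < s <= 1 and 0 < l <= 1):
                raise ValidationError(
                    f"inversion breakpoints on {chrom} must be arm fractions in "
                    f"(0, 1], got ({s}, {l})"
                )
        for lib, (s, l) in dict(self.aneuploid_artifacts).items():
            if lib not in ARM_NAMES:
                raise ValidationError(f"artifact on unknown arm library {lib!r}")
            if lib.startswith("3B"):
                raise ValidationError(
                    "3B was flow-sorted whole from euploid stock; no per-arm "
                    "artifact can apply"
                )
            if not (0 < s <= 1 and 0 < l <= 1):
                raise ValidationError(
                    f"artifact breakpoints on {lib} must be arm fractions in (0, 1]"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["euploid_inversions"] = {k: list(v) for k, v in self.euploid_inversions.items()}
        d["aneuploid_artifacts"] = {k: list(v) for k, v in self.aneuploid_artifacts.items()}
        d["homoeologue_identity"] = list(self.homoeologue_identity)
        d["paralog_identity"] = list(self.paralog_identity)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        d = dict(data)
        if "recombination" in d and isinstance(d["recombination"], Mapping):
            d["recombination"] = RecombinationProfile(**d["recombination"])
        for key in ("euploid_inversions", "aneuploid_artifacts"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in dict(d[key]).items()}
        for key in ("homoeologue_identity", "paralog_identity"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GenomeModel:
    """Simulated gene placements plus everything hit emission needs.

    ``copies`` has one row per (gene, subgenome) placement with ancestral
    and post-rearrangement arms, library membership and per-copy identity;
    ``genes`` has per-gene attributes (length, decoy/duplication targets).
    """

    config: SimulationConfig
    copies: pd.DataFrame
    genes: pd.DataFrame

    @property
    def centromere_mb(self) -> float:
        return self.config.chromosome_length_mb * self.config.centromere_fraction

    def arm_length_mb(self, arm: str) -> float:
        if arm == "S":
            return self.centromere_mb
        return self.config.chromosome_length_mb - self.centromere_mb


def _apply_artifact(
    lib: str, arm: str, depth: float, artifacts: Mapping
) -> str:
    """Arm of a copy inside the aneuploid line sorted for `lib`."""
    cfg = artifacts.get(lib)
    if cfg is None:
        return arm
    s, l = cfg
    bp = s if arm == "S" else l
    return other_arm(arm) if depth < bp else arm


def simulate_genome(config: SimulationConfig) -> tuple[GenomeModel, pd.DataFrame]:
    """Place genes, apply rearrangements and losses, and build the truth table.

    Deterministic given the config (which carries the seed).  Returns the
    genome model and a per-gene truth table whose ``nonstandard`` column
    marks genes whose emitted libraries form a clean nonstandard triplet.
    """
    rng = np.random.default_rng(config.seed)
    inv = dict(config.euploid_inversions)
    art = dict(config.aneuploid_artifacts)

    gene_rows = []
    copy_rows = []

    def add_gene(gene: str, group: int, role: str) -> None:
        gene_rows.append({"gene": gene, "group": group, "role": role})

    def add_copy(gene, group, sg, chrom, aset, depth, arm, role):
        copy_rows.append(
            {
                "gene": gene, "group": group, "subgenome": sg,
                "chromosome": chrom, "set": aset, "depth": float(depth),
                "baseline_arm": arm, "role": role,
            }
        )

    # --- core homoeologous triplets -------------------------------------
    for group in GROUPS:
        n = config.genes_per_group
        sets = np.where(rng.random(n) < 0.5, "S", "L")
        depths = rng.uniform(0.001, 0.999, size=n)
        for i in range(n):
            gene = f"g{group}_{i:04d}"
            add_gene(gene, group, "core")
            for sg in SUBGENOMES:
                chrom = f"{group}{sg}"
                arm = DEFAULT_TABLE.set_arm(group, sg, str(sets[i]))
                add_copy(gene, group, sg, chrom, str(sets[i]), depths[i], arm, "core")

    # --- terminal original-4AS segment on modern 4AS --------------------
    # These genes match 4BS/4DS (the short set) yet sit on the modern 4AS,
    # distally: the one segment of modern 4A that escaped the arm swap.
    depths_t = rng.uniform(0.85, 0.999, size=config.terminal_4AS_genes)
    for i in range(config.terminal_4AS_genes):
        gene = f"g4_term{i:03d}"
        add_gene(gene, 4, "terminal_4AS")
        add_copy(gene, 4, "A", "4A", "S", depths_t[i], "S", "terminal_4AS")
        for sg in ("B", "D"):
            add_copy(gene, 4, sg, f"4{sg}", "S", depths_t[i], "S", "terminal_4AS")

    # --- 5AL and 7BS translocation residents on modern 4AL --------------
    n_tr = config.translocated_genes_per_donor
    depths_5 = rng.uniform(0.6, 0.999, size=n_tr)
    depths_7 = rng.uniform(0.6, 0.999, size=n_tr)
    for i in range(n_tr):
        gene = f"g5_tr{i:03d}"
        add_gene(gene, 5, "translocated")
        add_copy(gene, 5, "A", "4A", "L", depths_5[i], "L", "translocated")
        add_copy(gene, 5, "B", "5B", "L", depths_5[i], "L", "translocated")
        add_copy(gene, 5, "D", "5D", "L", depths_5[i], "L", "translocated")
    for i in range(n_tr):
        gene = f"g7_tr{i:03d}"
        add_gene(gene, 7, "translocated")
        add_copy(gene, 7, "A", "7A", "S", depths_7[i], "S", "translocated")
        add_copy(gene, 7, "B", "4A", "S", depths_7[i], "L", "translocated")
        add_copy(gene, 7, "D", "7D", "S", depths_7[i], "S", "translocated")

    copies = pd.DataFrame(copy_rows)
    genes = pd.DataFrame(gene_rows)

    # --- euploid pericentric inversions ---------------------------------
    def euploid_arm(row) -> str:
        cfg = inv.get(row.chromosome)
        if cfg is None:
            return row.baseline_arm
        s, l = cfg
        bp = s if row.baseline_arm == "S" else l
        return other_arm(row.baseline_arm) if row.depth < bp else row.baseline_arm

    copies["arm_euploid"] = [euploid_arm(r) for r in copies.itertuples(index=False)]
    copies["moved_euploid"] = copies["arm_euploid"] != copies["baseline_arm"]

    # --- losses ----------------------------------------------------------
    copies["lost"] = rng.random(len(copies)) < config.loss_rate

    # --- arm-library membership under aneuploid artifacts ---------------
    member_s, member_l, moved_art = [], [], []
    for r in copies.itertuples(index=False):
        if r.chromosome == "3B":
            ms, ml = r.arm_euploid == "S", r.arm_euploid == "L"
            moved = False
        else:
            ms = _apply_artifact(f"{r.chromosome}S", r.arm_euploid, r.depth, art) == "S"
            ml = _apply_artifact(f"{r.chromosome}L", r.arm_euploid, r.depth, art) == "L"
            moved = (ms, ml) != (r.arm_euploid == "S", r.arm_euploid == "L")
        member_s.append(ms)
        member_l.append(ml)
        moved_art.append(moved)
    copies["member_S"] = member_s
    copies["member_L"] = member_l
    copies["moved_artifact"] = moved_art

    # --- per-copy identities and per-gene attributes ---------------------
    hm, hs = config.homoeologue_identity
    copies["pident"] = np.clip(rng.normal(hm, hs, size=len(copies)), 80.0, 100.0)

    genes = genes.sort_values("gene").reset_index(drop=True)
    n_genes = len(genes)
    genes["length"] = np.clip(
        rng.normal(600, 80, size=n_genes), 150, 3000
    ).astype(int)
    pm, ps = config.paralog_identity

    def off_group_lib(group: int) -> str:
        others = [c for c in CHROMOSOMES if split_chromosome(c)[0] != group]
        chrom = others[rng.integers(len(others))]
        return chrom + ("S" if rng.random() < 0.5 else "L")

    genes["duplicated"] = rng.random(n_genes) < config.duplication_rate
    genes["dup_lib"] = [
        off_group_lib(g) if d else ""
        for g, d in zip(genes["group"], genes["duplicated"])
    ]
    genes["dup_pident"] = np.clip(rng.normal(pm, ps, size=n_genes), 70.0, 99.5)
    genes["has_decoy"] = rng.random(n_genes) < config.decoy_rate
    genes["decoy_lib"] = [
        off_group_lib(g) if d else ""
        for g, d in zip(genes["group"], genes["has_decoy"])
    ]
    genes["decoy_pident"] = np.clip(rng.normal(pm, 1.6 * ps, size=n_genes), 70.0, 99.5)
    genes["dup_depth"] = rng.uniform(0.01, 0.99, size=n_genes)
    genes["decoy_depth"] = rng.uniform(0.01, 0.99, size=n_genes)

    model = GenomeModel(config=config, copies=copies, genes=genes)
    truth = _build_truth(model)
    return model, truth


def _copy_libraries(row) -> list[str]:
    """Arm libraries in which one (non-lost) copy is detectable."""
    if row.lost:
        return []
    if row.chromosome == "3B":
        return [f"3B{row.arm_euploid}"]
    libs = []
    if row.member_S:
        libs.append(f"{row.chromosome}S")
    if row.member_L:
        libs.append(f"{row.chromosome}L")
    return libs


def _build_truth(model: GenomeModel) -> pd.DataFrame:
    rows = []
    copies = model.copies.sort_values(["gene", "subgenome"])
    gene_attrs = model.genes.set_index("gene")
    for gene, gdf in copies.groupby("gene", sort=True):
        libs: dict[str, str] = {}
        for r in gdf.itertuples(index=False):
            cl = _copy_libraries(r)
            if len(cl) == 0:
                libs[r.subgenome] = "none"
            elif len(cl) == 2:
                libs[r.subgenome] = "both"
            else:
                libs[r.subgenome] = cl[0]
        pattern = classification = transfer = None
        named = [v for v in libs.values() if v not in ("none", "both")]
        if len(named) == 3:
            lib_groups = {int(v[0]) for v in named}
            lib_subs = {v[1] for v in named}
            if len(lib_groups) == 1 and len(lib_subs) == 3:
                group = lib_groups.pop()
                arms = {v[1]: v[2] for v in named}
                classification, transfer = classify_triplet(arms, group, DEFAULT_TABLE)
                pattern = format_triplet(arms, group)
        attrs = gene_attrs.loc[gene]
        rows.append(
            {
                "gene": gene,
                "group": int(gdf["group"].iloc[0]),
                "lib_A": libs.get("A", "none"),
                "lib_B": libs.get("B", "none"),
                "lib_D": libs.get("D", "none"),
                "pattern": pattern,
                "classification": classification,
                "transfer": transfer,
                "moved_by_euploid_inversion": bool(gdf["moved_euploid"].any()),
                "moved_by_aneuploid_artifact": bool(gdf["moved_artifact"].any()),
                "nonstandard": classification == "nonstandard",
                "lost_any": bool(gdf["lost"].any()),
                "duplicated": bool(attrs["duplicated"]),
                "has_decoy": bool(attrs["has_decoy"]),
                "translocated": attrs["role"] == "translocated",
                "structural_4A": attrs["role"] == "terminal_4AS",
                "both_arms": "both" in libs.values(),
                "incomplete": "none" in libs.values(),
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def genetic_map(
    model: GenomeModel, profile: RecombinationProfile | None = None
) -> pd.DataFrame:
    """Map positions (gene, chromosome, cM) under recombination suppression.

    Positions reflect the euploid chromosome structure (genetic maps are
    built from euploid crosses), so a gene relocated by a euploid inversion
    maps at its new, pericentromeric position.  cM increases monotonically
    with physical position; genes within the suppressed pericentromeric
    window collapse to nearly identical map positions.
    """
    profile = profile or model.config.recombination
    if not isinstance(profile, RecombinationProfile):
        profile = RecombinationProfile(**profile)

    L = model.config.chromosome_length_mb
    cen = model.centromere_mb
    a = cen * (1 - profile.suppressed_fraction)
    b = cen + profile.suppressed_fraction * (L - cen)
    d1, d2 = profile.distal_density, profile.suppressed_density

    def cum(x: np.ndarray) -> np.ndarray:
        return (
            np.minimum(x, a) * d1
            + np.clip(x - a, 0, b - a) * d2
            + np.clip(x - b, 0, None) * d1
        )

    total = cum(np.array([L]))[0]

    live = model.copies[~model.copies["lost"]]
    arm_len = np.where(live["arm_euploid"] == "S", cen, L - cen)
    pos = np.where(
        live["arm_euploid"] == "S",
        cen - live["depth"].to_numpy() * arm_len,
        cen + live["depth"].to_numpy() * arm_len,
    )
    cm = model.config.genetic_length_cm * cum(pos) / total
    out = pd.DataFrame(
        {
            "gene": live["gene"].to_numpy(),
            "chromosome": live["chromosome"].to_numpy(),
            "cM": np.round(cm, 4),
        }
    )
    out = out.drop_duplicates(subset=["gene", "chromosome"])
    return out.sort_values(["chromosome", "gene"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hit emission
# ---------------------------------------------------------------------------

def _bitscore(length: np.ndarray, pident: np.ndarray) -> np.ndarray:
    return np.round(2.0 * length * pident / 100.0, 1)


def _evalue(bitscore: np.ndarray) -> np.ndarray:
    return 10.0 ** (-np.minimum(bitscore / 3.0, 180.0))


def emit_hits(model: GenomeModel) -> pd.DataFrame:
    """Emit the 12-column tabular hit file implied by the genome model.

    One hit per arm library in which a surviving copy is detectable (3B
    copies hit the whole-chromosome '3B' subject, with pseudomolecule
    coordinates on the 774 Mb / 265-387 Mb centromere scale), plus
    cross-group paralog hits for duplicated genes and decoy hits.  Purely a
    deterministic rendering of the model: all randomness was drawn at
    simulation time.
    """
    cfg = model.config
    lengths = model.genes.set_index("gene")["length"]
    rows = []

    for r in model.copies.sort_values(["gene", "chromosome"]).itertuples(index=False):
        length = int(lengths[r.gene])
        for lib in _copy_libraries(r):
            if r.chromosome == "3B":
                sseqid = "3B"
                if r.arm_euploid == "S":
                    pos = int(DEFAULT_3B_CENTROMERE.start_bp * (1 - r.depth)) + 1
                else:
                    pos = int(
                        DEFAULT_3B_CENTROMERE.end_bp
                        + r.depth * (_3B_LENGTH_BP - DEFAULT_3B_CENTROMERE.end_bp)
                    )
            else:
                sseqid = lib
                pos = int(r.depth * model.arm_length_mb(lib[2]) * MB) + 1
            rows.append((r.gene, sseqid, float(r.pident), length, pos))

    for g in model.genes.itertuples(index=False):
        length = int(g.length)
        if g.duplicated:
            pos = int(g.dup_depth * model.arm_length_mb(g.dup_lib[2]) * MB) + 1
            rows.append((g.gene, g.dup_lib, float(g.dup_pident), length, pos))
        if g.has_decoy:
            pos = int(g.decoy_depth * model.arm_length_mb(g.decoy_lib[2]) * MB) + 1
            rows.append((g.gene, g.decoy_lib, float(g.decoy_pident), length, pos))

    if not rows:
        return pd.DataFrame(columns=BLAST6_COLUMNS)

    df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "length", "sstart"])
    df["pident"] = np.round(df["pident"], 2)
    df["mismatch"] = (df["length"] * (1 - df["pident"] / 100.0)).astype(int)
    df["gapopen"] = 0
    df["qstart"] = 1
    df["qend"] = df["length"]
    df["send"] = df["sstart"] + df["length"] - 1
    df["bitscore"] = _bitscore(df["length"].to_numpy(), df["pident"].to_numpy())
    df["evalue"] = _evalue(df["bitscore"].to_numpy())
    df = df[BLAST6_COLUMNS]
    return df.sort_values(
        ["qseqid", "bitscore", "sseqid"], ascending=[True, False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------

def default_scenario(seed: int) -> SimulationConfig:
    """Default study conditions: inversions planted on six chromosomes.

    Breakpoint depths stay within the recombination-suppressed window so
    the co-mapping criterion is satisfiable, mirroring inversions whose
    breakpoints sit in low-recombination pericentromeric regions.
    """
    return SimulationConfig(
        seed=seed,
        euploid_inversions={
            "1A": (0.10, 0.20),
            "2B": (0.08, 0.18),
            "4A": (0.15, 0.10),
            "5D": (0.12, 0.12),
            "6B": (0.18, 0.08),
            "7A": (0.10, 0.10),
        },
    )


def fig3a_scenario(seed: int) -> SimulationConfig:
    """Nested triple inversion on group 6 (noise-free).

    Inverted segments on both arms are larger on 6D than on 6B than on 6A,
    the textbook case yielding exactly four nonstandard patterns.
    """
    return SimulationConfig(
        seed=seed,
        euploid_inversions={
            "6A": (0.08, 0.08),
            "6B": (0.16, 0.16),
            "6D": (0.24, 0.24),
        },
        loss_rate=0.0,
        duplication_rate=0.0,
        decoy_rate=0.0,
        terminal_4AS_genes=0,
        translocated_genes_per_donor=0,
    )


def aneuploid_demo_scenario(seed: int) -> SimulationConfig:
    """Euploid inversions plus paired per-line artifacts on group 6.

    Each chromosome's two telosome lines carry the same artifact inversion,
    which composes with the euploid inversion into disjoint flip windows on
    the three homoeologues; the emitted truth shows six distinct
    nonstandard patterns, more than any single genotype with at most one
    pericentric inversion per chromosome can produce.
    """
    return SimulationConfig(
        seed=seed,
        euploid_inversions={
            "6A": (0.05, 0.05),
            "6B": (0.30, 0.30),
            "6D": (0.55, 0.55),
        },
        aneuploid_artifacts={
            "6AS": (0.25, 0.25), "6AL": (0.25, 0.25),
            "6BS": (0.50, 0.50), "6BL": (0.50, 0.50),
            "6DS": (0.75, 0.75), "6DL": (0.75, 0.75),
        },
        loss_rate=0.0,
        duplication_rate=0.0,
        decoy_rate=0.0,
        terminal_4AS_genes=0,
        translocated_genes_per_donor=0,
    )
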