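# Methods

## Expected homoeology and the structural baseline

The package models hexaploid wheat as seven homoeologous groups times three
subgenomes (A, B, D), each chromosome split into a short (S) and long (L)
arm. For every group the six arms partition into two mutually homoeologous
triplets, the *short set* and the *long set*. Groups 1–3 and 5–7 use the
identity relationship ((xAS,xBS,xDS) and (xAL,xBL,xDL)); group 4 encodes
the consequence of the ancient 4A/5A/7B cyclic translocation, which
reversed the arm ratio of 4A: the short set is (4AL,4BS,4DS) and the long
set (4AS,4BL,4DL). The table is serializable, so other allopolyploids (or
alternative swap hypotheses) can be described in a config file.

Modern chromosome 4A is additionally carried as an ordinal ten-segment
model: each segment records its ancestral origin (original 4AS, original
4AL, 5AL or 7BS), its modern arm, and the homoeologous arms its sequences
match. Segment base-pair extents are deliberately not modelled — the
published evidence fixes the segment count, the four origins and the
terminal modern-4AS segment (original-4AS material matching the 4BS/4DS
termini), but not physical boundaries, so the model is ordinal only. The
internal order of the remaining segments is a stylized choice consistent
with those constraints.

Chromosome 3B is the special case: it was flow-sorted whole, so arm
assignment uses pseudomolecule coordinates against a centromere interval
(default 265–387 Mb on the 774 Mb scale). Positions strictly below the
interval are 3BS, strictly above are 3BL; positions inside the interval,
boundaries included, are centromeric-ambiguous and excluded. Coordinates
are 1-based inclusive and compared exactly; treating boundary positions as
ambiguous is the conservative choice given that only the interval, not its
boundary semantics, is documented.

## Pattern classification

Input is standard 12-column tabular BLAST output whose subjects are arm
library names ("1AL" … "7DS") or the whole-chromosome "3B". The pipeline:

1. **E-value filter**, default 1e-5 (configurable).
2. **3B resolution**: hits on "3B" are assigned an arm by the midpoint of
   the subject coordinates; centromeric midpoints are dropped before any
   triplet forms. The midpoint is an unstated-but-deterministic choice.
3. **Both-arm exclusion**: a gene with significant hits on both arms of
   any one chromosome is excluded outright. Telosome production can leave
   a minute pericentromeric region in both arm libraries, so such genes
   have no determinable arm of origin.
4. **Ranking**: one best HSP per arm library, ordered by descending
   bitscore with a total tie-break chain (ascending e-value, descending
   identity, lexicographic library id). Ranking by best HSP per library is
   a documented choice; ranking all HSPs independently is the alternative
   and would only change which library occupies a rank when one library
   carries several near-identical HSPs.
5. **Top-3 triplet**: if the three best hits cover the three subgenomes of
   one group, the gene yields a triplet, classified *standard* when it
   equals an expected triplet and *nonstandard* otherwise. A nonstandard
   triplet always has a unique minority subgenome (its distance to one
   expected triplet is exactly 1), which names the inferred transfer,
   e.g. 1AS/1BL/1DL → `1AL->1AS`. Fewer than three usable hits →
   `excluded_incomplete`; three hits not covering one group →
   `excluded_top3_not_homoeologous`.
6. **Secondary-hit flag**: for nonstandard genes, hits ranked 4–10 are
   inspected; an opposite-arm hit on a triplet chromosome scoring within
   δ (default 10% of the rank-3 bitscore) flags the gene
   `flagged_ambiguous_secondary`. The flag automates a visual
   re-inspection step and never excludes a gene by itself. Note a design
   consequence: because the both-arm exclusion in step 3 already removes
   genes with *any* significant opposite-arm hit, the flag cannot fire
   inside the full pipeline with default settings — it exists as a
   standalone check (and for workflows that relax step 3). The caller
   tallies flagged genes separately and its strict mode drops them.

Classification is total (every gene gets exactly one status, and status
counts sum to the gene count) and deterministic (the tie-break chain is a
total order, so identical hit tables give byte-identical outputs).

## Inversion calling

Nonstandard genes are aggregated per chromosome by the direction of their
inferred transfer (short→long vs long→short; each gene counts on exactly
one chromosome, the one carrying its minority arm). A chromosome is called:

* **strong** — total ≥ 6, at least 3 genes per direction, and the
  co-mapping criterion holds: some short-direction gene and some
  long-direction gene lie within ε cM (default 2.0) on that chromosome's
  genetic map. Pericentromeric recombination suppression collapses genes
  inside a centromere-spanning inversion onto nearly one map position, so
  co-mapping operationalizes "the inversion encompasses the centromere".
* **putative** — total ≥ 11 with fewer than 3 genes in the minority
  direction (one-sided evidence). The two classes cannot overlap by
  construction. This operationalization reproduces the published class
  assignments: it admits exactly the four one-sided chromosomes (4D 20/0,
  5A 12/1, 6D 1/13, 7D 2/9) and none of the strong ones.
* **none** — everything else, including chromosomes that meet the count
  criteria but fail co-mapping (the published 1B case, 3/3, is presumed to
  be of this kind; its outcome is never hard-coded).

3B calls carry a `data_quality_warning`: with coordinate-derived arm
assignments, scaffold misplacement in the pseudomolecule can mimic
nonstandard locations, which is why the original survey declined to call
3B. ε is configurable; 2.0 cM encodes "co-located or tightly linked"
against maps whose pericentromeric bins span ~1 cM.

The report path emits the 21-row direction-count table with class
annotations and a grand total asserted equal to the number of accepted
nonstandard genes. The packaged survey fixture (551 genes over 21
chromosomes) is expanded into synthetic pattern rows and driven through
this same counting path, not summed separately.

## Pattern combinatorics

A pericentric inversion on subgenome c is parameterized by breakpoint
depths (s_c, l_c), distances from the centromere on the two arms; a gene at
depth d on an arm moves to the opposite arm iff d is smaller than the
breakpoint depth on its side. Only comparisons matter, so depths are
discretized to ranks 1..3 per side (ties included — they merge probe
intervals but never create patterns) and probe genes placed at interval
midpoints exhaust the behaviour space. The canonical space is every subset
of inverted homoeologues × every rank assignment per side: 1000
configurations, enumerable in milliseconds.

Exhaustive search gives the maximum number of distinct nonstandard triplets
achievable by a single genotype: **4** (and 0, 2, 4 when restricted to 0,
1, 2 inversions). The closed form is 2·min(k, 2) for k inversions: on each
ancestral side the movable probe classes are the nested proper prefixes of
the breakpoint order (at most min(k, 2) of them, since the full set of
three moved homoeologues appears standard), and the two sides contribute
disjoint triplets at the maximum. The brute-force search and the closed
form are kept as independent routes and cross-checked in tests.

The engine works in homoeologous-set space and renders arm letters through
the expected-homoeology table, so the group-4 swap relabels patterns
without changing any count; this label-invariance is property-tested.
Feasibility of an observed pattern set is decided by searching the
canonical space for a witness configuration whose achievable set is a
superset; any 5-pattern set is infeasible, and subsets of feasible sets
remain feasible (tested). Multiple sequential pericentric inversions on
one chromosome are outside the modelled space by design: the bound is a
statement about single-inversion genotypes, and the simulator's artifact
machinery (below) shows how sequential inversions escape it.

## The synthetic genome

The simulator emulates what the arm-shotgun study design observes, not
wheat sequence itself. Conditions and defaults:

* **Placement** — 200 homoeologous triplet genes per group (each
  chromosome thus carries ~200 loci), ancestral set drawn uniformly,
  depth uniform on the arm as a fraction of arm length and shared across
  the three copies (homoeologues retain ancestral positions). Chromosomes
  are 800 Mb with the centromere at fraction 0.45.
* **Group-4 structure** — group-4 triplets follow the arm swap; 12 genes
  form the distal terminal original-4AS segment (pattern 4AS/4BS/4DS,
  truth-labelled `structural_4A`); 8 genes per donor represent 5AL- and
  7BS-origin residents of modern 4AL, whose triplets straddle groups and
  exercise the `excluded_top3_not_homoeologous` path.
* **Euploid inversions** — per chromosome, breakpoint depths as arm
  fractions; copies shallower than the breakpoint flip arms at the same
  depth (depth preservation through an inversion is a simplification; only
  arm membership and pericentromeric co-mapping matter downstream).
* **Aneuploid artifacts** — an artifact attached to an arm library applies
  a further pericentric inversion *inside the telosome line sorted for
  that library*. An artifact in only one of a chromosome's two lines makes
  window genes appear in both arm libraries (excluded as both-arm
  downstream) or in neither (incomplete) — exactly the pericentromeric
  ambiguity the exclusion rule exists for — and cannot create new clean
  triplets. Applying the same artifact to both lines acts as a clean
  second inversion; the packaged demo composes such artifacts with euploid
  inversions into disjoint flip windows on the three group-6 homoeologues
  (euploid depths 0.05/0.30/0.55, artifact depths 0.25/0.50/0.75),
  yielding six distinct nonstandard patterns whose feasibility verdict is
  infeasible. 3B has no telosome lines, so artifacts on 3B are rejected.
* **Noise** — per-copy loss rate 0.05, per-gene cross-group duplication
  rate 0.10 and decoy-hit rate 0.05 (duplication and loss are common in
  polyploid wheat; the published survey's nonstandard genes were
  mostly multi-locus). Duplications and decoys land on other groups;
  same-group near-paralogs are not modelled, so false nonstandard triplets
  cannot arise from noise — noise costs sensitivity, not specificity.
  Identities: homoeologues N(96.5, 1.2), cross-group paralogs N(89, 5),
  decoys with 1.6× the paralog spread so they occasionally crack the
  top 3. Bitscores are 2·length·identity; only rank order is consumed.
* **Genetic map** — recombination density is 0.02 (relative to distal)
  within the pericentromeric 30% of each arm; cM positions are the scaled
  cumulative density at the gene's euploid physical position (maps come
  from euploid crosses), 150 cM per chromosome. Pericentromeric genes
  collapse to within ~1.3 cM, reproducing the co-mapping signal.
* **Determinism** — one `numpy` generator seeded from the mandatory config
  seed; all draws happen at simulation time, so hit emission is a pure
  rendering and identical configs give byte-identical outputs.

The default recovery scenario plants inversions on six chromosomes, one
per group where possible (1A, 2B, 4A, 5D, 6B, 7A), with breakpoint depths
0.08–0.20 — inside the recombination-suppressed window, as real
pericentric inversion breakpoints are. One inversion per group avoids a
real limitation of the arm-pattern method that the nested worked example
displays: with nested inversions, genes witness only the homoeologues
where their movement differs from the majority, so middle homoeologues are
invisible.

What passing recovery tests do *not* show about real data: the simulator
has no same-group paralogy, no HSP fragmentation, no assembly errors or
scaffold misplacement (the 3B failure mode), no identity structure along
chromosomes, and its map has no marker sparsity. Recovery at sensitivity
1.0 under these conditions validates the decision logic, not the
error rates achievable on real shotgun libraries.

## Bin reconciliation

Deletion-bin labels are parsed with both plain hyphens and en-dashes as
interval separators (public bin nomenclature mixes them), including the
stray-hyphen variant `C-4AL-12-0.43`. `C-`-prefixed labels are
centromere-anchored with interval [0, f]. Verdicts: same arm →
*concordant*; opposite arm → *contradicts*, unless the bin is
centromere-anchored and no ditelosomic hybridization evidence is available,
in which case *uninformative_pericentromeric* — presence in all deletion
lines cannot distinguish a pericentromeric short- from long-arm location
without arm-level evidence. Ditelosomic-evidence availability is an input
column (it came from scrutinizing autoradiographs, which is not
automatable) and defaults to available. Whether bins spanning the
centromere into both arms exist in the wild is left open; the parser
rejects anchored labels carrying a second fraction.

## Numerical and interface choices

* Transfers are rendered with ASCII arrows (`1DL->1DS`) in all files.
* TSV column orders are frozen constants (`PATTERN_COLUMNS`,
  `CALL_COLUMNS`, `REPORT_COLUMNS`, `VERDICT_COLUMNS`, `TRUTH_COLUMNS`)
  so outputs are diffable.
* Probe depths equal to a breakpoint are degenerate inputs and raise;
  simulated depths are continuous draws, so coincidences have measure
  zero.
* `build_ortholog_set` treats within-source reciprocal pairs as input
  errors rather than silently merging them; only cross-source clusters are
  documented behaviour.
* The acceptance script sizes its experiments as 25 noisy genomes of 7×200
  triplet genes, enough that binomial fluctuation in per-direction counts
  (means ≥ 8 where it matters) stays far from the decision thresholds.
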