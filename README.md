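# armshift

Inference of pericentric rearrangements in allohexaploid wheat from
chromosome-arm shotgun hit data.

## The problem

Hexaploid bread wheat (*Triticum aestivum*, genomes AABBDD) carries three
homoeologous copies of most genes, one per subgenome. When the wheat
chromosome complement is decomposed into flow-sorted arm libraries, each
gene can be located to a chromosome arm by its best BLASTn hits. If the
three homoeologous copies of a gene do not sit on mutually homoeologous
arms — say the hits fall on 1AS/1BL/1DL instead of 1AL/1BL/1DL — the gene
witnesses a *pericentric inversion*: an inversion whose breakpoints lie on
opposite arms, so the inverted segment spans the centromere and ferries
genes across it. `armshift` turns tabular hit files into such arm-pattern
calls, aggregates them into per-chromosome inversion verdicts, checks them
against deletion-bin EST locations, and answers a combinatorial question
with direct experimental consequences: **how many distinct nonstandard
arm-location patterns can a single genotype display?**

The answer — proved here by exhaustive search and in closed form — is
**four** per homoeologous group, as long as each chromosome carries at most
one pericentric inversion. Observing five or more patterns in one group
(as happens on wheat groups 4, 6 and 7) is therefore evidence that some of
the rearrangements arose independently in the aneuploid (ditelosomic)
stocks used to flow-sort the arms, not in the euploid genotype itself.

## What the package computes

| stage | module | decision rule |
|---|---|---|
| expected homoeology | `armshift.homoeology` | per-group arm triplets, with the group-4 swap (modern 4AL ↔ 4BS/4DS) from the 4A/5A/7B cyclic translocation; ten-segment modern-4A model; 3B arm assignment from pseudomolecule coordinates against the 265–387 Mb centromere interval |
| pattern classification | `armshift.classify` | e-value filter (default 1e-5), both-arm exclusion, best-HSP-per-library top-3 ranking, triplet classification, inferred transfer (e.g. `1DL->1DS`), secondary-hit ambiguity flag |
| inversion calls | `armshift.call` | **strong**: ≥ 6 transferred genes, ≥ 3 per arm, and short- and long-arm genes co-mapping within ε cM (default 2.0); **putative**: ≥ 11 genes with < 3 in the minority direction |
| combinatorics | `armshift.combinatorics` | pattern derivation per probe gene, exhaustive enumeration over rank-discretized inversion configurations, the max-four bound, feasibility verdicts with witness configurations |
| bin reconciliation | `armshift.bins` | concordant / contradicts / uninformative-pericentromeric verdicts for deletion-bin labels such as `C-1AS1-0.47` |
| simulation | `armshift.simulate` | synthetic AABBDD genomes with planted inversions, per-arm-library aneuploid artifacts, gene loss/duplication, decoy hits, recombination-suppressed genetic maps, and full truth tables |

## Worked example

Simulate the textbook nested triple inversion on group 6 (inverted segments
larger on 6D than on 6B than on 6A), classify the emitted hits and call
inversions:

```bash
$ armshift pipeline --preset fig3a --seed 7 --out demo
filters: accepted=1400, excluded_both_arms=0, excluded_incomplete=0, excluded_top3_not_homoeologous=0, flagged_ambiguous_secondary=0; nonstandard=29
calls: 2 strong, 0 putative -> demo
```

All 1400 simulated genes classify cleanly; 29 show nonstandard arm
locations, and the caller reports strong inversions on 6A (9 short-to-long,
4 long-to-short transfers) and 6D (8 and 8) — note that with *nested*
inversions the middle homoeologue (6B) is invisible to the arm-pattern
method, because a gene only looks nonstandard on the homoeologues where its
movement differs from the majority. The distinct nonstandard triplets are
exactly the four the combinatorics predicts:

```bash
$ armshift enumerate --inversions "A:1:1,B:2:2,D:3:3" --group 6
6AL/6BL/6DS
6AL/6BS/6DS
6AS/6BL/6DL
6AS/6BS/6DL
n_nonstandard_patterns	4
```

Adding a fifth pattern makes the set impossible for a single genotype:

```bash
$ armshift feasibility --patterns "6AS/6BS/6DL,6AS/6BL/6DL,6AL/6BS/6DS,6AL/6BL/6DS,6AL/6BS/6DL"
infeasible: no single-genotype inversion configuration reproduces the observed patterns
```

The library surface mirrors the CLI: `simulate_genome`, `classify_all`,
`call_all`, `enumerate_patterns`, `feasibility_check`, `reconcile_all`.

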