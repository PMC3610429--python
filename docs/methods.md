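# Methods

## Scope and model

`orthotrace` consolidates two independent orthogroup predictions over a
curated inventory of protein-translocation factors and resolves
co-orthologue ambiguity with four evidence channels.  The package treats
the orthogroup predictors as exchangeable inputs: externally produced group
files (OrthoMCL-style `groups` text or pairwise TSV) can be loaded
directly, and two built-in surrogate engines make the pipeline end-to-end
runnable at desk scale.  The surrogates are deliberately simple — they are
stand-ins *authored as such*, not reimplementations of the external tools:

* **RBH + inparalogs.**  Pairwise similarity is the Smith–Waterman local
  alignment score (BLOSUM62, gap open 11, extend 1, as bundled with
  Biopython) divided by the shorter sequence length.  Seed orthologues are
  mutually best-scoring cross-species pairs; a same-species gene joins when
  its similarity to a seed member is at least the seed score (ties
  included, so fresh identical duplicates always attach); overlapping
  clusters merge transitively.  All tie-breaks are lexicographic on
  (species, gene id), so the output is deterministic.
* **Markov flow clustering.**  The similarity graph becomes a
  column-stochastic matrix (self-loops at each node's maximum incident
  weight stabilise the flow); expansion (matrix squaring) alternates with
  inflation (elementwise power, default 1.5, then column renormalisation)
  until the largest entry change falls below 1e-6 (max 100 iterations).
  Column sums are asserted to within 1e-9 after every step.  Groups are
  connected components of the limit matrix thresholded at 1e-8; flow
  cannot cross components of the input graph, so MCL output always refines
  the graph's connected components.

All-vs-all alignment uses an exact shared-4-mer prescreen: a pair with no
common 4-mer is skipped.  At 5% per-site divergence orthologous pairs share
hundreds of 4-mers, so the prescreen only removes pairs that could not have
reached the edge threshold (normalised score 1.0) anyway; it can be
disabled (`kmer_prefilter=None`).

## Consolidation statistics

A factor's orthologue set per method and species is the union over its
baits of the bait's group-mates in that species, minus the factor's own
baits there.  Between-method **overlap** is the fraction of factors whose
sets are *identical* for every method and target species — the strictest
possible granularity; a per-gene Jaccard variant is available
(`jaccard_overlap_statistic`) for a softer view.  **Missing** counts
factors empty under *every* method in the target species; **multiplicity**
counts factors whose consensus (union over methods) has more than one
member.  Orthologue totals are reported both as distinct genes and as
factor–gene assignments, since several factors may legitimately share a
gene.

## Evidence channels and the cascade

Per factor, side A is its species-A baits plus consensus co-orthologues
there; side B is the consensus set in species B.  Candidates (the cross
product) are resolved in this order, each stage consuming the pairs it can
settle:

1. **consensus** — a 1:1 situation is assigned outright;
2. **architecture** — ordered domain-name lists, compared under an
   editable clan-like equivalence map (the bundled map joins the
   zinc-finger families RING_2 and C3HC4_2, which profile scans report
   interchangeably).  Domain *lengths* and hit coordinates are ignored:
   two proteins with the same ordered families are architecture-equal even
   if one domain is shorter.  Overlapping domain hits are resolved
   pairwise — a hit loses to any hit covering more than half of the
   shorter one with higher score (ties: lower start wins).  A side-A gene
   with no architecture-equal candidate is scanned for split-gene events:
   its architecture is compared with concatenations of two co-chromosomal
   genes within rank gap 1 (either order); hits produce one assignment row
   per partner sharing a fusion id.  Tandem repeats are kept distinct
   (WD40×3 ≠ WD40×2) — a deliberate choice, flagged as a divergence risk
   against pipelines that collapse repeats.
3. **synteny (`+`)** — windowed shared-synteny scores over the remaining
   candidates; greedy score-descending matching; flag only on positive,
   strictly dominant scores.  The counting unit is "window-A genes with at
   least one partner", symmetrised as the minimum of the two directions;
   both directional counts are retained, and a counts-all-pairs unit is
   available (`count_unit="pairs"`).
4. **expression (`#`)** — Pearson correlation of log2(1+x)-transformed,
   platform-scaled profiles across shared canonical tissues (≥3 required;
   microarray values ×100, RNA-seq ×1000 by default).  Flag requires
   r ≥ 0.8 and a margin of 0.1 over every competitor sharing an endpoint;
   both thresholds are artifact choices (the historical analysis used
   visual inspection) and are exposed as parameters.  Spearman is offered
   as an alternative.
5. anything left is emitted as an **unresolved** row listing the surviving
   candidates — expert-judgment cases are reported, not guessed.

The cascade order (consensus → architecture → synteny → expression) is a
configuration-level choice; the stages are independent functions, so any
permutation can be driven externally.

Protein-length agreement is summarised by the through-origin least-squares
fit y = a·x (closed form a = Σxy/Σx²); no intercept is fitted because
orthologous proteins are expected to scale through the origin.

Factor categories (for colour-coded overview tables) are assigned with a
fixed precedence: absent from all plants ≻ plant-only baits ≻ absent from
species B ≻ equal / more-in-B / fewer-in-B by count comparison.

## QC filters

Two screens precede inference.  The CDS/protein eligibility check keeps an
entry iff its CDS length is 3·L or 3·(L+1) (terminal stop codon optional;
`strict=True` demands it), its id is unique and it pairs one-to-one across
the files; totals mismatch raises a global flag.  The quality filter drops
proteins shorter than 10 residues or with more than 20% `*` symbols; both
thresholds are strict inequalities, so boundary cases (length exactly 10,
exactly 20% stops) are kept.  Violations are always reported with reasons,
never silently dropped — callers choose whether to remove or merely flag.

## The simulator

The generator's defaults *are* the study conditions: 150 ancestral genes on
2 chromosomes, protein lengths uniform on 60–120 aa, architectures of 1–3
domains from a 30-name alphabet; lineage A undergoes two whole-genome
duplications at retention 0.3, lineage B one triplication at retention 0.4;
gene loss 0.1 applied to every gene after duplication; 5% uniform per-site
substitution per copy; 20 adjacent-transposition rearrangement operations
per lineage; 4-tissue lognormal expression (base σ = 1.0, copy noise
σ = 0.25) tagged microarray (species A) / RNA-seq (species B); emulated
method outputs disagree on 18% of factor-linked groups.

Design notes and deliberate simplifications:

* substitution is uniform random replacement (a site may resample its own
  residue); no indels, no rate heterogeneity, no codon structure.  This is
  sufficient for similarity *ranking*, which is all the engines consume —
  absolute score calibration is out of scope.
* loss applies to every gene copy, originals included, so the expected
  descendant count under one WGD is n·(1+p)·(1−q).
* rearrangement is composed adjacent transpositions, chosen so the 7-gene
  window signal degrades gradually with the op count; swaps that would
  separate planted split-gene partners are rejected, keeping partners
  rank-adjacent as the fusion scan requires.
* split-gene events are only applied to families with exactly one
  surviving copy in the splitting lineage and ≥2 domains; the architecture
  and sequence are divided at a random domain boundary.
* emulated method 2 perturbs each factor-linked group independently
  (dropping a non-bait member, or swapping in a decoy for 2-member
  groups) so the overlap statistic is exactly Binomial(n, 1−d) — no
  cross-group side effects.
* every stage draws from its own spawned RNG stream under one master seed;
  a bundle is byte-identical across runs with the same configuration.

What passing tests on simulated data do *not* show: robustness to real
annotation noise (fragmented gene models, isoforms, tandem arrays),
alignment-score calibration on real divergence levels, or the behaviour of
the external clustering tools themselves — the engines here are surrogates
and real group files should be substituted where available.

## Problem sizes and numerical choices

Default test and acceptance runs use 150 ancestral genes (≈450 descendant
proteins, ≈10⁵ candidate alignments after prescreening), which exercises
every code path in seconds while leaving duplication/loss statistics
non-degenerate.  Oracle-equivalence checks run the exhaustive
implementations at n ≤ 30 sequence length, ≤ 15-gene windows and ≤ 4×4
assignment matrices, where brute force is exact and fast.  Floating-point
tolerances: alignment scores are compared to the DP oracle at 1e-12
(identical arithmetic), the length-fit slope to a derivative root-finder at
1e-10, MCL column sums at 1e-9.  Greedy matching is used for candidate
pairing (deterministic and transparent at factor-scale candidate sets);
exhaustive optimal matching is available behind `optimal=True` and the test
suite quantifies how often greedy is sub-optimal on random matrices.

## Known limitations

* The two built-in engines omit InParanoid confidence/bootstrap scores and
  OrthoMCL's between-species score normalisation; multi-species merging is
  plain transitive closure.
* Architecture identity ignores domain counts' residue spans entirely; a
  truncated domain still matches.
* The expression channel assumes profiles are already normalised per
  platform up to a global scale factor; no raw-intensity preprocessing.
* Categories depend on which species are declared "plant"; in simulated
  data all baits come from species A, so the plant-only bin dominates
  unless the caller supplies a non-plant bait species.
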