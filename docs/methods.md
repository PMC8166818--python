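# Methods

This note documents the models, conventions and design choices behind
each stage, what the synthetic study conditions emulate, and what
passing tests do and do not establish about real data.

## Family classification by domain architecture

A family signature is an ordered list of counted domain requirements
`(domain, min, max)` plus an optional forbidden set. A gene satisfies a
signature when every required domain's instance count lies in its
bounds and no forbidden domain is present; among satisfied signatures
the most *specific* one (most required domain types) wins, and an exact
specificity tie is surfaced as an error rather than resolved silently.
Because signatures constrain only the domains they name, a domain
absent from every signature (a decoy) can never change a verdict.

The shipped set encodes seven signatures covering the nine core pathway
genes:

| family | requirements |
|---|---|
| Notch | EGF ≥ *several*, LNR = 3, TM ≥ 1, ANK ≥ *several* |
| Delta | MNLL ≥ 1, DSL ≥ 1, EGF ≥ 1 |
| Jagged | Delta requirements + VWC ≥ 1 |
| Dll | DSL ≥ 1 (catch-all below Delta) |
| Presenilin | Presenilin ≥ 1 |
| Su(H) | LAG1-DNAbind ≥ 1 |
| Hes/Hey-related | bHLH ≥ 1 |

Choices worth flagging:

* **"Several"** has no published numeric floor; it is operationalised
  as `several_min_count` (default 2), the weakest common reading, and
  is configurable. The canonical 29–36 EGF range of vertebrate Notch
  receptors describes typical architecture, not a filter, so EGF counts
  are uncapped.
* **LNR is fixed at exactly three** because the three-repeat negative
  regulatory region is definitional; a four-LNR gene is left
  unassigned rather than silently accepted.
* **Domain order is not enforced by default** (no order requirement is
  part of the verbal definitions); signatures carry order metadata so
  enforcement can be switched on.
* **Hes/Hey subtypes are not an architecture question.** Hes, Hey,
  Helt and Cwo all carry bHLH(+Orange); architecture assigns the
  superfamily label and subtype identity is delegated to clade
  assignment on a gene tree (below). Consequently the signature set has
  seven entries for nine gene families.
* **Overlap resolution** admits hits best-first by (E-value, start,
  domain name) and drops a hit overlapping an admitted one by more than
  50% of the shorter hit — a deterministic greedy rule; upstream tools
  do not document an overlap policy, so this one is explicit.
* The E-value screen (default 1e-5) keeps hits with E ≤ threshold.

## Premature-termination typing

Input is a reference/derived paralog CDS pair; the reference must be a
clean frame-0 ORF (ATG start, terminal stop, no internal stop).
Translation uses the standard genetic code only; codons containing N
translate to X and never terminate.

**Alignment.** Global pairwise alignment with affine gaps, match +2,
mismatch −1, gap open −5, gap extend −1 (a length-L gap costs
5 + (L−1)). These values are fixed and documented because the analysis
depends on reproducible indel placement, and the upstream viewer-based
comparisons they replace publish no parameters. After traceback, every
gap run is left-normalised — slid left while the flanking residue
entering the run equals the residue leaving it — so an indel inside a
homopolymer is always reported at the run's first base. The planted
truths use the same canonical coordinate, which is what makes exact
coordinate recovery a meaningful test. The DP score is verified in
tests against an independent scalar implementation, and the emitted
alignment is re-scored column-by-column to confirm it achieves the
optimum.

**Mechanism taxonomy.** Let the derived paralog's first in-frame stop
span nucleotides [lo, hi). Typing is positional:

1. a substitution column inside the span → `substitution_nonsense`;
2. an insertion whose inserted bases overlap the span → `insertion_stop`
   (the inserted base is part of the stop codon);
3. otherwise the nearest upstream frame-shifting indel whose effect
   reaches the stop (a deletion boundary at or before lo, or an
   insertion ending at or before lo) → `deletion_frameshift` /
   `insertion_frameshift`.

When several differences precede the stop, the nearest upstream edit is
reported as causal and all others as alternates — real paralog pairs
accumulate many differences and a single hard call would overstate
certainty. Scanning upstream nearest-first is equivalent to the
windowed search (30 codons, then widen) that motivated it.

**Anchor window.** The report includes the offset, in reference-frame
amino acids, from the last anchor residue (arginine by default; the
conserved arginine is specific to the Delta comparison and the anchor
is configurable) to the stop, and whether it falls in the configured
window (default 1–10 inclusive). Whether offsets of exactly 0 or 11
should count is genuinely unspecified, which is why the bounds are
config, not constants. A reference with no anchor upstream yields an
explicit *indeterminate* flag, never `False`.

## Dollo gain/loss reconstruction

Under Dollo parsimony a family arises exactly once and is only lost
thereafter. On a rooted tree with a 0/1 leaf vector, the optimum is
closed-form: the gain edge is the edge above the MRCA of present
leaves, and the loss edges are the stems of the maximal wholly-absent
subtrees inside the gain clade. Both are unique, so no search is
involved; the test suite nevertheless checks the construction against
brute-force enumeration of all single-gain histories on random trees
(≤ 7 leaves, all nonzero vectors). Edges are identified by the leaf set
below them. Polytomies are accepted (each child treated
independently); unrooted trees are rejected rather than auto-rooted,
because the reconstruction is meaningless without a root. When every
leaf is present the gain sits on a virtual edge above the root and is
flagged `origin_at_root` — "at or before the root of the sampled taxa"
is all the data can support.

The packaged mollusc fixture encodes a conventional topology — chiton
outgroup, then gastropods sister to cephalopod+bivalves — with the
three Delta2-less gastropods placed pairwise non-adjacently so the
planted history (one conchiferan-stem gain, three independent terminal
losses) is the unique optimum. Published mollusc phylogenies differ in
detail; the fixture freezes one so the expected answer is exact.

## Distance phylogenetics

The tree-building route is deliberately desk-scale: uncorrected
p-distance + neighbor joining + column-resampling bootstrap. ML and
Bayesian inference are out of scope; NJ is an acceptable surrogate for
clade questions because on additive distances it is consistent
(verified on random trees in the tests), and the clade questions asked
here (paralog monophyly, subtype nesting) are topological.

Conventions: alignment columns are dropped when their gap fraction
exceeds `gap_fraction_trim` (an explicit rule replacing tool-internal
trimming heuristics); p-distance excludes columns with a gap in either
row and flags a pair with zero comparable columns as missing rather
than zero; NJ breaks Q-matrix ties by the lexicographically smallest
label pair; a negative NJ branch length is clamped to zero with the
deficit moved to the sister branch, preserving the cherry span.
Bootstrap support is reported on bipartitions (edge-based, rooting-
independent); replicate column indices come from
`numpy.random.default_rng(seed)` consumed in replicate order, making
supports bit-reproducible. Subtype assignment walks from a query leaf
rootward; the first ancestor containing any reference leaf decides
(one reference subtype → that subtype, several → ambiguous), which is
exactly the smallest-pure-clade rule since larger clades only add
references.

## Expression trend comparison

Profiles are compared by Spearman rank correlation by default: RPKM
and FPKM are within-sample units, so only trends are comparable, and
rank correlation is invariant to per-gene positive affine transforms
(property-tested), making unit mixing harmless. "Complementary
expression" has no quantitative definition in the comparative
literature; it is operationalised as ρ ≤ `complementarity_threshold`
(default −0.5) with the threshold printed in every report. At least
four stages are required (rank correlation on fewer is degenerate);
constant profiles are flagged and excluded, never zeroed. The peak
report uses a (max+1)/(median+1) ratio — the +1 pseudocount avoids
division by zero for silent genes and is named in the output column.
Genes with median raw expression below `low_expression_floor` carry a
flag with no further claim attached. Cross-species comparison is
restricted to trend statements; no cross-species value normalisation is
attempted.

## Synthetic study conditions

Every generator is a pure function of its arguments including the seed.

* **Architectures** are emitted as hit-table annotations, not sequence
  motifs: the classification logic consumes hit tables, and profile-HMM
  scanning is out of scope, so nothing would be tested by embedding
  motifs. Planted genes draw instance counts from the signature bounds,
  lay hits non-overlapping in order, and draw E-values log-uniform on
  [1e−30, 1e−8].
* **Truncation plants** start from a clean ORF built directly from the
  61 sense codons (so no incidental in-frame stop can occur), apply one
  edit at a target codon, and record the left-normalised coordinate.
  Candidate edits are filtered to those whose positional classification
  matches the requested mechanism; if none exists at the target codon
  the generator raises a `PlantError` advising a different target —
  roughly 40–60% of random targets admit a nonsense substitution or
  stop-forming insertion, so callers scan or resample.
* **Gain/loss simulation** takes an explicit gain clade and pairwise
  non-nested loss clades and emits the implied leaf vector; recovery is
  guaranteed only when the planted history is the unique optimum, which
  the tests check via the enumeration oracle.
* **Expression pairs** are affine transforms on an RPKM-like 0–10
  scale: the second profile is `a·x + b` (similar), `a·(10−x) + b`
  (complementary) with a ~ U(0.5, 2), b ~ U(0, 2), or an independent
  draw (unrelated), plus Gaussian noise in the same units.
* **Random trees** join uniformly chosen clusters with branch lengths
  U(0.1, 2.0) — only topology matters to Dollo, only additivity to the
  NJ consistency tests.

What passing these tests shows: the implementations are exact on their
own definitions and recover planted truth under clean and moderately
noisy conditions. What they do not show: robustness to the failure
modes of real annotation pipelines — fragmented gene models, chimeric
hits, missed domains, assembly-dependent absence calls, or expression
noise structure beyond i.i.d. Gaussian perturbation of a planted trend.
Absence of a gene in a draft genome is weaker evidence than absence in
a finished one, and the Dollo loss counts inherit that caveat.

## Problem sizes and numerical conventions

The acceptance script runs 200 planted genes, 500 planted truncations
(125 per mechanism, 150-codon ORFs), 100 random trees (4–7 leaves, all
nonzero presence vectors) against the enumeration oracle, 100 8-leaf NJ
recoveries, 200 bootstrap replicates, and 1000 expression replicates —
sizes chosen so the full recomputation completes in well under a
minute while every rate is estimated on hundreds of cases. All scores
in the alignment DP are integer-valued, so floating-point equality in
traceback is exact. Output floats are formatted with `%g` and reports
are written with sorted keys, which together with seeded RNG makes
whole runs byte-reproducible.

## Known limitations

* Signatures are count-based; they cannot express inter-domain spacing
  or positional constraints (e.g. TM location), and TM detection itself
  is delegated to the upstream annotation.
* The truncation module compares exactly two paralogs; it does not
  reconstruct ancestral sequences, handle splice variants, or test
  selection (dN/dS).
* NJ trees are for clade questions, not publication phylogenetics; no
  rate heterogeneity, no model selection.
* Relative-age claims about paralog clades (which duplicate "appeared
  later") mix topology with branch-length reasoning and are not
  asserted by this package; only monophyly is.
* The four-group DSL partition (dsl_only, dsl_tandem, dsl_egf,
  dsl_egf_other) reconstructs a described branch structure whose groups
  were never formally named; the mapping is documented in
  `architecture.dsl_group`.
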