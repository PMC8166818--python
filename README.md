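# notchevo

Comparative evolution of Notch-pathway gene families, as a tested,
reusable pipeline. The package targets the questions that arise when a
signalling pathway is surveyed across many genomes — here the Notch
pathway across metazoans, with emphasis on lophotrochozoans and the
duplicated mollusc ligand *Delta2*:

1. **Which family is each gene?** Families are defined by counted domain
   architectures (e.g. *Notch* = several EGF repeats + exactly three LNR
   repeats + a TM domain + several ANK repeats; *Jagged* = the *Delta*
   architecture plus a VWC domain; a DSL-bearing gene missing the full
   *Delta* layout is *Delta-like*). `notchevo.architecture` applies these
   signatures to E-value-filtered domain-hit tables, resolves overlaps,
   groups DSL genes into four architecture classes, and builds
   presence/absence and domain-count matrices.
2. **Why is the derived paralog truncated?** `notchevo.truncation`
   aligns a reference/derived CDS pair (global, affine gaps: match +2,
   mismatch −1, gap open −5, extend −1, left-normalised gaps), finds the
   derived paralog's first in-frame stop, and types its cause:
   `insertion_stop`, `substitution_nonsense`, `deletion_frameshift` or
   `insertion_frameshift`, with the exact causal edit coordinate and the
   offset from the last reference arginine.
3. **Where did the family originate and where was it lost?**
   `notchevo.gainloss` reconstructs the Dollo-parsimony history (single
   gain, minimal losses) of each family on a rooted species tree: the
   gain edge is the MRCA stem of the present taxa, the losses are the
   stems of the maximal wholly-absent subtrees — both exact.
4. **Do paralogs fall into separate clades?** `notchevo.phylo` provides
   gap-fraction trimming, p-distances, neighbor joining, bipartition
   bootstrap support, monophyly tests and clade-based subtype assignment
   (used for the architecturally identical Hes/Hey/Helt/Cwo repressors).
5. **Are paralog expression programs complementary?**
   `notchevo.expression` compares stage-resolved RPKM/FPKM profiles by
   rank correlation; a pair is *complementary* at ρ ≤ −0.5 and *similar*
   at ρ ≥ +0.5 (both thresholds configurable and surfaced in reports).

Because the original genome-scale inputs are external downloads, the
package ships a synthetic-data module (`notchevo.synthetic`) that plants
ground truth for every stage — domain architectures, termination
mutations, gain/loss histories, expression relations — so the entire
pipeline is testable end to end with exact expected answers.

## Worked example

The packaged mollusc case study (`examples/03_dollo_gainloss.py`):

```
Delta1: gain above [root (or earlier)]
  losses (0): -
Delta2: gain above [Aca_gastropod+Bgl_gastropod+Cgi_bivalve+Ech_gastropod+Hdh_gastropod+Lgi_gastropod+Mye_bivalve+Obi_cephalopod]
  losses (3): ['Aca_gastropod', 'Bgl_gastropod', 'Ech_gastropod']
Helt: gain above [root (or earlier)]
  losses (2): ['Aca_gastropod+Ech_gastropod+Hdh_gastropod', 'Bgl_gastropod']
```

Delta1 is present in every taxon, so its origin lies at or before the
root of the sampled taxa. Delta2 originates once, on the stem of the
gastropod+cephalopod+bivalve clade (it is absent from the chiton
outgroup), and is lost three times, each on a terminal gastropod branch.
Helt is ancestral but lost twice within gastropods, once on an internal
branch spanning a whole subclade.

Expression comparison of the same ligands
(`examples/05_expression_complementarity.py`):

```
Delta1 vs Delta2: rho=-1.00 -> complementary
Jagged vs Delta2: rho=+1.00 -> similar
Jagged vs Delta1: rho=-1.00 -> complementary
```

Delta1 and Delta2 have anti-correlated developmental programs, and
Jagged's profile ranks closer to Delta2 than to Delta1 — the bivalve
pattern.

The other examples cover family classification
(`01_classify_families.py`), truncation mechanism typing
(`02_truncation_mechanisms.py`) and tree building with subtype
assignment (`04_tree_and_subtypes.py`).

## Command line

A thin CLI wraps the same library calls:

```sh
notchevo make-fixtures --seed 42 --out-dir fixtures/
notchevo run --manifest fixtures/manifest.txt --out-dir results/
notchevo gainloss --tree sp.nwk --matrix presence.tsv --out-dir out/
```

`run` executes classify → gainloss → truncation → expression → tree on a
manifest of input paths and writes TSV outputs plus `report.json`; two
runs with the same manifest and seed are byte-identical. Exit codes:
0 success, 2 validation error, 3 I/O error.

## Scope

The package consumes standard upstream products rather than producing
them: domain-hit tables (HMMER-style), pre-aligned protein FASTA, rooted
newick species trees, and expression matrices. Profile-HMM scanning,
multiple-alignment construction, ML/Bayesian tree inference and read
quantification are out of scope; neighbor joining serves as the
desk-scale tree-building route and a simple gap-fraction rule replaces
automated alignment trimming.
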