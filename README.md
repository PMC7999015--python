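# fvimprint

Homology-guided discovery of imprinted genes from reciprocal-cross clone
sequencing.

## The problem

Genomic imprinting is parent-of-origin-dependent monoallelic (or strongly
biased) expression in offspring tissue. In flowering plants it occurs
mainly in the endosperm, the triploid seed tissue that carries two
maternal genome copies and one paternal — so under ordinary biallelic
expression the maternal:paternal allelic ratio is expected to be 2:1 in
endosperm and 1:1 in the diploid embryo. A gene whose maternal allele
dominates far beyond that expectation, *in both directions of a
reciprocal cross*, is a maternally expressed gene (MEG); paternal
dominance gives a PEG. The reciprocal design is what separates
imprinting (which tracks the parental role) from a fixed allelic bias
(which tracks the nucleotide allele).

`fvimprint` implements the desk half of a classic low-throughput hunt
for conserved imprinted genes, as used for wild strawberry
(*Fragaria vesca*):

1. **Homology screen** (`fvimprint.homology`) — candidate genes are the
   proteome subjects homologous to query proteins known to be imprinted
   elsewhere. Exact Smith–Waterman with affine gaps (BLOSUM62, open 11 /
   extend 1); significance via the Karlin–Altschul transform
   `bit = (λS − ln K)/ln 2`, `E = m·n·2^−bit`; default cutoff `E < 1e-9`.
2. **SNP detection** (`fvimprint.snps`) — per-parent consensus from ~20
   cloned Sanger reads per gene; *pure* SNP sites (every clone of each
   parent agrees, and the parents differ) are the only positions that can
   assign a hybrid clone to a parent.
3. **Imprinting classification** (`fvimprint.classify`) — hybrid clones
   are genotyped at the SNP sites (one vote per clone, sites on a clone
   are linked) and counted as maternal/paternal per tissue and cross
   direction. Strict threshold rules: endosperm MEG if m:p > 4:1 in both
   directions, PEG if p:m > 2:1 in both; embryo uses a symmetric 3:1
   rule. Same-nucleotide dominance in both directions is reported as
   `ALLELIC_BIAS`, not imprinting.
4. **Expression profiling** (`fvimprint.qpcr`) — relative expression
   across tissues by 2^−ΔΔCT against a reference gene, technical
   replicates averaged before biological-replicate statistics, Welch
   t-test stars on ΔCT.
5. **Synthetic data** (`fvimprint.simulate`) — because the original
   Sanger data are not deposited, a seeded generator produces parental
   haplotypes with planted SNPs, Bernoulli clone sampling at the
   ploidy-expected maternal fractions, and qPCR plates; plus a fixed
   "paper fixture" that mirrors the published candidate-gene funnel.

## Worked example

```sh
python examples/04_full_pipeline.py
```

runs the whole pipeline on the packaged fixture and prints

```
"candidates_found": 17,
"snpless_candidates": 10,
"informative_genes": 7,
"calls_per_tissue": {
  "endosperm": {"MEG": 5, "BIALLELIC": 2},
  "embryo":    {"BIALLELIC": 7}
}
```

— 15 query proteins yield 17 candidate homologs (one query has no
homolog, two have paralogous multi-hits); 10 candidates carry no SNPs
between the parents and are uninformative; of the 7 informative genes,
5 are endosperm MEGs (monoallelic, m:p ratio ∞ in both directions) and
none is imprinted in embryo, where every ratio sits at the 1:1
expectation. `examples/01–03` exercise each stage separately, and the
`fvimprint` command exposes the same stages as subcommands
(`simulate`, `screen`, `snps`, `classify`, `qpcr`, `run-all`).

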