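# Methods

## Study design being modelled

Two inbred parental ecotypes are crossed in both orientations
(reciprocal cross). For each candidate gene, the CDS is amplified from
each parent and from hybrid endosperm and embryo, cloned, and ~20
colonies per sample are Sanger-sequenced. Each colony carries one cDNA
molecule, so the fraction of colonies per allele estimates the allelic
expression ratio. The endosperm is triploid (2 maternal : 1 paternal
genome copies), the embryo diploid, giving expected maternal fractions
of 2/3 and 1/2 under biallelic expression.

## Homology screen

Candidates are found by exact local alignment of query proteins against
a candidate proteome — Smith–Waterman with affine gaps, BLOSUM62, gap
open 11 / extend 1. No heuristic seeding or composition-based
statistics: at desk scale the exact DP is fast and fully deterministic.

Significance uses the ungapped Karlin–Altschul constants for BLOSUM62
(λ = 0.3176, K = 0.134, configurable): `bit = (λS − ln K)/ln 2` and
`E = m·n·2^−bit` with `m` the query length and `n` the total database
length. These constants are nominally for ungapped statistics; applied
to gapped scores they are a deliberate simplification — E-values here
separate "clearly homologous" from "chance" by hundreds of orders of
magnitude, and no conclusion rests on their absolute calibration. The
default cutoff is `E < 1e-9`. Ties in E break lexicographically by
subject id so hit tables are reproducible.

Two column metrics are reported per hit: identity (identical columns /
alignment length) and similarity (identical-or-positive-scoring columns
/ alignment length). `percent_similarity` as a standalone operation uses
the *global* alignment length including gap columns — the conventional
"similarity over alignment" number quoted when comparing two specific
proteins. A column that is identical counts as similar even where the
matrix diagonal is non-positive (the X/X corner case), preserving
identity ≤ similarity.

## SNP detection

Per-parent consensus is the per-column plurality base over the clone
reads; purity is the plurality fraction (N excluded from the vote,
counted in the denominator). A tied column takes the alphabetically
first base but is flagged and given purity 0, so it can never pass any
threshold. The purity threshold defaults to 1.0 — the strict reading of
"pure site": every clone of each parent must agree — and is configurable
down to 0.9 for noisy reads.

SNP sites are positions where the parental consensuses differ and both
purities pass. Coordinates are 1-based on the parent-A consensus. Reads
are assumed full-length and co-linear (the amplicon design guarantees
this); a rare length-discordant read or consensus pair is reconciled by
global alignment, with indel columns excluded from calling —
substitutions only.

Genotyping maps each hybrid clone's base at every SNP site to the
parent-A allele, parent-B allele, or unknown (third base / N). Unknowns
are data, not errors: they absorb sequencing noise without biasing the
parental counts.

## Imprinting classification

Counts are aggregated **per clone**, not per site: a clone votes once,
by majority over the gene's SNP sites, because sites on one cDNA clone
are fully linked and per-site pooling would pseudo-replicate. Tied or
all-unknown clones count as unknown.

Rules, applied with strict inequalities ("higher than"):

| tissue | MEG | PEG | biallelic expectation |
|---|---|---|---|
| endosperm | m/p > 4 in both directions | p/m > 2 in both | 2:1 |
| embryo | m/p > 3 in both | p/m > 3 in both | 1:1 |

The endosperm PEG threshold is laxer than the MEG one relative to the
2:1 prior — asymmetric in the opposite direction of the prior. It is
implemented as stated because it is the published rule; the
`Thresholds` dataclass makes it configurable.

`p = 0` gives ratio +∞ (monoallelic maternal). A sample with fewer than
`min_informative = 5` parent-assignable clones is UNINFORMATIVE: ratios
from tiny denominators are unstable, and the source protocol is silent
on a minimum. If one fixed nucleotide allele (rather than one parental
role) clears the role-appropriate thresholds in both directions the
call is ALLELIC_BIAS — a category added here because the reciprocal
design exists precisely to make that distinction. Everything else is
BIALLELIC; no goodness-of-fit test changes a call (the original
judgment was visual "close to 2:1 / 1:1").

Thresholds must hold in **both** reciprocal directions (the default;
the alternative pooled reading is expressible by summing counts before
classification). `brute_force_oracle` re-derives every call by
exhaustive enumeration with exact integer arithmetic (`m > t·p`) and is
used to verify the classifier exactly over all count tables with up to
20 clones per direction.

## qPCR relative expression

Technical replicates are averaged first (standard practice); each
biological replicate gives ΔCT = mean(target) − mean(reference). ΔΔCT
is taken against the *mean* calibrator ΔCT, and the tissue-level fold
change is `2^−(mean ΔCT − calibrator mean ΔCT)`, so the calibrator's own
fold is exactly 1; the spread reported is the SD of per-replicate
folds. Fold changes are invariant to adding a constant to all Ct
values.

Significance is a two-sided Welch t-test on ΔCT values versus a named
baseline tissue (ΔCT is approximately normal on the log2 scale; the
original analysis software did not name its test, so the test and the
calibrator are explicit configuration here). Stars: p ≤ 0.05 (*),
0.01 (**), 0.001 (***). Identical zero-variance replicate sets return
p = 1 rather than an undefined statistic. No amplification-efficiency
correction (Pfaffl) or multi-reference normalisation is attempted.

## Synthetic data generator

What it emulates: planted CDS substitutions between two inbred parents
(exactly `n_snps` positions, uniform without replacement, recorded as a
1-based ground-truth manifest); i.i.d. Bernoulli clone origin at the
gene's maternal fraction for the tissue (MEG defaults to 1.0 in
endosperm; biallelic to the ploidy fractions 2/3 and 1/2); optional
beta-binomial overdispersion (`overdispersion_rho`) to inject
maternal-tissue contamination for false-positive studies; independent
per-base substitution errors (default 0 so planted truth is exactly
recoverable); qPCR plates of 3 biological × 4 technical replicates with
Gaussian Ct noise.

What it does not emulate: chromatogram-level artefacts, indels,
PCR/cloning bias between alleles, heterozygous parents, maternal seed
coat RNA in dissected tissue, or linkage to flanking genomic context.
Passing tests therefore demonstrate the *analysis* is correct under its
stated sampling model, not that the wet-lab steps are robust.

All randomness flows from one integer seed through CRC-keyed
`SeedSequence` children, so any sample can be regenerated in isolation
and whole runs are byte-identical. Clone-origin streams are keyed by
direction *index*, so regenerating with the parents listed in the
opposite order swaps maternal/paternal ground-truth labels exactly —
a property the tests exercise.

### The packaged fixture

`make_paper_fixture` (fixed documented seed `FIXTURE_SEED = 1203800`)
mirrors the published candidate-gene funnel: 15 query proteins (one,
the MEA analogue, without homolog; one with two paralogous subjects and
one with three), a proteome of 17 subjects plus 5 unrelated decoys,
17 candidate genes of which 10 carry no parental SNPs and 7 carry
(1, 2, 19, 17, 3, 11, 2) planted SNPs, 5 of those MEG in endosperm and
all biallelic in embryo, plus qPCR plates for the 5 MEGs
(endosperm-enriched fold changes against a leaf calibrator).

Fixture queries are 15%-diverged copies of their subjects — far beyond
chance similarity for any seed — and fixture *hybrid* samples use
engineered clone counts (the rounded expectation: a biallelic endosperm
sample of 20 clones has exactly 13 maternal) rather than Bernoulli
draws. The fixture is a regression artifact whose funnel counts must be
reproduced deterministically; free-running simulations via
`SimulationConfig` always sample stochastically.

## Problem sizes and numerics

Default suite sizes: exhaustive classifier verification at n = 20
clones per direction (53,361 count tables per tissue); binomial
convergence and false-positive calibration at 10,000 draws within 3
binomial SE; SNP round-trips over 100 random gene specs of 50–500 nt;
brute-force alignment oracles on sequences of length ≤ 6 (exhaustive
path enumeration is exponential). These sizes make every check exact or
3-SE-bounded while keeping the whole suite under a minute of compute.

## Known limitations

- E-value calibration is nominal (ungapped constants on gapped scores).
- Similarity percentages depend on alignment parameters; published
  similarity tables produced by other tools are reference values, not
  reproduction targets.
- The classifier is the published threshold rule, not a statistical
  test; the binomial machinery here quantifies the rule's error rates
  but never replaces it.
- Single-reference qPCR normalisation with perfect efficiency assumed.
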