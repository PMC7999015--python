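"""From parental clone reads to imprinting calls.

For each fixture gene: build per-parent consensus sequences from 20
cloned reads, call pure parent-distinguishing SNP sites, genotype the
hybrid endosperm/embryo clones of both reciprocal cross directions at
those sites, and classify each gene as MEG / PEG / biallelic.
"""

from fvimprint import call_snps, classify_all, count_alleles, make_paper_fixture

fixture = make_paper_fixture()
parent_a, parent_b = fixture.config.parents

snps = {
    gene: call_snps(
        fixture.parent_reads[(gene, parent_a)],
        fixture.parent_reads[(gene, parent_b)],
    )
    for gene in fixture.gene_ids
}
informative = {g: s for g, s in snps.items() if s}
print(f"{len(snps) - len(informative)} of {len(snps)} candidates have no "
      f"parental SNPs (uninformative)")
print("SNP sites per informative gene:",
      {g: len(s) for g, s in informative.items()})

counts = [
    count_alleles(read_set, snps[gene], tissue, direction,
                  a_is_maternal=direction[0] == parent_a)
    for (gene, tissue, direction), read_set in fixture.hybrid_reads.items()
    if snps[gene]
]
result = classify_all(counts)
print()
print(f"{'gene':<10}{'tissue':<11}{'call':<11}{'m:p dir1':>9}{'m:p dir2':>9}")
for call in result.calls:
    print(f"{call.gene_id:<10}{call.tissue:<11}{call.call:<11}"
          f"{call.ratio_dir1:>9.2f}{call.ratio_dir2:>9.2f}")
print()
print("summary:", result.summary)
# A MEG needs the maternal allele above 4:1 in BOTH reciprocal
# directions of the endosperm (the biallelic expectation there is 2:1
# because the endosperm is triploid); embryo calls use a symmetric 3:1
# rule around its 1:1 expectation.
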