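"""Parental SNP discovery from cloned-sequence reads.

Each parent of a cross is represented by a set of cloned, Sanger-sequenced
reads of one gene's CDS.  A per-parent consensus is built by per-column
plurality vote; a site is *pure* when the plurality fraction reaches the
purity threshold (1.0 by default: every clone agrees).  SNP sites are the
positions where the two parental consensuses carry different bases and both
parents are pure — only such sites can tell the parental alleles apart in
hybrid tissue.

Coordinates are 1-based on the parent-A consensus, with gap columns of the
consensus-consensus alignment excluded from numbering.  Indel columns are
never called (substitutions only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from biotite.sequence import NucleotideSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

__all__ = [
    "CloneReadSet",
    "SnpSite",
    "consensus",
    "call_snps",
    "genotype_clone",
]

_NT_ALPHABET = set("ACGTN")

# Allele labels used throughout: the read carries parent A's base, parent
# B's base, or something else entirely (sequencing error / third allele).
ALLELE_A = "A-allele"
ALLELE_B = "B-allele"
UNKNOWN = "unknown"


@dataclass
class CloneReadSet:
    """Cloned reads of one gene from one sample (parent or hybrid tissue).

    ``origins`` is simulator ground truth ("maternal"/"paternal" per clone);
    it is absent for real data and never consulted by the callers here.
    """

    gene_id: str
    sample_label: str
    reads: list[str]
    origins: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError(
                f"{self.gene_id}/{self.sample_label}: empty clone read set"
            )
        self.reads = [r.upper() for r in self.reads]
        for k, read in enumerate(self.reads):
            bad = set(read) - _NT_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.gene_id}/{self.sample_label} clone {k}: "
                    f"invalid symbols {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class SnpSite:
    """A parent-distinguishing, purity-passing position on the CDS."""

    gene_id: str
    position: int  # 1-based on the parent-A consensus
    base_a: str
    base_b: str
    purity_a: float
    purity_b: float

    def __post_init__(self) -> None:
        if self.base_a == self.base_b:
            raise ValueError(f"{self.gene_id} pos {self.position}: bases equal")


@dataclass
class Consensus:
    """Plurality consensus with per-site purity and tie flags."""

    sequence: str
    purity: np.ndarray
    tie: np.ndarray  # True where the plurality base was not unique

    def __len__(self) -> int:
        return len(self.sequence)


def _reconcile_lengths(reads: list[str]) -> list[str]:
    """Bring reads to a common length.

    Clone reads are assumed full-length and co-linear; a rare indel-bearing
    read is reconciled by global alignment to the longest read, dropping its
    insertions and padding its deletions with N.
    """
    target = max(reads, key=len)
    if all(len(r) == len(target) for r in reads):
        return reads
    matrix = SubstitutionMatrix.std_nucleotide_matrix()
    ref = NucleotideSequence(target.replace("N", "A"))
    fixed = []
    for read in reads:
        if len(read) == len(target):
            fixed.append(read)
            continue
        aln = align_optimal(
            ref,
            NucleotideSequence(read.replace("N", "A")),
            matrix,
            gap_penalty=(-10, -1),
            local=False,
        )[0]
        out = ["N"] * len(target)
        for i, j in aln.trace:
            if i != -1 and j != -1:
                out[i] = read[j]
        fixed.append("".join(out))
    return fixed


def consensus(read_set: CloneReadSet) -> Consensus:
    """Per-column plurality consensus of a clone read set.

    Purity is the plurality fraction (N calls excluded from the vote but
    counted in the denominator).  Ties break alphabetically and flag the
    column as impure so it can never pass a strict purity threshold.
    """
    reads = _reconcile_lengths(read_set.reads)
    arr = np.array([list(r) for r in reads])
    n_reads, length = arr.shape
    seq = []
    purity = np.zeros(length)
    tie = np.zeros(length, dtype=bool)
    for col in range(length):
        bases, counts = np.unique(arr[:, col], return_counts=True)
        keep = bases != "N"
        bases, counts = bases[keep], counts[keep]
        if bases.size == 0:
            seq.append("N")
            continue
        top = counts.max()
        winners = bases[counts == top]
        seq.append(sorted(winners)[0])  # alphabetical tie-break
        purity[col] = top / n_reads
        if winners.size > 1:
            tie[col] = True
            purity[col] = 0.0  # a tied column is never pure
    return Consensus("".join(seq), purity, tie)


def call_snps(
    parent_a: CloneReadSet,
    parent_b: CloneReadSet,
    purity_threshold: float = 1.0,
) -> list[SnpSite]:
    """Pure parent-distinguishing SNP sites between two parents' clone sets.

    A gene with an empty result is *uninformative*: its parents cannot be
    told apart in hybrid tissue.  Indel columns between the consensuses are
    skipped; numbering follows parent A's bases.
    """
    if parent_a.gene_id != parent_b.gene_id:
        raise ValueError(
            f"gene mismatch: {parent_a.gene_id!r} vs {parent_b.gene_id!r}"
        )
    cons_a = consensus(parent_a)
    cons_b = consensus(parent_b)
    gene = parent_a.gene_id
    if len(cons_a) == len(cons_b):
        pairs = [(i, i) for i in range(len(cons_a))]
    else:
        matrix = SubstitutionMatrix.std_nucleotide_matrix()
        try:
            aln = align_optimal(
                NucleotideSequence(cons_a.sequence.replace("N", "A")),
                NucleotideSequence(cons_b.sequence.replace("N", "A")),
                matrix,
                gap_penalty=(-10, -1),
                local=False,
            )[0]
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"{gene}: parental consensuses not alignable") from exc
        pairs = [(i, j) for i, j in aln.trace if i != -1 and j != -1]
    sites = []
    for i, j in pairs:
        base_a, base_b = cons_a.sequence[i], cons_b.sequence[j]
        if base_a == base_b or "N" in (base_a, base_b):
            continue
        if cons_a.purity[i] < purity_threshold or cons_b.purity[j] < purity_threshold:
            continue
        sites.append(
            SnpSite(
                gene_id=gene,
                position=i + 1,
                base_a=base_a,
                base_b=base_b,
                purity_a=float(cons_a.purity[i]),
                purity_b=float(cons_b.purity[j]),
            )
        )
    return sites


def genotype_clone(read: str, snps: list[SnpSite]) -> list[str]:
    """Assign a clone read to a parental allele at every SNP site.

    Returns one of ``"A-allele"``, ``"B-allele"`` or ``"unknown"`` per site
    (a third base, an N, or a position beyond the read is unknown — data,
    not an error).
    """
    read = read.upper()
    calls = []
    for site in snps:
        idx = site.position - 1
        base = read[idx] if idx < len(read) else "N"
        if base == site.base_a:
            calls.append(ALLELE_A)
        elif base == site.base_b:
            calls.append(ALLELE_B)
        else:
            calls.append(UNKNOWN)
    return calls
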