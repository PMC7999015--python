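"""Parent-of-origin classification of hybrid allele counts.

In a reciprocal cross the same two parents are crossed in both directions,
so a genuinely imprinted gene must favour the *parental role* (maternal or
paternal) in both directions, while a fixed allelic bias favours the same
*nucleotide allele* and therefore switches roles between directions.

Under biallelic expression the expected maternal:paternal ratio is 2:1 in
triploid endosperm (two maternal genomes, one paternal) and 1:1 in diploid
embryo.  Calls use strict ratio thresholds on clone counts:

* endosperm — MEG if m/p > 4 in both directions; PEG if p/m > 2 in both
  (the endosperm rules are deliberately asymmetric around the 2:1 prior);
* embryo — MEG if m/p > 3 in both directions; PEG if p/m > 3 in both.

A sample with fewer informative clones than ``min_informative`` (clones
whose allele could be assigned to a parent) is uninformative.  Everything
that clears the informativeness bar and no threshold is biallelic.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .snps import ALLELE_A, ALLELE_B, SnpSite, genotype_clone

__all__ = [
    "AlleleCountTable",
    "ImprintCall",
    "Thresholds",
    "ratio",
    "classify_tissue",
    "classify_all",
    "count_alleles",
    "counts_from_fraction",
    "brute_force_oracle",
]

TISSUES = ("endosperm", "embryo")

MEG = "MEG"
PEG = "PEG"
BIALLELIC = "BIALLELIC"
ALLELIC_BIAS = "ALLELIC_BIAS"
UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class Thresholds:
    """Strict ratio thresholds ("higher than"), per tissue."""

    endosperm_meg: float = 4.0  # m/p must exceed this in both directions
    endosperm_peg: float = 2.0  # p/m must exceed this in both directions
    embryo: float = 3.0  # symmetric 3:1 rule for embryo MEG and PEG

    def for_tissue(self, tissue: str) -> tuple[float, float]:
        if tissue == "endosperm":
            return self.endosperm_meg, self.endosperm_peg
        if tissue == "embryo":
            return self.embryo, self.embryo
        raise ValueError(f"unknown tissue {tissue!r}")


@dataclass(frozen=True)
class AlleleCountTable:
    """Maternal/paternal clone counts for one gene x tissue x direction.

    ``direction`` is the ordered (maternal parent, paternal parent) pair.
    """

    gene_id: str
    tissue: str
    direction: tuple[str, str]
    m_count: int
    p_count: int
    unknown_count: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if min(self.m_count, self.p_count, self.unknown_count) < 0:
            raise ValueError("negative count")

    @property
    def informative(self) -> int:
        return self.m_count + self.p_count


@dataclass(frozen=True)
class ImprintCall:
    """Per-gene, per-tissue verdict with the two directional m/p ratios."""

    gene_id: str
    tissue: str
    call: str
    ratio_dir1: float
    ratio_dir2: float
    flags: str = ""


def ratio(m_count: int, p_count: int) -> float:
    """Maternal:paternal expression ratio; monoallelic maternal is +inf."""
    if m_count == 0 and p_count == 0:
        raise ValueError("no informative clones: uninformative sample")
    if p_count == 0:
        return math.inf
    return m_count / p_count


def _exceeds(num: int, den: int, threshold: float) -> bool:
    """Strictly ``num/den > threshold`` with num/0 = +inf (num > 0)."""
    if den == 0:
        return num > 0
    return num / den > threshold


def classify_tissue(
    counts_dir1: AlleleCountTable,
    counts_dir2: AlleleCountTable,
    tissue: str,
    thresholds: Thresholds | None = None,
    min_informative: int = 5,
) -> ImprintCall:
    """Classify one gene in one tissue from both reciprocal directions.

    MEG/PEG require the threshold to hold in BOTH directions (parental
    role consistent).  If instead one fixed nucleotide allele clears the
    role-appropriate threshold in both directions, the gene shows an
    allelic bias, not imprinting.
    """
    thresholds = thresholds or Thresholds()
    if counts_dir1.tissue != tissue or counts_dir2.tissue != tissue:
        raise ValueError(
            f"{counts_dir1.gene_id}: tissue mismatch "
            f"({counts_dir1.tissue}/{counts_dir2.tissue} vs {tissue})"
        )
    if counts_dir1.gene_id != counts_dir2.gene_id:
        raise ValueError("gene mismatch between directions")
    meg_t, peg_t = thresholds.for_tissue(tissue)
    gene = counts_dir1.gene_id
    m1, p1 = counts_dir1.m_count, counts_dir1.p_count
    m2, p2 = counts_dir2.m_count, counts_dir2.p_count

    if counts_dir1.informative < min_informative or counts_dir2.informative < min_informative:
        return ImprintCall(gene, tissue, UNINFORMATIVE, math.nan, math.nan,
                           flags="informative clones below minimum")

    r1 = ratio(m1, p1)
    r2 = ratio(m2, p2)
    if _exceeds(m1, p1, meg_t) and _exceeds(m2, p2, meg_t):
        call = MEG
    elif _exceeds(p1, m1, peg_t) and _exceeds(p2, m2, peg_t):
        call = PEG
    elif (_exceeds(m1, p1, meg_t) and _exceeds(p2, m2, peg_t)) or (
        _exceeds(p1, m1, peg_t) and _exceeds(m2, p2, meg_t)
    ):
        # the same nucleotide allele dominates both directions: the
        # maternal allele of one direction is the paternal allele of the
        # reciprocal one
        call = ALLELIC_BIAS
    else:
        call = BIALLELIC
    return ImprintCall(gene, tissue, call, r1, r2)


def count_alleles(
    read_set,
    snps: list[SnpSite],
    tissue: str,
    direction: tuple[str, str],
    a_is_maternal: bool,
) -> AlleleCountTable:
    """Aggregate clone genotypes into a maternal/paternal count table.

    Each clone votes once: its allele is the majority call across the
    gene's SNP sites (sites on one clone are fully linked), with ties or
    all-unknown clones counted as unknown.
    """
    m = p = unk = 0
    for read in read_set.reads:
        calls = Counter(genotype_clone(read, snps))
        a, b = calls[ALLELE_A], calls[ALLELE_B]
        if a == b:  # includes all-unknown
            unk += 1
            continue
        is_a = a > b
        maternal = is_a == a_is_maternal
        if maternal:
            m += 1
        else:
            p += 1
    return AlleleCountTable(
        gene_id=read_set.gene_id,
        tissue=tissue,
        direction=direction,
        m_count=m,
        p_count=p,
        unknown_count=unk,
    )


def counts_from_fraction(
    gene_id: str,
    tissue: str,
    direction: tuple[str, str],
    maternal_fraction: float,
    effective_n: int,
) -> AlleleCountTable:
    """Convert a maternal-allele fraction (e.g. densitometry peak ratio)
    plus an effective sample size into an integer count table."""
    if not 0.0 <= maternal_fraction <= 1.0:
        raise ValueError("maternal_fraction outside [0, 1]")
    m = round(maternal_fraction * effective_n)
    return AlleleCountTable(gene_id, tissue, direction, m, effective_n - m)


@dataclass
class ClassificationResult:
    calls: list[ImprintCall]
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": c.gene_id,
                "tissue": c.tissue,
                "call": c.call,
                "ratio_dir1": c.ratio_dir1,
                "ratio_dir2": c.ratio_dir2,
                "flags": c.flags,
            }
            for c in self.calls
        )


def classify_all(
    counts: list[AlleleCountTable],
    thresholds: Thresholds | None = None,
    min_informative: int = 5,
) -> ClassificationResult:
    """One call per gene per tissue, plus per-tissue summary counts.

    A gene/tissue missing one reciprocal direction is flagged
    uninformative rather than dropped.
    """
    thresholds = thresholds or Thresholds()
    grouped: dict[tuple[str, str], dict[tuple[str, str], AlleleCountTable]] = {}
    for table in counts:
        grouped.setdefault((table.gene_id, table.tissue), {})[table.direction] = table
    calls = []
    for (gene, tissue), by_dir in sorted(grouped.items()):
        if len(by_dir) < 2:
            calls.append(
                ImprintCall(gene, tissue, UNINFORMATIVE, math.nan, math.nan,
                            flags="missing reciprocal direction")
            )
            continue
        dir1, dir2 = sorted(by_dir)
        calls.append(
            classify_tissue(
                by_dir[dir1], by_dir[dir2], tissue, thresholds, min_informative
            )
        )
    summary = {
        tissue: dict(Counter(c.call for c in calls if c.tissue == tissue))
        for tissue in TISSUES
    }
    return ClassificationResult(calls, summary)


def brute_force_oracle(
    n_clones: int,
    tissue: str,
    thresholds: Thresholds | None = None,
    min_informative: int = 5,
) -> dict[tuple[int, int, int, int], str]:
    """Exhaustive reference classifier over all count tables.

    Enumerates every (m1, p1, m2, p2) with m+p <= n_clones per direction
    and applies the threshold rules verbatim using exact integer
    arithmetic (``m > t*p`` instead of division), independently of
    :func:`classify_tissue`.  Intended as a test oracle; n_clones <= 30.
    """
    if n_clones > 30:
        raise ValueError("oracle is exhaustive; keep n_clones <= 30")
    thresholds = thresholds or Thresholds()
    meg_t, peg_t = thresholds.for_tissue(tissue)
    pairs = [
        (m, p)
        for m in range(n_clones + 1)
        for p in range(n_clones + 1 - m)
    ]
    out = {}
    for (m1, p1), (m2, p2) in itertools.product(pairs, pairs):
        if m1 + p1 < min_informative or m2 + p2 < min_informative:
            call = UNINFORMATIVE
        elif m1 > meg_t * p1 and m2 > meg_t * p2:
            call = MEG
        elif p1 > peg_t * m1 and p2 > peg_t * m2:
            call = PEG
        elif (m1 > meg_t * p1 and p2 > peg_t * m2) or (
            p1 > peg_t * m1 and m2 > meg_t * p2
        ):
            call = ALLELIC_BIAS
        else:
            call = BIALLELIC
        out[(m1, p1, m2, p2)] = call
    return out
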