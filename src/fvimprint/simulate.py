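"""Synthetic reciprocal-cross data with known ground truth.

The generator emulates the experimental design the pipeline analyses: two
inbred parental ecotypes whose CDS differ by planted SNPs, reciprocal F1
crosses, and clone sampling from triploid endosperm (two maternal genome
copies to one paternal, so a biallelic gene yields maternal clones with
probability 2/3) and diploid embryo (probability 1/2).  Clone origin is
i.i.d. Bernoulli per clone, optionally overdispersed (beta-binomial) to
mimic maternal-tissue contamination; per-base read errors are independent
substitutions at a configurable rate (0 by default, so planted truth is
exactly recoverable).

All randomness flows from a single integer seed through keyed
sub-generators, so identical configurations produce byte-identical
output and individual samples can be regenerated in isolation.

``make_paper_fixture`` builds a fixed bundle mirroring a published
candidate-gene funnel: 15 query proteins of which one has no homolog, a
proteome yielding 17 hits (one query with two subjects, one with three),
10 candidate genes with no parental SNPs and 7 informative ones with
planted SNP counts (1, 2, 19, 17, 3, 11, 2), five of them maternally
expressed in endosperm only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .homology import ProteinRecord
from .snps import CloneReadSet

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "make_parental_haplotypes",
    "sample_clone_reads",
    "simulate_qpcr",
    "make_paper_fixture",
    "PaperFixture",
    "FIXTURE_SEED",
]

NUCLEOTIDES = np.array(list("ACGT"))
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
TISSUES = ("endosperm", "embryo")

MEG = "MEG"
PEG = "PEG"
BIALLELIC = "BIALLELIC"

# Expected maternal fraction under biallelic expression, by tissue ploidy:
# endosperm is triploid (2m:1p genomes), embryo diploid (1m:1p).
BIALLELIC_FRACTIONS = {"endosperm": 2.0 / 3.0, "embryo": 0.5}

# Fixed, documented seed of the packaged paper fixture.
FIXTURE_SEED = 1203800


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Keyed child generator: deterministic, order-independent streams."""
    key = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth description of one simulated gene.

    ``maternal_fraction_*`` is the probability that a sampled hybrid clone
    is of maternal origin; defaults follow the imprint state (MEG 1.0,
    PEG 0.0, biallelic the ploidy expectation) and can be overridden for
    partial imprinting.
    """

    gene_id: str
    cds_length: int
    n_snps: int
    imprint_state: str = BIALLELIC
    maternal_fraction_endosperm: float | None = None
    maternal_fraction_embryo: float | None = None

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError(f"{self.gene_id}: cds_length must be positive")
        if not 0 <= self.n_snps <= self.cds_length:
            raise ValueError(
                f"{self.gene_id}: n_snps {self.n_snps} exceeds CDS length "
                f"{self.cds_length}"
            )
        if self.imprint_state not in (MEG, PEG, BIALLELIC):
            raise ValueError(f"{self.gene_id}: unknown state {self.imprint_state!r}")
        for frac in (self.maternal_fraction_endosperm, self.maternal_fraction_embryo):
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ValueError(f"{self.gene_id}: maternal fraction outside [0,1]")

    def maternal_fraction(self, tissue: str) -> float:
        if tissue == "endosperm":
            override = self.maternal_fraction_endosperm
        elif tissue == "embryo":
            override = self.maternal_fraction_embryo
        else:
            raise ValueError(f"unknown tissue {tissue!r}")
        if override is not None:
            return override
        if self.imprint_state == MEG:
            return 1.0 if tissue == "endosperm" else BIALLELIC_FRACTIONS[tissue]
        if self.imprint_state == PEG:
            return 0.0 if tissue == "endosperm" else BIALLELIC_FRACTIONS[tissue]
        return BIALLELIC_FRACTIONS[tissue]


@dataclass(frozen=True)
class SimulationConfig:
    """One reciprocal cross: parents, genes, sampling depth, error rate.

    ``overdispersion_rho`` > 0 switches clone-origin sampling from
    Bernoulli(f) to a beta-binomial mixture (the per-sample maternal
    fraction is drawn from Beta with mean f and intra-class correlation
    rho), emulating maternal-tissue contamination.
    """

    seed: int
    genes: tuple[GeneSpec, ...]
    parents: tuple[str, str] = ("10-41", "18-86")
    clones_per_sample: int = 20
    per_base_read_error: float = 0.0
    overdispersion_rho: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if self.clones_per_sample <= 0:
            raise ValueError("clones_per_sample must be positive")
        if not 0.0 <= self.per_base_read_error < 1.0:
            raise ValueError("per_base_read_error must be in [0, 1)")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must be in [0, 1)")

    @property
    def cross_directions(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """Both reciprocal (maternal, paternal) orientations, always."""
        a, b = self.parents
        return ((a, b), (b, a))

    def gene(self, gene_id: str) -> GeneSpec:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _random_cds(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(NUCLEOTIDES, size=length)


def make_parental_haplotypes(
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Parental CDS pair per gene, differing at exactly ``n_snps`` sites.

    Returns ``(haplotypes, manifest)``: haplotypes maps gene_id to
    {parent_name: sequence} in ``config.parents`` order; the manifest
    records the planted truth with 1-based positions and the base carried
    by each parent.
    """
    parent_a, parent_b = config.parents
    haplotypes: dict[str, dict[str, str]] = {}
    rows = []
    for gene in config.genes:
        rng = _rng(config.seed, "haplotype", gene.gene_id)
        seq_a = _random_cds(rng, gene.cds_length)
        seq_b = seq_a.copy()
        positions = np.sort(
            rng.choice(gene.cds_length, size=gene.n_snps, replace=False)
        )
        for pos in positions:
            alternatives = NUCLEOTIDES[NUCLEOTIDES != seq_a[pos]]
            seq_b[pos] = rng.choice(alternatives)
            rows.append(
                {
                    "gene": gene.gene_id,
                    "position": int(pos) + 1,
                    parent_a: str(seq_a[pos]),
                    parent_b: str(seq_b[pos]),
                }
            )
        haplotypes[gene.gene_id] = {
            parent_a: "".join(seq_a),
            parent_b: "".join(seq_b),
        }
    manifest = pd.DataFrame(rows, columns=["gene", "position", parent_a, parent_b])
    return haplotypes, manifest


def _apply_read_errors(
    read: str, rate: float, rng: np.random.Generator
) -> str:
    if rate == 0.0:
        return read
    arr = np.array(list(read))
    hit = rng.random(arr.size) < rate
    for idx in np.nonzero(hit)[0]:
        arr[idx] = rng.choice(NUCLEOTIDES[NUCLEOTIDES != arr[idx]])
    return "".join(arr)


def parental_clone_reads(
    gene: GeneSpec, parent: str, config: SimulationConfig,
    haplotypes: dict[str, dict[str, str]],
) -> CloneReadSet:
    """Clone reads of one parent's own leaves: copies of its haplotype."""
    if parent not in config.parents:
        raise ValueError(f"unknown parent {parent!r}")
    rng = _rng(config.seed, "parent-reads", gene.gene_id, parent)
    hap = haplotypes[gene.gene_id][parent]
    reads = [
        _apply_read_errors(hap, config.per_base_read_error, rng)
        for _ in range(config.clones_per_sample)
    ]
    return CloneReadSet(gene.gene_id, f"parent|{parent}", reads)


def sample_clone_reads(
    gene: GeneSpec,
    tissue: str,
    direction: tuple[str, str],
    config: SimulationConfig,
    haplotypes: dict[str, dict[str, str]],
    n_clones: int | None = None,
    exact_counts: bool = False,
) -> CloneReadSet:
    """Sample hybrid-tissue clone reads for one cross direction.

    Each clone is a full-length copy of the maternal or paternal parent's
    haplotype; origin is Bernoulli with the gene's maternal fraction for
    the tissue (beta-binomial when overdispersion is configured).  With
    ``exact_counts`` the maternal count is fixed to round(f * n) and only
    the clone order is randomised — used by the engineered fixture.
    Ground-truth origins are kept on the returned read set.
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}")
    directions = config.cross_directions
    if tuple(direction) not in directions:
        raise ValueError(f"unknown cross direction {direction!r}")
    dir_index = directions.index(tuple(direction))
    maternal_parent, paternal_parent = direction
    n = n_clones if n_clones is not None else config.clones_per_sample
    fraction = gene.maternal_fraction(tissue)
    rng = _rng(config.seed, "hybrid-reads", gene.gene_id, tissue, dir_index)
    if exact_counts:
        n_maternal = round(fraction * n)
        origins = np.array(
            ["maternal"] * n_maternal + ["paternal"] * (n - n_maternal)
        )
        rng.shuffle(origins)
    else:
        if config.overdispersion_rho > 0 and 0 < fraction < 1:
            rho = config.overdispersion_rho
            conc = (1 - rho) / rho
            fraction = rng.beta(fraction * conc, (1 - fraction) * conc)
        origins = np.where(rng.random(n) < fraction, "maternal", "paternal")
    haps = haplotypes[gene.gene_id]
    reads = [
        _apply_read_errors(
            haps[maternal_parent if o == "maternal" else paternal_parent],
            config.per_base_read_error,
            rng,
        )
        for o in origins
    ]
    label = f"{tissue}|{maternal_parent}x{paternal_parent}"
    return CloneReadSet(gene.gene_id, label, reads, origins=list(origins))


def simulate_qpcr(
    gene_id: str,
    fold_by_tissue: dict[str, float],
    calibrator_tissue: str,
    seed: int,
    n_bio_reps: int = 3,
    n_tech_reps: int = 4,
    noise_sd: float = 0.0,
    reference_ct: float = 20.0,
    base_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Simulated Ct table for one gene against a reference gene.

    True relative expression of each tissue versus the calibrator is
    ``fold_by_tissue[tissue] / fold_by_tissue[calibrator]``; Gaussian
    technical noise (sd in Ct units) is added independently to target and
    reference wells.  Layout: ``n_bio_reps`` x ``n_tech_reps`` per tissue.
    """
    if calibrator_tissue not in fold_by_tissue:
        raise ValueError(f"calibrator {calibrator_tissue!r} missing from folds")
    for tissue, fold in fold_by_tissue.items():
        if fold <= 0:
            raise ValueError(f"{tissue}: fold change must be positive, got {fold}")
    rng = _rng(seed, "qpcr", gene_id)
    rows = []
    for tissue in fold_by_tissue:
        # dCt is offset by -log2(fold): doubling expression lowers Ct by 1
        true_dct = base_delta_ct - np.log2(fold_by_tissue[tissue])
        for bio in range(1, n_bio_reps + 1):
            for tech in range(1, n_tech_reps + 1):
                ref = reference_ct + rng.normal(0.0, noise_sd) if noise_sd else reference_ct
                tgt = reference_ct + true_dct + (
                    rng.normal(0.0, noise_sd) if noise_sd else 0.0
                )
                rows.append(
                    {
                        "gene": gene_id,
                        "tissue": tissue,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "ct_target": tgt,
                        "ct_reference": ref,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The packaged paper fixture
# ---------------------------------------------------------------------------

# Candidate-gene funnel: 10 genes with no parental SNPs, 7 informative.
SNPLESS_GENES = (
    "FvFIE", "FvYLS9", "FvMLP", "FvUNP", "FvKH",
    "FvVIP2", "FvYLS3", "FvUNP1", "FvMIA40", "FvAMI",
)
# gene -> (planted SNP count, endosperm state); all genes biallelic in embryo
INFORMATIVE_GENES = {
    "FvARI8": (1, MEG),
    "FvBRO1": (2, MEG),
    "FvKHDP-2": (19, MEG),
    "FvDRIP2": (17, MEG),
    "FvLTP3": (3, MEG),
    "FvTAR4": (11, BIALLELIC),
    "FvCAL": (2, BIALLELIC),
}
ENDOSPERM_MEGS = tuple(g for g, (_, s) in INFORMATIVE_GENES.items() if s == MEG)

# query -> candidate subject genes; one query deliberately without homolog
# and two with multiple subjects (paralogous candidates).
QUERY_MAP: dict[str, tuple[str, ...]] = {
    "AtMEA": (),
    "AtFIE": ("FvFIE",),
    "AtYLS9": ("FvYLS9",),
    "AtMLP": ("FvMLP",),
    "AtUNP": ("FvUNP",),
    "AtARI8": ("FvARI8",),
    "AtKH": ("FvKH",),
    "AtCAL": ("FvCAL",),
    "AtMIA40": ("FvMIA40",),
    "AtAMI": ("FvAMI",),
    "AtTAR4": ("FvTAR4",),
    "AtVIP2": ("FvVIP2",),
    "AtKHDP2": ("FvKHDP-2",),
    "AT1G62790": ("FvYLS3", "FvLTP3"),
    "AT3G49540": ("FvDRIP2", "FvBRO1", "FvUNP1"),
}

QPCR_TISSUES = ("leaf", "root", "endosperm", "embryo")
QPCR_CALIBRATOR = "leaf"
# true fold changes vs leaf for the five endosperm MEGs (endosperm-enriched)
QPCR_FOLDS = {"leaf": 1.0, "root": 0.5, "endosperm": 8.0, "embryo": 2.0}


@dataclass
class PaperFixture:
    """In-memory bundle of the packaged reciprocal-cross study fixture."""

    seed: int
    config: SimulationConfig
    queries: list[ProteinRecord]
    proteome: list[ProteinRecord]
    haplotypes: dict[str, dict[str, str]]
    snp_manifest: pd.DataFrame
    parent_reads: dict[tuple[str, str], CloneReadSet]  # (gene, parent)
    hybrid_reads: dict[tuple[str, str, tuple[str, str]], CloneReadSet]
    ct_table: pd.DataFrame
    truth: pd.DataFrame = field(default=None)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.config.genes]

    def write(self, outdir) -> None:
        """Write the bundle as FASTA/TSV files under ``outdir``."""
        from . import io as fio

        fio.write_fixture(self, outdir)


def _mutate_protein(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(out.size) < rate
    for idx in np.nonzero(hit)[0]:
        out[idx] = rng.choice(AMINO_ACIDS[AMINO_ACIDS != out[idx]])
    return out


def _fixture_proteins(
    seed: int,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """15 queries and a proteome yielding exactly 17 confident hits.

    Each subject is a 15%-diverged copy of its query's family sequence,
    far above chance similarity; decoys and the homolog-less query are
    unrelated random sequences, far below the E-value cutoff.
    """
    rng = _rng(seed, "proteins")
    queries, proteome = [], []
    for query_id, subjects in QUERY_MAP.items():
        length = int(rng.integers(150, 420))
        family = rng.choice(AMINO_ACIDS, size=length)
        queries.append(ProteinRecord(query_id, "".join(family)))
        for subject_id in subjects:
            diverged = _mutate_protein(family, 0.15, rng)
            proteome.append(ProteinRecord(subject_id, "".join(diverged)))
    for k in range(5):  # unrelated decoys
        length = int(rng.integers(150, 420))
        proteome.append(
            ProteinRecord(f"XP_DECOY_{k + 1}", "".join(rng.choice(AMINO_ACIDS, length)))
        )
    return queries, proteome


def make_paper_fixture(seed: int = FIXTURE_SEED) -> PaperFixture:
    """Build the fixed study fixture mirroring the candidate-gene funnel.

    Hybrid clone sampling is *engineered*: maternal counts are the rounded
    expectation for each gene's state (e.g. a biallelic endosperm sample of
    20 clones has exactly 13 maternal), so the downstream funnel counts are
    reproduced deterministically for any seed.
    """
    genes = []
    rng = _rng(seed, "gene-lengths")
    for gene_id in SNPLESS_GENES:
        genes.append(
            GeneSpec(gene_id, int(rng.integers(300, 900)), 0, BIALLELIC)
        )
    for gene_id, (n_snps, state) in INFORMATIVE_GENES.items():
        genes.append(
            GeneSpec(gene_id, int(rng.integers(300, 900)), n_snps, state)
        )
    config = SimulationConfig(seed=seed, genes=tuple(genes))
    haplotypes, manifest = make_parental_haplotypes(config)

    parent_reads = {
        (gene.gene_id, parent): parental_clone_reads(gene, parent, config, haplotypes)
        for gene in config.genes
        for parent in config.parents
    }
    hybrid_reads = {}
    for gene_id in INFORMATIVE_GENES:
        gene = config.gene(gene_id)
        for tissue in TISSUES:
            for direction in config.cross_directions:
                hybrid_reads[(gene_id, tissue, direction)] = sample_clone_reads(
                    gene, tissue, direction, config, haplotypes, exact_counts=True
                )

    queries, proteome = _fixture_proteins(seed)

    ct_tables = [
        simulate_qpcr(
            gene_id,
            QPCR_FOLDS,
            QPCR_CALIBRATOR,
            seed=seed,
            noise_sd=0.1,
        )
        for gene_id in ENDOSPERM_MEGS
    ]
    ct_table = pd.concat(ct_tables, ignore_index=True)

    truth = pd.DataFrame(
        {
            "gene": g.gene_id,
            "cds_length": g.cds_length,
            "n_snps": g.n_snps,
            "endosperm_state": g.imprint_state,
            "maternal_fraction_endosperm": g.maternal_fraction("endosperm"),
            "maternal_fraction_embryo": g.maternal_fraction("embryo"),
        }
        for g in config.genes
    )
    return PaperFixture(
        seed=seed,
        config=config,
        queries=queries,
        proteome=proteome,
        haplotypes=haplotypes,
        snp_manifest=manifest,
        parent_reads=parent_reads,
        hybrid_reads=hybrid_reads,
        ct_table=ct_table,
        truth=truth,
    )
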