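"""End-to-end orchestration: screen -> SNPs -> counts -> calls -> qPCR.

``run_all`` chains the four analysis stages over either the packaged
study fixture or user-supplied files, writing one TSV per stage plus a
JSON summary of the candidate-gene funnel.  Any stage failure halts the
run with the stage name; outputs of completed stages are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as fio
from .classify import Thresholds, classify_all, count_alleles
from .homology import screen
from .qpcr import relative_expression
from .simulate import FIXTURE_SEED, TISSUES, make_paper_fixture
from .snps import call_snps

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "run_fixture"]


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline in one place.

    Defaults: E-value cutoff 1e-9, purity 1.0 (every clone must agree),
    minimum informative clones 5, endosperm MEG/PEG thresholds 4 and 2,
    embryo threshold 3.
    """

    outdir: Path
    seed: int = FIXTURE_SEED
    paper_fixture: bool = False
    queries: Path | None = None
    proteome: Path | None = None
    parent_dir: Path | None = None
    hybrid_dir: Path | None = None
    ct_table: Path | None = None
    e_cutoff: float = 1e-9
    purity_threshold: float = 1.0
    min_informative: int = 5
    thresholds: Thresholds = field(default_factory=Thresholds)
    calibrator_tissue: str = "leaf"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.e_cutoff <= 0 or not 0 < self.purity_threshold <= 1:
            raise ValueError("thresholds must be positive")
        if not self.paper_fixture and not (self.queries and self.proteome):
            raise ValueError("provide input paths or set paper_fixture=True")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return out

        return wrapper

    return deco


@dataclass
class PipelineResult:
    hits: object
    snps: dict
    counts: list
    calls: object
    expression: object
    summary: dict


def _load_inputs(config: PipelineConfig):
    if config.paper_fixture:
        fixture = make_paper_fixture(config.seed)
        parent_reads = fixture.parent_reads
        hybrid_reads = fixture.hybrid_reads
        return (
            fixture.queries,
            fixture.proteome,
            parent_reads,
            hybrid_reads,
            fixture.ct_table,
            fixture.config.parents,
        )
    queries = fio.read_protein_fasta(config.queries)
    proteome = fio.read_protein_fasta(config.proteome)
    parent_reads = {}
    parents = set()
    for path in sorted(Path(config.parent_dir).glob("*.fasta")):
        gene, parent = path.stem.split("__")
        parent_reads[(gene, parent)] = fio.read_clone_reads(path)
        parents.add(parent)
    hybrid_reads = {}
    if config.hybrid_dir:
        for path in sorted(Path(config.hybrid_dir).glob("*.fasta")):
            gene, tissue, cross = path.stem.split("__")
            direction = tuple(cross.split("x"))
            hybrid_reads[(gene, tissue, direction)] = fio.read_clone_reads(path)
    ct = fio.read_tsv(config.ct_table) if config.ct_table else None
    return queries, proteome, parent_reads, hybrid_reads, ct, tuple(sorted(parents))


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run the full discovery pipeline and write its report bundle."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    queries, proteome, parent_reads, hybrid_reads, ct, parents = _load_inputs(config)

    # stage 1: homology screen
    hits, not_found = _stage("screen")(screen)(queries, proteome, config.e_cutoff)
    hits_df = fio.hits_frame(hits)
    fio.write_tsv(hits_df, outdir / "hits.tsv")
    logger.info("screen: %d queries -> %d hits (%d without homolog)",
                len(queries), len(hits), len(not_found))

    # stage 2: parental SNP discovery on candidates with parent reads
    candidates = sorted(
        {h.subject_id for h in hits if any(g == h.subject_id for g, _ in parent_reads)}
    )
    snps_by_gene = {}
    for gene in candidates:
        parent_a, parent_b = parents
        sites = _stage("snps")(call_snps)(
            parent_reads[(gene, parent_a)],
            parent_reads[(gene, parent_b)],
            config.purity_threshold,
        )
        snps_by_gene[gene] = sites
    all_sites = [s for sites in snps_by_gene.values() for s in sites]
    fio.write_tsv(fio.snps_frame(all_sites), outdir / "snps.tsv")
    informative = sorted(g for g, s in snps_by_gene.items() if s)
    logger.info("snps: %d candidates -> %d informative", len(candidates),
                len(informative))

    # stage 3: allele counting in hybrid tissues (parent A allele = parents[0])
    counts = []
    for (gene, tissue, direction), read_set in sorted(hybrid_reads.items()):
        sites = snps_by_gene.get(gene, [])
        if not sites:
            continue
        counts.append(
            _stage("counts")(count_alleles)(
                read_set, sites, tissue, direction,
                a_is_maternal=(direction[0] == parents[0]),
            )
        )
    fio.write_tsv(fio.counts_frame(counts), outdir / "counts.tsv")

    # stage 4: imprinting calls
    result = _stage("classify")(classify_all)(
        counts, config.thresholds, config.min_informative
    )
    fio.write_tsv(result.to_frame(), outdir / "calls.tsv")

    # stage 5: qPCR relative expression (optional input)
    expr = None
    if ct is not None:
        expr = _stage("qpcr")(relative_expression)(ct, config.calibrator_tissue)
        fio.write_tsv(expr, outdir / "expr.tsv")

    summary = {
        "n_queries": len(queries),
        "queries_without_homolog": sorted(not_found),
        "candidates_found": len(hits),
        "snpless_candidates": len(candidates) - len(informative),
        "informative_genes": len(informative),
        "snps_per_gene": {g: len(s) for g, s in snps_by_gene.items()},
        "calls_per_tissue": {
            t: result.summary.get(t, {}) for t in TISSUES
        },
    }
    fio.write_json(summary, outdir / "summary.json")
    return PipelineResult(hits_df, snps_by_gene, counts, result, expr, summary)


def run_fixture(outdir, seed: int = FIXTURE_SEED) -> PipelineResult:
    """Convenience wrapper: run the pipeline on the packaged fixture."""
    return run_all(PipelineConfig(outdir=Path(outdir), seed=seed, paper_fixture=True))
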