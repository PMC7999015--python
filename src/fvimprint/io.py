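"""Shared readers and writers: FASTA via Biopython, TSV via pandas.

File dialects are fixed for bit-exact reproducibility: TSV with a header
row, UTF-8, '.' decimal, '\\n' line endings; FASTA wrapped at 60 columns.
Clone-read FASTA headers follow ``gene|sample|clone_k``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology import HomologHit, ProteinRecord
from .snps import CloneReadSet, SnpSite

FASTA_WRAP = 60


def read_protein_fasta(path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def _wrap(seq: str) -> str:
    return "\n".join(seq[i : i + FASTA_WRAP] for i in range(0, len(seq), FASTA_WRAP))


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs wrapped at 60 columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{_wrap(seq)}\n")


def write_clone_reads(read_set: CloneReadSet, path) -> None:
    write_fasta(
        [
            (f"{read_set.gene_id}|{read_set.sample_label}|clone_{k + 1}", read)
            for k, read in enumerate(read_set.reads)
        ],
        path,
    )


def read_clone_reads(path) -> CloneReadSet:
    """Read one gene-sample clone FASTA (headers ``gene|sample|clone_k``)."""
    reads, gene_id, sample = [], None, None
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed clone header {rec.id!r}")
        gene_id = parts[0]
        sample = "|".join(parts[1:-1])
        reads.append(str(rec.seq))
    if not reads:
        raise ValueError(f"{path}: no clone reads")
    return CloneReadSet(gene_id, sample, reads)


def write_tsv(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def hits_frame(hits: list[HomologHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": h.query_id,
            "subject": h.subject_id,
            "raw_score": h.raw_score,
            "bit_score": round(h.bit_score, 2),
            "e_value": f"{h.e_value:.3g}",
            "identity_pct": round(h.identity_pct, 2),
            "similarity_pct": round(h.similarity_pct, 2),
            "aligned_length": h.aligned_length,
        }
        for h in hits
    )


def snps_frame(sites: list[SnpSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": s.gene_id,
            "position": s.position,
            "base_a": s.base_a,
            "base_b": s.base_b,
            "purity_a": s.purity_a,
            "purity_b": s.purity_b,
        }
        for s in sites
    )


def counts_frame(tables) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": t.gene_id,
            "tissue": t.tissue,
            "direction": f"{t.direction[0]}x{t.direction[1]}",
            "m_count": t.m_count,
            "p_count": t.p_count,
            "unknown_count": t.unknown_count,
        }
        for t in tables
    )


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_fixture(fixture, outdir) -> None:
    """Write a :class:`~fvimprint.simulate.PaperFixture` bundle to disk."""
    outdir = Path(outdir)
    write_fasta([(q.id, q.sequence) for q in fixture.queries], outdir / "queries.faa")
    write_fasta(
        [(p.id, p.sequence) for p in fixture.proteome], outdir / "proteome.faa"
    )
    for (gene, parent), read_set in fixture.parent_reads.items():
        write_clone_reads(read_set, outdir / "parents" / f"{gene}__{parent}.fasta")
    origin_rows = []
    for (gene, tissue, direction), read_set in fixture.hybrid_reads.items():
        name = f"{gene}__{tissue}__{direction[0]}x{direction[1]}.fasta"
        write_clone_reads(read_set, outdir / "hybrids" / name)
        for k, origin in enumerate(read_set.origins):
            origin_rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "direction": f"{direction[0]}x{direction[1]}",
                    "clone": k + 1,
                    "origin": origin,
                }
            )
    write_tsv(fixture.snp_manifest, outdir / "truth" / "snps.tsv")
    write_tsv(fixture.truth, outdir / "truth" / "genes.tsv")
    write_tsv(pd.DataFrame(origin_rows), outdir / "truth" / "origins.tsv")
    write_tsv(fixture.ct_table, outdir / "qpcr" / "ct.tsv")
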