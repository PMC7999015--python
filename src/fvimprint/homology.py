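"""Protein homology screening by optimal pairwise alignment.

Candidate imprinted genes are found by aligning query proteins (known
imprinted genes from reference species) against a candidate proteome and
keeping subjects whose E-value falls below a cutoff.  The alignment is
exact Smith-Waterman with affine gap penalties (no heuristic seeding), so
the hit list is a deterministic function of the inputs.

Significance follows the Karlin-Altschul framework: a raw local score ``S``
is converted to a bit score ``bit = (lambda * S - ln K) / ln 2`` using
published ungapped BLOSUM62 constants, and the expected number of chance
hits in a search space of query length ``m`` times database length ``n`` is
``E = m * n * 2**-bit``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

__all__ = [
    "ProteinRecord",
    "HomologHit",
    "AlignmentScoring",
    "local_align",
    "percent_similarity",
    "percent_identity",
    "screen",
]

# Ungapped Karlin-Altschul constants for BLOSUM62 (natural-log units).
BLOSUM62_LAMBDA = 0.3176
BLOSUM62_K = 0.134

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (20-letter alphabet plus X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        for pos, res in enumerate(seq, start=1):
            if res not in _AA_ALPHABET:
                raise ValueError(
                    f"protein {self.id!r}: invalid residue {res!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologHit:
    """A scored query-subject homology hit."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity_pct: float
    similarity_pct: float
    aligned_length: int


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap penalties and E-value constants.

    Defaults mirror the classic protein-search parameterisation:
    BLOSUM62, gap open 11, gap extend 1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = BLOSUM62_LAMBDA
    ka_k: float = BLOSUM62_K
    _matrix: SubstitutionMatrix = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        alph = ProteinSequence.alphabet
        matrix = SubstitutionMatrix(alph, alph, self.matrix_name)
        object.__setattr__(self, "_matrix", matrix)

    @property
    def matrix(self) -> SubstitutionMatrix:
        return self._matrix

    @property
    def gap_penalty(self) -> tuple[int, int]:
        # biotite convention: (open, extend), both negative
        return (-self.gap_open, -self.gap_extend)


def bit_score(raw_score: float, scoring: AlignmentScoring | None = None) -> float:
    """Karlin-Altschul bit score of a raw alignment score."""
    scoring = scoring or AlignmentScoring()
    return (scoring.ka_lambda * raw_score - math.log(scoring.ka_k)) / math.log(2)


def e_value(bit: float, query_len: int, database_len: int) -> float:
    """Expected chance hits: ``E = m * n * 2**-bit`` (search-space product)."""
    return query_len * database_len * math.pow(2.0, -bit)


def _column_stats(alignment, matrix: SubstitutionMatrix) -> tuple[int, int, int]:
    """(identical, similar, total) columns of an alignment.

    A column is *similar* if it is identical or has a positive substitution
    score; gap columns count toward the total only.
    """
    trace = alignment.trace
    seq_a, seq_b = alignment.sequences
    identical = similar = 0
    for i, j in trace:
        if i == -1 or j == -1:
            continue
        code_a = seq_a.code[i]
        code_b = seq_b.code[j]
        if code_a == code_b:
            identical += 1
            similar += 1
        elif matrix.get_score_by_code(code_a, code_b) > 0:
            similar += 1
    return identical, similar, len(trace)


def local_align(
    query: ProteinRecord,
    subject: ProteinRecord,
    scoring: AlignmentScoring | None = None,
    database_len: int | None = None,
) -> HomologHit:
    """Optimal Smith-Waterman alignment of ``query`` against ``subject``.

    ``database_len`` is the total residue count of the searched database;
    it defaults to ``len(subject)`` for a single pairwise comparison.
    """
    scoring = scoring or AlignmentScoring()
    seq_q = ProteinSequence(query.sequence)
    seq_s = ProteinSequence(subject.sequence)
    alignment = align_optimal(
        seq_q, seq_s, scoring.matrix, gap_penalty=scoring.gap_penalty, local=True
    )[0]
    raw = int(alignment.score)
    identical, similar, length = _column_stats(alignment, scoring.matrix)
    bit = bit_score(raw, scoring)
    n = database_len if database_len is not None else len(subject)
    return HomologHit(
        query_id=query.id,
        subject_id=subject.id,
        raw_score=raw,
        bit_score=bit,
        e_value=e_value(bit, len(query), n),
        identity_pct=100.0 * identical / length if length else 0.0,
        similarity_pct=100.0 * similar / length if length else 0.0,
        aligned_length=length,
    )


def _global_alignment(a: ProteinRecord, b: ProteinRecord, scoring: AlignmentScoring):
    return align_optimal(
        ProteinSequence(a.sequence),
        ProteinSequence(b.sequence),
        scoring.matrix,
        gap_penalty=scoring.gap_penalty,
        local=False,
    )[0]


def percent_similarity(
    a: ProteinRecord, b: ProteinRecord, scoring: AlignmentScoring | None = None
) -> float:
    """Percent positive-scoring columns over the global alignment length.

    Gap columns count toward the length but never as similar, so two
    unrelated sequences with all-negative substitution scores give 0.
    """
    scoring = scoring or AlignmentScoring()
    alignment = _global_alignment(a, b, scoring)
    _, similar, length = _column_stats(alignment, scoring.matrix)
    return 100.0 * similar / length


def percent_identity(
    a: ProteinRecord, b: ProteinRecord, scoring: AlignmentScoring | None = None
) -> float:
    """Percent identical columns over the global alignment length."""
    scoring = scoring or AlignmentScoring()
    alignment = _global_alignment(a, b, scoring)
    identical, _, length = _column_stats(alignment, scoring.matrix)
    return 100.0 * identical / length


def screen(
    queries: list[ProteinRecord],
    proteome: list[ProteinRecord],
    e_cutoff: float = 1e-9,
    scoring: AlignmentScoring | None = None,
) -> tuple[list[HomologHit], list[str]]:
    """Screen every query against the whole proteome.

    Returns ``(hits, not_found)``: all hits with ``e_value < e_cutoff``
    sorted by ascending E (subject id breaks ties), plus the ids of
    queries with no passing subject.  One query may legitimately yield
    several hits (paralogous subjects).
    """
    if not proteome:
        raise ValueError("proteome is empty")
    scoring = scoring or AlignmentScoring()
    database_len = sum(len(p) for p in proteome)
    hits: list[HomologHit] = []
    not_found: list[str] = []
    for query in queries:
        query_hits = [
            hit
            for subject in proteome
            if (hit := local_align(query, subject, scoring, database_len)).e_value
            < e_cutoff
        ]
        if query_hits:
            hits.extend(query_hits)
        else:
            not_found.append(query.id)
    hits.sort(key=lambda h: (h.e_value, h.subject_id))
    return hits, not_found
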