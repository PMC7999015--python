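"""Independent brute-force oracles for alignment scoring.

Exhaustive recursion over every alignment path (affine gap state carried
explicitly: a gap of length L costs open + (L-1)*extend).  Exponential,
usable only on toy sequences — which is the point: it shares no code
with the dynamic-programming implementation it checks.
"""

import math
from functools import lru_cache

from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix

_MATRIX = SubstitutionMatrix.std_protein_matrix()
_ALPH = ProteinSequence.alphabet


def blosum62(a: str, b: str) -> int:
    return _MATRIX.get_score(a, b)


def global_align_score(a: str, b: str, open_pen: int = 11, ext_pen: int = 1) -> int:
    """Best global alignment score by exhaustive path enumeration."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            options.append(blosum62(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = ext_pen if state == "D" else open_pen
            options.append(-cost + rec(i + 1, j, "D"))
        if j < len(b):  # gap in a
            cost = ext_pen if state == "I" else open_pen
            options.append(-cost + rec(i, j + 1, "I"))
        return max(options)

    return rec(0, 0, "M")


def local_align_score(a: str, b: str, open_pen: int = 11, ext_pen: int = 1) -> int:
    """Best local alignment score: max global score over all substring
    pairs, floored at zero (the empty alignment)."""
    best = 0
    for i0 in range(len(a) + 1):
        for i1 in range(i0, len(a) + 1):
            for j0 in range(len(b) + 1):
                for j1 in range(j0, len(b) + 1):
                    sub_a, sub_b = a[i0:i1], b[j0:j1]
                    if not sub_a or not sub_b:
                        continue
                    best = max(best, global_align_score(sub_a, sub_b, open_pen, ext_pen))
    return best
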