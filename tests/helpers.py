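"""Independent oracles used by the test suite.

These deliberately avoid the package's own computation paths: the
alignment oracle enumerates every global alignment explicitly, and the
repertoire-homology oracle is a plain double loop over sequence pairs.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_MATRICES = {}


def _matrix(name: str):
    if name not in _MATRICES:
        _MATRICES[name] = substitution_matrices.load(name)
    return _MATRICES[name]


def bruteforce_align_score(
    a: str, b: str, matrix_name: str, gap_open: float, gap_extend: float,
) -> float:
    """Maximum global-alignment score by exhaustive enumeration of all paths.

    A gap run of length L costs ``gap_open + gap_extend * (L - 1)``; each
    maximal run pays its own opening penalty. Feasible only for short
    sequences (the number of alignments grows like the Delannoy numbers).
    """
    sub = _matrix(matrix_name)
    best = -math.inf

    stack = [(0, 0, 0.0, None)]  # i, j, score, previous op ('M','A','B')
    while stack:
        i, j, score, prev = stack.pop()
        if i == len(a) and j == len(b):
            if score > best:
                best = score
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, score + sub[a[i], b[j]], "M"))
        if j < len(b):  # gap in a, consuming b[j]
            pen = gap_extend if prev == "A" else gap_open
            stack.append((i, j + 1, score - pen, "A"))
        if i < len(a):  # gap in b, consuming a[i]
            pen = gap_extend if prev == "B" else gap_open
            stack.append((i + 1, j, score - pen, "B"))
    return best


def bruteforce_repertoire_homology(ri, rj, seq_homology) -> float:
    """Abundance-weighted best-match average via an explicit double loop.

    ``seq_homology(a, b)`` supplies the pairwise homology; aggregation
    (best match per query, abundance weighting, joint normalization) is
    recomputed here from the definition.
    """
    total = 0.0
    for a, w in zip(ri.sequences, ri.abundances):
        total += w * max(seq_homology(a, b) for b in rj.sequences)
    for b, w in zip(rj.sequences, rj.abundances):
        total += w * max(seq_homology(a, b) for a in ri.sequences)
    return total / (sum(ri.abundances) + sum(rj.abundances))
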