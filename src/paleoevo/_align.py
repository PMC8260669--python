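"""Global pairwise alignment (Needleman-Wunsch, linear gap penalty).

Used for LTR-LTR nucleotide alignments and for protein alignments that
guide codon-aware CDS alignment. The traceback is deterministic: at every
cell the diagonal move is preferred, then the vertical (gap in the second
sequence), then the horizontal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nw_align", "nw_score"]


def _score_matrix(a: str, b: str, match: float, mismatch: float, gap: float) -> np.ndarray:
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    j = np.arange(1, m + 1, dtype=np.float64)
    # Row recurrence: the horizontal (left) dependency under a linear gap
    # cost is a running prefix maximum of c[k] - gap*k, so each row is
    # computed with vector operations only.
    for i in range(1, n + 1):
        sub = np.where(av[i - 1] == bv, match, mismatch)
        c = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        H[i, 1:] = np.maximum.accumulate(c - gap * j) + gap * j
    return H


def nw_score(a: str, b: str, match: float = 1, mismatch: float = -1, gap: float = -2) -> float:
    """Optimal global alignment score of ``a`` vs ``b``."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return float(_score_matrix(a, b, match, mismatch, gap)[len(a), len(b)])


def nw_align(
    a: str,
    b: str,
    match: float = 1,
    mismatch: float = -1,
    gap: float = -2,
) -> tuple[str, str, float]:
    """Globally align two sequences.

    Returns ``(aligned_a, aligned_b, score)`` with ``-`` as the gap
    character. Ties in the dynamic program are broken diagonal > up > left,
    so the output is a deterministic function of the inputs.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    H = _score_matrix(a, b, match, mismatch, gap)
    i, j = len(a), len(b)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if h == H[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and h == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(H[len(a), len(b)])
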