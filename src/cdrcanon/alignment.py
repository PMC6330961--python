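"""Smith-Waterman local alignment scoring under PAM30.

Template ranking for short CDR loops needs only the optimal local-alignment
score, not the alignment itself, and needs it for ~10^5 sequence pairs per
loop group, so the scorer is a numba-compiled affine-gap DP kernel over
integer-encoded sequences.  Gap costs follow the NCBI convention: a gap of
length k costs ``gap_open + k * gap_extend`` (defaults 9 + k, the blastp
PAM30 defaults).
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path
from typing import Union

import numpy as np
from numba import njit

from .records import AMINO_ACIDS

__all__ = [
    "load_pam30",
    "read_ncbi_matrix",
    "substitution_array",
    "align_score",
    "pairwise_scores",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_GAP_OPEN = 9
DEFAULT_GAP_EXTEND = 1


@lru_cache(maxsize=1)
def load_pam30() -> np.ndarray:
    """PAM30 as a 20x20 int array in alphabetical residue order."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("PAM30")
    return substitution_array(mat)


def substitution_array(mat) -> np.ndarray:
    """Project a biopython substitution matrix onto the 20-residue alphabet."""
    arr = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            arr[i, j] = int(mat[a, b])
    return arr


def read_ncbi_matrix(path: Union[str, Path]) -> np.ndarray:
    """Parse an NCBI-format substitution matrix file (e.g. a custom PAM30).

    Lines starting with ``#`` are comments; the first data line lists the
    column residues.  Residues outside the 20 standard codes (B, Z, X, *)
    are ignored.
    """
    header: list[str] = []
    rows: dict[str, dict[str, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if not header:
            header = parts
            continue
        row_aa, values = parts[0], parts[1:]
        rows[row_aa] = {aa: int(v) for aa, v in zip(header, values)}
    arr = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        if a not in rows:
            raise ValueError(f"matrix file lacks residue {a}")
        for j, b in enumerate(AMINO_ACIDS):
            arr[i, j] = rows[a][b]
    return arr


def encode_seq(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in {seq!r}") from None


@njit(cache=False)
def _sw_score(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jit
    n, m = a.shape[0], b.shape[0]
    NEG = -(10 ** 9)
    H_prev = np.zeros(m + 1, dtype=np.int64)
    E_prev = np.full(m + 1, NEG, dtype=np.int64)  # gap in a (vertical)
    best = 0
    for i in range(1, n + 1):
        H_cur = np.zeros(m + 1, dtype=np.int64)
        E_cur = np.empty(m + 1, dtype=np.int64)
        E_cur[0] = NEG
        F = NEG  # gap in b (horizontal), scans along j
        for j in range(1, m + 1):
            E_cur[j] = max(H_prev[j] - gap_open - gap_extend,
                           E_prev[j] - gap_extend)
            F = max(H_cur[j - 1] - gap_open - gap_extend, F - gap_extend)
            diag = H_prev[j - 1] + sub[a[i - 1], b[j - 1]]
            h = diag
            if E_cur[j] > h:
                h = E_cur[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            H_cur[j] = h
            if h > best:
                best = h
        H_prev = H_cur
        E_prev = E_cur
    return best


def align_score(
    query_seq: str,
    template_seq: str,
    matrix: np.ndarray | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> int:
    """Optimal Smith-Waterman local-alignment score of two sequences.

    Symmetric in its arguments.  A gap of length k costs
    ``gap_open + k * gap_extend``.
    """
    if not query_seq or not template_seq:
        raise ValueError("sequences must be nonempty")
    sub = load_pam30() if matrix is None else matrix
    return int(
        _sw_score(encode_seq(query_seq), encode_seq(template_seq), sub,
                  gap_open, gap_extend)
    )


def pairwise_scores(
    seqs: list[str],
    matrix: np.ndarray | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> np.ndarray:
    """Symmetric all-against-all score matrix (diagonal = self-scores)."""
    sub = load_pam30() if matrix is None else matrix
    encoded = [encode_seq(s) for s in seqs]
    n = len(encoded)
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i, n):
            s = _sw_score(encoded[i], encoded[j], sub, gap_open, gap_extend)
            out[i, j] = s
            out[j, i] = s
    return out
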