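"""One-hot sequence encoding for CDR cluster classifiers.

Each record is encoded over a window of ``loop_length + 2 * flank_width``
positions, 20 indicator columns per position, so a length-10 loop with
10-residue flanks becomes a 600-feature binary vector.  Positions follow
the loop-anchored convention: position 1 is the first loop residue, -1 the
residue immediately preceding the loop (there is no position 0), and the
downstream flank continues L+1 ... L+flank_width.  Flanks shorter than
``flank_width`` (chain termini) leave all-zero blocks at the outermost
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .records import AMINO_ACIDS, CdrRecord, LoopGroup

__all__ = [
    "FeatureMatrix",
    "EncodingError",
    "feature_name",
    "parse_feature_name",
    "window_positions",
    "one_hot_encode",
    "encode_group",
    "decode_vector",
    "OneHotCdrEncoder",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)


class EncodingError(ValueError):
    pass


def window_positions(loop_length: int, flank_width: int) -> list[int]:
    """Loop-anchored position labels for the encoding window, in order."""
    upstream = list(range(-flank_width, 0))
    loop = list(range(1, loop_length + 1))
    downstream = list(range(loop_length + 1, loop_length + 1 + flank_width))
    return upstream + loop + downstream


def feature_name(position: int, residue: str) -> str:
    """``(-1, 'G') -> '-1:G'`` — position label plus residue letter."""
    if position == 0:
        raise EncodingError("position 0 does not exist (loop starts at 1)")
    if residue not in _AA_INDEX:
        raise EncodingError(f"unknown residue {residue!r}")
    return f"{position}:{residue}"


def parse_feature_name(name: str) -> tuple[int, str]:
    pos_s, _, residue = name.partition(":")
    position = int(pos_s)
    if position == 0 or residue not in _AA_INDEX:
        raise EncodingError(f"malformed feature name {name!r}")
    return position, residue


def _block_index(position: int, loop_length: int, flank_width: int) -> int:
    # map a position label to its 20-column block index in the window
    if position < 0:
        idx = position + flank_width
        if idx < 0:
            raise EncodingError(f"position {position} outside flank width {flank_width}")
    elif position == 0:
        raise EncodingError("position 0 does not exist")
    else:
        idx = flank_width + position - 1
        if position > loop_length + flank_width:
            raise EncodingError(
                f"position {position} beyond window for loop length {loop_length}"
            )
    return idx


def one_hot_encode(record: CdrRecord, flank_width: int = 10) -> np.ndarray:
    """Encode one record as a flat binary vector.

    The vector has ``(loop_length + 2*flank_width) * 20`` entries; each
    present position contributes exactly one 1, padded flank positions an
    all-zero block.
    """
    if flank_width < 0:
        raise ValueError("flank_width must be >= 0")
    L = record.loop_length
    n_pos = L + 2 * flank_width
    vec = np.zeros(n_pos * N_AA, dtype=np.uint8)

    up = record.flank_up[-flank_width:] if flank_width else ""
    down = record.flank_down[:flank_width] if flank_width else ""
    # upstream flank is right-aligned against the loop start
    for offset, aa in enumerate(reversed(up)):
        pos = -(offset + 1)
        _set(vec, pos, aa, L, flank_width, record.record_id)
    for i, aa in enumerate(record.loop_seq):
        _set(vec, i + 1, aa, L, flank_width, record.record_id)
    for i, aa in enumerate(down):
        _set(vec, L + 1 + i, aa, L, flank_width, record.record_id)
    return vec


def _set(vec, position, aa, loop_length, flank_width, rid):
    if aa not in _AA_INDEX:
        raise EncodingError(
            f"{rid}: non-standard residue {aa!r} at position {position}"
        )
    block = _block_index(position, loop_length, flank_width)
    vec[block * N_AA + _AA_INDEX[aa]] = 1


def decode_vector(
    vec: np.ndarray, loop_length: int, flank_width: int = 10
) -> tuple[str, str, str]:
    """Invert :func:`one_hot_encode` -> (flank_up, loop_seq, flank_down)."""
    positions = window_positions(loop_length, flank_width)
    chars: dict[int, str] = {}
    for block, pos in enumerate(positions):
        col = vec[block * N_AA : (block + 1) * N_AA]
        hits = np.flatnonzero(col)
        if hits.size > 1:
            raise EncodingError(f"position {pos}: multiple residues set")
        if hits.size == 1:
            chars[pos] = AMINO_ACIDS[hits[0]]
    up = "".join(chars[p] for p in sorted(c for c in chars if c < 0))
    loop = "".join(chars[p] for p in range(1, loop_length + 1))
    down = "".join(
        chars[p] for p in sorted(c for c in chars if c > loop_length)
    )
    return up, loop, down


@dataclass
class FeatureMatrix:
    """Encoded loop group: binary matrix plus aligned names and labels."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    labels: list[str]

    def to_triplets(self, path) -> None:
        """Export the nonzero entries as a ``row\tcol\tname`` sparse file."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("row\tcol\tfeature\n")
            rows, cols = np.nonzero(self.values)
            for r, c in zip(rows, cols):
                fh.write(f"{r}\t{c}\t{self.feature_names[c]}\n")


def encode_group(group: LoopGroup, flank_width: int = 10) -> FeatureMatrix:
    """Encode every record of a loop group; row order follows record order."""
    L = group.loop_length
    names = [
        feature_name(pos, aa)
        for pos in window_positions(L, flank_width)
        for aa in AMINO_ACIDS
    ]
    values = np.vstack([one_hot_encode(r, flank_width) for r in group.records])
    return FeatureMatrix(
        values=values,
        feature_names=names,
        sample_ids=[r.record_id for r in group.records],
        labels=[r.cluster_label for r in group.records],
    )


class OneHotCdrEncoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer from CdrRecord lists to binary matrices.

    Parameters
    ----------
    flank_width : int, default 10
        Framework residues included on each side of the loop.
    """

    def __init__(self, flank_width: int = 10):
        self.flank_width = flank_width

    def fit(self, X, y=None):
        X = list(X)
        if not X:
            raise ValueError("cannot fit on an empty record list")
        lengths = {r.loop_length for r in X}
        if len(lengths) != 1:
            raise EncodingError(f"mixed loop lengths {sorted(lengths)}")
        self.loop_length_ = lengths.pop()
        self.feature_names_ = [
            feature_name(pos, aa)
            for pos in window_positions(self.loop_length_, self.flank_width)
            for aa in AMINO_ACIDS
        ]
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        X = list(X)
        for r in X:
            if r.loop_length != self.loop_length_:
                raise EncodingError(
                    f"{r.record_id}: loop length {r.loop_length} != fitted "
                    f"length {self.loop_length_}"
                )
        return np.vstack([one_hot_encode(r, self.flank_width) for r in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
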