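"""Core domain types for cluster-annotated CDR loops.

A non-H3 CDR loop (H1, H2, L1, L2 or L3) of a given length belongs to one of
a small number of canonical structural clusters, named like ``H2-10-1`` or
``L3-9-cis7-1``, or to the catch-all ``"none"`` class.  Every model in this
package is trained and evaluated on one :class:`LoopGroup` — all records of
a single (loop type, loop length) pair — because clusters are only defined
within such a group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AMINO_ACIDS",
    "NONE_LABEL",
    "LOOP_TYPES",
    "CdrRecord",
    "LoopGroup",
    "DatasetManifest",
    "merge_sparse_clusters",
]

#: The 20 standard one-letter amino-acid codes, alphabetical; this ordering
#: fixes one-hot feature indices and substitution-matrix row order everywhere.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Catch-all label for loops outside any canonical cluster.
NONE_LABEL = "none"

LOOP_TYPES = ("H1", "H2", "L1", "L2", "L3")


class RecordError(ValueError):
    """A CdrRecord violates a structural invariant."""


@dataclass(frozen=True)
class CdrRecord:
    """One cluster-annotated CDR loop.

    Parameters
    ----------
    record_id:
        Unique identifier (conventionally structure id + chain + loop).
    loop_type:
        One of H1, H2, L1, L2, L3.
    loop_length:
        Number of residues in the loop proper.
    loop_seq:
        Loop sequence, exactly ``loop_length`` residues.
    flank_up, flank_down:
        Up to 10 residues of framework sequence immediately preceding /
        following the loop; may be shorter at chain termini.
    cluster_label:
        Canonical cluster name (e.g. ``"L3-9-cis7-1"``) or ``"none"``.
    dihedrals:
        Optional tuple of per-loop-residue backbone (phi, psi) pairs in
        degrees, each angle in (-180, 180].
    """

    record_id: str
    loop_type: str
    loop_length: int
    loop_seq: str
    flank_up: str = ""
    flank_down: str = ""
    cluster_label: str = NONE_LABEL
    dihedrals: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if self.loop_type not in LOOP_TYPES:
            raise RecordError(
                f"{self.record_id}: unknown loop type {self.loop_type!r}"
            )
        if self.loop_length <= 0:
            raise RecordError(f"{self.record_id}: loop_length must be positive")
        if len(self.loop_seq) != self.loop_length:
            raise RecordError(
                f"{self.record_id}: loop_seq length {len(self.loop_seq)} "
                f"!= loop_length {self.loop_length}"
            )
        if self.dihedrals is not None:
            if len(self.dihedrals) != self.loop_length:
                raise RecordError(
                    f"{self.record_id}: {len(self.dihedrals)} dihedral pairs "
                    f"for a length-{self.loop_length} loop"
                )
            for phi, psi in self.dihedrals:
                for a in (phi, psi):
                    if not (math.isfinite(a) and -180.0 < a <= 180.0):
                        raise RecordError(
                            f"{self.record_id}: angle {a} outside (-180, 180]"
                        )

    @property
    def flanked_seq(self) -> str:
        """Flank + loop + flank, the sequence the classifiers consume."""
        return self.flank_up + self.loop_seq + self.flank_down

    def is_sanitized(self) -> bool:
        """True when every residue is one of the 20 standard codes."""
        return all(c in _AA_SET for c in self.flanked_seq)

    def label_consistent(self) -> bool:
        """Check the cluster label parses to this record's type and length.

        ``"none"`` is always consistent; otherwise the label must start with
        ``"<loop_type>-<loop_length>-"``.
        """
        if self.cluster_label == NONE_LABEL:
            return True
        return self.cluster_label.startswith(
            f"{self.loop_type}-{self.loop_length}-"
        )


@dataclass
class LoopGroup:
    """All records of one (loop type, loop length) pair."""

    loop_type: str
    loop_length: int
    records: list[CdrRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.loop_type != self.loop_type or r.loop_length != self.loop_length:
                raise RecordError(
                    f"record {r.record_id} ({r.loop_type}-{r.loop_length}) "
                    f"does not belong in group {self.key}"
                )

    @property
    def key(self) -> str:
        return f"{self.loop_type}-{self.loop_length}"

    @property
    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self.records:
            sizes[r.cluster_label] = sizes.get(r.cluster_label, 0) + 1
        return sizes

    @property
    def labels(self) -> list[str]:
        return [r.cluster_label for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class DatasetManifest:
    """A collection of loop groups plus ingestion bookkeeping."""

    groups: list[LoopGroup] = field(default_factory=list)
    provenance: str = ""
    merge_threshold: int = 3
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (row id, reason)

    @property
    def n_records(self) -> int:
        return sum(len(g) for g in self.groups)

    def group(self, loop_type: str, loop_length: int) -> LoopGroup:
        for g in self.groups:
            if g.loop_type == loop_type and g.loop_length == loop_length:
                return g
        raise KeyError(f"no group {loop_type}-{loop_length}")

    def iter_records(self) -> Iterable[CdrRecord]:
        for g in self.groups:
            yield from g.records


def merge_sparse_clusters(group: LoopGroup, min_size: int = 3) -> LoopGroup:
    """Relabel clusters with fewer than ``min_size`` members as ``"none"``.

    Mirrors the dataset rule that clusters too sparse to model are pooled
    into the catch-all class.  Records already labelled ``"none"`` are left
    untouched; the operation is idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sizes = group.cluster_sizes
    sparse = {c for c, n in sizes.items() if c != NONE_LABEL and n < min_size}
    new_records = [
        CdrRecord(
            record_id=r.record_id,
            loop_type=r.loop_type,
            loop_length=r.loop_length,
            loop_seq=r.loop_seq,
            flank_up=r.flank_up,
            flank_down=r.flank_down,
            cluster_label=NONE_LABEL if r.cluster_label in sparse else r.cluster_label,
            dihedrals=r.dihedrals,
        )
        for r in group.records
    ]
    return LoopGroup(group.loop_type, group.loop_length, new_records)
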