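"""Reading and writing cluster-annotated CDR tables and FASTA files.

The canonical on-disk form is a tab-separated table with header columns

    record_id  loop_type  loop_length  seq_before  cdr_seq  seq_after
    cluster    phi_psi

where ``phi_psi`` holds semicolon-joined ``phi,psi`` degree pairs, one per
loop residue (empty when dihedrals are absent).  A :class:`TableDialect`
maps foreign column names (e.g. a PyIgClassify-style download) onto this
schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    AMINO_ACIDS,
    CdrRecord,
    DatasetManifest,
    LoopGroup,
    RecordError,
)

__all__ = [
    "TableDialect",
    "CANONICAL_COLUMNS",
    "SchemaError",
    "read_cdr_table",
    "write_cdr_table",
    "write_fasta",
]

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = (
    "record_id",
    "loop_type",
    "loop_length",
    "seq_before",
    "cdr_seq",
    "seq_after",
    "cluster",
    "phi_psi",
)

_AA_SET = frozenset(AMINO_ACIDS)


class SchemaError(ValueError):
    """The input table is missing a mandatory column."""


class EmptyTableError(ValueError):
    """The input table contains no rows."""


@dataclass(frozen=True)
class TableDialect:
    """Maps input column names onto the canonical schema.

    ``columns`` maps canonical name -> input column name.  Only ``phi_psi``
    and ``seq_before``/``seq_after`` may be absent from the mapping (flanks
    and dihedrals are optional).
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in CANONICAL_COLUMNS}
    )
    sep: str = "\t"

    def source(self, canonical: str) -> Optional[str]:
        return self.columns.get(canonical)


_MANDATORY = ("record_id", "loop_type", "loop_length", "cdr_seq", "cluster")


def _format_phi_psi(dihedrals) -> str:
    if dihedrals is None:
        return ""
    return ";".join(f"{phi:.3f},{psi:.3f}" for phi, psi in dihedrals)


def _parse_phi_psi(text: str):
    text = (text or "").strip()
    if not text:
        return None
    pairs = []
    for chunk in text.split(";"):
        phi_s, psi_s = chunk.split(",")
        pairs.append((float(phi_s), float(psi_s)))
    return tuple(pairs)


def read_cdr_table(
    path: Union[str, Path],
    dialect: Optional[TableDialect] = None,
) -> DatasetManifest:
    """Read a cluster-annotated CDR table into a grouped manifest.

    Rows whose sequence contains a non-standard residue (X, B, Z, gaps, ...)
    are dropped and logged; everything else becomes a :class:`CdrRecord`,
    grouped by (loop type, loop length).
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    for canonical in _MANDATORY:
        col = dialect.source(canonical)
        if col is None or col not in df.columns:
            raise SchemaError(f"input table lacks mandatory column {canonical!r}")
    if len(df) == 0:
        raise EmptyTableError(f"{path} contains no data rows")

    manifest = DatasetManifest(provenance=str(path))
    buckets: dict[tuple[str, int], list[CdrRecord]] = {}

    def col(row, canonical, default=""):
        name = dialect.source(canonical)
        if name is None or name not in df.columns:
            return default
        return row[name]

    for _, row in df.iterrows():
        rid = col(row, "record_id")
        seq_before = col(row, "seq_before")
        cdr_seq = col(row, "cdr_seq")
        seq_after = col(row, "seq_after")
        full = seq_before + cdr_seq + seq_after
        bad = sorted({c for c in full if c not in _AA_SET})
        if bad:
            reason = f"non-standard residue(s) {''.join(bad)}"
            manifest.dropped.append((rid, reason))
            logger.warning("dropping record %s: %s", rid, reason)
            continue
        try:
            rec = CdrRecord(
                record_id=rid,
                loop_type=col(row, "loop_type"),
                loop_length=int(col(row, "loop_length")),
                loop_seq=cdr_seq,
                flank_up=seq_before,
                flank_down=seq_after,
                cluster_label=col(row, "cluster"),
                dihedrals=_parse_phi_psi(col(row, "phi_psi")),
            )
        except (RecordError, ValueError) as exc:
            manifest.dropped.append((rid, str(exc)))
            logger.warning("dropping record %s: %s", rid, exc)
            continue
        buckets.setdefault((rec.loop_type, rec.loop_length), []).append(rec)

    for (loop_type, loop_length), records in sorted(buckets.items()):
        manifest.groups.append(LoopGroup(loop_type, loop_length, records))
    if manifest.n_records:
        logger.info(
            "read %d records in %d groups from %s (%d dropped)",
            manifest.n_records, len(manifest.groups), path, len(manifest.dropped),
        )
    return manifest


def write_cdr_table(manifest: DatasetManifest, path: Union[str, Path]) -> None:
    """Write a manifest as a canonical tab-separated table (UTF-8, LF)."""
    rows = [
        {
            "record_id": r.record_id,
            "loop_type": r.loop_type,
            "loop_length": r.loop_length,
            "seq_before": r.flank_up,
            "cdr_seq": r.loop_seq,
            "seq_after": r.flank_down,
            "cluster": r.cluster_label,
            "phi_psi": _format_phi_psi(r.dihedrals),
        }
        for r in manifest.iter_records()
    ]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_fasta(
    manifest: DatasetManifest, path: Union[str, Path], flanked: bool = True
) -> None:
    """Write loop sequences as FASTA; header is ``record_id|cluster_label``."""
    seqs = [
        SeqRecord(
            Seq(r.flanked_seq if flanked else r.loop_seq),
            id=f"{r.record_id}|{r.cluster_label}",
            description="",
        )
        for r in manifest.iter_records()
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seqs, fh, "fasta")
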