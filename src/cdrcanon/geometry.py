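"""Dihedral-angle geometry of canonical clusters.

The structural dissimilarity of two equal-length loops is the summed
per-residue angular distance ``D(i,j) = sum_r 2(1-cos(dphi_r)) +
2(1-cos(dpsi_r))`` over the loop residues (flanks excluded).  Each
cluster's exemplar is approximated as the medoid under this distance; the
cluster radius is the largest member-to-exemplar distance, and a member's
structural neighbors are the other members closer than a fixed fraction
(default 1/15) of the radius.  These quantities explain misclassification:
queries far from their exemplar, or with few neighbors, are the ones the
sequence-based classifiers tend to get wrong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import CdrRecord

__all__ = [
    "ClusterGeometry",
    "angle_term",
    "loop_distance",
    "compute_exemplar",
    "structural_neighbors",
    "exemplar_distance_profile",
    "exemplar_separation",
]

logger = logging.getLogger(__name__)

#: Fraction of the cluster radius defining the structural-neighbor cutoff.
NEIGHBOR_FRACTION = 1.0 / 15.0


def angle_term(theta1: float, theta2: float) -> float:
    """``2(1 - cos(theta1 - theta2))`` with angles in degrees; range [0, 4]."""
    return 2.0 * (1.0 - np.cos(np.deg2rad(theta1 - theta2)))


def _dihedral_array(record: CdrRecord) -> np.ndarray:
    if record.dihedrals is None:
        raise ValueError(f"{record.record_id} carries no dihedrals")
    return np.asarray(record.dihedrals, dtype=np.float64)


def loop_distance(i: CdrRecord, j: CdrRecord) -> float:
    """Dihedral-angle distance between two equal-length loops.

    Symmetric, zero on identical angle lists, bounded by 8N for an N-residue
    loop (phi and psi each contribute at most 4 per residue).
    """
    if i.loop_length != j.loop_length:
        raise ValueError(
            f"loop length mismatch: {i.record_id} ({i.loop_length}) vs "
            f"{j.record_id} ({j.loop_length})"
        )
    a = np.deg2rad(_dihedral_array(i))
    b = np.deg2rad(_dihedral_array(j))
    return float(np.sum(2.0 * (1.0 - np.cos(a - b))))


@dataclass
class ClusterGeometry:
    """Exemplar, radius and member distances of one cluster."""

    cluster_label: str
    exemplar_id: str
    radius: float
    member_distances: dict[str, float]

    @property
    def exemplar_record(self) -> CdrRecord:
        return self._exemplar_record

    def _attach(self, record: CdrRecord) -> "ClusterGeometry":
        self._exemplar_record = record
        return self


def compute_exemplar(records: Sequence[CdrRecord],
                     cluster_label: str | None = None,
                     exemplar_id: str | None = None) -> ClusterGeometry:
    """Medoid exemplar, radius, and member distances of a cluster.

    The exemplar is the member minimizing the summed dihedral distance to
    all members (ties broken by smallest record id); pass ``exemplar_id`` to
    honor an externally supplied exemplar instead.
    """
    records = sorted(records, key=lambda r: r.record_id)
    if not records:
        raise ValueError("empty cluster")
    label = cluster_label or records[0].cluster_label
    angles = np.deg2rad(np.array([_dihedral_array(r) for r in records]))
    n = len(records)
    dist = np.zeros((n, n))
    for a in range(n):
        diff = angles[a][None, :, :] - angles
        dist[a] = np.sum(2.0 * (1.0 - np.cos(diff)), axis=(1, 2))
    if exemplar_id is not None:
        ids = [r.record_id for r in records]
        if exemplar_id not in ids:
            raise ValueError(f"exemplar {exemplar_id} not among the members")
        medoid = ids.index(exemplar_id)
    else:
        medoid = int(np.argmin(dist.sum(axis=1)))  # first index wins ties
    member_distances = {
        r.record_id: float(dist[medoid, k]) for k, r in enumerate(records)
    }
    geo = ClusterGeometry(
        cluster_label=label,
        exemplar_id=records[medoid].record_id,
        radius=float(dist[medoid].max()),
        member_distances=member_distances,
    )
    return geo._attach(records[medoid])


def structural_neighbors(
    query: CdrRecord,
    geometry: ClusterGeometry,
    members: Sequence[CdrRecord],
    fraction: float = NEIGHBOR_FRACTION,
) -> int:
    """Members (excluding the query) strictly closer than fraction * radius."""
    threshold = fraction * geometry.radius
    if geometry.radius == 0.0 and len(members) > 1:
        logger.warning(
            "cluster %s has zero radius; neighbor count is 0 by convention",
            geometry.cluster_label,
        )
        return 0
    count = 0
    for m in members:
        if m.record_id == query.record_id:
            continue
        if loop_distance(query, m) < threshold:
            count += 1
    return count


def exemplar_distance_profile(
    records: Sequence[CdrRecord],
    geometries: dict[str, ClusterGeometry],
    predictions: dict[str, str],
) -> pd.DataFrame:
    """Per-record distance to the cognate exemplar, split by correctness.

    Drives the correct-vs-incorrect distance comparison: rows hold
    record id, true cluster, exemplar distance and whether the prediction
    matched.  Records whose cluster has no geometry are skipped.
    """
    rows = []
    for r in records:
        geo = geometries.get(r.cluster_label)
        if geo is None:
            continue
        rows.append({
            "record_id": r.record_id,
            "cluster": r.cluster_label,
            "exemplar_distance": geo.member_distances.get(
                r.record_id, loop_distance(r, geo.exemplar_record)
            ),
            "correct": predictions[r.record_id] == r.cluster_label,
        })
    return pd.DataFrame(rows, columns=[
        "record_id", "cluster", "exemplar_distance", "correct",
    ])


def exemplar_separation(geometry_a: ClusterGeometry,
                        geometry_b: ClusterGeometry) -> float:
    """Dihedral distance between two clusters' exemplar loops."""
    return loop_distance(geometry_a.exemplar_record, geometry_b.exemplar_record)
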