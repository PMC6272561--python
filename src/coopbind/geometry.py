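"""Geometric trajectory statistics.

Superposition RMSD/RMSF, aromatic ring perception and ring-ring stacking
geometry, close-contact frame fractions, hydrogen bonds, and generic distance
series over a conformational ensemble.

Conventions (all configurable where a cutoff appears):

* ring-ring distance is centroid-centroid (Angstrom);
* the inter-plane angle is the angle between least-squares plane normals
  folded into [0, 90] degrees (antiparallel normals give 0);
* stacking and close-contact cutoffs use strict ``<`` comparison;
* close contacts consider heavy atoms only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from coopbind.model_io import Ensemble, Frame, Topology

STACKING_CUTOFF = 7.0  # Angstrom, strict <
CONTACT_CUTOFF = 5.0  # Angstrom, strict <
PARALLEL_MAX_ANGLE = 30.0  # degrees
PERPENDICULAR_MIN_ANGLE = 60.0  # degrees
PLANARITY_TOLERANCE = 0.1  # Angstrom RMS out-of-plane


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric inputs."""


@dataclass(frozen=True)
class SeriesSummary:
    """Mean +/- sample standard deviation of a per-frame series."""

    mean: float
    sample_std: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise GeometryError("summary requires at least one frame")
        if self.sample_std < 0:
            raise GeometryError("sample_std must be >= 0")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SeriesSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise GeometryError("cannot summarize an empty series")
        std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(mean=float(arr.mean()), sample_std=std, n_frames=int(arr.size))

    @property
    def standard_error(self) -> float:
        return self.sample_std / math.sqrt(self.n_frames)


@dataclass(frozen=True)
class RingSystem:
    """A 5- or 6-membered bond-graph cycle that is planar in a reference frame."""

    ring_id: int
    member_atoms: tuple[int, ...]
    owner_partition: str


@dataclass(frozen=True)
class StackingRecord:
    frame_index: int
    ring_a: int
    ring_b: int
    centroid_distance: float
    interplane_angle: float
    stacking_class: str


@dataclass
class ContactProfile:
    """Per-residue fraction of frames with a close ligand contact."""

    fractions: dict[tuple[str, int, str], float]
    cutoff: float
    ligand_partition: str
    n_frames: int


@dataclass(frozen=True)
class HBondRecord:
    donor_atom: int
    acceptor_atom: int
    heavy_atom_distance: float
    donor_angle: float
    occupancy: float


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``reference``
    over the selected atoms.  The rotation is proper (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.arange(len(mobile))
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise GeometryError("empty atom selection")
    x = mobile[sel]
    y = reference[sel]
    if x.shape != y.shape:
        raise GeometryError("selection lengths differ between coordinate sets")
    if sel.size < 3 or _is_collinear(x) or _is_collinear(y):
        raise GeometryError(
            "superposition needs at least 3 non-collinear selected atoms"
        )
    if np.array_equal(x, y):  # identical selections superpose exactly
        return np.eye(3), np.zeros(3), 0.0
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = y.mean(axis=0) - rot @ x.mean(axis=0)
    moved = xc @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - yc) ** 2, axis=1))))
    return rot, trans, rmsd


def _is_collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s.size < 2 or s[1] < tol * max(s[0], 1.0))


def backbone_rmsd_series(
    ensemble: Ensemble,
    reference: Frame,
    selection: Sequence[int],
) -> tuple[list[float], SeriesSummary]:
    """Per-frame superposition RMSD onto ``reference`` over ``selection``."""
    values = [
        kabsch_superpose(f.coordinates, reference.coordinates, selection)[2]
        for f in ensemble.frames
    ]
    return values, SeriesSummary.from_values(values)


def backbone_selection(topology: Topology, names: Sequence[str] = ("N", "CA", "C")) -> np.ndarray:
    """Indices of backbone atoms by name; falls back to all heavy atoms when
    fewer than 3 names match (superposition would be underdetermined)."""
    idx = [i for i, a in enumerate(topology.atoms) if a.name in names]
    if len(idx) < 3:
        idx = list(np.flatnonzero(topology.heavy_mask()))
    return np.asarray(idx, dtype=int)


def rmsf_per_residue(
    ensemble: Ensemble,
    selection: Sequence[int] | None = None,
    align_selection: Sequence[int] | None = None,
) -> dict[tuple[str, int, str], float]:
    """Per-residue RMSF after superposing every frame onto frame 1.

    Frames are superposed over ``align_selection`` (default: same as
    ``selection``); the per-atom fluctuation is the root-mean-square
    displacement about the atom's time-averaged position, and residue values
    average over the residue's selected atoms.
    """
    if ensemble.n_frames < 2:
        raise GeometryError("RMSF requires at least two frames")
    top = ensemble.topology
    if selection is None:
        selection = np.arange(top.n_atoms)
    sel = np.asarray(selection, dtype=int)
    align = sel if align_selection is None else np.asarray(align_selection, int)
    ref = ensemble.frames[0].coordinates
    aligned = np.empty((ensemble.n_frames, sel.size, 3))
    for k, f in enumerate(ensemble.frames):
        rot, trans, _ = kabsch_superpose(f.coordinates, ref, align)
        aligned[k] = f.coordinates[sel] @ rot.T + trans
    mean_pos = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
    buckets: dict[tuple[str, int, str], list[float]] = {}
    for local, atom_index in enumerate(sel):
        buckets.setdefault(top.residue_of(int(atom_index)), []).append(
            float(per_atom[local])
        )
    return {key: float(np.mean(vals)) for key, vals in buckets.items()}


# ---------------------------------------------------------------------------
# rings and stacking
# ---------------------------------------------------------------------------

def _order_cycle(members: Sequence[int], bonds: frozenset[tuple[int, int]]) -> tuple[int, ...]:
    """Order cycle members by walking the induced bond subgraph."""
    member_set = set(members)
    adj = {m: [] for m in members}
    for i, j in bonds:
        if i in member_set and j in member_set:
            adj[i].append(j)
            adj[j].append(i)
    start = min(members)
    order = [start]
    prev = None
    while len(order) < len(members):
        nxt = [v for v in adj[order[-1]] if v != prev]
        if not nxt:
            raise GeometryError(f"atoms {sorted(members)} do not form a simple cycle")
        prev = order[-1]
        order.append(nxt[0])
    return tuple(order)


def plane_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through ``points``.

    Returns ``(centroid, unit_normal, rms_out_of_plane)``.
    """
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    centered = points - centroid
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s.size < 2 or s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("ring members are collinear; plane is undefined")
    normal = vt[2]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal, rms


def perceive_rings(
    topology: Topology,
    reference: Frame,
    planarity_tolerance: float = PLANARITY_TOLERANCE,
) -> list[RingSystem]:
    """All planar 5-6 membered cycles of the bond graph.

    Explicit ``ring_definitions`` in the topology override perception (they
    are still cycle-ordered, but skip the planarity filter).  Ring ids number
    the returned rings consecutively from 0.
    """
    rings: list[RingSystem] = []
    if topology.ring_definitions:
        candidate_cycles = [list(r) for r in topology.ring_definitions]
        check_planarity = False
    else:
        g = nx.Graph()
        g.add_nodes_from(range(topology.n_atoms))
        g.add_edges_from(topology.bonds)
        candidate_cycles = [
            c for c in nx.minimum_cycle_basis(g) if len(c) in (5, 6)
        ]
        candidate_cycles.sort(key=min)
        check_planarity = True
    for members in candidate_cycles:
        ordered = _order_cycle(members, topology.bonds)
        if check_planarity:
            _, _, rms = plane_fit(reference.coordinates[list(ordered)])
            if rms > planarity_tolerance:
                continue
        partitions = {topology.atoms[i].partition for i in ordered}
        owner = (
            partitions.pop()
            if len(partitions) == 1
            else topology.atoms[ordered[0]].partition
        )
        rings.append(
            RingSystem(
                ring_id=len(rings), member_atoms=ordered, owner_partition=owner
            )
        )
    return rings


def ring_pair_geometry(
    frame: Frame, ring_a: RingSystem, ring_b: RingSystem
) -> tuple[float, float]:
    """Centroid distance (Angstrom) and inter-plane angle (degrees, [0, 90])."""
    ca, na, _ = plane_fit(frame.coordinates[list(ring_a.member_atoms)])
    cb, nb, _ = plane_fit(frame.coordinates[list(ring_b.member_atoms)])
    distance = float(np.linalg.norm(ca - cb))
    cosang = abs(float(np.dot(na, nb)))
    angle = math.degrees(math.acos(min(1.0, max(0.0, cosang))))
    return distance, angle


def classify_stacking(
    interplane_angle: float,
    parallel_max: float = PARALLEL_MAX_ANGLE,
    perpendicular_min: float = PERPENDICULAR_MIN_ANGLE,
) -> str:
    """Map an inter-plane angle to parallel / tilted / perpendicular."""
    if not 0.0 <= interplane_angle <= 90.0:
        raise GeometryError(
            f"interplane angle {interplane_angle} outside [0, 90] degrees"
        )
    if interplane_angle < parallel_max:
        return "parallel"
    if interplane_angle > perpendicular_min:
        return "perpendicular"
    return "tilted"


@dataclass
class StackingSummary:
    """Per ring pair: stats over qualifying frames and over all frames."""

    ring_a: int
    ring_b: int
    occupancy: float
    distance_qualifying: SeriesSummary | None
    angle_qualifying: SeriesSummary | None
    distance_all: SeriesSummary
    angle_all: SeriesSummary


def detect_stacking(
    ensemble: Ensemble,
    rings: Sequence[RingSystem],
    cutoff: float = STACKING_CUTOFF,
    cross_partition_only: bool = True,
    parallel_max: float = PARALLEL_MAX_ANGLE,
    perpendicular_min: float = PERPENDICULAR_MIN_ANGLE,
) -> tuple[list[StackingRecord], list[StackingSummary]]:
    """Per-frame stacking records for ring pairs closer than ``cutoff``.

    A record is emitted only when the centroid distance is strictly below the
    cutoff.  Summaries report statistics both over qualifying frames only and
    over all frames (the averaging convention is ambiguous in general use, so
    both are provided).
    """
    pairs = [
        (a, b)
        for ai, a in enumerate(rings)
        for b in rings[ai + 1 :]
        if (not cross_partition_only) or a.owner_partition != b.owner_partition
    ]
    records: list[StackingRecord] = []
    summaries: list[StackingSummary] = []
    for a, b in pairs:
        dists, angles, qual_d, qual_a = [], [], [], []
        for fi, frame in enumerate(ensemble.frames):
            d, ang = ring_pair_geometry(frame, a, b)
            dists.append(d)
            angles.append(ang)
            if d < cutoff:
                qual_d.append(d)
                qual_a.append(ang)
                records.append(
                    StackingRecord(
                        frame_index=fi,
                        ring_a=a.ring_id,
                        ring_b=b.ring_id,
                        centroid_distance=d,
                        interplane_angle=ang,
                        stacking_class=classify_stacking(
                            ang, parallel_max, perpendicular_min
                        ),
                    )
                )
        summaries.append(
            StackingSummary(
                ring_a=a.ring_id,
                ring_b=b.ring_id,
                occupancy=len(qual_d) / ensemble.n_frames,
                distance_qualifying=(
                    SeriesSummary.from_values(qual_d) if qual_d else None
                ),
                angle_qualifying=(
                    SeriesSummary.from_values(qual_a) if qual_a else None
                ),
                distance_all=SeriesSummary.from_values(dists),
                angle_all=SeriesSummary.from_values(angles),
            )
        )
    return records, summaries


# ---------------------------------------------------------------------------
# contacts, hydrogen bonds, distances
# ---------------------------------------------------------------------------

def close_contact_fraction(
    ensemble: Ensemble,
    ligand_partition: str = "ligand1",
    cutoff: float = CONTACT_CUTOFF,
    include_zero: bool = False,
) -> ContactProfile:
    """Fraction of frames each receptor residue sits within ``cutoff`` of the ligand.

    The per-frame criterion is minimum heavy-atom distance strictly below the
    cutoff.  Residues never in contact are omitted unless ``include_zero``.
    """
    top = ensemble.topology
    lig_idx = top.partition_indices(ligand_partition)
    if lig_idx.size == 0:
        raise GeometryError(f"partition {ligand_partition!r} has no atoms")
    heavy = top.heavy_mask()
    lig_idx = lig_idx[heavy[lig_idx]]
    rec_idx = top.partition_indices("receptor")
    rec_idx = rec_idx[heavy[rec_idx]]
    residue_keys = sorted({top.residue_of(int(i)) for i in rec_idx}, key=lambda k: (k[0], k[1]))
    res_atoms = {
        key: np.array([i for i in rec_idx if top.residue_of(int(i)) == key])
        for key in residue_keys
    }
    counts = {key: 0 for key in residue_keys}
    for frame in ensemble.frames:
        lig_xyz = frame.coordinates[lig_idx]
        for key, idx in res_atoms.items():
            dmin = cdist(frame.coordinates[idx], lig_xyz).min()
            if dmin < cutoff:
                counts[key] += 1
    fractions = {
        key: counts[key] / ensemble.n_frames
        for key in residue_keys
        if include_zero or counts[key] > 0
    }
    return ContactProfile(
        fractions=fractions,
        cutoff=cutoff,
        ligand_partition=ligand_partition,
        n_frames=ensemble.n_frames,
    )


def _bonded_hydrogens(topology: Topology, heavy: int) -> list[int]:
    out = []
    for i, j in topology.bonds:
        if i == heavy and topology.atoms[j].element.upper() == "H":
            out.append(j)
        elif j == heavy and topology.atoms[i].element.upper() == "H":
            out.append(i)
    return out


def hydrogen_bonds(
    ensemble: Ensemble,
    donors: Sequence[int],
    acceptors: Sequence[int],
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
    use_angle: bool = True,
) -> list[HBondRecord]:
    """Occupancy and mean geometry per donor-acceptor pair.

    A frame satisfies the bond when the heavy-atom distance is below ``d_cut``
    and (in angle mode) the best donor-H-acceptor angle is at least
    ``angle_cut`` degrees.  Reported distance/angle are means over satisfying
    frames; pairs never satisfied report occupancy 0 and all-frame means.
    """
    top = ensemble.topology
    records: list[HBondRecord] = []
    for d in donors:
        hydrogens = _bonded_hydrogens(top, int(d))
        if use_angle and not hydrogens:
            raise GeometryError(
                f"donor atom {top.atoms[int(d)].serial} has no bonded hydrogen; "
                "required for angle screening"
            )
        for a in acceptors:
            if int(a) == int(d):
                continue
            dists, angles, hits = [], [], 0
            for frame in ensemble.frames:
                xyz = frame.coordinates
                dist = float(np.linalg.norm(xyz[int(d)] - xyz[int(a)]))
                if use_angle:
                    best = 0.0
                    for h in hydrogens:
                        v1 = xyz[int(d)] - xyz[h]
                        v2 = xyz[int(a)] - xyz[h]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        best = max(
                            best,
                            math.degrees(math.acos(min(1.0, max(-1.0, cosang)))),
                        )
                    angle = best
                else:
                    angle = float("nan")
                ok = dist < d_cut and ((not use_angle) or angle >= angle_cut)
                if ok:
                    hits += 1
                    dists.append(dist)
                    angles.append(angle)
            if hits:
                mean_d = float(np.mean(dists))
                mean_a = float(np.mean(angles)) if use_angle else float("nan")
            else:
                all_d = [
                    float(np.linalg.norm(f.coordinates[int(d)] - f.coordinates[int(a)]))
                    for f in ensemble.frames
                ]
                mean_d = float(np.mean(all_d))
                mean_a = float("nan")
            records.append(
                HBondRecord(
                    donor_atom=int(d),
                    acceptor_atom=int(a),
                    heavy_atom_distance=mean_d,
                    donor_angle=mean_a,
                    occupancy=hits / ensemble.n_frames,
                )
            )
    return records


def distance_series(
    ensemble: Ensemble, atom_a: int, atom_b: int
) -> SeriesSummary:
    """Mean +/- sample std of the per-frame distance between two atoms."""
    if atom_a == atom_b:
        raise GeometryError("distance series needs two distinct atoms")
    values = [
        float(np.linalg.norm(f.coordinates[atom_a] - f.coordinates[atom_b]))
        for f in ensemble.frames
    ]
    return SeriesSummary.from_values(values)
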