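"""Synthetic receptor-ligand ensembles with known ground truth.

Builds a miniature binding pocket from template residues (aromatic six-ring
side-chain analogues, a donor analogue, aliphatic spacers) plus one or two
rigid two-ring ligands, places ligand rings to hit requested stacking
geometries exactly in the base frame, and jitters the base frame with
i.i.d. isotropic Gaussian noise (optionally plus a per-molecule rigid-body
drift walk) to emulate an equilibrated trajectory.

The jitter is deliberately NOT a physical model: it provides just enough
statistical structure to validate estimators of means, fractions and signs.
Randomness uses the counter-based Philox generator, so ensembles are
reproducible bit-for-bit across platforms for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from coopbind import geometry
from coopbind.model_io import AtomRecord, Ensemble, Frame, Topology

RING_RADIUS = 1.39  # A, aromatic C-C ring circumradius


class SyntheticSpecError(ValueError):
    """Raised for infeasible or invalid generator specifications."""


# name -> (element, rmin_half, epsilon, born_radius)
ATOM_TYPES = {
    "CA": ("C", 1.908, 0.0860, 1.70),
    "CT": ("C", 1.908, 0.1094, 1.70),
    "N": ("N", 1.824, 0.1700, 1.55),
    "H": ("H", 0.600, 0.0157, 1.20),
    "O": ("O", 1.661, 0.2100, 1.50),
}

# polar-pairs charge scheme (elementary units); neutral scheme is all zero
POLAR_CHARGES = {"N": -0.40, "H": 0.40, "O": -0.30, "C7": 0.30}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic arm."""

    seed: int = 0
    n_frames: int = 10
    jitter_sigma: float = 0.1
    receptor_n_residues: int = 4
    n_aromatic_residues: int = 1
    n_ligands: int = 1
    stacking_targets: list[tuple[float, float]] = field(
        default_factory=lambda: [(4.5, 0.0)]
    )
    charge_scheme: str = "neutral"
    drift: float = 0.0
    hbond_target: float | None = None
    ligand_offsets: list[tuple[float, float, float]] | None = None
    min_separation: float = 1.5

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SyntheticSpecError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise SyntheticSpecError("jitter_sigma must be >= 0")
        if not 4 <= self.receptor_n_residues <= 30:
            raise SyntheticSpecError("receptor_n_residues must be in [4, 30]")
        if self.n_aromatic_residues > self.receptor_n_residues:
            raise SyntheticSpecError("more aromatic residues than residues")
        if self.n_ligands not in (1, 2):
            raise SyntheticSpecError("n_ligands must be 1 or 2")
        if self.charge_scheme not in ("neutral", "polar-pairs"):
            raise SyntheticSpecError(f"unknown charge scheme {self.charge_scheme!r}")
        if len(self.stacking_targets) > self.n_ligands:
            raise SyntheticSpecError("more stacking targets than ligands")
        for d, a in self.stacking_targets:
            if d <= 0 or not 0 <= a <= 90:
                raise SyntheticSpecError(f"infeasible stacking target ({d}, {a})")


@dataclass
class GroundTruthManifest:
    """Per-frame true geometry and design facts of a generated ensemble."""

    seed: int
    n_frames: int
    jitter_sigma: float
    stacking_pairs: list[dict]  # receptor/ligand ring atoms + per-frame truth
    contact_indicators: dict[str, list[int]]  # residue key -> per-frame 0/1
    contact_cutoff: float
    hbond_pairs: list[dict]
    designed_ligand1_distance: float | None
    attractive_vdw: bool

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_frames": self.n_frames,
            "jitter_sigma": self.jitter_sigma,
            "stacking_pairs": self.stacking_pairs,
            "contact_indicators": self.contact_indicators,
            "contact_cutoff": self.contact_cutoff,
            "hbond_pairs": self.hbond_pairs,
            "designed_ligand1_distance": self.designed_ligand1_distance,
            "attractive_vdw": self.attractive_vdw,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _hexagon(center: np.ndarray, radius: float = RING_RADIUS) -> np.ndarray:
    ang = np.arange(6) * math.pi / 3.0
    ring = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1
    )
    return ring + center


def _rotation_about_x(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


class _Builder:
    def __init__(self, charge_scheme: str) -> None:
        self.names: list[str] = []
        self.types: list[str] = []
        self.resnums: list[int] = []
        self.resnames: list[str] = []
        self.chains: list[str] = []
        self.partitions: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []
        self.charge_scheme = charge_scheme

    def add_atom(
        self,
        name: str,
        atype: str,
        xyz: np.ndarray,
        resnum: int,
        resname: str,
        chain: str,
        partition: str,
    ) -> int:
        self.names.append(name)
        self.types.append(atype)
        self.coords.append(np.asarray(xyz, dtype=float))
        self.resnums.append(resnum)
        self.resnames.append(resname)
        self.chains.append(chain)
        self.partitions.append(partition)
        return len(self.names) - 1

    def charge_for(self, name: str, atype: str) -> float:
        if self.charge_scheme == "neutral":
            return 0.0
        return POLAR_CHARGES.get(name, POLAR_CHARGES.get(atype, 0.0))

    def finish(self) -> tuple[Topology, Frame]:
        atoms = []
        for i, (name, atype) in enumerate(zip(self.names, self.types)):
            element, rmh, eps, born = ATOM_TYPES[atype]
            atoms.append(
                AtomRecord(
                    serial=i + 1,
                    name=name,
                    element=element,
                    residue_number=self.resnums[i],
                    residue_name=self.resnames[i],
                    chain_id=self.chains[i],
                    partial_charge=self.charge_for(name, atype),
                    lj_rmin_half=rmh,
                    lj_epsilon=eps,
                    born_radius=born,
                    partition=self.partitions[i],
                )
            )
        top = Topology(atoms=atoms, bonds=frozenset(self.bonds))
        return top, Frame(model_index=1, coordinates=np.vstack(self.coords))


def _add_ring(
    b: _Builder,
    center: np.ndarray,
    resnum: int,
    resname: str,
    chain: str,
    partition: str,
    prefix: str = "C",
) -> list[int]:
    idx = [
        b.add_atom(f"{prefix}{k + 1}", "CA", xyz, resnum, resname, chain, partition)
        for k, xyz in enumerate(_hexagon(center))
    ]
    for k in range(6):
        b.bonds.append((idx[k], idx[(k + 1) % 6]))
    return idx


def build_toy_complex(spec: SyntheticSpec) -> tuple[Topology, Frame]:
    """Construct the base-frame complex described by ``spec``.

    Receptor residues sit on a line along x at 8 A spacing with aromatic
    rings lying in the z = 0 plane; ligand k's first ring is placed over
    aromatic residue k's ring at the k-th stacking target (centroid offset
    along +z, plane tilted about x), so the base-frame ring geometry meets
    the target exactly.  Steric feasibility (no inter-molecule atom pair
    below ``min_separation``) is enforced.
    """
    b = _Builder(spec.charge_scheme)
    aromatic_rings: list[list[int]] = []

    for i in range(spec.receptor_n_residues):
        resnum = i + 1
        center = np.array([8.0 * i, 0.0, 0.0])
        if i < spec.n_aromatic_residues:
            ring = _add_ring(b, center, resnum, "ARO", "A", "receptor")
            cb = b.add_atom(
                "CB", "CT", center + np.array([RING_RADIUS + 1.5, 0, 0]),
                resnum, "ARO", "A", "receptor",
            )
            b.bonds.append((ring[0], cb))
            aromatic_rings.append(ring)
        elif i == spec.n_aromatic_residues:
            base = center + np.array([0.0, -5.0, 0.0])
            cb = b.add_atom("CB", "CT", base, resnum, "DON", "A", "receptor")
            n = b.add_atom(
                "N", "N", base + np.array([1.47, 0, 0]), resnum, "DON", "A",
                "receptor",
            )
            h = b.add_atom(
                "H", "H", base + np.array([2.48, 0, 0]), resnum, "DON", "A",
                "receptor",
            )
            b.bonds.append((cb, n))
            b.bonds.append((n, h))
        else:
            b.add_atom(
                "CB", "CT", center + np.array([0.0, -5.0, 0.0]), resnum,
                "ALA", "A", "receptor",
            )

    ligand_info = []
    for k in range(spec.n_ligands):
        partition = f"ligand{k + 1}"
        chain = "B" if k == 0 else "C"
        resname = f"LG{k + 1}"
        if k < len(spec.stacking_targets):
            dist, angle = spec.stacking_targets[k]
        else:
            dist, angle = 4.0 + 4.0 * k, 0.0
        aro = aromatic_rings[min(k, len(aromatic_rings) - 1)] if aromatic_rings else None
        if aro is not None:
            target_centroid = np.mean([b.coords[i] for i in aro], axis=0) + np.array(
                [0.0, 0.0, dist]
            )
        else:
            target_centroid = np.array([0.0, 0.0, dist])
        rot = _rotation_about_x(angle)
        offset = np.zeros(3)
        if spec.ligand_offsets is not None and k < len(spec.ligand_offsets):
            offset = np.asarray(spec.ligand_offsets[k], dtype=float)

        def place(local: np.ndarray) -> np.ndarray:
            return rot @ local + target_centroid + offset

        ring_a = [
            b.add_atom(f"C{j + 1}", "CA", place(xyz), 1, resname, chain, partition)
            for j, xyz in enumerate(_hexagon(np.zeros(3)))
        ]
        for j in range(6):
            b.bonds.append((ring_a[j], ring_a[(j + 1) % 6]))
        linker = b.add_atom(
            "C7", "CT", place(np.array([RING_RADIUS + 1.5, 0, 0])), 1, resname,
            chain, partition,
        )
        oxy = b.add_atom(
            "O1", "O", place(np.array([RING_RADIUS + 1.5, 1.4, 0])), 1,
            resname, chain, partition,
        )
        ring_b = [
            b.add_atom(f"C{j + 8}", "CA", place(xyz), 1, resname, chain, partition)
            for j, xyz in enumerate(_hexagon(np.array([2 * RING_RADIUS + 3.0, 0, 0])))
        ]
        for j in range(6):
            b.bonds.append((ring_b[j], ring_b[(j + 1) % 6]))
        b.bonds.append((ring_a[0], linker))
        b.bonds.append((linker, oxy))
        b.bonds.append((linker, ring_b[3]))
        ligand_info.append({"ring_a": ring_a, "ring_b": ring_b, "oxygen": oxy})

    # aim the donor N-H at ligand1's oxygen at the requested length
    if spec.hbond_target is not None:
        if spec.n_aromatic_residues >= spec.receptor_n_residues:
            raise SyntheticSpecError(
                "hbond_target needs a non-aromatic donor residue"
            )
        if not ligand_info:
            raise SyntheticSpecError("hbond_target needs a ligand")
        names = b.names
        n_idx = next(
            i for i, (nm, p) in enumerate(zip(names, b.partitions))
            if nm == "N" and p == "receptor"
        )
        h_idx = n_idx + 1
        cb_idx = n_idx - 1
        o_pos = b.coords[ligand_info[0]["oxygen"]]
        u = np.array([0.0, 1.0, 0.0])
        b.coords[n_idx] = o_pos + spec.hbond_target * u
        b.coords[h_idx] = b.coords[n_idx] - 1.01 * u
        b.coords[cb_idx] = b.coords[n_idx] + 1.47 * u

    top, frame = b.finish()
    _check_feasibility(top, frame, spec.min_separation)
    return top, frame


def _check_feasibility(top: Topology, frame: Frame, min_sep: float) -> None:
    from scipy.spatial.distance import pdist, squareform

    parts = np.array([a.partition for a in top.atoms])
    d = squareform(pdist(frame.coordinates))
    cross = parts[:, None] != parts[None, :]
    np.fill_diagonal(d, np.inf)
    worst = d[cross].min() if cross.any() else np.inf
    if worst < min_sep:
        raise SyntheticSpecError(
            f"infeasible construction: inter-molecule atoms {worst:.2f} A apart "
            f"(< {min_sep} A)"
        )


def generate_ensemble(
    topology: Topology, base: Frame, spec: SyntheticSpec
) -> tuple[Ensemble, GroundTruthManifest]:
    """Jitter the base frame into an ensemble plus its ground-truth manifest.

    Frame k is the base frame plus i.i.d. N(0, sigma^2) displacements per
    coordinate, optionally plus a per-molecule rigid translation performing a
    Gaussian random walk of step ``spec.drift``.  The manifest records the
    ring geometry and contact indicators actually realized in each frame.
    """
    rng = np.random.Generator(np.random.Philox(spec.seed))
    n_atoms = topology.n_atoms
    parts = [a.partition for a in topology.atoms]
    unique_parts = sorted(set(parts))
    part_idx = {
        p: np.array([i for i, q in enumerate(parts) if q == p])
        for p in unique_parts
    }
    frames = []
    drift_state = {p: np.zeros(3) for p in unique_parts}
    for k in range(spec.n_frames):
        xyz = base.coordinates.copy()
        if spec.jitter_sigma > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_sigma, size=(n_atoms, 3))
        if spec.drift > 0:
            for p in unique_parts:
                drift_state[p] = drift_state[p] + rng.normal(0.0, spec.drift, 3)
                xyz[part_idx[p]] += drift_state[p]
        frames.append(Frame(model_index=k + 1, coordinates=xyz))
    ensemble = Ensemble(topology=topology, frames=frames)

    rings = geometry.perceive_rings(topology, base)
    receptor_rings = [r for r in rings if r.owner_partition == "receptor"]
    stacking_pairs = []
    for k in range(len(spec.stacking_targets)):
        lig_rings = [r for r in rings if r.owner_partition == f"ligand{k + 1}"]
        aro = receptor_rings[min(k, len(receptor_rings) - 1)] if receptor_rings else None
        if aro is None or not lig_rings:
            continue
        lig_ring = lig_rings[0]
        dists, angles = [], []
        for f in frames:
            d, a = geometry.ring_pair_geometry(f, aro, lig_ring)
            dists.append(d)
            angles.append(a)
        stacking_pairs.append(
            {
                "receptor_ring_atoms": list(aro.member_atoms),
                "ligand_ring_atoms": list(lig_ring.member_atoms),
                "target_distance": spec.stacking_targets[k][0],
                "target_angle": spec.stacking_targets[k][1],
                "frame_distances": dists,
                "frame_angles": angles,
            }
        )

    cutoff = geometry.CONTACT_CUTOFF
    heavy = topology.heavy_mask()
    lig1 = topology.partition_indices("ligand1")
    lig1 = lig1[heavy[lig1]]
    indicators: dict[str, list[int]] = {}
    if lig1.size:
        rec = topology.partition_indices("receptor")
        rec = rec[heavy[rec]]
        by_res: dict[tuple[str, int, str], np.ndarray] = {}
        for i in rec:
            by_res.setdefault(topology.residue_of(int(i)), [])
        for i in rec:
            by_res[topology.residue_of(int(i))].append(int(i))  # type: ignore[union-attr]
        for key, idx in by_res.items():
            flags = []
            arr = np.asarray(idx)
            for f in frames:
                dmin = np.min(
                    np.linalg.norm(
                        f.coordinates[arr][:, None, :] - f.coordinates[lig1][None],
                        axis=2,
                    )
                )
                flags.append(int(dmin < cutoff))
            indicators["/".join(map(str, key))] = flags

    hbond_pairs = []
    if spec.hbond_target is not None:
        n_idx = next(
            i for i, a in enumerate(topology.atoms)
            if a.name == "N" and a.partition == "receptor"
        )
        o_idx = next(
            i for i, a in enumerate(topology.atoms)
            if a.name == "O1" and a.partition == "ligand1"
        )
        hbond_pairs.append(
            {
                "donor": n_idx,
                "acceptor": o_idx,
                "target_length": spec.hbond_target,
            }
        )

    manifest = GroundTruthManifest(
        seed=spec.seed,
        n_frames=spec.n_frames,
        jitter_sigma=spec.jitter_sigma,
        stacking_pairs=stacking_pairs,
        contact_indicators=indicators,
        contact_cutoff=cutoff,
        hbond_pairs=hbond_pairs,
        designed_ligand1_distance=(
            spec.stacking_targets[0][0] if spec.stacking_targets else None
        ),
        attractive_vdw=True,
    )
    return ensemble, manifest


@dataclass
class StudyBundle:
    """Two paired arms (normal / cooperative) plus design metadata."""

    arms: dict[str, tuple[Topology, Ensemble, GroundTruthManifest]]
    designed_stronger_arm: str


def make_two_arm_study(
    spec_normal: SyntheticSpec, spec_cooperative: SyntheticSpec
) -> StudyBundle:
    """Build paired single-ligand and two-ligand arms on one receptor template.

    The designed "stronger binding" arm is the one whose first stacking
    target puts ligand 1 closer to its aromatic partner.
    """
    for attr in ("receptor_n_residues", "n_aromatic_residues", "charge_scheme"):
        if getattr(spec_normal, attr) != getattr(spec_cooperative, attr):
            raise SyntheticSpecError(
                f"receptor templates differ: {attr} mismatch "
                f"({getattr(spec_normal, attr)} vs {getattr(spec_cooperative, attr)})"
            )
    if spec_cooperative.n_ligands != 2:
        raise SyntheticSpecError("cooperative arm must have n_ligands = 2")
    arms = {}
    for label, spec in (("normal", spec_normal), ("cooperative", spec_cooperative)):
        top, base = build_toy_complex(spec)
        ens, manifest = generate_ensemble(top, base, spec)
        arms[label] = (top, ens, manifest)
    d_normal = spec_normal.stacking_targets[0][0]
    d_coop = spec_cooperative.stacking_targets[0][0]
    stronger = "cooperative" if d_coop < d_normal else "normal"
    return StudyBundle(arms=arms, designed_stronger_arm=stronger)


def spec_from_dict(doc: dict) -> SyntheticSpec:
    """Build a spec from a parsed YAML/JSON mapping (CLI entry point)."""
    doc = dict(doc)
    if "stacking_targets" in doc:
        doc["stacking_targets"] = [tuple(t) for t in doc["stacking_targets"]]
    if doc.get("ligand_offsets") is not None:
        doc["ligand_offsets"] = [tuple(t) for t in doc["ligand_offsets"]]
    return SyntheticSpec(**doc)
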