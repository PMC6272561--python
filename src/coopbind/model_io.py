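"""Structure and parameter I/O.

Ensembles are multi-model PDB files (wwPDB v3.3 fixed columns, MODEL/ENDMDL
delimited); per-atom force-field parameters travel in a JSON sidecar keyed by
atom serial order.  Coordinates are Angstrom, charges elementary units,
energies kcal/mol throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

PARTITIONS = ("receptor", "ligand1", "ligand2", "cofactor")

#: default 1-4 nonbonded scale factors (applied when the sidecar omits them)
DEFAULT_EE_SCALE = 1.0 / 1.2
DEFAULT_VDW_SCALE = 0.5


class TopologyError(ValueError):
    """Raised when a topology sidecar is inconsistent or incomplete."""


class EnsembleParseError(ValueError):
    """Raised when a structure file cannot be parsed against its topology."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom's identity and nonbonded parameters."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    partial_charge: float
    lj_rmin_half: float
    lj_epsilon: float
    born_radius: float
    partition: str

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise TopologyError(f"atom serial must be positive, got {self.serial}")
        if self.lj_rmin_half <= 0:
            raise TopologyError(f"atom {self.serial}: lj_rmin_half must be > 0")
        if self.lj_epsilon < 0:
            raise TopologyError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if self.born_radius <= 0:
            raise TopologyError(f"atom {self.serial}: born_radius must be > 0")
        if self.partition not in PARTITIONS:
            raise TopologyError(
                f"atom {self.serial}: unknown partition {self.partition!r}; "
                f"expected one of {PARTITIONS}"
            )


def _normalize_pairs(pairs: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    out = set()
    for i, j in pairs:
        if i == j:
            raise TopologyError(f"self-pair ({i},{i}) is not allowed")
        out.add((min(i, j), max(i, j)))
    return frozenset(out)


@dataclass
class Topology:
    """Atoms, bond graph, nonbonded bookkeeping and molecule partitions.

    ``bonds``, ``exclusions_12_13`` and ``scaled_14`` hold unordered pairs of
    0-based atom indices.  Exclusions (graph distance 1 and 2) and scaled 1-4
    pairs (graph distance 3) are derived from the bond graph when not given.
    """

    atoms: list[AtomRecord]
    bonds: frozenset[tuple[int, int]] = frozenset()
    exclusions_12_13: frozenset[tuple[int, int]] = None  # type: ignore[assignment]
    scaled_14: frozenset[tuple[int, int]] = None  # type: ignore[assignment]
    ring_definitions: list[list[int]] = field(default_factory=list)
    ee_scale: float = DEFAULT_EE_SCALE
    vdw_scale: float = DEFAULT_VDW_SCALE

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise TopologyError("topology must contain at least one atom")
        self.bonds = _normalize_pairs(self.bonds)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"bond ({i},{j}) references a missing atom")
        derived_excl, derived_14 = derive_exclusions(n, self.bonds)
        if self.exclusions_12_13 is None:
            self.exclusions_12_13 = derived_excl
        else:
            self.exclusions_12_13 = _normalize_pairs(self.exclusions_12_13)
        if self.scaled_14 is None:
            self.scaled_14 = derived_14
        else:
            self.scaled_14 = _normalize_pairs(self.scaled_14)
        for pair in self.exclusions_12_13 | self.scaled_14:
            for k in pair:
                if not (0 <= k < n):
                    raise TopologyError(f"pair {pair} references a missing atom")
        for ring in self.ring_definitions:
            for k in ring:
                if not (0 <= k < n):
                    raise TopologyError(f"ring {ring} references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def partition_indices(self, partition: str) -> np.ndarray:
        """0-based indices of all atoms in ``partition`` (topology order)."""
        if partition not in PARTITIONS:
            raise TopologyError(f"unknown partition {partition!r}")
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.partition == partition],
            dtype=int,
        )

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_number, residue_name) keys in atom order."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_number, a.residue_name))
        return list(seen)

    def residue_of(self, index: int) -> tuple[str, int, str]:
        a = self.atoms[index]
        return (a.chain_id, a.residue_number, a.residue_name)

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.element.upper() != "H" for a in self.atoms], dtype=bool)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def born_radii(self) -> np.ndarray:
        return np.array([a.born_radius for a in self.atoms], dtype=float)

    def lj_params(self) -> tuple[np.ndarray, np.ndarray]:
        rmh = np.array([a.lj_rmin_half for a in self.atoms], dtype=float)
        eps = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        return rmh, eps


def derive_exclusions(
    n_atoms: int, bonds: Iterable[tuple[int, int]]
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """1-2/1-3 exclusion pairs and 1-4 scaled pairs from the bond graph.

    A pair is excluded if its bond-graph distance is 1 or 2, and scaled if the
    distance is exactly 3.  Symmetric and idempotent by construction.
    """
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in _normalize_pairs(bonds):
        adj[i].add(j)
        adj[j].add(i)
    excluded: set[tuple[int, int]] = set()
    scaled: set[tuple[int, int]] = set()
    for i in range(n_atoms):
        # breadth-first out to distance 3
        dist = {i: 0}
        frontier = [i]
        for d in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for j, d in dist.items():
            if j <= i:
                continue
            if d in (1, 2):
                excluded.add((i, j))
            elif d == 3:
                scaled.add((i, j))
    return frozenset(excluded), frozenset(scaled)


@dataclass
class Frame:
    """One coordinate snapshot (model) of an ensemble."""

    model_index: int
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise EnsembleParseError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise EnsembleParseError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Ensemble:
    """An ordered list of frames sharing one topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise EnsembleParseError("ensemble must contain at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.n_atoms != n:
                raise EnsembleParseError(
                    f"frame {f.model_index} has {f.n_atoms} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# topology sidecar (JSON)
# ---------------------------------------------------------------------------

_REQUIRED_ATOM_KEYS = (
    "serial",
    "name",
    "element",
    "resnum",
    "resname",
    "chain",
    "charge",
    "rmin_half",
    "epsilon",
    "born_radius",
    "partition",
)


def read_topology(path: str | Path) -> Topology:
    """Load the JSON parameter sidecar.

    Bonds and rings are given as atom serial pairs/lists and mapped to 0-based
    indices by the serial order in ``atoms``.  Exclusions and 1-4 pairs are
    always derived from the bond graph.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if "atoms" not in raw or not raw["atoms"]:
        raise TopologyError(f"{path}: sidecar has no atoms")
    atoms = []
    for rec in raw["atoms"]:
        missing = [k for k in _REQUIRED_ATOM_KEYS if k not in rec]
        if missing:
            raise TopologyError(
                f"{path}: atom record {rec.get('serial', '?')} is missing "
                f"required keys {missing}"
            )
        atoms.append(
            AtomRecord(
                serial=int(rec["serial"]),
                name=str(rec["name"]),
                element=str(rec["element"]),
                residue_number=int(rec["resnum"]),
                residue_name=str(rec["resname"]),
                chain_id=str(rec["chain"]),
                partial_charge=float(rec["charge"]),
                lj_rmin_half=float(rec["rmin_half"]),
                lj_epsilon=float(rec["epsilon"]),
                born_radius=float(rec["born_radius"]),
                partition=str(rec["partition"]),
            )
        )
    serial_to_index: dict[int, int] = {}
    for i, a in enumerate(atoms):
        if a.serial in serial_to_index:
            raise TopologyError(f"{path}: duplicate atom serial {a.serial}")
        serial_to_index[a.serial] = i

    def lookup(serial: int) -> int:
        try:
            return serial_to_index[int(serial)]
        except KeyError:
            raise TopologyError(f"{path}: unknown atom serial {serial}") from None

    bonds = frozenset(
        (lookup(i), lookup(j)) for i, j in raw.get("bonds", [])
    )
    rings = [[lookup(s) for s in ring] for ring in raw.get("rings", [])]
    factors = raw.get("scaled_14_factors", {})
    return Topology(
        atoms=atoms,
        bonds=bonds,
        ring_definitions=rings,
        ee_scale=float(factors.get("ee_scale", DEFAULT_EE_SCALE)),
        vdw_scale=float(factors.get("vdw_scale", DEFAULT_VDW_SCALE)),
    )


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write the JSON sidecar read back by :func:`read_topology`."""
    serials = [a.serial for a in topology.atoms]
    doc = {
        "atoms": [
            {
                "serial": a.serial,
                "name": a.name,
                "element": a.element,
                "resnum": a.residue_number,
                "resname": a.residue_name,
                "chain": a.chain_id,
                "charge": a.partial_charge,
                "rmin_half": a.lj_rmin_half,
                "epsilon": a.lj_epsilon,
                "born_radius": a.born_radius,
                "partition": a.partition,
            }
            for a in topology.atoms
        ],
        "bonds": sorted([serials[i], serials[j]] for i, j in topology.bonds),
        "rings": [[serials[i] for i in ring] for ring in topology.ring_definitions],
        "scaled_14_factors": {
            "ee_scale": topology.ee_scale,
            "vdw_scale": topology.vdw_scale,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

_COORD_MIN = -999.999
_COORD_MAX = 9999.999


def _parse_atom_line(line: str, lineno: int) -> tuple[int, np.ndarray]:
    if len(line) < 54:
        raise EnsembleParseError(f"line {lineno}: truncated ATOM/HETATM record")
    altloc = line[16]
    if altloc not in (" ", ""):
        raise EnsembleParseError(
            f"line {lineno}: alternate location indicator {altloc!r} not supported"
        )
    icode = line[26]
    if icode not in (" ", ""):
        raise EnsembleParseError(
            f"line {lineno}: insertion code {icode!r} not supported"
        )
    try:
        serial = int(line[6:11])
    except ValueError:
        raise EnsembleParseError(
            f"line {lineno}: unparsable atom serial {line[6:11]!r}"
        ) from None
    try:
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
    except ValueError:
        raise EnsembleParseError(
            f"line {lineno}: unparsable coordinate field in {line[30:54]!r}"
        ) from None
    return serial, xyz


def _check_model(
    serials: list[int],
    coords: list[np.ndarray],
    topology: Topology,
    model_index: int,
) -> Frame:
    expected = [a.serial for a in topology.atoms]
    for pos, exp in enumerate(expected):
        if pos >= len(serials):
            raise EnsembleParseError(
                f"model {model_index}: atom serial {exp} missing "
                f"(model has {len(serials)} atoms, topology has {len(expected)})"
            )
        if serials[pos] != exp:
            raise EnsembleParseError(
                f"model {model_index}: atom serial mismatch at position {pos + 1}: "
                f"file has {serials[pos]}, topology expects {exp}"
            )
    if len(serials) > len(expected):
        raise EnsembleParseError(
            f"model {model_index}: unexpected extra atom serial "
            f"{serials[len(expected)]} beyond topology ({len(expected)} atoms)"
        )
    return Frame(model_index=model_index, coordinates=np.vstack(coords))


def read_ensemble(path: str | Path, topology: Topology) -> Ensemble:
    """Read a (multi-)model PDB file against ``topology``.

    Atom matching is positional with the serial column as a checked
    redundancy; a model whose atoms do not line up with the topology raises
    :class:`EnsembleParseError` naming the first offending serial.
    """
    frames: list[Frame] = []
    serials: list[int] = []
    coords: list[np.ndarray] = []
    model_index: int | None = None
    in_model = False
    saw_model_records = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_records = True
                in_model = True
                try:
                    model_index = int(line.split()[1])
                except (IndexError, ValueError):
                    model_index = len(frames) + 1
                serials, coords = [], []
            elif rec == "ENDMDL":
                frames.append(
                    _check_model(serials, coords, topology, model_index or 0)
                )
                in_model = False
                serials, coords = [], []
            elif rec in ("ATOM", "HETATM"):
                serial, xyz = _parse_atom_line(line.rstrip("\n"), lineno)
                serials.append(serial)
                coords.append(xyz)
    if in_model:
        raise EnsembleParseError(f"{path}: MODEL record without matching ENDMDL")
    if not saw_model_records:
        if not serials:
            raise EnsembleParseError(f"{path}: no ATOM/HETATM records found")
        frames.append(_check_model(serials, coords, topology, 1))
    if not frames:
        raise EnsembleParseError(f"{path}: file contains no models")
    return Ensemble(topology=topology, frames=frames)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL/ENDMDL pair per frame).

    Coordinates are emitted at fixed %8.3f precision; values outside the
    representable field range raise :class:`EnsembleParseError`.
    """
    top = ensemble.topology
    lines: list[str] = []
    for k, frame in enumerate(ensemble.frames, start=1):
        if np.any(frame.coordinates < _COORD_MIN) or np.any(
            frame.coordinates > _COORD_MAX
        ):
            raise EnsembleParseError(
                f"frame {k}: coordinate outside PDB fixed-width range "
                f"[{_COORD_MIN}, {_COORD_MAX}]"
            )
        lines.append(f"MODEL     {k:4d}")
        for a, xyz in zip(top.atoms, frame.coordinates):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
                f"{(a.chain_id or ' '):1.1s}{a.residue_number:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
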