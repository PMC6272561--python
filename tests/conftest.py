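"""Shared fixtures: tiny hand-built systems and synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from coopbind.model_io import AtomRecord, Ensemble, Frame, Topology


def make_atoms(
    n: int,
    element: str = "C",
    partition: str = "receptor",
    charge: float = 0.0,
    rmin_half: float = 1.9,
    epsilon: float = 0.1,
    born_radius: float = 1.7,
    residue_number: int | list[int] | None = None,
    chain: str = "A",
) -> list[AtomRecord]:
    """Uniform atom records for ad-hoc test topologies."""
    if residue_number is None:
        residue_number = [1] * n
    elif isinstance(residue_number, int):
        residue_number = [residue_number] * n
    return [
        AtomRecord(
            serial=i + 1,
            name=f"X{i + 1}",
            element=element,
            residue_number=residue_number[i],
            residue_name="RES",
            chain_id=chain,
            partial_charge=charge,
            lj_rmin_half=rmin_half,
            lj_epsilon=epsilon,
            born_radius=born_radius,
            partition=partition,
        )
        for i in range(n)
    ]


def single_frame_ensemble(topology: Topology, coords: np.ndarray) -> Ensemble:
    return Ensemble(topology=topology, frames=[Frame(1, coords)])


def multi_frame_ensemble(topology: Topology, coord_list) -> Ensemble:
    frames = [Frame(k + 1, np.asarray(c)) for k, c in enumerate(coord_list)]
    return Ensemble(topology=topology, frames=frames)


@pytest.fixture
def hexagon():
    """Regular hexagon of circumradius 1.39 A in the z=0 plane."""
    ang = np.arange(6) * np.pi / 3.0
    return np.stack(
        [1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)], axis=1
    )


@pytest.fixture
def benzene_topology():
    atoms = make_atoms(6)
    bonds = frozenset((i, (i + 1) % 6) for i in range(6))
    return Topology(atoms=atoms, bonds=bonds)


@pytest.fixture
def toy_spec():
    from coopbind.synth import SyntheticSpec

    return SyntheticSpec(
        seed=7,
        n_frames=5,
        jitter_sigma=0.05,
        receptor_n_residues=4,
        n_aromatic_residues=1,
        n_ligands=1,
        stacking_targets=[(4.5, 20.0)],
        charge_scheme="polar-pairs",
        hbond_target=3.0,
    )


@pytest.fixture
def toy_system(toy_spec):
    from coopbind.synth import build_toy_complex

    return build_toy_complex(toy_spec)


@pytest.fixture
def toy_ensemble(toy_spec, toy_system):
    from coopbind.synth import generate_ensemble

    top, base = toy_system
    return generate_ensemble(top, base, toy_spec)
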