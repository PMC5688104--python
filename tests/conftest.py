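"""Shared fixtures: sequences, reference structures, mdtraj conversion."""

from __future__ import annotations

import numpy as np
import pytest

from pepscape.geometry import (THREE_LETTER, BackboneStructure, DihedralTrace,
                               PeptideSequence, build_from_dihedrals,
                               ideal_helix)


@pytest.fixture(scope="session")
def p53_sequence() -> PeptideSequence:
    return PeptideSequence("p53-WT", "QETFSDLWKLLP")


@pytest.fixture(scope="session")
def polyala20() -> PeptideSequence:
    return PeptideSequence("polyA20", "A" * 20)


@pytest.fixture(scope="session")
def alpha_helix_20(polyala20) -> BackboneStructure:
    return ideal_helix(polyala20)


@pytest.fixture(scope="session")
def ppii_helix_20(polyala20) -> BackboneStructure:
    return build_from_dihedrals(
        polyala20, DihedralTrace.uniform(20, -75.0, 145.0))


@pytest.fixture(scope="session")
def extended_20(polyala20) -> BackboneStructure:
    return build_from_dihedrals(
        polyala20, DihedralTrace.uniform(20, 180.0, 180.0))


def to_mdtraj(structures):
    """Convert structures (or an Ensemble) to an mdtraj Trajectory."""
    import mdtraj as md

    from pepscape.landscape import Ensemble

    if isinstance(structures, Ensemble):
        residues = structures.sequence.residues
        atoms = structures.atoms
        n_frames = structures.n_frames
    else:
        structures = list(structures)
        residues = structures[0].sequence.residues
        atoms = {k: np.stack([s.atoms[k] for s in structures])
                 for k in ("N", "CA", "C", "O")}
        n_frames = len(structures)

    top = md.Topology()
    chain = top.add_chain()
    elements = {"N": md.element.nitrogen, "CA": md.element.carbon,
                "C": md.element.carbon, "O": md.element.oxygen}
    for aa in residues:
        res = top.add_residue(THREE_LETTER[aa], chain)
        for name in ("N", "CA", "C", "O"):
            top.add_atom(name, elements[name], res)
    n = len(residues)
    xyz = np.concatenate(
        [np.stack([atoms[name][:, i] for name in ("N", "CA", "C", "O")],
                  axis=1) for i in range(n)], axis=1)
    assert xyz.shape == (n_frames, 4 * n, 3)
    return md.Trajectory(xyz / 10.0, top)   # mdtraj wants nm


def reference_dssp(structures) -> list[str]:
    """Reference DSSP labels via mdtraj, mapped onto our alphabet."""
    import mdtraj as md

    labels = md.compute_dssp(to_mdtraj(structures), simplified=False)
    return ["".join(row).replace(" ", "C").replace("B", "E")
            for row in labels]
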