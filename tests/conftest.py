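"""Shared fixtures: hand-built PDB texts, synthetic corpora, trained tables."""

import math

import numpy as np
import pytest
from hypothesis import settings

import igscore as ig

settings.register_profile("suite", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("suite")


PDB_LINE = ("ATOM  {serial:5d} {name:^4s} {res:3s} {chain:1s}{resseq:4d}"
            "    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}")


def make_pdb_text(atoms):
    """atoms: list of (atom_name, resname, chain, resseq, x, y, z, element)."""
    lines = []
    for k, (name, res, chain, resseq, x, y, z, elem) in enumerate(atoms, 1):
        fmt_name = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(PDB_LINE.format(serial=k, name=fmt_name, res=res, chain=chain,
                                     resseq=resseq, x=x, y=y, z=z, elem=elem))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_model(coords, resnames=None, atom_names=None, residue_indices=None,
               identifier="m"):
    """Build a StructureModel directly from coordinates."""
    coords = np.asarray(coords, float)
    n = len(coords)
    resnames = resnames or ["ALA"] * n
    atom_names = atom_names or ["CA"] * n
    residue_indices = residue_indices if residue_indices is not None else list(range(n))
    atoms = [
        ig.AtomSite(resnames[i], atom_names[i], residue_indices[i], "A",
                    float(coords[i][0]), float(coords[i][1]), float(coords[i][2]))
        for i in range(n)
    ]
    return ig.StructureModel(identifier, atoms)


def brute_force_pairs(model, min_separation, cutoff):
    """O(n²) double-loop oracle for qualifying-pair enumeration."""
    out = []
    atoms = model.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            if abs(a.residue_index - b.residue_index) < min_separation:
                continue
            d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            if d < cutoff:
                out.append((ig.PairTypeKey.make(a.atom_type, b.atom_type), d))
    return out


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def small_corpus():
    """20 compact synthetic natives, 60-100 residues."""
    rng = np.random.default_rng(42)
    return [
        ig.generate_native(ig.SyntheticSpec(
            n_residues=int(rng.integers(60, 101)), seed=int(rng.integers(2**31 - 1))))
        for _ in range(20)
    ]


@pytest.fixture(scope="session")
def trained_table(small_corpus):
    return ig.train(small_corpus, selection="ca_only")


@pytest.fixture(scope="session")
def tig_potential(trained_table):
    return ig.build_potential(trained_table, "TIG")


@pytest.fixture(scope="session")
def pmf_potential(trained_table):
    return ig.build_potential(trained_table, "PMF")
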