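"""PDB parsing and enumeration of scorable atom pairs.

A statistical potential consumes interatomic distances observed between
heavy atoms of the 20 standard amino acids.  This module reduces a PDB
file to that view: one chain, heavy atoms only, residues renumbered
gap-free in order of appearance (so sequence separation cannot be
inflated by author numbering gaps or insertion codes), and a single
conformer per atom when alternate locations are present.

Pair enumeration applies the two filters every downstream statistic
shares: a minimum sequence separation (default 4, i.e. pairs within
residues i..i+3 are excluded) and a strict distance cutoff (default
15.0 Å).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

log = logging.getLogger(__name__)

#: the closed alphabet of residue names a potential is trained on
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

DEFAULT_MIN_SEPARATION = 4
DEFAULT_CUTOFF = 15.0


class ChainNotFoundError(KeyError):
    """Requested chain id is absent from the file."""


class EmptyChainError(ValueError):
    """Chain contains no heavy atoms of standard residues."""


@dataclass(frozen=True)
class AtomSite:
    """One heavy atom: residue identity, chain-sequential index, coordinates (Å)."""

    residue_name: str
    atom_name: str
    residue_index: int
    chain_id: str
    x: float
    y: float
    z: float

    @property
    def atom_type(self) -> tuple[str, str]:
        return (self.residue_name, self.atom_name)


@dataclass
class StructureModel:
    """An ordered single-chain collection of :class:`AtomSite`."""

    identifier: str
    atoms: list[AtomSite] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return len({a.residue_index for a in self.atoms})

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float64 coordinate array."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=np.int64)

    def with_coords(self, coords: np.ndarray, identifier: str | None = None) -> "StructureModel":
        """Copy of the model with coordinates replaced (same atom identities)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [
            AtomSite(a.residue_name, a.atom_name, a.residue_index, a.chain_id,
                     float(p[0]), float(p[1]), float(p[2]))
            for a, p in zip(self.atoms, coords)
        ]
        return StructureModel(identifier or self.identifier, atoms)


@dataclass(frozen=True, order=True)
class PairTypeKey:
    """Canonicalized pair of atom types; key(a, b) == key(b, a).

    ``first`` and ``second`` are ``(residue_name, atom_name)`` tuples with
    ``first <= second`` lexicographically.
    """

    first: tuple[str, str]
    second: tuple[str, str]

    @classmethod
    def make(cls, a: tuple[str, str], b: tuple[str, str]) -> "PairTypeKey":
        return cls(a, b) if a <= b else cls(b, a)

    def __str__(self) -> str:  # "CYS:CA-CYS:CA"
        return f"{format_atom_type(self.first)}-{format_atom_type(self.second)}"


def format_atom_type(t: tuple[str, str]) -> str:
    return f"{t[0]}:{t[1]}"


def parse_atom_type(s: str) -> tuple[str, str]:
    res, _, atom = s.partition(":")
    if not atom:
        raise ValueError(f"atom type {s!r} is not of the form RES:ATOM")
    return (res, atom)


_HYDROGEN_ELEMENTS = {"H", "D"}


def _is_hydrogen(atom) -> bool:
    elem = (atom.element or "").strip().upper()
    if elem:
        return elem in _HYDROGEN_ELEMENTS
    name = atom.get_name().strip()
    return bool(name) and (name[0] in "HD" or (name[0].isdigit() and len(name) > 1 and name[1] in "HD"))


def parse_pdb_chain(path: str | Path, chain_id: str | None = None) -> StructureModel:
    """Read one chain of a PDB file into a :class:`StructureModel`.

    Only the first MODEL block is used.  Hydrogens, waters, ligands and
    nonstandard residues (MSE, ...) are dropped; kept residues are
    renumbered 0..n-1 in order of appearance.  ``chain_id=None`` takes the
    first chain in the file.

    Raises
    ------
    FileNotFoundError, ChainNotFoundError, EmptyChainError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure.get_models())
    if not models:
        raise EmptyChainError(f"{path}: no coordinates")
    first = models[0]
    chains = {c.id: c for c in first}
    if chain_id is None:
        if not chains:
            raise EmptyChainError(f"{path}: no chains")
        chain = next(iter(first))
        chain_id = chain.id
    else:
        try:
            chain = chains[chain_id]
        except KeyError:
            raise ChainNotFoundError(
                f"chain {chain_id!r} not found in {path} (available: {sorted(chains)})"
            ) from None

    atoms: list[AtomSite] = []
    res_idx = -1
    n_nonstandard = 0
    for residue in chain:
        hetflag = residue.id[0]
        resname = residue.get_resname().strip()
        if hetflag != " " or resname not in STANDARD_RESIDUES:
            if hetflag.startswith("H_") and resname not in ("HOH", "WAT"):
                n_nonstandard += 1
            continue
        res_idx += 1
        # iterating a Residue yields the selected conformer of disordered atoms
        for atom in residue:
            if _is_hydrogen(atom):
                continue
            x, y, z = (float(v) for v in atom.coord)
            atoms.append(AtomSite(resname, atom.get_name().strip(), res_idx, chain_id, x, y, z))
    if n_nonstandard:
        log.warning("%s chain %s: dropped %d nonstandard residue(s)", path, chain_id, n_nonstandard)
    if not atoms:
        raise EmptyChainError(f"{path}: chain {chain_id!r} has no standard-residue heavy atoms")
    return StructureModel(f"{path.stem}{chain_id}", atoms)


def select_atoms(model: StructureModel, selection: str) -> StructureModel:
    """Restrict a model to an atom subset: ``all_heavy`` (identity) or ``ca_only``.

    ``ca_only`` keeps exactly one CA per residue; residues lacking a CA are
    omitted with a warning.  Residue indices are preserved so sequence
    separation is unchanged.
    """
    if selection == "all_heavy":
        return model
    if selection != "ca_only":
        raise ValueError(f"unknown selection {selection!r}")
    seen: set[int] = set()
    kept: list[AtomSite] = []
    residues: set[int] = set()
    for a in model.atoms:
        residues.add(a.residue_index)
        if a.atom_name == "CA" and a.residue_index not in seen:
            seen.add(a.residue_index)
            kept.append(a)
    missing = residues - seen
    if missing:
        log.warning("%s: %d residue(s) lack a CA atom and were omitted",
                    model.identifier, len(missing))
    return StructureModel(model.identifier, kept)


def pair_arrays(
    model: StructureModel,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized qualifying-pair enumeration.

    Returns ``(types, lo, hi, dist)`` where ``types`` is the sorted list of
    atom types present, and for each qualifying pair ``lo[k] <= hi[k]`` index
    into ``types`` (canonical order) and ``dist[k]`` is the distance in Å.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(model.atoms)
    types = sorted({a.atom_type for a in model.atoms})
    if n < 2:
        return types, np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)
    code = {t: k for k, t in enumerate(types)}
    tcode = np.array([code[a.atom_type] for a in model.atoms], dtype=np.int64)
    ridx = model.residue_indices()
    coords = model.coords()
    iu, ju = np.triu_indices(n, k=1)
    keep = np.abs(ridx[iu] - ridx[ju]) >= min_separation
    iu, ju = iu[keep], ju[keep]
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    keep = d < cutoff
    iu, ju, d = iu[keep], ju[keep], d[keep]
    lo = np.minimum(tcode[iu], tcode[ju])
    hi = np.maximum(tcode[iu], tcode[ju])
    return types, lo, hi, d


def iter_qualifying_pairs(
    model: StructureModel,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    cutoff: float = DEFAULT_CUTOFF,
) -> Iterator[tuple[PairTypeKey, float]]:
    """Yield every unordered qualifying atom pair as ``(PairTypeKey, distance)``.

    A pair qualifies when the residue-index separation is at least
    ``min_separation`` and the distance is strictly below ``cutoff``;
    intra-residue pairs never qualify.  Each pair is yielded exactly once.
    """
    types, lo, hi, d = pair_arrays(model, min_separation, cutoff)
    for a, b, dist in zip(lo, hi, d):
        yield PairTypeKey(types[a], types[b]), float(dist)


def read_chain_list(path: str | Path) -> list[tuple[str, str]]:
    """Parse a whitespace-separated ``pdbfile chain`` list; '#' starts a comment."""
    entries: list[tuple[str, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) == 1 and len(parts[0]) == 5:
            # "1abcA" shorthand from culling servers
            entries.append((parts[0][:4], parts[0][4]))
        elif len(parts) >= 2:
            entries.append((parts[0], parts[1]))
        else:
            raise ValueError(f"unparseable chain-list line: {raw!r}")
    return entries
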