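"""Synthetic protein-like chains, graded-noise decoys, and toy benchmarks.

Everything downstream — training, scoring, benchmarking — can be
exercised without any structure download.  Natives are Cα traces with
~3.8 Å virtual bonds: an ideal α-helix, a self-avoiding random walk, or
a compact centroid-biased walk ("mixed", the default, whose radius of
gyration grows roughly like n^0.4 as in globular proteins).  Decoys add
isotropic Gaussian coordinate noise of a chosen sigma, so their true
quality is known by construction and graded by sigma; clashes at high
sigma are left in deliberately — they are exactly the non-native signal
a potential must penalize.

True quality is a simplified TM-score-style measure on superposed Cα
sets (optimal least-squares rotation, then a Levitt–Gerstein-type
distance weighting with the usual length-dependent d0).  It is NOT the
published TM-score algorithm: it assumes equal length and a fixed 1:1
residue correspondence, which the fixtures guarantee.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_io import AtomSite, StructureModel, select_atoms

log = logging.getLogger(__name__)

AA20 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

#: Swiss-Prot-like background amino-acid composition (order as AA20)
NATURAL_COMPOSITION = np.array([
    0.0826, 0.0553, 0.0406, 0.0546, 0.0137, 0.0393, 0.0672, 0.0708, 0.0227,
    0.0591, 0.0965, 0.0580, 0.0241, 0.0386, 0.0474, 0.0665, 0.0536, 0.0110,
    0.0292, 0.0686,
])
NATURAL_COMPOSITION = NATURAL_COMPOSITION / NATURAL_COMPOSITION.sum()

#: Kyte-Doolittle hydropathy (order as AA20), rescaled to [-1, 1]
HYDROPATHY = np.array([
    1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5, 3.8, -3.9,
    1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2,
]) / 4.5

#: strength of the burial-composition coupling in synthetic natives
BURIAL_COUPLING = 1.5

BOND_LENGTH = 3.8       # Å, consecutive Cα virtual bond
BOND_JITTER = 0.04      # Å, keeps bonds within 3.8 ± 0.05
CLASH_DISTANCE = 3.5    # Å, minimum non-bonded approach in natives

DEFAULT_SIGMAS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 9.0, 12.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic native chain."""

    n_residues: int = 120
    seed: int = 0
    fold_type: str = "mixed"  # helix | random_walk | mixed
    composition: tuple[float, ...] | None = None
    decoy_sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    with_cb: bool = False

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("n_residues must be >= 5")
        if any(s < 0 for s in self.decoy_sigmas):
            raise ValueError("decoy sigmas must be >= 0")
        if self.fold_type not in ("helix", "random_walk", "mixed"):
            raise ValueError(f"unknown fold_type {self.fold_type!r}")


def _helix_coords(n: int) -> np.ndarray:
    # ideal alpha-helix Ca geometry: 100 deg/residue, 1.5 Å rise, 2.3 Å radius
    t = np.arange(n) * np.deg2rad(100.0)
    return np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)], axis=1)


def _walk_coords(n: int, rng: np.random.Generator, compact: bool) -> np.ndarray:
    """Self-avoiding walk with ~3.8 Å steps; optional centroid bias for compactness."""
    target_radius = 2.5 * n ** 0.4
    for _restart in range(40):
        coords = [np.zeros(3), np.array([BOND_LENGTH, 0.0, 0.0])]
        failed = False
        backtracks = 0
        i = 2
        while i < n:
            pts = np.array(coords)
            centroid = pts.mean(axis=0)
            last = coords[-1]
            placed = False
            for _trial in range(80):
                v = rng.normal(size=3)
                if compact:
                    to_center = centroid - last
                    dist_c = np.linalg.norm(to_center)
                    bias = 0.3 + (0.9 if dist_c > target_radius else 0.0)
                    if dist_c > 0:
                        v = v + bias * np.sqrt(3.0) * to_center / dist_c
                norm = np.linalg.norm(v)
                if norm == 0:
                    continue
                step = (BOND_LENGTH + rng.uniform(-BOND_JITTER, BOND_JITTER)) * v / norm
                cand = last + step
                # all previous atoms except the bonded neighbour must stay clear
                if np.min(np.linalg.norm(pts[:-1] - cand, axis=1)) >= CLASH_DISTANCE:
                    coords.append(cand)
                    placed = True
                    break
            if not placed:
                # backtrack a few residues and retry
                backtracks += 1
                drop = min(5, len(coords) - 2)
                if drop <= 0 or backtracks > 50 + 2 * n:
                    failed = True
                    break
                del coords[-drop:]
                i -= drop
                continue
            i += 1
        if not failed and len(coords) == n:
            return np.array(coords)
    raise RuntimeError(
        "self-avoiding placement failed repeatedly; try a larger box (fewer residues "
        "or weaker compactness)")


def generate_native(spec: SyntheticSpec) -> StructureModel:
    """Deterministically generate one synthetic native Cα chain.

    Consecutive Cα distances are 3.8 ± 0.05 Å and no non-bonded pair comes
    closer than 3.5 Å.  With ``with_cb`` a pseudo-CB is added at 1.53 Å
    along the direction away from the chain (GLY excepted), to exercise
    multi-atom typing.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.composition, float) if spec.composition is not None \
        else NATURAL_COMPOSITION
    comp = comp / comp.sum()
    if spec.fold_type == "helix":
        coords = _helix_coords(spec.n_residues)
    else:
        coords = _walk_coords(spec.n_residues, rng, compact=(spec.fold_type == "mixed"))
    names = _draw_names(coords, comp, rng)
    atoms: list[AtomSite] = []
    for i, (name, p) in enumerate(zip(names, coords)):
        atoms.append(AtomSite(str(name), "CA", i, "A", float(p[0]), float(p[1]), float(p[2])))
        if spec.with_cb and name != "GLY":
            d = _cb_direction(coords, i)
            q = p + 1.53 * d
            atoms.append(AtomSite(str(name), "CB", i, "A", float(q[0]), float(q[1]), float(q[2])))
    return StructureModel(f"syn-{spec.fold_type}-{spec.seed}", atoms)


def _draw_names(coords: np.ndarray, comp: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Draw residue names with burial-dependent bias around a base composition.

    Real globular folds bury hydrophobic residues; without that coupling a
    knowledge-based potential has no type-specific distance preferences to
    learn from synthetic chains.  Positions near the centroid favour
    hydrophobic residues, exposed ones polar, via a Boltzmann-like tilt
    exp(-BURIAL_COUPLING · hydropathy · z) of the composition, where z is
    the standardized distance from the centroid.
    """
    r = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    z = (r - r.mean()) / (r.std() or 1.0)
    names = []
    for zi in z:
        p = comp * np.exp(-BURIAL_COUPLING * HYDROPATHY * zi)
        names.append(AA20[int(rng.choice(len(AA20), p=p / p.sum()))])
    return names


def _cb_direction(coords: np.ndarray, i: int) -> np.ndarray:
    # pseudo-CB points away from the local chain direction
    n = len(coords)
    prev_ = coords[i - 1] if i > 0 else coords[i + 1]
    next_ = coords[i + 1] if i < n - 1 else coords[i - 1]
    d = 2 * coords[i] - prev_ - next_
    nrm = np.linalg.norm(d)
    if nrm < 1e-6:
        d = np.cross(next_ - prev_, [0.0, 0.0, 1.0])
        nrm = np.linalg.norm(d)
        if nrm < 1e-6:
            d, nrm = np.array([1.0, 0.0, 0.0]), 1.0
    return d / nrm


def generate_decoy(native: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Perturb every coordinate with i.i.d. Gaussian noise of the given sigma (Å)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    coords = native.coords()
    if sigma > 0:
        coords = coords + rng.normal(0.0, sigma, coords.shape)
    return native.with_coords(coords, f"{native.identifier}-s{sigma:g}-{seed}")


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal least-squares superposition of Q onto P (both (L, 3)).

    Returns the per-atom distances after superposition and the RMSD.
    Standard Kabsch algorithm: centroids removed, rotation from the SVD of
    the covariance with a determinant correction against reflections.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both be (L, 3)")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc - Qc @ R.T
    dists = np.linalg.norm(diff, axis=1)
    return dists, float(np.sqrt(np.mean(dists ** 2)))


def toy_quality(reference: StructureModel, model: StructureModel) -> float:
    """Simplified TM-score-style quality in (0, 1] for same-length Cα sets.

    q = (1/L) Σ 1/(1 + (d_i/d0)²) with d0 = max(1.24·(L−15)^(1/3) − 1.8, 0.5),
    after optimal superposition.  Identity gives 1; invariant to rigid
    motions of either input.
    """
    P = select_atoms(reference, "ca_only").coords()
    Q = select_atoms(model, "ca_only").coords()
    if P.shape != Q.shape:
        raise ValueError(
            f"length mismatch: {P.shape[0]} vs {Q.shape[0]} residues")
    L = P.shape[0]
    d0 = max(1.24 * np.cbrt(L - 15.0) - 1.8, 0.5)
    dists, _ = kabsch_superpose(P, Q)
    return float(np.mean(1.0 / (1.0 + (dists / d0) ** 2)))


def generate_benchmark_set(
    n_targets: int,
    decoys_per_target: int,
    sigmas: Sequence[float] = DEFAULT_SIGMAS,
    seed: int = 0,
    n_residues: tuple[int, int] = (80, 250),
    fold_type: str = "mixed",
) -> tuple[dict[str, StructureModel], pd.DataFrame]:
    """Full toy decoy benchmark: natives + graded decoys + quality table.

    Each target gets one native (quality 1.0) and ``decoys_per_target``
    decoys cycling through ``sigmas``.  Returns ``(models, quality)`` where
    ``models`` maps model id to structure and ``quality`` has columns
    target, model, metric, value.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    models: dict[str, StructureModel] = {}
    rows: list[tuple[str, str, str, float]] = []
    for t in range(n_targets):
        length = int(rng.integers(n_residues[0], n_residues[1] + 1))
        spec = SyntheticSpec(n_residues=length, seed=int(rng.integers(2**31 - 1)),
                             fold_type=fold_type)
        native = generate_native(spec)
        tid = f"T{t:03d}"
        native.identifier = f"{tid}_native"
        models[native.identifier] = native
        rows.append((tid, native.identifier, "toy_tm", 1.0))
        for k in range(decoys_per_target):
            sigma = float(sigmas[k % len(sigmas)])
            decoy = generate_decoy(native, sigma, int(rng.integers(2**31 - 1)))
            decoy.identifier = f"{tid}_d{k:03d}"
            models[decoy.identifier] = decoy
            rows.append((tid, decoy.identifier, "toy_tm", toy_quality(native, decoy)))
    quality = pd.DataFrame(rows, columns=["target", "model", "metric", "value"])
    return models, quality


_PDB_ATOM = ("ATOM  {serial:5d} {name:^4s}{altloc:1s}{res:3s} {chain:1s}{resseq:4d}"
             "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}")


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal single-chain PDB file (ATOM records + END)."""
    lines = []
    serial = 0
    for a in model.atoms:
        serial += 1
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(_PDB_ATOM.format(
            serial=serial, name=name, altloc=" ", res=a.residue_name, chain=a.chain_id,
            resseq=a.residue_index + 1, icode=" ", x=a.x, y=a.y, z=a.z,
            occ=1.0, b=0.0, elem=a.atom_name[0]))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
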