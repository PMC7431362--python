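"""Per-bin score terms, whole-structure scores, and score profiles.

Four scoring formalisms share the same trained frequencies and differ
only in the per-bin term applied to (f_OBS, f_REF):

PMF    -ln(f_OBS / f_REF)                     inverse-Boltzmann form, kT = 1
TIG    -(f_OBS - f_REF) / f_REF               total information gain
MCK1   -(f_OBS - f_REF) / ((f_OBS+f_REF)/2)   mock control, arithmetic mean
MCK2   -(f_OBS - f_REF) / max(f_OBS, f_REF)   mock control, max

Wherever a formalism is genuinely undefined (f_REF = 0 for all four;
additionally f_OBS = 0 for PMF) the term takes a fixed default of +10.
TIG at f_OBS = 0 is defined and equals exactly +1, giving its
characteristic two-plateau repulsive region (+1 where the pair type was
never seen at that distance, +10 where no atoms at all were).

Scores are pseudo-energy-like sums over qualifying pairs: lower is more
native-like.  They are dimensionless and are not length-normalized;
ranking happens within one target, where length cancels.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .structure_io import (
    EmptyChainError,
    PairTypeKey,
    StructureModel,
    pair_arrays,
    select_atoms,
)
from .training import BinGrid, FrequencyTable

log = logging.getLogger(__name__)

DEFAULT_UNDEFINED = 10.0
KT = 1.0

FORMALISMS = ("PMF", "TIG", "MCK1", "MCK2")


def _pmf_terms(f_obs: np.ndarray, f_ref: np.ndarray, default: float) -> np.ndarray:
    out = np.full(np.broadcast(f_obs, f_ref).shape, default, dtype=float)
    ok = (f_obs > 0) & (f_ref > 0)
    with np.errstate(divide="ignore"):
        out[ok] = -KT * np.log(np.asarray(f_obs, float)[ok] / np.asarray(f_ref, float)[ok])
    return out


def _tig_terms(f_obs: np.ndarray, f_ref: np.ndarray, default: float) -> np.ndarray:
    f_obs = np.asarray(f_obs, float)
    f_ref = np.asarray(f_ref, float)
    out = np.full(np.broadcast(f_obs, f_ref).shape, default, dtype=float)
    ok = f_ref > 0
    fo, fr = np.broadcast_arrays(f_obs, f_ref)
    out[ok] = -(fo[ok] - fr[ok]) / fr[ok]
    return out


def _mck1_terms(f_obs: np.ndarray, f_ref: np.ndarray, default: float) -> np.ndarray:
    f_obs = np.asarray(f_obs, float)
    f_ref = np.asarray(f_ref, float)
    out = np.full(np.broadcast(f_obs, f_ref).shape, default, dtype=float)
    fo, fr = np.broadcast_arrays(f_obs, f_ref)
    ok = (fo > 0) | (fr > 0)
    out[ok] = -(fo[ok] - fr[ok]) / ((fo[ok] + fr[ok]) / 2.0)
    return out


def _mck2_terms(f_obs: np.ndarray, f_ref: np.ndarray, default: float) -> np.ndarray:
    f_obs = np.asarray(f_obs, float)
    f_ref = np.asarray(f_ref, float)
    out = np.full(np.broadcast(f_obs, f_ref).shape, default, dtype=float)
    fo, fr = np.broadcast_arrays(f_obs, f_ref)
    ok = (fo > 0) | (fr > 0)
    out[ok] = -(fo[ok] - fr[ok]) / np.maximum(fo[ok], fr[ok])
    return out


_TERM_FUNCS: dict[str, Callable[[np.ndarray, np.ndarray, float], np.ndarray]] = {
    "PMF": _pmf_terms,
    "TIG": _tig_terms,
    "MCK1": _mck1_terms,
    "MCK2": _mck2_terms,
}


def pmf_term(f_obs: float, f_ref: float, default: float = DEFAULT_UNDEFINED) -> float:
    """-ln(f_obs/f_ref) with kT = 1; +10 when f_ref = 0 or f_obs = 0."""
    return float(_pmf_terms(np.array([f_obs]), np.array([f_ref]), default)[0])


def tig_term(f_obs: float, f_ref: float, default: float = DEFAULT_UNDEFINED) -> float:
    """-(f_obs - f_ref)/f_ref; +10 when f_ref = 0.  Equals +1 at f_obs = 0."""
    return float(_tig_terms(np.array([f_obs]), np.array([f_ref]), default)[0])


def mck1_term(f_obs: float, f_ref: float, default: float = DEFAULT_UNDEFINED) -> float:
    """-(f_obs - f_ref)/((f_obs + f_ref)/2); +10 only at the undefined 0/0."""
    return float(_mck1_terms(np.array([f_obs]), np.array([f_ref]), default)[0])


def mck2_term(f_obs: float, f_ref: float, default: float = DEFAULT_UNDEFINED) -> float:
    """-(f_obs - f_ref)/max(f_obs, f_ref); +10 only at the undefined 0/0."""
    return float(_mck2_terms(np.array([f_obs]), np.array([f_ref]), default)[0])


TERM_FUNCTIONS = {
    "PMF": pmf_term,
    "TIG": tig_term,
    "MCK1": mck1_term,
    "MCK2": mck2_term,
}


@dataclass
class PotentialTable:
    """Per-pair-type, per-bin score terms for one formalism."""

    grid: BinGrid
    formalism: str
    per_pair: dict[PairTypeKey, np.ndarray]
    default_undefined: float = DEFAULT_UNDEFINED
    kT: float = KT
    min_separation: int = 4
    selection: str = "all_heavy"


def build_potential(
    freq: FrequencyTable,
    formalism: str,
    default_undefined: float = DEFAULT_UNDEFINED,
) -> PotentialTable:
    """Apply a formalism's term bin-wise to every sufficiently-observed pair type."""
    if formalism not in _TERM_FUNCS:
        raise ValueError(f"unknown formalism {formalism!r}; expected one of {FORMALISMS}")
    fn = _TERM_FUNCS[formalism]
    per_pair = {
        key: fn(stats.frequencies, freq.reference, default_undefined)
        for key, stats in freq.sufficient_pairs().items()
    }
    return PotentialTable(freq.grid, formalism, per_pair, default_undefined, KT,
                          freq.min_separation, freq.selection)


@dataclass
class ScoreReport:
    """Whole-structure score: the sum of per-pair terms over qualifying pairs."""

    identifier: str
    formalism: str
    total: float
    n_pairs_scored: int
    n_pairs_skipped: int

    @property
    def per_pair_mean(self) -> float:
        """Optional length-normalized view (total / pairs scored)."""
        return self.total / self.n_pairs_scored if self.n_pairs_scored else 0.0


def score_structure(
    model: StructureModel,
    potential: PotentialTable,
    selection: str | None = None,
    min_separation: int | None = None,
) -> ScoreReport:
    """Score a model: sum the potential's term at each qualifying pair's bin.

    Pairs whose type is absent from the potential contribute 0 and are
    counted as skipped (a training-coverage gap, not evidence either way).
    ``selection``/``min_separation`` default to the potential's training
    metadata; an explicit mismatch is honoured but warned about.
    """
    if selection is None:
        selection = potential.selection
    elif selection != potential.selection:
        log.warning("scoring selection %r differs from training selection %r",
                    selection, potential.selection)
    if min_separation is None:
        min_separation = potential.min_separation
    elif min_separation != potential.min_separation:
        log.warning("scoring min_separation %d differs from training value %d",
                    min_separation, potential.min_separation)
    sub = select_atoms(model, selection)
    if not sub.atoms:
        raise EmptyChainError(f"{model.identifier}: no atoms left after selection {selection!r}")
    types, lo, hi, d = pair_arrays(sub, min_separation, potential.grid.cutoff)
    if d.size == 0:
        return ScoreReport(model.identifier, potential.formalism, 0.0, 0, 0)
    bins = potential.grid.bin_index(d)
    pair_code = lo * len(types) + hi
    order = np.argsort(pair_code, kind="stable")
    codes, starts = np.unique(pair_code[order], return_index=True)
    bin_groups = np.split(bins[order], starts[1:])
    total = 0.0
    scored = skipped = 0
    for c, bg in zip(codes, bin_groups):
        key = PairTypeKey(types[int(c) // len(types)], types[int(c) % len(types)])
        terms = potential.per_pair.get(key)
        if terms is None:
            skipped += bg.size
        else:
            total += float(terms[bg].sum())
            scored += bg.size
    return ScoreReport(model.identifier, potential.formalism, total, scored, skipped)


def score_profile(potential: PotentialTable, key: PairTypeKey) -> pd.DataFrame:
    """Distance profile of one pair type: (bin_center, score) per bin.

    Raises ``KeyError`` listing the nearest available keys when absent.
    """
    terms = potential.per_pair.get(key)
    if terms is None:
        available = [str(k) for k in potential.per_pair]
        near = difflib.get_close_matches(str(key), available, n=5, cutoff=0.0)
        raise KeyError(f"pair type {key} not in potential; nearest available: {near}")
    return pd.DataFrame({"bin_center": potential.grid.centers, "score": terms})


def reports_to_frame(reports: list[ScoreReport]) -> pd.DataFrame:
    """Score table with columns model, formalism, total_score, n_pairs_scored, n_pairs_skipped."""
    return pd.DataFrame(
        {
            "model": [r.identifier for r in reports],
            "formalism": [r.formalism for r in reports],
            "total_score": [r.total for r in reports],
            "n_pairs_scored": [r.n_pairs_scored for r in reports],
            "n_pairs_skipped": [r.n_pairs_skipped for r in reports],
        }
    )
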