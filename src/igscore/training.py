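"""Training of distance frequency tables from native structures.

For every canonical atom-type pair the qualifying interatomic distances
observed across a corpus of native chains are pooled and turned into a
binned frequency vector f_OBS(r) by Gaussian kernel density estimation
(Scott's rule-of-thumb bandwidth), on a grid of 0.5 Å bins up to a
15.0 Å cutoff.  The reference state f_REF(r) is the count-weighted
arithmetic mean of all per-pair vectors — equivalently, the distance
distribution with atom types made indistinct.

Frequencies, not counts, are what the scoring formalisms consume; no
pseudo-counts are added anywhere.  Zero-frequency handling is the
scoring terms' business.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import ndtr

from .structure_io import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_SEPARATION,
    PairTypeKey,
    StructureModel,
    format_atom_type,
    pair_arrays,
    parse_atom_type,
    select_atoms,
)

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.5
DEFAULT_MIN_COUNT = 2
#: bin masses below this are treated as exactly zero (numerically unobserved)
FREQUENCY_FLOOR = 1e-9

REF_KEY_TOKEN = "__REF__"


@dataclass(frozen=True)
class BinGrid:
    """Half-open distance bins [k·w, (k+1)·w) covering [0, cutoff)."""

    bin_width: float = DEFAULT_BIN_WIDTH
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.cutoff <= 0:
            raise ValueError("bin_width and cutoff must be positive")
        n = self.cutoff / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cutoff must be an integer multiple of bin_width")

    @property
    def n_bins(self) -> int:
        return int(round(self.cutoff / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_index(self, d) -> np.ndarray:
        """Map distances in [0, cutoff) to bin indices."""
        d = np.asarray(d, dtype=float)
        if np.any(d < 0) or np.any(d >= self.cutoff):
            raise ValueError("distance outside [0, cutoff)")
        return np.minimum((d / self.bin_width).astype(np.int64), self.n_bins - 1)


@dataclass
class PairStats:
    """Binned frequency vector for one pair type plus its raw observation count."""

    frequencies: np.ndarray
    count: int


@dataclass
class FrequencyTable:
    """Per-pair-type binned frequencies plus the pooled reference state.

    ``per_pair`` holds every pair type seen in the corpus, including ones
    with too few observations (their vectors are all-zero and they are
    excluded from the reference and from scoring).
    """

    grid: BinGrid
    per_pair: dict[PairTypeKey, PairStats]
    reference: np.ndarray
    min_separation: int = DEFAULT_MIN_SEPARATION
    selection: str = "all_heavy"
    min_count: int = DEFAULT_MIN_COUNT

    @property
    def total_count(self) -> int:
        return sum(p.count for p in self.per_pair.values())

    def is_sufficient(self, key: PairTypeKey) -> bool:
        stats = self.per_pair.get(key)
        return stats is not None and stats.count >= self.min_count

    def sufficient_pairs(self) -> dict[PairTypeKey, PairStats]:
        return {k: v for k, v in self.per_pair.items() if v.count >= self.min_count}


def scott_bandwidth(x: np.ndarray) -> float:
    """Rule-of-thumb bandwidth h = 1.06 · min(sd, IQR/1.349) · n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(x.std(ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("degenerate sample (zero spread)")
    return 1.06 * scale * n ** (-1 / 5)


def estimate_frequencies(
    distances: Sequence[float] | np.ndarray,
    grid: BinGrid,
    bandwidth_rule: str = "scott",
    bandwidth: float | None = None,
    frequency_floor: float = FREQUENCY_FLOOR,
) -> np.ndarray:
    """KDE-smoothed bin frequencies for one pair type's distance sample.

    Each observation contributes its Gaussian kernel's exact mass within
    every bin (difference of normal CDFs at the bin edges); the vector is
    then renormalized over [0, cutoff), discarding mass smoothed past the
    cutoff.  Bin masses below ``frequency_floor`` are zeroed (they reflect
    far kernel tails, not observations) and the vector renormalized again.

    A sample with zero spread puts frequency 1 in its single occupied bin.
    Fewer than 2 observations yield an all-zero ("insufficient") vector.
    ``bandwidth`` overrides the rule when given (used for convergence
    checks).
    """
    x = np.asarray(distances, dtype=float)
    out = np.zeros(grid.n_bins)
    if x.size < 2:
        return out
    if x.size and (x.min() < 0 or x.max() >= grid.cutoff):
        raise ValueError("distances outside [0, cutoff)")
    if x.std(ddof=1) == 0:
        out[int(grid.bin_index(x[:1])[0])] = 1.0
        return out
    if bandwidth is not None:
        h = float(bandwidth)
    elif bandwidth_rule == "scott":
        h = scott_bandwidth(x)
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    edges = grid.edges
    # mass of each sample's kernel inside every bin, accumulated in chunks
    cum = np.zeros(edges.size)
    for start in range(0, x.size, 65536):
        chunk = x[start:start + 65536, None]
        cum += ndtr((edges[None, :] - chunk) / h).sum(axis=0)
    freq = np.diff(cum) / x.size
    total = freq.sum()
    if total <= 0:  # pathological bandwidth; fall back to a plain histogram
        hist, _ = np.histogram(x, bins=edges)
        freq = hist.astype(float)
        total = freq.sum()
    freq /= total
    if frequency_floor > 0:
        freq[freq < frequency_floor] = 0.0
        freq /= freq.sum()
    return freq


def collect_distances(
    corpus: Iterable[StructureModel],
    min_separation: int = DEFAULT_MIN_SEPARATION,
    grid: BinGrid | None = None,
) -> dict[PairTypeKey, np.ndarray]:
    """Pool qualifying-pair distances over a corpus, grouped by canonical pair type.

    Distances are kept raw (not binned) so the KDE sees the full sample.
    """
    grid = grid or BinGrid()
    buckets: dict[PairTypeKey, list[np.ndarray]] = {}
    n_chains = 0
    for model in corpus:
        n_chains += 1
        types, lo, hi, d = pair_arrays(model, min_separation, grid.cutoff)
        if d.size == 0:
            continue
        pair_code = lo * len(types) + hi
        order = np.argsort(pair_code, kind="stable")
        codes, starts = np.unique(pair_code[order], return_index=True)
        splits = np.split(d[order], starts[1:])
        for c, ds in zip(codes, splits):
            key = PairTypeKey(types[int(c) // len(types)], types[int(c) % len(types)])
            buckets.setdefault(key, []).append(ds)
    if n_chains == 0:
        raise ValueError("empty corpus")
    return {k: np.concatenate(v) for k, v in buckets.items()}


def build_reference(per_pair: Mapping[PairTypeKey, PairStats], min_count: int = DEFAULT_MIN_COUNT) -> np.ndarray:
    """Count-weighted arithmetic mean of the usable per-pair frequency vectors."""
    usable = [(p.count, p.frequencies) for p in per_pair.values() if p.count >= min_count]
    if not usable:
        raise ValueError("no pair type has enough observations to build a reference")
    total = sum(c for c, _ in usable)
    ref = np.zeros_like(usable[0][1])
    for c, f in usable:
        ref += c * f
    ref /= total
    return ref


def train(
    corpus: Iterable[StructureModel],
    grid: BinGrid | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    selection: str = "all_heavy",
    min_count: int = DEFAULT_MIN_COUNT,
    bandwidth_rule: str = "scott",
    frequency_floor: float = FREQUENCY_FLOOR,
) -> FrequencyTable:
    """Full training pipeline: collect → KDE per pair type → pooled reference.

    Deterministic for a fixed corpus and parameters.  ``selection`` is applied
    to every chain before pair enumeration and recorded in the table.
    """
    grid = grid or BinGrid()
    models = [select_atoms(m, selection) for m in corpus]
    distances = collect_distances(models, min_separation, grid)
    per_pair: dict[PairTypeKey, PairStats] = {}
    for key in sorted(distances):
        ds = distances[key]
        if ds.size >= min_count and ds.size >= 2:
            freq = estimate_frequencies(ds, grid, bandwidth_rule, frequency_floor=frequency_floor)
        else:
            freq = np.zeros(grid.n_bins)
        per_pair[key] = PairStats(freq, int(ds.size))
    reference = build_reference(per_pair, min_count)
    n_ok = sum(1 for p in per_pair.values() if p.count >= min_count)
    log.info("trained %d pair types (%d with >= %d observations), %d distances",
             len(per_pair), n_ok, min_count, sum(p.count for p in per_pair.values()))
    return FrequencyTable(grid, per_pair, reference, min_separation, selection, min_count)


# ---------------------------------------------------------------------------
# On-disk format: tab-separated text, one row per (pair, bin), reference rows
# under the reserved key __REF__, header line with the training parameters.
# Floats are written with repr() so read→write round-trips bit-exactly.

def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    lines = [
        "# igscore frequency table v1",
        "# bin_width={}\tcutoff={}\tmin_separation={}\tselection={}\tmin_count={}".format(
            repr(table.grid.bin_width), repr(table.grid.cutoff),
            table.min_separation, table.selection, table.min_count),
        "pair_first\tpair_second\tbin_lo\tbin_hi\tf_obs\tcount",
    ]
    edges = table.grid.edges
    def rows(first: str, second: str, freq: np.ndarray, count: int) -> None:
        for b in range(table.grid.n_bins):
            lines.append("\t".join((
                first, second, repr(float(edges[b])), repr(float(edges[b + 1])),
                repr(float(freq[b])), str(count),
            )))
    for key in sorted(table.per_pair):
        stats = table.per_pair[key]
        rows(format_atom_type(key.first), format_atom_type(key.second),
             stats.frequencies, stats.count)
    rows(REF_KEY_TOKEN, REF_KEY_TOKEN, table.reference, table.total_count)
    Path(path).write_text("\n".join(lines) + "\n")


def read_frequency_table(path: str | Path) -> FrequencyTable:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("# igscore frequency table"):
        raise ValueError(f"{path}: not an igscore frequency table")
    params = dict(item.split("=", 1) for item in text[1][2:].split("\t"))
    grid = BinGrid(float(params["bin_width"]), float(params["cutoff"]))
    min_separation = int(params["min_separation"])
    selection = params["selection"]
    min_count = int(params["min_count"])
    per_pair: dict[PairTypeKey, PairStats] = {}
    reference = np.zeros(grid.n_bins)
    cur_key: tuple[str, str] | None = None
    freq = np.zeros(grid.n_bins)
    count = 0

    def flush() -> None:
        nonlocal freq
        if cur_key is None:
            return
        if cur_key[0] == REF_KEY_TOKEN:
            reference[:] = freq
        else:
            key = PairTypeKey(parse_atom_type(cur_key[0]), parse_atom_type(cur_key[1]))
            per_pair[key] = PairStats(freq.copy(), count)
        freq = np.zeros(grid.n_bins)

    for line in text[3:]:
        if not line.strip():
            continue
        first, second, bin_lo, _bin_hi, f_obs, cnt = line.split("\t")
        if (first, second) != cur_key:
            flush()
            cur_key = (first, second)
        count = int(cnt)
        freq[int(round(float(bin_lo) / grid.bin_width))] = float(f_obs)
    flush()
    return FrequencyTable(grid, per_pair, reference, min_separation, selection, min_count)
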