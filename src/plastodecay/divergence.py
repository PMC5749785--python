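"""Alignment partition statistics and divergence-hotspot ranking.

p-distances use pairwise deletion: only columns where both rows hold an
unambiguous base (A/C/G/T) are compared. Site classification never counts
gaps or N as states.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats

BASES = frozenset("ACGT")


class UndefinedSignal(ValueError):
    """A statistic is undefined for the given input (e.g. no compared sites)."""


@dataclass
class AlignedMatrix:
    """Aligned rows over {A,C,G,T,N,-} plus named (possibly overlapping)
    partitions given as column index arrays."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("rows have unequal lengths")
        self.length = lengths.pop()
        self.rows = {t: r.upper() for t, r in self.rows.items()}
        for name, idx in self.partitions.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.length):
                raise ValueError(f"partition {name!r} indices out of range")
            self.partitions[name] = idx

    @classmethod
    def from_fasta(cls, path, partitions: Optional[dict] = None) -> "AlignedMatrix":
        from Bio import SeqIO

        rows = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")}
        return cls(list(rows), rows, partitions or {})

    def columns(self, indices: Optional[np.ndarray] = None):
        idx = range(self.length) if indices is None else indices
        for j in idx:
            yield [self.rows[t][j] for t in self.taxa]


def read_partition_file(path) -> dict[str, np.ndarray]:
    """RAxML-style partition lines: ``name = 1-500, 700-900`` (1-based)."""
    partitions: dict[str, np.ndarray] = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"bad partition line: {line!r}")
        name, spec = line.split("=", 1)
        name = name.split(",")[-1].strip()  # tolerate "DNA, name = ..."
        idx: list[int] = []
        for chunk in spec.split(","):
            chunk = chunk.strip()
            if "-" in chunk:
                lo, hi = chunk.split("-")
                idx.extend(range(int(lo) - 1, int(hi)))
            elif chunk:
                idx.append(int(chunk) - 1)
        partitions[name] = np.array(sorted(set(idx)), dtype=int)
    return partitions


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def p_distance(row_a: str, row_b: str) -> Optional[float]:
    """Differing sites / compared sites under pairwise deletion.

    Returns None (undefined) when no site has unambiguous bases in both rows.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    compared = differing = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a in BASES and b in BASES:
            compared += 1
            if a != b:
                differing += 1
    if compared == 0:
        return None
    return differing / compared


CONSTANT, VARIABLE, INFORMATIVE = ("constant", "variable-uninformative",
                                   "parsimony-informative")


def site_classes(columns) -> list[str]:
    """Per-column label; gaps/N never count as states."""
    labels = []
    for col in columns:
        counts: dict[str, int] = {}
        for sym in col:
            if sym in BASES:
                counts[sym] = counts.get(sym, 0) + 1
        if len(counts) < 2:
            labels.append(CONSTANT)
        elif sum(1 for v in counts.values() if v >= 2) >= 2:
            labels.append(INFORMATIVE)
        else:
            labels.append(VARIABLE)
    return labels


@dataclass
class PartitionStats:
    name: str
    length: int
    variable: int
    informative: int
    mean_p_distance: float
    gc_percent: float
    empty: bool = False

    @property
    def variable_pct(self) -> float:
        return 100.0 * self.variable / self.length if self.length else 0.0

    @property
    def informative_pct(self) -> float:
        return 100.0 * self.informative / self.length if self.length else 0.0


def partition_stats(matrix: AlignedMatrix,
                    partitions: Optional[dict[str, np.ndarray]] = None
                    ) -> list[PartitionStats]:
    """Length, variable/PIC counts, mean pairwise p-distance and GC% per
    partition (the whole matrix when no partitions are given)."""
    parts = partitions if partitions is not None else matrix.partitions
    if not parts:
        parts = {"all": np.arange(matrix.length)}
    out = []
    for name, idx in parts.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            out.append(PartitionStats(name, 0, 0, 0, 0.0, 0.0, empty=True))
            continue
        labels = site_classes(matrix.columns(idx))
        variable = sum(1 for l in labels if l != CONSTANT)
        informative = sum(1 for l in labels if l == INFORMATIVE)
        sub = {t: "".join(matrix.rows[t][j] for j in idx) for t in matrix.taxa}
        dists = [d for a, b in itertools.combinations(matrix.taxa, 2)
                 if (d := p_distance(sub[a], sub[b])) is not None]
        mean_p = float(np.mean(dists)) if dists else 0.0
        pooled = "".join(sub.values())
        gc_bases = sum(pooled.count(b) for b in "GC")
        acgt = sum(pooled.count(b) for b in "ACGT")
        gc = 100.0 * gc_bases / acgt if acgt else 0.0
        out.append(PartitionStats(name, int(idx.size), variable, informative,
                                  mean_p, gc))
    return out


# ---------------------------------------------------------------------------
# Correlation and ranking
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float],
                 method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    ``method='t'`` uses the two-sided t-distribution approximation;
    ``method='permutation'`` permutes one ranking (exact for n <= 8,
    otherwise 10,000 seeded Monte-Carlo draws).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedSignal("zero variance in a ranking")
    rho, p_t = _stats.spearmanr(x, y)
    if method == "t":
        return float(rho), float(p_t)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rx = _stats.rankdata(x)
    ry = _stats.rankdata(y)

    def stat(perm_ry) -> float:
        return abs(np.corrcoef(rx, perm_ry)[0, 1])

    observed = stat(ry)
    n = len(x)
    count = total = 0
    if n <= 8:
        for perm in itertools.permutations(ry):
            total += 1
            if stat(np.array(perm)) >= observed - 1e-12:
                count += 1
    else:
        rng = np.random.default_rng(0)
        for _ in range(10000):
            total += 1
            if stat(rng.permutation(ry)) >= observed - 1e-12:
                count += 1
    return float(rho), count / total


def rank_hotspots(stats: Sequence[PartitionStats], k: int = 10
                  ) -> list[PartitionStats]:
    """Top-k partitions by PIC count; ties by mean p-distance, then name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(stats, key=lambda s: (-s.informative,
                                          -s.mean_p_distance, s.name))
    return ranked[:k]


def stats_table(stats: Sequence[PartitionStats]) -> str:
    lines = ["name\tlength_bp\tvariable\tvariable_pct\tinformative\t"
             "informative_pct\tmean_p_distance\tgc_percent"]
    for s in stats:
        lines.append("\t".join([
            s.name, str(s.length), str(s.variable), f"{s.variable_pct:.2f}",
            str(s.informative), f"{s.informative_pct:.2f}",
            f"{s.mean_p_distance:.6f}", f"{s.gc_percent:.1f}"]))
    return "\n".join(lines) + "\n"
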