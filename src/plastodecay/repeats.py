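"""Microsatellite (SSR) and long direct/palindromic repeat detection.

SSRs are maximal perfect tandem runs of 1-6 bp units meeting per-unit-size
minimum copy counts (MISA-style). Long repeats are maximal ungapped pairs
of >= ``min_len`` bp with at most ``max_mismatch`` Hamming mismatches AND
identity >= ``min_identity`` (both filters, mirroring "-h 3" plus the >90%
identity rule); the second copy may match the first directly or as its
reverse complement (palindromic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .plastome import GeneAnnotation, revcomp

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
IR_PAIR_MIN_LEN = 1000


@dataclass
class RepeatHit:
    kind: str                           # "tandem", "direct" or "palindromic"
    intervals: list[tuple[int, int]]    # one (SSR) or two, 0-based half-open
    length: int
    unit: Optional[str] = None          # SSR motif
    copies: int = 0
    n_mismatches: int = 0
    identity: float = 1.0
    contexts: list[str] = field(default_factory=list)
    is_ir_pair: bool = False

    @property
    def context(self) -> Optional[str]:
        return self.contexts[0] if self.contexts else None


def _minimal_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

def find_ssrs(sequence: str,
              thresholds: Optional[dict[int, int]] = None) -> list[RepeatHit]:
    """Maximal perfect tandem runs; smallest-period reporting, deduplicated.

    A maximal run of period ``p`` and length ``L`` reports
    ``copies = L // p`` complete copies (reported length ``p * copies``).
    Runs whose unit is itself periodic are left to the smaller period;
    overlapping reports keep the smallest-period run.
    """
    sequence = sequence.upper()
    thresholds = dict(thresholds or DEFAULT_SSR_THRESHOLDS)
    n = len(sequence)
    candidates: list[RepeatHit] = []
    for p in sorted(thresholds):
        min_copies = thresholds[p]
        i = 0
        while i < n - p:
            if sequence[i] != sequence[i + p]:
                i += 1
                continue
            j = i
            while j < n - p and sequence[j] == sequence[j + p]:
                j += 1
            run_len = (j - i) + p            # periodic stretch [i, i+run_len)
            copies = run_len // p
            unit = sequence[i:i + p]
            if copies >= min_copies and _minimal_period(unit) == p \
                    and "N" not in unit:
                candidates.append(RepeatHit(
                    kind="tandem", intervals=[(i, i + p * copies)],
                    length=p * copies, unit=unit, copies=copies))
            i = j + 1
    candidates.sort(key=lambda h: (len(h.unit), h.intervals[0]))
    kept: list[RepeatHit] = []
    for cand in candidates:
        cs, ce = cand.intervals[0]
        clash = any(len(k.unit) < len(cand.unit)
                    and k.intervals[0][0] < ce and cs < k.intervals[0][1]
                    for k in kept)
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda h: h.intervals[0])
    return kept


# ---------------------------------------------------------------------------
# Long repeats
# ---------------------------------------------------------------------------

def _seed_diagonals(a: str, b: str, k: int) -> dict[int, list[int]]:
    """Exact shared k-mer seeds grouped by diagonal d = j - i; the values
    are sorted seed positions in ``a`` coordinates."""
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i:i + k], []).append(i)
    out: dict[int, list[int]] = {}
    for j in range(len(b) - k + 1):
        for i in index.get(b[j:j + k], ()):
            out.setdefault(j - i, []).append(i)
    for seeds in out.values():
        seeds.sort()
    return out


def _maximal_windows(mismatch_at: list[bool], h: int, min_len: int,
                     left_true_end: bool = True, right_true_end: bool = True):
    """Maximal (non-extendable) windows with <= h mismatches, >= min_len.

    A side is blocked when it sits on a true sequence end, or when the
    adjacent position is a mismatch that would push the count past ``h``
    (adjacent positions at window bounds are mismatches by construction,
    so that reduces to ``k == h``).
    """
    m = len(mismatch_at)
    pos = [t for t, bad in enumerate(mismatch_at) if bad]
    bounds = [-1] + pos + [m]
    out = set()
    for w in range(len(bounds) - 1):
        hi_idx = min(w + h + 1, len(bounds) - 1)
        lo = bounds[w] + 1
        hi = bounds[hi_idx] - 1
        if hi - lo + 1 < min_len:
            continue
        k = sum(1 for t in pos if lo <= t <= hi)
        left_blocked = k == h or (lo == 0 and left_true_end)
        right_blocked = k == h or (hi + 1 == m and right_true_end)
        if left_blocked and right_blocked:
            out.add((lo, hi + 1, k))
    return out


def _windows_near_seeds(is_mismatch, lo_t: int, hi_t: int, seeds: list[int],
                        h: int, min_len: int):
    """Maximal <=h-mismatch windows on a diagonal, probing only around
    exact-match seeds. Any window of >= min_len with <= h mismatches
    contains an exact ``seed_k``-mer (pigeonhole), and extending h+1
    mismatches either side of a seed bounds every such window, so this is
    exhaustive over qualifying windows."""
    out = set()
    # two expansions are identical unless a mismatch separates their seeds,
    # so after processing one seed, skip forward to the next mismatch
    skip_until = lo_t - 1
    for t0 in seeds:
        if t0 <= skip_until:
            continue
        left, seen = t0, 0
        while left > lo_t and seen <= h:
            if is_mismatch(left - 1):
                seen += 1
            left -= 1
        right, seen = t0, 0
        first_mismatch_after = None
        while right < hi_t and seen <= h:
            if is_mismatch(right):
                seen += 1
                if first_mismatch_after is None:
                    first_mismatch_after = right
            right += 1
        skip_until = (hi_t if first_mismatch_after is None
                      else first_mismatch_after)
        local = [is_mismatch(t) for t in range(left, right)]
        for wlo, whi, k in _maximal_windows(local, h, min_len,
                                            left_true_end=(left == lo_t),
                                            right_true_end=(right == hi_t)):
            out.add((left + wlo, left + whi, k))
    return out


def _best_per_overlap_group(windows):
    """Collapse overlapping same-diagonal windows to the best-scoring one
    (longest net of mismatches, then fewest mismatches, then leftmost)."""
    out = []
    group: list = []
    for w in sorted(windows):
        if group and w[0] < max(x[1] for x in group):
            group.append(w)
        else:
            if group:
                out.append(min(group, key=lambda x: (-(x[1] - x[0] - x[2]),
                                                     x[2], x[0])))
            group = [w]
    if group:
        out.append(min(group, key=lambda x: (-(x[1] - x[0] - x[2]),
                                             x[2], x[0])))
    return out


def find_long_repeats(sequence: str, min_len: int = 30, max_mismatch: int = 3,
                      min_identity: float = 0.90, max_reports: int = 10000,
                      seed_k: int = 7) -> list[RepeatHit]:
    """Maximal direct and palindromic repeat pairs (see module docstring)."""
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    sequence = sequence.upper()
    n = len(sequence)
    rc = revcomp(sequence)
    found: dict[tuple, RepeatHit] = {}

    # direct: sequence vs itself, diagonals d > 0
    direct_seeds = _seed_diagonals(sequence, sequence, seed_k)
    for d in sorted(x for x in direct_seeds if x > 0):
        span = n - d
        if span < min_len:
            continue

        def mm_direct(t, d=d):
            return sequence[t] != sequence[t + d] or sequence[t] == "N"

        raw = _windows_near_seeds(mm_direct, 0, span, direct_seeds[d],
                                  max_mismatch, min_len)
        windows = [(lo, hi, k) for lo, hi, k in raw
                   if 1.0 - k / (hi - lo) >= min_identity]
        for lo, hi, k in _best_per_overlap_group(windows):
            length = hi - lo
            identity = 1.0 - k / length
            key = ("direct", lo, hi, d)
            found[key] = RepeatHit(
                kind="direct", intervals=[(lo, hi), (lo + d, hi + d)],
                length=length, n_mismatches=k, identity=identity)

    # palindromic: sequence vs its reverse complement
    pal_seeds = _seed_diagonals(sequence, rc, seed_k)
    for d in sorted(pal_seeds):
        lo_t, hi_t = max(0, -d), min(n, n - d)
        if hi_t - lo_t < min_len:
            continue

        def mm_pal(t, d=d):
            return sequence[t] != rc[t + d] or sequence[t] == "N"

        raw = _windows_near_seeds(mm_pal, lo_t, hi_t, pal_seeds[d],
                                  max_mismatch, min_len)
        windows = [(lo, hi, k) for lo, hi, k in raw
                   if 1.0 - k / (hi - lo) >= min_identity]
        for lo, hi, k in _best_per_overlap_group(windows):
            length = hi - lo
            identity = 1.0 - k / length
            a = (lo, hi)
            b = (n - (hi + d), n - (lo + d))   # second copy, forward coords
            if a == b:
                continue                        # perfect self-palindrome
            first, second = sorted([a, b])
            key = ("palindromic", first, second)
            if key in found:
                continue
            found[key] = RepeatHit(
                kind="palindromic", intervals=[first, second],
                length=length, n_mismatches=k, identity=identity,
                is_ir_pair=length >= IR_PAIR_MIN_LEN)

    # a palindromic pair is seen from both copies' perspectives; merge the
    # mirror windows (overlapping in both intervals) keeping the best one
    palindromic = [h for h in found.values() if h.kind == "palindromic"]
    kept: list[RepeatHit] = [h for h in found.values() if h.kind == "direct"]
    for hit in sorted(palindromic,
                      key=lambda h: (-(h.length - h.n_mismatches),
                                     h.n_mismatches, h.intervals[0])):
        def overlaps(a, b):
            return a[0] < b[1] and b[0] < a[1]
        if not any(k.kind == "palindromic"
                   and overlaps(k.intervals[0], hit.intervals[0])
                   and overlaps(k.intervals[1], hit.intervals[1])
                   for k in kept):
            kept.append(hit)
    hits = sorted(kept, key=lambda h: (-h.length, h.n_mismatches,
                                       h.intervals[0]))
    return hits[:max_reports]


# ---------------------------------------------------------------------------
# Context annotation and cross-species sharing
# ---------------------------------------------------------------------------

_CONTEXT_CLASSES = ("CDS", "tRNA", "rRNA", "intron", "pseudogene")


def _interval_context(interval: tuple[int, int],
                      annotations: Sequence[GeneAnnotation]) -> str:
    s, e = interval
    overlap: dict[str, int] = {}
    for ann in annotations:
        if ann.feature_class not in _CONTEXT_CLASSES:
            continue
        for ps, pe in ann.parts:
            o = min(e, pe) - max(s, ps)
            if o > 0:
                overlap[ann.feature_class] = overlap.get(ann.feature_class, 0) + o
    covered = sum(overlap.values())
    overlap["intergenic"] = max(0, (e - s) - covered)
    top = max(overlap.values())
    winners = [c for c, v in overlap.items() if v == top]
    return winners[0] if len(winners) == 1 else "intergenic"


def annotate_repeat_context(hits: Sequence[RepeatHit],
                            annotations: Sequence[GeneAnnotation]
                            ) -> list[RepeatHit]:
    """Label each hit interval with its majority feature class."""
    for hit in hits:
        hit.contexts = [_interval_context(iv, annotations)
                        for iv in hit.intervals]
    return list(hits)


def repeat_locus_key(hit: RepeatHit,
                     annotations: Sequence[GeneAnnotation]) -> tuple:
    """Coordinate-free locus identity: kind, unit and flanking genes."""
    mid = sum(hit.intervals[0]) // 2
    upstream = downstream = None
    best_up = best_down = None
    for ann in annotations:
        if ann.end <= mid and (best_up is None or ann.end > best_up):
            best_up, upstream = ann.end, ann.name
        if ann.start >= mid and (best_down is None or ann.start < best_down):
            best_down, downstream = ann.start, ann.name
        if ann.start <= mid < ann.end:
            upstream = downstream = ann.name
            break
    return (hit.kind, hit.unit, upstream, downstream)


def shared_repeats(hits_by_species: dict[str, Sequence[RepeatHit]],
                   annotations_by_species: dict[str, Sequence[GeneAnnotation]]
                   ) -> set[tuple]:
    """Repeat loci present in every species, matched by locus key."""
    if len(hits_by_species) < 2:
        raise ValueError("need at least two species")
    keysets = []
    for species, hits in hits_by_species.items():
        anns = annotations_by_species[species]
        keysets.append({repeat_locus_key(h, anns) for h in hits})
    shared = keysets[0]
    for ks in keysets[1:]:
        shared &= ks
    return shared


def summarize_repeats(hits: Sequence[RepeatHit]) -> dict:
    """Counts by kind and by length bin, IR pair excluded."""
    by_kind: dict[str, int] = {}
    by_bin: dict[str, int] = {}
    for hit in hits:
        if hit.is_ir_pair:
            continue
        by_kind[hit.kind] = by_kind.get(hit.kind, 0) + 1
        lo = (hit.length // 10) * 10
        label = f"{lo}-{lo + 9}"
        by_bin[label] = by_bin.get(label, 0) + 1
    return {"by_kind": by_kind, "by_length_bin": by_bin}
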