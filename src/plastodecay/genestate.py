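"""Gene degradation-state calling and the 22-character ndh matrix.

A query plastome is scanned for each reference coding sequence with a
Smith-Waterman local aligner (match +1, mismatch -1, linear gap -2); the
resulting hits are classified into one of four states:

``complete``
    >= 95% reference coverage, intact reading frame (ATG start, terminal
    stop, no internal stop, no frameshifting indel).
``pseudogene``
    > 20% coverage with at least one lesion. Uncovered reference ends are
    themselves coded as lesions (``no_start`` / ``no_stop``) so that every
    disrupted locus above the coverage floor lands here.
``fragment``
    <= 20% coverage but at least one hit of >= 25 bp ("decayed").
``deleted``
    no hit of >= 25 bp at >= 70% identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .parsimony import CharacterMatrix
from .plastome import PlastomeRecord, revcomp
from .simulate import NDH_GENES

MIN_HIT_LEN = 25
MIN_IDENTITY = 0.70
COMPLETE_COVERAGE = 0.95
PSEUDOGENE_COVERAGE = 0.20
MATCH, MISMATCH, GAP = 2, -3, -5   # blastn-flavoured; noise drifts negative
_STOPS = {"TAA", "TAG", "TGA"}


class AmbiguousLocusError(ValueError):
    def __init__(self, message, hits):
        super().__init__(message)
        self.hits = hits


@dataclass
class LocalHit:
    """One local alignment between the query genome and a reference CDS.

    ``query_start/end`` are forward-strand genome coordinates regardless of
    ``strand``; ``pairs`` lists (ref_index, query_offset) aligned columns in
    coding orientation with ``None`` marking a gap on that side.
    """

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    score: int
    identity: float
    n_columns: int
    n_matches: int
    pairs: list[tuple[Optional[int], Optional[int]]] = field(repr=False,
                                                             default_factory=list)
    query_coding: str = ""

    def gap_runs(self) -> list[int]:
        runs, current = [], 0
        for r, q in self.pairs:
            if r is None or q is None:
                current += 1
            elif current:
                runs.append(current)
                current = 0
        if current:
            runs.append(current)
        return runs


@dataclass
class GeneStateCall:
    gene: str
    state: str
    coverage: float
    lesions: set[str] = field(default_factory=set)
    hits: list[LocalHit] = field(default_factory=list)

    def intervals(self) -> list[tuple[int, int]]:
        return [(h.query_start, h.query_end) for h in self.hits]


# ---------------------------------------------------------------------------
# Smith-Waterman (vectorized over the genome axis via a prefix-scan
# reformulation of the linear-gap horizontal term)
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 64, dtype=np.uint8)
    for i, b in enumerate("ACGTN"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _sw_matrix(ref: np.ndarray, query: np.ndarray) -> np.ndarray:
    m, n = len(ref), len(query)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    jj = np.arange(1, n + 1, dtype=np.int32)
    two_j = -GAP * jj
    for i in range(1, m + 1):
        sub = np.where((query == ref[i - 1]) & (query < 4) & (ref[i - 1] < 4),
                       MATCH, MISMATCH).astype(np.int32)
        b = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP)
        np.maximum(b, 0, out=b)
        scan = np.maximum.accumulate(b + two_j) - two_j
        H[i, 1:] = np.maximum(b, scan)
    return H


def _traceback(H: np.ndarray, ref: np.ndarray, query: np.ndarray,
               i: int, j: int):
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    matches = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = MATCH if (ref[i - 1] == query[j - 1] and ref[i - 1] < 4
                        and query[j - 1] < 4) else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + sub:
            pairs.append((i - 1, j - 1))
            matches += 1 if sub == MATCH else 0
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + GAP:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return pairs, matches, i, j


def _best_local(ref: np.ndarray, query: np.ndarray):
    H = _sw_matrix(ref, query)
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    score = int(H[i, j])
    if score <= 0:
        return None
    pairs, matches, i0, j0 = _traceback(H, ref, query, i, j)
    return {"score": score, "pairs": pairs, "matches": matches,
            "ref_start": i0, "ref_end": i, "q_start": j0, "q_end": j}


MIN_HIT_SCORE = 40  # noise floor: random genome-scale hits rarely reach this


def locate_gene(query: PlastomeRecord | str, reference_gene: str,
                min_len: int = MIN_HIT_LEN,
                min_identity: float = MIN_IDENTITY,
                max_hits: int = 50,
                min_score: int = MIN_HIT_SCORE) -> list[LocalHit]:
    """Maximal local alignments of the reference CDS on both genome strands.

    Hits shorter than ``min_len`` aligned columns, below ``min_identity``
    (matches / columns) or scoring under ``min_score`` (which suppresses
    the random short matches any genome-scale local alignment produces)
    are discarded. Found hits are masked and the scan repeats, so multiple
    disjoint remnants of one gene are all reported.
    """
    if len(reference_gene) < MIN_HIT_LEN:
        raise ValueError(f"reference gene shorter than {MIN_HIT_LEN} bp")
    genome = query.sequence if isinstance(query, PlastomeRecord) else query
    genome = genome.upper()
    ref = _encode(reference_gene.upper())
    n = len(genome)
    hits: list[LocalHit] = []
    for strand in "+-":
        text = genome if strand == "+" else revcomp(genome)
        q = _encode(text).copy()
        for _ in range(max_hits):
            best = _best_local(ref, q)
            if best is None or best["score"] < min_score:
                break
            js, je = best["q_start"], best["q_end"]
            n_cols = len(best["pairs"])
            identity = best["matches"] / n_cols if n_cols else 0.0
            if strand == "+":
                qs, qe = js, je
            else:
                qs, qe = n - je, n - js
            if n_cols >= min_len and identity >= min_identity:
                hits.append(LocalHit(
                    query_start=qs, query_end=qe,
                    ref_start=best["ref_start"], ref_end=best["ref_end"],
                    strand=strand, score=best["score"], identity=identity,
                    n_columns=n_cols, n_matches=best["matches"],
                    pairs=best["pairs"],
                    query_coding=text[js:je]))
            q[js:je] = 64  # mask and rescan
    hits.sort(key=lambda h: (h.query_start, h.query_end))
    return hits


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total, last_end = 0, None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def _check_ambiguous(hits: list[LocalHit]) -> None:
    for i, a in enumerate(hits):
        for b in hits[i + 1:]:
            if a.strand == b.strand:
                continue
            overlap = (min(a.query_end, b.query_end)
                       - max(a.query_start, b.query_start))
            shorter = min(a.query_end - a.query_start,
                          b.query_end - b.query_start)
            if shorter > 0 and overlap > 0.5 * shorter:
                raise AmbiguousLocusError(
                    "overlapping hits on contradictory strands", [a, b])


def _frame_lesions(hit: LocalHit, ref_len: int) -> set[str]:
    lesions: set[str] = set()
    if any(run % 3 for run in hit.gap_runs()):
        lesions.add("frameshift")
    # reconstruct aligned codons in the reference reading frame
    by_ref: dict[int, str] = {}
    qsyms = hit.query_coding
    qoffset = None
    for r, q in hit.pairs:
        if q is not None and qoffset is None:
            qoffset = q
        if r is not None and q is not None:
            by_ref[r] = qsyms[q - qoffset]
    n_codons = ref_len // 3
    if 0 in by_ref and 1 in by_ref and 2 in by_ref:
        if by_ref[0] + by_ref[1] + by_ref[2] != "ATG":
            lesions.add("no_start")
    else:
        lesions.add("no_start")
    last = (n_codons - 1) * 3
    if last in by_ref and last + 1 in by_ref and last + 2 in by_ref:
        if by_ref[last] + by_ref[last + 1] + by_ref[last + 2] not in _STOPS:
            lesions.add("no_stop")
    else:
        lesions.add("no_stop")
    for c in range(1, n_codons - 1):
        p = 3 * c
        if p in by_ref and p + 1 in by_ref and p + 2 in by_ref:
            codon = by_ref[p] + by_ref[p + 1] + by_ref[p + 2]
            if codon in _STOPS:
                lesions.add("internal_stop")
                break
    return lesions


def classify_gene_state(hits: list[LocalHit], reference_gene: str,
                        gene: str = "gene") -> GeneStateCall:
    """Four-state call (complete/pseudogene/fragment/deleted) from hits."""
    if not hits:
        return GeneStateCall(gene, "deleted", 0.0)
    _check_ambiguous(hits)
    coverage = _union_length([(h.ref_start, h.ref_end) for h in hits]) \
        / len(reference_gene)
    best = max(hits, key=lambda h: (h.ref_end - h.ref_start, h.n_matches))
    lesions = _frame_lesions(best, len(reference_gene))
    if coverage >= COMPLETE_COVERAGE and not lesions:
        return GeneStateCall(gene, "complete", coverage, set(), hits)
    if coverage > PSEUDOGENE_COVERAGE:
        return GeneStateCall(gene, "pseudogene", coverage, lesions, hits)
    return GeneStateCall(gene, "fragment", coverage, lesions, hits)


def classify_genome(query: PlastomeRecord, references: dict[str, str],
                    **kwargs) -> dict[str, GeneStateCall]:
    """Locate + classify every reference gene against one query genome."""
    calls = {}
    for gene, ref in references.items():
        hits = locate_gene(query, ref, **kwargs)
        calls[gene] = classify_gene_state(hits, ref, gene)
    return calls


# ---------------------------------------------------------------------------
# The 22-character ndh matrix
# ---------------------------------------------------------------------------

_ENCODE = {"complete": ("1", "2"), "pseudogene": ("1", "0"),
           "fragment": ("1", "1"), "deleted": ("0", "-")}
_DECODE = {v: k for k, v in _ENCODE.items()}


@dataclass
class NdhCharacterMatrix:
    """Taxa x 22 matrix: presence (1-11) and degradation state (12-22).

    Character i+11 is "-" (inapplicable) exactly when character i is 0.
    Gene order is fixed: ndhA..ndhK.
    """

    taxa: list[str]
    rows: dict[str, list[str]]

    def __post_init__(self):
        for taxon in self.taxa:
            row = self.rows[taxon]
            if len(row) != 22:
                raise ValueError(f"{taxon}: expected 22 characters")
            for i in range(11):
                if (row[i] == "0") != (row[i + 11] == "-"):
                    raise ValueError(
                        f"{taxon}: character {i + 12} must be '-' iff "
                        f"character {i + 1} is 0")

    def to_character_matrix(self, gap_as_state: bool = False) -> CharacterMatrix:
        return CharacterMatrix(self.rows, gap_as_state=gap_as_state)

    def decode(self) -> dict[str, dict[str, str]]:
        out = {}
        for taxon in self.taxa:
            row = self.rows[taxon]
            out[taxon] = {g: _DECODE[(row[i], row[i + 11])]
                          for i, g in enumerate(NDH_GENES)}
        return out

    def to_tsv(self) -> str:
        header = ["taxon"] + [f"char{i + 1}" for i in range(22)]
        lines = ["\t".join(header)]
        for taxon in self.taxa:
            lines.append("\t".join([taxon] + self.rows[taxon]))
        return "\n".join(lines) + "\n"

    def to_nexus(self) -> str:
        return self.to_character_matrix().to_nexus()


def encode_ndh_matrix(calls: dict[str, dict[str, "GeneStateCall | str"]]
                      ) -> NdhCharacterMatrix:
    """Encode per-taxon ndh state calls into the 22-character matrix."""
    rows = {}
    for taxon, gene_calls in calls.items():
        presence, states = [], []
        for gene in NDH_GENES:
            if gene not in gene_calls:
                raise ValueError(f"{taxon}: missing call for {gene}")
            call = gene_calls[gene]
            state = call.state if isinstance(call, GeneStateCall) else str(call)
            if state not in _ENCODE:
                raise ValueError(f"{taxon}/{gene}: unknown state {state!r}")
            p, s = _ENCODE[state]
            presence.append(p)
            states.append(s)
        rows[taxon] = presence + states
    return NdhCharacterMatrix(list(calls), rows)
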