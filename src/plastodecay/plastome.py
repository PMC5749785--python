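"""Plastome records, standard-format I/O and composition statistics.

Internal coordinates are 0-based half-open throughout; GFF3 and GenBank
conversions happen only at the file boundary (1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

VALID_ALPHABET = set("ACGTN")
FEATURE_CLASSES = {"CDS", "tRNA", "rRNA", "intron", "pseudogene", "other"}
REGION_NAMES = ("LSC", "IRa", "SSC", "IRb")


class PlastomeError(ValueError):
    pass


class NoQuadripartiteSignal(PlastomeError):
    """Raised when no inverted-repeat pair of the required size exists."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GeneAnnotation:
    """A (possibly multi-part) feature on the plastome.

    ``parts`` are 0-based half-open intervals ordered 5'->3' on the coding
    strand as they appear in genome coordinates.
    """

    name: str
    feature_class: str = "CDS"
    strand: str = "+"
    parts: list[tuple[int, int]] = field(default_factory=list)
    region: Optional[str] = None

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise PlastomeError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in "+-":
            raise PlastomeError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.parts:
            if not (0 <= s < e):
                raise PlastomeError(f"bad interval ({s}, {e}) on {self.name}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    def length(self) -> int:
        return sum(e - s for s, e in self.parts)


@dataclass
class PlastomeRecord:
    """A circular plastome: sequence, annotations and region boundaries."""

    identifier: str
    sequence: str
    annotations: list[GeneAnnotation] = field(default_factory=list)
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise PlastomeError(
                f"sequence of {self.identifier} contains unsupported symbols "
                f"{sorted(bad)}; only A/C/G/T/N are accepted")
        for ann in self.annotations:
            if ann.end > len(self.sequence):
                raise PlastomeError(
                    f"feature {ann.name} ends at {ann.end} beyond sequence "
                    f"length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, name: str) -> GeneAnnotation:
        for ann in self.annotations:
            if ann.name == name:
                return ann
        raise KeyError(name)

    def genes(self, name: str) -> list[GeneAnnotation]:
        return [a for a in self.annotations if a.name == name]

    def feature_sequence(self, ann: GeneAnnotation) -> str:
        """Coding-strand sequence of a feature (parts concatenated)."""
        chunks = [self.sequence[s:e] for s, e in ann.parts]
        seq = "".join(chunks)
        return revcomp(seq) if ann.strand == "-" else seq

    def region_sequence(self, region: str) -> str:
        s, e = self.regions[region]
        return self.sequence[s:e]


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases: 100*(G+C)/(A+C+G+T)."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise PlastomeError("empty (or all-N) sequence has no GC content")
    return 100.0 * (counts["G"] + counts["C"]) / total


@dataclass
class CodonUsage:
    counts: dict[str, int]
    frequencies: dict[str, float]
    amino_acid_totals: dict[str, int]
    n_codons: int
    trimmed: list[str] = field(default_factory=list)


def codon_usage(cds_set: Sequence[str], table_id: int = 11) -> CodonUsage:
    """Codon counts/frequencies and amino-acid totals (translation table 11).

    Sequences whose length is not a multiple of three are trimmed of the
    incomplete terminal codon; the trimming is recorded.
    """
    if not cds_set:
        raise PlastomeError("empty CDS set")
    table = CodonTable.unambiguous_dna_by_id[table_id]
    counts: dict[str, int] = {}
    trimmed = []
    for idx, cds in enumerate(cds_set):
        cds = cds.upper()
        if len(cds) % 3:
            trimmed.append(f"sequence {idx}: trimmed {len(cds) % 3} bp")
            cds = cds[: len(cds) - len(cds) % 3]
        for i in range(0, len(cds), 3):
            codon = cds[i:i + 3]
            counts[codon] = counts.get(codon, 0) + 1
    n = sum(counts.values())
    freqs = {c: k / n for c, k in counts.items()}
    aa: dict[str, int] = {}
    for codon, k in counts.items():
        if codon in table.stop_codons:
            name = "*"
        elif codon in table.forward_table:
            name = table.forward_table[codon]
        else:
            name = "X"  # codons containing N
        aa[name] = aa.get(name, 0) + k
    return CodonUsage(counts, freqs, aa, n, trimmed)


# ---------------------------------------------------------------------------
# Quadripartite structure detection
# ---------------------------------------------------------------------------

@dataclass
class QuadripartiteRegions:
    """Region boundaries on the canonical (LSC-first) linearization."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    rotation: int  # offset of canonical position 0 on the input sequence

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRa": self.ira,
                "SSC": self.ssc, "IRb": self.irb}

    def lengths(self) -> dict[str, int]:
        return {k: e - s for k, (s, e) in self.as_dict().items()}


def _best_palindromic_window(seq: str, min_ir: int, max_mismatch_frac: float,
                             k: int = 25):
    """Longest pair (a, b) with seq[b] ~ revcomp(seq[a]) on the circle."""
    n = len(seq)
    s2 = seq + seq
    rc2 = revcomp(s2)
    cap = n // 2
    # seed: exact k-mers shared between the doubled forward and rc sequences
    index: dict[str, list[int]] = {}
    for p in range(0, len(s2) - k + 1):
        index.setdefault(s2[p:p + k], []).append(p)
    diagonals: set[int] = set()
    for q in range(0, len(rc2) - k + 1, k // 2):
        for p in index.get(rc2[q:q + k], ()):
            diagonals.add(q - p)
    best = None
    mismatch_penalty = 4  # random flanks drift to -2/base, halting extension
    for d in diagonals:
        lo = max(0, -d)
        hi = min(len(s2), len(rc2) - d)
        if hi - lo < min_ir:
            continue
        # Kadane max-scoring subarray: windows start and end on exact matches
        cur, cur_start = 0, lo
        window = None
        for t in range(lo, hi):
            sc = 1 if s2[t] == rc2[t + d] else -mismatch_penalty
            if cur <= 0:
                cur, cur_start = sc, t
            else:
                cur += sc
            if window is None or cur > window[0]:
                window = (cur, cur_start, t)
        if window is None:
            continue
        score, a0, a_last = window
        length = a_last - a0 + 1
        mism = (length - score) // (mismatch_penalty + 1)
        if length < min_ir or length > cap or \
                mism > max_mismatch_frac * length:
            continue
        a1 = a_last + 1
        b0 = 2 * n - (a1 + d)
        sa, sb = a0 % n, b0 % n
        # require disjoint circular arcs [sa, sa+length), [sb, sb+length)
        if (sb - sa) % n >= length and (sa - sb) % n >= length:
            if best is None or length > best[0]:
                best = (length, sa, sb)
    return best


def detect_quadripartite(seq: str, min_ir: int = 1000,
                         max_mismatch_frac: float = 0.01) -> QuadripartiteRegions:
    """Locate the IR pair and derive LSC/IRa/SSC/IRb boundaries.

    The maximal pair of disjoint intervals that are reverse complements
    (<=1% mismatches) and each >= ``min_ir`` defines the IRs; the larger
    inter-IR arc is the LSC, the smaller the SSC, and the canonical
    linearization is rotated so the LSC starts at position 0. Raises
    :class:`NoQuadripartiteSignal` when no such pair exists.
    """
    n = len(seq)
    if n < 4 * min_ir:
        raise PlastomeError(f"sequence ({n} bp) shorter than 4*min_ir")
    seq = seq.upper()
    best = _best_palindromic_window(seq, min_ir, max_mismatch_frac)
    if best is None:
        raise NoQuadripartiteSignal(
            f"no inverted pair >= {min_ir} bp found; single-copy genome")
    ir_len, a_start, b_start = best
    # order the two IR copies around the circle and measure the two gaps
    first, second = sorted([a_start, b_start])
    gap1 = (second - (first + ir_len)) % n       # between first and second
    gap2 = (first - (second + ir_len)) % n       # wraps past the origin
    seg1 = "".join(seq[(first + ir_len + i) % n] for i in range(gap1))
    seg2 = "".join(seq[(second + ir_len + i) % n] for i in range(gap2))
    if gap2 > gap1 or (gap2 == gap1 and seg2 < seg1):
        lsc_len, ssc_len = gap2, gap1
        rotation = (second + ir_len) % n
    else:
        lsc_len, ssc_len = gap1, gap2
        rotation = (first + ir_len) % n
    lsc = (0, lsc_len)
    ira = (lsc_len, lsc_len + ir_len)
    ssc = (lsc_len + ir_len, lsc_len + ir_len + ssc_len)
    irb = (lsc_len + ir_len + ssc_len, n)
    return QuadripartiteRegions(lsc, ira, ssc, irb, rotation)


def rotate_sequence(seq: str, offset: int) -> str:
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_GFF_TYPES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
              "intron": "intron", "pseudogene": "pseudogene",
              "other": "region"}
_GFF_TYPES_BACK = {v: k for k, v in _GFF_TYPES.items()}


def write_fasta(record: PlastomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.identifier}\n")
        for i in range(0, len(record.sequence), 70):
            fh.write(record.sequence[i:i + 70] + "\n")


def write_gff3(record: PlastomeRecord, path) -> None:
    lines = ["##gff-version 3",
             f"##sequence-region {record.identifier} 1 {len(record.sequence)}"]
    seen: dict[str, int] = {}
    for ann in record.annotations:
        seen[ann.name] = seen.get(ann.name, 0) + 1
        uid = ann.name if seen[ann.name] == 1 else f"{ann.name}.{seen[ann.name]}"
        attrs = f"ID={uid};Name={ann.name}"
        if ann.region:
            attrs += f";region={ann.region}"
        for s, e in ann.parts:
            lines.append("\t".join([
                record.identifier, "plastodecay",
                _GFF_TYPES[ann.feature_class],
                str(s + 1), str(e), ".", ann.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneAnnotation]:
    features: dict[str, GeneAnnotation] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise PlastomeError(f"{path}:{lineno}: expected 9 columns")
        _, _, ftype, start, end, _, strand, _, attrs = cols
        try:
            s, e = int(start) - 1, int(end)
        except ValueError as exc:
            raise PlastomeError(f"{path}:{lineno}: bad coordinates") from exc
        if s < 0 or e <= s:
            raise PlastomeError(f"{path}:{lineno}: bad interval {start}-{end}")
        attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        uid = attr_map.get("ID") or attr_map.get("Name")
        if not uid:
            raise PlastomeError(f"{path}:{lineno}: feature without ID/Name")
        name = uid
        if name not in features:
            features[name] = GeneAnnotation(
                name=attr_map.get("Name", uid),
                feature_class=_GFF_TYPES_BACK.get(ftype, "other"),
                strand=strand, parts=[],
                region=attr_map.get("region"))
            order.append(name)
        features[name].parts.append((s, e))
    for ann in features.values():
        ann.parts.sort()
    return [features[n] for n in order]


def read_fasta_sequence(path) -> tuple[str, str]:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def read_plastome(path, fmt: str = "fasta+gff3",
                  gff_path=None) -> PlastomeRecord:
    """Read a plastome from ``fasta+gff3`` or a GenBank flat file."""
    if fmt == "fasta+gff3":
        identifier, seq = read_fasta_sequence(path)
        annotations = read_gff3(gff_path) if gff_path else []
        record = PlastomeRecord(identifier, seq, annotations)
    elif fmt == "genbank":
        gb = next(SeqIO.parse(str(path), "genbank"))
        annotations = []
        for feat in gb.features:
            if feat.type not in ("CDS", "tRNA", "rRNA", "gene", "misc_feature"):
                continue
            if feat.type == "gene":
                continue  # rely on the typed child features
            name = (feat.qualifiers.get("gene", [None])[0]
                    or feat.qualifiers.get("locus_tag", [feat.type])[0])
            parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
            strand = "-" if feat.location.strand == -1 else "+"
            fclass = feat.type if feat.type in FEATURE_CLASSES else "other"
            annotations.append(GeneAnnotation(name, fclass, strand,
                                              sorted(parts)))
        record = PlastomeRecord(gb.id or gb.name, str(gb.seq), annotations)
    else:
        raise PlastomeError(f"unknown format {fmt!r}")
    try:
        regions = detect_quadripartite(record.sequence)
        if regions.rotation == 0:
            record.regions = regions.as_dict()
    except (NoQuadripartiteSignal, PlastomeError):
        pass
    return record


def region_report(record: PlastomeRecord) -> str:
    """TSV report of region sizes and GC content."""
    lines = ["region\tstart\tend\tlength_bp\tgc_percent"]
    lines.append("\t".join([
        "genome", "1", str(len(record)), str(len(record)),
        f"{gc_content(record.sequence):.1f}"]))
    for name in REGION_NAMES:
        if name in record.regions:
            s, e = record.regions[name]
            lines.append("\t".join([
                name, str(s + 1), str(e), str(e - s),
                f"{gc_content(record.sequence[s:e]):.1f}"]))
    return "\n".join(lines) + "\n"
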