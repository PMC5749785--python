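"""Synthetic plastomes, alignments and degradation scenarios.

Everything downstream (structure detection, gene-state calling, repeat
scanning, divergence statistics, parsimony) is testable against the ground
truth planted here. All operations are pure functions of their arguments,
with per-operation random streams derived from ``(seed, operation name)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import trees as _t
from ._rng import stream
from .plastome import GeneAnnotation, PlastomeRecord, revcomp

NDH_GENES = ["ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF",
             "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK"]
STATES = ("complete", "pseudogene", "fragment", "deleted")
LESION_KINDS = ("none", "start_loss", "premature_stop", "frameshift",
                "truncate", "excise")
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class BlueprintError(ValueError):
    pass


class MissingGeneError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Blueprint
# ---------------------------------------------------------------------------

@dataclass
class GeneSpec:
    name: str
    region: str                      # LSC, SSC or IRa (IRb copies are implied)
    strand: str = "+"
    n_codons: int = 100
    feature_class: str = "CDS"

    @property
    def length_bp(self) -> int:
        return 3 * self.n_codons


@dataclass
class RepeatPlan:
    kind: str                        # "ssr", "direct" or "palindromic"
    region: str = "LSC"
    unit: Optional[str] = None       # SSR motif
    copies: int = 0                  # SSR copy count
    length: int = 0                  # direct/palindromic copy length


@dataclass
class PlastomeBlueprint:
    """Recipe for one quadripartite genome with known gene/repeat truth."""

    lsc: int
    ir: int
    ssc: int
    genes: list[GeneSpec] = field(default_factory=list)
    repeats: list[RepeatPlan] = field(default_factory=list)
    seed: int = 0
    identifier: str = "synthetic"

    @property
    def total_length(self) -> int:
        return self.lsc + self.ssc + 2 * self.ir

    def validate(self) -> None:
        if min(self.lsc, self.ir, self.ssc) <= 0:
            raise BlueprintError("region lengths must be positive")
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise BlueprintError("duplicate gene names in roster")
        for g in self.genes:
            if g.region not in ("LSC", "SSC", "IRa"):
                raise BlueprintError(f"{g.name}: region must be LSC/SSC/IRa")
        for region, size in (("LSC", self.lsc), ("SSC", self.ssc),
                             ("IRa", self.ir)):
            members = [g for g in self.genes if g.region == region]
            used = sum(g.length_bp for g in members)
            if used + 2 * (len(members) + 1) > size:
                raise BlueprintError(
                    f"genes overflow region {region}: {used} bp of {size}")


def desk_blueprint(seed: int = 0) -> PlastomeBlueprint:
    """~14 kb desk-scale quadripartite genome carrying all 11 ndh genes."""
    genes = [GeneSpec("psbA", "LSC", "+", 120),
             GeneSpec("matK", "LSC", "-", 150),
             GeneSpec("rbcL", "LSC", "+", 140),
             GeneSpec("ndhA", "LSC", "+", 120),
             GeneSpec("ndhC", "LSC", "+", 40),
             GeneSpec("ndhD", "LSC", "-", 110),
             GeneSpec("ndhE", "LSC", "+", 34),
             GeneSpec("ndhG", "LSC", "+", 59),
             GeneSpec("ndhH", "LSC", "+", 131),
             GeneSpec("ndhI", "LSC", "-", 56),
             GeneSpec("ndhJ", "LSC", "+", 53),
             GeneSpec("ndhK", "LSC", "+", 75),
             GeneSpec("trnH", "LSC", "+", 25, "tRNA"),
             GeneSpec("ndhB", "IRa", "+", 120),
             GeneSpec("rrn16", "IRa", "+", 150, "rRNA"),
             GeneSpec("ndhF", "SSC", "-", 100)]
    repeats = [RepeatPlan("ssr", "LSC", unit="A", copies=12),
               RepeatPlan("ssr", "LSC", unit="AT", copies=7),
               RepeatPlan("direct", "LSC", length=40),
               RepeatPlan("palindromic", "LSC", length=35)]
    return PlastomeBlueprint(lsc=8000, ir=2500, ssc=1000, genes=genes,
                             repeats=repeats, seed=seed)


def mini_blueprint(seed: int = 0) -> PlastomeBlueprint:
    """~5.2 kb genome for fast round-trip tests (short ndh stand-ins)."""
    genes = ([GeneSpec(n, "LSC", "+" if i % 2 else "-", 60)
              for i, n in enumerate(NDH_GENES) if n not in ("ndhB", "ndhF")]
             + [GeneSpec("ndhB", "IRa", "+", 60),
                GeneSpec("ndhF", "SSC", "-", 60)])
    return PlastomeBlueprint(lsc=3200, ir=800, ssc=600, genes=genes,
                             seed=seed)


def full_scale_blueprint(seed: int = 0) -> PlastomeBlueprint:
    """~140 kb stress-test genome at realistic plastome scale."""
    bp = desk_blueprint(seed)
    bp.lsc, bp.ir, bp.ssc = 80000, 25000, 10000
    return bp


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthRow:
    taxon: str
    gene: str
    true_state: str
    lesion: str
    start: int        # 1-based inclusive (GFF3 convention); 0 when deleted
    end: int
    strand: str


@dataclass
class TruthManifest:
    rows: list[TruthRow] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)
    tree_newick: Optional[str] = None
    rate: Optional[float] = None

    def states(self, taxon: Optional[str] = None) -> dict[str, str]:
        return {r.gene: r.true_state for r in self.rows
                if taxon is None or r.taxon == taxon}

    def to_json(self) -> str:
        return json.dumps({"rows": [asdict(r) for r in self.rows],
                           "repeats": self.repeats,
                           "tree_newick": self.tree_newick,
                           "rate": self.rate}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        data = json.loads(text)
        return cls(rows=[TruthRow(**r) for r in data["rows"]],
                   repeats=data["repeats"],
                   tree_newick=data["tree_newick"], rate=data["rate"])

    def to_tsv(self) -> str:
        lines = ["taxon\tgene\ttrue_state\tlesion\tstart\tend\tstrand"]
        for r in self.rows:
            lines.append("\t".join([r.taxon, r.gene, r.true_state, r.lesion,
                                    str(r.start), str(r.end), r.strand]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "TruthManifest":
        rows = []
        for line in text.strip().splitlines()[1:]:
            taxon, gene, state, lesion, start, end, strand = line.split("\t")
            rows.append(TruthRow(taxon, gene, state, lesion,
                                 int(start), int(end), strand))
        return cls(rows=rows)


# ---------------------------------------------------------------------------
# Trees and sequence evolution
# ---------------------------------------------------------------------------

def generate_tree(n_taxa: int, seed: int = 0,
                  labels: Optional[Sequence[str]] = None) -> _t.PhyloTree:
    """Random binary unrooted tree with positive branch lengths."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if labels is None:
        labels = [f"T{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("labels length != n_taxa")
    rng = stream(seed, "generate_tree")
    return _t.random_topology(labels, rng, branch_lengths=(0.02, 0.2))


def _jc_mutate(seq_codes: np.ndarray, d: float,
               rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch: d expected substitutions/site."""
    if d <= 0:
        return seq_codes.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    hit = rng.random(seq_codes.size) < p_change
    out = seq_codes.copy()
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return codes


def evolve_alignment(tree: _t.PhyloTree, root_length: int, rate: float = 1.0,
                     seed: int = 0,
                     root_sequence: Optional[str] = None) -> dict[str, str]:
    """Evolve an ungapped alignment along ``tree`` under Jukes-Cantor.

    Branch divergence is ``branch_length * rate`` expected substitutions
    per site; the returned mapping has one equal-length row per leaf.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if root_length < 1 and root_sequence is None:
        raise ValueError("root_length must be >= 1")
    rng = stream(seed, "evolve_alignment")
    if root_sequence is None:
        root_codes = rng.integers(0, 4, size=root_length).astype(np.uint8)
    else:
        root_codes = _str_to_codes(root_sequence.upper())
    out: dict[str, str] = {}

    def descend(node: _t.Node, codes: np.ndarray) -> None:
        if node.is_leaf:
            out[node.label] = _codes_to_str(codes)
            return
        for child in node.children:
            d = (child.length or 0.0) * rate
            descend(child, _jc_mutate(codes, d, rng))

    descend(tree.root, root_codes)
    return out


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    non_stop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in _STOPS]
    idx = rng.integers(0, len(non_stop), size=n_codons - 2)
    codons = ["ATG"] + [non_stop[i] for i in idx] + ["TAA"]
    return "".join(codons)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return _codes_to_str(rng.integers(0, 4, size=n).astype(np.uint8))


def build_plastome(blueprint: PlastomeBlueprint) -> tuple[PlastomeRecord, TruthManifest]:
    """Materialize a blueprint into a quadripartite genome plus its truth.

    Genes are laid out left to right inside their region with even spacers;
    IRb is the exact reverse complement of IRa, so any IRa gene appears
    twice (the IRb copy has its strand flipped). Planted repeats occupy the
    spacer downstream of the last gene of their region.
    """
    blueprint.validate()
    rng = stream(blueprint.seed, "build_plastome")
    region_sizes = {"LSC": blueprint.lsc, "IRa": blueprint.ir,
                    "SSC": blueprint.ssc}
    region_offsets = {"LSC": 0, "IRa": blueprint.lsc,
                      "SSC": blueprint.lsc + blueprint.ir}
    region_seqs = {r: list(_random_seq(n, rng)) for r, n in region_sizes.items()}
    annotations: list[GeneAnnotation] = []
    truth_rows: list[TruthRow] = []
    cursors: dict[str, int] = {}

    for region in ("LSC", "IRa", "SSC"):
        members = [g for g in blueprint.genes if g.region == region]
        if not members:
            cursors[region] = 0
            continue
        used = sum(g.length_bp for g in members)
        spacer = (region_sizes[region] - used) // (len(members) + 1)
        pos = spacer
        for g in members:
            body = (_random_orf(g.n_codons, rng) if g.feature_class == "CDS"
                    else _random_seq(g.length_bp, rng))
            placed = revcomp(body) if g.strand == "-" else body
            region_seqs[region][pos:pos + g.length_bp] = list(placed)
            start = region_offsets[region] + pos
            annotations.append(GeneAnnotation(
                g.name, g.feature_class, g.strand,
                [(start, start + g.length_bp)], region))
            pos += g.length_bp + spacer
        cursors[region] = pos - spacer + 2  # first free position

    repeat_truth: list[dict] = []
    for plan in blueprint.repeats:
        if plan.region not in region_sizes:
            raise BlueprintError(f"repeat planned in unknown region {plan.region}")
        if plan.kind == "ssr":
            body = plan.unit * plan.copies
            need = len(body)
        elif plan.kind in ("direct", "palindromic"):
            core = _random_seq(plan.length, rng)
            second = core if plan.kind == "direct" else revcomp(core)
            gap = _random_seq(17, rng)
            body = core + gap + second
            need = len(body)
        else:
            raise BlueprintError(f"unknown repeat kind {plan.kind!r}")
        pos = cursors[plan.region]
        if pos + need + 2 > region_sizes[plan.region]:
            raise BlueprintError(f"repeat overflows region {plan.region}")
        region_seqs[plan.region][pos:pos + need] = list(body)
        # guard bases so planted tandem runs cannot extend into background
        for flank, avoid in ((pos - 1, body[0]), (pos + need, body[-1])):
            if 0 <= flank < region_sizes[plan.region] and \
                    region_seqs[plan.region][flank] == avoid:
                region_seqs[plan.region][flank] = "C" if avoid != "C" else "G"
        abs_pos = region_offsets[plan.region] + pos
        if plan.kind == "ssr":
            repeat_truth.append({"kind": "ssr", "unit": plan.unit,
                                 "copies": plan.copies,
                                 "start": abs_pos, "end": abs_pos + need})
        else:
            repeat_truth.append({
                "kind": plan.kind, "length": plan.length,
                "start1": abs_pos, "end1": abs_pos + plan.length,
                "start2": abs_pos + plan.length + 17, "end2": abs_pos + need})
        cursors[plan.region] = pos + need + 3

    # guard bases: the IR pair must not extend by chance into its flanks
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    lsc_seq, ssc_seq = region_seqs["LSC"], region_seqs["SSC"]
    if ssc_seq[0] == comp[ssc_seq[-1]]:
        ssc_seq[0] = "A" if ssc_seq[0] != "A" else "C"
    if lsc_seq[-1] == comp[lsc_seq[0]]:
        lsc_seq[-1] = "A" if lsc_seq[-1] != "A" else "C"
    ira = "".join(region_seqs["IRa"])
    sequence = ("".join(region_seqs["LSC"]) + ira
                + "".join(region_seqs["SSC"]) + revcomp(ira))
    # IRb mirror annotations for IRa genes
    irb_offset = blueprint.lsc + blueprint.ir + blueprint.ssc
    ira_offset = blueprint.lsc
    for ann in [a for a in annotations if a.region == "IRa"]:
        s, e = ann.parts[0]
        rs = irb_offset + (blueprint.ir - (e - ira_offset))
        re_ = irb_offset + (blueprint.ir - (s - ira_offset))
        annotations.append(GeneAnnotation(
            ann.name, ann.feature_class,
            "-" if ann.strand == "+" else "+", [(rs, re_)], "IRb"))

    regions = {"LSC": (0, blueprint.lsc),
               "IRa": (blueprint.lsc, blueprint.lsc + blueprint.ir),
               "SSC": (blueprint.lsc + blueprint.ir, irb_offset),
               "IRb": (irb_offset, blueprint.total_length)}
    record = PlastomeRecord(blueprint.identifier, sequence,
                            annotations, regions)
    for g in blueprint.genes:
        ann = record.gene(g.name)
        truth_rows.append(TruthRow(blueprint.identifier, g.name, "complete",
                                   "none", ann.start + 1, ann.end, g.strand))
    return record, TruthManifest(rows=truth_rows, repeats=repeat_truth)


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

@dataclass
class LesionRecipe:
    kind: str                 # one of LESION_KINDS except "none"
    truncate_to: int = 30     # bp kept by "truncate"

    def target_state(self) -> str:
        return {"start_loss": "pseudogene", "premature_stop": "pseudogene",
                "frameshift": "pseudogene", "truncate": "fragment",
                "excise": "deleted"}[self.kind]

    def __post_init__(self):
        if self.kind not in LESION_KINDS or self.kind == "none":
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.kind == "truncate" and self.truncate_to < 25:
            raise ValueError("fragments must retain >= 25 bp")


@dataclass
class DegradationScenario:
    """Per-gene lesion recipes for one taxon."""

    taxon: str
    recipes: dict[str, LesionRecipe] = field(default_factory=dict)

    def target_states(self, genes: Sequence[str]) -> dict[str, str]:
        return {g: (self.recipes[g].target_state() if g in self.recipes
                    else "complete") for g in genes}


def _edit_gene(sequence: str, ann: GeneAnnotation,
               recipe: LesionRecipe) -> tuple[str, int, Optional[tuple[int, int]]]:
    """Apply one lesion; returns (new sequence, length delta, new interval)."""
    s, e = ann.parts[0]
    coding = sequence[s:e]
    if ann.strand == "-":
        coding = revcomp(coding)
    if recipe.kind == "start_loss":
        coding = "T" + coding[1:]                      # ATG -> TTG
        new = coding
    elif recipe.kind == "premature_stop":
        m = (len(coding) // 3 // 2) * 3
        coding = coding[:m] + "TAA" + coding[m + 3:]
        new = coding
    elif recipe.kind == "frameshift":
        cut = (len(coding) // 3 // 3) * 3 + 1
        coding = coding[:cut] + "A" + coding[cut:]
        new = coding
    elif recipe.kind == "truncate":
        new = coding[:recipe.truncate_to]
    elif recipe.kind == "excise":
        new = ""
    else:  # pragma: no cover
        raise ValueError(recipe.kind)
    if ann.strand == "-" and new:
        new = revcomp(new)
    out = sequence[:s] + new + sequence[e:]
    delta = len(new) - (e - s)
    interval = None if not new else (s, s + len(new))
    return out, delta, interval


def apply_degradation(record: PlastomeRecord, scenario: DegradationScenario
                      ) -> tuple[PlastomeRecord, TruthManifest]:
    """Apply a scenario's lesions to (a copy of) one plastome.

    IR-duplicated genes are edited in both copies so the inverted repeats
    stay mirror images. Downstream annotation and region coordinates are
    shifted consistently after insertions/excisions.
    """
    known = {a.name for a in record.annotations}
    for gene in scenario.recipes:
        if gene not in known:
            raise MissingGeneError(f"gene {gene!r} not present in plastome")

    sequence = record.sequence
    annotations = [GeneAnnotation(a.name, a.feature_class, a.strand,
                                  list(a.parts), a.region)
                   for a in record.annotations]
    regions = dict(record.regions)

    targets = [a for a in annotations if a.name in scenario.recipes]
    for ann in sorted(targets, key=lambda a: -a.start):
        recipe = scenario.recipes[ann.name]
        sequence, delta, interval = _edit_gene(sequence, ann, recipe)
        edit_at = ann.start
        if interval is None:
            annotations = [a for a in annotations if a is not ann]
        else:
            ann.parts = [interval]
        if delta:
            for other in annotations:
                if other is ann:
                    continue
                other.parts = [(s + delta if s >= edit_at + 1 else s,
                                e + delta if e > edit_at else e)
                               for s, e in other.parts]
            regions = {name: (s + delta if s > edit_at else s,
                              e + delta if e >= edit_at + 1 else e)
                       for name, (s, e) in regions.items()}

    new_record = PlastomeRecord(scenario.taxon, sequence, annotations, regions)
    rows = []
    seen = set()
    for ann in record.annotations:
        if ann.name in seen or ann.feature_class not in ("CDS",):
            continue
        seen.add(ann.name)
        recipe = scenario.recipes.get(ann.name)
        state = recipe.target_state() if recipe else "complete"
        lesion = recipe.kind if recipe else "none"
        if state == "deleted":
            rows.append(TruthRow(scenario.taxon, ann.name, state, lesion,
                                 0, 0, ann.strand))
        else:
            cur = new_record.gene(ann.name)
            rows.append(TruthRow(scenario.taxon, ann.name, state, lesion,
                                 cur.start + 1, cur.end, cur.strand))
    return new_record, TruthManifest(rows=rows)


def orf_lesions(cds: str) -> set[str]:
    """Lesions evident from a coding sequence itself (no alignment)."""
    lesions: set[str] = set()
    if not cds.startswith("ATG"):
        lesions.add("no_start")
    if len(cds) % 3:
        lesions.add("frameshift")
    if cds[-3:] not in _STOPS:
        lesions.add("no_stop")
    n_codons = len(cds) // 3
    for c in range(1, n_codons - 1):
        if cds[3 * c:3 * c + 3] in _STOPS:
            lesions.add("internal_stop")
            break
    return lesions


def evolve_plastomes(record: PlastomeRecord, tree: _t.PhyloTree,
                     rate: float, seed: int = 0) -> dict[str, PlastomeRecord]:
    """Evolve a built plastome along a tree (JC, substitutions only).

    Only LSC+IRa+SSC evolve; each leaf's IRb is re-derived as the reverse
    complement of its IRa, mimicking the concerted evolution that keeps
    real inverted repeats identical.
    """
    if "IRb" not in record.regions:
        raise ValueError("record lacks quadripartite regions")
    irb_start, irb_end = record.regions["IRb"]
    ira_start, ira_end = record.regions["IRa"]
    core = record.sequence[:irb_start]
    leaf_rows = evolve_alignment(tree, len(core), rate=rate, seed=seed,
                                 root_sequence=core)
    out = {}
    for taxon, core_seq in leaf_rows.items():
        ira = core_seq[ira_start:ira_end]
        seq = core_seq + revcomp(ira)
        out[taxon] = PlastomeRecord(
            taxon, seq,
            [GeneAnnotation(a.name, a.feature_class, a.strand, list(a.parts),
                            a.region) for a in record.annotations],
            dict(record.regions))
    return out


def random_scenario(taxon: str, genes: Sequence[str], seed: int,
                    truncate_to: int = 30) -> DegradationScenario:
    """Random state per gene (uniform over the four states), seeded."""
    rng = stream(seed, "random_scenario")
    recipes = {}
    lesions_by_state = {"pseudogene": ["start_loss", "premature_stop",
                                       "frameshift"],
                        "fragment": ["truncate"], "deleted": ["excise"]}
    for gene in genes:
        state = STATES[int(rng.integers(0, 4))]
        if state == "complete":
            continue
        options = lesions_by_state[state]
        kind = options[int(rng.integers(0, len(options)))]
        recipes[gene] = LesionRecipe(kind, truncate_to=truncate_to)
    return DegradationScenario(taxon, recipes)
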