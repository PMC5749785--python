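"""End-to-end orchestration: simulate -> classify -> encode -> search ->
trace -> report, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from . import divergence as _dv
from . import genestate as _gs
from . import parsimony as _p
from . import repeats as _rp
from . import simulate as _sim
from . import trees as _t
from .plastome import write_fasta, write_gff3


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Thresholds and run parameters; defaults are the published values."""

    n_taxa: int = 6
    seed: int = 1
    rate: float = 0.02
    blueprint: str = "desk"           # desk | mini | full
    outgroup: Optional[str] = None    # default: first taxon
    search_method: str = "branch_and_bound"
    bootstrap_reps: int = 0
    scenarios: Optional[dict[str, dict[str, str]]] = None
    fragment_floor_bp: int = 25
    pseudogene_coverage_floor: float = 0.20
    repeat_min_len: int = 30
    repeat_min_identity: float = 0.90
    repeat_max_mismatch: int = 3
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: dict(_rp.DEFAULT_SSR_THRESHOLDS))
    outdir: str = "plastodecay_out"

    def __post_init__(self):
        positive = {"fragment_floor_bp": self.fragment_floor_bp,
                    "pseudogene_coverage_floor": self.pseudogene_coverage_floor,
                    "repeat_min_len": self.repeat_min_len,
                    "repeat_min_identity": self.repeat_min_identity}
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_taxa < 4:
            raise ConfigError("n_taxa must be >= 4 for tree search")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "ssr_thresholds" in data:
            data["ssr_thresholds"] = {int(k): int(v)
                                      for k, v in data["ssr_thresholds"].items()}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return yaml.safe_dump(out, sort_keys=True)


def default_scenarios(taxa: list[str]) -> dict[str, dict[str, str]]:
    """Progressive ndh degradation along the taxon list: the first two taxa
    keep a complete repertoire, later taxa accumulate pseudogenization,
    decay and deletion."""
    plans = [
        {},
        {},
        {"ndhA": "start_loss"},
        {"ndhA": "start_loss", "ndhC": "truncate"},
        {"ndhA": "premature_stop", "ndhC": "truncate", "ndhD": "excise"},
        {"ndhA": "premature_stop", "ndhC": "excise", "ndhD": "excise",
         "ndhG": "frameshift", "ndhE": "truncate"},
        {"ndhA": "excise", "ndhC": "excise", "ndhD": "excise",
         "ndhG": "start_loss", "ndhE": "truncate", "ndhI": "truncate"},
        {"ndhA": "excise", "ndhC": "excise", "ndhD": "excise",
         "ndhE": "excise", "ndhG": "excise", "ndhI": "truncate",
         "ndhJ": "frameshift"},
    ]
    return {t: plans[min(i, len(plans) - 1)] for i, t in enumerate(taxa)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the manifest dict."""
    t0 = time.time()
    outdir = Path(config.outdir)
    stage_times: dict[str, float] = {}
    for sub in ("calls", "matrix", "trees", "divergence", "repeats",
                "manifest", "genomes"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    def tick(stage: str) -> None:
        stage_times[stage] = round(time.time() - t0, 3)

    # -- simulate --------------------------------------------------------
    presets = {"desk": _sim.desk_blueprint, "mini": _sim.mini_blueprint,
               "full": _sim.full_scale_blueprint}
    if config.blueprint not in presets:
        raise ConfigError(f"unknown blueprint preset {config.blueprint!r}")
    blueprint = presets[config.blueprint](config.seed)
    base_record, base_truth = _sim.build_plastome(blueprint)
    tree = _sim.generate_tree(config.n_taxa, config.seed)
    taxa = tree.leaf_labels()
    evolved = _sim.evolve_plastomes(base_record, tree, config.rate,
                                    config.seed)
    scenario_map = config.scenarios or default_scenarios(taxa)
    truth_rows = []
    taxon_records = {}
    for taxon in taxa:
        recipes = {g: _sim.LesionRecipe(kind)
                   for g, kind in scenario_map.get(taxon, {}).items()}
        scenario = _sim.DegradationScenario(taxon, recipes)
        record, truth = _sim.apply_degradation(evolved[taxon], scenario)
        taxon_records[taxon] = record
        for row in truth.rows:
            if row.true_state == "complete":
                # background substitutions can themselves disable a gene;
                # the manifest records the genome as built, not the intent
                lesions = _sim.orf_lesions(
                    record.feature_sequence(record.gene(row.gene)))
                if lesions:
                    row.true_state = "pseudogene"
                    row.lesion = "evolved:" + ",".join(sorted(lesions))
        truth_rows.extend(truth.rows)
        write_fasta(record, outdir / "genomes" / f"{taxon}.fasta")
        write_gff3(record, outdir / "genomes" / f"{taxon}.gff3")
    manifest_truth = _sim.TruthManifest(rows=truth_rows,
                                        repeats=base_truth.repeats,
                                        tree_newick=_t.to_newick(tree),
                                        rate=config.rate)
    (outdir / "manifest" / "truth.json").write_text(manifest_truth.to_json())
    (outdir / "trees" / "true_tree.nwk").write_text(_t.to_newick(tree) + "\n")
    tick("simulate")

    # -- classify --------------------------------------------------------
    references = {g.name: base_record.feature_sequence(base_record.gene(g.name))
                  for g in blueprint.genes if g.feature_class == "CDS"}
    calls = {}
    call_lines = ["taxon\tgene\tstate\tcoverage\tlesions\tintervals"]
    for taxon in taxa:
        calls[taxon] = _gs.classify_genome(taxon_records[taxon], references)
        for gene, call in sorted(calls[taxon].items()):
            call_lines.append("\t".join([
                taxon, gene, call.state, f"{call.coverage:.3f}",
                ",".join(sorted(call.lesions)) or "-",
                ";".join(f"{s}-{e}" for s, e in call.intervals()) or "-"]))
    (outdir / "calls" / "gene_states.tsv").write_text(
        "\n".join(call_lines) + "\n")
    tick("classify")

    # -- encode ----------------------------------------------------------
    ndh_calls = {t: {g: calls[t][g] for g in _sim.NDH_GENES} for t in taxa}
    matrix = _gs.encode_ndh_matrix(ndh_calls)
    (outdir / "matrix" / "ndh_matrix.tsv").write_text(matrix.to_tsv())
    (outdir / "matrix" / "ndh_matrix.nex").write_text(matrix.to_nexus())
    tick("encode")

    # -- search + trace --------------------------------------------------
    cmatrix = matrix.to_character_matrix()
    result = _p.search_mp(cmatrix, method=config.search_method,
                          seed=config.seed)
    consensus = _t.strict_consensus(result.trees)
    outgroup = config.outgroup or taxa[0]
    changes = _p.acctran_map(result.trees[0], cmatrix, outgroup=outgroup)
    (outdir / "trees" / "mp_trees.nwk").write_text(
        "\n".join(_t.to_newick(t, lengths=False) for t in result.trees) + "\n")
    (outdir / "trees" / "consensus.nwk").write_text(
        _t.to_newick(consensus, lengths=False) + "\n")
    change_lines = ["character\tbranch\tfrom_state\tto_state\tdepth"]
    for per_char in changes:
        for ch in per_char:
            change_lines.append("\t".join([
                str(ch.character + 1), ch.branch_name, ch.from_state,
                ch.to_state, str(ch.depth)]))
    (outdir / "trees" / "acctran_changes.tsv").write_text(
        "\n".join(change_lines) + "\n")
    search_summary = {"min_length": result.min_length,
                      "n_mp_trees": len(result.trees),
                      "ci": round(result.ci, 6),
                      "ri": None if result.ri is None else round(result.ri, 6),
                      "method": result.method}
    if config.bootstrap_reps:
        support = _p.bootstrap_support(cmatrix, n_reps=config.bootstrap_reps,
                                       method=config.search_method,
                                       seed=config.seed)
        search_summary["bootstrap"] = {
            "|".join(sorted(min(s, key=sorted))): round(v, 1)
            for s, v in support.items()}
    (outdir / "trees" / "search_summary.json").write_text(
        json.dumps(search_summary, indent=1, sort_keys=True))
    tick("search")

    # -- divergence ------------------------------------------------------
    # statistics run on the pre-lesion evolved alignment (no indels)
    irb_start = base_record.regions["IRb"][0]
    evo_rows = {t: evolved[t].sequence[:irb_start] for t in taxa}
    partitions = {name: np.arange(s, min(e, irb_start))
                  for name, (s, e) in base_record.regions.items()
                  if s < irb_start}
    for g in blueprint.genes:
        ann = base_record.gene(g.name)
        if ann.end <= irb_start:
            partitions[g.name] = np.arange(ann.start, ann.end)
    aligned = _dv.AlignedMatrix(taxa, evo_rows, partitions)
    pstats = _dv.partition_stats(aligned)
    (outdir / "divergence" / "partition_stats.tsv").write_text(
        _dv.stats_table(pstats))
    hotspots = _dv.rank_hotspots(
        [s for s in pstats if s.name in {g.name for g in blueprint.genes}],
        k=10)
    (outdir / "divergence" / "hotspots.tsv").write_text(
        _dv.stats_table(hotspots))
    tick("divergence")

    # -- repeats ---------------------------------------------------------
    repeat_lines = ["taxon\tkind\tunit\tcopies\tlength\tidentity\t"
                    "intervals\tcontexts\tis_ir_pair"]
    for taxon in taxa:
        seq = taxon_records[taxon].sequence
        hits = (_rp.find_ssrs(seq, config.ssr_thresholds)
                + _rp.find_long_repeats(seq, min_len=config.repeat_min_len,
                                        max_mismatch=config.repeat_max_mismatch,
                                        min_identity=config.repeat_min_identity))
        _rp.annotate_repeat_context(hits, taxon_records[taxon].annotations)
        for h in hits:
            repeat_lines.append("\t".join([
                taxon, h.kind, h.unit or "-", str(h.copies), str(h.length),
                f"{h.identity:.3f}",
                ";".join(f"{s}-{e}" for s, e in h.intervals),
                ",".join(h.contexts), str(h.is_ir_pair)]))
    (outdir / "repeats" / "repeats.tsv").write_text(
        "\n".join(repeat_lines) + "\n")
    tick("repeats")

    # -- manifest --------------------------------------------------------
    outputs = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            outputs[str(path.relative_to(outdir))] = _sha256(path)
    manifest = {"version": __version__,
                "config": yaml.safe_load(config.to_yaml()),
                "stage_seconds": stage_times,
                "outputs_sha256": outputs}
    (outdir / "manifest" / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
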