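import numpy as np
import pytest
from scipy import stats as sps

from plastodecay import simulate as sim
from plastodecay import trees as t
from plastodecay.plastome import detect_quadripartite, revcomp

STOPS = {"TAA", "TAG", "TGA"}


class TestBlueprint:
    def test_total_length(self):
        bp = sim.PlastomeBlueprint(lsc=8000, ir=2500, ssc=1000)
        assert bp.total_length == 14000

    def test_overflow_rejected(self):
        bp = sim.PlastomeBlueprint(
            lsc=500, ir=300, ssc=300,
            genes=[sim.GeneSpec("g1", "LSC", "+", 100),
                   sim.GeneSpec("g2", "LSC", "+", 100)])
        with pytest.raises(sim.BlueprintError):
            bp.validate()

    def test_duplicate_names_rejected(self):
        bp = sim.PlastomeBlueprint(
            lsc=5000, ir=1000, ssc=800,
            genes=[sim.GeneSpec("g", "LSC"), sim.GeneSpec("g", "SSC")])
        with pytest.raises(sim.BlueprintError):
            bp.validate()


class TestBuildPlastome:
    def test_length_and_ir_mirror(self, desk_plastome):
        bp, record, _ = desk_plastome
        assert len(record) == bp.total_length == 14000
        assert record.region_sequence("IRb") == \
            revcomp(record.region_sequence("IRa"))

    def test_round_trip_region_detection(self, desk_plastome):
        bp, record, _ = desk_plastome
        regions = detect_quadripartite(record.sequence)
        assert regions.rotation == 0
        assert regions.lengths() == {"LSC": bp.lsc, "IRa": bp.ir,
                                     "SSC": bp.ssc, "IRb": bp.ir}

    def test_genes_have_intact_orfs(self, desk_plastome):
        bp, record, _ = desk_plastome
        for g in bp.genes:
            ann = record.gene(g.name)
            assert ann.length() == 3 * g.n_codons
            if g.feature_class != "CDS":
                continue
            cds = record.feature_sequence(ann)
            assert cds.startswith("ATG")
            assert cds[-3:] in STOPS
            assert not any(cds[i:i + 3] in STOPS
                           for i in range(3, len(cds) - 3, 3))

    def test_ir_gene_duplicated_with_flipped_strand(self, desk_plastome):
        _, record, _ = desk_plastome
        copies = record.genes("ndhB")
        assert {c.region for c in copies} == {"IRa", "IRb"}
        assert {c.strand for c in copies} == {"+", "-"}
        seqs = {record.feature_sequence(c) for c in copies}
        assert len(seqs) == 1  # identical coding sequence

    def test_planted_repeats_verbatim(self, desk_plastome):
        _, record, truth = desk_plastome
        for rep in truth.repeats:
            if rep["kind"] == "ssr":
                assert record.sequence[rep["start"]:rep["end"]] == \
                    rep["unit"] * rep["copies"]
            else:
                a = record.sequence[rep["start1"]:rep["end1"]]
                b = record.sequence[rep["start2"]:rep["end2"]]
                assert b == (a if rep["kind"] == "direct" else revcomp(a))

    def test_determinism(self):
        r1, _ = sim.build_plastome(sim.desk_blueprint(5))
        r2, _ = sim.build_plastome(sim.desk_blueprint(5))
        assert r1.sequence == r2.sequence


class TestEvolveAlignment:
    def test_rate_zero_identical(self):
        tree = sim.generate_tree(4, seed=0)
        rows = sim.evolve_alignment(tree, 300, rate=0.0, seed=1)
        assert len(set(rows.values())) == 1

    def test_negative_rate_rejected(self):
        tree = sim.generate_tree(4, seed=0)
        with pytest.raises(ValueError):
            sim.evolve_alignment(tree, 100, rate=-0.1, seed=1)

    def test_byte_identical_reruns(self):
        tree = sim.generate_tree(5, seed=2)
        assert sim.evolve_alignment(tree, 1000, 0.5, seed=9) == \
            sim.evolve_alignment(tree, 1000, 0.5, seed=9)

    def test_jc_expectation(self):
        # two leaves at path distance d: E[p] = 3/4 (1 - exp(-4d/3))
        tree = t.from_newick("(A:0.06,B:0.09,C:0.0001);")
        d = 0.15
        expected = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        obs = []
        for seed in range(50):
            rows = sim.evolve_alignment(tree, 100_000, rate=1.0, seed=seed)
            diff = sum(a != b for a, b in zip(rows["A"], rows["B"]))
            obs.append(diff / 100_000)
        se = np.std(obs, ddof=1) / np.sqrt(len(obs))
        assert abs(np.mean(obs) - expected) < 3 * se

    def test_base_composition_neutral(self):
        # pooled leaf base counts stay uniform under JC
        counts = np.zeros(4)
        for seed in range(20):
            tree = sim.generate_tree(4, seed=seed)
            rows = sim.evolve_alignment(tree, 2000, rate=0.5, seed=seed)
            for s in rows.values():
                for i, b in enumerate("ACGT"):
                    counts[i] += s.count(b)
        chi2 = sps.chisquare(counts)
        assert chi2.pvalue > 0.01


class TestApplyDegradation:
    @pytest.fixture()
    def built(self):
        return sim.build_plastome(sim.mini_blueprint(4))

    def test_excise_removes_gene_and_shrinks_genome(self, built):
        record, _ = built
        length = record.gene("ndhD").length()
        out, truth = sim.apply_degradation(
            record, sim.DegradationScenario(
                "tx", {"ndhD": sim.LesionRecipe("excise")}))
        assert len(out) == len(record) - length
        assert not out.genes("ndhD")
        assert truth.states()["ndhD"] == "deleted"

    def test_start_loss_keeps_length(self, built):
        record, _ = built
        out, _ = sim.apply_degradation(
            record, sim.DegradationScenario(
                "tx", {"ndhA": sim.LesionRecipe("start_loss")}))
        assert len(out) == len(record)
        cds = out.feature_sequence(out.gene("ndhA"))
        assert not cds.startswith("ATG") and cds.startswith("TTG")

    def test_frameshift_grows_by_one(self, built):
        record, _ = built
        out, _ = sim.apply_degradation(
            record, sim.DegradationScenario(
                "tx", {"ndhE": sim.LesionRecipe("frameshift")}))
        assert len(out) == len(record) + 1

    def test_truncate_floor_enforced(self):
        with pytest.raises(ValueError):
            sim.LesionRecipe("truncate", truncate_to=24)

    def test_unknown_gene(self, built):
        record, _ = built
        with pytest.raises(sim.MissingGeneError):
            sim.apply_degradation(record, sim.DegradationScenario(
                "tx", {"nope": sim.LesionRecipe("excise")}))

    def test_downstream_annotations_shifted(self, built):
        record, _ = built
        target = record.gene("ndhA")
        length = target.length()
        out, _ = sim.apply_degradation(
            record, sim.DegradationScenario(
                "tx", {"ndhA": sim.LesionRecipe("excise")}))
        for ann in record.annotations:
            if ann.name == "ndhA":
                continue
            new = out.gene(ann.name) if ann.region != "IRb" else None
            if new is None:
                continue
            expected_shift = length if ann.start > target.start else 0
            assert new.start == ann.start - expected_shift
            # sequence under the annotation is untouched
            assert out.feature_sequence(new) == record.feature_sequence(ann)

    def test_ir_copies_degraded_symmetrically(self, built):
        record, _ = built
        out, _ = sim.apply_degradation(
            record, sim.DegradationScenario(
                "tx", {"ndhB": sim.LesionRecipe("start_loss")}))
        a, b = out.genes("ndhB")
        assert out.feature_sequence(a) == out.feature_sequence(b)


class TestTruthManifest:
    def test_tsv_round_trip(self, built=None):
        record, _ = sim.build_plastome(sim.mini_blueprint(2))
        scenario = sim.random_scenario("tx9", sim.NDH_GENES, 9)
        _, manifest = sim.apply_degradation(record, scenario)
        again = sim.TruthManifest.from_tsv(manifest.to_tsv())
        assert again.rows == manifest.rows

    def test_json_round_trip(self):
        record, truth = sim.build_plastome(sim.desk_blueprint(2))
        truth.tree_newick = "(A,B,C);"
        truth.rate = 0.05
        again = sim.TruthManifest.from_json(truth.to_json())
        assert again == truth


class TestEvolvePlastomes:
    def test_ir_stays_mirrored_and_structure_detectable(self):
        record, _ = sim.build_plastome(sim.desk_blueprint(3))
        tree = sim.generate_tree(4, seed=3)
        out = sim.evolve_plastomes(record, tree, rate=0.05, seed=3)
        for taxon, rec in out.items():
            assert len(rec) == len(record)
            assert rec.region_sequence("IRb") == \
                revcomp(rec.region_sequence("IRa"))
            regions = detect_quadripartite(rec.sequence)
            assert regions.lengths() == {
                k: e - s for k, (s, e) in record.regions.items()}
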