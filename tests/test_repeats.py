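import numpy as np
import pytest

from plastodecay import repeats as rp
from plastodecay.plastome import GeneAnnotation, revcomp
from oracles import long_repeat_oracle, ssr_oracle


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestFindSsrs:
    def test_mono_run_meets_threshold(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 400) + "G" + "A" * 10 + "G" + _random_seq(rng, 400)
        hits = [h for h in rp.find_ssrs(seq) if h.unit == "A"]
        assert len(hits) == 1
        assert hits[0].copies == 10
        assert hits[0].intervals == [(401, 411)]

    def test_nine_copies_below_floor(self):
        seq = "GC" * 30 + "C" + "A" * 9 + "G" + "GT" * 30
        assert all(h.unit != "A" for h in rp.find_ssrs(seq))

    def test_dinucleotide_not_double_mono(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 200) + "G" + "AT" * 6 + "G" + _random_seq(rng, 200)
        hits = rp.find_ssrs(seq)
        (hit,) = [h for h in hits if 195 < h.intervals[0][0] < 215]
        assert hit.unit == "AT" and hit.copies == 6

    def test_periodic_unit_reports_smallest_period(self):
        seq = "CG" + "A" * 20 + "CG"
        hits = rp.find_ssrs(seq)
        assert all(h.unit == "A" for h in hits if "A" in h.unit)

    def test_length_invariant(self):
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 500) + "ACG" * 7 + _random_seq(rng, 500)
        for h in rp.find_ssrs(seq):
            assert h.length == len(h.unit) * h.copies

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # low-entropy alphabet mix to provoke plenty of runs
        parts = []
        for _ in range(60):
            if rng.random() < 0.4:
                unit = _random_seq(rng, int(rng.integers(1, 7)))
                parts.append(unit * int(rng.integers(2, 14)))
            else:
                parts.append(_random_seq(rng, int(rng.integers(20, 120))))
        seq = "".join(parts)[:10_000]
        got = sorted((h.intervals[0][0], h.intervals[0][1], h.unit, h.copies)
                     for h in rp.find_ssrs(seq))
        assert got == ssr_oracle(seq, rp.DEFAULT_SSR_THRESHOLDS)


class TestFindLongRepeats:
    def test_planted_direct_pair(self):
        rng = np.random.default_rng(3)
        core = _random_seq(rng, 40)
        seq = (_random_seq(rng, 300) + core + _random_seq(rng, 400)
               + core + _random_seq(rng, 300))
        hits = [h for h in rp.find_long_repeats(seq) if h.kind == "direct"]
        assert len(hits) == 1
        (a, b) = hits[0].intervals
        assert a[0] <= 300 and a[1] >= 340
        assert b[0] <= 740 and b[1] >= 780

    def test_planted_palindromic_pair(self):
        rng = np.random.default_rng(4)
        core = _random_seq(rng, 35)
        seq = (_random_seq(rng, 250) + core + _random_seq(rng, 350)
               + revcomp(core) + _random_seq(rng, 250))
        hits = [h for h in rp.find_long_repeats(seq)
                if h.kind == "palindromic"]
        assert len(hits) == 1

    def test_min_len_floor(self):
        with pytest.raises(ValueError):
            rp.find_long_repeats("ACGT" * 100, min_len=7)

    def test_monotone_in_min_len(self):
        rng = np.random.default_rng(5)
        core = _random_seq(rng, 60)
        seq = _random_seq(rng, 200) + core + _random_seq(rng, 100) + core
        n30 = len(rp.find_long_repeats(seq, min_len=30))
        n50 = len(rp.find_long_repeats(seq, min_len=50))
        assert n50 <= n30

    def test_strand_symmetry(self):
        rng = np.random.default_rng(6)
        core = _random_seq(rng, 45)
        seq = (_random_seq(rng, 150) + core + _random_seq(rng, 100)
               + revcomp(core) + _random_seq(rng, 100) + core)
        fwd = rp.find_long_repeats(seq)
        rev = rp.find_long_repeats(revcomp(seq))
        assert sorted((h.kind, h.length, h.n_mismatches) for h in fwd) == \
            sorted((h.kind, h.length, h.n_mismatches) for h in rev)

    @pytest.mark.parametrize("seed", [20, 21])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = list(_random_seq(rng, 2000))
        # plant a handful of degraded copies
        for _ in range(4):
            length = int(rng.integers(30, 70))
            src = int(rng.integers(0, 2000 - length))
            dst = int(rng.integers(0, 2000 - length))
            chunk = seq[src:src + length]
            if rng.random() < 0.5:
                chunk = list(revcomp("".join(chunk)))
            for _ in range(int(rng.integers(0, 4))):
                chunk[int(rng.integers(length))] = "ACGT"[int(rng.integers(4))]
            seq[dst:dst + length] = chunk
        seq = "".join(seq)
        got = {(h.kind, tuple(h.intervals[0]), tuple(h.intervals[1]),
                h.n_mismatches)
               for h in rp.find_long_repeats(seq)}
        assert got == long_repeat_oracle(seq)


class TestContextAnnotation:
    ANNS = [GeneAnnotation("g1", "CDS", "+", [(100, 400)]),
            GeneAnnotation("i1", "intron", "+", [(400, 500)]),
            GeneAnnotation("t1", "tRNA", "+", [(800, 875)])]

    def test_inside_cds(self):
        hit = rp.RepeatHit("tandem", [(150, 170)], 20, unit="A", copies=20)
        rp.annotate_repeat_context([hit], self.ANNS)
        assert hit.context == "CDS"

    def test_intergenic(self):
        hit = rp.RepeatHit("tandem", [(600, 630)], 30, unit="AT", copies=15)
        rp.annotate_repeat_context([hit], self.ANNS)
        assert hit.context == "intergenic"

    def test_majority_rule(self):
        # 60/40 split between CDS and intron -> CDS
        hit = rp.RepeatHit("tandem", [(340, 440)], 100, unit="A", copies=100)
        rp.annotate_repeat_context([hit], self.ANNS)
        assert hit.context == "CDS"

    def test_tie_goes_intergenic(self):
        hit = rp.RepeatHit("tandem", [(350, 450)], 100, unit="A", copies=100)
        rp.annotate_repeat_context([hit], self.ANNS)
        assert hit.context == "intergenic"


class TestSharedRepeats:
    def _species(self, seq, anns):
        hits = rp.find_ssrs(seq)
        rp.annotate_repeat_context(hits, anns)
        return hits

    def test_identical_genomes_share_everything(self):
        rng = np.random.default_rng(9)
        seq = (_random_seq(rng, 300) + "A" * 12 + _random_seq(rng, 300)
               + "TG" * 8 + _random_seq(rng, 300))
        anns = [GeneAnnotation("gA", "CDS", "+", [(50, 250)])]
        hits = self._species(seq, anns)
        shared = rp.shared_repeats({"s1": hits, "s2": hits},
                                   {"s1": anns, "s2": anns})
        assert len(shared) == len({rp.repeat_locus_key(h, anns)
                                   for h in hits})

    def test_disjoint_sets_share_nothing(self):
        rng = np.random.default_rng(10)
        s1 = _random_seq(rng, 200) + "A" * 12 + _random_seq(rng, 200)
        s2 = _random_seq(rng, 200) + "CT" * 8 + _random_seq(rng, 200)
        shared = rp.shared_repeats(
            {"s1": self._species(s1, []), "s2": self._species(s2, [])},
            {"s1": [], "s2": []})
        assert shared == set()

    def test_planted_shared_loci_recovered(self):
        rng = np.random.default_rng(11)
        shared_units = ["A" * 11, "GT" * 7, "CAT" * 6, "C" * 13, "TA" * 9]
        anns = {}
        hitmap = {}
        for sp in ("s1", "s2", "s3"):
            chunks = []
            gene_anns = []
            pos = 0
            for i, unit_run in enumerate(shared_units):
                gene = _random_seq(rng, 120)
                chunks.append(gene)
                gene_anns.append(GeneAnnotation(
                    f"g{i}", "CDS", "+", [(pos, pos + 120)]))
                pos += 120
                chunks.append("G" + unit_run + "G")
                pos += len(unit_run) + 2
                filler = _random_seq(rng, 80)  # species-specific noise zone
                chunks.append(filler)
                pos += 80
            seq = "".join(chunks)
            anns[sp] = gene_anns
            hitmap[sp] = self._species(seq, gene_anns)
        shared = rp.shared_repeats(hitmap, anns)
        planted_kinds = {("tandem", u[:1] if len(set(u)) == 1 else None)
                         for u in shared_units}
        assert len(shared) >= 5

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            rp.shared_repeats({"s1": []}, {"s1": []})


class TestSummary:
    def test_ir_pair_excluded(self):
        hits = [rp.RepeatHit("palindromic", [(0, 2000), (5000, 7000)], 2000,
                             is_ir_pair=True),
                rp.RepeatHit("direct", [(10, 50), (100, 140)], 40)]
        summary = rp.summarize_repeats(hits)
        assert summary["by_kind"] == {"direct": 1}
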