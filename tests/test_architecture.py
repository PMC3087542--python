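"""IR detection, quadripartite partitioning, region stats, content diffs."""

from __future__ import annotations

import random

import pytest

from plastarch.architecture import (
    QuadripartiteStructure,
    brute_force_ir_pair,
    classify_gene_regions,
    detect_inverted_repeat,
    gene_content_diff,
    quadripartite_total,
    region_sequence,
    region_stats,
)
from plastarch.errors import UnsupportedInputError
from plastarch.model import GeneFeature, PlastomeRecord, revcomp
from plastarch.simulate import gen_plastome


def _random_seq(n, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _constructed_circle(seed=11):
    """X(100) + R(30) + Y(40) + revcomp(R), all flanks repeat-free."""
    rng = random.Random(seed)
    while True:
        x = _random_seq(100, rng.randrange(1 << 30))
        r = _random_seq(30, rng.randrange(1 << 30))
        y = _random_seq(40, rng.randrange(1 << 30))
        seq = x + r + y + revcomp(r)
        oracle = brute_force_ir_pair(seq, 10)
        if oracle is not None and oracle[2] == 30:
            return seq


class TestDetection:
    def test_constructed_circle(self):
        seq = _constructed_circle()
        rec = PlastomeRecord("toy", seq, circular=True)
        st = detect_inverted_repeat(rec, min_length=10)
        assert st is not None
        assert st.ir_length == 30
        assert st.lsc_length == 100
        assert st.ssc_length == 40
        # the detected copies really are reverse complements
        assert region_sequence(seq, st.ira) == revcomp(region_sequence(seq, st.irb))

    def test_repeat_free_circle_returns_none(self):
        for seed in range(3):
            seq = _random_seq(1000, seed=100 + seed)
            rec = PlastomeRecord(f"r{seed}", seq, circular=True)
            if brute_force_ir_pair(seq, 50) is None:
                assert detect_inverted_repeat(rec, min_length=50) is None
                return
        pytest.fail("no repeat-free 1-kb circle found in three draws")

    def test_linear_record_unsupported(self):
        rec = PlastomeRecord("lin", "ACGT" * 50, circular=False)
        with pytest.raises(UnsupportedInputError):
            detect_inverted_repeat(rec, min_length=10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle_on_small_circles(self, seed):
        """Detector output equals the quadratic all-pairs scan."""
        rng = random.Random(seed)
        n = rng.randint(60, 120)
        seq = _random_seq(n, seed=1000 + seed)
        # plant a small IR in half the cases
        if seed % 2:
            r = _random_seq(12, seed=2000 + seed)
            seq = seq[: n // 3] + r + seq[n // 3 :] + revcomp(r)
        rec = PlastomeRecord("t", seq, circular=True)
        oracle = brute_force_ir_pair(seq, 5)
        st = detect_inverted_repeat(rec, min_length=5)
        if oracle is None:
            assert st is None
        else:
            i, j, length = oracle
            assert st is not None
            assert st.ir_length == length
            assert {st.ira[0] % len(seq), st.irb[0] % len(seq)} == {i, j}

    def test_tiling_conservation(self):
        rec, log = gen_plastome(lsc_len=1000, ssc_len=400, ir_len=300, n_genes=5, seed=7)
        st = detect_inverted_repeat(rec, min_length=100)
        assert st is not None
        assert st.lsc_length + st.ssc_length + 2 * st.ir_length == st.total_length
        assert (st.ira, st.irb) == log.ir_intervals

    def test_rotation_invariance(self):
        rec, _ = gen_plastome(lsc_len=800, ssc_len=300, ir_len=200, n_genes=4, seed=9)
        st = detect_inverted_repeat(rec, min_length=100)
        n = len(rec.sequence)
        k = 137
        rot = rec.rotated(k)
        st_rot = detect_inverted_repeat(rot, min_length=100)
        assert st_rot is not None and st_rot.ir_length == st.ir_length
        starts = {(st.ira[0] - k) % n, (st.irb[0] - k) % n}
        assert {st_rot.ira[0] % n, st_rot.irb[0] % n} == starts


class TestRegionStats:
    def test_printed_region_sums(self):
        assert quadripartite_total(93_542, 19_469, 10_149) == 133_309
        assert quadripartite_total(91_862, 27_205, 13_118) == 145_303

    def test_all_g_circle_gc_one(self):
        n = 120
        seq = "G" * n
        st = QuadripartiteStructure(
            ira=(50, 70), irb=(100, 120), lsc=(0, 50), ssc=(70, 100),
            ir_length=20, lsc_length=50, ssc_length=30, total_length=n,
        )
        rec = PlastomeRecord("allg", seq, circular=True)
        rep = region_stats(rec, st)
        assert rep.gc_lsc == rep.gc_ssc == rep.gc_ir == rep.gc_total == 1.0
        assert rep.total_length == n

    def test_gc_excludes_n(self):
        rec = PlastomeRecord("n", "GCNNAT" * 20, circular=True)
        st = QuadripartiteStructure(
            ira=(40, 60), irb=(100, 120), lsc=(0, 40), ssc=(60, 100),
            ir_length=20, lsc_length=40, ssc_length=40, total_length=120,
        )
        rep = region_stats(rec, st)
        assert rep.gc_total == pytest.approx(0.5)


class TestGeneRegions:
    def _record_with_structure(self):
        rec, log = gen_plastome(
            lsc_len=1500, ssc_len=600, ir_len=400, n_genes=10, seed=21,
            straddle_junctions=2,
        )
        st = detect_inverted_repeat(rec, min_length=100)
        assert st is not None
        return rec, st, log

    def test_ir_duplicate_copy_count(self):
        rec, st, _ = self._record_with_structure()
        assignment = classify_gene_regions(rec, st)
        ir_genes = {
            rec.features[i].name
            for i, lab in assignment.regions.items()
            if lab == "IR"
        }
        for g in ir_genes:
            assert assignment.copy_counts[g] == 2

    def test_junction_straddlers_flagged_partial(self):
        rec, st, log = self._record_with_structure()
        assignment = classify_gene_regions(rec, st)
        labels = {
            rec.features[i].name: lab for i, lab in assignment.regions.items()
        }
        # generator plants jnc1 across LSC/IRA and jnc2 across IRA/SSC
        assert labels["jnc1"] == "IR-partial(LSC)"
        assert labels["jnc2"] == "IR-partial(SSC)"

    def test_four_junction_tables_present(self):
        rec, st, _ = self._record_with_structure()
        assignment = classify_gene_regions(rec, st)
        assert set(assignment.junctions) == {"LSC/IRA", "IRA/SSC", "SSC/IRB", "IRB/LSC"}
        flagged = {
            g for genes in assignment.junctions.values() for g, p in genes if p
        }
        assert {"jnc1", "jnc2"} <= flagged

    def test_straddler_via_manual_record(self):
        # a gene across the IRB/SSC junction is IR-partial(SSC)
        seq = "A" * 300
        st = QuadripartiteStructure(
            ira=(100, 150), irb=(250, 300), lsc=(0, 100), ssc=(150, 250),
            ir_length=50, lsc_length=100, ssc_length=100, total_length=300,
        )
        feat = GeneFeature("ndhF", 1, ((230, 270),), "CDS")
        rec = PlastomeRecord("m", seq, True, [feat])
        assignment = classify_gene_regions(rec, st)
        assert assignment.regions[0] == "IR-partial(SSC)"


class TestContentDiff:
    def _rec(self, name, genes):
        seq = "ACGT" * 300
        feats = []
        pos = 0
        for gname, n_intervals, pseudo in genes:
            intervals = tuple(
                (pos + 40 * i, pos + 40 * i + 30) for i in range(n_intervals)
            )
            feats.append(GeneFeature(gname, 1, intervals, "CDS", pseudo))
            pos += 40 * n_intervals + 10
        return PlastomeRecord(name, seq, True, feats)

    def test_identical_records_empty_diff(self):
        a = self._rec("a", [("psbA", 1, False), ("clpP", 2, False)])
        b = self._rec("b", [("psbA", 1, False), ("clpP", 2, False)])
        diff = gene_content_diff(a, b)
        assert not any(
            [diff.only_in_a, diff.only_in_b, diff.pseudo_in_exactly_one,
             diff.intron_diffs, diff.copy_number_diffs]
        )

    def test_gene_presence_pseudo_and_introns(self):
        a = self._rec("equisetum", [("trnS-CGA", 1, False), ("clpP", 2, False), ("rps16", 1, False)])
        b = self._rec("isoetes", [("clpP", 3, False), ("rps16", 1, True), ("tufA", 1, True)])
        diff = gene_content_diff(a, b)
        assert diff.only_in_a == ["trnS-CGA"]
        assert diff.only_in_b == ["tufA"]
        assert diff.pseudo_in_exactly_one == ["rps16"]
        assert diff.intron_diffs == {"clpP": (1, 2)}

    def test_empty_feature_table_warns(self):
        a = self._rec("a", [("psbA", 1, False)])
        empty = PlastomeRecord("e", "ACGT" * 10, True, [])
        with pytest.warns(UserWarning):
            diff = gene_content_diff(a, empty)
        assert diff.only_in_a == []
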