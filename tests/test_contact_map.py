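import numpy as np
import pytest

from v2gmap.contact_map import (
    ConsensusLoop,
    Loop,
    build_consensus,
    canonicalize,
    merge_resolutions,
    promoter_interacting_ocrs,
    read_loops_bedpe,
    union_timepoints,
    write_loops_bedpe,
)
from v2gmap.genomic_core import OCR, GeneModel, GenomicInterval, promoter_windows


def mk_loop(s1, s2, resolution=1000, timepoint="unstim", chrom="chr1", loop_id=""):
    return Loop(
        GenomicInterval(chrom, s1, s1 + resolution),
        GenomicInterval(chrom, s2, s2 + resolution),
        resolution,
        timepoint,
        loop_id=loop_id,
    )


def oracle_merge(loops):
    """Exhaustive greedy oracle: same canonical ordering, but overlap
    decided by a from-scratch pairwise both-anchor check."""

    def ov(a, b):
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    items = sorted(
        loops,
        key=lambda l: (l.resolution, l.anchor1.chrom, l.anchor1.start, l.anchor1.end,
                       l.anchor2.start, l.anchor2.end, l.loop_id),
    )
    kept = []
    for cand in items:
        if not any(
            ov(cand.anchor1, k.anchor1) and ov(cand.anchor2, k.anchor2) for k in kept
        ):
            kept.append(cand)
    return [
        (k.anchor1.start, k.anchor1.end, k.anchor2.start, k.anchor2.end, k.resolution)
        for k in kept
    ]


def random_loops(rng, n, timepoint="unstim"):
    loops = []
    for i in range(n):
        res = int(rng.choice([1000, 2000, 4000]))
        a = (int(rng.integers(0, 80)) * res) % 200_000
        gap = int(rng.integers(2, 40)) * res
        loops.append(mk_loop(a, a + gap, res, timepoint, loop_id=f"l{i}"))
    return loops


class TestCanonicalize:
    def test_swaps_reversed(self):
        lp = Loop(
            GenomicInterval("chr1", 5000, 6000),
            GenomicInterval("chr1", 100, 1100),
            1000,
            "unstim",
        )
        c = canonicalize(lp)
        assert c.anchor1.start == 100 and c.anchor2.start == 5000

    def test_idempotent(self):
        lp = mk_loop(100, 5000)
        assert canonicalize(canonicalize(lp)) == canonicalize(lp)

    def test_trans_chromosomal_rejected(self):
        with pytest.raises(ValueError, match="trans"):
            Loop(
                GenomicInterval("chr1", 0, 1000),
                GenomicInterval("chr2", 5000, 6000),
                1000,
                "unstim",
            )

    def test_overlapping_anchors_rejected(self):
        with pytest.raises(ValueError):
            mk_loop(1000, 1500, 1000)

    def test_unknown_resolution(self):
        with pytest.raises(ValueError):
            Loop(
                GenomicInterval("chr1", 0, 500),
                GenomicInterval("chr1", 5000, 5500),
                500,
                "unstim",
            )


class TestMergeResolutions:
    def test_coarse_absorbed_by_fine(self):
        fine = mk_loop(10_000, 50_000, 1000, loop_id="fine")
        coarse = mk_loop(8_000, 48_000, 4000, loop_id="coarse")
        merged = merge_resolutions([fine, coarse])
        assert len(merged) == 1
        assert merged[0].resolution == 1000
        assert "coarse" in merged[0].absorbed

    def test_one_shared_anchor_keeps_both(self):
        l1 = mk_loop(10_000, 50_000, 1000, loop_id="a")
        l2 = mk_loop(10_000, 90_000, 1000, loop_id="b")
        assert len(merge_resolutions([l1, l2])) == 2

    def test_every_1kb_loop_retained(self, rng):
        for _ in range(30):
            loops = random_loops(rng, int(rng.integers(5, 60)))
            merged = merge_resolutions(loops)
            fine_keys = {
                (l.anchor1.start, l.anchor2.start)
                for l in loops
                if l.resolution == 1000
            }
            kept_fine = {
                (c.anchor1.start, c.anchor2.start)
                for c in merged
                if c.resolution == 1000
            }
            assert fine_keys == kept_fine

    def test_matches_exhaustive_oracle_100_fixtures(self, rng):
        for _ in range(100):
            loops = random_loops(rng, int(rng.integers(2, 80)))
            merged = merge_resolutions(loops)
            got = [
                (c.anchor1.start, c.anchor1.end, c.anchor2.start, c.anchor2.end,
                 c.resolution)
                for c in merged
            ]
            assert sorted(got) == sorted(oracle_merge(loops))

    def test_idempotent(self, rng):
        loops = random_loops(rng, 40)
        once = merge_resolutions(loops)
        twice = union_timepoints([once])
        assert [
            (c.anchor1, c.anchor2, c.resolution, c.timepoints) for c in twice
        ] == [(c.anchor1, c.anchor2, c.resolution, c.timepoints) for c in once]

    def test_output_never_larger(self, rng):
        loops = random_loops(rng, 50)
        assert len(merge_resolutions(loops)) <= len(loops)


class TestUnionTimepoints:
    def test_same_loop_all_stages(self):
        sets = [
            merge_resolutions([mk_loop(10_000, 50_000, 1000, tp, loop_id=f"l_{tp}")])
            for tp in ("unstim", "8h", "24h")
        ]
        merged = union_timepoints(sets)
        assert len(merged) == 1
        assert merged[0].timepoints == {"unstim", "8h", "24h"}

    def test_unique_loop_single_flag(self):
        sets = [
            merge_resolutions([mk_loop(10_000, 50_000, 1000, "unstim")]),
            merge_resolutions([mk_loop(100_000, 150_000, 1000, "8h")]),
        ]
        merged = union_timepoints(sets)
        flags = sorted(tuple(sorted(c.timepoints)) for c in merged)
        assert flags == [("8h",), ("unstim",)]

    def test_permutation_invariance(self, rng):
        per_tp = [random_loops(rng, 30, tp) for tp in ("unstim", "8h", "24h")]
        sets = [merge_resolutions(ls) for ls in per_tp]

        def key(consensus):
            return sorted(
                (c.anchor1.start, c.anchor2.start, c.resolution, tuple(sorted(c.timepoints)))
                for c in consensus
            )

        base = key(union_timepoints(sets))
        for order in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            assert key(union_timepoints([sets[i] for i in order])) == base


class TestPromoterInteractingOcrs:
    def _setup(self):
        gene = GeneModel("G1", "S1", "chr1", "+", (100_000,))
        windows = promoter_windows(gene)  # [98500, 100500)
        ocr = OCR("o1", GenomicInterval("chr1", 150_200, 150_600), frozenset({"unstim"}))
        loop = mk_loop(100_000, 150_000, 1000, "unstim", loop_id="L1")
        consensus = merge_resolutions([loop])
        return gene, windows, ocr, consensus

    def test_basic_contact(self):
        gene, windows, ocr, consensus = self._setup()
        (c,) = promoter_interacting_ocrs(consensus, windows, [ocr])
        assert (c.ocr_id, c.gene_id) == ("o1", "G1")
        assert c.contact_class == "distal"
        assert c.timepoints == {"unstim"}
        assert "L1" in c.loop_ids

    def test_multi_promoter_anchor(self):
        g1 = GeneModel("G1", "S1", "chr1", "+", (100_000,))
        g2 = GeneModel("G2", "S2", "chr1", "-", (100_300,))
        windows = promoter_windows(g1) + promoter_windows(g2)
        ocr = OCR("o1", GenomicInterval("chr1", 150_200, 150_600), frozenset({"unstim"}))
        consensus = merge_resolutions([mk_loop(100_000, 150_000, 1000, "unstim")])
        contacts = promoter_interacting_ocrs(consensus, windows, [ocr])
        assert {(c.ocr_id, c.gene_id) for c in contacts} == {("o1", "G1"), ("o1", "G2")}

    def test_promoter_proximal_class(self):
        # a two-TSS gene: the OCR sits in the promoter window of one TSS
        # while a loop connects it to the window of the other TSS, so the
        # resulting contact targets the OCR's own gene promoter
        gene = GeneModel("G1", "S1", "chr1", "+", (100_000, 150_500))
        windows = promoter_windows(gene)
        ocr = OCR("o1", GenomicInterval("chr1", 99_000, 99_400), frozenset({"unstim"}))
        lp = mk_loop(99_000, 150_000, 1000, "unstim")
        contacts = promoter_interacting_ocrs(merge_resolutions([lp]), windows, [ocr])
        by_gene = {c.gene_id: c for c in contacts}
        assert by_gene["G1"].contact_class == "promoter_proximal"

    def test_no_shared_timepoint_dropped(self):
        gene, windows, _, consensus = self._setup()
        ocr = OCR("o1", GenomicInterval("chr1", 150_200, 150_600), frozenset({"24h"}))
        assert promoter_interacting_ocrs(consensus, windows, [ocr]) == []
        kept = promoter_interacting_ocrs(
            consensus, windows, [ocr], require_timepoint_support=False
        )
        assert len(kept) == 1

    def test_matches_triple_loop_brute_force(self, rng):
        genes = [
            GeneModel(f"G{i}", f"S{i}", "chr1", "+", (int(rng.integers(0, 500_000)),))
            for i in range(15)
        ]
        windows = [w for g in genes for w in promoter_windows(g)]
        ocrs = [
            OCR(
                f"o{i}",
                GenomicInterval(
                    "chr1", int(s := rng.integers(0, 500_000)), int(s) + 400
                ),
                frozenset({"unstim"}),
            )
            for i in range(25)
        ]
        consensus = merge_resolutions(random_loops(rng, 40))

        def ov(a, b):
            return a.chrom == b.chrom and a.start < b.end and b.start < a.end

        expected = set()
        for lp in consensus:
            for w in windows:
                for o in ocrs:
                    if ov(lp.anchor1, w.interval) and ov(lp.anchor2, o.interval):
                        expected.add((o.peak_id, w.gene_id))
                    if ov(lp.anchor2, w.interval) and ov(lp.anchor1, o.interval):
                        expected.add((o.peak_id, w.gene_id))
        got = {
            (c.ocr_id, c.gene_id)
            for c in promoter_interacting_ocrs(consensus, sorted(windows, key=lambda w: w.interval.start), ocrs)
        }
        assert got == expected

    def test_every_contact_re_satisfies_predicate(self, rng):
        genes = [
            GeneModel(f"G{i}", f"S{i}", "chr1", "+", (int(rng.integers(0, 500_000)),))
            for i in range(10)
        ]
        windows = [w for g in genes for w in promoter_windows(g)]
        ocrs = [
            OCR(
                f"o{i}",
                GenomicInterval("chr1", int(s := rng.integers(0, 500_000)), int(s) + 300),
                frozenset({"unstim"}),
            )
            for i in range(20)
        ]
        consensus = merge_resolutions(random_loops(rng, 30))
        windows_by_gene = {}
        for w in windows:
            windows_by_gene.setdefault(w.gene_id, []).append(w)
        ocr_by_id = {o.peak_id: o for o in ocrs}
        for c in promoter_interacting_ocrs(consensus, windows, ocrs):
            o = ocr_by_id[c.ocr_id]
            ok = False
            for lp in consensus:
                for wa, oa in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
                    if any(wa.overlaps(w.interval) for w in windows_by_gene[c.gene_id]) and oa.overlaps(o.interval):
                        ok = True
            assert ok, f"contact {c} has no supporting loop"


class TestBedpeIO:
    def test_round_trip(self, tmp_path):
        loops = [
            mk_loop(10_000, 50_000, 1000, "unstim", loop_id="L1"),
            mk_loop(8_000, 48_000, 4000, "24h", loop_id="L2"),
        ]
        p = tmp_path / "loops.bedpe"
        write_loops_bedpe(loops, p)
        assert read_loops_bedpe(p) == loops

    def test_reversed_anchors_canonicalized_on_read(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text(
            "chr1\t50000\t51000\tchr1\t10000\t11000\tL1\t0\t.\t.\t1000\tunstim\t1e-08\n"
        )
        (lp,) = read_loops_bedpe(p)
        assert lp.anchor1.start == 10_000

    def test_significance_filter(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        write_loops_bedpe(
            [
                Loop(GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 9000, 10000),
                     1000, "unstim", qvalue=1e-8, loop_id="keep"),
                Loop(GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 20000, 21000),
                     1000, "unstim", qvalue=0.5, loop_id="drop"),
            ],
            p,
        )
        loops = read_loops_bedpe(p, min_significance=1e-6)
        assert [l.loop_id for l in loops] == ["keep"]


class TestBuildConsensus:
    def test_orders_agree_on_disjoint_loops(self, rng):
        loops = []
        for tp in ("unstim", "8h", "24h"):
            loops.extend(random_loops(rng, 20, tp))
        a = build_consensus(loops, order="resolutions_first")
        b = build_consensus(loops, order="stages_first")

        def anchors(cs):
            return sorted((c.anchor1.start, c.anchor2.start) for c in cs)

        # the two orders may differ on pathological nestings but must agree
        # on total coverage of 1 kb calls
        fine = {
            (l.anchor1.start, l.anchor2.start) for l in loops if l.resolution == 1000
        }
        assert fine <= set(anchors(a))
        assert fine <= set(anchors(b))

    def test_unknown_order(self):
        with pytest.raises(ValueError):
            build_consensus([], order="nope")
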