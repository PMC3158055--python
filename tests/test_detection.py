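"""Read-pair/split-read calling rules and reference-MEI selection filters."""

import numpy as np
import pytest

import meipop as mp
from meipop.model import Interval, MappedFragment


def rp(pos, side, family="Alu", frag_len=200, sample="s1", chrom="chr1"):
    return MappedFragment(sample, chrom, pos, side, frag_len, family)


def split(ref_start, ref_end, side, family="Alu", sample="s1", chrom="chr1"):
    return MappedFragment(sample, chrom, ref_start, side, ref_end - ref_start + 1,
                          family, split=True, ref_start=ref_start, ref_end=ref_end)


class TestRpCalling:
    def test_minimal_two_per_side_cluster_yields_one_call(self):
        frags = [rp(900, "5p"), rp(950, "5p"), rp(1040, "3p"), rp(1080, "3p")]
        calls = mp.call_rp_insertions(frags, {}, 200)
        assert len(calls) == 1
        call = calls[0]
        assert call.methods == {"RP"}
        assert call.n_alt5 == 2 and call.n_alt3 == 2
        # leftmost position compatible with the cluster: right of the last 5'
        # anchor, not past the first 3' anchor
        assert call.pos == 951

    def test_one_sided_evidence_is_not_called(self):
        frags = [rp(900, "5p"), rp(950, "5p"), rp(980, "5p")]
        assert mp.call_rp_insertions(frags, {}, 200) == []

    @pytest.mark.parametrize("distance,n_expected", [(50, 0), (250, 1)])
    def test_same_family_annotation_masking_window(self, distance, n_expected):
        frags = [rp(900, "5p"), rp(950, "5p"), rp(1040, "3p"), rp(1080, "3p")]
        calls = mp.call_rp_insertions(frags, {}, 200)
        pos = calls[0].pos
        ann = {"Alu": [Interval("chr1", pos + distance, pos + distance + 300)]}
        assert len(mp.call_rp_insertions(frags, ann, 200)) == n_expected

    def test_other_family_annotation_does_not_mask(self):
        frags = [rp(900, "5p"), rp(950, "5p"), rp(1040, "3p"), rp(1080, "3p")]
        ann = {"L1": [Interval("chr1", 990, 1290)]}
        assert len(mp.call_rp_insertions(frags, ann, 200)) == 1

    def test_empty_input(self):
        assert mp.call_rp_insertions([], {}, 200) == []

    def test_perfect_recall_on_simulated_fragments(self):
        # with no dropout, no masking conflicts, and >=2 fragments per side,
        # every simulated non-reference locus is recovered
        cfg = mp.SimConfig(
            theta_by_family={"Alu": 30.0, "L1": 0.0, "SVA": 0.0},
            n_samples_by_pop={"P": 6},
            genome_length=30_000_000,
            coverage_mean=30.0,
            element_density_per_mb=0.0,
            exact_panel=False,
            seed=23,
        )
        loci, tracks = mp.simulate_catalog(cfg)
        loci = [l for l in loci if not l.on_reference]
        g = mp.simulate_cohort(loci, cfg)
        support, frags = mp.simulate_evidence(g, loci, cfg, tracks, fragments=True)
        rp_frags = [f for f in frags if not f.split]
        calls = mp.call_rp_insertions(rp_frags, tracks.elements, 200)
        per_side = support.groupby("locus_id")[["n_alt5", "n_alt3"]].sum()
        expected = {
            l.locus_id for l in loci
            if per_side.loc[l.locus_id, "n_alt5"] >= 2
            and per_side.loc[l.locus_id, "n_alt3"] >= 2
        }
        recovered = set()
        for locus in loci:
            if any(c.chrom == locus.chrom and abs(c.pos - locus.pos) <= 200
                   and c.family == locus.family for c in calls):
                recovered.add(locus.locus_id)
        assert expected <= recovered

    def test_background_pairs_create_calls_only_without_masking(self):
        cfg = mp.SimConfig(
            theta_by_family={"Alu": 0.5, "L1": 0.0, "SVA": 0.0},
            n_samples_by_pop={"P": 2},
            genome_length=20_000_000,
            element_density_per_mb=1.0,
            background_per_element=1.0,
            exact_panel=False,
            seed=29,
        )
        loci, tracks = mp.simulate_catalog(cfg)
        g = mp.simulate_cohort(loci, cfg)
        _, frags = mp.simulate_evidence(g, loci, cfg, tracks, fragments=True)
        bg = [f for f in frags if not f.split]
        masked = mp.call_rp_insertions(bg, tracks.elements, 300)
        unmasked = mp.call_rp_insertions(bg, {}, 300)
        true_pos = {l.pos for l in loci}

        def is_false(call):
            return all(abs(call.pos - p) > 300 for p in true_pos)

        assert not any(is_false(c) for c in masked)
        assert any(is_false(c) for c in unmasked)


class TestSrCalling:
    def test_single_split_fragment_is_a_call_with_unknown_tsd(self):
        calls = mp.call_sr_insertions([split(100, 180, "5p")])
        assert len(calls) == 1
        assert calls[0].tsd_len is None
        assert calls[0].pos == 180
        assert calls[0].methods == {"SR"}

    def test_two_sided_extents_give_tsd_overlap_and_leftmost_position(self):
        calls = mp.call_sr_insertions([split(100, 180, "5p"), split(165, 240, "3p")])
        assert len(calls) == 1
        assert calls[0].tsd_len == 16
        assert calls[0].pos == 165

    def test_disjoint_extents_give_zero_tsd(self):
        calls = mp.call_sr_insertions([split(100, 150, "5p"), split(160, 240, "3p")])
        assert len(calls) == 1
        assert calls[0].tsd_len == 0

    def test_distant_clusters_stay_separate(self):
        calls = mp.call_sr_insertions([split(100, 180, "5p"), split(500, 580, "5p")])
        assert len(calls) == 2


class TestReferenceSelection:
    def make(self, d_start, d_end, a_start, a_end, family="Alu", gap_frac=1.0):
        deletion = Interval("chr1", d_start, d_end, "del1")
        anns = {family: [Interval("chr1", a_start, a_end, family)]}
        gap_len = int(round((d_end - d_start + 1) * gap_frac))
        gaps = [Interval("chr1", d_start, d_start + gap_len - 1)] if gap_len else []
        return [deletion], anns, gaps

    def test_exact_match_inside_gap_selected(self):
        dels, anns, gaps = self.make(1000, 1299, 1000, 1299)
        selected = mp.select_reference_mei(dels, anns, gaps)
        assert len(selected) == 1
        assert selected[0].family == "Alu"
        assert selected[0].detection_mode == mp.REFERENCE

    def test_alu_start_offset_beyond_20bp_window_rejected(self):
        dels, anns, gaps = self.make(1000, 1299, 1025, 1299)
        assert mp.select_reference_mei(dels, anns, gaps) == []

    def test_l1_offsets_within_200bp_window_selected(self):
        # both ends off by 150 bp, ~97% reciprocal overlap, 80% gap coverage
        dels, anns, gaps = self.make(10_000, 16_000, 10_150, 16_150,
                                     family="L1", gap_frac=0.8)
        selected = mp.select_reference_mei(dels, anns, gaps)
        assert len(selected) == 1
        assert selected[0].family == "L1"

    def test_gap_coverage_below_75pct_rejected(self):
        dels, anns, gaps = self.make(1000, 1299, 1000, 1299, gap_frac=0.70)
        assert mp.select_reference_mei(dels, anns, gaps) == []

    def test_low_reciprocal_overlap_rejected(self):
        # 40% overlap: deletion [1000,1299] vs annotation [1180,1479]
        dels, anns, gaps = self.make(1000, 1299, 1180, 1479)
        assert mp.select_reference_mei(dels, anns, gaps) == []

    def test_input_order_invariance(self):
        d1 = Interval("chr1", 1000, 1299, "a")
        d2 = Interval("chr1", 5000, 5299, "b")
        anns = {"Alu": [Interval("chr1", 1000, 1299), Interval("chr1", 5000, 5299)]}
        gaps = [Interval("chr1", 900, 1400), Interval("chr1", 4900, 5400)]
        fwd = mp.select_reference_mei([d1, d2], anns, gaps)
        rev = mp.select_reference_mei([d2, d1], anns, gaps)
        assert [(c.pos, c.family) for c in fwd] == [(c.pos, c.family) for c in rev]

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            Interval("chr1", 100, 50)
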