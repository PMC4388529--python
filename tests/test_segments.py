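"""Segment calling, masking, gene projection, recurrence, region scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from cnmod.segments import (
    CallMatrix,
    GenomicInterval,
    SampleProfile,
    SegmentCall,
    call_segment,
    gene_level_calls,
    genes_in_regions,
    mask_segments,
    read_gistic_lesions,
    recurrence_filter,
    score_regions,
)
from conftest import HANDCRAFTED_CALLS, HANDCRAFTED_CN
from oracles import pairwise_overlap_keep


def seg(chrom, start, end, markers, cn, sample="s"):
    return SegmentCall(sample, GenomicInterval(chrom, start, end), markers, cn)


class TestCallSegment:
    @pytest.mark.parametrize(
        "cn,ploidy,markers,expected",
        [
            (3.8, 2.8, 12, 1),    # 1.0 above ploidy: gain
            (1.9, 2.8, 12, 0),    # exactly 0.9 below: strict threshold, neutral
            (4.5, 2.8, 5, 0),     # amplitude ample but too few markers
            (1.0, 2.8, 12, -1),   # 1.8 below: loss
            (2.8, 2.8, 50, 0),    # at ploidy
            (4.8, 3.9, 10, 0),    # exactly 0.9 above, boundary again
            (0.0, 1.5, 10, -1),   # total loss at low ploidy: 1.5 below
        ],
    )
    def test_threshold_and_marker_rules(self, cn, ploidy, markers, expected):
        assert call_segment(seg("chr1", 0, 100, markers, cn), ploidy) == expected

    @given(
        dev=st.floats(-4, 4, allow_nan=False),
        ploidy=st.floats(1.5, 4.0),
        markers=st.integers(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_in_deviation(self, dev, ploidy, markers):
        """Negating (cn - ploidy) flips the sign of the call."""
        up = max(0.0, ploidy + dev)
        down = max(0.0, ploidy - dev)
        if up != ploidy + dev or down != ploidy - dev:
            return  # clipped at cn=0: deviation no longer symmetric
        plus = call_segment(seg("chr1", 0, 1, markers, up), ploidy)
        minus = call_segment(seg("chr1", 0, 1, markers, down), ploidy)
        assert plus == -minus

    def test_rejects_nonpositive_delta(self):
        with pytest.raises(ValueError):
            call_segment(seg("chr1", 0, 1, 20, 5.0), 2.0, delta=0.0)


class TestMaskSegments:
    def make_profile(self, segs):
        return SampleProfile("s", 2.0, 0.7, segs)

    def test_fully_masked_segment_removed(self):
        prof = self.make_profile([seg("chr1", 100, 200, 20, 4.0)])
        out = mask_segments(prof, [GenomicInterval("chr1", 0, 500)])
        assert out.segments == []

    def test_exactly_half_overlap_is_kept(self):
        prof = self.make_profile([seg("chr1", 0, 1000, 20, 4.0)])
        out = mask_segments(prof, [GenomicInterval("chr1", 0, 500)])
        assert len(out.segments) == 1

    def test_union_of_masks_not_max_single_mask(self):
        # two masks each 30% of the segment: union 60% -> removed
        prof = self.make_profile([seg("chr1", 0, 1000, 20, 4.0)])
        masks = [GenomicInterval("chr1", 0, 300), GenomicInterval("chr1", 500, 800)]
        assert mask_segments(prof, masks).segments == []

    def test_idempotent(self):
        prof = self.make_profile(
            [seg("chr1", 0, 1000, 20, 4.0), seg("chr1", 2000, 2100, 5, 1.0)]
        )
        masks = [GenomicInterval("chr1", 0, 700)]
        once = mask_segments(prof, masks)
        twice = mask_segments(once, masks)
        assert [s.interval for s in once.segments] == [s.interval for s in twice.segments]

    def test_matches_pairwise_overlap_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            starts = np.sort(rng.choice(np.arange(0, 5000, 10), size=10, replace=False))
            segs = [
                seg("chr1", int(s), int(s + rng.integers(5, 200)), 20, 4.0)
                for s in starts
            ]
            # rebuild non-overlapping: clip ends at next start
            segs = [
                seg("chr1", s.interval.start,
                    min(s.interval.end, nxt.interval.start), 20, 4.0)
                for s, nxt in zip(segs, segs[1:])
                if s.interval.start < min(s.interval.end, nxt.interval.start)
            ]
            masks = [
                GenomicInterval("chr1", int(a), int(a) + int(rng.integers(20, 400)))
                for a in rng.choice(np.arange(0, 5000, 7), size=6, replace=False)
            ]
            prof = self.make_profile(segs)
            got = {
                (s.interval.chrom, s.interval.start, s.interval.end)
                for s in mask_segments(prof, masks).segments
            }
            expected = set(
                pairwise_overlap_keep(
                    [(s.interval.chrom, s.interval.start, s.interval.end) for s in segs],
                    [(m.chrom, m.start, m.end) for m in masks],
                )
            )
            assert got == expected


class TestGeneLevelCalls:
    def test_handcrafted_golden_matrix(
        self, handcrafted_profiles, handcrafted_mask, genome_map_10
    ):
        """3-sample/10-gene fixture reproduces the hand-computed call matrix,
        including the strict >0.9 boundary, the >=10-marker rule and the
        strict >50% mask rule."""
        masked = [mask_segments(p, handcrafted_mask) for p in handcrafted_profiles]
        cm = gene_level_calls(masked, genome_map_10)
        pd.testing.assert_frame_equal(
            cm.calls.astype(int), HANDCRAFTED_CALLS, check_dtype=False
        )
        pd.testing.assert_frame_equal(cm.cn, HANDCRAFTED_CN, check_dtype=False)

    def test_midpoint_rule_for_breakpoint_spanning_gene(self):
        gm = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "start": [0], "end": [1000]}
        )
        # gene spans the breakpoint at 400; midpoint 500 sits in the neutral part
        prof = SampleProfile(
            "s", 2.0, 0.7,
            [seg("chr1", 0, 400, 20, 5.0), seg("chr1", 400, 1000, 20, 2.0)],
        )
        cm = gene_level_calls([prof], gm)
        assert cm.calls.loc["g", "s"] == 0
        assert cm.cn.loc["g", "s"] == 2.0

    def test_uncovered_gene_defaults_to_ploidy(self):
        gm = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr7"], "start": [0], "end": [100]}
        )
        prof = SampleProfile("s", 3.2, 0.7, [])
        cm = gene_level_calls([prof], gm)
        assert cm.calls.loc["g", "s"] == 0
        assert cm.cn.loc["g", "s"] == pytest.approx(3.2)

    def test_duplicate_gene_ids_rejected(self):
        gm = pd.DataFrame(
            {"gene": ["g", "g"], "chrom": ["chr1", "chr1"],
             "start": [0, 100], "end": [50, 200]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            gene_level_calls([SampleProfile("s", 2.0, 0.7, [])], gm)


class TestRecurrence:
    def _cm(self, calls: np.ndarray) -> CallMatrix:
        genes = [f"g{i}" for i in range(calls.shape[0])]
        samples = [f"s{j}" for j in range(calls.shape[1])]
        calls_df = pd.DataFrame(calls, index=genes, columns=samples)
        return CallMatrix(calls_df, calls_df.astype(float) + 2.0)

    def test_20pct_threshold_is_inclusive(self):
        calls = np.zeros((2, 41), dtype=int)
        calls[0, :9] = -1   # 9/41 = 0.2195 -> recurrent
        calls[1, :8] = -1   # 8/41 = 0.195  -> not recurrent
        rec = recurrence_filter(self._cm(calls))
        assert rec.loss_genes == {"g0"}
        assert rec.gain_genes == set()

    def test_all_neutral_matrix_yields_empty_sets(self):
        rec = recurrence_filter(self._cm(np.zeros((5, 10), dtype=int)))
        assert rec.gain_genes == set() and rec.loss_genes == set()

    def test_frequencies_bounded_and_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([-1, 0, 1], size=(30, 20))
        cm = self._cm(calls)
        rec = recurrence_filter(cm, min_freq=0.0)
        assert ((rec.frequencies >= 0) & (rec.frequencies <= 1)).all().all()
        sizes = [
            len(recurrence_filter(cm, min_freq=f).gain_genes)
            for f in (0.0, 0.2, 0.4, 0.8, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


def _flat_profiles(n_samples, ploidy=2.0, chrom_end=100_000):
    return [
        SampleProfile(
            f"s{j}", ploidy, 0.7,
            [seg("chr1", 0, chrom_end, 50, ploidy, sample=f"s{j}")],
        )
        for j in range(n_samples)
    ]


class TestScoreRegions:
    def _gm(self, n_genes):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n_genes)],
                "chrom": ["chr1"] * n_genes,
                "start": [100 * i for i in range(n_genes)],
                "end": [100 * i + 100 for i in range(n_genes)],
            }
        )

    def test_no_alterations_no_regions(self):
        n_genes, n_samples = 50, 10
        gm = self._gm(n_genes)
        profiles = _flat_profiles(n_samples)
        calls = pd.DataFrame(0, index=gm["gene"], columns=[p.sample_id for p in profiles])
        cm = CallMatrix(calls, calls.astype(float) + 2.0)
        scan = score_regions(cm, profiles, gm, n_perm=100, seed=1)
        assert scan.regions == []

    def test_fully_penetrant_block_attains_max_score_and_min_p(self):
        n_genes, n_samples = 60, 30
        gm = self._gm(n_genes)
        profiles = _flat_profiles(n_samples)
        samples = [p.sample_id for p in profiles]
        cn = pd.DataFrame(2.0, index=gm["gene"], columns=samples)
        cn.iloc[10:20] = 3.0  # block gained in 100% of samples, amplitude 1.0
        calls = pd.DataFrame(0, index=gm["gene"], columns=samples)
        calls.iloc[10:20] = 1
        cm = CallMatrix(calls, cn)
        scan = score_regions(cm, profiles, gm, n_perm=150, seed=2)
        block = scan.gene_table.iloc[10:20]
        assert np.allclose(block["gain_score"], 30.0)  # 30 samples x amplitude 1.0
        assert (block["gain_p"] == scan.gene_table["gain_p"].min()).all()
        gains = [r for r in scan.regions if r.direction == "gain"]
        assert len(gains) == 1 and gains[0].score == pytest.approx(30.0)
        assert genes_in_regions(gains, gm) == {f"g{i}" for i in range(10, 20)}

    def test_scores_invariant_to_sample_order(self):
        n_genes, n_samples = 30, 8
        gm = self._gm(n_genes)
        rng = np.random.default_rng(5)
        profiles = _flat_profiles(n_samples)
        samples = [p.sample_id for p in profiles]
        cn = pd.DataFrame(
            2.0 + rng.normal(0, 0.5, (n_genes, n_samples)).clip(-1.5),
            index=gm["gene"], columns=samples,
        )
        calls = pd.DataFrame(0, index=gm["gene"], columns=samples)
        cm = CallMatrix(calls, cn)
        fwd = score_regions(cm, profiles, gm, n_perm=100, seed=3)
        rev = score_regions(
            CallMatrix(calls[samples[::-1]], cn[samples[::-1]]),
            profiles[::-1], gm, n_perm=100, seed=3,
        )
        np.testing.assert_allclose(
            fwd.gene_table["gain_score"], rev.gene_table["gain_score"]
        )
        np.testing.assert_allclose(
            fwd.gene_table["loss_score"], rev.gene_table["loss_score"]
        )

    def test_null_pvalues_uniform(self):
        """On null data, empirical p-values are uniform (KS p > 0.01)."""
        n_genes, n_samples = 200, 10
        gm = self._gm(n_genes)
        rng = np.random.default_rng(7)
        profiles = _flat_profiles(n_samples)
        samples = [p.sample_id for p in profiles]
        cn = pd.DataFrame(
            2.0 + rng.normal(0, 0.3, (n_genes, n_samples)),
            index=gm["gene"], columns=samples,
        ).clip(lower=0)
        calls = pd.DataFrame(0, index=gm["gene"], columns=samples)
        scan = score_regions(CallMatrix(calls, cn), profiles, gm, n_perm=200, seed=9)
        assert kstest(scan.gene_table["gain_p"], "uniform").pvalue > 0.01

    def test_rejects_small_permutation_count(self, genome_map_10):
        profiles = _flat_profiles(3, chrom_end=10_000)
        calls = pd.DataFrame(
            0, index=genome_map_10["gene"], columns=[p.sample_id for p in profiles]
        )
        with pytest.raises(ValueError, match="n_perm"):
            score_regions(
                CallMatrix(calls, calls + 2.0), profiles, genome_map_10, n_perm=10
            )


GISTIC_FIXTURE = """\
Unique Name\tDescriptor\tWide Peak Limits\tPeak Limits\tq values
Amplification Peak  1\t8q24.21\tchr8:128706589-128801451(probes 1:5)\tchr8:128706589-128801451\t0.002
Deletion Peak  1\t9p21.3\tchr9:21967751-21995300(probes 9:13)\tchr9:21967751-21995300\t0.2
"""


class TestGisticParser:
    def test_minimal_two_row_fixture(self, tmp_path):
        path = tmp_path / "all_lesions.txt"
        path.write_text(GISTIC_FIXTURE)
        regions = read_gistic_lesions(path)
        assert len(regions) == 2
        assert {r.direction for r in regions} == {"gain", "loss"}
        deletion = next(r for r in regions if r.direction == "loss")
        assert deletion.q == 0.2
        # 1-based inclusive chr9:21967751-21995300 -> 0-based half-open
        assert (deletion.interval.start, deletion.interval.end) == (21967750, 21995300)

    def test_malformed_coordinates_name_the_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(GISTIC_FIXTURE.replace("chr9:21967751-21995300(probes 9:13)", "oops"))
        with pytest.raises(ValueError, match=r"bad.txt:3"):
            read_gistic_lesions(path)

    def test_missing_header_column_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(GISTIC_FIXTURE.replace("q values", "quality"))
        with pytest.raises(ValueError, match="q value"):
            read_gistic_lesions(path)
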