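import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import lsq_linear

from breakscan import dba
from breakscan.models import CensusGene, CnaBreakpoint, CnaSegment, GeneModel

from conftest import make_track


def tv_oracle(y, lam):
    """Independent exact TV-denoiser: box-constrained dual QP via BVLS.

    min ||y - D^T u||^2 over |u_i| <= lam; the primal fit is y - D^T u.
    """
    n = len(y)
    D = sparse.diags([np.full(n - 1, -1.0), np.ones(n - 1)], [0, 1], shape=(n - 1, n)).toarray()
    res = lsq_linear(D.T, y, bounds=(-lam, lam), method="bvls", tol=1e-14)
    return y - D.T @ res.x


class TestTvDenoise:
    @pytest.mark.parametrize("n,lam,seed", [(50, 0.5, 0), (200, 1.0, 1), (400, 2.5, 2), (37, 0.05, 3)])
    def test_matches_qp_oracle(self, n, lam, seed):
        rng = np.random.default_rng(seed)
        y = 0.2 * rng.normal(size=n).cumsum() + rng.normal(size=n)
        assert np.max(np.abs(dba.tv_denoise(y, lam) - tv_oracle(y, lam))) < 1e-8

    def test_flat_track_fits_zero(self):
        track = make_track(np.zeros(100))
        fitted = dba.segment_track(track, penalty=1.0)
        assert np.all(fitted == 0.0)

    def test_step_track_changepoints(self):
        rng = np.random.default_rng(7)
        y = np.concatenate([np.zeros(200), np.full(100, 0.8), np.zeros(200)]) + rng.normal(0, 0.1, 500)
        fitted = dba.segment_track(make_track(y), fdr=0.01, seed=0)
        cps = np.flatnonzero(np.abs(np.diff(fitted)) > 1e-12) + 1
        onsets = [c for c in cps if abs(c - 200) <= 3]
        offsets = [c for c in cps if abs(c - 300) <= 3]
        assert onsets and offsets

    def test_total_variation_shrinks(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=300)
        for lam in (0.1, 1.0, 5.0):
            f = dba.tv_denoise(y, lam)
            assert np.abs(np.diff(f)).sum() <= np.abs(np.diff(y)).sum() + 1e-12

    def test_all_missing_rejected(self):
        track = make_track(np.full(10, np.nan))
        with pytest.raises(ValueError, match="missing"):
            dba.segment_track(track, penalty=1.0)


def smooth(signal, **kw):
    track = make_track(np.asarray(signal, dtype=float))
    return dba.copy_number_smooth(np.asarray(signal, dtype=float), track, **kw), track


class TestCopyNumberSmooth:
    def test_short_standard_cna_rejected(self):
        segs, _ = smooth(np.concatenate([np.zeros(100), np.full(30, 0.5), np.zeros(150)]))
        assert segs == []

    def test_short_high_level_cna_accepted(self):
        segs, _ = smooth(np.concatenate([np.zeros(100), np.full(12, 1.4), np.zeros(150)]))
        (seg,) = segs
        assert seg.level == "high"
        assert (seg.start_probe, seg.end_probe) == (100, 112)

    def test_clean_step_boundaries_exact(self):
        segs, _ = smooth(np.concatenate([np.zeros(150), np.full(120, 0.8), np.zeros(150)]))
        (seg,) = segs
        assert (seg.start_probe, seg.end_probe) == (150, 270)
        assert seg.mean_log2 == pytest.approx(0.8)
        assert seg.level == "standard" and seg.sign == "gain"

    def test_loss_sign(self):
        segs, _ = smooth(np.concatenate([np.zeros(60), np.full(80, -0.6), np.zeros(60)]))
        (seg,) = segs
        assert seg.sign == "loss" and seg.mean_log2 == pytest.approx(-0.6)

    def test_overcalled_same_sign_levels_merge(self):
        # fused lasso overcall: 0.45 then 0.55 (shift < theta) is one CNA
        segs, _ = smooth(np.concatenate([np.zeros(50), np.full(40, 0.45), np.full(40, 0.55), np.zeros(100)]))
        (seg,) = segs
        assert (seg.start_probe, seg.end_probe) == (50, 130)

    def test_level_shift_beyond_theta_terminates(self):
        # 0.4 -> 1.6 jump (>= theta) must split into two segments
        segs, _ = smooth(np.concatenate([np.full(80, 0.4), np.full(80, 1.6), np.zeros(80)]))
        assert [s.start_probe for s in segs] == [0, 80]
        assert [round(s.mean_log2, 3) for s in segs] == [0.4, 1.6]

    def test_raising_theta_is_monotone(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 0.1, 600)
        y[100:200] += 0.5
        y[350:450] += 0.35
        track = make_track(y)
        fitted = dba.segment_track(track, fdr=0.01, seed=0)
        counts = [
            len(dba.copy_number_smooth(fitted, track, theta=theta)) for theta in (0.2, 0.3, 0.4, 0.6)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_emitted_segments_sorted_disjoint(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 0.15, 800)
        y[100:250] += 0.8
        y[400:420] -= 1.5
        track = make_track(y)
        fitted = dba.segment_track(track, fdr=0.01, seed=0)
        segs = dba.copy_number_smooth(fitted, track)
        bounds = [(s.start_probe, s.end_probe) for s in segs]
        assert bounds == sorted(bounds)
        for (_, e1), (s2, _) in zip(bounds, bounds[1:]):
            assert s2 >= e1
        # CnaSegment __post_init__ enforces length/amplitude invariants


@pytest.fixture
def genes():
    plus = GeneModel("PLUS", "chr1", "+", ((100_000, 110_000), (140_000, 150_000)))
    minus = GeneModel("MINUS", "chr1", "-", ((340_000, 350_000), (300_000, 310_000)))
    return [plus, minus]


def gain_segment(start_pos, end_pos, mean=0.8, n=120):
    return CnaSegment(
        sample_id="S", chrom="chr1", start_probe=0, end_probe=n,
        start_pos=start_pos, end_pos=end_pos, mean_log2=mean,
        level="high" if abs(mean) >= 1 else "standard",
        sign="gain" if mean > 0 else "loss",
    )


class TestIntragenic:
    def test_boundary_inside_gene(self, genes):
        seg = gain_segment(120_000, 500_000)
        calls = dba.call_intragenic_breakpoints([seg], genes)
        hit = [c for c in calls if c.gene_id == "PLUS"]
        assert len(hit) == 1
        assert hit[0].boundary_pos == 120_000
        assert hit[0].transition == "gain_starts"

    def test_contained_gene_has_no_breakpoint(self, genes):
        seg = gain_segment(90_000, 200_000)
        assert [c for c in dba.call_intragenic_breakpoints([seg], genes) if c.gene_id == "PLUS"] == []

    def test_minus_strand_boundary_side(self, genes):
        # gain starts mid-gene and extends toward higher coordinates: on a
        # minus-strand gene the covered genomic-right portion is the 5' end
        seg = gain_segment(305_000, 500_000)
        (call,) = [c for c in dba.call_intragenic_breakpoints([seg], genes) if c.gene_id == "MINUS"]
        assert call.boundary_side == "upper_5prime"
        # mirror: same geometry on the plus-strand gene covers the 3' end
        seg2 = gain_segment(105_000, 160_000)
        (call2,) = [c for c in dba.call_intragenic_breakpoints([seg2], genes) if c.gene_id == "PLUS"]
        assert call2.boundary_side == "lower_3prime"

    def test_focal_flag(self, genes):
        seg = gain_segment(120_000, 500_000, n=120)
        (call,) = [c for c in dba.call_intragenic_breakpoints([seg], genes) if c.gene_id == "PLUS"]
        assert call.focal
        big = gain_segment(120_000, 500_000, n=5000)
        (call,) = [c for c in dba.call_intragenic_breakpoints([big], genes) if c.gene_id == "PLUS"]
        assert not call.focal


class TestCensusDirection:
    def bp(self, gene, sign, covered_end):
        seg = gain_segment(0, 10, mean=0.8 if sign == "gain" else -0.8)
        return CnaBreakpoint(
            gene_id=gene, sample_id="S", boundary_pos=5,
            boundary_side="upper_5prime" if covered_end == "five_prime" else "lower_3prime",
            transition=f"{sign}_starts", segment=seg, focal=True,
        )

    def test_abl1_like_rules(self):
        census = [CensusGene("ABL1", "three_prime")]
        keep = dba.census_direction_filter([self.bp("ABL1", "gain", "three_prime")], census)
        assert len(keep) == 1  # amplification of the 3' end
        keep = dba.census_direction_filter([self.bp("ABL1", "loss", "five_prime")], census)
        assert len(keep) == 1  # deletion of the 5' end
        drop = dba.census_direction_filter([self.bp("ABL1", "gain", "five_prime")], census)
        assert drop == []

    def test_either_role_passes_everything(self):
        census = [CensusGene("EWSR1", "either")]
        calls = [self.bp("EWSR1", s, e) for s in ("gain", "loss") for e in ("five_prime", "three_prime")]
        assert len(dba.census_direction_filter(calls, census)) == 4

    def test_empty_census_disables_filter(self):
        calls = [self.bp("ANY", "gain", "five_prime")]
        assert dba.census_direction_filter(calls, []) == calls
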