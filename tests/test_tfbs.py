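import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nucmap import (ValidationError, classify_sites, fold_change,
                    scan_pwm, site_occupancy)
from nucmap.fragment_io import GenomicRegion
from nucmap.occupancy import OccupancyTrack
from nucmap.simulate import DEFAULT_MOTIF, reverse_complement
from nucmap.tfbs import (PredictedSite, log_odds_matrix, read_sites,
                         summarize_sites, write_sites)

BASES = "ACGT"


def brute_force_scan(sequence, motif, threshold):
    """Per-position, per-strand scorer used as the exhaustive oracle."""
    lo = log_odds_matrix(motif)
    width = motif.width
    smin = sum(lo[:, j].min() for j in range(width))
    smax = sum(lo[:, j].max() for j in range(width))
    hits = []
    for pos in range(len(sequence) - width + 1):
        window = sequence[pos:pos + width]
        if any(b not in BASES for b in window):
            continue
        fwd = sum(lo[BASES.index(window[j]), j] for j in range(width))
        rc = reverse_complement(window)
        rev = sum(lo[BASES.index(rc[j]), j] for j in range(width))
        score, strand = (fwd, "+") if fwd >= rev else (rev, "-")
        rel = (score - smin) / (smax - smin)
        if rel >= threshold:
            hits.append((pos, strand, pytest.approx(score, abs=1e-9)))
    return hits


def random_sequence(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


class TestScanPWM:
    def test_consensus_scores_relative_one(self):
        consensus = DEFAULT_MOTIF.consensus()
        sites = scan_pwm(consensus, DEFAULT_MOTIF, threshold=1.0)
        assert len(sites) == 1
        assert sites[0].start == 0
        assert sites[0].strand == "+"
        assert sites[0].relative_score == pytest.approx(1.0, abs=1e-12)

    def test_threshold_one_on_random_sequence_usually_empty(self, rng):
        seq = random_sequence(rng, 2000)
        assert scan_pwm(seq, DEFAULT_MOTIF, threshold=1.0) == []

    def test_sequence_shorter_than_motif(self):
        assert scan_pwm("ACGT", DEFAULT_MOTIF, threshold=0.0) == []

    def test_matches_exhaustive_oracle(self, rng):
        seq = random_sequence(rng, 2000)
        sites = scan_pwm(seq, DEFAULT_MOTIF, threshold=0.8)
        expected = brute_force_scan(seq, DEFAULT_MOTIF, 0.8)
        got = [(s.start, s.strand, s.pwm_score) for s in sites]
        assert len(got) == len(expected)
        for (p, st_, sc), (ep, est, esc) in zip(got, expected):
            assert (p, st_) == (ep, est)
            assert sc == esc

    def test_ambiguous_windows_not_scored(self, rng):
        consensus = DEFAULT_MOTIF.consensus()
        seq = consensus[:7] + "N" + consensus[8:]
        assert scan_pwm(seq, DEFAULT_MOTIF, threshold=0.0) == []

    def test_reverse_complement_mirror(self, rng):
        seq = random_sequence(rng, 500)
        fwd_sites = scan_pwm(seq, DEFAULT_MOTIF, threshold=0.75)
        rc_sites = scan_pwm(reverse_complement(seq), DEFAULT_MOTIF, threshold=0.75)
        width = DEFAULT_MOTIF.width
        mirrored = sorted(
            (len(seq) - width - s.start, "-" if s.strand == "+" else "+",
             round(s.pwm_score, 9))
            for s in rc_sites)
        original = sorted((s.start, s.strand, round(s.pwm_score, 9))
                          for s in fwd_sites)
        assert original == mirrored

    def test_planted_reverse_strand_hit(self, rng):
        seq = random_sequence(rng, 200)
        word = reverse_complement(DEFAULT_MOTIF.consensus())
        seq = seq[:100] + word + seq[100 + len(word):]
        sites = scan_pwm(seq, DEFAULT_MOTIF, threshold=1.0)
        assert [(s.start, s.strand) for s in sites] == [(100, "-")]


class TestClassify:
    @staticmethod
    def site(region="r", start=0):
        return PredictedSite(region=region, start=start, strand="+", width=15,
                             pwm_score=10.0, relative_score=0.9)

    def test_above_cutoff_functional(self):
        out = classify_sites([self.site()], {"r:0:+": (30.0, 30.0)})
        assert out[0].functional is True
        assert out[0].chip_mean == 30.0

    def test_boundary_exactly_20_is_functional(self):
        out = classify_sites([self.site()], {"r:0:+": (20.0, 20.0)})
        assert out[0].functional is True

    def test_mean_rule_one_sided_signal(self):
        out = classify_sites([self.site()], {"r:0:+": (38.0, 0.0)})
        assert out[0].chip_mean == 19.0
        assert out[0].functional is False

    def test_missing_entry_scored_zero_with_warning(self, caplog):
        out = classify_sites([self.site()], {})
        assert out[0].functional is False
        assert out[0].chip_oct4 == 0.0

    def test_negative_chip_raises(self):
        with pytest.raises(ValidationError):
            classify_sites([self.site()], {"r:0:+": (-1.0, 5.0)})

    def test_class_map_applied(self):
        out = classify_sites([self.site()], {"r:0:+": (25.0, 25.0)},
                             class_map={"r": "class2_poised"})
        assert out[0].gene_class == "class2_poised"

    @given(cutoffs=st.lists(st.floats(0, 60, allow_nan=False), min_size=2, max_size=6))
    def test_monotone_in_cutoff(self, cutoffs):
        sites = [self.site(start=i) for i in range(5)]
        chip = {f"r:{i}:+": (10.0 * i, 5.0 * i) for i in range(5)}
        counts = []
        for cutoff in sorted(cutoffs):
            out = classify_sites(sites, chip, cutoff=cutoff)
            counts.append(sum(s.functional for s in out))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSiteOccupancy:
    @staticmethod
    def track(values):
        region = GenomicRegion("r", "chr1", 0, len(values))
        return OccupancyTrack(regions=[region], values={"r": np.asarray(values, float)},
                              stage="gc_adjusted")

    @staticmethod
    def site(start, width=15):
        return PredictedSite(region="r", start=start, strand="+", width=width,
                             pwm_score=0.0, relative_score=1.0)

    def test_constant_track(self):
        assert site_occupancy(self.track(np.ones(100)), self.site(10)) == 1.0

    def test_arithmetic_sequence_mean(self):
        values = np.arange(1, 101, dtype=float)
        # positions 0..14 hold 1..15 -> mean 8
        assert site_occupancy(self.track(values), self.site(0)) == 8.0

    def test_random_track_matches_direct_mean(self, rng):
        values = rng.random(300)
        track = self.track(values)
        for start in (0, 100, 285):
            assert site_occupancy(track, self.site(start)) == pytest.approx(
                values[start:start + 15].mean())

    def test_site_past_edge_raises(self):
        with pytest.raises(ValidationError):
            site_occupancy(self.track(np.ones(100)), self.site(90))


class TestFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (1.0, 1.0, 0.0),
        (0.5, 2.0, -2.0),
        (2.0, 0.5, 2.0),
    ])
    def test_closed_forms(self, a, b, expected):
        assert fold_change(a, b) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_raises(self):
        with pytest.raises(ValidationError):
            fold_change(0.0, 1.0)
        with pytest.raises(ValidationError):
            fold_change(1.0, -2.0)

    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    def test_antisymmetry(self, a, b):
        assert fold_change(a, b) == -fold_change(b, a)


class TestSitesIO:
    def test_round_trip(self, tmp_path, rng):
        seq = random_sequence(rng, 400)
        word = DEFAULT_MOTIF.consensus()
        seq = seq[:50] + word + seq[65:]
        sites = scan_pwm(seq, DEFAULT_MOTIF, threshold=0.9)
        sites = classify_sites(sites, {s.site_id: (25.0, 30.0) for s in sites},
                               class_map={"region": "class1_active"})
        write_sites(sites, tmp_path / "sites.tsv")
        again = read_sites(tmp_path / "sites.tsv")
        assert len(again) == len(sites)
        for a, b in zip(again, sites):
            assert (a.region, a.start, a.strand, a.width, a.functional,
                    a.gene_class) == (b.region, b.start, b.strand, b.width,
                                      b.functional, b.gene_class)
            assert a.pwm_score == pytest.approx(b.pwm_score, rel=1e-12)
            assert a.chip_oct4 == b.chip_oct4 and a.chip_sox2 == b.chip_sox2


class TestParameterRecovery:
    def test_mean_fold_at_displaced_sites_recovers_log2_delta(self):
        import nucmap
        from nucmap.simulate import (MotifPlacement, RegionSpec, SimConfig,
                                     make_world, sample_library)

        placements = [MotifPlacement("r", 600 + 900 * k, "+", functional=(k % 2 == 0))
                      for k in range(8)]
        cfg = SimConfig(seed=21, regions=[RegionSpec("r", 8500)],
                        placements=placements, delta=0.5, depth=150_000)
        world = make_world(cfg)
        sites = nucmap.scan_regions(world.sequences, world.motif, 1.0)
        sites = nucmap.classify_sites(sites, world.chip_scores(),
                                      class_map=world.gene_classes)
        vivo = nucmap.normalize_track(nucmap.build_occupancy(
            sample_library(world, "invivo"), world.regions))
        vitro = nucmap.normalize_track(nucmap.build_occupancy(
            sample_library(world, "invitro"), world.regions))
        vivo.stage = vitro.stage = "gc_adjusted"  # no GC bias injected
        summaries = summarize_sites(sites, vivo, vitro)
        func = [s.log2_fold for s in summaries if s.site.functional]
        nonfunc = [s.log2_fold for s in summaries if not s.site.functional]
        # displaced mass (~4*147*0.5/8500) shifts normalized folds up slightly
        assert np.mean(func) == pytest.approx(math.log2(0.5), abs=0.2)
        assert np.mean(nonfunc) == pytest.approx(0.0, abs=0.2)
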