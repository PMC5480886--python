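import numpy as np
import pytest

from bsamap import (
    PoolObservation, ScanParams, Variant, build_af_tracks,
    detect_candidate_regions, expected_pool_af, region_snp_report, smooth_track,
)
from bsamap.afmap import AFTrack


class TestExpectedPoolAf:
    @pytest.mark.parametrize(
        "comp,expected",
        [((0, 0, 30), 1.0), ((0, 30, 0), 0.5), ((10, 20, 0), 1 / 3),
         ((25, 50, 25), 0.5)],
    )
    def test_mendelian_pool_expectations(self, comp, expected):
        assert expected_pool_af(*comp) == pytest.approx(expected)

    def test_scaling_invariance(self):
        for scale in (2, 7, 100):
            assert expected_pool_af(10, 20, 0) == expected_pool_af(
                10 * scale, 20 * scale, 0
            )

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            expected_pool_af(0, 0, 0)


def track_variants(afs, pool="SbPool1", chrom="Chr01", start=1000, spacing=1000):
    out = []
    for i, af in enumerate(afs):
        depth = 40
        obs = {pool: PoolObservation(depth, int(round(af * depth)), 99)}
        out.append(Variant(chrom=chrom, pos=start + i * spacing, ref="G", alt="A", pools=obs))
    return out


class TestBuildTrack:
    def test_points_in_position_order(self):
        vs = track_variants([0.4, 0.5, 0.6])
        tracks = build_af_tracks(vs[::-1], "SbPool1")
        t = tracks["Chr01"]
        assert list(t.positions) == [1000, 2000, 3000]
        assert np.allclose(t.af, [0.4, 0.5, 0.6])

    def test_empty_input(self):
        assert build_af_tracks([], "SbPool1") == {}

    def test_unknown_pool_rejected(self):
        with pytest.raises(KeyError):
            build_af_tracks(track_variants([0.5]), "nope")

    def test_zero_depth_is_missing(self):
        v = Variant(chrom="Chr01", pos=5, ref="G", alt="A",
                    pools={"SbPool1": PoolObservation(0, 0, 0)})
        t = build_af_tracks([v], "SbPool1")["Chr01"]
        assert np.isnan(t.af[0])

    def test_track_maximum_near_causal_site(self, desk_run):
        rc, res = desk_run
        cfg = rc.sim
        variants = res.filter_result.kept
        tracks = build_af_tracks(variants, "SbPool1")
        t = tracks[cfg.causal_chrom_name]
        w = smooth_track(t, 1_000_000, 200_000)
        peak = w.loc[w.mean_af.idxmax()]
        causal = cfg.resolved_causal_pos()
        assert peak.start - 1_000_000 <= causal <= peak.end + 1_000_000


class TestSmoothTrack:
    def test_constant_track(self):
        t = build_af_tracks(track_variants([0.5] * 50), "SbPool1")["Chr01"]
        w = smooth_track(t, window_bp=10_000, step_bp=2_000)
        assert np.allclose(w.mean_af.dropna(), 0.5)

    def test_single_window_mean(self):
        t = build_af_tracks(track_variants([0.2, 0.4, 0.6, 0.3, 0.5]), "SbPool1")["Chr01"]
        w = smooth_track(t, window_bp=100_000, step_bp=100_000, min_snps=1)
        assert len(w) == 1
        assert w.mean_af.iloc[0] == pytest.approx(0.4)

    def test_sparse_windows_marked_missing(self):
        t = build_af_tracks(track_variants([0.5] * 3), "SbPool1")["Chr01"]
        w = smooth_track(t, window_bp=100_000, step_bp=100_000, min_snps=5)
        assert w.mean_af.isna().all()

    def test_plateau_construction(self):
        """AF 1.0 over [57.9, 60.0] Mb and 0.5 elsewhere: window means are
        >= 0.95 exactly over the plateau."""
        positions = np.arange(50_000_000, 65_000_000, 50_000)
        afs = np.where((positions >= 57_900_000) & (positions <= 60_000_000), 1.0, 0.5)
        vs = track_variants(afs, start=positions[0], spacing=50_000)
        t = build_af_tracks(vs, "SbPool1")["Chr01"]
        w = smooth_track(t, window_bp=1_000_000, step_bp=1_000_000,
                         chrom_length=65_000_000).dropna(subset=["mean_af"])
        high = w[w.mean_af >= 0.95]
        assert not high.empty
        assert high.start.min() >= 57_000_000
        assert high.end.max() <= 61_000_000

    def test_global_mean_preserved_when_step_equals_window(self):
        rng = np.random.default_rng(4)
        afs = rng.uniform(0, 1, 200)
        vs = track_variants(afs)
        t = build_af_tracks(vs, "SbPool1")["Chr01"]
        w = smooth_track(t, window_bp=20_000, step_bp=20_000, min_snps=1)
        quantized = np.round(afs * 40) / 40  # depth-40 AF quantization
        weighted = (w.mean_af * w.n_snps).sum() / w.n_snps.sum()
        assert weighted == pytest.approx(quantized.mean(), abs=1e-9)
        assert w.mean_af.dropna().between(0, 1).all()

    def test_bad_window_step_rejected(self):
        t = build_af_tracks(track_variants([0.5]), "SbPool1")["Chr01"]
        with pytest.raises(ValueError):
            smooth_track(t, window_bp=100, step_bp=200)


def three_pool_variants(af_by_pool, n=60, chrom="Chr01", start=1000, spacing=20_000):
    out = []
    for i in range(n):
        pools = {}
        for pool, af in af_by_pool.items():
            a = af[i] if np.ndim(af) else af
            pools[pool] = PoolObservation(40, int(round(a * 40)), 99)
        out.append(Variant(chrom=chrom, pos=start + i * spacing, ref="G", alt="A", pools=pools))
    return out


class TestDetectCandidateRegions:
    def test_flat_half_tracks_no_region(self):
        vs = three_pool_variants({"SbPool1": 0.5, "SbPool2": 0.5, "SbPool4": 0.5})
        assert detect_candidate_regions(vs) == []

    def test_fixed_mutant_chromosome_single_region(self):
        vs = three_pool_variants({"SbPool1": 1.0, "SbPool2": 1.0, "SbPool4": 1 / 3})
        regions = detect_candidate_regions(vs)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (vs[0].pos, vs[-1].pos)
        assert r.n_snps == len(vs)

    def test_nonmutant_pool_veto(self):
        """High AF in the non-mutant pool too (e.g. a shared sweep) must not
        be called a candidate region."""
        vs = three_pool_variants({"SbPool1": 1.0, "SbPool2": 1.0, "SbPool4": 0.95})
        assert detect_candidate_regions(vs) == []

    def test_end_to_end_recovery(self, desk_run):
        rc, res = desk_run
        assert len(res.regions) == 1
        top = res.regions[0]
        assert top.chrom == rc.sim.causal_chrom_name
        assert top.contains(rc.sim.causal_chrom_name, rc.sim.resolved_causal_pos() + 1)


class TestRegionSnpReport:
    def test_planted_snp_count_reported(self):
        """A region planted with 211 SNPs reports 211 rows — the size of a
        mapped locus's SNP list."""
        vs = three_pool_variants(
            {"SbPool1": 1.0, "SbPool2": 1.0, "SbPool4": 1 / 3}, n=211
        )
        region = detect_candidate_regions(vs)[0]
        df, summary = region_snp_report(region)
        assert len(df) == 211 and summary["n_snps"] == 211

    def test_empty_region_table_has_header(self):
        from bsamap.afmap import CandidateRegion

        region = CandidateRegion("Chr01", 1, 1, [], {}, 0.0)
        df, summary = region_snp_report(region)
        assert df.empty and list(df.columns)[:2] == ["chrom", "pos"]
        assert summary["n_snps"] == 0

    def test_gene_count_consistency(self, desk_run):
        _, res = desk_run
        assert res.region_summary["n_genes_overlapped"] == len(
            set(res.region_summary["genes"])
        )
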