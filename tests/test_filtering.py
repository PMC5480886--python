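import numpy as np
import pytest

from bsamap import (
    FilterParams, PoolObservation, Variant, apply_filters, compute_af,
    is_ems_transition, mask_repeats, observations_to_variants, relaxed_reextract,
)
from bsamap.filtering import (
    DataIntegrityError, InvalidAlleleError, REASON_AF, REASON_DEPTH, REASON_GQ,
    REASON_NON_EMS, REASON_REPEAT, REASON_WT,
)


def mkvar(ref="G", alt="A", depth=50, alt_n=None, gq=60, pos=100, pools=None, **kw):
    if pools is None:
        alt_n = int(0.6 * depth) if alt_n is None else alt_n
        pools = {"SbPool1": PoolObservation(depth, alt_n, gq)}
    return Variant(chrom="Chr01", pos=pos, ref=ref, alt=alt, pools=pools, **kw)


class TestEmsTransition:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("G", "A", True), ("C", "T", True), ("A", "T", False), ("A", "G", False),
         ("T", "C", False), ("G", "C", False)],
    )
    def test_reference_strand_transitions(self, ref, alt, expected):
        assert is_ems_transition(ref, alt) is expected

    def test_invalid_base_rejected(self):
        with pytest.raises(InvalidAlleleError):
            is_ems_transition("N", "A")


class TestComputeAf:
    def test_fraction_and_missing(self):
        assert compute_af(PoolObservation(10, 6, 50)) == pytest.approx(0.6)
        assert compute_af(PoolObservation(40, 0, 50)) == 0.0
        assert compute_af(PoolObservation(0, 0, 0)) is None

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(DataIntegrityError):
            PoolObservation(10, 11, 50)


class TestApplyFilters:
    def test_clean_canonical_variant_kept(self):
        res = apply_filters([mkvar()], set())
        assert len(res.kept) == 1 and not res.removed

    def test_low_depth_removed_with_reason(self):
        res = apply_filters([mkvar(depth=9, alt_n=6)], set())
        assert res.removed[0].reason == REASON_DEPTH

    def test_boundaries_inclusive(self):
        v = mkvar(depth=150, alt_n=45, gq=30)  # AF exactly 0.30, GQ 30, DP 150
        assert apply_filters([v], set()).kept
        v10 = mkvar(depth=10, alt_n=3, gq=30)
        assert apply_filters([v10], set()).kept

    def test_wt_allele_removed(self):
        v = mkvar(pos=7)
        res = apply_filters([v], {("Chr01", 7, "G", "A")})
        assert res.removed[0].reason == REASON_WT

    def test_transversion_removed_first(self):
        # order of reasons follows the stated criteria: EMS type precedes depth
        v = mkvar(ref="A", alt="T", depth=5, alt_n=3)
        assert apply_filters([v], set()).removed[0].reason == REASON_NON_EMS

    def test_multi_pool_union_policy(self):
        """A variant failing in one mutant pool but passing in the other is
        kept under the default at-least-one-mutant-pool policy."""
        pools = {
            "SbPool1": PoolObservation(5, 3, 20),
            "SbPool2": PoolObservation(40, 24, 99),
            "SbPool4": PoolObservation(40, 13, 99),
        }
        v = mkvar(pools=pools)
        assert apply_filters([v], set()).kept
        strict = FilterParams(require_all_pools=True)
        assert apply_filters([v], set(), strict).removed[0].reason == REASON_DEPTH

    def test_partition_property(self, rng):
        variants = random_variants(rng, 300)
        res = apply_filters(variants, set())
        assert len(res.kept) + len(res.removed) == len(variants)
        keys = sorted(v.key for v in res.kept + res.removed)
        assert keys == sorted(v.key for v in variants)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(min_dp=200, max_dp=100)


def random_variants(rng, n, pool_names=("SbPool1", "SbPool2", "SbPool4")):
    bases = "ACGT"
    out = []
    for i in range(n):
        ref = bases[rng.integers(4)]
        alt = rng.choice([b for b in bases if b != ref])
        pools = {}
        for p in pool_names:
            depth = int(rng.integers(0, 200))
            pools[p] = PoolObservation(
                depth, int(rng.integers(0, depth + 1)), int(rng.integers(0, 100))
            )
        out.append(
            Variant(chrom="Chr01", pos=i + 1, ref=ref, alt=str(alt), pools=pools,
                    in_wt=bool(rng.random() < 0.1))
        )
    return out


def brute_force_expected(v, params: FilterParams):
    """Independent re-evaluation of the five criteria, variant by variant."""
    if (v.ref, v.alt) not in {("G", "A"), ("C", "T")}:
        return REASON_NON_EMS
    obs = [v.pools[p] for p in params.mutant_pools if p in v.pools]
    dp_ok = [params.min_dp <= o.depth <= params.max_dp for o in obs]
    if not any(dp_ok):
        return REASON_DEPTH
    af_ok = [d and o.depth > 0 and o.alt / o.depth >= params.min_af
             for d, o in zip(dp_ok, obs)]
    if not any(af_ok):
        return REASON_AF
    gq_ok = [a and o.gq >= params.min_gq for a, o in zip(af_ok, obs)]
    if not any(gq_ok):
        return REASON_GQ
    if v.in_wt:
        return REASON_WT
    return None


class TestBruteForceOracle:
    def test_filter_matches_independent_reevaluation(self, rng):
        """On a 1,000-variant random table the filter agrees with a
        brute-force predicate evaluation for every variant, including the
        first-failure reason code."""
        params = FilterParams()
        variants = random_variants(rng, 1000)
        res = apply_filters(variants, set(), params)
        got = {v.key: v.reason for v in res.kept + res.removed}
        for v in variants:
            assert got[v.key] == brute_force_expected(v, params), v


class TestMaskRepeats:
    def test_masking_is_region_local(self):
        repeats = {"Chr01": [(90, 200)]}
        inside = mkvar(pos=100)
        region = ("Chr01", 0, 1000)
        res = mask_repeats([inside], repeats, region)
        assert res.removed and res.removed[0].reason == REASON_REPEAT
        # same repeat, but variant outside the stated region: untouched
        res2 = mask_repeats([inside], repeats, ("Chr01", 5000, 9000))
        assert res2.kept == [inside]

    def test_empty_track_is_identity(self):
        vs = [mkvar(pos=p) for p in (10, 20)]
        res = mask_repeats(vs, {}, ("Chr01", 0, 100))
        assert res.kept == vs and not res.removed


class TestRelaxedReextract:
    def test_gq_failure_flagged_not_lost(self):
        v = mkvar(gq=25, pos=50)
        df = relaxed_reextract([v], ("Chr01", 0, 100))
        assert len(df) == 1
        assert bool(df.iloc[0].gq_fail) and not bool(df.iloc[0].passes_all)

    def test_clean_region_matches_kept_set(self):
        vs = [mkvar(pos=p) for p in (10, 20, 30)]
        df = relaxed_reextract(vs, ("Chr01", 0, 100))
        assert df.passes_all.all() and len(df) == 3

    def test_empty_region(self):
        df = relaxed_reextract([mkvar(pos=10)], ("Chr02", 0, 100))
        assert df.empty and "failed_criteria" in df.columns


class TestTruthRecovery:
    def test_planted_artifacts_removed_causal_kept(self, tiny_study):
        """With error-free deep observations every planted non-canonical and
        WT-shared variant is removed and the causal variant survives."""
        from bsamap import sample_pooled_reads
        from dataclasses import replace

        cfg = replace(tiny_study["config"], error_rate=0.0)
        obs = sample_pooled_reads(tiny_study["truth"], tiny_study["pools"], cfg)
        variants = observations_to_variants(obs)
        res = apply_filters(variants, set())
        kept_keys = {(v.chrom, v.pos) for v in res.kept}
        truth = tiny_study["truth"]
        for v in truth.variants:
            if not v.ems_canonical or v.in_wt:
                assert (v.chrom, v.pos) not in kept_keys
        cv = truth.causal_variant
        assert (cv.chrom, cv.pos) in kept_keys
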