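import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile
from nucpos.dyad_profiles import (
    SizeFilter,
    aggregate_profiles,
    at_content_track,
    chr_dna_ratio,
    dyads_from_fragments,
    gene_profile,
    normalize_profile,
    occupancy_from_dyads,
    select_nucleosomal,
)
from nucpos.model import Anchor, DyadTrack, FragmentRecord, FragmentSet, GeneModel
from nucpos.pipeline import atg_aggregate, simulate_cohort
from nucpos.synthetic import SimulationConfig, simulate_chromatin_fragments


class TestSizeSelection:
    @pytest.mark.parametrize(
        "length,kept",
        [(119, False), (120, True), (150, True), (180, True), (181, False)],
    )
    def test_inclusive_bounds(self, length, kept):
        frags = [FragmentRecord("chr1", 0, length)]
        out = list(select_nucleosomal(frags))
        assert (len(out) == 1) == kept

    def test_enumeration_over_uniform_support(self):
        # one fragment of every length 100..200: exactly 61 of 101 survive
        frags = FragmentSet("chr1", np.zeros(101, dtype=int), np.arange(100, 201))
        assert len(select_nucleosomal(frags)) == 61


class TestDyadBinning:
    @pytest.mark.parametrize(
        "start,end,dyad", [(100, 250, 174), (10, 11, 10), (0, 2, 0)]
    )
    def test_midpoint_floor(self, start, end, dyad):
        track = dyads_from_fragments([FragmentRecord("chr1", start, end)], {"chr1": 300})
        assert track.counts["chr1"][dyad] == 1
        assert track.total_dyads == 1

    def test_additivity_and_conservation(self):
        frags = [FragmentRecord("chr1", 100, 250)] * 3
        track = dyads_from_fragments(frags, {"chr1": 300})
        assert track.counts["chr1"][174] == 3
        assert track.total_dyads == 3

    def test_fast_and_slow_paths_agree(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 800, 500)
        ends = starts + rng.integers(1, 200, 500)
        fs = FragmentSet("chr1", starts, ends)
        a = dyads_from_fragments(fs, {"chr1": 1000})
        b = dyads_from_fragments(list(fs), {"chr1": 1000})
        np.testing.assert_array_equal(a.counts["chr1"], b.counts["chr1"])

    def test_out_of_bounds_skipped(self):
        track = dyads_from_fragments(
            [FragmentRecord("chr1", 250, 400), FragmentRecord("chr1", 100, 200)],
            {"chr1": 300},
        )
        assert track.total_dyads == 1


class TestGeneProfiles:
    def test_plus_strand_offsets(self):
        v = np.zeros(3000, dtype=int)
        v[1060] = 7
        track = DyadTrack({"chr1": v})
        gene = GeneModel("g", "chr1", "+", 1000, 2499)
        p = gene_profile(track, gene, Anchor.ATG, (-600, 600))
        assert p.value_at(60) == 7

    def test_minus_strand_mirror(self):
        v = np.zeros(3000, dtype=int)
        v[1940] = 5
        track = DyadTrack({"chr1": v})
        gene = GeneModel("g", "chr1", "-", 2000, 501)
        p = gene_profile(track, gene, Anchor.ATG, (-600, 600))
        assert p.value_at(60) == 5

    def test_chromosome_edge_masking(self):
        track = DyadTrack({"chr1": np.zeros(5000, dtype=int)})
        gene = GeneModel("g", "chr1", "+", 100, 1500)
        p = gene_profile(track, gene, Anchor.ATG, (-600, 600))
        assert not p.mask[:500].any() and p.mask[500:].all()

    def test_plus_one_anchor_requires_assignment(self):
        track = DyadTrack({"chr1": np.zeros(100, dtype=int)})
        gene = GeneModel("g", "chr1", "+", 10, 80)
        with pytest.raises(ValueError, match="g"):
            gene_profile(track, gene, Anchor.PLUS_ONE, (-10, 10))


class TestAggregation:
    def test_mean_of_profiles(self):
        agg = aggregate_profiles([make_profile([1, 2, 3]), make_profile([3, 2, 1])])
        np.testing.assert_allclose(agg.values, [2, 2, 2])
        assert agg.n_genes == 2

    def test_masked_bins_use_remaining_genes(self):
        a = make_profile([1, 2, 3], mask=[False, True, True])
        b = make_profile([5, 4, 3])
        agg = aggregate_profiles([a, b])
        np.testing.assert_allclose(agg.values, [5, 3, 3])
        assert agg.mask.all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_profiles([])

    def test_planted_summits_recovered_in_aggregate(self):
        # phased dyads at {60, 230, 400} plus uniform noise across 100 genes
        rng = np.random.default_rng(5)
        profiles = []
        for _ in range(100):
            v = np.zeros(1201)
            for s in (60, 230, 400):
                hits = 600 + s + rng.integers(-2, 3, size=30)
                np.add.at(v, hits, 1)
            np.add.at(v, rng.integers(0, 1201, 40), 1)
            profiles.append(make_profile(v, lo=-600))
        agg = aggregate_profiles(profiles)
        for s in (60, 230, 400):
            window = agg.values[agg.index(s) - 10 : agg.index(s) + 11]
            assert abs((np.argmax(window) - 10)) <= 2


class TestNormalization:
    def test_examples(self):
        np.testing.assert_allclose(
            normalize_profile(make_profile([1, 2, 3])).values, [0.5, 1.0, 1.5]
        )
        np.testing.assert_allclose(
            normalize_profile(make_profile([4.2] * 5)).values, np.ones(5)
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=2, max_size=50)
    )
    def test_idempotent_and_scale_invariant(self, values):
        p = make_profile(values)
        once = normalize_profile(p)
        np.testing.assert_allclose(once.values[once.mask].mean(), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            normalize_profile(once).values, once.values, atol=1e-12
        )
        scaled = normalize_profile(make_profile(np.asarray(values) * 7.0))
        np.testing.assert_allclose(scaled.values, once.values, rtol=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(make_profile([0, 0, 0]))


class TestChrDnaRatio:
    def test_self_ratio_is_one(self):
        p = normalize_profile(make_profile([1, 2, 3, 2, 1]))
        ratio = chr_dna_ratio(p, p)
        np.testing.assert_allclose(ratio.values[ratio.mask], 1.0)

    def test_pointwise_division(self):
        chrom = make_profile([2.0, 0.5, 0.5])
        naked = make_profile([0.5, 0.5, 2.0])
        ratio = chr_dna_ratio(chrom, naked)
        assert ratio.value_at(0) == 4.0

    def test_floor_masks_dropout_bins(self):
        chrom = normalize_profile(make_profile([1, 1, 1, 1]))
        naked = make_profile([0.0, 4 / 3, 4 / 3, 4 / 3])
        ratio = chr_dna_ratio(chrom, naked, floor=0.05)
        assert not ratio.mask[0] and ratio.mask[1:].all()

    def test_window_mismatch_rejected(self):
        a = normalize_profile(make_profile([1, 2, 3]))
        b = normalize_profile(make_profile([1, 2, 3, 4]))
        with pytest.raises(ValueError):
            chr_dna_ratio(a, b)

    def test_unnormalized_input_rejected(self):
        a = make_profile([1, 2, 3])
        with pytest.raises(ValueError, match="normalized"):
            chr_dna_ratio(a, a)


class TestATContent:
    def test_hand_counts(self):
        at = at_content_track("ATATAT", 3)
        assert at[2] == 1.0
        gc = at_content_track("GCGCGC", 3)
        np.testing.assert_allclose(gc[1:-1], 0.0)
        # N is excluded from numerator and denominator: A,T of A,T,G,C -> 2/4
        assert at_content_track("ATGCN", 5)[2] == 0.5

    def test_window_validation(self):
        with pytest.raises(ValueError):
            at_content_track("ATGC", 2)
        with pytest.raises(ValueError):
            at_content_track("ATG", 5)


class TestOccupancy:
    def test_footprint_extension(self):
        v = np.zeros(400, dtype=int)
        v[200] = 2
        occ = occupancy_from_dyads(DyadTrack({"chr1": v}), footprint=147)
        assert occ.counts["chr1"][200 - 73] == 2
        assert occ.counts["chr1"][200 + 73] == 2
        assert occ.counts["chr1"][200 - 74] == 0
        assert occ.counts["chr1"].sum() == 2 * 147


def _mirror_cohort_profiles():
    """Aggregate ATG profile of a cohort and of its mirror image."""
    cfg = SimulationConfig(
        seed=21,
        n_genes=60,
        fragment_length_mean=151.0,
        fragment_length_sd=0.0,  # odd lengths keep the dyad exactly central
    )
    cohort = simulate_cohort(cfg, with_naked=False)
    track = cohort.tracks[("growth", 1)]
    L = cohort.truth.chrom_sizes["chr1"]
    fwd = atg_aggregate(track, cohort.genes, (-300, 300))

    frags = simulate_chromatin_fragments(cohort.truth, "growth", 1)
    kept = frags.filter_length(120, 180)
    mirrored = FragmentSet("chr1", L - kept.ends, L - kept.starts)
    mtrack = dyads_from_fragments(mirrored, {"chr1": L})
    mgenes = [
        GeneModel(
            g.gene_id,
            g.chrom,
            "-" if g.strand == "+" else "+",
            L - 1 - g.atg,
            L - 1 - g.stop,
        )
        for g in cohort.genes
    ]
    rev = atg_aggregate(mtrack, mgenes, (-300, 300))
    return fwd, rev


def test_strand_mirror_symmetry():
    """Reversing genome, annotation, and fragments leaves profiles unchanged."""
    fwd, rev = _mirror_cohort_profiles()
    np.testing.assert_allclose(rev.values, fwd.values, atol=1e-9)
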