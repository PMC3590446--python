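import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodtemplate import (
    CandidateRecord,
    ChromosomeLayout,
    GAConfig,
    TemplateSpec,
    Volume,
    build_template,
    decode,
    encode,
    exhaustive_match,
    fitness,
    ga_search,
    non_maximum_suppression,
    repair,
    similarity,
)
from tests.conftest import center_radius_match


class TestChromosomeCodec:
    layout = ChromosomeLayout()

    def test_default_width_is_28_bits(self):
        assert self.layout.n_bits == 28

    def test_semicircle_layout_adds_angle_gene(self):
        assert ChromosomeLayout(angle_bits=4).n_bits == 32

    def test_all_zero_bits_decode_to_origin_and_r_min(self):
        from nodtemplate.matching import Chromosome

        chrom = Chromosome(bits=(0,) * 28, layout=self.layout)
        center, R, angle = decode(chrom, radius_range=(5, 30))
        assert center == (0, 0, 0) and R == 5 and angle is None

    def test_big_endian_field_convention(self):
        # x-field 000000011 -> x = 3
        bits = (0, 0, 0, 0, 0, 0, 0, 1, 1) + (0,) * 19
        from nodtemplate.matching import Chromosome

        center, _, _ = decode(Chromosome(bits=bits, layout=self.layout))
        assert center[0] == 3

    @given(st.integers(0, 511), st.integers(0, 511), st.integers(0, 31),
           st.integers(5, 30))
    @settings(max_examples=100, deadline=None)
    def test_decode_encode_round_trip(self, x, y, z, R):
        chrom = encode((x, y, z), R, None, self.layout, radius_range=(5, 30))
        assert decode(chrom, radius_range=(5, 30)) == ((x, y, z), R, None)

    def test_angle_gene_quantization(self):
        layout = ChromosomeLayout(angle_bits=4)
        chrom = encode((1, 2, 3), 10, 247.5, layout)
        _, _, angle = decode(chrom)
        assert angle == 247.5  # 11 * 22.5 degrees

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            encode((512, 0, 0), 10, None, self.layout)
        with pytest.raises(ValueError):
            encode((0, 0, 0), 31, None, self.layout, radius_range=(5, 30))

    def test_radius_gene_clipped_at_r_max(self):
        from nodtemplate.matching import Chromosome

        bits = [0] * 28
        bits[23:28] = [1, 1, 1, 1, 1]  # gene 31 -> R = 5 + 31 clipped to 30
        _, R, _ = decode(Chromosome(bits=tuple(bits), layout=self.layout))
        assert R == 30


class TestSimilarity:
    def test_self_similarity_is_one(self):
        img = build_template(TemplateSpec("circle", R=7.0))
        assert similarity(img.values, img) == pytest.approx(1.0)

    def test_negated_image_is_minus_one(self):
        img = build_template(TemplateSpec("circle", R=7.0))
        assert similarity(255.0 - img.values, img) == pytest.approx(-1.0)

    def test_hand_computed_2x2(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert similarity(a, b) == pytest.approx(6.5 / np.sqrt(5 * 8.75), abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(5, 5)), rng.normal(size=(5, 5))
        assert similarity(a, b) == pytest.approx(similarity(b, a))

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_positive_affine_rescaling(self, gain, offset):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
        assert similarity(gain * a + offset, b) == pytest.approx(
            similarity(a, b), abs=1e-9
        )

    def test_zero_variance_is_non_candidate(self):
        img = build_template(TemplateSpec("circle", R=5.0))
        flat = np.full_like(img.values, 42.0)
        assert similarity(flat, img) == float("-inf")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.zeros((3, 3)), np.zeros((4, 4)))


class TestFitness:
    def _planted_volume(self, spec, center=(16, 16, 1), dims=(32, 32, 3)):
        img = build_template(spec)
        data = np.full(dims, 20.0)
        offs = np.argwhere(img.support) - np.array(img.center)
        if offs.shape[1] == 2:
            offs = np.hstack([offs, np.zeros((len(offs), 1), dtype=int)])
        coords = offs + np.array(center)
        data[coords[:, 0], coords[:, 1], coords[:, 2]] = img.values[img.support]
        return Volume(data=data)

    def test_planted_template_scores_one(self):
        spec = TemplateSpec("circle", R=6.0)
        vol = self._planted_volume(spec)
        chrom = encode((16, 16, 1), 6, None, ChromosomeLayout())
        assert fitness(vol, chrom, spec) == pytest.approx(1.0)

    def test_uniform_region_is_invalid(self):
        spec = TemplateSpec("circle", R=5.0)
        vol = Volume(data=np.full((32, 32, 3), 50.0))
        chrom = encode((16, 16, 1), 5, None, ChromosomeLayout())
        assert fitness(vol, chrom, spec) == float("-inf")

    def test_window_outside_volume_is_invalid(self):
        spec = TemplateSpec("circle", R=6.0)
        vol = self._planted_volume(spec)
        chrom = encode((2, 2, 1), 6, None, ChromosomeLayout())
        assert fitness(vol, chrom, spec) == float("-inf")

    def test_noisy_planted_template_degrades_gracefully(self):
        spec = TemplateSpec("circle", R=8.0)
        vol = self._planted_volume(spec)
        noisy = Volume(data=vol.data + np.random.default_rng(0).normal(0, 5, vol.shape))
        chrom = encode((16, 16, 1), 8, None, ChromosomeLayout())
        assert fitness(noisy, chrom, spec) > 0.9


class TestRepair:
    layout = ChromosomeLayout()

    def test_in_space_location_is_identity(self):
        chrom = encode((10, 10, 0), 7, None, self.layout)
        assert repair(chrom, {(10, 10, 0)}) is chrom

    def test_singleton_space(self):
        chrom = encode((100, 200, 3), 7, None, self.layout)
        fixed = repair(chrom, {(10, 10, 0)})
        center, R, _ = decode(fixed)
        assert center == (10, 10, 0) and R == 7  # radius gene untouched

    def test_lexicographic_tie_break(self):
        space = {(0, 0, 0), (4, 0, 0)}
        c1 = repair(encode((1, 0, 0), 5, None, self.layout), space)
        assert decode(c1)[0] == (0, 0, 0)
        c2 = repair(encode((2, 0, 0), 5, None, self.layout), space)
        assert decode(c2)[0] == (0, 0, 0)  # equidistant -> lexicographic winner
        c3 = repair(encode((3, 0, 0), 5, None, self.layout), space)
        assert decode(c3)[0] == (4, 0, 0)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            repair(encode((1, 1, 1), 5, None, self.layout), set())


class TestGASearch:
    def test_recovers_planted_circles(self, toy_phantom, toy_ga_config):
        vol, _, truth, space = toy_phantom
        found = ga_search(vol, space, "circle", toy_ga_config)
        for nod in truth.nodules:
            assert center_radius_match(found, nod)

    def test_deterministic_per_seed(self, toy_phantom, toy_ga_config):
        vol, _, _, space = toy_phantom
        a = ga_search(vol, space, "circle", toy_ga_config)
        b = ga_search(vol, space, "circle", toy_ga_config)
        assert a == b

    def test_pure_noise_yields_no_candidates(self):
        rng = np.random.default_rng(12)
        vol = Volume(data=rng.normal(50.0, 2.0, (24, 24, 3)))
        space = {(x, y, 1) for x in range(6, 18) for y in range(6, 18)}
        cfg = GAConfig(seed=1, generations=10, population_size=30, radius_range=(5, 8))
        assert ga_search(vol, space, "circle", cfg) == []

    def test_candidates_lie_in_space_above_threshold(self, toy_phantom, toy_ga_config):
        vol, _, _, space = toy_phantom
        found = ga_search(vol, space, "circle", toy_ga_config, dedup=False)
        assert found
        for rec in found:
            assert rec.similarity > toy_ga_config.similarity_threshold
            assert space.contains(*rec.center)

    def test_tiny_population_rejected(self, toy_phantom, toy_ga_config):
        vol, _, _, space = toy_phantom
        from dataclasses import replace

        with pytest.raises(ValueError):
            ga_search(vol, space, "circle", replace(toy_ga_config, population_size=1))

    def test_empty_space_rejected(self, toy_phantom, toy_ga_config):
        vol, _, _, _ = toy_phantom
        with pytest.raises(ValueError):
            ga_search(vol, set(), "circle", toy_ga_config)


class TestExhaustiveMatch:
    def test_single_planted_template_peaks_at_truth(self):
        spec = TemplateSpec("circle", R=6.0)
        img = build_template(spec)
        data = np.full((32, 32, 3), 20.0)
        offs = np.argwhere(img.support) - np.array(img.center)
        data[offs[:, 0] + 16, offs[:, 1] + 16, 1] = img.values[img.support]
        vol = Volume(data=data)
        space = {(x, y, 1) for x in range(8, 25) for y in range(8, 25)}
        found = exhaustive_match(vol, space, "circle",
                                 config=GAConfig(radius_range=(5, 8)), dedup=True)
        assert found[0].center == (16, 16, 1)
        assert found[0].R == 6.0
        assert found[0].similarity == pytest.approx(1.0)

    def test_finds_both_planted_circles(self, toy_phantom, toy_ga_config):
        vol, _, truth, space = toy_phantom
        found = exhaustive_match(vol, space, "circle", config=toy_ga_config)
        for nod in truth.nodules:
            assert center_radius_match(found, nod)

    def test_ga_harvest_contained_in_exhaustive(self, toy_phantom, toy_ga_config):
        vol, _, _, space = toy_phantom
        ga = ga_search(vol, space, "circle", toy_ga_config, dedup=False)
        ex = exhaustive_match(vol, space, "circle", config=toy_ga_config)
        ex_keys = {(r.center, r.R, r.angle) for r in ex}
        assert {(r.center, r.R, r.angle) for r in ga} <= ex_keys


def test_non_maximum_suppression_keeps_strongest_of_overlap():
    recs = [
        CandidateRecord(center=(10, 10, 1), shape="circle", R=6.0, similarity=0.95),
        CandidateRecord(center=(12, 10, 1), shape="circle", R=6.0, similarity=0.90),
        CandidateRecord(center=(25, 25, 1), shape="circle", R=5.0, similarity=0.85),
    ]
    kept = non_maximum_suppression(recs)
    assert [r.center for r in kept] == [(10, 10, 1), (25, 25, 1)]
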