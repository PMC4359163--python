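"""Synthetic generators: determinism, forward-model exactness, fixture behavior."""

import numpy as np
import pandas as pd
import pytest

from temnet.deconvolution import enumerate_replicate_triples
from temnet.mis import mis_unroll
from temnet.synthetic import (
    MixtureDesign,
    PlantedDesign,
    default_planted_design,
    generate_mixture_dataset,
    generate_random_network,
    generate_response_dataset,
    paperlike_network,
    tem_phenotype_queries,
)


class TestPlantedDesignDefaults:
    def test_study_shaped_rosters(self):
        design = default_planted_design()
        assert len(design.receptors) == 7
        assert len(design.cytokines) == 11
        assert len(design.treatments) == 12

    def test_quartile_filling_cell_counts(self):
        # 25% of cells per side and readout kind respond, so the pooled
        # quartile cutoffs separate responders from noise cells.
        design = default_planted_design()
        receptor_cells = {(t, r): sr for t, r, sr, _, _ in design.planted_links}
        cytokine_cells = {(t, c): sc for t, _, _, c, sc in design.planted_links}
        assert len(receptor_cells) == 42  # of 84
        assert len(cytokine_cells) == 66  # of 132
        assert sum(1 for s in receptor_cells.values() if s > 0) == 21
        assert sum(1 for s in cytokine_cells.values() if s > 0) == 33

    def test_planted_pairs_are_coherent(self):
        design = default_planted_design()
        products = {}
        for t, r, sr, c, sc in design.planted_links:
            products.setdefault((r, c), set()).add(sr * sc)
        assert all(len(p) == 1 for p in products.values())
        assert {-1} in products.values()  # an anti-correlated pair exists


class TestResponseGenerator:
    def test_noiseless_values_are_exact_powers_of_two(self):
        design = default_planted_design(noise_sd=0.0, seed=0)
        receptor_table, cytokine_table, _ = generate_response_dataset(design)
        planted = {(t, r): sr for t, r, sr, _, _ in design.planted_links}
        for (treatment, readout), group in receptor_table.data.groupby(
            ["treatment", "readout"]
        ):
            expected = 100.0 * 2.0 ** planted.get((treatment, readout), 0)
            assert np.allclose(group["value"], expected)
        assert (cytokine_table.data["value"] > 0).all()

    def test_same_seed_is_bit_reproducible(self):
        a = generate_response_dataset(default_planted_design(seed=9))
        b = generate_response_dataset(default_planted_design(seed=9))
        pd.testing.assert_frame_equal(a[0].data, b[0].data)
        pd.testing.assert_frame_equal(a[1].data, b[1].data)

    def test_different_seeds_share_the_truth_but_not_the_noise(self):
        a = generate_response_dataset(default_planted_design(seed=1))
        b = generate_response_dataset(default_planted_design(seed=2))
        assert a[2] == b[2]
        assert not a[0].data["value"].equals(b[0].data["value"])

    def test_conflicting_planted_signs_rejected(self):
        design = default_planted_design()
        t, r, sr, c, sc = design.planted_links[0]
        bad = PlantedDesign(
            receptors=design.receptors,
            cytokines=design.cytokines,
            treatments=design.treatments,
            planted_links=design.planted_links + ((t, r, -sr, c, sc),),
        )
        with pytest.raises(ValueError, match="conflicting"):
            generate_response_dataset(bad)


class TestMixtureGenerator:
    def test_compositions_lie_on_the_simplex(self):
        _, compositions, _ = generate_mixture_dataset(MixtureDesign(seed=0))
        assert np.allclose(compositions.sum(axis=1), 1.0)
        assert (compositions >= 0).all()

    def test_noiseless_forward_model_is_exact(self):
        measurements, compositions, truth = generate_mixture_dataset(
            MixtureDesign(noise_sd=0.0, seed=1)
        )
        assert np.allclose(measurements, compositions @ truth)

    def test_nine_replicates_feed_84_triples_downstream(self):
        measurements, _, _ = generate_mixture_dataset(MixtureDesign(n_replicates=9, seed=2))
        assert len(enumerate_replicate_triples(len(measurements))) == 84

    def test_seed_determinism(self):
        a = generate_mixture_dataset(MixtureDesign(seed=5))
        b = generate_mixture_dataset(MixtureDesign(seed=5))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestRandomNetworks:
    def test_single_input_node(self):
        network = generate_random_network(1, seed=0)
        assert network.to_text().strip().splitlines()[1] == "N1, N1"

    def test_same_seed_gives_identical_equation_text(self):
        assert (
            generate_random_network(10, seed=4).to_text()
            == generate_random_network(10, seed=4).to_text()
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_indegree_bound_is_respected(self, seed):
        network = generate_random_network(12, max_indegree=3, seed=seed)
        for node in network.nodes:
            assert len(network.regulators(node)) <= 3


class TestPaperlikeFixture:
    def test_flagged_as_a_reconstruction(self, paperlike):
        assert paperlike.metadata["reconstruction"] is True

    def test_unperturbed_network_has_fixed_points(self, paperlike):
        assert len(paperlike.fixed_points()) >= 1

    def test_promoting_triple_forces_both_receptors_high(self, paperlike):
        fps = paperlike.clamp({"TNFA": 1, "ANG2": 1, "PLGF": 1}).fixed_points()
        assert fps
        assert all(s["TIE2"] == 1 and s["VEGFR1"] == 1 for s in fps)

    def test_tie2_inhibition_with_tgfb_and_vegf_silences_vegfr1(self, paperlike):
        fps = paperlike.clamp({"TIE2": 0, "TGFB": 1, "VEGF": 1}).fixed_points()
        assert fps
        assert all(s["VEGFR1"] == 0 for s in fps)

    def test_unique_promoting_mis_is_the_ligand_triple(self, paperlike):
        queries = tem_phenotype_queries(paperlike)
        (promoting,) = mis_unroll(queries["promoting"])
        assert {(iv.node, iv.polarity) for iv in promoting} == {
            ("TNFA", 1),
            ("PLGF", 1),
            ("ANG2", 1),
        }

    def test_dampening_mis_include_direct_double_inhibition(self, paperlike):
        queries = tem_phenotype_queries(paperlike)
        dampening = mis_unroll(queries["dampening"])
        assert {("TIE2", 0), ("VEGFR1", 0)} in [
            {(iv.node, iv.polarity) for iv in s} for s in dampening
        ]
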