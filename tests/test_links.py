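"""Three-criteria link retention and network assembly."""

import numpy as np
import pytest

from temnet import response as rd
from temnet.links import (
    InferenceConfig,
    LinkInferrer,
    amplitude_cutoffs,
    enumerate_candidate_links,
    infer_links,
    is_coherent,
    is_reproducible,
    links_to_network,
    passes_amplitude,
)
from temnet.synthetic import PlantedDesign, default_planted_design, generate_response_dataset


class TestCandidates:
    @pytest.mark.parametrize(
        "n_r, n_c, n_t, expected", [(7, 11, 12, 924), (1, 1, 1, 1), (2, 3, 4, 24)]
    )
    def test_candidate_count_is_the_roster_product(self, n_r, n_c, n_t, expected):
        candidates = enumerate_candidate_links(
            [f"R{i}" for i in range(n_r)],
            [f"C{i}" for i in range(n_c)],
            [f"T{i}" for i in range(n_t)],
        )
        assert len(candidates) == expected
        assert len(set(candidates)) == expected

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidate_links([], ["C"], ["T"])


class TestReproducibility:
    @pytest.mark.parametrize(
        "values, flag, sign",
        [
            ([1, 1, 1, -1], True, 1),       # 3/4 meets the threshold
            ([1, 1, -1, -1], False, 0),      # a tie has no majority sign
            ([-2, -1, -3, 1], True, -1),
            ([0.5, 0.4, -0.1, 0.2, 0.3], True, 1),  # 4/5
            ([0, 0, 0], False, 0),           # all zero: undefined sign
        ],
    )
    def test_majority_sign_threshold(self, values, flag, sign):
        got_flag, got_sign = is_reproducible(values)
        assert (got_flag, got_sign) == (flag, sign)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            is_reproducible([1.0])


class TestAmplitude:
    pooled = [-1.0, -0.5, -0.1, 0.0, 0.1, 0.2, 0.5, 1.0]

    def test_extremes_pass_median_fails(self):
        assert passes_amplitude(1.0, self.pooled)
        assert passes_amplitude(-1.0, self.pooled)
        assert not passes_amplitude(0.05, self.pooled)

    def test_cutoffs_match_sorting_oracle(self):
        rng = np.random.default_rng(4)
        pooled = rng.normal(size=101)
        lower, upper = amplitude_cutoffs(pooled)
        ranked = np.sort(pooled)
        assert lower == pytest.approx(ranked[25])  # 0.25 * (101 - 1)
        assert upper == pytest.approx(ranked[75])

    def test_cutoff_ties_are_inclusive(self):
        pooled = [0.0, 1.0, 2.0, 3.0, 4.0]
        lower, upper = amplitude_cutoffs(pooled)
        assert passes_amplitude(upper, pooled)
        assert passes_amplitude(lower, pooled)


class TestCoherence:
    def test_constant_positive_product(self):
        flag, sign = is_coherent({"T1": 1, "T2": -1, "T3": 1}, {"T1": 1, "T2": -1, "T3": 1})
        assert (flag, sign) == (True, 1)

    def test_constant_negative_product(self):
        flag, sign = is_coherent(
            {"T1": 1, "T2": -1, "T3": 1, "T4": -1},
            {"T1": -1, "T2": 1, "T3": -1, "T4": 1},
        )
        assert (flag, sign) == (True, -1)

    def test_mixed_products_fail(self):
        flag, _ = is_coherent({"T1": 1, "T2": 1}, {"T1": 1, "T2": -1})
        assert not flag

    def test_single_informative_treatment_is_vacuous(self):
        flag, _ = is_coherent({"T1": 1}, {"T1": 1})
        assert not flag


class TestInference:
    def test_noiseless_planted_links_are_recovered_exactly(self, noiseless_dataset):
        receptor_table, cytokine_table, truth = noiseless_dataset
        links = infer_links(receptor_table, cytokine_table)
        assert sorted(links) == sorted(truth)

    def test_noisy_default_design_keeps_perfect_precision_and_recall(self, planted_dataset):
        receptor_table, cytokine_table, truth = planted_dataset
        links = infer_links(receptor_table, cytokine_table)
        assert sorted(links) == sorted(truth)

    def test_all_null_dataset_retains_far_below_quartile_admission(self):
        design = PlantedDesign(noise_sd=0.05, seed=3)
        receptor_table, cytokine_table, _ = generate_response_dataset(design)
        links = infer_links(receptor_table, cytokine_table)
        assert len(links) / 924 < 0.25

    def test_tightening_criteria_never_enlarges_the_link_set(self, planted_dataset):
        receptor_table, cytokine_table, _ = planted_dataset
        base = set(infer_links(receptor_table, cytokine_table))
        tighter = set(
            infer_links(
                receptor_table,
                cytokine_table,
                InferenceConfig(
                    reproducibility_fraction=1.0, amplitude_quantiles=(0.1, 0.9)
                ),
            )
        )
        assert tighter <= base

    def test_result_is_independent_of_row_order(self, planted_dataset):
        receptor_table, cytokine_table, _ = planted_dataset
        shuffled = rd.ResponseTable(
            receptor_table.data.sample(frac=1.0, random_state=0).reset_index(drop=True),
            rd.RECEPTOR,
        )
        assert infer_links(shuffled, cytokine_table) == infer_links(
            receptor_table, cytokine_table
        )

    def test_disjoint_treatments_are_a_configuration_error(self, planted_dataset):
        receptor_table, cytokine_table, _ = planted_dataset
        renamed = cytokine_table.data.assign(
            treatment="X_" + cytokine_table.data["treatment"]
        )
        with pytest.raises(ValueError, match="share no treatments"):
            infer_links(receptor_table, rd.ResponseTable(renamed, rd.CYTOKINE))

    def test_estimator_exposes_fitted_attributes(self, planted_dataset):
        receptor_table, cytokine_table, _ = planted_dataset
        inferrer = LinkInferrer().fit(receptor_table, cytokine_table)
        assert len(inferrer.candidates_) == 924
        assert set(inferrer.cutoffs_) == {rd.RECEPTOR, rd.CYTOKINE}
        assert inferrer.get_params()["reproducibility_fraction"] == 0.75


class TestNetworkAssembly:
    def test_single_activating_link_builds_a_chain(self):
        from temnet.links import RetainedLink

        network = links_to_network([RetainedLink("T", "R", 1, "C", 1, 1)])
        assert set(network.nodes) == {"T", "R", "C"}
        state = {n: 1 for n in network.nodes}
        fps = [s for s in network.fixed_points() if s["T"] == 1]
        assert fps and all(s["R"] == 1 and s["C"] == 1 for s in fps)

    def test_combined_treatment_creates_an_and_node(self):
        from temnet.links import RetainedLink

        network = links_to_network([RetainedLink("TGFB+PLGF", "R", 1, "C", -1, -1)])
        assert "PLGF_AND_TGFB" in network.nodes
        assert set(network.regulators("PLGF_AND_TGFB")) == {"TGFB", "PLGF"}

    def test_fixed_points_reproduce_planted_signs_under_single_ligand_inputs(
        self, noiseless_dataset
    ):
        # Single-ligand boundary conditions: each readout's steady state
        # matches the planted sign.  (Under combined inputs the OR/NOT-OR
        # template lets inhibiting treatments dominate by convention.)
        _, _, truth = noiseless_dataset
        network = links_to_network(truth)
        ligands = set(network.inputs)
        by_treatment = {}
        for link in truth:
            by_treatment.setdefault(link.treatment, []).append(link)
        for treatment, links in by_treatment.items():
            components = set(treatment.split("+"))
            if len(components) != 1:
                continue
            clamped = network.clamp({l: int(l in components) for l in ligands})
            fps = clamped.fixed_points()
            assert len(fps) == 1
            state = fps[0]
            for link in links:
                assert state[link.receptor] == (1 if link.receptor_sign > 0 else 0)
                assert state[link.cytokine] == (1 if link.cytokine_sign > 0 else 0)

    def test_empty_link_set_rejected(self):
        with pytest.raises(ValueError):
            links_to_network([])
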