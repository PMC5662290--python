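import numpy as np
import pytest

from arborscale.morphometry import decompose_twigs, total_cable
from arborscale.skeletons import SkeletonError
from arborscale.synthetic import (
    GrowthSpec,
    default_normalized_input,
    generate_circuit_pair,
    generate_neuron,
)


@pytest.fixture(scope="module")
def pair():
    return generate_circuit_pair(GrowthSpec(seed=123))


class TestGenerateNeuron:
    def test_zero_twig_density_gives_pure_backbone(self, rng):
        spec = GrowthSpec(twig_density_per_um=0.0)
        gn = generate_neuron(spec, 0, "A09a", "L", rng)
        assert gn.n_twigs == 0
        assert gn.twig_membership == {}
        assert not gn.skeleton.tagged("microtubule_end")

    def test_twig_count_matches_poisson_rate(self):
        """Twig count / backbone cable ~ spec density (within 3 sd of the
        Poisson rate, pooled over several neurons)."""
        spec = GrowthSpec()
        rng = np.random.default_rng(5)
        total_twigs, expectation = 0, 0.0
        for _ in range(10):
            gn = generate_neuron(spec, 0, "A09a", "L", rng)
            total_twigs += gn.n_twigs
            expectation += spec.twig_density_per_um * spec.backbone_cable_um
        assert abs(total_twigs - expectation) < 3 * np.sqrt(expectation)

    def test_tag_mode_decomposition_recovers_ground_truth(self, rng):
        spec = GrowthSpec()
        gn = generate_neuron(spec, 0, "A02n", "R", rng)
        dec = decompose_twigs(gn.skeleton, mode="tags")
        assert set(dec.membership) == set(gn.twig_membership)
        # identical partition: same node grouping
        truth_groups = {
            frozenset(gn.twig_nodes(t)) for t in gn.twig_root_of
        }
        got_groups = {
            frozenset(dec.twig_nodes(t)) for t in dec.table["twig_id"]
        }
        assert truth_groups == got_groups
        # and every twig root matches
        roots_truth = {gn.twig_root_of[t] for t in gn.twig_root_of}
        assert roots_truth == set(dec.table["root_node"])

    def test_stage_two_neuron_is_larger(self, rng):
        spec = GrowthSpec()
        a = generate_neuron(spec, 0, "A09a", "L", rng)
        b = generate_neuron(spec, 1, "A09a", "L", rng)
        assert total_cable(b.skeleton) > 2 * total_cable(a.skeleton)

    def test_degenerate_spec_rejected(self, rng):
        with pytest.raises(SkeletonError, match="zero cable"):
            generate_neuron(GrowthSpec(backbone_cable_um=0.0), 0, "x", "L", rng)


class TestSpecValidation:
    def test_infeasible_matrix_rejected(self):
        w = default_normalized_input() * 3.0
        with pytest.raises(SkeletonError, match="infeasible"):
            GrowthSpec(normalized_input=w).validate()

    def test_negative_fold_rejected(self):
        with pytest.raises(SkeletonError, match="fold"):
            GrowthSpec(fold_cable=-1.0).validate()

    def test_improper_twig_distribution_rejected(self):
        with pytest.raises(SkeletonError, match="improper"):
            GrowthSpec(synapses_per_twig_probs=(0.9, 0.3)).validate()


class TestCircuitPair:
    def test_fixed_seed_bit_identical(self):
        a1, b1, _ = generate_circuit_pair(GrowthSpec(seed=9))
        a2, b2, _ = generate_circuit_pair(GrowthSpec(seed=9))
        for c1, c2 in ((a1, a2), (b1, b2)):
            assert set(c1.skeletons) == set(c2.skeletons)
            for nid in c1.skeletons:
                s1, s2 = c1.skeletons[nid], c2.skeletons[nid]
                assert s1.nodes == s2.nodes
                assert s1.tags == s2.tags
            assert len(c1.connectors) == len(c2.connectors)
            for x, y in zip(c1.connectors, c2.connectors):
                assert (x.pre, x.posts, x.location) == (y.pre, y.posts, y.location)

    def test_truth_tables_track_generated_quantities(self, pair):
        c1, c2, truth = pair
        for stage, circuit in zip(("stage1", "stage2"), (c1, c2)):
            sub = truth.per_neuron[truth.per_neuron["stage"] == stage]
            for row in sub.itertuples():
                assert row.neuron_id in circuit.skeletons
                inputs = circuit.inputs_by_node(row.neuron_id)
                assert sum(inputs.values()) == row.n_inputs

    def test_unity_folds_give_statistically_identical_stages(self):
        spec = GrowthSpec(
            seed=21, fold_cable=1.0, fold_inputs=1.0, fold_twigs=1.0,
            fold_backbone_cable=1.0, fold_axon=1.0,
            neuropile_width_um=(43.0, 43.0), segment_length_um=(15.0, 15.0),
        )
        _, _, truth = generate_circuit_pair(spec)
        means = truth.per_neuron.groupby("stage")[
            ["dendritic_cable_um", "n_twigs", "n_inputs"]
        ].mean()
        ratio = means.loc["stage2"] / means.loc["stage1"]
        assert abs(ratio["n_inputs"] - 1.0) < 1e-9  # fixed by construction
        assert abs(ratio["dendritic_cable_um"] - 1.0) < 0.15
        assert abs(ratio["n_twigs"] - 1.0) < 0.15

    def test_fold_factors_realized_in_truth(self, pair):
        _, _, truth = pair
        means = truth.per_neuron.groupby("stage")[
            ["dendritic_cable_um", "n_twigs", "n_inputs"]
        ].mean()
        ratio = means.loc["stage2"] / means.loc["stage1"]
        spec = truth.spec
        assert ratio["dendritic_cable_um"] == pytest.approx(spec.fold_cable, rel=0.10)
        assert ratio["n_twigs"] == pytest.approx(spec.fold_twigs, rel=0.10)
        assert ratio["n_inputs"] == pytest.approx(spec.fold_inputs, rel=1e-9)

    def test_normalized_input_correlated_across_stages(self):
        """Realized per-type source fractions correlate strongly between
        stages when per-stage sampling noise is small (many inputs per cell);
        both stages estimate the same target matrix."""
        _, _, truth = generate_circuit_pair(GrowthSpec(seed=31, n_inputs=400))
        sc = truth.source_counts
        sc = sc[sc["source"] != "background"].copy()
        # mirror left-side labels so homologous connections align
        def canonical(row):
            src = row["source"]
            if row["side"] == "L":
                src = src[:-2] + ("_R" if src.endswith("_L") else "_L")
            return src

        sc["csource"] = sc.apply(canonical, axis=1)
        per = (
            sc.groupby(["stage", "cell_type", "csource"])["contacts"]
            .sum()
            .unstack("stage")
        )
        frac = per / per.sum(axis=0)
        corr = np.corrcoef(frac["stage1"], frac["stage2"])[0, 1]
        assert corr > 0.9

    def test_posts_per_site_distribution_is_polyadic(self, pair):
        """Sites draw a 1 + Poisson(lambda) size target, truncated by how
        many ungrouped contacts lie within the spatial grouping radius; the
        result must stay properly polyadic: support from 1 upward, a
        substantial multi-contact share, mean below the untruncated target."""
        c1, _, truth = pair
        sizes = np.array([c.n_posts for c in c1.connectors])
        lam = truth.spec.posts_per_site_lambda
        assert sizes.min() >= 1
        assert np.mean(sizes >= 2) > 0.3
        assert sizes.max() >= 3
        assert 1.0 < sizes.mean() <= 1 + lam + 0.1

    def test_most_twigs_host_one_or_two_synapses(self, pair):
        c1, _, truth = pair
        frac_12 = []
        for nid, gn in truth.generated.items():
            if not gn.twig_root_of or gn.skeleton.stage != "stage1":
                continue
            inputs = c1.inputs_by_node(nid)
            per_twig = {}
            for node, cnt in inputs.items():
                t = gn.twig_membership.get(node)
                if t is not None:
                    per_twig[t] = per_twig.get(t, 0) + cnt
            if per_twig:
                counts = np.array(list(per_twig.values()))
                frac_12.append(np.mean(counts <= 2))
        assert np.mean(frac_12) > 0.75
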