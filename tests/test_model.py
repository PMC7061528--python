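import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grn_landscape.model import (
    ACTIVATION,
    REPRESSION,
    GeneNode,
    NetworkSpec,
    ParameterSet,
    Regulation,
    binding_propensity,
    compile_network,
    default_network,
    load_network,
    network_from_dict,
    network_to_dict,
    save_network,
    synthesis_rate,
    unbinding_rate,
    validate,
)


class TestDefaultNetwork:
    def test_six_nodes(self, default_net):
        assert len(default_net.nodes) == 6

    def test_sixteen_regulations_seven_activations_nine_repressions(self, default_net):
        assert len(default_net.regulations) == 16
        signs = [r.sign for r in default_net.regulations]
        assert signs.count(ACTIVATION) == 7
        assert signs.count(REPRESSION) == 9

    def test_contains_mir200_zeb_repression(self, default_net):
        reg = default_net.regulation("miR200-|ZEB")
        assert reg.sign == REPRESSION

    def test_named_regulations_present(self, default_net):
        ids = {r.id for r in default_net.regulations}
        for expected in [
            "P53->miR200", "P53->miR145", "P53->MDM2", "miR145-|ZEB",
            "miR145-|OCT4", "miR145-|MDM2", "ZEB-|miR200", "ZEB-|miR145",
            "ZEB->ZEB", "OCT4->miR200", "MDM2-|P53", "miR200-|ZEB",
            "OCT4->OCT4", "P53->P53",
        ]:
            assert expected in ids

    def test_default_parameters_match_printed_values(self, default_net):
        p = default_net.params
        assert p.k == 1.0
        assert p.g0 == 50.0
        assert p.lambda_a == 8.0
        assert p.lambda_r == 0.5
        assert p.h_a == 2.0
        assert p.h_r == 1.875
        assert p.omega == 1000.0
        assert p.f == p.k * p.omega

    def test_unique_node_names(self, default_net):
        names = default_net.node_names()
        assert len(names) == len(set(names))


class TestValidate:
    def test_default_is_valid(self, default_net):
        assert validate(default_net) == []

    def test_unknown_target_named_in_violation(self, default_net):
        bad = NetworkSpec(
            default_net.nodes,
            default_net.regulations + [Regulation("P53", "X", REPRESSION)],
            default_net.params,
        )
        violations = validate(bad)
        assert len(violations) == 1
        assert "X" in violations[0]

    def test_bad_repression_fold(self, default_net):
        bad = NetworkSpec(
            default_net.nodes,
            [Regulation("P53", "MDM2", REPRESSION, lam=1.5)],
            default_net.params,
        )
        violations = validate(bad)
        assert len(violations) == 1
        assert "fold" in violations[0]

    def test_nonpositive_rates_flagged(self):
        net = NetworkSpec([GeneNode("A", g0=-1.0)], [], ParameterSet())
        assert any("g0" in v for v in validate(net))


class TestSynthesisRate:
    params = ParameterSet()

    def test_all_unbound_gives_g0(self):
        gene = GeneNode("G")
        sites = [Regulation("A", "G", ACTIVATION), Regulation("B", "G", REPRESSION)]
        assert synthesis_rate(gene, sites, [0, 0], self.params) == 50.0

    def test_one_activator_bound(self):
        gene = GeneNode("G")
        sites = [Regulation("A", "G", ACTIVATION), Regulation("B", "G", REPRESSION)]
        assert synthesis_rate(gene, sites, [1, 0], self.params) == 400.0

    def test_activator_plus_repressor_bound(self):
        gene = GeneNode("G")
        sites = [Regulation("A", "G", ACTIVATION), Regulation("B", "G", REPRESSION)]
        assert synthesis_rate(gene, sites, [1, 1], self.params) == 200.0

    def test_occupancy_length_mismatch_raises(self):
        gene = GeneNode("G")
        sites = [Regulation("A", "G", ACTIVATION)]
        with pytest.raises(ValueError):
            synthesis_rate(gene, sites, [1, 0], self.params)

    @given(occ=st.lists(st.booleans(), min_size=0, max_size=6))
    def test_bounded_by_extreme_folds(self, occ):
        gene = GeneNode("G")
        sites = [
            Regulation("A", "G", ACTIVATION if i % 2 == 0 else REPRESSION)
            for i in range(len(occ))
        ]
        n_act = sum(1 for i, o in enumerate(occ) if o and i % 2 == 0)
        n_rep = sum(1 for i, o in enumerate(occ) if o and i % 2 == 1)
        rate = synthesis_rate(gene, sites, occ, self.params)
        lo = 50.0 * self.params.lambda_r ** len(sites)
        hi = 50.0 * self.params.lambda_a ** len(sites)
        assert lo - 1e-12 <= rate <= hi + 1e-12
        assert rate == pytest.approx(
            50.0 * self.params.lambda_a ** n_act * self.params.lambda_r ** n_rep
        )


class TestBindingPropensity:
    params = ParameterSet()  # volume = 1: bare printed formulas

    def test_dimer_formula(self):
        reg = Regulation("A", "B", ACTIVATION, m=2, h=2.0)
        assert binding_propensity(reg, 3, self.params) == 6.0

    def test_tetramer_fewer_copies_than_order(self):
        reg = Regulation("A", "B", ACTIVATION, m=4, h=2.0)
        assert binding_propensity(reg, 3, self.params) == 0.0

    def test_tetramer_divisor_is_six(self):
        # printed tetramer combinatoric divisor is 6, not 4!
        reg = Regulation("A", "B", ACTIVATION, m=4, h=2.0)
        assert binding_propensity(reg, 4, self.params) == pytest.approx(8.0)

    def test_monomer_linear(self):
        reg = Regulation("A", "B", ACTIVATION, m=1, h=2.0)
        assert binding_propensity(reg, 7, self.params) == 14.0

    def test_negative_copy_number_raises(self):
        reg = Regulation("A", "B", ACTIVATION, m=1)
        with pytest.raises(ValueError):
            binding_propensity(reg, -1, self.params)

    def test_strength_scale_multiplies(self):
        reg = Regulation("A", "B", ACTIVATION, m=1, h=2.0, strength_scale=1.5)
        assert binding_propensity(reg, 10, self.params) == pytest.approx(30.0)

    def test_volume_normalization(self):
        reg = Regulation("A", "B", ACTIVATION, m=2, h=2.0)
        p = ParameterSet(volume=50.0)
        assert binding_propensity(reg, 3, p) == pytest.approx(6.0 / 50.0)
        reg1 = Regulation("A", "B", ACTIVATION, m=1, h=2.0)
        assert binding_propensity(reg1, 3, p) == pytest.approx(6.0)  # monomer unscaled

    @given(
        n=st.integers(min_value=0, max_value=500),
        m=st.sampled_from([1, 2, 4]),
    )
    @settings(max_examples=60)
    def test_nondecreasing_in_n_and_zero_below_m(self, n, m):
        reg = Regulation("A", "B", REPRESSION, m=m)
        a = binding_propensity(reg, n, self.params)
        b = binding_propensity(reg, n + 1, self.params)
        assert b >= a >= 0.0
        if n < m:
            assert a == 0.0


class TestUnbindingRate:
    def test_f_equals_k_omega(self):
        reg = Regulation("A", "B", ACTIVATION)
        assert unbinding_rate(reg, ParameterSet(k=1.0, omega=1000.0)) == 1000.0
        assert unbinding_rate(reg, ParameterSet(k=1.0, omega=1.0)) == 1.0
        assert unbinding_rate(reg, ParameterSet(k=2.0, omega=1000.0)) == 2000.0

    def test_per_regulation_override(self):
        reg = Regulation("A", "B", ACTIVATION, f=123.0)
        assert unbinding_rate(reg, ParameterSet()) == 123.0


class TestEquilibriumConstants:
    def test_xeq_values(self):
        p = ParameterSet()
        assert p.xeq_a == pytest.approx(500.0)
        assert p.xeq_r == pytest.approx(1000.0 / 1.875)


class TestConfigIO:
    def test_roundtrip(self, tmp_path, default_net):
        path = tmp_path / "net.yaml"
        save_network(default_net, str(path))
        loaded = load_network(str(path))
        assert network_to_dict(loaded) == network_to_dict(default_net)

    def test_invalid_config_raises(self, tmp_path, default_net):
        doc = network_to_dict(default_net)
        doc["regulations"][0]["target"] = "NOPE"
        path = tmp_path / "bad.yaml"
        import yaml

        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ValueError, match="NOPE"):
            load_network(str(path))

    def test_shipped_default_file_matches_builder(self):
        from grn_landscape.model import default_network_path

        loaded = load_network(default_network_path())
        assert network_to_dict(loaded) == network_to_dict(default_network())


class TestCompileNetwork:
    def test_shapes_and_grouping(self, default_compiled):
        c = default_compiled
        assert c.n_species == 6
        assert c.n_sites == 16
        assert c.tgt_ptr[-1] == 16
        # sites grouped by target cover each site exactly once
        assert sorted(c.tgt_sites.tolist()) == list(range(16))

    def test_with_strength_changes_exactly_one_site(self, default_net):
        c0 = compile_network(default_net)
        c1 = compile_network(default_net.with_strength("miR200-|ZEB", 1.5))
        diff = np.nonzero(c0.site_h != c1.site_h)[0]
        assert len(diff) == 1
        i = diff[0]
        assert c1.site_h[i] == pytest.approx(1.5 * c0.site_h[i])

    def test_with_strength_unknown_regulation(self, default_net):
        with pytest.raises(KeyError):
            default_net.with_strength("A->B", 2.0)
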