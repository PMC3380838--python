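"""Model-family construction: species/reaction counts, readouts,
conservation-law structure, and the deficiency-zero variants."""
import numpy as np
import pytest

from multiphos.crn import ConfigurationError, conservation_laws, network_summary
from multiphos.models import (ModelConfig, ParameterSet, build_network, readout,
                              species_order)


@pytest.mark.parametrize(
    "config, n_species, n_reactions",
    [
        (ModelConfig(1, "LR", scaffold=False), 2, 2),
        # 6 binding + 2 phos-on + 2 dephos-on + 2 dephos-off
        (ModelConfig(2, "LR", scaffold=True), 7, 12),
        # 6 binding + 3*2 kinase-on + 3*2 phosphatase-on + 3*2 phosphatase-off
        (ModelConfig(2, "MA", scaffold=True), 15, 24),
        # one kinase and one phosphatase Michaelis-Menten mechanism
        (ModelConfig(1, "MA", scaffold=False), 6, 6),
    ],
)
def test_species_and_reaction_counts(config, n_species, n_reactions):
    net = build_network(config)
    assert net.n_species == n_species
    assert len(net.reactions) == n_reactions


@pytest.mark.parametrize(
    "config, expected",
    [
        (ModelConfig(2, "LR", scaffold=False), {"S2"}),
        (ModelConfig(2, "LR", scaffold=True), {"S2", "S2_B"}),
        (ModelConfig(2, "MA", scaffold=True), {"S2", "S2_B", "P_S2", "P_S2_B"}),
        (ModelConfig(2, "MA", scaffold=True, dephos_location="off_scaffold_only"),
         {"S2", "S2_B", "P_S2"}),
    ],
)
def test_readout_species(config, expected):
    assert set(readout(config)) == expected


@pytest.mark.parametrize(
    "config, n_laws",
    [
        (ModelConfig(3, "LR", scaffold=True), 2),
        (ModelConfig(3, "LR", scaffold=False), 1),
        (ModelConfig(3, "MA", scaffold=True), 4),
        (ModelConfig(3, "MA", scaffold=False), 3),
    ],
)
def test_conservation_law_counts_per_family(config, n_laws):
    assert len(conservation_laws(build_network(config))) == n_laws


def test_lr_networks_have_no_enzyme_species_and_ma_always_do():
    for n in (1, 3):
        lr = build_network(ModelConfig(n, "LR", scaffold=True))
        assert "K" not in lr.species and "P" not in lr.species
        ma = build_network(ModelConfig(n, "MA", scaffold=False))
        assert "K" in ma.species and "P" in ma.species


def test_on_scaffold_only_requires_a_scaffold():
    cfg = ModelConfig(2, "LR", scaffold=False, phos_location="on_scaffold_only")
    with pytest.raises(ConfigurationError):
        build_network(cfg)


def test_all_on_scaffold_topology_is_deficiency_zero_weakly_reversible():
    cfg = ModelConfig(3, "LR", scaffold=True,
                      phos_location="on_scaffold_only",
                      dephos_location="on_scaffold_only")
    s = network_summary(build_network(cfg))
    assert s.deficiency == 0
    assert s.weakly_reversible


def test_all_off_scaffold_topology_is_deficiency_zero_weakly_reversible():
    cfg = ModelConfig(3, "LR", scaffold=True,
                      phos_location="off_scaffold_only",
                      dephos_location="off_scaffold_only")
    s = network_summary(build_network(cfg))
    assert s.deficiency == 0
    assert s.weakly_reversible


def test_parameter_set_validation_and_derived_constants():
    p = ParameterSet(n=1, a=np.array([2.0]), d=np.array([1.0]), kcat=np.array([3.0]),
                     ap=np.array([1.0]), dp=np.array([1.0]), kp=np.array([1.0]),
                     alpha=np.array([1.0, 2.0]), beta=np.array([0.5, 4.0]))
    assert p.km[0] == pytest.approx(2.0)
    assert p.kmp[0] == pytest.approx(2.0)
    assert np.allclose(p.kd, [0.5, 2.0])
    with pytest.raises(ConfigurationError):
        ParameterSet(n=1, b=np.array([-1.0]), c=np.array([1.0]))
    with pytest.raises(ConfigurationError):
        ParameterSet(n=2, b=np.array([1.0]), c=np.array([1.0, 1.0]))
    round_trip = ParameterSet.from_dict(p.to_dict())
    assert np.allclose(round_trip.alpha, p.alpha)


def test_rate_map_covers_every_network_rate_and_scales_with_ktot():
    cfg = ModelConfig(2, "LR", scaffold=True)
    p = ParameterSet(n=2, b=np.array([1.0, 2.0]), c=np.array([3.0, 4.0]),
                     alpha=np.ones(3), beta=np.ones(3), P_tot=2.0)
    net = build_network(cfg)
    rates = p.rate_map(cfg, ktot=10.0)
    assert set(rates) == set(net.rate_names)
    assert rates["bK0_on"] == pytest.approx(10.0)     # b_0 * K_tot
    assert rates["cP1_off"] == pytest.approx(6.0)     # c_1 * P_tot
    assert p.rate_map(cfg, ktot=20.0)["bK0_on"] == pytest.approx(20.0)


def test_species_order_matches_network_species():
    for cfg in (ModelConfig(2, "MA", scaffold=True), ModelConfig(4, "LR", scaffold=True)):
        assert list(build_network(cfg).species) == species_order(cfg)
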