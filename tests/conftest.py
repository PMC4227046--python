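import numpy as np
import pytest

from motophys import GroupSpec, ModelCell, TreeSpec


@pytest.fixture(scope="session")
def wt_imm_spec():
    return GroupSpec.from_tables("WT", "immediate")


@pytest.fixture(scope="session")
def wt_del_spec():
    return GroupSpec.from_tables("WT", "delayed")


def make_cell(**overrides) -> ModelCell:
    """A hand-specified immediate-firing cell with round numbers."""
    params = dict(
        id="test_cell", genotype="WT", pattern="immediate",
        V_rest=-65.0, G_in=33.0, V_th=-45.0, delta_V=20.0,
        rheobase_true=0.66, ap_amplitude=84.0, ap_halfwidth=1.7,
        ahp_amplitude=5.0, ahp_tau=42.0, gain_true=35.0,
        f_half_second_true=13.75, mmo_present=False,
        delay_scale=0.0, noise_sd=0.3, seed=42,
    )
    params.update(overrides)
    # keep the Ohmic relation consistent unless the caller broke it on purpose
    if "rheobase_true" not in overrides and (
            "G_in" in overrides or "V_th" in overrides or "delta_V" in overrides):
        params["delta_V"] = params["V_th"] - params["V_rest"]
        params["rheobase_true"] = params["G_in"] * params["delta_V"] / 1000.0
    return ModelCell(**params)


def make_delayed_cell(**overrides) -> ModelCell:
    params = dict(
        id="test_delayed", genotype="WT", pattern="delayed",
        V_rest=-64.0, G_in=52.0, V_th=-33.0, delta_V=31.0,
        rheobase_true=1.612, ap_amplitude=89.0, ap_halfwidth=1.4,
        ahp_amplitude=5.0, ahp_tau=27.0, gain_true=float("nan"),
        f_half_second_true=30.0, mmo_present=True,
        delay_scale=2.5, noise_sd=0.3, seed=43,
    )
    params.update(overrides)
    return ModelCell(**params)


@pytest.fixture
def simple_cell():
    return make_cell()


@pytest.fixture
def delayed_cell():
    return make_delayed_cell()


@pytest.fixture(scope="session")
def tiny_tree_spec():
    """Degenerate spec: 1 primary dendrite, 3 bifurcations, 700 um total."""
    from motophys.tables import Row
    return TreeSpec(
        n_primary=Row(1, 0, 1, 1, 1),
        n_branch_points=Row(3, 0, 3, 3, 1),
        total_length=Row(0.7, 0, 0.7, 0.7, 1),
        terminal_segment_length=Row(100, 0, 100, 100, 1),
        z_excursion=Row(0, 0, 0, 1, 1),
        p_plunge=0.0,
    )
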