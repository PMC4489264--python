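import numpy as np
import pandas as pd
import pytest

from cgnma import fixtures as fx
from cgnma.enm import InteractionMatrix, PotentialParams, contact_weight
from cgnma.model import ElasticNetworkModel
from cgnma.mutations import (CombinationModel, MutationSpec, bfactor_delta_profile,
                             calibrate, color_scale, combine_ddg, ddS_vib,
                             enumerate_mutations, heatmap_matrix, model_mutant,
                             top_stabilizing)
from cgnma.structure_io import Atom, Residue, Structure


# ------------------------------------------------------------- enumeration
def test_enumerate_all_expands_to_19(helix20):
    specs = enumerate_mutations("A:10:ALL", helix20)
    wt = helix20.chains["A"][9].aa_type
    assert len(specs) == 19
    assert wt not in {s.mut_aa for s in specs}


def test_enumerate_skips_self_mutation(helix20):
    # positions 10-12; one of them already carries the target type
    target = helix20.chains["A"][10].aa_type
    specs = enumerate_mutations(f"A:11-13:{target}", helix20)
    assert len(specs) == 2
    assert all(s.mut_aa == target for s in specs)


def test_enumerate_warns_on_absent_position(helix20):
    with pytest.warns(UserWarning, match="absent"):
        specs = enumerate_mutations("A:999:ALL", helix20)
    assert specs == []


def test_enumerate_rejects_bad_syntax(helix20):
    with pytest.raises(ValueError, match="A:ten:ALL"):
        enumerate_mutations("A:ten:ALL", helix20)
    with pytest.raises(ValueError, match="B1"):
        enumerate_mutations("A:3:B1", helix20)


def test_mutation_spec_rejects_self_and_nonstandard():
    with pytest.raises(ValueError):
        MutationSpec("A", 1, "A", "A")
    with pytest.raises(ValueError):
        MutationSpec("A", 1, "X", "G")


# ------------------------------------------------------------- mutant models
def test_sequence_swap_to_glycine_strips_sidechain(helix20):
    res_wt = helix20.chains["A"][4]
    spec = MutationSpec("A", 5, res_wt.aa_type, "G")
    mut = model_mutant(helix20, spec)
    res = mut.find("A", 5)
    assert res.name == "GLY"
    assert {a.name for a in res.atoms} <= {"N", "CA", "C", "O", "OXT"}
    # backbone/CA untouched
    np.testing.assert_array_equal(res.node_coord, res_wt.node_coord)


def test_sequence_swap_to_tryptophan_raises_contact_weight():
    # ALA and a neighbor 5 A apart: the larger W census must increase the
    # contact weight (numeric check of the monotone ramp-sum argument)
    ca = np.zeros(3)
    ala = Residue("A", 1, "", "ALA", [
        Atom("CA", "C", ca, False, 1), Atom("CB", "C", ca + [1.5, 0, 0], False, 1)])
    other = Residue("A", 5, "", "ALA", [
        Atom("CA", "C", [5.0, 0, 0], False, 1), Atom("CB", "C", [3.5, 0, 0], False, 1)])
    s = Structure(chains={"A": [ala, other]})
    im = InteractionMatrix.default()
    w_before = contact_weight(s.chains["A"][0], other, im)
    mut = model_mutant(s, MutationSpec("A", 1, "A", "W"))
    w_after = contact_weight(mut.chains["A"][0], other, im)
    assert w_after > w_before


def test_external_command_failure_skips(helix20):
    res = helix20.chains["A"][2]
    spec = MutationSpec("A", 3, res.aa_type, "G")
    with pytest.warns(UserWarning, match="skipped"):
        out = model_mutant(helix20, spec, mode="external_command",
                           command_template="false {input} {output}")
    assert out is None


# ------------------------------------------------------------- ddS and Eq
def test_dds_zero_on_identity_and_antisymmetric(helix20_results, dumbbell_results):
    m = helix20_results.modes
    assert ddS_vib(m, m) == 0.0
    other = dumbbell_results.modes
    # same trivial count but different size -> error
    with pytest.raises(ValueError):
        ddS_vib(m, other)


def test_dds_antisymmetry_on_real_mutation(helix20, helix20_results):
    spec = MutationSpec("A", 5, helix20.chains["A"][4].aa_type, "G")
    mut_res = ElasticNetworkModel(model_mutant(helix20, spec), preprocessed=True).fit()
    forward = ddS_vib(helix20_results.modes, mut_res.modes)
    backward = ddS_vib(mut_res.modes, helix20_results.modes)
    assert forward != 0.0
    assert forward == -backward


def test_anm_scores_every_mutation_neutral(helix20):
    """The sequence-agnostic control: uniform-spring networks cannot see
    mutations, so ddS_vib is exactly zero."""
    params = PotentialParams.anm()
    wt = ElasticNetworkModel(helix20, params=params).fit()
    for pos in (3, 8, 15):
        wt_aa = helix20.chains["A"][pos - 1].aa_type
        for target in ("G", "W"):
            if target == wt_aa:
                continue
            mut = model_mutant(helix20, MutationSpec("A", pos, wt_aa, target))
            mut_res = ElasticNetworkModel(mut, params=params, preprocessed=True).fit()
            assert ddS_vib(wt.modes, mut_res.modes) == 0.0


@pytest.mark.parametrize("dds,ddg_b,alpha,beta,expected", [
    (1.0, 1.0, -1.12, 0.38, -0.74),
    (0.0, 0.0, -1.12, 0.38, 0.0),
    (3.5, 2.0, 0.0, 1.0, 2.0),
])
def test_combine_ddg_affine(dds, ddg_b, alpha, beta, expected):
    assert combine_ddg(dds, ddg_b, CombinationModel(alpha, beta)) == pytest.approx(expected)


def test_combine_ddg_missing_external_term():
    assert combine_ddg(1.0, None) is None


# ------------------------------------------------------------- calibration
def test_calibration_recovers_true_coefficients():
    table = fx.make_ddg_table(alpha=-1.0, beta=0.4, n=300, sigma=0.1, seed=7)
    result = calibrate(table, n_bootstrap=1000, seed=7)
    assert result.alpha_median == pytest.approx(-1.0, abs=0.1)
    assert result.beta_median == pytest.approx(0.4, abs=0.1)
    assert result.rmse_median["all"] < 0.2


def test_calibration_exact_on_noise_free_table():
    table = fx.make_ddg_table(alpha=-1.3, beta=0.25, n=50, sigma=0.0, seed=3)
    result = calibrate(table, n_bootstrap=1)
    assert result.alpha_median == pytest.approx(-1.3, abs=1e-10)
    assert result.beta_median == pytest.approx(0.25, abs=1e-10)
    assert result.rmse_median["all"] == pytest.approx(0.0, abs=1e-10)


def test_calibration_handles_degenerate_column():
    table = fx.make_ddg_table(alpha=-0.8, beta=0.0, n=100, sigma=0.05, seed=5)
    table["ddG_B"] = 0.0
    with pytest.warns(UserWarning, match="rank-deficient"):
        result = calibrate(table, n_bootstrap=50, seed=1)
    assert result.n_resampled > 0
    assert result.alpha_median == pytest.approx(-0.8, abs=0.1)


def test_calibration_rejects_tiny_tables():
    with pytest.raises(ValueError):
        calibrate(pd.DataFrame({"ddG_A": [1], "ddG_B": [1], "ddG_exp": [1]}))


# ------------------------------------------------------------- dynamics maps
def test_bfactor_delta_profile_signs(helix20_results):
    b = helix20_results.bfactors
    np.testing.assert_array_equal(bfactor_delta_profile(b, b), np.zeros_like(b))
    other = b + 0.1
    np.testing.assert_allclose(bfactor_delta_profile(b, other),
                               -bfactor_delta_profile(other, b))
    with pytest.raises(ValueError):
        bfactor_delta_profile(b, b[:-1])


def test_large_to_small_mutation_gains_flexibility_locally(helix20, helix20_results):
    # removing a bulky side chain softens local contacts -> positive delta
    pos = 15
    wt_aa = helix20.chains["A"][pos - 1].aa_type
    assert wt_aa == "W"
    spec = MutationSpec("A", pos, wt_aa, "G")
    mut_res = ElasticNetworkModel(model_mutant(helix20, spec), preprocessed=True).fit()
    delta = bfactor_delta_profile(helix20_results.bfactors, mut_res.bfactors)
    site = pos - 1
    assert delta[site - 1:site + 2].max() > 0


@pytest.mark.parametrize("deltas", [
    np.array([[-1.0, 0.0, 1.0]]),
    np.array([[0.2, -0.4], [0.9, 0.0]]),
    np.array([[0.0, 0.0, 0.3]]),
])
def test_color_scale_matches_direct_formula(deltas):
    absd = np.abs(deltas)
    spread = 3.0 * absd.std()
    expected = min(absd.max(), spread) if spread > 0 else absd.max()
    assert color_scale(deltas) == pytest.approx(expected)


def test_color_scale_degenerate_cases():
    assert color_scale(np.zeros((2, 3))) == 0.0
    # equal nonzero deltas: std of |delta| is 0 -> fall back to max
    assert color_scale(np.full((2, 3), 0.7)) == pytest.approx(0.7)


# ------------------------------------------------------------- summaries
def _score(chain, pos, wt, mut, ddg):
    from cgnma.mutations import MutationScore
    return MutationScore(MutationSpec(chain, pos, wt, mut), ddS_vib=ddg,
                         ddG_B=None, ddG_combined=None)


def test_heatmap_requires_enough_coverage():
    scores = [_score("A", p, "A", m, float(p)) for p in (1, 2, 3) for m in "GWF"]
    grid = heatmap_matrix(scores)
    assert grid.shape == (3, 3)
    single_pos = [_score("A", 1, "A", m, 0.0) for m in "GWFYLIVMCDESTNQHKR"]
    assert heatmap_matrix(single_pos) is None


def test_top_stabilizing_sorted_and_capped():
    scores = [_score("A", p, "A", "G", float(30 - p)) for p in range(1, 31)]
    top = top_stabilizing(scores, 25)
    assert len(top) == 25
    assert top["ddG"].is_monotonic_increasing
    few = top_stabilizing(scores[:4], 25)
    assert len(few) == 4
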