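import itertools

import numpy as np
import pytest

from cgnma.ensembles import (ModeSelection, SamplingParams, amplitude_grid,
                             build_ensemble, enforce_cap, filter_min_separation,
                             generate_conformers, mode_trajectory,
                             order_trajectory, pairwise_rmsd_matrix, rmsd)


# ------------------------------------------------------------- grids
def test_single_mode_grid_counts():
    sel = ModeSelection([7])
    tuples = amplitude_grid(sel, SamplingParams(max_rmsd=1.0, min_rmsd=0.5), 16)
    # delta = 0.5*4 = 2, A = 4 -> {0, +-2, +-4}
    assert sorted(tuples) == [(-4.0,), (-2.0,), (0.0,), (2.0,), (4.0,)]


def test_two_mode_grid_matches_bruteforce_ball():
    n = 9
    sel = ModeSelection([7, 8])
    params = SamplingParams(max_rmsd=0.5, min_rmsd=0.5)
    tuples = set(amplitude_grid(sel, params, n))
    # oracle: brute-force enumeration of the delta-lattice inside the ball
    delta = 0.5 * 3
    expected = {
        (a, b)
        for a, b in itertools.product([-delta, 0.0, delta], repeat=2)
        if np.hypot(a, b) <= delta + 1e-9
    }
    assert tuples == expected
    assert len(tuples) == 5


def test_grid_respects_max_rmsd():
    n = 25
    sel = ModeSelection([7, 8, 9])
    params = SamplingParams(max_rmsd=2.0, min_rmsd=0.7)
    for tup in amplitude_grid(sel, params, n):
        assert np.sqrt(sum(a * a for a in tup)) / np.sqrt(n) <= 2.0 + 1e-9


def test_grid_contains_input_once():
    tuples = amplitude_grid(ModeSelection([7, 8]),
                            SamplingParams(max_rmsd=2.0, min_rmsd=0.5), 16)
    assert sum(1 for t in tuples if all(a == 0 for a in t)) == 1


# ------------------------------------------------------------- cap
def test_cap_leaves_small_grids_alone():
    sel = ModeSelection([7])
    params = SamplingParams(max_rmsd=1.0, min_rmsd=0.5)
    tuples, eff = enforce_cap(sel, params, 16)
    assert eff == params.min_rmsd
    assert len(tuples) == 5


def test_cap_shrinks_overflowing_grid():
    sel = ModeSelection([7, 8, 9])
    params = SamplingParams(max_rmsd=10.0, min_rmsd=1.0)  # 21^3 raw points
    tuples, eff = enforce_cap(sel, params, 20)
    assert len(tuples) <= params.cap
    assert eff > params.min_rmsd


def test_cap_one_keeps_only_input():
    sel = ModeSelection([7, 8])
    params = SamplingParams(max_rmsd=2.0, min_rmsd=0.5, cap=1)
    tuples, _ = enforce_cap(sel, params, 16)
    assert tuples == [(0.0, 0.0)]


def test_min_separation_filter_is_noop_on_lattice():
    tuples = amplitude_grid(ModeSelection([7, 8]),
                            SamplingParams(max_rmsd=2.0, min_rmsd=0.5), 16)
    delta = 0.5 * 4
    assert len(filter_min_separation(tuples, delta)) == len(tuples)


def test_min_separation_filter_drops_close_tuples():
    tuples = [(0.0,), (0.4,), (1.0,)]
    kept = filter_min_separation(tuples, 1.0)
    assert kept == [(0.0,), (1.0,)]


# ------------------------------------------------------------- conformers
def test_zero_tuple_reproduces_input(helix20_results):
    model = helix20_results.model.coarse
    confs = generate_conformers(model, helix20_results.modes, ModeSelection([7]),
                                [(0.0,)])
    np.testing.assert_array_equal(confs[0].coords, model.nodes)
    assert confs[0].rmsd_from_input == 0.0


def test_single_mode_rmsd_closed_form(helix20_results):
    model = helix20_results.model.coarse
    a = 3.7
    confs = generate_conformers(model, helix20_results.modes, ModeSelection([8]),
                                [(a,)])
    assert confs[0].rmsd_from_input == pytest.approx(a / np.sqrt(model.n_nodes),
                                                     abs=1e-8)


def test_multi_mode_rmsd_matches_coordinates(helix20_results, rng):
    """Closed-form sqrt(sum a^2 / N) equals the coordinate RMSD because the
    eigenvectors are orthonormal."""
    model = helix20_results.model.coarse
    sel = ModeSelection([7, 8, 9])
    tuples = [tuple(rng.normal(scale=2.0, size=3)) for _ in range(100)]
    confs = generate_conformers(model, helix20_results.modes, sel, tuples)
    for conf in confs:
        closed = np.sqrt(sum(a * a for a in conf.amplitudes) / model.n_nodes)
        by_coords = rmsd(model.nodes, conf.coords)
        assert by_coords == pytest.approx(closed, abs=1e-8)
        assert conf.rmsd_from_input == pytest.approx(closed, abs=1e-8)


def test_selection_rejects_trivial_modes(helix20_results):
    with pytest.raises(ValueError):
        ModeSelection([6, 7])
    with pytest.raises(ValueError):
        ModeSelection([7, 7])
    sel = ModeSelection([3 * 20 + 1])
    with pytest.raises(ValueError):
        sel.validate_against(helix20_results.modes)


# ------------------------------------------------------------- rmsd
def test_rmsd_basics(rng):
    x = rng.normal(size=(10, 3))
    assert rmsd(x, x) == 0.0
    assert rmsd(x, x + [1.0, 0, 0]) == pytest.approx(1.0)
    y = rng.normal(size=(10, 3))
    brute = np.sqrt(np.mean([np.sum((xi - yi) ** 2) for xi, yi in zip(x, y)]))
    assert rmsd(x, y) == pytest.approx(brute)
    with pytest.raises(ValueError):
        rmsd(x, y[:-1])


# ------------------------------------------------------------- ordering
def brute_force_best_path(d):
    n = d.shape[0]
    best, best_total = None, np.inf
    for perm in itertools.permutations(range(n)):
        total = sum(d[perm[i], perm[i + 1]] for i in range(n - 1))
        if total < best_total:
            best, best_total = list(perm), total
    return best, best_total


def path_total(d, path):
    return sum(d[path[i], path[i + 1]] for i in range(len(path) - 1))


def test_ordering_three_points_on_line():
    pts = np.array([[0.0], [1.0], [5.0]])
    d = np.abs(pts - pts.T)
    path = order_trajectory(d)
    assert path in ([0, 1, 2], [2, 1, 0])
    assert path_total(d, path) == pytest.approx(5.0)


def test_ordering_two_conformers():
    d = np.array([[0.0, 2.5], [2.5, 0.0]])
    path = order_trajectory(d)
    assert sorted(path) == [0, 1]
    assert path_total(d, path) == pytest.approx(2.5)


def test_ordering_beats_single_start_and_matches_bruteforce(rng):
    for n in (4, 5, 6, 7, 8):
        pts = rng.normal(size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        multi = order_trajectory(d)
        total_multi = path_total(d, multi)
        _, optimum = brute_force_best_path(d)
        # multi-start greedy: never better than the exact optimum, never
        # worse than greedy from index 0
        greedy0 = path_total(d, _greedy_from(d, 0))
        assert optimum <= total_multi + 1e-12
        assert total_multi <= greedy0 + 1e-12


def _greedy_from(d, start):
    n = d.shape[0]
    visited = {start}
    path = [start]
    while len(path) < n:
        cur = path[-1]
        nxt = min((j for j in range(n) if j not in visited), key=lambda j: d[cur, j])
        path.append(nxt)
        visited.add(nxt)
    return path


def test_ordering_matches_optimum_on_fixture_ensemble(helix20_results):
    ens = helix20_results.sample_ensemble([7, 8], max_rmsd=1.0, min_rmsd=0.8)
    assert 2 <= len(ens) <= 8
    _, optimum = brute_force_best_path(ens.pairwise_rmsd)
    assert path_total(ens.pairwise_rmsd, ens.ordering) == pytest.approx(optimum)


# ------------------------------------------------------------- trajectories
def test_mode_trajectory_frames(helix20_results):
    model = helix20_results.model.coarse
    a = 5.0
    frames = mode_trajectory(model, helix20_results.modes, 7, a, n_frames=8)
    np.testing.assert_array_equal(frames[0], model.nodes)
    excursions = [rmsd(model.nodes, f) for f in frames]
    assert max(excursions) == pytest.approx(a / np.sqrt(model.n_nodes), rel=1e-6)
    with pytest.raises(ValueError):
        mode_trajectory(model, helix20_results.modes, 3, a)


def test_twenty_mode_trajectories_emitted(tmp_path, helix20_results):
    from cgnma.ensembles import emit_mode_trajectories
    paths = emit_mode_trajectories(helix20_results.model.coarse,
                                   helix20_results.modes, 2.0, 6, tmp_path)
    assert len(paths) == 20
    assert all(p.exists() for p in paths)


# ------------------------------------------------------------- pipeline
def test_ensemble_respects_all_constraints(helix20_results):
    ens = helix20_results.sample_ensemble([7, 8, 9], max_rmsd=10.0, min_rmsd=1.0)
    assert len(ens) <= 350
    assert ens.effective_min_rmsd > 1.0
    for conf in ens.conformers:
        assert conf.rmsd_from_input <= 10.0 + 1e-9
    off = ens.pairwise_rmsd[np.triu_indices(len(ens), 1)]
    assert off.min() >= ens.effective_min_rmsd - 1e-8
    assert sorted(ens.ordering) == list(range(len(ens)))


def test_ensemble_outputs_written(tmp_path, helix20_results):
    ens = helix20_results.sample_ensemble([7, 8], max_rmsd=1.0, min_rmsd=0.5)
    ens.write_outputs(tmp_path, n_frames=4, modes=helix20_results.modes)
    assert (tmp_path / "trajectory.pdb").exists()
    assert (tmp_path / "amplitudes.csv").exists()
    assert (tmp_path / "pairwise_rmsd.txt").exists()
    assert len(list(tmp_path.glob("mode_*.pdb"))) == 20
    assert len(list(tmp_path.glob("conformer_*.pdb"))) == len(ens)
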