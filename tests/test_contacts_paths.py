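import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from metacal import contacts_paths as cp
from metacal import synthetic as syn
from metacal.errors import (
    DimensionError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidPathError,
)


class TestSwitchingValue:
    @pytest.mark.parametrize(
        "r, r0, expected",
        [
            (0.0, 4.5, 1.0),                 # perfect contact
            (4.5, 4.5, 0.6),                 # removable singularity at r = r0
            (9.0, 4.5, 63.0 / 1023.0),       # x = 2 closed form
            (13.0, 6.5, 63.0 / 1023.0),      # same ratio, sidechain cutoff
        ],
    )
    def test_closed_form_values(self, r, r0, expected):
        assert cp.switching_value(r, r0) == pytest.approx(expected, abs=1e-12)

    def test_limit_at_r0_matches_two_sided_evaluation(self):
        # L'Hopital oracle: approach r0 from both sides
        r0 = 4.5
        lo = cp.switching_value(r0 * (1 - 1e-8), r0)
        hi = cp.switching_value(r0 * (1 + 1e-8), r0)
        assert lo == pytest.approx(0.6, abs=1e-6)
        assert hi == pytest.approx(0.6, abs=1e-6)
        assert cp.switching_value(r0, r0) == pytest.approx(0.6, abs=1e-14)

    @settings(max_examples=100, derandomize=True)
    @given(
        r=st.floats(0.0, 100.0),
        r0=st.floats(0.1, 20.0),
        dr=st.floats(1e-6, 10.0),
    )
    def test_bounded_and_decreasing(self, r, r0, dr):
        s1 = cp.switching_value(r, r0)
        s2 = cp.switching_value(r + dr, r0)
        assert 0.0 <= s2 <= s1 <= 1.0
        if r >= 0.3 * r0:  # strict once the decrease is representable
            assert s2 < s1

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            cp.switching_value(1.0, 0.0)
        with pytest.raises(Exception):
            cp.switching_value(-1.0, 4.5)


class TestContactSelection:
    def test_threshold_masks(self):
        sa = np.array([0.9, 0.5, 0.1])
        si = np.array([0.1, 0.5, 0.9])
        mask = cp.select_activation_contacts(sa, si, threshold=0.65)
        # formed on activation, unchanged, broken on activation
        assert mask.tolist() == [True, False, True]

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            cp.select_activation_contacts([0.9, 0.1], [0.1], 0.65)

    def test_selection_invariants(self):
        with pytest.raises(InvalidParameterError):
            cp.ContactSelection(
                contacts=[cp.Contact("A", "B")], threshold=1.5
            )
        with pytest.raises(InvalidParameterError):
            cp.Contact("A", "B", r0=-1.0)
        with pytest.raises(InvalidParameterError):
            cp.ContactSelection(
                contacts=[cp.Contact("A", "B"), cp.Contact("A", "B")],
            )


class TestContactMapDistance:
    def test_examples(self):
        assert cp.contact_map_distance([0.3, 0.7], [0.3, 0.7]) == 0.0
        assert cp.contact_map_distance([1.0], [0.0]) == 1.0
        assert cp.contact_map_distance([0.9, 0.1], [0.1, 0.9]) == pytest.approx(
            np.sqrt(1.28), abs=1e-12
        )

    def test_dimension_error(self):
        with pytest.raises(DimensionError):
            cp.contact_map_distance([0.1, 0.2], [0.1])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.random((3, 6))
        dab = cp.contact_map_distance(a, b)
        dbc = cp.contact_map_distance(b, c)
        dac = cp.contact_map_distance(a, c)
        assert dac <= dab + dbc + 1e-12


class TestEndpointsAndDensity:
    def test_collinear_extremes(self):
        frames = np.array([[0.0], [0.1], [0.3]])
        assert cp.find_endpoints(frames) == (0, 2)
        assert cp.find_endpoints(frames[:2]) == (0, 1)

    def test_matches_bruteforce_on_random_cloud(self, rng):
        frames = rng.random((20, 4))
        D = cdist(frames, frames)
        best = max(
            ((i, j) for i in range(20) for j in range(i + 1, 20)),
            key=lambda p: (D[p], -p[0], -p[1]),
        )
        assert cp.find_endpoints(frames) == best

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            cp.find_endpoints(np.array([[0.5]]))

    def test_density_examples(self):
        frames = np.array([[0.0], [0.0], [0.0], [0.0], [0.9]])
        rho = cp.local_density(frames, radius=0.1)
        assert rho.tolist() == [3, 3, 3, 3, 0]

    def test_density_matches_bruteforce(self, rng):
        frames = rng.random((50, 3))
        radius = 0.4
        rho = cp.local_density(frames, radius=radius)
        D = cdist(frames, frames)
        expected = ((D <= radius).sum(axis=1) - 1)
        assert np.array_equal(rho, expected)

    def test_density_invalid_radius(self):
        with pytest.raises(InvalidParameterError):
            cp.local_density(np.zeros((3, 1)), radius=0.0)


class TestPathObjective:
    def test_equal_edges_zero_variance(self):
        frames = np.array([[0.0], [1.0], [2.0], [3.0]])
        D = cdist(frames, frames)
        rho = np.zeros(4)
        terms = cp.path_objective_terms([0, 1, 2, 3], D, rho)
        assert terms["variance"] == 0.0
        assert cp.path_objective([0, 1, 2, 3], D, rho, k=1.0) == 0.0

    def test_homogeneity_of_terms(self, rng):
        frames = rng.random((8, 3))
        D = cdist(frames, frames)
        rho = cp.local_density(frames, radius=0.5).astype(float)
        t1 = cp.path_objective_terms([0, 3, 5, 7], D, rho)
        t2 = cp.path_objective_terms([0, 3, 5, 7], 2 * D, rho)
        assert t2["length"] == pytest.approx(2 * t1["length"])
        assert t2["variance"] == pytest.approx(4 * t1["variance"])
        assert t2["density"] == t1["density"]

    def test_matches_term_by_term_oracle(self, rng):
        frames = rng.random((10, 2))
        D = cdist(frames, frames)
        rho = cp.local_density(frames, radius=0.5).astype(float)
        idx = [0, 4, 2, 9]
        d = np.array([D[a, b] for a, b in zip(idx[:-1], idx[1:])])
        var = 0.5 * np.sum((d - d.mean()) ** 2)
        k = 0.7
        expected_ratio = k * var * d.sum() / rho[idx].sum()
        assert cp.path_objective(idx, D, rho, k=k) == pytest.approx(
            expected_ratio, rel=1e-12
        )
        expected_sum = k * var + d.sum() - rho[idx].sum()
        assert cp.path_objective(
            idx, D, rho, k=k, form="composite"
        ) == pytest.approx(expected_sum, rel=1e-12)

    def test_repeated_node_rejected(self):
        with pytest.raises(InvalidPathError):
            cp.path_objective([0, 1, 1], np.zeros((3, 3)), np.zeros(3), 1.0)


class TestAnnealPath:
    def _exhaustive_best(self, frames, n_nodes, k_final):
        D = cdist(frames, frames)
        rho = cp.local_density(frames).astype(float)
        j0, jN = cp.find_endpoints(frames)
        pool = [i for i in range(len(frames)) if i not in (j0, jN)]
        best = np.inf
        for interior in itertools.permutations(pool, n_nodes - 2):
            w = cp.path_objective([j0, *interior, jN], D, rho, k=k_final)
            best = min(best, w)
        return best

    def test_attains_exhaustive_optimum(self, rng):
        frames = rng.random((12, 5))
        cfg = cp.AnnealConfig(n_nodes=4, seed=0)
        best = self._exhaustive_best(frames, 4, cfg.k_schedule[-1])
        path = cp.anneal_path(frames, cfg)
        assert path.objective == pytest.approx(best, rel=1e-9)

    def test_high_success_rate_over_seeds(self, rng):
        frames = rng.random((13, 4))
        k_final = cp.AnnealConfig().k_schedule[-1]
        best = self._exhaustive_best(frames, 5, k_final)
        hits = sum(
            np.isclose(
                cp.anneal_path(frames, cp.AnnealConfig(n_nodes=5, seed=s)).objective,
                best, rtol=1e-9,
            )
            for s in range(20)
        )
        assert hits >= 19  # >= 95% of 20 seeded runs

    def test_deterministic_given_seed(self, rng):
        frames = rng.random((30, 4))
        cfg = cp.AnnealConfig(n_nodes=5, seed=3)
        p1 = cp.anneal_path(frames, cfg)
        p2 = cp.anneal_path(frames, cfg)
        assert p1.node_indices == p2.node_indices
        assert p1.objective == p2.objective

    def test_endpoints_pinned(self, rng):
        frames = rng.random((25, 3))
        path = cp.anneal_path(frames, cp.AnnealConfig(n_nodes=5, seed=0))
        j0, jN = cp.find_endpoints(frames)
        assert path.node_indices[0] == j0
        assert path.node_indices[-1] == jN

    def test_chain_identity_selection(self):
        # frames already on an equally spaced 1-D chain: identity is optimal
        frames = np.linspace(0, 1, 6)[:, None]
        path = cp.anneal_path(frames, cp.AnnealConfig(n_nodes=6, seed=0,
                                                      n_iters=50))
        assert path.edge_lengths.var() == pytest.approx(0.0, abs=1e-24)

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            cp.AnnealConfig(n_nodes=2)
        with pytest.raises(InvalidParameterError):
            cp.AnnealConfig(k_schedule=(0.1, 0.2))
        with pytest.raises(InsufficientDataError):
            cp.anneal_path(np.zeros((3, 2)), cp.AnnealConfig(n_nodes=4))


class TestPathCVs:
    def test_dominant_node(self):
        # third node (k = 3 in 1-based numbering) at the probe, all others
        # >= 10/lambda away in distinct directions
        lam = 2.0
        nodes = np.zeros((5, 6))
        for j, far in enumerate([0, 1, 3, 4]):
            nodes[far, j] = 10.0 / lam + 1.0 + j
        R = np.zeros(6)
        S, Z = cp.path_cvs(R, cp.PathModel(nodes=nodes, lam=lam))
        assert S == pytest.approx(3.0, abs=1e-3)
        assert Z == pytest.approx(0.0, abs=1e-3)

    def test_two_node_closed_form(self):
        lam = 2.0
        d = 0.8
        nodes = np.array([[d, 0.0], [0.0, d]])  # R at origin is d from both
        S, Z = cp.path_cvs(np.zeros(2), cp.PathModel(nodes=nodes, lam=lam))
        assert S == pytest.approx(1.5, rel=1e-12)
        assert Z == pytest.approx(d - np.log(2.0) / lam, rel=1e-12)

    def test_storage_order_invariance(self, rng):
        # permuting the frame storage order (node order kept) leaves S, Z as-is
        frames = rng.random((40, 5))
        cfg = cp.AnnealConfig(n_nodes=5, seed=1)
        path = cp.anneal_path(frames, cfg)
        perm = rng.permutation(40)
        inv = np.argsort(perm)
        path_perm = cp.PathModel(
            nodes=frames[perm][[int(inv[i]) for i in path.node_indices]],
            lam=path.lam,
        )
        probe = rng.random(5)
        assert cp.path_cvs(probe, path) == cp.path_cvs(probe, path_perm)

    def test_s_in_range_and_table_consistency(self, rng):
        frames = rng.random((30, 4))
        path = cp.anneal_path(frames, cp.AnnealConfig(n_nodes=6, seed=0))
        table = cp.path_cvs_table(frames, path)
        assert np.all(table[:, 0] >= 1.0) and np.all(table[:, 0] <= 6.0)
        S0, Z0 = cp.path_cvs(frames[17], path)
        assert table[17, 0] == pytest.approx(S0, rel=1e-12)
        assert table[17, 1] == pytest.approx(Z0, rel=1e-12)

    def test_auto_lambda(self):
        nodes = np.array([[0.0], [1.0], [2.0]])
        path = cp.PathModel.with_auto_lambda(nodes)
        assert path.lam == pytest.approx(2.3 / 1.0)

    def test_dimension_error(self):
        path = cp.PathModel(nodes=np.zeros((3, 4)))
        with pytest.raises(DimensionError):
            cp.path_cvs(np.zeros(5), path)


def test_synthetic_transition_path_has_small_edge_variance():
    """N=10 path through the curved synthetic transition has near-equal edges."""
    frames = syn.curved_contact_trajectory(seed=0)
    sep = cp.contact_map_distance(*[frames[i] for i in cp.find_endpoints(frames)])
    assert sep == pytest.approx(2.0, abs=0.3)
    path = cp.anneal_path(frames, cp.AnnealConfig(n_nodes=10, seed=0))
    assert path.edge_lengths.var() < 0.05
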