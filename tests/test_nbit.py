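import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metacal import nbit
from metacal import synthetic as syn
from metacal.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidBlockError,
    NormalizationError,
)

BIT_EDGES = np.array([-0.5, 0.5, 1.5])


def _bit_frame(**cols):
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()})


def _all_pairs():
    """Every (x, y) combination once: an exactly independent uniform joint."""
    xy = np.array(list(itertools.product([0, 1], repeat=2)) * 64)
    return xy[:, 0], xy[:, 1]


class TestEntropy:
    def test_uniform_four_cells(self):
        h = nbit.HistogramND(edges=(np.arange(5.0),), probs=np.full(4, 0.25))
        assert nbit.entropy(h) == pytest.approx(np.log(4), rel=1e-14)
        assert nbit.entropy(h, bits=True) == pytest.approx(2.0, rel=1e-14)

    def test_point_mass(self):
        assert nbit.entropy(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_direct_sum(self):
        assert nbit.entropy(np.array([0.5, 0.25, 0.25]), bits=True) == \
            pytest.approx(1.5, rel=1e-14)

    def test_unnormalized_rejected(self):
        with pytest.raises(NormalizationError):
            nbit.entropy(np.array([0.5, 0.2]))

    def test_bounded_by_occupied_cells(self, rng):
        p = rng.random(20)
        p /= p.sum()
        assert nbit.entropy(p) <= np.log(np.count_nonzero(p)) + 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.0, 1.0))
    def test_concavity_under_mixing(self, seed, alpha):
        rng = np.random.default_rng(seed)
        p = rng.random(8); p /= p.sum()
        q = rng.random(8); q /= q.sum()
        mixed = nbit.entropy(alpha * p + (1 - alpha) * q)
        assert mixed >= alpha * nbit.entropy(p) + (1 - alpha) * nbit.entropy(q) - 1e-12


class TestMutualInformation:
    def test_independent_bits_zero(self):
        x, y = _all_pairs()
        mi = nbit.mutual_information(
            _bit_frame(x=x, y=y), None, "x", "y",
            edges={"x": BIT_EDGES, "y": BIT_EDGES},
        )
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_identical_bits_one_bit(self):
        x, _ = _all_pairs()
        mi = nbit.mutual_information(
            _bit_frame(x=x, y=x.copy()), None, "x", "y",
            edges={"x": BIT_EDGES, "y": BIT_EDGES}, bits=True,
        )
        assert mi == pytest.approx(1.0, rel=1e-12)

    def test_bivariate_gaussian_closed_form(self):
        """MI of a rho=0.5 Gaussian: -1/2 ln(1 - rho^2), 64x64 bins, 1e6 draws."""
        rho = 0.5
        rng = np.random.default_rng(42)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=1_000_000)
        df = pd.DataFrame(z, columns=["x", "y"])
        edges = nbit.make_edges(df, ["x", "y"], bins=64)
        mi = nbit.mutual_information(df, None, "x", "y", edges=edges)
        assert mi == pytest.approx(-0.5 * np.log(1 - rho**2), abs=0.01)

    def test_overlapping_blocks_rejected(self):
        x, y = _all_pairs()
        with pytest.raises(InvalidBlockError):
            nbit.mutual_information(
                _bit_frame(x=x, y=y), None, ("x", "y"), "y",
                edges={"x": BIT_EDGES, "y": BIT_EDGES},
            )


class TestConditionalMI:
    def test_independent_conditioner_reduces_to_mi(self, rng):
        n = 4000
        x = rng.integers(0, 2, n)
        y = (x + (rng.random(n) < 0.2)) % 2
        z = rng.integers(0, 2, n)  # independent of (x, y)
        df = _bit_frame(x=x, y=y, z=z)
        edges = {c: BIT_EDGES for c in "xyz"}
        mi = nbit.mutual_information(df, None, "x", "y", edges=edges)
        cmi = nbit.conditional_mi(df, None, "x", "y", "z", edges=edges)
        assert cmi == pytest.approx(mi, abs=0.01)

    def test_copy_triple_zero(self):
        x, _ = _all_pairs()
        df = _bit_frame(x=x, y=x.copy(), z=x.copy())
        cmi = nbit.conditional_mi(df, None, "x", "y", "z",
                                  edges={c: BIT_EDGES for c in "xyz"})
        assert cmi == pytest.approx(0.0, abs=1e-12)

    def test_xor_triple_one_bit(self):
        x, y = _all_pairs()
        df = _bit_frame(x=x, y=y, z=x ^ y)
        cmi = nbit.conditional_mi(df, None, "x", "y", "z",
                                  edges={c: BIT_EDGES for c in "xyz"},
                                  bits=True)
        assert cmi == pytest.approx(1.0, rel=1e-12)


class TestCoInformation:
    def test_copy_triple_plus_one_bit(self):
        x, _ = _all_pairs()
        df = _bit_frame(x=x, y=x.copy(), z=x.copy())
        ci = nbit.co_information(df, None, "x", "y", "z",
                                 edges={c: BIT_EDGES for c in "xyz"}, bits=True)
        assert ci == pytest.approx(1.0, rel=1e-12)

    def test_xor_triple_minus_one_bit(self):
        x, y = _all_pairs()
        df = _bit_frame(x=x, y=y, z=x ^ y)
        ci = nbit.co_information(df, None, "x", "y", "z",
                                 edges={c: BIT_EDGES for c in "xyz"}, bits=True)
        assert ci == pytest.approx(-1.0, rel=1e-12)

    def test_independent_z_gives_zero(self):
        x, y = _all_pairs()
        z = np.tile([0, 1], x.size // 2)
        # z cycles independently of the (x, y) block structure
        df = _bit_frame(x=x, y=y, z=z)
        ci = nbit.co_information(df, None, "x", "y", "z",
                                 edges={c: BIT_EDGES for c in "xyz"})
        assert ci == pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_route_agreement_and_permutation_symmetry(self, seed):
        """Eq-8 and Eq-9 routes agree and CI is symmetric in (X, Y, Z)."""
        rng = np.random.default_rng(seed)
        n = 500
        df = pd.DataFrame({
            "x": rng.integers(0, 3, n).astype(float),
            "y": rng.integers(0, 3, n).astype(float),
            "z": (rng.integers(0, 3, n) + rng.integers(0, 2, n)).astype(float),
        })
        w = rng.random(n) + 0.1
        edges = {c: np.arange(-0.5, 5.0) for c in "xyz"}
        ci8 = nbit.co_information(df, w, "x", "y", "z", edges=edges, route="eq8")
        ci9 = nbit.co_information(df, w, "x", "y", "z", edges=edges, route="eq9")
        assert ci8 == pytest.approx(ci9, abs=1e-10)
        vals = [
            nbit.co_information(df, w, a, b, c, edges=edges)
            for a, b, c in itertools.permutations("xyz")
        ]
        assert np.ptp(vals) < 1e-10

    def test_uniform_weights_equal_unweighted(self, rng):
        df = pd.DataFrame(rng.integers(0, 4, (300, 3)).astype(float),
                          columns=["x", "y", "z"])
        edges = {c: np.arange(-0.5, 4.5) for c in "xyz"}
        ci_none = nbit.co_information(df, None, "x", "y", "z", edges=edges)
        ci_unif = nbit.co_information(df, np.full(300, 2.5), "x", "y", "z",
                                      edges=edges)
        assert ci_none == ci_unif


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(5)
    latent = np.cumsum(rng.standard_normal(20_000)) * 0.05
    feats, roles = syn.planted_information_field(
        latent, n_redundant=3, n_synergistic=2, n_noise=3,
        noise_sigma=0.3, seed=5,
    )
    return feats, roles


class TestResidueScan:
    def test_driven_residues_outrank_noise(self, planted):
        feats, roles = planted
        blocks = [(n, (f"{n}_x", f"{n}_y", f"{n}_z")) for n in sorted(roles)]
        out = nbit.residue_scan(feats, None, ("PC1", "PC2"), ("act1", "act2"),
                                blocks, bins=8)
        out["role"] = out["residue"].map(roles)
        worst_redundant = out.loc[out.role == "redundant", "ci"].abs().min()
        best_noise = out.loc[out.role == "noise", "ci"].abs().max()
        assert worst_redundant > best_noise

    def test_processing_order_invariance(self, planted):
        feats, roles = planted
        blocks = [(n, (f"{n}_x", f"{n}_y", f"{n}_z")) for n in sorted(roles)]
        a = nbit.residue_scan(feats, None, ("PC1", "PC2"), ("act1", "act2"),
                              blocks, bins=6)
        b = nbit.residue_scan(feats, None, ("PC1", "PC2"), ("act1", "act2"),
                              blocks[::-1], bins=6)
        merged = a.merge(b, on="residue", suffixes=("_a", "_b"))
        assert np.array_equal(merged["ci_a"].to_numpy(),
                              merged["ci_b"].to_numpy())

    def test_pure_noise_ci_near_zero(self, rng):
        # Miller-Madow cancels the plug-in bias of the high-dimensional joints
        n = 50_000
        feats = pd.DataFrame(rng.standard_normal((n, 7)),
                             columns=["PC1", "PC2", "act1", "act2",
                                      "r_x", "r_y", "r_z"])
        out = nbit.residue_scan(feats, None, ("PC1", "PC2"), ("act1", "act2"),
                                [("r", ("r_x", "r_y", "r_z"))], bins=4,
                                miller_madow=True)
        assert abs(out["ci"].iloc[0]) < 0.02

    def test_normalization_column(self, planted):
        feats, roles = planted
        blocks = [(n, (f"{n}_x", f"{n}_y", f"{n}_z")) for n in sorted(roles)]
        out = nbit.residue_scan(feats, None, ("PC1", "PC2"), ("act1", "act2"),
                                blocks, bins=6)
        assert out["ci_normalized"].abs().max() == pytest.approx(1.0)

    def test_inconsistent_edges_rejected(self, planted):
        feats, roles = planted
        names = sorted(roles)[:2]
        blocks = [(n, (f"{n}_x", f"{n}_y", f"{n}_z")) for n in names]
        edges = nbit.make_edges(
            feats, ["PC1", "PC2", "act1", "act2"]
            + [c for _, cols in blocks for c in cols], bins=6,
        )
        edges[f"{names[0]}_x"] = edges[f"{names[0]}_x"] + 0.1  # break sharing
        with pytest.raises(InvalidBlockError):
            nbit.residue_scan(feats, None, ("PC1", "PC2"), ("act1", "act2"),
                              blocks, edges=edges)


class TestPocketPCA:
    def test_line_captures_all_variance(self):
        t = np.linspace(-1, 1, 50)
        coords = np.column_stack([t, 2 * t, -t])
        _, _, evr = nbit.pocket_pca(coords)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_gaussian_split(self, rng):
        coords = rng.standard_normal((20_000, 2))
        _, _, evr = nbit.pocket_pca(coords)
        assert evr[0] == pytest.approx(0.5, abs=0.03)
        assert evr[1] == pytest.approx(0.5, abs=0.03)

    def test_recovers_planted_subspace(self, rng):
        d = 6
        basis, _ = np.linalg.qr(rng.standard_normal((d, 2)))
        scores = rng.standard_normal((5000, 2)) * [3.0, 1.5]
        coords = scores @ basis.T + 0.01 * rng.standard_normal((5000, d))
        _, loadings, _ = nbit.pocket_pca(coords)
        for i in range(2):
            cos = abs(loadings[i] @ basis[:, i])
            assert cos > 0.99

    def test_sign_convention_deterministic(self, rng):
        coords = rng.standard_normal((100, 3)) * [2.0, 1.0, 0.5]
        _, loadings, _ = nbit.pocket_pca(coords)
        for comp in loadings:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            nbit.pocket_pca(np.zeros((2, 3)))
        with pytest.raises(DegenerateInputError):
            nbit.pocket_pca(np.ones((10, 3)))
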