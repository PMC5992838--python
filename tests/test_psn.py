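import numpy as np
import pytest

from psnpipe import (FusionConfig, OmicsMatrix, PSNConfig,
                     PatientSimilarityNetwork, ValidationError, fuse_networks,
                     pearson_psn, rescale_correlations, scale_free_fit,
                     select_beta)
from psnpipe.datatypes import CorrelationMatrix
from psnpipe.psn import ScaleFreeWarning, truncated_fit_index

from conftest import block_psn, random_psn


def profiles(rows, tag="src"):
    rows = np.asarray(rows, dtype=float)
    return OmicsMatrix([f"p{i}" for i in range(rows.shape[0])],
                       [f"f{j}" for j in range(rows.shape[1])], rows, tag)


class TestPearson:
    def test_hand_computed_correlations(self):
        m = profiles([[1, 2, 3], [2, 4, 6], [3, 2, 1]])
        cm = pearson_psn(m)
        assert cm.c[0, 1] == pytest.approx(1.0)
        assert cm.c[0, 2] == pytest.approx(-1.0)
        assert cm.c[1, 2] == pytest.approx(-1.0)

    def test_identical_and_opposite_profiles(self):
        m = profiles([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        cm = pearson_psn(m)
        assert cm.c[0, 1] == pytest.approx(1.0)
        assert cm.c[0, 2] == pytest.approx(-1.0)

    def test_flat_profile_errors_with_patient_name(self):
        m = profiles([[1, 2, 3], [5, 5, 5]])
        with pytest.raises(ValidationError, match="p1"):
            pearson_psn(m)


class TestRescale:
    def cm(self, c):
        c = np.asarray(c, dtype=float)
        return CorrelationMatrix([f"p{i}" for i in range(len(c))], c)

    def test_extremes_map_to_zero_and_one(self):
        c = np.array([[1, 0.2, 0.8], [0.2, 1, 0.5], [0.8, 0.5, 1]])
        for beta in (1, 2, 6, 12):
            psn = rescale_correlations(self.cm(c), beta)
            assert psn.w[0, 1] == pytest.approx(0.0)   # c = min(C)
            assert psn.w[0, 2] == pytest.approx(1.0)   # c = max(C)

    def test_hand_evaluated_midpoint(self):
        # min(C)=0.2, max(C)=0.8, c=0.5, beta=2 -> ((0.5-0.2)/0.6)^2 = 0.25
        c = np.array([[1, 0.2, 0.8], [0.2, 1, 0.5], [0.8, 0.5, 1]])
        psn = rescale_correlations(self.cm(c), 2)
        assert psn.w[1, 2] == pytest.approx(0.25)

    def test_tags(self):
        c = np.array([[1, 0.2, 0.8], [0.2, 1, 0.5], [0.8, 0.5, 1]])
        assert rescale_correlations(self.cm(c), 1).meta["tag"] == "correl"
        assert rescale_correlations(self.cm(c), 2).meta["tag"] == "WGCNA"

    def test_beta_one_is_plain_minmax(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(-1, 1, (8, 8))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        cm = self.cm(c)
        psn = rescale_correlations(cm, 1)
        off = cm.offdiag()
        expected = (c - off.min()) / (off.max() - off.min())
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(psn.w, expected, atol=1e-12)

    def test_monotone_in_correlation(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(-1, 1, (10, 10))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        for beta in (1, 2, 8):
            psn = rescale_correlations(self.cm(c), beta)
            iu = np.triu_indices(10, 1)
            order = np.argsort(c[iu])
            w_sorted = psn.w[iu][order]
            assert (np.diff(w_sorted) >= -1e-12).all()

    def test_degenerate_range_errors(self):
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        with pytest.raises(ValidationError, match="degenerate"):
            rescale_correlations(self.cm(c), 2)


class TestScaleFreeFit:
    def test_exact_truncated_law_fits_perfectly(self):
        """Connectivities whose binned log-frequency lies exactly on the
        truncated model (pure exponential decay over arithmetic bins)."""
        levels = 10.0 + 15.0 * np.arange(10)
        counts = 2 ** np.arange(9, -1, -1)
        k = np.repeat(levels, counts)
        assert truncated_fit_index(k, 10) == pytest.approx(1.0, abs=1e-9)

    def test_index_bounded(self):
        for seed in range(5):
            psn = random_psn(n=60, seed=seed)
            fit = scale_free_fit(psn)
            assert 0.0 <= fit <= 1.0

    def test_degenerate_connectivity_warns_and_zero(self):
        n = 30
        w = np.full((n, n), 0.5)
        np.fill_diagonal(w, 0)
        psn = PatientSimilarityNetwork([f"p{i}" for i in range(n)], w)
        with pytest.warns(UserWarning, match="connectivities"):
            assert scale_free_fit(psn) == 0.0


class TestSelectBeta:
    def test_matches_brute_force_scan(self, modular_net):
        cm = pearson_psn(modular_net)
        config = PSNConfig()
        fits = {b: scale_free_fit(rescale_correlations(cm, b), config.fit_bins)
                for b in config.beta_candidates}
        reaching = [b for b in config.beta_candidates
                    if fits[b] >= config.scale_free_target]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ScaleFreeWarning)
            beta, psn = select_beta(cm, config)
        if reaching:
            assert beta == reaching[0]   # smallest qualifying candidate
        else:
            assert beta == max(fits, key=fits.get)
        assert psn.meta["beta"] == beta
        assert psn.meta["fit_index"] == pytest.approx(fits[beta])

    def test_zero_target_returns_first_candidate(self, modular_net):
        cm = pearson_psn(modular_net)
        beta, _ = select_beta(cm, PSNConfig(scale_free_target=0.0))
        assert beta == 2

    def test_unreachable_target_warns_and_returns_best(self, modular_net):
        cm = pearson_psn(modular_net)
        with pytest.warns(ScaleFreeWarning):
            beta, psn = select_beta(cm, PSNConfig(scale_free_target=1.0))
        fits = {b: scale_free_fit(rescale_correlations(cm, b))
                for b in (2, 4, 6, 8, 10, 12)}
        assert beta == max(fits, key=fits.get)


class TestFusion:
    def test_self_fusion_preserves_knn_sets(self):
        psn, _ = block_psn(n=40, n_blocks=4, seed=0)
        fused = fuse_networks([psn, psn], FusionConfig(K=9, T=50))
        for i in range(psn.n_patients):
            before = set(np.argsort(-psn.w[i])[:9])
            after = set(np.argsort(-fused.w[i])[:9])
            assert before == after

    def test_iterates_converge_monotonically(self):
        a, _ = block_psn(n=40, seed=1)
        b, _ = block_psn(n=40, seed=2)
        outs = [fuse_networks([a, b], FusionConfig(K=9, T=t)).w
                for t in range(39, 51)]
        dists = [np.linalg.norm(y - x) for x, y in zip(outs, outs[1:])]
        assert all(d2 <= d1 * (1 + 1e-6) for d1, d2 in zip(dists, dists[1:]))

    def test_output_invariants(self):
        a = random_psn(n=25, seed=3)
        b = random_psn(n=25, seed=4)
        fused = fuse_networks([a, b], FusionConfig(K=5, T=10))
        assert np.allclose(fused.w, fused.w.T)
        assert fused.w.min() >= 0 and fused.w.max() <= 1
        assert np.abs(np.diag(fused.w)).max() == 0
        assert fused.meta["tag"] == "fused"

    def test_mismatched_patients_error(self):
        a = random_psn(n=10, seed=0)
        b = random_psn(n=11, seed=0)
        with pytest.raises(ValidationError, match="differ"):
            fuse_networks([a, b], FusionConfig(K=3, T=5))


class TestNetworkInvariantsFuzz:
    @pytest.mark.parametrize("seed", range(5))
    def test_rescaled_networks_valid(self, seed):
        rng = np.random.default_rng(seed)
        m = OmicsMatrix([f"p{i}" for i in range(15)],
                        [f"f{j}" for j in range(40)],
                        rng.normal(size=(15, 40)), "x")
        cm = pearson_psn(m)
        for beta in (1, 2, 6):
            psn = rescale_correlations(cm, beta)
            assert np.allclose(psn.w, psn.w.T)
            assert psn.w.min() >= 0 and psn.w.max() <= 1
            assert np.abs(np.diag(psn.w)).max() == 0
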