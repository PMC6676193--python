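"""Sparse factor-analysis biclustering: fit, information content, extraction."""

import numpy as np
import pandas as pd
import pytest

from methylink import correlation, fabia, synthetic
from methylink.errors import ConfigurationError, DataIntegrityError

CFG = fabia.FabiaConfig(K=3, n_iter=200, seed=0)


def _planted_matrix(rng, n=120, l=30, blocks=((40, 8),), noise=0.0):
    """X = sum of planted outer products + Gaussian noise, plus truth."""
    X = np.zeros((n, l))
    truth = []
    r0 = c0 = 0
    for nr, nc in blocks:
        lam = np.zeros(n)
        lam[r0:r0 + nr] = rng.choice([-2.0, 2.0], size=nr)
        z = np.zeros(l)
        z[c0:c0 + nc] = rng.choice([-1.5, 1.5], size=nc)
        X += np.outer(lam, z)
        truth.append((set(range(r0, r0 + nr)), set(range(c0, c0 + nc))))
        r0 += nr
        c0 += nc
    X += rng.normal(0, noise, size=(n, l))
    return X, truth


def test_all_zero_input_gives_null_model():
    model = fabia.fit(np.zeros((30, 10)), CFG)
    assert np.abs(model.loadings).max() < 1e-6
    ic = fabia.information_content(model)
    np.testing.assert_allclose(ic, 0.0, atol=1e-6)
    assert fabia.extract_biclusters(model, CFG) == []


def test_rank_one_noiseless_reconstruction(rng):
    X, _ = _planted_matrix(rng, n=60, l=20, blocks=((20, 6),))
    model = fabia.fit(X, fabia.FabiaConfig(K=3, n_iter=300, seed=1))
    ic = fabia.information_content(model)
    best = int(np.argmax(ic))
    recon = np.outer(model.loadings[:, best], model.factors[best])
    rel = np.linalg.norm(X - recon) / np.linalg.norm(X)
    assert rel < 1e-3
    others = np.delete(ic, best)
    assert (others < 0.01 * ic[best]).all()


def test_noiseless_block_membership_recovered_exactly(rng):
    X, truth = _planted_matrix(rng, n=80, l=24, blocks=((30, 8),))
    cfg = fabia.FabiaConfig(K=3, n_iter=300, seed=2)
    model = fabia.fit(X, cfg)
    bics = fabia.extract_biclusters(model, cfg)
    assert len(bics) == 1
    rows, cols = truth[0]
    assert set(bics[0].probe_ids) == rows
    assert set(bics[0].parameter_ids) == cols


def test_seed_determinism(rng):
    X, _ = _planted_matrix(rng, noise=0.3)
    m1 = fabia.fit(X, CFG)
    m2 = fabia.fit(X, CFG)
    np.testing.assert_array_equal(m1.loadings, m2.loadings)
    np.testing.assert_array_equal(m1.factors, m2.factors)


def test_nonfinite_input_rejected():
    X = np.zeros((20, 10))
    X[0, 0] = np.nan
    with pytest.raises(DataIntegrityError):
        fabia.fit(X, CFG)


def test_k_must_be_below_matrix_dims():
    with pytest.raises(ConfigurationError):
        fabia.fit(np.zeros((5, 4)), fabia.FabiaConfig(K=4, n_iter=10))


def test_reconstruction_error_settles_in_final_iterations(rng):
    X, _ = _planted_matrix(rng, n=100, l=30, blocks=((30, 8), (30, 8)), noise=0.2)
    model = fabia.fit(X, fabia.FabiaConfig(K=5, n_iter=300, seed=3))
    tail = model.objective_trace[-30:]
    assert (np.diff(tail) <= 1e-6).all()
    # reconstruction reaches the noise floor (within 10%)
    noise_floor = 0.2 ** 2
    assert model.objective_trace[-1] <= noise_floor * 1.10


class TestInformationContent:
    def _model(self, lam, psi, l=6):
        n, K = lam.shape
        return fabia.FabiaModel(
            loadings=lam, factors=np.zeros((K, l)), psi=psi,
            xi=np.ones((K, l)), objective_trace=np.zeros(1),
            data=np.zeros((n, l)), row_ids=pd.RangeIndex(n),
            col_ids=pd.RangeIndex(l),
        )

    def test_zero_loading_vector_has_zero_ic(self):
        lam = np.zeros((5, 2))
        lam[:, 0] = [1, 2, 0, 0, 1]
        ic = fabia.information_content(self._model(lam, np.ones(5)))
        assert ic[1] == pytest.approx(0.0, abs=1e-12)
        assert ic[0] > 0

    def test_doubling_loading_norm_increases_ic(self):
        lam = np.zeros((5, 1)); lam[:, 0] = [1.0, 0.5, 0.2, 0.0, 0.3]
        psi = np.full(5, 0.5)
        ic1 = fabia.information_content(self._model(lam, psi))[0]
        ic2 = fabia.information_content(self._model(2 * lam, psi))[0]
        assert ic2 > ic1

    def test_matches_gaussian_mutual_information_oracle(self, rng):
        """5x4 two-factor model vs MI computed from joint covariance
        determinants (unit Gaussian factor prior)."""
        lam = rng.normal(size=(5, 2))
        lam[:, 0] *= 4.0   # ||lam_1|| >> ||lam_2||
        psi = rng.uniform(0.5, 1.5, 5)
        l = 4
        ic = fabia.information_content(self._model(lam, psi, l=l))
        # oracle: I(z_i; x) = 0.5 ln( det(Sigma_x) / det(Sigma_x|z_i) )
        Sigma_x = lam @ lam.T + np.diag(psi)
        oracle = []
        for i in range(2):
            cov_given = Sigma_x - np.outer(lam[:, i], lam[:, i])
            mi = 0.5 * (np.linalg.slogdet(Sigma_x)[1]
                        - np.linalg.slogdet(cov_given)[1])
            oracle.append(l * mi)
        np.testing.assert_allclose(ic, oracle, rtol=1e-8)
        assert ic[0] > ic[1]


def test_sparseness_reduces_nonzero_loadings(rng):
    """Statistically over 10 seeds: higher sparseness -> no more |lam|>0.01."""
    X, _ = _planted_matrix(rng, n=80, l=24, blocks=((25, 6),), noise=0.5)
    counts = {}
    for sp in (0.05, 0.5):
        total = 0
        for seed in range(10):
            model = fabia.fit(X, fabia.FabiaConfig(K=4, n_iter=120, seed=seed,
                                                   sparseness=sp))
            total += int((np.abs(model.loadings) > 0.01).sum())
        counts[sp] = total
    assert counts[0.5] <= counts[0.05]


class TestSelectInformative:
    def _bic(self, ic):
        return fabia.Bicluster("b", [], np.array([]), [], np.array([]), ic)

    def test_zero_threshold_is_identity(self):
        bics = [self._bic(3.0), self._bic(1.0)]
        assert fabia.select_informative(bics, 0.0) == bics

    def test_threshold_above_max_empties_list(self):
        assert fabia.select_informative([self._bic(3.0)], 10.0) == []

    def test_planted_count_stable_over_ic_eps_decade(self, rng):
        """3 planted signals, K=10: exactly 3 biclusters across a decade of
        ic_eps values (spurious factors collapse to zero information)."""
        X, _ = _planted_matrix(rng, n=300, l=40,
                               blocks=((60, 9), (60, 9), (60, 9)), noise=0.0)
        model = fabia.fit(X, fabia.FabiaConfig(K=10, n_iter=200, seed=5))
        base = fabia.extract_biclusters(model, fabia.FabiaConfig(
            K=10, n_iter=200, seed=5, ic_eps=0.0))
        for eps in (0.5, 1.0, 2.0, 5.0):
            assert len(fabia.select_informative(list(base), eps)) == 3


def test_planted_bicluster_recovery_from_correlation_matrix():
    """Generator -> Spearman -> standardize -> fit: axis-wise Jaccard >= 0.8
    for every planted bicluster (single-subject, 500x60, effect = 3*bio)."""
    cfg = synthetic.SimulationConfig(
        n_subjects=1, n_probes=500, n_parameters=60, n_planted=3,
        probe_block_size=130, param_block_size=12, effect_sd=3 * 0.065, seed=8)
    study = synthetic.generate_study(cfg)
    subj = study.subjects[0]
    rho = correlation.spearman_matrix(study.beta[subj], study.params[subj])
    X = correlation.standardize(rho)
    fcfg = fabia.FabiaConfig(K=10, n_iter=500, seed=8)
    bics = fabia.extract_biclusters(fabia.fit(X, fcfg), fcfg)
    for pb, qb in zip(study.truth["planted_probes"], study.truth["planted_params"]):
        pb, qb = set(pb), set(qb)
        best = max(
            min(len(set(b.probe_ids) & pb) / len(set(b.probe_ids) | pb),
                len(set(b.parameter_ids) & qb) / len(set(b.parameter_ids) | qb))
            for b in bics)
        assert best >= 0.8
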