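"""Signature extraction, reference assignment, decomposition, subsampling."""

import numpy as np
import pandas as pd
import pytest

from radmut.signatures import (
    SignatureSet,
    assign_to_reference,
    cosine_similarity,
    decompose_signature,
    extract_signatures,
    nmf_kl,
    refit_exposures,
    subsample_robustness,
)
from radmut.simulate import make_truth_signatures, simulate_catalog


def test_cosine_basic_values():
    v = np.array([0.2, 0.5, 0.3])
    assert cosine_similarity(v, v) == pytest.approx(1.0)
    assert cosine_similarity([1, 0, 0], [0, 1, 0]) == 0.0
    assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(1 / np.sqrt(2))
    with pytest.raises(ValueError):
        cosine_similarity([0, 0], [1, 0])
    with pytest.raises(ValueError):
        cosine_similarity([1, 0], [1, 0, 0])


@pytest.mark.parametrize("seed", [0, 3])
def test_nmf_kl_objective_monotone_and_nonnegative(seed):
    rng = np.random.default_rng(seed)
    V = rng.poisson(5.0, size=(30, 8)).astype(float)
    W, H, losses = nmf_kl(V, k=3, seed=seed, max_iter=300)
    assert (W >= 0).all() and (H >= 0).all()
    assert np.allclose(W.sum(axis=0), 1.0, atol=1e-9)
    diffs = np.diff(losses)
    assert (diffs <= 1e-6 * max(abs(losses[0]), 1)).all()  # non-increasing


def test_nmf_kl_input_validation():
    with pytest.raises(ValueError):
        nmf_kl(np.zeros((5, 4)), 2, seed=0)
    with pytest.raises(ValueError):
        nmf_kl(-np.ones((5, 4)), 2, seed=0)


def test_nmf_matches_sklearn_oracle_loss():
    """Our KL multiplicative updates reach a fit at least as good (within
    5%) as scikit-learn's KL NMF on the same catalog."""
    from sklearn.decomposition import NMF

    rng = np.random.default_rng(11)
    V = rng.poisson(8.0, size=(40, 10)).astype(float) + 1e-9
    _, _, losses = nmf_kl(V, 3, seed=1, max_iter=2000, tol=1e-10)
    sk = NMF(n_components=3, beta_loss="kullback-leibler", solver="mu",
             init="random", random_state=1, max_iter=2000, tol=1e-10)
    Wsk = sk.fit_transform(V)
    WHsk = np.maximum(Wsk @ sk.components_, 1e-12)
    mask = V > 0
    sk_loss = float(np.sum(V[mask] * np.log(V[mask] / WHsk[mask])) - V.sum()
                    + WHsk.sum())
    assert losses[-1] <= sk_loss * 1.05 + 1e-6


def test_rank1_catalog_recovers_common_spectrum():
    rng = np.random.default_rng(2)
    spectrum = rng.dirichlet(np.ones(20))
    V = pd.DataFrame(np.outer(spectrum, [1000, 2000, 1500]).round(),
                     index=[f"cat{i}" for i in range(20)],
                     columns=["a", "b", "c"])
    res = extract_signatures(V, [1], n_replicates=3, seed=4)
    assert res.selected_k == 1
    sig = res.signatures.signatures.iloc[:, 0].values
    assert cosine_similarity(sig, spectrum) >= 0.999


def test_noiseless_separable_catalog_exact_recovery(truth_signatures):
    """Catalog built exactly as S.E with near-pure clones: every truth
    column is recovered at cosine >= 0.99."""
    T = truth_signatures
    E = np.array(
        [[3000, 0, 0, 1500, 500, 1000, 2500],
         [0, 3000, 0, 1500, 2000, 500, 300],
         [0, 0, 3000, 0, 500, 1500, 200]], dtype=float,
    )
    V = pd.DataFrame((T.values @ E).round(), index=T.index,
                     columns=[f"c{i}" for i in range(E.shape[1])])
    res = extract_signatures(V, [3], n_replicates=1, seed=3)
    for t in T.columns:
        best = max(cosine_similarity(T[t], res.signatures.signatures[n])
                   for n in res.signatures.names)
        assert best >= 0.99


def test_extraction_is_deterministic(recovery_catalog):
    a = extract_signatures(recovery_catalog["catalog"], [3], n_replicates=3, seed=9)
    b = extract_signatures(recovery_catalog["catalog"], [3], n_replicates=3, seed=9)
    pd.testing.assert_frame_equal(a.signatures.signatures, b.signatures.signatures)
    pd.testing.assert_frame_equal(a.exposures, b.exposures)


def test_exposure_refit_conserves_clone_totals(recovery_catalog):
    res = extract_signatures(recovery_catalog["catalog"], [3],
                             n_replicates=3, seed=9)
    V = recovery_catalog["catalog"]
    assert (res.exposures.values >= 0).all()
    np.testing.assert_allclose(res.exposures.sum(axis=0), V.sum(axis=0),
                               rtol=1e-6)


def _sigset(df):
    return SignatureSet(categories=list(df.index), signatures=df,
                        stability=pd.Series(1.0, index=df.columns),
                        reconstruction_error=0.0)


def test_assignment_threshold_boundary_inclusive():
    cats = [f"c{i}" for i in range(10)]
    ref = pd.DataFrame({"R1": np.eye(10)[0], "R2": np.eye(10)[1]}, index=cats)

    def spectrum_with_cosine(c):
        v = np.zeros(10)
        v[0], v[2] = c, np.sqrt(1 - c**2)
        return v

    for c, expected in [(0.85, "R1"), (0.84, None), (1.0, "R1")]:
        ext = _sigset(pd.DataFrame({"E": spectrum_with_cosine(c)}, index=cats))
        assert assign_to_reference(ext, ref)["E"] == expected
    # scaling invariance
    ext = _sigset(pd.DataFrame({"E": 7.3 * spectrum_with_cosine(0.9)}, index=cats))
    assert assign_to_reference(ext, ref)["E"] == "R1"
    with pytest.raises(ValueError, match="category order"):
        assign_to_reference(ext, ref.iloc[::-1])


@pytest.mark.parametrize("seed", range(4))
def test_decompose_recovers_exact_conic_combinations(seed, truth_signatures):
    rng = np.random.default_rng(seed)
    ref = truth_signatures
    k = int(rng.integers(1, 4))
    chosen = rng.choice(ref.columns, size=k, replace=False)
    w = rng.dirichlet(np.ones(k) * 2)
    w = np.maximum(w, 0.08)
    w /= w.sum()
    spectrum = ref[chosen].values @ w
    res = decompose_signature(spectrum, ref)
    assert res.cosine >= 1 - 1e-9
    for name, wi in zip(chosen, w):
        assert res.weights.get(name, 0.0) == pytest.approx(wi, abs=1e-6)


def test_decompose_exact_two_component_mixture(truth_signatures):
    ref = truth_signatures
    spectrum = 0.6 * ref.iloc[:, 0] + 0.4 * ref.iloc[:, 1]
    res = decompose_signature(spectrum.values, ref)
    assert res.weights[ref.columns[0]] == pytest.approx(0.6, abs=1e-6)
    assert res.weights[ref.columns[1]] == pytest.approx(0.4, abs=1e-6)
    assert res.cosine == pytest.approx(1.0)
    single = decompose_signature(ref.iloc[:, 2].values, ref)
    assert single.weights == pytest.approx({ref.columns[2]: 1.0})


def test_decompose_flags_poor_fit_for_orthogonal_spectrum():
    cats = [f"c{i}" for i in range(6)]
    ref = pd.DataFrame({"R1": [1, 0, 0, 0, 0, 0], "R2": [0, 1, 0, 0, 0, 0]},
                       index=cats, dtype=float)
    res = decompose_signature(np.array([0, 0, 1, 0, 0, 0.0]), ref)
    assert res.poor_fit and res.cosine < 1.0
    with pytest.raises(ValueError, match="empty reference"):
        decompose_signature(np.ones(6), ref[[]])


def test_subsampling_identity_cases(recovery_catalog):
    own = recovery_catalog["catalog"]
    reports = subsample_robustness(own, {}, k_range=[3], n_repeats=2, seed=1,
                                   n_replicates=3)
    for rep in reports:
        for m in rep["matches"].values():
            assert m["cosine"] == pytest.approx(1.0)
            assert m["exposure_correlation"] == pytest.approx(1.0)
    # fraction 0 removes nothing
    ext = own.iloc[:, :4].copy()
    ext.columns = [f"e{i}" for i in range(4)]
    reports = subsample_robustness(own, {"ext": ext}, k_range=[3], fraction=0.0,
                                   n_repeats=1, seed=1, n_replicates=3)
    assert all(m["cosine"] == pytest.approx(1.0)
               for m in reports[0]["matches"].values())
    with pytest.raises(ValueError, match="fewer than 2"):
        subsample_robustness(own, {"tiny": ext.iloc[:, :1]}, k_range=[3])


def test_subsampled_extraction_remains_stable(truth_signatures):
    """Pooled cohort with external samples from the same processes: every
    original signature is re-found at cosine >= 0.9 in all repeats."""
    rng = np.random.default_rng(21)

    def catalog(n, prefix, seed):
        clones = [f"{prefix}{i}" for i in range(n)]
        E = pd.DataFrame(rng.dirichlet([0.5] * 3, size=n).T,
                         index=truth_signatures.columns, columns=clones)
        b = pd.Series(rng.integers(2000, 5001, n), index=clones)
        return simulate_catalog(truth_signatures, E, b, seed=seed)

    own = catalog(21, "own", 31)
    external = {"mutagen_panel": catalog(40, "k", 32),
                "knockout_panel": catalog(20, "z", 33)}
    reports = subsample_robustness(own, external, k_range=[3], n_repeats=3,
                                   seed=7, n_replicates=4)
    assert len(reports) == 3
    for rep in reports:
        assert all(m["cosine"] >= 0.9 for m in rep["matches"].values())
        assert all(m["exposure_correlation"] >= 0.9
                   for m in rep["matches"].values())


def test_refit_exposures_on_known_mixture(truth_signatures):
    T = truth_signatures
    E_true = pd.DataFrame([[800.0, 0.0], [200.0, 500.0], [0.0, 500.0]],
                          index=T.columns, columns=["a", "b"])
    V = pd.DataFrame(T.values @ E_true.values, index=T.index, columns=["a", "b"])
    E_fit = refit_exposures(V, T)
    np.testing.assert_allclose(E_fit.values, E_true.values, atol=1e-6)
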