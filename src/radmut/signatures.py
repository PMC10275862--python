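"""De-novo mutational-signature extraction and reference decomposition.

The extractor factorizes a categories x samples count catalog as
``V ~ S . E`` with non-negative S (spectra, columns sum to 1) and E
(activities), using Kullback-Leibler NMF with multiplicative updates —
the natural objective for count data. Robustness is assessed by repeated
factorization of bootstrap-resampled catalogs: replicate solutions are
matched by cosine similarity and per-signature stability is the mean
similarity of the matched replicate spectra to their consensus. Extracted
spectra are then assigned to, and decomposed over, a reference catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

_EPS = 1e-12


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra of unequal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero spectrum")
    return float(np.dot(a, b) / (na * nb))


def nmf_kl(
    V: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """KL-divergence NMF by multiplicative updates.

    Returns (W, H, losses); the generalized KL divergence is non-increasing
    across iterations (Lee-Seung updates) and the iteration stops when the
    relative improvement drops below ``tol``.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("catalog must be non-negative")
    m, n = V.shape
    if k >= min(m, n) + 1 and k > min(m, n):
        raise ValueError(f"rank {k} too large for a {m}x{n} catalog")
    if V.sum() == 0:
        raise ValueError("all-zero catalog")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n)) * scale

    def kl(Vhat):
        mask = V > 0
        return float(
            np.sum(V[mask] * np.log(V[mask] / np.maximum(Vhat[mask], _EPS)))
            - V.sum() + Vhat.sum()
        )

    losses = [kl(W @ H)]
    ones = np.ones_like(V)
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.T @ ones, _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(ones @ H.T, _EPS)
        losses.append(kl(W @ H))
        prev, cur = losses[-2], losses[-1]
        if prev - cur <= tol * max(abs(prev), 1.0):
            break
    # push scale into H so W columns sum to 1
    colsum = np.maximum(W.sum(axis=0), _EPS)
    W = W / colsum
    H = H * colsum[:, None]
    return W, H, losses


@dataclass
class SignatureSet:
    categories: list[str]
    signatures: pd.DataFrame      # categories x names, columns sum to 1
    stability: pd.Series          # per-signature reproducibility in [0, 1]
    reconstruction_error: float   # relative Frobenius error of V ~ S.E

    @property
    def names(self) -> list[str]:
        return list(self.signatures.columns)


@dataclass
class ExtractionResult:
    selected_k: int
    signatures: SignatureSet
    exposures: pd.DataFrame       # names x clones, attributed counts
    rank_survey: pd.DataFrame     # per-k mean stability / reconstruction error


def _signature_prefix(n_categories: int) -> str:
    return {96: "SBS96", 83: "ID83", 6: "SBS6"}.get(n_categories, f"SIG{n_categories}")


def _bootstrap_catalog(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-sample multinomial resample preserving each column's total."""
    out = np.zeros_like(V, dtype=float)
    for j in range(V.shape[1]):
        total = int(round(V[:, j].sum()))
        if total == 0:
            continue
        p = V[:, j] / V[:, j].sum()
        out[:, j] = rng.multinomial(total, p)
    return out


def _match_columns(W: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Permutation of W's columns best matching centroids by cosine."""
    k = W.shape[1]
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = cosine_similarity(centroids[:, i], W[:, j])
    _, cols = linear_sum_assignment(-sim)
    return cols


def refit_exposures(V: pd.DataFrame, S: pd.DataFrame) -> pd.DataFrame:
    """Per-clone NNLS of the catalog on the signature matrix, rescaled so
    attributed counts sum to the clone's observed total."""
    E = np.zeros((S.shape[1], V.shape[1]))
    Sm = S.values
    for j, clone in enumerate(V.columns):
        w, _ = nnls(Sm, V[clone].values.astype(float))
        total = V[clone].sum()
        attributed = (Sm @ w).sum()
        if attributed > 0:
            w = w * (total / attributed)
        E[:, j] = w
    return pd.DataFrame(E, index=S.columns, columns=V.columns)


def extract_signatures(
    catalog: pd.DataFrame,
    k_range,
    n_replicates: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
    stability_floor: float = 0.8,
) -> ExtractionResult:
    """Extract signatures over a range of ranks and select the best rank.

    For each k, ``n_replicates`` KL-NMF runs on bootstrap-resampled
    catalogs are matched to a running consensus; per-signature stability is
    the mean cosine of matched replicates to the consensus. The selected
    rank is the largest one whose mean stability reaches
    ``stability_floor`` (falling back to the most stable rank). Deterministic
    given ``seed``.
    """
    k_range = sorted(set(int(k) for k in k_range))
    V = catalog.values.astype(float)
    n_samples = V.shape[1]
    if max(k_range) >= n_samples:
        raise ValueError("max rank must be below the number of samples")
    root = np.random.default_rng(seed)
    per_k: dict[int, dict] = {}
    survey_rows = []
    for k in k_range:
        centroids = None
        matched: list[np.ndarray] = []
        for rep in range(n_replicates):
            rep_seed = int(root.integers(0, 2**31 - 1))
            rng = np.random.default_rng(rep_seed)
            Vb = _bootstrap_catalog(V, rng) if n_replicates > 1 else V
            if Vb.sum() == 0:
                Vb = V
            W, _, _ = nmf_kl(Vb, k, seed=rep_seed, max_iter=max_iter, tol=tol)
            if centroids is None:
                centroids = W.copy()
                matched.append(W)
            else:
                order = _match_columns(W, centroids)
                Wm = W[:, order]
                matched.append(Wm)
                stacked = np.stack(matched)
                centroids = stacked.mean(axis=0)
                centroids /= np.maximum(centroids.sum(axis=0), _EPS)
        stacked = np.stack(matched)
        consensus = stacked.mean(axis=0)
        consensus /= np.maximum(consensus.sum(axis=0), _EPS)
        stab = np.array(
            [
                np.mean([cosine_similarity(m[:, j], consensus[:, j]) for m in matched])
                for j in range(k)
            ]
        )
        # order signatures by total attributed burden for stable naming
        S_tmp = pd.DataFrame(consensus, index=catalog.index,
                             columns=[f"tmp{j}" for j in range(k)])
        E_tmp = refit_exposures(catalog, S_tmp)
        order = np.argsort(-E_tmp.sum(axis=1).values)
        consensus, stab = consensus[:, order], stab[order]
        recon = np.linalg.norm(V - S_tmp.values[:, order] @ E_tmp.values[order]) / max(
            np.linalg.norm(V), _EPS
        )
        per_k[k] = {"signatures": consensus, "stability": stab, "recon": recon}
        survey_rows.append(
            {"k": k, "mean_stability": float(stab.mean()),
             "min_stability": float(stab.min()),
             "reconstruction_error": float(recon)}
        )
    survey = pd.DataFrame(survey_rows).set_index("k")
    # rank rule: every signature of a qualifying rank must reach the
    # stability floor; a larger rank is only preferred when it buys a
    # meaningful (>= 5% relative) reconstruction-error improvement over the
    # smaller qualifying rank, mirroring "high stability and low
    # reconstruction error" without chasing noise splits
    qualifying = [k for k in k_range if per_k[k]["stability"].min() >= stability_floor]
    if not qualifying:
        selected = int(survey["mean_stability"].idxmax())
    else:
        selected = qualifying[0]
        for k in qualifying[1:]:
            prev_err, err = per_k[selected]["recon"], per_k[k]["recon"]
            if err <= prev_err * 0.95:
                selected = k

    prefix = _signature_prefix(len(catalog.index))
    names = [f"{prefix}{chr(ord('A') + j)}" for j in range(selected)]
    S = pd.DataFrame(per_k[selected]["signatures"], index=catalog.index, columns=names)
    E = refit_exposures(catalog, S)
    sig_set = SignatureSet(
        categories=list(catalog.index),
        signatures=S,
        stability=pd.Series(per_k[selected]["stability"], index=names),
        reconstruction_error=float(per_k[selected]["recon"]),
    )
    return ExtractionResult(
        selected_k=selected, signatures=sig_set, exposures=E, rank_survey=survey
    )


# --- reference assignment & decomposition ---------------------------------

def assign_to_reference(
    extracted: SignatureSet, reference: pd.DataFrame, threshold: float = 0.85
) -> dict[str, str | None]:
    """Best-cosine reference assignment; below-threshold spectra stay
    unassigned. Invariant to scaling of either spectrum."""
    if list(extracted.categories) != list(reference.index):
        raise ValueError("category order mismatch between extraction and reference")
    out: dict[str, str | None] = {}
    for name in extracted.names:
        sims = {
            ref: cosine_similarity(extracted.signatures[name], reference[ref])
            for ref in reference.columns
        }
        best = max(sims.values())
        if best >= threshold:
            ties = sorted(r for r, s in sims.items() if np.isclose(s, best, atol=1e-12))
            if len(ties) > 1:
                import warnings

                warnings.warn(
                    f"cosine tie for {name}: {ties}; keeping {ties[0]}", stacklevel=2
                )
            out[name] = ties[0]
        else:
            out[name] = None
    return out


@dataclass
class DecompositionResult:
    name: str
    weights: dict[str, float] = field(default_factory=dict)  # normalized, sum 1
    cosine: float = 0.0
    poor_fit: bool = False


def decompose_signature(
    spectrum,
    reference: pd.DataFrame,
    name: str = "extracted",
    min_weight: float = 0.05,
    poor_fit_cosine: float = 0.9,
) -> DecompositionResult:
    """Model a spectrum as a conic combination of reference signatures.

    Non-negative least squares, then components contributing less than
    ``min_weight`` of the total are pruned and the fit repeated until the
    support is stable. Reported weights are normalized to sum 1.
    """
    if reference.shape[1] == 0:
        raise ValueError("empty reference catalog")
    s = np.asarray(spectrum, dtype=float).ravel()
    if s.shape[0] != reference.shape[0]:
        raise ValueError("spectrum length does not match reference categories")
    cols = list(reference.columns)
    while True:
        R = reference[cols].values
        w, _ = nnls(R, s)
        total = w.sum()
        if total == 0:
            return DecompositionResult(name=name, weights={}, cosine=0.0, poor_fit=True)
        keep = [c for c, wi in zip(cols, w) if wi / total >= min_weight]
        if keep == cols or not keep:
            break
        cols = keep
    recon = reference[cols].values @ w
    cos = cosine_similarity(s, recon) if recon.sum() > 0 else 0.0
    weights = {c: float(wi / total) for c, wi in zip(cols, w) if wi > 0}
    return DecompositionResult(
        name=name, weights=weights, cosine=cos, poor_fit=cos < poor_fit_cosine
    )


# --- subsampling robustness check -----------------------------------------

def subsample_robustness(
    own_catalog: pd.DataFrame,
    external_catalogs: dict[str, pd.DataFrame],
    k_range,
    fraction: float = 0.5,
    n_repeats: int = 3,
    seed: int = 0,
    n_replicates: int = 10,
) -> list[dict]:
    """Check that external pooled data does not dominate the extraction.

    Per repeat, ``floor(fraction * m)`` samples of each external dataset are
    removed uniformly at random, signatures are re-extracted from the
    reduced pool, and each original signature is matched to its best
    re-extracted counterpart (cosine); exposures on the cohort's own clones
    are compared by Pearson correlation.
    """
    for dname, ext in external_catalogs.items():
        if ext.shape[1] < 2:
            raise ValueError(f"external dataset {dname!r} has fewer than 2 samples")
    pooled = pd.concat([own_catalog] + list(external_catalogs.values()), axis=1)
    original = extract_signatures(pooled, k_range, n_replicates=n_replicates, seed=seed)
    own_cols = list(own_catalog.columns)
    rng = np.random.default_rng(seed)
    reports = []
    for rep in range(n_repeats):
        kept_parts = [own_catalog]
        for dname, ext in external_catalogs.items():
            m = ext.shape[1]
            n_drop = int(np.floor(fraction * m))
            drop = set(rng.choice(m, size=n_drop, replace=False)) if n_drop else set()
            kept_parts.append(ext.iloc[:, [j for j in range(m) if j not in drop]])
        reduced = pd.concat(kept_parts, axis=1)
        if reduced.shape[1] == pooled.shape[1]:
            # nothing removed (fraction 0 or no external data): the repeat
            # is the original extraction itself
            sub = original
        else:
            sub = extract_signatures(
                reduced, [original.selected_k], n_replicates=n_replicates,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        matches = {}
        for name in original.signatures.names:
            sims = {
                other: cosine_similarity(
                    original.signatures.signatures[name],
                    sub.signatures.signatures[other],
                )
                for other in sub.signatures.names
            }
            best = max(sims, key=sims.get)
            exp_a = original.exposures.loc[name, own_cols].values
            exp_b = sub.exposures.loc[best, own_cols].values
            if np.std(exp_a) > 0 and np.std(exp_b) > 0:
                corr = float(np.corrcoef(exp_a, exp_b)[0, 1])
            else:
                corr = float("nan")
            matches[name] = {"match": best, "cosine": sims[best],
                             "exposure_correlation": corr}
        reports.append({"repeat": rep, "matches": matches,
                        "n_samples": reduced.shape[1]})
    return reports
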