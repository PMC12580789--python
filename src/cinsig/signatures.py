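"""De-novo signature extraction and activity assignment.

The model: a sample's 44-dimensional feature count vector is a nonnegative
mixture of K signature profiles, V ≈ W·H with W (features x K, columns
L1-normalized) and H (K x samples, nonnegative activities). W and H are
estimated by multiplicative-update NMF minimizing the generalized
Kullback-Leibler divergence — the natural objective for count data.

Rank selection follows the bootstrap-stability recipe: for each candidate
rank, Poisson-resample the count vectors many times, factorize each
resample, pool all signature columns, cluster them into k groups by cosine
distance (k-medoids), and score the rank by the mean silhouette. The
selected rank is the largest one whose stability reaches the threshold
(default 0.8); consensus signatures are the cluster medoids.

Assignment to new samples is per-sample nonnegative least squares followed
by backward pruning of signatures whose removal barely changes the
reconstruction, approximating sparse refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

_EPS = np.finfo(float).tiny


def generalized_kl(V: np.ndarray, WH: np.ndarray) -> float:
    """D(V || WH) = sum V log(V/WH) - V + WH, with 0 log 0 = 0."""
    mask = V > 0
    div = float(np.sum(WH) - np.sum(V))
    div += float(np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))))
    return div


def nmf_kl(
    V: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    warn: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative-update NMF of a nonnegative (features x samples) matrix
    under generalized KL divergence.

    Returns (W, H) with W L1-normalized per column and the scale absorbed into
    H. All-zero rows/columns are dropped for the updates and re-inserted as
    zeros. Deterministic given the seed.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    if k < 1 or k > min(V.shape):
        raise ValueError(f"rank {k} outside 1..{min(V.shape)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    row_ok = V.sum(axis=1) > 0
    col_ok = V.sum(axis=0) > 0
    if warn and (not row_ok.all() or not col_ok.all()):
        warnings.warn("all-zero rows/columns dropped for NMF and re-inserted as zeros")
    Vr = V[np.ix_(row_ok, col_ok)]
    n_rows, n_cols = Vr.shape
    if k > min(n_rows, n_cols):
        raise ValueError("rank exceeds nonzero dimensions of V")

    scale = Vr.mean()
    W = rng.uniform(0.1, 1.0, size=(n_rows, k)) * np.sqrt(scale / k)
    H = rng.uniform(0.1, 1.0, size=(k, n_cols)) * np.sqrt(scale / k)

    prev_div = np.inf
    last_checked = np.inf
    for it in range(max_iter):
        WH = W @ H
        np.maximum(WH, _EPS, out=WH)
        ratio = Vr / WH
        H *= (W.T @ ratio) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        np.maximum(WH, _EPS, out=WH)
        ratio = Vr / WH
        W *= (ratio @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if (it + 1) % 10 == 0:
            div = generalized_kl(Vr, np.maximum(W @ H, _EPS))
            if (it + 1) % 100 == 0:
                # KL divergence is non-increasing under MU up to roundoff
                assert div <= last_checked * (1 + 1e-9) + 1e-9, (
                    f"divergence increased: {last_checked} -> {div}"
                )
                last_checked = div
            if prev_div < np.inf and abs(prev_div - div) <= tol * max(prev_div, _EPS):
                break
            prev_div = div

    # L1-normalize signature columns; activities absorb the scale
    col_sums = np.maximum(W.sum(axis=0), _EPS)
    W /= col_sums
    H *= col_sums[:, None]

    W_full = np.zeros((V.shape[0], k))
    H_full = np.zeros((k, V.shape[1]))
    W_full[row_ok] = W
    H_full[:, col_ok] = H
    return W_full, H_full


# ---------------------------------------------------------------------------
# k-medoids consensus over pooled bootstrap solutions
# ---------------------------------------------------------------------------

def _cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances between columns of X."""
    norms = np.linalg.norm(X, axis=0)
    Xn = X / np.maximum(norms, _EPS)
    sim = np.clip(Xn.T @ Xn, -1.0, 1.0)
    return 1.0 - sim


def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
              ) -> tuple[np.ndarray, np.ndarray]:
    """Plain alternating k-medoids on a precomputed distance matrix.

    Initialization is k-means++-style on distances with the supplied RNG.
    Returns (labels, medoid indices).
    """
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d_min = D[:, medoids].min(axis=1)
        probs = d_min**2
        total = probs.sum()
        if total <= 0:
            # all points coincide with existing medoids; pick arbitrary distinct
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(remaining[0] if remaining else medoids[0])
            continue
        medoids.append(int(rng.choice(n, p=probs / total)))
    medoids_arr = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids_arr], axis=1)
        new_medoids = medoids_arr.copy()
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(new_medoids, medoids_arr):
            break
        medoids_arr = new_medoids
    labels = np.argmin(D[:, medoids_arr], axis=1)
    return labels, medoids_arr


def signature_names(k: int) -> list[str]:
    """SCN-A, SCN-B, ... (doubling letters past Z)."""
    names = []
    for i in range(k):
        letter = ascii_uppercase[i % 26] * (i // 26 + 1)
        names.append(f"SCN-{letter}")
    return names


@dataclass
class ExtractionReport:
    """Bookkeeping for rank selection across the tested range."""

    rank_range: list[int]
    stability: dict[int, float] = field(default_factory=dict)  # mean silhouette
    min_signature_stability: dict[int, float] = field(default_factory=dict)
    reconstruction_error: dict[int, float] = field(default_factory=dict)
    selected_rank: int = 0
    stability_threshold: float = 0.8
    fallback_used: bool = False
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rank_range": self.rank_range,
            "stability": {str(k): v for k, v in self.stability.items()},
            "min_signature_stability": {
                str(k): v for k, v in self.min_signature_stability.items()
            },
            "reconstruction_error": {
                str(k): v for k, v in self.reconstruction_error.items()
            },
            "selected_rank": self.selected_rank,
            "stability_threshold": self.stability_threshold,
            "fallback_used": self.fallback_used,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def extract_signatures(
    V: pd.DataFrame,
    rank_range: tuple[int, int] = (2, 14),
    n_bootstraps: int = 100,
    n_inits: int = 10,
    seed: int = 0,
    stability_threshold: float = 0.8,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> tuple[pd.DataFrame, ExtractionReport]:
    """Stability-selected NMF over a (samples x features) count matrix.

    For every rank k in ``rank_range``, each bootstrap Poisson-resamples the
    count matrix and is factorized from ``n_inits`` random starts; the pooled
    signature columns are clustered into k groups by cosine k-medoids, and
    the rank's stability is the mean silhouette of that clustering. Returns
    the consensus SignatureSet (features x K, L1-normalized columns) for the
    selected rank and the full report.
    """
    kmin, kmax = rank_range
    ks = [k for k in range(kmin, kmax + 1) if k <= min(V.shape)]
    if not ks:
        raise ValueError(f"empty rank range {rank_range} for matrix {V.shape}")
    X = V.to_numpy(dtype=float).T  # features x samples
    report = ExtractionReport(rank_range=ks, stability_threshold=stability_threshold,
                              seed=seed)
    consensus: dict[int, np.ndarray] = {}
    for k in ks:
        pooled: list[np.ndarray] = []
        errors: list[float] = []
        for b in range(n_bootstraps):
            rng_b = np.random.default_rng([seed, k, b])
            Xb = rng_b.poisson(X).astype(float)
            for init in range(n_inits):
                rng_i = np.random.default_rng([seed, k, b, init])
                W, H = nmf_kl(Xb, k, seed=rng_i, max_iter=max_iter, tol=tol,
                              warn=False)
                pooled.append(W)
                errors.append(generalized_kl(Xb, np.maximum(W @ H, _EPS)))
        P = np.concatenate(pooled, axis=1)  # features x (k * B * I)
        report.reconstruction_error[k] = float(np.mean(errors))
        if P.shape[1] <= k:
            report.stability[k] = float("nan")
            report.min_signature_stability[k] = float("nan")
            consensus[k] = P[:, :k]
            continue
        D = _cosine_distance_matrix(P)
        labels, medoids = _kmedoids(D, k, np.random.default_rng([seed, k, 7]))
        if len(np.unique(labels)) < 2:
            report.stability[k] = float("nan")
            report.min_signature_stability[k] = float("nan")
        else:
            sil = silhouette_samples(D, labels, metric="precomputed")
            report.stability[k] = float(sil.mean())
            report.min_signature_stability[k] = float(
                min(sil[labels == c].mean() for c in np.unique(labels))
            )
        consensus[k] = P[:, medoids]

    # a rank is stable only if its *least* reproducible signature is stable,
    # mirroring the per-signature stability gate of extraction tools
    stable = [
        k for k in ks
        if report.min_signature_stability.get(k, float("nan")) >= stability_threshold
    ]
    if stable:
        selected = max(stable)
    else:
        finite = {k: s for k, s in report.min_signature_stability.items()
                  if np.isfinite(s)}
        selected = max(finite, key=finite.get) if finite else ks[0]
        report.fallback_used = True
    report.selected_rank = selected

    W = consensus[selected]
    W = W / np.maximum(W.sum(axis=0), _EPS)
    # deterministic column order: by descending total weight on the pooled matrix
    order = np.argsort([-float(w @ X.sum(axis=1)) for w in W.T], kind="stable")
    W = W[:, order]
    signatures = pd.DataFrame(W, index=V.columns, columns=signature_names(W.shape[1]))
    return signatures, report


# ---------------------------------------------------------------------------
# activity assignment
# ---------------------------------------------------------------------------

def _relative_error(v: np.ndarray, W: np.ndarray, h: np.ndarray) -> float:
    denom = np.linalg.norm(v)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(v - W @ h) / denom)


def assign_activities(
    V_new: pd.DataFrame,
    signatures: pd.DataFrame,
    prune_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-sample NNLS refit of counts on the signature matrix with backward
    pruning: iteratively drop the signature whose removal increases relative
    reconstruction error least, while the increase stays below the threshold.
    """
    if list(V_new.columns) != list(signatures.index):
        missing = set(signatures.index).symmetric_difference(V_new.columns)
        raise ValueError(f"feature layout mismatch; differing columns: {sorted(missing)}")
    W = signatures.to_numpy(dtype=float)
    K = W.shape[1]
    H = np.zeros((len(V_new), K))
    for i, (_, row) in enumerate(V_new.iterrows()):
        v = row.to_numpy(dtype=float)
        if v.sum() == 0:
            continue
        active = list(range(K))
        h, _ = nnls(W, v)
        err = _relative_error(v, W, h)
        while len(active) > 1:
            best_err, best_drop, best_h = np.inf, None, None
            for s in active:
                trial = [a for a in active if a != s]
                h_t, _ = nnls(W[:, trial], v)
                e_t = _relative_error(v, W[:, trial], h_t)
                if e_t < best_err:
                    best_err, best_drop, best_h = e_t, s, h_t
            if best_err - err < prune_threshold:
                active = [a for a in active if a != best_drop]
                err = best_err
                h = np.zeros(K)
                h[active] = best_h
            else:
                break
        H[i] = h
    return pd.DataFrame(H, index=V_new.index, columns=signatures.columns)


def exposure_fractions(exposures: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize activities to mixture fractions (zero rows stay zero)."""
    totals = exposures.sum(axis=1)
    out = exposures.div(totals.where(totals > 0, 1.0), axis=0)
    return out


def correlate_with_reference(
    exposures: pd.DataFrame,
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of each signature against each reference activity
    over shared samples, with Benjamini-Hochberg q-values across all pairs."""
    shared = exposures.index.intersection(reference.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    E, R = exposures.loc[shared], reference.loc[shared]
    rows = []
    for sig in E.columns:
        for ref in R.columns:
            x, y = E[sig].to_numpy(), R[ref].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearmanr(x, y)
            rows.append({"signature": sig, "reference": ref, "rho": rho, "p": p})
    table = pd.DataFrame(rows)
    valid = table["p"].notna()
    table["q"] = np.nan
    if valid.any():
        table.loc[valid, "q"] = multipletests(table.loc[valid, "p"], method="fdr_bh")[1]
    return table
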