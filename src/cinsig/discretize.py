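"""Cohort-level discretization and assembly of the 44-column feature matrix.

Continuous feature families (event lengths, segment sizes, changepoints,
fragmentation counts, oscillation chain lengths, magnitude quantiles) are
discretized with models fitted once on the extraction cohort and then frozen:
Jenks natural breaks (exact Fisher dynamic programming) for most families and
a BIC-selected 1-D Gaussian mixture for segments-per-5Mb. Event-count
families pass through as single columns. The resulting matrix of nonnegative
integer counts (samples x 44) is the NMF input.

The per-family bin split composing 44 columns is a versioned layout
(``DEFAULT_LAYOUT``, version ``v1``) and can be swapped without code change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .cn_features import CNRawFeatures
from .sv_events import SVFeatureCounts


# ---------------------------------------------------------------------------
# Jenks natural breaks (exact DP)
# ---------------------------------------------------------------------------

def jenks_breaks(values: list[float] | np.ndarray, k: int) -> list[float]:
    """Exact Fisher-Jenks optimal 1-D classification into ``k`` classes.

    Minimizes the within-class sum of squared deviations by dynamic
    programming over the sorted values; returns the k-1 class boundaries as
    the upper edge (maximum value) of each lower class. Requires at least
    ``k`` distinct values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    n_distinct = len(np.unique(x))
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_distinct < k:
        raise ValueError(f"need >= {k} distinct values, got {n_distinct}")

    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd_vec(i: np.ndarray, j: int) -> np.ndarray:
        """Within-class SSD of x[i..j] inclusive, vectorized over i."""
        m = j - i + 1
        s = csum[j + 1] - csum[i]
        return (csq[j + 1] - csq[i]) - s * s / m

    # dp[m][j]: minimal cost of splitting x[0..j] into m+1 classes
    dp = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)
    dp[0] = csq[1:] - csum[1:] ** 2 / np.arange(1, n + 1)
    for m in range(1, k):
        for j in range(m, n):
            i = np.arange(m, j + 1)
            costs = dp[m - 1][i - 1] + ssd_vec(i, j)
            best = int(np.argmin(costs))  # first minimum: deterministic
            dp[m][j] = costs[best]
            split[m][j] = m + best
    # backtrack: boundaries are the last element of each class except the top
    breaks = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = split[m][j]
        breaks.append(float(x[i - 1]))
        j = i - 1
    return sorted(breaks)


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture binning
# ---------------------------------------------------------------------------

def gmm_bins(
    values: list[float] | np.ndarray,
    max_components: int = 4,
    seed: int = 0,
) -> list[float]:
    """Breaks at posterior crossovers of a BIC-selected 1-D Gaussian mixture.

    Fits 1..max_components by EM, picks the BIC-best model, and places a break
    between each pair of mean-adjacent components where their posterior
    responsibilities cross. A single-component winner yields no breaks (the
    caller falls back to quantile tertiles).
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError(f"need >= 10 values, got {len(x)}")
    reg = max(1e-6 * float(np.var(x)), 1e-12)  # variance floor for degenerate input
    best_model, best_bic = None, np.inf
    for n_comp in range(1, max_components + 1):
        if n_comp > len(np.unique(x)):
            break
        gm = GaussianMixture(
            n_components=n_comp,
            covariance_type="full",
            reg_covar=reg,
            n_init=3,
            init_params="k-means++",
            random_state=seed,
            max_iter=500,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_model, best_bic = gm, bic
    assert best_model is not None
    means = best_model.means_.ravel()
    order = np.argsort(means)
    breaks: list[float] = []
    for a, b in zip(order, order[1:]):
        lo, hi = means[a], means[b]
        if hi - lo <= 0:
            continue
        grid = np.linspace(lo, hi, 513).reshape(-1, 1)
        resp = best_model.predict_proba(grid)
        diff = resp[:, a] - resp[:, b]
        cross = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        if len(cross):
            i = cross[0]
            breaks.append(float((grid[i, 0] + grid[i + 1, 0]) / 2))
    return sorted(breaks)


def quantile_tertile_breaks(values: np.ndarray) -> list[float]:
    """Fallback tertile breaks when a mixture collapses to one component."""
    qs = np.quantile(np.asarray(values, dtype=float), [1 / 3, 2 / 3])
    return sorted(set(float(q) for q in qs))


# ---------------------------------------------------------------------------
# models and layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationModel:
    """A frozen per-family binning model; assignment never refits."""

    family: str
    method: str  # jenks | gmm | fixed
    n_bins: int
    breaks: tuple[float, ...]
    log_transform: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if list(self.breaks) != sorted(set(self.breaks)):
            raise ValueError(f"{self.family}: breaks must be strictly increasing")
        if not self.degenerate and len(self.breaks) != self.n_bins - 1:
            raise ValueError(
                f"{self.family}: {len(self.breaks)} breaks inconsistent with "
                f"{self.n_bins} bins"
            )

    def transform(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.log_transform:
            v = np.log10(np.maximum(v, 1.0))
        return v

    def bin_of(self, values: list[float] | np.ndarray) -> np.ndarray:
        """Bin index per value: value <= break_i falls below break_i; extremes
        clamp into the edge bins."""
        v = self.transform(np.asarray(values, dtype=float))
        return np.searchsorted(np.asarray(self.breaks), v, side="left")


@dataclass(frozen=True)
class FamilySpec:
    name: str
    kind: str  # count | lengths | scalar
    source: str  # attribute on SVFeatureCounts / CNRawFeatures
    n_bins: int = 1
    method: str = "fixed"
    log_transform: bool = False


# v1 layout: 21 SV + 23 CN columns = 44
DEFAULT_LAYOUT: tuple[FamilySpec, ...] = (
    FamilySpec("simple", "count", "simple"),
    FamilySpec("complex", "count", "complex"),
    FamilySpec("intra", "count", "intra"),
    FamilySpec("inter", "count", "inter"),
    FamilySpec("compact", "count", "compact"),
    FamilySpec("sparse", "count", "sparse"),
    FamilySpec("deletion_length", "lengths", "deletion_lengths", 5, "jenks", True),
    FamilySpec("duplication_length", "lengths", "duplication_lengths", 5, "jenks", True),
    FamilySpec("insertion", "count", "insertions"),
    FamilySpec("reciprocal", "count", "reciprocal"),
    FamilySpec("unbalanced_translocation", "count", "unbalanced_translocation"),
    FamilySpec("LINE", "count", "line"),
    FamilySpec("chromothripsis", "count", "chromothripsis"),
    FamilySpec("deletion_magnitude", "scalar", "deletion_magnitude", 3, "jenks"),
    FamilySpec("duplication_magnitude", "scalar", "duplication_magnitude", 3, "jenks"),
    FamilySpec("segment_size", "lengths", "segment_lengths", 3, "jenks", True),
    FamilySpec("segments_per_5mb", "lengths", "segments_per_window", 3, "gmm", True),
    FamilySpec("oscillation_chain", "lengths", "oscillation_chains", 3, "jenks"),
    FamilySpec("segments_per_arm", "lengths", "segments_per_arm", 3, "jenks"),
    FamilySpec("changepoint", "lengths", "changepoints", 5, "jenks"),
)

LAYOUT_VERSION = "v1"


def layout_columns(layout: tuple[FamilySpec, ...] = DEFAULT_LAYOUT) -> list[str]:
    """The canonical ordered column names (44 for the default layout)."""
    cols = []
    for fam in layout:
        if fam.n_bins == 1:
            cols.append(fam.name)
        else:
            cols.extend(f"{fam.name}_bin{i + 1}" for i in range(fam.n_bins))
    return cols


N_FEATURES = len(layout_columns())  # 44 in the v1 layout


def _family_values(
    fam: FamilySpec,
    sv: SVFeatureCounts,
    cn: CNRawFeatures,
) -> list[float]:
    obj = sv if hasattr(sv, fam.source) else cn
    value = getattr(obj, fam.source)
    if fam.kind == "scalar":
        return [float(value)]
    if fam.kind == "lengths":
        return [float(v) for v in value]
    return [float(value)]


def fit_cohort_models(
    sv_counts: dict[str, SVFeatureCounts],
    cn_raw: dict[str, CNRawFeatures],
    layout: tuple[FamilySpec, ...] = DEFAULT_LAYOUT,
    seed: int = 0,
) -> dict[str, DiscretizationModel]:
    """Fit one frozen discretization model per continuous family by pooling
    values across the extraction samples. Count families get no model."""
    models: dict[str, DiscretizationModel] = {}
    for fam in layout:
        if fam.n_bins == 1:
            continue
        pooled: list[float] = []
        for sample in sv_counts:
            pooled.extend(_family_values(fam, sv_counts[sample], cn_raw[sample]))
        arr = np.asarray(pooled, dtype=float)
        if fam.log_transform:
            arr = np.log10(np.maximum(arr, 1.0))
        breaks: list[float]
        degenerate = False
        n_distinct = len(np.unique(arr)) if len(arr) else 0
        if n_distinct < 2:
            breaks, degenerate = [], True
        elif fam.method == "jenks":
            if n_distinct < fam.n_bins:
                # fewer distinct values than bins: one class per value
                uniq = np.unique(arr)
                breaks, degenerate = [float(u) for u in uniq[:-1]], True
            else:
                breaks = jenks_breaks(arr, fam.n_bins)
        elif fam.method == "gmm":
            if len(arr) < 10:
                breaks, degenerate = quantile_tertile_breaks(arr), True
            else:
                breaks = gmm_bins(arr, max_components=fam.n_bins, seed=seed)
                if len(breaks) != fam.n_bins - 1:
                    breaks = quantile_tertile_breaks(arr)
                    degenerate = True
            if len(breaks) != fam.n_bins - 1:
                degenerate = True
        else:
            raise ValueError(f"unknown method {fam.method!r}")
        models[fam.name] = DiscretizationModel(
            family=fam.name,
            method=fam.method,
            n_bins=fam.n_bins,
            breaks=tuple(breaks),
            log_transform=fam.log_transform,
            degenerate=degenerate,
        )
    return models


def build_feature_matrix(
    sv_counts: dict[str, SVFeatureCounts],
    cn_raw: dict[str, CNRawFeatures],
    models: dict[str, DiscretizationModel],
    layout: tuple[FamilySpec, ...] = DEFAULT_LAYOUT,
) -> pd.DataFrame:
    """Histogram every sample's raw features through the frozen models.

    Returns samples x N_FEATURES nonnegative integer counts; scalar families
    contribute a single count of 1 in their bin.
    """
    columns = layout_columns(layout)
    col_index = {c: i for i, c in enumerate(columns)}
    samples = sorted(sv_counts)
    data = np.zeros((len(samples), len(columns)), dtype=int)
    for row, sample in enumerate(samples):
        sv, cn = sv_counts[sample], cn_raw[sample]
        for fam in layout:
            values = _family_values(fam, sv, cn)
            if fam.n_bins == 1:
                data[row, col_index[fam.name]] = int(values[0])
                continue
            model = models[fam.name]
            if not values:
                continue
            bins = np.clip(model.bin_of(values), 0, fam.n_bins - 1)
            base = col_index[f"{fam.name}_bin1"]
            np.add.at(data[row], base + bins, 1)
    if (data < 0).any():
        raise ValueError("negative feature counts")
    return pd.DataFrame(data, index=samples, columns=columns)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_models(models: dict[str, DiscretizationModel], path: str | Path) -> None:
    payload = {
        name: {
            "family": m.family,
            "method": m.method,
            "n_bins": m.n_bins,
            "breaks": list(m.breaks),
            "log_transform": m.log_transform,
            "degenerate": m.degenerate,
        }
        for name, m in sorted(models.items())
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_models(path: str | Path) -> dict[str, DiscretizationModel]:
    payload = json.loads(Path(path).read_text())
    return {
        name: DiscretizationModel(
            family=d["family"],
            method=d["method"],
            n_bins=d["n_bins"],
            breaks=tuple(d["breaks"]),
            log_transform=d["log_transform"],
            degenerate=d.get("degenerate", False),
        )
        for name, d in payload.items()
    }


def save_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample")


def load_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")
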