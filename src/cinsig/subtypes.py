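"""Subtype discovery and clinical association statistics.

Samples are clustered on their signature exposure fractions by Monti-style
consensus clustering: repeated subsampling, average-linkage hierarchical
clustering under 1 - Pearson distance, and a consensus matrix of
co-clustering frequencies whose own clustering yields the final labels.
Patient-level stability asks whether all of a patient's samples land in one
cluster. A random-forest classifier reproduces the labeling on held-out
cohorts.

Survival machinery: Kaplan-Meier product-limit estimator, the multi-group
log-rank test (observed vs expected with hypergeometric variance), and
Harrell's concordance index are first-class implementations here; Cox
proportional-hazards fitting is delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows get distance 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return np.clip(1.0 - corr, 0.0, 2.0)


@dataclass
class ConsensusResult:
    consensus: np.ndarray  # samples x samples, for the chosen k
    linkage_matrix: np.ndarray
    chosen_k: int
    labels: pd.Series  # sample -> cluster id (1-based)
    cdf_area: dict[int, float]
    delta_area: dict[int, float]


def consensus_cluster(
    exposures: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    n_resamples: int = 1000,
    item_fraction: float = 0.8,
    seed: int = 0,
    k: int | None = None,
    delta_threshold: float = 0.1,
) -> ConsensusResult:
    """Monti consensus clustering of samples by exposure profile.

    ``exposures`` rows are row-normalized internally. Unless ``k`` fixes it,
    the number of clusters is picked by the consensus-CDF elbow: the largest
    k whose relative area increase is still at least ``delta_threshold``.
    """
    n = len(exposures)
    kmin, kmax = k_range
    if k is not None:
        kmin = kmax = k
    if n < 2 * kmax:
        raise ValueError(f"need >= {2 * kmax} samples for k up to {kmax}, got {n}")
    totals = exposures.sum(axis=1)
    X = exposures.div(totals.where(totals > 0, 1.0), axis=0).to_numpy(dtype=float)
    D = _pearson_distance(X)
    rng = np.random.default_rng(seed)
    m = max(int(round(item_fraction * n)), kmax + 1)

    ks = list(range(kmin, kmax + 1))
    together = {kk: np.zeros((n, n)) for kk in ks}
    co_sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="average")
        for kk in ks:
            labels = fcluster(Z, t=kk, criterion="maxclust")
            for c in np.unique(labels):
                members = idx[labels == c]
                together[kk][np.ix_(members, members)] += 1

    consensus = {}
    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn("some sample pairs were never co-sampled; consensus set to 0")
    for kk in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sampled > 0, together[kk] / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        consensus[kk] = (M + M.T) / 2

    # CDF area over upper-triangular consensus entries (Monti's A(k))
    areas: dict[int, float] = {}
    for kk in ks:
        vals = consensus[kk][np.triu_indices(n, k=1)]
        xs = np.sort(vals)
        # area under empirical CDF on [0, 1]
        grid = np.concatenate([[0.0], xs, [1.0]])
        cdf = np.concatenate([[0.0], np.arange(1, len(xs) + 1) / len(xs), [1.0]])
        areas[kk] = float(np.sum(np.diff(grid) * cdf[:-1]))
    delta: dict[int, float] = {}
    for i, kk in enumerate(ks):
        if i == 0:
            delta[kk] = areas[kk]
        else:
            prev = areas[ks[i - 1]]
            delta[kk] = (areas[kk] - prev) / prev if prev > 0 else 0.0
    if k is not None:
        chosen = k
    else:
        eligible = [kk for kk in ks if delta[kk] >= delta_threshold]
        chosen = max(eligible) if eligible else ks[0]

    M = consensus[chosen]
    Z = linkage(squareform(np.clip(1.0 - M, 0.0, 1.0), checks=False), method="average")
    labels = fcluster(Z, t=chosen, criterion="maxclust")
    return ConsensusResult(
        consensus=M,
        linkage_matrix=Z,
        chosen_k=chosen,
        labels=pd.Series(labels, index=exposures.index, name="cluster"),
        cdf_area=areas,
        delta_area=delta,
    )


# ---------------------------------------------------------------------------
# patient-level stability
# ---------------------------------------------------------------------------

@dataclass
class SubtypeLabeling:
    sample_subtype: pd.Series
    patient_subtype: dict[str, str]  # patient -> subtype label or "unstable"
    stability_fraction: float


def patient_stability(
    labels: pd.Series, sample_to_patient: dict[str, str]
) -> SubtypeLabeling:
    """Fraction of patients whose samples all share one cluster.

    Single-sample patients are trivially stable; unstable patients get the
    label "unstable".
    """
    per_patient: dict[str, set] = {}
    for sample, cluster in labels.items():
        patient = sample_to_patient[sample]
        per_patient.setdefault(patient, set()).add(cluster)
    patient_subtype = {
        pat: (str(next(iter(cl))) if len(cl) == 1 else "unstable")
        for pat, cl in per_patient.items()
    }
    n_stable = sum(1 for v in patient_subtype.values() if v != "unstable")
    return SubtypeLabeling(
        sample_subtype=labels,
        patient_subtype=patient_subtype,
        stability_fraction=n_stable / len(per_patient) if per_patient else float("nan"),
    )


# ---------------------------------------------------------------------------
# validation classifier
# ---------------------------------------------------------------------------

def train_subtype_classifier(
    exposures_train: pd.DataFrame,
    labels_train: pd.Series,
    seed: int = 0,
    n_estimators: int = 500,
) -> RandomForestClassifier:
    """Random forest on exposure fractions; OOB accuracy is stored on the
    fitted model (``oob_score_``). Requires >= 5 samples per class."""
    counts = labels_train.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    if (counts < 5).any():
        small = counts[counts < 5].index.tolist()
        raise ValueError(f"classes with < 5 samples: {small}")
    totals = exposures_train.sum(axis=1)
    X = exposures_train.div(totals.where(totals > 0, 1.0), axis=0)
    clf = RandomForestClassifier(
        n_estimators=n_estimators, oob_score=True, random_state=seed
    )
    clf.fit(X.to_numpy(), labels_train.loc[X.index].to_numpy())
    return clf


def classify_samples(
    clf: RandomForestClassifier, exposures_new: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    totals = exposures_new.sum(axis=1)
    X = exposures_new.div(totals.where(totals > 0, 1.0), axis=0)
    labels = pd.Series(clf.predict(X.to_numpy()), index=exposures_new.index)
    probs = pd.DataFrame(
        clf.predict_proba(X.to_numpy()), index=exposures_new.index, columns=clf.classes_
    )
    return labels, probs


# ---------------------------------------------------------------------------
# survival statistics
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit curve."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def at(self, t: float) -> float:
        """S(t): survival just after time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Product-limit estimator; with no censoring it equals the empirical
    survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("survival times must be nonnegative")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events]) if events.any() else np.array([])
    surv, at_risk = [], []
    s = 1.0
    for t in uniq:
        n_t = int(np.sum(times >= t))
        d_t = int(np.sum((times == t) & events))
        s *= 1.0 - d_t / n_t
        surv.append(s)
        at_risk.append(n_t)
    return SurvivalCurve(
        event_times=uniq,
        at_risk=np.asarray(at_risk),
        survival=np.asarray(surv),
        censor_times=np.sort(times[~events]),
    )


def logrank(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    """Multi-group log-rank test.

    ``groups`` is a list of (times, events). Returns (chi2, p) with
    groups - 1 degrees of freedom; the statistic compares observed event
    counts with their hypergeometric expectations at each event time.
    """
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=bool) for _, e in groups]
    all_event_times = np.unique(np.concatenate([t[e] for t, e in zip(times, events)]))
    if len(all_event_times) == 0:
        return 0.0, 1.0
    OmE = np.zeros(g)
    V = np.zeros((g, g))
    for t in all_event_times:
        n_g = np.array([np.sum(tt >= t) for tt in times], dtype=float)
        d_g = np.array(
            [np.sum((tt == t) & ee) for tt, ee in zip(times, events)], dtype=float
        )
        n, d = n_g.sum(), d_g.sum()
        if n <= 1:
            continue
        e_g = d * n_g / n
        OmE += d_g - e_g
        factor = d * (n - d) / (n * n * (n - 1))
        V += factor * (np.diag(n_g * n) - np.outer(n_g, n_g))
    # use the first g-1 components (the last is linearly dependent)
    v = OmE[:-1]
    Vsub = V[:-1, :-1]
    if np.allclose(v, 0):
        return 0.0, 1.0
    chi2 = float(v @ np.linalg.pinv(Vsub) @ v)
    p = float(chi2_dist.sf(chi2, df=g - 1))
    return chi2, p


def concordance_index(
    risk: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Harrell's C: among comparable pairs (the earlier time is an event),
    the fraction where the earlier-event subject has the higher risk score;
    risk ties count one half."""
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = len(risk)
    concordant = comparable = 0.0
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            # comparable: i has the strictly earlier event; tied times skipped
            if times[j] > times[i]:
                comparable += 1
                if risk[i] > risk[j]:
                    concordant += 1
                elif risk[i] == risk[j]:
                    concordant += 0.5
    if comparable == 0:
        return float("nan")
    return concordant / comparable


def cox_ph(
    df: pd.DataFrame, duration_col: str, event_col: str
) -> "pd.DataFrame":
    """Thin wrapper over lifelines' Cox proportional-hazards fit; returns the
    summary table with the model concordance attached as an attribute."""
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    summary = cph.summary.copy()
    summary.attrs["concordance"] = float(cph.concordance_index_)
    return summary


# ---------------------------------------------------------------------------
# enrichment and grouping helpers
# ---------------------------------------------------------------------------

def median_split(patient_activity: pd.Series) -> pd.Series:
    """Split per-patient activities at the cohort median: strictly above ->
    'high', at or below -> 'low'."""
    med = patient_activity.median()
    return pd.Series(
        np.where(patient_activity > med, "high", "low"), index=patient_activity.index
    )


def summarize_per_patient(
    sample_values: pd.Series, sample_to_patient: dict[str, str]
) -> pd.Series:
    """Per-patient sample median of a per-sample quantity."""
    df = pd.DataFrame(
        {"value": sample_values, "patient": [sample_to_patient[s] for s in sample_values.index]}
    )
    return df.groupby("patient")["value"].median()


def mann_whitney(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null for small groups, tie-corrected
    normal approximation otherwise."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if min(len(x), len(y)) <= exact_max_n and not _has_ties(x, y) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return len(np.unique(combined)) < len(combined)


def enrichment_tests(
    exposures: pd.DataFrame, annotation: pd.Series
) -> pd.DataFrame:
    """Mann-Whitney enrichment of each signature activity in a binary
    annotation, BH-corrected across the signature family."""
    ann = annotation.loc[exposures.index].astype(bool)
    if ann.all() or (~ann).all():
        raise ValueError("annotation must have samples in both classes")
    rows = []
    for sig in exposures.columns:
        u, p = mann_whitney(
            exposures.loc[ann, sig].to_numpy(), exposures.loc[~ann, sig].to_numpy()
        )
        rows.append({"signature": sig, "U": u, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def presence_absence(counts: np.ndarray | pd.Series) -> np.ndarray:
    """Convert event counts to presence (count > 0) / absence indicators."""
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return (arr > 0).astype(int)
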