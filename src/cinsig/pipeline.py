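"""End-to-end orchestration: simulate/load -> features -> extract -> assign ->
cluster -> classify -> survival -> report.

``PipelineConfig`` is validated up front (unknown keys rejected); every
stage writes its table under the output directory and the final manifest
records the seed and a content hash of the configuration, so a rerun with
the same config and seed reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cn_features import CNRawFeatures, cn_raw_features
from .discretize import (
    DEFAULT_LAYOUT,
    LAYOUT_VERSION,
    build_feature_matrix,
    fit_cohort_models,
    save_feature_matrix,
    save_models,
)
from .genome import GenomeModel
from .selection import correct_purity, select_extraction_samples
from .signatures import assign_activities, exposure_fractions, extract_signatures
from .simulate import SyntheticCohort, simulate_cohort
from .subtypes import (
    consensus_cluster,
    concordance_index,
    km_estimate,
    logrank,
    patient_stability,
    train_subtype_classifier,
)
from .sv_events import SVFeatureCounts, sv_feature_counts


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    # cohort
    n_patients: int = 40
    alpha: float = 0.3
    # selection
    purity_threshold: float = 0.20
    exclude_relapse: bool = False
    # SV features
    proximity: int = 5_000
    span_threshold: int = 5_000_000
    # NMF
    rank_range: tuple[int, int] = (2, 8)
    n_bootstraps: int = 20
    n_inits: int = 2
    nmf_max_iter: int = 2_000
    stability_threshold: float = 0.8
    # clustering
    k_clusters: int | None = None
    k_range: tuple[int, int] = (2, 6)
    n_resamples: int = 250
    # survival
    endpoint: str = "pfi"  # pfi | os

    _KNOWN = None  # populated below

    def validate(self) -> None:
        if not 0.0 <= self.purity_threshold <= 1.0:
            raise ValueError(f"purity_threshold {self.purity_threshold} outside [0, 1]")
        if self.proximity <= 0 or self.span_threshold <= 0:
            raise ValueError("proximity and span_threshold must be positive")
        if self.rank_range[0] < 1 or self.rank_range[0] > self.rank_range[1]:
            raise ValueError(f"bad rank_range {self.rank_range}")
        if self.endpoint not in ("pfi", "os"):
            raise ValueError(f"endpoint must be pfi or os, got {self.endpoint!r}")
        if self.n_patients < 0 or self.n_bootstraps < 1 or self.n_inits < 1:
            raise ValueError("cohort/NMF sizes must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()
                 if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rank_range" in d:
            d = {**d, "rank_range": tuple(d["rank_range"])}
        if "k_range" in d:
            d = {**d, "k_range": tuple(d["k_range"])}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        """Hash of the scientific configuration; output paths excluded."""
        payload = {k: v for k, v in asdict(self).items()
                   if not k.startswith("_") and k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def compute_raw_features(
    cohort: SyntheticCohort,
    genome: GenomeModel,
    samples: list[str] | None = None,
    proximity: int = 5_000,
    span_threshold: int = 5_000_000,
) -> tuple[dict[str, SVFeatureCounts], dict[str, CNRawFeatures]]:
    """Per-sample SV and CN raw features for the requested samples."""
    wanted = set(samples) if samples is not None else None
    sv: dict[str, SVFeatureCounts] = {}
    cn: dict[str, CNRawFeatures] = {}
    for bundle in cohort.samples:
        sid = bundle.profile.sample
        if wanted is not None and sid not in wanted:
            continue
        sv[sid] = sv_feature_counts(
            sid, bundle.junctions, bundle.segments, genome,
            proximity=proximity, span_threshold=span_threshold,
        )
        cn[sid] = cn_raw_features(
            sid, bundle.segments, bundle.profile.ploidy, genome
        )
    return sv, cn


def run_pipeline(
    config: PipelineConfig,
    cohort: SyntheticCohort | None = None,
    genome: GenomeModel | None = None,
) -> dict:
    """Run all stages and write the report bundle; returns the manifest dict."""
    config.validate()
    genome = genome or GenomeModel.grch38()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: cohort ---------------------------------------------------
    if cohort is None:
        cohort = simulate_cohort(
            config.n_patients, genome=genome, alpha=config.alpha, seed=config.seed
        )
    cohort.exposures.to_csv(outdir / "truth_exposures.tsv", sep="\t",
                            index_label="sample")

    # --- stage 2: selection + features --------------------------------------
    profiles = correct_purity(cohort.profiles())
    extraction = select_extraction_samples(
        profiles, config.purity_threshold, exclude_relapse=config.exclude_relapse
    )
    eligible = sorted(
        p.sample for p in profiles if p.purity >= config.purity_threshold
    )
    if len(extraction) < 4:
        raise RuntimeError("stage features: too few extraction samples")
    sv, cn = compute_raw_features(
        cohort, genome, samples=eligible,
        proximity=config.proximity, span_threshold=config.span_threshold,
    )
    models = fit_cohort_models(
        {s: sv[s] for s in extraction}, {s: cn[s] for s in extraction},
        DEFAULT_LAYOUT, seed=config.seed,
    )
    save_models(models, outdir / "discretization_models.json")
    matrix = build_feature_matrix(sv, cn, models, DEFAULT_LAYOUT)
    save_feature_matrix(matrix, outdir / "feature_matrix.tsv")

    # --- stage 3: extraction -------------------------------------------------
    V_extract = matrix.loc[extraction]
    signatures, report = extract_signatures(
        V_extract,
        rank_range=config.rank_range,
        n_bootstraps=config.n_bootstraps,
        n_inits=config.n_inits,
        seed=config.seed,
        stability_threshold=config.stability_threshold,
        max_iter=config.nmf_max_iter,
    )
    signatures.to_csv(outdir / "signatures.tsv", sep="\t", index_label="feature")
    report.to_json(outdir / "extraction_report.json")

    # --- stage 4: assignment -------------------------------------------------
    exposures = assign_activities(matrix, signatures)
    exposures.to_csv(outdir / "exposures.tsv", sep="\t", index_label="sample")

    # --- stage 5: consensus clustering --------------------------------------
    fractions = exposure_fractions(exposures)
    result = consensus_cluster(
        fractions, k_range=config.k_range, n_resamples=config.n_resamples,
        seed=config.seed, k=config.k_clusters,
    )
    labeling = patient_stability(result.labels, cohort.sample_to_patient)
    labels_df = pd.DataFrame(
        {
            "sample": result.labels.index,
            "patient": [cohort.sample_to_patient[s] for s in result.labels.index],
            "subtype": result.labels.to_numpy(),
        }
    )
    labels_df["stable"] = [
        labeling.patient_subtype[p] != "unstable" for p in labels_df["patient"]
    ]
    labels_df.to_csv(outdir / "subtype_labels.tsv", sep="\t", index=False)

    # --- stage 6: validation classifier --------------------------------------
    class_counts = result.labels.value_counts()
    oob = float("nan")
    if len(class_counts) >= 2 and (class_counts >= 5).all():
        clf = train_subtype_classifier(fractions, result.labels, seed=config.seed)
        oob = float(clf.oob_score_)

    # --- stage 7: survival ----------------------------------------------------
    clin = {c.patient: c for c in cohort.clinical}
    time_attr = "pfi_days" if config.endpoint == "pfi" else "os_days"
    event_attr = "pfi_event" if config.endpoint == "pfi" else "os_event"
    groups = {}
    for pat, subtype in labeling.patient_subtype.items():
        if subtype == "unstable" or pat not in clin:
            continue
        groups.setdefault(subtype, []).append(
            (getattr(clin[pat], time_attr), getattr(clin[pat], event_attr))
        )
    survival: dict = {"endpoint": config.endpoint}
    usable = {k: v for k, v in groups.items() if len(v) >= 3}
    if len(usable) >= 2:
        arrs = [
            (np.array([t for t, _ in v]), np.array([e for _, e in v]))
            for v in usable.values()
        ]
        chi2, p = logrank(arrs)
        survival.update({"logrank_chi2": chi2, "logrank_p": p,
                         "groups": {k: len(v) for k, v in usable.items()}})
        curves = {k: km_estimate(t, e) for k, (t, e) in zip(usable, arrs)}
        survival["median_survival"] = {
            k: _median_survival(c) for k, c in curves.items()
        }
    # risk score = 1 - HRD-ness proxy: mean activity-weighted hazard is not
    # observable here, so report C of subtype-mean PFI ordering
    pat_rows = [
        (pat, subtype, getattr(clin[pat], time_attr), getattr(clin[pat], event_attr))
        for pat, subtype in labeling.patient_subtype.items()
        if subtype != "unstable" and pat in clin
    ]
    if pat_rows and len({r[1] for r in pat_rows}) >= 2:
        df = pd.DataFrame(pat_rows, columns=["patient", "subtype", "time", "event"])
        mean_time = df.groupby("subtype")["time"].mean()
        risk = df["subtype"].map(lambda s: -mean_time[s]).to_numpy()
        survival["concordance_index"] = concordance_index(
            risk, df["time"].to_numpy(), df["event"].to_numpy()
        )
    (outdir / "survival.json").write_text(
        json.dumps(survival, indent=2, sort_keys=True, default=float) + "\n"
    )

    # --- stage 8: manifest ----------------------------------------------------
    manifest = {
        "version": __version__,
        "layout_version": LAYOUT_VERSION,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_samples": len(matrix),
        "n_extraction_samples": len(extraction),
        "selected_rank": report.selected_rank,
        "rank_stability": {str(k): v for k, v in report.stability.items()},
        "chosen_k_clusters": result.chosen_k,
        "patient_stability_fraction": labeling.stability_fraction,
        "classifier_oob_accuracy": oob,
        "survival": survival,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n"
    )
    return manifest


def _median_survival(curve) -> float:
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.event_times[below[0]]) if len(below) else float("inf")
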