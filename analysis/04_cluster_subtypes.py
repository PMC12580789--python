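#!/usr/bin/env python
"""Consensus-cluster the cohort on signature exposures into molecular
subtypes, measure patient-level stability, and train the validation
classifier.

Outputs subtype labels, the per-patient stability fraction, and the
random-forest out-of-bag accuracy under results/subtypes/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from cinsig.io import read_profiles
from cinsig.signatures import exposure_fractions
from cinsig.subtypes import (
    classify_samples,
    consensus_cluster,
    patient_stability,
    train_subtype_classifier,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11
OUT = Path("results/subtypes")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exposures = pd.read_csv("results/signatures/exposures.tsv", sep="\t",
                            index_col="sample")
    profiles = read_profiles("results/cohort/metadata.tsv")
    sample_to_patient = {p.sample: p.patient for p in profiles}

    fractions = exposure_fractions(exposures)
    result = consensus_cluster(fractions, k_range=(2, 6), n_resamples=500,
                               seed=SEED)
    labeling = patient_stability(result.labels, sample_to_patient)
    print(f"consensus clustering chose k={result.chosen_k}; "
          f"{labeling.stability_fraction:.0%} of patients have all samples "
          "in one cluster")

    labels_df = pd.DataFrame({
        "sample": result.labels.index,
        "patient": [sample_to_patient[s] for s in result.labels.index],
        "subtype": result.labels.to_numpy(),
    })
    labels_df["stable"] = [
        labeling.patient_subtype[p] != "unstable" for p in labels_df["patient"]
    ]
    labels_df.to_csv(OUT / "subtype_labels.tsv", sep="\t", index=False)

    counts = result.labels.value_counts()
    summary = {
        "chosen_k": int(result.chosen_k),
        "stability_fraction": labeling.stability_fraction,
        "cluster_sizes": {str(k): int(v) for k, v in counts.items()},
    }
    if len(counts) >= 2 and (counts >= 5).all():
        clf = train_subtype_classifier(fractions, result.labels, seed=SEED)
        predicted, _ = classify_samples(clf, fractions)
        summary["classifier_oob_accuracy"] = float(clf.oob_score_)
        print(f"random-forest validation classifier: OOB accuracy "
              f"{clf.oob_score_:.2f}")
    json.dump(summary, open(OUT / "summary.json", "w"), indent=2)


if __name__ == "__main__":
    main()
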