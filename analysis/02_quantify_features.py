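#!/usr/bin/env python
"""Quantify the 44 CIN features and build the extraction-ready count matrix.

Reads the simulated cohort tables from results/cohort/, applies the purity
correction and per-(patient, tissue-area) extraction selection, fits the
cohort discretization models (Jenks natural breaks; Gaussian mixture for
segments-per-5Mb) on the extraction samples, and writes the samples x 44
feature matrix plus the frozen models under results/features/.
"""

import json
import sys
from collections import defaultdict
from pathlib import Path

from cinsig.cn_features import cn_raw_features
from cinsig.discretize import (
    build_feature_matrix,
    fit_cohort_models,
    save_feature_matrix,
    save_models,
)
from cinsig.genome import GenomeModel
from cinsig.io import read_junctions, read_profiles, read_segments
from cinsig.selection import correct_purity, select_extraction_samples
from cinsig.sv_events import sv_feature_counts

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11
COHORT = Path("results/cohort")
OUT = Path("results/features")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = GenomeModel.grch38()
    segments = read_segments(COHORT / "segments.tsv")
    junctions = read_junctions(COHORT / "junctions.bedpe")
    profiles = correct_purity(read_profiles(COHORT / "metadata.tsv"))

    extraction = select_extraction_samples(profiles, purity_threshold=0.20)
    eligible = sorted(p.sample for p in profiles if p.purity >= 0.20)
    print(f"{len(profiles)} samples -> {len(eligible)} above purity 0.20, "
          f"{len(extraction)} selected for extraction "
          "(highest purity per patient x tissue area)")

    segs_by, juncs_by = defaultdict(list), defaultdict(list)
    for s in segments:
        segs_by[s.sample].append(s)
    for j in junctions:
        juncs_by[j.sample].append(j)
    ploidy = {p.sample: p.ploidy for p in profiles}

    sv = {s: sv_feature_counts(s, juncs_by[s], segs_by[s], genome)
          for s in eligible}
    cn = {s: cn_raw_features(s, segs_by[s], ploidy[s], genome)
          for s in eligible}

    models = fit_cohort_models(
        {s: sv[s] for s in extraction}, {s: cn[s] for s in extraction},
        seed=SEED,
    )
    save_models(models, OUT / "discretization_models.json")
    matrix = build_feature_matrix(sv, cn, models)
    save_feature_matrix(matrix, OUT / "feature_matrix.tsv")
    json.dump(extraction, open(OUT / "extraction_samples.json", "w"), indent=2)

    print(f"feature matrix: {matrix.shape[0]} samples x {matrix.shape[1]} features, "
          f"median row total {int(matrix.sum(axis=1).median())} counts")
    for fam, m in sorted(models.items()):
        tag = " (degenerate fallback)" if m.degenerate else ""
        print(f"  {fam}: {m.method}, breaks {[round(b, 2) for b in m.breaks]}{tag}")


if __name__ == "__main__":
    main()
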