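"""Synthetic tumor-genome cohorts with known mutational-process exposures.

Each sample's segment and junction profile is generated as a mixture of six
named process templates that caricature recognizable genomic phenotypes:

* ``BRCA1like`` — very small deletions (mass concentrated below 200 bp) and
  1-45 kb duplications on a highly fragmented near-diploid genome.
* ``BRCA2like`` — small-to-medium deletions (< 36 kb) and an elevated number
  of unbalanced translocations.
* ``TandemDup`` — a tandem-duplicator phenotype: many short-medium
  duplications and long copy-number oscillation chains.
* ``Amplifier`` — focal high-level amplification on one chromosome, high
  changepoints, and inter-chromosomal events.
* ``WGDRearranged`` — tetraploid baseline with heavy segment fragmentation.
* ``SimpleGenome`` — near-diploid with almost no structural variants.

Generated profiles are junction-segment concordant by construction: every
same-chromosome DEL/DUP junction lands on segment boundaries with the
corresponding copy-number step (a validator is provided). Copy-number-
decreasing intervals are placed disjointly so the profile never clamps at
zero and no step is lost.

Cohorts attach purity/ploidy metadata and subtype-linked survival times so
the selection rules, clustering, and survival statistics all have signal.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cn_features import round_half_up
from .genome import GenomeModel
from .types import ClinicalRecord, CopyNumberSegment, Junction, SampleProfile, make_junction

TEMPLATE_NAMES = (
    "BRCA1like",
    "BRCA2like",
    "TandemDup",
    "Amplifier",
    "WGDRearranged",
    "SimpleGenome",
)


@dataclass(frozen=True)
class ProcessTemplate:
    """Event rates and size distributions of one mutational process."""

    name: str
    ploidy: float
    # expected events per genome
    del_rate: float
    dup_rate: float
    reciprocal_rate: float
    tra_rate: float  # unbalanced translocations
    insertion_rate: float
    line_rate: float
    complex_rate: float  # chromothripsis-like clustered events
    fragmentation_rate: float  # small CN-only alterations
    oscillation_rate: float  # CN-only alternating chains
    focal_amp_rate: float
    # log-normal length parameters (natural log of bp)
    del_len: tuple[float, float] = (np.log(10_000), 1.0)
    dup_len: tuple[float, float] = (np.log(50_000), 1.0)
    frag_len: tuple[float, float] = (np.log(800_000), 0.8)
    # probability a fragmentation step is +/-2 copies instead of 1
    big_step_prob: float = 0.0
    # copy-number step of deletion / duplication events
    del_delta: int = 1
    dup_delta: int = 1
    # mean number of extra stacked junctions per duplication locus (pyrgo-like)
    dup_stack: float = 0.0
    # how many chromosomes the process concentrates on (None = genome-wide)
    n_active_chroms: int | None = None
    # per-patient log hazard for the survival link
    log_hazard: float = 0.0


def builtin_templates() -> dict[str, ProcessTemplate]:
    """The six built-in process templates at their default calibration."""
    return {
        "BRCA1like": ProcessTemplate(
            name="BRCA1like", ploidy=2.0,
            del_rate=150, dup_rate=10, reciprocal_rate=12, tra_rate=1,
            insertion_rate=2, line_rate=1, complex_rate=0.1,
            fragmentation_rate=40, oscillation_rate=0.3, focal_amp_rate=0.0,
            del_len=(np.log(100), 1.0),       # >= 60% of mass below 200 bp
            dup_len=(np.log(8_000), 1.0),     # bulk between 1 and 45 kb
            frag_len=(np.log(150_000), 0.8),
            n_active_chroms=6,
            log_hazard=-0.9,
        ),
        "BRCA2like": ProcessTemplate(
            name="BRCA2like", ploidy=2.0,
            del_rate=70, dup_rate=10, reciprocal_rate=1, tra_rate=20,
            insertion_rate=0.5, line_rate=0.5, complex_rate=0.1,
            fragmentation_rate=20, oscillation_rate=0.2, focal_amp_rate=0.0,
            del_len=(np.log(5_000), 1.0),     # essentially all below 36 kb
            dup_len=(np.log(40_000), 0.8),
            frag_len=(np.log(500_000), 0.8),
            del_delta=2,
            n_active_chroms=14,
            log_hazard=-1.1,
        ),
        "TandemDup": ProcessTemplate(
            name="TandemDup", ploidy=2.2,
            del_rate=6, dup_rate=60, reciprocal_rate=1, tra_rate=2,
            insertion_rate=0.5, line_rate=5, complex_rate=0.2,
            fragmentation_rate=6, oscillation_rate=8.0, focal_amp_rate=0.1,
            del_len=(np.log(20_000), 1.0),
            dup_len=(np.log(30_000), 0.8),
            frag_len=(np.log(250_000), 0.8),
            dup_delta=3,
            dup_stack=1.5,
            n_active_chroms=9,
            log_hazard=0.3,
        ),
        "Amplifier": ProcessTemplate(
            name="Amplifier", ploidy=2.5,
            del_rate=3, dup_rate=6, reciprocal_rate=1, tra_rate=8,
            insertion_rate=1, line_rate=0.5, complex_rate=1.5,
            fragmentation_rate=2, oscillation_rate=0.3, focal_amp_rate=7.0,
            del_len=(np.log(100_000), 1.2),
            dup_len=(np.log(500_000), 1.0),
            frag_len=(np.log(1_500_000), 1.0),
            big_step_prob=0.5,
            del_delta=3,
            dup_delta=3,
            n_active_chroms=4,
            log_hazard=0.5,
        ),
        "WGDRearranged": ProcessTemplate(
            name="WGDRearranged", ploidy=4.0,
            del_rate=30, dup_rate=30, reciprocal_rate=3, tra_rate=8,
            insertion_rate=1, line_rate=1, complex_rate=0.3,
            fragmentation_rate=60, oscillation_rate=0.5, focal_amp_rate=0.3,
            del_len=(np.log(2_000_000), 1.2),
            dup_len=(np.log(8_000_000), 1.0),
            frag_len=(np.log(4_000_000), 1.0),
            big_step_prob=0.5,
            log_hazard=0.4,
        ),
        "SimpleGenome": ProcessTemplate(
            name="SimpleGenome", ploidy=2.0,
            del_rate=0.5, dup_rate=0.5, reciprocal_rate=0.1, tra_rate=0.3,
            insertion_rate=0.1, line_rate=0.1, complex_rate=0.0,
            fragmentation_rate=1.5, oscillation_rate=0.0, focal_amp_rate=0.0,
            del_len=(np.log(50_000), 1.0),
            dup_len=(np.log(50_000), 1.0),
            frag_len=(np.log(1_000_000), 0.5),
            log_hazard=-0.4,
        ),
    }


@dataclass
class SampleBundle:
    """One simulated sample: genome profile, metadata, and the truth."""

    profile: SampleProfile
    segments: list[CopyNumberSegment]
    junctions: list[Junction]
    weights: dict[str, float]


@dataclass
class SyntheticCohort:
    samples: list[SampleBundle]
    clinical: list[ClinicalRecord]
    exposures: pd.DataFrame  # ground-truth mixture weights, rows sum to 1
    config: dict
    seed: int

    @property
    def sample_to_patient(self) -> dict[str, str]:
        return {b.profile.sample: b.profile.patient for b in self.samples}

    def all_segments(self) -> list[CopyNumberSegment]:
        return [s for b in self.samples for s in b.segments]

    def all_junctions(self) -> list[Junction]:
        return [j for b in self.samples for j in b.junctions]

    def profiles(self) -> list[SampleProfile]:
        return [b.profile for b in self.samples]

    def save_config(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.config, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# single-sample generator
# ---------------------------------------------------------------------------

def _pick_chrom(genome: GenomeModel, rng: np.random.Generator) -> str:
    lengths = np.array([genome.lengths[c] for c in genome.chromosomes], dtype=float)
    return str(rng.choice(np.asarray(genome.chromosomes), p=lengths / lengths.sum()))


def _lognormal_len(params: tuple[float, float], rng: np.random.Generator) -> int:
    mu, sigma = params
    return max(50, int(rng.lognormal(mu, sigma)))


class _IntervalBook:
    """Tracks copy-number-altering intervals per chromosome.

    Negative (CN-decreasing) intervals are kept mutually disjoint so the
    profile never dips below baseline-1 and no junction step can cancel.
    """

    def __init__(self, genome: GenomeModel, rng: np.random.Generator) -> None:
        self.genome = genome
        self.rng = rng
        self.pos: dict[str, list[tuple[int, int, int]]] = {}
        self.neg: dict[str, list[tuple[int, int, int]]] = {}

    def add_positive(self, chrom: str, start: int, end: int, delta: int) -> None:
        self.pos.setdefault(chrom, []).append((start, end, delta))

    def try_add_negative(self, chrom: str, start: int, end: int, delta: int = 1) -> bool:
        existing = self.neg.setdefault(chrom, [])
        for s, e, _ in existing:
            if start < e and s < end:
                return False
        existing.append((start, end, delta))
        return True

    def place_negative(self, chrom: str, length: int, delta: int = 1,
                       tries: int = 20) -> tuple[int, int] | None:
        limit = self.genome.lengths[chrom] - length - 1_000_000
        if limit <= 1_000_000:
            return None
        for _ in range(tries):
            start = int(self.rng.integers(1_000_000, limit))
            if self.try_add_negative(chrom, start, start + length, delta):
                return start, start + length
        return None

    def build_segments(self, sample: str, baseline: dict[str, int]
                       ) -> list[CopyNumberSegment]:
        segments: list[CopyNumberSegment] = []
        for chrom in self.genome.chromosomes:
            events: list[tuple[int, int]] = []  # (pos, delta at pos going right)
            for s, e, d in self.pos.get(chrom, []):
                events.append((s, d))
                events.append((e, -d))
            for s, e, d in self.neg.get(chrom, []):
                events.append((s, -d))
                events.append((e, d))
            cuts = sorted({0, self.genome.lengths[chrom]}
                          | {p for p, _ in events})
            deltas: dict[int, int] = {}
            for p, d in events:
                deltas[p] = deltas.get(p, 0) + d
            cn = baseline[chrom]
            for a, b in zip(cuts, cuts[1:]):
                cn += deltas.get(a, 0)
                segments.append(
                    CopyNumberSegment(sample, chrom, a, b, float(max(cn, 0)))
                )
        return segments


def _simulate_events(
    sample: str,
    weights: dict[str, float],
    genome: GenomeModel,
    rng: np.random.Generator,
    templates: dict[str, ProcessTemplate],
) -> tuple[list[CopyNumberSegment], list[Junction]]:
    book = _IntervalBook(genome, rng)
    junctions: list[Junction] = []
    ploidy = sum(w * templates[t].ploidy for t, w in weights.items())
    baseline = {c: max(round_half_up(ploidy), 1) for c in genome.chromosomes}

    for tname, w in weights.items():
        if w <= 0:
            continue
        tpl = templates[tname]

        # regional instability: concentrate this process on a per-sample
        # subset of chromosomes when the template declares one
        if tpl.n_active_chroms is not None:
            lengths = np.array([genome.lengths[c] for c in genome.chromosomes], float)
            pool = list(
                rng.choice(
                    np.asarray(genome.chromosomes),
                    size=min(tpl.n_active_chroms, len(genome.chromosomes)),
                    replace=False,
                    p=lengths / lengths.sum(),
                )
            )
        else:
            pool = None

        def pick(local_rng=rng):
            if pool is None:
                return _pick_chrom(genome, local_rng)
            return str(local_rng.choice(np.asarray(pool)))

        for _ in range(rng.poisson(w * tpl.del_rate)):
            chrom = pick()
            length = _lognormal_len(tpl.del_len, rng)
            # a loss deeper than the baseline would clamp at zero and erase
            # steps of events nested inside it
            placed = book.place_negative(
                chrom, length, delta=min(tpl.del_delta, baseline[chrom])
            )
            if placed is None:
                continue
            s, e = placed
            junctions.append(make_junction(sample, chrom, s, "+", chrom, e, "-"))

        for _ in range(rng.poisson(w * tpl.dup_rate)):
            chrom = pick()
            length = _lognormal_len(tpl.dup_len, rng)
            length = min(length, (genome.lengths[chrom] - 2_100_000) // 2)
            s = int(rng.integers(1_000_000, genome.lengths[chrom] - length - 1_000_000))
            n_stack = 1 + (int(rng.poisson(tpl.dup_stack)) if tpl.dup_stack > 0 else 0)
            for _i in range(n_stack):
                off_s = int(rng.integers(0, 1_500)) if _i else 0
                off_e = int(rng.integers(0, 1_500)) if _i else 0
                book.add_positive(chrom, s + off_s, s + length + off_e, tpl.dup_delta)
                junctions.append(
                    make_junction(sample, chrom, s + off_s, "-",
                                  chrom, s + length + off_e, "+")
                )

        for _ in range(rng.poisson(w * tpl.reciprocal_rate)):
            chrom = pick()
            sep = int(min(rng.lognormal(np.log(2e6), 1.0), 3e7)) + 10_000
            s = int(rng.integers(1_000_000, genome.lengths[chrom] - sep - 1_100_000))
            d1, d2 = int(rng.integers(100, 2_000)), int(rng.integers(100, 2_000))
            junctions.append(
                make_junction(sample, chrom, s, "+", chrom, s + sep, "+", svtype="INV")
            )
            junctions.append(
                make_junction(
                    sample, chrom, s + d1, "-", chrom, s + sep + d2, "-", svtype="INV"
                )
            )

        for _ in range(rng.poisson(w * tpl.tra_rate)):
            c1 = _pick_chrom(genome, rng)
            c2 = _pick_chrom(genome, rng)
            if c1 == c2:
                continue
            loss_len = int(rng.integers(1_000_000, 6_000_000))
            placed = book.place_negative(
                c1, loss_len, delta=min(tpl.del_delta, baseline[c1])
            )
            if placed is None:
                continue
            p1 = placed[0]
            p2 = int(rng.integers(1_000_000, genome.lengths[c2] - 1_000_000))
            junctions.append(make_junction(sample, c1, p1, "+", c2, p2, "-"))

        for kind in ("insertion", "line"):
            rate = tpl.insertion_rate if kind == "insertion" else tpl.line_rate
            for _ in range(rng.poisson(w * rate)):
                cd = _pick_chrom(genome, rng)
                ca = _pick_chrom(genome, rng)
                if cd == ca:
                    continue
                donor_len = int(rng.integers(500, 50_000))
                d1 = int(rng.integers(1_000_000, genome.lengths[cd] - donor_len - 1_000_000))
                p = int(rng.integers(1_000_000, genome.lengths[ca] - 1_000_000))
                if kind == "line":
                    junctions.append(
                        make_junction(sample, cd, d1, "+", ca, p, "-", flags={"LINE"})
                    )
                else:
                    delta = int(rng.integers(50, 1_500))
                    junctions.append(make_junction(sample, cd, d1, "+", ca, p, "-"))
                    junctions.append(
                        make_junction(sample, cd, d1 + donor_len, "-", ca, p + delta, "+")
                    )

        for _ in range(rng.poisson(w * tpl.complex_rate)):
            chrom = _pick_chrom(genome, rng)
            n_junc = 8 + int(rng.integers(0, 5))
            spacing = rng.integers(50_000, 350_000, size=n_junc)
            start = int(
                rng.integers(1_000_000, genome.lengths[chrom] - int(spacing.sum()) - 2_000_000)
            )
            knots = start + np.concatenate([[0], np.cumsum(spacing)])
            for i in range(n_junc):
                a = int(knots[i] + rng.integers(0, 2_000))
                b = int(knots[i + 1] - rng.integers(0, 2_000))
                if i % 2 == 0:
                    # elevated interval spanned by a concordant DUP-type junction
                    book.add_positive(chrom, int(knots[i]), int(knots[i + 1]), 1)
                    junctions.append(
                        make_junction(sample, chrom, int(knots[i]), "-",
                                      chrom, int(knots[i + 1]), "+")
                    )
                else:
                    junctions.append(
                        make_junction(sample, chrom, a, "+", chrom, b, "+", svtype="INV")
                    )

        for _ in range(rng.poisson(w * tpl.fragmentation_rate)):
            chrom = pick()
            length = int(rng.lognormal(*tpl.frag_len)) + 10_000
            if rng.random() < 0.5:
                delta = 2 if rng.random() < tpl.big_step_prob else 1
                book.place_negative(chrom, min(length, genome.lengths[chrom] // 4),
                                    delta=min(delta, baseline[chrom]))
            else:
                delta = 2 if rng.random() < tpl.big_step_prob else 1
                length = min(length, (genome.lengths[chrom] - 2_100_000) // 2)
                s = int(rng.integers(1_000_000, genome.lengths[chrom] - length - 1_000_000))
                book.add_positive(chrom, s, s + length, delta)

        for _ in range(rng.poisson(w * tpl.oscillation_rate)):
            chrom = pick()
            n_up = 4 + int(rng.integers(0, 4))  # 2*n_up+1 alternating segments
            spacing = rng.integers(100_000, 500_000, size=2 * n_up)
            start = int(
                rng.integers(1_000_000, genome.lengths[chrom] - int(spacing.sum()) - 2_000_000)
            )
            cuts = start + np.concatenate([[0], np.cumsum(spacing)])
            for i in range(n_up):
                book.add_positive(chrom, int(cuts[2 * i]), int(cuts[2 * i + 1]), 1)

        for _ in range(rng.poisson(w * tpl.focal_amp_rate)):
            chrom = _pick_chrom(genome, rng)
            length = int(rng.integers(500_000, 3_000_000))
            s = int(rng.integers(1_000_000, genome.lengths[chrom] - length - 1_000_000))
            amp = 6 + int(rng.poisson(3.0))  # total CN >= baseline + 6 >= 8
            book.add_positive(chrom, s, s + length, amp)

    segments = book.build_segments(sample, baseline)
    return segments, junctions


TISSUE_SITES = ("ovary", "fallopian tube", "omentum", "peritoneum", "ascites", "lymph nodes")


def simulate_sample(
    weights: dict[str, float],
    genome: GenomeModel,
    seed: int | list[int] = 0,
    sample: str = "S1",
    patient: str = "P1",
    templates: dict[str, ProcessTemplate] | None = None,
) -> SampleBundle:
    """Generate one sample from a mixture of process templates.

    ``weights`` must be nonnegative and sum to 1 (within 1e-9).
    """
    templates = templates or builtin_templates()
    total = sum(weights.values())
    if any(w < 0 for w in weights.values()) or abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must be nonnegative and sum to 1, got {total}")
    unknown = set(weights) - set(templates)
    if unknown:
        raise ValueError(f"unknown templates {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    segments, junctions = _simulate_events(sample, weights, genome, rng, templates)
    ploidy = sum(w * templates[t].ploidy for t, w in weights.items())
    width = 0.6 if rng.random() < 0.05 else float(rng.uniform(0.0, 0.3))
    profile = SampleProfile(
        sample=sample,
        patient=patient,
        tissue_site=str(rng.choice(np.asarray(TISSUE_SITES))),
        purity=float(rng.uniform(0.15, 0.95)),
        ploidy=float(ploidy),
        purity_range_width=width,
        treatment_phase=str(rng.choice(np.asarray(["pre", "post-NACT", "relapse"]),
                                       p=[0.5, 0.43, 0.07])),
    )
    return SampleBundle(profile=profile, segments=segments, junctions=junctions,
                        weights=dict(weights))


def simulate_cohort(
    n_patients: int,
    genome: GenomeModel | None = None,
    samples_per_patient: dict[int, float] | None = None,
    alpha: float | np.ndarray = 0.3,
    within_patient_concentration: float = 80.0,
    seed: int = 0,
    templates: dict[str, ProcessTemplate] | None = None,
) -> SyntheticCohort:
    """Generate a multi-sample cohort with patient-shared mixtures.

    Each patient draws a base mixture from a Dirichlet prior; each of their
    samples jitters it (Dirichlet concentrated around the base), giving
    realistic within-patient stability. Survival follows a proportional-
    hazards link on the patient's dominant template.
    """
    genome = genome or GenomeModel.grch38()
    templates = templates or builtin_templates()
    names = list(templates)
    samples_per_patient = samples_per_patient or {1: 0.4, 2: 0.35, 3: 0.25}
    alpha_vec = (np.full(len(names), alpha) if np.isscalar(alpha)
                 else np.asarray(alpha, dtype=float))
    rng = np.random.default_rng([seed, 0])

    bundles: list[SampleBundle] = []
    clinical: list[ClinicalRecord] = []
    truth_rows = {}
    counts = np.array(list(samples_per_patient.keys()))
    probs = np.array(list(samples_per_patient.values()), dtype=float)
    probs /= probs.sum()
    for p_idx in range(n_patients):
        patient = f"P{p_idx + 1:03d}"
        base = rng.dirichlet(alpha_vec)
        n_samples = int(rng.choice(counts, p=probs))
        for s_idx in range(n_samples):
            sample = f"{patient}_S{s_idx + 1}"
            jitter = rng.dirichlet(base * within_patient_concentration + 1e-3)
            weights = dict(zip(names, jitter))
            bundle = simulate_sample(
                weights, genome, seed=[seed, 1, p_idx, s_idx], sample=sample,
                patient=patient, templates=templates,
            )
            bundles.append(bundle)
            truth_rows[sample] = jitter
        dominant = names[int(np.argmax(base))]
        loghaz = templates[dominant].log_hazard
        pfi = float(rng.exponential(400.0 * np.exp(-loghaz)))
        pfi_censor = float(rng.uniform(200.0, 1500.0))
        os_t = float(rng.exponential(1200.0 * np.exp(-loghaz)))
        os_censor = float(rng.uniform(400.0, 3000.0))
        clinical.append(
            ClinicalRecord(
                patient=patient,
                pfi_days=min(pfi, pfi_censor),
                pfi_event=pfi <= pfi_censor,
                os_days=min(os_t, os_censor),
                os_event=os_t <= os_censor,
                hr_status="HRD" if dominant in ("BRCA1like", "BRCA2like") else "HRP",
                mutations=frozenset(
                    {"BRCA1"} if dominant == "BRCA1like"
                    else {"BRCA2"} if dominant == "BRCA2like"
                    else set()
                ),
            )
        )
    exposures = pd.DataFrame.from_dict(truth_rows, orient="index", columns=names)
    config = {
        "n_patients": n_patients,
        "samples_per_patient": {str(k): v for k, v in samples_per_patient.items()},
        "alpha": alpha if np.isscalar(alpha) else list(alpha_vec),
        "within_patient_concentration": within_patient_concentration,
        "templates": names,
        "seed": seed,
    }
    return SyntheticCohort(samples=bundles, clinical=clinical, exposures=exposures,
                           config=config, seed=seed)


# ---------------------------------------------------------------------------
# validation and NMF-level simulation
# ---------------------------------------------------------------------------

def check_concordance(
    segments: list[CopyNumberSegment], junctions: list[Junction], tol_bp: int = 1
) -> list[str]:
    """Junction-segment concordance: every same-chromosome DEL/DUP junction
    must hit a segment boundary with a rounded CN step >= 1 at both breakends.
    Returns a list of violation messages (empty = concordant)."""
    boundaries: dict[tuple[str, str], dict[int, float]] = {}
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample, s.chrom), []).append(s)
    for key, segs in by_key.items():
        segs.sort(key=lambda s: s.start)
        steps = {}
        for a, b in zip(segs, segs[1:]):
            steps[b.start] = abs(round_half_up(b.cn) - round_half_up(a.cn))
        boundaries[key] = steps
    violations = []
    for j in junctions:
        if j.svtype not in ("DEL", "DUP") or not j.intrachromosomal:
            continue
        steps = boundaries.get((j.sample, j.bnd_a.chrom), {})
        for bnd in (j.bnd_a, j.bnd_b):
            hit = any(
                abs(pos - bnd.pos) <= tol_bp and step >= 1
                for pos, step in steps.items()
            )
            if not hit:
                violations.append(
                    f"{j.sample}: {j.svtype} breakend {bnd.chrom}:{bnd.pos} "
                    "has no matching CN step"
                )
    return violations


def synthetic_count_matrix(
    n_signatures: int,
    n_samples: int,
    n_features: int = 44,
    seed: int = 0,
    mean_total: float = 800.0,
    exposure_alpha: float = 0.5,
    max_pairwise_cosine: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Poisson count cohort from planted signatures, for factorization tests.

    Returns (V, W_true, H_true): V is samples x features counts, W_true is
    features x K L1-normalized planted profiles (pairwise cosine bounded),
    H_true is samples x K true activities.
    """
    rng = np.random.default_rng([seed, 99])
    for _ in range(200):
        W = rng.gamma(0.3, 1.0, size=(n_features, n_signatures))
        W /= W.sum(axis=0)
        Wn = W / np.linalg.norm(W, axis=0)
        cos = Wn.T @ Wn
        np.fill_diagonal(cos, 0.0)
        if cos.max() <= max_pairwise_cosine:
            break
    H = rng.dirichlet(np.full(n_signatures, exposure_alpha), size=n_samples)
    totals = rng.uniform(0.6 * mean_total, 1.4 * mean_total, size=n_samples)
    H_scaled = H * totals[:, None]
    V = rng.poisson(H_scaled @ W.T).astype(float)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    sig_names = [f"true{i + 1}" for i in range(n_signatures)]
    feat_names = [f"f{i + 1}" for i in range(n_features)]
    return (
        pd.DataFrame(V, index=samples, columns=feat_names),
        pd.DataFrame(W, index=feat_names, columns=sig_names),
        pd.DataFrame(H_scaled, index=samples, columns=sig_names),
    )
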