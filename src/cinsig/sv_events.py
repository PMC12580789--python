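"""Junction clustering and structural-variant event features.

Junctions are grouped into events by single-linkage proximity clustering of
their breakends (default 5 kb), the base-proximity convention of SV
resolution tools. Each cluster is then classified into the event taxonomy
used for feature counting: simple local events (deletion, tandem
duplication, unbalanced translocation), reciprocal two-break events,
insertions, LINE insertions, and complex (>= 3 junction) clusters, plus the
compact/sparse and intra/inter-chromosomal dichotomies.

A simplified chromothripsis detector flags chromosomes combining a dense
junction cluster with a long run of copy-number oscillation between two
states. It is an approximation in the spirit of high-confidence
chromothripsis callers, not a reimplementation of one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .types import CopyNumberSegment, Junction

DEFAULT_PROXIMITY = 5_000
DEFAULT_SPAN_THRESHOLD = 5_000_000
DEFAULT_CN_STEP = 1.0
DEFAULT_INSERTION_DONOR_MAX = 100_000
DEFAULT_INSERTION_DISPLACEMENT_MIN = 1_000_000

EVENT_LABELS = (
    "deletion",
    "duplication",
    "reciprocal",
    "unbalanced_translocation",
    "insertion",
    "LINE",
)


@dataclass(frozen=True)
class JunctionCluster:
    """A set of junctions treated as one rearrangement event."""

    junctions: tuple[Junction, ...]
    labels: frozenset[str] = field(default_factory=frozenset)
    cn_unavailable: bool = False

    def __post_init__(self) -> None:
        if not self.junctions:
            raise ValueError("cluster must contain at least one junction")
        bad = set(self.labels) - set(EVENT_LABELS)
        if bad:
            raise ValueError(f"unknown event labels {sorted(bad)}")

    @property
    def size_class(self) -> str:
        n = len(self.junctions)
        return "simple" if n == 1 else ("pair" if n == 2 else "complex")

    @property
    def chromosomes(self) -> frozenset[str]:
        return frozenset(
            c for j in self.junctions for c in (j.bnd_a.chrom, j.bnd_b.chrom)
        )

    @property
    def footprint(self) -> dict[str, tuple[int, int]]:
        """Per-chromosome (min, max) breakend positions."""
        fp: dict[str, tuple[int, int]] = {}
        for j in self.junctions:
            for bnd in (j.bnd_a, j.bnd_b):
                lo, hi = fp.get(bnd.chrom, (bnd.pos, bnd.pos))
                fp[bnd.chrom] = (min(lo, bnd.pos), max(hi, bnd.pos))
        return fp

    @property
    def intrachromosomal(self) -> bool:
        return len(self.chromosomes) == 1


def cluster_junctions(
    junctions: list[Junction], proximity: int = DEFAULT_PROXIMITY
) -> list[JunctionCluster]:
    """Single-linkage clustering of one sample's junctions by breakend proximity.

    Two junctions share a cluster iff some pair of their breakends lies on the
    same chromosome within ``proximity`` bp, transitively closed.
    """
    samples = {j.sample for j in junctions}
    if len(samples) > 1:
        raise ValueError(f"junctions from multiple samples: {sorted(samples)}")
    n = len(junctions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # In 1-D, single linkage only needs links between position-adjacent
    # breakends on each chromosome (transitivity supplies the rest).
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, j in enumerate(junctions):
        for bnd in (j.bnd_a, j.bnd_b):
            per_chrom.setdefault(bnd.chrom, []).append((bnd.pos, idx))
    for ends in per_chrom.values():
        ends.sort()
        for (pos_a, ia), (pos_b, ib) in zip(ends, ends[1:]):
            if pos_b - pos_a <= proximity:
                union(ia, ib)

    groups: dict[int, list[Junction]] = {}
    for idx, j in enumerate(junctions):
        groups.setdefault(find(idx), []).append(j)
    clusters = [JunctionCluster(tuple(members)) for members in groups.values()]
    clusters.sort(
        key=lambda c: (min(c.footprint), min(lo for lo, _ in c.footprint.values()))
    )
    return clusters


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _cn_step_at(
    segments: list[CopyNumberSegment], chrom: str, pos: int
) -> float | None:
    """Rounded-CN difference across the segment boundary nearest ``pos``.

    Returns None when no adjacent segment pair brackets the position
    (CN unavailable).
    """
    segs = sorted((s for s in segments if s.chrom == chrom), key=lambda s: s.start)
    if len(segs) < 2:
        return None
    best: float | None = None
    best_dist = math.inf
    for prev, cur in zip(segs, segs[1:]):
        dist = abs(cur.start - pos)
        if dist < best_dist:
            best_dist = dist
            best = abs(round(cur.cn) - round(prev.cn))
    # only trust a boundary reasonably near the breakend
    return best if best_dist <= DEFAULT_PROXIMITY * 2 else None


def _is_reciprocal_pair(j1: Junction, j2: Junction, proximity: int) -> bool:
    """Two INV (or TRA) junctions with opposing orientations whose breakends pair up."""
    if j1.svtype == j2.svtype == "INV":
        oris1 = (j1.bnd_a.orientation, j1.bnd_b.orientation)
        oris2 = (j2.bnd_a.orientation, j2.bnd_b.orientation)
        if oris1 == oris2:  # need ++ against --
            return False
    elif j1.svtype == j2.svtype == "TRA":
        if {j1.bnd_a.chrom, j1.bnd_b.chrom} != {j2.bnd_a.chrom, j2.bnd_b.chrom}:
            return False
        opposing = (
            j1.bnd_a.orientation != j2.bnd_a.orientation
            and j1.bnd_b.orientation != j2.bnd_b.orientation
        )
        if not opposing:
            return False
    else:
        return False
    # breakends must mutually pair within proximity on matching chromosomes
    pairs = 0
    used = set()
    for b1 in (j1.bnd_a, j1.bnd_b):
        for k, b2 in enumerate((j2.bnd_a, j2.bnd_b)):
            if k in used:
                continue
            if b1.chrom == b2.chrom and abs(b1.pos - b2.pos) <= proximity:
                pairs += 1
                used.add(k)
                break
    return pairs == 2


def _is_insertion_pair(
    j1: Junction,
    j2: Junction,
    proximity: int,
    donor_max: int,
    displacement_min: int,
) -> bool:
    """Pair excising a short donor interval and re-joining it far away.

    Two breakends (one per junction) fall together at the acceptor site; the
    remaining two delimit a donor interval <= ``donor_max`` that lies at least
    ``displacement_min`` away or on another chromosome.
    """
    b1s, b2s = (j1.bnd_a, j1.bnd_b), (j2.bnd_a, j2.bnd_b)
    for i in range(2):
        for k in range(2):
            acc1, acc2 = b1s[i], b2s[k]
            don1, don2 = b1s[1 - i], b2s[1 - k]
            if acc1.chrom != acc2.chrom or abs(acc1.pos - acc2.pos) > proximity:
                continue
            if don1.chrom != don2.chrom:
                continue
            if abs(don1.pos - don2.pos) > donor_max:
                continue
            if don1.chrom != acc1.chrom:
                return True
            donor_mid = (don1.pos + don2.pos) // 2
            if abs(donor_mid - acc1.pos) >= displacement_min:
                return True
    return False


def classify_cluster(
    cluster: JunctionCluster,
    segments: list[CopyNumberSegment],
    genome: GenomeModel | None = None,
    proximity: int = DEFAULT_PROXIMITY,
    cn_step_threshold: float = DEFAULT_CN_STEP,
    insertion_donor_max: int = DEFAULT_INSERTION_DONOR_MAX,
    insertion_displacement_min: int = DEFAULT_INSERTION_DISPLACEMENT_MIN,
) -> JunctionCluster:
    """Assign event labels to a cluster (returns a labeled copy)."""
    labels: set[str] = set()
    cn_unavailable = False

    if any("LINE" in j.flags for j in cluster.junctions):
        labels.add("LINE")

    if cluster.size_class == "simple":
        (j,) = cluster.junctions
        if j.svtype == "DEL":
            labels.add("deletion")
        elif j.svtype == "DUP":
            labels.add("duplication")
        elif j.svtype == "INS":
            labels.add("insertion")
        elif j.svtype == "TRA":
            steps = [
                _cn_step_at(segments, bnd.chrom, bnd.pos)
                for bnd in (j.bnd_a, j.bnd_b)
            ]
            known = [s for s in steps if s is not None]
            if not known:
                cn_unavailable = True
            elif any(s >= cn_step_threshold for s in known):
                labels.add("unbalanced_translocation")
    elif cluster.size_class == "pair":
        j1, j2 = cluster.junctions
        if _is_reciprocal_pair(j1, j2, proximity):
            labels.add("reciprocal")
        elif _is_insertion_pair(
            j1, j2, proximity, insertion_donor_max, insertion_displacement_min
        ):
            labels.add("insertion")

    # a LINE event is not additionally counted as a local deletion/duplication
    if "LINE" in labels:
        labels -= {"deletion", "duplication"}
    return replace(cluster, labels=frozenset(labels), cn_unavailable=cn_unavailable)


def compact_or_sparse(
    cluster: JunctionCluster,
    genome: GenomeModel | None = None,
    span_threshold: int = DEFAULT_SPAN_THRESHOLD,
) -> str:
    """``compact`` iff every touched chromosome's footprint span <= threshold."""
    spans = [hi - lo for lo, hi in cluster.footprint.values()]
    return "compact" if all(s <= span_threshold for s in spans) else "sparse"


# ---------------------------------------------------------------------------
# chromothripsis-like detection
# ---------------------------------------------------------------------------

def _alternating_runs(values: list[int]) -> list[tuple[int, int]]:
    """Maximal (start, length) runs alternating between exactly two states (ABAB...)."""
    runs = []
    n = len(values)
    i = 0
    while i < n - 1:
        if values[i] == values[i + 1]:
            i += 1
            continue
        j = i + 2
        while j < n and values[j] == values[j - 2] and values[j] != values[j - 1]:
            j += 1
        runs.append((i, j - i))
        # next run may start at the last two elements of this one
        i = j - 1
    return runs


def detect_chromothripsis_like(
    segments: list[CopyNumberSegment],
    junctions: list[Junction],
    genome: GenomeModel | None = None,
    min_oscillations: int = 10,
    min_junctions: int = 6,
    proximity: int = DEFAULT_PROXIMITY,
    clusters: list[JunctionCluster] | None = None,
) -> dict[str, bool]:
    """Flag chromosomes carrying a dense cluster plus a long CN oscillation.

    A chromosome is flagged iff some single cluster contributes at least
    ``min_junctions`` intrachromosomal junctions on it AND a run of at least
    ``min_oscillations`` consecutive segments alternates between exactly two
    rounded CN states while overlapping that cluster's footprint.
    """
    if clusters is None:
        clusters = cluster_junctions(junctions, proximity) if junctions else []
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    flagged: dict[str, bool] = {c: False for c in by_chrom}
    for cluster in clusters:
        for chrom in cluster.chromosomes:
            n_intra = sum(
                1
                for j in cluster.junctions
                if j.intrachromosomal and j.bnd_a.chrom == chrom
            )
            if n_intra < min_junctions:
                continue
            segs = sorted(by_chrom.get(chrom, []), key=lambda s: s.start)
            if len(segs) < min_oscillations:
                continue
            lo, hi = cluster.footprint[chrom]
            rounded = [int(math.floor(s.cn + 0.5)) for s in segs]
            for start, length in _alternating_runs(rounded):
                if length < min_oscillations:
                    continue
                run_lo = segs[start].start
                run_hi = segs[start + length - 1].end
                if run_lo <= hi and lo <= run_hi:
                    flagged[chrom] = True
                    break
    return flagged


# ---------------------------------------------------------------------------
# per-sample feature counts
# ---------------------------------------------------------------------------

@dataclass
class SVFeatureCounts:
    """Per-sample SV event counts plus raw lengths awaiting discretization."""

    sample: str
    simple: int = 0
    complex: int = 0
    intra: int = 0
    inter: int = 0
    compact: int = 0
    sparse: int = 0
    insertions: int = 0
    reciprocal: int = 0
    unbalanced_translocation: int = 0
    line: int = 0
    chromothripsis: int = 0
    deletion_lengths: list[int] = field(default_factory=list)
    duplication_lengths: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.intra + self.inter


def sv_feature_counts(
    sample: str,
    junctions: list[Junction],
    segments: list[CopyNumberSegment],
    genome: GenomeModel | None = None,
    proximity: int = DEFAULT_PROXIMITY,
    span_threshold: int = DEFAULT_SPAN_THRESHOLD,
    **classify_kwargs,
) -> SVFeatureCounts:
    """Cluster, classify, and tally one sample's SV features."""
    counts = SVFeatureCounts(sample=sample)
    if not junctions:
        return counts
    clusters = [
        classify_cluster(c, segments, genome, proximity=proximity, **classify_kwargs)
        for c in cluster_junctions(junctions, proximity)
    ]
    for c in clusters:
        if c.intrachromosomal:
            counts.intra += 1
        else:
            counts.inter += 1
        if compact_or_sparse(c, genome, span_threshold) == "compact":
            counts.compact += 1
        else:
            counts.sparse += 1
        if c.size_class == "complex":
            counts.complex += 1
        elif c.size_class == "simple" and c.labels & {
            "deletion",
            "duplication",
            "unbalanced_translocation",
        }:
            counts.simple += 1
        if "deletion" in c.labels:
            counts.deletion_lengths.append(c.junctions[0].length or 0)
        if "duplication" in c.labels:
            counts.duplication_lengths.append(c.junctions[0].length or 0)
        if "insertion" in c.labels:
            counts.insertions += 1
        if "reciprocal" in c.labels:
            counts.reciprocal += 1
        if "unbalanced_translocation" in c.labels:
            counts.unbalanced_translocation += 1
        if "LINE" in c.labels:
            counts.line += 1
    flags = detect_chromothripsis_like(
        segments, junctions, genome, proximity=proximity, clusters=clusters
    )
    counts.chromothripsis = sum(flags.values())
    return counts


def clusters_table(sample: str, clusters: list[JunctionCluster]) -> pd.DataFrame:
    """Flat cluster summary for the TSV writer."""
    rows = []
    for i, c in enumerate(clusters):
        fp = ";".join(
            f"{chrom}:{lo}-{hi}" for chrom, (lo, hi) in sorted(c.footprint.items())
        )
        rows.append(
            {
                "sample": sample,
                "cluster": i,
                "n_junctions": len(c.junctions),
                "size_class": c.size_class,
                "labels": ",".join(sorted(c.labels)),
                "chromosomes": ",".join(sorted(c.chromosomes)),
                "footprint": fp,
            }
        )
    return pd.DataFrame(rows)


def breakpoint_density(
    junctions: list[Junction],
    genome: GenomeModel,
    bin_size: int = 500_000,
) -> pd.DataFrame:
    """Breakend counts in fixed genomic bins (default 0.5 Mb).

    Every breakend increments exactly one bin, so the bin total is twice the
    junction count. Breakends beyond the chromosome end are rejected.
    """
    counts: dict[str, np.ndarray] = {
        chrom: np.zeros(
            (genome.lengths[chrom] + bin_size - 1) // bin_size, dtype=int
        )
        for chrom in genome.chromosomes
    }
    for j in junctions:
        for bnd in (j.bnd_a, j.bnd_b):
            if bnd.chrom not in counts:
                raise ValueError(f"breakend on unknown chromosome {bnd.chrom}")
            if not 0 <= bnd.pos < genome.lengths[bnd.chrom]:
                raise ValueError(
                    f"breakend {bnd.chrom}:{bnd.pos} beyond chromosome length"
                )
            counts[bnd.chrom][bnd.pos // bin_size] += 1
    rows = []
    for chrom in genome.chromosomes:
        for i, c in enumerate(counts[chrom]):
            rows.append({"chrom": chrom, "bin_start": i * bin_size, "count": int(c)})
    return pd.DataFrame(rows)
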