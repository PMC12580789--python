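"""Copy-number-derived feature families, as raw per-sample value collections.

Each family is later discretized at cohort level into the fixed feature
layout; this module only measures. Families:

* deletion / duplication magnitude — length-weighted 20th / 80th percentile
  of log(cn / ploidy): how deleted and how amplified the genome is.
* segment lengths — raw bp lengths.
* changepoints — |CN difference| across adjacent same-chromosome boundaries.
* segments per 5 Mb window and per chromosome arm — fragmentation measures.
* oscillation chain lengths — runs of >= 3 consecutive segments alternating
  between exactly two rounded CN states, a chromothripsis hallmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel
from .types import CopyNumberSegment

CN_LOG_FLOOR = 0.01  # cn=0 clipped here before the log to stay finite


class EmptyProfileError(ValueError):
    """Raised when a feature needs at least one segment and none exist."""


@dataclass
class CNRawFeatures:
    """One sample's raw CN feature values, pre-discretization."""

    sample: str
    deletion_magnitude: float = 0.0
    duplication_magnitude: float = 0.0
    segment_lengths: list[int] = field(default_factory=list)
    changepoints: list[float] = field(default_factory=list)
    segments_per_window: list[int] = field(default_factory=list)
    segments_per_arm: list[int] = field(default_factory=list)
    oscillation_chains: list[int] = field(default_factory=list)


def _by_chrom(segments: list[CopyNumberSegment]) -> dict[str, list[CopyNumberSegment]]:
    out: dict[str, list[CopyNumberSegment]] = {}
    for s in segments:
        out.setdefault(s.chrom, []).append(s)
    for segs in out.values():
        segs.sort(key=lambda s: s.start)
    return out


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Inverted-CDF weighted quantile: smallest value whose cumulative weight
    fraction reaches q."""
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights) / weights.sum()
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(values[min(idx, len(values) - 1)])


def magnitude_quantiles(
    segments: list[CopyNumberSegment], ploidy: float
) -> tuple[float, float]:
    """Length-weighted (q20, q80) of log(cn / ploidy) over the segments."""
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    if not segments:
        raise EmptyProfileError("magnitude quantiles need at least one segment")
    cn = np.array([max(s.cn, CN_LOG_FLOOR) for s in segments], dtype=float)
    lengths = np.array([s.length for s in segments], dtype=float)
    logratio = np.log(cn / ploidy)
    q20 = _weighted_quantile(logratio, lengths, 0.20)
    q80 = _weighted_quantile(logratio, lengths, 0.80)
    return q20, q80


def changepoints(segments: list[CopyNumberSegment]) -> list[float]:
    """|CN_i − CN_{i+1}| at each adjacent same-chromosome segment boundary."""
    out: list[float] = []
    for segs in _by_chrom(segments).values():
        out.extend(abs(a.cn - b.cn) for a, b in zip(segs, segs[1:]))
    return out


def segments_per_window(
    segments: list[CopyNumberSegment],
    genome: GenomeModel,
    window: int = 5_000_000,
    min_count: int = 2,
) -> list[int]:
    """Segment counts in fixed windows tiled from position 0; a segment counts
    in every window it overlaps.

    Windows below ``min_count`` segments are omitted: with a full-coverage
    segmentation every window holds at least one segment, so single-segment
    windows measure genome size rather than fragmentation and would swamp the
    count distribution with a constant.
    """
    counts: dict[tuple[str, int], int] = {}
    for s in segments:
        if s.chrom not in genome.lengths:
            continue
        first = s.start // window
        last = (s.end - 1) // window
        n_windows = (genome.lengths[s.chrom] + window - 1) // window
        for w in range(first, min(last, n_windows - 1) + 1):
            counts[(s.chrom, w)] = counts.get((s.chrom, w), 0) + 1
    return [counts[k] for k in sorted(counts) if counts[k] >= min_count]


def segments_per_arm(
    segments: list[CopyNumberSegment], genome: GenomeModel
) -> list[int]:
    """Segment counts per chromosome arm; a centromere-spanning segment counts
    in both arms. Arms with zero segments are omitted."""
    counts: dict[tuple[str, str], int] = {}
    arms = genome.arms
    for s in segments:
        for chrom, arm, lo, hi in arms:
            if s.chrom == chrom and s.start < hi and lo < s.end:
                key = (chrom, arm)
                counts[key] = counts.get(key, 0) + 1
    return [counts[k] for k in sorted(counts)]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def oscillation_chains(segments: list[CopyNumberSegment]) -> list[int]:
    """Lengths of maximal runs (>= 3) of consecutive segments whose rounded CN
    alternates between exactly two states (ABAB...)."""
    from .sv_events import _alternating_runs

    lengths: list[int] = []
    for segs in _by_chrom(segments).values():
        rounded = [round_half_up(s.cn) for s in segs]
        lengths.extend(
            length for _, length in _alternating_runs(rounded) if length >= 3
        )
    return lengths


def cn_raw_features(
    sample: str,
    segments: list[CopyNumberSegment],
    ploidy: float,
    genome: GenomeModel,
    window: int = 5_000_000,
) -> CNRawFeatures:
    """Assemble all CN feature families for one sample."""
    if not segments:
        raise EmptyProfileError(f"sample {sample} has no segments")
    q20, q80 = magnitude_quantiles(segments, ploidy)
    return CNRawFeatures(
        sample=sample,
        deletion_magnitude=q20,
        duplication_magnitude=q80,
        segment_lengths=[s.length for s in segments],
        changepoints=changepoints(segments),
        segments_per_window=segments_per_window(segments, genome, window),
        segments_per_arm=segments_per_arm(segments, genome),
        oscillation_chains=oscillation_chains(segments),
    )
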