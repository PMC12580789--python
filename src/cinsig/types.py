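"""Core domain records: copy-number segments, SV junctions, sample and clinical metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SVTYPES = ("DEL", "DUP", "INV", "TRA", "INS", "UNKNOWN")
ANNOTATION_FLAGS = ("LINE", "TYFONAS", "PYRGO", "BFB", "CHROMOPLEXY", "RIGMA")
TISSUE_AREAS = ("primary", "proximal_metastasis", "ascites", "other")

# Tissue site -> tissue area; total and deterministic, anything unlisted is "other".
_TISSUE_AREA_MAP = {
    "fallopian tube": "primary",
    "ovary": "primary",
    "omentum": "proximal_metastasis",
    "mesentery": "proximal_metastasis",
    "peritoneum": "proximal_metastasis",
    "ascites": "ascites",
}


def tissue_area(site: str) -> str:
    """Map a tissue site to its area (primary / proximal_metastasis / ascites / other)."""
    return _TISSUE_AREA_MAP.get(site.strip().lower(), "other")


@dataclass(frozen=True)
class CopyNumberSegment:
    """One genomic interval with a total copy number for one sample.

    Coordinates are 0-based half-open. ``minor_cn`` is the minor-allele copy
    number when an allele-specific caller provided one.
    """

    sample: str
    chrom: str
    start: int
    end: int
    cn: float
    minor_cn: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.sample} {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.cn < 0:
            raise ValueError(f"negative copy number {self.cn}")
        if self.minor_cn is not None and self.minor_cn > self.cn + 1e-9:
            raise ValueError(f"minor CN {self.minor_cn} exceeds total CN {self.cn}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    orientation: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural order for human chromosome names; unknown names sort last, lexicographically."""
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (int(name), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (order.get(name, 99), name)


@dataclass(frozen=True)
class Junction:
    """A breakend pair — the atomic structural-variant record.

    Breakends are stored canonically (A <= B by chromosome order then
    position). The svtype hint follows the usual orientation convention for
    same-chromosome junctions: +/- DEL, -/+ DUP, ++ or -- INV; cross-chromosome
    junctions are TRA.
    """

    sample: str
    bnd_a: Breakend
    bnd_b: Breakend
    svtype: str = "UNKNOWN"
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        a, b = self.bnd_a, self.bnd_b
        if (_chrom_sort_key(a.chrom), a.pos) > (_chrom_sort_key(b.chrom), b.pos):
            raise ValueError("breakends not in canonical order (A <= B)")
        same = a.chrom == b.chrom
        if self.svtype in ("DEL", "DUP", "INV") and not same:
            raise ValueError(f"{self.svtype} requires both breakends on one chromosome")
        if self.svtype == "TRA" and same:
            raise ValueError("TRA requires breakends on different chromosomes")
        bad = set(self.flags) - set(ANNOTATION_FLAGS)
        if bad:
            raise ValueError(f"unknown annotation flags {sorted(bad)}")

    @property
    def intrachromosomal(self) -> bool:
        return self.bnd_a.chrom == self.bnd_b.chrom

    @property
    def length(self) -> int | None:
        """|posB - posA| for same-chromosome junctions, None across chromosomes."""
        if not self.intrachromosomal:
            return None
        return abs(self.bnd_b.pos - self.bnd_a.pos)


def make_junction(
    sample: str,
    chrom_a: str,
    pos_a: int,
    ori_a: str,
    chrom_b: str,
    pos_b: int,
    ori_b: str,
    svtype: str | None = None,
    flags: frozenset[str] | set[str] = frozenset(),
) -> Junction:
    """Build a junction, canonicalizing breakend order and inferring the svtype hint.

    An explicit ``svtype`` always wins over orientation-based inference.
    """
    a = Breakend(chrom_a, pos_a, ori_a)
    b = Breakend(chrom_b, pos_b, ori_b)
    if (_chrom_sort_key(a.chrom), a.pos) > (_chrom_sort_key(b.chrom), b.pos):
        a, b = b, a
    if svtype is None:
        if a.chrom != b.chrom:
            svtype = "TRA"
        elif (a.orientation, b.orientation) == ("+", "-"):
            svtype = "DEL"
        elif (a.orientation, b.orientation) == ("-", "+"):
            svtype = "DUP"
        elif a.orientation == b.orientation:
            svtype = "INV"
        else:  # unreachable with the two-symbol alphabet
            svtype = "UNKNOWN"
    return Junction(sample, a, b, svtype, frozenset(flags))


@dataclass(frozen=True)
class SampleProfile:
    """Per-sample metadata as produced by the CN caller plus clinical annotation."""

    sample: str
    patient: str
    tissue_site: str
    purity: float
    ploidy: float
    purity_range_width: float = 0.0
    treatment_phase: str = "pre"  # pre | post-NACT | relapse

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity {self.purity} outside [0, 1]")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")

    @property
    def tissue_area(self) -> str:
        return tissue_area(self.tissue_site)

    def with_purity(self, purity: float) -> "SampleProfile":
        return replace(self, purity=purity)


@dataclass(frozen=True)
class ClinicalRecord:
    """Patient-level outcomes: platinum-free interval and overall survival."""

    patient: str
    pfi_days: float
    pfi_event: bool
    os_days: float
    os_event: bool
    hr_status: str = "unknown"  # HRD | HRP | unknown
    mutations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pfi_days < 0 or self.os_days < 0:
            raise ValueError("survival times must be nonnegative")
        if self.hr_status not in ("HRD", "HRP", "unknown"):
            raise ValueError(f"bad HR status {self.hr_status!r}")
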