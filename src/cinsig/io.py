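"""Readers and writers for the canonical text formats.

Segments travel as TSV (``sample, chrom, start, end, cn[, minor_cn]``) with
0-based half-open coordinates; SEG-style input (1-based inclusive) is converted
on read. Junctions travel as 10-column BEDPE whose ``name`` column carries the
sample id, plus an optional 11th column of comma-separated annotation flags.
Both writers emit a canonical dialect that round-trips byte-exactly.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path

import pandas as pd

from .types import ClinicalRecord, CopyNumberSegment, Junction, SampleProfile, make_junction


class ParseError(ValueError):
    """A malformed input row; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


def _fmt(x: float) -> str:
    """Canonical number formatting: integers without a decimal point."""
    return f"{x:g}"


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

def validate_segments(segments: list[CopyNumberSegment]) -> None:
    """Check that each sample's per-chromosome segments are sorted and disjoint."""
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = defaultdict(list)
    for seg in segments:
        by_key[(seg.sample, seg.chrom)].append(seg)
    for (sample, chrom), segs in by_key.items():
        ordered = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"overlapping segments for sample {sample} on {chrom}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


def read_segments(path: str | Path, format: str = "tsv") -> list[CopyNumberSegment]:
    """Read a segment table; returns per-sample-per-chromosome sorted segments.

    ``format='seg'`` treats coordinates as 1-based inclusive and converts to
    0-based half-open.
    """
    if format not in ("tsv", "seg"):
        raise ValueError(f"unknown segment format {format!r}")
    path = Path(path)
    segments: list[CopyNumberSegment] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = {"sample", "chrom", "start", "end", "cn"} - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                start = int(row["start"])
                end = int(row["end"])
                if format == "seg":
                    start -= 1  # 1-based inclusive -> 0-based half-open
                minor = row.get("minor_cn")
                seg = CopyNumberSegment(
                    sample=row["sample"],
                    chrom=row["chrom"],
                    start=start,
                    end=end,
                    cn=float(row["cn"]),
                    minor_cn=float(minor) if minor not in (None, "", ".") else None,
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            segments.append(seg)
    segments.sort(key=lambda s: (s.sample, s.chrom, s.start))
    validate_segments(segments)
    return segments


def write_segments(segments: list[CopyNumberSegment], path: str | Path) -> None:
    """Write the canonical segments TSV (sorted; byte-stable round-trip)."""
    has_minor = any(s.minor_cn is not None for s in segments)
    header = ["sample", "chrom", "start", "end", "cn"] + (["minor_cn"] if has_minor else [])
    ordered = sorted(segments, key=lambda s: (s.sample, s.chrom, s.start))
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for s in ordered:
            row = [s.sample, s.chrom, str(s.start), str(s.end), _fmt(s.cn)]
            if has_minor:
                row.append(_fmt(s.minor_cn) if s.minor_cn is not None else ".")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# junctions (BEDPE)
# ---------------------------------------------------------------------------

def read_junctions(path: str | Path, format: str = "bedpe") -> list[Junction]:
    """Read junctions from BEDPE; breakend positions are the interval starts.

    Column 7 (name) is the sample id; column 11, when present, holds
    comma-separated annotation flags. The svtype hint is inferred from strand
    orientations unless flags include an explicit ``SVTYPE=`` token.
    """
    if format != "bedpe":
        raise ValueError(f"unknown junction format {format!r}")
    junctions: list[Junction] = []
    with open(Path(path), newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: expected >= 10 BEDPE columns")
            c1, s1, _e1, c2, s2, _e2, name, _score, o1, o2 = fields[:10]
            for ori in (o1, o2):
                if ori not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: unknown strand symbol {ori!r}")
            svtype = None
            flags: set[str] = set()
            if len(fields) > 10 and fields[10] not in ("", "."):
                for token in fields[10].split(","):
                    if token.startswith("SVTYPE="):
                        svtype = token.removeprefix("SVTYPE=")
                    elif token:
                        flags.add(token)
            try:
                junctions.append(
                    make_junction(
                        sample=name if name != "." else "unknown",
                        chrom_a=c1, pos_a=int(s1), ori_a=o1,
                        chrom_b=c2, pos_b=int(s2), ori_b=o2,
                        svtype=svtype, flags=flags,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return junctions


def write_junctions(junctions: list[Junction], path: str | Path) -> None:
    """Write canonical BEDPE (pos, pos+1 intervals; flags in column 11)."""
    with open(path, "w", newline="") as fh:
        for j in junctions:
            a, b = j.bnd_a, j.bnd_b
            tokens = [f"SVTYPE={j.svtype}"] + sorted(j.flags)
            fh.write(
                "\t".join(
                    [
                        a.chrom, str(a.pos), str(a.pos + 1),
                        b.chrom, str(b.pos), str(b.pos + 1),
                        j.sample, ".", a.orientation, b.orientation,
                        ",".join(tokens),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# metadata / clinical tables
# ---------------------------------------------------------------------------

def read_profiles(path: str | Path) -> list[SampleProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "patient": str})
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            SampleProfile(
                sample=row["sample"],
                patient=row["patient"],
                tissue_site=row["tissue_site"],
                purity=float(row["purity"]),
                ploidy=float(row["ploidy"]),
                purity_range_width=float(row.get("purity_range_width", 0.0)),
                treatment_phase=str(row.get("treatment_phase", "pre")),
            )
        )
    return profiles


def write_profiles(profiles: list[SampleProfile], path: str | Path) -> None:
    rows = [
        {
            "sample": p.sample,
            "patient": p.patient,
            "tissue_site": p.tissue_site,
            "purity": _fmt(p.purity),
            "ploidy": _fmt(p.ploidy),
            "purity_range_width": _fmt(p.purity_range_width),
            "treatment_phase": p.treatment_phase,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    records = []
    for _, row in df.iterrows():
        muts = row.get("mutations")
        records.append(
            ClinicalRecord(
                patient=row["patient"],
                pfi_days=float(row["pfi_days"]),
                pfi_event=bool(int(row["pfi_event"])),
                os_days=float(row["os_days"]),
                os_event=bool(int(row["os_event"])),
                hr_status=str(row.get("hr_status", "unknown")),
                mutations=frozenset(
                    str(muts).split(",") if isinstance(muts, str) and muts else []
                ),
            )
        )
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {
            "patient": r.patient,
            "pfi_days": _fmt(r.pfi_days),
            "pfi_event": int(r.pfi_event),
            "os_days": _fmt(r.os_days),
            "os_event": int(r.os_event),
            "hr_status": r.hr_status,
            "mutations": ",".join(sorted(r.mutations)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
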