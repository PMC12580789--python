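"""Cohort sample-selection rules applied before signature extraction.

Two rules from the CN-calling and extraction protocol:

1. Purity correction — when the CN caller's purity solutions span a range
   wider than 0.5 (max minus min), the point estimate is unreliable and is
   set to zero.
2. Extraction selection — keep samples with purity at or above a threshold
   (default 0.20), and for each (patient, tissue area) keep only the
   highest-purity sample, so multi-sampled patients do not dominate the
   extraction while tissue variability is preserved.

Purity correction runs before selection, so zeroed samples fall below the
threshold and are excluded from extraction.
"""

from __future__ import annotations

from .types import SampleProfile

PURITY_RANGE_LIMIT = 0.5
DEFAULT_PURITY_THRESHOLD = 0.20


def correct_purity(profiles: list[SampleProfile]) -> list[SampleProfile]:
    """Zero the purity of samples whose purity-solution range exceeds 0.5 (strict)."""
    return [
        p.with_purity(0.0) if p.purity_range_width > PURITY_RANGE_LIMIT else p
        for p in profiles
    ]


def select_extraction_samples(
    profiles: list[SampleProfile],
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
    exclude_relapse: bool = False,
) -> list[str]:
    """Sample ids eligible for de-novo extraction.

    Keeps samples with purity >= ``purity_threshold`` and, per (patient,
    tissue area), the single highest-purity sample; purity ties break to the
    lexicographically smaller sample id. Relapse samples are eligible by
    default; pass ``exclude_relapse=True`` to restrict extraction to
    pre-treatment and post-NACT samples.
    """
    best: dict[tuple[str, str], SampleProfile] = {}
    for p in profiles:
        if p.purity < purity_threshold:
            continue
        if exclude_relapse and p.treatment_phase == "relapse":
            continue
        key = (p.patient, p.tissue_area)
        cur = best.get(key)
        if cur is None or (p.purity, ) > (cur.purity, ) or (
            p.purity == cur.purity and p.sample < cur.sample
        ):
            best[key] = p
    return sorted(p.sample for p in best.values())
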