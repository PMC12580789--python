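"""Hand-designed six-sample fixture for the feature-matrix golden test.

Each sample exercises one event type on a toy genome (three 100 Mb
chromosomes, centromeres at 50 Mb); the expected 44-column matrix was
tallied by hand against the fixed discretization models in
``tests/data/golden_models.json`` and committed as
``tests/data/golden_feature_matrix.tsv``.
"""

from cinsig.types import CopyNumberSegment, make_junction

PLOIDY = 2.0


def _flat(sample, chroms=("chr1", "chr2", "chr3"), cn=2.0, length=100_000_000):
    return [CopyNumberSegment(sample, c, 0, length, cn) for c in chroms]


def build_samples():
    """Returns {sample: (segments, junctions)} for the six fixture samples."""
    samples = {}

    # S1: flat diploid genome, no junctions
    samples["S1_flat"] = (_flat("S1_flat"), [])

    # S2: one 30 kb deletion on chr1 at 10 Mb
    segs = [
        CopyNumberSegment("S2_del", "chr1", 0, 10_000_000, 2.0),
        CopyNumberSegment("S2_del", "chr1", 10_000_000, 10_030_000, 1.0),
        CopyNumberSegment("S2_del", "chr1", 10_030_000, 100_000_000, 2.0),
    ] + _flat("S2_del", chroms=("chr2", "chr3"))
    juncs = [make_junction("S2_del", "chr1", 10_000_000, "+", "chr1", 10_030_000, "-")]
    samples["S2_del"] = (segs, juncs)

    # S3: one 500 kb duplication on chr2 at 20 Mb
    segs = _flat("S3_dup", chroms=("chr1",)) + [
        CopyNumberSegment("S3_dup", "chr2", 0, 20_000_000, 2.0),
        CopyNumberSegment("S3_dup", "chr2", 20_000_000, 20_500_000, 3.0),
        CopyNumberSegment("S3_dup", "chr2", 20_500_000, 100_000_000, 2.0),
    ] + _flat("S3_dup", chroms=("chr3",))
    juncs = [make_junction("S3_dup", "chr2", 20_000_000, "-", "chr2", 20_500_000, "+")]
    samples["S3_dup"] = (segs, juncs)

    # S4: reciprocal inversion pair on chr3 (balanced; flat CN)
    juncs = [
        make_junction("S4_recip", "chr3", 5_000_000, "+", "chr3", 8_000_000, "+",
                      svtype="INV"),
        make_junction("S4_recip", "chr3", 5_002_000, "-", "chr3", 8_001_000, "-",
                      svtype="INV"),
    ]
    samples["S4_recip"] = (_flat("S4_recip"), juncs)

    # S5: unbalanced translocation chr1:40Mb <-> chr2:60Mb with a CN step on chr1
    segs = [
        CopyNumberSegment("S5_tra", "chr1", 0, 40_000_000, 3.0),
        CopyNumberSegment("S5_tra", "chr1", 40_000_000, 100_000_000, 2.0),
    ] + _flat("S5_tra", chroms=("chr2", "chr3"))
    juncs = [make_junction("S5_tra", "chr1", 40_000_000, "+", "chr2", 60_000_000, "-")]
    samples["S5_tra"] = (segs, juncs)

    # S6: a 3-junction complex cluster on chr3 plus one LINE insertion junction
    juncs = [
        make_junction("S6_cx", "chr3", 10_000_000, "+", "chr3", 10_001_000, "+",
                      svtype="INV"),
        make_junction("S6_cx", "chr3", 10_001_500, "-", "chr3", 10_002_500, "-",
                      svtype="INV"),
        make_junction("S6_cx", "chr3", 10_002_000, "+", "chr3", 10_003_000, "+",
                      svtype="INV"),
        make_junction("S6_cx", "chr1", 10_000_000, "+", "chr2", 30_000_000, "-",
                      flags={"LINE"}),
    ]
    samples["S6_cx"] = (_flat("S6_cx"), juncs)

    return samples
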