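"""A 10-variant toy selection assay with hand-written reads.

Every downstream number (counts, RPM, detected fractions, survival ratios)
is small enough to verify by hand; the expected values frozen in the tests
were computed on paper from the read lists below.
"""

from denovolib.assay_quant import BarcodeScheme, SampleCondition
from denovolib.synthetic_data import READ_PAD3, READ_PAD5

#: ten references: ATG + one codon repeated three times, pairwise edit
#: distance >= 3 so single-substitution reads assign uniquely at max_edit 2
TOY_REFS = {
    f"v{i+1:02d}": "ATG" + c * 3
    for i, c in enumerate(
        ["AAA", "CCC", "GGG", "TTT", "AAC", "CCG", "GGT", "TTA", "ACG", "CTT"]
    )
}

TOY_SCHEME = BarcodeScheme(
    barcodes={
        "pre1": ("ACGTACGT", "TGCATGCA"),
        "pre2": ("GGTTGGTT", "CCAACCAA"),
        "post1": ("CATGCATG", "GTACGTAC"),
        "post2": ("TTGGAACC", "AACCTTGG"),
    },
    conditions={
        "pre1": SampleCondition("TOY", 37, 0, 1),
        "pre2": SampleCondition("TOY", 37, 0, 2),
        "post1": SampleCondition("TOY", 37, 100, 1),
        "post2": SampleCondition("TOY", 37, 100, 2),
    },
)


def _read(sample: str, vid: str, n: int, mutate: int | None = None):
    b5, b3 = TOY_SCHEME.barcodes[sample]
    seq = b5 + READ_PAD5 + TOY_REFS[vid] + READ_PAD3 + b3
    if mutate is not None:
        pos = len(b5) + len(READ_PAD5) + mutate
        base = "C" if seq[pos] != "C" else "G"
        seq = seq[:pos] + base + seq[pos + 1 :]
    return [(f"{sample}_{vid}_{k}", seq, "I" * len(seq)) for k in range(n)]


def toy_reads():
    """Hand-written read set.

    Per-sample variant counts after assignment:
        pre1:  v01 x5 (one with a single CDS substitution), v02 x15
               (one with a 1-mismatch 5' barcode)
        pre2:  v01 x10, v02 x10
        post1: v01 x10
        post2: v01 x5, v02 x5
    plus one junk read whose 5' barcode is 2 mismatches from every sample
    (stays unassigned at max_mismatch 1).
    """
    reads = []
    reads += _read("pre1", "v01", 4) + _read("pre1", "v01", 1, mutate=5)
    good, = _read("pre1", "v02", 1)
    b5 = TOY_SCHEME.barcodes["pre1"][0]
    off_barcode = ("pre1_v02_bc", "T" + good[1][1:], good[2])
    assert b5[0] != "T"
    reads += _read("pre1", "v02", 14) + [off_barcode]
    reads += _read("pre2", "v01", 10) + _read("pre2", "v02", 10)
    reads += _read("post1", "v01", 10)
    reads += _read("post2", "v01", 5) + _read("post2", "v02", 5)
    junk = _read("pre1", "v03", 1)[0]
    reads += [("junk", "TT" + junk[1][2:], junk[2])]
    return reads


#: hand-computed expectations
TOY_EXPECTED = {
    "counts": {
        "pre1": {"v01": 5, "v02": 15},
        "pre2": {"v01": 10, "v02": 10},
        "post1": {"v01": 10},
        "post2": {"v01": 5, "v02": 5},
    },
    "rpm_pre1": {"v01": 250_000.0, "v02": 750_000.0},
    "detected": {"pre1": 0.2, "pre2": 0.2, "post1": 0.1, "post2": 0.2},
    "ratios": {1: 0.5, 2: 1.0},
    "mean_survival": 0.75,
    "n_unassigned": 1,
}
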