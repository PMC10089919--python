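"""Selection-assay read quantification and survival statistics.

Turns barcoded amplicon reads from the twin-arginine export assay into
per-variant counts, reads-per-million (RPM) values, detected-library
fractions at the 100-RPM threshold, and per-replicate survival ratios with
outlier exclusion, confidence intervals and one-tailed Welch tests.

Read layout (simulator convention, sense strand):

    bc5 (8 nt) + pad5 + CDS + pad3 + bc3 (8 nt)

Survival is the per-replicate paired ratio of post-selection to
pre-selection detected fractions, averaged over replicates; ampicillin and
no-ampicillin platings from the same transformation/plating index form a
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import reverse_complement

RPM_DETECTION_THRESHOLD = 100.0
BARCODE_LEN = 8


@dataclass(frozen=True)
class SampleCondition:
    """Metadata for one plating sample."""

    library: str
    temperature: int  # 30 or 37 (deg C)
    ampicillin: int  # 0 or 100 (ug/ml)
    replicate: int  # 1..9 (transformation x plating)


@dataclass
class BarcodeScheme:
    """sample_id -> (5' barcode, 3' barcode) plus condition metadata."""

    barcodes: dict[str, tuple[str, str]]
    conditions: dict[str, SampleCondition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = list(self.barcodes.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate barcode pairs in scheme")
        for sid, (b5, b3) in self.barcodes.items():
            if len(b5) != BARCODE_LEN or len(b3) != BARCODE_LEN:
                raise ValueError(f"{sid}: barcodes must be {BARCODE_LEN} nt")


def generate_barcode_scheme(
    conditions: Mapping[str, SampleCondition],
    seed: int = 0,
    min_hamming: int = 3,
    max_tries: int = 200_000,
) -> BarcodeScheme:
    """Random 8-nt barcode pairs with pairwise Hamming >= min_hamming
    within each end."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def make_set(n: int) -> list[str]:
        out: list[str] = []
        for _ in range(max_tries):
            if len(out) == n:
                return out
            bc = "".join(rng.choice(bases, size=BARCODE_LEN))
            if all(sum(a != b for a, b in zip(bc, o)) >= min_hamming for o in out):
                out.append(bc)
        raise RuntimeError("barcode generation failed")

    ids = list(conditions)
    b5s = make_set(len(ids))
    b3s = make_set(len(ids))
    return BarcodeScheme(
        barcodes={sid: (b5s[i], b3s[i]) for i, sid in enumerate(ids)},
        conditions=dict(conditions),
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    scheme: BarcodeScheme,
    max_mismatch: int = 1,
    rc: bool = False,
) -> tuple[dict[str, list[tuple[str, str, str]]], list[tuple[str, str, str]]]:
    """Assign reads to samples by their terminal 8-nt barcodes.

    A read is assigned to the unique sample whose 5' and 3' barcodes are
    both within max_mismatch; no match or a tie leaves it unassigned. With
    rc=True, reads failing on the sense strand are retried reverse-
    complemented (off by default; the simulator emits sense reads).
    """
    assigned: dict[str, list[tuple[str, str, str]]] = {s: [] for s in scheme.barcodes}
    unassigned: list[tuple[str, str, str]] = []

    def best_sample(seq: str) -> str | None:
        if len(seq) < 2 * BARCODE_LEN:
            return None
        head, tail = seq[:BARCODE_LEN], seq[-BARCODE_LEN:]
        hits = []
        for sid, (b5, b3) in scheme.barcodes.items():
            d = max(_hamming(head, b5), _hamming(tail, b3))
            if d <= max_mismatch:
                hits.append((d, sid))
        if not hits:
            return None
        hits.sort()
        if len(hits) > 1 and hits[0][0] == hits[1][0]:
            return None  # ambiguous
        return hits[0][1]

    for read in reads:
        sid = best_sample(read[1])
        if sid is None and rc:
            flipped = reverse_complement(read[1])
            sid = best_sample(flipped)
            if sid is not None:
                read = (read[0], flipped, read[2][::-1])
        if sid is None:
            unassigned.append(read)
        else:
            assigned[sid].append(read)
    return assigned, unassigned


class ReferenceIndex:
    """Designed CDS set indexed for exact and near-match read assignment.

    Exact matches hit a dictionary; otherwise the read is assigned to the
    unique nearest reference within max_edit edit distance (edlib), with
    equidistant references reported as ambiguous.
    """

    def __init__(self, references: Mapping[str, str], max_edit: int = 2):
        seqs = list(references.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate reference sequences")
        self.max_edit = max_edit
        self.exact = {seq: vid for vid, seq in references.items()}
        self.by_length: dict[int, list[tuple[str, str]]] = {}
        for vid, seq in references.items():
            for l in range(len(seq) - max_edit, len(seq) + max_edit + 1):
                self.by_length.setdefault(l, []).append((vid, seq))

    def assign(self, read_cds: str) -> str:
        """variant_id, or "ambiguous"/"unmapped"."""
        hit = self.exact.get(read_cds)
        if hit is not None:
            return hit
        best_d, best_vid, tie = self.max_edit + 1, None, False
        for vid, seq in self.by_length.get(len(read_cds), ()):
            res = edlib.align(read_cds, seq, task="distance", k=self.max_edit)
            d = res["editDistance"]
            if d < 0:
                continue
            if d < best_d:
                best_d, best_vid, tie = d, vid, False
            elif d == best_d:
                tie = True
        if best_vid is None:
            return "unmapped"
        return "ambiguous" if tie else best_vid


def assign_read(read_cds_region: str, references: Mapping[str, str] | ReferenceIndex, max_edit: int = 2) -> str:
    """One-shot wrapper over ReferenceIndex.assign."""
    index = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references, max_edit)
    )
    return index.assign(read_cds_region)


def count_reads(
    assigned: Mapping[str, Sequence[tuple[str, str, str]]],
    references: Mapping[str, str],
    max_edit: int = 2,
    pad5: str = "",
    pad3: str = "",
) -> pd.DataFrame:
    """Variant x sample count matrix from demultiplexed reads.

    The CDS region is the read minus terminal barcodes and constant pads.
    Extra columns in ``.attrs``: per-sample assigned totals and
    unmapped/ambiguous tallies.
    """
    index = ReferenceIndex(references, max_edit)
    counts = pd.DataFrame(0, index=list(references), columns=list(assigned), dtype=int)
    meta = {"assigned_total": {}, "unmapped": {}, "ambiguous": {}}
    for sid, reads in assigned.items():
        unmapped = ambiguous = 0
        for _, seq, _ in reads:
            cds = seq[BARCODE_LEN + len(pad5) : len(seq) - BARCODE_LEN - len(pad3)]
            vid = index.assign(cds)
            if vid == "unmapped":
                unmapped += 1
            elif vid == "ambiguous":
                ambiguous += 1
            else:
                counts.loc[vid, sid] += 1
        meta["assigned_total"][sid] = int(counts[sid].sum())
        meta["unmapped"][sid] = unmapped
        meta["ambiguous"][sid] = ambiguous
    counts.attrs.update(meta)
    return counts


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize counts to reads-per-million per sample.

    Samples with zero assigned reads are dropped with a warning flag in
    ``.attrs["excluded_samples"]``.
    """
    totals = counts.sum(axis=0)
    good = totals[totals > 0].index
    rpm = counts[good] / totals[good] * 1e6
    rpm.attrs["excluded_samples"] = [c for c in counts.columns if c not in set(good)]
    return rpm


def detected_fraction(
    rpm_column: pd.Series | np.ndarray,
    n_designed: int,
    threshold: float = RPM_DETECTION_THRESHOLD,
) -> float:
    """Fraction of the designed library detected at >= threshold RPM.

    Inclusive at the threshold: the filter removes variants strictly below
    100 RPM (< 0.01% of reads in the sample).
    """
    if n_designed < 1:
        raise ValueError("n_designed must be >= 1")
    values = np.asarray(rpm_column, dtype=float)
    return float((values >= threshold).sum()) / n_designed


# ---------------------------------------------------------------------------
# Replicate statistics
# ---------------------------------------------------------------------------

@dataclass
class SurvivalEstimate:
    """Per-replicate survival ratios with outlier exclusion and 95% CI."""

    ratios: dict[int, float]  # replicate index -> post/pre ratio (all pairs)
    excluded: list[int]
    mean: float
    sd: float
    n: int
    ci95: tuple[float, float]

    @property
    def retained(self) -> list[float]:
        return [r for i, r in self.ratios.items() if i not in self.excluded]


def grubbs_exclude(
    values: Sequence[float],
    alpha: float = 0.05,
    max_excluded: int = 1,
) -> tuple[list[float], list[int]]:
    """Iterative two-sided Grubbs outlier test.

    Returns (retained values, excluded 0-based indices). With fewer than 3
    values, or zero spread, nothing is excluded.
    """
    vals = list(values)
    idx = list(range(len(vals)))
    excluded: list[int] = []
    while len(excluded) < max_excluded and len(vals) >= 3:
        arr = np.asarray(vals)
        mean, sd = arr.mean(), arr.std(ddof=1)
        if sd == 0:
            break
        n = len(arr)
        g = np.abs(arr - mean) / sd
        imax = int(np.argmax(g))
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        if g[imax] <= g_crit:
            break
        excluded.append(idx.pop(imax))
        vals.pop(imax)
    return vals, sorted(excluded)


def survival_estimate(
    pre_fractions: Sequence[float],
    post_fractions: Sequence[float],
    pairing: Sequence[int] | None = None,
    alpha: float = 0.05,
    max_excluded: int = 1,
) -> SurvivalEstimate:
    """Paired post/pre detected-fraction ratios with Grubbs exclusion.

    ``pairing`` labels the replicate index of each pair (default 1..n).
    Pairs with a zero pre-selection fraction are dropped with a warning
    (they carry no information about survival).
    """
    if len(pre_fractions) != len(post_fractions):
        raise ValueError("pre/post replicate lists differ in length")
    if len(pre_fractions) < 2:
        raise ValueError("need at least 2 replicate pairs")
    pairing = list(pairing) if pairing is not None else list(range(1, len(pre_fractions) + 1))
    ratios: dict[int, float] = {}
    for rep, pre, post in zip(pairing, pre_fractions, post_fractions):
        if pre <= 0:
            continue  # dropped: no detectable input
        ratios[rep] = post / pre
    reps = list(ratios)
    retained_vals, excluded_pos = grubbs_exclude(
        [ratios[r] for r in reps], alpha=alpha, max_excluded=max_excluded
    )
    excluded = [reps[i] for i in excluded_pos]
    arr = np.asarray(retained_vals)
    n = len(arr)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    if n >= 2:
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    else:
        ci = (mean, mean)
    return SurvivalEstimate(ratios=ratios, excluded=excluded, mean=mean, sd=sd, n=n, ci95=ci)


def one_tailed_welch(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "greater",
) -> dict[str, float]:
    """Welch's unequal-variance t-test, one-tailed.

    ``alternative="greater"`` tests mean(A) > mean(B). Degenerate input
    (zero variance in both groups with equal means) returns t=0, p=0.5.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p": 0.5}
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Count-level pipeline driver
# ---------------------------------------------------------------------------

def survival_from_counts(
    pre_counts: pd.DataFrame,
    post_counts: pd.DataFrame,
    n_designed: int,
    threshold: float = RPM_DETECTION_THRESHOLD,
    pairing: Sequence[int] | None = None,
) -> SurvivalEstimate:
    """Counts -> RPM -> detection -> paired survival, one library.

    pre/post count frames must have replicate-matched columns in the same
    order (column i of each is plating pair i).
    """
    pre_rpm = rpm_normalize(pre_counts)
    post_rpm = rpm_normalize(post_counts)
    pre_f = [detected_fraction(pre_rpm[c], n_designed, threshold) for c in pre_rpm]
    post_f = [detected_fraction(post_rpm[c], n_designed, threshold) for c in post_rpm]
    return survival_estimate(pre_f, post_f, pairing=pairing)
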