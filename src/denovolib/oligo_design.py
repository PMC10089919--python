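"""Codon-optimized CDS design and synthesis-oligo assembly.

Each library protein is reverse-translated for E. coli expression (either
the single highest-frequency codon per residue, or host-harmonized codon
allocation), repaired to satisfy synthesis constraints -- no undesired
restriction sites, no homopolymer run of 5 bp or longer -- and assembled
into a synthesis unit:

    primer5 (15 nt) + "CAT" + CDS + "CTCGAG" + primer3 (15 nt)

The "CAT" left flank together with the CDS's leading ATG forms the single
designed NdeI site (CATATG); the right flank is the single designed XhoI
site (CTCGAG). Both are whitelisted by position; any other occurrence of a
forbidden motif anywhere in the assembled oligo is a violation. CDSs carry
no stop codon: the libraries are expressed as internal fusions
(ssTorA-ORF-beta-lactamase and ORF-FLAG).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import (
    AA_TO_CODONS,
    CodonUsageTable,
    NucleotideSeq,
    ProteinRecord,
    translate_cds,
)

#: NdeI, XhoI (designed, must occur once each), EcoRI, BamHI (used in the
#: later subcloning PCR and must not cut internally).
DEFAULT_FORBIDDEN_MOTIFS = frozenset({"CATATG", "CTCGAG", "GAATTC", "GGATCC"})


class DesignFailure(RuntimeError):
    """A CDS could not be made constraint-compliant."""


class AssemblyError(RuntimeError):
    """An assembled oligo violates its own invariants (junction problem)."""


@dataclass(frozen=True)
class DesignConstraints:
    forbidden_motifs: frozenset[str] = DEFAULT_FORBIDDEN_MOTIFS
    max_homopolymer: int = 4
    flank_left: str = "CAT"
    flank_right: str = "CTCGAG"
    primer_len: int = 15

    def __post_init__(self) -> None:
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")
        for m in self.forbidden_motifs:
            if set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} not over ACGT")


@dataclass(frozen=True)
class OligoRecord:
    """A designed synthesis unit for one library variant."""

    variant_id: str
    primer5: str
    flank_left: str
    cds: str
    flank_right: str
    primer3: str

    @property
    def full_sequence(self) -> str:
        return self.primer5 + self.flank_left + self.cds + self.flank_right + self.primer3

    @property
    def designed_sites(self) -> tuple[tuple[int, str], ...]:
        """(position, motif) of the intentionally designed restriction sites."""
        sites = []
        left = self.primer5 + self.flank_left
        if left.endswith("CAT") and self.cds.startswith("ATG"):
            sites.append((len(left) - 3, "CATATG"))
        fr_start = len(left) + len(self.cds)
        for m in ("CTCGAG",):
            off = self.flank_right.find(m)
            if off >= 0:
                sites.append((fr_start + off, m))
        return tuple(sites)


@dataclass
class Violation:
    kind: str  # "motif" | "homopolymer"
    position: int
    length: int
    detail: str
    whitelisted: bool = False

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass
class ViolationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not [v for v in self.violations if not v.whitelisted]


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan_motifs(seq: str, motifs: Iterable[str]) -> list[tuple[int, str]]:
    """All (position, motif) occurrences, overlapping ones included."""
    hits = []
    for m in motifs:
        start = 0
        while True:
            pos = seq.find(m, start)
            if pos < 0:
                break
            hits.append((pos, m))
            start = pos + 1
    return sorted(hits)


def scan_homopolymers(seq: str, max_run: int) -> list[tuple[int, int]]:
    """(position, run_length) of maximal runs exceeding max_run."""
    return [
        (m.start(), m.end() - m.start())
        for m in re.finditer(r"(A+|C+|G+|T+)", seq)
        if m.end() - m.start() > max_run
    ]


def _find_violations(
    seq: str,
    constraints: DesignConstraints,
    whitelist: frozenset[tuple[int, str]] = frozenset(),
) -> list[Violation]:
    out = [
        Violation("motif", pos, len(m), m, whitelisted=(pos, m) in whitelist)
        for pos, m in scan_motifs(seq, constraints.forbidden_motifs)
    ]
    out += [
        Violation("homopolymer", pos, run, seq[pos] * run)
        for pos, run in scan_homopolymers(seq, constraints.max_homopolymer)
    ]
    return sorted(out, key=lambda v: v.position)


# ---------------------------------------------------------------------------
# Reverse translation
# ---------------------------------------------------------------------------

def reverse_translate_max(protein: str | ProteinRecord, table: CodonUsageTable) -> NucleotideSeq:
    """Encode every residue with its highest-frequency host codon."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    return NucleotideSeq("".join(table.max_codon(aa) for aa in seq))


def harmonize_codons(protein: str | ProteinRecord, table: CodonUsageTable) -> NucleotideSeq:
    """Allocate synonymous codons in proportion to host usage.

    For an amino acid occurring k times, codon quotas are the
    largest-remainder apportionment of k times the host usage fractions
    (ties broken by higher remainder, then higher frequency, then
    alphabetically). Quotas are spent on the residue's occurrences
    left-to-right in descending-frequency order, so the output is
    deterministic and the common codons land first.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    counts: dict[str, int] = {}
    for aa in seq:
        counts[aa] = counts.get(aa, 0) + 1

    allocation: dict[str, list[str]] = {}
    for aa, k in counts.items():
        fracs = table.fractions(aa)
        quotas = {c: math.floor(k * f) for c, f in fracs.items()}
        short = k - sum(quotas.values())
        remainders = sorted(
            fracs,
            key=lambda c: (-(k * fracs[c] - quotas[c]), -table.frequency[c], c),
        )
        for c in remainders[:short]:
            quotas[c] += 1
        ordered = sorted(quotas, key=lambda c: (-table.frequency[c], c))
        queue: list[str] = []
        for c in ordered:
            queue.extend([c] * quotas[c])
        allocation[aa] = queue

    cursors = {aa: 0 for aa in counts}
    codons = []
    for aa in seq:
        codons.append(allocation[aa][cursors[aa]])
        cursors[aa] += 1
    return NucleotideSeq("".join(codons))


# ---------------------------------------------------------------------------
# Constraint repair
# ---------------------------------------------------------------------------

def _log_w_score(codons: Sequence[str], table: CodonUsageTable) -> float:
    return sum(math.log(table.w[c]) for c in codons)


def repair_constraints(
    cds: str | NucleotideSeq,
    constraints: DesignConstraints,
    table: CodonUsageTable,
    left_context: str = "",
    right_context: str = "",
    max_iterations: int | None = None,
) -> NucleotideSeq:
    """Make a CDS constraint-compliant by synonymous single-codon swaps.

    Violations (forbidden motifs; homopolymer runs > max) are searched on
    left_context + cds + right_context so junction-spanning problems are
    caught, but only codons of the CDS are editable. Whitelisted designed
    sites at the context junctions are skipped. Violations are processed
    left-to-right: at each one, every synonymous substitution of a codon
    overlapping the violating window is scored, and among substitutions
    that strictly reduce the badness -- the pair (violation count, total
    excess length), compared lexicographically, so shortening a long run
    counts as progress even before it disappears -- the one with maximal
    sum of log relative adaptiveness is applied. When no swap reduces
    badness, a badness-preserving swap to a codon assignment not seen
    before is accepted instead (e.g. turning a homopolymer run into a
    single motif hit that a later swap removes); badness never increases
    and the seen-state set rules out cycles.
    The pass repeats to fixpoint; a pass with no progress, or exceeding the
    iteration bound (10 x CDS length), raises DesignFailure.
    """
    seq = str(cds)
    if len(seq) % 3:
        raise ValueError("CDS length not divisible by 3")
    protein = translate_cds(seq)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    off = len(left_context)
    if max_iterations is None:
        max_iterations = 10 * len(seq)

    whitelist = set()
    joined = left_context + seq + right_context
    # designed NdeI across left junction, designed XhoI in right context
    if left_context.endswith("CAT") and seq.startswith("ATG"):
        whitelist.add((off - 3, "CATATG"))
    for m in constraints.forbidden_motifs:
        p = right_context.find(m)
        if p >= 0:
            whitelist.add((off + len(seq) + p, m))
    wl = frozenset(whitelist)

    def violations_of(codon_list: Sequence[str]) -> list[Violation]:
        s = left_context + "".join(codon_list) + right_context
        return [v for v in _find_violations(s, constraints, wl) if not v.whitelisted]

    def badness(viols: Sequence[Violation]) -> tuple[int, int]:
        excess = sum(
            v.length - constraints.max_homopolymer if v.kind == "homopolymer" else 1
            for v in viols
        )
        return (len(viols), excess)

    current = violations_of(codons)
    seen = {tuple(codons)}
    for _ in range(max_iterations):
        if not current:
            return NucleotideSeq("".join(codons))
        progressed = False
        for viol in current:
            lo = max(0, (viol.position - off) // 3)
            hi = min(len(codons) - 1, (viol.end - 1 - off) // 3)
            if hi < lo:
                continue  # violation entirely inside a fixed context
            best: tuple[int, float, int, str] | None = None
            b_current = badness(current)
            for ci in range(lo, hi + 1):
                aa = protein[ci]
                for alt in AA_TO_CODONS[aa]:
                    if alt == codons[ci]:
                        continue
                    trial = codons[:]
                    trial[ci] = alt
                    trial_viols = violations_of(trial)
                    b_trial = badness(trial_viols)
                    if b_trial < b_current:
                        tier = 1
                    elif b_trial == b_current and tuple(trial) not in seen:
                        tier = 0  # sidestep: badness unchanged, new state
                    else:
                        continue
                    cand = (tier, _log_w_score(trial, table), -ci, alt)
                    if best is None or cand > best:
                        best = cand
            if best is not None:
                codons[-best[2]] = best[3]
                seen.add(tuple(codons))
                progressed = True
                break
        if not progressed:
            raise DesignFailure(
                f"cannot satisfy constraints for CDS of {protein[:12]}... "
                f"({len(current)} violation(s) remain)"
            )
        current = violations_of(codons)
    if current:
        raise DesignFailure("iteration bound reached with violations remaining")
    return NucleotideSeq("".join(codons))


# ---------------------------------------------------------------------------
# Assembly and validation
# ---------------------------------------------------------------------------

def assemble_oligo(
    variant_id: str,
    cds: str | NucleotideSeq,
    constraints: DesignConstraints,
    primer5: str,
    primer3: str,
) -> OligoRecord:
    """Assemble primer5 + flank_left + cds + flank_right + primer3.

    Raises AssemblyError if the concatenation creates any unwhitelisted
    violation (e.g. a motif or run spanning a junction) or if the designed
    sites do not occur exactly once each.
    """
    cds = str(cds)
    if not cds.startswith("ATG"):
        raise ValueError(f"{variant_id}: CDS must start with ATG")
    if len(primer5) != constraints.primer_len or len(primer3) != constraints.primer_len:
        raise ValueError(f"{variant_id}: primers must be {constraints.primer_len} nt")
    oligo = OligoRecord(
        variant_id=variant_id,
        primer5=primer5,
        flank_left=constraints.flank_left,
        cds=cds,
        flank_right=constraints.flank_right,
        primer3=primer3,
    )
    report = validate_oligo(oligo, constraints)
    if not report.ok:
        bad = [v for v in report.violations if not v.whitelisted]
        raise AssemblyError(f"{variant_id}: junction violation(s): {bad}")
    full = oligo.full_sequence
    if full.count("CATATG") != 1 or full.count("CTCGAG") != 1:
        raise AssemblyError(f"{variant_id}: designed sites not unique")
    return oligo


def validate_oligo(oligo: OligoRecord, constraints: DesignConstraints) -> ViolationReport:
    """QC scan of an assembled oligo on the sense strand.

    Forbidden-motif occurrences at the designed NdeI/XhoI positions are
    reported as whitelisted; everything else (including homopolymer runs
    longer than max_homopolymer anywhere, junctions included) is a violation.
    """
    wl = frozenset(oligo.designed_sites)
    return ViolationReport(_find_violations(oligo.full_sequence, constraints, wl))


# ---------------------------------------------------------------------------
# Primer pads
# ---------------------------------------------------------------------------

def generate_primer_pads(
    n_pads: int,
    constraints: DesignConstraints,
    seed: int = 0,
    gc_range: tuple[float, float] = (0.4, 0.6),
    max_pad_run: int = 3,
    min_hamming: int = 6,
    max_tries: int = 100_000,
) -> list[str]:
    """Generate constant primer pads for amplifying sub-libraries.

    Pads have 40-60% GC, no forbidden motif (also when abutting the designed
    flanks), homopolymer runs of at most max_pad_run (stricter than the
    oligo-wide limit so junctions stay safe), and pairwise Hamming distance
    >= min_hamming.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pads: list[str] = []
    for _ in range(max_tries):
        if len(pads) == n_pads:
            return pads
        pad = "".join(rng.choice(bases, size=constraints.primer_len))
        gc = (pad.count("G") + pad.count("C")) / len(pad)
        if not gc_range[0] <= gc <= gc_range[1]:
            continue
        if scan_homopolymers(pad, max_pad_run):
            continue
        # junction-safe against both flanks and against an ATG-leading CDS
        left_ctx = pad + constraints.flank_left + "ATG"
        right_ctx = constraints.flank_right + pad
        hits = scan_motifs(pad, constraints.forbidden_motifs)
        hits += [
            h
            for h in scan_motifs(left_ctx, constraints.forbidden_motifs)
            if h != (len(pad) + len(constraints.flank_left) - 3, "CATATG")
        ]
        hits += [
            h
            for h in scan_motifs(right_ctx, constraints.forbidden_motifs)
            if h != (0, "CTCGAG")
        ]
        if hits:
            continue
        if any(
            sum(a != b for a, b in zip(pad, other)) < min_hamming for other in pads
        ):
            continue
        pads.append(pad)
    raise DesignFailure(f"could not generate {n_pads} primer pads in {max_tries} tries")


# ---------------------------------------------------------------------------
# Full design driver
# ---------------------------------------------------------------------------

def design_oligos(
    records: Sequence[ProteinRecord],
    table: CodonUsageTable,
    constraints: DesignConstraints | None = None,
    mode: str = "harmonized",
    primer5: str | None = None,
    primer3: str | None = None,
    pad_seed: int = 0,
) -> tuple[list[OligoRecord], list[str]]:
    """Design one oligo per protein; returns (oligos, modification log).

    Proteins lacking a leading Met get one prepended (the flank "CAT" plus
    the leading ATG forms the NdeI site); each such change is logged.
    """
    constraints = constraints or DesignConstraints()
    if primer5 is None or primer3 is None:
        pads = generate_primer_pads(2, constraints, seed=pad_seed)
        primer5 = primer5 or pads[0]
        primer3 = primer3 or pads[1]
    encode = {"max": reverse_translate_max, "harmonized": harmonize_codons}[mode]
    left_ctx = primer5 + constraints.flank_left
    right_ctx = constraints.flank_right + primer3
    oligos: list[OligoRecord] = []
    log: list[str] = []
    for rec in records:
        protein = rec.sequence
        if not protein.startswith("M"):
            protein = "M" + protein
            log.append(f"{rec.id}: prepended Met for NdeI-compatible start")
        cds = encode(protein, table)
        cds = repair_constraints(cds, constraints, table, left_ctx, right_ctx)
        oligos.append(assemble_oligo(rec.id, cds, constraints, primer5, primer3))
    return oligos, log
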