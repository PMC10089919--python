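"""Shared domain types, alphabets, and readers/writers for standard formats.

Everything downstream works on the canonical 20-letter amino-acid alphabet
and uppercase ACGT nucleotide strings. Ambiguous residues (X, B, Z, U, ...)
are rejected at ingest: the designed libraries contain none, so their
appearance always indicates a corrupted input.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)
NUCLEOTIDES = "ACGT"
NUCLEOTIDE_SET = frozenset(NUCLEOTIDES)

#: The 61 sense codons of the standard genetic code, codon -> amino acid.
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: amino acid -> tuple of synonymous sense codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AMINO_ACIDS
}


class ParseError(ValueError):
    """A malformed input file (bad syntax or illegal characters)."""


class Origin(str, enum.Enum):
    """Provenance class of a library member."""

    denovo_human = "denovo_human"
    denovo_fly = "denovo_fly"
    random_synthetic = "random_synthetic"


@dataclass(frozen=True)
class ProteinRecord:
    """One library member: identifier, origin class and amino-acid sequence."""

    id: str
    origin: Origin
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty protein sequence")
        bad = set(self.sequence) - AMINO_ACID_SET
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue(s) {sorted(bad)} "
                "(only the canonical 20 amino acids are allowed)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NucleotideSeq:
    """An uppercase ACGT string."""

    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - NUCLEOTIDE_SET
        if bad:
            raise ValueError(f"illegal nucleotide(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def check_unique_ids(records: Iterable[ProteinRecord]) -> None:
    """Raise ValueError on duplicate ids within a library."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id: {rec.id}")
        seen.add(rec.id)


@dataclass
class CodonUsageTable:
    """Per-codon usage frequencies and derived relative adaptiveness.

    ``frequency`` maps each of the 61 sense codons to a positive usage value
    (per-1000 or fraction -- only ratios matter downstream). ``w`` is the
    relative codon adaptiveness: a codon's frequency divided by the maximal
    synonymous frequency, so the preferred codon of every amino acid has
    w == 1 and all w lie in (0, 1].
    """

    frequency: dict[str, float]
    taxon: str = ""
    w: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        missing = sorted(set(CODON_TO_AA) - set(self.frequency))
        if missing:
            raise ValueError(f"codon table missing sense codons: {missing}")
        nonpos = sorted(c for c in CODON_TO_AA if self.frequency[c] <= 0)
        if nonpos:
            raise ValueError(f"non-positive codon frequencies: {nonpos}")
        self.w = {}
        for aa, codons in AA_TO_CODONS.items():
            mx = max(self.frequency[c] for c in codons)
            for c in codons:
                self.w[c] = self.frequency[c] / mx

    def max_codon(self, aa: str) -> str:
        """The highest-frequency codon for an amino acid (ties: alphabetical)."""
        return max(AA_TO_CODONS[aa], key=lambda c: (self.frequency[c], c))

    def fractions(self, aa: str) -> dict[str, float]:
        """Synonymous-codon usage fractions for an amino acid (sum to 1)."""
        codons = AA_TO_CODONS[aa]
        tot = sum(self.frequency[c] for c in codons)
        return {c: self.frequency[c] / tot for c in codons}


def load_codon_table(path: str | Path | None = None, taxon_label: str = "e_coli_k12") -> CodonUsageTable:
    """Load a Kazusa-style codon usage table (``codon  per-1000`` lines).

    With no path, the packaged E. coli K12 table is loaded. Stop-codon lines
    are accepted and ignored; all 61 sense codons must be present.
    """
    if path is None:
        text = (
            resources.files("denovolib.data")
            .joinpath("ecoli_k12_codon_usage.txt")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    freq: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: expected 'codon frequency'")
        codon = parts[0].upper().replace("U", "T")
        if len(codon) != 3 or set(codon) - NUCLEOTIDE_SET:
            raise ParseError(f"line {lineno}: bad codon {parts[0]!r}")
        try:
            freq[codon] = float(parts[1])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad frequency {parts[1]!r}") from exc
    sense = {c: f for c, f in freq.items() if c not in STOP_CODONS}
    return CodonUsageTable(frequency=sense, taxon=taxon_label)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: frozenset[str] | None = AMINO_ACID_SET) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) in file order.

    Ids are the header up to the first whitespace. Sequences are validated
    against ``alphabet`` (pass ``NUCLEOTIDE_SET`` for DNA, ``None`` to skip).
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet is not None:
            bad = set(seq) - alphabet
            if bad:
                raise ParseError(
                    f"{path.name}, record {rec.id!r}: illegal characters {sorted(bad)}"
                )
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqrecs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read 4-line FASTQ records as (id, sequence, quality-string).

    Qualities are carried but unused downstream (quality handling is delegated
    to an upstream merged-read preprocessor).
    """
    path = Path(path)
    out: list[tuple[str, str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            qstr = "".join(chr(q + 33) for q in quals)
            out.append((rec.id, str(rec.seq).upper(), qstr))
    except ValueError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    return out


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality-string) triples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"{rid}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate_cds(cds: str | NucleotideSeq) -> str:
    """Translate a CDS with the standard genetic code.

    The CDS must have length divisible by 3 and contain no stop codon (the
    designed CDSs are expressed as internal fusions and carry none).
    """
    seq = str(cds)
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    bad = set(seq) - NUCLEOTIDE_SET
    if bad:
        raise ValueError(f"illegal nucleotide(s) {sorted(bad)}")
    protein = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at position {i}")
        protein.append(CODON_TO_AA[codon])
    return "".join(protein)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def proteins_to_fasta(path: str | Path, records: Sequence[ProteinRecord]) -> None:
    write_fasta(path, ((r.id, r.sequence) for r in records))


def proteins_from_fasta(path: str | Path, origin: Origin) -> list[ProteinRecord]:
    recs = [ProteinRecord(i, origin, s) for i, s in read_fasta(path)]
    check_unique_ids(recs)
    return recs
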