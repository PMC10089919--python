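"""Candidate selection and composition/length-matched random library design.

A de novo candidate set (library DN) is filtered to the 44-66 residue window
that single-oligo synthesis permits; a synthetic random library (library R)
is then generated by drawing residues i.i.d. from DN's pooled amino-acid
frequency distribution, with the length multiset copied exactly. Any
biophysical difference between the two libraries is then attributable to
residue ordering rather than composition or length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import AMINO_ACIDS, Origin, ProteinRecord

MIN_LENGTH_DEFAULT = 44
MAX_LENGTH_DEFAULT = 66
LIBRARY_SIZE_DEFAULT = 1800


@dataclass(frozen=True)
class CompositionProfile:
    """Pooled amino-acid counts and fractions over a set of proteins."""

    counts: dict[str, int]
    total_residues: int

    @property
    def freq(self) -> dict[str, float]:
        return {aa: c / self.total_residues for aa, c in self.counts.items()}

    def as_vector(self) -> np.ndarray:
        """Fractions in canonical amino-acid order."""
        return np.array([self.freq.get(aa, 0.0) for aa in AMINO_ACIDS])


def filter_by_length(
    records: Sequence[ProteinRecord],
    min_len: int = MIN_LENGTH_DEFAULT,
    max_len: int = MAX_LENGTH_DEFAULT,
) -> list[ProteinRecord]:
    """Keep records with min_len <= length <= max_len (inclusive), in order.

    The lower bound reflects the diminishing likelihood of domain-like
    structure in very short proteins; the upper bound is the longest CDS a
    single synthesis oligo accommodates.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]


def composition_profile(records: Sequence[ProteinRecord]) -> CompositionProfile:
    """Pooled residue counts over all records."""
    if not records:
        raise ValueError("composition_profile requires at least one record")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for rec in records:
        for aa in rec.sequence:
            counts[aa] += 1
    counts = {aa: c for aa, c in counts.items() if c}
    return CompositionProfile(counts=counts, total_residues=sum(counts.values()))


def generate_random_library(
    profile: CompositionProfile,
    lengths: Sequence[int],
    n: int,
    seed: int,
    id_template: str = "R{:04d}",
    existing_ids: set[str] | None = None,
) -> list[ProteinRecord]:
    """Generate n random-sequence proteins matched to a composition profile.

    The i-th output sequence has the i-th length of ``lengths`` (input order
    preserved); residues are drawn i.i.d. from the profile from a single
    seeded stream, so regeneration under the same seed is byte-identical and
    the library is extendable by continuing the stream.
    """
    if n != len(lengths):
        raise ValueError(f"n={n} does not match |lengths|={len(lengths)}")
    alphabet = sorted(profile.counts)
    probs = np.array([profile.freq[aa] for aa in alphabet])
    rng = np.random.default_rng(seed)
    out: list[ProteinRecord] = []
    for i, length in enumerate(lengths):
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        rid = id_template.format(i + 1)
        if existing_ids and rid in existing_ids:
            raise ValueError(f"generated id {rid} collides with an input id")
        out.append(ProteinRecord(rid, Origin.random_synthetic, seq))
    return out


def compare_composition(
    profile_a: CompositionProfile, profile_b: CompositionProfile
) -> dict[str, float]:
    """Total-variation distance and chi-square test between two profiles.

    TV = 0.5 * sum_i |a_i - b_i| over the union alphabet. The chi-square test
    compares B's counts to expectations under A's fractions (categories with
    zero expectation under A are pooled out of the test but still contribute
    to TV).
    """
    alphabet = sorted(set(profile_a.counts) | set(profile_b.counts))
    fa = np.array([profile_a.freq.get(aa, 0.0) for aa in alphabet])
    fb = np.array([profile_b.freq.get(aa, 0.0) for aa in alphabet])
    tv = 0.5 * float(np.abs(fa - fb).sum())

    counts_b = np.array([profile_b.counts.get(aa, 0) for aa in alphabet], dtype=float)
    mask = fa > 0
    if mask.sum() >= 2 and counts_b[mask].sum() > 0:
        obs = counts_b[mask]
        exp = fa[mask] / fa[mask].sum() * obs.sum()
        chi2_p = float(stats.chisquare(obs, exp).pvalue)
    else:
        chi2_p = float("nan")
    return {"total_variation": tv, "chi2_p": chi2_p}


def design_matched_library(
    candidates: Sequence[ProteinRecord],
    n: int = LIBRARY_SIZE_DEFAULT,
    min_len: int = MIN_LENGTH_DEFAULT,
    max_len: int = MAX_LENGTH_DEFAULT,
    seed: int = 0,
    select: str = "longest",
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Full design step: filter candidates, pick n, generate matched library R.

    ``select`` resolves how n members are chosen among compatible candidates:
    'longest' (default; ties broken by input order), 'first', or 'random'.
    Returns (library_DN, library_R).
    """
    compatible = filter_by_length(candidates, min_len, max_len)
    if len(compatible) < n:
        raise ValueError(
            f"only {len(compatible)} candidates in [{min_len}, {max_len}], need {n}"
        )
    if select == "longest":
        order = sorted(range(len(compatible)), key=lambda i: -len(compatible[i]))
        chosen = sorted(order[:n])
    elif select == "first":
        chosen = list(range(n))
    elif select == "random":
        chosen = sorted(np.random.default_rng(seed).choice(len(compatible), n, replace=False))
    else:
        raise ValueError(f"unknown selection mode {select!r}")
    dn = [compatible[i] for i in chosen]
    profile = composition_profile(dn)
    lengths = [len(r) for r in dn]
    r_lib = generate_random_library(
        profile, lengths, n, seed, existing_ids={rec.id for rec in dn}
    )
    return dn, r_lib
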