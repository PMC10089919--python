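"""Oligo design: codon choice, constraint repair, assembly, validation.

Repair results are checked against exhaustive enumeration over all
synonymous encodings for toy proteins, which is feasible up to ~6 residues.
"""

import itertools
import math

import pytest

import denovolib as dl
from denovolib.core_io import AA_TO_CODONS
from denovolib.oligo_design import (
    AssemblyError,
    DesignConstraints,
    scan_homopolymers,
    scan_motifs,
    validate_oligo,
)


def _all_encodings(protein):
    for combo in itertools.product(*(AA_TO_CODONS[aa] for aa in protein)):
        yield "".join(combo)


def _is_valid(seq, constraints):
    return not scan_motifs(seq, constraints.forbidden_motifs) and not scan_homopolymers(
        seq, constraints.max_homopolymer
    )


def _score(cds, table):
    return sum(math.log(table.w[cds[i : i + 3]]) for i in range(0, len(cds), 3))


class TestReverseTranslateMax:
    @pytest.mark.parametrize("protein,cds", [("M", "ATG"), ("W", "TGG"), ("K", "AAA")])
    def test_single_codon_choices(self, k12_table, protein, cds):
        assert str(dl.reverse_translate_max(protein, k12_table)) == cds

    def test_full_translation_round_trip(self, k12_table, candidate_pool):
        for rec in candidate_pool[:10]:
            cds = dl.reverse_translate_max(rec, k12_table)
            assert dl.translate_cds(cds) == rec.sequence


class TestHarmonizeCodons:
    def test_single_codon_amino_acid(self, k12_table):
        assert str(dl.harmonize_codons("MMMM", k12_table)) == "ATG" * 4

    def test_largest_remainder_leucine(self, toy_table):
        """4 Leu at fractions {CTG 0.5, CTC 0.25, TTA 0.25} -> 2 CTG, 1 CTC,
        1 TTA, assigned in descending-frequency order."""
        cds = str(dl.harmonize_codons("LLLL", toy_table))
        codons = [cds[i : i + 3] for i in range(0, 12, 3)]
        assert codons == ["CTG", "CTG", "CTC", "TTA"]

    def test_translation_preserved(self, k12_table, candidate_pool):
        for rec in candidate_pool[:10]:
            assert dl.translate_cds(dl.harmonize_codons(rec, k12_table)) == rec.sequence


class TestRepairConstraints:
    def test_homopolymer_run_fixed(self, k12_table):
        constraints = DesignConstraints()
        fixed = str(dl.repair_constraints("ATGAAAAAA", constraints, k12_table))
        assert dl.translate_cds(fixed) == "MKK"
        assert not scan_homopolymers(fixed, constraints.max_homopolymer)
        # exhaustive oracle: a compliant encoding exists
        assert any(_is_valid(e, constraints) for e in _all_encodings("MKK"))

    def test_motif_across_junction_fixed(self, k12_table):
        # Glu-Phe encoded GAA+TTC contains EcoRI GAATTC
        constraints = DesignConstraints()
        fixed = str(dl.repair_constraints("ATGGAATTC", constraints, k12_table))
        assert dl.translate_cds(fixed) == "MEF"
        assert "GAATTC" not in fixed

    def test_already_valid_returned_unchanged(self, k12_table):
        constraints = DesignConstraints()
        cds = "ATGGCGTGG"  # MAW, no motif, max run 1
        assert str(dl.repair_constraints(cds, constraints, k12_table)) == cds

    def test_local_score_optimality(self, k12_table):
        """No constraint-satisfying single-substitution neighbour of the
        repaired CDS scores higher in sum log w (exhaustive check)."""
        constraints = DesignConstraints()
        for protein, raw in (("MKK", "ATGAAAAAA"), ("MEF", "ATGGAATTC")):
            fixed = str(dl.repair_constraints(raw, constraints, k12_table))
            assert _is_valid(fixed, constraints)
            score = _score(fixed, k12_table)
            codons = [fixed[i : i + 3] for i in range(0, len(fixed), 3)]
            for ci, aa in enumerate(protein):
                for alt in AA_TO_CODONS[aa]:
                    trial = codons[:]
                    trial[ci] = alt
                    neighbour = "".join(trial)
                    if neighbour != fixed and _is_valid(neighbour, constraints):
                        assert _score(neighbour, k12_table) <= score + 1e-12

    def test_context_aware_repair(self, k12_table):
        """A CDS ending in GAATT is fine alone but forms EcoRI against the
        right flank CTCGAG; repair with context must remove it."""
        constraints = DesignConstraints()
        raw = "ATGAGAATT"  # M R I, ends GAATT; + "CTCGAG" -> GAATTC
        assert "GAATTC" in raw + "CTCGAG"
        fixed = str(
            dl.repair_constraints(raw, constraints, k12_table, right_context="CTCGAG")
        )
        assert "GAATTC" not in fixed + "CTCGAG"
        assert dl.translate_cds(fixed) == "MRI"


class TestAssembleValidate:
    @pytest.fixture(scope="class")
    def pads(self):
        return dl.generate_primer_pads(2, DesignConstraints(), seed=5)

    def test_full_length_arithmetic(self, k12_table, pads):
        constraints = DesignConstraints()
        cds = str(dl.repair_constraints("ATGAAAGTT", constraints, k12_table))
        oligo = dl.assemble_oligo("v1", cds, constraints, pads[0], pads[1])
        assert len(oligo.full_sequence) == len(cds) + 39  # 15 + 3 + L + 6 + 15

    def test_designed_sites_unique_and_whitelisted(self, k12_table, pads):
        constraints = DesignConstraints()
        cds = str(dl.repair_constraints("ATGAAAGTT", constraints, k12_table))
        oligo = dl.assemble_oligo("v1", cds, constraints, pads[0], pads[1])
        full = oligo.full_sequence
        assert full.count("CATATG") == 1 and full.count("CTCGAG") == 1
        report = validate_oligo(oligo, constraints)
        assert report.ok
        whitelisted = [v for v in report.violations if v.whitelisted]
        assert {v.detail for v in whitelisted} == {"CATATG", "CTCGAG"}

    def test_round_trip_parse(self, k12_table, pads):
        constraints = DesignConstraints()
        cds = str(dl.repair_constraints("ATGAAAGTT", constraints, k12_table))
        oligo = dl.assemble_oligo("v1", cds, constraints, pads[0], pads[1])
        full = oligo.full_sequence
        recovered = full[15 + 3 : len(full) - 6 - 15]
        assert recovered == cds

    def test_primer_run_reported(self, pads):
        constraints = DesignConstraints()
        oligo = dl.OligoRecord("v1", "GGGGG" + pads[0][5:], "CAT", "ATGAAAGTT", "CTCGAG", pads[1])
        report = validate_oligo(oligo, constraints)
        runs = [v for v in report.violations if v.kind == "homopolymer"]
        assert len(runs) == 1 and runs[0].position == 0

    def test_noncompliant_cds_raises(self, k12_table, pads):
        constraints = DesignConstraints()
        with pytest.raises(AssemblyError):
            dl.assemble_oligo("v1", "ATGGAATTC", constraints, pads[0], pads[1])


class TestDesignOligos:
    def test_library_scale_design_clean(self, small_libraries, k12_table):
        dn, rl = small_libraries
        constraints = DesignConstraints()
        oligos, log = dl.design_oligos(dn + rl, k12_table, constraints, pad_seed=3)
        assert len(oligos) == len(dn) + len(rl)
        assert all(validate_oligo(o, constraints).ok for o in oligos)
        for oligo, rec in zip(oligos, dn + rl):
            protein = dl.translate_cds(oligo.cds)
            assert protein in (rec.sequence, "M" + rec.sequence)

    def test_met_prepended_and_logged(self, k12_table):
        rec = dl.ProteinRecord("x1", dl.Origin.denovo_human, "KVLW" * 12)
        oligos, log = dl.design_oligos([rec], k12_table, pad_seed=3)
        assert dl.translate_cds(oligos[0].cds) == "M" + rec.sequence
        assert any("x1" in line for line in log)


class TestPrimerPads:
    def test_constraints_hold(self):
        constraints = DesignConstraints()
        pads = dl.generate_primer_pads(4, constraints, seed=9)
        assert len(pads) == 4
        for pad in pads:
            gc = (pad.count("G") + pad.count("C")) / len(pad)
            assert 0.4 <= gc <= 0.6
            assert not scan_motifs(pad, constraints.forbidden_motifs)
            assert not scan_homopolymers(pad, 3)
        for i, a in enumerate(pads):
            for b in pads[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 6
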