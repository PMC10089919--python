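# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that a maintainer would otherwise have
to reverse-engineer from the code.

## Matched library design

Candidates are kept if their length lies in the inclusive window
[44, 66] residues: below 44 the prior probability of domain-like structure
is poor, and 66 is the longest CDS a single synthesis oligo accommodates
once flanks and primer pads are added. When more candidates are compatible
than the target size *n* = 1,800, selection defaults to the *longest*
compatible candidates (ties broken by input order); `first` and `random`
are available.

The random library is generated by drawing residues i.i.d. from the pooled
amino-acid frequency distribution of the selected candidates, from a single
seeded NumPy generator, with the length multiset copied index-by-index.
Consequences worth stating: the length multiset matches *exactly*; the
composition matches only statistically, with total-variation distance
shrinking as (pooled residues)^(-1/2) — about 0.005–0.008 at 1,800 × ~55
residues, comfortably below the 0.01 design target. We deliberately do not
match GC content, dinucleotide bias, or per-position composition: the
random library is a composition-and-length control, not a simulated genomic
ORF.

## Oligo design

Two deterministic reverse-translation modes are provided. `max` uses each
amino acid's highest-frequency codon in the host table. `harmonized`
apportions each amino acid's occurrences across its synonymous codons in
proportion to host usage by largest-remainder apportionment (remainder,
then frequency, then alphabetical tie-breaks), spending quotas left-to-right
in descending-frequency order. The harmonized mode is this package's own
stand-in for external codon-harmonization optimizers; it preserves host
codon-usage *proportions* exactly up to rounding, which is the property the
comparison needs.

Constraint repair walks violations left-to-right. A violation is any
occurrence of a forbidden motif (defaults: NdeI `CATATG`, XhoI `CTCGAG`,
EcoRI `GAATTC`, BamHI `GGATCC` — the latter two because the libraries are
later PCR-amplified with primers introducing EcoRI/BamHI and must not cut
internally) or any homopolymer run of 5 bp or longer (max run 4). Scanning
is on the sense strand of `left_context + CDS + right_context`, so
junction-spanning problems are caught, but only CDS codons are editable; the
designed NdeI (flank `CAT` + leading `ATG`) and XhoI (right flank) sites
are whitelisted by position. At each violation, all synonymous single-codon
substitutions over codons overlapping the violating window are scored. The
progress measure is the lexicographic *badness* (violation count, total
excess length): a swap that shrinks an 8-bp run to 5 bp is progress even
though the count is unchanged. Among badness-reducing swaps the one with
maximal Σ log *w* (relative codon adaptiveness) wins; if none reduces
badness, a badness-preserving swap to a previously unseen codon assignment
is taken (needed, e.g., for Glu-Phe-Phe `GAA-TTT-TTC`, where the only
run-removing swap creates `GAATTC` and a second swap must clean it up).
Badness never increases and states never repeat, so the bounded iteration
(10 × CDS length) terminates; unsatisfiable inputs raise a design failure
naming the variant. Stop codons never enter: substitutions draw only from
sense codons, and CDSs carry no stop because the libraries are expressed as
internal fusions.

Primer pads are generated per library (40–60% GC, no forbidden motif also
when abutting the flanks, runs capped at 3 — stricter than the oligo-wide
limit so junctions stay safe — and pairwise Hamming ≥ 6). Proteins lacking
a leading Met get one prepended (logged): the `CAT` flank plus `ATG` *is*
the NdeI site. Reverse-complement-strand motif scanning is intentionally
not part of validation defaults; synthesis and cloning act on the designed
strand and the whitelist is positional.

## Sequence features

- **GRAVY**: mean Kyte–Doolittle hydropathy (table shipped as data).
- **Charge / isoelectric point**: Henderson–Hasselbalch sum over the two
  termini and D, E, C, Y, H, K, R side chains with EMBOSS default pKa
  values (shipped as editable data). Each term is strictly decreasing in
  pH, so the IEP is the unique root; bisection runs to an interval of
  1e-7 pH because the charge curve can be nearly flat at the root and a
  charge tolerance alone does not pin the pH down.
- **Low-complexity regions**: per window (default 15) and residue, the
  binomial tail P(X ≥ observed | window, background frequency); windows
  with p < 1e-3 are merged per residue. The p-values are descriptive and
  deliberately not multiplicity-corrected.
- **Mean entropy**: mean Shannon entropy over sliding windows (default 10),
  in bits; sequences shorter than the window fall back to one whole-length
  window.
- **DnaK sites**: score = mean core hydropathy (5 residues) + 0.5 per K/R
  in the two flanking positions; windows ≥ threshold merged. This is an
  explicitly simplified heuristic for the chaperone's preference for short
  hydrophobic stretches with basic flanks, not a reimplementation of any
  trained predictor, and no numeric agreement with such tools is claimed.
  The default threshold (0.25) was calibrated once on the DN-like synthetic
  fixture toward a target of ~4 merged sites per sequence; because
  overlapping windows merge, the achievable mean saturates near 3.0 for
  44–66-mers and the non-monotone threshold→count curve is searched on a
  grid (`calibrate_dnak_threshold`), not bisected. Known limitation: the
  merged-site count under-resolves adjacent binding regions.

## Selection-assay quantification

Reads follow the simulator convention `bc5(8) + pad + CDS + pad + bc3(8)`
on the sense strand (an `rc` flag enables reverse-complement rescue for
real data). Demultiplexing accepts a read if both barcodes are within 1
mismatch of a unique sample; ties and misses are left unassigned. Read →
variant assignment tries an exact dictionary hit, then the unique nearest
reference within edit distance 2 (edlib, length-bucketed); equidistant hits
are ambiguous and discarded. RPM is count / assigned-total × 10⁶ per
sample; a variant is detected at ≥ 100 RPM (inclusive — the filter removes
variants *below* 0.01% of sample reads), and a sample with zero assigned
reads is excluded with a flag rather than poisoning downstream ratios.

Survival is the mean over replicates of the paired ratio
(post-selection detected fraction) / (pre-selection detected fraction),
pairing the ampicillin and no-ampicillin platings of the same
transformation/plating index. The per-replicate-ratio form (rather than the
ratio of pooled means) is what makes the reported survival consistent with
its own per-condition detected fractions. Outliers among ratios are removed
by iterative two-sided Grubbs at α = 0.05 with at most one exclusion per
group — the outlier criterion is this package's documented choice, sized so
that a 9-replicate group can drop to 8 but no further. Confidence intervals
are t-based on the retained ratios; between-library comparisons use
one-tailed Welch (unequal-variance) tests, unadjusted. Degenerate input
(zero variance in both groups, equal means) returns p = 0.5 by convention.

## Blot decomposition

With T₀,S₀ the Lon⁻ total/soluble lane intensities and T₁,S₁ the Lon⁺
lanes, all divided by T₀:

    sol_undeg   = S₁/T₀            sol_deg   = (S₀−S₁)/T₀
    insol_undeg = (T₁−S₁)/T₀       insol_deg = (T₀−S₀−T₁+S₁)/T₀

This is the unique linear accounting of soluble/insoluble ×
degraded/undegraded mass normalized to the Lon⁻ total, and the four raw
components sum to 1 identically. Densitometry is noisy: S > T and T₁ > T₀
are clipped (components floored at 0, vector renormalized) and flagged, not
errored. Intensities are comparable only within a blot, so Lon⁻/Lon⁺ pairs
must share library, chaperone condition and replicate index — enforced at
pairing. Replicates are technical; aggregation reports per-component mean
and sd, and the one-tailed tests treat replicates as independent, a
documented simplification. Normalization is per replicate pair (not per
condition mean), the choice that keeps each replicate's components an exact
partition.

## Synthetic data: what it emulates and what it does not

The selection simulator reproduces the assay's *structure*: 1,800 variants
per library, three transformations × three platings = nine paired
replicates, multinomial sequencing at depth 10⁶ per sample, and i.i.d.
substitution errors at 0.3% per base. Latent state per variant: relative
abundance lognormal with σ = 0.5 across variants (oligo-pool synthesis
spread), jittered per transformation with σ = 0.1; survival probability
drawn from a Beta with concentration 0.02 — nearly binary variant fate,
reflecting that a fusion construct either tolerates export selection or
does not. Scenario means are 0.436 (DN) / 0.305 (R) at 37 °C and 0.713 /
0.697 at 30 °C. Survival acts as a deterministic weight in the
post-selection multinomial (the colony-count law-of-large-numbers limit);
colony-level stochasticity, PCR bias, chimeras and quality scores are not
modeled.

Two operating modes share this latent model. The *read-level* mode emits
per-sample FASTQ through the full barcode/pad/CDS construction with
explicit substitution errors and is used end-to-end at small scale. The
*count-level* mode skips read synthesis and folds sequencing errors into a
per-variant binomial read loss — a read with more than 2 substitutions
cannot be assigned at the edit-distance tolerance, and with ≤ 2 it is
assigned correctly because designed CDSs are mutually distant — which is
uniform thinning up to a small length-dependent term and therefore leaves
RPM fractions essentially unchanged. Large-scale statistics (the 20–100
seed scenario runs in the tests and acceptance script) use the count-level
mode; this is a deliberate problem-size choice, and the read-level path is
itself validated against hand computation and exact assignment tests.

What passing tests therefore show: the estimators recover the parameters
of *this* generative model (detected-fraction-ratio survival to within
~0.01–0.015 of truth at depth 10⁶, with a small positive bias from
renormalization of surviving variants' abundances against the 100-RPM
threshold; blot components to MAE ≈ 0.03 at CV 10%). What they do not
show: robustness to the cloning bottlenecks that depress real pre-selection
diversity to ~76% (our σ = 0.5 abundance model detects ~99.9% of variants
pre-selection), to indels (a stress flag exists), or to between-replicate
biological variability beyond the transformation jitter — real replicate
scatter is larger, so real p-values are far less extreme than simulated
ones.

The blot simulator draws each lane intensity as its latent mean times a
unit-mean lognormal factor with CV 10% (three replicates); CV = 0
reproduces the truth exactly under the decomposition, which is the
noiseless-inversion identity used in tests.

## Numerical and interface conventions

All intervals are 0-based half-open. All generators take integer seeds and
are byte-reproducible given (configuration, seed); derived child seeds come
from `numpy.random.SeedSequence` and stay below 2³¹. Ambiguous amino-acid
letters are rejected at ingest (designed libraries contain none). FASTQ
quality strings are carried but unused — quality handling belongs to an
upstream merged-read preprocessor, which is out of scope along with
paired-end merging, SAM/BAM emission, mass-spectrometry search, and any
reimplementation of external structure/disorder predictors.
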