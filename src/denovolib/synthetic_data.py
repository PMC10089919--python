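"""Synthetic inputs with known ground truth for every pipeline stage.

Generates candidate protein pools (a stand-in for published de novo
candidate lists), selection-assay sequencing data with known per-variant
survival, and blot intensities with known four-fraction composition, so the
whole pipeline can be exercised and its estimators checked for parameter
recovery without any external download.

The selection simulator mirrors the assay's replicate structure: three
transformations, each plated three times with and without ampicillin, for
nine paired replicates per library. Each variant carries a latent relative
abundance (lognormal across variants, mildly jittered per transformation)
and a latent survival probability s_i drawn from a Beta distribution whose
default concentration is far below 1, making variant fate near-binary: a
fusion construct either tolerates export selection or it does not.
Sequencing is multinomial at the configured depth; substitution errors can
be emitted per base (read-level mode) or, in the count-level fast path,
folded into a per-variant binomial read loss (a read with more than
``max_edit`` errors cannot be assigned to its reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_quant import (
    BarcodeScheme,
    SampleCondition,
    SurvivalEstimate,
    generate_barcode_scheme,
    one_tailed_welch,
    survival_from_counts,
)
from .blot_model import COMPONENTS, BlotMeasurement, FractionEstimate
from .core_io import AMINO_ACIDS, Origin, ProteinRecord

#: Average amino-acid frequencies of annotated proteins (UniProt-style
#: averages, normalized); the stand-in composition for candidate pools.
DEFAULT_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: Constant pads between barcode and CDS in simulated amplicon reads.
READ_PAD5 = "GTAC"
READ_PAD3 = "CATG"


def simulate_candidate_pool(
    n: int,
    length_range: tuple[int, int] = (44, 66),
    composition: Mapping[str, float] | None = None,
    seed: int = 0,
    fly_fraction: float = 176 / 1800,
    id_template: str = "DN{:04d}",
) -> list[ProteinRecord]:
    """Random candidate proteins emulating a de novo candidate list.

    Lengths are uniform over the (inclusive) range, residues i.i.d. from the
    composition, and a leading Met is enforced. The first
    ``round(fly_fraction * n)`` records are labelled fly-origin, the rest
    human, mirroring the 176/1,624 species split of the real candidate set.
    """
    comp = dict(composition or DEFAULT_COMPOSITION)
    aas = sorted(comp)
    probs = np.array([comp[a] for a in aas])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    n_fly = round(fly_fraction * n)
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "M" + "".join(rng.choice(aas, size=length - 1, p=probs))
        origin = Origin.denovo_fly if i < n_fly else Origin.denovo_human
        out.append(ProteinRecord(id_template.format(i + 1), origin, seq))
    return out


# ---------------------------------------------------------------------------
# Selection assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayTruth:
    """Ground-truth configuration for one simulated library selection."""

    n_variants: int = 1800
    survival_mean: float = 0.436
    survival_concentration: float = 0.02
    abundance_sigma: float = 0.5
    transformation_sigma: float = 0.1
    n_transformations: int = 3
    n_platings: int = 3
    depth: int = 1_000_000
    error_rate: float = 0.003
    max_edit: int = 2
    seed: int = 0

    @property
    def n_replicates(self) -> int:
        return self.n_transformations * self.n_platings


@dataclass
class AssayDraw:
    """Realized latent state: abundances, survival probabilities."""

    abundance: np.ndarray  # sums to 1
    survival: np.ndarray  # in [0, 1]

    @property
    def realized_mean_survival(self) -> float:
        return float(self.survival.mean())


def draw_assay_truth(truth: AssayTruth) -> AssayDraw:
    """Draw the latent per-variant state for one seed."""
    rng = np.random.default_rng(truth.seed)
    a = rng.lognormal(0.0, truth.abundance_sigma, truth.n_variants)
    a /= a.sum()
    c = truth.survival_concentration
    s = rng.beta(truth.survival_mean * c, (1 - truth.survival_mean) * c, truth.n_variants)
    return AssayDraw(abundance=a, survival=s)


def _mapping_keep_prob(cds_lengths: np.ndarray, truth: AssayTruth) -> np.ndarray:
    """P(read carries <= max_edit substitution errors) per variant.

    Reads with more errors than the assignment tolerance are unmappable; in
    the count-level fast path this is applied as binomial thinning.
    """
    from scipy import stats

    return stats.binom.cdf(truth.max_edit, cds_lengths, truth.error_rate)


def simulate_selection_counts(
    truth: AssayTruth,
    cds_lengths: np.ndarray | None = None,
    draw: AssayDraw | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, AssayDraw]:
    """Count-level assay simulation: (pre_counts, post_counts, draw).

    Each frame is variants x replicates (columns "rep1".."rep9"); column i
    of pre and post share a transformation/plating pair. When
    ``cds_lengths`` is given, sequencing substitution errors are folded in
    as per-variant read loss at the assignment tolerance.
    """
    if truth.depth <= 0:
        raise ValueError("depth must be positive")
    draw = draw or draw_assay_truth(truth)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    keep = (
        _mapping_keep_prob(np.asarray(cds_lengths), truth)
        if cds_lengths is not None
        else None
    )
    pre_cols, post_cols = {}, {}
    rep = 0
    for _ in range(truth.n_transformations):
        a_t = draw.abundance * rng.lognormal(0.0, truth.transformation_sigma, truth.n_variants)
        a_t /= a_t.sum()
        w = a_t * draw.survival
        w_sum = w.sum()
        for _ in range(truth.n_platings):
            rep += 1
            pre = rng.multinomial(truth.depth, a_t)
            post = (
                rng.multinomial(truth.depth, w / w_sum)
                if w_sum > 0
                else np.zeros(truth.n_variants, dtype=int)
            )
            if keep is not None:
                pre = rng.binomial(pre, keep)
                post = rng.binomial(post, keep)
            pre_cols[f"rep{rep}"] = pre
            post_cols[f"rep{rep}"] = post
    index = [f"v{i+1:04d}" for i in range(truth.n_variants)]
    return (
        pd.DataFrame(pre_cols, index=index),
        pd.DataFrame(post_cols, index=index),
        draw,
    )


def simulate_selection_reads(
    references: Mapping[str, str],
    truth: AssayTruth,
    scheme: BarcodeScheme | None = None,
    library: str = "DN",
    temperature: int = 37,
) -> tuple[dict[str, list[tuple[str, str, str]]], BarcodeScheme, AssayDraw]:
    """Read-level assay simulation for a designed CDS reference set.

    Returns ({sample_id: [(id, sequence, quality), ...]}, scheme, draw).
    Each read is bc5 + pad + CDS + pad + bc3 with i.i.d. substitution
    errors at ``truth.error_rate``; sample ids are "<lib>_pre_repN" /
    "<lib>_post_repN". Intended for modest depths; the count-level path
    covers large-scale statistics.
    """
    vids = list(references)
    if len(vids) != truth.n_variants:
        truth = replace(truth, n_variants=len(vids))
    if scheme is None:
        conditions = {}
        for r in range(1, truth.n_replicates + 1):
            conditions[f"{library}_pre_rep{r}"] = SampleCondition(library, temperature, 0, r)
            conditions[f"{library}_post_rep{r}"] = SampleCondition(library, temperature, 100, r)
        scheme = generate_barcode_scheme(conditions, seed=truth.seed)
    pre, post, draw = simulate_selection_counts(truth)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
    bases = np.array(list("ACGT"))

    def emit(sample: str, counts: np.ndarray) -> list[tuple[str, str, str]]:
        b5, b3 = scheme.barcodes[sample]
        reads = []
        k = 0
        for vi in np.flatnonzero(counts):
            template = b5 + READ_PAD5 + references[vids[vi]] + READ_PAD3 + b3
            arr = np.frombuffer(template.encode(), dtype="S1")
            for _ in range(int(counts[vi])):
                k += 1
                errs = np.flatnonzero(rng.random(len(template)) < truth.error_rate)
                seq = arr.copy()
                for pos in errs:
                    alt = [b for b in bases if b.encode() != seq[pos]]
                    seq[pos] = rng.choice(alt).encode()
                s = seq.tobytes().decode()
                reads.append((f"{sample}_read{k}", s, "I" * len(s)))
        return reads

    samples: dict[str, list[tuple[str, str, str]]] = {}
    for r in range(1, truth.n_replicates + 1):
        samples[f"{library}_pre_rep{r}"] = emit(f"{library}_pre_rep{r}", pre[f"rep{r}"].to_numpy())
        samples[f"{library}_post_rep{r}"] = emit(f"{library}_post_rep{r}", post[f"rep{r}"].to_numpy())
    return samples, scheme, draw


#: Library-level mean survival truths per assay scenario (selection
#: temperature), matching the regime the pipeline is meant to quantify.
SCENARIOS: dict[str, dict[str, float]] = {
    "37C": {"DN": 0.436, "R": 0.305},
    "30C": {"DN": 0.713, "R": 0.697},
}


def run_selection_scenario(
    scenario: str = "37C",
    seed: int = 0,
    n_variants: int = 1800,
    depth: int = 1_000_000,
    cds_lengths: np.ndarray | None = None,
    **truth_overrides,
) -> dict:
    """Simulate both libraries for a scenario and estimate survival.

    Returns per-library SurvivalEstimate objects, realized truths, detected
    fractions, and the one-tailed Welch test of DN survival > R survival.
    """
    means = SCENARIOS[scenario]
    out: dict = {"scenario": scenario, "libraries": {}}
    retained: dict[str, list[float]] = {}
    for k, (lib, mean) in enumerate(means.items()):
        truth = AssayTruth(
            n_variants=n_variants,
            survival_mean=mean,
            depth=depth,
            seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)),
            **truth_overrides,
        )
        pre, post, draw = simulate_selection_counts(truth, cds_lengths=cds_lengths)
        est = survival_from_counts(pre, post, n_designed=n_variants)
        pre_rpm = pre / pre.sum(axis=0) * 1e6
        out["libraries"][lib] = {
            "truth_mean": mean,
            "realized_mean": draw.realized_mean_survival,
            "estimate": est,
            "pre_detected": float((pre_rpm >= 100).sum(axis=0).mean()) / n_variants,
        }
        retained[lib] = est.retained
    out["welch"] = one_tailed_welch(retained["DN"], retained["R"], alternative="greater")
    return out


# ---------------------------------------------------------------------------
# Blot simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlotTruth:
    """Ground truth for one library/condition blot series."""

    fractions: tuple[float, float, float, float] = (0.25, 0.15, 0.45, 0.15)
    library: str = "DN"
    chaperone: str = "none"
    scale: float = 1000.0
    cv: float = 0.10
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("truth fractions must sum to 1")


def simulate_blot(truth: BlotTruth) -> list[BlotMeasurement]:
    """Simulate lane intensities under multiplicative lognormal noise.

    Per replicate, the four latent lane means are
    T0 = scale, S0 = scale * (sol_undeg + sol_deg),
    T1 = scale * (sol_undeg + insol_undeg), S1 = scale * sol_undeg,
    each multiplied by an independent lognormal factor with the configured
    coefficient of variation. cv=0 reproduces the truth exactly under
    infer_fractions.
    """
    su, sd, iu, idg = truth.fractions
    rng = np.random.default_rng(truth.seed)
    sigma = float(np.sqrt(np.log1p(truth.cv**2)))
    mu = -0.5 * sigma**2  # unit-mean noise
    out = []
    for rep in range(1, truth.replicates + 1):
        eps = rng.lognormal(mu, sigma, 4) if truth.cv > 0 else np.ones(4)
        T0 = truth.scale * eps[0]
        S0 = truth.scale * (su + sd) * eps[1]
        T1 = truth.scale * (su + iu) * eps[2]
        S1 = truth.scale * su * eps[3]
        base = dict(library=truth.library, chaperone=truth.chaperone, replicate=rep)
        out.append(BlotMeasurement(lon=False, intensity_T=T0, intensity_S=S0, **base))
        out.append(BlotMeasurement(lon=True, intensity_T=T1, intensity_S=S1, **base))
    return out


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def truth_report(
    truth_values: Mapping[str, float],
    estimates: Mapping[str, float],
    cis: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Bias, mean absolute error and (optionally) CI coverage.

    Keys of ``estimates`` must match ``truth_values`` exactly.
    """
    if set(truth_values) != set(estimates):
        raise ValueError("mismatched ids between truth and estimates")
    keys = sorted(truth_values)
    diffs = np.array([estimates[k] - truth_values[k] for k in keys])
    report = {
        "bias": float(diffs.mean()),
        "mae": float(np.abs(diffs).mean()),
        "n": len(keys),
    }
    if cis is not None:
        cover = [cis[k][0] <= truth_values[k] <= cis[k][1] for k in keys if k in cis]
        report["ci_coverage"] = float(np.mean(cover)) if cover else float("nan")
    return report


def blot_recovery(
    truth: BlotTruth,
    n_sims: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Mean absolute component error of infer_fractions over simulations.

    Each simulated experiment draws ``truth.replicates`` noisy Lon-/Lon+
    pairs, averages the per-replicate estimates, and contributes its mean
    absolute error over the four components.
    """
    from .blot_model import infer_fractions, pair_measurements

    seeds = np.random.SeedSequence([seed, 3]).generate_state(n_sims) % (2**31)
    maes = []
    for s in seeds:
        ms = simulate_blot(replace(truth, seed=int(s)))
        ests = [infer_fractions(lo, hi) for lo, hi in pair_measurements(ms)]
        mean_vec = np.mean([e.as_vector() for e in ests], axis=0)
        maes.append(np.abs(mean_vec - np.array(truth.fractions)).mean())
    return {"component_mae": float(np.mean(maes)), "n_sims": n_sims}
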