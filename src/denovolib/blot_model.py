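"""Solubility and degradability decomposition from blot densitometry.

Cell-free expression of each library is blotted as a total (T) lane and a
soluble (S) lane; S/T estimates the soluble fraction. Adding Lon protease
(which preferentially degrades disordered, exposed-hydrophobic protein)
gives a second T/S pair, and the four-way decomposition

    sol_undeg   = S1 / T0
    sol_deg     = (S0 - S1) / T0
    insol_undeg = (T1 - S1) / T0
    insol_deg   = (T0 - S0 - T1 + S1) / T0

(with T0,S0 the Lon- lanes and T1,S1 the Lon+ lanes, all normalized by the
Lon- total) is the unique linear accounting of soluble/insoluble x
degraded/undegraded mass that sums to 1 exactly. Densitometry noise can
drive individual components negative; they are clipped to 0 and the vector
renormalized, with a flag recorded. Intensities are comparable only within
a blot, so Lon-/Lon+ pairs must share a replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay_quant import one_tailed_welch

COMPONENTS = ("sol_undeg", "sol_deg", "insol_undeg", "insol_deg")


@dataclass(frozen=True)
class BlotMeasurement:
    """One blot replicate: total and soluble lane intensities."""

    library: str  # "DN" | "R"
    chaperone: str  # "none" | "DnaK" | "GroEL" | "DnaK+GroEL"
    lon: bool  # Lon protease present
    replicate: int
    intensity_T: float
    intensity_S: float

    def __post_init__(self) -> None:
        if self.intensity_T <= 0 or self.intensity_S <= 0:
            raise ValueError("lane intensities must be positive")


@dataclass
class FractionEstimate:
    """Four-way solubility x degradability composition of one replicate."""

    sol_undeg: float
    sol_deg: float
    insol_undeg: float
    insol_deg: float
    flags: list[str] = field(default_factory=list)

    def as_vector(self) -> np.ndarray:
        return np.array([self.sol_undeg, self.sol_deg, self.insol_undeg, self.insol_deg])

    @property
    def soluble_fraction(self) -> float:
        return self.sol_undeg + self.sol_deg


def soluble_fraction(T: float, S: float) -> float:
    """S/T clipped to [0, 1]; S > T is treated as densitometry noise."""
    if T <= 0:
        raise ValueError("total-lane intensity must be positive")
    return float(np.clip(S / T, 0.0, 1.0))


def infer_fractions(
    m_lonminus: BlotMeasurement, m_lonplus: BlotMeasurement
) -> FractionEstimate:
    """Four-way decomposition from a paired Lon-/Lon+ replicate.

    The raw components sum to 1 identically; negative values (noise) are
    clipped to 0 and the vector renormalized, recording a flag per clip.
    """
    if m_lonplus.lon is False or m_lonminus.lon is True:
        raise ValueError("arguments must be (Lon- measurement, Lon+ measurement)")
    same = (
        m_lonminus.library == m_lonplus.library
        and m_lonminus.chaperone == m_lonplus.chaperone
        and m_lonminus.replicate == m_lonplus.replicate
    )
    if not same:
        raise ValueError("Lon-/Lon+ pair must match library, chaperone and replicate")
    T0, S0 = m_lonminus.intensity_T, m_lonminus.intensity_S
    T1, S1 = m_lonplus.intensity_T, m_lonplus.intensity_S
    if T0 <= 0:
        raise ValueError("Lon- total intensity must be positive")
    raw = np.array(
        [S1 / T0, (S0 - S1) / T0, (T1 - S1) / T0, (T0 - S0 - T1 + S1) / T0]
    )
    flags = [f"clipped_{COMPONENTS[i]}" for i in np.flatnonzero(raw < 0)]
    clipped = np.clip(raw, 0.0, None)
    vec = clipped / clipped.sum()
    return FractionEstimate(*vec.tolist(), flags=flags)


def aggregate_fractions(estimates: Sequence[FractionEstimate]) -> dict[str, tuple[float, float]]:
    """Per-component (mean, sd) over replicates."""
    mat = np.array([e.as_vector() for e in estimates])
    return {
        c: (float(mat[:, i].mean()), float(mat[:, i].std(ddof=1)) if len(mat) > 1 else 0.0)
        for i, c in enumerate(COMPONENTS)
    }


def degraded_total(est: FractionEstimate) -> float:
    """Degraded mass fraction regardless of solubility."""
    return est.sol_deg + est.insol_deg


def compare_blot(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "greater",
) -> dict[str, float]:
    """One-tailed Welch test on replicate-level fraction values."""
    return one_tailed_welch(group_a, group_b, alternative=alternative)


def pair_measurements(
    measurements: Sequence[BlotMeasurement],
) -> list[tuple[BlotMeasurement, BlotMeasurement]]:
    """Group a flat measurement list into matched Lon-/Lon+ replicate pairs."""
    key = lambda m: (m.library, m.chaperone, m.replicate)
    minus = {key(m): m for m in measurements if not m.lon}
    plus = {key(m): m for m in measurements if m.lon}
    missing = set(minus) ^ set(plus)
    if missing:
        raise ValueError(f"unpaired Lon conditions for: {sorted(missing)}")
    return [(minus[k], plus[k]) for k in sorted(minus)]
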