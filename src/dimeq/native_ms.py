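"""Charge-state bookkeeping for native mass spectra.

Native MS quantifies non-covalent species from the summed intensities of
their charge-state series.  This module covers the minimal arithmetic:
m/z positions of protonated charge states, peak-to-species assignment
within a ppm tolerance (ambiguous peaks are flagged and excluded from
quantification), and conversion of assigned series into per-species
signal fractions.  Positive-ion protonation only; no adducts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

__all__ = [
    "PROTON_MASS",
    "ChargeSeries",
    "AssignmentResult",
    "compute_mz",
    "assign_species_peaks",
    "species_signal_fractions",
]

#: proton mass in Da
PROTON_MASS = 1.00728


def compute_mz(mass: float, z: int) -> float:
    """m/z (Th) of a species of neutral ``mass`` carrying ``z`` protons."""
    if mass <= 0:
        raise ValidationError("mass must be > 0")
    if z < 1:
        raise ValidationError("charge must be >= 1")
    return (mass + z * PROTON_MASS) / z


@dataclass
class ChargeSeries:
    """Assigned charge-state series of one species."""

    species: str
    mass: float
    charges: list[int] = field(default_factory=list)
    mz_values: list[float] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)

    @property
    def total_intensity(self) -> float:
        return float(sum(self.intensities))


@dataclass
class AssignmentResult:
    """Outcome of peak assignment: assigned series plus rejects."""

    series: list[ChargeSeries]
    ambiguous: list[tuple[float, float]]
    unassigned: list[tuple[float, float]]


def assign_species_peaks(
    peaks: list[tuple[float, float]],
    candidates: list[tuple[str, float]],
    tolerance_ppm: float = 50.0,
    z_range: tuple[int, int] = (1, 50),
) -> AssignmentResult:
    """Assign (mz, intensity) peaks to candidate (species, mass) charge states.

    A peak matches (species, z) when |mz - mz_theo| / mz_theo * 1e6 is
    within ``tolerance_ppm``.  Peaks matching more than one species are
    flagged ambiguous and excluded from quantification; peaks matching
    nothing are reported unassigned.
    """
    if tolerance_ppm <= 0:
        raise ValidationError("tolerance_ppm must be > 0")
    z_lo, z_hi = z_range
    if z_lo < 1 or z_hi < z_lo:
        raise ValidationError("invalid charge range")
    theo = []  # (species, mass, z, mz)
    for species, mass in candidates:
        for z in range(z_lo, z_hi + 1):
            theo.append((species, mass, z, compute_mz(mass, z)))

    series: dict[str, ChargeSeries] = {
        sp: ChargeSeries(species=sp, mass=m) for sp, m in candidates
    }
    ambiguous: list[tuple[float, float]] = []
    unassigned: list[tuple[float, float]] = []
    for mz, intensity in peaks:
        hits = [
            (sp, z, mz_t)
            for sp, _m, z, mz_t in theo
            if abs(mz - mz_t) / mz_t * 1e6 <= tolerance_ppm
        ]
        hit_species = {sp for sp, _z, _ in hits}
        if not hits:
            unassigned.append((mz, intensity))
        elif len(hit_species) > 1:
            ambiguous.append((mz, intensity))
        else:
            sp, z, _ = hits[0]
            s = series[sp]
            s.charges.append(z)
            s.mz_values.append(mz)
            s.intensities.append(float(intensity))
    return AssignmentResult(
        [s for s in series.values()], ambiguous, unassigned
    )


def species_signal_fractions(series: list[ChargeSeries]) -> dict[str, float]:
    """Per-species fraction of total summed intensity; sums to 1."""
    if not series:
        raise ValidationError("at least one charge series is required")
    totals = {s.species: s.total_intensity for s in series}
    grand = sum(totals.values())
    if grand <= 0:
        raise ValidationError("all-zero intensities: fractions undefined")
    return {sp: t / grand for sp, t in totals.items()}


def read_peak_list(path) -> list[tuple[float, float]]:
    """Read a two-column (mz, intensity) CSV peak list."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "mz" not in cols or "intensity" not in cols:
        raise ValidationError(f"{path}: expected columns mz, intensity")
    df.columns = cols
    return list(zip(df["mz"].astype(float), df["intensity"].astype(float)))
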