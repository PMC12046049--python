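"""Forward model of the competitive FLNC d24 dimerisation system.

Two coupled equilibria share the FLNC monomer F:

    F2 <-> 2 F        kd_homo   = [F]^2 / [F2]
    FH <-> F + H      kd_hetero = [F][H] / [FH]

HSPB7 (H) does not self-dimerise, so the only H-containing complex is the
heterodimer FH.  Eliminating [H] = h_total / (1 + [F]/kd_hetero) reduces the
system to a single mass balance in the free FLNC monomer concentration,

    g([F]) = [F] + 2 [F]^2 / kd_homo + [F] h_total / (kd_hetero + [F]) - f_total,

which is strictly increasing on [0, f_total] and therefore has a unique
root, found here by bracketed root-finding.  On top of the solver this
module provides the analytic homodimer-only solution (the h_total = 0
oracle), noise-free titration simulation under a choice of signal model,
and the 1:1 peptide-binding isotherm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .errors import NumericalError, ValidationError
from .titration import SIGNAL_MODELS, SPECIES, TitrationDataset, make_dataset

__all__ = [
    "EquilibriumSystem",
    "SpeciesState",
    "solve_species",
    "homodimer_closed_form",
    "species_fractions",
    "simulate_titration",
    "peptide_isotherm",
]


@dataclass(frozen=True)
class EquilibriumSystem:
    """Dissociation constants and totals defining one solution condition.

    Parameters are molar.  ``kd_homo`` is the FLNC homodimer dissociation
    constant, ``kd_hetero`` the FLNC:HSPB7 heterodimer one; either may be
    ``math.inf`` to disable the corresponding complex.
    """

    kd_homo: float
    kd_hetero: float
    f_total: float
    h_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kd_homo", "kd_hetero", "f_total", "h_total"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or math.isnan(v):
                raise ValidationError(f"{name} must be a finite number, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.kd_homo == 0 or self.kd_hetero == 0:
            raise ValidationError("dissociation constants must be strictly positive")
        for name in ("f_total", "h_total"):
            if math.isinf(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (molar) of the four species."""

    f_mono: float
    f_dimer: float
    h_mono: float
    fh_hetero: float

    def as_array(self) -> np.ndarray:
        """Concentrations ordered as :data:`dimeq.titration.SPECIES`."""
        return np.array([self.f_mono, self.f_dimer, self.fh_hetero, self.h_mono])


def _mass_balance(f: float, system: EquilibriumSystem) -> float:
    homo = 0.0 if math.isinf(system.kd_homo) else 2.0 * f * f / system.kd_homo
    hetero = (
        0.0
        if math.isinf(system.kd_hetero)
        else f * system.h_total / (system.kd_hetero + f)
    )
    return f + homo + hetero - system.f_total


def solve_species(system: EquilibriumSystem, max_iter: int = 200) -> SpeciesState:
    """Solve the coupled equilibria for the species concentrations.

    Uses bracketed root-finding on the monotone single-variable mass
    balance in the free monomer concentration; the bracket [0, f_total]
    always contains the unique root.
    """
    if system.f_total == 0.0:
        return SpeciesState(0.0, 0.0, system.h_total, 0.0)
    g0 = _mass_balance(0.0, system)
    g1 = _mass_balance(system.f_total, system)
    if g0 > 0 or g1 < 0:  # pragma: no cover - unreachable for valid systems
        raise NumericalError("mass balance bracket failed; inputs inconsistent")
    # absolute tolerance far below any concentration of interest, so the
    # relative tolerance (machine precision) governs; the root can sit many
    # orders of magnitude below f_total in tight-capping regimes
    xtol = max(1e-18 * system.f_total, 5e-324)
    try:
        f = brentq(
            _mass_balance,
            0.0,
            system.f_total,
            args=(system,),
            xtol=xtol,
            rtol=8.9e-16,
            maxiter=max_iter,
        )
    except RuntimeError as exc:  # pragma: no cover - monotone bracket
        raise NumericalError(f"species solver did not converge: {exc}") from exc
    f = float(f)
    f_dimer = 0.0 if math.isinf(system.kd_homo) else f * f / system.kd_homo
    if math.isinf(system.kd_hetero):
        fh = 0.0
    else:
        fh = f * system.h_total / (system.kd_hetero + f)
    h_mono = system.h_total - fh
    return SpeciesState(f, f_dimer, max(h_mono, 0.0), fh)


def homodimer_closed_form(kd_homo: float, f_total: float) -> SpeciesState:
    """Analytic solution of the homodimer-only system (h_total = 0).

    From 2 [F]^2 / kd + [F] = f_total the free monomer is the positive
    quadratic root ``kd (-1 + sqrt(1 + 8 f_total / kd)) / 4``.
    """
    if kd_homo <= 0:
        raise ValidationError("kd_homo must be > 0")
    if f_total < 0:
        raise ValidationError("f_total must be >= 0")
    if f_total == 0.0:
        return SpeciesState(0.0, 0.0, 0.0, 0.0)
    if math.isinf(kd_homo):
        return SpeciesState(f_total, 0.0, 0.0, 0.0)
    # sqrt(1+r)-1 written as r/(sqrt(1+r)+1) to avoid cancellation when
    # f_total << kd; the dimer from the equilibrium expression (not the
    # mass-balance remainder) for the same reason
    ratio = 8.0 * f_total / kd_homo
    f = kd_homo * ratio / (math.sqrt(1.0 + ratio) + 1.0) / 4.0
    f_dimer = f * f / kd_homo
    return SpeciesState(f, f_dimer, 0.0, 0.0)


def _homodimer_free_monomer(kd_homo: float, f_total: np.ndarray) -> np.ndarray:
    """Vectorised closed-form free monomer for the h_total = 0 case."""
    f_total = np.asarray(f_total, dtype=float)
    return kd_homo * (np.sqrt(1.0 + 8.0 * f_total / kd_homo) - 1.0) / 4.0


def species_fractions(
    kd_homo: float,
    kd_hetero: float,
    f_totals: np.ndarray,
    h_totals: np.ndarray,
    signal_model: str = "species_molar",
) -> np.ndarray:
    """Noise-free signal fractions, shape (n_points, 4).

    Columns follow :data:`dimeq.titration.SPECIES`:
    (monomer, homodimer, heterodimer, hsp_monomer).

    Under ``species_molar`` the signal of each species is proportional to
    its molar concentration; ``per_subunit`` weights dimeric species by
    the number of subunits they contain (x2).
    """
    if signal_model not in SIGNAL_MODELS:
        raise ValidationError(f"unknown signal model {signal_model!r}")
    f_totals = np.asarray(f_totals, dtype=float)
    h_totals = np.asarray(h_totals, dtype=float)
    n = f_totals.size
    conc = np.zeros((n, 4))
    if np.all(h_totals == 0.0):
        f = _homodimer_free_monomer(kd_homo, f_totals)
        conc[:, 0] = f
        conc[:, 1] = (f_totals - f) / 2.0
    else:
        for i in range(n):
            st = solve_species(
                EquilibriumSystem(kd_homo, kd_hetero, f_totals[i], h_totals[i])
            )
            conc[i] = st.as_array()
    weights = np.array([1.0, 2.0, 2.0, 1.0]) if signal_model == "per_subunit" else np.ones(4)
    signal = conc * weights
    totals = signal.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError("cannot form fractions: zero total signal at a point")
    return signal / totals[:, None]


def simulate_titration(
    system_template: EquilibriumSystem,
    f_total_series: Iterable[float],
    signal_model: str = "species_molar",
    label: str = "",
) -> TitrationDataset:
    """Noise-free titration: solve the system at each point of the series.

    ``system_template`` supplies KDs and h_total; ``f_total_series`` must
    be strictly positive and sorted ascending.
    """
    series = np.asarray(list(f_total_series), dtype=float)
    if series.size == 0:
        raise ValidationError("f_total_series must not be empty")
    if np.any(series <= 0):
        raise ValidationError("f_total_series must be strictly positive")
    if np.any(np.diff(series) <= 0):
        raise ValidationError("f_total_series must be sorted strictly ascending")
    h = np.full_like(series, system_template.h_total)
    fractions = species_fractions(
        system_template.kd_homo, system_template.kd_hetero, series, h, signal_model
    )
    return make_dataset(series, h, fractions[None, :, :], signal_model, label)


def peptide_isotherm(
    kd: float,
    ligand_total: float,
    receptor_total: float = 0.0,
    mode: str = "free_ligand_approx",
) -> float:
    """Fraction of receptor bound under a 1:1 isotherm.

    ``free_ligand_approx`` treats the total ligand as free (the Hill model
    with slope and Bmax fixed at 1); ``exact_depletion`` solves the
    single-site quadratic accounting for ligand consumed by binding.
    """
    if kd <= 0:
        raise ValidationError("kd must be > 0")
    if ligand_total < 0 or receptor_total < 0:
        raise ValidationError("concentrations must be >= 0")
    if mode == "free_ligand_approx":
        return ligand_total / (kd + ligand_total)
    if mode == "exact_depletion":
        if receptor_total == 0.0:
            return ligand_total / (kd + ligand_total)
        s = receptor_total + ligand_total + kd
        bound = (s - math.sqrt(s * s - 4.0 * receptor_total * ligand_total)) / 2.0
        return min(max(bound / receptor_total, 0.0), 1.0)
    raise ValidationError(f"unknown isotherm mode {mode!r}")
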