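"""Dissociation-constant estimation from replicate titration fractions.

All fits minimise a least-squares objective over log10(KD) with a bounded
scalar optimiser; the residual surface of the 1-D forward models used here
is unimodal, so no multi-start is needed.  By default each technical
replicate is fitted independently and the estimate is reported as
mean +/- SD across replicates (a weighted fit to the replicate means is
available via ``replicate_mode="mean"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .equilibria import species_fractions
from .errors import ValidationError
from .titration import SPECIES, TitrationDataset

__all__ = [
    "KdEstimate",
    "FitWarning",
    "fit_homodimer_kd",
    "fit_heterodimer_kd",
    "fit_peptide_kd",
    "bootstrap_uncertainty",
]

#: log10 bracket (in molar) for all KD searches
LOG10_KD_BRACKET = (-12.0, -2.0)


class FitWarning(UserWarning):
    """Non-fatal fitting diagnostics (boundary estimates, degenerate data)."""


@dataclass(frozen=True)
class KdEstimate:
    """A fitted dissociation constant with its uncertainty."""

    kd: float
    sd: float
    n_replicates: int
    residual_rms: float
    method: str

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValidationError("kd must be > 0")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


def _minimise_log_kd(objective: Callable[[float], float], xatol: float = 1e-9) -> float:
    lo, hi = LOG10_KD_BRACKET
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    x = float(res.x)
    if x < lo + 1e-3 or x > hi - 1e-3:
        warnings.warn(
            "KD estimate is at the search boundary; the data carry no curvature "
            "(all-monomer or all-dimer) and the value is a bound, not an estimate",
            FitWarning,
            stacklevel=3,
        )
    return x


def _check_min_points(data: TitrationDataset) -> None:
    if data.n_points < 3:
        raise ValidationError(
            f"fitting requires >= 3 concentration points, got {data.n_points}"
        )


def _summarise(kds: np.ndarray, rms: float, method: str) -> KdEstimate:
    if kds.size == 1:
        warnings.warn(
            "single-replicate dataset: SD reported as 0", FitWarning, stacklevel=3
        )
        sd = 0.0
    else:
        sd = float(np.std(kds, ddof=1))
    return KdEstimate(float(np.mean(kds)), sd, int(kds.size), rms, method)


def _replicate_tables(data: TitrationDataset, replicate_mode: str):
    """Yield (f_totals, h_totals, fraction matrix) per fit unit."""
    if replicate_mode == "independent":
        for rep in data.replicates:
            mat = data.fraction_matrix(rep)
            idx = mat.index.to_frame(index=False)
            yield idx["f_total"].to_numpy(), idx["h_total"].to_numpy(), mat.to_numpy()
    elif replicate_mode == "mean":
        mats = [data.fraction_matrix(rep) for rep in data.replicates]
        mean = sum(m.to_numpy() for m in mats) / len(mats)
        idx = mats[0].index.to_frame(index=False)
        yield idx["f_total"].to_numpy(), idx["h_total"].to_numpy(), mean
    else:
        raise ValidationError(f"unknown replicate_mode {replicate_mode!r}")


def fit_homodimer_kd(
    data: TitrationDataset, replicate_mode: str = "independent"
) -> KdEstimate:
    """Fit the homodimer KD from a FLNC-only titration (h_total = 0).

    The objective is the squared deviation of the observed homodimer
    signal fraction from the closed-form prediction, summed over points.
    """
    _check_min_points(data)
    if (data.df["h_total"] != 0).any():
        raise ValidationError("homodimer fit requires h_total = 0 at every point")
    all_obs = data.df[data.df["species"] == "homodimer"]["fraction"].to_numpy()
    if np.all(all_obs < 0.05) or np.all(all_obs > 0.95):
        warnings.warn(
            "no curvature in the titration (all-monomer or all-dimer data): "
            "the KD is a boundary estimate, not a measurement",
            FitWarning,
            stacklevel=2,
        )
    kds, sses, n_obs = [], 0.0, 0
    for f_tot, h_tot, frac in _replicate_tables(data, replicate_mode):
        obs = frac[:, SPECIES.index("homodimer")]

        def sse(log_kd: float) -> float:
            pred = species_fractions(
                10.0**log_kd, np.inf, f_tot, h_tot, data.signal_model
            )[:, SPECIES.index("homodimer")]
            return float(np.sum((obs - pred) ** 2))

        x = _minimise_log_kd(sse)
        kds.append(10.0**x)
        sses += sse(x)
        n_obs += obs.size
    return _summarise(np.array(kds), float(np.sqrt(sses / n_obs)), "homodimer_lsq")


def _fit_hetero_once(data, kd_homo_value: float, replicate_mode: str):
    kds, sses, n_obs = [], 0.0, 0
    for f_tot, h_tot, frac in _replicate_tables(data, replicate_mode):

        def sse(log_kd: float) -> float:
            pred = species_fractions(
                kd_homo_value, 10.0**log_kd, f_tot, h_tot, data.signal_model
            )
            return float(np.sum((frac - pred) ** 2))

        x = _minimise_log_kd(sse)
        kds.append(10.0**x)
        sses += sse(x)
        n_obs += frac.size
    return np.array(kds), float(np.sqrt(sses / n_obs))


def fit_heterodimer_kd(
    data: TitrationDataset,
    kd_homo: KdEstimate,
    replicate_mode: str = "independent",
) -> KdEstimate:
    """Fit the heterodimer KD with the homodimer KD held fixed.

    Residuals run over all four species fractions simultaneously.  The
    homodimer-KD uncertainty is propagated by refitting at
    kd_homo +/- sd and adding half the spread in quadrature to the
    replicate SD.
    """
    _check_min_points(data)
    if (data.df["h_total"] <= 0).any():
        raise ValidationError("heterodimer fit requires h_total > 0 at every point")
    kds, rms = _fit_hetero_once(data, kd_homo.kd, replicate_mode)
    est = _summarise(kds, rms, "heterodimer_lsq")
    if kd_homo.sd > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitWarning)
            hi, _ = _fit_hetero_once(data, kd_homo.kd + kd_homo.sd, replicate_mode)
            lo, _ = _fit_hetero_once(
                data, max(kd_homo.kd - kd_homo.sd, kd_homo.kd * 1e-3), replicate_mode
            )
        spread = abs(float(np.mean(hi)) - float(np.mean(lo))) / 2.0
        est = KdEstimate(
            est.kd,
            float(np.hypot(est.sd, spread)),
            est.n_replicates,
            est.residual_rms,
            est.method,
        )
    return est


def fit_peptide_kd(
    data: TitrationDataset, replicate_mode: str = "independent"
) -> KdEstimate:
    """Fit a 1:1 binding KD from fraction-bound vs ligand concentration.

    The dataset encodes fraction bound as the ``heterodimer`` species
    fraction, with ligand concentration in ``f_total``.  The model is the
    Hill isotherm with slope and Bmax fixed at 1.
    """
    _check_min_points(data)
    kds, sses, n_obs = [], 0.0, 0
    informative = False
    for f_tot, _h_tot, frac in _replicate_tables(data, replicate_mode):
        obs = frac[:, SPECIES.index("heterodimer")]
        if np.any((obs > 0.1) & (obs < 0.9)):
            informative = True

        def sse(log_kd: float) -> float:
            pred = f_tot / (10.0**log_kd + f_tot)
            return float(np.sum((obs - pred) ** 2))

        x = _minimise_log_kd(sse)
        kds.append(10.0**x)
        sses += sse(x)
        n_obs += obs.size
    if not informative:
        warnings.warn(
            "no observation with fraction bound in (0.1, 0.9); the KD is poorly "
            "constrained by these concentrations",
            FitWarning,
            stacklevel=2,
        )
    return _summarise(np.array(kds), float(np.sqrt(sses / n_obs)), "peptide_hill1")


def bootstrap_uncertainty(
    data: TitrationDataset,
    fitter: Callable[[TitrationDataset], KdEstimate],
    n_boot: int = 200,
    seed: int = 0,
) -> KdEstimate:
    """Bootstrap SD by resampling replicates (with replacement) per point.

    ``fitter`` is any of the fit functions taking only the dataset (bind
    extra arguments with ``functools.partial``).  Deterministic for a
    fixed seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    reps = data.replicates
    base = fitter(data)
    boot_kds = np.empty(n_boot)
    groups = {
        (f, h): sub
        for (f, h), sub in data.df.groupby(["f_total", "h_total"], sort=True)
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitWarning)
        for b in range(n_boot):
            parts = []
            for key, sub in groups.items():
                chosen = rng.choice(reps, size=len(reps), replace=True)
                for new_rep, old_rep in enumerate(chosen, start=1):
                    block = sub[sub["replicate"] == old_rep].copy()
                    block["replicate"] = new_rep
                    parts.append(block)
            resampled = TitrationDataset(
                pd.concat(parts, ignore_index=True),
                signal_model=data.signal_model,
                label=data.label,
            )
            boot_kds[b] = fitter(resampled).kd
    return KdEstimate(
        base.kd,
        float(np.std(boot_kds, ddof=1)),
        base.n_replicates,
        base.residual_rms,
        base.method + "+bootstrap",
    )

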