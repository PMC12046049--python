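"""Statistical calibration studies run on synthetic ground truth.

These are the package's self-checks: Monte-Carlo parameter recovery for
the KD fitters and type-I-error calibration for the HDX significance
test.  Both the test suite and the reproduction script drive them, so
the study conditions live here in one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import FitWarning, KdEstimate, fit_heterodimer_kd, fit_homodimer_kd
from .hdx import ttest_significance
from .synthetic import TitrationSpec, gen_titration

__all__ = ["RecoveryResult", "kd_recovery_study", "hdx_type1_study"]


@dataclass
class RecoveryResult:
    """Per-run recovered KDs against one truth value."""

    kd_truth: float
    mode: str
    kds: np.ndarray  # fitted mean KD per run
    sds: np.ndarray  # replicate SD per run

    @property
    def relative_errors(self) -> np.ndarray:
        return np.abs(self.kds - self.kd_truth) / self.kd_truth

    @property
    def median_relative_error(self) -> float:
        return float(np.median(self.relative_errors))

    def truth_within(self, n_sd: float = 3.0) -> np.ndarray:
        """Per run: does mean +/- n_sd*SD cover the truth?"""
        return np.abs(self.kds - self.kd_truth) <= n_sd * self.sds


def kd_recovery_study(
    kd_truth: float,
    mode: str,
    n_runs: int = 100,
    seed: int = 0,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    kd_homo_fixed: float | None = None,
) -> RecoveryResult:
    """Fit ``n_runs`` independently-seeded synthetic titrations.

    ``mode`` is "homo" or "hetero"; heterodimer runs hold the homodimer
    KD fixed at its true value (``kd_homo_fixed``).
    """
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    kds = np.empty(n_runs)
    sds = np.empty(n_runs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitWarning)
        for i, s in enumerate(run_seeds):
            if mode == "homo":
                spec = TitrationSpec(
                    kd_homo=kd_truth,
                    noise_sd=noise_sd,
                    n_replicates=n_replicates,
                    seed=int(s),
                )
                data, _ = gen_titration(spec)
                est = fit_homodimer_kd(data)
            elif mode == "hetero":
                if kd_homo_fixed is None:
                    raise ValueError("hetero mode requires kd_homo_fixed")
                spec = TitrationSpec(
                    kd_homo=kd_homo_fixed,
                    kd_hetero=kd_truth,
                    noise_sd=noise_sd,
                    n_replicates=n_replicates,
                    seed=int(s),
                )
                data, _ = gen_titration(spec)
                est = fit_heterodimer_kd(
                    data,
                    KdEstimate(kd_homo_fixed, 0.0, 1, 0.0, "fixed_truth"),
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            kds[i] = est.kd
            sds[i] = est.sd
    return RecoveryResult(kd_truth, mode, kds, sds)


def hdx_type1_study(
    n_trials: int = 10_000,
    n_replicates: int = 3,
    sigma: float = 0.05,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the default t-test under a simulated null.

    Both states draw from the same Gaussian; returns the fraction of
    trials declared significant at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sigma, (n_trials, n_replicates))
    b = rng.normal(0.0, sigma, (n_trials, n_replicates))
    delta = a.mean(axis=1) - b.mean(axis=1)
    _p, sig = ttest_significance(
        delta,
        a.std(axis=1, ddof=1),
        b.std(axis=1, ddof=1),
        np.full(n_trials, n_replicates),
        np.full(n_trials, n_replicates),
        alpha=alpha,
    )
    return float(np.mean(sig))
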