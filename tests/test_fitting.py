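"""KD fitting: round trips, noise robustness, uncertainty reporting."""

import warnings

import numpy as np
import pytest

from dimeq.errors import ValidationError
from dimeq.fitting import (
    FitWarning,
    KdEstimate,
    bootstrap_uncertainty,
    fit_heterodimer_kd,
    fit_homodimer_kd,
    fit_peptide_kd,
)
from dimeq.synthetic import TitrationSpec, gen_titration
from dimeq.titration import SPECIES, TitrationDataset, make_dataset


def peptide_dataset(kd, ligands, n_rep=1, noise=0.0, seed=0):
    """Fraction-bound observations encoded as the heterodimer species."""
    rng = np.random.default_rng(seed)
    ligands = np.asarray(ligands, dtype=float)
    fracs = np.zeros((n_rep, ligands.size, len(SPECIES)))
    for r in range(n_rep):
        bound = ligands / (kd + ligands) + rng.normal(0, noise, ligands.size)
        bound = np.clip(bound, 0.0, 1.0)
        fracs[r, :, SPECIES.index("heterodimer")] = bound
        fracs[r, :, SPECIES.index("monomer")] = 1.0 - bound
    return make_dataset(ligands, np.zeros_like(ligands), fracs)


class TestHomodimerFit:
    def test_noise_free_round_trip(self):
        kd = 75.9e-9
        data, _ = gen_titration(TitrationSpec(kd_homo=kd, noise_sd=0.0, n_replicates=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitWarning)
            est = fit_homodimer_kd(data)
        assert est.kd == pytest.approx(kd, rel=1e-6)

    def test_noisy_recovery_within_3sd(self):
        kd = 75.9e-9
        hits = 0
        for seed in range(20):
            data, _ = gen_titration(TitrationSpec(kd_homo=kd, noise_sd=0.02, seed=seed))
            est = fit_homodimer_kd(data)
            hits += abs(est.kd - kd) <= 3 * est.sd
        assert hits >= 18

    def test_single_replicate_reports_sd_zero_with_warning(self):
        data, _ = gen_titration(
            TitrationSpec(kd_homo=1e-8, noise_sd=0.01, n_replicates=1, seed=1)
        )
        with pytest.warns(FitWarning, match="single-replicate"):
            est = fit_homodimer_kd(data)
        assert est.sd == 0.0
        assert est.n_replicates == 1

    def test_no_curvature_flags_boundary(self):
        # concentrations far below KD: essentially all monomer
        kd = 1e-4
        data, _ = gen_titration(
            TitrationSpec(
                kd_homo=kd,
                f_total_series=tuple(np.geomspace(1e-12, 1e-11, 4)),
                noise_sd=0.0,
                n_replicates=1,
            )
        )
        with pytest.warns(FitWarning, match="boundary"):
            fit_homodimer_kd(data)

    def test_requires_h_free_points(self):
        data, _ = gen_titration(
            TitrationSpec(kd_homo=1e-8, kd_hetero=1e-9, noise_sd=0.0, n_replicates=1)
        )
        with pytest.raises(ValidationError):
            fit_homodimer_kd(data)

    def test_unit_invariance(self, tmp_path):
        kd = 5e-8
        data, _ = gen_titration(TitrationSpec(kd_homo=kd, noise_sd=0.01, seed=3))
        # write in molar, re-read pretending the numbers are nM-scaled
        path_m = tmp_path / "m.csv"
        data.to_csv(path_m)
        df_nm = data.df.copy()
        df_nm[["f_total", "h_total"]] *= 1e9
        path_nm = tmp_path / "nm.csv"
        df_nm.to_csv(path_nm, index=False)
        est_m = fit_homodimer_kd(TitrationDataset.from_csv(path_m, unit="M"))
        est_nm = fit_homodimer_kd(TitrationDataset.from_csv(path_nm, unit="nM"))
        assert est_m.kd == pytest.approx(est_nm.kd, rel=1e-9)


class TestHeterodimerFit:
    def test_noise_free_round_trip_at_reported_values(self):
        kd_homo, kd_het = 75.9e-9, 3.9e-9
        data, _ = gen_titration(
            TitrationSpec(
                kd_homo=kd_homo,
                kd_hetero=kd_het,
                h_total=5e-6,
                f_total_series=tuple(np.geomspace(5e-7, 5e-5, 8)),
                noise_sd=0.0,
                n_replicates=1,
            )
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitWarning)
            est = fit_heterodimer_kd(data, KdEstimate(kd_homo, 0.0, 1, 0.0, "fixed"))
        assert est.kd == pytest.approx(kd_het, rel=1e-6)

    def test_weak_heterodimer_recovered(self):
        kd_homo, kd_het = 1e-9, 1e-7  # heterodimer much weaker than homodimer
        data, _ = gen_titration(
            TitrationSpec(kd_homo=kd_homo, kd_hetero=kd_het, noise_sd=0.02, seed=11)
        )
        est = fit_heterodimer_kd(data, KdEstimate(kd_homo, 0.0, 1, 0.0, "fixed"))
        assert abs(est.kd - kd_het) <= max(3 * est.sd, 0.25 * kd_het)

    def test_point_order_invariance(self):
        data, _ = gen_titration(
            TitrationSpec(kd_homo=75.9e-9, kd_hetero=3.9e-9, noise_sd=0.01, seed=2)
        )
        kd_homo = KdEstimate(75.9e-9, 0.0, 1, 0.0, "fixed")
        est1 = fit_heterodimer_kd(data, kd_homo)
        shuffled = TitrationDataset(
            data.df.sample(frac=1.0, random_state=0).reset_index(drop=True),
            signal_model=data.signal_model,
        )
        est2 = fit_heterodimer_kd(shuffled, kd_homo)
        assert est1.kd == pytest.approx(est2.kd, rel=1e-12)

    def test_kd_homo_uncertainty_inflates_sd(self):
        data, _ = gen_titration(
            TitrationSpec(kd_homo=75.9e-9, kd_hetero=3.9e-9, noise_sd=0.01, seed=4)
        )
        tight = fit_heterodimer_kd(data, KdEstimate(75.9e-9, 0.0, 1, 0.0, "fixed"))
        loose = fit_heterodimer_kd(data, KdEstimate(75.9e-9, 8.4e-9, 1, 0.0, "fixed"))
        assert loose.sd >= tight.sd


class TestPeptideFit:
    def test_exact_round_trip(self):
        kd = 100e-6
        data = peptide_dataset(kd, np.geomspace(kd / 20, kd * 20, 8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitWarning)
            est = fit_peptide_kd(data)
        assert est.kd == pytest.approx(kd, rel=1e-6)

    def test_half_saturation_on_fitted_curve(self):
        from dimeq.equilibria import peptide_isotherm

        kd = 100e-6
        data = peptide_dataset(kd, np.geomspace(kd / 20, kd * 20, 8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitWarning)
            est = fit_peptide_kd(data)
        assert peptide_isotherm(est.kd, est.kd) == pytest.approx(0.5)

    def test_no_binding_hits_upper_bracket_with_warning(self):
        data = peptide_dataset(1.0, np.geomspace(1e-6, 1e-4, 6))  # fractions ~ 0
        with pytest.warns(FitWarning):
            est = fit_peptide_kd(data)
        assert est.kd > 1e-3  # pushed to the weak-binding end of the bracket


class TestBootstrap:
    def test_zero_noise_gives_zero_sd(self):
        data, _ = gen_titration(TitrationSpec(kd_homo=1e-8, noise_sd=0.0))
        est = bootstrap_uncertainty(data, fit_homodimer_kd, n_boot=100, seed=0)
        assert est.sd <= 1e-8 * est.kd

    def test_deterministic_for_fixed_seed(self):
        data, _ = gen_titration(TitrationSpec(kd_homo=1e-8, noise_sd=0.02, seed=5))
        a = bootstrap_uncertainty(data, fit_homodimer_kd, n_boot=100, seed=7)
        b = bootstrap_uncertainty(data, fit_homodimer_kd, n_boot=100, seed=7)
        assert a.kd == b.kd and a.sd == b.sd

    def test_bootstrap_sd_tracks_monte_carlo_sd(self):
        kd = 1e-8
        data, _ = gen_titration(TitrationSpec(kd_homo=kd, noise_sd=0.02, seed=9))
        boot = bootstrap_uncertainty(data, fit_homodimer_kd, n_boot=200, seed=1)
        # Monte-Carlo truth: SD of fitted means over fresh datasets
        mc = []
        for seed in range(60):
            d, _ = gen_titration(TitrationSpec(kd_homo=kd, noise_sd=0.02, seed=100 + seed))
            mc.append(fit_homodimer_kd(d).kd)
        mc_sd = np.std(mc, ddof=1)
        assert mc_sd / 2 <= boot.sd <= mc_sd * 2

    def test_small_n_boot_rejected(self):
        data, _ = gen_titration(TitrationSpec(kd_homo=1e-8, noise_sd=0.0))
        with pytest.raises(ValidationError):
            bootstrap_uncertainty(data, fit_homodimer_kd, n_boot=50)


def test_estimator_error_shrinks_with_noise():
    """Median recovery error decreases monotonically as noise vanishes."""
    kd = 75.9e-9
    medians = []
    for sigma in (0.08, 0.02, 0.005):
        errs = []
        for seed in range(25):
            data, _ = gen_titration(
                TitrationSpec(kd_homo=kd, noise_sd=sigma, seed=seed)
            )
            errs.append(abs(fit_homodimer_kd(data).kd - kd) / kd)
        medians.append(np.median(errs))
    assert medians[0] > medians[1] > medians[2]
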