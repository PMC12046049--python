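"""Ground-truth synthetic data generators.

Every analysis stage in the package has a paired generator here that
produces data with a known answer plus a machine-readable truth record,
so round-trip tests (and parameter-recovery studies) need no external
downloads.  All generators are deterministic for a fixed seed.

What is emulated, and what is not:

* titrations — replicate species signal fractions from the equilibrium
  forward model with truncated Gaussian noise in fraction space
  (renormalised to sum 1); three replicates per point as in typical
  native-MS titration practice.  Instrument effects (charge-state
  response, adducts, peak overlap) are not modelled.
* trajectories — two-chain toy systems in which scheduled donor-H /
  acceptor geometries satisfy the hydrogen-bond criteria in a controlled
  fraction of frames.  No force field or physical dynamics is claimed.
* HDX uptake — single-exponential exchange kinetics per peptide with a
  protection factor applied to designated interface peptides in the
  bound state; EX1/bimodal behaviour and back-exchange are not modelled.
* spectra — charge-state peak lists at exact protonated m/z positions
  with Gaussian charge envelopes and optional ppm jitter; no isotope
  structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import species_fractions
from .errors import ValidationError
from .hdx import UptakeTable, max_uptake
from .md_contacts import Trajectory
from .native_ms import compute_mz
from .titration import SPECIES, TitrationDataset, make_dataset

__all__ = [
    "TitrationSpec",
    "TrajectorySpec",
    "HdxSpec",
    "SpectrumSpec",
    "gen_titration",
    "gen_trajectory",
    "gen_hdx",
    "gen_spectrum",
]


# ---------------------------------------------------------------------------
# titrations


@dataclass(frozen=True)
class TitrationSpec:
    """Design of a synthetic titration.

    When ``f_total_series`` is omitted it defaults to 8 points spanning
    0.1-100x the relevant KD; for heterodimer designs ``h_total``
    defaults to 3x kd_hetero.  Concentration grids that bracket the KD
    make the constant identifiable, and keeping the capping partner near
    its KD (rather than deep in the stoichiometric-depletion regime)
    preserves sensitivity of the species fractions to the constant —
    both standard titration-design rules.
    """

    kd_homo: float
    kd_hetero: float | None = None  # None -> homodimer-only titration
    h_total: float | None = None
    f_total_series: tuple[float, ...] | None = None
    n_replicates: int = 3
    noise_sd: float = 0.02
    signal_model: str = "species_molar"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.kd_homo <= 0:
            raise ValidationError("kd_homo must be > 0")
        if self.kd_hetero is not None and self.kd_hetero <= 0:
            raise ValidationError("kd_hetero must be > 0")


def gen_titration(spec: TitrationSpec) -> tuple[TitrationDataset, dict]:
    """Simulate a replicate titration; returns (dataset, truth record)."""
    if spec.kd_hetero is None:
        kd_hetero = math.inf
        h_total = 0.0
        anchor = spec.kd_homo
    else:
        kd_hetero = spec.kd_hetero
        h_total = 3.0 * kd_hetero if spec.h_total is None else spec.h_total
        anchor = kd_hetero
    if spec.f_total_series is None:
        series = np.geomspace(0.1 * anchor, 100.0 * anchor, 8)
    else:
        series = np.asarray(spec.f_total_series, dtype=float)
    h = np.full_like(series, h_total)
    clean = species_fractions(spec.kd_homo, kd_hetero, series, h, spec.signal_model)

    rng = np.random.default_rng(spec.seed)
    # only species present in the experiment show peaks: noise applies to them
    present = clean.max(axis=0) > 0.0
    reps = np.empty((spec.n_replicates, series.size, len(SPECIES)))
    for r in range(spec.n_replicates):
        noisy = clean.copy()
        noisy[:, present] += rng.normal(
            0.0, spec.noise_sd, (series.size, int(present.sum()))
        )
        noisy = np.clip(noisy, 0.0, None)  # truncate below zero
        totals = noisy.sum(axis=1, keepdims=True)
        # degenerate all-zero rows fall back to the clean fractions
        bad = totals[:, 0] <= 0
        noisy[bad] = clean[bad]
        totals[bad] = 1.0
        reps[r] = noisy / totals
    data = make_dataset(
        series, h, reps, spec.signal_model, label=f"synthetic(seed={spec.seed})"
    )
    truth = dict(
        kd_homo=spec.kd_homo,
        kd_hetero=spec.kd_hetero,
        h_total=h_total,
        f_total_series=series.tolist(),
        noise_sd=spec.noise_sd,
        n_replicates=spec.n_replicates,
        signal_model=spec.signal_model,
        seed=spec.seed,
    )
    return data, truth


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class TrajectorySpec:
    """Toy two-chain trajectory with scheduled H-bond occupancies.

    ``pairs`` maps (residue on chain A, residue on chain B) to a target
    occupancy percentage.  Each pair is an isolated N-H donor (chain A)
    facing an O acceptor (chain B) on a 20 A grid; in "bonded" frames the
    geometry is d(H,A) = 2.0 A at a 175 deg D-H-A angle, in "broken"
    frames the acceptor retreats to 5 A.  The number of bonded frames is
    floor(target / 100 * n_frames), recorded in the truth table.
    """

    pairs: tuple[tuple[int, int, float], ...] = ((1, 101, 100.0),)
    n_frames: int = 20
    spacing: float = 20.0
    rotate: bool = False
    jitter_sd: float = 0.0  # Gaussian coordinate jitter (A) for non-bond atoms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        for ra, rb, occ in self.pairs:
            if not (0.0 <= occ <= 100.0):
                raise ValidationError(
                    f"target occupancy must be in [0, 100], got {occ} for ({ra},{rb})"
                )


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, pd.DataFrame]:
    """Build the toy trajectory; returns (trajectory, truth table)."""
    rng = np.random.default_rng(spec.seed)
    # atom roster: per pair, chain A {N, H, CA} and chain B {O, CA}
    chain_ids, res_ids, res_names, atom_names, elements = [], [], [], [], []
    for ra, rb, _occ in spec.pairs:
        for chain, res, atoms in (
            ("A", ra, [("N", "N"), ("H", "H"), ("CA", "C")]),
            ("B", rb, [("O", "O"), ("CA", "C")]),
        ):
            for name, elem in atoms:
                chain_ids.append(chain)
                res_ids.append(res)
                res_names.append("GLY")
                atom_names.append(name)
                elements.append(elem)
    n_atoms = len(chain_ids)

    bonded_frames = [
        int(math.floor(occ / 100.0 * spec.n_frames)) for _ra, _rb, occ in spec.pairs
    ]
    coords = np.empty((spec.n_frames, n_atoms, 3))
    u = np.array([1.0, 0.0, 0.0])
    ang = math.radians(180.0 - 175.0)  # acceptor direction, 175 deg D-H-A angle
    a_dir = np.array([math.cos(ang), math.sin(ang), 0.0])
    for fi in range(spec.n_frames):
        atom = 0
        for pi, (_ra, _rb, _occ) in enumerate(spec.pairs):
            base = np.array([spec.spacing * pi, 0.0, 0.0])
            n_pos = base
            h_pos = base + 1.0 * u
            ca_a = base - np.array([1.45, 0.0, 0.0])
            if fi < bonded_frames[pi]:
                o_pos = h_pos + 2.0 * a_dir
            else:
                o_pos = h_pos + 5.0 * u
            ca_b = o_pos + np.array([1.23, 0.8, 0.0])
            for pos in (n_pos, h_pos, ca_a, o_pos, ca_b):
                jit = (
                    rng.normal(0.0, spec.jitter_sd, 3)
                    if spec.jitter_sd > 0
                    else 0.0
                )
                coords[fi, atom] = pos + jit
                atom += 1
        if spec.rotate:
            rot = _rotation_matrix(rng)
            shift = rng.normal(0.0, 10.0, 3)
            coords[fi] = coords[fi] @ rot.T + shift

    traj = Trajectory(
        coords,
        np.array(chain_ids),
        np.array(res_ids),
        np.array(res_names),
        np.array(atom_names),
        np.array(elements),
    )
    truth = pd.DataFrame(
        dict(
            res_a=[p[0] for p in spec.pairs],
            res_b=[p[1] for p in spec.pairs],
            target_pct=[p[2] for p in spec.pairs],
            bonded_frames=bonded_frames,
            realized_pct=[100.0 * b / spec.n_frames for b in bonded_frames],
        )
    )
    return traj, truth


# ---------------------------------------------------------------------------
# HDX


#: default pepsin-like peptide map over an ACD-sized span (residues 78-162)
DEFAULT_PEPTIDES: tuple[tuple[int, int], ...] = (
    (78, 88),
    (86, 95),
    (93, 100),
    (101, 109),
    (108, 117),
    (118, 127),
    (125, 135),
    (133, 142),
    (140, 150),
    (148, 162),
)


@dataclass(frozen=True)
class HdxSpec:
    """Design of a synthetic two-state HDX-MS experiment.

    Uptake follows u(t) = u_max (1 - exp(-k0 t / P)) per peptide, with
    P = 1 in the free state and P = ``protection_factor`` on peptides
    fully contained in ``protected_range`` in the bound state.  Intrinsic
    rates k0 are drawn log-uniformly per peptide so the 500 s timepoint
    sits mid-exchange; replicate noise is Gaussian in Da, clipped to
    [0, u_max].
    """

    peptides: tuple[tuple[int, int], ...] = DEFAULT_PEPTIDES
    protected_range: tuple[int, int] = (101, 117)
    protection_factor: float = 10.0
    timepoints: tuple[float, ...] = (30.0, 60.0, 500.0, 1000.0, 5000.0)
    n_replicates: int = 3
    noise_sd: float = 0.05  # Da
    k0_range: tuple[float, float] = (1e-3, 1e-2)  # s^-1
    first_residue: int = 78
    last_residue: int = 162
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protection_factor < 1:
            raise ValidationError("protection_factor must be >= 1")
        if self.k0_range[0] <= 0 or self.k0_range[1] < self.k0_range[0]:
            raise ValidationError("k0_range must be positive and ordered")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for start, end in self.peptides:
            if not (self.first_residue <= start <= end <= self.last_residue):
                raise ValidationError(f"peptide {start}-{end} outside protein span")


def gen_hdx(spec: HdxSpec) -> tuple[UptakeTable, dict]:
    """Simulate two-state uptake; returns (table, truth record)."""
    rng = np.random.default_rng(spec.seed)
    n_res = spec.last_residue - spec.first_residue + 1
    # proline-free random sequence keeps every backbone amide exchange-competent
    alphabet = np.array(list("ACDEFGHIKLMNQRSTVWY"))
    protein = "".join(rng.choice(alphabet, n_res))

    lo, hi = spec.protected_range
    protected = [
        (start, end) for start, end in spec.peptides if lo <= start and end <= hi
    ]
    k0s = {
        pep: float(
            np.exp(
                rng.uniform(math.log(spec.k0_range[0]), math.log(spec.k0_range[1]))
            )
        )
        for pep in spec.peptides
    }

    rows = []
    for start, end in spec.peptides:
        seq = protein[start - spec.first_residue : end - spec.first_residue + 1]
        umax = max_uptake(seq)
        k0 = k0s[(start, end)]
        for state in ("free", "bound"):
            pf = (
                spec.protection_factor
                if state == "bound" and (start, end) in protected
                else 1.0
            )
            for t in spec.timepoints:
                mean = umax * (1.0 - math.exp(-k0 * t / pf))
                for rep in range(1, spec.n_replicates + 1):
                    u = mean + rng.normal(0.0, spec.noise_sd)
                    rows.append(
                        dict(
                            sequence=seq,
                            start=start,
                            end=end,
                            state=state,
                            timepoint_s=t,
                            replicate=rep,
                            uptake_Da=float(np.clip(u, 0.0, umax)),
                        )
                    )
    table = UptakeTable(pd.DataFrame(rows))
    truth = dict(
        protein=protein,
        first_residue=spec.first_residue,
        protected_peptides=protected,
        protected_residues=list(range(lo, hi + 1)),
        protection_factor=spec.protection_factor,
        k0=k0s,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class SpectrumSpec:
    """Synthetic native-MS peak list for a set of species.

    Intensities follow fraction x Gaussian charge envelope; peak m/z
    positions are exact protonated values plus optional ppm jitter.
    """

    species: tuple[tuple[str, float], ...] = (("monomer", 11000.0),)
    fractions: tuple[float, ...] = (1.0,)
    z_range: tuple[int, int] = (8, 15)
    envelope_sd: float = 1.5  # charge units
    jitter_ppm: float = 0.0
    intensity_scale: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) != len(self.fractions):
            raise ValidationError("species and fractions length mismatch")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1 (within 1e-9)")
        for _name, mass in self.species:
            if mass <= 0:
                raise ValidationError("species masses must be > 0")
        if self.jitter_ppm < 0:
            raise ValidationError("jitter_ppm must be >= 0")


def gen_spectrum(spec: SpectrumSpec) -> tuple[list[tuple[float, float]], dict]:
    """Generate the (mz, intensity) peak list; returns (peaks, truth)."""
    rng = np.random.default_rng(spec.seed)
    z_lo, z_hi = spec.z_range
    zs = np.arange(z_lo, z_hi + 1)
    z_centre = (z_lo + z_hi) / 2.0
    envelope = np.exp(-((zs - z_centre) ** 2) / (2.0 * spec.envelope_sd**2))
    envelope /= envelope.sum()
    peaks: list[tuple[float, float]] = []
    for (name, mass), frac in zip(spec.species, spec.fractions):
        for z, env in zip(zs, envelope):
            mz = compute_mz(mass, int(z))
            if spec.jitter_ppm > 0:
                mz *= 1.0 + rng.normal(0.0, spec.jitter_ppm * 1e-6)
            peaks.append((mz, frac * env * spec.intensity_scale))
    peaks.sort()
    truth = dict(
        species=dict((name, mass) for name, mass in spec.species),
        fractions=dict(
            (name, frac) for (name, _m), frac in zip(spec.species, spec.fractions)
        ),
        z_range=spec.z_range,
        jitter_ppm=spec.jitter_ppm,
        seed=spec.seed,
    )
    return peaks, truth
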