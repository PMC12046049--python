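# Methods

## The competitive dimerisation model

Two equilibria share the free FLNC d24 monomer F:

    F2 <-> 2 F        K_homo = [F]^2 / [F2]
    FH <-> F + H      K_het  = [F][H] / [FH]

HSPB7 is treated as strictly monomeric (its ACD lacks the inter-monomer
salt bridges that stabilise the canonical sHSP dimer interface), so the
only H-containing complex is the heterodimer, and higher-order oligomers
are out of scope.  Substituting [H] = H_tot / (1 + [F]/K_het) into the
FLNC mass balance gives a single strictly increasing function of [F] on
[0, F_tot], so the equilibrium state is unique.  We solve it with
Brent's method on the bracket [0, F_tot].  The absolute tolerance is set
to 1e-18 x F_tot — far below any concentration of interest — so the
machine-precision relative tolerance governs; this matters in
tight-capping regimes (K_het of order 1e-15 M), where the root lies many
orders of magnitude below F_tot and the mass-balance slope is steep.

The homodimer-only case has the closed form
[F] = K (sqrt(1 + 8 F_tot/K) - 1)/4, implemented in the cancellation-free
arrangement sqrt(1+r) - 1 = r/(sqrt(1+r) + 1) and with the dimer taken
from the equilibrium expression [F]^2/K rather than the mass-balance
remainder (F_tot - [F])/2, which loses all significant digits when
F_tot << K.  This closed form is the analytic oracle against which the
numerical solver is checked (agreement <= 1e-10 relative over random
systems spanning K in 1e-10–1e-3 M).

## Signal model for native-MS titrations

The data are species signal fractions at each total concentration.  The
default assumes measured intensity proportional to the molar
concentration of each species (equal per-species response); a
per-subunit weighting (dimers counted twice) is selectable for
sensitivity analysis.  Neither assumption is obviously correct for
electrospray response of complexes of different mass; offering both and
defaulting to the simpler one makes the assumption explicit and
switchable rather than implicit.

## KD fitting

All fits are 1-D least squares over log10 K_D on the bracket
[1e-12, 1e-2] M with a bounded scalar minimiser; the residual surfaces
of these forward models are unimodal in log K_D, so no multi-start is
used.  By default each technical replicate is fitted independently and
the estimate is reported as mean +/- SD over replicates, matching how
triplicate titrations are conventionally summarised; a weighted fit to
replicate means is available.  The homodimer fit uses the dimer signal
fraction; the heterodimer fit holds K_homo fixed (from an independent
homodimer titration) and minimises residuals over all four species
fractions simultaneously — co-fitting both constants from one titration
invites a ridge degeneracy that the two-step protocol avoids.  The
K_homo uncertainty is propagated by refitting at K_homo +/- SD and
adding half the spread in quadrature.  Datasets whose dimer fraction
never leaves [0, 0.05] or [0.95, 1] carry no curvature; the fit then
warns and the returned value is a boundary estimate, not a measurement.
A replicate-resampling bootstrap is available as an alternative error
model.

Peptide-binding isotherms use the 1:1 Hill model with slope and maximum
fixed at 1, i.e. fraction bound = L/(K_D + L) with total ligand as free
ligand; an exact single-site depletion mode is provided because receptor
depletion is plausible at tens-of-µM concentrations.

## Free energies

dG = RT ln(K_D / 1 M) at T = 298.15 K (R = 8.31446 J/mol/K), so lower
dG means a more stable complex.  No temperature is attached to the
reported constants; 298.15 K reproduces the reported energy differences
(5.4, 9.9, 3.2 kJ/mol to one decimal) and is the configurable default.
ddG is computed as RT (ln K_a - ln K_b) — the difference of logarithms,
not the logarithm of the ratio — so antisymmetry under argument swap is
exact in floating point.  Errors propagate to first order with no
covariance between constants.  One reported value does not recompute
from the rounded constants: the heterodimer stabilisation by Y2683E is
1.4 kJ/mol from K_D 3.9 vs 2.2 nM, versus a reported 1.5 kJ/mol,
presumably because unrounded fit values were used; we flag rather than
force it.

## MD interface analysis

Hydrogen bonds use the geometric criteria D–H <= 1.2 Å, H···A <= 3.0 Å,
angle(D,H,A) >= 150°, all cutoffs inclusive so boundary behaviour is
deterministic.  Donors are N/O/S atoms with a hydrogen within the D–H
cutoff; acceptors are N/O (S behind a flag).  Chemistry is inferred from
elements and hydrogen proximity rather than a residue template library,
so the same code runs on toy systems and force-field output.  Occupancy
of a residue pair is the percentage of frames with at least one
inter-chain bond between them (capped at 100%); a sum-of-bonds variant
that can exceed 100% is available behind a flag, since the counting rule
for pairs that form several simultaneous bonds is a genuine convention
choice.  Frames are weighted equally with no time-decorrelation
correction.  Difference maps are occupancy(b) - occupancy(a) over the
union of pairs, missing pairs counting as zero.

Contact profiles report, per residue of the query chain, the minimum and
mean over frames of the per-frame shortest heavy-atom distance to the
partner chain, with a linear saturation rescaling (default 3–15 Å) for
structure colouring.  Superposition RMSD uses the Kabsch algorithm
(SVD with reflection correction); the test suite cross-checks it against
an independent quaternion-based implementation.  Note that optimal
superposition absorbs 1/n of a single-atom displacement into the
translation: displacing one atom of a rigid n-atom selection by d gives
RMSD d sqrt(n-1)/n (0.0995 Å for d = 1 Å, n = 100), not d/sqrt(n).

Trajectories are multi-model PDB; insertion codes are rejected, residues
are keyed by (chain, residue number), and inputs are assumed imaged and
whole (no periodicity handling).

## Differential HDX

Uptake differences are computed per peptide and labelling time as
mean(state A) - mean(state B); with A = bound and B = free, negative
values denote protection in the complex.  The theoretical maximum uptake
of a peptide is (length - 1) minus prolines at positions 2..length
(the N-terminal amide back-exchanges too fast; prolines have no amide
hydrogen), and differences are also reported as fractions of this
maximum.  Significance is a per-peptide two-tailed t-test at
alpha = 0.01.  The default pools the replicate variances of the two
states (Student's t, df = n_a + n_b - 2): with triplicates this test has
exact type-I control under the equal-variance null, which HDX replicates
measured on one instrument satisfy to good approximation, and its
calibration is verified by simulation (empirical rate within the exact
binomial 99% interval around 0.01 at 10 000 null trials).  Welch's
unequal-variance test is noticeably conservative at n = 3 (empirical
type-I near 0.005) and is provided as an option rather than the default,
as is a pooled-SD global threshold.  No multiple-testing correction is
applied by default (per-peptide alpha), with Bonferroni behind a flag.
No back-exchange correction is made: all comparisons are state-vs-state
under identical labelling.

Projection onto residues assigns each residue the aggregate of the
values of all significant peptides covering it (most-negative,
mean, or smallest-magnitude rule); uncovered residues are reported as
no-data, not zero, because digestion defines the spatial resolution.
For deciding which peptides constitute the protected set we additionally
require significant protection at two or more of the five labelling
times; this multi-timepoint confirmation suppresses isolated
single-timepoint false positives at the per-test alpha while leaving
genuine protection (which persists across the time course) untouched.

## Synthetic data: what it emulates and what it does not

The generators produce data with known ground truth so that every
pipeline stage can be validated end-to-end.

*Titrations* follow the equilibrium forward model with Gaussian noise
applied in fraction space to the species present in the experiment, then
renormalised; defaults are 8 concentration points spanning 0.1–100x the
true K_D, 3 replicates, sigma = 0.02.  For heterodimer designs the
fixed HSPB7 total defaults to 3x K_het: grids that bracket the constant,
with the capping partner near its K_D rather than deep in the
stoichiometric-depletion regime, are what make the constant
identifiable — the standard titration-design rules.  Not modelled:
charge-state-dependent response, adduction, peak overlap, or
concentration-measurement error.

*Trajectories* are two-chain toy systems: isolated N–H donors facing O
acceptors on a 20 Å grid, with the acceptor at 2.0 Å/175° in "bonded"
frames and 5 Å in "broken" frames, scheduled so each pair hits its
target occupancy exactly (bonded frames = floor(target x N/100), the
rounding recorded in the truth table).  No force field or dynamics is
claimed; these trajectories validate bookkeeping and geometry, not
physics, so occupancy tests passing says nothing about sampling
convergence on real simulations.

*HDX tables* use single-exponential exchange,
u(t) = u_max (1 - exp(-k0 t / P)), with per-peptide intrinsic rates
drawn log-uniformly from 1e-3–1e-2 s^-1 (placing the 500 s point
mid-exchange), P = 1 in the free state and P = 10 on interface peptides
in the bound state, and Gaussian replicate noise of 0.05 Da clipped to
[0, u_max].  EX1/bimodal exchange, back-exchange and inter-residue rate
heterogeneity within a peptide are not modelled.

*Spectra* place charge-state peaks at exact protonated m/z values with a
Gaussian charge envelope and optional ppm jitter; no isotope structure.

All generators are bit-deterministic for a fixed seed and emit a
machine-readable truth record consumed by the tests.

## Problem sizes

The validation studies use 100 independently seeded titrations per
constant for parameter recovery, 1000 random systems for solver/oracle
agreement, 20-frame toy trajectories for occupancy exactness, 200-atom
5-frame random trajectories for the contact-profile brute-force
cross-check, and 10 000 null trials for significance-test calibration.
These sizes give stable Monte-Carlo summaries (binomial/median standard
errors well below the margins being checked) while keeping the full
validation run in the tens of seconds.

## Known limitations

Equilibrium only (no kinetics); no trimers or higher oligomers; no
HSPB7 self-association; native-MS quantification assumes the chosen
response model; H-bond analysis requires explicit hydrogens and exactly
the geometric criteria above (no energy-based definition); HDX analysis
is peptide-level (no residue-level exchange modelling) and assumes
Gaussian replicate noise.  Reported experimental constants appear only
as worked-example inputs; nothing in the package claims to reproduce
instrument-level raw data.
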