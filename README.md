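# dimeq

Quantitative analysis of competitive protein dimerisation, built around
the FLNC d24 / HSPB7 system: the C-terminal immunoglobulin-like domain
24 of filamin C (FLNC d24) homo-dimerises, and the α-crystallin domain
(ACD) of the cardiac small heat-shock protein HSPB7 competes for the
same interface, capping the FLNC monomer as a tight heterodimer.
Phosphomimic substitutions at the interface (T2677D, Y2683E) shift the
coupled equilibria in opposite directions.  `dimeq` provides the
machinery to quantify that picture from experiment-shaped data:

* **Coupled equilibria** — for F₂ ⇌ 2F (K_D,homo = [F]²/[F₂]) and
  FH ⇌ F + H (K_D,het = [F][H]/[FH]) with HSPB7 monomeric, the species
  concentrations follow from a single monotone mass balance in [F],

      g([F]) = [F] + 2[F]²/K_homo + [F]·H_tot/(K_het + [F]) − F_tot = 0,

  solved by bracketed root-finding (with the analytic quadratic solution
  as the homodimer-only special case).
* **KD fitting** — least squares on native-MS titration signal
  fractions, per technical replicate (mean ± SD), in log K_D space;
  1:1 peptide-binding isotherms with slope and B_max fixed at 1;
  optional bootstrap uncertainties.
* **Free-energy ledger** — ΔG = RT ln(K_D/c°) at 298.15 K with
  first-order error propagation; all pairwise ΔΔGs between variants and
  the homo-vs-hetero stability gap per variant.
* **Native-MS bookkeeping** — charge-state m/z arithmetic, ppm-tolerance
  peak assignment (ambiguous peaks flagged and excluded), species signal
  fractions.
* **MD interface analysis** — hydrogen-bond detection on multi-model PDB
  trajectories with inclusive geometric cutoffs (D–H ≤ 1.2 Å,
  H···A ≤ 3.0 Å, ∠DHA ≥ 150°), residue-pair occupancy maps and signed
  difference maps, per-residue shortest heavy-atom contact profiles,
  and Kabsch superposition RMSD.
* **Differential HDX-MS** — Woods-plot uptake differences between bound
  and free states, peptide-level two-tailed t-test at α = 0.01,
  normalisation by the theoretical maximum uptake, and projection of
  significant protection onto residues.
* **Synthetic ground truth** — seeded generators for titrations,
  toy trajectories with scheduled H-bond occupancies, two-state exchange
  kinetics, and charge-state spectra, so every stage is testable
  end-to-end with known answers.

## Worked example

Build the free-energy ledger from the reported dissociation constants
(homodimer: WT 75.9 ± 8.4 nM, T2677D 8.5 ± 1.0 nM, Y2683E
4047 ± 557 nM; heterodimer with HSPB7 ACD: WT 3.9 ± 0.9 nM, T2677D
14.1 ± 0.5 nM, Y2683E 2.2 ± 0.6 nM):

```sh
dimeq reproduce-fig4c --kds builtin_printed_table --out ledger.csv
```

which logs

```
ddG(homodimer: WT vs T2677D) = 5.4 +/- 0.4 kJ/mol
ddG(homodimer: WT vs Y2683E) = -9.9 +/- 0.4 kJ/mol
ddG(heterodimer: WT vs T2677D) = -3.2 +/- 0.6 kJ/mol
ddG(heterodimer: WT vs Y2683E) = 1.4 +/- 0.9 kJ/mol
```

Read: the T2677D phosphomimic stabilises the homodimer by 5.4 kJ/mol
and destabilises the heterodimer by 3.2 kJ/mol (so it favours
homo-dimerisation), while Y2683E weakens the homodimer by 9.9 kJ/mol
and slightly tightens the heterodimer; for wild-type FLNC d24 the
heterodimer is the more stable species by 7.4 kJ/mol (the `gaps` table
in `ledger.csv`).  Or from Python:

```python
from dimeq import ddg_between
ddg, err = ddg_between(75.9e-9, 8.5e-9)   # (5.43, 0.40) kJ/mol
```

The same pipeline can re-fit every constant from synthetic titrations
generated at those KDs before building the ledger:

```sh
dimeq reproduce-fig4c --kds synthetic --seed 1 --out ledger_refit.csv
```

Other subcommands (`simulate-titration`, `fit-kd`, `energy-ledger`,
`hbond-map`, `contact-profile`, `rmsd`, `hdx-diff`, `synth`) expose the
remaining stages on plain CSV/JSON files; each run writes a
`<out>.run.json` sidecar echoing its resolved configuration.

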