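"""Free-energy ledger: KDs -> dissociation free energies and differences.

The standard binding free energy of a complex relative to its free
monomers at the 1 M standard state is

    dG = R T ln(KD / c0),        c0 = 1 M,

so tighter binding (smaller KD) gives a more negative dG ("lower = more
stable").  Differences between variants or species follow as
ddG = R T ln(KD_a / KD_b), with first-order error propagation
ddG_err = R T sqrt((sd_a/KD_a)^2 + (sd_b/KD_b)^2) assuming independent KD
estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .fitting import KdEstimate

__all__ = [
    "R_KJ",
    "DEFAULT_TEMPERATURE",
    "EnergyLedger",
    "kd_to_dg",
    "ddg_between",
    "build_ledger",
]

#: gas constant, kJ mol^-1 K^-1
R_KJ = 8.31446e-3

#: default temperature (K) for KD -> dG conversion
DEFAULT_TEMPERATURE = 298.15


def kd_to_dg(
    kd: float, sd: float = 0.0, temperature: float = DEFAULT_TEMPERATURE
) -> tuple[float, float]:
    """Dissociation free energy (kJ/mol) and its first-order error."""
    if kd <= 0:
        raise ValidationError("kd must be > 0")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    rt = R_KJ * temperature
    return rt * math.log(kd), rt * (sd / kd)


def ddg_between(
    kd_a: float,
    kd_b: float,
    sd_a: float = 0.0,
    sd_b: float = 0.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[float, float]:
    """Free-energy difference dG(a) - dG(b) in kJ/mol with propagated error.

    Positive when complex a is less stable (larger KD) than complex b.
    Antisymmetric under swapping the arguments.
    """
    if kd_a <= 0 or kd_b <= 0:
        raise ValidationError("both kds must be > 0")
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("sds must be >= 0")
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")
    rt = R_KJ * temperature
    # difference of logs (not log of ratio) keeps ddg(a,b) == -ddg(b,a) exact
    ddg = rt * (math.log(kd_a) - math.log(kd_b))
    err = rt * math.hypot(sd_a / kd_a, sd_b / kd_b)
    return ddg, err


@dataclass
class EnergyLedger:
    """Per-(variant, species) dG table plus derived pairwise differences."""

    entries: pd.DataFrame
    pairwise: pd.DataFrame
    gaps: pd.DataFrame
    temperature: float = DEFAULT_TEMPERATURE

    def to_csv(self, path) -> None:
        """Serialise the three tables into one long CSV with a `table` tag."""
        frames = []
        for name, df in (
            ("entries", self.entries),
            ("pairwise", self.pairwise),
            ("gaps", self.gaps),
        ):
            d = df.copy()
            d.insert(0, "table", name)
            frames.append(d)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def build_ledger(
    estimates,
    temperature: float = DEFAULT_TEMPERATURE,
) -> EnergyLedger:
    """Assemble the free-energy ledger from labelled KD estimates.

    ``estimates`` maps (variant, species) -> KdEstimate, e.g.
    ("WT", "homodimer") — either a dict or an iterable of
    ((variant, species), estimate) pairs.  The ledger holds per-entry
    dGs, all pairwise within-species ddGs, and the homo-vs-hetero gap
    per variant.
    """
    if not isinstance(estimates, dict):
        pairs = list(estimates)
        keys = [k for k, _v in pairs]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (variant, species) keys")
        estimates = dict(pairs)
    if not estimates:
        raise ValidationError("at least one estimate is required")

    rows = []
    for (variant, species), est in estimates.items():
        dg, err = kd_to_dg(est.kd, est.sd, temperature)
        rows.append(
            dict(
                variant=variant,
                species=species,
                kd_M=est.kd,
                sd_M=est.sd,
                dg_kJmol=dg,
                dg_err_kJmol=err,
            )
        )
    entries = pd.DataFrame(rows)

    pair_rows = []
    for species in entries["species"].unique():
        sub = [(k, v) for k, v in estimates.items() if k[1] == species]
        for i, ((va, _), ea) in enumerate(sub):
            for (vb, _), eb in sub[i + 1 :]:
                ddg, err = ddg_between(ea.kd, eb.kd, ea.sd, eb.sd, temperature)
                pair_rows.append(
                    dict(
                        species=species,
                        variant_a=va,
                        variant_b=vb,
                        ddg_kJmol=ddg,
                        ddg_err_kJmol=err,
                    )
                )
    pairwise = pd.DataFrame(
        pair_rows,
        columns=["species", "variant_a", "variant_b", "ddg_kJmol", "ddg_err_kJmol"],
    )

    gap_rows = []
    for variant in entries["variant"].unique():
        homo = estimates.get((variant, "homodimer"))
        hetero = estimates.get((variant, "heterodimer"))
        if homo is not None and hetero is not None:
            # gap = dG(homo) - dG(hetero); positive when the heterodimer is tighter
            gap, err = ddg_between(homo.kd, hetero.kd, homo.sd, hetero.sd, temperature)
            gap_rows.append(
                dict(variant=variant, gap_kJmol=gap, gap_err_kJmol=err)
            )
    gaps = pd.DataFrame(gap_rows, columns=["variant", "gap_kJmol", "gap_err_kJmol"])

    return EnergyLedger(entries, pairwise, gaps, temperature)
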