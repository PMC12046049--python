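"""Titration dataset container.

A titration is a series of total-concentration points, each observed as
per-species signal fractions in one or more technical replicates.  The
container wraps a tidy :class:`pandas.DataFrame` with columns

    f_total   total FLNC-subunit concentration (M)
    h_total   total HSPB7-subunit concentration (M)
    replicate integer replicate index (1-based)
    species   one of :data:`SPECIES`
    fraction  signal fraction in [0, 1]

Fractions within one (point, replicate) must sum to 1.  This is the common
substrate of the forward simulator and all fitting routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .units import to_molar

#: canonical species labels of the competitive dimerisation system
SPECIES = ("monomer", "homodimer", "heterodimer", "hsp_monomer")

#: accepted signal models (see :mod:`dimeq.equilibria`)
SIGNAL_MODELS = ("species_molar", "per_subunit")

_COLUMNS = ["f_total", "h_total", "replicate", "species", "fraction"]


@dataclass
class TitrationDataset:
    """Replicate signal fractions across a concentration series."""

    df: pd.DataFrame
    signal_model: str = "species_molar"
    label: str = ""

    def __post_init__(self) -> None:
        if self.signal_model not in SIGNAL_MODELS:
            raise ValidationError(
                f"unknown signal model {self.signal_model!r}; expected one of {SIGNAL_MODELS}"
            )
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"titration table missing columns {missing}")
        bad = set(self.df["species"]) - set(SPECIES)
        if bad:
            raise ValidationError(f"unknown species labels {sorted(bad)}")
        self.validate_fraction_sums()

    # -- structure ---------------------------------------------------------

    @property
    def points(self) -> pd.DataFrame:
        """Unique (f_total, h_total) concentration points, ascending in f_total."""
        return (
            self.df[["f_total", "h_total"]]
            .drop_duplicates()
            .sort_values("f_total")
            .reset_index(drop=True)
        )

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def replicates(self) -> list[int]:
        return sorted(self.df["replicate"].unique())

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def validate_fraction_sums(self, tol: float = 1e-6) -> None:
        """Check that fractions sum to 1 within each (point, replicate)."""
        sums = self.df.groupby(["f_total", "h_total", "replicate"])["fraction"].sum()
        if not np.allclose(sums.to_numpy(), 1.0, atol=tol, rtol=0.0):
            worst = float(np.abs(sums.to_numpy() - 1.0).max())
            raise ValidationError(
                f"signal fractions must sum to 1 per (point, replicate); worst deviation {worst:.3g}"
            )

    def replicate_subset(self, replicate: int) -> pd.DataFrame:
        return self.df[self.df["replicate"] == replicate]

    def fraction_matrix(self, replicate: int) -> pd.DataFrame:
        """Points x species matrix of fractions for one replicate."""
        sub = self.replicate_subset(replicate)
        mat = sub.pivot_table(
            index=["f_total", "h_total"], columns="species", values="fraction"
        )
        for sp in SPECIES:
            if sp not in mat.columns:
                mat[sp] = 0.0
        return mat[list(SPECIES)].sort_index(level="f_total")

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        path,
        unit: str = "M",
        signal_model: str = "species_molar",
        label: str = "",
    ) -> "TitrationDataset":
        """Read a tidy titration CSV; concentrations tagged with ``unit``."""
        df = pd.read_csv(path)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        df = df.copy()
        for col in ("f_total", "h_total"):
            df[col] = [to_molar(v, unit) for v in df[col]]
        return cls(df[_COLUMNS], signal_model=signal_model, label=label)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def make_dataset(
    f_totals: np.ndarray,
    h_totals: np.ndarray,
    fractions: np.ndarray,
    signal_model: str = "species_molar",
    label: str = "",
) -> TitrationDataset:
    """Assemble a dataset from a (replicates, points, species) fraction array."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 3 or fractions.shape[2] != len(SPECIES):
        raise ValidationError(
            "fractions must have shape (n_replicates, n_points, n_species)"
        )
    n_rep, n_pts, _ = fractions.shape
    if len(f_totals) != n_pts or len(h_totals) != n_pts:
        raise ValidationError("concentration series length mismatch")
    rows = []
    for r in range(n_rep):
        for p in range(n_pts):
            for s, sp in enumerate(SPECIES):
                rows.append(
                    (float(f_totals[p]), float(h_totals[p]), r + 1, sp, fractions[r, p, s])
                )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return TitrationDataset(df, signal_model=signal_model, label=label)
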