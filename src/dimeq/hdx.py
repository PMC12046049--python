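"""Differential hydrogen-deuterium exchange (HDX-MS) analysis.

Compares per-peptide deuterium uptake between two states (e.g. a protein
alone versus in complex), following the standard Woods-plot workflow:

* delta = mean uptake in state A minus state B per (peptide, timepoint);
  with A = free and B = bound, negative deltas denote protection in the
  complex,
* peptide-level two-tailed t-test at alpha = 0.01 for significance.
  The default pools the replicate variances of the two states (exact
  type-I control under the equal-variance null that HDX replicates of
  one instrument satisfy); Welch's unequal-variance form and a
  pooled-SD global threshold are available as alternatives,
* normalisation by the theoretical maximum uptake of each peptide
  (backbone amides excluding the N-terminal residue and prolines),
* projection of significant peptide-level differences onto residues,
  acknowledging that digestion limits spatial resolution.

No back-exchange correction is applied: all comparisons are relative,
state versus state, under identical labelling conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "UptakeTable",
    "max_uptake",
    "uptake_difference",
    "ttest_significance",
    "welch_significance",
    "global_threshold_significance",
    "project_to_residues",
    "consistently_protected_peptides",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")

_REQUIRED = [
    "sequence",
    "start",
    "end",
    "state",
    "timepoint_s",
    "replicate",
    "uptake_Da",
]


def max_uptake(sequence: str) -> int:
    """Theoretical maximum deuterium uptake of a peptide (Da equivalents).

    Backbone amides only: the N-terminal residue back-exchanges too fast
    to retain label and prolines have no amide hydrogen, so the maximum
    is (length - 1) minus the number of prolines at positions 2..length.
    """
    if len(sequence) < 2:
        raise ValidationError("peptide sequence must have length >= 2")
    bad = set(sequence.upper()) - _AA
    if bad:
        raise ValidationError(f"invalid amino-acid letters {sorted(bad)}")
    seq = sequence.upper()
    return (len(seq) - 1) - seq[1:].count("P")


@dataclass
class UptakeTable:
    """Long-format peptide x state x timepoint x replicate uptake table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"uptake table missing columns {missing}")
        if (self.df["uptake_Da"] < 0).any():
            raise ValidationError("uptake must be >= 0")
        for seq, start, end in (
            self.df[["sequence", "start", "end"]].drop_duplicates().itertuples(index=False)
        ):
            if end - start + 1 != len(seq):
                raise ValidationError(
                    f"peptide {seq} spans {start}-{end} but has length {len(seq)}"
                )

    @property
    def states(self) -> list[str]:
        return sorted(self.df["state"].unique())

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.df["timepoint_s"].unique())

    @classmethod
    def from_csv(cls, path) -> "UptakeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _degenerate_pvalues(delta: np.ndarray, se2: np.ndarray) -> np.ndarray:
    """p-values for zero-variance cells: significant iff the delta is nonzero."""
    p = np.ones_like(delta)
    degenerate = se2 == 0
    if np.any(degenerate & (delta != 0)):
        warnings.warn(
            "zero replicate variance with nonzero difference: significant by "
            "convention",
            UserWarning,
            stacklevel=3,
        )
    p[degenerate & (delta != 0)] = 0.0
    return p


def ttest_significance(
    delta: np.ndarray,
    sd_a: np.ndarray,
    sd_b: np.ndarray,
    n_a: np.ndarray,
    n_b: np.ndarray,
    alpha: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-tailed pooled-variance Student t-test.

    Exact type-I control when the two states share a common replicate
    variance (df = n_a + n_b - 2).  Returns (p_values, significant).
    """
    delta = np.asarray(delta, dtype=float)
    sd_a = np.asarray(sd_a, dtype=float)
    sd_b = np.asarray(sd_b, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_a < 2) or np.any(n_b < 2):
        raise ValidationError("t-test requires n >= 2 replicates per state")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se2 = pooled_var * (1.0 / n_a + 1.0 / n_b)
    p = _degenerate_pvalues(delta, se2)
    ok = se2 > 0
    if np.any(ok):
        t = delta[ok] / np.sqrt(se2[ok])
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df[ok])
    return p, p < alpha


def welch_significance(
    delta: np.ndarray,
    sd_a: np.ndarray,
    sd_b: np.ndarray,
    n_a: np.ndarray,
    n_b: np.ndarray,
    alpha: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-tailed Welch t-test on mean differences.

    Returns (p_values, significant).  Zero variance in both states with a
    nonzero delta is significant by convention (p = 0).
    """
    delta = np.asarray(delta, dtype=float)
    sd_a = np.asarray(sd_a, dtype=float)
    sd_b = np.asarray(sd_b, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_a < 2) or np.any(n_b < 2):
        raise ValidationError("Welch test requires n >= 2 replicates per state")
    va = sd_a**2 / n_a
    vb = sd_b**2 / n_b
    se2 = va + vb
    p = _degenerate_pvalues(delta, se2)
    ok = se2 > 0
    if np.any(ok):
        t = delta[ok] / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            va[ok] ** 2 / (n_a[ok] - 1) + vb[ok] ** 2 / (n_b[ok] - 1)
        )
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return p, p < alpha


def global_threshold_significance(
    delta: np.ndarray,
    sd_a: np.ndarray,
    sd_b: np.ndarray,
    n_a: np.ndarray,
    n_b: np.ndarray,
    alpha: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Global pooled-SD threshold: |delta| beyond a z-quantile of the
    pooled replicate standard error, shared across all peptides."""
    delta = np.asarray(delta, dtype=float)
    se = np.sqrt(
        np.mean(np.asarray(sd_a, dtype=float) ** 2 / np.asarray(n_a, dtype=float))
        + np.mean(np.asarray(sd_b, dtype=float) ** 2 / np.asarray(n_b, dtype=float))
    )
    crit = stats.norm.ppf(1 - alpha / 2.0) * se
    sig = np.abs(delta) > crit
    p = np.where(sig, 0.0, 1.0)  # no per-peptide p under the global threshold
    return p, sig


def uptake_difference(
    table: UptakeTable,
    state_a: str,
    state_b: str,
    alpha: float = 0.01,
    test: str = "ttest",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-(peptide, timepoint) uptake difference mean(a) - mean(b).

    Returns a Woods-plot-ready frame with columns sequence, start, end,
    timepoint_s, delta_Da, sd_a, sd_b, n_a, n_b, ci_halfwidth_Da,
    p_value, significant, fraction_of_max.  Peptides with missing
    replicate cells in either state are excluded with a warning.
    """
    for state in (state_a, state_b):
        if state not in table.states:
            raise ValidationError(f"state {state!r} not in table (have {table.states})")
    df = table.df[table.df["state"].isin([state_a, state_b])]
    agg = (
        df.groupby(["sequence", "start", "end", "timepoint_s", "state"])["uptake_Da"]
        .agg(["mean", "std", "count"])
        .unstack("state")
    )
    complete = agg.dropna()
    dropped = len(agg) - len(complete)
    if dropped:
        warnings.warn(
            f"excluded {dropped} (peptide, timepoint) cells with missing replicates",
            UserWarning,
            stacklevel=2,
        )
    mean_a = complete[("mean", state_a)].to_numpy()
    mean_b = complete[("mean", state_b)].to_numpy()
    sd_a = complete[("std", state_a)].to_numpy()
    sd_b = complete[("std", state_b)].to_numpy()
    n_a = complete[("count", state_a)].to_numpy()
    n_b = complete[("count", state_b)].to_numpy()
    delta = mean_a - mean_b

    if test == "ttest":
        p, sig = ttest_significance(delta, sd_a, sd_b, n_a, n_b, alpha)
    elif test == "welch":
        p, sig = welch_significance(delta, sd_a, sd_b, n_a, n_b, alpha)
    elif test == "global":
        p, sig = global_threshold_significance(delta, sd_a, sd_b, n_a, n_b, alpha)
    else:
        raise ValidationError(f"unknown test {test!r}")
    if bonferroni:
        n_tests = len(delta)
        p = np.minimum(p * n_tests, 1.0)
        sig = p < alpha

    # 99%-style confidence halfwidth on the difference (Welch degrees of freedom)
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        dof = np.where(
            se > 0,
            (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1)),
            1.0,
        )
    ci = stats.t.ppf(1 - alpha / 2.0, dof) * se

    out = complete.index.to_frame(index=False)
    out["delta_Da"] = delta
    out["sd_a"] = sd_a
    out["sd_b"] = sd_b
    out["n_a"] = n_a.astype(int)
    out["n_b"] = n_b.astype(int)
    out["ci_halfwidth_Da"] = ci
    out["p_value"] = p
    out["significant"] = sig
    out["fraction_of_max"] = [
        d / max_uptake(s) for d, s in zip(delta, out["sequence"])
    ]
    return out.sort_values(["start", "end", "timepoint_s"]).reset_index(drop=True)


def consistently_protected_peptides(
    diff: pd.DataFrame, min_timepoints: int = 2
) -> pd.DataFrame:
    """Peptides significantly protected (delta < 0) at >= ``min_timepoints``.

    Requiring confirmation across the labelling time course suppresses
    isolated single-timepoint false positives at the per-test alpha.
    """
    prot = diff[diff["significant"] & (diff["delta_Da"] < 0)]
    counts = prot.groupby(["sequence", "start", "end"]).size()
    keep = counts[counts >= min_timepoints].index
    return (
        diff.set_index(["sequence", "start", "end"])
        .loc[keep]
        .reset_index()
        .drop_duplicates(subset=["sequence", "start", "end"])[
            ["sequence", "start", "end"]
        ]
        .reset_index(drop=True)
    )


def project_to_residues(
    records: pd.DataFrame,
    rule: str = "max_protection",
    timepoint: float | None = None,
    value_col: str = "fraction_of_max",
    significant_only: bool = True,
) -> pd.DataFrame:
    """Project peptide-level differences onto residues.

    Each residue receives the aggregate of ``value_col`` over all
    (significant) peptides covering it, under ``rule``:

    * ``min_abs``: the value of smallest magnitude (conservative, because
      digestion resolution can spread protection beyond true residues),
    * ``mean``: plain average,
    * ``max_protection``: the most negative value.

    Residues covered by no peptide are absent from the output (no-data,
    not zero).
    """
    df = records
    if timepoint is not None:
        df = df[df["timepoint_s"] == timepoint]
    if significant_only:
        df = df[df["significant"]]
    if df.empty:
        raise ValidationError("no (significant) records to project")
    values: dict[int, list[float]] = {}
    for row in df.itertuples(index=False):
        for res in range(int(row.start), int(row.end) + 1):
            values.setdefault(res, []).append(float(getattr(row, value_col)))
    if rule == "min_abs":
        agg = {r: min(v, key=abs) for r, v in values.items()}
    elif rule == "mean":
        agg = {r: float(np.mean(v)) for r, v in values.items()}
    elif rule == "max_protection":
        agg = {r: min(v) for r, v in values.items()}
    else:
        raise ValidationError(f"unknown projection rule {rule!r}")
    out = pd.DataFrame(
        dict(
            residue=sorted(agg),
            value=[agg[r] for r in sorted(agg)],
            n_peptides=[len(values[r]) for r in sorted(agg)],
        )
    )
    return out
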