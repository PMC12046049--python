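"""Reported dissociation constants for the FLNC d24 / HSPB7 ACD system.

These are the native-MS titration results for the wild-type FLNC d24 and
its two phosphomimic variants (T2677D mimicking pT2677, Y2683E mimicking
pY2683), for both the FLNC homodimer and the FLNC:HSPB7-ACD heterodimer.
They serve as a worked-example input for the free-energy ledger (the
``reproduce-fig4c`` pipeline) and as ground-truth values for synthetic
parameter-recovery studies.
"""

from __future__ import annotations

from .fitting import KdEstimate

__all__ = ["REPORTED_KDS", "reported_estimates"]

#: (variant, species) -> (KD in nM, SD in nM), from native-MS titrations
REPORTED_KDS: dict[tuple[str, str], tuple[float, float]] = {
    ("WT", "homodimer"): (75.9, 8.4),
    ("T2677D", "homodimer"): (8.5, 1.0),
    ("Y2683E", "homodimer"): (4047.0, 557.0),
    ("WT", "heterodimer"): (3.9, 0.9),
    ("T2677D", "heterodimer"): (14.1, 0.5),
    ("Y2683E", "heterodimer"): (2.2, 0.6),
}


def reported_estimates() -> dict[tuple[str, str], KdEstimate]:
    """The reported KD table as :class:`KdEstimate` objects (molar)."""
    return {
        key: KdEstimate(
            kd=kd * 1e-9,
            sd=sd * 1e-9,
            n_replicates=3,
            residual_rms=float("nan"),
            method="reported",
        )
        for key, (kd, sd) in REPORTED_KDS.items()
    }
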