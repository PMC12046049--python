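"""Shared fixtures: small deterministic synthetic inputs."""

import numpy as np
import pytest

from dimeq.md_contacts import Trajectory


@pytest.fixture
def printed_kds_nM():
    """Reported KD table (nM) used as a worked-example input."""
    return {
        ("WT", "homodimer"): (75.9, 8.4),
        ("T2677D", "homodimer"): (8.5, 1.0),
        ("Y2683E", "homodimer"): (4047.0, 557.0),
        ("WT", "heterodimer"): (3.9, 0.9),
        ("T2677D", "heterodimer"): (14.1, 0.5),
        ("Y2683E", "heterodimer"): (2.2, 0.6),
    }


def make_two_chain_frame(acceptor_offset, angle_deg=180.0):
    """One-frame trajectory: chain A N-H donor facing a chain B O acceptor.

    The acceptor sits ``acceptor_offset`` A from the hydrogen, at the
    given D-H-A angle.  Includes a heavy CA scaffold atom per chain.
    """
    ang = np.radians(180.0 - angle_deg)
    h = np.array([1.0, 0.0, 0.0])
    a = h + acceptor_offset * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords = np.array(
        [
            [0.0, 0.0, 0.0],  # N (donor)
            h,  # H
            [-1.45, 0.0, 0.0],  # CA chain A
            a,  # O (acceptor)
            a + [1.23, 0.8, 0.0],  # CA chain B
        ]
    )[None, :, :]
    return Trajectory(
        coords,
        chain_ids=np.array(["A", "A", "A", "B", "B"]),
        res_ids=np.array([1, 1, 1, 50, 50]),
        res_names=np.array(["GLY"] * 5),
        atom_names=np.array(["N", "H", "CA", "O", "CA"]),
        elements=np.array(["N", "H", "C", "O", "C"]),
    )


@pytest.fixture
def ideal_hbond_frame():
    return make_two_chain_frame(2.0, 180.0)
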