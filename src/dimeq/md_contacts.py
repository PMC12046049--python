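"""Trajectory-level interface analysis of two-chain complexes.

Operates on multi-model PDB trajectories with explicit hydrogens and
provides:

* geometric hydrogen-bond detection with inclusive cutoffs
  (donor-H <= 1.2 A, H-acceptor <= 3.0 A, D-H-A angle >= 150 deg),
* residue-pair H-bond occupancy maps (percentage of frames) and signed
  difference maps between two simulations,
* per-residue shortest heavy-atom contact-distance profiles (minimum and
  mean over frames) with a linear "surface saturation" rescaling for
  structure colouring,
* least-squares (Kabsch) superposition RMSD against a reference frame.

Donor/acceptor chemistry is inferred from elements and bonded-hydrogen
proximity (an H within the donor-H cutoff of an N/O/S atom marks that
atom as a donor), not from a residue template library, so the same code
runs on toy systems and on real force-field output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError, ValidationError

__all__ = [
    "Trajectory",
    "HBondCriteria",
    "OccupancyMap",
    "ContactProfile",
    "detect_hbonds_frame",
    "hbond_occupancy",
    "occupancy_difference",
    "contact_profile",
    "surface_saturation_values",
    "trajectory_rmsd",
    "kabsch_superpose",
]

_DONOR_ELEMENTS = ("N", "O", "S")
_ACCEPTOR_ELEMENTS = ("N", "O")


@dataclass
class Trajectory:
    """Frames x atoms with chain/residue/element identity, coordinates in A."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValidationError("at least one frame is required")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        n_atoms = self.coords.shape[1]
        for name in ("chain_ids", "res_ids", "res_names", "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise ValidationError(f"{name} must have one entry per atom")
            setattr(self, name, arr)
        self.elements = np.char.upper(self.elements.astype(str))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.chain_ids.tolist()))

    def chain_mask(self, chain: str) -> np.ndarray:
        mask = self.chain_ids == chain
        if not mask.any():
            raise ValidationError(f"chain {chain!r} not present (have {self.chains})")
        return mask

    # -- I/O (multi-model PDB via biotite) ---------------------------------

    @classmethod
    def from_pdb(cls, path) -> "Trajectory":
        """Read a multi-model PDB (MODEL/ENDMDL) trajectory."""
        import biotite.structure.io.pdb as pdb

        try:
            pdb_file = pdb.PDBFile.read(str(path))
        except OSError as exc:
            raise InputError(f"cannot read trajectory {path}: {exc}") from exc
        stack = pdb_file.get_structure(model=None)
        if stack.stack_depth() < 1:
            raise ValidationError(f"{path}: no models found")
        if np.any(stack.ins_code != ""):
            raise ValidationError("insertion codes are unsupported")
        return cls(
            coords=np.asarray(stack.coord, dtype=float),
            chain_ids=np.asarray(stack.chain_id),
            res_ids=np.asarray(stack.res_id),
            res_names=np.asarray(stack.res_name),
            atom_names=np.asarray(stack.atom_name),
            elements=np.asarray(stack.element),
        )

    def to_pdb(self, path) -> None:
        """Write the trajectory as a multi-model PDB."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        stack = struc.AtomArrayStack(self.n_frames, self.n_atoms)
        stack.coord = self.coords
        stack.chain_id = self.chain_ids.astype("U4")
        stack.res_id = self.res_ids.astype(int)
        stack.res_name = self.res_names.astype("U5")
        stack.atom_name = self.atom_names.astype("U6")
        stack.element = self.elements.astype("U2")
        pdb_file = pdb.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition; all cutoffs inclusive."""

    max_dh: float = 1.2  # donor-hydrogen distance, A
    max_ha: float = 3.0  # hydrogen-acceptor distance, A
    min_angle_dha: float = 150.0  # donor-hydrogen-acceptor angle, deg

    def __post_init__(self) -> None:
        if self.max_dh <= 0 or self.max_ha <= 0:
            raise ValidationError("distance cutoffs must be positive")
        if not (0.0 < self.min_angle_dha <= 180.0):
            raise ValidationError("min_angle_dha must be in (0, 180]")


@dataclass
class OccupancyMap:
    """(chain_i, resnum_i, chain_j, resnum_j) -> occupancy percentage."""

    entries: dict[tuple[str, int, str, int], float]
    n_frames: int = 0
    signed: bool = False  # True for difference maps, where negatives are meaningful

    def __post_init__(self) -> None:
        if not self.signed:
            for key, occ in self.entries.items():
                if not (0.0 <= occ):
                    raise ValidationError(
                        f"occupancy must be >= 0, got {occ} for {key}"
                    )

    def to_dataframe(self):
        import pandas as pd

        rows = [
            dict(chain_i=ci, resnum_i=ri, chain_j=cj, resnum_j=rj, occupancy_pct=occ)
            for (ci, ri, cj, rj), occ in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["chain_i", "resnum_i", "chain_j", "resnum_j", "occupancy_pct"]
        )


def _find_donor_hydrogens(
    traj: Trajectory, frame: np.ndarray, chain_mask: np.ndarray, max_dh: float
) -> list[tuple[int, int]]:
    """(donor_atom_index, hydrogen_index) pairs within one chain."""
    h_idx = np.flatnonzero(chain_mask & (traj.elements == "H"))
    d_idx = np.flatnonzero(chain_mask & np.isin(traj.elements, _DONOR_ELEMENTS))
    if h_idx.size == 0 or d_idx.size == 0:
        return []
    dists = cdist(frame[h_idx], frame[d_idx])
    pairs = []
    for hi, row in zip(h_idx, dists):
        close = np.flatnonzero(row <= max_dh)
        for c in close:
            pairs.append((int(d_idx[c]), int(hi)))
    return pairs


def detect_hbonds_frame(
    traj: Trajectory,
    frame_index: int,
    criteria: HBondCriteria = HBondCriteria(),
    donor_chain: str | None = None,
    acceptor_chain: str | None = None,
    include_s_acceptors: bool = False,
) -> list[tuple[int, int, int]]:
    """Inter-chain H-bond triplets (donor, hydrogen, acceptor) in one frame.

    Both donation directions are scanned when ``donor_chain`` /
    ``acceptor_chain`` are left unset (requires exactly two chains).
    Returned indices are atom indices into the trajectory roster.
    """
    if not (traj.elements == "H").any():
        raise ValidationError(
            "hydrogen-bond detection requires explicit hydrogens, but the atom "
            "roster contains none"
        )
    frame = traj.coords[frame_index]
    if donor_chain is None or acceptor_chain is None:
        chains = traj.chains
        if len(chains) != 2:
            raise ValidationError(
                "specify donor_chain/acceptor_chain explicitly for !=2 chains"
            )
        directions = [(chains[0], chains[1]), (chains[1], chains[0])]
    else:
        directions = [(donor_chain, acceptor_chain)]

    acceptor_elements = (
        _ACCEPTOR_ELEMENTS + ("S",) if include_s_acceptors else _ACCEPTOR_ELEMENTS
    )
    bonds: list[tuple[int, int, int]] = []
    for dc, ac in directions:
        d_mask = traj.chain_mask(dc)
        a_mask = traj.chain_mask(ac) & np.isin(traj.elements, acceptor_elements)
        a_idx = np.flatnonzero(a_mask)
        if a_idx.size == 0:
            continue
        for d_i, h_i in _find_donor_hydrogens(traj, frame, d_mask, criteria.max_dh):
            ha = np.linalg.norm(frame[a_idx] - frame[h_i], axis=1)
            within = a_idx[ha <= criteria.max_ha]
            for a_i in within:
                v1 = frame[d_i] - frame[h_i]
                v2 = frame[a_i] - frame[h_i]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                cosang = float(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))
                angle = math.degrees(math.acos(cosang))
                if angle >= criteria.min_angle_dha:
                    bonds.append((int(d_i), int(h_i), int(a_i)))
    return bonds


def hbond_occupancy(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    chain_a: str | None = None,
    chain_b: str | None = None,
    count_multiple: bool = False,
    include_s_acceptors: bool = False,
) -> OccupancyMap:
    """Residue-pair H-bond occupancy (%) over all frames.

    A residue pair counts once per frame regardless of how many
    simultaneous bonds it forms (occupancy capped at 100); with
    ``count_multiple=True`` every bond is summed and occupancies may
    exceed 100.
    """
    if chain_a is None or chain_b is None:
        chains = traj.chains
        if len(chains) != 2:
            raise ValidationError("specify chain_a/chain_b explicitly for !=2 chains")
        chain_a, chain_b = chains
    counts: dict[tuple[str, int, str, int], float] = {}
    for fi in range(traj.n_frames):
        bonds = detect_hbonds_frame(
            traj, fi, criteria, include_s_acceptors=include_s_acceptors
        )
        frame_pairs: dict[tuple[str, int, str, int], int] = {}
        for d_i, _h_i, a_i in bonds:
            # orient the key as (residue on chain_a, residue on chain_b)
            if traj.chain_ids[d_i] == chain_a:
                key = (
                    chain_a,
                    int(traj.res_ids[d_i]),
                    chain_b,
                    int(traj.res_ids[a_i]),
                )
            else:
                key = (
                    chain_a,
                    int(traj.res_ids[a_i]),
                    chain_b,
                    int(traj.res_ids[d_i]),
                )
            frame_pairs[key] = frame_pairs.get(key, 0) + 1
        for key, n in frame_pairs.items():
            inc = n if count_multiple else 1
            counts[key] = counts.get(key, 0) + inc
    entries = {k: 100.0 * v / traj.n_frames for k, v in counts.items()}
    return OccupancyMap(entries, n_frames=traj.n_frames)


def occupancy_difference(map_a: OccupancyMap, map_b: OccupancyMap) -> OccupancyMap:
    """Signed per-pair difference (b - a) over the union of keys.

    Missing pairs count as 0% occupancy.  Antisymmetric under swapping
    the arguments.
    """
    keys = set(map_a.entries) | set(map_b.entries)
    diff = {
        k: map_b.entries.get(k, 0.0) - map_a.entries.get(k, 0.0) for k in keys
    }
    return OccupancyMap(diff, max(map_a.n_frames, map_b.n_frames), signed=True)


@dataclass
class ContactProfile:
    """Per-residue shortest heavy-atom distances to the partner chain."""

    res_ids: np.ndarray
    min_shortest: np.ndarray  # minimum over frames, A
    avg_shortest: np.ndarray  # mean over frames, A
    query_chain: str = ""
    partner_chain: str = ""

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            dict(
                res_id=self.res_ids,
                min_shortest_A=self.min_shortest,
                avg_shortest_A=self.avg_shortest,
            )
        )


def contact_profile(
    traj: Trajectory, query_chain: str, partner_chain: str
) -> ContactProfile:
    """Min/mean over frames of the per-frame shortest heavy-atom distance
    from each residue of ``query_chain`` to any heavy atom of
    ``partner_chain``."""
    heavy = traj.elements != "H"
    q_mask = traj.chain_mask(query_chain) & heavy
    p_mask = traj.chain_mask(partner_chain) & heavy
    if not q_mask.any() or not p_mask.any():
        raise ValidationError("both chains need at least one heavy atom")
    q_idx = np.flatnonzero(q_mask)
    p_idx = np.flatnonzero(p_mask)
    q_res = traj.res_ids[q_idx]
    res_ids = np.unique(q_res)
    per_frame = np.empty((traj.n_frames, res_ids.size))
    for fi in range(traj.n_frames):
        d = cdist(traj.coords[fi, q_idx], traj.coords[fi, p_idx])
        atom_min = d.min(axis=1)
        for ri, res in enumerate(res_ids):
            per_frame[fi, ri] = atom_min[q_res == res].min()
    return ContactProfile(
        res_ids=res_ids,
        min_shortest=per_frame.min(axis=0),
        avg_shortest=per_frame.mean(axis=0),
        query_chain=query_chain,
        partner_chain=partner_chain,
    )


def surface_saturation_values(
    profile: ContactProfile, d_min: float = 3.0, d_max: float = 15.0
) -> np.ndarray:
    """Linear [0, 1] rescaling of avg_shortest for surface colouring.

    1 at/below ``d_min`` (tight contact), 0 at/beyond ``d_max``; the
    saturation decreases linearly with the average shortest distance.
    """
    if profile.res_ids.size == 0:
        raise ValidationError("empty contact profile")
    if d_max <= d_min:
        raise ValidationError("d_max must exceed d_min")
    return np.clip((d_max - profile.avg_shortest) / (d_max - d_min), 0.0, 1.0)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the superposed coordinates and the RMSD after optimal
    rotation + translation (Kabsch algorithm, reflection-corrected).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    p = mobile - mc
    q = reference - rc
    h = p.T @ q
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = p @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rmsd


def trajectory_rmsd(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: np.ndarray | Callable[[Trajectory], np.ndarray] | None = None,
) -> np.ndarray:
    """Optimal-superposition RMSD (A) of each frame against a reference frame.

    ``selection`` is a boolean atom mask, a predicate building one, or
    None for all atoms.
    """
    if selection is None:
        mask = np.ones(traj.n_atoms, dtype=bool)
    elif callable(selection):
        mask = np.asarray(selection(traj), dtype=bool)
    else:
        mask = np.asarray(selection, dtype=bool)
    if mask.shape != (traj.n_atoms,):
        raise ValidationError("selection mask must have one entry per atom")
    if not mask.any():
        raise ValidationError("empty atom selection")
    ref = traj.coords[reference_frame, mask]
    out = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        _, out[fi] = kabsch_superpose(traj.coords[fi, mask], ref)
    return out


def apply_rigid(
    traj: Trajectory, rotation: np.ndarray, translation: Sequence[float]
) -> Trajectory:
    """Apply one rigid-body motion to every frame (geometry-preserving)."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    coords = traj.coords @ rotation.T + translation
    return Trajectory(
        coords,
        traj.chain_ids,
        traj.res_ids,
        traj.res_names,
        traj.atom_names,
        traj.elements,
    )
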