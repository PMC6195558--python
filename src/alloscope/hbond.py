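"""Hydrogen-bond and salt-bridge detection, inter-domain counts and
windowed per-pair occupancy tables.

Geometric criterion (GROMACS hbond defaults): donor-acceptor distance
<= 3.5 Angstrom and hydrogen-donor-acceptor angle <= 30 degrees. Donors
are N/O atoms carrying a hydrogen of the same residue within 1.25 Angstrom
in the analyzed frame (the topology carries no bond table); acceptors are
N/O atoms. A heavy-atom fallback (distance criterion only) serves
Calpha-resolution systems without explicit hydrogens.

Occupancy tables follow the windowed-average convention: the analyzed
interval is tiled by consecutive non-overlapping windows (last window may
be shorter); a residue pair counts as bonded in a frame when at least one
hydrogen bond between its residues exists; cells strictly below 50%
occupancy are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, TopologyFormatError
from .geometry import TimeSeries
from .structure import ResidueSelection, Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "OccupancyTable",
    "detect_hbonds_frame",
    "interdomain_hbond_count",
    "pair_occupancy",
    "detect_salt_bridges",
    "POSITIVE_SIDECHAIN_ATOMS",
    "NEGATIVE_SIDECHAIN_ATOMS",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``angle_cutoff_deg`` bounds the hydrogen-donor-acceptor deviation angle
    (angle at the donor between the D->H and D->A directions).
    """

    distance_cutoff: float = 3.5
    angle_cutoff_deg: float = 30.0
    donor_elements: tuple[str, ...] = ("N", "O")
    acceptor_elements: tuple[str, ...] = ("N", "O")
    dh_bond_max: float = 1.25
    heavy_only: bool = False

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.dh_bond_max <= 0:
            raise InputError("distance cutoffs must be positive")
        if not (0 < self.angle_cutoff_deg < 90):
            raise InputError("angle cutoff must lie in (0, 90) degrees")


@dataclass(frozen=True)
class HBondRecord:
    """One detected hydrogen bond in one frame."""

    donor_residue: tuple[str, int, str]  # chain, resnum, resname
    acceptor_residue: tuple[str, int, str]
    donor_atom: str
    acceptor_atom: str
    frame: int


def _element_mask(topology: Topology, elements: tuple[str, ...]) -> np.ndarray:
    wanted = {e.upper() for e in elements}
    return np.array([str(e).upper() in wanted for e in topology.elements])


def _residue_tuple(topology: Topology, atom_index: int) -> tuple[str, int, str]:
    ri = topology.atom_resindex[atom_index]
    return (
        str(topology.res_chains[ri]),
        int(topology.res_numbers[ri]),
        str(topology.res_names[ri]),
    )


def _detect_directed(
    coords: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria,
    donor_side: np.ndarray,
    acceptor_side: np.ndarray,
    frame: int,
) -> list[HBondRecord]:
    """Donor in ``donor_side`` -> acceptor in ``acceptor_side`` bonds."""
    elem = topology.elements
    donors_all = donor_side[_element_mask(topology, criteria.donor_elements)[donor_side]]
    acceptors = acceptor_side[
        _element_mask(topology, criteria.acceptor_elements)[acceptor_side]
    ]
    if len(donors_all) == 0 or len(acceptors) == 0:
        return []

    records: list[HBondRecord] = []
    acc_tree = cKDTree(coords[acceptors])

    if criteria.heavy_only:
        for d in donors_all:
            for k in acc_tree.query_ball_point(coords[d], criteria.distance_cutoff):
                a = acceptors[k]
                if topology.atom_resindex[a] == topology.atom_resindex[d]:
                    continue
                records.append(
                    HBondRecord(
                        _residue_tuple(topology, d),
                        _residue_tuple(topology, a),
                        str(topology.atom_names[d]),
                        str(topology.atom_names[a]),
                        frame,
                    )
                )
        return records

    hydrogens = donor_side[
        np.array([str(elem[i]).upper() == "H" for i in donor_side])
    ]
    if len(hydrogens) == 0:
        return []  # no donatable hydrogens on this side
    cos_cut = np.cos(np.radians(criteria.angle_cutoff_deg))
    h_by_res: dict[int, list[int]] = {}
    for h in hydrogens:
        h_by_res.setdefault(int(topology.atom_resindex[h]), []).append(int(h))

    for d in donors_all:
        res = int(topology.atom_resindex[d])
        attached = [
            h
            for h in h_by_res.get(res, [])
            if np.linalg.norm(coords[h] - coords[d]) <= criteria.dh_bond_max
        ]
        if not attached:
            continue
        for k in acc_tree.query_ball_point(coords[d], criteria.distance_cutoff):
            a = acceptors[k]
            if topology.atom_resindex[a] == res:
                continue
            da = coords[a] - coords[d]
            nda = np.linalg.norm(da)
            if nda < 1e-9:
                continue
            for h in attached:
                dh = coords[h] - coords[d]
                ndh = np.linalg.norm(dh)
                if ndh < 1e-9:
                    continue
                if np.dot(dh, da) / (ndh * nda) >= cos_cut:
                    records.append(
                        HBondRecord(
                            _residue_tuple(topology, d),
                            _residue_tuple(topology, a),
                            str(topology.atom_names[d]),
                            str(topology.atom_names[a]),
                            frame,
                        )
                    )
                    break  # one bond per donor-acceptor pair
    return records


def detect_hbonds_frame(
    coords: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    frame: int = 0,
) -> list[HBondRecord]:
    """All inter-selection hydrogen bonds of one frame (both directions)."""
    if not criteria.heavy_only:
        elem = topology.elements
        has_h = any(
            str(elem[i]).upper() == "H"
            for side in (selection_a.atom_indices, selection_b.atom_indices)
            for i in side
        )
        if not has_h:
            raise TopologyFormatError(
                "no hydrogens in either selection; request the heavy_only "
                "fallback for Calpha/heavy-atom systems"
            )
    out = _detect_directed(
        coords, topology, criteria, selection_a.atom_indices, selection_b.atom_indices, frame
    )
    out += _detect_directed(
        coords, topology, criteria, selection_b.atom_indices, selection_a.atom_indices, frame
    )
    if criteria.heavy_only:
        # distance-only criterion is direction-symmetric: deduplicate pairs
        seen: set = set()
        unique = []
        for rec in out:
            key = frozenset(
                [
                    (rec.donor_residue, rec.donor_atom),
                    (rec.acceptor_residue, rec.acceptor_atom),
                ]
            )
            if key not in seen:
                seen.add(key)
                unique.append(rec)
        out = unique
    return out


def interdomain_hbond_count(
    trajectory: Trajectory,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    criteria: HBondCriteria | None = None,
    smoothing_ns: float | None = None,
) -> TimeSeries:
    """Total number of inter-domain hydrogen bonds per frame.

    The raw (unsmoothed) series is canonical; ``smoothing_ns`` applies an
    optional centered running mean (the figure-style 5 ns average).
    """
    criteria = criteria or HBondCriteria()
    counts = np.array(
        [
            len(
                detect_hbonds_frame(
                    trajectory.coordinates[f],
                    trajectory.topology,
                    criteria,
                    selection_a,
                    selection_b,
                    f,
                )
            )
            for f in range(trajectory.n_frames)
        ],
        dtype=float,
    )
    series = TimeSeries(
        trajectory.times_ns,
        counts,
        f"H-bonds {selection_a.domain}-{selection_b.domain}",
        "count",
    )
    if smoothing_ns:
        series = series.smoothed(smoothing_ns)
    return series


@dataclass
class OccupancyTable:
    """Residue-pair occupancy fractions over consecutive time windows.

    ``occupancy[p, w]`` is the fraction of window ``w``'s frames in which
    pair ``p`` is bonded. ``formed[p, f]`` keeps the per-frame bond state
    for downstream event annotation. Cells strictly below 0.5 are flagged
    (occupancy exactly 50% is not flagged).
    """

    pair_keys: list[tuple[tuple[str, int, str], tuple[str, int, str]]]
    window_edges_ns: np.ndarray
    occupancy: np.ndarray
    frames_per_window: np.ndarray
    formed: np.ndarray
    times_ns: np.ndarray

    def __post_init__(self) -> None:
        self.window_edges_ns = np.asarray(self.window_edges_ns, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.size and (
            self.occupancy.min() < 0 or self.occupancy.max() > 1
        ):
            raise InputError("occupancy fractions must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_keys)

    @property
    def n_windows(self) -> int:
        return len(self.window_edges_ns) - 1

    @property
    def flagged(self) -> np.ndarray:
        """True where occupancy is strictly below 50%."""
        return self.occupancy < 0.5

    @staticmethod
    def pair_label(key) -> str:
        (ca, na, rna), (cb, nb, rnb) = key
        return f"{ca}:{rna}{na}-{cb}:{rnb}{nb}"

    @property
    def pair_labels(self) -> list[str]:
        return [self.pair_label(k) for k in self.pair_keys]

    def window_labels(self) -> list[str]:
        e = self.window_edges_ns
        return [f"{e[i]:g}-{e[i + 1]:g}ns" for i in range(self.n_windows)]

    def row(self, chain_a: str, num_a: int, chain_b: str, num_b: int) -> int | None:
        """Row index for a residue pair (order-insensitive); None if absent."""
        want = {(chain_a, num_a), (chain_b, num_b)}
        for i, ((ca, na, _), (cb, nb, _)) in enumerate(self.pair_keys):
            if {(ca, na), (cb, nb)} == want:
                return i
        return None

    def whole_trajectory_occupancy(self) -> np.ndarray:
        """Per-pair occupancy over the whole analyzed interval."""
        return self.formed.mean(axis=1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.occupancy, index=self.pair_labels, columns=self.window_labels()
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().rename_axis("pair").to_csv(path)

    def to_json(self, path) -> None:
        import json

        payload = {
            "window_edges_ns": self.window_edges_ns.tolist(),
            "pairs": {
                label: {
                    "occupancy": self.occupancy[i].tolist(),
                    "flagged": self.flagged[i].tolist(),
                }
                for i, label in enumerate(self.pair_labels)
            },
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1)


def _window_edges(times: np.ndarray, window_ns: float) -> np.ndarray:
    t0 = times[0]
    t_end = times[-1]
    spacing = np.median(np.diff(times)) if len(times) > 1 else window_ns
    if window_ns < spacing:
        raise InputError(
            f"window ({window_ns} ns) shorter than frame spacing ({spacing} ns)"
        )
    n_full = int(np.floor((t_end - t0) / window_ns + 1e-9))
    edges = [t0 + i * window_ns for i in range(n_full + 1)]
    if edges[-1] <= t_end:
        edges.append(t_end + spacing)  # final (possibly partial) window
    return np.asarray(edges)


def _occupancy_from_states(
    pair_keys: list,
    formed: np.ndarray,
    times: np.ndarray,
    window_ns: float,
) -> OccupancyTable:
    edges = _window_edges(times, window_ns)
    n_w = len(edges) - 1
    occupancy = np.zeros((len(pair_keys), n_w))
    frames_per_window = np.zeros(n_w, dtype=int)
    which = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, n_w - 1)
    for w in range(n_w):
        mask = which == w
        frames_per_window[w] = mask.sum()
        if frames_per_window[w]:
            occupancy[:, w] = formed[:, mask].mean(axis=1)
    return OccupancyTable(pair_keys, edges, occupancy, frames_per_window, formed, times)


def _collect_pair_states(records_per_frame: list[list[HBondRecord]], n_frames: int):
    """Per-frame bonded state for every residue pair ever bonded."""
    pair_index: dict = {}
    pair_keys: list = []
    rows: list[np.ndarray] = []
    for f, records in enumerate(records_per_frame):
        for rec in records:
            a, b = rec.donor_residue, rec.acceptor_residue
            key = (a, b) if (a[0], a[1]) <= (b[0], b[1]) else (b, a)
            if key not in pair_index:
                pair_index[key] = len(pair_keys)
                pair_keys.append(key)
                rows.append(np.zeros(n_frames, dtype=bool))
            rows[pair_index[key]][f] = True
    order = sorted(range(len(pair_keys)), key=lambda i: pair_keys[i])
    pair_keys = [pair_keys[i] for i in order]
    formed = (
        np.stack([rows[i] for i in order])
        if pair_keys
        else np.zeros((0, n_frames), dtype=bool)
    )
    return pair_keys, formed


def pair_occupancy(
    trajectory: Trajectory,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    criteria: HBondCriteria | None = None,
    window_ns: float = 50.0,
) -> OccupancyTable:
    """Windowed hydrogen-bond occupancy for every residue pair ever bonded."""
    criteria = criteria or HBondCriteria()
    records_per_frame = [
        detect_hbonds_frame(
            trajectory.coordinates[f],
            trajectory.topology,
            criteria,
            selection_a,
            selection_b,
            f,
        )
        for f in range(trajectory.n_frames)
    ]
    pair_keys, formed = _collect_pair_states(records_per_frame, trajectory.n_frames)
    return _occupancy_from_states(pair_keys, formed, trajectory.times_ns, window_ns)


#: Side-chain atoms carrying the formal positive charge, by residue name.
POSITIVE_SIDECHAIN_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "HSP": ("ND1", "NE2"),
    "HIP": ("ND1", "NE2"),
}

#: Side-chain atoms carrying the formal negative charge, by residue name.
NEGATIVE_SIDECHAIN_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


def _charged_atoms(topology: Topology, indices: np.ndarray, table: dict) -> np.ndarray:
    keep = []
    for i in indices:
        ri = topology.atom_resindex[i]
        resname = str(topology.res_names[ri]).upper()
        if resname in table and str(topology.atom_names[i]).strip() in table[resname]:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def detect_salt_bridges(
    trajectory: Trajectory,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    cutoff: float = 4.0,
    window_ns: float = 50.0,
) -> OccupancyTable:
    """Windowed salt-bridge occupancy between the two selections.

    A bridge exists in a frame when any positively charged side-chain
    nitrogen of a LYS/ARG/HIS(+) residue on one side lies within ``cutoff``
    of a carboxylate oxygen (ASP/GLU) on the other side.
    """
    topo = trajectory.topology
    n_frames = trajectory.n_frames
    sides = [
        (
            _charged_atoms(topo, selection_a.atom_indices, POSITIVE_SIDECHAIN_ATOMS),
            _charged_atoms(topo, selection_b.atom_indices, NEGATIVE_SIDECHAIN_ATOMS),
        ),
        (
            _charged_atoms(topo, selection_b.atom_indices, POSITIVE_SIDECHAIN_ATOMS),
            _charged_atoms(topo, selection_a.atom_indices, NEGATIVE_SIDECHAIN_ATOMS),
        ),
    ]
    records_per_frame: list[list[HBondRecord]] = []
    for f in range(n_frames):
        coords = trajectory.coordinates[f]
        recs: list[HBondRecord] = []
        for pos, neg in sides:
            if len(pos) == 0 or len(neg) == 0:
                continue
            tree = cKDTree(coords[neg])
            for p in pos:
                for k in tree.query_ball_point(coords[p], cutoff):
                    a = neg[k]
                    recs.append(
                        HBondRecord(
                            _residue_tuple(topo, p),
                            _residue_tuple(topo, a),
                            str(topo.atom_names[p]),
                            str(topo.atom_names[a]),
                            f,
                        )
                    )
        records_per_frame.append(recs)
    pair_keys, formed = _collect_pair_states(records_per_frame, n_frames)
    return _occupancy_from_states(pair_keys, formed, trajectory.times_ns, window_ns)
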