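"""Geometric observables: superposition, RMSD, RMSF, COM distances, the
hinge angle and solvent-accessible surface area.

All distances are in Angstrom, times in ns, angles in degrees. The
superposition uses a least-squares rigid fit (rotation + translation) per
frame; RMSD/RMSF assume the trajectory has already been superposed onto a
common reference unless a fit is requested inline.

No periodic-boundary unwrapping is performed: inputs are required to be
pre-imaged so the analyzed complex is whole in every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    InputError,
    InsufficientDataError,
    ParameterizationError,
    TopologyMismatchError,
)
from .structure import ResidueSelection, Trajectory

__all__ = [
    "TimeSeries",
    "RMSFProfile",
    "HingeAngleSeries",
    "superpose",
    "rmsd_timeseries",
    "rmsf_profile",
    "com_distance_timeseries",
    "hinge_angle_timeseries",
    "sasa_timeseries",
    "BONDI_RADII",
]


@dataclass
class TimeSeries:
    """A per-frame scalar observable."""

    times_ns: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times_ns) != len(self.values):
            raise InputError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"non-finite values in series {self.label!r}")

    def __len__(self) -> int:
        return len(self.values)

    def smoothed(self, window_ns: float) -> "TimeSeries":
        """Centered running mean over ``window_ns``."""
        if window_ns <= 0 or len(self) < 2:
            return self
        dt = np.median(np.diff(self.times_ns))
        w = max(1, int(round(window_ns / dt)))
        if w <= 1:
            return self
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.concatenate(
            [np.full(pad, self.values[0]), self.values, np.full(w - 1 - pad, self.values[-1])]
        )
        smoothed = np.convolve(padded, kernel, mode="valid")
        return TimeSeries(self.times_ns, smoothed, self.label + " (smoothed)", self.units)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ns": self.times_ns, "value": self.values, "label": self.label}
        )


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Angstrom)."""

    residue_labels: list[str]
    values: np.ndarray
    window: tuple[int, int]
    units: str = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise InputError("RMSF values must be non-negative")

    def mean(self) -> float:
        """Mean over residues (a per-region average)."""
        return float(np.mean(self.values))

    def std(self) -> float:
        """SD across residues of the per-residue values."""
        return float(np.std(self.values))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"residue": self.residue_labels, "value": self.values})


@dataclass
class HingeAngleSeries:
    """Time series of a three-selection hinge angle in degrees."""

    series: TimeSeries
    selection_labels: tuple[str, str, str] = ("apex", "armA", "armB")

    def __post_init__(self) -> None:
        vals = self.series.values
        if np.any((vals < 0) | (vals > 180)):
            raise InputError("angles must lie in [0, 180] degrees")


def _reference_coords(
    trajectory: Trajectory, reference: "int | np.ndarray"
) -> np.ndarray:
    if isinstance(reference, (int, np.integer)):
        return trajectory.coordinates[int(reference)]
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (trajectory.n_atoms, 3):
        raise TopologyMismatchError(
            f"reference frame shape {ref.shape} does not match trajectory atoms"
        )
    return ref


def superpose(
    trajectory: Trajectory,
    fit_selection: ResidueSelection,
    reference: "int | np.ndarray" = 0,
) -> Trajectory:
    """Least-squares superpose every frame onto the reference.

    The optimal rotation + translation is computed over ``fit_selection``
    and applied to all atoms of the frame. Returns a new Trajectory.
    """
    idx = fit_selection.atom_indices
    if len(idx) < 3:
        raise DegenerateGeometryError("superposition needs >= 3 fit atoms")
    ref = _reference_coords(trajectory, reference)[idx]
    ref_center = ref.mean(axis=0)
    ref_centered = ref - ref_center
    # collinearity check: rank of the centered reference fit set
    if np.linalg.matrix_rank(ref_centered, tol=1e-8) < 2:
        raise DegenerateGeometryError("fit selection is collinear/degenerate")

    out = np.empty_like(trajectory.coordinates)
    for f in range(trajectory.n_frames):
        frame = trajectory.coordinates[f]
        mobile = frame[idx]
        mob_center = mobile.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mobile - mob_center)
        out[f] = rot.apply(frame - mob_center) + ref_center
    return trajectory.with_coordinates(out)


def rmsd_timeseries(
    trajectory: Trajectory,
    selection: ResidueSelection,
    reference: "int | np.ndarray" = 0,
    fit: bool = False,
    fit_selection: ResidueSelection | None = None,
) -> TimeSeries:
    """Per-frame RMSD over ``selection`` against the reference, in Angstrom.

    With ``fit=True`` each frame is first superposed (over ``fit_selection``,
    default the same selection).
    """
    if fit:
        trajectory = superpose(trajectory, fit_selection or selection, reference)
    ref = _reference_coords(trajectory, reference)[selection.atom_indices]
    deltas = trajectory.coordinates[:, selection.atom_indices, :] - ref[None]
    values = np.sqrt(np.mean(np.sum(deltas**2, axis=2), axis=1))
    return TimeSeries(trajectory.times_ns, values, f"RMSD {selection.domain}", "A")


def rmsf_profile(
    trajectory: Trajectory,
    selection: ResidueSelection,
    window: tuple[int, int] | None = None,
) -> RMSFProfile:
    """Per-residue RMSF at the selection's atoms (one atom per residue, CA).

    RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>) over the frame window.
    """
    start, stop = trajectory.frame_range(window)
    if stop - start < 2:
        raise InsufficientDataError("RMSF needs at least two frames")
    coords = trajectory.coordinates[start:stop, selection.atom_indices, :]
    mean = coords.mean(axis=0)
    sq = np.sum((coords - mean[None]) ** 2, axis=2).mean(axis=0)
    values = np.sqrt(sq)
    topo = trajectory.topology
    labels = [
        topo.residue_label(topo.atom_resindex[i]) for i in selection.atom_indices
    ]
    return RMSFProfile(labels, values, (start, stop))


def _centroids(
    coords: np.ndarray, idx: np.ndarray, masses: np.ndarray | None
) -> np.ndarray:
    sub = coords[:, idx, :]
    if masses is None:
        return sub.mean(axis=1)
    w = masses[idx]
    return np.einsum("fai,a->fi", sub, w) / w.sum()


def com_distance_timeseries(
    trajectory: Trajectory,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    mass_weighted: bool = True,
) -> TimeSeries:
    """Per-frame distance between the two selections' centers of mass (A).

    No periodic-image correction is applied (the complex is assumed whole).
    Overlapping selections trigger a warning, not an error.
    """
    import warnings as _warnings

    if np.intersect1d(selection_a.atom_indices, selection_b.atom_indices).size:
        _warnings.warn(
            f"selections {selection_a.domain!r} and {selection_b.domain!r} overlap",
            stacklevel=2,
        )
    masses = trajectory.topology.masses if mass_weighted else None
    com_a = _centroids(trajectory.coordinates, selection_a.atom_indices, masses)
    com_b = _centroids(trajectory.coordinates, selection_b.atom_indices, masses)
    values = np.linalg.norm(com_a - com_b, axis=1)
    return TimeSeries(
        trajectory.times_ns,
        values,
        f"COM {selection_a.domain}-{selection_b.domain}",
        "A",
    )


def hinge_angle_timeseries(
    trajectory: Trajectory,
    apex: ResidueSelection,
    arm_a: ResidueSelection,
    arm_b: ResidueSelection,
) -> HingeAngleSeries:
    """Angle (degrees) at the apex COM subtended by the two arm COMs.

    Geometric (unweighted) centers of the three selections are used. For
    the nSH2 detachment this is the hinge angle phi: apex = helix 339-347,
    arms = residue 545 and helix 400-410.
    """
    coords = trajectory.coordinates
    p_apex = _centroids(coords, apex.atom_indices, None)
    p_a = _centroids(coords, arm_a.atom_indices, None)
    p_b = _centroids(coords, arm_b.atom_indices, None)
    v1 = p_a - p_apex
    v2 = p_b - p_apex
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    bad = (n1 < 1e-9) | (n2 < 1e-9)
    if np.any(bad):
        raise DegenerateGeometryError(
            f"coincident COMs at frame(s) {np.flatnonzero(bad)[:5].tolist()}: "
            "hinge angle undefined"
        )
    cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    series = TimeSeries(
        trajectory.times_ns,
        angles,
        f"phi {apex.domain}({arm_a.domain},{arm_b.domain})",
        "deg",
    )
    return HingeAngleSeries(series, (apex.domain, arm_a.domain, arm_b.domain))


#: Bondi van-der-Waals radii (Angstrom).
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "Se": 1.90,
    "I": 1.98,
}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa_frame(
    coords: np.ndarray,
    radii: np.ndarray,
    subset: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Shrake-Rupley SASA (A^2) of ``subset`` atoms in the context of all atoms."""
    points = _sphere_points(n_points)
    extended = radii + probe_radius
    tree = cKDTree(coords)
    max_r = extended.max()
    total = 0.0
    for i in subset:
        r_i = extended[i]
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], r_i + max_r)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < r_i + extended[j]
        ]
        surface = coords[i] + r_i * points
        if neighbors:
            ncoords = coords[neighbors]
            nrad = extended[np.asarray(neighbors)]
            d2 = np.sum(
                (surface[:, None, :] - ncoords[None, :, :]) ** 2, axis=2
            )
            exposed = np.all(d2 >= (nrad**2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * r_i**2 * frac
    return float(total)


def sasa_timeseries(
    trajectory: Trajectory,
    selection: ResidueSelection,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> TimeSeries:
    """Per-frame solvent-accessible surface area of the selection (A^2).

    Shrake-Rupley quadrature with Bondi radii, evaluated in the context of
    the full complex (all atoms occlude, the area of the selection atoms is
    summed).
    """
    topo = trajectory.topology
    radii = np.empty(topo.n_atoms)
    for i, el in enumerate(topo.elements):
        key = str(el).capitalize()
        if key not in BONDI_RADII:
            raise ParameterizationError(f"no van-der-Waals radius for element {el!r}")
        radii[i] = BONDI_RADII[key]
    values = np.array(
        [
            sasa_frame(
                trajectory.coordinates[f],
                radii,
                selection.atom_indices,
                probe_radius,
                n_points,
            )
            for f in range(trajectory.n_frames)
        ]
    )
    return TimeSeries(
        trajectory.times_ns, values, f"SASA {selection.domain}", "A^2"
    )
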