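"""Distance-fluctuation (DF) maps.

DF_ij is the variance over a trajectory window of the scalar Calpha-Calpha
distance d_ij(t). Pairs moving as a rigid body have DF near zero; the
conventional rigidity criterion is DF < 0.3 A^2, below which inter-domain
pairs are taken to support strong allosteric coordination. No
superposition is required: pairwise distances are frame-internal.

The variance is accumulated with a numerically stable two-pass algorithm
(mean first, then squared deviations), frame by frame, so large systems
never materialize a frames x pairs array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InputError, InsufficientDataError
from .structure import DomainMap, ResidueSelection, Trajectory

__all__ = [
    "DFMatrix",
    "DFBlockSummary",
    "distance_fluctuation_matrix",
    "interdomain_df_summary",
    "save_df_heatmap",
]

#: Conventional rigid-body threshold (A^2) for inter-domain coordination.
RIGIDITY_THRESHOLD_A2 = 0.3


@dataclass
class DFMatrix:
    """Symmetric matrix of pairwise-distance variances (A^2)."""

    residue_keys: list[tuple[str, int]]  # (chain, resnum) per Calpha node
    residue_labels: list[str]
    matrix: np.ndarray
    window: tuple[int, int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.residue_keys)
        if self.matrix.shape != (n, n):
            raise InputError("DF matrix shape does not match residue count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise InputError("DF matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise InputError("DF matrix diagonal must be exactly zero")
        if np.any(self.matrix < 0):
            raise InputError("DF values must be non-negative")

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def rows_for(self, domain_map: DomainMap, name: str) -> np.ndarray:
        """Row indices whose residues belong to the named domain entry."""
        if name not in domain_map:
            raise KeyError(f"domain {name!r} not in map")
        hits = []
        for i, (chain, num) in enumerate(self.residue_keys):
            for c, first, last in domain_map[name]:
                if chain == c and first <= num <= last:
                    hits.append(i)
                    break
        if not hits:
            raise KeyError(f"domain {name!r} has no residues in this DF matrix")
        return np.asarray(hits, dtype=int)

    def to_long_dataframe(self):
        import pandas as pd

        n = self.n_residues
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "res_i": [self.residue_labels[i] for i in iu[0]],
                "res_j": [self.residue_labels[j] for j in iu[1]],
                "df_A2": self.matrix[iu],
            }
        )

    def to_csv(self, path) -> None:
        self.to_long_dataframe().to_csv(path, index=False)

    def to_square_text(self, path) -> None:
        """Plain-text square matrix with residue-label header row/column."""
        with open(path, "w") as handle:
            handle.write("residue\t" + "\t".join(self.residue_labels) + "\n")
            for label, row in zip(self.residue_labels, self.matrix):
                handle.write(label + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


@dataclass
class DFBlockSummary:
    """Summary of one inter- (or intra-) domain DF block."""

    domain_a: str
    domain_b: str
    block: np.ndarray
    mean_df: float
    fraction_below_threshold: float
    threshold: float
    n_pairs: int


def distance_fluctuation_matrix(
    trajectory: Trajectory,
    selection: ResidueSelection,
    window: tuple[int, int] | None = None,
) -> DFMatrix:
    """Pairwise distance variance for every residue pair of the selection.

    The selection must hold one atom per residue (Calpha nodes).
    """
    if len(selection.atom_indices) != len(selection.residue_indices):
        raise InputError("DF selection must contain one atom per residue")
    start, stop = trajectory.frame_range(window)
    n_frames = stop - start
    if n_frames < 2:
        raise InsufficientDataError("distance fluctuations need >= 2 frames")
    idx = selection.atom_indices

    mean_d = None
    for f in range(start, stop):
        d = pdist(trajectory.coordinates[f, idx, :])
        mean_d = d if mean_d is None else mean_d + d
    mean_d /= n_frames

    ss = np.zeros_like(mean_d)
    for f in range(start, stop):
        dev = pdist(trajectory.coordinates[f, idx, :]) - mean_d
        ss += dev * dev
    var = ss / n_frames

    matrix = squareform(var)
    topo = trajectory.topology
    res_idx = [int(topo.atom_resindex[i]) for i in idx]
    keys = [topo.residue_key(r) for r in res_idx]
    labels = [topo.residue_label(r) for r in res_idx]
    return DFMatrix(keys, labels, matrix, (start, stop))


def interdomain_df_summary(
    matrix: DFMatrix,
    domain_map: DomainMap,
    domain_a: str,
    domain_b: str,
    rigidity_threshold: float = RIGIDITY_THRESHOLD_A2,
) -> DFBlockSummary:
    """Block submatrix between two domains with mean DF and the fraction of
    pairs strictly below the rigidity threshold.

    For an intra-domain block (``domain_a == domain_b``) the diagonal is
    excluded from the statistics.
    """
    rows = matrix.rows_for(domain_map, domain_a)
    cols = matrix.rows_for(domain_map, domain_b)
    block = matrix.matrix[np.ix_(rows, cols)]
    if domain_a == domain_b:
        n = len(rows)
        offdiag = ~np.eye(n, dtype=bool)
        values = block[offdiag]
    else:
        values = block.ravel()
    n_pairs = values.size
    if n_pairs == 0:
        raise InputError(f"no residue pairs between {domain_a!r} and {domain_b!r}")
    return DFBlockSummary(
        domain_a=domain_a,
        domain_b=domain_b,
        block=block,
        mean_df=float(values.mean()),
        fraction_below_threshold=float(np.mean(values < rigidity_threshold)),
        threshold=rigidity_threshold,
        n_pairs=int(n_pairs),
    )


def save_df_heatmap(
    matrix: DFMatrix,
    path,
    midpoint: float = RIGIDITY_THRESHOLD_A2,
    vmax: float | None = None,
) -> None:
    """Render the DF map with a black (rigid) to red (plastic) scale.

    The color midpoint sits at the rigidity threshold so rigid blocks read
    dark and plastic blocks read red.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    cmap = LinearSegmentedColormap.from_list("df", ["black", "darkred", "red"])
    vmax = vmax or max(float(matrix.matrix.max()), midpoint * 2)
    norm = TwoSlopeNorm(vmin=0.0, vcenter=midpoint, vmax=vmax)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.matrix, cmap=cmap, norm=norm, origin="lower")
    fig.colorbar(im, ax=ax, label="distance fluctuation (A$^2$)")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
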