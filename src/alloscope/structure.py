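"""Topology/trajectory ingestion and the domain-map data model.

Everything downstream (geometry, hydrogen bonds, distance-fluctuation maps,
network analysis, event annotation) consumes the three containers defined
here:

``Topology``
    Atom/residue/chain hierarchy with names, elements and masses.
``Trajectory``
    Frames x atoms x 3 coordinates in Angstrom plus frame times in ns.
``DomainMap``
    Named, chain-qualified inclusive residue-number ranges (nSH2, helical,
    C2, kinase, ...), read from a plain-text config file.

File parsing is delegated to MDAnalysis; this module converts to plain
NumPy containers, enforces the package's unit conventions (Angstrom, ns)
and validates the invariants the rest of the pipeline relies on.

Conventions
-----------
* Internal length unit is Angstrom everywhere (MDAnalysis native unit).
* Residue numbers are taken verbatim from the input file (author/PDB
  numbering); ranges are 1-based and inclusive.
* Chains disambiguate residue numbers: the same number may exist on both
  the catalytic (p110alpha) and regulatory (p85alpha) subunits.
* GRO files carry no chain identifiers; atoms loaded from GRO are assigned
  chain ``"A"``. Multi-chain systems should use a PDB topology.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    EmptySelectionError,
    InputError,
    TopologyFormatError,
    TopologyMismatchError,
)

__all__ = [
    "Topology",
    "Trajectory",
    "DomainMap",
    "ResidueSelection",
    "load_topology",
    "load_trajectory",
    "load_domain_map",
    "pi3k_domain_map",
    "select_domain",
]

#: Standard atomic weights (amu) used when the input provides no masses.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "NA": 22.990,
    "MG": 24.305,
    "K": 39.098,
    "CA": 40.078,  # element calcium; atom *name* CA is carbon (handled below)
    "ZN": 65.38,
    "FE": 55.845,
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "SE"}


def infer_element(atom_name: str) -> str:
    """Infer the element from an atom name (PDB convention).

    The leading alphabetic characters are examined; two-letter elements are
    only accepted when the full stripped name matches a known two-letter
    symbol (so the alpha-carbon name ``CA`` stays carbon).
    """
    stripped = "".join(ch for ch in atom_name.strip() if ch.isalpha()).upper()
    if not stripped:
        raise TopologyFormatError(f"cannot infer element from atom name {atom_name!r}")
    if stripped in _TWO_LETTER_ELEMENTS:
        return stripped.capitalize()
    return stripped[0]


@dataclass
class Topology:
    """Atom/residue/chain hierarchy of one molecular system.

    Atom indices are 0-based and contiguous; every atom belongs to exactly
    one residue (``atom_resindex``). Residue numbers (``res_numbers``) keep
    the input file's numbering.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    atom_resindex: np.ndarray
    res_numbers: np.ndarray
    res_names: np.ndarray
    res_chains: np.ndarray

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.atom_resindex = np.asarray(self.atom_resindex, dtype=int)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.res_chains = np.asarray(self.res_chains, dtype=object)
        if np.any(self.masses <= 0):
            raise TopologyFormatError("all atom masses must be positive")
        if self.atom_resindex.min(initial=0) < 0 or (
            self.n_atoms and self.atom_resindex.max() >= self.n_residues
        ):
            raise TopologyFormatError("atom_resindex out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.res_numbers)

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.res_chains.tolist()))

    def residue_label(self, res_index: int) -> str:
        """Human-readable label ``chain:RESNAMEnum`` for one residue."""
        return (
            f"{self.res_chains[res_index]}:"
            f"{self.res_names[res_index]}{self.res_numbers[res_index]}"
        )

    def residue_key(self, res_index: int) -> tuple[str, int]:
        return (str(self.res_chains[res_index]), int(self.res_numbers[res_index]))

    def residue_index(self, chain: str, resnum: int) -> int:
        """0-based residue index for a (chain, residue-number) pair."""
        hits = np.flatnonzero((self.res_chains == chain) & (self.res_numbers == resnum))
        if len(hits) == 0:
            raise KeyError(f"residue {chain}:{resnum} not in topology")
        return int(hits[0])


@dataclass
class Trajectory:
    """Coordinates over time for one :class:`Topology`.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Angstrom;
    ``times_ns`` is strictly increasing.
    """

    topology: Topology
    coordinates: np.ndarray
    times_ns: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise InputError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"trajectory has {self.coordinates.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.coordinates.shape[0] == 0:
            raise InputError("trajectory contains zero frames")
        if len(self.times_ns) != self.coordinates.shape[0]:
            raise InputError("times and coordinates disagree on frame count")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise InputError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise InputError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame_range(self, window: tuple[int, int] | None) -> tuple[int, int]:
        """Normalize an optional (start, stop) frame window (stop exclusive)."""
        if window is None:
            return 0, self.n_frames
        start, stop = window
        start = max(0, int(start))
        stop = self.n_frames if stop is None else min(self.n_frames, int(stop))
        if stop <= start:
            raise InputError(f"empty frame window {window!r}")
        return start, stop

    def with_coordinates(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, coords, self.times_ns.copy())


@dataclass
class ResidueSelection:
    """Ordered atom indices belonging to one named domain."""

    atom_indices: np.ndarray
    domain: str
    residue_indices: np.ndarray

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if len(self.atom_indices) == 0:
            raise EmptySelectionError(f"selection for {self.domain!r} is empty")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass
class DomainMap:
    """Named residue ranges per chain.

    ``entries`` maps a domain name to a list of ``(chain, first, last)``
    inclusive ranges. Multi-range entries are allowed; ranges of one entry
    on the same chain must not overlap.
    """

    entries: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ranges in self.entries.items():
            by_chain: dict[str, list[tuple[int, int]]] = {}
            for chain, first, last in ranges:
                if last < first:
                    raise InputError(f"{name}: range {chain}:{first}-{last} is inverted")
                by_chain.setdefault(chain, []).append((first, last))
            for chain, spans in by_chain.items():
                spans.sort()
                for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                    if b0 <= a1:
                        raise InputError(
                            f"{name}: overlapping ranges on chain {chain}: "
                            f"{a0}-{a1} and {b0}-{b1}"
                        )

    def names(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> list[tuple[str, int, int]]:
        return self.entries[name]

    def resolve(self, topology: Topology, name: str) -> np.ndarray:
        """0-based residue indices of ``name`` in ``topology`` (residue order)."""
        if name not in self.entries:
            raise KeyError(f"domain {name!r} not in map (have: {self.names()})")
        mask = np.zeros(topology.n_residues, dtype=bool)
        for chain, first, last in self.entries[name]:
            mask |= (
                (topology.res_chains == chain)
                & (topology.res_numbers >= first)
                & (topology.res_numbers <= last)
            )
        indices = np.flatnonzero(mask)
        if len(indices) == 0:
            raise EmptySelectionError(f"domain {name!r} resolves to zero residues")
        return indices


def _check_pdb_serials(path: Path) -> None:
    """Reject PDB files with duplicate atom serials within one model."""
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "MODEL" or record == "ENDMDL":
                seen.clear()
            elif record in ("ATOM", "HETATM"):
                serial = line[6:11].strip()
                if serial and serial in seen:
                    raise TopologyFormatError(
                        f"duplicate atom serial {serial} at line {lineno} of {path}"
                    )
                seen.add(serial)


def _universe_to_topology(universe) -> Topology:
    atoms = universe.atoms
    names = np.array([a.name for a in atoms], dtype=object)
    try:
        elements = np.array(
            [str(e).capitalize() if str(e).strip() else "" for e in atoms.elements],
            dtype=object,
        )
    except Exception:  # elements attribute absent
        elements = np.array([""] * len(atoms), dtype=object)
    for i, (el, nm) in enumerate(zip(elements, names)):
        if not el:
            elements[i] = infer_element(nm)
    try:
        masses = np.asarray(atoms.masses, dtype=float)
    except Exception:
        masses = np.zeros(len(atoms))
    bad = ~np.isfinite(masses) | (masses <= 0)
    if np.any(bad):
        masses = masses.copy()
        for i in np.flatnonzero(bad):
            key = str(elements[i]).upper()
            masses[i] = ELEMENT_MASSES.get(key, 12.011)

    residues = universe.residues
    res_numbers = np.asarray(residues.resids, dtype=int)
    res_names = np.array([r.resname for r in residues], dtype=object)
    chain_ids = []
    for r in residues:
        cid = ""
        try:
            cid = str(r.atoms.chainIDs[0]).strip()
        except Exception:
            pass
        if not cid:
            try:
                segid = str(r.segid).strip()
                cid = segid if len(segid) == 1 else ""
            except Exception:
                cid = ""
        chain_ids.append(cid or "A")
    res_chains = np.array(chain_ids, dtype=object)
    atom_resindex = np.asarray(atoms.resindices, dtype=int)
    return Topology(
        atom_names=names,
        elements=elements,
        masses=masses,
        atom_resindex=atom_resindex,
        res_numbers=res_numbers,
        res_names=res_names,
        res_chains=res_chains,
    )


def load_topology(path: str | Path, format: str | None = None) -> Topology:
    """Load a PDB or GRO topology.

    Elements are taken from the file when present and inferred from atom
    names otherwise; missing masses default to standard atomic weights.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise InputError(f"topology file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise InputError(f"unsupported topology format {fmt!r} (expected PDB or GRO)")
    if fmt == "PDB":
        _check_pdb_serials(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(path), format=fmt, to_guess=())
    except TopologyFormatError:
        raise
    except Exception as exc:
        raise InputError(f"could not parse {path}: {exc}") from exc
    return _universe_to_topology(universe)


def load_trajectory(
    topology: Topology,
    path: str | Path,
    format: str | None = None,
    stride: int = 1,
    topology_path: str | Path | None = None,
    dt_ns: float | None = None,
) -> Trajectory:
    """Load an XTC, DCD or multi-model-PDB trajectory against ``topology``.

    Coordinates are converted to Angstrom and frames subsampled by
    ``stride``. Times come from the file (ps -> ns) when present; formats
    without time stamps get ``frame * stride * dt_ns`` (default 1 ns per
    stored frame).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise InputError(f"trajectory file not found: {path}")
    if stride < 1:
        raise InputError("stride must be a positive integer")
    fmt = (format or path.suffix.lstrip(".")).upper()

    n_atoms = topology.n_atoms
    if fmt in ("XTC", "DCD"):  # these formats declare their own atom count
        from MDAnalysis.coordinates.DCD import DCDReader
        from MDAnalysis.coordinates.XTC import XTCReader

        reader_cls = XTCReader if fmt == "XTC" else DCDReader
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                file_atoms = reader_cls(str(path)).n_atoms
        except Exception as exc:
            raise InputError(f"could not read trajectory {path}: {exc}") from exc
        if file_atoms != n_atoms:
            raise TopologyMismatchError(
                f"trajectory has {file_atoms} atoms, topology has {n_atoms}"
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if topology_path is not None:
                universe = mda.Universe(str(topology_path), str(path), to_guess=())
            elif fmt == "PDB":
                universe = mda.Universe(str(path), format="PDB", to_guess=())
            else:
                universe = mda.Universe.empty(n_atoms, trajectory=True)
                universe.load_new(str(path), format=fmt)
        except Exception as exc:
            raise InputError(f"could not read trajectory {path}: {exc}") from exc

    if universe.atoms.n_atoms != n_atoms:
        raise TopologyMismatchError(
            f"trajectory has {universe.atoms.n_atoms} atoms, "
            f"topology has {n_atoms}"
        )

    coords, times = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in universe.trajectory[::stride]:
            coords.append(ts.positions.astype(float).copy())
            times.append(float(ts.time))  # MDAnalysis time unit: ps
    if not coords:
        raise InputError(f"trajectory {path} contains zero frames")
    coordinates = np.stack(coords)
    times_arr = np.asarray(times) / 1000.0  # ps -> ns
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        spacing = 1.0 if dt_ns is None else float(dt_ns)
        times_arr = np.arange(len(coords)) * spacing * stride
    elif dt_ns is not None:
        times_arr = np.arange(len(coords)) * float(dt_ns) * stride
    return Trajectory(topology, coordinates, times_arr)


def load_domain_map(path: str | Path) -> DomainMap:
    """Read a domain map from a plain-text config file.

    Schema: one entry per line, ``name = CHAIN:FIRST-LAST[, CHAIN:FIRST-LAST...]``;
    ``#`` starts a comment; blank lines ignored. A single residue may be
    written ``CHAIN:NUM``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"domain map file not found: {path}")
    return parse_domain_map(path.read_text())


def parse_domain_map(text: str) -> DomainMap:
    entries: dict[str, list[tuple[str, int, int]]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"domain map line {lineno}: expected 'name = ranges'")
        name, spec = (part.strip() for part in line.split("=", 1))
        if name in entries:
            raise InputError(f"domain map line {lineno}: duplicate entry {name!r}")
        ranges = []
        for token in spec.split(","):
            token = token.strip()
            if not token:
                continue
            if ":" not in token:
                raise InputError(
                    f"domain map line {lineno}: range {token!r} lacks a chain qualifier"
                )
            chain, span = token.split(":", 1)
            chain = chain.strip()
            if "-" in span:
                first_s, last_s = span.split("-", 1)
            else:
                first_s = last_s = span
            try:
                first, last = int(first_s), int(last_s)
            except ValueError as exc:
                raise InputError(
                    f"domain map line {lineno}: bad residue numbers in {token!r}"
                ) from exc
            ranges.append((chain, first, last))
        if not ranges:
            raise InputError(f"domain map line {lineno}: no ranges for {name!r}")
        entries[name] = ranges
    return DomainMap(entries)


def pi3k_domain_map() -> DomainMap:
    """The packaged PI3Kalpha (p110alpha chain A / p85alpha chain B) map."""
    ref = importlib.resources.files("alloscope.data").joinpath("pi3k_domains.cfg")
    return parse_domain_map(ref.read_text())


def select_domain(
    topology: Topology,
    domain_map: DomainMap,
    name: str,
    atom_subset: str = "CA",
) -> ResidueSelection:
    """Atoms of one named domain, restricted to ``all``, ``heavy`` or ``CA``.

    Atoms are returned in residue order (and file order within a residue).
    """
    if atom_subset not in ("all", "heavy", "CA"):
        raise InputError(f"unknown atom subset {atom_subset!r}")
    res_indices = domain_map.resolve(topology, name)
    res_mask = np.zeros(topology.n_residues, dtype=bool)
    res_mask[res_indices] = True
    atom_mask = res_mask[topology.atom_resindex]
    if atom_subset == "heavy":
        atom_mask &= np.array([e.upper() != "H" for e in topology.elements])
    elif atom_subset == "CA":
        atom_mask &= np.array([n.strip() == "CA" for n in topology.atom_names])
    atom_indices = np.flatnonzero(atom_mask)
    if len(atom_indices) == 0:
        raise EmptySelectionError(
            f"domain {name!r} has no atoms in subset {atom_subset!r}"
        )
    return ResidueSelection(
        atom_indices=atom_indices,
        domain=name,
        residue_indices=np.unique(topology.atom_resindex[atom_indices]),
    )
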