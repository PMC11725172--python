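"""Bead topologies, replica coordinate ensembles, selections, and the region registry.

The coarse-grained model follows the Martini convention: one backbone bead
(``BB``) per residue plus up to three side-chain beads (``SC1``–``SC3``), and a
flavin cofactor represented by the five isoalloxazine beads ``FLA1``–``FLA5``.
Internal units are Angstrom and microseconds throughout.

Topology files (GRO/PDB) and binary coordinate formats (XTC/TRR/DCD) are read
through MDAnalysis; a plain whitespace table dialect is provided as a
language-neutral text format for fixtures and interchange.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    ParseError,
    PBCJumpError,
    SelectionError,
    ShapeError,
    TopologyError,
)

__all__ = [
    "BeadTopology",
    "Ensemble",
    "RegionSet",
    "read_topology",
    "read_coordinates",
    "write_table",
    "write_dcd",
    "select",
    "stack_replicas",
]

#: residue names treated as the flavin cofactor rather than protein
COFACTOR_RESNAMES = frozenset({"FAD", "FLA", "FMN"})

FLA_BEADS = ("FLA1", "FLA2", "FLA3", "FLA4", "FLA5")


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadTopology:
    """Per-bead metadata of a coarse-grained structure.

    Residue indices are 1-based and taken verbatim from the source file so that
    they match the literature numbering of the protein.
    """

    bead_id: np.ndarray          # (n_beads,) int, contiguous from 0
    residue_index: np.ndarray    # (n_beads,) int, 1-based
    residue_name: np.ndarray     # (n_beads,) str
    bead_name: np.ndarray        # (n_beads,) str
    chain_id: np.ndarray         # (n_beads,) str

    def __post_init__(self):
        n = len(self.bead_id)
        for name in ("residue_index", "residue_name", "bead_name", "chain_id"):
            if len(getattr(self, name)) != n:
                raise ShapeError(f"topology field {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if not np.array_equal(self.bead_id, np.arange(n)):
            raise TopologyError("bead_ids must be unique and contiguous from 0")
        self._validate_beads()

    def _validate_beads(self) -> None:
        prot = self.protein_mask
        # exactly one BB bead per protein residue
        for res in np.unique(self.residue_index[prot]):
            names = self.bead_name[prot & (self.residue_index == res)]
            n_bb = int(np.sum(names == "BB"))
            if n_bb != 1:
                raise TopologyError(
                    f"residue {res} has {n_bb} BB beads (expected exactly 1)")
        # cofactor, when present, carries FLA1..FLA5 exactly once each
        fla_names = self.bead_name[~prot]
        present = [b for b in fla_names if b.startswith("FLA")]
        if present:
            counts = {b: present.count(b) for b in FLA_BEADS}
            if any(c != 1 for c in counts.values()) or len(present) != 5:
                raise TopologyError(
                    f"cofactor must contribute FLA1-FLA5 exactly once, got {sorted(present)}")
        # residue index non-decreasing within each chain
        for chain in np.unique(self.chain_id):
            idx = self.residue_index[self.chain_id == chain]
            if np.any(np.diff(idx) < 0):
                raise TopologyError(f"residue_index decreases within chain {chain!r}")

    # -- derived views ------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.bead_id)

    @property
    def protein_mask(self) -> np.ndarray:
        return ~np.isin(self.residue_name, list(COFACTOR_RESNAMES))

    @property
    def n_residues(self) -> int:
        """Number of protein residues (largest protein residue index)."""
        return int(self.residue_index[self.protein_mask].max())

    @property
    def bb_indices(self) -> np.ndarray:
        """Bead indices of all backbone beads, in residue order."""
        mask = self.protein_mask & (self.bead_name == "BB")
        return self.bead_id[mask]

    @property
    def fla_indices(self) -> np.ndarray:
        """Bead indices of the isoalloxazine beads FLA1-FLA5 (may be empty)."""
        return self.bead_id[np.isin(self.bead_name, FLA_BEADS)]

    def bead_index(self, residue: int, bead_name: str) -> int:
        """Index of a single named bead of one residue."""
        mask = (self.residue_index == residue) & (self.bead_name == bead_name)
        hits = self.bead_id[mask]
        if len(hits) != 1:
            raise SelectionError(
                f"expected one bead {bead_name!r} in residue {residue}, found {len(hits)}")
        return int(hits[0])

    def residue_beads(self, residue: int) -> np.ndarray:
        """All bead indices belonging to one residue (protein or cofactor)."""
        return self.bead_id[self.residue_index == residue]


# ---------------------------------------------------------------------------
# region registry
# ---------------------------------------------------------------------------

#: canonical region ranges (1-based, inclusive) of the 497-residue protein
_PAPER_RANGES: dict[str, tuple[int, int]] = {
    "PBL": (220, 245),
    "CT": (470, 497),
    "CL": (170, 200),
    "OPP": (80, 90),
    "REF": (388, 399),
    "EEE": (440, 460),
    "R20_33": (20, 33),
    "R110_125": (110, 125),
    # alternates used in some figure captions of the source structure
    "CT_core": (480, 497),
    "REF_alt": (389, 399),
}

#: the eight regions used for region-resolved statistics
PRIMARY_REGIONS = ("PBL", "CT", "CL", "OPP", "REF", "EEE", "R20_33", "R110_125")

#: tryptophan tetrad, in electron-transfer order (surface-exposed last)
_PAPER_TETRAD: dict[str, int] = {
    "Trp_A": 395, "Trp_B": 372, "Trp_C": 318, "Trp_D": 369,
}

PAPER_N_RESIDUES = 497


@dataclass(frozen=True)
class RegionSet:
    """Named residue-index ranges plus named single-residue sets.

    Ranges are 1-based inclusive.  The default registry carries the canonical
    regions of the 497-residue avian cryptochrome 4 model (phosphate-binding
    loop, C-terminal tail, connecting loop, EEE motif, ...) and the tryptophan
    tetrad W395/W372/W318/W369.
    """

    ranges: dict[str, tuple[int, int]]
    residue_sets: dict[str, dict[str, int]] = field(default_factory=dict)
    n_residues: int = PAPER_N_RESIDUES

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if not (1 <= lo <= hi <= self.n_residues):
                raise SelectionError(
                    f"region {name!r} range ({lo}, {hi}) outside [1, {self.n_residues}]")
        for name, members in self.residue_sets.items():
            if name in self.ranges:
                raise SelectionError(f"duplicate region name {name!r}")
            for label, res in members.items():
                if not (1 <= res <= self.n_residues):
                    raise SelectionError(
                        f"{name}[{label}] = {res} outside [1, {self.n_residues}]")

    @classmethod
    def paper_registry(cls) -> "RegionSet":
        """The full-size (497 residue) canonical registry."""
        return cls(ranges=dict(_PAPER_RANGES),
                   residue_sets={"tetrad": dict(_PAPER_TETRAD)},
                   n_residues=PAPER_N_RESIDUES)

    @classmethod
    def rescaled(cls, n_residues: int) -> "RegionSet":
        """Canonical registry rescaled proportionally onto a smaller toy protein."""
        if n_residues == PAPER_N_RESIDUES:
            return cls.paper_registry()
        s = n_residues / PAPER_N_RESIDUES

        def m(r: int) -> int:
            return min(n_residues, max(1, round(r * s)))

        ranges = {name: (m(lo), m(hi)) for name, (lo, hi) in _PAPER_RANGES.items()}
        tetrad = {label: m(r) for label, r in _PAPER_TETRAD.items()}
        if len(set(tetrad.values())) != 4:
            raise SelectionError(
                f"n_residues={n_residues} too small: rescaled tetrad residues collide")
        return cls(ranges=ranges, residue_sets={"tetrad": tetrad}, n_residues=n_residues)

    def residues(self, region: str | tuple[int, int]) -> np.ndarray:
        """Sorted residue indices of a named region, named set, or explicit range."""
        if isinstance(region, str):
            if region in self.ranges:
                lo, hi = self.ranges[region]
                return np.arange(lo, hi + 1)
            if region in self.residue_sets:
                return np.array(sorted(set(self.residue_sets[region].values())))
            raise SelectionError(f"unknown region {region!r}")
        lo, hi = region
        return np.arange(lo, hi + 1)

    def label_of(self, residue: int) -> str:
        """First primary region containing the residue, else 'background'."""
        for name in PRIMARY_REGIONS:
            if name not in self.ranges:
                continue
            lo, hi = self.ranges[name]
            if lo <= residue <= hi:
                return name
        return "background"


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """Replicated bead-coordinate time series.

    coordinates : (n_replicas, n_frames, n_beads, 3) in Angstrom
    frame_times : (n_frames,) in microseconds, strictly increasing from 0
    aligned_to  : label of the common superposition target, or None when raw
    """

    topology: BeadTopology
    coordinates: np.ndarray
    frame_times: np.ndarray
    label: str = ""
    aligned_to: str | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coordinates.ndim != 4 or self.coordinates.shape[-1] != 3:
            raise ShapeError(
                f"coordinates must be (n_replicas, n_frames, n_beads, 3), "
                f"got {self.coordinates.shape}")
        if self.coordinates.shape[2] != self.topology.n_beads:
            raise ShapeError(
                f"{self.coordinates.shape[2]} beads in coordinates vs "
                f"{self.topology.n_beads} in topology")
        if len(self.frame_times) != self.coordinates.shape[1]:
            raise ShapeError("frame_times length does not match n_frames")
        if len(self.frame_times) and self.frame_times[0] != 0.0:
            raise ShapeError("frame_times must start at 0")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ShapeError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise ShapeError("coordinates contain NaN/Inf")

    @property
    def n_replicas(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[2]

    @property
    def duration(self) -> float:
        return float(self.frame_times[-1])

    @property
    def dt(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])

    def subset(self, replica_ids) -> "Ensemble":
        """New ensemble restricted to the given replica indices."""
        ids = np.atleast_1d(np.asarray(replica_ids, dtype=int))
        return replace(self, coordinates=self.coordinates[ids])

    def check_continuity(self, bound: float = 10.0, on_jump: str = "warn") -> float:
        """Sanity check that the trajectory carries no wrapping artifacts.

        Input trajectories are required to be unwrapped; a per-bead displacement
        between consecutive frames above ``bound`` (Angstrom) indicates a
        periodic-boundary jump.  Returns the largest displacement found.
        """
        if self.n_frames < 2:
            return 0.0
        step = np.linalg.norm(np.diff(self.coordinates, axis=1), axis=-1)
        worst = float(step.max())
        if worst > bound:
            msg = (f"consecutive-frame displacement {worst:.2f} A exceeds the "
                   f"sanity bound {bound:.2f} A; trajectories must be unwrapped "
                   f"before analysis")
            if on_jump == "error":
                raise PBCJumpError(msg)
            warnings.warn(msg, stacklevel=2)
        return worst


def stack_replicas(replicas: list[Ensemble]) -> Ensemble:
    """Combine single-replica ensembles sharing topology and time grid."""
    if not replicas:
        raise ShapeError("no replicas to stack")
    first = replicas[0]
    for r in replicas[1:]:
        if r.n_beads != first.n_beads:
            raise ShapeError("replicas differ in bead count")
        if not np.allclose(r.frame_times, first.frame_times):
            raise ShapeError("replicas differ in time grid")
    coords = np.concatenate([r.coordinates for r in replicas], axis=0)
    return replace(first, coordinates=coords)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"tsv": "table", "txt": "table", "dat": "table"}.get(suffix, suffix)


def read_topology(path: str | Path, format: str | None = None) -> BeadTopology:
    """Read a bead topology from a GRO or PDB file.

    Residue indices are taken from the file, not renumbered; bead order follows
    file order.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise ParseError(f"topology file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt not in ("gro", "pdb"):
        raise ParseError(f"unsupported topology format {fmt!r} (expected gro or pdb)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), topology_format=fmt)
        except Exception as exc:  # MDAnalysis raises a zoo of parse errors
            raise ParseError(f"could not parse {path.name}: {exc}") from exc
    atoms = u.atoms
    n = len(atoms)
    chain = atoms.segids if hasattr(atoms, "segids") else np.full(n, "A")
    chain = np.array([c if c else "A" for c in chain])
    return BeadTopology(
        bead_id=np.arange(n),
        residue_index=atoms.resids.astype(int),
        residue_name=atoms.resnames.astype(str),
        bead_name=atoms.names.astype(str),
        chain_id=chain,
    )


_TABLE_HEADER = "frame bead_id x y z"


def read_coordinates(
    path: str | Path,
    topology: BeadTopology,
    format: str | None = None,
    dt: float = 1.0,
    pbc_bound: float = 10.0,
    on_jump: str = "warn",
    label: str = "",
) -> Ensemble:
    """Read one replica's coordinate series into a single-replica Ensemble.

    ``dt`` is the frame spacing in microseconds (binary trajectory formats do
    not carry the unit convention used here, so the stride is supplied).
    Coordinates are returned in Angstrom.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "table":
        coords = _read_table(path, topology)
    elif fmt in ("xtc", "trr", "dcd"):
        coords = _read_mda(path, fmt, topology)
    else:
        raise ParseError(f"unsupported coordinate format {fmt!r}")
    times = np.arange(coords.shape[0]) * dt
    ens = Ensemble(topology=topology, coordinates=coords[None], frame_times=times,
                   label=label)
    ens.check_continuity(bound=pbc_bound, on_jump=on_jump)
    return ens


def _read_table(path: Path, topology: BeadTopology) -> np.ndarray:
    """Plain-table dialect: header then one ``frame bead_id x y z`` row per bead."""
    with open(path) as fh:
        header = fh.readline().split()
        if header != _TABLE_HEADER.split():
            raise ParseError(f"bad table header {' '.join(header)!r}, "
                             f"expected {_TABLE_HEADER!r}", line=1)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(f"expected 5 columns, got {len(parts)}", line=lineno)
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    data = np.asarray(rows)
    n_beads = topology.n_beads
    if len(data) % n_beads:
        raise ShapeError(f"{len(data)} rows is not a multiple of {n_beads} beads")
    n_frames = len(data) // n_beads
    coords = np.empty((n_frames, n_beads, 3))
    frames = data[:, 0].astype(int)
    beads = data[:, 1].astype(int)
    if beads.min() < 0 or beads.max() >= n_beads:
        raise ShapeError(f"bead_id out of range for {n_beads}-bead topology")
    coords[frames, beads] = data[:, 2:5]
    return coords


def _read_mda(path: Path, fmt: str, topology: BeadTopology) -> np.ndarray:
    import MDAnalysis as mda

    reader_cls = {
        "xtc": mda.coordinates.XTC.XTCReader,
        "trr": mda.coordinates.TRR.TRRReader,
        "dcd": mda.coordinates.DCD.DCDReader,
    }[fmt]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(str(path))
        try:
            if reader.n_atoms != topology.n_beads:
                raise ShapeError(f"{reader.n_atoms} beads in {path.name} vs "
                                 f"{topology.n_beads} in topology")
            coords = np.array([ts.positions.copy() for ts in reader], dtype=float)
        finally:
            reader.close()
    return coords


def write_table(ensemble: Ensemble, path: str | Path, replica: int = 0) -> None:
    """Write one replica in the plain-table dialect (header mandatory)."""
    coords = ensemble.coordinates[replica]
    n_frames, n_beads, _ = coords.shape
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER + "\n")
        for f in range(n_frames):
            for b in range(n_beads):
                x, y, z = coords[f, b]
                fh.write(f"{f} {b} {x:.6f} {y:.6f} {z:.6f}\n")


def write_dcd(ensemble: Ensemble, path: str | Path, replica: int = 0) -> None:
    """Write one replica as a DCD trajectory (Angstrom)."""
    import MDAnalysis as mda

    coords = ensemble.coordinates[replica]
    n_beads = coords.shape[1]
    u = mda.Universe.empty(n_beads, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.coordinates.DCD.DCDWriter(str(path), n_beads) as w:
            for frame in coords:
                u.atoms.positions = frame
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def select(
    obj: Ensemble | BeadTopology,
    region: str | tuple[int, int],
    regions: RegionSet | None = None,
    bead_names: set[str] | tuple[str, ...] | None = ("BB",),
) -> np.ndarray:
    """Sorted, duplicate-free bead indices of a region.

    Per the backbone convention of region-resolved statistics, the default bead
    filter keeps only BB beads; pass ``bead_names`` explicitly (or None for all
    beads) to select side-chain or cofactor beads.
    """
    topo = obj.topology if isinstance(obj, Ensemble) else obj
    if regions is None and not isinstance(region, str):
        lo, hi = region          # explicit range needs no registry
        residues = np.arange(lo, hi + 1)
    else:
        regions = regions or RegionSet.rescaled(topo.n_residues)
        residues = regions.residues(region)
    mask = np.isin(topo.residue_index, residues) & topo.protein_mask
    if bead_names is not None:
        mask &= np.isin(topo.bead_name, list(bead_names))
    idx = np.unique(topo.bead_id[mask])
    if idx.size == 0:
        raise SelectionError(f"selection {region!r} with beads {bead_names} is empty")
    return idx
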