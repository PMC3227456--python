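"""Structure input and surface-residue selection.

Reads protein chains from PDB files, reads dot-surface vertex files in the
MSMS ``.vert`` layout, and decides which residues of a chain lie on the
molecular surface.  A chain is reduced to its surface residues, each
represented by its one-letter residue type and its C-alpha coordinate; that
reduced form (:class:`SurfaceChain`) is the input to the patch descriptor.

Two surface-selection routes are provided:

* :func:`select_surface_residues` consumes a dot surface produced by an
  external Connolly-surface program (MSMS-style vertex file).  A residue is
  a surface residue iff it owns at least one surface vertex, where each
  vertex is owned by the atom nearest to it.
* :func:`sasa_surface_fallback` needs no external program: it computes
  per-residue solvent-accessible surface area with a Shrake-Rupley sphere
  sampling and keeps residues whose relative SASA exceeds a threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

logger = logging.getLogger("surfpatch")

#: Canonical one-letter amino-acid alphabet, alphabetical order.  All
#: descriptor blocks are laid out in this order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Nonstandard residues folded into the 20-letter alphabet; anything else
# (ligands, waters, sugars) is discarded.
NONSTANDARD_MAP = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS"}

#: Default solvent probe radius in Angstrom.
DEFAULT_PROBE_RADIUS = 1.4

# Van der Waals radii by element (Angstrom); fallback 1.8 for unknowns.
_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

# Maximum accessible surface area per residue type (Angstrom^2), theoretical
# values of Tien et al.; used to turn absolute SASA into relative SASA.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


class PDBFormatError(ValueError):
    """Raised when a structure or vertex file cannot be interpreted."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of a residue, already altloc-resolved."""

    name: str
    coord: np.ndarray  # shape (3,), Angstrom
    element: str = "C"

    @property
    def vdw_radius(self) -> float:
        return _VDW_RADII.get(self.element.upper(), 1.8)


@dataclass
class ResidueAtoms:
    """A residue with all its (altloc-resolved) atoms, pre surface selection."""

    chain_id: str
    residue_seq: int
    residue_type: str  # one-letter code
    atoms: list[AtomRecord]

    @property
    def ca_coord(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return a.coord
        return None


@dataclass(frozen=True)
class Residue:
    """A surface residue: one-letter type plus C-alpha position."""

    chain_id: str
    residue_seq: int
    residue_type: str
    ca_coord: np.ndarray
    is_surface: bool = True

    def __post_init__(self):
        if self.residue_type not in AA_INDEX:
            raise ValueError(f"unknown residue type {self.residue_type!r}")
        if not np.all(np.isfinite(self.ca_coord)):
            raise ValueError("non-finite C-alpha coordinate")


@dataclass
class SurfaceChain:
    """One protein chain reduced to its surface residues.

    Residues are kept in source residue-number order, which makes the
    serialized form deterministic.
    """

    structure_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of C-alpha coordinates."""
        if not self.residues:
            return np.empty((0, 3))
        return np.vstack([r.ca_coord for r in self.residues])

    @property
    def types(self) -> list[str]:
        return [r.residue_type for r in self.residues]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("structure_id\tchain_id\tresidue_seq\tresidue_type\tx\ty\tz\n")
            for r in self.residues:
                x, y, z = r.ca_coord
                fh.write(
                    f"{self.structure_id}\t{self.chain_id}\t{r.residue_seq}"
                    f"\t{r.residue_type}\t{x:.3f}\t{y:.3f}\t{z:.3f}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SurfaceChain":
        residues = []
        structure_id = chain_id = None
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("structure_id"):
                raise PDBFormatError(f"not a SurfaceChain TSV: {path}")
            for line in fh:
                sid, cid, seq, typ, x, y, z = line.rstrip("\n").split("\t")
                structure_id, chain_id = sid, cid
                residues.append(
                    Residue(cid, int(seq), typ, np.array([float(x), float(y), float(z)]))
                )
        if structure_id is None:
            raise PDBFormatError(f"empty SurfaceChain TSV: {path}")
        return cls(structure_id, chain_id, residues)


@dataclass
class SurfaceVertexSet:
    """A dot-surface sampling: vertex coordinates, optional unit normals,
    and the 1-based index of each vertex's nearest atom when the surface
    program recorded it."""

    vertices: np.ndarray  # (m, 3)
    normals: np.ndarray | None = None
    nearest_atom_index: np.ndarray | None = None  # 1-based
    probe_radius: float = DEFAULT_PROBE_RADIUS

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-3):
                raise ValueError("surface normals are not unit length")

    def __len__(self) -> int:
        return len(self.vertices)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _resolve_residue_name(resname: str) -> str | None:
    """Map a 3-letter residue name to the 20-letter alphabet, or None."""
    resname = resname.strip().upper()
    resname = NONSTANDARD_MAP.get(resname, resname)
    return THREE_TO_ONE.get(resname)


def _pick_altloc(children) -> object:
    # Highest occupancy wins; ties broken by lexicographically first altloc.
    def key(atom):
        occ = atom.get_occupancy()
        occ = 0.0 if occ is None else occ
        return (-occ, atom.get_altloc())

    return sorted(children, key=key)[0]


def read_pdb_chains(
    path: str | Path, model_policy: str = "first"
) -> list[tuple[str, list[ResidueAtoms]]]:
    """Read a PDB file into per-chain residue lists.

    Only the first model of a multi-model file is used.  Waters and hetero
    records are ignored except for nonstandard residues that map back into
    the canonical alphabet (e.g. selenomethionine).  Alternate locations
    are resolved to the highest-occupancy conformer (ties: lexicographically
    first altloc code).  Residues with no C-alpha atom are dropped with a
    logged warning.

    Parameters
    ----------
    path
        PDB file with at least one ATOM record.
    model_policy
        Only ``"first"`` is supported: read model 1 and ignore the rest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    if model_policy != "first":
        raise ValueError(f"unsupported model_policy {model_policy!r}")

    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))

    models = list(structure)
    if not models:
        raise PDBFormatError(f"no parsable ATOM records in {path}")
    model = models[0]

    chains: list[tuple[str, list[ResidueAtoms]]] = []
    n_residues = 0
    for chain in model:
        residues: list[ResidueAtoms] = []
        for res in chain:
            hetflag, resseq, _icode = res.get_id()
            one = _resolve_residue_name(res.get_resname())
            if one is None:
                continue  # water, ligand, or unmappable nonstandard residue
            atoms = []
            for atom in res.get_list():
                if atom.is_disordered():
                    atom = _pick_altloc(atom.disordered_get_list())
                # PDB coordinates carry exactly 3 decimals; rounding undoes
                # the parser's float32 storage losslessly.
                coord = np.round(np.asarray(atom.get_coord(), dtype=float), 3)
                atoms.append(
                    AtomRecord(
                        name=atom.get_name().strip(),
                        coord=coord,
                        element=(atom.element or "C").strip() or "C",
                    )
                )
            ra = ResidueAtoms(chain.id, resseq, one, atoms)
            if ra.ca_coord is None:
                logger.warning(
                    "dropping residue %s%s %s: no C-alpha atom",
                    chain.id, resseq, res.get_resname(),
                )
                continue
            residues.append(ra)
            n_residues += 1
        if residues:
            chains.append((chain.id, residues))

    if n_residues == 0:
        raise PDBFormatError(f"no parsable ATOM records in {path}")
    return chains


# ---------------------------------------------------------------------------
# MSMS vertex files
# ---------------------------------------------------------------------------

def read_msms_vertices(path: str | Path) -> SurfaceVertexSet:
    """Read an MSMS-style ``.vert`` dot-surface file.

    Layout: three header lines (the third declares the vertex count),
    then one vertex per line — x y z nx ny nz followed by integer fields
    whose second entry is the 1-based index of the closest atom sphere.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such vertex file: {path}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise PDBFormatError(f"truncated vertex file (no header): {path}")
    header_fields = lines[2].split()
    try:
        declared = int(header_fields[0])
    except (IndexError, ValueError) as exc:
        raise PDBFormatError(f"bad vertex-count header in {path}") from exc
    if declared <= 0:
        raise PDBFormatError(f"vertex file declares an empty surface: {path}")

    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != declared:
        raise PDBFormatError(
            f"vertex count mismatch in {path}: header says {declared}, "
            f"body has {len(body)} lines"
        )

    verts = np.empty((declared, 3))
    normals = np.empty((declared, 3))
    nearest = np.empty(declared, dtype=int)
    have_nearest = True
    for i, ln in enumerate(body):
        fields = ln.split()
        try:
            values = [float(f) for f in fields[:6]]
        except ValueError as exc:
            raise PDBFormatError(
                f"non-numeric vertex coordinate at line {i + 4} of {path}"
            ) from exc
        if len(values) < 6:
            raise PDBFormatError(
                f"short vertex line at line {i + 4} of {path}"
            )
        verts[i] = values[:3]
        normals[i] = values[3:6]
        if len(fields) >= 8:
            try:
                nearest[i] = int(fields[7])
            except ValueError as exc:
                raise PDBFormatError(
                    f"bad atom index at line {i + 4} of {path}"
                ) from exc
        else:
            have_nearest = False

    return SurfaceVertexSet(
        vertices=verts,
        normals=normals,
        nearest_atom_index=nearest if have_nearest else None,
    )


# ---------------------------------------------------------------------------
# Surface selection: vertex ownership
# ---------------------------------------------------------------------------

def select_surface_residues(
    chain: list[ResidueAtoms],
    vertices: SurfaceVertexSet,
    structure_id: str = "",
    chain_id: str | None = None,
) -> SurfaceChain:
    """Mark residues that own at least one surface vertex.

    Each vertex is owned by the atom nearest to it: the vertex file's
    nearest-atom index is used when present (atom numbering follows the
    flattened residue/atom order of ``chain``), otherwise a nearest-neighbor
    search over all chain atoms decides ownership.  The output keeps only
    surface residues, each reduced to residue type plus C-alpha coordinate.
    """
    if not chain:
        raise ValueError("empty chain")
    if len(vertices) == 0:
        raise ValueError("empty vertex set")

    # Flatten atoms; remember which residue each atom belongs to.
    atom_coords = []
    atom_residue = []
    for ri, res in enumerate(chain):
        for atom in res.atoms:
            atom_coords.append(atom.coord)
            atom_residue.append(ri)
    atom_coords = np.asarray(atom_coords)
    atom_residue = np.asarray(atom_residue)

    if vertices.nearest_atom_index is not None:
        owners = np.asarray(vertices.nearest_atom_index) - 1  # to 0-based
        if owners.min() < 0 or owners.max() >= len(atom_coords):
            raise ValueError(
                "vertex nearest-atom index out of range for this chain"
            )
    else:
        tree = cKDTree(atom_coords)
        _, owners = tree.query(vertices.vertices)

    surface_mask = np.zeros(len(chain), dtype=bool)
    surface_mask[atom_residue[owners]] = True

    cid = chain_id if chain_id is not None else chain[0].chain_id
    residues = [
        Residue(cid, res.residue_seq, res.residue_type, res.ca_coord)
        for ri, res in enumerate(chain)
        if surface_mask[ri] and res.ca_coord is not None
    ]
    if not residues:
        raise ValueError(
            f"no surface residues for chain {cid}: surface/structure mismatch?"
        )
    return SurfaceChain(structure_id, cid, residues)


# ---------------------------------------------------------------------------
# Surface selection: SASA fallback
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_SPHERE_POINTS = _fibonacci_sphere(960)


def shrake_rupley_sasa(
    chain: list[ResidueAtoms], probe_radius: float = DEFAULT_PROBE_RADIUS
) -> np.ndarray:
    """Per-residue solvent-accessible surface area (Angstrom^2).

    Shrake-Rupley sphere sampling with a fixed 960-point lattice per atom:
    a sample point on an atom's solvent-expanded sphere is accessible iff it
    lies outside every other atom's expanded sphere.
    """
    coords, radii, owner = [], [], []
    for ri, res in enumerate(chain):
        for atom in res.atoms:
            coords.append(atom.coord)
            radii.append(atom.vdw_radius + probe_radius)
            owner.append(ri)
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    owner = np.asarray(owner)

    tree = cKDTree(coords)
    sasa = np.zeros(len(chain))
    for ai in range(len(coords)):
        r = radii[ai]
        pts = coords[ai] + r * _SPHERE_POINTS
        neighbors = [
            j for j in tree.query_ball_point(coords[ai], r + radii.max())
            if j != ai
            and np.linalg.norm(coords[j] - coords[ai]) < r + radii[j]
        ]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            accessible &= (
                np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            )
        frac = accessible.mean()
        sasa[owner[ai]] += frac * 4.0 * math.pi * r * r
    return sasa


def sasa_surface_fallback(
    chain: list[ResidueAtoms],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    rel_threshold: float = 0.05,
    structure_id: str = "",
    chain_id: str | None = None,
) -> SurfaceChain:
    """Surface selection without a dot-surface file.

    A residue is a surface residue iff its relative SASA — absolute SASA
    divided by the residue type's maximum accessible area — reaches
    ``rel_threshold``.  Deterministic: the sphere sampling uses a fixed
    960-point lattice.
    """
    if not chain:
        raise ValueError("empty chain")
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")

    usable = []
    for res in chain:
        if res.residue_type not in MAX_SASA:
            logger.warning(
                "skipping residue %s%s: unknown type %r",
                res.chain_id, res.residue_seq, res.residue_type,
            )
            continue
        usable.append(res)

    sasa = shrake_rupley_sasa(usable, probe_radius)
    cid = chain_id if chain_id is not None else chain[0].chain_id
    residues = [
        Residue(cid, res.residue_seq, res.residue_type, res.ca_coord)
        for res, area in zip(usable, sasa)
        if area / MAX_SASA[res.residue_type] >= rel_threshold
        and res.ca_coord is not None
    ]
    if not residues:
        raise ValueError(f"no surface residues for chain {cid}")
    return SurfaceChain(structure_id, cid, residues)
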