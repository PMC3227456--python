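"""Synthetic labeled protein surfaces for testing and benchmarking.

Real benchmark sets for this method are families of PDB chains with their
Connolly surfaces; those require downloads and an external surface program.
This module generates stand-ins: labeled point clouds of residues placed on
a jittered spherical shell, so that every residue is a surface residue by
construction and the descriptor pipeline can be exercised end to end.

A :class:`FamilySpec` controls what makes a family recognizable:

* ``composition`` — the residue-type frequencies (a length-20 probability
  vector over the alphabetical amino-acid order);
* ``cooccurrence_boost`` — ordered residue-type pairs that are
  preferentially placed within patch range of each other, which plants a
  signal in the co-occurrence (RC/DRC) statistics specifically;
* geometry — shell radius, positional jitter and a residue-count range,
  shared across families so the pooled distance distribution (DD1) carries
  little family signal, mirroring the finding that co-occurrence is the
  discriminative component.

Chains can be written out as minimally valid single-CA PDB files with
matching MSMS-style vertex files, so the reading and surface-selection code
paths are testable without any downloaded structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import (
    ALPHABET,
    DEFAULT_PROBE_RADIUS,
    ONE_TO_THREE,
    Residue,
    SurfaceChain,
)

RNGLike = int | np.random.Generator | np.random.SeedSequence


def _rng(seed: RNGLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FamilySpec:
    """Recipe for one synthetic protein family."""

    name: str
    composition: np.ndarray  # (20,) probabilities, alphabetical order
    cooccurrence_boost: dict[tuple[str, str], float] = field(default_factory=dict)
    size_range: tuple[int, int] = (60, 90)
    radius: float = 16.0  # Angstrom, spherical shell
    jitter: float = 1.2  # Angstrom, isotropic Gaussian noise
    tau_p: float = 10.0  # patch range the boost targets
    #: Distance band (Angstrom) at which boosted partners are placed.
    boost_distance_range: tuple[float, float] = (2.0, 7.0)
    #: Residue types that congregate in a spherical-cap patch on the shell,
    #: emulating the chemically biased surface patches of real families
    #: (hydrophobic cores, charged interfaces).  Clustering shifts the
    #: distance distribution *conditioned on those central types* (DD2)
    #: strongly, while the pooled distribution (DD1) only sees it diluted
    #: by the squared fraction of clustered residues.
    cluster_types: str = ""
    cluster_prob: float = 0.8  # chance a cluster-type residue joins the cap
    cluster_spread: float = 0.2  # angular std dev (radians) of the cap

    def __post_init__(self):
        self.composition = np.asarray(self.composition, dtype=float)
        if self.composition.shape != (20,) or abs(self.composition.sum() - 1) > 1e-9:
            raise ValueError("composition must be a length-20 probability vector")
        if self.size_range[0] > self.size_range[1] or self.size_range[0] < 1:
            raise ValueError(f"bad size_range {self.size_range}")
        if not self.radius > self.jitter >= 0:
            raise ValueError("need radius > jitter >= 0")
        for (t1, t2), strength in self.cooccurrence_boost.items():
            if t1 not in ALPHABET or t2 not in ALPHABET or strength < 1:
                raise ValueError(f"bad boost ({t1},{t2}) strength {strength}")


def _tilted_composition(signature: str, factor: float = 4.0) -> np.ndarray:
    """Uniform composition with the signature residues upweighted."""
    w = np.ones(20)
    for aa in signature:
        w[ALPHABET.index(aa)] *= factor
    return w / w.sum()


def default_family_specs() -> list[FamilySpec]:
    """Three families differing in composition and co-occurrence structure
    but sharing geometry — the default benchmark conditions."""
    return [
        FamilySpec("glyrich", _tilted_composition("GAS"),
                   cooccurrence_boost={("G", "A"): 4.0},
                   boost_distance_range=(2.0, 5.0),
                   cluster_types="GAS"),
        FamilySpec("charged", _tilted_composition("KED"),
                   cooccurrence_boost={("K", "E"): 4.0},
                   boost_distance_range=(4.0, 7.0),
                   cluster_types="KED"),
        FamilySpec("aromatic", _tilted_composition("WFY"),
                   cooccurrence_boost={("W", "F"): 4.0},
                   boost_distance_range=(6.0, 9.0),
                   cluster_types="WFY"),
    ]


# ---------------------------------------------------------------------------
# Chain sampling
# ---------------------------------------------------------------------------

def _shell_point(rng: np.random.Generator, radius: float, jitter: float) -> np.ndarray:
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    return d * radius + rng.normal(scale=jitter, size=3) if jitter > 0 else d * radius


def sample_chain(
    spec: FamilySpec, seed: RNGLike, structure_id: str = "SYN0", chain_id: str = "A"
) -> SurfaceChain:
    """Draw one labeled synthetic surface chain.

    Residue count is uniform over ``size_range``; positions sit on the
    spherical shell with Gaussian jitter; types follow ``composition``.
    For each boosted pair (T1, T2) with strength s, each T1 residue with
    probability min(0.9, 0.2*(s-1)) gains a T2 partner placed within patch
    range.  Coordinates are rounded to 0.001 Angstrom so chains survive a
    PDB round-trip bit-for-bit.  Fully reproducible from the seed.
    """
    rng = _rng(seed)
    n = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
    types = list(rng.choice(list(ALPHABET), size=n, p=spec.composition))

    cap_dir = rng.normal(size=3)
    cap_dir /= np.linalg.norm(cap_dir)
    positions = []
    for typ in types:
        if typ in spec.cluster_types and rng.random() < spec.cluster_prob:
            d = cap_dir + rng.normal(scale=spec.cluster_spread, size=3)
            d /= np.linalg.norm(d)
            pos = d * spec.radius + rng.normal(scale=spec.jitter, size=3)
        else:
            pos = _shell_point(rng, spec.radius, spec.jitter)
        positions.append(pos)

    for (t1, t2), strength in sorted(spec.cooccurrence_boost.items()):
        p = min(0.9, 0.2 * (strength - 1.0))
        for i in range(n):
            if types[i] == t1 and rng.random() < p:
                # partner within patch range: step along the shell, rescale
                step = rng.normal(size=3)
                lo, hi = spec.boost_distance_range
                step *= rng.uniform(lo, hi) / np.linalg.norm(step)
                partner = positions[i] + step
                partner *= spec.radius / np.linalg.norm(partner)
                partner += rng.normal(scale=spec.jitter, size=3)
                positions.append(partner)
                types.append(t2)

    residues = [
        Residue(chain_id, seq, typ, np.round(pos, 3))
        for seq, (typ, pos) in enumerate(zip(types, positions), start=1)
    ]
    return SurfaceChain(structure_id, chain_id, residues)


def generate_family_dataset(
    specs: list[FamilySpec], chains_per_family: int, seed: int
) -> tuple[list[SurfaceChain], dict[tuple[str, str], str]]:
    """Labeled chains for a multi-family benchmark, deterministic per seed.

    Returns the chains and a {(structure_id, chain_id): family name} map
    ready for database building and evaluation.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 family specs")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * chains_per_family)
    chains: list[SurfaceChain] = []
    labels: dict[tuple[str, str], str] = {}
    k = 0
    for fi, spec in enumerate(specs):
        for ci in range(chains_per_family):
            sid = f"F{fi}C{ci:03d}"
            chain = sample_chain(spec, children[k], structure_id=sid)
            chains.append(chain)
            labels[(sid, chain.chain_id)] = spec.name
            k += 1
    return chains, labels


# ---------------------------------------------------------------------------
# Toy file writers
# ---------------------------------------------------------------------------

def write_toy_pdb(chain: SurfaceChain, path: str | Path) -> None:
    """Write a minimally valid PDB: one CA ATOM line per residue, fixed
    columns per the PDB format, terminated by TER/END."""
    lines = []
    for serial, r in enumerate(chain.residues, start=1):
        res3 = ONE_TO_THREE[r.residue_type]
        x, y, z = r.ca_coord
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3:<3s} {chain.chain_id:1s}"
            f"{r.residue_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_toy_vert(
    chain: SurfaceChain,
    path: str | Path,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    offset: float = 3.1,
) -> None:
    """Write a matching MSMS-style vertex file.

    One vertex per residue, pushed radially outward from the chain centroid
    by ``offset`` Angstrom (roughly a carbon van der Waals radius plus the
    probe), with the correct 1-based nearest-atom index — so surface
    selection by vertex ownership marks every residue as surface.
    """
    coords = chain.coords
    centroid = coords.mean(axis=0)
    lines = [
        "# toy dot surface",
        "#faces  0",
        f"{len(chain):5d} {len(chain):5d}  1.00 {probe_radius:5.2f}",
    ]
    for i, c in enumerate(coords):
        d = c - centroid
        norm = np.linalg.norm(d)
        u = d / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        v = c + u * offset
        lines.append(
            f"{v[0]:9.3f} {v[1]:9.3f} {v[2]:9.3f} "
            f"{u[0]:9.3f} {u[1]:9.3f} {u[2]:9.3f} "
            f"{0:7d} {i + 1:7d} {1:2d}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
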