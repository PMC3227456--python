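"""Surface patches and the invariant descriptor.

A *patch* is the set of surface residues whose C-alpha lies within a
distance threshold tau_p of a chosen central residue's C-alpha.  Every
surface residue centers exactly one patch, so a chain with n surface
residues yields n local descriptors.

The *local descriptor* of a patch is a (20+1) x (b+1) matrix D_A: 20 rows
for the residue types of the patch members, b columns for uniform distance
bins over (0, tau_p].  The extra row (sum C) is the column marginal — the
patch's distance distribution; the extra column (sum R) is the row
marginal — the patch's residue co-occurrence counts.

The *global descriptor* averages, per central residue type, the normalized
sum C and sum R vectors over all patches centered on that type.  Four flat
vector views are derived from it:

* DD1  (length b)        pooled distance distribution, central type ignored
* DD2  (length 20*b)     Pr{d | R_c}: the 20 mean sum C blocks
* RC   (length 400)      Pr{R_i | R_c}: the 20 mean sum R blocks
* DRC  (length 20*(b+20)) per type, sum C block followed by sum R block

All four are invariant to rotation, translation, mirroring and residue
input order, and their lengths do not depend on chain size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AA_INDEX, ALPHABET, SurfaceChain

#: Defaults for patch radius (Angstrom) and distance-bin count.
DEFAULT_TAU_P = 10.0
DEFAULT_BINS = 5

N_TYPES = 20

#: How per-patch statistics are combined into a global block: "per_patch"
#: normalizes each patch's marginals to probability vectors before
#: averaging; "pooled" sums raw counts over patches and normalizes once.
POOLING_MODES = ("per_patch", "pooled")


# ---------------------------------------------------------------------------
# Patches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchMember:
    index: int
    residue_type: str
    distance: float


@dataclass
class Patch:
    """One circular surface patch: a central residue and its neighbors.

    Members exclude the center itself and are sorted by (distance, index),
    each with its Euclidean C-alpha distance d to the center, 0 < d <= tau_p.
    """

    center_index: int
    center_type: str
    members: list[PatchMember]
    tau_p: float = DEFAULT_TAU_P

    def __len__(self) -> int:
        return len(self.members)


def build_patches(chain: SurfaceChain, tau_p: float = DEFAULT_TAU_P) -> list[Patch]:
    """One patch per surface residue, membership by C-alpha distance <= tau_p.

    A center with no neighbor inside tau_p yields an empty patch; empty
    patches are kept (they contribute nothing to the distributions).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    if tau_p <= 0:
        raise ValueError("tau_p must be positive")

    coords = chain.coords
    types = chain.types
    dists = cdist(coords, coords)
    patches = []
    for c in range(len(chain)):
        members = [
            PatchMember(i, types[i], float(dists[c, i]))
            for i in range(len(chain))
            if i != c and dists[c, i] <= tau_p
        ]
        members.sort(key=lambda m: (m.distance, m.index))
        patches.append(Patch(c, types[c], members, tau_p))
    return patches


# ---------------------------------------------------------------------------
# Local descriptor
# ---------------------------------------------------------------------------

@dataclass
class LocalDescriptor:
    """The count matrix of one patch plus its two marginals.

    ``counts[i, j]`` is the number of patch members of residue type i
    (alphabetical index) at a center distance in bin j.  Bin j (0-based)
    covers [j*tau_p/b, (j+1)*tau_p/b), except the last bin which is closed
    at tau_p.
    """

    center_type: str
    counts: np.ndarray  # (20, b) integer
    b: int
    tau_p: float

    @property
    def sum_c(self) -> np.ndarray:
        """Distance-distribution marginal (length b): counts summed over types."""
        return self.counts.sum(axis=0)

    @property
    def sum_r(self) -> np.ndarray:
        """Co-occurrence marginal (length 20): counts summed over bins."""
        return self.counts.sum(axis=1)

    @property
    def n_members(self) -> int:
        return int(self.counts.sum())


def local_descriptor(patch: Patch, b: int = DEFAULT_BINS) -> LocalDescriptor:
    """Bin the patch members into the (20 x b) count matrix."""
    if b < 1:
        raise ValueError("bin count must be >= 1")
    counts = np.zeros((N_TYPES, b), dtype=np.int64)
    width = patch.tau_p / b
    for m in patch.members:
        if not 0 < m.distance <= patch.tau_p:
            raise ValueError(
                f"patch member distance {m.distance} outside (0, {patch.tau_p}]"
            )
        j = min(int(m.distance / width), b - 1)  # closed last bin
        counts[AA_INDEX[m.residue_type], j] += 1
    return LocalDescriptor(patch.center_type, counts, b, patch.tau_p)


# ---------------------------------------------------------------------------
# Global descriptor
# ---------------------------------------------------------------------------

@dataclass
class GlobalBlock:
    mean_sum_c: np.ndarray  # (b,) probability vector or zeros
    mean_sum_r: np.ndarray  # (20,) probability vector or zeros
    patch_count: int  # non-empty patches averaged


@dataclass
class GlobalDescriptor:
    """Per-central-type averaged patch statistics for one chain.

    ``blocks`` maps each of the 20 residue letters to its averaged distance
    distribution (length b) and co-occurrence distribution (length 20); a
    type never observed as a (non-empty) patch center carries zero vectors.
    """

    blocks: dict[str, GlobalBlock]
    b: int
    tau_p: float
    skipped_empty: int = 0

    def vector(self, scheme: str) -> np.ndarray:
        scheme = scheme.lower()
        if scheme == "dd2":
            return dd2_vector(self)
        if scheme == "rc":
            return rc_vector(self)
        if scheme == "drc":
            return drc_vector(self)
        raise ValueError(f"unknown scheme {scheme!r} (dd1 needs the local descriptors)")


def _normalize(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    return v / total if total > 0 else v.astype(float)


def global_descriptor(
    locals_: list[LocalDescriptor],
    b: int = DEFAULT_BINS,
    tau_p: float = DEFAULT_TAU_P,
    pooling: str = "per_patch",
) -> GlobalDescriptor:
    """Average local descriptors per central residue type.

    Empty patches are skipped (their marginals have no normalization).  With
    ``pooling="per_patch"`` (default) each non-empty patch's marginals are
    normalized to probability vectors first, then averaged, so every patch
    contributes equally; ``"pooled"`` sums raw counts per type and
    normalizes once, weighting patches by member count.
    """
    if pooling not in POOLING_MODES:
        raise ValueError(f"pooling must be one of {POOLING_MODES}")
    for ld in locals_:
        if ld.b != b or ld.tau_p != tau_p:
            raise ValueError("local descriptors disagree on b or tau_p")

    by_type: dict[str, list[LocalDescriptor]] = {aa: [] for aa in ALPHABET}
    skipped = 0
    for ld in locals_:
        if ld.n_members == 0:
            skipped += 1
            continue
        by_type[ld.center_type].append(ld)

    blocks = {}
    for aa in ALPHABET:
        group = by_type[aa]
        if not group:
            blocks[aa] = GlobalBlock(np.zeros(b), np.zeros(N_TYPES), 0)
            continue
        if pooling == "per_patch":
            mean_c = np.mean([_normalize(ld.sum_c) for ld in group], axis=0)
            mean_r = np.mean([_normalize(ld.sum_r) for ld in group], axis=0)
        else:
            mean_c = _normalize(np.sum([ld.sum_c for ld in group], axis=0))
            mean_r = _normalize(np.sum([ld.sum_r for ld in group], axis=0))
        blocks[aa] = GlobalBlock(mean_c, mean_r, len(group))
    return GlobalDescriptor(blocks, b, tau_p, skipped_empty=skipped)


# ---------------------------------------------------------------------------
# Flat vector views
# ---------------------------------------------------------------------------

def dd2_vector(g: GlobalDescriptor) -> np.ndarray:
    """Concatenate the 20 mean distance-distribution blocks (length 20*b)."""
    return np.concatenate([g.blocks[aa].mean_sum_c for aa in ALPHABET])


def rc_vector(g: GlobalDescriptor) -> np.ndarray:
    """Concatenate the 20 mean co-occurrence blocks (length 400)."""
    return np.concatenate([g.blocks[aa].mean_sum_r for aa in ALPHABET])


def drc_vector(g: GlobalDescriptor) -> np.ndarray:
    """Per type, distance block then co-occurrence block (length 20*(b+20))."""
    parts = []
    for aa in ALPHABET:
        parts.append(g.blocks[aa].mean_sum_c)
        parts.append(g.blocks[aa].mean_sum_r)
    return np.concatenate(parts)


def dd1_vector(locals_: list[LocalDescriptor]) -> np.ndarray:
    """Pooled distance distribution with the central type ignored (length b).

    The baseline descriptor: average of the normalized sum C vectors over
    all non-empty patches regardless of central residue type.
    """
    if not locals_:
        raise ValueError("no local descriptors")
    b = locals_[0].b
    rows = [_normalize(ld.sum_c) for ld in locals_ if ld.n_members > 0]
    if not rows:
        return np.zeros(b)
    return np.mean(rows, axis=0)


def vector_length(scheme: str, b: int = DEFAULT_BINS) -> int:
    """Fixed dimensionality of each descriptor view (chain-size independent)."""
    return {
        "dd1": b,
        "dd2": N_TYPES * b,
        "rc": N_TYPES * N_TYPES,
        "drc": N_TYPES * (b + N_TYPES),
    }[scheme.lower()]


def coordinate_names(scheme: str, b: int = DEFAULT_BINS) -> list[str]:
    """Header names for the flat TSV export, one per vector coordinate."""
    scheme = scheme.lower()
    if scheme == "dd1":
        return [f"bin{j + 1}" for j in range(b)]
    names = []
    for aa in ALPHABET:
        bins = [f"{aa}_bin{j + 1}" for j in range(b)]
        coocs = [f"{aa}_cooc_{other}" for other in ALPHABET]
        if scheme == "dd2":
            names += bins
        elif scheme == "rc":
            names += coocs
        elif scheme == "drc":
            names += bins + coocs
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return names


# ---------------------------------------------------------------------------
# Convenience pipeline + export
# ---------------------------------------------------------------------------

def describe_chain(
    chain: SurfaceChain,
    tau_p: float = DEFAULT_TAU_P,
    b: int = DEFAULT_BINS,
    pooling: str = "per_patch",
) -> tuple[GlobalDescriptor, list[LocalDescriptor]]:
    """Full descriptor pipeline for one surface chain."""
    patches = build_patches(chain, tau_p)
    locals_ = [local_descriptor(p, b) for p in patches]
    return global_descriptor(locals_, b, tau_p, pooling), locals_


def chain_vector(
    chain: SurfaceChain,
    scheme: str,
    tau_p: float = DEFAULT_TAU_P,
    b: int = DEFAULT_BINS,
    pooling: str = "per_patch",
) -> np.ndarray:
    """Descriptor vector of one chain under the named scheme."""
    g, locals_ = describe_chain(chain, tau_p, b, pooling)
    if scheme.lower() == "dd1":
        return dd1_vector(locals_)
    return g.vector(scheme)


def descriptor_to_json(g: GlobalDescriptor, path: str | Path | None = None) -> str:
    payload = {
        "b": g.b,
        "tau_p": g.tau_p,
        "skipped_empty_patches": g.skipped_empty,
        "blocks": {
            aa: {
                "mean_sum_c": g.blocks[aa].mean_sum_c.tolist(),
                "mean_sum_r": g.blocks[aa].mean_sum_r.tolist(),
                "patch_count": g.blocks[aa].patch_count,
            }
            for aa in ALPHABET
        },
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def descriptor_from_json(path: str | Path) -> GlobalDescriptor:
    payload = json.loads(Path(path).read_text())
    blocks = {
        aa: GlobalBlock(
            np.asarray(blk["mean_sum_c"], dtype=float),
            np.asarray(blk["mean_sum_r"], dtype=float),
            int(blk["patch_count"]),
        )
        for aa, blk in payload["blocks"].items()
    }
    return GlobalDescriptor(
        blocks, int(payload["b"]), float(payload["tau_p"]),
        skipped_empty=int(payload.get("skipped_empty_patches", 0)),
    )


def vector_to_tsv(vector: np.ndarray, scheme: str, b: int, path: str | Path) -> None:
    names = coordinate_names(scheme, b)
    if len(names) != len(vector):
        raise ValueError(
            f"vector length {len(vector)} does not match scheme {scheme} at b={b}"
        )
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        fh.write("\t".join(f"{x:.10g}" for x in vector) + "\n")
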