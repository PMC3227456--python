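"""Descriptor matching, database ranking and retrieval evaluation.

Chains are compared by the Euclidean distance between their flat descriptor
vectors; a query against a database yields a full ranking (rank 1 = most
similar).  Retrieval quality is scored with the enrichment factor
N_obs/N_exp at a screening fraction, and with precision/recall where the
number of true matches expected at rank r is min{r, query group size}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np

from . import patch_descriptor as pd_mod
from .patch_descriptor import DEFAULT_BINS, DEFAULT_TAU_P, vector_length
from .structure_io import SurfaceChain

SCHEMES = ("dd1", "dd2", "rc", "drc")


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------

def euclidean_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """Plain Euclidean distance between two descriptor vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(
            f"descriptor length mismatch: {v1.shape[0]} vs {v2.shape[0]}"
        )
    return float(np.sqrt(np.sum((v1 - v2) ** 2)))


# ---------------------------------------------------------------------------
# Database
# ---------------------------------------------------------------------------

@dataclass
class DatabaseEntry:
    structure_id: str
    chain_id: str
    group: str | None
    vector: np.ndarray

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure_id, self.chain_id)


@dataclass
class DescriptorDatabase:
    """A set of chains under one descriptor scheme, ready for screening."""

    scheme: str
    b: int = DEFAULT_BINS
    tau_p: float = DEFAULT_TAU_P
    entries: list[DatabaseEntry] = field(default_factory=list)

    def __post_init__(self):
        self.scheme = self.scheme.lower()
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def expected_length(self) -> int:
        return vector_length(self.scheme, self.b)

    def add(self, structure_id: str, chain_id: str,
            vector: np.ndarray, group: str | None = None) -> None:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.expected_length,):
            raise ValueError(
                f"vector length {vector.shape[0]} does not match scheme "
                f"{self.scheme} at b={self.b} (expected {self.expected_length})"
            )
        key = (structure_id, chain_id)
        if any(e.key == key for e in self.entries):
            raise ValueError(f"duplicate database entry {key}")
        self.entries.append(DatabaseEntry(structure_id, chain_id, group, vector))

    @property
    def labels(self) -> dict[tuple[str, str], str | None]:
        return {e.key: e.group for e in self.entries}

    def group_size(self, group: str) -> int:
        return sum(1 for e in self.entries if e.group == group)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "b": self.b,
            "tau_p": self.tau_p,
            "count": len(self.entries),
            "entries": [
                {
                    "structure_id": e.structure_id,
                    "chain_id": e.chain_id,
                    "group": e.group,
                    "vector": e.vector.tolist(),
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorDatabase":
        payload = json.loads(Path(path).read_text())
        db = cls(payload["scheme"], int(payload["b"]), float(payload["tau_p"]))
        for e in payload["entries"]:
            db.add(e["structure_id"], e["chain_id"],
                   np.asarray(e["vector"], dtype=float), e.get("group"))
        if len(db) != payload.get("count", len(db)):
            raise ValueError(f"entry count mismatch in {path}")
        return db


def build_database(
    chains: list[SurfaceChain],
    scheme: str,
    groups: dict[tuple[str, str], str] | None = None,
    b: int = DEFAULT_BINS,
    tau_p: float = DEFAULT_TAU_P,
    pooling: str = "per_patch",
) -> DescriptorDatabase:
    """Compute one descriptor per chain and assemble the database."""
    db = DescriptorDatabase(scheme, b, tau_p)
    for chain in chains:
        vec = pd_mod.chain_vector(chain, scheme, tau_p, b, pooling)
        group = None
        if groups is not None:
            group = groups.get((chain.structure_id, chain.chain_id))
        db.add(chain.structure_id, chain.chain_id, vec, group)
    return db


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedHit:
    structure_id: str
    chain_id: str
    distance: float
    rank: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure_id, self.chain_id)


@dataclass
class RankedList:
    query_id: str
    hits: list[RankedHit]

    def __len__(self) -> int:
        return len(self.hits)

    def rank_of(self, structure_id: str, chain_id: str) -> int:
        for h in self.hits:
            if h.key == (structure_id, chain_id):
                return h.rank
        raise KeyError((structure_id, chain_id))

    def to_tsv(self, path: str | Path,
               annotations: dict[tuple[str, str], str] | None = None,
               header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(header if header.endswith("\n") else header + "\n")
            fh.write("structure_id\tchain\trank\tdistance\tannotation\n")
            for h in self.hits:
                ann = (annotations or {}).get(h.key, "")
                fh.write(
                    f"{h.structure_id}\t{h.chain_id}\t{h.rank}"
                    f"\t{h.distance:.6g}\t{ann}\n"
                )


def rank_database(
    query_vector: np.ndarray, db: DescriptorDatabase, query_id: str = "query"
) -> RankedList:
    """Rank all database chains by ascending descriptor distance.

    Stable sort on (distance, structure_id, chain_id); a chain identical to
    the query (the self-hit) therefore sits at rank 1 with distance 0.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    query_vector = np.asarray(query_vector, dtype=float)
    scored = [
        (euclidean_distance(query_vector, e.vector), e.structure_id, e.chain_id)
        for e in db.entries
    ]
    scored.sort()
    hits = [
        RankedHit(sid, cid, dist, rank)
        for rank, (dist, sid, cid) in enumerate(scored, start=1)
    ]
    return RankedList(query_id, hits)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class RetrievalEval:
    enrichment: list[tuple[float, float]]  # (screen fraction, EF)
    pr_points: list[tuple[float, float]]  # (recall, precision), rank order
    auc: float


DEFAULT_FRACTIONS = (0.01, 0.02, 0.05, 0.10, 0.20, 0.50, 1.00)


def _group_members(labels: dict[tuple[str, str], str | None], group: str) -> set:
    members = {k for k, v in labels.items() if v == group}
    if not members:
        raise ValueError(f"query group {group!r} absent from labels")
    return members


def enrichment_curve(
    ranked: RankedList,
    labels: dict[tuple[str, str], str | None],
    query_group: str,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
) -> list[tuple[float, float]]:
    """Enrichment factor N_obs/N_exp at each screening fraction.

    At fraction f the top ceil(f*N) hits are retrieved; N_obs counts query-
    group members among them and N_exp is the count a random draw of the
    same size would yield on average.  EF decays to 1 at full screening.
    """
    members = _group_members(labels, query_group)
    n = len(ranked)
    group_size = len(members)
    points = []
    for f in fractions:
        k = ceil(f * n)
        k = max(1, min(k, n))
        n_obs = sum(1 for h in ranked.hits[:k] if h.key in members)
        n_exp = k * group_size / n
        points.append((f, n_obs / n_exp))
    return points


def precision_recall(
    ranked: RankedList,
    labels: dict[tuple[str, str], str | None],
    query_group: str,
    drop_self: bool = False,
) -> RetrievalEval:
    """Precision/recall over ranks, with recall denominator min{r, group size}.

    With ``drop_self`` the rank-1 hit (normally the query itself) is removed
    before scoring.  The area under the precision-recall curve is a
    trapezoid over recall-sorted points, with (recall 0, first precision)
    prepended.
    """
    members = _group_members(labels, query_group)
    hits = ranked.hits[1:] if drop_self else ranked.hits
    if not hits:
        raise ValueError("no hits to evaluate")
    group_size = len(members)
    if drop_self:
        group_size = max(1, group_size - 1)

    pr = []
    correct = 0
    for r, h in enumerate(hits, start=1):
        if h.key in members:
            correct += 1
        precision = correct / r
        recall = correct / min(r, group_size)
        pr.append((recall, precision))

    auc = pr_auc(pr)
    enr = enrichment_curve(ranked, labels, query_group)
    return RetrievalEval(enrichment=enr, pr_points=pr, auc=auc)


def pr_auc(pr_points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under a (recall, precision) point list."""
    pts = sorted(pr_points, key=lambda p: p[0])
    recalls = [0.0] + [p[0] for p in pts]
    precisions = [pts[0][1]] + [p[1] for p in pts]
    return float(np.trapezoid(precisions, recalls))


def average_precision_recall(
    evals: list[RetrievalEval],
) -> tuple[list[tuple[float, float]], float]:
    """Average PR curves of several queries pointwise by rank.

    All ranked lists must cover the same database size.  Returns the
    averaged (recall, precision) points and their trapezoidal AUC.
    """
    if not evals:
        raise ValueError("no evaluations to average")
    lengths = {len(e.pr_points) for e in evals}
    if len(lengths) != 1:
        raise ValueError(f"ranked lists of unequal length: {sorted(lengths)}")
    stacked = np.array([e.pr_points for e in evals])  # (q, r, 2)
    mean_pts = [(float(r), float(p)) for r, p in stacked.mean(axis=0)]
    return mean_pts, pr_auc(mean_pts)
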