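"""Optional full-scale benchmark on downloaded protein structures.

The published-scale evaluation needs a few hundred PDB chains from three
functional families (uracil-DNA glycosylase, estrogen receptor, cell
division protein kinase 2) plus their Connolly dot surfaces from an
external surface program (MSMS).  Neither ships with this repository, so
this script is for users who have fetched the data themselves.

Expected layout:

    <data_dir>/
        labels.tsv          structure_id <TAB> chain_id <TAB> family
        <structure_id>.pdb  one per structure
        <structure_id>.vert matching MSMS vertex file (optional; without
                            it the built-in SASA fallback is used)

It builds all four descriptor databases (DD1/DD2/RC/DRC at tau_p = 10 A,
b = 5), runs every chain as a retrieval query, averages precision-recall
per scheme, and checks the qualitative ordering the method predicts:

    AUC(DD1) < AUC(DD2) <= max(AUC(RC), AUC(DRC))

Usage:
    python scripts/real_data_screen.py <data_dir> [--queries-per-family N]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

from surfpatch import (
    read_msms_vertices,
    read_pdb_chains,
    sasa_surface_fallback,
    select_surface_residues,
)
from surfpatch.matching_retrieval import (
    average_precision_recall,
    build_database,
    precision_recall,
    rank_database,
)

SCHEMES = ("dd1", "dd2", "rc", "drc")


def load_labels(path: Path) -> dict[tuple[str, str], str]:
    labels = {}
    for line in path.read_text().splitlines():
        if line.startswith("#") or line.startswith("structure_id"):
            continue
        sid, cid, fam = line.split("\t")
        labels[(sid, cid)] = fam
    return labels


def load_chains(data_dir: Path, labels):
    chains = []
    wanted = {sid for sid, _cid in labels}
    for sid in sorted(wanted):
        pdb = data_dir / f"{sid}.pdb"
        if not pdb.exists():
            print(f"warning: missing {pdb}, skipping", file=sys.stderr)
            continue
        vert = data_dir / f"{sid}.vert"
        for cid, residues in read_pdb_chains(pdb):
            if (sid, cid) not in labels:
                continue
            if vert.exists():
                sc = select_surface_residues(
                    residues, read_msms_vertices(vert),
                    structure_id=sid, chain_id=cid,
                )
            else:
                sc = sasa_surface_fallback(
                    residues, structure_id=sid, chain_id=cid)
            chains.append(sc)
    return chains


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("data_dir", type=Path)
    ap.add_argument("--queries-per-family", type=int, default=3)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    labels = load_labels(args.data_dir / "labels.tsv")
    chains = load_chains(args.data_dir, labels)
    if len(chains) < 10:
        sys.exit("too few chains loaded; check the data directory layout")
    print(f"loaded {len(chains)} chains, "
          f"{len(set(labels.values()))} families")

    rng = np.random.default_rng(args.seed)
    aucs = {}
    for scheme in SCHEMES:
        db = build_database(chains, scheme, labels)
        evals = []
        for fam in sorted(set(labels.values())):
            members = [e for e in db.entries if e.group == fam]
            picks = rng.choice(
                len(members),
                size=min(args.queries_per_family, len(members)),
                replace=False,
            )
            for qi in picks:
                entry = members[int(qi)]
                ranked = rank_database(entry.vector, db)
                evals.append(precision_recall(ranked, labels, fam))
        _pts, auc = average_precision_recall(evals)
        aucs[scheme] = auc
        print(f"{scheme.upper():4s} mean PR AUC = {auc:.4f}")

    ok = aucs["dd1"] < aucs["dd2"] <= max(aucs["rc"], aucs["drc"])
    print("qualitative ordering DD1 < DD2 <= max(RC, DRC):",
          "holds" if ok else "VIOLATED")
    sys.exit(0 if ok else 1)


if __name__ == "__main__":
    main()
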