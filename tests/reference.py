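"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately written in plain Python (nested loops,
dicts, ``math.dist``) with no shared code with the package implementation,
so that agreement between the two is meaningful.
"""

from __future__ import annotations

import math

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_locals(chain, tau_p: float, b: int):
    """All-ordered-pairs local descriptor counts, one (center_type, counts)
    per residue; counts is a 20 x b nested list."""
    coords = [tuple(r.ca_coord) for r in chain.residues]
    types = [r.residue_type for r in chain.residues]
    n = len(coords)
    out = []
    width = tau_p / b
    for c in range(n):
        counts = [[0] * b for _ in range(20)]
        for i in range(n):
            if i == c:
                continue
            d = math.dist(coords[c], coords[i])
            if d <= tau_p:
                j = b - 1 if d >= tau_p else int(d // width)
                j = min(j, b - 1)
                counts[ALPHABET.index(types[i])][j] += 1
        out.append((types[c], counts))
    return out


def _norm(vec):
    total = sum(vec)
    return [v / total for v in vec] if total else [0.0] * len(vec)


def brute_force_globals(locals_, b: int):
    """Per-central-type averaged normalized marginals, summed in reverse
    order relative to the package (a genuinely different accumulation)."""
    blocks = {}
    for aa in ALPHABET:
        group = [counts for t, counts in locals_
                 if t == aa and sum(map(sum, counts)) > 0]
        if not group:
            blocks[aa] = ([0.0] * b, [0.0] * 20)
            continue
        acc_c = [0.0] * b
        acc_r = [0.0] * 20
        for counts in reversed(group):
            sum_c = [sum(counts[i][j] for i in range(20)) for j in range(b)]
            sum_r = [sum(counts[i][j] for j in range(b)) for i in range(20)]
            for j, v in enumerate(_norm(sum_c)):
                acc_c[j] += v
            for i, v in enumerate(_norm(sum_r)):
                acc_r[i] += v
        blocks[aa] = ([v / len(group) for v in acc_c],
                      [v / len(group) for v in acc_r])
    return blocks


def brute_force_vectors(chain, tau_p: float, b: int):
    """All four descriptor views computed from scratch; returns a dict."""
    locals_ = brute_force_locals(chain, tau_p, b)
    blocks = brute_force_globals(locals_, b)
    dd2, rc, drc = [], [], []
    for aa in ALPHABET:
        c_blk, r_blk = blocks[aa]
        dd2 += c_blk
        rc += r_blk
        drc += c_blk + r_blk

    dd1_rows = []
    for _t, counts in locals_:
        sum_c = [sum(counts[i][j] for i in range(20)) for j in range(b)]
        if sum(sum_c) > 0:
            dd1_rows.append(_norm(sum_c))
    if dd1_rows:
        dd1 = [sum(row[j] for row in dd1_rows) / len(dd1_rows) for j in range(b)]
    else:
        dd1 = [0.0] * b
    return {"dd1": dd1, "dd2": dd2, "rc": rc, "drc": drc, "locals": locals_}


def brute_force_sasa(chain, probe_radius: float, sphere_points):
    """Point-counting SASA with plain loops over the same sphere lattice."""
    atoms = []
    for ri, res in enumerate(chain):
        for a in res.atoms:
            atoms.append((tuple(a.coord), a.vdw_radius + probe_radius, ri))
    sasa = [0.0] * len(chain)
    for ai, (c, r, owner) in enumerate(atoms):
        accessible = 0
        for p in sphere_points:
            pt = (c[0] + r * p[0], c[1] + r * p[1], c[2] + r * p[2])
            buried = False
            for bi, (c2, r2, _o2) in enumerate(atoms):
                if bi == ai:
                    continue
                if math.dist(pt, c2) < r2:
                    buried = True
                    break
            if not buried:
                accessible += 1
        sasa[owner] += accessible / len(sphere_points) * 4 * math.pi * r * r
    return sasa
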