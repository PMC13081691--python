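"""Independent brute-force oracles used to cross-check the vectorized
implementations.  Everything here is written with plain Python loops and no
imports from the package's scoring internals."""

from __future__ import annotations

import math


def d0_ref(n: int) -> float:
    return max(1.0, 1.24 * (max(n - 15, 0)) ** (1.0 / 3.0) - 1.8)


def ipsae_bruteforce(pae, la: int, lb: int, cutoff: float):
    """All three ipSAE variants, both directions, by double loops.

    ``pae`` is an (la+lb)×(la+lb) nested list; chain A occupies rows/cols
    0..la-1, chain B the rest.  Returns {variant: (ab, ba, max)}.
    """
    a_idx = list(range(la))
    b_idx = list(range(la, la + lb))

    def direction(rows, cols, variant):
        # residues participating in any sub-cutoff pair, for d0dom
        row_part = [i for i in rows if any(pae[i][j] < cutoff for j in cols)]
        col_part = [j for j in cols if any(pae[i][j] < cutoff for i in rows)]
        n_dom = len(row_part) + len(col_part)
        best = 0.0
        for i in rows:
            sel = [j for j in cols if pae[i][j] < cutoff]
            if not sel:
                continue
            if variant == "ipsae":
                d0 = d0_ref(len(sel))
            elif variant == "d0chn":
                d0 = d0_ref(la + lb)
            else:
                d0 = d0_ref(n_dom)
            score = sum(
                1.0 / (1.0 + (pae[i][j] / d0) ** 2) for j in sel
            ) / len(sel)
            best = max(best, score)
        return best

    out = {}
    for variant in ("ipsae", "d0chn", "d0dom"):
        ab = direction(a_idx, b_idx, variant)
        ba = direction(b_idx, a_idx, variant)
        out[variant] = (ab, ba, max(ab, ba))
    return out


def masked_iptm_bruteforce(pae, coords_a, coords_b, cutoff_dist: float):
    """Coordinate-masked interface pTM by loops.

    ``coords_a``/``coords_b``: per-residue lists of (x, y, z) atom tuples.
    ``pae`` indexed as in :func:`ipsae_bruteforce`.
    """
    la, lb = len(coords_a), len(coords_b)

    def res_dist(ra, rb):
        return min(
            math.dist(p, q) for p in ra for q in rb
        )

    mask_a = [any(res_dist(coords_a[i], coords_b[j]) <= cutoff_dist
                  for j in range(lb)) for i in range(la)]
    mask_b = [any(res_dist(coords_a[i], coords_b[j]) <= cutoff_dist
                  for i in range(la)) for j in range(lb)]
    iface_a = [i for i in range(la) if mask_a[i]]
    iface_b = [j for j in range(lb) if mask_b[j]]
    n = len(iface_a) + len(iface_b)
    if n == 0:
        return 0.0
    d0 = d0_ref(n)

    def kernel(x):
        return 1.0 / (1.0 + (x / d0) ** 2)

    best = 0.0
    for i in iface_a:
        vals = [kernel(pae[i][la + j]) for j in iface_b]
        if vals:
            best = max(best, sum(vals) / len(vals))
    for j in iface_b:
        vals = [kernel(pae[la + j][i]) for i in iface_a]
        if vals:
            best = max(best, sum(vals) / len(vals))
    return best


def contacts_bruteforce(res_atoms_a, res_atoms_b, cutoff: float):
    """All residue-residue contacts by full atom-pair enumeration.

    Inputs are lists (per residue) of (x, y, z) tuples; returns sorted
    (i+1, j+1, min_dist) triples for pairs within the cutoff."""
    out = []
    for i, ra in enumerate(res_atoms_a):
        for j, rb in enumerate(res_atoms_b):
            dmin = min(math.dist(p, q) for p in ra for q in rb)
            if dmin <= cutoff:
                out.append((i + 1, j + 1, dmin))
    return sorted(out)


def lddt_bruteforce(atoms_ref, atoms_other, radius=15.0,
                    thresholds=(0.5, 1.0, 2.0, 4.0)):
    """One direction of interface lDDT by full pair enumeration.

    ``atoms_ref``: list of (chain, key, (x, y, z)); ``atoms_other``: dict
    key → (x, y, z) for the mapped atoms (missing keys = unmapped).
    Returns (score, n_mapped_pairs, n_reference_pairs).
    """
    n_ref = 0
    deltas = []
    for p in range(len(atoms_ref)):
        for q in range(p + 1, len(atoms_ref)):
            ch_p, key_p, xyz_p = atoms_ref[p]
            ch_q, key_q, xyz_q = atoms_ref[q]
            if ch_p == ch_q:
                continue
            d_ref = math.dist(xyz_p, xyz_q)
            if d_ref >= radius:
                continue
            n_ref += 1
            if key_p in atoms_other and key_q in atoms_other:
                d_other = math.dist(atoms_other[key_p], atoms_other[key_q])
                deltas.append(abs(d_ref - d_other))
    if not deltas:
        return 0.0, 0, n_ref
    score = sum(
        sum(1 for d in deltas if d < t) / len(deltas) for t in thresholds
    ) / len(thresholds)
    return score, len(deltas), n_ref


def moment_bruteforce(values, delta_deg=100.0):
    """Hydrophobic moment as an explicit complex sum."""
    total = complex(0.0, 0.0)
    for n, h in enumerate(values):
        ang = math.radians(delta_deg) * n
        total += h * complex(math.cos(ang), math.sin(ang))
    return abs(total) / len(values)
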