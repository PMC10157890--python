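"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: Python double loops over explicit
atom lists, exact rational hypergeometric sums, and full permutation
enumeration.  The chemistry tables are hard-coded copies of the standard
PDB v3 group definitions so the oracle does not share code with the
package's classification logic.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

# hard-coded residue chemistry (independent of kdacsel.chemistry)
CATION_H = {
    "ARG": ["HE", "HH11", "HH12", "HH21", "HH22"],
    "LYS": ["HZ1", "HZ2", "HZ3"],
    "HIS": ["HD1", "HE2"],
}
ANION_O = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
SC_DONORS = {
    "SER": [("OG", "HG")], "THR": [("OG1", "HG1")], "TYR": [("OH", "HH")],
    "CYS": [("SG", "HG")],
    "ASN": [("ND2", "HD21"), ("ND2", "HD22")],
    "GLN": [("NE2", "HE21"), ("NE2", "HE22")],
    "TRP": [("NE1", "HE1")],
    "HIS": [("ND1", "HD1"), ("NE2", "HE2")],
    "ARG": [("NE", "HE"), ("NH1", "HH11"), ("NH1", "HH12"),
            ("NH2", "HH21"), ("NH2", "HH22")],
    "LYS": [("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
    "ALY": [("NZ", "HZ")],
}
SC_ACCEPTORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"], "GLN": ["OE1"], "HIS": ["ND1", "NE2"], "MET": ["SD"],
    "ALY": ["OH"],
}
BB_ACCEPTORS = ["O", "OXT"]


def min_distance_bruteforce(coords_a, coords_b) -> float:
    best = math.inf
    for xa in coords_a:
        for xb in coords_b:
            d = math.dist(tuple(xa), tuple(xb))
            best = min(best, d)
    return best


def _atoms(residue):
    """residue = (res_name, {atom_name: xyz})"""
    return residue[1]


def contact_bruteforce(res_a, res_b, cutoff=0.30) -> bool:
    d = min_distance_bruteforce(
        list(_atoms(res_a).values()), list(_atoms(res_b).values())
    )
    return d <= cutoff


def ionic_bruteforce(res_a, res_b, cutoff=0.25) -> bool:
    """Either orientation: cationic H of one residue vs anionic O of other."""
    hit = False
    for cat, an in ((res_a, res_b), (res_b, res_a)):
        hs = [xyz for n, xyz in _atoms(cat).items()
              if n in CATION_H.get(cat[0], [])]
        os_ = [xyz for n, xyz in _atoms(an).items()
               if n in ANION_O.get(an[0], [])]
        for h in hs:
            for o in os_:
                if math.dist(tuple(h), tuple(o)) <= cutoff:
                    hit = True
    return hit


def _angle_deg(v1, v2) -> float:
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def hbond_bruteforce(
    donor_res, acceptor_res, donor_scope, acceptor_scope,
    dist_cutoff=0.35, angle_max=30.0,
) -> bool:
    datoms = _atoms(donor_res)
    aatoms = _atoms(acceptor_res)
    if donor_scope == "sidechain":
        pairs = SC_DONORS.get(donor_res[0], [])
    else:
        pairs = [("N", "H")]
    if acceptor_scope == "sidechain":
        acc_names = SC_ACCEPTORS.get(acceptor_res[0], [])
    else:
        acc_names = BB_ACCEPTORS
    for d_name, h_name in pairs:
        if d_name not in datoms or h_name not in datoms:
            continue
        d, h = datoms[d_name], datoms[h_name]
        for a_name in acc_names:
            if a_name not in aatoms:
                continue
            a = aatoms[a_name]
            if math.dist(tuple(d), tuple(a)) > dist_cutoff:
                continue
            if _angle_deg(
                np.subtract(h, d), np.subtract(a, d)
            ) <= angle_max:
                return True
    return False


def hbond_sidechain_bruteforce(res_e, res_s) -> bool:
    return hbond_bruteforce(res_e, res_s, "sidechain", "sidechain") or \
        hbond_bruteforce(res_s, res_e, "sidechain", "sidechain")


def hbond_backbone_bruteforce(res_e, res_s) -> bool:
    return hbond_bruteforce(res_e, res_s, "sidechain", "backbone") or \
        hbond_bruteforce(res_s, res_e, "backbone", "sidechain")


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_exact(table) -> Fraction:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    (a, b), (c, d) = [list(map(int, row)) for row in table]
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k) -> Fraction:
        return Fraction(
            math.comb(col1, k) * math.comb(n - col1, row1 - k),
            math.comb(n, row1),
        )

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p_k = pmf(k)
        if p_k <= p_obs * Fraction(10**7 + 1, 10**7):
            total += p_k
    return total


def mwu_exact_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by full combination enumeration.

    Assumes no ties.  Returns (U of x, two-sided p).
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    r1 = sum(ranks[v] for v in x)
    u1 = r1 - n1 * (n1 + 1) / 2
    u_obs = max(u1, n1 * n2 - u1)
    count = 0
    total = 0
    all_ranks = range(1, n1 + n2 + 1)
    for combo in itertools.combinations(all_ranks, n1):
        total += 1
        u = sum(combo) - n1 * (n1 + 1) / 2
        if max(u, n1 * n2 - u) >= u_obs:
            count += 1
    return u1, count / total


def pooled_t_textbook(a, b) -> tuple[float, float]:
    """Pooled two-sample t by the textbook formula + scipy's t survival."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    s2 = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    return t, 2 * tdist.sf(abs(t), n1 + n2 - 2)
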