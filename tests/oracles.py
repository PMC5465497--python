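"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by a route disjoint from the library
implementation: a plain O(n^2) dynamic-programming aligner, an
exhaustive all-atom-pairs contact scan, and an Euler-grid + simplex
rotation minimiser for superposition RMSD.
"""

from __future__ import annotations

import math

import numpy as np


# -- unit-score Needleman-Wunsch ---------------------------------------------


def nw_unit_align(a: str, b: str, match=1.0, mismatch=-1.0, gap=-1.0):
    """Global DP alignment; returns list of (i, j) aligned index pairs."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=int)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        score[i, 0] = i * gap
        ptr[i, 0] = 1
    for j in range(1, m + 1):
        score[0, j] = j * gap
        ptr[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = score[i - 1, j] + gap
            l = score[i, j - 1] + gap
            best = max(d, u, l)
            score[i, j] = best
            ptr[i, j] = 0 if best == d else (1 if best == u else 2)
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


# -- brute-force contact scan -------------------------------------------------


def brute_force_contacts(model, chain_pair, criteria):
    """All-pairs atom scan; returns {(kind, num_i, num_j): min_distance}."""
    ca, cb = sorted(chain_pair)
    chain_i = model.chain(ca)
    chain_j = model.chain(cb)
    found = {}
    for ri in chain_i.residues:
        for rj in chain_j.residues:
            for ai in ri.atoms:
                if ai.name in ("N", "CA", "C", "O", "OXT"):
                    continue
                for aj in rj.atoms:
                    if aj.name in ("N", "CA", "C", "O", "OXT"):
                        continue
                    d = math.dist(ai.xyz, aj.xyz)
                    hydro = (
                        ri.name in criteria.hydrophobic_residues
                        and rj.name in criteria.hydrophobic_residues
                        and ai.element == "C"
                        and aj.element == "C"
                        and d <= criteria.hydrophobic_cutoff
                    )
                    charged = {ai.element, aj.element} <= {"N", "O"}
                    ionic = (
                        (
                            (ri.name in criteria.basic_residues and rj.name in criteria.acidic_residues)
                            or (ri.name in criteria.acidic_residues and rj.name in criteria.basic_residues)
                        )
                        and ai.element in ("N", "O")
                        and aj.element in ("N", "O")
                        and d <= criteria.ionic_cutoff
                    )
                    for ok, kind in ((hydro, "hydrophobic"), (ionic, "ionic")):
                        if ok:
                            key = (kind, ri.number, rj.number)
                            if key not in found or d < found[key]:
                                found[key] = d
    return found


# -- rotation-grid RMSD minimiser --------------------------------------------


def _euler_matrix(a, b, c):
    ca_, sa = math.cos(a), math.sin(a)
    cb_, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    rz1 = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
    ry = np.array([[cb_, 0, sb], [0, 1, 0], [-sb, 0, cb_]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def grid_search_rmsd(mobile, target, coarse_steps=24, refine=True):
    """Minimum RMSD over rotations via Euler-angle grid + Nelder-Mead.

    Translation is optimal at matched centroids for any rotation, so
    both clouds are centred first.  Independent of the Kabsch route.
    """
    from scipy.optimize import minimize

    X = np.asarray(mobile, float)
    Y = np.asarray(target, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def rmsd_of(angles):
        R = _euler_matrix(*angles)
        return float(np.sqrt(np.mean(np.sum((Xc @ R.T - Yc) ** 2, axis=1))))

    best, best_angles = np.inf, None
    alphas = np.linspace(0, 2 * np.pi, coarse_steps, endpoint=False)
    betas = np.linspace(0, np.pi, coarse_steps // 2 + 1)
    gammas = alphas
    for a in alphas:
        for b in betas:
            for c in gammas:
                r = rmsd_of((a, b, c))
                if r < best:
                    best, best_angles = r, (a, b, c)
    if refine:
        res = minimize(
            rmsd_of,
            best_angles,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
        )
        best = min(best, float(res.fun))
    return best
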