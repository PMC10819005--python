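"""Independent brute-force / closed-form oracles used across the test suite.

Everything here deliberately avoids the package's own computational paths:
per-point polynomial regression for smoothing, full SVD for the rank-1
factorization, dense grid search for sigmoid fits, O(N^2) Python loops for
the trajectory detectors, Simpson quadrature for enthalpy integrals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import curve_fit
from scipy.special import expit


# ---------------------------------------------------------------- smoothing

def sg_oracle(values, window, degree):
    """Per-point weighted least-squares polynomial, window clipped at edges."""
    v = np.asarray(values, float)
    half = window // 2
    out = np.empty_like(v)
    for i in range(v.size):
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        x = np.arange(lo, hi) - i
        deg = min(degree, hi - lo - 1)
        coef = np.polynomial.polynomial.polyfit(x, v[lo:hi], deg)
        out[i] = coef[0]
    return out


# ---------------------------------------------------------------- SVD

def leading_svd_triplet(D):
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    u, sigma, v = U[:, 0], s[0], Vt[0]
    if u.sum() < 0:
        u, v = -u, -v
    return u, sigma, v


# ---------------------------------------------------------------- sigmoids

def _sig(T, T0, dT):
    return expit(-(np.asarray(T) - T0) / dT)


def grid_oracle_single(T, y, T0_range, dT_range, T0_step=0.002, dT_step=0.02):
    """Dense grid search over (T0, dT) with exact linear solve for (A1, A2)."""
    T = np.asarray(T, float)
    y = np.asarray(y, float)
    T0s = np.arange(*T0_range, T0_step)
    dTs = np.arange(*dT_range, dT_step)
    best = (math.inf, None)
    yy = float(y @ y)
    for dT in dTs:
        G = _sig(T[None, :], T0s[:, None], dT)          # (K, n)
        H = 1.0 - G
        a11 = np.sum(G * G, axis=1)
        a12 = np.sum(G * H, axis=1)
        a22 = np.sum(H * H, axis=1)
        b1 = G @ y
        b2 = H @ y
        det = a11 * a22 - a12 * a12
        det = np.where(det == 0, np.nan, det)
        A1 = (a22 * b1 - a12 * b2) / det
        A2 = (a11 * b2 - a12 * b1) / det
        ss = yy - (A1 * b1 + A2 * b2)
        k = int(np.nanargmin(ss))
        if ss[k] < best[0]:
            best = (float(ss[k]), (float(A1[k]), float(A2[k]), float(T0s[k]), float(dT)))
    return best[1]


def _double_model(T, A1, A2, T01, dT1, T02, dT2, f):
    return A2 + (A1 - A2) * (f * _sig(T, T01, dT1) + (1 - f) * _sig(T, T02, dT2))


def two_stage_oracle_double(T, y, T01_range, T02_range, dT1_list, dT2_list,
                            step=0.1):
    """Coarse grid with linear amplitude solve, then an independent polish.

    Stage 1: for each (T01, dT1, T02, dT2), y is linear in (offset, p, q)
    over the basis (1, g1, g2); solve exactly and keep the best SS.
    Stage 2: polish all seven parameters with curve_fit from the grid optimum.
    """
    T = np.asarray(T, float)
    y = np.asarray(y, float)
    best = (math.inf, None)
    for T01 in np.arange(*T01_range, step):
        for T02 in np.arange(*T02_range, step):
            if T02 <= T01:
                continue
            for dT1 in dT1_list:
                for dT2 in dT2_list:
                    X = np.column_stack([np.ones_like(T), _sig(T, T01, dT1),
                                         _sig(T, T02, dT2)])
                    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                    ss = float(np.sum((X @ coef - y) ** 2))
                    if ss < best[0]:
                        best = (ss, (coef, T01, dT1, T02, dT2))
    coef, T01, dT1, T02, dT2 = best[1]
    off, p, q = coef
    amp = p + q
    A2 = off
    A1 = off + amp
    f = p / amp if amp != 0 else 0.5
    f = min(max(f, 1e-3), 1 - 1e-3)
    p0 = [A1, A2, T01, dT1, T02, dT2, f]
    popt, _ = curve_fit(_double_model, T, y, p0=p0, maxfev=20000)
    T0s = sorted([popt[2], popt[4]])
    return T0s


# ---------------------------------------------------------------- trajectory

def mi_dist(p, q, box):
    d = [p[k] - q[k] for k in range(3)]
    d = [d[k] - box[k] * round(d[k] / box[k]) for k in range(3)]
    return math.sqrt(sum(x * x for x in d))


def min_distance_bf(pos, box, sel_a, sel_b):
    return min(mi_dist(pos[i], pos[j], box)
               for i in sel_a for j in sel_b if i != j)


def count_contacts_bf(pos, box, sel_a, sel_b, cutoff):
    return sum(1 for i in sel_a for j in sel_b
               if i != j and mi_dist(pos[i], pos[j], box) <= cutoff)


def hbonds_bf(pos, box, donors, hydrogens_of, acceptors, r_cut, angle_cut_deg):
    """Exhaustive (donor, hydrogen, acceptor) triple enumeration."""
    out = []
    for d in donors:
        for a in acceptors:
            if a == d or mi_dist(pos[d], pos[a], box) > r_cut:
                continue
            for h in hydrogens_of.get(d, []):
                va = np.array([pos[a][k] - pos[d][k] for k in range(3)])
                va -= box * np.round(va / box)
                vh = np.array([pos[h][k] - pos[d][k] for k in range(3)])
                vh -= box * np.round(vh / box)
                cos = float(va @ vh / (np.linalg.norm(va) * np.linalg.norm(vh)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cos))))
                if ang <= angle_cut_deg:
                    out.append((d, h, a))
    return out


def salt_bridges_bf(pos, box, cat_atoms, an_atoms, cutoff):
    """Exhaustive group-pair enumeration; cat/an_atoms map group id -> atoms."""
    out = []
    for cg, ca in cat_atoms.items():
        for ag, aa in an_atoms.items():
            if min(mi_dist(pos[i], pos[j], box) for i in ca for j in aa) <= cutoff:
                out.append((cg, ag))
    return out


# ---------------------------------------------------------------- quadrature

def simpson_integral(t, bounds):
    """Simpson-rule enthalpy integral on the thermogram's native grid."""
    lo, hi = bounds
    mask = (t.temperatures >= lo) & (t.temperatures <= hi)
    return float(simpson(t.excess_heat_capacity[mask], x=t.temperatures[mask]))
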