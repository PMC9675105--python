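"""Naive-loop reference implementations used as independent oracles.

Everything here is written directly from the defining formulas with
plain Python loops and no shared code with the package, so agreement
between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np


# --- neighbourhoods and topology similarity -------------------------------

def path_enumeration_neighbor_sets(edges, u):
    """S1 and S2 of u by enumerating all length-1 and length-2 paths."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    s1 = set(adj.get(u, set()))
    s2 = set()
    for w in adj.get(u, set()):
        for v in adj.get(w, set()):
            if v != u and w != v:
                s2.add(v)
    return s1, s2


def naive_fs(edges, u, v, alpha):
    s1, s2 = path_enumeration_neighbor_sets(edges, u)
    if v in s1 and v in s2:
        return 1.0
    if v in s1:
        return alpha
    if v in s2:
        return 1.0 - alpha
    return 0.0


def naive_ms(complexes, u, v):
    """complexes: list of (cid, set of members)."""
    cu = {cid for cid, members in complexes if u in members}
    cv = {cid for cid, members in complexes if v in members}
    if not cu or not cv:
        return 0.0
    return len(cu & cv) ** 2 / (len(cu) * len(cv))


def naive_mpp(edges, complexes, proteins, alpha, beta):
    """Dense all-pairs blend by direct substitution."""
    n = len(proteins)
    out = np.zeros((n, n))
    for i, u in enumerate(proteins):
        for j, v in enumerate(proteins):
            if i == j:
                continue
            out[i, j] = beta * naive_fs(edges, u, v, alpha) + (1 - beta) * naive_ms(
                complexes, u, v
            )
    return out


# --- domain layers ---------------------------------------------------------

def naive_spd(mpp_dense, pindex, u, pl):
    """Max of mpp(u, p) over the protein list."""
    return max(mpp_dense[pindex[u], pindex[p]] for p in pl)


def naive_mdd(mpp_dense, pindex, pl_i, pl_j):
    num = sum(naive_spd(mpp_dense, pindex, p, pl_i) for p in pl_i)
    num += sum(naive_spd(mpp_dense, pindex, p, pl_j) for p in pl_j)
    return num / (len(pl_i) + len(pl_j))


# --- transition rows -------------------------------------------------------

def naive_transition(mpp_dense, mpd_dense, mdd_dense, lam):
    """Per-row evaluation of the four block formulas."""
    n_p, n_d = mpd_dense.shape
    n = n_p + n_d
    t = np.zeros((n, n))
    for i in range(n_p):
        srow = mpp_dense[i].sum()
        has_dom = mpd_dense[i].sum() > 0
        if srow > 0:
            scale = (1 - lam) if has_dom else 1.0
            t[i, :n_p] = scale * mpp_dense[i] / srow
        if has_dom:
            t[i, n_p:] = lam * mpd_dense[i] / mpd_dense[i].sum()
    for i in range(n_d):
        srow = mdd_dense[i].sum()
        has_prot = mpd_dense[:, i].sum() > 0
        if srow > 0:
            scale = (1 - lam) if has_prot else 1.0
            t[n_p + i, n_p:] = scale * mdd_dense[i] / srow
        if has_prot:
            t[n_p + i, :n_p] = lam * mpd_dense[:, i] / mpd_dense[:, i].sum()
    return t


def naive_initial_scores(mpp_dense, mpd_dense, u_idx):
    n_p, n_d = mpd_dense.shape
    h_p = mpp_dense[u_idx].copy()
    h_d = np.zeros(n_d)
    for j in range(n_d):
        members = np.nonzero(mpd_dense[:, j])[0]
        if members.size:
            h_d[j] = max(h_p[i] for i in members)
    return np.concatenate([h_p, h_d])


# --- function scoring ------------------------------------------------------

def naive_function_scores(scores, annotations, target):
    """Double loop over partners and their terms; returns term -> score."""
    out = {}
    for partner, pr in scores.items():
        if partner == target or pr <= 0:
            continue
        for term in annotations.get(partner, set()):
            out[term] = out.get(term, 0.0) + pr
    return out


def naive_top_partner_term_count(scores, annotations, target):
    best, count = None, 0
    for partner, pr in scores.items():
        if partner == target or pr <= 0:
            continue
        c = len(annotations.get(partner, set()))
        if c == 0:
            continue
        if best is None or pr > best or (pr == best and c > count):
            best, count = pr, c
    return count


# --- ROC ladder ------------------------------------------------------------

def naive_roc_points(ordered_terms, truth, universe, k_max):
    """Hand ladder for a single protein: (tpr, fpr) per K."""
    universe = list(universe)
    listed = [t for t in ordered_terms if t in set(universe)]
    padded = listed + sorted(set(universe) - set(listed))
    pts = []
    for k in range(1, k_max + 1):
        pos = set(padded[:k])
        tpr = len(pos & truth) / len(truth)
        fpr = len(pos - truth) / (len(universe) - len(truth))
        pts.append((tpr, fpr))
    return pts
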