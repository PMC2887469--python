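"""Numba inner loops for the inheritance-vector HMM.

Per inheritance vector, marker-data likelihood is evaluated through the
founder-allele graph: typed homozygotes pin founder allele slots, typed
heterozygotes force their two slots to differ, and each connected component
contributes the summed probability of its consistent allele assignments.
The union-find below carries a parity bit (same/different allele as the
component root) and an optional fixed root allele.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _find(parent, parity, x):
    """Root of x and parity of x relative to that root."""
    p = 0
    while parent[x] != x:
        p ^= parity[x]
        x = parent[x]
    return x, p


@njit(cache=False)
def marker_emission(slots_p, slots_m, gcodes, p1, out):
    """P(marker genotypes | inheritance vector) for every vector.

    slots_p/slots_m: (V, n_ind) founder-slot of each individual's paternal /
    maternal allele.  gcodes: per individual, -1 missing, 0 = hom allele-1,
    1 = het, 2 = hom allele-2.  p1 = frequency of allele 1.
    """
    n_vec, n_ind = slots_p.shape
    n_slots = 0
    for v in range(n_vec):
        for i in range(n_ind):
            if slots_p[v, i] + 1 > n_slots:
                n_slots = slots_p[v, i] + 1
            if slots_m[v, i] + 1 > n_slots:
                n_slots = slots_m[v, i] + 1
    p = np.empty(2)
    p[0] = p1
    p[1] = 1.0 - p1
    parent = np.empty(n_slots, dtype=np.int64)
    parity = np.empty(n_slots, dtype=np.int64)
    value = np.empty(n_slots, dtype=np.int64)
    n0 = np.zeros(n_slots, dtype=np.int64)
    n1 = np.zeros(n_slots, dtype=np.int64)

    for v in range(n_vec):
        for s in range(n_slots):
            parent[s] = s
            parity[s] = 0
            value[s] = -1
        ok = True
        for i in range(n_ind):
            g = gcodes[i]
            if g < 0:
                continue
            sp = slots_p[v, i]
            sm = slots_m[v, i]
            if g == 1:  # heterozygote: slots must differ
                if sp == sm:
                    ok = False
                    break
                rx, px = _find(parent, parity, sp)
                ry, py = _find(parent, parity, sm)
                if rx == ry:
                    if (px ^ py) != 1:
                        ok = False
                        break
                else:
                    parent[ry] = rx
                    parity[ry] = px ^ py ^ 1
                    if value[ry] != -1:
                        cand = value[ry] ^ parity[ry]
                        if value[rx] == -1:
                            value[rx] = cand
                        elif value[rx] != cand:
                            ok = False
                            break
                        value[ry] = -1
            else:  # homozygote: both slots pinned to allele a
                a = 0 if g == 0 else 1
                for s in (sp, sm):
                    r, pr = _find(parent, parity, s)
                    val = a ^ pr
                    if value[r] == -1:
                        value[r] = val
                    elif value[r] != val:
                        ok = False
                        break
                if not ok:
                    break
        if not ok:
            out[v] = 0.0
            continue

        for s in range(n_slots):
            n0[s] = 0
            n1[s] = 0
        prob = 1.0
        for s in range(n_slots):
            r, pr = _find(parent, parity, s)
            if pr == 0:
                n0[r] += 1
            else:
                n1[r] += 1
        for r in range(n_slots):
            c0 = n0[r]
            c1 = n1[r]
            if c0 + c1 == 0:
                continue
            if parent[r] != r:
                continue
            if value[r] >= 0:
                a = value[r]
                prob *= p[a] ** c0 * p[1 - a] ** c1
            else:
                prob *= p[0] ** c0 * p[1] ** c1 + p[1] ** c0 * p[0] ** c1
        out[v] = prob


@njit(cache=False)
def disease_emission(slots_p, slots_m, phenos, f, q, n_founder_slots, out):
    """P(phenotypes | inheritance vector, disease locus here) for every vector.

    Sums over all founder disease-allele configurations.  phenos: -1 unknown,
    0 unaffected, 1 affected.  f: penetrance for 0/1/2 copies.  q: disease
    allele frequency.
    """
    n_vec, n_ind = slots_p.shape
    n_cfg = 1 << n_founder_slots
    prior = np.empty(n_cfg)
    for c in range(n_cfg):
        pr = 1.0
        for s in range(n_founder_slots):
            if (c >> s) & 1:
                pr *= q
            else:
                pr *= 1.0 - q
        prior[c] = pr
    for v in range(n_vec):
        total = 0.0
        for c in range(n_cfg):
            pr = prior[c]
            if pr == 0.0:
                continue
            for i in range(n_ind):
                ph = phenos[i]
                if ph < 0:
                    continue
                n = ((c >> slots_p[v, i]) & 1) + ((c >> slots_m[v, i]) & 1)
                if ph == 1:
                    pr *= f[n]
                else:
                    pr *= 1.0 - f[n]
                if pr == 0.0:
                    break
            total += pr
        out[v] = total
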