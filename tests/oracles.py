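"""Independent brute-force pedigree-likelihood oracle.

Enumerates the full inheritance-vector state space explicitly, computes
each marker's emission by direct enumeration of founder-allele assignments
(allele letters summed against observed dosages, no partition/class
machinery), and chains markers with dense transition matrices built from
the popcount closed form theta^k (1-theta)^(m-k).  Deliberately written as
straight loops so it shares no algorithmic shortcuts with the production
engine; only feasible for small pedigrees and a few markers.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from forcekin.engine import haldane_theta
from forcekin.pedigree import MALE, Pedigree


def brute_force_log_likelihood(
    ped: Pedigree,
    genotypes: dict[str, np.ndarray],
    markers: pd.DataFrame,
    mode: str = "autosomal",
) -> float:
    typed = [iid for iid, g in genotypes.items() if g is not None]
    order = ped.topo_order()
    nonf = [i for i in order if not ped.members[i].is_founder]

    slot_of: dict[str, tuple[int, ...]] = {}
    ns = 0
    for iid in order:
        ind = ped.members[iid]
        if ind.is_founder:
            if mode == "X" and ind.sex == MALE:
                slot_of[iid] = (ns,)
                ns += 1
            else:
                slot_of[iid] = (ns, ns + 1)
                ns += 2

    bits: dict[tuple[str, str], int] = {}
    nb = 0
    for iid in nonf:
        if mode == "autosomal":
            bits[(iid, "p")] = nb
            bits[(iid, "m")] = nb + 1
            nb += 2
        else:
            bits[(iid, "m")] = nb
            nb += 1

    def slots_for(iid: str, state: int) -> tuple[int, ...]:
        ind = ped.members[iid]
        if ind.is_founder:
            return slot_of[iid]
        if mode == "autosomal":
            bp = (state >> bits[(iid, "p")]) & 1
            bm = (state >> bits[(iid, "m")]) & 1
            return (
                slots_for(ind.father, state)[bp],
                slots_for(ind.mother, state)[bm],
            )
        bm = (state >> bits[(iid, "m")]) & 1
        mat = slots_for(ind.mother, state)[bm]
        if ind.sex == MALE:
            return (mat,)
        return (slots_for(ind.father, state)[0], mat)

    S = 1 << nb
    n = len(markers)
    freqs = np.clip(markers["freq"].to_numpy(dtype=float), 1e-4, 1 - 1e-4)
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_cm"].to_numpy(dtype=float)

    em = np.zeros((n, S))
    for s in range(S):
        slots = {iid: slots_for(iid, s) for iid in typed}
        involved = sorted({x for v in slots.values() for x in v})
        for t in range(n):
            p = freqs[t]
            tot = 0.0
            for assign in itertools.product((0, 1), repeat=len(involved)):
                alleles = dict(zip(involved, assign))
                ok = True
                for iid, sl in slots.items():
                    d = genotypes[iid][t]
                    if d < 0:
                        continue
                    if sum(alleles[x] for x in sl) != d:
                        ok = False
                        break
                if ok:
                    w = 1.0
                    for a in assign:
                        w *= p if a else (1.0 - p)
                    tot += w
            em[t, s] = tot

    def transition(f: np.ndarray, theta: float) -> np.ndarray:
        if nb == 0:
            return f
        out = np.zeros(S)
        js = np.arange(S)
        block = 2048
        for j0 in range(0, S, block):
            jb = js[j0 : j0 + block]
            k = np.bitwise_count(np.bitwise_xor.outer(np.arange(S), jb))
            T = theta**k * (1.0 - theta) ** (nb - k)
            out[j0 : j0 + block] = f @ T
        return out

    total = 0.0
    for ch in pd.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        f = em[idx[0]] / S
        for prev, t in zip(idx, idx[1:]):
            theta = float(haldane_theta(pos[t] - pos[prev]))
            f = transition(f, theta) * em[t]
        tot = f.sum()
        if tot <= 0:
            return -np.inf
        total += np.log(tot)
    return total
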