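"""Multipoint pedigree likelihood on linked biallelic SNPs.

The likelihood of observed genotypes in a pedigree is computed with a
hidden Markov model over inheritance vectors (one bit per modeled meiosis,
recording whether the grandpaternal or grandmaternal allele was transmitted).
Along a chromosome the vector evolves marker to marker with each bit flipping
independently with the recombination fraction of the inter-marker gap
(Haldane map function, no interference).  At each marker the emission is the
probability of all typed genotypes given the vector, obtained by summing
over founder-allele assignments; because markers are biallelic and founder
alleles are exchangeable draws from one population frequency, the emission
depends on the vector only through the *partition* of the typed individuals'
founder-allele slots into identity classes, which lets emissions be computed
once per class and per marker, fully vectorised.

Complexity is O(m * 2^m) per marker interval for m meioses.  Likelihoods for
a batch of genotype observation sets sharing the same pedigree and marker
map are computed in one pass (leading batch axis), which is what makes the
simulation studies affordable.

Genotypes are alt-allele dosages: diploid sites in {0, 1, 2}, hemizygous
sites (male X) in {0, 1}; -1 marks missing/uncalled sites, which simply
contribute no constraint at that marker.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, Pedigree

__all__ = ["haldane_theta", "pedigree_log_likelihood", "hwe_log_likelihood"]

FREQ_FLOOR = 1e-4  # allele-frequency clamp avoiding impossible founder alleles
DEFAULT_MAX_MEIOSES = 18


def haldane_theta(d_cm):
    """Recombination fraction for a map distance in centimorgans.

    Haldane's map function (no crossover interference):
    theta = (1 - exp(-2 d)) / 2 with d in Morgans.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def _clamp(freq: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(freq, dtype=float), FREQ_FLOOR, 1.0 - FREQ_FLOOR)


class _MeiosisLayout:
    """Founder-allele slot arrays over the full inheritance-vector space."""

    def __init__(self, ped: Pedigree, mode: str, max_meioses: int):
        if mode not in ("autosomal", "X"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        # count meioses: autosomal = 2 per non-founder; X = 1 (maternal) per
        # non-founder (father -> daughter X transmission is deterministic,
        # sons receive no paternal X).
        nonf = ped.nonfounders
        m = (2 if mode == "autosomal" else 1) * len(nonf)
        if m > max_meioses:
            raise ValueError(
                f"pedigree requires {m} meioses (> cap {max_meioses}); "
                "the 2^m inheritance-vector space would be too large"
            )
        self.n_meioses = m
        self.n_states = 1 << m
        S = self.n_states
        states = np.arange(S)

        def bit(b: int) -> np.ndarray:
            return (states >> b) & 1

        # slots[iid] -> list of per-state founder-slot index arrays
        # (autosomal: [paternal, maternal]; X: male [x], female [pat, mat])
        slots: dict[str, list[np.ndarray]] = {}
        next_slot = 0
        next_bit = 0
        for iid in ped.topo_order():
            ind = ped.members[iid]
            if ind.is_founder:
                if mode == "autosomal":
                    a = [np.full(S, next_slot), np.full(S, next_slot + 1)]
                    next_slot += 2
                elif ind.sex == MALE:
                    a = [np.full(S, next_slot)]
                    next_slot += 1
                else:
                    a = [np.full(S, next_slot), np.full(S, next_slot + 1)]
                    next_slot += 2
                slots[iid] = a
                continue
            if mode == "autosomal":
                fa, mo = slots[ind.father], slots[ind.mother]
                bp, bm = bit(next_bit), bit(next_bit + 1)
                next_bit += 2
                slots[iid] = [
                    np.where(bp == 0, fa[0], fa[1]),
                    np.where(bm == 0, mo[0], mo[1]),
                ]
            else:  # X
                mo = slots[ind.mother]
                bm = bit(next_bit)
                next_bit += 1
                mat = np.where(bm == 0, mo[0], mo[1])
                if ind.sex == MALE:
                    slots[iid] = [mat]
                else:
                    fa = slots[ind.father]
                    if len(fa) != 1:
                        raise AssertionError("father must be hemizygous in X mode")
                    slots[iid] = [fa[0], mat]
        self.slots = slots


def _canonical_partitions(slot_matrix: np.ndarray):
    """Relabel each row of a slot-index matrix by order of first appearance.

    Returns (patterns (K, J), class_of_state (S,)).
    """
    S, J = slot_matrix.shape
    out = np.zeros((S, J), dtype=np.int16)
    nxt = np.zeros(S, dtype=np.int16)
    for j in range(J):
        assigned = np.full(S, -1, dtype=np.int16)
        for k in range(j - 1, -1, -1):
            hit = slot_matrix[:, k] == slot_matrix[:, j]
            assigned[hit] = out[hit, k]
        is_new = assigned < 0
        out[:, j] = np.where(is_new, nxt, assigned)
        nxt += is_new
    patterns, class_of_state = np.unique(out, axis=0, return_inverse=True)
    return patterns, class_of_state


def _emissions(
    patterns: np.ndarray,
    typed_cols: list[np.ndarray],
    dosages: list[np.ndarray],
    ploidies: list[int],
    freq: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    """Per-marker, per-class emission probabilities, shape (B, n, K)."""
    K = patterns.shape[0]
    B, n = dosages[0].shape
    p = freq[None, :]
    # score[j][dos] = P(observed dosage of typed j | true dosage dos), (B, n)
    score: list[list[np.ndarray]] = []
    for d, pl in zip(dosages, ploidies):
        n_geno = 3 if pl == 2 else 2
        per_dos = []
        for dos in range(pl + 1):
            match = (d == dos).astype(float)
            s = (1.0 - error_rate) * match + error_rate / n_geno
            s = np.where(d < 0, 1.0, s)
            per_dos.append(s)
        score.append(per_dos)
    E = np.zeros((B, n, K))
    max_c = int(patterns.max(initial=-1)) + 1
    # weight of an assignment depends only on (#classes, #alt classes)
    pow_p = [np.ones_like(p)] + [None] * max_c
    pow_q = [np.ones_like(p)] + [None] * max_c
    for i in range(1, max_c + 1):
        pow_p[i] = pow_p[i - 1] * p
        pow_q[i] = pow_q[i - 1] * (1.0 - p)
    for k in range(K):
        labels = [patterns[k, cols] for cols in typed_cols]
        c = int(max(lab.max() for lab in labels)) + 1
        acc = np.zeros((B, n))
        for a in range(1 << c):
            bits = [(a >> i) & 1 for i in range(c)]
            s_alt = sum(bits)
            term = pow_p[s_alt] * pow_q[c - s_alt]
            mask = None
            for j, lab in enumerate(labels):
                dos = int(sum(bits[l] for l in lab))
                mj = score[j][dos]
                mask = mj if mask is None else mask * mj
            acc += term * mask
        E[:, :, k] = acc
    return E


def _mix_bits(x: np.ndarray, m: int, theta: float) -> np.ndarray:
    """Apply the per-meiosis transition (flip w.p. theta) to every bit."""
    if theta == 0.0 or m == 0:
        return x
    B, S = x.shape
    for b in range(m):
        v = x.reshape(B, S >> (b + 1), 2, 1 << b)
        x = ((1.0 - theta) * v + theta * v[:, :, ::-1, :]).reshape(B, S)
    return x


def pedigree_log_likelihood(
    ped: Pedigree,
    genotypes: dict[str, np.ndarray],
    markers: pd.DataFrame,
    mode: str = "autosomal",
    *,
    error_rate: float = 0.0,
    max_meioses: int = DEFAULT_MAX_MEIOSES,
):
    """Natural-log likelihood of typed genotypes given a pedigree.

    Parameters
    ----------
    ped
        Pedigree containing every typed individual.
    genotypes
        ``iid -> dosage array``; shape ``(n_markers,)`` or ``(B, n_markers)``
        for a batch of observation sets sharing the marker map.  Dosages are
        alt-allele counts, -1 for missing.
    markers
        DataFrame with columns ``chrom``, ``pos_cm``, ``freq`` sorted by
        chromosome then genetic position.  ``freq`` is the alt-allele
        frequency in the analysis population (clamped internally).
    mode
        ``"autosomal"`` or ``"X"`` (male typed individuals hemizygous).
    error_rate
        Optional per-genotype error probability mixed uniformly over the
        genotype space, absorbing Mendelian conflicts; 0 = strict (a
        conflicting marker zeroes the likelihood, giving -inf).

    Returns
    -------
    float or ndarray of shape (B,)
    """
    typed = [iid for iid, g in genotypes.items() if g is not None]
    if not typed:
        return 0.0
    for iid in typed:
        if iid not in ped:
            raise KeyError(f"typed individual {iid!r} not in pedigree")
    arrs = []
    scalar = np.asarray(genotypes[typed[0]]).ndim == 1
    for iid in typed:
        a = np.asarray(genotypes[iid], dtype=np.int64)
        if a.ndim == 1:
            a = a[None, :]
        arrs.append(a)
    B, n = arrs[0].shape
    if len(markers) != n:
        raise ValueError("genotype arrays must align with the marker table")
    if n == 0:
        out = np.zeros(B)
        return float(out[0]) if scalar else out

    layout = _MeiosisLayout(ped, mode, max_meioses)
    cols: list[np.ndarray] = []
    ploidies: list[int] = []
    mats = []
    start = 0
    for iid in typed:
        s = layout.slots[iid]
        mats.extend(s)
        cols.append(np.arange(start, start + len(s)))
        ploidies.append(len(s))
        start += len(s)
    slot_matrix = np.stack(mats, axis=1)
    patterns, class_of_state = _canonical_partitions(slot_matrix)

    freq = _clamp(markers["freq"].to_numpy())
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_cm"].to_numpy(dtype=float)

    E = _emissions(patterns, cols, arrs, ploidies, freq, error_rate)

    m = layout.n_meioses
    S = layout.n_states
    # large batched passes are memory-bandwidth bound; single precision is
    # ample there (per-marker rescaling keeps values near 1)
    dtype = np.float32 if B * S >= (1 << 19) and B >= 32 else np.float64
    E = E.astype(dtype, copy=False)
    loglik = np.zeros(B)
    dead = np.zeros(B, dtype=bool)
    for ch in pd.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        d = np.diff(pos[idx])
        if np.any(d < 0):
            raise ValueError(f"markers on {ch!r} not sorted by pos_cm")
        thetas = haldane_theta(d)
        x = E[:, idx[0], :][:, class_of_state]
        for step, t in enumerate(idx[1:]):
            c = x.max(axis=1)
            ok = c > 0
            dead |= ~ok
            c = np.where(ok, c, 1.0)
            loglik += np.where(ok, np.log(c), 0.0)
            x = x / c[:, None]
            x = _mix_bits(x, m, float(thetas[step]))
            x = x * E[:, t, :][:, class_of_state]
        tot = x.sum(axis=1) / S
        ok = tot > 0
        dead |= ~ok
        loglik += np.where(ok, np.log(np.where(ok, tot, 1.0)), 0.0)
    loglik = np.where(dead, -np.inf, loglik)
    return float(loglik[0]) if scalar else loglik


def hwe_log_likelihood(
    dosage: np.ndarray, freq: np.ndarray, ploidy: np.ndarray | int = 2
):
    """Log probability of one individual's genotypes under Hardy-Weinberg.

    ``ploidy`` may be a scalar or a per-marker array (1 for hemizygous
    sites).  Missing dosages (-1) contribute zero.
    """
    d = np.asarray(dosage, dtype=np.int64)
    scalar = d.ndim == 1
    if scalar:
        d = d[None, :]
    p = _clamp(freq)[None, :]
    pl = np.broadcast_to(np.asarray(ploidy), p.shape[1:])[None, :]
    q = 1.0 - p
    ll = np.zeros(d.shape)
    ll = np.where((pl == 2) & (d == 0), 2 * np.log(q), ll)
    ll = np.where((pl == 2) & (d == 1), np.log(2 * p * q), ll)
    ll = np.where((pl == 2) & (d == 2), 2 * np.log(p), ll)
    ll = np.where((pl == 1) & (d == 0), np.log(q), ll)
    ll = np.where((pl == 1) & (d == 1), np.log(p), ll)
    ll = np.where(d < 0, 0.0, ll)
    out = ll.sum(axis=1)
    return float(out[0]) if scalar else out
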