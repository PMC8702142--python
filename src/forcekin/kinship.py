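"""Kinship likelihood ratios: pairwise, missing-person pedigree, X-chromosomal.

Every LR compares a related hypothesis H1 against unrelatedness H2,
LR = Pr(DNA | H1) / Pr(DNA | H2), with likelihoods from the linked-marker
inheritance-vector HMM (:mod:`forcekin.engine`).  Posterior probabilities
assume a flat prior over the tested hypothesis set; the default pairwise
report uses the two-hypothesis pair (posterior = LR / (1 + LR)).  A
prediction has *strong statistical support* when log10 LR >= 4 and the
posterior >= 99.99%.

The kappa-coefficient closed form for unlinked markers is provided both as
a fast unlinked mode and as the independent cross-check the test suite uses
against the multipoint engine.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .calling import CalledProfile, profile_dosages
from .engine import hwe_log_likelihood, pedigree_log_likelihood
from .panel import PanelManifest
from .pedigree import RELATIONSHIPS, Pedigree, relationship_template

logger = logging.getLogger(__name__)

LOG10_LR_STRONG = 4.0
POSTERIOR_STRONG = 0.9999
LN10 = np.log(10.0)

__all__ = [
    "LRResult",
    "prepare_markers",
    "kappa_log10_lr",
    "pairwise_log10_lr",
    "pairwise_lr",
    "missing_person_log10_lr",
    "missing_person_pedigree_lr",
    "x_chromosome_lr",
    "posteriors",
    "two_hypothesis_posterior",
    "is_strong_support",
    "blind_search",
]


@dataclass(frozen=True)
class LRResult:
    hypothesis: str
    log10_lr: float
    posterior: float
    n_markers_used: int
    strong_support: bool


def two_hypothesis_posterior(log10_lr: float) -> float:
    """Flat-prior posterior of H1 against the single alternative H2."""
    return float(1.0 / (1.0 + 10.0 ** (-np.asarray(log10_lr, dtype=float))))


def is_strong_support(log10_lr: float, posterior: float) -> bool:
    return log10_lr >= LOG10_LR_STRONG and posterior >= POSTERIOR_STRONG


def posteriors(log10_lrs: dict[str, float]) -> dict[str, float]:
    """Flat-prior posteriors over a hypothesis set given per-hypothesis
    log10 LRs (each against unrelated).  'unrelated' (log10 LR = 0) is
    added if absent; the result sums to 1."""
    lrs = dict(log10_lrs)
    lrs.setdefault("unrelated", 0.0)
    names = list(lrs)
    vals = np.array([lrs[h] for h in names]) * LN10
    if np.all(np.isneginf(vals)):
        raise ValueError("all hypothesis likelihoods are zero")
    log_z = logsumexp(vals)
    return {h: float(np.exp(v - log_z)) for h, v in zip(names, vals)}


def prepare_markers(
    panel: PanelManifest,
    population: str,
    categories: tuple[str, ...] = ("kinship",),
    mode: str = "autosomal",
) -> pd.DataFrame:
    """Marker table (snp_id, chrom, pos_cm, freq) for the LR engine.

    Autosomal mode draws from the requested autosomal categories; X mode
    uses X-SNPs.  Co-located markers are perturbed by 1e-6 cM with a
    warning so inter-marker gaps are strictly positive.
    """
    df = panel.df
    if mode == "X":
        sel = df["category"] == "X"
    else:
        sel = df["category"].isin(categories) & ~df["chrom"].isin(["X", "Y"])
    if (df.loc[sel, "category"] == "Y").any():
        raise ValueError("Y-category markers cannot be used for kinship LRs")
    out = df.loc[sel, ["snp_id", "chrom", "pos_cm", f"freq_{population}"]].rename(
        columns={f"freq_{population}": "freq"}
    )
    if out["pos_cm"].isna().any():
        raise ValueError("kinship markers need genetic positions")
    out = out.sort_values(["chrom", "pos_cm"], kind="stable").reset_index(drop=True)
    pos = out["pos_cm"].to_numpy().copy()
    for ch in out["chrom"].unique():
        idx = np.flatnonzero(out["chrom"] == ch)
        ties = np.flatnonzero(np.diff(pos[idx]) == 0)
        if len(ties):
            logger.warning("%d co-located markers on %s perturbed by 1e-6 cM",
                           len(ties), ch)
            for t in ties:
                pos[idx[t + 1]] = pos[idx[t]] + 1e-6
    out["pos_cm"] = pos
    return out


def kappa_log10_lr(
    dos_a: np.ndarray, dos_b: np.ndarray, freq: np.ndarray,
    kappa: tuple[float, float, float],
) -> float | np.ndarray:
    """Closed-form unlinked-marker log10 LR from IBD coefficients.

    Per marker, P(G_A, G_B | kappa) = k0 P(G_A) P(G_B)
    + k1 P(G_A) T(G_B | G_A) + k2 P(G_A) [G_A = G_B], where T conditions
    B's genotype on one allele shared IBD with A; the LR divides by the
    unrelated term.  Exact only when markers are unlinked.
    """
    dA = np.atleast_2d(np.asarray(dos_a, dtype=np.int64))
    dB = np.atleast_2d(np.asarray(dos_b, dtype=np.int64))
    scalar = np.asarray(dos_a).ndim == 1
    p = np.clip(np.asarray(freq, dtype=float), 1e-4, 1 - 1e-4)[None, :]
    q = 1.0 - p
    hwe = [q * q, 2 * p * q, p * p]

    def P(d):
        out = np.zeros(d.shape)
        for v in range(3):
            out = np.where(d == v, hwe[v], out)
        return out

    # T[dB | dA]: one allele IBD from A, the other from the population
    def T(dA_, dB_):
        out = np.zeros(dA_.shape)
        out = np.where((dA_ == 0) & (dB_ == 0), q, out)
        out = np.where((dA_ == 0) & (dB_ == 1), p, out)
        out = np.where((dA_ == 1) & (dB_ == 0), 0.5 * q, out)
        out = np.where((dA_ == 1) & (dB_ == 1), 0.5, out)
        out = np.where((dA_ == 1) & (dB_ == 2), 0.5 * p, out)
        out = np.where((dA_ == 2) & (dB_ == 1), q, out)
        out = np.where((dA_ == 2) & (dB_ == 2), p, out)
        return out

    k0, k1, k2 = kappa
    pa, pb = P(dA), P(dB)
    joint = k0 * pa * pb + k1 * pa * T(dA, dB) + k2 * pa * (dA == dB)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_marker = np.log10(joint) - np.log10(pa * pb)
    per_marker = np.where((dA < 0) | (dB < 0), 0.0, per_marker)
    out = per_marker.sum(axis=1)
    return float(out[0]) if scalar else out


def _count_shared(dA, dB):
    dA = np.atleast_2d(dA)
    dB = np.atleast_2d(dB)
    return ((dA >= 0) & (dB >= 0)).sum(axis=1)


def pairwise_log10_lr(
    dos_a: np.ndarray,
    dos_b: np.ndarray,
    hypothesis: str,
    markers: pd.DataFrame,
    *,
    mode: str = "autosomal",
    sexes: tuple[str, str] = ("M", "F"),
    error_rate: float = 0.0,
    unlinked: bool = False,
):
    """log10 LR for a pairwise relationship hypothesis vs unrelated.

    Accepts single dosage vectors or batches (B, n_markers).  ``unlinked``
    switches to the kappa closed form (valid only for unlinked markers,
    autosomal mode).
    """
    hyp = RELATIONSHIPS[hypothesis]
    if hypothesis == "unrelated":
        base = np.zeros(np.atleast_2d(dos_a).shape[0])
        return float(base[0]) if np.asarray(dos_a).ndim == 1 else base
    if unlinked:
        if mode != "autosomal":
            raise ValueError("unlinked closed form is autosomal-only")
        return kappa_log10_lr(dos_a, dos_b, markers["freq"].to_numpy(), hyp.kappa)
    ped, a_id, b_id = relationship_template(hypothesis, *sexes)
    l1 = pedigree_log_likelihood(
        ped, {a_id: dos_a, b_id: dos_b}, markers, mode, error_rate=error_rate
    )
    freq = markers["freq"].to_numpy()
    if mode == "X":
        pl_a = 1 if sexes[0] == "M" else 2
        pl_b = 1 if sexes[1] == "M" else 2
    else:
        pl_a = pl_b = 2
    l0 = hwe_log_likelihood(dos_a, freq, pl_a) + hwe_log_likelihood(dos_b, freq, pl_b)
    return (l1 - l0) / LN10


def pairwise_lr(
    profile_a: CalledProfile,
    profile_b: CalledProfile,
    hypothesis: str,
    panel: PanelManifest,
    population: str = "EUR",
    *,
    error_rate: float = 0.0,
) -> LRResult:
    """Pairwise kinship LR between two called profiles (autosomal
    kinship-category SNPs only; imbalanced and uncalled sites are never
    used)."""
    markers = prepare_markers(panel, population)
    dA = profile_dosages(profile_a, markers, panel)
    dB = profile_dosages(profile_b, markers, panel)
    n_shared = int(_count_shared(dA, dB)[0])
    if n_shared == 0:
        logger.warning("no shared called kinship markers; LR = 1")
        return LRResult(hypothesis, 0.0, 0.5, 0, False)
    l10 = float(
        pairwise_log10_lr(dA, dB, hypothesis, markers, error_rate=error_rate)
    )
    post = two_hypothesis_posterior(l10)
    return LRResult(hypothesis, l10, post, n_shared, is_strong_support(l10, post))


def missing_person_log10_lr(
    family: Pedigree,
    missing_id: str,
    reference_dosages: dict[str, np.ndarray],
    unknown_dosage: np.ndarray,
    markers: pd.DataFrame,
    *,
    error_rate: float = 0.0,
):
    """log10 LR that the unknown sample is the pedigree's missing member
    versus an unrelated individual.

    LR = L(pedigree with the unknown placed in the missing slot) /
    [L(pedigree, slot untyped) * L(unknown alone under HWE)].
    """
    if missing_id not in family:
        raise KeyError(f"missing person {missing_id!r} not in pedigree")
    if missing_id in reference_dosages:
        raise ValueError("missing person cannot also be a typed reference")
    geno1 = dict(reference_dosages)
    geno1[missing_id] = unknown_dosage
    l1 = pedigree_log_likelihood(family, geno1, markers, error_rate=error_rate)
    l_refs = pedigree_log_likelihood(
        family, reference_dosages, markers, error_rate=error_rate
    )
    l_unk = hwe_log_likelihood(unknown_dosage, markers["freq"].to_numpy(), 2)
    return (l1 - (l_refs + l_unk)) / LN10


def missing_person_pedigree_lr(
    family: Pedigree,
    missing_id: str,
    reference_profiles: dict[str, CalledProfile],
    unknown_profile: CalledProfile,
    panel: PanelManifest,
    population: str = "EUR",
    *,
    error_rate: float = 0.0,
) -> LRResult:
    markers = prepare_markers(panel, population)
    refs = {
        iid: profile_dosages(p, markers, panel)
        for iid, p in reference_profiles.items()
    }
    unk = profile_dosages(unknown_profile, markers, panel)
    n_used = int((unk >= 0).sum())
    if n_used == 0:
        raise ValueError("unknown profile has zero called kinship SNPs")
    l10 = float(
        missing_person_log10_lr(
            family, missing_id, refs, unk, markers, error_rate=error_rate
        )
    )
    post = two_hypothesis_posterior(l10)
    return LRResult("missing_person", l10, post, n_used, is_strong_support(l10, post))


def x_chromosome_lr(
    profile_a: CalledProfile,
    profile_b: CalledProfile,
    panel: PanelManifest,
    population: str = "EUR",
    hypothesis: str = "full_siblings",
    *,
    error_rate: float = 0.0,
) -> LRResult:
    """Pairwise LR from X-SNPs under X-chromosomal inheritance (males
    hemizygous; father-to-daughter transmission deterministic)."""
    if profile_a.sex not in "MF" or profile_b.sex not in "MF":
        raise ValueError("X-chromosomal LR requires known sexes")
    markers = prepare_markers(panel, population, mode="X")
    dA = profile_dosages(profile_a, markers, panel)
    dB = profile_dosages(profile_b, markers, panel)
    n_shared = int(_count_shared(dA, dB)[0])
    if n_shared == 0:
        return LRResult(hypothesis, 0.0, 0.5, 0, False)
    l10 = float(
        pairwise_log10_lr(
            dA, dB, hypothesis, markers, mode="X",
            sexes=(profile_a.sex, profile_b.sex), error_rate=error_rate,
        )
    )
    post = two_hypothesis_posterior(l10)
    return LRResult(hypothesis, l10, post, n_shared, is_strong_support(l10, post))


def hypotheses_up_to(max_degree: int) -> list[str]:
    return [
        name
        for name, h in RELATIONSHIPS.items()
        if h.degree is not None and h.degree <= max_degree
    ]


def blind_search(
    dosages: dict[str, np.ndarray],
    markers: pd.DataFrame,
    max_degree: int = 6,
    *,
    pairs: list[tuple[str, str]] | None = None,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """All-pairs kinship screen.

    For every unordered pair of profiles (or an explicit ``pairs`` list),
    LRs for all relationship hypotheses up to ``max_degree`` are computed
    (batched over pairs); the best related hypothesis is reported with its
    flat-prior posterior over the tested set (including unrelated) and the
    strong-support flag.
    """
    ids = list(dosages)
    if pairs is None:
        pairs = list(itertools.combinations(ids, 2))
    if not pairs:
        return pd.DataFrame(
            columns=["id_a", "id_b", "best_hypothesis", "log10_lr",
                     "posterior", "strong_support"]
        )
    dA = np.stack([dosages[a] for a, _ in pairs])
    dB = np.stack([dosages[b] for _, b in pairs])
    hyps = hypotheses_up_to(max_degree)
    lrs = {
        h: np.asarray(pairwise_log10_lr(dA, dB, h, markers, error_rate=error_rate))
        for h in hyps
    }
    rows = []
    for i, (a, b) in enumerate(pairs):
        per_pair = {h: float(lrs[h][i]) for h in hyps}
        post = posteriors(per_pair)
        best = max(per_pair, key=per_pair.get)
        l10 = per_pair[best]
        rows.append(
            {
                "id_a": a,
                "id_b": b,
                "best_hypothesis": best,
                "log10_lr": l10,
                "posterior": post[best],
                "strong_support": is_strong_support(l10, post[best]),
            }
        )
    return pd.DataFrame(rows)
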