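"""Synthetic inputs: population frequencies, pedigree genotypes, sequencing
observations.

This module generates everything the downstream pipeline consumes, emulating
the study conditions the real laboratory data provided:

* continental allele-frequency structure via the Balding-Nichols model,
* pedigree genotypes by gene dropping with recombination over a genetic map
  (Haldane map function, no interference; founders drawn in Hardy-Weinberg
  and linkage equilibrium — appropriate for an LD-pruned panel),
* per-site coverage / allele-count observations with negative-binomial
  coverage, per-site dropout and a symmetric per-read allele-flip error,
  with presets for high-quality reference samples and degraded bone samples.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import haldane_theta
from .panel import FREQ_COLS, POPULATIONS, GeneticMap, PanelManifest
from .pedigree import FEMALE, MALE, Pedigree

__all__ = [
    "SeqModelParams",
    "REFERENCE_PRESET",
    "BONE_PRESET",
    "TrueGenotypes",
    "build_panel_skeleton",
    "fixture_genetic_map",
    "generate_population_frequencies",
    "simulate_pedigree_genotypes",
    "simulate_observations",
    "subsample_panel",
]

# human autosome genetic lengths, cM (sex-averaged, rounded)
AUTOSOME_CM = {
    "1": 286, "2": 269, "3": 232, "4": 214, "5": 209, "6": 194, "7": 187,
    "8": 169, "9": 167, "10": 174, "11": 161, "12": 176, "13": 131,
    "14": 125, "15": 132, "16": 134, "17": 137, "18": 129, "19": 111,
    "20": 115, "21": 70, "22": 79,
}
X_CM = 181
BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SeqModelParams:
    """Sequencing observation model.

    coverage ~ NegativeBinomial(mean=mean_cov, dispersion), zeroed at
    dropout sites; each read reports an allele drawn uniformly from the
    genotype, flipped to the other panel allele with probability
    ``error_rate``.
    """

    mean_cov: float = 225.0
    dispersion: float = 5.0
    error_rate: float = 0.005
    dropout_frac: float = 0.005
    lowq_flag_rate: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.mean_cov <= 0 or self.dispersion <= 0:
            raise ValueError("mean_cov and dispersion must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0 <= self.dropout_frac <= 1):
            raise ValueError("dropout_frac must be in [0, 1]")


REFERENCE_PRESET = SeqModelParams(225.0, 5.0, 0.005, 0.005)
BONE_PRESET = SeqModelParams(8.0, 1.0, 0.01, 0.3)


@dataclass
class TrueGenotypes:
    """Simulated truth: per individual, an (n_panel, 2) allele array.

    Alleles are alt-indicators (0 = ref, 1 = alt); -1 marks an absent copy
    (paternal column of male X sites, Y sites of females and the second Y
    column of males).  Columns are ordered (paternal, maternal); Y alleles
    sit in the paternal column.
    """

    panel: PanelManifest
    alleles: dict[str, np.ndarray]
    sexes: dict[str, str]

    def dosage(self, iid: str, rows: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele dosage per panel row (hemizygous sites 0/1; -1 where
        the individual carries no copy)."""
        a = self.alleles[iid]
        if rows is not None:
            a = a[rows]
        present = a >= 0
        d = np.where(present, a, 0).sum(axis=1)
        return np.where(present.any(axis=1), d, -1)


def _chrom_plan(n: int, lengths: Mapping[str, int]) -> list[tuple[str, int]]:
    total = sum(lengths.values())
    plan, assigned = [], 0
    items = list(lengths.items())
    for i, (ch, L) in enumerate(items):
        k = n - assigned if i == len(items) - 1 else max(1, round(n * L / total))
        plan.append((ch, min(k, n - assigned)))
        assigned += plan[-1][1]
    return plan


def build_panel_skeleton(
    n_kinship: int = 3931,
    n_ii: int = 134,
    n_ai: int = 241,
    n_pi: int = 41,
    n_x: int = 246,
    n_y: int = 829,
    seed: int = 0,
) -> PanelManifest:
    """A synthetic panel skeleton on a linear 1 cM / Mbp genome.

    Kinship (and X) SNPs are evenly spaced so the design spacing criterion
    holds by construction; placeholder frequencies (0.5) are filled in by
    :func:`generate_population_frequencies`.  Defaults reproduce the
    category composition of the full assay (5422 markers).
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(snp_id, chrom, pos_cm, category):
        ref, alt = rng.choice(4, size=2, replace=False)
        pos_bp = int(round(pos_cm * 1e6)) if pos_cm is not None else len(rows) + 1
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "pos_bp": pos_bp,
                "pos_cm": np.nan if pos_cm is None else pos_cm,
                "ref": BASES[ref],
                "alt": BASES[alt],
                **{c: 0.5 for c in FREQ_COLS},
                "category": category,
                "n_baits": 4 if category not in ("X", "Y") else 2,
            }
        )

    counter = 0
    for cat, n in (("kinship", n_kinship), ("iiSNP", n_ii), ("aiSNP", n_ai),
                   ("piSNP", n_pi)):
        offset = {"kinship": 0.0, "iiSNP": 0.11, "aiSNP": 0.23, "piSNP": 0.37}[cat]
        for ch, k in _chrom_plan(n, AUTOSOME_CM):
            L = AUTOSOME_CM[ch]
            step = L / (k + 1)
            for i in range(k):
                counter += 1
                add(f"rs{cat[:2]}{counter:06d}", ch, (i + 1) * step + offset, cat)
    for i in range(n_x):
        counter += 1
        add(f"rsX{counter:06d}", "X", (i + 1) * X_CM / (n_x + 1), "X")
    for i in range(n_y):
        counter += 1
        add(f"rsY{counter:06d}", "Y", None, "Y")
        rows[-1]["pos_bp"] = (i + 1) * 10_000
    df = pd.DataFrame(rows).sort_values(["chrom", "pos_bp"], kind="stable")
    return PanelManifest(df)


def fixture_genetic_map() -> GeneticMap:
    """The linear 1 cM / Mbp map matching :func:`build_panel_skeleton`."""
    anchors = {
        ch: (np.array([1, int(L * 1e6)]), np.array([0.0, float(L)]))
        for ch, L in {**AUTOSOME_CM, "X": X_CM}.items()
    }
    return GeneticMap(anchors)


def generate_population_frequencies(
    panel: PanelManifest,
    fst: float = 0.1,
    ai_fst: float = 0.35,
    seed: int = 0,
) -> PanelManifest:
    """Fill per-population alt-allele frequencies via Balding-Nichols.

    Per SNP an ancestral frequency p ~ Uniform(0.05, 0.95) is drawn and each
    population's frequency comes from Beta(p(1-F)/F, (1-p)(1-F)/F).
    Ancestry-informative SNPs use the larger divergence ``ai_fst`` so the
    continental groups separate clearly.
    """
    for f in (fst, ai_fst):
        if not (0 < f < 1):
            raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    df = panel.df.copy()
    n = len(df)
    p = rng.uniform(0.05, 0.95, size=n)
    F = np.where(df["category"].to_numpy() == "aiSNP", ai_fst, fst)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    for col in FREQ_COLS:
        df[col] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    return PanelManifest(df)


def _gamete(hap: np.ndarray, theta: np.ndarray, rng) -> np.ndarray:
    """One recombinant gamete from an (n, 2) haplotype pair."""
    n = hap.shape[0]
    sw = np.empty(n, dtype=np.int8)
    sw[0] = rng.integers(0, 2)
    if n > 1:
        flips = (rng.random(n - 1) < theta).astype(np.int8)
        sw[1:] = flips
        sw = np.bitwise_xor.accumulate(sw)
    return hap[np.arange(n), sw]


def simulate_pedigree_genotypes(
    ped: Pedigree,
    panel: PanelManifest,
    population: str = "EUR",
    seed: int = 0,
) -> TrueGenotypes:
    """Gene-drop genotypes for every pedigree member over the whole panel.

    Founder haplotypes are iid Bernoulli(freq) draws (HWE, linkage
    equilibrium); each meiosis transmits a recombinant haplotype with
    inter-marker switch probabilities from the Haldane map function.  X
    sites: fathers pass their single X to daughters; sons carry no paternal
    X.  Y sites are copied down patrilines without mutation.
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    rng = np.random.default_rng(seed)
    df = panel.df
    n = len(df)
    freq = df[f"freq_{population}"].to_numpy(dtype=float)
    cat = df["category"].to_numpy()
    chrom = df["chrom"].to_numpy()
    is_y = cat == "Y"
    is_x = cat == "X"
    is_auto = ~is_y & ~is_x
    if (~is_y & df["pos_cm"].isna().to_numpy()).any():
        raise ValueError("autosomal/X panel SNPs need genetic positions")
    pos = df["pos_cm"].to_numpy(dtype=float)

    # per-chromosome autosomal blocks (X handled separately)
    blocks = []
    for ch in pd.unique(chrom[is_auto]):
        idx = np.flatnonzero(is_auto & (chrom == ch))
        blocks.append(idx)
    x_idx = np.flatnonzero(is_x)
    y_idx = np.flatnonzero(is_y)
    thetas = [haldane_theta(np.diff(pos[idx])) for idx in blocks]
    x_theta = haldane_theta(np.diff(pos[x_idx])) if len(x_idx) > 1 else np.empty(0)

    out: dict[str, np.ndarray] = {}
    sexes: dict[str, str] = {}
    for iid in ped.topo_order():
        ind = ped.members[iid]
        sexes[iid] = ind.sex
        g = np.full((n, 2), -1, dtype=np.int8)
        if ind.is_founder:
            for idx in blocks:
                g[idx] = rng.random((len(idx), 2)) < freq[idx, None]
            if ind.sex == FEMALE:
                g[x_idx] = rng.random((len(x_idx), 2)) < freq[x_idx, None]
            else:
                g[x_idx, 1] = rng.random(len(x_idx)) < freq[x_idx]
                g[y_idx, 0] = rng.random(len(y_idx)) < freq[y_idx]
        else:
            fa, mo = out[ind.father], out[ind.mother]
            for idx, th in zip(blocks, thetas):
                g[idx, 0] = _gamete(fa[idx], th, rng)
                g[idx, 1] = _gamete(mo[idx], th, rng)
            g[x_idx, 1] = _gamete(mo[x_idx], x_theta, rng)
            if ind.sex == FEMALE:
                g[x_idx, 0] = fa[x_idx, 1]  # father's single X
            else:
                g[y_idx, 0] = fa[y_idx, 0]  # patrilineal Y
        out[iid] = g
    return TrueGenotypes(panel, out, sexes)


def simulate_observations(
    truth: TrueGenotypes,
    params: SeqModelParams,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Coverage / allele-count observations for each (typed) individual.

    Returns a long-format table (sample_id, snp_id, coverage, count_A,
    count_C, count_G, count_T, lowq_minor_flag); sites where the individual
    carries no copy (female Y sites) emit no row.  Read counts always sum
    to coverage.
    """
    rng = np.random.default_rng(params.seed)
    df = truth.panel.df
    ref = df["ref"].to_numpy()
    alt = df["alt"].to_numpy()
    snp_ids = df["snp_id"].to_numpy()
    frames = []
    for iid in sample_ids if sample_ids is not None else truth.alleles:
        g = truth.alleles[iid]
        present = g >= 0
        ploidy = present.sum(axis=1)
        rows = np.flatnonzero(ploidy > 0)
        k = len(rows)
        nb_p = params.dispersion / (params.dispersion + params.mean_cov)
        cov = rng.negative_binomial(params.dispersion, nb_p, size=k)
        cov[rng.random(k) < params.dropout_frac] = 0
        dos = np.where(present[rows], g[rows], 0).sum(axis=1)
        pl = ploidy[rows]
        # per-read P(read alt) after the symmetric flip error
        p_alt_true = dos / pl
        e = params.error_rate
        p_alt = p_alt_true * (1 - e) + (1 - p_alt_true) * e
        n_alt = rng.binomial(cov, p_alt)
        n_ref = cov - n_alt
        counts = {b: np.zeros(k, dtype=np.int64) for b in "ACGT"}
        for b in "ACGT":
            sel_r = ref[rows] == b
            counts[b][sel_r] += n_ref[sel_r]
            sel_a = alt[rows] == b
            counts[b][sel_a] += n_alt[sel_a]
        is_hom = (p_alt_true == 0.0) | (p_alt_true == 1.0)
        minor = np.minimum(n_alt, n_ref)
        flag = is_hom & (minor > 0) & (rng.random(k) < params.lowq_flag_rate)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": iid,
                    "snp_id": snp_ids[rows],
                    "coverage": cov,
                    "count_A": counts["A"],
                    "count_C": counts["C"],
                    "count_G": counts["G"],
                    "count_T": counts["T"],
                    "lowq_minor_flag": flag,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def subsample_panel(obj, panel: PanelManifest, fraction: float, seed: int = 0):
    """Retain a uniformly random round(fraction * n) subset of the
    kinship-category SNPs; all other markers are untouched.

    ``obj`` may be an observation DataFrame or a
    :class:`~forcekin.calling.CalledProfile`.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    kin_ids = panel.category("kinship")["snp_id"].to_numpy()
    if len(kin_ids) == 0:
        raise ValueError("panel has no kinship SNPs")
    if fraction == 1.0:
        return obj
    rng = np.random.default_rng(seed)
    n_keep = round(fraction * len(kin_ids))
    keep = set(rng.choice(kin_ids, size=n_keep, replace=False))
    drop = set(kin_ids) - keep
    if isinstance(obj, pd.DataFrame):
        return obj[~obj["snp_id"].isin(drop)].reset_index(drop=True)
    from .calling import CalledProfile  # local to avoid a cycle

    if isinstance(obj, CalledProfile):
        sites = {s: v for s, v in obj.sites.items() if s not in drop}
        return CalledProfile(obj.sample_id, obj.sex, sites, panel)
    raise TypeError(f"cannot subsample {type(obj).__name__}")
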