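"""Panel data model, manifest I/O, and the kinship-SNP selection cascade.

A marker panel is represented by :class:`PanelManifest`, a thin validated
wrapper around a pandas DataFrame with one row per SNP.  The design cascade
(:func:`design_kinship_panel`) applies, in order: chip intersection, a
per-population frequency window, genetic-distance thinning, LD pruning
against a reference genotype matrix, a cap on between-population frequency
differences, and a clinical-region exclusion list, reporting the number of
surviving candidates after each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")
FREQ_COLS = tuple(f"freq_{p}" for p in POPULATIONS)
CATEGORIES = ("kinship", "iiSNP", "aiSNP", "piSNP", "X", "Y")
MANIFEST_COLUMNS = (
    "snp_id",
    "chrom",
    "pos_bp",
    "pos_cm",
    "ref",
    "alt",
    *FREQ_COLS,
    "category",
    "n_baits",
)

__all__ = [
    "POPULATIONS",
    "FREQ_COLS",
    "CATEGORIES",
    "PanelSNP",
    "PanelManifest",
    "GeneticMap",
    "DesignParams",
    "read_manifest",
    "write_manifest",
    "intersect_chip_candidates",
    "filter_frequency_range",
    "thin_by_genetic_distance",
    "prune_by_ld",
    "filter_population_differentiation",
    "exclude_regions",
    "design_kinship_panel",
    "read_blocklist_bed",
]


@dataclass(frozen=True)
class PanelSNP:
    """One panel marker."""

    snp_id: str
    chrom: str
    pos_bp: int
    pos_cm: float | None
    ref_allele: str
    alt_allele: str
    freq: dict[str, float]
    category: str
    n_baits: int = 0

    @property
    def maf(self) -> dict[str, float]:
        """Folded minor-allele frequency per population."""
        return {p: min(f, 1.0 - f) for p, f in self.freq.items()}


@dataclass(frozen=True)
class DesignParams:
    """Kinship-SNP selection thresholds.

    ``freq_mode`` selects how the 0.2-0.8 frequency window is read:
    ``"alt"`` applies it to the designated (alt) allele frequency (the
    chip-annotation convention), ``"maf"`` to the folded minor-allele
    frequency.
    """

    freq_lo: float = 0.2
    freq_hi: float = 0.8
    min_cm: float = 0.5
    r2_max: float = 0.1
    max_pop_diff: float = 0.35
    ld_window_cm: float = 10.0
    freq_mode: str = "alt"

    def __post_init__(self):
        if not (0 <= self.freq_lo < self.freq_hi <= 1):
            raise ValueError("require 0 <= freq_lo < freq_hi <= 1")
        if self.min_cm <= 0:
            raise ValueError("min_cm must be positive")
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must be in (0, 1]")
        if not (0 < self.max_pop_diff <= 1):
            raise ValueError("max_pop_diff must be in (0, 1]")
        if self.freq_mode not in ("alt", "maf"):
            raise ValueError("freq_mode must be 'alt' or 'maf'")


class GeneticMap:
    """Per-chromosome (pos_bp, pos_cm) anchors with linear interpolation."""

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.anchors = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(bp)
            bp, cm = bp[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: pos_cm must be non-decreasing in pos_bp")
            self.anchors[chrom] = (bp, cm)

    def interpolate(self, chrom: str, pos_bp: np.ndarray) -> np.ndarray:
        """Genetic positions for physical positions; NaN outside anchor range."""
        pos = np.asarray(pos_bp, dtype=np.int64)
        if chrom not in self.anchors:
            return np.full(pos.shape, np.nan)
        bp, cm = self.anchors[chrom]
        out = np.interp(pos, bp, cm)
        out = np.where((pos < bp[0]) | (pos > bp[-1]), np.nan, out)
        return out

    @classmethod
    def read(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        need = {"chrom", "pos_bp", "pos_cm"}
        if not need.issubset(df.columns):
            raise ValueError(f"genetic map must have columns {sorted(need)}")
        return cls(
            {
                str(ch): (g["pos_bp"].to_numpy(), g["pos_cm"].to_numpy())
                for ch, g in df.groupby("chrom")
            }
        )

    def write(self, path: str | Path) -> None:
        rows = []
        for ch, (bp, cm) in self.anchors.items():
            rows.append(pd.DataFrame({"chrom": ch, "pos_bp": bp, "pos_cm": cm}))
        pd.concat(rows).to_csv(path, sep="\t", index=False)


class PanelManifest:
    """Ordered, validated collection of panel SNPs."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        dup = df["snp_id"][df["snp_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate snp_id: {sorted(set(dup))[:5]}")
        for i, row in df.iterrows():
            rowno = i + 2  # header is line 1
            if row["category"] not in CATEGORIES:
                raise ValueError(
                    f"row {rowno}: unknown category {row['category']!r}"
                )
            if row["pos_bp"] < 1:
                raise ValueError(f"row {rowno}: pos_bp must be >= 1")
            if row["ref"] == row["alt"]:
                raise ValueError(f"row {rowno}: ref equals alt")
            for col in FREQ_COLS:
                f = row[col]
                if not (0.0 <= f <= 1.0):
                    raise ValueError(
                        f"row {rowno}: column {col} value {f} outside [0, 1]"
                    )
            if row["category"] == "Y" and pd.notna(row["pos_cm"]):
                raise ValueError(f"row {rowno}: Y-SNPs carry no genetic position")
        # manifest sorted by position within chromosome
        for ch, g in df.groupby("chrom", sort=False):
            if not g["pos_bp"].is_monotonic_increasing:
                raise ValueError(f"manifest not sorted by pos_bp on {ch}")
        self.df = df

    @property
    def category_counts(self) -> dict[str, int]:
        return self.df["category"].value_counts().to_dict()

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, snp_ids: Iterable[str]) -> "PanelManifest":
        keep = set(snp_ids)
        return PanelManifest(self.df[self.df["snp_id"].isin(keep)])

    def category(self, *cats: str) -> pd.DataFrame:
        return self.df[self.df["category"].isin(cats)]

    def snps(self) -> list[PanelSNP]:
        out = []
        for _, r in self.df.iterrows():
            out.append(
                PanelSNP(
                    snp_id=r["snp_id"],
                    chrom=str(r["chrom"]),
                    pos_bp=int(r["pos_bp"]),
                    pos_cm=None if pd.isna(r["pos_cm"]) else float(r["pos_cm"]),
                    ref_allele=r["ref"],
                    alt_allele=r["alt"],
                    freq={p: float(r[f"freq_{p}"]) for p in POPULATIONS},
                    category=r["category"],
                    n_baits=int(r["n_baits"]),
                )
            )
        return out


def read_manifest(path: str | Path) -> PanelManifest:
    """Read and validate a panel manifest TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "snp_id": str})
    return PanelManifest(df)


def write_manifest(manifest: PanelManifest, path: str | Path) -> None:
    manifest.df.to_csv(path, sep="\t", index=False)


def intersect_chip_candidates(*chip_lists: Iterable[str]) -> set[str]:
    """SNP ids present on every chip (requires at least two chip lists)."""
    sets = [set(c) for c in chip_lists]
    if len(sets) < 2:
        raise ValueError("need at least two chip lists to intersect")
    if any(not s for s in sets):
        raise ValueError("chip lists must be non-empty")
    out = set.intersection(*sets)
    if not out:
        logger.warning("chip intersection is empty")
    return out


def _freq_window_value(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    vals = df[list(FREQ_COLS)]
    if mode == "maf":
        return np.minimum(vals, 1.0 - vals)
    return vals


def filter_frequency_range(df: pd.DataFrame, params: DesignParams) -> pd.DataFrame:
    """Retain SNPs whose (alt or folded) frequency lies in the window in
    every population; rows with missing frequencies are excluded."""
    vals = _freq_window_value(df, params.freq_mode)
    complete = vals.notna().all(axis=1)
    if (~complete).any():
        logger.info("frequency filter: %d rows missing a population frequency",
                    int((~complete).sum()))
    ok = complete & (vals >= params.freq_lo).all(axis=1) & (
        vals <= params.freq_hi
    ).all(axis=1)
    return df[ok]


def thin_by_genetic_distance(
    df: pd.DataFrame, genetic_map: GeneticMap | None, params: DesignParams
) -> pd.DataFrame:
    """Greedy left-to-right per-chromosome thinning to >= min_cm spacing.

    Genetic positions absent from the manifest are interpolated from the
    map; SNPs outside the map's anchor range are excluded.  Co-located SNPs
    are ranked so the one with mean folded MAF closest to 0.5 wins.
    """
    df = df.copy()
    cm = df["pos_cm"].to_numpy(dtype=float)
    if genetic_map is not None:
        for ch in df["chrom"].unique():
            sel = (df["chrom"] == ch).to_numpy() & np.isnan(cm)
            if sel.any():
                cm[sel] = genetic_map.interpolate(str(ch), df.loc[sel, "pos_bp"])
    df["pos_cm"] = cm
    uncovered = df["pos_cm"].isna()
    if uncovered.any():
        logger.info("cM thinning: %d SNPs not coverable by the genetic map",
                    int(uncovered.sum()))
        df = df[~uncovered]
    maf = np.minimum(df[list(FREQ_COLS)], 1.0 - df[list(FREQ_COLS)]).mean(axis=1)
    df = df.assign(_tie=np.abs(0.5 - maf)).sort_values(
        ["chrom", "pos_cm", "_tie"], kind="stable"
    )
    keep_idx = []
    for _, g in df.groupby("chrom", sort=False):
        last = -np.inf
        for idx, p in zip(g.index, g["pos_cm"]):
            if p - last >= params.min_cm or not np.isfinite(last):
                keep_idx.append(idx)
                last = p
    out = df.loc[keep_idx].drop(columns="_tie")
    return out.sort_values(["chrom", "pos_bp"], kind="stable")


def prune_by_ld(
    df: pd.DataFrame,
    ref_genotypes: pd.DataFrame,
    params: DesignParams,
) -> pd.DataFrame:
    """Greedy LD pruning: within a chromosome, a SNP is dropped when its
    squared Pearson dosage correlation with any earlier retained SNP inside
    the window reaches ``r2_max``.

    ``ref_genotypes`` is a samples x SNPs dosage matrix (columns keyed by
    snp_id, values in {0, 1, 2}).
    """
    keep_rows = []
    for ch, g in df.sort_values(["chrom", "pos_bp"]).groupby("chrom", sort=False):
        kept: list[tuple[float, np.ndarray]] = []  # (pos_cm, standardized dosage)
        for _, row in g.iterrows():
            sid = row["snp_id"]
            if sid not in ref_genotypes.columns:
                logger.info("LD pruning: no reference genotypes for %s", sid)
                continue
            x = ref_genotypes[sid].to_numpy(dtype=float)
            sd = x.std()
            if sd == 0:
                logger.info("LD pruning: %s has zero variance in reference", sid)
                continue
            z = (x - x.mean()) / sd
            pos = row["pos_cm"] if pd.notna(row["pos_cm"]) else np.nan
            ok = True
            for kpos, kz in kept:
                if np.isfinite(pos) and np.isfinite(kpos) and abs(pos - kpos) > params.ld_window_cm:
                    continue
                r2 = (z @ kz / len(z)) ** 2
                if r2 >= params.r2_max:
                    ok = False
                    break
            if ok:
                kept.append((pos, z))
                keep_rows.append(row.name)
    return df.loc[keep_rows]


def filter_population_differentiation(
    df: pd.DataFrame, params: DesignParams
) -> pd.DataFrame:
    """Retain SNPs whose max between-population frequency difference is
    strictly below ``max_pop_diff``."""
    vals = df[list(FREQ_COLS)]
    complete = vals.notna().all(axis=1)
    diff = vals.max(axis=1) - vals.min(axis=1)
    return df[complete & (diff < params.max_pop_diff)]


def read_blocklist_bed(path: str | Path) -> set[tuple[str, int, int]]:
    """Read a BED blocklist (0-based half-open) into 1-based half-open
    (chrom, start, end) intervals."""
    out = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected 3+ BED columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            out.add((chrom, s + 1, e + 1))
    return out


def exclude_regions(
    df: pd.DataFrame, blocklist: set[tuple[str, int, int]]
) -> pd.DataFrame:
    """Remove SNPs whose position falls in any 1-based half-open interval."""
    for chrom, start, end in blocklist:
        if start >= end:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
    drop = pd.Series(False, index=df.index)
    for chrom, start, end in blocklist:
        drop |= (
            (df["chrom"].astype(str) == str(chrom))
            & (df["pos_bp"] >= start)
            & (df["pos_bp"] < end)
        )
    return df[~drop]


def design_kinship_panel(
    candidates: pd.DataFrame,
    chip_lists: Sequence[Iterable[str]],
    genetic_map: GeneticMap | None,
    ref_genotypes: pd.DataFrame,
    blocklist: set[tuple[str, int, int]],
    params: DesignParams = DesignParams(),
) -> tuple[PanelManifest, pd.DataFrame]:
    """Run the full selection cascade and report per-step attrition.

    Steps, in order: chip intersection, frequency window, genetic-distance
    thinning, LD pruning, population-differentiation cap, clinical-region
    exclusion.  Returns the resulting kinship manifest and a DataFrame with
    one row per step (columns ``step``, ``n_remaining``).
    """
    steps: list[tuple[str, int]] = []
    df = candidates.copy()
    on_chips = intersect_chip_candidates(*chip_lists) if chip_lists else None
    if on_chips is not None:
        df = df[df["snp_id"].isin(on_chips)]
    steps.append(("chip_intersection", len(df)))
    df = filter_frequency_range(df, params)
    steps.append(("frequency_window", len(df)))
    df = thin_by_genetic_distance(df, genetic_map, params)
    steps.append(("cm_thinning", len(df)))
    df = prune_by_ld(df, ref_genotypes, params)
    steps.append(("ld_pruning", len(df)))
    df = filter_population_differentiation(df, params)
    steps.append(("population_differentiation", len(df)))
    df = exclude_regions(df, blocklist)
    steps.append(("clinical_exclusion", len(df)))
    for (name, n), (_, n_prev) in zip(steps[1:], steps):
        logger.info("design cascade %s: %d -> %d", name, n_prev, n)
    out = df.copy()
    out["category"] = "kinship"
    if "n_baits" not in out.columns:
        out["n_baits"] = 4
    manifest = PanelManifest(out.sort_values(["chrom", "pos_bp"], kind="stable"))
    report = pd.DataFrame(steps, columns=["step", "n_remaining"])
    return manifest, report
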