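"""Threshold-based genotype calling from coverage / allele counts.

A site needs at least 10 reads to be analysed.  With major-allele read
fraction f and minor fraction m = 1 - f over the top two observed alleles:
m <= 0.10 calls a homozygote, m >= 0.30 calls a heterozygote (diploid
sites), and the in-between band 0.10 < m < 0.30 is flagged "imbalanced" and
excluded from every downstream analysis.  Hemizygous sites (Y, male X) are
called under the homozygote rule only.

The module also computes profile completeness against the sex-adjusted
maximum (females cannot call Y-SNPs), concordance summaries against truth
or published genotypes, and TSV / VCF profile export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelManifest

logger = logging.getLogger(__name__)

MIN_COVERAGE = 10
HOM_MAX_MINOR = 0.10
HET_MIN_MINOR = 0.30
Y_SEX_INFER_MIN_SITES = 50

__all__ = [
    "SiteObservation",
    "CalledSite",
    "CalledProfile",
    "call_site",
    "call_profile",
    "resolve_artifact_minor",
    "concordance_report",
    "concordance_percent",
    "specificity_fold_change",
    "read_observations",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_profile_vcf",
    "profile_dosages",
]


@dataclass(frozen=True)
class SiteObservation:
    """Per-SNP read counts for one sample."""

    snp_id: str
    coverage: int
    allele_counts: dict[str, int]
    lowq_minor_flag: bool = False

    def __post_init__(self):
        if any(c < 0 for c in self.allele_counts.values()):
            raise ValueError(f"{self.snp_id}: negative allele count")
        if sum(self.allele_counts.values()) != self.coverage:
            raise ValueError(f"{self.snp_id}: allele counts must sum to coverage")


@dataclass(frozen=True)
class CalledSite:
    snp_id: str
    status: str  # called | imbalanced | no_call
    genotype: tuple[str, ...] | None
    coverage: int
    minor_fraction: float
    major_allele: str | None = None
    lowq_minor_flag: bool = False
    # homozygote noted for an imbalanced site after artifact-minor removal;
    # used only in concordance accounting, never downstream
    noted_genotype: tuple[str, ...] | None = None


def call_site(
    obs: SiteObservation,
    ploidy: int = 2,
    *,
    min_coverage: int = MIN_COVERAGE,
    hom_max_minor: float = HOM_MAX_MINOR,
    het_min_minor: float = HET_MIN_MINOR,
) -> CalledSite:
    """Call one site from its allele counts.

    Boundary rules: minor fraction exactly 0.10 calls the homozygote;
    exactly 0.30 calls the heterozygote.  Alleles are ranked by count with
    lexicographic tie-break; reads beyond the top two alleles count toward
    coverage but not the genotype.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if obs.coverage < min_coverage:
        return CalledSite(obs.snp_id, "no_call", None, obs.coverage, 0.0)
    ranked = sorted(obs.allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = [(a, c) for a, c in ranked if c > 0]
    major, c1 = ranked[0]
    minor, c2 = ranked[1] if len(ranked) > 1 else (None, 0)
    m = c2 / (c1 + c2)
    if m <= hom_max_minor:
        geno = (major,) if ploidy == 1 else (major, major)
        return CalledSite(obs.snp_id, "called", geno, obs.coverage, m, major)
    if m >= het_min_minor and ploidy == 2:
        geno = tuple(sorted((major, minor)))
        return CalledSite(obs.snp_id, "called", geno, obs.coverage, m, major)
    return CalledSite(
        obs.snp_id, "imbalanced", None, obs.coverage, m, major,
        lowq_minor_flag=obs.lowq_minor_flag,
    )


def resolve_artifact_minor(site: CalledSite, ploidy: int = 2) -> CalledSite:
    """Note an imbalanced site as homozygote when its minor allele is the
    flagged low-quality artifact.  The site stays imbalanced and is never
    used downstream; the noted genotype serves concordance accounting only.
    """
    if site.status != "imbalanced" or not site.lowq_minor_flag:
        return site
    noted = (site.major_allele,) if ploidy == 1 else (site.major_allele,) * 2
    return replace(site, noted_genotype=noted)


@dataclass
class CalledProfile:
    sample_id: str
    sex: str  # M | F | unknown
    sites: dict[str, CalledSite]
    panel: PanelManifest

    @property
    def n_called(self) -> int:
        return sum(1 for s in self.sites.values() if s.status == "called")

    def max_callable(self) -> int:
        """Sex-adjusted maximum: females cannot call Y-SNPs."""
        total = len(self.panel)
        n_y = self.panel.category_counts.get("Y", 0)
        return total - n_y if self.sex == "F" else total

    @property
    def percent_called(self) -> float:
        return 100.0 * self.n_called / self.max_callable()

    @property
    def mean_coverage_called(self) -> float:
        cov = [s.coverage for s in self.sites.values() if s.status == "called"]
        return float(np.mean(cov)) if cov else 0.0


def infer_sex(observations: pd.DataFrame, panel: PanelManifest) -> str:
    """Male iff at least 50 Y-SNP sites reach the coverage threshold."""
    y_ids = set(panel.category("Y")["snp_id"])
    obs_y = observations[
        observations["snp_id"].isin(y_ids)
        & (observations["coverage"] >= MIN_COVERAGE)
    ]
    return "M" if len(obs_y) >= Y_SEX_INFER_MIN_SITES else "F"


def call_profile(
    observations: pd.DataFrame,
    panel: PanelManifest,
    sex: str = "unknown",
    sample_id: str | None = None,
) -> CalledProfile:
    """Call every observed site of one sample against the panel.

    ``observations``: long table with columns snp_id, coverage,
    count_A..count_T, lowq_minor_flag (optionally sample_id, filtered to
    ``sample_id``).  Female samples skip Y-SNPs (not applicable).  Unknown
    sex is inferred from Y-SNP coverage.
    """
    obs = observations
    if sample_id is not None and "sample_id" in obs.columns:
        obs = obs[obs["sample_id"] == sample_id]
    elif "sample_id" in obs.columns:
        uniq = obs["sample_id"].unique()
        if len(uniq) != 1:
            raise ValueError("observations contain multiple samples; pass sample_id")
        sample_id = str(uniq[0])
    if sex == "unknown":
        sex = infer_sex(obs, panel)
    pdf = panel.df
    cats = dict(zip(pdf["snp_id"], pdf["category"]))
    sites: dict[str, CalledSite] = {}
    for rec in obs.itertuples(index=False):
        sid = rec.snp_id
        if sid not in cats:
            logger.warning("observation for %s not in panel; ignored", sid)
            continue
        cat = cats[sid]
        if cat == "Y" and sex == "F":
            continue
        ploidy = 1 if (cat == "Y" or (cat == "X" and sex == "M")) else 2
        counts = {
            b: int(getattr(rec, f"count_{b}"))
            for b in "ACGT"
            if getattr(rec, f"count_{b}", 0) > 0
        }
        so = SiteObservation(
            sid, int(rec.coverage), counts, bool(getattr(rec, "lowq_minor_flag", False))
        )
        sites[sid] = resolve_artifact_minor(call_site(so, ploidy), ploidy)
    # panel sites never observed are no-calls
    for sid in pdf["snp_id"]:
        if sid not in sites and not (cats[sid] == "Y" and sex == "F"):
            sites[sid] = CalledSite(sid, "no_call", None, 0, 0.0)
    return CalledProfile(sample_id or "sample", sex, sites, panel)


@dataclass(frozen=True)
class ConcordanceReport:
    compared: int
    concordant: int
    discordant: int
    imbalanced_compared: int
    imbalanced_concordant: int
    non_comparable: int

    @property
    def percent_called(self) -> float:
        return concordance_percent(self.concordant, self.compared)

    @property
    def percent_overall(self) -> float:
        return concordance_percent(
            self.concordant + self.imbalanced_concordant,
            self.compared + self.imbalanced_compared,
        )


def concordance_percent(concordant: int, compared: int) -> float:
    """Concordance as a percentage, two-decimal convention."""
    if compared == 0:
        raise ValueError("no comparable genotypes")
    return round(100.0 * concordant / compared, 2)


def concordance_report(
    profile: CalledProfile, truth: dict[str, tuple[str, ...] | None]
) -> ConcordanceReport:
    """Compare called (and separately, imbalanced-noted) genotypes to a
    truth/published set.  Sites uncallable on either side are counted as
    non-comparable."""
    overlap = [s for s in profile.sites if s in truth]
    if not overlap:
        raise ValueError("no overlapping snp_ids to compare")
    comp = conc = imb_comp = imb_conc = non = 0
    for sid in overlap:
        site = profile.sites[sid]
        t = truth[sid]
        if t is None or site.status == "no_call":
            non += 1
            continue
        t_sorted = tuple(sorted(t))
        if site.status == "called":
            comp += 1
            conc += site.genotype == t_sorted
        elif site.noted_genotype is not None:
            imb_comp += 1
            imb_conc += tuple(sorted(site.noted_genotype)) == t_sorted
    return ConcordanceReport(comp, conc, comp - conc, imb_comp, imb_conc, non)


def specificity_fold_change(shotgun_pct: float, capture_pct: float) -> float:
    """Fold increase in mapped-read specificity from capture enrichment."""
    if shotgun_pct <= 0:
        raise ValueError("shotgun specificity must be positive")
    return capture_pct / shotgun_pct


# ---------------------------------------------------------------------------
# I/O

def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"snp_id": str, "sample_id": str}
    )
    need = {"snp_id", "coverage", "count_A", "count_C", "count_G", "count_T"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns {sorted(missing)}")
    if "lowq_minor_flag" not in df.columns:
        df["lowq_minor_flag"] = False
    return df


def write_profile_tsv(profile: CalledProfile, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("sample_id\tsnp_id\tstatus\tgenotype\tcoverage\tminor_fraction\n")
        for sid in profile.panel.df["snp_id"]:
            if sid not in profile.sites:
                continue
            s = profile.sites[sid]
            gt = "/".join(s.genotype) if s.genotype else "."
            fh.write(
                f"{profile.sample_id}\t{sid}\t{s.status}\t{gt}\t"
                f"{s.coverage}\t{s.minor_fraction:.4f}\n"
            )


def read_profile_tsv(path: str | Path, panel: PanelManifest, sex: str = "unknown") -> CalledProfile:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"snp_id": str, "sample_id": str}
    )
    sites = {}
    sample_id = "sample"
    for rec in df.itertuples(index=False):
        sample_id = rec.sample_id
        geno = None if rec.genotype == "." else tuple(rec.genotype.split("/"))
        sites[rec.snp_id] = CalledSite(
            rec.snp_id, rec.status, geno, int(rec.coverage), float(rec.minor_fraction)
        )
    if sex == "unknown":
        y_ids = set(panel.category("Y")["snp_id"])
        n_y_called = sum(
            1 for s in sites.values()
            if s.snp_id in y_ids and s.coverage >= MIN_COVERAGE
        )
        sex = "M" if n_y_called >= Y_SEX_INFER_MIN_SITES else "F"
    return CalledProfile(str(sample_id), sex, sites, panel)


def write_profile_vcf(profile: CalledProfile, path: str | Path) -> None:
    """Export called genotypes as VCF; no-calls are missing GT, imbalanced
    sites carry the IMB filter tag."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "forcekin")
    for ch in pd.unique(profile.panel.df["chrom"]):
        header.contigs.add(str(ch))
    header.filters.add("IMB", None, None, "Imbalanced allele ratio (10-30% minor)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(profile.sample_id)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for _, row in profile.panel.df.iterrows():
        sid = row["snp_id"]
        if sid not in profile.sites:
            continue
        site = profile.sites[sid]
        rec = vf.new_record(
            contig=str(row["chrom"]),
            start=int(row["pos_bp"]) - 1,
            stop=int(row["pos_bp"]),
            alleles=(row["ref"], row["alt"]),
            id=sid,
        )
        alleles = {row["ref"]: 0, row["alt"]: 1}
        if site.status == "called" and all(a in alleles for a in site.genotype):
            gt = tuple(alleles[a] for a in site.genotype)
            rec.samples[profile.sample_id]["GT"] = gt
            rec.filter.add("PASS")
        else:
            rec.samples[profile.sample_id]["GT"] = (None,) * max(len(site.genotype or (None, None)), 1)
            rec.filter.add("IMB" if site.status == "imbalanced" else "PASS")
        vf.write(rec)
    vf.close()


def profile_dosages(
    profile: CalledProfile, marker_df: pd.DataFrame, panel: PanelManifest
) -> np.ndarray:
    """Alt-allele dosages of a called profile aligned to a marker table.

    Only cleanly called genotypes over the panel's ref/alt alleles yield a
    dosage; everything else (no_call, imbalanced, off-panel alleles) is -1.
    """
    pdf = panel.df.set_index("snp_id")
    out = np.full(len(marker_df), -1, dtype=np.int64)
    for i, sid in enumerate(marker_df["snp_id"]):
        site = profile.sites.get(sid)
        if site is None or site.status != "called":
            continue
        alt = pdf.at[sid, "alt"]
        ref = pdf.at[sid, "ref"]
        if all(a in (ref, alt) for a in site.genotype):
            out[i] = sum(a == alt for a in site.genotype)
    return out
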