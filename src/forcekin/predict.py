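"""Ancestry, Y-haplogroup and phenotype-encoding predictions from called
profiles.

Ancestry uses two complementary views of the ancestry-informative SNPs:
a naive Bayes classifier over per-population Hardy-Weinberg genotype
likelihoods with a flat prior, and a PCA trained on a labelled reference
genotype matrix onto which query profiles are projected.  Y haplogroups are
assigned from derived alleles against a haplogroup tree, scoring each
candidate by on-path derived support minus off-path conflicts.  Phenotype
handling is limited to strand-normalised effect-allele dosage encoding
(0/1/2/NA) and batch-file export for the external prediction webtool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .calling import CalledProfile
from .panel import POPULATIONS, PanelManifest

logger = logging.getLogger(__name__)

FREQ_CLAMP = 1e-4
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "AncestryReference",
    "YHaplogroupTable",
    "ancestry_naive_bayes",
    "ancestry_pca",
    "assign_y_haplogroup",
    "encode_hirisplex",
    "hirisplex_batch_file",
]


@dataclass
class AncestryReference:
    """Per-aiSNP alt-allele frequencies by population, plus an optional
    labelled genotype matrix (individuals x aiSNPs, dosages) for PCA."""

    frequencies: pd.DataFrame  # index snp_id, columns population labels
    genotypes: pd.DataFrame | None = None  # index individuals, columns snp_id
    labels: pd.Series | None = None  # population label per individual

    def __post_init__(self):
        vals = self.frequencies.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("reference frequencies must lie in [0, 1]")

    @classmethod
    def from_panel(cls, panel: PanelManifest) -> "AncestryReference":
        ai = panel.category("aiSNP").set_index("snp_id")
        freq = ai[[f"freq_{p}" for p in POPULATIONS]]
        freq.columns = list(POPULATIONS)
        return cls(freq)


def _ai_dosages(profile: CalledProfile, panel: PanelManifest, snp_ids) -> dict[str, int]:
    pdf = panel.df.set_index("snp_id")
    out = {}
    for sid in snp_ids:
        site = profile.sites.get(sid)
        if site is None or site.status != "called" or sid not in pdf.index:
            continue
        ref, alt = pdf.at[sid, "ref"], pdf.at[sid, "alt"]
        if all(a in (ref, alt) for a in site.genotype):
            out[sid] = sum(a == alt for a in site.genotype)
    return out


def ancestry_naive_bayes(
    profile: CalledProfile, reference: AncestryReference, panel: PanelManifest
) -> dict:
    """Flat-prior population posteriors from called aiSNP genotypes.

    Per population, the log-likelihood sums log HWE genotype probabilities
    at each called aiSNP (frequencies clamped away from 0/1); markers
    absent from the reference are excluded.
    """
    snp_ids = [s for s in reference.frequencies.index]
    dos = _ai_dosages(profile, panel, snp_ids)
    if not dos:
        raise ValueError("no usable aiSNPs shared with the reference")
    used = list(dos)
    d = np.array([dos[s] for s in used])
    loglik = {}
    for pop in reference.frequencies.columns:
        p = np.clip(
            reference.frequencies.loc[used, pop].to_numpy(),
            FREQ_CLAMP, 1 - FREQ_CLAMP,
        )
        q = 1 - p
        ll = np.where(d == 0, 2 * np.log(q), 0.0)
        ll = np.where(d == 1, np.log(2 * p * q), ll)
        ll = np.where(d == 2, 2 * np.log(p), ll)
        loglik[pop] = float(ll.sum())
    pops = list(loglik)
    vals = np.array([loglik[p] for p in pops])
    post = np.exp(vals - logsumexp(vals))
    return {
        "posteriors": dict(zip(pops, post.tolist())),
        "log_likelihoods": loglik,
        "n_aisnps_used": len(used),
    }


def ancestry_pca(
    reference: AncestryReference,
    query_genotypes: dict[str, int],
    n_components: int = 2,
) -> dict:
    """Project a query profile onto principal axes trained on the labelled
    reference genotype matrix.

    Columns are centred and scaled by reference statistics; missing values
    (reference or query) are mean-imputed, i.e. projected at zero after
    centring.  The query must share at least half of the matrix markers.
    """
    if reference.genotypes is None:
        raise ValueError("reference has no genotype matrix for PCA")
    from sklearn.decomposition import PCA

    X = reference.genotypes.to_numpy(dtype=float)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate reference matrix (all markers constant)")
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    pca = PCA(n_components=n_components)
    ref_coords = pca.fit_transform(Z)

    cols = list(reference.genotypes.columns)
    shared = [c for c in cols if c in query_genotypes]
    if len(shared) < 0.5 * len(cols):
        raise ValueError(
            f"query shares only {len(shared)}/{len(cols)} PCA markers (< 50%)"
        )
    q = np.array(
        [float(query_genotypes.get(c, np.nan)) for c in cols], dtype=float
    )
    q = np.where(np.isnan(q), mean, q)
    qz = (q - mean) / sd
    q_coords = pca.transform(qz[None, :])[0]
    return {
        "reference_coords": pd.DataFrame(
            ref_coords,
            index=reference.genotypes.index,
            columns=[f"PC{i+1}" for i in range(n_components)],
        ).assign(
            population=(
                reference.labels.reindex(reference.genotypes.index)
                if reference.labels is not None else None
            )
        ),
        "query_coords": q_coords,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }


class YHaplogroupTable:
    """Defining SNPs of a Y-haplogroup tree.

    ``variants``: rows (snp_id, haplogroup, ancestral, derived);
    ``parent``: haplogroup -> parent haplogroup (tree, single root).
    """

    def __init__(self, variants: pd.DataFrame, parent: dict[str, str | None]):
        need = {"snp_id", "haplogroup", "ancestral", "derived"}
        if not need.issubset(variants.columns):
            raise ValueError(f"variant table needs columns {sorted(need)}")
        self.variants = variants.reset_index(drop=True)
        self.parent = dict(parent)
        roots = [h for h, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("haplogroup tree must have exactly one root")
        self.root = roots[0]
        for h in self.parent:
            if len(self.path(h)) > len(self.parent):
                raise ValueError("haplogroup tree contains a cycle")

    def path(self, haplogroup: str) -> list[str]:
        """Root-to-node path."""
        out, cur, seen = [], haplogroup, set()
        while cur is not None:
            if cur in seen:
                raise ValueError("haplogroup tree contains a cycle")
            seen.add(cur)
            out.append(cur)
            cur = self.parent.get(cur)
        return out[::-1]

    def depth(self, haplogroup: str) -> int:
        return len(self.path(haplogroup)) - 1

    @classmethod
    def read(cls, variants_path: str | Path, tree_path: str | Path):
        v = pd.read_csv(variants_path, sep="\t", comment="#")
        t = pd.read_csv(tree_path, sep="\t", comment="#")
        parent = {
            str(r.haplogroup): (None if pd.isna(r.parent) or r.parent == "."
                                else str(r.parent))
            for r in t.itertuples(index=False)
        }
        return cls(v, parent)

    def write(self, variants_path: str | Path, tree_path: str | Path) -> None:
        self.variants.to_csv(variants_path, sep="\t", index=False)
        pd.DataFrame(
            {
                "haplogroup": list(self.parent),
                "parent": [p if p is not None else "." for p in self.parent.values()],
            }
        ).to_csv(tree_path, sep="\t", index=False)


def assign_y_haplogroup(
    y_calls: dict[str, str], table: YHaplogroupTable
) -> dict:
    """Assign the most refined supported Y haplogroup.

    ``y_calls``: snp_id -> called allele (hemizygous).  Haplogroups with at
    least one derived call are candidates; the reported haplogroup
    maximises (derived calls on its root path) - (derived calls off path),
    ties broken toward the shallower node.  Off-path derived calls are
    returned as conflicts and on-path ancestral calls as possible
    back-mutations.
    """
    if not y_calls:
        raise ValueError("no called Y-SNPs")
    derived_by_hg: dict[str, list[str]] = {}
    ancestral_by_hg: dict[str, list[str]] = {}
    for r in table.variants.itertuples(index=False):
        allele = y_calls.get(r.snp_id)
        if allele is None:
            continue
        if allele == r.derived:
            derived_by_hg.setdefault(r.haplogroup, []).append(r.snp_id)
        elif allele == r.ancestral:
            ancestral_by_hg.setdefault(r.haplogroup, []).append(r.snp_id)
    if not derived_by_hg:
        return {
            "haplogroup": table.root,
            "supporting": [],
            "conflicts": [],
            "back_mutations": [],
            "score": 0,
        }
    total_derived = sum(len(v) for v in derived_by_hg.values())
    best, best_key = None, None
    for hg in derived_by_hg:
        on_path = set(table.path(hg))
        support = sum(len(derived_by_hg.get(h, [])) for h in on_path)
        score = support - (total_derived - support)
        key = (score, -table.depth(hg))
        if best_key is None or key > best_key:
            best, best_key = hg, key
    on_path = set(table.path(best))
    supporting = [s for h in on_path for s in derived_by_hg.get(h, [])]
    conflicts = [
        s for h, ss in derived_by_hg.items() if h not in on_path for s in ss
    ]
    back = [s for h in on_path for s in ancestral_by_hg.get(h, [])]
    return {
        "haplogroup": best,
        "supporting": sorted(supporting),
        "conflicts": sorted(conflicts),
        "back_mutations": sorted(back),
        "score": best_key[0],
    }


def encode_hirisplex(
    profile: CalledProfile, effect_table: pd.DataFrame, panel: PanelManifest
) -> dict[str, int | str]:
    """Effect-allele dosage encoding (0/1/2/NA) of the phenotype SNPs.

    ``effect_table``: columns snp_id, effect_allele, strand ('+'/'-'); a
    minus-strand row means the panel genotype must be complemented before
    counting effect alleles.  Uncalled or imbalanced sites encode as 'NA'.
    """
    need = {"snp_id", "effect_allele", "strand"}
    if not need.issubset(effect_table.columns):
        raise ValueError(f"effect table needs columns {sorted(need)}")
    pi_ids = set(panel.category("piSNP")["snp_id"])
    covered = set(effect_table["snp_id"])
    missing = pi_ids - covered
    if missing:
        raise ValueError(f"effect table missing piSNPs: {sorted(missing)[:5]}")
    out: dict[str, int | str] = {}
    for r in effect_table.itertuples(index=False):
        sid = r.snp_id
        site = profile.sites.get(sid)
        if site is None or site.status != "called":
            out[sid] = "NA"
            continue
        geno = site.genotype
        if r.strand == "-":
            geno = tuple(COMPLEMENT[a] for a in geno)
        out[sid] = sum(a == r.effect_allele for a in geno)
    return out


def hirisplex_batch_file(
    encodings: dict[str, dict[str, int | str]],
    effect_table: pd.DataFrame,
    path: str | Path,
) -> None:
    """Row-per-sample CSV in the webtool's upload layout."""
    cols = list(effect_table["snp_id"])
    rows = []
    for sample, enc in encodings.items():
        rows.append({"sampleid": sample, **{c: enc.get(c, "NA") for c in cols}})
    pd.DataFrame(rows, columns=["sampleid", *cols]).to_csv(path, index=False)
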