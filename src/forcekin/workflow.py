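"""End-to-end orchestration: fixture generation, configuration, and the
call -> kinship -> prediction report bundle.

:func:`make_fixture` writes a miniature but structurally complete input set
(panel + frequencies, genetic map, five missing-person family pedigrees,
Y-haplogroup tree, phenotype effect table, and simulated reference /
degraded-bone observations), standing in for casework data that cannot be
redistributed.  :func:`run_end_to_end` drives every pipeline stage over
such a directory and writes a deterministic report bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (
    CalledProfile,
    call_profile,
    profile_dosages,
    read_observations,
)
from .kinship import (
    hypotheses_up_to,
    missing_person_pedigree_lr,
    pairwise_lr,
    prepare_markers,
    x_chromosome_lr,
)
from .panel import PanelManifest, read_manifest, write_manifest
from .pedigree import FEMALE, MALE, Individual, Pedigree, read_ped, write_ped
from .predict import (
    AncestryReference,
    YHaplogroupTable,
    ancestry_naive_bayes,
    assign_y_haplogroup,
    encode_hirisplex,
    hirisplex_batch_file,
)
from .simulate import (
    BONE_PRESET,
    REFERENCE_PRESET,
    SeqModelParams,
    build_panel_skeleton,
    fixture_genetic_map,
    generate_population_frequencies,
    simulate_observations,
    simulate_pedigree_genotypes,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "make_fixture", "run_end_to_end", "FIXTURE_FAMILIES"]


@dataclass
class RunConfig:
    """Resolved configuration of an end-to-end run.

    Thresholds default to the published values (10X coverage, 90%
    homozygote / 30% heterozygote allele fractions, strong support at
    LR >= 1e4 with posterior >= 99.99%) and are logged with every run.
    """

    fixture_dir: str
    out_dir: str
    population: str = "EUR"
    seed: int = 0
    min_coverage: int = 10
    hom_max_minor: float = 0.10
    het_min_minor: float = 0.30
    strong_lr: float = 1e4
    strong_posterior: float = 0.9999
    pairwise_max_degree: int = 3
    families: list[str] | None = None
    run_pedigree: bool = True
    run_x: bool = True
    run_predictions: bool = True
    error_rate: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        missing = {"fixture_dir", "out_dir"} - set(data)
        if missing:
            raise ValueError(f"config missing required keys {sorted(missing)}")
        return cls(**data)

    def resolved(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _family_pedigrees() -> dict[str, tuple[Pedigree, str, dict[str, str], list[str]]]:
    """Five missing-person family structures: pedigree, missing id,
    typed reference ids -> relationship note, bone extract ids."""
    fams = {}
    # A: grandniece + nephew references
    fams["A"] = (
        Pedigree(
            [
                Individual("A_gf", MALE), Individual("A_gm", FEMALE),
                Individual("A_MP", MALE, "A_gf", "A_gm"),
                Individual("A_sib", MALE, "A_gf", "A_gm"),
                Individual("A_sibsp", FEMALE),
                Individual("2", MALE, "A_sib", "A_sibsp"),  # nephew (2nd deg)
                Individual("A_nsp", FEMALE),
                Individual("1", FEMALE, "2", "A_nsp"),  # grandniece (3rd deg)
            ]
        ),
        "A_MP",
        {"1": "grandniece", "2": "nephew"},
        ["3"],
    )
    # B: nephew + great-grandnephew + great-grandniece
    fams["B"] = (
        Pedigree(
            [
                Individual("B_gf", MALE), Individual("B_gm", FEMALE),
                Individual("B_MP", MALE, "B_gf", "B_gm"),
                Individual("B_sib", MALE, "B_gf", "B_gm"),
                Individual("B_sibsp", FEMALE),
                Individual("4", MALE, "B_sib", "B_sibsp"),  # nephew
                Individual("B_niece", FEMALE, "B_sib", "B_sibsp"),
                Individual("B_nsp", MALE),
                Individual("B_gn", MALE, "B_nsp", "B_niece"),
                Individual("B_gnsp", FEMALE),
                Individual("5", MALE, "B_gn", "B_gnsp"),  # great-grandnephew
                Individual("6", FEMALE, "B_gn", "B_gnsp"),  # great-grandniece
            ]
        ),
        "B_MP",
        {"4": "nephew", "5": "great_grandnephew", "6": "great_grandniece"},
        ["7.1", "7.2"],
    )
    # C: first cousin twice removed + nephew + daughter
    fams["C"] = (
        Pedigree(
            [
                Individual("C_ggf", MALE), Individual("C_ggm", FEMALE),
                Individual("C_p1", MALE, "C_ggf", "C_ggm"),
                Individual("C_p2", MALE, "C_ggf", "C_ggm"),
                Individual("C_p1sp", FEMALE),
                Individual("C_MP", MALE, "C_p1", "C_p1sp"),
                Individual("C_sib", MALE, "C_p1", "C_p1sp"),
                Individual("C_sibsp", FEMALE),
                Individual("9", MALE, "C_sib", "C_sibsp"),  # nephew
                Individual("C_mpsp", FEMALE),
                Individual("10", FEMALE, "C_MP", "C_mpsp"),  # daughter
                Individual("C_p2sp", FEMALE),
                Individual("C_1c", MALE, "C_p2", "C_p2sp"),
                Individual("C_1csp", FEMALE),
                Individual("C_1cc", MALE, "C_1c", "C_1csp"),
                Individual("C_1ccsp", FEMALE),
                Individual("8", MALE, "C_1cc", "C_1ccsp"),  # 1C twice removed
            ]
        ),
        "C_MP",
        {"8": "first_cousin_twice_removed", "9": "nephew", "10": "daughter"},
        ["11.1", "11.2"],
    )
    # D: sister + grandniece
    fams["D"] = (
        Pedigree(
            [
                Individual("D_f", MALE), Individual("D_m", FEMALE),
                Individual("D_MP", MALE, "D_f", "D_m"),
                Individual("12", FEMALE, "D_f", "D_m"),  # sister
                Individual("D_ssp", MALE),
                Individual("D_niece", FEMALE, "D_ssp", "12"),
                Individual("D_nsp", MALE),
                Individual("13", FEMALE, "D_nsp", "D_niece"),  # grandniece
            ]
        ),
        "D_MP",
        {"12": "sister", "13": "grandniece"},
        ["14.1", "14.2", "14.3"],
    )
    # E: son + daughter
    fams["E"] = (
        Pedigree(
            [
                Individual("E_MP", MALE), Individual("E_sp", FEMALE),
                Individual("15", MALE, "E_MP", "E_sp"),  # son
                Individual("16", FEMALE, "E_MP", "E_sp"),  # daughter
            ]
        ),
        "E_MP",
        {"15": "son", "16": "daughter"},
        ["17.1", "17.2"],
    )
    return fams


FIXTURE_FAMILIES = _family_pedigrees()


def _fixture_y_table(panel: PanelManifest) -> YHaplogroupTable:
    """A small synthetic Y-haplogroup tree over the panel's Y-SNPs.

    Derived alleles are the panel alt alleles; SNPs are spread evenly over
    a three-clade, depth-six tree.
    """
    parent = {
        "ROOT": None,
        "R": "ROOT", "R1": "R", "R1a": "R1", "R1a1": "R1a", "R1a1a": "R1a1",
        "I": "ROOT", "I1": "I", "I1a": "I1",
        "J": "ROOT", "J1": "J",
    }
    hgs = [h for h in parent if h != "ROOT"]
    ydf = panel.category("Y")
    rows = []
    for i, r in enumerate(ydf.itertuples(index=False)):
        rows.append(
            {
                "snp_id": r.snp_id,
                "haplogroup": hgs[i % len(hgs)],
                "ancestral": r.ref,
                "derived": r.alt,
            }
        )
    return YHaplogroupTable(pd.DataFrame(rows), parent)


def _apply_y_haplogroup(truth, table: YHaplogroupTable, leaf: str, ped: Pedigree):
    """Overwrite Y alleles so every patriline carries the given haplogroup."""
    ydf = truth.panel.df["category"].to_numpy() == "Y"
    y_rows = np.flatnonzero(ydf)
    on_path = set(table.path(leaf))
    by_snp = dict(zip(table.variants["snp_id"], table.variants["haplogroup"]))
    snp_ids = truth.panel.df["snp_id"].to_numpy()[y_rows]
    derived = np.array([by_snp.get(s) in on_path for s in snp_ids])
    for iid, g in truth.alleles.items():
        if truth.sexes[iid] == MALE:
            g[y_rows, 0] = derived.astype(np.int8)


def _fixture_effect_table(panel: PanelManifest, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for r in panel.category("piSNP").itertuples(index=False):
        minus = bool(rng.random() < 0.25)
        from .predict import COMPLEMENT

        eff = COMPLEMENT[r.alt] if minus else r.alt
        rows.append(
            {"snp_id": r.snp_id, "effect_allele": eff,
             "strand": "-" if minus else "+"}
        )
    return pd.DataFrame(rows)


def make_fixture(
    out_dir: str | Path,
    seed: int = 0,
    *,
    n_kinship: int = 400,
    n_ii: int = 30,
    n_ai: int = 40,
    n_pi: int = 20,
    n_x: int = 30,
    n_y: int = 60,
    reference_preset: SeqModelParams = REFERENCE_PRESET,
    bone_preset: SeqModelParams = BONE_PRESET,
) -> Path:
    """Write a complete miniature input directory (about 10% panel scale).

    Contents: panel manifest with Balding-Nichols population frequencies,
    linear genetic map, PED file with the five family structures, simulated
    reference observations (high-coverage preset) and bone-extract
    observations (degraded preset), Y-haplogroup tables and the phenotype
    effect table.  Regenerating with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skeleton = build_panel_skeleton(n_kinship, n_ii, n_ai, n_pi, n_x, n_y, seed=seed)
    panel = generate_population_frequencies(skeleton, seed=seed + 1)
    write_manifest(panel, out / "panel.tsv")
    fixture_genetic_map().write(out / "genetic_map.tsv")

    fams = _family_pedigrees()
    write_ped({f: ped for f, (ped, *_rest) in fams.items()}, out / "pedigrees.ped")

    ytable = _fixture_y_table(panel)
    ytable.write(out / "y_variants.tsv", out / "y_tree.tsv")
    effect = _fixture_effect_table(panel, seed + 2)
    effect.to_csv(out / "pi_effect_table.tsv", sep="\t", index=False)

    leaves = {"A": "R1a1a", "B": "I1a", "C": "J1", "D": "R1a1", "E": "I1"}
    ref_frames, bone_frames, meta_rows = [], [], []
    for i, (fam, (ped, mp_id, refs, extracts)) in enumerate(fams.items()):
        truth = simulate_pedigree_genotypes(ped, panel, "EUR", seed=seed + 10 + i)
        _apply_y_haplogroup(truth, ytable, leaves[fam], ped)
        rp = SeqModelParams(
            reference_preset.mean_cov, reference_preset.dispersion,
            reference_preset.error_rate, reference_preset.dropout_frac,
            seed=seed + 100 + i,
        )
        ref_frames.append(
            simulate_observations(truth, rp, sample_ids=list(refs))
        )
        for j, ext in enumerate(extracts):
            # extract quality varies widely between bone extracts; the
            # first extract per case emulates a better-preserved sample
            mean_cov = bone_preset.mean_cov * (4 if j == 0 else 1)
            dropout = bone_preset.dropout_frac * (0.5 if j == 0 else 1)
            bp = SeqModelParams(
                mean_cov, bone_preset.dispersion,
                bone_preset.error_rate, dropout,
                seed=seed + 200 + 10 * i + j,
            )
            obs = simulate_observations(truth, bp, sample_ids=[mp_id])
            obs = obs.assign(sample_id=ext)
            bone_frames.append(obs)
        for rid in refs:
            meta_rows.append(
                {"sample_id": rid, "family": fam, "role": refs[rid],
                 "sex": ped.sex(rid), "type": "reference"}
            )
        for ext in extracts:
            # the missing person's sex is case metadata, not inferred
            meta_rows.append(
                {"sample_id": ext, "family": fam, "role": "unknown",
                 "sex": ped.sex(mp_id), "type": "bone"}
            )
    pd.concat(ref_frames, ignore_index=True).to_csv(
        out / "observations_reference.tsv", sep="\t", index=False
    )
    pd.concat(bone_frames, ignore_index=True).to_csv(
        out / "observations_bone.tsv", sep="\t", index=False
    )
    pd.DataFrame(meta_rows).to_csv(out / "samples.tsv", sep="\t", index=False)
    return out


def _table_header(config: RunConfig) -> str:
    cfg = ", ".join(f"{k}={v}" for k, v in sorted(config.resolved().items()))
    return f"forcekin {__version__}\n{cfg}"


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        for line in _table_header(config).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_end_to_end(config: RunConfig) -> dict[str, Path]:
    """Run call -> completeness -> kinship -> prediction over a fixture
    directory, writing one TSV per stage.  Deterministic given the seeds
    recorded in the fixture."""
    fx = Path(config.fixture_dir)
    if not (fx / "panel.tsv").exists():
        raise ValueError(f"config: panel manifest not found under {fx}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", config.resolved())

    panel = read_manifest(fx / "panel.tsv")
    peds = read_ped(fx / "pedigrees.ped")
    meta = pd.read_csv(fx / "samples.tsv", sep="\t", dtype=str)
    obs = pd.concat(
        [
            read_observations(fx / "observations_reference.tsv"),
            read_observations(fx / "observations_bone.tsv"),
        ],
        ignore_index=True,
    )
    fams = {
        f: (peds[f], FIXTURE_FAMILIES[f][1], FIXTURE_FAMILIES[f][2],
            FIXTURE_FAMILIES[f][3])
        for f in peds
        if config.families is None or f in config.families
    }

    logger.info("stage calling: %d samples", meta["sample_id"].nunique())
    profiles: dict[str, CalledProfile] = {}
    completeness = []
    for rec in meta.itertuples(index=False):
        if config.families is not None and rec.family not in config.families:
            continue
        sex = rec.sex if rec.sex in ("M", "F") else "unknown"
        prof = call_profile(obs, panel, sex=sex, sample_id=rec.sample_id)
        profiles[rec.sample_id] = prof
        completeness.append(
            {
                "sample_id": rec.sample_id,
                "family": rec.family,
                "type": rec.type,
                "sex": prof.sex,
                "n_called": prof.n_called,
                "max_callable": prof.max_callable(),
                "percent_called": round(prof.percent_called, 1),
                "mean_coverage_called": round(prof.mean_coverage_called, 1),
            }
        )
    paths: dict[str, Path] = {}
    comp_df = pd.DataFrame(completeness)
    _write_table(comp_df, out / "completeness.tsv", config)
    paths["completeness"] = out / "completeness.tsv"

    logger.info("stage pairwise kinship")
    hyps = hypotheses_up_to(config.pairwise_max_degree)
    rows = []
    for fam, (ped, mp_id, refs, extracts) in fams.items():
        for ext in extracts:
            if ext not in profiles:
                continue
            for rid in refs:
                for hyp in hyps:
                    res = pairwise_lr(
                        profiles[ext], profiles[rid], hyp, panel,
                        config.population, error_rate=config.error_rate,
                    )
                    rows.append(
                        {
                            "family": fam, "unknown": ext, "reference": rid,
                            "reference_role": refs[rid], "hypothesis": hyp,
                            "log10_lr": round(res.log10_lr, 3),
                            "posterior": res.posterior,
                            "n_markers": res.n_markers_used,
                            "strong_support": res.strong_support,
                        }
                    )
    _write_table(pd.DataFrame(rows), out / "pairwise_lr.tsv", config)
    paths["pairwise"] = out / "pairwise_lr.tsv"

    if config.run_pedigree:
        logger.info("stage pedigree (missing-person) kinship")
        rows = []
        for fam, (ped, mp_id, refs, extracts) in fams.items():
            ref_profiles = {r: profiles[r] for r in refs if r in profiles}
            for ext in extracts:
                if ext not in profiles:
                    continue
                res = missing_person_pedigree_lr(
                    ped, mp_id, ref_profiles, profiles[ext], panel,
                    config.population, error_rate=config.error_rate,
                )
                rows.append(
                    {
                        "family": fam, "unknown": ext,
                        "log10_lr": round(res.log10_lr, 3),
                        "posterior": res.posterior,
                        "n_markers": res.n_markers_used,
                        "strong_support": res.strong_support,
                    }
                )
        _write_table(pd.DataFrame(rows), out / "pedigree_lr.tsv", config)
        paths["pedigree"] = out / "pedigree_lr.tsv"

    if config.run_x and "D" in fams:
        logger.info("stage X-chromosomal kinship (family D full siblings)")
        rows = []
        for ext in fams["D"][3]:
            if ext in profiles and "12" in profiles:
                res = x_chromosome_lr(
                    profiles[ext], profiles["12"], panel, config.population,
                    error_rate=config.error_rate,
                )
                rows.append(
                    {
                        "unknown": ext, "reference": "12",
                        "hypothesis": res.hypothesis,
                        "log10_lr": round(res.log10_lr, 3),
                        "posterior": res.posterior,
                        "n_markers": res.n_markers_used,
                    }
                )
        _write_table(pd.DataFrame(rows), out / "x_lr.tsv", config)
        paths["x"] = out / "x_lr.tsv"

    if config.run_predictions:
        logger.info("stage predictions (ancestry / Y haplogroup / phenotype)")
        ytable = YHaplogroupTable.read(fx / "y_variants.tsv", fx / "y_tree.tsv")
        effect = pd.read_csv(fx / "pi_effect_table.tsv", sep="\t")
        ref = AncestryReference.from_panel(panel)
        rows, encodings = [], {}
        for sid, prof in profiles.items():
            try:
                nb = ancestry_naive_bayes(prof, ref, panel)
                top = max(nb["posteriors"], key=nb["posteriors"].get)
                anc = f"{top}:{nb['posteriors'][top]:.4f}"
                n_ai = nb["n_aisnps_used"]
            except ValueError:
                anc, n_ai = "NA", 0
            yhap = "NA"
            if prof.sex == "M":
                calls = {
                    s.snp_id: s.genotype[0]
                    for s in prof.sites.values()
                    if s.status == "called" and len(s.genotype) == 1
                }
                calls = {
                    k: v for k, v in calls.items()
                    if k in set(ytable.variants["snp_id"])
                }
                if calls:
                    yhap = assign_y_haplogroup(calls, ytable)["haplogroup"]
            encodings[sid] = encode_hirisplex(prof, effect, panel)
            rows.append(
                {"sample_id": sid, "ancestry_top": anc, "n_aisnps": n_ai,
                 "y_haplogroup": yhap}
            )
        _write_table(pd.DataFrame(rows), out / "predictions.tsv", config)
        hirisplex_batch_file(encodings, effect, out / "hirisplex_batch.csv")
        paths["predictions"] = out / "predictions.tsv"
        paths["hirisplex"] = out / "hirisplex_batch.csv"
    return paths
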