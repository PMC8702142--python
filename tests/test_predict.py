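"""Ancestry, Y-haplogroup and phenotype-encoding predictions."""

import numpy as np
import pandas as pd
import pytest

from forcekin.calling import CalledProfile, CalledSite
from forcekin.panel import POPULATIONS
from forcekin.predict import (
    AncestryReference,
    YHaplogroupTable,
    ancestry_naive_bayes,
    ancestry_pca,
    assign_y_haplogroup,
    encode_hirisplex,
    hirisplex_batch_file,
)


def _profile(panel, genotypes, sex="M"):
    sites = {}
    for sid, geno in genotypes.items():
        if geno is None:
            sites[sid] = CalledSite(sid, "no_call", None, 0, 0.0)
        else:
            sites[sid] = CalledSite(sid, "called", tuple(geno), 100, 0.0)
    return CalledProfile("q", sex, sites, panel)


class TestNaiveBayes:
    def test_hand_arithmetic_two_populations(self, small_panel):
        """alt/alt at one SNP, p=0.9 vs 0.1: posterior 0.81/(0.81+0.01)."""
        ai = small_panel.category("aiSNP")["snp_id"].iloc[0]
        row = small_panel.df.set_index("snp_id").loc[ai]
        ref = AncestryReference(
            pd.DataFrame({"pop1": [0.9], "pop2": [0.1]}, index=[ai])
        )
        prof = _profile(small_panel, {ai: (row["alt"], row["alt"])})
        out = ancestry_naive_bayes(prof, ref, small_panel)
        assert out["posteriors"]["pop1"] == pytest.approx(0.81 / 0.82, rel=1e-6)
        assert out["n_aisnps_used"] == 1

    def test_identical_frequencies_uniform_posterior(self, small_panel):
        ref = AncestryReference.from_panel(small_panel)
        flat = ref.frequencies.copy()
        for p in POPULATIONS:
            flat[p] = ref.frequencies["EUR"]
        genos = {}
        pdf = small_panel.df.set_index("snp_id")
        for sid in flat.index[:10]:
            genos[sid] = (pdf.at[sid, "ref"], pdf.at[sid, "alt"])
        prof = _profile(small_panel, genos)
        out = ancestry_naive_bayes(prof, AncestryReference(flat), small_panel)
        for v in out["posteriors"].values():
            assert v == pytest.approx(0.2, abs=1e-9)

    def test_posteriors_sum_to_one(self, small_panel):
        ref = AncestryReference.from_panel(small_panel)
        pdf = small_panel.df.set_index("snp_id")
        genos = {
            sid: (pdf.at[sid, "ref"], pdf.at[sid, "ref"])
            for sid in ref.frequencies.index[:15]
        }
        out = ancestry_naive_bayes(
            _profile(small_panel, genos), ref, small_panel
        )
        assert sum(out["posteriors"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_usable_aisnps_rejected(self, small_panel):
        ref = AncestryReference.from_panel(small_panel)
        with pytest.raises(ValueError):
            ancestry_naive_bayes(_profile(small_panel, {}), ref, small_panel)

    def test_simulated_profile_assigned_to_source_population(self):
        """A profile drawn from the EUR frequencies of a divergent 5-pop
        reference is called EUR with posterior > 0.99 (~240 aiSNPs)."""
        from forcekin.pedigree import Individual, Pedigree
        from forcekin.simulate import (
            build_panel_skeleton,
            generate_population_frequencies,
            simulate_pedigree_genotypes,
        )

        panel = generate_population_frequencies(
            build_panel_skeleton(0, 0, 240, 0, 0, 0, seed=33),
            fst=0.15, ai_fst=0.15, seed=34,
        )
        truth = simulate_pedigree_genotypes(
            Pedigree([Individual("u", "M")]), panel, population="EUR", seed=35
        )
        pdf = panel.df
        genos = {}
        for i, sid in enumerate(pdf["snp_id"]):
            d = truth.dosage("u")[i]
            a = [pdf["ref"].iloc[i], pdf["alt"].iloc[i]]
            genos[sid] = (a[0], a[0]) if d == 0 else (
                (a[0], a[1]) if d == 1 else (a[1], a[1])
            )
        prof = _profile(panel, genos)
        out = ancestry_naive_bayes(
            prof, AncestryReference.from_panel(panel), panel
        )
        assert out["posteriors"]["EUR"] > 0.99


class TestPCA:
    def _reference(self, seed=0, n_snp=60, n_per_pop=30, fst=0.2):
        rng = np.random.default_rng(seed)
        freqs = {}
        for pop in ("P1", "P2"):
            p = np.clip(rng.beta(2, 2, n_snp) + (0.25 if pop == "P2" else -0.25) * rng.random(n_snp), 0.02, 0.98)
            freqs[pop] = p
        rows, labels = [], []
        for pop in ("P1", "P2"):
            for i in range(n_per_pop):
                rows.append(rng.binomial(2, freqs[pop]))
                labels.append(pop)
        geno = pd.DataFrame(
            np.array(rows), columns=[f"ai{j}" for j in range(n_snp)],
            index=[f"{l}_{i}" for i, l in enumerate(labels)],
        )
        return AncestryReference(
            pd.DataFrame({p: freqs[p] for p in freqs}, index=geno.columns),
            genotypes=geno,
            labels=pd.Series(labels, index=geno.index),
        )

    def test_query_equal_to_reference_individual_projects_identically(self):
        ref = self._reference()
        first = ref.genotypes.iloc[0]
        out = ancestry_pca(ref, dict(first))
        np.testing.assert_allclose(
            out["query_coords"],
            out["reference_coords"]
            .loc[first.name, ["PC1", "PC2"]]
            .to_numpy(dtype=float),
            atol=1e-8,
        )

    def test_first_component_separates_populations(self):
        from sklearn.metrics import silhouette_score

        ref = self._reference(seed=1)
        out = ancestry_pca(ref, dict(ref.genotypes.iloc[0]))
        coords = out["reference_coords"]
        score = silhouette_score(
            coords[["PC1"]].to_numpy(), coords["population"].to_numpy()
        )
        assert score > 0

    def test_fully_missing_query_rejected(self):
        ref = self._reference()
        with pytest.raises(ValueError, match="50%"):
            ancestry_pca(ref, {})

    def test_constant_matrix_rejected(self):
        geno = pd.DataFrame(
            np.ones((10, 5), dtype=int), columns=[f"ai{j}" for j in range(5)]
        )
        ref = AncestryReference(
            pd.DataFrame({"P1": [0.5] * 5}, index=geno.columns), genotypes=geno
        )
        with pytest.raises(ValueError, match="degenerate"):
            ancestry_pca(ref, dict(geno.iloc[0]))


def _small_tree():
    parent = {"ROOT": None, "A": "ROOT", "A1": "A", "A1a": "A1", "B": "ROOT",
              "B1": "B"}
    rows = []
    for i, hg in enumerate(["A", "A1", "A1a", "B", "B1", "A1a", "B"]):
        rows.append(
            {"snp_id": f"y{i}", "haplogroup": hg, "ancestral": "C",
             "derived": "T"}
        )
    return YHaplogroupTable(pd.DataFrame(rows), parent)


class TestYHaplogroup:
    def test_clean_path_reports_leaf_without_conflicts(self):
        table = _small_tree()
        calls = {"y0": "T", "y1": "T", "y2": "T", "y3": "C", "y4": "C"}
        out = assign_y_haplogroup(calls, table)
        assert out["haplogroup"] == "A1a"
        assert out["conflicts"] == []

    def test_all_ancestral_reports_root(self):
        table = _small_tree()
        out = assign_y_haplogroup({f"y{i}": "C" for i in range(5)}, table)
        assert out["haplogroup"] == "ROOT"
        assert out["score"] == 0

    def test_off_path_derived_reported_as_conflicts(self):
        table = _small_tree()
        calls = {"y0": "T", "y1": "T", "y3": "T"}
        out = assign_y_haplogroup(calls, table)
        assert out["haplogroup"] == "A1"
        assert out["conflicts"] == ["y3"]

    def test_order_invariance(self):
        table = _small_tree()
        calls = {"y0": "T", "y1": "T", "y2": "T", "y4": "C"}
        a = assign_y_haplogroup(dict(sorted(calls.items())), table)
        b = assign_y_haplogroup(dict(sorted(calls.items(), reverse=True)), table)
        assert a == b

    def test_dropout_robust_leaf_recovery(self):
        """A profile derived along one root-to-leaf path with 5% random
        call dropout recovers the correct leaf in >= 95% of replicates."""
        parent = {"ROOT": None}
        rows = []
        prev = "ROOT"
        for depth in range(6):
            hg = f"H{depth}"
            parent[hg] = prev
            prev = hg
        # a second decoy branch
        parent["D0"] = "ROOT"
        parent["D1"] = "D0"
        hgs = [f"H{d}" for d in range(6)] + ["D0", "D1"]
        for i in range(60):
            rows.append(
                {"snp_id": f"y{i}", "haplogroup": hgs[i % len(hgs)],
                 "ancestral": "C", "derived": "T"}
            )
        table = YHaplogroupTable(pd.DataFrame(rows), parent)
        on_path = {f"H{d}" for d in range(6)}
        rng = np.random.default_rng(17)
        ok = 0
        for _ in range(100):
            calls = {}
            for r in table.variants.itertuples(index=False):
                if rng.random() < 0.05:
                    continue  # dropout
                calls[r.snp_id] = "T" if r.haplogroup in on_path else "C"
            out = assign_y_haplogroup(calls, table)
            ok += out["haplogroup"] == "H5"
        assert ok >= 95


class TestHirisplexEncoding:
    def _effect(self, panel):
        rows = []
        for i, r in enumerate(panel.category("piSNP").itertuples(index=False)):
            rows.append(
                {"snp_id": r.snp_id, "effect_allele": r.alt, "strand": "+"}
            )
        return pd.DataFrame(rows)

    def test_effect_homozygote_encodes_two(self, small_panel):
        effect = self._effect(small_panel)
        sid = effect["snp_id"].iloc[0]
        alt = small_panel.df.set_index("snp_id").at[sid, "alt"]
        prof = _profile(small_panel, {sid: (alt, alt)})
        enc = encode_hirisplex(prof, effect, small_panel)
        assert enc[sid] == 2

    def test_no_call_encodes_na(self, small_panel):
        effect = self._effect(small_panel)
        sid = effect["snp_id"].iloc[0]
        prof = _profile(small_panel, {sid: None})
        enc = encode_hirisplex(prof, effect, small_panel)
        assert enc[sid] == "NA"

    def test_minus_strand_complement_counting(self, small_panel):
        """Genotype C/T on a minus-strand marker with plus-strand effect
        allele G complements to G/A and counts one effect allele."""
        effect = self._effect(small_panel)
        sid = effect["snp_id"].iloc[0]
        effect.loc[effect["snp_id"] == sid, ["effect_allele", "strand"]] = ["G", "-"]
        prof = _profile(small_panel, {sid: ("C", "T")})
        enc = encode_hirisplex(prof, effect, small_panel)
        assert enc[sid] == 1

    def test_values_restricted_to_alphabet(self, small_panel):
        effect = self._effect(small_panel)
        pdf = small_panel.df.set_index("snp_id")
        genos = {}
        rng = np.random.default_rng(2)
        for sid in effect["snp_id"]:
            if rng.random() < 0.3:
                genos[sid] = None
            else:
                a = [pdf.at[sid, "ref"], pdf.at[sid, "alt"]]
                genos[sid] = tuple(rng.choice(a, 2))
        enc = encode_hirisplex(_profile(small_panel, genos), effect, small_panel)
        assert set(map(str, enc.values())) <= {"0", "1", "2", "NA"}

    def test_missing_pisnp_in_effect_table_rejected(self, small_panel):
        effect = self._effect(small_panel).iloc[1:]
        with pytest.raises(ValueError, match="effect table"):
            encode_hirisplex(_profile(small_panel, {}), effect, small_panel)

    def test_batch_file_layout(self, tmp_path, small_panel):
        effect = self._effect(small_panel)
        enc = {s: "NA" for s in effect["snp_id"]}
        path = tmp_path / "batch.csv"
        hirisplex_batch_file({"s1": enc, "s2": enc}, effect, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["sampleid", *effect["snp_id"]]
        assert len(df) == 2
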