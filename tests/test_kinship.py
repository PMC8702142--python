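"""LR layer: posteriors, symmetry, missing person, blind search, X LRs."""

import numpy as np
import pandas as pd
import pytest

from forcekin.kinship import (
    blind_search,
    is_strong_support,
    kappa_log10_lr,
    missing_person_log10_lr,
    pairwise_log10_lr,
    posteriors,
    prepare_markers,
    two_hypothesis_posterior,
)
from forcekin.pedigree import (
    RELATIONSHIPS,
    Individual,
    Pedigree,
    relationship_template,
)
from forcekin.study import _simulate_pair_dosages

from conftest import unlinked_markers


class TestClosedFormExamples:
    def test_parent_offspring_shared_homozygote(self):
        """Parent alt/alt, child alt/alt at p=0.4: LR = 1/p = 2.5."""
        lr = kappa_log10_lr(
            np.array([2]), np.array([2]), np.array([0.4]), (0, 1, 0)
        )
        assert 10**lr == pytest.approx(2.5)

    def test_full_siblings_shared_homozygote(self):
        """Both sibs alt/alt at p=0.5: LR = (k0 p^2 + k1 p + k2)/p^2 = 2.25."""
        lr = kappa_log10_lr(
            np.array([2]), np.array([2]), np.array([0.5]), (0.25, 0.5, 0.25)
        )
        assert 10**lr == pytest.approx(2.25)

    def test_no_shared_markers_unit_lr(self):
        lr = kappa_log10_lr(
            np.array([-1, 2]), np.array([1, -1]), np.array([0.4, 0.4]),
            (0.25, 0.5, 0.25),
        )
        assert lr == 0.0


class TestPosteriors:
    def test_lr_ten_thousand_meets_criterion(self):
        post = two_hypothesis_posterior(4.0)
        assert post == pytest.approx(10000 / 10001)
        assert post >= 0.9999
        assert is_strong_support(4.0, post)

    def test_equal_likelihoods_uniform(self):
        post = posteriors({"a": 0.0, "b": 0.0, "c": 0.0})
        for v in post.values():
            assert v == pytest.approx(0.25)  # + implicit unrelated

    def test_zero_likelihood_zero_posterior(self):
        post = posteriors({"a": -np.inf, "b": 1.0})
        assert post["a"] == 0.0

    def test_normalization_and_permutation_invariance(self):
        lrs = {"a": 2.0, "b": -1.0, "c": 0.5}
        p1 = posteriors(lrs)
        p2 = posteriors(dict(reversed(list(lrs.items()))))
        assert sum(p1.values()) == pytest.approx(1.0, abs=1e-12)
        for k in lrs:
            assert p1[k] == pytest.approx(p2[k], rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            posteriors({"a": -np.inf, "unrelated": -np.inf})


class TestPairwiseSymmetry:
    @pytest.mark.parametrize(
        "hyp", ["full_siblings", "half_siblings", "first_cousins",
                "second_cousins"]
    )
    def test_symmetric_templates_commute(self, hyp):
        rng = np.random.default_rng(1)
        markers = unlinked_markers(20, seed=1)
        dA = rng.integers(0, 3, 20)
        dB = rng.integers(0, 3, 20)
        ab = pairwise_log10_lr(dA, dB, hyp, markers)
        ba = pairwise_log10_lr(dB, dA, hyp, markers)
        assert ab == pytest.approx(ba, rel=1e-9, abs=1e-9)

    def test_unrelated_hypothesis_unit_lr(self):
        markers = unlinked_markers(5)
        d = np.ones(5, dtype=int)
        assert pairwise_log10_lr(d, d, "unrelated", markers) == 0.0


class TestExpectedLRUnderH2:
    def test_mean_lr_is_one_for_unrelated_pairs(self, markers_eur):
        """E[LR] = 1 under H2: 2000 unrelated pairs at 50 markers."""
        rng = np.random.default_rng(2)
        markers = unlinked_markers(50, seed=2)
        dA, dB = _simulate_pair_dosages("full_siblings", markers, 2000, rng, False)
        l10 = pairwise_log10_lr(dA, dB, "full_siblings", markers)
        lrs = 10.0**np.asarray(l10)
        se = lrs.std(ddof=1) / np.sqrt(len(lrs))
        assert abs(lrs.mean() - 1.0) < 3 * se


class TestMissingPerson:
    def _family(self):
        return Pedigree(
            [
                Individual("f", "M"), Individual("m", "F"),
                Individual("mp", "M", "f", "m"),
                Individual("sib", "F", "f", "m"),
                Individual("sp", "M"),
                Individual("niece", "F", "sp", "sib"),
            ]
        )

    def test_true_missing_person_strongly_supported(self, markers_eur):
        """Unknown simulated as the true missing person against three
        typed relatives: log10 LR far above 4."""
        from forcekin.simulate import simulate_pedigree_genotypes

        fam = self._family()
        # simulate on the small panel, typed refs = f, sib, niece
        import forcekin.calling as calling

        truth_seed = 80
        from forcekin.simulate import build_panel_skeleton  # noqa: F401

        ped_markers = markers_eur
        # direct dosage simulation through the pedigree
        rng = np.random.default_rng(truth_seed)
        dosages = _drop_family(fam, ped_markers, rng)
        refs = {i: dosages[i] for i in ("f", "sib", "niece")}
        l10 = missing_person_log10_lr(fam, "mp", refs, dosages["mp"], ped_markers)
        assert l10 > 10

    def test_unrelated_unknown_rarely_positive(self, markers_eur):
        fam = self._family()
        rng = np.random.default_rng(81)
        dosages = _drop_family(fam, markers_eur, rng)
        refs = {i: dosages[i] for i in ("f", "sib", "niece")}
        freq = markers_eur["freq"].to_numpy()
        neg = 0
        n_rep = 40
        for _ in range(n_rep):
            stranger = (
                (rng.random(len(freq)) < freq).astype(int)
                + (rng.random(len(freq)) < freq).astype(int)
            )
            l10 = missing_person_log10_lr(fam, "mp", refs, stranger, markers_eur)
            neg += l10 <= 0
        assert neg >= 0.9 * n_rep

    def test_untyped_references_give_unit_lr(self, markers_eur):
        fam = self._family()
        rng = np.random.default_rng(82)
        freq = markers_eur["freq"].to_numpy()
        unknown = (
            (rng.random(len(freq)) < freq).astype(int)
            + (rng.random(len(freq)) < freq).astype(int)
        )
        l10 = missing_person_log10_lr(fam, "mp", {}, unknown, markers_eur)
        assert l10 == pytest.approx(0.0, abs=1e-9)

    def test_oversized_pedigree_rejected_clearly(self, markers_eur):
        """A reference constellation needing more meioses than the cap is
        refused with an explanatory error."""
        inds = [Individual("g1", "M"), Individual("g2", "F")]
        prev = "g1"
        # long descent chain: 10 non-founders > 9-meiosis budget at cap 18
        for i in range(10):
            inds.append(Individual(f"sp{i}", "F"))
            inds.append(Individual(f"c{i}", "M", prev, f"sp{i}"))
            prev = f"c{i}"
        fam = Pedigree(inds)
        d = np.zeros(len(markers_eur), dtype=int)
        with pytest.raises(ValueError, match="meioses"):
            missing_person_log10_lr(fam, "g1", {prev: d}, d, markers_eur)


def _drop_family(ped, markers, rng):
    """Single-locus-exact gene dropping of dosages for every member."""
    freq = markers["freq"].to_numpy()
    from forcekin.engine import haldane_theta

    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_cm"].to_numpy()
    n = len(markers)
    theta = np.ones(n) * 0.5
    for ch in pd.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        theta[idx[1:]] = haldane_theta(np.diff(pos[idx]))
    haps = {}
    for iid in ped.topo_order():
        ind = ped.members[iid]
        if ind.is_founder:
            haps[iid] = (rng.random((n, 2)) < freq[:, None]).astype(int)
        else:
            g = np.empty((n, 2), dtype=int)
            for col, par in ((0, ind.father), (1, ind.mother)):
                sw = rng.random(n) < theta
                pick = np.bitwise_xor.accumulate(sw.astype(np.int8))
                g[:, col] = haps[par][np.arange(n), pick]
            haps[iid] = g
    return {iid: h.sum(axis=1) for iid, h in haps.items()}


class TestBlindSearch:
    def test_parent_offspring_pair_flagged_top(self, markers_eur):
        rng = np.random.default_rng(3)
        ped, a, b = relationship_template("parent_offspring")
        dos = _drop_family(ped, markers_eur, rng)
        freq = markers_eur["freq"].to_numpy()
        stranger = (
            (rng.random(len(freq)) < freq).astype(int)
            + (rng.random(len(freq)) < freq).astype(int)
        )
        table = blind_search(
            {"p": dos[a], "c": dos[b], "s": stranger}, markers_eur, max_degree=3
        )
        po_row = table[(table.id_a == "p") & (table.id_b == "c")].iloc[0]
        assert po_row.best_hypothesis == "parent_offspring"
        assert po_row.log10_lr > 4
        # at this reduced panel scale the posterior mass may be shared with
        # the other first-degree hypothesis, but relatedness is unambiguous
        per_pair = {
            h: float(
                pairwise_log10_lr(dos[a], dos[b], h, markers_eur)
            )
            for h in ("parent_offspring", "full_siblings")
        }
        post = posteriors(per_pair)
        assert post["parent_offspring"] + post["full_siblings"] > 0.999
        stranger_rows = table[(table.id_a == "s") | (table.id_b == "s")]
        assert not stranger_rows.strong_support.any()

    def test_single_profile_empty_table(self, markers_eur):
        table = blind_search({"only": np.zeros(len(markers_eur), int)}, markers_eur)
        assert len(table) == 0

    def test_max_degree_limits_hypotheses(self, markers_eur):
        from forcekin.kinship import hypotheses_up_to

        assert set(hypotheses_up_to(3)) == {
            "parent_offspring", "full_siblings", "half_siblings", "first_cousins",
        }
        assert len(hypotheses_up_to(6)) == 7


class TestXChromosome:
    def _x_markers(self, panel):
        return prepare_markers(panel, "EUR", mode="X")

    def test_true_sibling_pairs_mostly_positive(self):
        """Brother/sister X-LR positive for true full siblings in >= 90%
        of replicates at the assay's X-SNP count (they share maternal X
        segments)."""
        from forcekin.simulate import (
            build_panel_skeleton,
            generate_population_frequencies,
            simulate_pedigree_genotypes,
        )

        panel = generate_population_frequencies(
            build_panel_skeleton(0, 0, 0, 0, 246, 0, seed=90), seed=91
        )
        markers = self._x_markers(panel)
        id_by_row = dict(zip(panel.df["snp_id"], range(len(panel.df))))
        sel = np.array([id_by_row[s] for s in markers["snp_id"]])
        ped, bro, sis = relationship_template("full_siblings", "M", "F")
        wins = 0
        n_rep = 200
        for r in range(n_rep):
            truth = simulate_pedigree_genotypes(ped, panel, seed=1000 + r)
            dA = truth.dosage(bro, sel)
            dB = truth.dosage(sis, sel)
            l10 = pairwise_log10_lr(
                dA, dB, "full_siblings", markers, mode="X", sexes=("M", "F")
            )
            wins += l10 > 0
        # long-run positive rate is ~0.92; 0.85 leaves binomial headroom
        assert wins >= 0.85 * n_rep

    def test_lr_normalizes_exactly_over_genotype_space(self, small_panel):
        """E[LR] = 1 under H2, checked by exhaustive enumeration: summing
        LR * P_H2 over every female genotype pair at two linked X markers
        returns exactly 1 (the H1 distribution normalizes)."""
        import itertools

        markers = self._x_markers(small_panel).iloc[:2].reset_index(drop=True)
        freq = markers["freq"].to_numpy()

        def hwe(d):
            p = np.clip(freq, 1e-4, 1 - 1e-4)
            probs = np.where(d == 0, (1 - p) ** 2, np.where(d == 1, 2 * p * (1 - p), p**2))
            return probs.prod()

        total = 0.0
        for ga in itertools.product(range(3), repeat=2):
            for gb in itertools.product(range(3), repeat=2):
                dA, dB = np.array(ga), np.array(gb)
                l10 = pairwise_log10_lr(
                    dA, dB, "full_siblings", markers, mode="X", sexes=("F", "F")
                )
                total += hwe(dA) * hwe(dB) * 10.0 ** float(l10)
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_empty_marker_set_unit_lr(self, small_panel):
        markers = self._x_markers(small_panel).iloc[:0]
        l10 = pairwise_log10_lr(
            np.empty(0, int), np.empty(0, int), "full_siblings", markers,
            mode="X", sexes=("F", "F"),
        )
        assert l10 == 0.0


class TestSubsamplingMonotonicity:
    def test_median_lr_non_increasing_with_panel_fraction(self, markers_eur):
        """True-relative LRs shrink (stochastically) as the panel drops
        100% -> 75% -> 25%."""
        rng = np.random.default_rng(5)
        n = len(markers_eur)
        medians = []
        dA, dB = _simulate_pair_dosages(
            "first_cousins", markers_eur, 100, rng, True
        )
        for frac in (1.0, 0.75, 0.25):
            da, db = dA.copy(), dB.copy()
            if frac < 1.0:
                for r in range(100):
                    drop = rng.choice(n, size=n - round(frac * n), replace=False)
                    da[r, drop] = -1
                    db[r, drop] = -1
            l10 = pairwise_log10_lr(da, db, "first_cousins", markers_eur)
            medians.append(float(np.median(np.asarray(l10))))
        assert medians[0] >= medians[1] >= medians[2]
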