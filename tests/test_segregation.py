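import numpy as np
import pandas as pd
import pytest

from polypkin.distances import pairwise_distances
from polypkin.genotype_io import FilterConfig, filter_colony_panel
from polypkin.mating import classification_null, classify_pairs
from polypkin.segregation import (
    CLASS_A,
    CLASS_B,
    CLASS_C,
    classify_colony,
    classify_snp,
    dropout_diagnostic,
    main_lineage,
    typeI_breakdown,
)
from polypkin.synthetic import ColonyRecipe, PopulationModel, simulate_colony, simulate_population
from tests.conftest import make_matrix


def _calls_df(pairs):
    return pd.DataFrame(
        [{"sample_a": a, "sample_b": b, "d": d, "type": t} for a, b, d, t in pairs]
    )


def _freqs(pm):
    t = simulate_population(pm)
    t.attrs["n_total_sites"] = pm.n_total_sites
    return t


class TestMainLineage:
    def test_full_clique_is_whole_colony(self):
        gm = make_matrix(np.zeros((5, 3), dtype=int))
        ids = gm.sample_ids
        pairs = [(a, b, 0, "I") for i, a in enumerate(ids) for b in ids[i + 1 :]]
        lin = main_lineage(gm, _calls_df(pairs))
        assert lin.members == ids and not lin.flagged

    def test_distant_polyp_excluded(self):
        gm = make_matrix(np.zeros((5, 3), dtype=int))
        ids = gm.sample_ids
        pairs = []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                t = "III" if "s5" in (a, b) else "I"
                pairs.append((a, b, 0 if t == "I" else 50, t))
        lin = main_lineage(gm, _calls_df(pairs))
        assert lin.members == ids[:4]

    def test_larger_of_two_cliques_wins(self):
        gm = make_matrix(np.zeros((5, 3), dtype=int))
        a_clique = [("s1", "s2"), ("s1", "s3"), ("s2", "s3")]
        b_clique = [("s4", "s5")]
        pairs = [(a, b, 0, "I") for a, b in a_clique + b_clique]
        pairs += [
            (a, b, 40, "III")
            for a in ("s1", "s2", "s3")
            for b in ("s4", "s5")
        ]
        lin = main_lineage(gm, _calls_df(pairs))
        assert lin.members == ["s1", "s2", "s3"]

    def test_no_type_one_pairs_degenerates_to_most_central_polyp(self):
        gm = make_matrix(np.zeros((3, 3), dtype=int))
        pairs = [("s1", "s2", 10, "II"), ("s1", "s3", 30, "II"), ("s2", "s3", 40, "II")]
        lin = main_lineage(gm, _calls_df(pairs))
        assert lin.flagged and lin.members == ["s1"]

    def test_consensus_is_modal_genotype(self):
        calls = np.array([[1, 0], [1, 0], [0, 2], [1, 2]])
        gm = make_matrix(calls)
        ids = gm.sample_ids
        pairs = [(a, b, 0, "I") for i, a in enumerate(ids) for b in ids[i + 1 :]]
        lin = main_lineage(gm, _calls_df(pairs))
        assert list(lin.consensus) == [1, 0]


class TestClassifySnp:
    def test_single_one_step_deviant_is_clonal_noise(self):
        col = np.array([1, 1, 1, 1, 0])
        cls = classify_snp(col, [0, 1, 2, 3, 4], 1)
        assert cls.snp_class == CLASS_A and cls.foreign_detail == "none"

    def test_segregating_clonal_alleles_are_mendelian(self):
        col = np.array([0, 1, 1, 1, 2])
        cls = classify_snp(col, [0, 1, 2, 3, 4], 1)
        assert cls.snp_class == CLASS_B

    def test_foreign_heterozygote_is_one_allele_mismatch(self):
        col = np.array([0, 0, 0, 0, 1])
        cls = classify_snp(col, [0, 1, 2, 3], 0)
        assert cls.snp_class == CLASS_C and cls.foreign_detail == "one_allele"

    def test_alternate_homozygote_is_fusion_signal(self):
        col = np.array([0, 0, 0, 0, 2])
        cls = classify_snp(col, [0, 1, 2, 3], 0)
        assert cls.snp_class == CLASS_C and cls.foreign_detail == "both_alleles"

    def test_monomorphic_site_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            classify_snp(np.array([0, 0, 0]), [0, 1, 2], 0)

    def test_all_heterozygote_site_is_mendelian(self):
        # both alleles present at every polyp: consistent with segregation
        cls = classify_snp(np.array([1, 1, 1]), [0, 1, 2], 1)
        assert cls.snp_class == CLASS_B

    def test_classes_are_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(3)
        lineage = [0, 1, 2]
        for _ in range(200):
            col = rng.integers(0, 3, size=6)
            if np.unique(col).size < 2:
                continue
            cons = np.bincount(col[lineage], minlength=3).argmax()
            cls = classify_snp(col, lineage, int(cons))
            assert cls.snp_class in {CLASS_A, CLASS_B, CLASS_C}
            assert (cls.foreign_detail != "none") == (cls.snp_class == CLASS_C)


class TestTypeIBreakdown:
    def _lineage(self, gm):
        ids = gm.sample_ids
        pairs = [(a, b, 0, "I") for i, a in enumerate(ids) for b in ids[i + 1 :]]
        return main_lineage(gm, _calls_df(pairs))

    def test_categories_and_fraction_sum(self):
        # rows = polyps, columns = sites with assorted deviation patterns
        gm = make_matrix(
            np.array(
                [[0, 0, 0, 0, 1], [1, 1, 0, 0, 0], [0, 1, 0, 1, 1], [1, 0, 2, 1, 1]]
            ).T
        )
        lin = self._lineage(gm)
        bd = typeI_breakdown(gm, lin)
        assert bd["n_sites"] == sum(bd["counts"].values())
        assert sum(bd["fractions"].values()) == pytest.approx(1.0)

    def test_singleton_vs_repeated_vs_unexplained(self):
        # site0: one deviant polyp (singleton); site1: two configs, both
        # carried twice (repeated); site2: three configs (unexplained)
        calls = np.array(
            [
                [1, 1, 0],
                [1, 1, 1],
                [1, 0, 2],
                [0, 0, 1],
            ]
        )
        gm = make_matrix(calls)
        bd = typeI_breakdown(gm, self._lineage(gm))
        assert bd["counts"] == {"singleton": 1, "repeated_one_step": 1, "unexplained": 1}

    def test_recovers_generator_event_mixture(self):
        # clones only: lineage-polymorphic sites arise from logged errors
        # and somatic mutations; predicted categories from the event log
        # should match the classifier's counts
        pm = PopulationModel(n_total_sites=80_000, fraction_polymorphic=0.025, seed=31)
        recipe = ColonyRecipe(
            n_clonal=6, n_offspring=0, n_unrelated=0,
            somatic_mutation_rate=0.006, sequencing_error_rate=0.004,
        )
        gm, truth = simulate_colony(_freqs(pm), recipe, seed=32)
        panel = filter_colony_panel(gm, recipe.colony_id, FilterConfig(min_depth=1))
        bd = typeI_breakdown(panel, self._lineage(panel))
        assert bd["n_sites"] > 40
        # oracle: rebuild each touched site's lineage genotypes from the
        # founder genotype plus the event log (never from the emitted
        # matrix) and categorize by carrier counts
        site_pos = {s: j for j, s in enumerate(gm.site_ids)}
        per_site: dict[str, dict[str, int]] = {}
        for ev in truth.somatic_events:
            for s in ev["samples"]:
                per_site.setdefault(ev["site_id"], {})[s] = ev["to"]
        for ev in truth.error_events:
            per_site.setdefault(ev["site_id"], {})[ev["sample"]] = ev["to"]
        predicted = {"singleton": 0, "repeated_one_step": 0, "unexplained": 0}
        n_predicted = 0
        panel_sites = set(panel.site_ids)
        for site, overrides in per_site.items():
            if site not in panel_sites:  # e.g. lost to a zero-depth call
                continue
            j = site_pos[site]
            founder_g = int(truth.founder_genotype[j])
            genos = [overrides.get(s, founder_g) for s in gm.sample_ids]
            values, counts = np.unique(genos, return_counts=True)
            if values.size < 2:
                continue
            n_predicted += 1
            if values.size == 2 and abs(int(values[0]) - int(values[1])) == 1:
                predicted["singleton" if counts.min() == 1 else "repeated_one_step"] += 1
            else:
                predicted["unexplained"] += 1
        assert n_predicted == bd["n_sites"]
        for key, frac in bd["fractions"].items():
            assert frac == pytest.approx(predicted[key] / n_predicted, abs=1e-9)


class TestForeignAlleleSpecificity:
    def test_no_settlers_no_alternate_homozygotes(self, default_study):
        gm, truths, _ = default_study
        for colony in ("C1", "C2", "C5"):  # recipes without settlers
            panel = filter_colony_panel(gm, colony, FilterConfig(min_snps_per_colony=1))
            calls = classify_pairs(
                pairwise_distances(panel), classification_null(panel, 300, seed=1)
            )
            cls, _ = classify_colony(panel, calls)
            assert (cls["foreign_detail"] == "both_alleles").sum() == 0

    def test_alternate_homozygotes_increase_with_settler_count(self):
        pm = PopulationModel(seed=41)
        freqs = _freqs(pm)
        counts = []
        for n_u in (1, 3):
            recipe = ColonyRecipe(
                colony_id="S", n_clonal=5, n_offspring=3, n_unrelated=n_u
            )
            gm, _ = simulate_colony(freqs, recipe, seed=42)
            panel = filter_colony_panel(gm, "S", FilterConfig(min_snps_per_colony=1))
            calls = classify_pairs(
                pairwise_distances(panel), classification_null(panel, 300, seed=2)
            )
            cls, _ = classify_colony(panel, calls)
            counts.append(int((cls["foreign_detail"] == "both_alleles").sum()))
        assert 0 < counts[0] < counts[1]


class TestDropoutDiagnostic:
    def _diag(self, depths, flags):
        n_sites = len(depths)
        calls = np.tile([0, 1], (n_sites, 1)).T  # 2 samples, polymorphic sites
        gm = make_matrix(calls, depth=np.vstack([depths, depths]))
        classifications = pd.DataFrame(
            {
                "site_id": gm.site_ids,
                "snp_class": [CLASS_C if f else CLASS_B for f in flags],
                "foreign_detail": ["both_alleles" if f else "none" for f in flags],
            }
        )
        return dropout_diagnostic(gm, classifications)

    def test_identical_depth_groups_show_no_difference(self):
        rep = self._diag([5, 7, 9, 5, 7, 9], [True, True, True, False, False, False])
        assert rep["welch"]["t"] == pytest.approx(0.0)
        assert rep["welch"]["p_value"] == pytest.approx(1.0)

    def test_exact_mannwhitney_matches_enumeration(self):
        from tests.oracles import exact_mannwhitney_two_sided_p

        rep = self._diag([1, 2, 3, 4, 5, 6], [True, True, True, False, False, False])
        assert rep["mannwhitney"]["method"] == "exact"
        assert rep["mannwhitney"]["U"] == 0.0
        oracle_p = exact_mannwhitney_two_sided_p([1, 2, 3], [4, 5, 6])
        assert oracle_p == pytest.approx(0.1)
        assert rep["mannwhitney"]["p_value"] == pytest.approx(oracle_p)

    def test_small_group_flagged_not_testable(self):
        rep = self._diag([5, 6, 7], [True, False, False])
        assert rep["testable"] is False

    def test_dropout_lowers_depth_at_alternate_homozygote_sites(self):
        # positive control: with dropout on and shallow coverage, the
        # fusion-signal sites are systematically shallower
        pm = PopulationModel(seed=6)
        recipe = ColonyRecipe(
            colony_id="D", n_clonal=4, n_offspring=6, n_unrelated=0,
            depth_mean=4.0, depth_dispersion=20.0, dropout_enabled=True,
            sequencing_error_rate=0.0, somatic_mutation_rate=0.0,
        )
        gm, truth = simulate_colony(_freqs(pm), recipe, seed=66)
        assert truth.dropout_events
        panel = filter_colony_panel(gm, "D", FilterConfig(min_depth=1, min_snps_per_colony=1))
        calls = classify_pairs(
            pairwise_distances(panel), classification_null(panel, 300, seed=3)
        )
        cls, _ = classify_colony(panel, calls)
        rep = dropout_diagnostic(panel, cls)
        assert rep["n_alt_hom_sites"] >= 10
        assert rep["welch"]["t"] < 0
        assert rep["welch"]["p_value"] < 0.05
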