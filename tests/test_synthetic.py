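import numpy as np
import pandas as pd
import pytest

from polypkin.distances import mismatch_counts
from polypkin.genotype_io import MISSING
from polypkin.synthetic import (
    ColonyRecipe,
    PopulationModel,
    emit_vcf,
    simulate_colony,
    simulate_dataset,
    simulate_population,
)


def _freq_table(pm):
    t = simulate_population(pm)
    t.attrs["n_total_sites"] = pm.n_total_sites
    return t


class TestSimulatePopulation:
    def test_polymorphic_site_count_is_exact(self):
        pm = PopulationModel(n_total_sites=10_000, fraction_polymorphic=0.005, seed=3)
        assert len(simulate_population(pm)) == 50

    def test_same_seed_reproduces_table(self):
        pm = PopulationModel(seed=42)
        pd.testing.assert_frame_equal(simulate_population(pm), simulate_population(pm))

    def test_zero_polymorphic_sites_rejected(self):
        pm = PopulationModel(n_total_sites=10, fraction_polymorphic=0.001)
        with pytest.raises(ValueError, match="zero polymorphic"):
            simulate_population(pm)

    def test_mean_heterozygosity_matches_closed_form(self):
        # E[2p(1-p)] for Uniform(a,b) = 2(E[p] - E[p^2]); Monte-Carlo check
        pm = PopulationModel(n_total_sites=400_000, fraction_polymorphic=0.01, seed=7)
        freqs = simulate_population(pm)["freq"].to_numpy()
        expected = pm.expected_heterozygosity()
        assert np.mean(2 * freqs * (1 - freqs)) == pytest.approx(expected, abs=0.005)


class TestSimulateColony:
    def test_clone_mates_identical_with_noise_off(self):
        pm = PopulationModel(n_total_sites=20_000, fraction_polymorphic=0.01, seed=1)
        recipe = ColonyRecipe(
            n_clonal=5, n_offspring=0, n_unrelated=0,
            somatic_mutation_rate=0.0, sequencing_error_rate=0.0,
        )
        gm, truth = simulate_colony(_freq_table(pm), recipe, seed=2)
        d, _ = mismatch_counts(gm.calls)
        assert d.max() == 0
        assert all(v == "clone" for v in truth.labels.values())

    def test_offspring_consistent_with_parental_gametes(self):
        pm = PopulationModel(n_total_sites=20_000, fraction_polymorphic=0.01, seed=5)
        recipe = ColonyRecipe(
            n_clonal=0, n_offspring=10, n_unrelated=0,
            somatic_mutation_rate=0.0, sequencing_error_rate=0.0,
        )
        gm, truth = simulate_colony(_freq_table(pm), recipe, seed=6)
        alleles = {0: {0}, 1: {0, 1}, 2: {1}}
        for row in gm.calls:
            for d, m, f in zip(row, truth.founder_genotype, truth.father_genotype):
                if d == MISSING:
                    continue
                assert any(
                    a + b == d for a in alleles[int(m)] for b in alleles[int(f)]
                )

    def test_clone_pair_distance_matches_error_rate_expectation(self):
        # with miscall rate e over L sites, E[pairwise d] ~= 2 e L (1 - e)
        e, L = 0.001, 10_000
        pm = PopulationModel(n_total_sites=2 * L, fraction_polymorphic=0.5, seed=8)
        recipe = ColonyRecipe(
            n_clonal=40, n_offspring=0, n_unrelated=0,
            somatic_mutation_rate=0.0, sequencing_error_rate=e,
        )
        gm, _ = simulate_colony(_freq_table(pm), recipe, seed=9)
        d, _ = mismatch_counts(gm.calls)
        iu = np.triu_indices(40, k=1)
        assert d[iu].mean() == pytest.approx(2 * e * L * (1 - e), rel=0.10)

    def test_somatic_mutations_shared_and_logged(self):
        pm = PopulationModel(n_total_sites=20_000, fraction_polymorphic=0.025, seed=10)
        recipe = ColonyRecipe(
            n_clonal=6, n_offspring=0, n_unrelated=0,
            somatic_mutation_rate=0.02, sequencing_error_rate=0.0,
        )
        gm, truth = simulate_colony(_freq_table(pm), recipe, seed=11)
        assert truth.somatic_events
        site_pos = {s: j for j, s in enumerate(gm.site_ids)}
        row = {s: i for i, s in enumerate(gm.sample_ids)}
        for ev in truth.somatic_events:
            j = site_pos[ev["site_id"]]
            for s in ev["samples"]:
                assert gm.calls[row[s], j] == ev["to"]

    def test_allele_frequencies_recovered_from_unrelated_sample(self):
        pm = PopulationModel(n_total_sites=20_000, fraction_polymorphic=0.01, seed=12)
        freqs = _freq_table(pm)
        recipe = ColonyRecipe(
            n_clonal=0, n_offspring=0, n_unrelated=300,
            somatic_mutation_rate=0.0, sequencing_error_rate=0.0,
        )
        gm, _ = simulate_colony(freqs, recipe, seed=13, colony_fst=0.0)
        est = gm.calls.mean(axis=0) / 2.0
        resid = est - freqs["freq"].to_numpy()
        assert np.abs(resid).mean() < 0.025  # ~ sampling error at n=300

    def test_pair_truth_covers_every_pair(self):
        pm = PopulationModel(n_total_sites=10_000, fraction_polymorphic=0.01, seed=14)
        recipe = ColonyRecipe(n_clonal=3, n_offspring=2, n_unrelated=1)
        gm, truth = simulate_colony(_freq_table(pm), recipe, seed=15)
        n = gm.n_samples
        assert len(truth.pair_classes) == n * (n - 1) // 2
        assert truth.expected_type("C1_c1", "C1_c2") == "I"
        assert truth.expected_type("C1_c1", "C1_o1") == "II"
        assert truth.expected_type("C1_o1", "C1_u1") == "III"


class TestEmitVcf:
    def test_fixture_recipes_regenerate_byte_identical(self, tmp_path):
        pm = PopulationModel(n_total_sites=5_000, fraction_polymorphic=0.01, seed=20)
        recipes = [
            ColonyRecipe(colony_id="A", n_clonal=4, n_offspring=0, n_unrelated=0),
            ColonyRecipe(colony_id="B", n_clonal=4, n_offspring=3, n_unrelated=0),
            ColonyRecipe(colony_id="C", n_clonal=4, n_offspring=3, n_unrelated=2),
        ]
        outputs = []
        for run in ("one", "two"):
            gm, truths, _ = simulate_dataset(pm, recipes, seed=21)
            paths = emit_vcf(gm, truths, tmp_path / run)
            outputs.append({k: p.read_bytes() for k, p in paths.items()})
        assert outputs[0] == outputs[1]

    def test_round_trips_through_genotype_io(self, tmp_path):
        from polypkin.genotype_io import read_vcf

        pm = PopulationModel(n_total_sites=5_000, fraction_polymorphic=0.01, seed=22)
        gm, truths, _ = simulate_dataset(pm, [ColonyRecipe()], seed=23)
        paths = emit_vcf(gm, truths, tmp_path)
        gm2 = read_vcf(paths["vcf"], paths["sample_map"])
        assert gm.equals(gm2)

    def test_empty_dataset_rejected(self, tmp_path):
        import polypkin.synthetic as syn

        gm, truths, _ = simulate_dataset(
            PopulationModel(n_total_sites=5_000, fraction_polymorphic=0.01, seed=24),
            [ColonyRecipe()],
            seed=25,
        )
        empty = gm.subset(samples=[])
        with pytest.raises(ValueError, match="empty"):
            syn.emit_vcf(empty, truths, tmp_path)
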