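import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polypkin.genotype_io import (
    MISSING,
    FilterConfig,
    colony_passes_retention,
    filter_colony_panel,
    population_panel,
    read_vcf,
    write_sample_map,
    write_vcf,
)
from tests.conftest import FIXTURE_CALLS, FIXTURE_DEPTH, make_matrix


class TestReadVcf:
    def test_matches_hand_transcription(self, fixture_vcf):
        gm = read_vcf(*fixture_vcf)
        assert gm.sample_ids == ["p1", "p2", "p3", "p4", "p5"]
        assert gm.site_ids == ["L1:10", "L1:40", "L2:5", "L2:61"]
        np.testing.assert_array_equal(gm.calls, FIXTURE_CALLS)
        np.testing.assert_array_equal(gm.depth, FIXTURE_DEPTH)
        assert gm.total_assayed_sites == 1000

    def test_missing_genotype_is_missing_regardless_of_depth(self, fixture_vcf):
        gm = read_vcf(*fixture_vcf)
        assert gm.calls[0, 1] == MISSING
        assert gm.depth[0, 1] == 3  # depth preserved for the no-call

    def test_rejects_multiallelic(self, tmp_path, fixture_vcf):
        vcf, smap = fixture_vcf
        bad = vcf.read_text().replace("L1\t10\t.\tA\tT", "L1\t10\t.\tA\tT,G")
        p = tmp_path / "bad.vcf"
        p.write_text(bad)
        with pytest.raises(ValueError, match="multiallelic"):
            read_vcf(p, smap)

    def test_rejects_sample_absent_from_map(self, tmp_path, fixture_vcf):
        vcf, smap = fixture_vcf
        trimmed = "\n".join(smap.read_text().splitlines()[:-1]) + "\n"
        p = tmp_path / "short_map.tsv"
        p.write_text(trimmed)
        with pytest.raises(ValueError, match="missing from sample map"):
            read_vcf(vcf, p)

    def test_write_read_round_trip_is_bit_exact(self, tmp_path, fixture_vcf):
        gm = read_vcf(*fixture_vcf)
        out_vcf = tmp_path / "rt.vcf"
        out_map = tmp_path / "rt_map.tsv"
        write_vcf(gm, out_vcf)
        write_sample_map(gm.sample_map, out_map)
        gm2 = read_vcf(out_vcf, out_map)
        assert gm.equals(gm2)


class TestColonyFilter:
    def test_low_depth_call_drops_site_at_full_presence(self):
        # depths (9,9,9,9,7): one call below 8 -> masked -> presence < 1.0
        gm = make_matrix(
            [[0], [1], [0], [1], [0]], depth=np.array([[9], [9], [9], [9], [7]])
        )
        panel = filter_colony_panel(gm, "C1", FilterConfig(min_snps_per_colony=1))
        assert panel.n_sites == 0
        assert panel.meta["filter_report"]["n_sites_dropped_presence"] == 1

    def test_monomorphic_site_dropped(self):
        gm = make_matrix([[0, 0], [0, 1], [0, 2], [0, 1], [0, 1]])
        panel = filter_colony_panel(gm, "C1", FilterConfig())
        assert panel.site_ids == ["L1:1"]
        assert panel.meta["filter_report"]["n_sites_dropped_monomorphic"] == 1

    def test_six_site_fixture_retains_exactly_two(self):
        # site0: polymorphic, full depth        -> kept
        # site1: monomorphic (all hom ref)      -> dropped
        # site2: one depth-7 call               -> dropped (presence)
        # site3: polymorphic, full depth        -> kept
        # site4: missing call                   -> dropped (presence)
        # site5: polymorphic except depth mask makes it monomorphic -> dropped
        calls = np.array(
            [
                [0, 0, 0, 2, MISSING, 1],
                [1, 0, 1, 0, 0, 0],
                [0, 0, 0, 1, 0, 0],
            ]
        )
        depth = np.full(calls.shape, 20)
        depth[1, 2] = 7
        depth[0, 5] = 7
        gm = make_matrix(calls, depth=depth)
        panel = filter_colony_panel(gm, "C1", FilterConfig())
        assert panel.site_ids == ["L0:1", "L3:1"]

    def test_unknown_colony_raises(self):
        gm = make_matrix([[0, 1]])
        with pytest.raises(ValueError, match="unknown colony"):
            filter_colony_panel(gm, "NOPE", FilterConfig())

    def test_empty_result_flagged_not_raised(self):
        gm = make_matrix([[0, 0], [0, 0]])
        with pytest.warns(UserWarning, match="no sites survive"):
            panel = filter_colony_panel(gm, "C1", FilterConfig())
        assert panel.meta["empty_warning"]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_filtering_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(-1, 3, size=(6, 12))
        depth = rng.integers(0, 20, size=(6, 12))
        gm = make_matrix(calls, depth=depth)
        cfg = FilterConfig(min_presence_fraction=0.5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            once = filter_colony_panel(gm, "C1", cfg)
            twice = filter_colony_panel(once, "C1", cfg)
        assert once.equals(twice)
        # retained panel never holds a depth-failing or monomorphic site
        live = once.calls != MISSING
        assert (once.depth[live] >= cfg.min_depth).all()
        for j in range(once.n_sites):
            obs = once.calls[:, j][once.calls[:, j] != MISSING]
            # both alleles present (allele-wise polymorphism)
            assert (obs == 1).any() or ((obs == 0).any() and (obs == 2).any())


class TestRetention:
    @pytest.mark.parametrize(
        "n_polyps, n_snps, expected, reason",
        [
            (5, 100, True, None),
            (4, 500, False, "polyp count"),
            (6, 99, False, "snp count"),
        ],
    )
    def test_thresholds(self, n_polyps, n_snps, expected, reason):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(n_polyps, n_snps))
        # guarantee polymorphism at every site
        calls[0] = 0
        calls[1] = 1
        gm = make_matrix(calls)
        panel = filter_colony_panel(gm, "C1", FilterConfig())
        assert panel.n_sites == n_snps
        ok, why = colony_passes_retention(panel, FilterConfig())
        assert ok is expected
        assert why == reason


class TestPopulationPanel:
    def _multi_locus_matrix(self):
        # 10 loci, 14 SNPs (loci 0-3 carry 2 SNPs each)
        site_ids = []
        for locus in range(10):
            site_ids.append(f"L{locus}:5")
            if locus < 4:
                site_ids.append(f"L{locus}:2")
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, size=(6, len(site_ids)))
        calls[0] = 1 - calls[0]
        gm = make_matrix(calls)
        gm.site_ids = site_ids
        return gm

    def test_one_snp_per_locus_keeps_lowest_position(self):
        gm = self._multi_locus_matrix()
        cfg = FilterConfig(min_presence_fraction=0.5, one_snp_per_locus=True)
        panel = population_panel(gm, "LOC1", cfg)
        assert panel.n_sites == 10
        assert "L0:2" in panel.site_ids and "L0:5" not in panel.site_ids

    def test_no_dedup_when_disabled(self):
        gm = self._multi_locus_matrix()
        cfg = FilterConfig(min_presence_fraction=0.5, one_snp_per_locus=False)
        assert population_panel(gm, "LOC1", cfg).n_sites == 14

    def test_empty_location_returns_empty_panel(self):
        gm = make_matrix([[0, 1]])
        panel = population_panel(
            gm, "LOC_NONE", FilterConfig(min_presence_fraction=0.5, one_snp_per_locus=True)
        )
        assert panel.n_samples == 0 and panel.meta["empty_warning"]
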