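"""P-site assignment, countable-CDS masking, densities, and calling rules."""

import numpy as np
import pandas as pd
import pytest

from pexsite.config import PipelineConfig
from pexsite.enrichment import (assign_psites, build_countable_mask,
                                call_enriched, compare_localizations,
                                compute_enrichment, count_and_density)
from pexsite.genes import FootprintTable, GeneModel
from pexsite.synth import RiboSimParams, generate_footprint_dataset


def _fp(chrom, strand, pos, length=28):
    return FootprintTable.from_arrays([chrom], [strand], [pos], [length])


class TestAssignPsites:
    def test_plus_strand_three_prime_anchored_offset(self):
        res = assign_psites(_fp("chrI", "+", 1000), offset_nt=15)
        assert res.psites.iloc[0].psite_pos == 985

    def test_minus_strand_mirror(self):
        res = assign_psites(_fp("chrI", "-", 1000), offset_nt=15)
        assert res.psites.iloc[0].psite_pos == 1015

    def test_zero_offset_identity(self):
        res = assign_psites(_fp("chrI", "+", 1000), offset_nt=0)
        assert res.psites.iloc[0].psite_pos == 1000

    def test_negative_resulting_position_dropped_and_reported(self):
        res = assign_psites(_fp("chrI", "+", 5), offset_nt=15)
        assert len(res.psites) == 0
        assert res.n_dropped == 1

    def test_negative_offset_raises(self):
        with pytest.raises(ValueError):
            assign_psites(_fp("chrI", "+", 100), offset_nt=-1)


class TestCountableMask:
    def test_same_strand_overlap_excluded_for_both(self, toy_genes):
        mask = build_countable_mask(toy_genes[:2])  # A=[99,200) B=[149,250), both +
        assert mask.intervals["geneA"] == [(99, 149)]
        assert mask.intervals["geneB"] == [(200, 250)]
        assert mask.countable_length["geneA"] == 50
        assert mask.countable_length["geneB"] == 50

    def test_opposite_strand_overlap_retained(self, toy_genes):
        mask = build_countable_mask([toy_genes[0], toy_genes[2]])  # + and -
        assert mask.countable_length["geneA"] == 101
        assert mask.countable_length["geneC"] == 101

    def test_single_gene_mask_is_its_cds(self, toy_genes):
        mask = build_countable_mask([toy_genes[3]])
        assert mask.intervals["geneD"] == [(500, 800), (900, 1100)]
        assert mask.countable_length["geneD"] == 500

    def test_fully_nested_gene_flagged_empty(self):
        outer = GeneModel("outer", "chrI", "+", [(0, 1000)])
        inner = GeneModel("inner", "chrI", "+", [(100, 200)])
        mask = build_countable_mask([outer, inner])
        assert mask.countable_length["inner"] == 0
        assert "inner" in mask.empty_genes
        assert mask.intervals["outer"] == [(0, 100), (200, 1000)]

    def test_matches_position_set_oracle(self, rng):
        """Interval sweep equals the brute-force per-position set arithmetic."""
        for _ in range(10):
            genes = []
            for i in range(6):
                start = int(rng.integers(0, 300))
                genes.append(GeneModel(
                    f"g{i}", "chrI", rng.choice(["+", "-"]),
                    [(start, start + int(rng.integers(20, 150)))]))
            mask = build_countable_mask(genes)
            for g in genes:
                own = set(range(*g.cds_intervals[0]))
                others = set()
                for o in genes:
                    if o.gene_id != g.gene_id and o.strand == g.strand:
                        others |= set(range(*o.cds_intervals[0]))
                expected = own - others
                got = set()
                for s, e in mask.intervals[g.gene_id]:
                    got |= set(range(s, e))
                assert got == expected, g.gene_id


class TestCountAndDensity:
    def _one_gene(self):
        return [GeneModel("g1", "chrI", "+", [(1000, 2000)])]

    def test_zero_psites_zero_counts(self):
        genes = self._one_gene()
        cd = count_and_density(
            pd.DataFrame({"chrom": [], "strand": [], "psite_pos": []}),
            genes, build_countable_mask(genes), library_size=10**6)
        assert cd.loc["g1", "count"] == 0

    def test_hand_arithmetic_example(self, rng):
        """50 in-mask P-sites, countable length 1000, library 1e6."""
        genes = self._one_gene()
        pos = rng.integers(1000, 2000, size=50)
        psites = pd.DataFrame({"chrom": ["chrI"] * 50, "strand": ["+"] * 50,
                               "psite_pos": pos})
        cd = count_and_density(psites, genes, build_countable_mask(genes),
                               library_size=10**6)
        assert cd.loc["g1", "count"] == 50
        assert cd.loc["g1", "density_rpm"] == pytest.approx(50.0)
        assert cd.loc["g1", "density_rpm_per_position"] == pytest.approx(0.05)

    def test_wrong_strand_not_counted(self):
        genes = self._one_gene()
        psites = pd.DataFrame({"chrom": ["chrI"], "strand": ["-"],
                               "psite_pos": [1500]})
        cd = count_and_density(psites, genes, build_countable_mask(genes),
                               library_size=100)
        assert cd.loc["g1", "count"] == 0

    def test_empty_mask_gene_flagged_nan_density(self):
        outer = GeneModel("outer", "chrI", "+", [(0, 1000)])
        inner = GeneModel("inner", "chrI", "+", [(100, 200)])
        genes = [outer, inner]
        cd = count_and_density(
            pd.DataFrame({"chrom": ["chrI"], "strand": ["+"], "psite_pos": [150]}),
            genes, build_countable_mask(genes), library_size=100)
        assert np.isnan(cd.loc["inner", "density_rpm"])
        assert cd.loc["inner", "countable_length"] == 0


def _records_from_counts(in_counts, pd_counts, genes, lib_in=None, lib_pd=None,
                         config=PipelineConfig()):
    mask = build_countable_mask(genes)
    gene_ids = [g.gene_id for g in genes]

    def table(counts, lib):
        rows = []
        for g, c in zip(genes, counts):
            L = mask.countable_length[g.gene_id]
            rpm = c * 1e6 / lib
            rows.append((g.gene_id, c, rpm if L else np.nan,
                         rpm / L if L else np.nan, L))
        return pd.DataFrame(rows, columns=[
            "gene_id", "count", "density_rpm", "density_rpm_per_position",
            "countable_length"]).set_index("gene_id")

    lib_in = lib_in or max(1, sum(in_counts))
    lib_pd = lib_pd or max(1, sum(pd_counts))
    return compute_enrichment(table(in_counts, lib_in),
                              table(pd_counts, lib_pd), genes, config)


class TestComputeEnrichment:
    def _genes(self, n=6):
        return [GeneModel(f"g{i}", "chrI", "+", [(i * 2000, i * 2000 + 1000)])
                for i in range(n)]

    def test_identity_gives_zero_log2_and_standard_normalization(self, rng):
        genes = self._genes()
        counts = list(rng.integers(200, 5000, size=6))
        rec = _records_from_counts(counts, counts, genes,
                                   lib_in=10**6, lib_pd=10**6)
        assert np.allclose(rec.log2_enrichment, 0.0)
        # identical enrichments: z-normalization undefined (sd 0) -> NaN
        assert rec.normalized_enrichment.isna().all()

    def test_normalized_has_zero_mean_unit_sd(self, rng):
        genes = self._genes()
        rec = _records_from_counts(
            list(rng.integers(200, 5000, size=6)),
            list(rng.integers(200, 5000, size=6)), genes,
            lib_in=10**6, lib_pd=10**6)
        z = rec.normalized_enrichment.dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_hand_arithmetic_fourfold(self):
        genes = self._genes(2)
        rec = _records_from_counts([1000, 1000], [4000, 1000], genes,
                                   lib_in=10**8, lib_pd=10**8)
        assert rec.loc["g0", "log2_enrichment"] == pytest.approx(2.0)
        assert rec.loc["g1", "log2_enrichment"] == pytest.approx(0.0)

    def test_input_count_filter_boundary(self):
        genes = self._genes(3)
        rec = _records_from_counts([99, 100, 5000], [500, 500, 500], genes,
                                   lib_in=10**6, lib_pd=10**6)
        assert not rec.loc["g0", "passed_filters"]  # fewer than 100
        assert rec.loc["g1", "passed_filters"]
        assert np.isnan(rec.loc["g0", "log2_enrichment"])

    def test_flagged_genes_never_pass(self):
        genes = self._genes(3)
        genes[0].dubious = True
        genes[1].mitochondrial = True
        rec = _records_from_counts([5000] * 3, [5000] * 3, genes,
                                   lib_in=10**6, lib_pd=10**6)
        assert not rec.loc["g0", "passed_filters"]
        assert not rec.loc["g1", "passed_filters"]
        assert rec.loc["g2", "passed_filters"]

    def test_zero_pulldown_sentinel_excluded_from_normalization(self, rng):
        genes = self._genes()
        pd_counts = list(rng.integers(200, 5000, size=6))
        pd_counts[2] = 0
        rec = _records_from_counts(
            list(rng.integers(200, 5000, size=6)), pd_counts, genes,
            lib_in=10**6, lib_pd=10**6)
        assert np.isneginf(rec.loc["g2", "log2_enrichment"])
        assert rec.loc["g2", "zero_pulldown"]
        assert np.isnan(rec.loc["g2", "normalized_enrichment"])
        z = rec.normalized_enrichment.dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_rpm_scale_invariance(self, rng):
        """Scaling all counts and the library by a constant leaves log2 fixed."""
        genes = self._genes()
        in_counts = list(rng.integers(200, 5000, size=6))
        pd_counts = list(rng.integers(200, 5000, size=6))
        a = _records_from_counts(in_counts, pd_counts, genes,
                                 lib_in=10**6, lib_pd=10**6)
        k = 7
        b = _records_from_counts([k * c for c in in_counts],
                                 [k * c for c in pd_counts], genes,
                                 lib_in=k * 10**6, lib_pd=k * 10**6)
        np.testing.assert_allclose(a.log2_enrichment, b.log2_enrichment)


class TestCalling:
    def _records(self, values, passed=None):
        n = len(values)
        passed = [True] * n if passed is None else passed
        return pd.DataFrame({
            "log2_enrichment": values,
            "normalized_enrichment": values,
            "passed_filters": passed,
        }, index=[f"g{i}" for i in range(n)])

    def test_cutoff_is_strictly_above(self):
        rec = self._records([0.6, 0.4, 0.5])
        assert call_enriched([rec]) == {"g0"}

    def test_dual_bait_intersection(self):
        a = self._records([0.6, 0.6])
        b = self._records([0.6, 0.1])
        assert call_enriched([a, b], require_all_baits=True) == {"g0"}
        assert call_enriched([a, b], require_all_baits=False) == {"g0", "g1"}

    def test_infinite_cutoff_empty(self):
        assert call_enriched([self._records([5.0, 9.0])],
                             cutoff=float("inf")) == set()

    def test_called_implies_passed(self):
        rec = self._records([2.0, 2.0], passed=[True, False])
        assert call_enriched([rec]) == {"g0"}

    def test_monotone_in_cutoff(self, rng):
        rec = self._records(list(rng.normal(0, 1, size=40)))
        sets = [call_enriched([rec], cutoff=c) for c in (-1, 0, 0.5, 1, 2)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_empty_record_list_raises(self):
        with pytest.raises(ValueError):
            call_enriched([])


class TestCompareLocalizations:
    def _records(self, values):
        return pd.DataFrame({
            "log2_enrichment": values,
            "normalized_enrichment": values,
            "passed_filters": [True] * len(values),
        }, index=[f"g{i}" for i in range(len(values))])

    def test_classification(self):
        a = self._records([2.0, 2.0, 0.0, 0.0])
        b = self._records([2.0, 0.0, 2.0, 0.0])
        cls = compare_localizations(a, b)["class"]
        assert list(cls) == ["both", "A-only", "B-only", "neither"]

    def test_empty_b_side_all_a_only(self):
        a = self._records([2.0, 2.0])
        b = self._records([0.0, 0.0])
        assert (compare_localizations(a, b)["class"] == ["A-only", "A-only"]).all()

    def test_disjoint_universes_raise(self):
        a = self._records([1.0])
        b = self._records([1.0]).rename(index={"g0": "h0"})
        with pytest.raises(ValueError):
            compare_localizations(a, b)


class TestSyntheticRecovery:
    def test_single_gene_effect_recovered(self):
        """log2 RPM ratio converges on the planted effect (binomial error)."""
        params = RiboSimParams(n_genes=1, n_enriched=1, true_log2_effect=1.5,
                               mean_input_footprints=20000, seed=4)
        ds = generate_footprint_dataset(params)
        rec = _pipeline_records(ds)["bait1"]
        c_in = rec.input_count.iloc[0]
        c_pd = rec.pulldown_count.iloc[0]
        se = np.sqrt(1 / c_in + 1 / c_pd) / np.log(2)
        assert abs(rec.log2_enrichment.iloc[0] - 1.5) < 3 * se

    def test_planted_effect_median_recovery(self):
        params = RiboSimParams(n_genes=200, n_enriched=20, true_log2_effect=2.0,
                               mean_input_footprints=1000, n_baits=1, seed=8)
        ds = generate_footprint_dataset(params)
        rec = _pipeline_records(ds)["bait1"]
        planted = ds.truth.loc[ds.truth.enriched, "gene_id"]
        assert abs(rec.loc[planted, "log2_enrichment"].median() - 2.0) < 0.1

    def test_generated_psites_land_in_source_cds(self):
        params = RiboSimParams(n_genes=40, n_enriched=4, n_baits=1,
                               mean_input_footprints=200, seed=15)
        ds = generate_footprint_dataset(params)
        cds_union = {}
        for g in ds.genes:
            cds_union.setdefault((g.chrom, g.strand), set()).update(
                g.cds_positions().tolist())
        for kind in ("input", "pulldown"):
            fp = ds.samples["bait1"][kind]
            n_gene = ds.meta["n_gene_footprints"]["bait1"][kind]
            ps = assign_psites(fp, params.psite_offset_nt)
            assert ps.n_dropped == 0
            gene_rows = ps.psites.iloc[:n_gene]
            for _, row in gene_rows.iterrows():
                assert row.psite_pos in cds_union[(row.chrom, row.strand)]
            bg_rows = ps.psites.iloc[n_gene:]
            for _, row in bg_rows.iterrows():
                assert row.psite_pos not in cds_union.get(
                    (row.chrom, row.strand), set())

    def test_dataset_deterministic_given_seed(self):
        params = RiboSimParams(n_genes=30, n_enriched=3, n_baits=1,
                               mean_input_footprints=50, seed=9)
        a = generate_footprint_dataset(params)
        b = generate_footprint_dataset(params)
        pd.testing.assert_frame_equal(a.samples["bait1"]["input"].df,
                                      b.samples["bait1"]["input"].df)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_gene_too_short_for_offset_raises(self):
        with pytest.raises(ValueError, match="gene_length"):
            RiboSimParams(gene_length_nt=40, footprint_length_nt=28,
                          psite_offset_nt=15)


def _pipeline_records(ds):
    mask = build_countable_mask(ds.genes)
    out = {}
    for bait, tables in ds.samples.items():
        cds = {}
        for kind, fp in tables.items():
            ps = assign_psites(fp, 15)
            cds[kind] = count_and_density(ps, ds.genes, mask,
                                          library_size=len(fp))
        out[bait] = compute_enrichment(cds["input"], cds["pulldown"], ds.genes)
    return out
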