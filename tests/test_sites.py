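import numpy as np
import pytest

from ednaclock import sites
from ednaclock.errors import DataError
from ednaclock.io import GeneInterval, MethylSiteRecord

SAMPLES = [("dph10", 10.0), ("dph12", 12.0)]


def rec(pos, code, submodel, sample="dph10", percent=50.0, coverage=3, score=900):
    return MethylSiteRecord(
        contig="MT", start=pos - 1, end=pos, mod_code=code, strand="+",
        score=score, coverage=coverage, percent_modified=percent,
        sample_id=sample, submodel=submodel,
    )


def all_samples(pos, code, submodel, percent=50.0, coverage=3):
    return [
        rec(pos, code, submodel, sample=s, percent=percent, coverage=coverage)
        for s, _ in SAMPLES
    ]


class TestReconcile:
    def test_m_by_both_submodels_is_5mC(self):
        records = all_samples(10, "m", "5mC") + all_samples(10, "m", "5mCG_5hmCG")
        result = sites.reconcile_modtypes(records, SAMPLES)
        assert [s.mod_type for s in result.sites] == ["5mC"]
        assert result.n_conflicts_dropped == 0

    def test_m_and_h_contradiction_dropped_and_counted(self):
        records = all_samples(10, "m", "5mC") + all_samples(10, "h", "5mCG_5hmCG")
        result = sites.reconcile_modtypes(records, SAMPLES)
        assert result.sites == []
        assert result.n_conflicts_dropped == 1

    def test_adenine_only_is_6mA(self):
        result = sites.reconcile_modtypes(all_samples(5, "a", "6mA"), SAMPLES)
        assert [s.mod_type for s in result.sites] == ["6mA"]

    def test_h_only_is_5hmC_even_with_zero_percent_m(self):
        records = all_samples(10, "h", "5mCG_5hmCG") + all_samples(
            10, "m", "5mC", percent=0.0
        )
        result = sites.reconcile_modtypes(records, SAMPLES)
        (site,) = result.sites
        assert site.mod_type == "5hmC"
        assert site.levels == (50.0, 50.0)

    def test_ambiguous_code_is_other_modC(self):
        result = sites.reconcile_modtypes(all_samples(10, "C", "5mC"), SAMPLES)
        assert [s.mod_type for s in result.sites] == ["other_modC"]

    def test_adenine_and_cytosine_same_site_is_data_error(self):
        records = all_samples(10, "a", "6mA") + all_samples(10, "m", "5mC")
        with pytest.raises(DataError, match="adenine and cytosine"):
            sites.reconcile_modtypes(records, SAMPLES)

    def test_missing_age_gets_zero_coverage(self):
        records = [rec(10, "a", "6mA", sample="dph10")]
        (site,) = sites.reconcile_modtypes(records, SAMPLES).sites
        assert site.coverage == (3, 0)

    def test_strands_are_distinct_sites(self):
        plus = all_samples(10, "a", "6mA")
        minus = [
            MethylSiteRecord("MT", 9, 10, "a", "-", 900, 3, 10.0, s, "6mA")
            for s, _ in SAMPLES
        ]
        result = sites.reconcile_modtypes(plus + minus, SAMPLES)
        assert len(result.sites) == 2
        collapsed = sites.reconcile_modtypes(plus + minus, SAMPLES, collapse_strand=True)
        assert len(collapsed.sites) == 1


class TestCoverageFilterAndDetection:
    def _site(self, levels, coverage):
        n = len(levels)
        return sites.ReconciledSite(
            contig="MT", position=1, strand="+", mod_type="6mA",
            ages=tuple(float(i) for i in range(n)),
            levels=tuple(levels), coverage=tuple(coverage),
            reliability=tuple([0.9] * n),
        )

    def test_partial_coverage_excluded(self):
        s = self._site([10] * 6, [1, 1, 1, 0, 1, 1])
        assert sites.filter_complete_coverage([s]) == []

    def test_full_coverage_retained(self):
        s = self._site([10] * 6, [1] * 6)
        assert sites.filter_complete_coverage([s]) == [s]

    def test_min_coverage_threshold(self):
        s = self._site([10] * 6, [3, 2, 2, 2, 2, 1])
        assert sites.filter_complete_coverage([s], min_coverage=2) == []

    def test_constant_levels_not_aging(self):
        assert sites.detect_aging_sites([self._site([20] * 6, [1] * 6)]) == []

    def test_single_unequal_level_is_aging(self):
        s = self._site([0, 0, 0, 0, 0, 100], [1] * 6)
        assert sites.detect_aging_sites([s]) == [s]

    def test_detection_idempotent(self):
        group = [
            self._site([0, 0, 0, 0, 0, 100], [1] * 6),
            self._site([20] * 6, [1] * 6),
        ]
        once = sites.detect_aging_sites(group)
        assert sites.detect_aging_sites(once) == once

    def test_sub_precision_differences_ignored(self):
        s = self._site([20.001, 20.002, 20.0, 20.0, 20.0, 20.0], [1] * 6)
        assert sites.detect_aging_sites([s]) == []


INTERVALS = [
    GeneInterval("ND1", 1, 100, "CDS"),
    GeneInterval("NC1", 101, 150, "NC"),
    GeneInterval("tRNA-Trp", 151, 200, "tRNA"),
]


class TestAnnotation:
    def _site(self, pos):
        return sites.ReconciledSite(
            contig="MT", position=pos, strand="+", mod_type="6mA",
            ages=(10.0,), levels=(1.0,), coverage=(1,), reliability=(0.9,),
        )

    def test_position_in_gap_gets_nc_label(self):
        (s,) = sites.annotate_genes([self._site(120)], INTERVALS)
        assert s.gene == "NC1"

    def test_interval_end_inclusive(self):
        (s,) = sites.annotate_genes([self._site(100)], INTERVALS)
        assert s.gene == "ND1"

    def test_position_outside_reference_raises(self):
        with pytest.raises(DataError, match="outside"):
            sites.annotate_genes([self._site(300)], INTERVALS)

    def test_density_report(self):
        annotated = sites.annotate_genes(
            [self._site(10), self._site(20), self._site(160)], INTERVALS
        )
        df = sites.aging_site_density(annotated, INTERVALS).set_index("gene")
        assert df.loc["ND1", "n_aging_sites"] == 2
        assert df.loc["ND1", "density"] == pytest.approx(2 / 100)
        assert df.loc["tRNA-Trp", "density"] == pytest.approx(1 / 50)
        assert df.loc["NC1", "n_aging_sites"] == 0


class TestDesignMatrix:
    def _sites(self):
        out = []
        for pos, mod in [(5, "5mC"), (10, "6mA"), (15, "6mA")]:
            out.append(
                sites.ReconciledSite(
                    contig="MT", position=pos, strand="+", mod_type=mod,
                    ages=(10.0, 12.0, 14.0, 17.0, 19.0, 24.0),
                    levels=(0.0, 10.0, 20.0, 30.0, 40.0, 50.0),
                    coverage=(1,) * 6, reliability=(0.9,) * 6, gene="ND1",
                )
            )
        return out

    def test_shape_and_response(self):
        d = sites.build_design_matrix(self._sites())
        assert d.X.shape == (6, 3)
        assert list(d.ages) == [10, 12, 14, 17, 19, 24]

    def test_modA_filtering(self):
        d = sites.build_design_matrix(self._sites(), dataset="modA")
        assert d.n_sites == 2
        assert set(d.metadata.mod_type) == {"6mA"}

    def test_zero_sites_after_filtering_raises(self):
        only_a = [s for s in self._sites() if s.mod_type == "6mA"]
        with pytest.raises(DataError):
            sites.build_design_matrix(only_a, dataset="modC")

    def test_column_order_is_stable_lexicographic(self):
        d1 = sites.build_design_matrix(self._sites())
        d2 = sites.build_design_matrix(list(reversed(self._sites())))
        assert d1.site_keys == d2.site_keys
        assert np.array_equal(d1.X, d2.X)


class TestPipelineCounts:
    def test_count_identity_on_generated_data(self, planted_dataset):
        from ednaclock import io as io_mod

        records = []
        for (sid, sub), path in planted_dataset.bedmethyl_paths.items():
            records.extend(io_mod.read_bedmethyl(path, sid, sub))
        recon = sites.reconcile_modtypes(records, planted_dataset.samples)
        covered = sites.filter_complete_coverage(recon.sites)
        aging = sites.detect_aging_sites(covered)
        cfg = planted_dataset.config
        total_emitted = cfg.n_sites
        assert len(recon.sites) + recon.n_conflicts_dropped == total_emitted
        dropped_cov = len(recon.sites) - len(covered)
        non_diff = len(covered) - len(aging)
        assert dropped_cov == cfg.n_incomplete_sites
        assert non_diff == cfg.n_constant_sites
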