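import math

import numpy as np
import pytest

from sdscan.affinity_stats import (
    OTHER,
    RPSU_STRONG_SD,
    UNCLASSIFIED,
    ChanceTailFit,
    FitFailure,
    classify_organism,
    count_excess_genes,
    cumulative_histogram,
    fit_chance_tail,
    read_tree_annotation,
    summarize_organism,
    write_tree_annotation,
)
from sdscan.synthetic_data import OrganismSpec, build_organism
from sdscan.tir_scan import GeneAffinity, scan_organism


def aff(dg, gene="g", product="p", organism="o", rprot=False, msd=0.0):
    return GeneAffinity(
        organism=organism, gene=gene, product=product, is_rprotein=rprot,
        sd_dG=dg, sd_offset=None, sd_helix_len=0, msd_dG=msd,
    )


class TestCumulativeHistogram:
    def test_direct_counts(self):
        h = cumulative_histogram([aff(-2.5), aff(-2.5), aff(-7.0)])
        assert h.count_at(-7) == 1
        assert h.count_at(-3) == 3
        assert h.count_at(0) == 3
        assert np.all(np.diff(h.counts) >= 0)  # monotone toward 0

    def test_all_zero_affinities(self):
        h = cumulative_histogram([aff(0.0)] * 4)
        assert h.count_at(0) == 4
        assert h.count_at(-1) == 0

    def test_additivity_on_shared_edges(self):
        a = [aff(-3.2), aff(-1.1)]
        b = [aff(-5.9), aff(-0.4)]
        combined = cumulative_histogram(a + b)
        ha, hb = cumulative_histogram(a), cumulative_histogram(b)
        for e in combined.edges:
            assert combined.count_at(e) == ha.count_at(e) + hb.count_at(e)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cumulative_histogram([])


class TestChanceTailFit:
    @staticmethod
    def synthetic_hist(a, b, lo=-12):
        """Counts following N(E) = round(exp(a + b E)) exactly."""
        edges = np.arange(lo, 1)
        counts = np.round(np.exp(a + b * edges)).astype(int)
        from sdscan.affinity_stats import CumulativeHistogram

        return CumulativeHistogram(organism="o", source="SD", edges=edges, counts=counts)

    def test_exact_line_recovered(self):
        a, b = math.log(5000), 1.2
        fit = fit_chance_tail(self.synthetic_hist(a, b))
        assert fit.intercept == pytest.approx(a, abs=0.05)
        assert fit.slope == pytest.approx(b, abs=0.02)
        # E* = -a/b ≈ -7.09 kcal/mol, the energy where the fit reaches 1
        assert fit.E_star == pytest.approx(-a / b, abs=0.1)
        assert fit.E_star == pytest.approx(-7.09, abs=0.1)

    def test_fit_reaches_one_at_e_star(self):
        fit = fit_chance_tail(self.synthetic_hist(math.log(3000), 1.0))
        assert math.exp(fit.intercept + fit.slope * fit.E_star) == pytest.approx(1.0)

    def test_flat_counts_fail(self):
        with pytest.raises(FitFailure, match="no decay"):
            fit_chance_tail(self.synthetic_hist(math.log(100), 0.0))

    def test_too_few_bins_fail(self):
        from sdscan.affinity_stats import CumulativeHistogram

        h = CumulativeHistogram(
            organism="o", source="SD",
            edges=np.arange(-12, 1),
            counts=np.array([0] * 10 + [20, 80, 300]),  # only -2, -1 usable
        )
        with pytest.raises(FitFailure, match="usable bins"):
            fit_chance_tail(h)


class TestExcessCounts:
    FIT = ChanceTailFit(intercept=12.0, slope=1.0, E_star=-12.0, n_bins=6, residual=0.0)

    def test_threshold_arithmetic(self):
        affs = [aff(-20.0), aff(-8.0), aff(-5.0)]
        counts = count_excess_genes(affs, self.FIT, thresholds=range(10))
        assert counts[0] == 1 and counts[8] == 1 and counts[9] == 0

    def test_no_gene_beyond_e_star(self):
        counts = count_excess_genes([aff(-3.0), aff(-1.0)], self.FIT)
        assert counts == (0,) * 9

    def test_non_increasing_in_k(self):
        affs = [aff(d) for d in (-20, -15, -14, -13, -12.5, -3)]
        counts = count_excess_genes(affs, self.FIT)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestClassification:
    @staticmethod
    def rp(gene, dg, product=None):
        products = {
            "rpsU": "30S ribosomal protein S21",
            "rpsR": "30S ribosomal protein S18",
            "rplE": "50S ribosomal protein L5",
        }
        return aff(dg, gene=gene, product=product or products.get(gene, "rp"), rprot=True)

    def test_strong_unique_minimum(self):
        affs = [self.rp("rpsU", -20.0), self.rp("rpsR", -11.0), self.rp("rplE", -4.0)]
        assert classify_organism(affs) == RPSU_STRONG_SD

    def test_minimum_but_too_weak(self):
        affs = [self.rp("rpsU", -12.5), self.rp("rpsR", -11.0)]
        assert classify_organism(affs) == OTHER

    def test_not_the_minimum(self):
        affs = [self.rp("rpsU", -14.0), self.rp("rpsR", -15.0)]
        assert classify_organism(affs) == OTHER

    def test_tie_is_conservative(self):
        affs = [self.rp("rpsU", -15.0), self.rp("rpsR", -15.0)]
        assert classify_organism(affs) == OTHER

    def test_missing_rpsu_unclassified(self):
        affs = [self.rp("rpsR", -15.0), self.rp("rplE", -4.0)]
        assert classify_organism(affs) == UNCLASSIFIED

    def test_threshold_is_strict(self):
        affs = [self.rp("rpsU", -13.0), self.rp("rpsR", -3.0)]
        assert classify_organism(affs) == OTHER  # -13 is not stronger than -13


class TestTreeAnnotation:
    @staticmethod
    def summary(organism, classification):
        from sdscan.affinity_stats import OrganismSummary

        return OrganismSummary(
            organism=organism, n_genes=10, n_rproteins=26, E_star=-7.0,
            excess_counts=(1,) * 9, rprotein_min_gene="rpsU",
            classification=classification,
        )

    def test_distinct_colors_and_round_trip(self, tmp_path):
        summaries = [self.summary("oA", RPSU_STRONG_SD), self.summary("oB", OTHER)]
        path = tmp_path / "itol.txt"
        write_tree_annotation(summaries, path)
        text = path.read_text()
        assert text.startswith("DATASET_COLORSTRIP")
        assert read_tree_annotation(path) == {"oA": RPSU_STRONG_SD, "oB": OTHER}

    def test_empty_header_only(self, tmp_path):
        path = tmp_path / "itol.txt"
        write_tree_annotation([], path)
        assert path.read_text().rstrip().endswith("DATA")


class TestOnSimulatedOrganisms:
    def test_e_star_stable_across_seeds(self, params):
        """Monte-Carlo stability of E* on large i.i.d. genomes (±1 kcal/mol)."""
        stars = []
        for seed in (101, 202):
            spec = OrganismSpec(seed=seed, n_cds=3000)
            org, _ = build_organism(spec, params)
            affs = scan_organism(org, spec.asd_tail, params)
            stars.append(summarize_organism(affs).E_star)
        assert abs(stars[0] - stars[1]) <= 1.0

    def test_depleted_sd_curve_right_shifted_vs_msd(self, params):
        """SD depletion mimics selection: the SD curve sits right of MSD."""
        from sdscan.synthetic_data import flavobacteriales_like_spec

        spec = flavobacteriales_like_spec(seed=77, n_cds=300)
        org, _ = build_organism(spec, params)
        affs = [a for a in scan_organism(org, spec.asd_tail, params) if a.gene != "rpsU"]
        assert all(a.sd_dG >= -6.0 for a in affs)
        # deep tail: MSD hits beyond -6 kcal/mol exceed (depleted) SD hits
        h_sd = cumulative_histogram(affs, "SD")
        h_msd = cumulative_histogram(affs, "MSD")
        assert h_sd.count_at(-7) == 0
        assert h_msd.count_at(-7) >= 1
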