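"""Efficiency, mutation pattern, enrichment factor and calls."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import besskit
from besskit import (
    CodonState,
    DEFAULT_TEMPLATE,
    PamTally,
    ReadErrorModel,
    be_efficiency,
    call_enriched,
    call_functional,
    compute_stats_table,
    enrichment_factor,
    fold_enrichment,
    generate_library_reads,
    merge_replicates,
    mutation_pattern,
    process_fastq,
    round_fold,
    uniformity_check,
    write_fastq,
)


def tally_of(**rows):
    return PamTally.from_counts(rows)


class TestBeEfficiency:
    def test_worked_example(self):
        row = {"n_total": 100, "n_TGA": 50, "n_TAA": 20, "n_TAG": 10,
               "n_TGG": 20, "n_other": 0}
        assert be_efficiency(row) == pytest.approx(0.80)

    def test_other_in_denominator_only(self):
        row = {"n_total": 100, "n_TGA": 40, "n_TAA": 0, "n_TAG": 0,
               "n_TGG": 40, "n_other": 20}
        assert be_efficiency(row) == pytest.approx(0.40)

    def test_all_unedited_and_empty(self):
        assert be_efficiency(
            {"n_total": 50, "n_TGA": 0, "n_TAA": 0, "n_TAG": 0,
             "n_TGG": 50, "n_other": 0}
        ) == 0.0
        assert math.isnan(be_efficiency(
            {"n_total": 0, "n_TGA": 0, "n_TAA": 0, "n_TAG": 0,
             "n_TGG": 0, "n_other": 0}
        ))

    def test_binomial_recovery_from_generator(self, template=DEFAULT_TEMPLATE):
        f = 0.30
        reads, truth = generate_library_reads(
            {"GGGG": 1.0}, f, template, 1000, ReadErrorModel.noiseless(), seed=17,
        )
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            fq = os.path.join(d, "r.fastq")
            write_fastq(reads, fq)
            tally = process_fastq(fq, template)
        est = be_efficiency(tally.row("GGGG"))
        assert est == pytest.approx(truth.edited_fraction("GGGG"))
        assert abs(est - f) < 3 * math.sqrt(f * (1 - f) / 1000)


class TestMutationPattern:
    def test_simple_proportions(self):
        t = tally_of(GGGG={"n_TGG": 0, "n_TGA": 50, "n_TAG": 20, "n_TAA": 30,
                           "n_other": 0})
        assert mutation_pattern(t) == {"TGA": 0.5, "TAG": 0.2, "TAA": 0.3}

    def test_single_edited_read(self):
        t = tally_of(AAAA={"n_TGG": 0, "n_TGA": 1, "n_TAG": 0, "n_TAA": 0,
                           "n_other": 0})
        assert mutation_pattern(t) == {"TGA": 1.0, "TAG": 0.0, "TAA": 0.0}

    def test_zero_edited_undefined(self):
        t = tally_of(AAAA={"n_TGG": 10, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0,
                           "n_other": 0})
        with pytest.raises(ValueError):
            mutation_pattern(t)

    def test_generator_triplet_recovered_within_3sigma(self):
        triplet = {"TGA": 0.5, "TAG": 0.2, "TAA": 0.3}
        n = 10_000
        _reads, truth = generate_library_reads(
            {"AGGA": 1.0}, 1.0, DEFAULT_TEMPLATE, n,
            ReadErrorModel.noiseless(), seed=23, edit_triplet=triplet,
        )
        t = PamTally.from_counts(
            {"AGGA": {f"n_{k}": truth.count("AGGA", s) for k, s in
                      [("TGA", CodonState.EDITED_TGA),
                       ("TAG", CodonState.EDITED_TAG),
                       ("TAA", CodonState.EDITED_TAA)]}}
        )
        pat = mutation_pattern(t)
        for k, p in triplet.items():
            assert abs(pat[k] - p) < 3 * math.sqrt(p * (1 - p) / n)
        # ordering: TGA most frequent, then TAA, then TAG
        assert pat["TGA"] > pat["TAA"] > pat["TAG"]


class TestEnrichmentFactor:
    def test_printed_definition_arithmetic(self):
        initial = tally_of(
            AAAA={"n_TGG": 990, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
            GGGG={"n_TGG": 10, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
        )
        enriched = tally_of(
            AAAA={"n_TGG": 910, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
            GGGG={"n_TGG": 10, "n_TGA": 80, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
        )
        # enriched: 90 reads of GGGG, 80 edited, of 1000 total; initial 10/1000
        assert enrichment_factor(initial, enriched, "GGGG") == pytest.approx(8.0)

    def test_identity_library_fully_edited_gives_ef_one(self):
        initial = tally_of(
            AGGA={"n_TGG": 30, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
            TTTT={"n_TGG": 70, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
        )
        enriched = tally_of(
            AGGA={"n_TGG": 0, "n_TGA": 30, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
            TTTT={"n_TGG": 0, "n_TGA": 70, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
        )
        for pam in ("AGGA", "TTTT"):
            assert enrichment_factor(initial, enriched, pam) == pytest.approx(1.0)

    def test_absent_from_initial_is_undefined(self):
        initial = tally_of(
            AAAA={"n_TGG": 100, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0})
        enriched = tally_of(
            GGGG={"n_TGG": 0, "n_TGA": 100, "n_TAG": 0, "n_TAA": 0, "n_other": 0})
        assert math.isnan(enrichment_factor(initial, enriched, "GGGG"))

    def test_all_reads_numerator_flag(self):
        initial = tally_of(
            AAAA={"n_TGG": 50, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
            GGGG={"n_TGG": 50, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
        )
        enriched = tally_of(
            AAAA={"n_TGG": 50, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
            GGGG={"n_TGG": 25, "n_TGA": 25, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
        )
        assert enrichment_factor(initial, enriched, "GGGG") == pytest.approx(0.5)
        assert enrichment_factor(
            initial, enriched, "GGGG", numerator="all"
        ) == pytest.approx(1.0)


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "p0,p1,fold,printed",
        [(0.073, 0.676, 9.26, 9), (0.010, 0.552, 55.2, 55), (0.4, 0.4, 1.0, 1)],
    )
    def test_mixture_worked_examples(self, p0, p1, fold, printed):
        f = fold_enrichment(p0, p1)
        assert f == pytest.approx(fold, abs=0.005)
        assert round_fold(f) == printed

    def test_zero_initial_is_error(self):
        with pytest.raises(ValueError):
            fold_enrichment(0.0, 0.5)

    def test_round_half_away_from_zero(self):
        assert round_fold(9.5) == 10
        assert round_fold(8.49) == 8


class TestCalls:
    def test_functional_strictly_greater(self):
        assert call_functional(0.011) is True
        assert call_functional(0.01) is False
        assert call_functional(float("nan")) is False

    def test_enriched_strictly_greater(self):
        assert call_enriched(5.0) is True  # e.g. every NGG in the screen
        assert call_enriched(1.0) is False
        assert call_enriched(float("nan")) is False

    def test_vectorized(self):
        out = call_functional(np.array([0.005, 0.02, np.nan]))
        assert list(out) == [False, True, False]


class TestUniformity:
    def test_perfectly_uniform(self):
        t = PamTally.from_counts(
            {p: {"n_TGG": 100, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0}
             for p in besskit.enumerate_pams(4)}
        )
        u = uniformity_check(t)
        assert u["chi2"] == 0.0 and u["cv"] == 0.0
        assert u["min_freq"] == u["max_freq"] == pytest.approx(1 / 256)

    def test_one_absent_pam_contributes_closed_form(self):
        pams = besskit.enumerate_pams(4)
        counts = {p: {"n_TGG": 100, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0,
                      "n_other": 0} for p in pams[1:]}
        # 25600 reads over 255 PAMs; expected per cell 100, absent cell adds
        # (0-100)^2/100 = 100; occupied cells add ((25600/255)-100)^2/100 each
        counts = {p: {"n_TGG": 0, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0,
                      "n_other": 0} for p in pams}
        for p in pams[1:]:
            counts[p]["n_TGG"] = 100
        counts[pams[1]]["n_TGG"] = 200  # keep total at 25600
        t = PamTally.from_counts(counts)
        u = uniformity_check(t)
        expected = 25_600 / 256
        manual = sum(
            (t.row(p)["n_total"] - expected) ** 2 / expected for p in pams
        )
        assert u["chi2"] == pytest.approx(manual)
        assert (0 - expected) ** 2 / expected == pytest.approx(100.0)

    def test_multinomial_pvalue_not_degenerate(self):
        rng = np.random.default_rng(3)
        pams = besskit.enumerate_pams(4)
        pvals = []
        for _ in range(20):
            draws = rng.multinomial(25_600, [1 / 256] * 256)
            t = PamTally.from_counts(
                {p: {"n_TGG": int(c), "n_TGA": 0, "n_TAG": 0, "n_TAA": 0,
                     "n_other": 0} for p, c in zip(pams, draws)}
            )
            pvals.append(uniformity_check(t)["p_value"])
        pvals = np.array(pvals)
        # p-values from true-uniform draws should look Uniform(0,1)
        assert sps.kstest(pvals, "uniform").pvalue > 1e-3


class TestStatsTableAndMerge:
    @pytest.fixture()
    def small_tables(self):
        initial = tally_of(
            AGGA={"n_TGG": 100, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
            TTTT={"n_TGG": 100, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0},
        )
        enriched = tally_of(
            AGGA={"n_TGG": 20, "n_TGA": 120, "n_TAG": 20, "n_TAA": 40, "n_other": 0},
            TTTT={"n_TGG": 198, "n_TGA": 1, "n_TAG": 0, "n_TAA": 1, "n_other": 0},
        )
        return initial, enriched

    def test_table_contents(self, small_tables):
        initial, enriched = small_tables
        df = compute_stats_table(initial, enriched).set_index("pam")
        assert df.loc["AGGA", "efficiency"] == pytest.approx(0.9)
        assert df.loc["AGGA", "enrichment_factor"] == pytest.approx(
            (180 / 400) / (100 / 200)
        )
        assert bool(df.loc["AGGA", "functional"]) is True
        assert bool(df.loc["TTTT", "functional"]) is False  # 2/200 = 1%, strict
        assert df.attrs["denominator"] == "classified_reads"

    def test_merge_replicates(self, small_tables):
        initial, enriched = small_tables
        t1 = compute_stats_table(initial, enriched)
        t2 = t1.copy()
        t2.loc[t2["pam"] == "AGGA", "efficiency"] = 0.7
        merged = merge_replicates([t1, t2]).set_index("pam")
        assert merged.loc["AGGA", "efficiency_mean"] == pytest.approx((0.9 + 0.7) / 2)
        assert bool(merged.loc["AGGA", "functional_consensus"]) is True
        assert bool(merged.loc["TTTT", "functional_consensus"]) is False

    def test_merge_mismatched_pam_sets(self, small_tables):
        initial, enriched = small_tables
        t1 = compute_stats_table(initial, enriched)
        t2 = t1[t1["pam"] == "AGGA"].copy()
        with pytest.raises(ValueError, match="TTTT"):
            merge_replicates([t1, t2])

    def test_subsampling_preserves_ef_in_expectation(self, template=DEFAULT_TEMPLATE):
        # EF from a 50% read subsample stays within 3 SE of the full-data EF
        rng = np.random.default_rng(29)
        pams = besskit.enumerate_pams(4)[:8]
        initial = tally_of(**{
            p: {"n_TGG": 1000, "n_TGA": 0, "n_TAG": 0, "n_TAA": 0, "n_other": 0}
            for p in pams
        })
        enr_counts = {
            p: {"n_TGG": 200, "n_TGA": 100 * (i + 1), "n_TAG": 0, "n_TAA": 0,
                "n_other": 0}
            for i, p in enumerate(pams)
        }
        enriched = tally_of(**enr_counts)
        full_ef = enrichment_factor(initial, enriched, pams[3])
        efs = []
        for _ in range(50):
            sub = {
                p: {k: int(rng.binomial(v, 0.5)) for k, v in row.items()
                    if k != "n_total"}
                for p, row in enr_counts.items()
            }
            efs.append(enrichment_factor(initial, tally_of(**sub), pams[3]))
        efs = np.array(efs)
        assert abs(efs.mean() - full_ef) < 3 * efs.std(ddof=1) / np.sqrt(len(efs))
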