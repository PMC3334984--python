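"""Array-evaluation statistics: QC, MAF, classification, gaps, panels,
cross-tabs, progeny informativeness, coverage accounting, concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from snparray import evaluate, refdata
from snparray.evaluate import (
    GenotypeMatrix,
    InsufficientDataError,
    SNPClassification,
    classify_snps,
    compare_panels,
    compute_maf,
    coverage_accounting,
    crosstab_validation,
    gap_statistics,
    maf_concordance,
    polymorphism_rate,
    progeny_informativeness,
    qc_genotypes,
)
from snparray.genome import InvalidConfigError
from snparray.utils import round_half_up


def make_matrix(columns: dict, gentrain=None, gencall10=None) -> GenotypeMatrix:
    """columns: snp -> list of calls; scores default to passing."""
    calls = pd.DataFrame(columns)
    snps = list(columns)
    scores = pd.DataFrame(
        {
            "gentrain": [gentrain.get(s, 0.9) if gentrain else 0.9 for s in snps],
            "gencall10": [gencall10.get(s, 0.8) if gencall10 else 0.8 for s in snps],
        },
        index=snps,
    )
    return GenotypeMatrix(calls=calls, snp_scores=scores)


class TestQC:
    def test_gentrain_at_and_below_threshold_fails(self):
        m = make_matrix(
            {"s1": ["AA", "AB"], "s2": ["AA", "AB"], "s3": ["AA", "AB"]},
            gentrain={"s1": 0.39, "s2": 0.40, "s3": 0.41},
        )
        passed, failed = qc_genotypes(m)
        assert failed == ["s1", "s2"]  # keep rule is strictly > 0.4
        assert passed == ["s3"]

    def test_gencall_threshold(self):
        m = make_matrix(
            {"s1": ["AA"], "s2": ["AA"]}, gencall10={"s1": 0.2, "s2": 0.21}
        )
        _, failed = qc_genotypes(m)
        assert failed == ["s1"]

    def test_nocall_majority_rule(self):
        m = make_matrix(
            {
                "half": ["NC", "NC", "AA", "AB"],       # exactly 50%: kept
                "over": ["NC", "NC", "NC", "AA"],       # 75%: failed
            }
        )
        passed, failed = qc_genotypes(m)
        assert passed == ["half"] and failed == ["over"]

    def test_all_perfect_scores_pass(self):
        m = make_matrix({"s1": ["AA", "BB"], "s2": ["AB", "AB"]})
        passed, failed = qc_genotypes(m)
        assert failed == []
        assert len(passed) == 2

    def test_planted_failure_classes_match_brute_force(self):
        """1000 simulated SNPs with random scores and no-call rates
        partition exactly as a record-by-record rule check."""
        rng = np.random.default_rng(0)
        n_samples = 20
        columns, gt, gc = {}, {}, {}
        for i in range(1000):
            s = f"s{i}"
            calls = rng.choice(["AA", "AB", "BB", "NC"], n_samples,
                               p=[0.4, 0.2, 0.2, 0.2])
            columns[s] = calls
            gt[s] = float(rng.uniform(0, 1))
            gc[s] = float(rng.uniform(0, 1))
        m = make_matrix(columns, gentrain=gt, gencall10=gc)
        passed, failed = qc_genotypes(m)
        expect_failed = {
            s
            for s in columns
            if gt[s] <= 0.4
            or gc[s] <= 0.2
            or np.mean(np.asarray(columns[s]) == "NC") > 0.5
        }
        assert set(failed) == expect_failed
        assert set(passed) | set(failed) == set(columns)
        assert not set(passed) & set(failed)


class TestMAF:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (["AA", "AA", "AA"], 0.0),
            (["AA", "AB", "BB"], 0.5),
            (["AA"] * 6 + ["AB"] * 3 + ["NC"], 3 / 18),
            (["BB", "BB"], 0.0),       # folded: all-B is monomorphic
        ],
    )
    def test_hand_counted_examples(self, calls, expected):
        assert compute_maf(calls) == pytest.approx(expected)

    def test_all_nocall_undefined(self):
        assert math.isnan(compute_maf(["NC", "NC"]))

    def test_maf_always_in_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            calls = rng.choice(["AA", "AB", "BB", "NC"], 11)
            maf = compute_maf(calls)
            if not math.isnan(maf):
                assert 0.0 <= maf <= 0.5


class TestClassification:
    def _matrix_with_outcomes(self, n_failed, n_mono, n_poly):
        columns, gt = {}, {}
        for i in range(n_failed):
            columns[f"f{i}"] = ["AA", "AB", "BB", "AA"]
            gt[f"f{i}"] = 0.1
        for i in range(n_mono):
            columns[f"m{i}"] = ["AA", "AA", "AA", "AA"]
        for i in range(n_poly):
            columns[f"p{i}"] = ["AA", "AB", "BB", "AB"]
        return make_matrix(columns, gentrain=gt)

    def test_proportions_at_two_decimals(self):
        """96 SNPs with 23 failed, 18 monomorphic, 55 polymorphic report
        proportions 0.24 / 0.19 / 0.57."""
        m = self._matrix_with_outcomes(23, 18, 55)
        cls = classify_snps(m)
        assert cls.counts == {"failed": 23, "monomorphic": 18, "polymorphic": 55}
        assert cls.proportions == {
            "failed": 0.24, "monomorphic": 0.19, "polymorphic": 0.57,
        }

    def test_all_failed(self):
        m = self._matrix_with_outcomes(5, 0, 0)
        cls = classify_snps(m)
        assert cls.proportions == {"failed": 1.0, "monomorphic": 0.0, "polymorphic": 0.0}

    def test_partition_conserves_totals(self):
        rng = np.random.default_rng(4)
        columns = {
            f"s{i}": rng.choice(["AA", "AB", "BB", "NC"], 10) for i in range(150)
        }
        gt = {f"s{i}": float(rng.uniform(0, 1)) for i in range(150)}
        cls = classify_snps(make_matrix(columns, gentrain=gt))
        assert sum(cls.counts.values()) == 150

    def test_bins_match_brute_force(self):
        rng = np.random.default_rng(9)
        mafs = rng.uniform(0, 0.5, 300)
        table = pd.DataFrame(
            {"outcome": "polymorphic", "maf": mafs},
            index=[f"s{i}" for i in range(300)],
        )
        cls = SNPClassification(table)
        bins = cls.maf_bins()
        assert bins["<5%"] == int((mafs < 0.05).sum())
        assert bins["5-10%"] == int(((mafs >= 0.05) & (mafs <= 0.10)).sum())
        assert bins[">10%"] == int((mafs > 0.10).sum())
        assert sum(bins.values()) == 300
        assert cls.maf_over(0.10) == pytest.approx((mafs > 0.10).mean())

    def test_polymorphism_rate_rounding(self):
        assert polymorphism_rate(919, 1114) == 82.5
        assert polymorphism_rate(6869, 8144) == 84.3


class TestGapStatistics:
    def test_three_positions_forced_arithmetic(self):
        stats = gap_statistics({"c1": [100_000, 200_000, 500_000]})
        row = stats.per_chromosome.loc["c1"]
        assert row["avg_gap_kb"] == pytest.approx(200.0)
        assert row["largest_gap_kb"] == pytest.approx(300.0)
        assert row["n_gaps_over"] == 1

    def test_single_snp_chromosome_has_no_gaps(self):
        stats = gap_statistics({"c1": [5000]})
        row = stats.per_chromosome.loc["c1"]
        assert row["n_gaps"] == 0
        assert math.isnan(row["avg_gap_kb"])

    def test_matches_brute_force_on_random_positions(self):
        rng = np.random.default_rng(2)
        pos = {
            "c1": np.sort(rng.choice(10**7, 50, replace=False)),
            "c2": np.sort(rng.choice(10**7, 30, replace=False)),
        }
        stats = gap_statistics(pos, threshold_kb=150)
        # independent successor-pair oracle
        all_gaps = []
        for c, p in pos.items():
            gaps = [(b - a) / 1000 for a, b in zip(sorted(p), sorted(p)[1:])]
            all_gaps.extend(gaps)
            row = stats.per_chromosome.loc[c]
            assert row["avg_gap_kb"] == pytest.approx(sum(gaps) / len(gaps))
            assert row["largest_gap_kb"] == pytest.approx(max(gaps))
            assert row["n_gaps_over"] == sum(g > 150 for g in gaps)
            assert row["n_gaps"] == row["n_snps"] - 1
        assert stats.total["avg_gap_kb"] == pytest.approx(np.mean(all_gaps))
        assert stats.total["n_gaps_over"] == sum(g > 150 for g in all_gaps)

    def test_duplicate_positions_rejected(self):
        with pytest.raises(InvalidConfigError):
            gap_statistics({"c1": [1, 1, 5]})


class TestPanelComparison:
    def test_published_overlap_counts(self):
        """5,967 shared with 425 and 477 panel-specific SNPs: union 6,869,
        shared fraction 86.9%."""
        a = {f"s{i}" for i in range(5967 + 425)}
        b = {f"s{i}" for i in range(5967)} | {f"t{i}" for i in range(477)}
        cmp = compare_panels(a, b)
        assert cmp.n_shared == 5967
        assert cmp.n_union == 6869
        assert cmp.shared_fraction_pct == 86.9

    def test_identical_sets(self):
        cmp = compare_panels({"a", "b"}, {"a", "b"})
        assert cmp.shared_fraction_pct == 100.0

    def test_disjoint_sets(self):
        cmp = compare_panels({"a"}, {"b"})
        assert cmp.n_shared == 0

    def test_mismatched_universe_rejected(self):
        t1 = pd.DataFrame({"outcome": ["polymorphic"], "maf": [0.2]}, index=["x"])
        t2 = pd.DataFrame({"outcome": ["polymorphic"], "maf": [0.2]}, index=["y"])
        with pytest.raises(InvalidConfigError):
            compare_panels(SNPClassification(t1), SNPClassification(t2))


class TestCrosstab:
    def test_exonic_row_proportion(self):
        """30 exonic SNPs of which 23 polymorphic: proportion 0.77."""
        rows = (
            [("exonic", "polymorphic")] * 23
            + [("exonic", "failed")] * 4
            + [("exonic", "monomorphic")] * 3
        )
        df = pd.DataFrame(rows, columns=["genic", "outcome"])
        df["maf"] = np.nan
        tab = crosstab_validation(df, ["genic"])
        row = tab[tab["value"] == "exonic"].iloc[0]
        assert row["total"] == 30
        assert row["polymorphic"] == 0.77
        assert row["failed"] == 0.13

    def test_single_snp_proportions_binary(self):
        df = pd.DataFrame(
            {"cat": ["x"], "outcome": ["polymorphic"], "maf": [0.3]}
        )
        tab = crosstab_validation(df, ["cat"])
        assert tab.iloc[0]["polymorphic"] == 1.0
        assert tab.iloc[0]["failed"] == 0.0

    def test_random_labels_match_brute_force_tally(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "cat": rng.choice(["p", "q", "r"], 40),
                "outcome": rng.choice(
                    ["failed", "monomorphic", "polymorphic"], 40
                ),
                "maf": rng.uniform(0, 0.5, 40),
            }
        )
        tab = crosstab_validation(df, ["cat"]).set_index("value")
        for value, g in df.groupby("cat"):
            for outcome in ("failed", "monomorphic", "polymorphic"):
                expected = round_half_up(
                    (g["outcome"] == outcome).sum() / len(g), 2
                )
                assert tab.loc[value, outcome] == expected
            poly = g[g["outcome"] == "polymorphic"]
            assert tab.loc[value, "maf_gt10"] == round_half_up(
                (poly["maf"] > 0.10).sum() / len(g), 2
            )

    def test_unlabeled_snp_rejected(self):
        df = pd.DataFrame({"cat": [None], "outcome": ["failed"], "maf": [np.nan]})
        with pytest.raises(InvalidConfigError):
            crosstab_validation(df, ["cat"])


class TestProgeny:
    def _flags_from_distribution(self, dist, n_progenies=5):
        """Expand {n_progenies_segregating: n_snps} into a boolean table."""
        rows = []
        for k, n in dist.items():
            for _ in range(n):
                rows.append([True] * k + [False] * (n_progenies - k))
        return pd.DataFrame(rows, columns=[f"prog{j}" for j in range(n_progenies)])

    def test_published_distribution_gives_95_percent(self):
        flags = self._flags_from_distribution({0: 3, 1: 14, 2: 10, 3: 17, 4: 10, 5: 1})
        summary = progeny_informativeness(flags)
        assert len(flags) == 55
        assert summary.any_progeny_fraction == pytest.approx(52 / 55)
        assert summary.any_progeny_pct == 95.0
        assert summary.distribution == {0: 3, 1: 14, 2: 10, 3: 17, 4: 10, 5: 1}

    def test_zero_flags(self):
        flags = self._flags_from_distribution({0: 10})
        summary = progeny_informativeness(flags)
        assert summary.any_progeny_fraction == 0.0
        assert all(v == 0.0 for v in summary.per_progeny.values())

    def test_all_flags(self):
        flags = self._flags_from_distribution({5: 7})
        summary = progeny_informativeness(flags)
        assert summary.any_progeny_fraction == 1.0
        assert all(v == 1.0 for v in summary.per_progeny.values())


class TestCoverage:
    def test_single_accession_recomputation(self):
        """5.85 M reads x 94 bp over a ~227.4 Mb genome is 2.42x."""
        records = pd.DataFrame(
            {
                "accession": ["Armking"],
                "pool": [1],
                "platform": ["shortread"],
                "read_length": [94],
                "read_count_million": [5.85],
            }
        )
        out, _ = coverage_accounting(records, genome_size=227.4e6)
        assert out["coverage"].iloc[0] == 2.42

    def test_zero_reads_zero_coverage(self):
        records = pd.DataFrame(
            {
                "accession": ["x"], "pool": [1], "platform": ["shortread"],
                "read_length": [100], "read_count_million": [0.0],
            }
        )
        out, agg = coverage_accounting(records, genome_size=1e6)
        assert out["coverage"].iloc[0] == 0.0
        assert agg["total_coverage"] == 0.0

    def test_panel_aggregates_from_reference_table(self):
        """Summing the published per-accession coverages reproduces the
        111.7x panel total; platform means are 2.16x (short-read, excluding
        the flagged low-yield run) and 0.22x (long-read)."""
        panel = refdata.detection_panel()
        assert round_half_up(panel["coverage"].sum(), 1) == 111.7
        # derive the effective genome size from the table itself
        total_bp = (panel["read_count_million"] * 1e6 * panel["read_length"]).sum()
        genome_size = total_bp / panel["coverage"].sum()
        assert genome_size == pytest.approx(227.4e6, rel=0.01)
        out, agg = coverage_accounting(
            panel, genome_size=genome_size, min_reads_million=0.1
        )
        # recomputed per-row coverage matches the published column closely
        assert (out["coverage"] - panel["coverage"]).abs().max() <= 0.06
        assert agg["platform_mean_coverage"]["longread"] == 0.22
        assert abs(agg["platform_mean_coverage"]["shortread"] - 2.16) <= 0.03
        assert agg["n_excluded_from_means"] == 1

    def test_invalid_genome_size(self):
        with pytest.raises(InvalidConfigError):
            coverage_accounting(pd.DataFrame(
                {"accession": [], "pool": [], "platform": [],
                 "read_length": [], "read_count_million": []}), genome_size=0)


class TestMafConcordance:
    def test_identical_vectors(self):
        a = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        assert maf_concordance(a, a.copy()) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        a = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        b = pd.Series([0.2, 0.2, 0.2], index=list("abc"))
        assert math.isnan(maf_concordance(a, b))

    def test_too_few_shared_snps(self):
        a = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(InsufficientDataError):
            maf_concordance(a, a.copy())

    def test_hand_vectors_match_textbook_formula(self):
        rng = np.random.default_rng(8)
        a = pd.Series(rng.uniform(0, 0.5, 10), index=[f"s{i}" for i in range(10)])
        b = pd.Series(rng.uniform(0, 0.5, 10), index=[f"s{i}" for i in range(10)])
        r = maf_concordance(a, b)
        x, y = a.to_numpy(), b.to_numpy()
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected)
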