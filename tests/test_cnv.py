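"""Exon amalgamation, normalisation, QC, Tukey screen and CNV follow-ups."""

import random
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amlpanel import (
    AmalgamatedExon,
    ExonCountMatrix,
    SnpAllelicCounts,
    TargetRegion,
    allelic_imbalance,
    amalgamate_exons,
    coverage_summary,
    detect_duplication_segment,
    exon_cv,
    flag_cnv_genes,
    matrix_from_exon_depths,
    normalize_counts,
    qc_samples,
    sex_linked_ratio,
    tukey_outlier_exons,
)


def make_matrix(values: np.ndarray, samples, gene_exons):
    """gene_exons: list of (gene, exon_index); columns align with values."""
    exons = [AmalgamatedExon(g, i, g, 1000 * i, 1000 * i + 100) for g, i in gene_exons]
    df = pd.DataFrame(values, index=pd.Index(samples, name="sample"),
                      columns=[e.key for e in exons])
    totals = pd.Series(1.0, index=df.index)
    return ExonCountMatrix(values=df, exons=exons, total_mapped_reads=totals)


class TestAmalgamate:
    def region(self, gene, start, end):
        return TargetRegion(gene, start, end, gene, 1, "exonic")

    def test_overlapping_merged(self):
        out = amalgamate_exons([self.region("G", 100, 200), self.region("G", 150, 250)])
        assert [(e.start, e.end, e.exon_index) for e in out] == [(100, 250, 1)]

    def test_disjoint_unchanged(self):
        out = amalgamate_exons([self.region("G", 100, 200), self.region("G", 300, 400)])
        assert [(e.start, e.end) for e in out] == [(100, 200), (300, 400)]

    @settings(max_examples=80, deadline=None)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)), min_size=1, max_size=25
        )
    )
    def test_matches_pairwise_merge_to_fixpoint_oracle(self, intervals):
        regions = [self.region("G", s, s + l) for s, l in intervals]
        got = [(e.start, e.end) for e in amalgamate_exons(regions)]

        # oracle: repeatedly merge any overlapping/touching pair until stable
        pool = [(s, s + l) for s, l in intervals]
        changed = True
        while changed:
            changed = False
            for i in range(len(pool)):
                for j in range(i + 1, len(pool)):
                    a, b = pool[i], pool[j]
                    if a[0] <= b[1] and b[0] <= a[1]:
                        pool[i] = (min(a[0], b[0]), max(a[1], b[1]))
                        pool.pop(j)
                        changed = True
                        break
                if changed:
                    break
        assert got == sorted(pool)


class TestNormalize:
    def exon(self, gene="G", idx=1, start=0, end=50):
        return AmalgamatedExon(gene, idx, "c", start, end)

    def test_arithmetic_identity(self):
        e = self.exon()
        depths = {"s1": {("c", p): 100.0 for p in range(1, 51)}}
        m = normalize_counts(depths, [e], {"s1": 1e6}, scale=1e6)
        assert m.values.loc["s1", e.key] == pytest.approx(100.0)

    def test_scale_invariance(self):
        e = self.exon()
        d1 = {"s1": {("c", p): 100.0 for p in range(1, 51)}}
        d2 = {"s1": {("c", p): 200.0 for p in range(1, 51)}}
        m1 = normalize_counts(d1, [e], {"s1": 1e6})
        m2 = normalize_counts(d2, [e], {"s1": 2e6})
        assert m1.values.equals(m2.values)

    def test_absent_positions_count_zero(self):
        e = self.exon()
        depths = {"s1": {("c", p): 100.0 for p in range(1, 26)}}  # half covered
        m = normalize_counts(depths, [e], {"s1": 1e6})
        assert m.values.loc["s1", e.key] == pytest.approx(50.0)


class TestQcSamples:
    def test_identical_samples_none_excluded(self):
        vals = np.full((6, 8), 50.0)
        m = make_matrix(vals, [f"s{i}" for i in range(6)],
                        [(g, i) for g in "AB" for i in range(1, 5)])
        retained, excluded = qc_samples(m)
        assert excluded == {} and len(retained) == 6

    def test_globally_aberrant_sample_excluded(self):
        rng = np.random.default_rng(0)
        genes = [f"g{k}" for k in range(10)]
        vals = rng.poisson(5000, size=(8, 20)).astype(float)
        vals[3] *= np.repeat(rng.lognormal(0, 0.8, size=10), 2)  # per-gene distortion
        m = make_matrix(vals, [f"s{i}" for i in range(8)],
                        [(g, i) for g in genes for i in (1, 2)])
        retained, excluded = qc_samples(m, max_outlier_genes=3)
        assert "s3" in excluded and len(excluded["s3"]) > 3
        assert "s3" not in retained

    def test_needs_four_samples(self):
        m = make_matrix(np.ones((3, 4)), list("abc"), [("G", i) for i in range(1, 5)])
        with pytest.raises(ValueError, match="at least 4"):
            qc_samples(m)


class TestExonCv:
    def test_constant_column_zero(self):
        m = make_matrix(np.full((4, 4), 7.0), list("abcd"), [("G", i) for i in range(1, 5)])
        assert (exon_cv(m) == 0).all()

    def test_two_pass_oracle(self):
        col = np.array([90.0, 100.0, 110.0])
        m = make_matrix(np.tile(col[:, None], (1, 4)), list("abc"),
                        [("G", i) for i in range(1, 5)])
        mean = col.sum() / 3
        sd = (sum((x - mean) ** 2 for x in col) / 2) ** 0.5
        assert exon_cv(m).iloc[0] == pytest.approx(sd / mean)

    def test_scaling_a_column_leaves_cv_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(10, 100, size=(5, 4))
        m1 = make_matrix(vals, list("abcde"), [("G", i) for i in range(1, 5)])
        vals2 = vals.copy()
        vals2[:, 2] *= 13.0
        m2 = make_matrix(vals2, list("abcde"), [("G", i) for i in range(1, 5)])
        assert np.allclose(exon_cv(m1), exon_cv(m2))

    def test_zero_mean_warns_and_sets_zero(self):
        vals = np.ones((4, 4))
        vals[:, 1] = 0.0
        m = make_matrix(vals, list("abcd"), [("G", i) for i in range(1, 5)])
        with pytest.warns(UserWarning, match="zero mean"):
            cv = exon_cv(m)
        assert cv.iloc[1] == 0.0


class TestTukeyScreen:
    def series(self, values):
        return pd.Series(values, index=[f"G:{i}" for i in range(1, len(values) + 1)])

    def test_single_extreme_flagged(self):
        flagged, fence = tukey_outlier_exons(self.series([0.10, 0.11, 0.12, 0.13, 0.50]))
        assert flagged == {"G:5"}
        q1, q3 = np.percentile([0.10, 0.11, 0.12, 0.13, 0.50], [25, 75])
        assert fence == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_all_equal_nothing_flagged(self):
        flagged, _ = tukey_outlier_exons(self.series([0.2] * 6))
        assert flagged == set()

    def test_matches_brute_force_quantile_oracle(self):
        """1000 random CV vectors: flag set equals a direct quantile oracle
        using the same declared interpolation (linear)."""
        rng = random.Random(5)
        for _ in range(1000):
            n = rng.randint(4, 40)
            vals = [rng.lognormvariate(0, 1) for _ in range(n)]
            flagged, _ = tukey_outlier_exons(self.series(vals))
            srt = sorted(vals)

            def quantile(q):  # linear interpolation between order statistics
                h = (n - 1) * q
                lo = int(h)
                hi = min(lo + 1, n - 1)
                return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

            q1, q3 = quantile(0.25), quantile(0.75)
            fence = q3 + 1.5 * (q3 - q1)
            oracle = {f"G:{i + 1}" for i, v in enumerate(vals) if v > fence}
            assert flagged == oracle


class TestFlagGenes:
    def cohort(self, n=8, genes=("A", "B", "C", "D", "E", "F"), exons=4, seed=0):
        rng = np.random.default_rng(seed)
        cols = [(g, i) for g in genes for i in range(1, exons + 1)]
        vals = rng.poisson(5000, size=(n, len(cols))).astype(float)
        return vals, cols

    def test_two_flagged_exons_with_fold_change_reported(self):
        vals, cols = self.cohort()
        idx = [i for i, (g, _e) in enumerate(cols) if g == "B"]
        vals[2, idx] *= 0.5  # whole-gene loss in sample s2
        m = make_matrix(vals, [f"s{i}" for i in range(8)], cols)
        cv = exon_cv(m)
        flagged, fence = tukey_outlier_exons(cv)
        flags = flag_cnv_genes(m, flagged, cvs=cv, fence=fence)
        assert [(f.gene, f.direction, f.implicated_samples) for f in flags] == [
            ("B", "loss", ["s2"])
        ]

    def test_single_exon_blip_not_gene_flagged(self):
        vals, cols = self.cohort()
        vals[1, 0] *= 3.0
        m = make_matrix(vals, [f"s{i}" for i in range(8)], cols)
        cv = exon_cv(m)
        flagged, fence = tukey_outlier_exons(cv)
        assert flag_cnv_genes(m, flagged, cvs=cv, fence=fence) == []

    def test_no_events_no_flags(self):
        vals, cols = self.cohort()
        m = make_matrix(vals, [f"s{i}" for i in range(8)], cols)
        cv = exon_cv(m)
        flagged, fence = tukey_outlier_exons(cv)
        assert flag_cnv_genes(m, flagged, cvs=cv, fence=fence) == []

    def test_few_exon_gene_warns(self):
        vals, cols = self.cohort(genes=("A", "B", "C", "D", "E"), exons=2)
        idx = [i for i, (g, _e) in enumerate(cols) if g == "B"]
        vals[2, idx] *= 0.5
        m = make_matrix(vals, [f"s{i}" for i in range(8)], cols)
        cv = exon_cv(m)
        flagged, fence = tukey_outlier_exons(cv)
        with pytest.warns(UserWarning, match="flanking"):
            flags = flag_cnv_genes(m, flagged, cvs=cv, fence=fence)
        assert [f.gene for f in flags] == ["B"]


class TestDuplicationSegment:
    def matrix_with_gain(self, first, last, fold=1.5, n_exons=14, seed=0):
        rng = np.random.default_rng(seed)
        cols = [("MLL", i) for i in range(1, n_exons + 1)]
        vals = rng.poisson(5000, size=(9, n_exons)).astype(float)
        for i in range(first - 1, last):
            vals[4, i] *= fold
        return make_matrix(vals, [f"s{i}" for i in range(9)], cols)

    def test_exons_2_to_9_recovered(self):
        m = self.matrix_with_gain(2, 9)
        seg = detect_duplication_segment(m, "MLL", "s4")
        assert seg is not None and seg[:2] == (2, 9)
        assert seg[2] == pytest.approx(1.5, rel=0.05)

    def test_flat_profile_none(self):
        m = self.matrix_with_gain(2, 9, fold=1.0)
        assert detect_duplication_segment(m, "MLL", "s4") is None

    def test_isolated_single_exon_none(self):
        m = self.matrix_with_gain(5, 5)
        assert detect_duplication_segment(m, "MLL", "s4") is None

    def test_needs_three_exons(self):
        m = make_matrix(np.ones((4, 2)), list("abcd"), [("G", 1), ("G", 2)])
        with pytest.raises(ValueError, match="fewer than 3"):
            detect_duplication_segment(m, "G", "a")


class TestSexLinkedRatio:
    def test_exact_double(self):
        cols = [("X1", i) for i in range(1, 5)]
        vals = np.vstack([np.full((3, 4), 100.0), np.full((2, 4), 50.0)])
        m = make_matrix(vals, ["f1", "f2", "f3", "m1", "m2"], cols)
        sexes = {"f1": "F", "f2": "F", "f3": "F", "m1": "M", "m2": "M"}
        assert sex_linked_ratio(m, sexes, "X1") == pytest.approx(2.0)

    def test_autosomal_poisson_near_one(self):
        rng = np.random.default_rng(3)
        cols = [("A1", i) for i in range(1, 11)]
        vals = rng.poisson(5000, size=(9, 10)).astype(float)
        m = make_matrix(vals, [f"s{i}" for i in range(9)], cols)
        sexes = {f"s{i}": ("F" if i < 5 else "M") for i in range(9)}
        assert sex_linked_ratio(m, sexes, "A1") == pytest.approx(1.0, abs=0.05)

    def test_x_gene_poisson_within_sampling_band(self):
        """Binomial/Poisson oracle: with per-exon depth ~5000 over 10 exons,
        the F:M ratio of means concentrates near 2 with relative sd well
        below 1%; 25 seeded draws must average within 3 SE of 2.0."""
        rng = np.random.default_rng(9)
        cols = [("X1", i) for i in range(1, 11)]
        ratios = []
        for _ in range(25):
            f = rng.poisson(5000, size=(5, 10)).astype(float)
            mvals = rng.poisson(2500, size=(4, 10)).astype(float)
            m = make_matrix(np.vstack([f, mvals]),
                            [f"f{i}" for i in range(5)] + [f"m{i}" for i in range(4)], cols)
            sexes = {s: s[0].upper() for s in m.samples}
            ratios.append(sex_linked_ratio(m, sexes, "X1"))
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 2.0) <= 3 * se

    def test_requires_both_sexes(self):
        m = make_matrix(np.ones((4, 2)), list("abcd"), [("G", 1), ("G", 2)])
        with pytest.raises(ValueError, match="each sex"):
            sex_linked_ratio(m, {s: "F" for s in "abcd"}, "G")


class TestAllelicImbalance:
    def test_informative_imbalanced_matches_fisher_oracle(self):
        from scipy import stats

        snp = SnpAllelicCounts("s", 700, 300, 500, 500)
        verdicts, _ = allelic_imbalance([snp])
        v = verdicts[0]
        _, p = stats.fisher_exact([[700, 300], [500, 500]])
        assert v.informative and v.imbalanced and v.direction == "B"
        assert v.p_value == pytest.approx(p)

    def test_homozygous_comparator_uninformative(self):
        verdicts, locus = allelic_imbalance([SnpAllelicCounts("s", 500, 500, 950, 50)])
        assert not verdicts[0].informative and locus == "no-evidence"

    def test_small_shift_not_imbalanced(self):
        # minor fraction drops 0.05 < delta even though counts are large
        verdicts, _ = allelic_imbalance([SnpAllelicCounts("s", 550, 450, 5000, 5000)])
        assert verdicts[0].informative and not verdicts[0].imbalanced

    def test_locus_verdicts(self):
        two = [
            SnpAllelicCounts("s1", 700, 300, 500, 500),
            SnpAllelicCounts("s2", 300, 700, 500, 500),
            SnpAllelicCounts("s3", 990, 10, 990, 10),
        ]
        _, locus = allelic_imbalance(two)
        assert locus == "deletion-consistent"
        one = two[:1] + [SnpAllelicCounts("s2", 990, 10, 992, 8)]
        _, locus = allelic_imbalance(one)
        assert locus == "suggestive"


class TestCoverageSummary:
    def targets(self, length=100):
        return [TargetRegion("c", 0, length, "G", 1, "exonic")]

    def test_uniform_coverage(self):
        depths = {("c", p): 100 for p in range(1, 101)}
        s = coverage_summary(depths, self.targets(), thresholds=[10, 100, 101])
        assert s["fractions"] == {10: 1.0, 100: 1.0, 101: 0.0}
        assert s["mean_depth"] == 100.0

    def test_half_uncovered(self):
        depths = {("c", p): 80 for p in range(1, 51)}
        s = coverage_summary(depths, self.targets(), thresholds=[1])
        assert s["fractions"][1] == 0.5

    def test_ragged_profile_matches_counting_oracle(self):
        rng = random.Random(2)
        depths = {("c", p): rng.randint(0, 50) for p in range(1, 101) if rng.random() < 0.8}
        thresholds = [1, 5, 25]
        s = coverage_summary(depths, self.targets(), thresholds=thresholds)
        for t in thresholds:
            n = sum(1 for p in range(1, 101) if depths.get(("c", p), 0) >= t)
            assert s["fractions"][t] == pytest.approx(n / 100)


def test_normalisation_scale_invariance_property():
    """Multiplying one sample's depths and total by a constant leaves its
    normalised row unchanged."""
    rng = np.random.default_rng(4)
    e = AmalgamatedExon("G", 1, "c", 0, 30)
    base = {("c", p): float(rng.integers(0, 200)) for p in range(1, 31)}
    m1 = normalize_counts({"s": base}, [e], {"s": 2e6})
    m2 = normalize_counts({"s": {k: 7 * v for k, v in base.items()}}, [e], {"s": 14e6})
    assert np.allclose(m1.values, m2.values)


def test_copy_number_proportionality():
    """Doubling a gene's copy number doubles expected normalised counts
    (checked within 3 standard errors over seeded Poisson draws)."""
    rng = np.random.default_rng(8)
    n_exons, depth, reps = 10, 5000, 30
    ratios = []
    for _ in range(reps):
        single = rng.poisson(depth, size=n_exons).mean()
        double = rng.poisson(2 * depth, size=n_exons).mean()
        ratios.append(double / single)
    se = np.std(ratios, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(ratios) - 2.0) <= 3 * se
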