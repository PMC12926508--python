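"""The hard-filter stack: exact binomial balance test, threshold boundaries,
order-independence, and artifact removal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

import malines as ml
from malines.filters import (FilterConfig, apply_site_filters,
                             binomial_balance_test)
from malines.variants import HET, HOM_REF, MISSING, SiteTable


def exact_two_sided_oracle(ref_reads: int, alt_reads: int) -> float:
    """Independent brute-force oracle: sum the probability of every outcome
    whose probability is no larger than the observed outcome's."""
    n = ref_reads + alt_reads
    probs = [binom.pmf(k, n, 0.5) for k in range(n + 1)]
    obs = binom.pmf(alt_reads, n, 0.5)
    return float(sum(p for p in probs if p <= obs * (1 + 1e-12)))


class TestBinomialBalance:
    def test_perfect_balance_gives_p_one(self):
        assert binomial_balance_test(10, 10) == pytest.approx(1.0)

    def test_total_imbalance_matches_closed_form(self):
        # all 40 reads on one allele: p = 2 * 0.5^40
        assert binomial_balance_test(40, 0) == pytest.approx(2 * 0.5 ** 40,
                                                             rel=1e-9)

    @pytest.mark.parametrize("ref,alt", [(30, 10), (40, 0), (25, 13), (1, 0),
                                         (7, 3), (60, 41), (50, 50), (2, 1)])
    def test_matches_brute_force_enumeration(self, ref, alt):
        assert binomial_balance_test(ref, alt) == pytest.approx(
            exact_two_sided_oracle(ref, alt), rel=1e-9)

    def test_thirty_ten_value(self):
        assert binomial_balance_test(30, 10) == pytest.approx(0.0022, abs=2e-4)

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError):
            binomial_balance_test(0, 0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 120), st.integers(0, 120))
    def test_agrees_with_scipy_binomtest(self, ref, alt):
        from scipy.stats import binomtest
        if ref + alt == 0:
            return
        expected = binomtest(alt, ref + alt, 0.5, alternative="two-sided").pvalue
        assert binomial_balance_test(ref, alt) == pytest.approx(expected,
                                                                rel=1e-9)


def _table(rows):
    """rows: (chrom, pos, ref, alts, gt, ad_ref, ad_alt, dp, fs, mq, rp)."""
    n = len(rows)
    n_lines = len(rows[0][4])
    return SiteTable(
        chrom=np.array([r[0] for r in rows], dtype=object),
        pos=np.array([r[1] for r in rows], dtype=np.int64),
        ref=np.array([r[2] for r in rows], dtype=object),
        alts=[tuple(r[3]) for r in rows],
        gt=np.array([r[4] for r in rows], dtype=np.int8),
        ad_ref=np.array([r[5] for r in rows], dtype=np.int32),
        ad_alt=np.array([r[6] for r in rows], dtype=np.int32),
        dp=np.array([r[7] for r in rows], dtype=np.int32),
        fs=np.array([r[8] for r in rows], dtype=float),
        mq_rank_sum=np.array([r[9] for r in rows], dtype=float),
        read_pos_rank_sum=np.array([r[10] for r in rows], dtype=float),
        samples=[f"L{i+1}" for i in range(n_lines)])


def _het_row(chrom, pos, dp=80, ad=(40, 40), fs=1.0, mq=0.0, rp=0.0,
             ref="A", alts=("G",)):
    return (chrom, pos, ref, alts, [HET, HOM_REF],
            [ad[0], dp], [ad[1], 0], [dp, dp], fs, mq, rp)


class TestThresholds:
    def test_fs_boundary_60_kept_61_removed(self):
        table = _table([_het_row("c1", 100, fs=60.0),
                        _het_row("c1", 200, fs=61.0)])
        out, report = apply_site_filters(table)
        assert out.n_sites == 1 and int(out.pos[0]) == 100
        assert report.removed_sites["fs"] == 1

    def test_rank_sum_thresholds_are_lower_bounds(self):
        table = _table([_het_row("c1", 100, mq=-12.5, rp=-8.0),
                        _het_row("c1", 200, mq=-12.6),
                        _het_row("c1", 300, rp=-8.1)])
        out, report = apply_site_filters(table)
        assert list(out.pos) == [100]
        assert report.removed_sites["mq_rank_sum"] == 1
        assert report.removed_sites["read_pos_rank_sum"] == 1

    def test_absent_annotations_pass(self):
        table = _table([_het_row("c1", 100, fs=np.nan, mq=np.nan, rp=np.nan)])
        out, _ = apply_site_filters(table)
        assert out.n_sites == 1
        assert (out.gt[0] != MISSING).all()

    def test_snp_within_20bp_of_indel_removed(self):
        indel = ("c1", 1000, "AT", ("A",), [HET, HOM_REF], [40, 80], [40, 0],
                 [80, 80], 1.0, 0.0, 0.0)
        table = _table([indel, _het_row("c1", 1015), _het_row("c1", 1025)])
        out, report = apply_site_filters(table)
        assert 1015 not in out.pos
        assert 1025 in out.pos
        assert report.removed_sites["near_indel"] == 1

    def test_multiallelic_site_dropped(self):
        table = _table([_het_row("c1", 100, alts=("G", "T"))])
        out, report = apply_site_filters(table)
        assert out.n_sites == 0
        assert report.removed_sites["multiallelic"] == 1

    def test_few_alt_reads_demoted(self):
        table = _table([_het_row("c1", 100, dp=54, ad=(50, 4))])
        out, _ = apply_site_filters(table)
        assert out.gt[0, 0] == MISSING       # failing het demoted
        assert out.gt[0, 1] == HOM_REF       # clean line untouched

    def test_depth_bounds_demote_genotypes(self):
        table = _table([_het_row("c1", 100, dp=19, ad=(10, 9)),
                        _het_row("c1", 200, dp=301, ad=(150, 151))])
        out, report = apply_site_filters(table)
        assert report.removed_genotypes["depth"] == 4  # both lines both sites
        assert (out.gt == MISSING).all()

    def test_unsorted_input_rejected(self):
        table = _table([_het_row("c1", 200), _het_row("c1", 100)])
        with pytest.raises(ValueError, match="sorted"):
            apply_site_filters(table)


class TestOrderIndependence:
    def test_surviving_set_is_conjunction_of_rules(self):
        rng = np.random.default_rng(11)
        rows = []
        for pos in range(100, 3100, 30):
            dp = int(rng.integers(10, 320))
            alt = int(rng.binomial(dp, rng.choice([0.5, 0.15])))
            ref = dp - alt
            is_indel = rng.random() < 0.1
            rows.append(("c1", pos, "AT" if is_indel else "A",
                         ("A",) if is_indel else ("G",),
                         [HET, HOM_REF], [ref, dp], [alt, 0], [dp, dp],
                         float(rng.exponential(20)),
                         float(rng.normal(0, 6)), float(rng.normal(0, 4))))
        table = _table(rows)
        cfg = FilterConfig()
        out, _ = apply_site_filters(table, config=cfg)
        surviving = {(c, int(p)) for c, p, g in
                     zip(out.chrom, out.pos, out.gt) if g[0] == HET}
        # oracle: independent conjunction of every rule, no ordering
        expected = set()
        indel_pos = [p for _, p, r, a, *_ in rows if len(r) != len(a[0])]
        for row in rows:
            c, p, r, alts, gt, adr, ada, dp, fs, mq, rp = row
            near = any(abs(p - q) <= 20 and p != q for q in indel_pos) or \
                (len(r) != len(alts[0]) and any(
                    abs(p - q) <= 20 and p != q for q in indel_pos))
            het_ok = (ada[0] >= 5 and
                      0.2 <= ada[0] / (adr[0] + ada[0]) <= 0.8 and
                      binomial_balance_test(adr[0], ada[0]) >= cfg.balance_alpha)
            if (not near and fs <= 60 and mq >= -12.5 and rp >= -8.0 and
                    20 <= dp[0] <= 300 and het_ok):
                expected.add((c, p))
        assert surviving == expected


class TestOnSimulatedData:
    def test_null_balance_removal_bounded_by_alpha(self, experiment):
        cfg = FilterConfig()
        _, report = apply_site_filters(experiment.sites, config=cfg)
        n_het = int((experiment.sites.gt == HET).sum())
        removed = report.removed_genotypes["het_balance"]
        alpha = cfg.balance_alpha
        bound = alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_het)
        assert removed / n_het <= bound

    def test_every_injected_artifact_class_removed(self, small_config):
        from dataclasses import replace
        cfg = replace(small_config, seed=7)
        artifacts = {cls: 5 for cls in ml.simulate.ARTIFACT_CLASSES}
        exp = ml.simulate_experiment(cfg, artifacts=artifacts)
        out, _ = apply_site_filters(exp.sites)
        surviving_het = {(c, int(p)) for c, p, g in
                         zip(out.chrom, out.pos, out.gt) if (g == HET).any()}
        for chrom, pos, cls in exp.artifact_truth:
            assert (chrom, pos) not in surviving_het, \
                f"artifact {cls} at {chrom}:{pos} survived"
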