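"""Count-matrix QC filters and exact binomial intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from finclock import qc


def _matrix(meth, total, fish_ids=None, site_ids=None):
    meth = np.atleast_2d(np.asarray(meth, dtype=np.int64))
    total = np.atleast_2d(np.asarray(total, dtype=np.int64))
    n_fish, n_sites = meth.shape
    fish_ids = fish_ids or [f"F{i}" for i in range(n_fish)]
    site_ids = site_ids or [f"s{j}" for j in range(n_sites)]
    sites = pd.DataFrame(
        {"site_id": site_ids, "chromosome": "chr1",
         "position": np.arange(1, n_sites + 1), "strand": "+"}
    )
    return qc.MethylationCountMatrix(fish_ids=fish_ids, sites=sites, meth=meth, total=total)


def _subs(site_ids, fractions, untreated=1000):
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "untreated_reads": untreated,
            "substituted_reads": [int(round(f * untreated)) for f in fractions],
        }
    )


def cp_oracle(x, n, conf=0.95):
    """Independent Clopper-Pearson oracle: invert the binomial tail tests
    numerically (no beta quantiles)."""
    alpha = 1 - conf
    if x == 0:
        low = 0.0
    else:
        low = optimize.brentq(lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    if x == n:
        high = 1.0
    else:
        high = optimize.brentq(lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    return low, high


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (0, 10, (0.0, 1 - 0.025 ** (1 / 10))),
            (10, 10, (0.025 ** (1 / 10), 1.0)),
            (8, 16, (0.2465101115, 0.7534898885)),
        ],
    )
    def test_reference_values(self, x, n, expected):
        low, high = qc.clopper_pearson_interval(x, n)
        assert low == pytest.approx(expected[0], abs=1e-9)
        assert high == pytest.approx(expected[1], abs=1e-9)

    def test_matches_tail_inversion_oracle_small_n(self):
        for n in (1, 2, 5, 16, 30):
            for x in range(n + 1):
                low, high = qc.clopper_pearson_interval(x, n)
                olow, ohigh = cp_oracle(x, n)
                assert low == pytest.approx(olow, abs=1e-9)
                assert high == pytest.approx(ohigh, abs=1e-9)

    def test_vectorized_matches_scalar(self):
        x = np.array([0, 3, 10])
        n = np.array([10, 10, 10])
        low, high = qc.clopper_pearson_interval(x, n)
        for i in range(3):
            s = qc.clopper_pearson_interval(int(x[i]), int(n[i]))
            assert low[i] == s[0] and high[i] == s[1]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            qc.clopper_pearson_interval(5, 4)
        with pytest.raises(ValueError):
            qc.clopper_pearson_interval(0, 0)


class TestSnpFilter:
    def test_threshold_is_strict(self):
        m = _matrix([[1, 1, 1]], [[2, 2, 2]])
        subs = _subs(["s0", "s1", "s2"], [0.06, 0.05, 0.01])
        out = qc.drop_ungenotyped_and_snp_sites(m, subs)
        assert out.site_ids == ["s1", "s2"]  # 0.05 exactly is retained

    def test_absent_site_treated_as_ungenotyped(self):
        m = _matrix([[1, 1]], [[2, 2]])
        subs = _subs(["s0"], [0.0])
        out = qc.drop_ungenotyped_and_snp_sites(m, subs)
        assert out.site_ids == ["s0"]

    def test_zero_untreated_reads_is_ungenotyped(self):
        m = _matrix([[1, 1]], [[2, 2]])
        subs = pd.DataFrame(
            {"site_id": ["s0", "s1"], "untreated_reads": [0, 100],
             "substituted_reads": [0, 0]}
        )
        assert qc.drop_ungenotyped_and_snp_sites(m, subs).site_ids == ["s1"]


class TestCoverageAndPresenceFilters:
    def test_individual_filter_is_strict_less_than(self):
        total = np.zeros((3, 50), dtype=np.int64)
        total[0, :50] = 10  # 50 observed sites
        total[1, :49] = 10  # 49 observed
        total[2, :50] = 10
        m = _matrix(np.zeros_like(total), total)
        out = qc.drop_low_coverage_individuals(m, min_sites=50)
        assert out.fish_ids == ["F0", "F2"]

    def test_all_fish_removed_raises(self):
        m = _matrix([[1]], [[5]])
        with pytest.raises(ValueError, match="threshold"):
            qc.drop_low_coverage_individuals(m, min_sites=10)

    def test_presence_boundary_at_80_percent(self):
        total = np.full((10, 3), 10, dtype=np.int64)
        total[:2, 0] = 0  # site 0 present in 80% exactly -> retained
        total[:3, 1] = 0  # site 1 present in 70% -> removed
        m = _matrix(np.zeros_like(total), total)
        out = qc.drop_low_presence_sites(m, min_frac=0.80)
        assert out.site_ids == ["s0", "s2"]


class TestCiWidthFilter:
    def test_depth16_retained_depth2_removed(self):
        total = np.full((10, 2), 16, dtype=np.int64)
        total[:, 1] = 2  # CP width at n=2 exceeds 0.85 for every x
        meth = (total // 2).astype(np.int64)
        m = _matrix(meth, total)
        out = qc.drop_wide_ci_sites(m)
        assert out.site_ids == ["s0"]

    def test_wide_in_exactly_20_percent_retained(self):
        total = np.full((10, 1), 16, dtype=np.int64)
        total[:2, 0] = 2  # wide in exactly 20% of fish; narrow in 80% -> kept
        m = _matrix((total // 2).astype(np.int64), total)
        assert qc.drop_wide_ci_sites(m).n_sites == 1


class TestPercentMethylation:
    def test_values_and_cis(self):
        m = _matrix([[8, 0, 0]], [[16, 20, 0]])
        pm = qc.percent_methylation(m)
        assert pm.p[0, 0] == 0.5
        assert pm.p[0, 1] == 0.0
        assert pm.ci_low[0, 1] == 0.0
        assert pm.ci_high[0, 1] == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-9)
        assert np.isnan(pm.p[0, 2])
        assert pm.provenance[0, 2] == qc.MISSING

    def test_global_summary_hand_values(self):
        m = _matrix([[7, 9], [7, 9]], [[10, 10], [10, 10]])
        mean, sd = qc.global_methylation_summary(qc.percent_methylation(m))
        assert mean == pytest.approx(0.8)
        assert sd == pytest.approx(np.std([0.7, 0.9], ddof=1))

    def test_constant_cells_zero_sd(self):
        m = _matrix([[8, 8], [8, 8]], [[10, 10], [10, 10]])
        mean, sd = qc.global_methylation_summary(qc.percent_methylation(m))
        assert (mean, sd) == (pytest.approx(0.8), 0.0)


class TestMatrixValidation:
    def test_meth_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="meth > total"):
            _matrix([[5]], [[4]])

    def test_duplicate_site_keys_rejected(self):
        sites = pd.DataFrame(
            {"site_id": ["a", "b"], "chromosome": "chr1", "position": [1, 1],
             "strand": "+"}
        )
        with pytest.raises(ValueError, match="duplicate site keys"):
            qc.MethylationCountMatrix(
                fish_ids=["F0"], sites=sites,
                meth=np.zeros((1, 2), dtype=np.int64),
                total=np.ones((1, 2), dtype=np.int64),
            )


class TestQcPipelineProperties:
    def test_filters_idempotent(self, qc_cohort):
        filtered, _, _, _, _, _ = qc_cohort
        again = qc.drop_low_presence_sites(
            qc.drop_wide_ci_sites(filtered), min_frac=0.80
        )
        assert again.n_sites == filtered.n_sites
        assert again.n_fish == filtered.n_fish

    def test_accounting_reconciles(self, qc_cohort):
        _, acct, _, _, _, _ = qc_cohort
        assert (
            acct["sites_in"]
            - acct["sites_removed_genotype_snp"]
            - acct["sites_removed_presence"]
            - acct["sites_removed_ci_width"]
            == acct["sites_out"]
        )
        assert acct["fish_in"] - acct["fish_removed_low_coverage"] == acct["fish_out"]
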