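"""Gonad zoning, category tables, and the two-tailed statistics with their
independent enumeration oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from territory3d import zoning
from territory3d.stats import (
    chi_square_two_tailed,
    fisher_exact_two_tailed,
    mann_whitney_two_tailed,
)


# ---------------------------------------------------------------------------
# independent oracles

def fisher_oracle(a, b, c, d):
    """Two-tailed Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def p_table(x):  # probability of table with top-left x, fixed margins
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = p_table(a)
    return sum(p_table(x) for x in range(lo, hi + 1)
               if p_table(x) <= p_obs + 1e-12)


def mann_whitney_oracle(xs, ys):
    """Exact two-tailed Mann-Whitney p by enumerating all group labelings."""
    pooled = list(xs) + list(ys)
    n1 = len(xs)

    def u_stat(group1_idx):
        g1 = [pooled[i] for i in group1_idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in group1_idx]
        u = 0.0
        for x in g1:
            for y in g2:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_stat(tuple(range(n1)))
    mu = n1 * (len(pooled) - n1) / 2.0
    dev_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mu) >= dev_obs - 1e-9:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------

class TestSplitMeioticZones:
    @pytest.mark.parametrize("n,expected", [
        (25, (5, 5, 5, 5, 5)),
        (27, (5, 5, 5, 5, 7)),   # round(27/5)=5, zone6 = 27-20
        (22, (4, 4, 4, 4, 6)),   # round(22/5)=4, zone6 = 22-16
    ])
    def test_printed_formula(self, n, expected):
        assert zoning.split_meiotic_zones(n) == expected

    def test_widths_sum_and_equal_zones(self):
        for n in range(5, 201):
            w = zoning.split_meiotic_zones(n)
            assert sum(w) == n
            assert len(set(w[:4])) == 1
            assert w[4] >= 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            zoning.split_meiotic_zones(4)


def gonad_table(clustered_rows, full_rows, n_rows=20, per_row=4):
    rows = []
    for r in range(1, n_rows + 1):
        for k in range(per_row):
            rows.append({
                "nucleus_id": f"n{r}-{k}",
                "row": r,
                "clustered": r in clustered_rows,
                "chrI_alignment": "full" if r in full_rows else "partial",
            })
    return pd.DataFrame(rows)


class TestAssignZones:
    def test_transition_zone_recovery(self):
        df = gonad_table(clustered_rows=set(range(11, 16)),
                         full_rows=set(range(16, 21)))
        out = zoning.assign_zones(df, zoning.ZoneScheme(premeiotic_rows=10))
        spans = out.attrs["zone_rows"]
        assert spans["premeiotic"] == (1, 10)
        assert spans["transition"] == (11, 15)
        assert (out[out["row"] <= 10]["zone"] == "premeiotic").all()

    def test_no_clustering_means_empty_tz(self):
        df = gonad_table(clustered_rows=set(), full_rows=set(range(1, 21)))
        out = zoning.assign_zones(df, zoning.ZoneScheme(premeiotic_rows=10))
        assert "transition" not in out.attrs["zone_rows"]

    def test_zone_labels_partition_all_nuclei(self):
        df = gonad_table(clustered_rows=set(range(11, 16)),
                         full_rows=set(range(16, 21)))
        out = zoning.assign_zones(df, zoning.ZoneScheme(premeiotic_rows=10))
        assert out["zone"].notna().all()

    def test_syp1_scheme(self):
        df = gonad_table(clustered_rows=set(range(6, 21)), full_rows=set(),
                         n_rows=20)
        out = zoning.assign_zones(
            df, zoning.ZoneScheme(kind="syp1_six_zone", premeiotic_rows=5))
        spans = out.attrs["zone_rows"]
        widths = [b - a + 1 for z, (a, b) in spans.items() if z != "premeiotic"]
        assert widths == [3, 3, 3, 3, 3]  # N=15, n=3

    def test_noncontiguous_rows_rejected(self):
        df = gonad_table(clustered_rows=set(), full_rows=set())
        df = df[df["row"] != 3]
        with pytest.raises(ValueError, match="contiguous"):
            zoning.assign_zones(df)


class TestJointAlignmentMatrix:
    def test_all_full(self):
        m = zoning.joint_alignment_matrix(["full"] * 3, ["full"] * 3)
        assert m.loc["full", "full"] == 3
        assert m.values.sum() == 3

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(0)
        states = list(zoning.ALIGNMENT_STATES)
        a = [states[i] for i in rng.integers(0, 3, 50)]
        b = [states[i] for i in rng.integers(0, 3, 50)]
        m = zoning.joint_alignment_matrix(a, b)
        for sa in states:
            for sb in states:
                assert m.loc[sa, sb] == sum(
                    1 for x, y in zip(a, b) if x == sa and y == sb)
        assert m.values.sum() == 50

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            zoning.joint_alignment_matrix(["full"], ["sideways"])


class TestStatistics:
    def test_fisher_printed_example(self):
        # [[3,0],[0,3]]: only 2 of the 20 equally weighted tables are as
        # extreme, p = 2/20 = 0.1
        assert fisher_exact_two_tailed([[3, 0], [0, 3]]) == pytest.approx(0.1)
        assert fisher_oracle(3, 0, 0, 3) == pytest.approx(0.1)

    def test_fisher_matches_oracle_on_sampled_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 8, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p = fisher_exact_two_tailed([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)

    def test_mann_whitney_identical_samples(self):
        assert mann_whitney_two_tailed([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mann_whitney_matches_exact_enumeration(self):
        rng = np.random.default_rng(2)
        for n1, n2 in [(3, 4), (4, 4), (5, 3)]:
            xs = rng.integers(0, 20, n1).tolist()  # distinct-ish, few ties
            ys = (rng.integers(0, 20, n2) + 0.5).tolist()
            p = mann_whitney_two_tailed(xs, ys)
            assert p == pytest.approx(mann_whitney_oracle(xs, ys), abs=1e-9)

    def test_chi_square_proportional_table(self):
        p = chi_square_two_tailed([[10, 20, 30], [1, 2, 3]])
        assert p == pytest.approx(1.0)

    def test_chi_square_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_two_tailed([[0, 0], [1, 2]])

    @given(st.integers(1, 10), st.integers(1, 10), st.integers(1, 10),
           st.integers(1, 10))
    @settings(max_examples=50, deadline=None)
    def test_fisher_p_in_unit_interval(self, a, b, c, d):
        p = fisher_exact_two_tailed([[a, b], [c, d]])
        assert 0.0 < p <= 1.0


class TestSummaries:
    def _tables(self):
        morpho = pd.DataFrame([
            # transition zone, chromosome I: counts {1,1,2,2}
            dict(nucleus_id="n1", chromosome="I", zone="transition",
                 segment_count=1, slenderness=7.0, highly_extended=True),
            dict(nucleus_id="n2", chromosome="I", zone="transition",
                 segment_count=1, slenderness=8.0, highly_extended=True),
            dict(nucleus_id="n3", chromosome="I", zone="transition",
                 segment_count=2, slenderness=6.5, highly_extended=True),
            dict(nucleus_id="n4", chromosome="I", zone="transition",
                 segment_count=2, slenderness=5.0, highly_extended=False),
        ])
        pairs = pd.DataFrame([
            dict(nucleus_id="n1", chromosome="I", zone="transition",
                 alignment_state="full"),
            dict(nucleus_id="n2", chromosome="I", zone="transition",
                 alignment_state="partial"),
            dict(nucleus_id="n3", chromosome="I", zone="transition",
                 alignment_state="unaligned"),
            dict(nucleus_id="n4", chromosome="I", zone="transition",
                 alignment_state="full"),
        ])
        return morpho, pairs

    def test_mean_and_sd_of_segment_counts(self):
        morpho, pairs = self._tables()
        out = zoning.summarize_zone_metrics(morpho, pairs)
        row = out["segment_counts"].iloc[0]
        assert row["mean"] == pytest.approx(1.5)
        assert row["sd"] == pytest.approx(np.std([1, 1, 2, 2], ddof=1))

    def test_tz_stratification_matches_filter_oracle(self):
        morpho, pairs = self._tables()
        out = zoning.summarize_zone_metrics(morpho, pairs)
        strata = out["tz_strata"].set_index("stratum")
        # oracle: n1, n4 are chromosome-I-full
        assert strata.loc["TZ-Full", "n"] == 2
        assert strata.loc["TZ-NF", "n"] == 2
        assert strata.loc["TZ-Full", "mean"] == pytest.approx(np.mean([1, 2]))

    def test_empty_stratum_absent_not_zero(self):
        morpho, pairs = self._tables()
        pairs["alignment_state"] = "full"  # nothing left for TZ-NF
        out = zoning.summarize_zone_metrics(morpho, pairs)
        assert "TZ-NF" not in set(out["tz_strata"]["stratum"])
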