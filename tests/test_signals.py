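"""Disproportionality statistics against independent oracles.

The ROR oracle recounts the 2×2 cells from raw report rows and applies the
odds-ratio formula directly; the Fisher oracle enumerates every table with
the observed margins and sums hypergeometric point probabilities; the BH
oracle applies the step-up definition literally.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_store, simple_universe
from pvsweet.signals import (ContingencyTable, build_table, fdr_adjust,
                             fisher_p, ror_ci, screen, screen_frames,
                             volcano_table)


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_table(demo_ids, exposures, case_ids):
    """Recount a/b/c/d by iterating over reports."""
    a = b = c = d = 0
    for pid in demo_ids:
        e, k = pid in exposures, pid in case_ids
        a += e and k
        b += e and not k
        c += k and not e
        d += not e and not k
    return a, b, c, d


def fisher_two_sided_by_enumeration(a, b, c, d):
    """Sum point probabilities ≤ the observed over all fixed-margin tables."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = stats.hypergeom.pmf(k, n, c1, r1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def bh_stepup(pvals):
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p in sorted order
        running = min(running, m * pvals[idx] / i)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------

class TestBuildTable:
    def test_hand_counted_fixture(self):
        store = simple_universe(n=100, drug_reports=10, event_reports=8,
                                overlap=4, drug="drugx")
        t = build_table(store, "drugx")
        assert (t.a, t.b, t.c, t.d) == (4, 6, 4, 86)

    def test_absent_drug(self):
        store = simple_universe()
        t = build_table(store, "no-such-drug")
        assert (t.a, t.b) == (0, 0) and t.c > 0

    def test_absent_event(self):
        store = simple_universe(event_reports=0, overlap=0)
        t = build_table(store, "drugx")
        assert (t.a, t.c) == (0, 0) and t.b == 10

    def test_report_counts_once_per_cell(self):
        store = simple_universe(n=20, drug_reports=5, event_reports=5,
                                overlap=5)
        # duplicate a drug row and a reaction row for report 0
        dup_drug = store.tables["drug"].iloc[[0]]
        dup_reac = store.tables["reac"].iloc[[0]]
        store.tables["drug"] = pd.concat([store.tables["drug"], dup_drug],
                                         ignore_index=True)
        store.tables["reac"] = pd.concat([store.tables["reac"], dup_reac],
                                         ignore_index=True)
        t = build_table(store, "drugx")
        assert t.n == 20 and t.a == 5


class TestRorCi:
    def test_point_estimate_hand_value(self):
        ror, _, _ = ror_ci(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0, rel=1e-12)

    def test_wald_ci_hand_value(self):
        _, lo, hi = ror_ci(ContingencyTable(10, 90, 100, 9900))
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(11.0 * math.exp(-1.959963985 * se), abs=0.01)
        assert hi == pytest.approx(11.0 * math.exp(+1.959963985 * se), abs=0.01)
        assert (lo, hi) == pytest.approx((5.56, 21.77), abs=0.01)

    def test_null_table_gives_one(self):
        ror, _, _ = ror_ci(ContingencyTable(10, 20, 30, 60))  # ad = bc
        assert ror == pytest.approx(1.0)

    def test_zero_cell_undefined_without_correction(self):
        assert all(np.isnan(ror_ci(ContingencyTable(0, 10, 10, 100))))

    def test_haldane_correction_defined(self):
        ror, lo, hi = ror_ci(ContingencyTable(0, 10, 10, 100), haldane=True)
        assert np.isfinite([ror, lo, hi]).all()

    def test_monotone_in_a(self):
        """Moving a report from (drug, no event) and (event, no drug) into the
        overlap cell never lowers the ROR."""
        prev = 0.0
        for a in range(1, 10):
            t = ContingencyTable(a, 20 - a, 30 - a, 50 + a)
            ror = ror_ci(t)[0]
            assert ror > prev
            prev = ror

    def test_random_fixtures_match_brute_force(self):
        """On 200 random small universes the pipeline table and ROR agree
        with a raw recount and the ad/bc formula to 1e-12 relative."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(20, 60))
            exposed = set(rng.choice(n, rng.integers(1, n // 2), replace=False))
            cases = set(rng.choice(n, rng.integers(1, n // 2), replace=False))
            demo = [{"primaryid": i, "caseid": i, "fda_dt": "20200101"}
                    for i in range(n)]
            drug = [{"primaryid": i, "caseid": i, "drug_seq": 1,
                     "role_cod": "PS",
                     "drugname": "drugx" if i in exposed else "other"}
                    for i in range(n)]
            reac = [{"primaryid": i, "caseid": i,
                     "pt": "Sweet syndrome" if i in cases else "Nausea"}
                    for i in range(n)]
            store = make_store(demo=demo, drug=drug, reac=reac)
            t = build_table(store, "drugx")
            a, b, c, d = brute_force_table(range(n), exposed, cases)
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
            if min(a, b, c, d) > 0:
                assert ror_ci(t)[0] == pytest.approx((a * d) / (b * c),
                                                     rel=1e-12)


class TestFisher:
    @pytest.mark.parametrize("cells", [
        (3, 1, 1, 3), (0, 5, 5, 0), (2, 8, 4, 26), (1, 1, 1, 37),
        (5, 0, 0, 5), (4, 6, 4, 26),
    ])
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        assert fisher_p(ContingencyTable(a, b, c, d)) == pytest.approx(
            fisher_two_sided_by_enumeration(a, b, c, d), rel=1e-9)

    def test_random_small_universes_match_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(4, 41))
            cells = rng.multinomial(n, [0.25] * 4)
            a, b, c, d = map(int, cells)
            assert fisher_p(ContingencyTable(a, b, c, d)) == pytest.approx(
                fisher_two_sided_by_enumeration(a, b, c, d), rel=1e-9)

    def test_proportional_table_p_is_one(self):
        assert fisher_p(ContingencyTable(4, 8, 2, 4)) == pytest.approx(1.0)


class TestFdr:
    def test_stepup_hand_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones_stay_one(self):
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_matches_literal_stepup_and_order_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        adj = fdr_adjust(p)
        assert adj == pytest.approx(bh_stepup(p), rel=1e-12)
        perm = rng.permutation(25)
        assert fdr_adjust(p[perm]) == pytest.approx(adj[perm], rel=1e-12)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()


class TestScreen:
    def test_small_n_not_flagged_despite_huge_ror(self):
        expo = pd.DataFrame({"primaryid": [1, 2, 3], "drug": "rare"})
        cases = {1, 2, 50, 51, 52}  # two exposed cases, three background
        out = screen_frames(expo, case_ids=cases, n_total=10_000)
        assert out["ror"].iloc[0] > 100
        assert not out["signal"].iloc[0]

    def test_strict_threshold_requires_more_than_three(self):
        expo = pd.DataFrame({"primaryid": range(4), "drug": "d"})
        cases = {0, 1, 2, 50, 51}  # exactly three exposed cases
        out_ge = screen_frames(expo, case_ids=cases, n_total=10_000,
                               min_cases=3)
        out_gt = screen_frames(expo, case_ids=cases, n_total=10_000,
                               min_cases=3, strict=True)
        assert bool(out_ge["signal"].iloc[0]) is True
        assert bool(out_gt["signal"].iloc[0]) is False

    def test_empty_drug_list_rejected(self):
        with pytest.raises(ValueError):
            screen(simple_universe(), drugs=[])

    def test_reporter_filter_same_schema(self, planted_store):
        full = screen(planted_store)
        md = screen(planted_store, reporter_filter="MD")
        assert list(md.columns) == list(full.columns)
        assert md["a"].sum() < full["a"].sum()

    def test_planted_signals_flagged_on_synthetic_corpus(self, planted_store):
        out = screen(planted_store)
        flagged = set(out.loc[out["signal"], "drug"])
        assert {"azathioprine", "azacitidine", "filgrastim"} <= flagged

    def test_volcano_table_axes(self, planted_store):
        out = screen(planted_store)
        v = volcano_table(out)
        row = v.set_index("drug").loc["azathioprine"]
        assert row["log2_ror"] == pytest.approx(
            np.log2(out.set_index("drug").loc["azathioprine", "ror"]))
        assert row["neg_log10_p_adj"] >= 0
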