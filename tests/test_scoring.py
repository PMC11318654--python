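"""Quality score, cumulative sums and Psi ensemble percentages."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aacascade import (
    ExperimentalDataset,
    ScoreTable,
    cumulative_scores,
    point_quality_score,
    psi_scores,
)


class TestPointScore:
    def test_maximum_at_exact_match(self):
        best = point_quality_score(1e-6, 1e-6, sigma=1.0)
        assert best == pytest.approx(-math.log(math.sqrt(2 * math.pi)))
        assert point_quality_score(1e-6, 2e-6) < best

    def test_four_logfold_error_passes_point_threshold(self):
        score = point_quality_score(math.e**4 * 1e-6, 1e-6, sigma=1.0)
        assert score == pytest.approx(-math.log(math.sqrt(2 * math.pi)) - 8.0)
        assert score == pytest.approx(-8.919, abs=1e-3)
        assert score > -10.0

    def test_threshold_semantics_of_close_points(self):
        assert -9.0 > -10.0  # counted as relatively close
        far = point_quality_score(math.e**4.6 * 1e-6, 1e-6)
        assert far < -10.0

    def test_matches_gaussian_logpdf_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            e, s = rng.lognormal(-14, 3, size=2)
            sigma = rng.uniform(0.3, 2.5)
            mine = point_quality_score(e, s, sigma=sigma)
            oracle = stats.norm.logpdf(math.log(e), loc=math.log(s), scale=sigma)
            assert mine == pytest.approx(oracle, rel=1e-12)

    def test_symmetry_and_monotone_decay(self):
        a = point_quality_score(1e-6, 1e-5)
        b = point_quality_score(1e-5, 1e-6)
        assert a == pytest.approx(b)
        closer = point_quality_score(1e-6, 2e-6)
        assert closer > a

    def test_unit_invariance(self):
        raw = point_quality_score(3e-6, 8e-7)
        scaled = point_quality_score(3e-6 * 450.0, 8e-7 * 450.0)
        assert scaled == pytest.approx(raw)

    def test_floor_and_validation(self):
        assert np.isfinite(point_quality_score(1e-6, 0.0))
        with pytest.raises(ValueError):
            point_quality_score(0.0, 1e-6)


def synthetic_table(n_variants=20, metabolites=("m1", "m2"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for v in range(n_variants):
        for m in metabolites:
            for t in (0.5, 1.0, 3.0, 6.0):
                rows.append((v, m, t, float(-rng.uniform(0, 30))))
    return ScoreTable(pd.DataFrame(
        rows, columns=["variant", "metabolite", "time_h", "score"]
    ))


class TestCumulative:
    def test_four_identical_points_sum(self):
        rows = [(0, "m", t, -5.0) for t in (0.5, 1, 3, 6)]
        tab = ScoreTable(pd.DataFrame(
            rows, columns=["variant", "metabolite", "time_h", "score"]
        ))
        assert tab.metabolite_totals()["cumulative"].iloc[0] == pytest.approx(-20.0)

    def test_perfect_variant_total(self):
        smax = -math.log(math.sqrt(2 * math.pi))
        rows = [(0, m, t, smax) for m in ("a", "b") for t in (0.5, 1, 3, 6)]
        tab = ScoreTable(pd.DataFrame(
            rows, columns=["variant", "metabolite", "time_h", "score"]
        ))
        assert tab.variant_totals()["total"].iloc[0] == pytest.approx(8 * smax)

    def test_against_brute_force_resummation(self):
        tab = synthetic_table(seed=3)
        wide = cumulative_scores(tab)
        for _, row in tab.points.iterrows():
            pass  # brute force below
        for v in tab.variants:
            sub = tab.points[tab.points["variant"] == v]
            total = sum(sub["score"])
            assert wide.loc[wide["variant"] == v, "total"].iloc[0] == \
                pytest.approx(total)
            for m in sub["metabolite"].unique():
                msum = sum(sub[sub["metabolite"] == m]["score"])
                assert wide.loc[wide["variant"] == v, m].iloc[0] == \
                    pytest.approx(msum)


class TestPsi:
    def test_hand_counted_percentages(self):
        # 3 variants, 1 metabolite, 2 time points with known pass pattern
        rows = [
            (0, "m", 0.5, -1.0), (0, "m", 1.0, -1.0),     # total -2 pass all
            (1, "m", 0.5, -15.0), (1, "m", 1.0, -30.0),   # fails point+metab
            (2, "m", 0.5, -9.0), (2, "m", 1.0, -50.0),    # mixed
        ]
        tab = ScoreTable(pd.DataFrame(
            rows, columns=["variant", "metabolite", "time_h", "score"]
        ))
        psi = psi_scores(tab)
        tp = psi.psi_timepoint.set_index("time_h")["psi"]
        assert tp[0.5] == pytest.approx(100 * 2 / 3)
        assert tp[1.0] == pytest.approx(100 * 1 / 3)
        # metabolite cumulative: -2, -45, -59 -> one of three above -40
        assert psi.psi_metabolite["psi"].iloc[0] == pytest.approx(100 / 3)
        assert psi.psi_total == pytest.approx(100.0)  # all totals above -500

    def test_known_total_fraction(self):
        rows = []
        for v in range(1000):
            total = -400.0 if v < 380 else -600.0
            rows.append((v, "m", 0.5, total))
        tab = ScoreTable(pd.DataFrame(
            rows, columns=["variant", "metabolite", "time_h", "score"]
        ))
        assert psi_scores(tab).psi_total == pytest.approx(38.0)

    def test_all_perfect_gives_100(self):
        smax = -math.log(math.sqrt(2 * math.pi))
        rows = [(v, "m", t, smax) for v in range(5) for t in (0.5, 1, 3, 6)]
        tab = ScoreTable(pd.DataFrame(
            rows, columns=["variant", "metabolite", "time_h", "score"]
        ))
        psi = psi_scores(tab)
        assert psi.psi_total == 100.0
        assert (psi.psi_timepoint["psi"] == 100.0).all()
        assert (psi.psi_metabolite["psi"] == 100.0).all()

    def test_internal_consistency_of_total(self):
        tab = synthetic_table(seed=9)
        psi = psi_scores(tab)
        totals = tab.points.groupby("variant")["score"].sum()
        expect = 100.0 * (totals > -500.0).mean()
        assert psi.psi_total == pytest.approx(expect)

    def test_adding_passing_variant_never_decreases_psi_total(self):
        tab = synthetic_table(n_variants=10, seed=4)
        before = psi_scores(tab).psi_total
        extra = [(999, m, t, -1.0) for m in ("m1", "m2") for t in (0.5, 1, 3, 6)]
        bigger = ScoreTable(pd.concat([
            tab.points,
            pd.DataFrame(extra, columns=["variant", "metabolite", "time_h", "score"]),
        ], ignore_index=True))
        assert psi_scores(bigger).psi_total >= before * 10 / 11 - 1e-9

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            psi_scores(ScoreTable(pd.DataFrame(
                columns=["variant", "metabolite", "time_h", "score"]
            )))


class TestDataset:
    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "metabolite": ["PGE2", "12-HETE"],
            "time_h": [0.5, 6.0],
            "conc_mM": [1e-6, 2e-8],
            "below_loq": [False, True],
        })
        ds = ExperimentalDataset(df, label="demo")
        path = ds.to_csv(tmp_path / "ds.csv")
        again = ExperimentalDataset.from_csv(path)
        pd.testing.assert_frame_equal(
            again.data, ds.data, check_dtype=False
        )

    def test_unit_conversion_requires_explicit_factor(self, tmp_path):
        path = tmp_path / "pg.csv"
        path.write_text(
            "metabolite,time_h,conc,unit\nPGE2,0.5,120.0,pg_per_1e6_cells\n"
        )
        with pytest.raises(ValueError, match="conversion_factor"):
            ExperimentalDataset.from_csv(path)
        path2 = tmp_path / "pg2.csv"
        path2.write_text(
            "metabolite,time_h,conc,unit,conversion_factor\n"
            "PGE2,0.5,120.0,pg_per_1e6_cells,1.0e-9\n"
        )
        ds = ExperimentalDataset.from_csv(path2)
        assert ds.data["conc_mM"].iloc[0] == pytest.approx(1.2e-7)

    def test_nonpositive_without_loq_flag_rejected(self):
        df = pd.DataFrame({
            "metabolite": ["PGE2"], "time_h": [0.5],
            "conc_mM": [0.0], "below_loq": [False],
        })
        with pytest.raises(ValueError, match="below-LOQ"):
            ExperimentalDataset(df)
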