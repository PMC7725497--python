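"""Stratified tables, percent arithmetic and Pearson correlation."""
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hatescan as hs


def _scored(i, score, ts="2020-03-05T10:00:00Z", country="Kuwait"):
    rec = hs.TweetRecord(id=f"s{i}", text="نص", created_at=ts,
                         user_id="u", location="x", country=country)
    cls = hs.classify_score(score)
    rec.score, rec.label, rec.level = cls.score, cls.label, cls.level
    return rec


# -- study periods -------------------------------------------------------


def test_default_periods_cover_study_window_without_gaps():
    p = hs.DEFAULT_PERIODS
    assert p.period_of(hs.TweetRecord(
        id="x", text="t", created_at="2020-01-27T00:00:01Z",
        user_id="u").created_at) == 0
    # March 31 falls in the second window (the windows as published leave it
    # unassigned; here every tweet belongs to exactly one period)
    assert p.period_of(hs.TweetRecord(
        id="x", text="t", created_at="2020-03-31T23:59:00Z",
        user_id="u").created_at) == 1
    assert p.period_of(hs.TweetRecord(
        id="x", text="t", created_at="2020-04-30T12:00:00Z",
        user_id="u").created_at) == 2


def test_timestamp_outside_all_windows_rejected():
    ts = hs.TweetRecord(id="x", text="t", created_at="2020-06-01T00:00:00Z",
                        user_id="u").created_at
    with pytest.raises(ValueError, match="outside"):
        hs.DEFAULT_PERIODS.period_of(ts)


# -- tabulate ------------------------------------------------------------


def test_tabulate_counts_percentages_and_mean_score():
    records = ([_scored(i, 0.55) for i in range(3)] +        # low
               [_scored(10 + i, 0.70) for i in range(2)] +   # average
               [_scored(20, 0.90)] +                         # high
               [_scored(30 + i, 0.10) for i in range(4)])    # non-hate
    table = hs.tabulate(records, "country")
    row = table.loc["Kuwait"]
    assert row.n_total == 10 and row.n_hate == 6 and row.n_nonhate == 4
    assert (row.n_low, row.n_average, row.n_high) == (3, 2, 1)
    assert row.pct_hate == pytest.approx(60.0)
    assert row.pct_low == pytest.approx(50.0)
    assert row.pct_low + row.pct_average + row.pct_high == pytest.approx(100.0)
    assert row.mean_hate_score == pytest.approx((0.55 * 3 + 0.70 * 2 + 0.90) / 6)
    assert 0.5 <= row.mean_hate_score <= 1.0


def test_tabulate_stratum_without_hate_reports_blank_levels():
    table = hs.tabulate([_scored(1, 0.2), _scored(2, 0.3)], "country")
    row = table.loc["Kuwait"]
    assert row.n_hate == 0
    assert math.isnan(row.pct_low) and math.isnan(row.mean_hate_score)


def test_tabulate_conserves_corpus_totals(noise_free_corpus, default_lexicon):
    records = hs.attach_countries(
        hs.remove_retweets_and_duplicates(noise_free_corpus.records),
        default_lexicon)
    rng = np.random.default_rng(1)
    for rec in records:
        cls = hs.classify_score(float(rng.random()))
        rec.score, rec.label, rec.level = cls.score, cls.label, cls.level
    by_country = hs.tabulate(records, "country")
    by_period = hs.tabulate(records, "period")
    for col in ("n_total", "n_hate", "n_nonhate", "n_low", "n_average", "n_high"):
        assert by_country[col].sum() == by_period[col].sum()
    assert by_country.n_total.sum() == len(records)
    n_hate_brute = sum(r.label == "hate" for r in records)
    assert by_country.n_hate.sum() == n_hate_brute
    assert (by_country.n_low + by_country.n_average + by_country.n_high
            == by_country.n_hate).all()


# -- percent arithmetic --------------------------------------------------


def test_percent_change_examples():
    assert hs.percent_change(118991, 253806) == 113.3
    assert hs.percent_change(6095, 2634) == -56.8
    assert hs.percent_change(7, 7) == 0.0
    with pytest.raises(ValueError):
        hs.percent_change(0, 5)


def test_share_of_total_examples():
    assert hs.share_of_total(6095, 11743) == 51.9
    assert hs.share_of_total(0, 10) == 0.0
    assert hs.share_of_total(153, 188) == 81.4
    with pytest.raises(ValueError):
        hs.share_of_total(1, 0)
    with pytest.raises(ValueError):
        hs.share_of_total(5, 4)


def test_rounding_is_half_up():
    assert hs.round_half_up(2.25, 1) == 2.3
    assert hs.round_half_up(-0.05, 1) == -0.1  # away from zero on .5


# -- pearson -------------------------------------------------------------


def test_pearson_perfect_linear_relation():
    x = [1.0, 2.0, 3.0, 4.0]
    r, p = hs.pearson(x, [2 * v + 1 for v in x])
    assert r == pytest.approx(1.0)
    assert p < 1e-6


def _brute_force_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def test_pearson_matches_hand_expanded_formula():
    x, y = [1, 2, 3, 4], [2, 1, 4, 3]
    r, _ = hs.pearson(x, y)
    assert abs(r - _brute_force_pearson(x, y)) < 1e-12


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(3, 100))
def test_pearson_matches_brute_force_on_random_vectors(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    r, p = hs.pearson(x, y)
    assert abs(r - _brute_force_pearson(x.tolist(), y.tolist())) < 1e-12
    assert -1.0 <= r <= 1.0 and 0.0 <= p <= 1.0


def test_pearson_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        hs.pearson([1, 2], [3, 4])
    with pytest.raises(ValueError):
        hs.pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        hs.pearson([1, 2, 3], [1, 2])


# -- build_report --------------------------------------------------------


def test_report_empty_corpus(tmp_path):
    summary = hs.build_report([], out_dir=tmp_path)
    assert summary["total_hate"] == 0
    assert "pearson_hate_vs_cases" not in summary
    assert (tmp_path / "summary.json").exists()


def test_report_byte_identical_across_reruns(tmp_path, noise_free_corpus,
                                             default_lexicon):
    records = hs.attach_countries(
        hs.remove_retweets_and_duplicates(noise_free_corpus.records),
        default_lexicon)
    rng = np.random.default_rng(2)
    for rec in records:
        cls = hs.classify_score(float(rng.random()))
        rec.score, rec.label, rec.level = cls.score, cls.label, cls.level
    hs.build_report(records, out_dir=tmp_path / "a")
    hs.build_report(records, out_dir=tmp_path / "b")
    for name in ("by_country.csv", "by_period.csv", "summary.json"):
        assert ((tmp_path / "a" / name).read_bytes()
                == (tmp_path / "b" / name).read_bytes())
    # every reported count re-derivable from the records by brute recount
    summary = json.loads((tmp_path / "a" / "summary.json").read_text())
    assert summary["total_hate"] == sum(r.label == "hate" for r in records)
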