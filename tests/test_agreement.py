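"""Paired testing, Lin's concordance and Bland-Altman agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import octametrics as om
from octametrics.agreement import (bland_altman, build_agreement_report,
                                   classify_agreement, concordance_correlation,
                                   paired_compare)


def sample(v1, v4, name="m"):
    return om.PairedSample(metric_name=name, v1=np.asarray(v1, float),
                           v4=np.asarray(v4, float))


# ---------------------------------------------------------------------------
# paired comparison


def test_paired_identical_arms_degenerate():
    r = paired_compare(sample([1, 2, 3, 4], [1, 2, 3, 4]))
    assert r.p_value == 1.0 and r.degenerate


def test_paired_shift_with_jitter_matches_hand_computed_t():
    v1 = np.array([1, 2, 3, 4, 5.0])
    jitter = np.array([0.1, -0.1, 0.2, -0.2, 0.0])
    v4 = v1 + 10 + jitter
    r = paired_compare(sample(v1, v4))
    d = v1 - v4
    t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
    p_oracle = 2 * stats.t.sf(abs(t), 4)
    assert r.test_name == "paired t"
    assert r.p_value == pytest.approx(p_oracle, rel=1e-9)
    assert r.p_value < 0.001


def test_paired_gates_to_wilcoxon_on_non_normal_differences():
    rng = np.random.default_rng(1)
    v4 = rng.normal(10, 1, 40)
    # heavy-tailed, strongly skewed differences
    v1 = v4 + np.exp(rng.normal(0, 1.2, 40))
    r = paired_compare(sample(v1, v4))
    assert r.shapiro_p < 0.05
    assert r.test_name == "Wilcoxon signed-rank"


# ---------------------------------------------------------------------------
# concordance correlation


def test_ccc_identity_line_is_perfect():
    r = concordance_correlation(sample([1, 2, 3, 5], [1, 2, 3, 5]))
    assert r.rho_c == pytest.approx(1.0)
    assert r.c_b == pytest.approx(1.0)
    assert r.category == "perfect"


def test_ccc_location_shift_closed_form():
    # v4 = v1 + c with c = biased SD of v1: rho = 1 and
    # rho_c = 2 s^2 / (2 s^2 + c^2) = 2/3
    v1 = np.array([1.0, 2.0, 3.0])
    c = np.sqrt(2.0 / 3.0)
    r = concordance_correlation(sample(v1, v1 + c))
    assert r.rho == pytest.approx(1.0)
    assert r.rho_c == pytest.approx(2.0 / 3.0)
    assert r.c_b == pytest.approx(2.0 / 3.0)


def test_ccc_matches_moment_formula_oracle():
    rng = np.random.default_rng(2)
    x = rng.normal(50, 5, 28)
    y = 0.8 * x + rng.normal(12, 3, 28)
    r = concordance_correlation(sample(x, y))
    # independent term-by-term evaluation with 1/n moments
    n = 28
    sx2 = ((x - x.mean()) ** 2).sum() / n
    sy2 = ((y - y.mean()) ** 2).sum() / n
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / n
    rho_c = 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    assert r.rho_c == pytest.approx(rho_c, abs=1e-12)
    # identity rho_c = rho * c_b
    assert r.rho_c == pytest.approx(r.rho * r.c_b, abs=1e-12)
    assert abs(r.rho_c) <= abs(r.rho)
    assert r.ci_low <= r.rho_c <= r.ci_high


def test_ccc_equals_pearson_iff_moments_match():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 50)
    noise = rng.normal(0, 0.5, 50)
    y = x + noise
    # force equal means and variances
    y = (y - y.mean()) / y.std() * x.std() + x.mean()
    r_eq = concordance_correlation(sample(x, y))
    assert r_eq.rho_c == pytest.approx(r_eq.rho, abs=1e-12)
    # unequal means: strict inequality
    r_ne = concordance_correlation(sample(x, y + 1.0))
    assert abs(r_ne.rho_c) < abs(r_ne.rho)


def test_ccc_decreases_monotonically_with_shift():
    rng = np.random.default_rng(4)
    x = rng.normal(10, 2, 30)
    vals = [concordance_correlation(sample(x, x + shift)).rho_c
            for shift in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_ccc_constant_arm_fails():
    with pytest.raises(ValueError, match="constant"):
        concordance_correlation(sample([1, 2, 3], [5, 5, 5]))


@pytest.mark.parametrize("value,category", [
    (0.308, "poor"),
    (0.899, "poor"),
    (0.90, "moderate"),
    (0.93, "moderate"),
    (0.95, "substantial"),
    (0.99, "substantial"),
    (0.995, "perfect"),
    (1.0, "perfect"),
])
def test_classify_agreement_cutpoints(value, category):
    assert classify_agreement(value) == category


# ---------------------------------------------------------------------------
# Bland-Altman


def test_ba_identical_arms():
    r = bland_altman(sample([1, 2, 3], [1, 2, 3]))
    assert r.bias == 0.0 and r.loa_low == r.loa_high == 0.0
    assert not r.bias_significant


def test_ba_constant_difference_degenerate():
    r = bland_altman(sample([10, 11, 12], [9, 10, 11]))
    assert r.bias == 1.0 and r.sd_diff == 0.0
    assert r.loa_low == r.loa_high == 1.0
    assert r.bias_significant


def test_ba_matches_moment_oracle():
    rng = np.random.default_rng(6)
    v1 = rng.normal(30, 3, 28)
    v4 = rng.normal(29, 3, 28)
    r = bland_altman(sample(v1, v4))
    d = v1 - v4
    assert r.bias == pytest.approx(d.mean())
    assert r.sd_diff == pytest.approx(d.std(ddof=1))
    assert r.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
    assert r.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
    half = stats.t.ppf(0.975, 27) * d.std(ddof=1) / np.sqrt(28)
    assert r.bias_ci_low == pytest.approx(d.mean() - half)
    assert r.loa_low <= r.bias <= r.loa_high


# ---------------------------------------------------------------------------
# report assembly


def _toy_metrics_frame(n=6, seed=0, v4_equals_v1=False):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        eye = f"eye{i:02d}"
        for plexus in ("SCP", "DCP", "CC"):
            base = {"SCP": (30, 10, 3), "DCP": (27, 11, 2.5),
                    "CC": (None, None, None)}[plexus]
            if plexus == "CC":
                v1_vals = {"fd_percent": 40 + rng.normal(0, 1)}
            else:
                v1_vals = {"pd_percent": base[0] + rng.normal(0, 1),
                           "vld_percent": base[1] + rng.normal(0, 0.3),
                           "vdi_pixels": base[2] + rng.normal(0, 0.1)}
            for mode in ("V1", "V4"):
                bump = 0.0 if (v4_equals_v1 or mode == "V1") else 1.0
                row = {"eye_id": eye, "plexus": plexus, "mode": mode,
                       "pd_percent": np.nan, "vld_percent": np.nan,
                       "vdi_pixels": np.nan, "fd_percent": np.nan}
                for key, val in v1_vals.items():
                    jitter = 0.0 if v4_equals_v1 or mode == "V1" else \
                        rng.normal(0, 0.2)
                    sign = -1.0 if key in ("fd_percent", "vld_percent") else 1.0
                    row[key] = val + sign * bump + jitter
                rows.append(row)
    return pd.DataFrame(rows)


def test_report_has_seven_rows_and_identities():
    rep = build_agreement_report(_toy_metrics_frame())
    assert len(rep.table) == 7
    for _, r in rep.table.iterrows():
        assert r["ccc"] == pytest.approx(r["pearson_rho"] * r["c_b"],
                                         abs=1e-12)
        assert r["ba_loa_low"] <= r["ba_bias"] <= r["ba_loa_high"]


def test_report_v4_equal_v1_perfect_agreement():
    rep = build_agreement_report(_toy_metrics_frame(v4_equals_v1=True))
    assert np.allclose(rep.table["ccc"], 1.0)
    assert (rep.table["ccc_category"] == "perfect").all()
    assert (rep.table["p_value"] == 1.0).all()


def test_report_pairs_by_eye_id_not_row_order():
    df = _toy_metrics_frame(seed=9)
    shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
    r1 = build_agreement_report(df)
    r2 = build_agreement_report(shuffled)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_report_excludes_eyes_missing_one_arm(caplog):
    df = _toy_metrics_frame()
    df = df[~((df.eye_id == "eye00") & (df["mode"] == "V4")
              & (df.plexus == "SCP"))]
    rep = build_agreement_report(df)
    assert rep.excluded_eyes.get("SCP PD") == 1
    scp_n = rep.table.loc[rep.table.metric == "SCP PD", "n"].iloc[0]
    cc_n = rep.table.loc[rep.table.metric == "CC FD", "n"].iloc[0]
    assert scp_n == cc_n - 1


def test_report_summary_mentions_each_metric():
    rep = build_agreement_report(_toy_metrics_frame())
    text = rep.summary()
    for name in ("SCP PD", "SCP VLD", "SCP VDI", "DCP PD", "DCP VLD",
                 "DCP VDI", "CC FD"):
        assert name in text
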