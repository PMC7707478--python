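"""Paired V1-vs-V4 agreement statistics.

For each vascular metric measured on the same eyes under two acquisition
modes (single volume V1 vs four-volume merge V4) the module reports:

* a paired comparison whose test is gated on normality of the per-eye
  differences (Shapiro-Wilk at alpha = 0.05: paired t-test when normal,
  Wilcoxon signed-rank otherwise);
* Lin's concordance correlation coefficient rho_c = rho * C_b, where rho is
  the Pearson correlation (precision) and C_b the bias-correction factor
  (accuracy: how far the best-fit line deviates from the identity line),
  with a 95% CI via the Fisher z-transform and Lin's variance, and a
  categorical reading (poor < 0.90, moderate 0.90-0.95, substantial
  0.95-0.99, perfect > 0.99);
* Bland-Altman agreement: bias (mean of the V1 - V4 differences), 95% limits
  of agreement bias -+ 1.96 * SD, and a bias-significance flag (zero outside
  the bias' 95% CI).

Differences are oriented V1 - V4 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .image import AcquisitionMode, Plexus

__all__ = [
    "PairedSample",
    "PairedTestResult",
    "CCCResult",
    "BAResult",
    "AgreementReport",
    "paired_compare",
    "concordance_correlation",
    "classify_agreement",
    "bland_altman",
    "build_agreement_report",
    "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

#: (plexus, csv column) pairs that make up the standard report rows.
METRIC_COLUMNS: list[tuple[str, str, str]] = [
    ("SCP", "pd_percent", "SCP PD"),
    ("SCP", "vld_percent", "SCP VLD"),
    ("SCP", "vdi_pixels", "SCP VDI"),
    ("DCP", "pd_percent", "DCP PD"),
    ("DCP", "vld_percent", "DCP VLD"),
    ("DCP", "vdi_pixels", "DCP VDI"),
    ("CC", "fd_percent", "CC FD"),
]


@dataclass
class PairedSample:
    """Per-eye paired measurements of one metric under V1 and V4."""

    metric_name: str
    v1: np.ndarray
    v4: np.ndarray

    def __post_init__(self) -> None:
        self.v1 = np.asarray(self.v1, dtype=float)
        self.v4 = np.asarray(self.v4, dtype=float)
        if self.v1.shape != self.v4.shape or self.v1.ndim != 1:
            raise ValueError("v1 and v4 must be 1-D arrays of equal length")
        if self.n < 3:
            raise ValueError("paired analysis needs n >= 3 eyes")
        if not (np.all(np.isfinite(self.v1)) and np.all(np.isfinite(self.v4))):
            raise ValueError("paired values must be finite")

    @property
    def n(self) -> int:
        return self.v1.size

    @property
    def differences(self) -> np.ndarray:
        """Per-eye differences, oriented V1 - V4."""
        return self.v1 - self.v4


@dataclass(frozen=True)
class PairedTestResult:
    p_value: float
    test_name: str
    shapiro_p: float | None = None
    degenerate: bool = False


def paired_compare(s: PairedSample) -> PairedTestResult:
    """Normality-gated paired comparison of the V1 - V4 differences."""
    d = s.differences
    if np.all(d == 0.0):
        return PairedTestResult(p_value=1.0, test_name="degenerate",
                                degenerate=True)
    if np.ptp(d) == 0.0:
        # constant nonzero difference: zero-variance t statistic diverges
        return PairedTestResult(p_value=0.0, test_name="paired t (degenerate)",
                                degenerate=True)
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= 0.05:
        p = float(stats.ttest_rel(s.v1, s.v4).pvalue)
        name = "paired t"
    else:
        p = float(stats.wilcoxon(s.v1, s.v4).pvalue)
        name = "Wilcoxon signed-rank"
    return PairedTestResult(p_value=p, test_name=name, shapiro_p=shapiro_p)


def classify_agreement(rho_c: float) -> str:
    """Categorical reading of a concordance coefficient.

    Below 0.90 poor; [0.90, 0.95) moderate; [0.95, 0.99] substantial;
    above 0.99 perfect.
    """
    if rho_c > 1.0 + 1e-12:
        raise ValueError("rho_c cannot exceed 1")
    if rho_c > 0.99:
        return "perfect"
    if rho_c >= 0.95:
        return "substantial"
    if rho_c >= 0.90:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class CCCResult:
    rho_c: float
    rho: float
    c_b: float
    ci_low: float
    ci_high: float
    category: str
    n: int


def concordance_correlation(s: PairedSample) -> CCCResult:
    """Lin's concordance correlation coefficient with 95% CI.

    Moment estimators use the biased (1/n) forms; the CI transforms rho_c
    with Fisher's z and uses Lin's asymptotic variance.
    """
    x, y, n = s.v1, s.v4, s.n
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("constant arm: Pearson correlation undefined")
    rho = sxy / np.sqrt(sx2 * sy2)
    rho_c = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    c_b = rho_c / rho if rho != 0.0 else float("nan")

    if abs(rho_c) >= 1.0 - 1e-12 or n <= 2 or rho == 0.0:
        lo = hi = rho_c
    else:
        u = (mx - my) / (sx2 * sy2) ** 0.25
        z = np.arctanh(rho_c)
        var_z = (1.0 / (n - 2)) * (
            (1.0 - rho**2) * rho_c**2 / ((1.0 - rho_c**2) * rho**2)
            + 4.0 * rho_c**3 * (1.0 - rho_c) * u**2
            / (rho * (1.0 - rho_c**2) ** 2)
            - 2.0 * rho_c**4 * u**4 / (rho**2 * (1.0 - rho_c**2) ** 2)
        )
        se = np.sqrt(max(var_z, 0.0))
        lo = float(np.tanh(z - 1.959963984540054 * se))
        hi = float(np.tanh(z + 1.959963984540054 * se))
    return CCCResult(rho_c=float(rho_c), rho=float(rho), c_b=float(c_b),
                     ci_low=lo, ci_high=hi,
                     category=classify_agreement(float(rho_c)), n=n)


@dataclass(frozen=True)
class BAResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_ci_low: float
    bias_ci_high: float
    bias_significant: bool
    n: int


def bland_altman(s: PairedSample) -> BAResult:
    """Bland-Altman bias, 95% limits of agreement and bias significance."""
    d = s.differences
    n = s.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    ci_low, ci_high = bias - half, bias + half
    significant = not (ci_low <= 0.0 <= ci_high)
    return BAResult(bias=bias, sd_diff=sd, loa_low=loa_low, loa_high=loa_high,
                    bias_ci_low=ci_low, bias_ci_high=ci_high,
                    bias_significant=significant, n=n)


@dataclass
class AgreementReport:
    """Per-metric agreement table plus Bland-Altman plot data.

    ``table`` has one row per metric with the arm means, the V1 - V4
    difference, the gated paired test, the CCC decomposition and the
    Bland-Altman quantities.  ``ba_data`` holds the per-eye (mean,
    difference) points behind each Bland-Altman panel.
    """

    table: pd.DataFrame
    ba_data: pd.DataFrame
    excluded_eyes: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Agreement of single-volume (V1) vs averaged (V4) acquisition",
                 "=" * 78]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['metric']:>8}: V1 {r['v1_mean']:6.2f}+-{r['v1_sd']:.2f}  "
                f"V4 {r['v4_mean']:6.2f}+-{r['v4_sd']:.2f}  "
                f"d {r['delta_mean']:+6.2f}+-{r['delta_sd']:.2f}  "
                f"p={r['p_value']:.4g} ({r['test_name']})  "
                f"CCC {r['ccc']:.3f} [{r['ccc_ci_low']:.3f},"
                f"{r['ccc_ci_high']:.3f}] {r['ccc_category']}  "
                f"BA bias {r['ba_bias']:+.2f} "
                f"LoA [{r['ba_loa_low']:.2f},{r['ba_loa_high']:.2f}]"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    def plot_bland_altman(self, path=None):
        """Render one Bland-Altman panel per metric (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        metrics = list(self.table["metric"])
        fig, axes = plt.subplots(1, len(metrics),
                                 figsize=(3.2 * len(metrics), 3.0),
                                 squeeze=False)
        for ax, metric in zip(axes[0], metrics):
            sub = self.ba_data[self.ba_data["metric"] == metric]
            row = self.table.set_index("metric").loc[metric]
            ax.scatter(sub["mean"], sub["difference"], s=12, alpha=0.7)
            for y, style in ((row["ba_bias"], "-"),
                             (row["ba_loa_low"], "--"),
                             (row["ba_loa_high"], "--")):
                ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
            ax.set_title(metric, fontsize=9)
            ax.set_xlabel("mean of V1, V4")
        axes[0][0].set_ylabel("V1 - V4")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig


def _paired_from_frame(df: pd.DataFrame, plexus: str, column: str,
                       name: str) -> tuple[PairedSample, list[str], int]:
    sub = df[df["plexus"] == plexus][["eye_id", "mode", column]].dropna()
    wide = sub.pivot_table(index="eye_id", columns="mode", values=column,
                           aggfunc="first")
    n_all = wide.shape[0]
    for mode in (AcquisitionMode.V1.value, AcquisitionMode.V4.value):
        if mode not in wide.columns:
            wide[mode] = np.nan
    complete = wide.dropna(subset=["V1", "V4"])
    n_dropped = n_all - complete.shape[0]
    sample = PairedSample(metric_name=name,
                          v1=complete["V1"].to_numpy(),
                          v4=complete["V4"].to_numpy())
    return sample, list(complete.index), n_dropped


def build_agreement_report(metrics: pd.DataFrame) -> AgreementReport:
    """Build the per-metric agreement table from a long-format metrics frame.

    Expected columns: ``eye_id``, ``plexus``, ``mode`` plus the metric
    columns ``pd_percent``, ``vld_percent``, ``vdi_pixels`` (SCP/DCP) and
    ``fd_percent`` (CC).  Pairing is by ``eye_id`` — row order is
    irrelevant; eyes missing one arm are excluded from that metric with a
    logged count.
    """
    required = {"eye_id", "plexus", "mode"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame must have columns {sorted(required)}")
    rows = []
    ba_rows = []
    excluded: dict[str, int] = {}
    for plexus, column, name in METRIC_COLUMNS:
        if column not in metrics.columns:
            continue
        if metrics.loc[metrics["plexus"] == plexus, column].dropna().empty:
            continue  # metric absent from this cohort
        sample, eye_ids, n_dropped = _paired_from_frame(metrics, plexus,
                                                        column, name)
        if n_dropped:
            excluded[name] = n_dropped
            logger.warning("%s: excluded %d eye(s) missing one arm",
                           name, n_dropped)
        test = paired_compare(sample)
        ccc = concordance_correlation(sample)
        ba = bland_altman(sample)
        d = sample.differences
        rows.append({
            "metric": name, "plexus": plexus, "n": sample.n,
            "v1_mean": sample.v1.mean(), "v1_sd": sample.v1.std(ddof=1),
            "v4_mean": sample.v4.mean(), "v4_sd": sample.v4.std(ddof=1),
            "delta_mean": d.mean(), "delta_sd": d.std(ddof=1),
            "p_value": test.p_value, "test_name": test.test_name,
            "ccc": ccc.rho_c, "pearson_rho": ccc.rho, "c_b": ccc.c_b,
            "ccc_ci_low": ccc.ci_low, "ccc_ci_high": ccc.ci_high,
            "ccc_category": ccc.category,
            "ba_bias": ba.bias, "ba_sd_diff": ba.sd_diff,
            "ba_loa_low": ba.loa_low, "ba_loa_high": ba.loa_high,
            "ba_bias_ci_low": ba.bias_ci_low, "ba_bias_ci_high": ba.bias_ci_high,
            "ba_bias_significant": ba.bias_significant,
        })
        means = (sample.v1 + sample.v4) / 2.0
        for eye, m, diff in zip(eye_ids, means, d):
            ba_rows.append({"metric": name, "eye_id": eye,
                            "mean": m, "difference": diff})
    if not rows:
        raise ValueError("no recognizable metric columns in the input frame")
    return AgreementReport(table=pd.DataFrame(rows),
                           ba_data=pd.DataFrame(ba_rows),
                           excluded_eyes=excluded)
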