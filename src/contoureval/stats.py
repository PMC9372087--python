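"""Paired-comparison statistics for manual vs auto contour evaluation.

Three tools, matching how segmentation-dosimetry studies report results:

* Bland–Altman agreement — bias (mean paired difference), 95% limits of
  agreement at bias ± 1.96·SD, and a two-sided one-sample t-test P for a
  zero mean difference, gated by a Shapiro–Wilk normality pre-check
  (α = 0.05): when the differences are clearly non-normal the parametric
  agreement P is reported as not applicable.
* Wilcoxon paired signed-rank test — exact null enumeration for small
  samples (≤ 25 nonzero, tie-free differences), otherwise the normal
  approximation with continuity correction; zero differences dropped,
  tied ranks averaged.
* Spearman rank correlation — Pearson correlation of mid-ranks, two-sided
  P from the t approximation. |r| ≥ 0.8 is labelled a strong correlation.

No multiple-testing correction is applied; results are reported per
structure, as is conventional for this kind of evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

STRONG_R = 0.8
ALPHA = 0.05
GEOMETRIC_METRICS = ("dsc", "hd95_mm", "jc")


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    n_outside: int
    p_bias: float
    shapiro_p: float
    applicable: bool  # False when the normality pre-check fails
    degenerate: bool = False

    @property
    def agreement(self) -> bool:
        return bool(self.applicable and self.p_bias > ALPHA)


@dataclass
class PairedTestResult:
    z_statistic: float
    p_value: float
    n_pairs: int
    n_nonzero: int
    no_difference: bool = False

    @property
    def significant(self) -> bool:
        return (not self.no_difference) and self.p_value < ALPHA


@dataclass
class CorrelationEntry:
    structure: str
    delta_metric: str
    geometric_metric: str
    r: float
    p_value: float
    n: int

    @property
    def strong(self) -> bool:
        return abs(self.r) >= STRONG_R


def _paired(manual, auto) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(manual, dtype=float)
    a = np.asarray(auto, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("manual and auto values must be 1D arrays of equal length")
    return m, a


def bland_altman(manual_values, auto_values) -> BlandAltmanResult:
    """Bland–Altman agreement of paired auto − manual differences."""
    m, a = _paired(manual_values, auto_values)
    n = len(m)
    if n < 3:
        raise ValueError(f"Bland–Altman needs at least 3 pairs, got {n}")
    d = a - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    n_outside = int(((d < loa_low) | (d > loa_high)).sum())

    if sd == 0.0:
        # all differences identical: zero-width limits, degenerate P
        p_bias = 1.0 if bias == 0.0 else np.nan
        return BlandAltmanResult(bias, sd, loa_low, loa_high, n, n_outside,
                                 p_bias=p_bias, shapiro_p=np.nan,
                                 applicable=bias == 0.0, degenerate=True)

    shapiro_p = float(sps.shapiro(d).pvalue)
    p_bias = float(sps.ttest_1samp(d, 0.0).pvalue)
    return BlandAltmanResult(bias, sd, loa_low, loa_high, n, n_outside,
                             p_bias=p_bias, shapiro_p=shapiro_p,
                             applicable=shapiro_p > ALPHA)


def wilcoxon_signed_rank(manual_values, auto_values) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test of auto vs manual."""
    m, a = _paired(manual_values, auto_values)
    d = a - m
    nz = d[d != 0.0]
    n_nonzero = len(nz)
    if n_nonzero == 0:
        return PairedTestResult(0.0, 1.0, len(d), 0, no_difference=True)
    if n_nonzero < 5:
        raise ValueError(
            f"Wilcoxon signed-rank needs >= 5 nonzero differences, got {n_nonzero}"
        )
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    mu = n_nonzero * (n_nonzero + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    sigma2 = n_nonzero * (n_nonzero + 1) * (2 * n_nonzero + 1) / 24.0
    sigma2 -= (tie_counts**3 - tie_counts).sum() / 48.0
    sigma = np.sqrt(sigma2)
    # signed z with continuity correction, as reported in comparison tables
    dev = w_plus - mu
    z = (dev - 0.5 * np.sign(dev)) / sigma if sigma > 0 else 0.0

    ties = len(np.unique(np.abs(nz))) < n_nonzero
    if n_nonzero <= 25 and not ties:
        p = float(sps.wilcoxon(nz, zero_method="wilcox", method="exact").pvalue)
    else:
        p = float(sps.wilcoxon(nz, zero_method="wilcox", correction=True,
                               method="approx").pvalue)
    return PairedTestResult(float(z), p, len(d), n_nonzero)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) and two-sided P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 4:
        raise ValueError(f"Spearman correlation needs at least 4 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def delta_dose(paired_dvi: pd.DataFrame) -> pd.DataFrame:
    """Per-case absolute dose differences |auto − manual| per structure metric.

    Expects a long table with columns case_id, structure, metric, provenance,
    value (the per-case output of the dosimetry evaluation). Cases missing
    either provenance for a (structure, metric) are excluded. The magnitude
    is used because a better contour overlap should mean a smaller
    difference regardless of its sign.
    """
    df = paired_dvi.dropna(subset=["metric", "value"])
    wide = df.pivot_table(index=["case_id", "structure", "metric"],
                          columns="provenance", values="value", aggfunc="first")
    wide = wide.dropna(subset=["manual", "auto"])
    out = wide.reset_index()
    out["delta"] = (out["auto"] - out["manual"]).abs()
    out["signed_delta"] = out["auto"] - out["manual"]
    return out[["case_id", "structure", "metric", "manual", "auto", "delta", "signed_delta"]]


def correlation_table(geom_table: pd.DataFrame, delta_table: pd.DataFrame,
                      metrics_of_record: dict[str, tuple[str, ...]],
                      min_cases: int = 4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman r between geometric metrics and per-case dose differences.

    For every structure and each of its dose metrics of record, correlates
    the per-case |Δ| against DSC, 95%HD and JC across cases. Returns the
    long table (one row per structure × Δmetric × geometric metric) and a
    heatmap matrix with rows ``structure ΔMetric`` and one column per
    geometric metric; cells with fewer than *min_cases* complete cases are NA.
    """
    entries = []
    for structure, metrics in metrics_of_record.items():
        g = geom_table[geom_table["structure"] == structure]
        for metric in metrics:
            d = delta_table[(delta_table["structure"] == structure)
                            & (delta_table["metric"] == metric)]
            merged = g.merge(d, on=["case_id", "structure"], how="inner")
            for gm in GEOMETRIC_METRICS:
                sub = merged[[gm, "delta"]].dropna()
                if len(sub) < min_cases:
                    entries.append(dict(structure=structure, delta_metric=f"d{metric}",
                                        geometric_metric=gm, r=np.nan, p_value=np.nan,
                                        n=len(sub), strong=False))
                    continue
                try:
                    r, p = spearman(sub[gm].to_numpy(), sub["delta"].to_numpy())
                except ValueError:
                    r, p = np.nan, np.nan
                entries.append(dict(structure=structure, delta_metric=f"d{metric}",
                                    geometric_metric=gm, r=r, p_value=p, n=len(sub),
                                    strong=bool(abs(r) >= STRONG_R) if np.isfinite(r) else False))
    table = pd.DataFrame(entries)
    heat = table.assign(row=table["structure"] + " " + table["delta_metric"]).pivot_table(
        index="row", columns="geometric_metric", values="r", aggfunc="first", dropna=False
    )
    return table, heat
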