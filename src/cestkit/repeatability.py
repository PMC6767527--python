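"""Test-retest repeatability and contrast statistics.

Bland-Altman analysis of paired ROI measurements (bias, 95% limits of
agreement, within-subject coefficient of variation), two-way
absolute-agreement single-measure ICC between readers, and Mann-Whitney U
contrast testing between ROI voxel populations.

Pairing conventions for the two-session / two-scan design: intrasession
pairs scan 1 with scan 2 inside each session; intersession pairs scan 1 of
session 1 with scan 1 of session 2, and likewise for scan 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "RepeatabilityReport",
    "bland_altman",
    "icc_absolute_agreement",
    "roi_contrast_test",
    "build_pairs",
    "repeatability_table",
    "bland_altman_plot",
]

LOA_MULTIPLIER = 1.96  # normal-theory 95% limits of agreement


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired measurements of one metric across ROI instances."""

    metric_label: str
    pairs: np.ndarray  # shape (n, 2)
    pairing: str = "intrasession"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"pairs must be (n, 2), got {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("need >= 2 pairs")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pairs contain non-finite values")
        object.__setattr__(self, "pairs", arr)


@dataclass(frozen=True)
class RepeatabilityReport:
    """Bland-Altman summary of one metric/pairing."""

    metric_label: str
    pairing: str
    bias: float
    loa_low: float
    loa_high: float
    loa_abs: float      # half-width, M0 units
    loa_pct: float      # half-width as % of grand mean (NaN if undefined)
    cv_pct: float       # within-subject CV, % (NaN if undefined)
    n_pairs: int
    pct_defined: bool


def bland_altman(data: PairedMeasurements, cv_convention: str = "within_subject") -> RepeatabilityReport:
    """Bland-Altman bias, 95% LOA, and coefficient of variation.

    bias = mean(m1 - m2); LOA = bias +/- 1.96 * SD(differences) with the
    n-1 sample standard deviation.  The default CV is the within-subject
    test-retest convention, (SD(differences)/sqrt(2)) / grand mean;
    ``cv_convention="per_pair"`` instead averages each pair's own
    SD/mean ratio.  Percentage fields are undefined (NaN, flagged) when the
    grand mean is zero.
    """
    m1, m2 = data.pairs[:, 0], data.pairs[:, 1]
    diff = m1 - m2
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa_abs = LOA_MULTIPLIER * sd
    grand_mean = float(np.mean(data.pairs))
    defined = grand_mean != 0.0
    if cv_convention == "within_subject":
        cv = (sd / np.sqrt(2.0)) / grand_mean * 100.0 if defined else np.nan
    elif cv_convention == "per_pair":
        means = data.pairs.mean(axis=1)
        if np.any(means == 0):
            defined = False
            cv = np.nan
        else:
            cv = float(np.mean(np.std(data.pairs, axis=1, ddof=1) / means) * 100.0)
    else:
        raise ValueError(f"unknown cv_convention {cv_convention!r}")
    return RepeatabilityReport(
        metric_label=data.metric_label,
        pairing=data.pairing,
        bias=bias,
        loa_low=bias - loa_abs,
        loa_high=bias + loa_abs,
        loa_abs=loa_abs,
        loa_pct=loa_abs / grand_mean * 100.0 if defined else np.nan,
        cv_pct=cv,
        n_pairs=int(data.pairs.shape[0]),
        pct_defined=defined,
    )


def icc_absolute_agreement(matrix) -> float:
    """Two-way random-effects, absolute-agreement, single-measure ICC (ICC(2,1)).

    ``matrix`` is (instances x readers).  Computed from the standard
    mean-squares decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN when the total variance is zero (undefined).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError(f"need >= 3 instances and >= 2 readers, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite values")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if sst == 0 or denom == 0:
        return float("nan")
    # the sample estimate can stray outside the population range on pure
    # noise; clamp so the reported coefficient stays interpretable
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


def roi_contrast_test(voxels_a, voxels_b) -> dict:
    """Mann-Whitney U contrast between two ROI voxel populations.

    Returns median difference (b - a), its percentage relative to
    median(a), and the two-sided tie-corrected p-value.
    """
    a = np.asarray(voxels_a, dtype=float)
    b = np.asarray(voxels_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 voxels per group")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    delta = med_b - med_a
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {
        "delta_median": delta,
        "delta_pct": delta / med_a * 100.0 if med_a != 0 else np.nan,
        "p_value": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def build_pairs(df: pd.DataFrame, metric: str, pairing: str, reader: str | int | None = None) -> PairedMeasurements:
    """Extract paired measurements from a long-format table.

    ``df`` columns: subject, session, scan, reader, roi, metric, value.
    Intrasession: (scan 1, scan 2) within each (subject, session, roi);
    intersession: (session 1, session 2) for each (subject, scan, roi).
    ROIs are pooled across tissue types (per-tissue breakdowns can be made
    by pre-filtering the table on ``roi``).
    """
    d = df[df["metric"] == metric]
    if reader is not None:
        d = d[d["reader"] == reader]
    piv = d.pivot_table(index=["subject", "roi"], columns=["session", "scan"],
                        values="value", aggfunc="first")
    pairs = []
    if pairing == "intrasession":
        for session in (1, 2):
            cols = [(session, 1), (session, 2)]
            if all(c in piv.columns for c in cols):
                sub = piv[cols].dropna()
                pairs.append(sub.to_numpy())
    elif pairing == "intersession":
        for scan in (1, 2):
            cols = [(1, scan), (2, scan)]
            if all(c in piv.columns for c in cols):
                sub = piv[cols].dropna()
                pairs.append(sub.to_numpy())
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    if not pairs:
        raise ValueError(f"no complete pairs for metric={metric!r}, pairing={pairing!r}")
    return PairedMeasurements(metric, np.vstack(pairs), pairing)


def repeatability_table(df: pd.DataFrame, metrics=("amide", "noe", "mt", "mtr_asym")) -> pd.DataFrame:
    """CV/LOA/bias summary per metric, pairing, and reader from a long table."""
    rows = []
    readers = sorted(df["reader"].unique())
    for metric in metrics:
        for pairing in ("intrasession", "intersession"):
            for reader in readers:
                rep = bland_altman(build_pairs(df, metric, pairing, reader))
                rows.append(
                    {"metric": metric, "pairing": pairing, "reader": reader,
                     "cv_pct": rep.cv_pct, "loa_abs": rep.loa_abs,
                     "loa_pct": rep.loa_pct, "bias": rep.bias, "n_pairs": rep.n_pairs}
                )
    return pd.DataFrame(rows)


def bland_altman_plot(data: PairedMeasurements, path) -> None:
    """Save a Bland-Altman scatter (mean vs difference) with bias and LOA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = bland_altman(data)
    means = data.pairs.mean(axis=1)
    diffs = data.pairs[:, 0] - data.pairs[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18)
    ax.axhline(rep.bias, color="k", lw=1, label=f"bias = {rep.bias:.3g}")
    for y in (rep.loa_low, rep.loa_high):
        ax.axhline(y, color="r", ls="--", lw=1)
    ax.set_xlabel("pair mean (fraction of M0)")
    ax.set_ylabel("difference m1 - m2")
    ax.set_title(f"{data.metric_label} ({data.pairing}); CV {rep.cv_pct:.3g}%")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
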