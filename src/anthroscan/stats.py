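"""Method-comparison statistics for digital vs. conventional anthropometry.

Given paired measurements of the same subjects by a digital pipeline (DA)
and a flexible tape (CA), this module computes, per site and device:

* the group means and their difference Δ = mean(DA) − mean(CA);
* a paired two-sided t test on the per-subject differences;
* ordinary least squares of DA on CA with R² and the regression standard
  error RMSE = sqrt(SSE / (n − 2));
* a Bland–Altman analysis: bias = mean(DA − CA), limits of agreement
  bias ± 1.96·SD, and the proportional-bias slope of (DA − CA) regressed
  on the pair means.

All formulas are spelled out here; scipy provides only the t distribution.
A paired RMSD sqrt(mean(d²)) is reported under its own name to avoid
ambiguity with the regression RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import RegressionError, SampleSizeError

#: significance tiers (two-sided p), strictest first
STAR_TIERS = ((1e-4, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_TIERS:
        if p < threshold:
            return stars
    return ""


@dataclass
class PairedSample:
    """Paired CA/DA readings for one site on one device."""

    ca: np.ndarray
    da: np.ndarray
    site: str = ""
    device: str = ""

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=np.float64)
        self.da = np.asarray(self.da, dtype=np.float64)
        if self.ca.shape != self.da.shape or self.ca.ndim != 1:
            raise ValueError("ca and da must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return len(self.ca)


def delta_means(ca_mean: float, da_mean: float) -> float:
    """Group-mean difference Δ = DA − CA (sign convention fixed)."""
    return float(da_mean) - float(ca_mean)


def paired_ttest(sample: PairedSample):
    """Two-sided paired t test on d = DA − CA.

    Returns ``(t, df, p, mean_diff, sd_diff)``.  Zero-variance conventions:
    identical pairs give t = 0, p = 1; a perfectly constant nonzero offset
    is a degenerate certainty, reported as t = ±inf, p = 0.
    """
    n = sample.n
    if n < 2:
        raise SampleSizeError(f"paired t test needs n >= 2, got {n}")
    d = sample.da - sample.ca
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0, mean, sd
        return float(np.sign(mean)) * np.inf, df, 0.0, mean, sd
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), df, p, mean, sd


def _ols(x: np.ndarray, y: np.ndarray):
    """Closed-form simple OLS: slope, intercept, r2, sse."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise RegressionError("zero predictor variance")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    sse = float((resid ** 2).sum())
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    return slope, intercept, r2, sse


def regression_eval(sample: PairedSample):
    """OLS of DA on CA: ``(slope, intercept, r2, rmse)``.

    RMSE is the regression standard error sqrt(SSE / (n − 2)).
    """
    n = sample.n
    if n < 3:
        raise SampleSizeError(f"regression needs n >= 3, got {n}")
    slope, intercept, r2, sse = _ols(sample.ca, sample.da)
    rmse = float(np.sqrt(sse / (n - 2)))
    return slope, intercept, r2, rmse


def bland_altman(sample: PairedSample):
    """Bias, limits of agreement, and proportional-bias slope.

    ``(bias, (lo, hi), ba_slope, ba_r2)`` with d = DA − CA regressed on the
    pair means m = (DA + CA) / 2; limits are bias ± 1.96 SD(d).
    """
    n = sample.n
    if n < 3:
        raise SampleSizeError(f"Bland-Altman needs n >= 3, got {n}")
    d = sample.da - sample.ca
    m = 0.5 * (sample.da + sample.ca)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    mm = m.mean()
    sxx = float(((m - mm) ** 2).sum())
    if sxx == 0.0 or sd == 0.0:
        # constant offset or degenerate means: no proportional trend
        slope, r2 = 0.0, 0.0
    else:
        slope, _, r2, _ = _ols(m, d)
    return bias, loa, float(slope), float(r2)


def rmsd(sample: PairedSample) -> float:
    """Paired root-mean-square difference sqrt(mean(d^2))."""
    d = sample.da - sample.ca
    return float(np.sqrt(np.mean(d ** 2)))


def compare_methods(samples) -> pd.DataFrame:
    """One comparison row per (site, device) sample.

    Columns follow the reporting layout of method-comparison tables: group
    means and SDs, Δ with significance stars, regression RMSE/R², and the
    Bland–Altman bias, limits and slope.
    """
    if not samples:
        raise SampleSizeError("need at least one paired sample")
    rows = []
    for s in samples:
        try:
            t, df, p, mean_d, sd_d = paired_ttest(s)
            slope, intercept, r2, rmse = regression_eval(s)
            bias, loa, ba_slope, ba_r2 = bland_altman(s)
        except Exception as exc:
            raise type(exc)(f"{s.site}/{s.device}: {exc}") from exc
        rows.append({
            "site": s.site,
            "device": s.device,
            "n": s.n,
            "ca_mean": float(s.ca.mean()),
            "ca_sd": float(s.ca.std(ddof=1)),
            "da_mean": float(s.da.mean()),
            "da_sd": float(s.da.std(ddof=1)),
            "delta_mean": delta_means(s.ca.mean(), s.da.mean()),
            "t": t,
            "df": df,
            "p": p,
            "stars": significance_stars(p),
            "slope": slope,
            "intercept": intercept,
            "r2": r2,
            "rmse": rmse,
            "rmsd": rmsd(s),
            "ba_bias": bias,
            "ba_lo": loa[0],
            "ba_hi": loa[1],
            "ba_slope": ba_slope,
            "ba_r2": ba_r2,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O and report shaping
# ---------------------------------------------------------------------------

def _norm_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [c.strip().lower().replace("-", "_") for c in df.columns]
    return df


def read_pairs_csv(path) -> list:
    """Read paired samples from a CSV with columns
    scan_id, device, site, ca_cm, da_cm (dashes accepted)."""
    df = _norm_columns(pd.read_csv(path))
    required = {"scan_id", "site", "ca_cm", "da_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "device" not in df.columns:
        df["device"] = "scanner"
    return samples_from_frame(df)


def samples_from_frame(df: pd.DataFrame) -> list:
    samples = []
    for (site, device), grp in df.groupby(["site", "device"], sort=True):
        samples.append(PairedSample(
            ca=grp["ca_cm"].to_numpy(), da=grp["da_cm"].to_numpy(),
            site=site, device=device))
    return samples


def means_table(report: pd.DataFrame) -> pd.DataFrame:
    """Group means ± SD and starred Δ per site/device."""
    out = report[["site", "device", "n"]].copy()
    out["ca"] = [f"{m:.1f} ± {s:.1f}"
                 for m, s in zip(report.ca_mean, report.ca_sd)]
    out["da"] = [f"{m:.1f} ± {s:.1f}"
                 for m, s in zip(report.da_mean, report.da_sd)]
    out["delta"] = [f"{d:.1f}{st}"
                    for d, st in zip(report.delta_mean, report.stars)]
    return out


def agreement_table(report: pd.DataFrame) -> pd.DataFrame:
    """RMSE / R² / Bland–Altman summary per site/device."""
    cols = ["site", "device", "n", "rmse", "r2", "ba_bias", "ba_lo",
            "ba_hi", "ba_slope", "ba_r2"]
    return report[cols].copy()


def bland_altman_plot(sample: PairedSample, path) -> None:
    """Scatter + Bland–Altman panel for one site/device (PNG/PDF)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slope, intercept, r2, _ = regression_eval(sample)
    bias, loa, ba_slope, _ = bland_altman(sample)
    d = sample.da - sample.ca
    m = 0.5 * (sample.da + sample.ca)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(sample.ca, sample.da, s=18, alpha=0.8)
    lims = [min(sample.ca.min(), sample.da.min()) - 2,
            max(sample.ca.max(), sample.da.max()) + 2]
    ax1.plot(lims, lims, "k--", lw=1, label="identity")
    xs = np.linspace(*lims, 50)
    ax1.plot(xs, slope * xs + intercept, "r-", lw=1,
             label=f"y = {slope:.2f}x + {intercept:.1f} (R²={r2:.2f})")
    ax1.set_xlabel("CA (cm)")
    ax1.set_ylabel("DA (cm)")
    ax1.legend(fontsize=8)

    ax2.scatter(m, d, s=18, alpha=0.8)
    for y, style in ((bias, "r-"), (loa[0], "k--"), (loa[1], "k--")):
        ax2.axhline(y, ls=style[1:], color=style[0], lw=1)
    ax2.set_xlabel("pair mean (cm)")
    ax2.set_ylabel("DA − CA (cm)")
    title = f"{sample.site} / {sample.device}"
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
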