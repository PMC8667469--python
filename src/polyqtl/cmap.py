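"""Continuous QTL mapping: regression of trait means on allele frequencies.

At low sequencing depth, integer dosage calls in polyploids are unreliable;
continuous mapping sidesteps calling by regressing the adjusted logit-scale
trait mean of each individual directly on its per-marker reference-allele
frequency estimate (the "continuous genotype").  Under additivity the
regression slope estimates the allele-substitution effect, attenuated by the
binomial measurement error of the frequency.  For triploid families the
attenuation (underestimation) factor is

    1 / (1 + 2 / S_T)

where S_T is the sequencing depth; with variable depth, the harmonic mean of
the per-sample depths stands in for S_T, because the error variance of a
frequency estimate scales with 1/depth.  The corrected effect divides the raw
slope by this factor.

Effects are reported per reference-allele copy: one copy in a triploid is a
frequency change of 1/3, so the per-copy effect is slope/3 (the raw
per-unit-frequency slope is available via ``effect_scale="per_unit_frequency"``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import harmonic_mean_depth

__all__ = [
    "regress_marker",
    "bias_factor",
    "correct_effect",
    "genome_scan",
    "manhattan_table",
]

_LN10 = np.log(10.0)


def regress_marker(means, freqs) -> dict:
    """OLS of trait means on allele frequencies at one marker.

    Pairs with a missing mean or frequency are dropped; requires >= 3
    complete pairs.  Returns slope, se, t, p (two-sided, n-2 df), r2 and n;
    a zero-variance frequency vector yields NaN statistics with
    ``monomorphic_in_sample=True``.
    """
    y = np.asarray(means, dtype=float)
    x = np.asarray(freqs, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need >=3 genotypes with mean and frequency")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        return {"slope": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
                "r2": np.nan, "n": n, "monomorphic_in_sample": True}
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    slope = sxy / sxx
    rss = max(syy - sxy ** 2 / sxx, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    if se > 0:
        t = slope / se
    else:
        t = np.sign(slope) * np.inf if slope != 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    r2 = (sxy ** 2 / (sxx * syy)) if syy > 0 else np.nan
    return {"slope": float(slope), "se": float(se), "t": float(t),
            "p": float(p), "r2": float(r2), "n": int(n),
            "monomorphic_in_sample": False}


def bias_factor(s_t: float) -> float:
    """Attenuation of the allele effect at harmonic-mean depth ``s_t``:
    1/(1 + 2/S_T), in (0,1), increasing in depth."""
    if s_t <= 0:
        raise ValueError("S_T must be positive")
    return 1.0 / (1.0 + 2.0 / s_t)


def correct_effect(beta_raw: float, s_t: float) -> float:
    """Measurement-error-corrected effect: beta_raw / bias_factor(S_T)."""
    return beta_raw / bias_factor(s_t)


def genome_scan(means: pd.Series, freqs: pd.DataFrame,
                depths: pd.DataFrame | None = None,
                sites: pd.DataFrame | None = None,
                alpha: float = 0.001, ploidy: int = 3,
                effect_scale: str = "per_allele_copy",
                global_s_t: float | None = None) -> pd.DataFrame:
    """Marker-by-marker regression scan of trait means on allele frequencies.

    Parameters
    ----------
    means
        Adjusted logit-scale trait means indexed by genotype id.
    freqs, depths
        Genotype x marker frequency and depth matrices (same columns);
        depths drive the per-marker harmonic-mean S_T used by the bias
        correction (pass ``global_s_t`` to use one genome-wide value instead).
    sites
        Optional per-marker ``chrom``/``pos`` metadata indexed like the
        columns of ``freqs``; output rows follow this physical order.

    Individuals missing a frequency at a marker are dropped for that marker
    only (pairwise deletion).
    """
    if effect_scale not in ("per_allele_copy", "per_unit_frequency"):
        raise ValueError("unknown effect_scale")
    common = means.index.intersection(freqs.index)
    if len(common) == 0:
        raise ValueError("no genotypes shared between means and frequencies")
    y = means.loc[common].to_numpy(dtype=float)
    F = freqs.loc[common].to_numpy(dtype=float)
    mask = np.isfinite(F) & np.isfinite(y)[:, None]
    n = mask.sum(axis=0).astype(float)

    Fm = np.where(mask, F, 0.0)
    ym = np.where(mask, y[:, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = Fm.sum(0), ym.sum(0)
        sxx = (Fm ** 2).sum(0) - sx ** 2 / n
        syy = (ym ** 2).sum(0) - sy ** 2 / n
        sxy = (Fm * ym).sum(0) - sx * sy / n
        slope = sxy / sxx
        rss = np.maximum(syy - sxy ** 2 / sxx, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        tstat = slope / se
        r2 = sxy ** 2 / (sxx * syy)
        logp = np.log(2.0) + stats.t.logsf(np.abs(tstat), n - 2)
        p = np.exp(logp)
        mlog10p = -logp / _LN10
    valid = (n >= 3) & (sxx > 1e-12)
    for arr in (slope, se, tstat, r2, p, mlog10p):
        arr[~valid] = np.nan

    if global_s_t is not None:
        s_t = np.full(F.shape[1], float(global_s_t))
    elif depths is not None:
        D = depths.loc[common].to_numpy(dtype=float)
        pos_mask = mask & (D > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(pos_mask, 1.0 / np.where(pos_mask, D, 1.0), 0.0)
            s_t = pos_mask.sum(0) / inv.sum(0)
        s_t[pos_mask.sum(0) == 0] = np.nan
    else:
        raise ValueError("provide a depth matrix or global_s_t")

    scale = (1.0 / ploidy) if effect_scale == "per_allele_copy" else 1.0
    beta_raw = slope * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_corr = beta_raw * (1.0 + 2.0 / s_t)
    out = pd.DataFrame({
        "snp_id": freqs.columns,
        "n": n.astype(int),
        "beta_raw": beta_raw,
        "beta_corrected": beta_corr,
        "se": se * scale,
        "minus_log10_p": mlog10p,
        "p": p,
        "explained_variance_percent": 100.0 * r2,
        "S_T": s_t,
        "monomorphic_in_sample": ~valid & (n >= 3),
    })
    if sites is not None:
        out.insert(1, "chrom", sites["chrom"].to_numpy())
        out.insert(2, "pos", sites["pos"].to_numpy())
        out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    out["significant"] = out["p"] < alpha
    out.attrs["alpha"] = alpha
    out.attrs["threshold_minus_log10_p"] = -np.log10(alpha)
    return out


def manhattan_table(records: pd.DataFrame, alpha: float | None = None,
                    figure_path: str | Path | None = None) -> pd.DataFrame:
    """Plot-ready (chrom, pos, -log10 p) table sorted by position; optionally
    renders a Manhattan plot with the significance threshold line."""
    if records.empty:
        import warnings

        warnings.warn("empty scan: no Manhattan table to build")
        return records
    alpha = alpha if alpha is not None else records.attrs.get("alpha", 0.001)
    tab = (records[["chrom", "pos", "minus_log10_p"]]
           .sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True))
    tab.attrs["threshold_minus_log10_p"] = -np.log10(alpha)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        offset = 0.0
        ticks = []
        for i, (chrom, grp) in enumerate(tab.groupby("chrom", sort=True)):
            x = grp["pos"].to_numpy() + offset
            ax.scatter(x, grp["minus_log10_p"], s=4,
                       color="C0" if i % 2 == 0 else "C1")
            ticks.append((offset + x[-1]) / 2 if len(x) else offset)
            offset = x[-1] if len(x) else offset
        ax.axhline(-np.log10(alpha), color="blue", lw=1)
        ax.set_xticks(ticks)
        ax.set_xticklabels(sorted(tab["chrom"].unique()), rotation=90, fontsize=6)
        ax.set_ylabel(r"$-\log_{10}(p)$")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return tab
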