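"""Logit-scale phenotype analysis: adjusted genotype means, variance
components, broad-sense heritability, and LSD comparisons.

Percentage traits (peripheral corm damage PD, total cross-section damage TXD)
are analysed on the logit scale.  Following the two-run "preliminary single
environment analysis" scheme, the mixed model

    logit(y) = mu + batch (fixed) + genotype_extra (fixed)
               + genotype_test (random) + block(batch) (random) + error

is fitted twice by REML:

1. with the test genotypes random, to estimate the variance components
   (sigma2_genotype, sigma2_block_within_batch, sigma2_residual) and the
   entry-mean broad-sense heritability
   H2 = sigma2_g / (sigma2_g + sigma2_e / r_h), r_h being the harmonic mean
   number of plots per test genotype;
2. with both genotype factors fixed, to produce unshrunken generalized-
   least-squares adjusted means under the first-run variance structure.

The unit of analysis is the plot mean over its plants, logit-transformed
after clamping proportions to [delta, 1-delta] with
delta = 1/(4 * n_plants * 100) so that 0% and 100% plots remain usable.

REML maximizes the profiled restricted log-likelihood over the two
variance ratios (genotype and block, both relative to the residual) on the
log scale with bounded derivative-free optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import expit as _expit
from scipy.special import logit as _logit

__all__ = [
    "logit",
    "inverse_logit",
    "compute_txd",
    "plot_means",
    "VarianceComponents",
    "fit_variance_components",
    "AdjustedMeansTable",
    "adjusted_means",
    "lsd_compare",
]


def logit(p):
    """ln(p / (1-p)) for proportions p in [0, 1]; NaN input is an error."""
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("logit of NaN")
    out = _logit(arr)
    return float(out) if out.ndim == 0 else out


def inverse_logit(x):
    """exp(x) / (1 + exp(x)), the proportion corresponding to a logit value."""
    out = _expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def compute_txd(upper_outer, upper_inner, lower_outer, lower_inner):
    """Total cross-section damage: the mean of the four cross-section
    readings (percent); any missing reading propagates to NaN."""
    readings = np.stack([np.asarray(v, dtype=float) for v in
                         (upper_outer, upper_inner, lower_outer, lower_inner)])
    if np.nanmin(readings) < 0 or np.nanmax(readings) > 100:
        raise ValueError("cross-section readings must be in [0, 100]")
    out = readings.mean(axis=0)
    return float(out) if out.ndim == 0 else out


def plot_means(obs: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Collapse plant-level percentages to clamped logit plot means.

    Returns one row per (genotype_id, batch, block) with columns
    ``genotype_id, genotype_role, batch, block, n_plants, y`` where ``y``
    is the logit of the plot-mean proportion.
    """
    df = obs[obs["trait"] == trait]
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    grouped = (df.groupby(["genotype_id", "genotype_role", "batch", "block"],
                          sort=True)["value_percent"]
               .agg(["mean", "size"]).reset_index())
    n_plants = int(grouped["size"].max())
    delta = 1.0 / (4 * n_plants * 100)
    p = np.clip(grouped["mean"].to_numpy() / 100.0, delta, 1.0 - delta)
    out = grouped.rename(columns={"size": "n_plants"}).drop(columns=["mean"])
    out["y"] = logit(p)
    return out


# ---------------------------------------------------------------------------
# model matrices

def _dummies(codes: np.ndarray, n_levels: int, drop_first: bool) -> np.ndarray:
    eye = np.eye(n_levels)
    d = eye[codes]
    return d[:, 1:] if drop_first else d


def _design(plot_df: pd.DataFrame, test_random: bool):
    """Fixed and random design matrices for the plot-mean model."""
    y = plot_df["y"].to_numpy(dtype=float)
    batch, batches = pd.factorize(plot_df["batch"], sort=True)
    rep_labels = (plot_df["batch"].astype(str) + ":" + plot_df["block"].astype(str))
    rep, _ = pd.factorize(rep_labels, sort=True)
    is_test = (plot_df["genotype_role"] == "test").to_numpy()
    test_ids = np.sort(plot_df.loc[is_test, "genotype_id"].unique())
    extra_ids = np.sort(plot_df.loc[~is_test, "genotype_id"].unique())

    X_parts = [np.ones((len(plot_df), 1)),
               _dummies(batch, len(batches), drop_first=True)]
    if test_random:
        # run 1: extras fixed (one column each; test plots are the baseline),
        # test genotypes random
        idx = {g: i for i, g in enumerate(extra_ids)}
        extra_d = np.zeros((len(plot_df), len(extra_ids)))
        for r, (gid, t) in enumerate(zip(plot_df["genotype_id"], is_test)):
            if not t:
                extra_d[r, idx[gid]] = 1.0
        X_parts.append(extra_d)
        gcodes = pd.Categorical(plot_df["genotype_id"],
                                categories=test_ids).codes
        Zg = np.zeros((len(plot_df), len(test_ids)))
        rows = np.flatnonzero(gcodes >= 0)
        Zg[rows, gcodes[rows]] = 1.0
    else:
        # run 2: every genotype fixed (drop-first coding)
        all_ids = np.concatenate([test_ids, extra_ids])
        all_ids = np.sort(all_ids)
        gcodes = pd.Categorical(plot_df["genotype_id"], categories=all_ids).codes
        X_parts.append(_dummies(gcodes, len(all_ids), drop_first=True))
        Zg = None
    X = np.concatenate(X_parts, axis=1)
    Zr = np.eye(rep.max() + 1)[rep]
    meta = {"batches": list(batches), "test_ids": list(test_ids),
            "extra_ids": list(extra_ids), "is_test": is_test}
    return y, X, Zg, Zr, meta


@dataclass
class VarianceComponents:
    sigma2_genotype: float
    sigma2_rep: float
    sigma2_residual: float
    H2: float
    r_h: float          # harmonic mean plots per test genotype
    loglik: float
    converged: bool
    n_obs: int
    message: str = ""


def _reml_neg_loglik(log_gammas, y, X, Zg, Zr):
    gg, gr = np.exp(log_gammas)
    n, p = X.shape
    W = np.eye(n) + gg * (Zg @ Zg.T) + gr * (Zr @ Zr.T)
    try:
        c = linalg.cho_factor(W, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdet_W = 2.0 * np.sum(np.log(np.diag(c[0])))
    Wi_y = linalg.cho_solve(c, y)
    Wi_X = linalg.cho_solve(c, X)
    XtWiX = X.T @ Wi_X
    sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    yPy = float(y @ Wi_y - (X.T @ Wi_y) @ beta)
    if yPy <= 0:
        return np.inf
    sigma_e2 = yPy / (n - p)
    return 0.5 * (logdet_W + logdet_XtWiX + (n - p) * np.log(sigma_e2) + (n - p))


def fit_variance_components(obs: pd.DataFrame, trait: str,
                            max_iter: int = 500) -> VarianceComponents:
    """First REML run: test genotypes random, extras and batch fixed.

    ``obs`` is a plant-level observation table (see :func:`plot_means` for the
    collapsing step applied first).  Raises if fewer than two replicated
    genotypes are present.
    """
    plots = plot_means(obs, trait)
    counts = plots[plots["genotype_role"] == "test"]["genotype_id"].value_counts()
    if len(counts) < 2 or counts.max() < 2:
        raise ValueError("need >=2 test genotypes with replication")
    y, X, Zg, Zr, meta = _design(plots, test_random=True)

    res = optimize.minimize(
        _reml_neg_loglik, x0=np.log([0.5, 0.5]), args=(y, X, Zg, Zr),
        method="Powell", bounds=[(-30.0, 10.0)] * 2,
        options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": max_iter})
    gg, gr = np.exp(res.x)
    n, p = X.shape
    W = np.eye(n) + gg * (Zg @ Zg.T) + gr * (Zr @ Zr.T)
    c = linalg.cho_factor(W, lower=True)
    Wi_y = linalg.cho_solve(c, y)
    Wi_X = linalg.cho_solve(c, X)
    XtWiX = X.T @ Wi_X
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    sigma_e2 = float(y @ Wi_y - (X.T @ Wi_y) @ beta) / (n - p)

    s2_g, s2_r = gg * sigma_e2, gr * sigma_e2
    r_h = stats.hmean(counts.to_numpy())
    h2 = s2_g / (s2_g + sigma_e2 / r_h) if s2_g + sigma_e2 > 0 else 0.0
    return VarianceComponents(
        sigma2_genotype=float(s2_g), sigma2_rep=float(s2_r),
        sigma2_residual=float(sigma_e2), H2=float(h2), r_h=float(r_h),
        loglik=-float(res.fun), converged=bool(res.success), n_obs=n,
        message="" if res.success else str(res.message))


@dataclass
class AdjustedMeansTable:
    """Per-genotype adjusted means on the logit scale with their GLS
    covariance, plus the variance components used."""

    means: pd.DataFrame          # genotype_id, genotype_role, mean, se
    cov: np.ndarray              # covariance of the genotype means
    components: VarianceComponents
    df_residual: int

    def as_series(self, roles: tuple[str, ...] = ("test",)) -> pd.Series:
        sel = self.means[self.means["genotype_role"].isin(roles)]
        return pd.Series(sel["mean"].to_numpy(), index=sel["genotype_id"])


def adjusted_means(obs: pd.DataFrame, components: VarianceComponents,
                   trait: str) -> AdjustedMeansTable:
    """Second run: both genotype factors fixed; unshrunken GLS means.

    Means are least-squares means at the average batch, weighted by the
    first-run variance structure V = sigma2_rep Zr Zr' + sigma2_resid I.
    """
    plots = plot_means(obs, trait)
    y, X, _, Zr, meta = _design(plots, test_random=False)
    n = len(y)
    V = components.sigma2_rep * (Zr @ Zr.T) + components.sigma2_residual * np.eye(n)
    c = linalg.cho_factor(V, lower=True)
    Vi_X = linalg.cho_solve(c, X)
    XtViX = X.T @ Vi_X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (X.T @ linalg.cho_solve(c, y))

    all_ids = sorted(plots["genotype_id"].unique())
    n_batches = len(meta["batches"])
    p = X.shape[1]
    n_geno = len(all_ids)
    # L rows: intercept, batch dummies at their average, genotype dummy
    L = np.zeros((n_geno, p))
    L[:, 0] = 1.0
    L[:, 1:n_batches] = 1.0 / n_batches
    for i in range(1, n_geno):          # genotype 0 is the baseline
        L[i, n_batches - 1 + i] = 1.0
    means = L @ beta
    cov = L @ cov_beta @ L.T
    se = np.sqrt(np.diag(cov))
    roles = plots.drop_duplicates("genotype_id").set_index("genotype_id")
    table = pd.DataFrame({
        "genotype_id": all_ids,
        "genotype_role": [roles.loc[g, "genotype_role"] for g in all_ids],
        "mean": means, "se": se})
    return AdjustedMeansTable(table, cov, components, df_residual=n - p)


def lsd_compare(table: AdjustedMeansTable, alpha: float = 0.05) -> dict:
    """Pairwise LSD comparison with letter grouping.

    LSD_pair = t(1 - alpha/2, residual df) * SED_pair.  Returns the letter
    assignment (insert-and-absorb over means sorted descending, ties broken
    by genotype id) and the minimum / average / maximum LSD over all pairs.
    """
    means = table.means["mean"].to_numpy()
    ids = table.means["genotype_id"].to_numpy()
    k = len(means)
    if k < 2:
        raise ValueError("need at least two genotypes to compare")
    tcrit = stats.t.ppf(1 - alpha / 2, table.df_residual)
    var = np.diag(table.cov)
    sed = np.sqrt(np.maximum(var[:, None] + var[None, :] - 2 * table.cov, 0.0))
    iu = np.triu_indices(k, 1)
    lsd = tcrit * sed
    order = np.lexsort((ids, -means))
    different = np.abs(means[:, None] - means[None, :]) > lsd

    # insert-and-absorb: maximal runs of mutually non-different sorted means
    intervals = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and not different[np.ix_(order[i:j + 2], order[i:j + 2])].any():
            j += 1
        if not intervals or intervals[-1][1] < j:
            intervals.append((i, j))
        i += 1
    letters = {g: "" for g in ids}
    for letter_idx, (a, b) in enumerate(intervals):
        ch = chr(ord("a") + letter_idx % 26)
        for pos in range(a, b + 1):
            letters[ids[order[pos]]] += ch
    return {
        "letters": letters,
        "lsd_min": float(lsd[iu].min()),
        "lsd_average": float(lsd[iu].mean()),
        "lsd_max": float(lsd[iu].max()),
        "alpha": alpha,
    }
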