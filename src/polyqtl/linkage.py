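"""Simplex-marker linkage maps and interval-mapping QTL confirmation.

Markers of the simplex parental class — tetraploid parent homozygous
(``AAAA`` or ``RRRR``), diploid parent heterozygous (``RA``) — segregate 1:1
in the triploid offspring exactly like a diploid backcross, so standard
two-point linkage and interval-mapping machinery applies:

* offspring dosage calls are recoded to 0/1 by carrier status of the diploid
  parent's segregating allele;
* markers are tested against the expected 1:1 ratio (chi-square, 1 df) and
  for missingness before mapping;
* pairwise recombination fractions (with coupling/repulsion phase and LOD),
  single-linkage grouping at a recombination threshold, greedy + 2-opt
  ordering, and Haldane map distances build the genetic map;
* simple interval mapping (SIM) regresses trait means on the conditional
  probability of the heterozygous class given flanking markers (a
  regression, Haley-Knott-style, approximation to mixture-model interval
  mapping), evaluated every ``step`` cM plus at marker positions; composite
  interval mapping (CIM) repeats the scan with SIM peak markers as
  cofactors, excluding cofactors within a window of the tested position;
* coupling-phase linkage disequilibrium (r^2) and a cross-chromosome group
  composition report (translocation flag) complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "haldane",
    "haldane_inverse",
    "select_simplex_markers",
    "chi_square_1to1",
    "segregation_filter",
    "pairwise_recombination",
    "pairwise_recombination_matrix",
    "group_markers",
    "order_markers",
    "LinkageGroup",
    "GeneticMap",
    "build_map",
    "conditional_genotype_probabilities",
    "sim_scan",
    "cim_scan",
    "pairwise_ld",
    "detect_translocation",
]


def haldane(r) -> np.ndarray | float:
    """Haldane map distance in cM: d = -50 ln(1 - 2r); requires r in [0, 0.5)."""
    arr = np.asarray(r, dtype=float)
    if np.any((arr < 0) | (arr >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    out = -50.0 * np.log1p(-2.0 * arr)
    return float(out) if out.ndim == 0 else out


def haldane_inverse(d_cm) -> np.ndarray | float:
    """Recombination fraction for a Haldane distance: r = (1 - e^(-2d/100))/2."""
    arr = np.asarray(d_cm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * (1.0 - np.exp(-2.0 * arr / 100.0))
    return float(out) if out.ndim == 0 else out


def select_simplex_markers(g4: np.ndarray, g2: np.ndarray,
                           offspring_dosage: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Keep homozygous-4x x heterozygous-2x markers; recode offspring to 0/1.

    The heterozygous offspring class — the carrier of the diploid parent's
    segregating allele — is coded 1 (dosage 1 under ``AAAA x RA``, dosage 2
    under ``RRRR x RA``); the homozygous class is coded 0.  Dosages
    impossible under the simplex model (evidence of a miscall) become NaN.

    Returns (indices of retained markers, recoded (m_kept, n) matrix).
    """
    g4 = np.asarray(g4)
    g2 = np.asarray(g2)
    keep = np.flatnonzero(((g4 == 0) | (g4 == 4)) & (g2 == 1))
    D = np.asarray(offspring_dosage, dtype=float)[keep]
    het_dosage = np.where(g4[keep] == 0, 1.0, 2.0)[:, None]
    hom_dosage = np.where(g4[keep] == 0, 0.0, 3.0)[:, None]
    M = np.full_like(D, np.nan)
    M[D == het_dosage] = 1.0
    M[D == hom_dosage] = 0.0
    return keep, M


def chi_square_1to1(n0: int, n1: int) -> tuple[float, float]:
    """Goodness-of-fit test of a 1:1 segregation ratio (1 df)."""
    if n0 + n1 <= 0:
        raise ValueError("empty marker")
    chi2 = (n0 - n1) ** 2 / (n0 + n1)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def segregation_filter(M: np.ndarray, alpha: float = 0.001) -> np.ndarray:
    """Keep-mask over markers whose 0/1 counts are compatible with 1:1."""
    n1 = np.nansum(M, axis=1)
    n = np.sum(np.isfinite(M), axis=1)
    n0 = n - n1
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (n0 - n1) ** 2 / np.where(n > 0, n, 1)
    p = stats.chi2.sf(chi2, 1)
    return (n > 0) & (p > alpha)


def pairwise_recombination_matrix(M: np.ndarray) -> dict[str, np.ndarray]:
    """All-pairs recombination estimates from 0/1 offspring vectors.

    Returns ``r`` (min(k, n-k)/n over complete pairs), ``coupling`` (True
    where mismatches <= matches), ``lod`` (vs r = 0.5 under the chosen
    phase), and ``n`` complete-pair counts.  Entries with no complete pairs
    are NaN.
    """
    A = (M == 1.0).astype(float)   # NaN compares False on both sides
    B = (M == 0.0).astype(float)
    V = np.isfinite(M).astype(float)
    n = V @ V.T
    k = A @ B.T + B @ A.T  # mismatched complete pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.minimum(k, n - k)
        r = rec / n
        coupling = k <= n - k
        with np.errstate(divide="ignore"):
            lod = (rec * np.log10(np.where(rec > 0, 2 * rec / n, 1.0))
                   + (n - rec) * np.log10(np.where(n - rec > 0,
                                                   2 * (n - rec) / n, 1.0)))
    r[n == 0] = np.nan
    lod[n == 0] = np.nan
    np.fill_diagonal(r, 0.0)
    return {"r": r, "coupling": coupling, "lod": lod, "n": n}


def pairwise_recombination(m1, m2) -> tuple[float, str, float]:
    """Two-marker wrapper: (r_hat, phase, LOD)."""
    res = pairwise_recombination_matrix(np.vstack([m1, m2]).astype(float))
    if np.isnan(res["r"][0, 1]):
        return np.nan, "unknown", np.nan
    phase = "coupling" if res["coupling"][0, 1] else "repulsion"
    return float(res["r"][0, 1]), phase, float(res["lod"][0, 1])


def group_markers(r: np.ndarray, r_threshold: float = 0.20,
                  min_size: int = 10) -> tuple[list[np.ndarray], int]:
    """Single-linkage grouping: connected components of the graph with edges
    r_hat <= r_threshold.  Groups below ``min_size`` are discarded (their
    count is returned)."""
    m = r.shape[0]
    adj = np.isfinite(r) & (r <= r_threshold)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups, dropped = [], 0
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if idx.size >= min_size:
            groups.append(idx)
        else:
            dropped += 1
    groups.sort(key=lambda g: (-g.size, g[0]))
    return groups, dropped


def _path_cost(order: np.ndarray, r: np.ndarray) -> float:
    return float(np.nansum(r[order[:-1], order[1:]]))


def order_markers(group: np.ndarray, r: np.ndarray,
                  max_passes: int = 20) -> np.ndarray:
    """Order a linkage group by greedy chaining plus 2-opt refinement.

    Objective: minimize the sum of adjacent recombination fractions.
    Deterministic (ties broken by marker index).
    """
    idx = np.asarray(group)
    if idx.size <= 2:
        return idx.copy()
    sub = r[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    sub = np.where(np.isnan(sub), 0.5, sub)
    m = idx.size
    # seed the chain with the closest pair
    a, b = np.unravel_index(np.argmin(sub), sub.shape)
    chain = [int(a), int(b)]
    free = set(range(m)) - set(chain)
    while free:
        fl = np.array(sorted(free))
        head, tail = chain[0], chain[-1]
        dh, dt = sub[head, fl], sub[tail, fl]
        if dh.min() <= dt.min():
            chain.insert(0, int(fl[np.argmin(dh)]))
        else:
            chain.append(int(fl[np.argmin(dt)]))
        free.discard(chain[0])
        free.discard(chain[-1])
    order = np.array(chain)

    # 2-opt: reverse segments while the adjacent-r sum improves
    def cost(o):
        return sub[o[:-1], o[1:]].sum()

    improved, passes = True, 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        for i in range(m - 1):
            for j in range(i + 1, m):
                new = np.concatenate([order[:i], order[i:j + 1][::-1], order[j + 1:]])
                if cost(new) < cost(order) - 1e-12:
                    order = new
                    improved = True
    return idx[order]


@dataclass
class LinkageGroup:
    """An ordered linkage group with phase-aligned offspring genotypes."""

    marker_ids: list[str]
    cm: np.ndarray                 # cumulative Haldane positions
    phase: np.ndarray              # True where coupling with the group anchor
    genotypes: np.ndarray          # (m, n) 0/1/NaN, aligned to coupling
    physical: pd.DataFrame | None = None  # chrom/pos per marker, if known

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    n_groups_discarded: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, grp in enumerate(self.groups, start=1):
            for i, mid in enumerate(grp.marker_ids):
                row = {"group": g, "marker": mid, "cm": float(grp.cm[i]),
                       "phase": "coupling" if grp.phase[i] else "repulsion"}
                if grp.physical is not None:
                    row["chrom"] = grp.physical.iloc[i]["chrom"]
                    row["pos"] = grp.physical.iloc[i]["pos"]
                rows.append(row)
        return pd.DataFrame(rows)


def _align_phases(order: np.ndarray, coupling: np.ndarray
                  ) -> np.ndarray:
    """Phase of each ordered marker relative to the first, propagated along
    adjacent pairs (adjacent estimates are the most reliable)."""
    m = order.size
    phase = np.ones(m, dtype=bool)
    for i in range(1, m):
        phase[i] = phase[i - 1] == coupling[order[i - 1], order[i]]
    return phase


def build_map(M: np.ndarray, marker_ids: list[str],
              r_threshold: float = 0.20, min_size: int = 10,
              physical: pd.DataFrame | None = None,
              use_physical_order: bool = False) -> GeneticMap:
    """Construct a genetic map from recoded simplex genotypes.

    ``M`` is the (m, n) 0/1/NaN matrix from :func:`select_simplex_markers`
    (after segregation/missingness filtering).  With ``use_physical_order``
    the marker order inside each group follows the supplied physical
    coordinates instead of the 2-opt ordering.
    """
    est = pairwise_recombination_matrix(M)
    groups, dropped = group_markers(est["r"], r_threshold, min_size)
    out = []
    for idx in groups:
        if use_physical_order:
            if physical is None:
                raise ValueError("physical order requested without coordinates")
            sub = physical.iloc[idx]
            ordered = idx[np.lexsort((sub["pos"].to_numpy(),
                                      sub["chrom"].to_numpy()))]
        else:
            ordered = order_markers(idx, est["r"])
        adj_r = np.clip(est["r"][ordered[:-1], ordered[1:]], 0.0, 0.4999)
        adj_r = np.where(np.isnan(adj_r), 0.4999, adj_r)
        cm = np.concatenate([[0.0], np.cumsum(haldane(adj_r))])
        phase = _align_phases(ordered, est["coupling"])
        geno = M[ordered].copy()
        geno[~phase] = 1.0 - geno[~phase]
        phys = physical.iloc[ordered].reset_index(drop=True) \
            if physical is not None else None
        out.append(LinkageGroup([marker_ids[i] for i in ordered], cm, phase,
                                geno, phys))
    return GeneticMap(out, dropped)


# ---------------------------------------------------------------------------
# interval mapping

def conditional_genotype_probabilities(group: LinkageGroup,
                                       positions: np.ndarray) -> np.ndarray:
    """P(heterozygous class) at each evaluation position for each offspring.

    Backcross flanking-marker formulas under Haldane (no interference); per
    individual the nearest non-missing markers left and right of the
    position are used; beyond the ends (or with one side entirely missing)
    the single-flank formula applies, and with no information the prior 0.5.

    Returns an array of shape (len(positions), n_offspring).
    """
    pos = np.asarray(positions, dtype=float)
    m, n = group.genotypes.shape
    out = np.full((pos.size, n), 0.5)
    cm = group.cm
    for i in range(n):
        gi = group.genotypes[:, i]
        obs = np.flatnonzero(np.isfinite(gi))
        if obs.size == 0:
            continue
        ocm, og = cm[obs], gi[obs]
        right = np.searchsorted(ocm, pos, side="left")
        left = right - 1
        has_l, has_r = left >= 0, right < obs.size
        # both flanks
        bl = has_l & has_r
        if bl.any():
            r1 = haldane_inverse(pos[bl] - ocm[left[bl]])
            r2 = haldane_inverse(ocm[right[bl]] - pos[bl])
            a, b = og[left[bl]], og[right[bl]]
            t1 = np.where(a == 1, 1 - r1, r1)         # P(het at pos | left)
            t2 = np.where(b == 1, 1 - r2, r2)         # P(right | het at pos)
            u1 = np.where(a == 1, r1, 1 - r1)
            u2 = np.where(b == 1, r2, 1 - r2)
            out[bl, i] = t1 * t2 / (t1 * t2 + u1 * u2)
        # single flank
        for mask, side in ((has_l & ~has_r, left), (has_r & ~has_l, right)):
            if mask.any():
                d = np.abs(pos[mask] - ocm[side[mask]])
                rr = haldane_inverse(d)
                a = og[side[mask]]
                out[mask, i] = np.where(a == 1, 1 - rr, rr)
    return out


def _grid(group: LinkageGroup, step: float) -> np.ndarray:
    lo, hi = group.cm[0], group.cm[-1]
    grid = np.arange(lo, hi + 1e-9, step)
    return np.unique(np.round(np.concatenate([grid, group.cm]), 10))


def _regress_columns(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, ...]:
    """OLS of y on each column of X; returns slope, t, -log10 p."""
    n = y.size
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(0)
    sxy = xc.T @ yc
    syy = (yc ** 2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        rss = np.maximum(syy - sxy ** 2 / sxx, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        t = slope / se
        logp = np.log(2.0) + stats.t.logsf(np.abs(t), n - 2)
    bad = sxx <= 1e-12
    slope[bad] = np.nan
    t[bad] = np.nan
    logp[bad] = 0.0
    return slope, t, -logp / np.log(10.0)


def _profile_peaks(profile: pd.DataFrame, threshold: float) -> pd.DataFrame:
    peaks = []
    for g, grp in profile.groupby("group", sort=True):
        v = grp["minus_log10_p"].to_numpy()
        for i in range(len(v)):
            if v[i] < threshold or not np.isfinite(v[i]):
                continue
            if (i == 0 or v[i] >= v[i - 1]) and (i == len(v) - 1 or v[i] > v[i + 1]):
                peaks.append(grp.iloc[i])
    return pd.DataFrame(peaks).reset_index(drop=True) if peaks else \
        pd.DataFrame(columns=profile.columns)


def _scan(gmap: GeneticMap, means: pd.Series, offspring_ids: list[str],
          step: float, threshold: float,
          cofactors: pd.DataFrame | None, window: float) -> dict:
    mean_vec = means.reindex(offspring_ids)
    keep = mean_vec.notna().to_numpy()
    y = mean_vec.to_numpy(dtype=float)[keep]
    if keep.sum() < 20:
        raise ValueError("need >=20 offspring with phenotypes")

    cof_cols, cof_meta = [], []
    if cofactors is not None and len(cofactors):
        for _, row in cofactors.iterrows():
            grp = gmap.groups[int(row["group"]) - 1]
            col = conditional_genotype_probabilities(
                grp, np.array([row["position_cm"]]))[0, keep]
            cof_cols.append(col)
            cof_meta.append((int(row["group"]), float(row["position_cm"])))

    records = []
    for g, grp in enumerate(gmap.groups, start=1):
        grid = _grid(grp, step)
        E = conditional_genotype_probabilities(grp, grid)[:, keep]
        marker_at: dict[float, str] = {}
        for c, mid in zip(grp.cm, grp.marker_ids):
            marker_at.setdefault(np.round(c, 10), mid)  # co-located markers
            # share one grid point; the first id labels it
        if not cof_cols:
            slope, t, mlp = _regress_columns(y, E.T)
            for i, p_cm in enumerate(grid):
                records.append((g, float(p_cm),
                                marker_at.get(np.round(p_cm, 10), ""),
                                float(slope[i]), float(mlp[i])))
        else:
            for i, p_cm in enumerate(grid):
                use = [c for c, (cg, ccm) in zip(cof_cols, cof_meta)
                       if cg != g or abs(ccm - p_cm) > window]
                slope, mlp = _cim_point(y, E[i], use)
                records.append((g, float(p_cm),
                                marker_at.get(np.round(p_cm, 10), ""),
                                slope, mlp))
    profile = pd.DataFrame(records, columns=["group", "position_cm", "marker",
                                             "effect", "minus_log10_p"])
    profile.attrs["threshold"] = threshold
    peaks = _profile_peaks(profile, threshold)
    return {"profile": profile, "peaks": peaks}


def _cim_point(y: np.ndarray, x: np.ndarray,
               covariates: list[np.ndarray]) -> tuple[float, float]:
    """Slope and -log10 p of x in a multiple regression with covariates;
    collinear covariates are dropped via QR rank inspection."""
    n = y.size
    cols = [np.ones(n)]
    for c in covariates:
        trial = np.column_stack(cols + [c])
        if np.linalg.matrix_rank(trial) > len(cols):
            cols.append(c)
    X = np.column_stack(cols + [x])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return np.nan, 0.0
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    dof = n - X.shape[1]
    if dof <= 0 or rss <= 0:
        return float(beta[-1]), np.inf
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(rss / dof * xtx_inv[-1, -1])
    t = beta[-1] / se
    logp = np.log(2.0) + stats.t.logsf(abs(t), dof)
    return float(beta[-1]), float(-logp / np.log(10.0))


def sim_scan(gmap: GeneticMap, means: pd.Series, offspring_ids: list[str],
             step: float = 5.0, threshold: float = 2.0) -> dict:
    """Simple interval mapping over all linkage groups.

    ``means`` is indexed by offspring genotype id; the evaluation grid is
    every ``step`` cM plus every marker position; peaks are local maxima of
    -log10(p) at or above ``threshold``.
    """
    return _scan(gmap, means, offspring_ids, step, threshold, None, 0.0)


def cim_scan(gmap: GeneticMap, means: pd.Series, offspring_ids: list[str],
             cofactors: pd.DataFrame, step: float = 5.0,
             threshold: float = 2.0, exclusion_window: float = 10.0) -> dict:
    """Composite interval mapping: SIM with cofactor genotype expectations as
    covariates.  ``cofactors`` needs columns ``group`` and ``position_cm``
    (typically the SIM peaks); cofactors within ``exclusion_window`` cM of
    the tested position on the same group are left out of that test."""
    return _scan(gmap, means, offspring_ids, step, threshold, cofactors,
                 exclusion_window)


def pairwise_ld(genotypes: np.ndarray, cm: np.ndarray | None = None) -> dict:
    """Coupling-phase LD among phase-aligned 0/1 markers.

    Returns the r^2 matrix over complete pairs and, when ``cm`` is given, a
    long-format decay table (pairwise distance vs r^2)."""
    M = np.asarray(genotypes, dtype=float)
    m = M.shape[0]
    r2 = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            ok = np.isfinite(M[i]) & np.isfinite(M[j])
            if ok.sum() < 2:
                continue
            a, b = M[i, ok], M[j, ok]
            if a.std() == 0 or b.std() == 0:
                continue
            r2[i, j] = r2[j, i] = np.corrcoef(a, b)[0, 1] ** 2
    out = {"r2": r2}
    if cm is not None:
        iu = np.triu_indices(m, 1)
        out["decay"] = pd.DataFrame({
            "distance_cm": np.abs(cm[iu[0]] - cm[iu[1]]),
            "r2": r2[iu],
        }).dropna().reset_index(drop=True)
    return out


def detect_translocation(gmap: GeneticMap,
                         min_fraction: float = 0.05) -> pd.DataFrame:
    """Flag linkage groups whose markers map to more than one physical
    chromosome (each contributing >= ``min_fraction`` of the group)."""
    rows = []
    for g, grp in enumerate(gmap.groups, start=1):
        if grp.physical is None:
            raise ValueError("physical chromosome labels are required")
        comp = grp.physical["chrom"].value_counts(normalize=True)
        major = comp[comp >= min_fraction]
        rows.append({
            "group": g,
            "n_markers": grp.n_markers,
            "chromosomes": ",".join(f"{c}:{f:.2f}" for c, f in comp.items()),
            "flagged": len(major) >= 2,
        })
    return pd.DataFrame(rows)
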