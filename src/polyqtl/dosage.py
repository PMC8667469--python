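"""Allele dosage estimation and marker classification from allelic read depths.

In a tetraploid (4x) x diploid (2x) banana cross the triploid offspring carry
0-3 copies of the VCF reference allele ("R") at each biallelic SNP.  Genotypes
are not observed directly: DArTSeq-style genotyping-by-sequencing yields, per
individual and site, a pair of (reference, alternative) read counts at low and
variable depth.  This module turns those counts into

* per-sample reference-allele frequency estimates (the "continuous genotypes"
  used by :mod:`polyqtl.cmap`),
* maximum-likelihood integer dosage calls under a binomial read-count model
  with sequencing error, accepted only when the best genotype is at least
  ``ratio_threshold`` (default 10) times more likely than the runner-up,
* a classification of each marker's parental dosage combination
  (e.g. ``AAAA x RA``) and its segregation status, and
* the marker filters (minor allele frequency, missingness) applied before
  mapping.

Dosage here always counts the reference allele; "R" denotes the VCF REF base
and "A" the alternative base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PARENTAL_CLASS_COUNTS",
    "ReadCountMatrix",
    "DosageCall",
    "ParentalCombination",
    "allele_frequency",
    "allele_frequency_matrix",
    "genotype_likelihood",
    "call_dosage",
    "call_dosage_matrix",
    "classify_parental_combination",
    "tabulate_combinations",
    "expected_offspring_distribution",
    "harmonic_mean_depth",
    "maf_filter",
    "missingness_filter",
]

#: SNP counts per parental dosage combination observed in the motivating
#: 'Monyet' (4x) x 'Kokopo' (2x) banana mapping population (37,436 DArTSeq
#: tags).  Keys are (tetraploid reference dosage, diploid reference dosage).
#: Used as the default class mix of the synthetic cross generator.
PARENTAL_CLASS_COUNTS: dict[tuple[int, int], int] = {
    (4, 2): 499, (4, 1): 9635, (4, 0): 3458,
    (3, 2): 451, (3, 1): 189, (3, 0): 48,
    (2, 2): 2035, (2, 1): 390, (2, 0): 206,
    (1, 2): 243, (1, 1): 109, (1, 0): 84,
    (0, 2): 5568, (0, 1): 4619, (0, 0): 9902,
}

_SEG_STATUSES = (
    "monomorphic",
    "polymorphic_nonsegregating",
    "segregates_P1_only",
    "segregates_P2_only",
    "segregates_both",
)


@dataclass
class ReadCountMatrix:
    """Per-site, per-sample (ref, alt) allelic depths plus site metadata.

    ``sites`` is a DataFrame with columns ``chrom, pos, ref, alt`` (1-based
    positions, unique by (chrom, pos)); ``ref_counts`` and ``alt_counts`` are
    integer arrays of shape (n_sites, n_samples).
    """

    sites: pd.DataFrame
    samples: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("allelic depths must be non-negative")
        if self.ref_counts.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count matrix shape does not match sites x samples")
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise ValueError("sites must be unique by (chrom, pos)")

    @property
    def depths(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    @classmethod
    def from_vcf(cls, path: str) -> "ReadCountMatrix":
        """Read an AD-bearing VCF; non-biallelic-SNP records are dropped."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, refs, alts = [], [], []
        n_dropped = 0
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_dropped += 1
                continue
            ad = v.format("AD")
            if ad is None:
                raise ValueError(f"record {v.CHROM}:{v.POS} has no AD field")
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0  # cyvcf2 encodes missing AD as a negative sentinel
            rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
            refs.append(ad[:, 0])
            alts.append(ad[:, 1])
        vcf.close()
        if not rows:
            raise ValueError(f"no biallelic SNP records with AD in {path}")
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        sites.attrs["n_dropped_non_biallelic"] = n_dropped
        return cls(sites, samples, np.array(refs), np.array(alts))


@dataclass
class DosageCall:
    """A maximum-likelihood dosage call for one sample at one site."""

    g: int | None
    likelihoods: np.ndarray
    ratio: float  # best / runner-up likelihood ratio (inf when runner-up is 0)


@dataclass
class ParentalCombination:
    """Parental dosage combination of a marker and its segregation status."""

    g_tetraploid: int
    g_diploid: int
    label: str = field(init=False)
    status: str = field(init=False)

    def __post_init__(self) -> None:
        g4, g2 = self.g_tetraploid, self.g_diploid
        if not (0 <= g4 <= 4) or not (0 <= g2 <= 2):
            raise ValueError(f"parental dosages out of range: g4={g4}, g2={g2}")
        self.label = "R" * g4 + "A" * (4 - g4) + "x" + "R" * g2 + "A" * (2 - g2)
        het4 = 0 < g4 < 4
        het2 = g2 == 1
        if het4 and het2:
            self.status = "segregates_both"
        elif het4:
            self.status = "segregates_P1_only"
        elif het2:
            self.status = "segregates_P2_only"
        elif (g4 == 4) == (g2 == 2):
            self.status = "monomorphic"
        else:
            self.status = "polymorphic_nonsegregating"

    @property
    def segregating(self) -> bool:
        return self.status.startswith("segregates")


def allele_frequency(ref_count, alt_count):
    """Reference-allele frequency ref/(ref+alt); NaN where depth is zero."""
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("allelic depths must be non-negative")
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(depth > 0, ref / np.where(depth > 0, depth, 1), np.nan)
    if f.ndim == 0:
        return float(f)
    return f


def allele_frequency_matrix(counts: ReadCountMatrix) -> np.ndarray:
    """(n_sites, n_samples) matrix of reference-allele frequencies."""
    return allele_frequency(counts.ref_counts, counts.alt_counts)


def _p_ref(g, ploidy: int, epsilon: float):
    """Expected reference-read fraction for dosage g with error rate epsilon."""
    frac = np.asarray(g, dtype=float) / ploidy
    return frac * (1.0 - epsilon) + (1.0 - frac) * epsilon


def genotype_likelihood(ref_count: int, alt_count: int, ploidy: int, g: int,
                        epsilon: float = 0.01) -> float:
    """Binomial likelihood of the read pair given reference dosage ``g``.

    P(D | g) = Binom(ref; ref+alt, p_g) with p_g = (g/ploidy)(1-eps) +
    (1 - g/ploidy) eps.
    """
    if not 0 <= g <= ploidy:
        raise ValueError(f"dosage {g} outside 0..{ploidy}")
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    return float(stats.binom.pmf(ref_count, ref_count + alt_count,
                                 _p_ref(g, ploidy, epsilon)))


def call_dosage(ref_count: int, alt_count: int, ploidy: int,
                epsilon: float = 0.01, ratio_threshold: float = 10.0) -> DosageCall:
    """ML dosage call; missing unless the best genotype is ``ratio_threshold``
    times more likely than the second best."""
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must exceed 1")
    liks = np.array([genotype_likelihood(ref_count, alt_count, ploidy, g, epsilon)
                     for g in range(ploidy + 1)])
    depth = ref_count + alt_count
    if depth == 0 or not np.isfinite(liks).all() or liks.max() == 0.0:
        return DosageCall(None, liks, np.nan)
    order = np.argsort(liks)[::-1]
    best, second = liks[order[0]], liks[order[1]]
    ratio = np.inf if second == 0 else best / second
    if ratio >= ratio_threshold:
        return DosageCall(int(order[0]), liks, float(ratio))
    return DosageCall(None, liks, float(ratio))


def call_dosage_matrix(ref_counts: np.ndarray, alt_counts: np.ndarray,
                       ploidy: int, epsilon: float = 0.01,
                       ratio_threshold: float = 10.0) -> np.ndarray:
    """Vectorized ML dosage calls; returns a float matrix with NaN = missing."""
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must exceed 1")
    ref = np.asarray(ref_counts)
    alt = np.asarray(alt_counts)
    n = ref + alt
    # log-likelihood per candidate dosage, stacked on a leading axis
    ps = _p_ref(np.arange(ploidy + 1), ploidy, epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.stack([stats.binom.logpmf(ref, n, p) for p in ps])
    ll = np.where(np.isnan(ll), -np.inf, ll)
    order = np.argsort(ll, axis=0)
    best_idx = order[-1]
    best = np.take_along_axis(ll, order[-1][None], axis=0)[0]
    second = np.take_along_axis(ll, order[-2][None], axis=0)[0]
    called = (n > 0) & np.isfinite(best) & (best - second >= np.log(ratio_threshold))
    out = np.where(called, best_idx.astype(float), np.nan)
    return out


def classify_parental_combination(g4: int, g2: int) -> ParentalCombination:
    """Classify a marker by its parental dosage pair (tetraploid, diploid)."""
    return ParentalCombination(int(g4), int(g2))


def tabulate_combinations(g4: np.ndarray, g2: np.ndarray,
                          weights: np.ndarray | None = None) -> dict:
    """Cross-tabulate parental dosage combinations over sites.

    Returns a dict with a 5x3 ``table`` (rows: tetraploid dosage 4..0 labelled
    RRRR..AAAA; columns: diploid RR/RA/AA) and the marginal totals by
    segregation status.  ``weights`` allows counts instead of one row per site.
    """
    g4 = np.asarray(g4, dtype=int)
    g2 = np.asarray(g2, dtype=int)
    w = np.ones_like(g4, dtype=float) if weights is None else np.asarray(weights, float)
    table = np.zeros((5, 3))
    status_totals = {s: 0.0 for s in _SEG_STATUSES}
    for a, b, wt in zip(g4, g2, w):
        comb = classify_parental_combination(a, b)
        table[4 - a, 2 - b] += wt
        status_totals[comb.status] += wt
    row_labels = ["RRRR", "RRRA", "RRAA", "RAAA", "AAAA"]
    col_labels = ["RR", "RA", "AA"]
    df = pd.DataFrame(table, index=row_labels, columns=col_labels)
    totals = {k: float(v) for k, v in status_totals.items()}
    totals["total_segregating"] = (totals["segregates_P1_only"]
                                   + totals["segregates_P2_only"]
                                   + totals["segregates_both"])
    totals["total"] = float(table.sum())
    return {"table": df, "totals": totals}


def expected_offspring_distribution(g4: int, g2: int) -> np.ndarray:
    """Offspring reference-dosage law (length-4 vector, dosage 0..3).

    Convolution of the tetraploid bivalent-gamete hypergeometric law
    C(g4,k) C(4-g4,2-k) / C(4,2) with the diploid Mendelian gamete law.
    """
    comb = classify_parental_combination(g4, g2)  # validates the range
    del comb
    tet = stats.hypergeom.pmf(np.arange(3), 4, g4, 2)
    dip = stats.hypergeom.pmf(np.arange(2), 2, g2, 1)
    return np.convolve(tet, dip)


def harmonic_mean_depth(depths) -> float:
    """Harmonic mean over strictly positive depths (S_T); zeros are missing
    observations, not depth-zero measurements, and are excluded."""
    d = np.asarray(depths, dtype=float)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("no positive depths: S_T undefined")
    return float(d.size / np.sum(1.0 / d))


def maf_filter(freqs: np.ndarray, threshold: float = 0.02) -> np.ndarray:
    """Boolean keep-mask over sites by minor allele frequency.

    The per-site population frequency is the mean of per-sample frequencies
    over non-missing samples (unweighted by depth); a site is kept iff
    min(f, 1-f) >= threshold.
    """
    f = np.nanmean(np.asarray(freqs, dtype=float), axis=1)
    maf = np.minimum(f, 1.0 - f)
    return np.where(np.isnan(maf), False, maf >= threshold)


def missingness_filter(calls: np.ndarray, max_missing: float = 0.10) -> np.ndarray:
    """Boolean keep-mask over sites: fraction of missing (NaN) sample values
    strictly below ``max_missing``."""
    m = np.asarray(calls, dtype=float)
    frac = np.isnan(m).mean(axis=1)
    return frac < max_missing
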