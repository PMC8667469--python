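"""Synthetic 4x x 2x -> 3x mapping population with known truth.

The generator emulates the structure of a banana weevil-resistance mapping
study: a tetraploid female ('Monyet'-like) crossed with a diploid male
('Kokopo'-like) producing ~138 triploid offspring, genotyped at tens of
thousands of SNPs on 11 chromosomes by low-depth sequencing, and phenotyped
for percentage corm-damage traits in a 4-batch x 2-block x 4-plant design.

Model summary
-------------
* Parental dosages per marker are drawn from a configurable mix of the 15
  (tetraploid, diploid) reference-dosage combinations; reference alleles are
  placed on uniformly random homologs, so marker pairs segregating from the
  same parent are in coupling or repulsion at random.
* Tetraploid meiosis uses random bivalent pairing (the 4 homologs form 2
  random disjoint pairs each meiosis) with independent Haldane
  (no-interference) crossover processes per bivalent and one chromatid
  sampled per bivalent; double reduction is not modelled.  At a single
  marker this yields the hypergeometric gamete law
  C(g4,k) C(4-g4,2-k) / C(4,2).
* Diploid meiosis is standard, with the same Haldane crossover process.
* Phenotypes live on the logit scale: the latent plot value is
  mu + sum_q beta_q * (reference dosage at QTL q) + genotype deviation
  + batch + block(batch) + plot error, observed as 100 * expit(latent)
  (plus a small per-plant deviation).
* Read counts: per site and sample the depth is negative binomial
  (mean, dispersion); zero depth means missing.  The reference count is
  Binomial(depth, p_g) with p_g = (g/ploidy)(1-eps) + (1-g/ploidy) eps.

All randomness flows from ``CrossConfig.seed`` through named
``numpy.random.SeedSequence`` child streams, so every product of a config is
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .dosage import PARENTAL_CLASS_COUNTS, ReadCountMatrix

__all__ = [
    "Chromosome",
    "CrossConfig",
    "TruthSet",
    "SimResult",
    "default_class_freqs",
    "simulate_parent_genotypes",
    "simulate_gamete_tetraploid",
    "simulate_gamete_diploid",
    "simulate_phenotypes",
    "simulate_read_counts",
    "simulate_cross",
    "write_outputs",
]

BP_PER_CM = 300_000  # physical scale used to assign base-pair positions

_STREAMS = ("positions", "parents", "meiosis", "phenotypes", "reads")


def default_class_freqs() -> dict[tuple[int, int], float]:
    """Parental-class probabilities proportional to the observed SNP counts
    in the motivating banana 4x x 2x population."""
    total = sum(PARENTAL_CLASS_COUNTS.values())
    return {k: v / total for k, v in PARENTAL_CLASS_COUNTS.items()}


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_cm: float
    n_markers: int


def _default_chromosomes() -> tuple[Chromosome, ...]:
    # 11 chromosomes, ~37k markers total, of which ~48% segregate under the
    # default class mix -> ~18k segregating SNPs as in the motivating study.
    return tuple(Chromosome(f"chr{i:02d}", 120.0, 3404) for i in range(1, 12))


@dataclass
class CrossConfig:
    """Configuration of the synthetic cross; defaults mirror the study design."""

    n_offspring: int = 138
    chromosomes: tuple[Chromosome, ...] = field(default_factory=_default_chromosomes)
    parental_class_freqs: dict[tuple[int, int], float] = field(
        default_factory=default_class_freqs)
    qtls: tuple[tuple[str, float, float], ...] = (("chr06", 60.0, 0.8),)
    #: optionally restrict the markers a QTL may snap to, e.g. (0, 1) for the
    #: simplex AAAA x RA class; None allows any segregating marker
    qtl_marker_class: tuple[int, int] | None = None
    mu: float = 0.25
    variance_components: tuple[float, float, float] = (0.2, 0.05, 0.8)
    sigma2_plant: float = 0.05
    design: tuple[int, int, int] = (4, 2, 4)  # batches, blocks/batch, plants/plot
    batch_effects: tuple[float, ...] = (0.0, -0.2, 0.1, 0.3)
    depth_model: tuple[float, float] = (20.0, 10.0)  # mean, NB dispersion k
    epsilon: float = 0.01
    marker_spacing: str = "random"  # "random" | "even"
    trait: str = "PD"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.variance_components) or self.sigma2_plant < 0:
            raise ValueError("variance components must be non-negative")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        freqs = np.array(list(self.parental_class_freqs.values()), dtype=float)
        if (freqs < 0).any() or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("parental_class_freqs must be a probability vector")
        for g4, g2 in self.parental_class_freqs:
            if not (0 <= g4 <= 4 and 0 <= g2 <= 2):
                raise ValueError(f"invalid parental class ({g4},{g2})")
        if len(self.batch_effects) != self.design[0]:
            raise ValueError("need one batch effect per batch")
        if self.marker_spacing not in ("random", "even"):
            raise ValueError("marker_spacing must be 'random' or 'even'")
        chrom_names = [c.name for c in self.chromosomes]
        if len(set(chrom_names)) != len(chrom_names):
            raise ValueError("chromosome names must be unique")
        for chrom, pos, _beta in self.qtls:
            if chrom not in chrom_names:
                raise ValueError(f"QTL chromosome {chrom!r} not simulated")
            length = dict((c.name, c.length_cm) for c in self.chromosomes)[chrom]
            if not 0 <= pos <= length:
                raise ValueError(f"QTL position {pos} outside {chrom}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosomes"] = [list(dataclasses.astuple(c)) for c in self.chromosomes]
        d["parental_class_freqs"] = {f"{k[0]},{k[1]}": v
                                     for k, v in self.parental_class_freqs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CrossConfig":
        d = dict(d)
        d["chromosomes"] = tuple(Chromosome(*c) for c in d["chromosomes"])
        d["parental_class_freqs"] = {
            tuple(int(x) for x in k.split(",")): v
            for k, v in d["parental_class_freqs"].items()}
        d["qtls"] = tuple(tuple(q) for q in d["qtls"])
        if d.get("qtl_marker_class") is not None:
            d["qtl_marker_class"] = tuple(d["qtl_marker_class"])
        for key in ("variance_components", "design", "batch_effects", "depth_model"):
            d[key] = tuple(d[key])
        return cls(**d)

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss)
                for name, ss in zip(_STREAMS, children)}


@dataclass
class TruthSet:
    """Ground truth of one simulated cross."""

    markers: pd.DataFrame           # chrom, pos_cm, pos, ref, alt, g4, g2
    tet_haplotypes: dict[str, np.ndarray]   # chrom -> (4, m) 0/1 (1 = ref allele)
    dip_haplotypes: dict[str, np.ndarray]   # chrom -> (2, m)
    offspring_dosages: np.ndarray   # (n_markers, n_offspring) ints 0..3
    offspring_ids: list[str]
    genetic_values: np.ndarray      # (n_offspring,) logit-scale QTL sums
    qtls: list[dict]                # chrom, pos_cm, beta, marker_index
    config: CrossConfig

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class SimResult:
    truth: TruthSet
    counts: ReadCountMatrix
    phenotypes: pd.DataFrame


# ---------------------------------------------------------------------------
# marker scaffold and parental genotypes

def _marker_positions(config: CrossConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom in config.chromosomes:
        m = chrom.n_markers
        if config.marker_spacing == "even":
            pos_cm = np.linspace(0.0, chrom.length_cm, m)
        else:
            pos_cm = np.sort(rng.uniform(0.0, chrom.length_cm, m))
            while np.any(np.diff(pos_cm) <= 0):  # vanishing probability
                pos_cm = np.sort(rng.uniform(0.0, chrom.length_cm, m))
        pos_bp = np.round(pos_cm * BP_PER_CM).astype(np.int64) + 1
        # strictly increasing physical positions (ties shifted by <= m bp,
        # negligible against the 3e5 bp/cM scale)
        pos_bp = np.maximum.accumulate(pos_bp) + np.arange(m)
        bases = np.array(list("ACGT"))
        ref = rng.integers(0, 4, m)
        alt = (ref + rng.integers(1, 4, m)) % 4
        for j in range(m):
            rows.append((chrom.name, pos_cm[j], int(pos_bp[j]),
                         bases[ref[j]], bases[alt[j]]))
    return pd.DataFrame(rows, columns=["chrom", "pos_cm", "pos", "ref", "alt"])


def simulate_parent_genotypes(config: CrossConfig,
                              rng: np.random.Generator | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-marker parental dosages (g4, g2) from the class mix."""
    rng = rng or config.streams()["parents"]
    classes = list(config.parental_class_freqs.keys())
    probs = np.array([config.parental_class_freqs[c] for c in classes])
    m = sum(c.n_markers for c in config.chromosomes)
    idx = rng.choice(len(classes), size=m, p=probs)
    g4 = np.array([classes[i][0] for i in idx], dtype=np.int8)
    g2 = np.array([classes[i][1] for i in idx], dtype=np.int8)
    return g4, g2


def _assign_haplotypes(dosage: np.ndarray, n_homologs: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(n_homologs, m) 0/1 alleles with column sums equal to ``dosage``,
    the carrier homologs drawn uniformly at random per marker."""
    m = dosage.size
    ranks = np.argsort(rng.random((m, n_homologs)), axis=1)
    hap = (ranks < dosage[:, None]).astype(np.int8)
    return hap.T


# ---------------------------------------------------------------------------
# meiosis

def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def _chromatid_mosaic(pos_cm: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """(n, m) 0/1 homolog-identity mosaics of a bivalent under Haldane
    recombination (Markov chain over markers; no interference)."""
    m = pos_cm.size
    r = _haldane_r(np.diff(pos_cm))
    start = rng.integers(0, 2, size=(n, 1))
    if m == 1:
        return start.astype(np.int8)
    switches = rng.random((n, m - 1)) < r
    return ((start + np.concatenate(
        [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1))
        % 2).astype(np.int8)

_PAIRINGS = np.array([[[0, 1], [2, 3]], [[0, 2], [1, 3]], [[0, 3], [1, 2]]])


def simulate_gamete_tetraploid(haplotypes: np.ndarray, pos_cm: np.ndarray,
                               rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Diploid gametes of a tetraploid parent: (n, 2, m) allele array.

    Each meiosis pairs the 4 homologs into 2 uniformly random disjoint
    bivalents and samples one Haldane-recombinant chromatid per bivalent.
    """
    m = pos_cm.size
    pairing = _PAIRINGS[rng.integers(0, 3, size=n)]        # (n, 2, 2)
    out = np.empty((n, 2, m), dtype=np.int8)
    cols = np.arange(m)
    for k in range(2):
        state = _chromatid_mosaic(pos_cm, n, rng)          # (n, m) in {0,1}
        homolog = np.take_along_axis(pairing[:, k, :], state, axis=1)  # (n, m)
        out[:, k, :] = haplotypes[homolog, cols[None, :]]
    return out


def simulate_gamete_diploid(haplotypes: np.ndarray, pos_cm: np.ndarray,
                            rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Haploid gametes of a diploid parent: (n, m) allele array."""
    state = _chromatid_mosaic(pos_cm, n, rng)
    cols = np.arange(pos_cm.size)
    return haplotypes[state, cols[None, :]]


# ---------------------------------------------------------------------------
# assembling the population

def _simulate_truth(config: CrossConfig,
                    streams: dict[str, np.random.Generator]) -> TruthSet:
    markers = _marker_positions(config, streams["positions"])
    g4, g2 = simulate_parent_genotypes(config, streams["parents"])
    markers["g4"] = g4
    markers["g2"] = g2

    rng = streams["meiosis"]
    n = config.n_offspring
    tet_haps, dip_haps = {}, {}
    dosage_blocks = []
    for chrom in config.chromosomes:
        sel = markers["chrom"] == chrom.name
        pos = markers.loc[sel, "pos_cm"].to_numpy()
        tet_h = _assign_haplotypes(markers.loc[sel, "g4"].to_numpy(), 4, rng)
        dip_h = _assign_haplotypes(markers.loc[sel, "g2"].to_numpy(), 2, rng)
        tet_haps[chrom.name] = tet_h
        dip_haps[chrom.name] = dip_h
        tet_gam = simulate_gamete_tetraploid(tet_h, pos, rng, n)   # (n,2,m)
        dip_gam = simulate_gamete_diploid(dip_h, pos, rng, n)      # (n,m)
        dosage_blocks.append((tet_gam.sum(axis=1) + dip_gam).T)    # (m,n)
    dosages = np.concatenate(dosage_blocks, axis=0).astype(np.int8)

    # QTLs snap to the nearest segregating marker (a monomorphic locus cannot
    # produce a mappable effect by construction).
    if config.qtl_marker_class is not None:
        c4, c2 = config.qtl_marker_class
        seg = (markers["g4"].to_numpy() == c4) & (markers["g2"].to_numpy() == c2)
    else:
        seg = (0 < markers["g4"].to_numpy()) & (markers["g4"].to_numpy() < 4)
        seg |= markers["g2"].to_numpy() == 1
    qtls = []
    genetic = np.zeros(n)
    for chrom, pos_cm, beta in config.qtls:
        cand = np.flatnonzero((markers["chrom"] == chrom).to_numpy() & seg)
        if cand.size == 0:
            raise ValueError(f"no segregating marker available on {chrom} for QTL")
        j = cand[np.argmin(np.abs(markers["pos_cm"].to_numpy()[cand] - pos_cm))]
        qtls.append({"chrom": chrom, "pos_cm": float(pos_cm), "beta": float(beta),
                     "marker_index": int(j)})
        genetic += beta * dosages[j].astype(float)

    ids = [f"F1-{i + 1:03d}" for i in range(n)]
    return TruthSet(markers, tet_haps, dip_haps, dosages, ids, genetic,
                    qtls, config)


EXTRA_GENOTYPES = ("Monyet", "Kokopo", "check_R1", "check_R2",
                   "check_S1", "check_S2")


def simulate_phenotypes(truth: TruthSet, config: CrossConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plant-level percentage observations for one trait.

    Offspring are split into disjoint batch subsets; the two parents and the
    four checks are repeated in every batch.  Output columns:
    genotype_id, genotype_role, batch, block, plant, trait, value_percent.
    """
    rng = rng or config.streams()["phenotypes"]
    n_batches, n_blocks, n_plants = config.design
    s2_g, s2_rep, s2_plot = config.variance_components

    geno_ids = list(truth.offspring_ids) + list(EXTRA_GENOTYPES)
    roles = {g: "test" for g in truth.offspring_ids}
    roles.update({"Monyet": "parent", "Kokopo": "parent"})
    roles.update({g: "check" for g in EXTRA_GENOTYPES[2:]})
    genetic = dict(zip(truth.offspring_ids, truth.genetic_values))
    # extras: fixed genotypic offsets drawn once (their dosages are not part
    # of the triploid QTL model)
    for g in EXTRA_GENOTYPES:
        genetic[g] = rng.normal(0.0, np.sqrt(s2_g) if s2_g > 0 else 0.0)
    geno_dev = {g: rng.normal(0.0, np.sqrt(s2_g)) if s2_g > 0 else 0.0
                for g in truth.offspring_ids}
    for g in EXTRA_GENOTYPES:
        geno_dev[g] = 0.0  # extras' deviation folded into their fixed offset

    batch_of = {}
    splits = np.array_split(np.arange(len(truth.offspring_ids)), n_batches)
    for b, idxs in enumerate(splits, start=1):
        for i in idxs:
            batch_of[truth.offspring_ids[i]] = b

    rows = []
    for b in range(1, n_batches + 1):
        members = [g for g in truth.offspring_ids if batch_of[g] == b]
        members += list(EXTRA_GENOTYPES)
        for blk in range(1, n_blocks + 1):
            blk_eff = rng.normal(0.0, np.sqrt(s2_rep)) if s2_rep > 0 else 0.0
            for g in members:
                plot_eff = rng.normal(0.0, np.sqrt(s2_plot)) if s2_plot > 0 else 0.0
                latent = (config.mu + genetic[g] + geno_dev[g]
                          + config.batch_effects[b - 1] + blk_eff + plot_eff)
                plant_dev = (rng.normal(0.0, np.sqrt(config.sigma2_plant), n_plants)
                             if config.sigma2_plant > 0 else np.zeros(n_plants))
                for p in range(1, n_plants + 1):
                    value = 100.0 * expit(latent + plant_dev[p - 1])
                    rows.append((g, roles[g], b, blk, p, config.trait, value))
    return pd.DataFrame(rows, columns=["genotype_id", "genotype_role", "batch",
                                       "block", "plant", "trait", "value_percent"])


def simulate_read_counts(truth: TruthSet, config: CrossConfig,
                         rng: np.random.Generator | None = None
                         ) -> ReadCountMatrix:
    """Allelic depths for the two parents and all offspring.

    Depths are negative binomial (mean, dispersion k); a zero depth is a
    missing observation downstream.  Reference counts are binomial with the
    error-adjusted expected reference fraction of each true dosage.
    """
    rng = rng or config.streams()["reads"]
    mean_depth, k = config.depth_model
    eps = config.epsilon
    m = len(truth.markers)
    samples = ["Monyet", "Kokopo"] + list(truth.offspring_ids)
    ploidies = np.array([4, 2] + [3] * len(truth.offspring_ids))
    dosage = np.concatenate(
        [truth.markers["g4"].to_numpy()[:, None],
         truth.markers["g2"].to_numpy()[:, None],
         truth.offspring_dosages], axis=1).astype(float)
    p_nb = k / (k + mean_depth)
    depth = rng.negative_binomial(k, p_nb, size=(m, len(samples)))
    p_ref = (dosage / ploidies[None, :]) * (1 - eps) \
        + (1 - dosage / ploidies[None, :]) * eps
    ref = rng.binomial(depth, p_ref)
    alt = depth - ref
    sites = truth.markers[["chrom", "pos", "ref", "alt"]].copy()
    return ReadCountMatrix(sites, samples, ref, alt)


def simulate_cross(config: CrossConfig) -> SimResult:
    """Run the full generator: truth, read counts, and phenotypes."""
    streams = config.streams()
    truth = _simulate_truth(config, streams)
    phenos = simulate_phenotypes(truth, config, streams["phenotypes"])
    counts = simulate_read_counts(truth, config, streams["reads"])
    return SimResult(truth, counts, phenos)


# ---------------------------------------------------------------------------
# output files

def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF (AD per sample), phenotype CSV, and a truth/config JSON."""
    from .vcfio import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "simulated.vcf",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
        "dosages": outdir / "true_dosages.csv",
    }
    write_vcf(result.counts, paths["vcf"])
    result.phenotypes.to_csv(paths["phenotypes"], index=False)
    truth = result.truth
    site_ids = (truth.markers["chrom"].astype(str) + "_"
                + truth.markers["pos"].astype(str))
    pd.DataFrame(truth.offspring_dosages, index=site_ids,
                 columns=truth.offspring_ids).to_csv(paths["dosages"])
    with open(paths["truth"], "w") as fh:
        json.dump({
            "seed": truth.config.seed,
            "config": truth.config.to_dict(),
            "qtls": truth.qtls,
        }, fh, indent=2)
    return paths
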