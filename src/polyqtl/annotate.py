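"""Closest-gene annotation of significant SNPs from a GFF3 file.

For each SNP the nearest feature of type ``gene`` on either strand is
reported (bedtools ``closestBed`` semantics: distance 0 when the SNP lies
inside the gene, otherwise the gap in bp to the nearest interval edge), and
SNP-gene distances are binned as within-gene, <1 kb, 1-4.5 kb, or >4.5 kb.
Exact ties are all reported, ordered by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneFeature",
    "AnnotationHit",
    "parse_gff3",
    "closest_feature",
    "bin_distance",
    "annotate_snps",
    "genes_to_bed",
]

DISTANCE_BINS = ("within_gene", "lt_1kb", "1kb_to_4.5kb", "gt_4.5kb")


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval; 0-based half-open coordinates internally."""

    chrom: str
    start: int          # 0-based inclusive
    end: int            # exclusive
    strand: str
    gene_id: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval for {self.gene_id}")


@dataclass(frozen=True)
class AnnotationHit:
    snp_id: str
    gene_id: str
    distance: int
    bin: str
    description: str = ""


def parse_gff3(path: str) -> list[GeneFeature]:
    """Extract gene-type features from a GFF3 file (via gffutils).

    GFF3 coordinates are 1-based inclusive; they are converted to 0-based
    half-open.  Malformed lines are skipped with a warning; a file without
    genes is an error.
    """
    import warnings

    import gffutils

    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
    except Exception as exc:  # fall back to a lenient pass
        warnings.warn(f"strict GFF3 parse failed ({exc}); retrying leniently")
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique",
                                checklines=0, keep_order=True)
    genes = []
    for f in db.features_of_type("gene"):
        gid = f.attributes.get("ID", [f.id])[0]
        desc = f.attributes.get("Name", f.attributes.get("description", [""]))[0]
        genes.append(GeneFeature(f.seqid, f.start - 1, f.end, f.strand or ".",
                                 gid, desc))
    if not genes:
        raise ValueError(f"no gene features found in {path}")
    return genes


def _distance_to(gene: GeneFeature, pos0: int) -> int:
    """bp gap from a 0-based SNP position to a gene interval (0 if inside)."""
    if gene.start <= pos0 < gene.end:
        return 0
    return gene.start - pos0 if pos0 < gene.start else pos0 - (gene.end - 1)


def closest_feature(chrom: str, pos: int, genes: list[GeneFeature]
                    ) -> list[AnnotationHit]:
    """Nearest gene(s) to a SNP (1-based position); strand is ignored.

    All genes at the minimal distance are returned, sorted by gene id; an
    empty list (with a warning) if the chromosome has no genes.
    """
    import warnings

    pos0 = pos - 1
    cand = [g for g in genes if g.chrom == chrom]
    if not cand:
        warnings.warn(f"no genes on {chrom}; SNP {chrom}:{pos} unannotated")
        return []
    d = np.array([_distance_to(g, pos0) for g in cand])
    best = d.min()
    hits = sorted((g for g, di in zip(cand, d) if di == best),
                  key=lambda g: g.gene_id)
    snp_id = f"{chrom}_{pos}"
    return [AnnotationHit(snp_id, g.gene_id, int(best), bin_distance(int(best)),
                         g.description) for g in hits]


def bin_distance(distance: int) -> str:
    """Distance bin: 0 -> within_gene, (0,1000) -> lt_1kb,
    [1000,4500] -> 1kb_to_4.5kb, >4500 -> gt_4.5kb."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance == 0:
        return "within_gene"
    if distance < 1000:
        return "lt_1kb"
    if distance <= 4500:
        return "1kb_to_4.5kb"
    return "gt_4.5kb"


def annotate_snps(snps: pd.DataFrame, genes: list[GeneFeature]) -> pd.DataFrame:
    """Closest-gene table for a SNP table with ``chrom``/``pos`` columns.

    Ties are all listed; the first row per SNP (lexicographically first gene
    id) is the canonical hit for downstream summaries.
    """
    import dataclasses

    rows = [dataclasses.asdict(h)
            for snp in snps.itertuples(index=False)
            for h in closest_feature(snp.chrom, int(snp.pos), genes)]
    if not rows:
        return pd.DataFrame(
            columns=["snp_id", "gene_id", "distance", "bin", "description"])
    return pd.DataFrame(rows)


def genes_to_bed(genes: list[GeneFeature], path: str) -> str:
    """Write gene intervals as BED (0-based half-open, preserving length)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    return path
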