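"""VCF 4.2 output for simulated allelic depths (reading goes through cyvcf2)."""

from __future__ import annotations

from pathlib import Path

from .dosage import ReadCountMatrix

_HEADER = """\
##fileformat=VCFv4.2
##source=polyqtl
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles in the order listed">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(counts: ReadCountMatrix, path: str | Path) -> Path:
    """Write the count matrix as a plain-text VCF 4.2 file with AD and DP."""
    path = Path(path)
    sites = counts.sites
    contigs = list(dict.fromkeys(sites["chrom"]))
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for c in contigs:
            last = int(sites.loc[sites["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={last + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(counts.samples) + "\n")
        ref_m, alt_m = counts.ref_counts, counts.alt_counts
        for j, site in enumerate(sites.itertuples(index=False)):
            cells = "\t".join(
                f"{ref_m[j, s]},{alt_m[j, s]}:{ref_m[j, s] + alt_m[j, s]}"
                for s in range(len(counts.samples)))
            fh.write(f"{site.chrom}\t{site.pos}\t{site.chrom}_{site.pos}\t"
                     f"{site.ref}\t{site.alt}\t.\tPASS\t.\tAD:DP\t{cells}\n")
    return path
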