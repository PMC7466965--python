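"""Genotype-to-sequence projection and CDS concatenation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from brewtrace.core_io.genome import GenomeModel, IntervalSet, reverse_complement
from brewtrace.core_io.variants import VariantTable
from brewtrace.errors import BrewtraceError

log = logging.getLogger(__name__)


def project_genotypes(
    reference: GenomeModel, vt: VariantTable, strain: str
) -> list[str]:
    """Transfer a strain's genotypes onto copies of the reference sequence.

    Returns ``ploidy`` haplotype strings: alternate alleles are substituted at
    called SNP sites (alleles assigned to haplotype copies in sorted order —
    phase is irrelevant downstream), MISSING genotypes become ``N``. Sites with
    alleles longer than 1 bp are skipped with a warning (SNP-only contract).
    """
    if strain not in vt.genotypes:
        raise BrewtraceError(f"strain {strain!r} not in variant table")
    p = vt.strain_ploidy[strain]
    haplotypes = {name: [list(reference.sequence(name)) for _ in range(p)]
                  for name in reference.chrom_names}
    gts = vt.genotypes[strain]
    missing = vt.is_missing(strain)
    for i in range(vt.n_sites):
        site = vt.sites.iloc[i]
        chrom, pos = site["chrom"], int(site["pos"])
        if chrom not in haplotypes:
            continue
        alleles = [site["ref"]] + [a for a in str(site["alt"]).split(",") if a != "."]
        if any(len(a) != 1 for a in alleles):
            log.warning("skipping non-SNP site %s:%d (allele > 1 bp)", chrom, pos + 1)
            continue
        if missing[i]:
            for copy in haplotypes[chrom]:
                copy[pos] = "N"
        else:
            for k, allele_idx in enumerate(sorted(gts[i])):
                if allele_idx >= 1:  # allele 0 keeps the reference base
                    haplotypes[chrom][k][pos] = alleles[allele_idx]
    return [
        "".join("".join(haplotypes[name][k]) for name in reference.chrom_names)
        for k in range(p)
    ]


@dataclass(frozen=True)
class _CdsBlock:
    offset: int
    chrom: str
    start: int
    end: int
    strand: str


class CdsMap:
    """Invertible map between concatenated-CDS and genome coordinates."""

    def __init__(self, blocks: list[_CdsBlock]):
        self.blocks = blocks
        self.length = sum(b.end - b.start for b in blocks)

    def to_genome(self, i: int) -> tuple[str, int]:
        if not 0 <= i < self.length:
            raise BrewtraceError(f"concatenated coordinate {i} out of range")
        for b in self.blocks:
            if b.offset <= i < b.offset + (b.end - b.start):
                off = i - b.offset
                if b.strand == "+":
                    return b.chrom, b.start + off
                return b.chrom, b.end - 1 - off
        raise AssertionError("unreachable")

    def to_concat(self, chrom: str, pos: int) -> int:
        for b in self.blocks:
            if b.chrom == chrom and b.start <= pos < b.end:
                if b.strand == "+":
                    return b.offset + (pos - b.start)
                return b.offset + (b.end - 1 - pos)
        raise BrewtraceError(f"{chrom}:{pos} lies in no CDS block")


def concatenate_cds(genome: GenomeModel, features: IntervalSet) -> tuple[str, CdsMap]:
    """Concatenate CDS intervals in genomic order; minus strands are
    reverse-complemented. Overlapping records are rejected."""
    recs = features.sorted().records
    offenders = []
    for a, b in zip(recs, recs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            offenders.append((a, b))
    if offenders:
        desc = "; ".join(
            f"{a.chrom}:{a.start}-{a.end} overlaps {b.chrom}:{b.start}-{b.end}"
            for a, b in offenders
        )
        raise BrewtraceError(f"overlapping CDS records: {desc}")

    parts, blocks, offset = [], [], 0
    for r in recs:
        seq = genome.sequence(r.chrom)[r.start : r.end]
        strand = r.label if r.label in ("+", "-") else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        parts.append(seq)
        blocks.append(_CdsBlock(offset, r.chrom, r.start, r.end, strand))
        offset += len(seq)
    return "".join(parts), CdsMap(blocks)
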