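"""Polyploid variant tables and VCF round-tripping.

Genotypes are stored per strain as an ``(n_sites, ploidy)`` integer array of
allele indices; a fully ``-1`` row encodes a MISSING genotype. Positions are
0-based internally and converted to/from 1-based VCF at the boundary.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from brewtrace.errors import FormatError, PloidyConflictError

MISSING = -1

#: INFO keys probed when reading a VCF (all Number=1 floats except SYN, a flag).
SITE_ANNOTATION_KEYS = ("QD", "MQ", "MQRankSum", "ReadPosRankSum", "FS", "SOR")
GENOTYPE_ANNOTATION_KEYS = ("GQ", "RGQ", "DP")


class VariantTable:
    """Sites × strains polyploid genotype matrix with annotations."""

    def __init__(
        self,
        sites: pd.DataFrame,
        genotypes: dict[str, np.ndarray],
        strain_ploidy: dict[str, int],
        site_annotations: Optional[pd.DataFrame] = None,
        genotype_annotations: Optional[dict[str, pd.DataFrame]] = None,
    ):
        self.sites = sites.reset_index(drop=True)
        self.genotypes = {s: np.asarray(g, dtype=np.int16) for s, g in genotypes.items()}
        self.strain_ploidy = dict(strain_ploidy)
        n = len(self.sites)
        for strain, g in self.genotypes.items():
            p = self.strain_ploidy[strain]
            if g.shape != (n, p):
                raise FormatError(
                    f"genotype array for {strain!r} has shape {g.shape}, "
                    f"expected ({n}, {p})"
                )
        self.site_annotations = (
            site_annotations.reset_index(drop=True)
            if site_annotations is not None
            else pd.DataFrame(index=range(n))
        )
        self.genotype_annotations = genotype_annotations or {}

    # -- basic accessors ----------------------------------------------------

    @property
    def strains(self) -> list[str]:
        return list(self.genotypes)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def is_missing(self, strain: str) -> np.ndarray:
        return (self.genotypes[strain] == MISSING).all(axis=1)

    def dosage(self, strain: str) -> np.ndarray:
        """Alternate-allele count per site (float, NaN where MISSING)."""
        g = self.genotypes[strain]
        d = (g >= 1).sum(axis=1).astype(float)
        d[self.is_missing(strain)] = np.nan
        return d

    def carries(self, strain: str) -> np.ndarray:
        """True where the strain has ≥1 alternate allele (False if MISSING)."""
        return np.nan_to_num(self.dosage(strain)) >= 1

    # -- transforms ---------------------------------------------------------

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            self.sites.loc[mask],
            {s: g[mask] for s, g in self.genotypes.items()},
            self.strain_ploidy,
            self.site_annotations.loc[mask],
            {s: a.loc[mask].reset_index(drop=True) for s, a in self.genotype_annotations.items()},
        )

    def subset_strains(self, strains: Iterable[str]) -> "VariantTable":
        strains = list(strains)
        return VariantTable(
            self.sites,
            {s: self.genotypes[s] for s in strains},
            {s: self.strain_ploidy[s] for s in strains},
            self.site_annotations,
            {s: self.genotype_annotations[s] for s in strains if s in self.genotype_annotations},
        )

    def biallelic_snp_mask(self) -> np.ndarray:
        return (~self.sites["is_indel"] & ~self.sites["is_multiallelic"]).to_numpy()

    def equals(self, other: "VariantTable", tol: float = 1e-5) -> bool:
        if self.strains != other.strains or self.strain_ploidy != other.strain_ploidy:
            return False
        base = ["chrom", "pos", "ref", "alt", "is_indel", "is_multiallelic"]
        if not self.sites[base].equals(other.sites[base]):
            return False
        for s in self.strains:
            if not np.array_equal(self.genotypes[s], other.genotypes[s]):
                return False
        for col in self.site_annotations.columns:
            if col not in other.site_annotations.columns:
                return False
            a = self.site_annotations[col].to_numpy(dtype=float)
            b = other.site_annotations[col].to_numpy(dtype=float)
            if not np.allclose(a, b, atol=tol, equal_nan=True):
                return False
        return True


# ---------------------------------------------------------------------------
# VCF reading


def read_variant_table(path: Union[str, Path]) -> VariantTable:
    """Parse a VCF 4.x file into a :class:`VariantTable`.

    Ploidy is inferred per strain from GT arity; mixed arities raise
    :class:`PloidyConflictError`. Multiallelic sites and indels are retained
    but flagged so downstream statistics can exclude them.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"VCF {path} has no sample columns")

    rows, ann_rows = [], []
    raw_gts: dict[str, list] = {s: [] for s in samples}
    raw_fmt: dict[str, dict[str, list]] = {
        s: {k: [] for k in GENOTYPE_ANNOTATION_KEYS} for s in samples
    }
    ploidy: dict[str, Optional[int]] = {s: None for s in samples}

    for v in vcf:
        alts = [a for a in v.ALT if a != "<NON_REF>"]
        is_indel = len(v.REF) != 1 or any(len(a) != 1 for a in alts)
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.start,
                "ref": v.REF,
                "alt": ",".join(alts) if alts else ".",
                "is_indel": bool(is_indel),
                "is_multiallelic": len(alts) > 1,
            }
        )
        ann = {k: _info_float(v, k) for k in SITE_ANNOTATION_KEYS}
        ann["SYN"] = float(v.INFO.get("SYN") is not None)
        ann_rows.append(ann)

        fmt = {k: _format_column(v, k, len(samples)) for k in GENOTYPE_ANNOTATION_KEYS}
        for i, s in enumerate(samples):
            alleles = v.genotypes[i][:-1]
            if any(a < 0 for a in alleles):
                raw_gts[s].append(None)
            else:
                if ploidy[s] is None:
                    ploidy[s] = len(alleles)
                elif ploidy[s] != len(alleles):
                    raise PloidyConflictError(s, v.CHROM, v.start, len(alleles), ploidy[s])
                raw_gts[s].append(tuple(alleles))
            for k in GENOTYPE_ANNOTATION_KEYS:
                raw_fmt[s][k].append(fmt[k][i])

    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "is_indel", "is_multiallelic"]
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    annotations = pd.DataFrame(ann_rows)

    genotypes, gt_ann = {}, {}
    for s in samples:
        p = ploidy[s] if ploidy[s] is not None else 2
        arr = np.full((len(sites), p), MISSING, dtype=np.int16)
        for i, gt in enumerate(raw_gts[s]):
            if gt is not None:
                arr[i] = gt
        genotypes[s] = arr[order]
        gt_ann[s] = pd.DataFrame(raw_fmt[s]).iloc[order].reset_index(drop=True)

    return VariantTable(
        sites.iloc[order],
        genotypes,
        {s: (ploidy[s] if ploidy[s] is not None else 2) for s in samples},
        annotations.iloc[order],
        gt_ann,
    )


def _info_float(variant, key: str) -> float:
    val = variant.INFO.get(key)
    if val is None:
        return math.nan
    try:
        return float(val)
    except (TypeError, ValueError):
        return math.nan


def _format_column(variant, key: str, n_samples: int) -> list[float]:
    try:
        arr = variant.format(key)
    except KeyError:
        arr = None
    if arr is None:
        return [math.nan] * n_samples
    out = []
    for row in np.asarray(arr, dtype=float):
        x = float(np.asarray(row).ravel()[0])
        out.append(math.nan if x < 0 or not math.isfinite(x) else x)
    return out


# ---------------------------------------------------------------------------
# VCF writing


def write_variant_table(vt: VariantTable, path: Union[str, Path]) -> None:
    """Write a plain-text VCF 4.2 file (no compression, no index)."""
    ann_cols = [c for c in vt.site_annotations.columns if c != "SYN"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=brewtrace\n")
        for chrom in dict.fromkeys(vt.sites["chrom"]):
            length = int(vt.sites.loc[vt.sites["chrom"] == chrom, "pos"].max()) + 2
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for key in ann_cols:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##INFO=<ID=SYN,Number=0,Type=Flag,Description="Synonymous site">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for key in GENOTYPE_ANNOTATION_KEYS:
            typ = "Integer" if key == "DP" else "Integer"
            fh.write(f'##FORMAT=<ID={key},Number=1,Type={typ},Description="{key}">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.strains)
            + "\n"
        )
        has_syn = "SYN" in vt.site_annotations.columns
        for i in range(vt.n_sites):
            site = vt.sites.iloc[i]
            info_parts = []
            for key in ann_cols:
                val = vt.site_annotations[key].iloc[i]
                if isinstance(val, float) and math.isnan(val):
                    continue
                info_parts.append(f"{key}={float(val):.6g}")
            if has_syn and vt.site_annotations["SYN"].iloc[i]:
                info_parts.append("SYN")
            cols = [
                site["chrom"],
                str(int(site["pos"]) + 1),
                ".",
                site["ref"],
                site["alt"],
                ".",
                ".",
                ";".join(info_parts) if info_parts else ".",
                "GT:GQ:RGQ:DP",
            ]
            for s in vt.strains:
                gt = vt.genotypes[s][i]
                if (gt == MISSING).all():
                    gt_str = "/".join(["."] * vt.strain_ploidy[s])
                else:
                    gt_str = "/".join(str(int(a)) for a in gt)
                fields = [gt_str]
                ann = vt.genotype_annotations.get(s)
                for key in GENOTYPE_ANNOTATION_KEYS:
                    if ann is not None and key in ann.columns:
                        val = ann[key].iloc[i]
                        fields.append("." if math.isnan(float(val)) else str(int(val)))
                    else:
                        fields.append(".")
                cols.append(":".join(fields))
            fh.write("\t".join(cols) + "\n")
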