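"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from brewtrace.core_io.variants import MISSING, VariantTable


def make_variant_table(
    genotypes: dict[str, list],
    ploidy: dict[str, int] | int = 4,
    chrom: str = "chrI",
    site_annotations: pd.DataFrame | None = None,
    genotype_annotations: dict[str, pd.DataFrame] | None = None,
    positions: list[int] | None = None,
    syn: bool | list | None = None,
) -> VariantTable:
    """Build a biallelic-SNP table from per-strain genotype tuples.

    Each genotype is a tuple of allele indices or None for MISSING.
    """
    strains = list(genotypes)
    n = len(genotypes[strains[0]])
    if isinstance(ploidy, int):
        ploidy = {s: ploidy for s in strains}
    arrays = {}
    for s in strains:
        arr = np.full((n, ploidy[s]), MISSING, dtype=np.int16)
        for i, gt in enumerate(genotypes[s]):
            if gt is not None:
                arr[i] = gt
        arrays[s] = arr
    alt = []
    for i in range(n):
        seg = any(
            genotypes[s][i] is not None and any(a >= 1 for a in genotypes[s][i])
            for s in strains
        )
        alt.append("T" if seg else ".")
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions if positions is not None else list(range(n)),
            "ref": "A",
            "alt": alt,
            "is_indel": False,
            "is_multiallelic": False,
        }
    )
    if syn is not None:
        flags = [float(syn)] * n if isinstance(syn, bool) else [float(x) for x in syn]
        syn_frame = pd.DataFrame({"SYN": flags})
        site_annotations = (
            syn_frame
            if site_annotations is None
            else pd.concat([site_annotations.reset_index(drop=True), syn_frame], axis=1)
        )
    return VariantTable(sites, arrays, ploidy, site_annotations, genotype_annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
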