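"""Small construction helpers shared across test modules."""

import numpy as np
import pandas as pd

from galdiv import GenotypeDataset


def build_ds(calls, chrom=None, pos=None, breeds=None, ids=None, alleles=None):
    """Hand-build a GenotypeDataset from a genotype code matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if ids is None:
        ids = [f"S{i}" for i in range(n)]
    if breeds is None:
        breeds = ["BRD"] * n
    if alleles is None:
        alleles = [("A", "C")] * m
    samples = pd.DataFrame({"id": ids, "breed": breeds, "sex": "unknown"})
    markers = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(m)],
            "chrom": np.asarray(chrom, dtype=int),
            "pos": np.asarray(pos, dtype=int),
            "allele_a": [a for a, _ in alleles],
            "allele_b": [b for _, b in alleles],
        }
    )
    return GenotypeDataset(samples, markers, calls)


def marker_index(markers: pd.DataFrame, chrom: int, bp: int) -> int:
    """Index of the marker at (chrom, bp) within its chromosome."""
    cpos = markers.loc[markers["chrom"] == chrom, "pos"].to_numpy()
    return int(np.searchsorted(cpos, bp))
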