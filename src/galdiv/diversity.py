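"""Per-breed genetic diversity indices.

For each breed the module reports the classic array-survey panel: mean and
SD of the minor allele frequency (MAF), observed and Hardy-Weinberg expected
heterozygosity (Ho, He = 2pq), and the excess-homozygosity inbreeding
coefficient F_HOM computed per individual as

    F_i = (O_i - E_i) / (L_i - E_i)

where O_i is the observed homozygote count over the individual's L_i
non-missing markers and E_i = sum_j [1 - 2 p_j (1 - p_j) c_j] is the count
expected under Hardy-Weinberg, with the small-sample correction
c_j = 2 n_j / (2 n_j - 1) (n_j = non-missing individuals at marker j in the
frequency cohort).  F_HOM is negative when a cohort carries an excess of
heterozygotes, as commercial layer/broiler stocks typically do.

MAF/Ho/He statistics are taken across markers; F_HOM statistics across
individuals (population SDs, ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GaldivError
from .io import MISSING, GenotypeDataset
from .qc import allele_frequencies


@dataclass
class BreedDiversityRecord:
    breed: str
    n: int
    maf_mean: float
    maf_sd: float
    ho_mean: float
    ho_sd: float
    he_mean: float
    he_sd: float
    fhom_mean: float
    fhom_sd: float


def _within_breed_freqs(ds: GenotypeDataset, breed: str) -> np.ndarray:
    return allele_frequencies(ds, group=breed)


def breed_maf_summary(ds: GenotypeDataset, breed: str) -> tuple[float, float]:
    """Mean and population SD of within-breed MAF over defined markers."""
    p = _within_breed_freqs(ds, breed)
    maf = np.minimum(p, 1.0 - p)
    maf = maf[~np.isnan(maf)]
    return float(maf.mean()), float(maf.std())


def heterozygosity(ds: GenotypeDataset, breed: str) -> tuple[float, float, float, float]:
    """(Ho mean, Ho sd, He mean, He sd) across defined markers of one breed."""
    mask = ds.breed_mask(breed)
    if mask.sum() < 2:
        raise GaldivError(f"breed {breed!r} needs at least 2 samples")
    calls = ds.calls[mask]
    valid = calls != MISSING
    n = valid.sum(axis=0)
    defined = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = (calls == 1).sum(axis=0) / n
    p = _within_breed_freqs(ds, breed)
    he = 2.0 * p * (1.0 - p)
    ho, he = ho[defined], he[defined]
    return (
        float(ho.mean()),
        float(ho.std()),
        float(he.mean()),
        float(he.std()),
    )


def f_hom(
    ds: GenotypeDataset,
    breed: str | None = None,
    freq_scope: str = "within_breed",
    correction: bool = True,
) -> tuple[pd.Series, float, float]:
    """Per-individual excess-homozygosity F plus its (mean, sd) over the cohort.

    ``freq_scope`` chooses the allele-frequency cohort for the expectation:
    ``"within_breed"`` (default; the only scope under which commercial-stock
    F_HOM can go negative alongside Ho > He) or ``"global"``.
    ``correction`` applies the 2n/(2n-1) small-sample factor, matching the
    convention of the standard genotype-analysis tools.

    Individuals where L_i == E_i (degenerate denominator) get NaN.
    """
    if freq_scope not in ("within_breed", "global"):
        raise GaldivError(f"freq_scope must be within_breed or global, got {freq_scope!r}")
    if breed is None:
        mask = np.ones(ds.n_samples, dtype=bool)
        scope_group = None
    else:
        mask = ds.breed_mask(breed)
        scope_group = breed if freq_scope == "within_breed" else None

    scope_calls = ds.calls if scope_group is None else ds.calls[ds.breed_mask(scope_group)]
    if scope_calls.shape[0] < 2:
        raise GaldivError("frequency cohort needs at least 2 samples")
    n_j = (scope_calls != MISSING).sum(axis=0)
    p = allele_frequencies(ds, group=scope_group)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 2.0 * n_j / (2.0 * n_j - 1.0) if correction else np.ones_like(p)
    e_j = 1.0 - 2.0 * p * (1.0 - p) * c
    defined = ~np.isnan(e_j)

    calls = ds.calls[mask][:, defined]
    e_j = e_j[defined]
    valid = calls != MISSING
    L = valid.sum(axis=1).astype(float)
    O = (valid & (calls != 1)).sum(axis=1).astype(float)
    E = valid @ e_j
    denom = L - E
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(np.abs(denom) > 1e-12, (O - E) / denom, np.nan)
    series = pd.Series(F, index=ds.samples["id"][mask].to_numpy(), name="f_hom")
    finite = series.dropna()
    return series, float(finite.mean()), float(finite.std())


def diversity_table(
    ds: GenotypeDataset,
    freq_scope: str = "within_breed",
    correction: bool = True,
) -> pd.DataFrame:
    """One row per breed with the full diversity panel (survey-table shape)."""
    rows = []
    for breed in ds.breeds:
        maf_mean, maf_sd = breed_maf_summary(ds, breed)
        ho_mean, ho_sd, he_mean, he_sd = heterozygosity(ds, breed)
        _, f_mean, f_sd = f_hom(ds, breed, freq_scope=freq_scope, correction=correction)
        rows.append(
            BreedDiversityRecord(
                breed=breed,
                n=int(ds.breed_mask(breed).sum()),
                maf_mean=maf_mean,
                maf_sd=maf_sd,
                ho_mean=ho_mean,
                ho_sd=ho_sd,
                he_mean=he_mean,
                he_sd=he_sd,
                fhom_mean=f_mean,
                fhom_sd=f_sd,
            ).__dict__
        )
    return pd.DataFrame(rows)
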