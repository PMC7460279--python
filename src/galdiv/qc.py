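"""SNP-array quality control.

Three filters, applied in a fixed order so the marker statistics reflect the
analyzed cohort:

1. samples with more than ``max_sample_missing`` missing genotypes removed;
2. markers with call rate below ``min_call_rate`` (on surviving samples)
   removed;
3. markers with minor allele frequency below ``min_maf`` (pooled over the
   surviving samples) removed.

All inequalities are strict, so items exactly at a threshold are kept.
Defaults (95% call rate, 5% MAF, 10% sample missingness) are the standard
array-QC settings for this kind of breed survey.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import GaldivError, QCError
from .io import MISSING, GenotypeDataset, subset


@dataclass
class QCReport:
    """Accounting of one :func:`apply_qc` run, serializable to text/JSON."""

    n_samples_in: int
    n_samples_out: int
    n_markers_in: int
    n_markers_out: int
    removed_samples: list[str] = field(default_factory=list)
    removed_markers_callrate: list[str] = field(default_factory=list)
    removed_markers_maf: list[str] = field(default_factory=list)
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    max_sample_missing: float = 0.10
    filter_order: tuple[str, ...] = (
        "sample_missingness",
        "marker_call_rate",
        "marker_maf",
    )

    def to_text(self) -> str:
        lines = [
            "QC report",
            f"  filter order: {' -> '.join(self.filter_order)}",
            f"  thresholds: call rate >= {self.min_call_rate}, "
            f"MAF >= {self.min_maf}, "
            f"sample missingness <= {self.max_sample_missing}",
            f"  samples: {self.n_samples_in} -> {self.n_samples_out} "
            f"({len(self.removed_samples)} removed)",
            f"  markers: {self.n_markers_in} -> {self.n_markers_out} "
            f"({len(self.removed_markers_callrate)} call rate, "
            f"{len(self.removed_markers_maf)} MAF)",
        ]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=list)


def snp_call_rate(ds: GenotypeDataset) -> np.ndarray:
    """Per-marker fraction of non-missing calls, in [0, 1]."""
    if ds.n_samples < 1:
        raise GaldivError("call rate needs at least one sample")
    return (ds.calls != MISSING).mean(axis=0)


def sample_missingness(ds: GenotypeDataset) -> np.ndarray:
    """Per-sample fraction of missing calls, in [0, 1]."""
    if ds.n_markers < 1:
        raise GaldivError("missingness needs at least one marker")
    return (ds.calls == MISSING).mean(axis=1)


def allele_frequencies(ds: GenotypeDataset, group: str | None = None) -> np.ndarray:
    """Per-marker frequency of allele B; NaN where no call is defined.

    ``group`` restricts the tally to one breed.
    """
    calls = ds.calls[ds.breed_mask(group)] if group is not None else ds.calls
    valid = calls != MISSING
    n = valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / (2.0 * n), np.nan)


def minor_allele_frequencies(ds: GenotypeDataset, group: str | None = None) -> np.ndarray:
    p = allele_frequencies(ds, group)
    return np.minimum(p, 1.0 - p)


def apply_qc(
    ds: GenotypeDataset,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    max_sample_missing: float = 0.10,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the three filters in order; raise :class:`QCError` if nothing survives."""
    for name, value in (
        ("min_call_rate", min_call_rate),
        ("min_maf", min_maf),
        ("max_sample_missing", max_sample_missing),
    ):
        if not 0.0 <= value <= 1.0:
            raise GaldivError(f"{name} must lie in [0, 1], got {value}")

    report = QCReport(
        n_samples_in=ds.n_samples,
        n_samples_out=ds.n_samples,
        n_markers_in=ds.n_markers,
        n_markers_out=ds.n_markers,
        min_call_rate=min_call_rate,
        min_maf=min_maf,
        max_sample_missing=max_sample_missing,
    )

    # 1. sample missingness (strict >)
    missing = sample_missingness(ds)
    drop = missing > max_sample_missing
    report.removed_samples = ds.samples["id"][drop].tolist()
    keep_ids = ds.samples["id"][~drop].tolist()
    if not keep_ids:
        raise QCError("empty after QC: all samples removed")
    ds = subset(ds, sample_ids=keep_ids)

    # 2. marker call rate on the surviving samples (strict <)
    rate = snp_call_rate(ds)
    drop = rate < min_call_rate
    report.removed_markers_callrate = ds.markers["id"][drop].tolist()
    keep = ds.markers["id"][~drop].tolist()
    if not keep:
        raise QCError("empty after QC: all markers removed by call rate")
    ds = subset(ds, marker_ids=keep)

    # 3. MAF pooled over the surviving samples (strict <); markers whose
    # frequency is undefined (no calls) are left for the call-rate filter.
    maf = minor_allele_frequencies(ds)
    with np.errstate(invalid="ignore"):
        drop = maf < min_maf
    drop &= ~np.isnan(maf)
    report.removed_markers_maf = ds.markers["id"][drop].tolist()
    keep = ds.markers["id"][~drop].tolist()
    if not keep:
        raise QCError("empty after QC: all markers removed by MAF")
    ds = subset(ds, marker_ids=keep)

    report.n_samples_out = ds.n_samples
    report.n_markers_out = ds.n_markers
    return ds, report
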