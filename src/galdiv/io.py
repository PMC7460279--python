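"""Genotype input/output and the central dataset container.

Genotypes are diploid biallelic SNP calls stored as a dense
``samples x markers`` matrix of small integers:

* ``0`` — homozygous for allele A (the first allele observed in the file),
* ``1`` — heterozygous,
* ``2`` — homozygous for allele B,
* ``MISSING`` (``-1``) — no call.

Two text formats are supported: whitespace-delimited PED/MAP (the de-facto
SNP-array interchange format, six leading PED columns with the family column
carrying the breed label) and a simple TSV genotype table (header of marker
ids; one row per sample: id, breed, codes 0/1/2/NA).

Markers are always kept sorted by (chromosome, position); chromosomes are
restricted to the chicken autosomes 1..28 that the analysis targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GaldivError, ParseError

MISSING = -1

#: Allele symbols accepted in PED files (ACGT or the numeric 0/1/2 coding;
#: "0" means missing).
VALID_ALLELES = frozenset("ACGT012")

MIN_CHROM = 1
MAX_CHROM = 28

SAMPLE_COLUMNS = ["id", "breed", "sex"]
MARKER_COLUMNS = ["id", "chrom", "pos", "allele_a", "allele_b"]


@dataclass
class GenotypeDataset:
    """Sample x marker diploid genotype matrix with breed labels and a map.

    Attributes
    ----------
    samples : pandas.DataFrame
        Columns ``id`` (unique), ``breed``, ``sex`` ("M"/"F"/"unknown").
    markers : pandas.DataFrame
        Columns ``id`` (unique), ``chrom`` (int, 1..28), ``pos`` (int bp,
        1-based, strictly increasing within chromosome), ``allele_a``,
        ``allele_b`` (single characters; ``"0"`` placeholder for the unseen
        allele of a monomorphic marker).
    calls : numpy.ndarray
        ``int8`` matrix of shape (n_samples, n_markers) with entries in
        {0, 1, 2, MISSING}.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise GaldivError(
                f"calls matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.samples["id"].duplicated().any():
            dupes = self.samples["id"][self.samples["id"].duplicated()].tolist()
            raise GaldivError(f"duplicate sample ids: {dupes}")
        if self.markers["id"].duplicated().any():
            dupes = self.markers["id"][self.markers["id"].duplicated()].tolist()
            raise GaldivError(f"duplicate marker ids: {dupes}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GaldivError("genotype codes must be in {0, 1, 2, MISSING}")
        chrom = self.markers["chrom"].to_numpy()
        if len(chrom) and ((chrom < MIN_CHROM) | (chrom > MAX_CHROM)).any():
            raise GaldivError(
                f"chromosomes must lie in {MIN_CHROM}..{MAX_CHROM}"
            )
        pos = self.markers["pos"].to_numpy()
        if len(chrom) > 1:
            same = chrom[1:] == chrom[:-1]
            if (chrom[1:] < chrom[:-1]).any():
                raise GaldivError("markers not sorted by chromosome")
            if (pos[1:][same] <= pos[:-1][same]).any():
                raise GaldivError(
                    "positions must be strictly increasing within chromosome"
                )

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["breed"]))

    def breed_mask(self, breed: str) -> np.ndarray:
        mask = (self.samples["breed"] == breed).to_numpy()
        if not mask.any():
            raise GaldivError(f"unknown breed: {breed!r}")
        return mask

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.samples.copy(), self.markers.copy(), self.calls.copy()
        )


def _sort_markers(markers: pd.DataFrame, calls: np.ndarray):
    order = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].to_numpy()))
    return markers.iloc[order].reset_index(drop=True), calls[:, order]


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

_SEX_IN = {"1": "M", "2": "F"}
_SEX_OUT = {"M": "1", "F": "2"}


def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Read a whitespace-delimited PED/MAP pair.

    The PED family column is taken as the breed label.  Allele A of each
    marker is the first allele observed scanning samples in file order, so
    the 0/1/2 coding is deterministic.  "0 0" genotypes and half-calls (one
    allele missing) become MISSING; half-calls additionally emit a warning.
    Markers are re-sorted by (chromosome, position) with the calls matrix
    permuted accordingly.
    """
    markers = _read_map(map_path)
    n_markers = len(markers)

    fam, ids, sexes, rows = [], [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected "
                    f"{6 + 2 * n_markers} fields, got {len(fields)}"
                )
            fam.append(fields[0])
            ids.append(fields[1])
            sexes.append(_SEX_IN.get(fields[4], "unknown"))
            rows.append(fields[6:])
    if not rows:
        raise ParseError(f"{ped_path}: no samples")

    tokens = np.array(rows, dtype="U1")  # (n_samples, 2 * n_markers)
    bad = ~np.isin(tokens, list(VALID_ALLELES))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{ped_path}: line {i + 1}: invalid allele symbol "
            f"{tokens[i, j]!r} (allowed: A C G T 0 1 2)"
        )

    n_samples = len(ids)
    calls = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    allele_a = np.empty(n_markers, dtype="U1")
    allele_b = np.empty(n_markers, dtype="U1")
    half_calls = 0
    for j in range(n_markers):
        a1 = tokens[:, 2 * j]
        a2 = tokens[:, 2 * j + 1]
        miss1 = a1 == "0"
        miss2 = a2 == "0"
        half_calls += int((miss1 ^ miss2).sum())
        missing = miss1 | miss2
        # interleave so "first observed" follows within-row allele order
        inter = np.empty(2 * n_samples, dtype="U1")
        inter[0::2] = np.where(missing, "0", a1)
        inter[1::2] = np.where(missing, "0", a2)
        observed = inter[inter != "0"]
        if observed.size == 0:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        a = observed[0]
        others = observed[observed != a]
        if others.size:
            b = others[0]
            if (others != b).any():
                extra = sorted(set(others) - {b})
                raise ParseError(
                    f"{ped_path}: marker {markers['id'].iloc[j]!r} has more "
                    f"than two alleles: {sorted({a, b} | set(extra))}"
                )
        else:
            b = "0"  # monomorphic: PED cannot name the unobserved allele
        allele_a[j], allele_b[j] = a, b
        code = (a1 != a).astype(np.int8) + (a2 != a).astype(np.int8)
        calls[:, j] = np.where(missing, MISSING, code)
    if half_calls:
        warnings.warn(
            f"{half_calls} half-called genotype(s) treated as missing",
            stacklevel=2,
        )

    markers["allele_a"] = allele_a
    markers["allele_b"] = allele_b
    samples = pd.DataFrame({"id": ids, "breed": fam, "sex": sexes})
    markers, calls = _sort_markers(markers, calls)
    return GenotypeDataset(samples, markers[MARKER_COLUMNS], calls)


def _read_map(map_path) -> pd.DataFrame:
    recs = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ParseError(
                    f"{map_path}: line {lineno}: expected 4 columns, "
                    f"got {len(fields)}"
                )
            chrom_s, marker_id, _cm, pos_s = fields
            try:
                chrom = int(chrom_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(
                    f"{map_path}: line {lineno}: non-integer chromosome "
                    f"or position"
                ) from exc
            recs.append((marker_id, chrom, pos))
    if not recs:
        raise ParseError(f"{map_path}: no markers")
    markers = pd.DataFrame(recs, columns=["id", "chrom", "pos"])
    if markers["id"].duplicated().any():
        dupes = markers["id"][markers["id"].duplicated()].tolist()
        raise ParseError(f"{map_path}: duplicate marker id(s): {dupes}")
    return markers


def write_ped_map(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write PED/MAP with Unix line endings (inverse of :func:`read_ped_map`)."""
    with open(map_path, "w", newline="\n") as fh:
        for rec in ds.markers.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\n")

    a = ds.markers["allele_a"].to_numpy(dtype="U1")
    b = ds.markers["allele_b"].to_numpy(dtype="U1")
    if ((b == "0") & np.isin(ds.calls, (1, 2)).any(axis=0)).any():
        raise GaldivError(
            "cannot write PED: allele B unnamed for a marker with "
            "het or alt-homozygous calls"
        )
    with open(ped_path, "w", newline="\n") as fh:
        for i, srec in enumerate(ds.samples.itertuples(index=False)):
            g = ds.calls[i]
            a1 = np.choose(
                np.where(g == MISSING, 3, g), [a, a, b, np.full_like(a, "0")]
            )
            a2 = np.choose(
                np.where(g == MISSING, 3, g), [a, b, b, np.full_like(a, "0")]
            )
            geno = " ".join(x + " " + y for x, y in zip(a1, a2))
            sex = _SEX_OUT.get(srec.sex, "0")
            fh.write(f"{srec.breed} {srec.id} 0 0 {sex} -9 {geno}\n")


# ---------------------------------------------------------------------------
# Genotype-table TSV
# ---------------------------------------------------------------------------


def read_genotype_table(path, markers: pd.DataFrame | None = None) -> GenotypeDataset:
    """Read the TSV genotype-table dialect.

    Header: ``sample_id<TAB>breed<TAB><marker ids...>``; one row per sample
    with codes 0/1/2/NA.  The table carries no marker map, so a placeholder
    map (chromosome 1, positions 1..m, alleles "1"/"2") is synthesized
    unless ``markers`` supplies one with matching ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: header must list sample_id, breed, markers")
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no samples")
    marker_ids = list(df.columns[2:])
    codes = df.iloc[:, 2:].to_numpy(dtype=object)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    calls = np.empty(codes.shape, dtype=np.int8)
    for (i, j), val in np.ndenumerate(codes):
        if val not in valid:
            raise ParseError(
                f"{path}: row {i + 2}, column {marker_ids[j]!r}: "
                f"invalid code {val!r} (allowed: 0 1 2 NA)"
            )
        calls[i, j] = valid[val]
    samples = pd.DataFrame(
        {"id": df.iloc[:, 0], "breed": df.iloc[:, 1], "sex": "unknown"}
    )
    if markers is None:
        markers = pd.DataFrame(
            {
                "id": marker_ids,
                "chrom": 1,
                "pos": np.arange(1, len(marker_ids) + 1),
                "allele_a": "1",
                "allele_b": "2",
            }
        )
    else:
        if list(markers["id"]) != marker_ids:
            raise GaldivError("supplied marker map does not match table header")
        markers = markers.copy()
    markers, calls = _sort_markers(markers, calls)
    return GenotypeDataset(samples, markers[MARKER_COLUMNS], calls)


def write_genotype_table(ds: GenotypeDataset, path) -> None:
    """Write the TSV genotype table (bit-exact round-trip of the calls)."""
    code = np.empty(ds.calls.shape, dtype="U2")
    for val, txt in ((0, "0"), (1, "1"), (2, "2"), (MISSING, "NA")):
        code[ds.calls == val] = txt
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\tbreed\t" + "\t".join(ds.markers["id"]) + "\n")
        for i, srec in enumerate(ds.samples.itertuples(index=False)):
            fh.write(f"{srec.id}\t{srec.breed}\t" + "\t".join(code[i]) + "\n")


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------


def subset(
    ds: GenotypeDataset,
    sample_ids=None,
    marker_ids=None,
    allow_empty: bool = False,
) -> GenotypeDataset:
    """Restrict a dataset to the given sample and/or marker ids.

    Dataset order is preserved (the id lists act as filters, not orderings).
    Unknown ids raise, listing the offenders; an empty marker selection
    raises unless ``allow_empty``.
    """
    samples, markers, calls = ds.samples, ds.markers, ds.calls
    if sample_ids is not None:
        wanted = set(sample_ids)
        unknown = wanted - set(samples["id"])
        if unknown:
            raise GaldivError(f"unknown sample id(s): {sorted(unknown)}")
        keep = samples["id"].isin(wanted).to_numpy()
        samples = samples[keep]
        calls = calls[keep, :]
    if marker_ids is not None:
        wanted = set(marker_ids)
        unknown = wanted - set(markers["id"])
        if unknown:
            raise GaldivError(f"unknown marker id(s): {sorted(unknown)}")
        keep = markers["id"].isin(wanted).to_numpy()
        markers = markers[keep]
        calls = calls[:, keep]
    if len(markers) == 0 and not allow_empty:
        raise GaldivError("subset would retain 0 markers (pass allow_empty=True)")
    if len(samples) == 0 and not allow_empty:
        raise GaldivError("subset would retain 0 samples (pass allow_empty=True)")
    return GenotypeDataset(
        samples.reset_index(drop=True), markers.reset_index(drop=True), calls
    )
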