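"""Runs-of-homozygosity detection, F_ROH and per-breed summaries.

A run of homozygosity (ROH) is a chromosomal stretch of (near-)exclusively
homozygous genotypes, the footprint of autozygosity.  Five constraints
define a valid run, with defaults matching standard 600K-array practice:

* at least ``min_snps`` SNPs (100) and ``min_length_kb`` kb (1000),
* at most ``max_het`` heterozygous (1) and ``max_missing`` missing (2) calls,
* average density of at least one SNP per ``min_density_kb_per_snp`` kb (100),
* no gap between consecutive SNPs above ``max_gap_kb`` kb (1000).

Two calling modes are provided.  ``segment`` mode (default) is the exact,
testable semantics: candidate runs are the maximal index ranges satisfying
all five constraints; overlapping candidates are resolved longest-first
(ties: leftmost).  ``window`` mode approximates the sliding-window heuristic
of the classic tools: 50-SNP windows are scored homozygous, a SNP is in-run
when >= 5% of its covering windows are homozygous, and maximal in-run
stretches are then subjected to the five constraints.

The individual genomic inbreeding coefficient F_ROH is the summed ROH
length divided by the autosomal genome length covered by the array —
944,270 kb for a chicken 600K panel spanning autosomes 1-28; for other maps
use :func:`map_genome_length_kb`.

Run lengths are ``end_bp - start_bp`` of the first/last SNP (the convention
that reproduces published island lengths exactly) and are binned into seven
right-closed classes: <=5, (5,10], (10,15], (15,20], (20,25], (25,30] and
>30 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GaldivError
from .io import MISSING, GenotypeDataset

#: Autosomal genome length (kb) covered by the chicken 600K array, GGA1-28.
CHICKEN_ARRAY_GENOME_KB = 944_270.0

LENGTH_CLASS_EDGES_MB = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
LENGTH_CLASS_LABELS = (
    "1-5Mb",
    "5-10Mb",
    "10-15Mb",
    "15-20Mb",
    "20-25Mb",
    "25-30Mb",
    ">30Mb",
)

SEGMENT_COLUMNS = [
    "sample_id",
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "n_het",
    "n_missing",
    "length_bp",
]


@dataclass
class ROHParams:
    min_length_kb: float = 1000.0
    min_snps: int = 100
    max_het: int = 1
    max_missing: int = 2
    min_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 1000.0
    mode: str = "segment"
    window_snps: int = 50
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "min_length_kb",
            "min_snps",
            "min_density_kb_per_snp",
            "max_gap_kb",
            "window_snps",
            "window_hit_threshold",
        ):
            if getattr(self, name) <= 0:
                raise GaldivError(f"ROH parameter {name} must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise GaldivError("max_het and max_missing must be >= 0")
        if self.mode not in ("segment", "window"):
            raise GaldivError(f"mode must be segment or window, got {self.mode!r}")


@dataclass
class ROHSegment:
    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int
    length_bp: int = field(init=False)

    def __post_init__(self) -> None:
        self.length_bp = self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# segment mode
# ---------------------------------------------------------------------------


def _maximal_valid_ranges(calls, pos, params):
    """All maximal index ranges satisfying the five constraints.

    A range is *valid* when it meets every constraint and *maximal* when no
    strictly larger valid range contains it.  For each start ``a`` only the
    largest valid end M(a) can be maximal, and (a, M(a)) is maximal exactly
    when M(a) exceeds M(a') of every earlier start — so one left-to-right
    sweep with a running maximum enumerates the maximal set.
    """
    n = len(pos)
    max_gap_bp = params.max_gap_kb * 1000.0
    min_len_bp = params.min_length_kb * 1000.0
    dens_bp = params.min_density_kb_per_snp * 1000.0
    max_het, max_mis, min_snps = params.max_het, params.max_missing, params.min_snps

    # blocks separated by oversized gaps; no valid range crosses a block edge
    gap_break = np.flatnonzero(np.diff(pos) > max_gap_bp)
    starts = np.concatenate(([0], gap_break + 1))
    ends = np.concatenate((gap_break, [n - 1]))

    # plain lists: the sweep is index-at-a-time and python-list access is
    # several times faster than numpy scalar indexing here
    het = (calls == 1).tolist()
    mis = (calls == MISSING).tolist()
    # smallest end index satisfying the minimum bp length, per start
    min_len_idx = np.searchsorted(pos, pos + int(min_len_bp), side="left").tolist()
    posl = pos.tolist()

    out = []
    for s, t in zip(starts.tolist(), ends.tolist()):
        if t - s + 1 < min_snps:
            continue
        b = s - 1
        nh = nm = 0
        best_end = -1
        for a in range(s, t + 1):
            while b < t and nh + het[b + 1] <= max_het and nm + mis[b + 1] <= max_mis:
                b += 1
                nh += het[b]
                nm += mis[b]
            # [a, b] is the structurally-maximal range for this start
            lo = a + min_snps - 1
            if min_len_idx[a] > lo:
                lo = min_len_idx[a]
            m = b
            pa = posl[a]
            while m >= lo and (posl[m] - pa) > dens_bp * (m - a + 1):
                m -= 1
            if m >= lo and m > best_end:
                out.append((a, m))
                best_end = m
            if b >= a:
                nh -= het[a]
                nm -= mis[a]
            else:  # window never opened at a (e.g. het SNP with max_het=0)
                b = a
    return out


def _select_longest_first(candidates, pos):
    """Greedy non-overlap resolution: longest bp span first, ties leftmost."""
    ranked = sorted(candidates, key=lambda ab: (-(pos[ab[1]] - pos[ab[0]]), ab[0]))
    taken: list[tuple[int, int]] = []
    for a, b in ranked:
        if all(b < ta or a > tb for ta, tb in taken):
            taken.append((a, b))
    return sorted(taken)


# ---------------------------------------------------------------------------
# window mode
# ---------------------------------------------------------------------------


def _window_in_run(calls, params):
    """Boolean in-run flags from the sliding-window heuristic."""
    n = len(calls)
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    kern = np.ones(w, dtype=np.int32)
    het_w = np.convolve(het, kern, mode="valid")
    mis_w = np.convolve(mis, kern, mode="valid")
    hom_w = ((het_w <= params.max_het) & (mis_w <= params.max_missing)).astype(np.int32)
    # SNP i is covered by windows max(0, i-w+1) .. min(n-w, i)
    hits = np.convolve(hom_w, kern, mode="full")  # length n
    cover = np.convolve(np.ones(n - w + 1, dtype=np.int32), kern, mode="full")
    return hits / cover >= params.window_hit_threshold


def _window_segments(calls, pos, params):
    in_run = _window_in_run(calls, params)
    edges = np.flatnonzero(np.diff(in_run.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [len(calls)]))
    out = []
    max_gap_bp = params.max_gap_kb * 1000.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if not in_run[lo]:
            continue
        # split stretches at oversized gaps, then apply the five constraints
        piece_start = lo
        for i in range(lo, hi):
            last = i == hi - 1
            split = (not last) and (pos[i + 1] - pos[i] > max_gap_bp)
            if split or last:
                a, b = piece_start, i
                piece_start = i + 1
                nh = int((calls[a : b + 1] == 1).sum())
                nm = int((calls[a : b + 1] == MISSING).sum())
                length = pos[b] - pos[a]
                if (
                    b - a + 1 >= params.min_snps
                    and length >= params.min_length_kb * 1000.0
                    and nh <= params.max_het
                    and nm <= params.max_missing
                    and length <= params.min_density_kb_per_snp * 1000.0 * (b - a + 1)
                ):
                    out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def call_roh_individual(
    calls: np.ndarray,
    positions: np.ndarray,
    params: ROHParams | None = None,
    sample_id: str = "sample",
    chrom: int = 1,
) -> list[ROHSegment]:
    """Call ROH for one sample along one chromosome.

    ``calls`` are genotype codes aligned to strictly increasing bp
    ``positions``.  Output is deterministic and sorted by start.
    """
    params = params or ROHParams()
    calls = np.asarray(calls)
    pos = np.asarray(positions, dtype=np.int64)
    if len(calls) != len(pos):
        raise GaldivError("calls and positions must align")
    if len(pos) > 1 and (np.diff(pos) <= 0).any():
        raise GaldivError("positions must be strictly increasing")
    if len(pos) == 0:
        return []

    if params.mode == "segment":
        candidates = _maximal_valid_ranges(calls, pos, params)
        chosen = _select_longest_first(candidates, pos)
    else:
        chosen = _window_segments(calls, pos, params)

    segments = []
    for a, b in chosen:
        seg = calls[a : b + 1]
        segments.append(
            ROHSegment(
                sample_id=sample_id,
                chrom=int(chrom),
                start_bp=int(pos[a]),
                end_bp=int(pos[b]),
                n_snps=b - a + 1,
                n_het=int((seg == 1).sum()),
                n_missing=int((seg == MISSING).sum()),
            )
        )
    return segments


def call_roh_dataset(ds: GenotypeDataset, params: ROHParams | None = None) -> pd.DataFrame:
    """Call ROH for every sample and chromosome; rows sorted by (sample, chrom, start)."""
    params = params or ROHParams()
    chroms = ds.markers["chrom"].to_numpy()
    pos = ds.markers["pos"].to_numpy()
    rows = []
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        cpos = pos[sel]
        sub = ds.calls[:, sel]
        for i, sid in enumerate(ds.samples["id"]):
            for seg in call_roh_individual(sub[i], cpos, params, sample_id=sid, chrom=chrom):
                rows.append(
                    (
                        seg.sample_id,
                        seg.chrom,
                        seg.start_bp,
                        seg.end_bp,
                        seg.n_snps,
                        seg.n_het,
                        seg.n_missing,
                        seg.length_bp,
                    )
                )
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    # keep the dataset's sample order, then genomic order
    order = {sid: k for k, sid in enumerate(ds.samples["id"])}
    if len(df):
        df = df.sort_values(
            by=["sample_id", "chrom", "start_bp"],
            key=lambda col: col.map(order) if col.name == "sample_id" else col,
            kind="stable",
        ).reset_index(drop=True)
    return df


def map_genome_length_kb(markers: pd.DataFrame) -> float:
    """Sum over chromosomes of (max pos - min pos), in kb."""
    span = markers.groupby("chrom")["pos"].agg(lambda s: s.max() - s.min())
    return float(span.sum()) / 1000.0


def froh(
    segments: pd.DataFrame,
    genome_length_kb: float = CHICKEN_ARRAY_GENOME_KB,
    sample_ids=None,
) -> pd.DataFrame:
    """Per-sample F_ROH records: froh, sum_roh_kb, n_roh and length-class sums (Mb).

    ``sample_ids`` fixes the output rows (samples without segments get
    zeros); by default the samples present in ``segments`` are used.
    """
    if genome_length_kb <= 0:
        raise GaldivError("genome_length_kb must be positive")
    if len(segments) and (segments["length_bp"] / 1000.0 > genome_length_kb).any():
        raise GaldivError("segment longer than the genome")
    if sample_ids is None:
        sample_ids = list(dict.fromkeys(segments["sample_id"])) if len(segments) else []
    rows = []
    by_sample = dict(iter(segments.groupby("sample_id"))) if len(segments) else {}
    for sid in sample_ids:
        segs = by_sample.get(sid)
        class_sums = np.zeros(len(LENGTH_CLASS_LABELS))
        if segs is None or not len(segs):
            sum_kb, n_roh = 0.0, 0
        else:
            lengths_mb = segs["length_bp"].to_numpy() / 1e6
            idx = np.searchsorted(LENGTH_CLASS_EDGES_MB, lengths_mb, side="left")
            np.add.at(class_sums, idx, lengths_mb)
            sum_kb = float(segs["length_bp"].sum()) / 1000.0
            n_roh = int(len(segs))
        rows.append((sid, sum_kb / genome_length_kb, sum_kb, n_roh, *class_sums))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "froh", "sum_roh_kb", "n_roh", *LENGTH_CLASS_LABELS],
    )


def length_class_sums(
    segments: pd.DataFrame,
    groups: pd.Series | dict | None = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Mean per-animal summed Mb in each of the seven length classes.

    Without ``groups`` (a sample_id -> breed mapping) one row per sample is
    returned; with groups, the per-breed mean over its animals (animals with
    no ROH contribute zeros).
    """
    per_sample = froh(segments, sample_ids=sample_ids)[
        ["sample_id", *LENGTH_CLASS_LABELS]
    ]
    if groups is None:
        return per_sample
    groups = pd.Series(groups) if isinstance(groups, dict) else groups
    merged = per_sample.set_index("sample_id")
    merged["breed"] = merged.index.map(groups)
    if merged["breed"].isna().any():
        missing = merged.index[merged["breed"].isna()].tolist()
        raise GaldivError(f"samples without a breed label: {missing}")
    return merged.groupby("breed", sort=False).mean(numeric_only=True).reset_index()


def roh_breed_summary(froh_records: pd.DataFrame, groups: pd.Series | dict) -> pd.DataFrame:
    """Breed-level summary: F_ROH mean/sd, mean and SD of n_roh, total n_roh."""
    groups = pd.Series(groups) if isinstance(groups, dict) else groups
    df = froh_records.copy()
    df["breed"] = df["sample_id"].map(groups)
    if df["breed"].isna().any():
        missing = df["sample_id"][df["breed"].isna()].tolist()
        raise GaldivError(f"samples without a breed label: {missing}")
    out = (
        df.groupby("breed", sort=False)
        .agg(
            n=("sample_id", "size"),
            froh_mean=("froh", "mean"),
            froh_sd=("froh", lambda s: s.std(ddof=0)),
            mean_n_roh=("n_roh", "mean"),
            sd_n_roh=("n_roh", lambda s: s.std(ddof=0)),
            total_n_roh=("n_roh", "sum"),
        )
        .reset_index()
    )
    return out
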