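"""Autozygosity islands: per-SNP ROH incidence, hotspot selection, annotation.

The incidence track counts, for every mapped SNP, the number of animals
whose ROH cover it (an animal contributes at most once per SNP) and divides
by the number of animals.  SNPs whose incidence reaches the empirical
(1 - top_fraction) quantile of the track — by default the top 0.1% tail —
are selected and merged into islands while consecutive selected SNPs lie
within ``merge_gap_kb``.  Island coordinates are the first/last member SNP
positions and island length is ``end_bp - start_bp``, the convention that
reproduces published island lengths exactly.

Islands can be annotated against user-supplied BED or GFF3 interval files;
a feature is reported when its interval intersects the island's closed bp
span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GaldivError, ParseError


@dataclass
class Island:
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    marker_ids: list[str]
    length_bp: int = field(init=False)

    def __post_init__(self) -> None:
        self.length_bp = self.end_bp - self.start_bp


def snp_incidence(
    segments: pd.DataFrame, markers: pd.DataFrame, n_animals: int
) -> pd.DataFrame:
    """Per-marker ROH incidence track.

    A marker is counted for an animal iff one of its ROH on the same
    chromosome satisfies ``start_bp <= pos <= end_bp`` (closed interval,
    so boundary SNPs count).  Overlapping segments of one animal cannot
    double-count: per-animal coverage is merged first.

    Returns a DataFrame (marker id, chrom, pos, count, proportion).
    """
    if n_animals <= 0:
        raise GaldivError("n_animals must be positive")
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    count = np.zeros(len(markers), dtype=np.int64)

    if len(segments):
        known = set(np.unique(chrom_arr))
        bad = set(np.unique(segments["chrom"])) - known
        if bad:
            raise GaldivError(f"segments reference unmapped chromosome(s): {sorted(bad)}")
        chrom_index = {c: np.flatnonzero(chrom_arr == c) for c in known}
        for (sid, chrom), segs in segments.groupby(["sample_id", "chrom"], sort=False):
            idx = chrom_index[chrom]
            cpos = pos_arr[idx]
            covered = np.zeros(len(idx), dtype=bool)
            for start, end in zip(segs["start_bp"], segs["end_bp"]):
                lo = np.searchsorted(cpos, start, side="left")
                hi = np.searchsorted(cpos, end, side="right")
                covered[lo:hi] = True
            count[idx[covered]] += 1

    if (count > n_animals).any():
        raise GaldivError("incidence count exceeds n_animals")
    return pd.DataFrame(
        {
            "id": markers["id"].to_numpy(),
            "chrom": chrom_arr,
            "pos": pos_arr,
            "count": count,
            "proportion": count / float(n_animals),
        }
    )


def detect_islands(
    track: pd.DataFrame,
    top_fraction: float = 0.001,
    merge_gap_kb: float = 1000.0,
    force: bool = False,
) -> list[Island]:
    """Select hotspot SNPs by quantile threshold and merge them into islands.

    The threshold is the empirical (1 - top_fraction) quantile of the
    proportions over *all* mapped SNPs (zero-incidence included); SNPs at or
    above it are selected.  Consecutive selected SNPs on one chromosome are
    merged while their spacing is <= ``merge_gap_kb``.
    """
    if not 0.0 < top_fraction < 1.0:
        raise GaldivError("top_fraction must lie strictly between 0 and 1")
    props = track["proportion"].to_numpy(dtype=float)
    if len(props) == 0:
        return []
    if np.all(props == props[0]) and not force:
        raise GaldivError(
            "degenerate track: all incidence proportions equal (pass force=True)"
        )
    threshold = float(np.quantile(props, 1.0 - top_fraction))
    selected = props >= threshold

    islands: list[Island] = []
    merge_gap_bp = merge_gap_kb * 1000.0
    chrom_all = track["chrom"].to_numpy()
    pos_all = track["pos"].to_numpy()
    ids_all = track["id"].to_numpy()
    for chrom in pd.unique(chrom_all):
        m = (chrom_all == chrom) & selected
        if not m.any():
            continue
        pos = pos_all[m]
        ids = ids_all[m]
        breaks = np.flatnonzero(np.diff(pos) > merge_gap_bp)
        bounds = np.concatenate(([0], breaks + 1, [len(pos)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            islands.append(
                Island(
                    chrom=int(chrom),
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi - 1]),
                    n_snps=hi - lo,
                    marker_ids=list(ids[lo:hi]),
                )
            )
    return islands


def island_threshold(track: pd.DataFrame, top_fraction: float = 0.001) -> float:
    """The incidence threshold :func:`detect_islands` would apply."""
    return float(np.quantile(track["proportion"].to_numpy(dtype=float), 1.0 - top_fraction))


def islands_table(islands: list[Island]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": isl.chrom,
                "n_snps": isl.n_snps,
                "start_bp": isl.start_bp,
                "end_bp": isl.end_bp,
                "length_bp": isl.length_bp,
            }
            for isl in islands
        ],
        columns=["chrom", "n_snps", "start_bp", "end_bp", "length_bp"],
    )


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------


def read_features(path) -> pd.DataFrame:
    """Read gene/QTL intervals from BED or GFF3 into 1-based closed coordinates.

    BED intervals (0-based half-open) are converted to start+1..end; GFF3 is
    already 1-based closed, with the ``Name`` (or ``ID``) attribute as the
    label.  Format is chosen by file extension (.gff/.gff3 vs anything else
    treated as BED).
    """
    path = str(path)
    is_gff = path.endswith((".gff", ".gff3"))
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if is_gff:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 columns")
                    chrom = int(fields[0])
                    start, end = int(fields[3]), int(fields[4])
                    name = _gff_label(fields[8]) or f"feature_{lineno}"
                else:
                    if len(fields) < 3:
                        raise ValueError("fewer than 3 columns")
                    chrom = int(fields[0])
                    start, end = int(fields[1]) + 1, int(fields[2])
                    name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
                if end < start:
                    raise ValueError("end before start")
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            recs.append((chrom, start, end, name))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])


def _gff_label(attributes: str) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attributes.split(";") if "=" in kv
    )
    return fields.get("Name") or fields.get("ID")


def overlap_intervals(
    islands: list[Island], features: pd.DataFrame
) -> list[list[str]]:
    """Per-island feature names whose closed interval intersects the island span.

    Output order follows the feature table (stable).
    """
    out = []
    for isl in islands:
        hits = features[
            (features["chrom"] == isl.chrom)
            & (features["start"] <= isl.end_bp)
            & (features["end"] >= isl.start_bp)
        ]
        out.append(hits["name"].tolist())
    return out
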