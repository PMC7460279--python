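"""One-shot orchestration: QC -> diversity -> structure -> ROH -> islands.

Every stage writes a flat TSV (or Newick/JSON) so each step can be re-run
or inspected independently; a run manifest records package version,
parameters and input checksums.  All files are written atomically (tmp file
+ rename), and a run is a pure function of (inputs, config): identical runs
produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_table
from .errors import GaldivError
from .io import MAX_CHROM, MIN_CHROM, GenotypeDataset, read_genotype_table, read_ped_map
from .islands import (
    detect_islands,
    island_threshold,
    islands_table,
    overlap_intervals,
    read_features,
    snp_incidence,
)
from .qc import apply_qc
from .roh import (
    CHICKEN_ARRAY_GENOME_KB,
    ROHParams,
    call_roh_dataset,
    froh,
    length_class_sums,
    map_genome_length_kb,
    roh_breed_summary,
)
from .structure import (
    breed_average_mds,
    ibs_distance,
    neighbor_joining,
    reynolds_distance,
    write_newick,
)

logger = logging.getLogger("galdiv")


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`; YAML round-trippable."""

    ped: str | None = None
    map: str | None = None
    table: str | None = None
    features: str | None = None
    out_dir: str = "galdiv_out"
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    max_sample_missing: float = 0.10
    roh: ROHParams = field(default_factory=ROHParams)
    top_fraction: float = 0.001
    merge_gap_kb: float = 1000.0
    genome_length_kb: float | None = None  # None: auto (array constant or map span)
    mds_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.roh, dict):
            self.roh = ROHParams(**self.roh)
        for name in ("min_call_rate", "min_maf", "max_sample_missing", "top_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise GaldivError(f"{name} must lie in [0, 1], got {value}")
        if self.table is None and (self.ped is None or self.map is None):
            raise GaldivError("config needs either ped+map or table input")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        _atomic_write(path, yaml.safe_dump(data, sort_keys=True))


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w", newline="\n") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _write_tsv(path, df: pd.DataFrame, float_format="%.6g") -> None:
    _atomic_write(path, df.to_csv(sep="\t", index=False, float_format=float_format))


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load(config: PipelineConfig) -> tuple[GenotypeDataset, dict]:
    checksums = {}
    if config.table is not None:
        ds = read_genotype_table(config.table)
        checksums[config.table] = _checksum(config.table)
    else:
        ds = read_ped_map(config.ped, config.map)
        checksums[config.ped] = _checksum(config.ped)
        checksums[config.map] = _checksum(config.map)
    return ds, checksums


def resolve_genome_length_kb(config: PipelineConfig, markers: pd.DataFrame) -> float:
    """Array constant when the map spans autosomes 1-28; else the map span."""
    if config.genome_length_kb is not None:
        return float(config.genome_length_kb)
    chroms = set(markers["chrom"].unique().tolist())
    if chroms == set(range(MIN_CHROM, MAX_CHROM + 1)):
        return CHICKEN_ARRAY_GENOME_KB
    length = map_genome_length_kb(markers)
    logger.info(
        "map does not span autosomes 1-28; using summed map span %.0f kb", length
    )
    return length


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and return the output directory.

    Outputs: qc_report.{txt,json}, diversity_table.tsv, ibs_distance.tsv,
    mds_coordinates.tsv, mds_breed_coordinates.tsv, reynolds_distance.tsv,
    nj_breeds.nwk, nj_individuals.nwk, roh_segments.tsv, roh_segments.bed,
    froh_per_sample.tsv, roh_breed_summary.tsv, roh_length_classes.tsv,
    incidence_track.tsv, islands.tsv, islands.bed, island_features.tsv
    (when a feature file is configured) and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, checksums = _load(config)
    logger.info("loaded %d samples x %d markers", ds.n_samples, ds.n_markers)

    ds, report = apply_qc(
        ds,
        min_call_rate=config.min_call_rate,
        min_maf=config.min_maf,
        max_sample_missing=config.max_sample_missing,
    )
    logger.info(
        "QC: %d samples, %d markers retained", report.n_samples_out, report.n_markers_out
    )
    _atomic_write(out / "qc_report.txt", report.to_text())
    _atomic_write(out / "qc_report.json", report.to_json())

    # diversity panel (survey-table shape)
    _write_tsv(out / "diversity_table.tsv", diversity_table(ds))

    # structure: IBS + MDS + Reynolds + NJ
    D = ibs_distance(ds)
    _atomic_write(
        out / "ibs_distance.tsv", D.to_frame().to_csv(sep="\t", float_format="%.8g")
    )
    from .structure import classical_mds  # local import avoids cycle at module load

    mds = classical_mds(D, k=config.mds_components)
    _atomic_write(
        out / "mds_coordinates.tsv",
        mds.coordinates.to_csv(sep="\t", float_format="%.8g"),
    )
    breed_mds = breed_average_mds(ds, k=config.mds_components)
    _atomic_write(
        out / "mds_breed_coordinates.tsv",
        breed_mds.coordinates.to_csv(sep="\t", float_format="%.8g"),
    )
    if len(ds.breeds) >= 3:
        reyn = reynolds_distance(ds)
        _atomic_write(
            out / "reynolds_distance.tsv",
            reyn.to_frame().to_csv(sep="\t", float_format="%.8g"),
        )
        _atomic_write(out / "nj_breeds.nwk", write_newick(neighbor_joining(reyn)) + "\n")
    if ds.n_samples >= 3:
        _atomic_write(
            out / "nj_individuals.nwk", write_newick(neighbor_joining(D)) + "\n"
        )

    # ROH and F_ROH
    segments = call_roh_dataset(ds, config.roh)
    logger.info("called %d ROH segments (mode=%s)", len(segments), config.roh.mode)
    header = (
        f"# galdiv {__version__} ROH call, mode={config.roh.mode}, "
        f"min_snps={config.roh.min_snps}, min_length_kb={config.roh.min_length_kb}, "
        f"max_het={config.roh.max_het}, max_missing={config.roh.max_missing}, "
        f"density={config.roh.min_density_kb_per_snp}, gap={config.roh.max_gap_kb}\n"
    )
    breed_of = dict(zip(ds.samples["id"], ds.samples["breed"]))
    seg_out = segments.copy()
    seg_out.insert(1, "breed", seg_out["sample_id"].map(breed_of))
    _atomic_write(
        out / "roh_segments.tsv", header + seg_out.to_csv(sep="\t", index=False)
    )
    bed = segments[["chrom", "start_bp", "end_bp", "sample_id"]].copy()
    bed["start_bp"] -= 1  # 0-based half-open
    _atomic_write(out / "roh_segments.bed", bed.to_csv(sep="\t", index=False, header=False))

    genome_kb = resolve_genome_length_kb(config, ds.markers)
    records = froh(segments, genome_length_kb=genome_kb, sample_ids=ds.samples["id"].tolist())
    _write_tsv(out / "froh_per_sample.tsv", records)
    _write_tsv(out / "roh_breed_summary.tsv", roh_breed_summary(records, breed_of))
    _write_tsv(out / "roh_length_classes.tsv", length_class_sums(
        segments, groups=breed_of, sample_ids=ds.samples["id"].tolist()
    ))

    # incidence + islands
    track = snp_incidence(segments, ds.markers, n_animals=ds.n_samples)
    _write_tsv(out / "incidence_track.tsv", track)
    threshold = island_threshold(track, config.top_fraction)
    isl = detect_islands(
        track, top_fraction=config.top_fraction, merge_gap_kb=config.merge_gap_kb
    )
    logger.info("detected %d island(s) at incidence threshold %.4f", len(isl), threshold)
    _write_tsv(out / "islands.tsv", islands_table(isl))
    ibed = islands_table(isl).copy()
    if len(ibed):
        ibed["start_bp"] -= 1
    _atomic_write(
        out / "islands.bed",
        ibed[["chrom", "start_bp", "end_bp"]].to_csv(sep="\t", index=False, header=False),
    )
    if config.features:
        feats = read_features(config.features)
        hits = overlap_intervals(isl, feats)
        rows = [
            {"chrom": s.chrom, "start_bp": s.start_bp, "end_bp": s.end_bp,
             "features": ",".join(names)}
            for s, names in zip(isl, hits)
        ]
        _write_tsv(
            out / "island_features.tsv",
            pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "features"]),
        )

    config_dump = json.loads(json.dumps(dataclasses.asdict(config), default=str))
    config_dump.pop("out_dir", None)  # implied by the manifest's location
    manifest = {
        "galdiv_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config_dump,
        "input_checksums": checksums,
        "n_samples": int(ds.n_samples),
        "n_markers": int(ds.n_markers),
        "genome_length_kb": genome_kb,
        "island_threshold": threshold,
        "n_roh": int(len(segments)),
        "n_islands": len(isl),
    }
    _atomic_write(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return out


def plot_outputs(out_dir) -> list[Path]:
    """Draw the MDS scatter, F_ROH boxplot and incidence Manhattan plot.

    Figures are drawn from the stage TSVs, so plotting can never corrupt a
    table; a missing table skips that figure with a warning.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    made = []

    mds_path = out / "mds_breed_coordinates.tsv"
    if mds_path.exists():
        coords = pd.read_csv(mds_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(7, 6))
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=12)
        for label, row in coords.iterrows():
            ax.annotate(str(label), (row.iloc[0], row.iloc[1]), fontsize=7)
        ax.set_xlabel("C1")
        ax.set_ylabel("C2")
        ax.set_title("Breed-average MDS of IBS distances")
        fig.savefig(out / "mds_plot.png", dpi=150)
        plt.close(fig)
        made.append(out / "mds_plot.png")
    else:
        warnings.warn("mds_breed_coordinates.tsv missing; skipping MDS plot")

    froh_path = out / "froh_per_sample.tsv"
    seg_path = out / "roh_segments.tsv"
    if froh_path.exists() and seg_path.exists():
        records = pd.read_csv(froh_path, sep="\t")
        seg = pd.read_csv(seg_path, sep="\t", comment="#")
        breed_of = dict(zip(seg["sample_id"], seg["breed"])) if len(seg) else {}
        records["breed"] = records["sample_id"].map(breed_of).fillna("?")
        order = list(dict.fromkeys(records["breed"]))
        data = [records.loc[records["breed"] == b, "froh"] for b in order]
        fig, ax = plt.subplots(figsize=(max(7, 0.3 * len(order)), 5))
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel("F_ROH")
        ax.tick_params(axis="x", rotation=90)
        ax.set_title("Genomic inbreeding from runs of homozygosity")
        fig.tight_layout()
        fig.savefig(out / "froh_boxplot.png", dpi=150)
        plt.close(fig)
        made.append(out / "froh_boxplot.png")
    else:
        warnings.warn("froh/segment tables missing; skipping F_ROH boxplot")

    track_path = out / "incidence_track.tsv"
    if track_path.exists():
        track = pd.read_csv(track_path, sep="\t")
        manifest_path = out / "manifest.json"
        threshold = None
        if manifest_path.exists():
            threshold = json.loads(manifest_path.read_text()).get("island_threshold")
        fig, ax = plt.subplots(figsize=(9, 4))
        offset = 0
        ticks, ticklabels = [], []
        for chrom, sub in track.groupby("chrom", sort=True):
            x = sub["pos"].to_numpy() + offset
            ax.scatter(x, sub["proportion"], s=3,
                       color="tab:blue" if chrom % 2 else "tab:cyan")
            ticks.append(offset + sub["pos"].max() / 2)
            ticklabels.append(str(chrom))
            offset += sub["pos"].max()
        if threshold is not None:
            ax.axhline(threshold, color="blue", lw=1, label="island threshold")
            ax.legend(loc="upper right", fontsize=8)
        ax.set_xticks(ticks, ticklabels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("ROH incidence")
        ax.set_title("Per-SNP ROH incidence")
        fig.tight_layout()
        fig.savefig(out / "incidence_manhattan.png", dpi=150)
        plt.close(fig)
        made.append(out / "incidence_manhattan.png")
    else:
        warnings.warn("incidence_track.tsv missing; skipping Manhattan plot")

    return made
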