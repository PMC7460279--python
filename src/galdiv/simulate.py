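"""Synthetic genotype datasets with known truth for every pipeline stage.

The generator emulates the statistical structure a multi-breed SNP-array
survey assumes, without modelling linkage disequilibrium:

* a marker map with uniformly placed, strictly increasing positions;
* breed allele frequencies drifted from a common ancestral Beta spectrum
  under a Balding-Nichols model (drift parameter ``divergence`` = c, so
  breed frequencies are Beta(p0 (1-c)/c, (1-p0)(1-c)/c) around ancestral
  p0 and E[(p_x - p_y)^2] = 2 c E[p0 (1-p0)] between two breeds);
* site-wise genotypes under Hardy-Weinberg with optional inbreeding F
  (probabilities p^2 + F p q, 2 p q (1 - F), q^2 + F p q) and i.i.d.
  missingness;
* injected autozygous segments at known locations, which are the sole
  source of runs of homozygosity (site-wise simulation carries no linkage),
  recorded in an exact truth table.

Injected segments are written as fully-called homozygous tracts (each
marker drawn homozygous by its breed frequency) and the two markers
flanking each tract are forced heterozygous, so truth boundaries are sharp
and a segment-mode caller can overshoot by at most one flanking SNP.
Placement is uniform over the feasible (non-overlapping) offsets of each
chromosome, so realized autozygous coverage matches the plan; a breed whose
plan covers fraction F* of the genome therefore has both F_HOM and F_ROH
expectations of about F*.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GaldivError
from .io import MISSING, GenotypeDataset


@dataclass
class SegmentPlan:
    """Autozygous segments to inject per individual."""

    count: int
    length_mb_range: tuple[float, float]
    chrom: int | None = None  # fix the chromosome (None: cycle over all)
    at_bp: int | None = None  # fix the start (hotspot); None: random
    probability: float = 1.0  # per-individual chance of carrying the segment


@dataclass
class BreedConfig:
    label: str
    n_individuals: int
    inbreeding_f: float = 0.0
    divergence: float = 0.1
    roh_plan: list[SegmentPlan] = field(default_factory=list)
    clade: str | None = None  # breeds sharing a clade share an extra drift stage


@dataclass
class SimConfig:
    n_chrom: int = 5
    snps_per_chrom: int = 1000
    chrom_length_bp: int = 40_000_000
    breeds: list[BreedConfig] = field(default_factory=list)
    missing_rate: float = 0.002
    base_beta: tuple[float, float] = (1.0, 1.0)
    clade_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise GaldivError("missing_rate must lie in [0, 1]")
        for b in self.breeds:
            if not 0.0 <= b.inbreeding_f <= 1.0:
                raise GaldivError(f"inbreeding_f of {b.label!r} must lie in [0, 1]")
            if not 0.0 < b.divergence < 1.0:
                raise GaldivError(f"divergence of {b.label!r} must lie in (0, 1)")


@dataclass
class TruthSet:
    """Exact truth for a simulated dataset."""

    segments: pd.DataFrame  # sample_id, chrom, start_bp, end_bp (member-SNP coords)
    breed_f: dict[str, float]  # configured F* per breed
    ancestral_freqs: np.ndarray
    breed_freqs: dict[str, np.ndarray]


def simulate_map(config: SimConfig) -> pd.DataFrame:
    """Uniform random marker map; strictly increasing positions per chromosome."""
    if config.snps_per_chrom < 2:
        raise GaldivError("snps_per_chrom must be >= 2")
    if config.chrom_length_bp < config.snps_per_chrom:
        raise GaldivError("chrom_length_bp must be >= snps_per_chrom")
    rng = np.random.default_rng(config.seed)
    recs = []
    for chrom in range(1, config.n_chrom + 1):
        pos = np.unique(
            rng.integers(1, config.chrom_length_bp + 1, size=config.snps_per_chrom)
        )
        while len(pos) < config.snps_per_chrom:  # redraw collisions
            extra = rng.integers(
                1, config.chrom_length_bp + 1, size=config.snps_per_chrom - len(pos)
            )
            pos = np.unique(np.concatenate([pos, extra]))
        for k, p in enumerate(pos):
            recs.append((f"snp{chrom}_{k}", chrom, int(p)))
    return pd.DataFrame(recs, columns=["id", "chrom", "pos"])


def simulate_breed_frequencies(
    n_markers: int,
    breeds: list[BreedConfig],
    base_beta: tuple[float, float] = (1.0, 1.0),
    clade_divergence: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Ancestral spectrum plus per-breed drifted allele frequencies.

    Breeds with the same ``clade`` label first share a clade-level drift
    stage (drift ``clade_divergence``), then drift independently; breeds
    without a clade drift straight from the ancestral pool.
    """
    alpha, beta = base_beta
    if alpha <= 0 or beta <= 0:
        raise GaldivError("base Beta parameters must be positive")
    rng = np.random.default_rng(seed)
    p0 = np.clip(rng.beta(alpha, beta, size=n_markers), 1e-4, 1 - 1e-4)

    def drift(p, c):
        c = float(c)
        return np.clip(
            rng.beta(p * (1 - c) / c, (1 - p) * (1 - c) / c), 1e-6, 1 - 1e-6
        )

    clade_pools: dict[str, np.ndarray] = {}
    out = {}
    for b in breeds:
        if b.clade is not None:
            if b.clade not in clade_pools:
                clade_pools[b.clade] = drift(p0, clade_divergence)
            out[b.label] = drift(clade_pools[b.clade], b.divergence)
        else:
            out[b.label] = drift(p0, b.divergence)
    return p0, out


def simulate_genotypes(
    freqs: np.ndarray,
    n: int,
    inbreeding_f: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    breed: str = "SIM",
    markers: pd.DataFrame | None = None,
) -> GenotypeDataset:
    """One breed of site-wise genotypes under HWE-with-F and i.i.d. missingness."""
    if not 0.0 <= inbreeding_f <= 1.0:
        raise GaldivError("inbreeding_f must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    f = inbreeding_f
    p2 = p * p + f * p * q  # hom allele B
    p1 = 2.0 * p * q * (1.0 - f)  # het
    u = rng.random((n, len(p)))
    calls = np.where(u < p2, 2, np.where(u < p2 + p1, 1, 0)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    if markers is None:
        markers = pd.DataFrame(
            {"id": [f"snp1_{k}" for k in range(len(p))], "chrom": 1,
             "pos": np.arange(1, len(p) + 1) * 1000}
        )
    markers = markers.copy()
    markers["allele_a"] = "A"
    markers["allele_b"] = "C"
    samples = pd.DataFrame(
        {
            "id": [f"{breed}_{i:03d}" for i in range(n)],
            "breed": breed,
            "sex": np.where(np.arange(n) % 2 == 0, "M", "F"),
        }
    )
    return GenotypeDataset(samples, markers[["id", "chrom", "pos", "allele_a", "allele_b"]], calls)


# ---------------------------------------------------------------------------
# autozygous-segment injection
# ---------------------------------------------------------------------------


def _feasible_start(rng, chrom_len, seg_len, occupied):
    """Uniform start over offsets where [start, start+seg_len] avoids ``occupied``.

    ``occupied`` is a list of (start, end) bp intervals already injected on
    this chromosome (kept with a small margin by the caller).  Returns None
    when the segment does not fit anywhere.
    """
    free = []
    cursor = 1
    for s, e in sorted(occupied):
        if s - cursor >= seg_len:
            free.append((cursor, s - seg_len))
        cursor = max(cursor, e + 1)
    if chrom_len - cursor >= seg_len:
        free.append((cursor, chrom_len - seg_len))
    if not free:
        return None
    weights = np.array([hi - lo + 1 for lo, hi in free], dtype=float)
    lo, hi = free[rng.choice(len(free), p=weights / weights.sum())]
    return int(rng.integers(lo, hi + 1))


def inject_roh(
    ds: GenotypeDataset,
    plan: list[SegmentPlan],
    seed: int = 0,
    flank_margin_snps: int = 4,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Inject autozygous segments into every individual per the plan.

    Within each injected span every marker is set homozygous for an allele
    drawn by its (dataset-wide realized) frequency; missing calls inside the
    span are overwritten, and the two markers flanking the span are forced
    heterozygous (see module docstring).  Segments of one individual are
    placed without overlap (uniformly over the feasible offsets) and kept at
    least ``flank_margin_snps`` markers apart so flanks never collide;
    a segment that no longer fits is skipped.

    Returns the modified dataset and the truth table (sample_id, chrom,
    start_bp, end_bp, n_snps) with member-SNP coordinates.
    """
    rng = np.random.default_rng(seed)
    ds = ds.copy()
    chroms = ds.markers["chrom"].to_numpy()
    pos = ds.markers["pos"].to_numpy()
    chrom_ids = list(np.unique(chroms))
    chrom_idx = {c: np.flatnonzero(chroms == c) for c in chrom_ids}
    chrom_len = {c: int(pos[chrom_idx[c]].max()) for c in chrom_ids}
    # dataset-wide allele-B frequency used to draw the homozygous allele
    valid = ds.calls != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        pfreq = np.where(
            valid.sum(axis=0) > 0,
            np.where(valid, ds.calls, 0).sum(axis=0) / (2.0 * np.maximum(valid.sum(axis=0), 1)),
            0.5,
        )

    truth_rows = []
    for i, sid in enumerate(ds.samples["id"]):
        occupied: dict[int, list[tuple[int, int]]] = {c: [] for c in chrom_ids}
        spans: list[tuple[int, int, int]] = []  # (chrom, start, end) planned bp
        cycle = 0
        for item in plan:
            for _ in range(item.count):
                seg_len = int(
                    rng.uniform(item.length_mb_range[0], item.length_mb_range[1]) * 1e6
                )
                if item.chrom is not None:
                    chrom = item.chrom
                else:
                    chrom = chrom_ids[cycle % len(chrom_ids)]
                    cycle += 1
                if seg_len > chrom_len[chrom]:
                    raise GaldivError(
                        f"planned segment of {seg_len} bp exceeds chromosome {chrom}"
                    )
                if item.probability < 1.0 and rng.random() >= item.probability:
                    continue
                if item.at_bp is not None:
                    start = int(item.at_bp)
                else:
                    start = _feasible_start(rng, chrom_len[chrom], seg_len, occupied[chrom])
                    if start is None:
                        continue  # no room left on this chromosome
                end = start + seg_len
                margin = (
                    int(np.median(np.diff(pos[chrom_idx[chrom]]))) * flank_margin_snps
                )
                occupied[chrom].append((start - margin, end + margin))
                spans.append((chrom, start, end))

        # resolve planned bp spans to member-SNP index ranges and merge any
        # that overlap or nearly touch, so flank markers of one truth segment
        # can never fall inside another
        ranges: dict[int, list[list[int]]] = {}
        for chrom, start, end in sorted(spans):
            cpos = pos[chrom_idx[chrom]]
            lo = int(np.searchsorted(cpos, start, side="left"))
            hi = int(np.searchsorted(cpos, end, side="right"))
            if hi - lo < 1:
                continue  # span contains no markers; nothing injected
            rows = ranges.setdefault(chrom, [])
            if rows and lo - rows[-1][1] <= flank_margin_snps:
                rows[-1][1] = max(rows[-1][1], hi)
            else:
                rows.append([lo, hi])

        for chrom, rows in ranges.items():
            idx = chrom_idx[chrom]
            cpos = pos[idx]
            for lo, hi in rows:
                member = idx[lo:hi]
                hom = np.where(rng.random(len(member)) < pfreq[member], 2, 0)
                ds.calls[i, member] = hom.astype(np.int8)
                for k in (lo - 1, lo - 2, hi, hi + 1):  # sharp flanks
                    if 0 <= k < len(idx):
                        ds.calls[i, idx[k]] = 1
                truth_rows.append(
                    (sid, chrom, int(cpos[lo]), int(cpos[hi - 1]), hi - lo)
                )

    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps"]
    )
    return ds, truth


# ---------------------------------------------------------------------------
# whole-study fixture
# ---------------------------------------------------------------------------

#: The 23 local breeds and 4 commercial stocks of an Italian-style survey,
#: with configured autozygosity fractions F* spanning the observed range
#: (commercial stocks near zero, a Siciliana-like breed at 0.6).  Two breed
#: pairs share a clade (recent common frequency pool), mirroring the
#: Padovana/Polverara situation.
_LOCAL_F = {
    "ANC": 0.20, "BSA": 0.10, "BPT": 0.10, "COR": 0.50, "PER": 0.30,
    "PLB": 0.42, "PLN": 0.30, "MER": 0.32, "PML": 0.17, "MOD": 0.26,
    "MUG": 0.22, "PPA": 0.50, "PPC": 0.41, "PPD": 0.23, "PPP": 0.48,
    "PPB": 0.31, "PPN": 0.35, "PRL": 0.35, "PRM": 0.41, "ROM": 0.19,
    "SIC": 0.60, "VLD": 0.12, "VLP": 0.24,
}
_COMMERCIAL_F = {"708": 0.034, "EUK": 0.033, "HYL": 0.038, "ISA": 0.030}
_CLADES = {"PPA": "PAD", "PPC": "PAD", "PPB": "POL", "PPN": "POL"}


def study_config(seed: int = 0) -> SimConfig:
    """The default whole-study simulation: 27 breeds on a reduced marker panel.

    5 chromosomes x 1000 SNPs x 40 Mb keeps a full pipeline run to minutes;
    breed sample sizes follow the survey design (20-24 per local breed,
    9-13 per commercial stock).  Each breed's F* is realized as injected
    autozygous coverage; one designed island region (chromosome 3,
    15.0-21.0 Mb) is injected in 90% of all animals.
    """
    rng = np.random.default_rng(seed)
    genome_mb = 5 * 40.0
    breeds = []

    def make_plan(f_star):
        target_mb = f_star * genome_mb
        plan = []
        # one segment per chromosome, length = target / n_chrom, floor 4.5 Mb
        per_chrom = target_mb / 5.0
        if per_chrom >= 4.5:
            for chrom in range(1, 6):
                plan.append(
                    SegmentPlan(
                        count=1,
                        length_mb_range=(per_chrom * 0.9, per_chrom * 1.1),
                        chrom=chrom,
                    )
                )
        elif target_mb >= 4.5:
            plan.append(SegmentPlan(count=1, length_mb_range=(target_mb, target_mb)))
        return plan

    for label, f_star in _LOCAL_F.items():
        breeds.append(
            BreedConfig(
                label=label,
                n_individuals=int(rng.integers(20, 25)),
                inbreeding_f=0.0,
                divergence=float(rng.uniform(0.08, 0.25)),
                roh_plan=make_plan(f_star)
                + [SegmentPlan(count=1, length_mb_range=(6.0, 6.0), chrom=3,
                               at_bp=15_000_000, probability=0.9)],
                clade=_CLADES.get(label),
            )
        )
    for label, f_star in _COMMERCIAL_F.items():
        breeds.append(
            BreedConfig(
                label=label,
                n_individuals=int(rng.integers(9, 14)),
                inbreeding_f=0.0,
                divergence=float(rng.uniform(0.05, 0.10)),
                roh_plan=make_plan(f_star)
                + [SegmentPlan(count=1, length_mb_range=(6.0, 6.0), chrom=3,
                               at_bp=15_000_000, probability=0.9)],
            )
        )
    return SimConfig(breeds=breeds, seed=seed)


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, TruthSet]:
    """Generate a full multi-breed dataset plus truth from a :class:`SimConfig`."""
    if not config.breeds:
        raise GaldivError("SimConfig lists no breeds")
    markers = simulate_map(config)
    seeds = np.random.SeedSequence(config.seed).spawn(2 + 2 * len(config.breeds))
    p0, freqs = simulate_breed_frequencies(
        len(markers),
        config.breeds,
        base_beta=config.base_beta,
        clade_divergence=config.clade_divergence,
        seed=seeds[0],
    )
    parts, truths = [], []
    for k, b in enumerate(config.breeds):
        part = simulate_genotypes(
            freqs[b.label],
            b.n_individuals,
            inbreeding_f=b.inbreeding_f,
            missing_rate=config.missing_rate,
            seed=seeds[1 + 2 * k],
            breed=b.label,
            markers=markers,
        )
        if b.roh_plan:
            part, truth = inject_roh(part, b.roh_plan, seed=seeds[2 + 2 * k])
            truths.append(truth)
        parts.append(part)
    samples = pd.concat([p.samples for p in parts], ignore_index=True)
    calls = np.vstack([p.calls for p in parts])
    ds = GenotypeDataset(samples, parts[0].markers.copy(), calls)
    truth = TruthSet(
        segments=(
            pd.concat(truths, ignore_index=True)
            if truths
            else pd.DataFrame(columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps"])
        ),
        breed_f={
            b.label: _planned_coverage(b, config) for b in config.breeds
        },
        ancestral_freqs=p0,
        breed_freqs=freqs,
    )
    return ds, truth


def _planned_coverage(b: BreedConfig, config: SimConfig) -> float:
    genome = config.n_chrom * config.chrom_length_bp / 1e6
    mb = sum(
        item.count * item.probability * sum(item.length_mb_range) / 2.0
        for item in b.roh_plan
    )
    return mb / genome


def make_study_fixture(seed: int = 0) -> tuple[GenotypeDataset, TruthSet]:
    """Convenience wrapper: simulate the default whole-study dataset."""
    return simulate_dataset(study_config(seed))
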