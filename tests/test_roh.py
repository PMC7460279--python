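import numpy as np
import pandas as pd
import pytest
from helpers import build_ds
from oracles import brute_force_roh

from galdiv import (
    CHICKEN_ARRAY_GENOME_KB,
    MISSING,
    GaldivError,
    ROHParams,
    call_roh_dataset,
    call_roh_individual,
    froh,
    length_class_sums,
    roh_breed_summary,
)

M = MISSING


def hom_run(n, span_bp, start=1):
    pos = np.linspace(start, start + span_bp, n).astype(np.int64)
    return np.zeros(n, dtype=np.int8), pos


class TestCallIndividual:
    def test_clean_run_is_one_segment(self):
        calls, pos = hom_run(150, 2_000_000)
        segs = call_roh_individual(calls, pos)
        assert len(segs) == 1
        assert segs[0].n_snps == 150
        assert segs[0].start_bp == pos[0] and segs[0].end_bp == pos[-1]

    def test_oversized_gap_splits_and_kills_short_sides(self):
        """A 1.5 Mb gap after SNP 70 leaves two sides below 100 SNPs: no ROH."""
        calls, pos = hom_run(150, 2_000_000)
        pos = pos.copy()
        pos[71:] += 1_500_000
        assert call_roh_individual(calls, pos) == []

    def test_sparse_run_fails_density(self):
        """120 homozygous SNPs over 13 Mb average 108 kb/SNP > 100: no ROH."""
        calls, pos = hom_run(120, 13_000_000)
        assert call_roh_individual(calls, pos) == []

    def test_regular_heterozygotes_block_all_runs(self):
        calls, pos = hom_run(400, 8_000_000)
        calls = calls.copy()
        calls[::50] = 1  # a het every 50 SNPs: any 100-SNP window has >= 2
        assert call_roh_individual(calls, pos) == []

    def test_single_het_and_two_missing_are_tolerated(self):
        calls, pos = hom_run(150, 2_000_000)
        calls = calls.copy()
        calls[50] = 1
        calls[[80, 90]] = M
        segs = call_roh_individual(calls, pos)
        assert len(segs) == 1
        assert segs[0].n_het == 1 and segs[0].n_missing == 2

    def test_unsorted_positions_raise(self):
        calls, pos = hom_run(120, 2_000_000)
        pos = pos.copy()
        pos[5] = pos[6]
        with pytest.raises(GaldivError, match="strictly increasing"):
            call_roh_individual(calls, pos)

    def test_invalid_params_raise(self):
        with pytest.raises(GaldivError):
            ROHParams(min_snps=0)
        with pytest.raises(GaldivError):
            ROHParams(mode="plink")

    def test_window_mode_calls_clean_run(self):
        calls, pos = hom_run(150, 2_000_000)
        segs = call_roh_individual(calls, pos, ROHParams(mode="window"))
        assert len(segs) == 1
        assert segs[0].n_snps == 150

    def test_window_mode_rejects_het_dense_data(self, rng):
        calls = rng.integers(0, 3, size=300).astype(np.int8)
        pos = np.sort(rng.choice(6_000_000, size=300, replace=False)) + 1
        assert call_roh_individual(calls, pos, ROHParams(mode="window")) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_chromosomes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(150, 400))
        spacing = rng.uniform(15_000, 130_000)
        pos = np.sort(rng.choice(int(n * spacing), size=n, replace=False)) + 1
        het_rate = rng.uniform(0.0, 0.05)
        mis_rate = rng.uniform(0.0, 0.05)
        u = rng.random(n)
        calls = np.zeros(n, dtype=np.int8)
        calls[u < het_rate] = 1
        calls[(u >= het_rate) & (u < het_rate + mis_rate)] = M
        params = ROHParams()
        got = [
            (int(np.searchsorted(pos, s.start_bp)), int(np.searchsorted(pos, s.end_bp)))
            for s in call_roh_individual(calls, pos, params)
        ]
        assert got == brute_force_roh(calls, pos, params)


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(4))
    def test_stricter_thresholds_never_add_roh(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 400
        pos = np.sort(rng.choice(12_000_000, size=n, replace=False)) + 1
        calls = (rng.random(n) < 0.02).astype(np.int8)
        base = len(call_roh_individual(calls, pos, ROHParams()))
        more_snps = len(call_roh_individual(calls, pos, ROHParams(min_snps=150)))
        longer = len(call_roh_individual(calls, pos, ROHParams(min_length_kb=2000)))
        assert more_snps <= base
        assert longer <= base


class TestFroh:
    def test_no_segments_is_zero(self):
        records = froh(pd.DataFrame(columns=["sample_id", "length_bp"]), sample_ids=["s"])
        assert records["froh"].iloc[0] == 0.0
        assert records["n_roh"].iloc[0] == 0

    def test_whole_genome_segment_is_one(self):
        seg = pd.DataFrame(
            [{"sample_id": "s", "chrom": 1, "start_bp": 1,
              "end_bp": 1 + int(CHICKEN_ARRAY_GENOME_KB * 1000),
              "length_bp": int(CHICKEN_ARRAY_GENOME_KB * 1000)}]
        )
        assert froh(seg)["froh"].iloc[0] == pytest.approx(1.0)

    def test_ten_percent_of_array_constant(self):
        seg = pd.DataFrame(
            [{"sample_id": "s", "chrom": 1, "start_bp": 1,
              "end_bp": 1 + 94_427_000, "length_bp": 94_427_000}]
        )
        assert froh(seg)["froh"].iloc[0] == pytest.approx(0.1)

    def test_segment_longer_than_genome_raises(self):
        seg = pd.DataFrame(
            [{"sample_id": "s", "length_bp": 2_000_000_000}]
        )
        with pytest.raises(GaldivError, match="longer than the genome"):
            froh(seg)

    def test_invariant_under_chromosome_relabelling(self):
        """Which chromosome carries the run does not change F_ROH."""
        chrom = np.repeat([1, 2], 150)
        pos = np.concatenate(
            [np.linspace(1, 3e6, 150), np.linspace(1, 3e6, 150)]
        ).astype(int)
        hom_then_het = np.concatenate(
            [np.zeros(150, dtype=np.int8), np.ones(150, dtype=np.int8)]
        )[None, :]
        het_then_hom = hom_then_het[:, ::-1].copy()
        ds1 = build_ds(hom_then_het, chrom=chrom, pos=pos)
        ds2 = build_ds(het_then_hom, chrom=chrom, pos=pos)
        f1 = froh(call_roh_dataset(ds1), sample_ids=["S0"])["froh"].iloc[0]
        f2 = froh(call_roh_dataset(ds2), sample_ids=["S0"])["froh"].iloc[0]
        assert f1 > 0
        assert f1 == pytest.approx(f2)

    def test_class_sums_total_matches_sum_roh(self):
        segs = pd.DataFrame(
            [
                {"sample_id": "s", "chrom": 1, "start_bp": 1,
                 "end_bp": 4_200_001, "length_bp": 4_200_000},
                {"sample_id": "s", "chrom": 2, "start_bp": 1,
                 "end_bp": 31_000_001, "length_bp": 31_000_000},
            ]
        )
        rec = froh(segs)
        total_mb = sum(rec.iloc[0][4:])
        assert total_mb == pytest.approx(rec["sum_roh_kb"].iloc[0] / 1000.0)


class TestLengthClasses:
    @pytest.mark.parametrize(
        "length_mb,label",
        [(4.2, "1-5Mb"), (5.0, "1-5Mb"), (5.1, "5-10Mb"), (31.0, ">30Mb")],
    )
    def test_right_closed_class_boundaries(self, length_mb, label):
        seg = pd.DataFrame(
            [{"sample_id": "s", "chrom": 1, "start_bp": 1,
              "end_bp": int(length_mb * 1e6) + 1, "length_bp": int(length_mb * 1e6)}]
        )
        per_sample = length_class_sums(seg)
        assert per_sample[label].iloc[0] == pytest.approx(length_mb)
        others = [c for c in per_sample.columns if c not in ("sample_id", label)]
        assert per_sample[others].iloc[0].sum() == 0

    def test_breed_mean_counts_zero_animals(self):
        seg = pd.DataFrame(
            [{"sample_id": "a", "chrom": 1, "start_bp": 1,
              "end_bp": 10_000_001, "length_bp": 10_000_000}]
        )
        out = length_class_sums(seg, groups={"a": "X", "b": "X"}, sample_ids=["a", "b"])
        assert out.loc[out["breed"] == "X", "5-10Mb"].iloc[0] == pytest.approx(5.0)


class TestBreedSummary:
    def test_means_and_totals(self):
        records = pd.DataFrame(
            {"sample_id": ["a", "b"], "froh": [0.1, 0.3],
             "sum_roh_kb": [1, 2], "n_roh": [2, 4]}
        )
        out = roh_breed_summary(records, {"a": "X", "b": "X"})
        assert out["mean_n_roh"].iloc[0] == pytest.approx(3.0)
        assert out["total_n_roh"].iloc[0] == 6
        assert out["froh_mean"].iloc[0] == pytest.approx(0.2)


class TestDatasetLevel:
    def test_one_long_run_per_sample(self):
        calls = np.zeros((4, 200), dtype=np.int8)
        pos = np.linspace(1, 4_000_000, 200).astype(int)
        ds = build_ds(calls, pos=pos)
        segs = call_roh_dataset(ds)
        assert len(segs) == 4
        assert set(segs["sample_id"]) == set(ds.samples["id"])

    def test_empty_dataset_gives_empty_table(self):
        calls = np.ones((2, 150), dtype=np.int8)  # all het: nothing callable
        ds = build_ds(calls, pos=np.linspace(1, 3e6, 150).astype(int))
        assert len(call_roh_dataset(ds)) == 0

    def test_output_sorted_by_sample_chrom_start(self, rng):
        chrom = np.repeat([1, 2], 200)
        pos = np.concatenate(
            [np.linspace(1, 4e6, 200), np.linspace(1, 4e6, 200)]
        ).astype(int)
        calls = np.zeros((3, 400), dtype=np.int8)
        ds = build_ds(calls, chrom=chrom, pos=pos)
        segs = call_roh_dataset(ds)
        assert segs["sample_id"].tolist() == sorted(
            segs["sample_id"].tolist(), key=["S0", "S1", "S2"].index
        )
        for _, sub in segs.groupby("sample_id"):
            assert sub["chrom"].is_monotonic_increasing
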