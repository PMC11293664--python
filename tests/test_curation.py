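"""Curation: aggregation, SD filters, domain-count filter, bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from stabbench import curation
from stabbench.curation import (
    CurationThresholds,
    aggregate_replicates,
    curate,
    filter_by_replicate_sd,
    filter_domains_by_count,
    read_measurements,
)
from stabbench.errors import DataConsistencyError, SchemaError
from stabbench.synthetic_data import SYNTHETIC_COLUMN_MAP

from conftest import SMALL_THRESHOLDS, write_raw_csv


class TestReadMeasurements:
    def test_reads_one_record_per_valid_row(self, tmp_path):
        path = write_raw_csv(
            tmp_path / "toy.csv",
            [
                ("A", "v1", "ACDEF", "r1", 1.0, 2.0, False),
                ("A", "v2", "ACDEG", "r1", 1.5, 2.1, False),
                ("B", "v1", "WYVTS", "r1", 0.5, 1.8, True),
            ],
        )
        df = read_measurements(path, SYNTHETIC_COLUMN_MAP)
        assert len(df) == 3
        assert df["protein_sequence"].tolist() == ["ACDEF", "ACDEG", "WYVTS"]

    def test_invalid_alphabet_row_dropped_and_logged(self, tmp_path):
        path = write_raw_csv(
            tmp_path / "bad.csv",
            [
                ("A", "v1", "ACDEF", "r1", 1.0, 2.0, False),
                ("A", "v2", "ACD3F", "r1", 1.5, 2.1, False),  # digit in sequence
                ("A", "v3", "ACDXF", "r1", 1.2, 2.0, False),  # X outside 20-aa alphabet
            ],
        )
        df = read_measurements(path, SYNTHETIC_COLUMN_MAP)
        assert len(df) == 1
        assert df.attrs["drop_log"]["invalid_sequence"] == 2

    def test_rows_missing_both_readouts_dropped(self, tmp_path):
        path = write_raw_csv(
            tmp_path / "miss.csv",
            [
                ("A", "v1", "ACDEF", "r1", "", 2.0, False),  # dG missing, logk present
                ("A", "v2", "ACDEG", "r1", "<1", "", False),  # censored dG, both missing
            ],
        )
        df = read_measurements(path, SYNTHETIC_COLUMN_MAP)
        assert len(df) == 1
        assert math.isnan(df["dG"].iloc[0])
        assert df.attrs["drop_log"]["no_stability_value"] == 1

    def test_missing_mapped_column_names_the_column(self, tmp_path):
        path = tmp_path / "cols.csv"
        pd.DataFrame({"domain_id": ["A"], "protein_sequence": ["ACDEF"]}).to_csv(
            path, index=False
        )
        with pytest.raises(SchemaError, match="variant_id"):
            read_measurements(path, SYNTHETIC_COLUMN_MAP)

    def test_empty_file_is_an_explicit_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(curation.MEASUREMENT_COLUMNS) + "\n")
        with pytest.raises(SchemaError, match="empty"):
            read_measurements(path, SYNTHETIC_COLUMN_MAP)

    def test_generator_roundtrip_preserves_row_count(self, tmp_path, small_dataset):
        records, truth = small_dataset
        records.to_csv(tmp_path / "sim.csv", index=False)
        df = read_measurements(tmp_path / "sim.csv", SYNTHETIC_COLUMN_MAP)
        assert len(df) == truth.n_rows


class TestAggregateReplicates:
    def test_mean_and_sample_sd(self, toy_measurements):
        agg = aggregate_replicates(toy_measurements)
        a1 = agg.loc[agg.variant_id == "A_v1"].iloc[0]
        assert a1.mean_dG == pytest.approx(5.0)
        assert a1.sd_dG == pytest.approx(math.sqrt(2), abs=1e-5)  # √(Σ(x−x̄)²/(n−1))
        assert a1.n_replicates == 2

    def test_singleton_has_no_sd(self, toy_measurements):
        agg = aggregate_replicates(toy_measurements)
        a2 = agg.loc[agg.variant_id == "A_v2"].iloc[0]
        assert a2.mean_dG == pytest.approx(2.5)
        assert math.isnan(a2.sd_dG)

    def test_identical_replicates_have_zero_sd(self, toy_measurements):
        agg = aggregate_replicates(toy_measurements)
        b1 = agg.loc[agg.variant_id == "B_v1"].iloc[0]
        assert b1.sd_dG == pytest.approx(0.0)
        assert b1.n_replicates == 3

    def test_conflicting_de_novo_flags_rejected(self, toy_measurements):
        bad = toy_measurements.copy()
        bad.loc[0, "is_de_novo"] = True
        with pytest.raises(DataConsistencyError):
            aggregate_replicates(bad)

    def test_idempotent_on_already_aggregated_input(self, toy_measurements):
        agg = aggregate_replicates(toy_measurements)
        # one row per group: re-aggregating through the measurement schema
        rows = agg.rename(columns={"mean_dG": "dG", "mean_log_k50": "log_k50"})
        rows["replicate_key"] = "r1"
        again = aggregate_replicates(rows[curation.MEASUREMENT_COLUMNS])
        pd.testing.assert_frame_equal(
            again[["domain_id", "protein_sequence", "mean_dG", "mean_log_k50"]],
            agg[["domain_id", "protein_sequence", "mean_dG", "mean_log_k50"]],
        )
        assert (again.n_replicates == 1).all()


class TestSdFilter:
    @pytest.mark.parametrize(
        "sd_dg, sd_lk, kept",
        [
            (2.5, 0.1, False),  # ΔG scatter above 2 kcal/mol
            (2.0, 0.5, True),  # exactly at both thresholds: retained (strict >)
            (0.1, 0.6, False),  # log K50 scatter above 0.5
            (np.nan, np.nan, True),  # single replicate, no SD defined
        ],
    )
    def test_boundary_behaviour(self, sd_dg, sd_lk, kept):
        df = pd.DataFrame(
            {
                "domain_id": ["A"],
                "variant_id": ["v"],
                "protein_sequence": ["ACDEF"],
                "mean_dG": [1.0],
                "sd_dG": [sd_dg],
                "mean_log_k50": [2.0],
                "sd_log_k50": [sd_lk],
                "n_replicates": [2],
                "is_de_novo": [False],
            }
        )
        out = filter_by_replicate_sd(df, CurationThresholds())
        assert (len(out) == 1) is kept


class TestDomainCountFilter:
    def _curated(self, counts):
        rows = []
        for domain, n in counts.items():
            for i in range(n):
                rows.append((domain, f"{domain}_v{i}", f"seq{domain}{i}", 1.0, 0.1,
                             2.0, 0.1, 2, False))
        return pd.DataFrame(rows, columns=curation.CURATED_COLUMNS)

    @pytest.mark.parametrize("n, kept", [(99, 0), (100, 100), (150, 150)])
    def test_at_least_100_unique_sequences(self, n, kept):
        out, _ = filter_domains_by_count(self._curated({"D": n}), CurationThresholds())
        assert len(out) == kept

    def test_small_domain_dropped_entirely(self):
        out, summary = filter_domains_by_count(
            self._curated({"big": 150, "small": 50}), CurationThresholds()
        )
        assert len(out) == 150
        assert set(out.domain_id) == {"big"}
        assert summary.n_domains_natural == 1


class TestCurateChain:
    def test_planted_bad_replicates_are_exactly_the_removed_set(self, small_dataset):
        records, truth = small_dataset
        agg = aggregate_replicates(records)
        filtered = filter_by_replicate_sd(agg, SMALL_THRESHOLDS)
        removed = set(map(tuple, agg[["domain_id", "protein_sequence"]].itertuples(index=False))) - set(
            map(tuple, filtered[["domain_id", "protein_sequence"]].itertuples(index=False))
        )
        assert removed == truth.planted_bad
        assert len(removed) > 0

    def test_filter_chain_is_monotone(self, small_dataset):
        records, _ = small_dataset
        agg = aggregate_replicates(records)
        after_sd = filter_by_replicate_sd(agg, SMALL_THRESHOLDS)
        after_count, summary = filter_domains_by_count(after_sd, SMALL_THRESHOLDS)
        keys = lambda df: set(map(tuple, df[["domain_id", "protein_sequence"]].itertuples(index=False)))
        assert keys(after_sd) <= keys(agg)
        assert keys(after_count) <= keys(after_sd)
        assert summary.n_after_domain_filter <= summary.n_after_sd_filter

    def test_infinite_thresholds_are_a_no_op(self, small_dataset):
        records, _ = small_dataset
        loose = CurationThresholds(sd_dG_max=float("inf"), sd_logk50_max=float("inf"),
                                   min_seqs_per_domain=1)
        curated, summary = curate(records, loose)
        assert len(curated) == len(aggregate_replicates(records))
        assert summary.n_raw_sequences == summary.n_after_domain_filter

    def test_summary_counts_consistent(self, small_curated):
        curated, summary = small_curated
        assert summary.n_after_domain_filter == len(curated)
        assert summary.n_domains_natural + summary.n_domains_de_novo == curated.domain_id.nunique()

    def test_curation_is_deterministic(self, small_dataset, tmp_path):
        records, _ = small_dataset
        out1, _ = curate(records, SMALL_THRESHOLDS)
        out2, _ = curate(records.copy(), SMALL_THRESHOLDS)
        curation.write_curated(out1, tmp_path / "a.csv")
        curation.write_curated(out2, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
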