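"""Curation of mega-scale proteolysis stability tables.

Raw tables carry one row per assayed molecule: a wildtype domain label, the
variant's amino-acid sequence, and stability readouts (folding free energy
ΔG in kcal/mol and/or log10 K50, the protease concentration at
half-maximal cleavage). The same protein sequence is typically measured
several times through synonymous DNA constructs; curation aggregates those
replicates, discards proteins whose replicate scatter exceeds fixed
standard-deviation thresholds, and drops domains with too few distinct
protein sequences to support per-domain statistics.

The three rules, applied in order:

1. aggregate replicate rows sharing ``(domain_id, protein_sequence)``;
2. remove aggregates whose replicate SD of ΔG exceeds ``sd_dG_max``
   (default 2 kcal/mol) or whose SD of log K50 exceeds ``sd_logk50_max``
   (default 0.5) — strict inequalities, single-replicate records pass;
3. remove every record of a domain with fewer than ``min_seqs_per_domain``
   (default 100) measurements.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataConsistencyError, SchemaError

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA20)

#: Column names as they appear in the Tsuboyama-style deposit; override via
#: ``column_map`` for other layouts. ``replicate_key`` and ``is_de_novo``
#: are optional.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "domain_id": "WT_name",
    "variant_id": "name",
    "protein_sequence": "aa_seq",
    "dG": "dG_ML",
    "log_k50": "log10_K50_ML",
    "replicate_key": "dna_seq",
    "is_de_novo": "is_de_novo",
}

MEASUREMENT_COLUMNS = [
    "domain_id",
    "variant_id",
    "protein_sequence",
    "replicate_key",
    "dG",
    "log_k50",
    "is_de_novo",
]

CURATED_COLUMNS = [
    "domain_id",
    "variant_id",
    "protein_sequence",
    "mean_dG",
    "sd_dG",
    "mean_log_k50",
    "sd_log_k50",
    "n_replicates",
    "is_de_novo",
]


@dataclass(frozen=True)
class CurationThresholds:
    """Filter thresholds; all strictly positive."""

    sd_dG_max: float = 2.0
    sd_logk50_max: float = 0.5
    min_seqs_per_domain: int = 100
    #: ``unique_sequences`` counts post-aggregation protein sequences per
    #: domain; ``raw_measurements`` counts pre-aggregation rows.
    count_mode: str = "unique_sequences"
    #: ddof for the replicate SD estimator (1 = sample SD).
    sd_ddof: int = 1

    def __post_init__(self):
        if self.sd_dG_max <= 0 or self.sd_logk50_max <= 0 or self.min_seqs_per_domain <= 0:
            raise ValueError("curation thresholds must be strictly positive")
        if self.count_mode not in ("unique_sequences", "raw_measurements"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass
class CurationSummary:
    """Bookkeeping counts along the filter chain (monotone non-increasing)."""

    n_raw_rows: int = 0
    n_dropped_rows: int = 0
    n_raw_sequences: int = 0
    n_after_sd_filter: int = 0
    n_after_domain_filter: int = 0
    n_domains_natural: int = 0
    n_domains_de_novo: int = 0
    drop_log: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _valid_sequence(seq: object) -> bool:
    return isinstance(seq, str) and len(seq) > 0 and set(seq) <= _AA_SET


def read_measurements(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a raw stability table into the measurement schema.

    Sequences are uppercased; rows whose sequence leaves the 20-letter
    alphabet, or where ΔG and log K50 are both missing/unparseable, are
    dropped and counted in ``df.attrs["drop_log"]``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    if raw.empty:
        raise SchemaError(f"input file is empty: {path}")
    required = ("domain_id", "variant_id", "protein_sequence", "dG", "log_k50")
    if column_map is None and not all(cmap[f] in raw.columns for f in required) and all(
        f in raw.columns for f in required
    ):
        # file already uses the canonical schema (e.g. generator output)
        cmap = {name: name for name in MEASUREMENT_COLUMNS}
    for field_name in required:
        if cmap[field_name] not in raw.columns:
            raise SchemaError(
                f"mapped column {cmap[field_name]!r} (for {field_name!r}) not in {path.name}"
            )

    df = pd.DataFrame(
        {
            "domain_id": raw[cmap["domain_id"]].astype(str),
            "variant_id": raw[cmap["variant_id"]].astype(str),
            "protein_sequence": raw[cmap["protein_sequence"]].astype(str).str.upper(),
        }
    )
    df["replicate_key"] = (
        raw[cmap["replicate_key"]].astype(str)
        if cmap.get("replicate_key") in raw.columns
        else [str(i) for i in range(len(raw))]
    )
    # censored entries (e.g. "<0.5") fail numeric parsing and become NaN
    df["dG"] = pd.to_numeric(raw[cmap["dG"]], errors="coerce")
    df["log_k50"] = pd.to_numeric(raw[cmap["log_k50"]], errors="coerce")
    if cmap.get("is_de_novo") in raw.columns:
        df["is_de_novo"] = (
            raw[cmap["is_de_novo"]].astype(str).str.lower().isin(("true", "1", "yes"))
        )
    else:
        df["is_de_novo"] = False

    bad_seq = ~df["protein_sequence"].map(_valid_sequence)
    no_value = df["dG"].isna() & df["log_k50"].isna()
    keep = ~(bad_seq | no_value)
    drop_log = {
        "invalid_sequence": int(bad_seq.sum()),
        "no_stability_value": int((no_value & ~bad_seq).sum()),
    }
    if not keep.all():
        logger.info("read_measurements: dropped %d/%d rows (%s)", (~keep).sum(), len(df), drop_log)
    out = df.loc[keep, MEASUREMENT_COLUMNS].reset_index(drop=True)
    out.attrs["drop_log"] = drop_log
    out.attrs["n_raw_rows"] = int(len(raw))
    return out


def aggregate_replicates(records: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Collapse replicate measurements of the same protein sequence.

    Groups by ``(domain_id, protein_sequence)`` regardless of DNA-level
    replicate keys; emits mean and sample SD (ddof=1; SD is NaN for
    singletons) for both readouts plus the replicate count.
    """
    if records.empty:
        raise SchemaError("aggregate_replicates: no records")
    flag_conflicts = records.groupby(["domain_id", "protein_sequence"])["is_de_novo"].nunique()
    if (flag_conflicts > 1).any():
        bad = flag_conflicts[flag_conflicts > 1].index[:5].tolist()
        raise DataConsistencyError(f"conflicting is_de_novo flags within groups: {bad}")

    grouped = records.groupby(["domain_id", "protein_sequence"], sort=True)
    agg = grouped.agg(
        variant_id=("variant_id", "first"),
        mean_dG=("dG", "mean"),
        sd_dG=("dG", lambda s: s.std(ddof=ddof)),
        mean_log_k50=("log_k50", "mean"),
        sd_log_k50=("log_k50", lambda s: s.std(ddof=ddof)),
        n_replicates=("protein_sequence", "size"),
        is_de_novo=("is_de_novo", "first"),
    ).reset_index()
    return agg[CURATED_COLUMNS]


def filter_by_replicate_sd(
    curated: pd.DataFrame, thresholds: CurationThresholds = CurationThresholds()
) -> pd.DataFrame:
    """Drop aggregates with excessive replicate scatter.

    Removal requires ``sd_dG > sd_dG_max`` OR ``sd_log_k50 > sd_logk50_max``
    (strict); records without a defined SD (single replicate) are retained.
    """
    sd_dg = curated["sd_dG"]
    sd_lk = curated["sd_log_k50"]
    bad = (sd_dg > thresholds.sd_dG_max) | (sd_lk > thresholds.sd_logk50_max)
    bad = bad.fillna(False)
    return curated.loc[~bad].reset_index(drop=True)


def filter_domains_by_count(
    curated: pd.DataFrame,
    thresholds: CurationThresholds = CurationThresholds(),
    raw_counts: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, CurationSummary]:
    """Drop whole domains with too few measurements.

    Under the default ``unique_sequences`` mode the per-domain count is the
    number of distinct protein sequences after aggregation; under
    ``raw_measurements`` it is the pre-aggregation row count (requires
    ``raw_counts``).
    """
    if thresholds.count_mode == "raw_measurements":
        if raw_counts is None:
            raise ValueError("raw_measurements count_mode requires raw_counts")
        counts = pd.Series(raw_counts)
    else:
        counts = curated.groupby("domain_id")["protein_sequence"].nunique()
    keep_domains = set(counts[counts >= thresholds.min_seqs_per_domain].index)
    out = curated.loc[curated["domain_id"].isin(keep_domains)].reset_index(drop=True)

    domains = out.drop_duplicates("domain_id")
    summary = CurationSummary(
        n_after_sd_filter=len(curated),
        n_after_domain_filter=len(out),
        n_domains_natural=int((~domains["is_de_novo"]).sum()),
        n_domains_de_novo=int(domains["is_de_novo"].sum()),
    )
    return out, summary


def curate(
    records: pd.DataFrame, thresholds: CurationThresholds = CurationThresholds()
) -> tuple[pd.DataFrame, CurationSummary]:
    """Full chain: aggregate → SD filter → domain-count filter."""
    agg = aggregate_replicates(records, ddof=thresholds.sd_ddof)
    after_sd = filter_by_replicate_sd(agg, thresholds)
    raw_counts = records.groupby("domain_id").size().to_dict()
    out, summary = filter_domains_by_count(after_sd, thresholds, raw_counts=raw_counts)
    summary.n_raw_rows = int(records.attrs.get("n_raw_rows", len(records)))
    summary.n_dropped_rows = sum(records.attrs.get("drop_log", {}).values())
    summary.n_raw_sequences = len(agg)
    summary.drop_log = dict(records.attrs.get("drop_log", {}))
    logger.info(
        "curate: %d aggregated -> %d after SD filter -> %d after domain filter "
        "(%d natural + %d de novo domains)",
        summary.n_raw_sequences,
        summary.n_after_sd_filter,
        summary.n_after_domain_filter,
        summary.n_domains_natural,
        summary.n_domains_de_novo,
    )
    return out, summary


def write_curated(curated: pd.DataFrame, path: str | Path) -> None:
    curated.to_csv(path, index=False, columns=CURATED_COLUMNS, float_format="%.6g")


def read_curated(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CURATED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"curated table missing columns: {sorted(missing)}")
    return df


def wildtype_sequences(curated: pd.DataFrame) -> dict[str, str]:
    """Wildtype sequence per domain: the modal-length most frequent variant.

    Synthetic and deposit tables both include the unmutated sequence; it is
    identified as the variant whose ``variant_id`` marks it as wildtype when
    such a label exists, otherwise the first sequence of the domain.
    """
    out: dict[str, str] = {}
    for domain_id, grp in curated.groupby("domain_id"):
        wt_mask = grp["variant_id"].str.contains("wt|wild", case=False, regex=True)
        row = grp.loc[wt_mask].iloc[0] if wt_mask.any() else grp.iloc[0]
        out[str(domain_id)] = row["protein_sequence"]
    return out
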