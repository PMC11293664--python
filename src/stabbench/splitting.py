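"""Two-layer train/validation/test splitting of curated stability data.

The dataset is hierarchical: domains hold mutants. Generalization is
therefore measured at two levels, and the split has two layers:

1. a fraction of whole domains (default 10%) is drawn uniformly at random
   and every one of their mutants is held out ("test_only" domains) —
   these measure cross-domain extrapolation;
2. mutants of the remaining ("core") domains are assigned to
   train/validation/test at an 80/10/10 ratio, stratified by domain so
   every core domain populates all three sets when large enough.

``validate_split`` audits the result for sequence-level leakage between
train and any test partition, domain atomicity, coverage, and realized
ratios.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

SPLIT_LABELS = ("train", "validation", "test", "test_only")

ASSIGNMENT_COLUMNS = ["domain_id", "variant_id", "protein_sequence", "split_label", "seed"]


@dataclass(frozen=True)
class SplitConfig:
    """Proportions and seed for the two-layer split."""

    test_only_domain_fraction: float = 0.10
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)  # train, validation, test
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.test_only_domain_fraction < 1):
            raise ConfigError("test_only_domain_fraction must lie in (0, 1)")
        if any(r < 0 for r in self.ratios) or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigError("ratios must be non-negative and sum to 1")


def split_domains(
    domain_ids: Iterable[str], config: SplitConfig
) -> tuple[list[str], list[str]]:
    """Draw the held-out domain layer.

    ``floor(fraction * n_domains)`` domains (minimum 1; a warning is
    emitted when the floor was 0) are drawn uniformly without replacement
    under ``config.seed``. Returns ``(core, test_only)``, each sorted.
    """
    ids = sorted(set(map(str, domain_ids)))
    if len(ids) < 2:
        raise ConfigError(f"need at least 2 domains to split, got {len(ids)}")
    n_test = math.floor(config.test_only_domain_fraction * len(ids))
    if n_test == 0:
        warnings.warn(
            "test_only fraction floors to 0 domains; drawing 1 so the "
            "held-out layer is non-empty",
            stacklevel=2,
        )
        n_test = 1
    rng = np.random.default_rng(config.seed)
    test_only = sorted(rng.choice(ids, size=n_test, replace=False).tolist())
    core = sorted(set(ids) - set(test_only))
    logger.info("split_domains: %d core, %d test_only (seed=%d)", len(core), n_test, config.seed)
    return core, test_only


def _domain_counts(n: int, ratios: Sequence[float]) -> tuple[int, int, int]:
    """Per-domain (train, validation, test) counts.

    Non-zero validation/test ratios get at least one record each (so
    per-domain rank statistics are computable); train takes the remainder.
    """
    r_train, r_val, r_test = ratios
    n_val = max(1, round(n * r_val)) if r_val > 0 else 0
    n_test = max(1, round(n * r_test)) if r_test > 0 else 0
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def split_mutants(core_records: pd.DataFrame, config: SplitConfig) -> pd.DataFrame:
    """Assign core-domain mutants to train/validation/test.

    Stratified by domain: within each domain, records are permuted under
    the seeded RNG and sliced into the three sets at the configured ratios
    (largest-remainder counts). Domains with fewer than 3 records cannot
    populate all sets and fall back to train with a warning.
    """
    rng = np.random.default_rng(config.seed + 1)
    pieces = []
    for domain_id in sorted(core_records["domain_id"].unique()):
        grp = core_records.loc[core_records["domain_id"] == domain_id]
        n = len(grp)
        labels = np.empty(n, dtype=object)
        if n < 3 and (config.ratios[1] > 0 or config.ratios[2] > 0):
            warnings.warn(
                f"domain {domain_id!r} has {n} record(s), too few for all "
                "three sets; assigning all to train",
                stacklevel=2,
            )
            labels[:] = "train"
        else:
            n_train, n_val, n_test = _domain_counts(n, config.ratios)
            order = rng.permutation(n)
            labels[order[:n_train]] = "train"
            labels[order[n_train : n_train + n_val]] = "validation"
            labels[order[n_train + n_val :]] = "test"
        piece = grp[["domain_id", "variant_id", "protein_sequence"]].copy()
        piece["split_label"] = labels
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    out["seed"] = config.seed
    return out[ASSIGNMENT_COLUMNS]


def make_assignment(curated: pd.DataFrame, config: SplitConfig) -> pd.DataFrame:
    """Full two-layer split of a curated table into an assignment table."""
    core, test_only = split_domains(curated["domain_id"].unique(), config)
    core_records = curated.loc[curated["domain_id"].isin(core)]
    assignment = split_mutants(core_records, config)
    held = curated.loc[curated["domain_id"].isin(test_only),
                       ["domain_id", "variant_id", "protein_sequence"]].copy()
    held["split_label"] = "test_only"
    held["seed"] = config.seed
    return pd.concat([assignment, held], ignore_index=True)[ASSIGNMENT_COLUMNS]


@dataclass
class SplitAudit:
    """Outcome of ``validate_split``: per-check pass/fail with offenders."""

    passed: bool
    checks: dict = field(default_factory=dict)
    realized_ratios: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def validate_split(assignment: pd.DataFrame, curated: pd.DataFrame) -> SplitAudit:
    """Audit an assignment for leakage and coverage.

    Checks: (i) no protein sequence assigned to train (or validation) also
    appears in test or test_only; (ii) no domain contributes records to
    both the core and test_only layers; (iii) every curated record is
    labelled exactly once. Duplicate sequences shared across *different*
    domains are reported as warnings, not failures.
    """
    checks: dict[str, dict] = {}

    train_like = assignment.loc[assignment["split_label"].isin(("train", "validation"))]
    test_like = assignment.loc[assignment["split_label"].isin(("test", "test_only"))]
    leaked = sorted(set(train_like["protein_sequence"]) & set(test_like["protein_sequence"]))
    checks["no_sequence_leakage"] = {
        "passed": not leaked,
        "offending": leaked[:20],
        "n_offending": len(leaked),
    }

    by_domain = assignment.groupby("domain_id")["split_label"].agg(set)
    mixed = sorted(
        d for d, labels in by_domain.items() if "test_only" in labels and len(labels) > 1
    )
    checks["domain_atomicity"] = {"passed": not mixed, "offending": mixed[:20],
                                  "n_offending": len(mixed)}

    key = ["domain_id", "protein_sequence"]
    curated_keys = set(map(tuple, curated[key].itertuples(index=False)))
    assigned_keys = set(map(tuple, assignment[key].itertuples(index=False)))
    dup = int(assignment.duplicated(key).sum())
    missing = sorted(curated_keys - assigned_keys)
    extra = sorted(assigned_keys - curated_keys)
    checks["full_coverage"] = {
        "passed": not missing and not extra and dup == 0,
        "n_missing": len(missing),
        "n_extra": len(extra),
        "n_duplicate_labels": dup,
        "offending": [list(k) for k in (missing + extra)[:20]],
    }

    counts = assignment["split_label"].value_counts()
    core_n = int(counts.reindex(("train", "validation", "test")).fillna(0).sum())
    realized = {
        label: (int(counts.get(label, 0)) / core_n if core_n and label != "test_only"
                else int(counts.get(label, 0)) / max(len(assignment), 1))
        for label in SPLIT_LABELS
    }

    warn: list[str] = []
    seq_domains = assignment.groupby("protein_sequence")["domain_id"].nunique()
    n_cross = int((seq_domains > 1).sum())
    if n_cross:
        warn.append(f"{n_cross} protein sequence(s) shared across different domain_ids")

    passed = all(c["passed"] for c in checks.values())
    if not passed:
        failed = [name for name, c in checks.items() if not c["passed"]]
        logger.warning("validate_split: FAILED checks %s", failed)
    return SplitAudit(passed=passed, checks=checks, realized_ratios=realized, warnings=warn)


def assignment_hash(assignment: pd.DataFrame) -> str:
    """Order-insensitive fingerprint of an assignment (provenance)."""
    canon = assignment.sort_values(["domain_id", "protein_sequence"]).reset_index(drop=True)
    payload = canon[ASSIGNMENT_COLUMNS].to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
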