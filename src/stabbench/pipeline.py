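"""End-to-end orchestration: curate → split → match → train → evaluate →
compare → recalibrate, as one reproducible, manifest-tracked run.

A run directory holds one artifact file per stage plus ``run.json``, a
manifest recording the config, the global seed, per-stage status and the
SHA-256 of every artifact. Re-running with ``resume=True`` skips stages
whose artifacts are present and checksum-clean; a failed stage marks the
manifest and downstream stages are not run.

All stage randomness flows from the single global seed (small fixed
offsets per stage, kept below 2**31).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curation, evaluation, predictors, sequence_matching, splitting, synthetic_data
from .errors import StageError

logger = logging.getLogger(__name__)

STAGES = ["curate", "split", "match", "train", "evaluate", "compare", "recalibrate"]


@dataclass
class RunConfig:
    """Nested per-stage configuration blocks; YAML round-trippable."""

    seed: int = 0
    out_dir: str = "runs/run"
    run_id: str = "run"
    input_csv: str | None = None  # real-data path; None -> simulate block
    column_map: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)  # SyntheticConfig overrides
    curation: dict = field(default_factory=dict)  # CurationThresholds overrides
    split: dict = field(default_factory=dict)  # SplitConfig overrides
    match: dict = field(default_factory=lambda: {"evalue_cutoff": 1e-3})
    train: dict = field(default_factory=lambda: {"model_family": "kmer_ridge"})
    compare: dict = field(default_factory=lambda: {"min_records": 30})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    def __init__(self, run_dir: Path, config: RunConfig):
        self.path = run_dir / "run.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "run_id": config.run_id,
                "seed": config.seed,
                "config": dataclasses.asdict(config),
                "stage_order": STAGES,
                "input": {},
                "stages": {},
            }

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))

    def record(self, stage: str, status: str, artifacts: dict[str, Path],
               extra: dict | None = None) -> None:
        self.data["stages"][stage] = {
            "status": status,
            "artifacts": {
                name: {"path": p.name, "sha256": _sha256(p)} for name, p in artifacts.items()
            },
            **(extra or {}),
        }
        self.save()

    def stage_clean(self, stage: str, run_dir: Path) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry or entry["status"] != "passed":
            return False
        for art in entry["artifacts"].values():
            p = run_dir / art["path"]
            if not p.exists() or _sha256(p) != art["sha256"]:
                return False
        return True


def _train_cfg(config: RunConfig) -> predictors.TrainingConfig:
    overrides = {k: v for k, v in config.train.items() if k != "model_family"}
    overrides.setdefault("seed", config.seed + 2)
    return predictors.TrainingConfig(**overrides)


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute all stages, returning the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(run_dir, config)
    config.to_yaml(run_dir / "config.yaml")

    # --- input: real table or synthetic drop-in ---------------------------
    if config.input_csv:
        measurements = curation.read_measurements(config.input_csv, config.column_map)
        manifest.data["input"] = {"path": str(config.input_csv),
                                  "sha256": _sha256(Path(config.input_csv))}
    else:
        sim_cfg = synthetic_data.SyntheticConfig(
            **{"seed": config.seed, **config.simulate}
        )
        measurements, truth = synthetic_data.generate_dataset(sim_cfg)
        synthetic_data.write_dataset(measurements, truth, run_dir)
        manifest.data["input"] = {
            "path": "measurements.csv",
            "sha256": _sha256(run_dir / "measurements.csv"),
            "synthetic": True,
        }
    manifest.save()

    state: dict = {}
    for stage in STAGES:
        if resume and manifest.stage_clean(stage, run_dir):
            logger.info("stage %s: clean, skipping", stage)
            _load_stage_outputs(stage, run_dir, state)
            continue
        try:
            _run_stage(stage, config, run_dir, manifest, state, measurements)
        except Exception as exc:
            manifest.record(stage, "failed", {}, {"error": str(exc)})
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return run_dir


def _run_stage(stage, config, run_dir, manifest, state, measurements):
    if stage == "curate":
        thresholds = curation.CurationThresholds(**config.curation)
        curated, summary = curation.curate(measurements, thresholds)
        curation.write_curated(curated, run_dir / "curated.csv")
        summary.to_json(run_dir / "curation_summary.json")
        wts = curation.wildtype_sequences(curated)
        with open(run_dir / "wildtypes.fasta", "w") as fh:
            for did in sorted(wts):
                fh.write(f">{did}\n{wts[did]}\n")
        state.update(curated=curated, wildtypes=wts)
        manifest.record(stage, "passed", {
            "curated": run_dir / "curated.csv",
            "summary": run_dir / "curation_summary.json",
            "wildtypes": run_dir / "wildtypes.fasta",
        })

    elif stage == "split":
        split_cfg = splitting.SplitConfig(**{"seed": config.seed, **config.split})
        assignment = splitting.make_assignment(state["curated"], split_cfg)
        audit = splitting.validate_split(assignment, state["curated"])
        assignment.to_csv(run_dir / "assignment.csv", index=False)
        audit.to_json(run_dir / "split_audit.json")
        if not audit.passed:
            raise StageError("split audit failed; see split_audit.json")
        state.update(assignment=assignment)
        manifest.record(stage, "passed", {
            "assignment": run_dir / "assignment.csv",
            "audit": run_dir / "split_audit.json",
        })

    elif stage == "match":
        assignment, wts = state["assignment"], state["wildtypes"]
        test_only = sorted(assignment.loc[assignment.split_label == "test_only", "domain_id"].unique())
        core = sorted(set(wts) - set(test_only))
        training_wts = {d: wts[d] for d in core}
        cutoff = config.match.get("evalue_cutoff", 1e-3)
        matches, identity = [], {}
        for did in test_only:
            m = sequence_matching.match_closest_training_domain(
                did, wts[did], training_wts, evalue_cutoff=cutoff)
            matches.append(m)
            identity[did] = m.identity_pct if m.match_type == "sequence" else 0.0
        identity.update({d: 100.0 for d in core})  # own wildtype is in training
        match_df = pd.DataFrame(
            [dataclasses.asdict(m) for m in matches],
            columns=["test_only_domain_id", "matched_train_domain_id", "match_type",
                     "identity_pct", "tm_score"],
        )
        match_df.to_csv(run_dir / "matches.csv", index=False)
        pd.Series(identity, name="max_identity_pct").rename_axis("domain_id").to_csv(
            run_dir / "identity.csv")
        state.update(matches=matches, identity=identity)
        manifest.record(stage, "passed", {
            "matches": run_dir / "matches.csv",
            "identity": run_dir / "identity.csv",
        })

    elif stage == "train":
        curated, assignment = state["curated"], state["assignment"]
        merged = curated.merge(assignment[["domain_id", "protein_sequence", "split_label"]],
                               on=["domain_id", "protein_sequence"])
        family = config.train.get("model_family", "kmer_ridge")
        predictor, log = predictors.train_predictor(
            family,
            merged.loc[merged.split_label == "train"],
            merged.loc[merged.split_label == "validation"],
            _train_cfg(config),
        )
        predictors.save_predictor(predictor, run_dir / "collective_model")
        eval_rows = merged.loc[merged.split_label.isin(("test", "test_only"))]
        preds = eval_rows[["domain_id", "protein_sequence"]].copy()
        preds["predicted_dG"] = predictor.predict(eval_rows["protein_sequence"].tolist())
        preds.to_csv(run_dir / "predictions.csv", index=False)
        (run_dir / "training_log.json").write_text(json.dumps(dataclasses.asdict(log), indent=2))
        state.update(merged=merged, collective=predictor, predictions=preds)
        manifest.record(stage, "passed", {
            "model": run_dir / "collective_model.json",
            "weights": run_dir / "collective_model.npz",
            "predictions": run_dir / "predictions.csv",
            "training_log": run_dir / "training_log.json",
        }, {"best_step": log.best_step})

    elif stage == "evaluate":
        evals = evaluation.evaluate_per_domain(
            state["predictions"], state["curated"], state["assignment"], state["identity"])
        evals.to_csv(run_dir / "per_domain_evaluation.csv", index=False)
        state.update(evals=evals)
        manifest.record(stage, "passed",
                        {"per_domain_evaluation": run_dir / "per_domain_evaluation.csv"})

    elif stage == "compare":
        merged, matches = state["merged"], state["matches"]
        matched = {m.test_only_domain_id: m.matched_train_domain_id
                   for m in matches if m.matched_train_domain_id}
        result: dict
        if not matched:
            result = {"status": "not_applicable",
                      "reason": "no test-set-only domain could be matched"}
            state.update(comparison=None)
        else:
            ensemble, skip_log = predictors.train_single_domain_ensemble(
                merged, config.train.get("model_family", "kmer_ridge"),
                _train_cfg(config), min_records=config.compare.get("min_records", 30),
                domains=sorted(set(matched.values())),
            )
            single_preds = []
            for test_dom, train_dom in sorted(matched.items()):
                if train_dom not in ensemble:
                    continue
                rows = merged.loc[merged.domain_id == test_dom,
                                  ["domain_id", "protein_sequence"]].copy()
                rows["predicted_dG"] = ensemble[train_dom].predict(
                    rows["protein_sequence"].tolist())
                single_preds.append(rows)
            if not single_preds:
                result = {"status": "not_applicable",
                          "reason": "all matched training domains were skipped"}
                state.update(comparison=None)
            else:
                sp = pd.concat(single_preds, ignore_index=True)
                covered = state["assignment"].loc[
                    state["assignment"].domain_id.isin(sp.domain_id.unique())]
                evals_single = evaluation.evaluate_per_domain(
                    sp, state["curated"], covered, state["identity"],
                    partitions=("test_only",))
                evals_collective = state["evals"].loc[
                    state["evals"].partition == "test_only"]
                comparison = evaluation.compare_collective_vs_single(
                    evals_collective, evals_single)
                result = {"status": "ok", **comparison.to_dict(), "skipped": skip_log}
                state.update(comparison=comparison)
        (run_dir / "comparison.json").write_text(json.dumps(result, indent=2))
        manifest.record(stage, "passed", {"comparison": run_dir / "comparison.json"})

    elif stage == "recalibrate":
        scored = state["predictions"].merge(
            state["curated"][["domain_id", "protein_sequence", "mean_dG"]],
            on=["domain_id", "protein_sequence"])
        test_only = state["assignment"].loc[
            state["assignment"].split_label == "test_only",
            ["domain_id", "protein_sequence"]]
        scored = scored.merge(test_only, on=["domain_id", "protein_sequence"])
        recal = evaluation.recalibrate_per_domain(scored)
        recal.to_csv(run_dir / "recalibration.csv", index=False)
        state.update(recalibration=recal)
        manifest.record(stage, "passed", {"recalibration": run_dir / "recalibration.csv"})

    else:  # pragma: no cover
        raise StageError(f"unknown stage {stage!r}")


def _load_stage_outputs(stage: str, run_dir: Path, state: dict) -> None:
    """Rehydrate state from artifacts when resuming past a clean stage."""
    if stage == "curate":
        state["curated"] = curation.read_curated(run_dir / "curated.csv")
        wts = {}
        for line in (run_dir / "wildtypes.fasta").read_text().split(">")[1:]:
            head, seq = line.split("\n", 1)
            wts[head.strip()] = seq.replace("\n", "")
        state["wildtypes"] = wts
    elif stage == "split":
        state["assignment"] = pd.read_csv(run_dir / "assignment.csv")
    elif stage == "match":
        ident = pd.read_csv(run_dir / "identity.csv", index_col=0)
        state["identity"] = ident["max_identity_pct"].to_dict()
        mdf = pd.read_csv(run_dir / "matches.csv")
        state["matches"] = [
            sequence_matching.DomainMatch(
                test_only_domain_id=r.test_only_domain_id,
                matched_train_domain_id=(None if pd.isna(r.matched_train_domain_id)
                                         else r.matched_train_domain_id),
                match_type=r.match_type,
                identity_pct=(None if pd.isna(r.identity_pct) else r.identity_pct),
                tm_score=(None if pd.isna(r.tm_score) else r.tm_score),
            )
            for r in mdf.itertuples()
        ]
    elif stage == "train":
        state["predictions"] = pd.read_csv(run_dir / "predictions.csv")
        state["collective"] = predictors.load_predictor(run_dir / "collective_model")
        state["merged"] = state["curated"].merge(
            state["assignment"][["domain_id", "protein_sequence", "split_label"]],
            on=["domain_id", "protein_sequence"])
    elif stage == "evaluate":
        state["evals"] = pd.read_csv(run_dir / "per_domain_evaluation.csv")
    elif stage == "compare":
        state["comparison"] = json.loads((run_dir / "comparison.json").read_text())
    elif stage == "recalibrate":
        state["recalibration"] = pd.read_csv(run_dir / "recalibration.csv")


def report(run_dir: str | Path) -> dict:
    """Summary tables of a completed run.

    Returns curation summary, per-domain evaluation, comparison and
    recalibration; raises on missing artifacts or checksum mismatches.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "run.json"
    if not manifest_path.exists():
        raise StageError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    missing = [s for s in STAGES
               if manifest["stages"].get(s, {}).get("status") != "passed"]
    if missing:
        raise StageError(f"run incomplete; stages not passed: {missing}")
    for stage, entry in manifest["stages"].items():
        for name, art in entry["artifacts"].items():
            p = run_dir / art["path"]
            if not p.exists():
                raise StageError(f"missing artifact {art['path']} (stage {stage})")
            if _sha256(p) != art["sha256"]:
                raise StageError(f"checksum mismatch for {art['path']} (stage {stage})")

    comparison = json.loads((run_dir / "comparison.json").read_text())
    return {
        "curation_summary": json.loads((run_dir / "curation_summary.json").read_text()),
        "per_domain_evaluation": pd.read_csv(run_dir / "per_domain_evaluation.csv"),
        "comparison": comparison,
        "recalibration": pd.read_csv(run_dir / "recalibration.csv"),
    }
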