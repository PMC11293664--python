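"""Synthetic mega-scale-style stability datasets with known ground truth.

Emulates the structure of a cDNA-display proteolysis deposit: hundreds of
small wildtype domains (40–72 aa, a mix of natural-like and de-novo-like
labels), each with a cloud of point mutants, insertions and deletions,
measured in replicate with Gaussian noise on both ΔG and a monotone
affine log K50 surrogate. A configurable fraction of variants is planted
with deliberately inconsistent replicates whose standard deviation is
guaranteed to exceed the curation thresholds — the curation filters must
remove exactly those.

The stability landscape is additive by construction: every domain obeys
one global stability rule defined on adjacent residue pairs (a 20×20
weight table summed over the sequence), plus a smaller domain-specific
per-position substitution table that does not transfer. The pair rule is
the reason collective training genuinely helps: a single domain's mutants
sample only the pair contexts of its own backbone, too sparsely to pin
down the 400 shared weights, while pooled training covers the pair space
densely — so a model trained on all domains ranks an unseen domain's
mutants better than one trained on any single (even homologous) domain.
A subset of domains is generated as homolog pairs at controlled sequence
identity to exercise identity-stratified evaluation; all other domains
are unrelated random sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .curation import AA20, MEASUREMENT_COLUMNS
from .errors import ConfigError
from . import sequence_matching

_AA = np.array(list(AA20))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults give a desk-scale analogue of the real deposit."""

    n_domains: int = 40
    length_range: tuple[int, int] = (40, 72)  # wildtype length envelope (aa)
    fraction_de_novo: float = 0.44  # cosmetic label mix
    mutants_per_domain: tuple[int, int] = (120, 220)
    mutation_weights: Mapping[str, float] = field(
        default_factory=lambda: {"substitution": 0.8, "insertion": 0.1, "deletion": 0.1}
    )
    max_mutations: int = 3  # edits per variant, 1..max
    shared_effect_sd: float = 0.5  # kcal/mol per adjacent residue pair, global rule
    domain_effect_sd: float = 0.2  # kcal/mol, domain-private substitution table
    epistasis_sd: float = 0.0  # optional pairwise term, off by default
    wildtype_dG_range: tuple[float, float] = (1.0, 5.0)  # kcal/mol
    replicate_count_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.3, 2: 0.5, 3: 0.2}
    )
    replicate_noise_sd: float = 0.3  # kcal/mol
    planted_bad_replicate_fraction: float = 0.02
    planted_sd_dG: float = 3.0  # guaranteed replicate SD of planted variants
    logk50_slope: float = 0.55
    logk50_intercept: float = 1.2
    logk50_noise_sd: float = 0.05
    n_homolog_pairs: int = 12
    homolog_identity_range: tuple[float, float] = (45.0, 95.0)
    seed: int = 0

    def __post_init__(self):
        if self.replicate_noise_sd < 0 or self.logk50_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if 2 * self.n_homolog_pairs > self.n_domains:
            raise ConfigError(
                f"{self.n_homolog_pairs} homolog pairs need "
                f"{2 * self.n_homolog_pairs} domains, have {self.n_domains}"
            )
        if self.length_range[0] < 10 or self.length_range[1] < self.length_range[0]:
            raise ConfigError("invalid length_range")


@dataclass
class GroundTruth:
    """Everything a test oracle needs about a generated dataset."""

    true_dG: dict  # (domain_id, protein_sequence) -> ΔG (kcal/mol)
    planted_bad: set  # keys of variants built to violate the SD filter
    wildtypes: dict  # domain_id -> wildtype sequence
    wildtype_dG: dict  # domain_id -> wildtype ΔG
    is_de_novo: dict  # domain_id -> bool
    shared_weights: dict  # adjacent residue pair "ab" -> kcal/mol, the transferable rule
    homolog_pairs: list  # (domain_a, domain_b, target_identity_pct)
    relatedness: dict  # domain_id -> list of related domain_ids
    n_rows: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_dG": {f"{d}\t{s}": v for (d, s), v in self.true_dG.items()},
            "planted_bad": sorted(f"{d}\t{s}" for d, s in self.planted_bad),
            "wildtypes": self.wildtypes,
            "wildtype_dG": self.wildtype_dG,
            "is_de_novo": self.is_de_novo,
            "shared_weights": self.shared_weights,
            "homolog_pairs": self.homolog_pairs,
            "relatedness": self.relatedness,
            "n_rows": self.n_rows,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def make_homolog_pair(
    wildtype: str, target_identity: float, rng: np.random.Generator | None = None
) -> str:
    """Derive a homolog of ``wildtype`` at ``target_identity`` percent.

    Identity is measured with the package's own local-alignment metric and
    the substitution count is adjusted until the measured identity lands
    within ±3 percentage points of the target.
    """
    if not (0 < target_identity <= 100):
        raise ConfigError("target identity must be in (0, 100]")
    rng = rng or np.random.default_rng(0)
    L = len(wildtype)
    if target_identity == 100:
        return wildtype
    if 100.0 / L > 6.0:
        raise ConfigError(f"sequence of length {L} too short for ±3-point identity control")

    k = int(round((1 - target_identity / 100) * L))
    for _ in range(25):
        k = min(max(k, 1), L - 1)
        # evenly spaced interior substitutions avoid end-clipping by the
        # local aligner
        positions = np.linspace(0, L - 1, k + 2)[1:-1].round().astype(int)
        seq = list(wildtype)
        for pos in np.unique(positions):
            choices = [a for a in AA20 if a != wildtype[pos]]
            seq[pos] = rng.choice(choices)
        candidate = "".join(seq)
        hit = sequence_matching.pairwise_local_alignment(wildtype, candidate)
        measured = hit.percent_identity if hit else 0.0
        if abs(measured - target_identity) <= 3.0:
            return candidate
        k += 1 if measured > target_identity else -1
    raise ConfigError(
        f"could not reach {target_identity:.1f}% identity on a {L}-mer within tolerance"
    )


def _mutate(
    wildtype: str, rng: np.random.Generator, config: SyntheticConfig
) -> tuple[str, list[tuple[int, str, str]]]:
    """One variant: returns (sequence, substitution list of (pos, old, new)).

    Substitutions are tracked for the domain-private effect table; indels
    contribute through the shared composition rule only.
    """
    kinds = list(config.mutation_weights)
    weights = np.array([config.mutation_weights[k] for k in kinds], dtype=float)
    weights /= weights.sum()
    n_edits = int(rng.integers(1, config.max_mutations + 1))
    seq = list(wildtype)
    subs: list[tuple[int, str, str]] = []
    for _ in range(n_edits):
        kind = rng.choice(kinds, p=weights)
        if kind == "deletion" and len(seq) > config.length_range[0]:
            del seq[int(rng.integers(0, len(seq)))]
        elif kind == "insertion" and len(seq) < config.length_range[1] + config.max_mutations:
            seq.insert(int(rng.integers(0, len(seq) + 1)), str(rng.choice(_AA)))
        else:
            pos = int(rng.integers(0, len(wildtype)))
            old = wildtype[pos]
            new = str(rng.choice([a for a in AA20 if a != old]))
            # apply at the original coordinate if still present
            if pos < len(seq) and seq[pos] == old:
                seq[pos] = new
                subs.append((pos, old, new))
    return "".join(seq), subs


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a raw measurement table plus its ground truth.

    Byte-identical across runs for a fixed config (single seeded RNG).
    """
    rng = np.random.default_rng(config.seed)
    shared_w = {
        a + b: w
        for (a, b), w in zip(
            ((a, b) for a in AA20 for b in AA20),
            rng.normal(0.0, config.shared_effect_sd, len(AA20) ** 2),
        )
    }

    n_de_novo = int(round(config.fraction_de_novo * config.n_domains))
    domain_ids = [f"dn_{i:03d}" if i < n_de_novo else f"nat_{i:03d}"
                  for i in range(config.n_domains)]

    wildtypes: dict[str, str] = {}
    homolog_pairs: list[tuple[str, str, float]] = []
    relatedness: dict[str, list[str]] = {d: [] for d in domain_ids}
    lo, hi = config.homolog_identity_range
    pair_partners = {}
    for j in range(config.n_homolog_pairs):
        a, b = domain_ids[2 * j], domain_ids[2 * j + 1]
        target = float(rng.uniform(lo, hi))
        pair_partners[b] = (a, target)
        homolog_pairs.append((a, b, target))
        relatedness[a].append(b)
        relatedness[b].append(a)
    for d in domain_ids:
        if d in pair_partners:
            parent, target = pair_partners[d]
            wildtypes[d] = make_homolog_pair(wildtypes[parent], target, rng)
        else:
            length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            wildtypes[d] = _random_sequence(rng, length)

    rep_counts = np.array(list(config.replicate_count_weights))
    rep_probs = np.array(list(config.replicate_count_weights.values()), dtype=float)
    rep_probs /= rep_probs.sum()

    rows = []
    truth = GroundTruth(
        true_dG={}, planted_bad=set(), wildtypes=dict(wildtypes), wildtype_dG={},
        is_de_novo={d: d.startswith("dn_") for d in domain_ids},
        shared_weights=shared_w, homolog_pairs=homolog_pairs, relatedness=relatedness,
    )

    def comp_dG(seq: str) -> float:
        return float(sum(shared_w[seq[i : i + 2]] for i in range(len(seq) - 1)))

    for domain_id in domain_ids:
        wt = wildtypes[domain_id]
        wt_dG = float(rng.uniform(*config.wildtype_dG_range))
        truth.wildtype_dG[domain_id] = wt_dG
        base = wt_dG - comp_dG(wt)  # domain offset pinning the wildtype ΔG
        u_table = rng.normal(0.0, config.domain_effect_sd, (len(wt), len(AA20)))
        aa_index = {a: i for i, a in enumerate(AA20)}

        n_mutants = int(rng.integers(*config.mutants_per_domain))
        variants: dict[str, float] = {wt: wt_dG}
        while len(variants) < n_mutants + 1:
            seq, subs = _mutate(wt, rng, config)
            if seq in variants:
                continue
            dg = base + comp_dG(seq) + sum(u_table[pos, aa_index[new]] for pos, _, new in subs)
            if config.epistasis_sd > 0 and len(subs) > 1:
                dg += float(rng.normal(0, config.epistasis_sd))
            variants[seq] = dg

        seq_list = list(variants)
        n_planted = int(round(config.planted_bad_replicate_fraction * len(seq_list)))
        planted = set(
            rng.choice(range(1, len(seq_list)), size=n_planted, replace=False).tolist()
        ) if n_planted else set()

        for vi, seq in enumerate(seq_list):
            dg_true = variants[seq]
            truth.true_dG[(domain_id, seq)] = dg_true
            variant_id = f"{domain_id}_wt" if vi == 0 else f"{domain_id}_v{vi:04d}"
            if vi in planted:
                truth.planted_bad.add((domain_id, seq))
                # two replicates split symmetrically: sample SD = planted_sd_dG
                d = config.planted_sd_dG / np.sqrt(2)
                dgs = [dg_true - d, dg_true + d]
            else:
                n_rep = int(rng.choice(rep_counts, p=rep_probs))
                dgs = (dg_true + rng.normal(0, config.replicate_noise_sd, n_rep)).tolist()
            for ri, dg_obs in enumerate(dgs):
                logk = (config.logk50_slope * dg_true + config.logk50_intercept
                        + float(rng.normal(0, config.logk50_noise_sd)))
                rows.append(
                    (domain_id, variant_id, seq, f"{variant_id}_r{ri}", dg_obs, logk,
                     truth.is_de_novo[domain_id])
                )

    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    truth.n_rows = len(df)
    df.attrs["n_raw_rows"] = len(df)
    df.attrs["drop_log"] = {}
    return df, truth


def write_dataset(df: pd.DataFrame, truth: GroundTruth, out_dir: str | Path) -> None:
    """Drop-in raw CSV (curation's default schema via identity column map) + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "measurements.csv", index=False, float_format="%.6g")
    truth.to_json(out_dir / "ground_truth.json")


#: Column map for reading generator output back through ``read_measurements``.
SYNTHETIC_COLUMN_MAP = {name: name for name in MEASUREMENT_COLUMNS}
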