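"""Pairwise sequence identity and closest-training-domain matching.

A test-set-only domain is characterised by how close it sits to the
training set: the maximum percent identity of any local alignment against
a training wildtype that passes an e-value cutoff (default 1e-3), with 0%
assigned when no alignment passes. The same machinery matches each
held-out domain to its closest training partner for the
collective-vs-single-domain training comparison; a structural adapter
(e.g. a Foldseek wrapper) may be plugged in as a fallback when no sequence
alignment exists, and is never required.

Alignment is Smith–Waterman (optimal local) under BLOSUM62 with affine
gap penalties (open 11, extend 1; a gap of length k costs 11 + (k-1)).
Percent identity uses alignment columns — matches / (aligned pairs +
internal gaps) × 100. Significance follows the Karlin–Altschul gapped
statistics E = K·m·n·exp(−λS) with the BLOSUM62/11/1 constants
λ = 0.267, K = 0.041 and a configurable effective database size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InvalidSequenceError

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA20)


@dataclass(frozen=True)
class ScoringParams:
    """Local-alignment scoring scheme and e-value statistics."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0  # charged for the first residue of a gap
    gap_extend: float = 1.0  # each further residue
    lambda_: float = 0.267  # Karlin-Altschul gapped BLOSUM62/11/1
    k_const: float = 0.041
    min_score: float = 1.0  # alignments scoring below this are "no hit"


@dataclass(frozen=True)
class AlignmentHit:
    query_domain_id: str
    target_domain_id: str
    percent_identity: float  # 0-100, matches / alignment columns
    evalue: float
    alignment_length: int  # columns, gaps included
    score: float  # raw Smith-Waterman score


@dataclass(frozen=True)
class DomainMatch:
    test_only_domain_id: str
    matched_train_domain_id: str | None
    match_type: str  # "sequence" | "structure" | "none"
    identity_pct: float | None = None
    tm_score: float | None = None


#: A structure adapter maps (query_id, training ids) -> (partner_id, tm_score)
#: or None. External tools (Foldseek etc.) are wrapped behind this callable;
#: structural alignment itself is never reimplemented here.
StructureAdapter = Callable[[str, Mapping[str, str]], tuple[str, float] | None]


def _check_sequences(*seqs: str) -> None:
    errors = [
        (i, s, f"invalid residues {sorted(set(s) - _AA_SET)}" if s else "empty sequence")
        for i, s in enumerate(seqs)
        if not s or not set(s) <= _AA_SET
    ]
    if errors:
        raise InvalidSequenceError(errors)


def _aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def evalue(score: float, m: int, n: int, params: ScoringParams = ScoringParams()) -> float:
    """Karlin-Altschul expectation for a raw local score against an m×n search space."""
    return params.k_const * m * n * math.exp(-params.lambda_ * score)


def pairwise_local_alignment(
    seq_a: str,
    seq_b: str,
    params: ScoringParams = ScoringParams(),
    db_size: int | None = None,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit | None:
    """Optimal local alignment of two protein sequences, or None for no hit.

    ``db_size`` (total residues searched) replaces ``len(seq_b)`` in the
    e-value search space when the pair is part of a one-vs-many scan.
    """
    _check_sequences(seq_a, seq_b)
    aligner = _aligner(params)
    if aligner.score(seq_a, seq_b) < params.min_score:
        return None
    # co-optimal alignments may differ in identity; aligning the pair in a
    # canonical orientation keeps identity(a, b) == identity(b, a)
    best = aligner.align(*sorted((seq_a, seq_b)))[0]
    counts = best.counts()
    n_columns = counts.aligned + counts.gaps
    identity = 100.0 * counts.identities / n_columns
    n_space = db_size if db_size is not None else len(seq_b)
    return AlignmentHit(
        query_domain_id=query_id,
        target_domain_id=target_id,
        percent_identity=identity,
        evalue=evalue(best.score, len(seq_a), n_space, params),
        alignment_length=int(n_columns),
        score=float(best.score),
    )


def align_to_training_set(
    query_seq: str,
    training: Mapping[str, str],
    params: ScoringParams = ScoringParams(),
    evalue_cutoff: float = 1e-3,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """All training-set hits passing the e-value cutoff, best score first."""
    if not training:
        raise ValueError("training set is empty")
    db_size = sum(len(s) for s in training.values())
    hits = []
    for target_id in sorted(training):
        hit = pairwise_local_alignment(
            query_seq, training[target_id], params,
            db_size=db_size, query_id=query_id, target_id=target_id,
        )
        if hit is not None and hit.evalue < evalue_cutoff:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.target_domain_id))
    return hits


def max_identity_to_train(
    query_seq: str,
    training: Mapping[str, str],
    params: ScoringParams = ScoringParams(),
    evalue_cutoff: float = 1e-3,
) -> float:
    """Highest percent identity to any training wildtype; 0 when no
    alignment passes the e-value cutoff."""
    hits = align_to_training_set(query_seq, training, params, evalue_cutoff)
    if not hits:
        return 0.0
    return max(h.percent_identity for h in hits)


def match_closest_training_domain(
    test_only_domain_id: str,
    test_only_seq: str,
    training: Mapping[str, str],
    params: ScoringParams = ScoringParams(),
    evalue_cutoff: float = 1e-3,
    structure_adapter: StructureAdapter | None = None,
) -> DomainMatch:
    """Closest training partner: by sequence identity first, then by the
    structural adapter when configured, else unmatched.

    Identity ties break by higher alignment score, then lexicographic id.
    """
    hits = align_to_training_set(
        test_only_seq, training, params, evalue_cutoff, query_id=test_only_domain_id
    )
    if hits:
        best = max(hits, key=lambda h: (h.percent_identity, h.score))
        tied = [h for h in hits
                if (h.percent_identity, h.score) == (best.percent_identity, best.score)]
        best = min(tied, key=lambda h: h.target_domain_id)
        return DomainMatch(
            test_only_domain_id=test_only_domain_id,
            matched_train_domain_id=best.target_domain_id,
            match_type="sequence",
            identity_pct=best.percent_identity,
        )
    if structure_adapter is not None:
        try:
            result = structure_adapter(test_only_domain_id, training)
        except Exception:  # adapter failures degrade to "no match"
            logger.exception("structure adapter failed for %s", test_only_domain_id)
            result = None
        if result is not None:
            partner, tm = result
            return DomainMatch(
                test_only_domain_id=test_only_domain_id,
                matched_train_domain_id=partner,
                match_type="structure",
                tm_score=tm,
            )
    return DomainMatch(
        test_only_domain_id=test_only_domain_id,
        matched_train_domain_id=None,
        match_type="none",
    )


def identity_table(
    test_domains: Mapping[str, str],
    training: Mapping[str, str],
    params: ScoringParams = ScoringParams(),
    evalue_cutoff: float = 1e-3,
) -> dict[str, float]:
    """max_identity_to_train for every query domain."""
    return {
        qid: max_identity_to_train(seq, training, params, evalue_cutoff)
        for qid, seq in test_domains.items()
    }
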