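"""Smith-Waterman local alignment scores and the normalized sequence kernel.

The genomic similarity of two proteins is the local alignment score
normalized by the geometric mean of the two self-alignment scores::

    S_p(A, B) = SW(A, B) / (sqrt(SW(A, A)) * sqrt(SW(B, B)))

which gives unit self-similarity and, for the substitution matrices used
in practice, values in [0, 1]. Scores are computed with Biopython's
pairwise aligner in local mode (score only, no traceback). An affine gap
of length L costs ``gap_open + gap_extend * L``.

Should a pair ever score above the geometric-mean bound — possible in
principle for pathological substitution matrices — the violation is
raised as a diagnostic rather than clipped, since it signals a scoring
misconfiguration, not data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, ContractError, ValidationError
from .records import PROTEIN_ALPHABET, ProteinRecord
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment scoring parameters.

    Defaults are the common protein choices: BLOSUM62 with gap open 10
    and extend 1. ``X`` scores 0 against every residue (neutral handling
    of unknowns).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend > 0):
            raise ConfigurationError("require gap_open >= gap_extend > 0")


@dataclass(frozen=True)
class AlignmentScore:
    """Raw local alignment score; 0 iff no positively scoring alignment exists."""

    raw: float
    params: ScoringConfig

    def __post_init__(self):
        if self.raw < 0:
            raise ValidationError("local alignment score cannot be negative")


@lru_cache(maxsize=8)
def _aligner(cfg: ScoringConfig) -> Align.PairwiseAligner:
    mat = substitution_matrices.load(cfg.matrix_name).copy()
    if "X" in mat.alphabet:
        ix = mat.alphabet.index("X")
        mat[ix, :] = 0.0
        mat[:, ix] = 0.0
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = mat
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; shifting by gap_extend makes
    # a gap of length L cost gap_open + gap_extend * L.
    aligner.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    aligner.extend_gap_score = -cfg.gap_extend
    return aligner


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ContractError("empty protein sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ContractError(f"illegal residue(s) {sorted(bad)} in sequence")


def smith_waterman(seq_a: str, seq_b: str, cfg: ScoringConfig = ScoringConfig()) -> AlignmentScore:
    """Optimal local alignment score under affine gaps (score only)."""
    _check_sequence(seq_a)
    _check_sequence(seq_b)
    raw = float(_aligner(cfg).score(seq_a, seq_b))
    return AlignmentScore(raw=max(raw, 0.0), params=cfg)


def normalized_sw(seq_a: str, seq_b: str, cfg: ScoringConfig = ScoringConfig()) -> float:
    """Normalized local-alignment similarity in [0, 1]; exactly 1 for A = B."""
    saa = smith_waterman(seq_a, seq_a, cfg).raw
    sbb = smith_waterman(seq_b, seq_b, cfg).raw
    if saa <= 0 or sbb <= 0:
        raise ValidationError(
            "degenerate input: zero self-alignment score "
            f"(|A|={len(seq_a)}, |B|={len(seq_b)})"
        )
    sab = smith_waterman(seq_a, seq_b, cfg).raw
    # exact bound check on the (integer-valued) scores before any sqrt
    if sab * sab > saa * sbb * (1 + 1e-12):
        raise ValidationError(
            f"normalized similarity exceeds 1 for sequences {seq_a!r} / {seq_b!r}: "
            f"SW(A,B)={sab}, SW(A,A)={saa}, SW(B,B)={sbb}; check the scoring matrix"
        )
    # sqrt of the product (not product of sqrts): exact for the A = B
    # perfect-square case, so identical sequences score exactly 1
    return min(1.0, sab / math.sqrt(saa * sbb))


def build_protein_similarity_matrix(
    records: list[ProteinRecord], cfg: ScoringConfig = ScoringConfig()
) -> SimilarityMatrix:
    """Symmetric normalized-alignment kernel over one protein class.

    Only the upper triangle is aligned; the matrix is mirrored. Mixing
    protein classes is a contract error — classes are modeled separately
    everywhere in the pipeline.
    """
    if not records:
        raise ContractError("need at least one protein record")
    classes = {r.protein_class for r in records}
    if len(classes) > 1:
        raise ContractError(f"mixed protein classes in one kernel: {sorted(classes)}")
    n = len(records)
    aligner = _aligner(cfg)
    self_scores = np.empty(n)
    for i, rec in enumerate(records):
        _check_sequence(rec.sequence)
        self_scores[i] = float(aligner.score(rec.sequence, rec.sequence))
        if self_scores[i] <= 0:
            raise ValidationError(f"protein {rec.id!r}: zero self-alignment score")
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sab = max(0.0, float(aligner.score(records[i].sequence, records[j].sequence)))
            if sab * sab > self_scores[i] * self_scores[j] * (1 + 1e-12):
                raise ValidationError(
                    f"normalized similarity exceeds 1 for {records[i].id!r} / {records[j].id!r}"
                )
            values[i, j] = values[j, i] = min(
                1.0, sab / math.sqrt(self_scores[i] * self_scores[j])
            )
    return SimilarityMatrix(ids=tuple(r.id for r in records), values=values)
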