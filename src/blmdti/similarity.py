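"""Tanimoto similarity on fingerprints and the kernel-matrix container.

The Tanimoto coefficient of two bitsets is ``AB / (A + B - AB)`` where
``A`` and ``B`` count the bits set in each fingerprint and ``AB`` the
bits set in both. The ratio is undefined when both fingerprints are
empty; by convention two empty fingerprints score 1 (two degenerate
bond-less molecules are identical under this representation) and an
empty against a non-empty fingerprint scores 0, so 0/0 is never
evaluated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ValidationError
from .fingerprints import Fingerprint


@dataclass
class SimilarityMatrix:
    """Symmetric unit-diagonal kernel over an ordered entity list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate ids in SimilarityMatrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValidationError("similarity matrix must be symmetric within 1e-12")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValidationError("similarity matrix diagonal must be exactly 1")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, entity_id: str) -> int:
        if not hasattr(self, "_index"):
            self._index = {e: i for i, e in enumerate(self.ids)}
        try:
            return self._index[entity_id]
        except KeyError:
            raise ContractError(f"id {entity_id!r} not in similarity matrix") from None

    def submatrix(self, row_idx: np.ndarray, col_idx: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(row_idx, col_idx)]


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient of two equal-width fingerprints, in [0, 1]."""
    if fp_a.width != fp_b.width:
        raise ContractError(f"fingerprint width mismatch: {fp_a.width} vs {fp_b.width}")
    a, b = fp_a.n_set, fp_b.n_set
    if a == 0 and b == 0:
        return 1.0
    ab = fp_a & fp_b
    return ab / (a + b - ab)


def _bit_matrix(fps: list[Fingerprint]) -> np.ndarray:
    widths = {fp.width for fp in fps}
    if len(widths) != 1:
        raise ContractError(f"fingerprints have mixed widths {sorted(widths)}")
    return np.stack([fp.bits for fp in fps]).astype(np.float64)


def _tanimoto_block(q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Vectorized pairwise Tanimoto between two 0/1 row-matrices."""
    inter = q @ t.T
    qa = q.sum(axis=1)[:, None]
    tb = t.sum(axis=1)[None, :]
    denom = qa + tb - inter
    out = np.zeros_like(inter)
    nz = denom > 0
    out[nz] = inter[nz] / denom[nz]
    # both all-zero: denominator 0 -> identical degenerate molecules
    out[(qa == 0) & (tb == 0)] = 1.0
    return out


def build_similarity_matrix(fps: list[Fingerprint], ids: list[str]) -> SimilarityMatrix:
    """All-pairs Tanimoto kernel over one compound library."""
    if len(fps) != len(ids) or len(fps) < 1:
        raise ContractError("need equal, non-zero numbers of fingerprints and ids")
    m = _bit_matrix(fps)
    values = _tanimoto_block(m, m)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0  # exact symmetry against float noise
    return SimilarityMatrix(ids=tuple(ids), values=values)


def cross_similarity(query_fps: list[Fingerprint], train_fps: list[Fingerprint]) -> np.ndarray:
    """Rectangular |query| x |train| Tanimoto block (screening mode)."""
    if not train_fps:
        raise ContractError("empty training fingerprint list")
    if not query_fps:
        raise ContractError("empty query fingerprint list")
    q = _bit_matrix(list(query_fps) + list(train_fps))
    return _tanimoto_block(q[: len(query_fps)], q[len(query_fps):])
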