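"""Bipartite local models over precomputed similarity kernels.

For a pair (compound c, protein t) two directional classifiers exist:

* compound side — anchor the protein t, train a kernel SVM over all
  other compounds using the chemical Tanimoto kernel, labels +1 for
  compounds with a known edge to t and -1 otherwise (any unknown pair is
  a negative), and score c;
* protein side — anchor the compound c, train over proteins with the
  sequence kernel, and score t.

The signed decision value is the prediction: positive sign means an
interaction, magnitude means confidence. The pair-mode score aggregates
the two sides (max by default). Anchors whose labels are single-class
admit no margin classifier; they are flagged untrainable and score
``-inf`` (no known positive evidence), with the pair score falling back
to the trainable side if one exists.

Screening external compound libraries uses the compound side alone: a
query molecule has a chemical-similarity row against the training
compounds but no sequence-side representation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import ContractError
from .records import InteractionSet
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

COMPOUND_SIDE = "compound_side"
PROTEIN_SIDE = "protein_side"
PAIR = "pair"

#: Score assigned when no local model can be trained for an anchor.
UNTRAINABLE_SCORE = float("-inf")


@dataclass
class LocalModel:
    """One trained (or untrainable) per-anchor classifier."""

    anchor_id: str
    side: str
    training_ids: tuple[str, ...]
    labels: np.ndarray  # +1/-1 over training_ids
    trainable: bool
    _clf: SVC | None = field(default=None, repr=False)

    def decision(self, kernel_rows: np.ndarray) -> np.ndarray:
        """Signed scores for rows of similarities against ``training_ids``
        (columns in training order)."""
        rows = np.atleast_2d(np.asarray(kernel_rows, dtype=float))
        if rows.shape[1] != len(self.training_ids):
            raise ContractError(
                f"kernel block has {rows.shape[1]} columns, model expects {len(self.training_ids)}"
            )
        if not self.trainable:
            return np.full(rows.shape[0], UNTRAINABLE_SCORE)
        return self._clf.decision_function(rows)


def train_local_model(
    anchor: str,
    side: str,
    kernel: SimilarityMatrix,
    interactions: InteractionSet,
    exclude: frozenset[str] | set[str] = frozenset(),
    C: float = 1.0,
    epsilon: float = 0.0,
    tol: float = 1e-9,
) -> LocalModel:
    """Train the local classifier anchored at one protein (compound side)
    or one compound (protein side).

    ``exclude`` removes entities from the training set entirely (the
    held-out entity of a cross-validated pair). ``epsilon`` optionally
    adds ``epsilon * I`` to the training kernel block as an escape hatch
    for solvers that reject an indefinite kernel; the similarity matrix
    itself is used unmodified by default.
    """
    if side == COMPOUND_SIDE:
        if anchor not in set(interactions.protein_ids):
            raise ContractError(f"anchor protein {anchor!r} not in interaction set")
        entities = interactions.compound_ids
        label_of = lambda e: 1 if interactions.has_edge(e, anchor) else -1
    elif side == PROTEIN_SIDE:
        if anchor not in set(interactions.compound_ids):
            raise ContractError(f"anchor compound {anchor!r} not in interaction set")
        entities = interactions.protein_ids
        label_of = lambda e: 1 if interactions.has_edge(anchor, e) else -1
    else:
        raise ContractError(f"unknown side {side!r}")
    if not set(exclude) <= set(entities):
        raise ContractError("exclude contains ids outside the training entities")

    training_ids = tuple(e for e in entities if e not in exclude)
    labels = np.array([label_of(e) for e in training_ids], dtype=np.int8)
    trainable = bool(labels.size) and (labels.min() == -1) and (labels.max() == 1)
    clf = None
    if trainable:
        idx = np.array([kernel.index_of(e) for e in training_ids])
        k_train = kernel.submatrix(idx, idx)
        if epsilon:
            k_train = k_train + epsilon * np.eye(len(idx))
        # tight solver tolerance: decision values must be insensitive (to
        # ~1e-8) to the order in which training entities are presented
        clf = SVC(kernel="precomputed", C=C, class_weight="balanced", tol=tol)
        clf.fit(k_train, labels)
    return LocalModel(
        anchor_id=anchor, side=side, training_ids=training_ids,
        labels=labels, trainable=trainable, _clf=clf,
    )


@dataclass(frozen=True)
class PairScore:
    """Signed decision value for one compound-protein pair."""

    compound_id: str
    protein_id: str
    score: float
    mode: str
    flags: tuple[str, ...] = ()

    @property
    def predicted(self) -> bool:
        return self.score > 0


def _kernel_row(kernel: SimilarityMatrix, entity: str, columns: tuple[str, ...]) -> np.ndarray:
    i = kernel.index_of(entity)
    cols = np.array([kernel.index_of(e) for e in columns])
    return kernel.values[i, cols]


def side_scores(
    c: str,
    t: str,
    chem_kernel: SimilarityMatrix,
    seq_kernel: SimilarityMatrix,
    interactions: InteractionSet,
    C: float = 1.0,
    epsilon: float = 0.0,
    exclude_self: bool = True,
) -> tuple[float, float, LocalModel, LocalModel]:
    """Both directional scores for one pair, with the pair's own label
    excluded from both training sets when ``exclude_self`` is set."""
    comp_model = train_local_model(
        t, COMPOUND_SIDE, chem_kernel, interactions,
        exclude={c} if exclude_self else frozenset(), C=C, epsilon=epsilon,
    )
    prot_model = train_local_model(
        c, PROTEIN_SIDE, seq_kernel, interactions,
        exclude={t} if exclude_self else frozenset(), C=C, epsilon=epsilon,
    )
    s_comp = float(comp_model.decision(_kernel_row(chem_kernel, c, comp_model.training_ids))[0])
    s_prot = float(prot_model.decision(_kernel_row(seq_kernel, t, prot_model.training_ids))[0])
    return s_comp, s_prot, comp_model, prot_model


def aggregate(s_comp: float, s_prot: float, aggregation: str = "max") -> tuple[float, tuple[str, ...]]:
    """Combine the two directional scores into the pair score.

    If exactly one side is untrainable the pair score is the other
    side's; if both are, the sentinel ``-inf`` is returned with a flag.
    """
    comp_ok = s_comp != UNTRAINABLE_SCORE
    prot_ok = s_prot != UNTRAINABLE_SCORE
    if not comp_ok and not prot_ok:
        return UNTRAINABLE_SCORE, ("both_untrainable",)
    if not comp_ok:
        return s_prot, ("compound_side_untrainable",)
    if not prot_ok:
        return s_comp, ("protein_side_untrainable",)
    if aggregation == "max":
        return max(s_comp, s_prot), ()
    if aggregation == "mean":
        return (s_comp + s_prot) / 2.0, ()
    raise ContractError(f"unknown aggregation {aggregation!r}")


def score_pair(
    c: str,
    t: str,
    chem_kernel: SimilarityMatrix,
    seq_kernel: SimilarityMatrix,
    interactions: InteractionSet,
    aggregation: str = "max",
    C: float = 1.0,
    epsilon: float = 0.0,
) -> PairScore:
    """Pair-mode score for (c, t), each side trained with the pair's own
    label held out."""
    if c not in set(interactions.compound_ids):
        raise ContractError(f"unknown compound id {c!r}")
    if t not in set(interactions.protein_ids):
        raise ContractError(f"unknown protein id {t!r}")
    s_comp, s_prot, _, _ = side_scores(c, t, chem_kernel, seq_kernel, interactions, C=C, epsilon=epsilon)
    score, flags = aggregate(s_comp, s_prot, aggregation)
    return PairScore(compound_id=c, protein_id=t, score=score, mode=PAIR, flags=flags)


def screen_queries(
    query_block: np.ndarray,
    query_ids: list[str],
    chem_kernel: SimilarityMatrix,
    interactions: InteractionSet,
    targets: list[str] | None = None,
    C: float = 1.0,
    epsilon: float = 0.0,
) -> list[PairScore]:
    """Score external query compounds against every (trainable) target.

    ``query_block`` is the |query| x |training compounds| Tanimoto block,
    columns aligned with ``interactions.compound_ids``. Only the chemical
    kernel is used — novel compounds have no protein-side model. Targets
    with single-class labels are skipped and logged. All-zero similarity
    rows (bond-less or utterly dissimilar queries) are flagged
    ``low_information``; their score is the model's bias-only response.
    """
    query_block = np.asarray(query_block, dtype=float)
    if query_block.shape != (len(query_ids), interactions.n_compounds):
        raise ContractError(
            f"query block shape {query_block.shape} does not match "
            f"{len(query_ids)} queries x {interactions.n_compounds} training compounds"
        )
    if targets is None:
        targets = list(interactions.protein_ids)
    out: list[PairScore] = []
    n_skipped = 0
    for t in targets:
        model = train_local_model(t, COMPOUND_SIDE, chem_kernel, interactions, C=C, epsilon=epsilon)
        if not model.trainable:
            n_skipped += 1
            logger.info("target %r skipped: single-class labels", t)
            continue
        # model may have been trained on the full compound list in kernel
        # order; align query columns to its training order
        cidx = {e: i for i, e in enumerate(interactions.compound_ids)}
        col = [cidx[e] for e in model.training_ids]
        scores = model.decision(query_block[:, col])
        for qid, row, s in zip(query_ids, query_block, scores):
            flags = ("low_information",) if not row.any() else ()
            out.append(PairScore(compound_id=qid, protein_id=t, score=float(s),
                                 mode=COMPOUND_SIDE, flags=flags))
    if n_skipped:
        logger.warning("screening skipped %d untrainable targets", n_skipped)
    return out


def export_edges(scores: list[PairScore], path: str | Path, threshold: float = 0.0,
                 header_comment: str | None = None) -> int:
    """Write predicted edges (score > threshold) as TSV, best first.

    Returns the number of edges written. Ties are broken by ids so the
    file is byte-identical across runs.
    """
    kept = sorted(
        (s for s in scores if s.score > threshold),
        key=lambda s: (-s.score, s.compound_id, s.protein_id),
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("compound_id\tprotein_id\tscore\tmode\n")
        for s in kept:
            fh.write(f"{s.compound_id}\t{s.protein_id}\t{s.score:.10g}\t{s.mode}\n")
    return len(kept)
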