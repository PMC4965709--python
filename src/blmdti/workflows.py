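"""End-to-end workflows: train/cross-validate per class, and screen an
external compound library against the trained targets.

Both workflows are deterministic functions of one :class:`RunConfig`:
every source of randomness flows from the single master seed, each
output file names the config hash in a header comment, and a manifest
records the config, seeds and input checksums so a rerun can be verified
byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import blm
from .alignment import ScoringConfig, build_protein_similarity_matrix
from .crossval import cross_validate
from .errors import ValidationError
from .fingerprints import fingerprint
from .io import (read_fasta, read_interactions, read_smiles_library,
                 write_matrix_tsv)
from .lipinski import profile_hits, profile_table
from .similarity import build_similarity_matrix, cross_similarity

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    ``proteins`` maps protein-class tags to FASTA paths; all other inputs
    are shared. Precedence when loading: CLI overrides > config file >
    these defaults.
    """

    compounds: str = "compounds.smi"
    proteins: dict[str, str] = field(default_factory=lambda: {"GPCR": "proteins.fasta"})
    interactions: str = "interactions.tsv"
    outdir: str = "out"
    query_compounds: str | None = None

    fingerprint_width: int = 1024
    max_path_atoms: int = 7
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    svm_c: float = 1.0
    kernel_epsilon: float = 0.0
    aggregation: str = "max"
    cv_folds: int = 10
    seed: int = 17
    screening_threshold: float = 0.0
    strict_training: bool = True
    strict_query: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        for key, value in data.items():
            logger.info("config: %s = %r (file/CLI)", key, value)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _preflight(paths: list[Path]) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise ValidationError("missing input file(s): " + ", ".join(missing))


def _chem_kernel(cfg: RunConfig, records):
    fps = [fingerprint(r.mol, width=cfg.fingerprint_width, max_atoms=cfg.max_path_atoms)
           for r in records]
    return fps, build_similarity_matrix(fps, [r.id for r in records])


def run_training_workflow(cfg: RunConfig) -> dict:
    """Build per-class similarity matrices and cross-validation reports.

    Returns the manifest dict (also written to ``outdir/manifest.json``),
    whose ``counts`` section is the per-class compounds/proteins/edges
    table every run logs.
    """
    inputs = [Path(cfg.compounds), Path(cfg.interactions)] + [Path(p) for p in cfg.proteins.values()]
    _preflight(inputs)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    scoring = ScoringConfig(matrix_name=cfg.matrix_name, gap_open=cfg.gap_open,
                            gap_extend=cfg.gap_extend)

    molecules = read_smiles_library(cfg.compounds, strict=cfg.strict_training)
    compound_ids = [m.id for m in molecules]
    proteins_by_class = {cls: read_fasta(path, cls) for cls, path in sorted(cfg.proteins.items())}
    interaction_sets = read_interactions(
        cfg.interactions,
        compound_ids=compound_ids,
        protein_ids={cls: [p.id for p in recs] for cls, recs in proteins_by_class.items()},
        strict=cfg.strict_training,
    )

    _, chem_kernel = _chem_kernel(cfg, molecules)
    write_matrix_tsv(chem_kernel.ids, chem_kernel.ids, chem_kernel.values,
                     outdir / "chem_similarity.tsv", header_comment=f"config_hash={chash}")

    counts: dict[str, dict] = {}
    reports: dict[str, dict] = {}
    for cls, prot_records in proteins_by_class.items():
        if len(prot_records) < 2:
            logger.warning("class %s skipped: fewer than 2 proteins", cls)
            continue
        if cls not in interaction_sets:
            logger.warning("class %s skipped: no interactions", cls)
            continue
        inter = interaction_sets[cls]
        counts[cls] = {"compounds": inter.n_compounds, "proteins": inter.n_proteins,
                       "interactions": inter.n_edges}
        logger.info("class %s: %d compounds, %d proteins, %d interactions",
                    cls, inter.n_compounds, inter.n_proteins, inter.n_edges)
        seq_kernel = build_protein_similarity_matrix(prot_records, scoring)
        write_matrix_tsv(seq_kernel.ids, seq_kernel.ids, seq_kernel.values,
                         outdir / f"seq_similarity_{cls}.tsv",
                         header_comment=f"config_hash={chash}")
        result = cross_validate(chem_kernel, seq_kernel, inter,
                                k=cfg.cv_folds, seed=cfg.seed,
                                aggregation=cfg.aggregation, C=cfg.svm_c,
                                epsilon=cfg.kernel_epsilon)
        result.to_json(outdir / f"cv_report_{cls}.json")
        result.write_scores_tsv(outdir / f"cv_scores_{cls}.tsv",
                                header_comment=f"config_hash={chash}")
        reports[cls] = result.pooled

    manifest = {
        "config": asdict(cfg),
        "config_hash": chash,
        "seed": cfg.seed,
        "cv_unit": "pair",
        "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
        "counts": counts,
        "pooled_metrics": reports,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_screening_workflow(cfg: RunConfig) -> dict:
    """Screen a query compound library with chemical similarity alone.

    For every protein class: train one compound-side model per target on
    the full training library, score each query compound, export the
    predicted-edge table (the interaction-network edge list), and profile
    the rule-of-five violation distribution of the hits.
    """
    if cfg.query_compounds is None:
        raise ValidationError("screening requires query_compounds")
    inputs = [Path(cfg.compounds), Path(cfg.interactions), Path(cfg.query_compounds)] + [
        Path(p) for p in cfg.proteins.values()]
    _preflight(inputs)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()

    molecules = read_smiles_library(cfg.compounds, strict=cfg.strict_training)
    queries = read_smiles_library(cfg.query_compounds, strict=cfg.strict_query)
    if not queries:
        raise ValidationError(f"query library {cfg.query_compounds} is empty after parsing")
    compound_ids = [m.id for m in molecules]
    proteins_by_class = {cls: read_fasta(path, cls) for cls, path in sorted(cfg.proteins.items())}
    interaction_sets = read_interactions(
        cfg.interactions, compound_ids=compound_ids,
        protein_ids={cls: [p.id for p in recs] for cls, recs in proteins_by_class.items()},
        strict=cfg.strict_training,
    )

    train_fps, chem_kernel = _chem_kernel(cfg, molecules)
    query_fps = [fingerprint(q.mol, width=cfg.fingerprint_width, max_atoms=cfg.max_path_atoms)
                 for q in queries]
    query_ids = [q.id for q in queries]
    query_lib = {q.id: q for q in queries}

    counts: dict[str, dict] = {}
    all_hit_rows: list[dict] = []
    for cls, inter in sorted(interaction_sets.items()):
        block = cross_similarity(query_fps, train_fps)
        scores = blm.screen_queries(block, query_ids, chem_kernel, inter, C=cfg.svm_c,
                                    epsilon=cfg.kernel_epsilon)
        n_edges = blm.export_edges(scores, outdir / f"hits_{cls}.tsv",
                                   threshold=cfg.screening_threshold,
                                   header_comment=f"config_hash={chash}")
        hits = [s for s in scores if s.score > cfg.screening_threshold]
        counts[cls] = {
            "queries": len(query_ids),
            "targets": inter.n_proteins,
            "predicted_edges": n_edges,
            "predicted_compounds": len({h.compound_id for h in hits}),
            "predicted_targets": len({h.protein_id for h in hits}),
        }
        logger.info("class %s: %d predicted edges over %d compounds / %d targets",
                    cls, n_edges, counts[cls]["predicted_compounds"],
                    counts[cls]["predicted_targets"])
        all_hit_rows.extend(
            {"compound_id": h.compound_id, "protein_id": h.protein_id, "protein_class": cls}
            for h in hits
        )

    rof = profile_hits(all_hit_rows, query_lib)
    with open(outdir / "rof_profile.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# config_hash={chash}\n")
        rof.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    hit_ids = sorted({r["compound_id"] for r in all_hit_rows})
    table = profile_table([query_lib[i] for i in hit_ids])
    with open(outdir / "rof_descriptors.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# config_hash={chash}\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.6g")

    manifest = {
        "config": asdict(cfg),
        "config_hash": chash,
        "seed": cfg.seed,
        "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
        "counts": counts,
    }
    with open(outdir / "screening_manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
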