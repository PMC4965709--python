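"""Readers and writers for the plain-text formats the pipeline touches.

Formats
-------
* compound library: ``<id><TAB or space><SMILES>`` per line, ``#`` comments
* proteins: FASTA (id = header token up to first whitespace)
* interactions: TSV with header ``compound_id  protein_id  protein_class``
* similarity matrices: TSV with id header row and id first column

SMILES chemistry (valences, aromaticity, implicit hydrogens) is delegated
to RDKit; a lightweight pre-validator scans the token stream first so that
the documented error classes — unbalanced parentheses, unmatched ring
closures, unknown tokens — are reported with a character offset, which
RDKit's parser does not expose.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

from .errors import ContractError, SmilesParseError, ValidationError
from .records import PROTEIN_ALPHABET, PROTEIN_CLASSES, InteractionSet, MoleculeRecord, ProteinRecord

logger = logging.getLogger(__name__)

# RDKit reports parse failures on stderr as well as via a None return;
# the None return is what we act on.
RDLogger.DisableLog("rdApp.error")

# Two-letter organic-subset halogens must be matched before single letters.
_ORGANIC_TOKENS = ("Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I")
_AROMATIC_TOKENS = ("b", "c", "n", "o", "p", "s")
_BOND_CHARS = set("-=#:/\\")


def _validate_smiles_tokens(smiles: str) -> None:
    """Scan the token stream of the supported dialect, raising
    :class:`SmilesParseError` with a character offset on the first
    structural problem. Chemistry is not checked here."""
    paren_stack: list[int] = []
    open_rings: dict[str, int] = {}
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "(":
            paren_stack.append(i)
            i += 1
        elif ch == ")":
            if not paren_stack:
                raise SmilesParseError("unbalanced ')'", offset=i)
            paren_stack.pop()
            i += 1
        elif ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise SmilesParseError("unterminated bracket atom", offset=n)
            if j == i + 1:
                raise SmilesParseError("empty bracket atom", offset=i)
            i = j + 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesParseError("'%' ring closure needs two digits", offset=i)
            key = smiles[i + 1 : i + 3]
            open_rings.pop(key, None) if key in open_rings else open_rings.setdefault(key, i)
            i += 3
        elif ch.isdigit():
            open_rings.pop(ch, None) if ch in open_rings else open_rings.setdefault(ch, i)
            i += 1
        elif ch in _BOND_CHARS or ch == ".":
            i += 1
        elif smiles.startswith(("Cl", "Br"), i):
            i += 2
        elif ch in "BCNOPSFI" or ch in "bcnops" or ch == "*":
            i += 1
        else:
            raise SmilesParseError(f"unknown token {ch!r}", offset=i)
    if paren_stack:
        raise SmilesParseError(
            f"unclosed '(' opened at offset {paren_stack[-1]}", offset=n
        )
    if open_rings:
        key, pos = next(iter(open_rings.items()))
        raise SmilesParseError(f"unmatched ring closure {key!r} opened at offset {pos}", offset=n)


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into a molecular graph.

    Supports the organic subset, bracket atoms with charge and hydrogen
    count, aromatic lowercase atoms, branches, ring closures (including
    ``%nn``), explicit bond symbols and multi-fragment dots. Stereo
    markers (``/ \\ @``) are accepted and ignored — the path fingerprints
    downstream are stereo-blind. Implicit hydrogens follow standard
    valence rules.

    Raises
    ------
    SmilesParseError
        On an empty string, a structural token error (with character
        offset), or a string RDKit rejects chemically.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string", offset=0)
    _validate_smiles_tokens(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"RDKit rejected SMILES {smiles!r}")
    return mol


@dataclass
class ParseReport:
    """Per-file account of skipped records in lenient mode."""

    n_read: int = 0
    n_skipped: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)  # (line number, message)


def read_smiles_library(
    path: str | Path, strict: bool = True, report: ParseReport | None = None
) -> list[MoleculeRecord]:
    """Read a ``<id> <SMILES>`` compound library.

    In strict mode (the default, used for training data) any unparseable
    SMILES aborts the read; in lenient mode (query libraries, whose SMILES
    are often ambiguous) bad records are skipped, counted and logged.
    Duplicate ids are always an error.
    """
    path = Path(path)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    rep = report if report is not None else ParseReport()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected '<id> <SMILES>', got {line!r}")
            rec_id, smiles = parts
            if rec_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate compound id {rec_id!r}")
            seen.add(rec_id)
            try:
                mol = parse_smiles(smiles)
            except SmilesParseError as exc:
                if strict:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
                rep.n_skipped += 1
                rep.errors.append((lineno, str(exc)))
                logger.warning("%s:%d: skipped %r: %s", path, lineno, rec_id, exc)
                continue
            rec = MoleculeRecord(id=rec_id, smiles=smiles, mol=mol)
            if rec.n_fragments > 1:
                logger.info(
                    "%s:%d: %r is a multi-fragment SMILES; fingerprinted as a bit union",
                    path, lineno, rec_id,
                )
            records.append(rec)
            rep.n_read += 1
    if rep.n_skipped:
        logger.warning("%s: skipped %d of %d records", path, rep.n_skipped, rep.n_read + rep.n_skipped)
    return records


def write_smiles_library(records: list[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.smiles}\n")


def read_fasta(path: str | Path, protein_class: str) -> list[ProteinRecord]:
    """Read a protein FASTA into records of one class.

    Sequences are uppercased; residues outside the 20 standard amino
    acids plus X are a validation error naming record and position.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: record {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise ValidationError(f"{path}: duplicate protein id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=seq, protein_class=protein_class))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_interactions(
    path: str | Path,
    compound_ids: dict[str, list[str]] | list[str] | None = None,
    protein_ids: dict[str, list[str]] | list[str] | None = None,
    strict: bool = True,
) -> dict[str, InteractionSet]:
    """Read a known-interaction TSV into one :class:`InteractionSet` per class.

    When entity id lists are provided they define the full bipartite grid
    (compounds/proteins with zero known edges included) and edges are
    cross-checked against them: in strict mode an unknown id is an error,
    in lenient mode the row is dropped and counted. Without id lists the
    grid is the set of ids appearing in the file. Duplicate rows are kept
    once and logged. Per-class id lists may be passed as dicts keyed by
    class tag.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"compound_id", "protein_id", "protein_class"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: header must contain {sorted(required)}")
    out: dict[str, InteractionSet] = {}
    for cls, sub in df.groupby("protein_class", sort=True):
        if cls not in PROTEIN_CLASSES:
            raise ValidationError(f"{path}: unknown protein class {cls!r}")
        cids = compound_ids.get(cls) if isinstance(compound_ids, dict) else compound_ids
        pids = protein_ids.get(cls) if isinstance(protein_ids, dict) else protein_ids
        rows = list(zip(sub["compound_id"], sub["protein_id"]))
        edges: set[tuple[str, str]] = set()
        n_dup = n_dropped = 0
        cset = set(cids) if cids is not None else None
        pset = set(pids) if pids is not None else None
        for c, p in rows:
            if (cset is not None and c not in cset) or (pset is not None and p not in pset):
                if strict:
                    raise ValidationError(
                        f"{path}: edge ({c!r}, {p!r}) references an id outside the loaded libraries"
                    )
                n_dropped += 1
                continue
            if (c, p) in edges:
                n_dup += 1
            edges.add((c, p))
        if n_dup:
            logger.info("%s [%s]: %d duplicated edge rows stored once", path, cls, n_dup)
        if n_dropped:
            logger.warning("%s [%s]: dropped %d edges with unknown ids", path, cls, n_dropped)
        if cids is None:
            cids = sorted({c for c, _ in edges})
        if pids is None:
            pids = sorted({p for _, p in edges})
        out[cls] = InteractionSet(
            compound_ids=tuple(cids), protein_ids=tuple(pids),
            edges=frozenset(edges), protein_class=cls,
        )
    return out


def write_interactions(sets: dict[str, InteractionSet] | InteractionSet, path: str | Path) -> None:
    """Write interaction sets back to the TSV interchange format."""
    if isinstance(sets, InteractionSet):
        sets = {sets.protein_class: sets}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound_id\tprotein_id\tprotein_class\n")
        for cls in sorted(sets):
            for c, p in sorted(sets[cls].edges):
                fh.write(f"{c}\t{p}\t{cls}\n")


def write_matrix_tsv(ids_rows, ids_cols, values: np.ndarray, path: str | Path,
                     header_comment: str | None = None) -> None:
    """Persist a (rectangular) similarity block as TSV with id headers."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("id\t" + "\t".join(ids_cols) + "\n")
        for rid, row in zip(ids_rows, values):
            fh.write(rid + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float)


def find_structural_duplicates(records: list[MoleculeRecord]) -> list[tuple[str, str]]:
    """Optional duplicate check: pairs of records whose canonical linear-path
    multisets coincide (same skeleton up to the path representation).
    Ids are otherwise opaque and never merged automatically."""
    from .fingerprints import enumerate_linear_paths

    by_key: dict[frozenset, str] = {}
    dups: list[tuple[str, str]] = []
    for rec in records:
        key = frozenset(enumerate_linear_paths(rec.mol))
        if key in by_key:
            dups.append((by_key[key], rec.id))
        else:
            by_key[key] = rec.id
    return dups
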