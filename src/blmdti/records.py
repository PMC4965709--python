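"""Core domain records: molecules, proteins and bipartite interaction sets.

Molecular graphs are RDKit ``Mol`` objects; protein sequences are plain
strings over the 20 standard residues plus ``X``. Interactions are stored
as an explicit bipartite edge set per protein class, with the ordered
entity lists preserved so kernel matrices can be aligned to them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .errors import ContractError, ValidationError

#: The six target categories modeled independently throughout the pipeline.
PROTEIN_CLASSES = ("GPCR", "ion_channel", "transporter", "receptor", "enzyme", "other")

#: Accepted protein alphabet: 20 standard residues plus X for unknowns.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class MoleculeRecord:
    """A compound: opaque id, the SMILES it was read from, and its graph."""

    id: str
    smiles: str
    mol: Chem.Mol

    def __post_init__(self):
        if not self.id:
            raise ValidationError("molecule id must be non-empty")
        if self.mol is None or self.mol.GetNumAtoms() < 1:
            raise ValidationError(f"molecule {self.id!r}: graph must have at least one atom")

    @property
    def n_fragments(self) -> int:
        """Number of connected components (multi-fragment SMILES have > 1)."""
        return len(Chem.GetMolFrags(self.mol))


@dataclass(frozen=True)
class ProteinRecord:
    """A target protein: opaque id, uppercase sequence, and its class tag."""

    id: str
    sequence: str
    protein_class: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValidationError(f"protein {self.id!r}: sequence must be uppercase")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            pos = next(i for i, ch in enumerate(self.sequence) if ch in bad)
            raise ValidationError(
                f"protein {self.id!r}: illegal residue {self.sequence[pos]!r} at position {pos}"
            )
        if self.protein_class not in PROTEIN_CLASSES:
            raise ValidationError(
                f"protein {self.id!r}: class {self.protein_class!r} not one of {PROTEIN_CLASSES}"
            )


@dataclass
class InteractionSet:
    """Known-positive compound-protein edges of one protein class.

    Any pair absent from ``edges`` is treated as a negative (non-interacting)
    example by every model in the package; there is no unknown state.
    """

    compound_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    protein_class: str = "other"

    def __post_init__(self):
        self.compound_ids = tuple(self.compound_ids)
        self.protein_ids = tuple(self.protein_ids)
        self.edges = frozenset(self.edges)
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValidationError("duplicate compound ids in InteractionSet")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein ids in InteractionSet")
        if self.protein_class not in PROTEIN_CLASSES:
            raise ValidationError(f"unknown protein class {self.protein_class!r}")
        cset, pset = set(self.compound_ids), set(self.protein_ids)
        for c, p in self.edges:
            if c not in cset:
                raise ValidationError(f"edge references unknown compound id {c!r}")
            if p not in pset:
                raise ValidationError(f"edge references unknown protein id {p!r}")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, compound_id: str, protein_id: str) -> bool:
        return (compound_id, protein_id) in self.edges

    def adjacency(self) -> np.ndarray:
        """Dense boolean matrix, compounds on rows, proteins on columns."""
        cidx = {c: i for i, c in enumerate(self.compound_ids)}
        pidx = {p: j for j, p in enumerate(self.protein_ids)}
        a = np.zeros((self.n_compounds, self.n_proteins), dtype=bool)
        for c, p in self.edges:
            a[cidx[c], pidx[p]] = True
        return a

    def labels_for_protein(self, protein_id: str) -> np.ndarray:
        """+1/-1 label over compounds: does each compound hit this protein?"""
        if protein_id not in set(self.protein_ids):
            raise ContractError(f"protein {protein_id!r} not in interaction set")
        return np.array(
            [1 if (c, protein_id) in self.edges else -1 for c in self.compound_ids],
            dtype=np.int8,
        )

    def labels_for_compound(self, compound_id: str) -> np.ndarray:
        """+1/-1 label over proteins: does this compound hit each protein?"""
        if compound_id not in set(self.compound_ids):
            raise ContractError(f"compound {compound_id!r} not in interaction set")
        return np.array(
            [1 if (compound_id, p) in self.edges else -1 for p in self.protein_ids],
            dtype=np.int8,
        )
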