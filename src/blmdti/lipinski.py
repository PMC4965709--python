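"""Rule-of-five descriptors and violation counting for predicted hits.

The four Lipinski criteria use the rule's original simple definitions:
molecular weight (average atomic masses, implicit hydrogens included),
hydrogen-bond donors as the count of N-H and O-H bonds, acceptors as the
count of nitrogen and oxygen atoms, and an estimated octanol-water logP.
A criterion is violated only strictly above its bound (MW > 500,
logP > 5, HBD > 5, HBA > 10), so a profile sitting exactly at the
thresholds has zero violations.

logP is inherently method-dependent; the default provider is the
Wildman-Crippen atom-contribution model (RDKit's implementation), and
any callable ``mol -> float`` can be substituted for it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .errors import ContractError
from .records import MoleculeRecord

#: Strict upper bounds of the four criteria, in evaluation order.
ROF_BOUNDS = {"molecular_weight": 500.0, "logp": 5.0, "hbd": 5.0, "hba": 10.0}

LogPProvider = Callable[[Chem.Mol], float]


def crippen_logp(mol: Chem.Mol) -> float:
    """Default logP provider: Wildman-Crippen atom contributions."""
    return float(Crippen.MolLogP(mol))


@dataclass(frozen=True)
class DescriptorProfile:
    """Rule-of-five descriptor set for one molecule."""

    molecular_weight: float  # g/mol
    hbd: int
    hba: int
    logp: float

    @property
    def rof_violations(self) -> int:
        return rof_violations(self)


def descriptors(mol: Chem.Mol, logp_provider: LogPProvider = crippen_logp) -> DescriptorProfile:
    """Compute the four rule-of-five descriptors of a molecular graph."""
    if mol is None or mol.GetNumAtoms() < 1:
        raise ContractError("descriptors need a non-empty molecular graph")
    return DescriptorProfile(
        molecular_weight=float(Descriptors.MolWt(mol)),
        hbd=int(Lipinski.NHOHCount(mol)),
        hba=int(Lipinski.NOCount(mol)),
        logp=logp_provider(mol),
    )


def rof_violations(profile: DescriptorProfile) -> int:
    """Number of Lipinski criteria strictly exceeded (0-4)."""
    return sum([
        profile.molecular_weight > ROF_BOUNDS["molecular_weight"],
        profile.logp > ROF_BOUNDS["logp"],
        profile.hbd > ROF_BOUNDS["hbd"],
        profile.hba > ROF_BOUNDS["hba"],
    ])


def profile_hits(hits, library: dict[str, MoleculeRecord] | list[MoleculeRecord],
                 logp_provider: LogPProvider = crippen_logp) -> pd.DataFrame:
    """Violation-count distribution of predicted hit compounds per class.

    ``hits`` is an iterable with ``compound_id`` and ``protein_id`` (or
    ``protein_class``) attributes/keys — typically the PairScore list of a
    screen. Each distinct hit compound is profiled once per class; the
    returned table has columns (protein_class, violation_count,
    n_compounds, proportion) with proportions summing to 1 per class.
    """
    if not isinstance(library, dict):
        library = {rec.id: rec for rec in library}
    per_class: dict[str, set[str]] = {}
    for h in hits:
        cid = h["compound_id"] if isinstance(h, dict) else h.compound_id
        cls = (h.get("protein_class") if isinstance(h, dict) else
               getattr(h, "protein_class", None)) or "all"
        per_class.setdefault(cls, set()).add(cid)
    missing = sorted({c for s in per_class.values() for c in s} - set(library))
    if missing:
        raise ContractError(f"hit compounds not in library: {missing}")
    rows = []
    for cls in sorted(per_class):
        counts: dict[int, int] = {}
        for cid in per_class[cls]:
            v = rof_violations(descriptors(library[cid].mol, logp_provider))
            counts[v] = counts.get(v, 0) + 1
        total = sum(counts.values())
        for v in sorted(counts):
            rows.append({"protein_class": cls, "violation_count": v,
                         "n_compounds": counts[v], "proportion": counts[v] / total})
    return pd.DataFrame(rows, columns=["protein_class", "violation_count", "n_compounds", "proportion"])


def profile_table(records: list[MoleculeRecord],
                  logp_provider: LogPProvider = crippen_logp) -> pd.DataFrame:
    """Per-compound descriptor table (id, mw, logp, hbd, hba, violations)."""
    rows = []
    for rec in records:
        p = descriptors(rec.mol, logp_provider)
        rows.append({"id": rec.id, "mw": p.molecular_weight, "logp": p.logp,
                     "hbd": p.hbd, "hba": p.hba, "violations": p.rof_violations})
    return pd.DataFrame(rows, columns=["id", "mw", "logp", "hbd", "hba", "violations"])
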