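"""Path-based (FP2-style) molecular fingerprints.

A molecule is indexed by its linear fragments: all simple paths of 2..7
heavy atoms. Each path is spelled as an alternating atom/bond token
string, canonicalized as the lexicographic minimum of its two reading
directions, and hashed with 64-bit FNV-1a into a fixed-width bitset
(default 1024 bits). Hydrogens carry no path information and are
excluded; stereochemistry is not encoded.

The hash is deliberately a documented, platform-independent string hash
rather than any particular toolkit's internal bit layout: two runs on any
platform produce identical fingerprints, which is what the downstream
kernels and their tests rely on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .errors import ConfigurationError

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1

_BOND_TOKEN = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def fnv1a64(s: str) -> int:
    """64-bit FNV-1a over the UTF-8 bytes of ``s``."""
    h = _FNV_OFFSET
    for b in s.encode("utf-8"):
        h = ((h ^ b) * _FNV_PRIME) & _MASK64
    return h


def _atom_token(atom: Chem.Atom) -> str:
    """Element + aromatic flag + formal charge; the path alphabet for atoms."""
    sym = atom.GetSymbol()
    tok = sym.lower() if atom.GetIsAromatic() else sym
    q = atom.GetFormalCharge()
    if q > 0:
        tok += "+" if q == 1 else f"+{q}"
    elif q < 0:
        tok += "-" if q == -1 else f"{q}"
    return tok


def _bond_token(bond: Chem.Bond) -> str:
    try:
        return _BOND_TOKEN[bond.GetBondType()]
    except KeyError:
        # Dative/other orders do not occur in the supported dialect;
        # fall back to single rather than crash on exotic input.
        return "-"


def enumerate_linear_paths(mol: Chem.Mol, max_atoms: int = 7, min_atoms: int = 2) -> set[str]:
    """All distinct canonical linear-path strings of ``min_atoms..max_atoms``
    heavy atoms.

    A path is simple (no repeated atom); each undirected path is reported
    once, as the lexicographically smaller of its two directional
    spellings. A single-atom molecule yields the empty set.
    """
    if max_atoms < 2:
        raise ConfigurationError("max_atoms must be >= 2")
    if not 2 <= min_atoms <= max_atoms:
        raise ConfigurationError("need 2 <= min_atoms <= max_atoms")
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    tokens = {a.GetIdx(): _atom_token(a) for a in heavy}
    paths: set[str] = set()
    visited = [False] * mol.GetNumAtoms()

    def extend(atom: Chem.Atom, spelling: list[str], depth: int) -> None:
        for bond in atom.GetBonds():
            nbr = bond.GetOtherAtom(atom)
            j = nbr.GetIdx()
            if nbr.GetAtomicNum() == 1 or visited[j]:
                continue
            spelling.append(_bond_token(bond))
            spelling.append(tokens[j])
            if depth + 1 >= min_atoms:
                fwd = "".join(spelling)
                rev = "".join(reversed(spelling))
                paths.add(min(fwd, rev))
            if depth + 1 < max_atoms:
                visited[j] = True
                extend(nbr, spelling, depth + 1)
                visited[j] = False
            spelling.pop()
            spelling.pop()

    for atom in heavy:
        i = atom.GetIdx()
        visited[i] = True
        extend(atom, [tokens[i]], 1)
        visited[i] = False
    return paths


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width bitset of hashed linear paths.

    ``n_set`` is the popcount — the quantity entering the Tanimoto
    coefficient for this molecule.
    """

    bits: np.ndarray  # uint8 0/1 vector of length width

    def __post_init__(self):
        object.__setattr__(self, "bits", np.ascontiguousarray(self.bits, dtype=np.uint8))

    @property
    def width(self) -> int:
        return self.bits.shape[0]

    @property
    def n_set(self) -> int:
        return int(self.bits.sum())

    def __and__(self, other: "Fingerprint") -> int:
        return int(np.count_nonzero(self.bits & other.bits))


def fingerprint(mol: Chem.Mol, width: int = 1024, max_atoms: int = 7, min_atoms: int = 2) -> Fingerprint:
    """Hash every distinct canonical path of a molecule into a bitset.

    Deterministic across runs and platforms; invariant to the order in
    which atoms appear in the input SMILES. A bond-less molecule (e.g.
    methane) maps to the all-zero fingerprint.
    """
    if width < 64:
        raise ConfigurationError("fingerprint width must be >= 64")
    bits = np.zeros(width, dtype=np.uint8)
    for path in enumerate_linear_paths(mol, max_atoms=max_atoms, min_atoms=min_atoms):
        bits[fnv1a64(path) % width] = 1
    return Fingerprint(bits=bits)
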