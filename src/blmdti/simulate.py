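"""Synthetic study-condition generator.

Real interaction data of the kind this pipeline analyses has three
statistical features the models rely on: compounds arrive in clusters of
structurally related molecules, targets in families of homologous
sequences, and the bipartite interaction matrix is sparse with an
elevated edge probability between matched cluster/family blocks. The
generator plants exactly this structure, at a deliberately desk-scale
size (about one order of magnitude below the real per-class datasets) so
a full-grid cross-validation runs in minutes:

* compounds — one random connected scaffold per cluster (a random tree
  over C/N/O/S with an optional ring closure, each cluster drawing its
  own element palette), members being scaffold copies with random
  decorations (element substitutions, appended methyl/hydroxyl branches);
* proteins — one random ancestral sequence per family, members being
  per-residue mutated copies;
* interactions — independent Bernoulli edges, probability ``p_in``
  inside matched cluster/family blocks and ``p_out`` elsewhere.

Everything is driven by one master seed; the three stages use fixed seed
offsets so any stage can be re-run independently and every artifact is
byte-identical across runs. The molecules are valid in the supported
SMILES dialect but make no claim of drug-likeness, and the sequences are
i.i.d.-mutated rather than phylogenetic: passing tests demonstrate that
the pipeline recovers planted block structure, not that it matches any
particular real database.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .errors import ConfigurationError, ValidationError
from .io import write_fasta, write_interactions, write_smiles_library
from .records import InteractionSet, MoleculeRecord, ProteinRecord

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_MAX_DEG = {"C": 4, "N": 3, "O": 2, "S": 2}
_PALETTE = ("C", "N", "O", "S")

# fixed per-stage seed offsets from the master seed
_SEED_COMPOUNDS, _SEED_PROTEINS, _SEED_INTERACTIONS = 1, 2, 3


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic per-class dataset.

    Defaults: 4 compound clusters x 25 members against 4 protein
    families x 10 members, in-block edge probability 0.30 and off-block
    0.01 (roughly 8% positive prevalence, comparable to the sparse
    per-class interaction matrices the method is used on).
    """

    n_compound_clusters: int = 4
    compounds_per_cluster: int = 25
    n_protein_families: int = 4
    proteins_per_family: int = 10
    scaffold_size_range: tuple[int, int] = (8, 12)
    decoration_rate: float = 0.15
    ring_closure_prob: float = 0.5
    sequence_length_range: tuple[int, int] = (150, 250)
    family_mutation_rate: float = 0.1
    p_in: float = 0.3
    p_out: float = 0.01
    affinity_map: tuple[tuple[float, ...], ...] | None = None
    protein_class: str = "GPCR"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_compound_clusters", "compounds_per_cluster",
                     "n_protein_families", "proteins_per_family"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("decoration_rate", "family_mutation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.affinity_map is None and not 0 <= self.p_out < self.p_in <= 1:
            raise ConfigurationError("require 0 <= p_out < p_in <= 1")
        for lo, hi in (self.scaffold_size_range, self.sequence_length_range):
            if not 2 <= lo <= hi:
                raise ConfigurationError("size ranges must satisfy 2 <= lo <= hi")

    def affinity(self) -> np.ndarray:
        """Cluster x family edge-probability matrix; by default ``p_in`` on
        the matched (diagonal, modulo) blocks and ``p_out`` elsewhere."""
        if self.affinity_map is not None:
            a = np.asarray(self.affinity_map, dtype=float)
            if a.shape != (self.n_compound_clusters, self.n_protein_families):
                raise ConfigurationError("affinity_map shape must be clusters x families")
            return a
        a = np.full((self.n_compound_clusters, self.n_protein_families), self.p_out)
        for i in range(self.n_compound_clusters):
            a[i, i % self.n_protein_families] = self.p_in
        return a


def _build_mol(elements: list[str], bonds: list[tuple[int, int]]) -> Chem.Mol:
    rw = Chem.RWMol()
    for el in elements:
        rw.AddAtom(Chem.Atom(el))
    for a, b in bonds:
        rw.AddBond(a, b, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _random_scaffold(rng: np.random.Generator, cfg: GeneratorConfig,
                     weights: np.ndarray) -> tuple[list[str], list[tuple[int, int]]]:
    """Random connected tree over the palette plus an optional ring closure."""
    lo, hi = cfg.scaffold_size_range
    for _ in range(50):
        n = int(rng.integers(lo, hi + 1))
        elements = [str(e) for e in rng.choice(_PALETTE, size=n, p=weights)]
        deg = [0] * n
        bonds: list[tuple[int, int]] = []
        ok = True
        for i in range(1, n):
            cand = [j for j in range(i) if deg[j] < _MAX_DEG[elements[j]]]
            if not cand:
                ok = False
                break
            j = int(cand[rng.integers(len(cand))])
            bonds.append((j, i))
            deg[j] += 1
            deg[i] += 1
        if not ok:
            continue
        if rng.random() < cfg.ring_closure_prob:
            bonded = set(bonds)
            cand2 = [(a, b) for a in range(n) for b in range(a + 1, n)
                     if (a, b) not in bonded
                     and deg[a] < _MAX_DEG[elements[a]] and deg[b] < _MAX_DEG[elements[b]]]
            if cand2:
                a, b = cand2[rng.integers(len(cand2))]
                bonds.append((a, b))
                deg[a] += 1
                deg[b] += 1
        return elements, bonds
    raise ValidationError("could not build a valence-satisfying scaffold after 50 tries")


def _decorate(rng: np.random.Generator, elements: list[str],
              bonds: list[tuple[int, int]], rate: float) -> tuple[list[str], list[tuple[int, int]]]:
    """Random per-site mutations: element substitution C<->N<->O or an
    appended methyl/hydroxyl branch."""
    elements = list(elements)
    bonds = list(bonds)
    deg = [0] * len(elements)
    for a, b in bonds:
        deg[a] += 1
        deg[b] += 1
    n0 = len(elements)
    for i in range(n0):
        if rng.random() >= rate:
            continue
        if rng.random() < 0.5:  # substitute element, valence permitting
            options = [e for e in ("C", "N", "O")
                       if e != elements[i] and deg[i] <= _MAX_DEG[e]]
            if options:
                elements[i] = str(options[rng.integers(len(options))])
        else:  # append a small branch
            if deg[i] < _MAX_DEG[elements[i]]:
                new_el = "C" if rng.random() < 0.5 else "O"
                elements.append(new_el)
                bonds.append((i, len(elements) - 1))
                deg[i] += 1
                deg.append(1)
    return elements, bonds


def generate_compounds(cfg: GeneratorConfig) -> tuple[list[MoleculeRecord], dict[str, int]]:
    """Clustered compound library; returns records and id -> cluster labels."""
    rng = np.random.default_rng(cfg.seed + _SEED_COMPOUNDS)
    records: list[MoleculeRecord] = []
    labels: dict[str, int] = {}
    for k in range(cfg.n_compound_clusters):
        weights = rng.dirichlet([6.0, 1.5, 1.5, 1.0])  # C-leaning, cluster-specific palette
        elements, bonds = _random_scaffold(rng, cfg, weights)
        for m in range(cfg.compounds_per_cluster):
            for attempt in range(20):
                try:
                    els, bds = _decorate(rng, elements, bonds, cfg.decoration_rate)
                    mol = _build_mol(els, bds)
                    break
                except Exception:
                    if attempt == 19:
                        raise ValidationError("decoration failed 20 times; check valence budgets")
            smiles = Chem.MolToSmiles(mol)
            rec_id = f"cmpd{k}_{m:03d}"
            records.append(MoleculeRecord(id=rec_id, smiles=smiles,
                                          mol=Chem.MolFromSmiles(smiles)))
            labels[rec_id] = k
    return records, labels


def generate_proteins(cfg: GeneratorConfig) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Families of homologous sequences; returns records and id -> family."""
    rng = np.random.default_rng(cfg.seed + _SEED_PROTEINS)
    lo, hi = cfg.sequence_length_range
    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    for f in range(cfg.n_protein_families):
        length = int(rng.integers(lo, hi + 1))
        ancestor = rng.choice(_AMINO, size=length)
        for m in range(cfg.proteins_per_family):
            seq = ancestor.copy()
            mutate = rng.random(length) < cfg.family_mutation_rate
            for pos in np.nonzero(mutate)[0]:
                choices = _AMINO[_AMINO != seq[pos]]
                seq[pos] = choices[rng.integers(len(choices))]
            rec_id = f"prot{f}_{m:02d}"
            records.append(ProteinRecord(id=rec_id, sequence="".join(seq),
                                         protein_class=cfg.protein_class))
            labels[rec_id] = f
    return records, labels


def generate_interactions(
    compound_labels: dict[str, int],
    protein_labels: dict[str, int],
    cfg: GeneratorConfig,
) -> InteractionSet:
    """Independent Bernoulli edges with block-elevated probability."""
    rng = np.random.default_rng(cfg.seed + _SEED_INTERACTIONS)
    affinity = cfg.affinity()
    compounds = tuple(compound_labels)
    proteins = tuple(protein_labels)
    edges = set()
    for c in compounds:
        for p in proteins:
            if rng.random() < affinity[compound_labels[c], protein_labels[p]]:
                edges.add((c, p))
    return InteractionSet(compound_ids=compounds, protein_ids=proteins,
                          edges=frozenset(edges), protein_class=cfg.protein_class)


@dataclass
class SyntheticDataset:
    """One generated per-class dataset plus its ground-truth labels."""

    config: GeneratorConfig
    compounds: list[MoleculeRecord]
    compound_clusters: dict[str, int]
    proteins: list[ProteinRecord]
    protein_families: dict[str, int]
    interactions: InteractionSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": outdir / "compounds.smi",
            "proteins": outdir / "proteins.fasta",
            "interactions": outdir / "interactions.tsv",
            "labels": outdir / "labels.tsv",
        }
        write_smiles_library(self.compounds, paths["compounds"])
        write_fasta(self.proteins, paths["proteins"])
        write_interactions(self.interactions, paths["interactions"])
        with open(paths["labels"], "w", encoding="utf-8", newline="\n") as fh:
            fh.write("entity_id\tkind\tgroup\n")
            for rec in self.compounds:
                fh.write(f"{rec.id}\tcompound\t{self.compound_clusters[rec.id]}\n")
            for rec in self.proteins:
                fh.write(f"{rec.id}\tprotein\t{self.protein_families[rec.id]}\n")
        return paths


def generate_dataset(cfg: GeneratorConfig = GeneratorConfig(),
                     outdir: str | Path | None = None) -> SyntheticDataset:
    """Run all three generator stages from one config."""
    compounds, c_labels = generate_compounds(cfg)
    proteins, p_labels = generate_proteins(cfg)
    interactions = generate_interactions(c_labels, p_labels, cfg)
    ds = SyntheticDataset(
        config=cfg, compounds=compounds, compound_clusters=c_labels,
        proteins=proteins, protein_families=p_labels, interactions=interactions,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds
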