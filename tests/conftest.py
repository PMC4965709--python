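"""Shared fixtures: parsed molecule panels and the default synthetic dataset
with its kernels and one audited cross-validation run (computed once per
session; several tests interrogate different properties of the same run)."""
from __future__ import annotations

import pytest

import blmdti as b

# molecules <= 12 heavy atoms spanning the supported dialect: chains,
# branches, rings, aromatics, heteroatoms, charges, multi-fragment dots
FIXTURE_SMILES = {
    "methane": "C",
    "ethanol": "CCO",
    "propane": "CCC",
    "butane": "CCCC",
    "isobutane": "CC(C)C",
    "neopentane": "CC(C)(C)C",
    "cyclopropane": "C1CC1",
    "cyclohexane": "C1CCCCC1",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "pyridine": "c1ccncc1",
    "phenol": "Oc1ccccc1",
    "acetate": "CC(=O)[O-]",
    "ammonium": "[NH4+]",
    "acetonitrile": "CC#N",
    "dms": "CSC",
    "salt_pair": "CCO.CC",
    "octane_pct_ring": "C%10CCCCC%10",
}


@pytest.fixture(scope="session")
def molecules() -> dict:
    return {name: b.parse_smiles(smi) for name, smi in FIXTURE_SMILES.items()}


@pytest.fixture(scope="session")
def default_dataset() -> b.SyntheticDataset:
    """The shipped study conditions: 4x25 compounds vs 4x10 proteins,
    p_in=0.3 / p_out=0.01, master seed 17 (the package default seed)."""
    return b.generate_dataset(b.GeneratorConfig(seed=17))


@pytest.fixture(scope="session")
def default_kernels(default_dataset):
    fps = [b.fingerprint(m.mol) for m in default_dataset.compounds]
    chem = b.build_similarity_matrix(fps, [m.id for m in default_dataset.compounds])
    seq = b.build_protein_similarity_matrix(default_dataset.proteins)
    return fps, chem, seq


@pytest.fixture(scope="session")
def default_cv(default_dataset, default_kernels) -> b.CVResult:
    _, chem, seq = default_kernels
    return b.cross_validate(chem, seq, default_dataset.interactions,
                            k=10, seed=17, audit=True)


@pytest.fixture(scope="session")
def clean_dataset() -> b.SyntheticDataset:
    """Small, cleanly separable dataset (no off-block edges, mild noise)
    for consistency-style checks."""
    cfg = b.GeneratorConfig(
        n_compound_clusters=2, compounds_per_cluster=8,
        n_protein_families=2, proteins_per_family=4,
        p_in=0.9, p_out=0.0, decoration_rate=0.1,
        sequence_length_range=(60, 80), seed=5,
    )
    return b.generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_kernels(clean_dataset):
    fps = [b.fingerprint(m.mol) for m in clean_dataset.compounds]
    chem = b.build_similarity_matrix(fps, [m.id for m in clean_dataset.compounds])
    seq = b.build_protein_similarity_matrix(clean_dataset.proteins)
    return fps, chem, seq
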