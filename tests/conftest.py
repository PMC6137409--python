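"""Shared fixtures: small simulated datasets imported into databases."""

from __future__ import annotations

import numpy as np
import pytest

from genodb import build_database, open_session
from genodb.synthdata import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Small two-chromosome dataset with missingness, imported and opened."""
    root = tmp_path_factory.mktemp("toy")
    spec = SimulationSpec(
        seed=11,
        n_pedigrees=5,
        offspring_per_pedigree=4,
        n_markers=37,
        chromosomes=(1, 2),
        bp_span=(1_000, 2_000_000),
        missing_rate=0.05,
    )
    ds = simulate_dataset(spec, root / "toy")
    db_path, report = build_database(ds.ped_path, ds.map_path, root / "toy.db")
    return spec, ds, db_path, report


@pytest.fixture()
def toy_session(toy):
    _, _, db_path, _ = toy
    return open_session(db_path)


@pytest.fixture(scope="session")
def nuc(tmp_path_factory):
    """Nucleotide-labelled dataset (for VCF/tped round trips)."""
    root = tmp_path_factory.mktemp("nuc")
    spec = SimulationSpec(
        seed=23,
        n_pedigrees=4,
        offspring_per_pedigree=3,
        n_markers=25,
        chromosomes=(1, 3),
        bp_span=(500, 900_000),
        missing_rate=0.08,
        allele_scheme="ACGT",
    )
    ds = simulate_dataset(spec, root / "nuc")
    db_path, _ = build_database(ds.ped_path, ds.map_path, root / "nuc.db")
    return spec, ds, db_path


@pytest.fixture()
def nuc_session(nuc):
    _, _, db_path = nuc
    return open_session(db_path)


def random_tableset(rng: np.random.Generator, tmp_path, tag: str):
    """Build a small random TableSet by simulating and importing."""
    from genodb.datastore import read_tables

    spec = SimulationSpec(
        seed=int(rng.integers(2**31)),
        n_pedigrees=int(rng.integers(1, 4)),
        offspring_per_pedigree=int(rng.integers(1, 4)),
        n_markers=int(rng.integers(1, 12)),
        chromosomes=(1, 2)[: int(rng.integers(1, 3))],
        bp_span=(100, 50_000),
        missing_rate=float(rng.uniform(0, 0.3)),
    )
    ds = simulate_dataset(spec, tmp_path / f"rt{tag}")
    db_path, _ = build_database(ds.ped_path, ds.map_path, tmp_path / f"rt{tag}.db")
    return read_tables(db_path)
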