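"""Shared fixtures: small hand-built atom models and generator outputs."""

from __future__ import annotations

import numpy as np
import pytest

from peptifiber import AtomModel, GeneratorSpec, make_monomer


def build_model(
    coords,
    radii=None,
    monomer_ids=None,
    regions=None,
    residues=None,
    elements=None,
    markers=None,
    probe_radius=0.14,
) -> AtomModel:
    """Terse AtomModel builder for hand-constructed test geometries."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return AtomModel(
        atom_ids=np.arange(1, n + 1),
        monomer_ids=np.asarray(monomer_ids) if monomer_ids is not None else np.ones(n, int),
        residues=np.asarray(residues, object) if residues is not None else np.array(["UNK"] * n, object),
        regions=np.asarray(regions, object) if regions is not None else np.array(["other"] * n, object),
        elements=np.asarray(elements, object) if elements is not None else np.array(["C"] * n, object),
        radii=np.asarray(radii, float) if radii is not None else np.full(n, 0.17),
        coords=coords,
        markers=markers or {},
        probe_radius=probe_radius,
    )


@pytest.fixture(scope="session")
def template():
    """One deterministic toy monomer shared across tests."""
    return make_monomer(GeneratorSpec(seed=7))


@pytest.fixture()
def single_atom():
    return build_model([[0.0, 0.0, 0.0]], radii=[0.15])
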