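"""Shared fixtures: small synthetic complexes and helper constructors."""

from __future__ import annotations

import numpy as np
import pytest

from rnabind.structures import Atom, Residue, Complex
from rnabind.synthetic import SynthConfig, generate_complex


def make_residue(chain_id: str, idx: int, aa: str, positions,
                 names=None, elements=None) -> Residue:
    positions = np.atleast_2d(np.asarray(positions, float))
    names = names or [f"X{k}" for k in range(len(positions))]
    elements = elements or ["C"] * len(positions)
    atoms = [Atom(n, e, p) for n, e, p in zip(names, elements, positions)]
    return Residue(chain_id, idx, aa, atoms)


def single_atom_chain(points, aa_codes=None, chain_id="A"):
    points = np.asarray(points, float)
    aa_codes = aa_codes or ["A"] * len(points)
    return [make_residue(chain_id, i + 1, aa, [p], names=["CA"])
            for i, (p, aa) in enumerate(zip(points, aa_codes))]


def rigid_transform(rng: np.random.Generator):
    """A random rotation + translation as a function on (n,3) coordinates."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return lambda xyz: xyz @ R.T + t


def transform_complex(cx: Complex, f) -> Complex:
    def conv_chain(chain):
        out = []
        for r in chain:
            atoms = [Atom(a.name, a.element, f(a.position[None])[0])
                     for a in r.atoms]
            out.append(Residue(r.chain_id, r.seq_index, r.aa_code, atoms,
                               pdb_resseq=r.pdb_resseq))
        return out

    return Complex(cx.id, [conv_chain(c) for c in cx.protein_chains],
                   [conv_chain(c) for c in cx.rna_chains])


@pytest.fixture(scope="session")
def small_complex():
    """A 30-residue synthetic complex with its annotation."""
    cfg = SynthConfig(n_residues=30, n_nucleotides=8, seed=5)
    return generate_complex(cfg)


@pytest.fixture(scope="session")
def medium_chain():
    """A 20-residue protein chain with multi-atom residues."""
    cfg = SynthConfig(n_residues=20, n_nucleotides=5, seed=9)
    cx, _ = generate_complex(cfg)
    return cx.protein_chains[0]
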