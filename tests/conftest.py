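"""Shared fixtures: synthetic complexes are expensive (SASA), so the
standard toy complex and its analysis are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ifevol import (
    ComplexStructure,
    Atom,
    Chain,
    Residue,
    analyze_complex,
    build_toy_complex,
    derive_interolog,
)
from ifevol.synth import PerturbationSpec, ToySpec


def make_residue(chain_id, number, aa, atoms):
    """Residue from a list of (name, element, xyz) tuples."""
    return Residue(
        chain_id=chain_id,
        number=number,
        icode="",
        aa_type=aa,
        atoms=[Atom(name=n, element=e, coords=np.array(xyz, float)) for n, e, xyz in atoms],
    )


def make_complex(res_a, res_b):
    return ComplexStructure(
        receptor=Chain(chain_id="A", residues=list(res_a)),
        ligand=Chain(chain_id="B", residues=list(res_b)),
        source_id="fixture",
    )


@pytest.fixture(scope="session")
def toy():
    """Standard planted toy complex, its ground truth and full analysis."""
    structure, truth = build_toy_complex(ToySpec(seed=1))
    analysis = analyze_complex(structure)
    return structure, truth, analysis


@pytest.fixture(scope="session")
def toy_pair(toy):
    """Toy complex plus a perturbed interolog (mixed, moderate rates)."""
    structure, truth, analysis = toy
    pert = PerturbationSpec(mutation_rate=0.2, switch_rate=0.15, rewire_rate=0.3, seed=17)
    derived, truth2 = derive_interolog(structure, truth, pert)
    analysis_b = analyze_complex(derived)
    return structure, derived, truth2, analysis, analysis_b


@pytest.fixture(scope="session")
def identity_corr(toy_pair):
    from ifevol.compare import CorrespondenceMap

    _sa, _sb, truth2, _aa, _ab = toy_pair
    return CorrespondenceMap(
        mapping=dict(truth2.correspondence), chain_pairing=[("A", "A"), ("B", "B")]
    )
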