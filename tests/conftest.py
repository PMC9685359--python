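import numpy as np
import pytest

from vacuform.core import AtomRecord, StructureModel, assign_solution_charges


def make_structure(residues, spacing=4.0, chain_offset=None):
    """Build a toy StructureModel from [(chain, resname), ...].

    Each residue gets N/CA/C/O/CB pseudo-atoms on a line along x, chains
    displaced along y. Charges are NOT assigned.
    """
    if chain_offset is None:
        chain_offset = np.array([0.0, 12.0, 0.0])
    atoms = []
    counters = {}
    offsets = {"N": (-1.2, 0.0, 0.0), "CA": (0.0, 0.0, 0.0),
               "C": (1.2, 0.0, 0.0), "O": (1.6, 1.0, 0.0),
               "CB": (0.0, -1.4, 0.6)}
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    chain_rank = {}
    for chain, resname in residues:
        ri = counters.get(chain, 0)
        counters[chain] = ri + 1
        if chain not in chain_rank:
            chain_rank[chain] = len(chain_rank)
        base = np.array([spacing * ri, 0.0, 0.0]) + chain_rank[chain] * chain_offset
        for name, off in offsets.items():
            atoms.append(AtomRecord(
                serial=len(atoms) + 1, name=name, element=elements[name],
                residue_index=ri, residue_name=resname, chain_id=chain,
                position=base + np.array(off), vdw_radius=1.7))
    return StructureModel(atoms)


@pytest.fixture
def toy_dimer():
    """Small deterministic homodimer with solution charges assigned."""
    from vacuform.synth import build_toy_dimer

    return build_toy_dimer(n_res_per_chain=24, seed=1)


@pytest.fixture
def charged_chain():
    """Single chain Gly-Lys-Asp-Gly with pH-7 charges."""
    s = make_structure([("A", "GLY"), ("A", "LYS"), ("A", "ASP"), ("A", "GLY")])
    return assign_solution_charges(s)
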