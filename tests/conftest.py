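"""Shared fixtures: toy structures, a small simulated library, DP oracle."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.PDB.StructureBuilder import StructureBuilder

import createscan as cs
from createscan.sim import GeneSpec, SimConfig


def build_structure(residues, het_atoms=()):
    """Programmatic Bio.PDB structure.

    ``residues``: list of (resseq, resname, [(atom_name, element, xyz), ...])
    ``het_atoms``: list of (atom_name, element, xyz) placed in one HETATM
    ligand residue.  Returns (structure, ligand_atoms).
    """
    sb = StructureBuilder()
    sb.init_structure("toy")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for resseq, resname, atoms in residues:
        sb.init_residue(resname, " ", resseq, " ")
        for name, element, xyz in atoms:
            sb.init_atom(name, np.array(xyz, dtype=float), 1.0, 1.0, " ",
                         name.ljust(4), None, element)
    ligand = []
    if het_atoms:
        sb.init_residue("LIG", "H_LIG", 9000, " ")
        for name, element, xyz in het_atoms:
            sb.init_atom(name, np.array(xyz, dtype=float), 1.0, 1.0, " ",
                         name.ljust(4), None, element)
    structure = sb.get_structure()
    if het_atoms:
        for res in structure.get_residues():
            if res.get_id()[0] != " ":
                ligand = list(res.get_atoms())
    return structure, ligand


def hw_edit_distance(query: str, target: str) -> int:
    """Quadratic DP infix edit distance (free gaps at target ends).

    Independent reference for the alignment backend: row-wise
    Needleman-Wunsch/Sellers recurrence with the horizontal-gap step done
    by a prefix-minimum, answer = min over the last row.
    """
    q = np.frombuffer(query.encode(), dtype="S1")
    t = np.frombuffer(target.encode(), dtype="S1")
    n = t.size
    prev = np.zeros(n + 1, dtype=np.int32)  # free leading target gaps
    jj = np.arange(n + 1, dtype=np.int32)
    for i in range(1, q.size + 1):
        sub = prev[:-1] + (t != q[i - 1])
        up = prev[1:] + 1
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        cur[1:] = np.minimum(sub, up)
        # left-gap closure: cur[j] = min_k<=j cur[k] + (j - k)
        cur = np.minimum.accumulate(cur - jj) + jj
        prev = cur
    return int(prev.min())


@pytest.fixture(scope="session")
def tiny_config():
    """Two-gene, six-site library at shallow depth: fast end-to-end runs."""
    return SimConfig(
        genes=[
            GeneSpec("geneA", "biosynthesis", n_sites=4),
            GeneSpec("geneB", "transport", n_sites=2),
        ],
        epsilon=0.03,
        depth_pre=20_000,
        depth_post=20_000,
        depth_window=20_000,
        n_replicates=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_library(tiny_config):
    return cs.simulate_library(tiny_config)
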