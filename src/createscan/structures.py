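"""Structure-guided selection of mutagenesis sites.

Targeted residues are those whose heavy atoms fall within a fixed-radius
shell (default 6.0 Å, inclusive) of caller-declared binding atoms —
substrate, co-factor, DNA, or allosteric-factor atoms.  Hydrogens are
ignored because their positions are unreliable in crystal structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .codons import THREE_TO_ONE, translate_codon


@dataclass(frozen=True)
class ResidueSite:
    """One targeted residue position in a gene.

    ``residue_index`` is 1-based protein coordinates; ``cds_offset`` is the
    0-based nucleotide offset of the codon within the coding sequence
    (3 * (residue_index - 1)).  Codon fields may be unset until the site is
    attached to its coding sequence with :meth:`with_cds`.
    """

    gene_id: str
    chain: str
    residue_index: int
    wt_aa: str
    wt_codon: Optional[str] = None
    cds_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if self.wt_codon is not None:
            if translate_codon(self.wt_codon) != self.wt_aa:
                raise ValueError(
                    f"wt_codon {self.wt_codon} does not encode {self.wt_aa}"
                )
            if self.cds_offset != 3 * (self.residue_index - 1):
                raise ValueError("cds_offset must equal 3*(residue_index-1)")

    def with_cds(self, cds: str) -> "ResidueSite":
        """Fill codon fields from the gene's coding sequence."""
        offset = 3 * (self.residue_index - 1)
        codon = cds[offset : offset + 3].upper()
        if len(codon) != 3:
            raise ValueError(f"CDS too short for residue {self.residue_index}")
        if translate_codon(codon) != self.wt_aa:
            raise ValueError(
                f"CDS codon {codon} at residue {self.residue_index} encodes "
                f"{translate_codon(codon)}, expected {self.wt_aa}"
            )
        return replace(self, wt_codon=codon, cds_offset=offset)


def site_from_cds(gene_id: str, cds: str, residue_index: int, chain: str = "A") -> ResidueSite:
    """Build a fully specified site directly from a coding sequence."""
    offset = 3 * (residue_index - 1)
    codon = cds[offset : offset + 3].upper()
    if len(codon) != 3:
        raise ValueError(f"CDS too short for residue {residue_index}")
    return ResidueSite(
        gene_id=gene_id,
        chain=chain,
        residue_index=residue_index,
        wt_aa=translate_codon(codon),
        wt_codon=codon,
        cds_offset=offset,
    )


def _is_heavy(atom) -> bool:
    element = (getattr(atom, "element", "") or "").strip().upper()
    if element:
        return element != "H"
    return not atom.get_name().strip().startswith("H")


def select_shell_residues(
    structure,
    binding_atoms: Sequence,
    radius: float = 6.0,
    gene_id: str = "",
) -> list[ResidueSite]:
    """Select protein residues within ``radius`` Å of any binding atom.

    Parameters
    ----------
    structure
        A Bio.PDB entity (Structure/Model/Chain) whose atoms carry chain,
        residue index and coordinates.
    binding_atoms
        Non-empty sequence of Bio.PDB atoms defining the binding site
        (substrate, co-factor, DNA or allosteric-factor atoms).
    radius
        Inclusive Euclidean distance cutoff in Å; must be positive.
    gene_id
        Gene identifier stamped onto the returned sites.

    Returns
    -------
    list of :class:`ResidueSite`, sorted by (chain, residue_index), with
    codon fields unset (attach a CDS with :meth:`ResidueSite.with_cds`).
    Hetero/non-protein residues — including the binding groups themselves —
    are excluded; only heavy atoms enter the distance computation.
    """
    if len(binding_atoms) == 0:
        raise ValueError("no binding sites declared")
    if radius <= 0:
        raise ValueError("radius must be positive")

    site_coords = np.asarray(
        [a.get_coord() for a in binding_atoms if _is_heavy(a)], dtype=float
    )
    if site_coords.size == 0:
        raise ValueError("no binding sites declared")

    hits: list[ResidueSite] = []
    for residue in structure.get_residues():
        hetflag, resseq, _icode = residue.get_id()
        if hetflag.strip():  # skip waters and hetero groups
            continue
        resname = residue.get_resname().strip().upper()
        if resname not in THREE_TO_ONE:
            continue
        coords = np.asarray(
            [a.get_coord() for a in residue.get_atoms() if _is_heavy(a)], dtype=float
        )
        if coords.size == 0:
            warnings.warn(
                f"residue {resname} {resseq} has no heavy-atom coordinates; skipped"
            )
            continue
        d = np.linalg.norm(coords[:, None, :] - site_coords[None, :, :], axis=-1)
        if d.min() <= radius:
            chain_id = residue.get_parent().get_id()
            hits.append(
                ResidueSite(
                    gene_id=gene_id,
                    chain=str(chain_id),
                    residue_index=int(resseq),
                    wt_aa=THREE_TO_ONE[resname],
                )
            )
    hits.sort(key=lambda s: (s.chain, s.residue_index))
    return hits
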