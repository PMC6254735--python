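"""CREATE cassette design: codon saturation, spacer choice, PAM-kill, assembly.

Each targeted residue receives 20 designs — 19 missense substitutions using
one preferred codon per amino acid and one synonymous design recoding the
wild-type amino acid with an alternate codon (so it is sequence-distinguishable
from wild type and can serve as the neutral null).  Every design is packaged
as a 230-nt cassette:

    18 nt subpool primer | 12 nt variant primer | 118 nt homology arm |
    35 nt J23119 promoter | 3 nt linker (ATC) | 20 nt spacer | 24 nt scaffold 5'

The homology arm carries the designed codon edit plus a synonymous PAM-kill
substitution that prevents Cas9 re-cutting of the repaired locus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .codons import (
    AMINO_ACIDS,
    DEFAULT_CODON_TABLE,
    PREFERRED_CODONS,
    revcomp,
    translate_codon,
)
from .structures import ResidueSite

# J23119 constitutive promoter (35 nt) and the 5' 24 nt of the canonical
# S. pyogenes sgRNA scaffold.
PROMOTER_J23119 = "TTGACAGCTAGCTCAGTCCTAGGTATAATGCTAGC"
LINKER = "ATC"
SCAFFOLD5 = "GTTTTAGAGCTAGAAATAGCAAGT"

SUBPOOL_PRIMER_LEN = 18
VARIANT_PRIMER_LEN = 12
ARM_LEN = 118
SPACER_LEN = 20
CASSETTE_LEN = 230

# homology-arm split around the 3-nt codon: 58 nt left, 57 nt right
ARM_LEFT = 58
ARM_RIGHT = ARM_LEN - ARM_LEFT - 3

SEED_LEN = 10  # PAM-proximal protospacer bases where a mismatch blocks cutting


@dataclass(frozen=True)
class MutationDesign:
    """One amino-acid substitution at one residue site."""

    design_id: str
    site: ResidueSite
    target_aa: str
    target_codon: str
    is_synonymous: bool

    def __post_init__(self) -> None:
        if translate_codon(self.target_codon) != self.target_aa:
            raise ValueError(
                f"target_codon {self.target_codon} does not encode {self.target_aa}"
            )
        if self.is_synonymous != (self.target_aa == self.site.wt_aa):
            raise ValueError("is_synonymous inconsistent with amino acids")
        if self.is_synonymous and self.target_codon == self.site.wt_codon:
            raise ValueError("synonymous design must differ from the native codon")


@dataclass(frozen=True)
class Substitution:
    """Single-nucleotide substitution in genome coordinates (0-based)."""

    pos: int
    ref: str
    alt: str

    def apply(self, seq: str, offset: int = 0) -> str:
        i = self.pos - offset
        if seq[i] != self.ref:
            raise ValueError(f"reference mismatch at {self.pos}: {seq[i]} != {self.ref}")
        return seq[:i] + self.alt + seq[i + 1 :]


@dataclass(frozen=True)
class SpacerHit:
    """A 20-nt protospacer and its NGG PAM in genome coordinates."""

    spacer: str  # 5'->3' protospacer as it appears in the gRNA
    pam_start: int  # 0-based start of the 3-nt PAM on the + strand coordinates
    strand: str  # '+' or '-'
    distance: int  # nt gap between the PAM and the edited codon (0 = overlap)


@dataclass(frozen=True)
class Cassette:
    design: MutationDesign
    subpool_primer: str
    variant_primer: str
    homology_arm: str
    promoter: str
    linker: str
    spacer: str
    scaffold5: str
    pam_kill: Substitution
    spacer_hit: SpacerHit = field(repr=False, compare=False, default=None)
    arm_start: int = 0  # genome coordinate of the arm's first base

    @property
    def full_seq(self) -> str:
        return (
            self.subpool_primer
            + self.variant_primer
            + self.homology_arm
            + self.promoter
            + self.linker
            + self.spacer
            + self.scaffold5
        )


def saturate_site(
    site: ResidueSite,
    codon_table: Optional[dict[str, str]] = None,
    fallback_codons: Optional[dict[str, Sequence[str]]] = None,
) -> list[MutationDesign]:
    """Enumerate the 20 designs (19 missense + 1 synonymous) for a site.

    ``codon_table`` maps each amino acid to its single preferred codon
    (defaults to the package's E. coli table).  When the preferred codon of
    the wild-type amino acid equals the native codon, the synonymous design
    falls back to the next-ranked codon from ``fallback_codons`` (defaults
    to the package's ranked table); with no fallback available an error is
    raised because the synonymous design would be unobservable.
    """
    if site.wt_codon is None:
        raise ValueError("site lacks codon annotation; attach a CDS first")
    table = DEFAULT_CODON_TABLE if codon_table is None else codon_table
    if fallback_codons is None:
        fallback_codons = PREFERRED_CODONS if codon_table is None else {}
    missing = [aa for aa in AMINO_ACIDS if aa not in table]
    if missing:
        raise ValueError(f"codon table lacks amino acids: {missing}")

    designs: list[MutationDesign] = []
    for aa in AMINO_ACIDS:
        codon = table[aa]
        if aa == site.wt_aa and codon == site.wt_codon:
            alternates = [
                c for c in fallback_codons.get(aa, ()) if c != site.wt_codon
            ]
            if not alternates:
                raise ValueError(
                    "synonymous design impossible at this site; "
                    "supply alternate synonymous codon"
                )
            codon = alternates[0]
        designs.append(
            MutationDesign(
                design_id=f"{site.gene_id}_{site.wt_aa}{site.residue_index}{aa}",
                site=site,
                target_aa=aa,
                target_codon=codon,
                is_synonymous=(aa == site.wt_aa),
            )
        )
    return designs


def _candidate_pams(
    genome: str, window_start: int, window_end: int, edit_start: int, edit_end: int
) -> list[SpacerHit]:
    """All NGG PAMs (both strands) whose 3 nt lie inside the window."""

    def interval_gap(a0: int, a1: int, b0: int, b1: int) -> int:
        if a1 <= b0:
            return b0 - a1
        if b1 <= a0:
            return a0 - b1
        return 0

    hits: list[SpacerHit] = []
    for p in range(max(window_start, 0), min(window_end - 3, len(genome) - 3) + 1):
        # + strand: PAM = genome[p:p+3] ending GG; protospacer is the 20 nt 5' of it
        if genome[p + 1 : p + 3] == "GG" and p >= SPACER_LEN:
            hits.append(
                SpacerHit(
                    spacer=genome[p - SPACER_LEN : p],
                    pam_start=p,
                    strand="+",
                    distance=interval_gap(p, p + 3, edit_start, edit_end),
                )
            )
        # - strand: + strand shows CCN; protospacer is the 20 nt 3' of it, revcomp'd
        if genome[p : p + 2] == "CC" and p + 3 + SPACER_LEN <= len(genome):
            hits.append(
                SpacerHit(
                    spacer=revcomp(genome[p + 3 : p + 3 + SPACER_LEN]),
                    pam_start=p,
                    strand="-",
                    distance=interval_gap(p, p + 3, edit_start, edit_end),
                )
            )
    # nearest PAM wins; ties: + strand first, then smaller genomic coordinate
    hits.sort(key=lambda h: (h.distance, h.strand != "+", h.pam_start))
    return hits


def design_pam_kill(
    genome: str,
    hit: SpacerHit,
    cds_start: int,
    cds_end: int,
    exclude: tuple[int, int] = (0, 0),
    within: Optional[tuple[int, int]] = None,
) -> Substitution:
    """Find a synonymous single-nt substitution disrupting ``hit``'s PAM.

    Preference order: (1) destroy the NGG itself, third-codon-position
    changes first; (2) any synonymous change within the 10-nt seed region
    of the protospacer.  Positions inside ``exclude`` (the designed codon
    edit, half-open genome interval) are never used; when ``within`` is
    given (the homology-arm window) the substitution must fall inside it.
    """
    if hit.strand == "+":
        pam_positions = [hit.pam_start + 1, hit.pam_start + 2]  # the two G's
        seed_positions = list(range(hit.pam_start - SEED_LEN, hit.pam_start))
        pam_intact = lambda g: g[hit.pam_start + 1 : hit.pam_start + 3] == "GG"
    else:
        pam_positions = [hit.pam_start, hit.pam_start + 1]  # the CC (G's on -)
        seed_positions = list(range(hit.pam_start + 3, hit.pam_start + 3 + SEED_LEN))
        pam_intact = lambda g: g[hit.pam_start : hit.pam_start + 2] == "CC"

    def synonymous_subs(pos: int) -> list[Substitution]:
        if not (cds_start <= pos < cds_end):
            return []
        if exclude[0] <= pos < exclude[1]:
            return []
        if within is not None and not (within[0] <= pos < within[1]):
            return []
        codon_idx = (pos - cds_start) // 3
        c0 = cds_start + 3 * codon_idx
        codon = genome[c0 : c0 + 3]
        aa = translate_codon(codon)
        if aa == "*":
            return []
        out = []
        for alt in "ACGT":
            if alt == genome[pos]:
                continue
            new_codon = codon[: pos - c0] + alt + codon[pos - c0 + 1 :]
            if translate_codon(new_codon) == aa:
                out.append(Substitution(pos=pos, ref=genome[pos], alt=alt))
        return out

    # tier 1: substitutions at the PAM G's that actually destroy the NGG,
    # codon third positions preferred
    tier1 = []
    for pos in pam_positions:
        for sub in synonymous_subs(pos):
            if not pam_intact(sub.apply(genome)):
                third = (pos - cds_start) % 3 == 2
                tier1.append((not third, pos, sub.alt, sub))
    if tier1:
        return min(tier1)[3]

    # tier 2: any synonymous change inside the seed (mismatch blocks cutting)
    for pos in sorted(p for p in seed_positions if 0 <= p < len(genome)):
        subs = synonymous_subs(pos)
        if subs:
            return subs[0]

    raise ValueError("cannot silently disrupt PAM")


def pick_spacer(
    genome: str,
    edit_start: int,
    edit_len: int = 3,
    window: Optional[tuple[int, int]] = None,
    cds_span: Optional[tuple[int, int]] = None,
) -> SpacerHit:
    """Choose the protospacer whose NGG PAM lies nearest the edit.

    ``window`` restricts the PAM search (defaults to the 118-nt homology-arm
    window around the edit).  When ``cds_span`` is given, candidates are
    additionally required to admit a synonymous PAM-kill, so the returned
    spacer is always usable in a cassette.  Ties break + strand first, then
    smaller genomic coordinate.
    """
    if window is None:
        window = (edit_start - ARM_LEFT, edit_start - ARM_LEFT + ARM_LEN)
    candidates = _candidate_pams(
        genome, window[0], window[1], edit_start, edit_start + edit_len
    )
    if not candidates:
        raise ValueError("no targetable PAM")
    if cds_span is None:
        return candidates[0]
    for hit in candidates:
        try:
            design_pam_kill(
                genome, hit, cds_span[0], cds_span[1],
                exclude=(edit_start, edit_start + edit_len),
                within=window,
            )
        except ValueError:
            continue
        return hit
    raise ValueError("no targetable PAM")


def random_primer(length: int, rng: random.Random) -> str:
    """Random primer with GC content in [40%, 60%]."""
    while True:
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        gc = (seq.count("G") + seq.count("C")) / length
        if 0.4 <= gc <= 0.6:
            return seq


def assemble_cassette(
    design: MutationDesign,
    spacer_hit: SpacerHit,
    pam_kill: Substitution,
    genome: str,
    cds_start: int,
    subpool_primer: str,
    variant_primer: str,
    promoter: str = PROMOTER_J23119,
    linker: str = LINKER,
    scaffold5: str = SCAFFOLD5,
) -> Cassette:
    """Build the 230-nt cassette for one design.

    The homology arm is the 118-nt genomic window placed 58 nt left /
    57 nt right of the 3-nt target codon, with the codon edit and the
    PAM-kill substitution applied.
    """
    if len(subpool_primer) != SUBPOOL_PRIMER_LEN:
        raise ValueError("subpool primer must be 18 nt")
    if len(variant_primer) != VARIANT_PRIMER_LEN:
        raise ValueError("variant primer must be 12 nt")
    if len(spacer_hit.spacer) != SPACER_LEN:
        raise ValueError("spacer must be 20 nt")

    codon_pos = cds_start + design.site.cds_offset
    arm_start = codon_pos - ARM_LEFT
    arm_end = arm_start + ARM_LEN
    if arm_start < 0 or arm_end > len(genome):
        raise ValueError("edit outside homology arm")
    if not (arm_start <= pam_kill.pos < arm_end):
        raise ValueError("edit outside homology arm")

    arm = genome[arm_start:arm_end]
    wt_codon = arm[ARM_LEFT : ARM_LEFT + 3]
    if wt_codon != design.site.wt_codon:
        raise ValueError(
            f"genome codon {wt_codon} does not match site wt_codon "
            f"{design.site.wt_codon}"
        )
    arm = arm[:ARM_LEFT] + design.target_codon + arm[ARM_LEFT + 3 :]
    arm = pam_kill.apply(arm, offset=arm_start)

    return Cassette(
        design=design,
        subpool_primer=subpool_primer,
        variant_primer=variant_primer,
        homology_arm=arm,
        promoter=promoter,
        linker=linker,
        spacer=spacer_hit.spacer,
        scaffold5=scaffold5,
        pam_kill=pam_kill,
        spacer_hit=spacer_hit,
        arm_start=arm_start,
    )


def revert_arm(cassette: Cassette) -> str:
    """Reconstruct the wild-type genomic window from a cassette's arm."""
    design = cassette.design
    arm = cassette.homology_arm
    # undo PAM kill, then the codon edit
    i = cassette.pam_kill.pos - cassette.arm_start
    if arm[i] != cassette.pam_kill.alt:
        raise ValueError("arm does not carry the recorded PAM kill")
    arm = arm[:i] + cassette.pam_kill.ref + arm[i + 1 :]
    if arm[ARM_LEFT : ARM_LEFT + 3] != design.target_codon:
        raise ValueError("arm does not carry the designed codon")
    return arm[:ARM_LEFT] + design.site.wt_codon + arm[ARM_LEFT + 3 :]


def design_cassette(
    design: MutationDesign,
    genome: str,
    cds_start: int,
    cds_end: int,
    subpool_primer: str,
    variant_primer: str,
) -> Cassette:
    """Convenience: pick spacer + PAM-kill and assemble in one step."""
    edit_start = cds_start + design.site.cds_offset
    window = (edit_start - ARM_LEFT, edit_start - ARM_LEFT + ARM_LEN)
    hit = pick_spacer(genome, edit_start, window=window, cds_span=(cds_start, cds_end))
    kill = design_pam_kill(
        genome, hit, cds_start, cds_end,
        exclude=(edit_start, edit_start + 3), within=window,
    )
    return assemble_cassette(
        design, hit, kill, genome, cds_start, subpool_primer, variant_primer
    )
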