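"""Library design: shell selection, codon saturation, spacer/PAM-kill,
cassette assembly."""

import numpy as np
import pytest

import createscan as cs
from createscan.codons import DEFAULT_CODON_TABLE, translate
from createscan.design import (
    ARM_LEFT,
    ARM_LEN,
    CASSETTE_LEN,
    SpacerHit,
    Substitution,
    revert_arm,
)
from createscan.structures import site_from_cds

from conftest import build_structure


# ---------------------------------------------------------------- shell


def test_shell_boundary_is_inclusive():
    structure, ligand = build_structure(
        [(1, "ALA", [("CA", "C", (6.0, 0.0, 0.0))])],
        het_atoms=[("O1", "O", (0.0, 0.0, 0.0))],
    )
    hits = cs.select_shell_residues(structure, ligand, radius=6.0, gene_id="g")
    assert [h.residue_index for h in hits] == [1]


def test_shell_excludes_distant_residues_and_hydrogens():
    structure, ligand = build_structure(
        [
            (1, "ALA", [("CA", "C", (7.5, 0.0, 0.0))]),
            # only a hydrogen is close; its heavy atom is far away
            (2, "GLY", [("HA", "H", (1.0, 0.0, 0.0)), ("CA", "C", (50.0, 0, 0))]),
        ],
        het_atoms=[("O1", "O", (0.0, 0.0, 0.0))],
    )
    assert cs.select_shell_residues(structure, ligand, radius=6.0) == []


def test_shell_requires_binding_atoms():
    structure, _ = build_structure([(1, "ALA", [("CA", "C", (0, 0, 0))])])
    with pytest.raises(ValueError, match="no binding sites"):
        cs.select_shell_residues(structure, [], radius=6.0)


def test_shell_matches_brute_force_on_random_structure():
    """Shell membership agrees with an all-pairs distance scan (25 residues)."""
    rng = np.random.default_rng(0)
    aas = ["ALA", "GLY", "SER", "LEU", "VAL"]
    residues = []
    coords_by_res = {}
    for i in range(1, 26):
        atoms = []
        xyz = rng.uniform(-10, 10, size=(rng.integers(1, 4), 3))
        for k, c in enumerate(xyz):
            atoms.append((f"C{k}", "C", tuple(c)))
        residues.append((i, aas[i % 5], atoms))
        coords_by_res[i] = xyz
    binding_xyz = rng.uniform(-10, 10, size=(2, 3))
    structure, ligand = build_structure(
        residues, het_atoms=[(f"O{k}", "O", tuple(c)) for k, c in enumerate(binding_xyz)]
    )

    hits = cs.select_shell_residues(structure, ligand, radius=6.0, gene_id="g")
    got = {h.residue_index for h in hits}

    expected = set()
    for i, xyz in coords_by_res.items():  # independent all-pairs scan
        for a in xyz:
            for b in binding_xyz:
                if np.sqrt(((a - b) ** 2).sum()) <= 6.0:
                    expected.add(i)
    assert got == expected
    assert [h.residue_index for h in hits] == sorted(got)


# ----------------------------------------------------------- saturation


def test_saturate_site_yields_20_designs_one_synonymous():
    site = site_from_cds("g", "GCT" * 25, 3)  # Ala site, native codon GCT
    designs = cs.saturate_site(site)
    assert len(designs) == 20
    assert sorted(d.target_aa for d in designs) == sorted(DEFAULT_CODON_TABLE)
    syn = [d for d in designs if d.is_synonymous]
    assert len(syn) == 1
    assert syn[0].target_aa == "A" and syn[0].target_codon == "GCG"
    assert all("*" != d.target_aa for d in designs)  # no stop designs


def test_saturate_preferred_codon_collision_falls_back():
    """A Leu site already using CTG gets the next-ranked codon CTT."""
    site = site_from_cds("g", "CTG" * 25, 1)
    designs = cs.saturate_site(site)
    syn = next(d for d in designs if d.is_synonymous)
    assert syn.target_codon == "CTT"
    # a bare one-codon-per-aa table has nowhere to fall back to
    with pytest.raises(ValueError, match="synonymous design impossible"):
        cs.saturate_site(site, codon_table=dict(DEFAULT_CODON_TABLE))


def test_saturating_815_sites_gives_16300_designs():
    cds = "GCT" * 900
    designs = []
    for i in range(1, 816):
        designs.append(cs.saturate_site(site_from_cds("g", cds, i)))
    assert sum(len(d) for d in designs) == 16300
    assert all(sum(d.is_synonymous for d in ds) == 1 for ds in designs)
    assert len({d.design_id for ds in designs for d in ds}) == 16300


def test_met_site_has_no_synonymous_design():
    site = site_from_cds("g", "ATG" * 25, 2)
    with pytest.raises(ValueError, match="synonymous design impossible"):
        cs.saturate_site(site)


# ----------------------------------------------------------- spacer/PAM


def _at_backbone(n):
    return ("AT" * n)[:n]


def test_pick_spacer_unique_candidate():
    """A single NGG 3 nt downstream of the edit is chosen, + strand."""
    g = list(_at_backbone(200))
    e = 100  # edit codon at [100, 103)
    p = e + 3 + 3  # PAM 3 nt past the edit's end
    g[p : p + 3] = "AGG"
    g = "".join(g)
    hit = cs.pick_spacer(g, e)
    assert hit.strand == "+" and hit.pam_start == p and hit.distance == 3
    assert hit.spacer == g[p - 20 : p]


def test_pick_spacer_nearest_pam_wins():
    """NGG at gap 4 (+) beats NGG at gap 9 (-)."""
    g = list(_at_backbone(200))
    e = 100
    p_plus = e + 3 + 4
    g[p_plus + 1 : p_plus + 3] = "GG"
    q_minus = e - 9 - 3  # CCN whose PAM ends 9 nt before the edit
    g[q_minus : q_minus + 2] = "CC"
    g = "".join(g)
    hit = cs.pick_spacer(g, e)
    assert hit.strand == "+" and hit.pam_start == p_plus and hit.distance == 4


def test_pick_spacer_beats_exhaustive_scan_on_random_windows():
    """The chosen PAM's distance never exceeds any candidate's distance."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        g = "".join(rng.choice(list("ACGT"), size=260))
        e = 130
        lo, hi = e - ARM_LEFT, e - ARM_LEFT + ARM_LEN
        # independent exhaustive PAM enumeration over the arm window
        dists = []
        for p in range(lo, hi - 2):
            has_plus = g[p + 1 : p + 3] == "GG" and p >= 20
            has_minus = g[p : p + 2] == "CC" and p + 23 <= len(g)
            if has_plus or has_minus:
                if p + 3 <= e:
                    dists.append(e - (p + 3))
                elif p >= e + 3:
                    dists.append(p - (e + 3))
                else:
                    dists.append(0)
        try:
            hit = cs.pick_spacer(g, e)
        except ValueError:
            assert not dists
            continue
        assert dists and hit.distance == min(dists)


def test_pick_spacer_no_pam_errors():
    with pytest.raises(ValueError, match="no targetable PAM"):
        cs.pick_spacer(_at_backbone(240), 120)


def test_pam_kill_prefers_synonymous_third_position():
    """A PAM overlapping a 4-fold Gly codon dies by a third-position change."""
    cds = "GCT" * 10 + "GGG" + "GCT" * 10
    flank = _at_backbone(60)
    genome = flank + cds + flank
    cds_start = len(flank)
    p = cds_start + 30  # PAM = the GGG codon; its GG sits at codon pos 2+3
    assert genome[p + 1 : p + 3] == "GG"
    hit = SpacerHit(spacer=genome[p - 20 : p], pam_start=p, strand="+", distance=0)
    sub = cs.design_pam_kill(genome, hit, cds_start, cds_start + len(cds))
    assert (sub.pos - cds_start) % 3 == 2  # codon third position
    edited = sub.apply(genome)
    assert edited[p + 1 : p + 3] != "GG"  # PAM destroyed
    assert translate(edited[cds_start : cds_start + len(cds)]) == translate(cds)


def test_pam_kill_falls_back_to_seed_when_pam_is_locked():
    """Trp/Ala-locked PAM G's force a synonymous seed-region substitution."""
    k = 10
    cds = "GCT" * k + "TGG" + "GCT" * 10  # Trp codon then Ala codon
    flank = _at_backbone(60)
    genome = flank + cds + flank
    cds_start = len(flank)
    p = cds_start + 3 * k + 1  # PAM G's: TGG third base + next GCT first base
    assert genome[p + 1 : p + 3] == "GG"
    hit = SpacerHit(spacer=genome[p - 20 : p], pam_start=p, strand="+", distance=0)
    sub = cs.design_pam_kill(genome, hit, cds_start, cds_start + len(cds))
    assert p - 10 <= sub.pos < p  # inside the seed
    edited = sub.apply(genome)
    assert translate(edited[cds_start : cds_start + len(cds)]) == translate(cds)


def test_pam_kill_in_noncoding_context_errors():
    g = _at_backbone(100) + "AGG" + _at_backbone(100)
    hit = SpacerHit(spacer=g[80:100], pam_start=100, strand="+", distance=0)
    with pytest.raises(ValueError, match="cannot silently disrupt PAM"):
        cs.design_pam_kill(g, hit, 150, 180)  # CDS nowhere near the PAM


# ------------------------------------------------------------- cassette


def test_cassette_anatomy(tiny_library):
    """230 nt, exact concatenation of the seven parts with printed lengths."""
    for cas in tiny_library.cassettes:
        assert len(cas.full_seq) == CASSETTE_LEN
        assert (len(cas.subpool_primer), len(cas.variant_primer),
                len(cas.homology_arm), len(cas.promoter), len(cas.linker),
                len(cas.spacer), len(cas.scaffold5)) == (18, 12, 118, 35, 3, 20, 24)
        assert cas.full_seq == (
            cas.subpool_primer + cas.variant_primer + cas.homology_arm
            + cas.promoter + cas.linker + cas.spacer + cas.scaffold5
        )


def test_cassette_arm_round_trip(tiny_library):
    """Reverting codon edit + PAM kill reproduces the reference window."""
    for cas in tiny_library.cassettes:
        gene = tiny_library.genes[cas.design.site.gene_id]
        ref = gene.genome[cas.arm_start : cas.arm_start + ARM_LEN]
        assert revert_arm(cas) == ref
        # 58 / 3 / 57 split around the codon
        assert cas.homology_arm[ARM_LEFT : ARM_LEFT + 3] == cas.design.target_codon


def test_cassette_spacer_targets_unedited_genome(tiny_library):
    """Each spacer matches a genomic protospacer adjacent to an NGG PAM."""
    from createscan.codons import revcomp

    for cas in tiny_library.cassettes[::7]:
        gene = tiny_library.genes[cas.design.site.gene_id]
        g = gene.genome
        hit = cas.spacer_hit
        p = hit.pam_start
        if hit.strand == "+":
            assert g[p + 1 : p + 3] == "GG"
            assert g[p - 20 : p] == cas.spacer
        else:
            assert g[p : p + 2] == "CC"
            assert revcomp(g[p + 3 : p + 23]) == cas.spacer


def test_edited_cds_translation_differs_at_exactly_target(tiny_library):
    for cas in tiny_library.cassettes[::5]:
        design = cas.design
        gene = tiny_library.genes[design.site.gene_id]
        g = gene.genome
        codon_pos = gene.cds_start + design.site.cds_offset
        edited = (
            g[:codon_pos] + design.target_codon + g[codon_pos + 3 :]
        )
        edited = cas.pam_kill.apply(edited)
        wt_prot = translate(g[gene.cds_start : gene.cds_end])
        ed_prot = translate(edited[gene.cds_start : gene.cds_end])
        diffs = [i for i, (a, b) in enumerate(zip(wt_prot, ed_prot), 1) if a != b]
        if design.is_synonymous:
            assert diffs == []
        else:
            assert diffs == [design.site.residue_index]
            assert ed_prot[design.site.residue_index - 1] == design.target_aa


def test_pam_kill_outside_arm_rejected(tiny_library):
    cas = tiny_library.cassettes[0]
    gene = tiny_library.genes[cas.design.site.gene_id]
    bad_kill = Substitution(pos=0, ref=gene.genome[0], alt="A" if gene.genome[0] != "A" else "C")
    with pytest.raises(ValueError, match="edit outside homology arm"):
        cs.assemble_cassette(
            cas.design, cas.spacer_hit, bad_kill, gene.genome, gene.cds_start,
            cas.subpool_primer, cas.variant_primer,
        )
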