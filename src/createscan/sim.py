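"""Synthetic selection experiments with known ground truth.

The generator emulates the structure of a pathway-scale CREATE screen:

* a saturation library over several synthetic genes (categories:
  biosynthesis, degradation, regulation, transport), each site carrying
  19 missense designs and 1 synonymous design;
* transformation with low genome-editing efficiency ``epsilon`` — each
  design's cell pool splits into an edited fraction (epsilon) and
  wild-type "escaper" cells (1 - epsilon) that carry the barcode plasmid
  but not the genomic edit;
* deterministic exponential growth of expected abundances over ``g``
  generations, multiplying each subpopulation by (1 + s)^g where s is the
  design's selection coefficient (synonymous designs are wild type at the
  protein level and grow like escapers unless explicitly overridden);
* multinomial read sampling at configured depths, for both cassette
  (barcode) amplicons and pre-selection genomic-window amplicons, with
  optional independent per-base substitution errors.

All randomness flows from ``SimConfig.seed``; two runs with the same
config are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from .quant import CountMatrix, Sample, SampleSheet
from .structures import site_from_cds
from .codons import PREFERRED_CODONS, STOP_CODONS, translate_codon
from .validation import GenomicWindow, enumerate_expected

FLANK = 150  # non-coding genomic flank on each side of a synthetic CDS
EDGE_CODONS = 20  # keep sites this many codons away from CDS ends

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GeneSpec:
    gene_id: str
    category: str
    n_sites: int
    n_codons: int = 120


@dataclass
class SimConfig:
    """Generative parameters for one synthetic selection experiment."""

    genes: list[GeneSpec]
    epsilon: float = 0.03  # genome-editing probability per transformed cell
    gene_fitness: dict[str, float] = field(default_factory=dict)  # missense s by gene
    category_fitness: dict[str, float] = field(default_factory=dict)
    design_fitness: dict[str, float] = field(default_factory=dict)  # overrides
    escaper_fitness: float = 0.0
    generations: float = 10.0
    depth_pre: int = 200_000
    depth_post: int = 200_000
    depth_window: int = 100_000
    error_rate: float = 0.0
    n_replicates: int = 2
    condition: str = "AEC"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must be in [0, 1]")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        for d in (self.depth_pre, self.depth_post, self.depth_window):
            if d < 0:
                raise ValueError("depths must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["genes"] = [GeneSpec(**g) for g in raw["genes"]]
        return cls(**raw)


@dataclass
class SimGene:
    spec: GeneSpec
    genome: str
    cds_start: int
    cds_end: int
    site_indices: list[int]  # 1-based residue indices


@dataclass
class SimLibrary:
    config: SimConfig
    genes: dict[str, SimGene]
    designs: list[dz.MutationDesign]
    cassettes: list[dz.Cassette]
    manifest: pd.DataFrame

    @property
    def n_designs(self) -> int:
        return len(self.designs)


@dataclass
class TrueState:
    """Ground-truth abundances before sequencing."""

    table: pd.DataFrame  # per design: s, pre_freq, post_freq, edited growth parts
    config: SimConfig

    @property
    def pre_freq(self) -> np.ndarray:
        return self.table["pre_freq"].to_numpy()

    @property
    def post_freq(self) -> np.ndarray:
        return self.table["post_freq"].to_numpy()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random open reading frame: ATG + sense codons + stop."""
    sense = sorted(
        c
        for aa, codons in PREFERRED_CODONS.items()
        for c in codons
        if aa not in ("M",)
    )
    body = rng.choice(sense, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _random_flank(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)].astype("U1"))


def simulate_library(config: SimConfig) -> SimLibrary:
    """Generate synthetic genes and the full saturation library over them.

    Sites are drawn from interior codons (at least 20 codons from either
    CDS end, never Met/Trp, so every site admits a distinguishable
    synonymous design) for which a spacer with a feasible synonymous
    PAM-kill exists.
    """
    rng = _rng(config, 1)
    subpool = dz.random_primer(dz.SUBPOOL_PRIMER_LEN, _PyRandom(rng))
    genes: dict[str, SimGene] = {}
    designs: list[dz.MutationDesign] = []
    cassettes: list[dz.Cassette] = []
    rows = []

    for spec in config.genes:
        if spec.n_codons < 2 * EDGE_CODONS + spec.n_sites:
            raise ValueError(f"gene {spec.gene_id} too short for {spec.n_sites} sites")
        cds = _random_cds(spec.n_codons, rng)
        genome = _random_flank(FLANK, rng) + cds + _random_flank(FLANK, rng)
        cds_start, cds_end = FLANK, FLANK + len(cds)

        candidates = [
            i
            for i in range(EDGE_CODONS + 1, spec.n_codons - EDGE_CODONS + 1)
            if translate_codon(cds[3 * (i - 1) : 3 * i]) not in ("M", "W", "*")
        ]
        rng.shuffle(candidates)
        chosen: list[int] = []
        site_hits = {}
        for i in candidates:
            if len(chosen) == spec.n_sites:
                break
            edit_start = cds_start + 3 * (i - 1)
            window = (edit_start - dz.ARM_LEFT, edit_start - dz.ARM_LEFT + dz.ARM_LEN)
            try:
                hit = dz.pick_spacer(
                    genome, edit_start, window=window, cds_span=(cds_start, cds_end)
                )
                kill = dz.design_pam_kill(
                    genome, hit, cds_start, cds_end,
                    exclude=(edit_start, edit_start + 3), within=window,
                )
            except ValueError:
                continue
            chosen.append(i)
            site_hits[i] = (hit, kill)
        if len(chosen) < spec.n_sites:
            raise ValueError(
                f"gene {spec.gene_id}: only {len(chosen)} designable sites found"
            )
        chosen.sort()
        genes[spec.gene_id] = SimGene(
            spec=spec, genome=genome, cds_start=cds_start, cds_end=cds_end,
            site_indices=chosen,
        )

        for i in chosen:
            site = site_from_cds(spec.gene_id, cds, i)
            hit, kill = site_hits[i]
            for d in dz.saturate_site(site):
                variant = dz.random_primer(dz.VARIANT_PRIMER_LEN, _PyRandom(rng))
                cas = dz.assemble_cassette(
                    d, hit, kill, genome, cds_start, subpool, variant
                )
                designs.append(d)
                cassettes.append(cas)
                rows.append(
                    {
                        "design_id": d.design_id,
                        "gene": spec.gene_id,
                        "category": spec.category,
                        "residue": i,
                        "wt_aa": site.wt_aa,
                        "target_aa": d.target_aa,
                        "wt_codon": site.wt_codon,
                        "target_codon": d.target_codon,
                        "is_synonymous": d.is_synonymous,
                        "spacer": cas.spacer,
                        "pam_kill": f"{kill.pos}:{kill.ref}>{kill.alt}",
                    }
                )

    manifest = pd.DataFrame(rows)
    return SimLibrary(
        config=config, genes=genes, designs=designs, cassettes=cassettes,
        manifest=manifest,
    )


class _PyRandom:
    """Adapter giving ``random.Random``-style choice over a numpy Generator."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def choice(self, seq):
        return seq[int(self._rng.integers(0, len(seq)))]


def fitness_of(config: SimConfig, library: SimLibrary) -> np.ndarray:
    """Resolve the selection coefficient of every design, in library order.

    Priority: explicit design override, else 0 for synonymous designs
    (they encode the wild-type protein), else the gene rule, else the
    category rule, else 0.
    """
    s = np.zeros(library.n_designs)
    cat = dict(zip(library.manifest["design_id"], library.manifest["category"]))
    for k, d in enumerate(library.designs):
        if d.design_id in config.design_fitness:
            s[k] = config.design_fitness[d.design_id]
        elif d.is_synonymous:
            s[k] = 0.0
        elif d.site.gene_id in config.gene_fitness:
            s[k] = config.gene_fitness[d.site.gene_id]
        else:
            s[k] = config.category_fitness.get(cat[d.design_id], 0.0)
    return s


def simulate_selection(config: SimConfig, library: SimLibrary) -> TrueState:
    """Expected pre/post abundances under the split-pool growth model.

    Each design starts at equal abundance.  Its pool splits into an edited
    fraction epsilon growing as (1+s_design)^g and an escaper fraction
    (1-epsilon) growing as (1+s_escaper)^g; post frequencies are the
    normalized sums.  Growth is deterministic: stochasticity enters only
    at sequencing.
    """
    s = fitness_of(config, library)
    if np.any(1.0 + s <= 0) or 1.0 + config.escaper_fitness <= 0:
        raise ValueError("lethal coefficient out of range")
    g = config.generations
    x_edit = (1.0 + s) ** g
    x_esc = (1.0 + config.escaper_fitness) ** g
    eps = config.epsilon

    n = library.n_designs
    pre = np.full(n, 1.0 / n)
    growth = eps * x_edit + (1.0 - eps) * x_esc
    post_unnorm = pre * growth
    post = post_unnorm / post_unnorm.sum()
    edited_final = np.divide(
        eps * x_edit, growth, out=np.zeros_like(growth), where=growth > 0
    )

    table = pd.DataFrame(
        {
            "design_id": [d.design_id for d in library.designs],
            "s": s,
            "pre_freq": pre,
            "post_freq": post,
            "edited_fraction_initial": eps,
            "edited_fraction_final": edited_final,
            "edited_growth": x_edit,
        }
    ).set_index("design_id")
    return TrueState(table=table, config=config)


def _mutate_reads(
    seqs: list[str], counts: np.ndarray, error_rate: float, rng: np.random.Generator
) -> list[str]:
    """Emit ``counts[k]`` copies of each source with per-base substitutions."""
    reads: list[str] = []
    for seq, n in zip(seqs, counts):
        n = int(n)
        if n == 0:
            continue
        if error_rate == 0.0:
            reads.extend([seq] * n)
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")
        mat = np.tile(arr, (n, 1))
        hits = rng.random(mat.shape) < error_rate
        n_hits = int(hits.sum())
        if n_hits:
            # substitute with a uniformly random *different* base
            shift = rng.integers(1, 4, size=n_hits)
            idx = np.searchsorted(
                _BASES, mat[hits]
            )  # current base index in ACGT
            mat[hits] = _BASES[(idx + shift) % 4]
        reads.extend(b"".join(row).decode() for row in mat)
    return reads


@dataclass
class SimReads:
    """Sequencing output of one simulated experiment."""

    sheet: SampleSheet
    true_counts: CountMatrix  # true read allocation per sample (oracle)
    reads: Optional[dict[str, list[str]]]  # sample_id -> cassette reads
    window_reads: Optional[dict[tuple[str, int], list[str]]]  # (gene, rep) -> reads
    windows: Optional[dict[str, GenomicWindow]]


def simulate_reads(
    state: TrueState,
    library: SimLibrary,
    emit_sequences: bool = False,
    emit_windows: bool = False,
) -> SimReads:
    """Draw sequencing reads for every sample of the experiment.

    Cassette-amplicon counts are multinomial draws from the true pre/post
    frequencies at the configured depths, per replicate.  Genomic-window
    amplicons are drawn from the *pre-selection* population, where a read
    shows design d's edited window with probability epsilon/n_designs and
    the wild-type window otherwise.  With ``emit_sequences`` the actual
    read strings (with sequencing errors) are produced; the true
    CountMatrix is always returned as the oracle.
    """
    config = state.config
    rng = _rng(config, 2)
    n = library.n_designs
    design_ids = list(state.table.index)

    samples = []
    counts = {}
    for rep in range(1, config.n_replicates + 1):
        for phase, freq, depth in (
            ("pre", state.pre_freq, config.depth_pre),
            ("post", state.post_freq, config.depth_post),
        ):
            sid = f"{config.condition}_{phase}_r{rep}"
            samples.append(
                Sample(sample_id=sid, condition=config.condition,
                       replicate=rep, phase=phase)
            )
            counts[sid] = rng.multinomial(depth, freq)
    sheet = SampleSheet(samples)
    count_df = pd.DataFrame(counts, index=design_ids)
    totals = count_df.sum(axis=0)
    true_counts = CountMatrix(
        counts=count_df, total_reads=totals.copy(), matched_reads=totals.copy()
    )

    reads = None
    if emit_sequences:
        cas_seqs = [c.full_seq for c in library.cassettes]
        reads = {
            sid: _mutate_reads(cas_seqs, count_df[sid].to_numpy(),
                               config.error_rate, rng)
            for sid in count_df.columns
        }

    window_reads = None
    windows = None
    if emit_windows:
        windows = {}
        window_reads = {}
        eps = config.epsilon
        for gene_id, gene in library.genes.items():
            cas = [c for c in library.cassettes if c.design.site.gene_id == gene_id]
            lo = min(c.arm_start for c in cas)
            hi = max(c.arm_start + dz.ARM_LEN for c in cas)
            win = enumerate_expected(gene_id, gene.genome, lo + 1, hi, cas)
            windows[gene_id] = win
            w = win.w
            probs = np.full(w + 1, eps / n)
            probs[-1] = 1.0 - w * eps / n  # wild type
            variant_seqs = [win.expected_variants[c.design.design_id] for c in sorted(
                cas, key=lambda c: c.design.design_id)] + [win.wt_seq]
            for rep in range(1, config.n_replicates + 1):
                draw = rng.multinomial(config.depth_window, probs)
                window_reads[(gene_id, rep)] = _mutate_reads(
                    variant_seqs, draw, config.error_rate, rng
                )

    return SimReads(
        sheet=sheet, true_counts=true_counts, reads=reads,
        window_reads=window_reads, windows=windows,
    )


def required_growth(
    target_log2: float, n_designs: int, epsilon: float, escaper_growth: float = 1.0
) -> float:
    """Edited-pool growth factor x = (1+s)^g giving a design a true
    post/pre log2 enrichment of ``target_log2`` against an otherwise
    neutral, equally abundant background.

    Solves log2( R_d / mean(R) ) = target with R_d = eps*x + (1-eps)*e
    and R = e for the n-1 neutral designs (e = escaper/neutral growth).
    """
    ratio = 2.0 ** target_log2
    n = n_designs
    e = escaper_growth
    # R_d / ((R_d + (n-1) e)/n) = ratio  =>  R_d = ratio*(n-1)*e / (n - ratio)
    if ratio >= n:
        raise ValueError("target enrichment unattainable at this library size")
    r_d = ratio * (n - 1) * e / (n - ratio)
    x = (r_d - (1.0 - epsilon) * e) / epsilon
    if x <= 0:
        raise ValueError("target below the escaper floor at this epsilon")
    return x


def study_config(seed: int = 0, winner_growth: float = 1024.0) -> SimConfig:
    """Desk-scale preset mirroring the study regime: editing efficiency
    ~3%, two biological replicates, depth 2e5, and one transporter gene
    whose loss-of-function missense designs are the dominant selection
    winners (>95% of the edited population after selection)."""
    g = 10.0
    s_win = winner_growth ** (1.0 / g) - 1.0
    return SimConfig(
        genes=[
            GeneSpec("synbioA", "biosynthesis", n_sites=12),
            GeneSpec("synbioB", "biosynthesis", n_sites=10),
            GeneSpec("syndegA", "degradation", n_sites=8),
            GeneSpec("synregA", "regulation", n_sites=10),
            GeneSpec("syntraA", "transport", n_sites=10),
        ],
        epsilon=0.03,
        gene_fitness={"syntraA": s_win},
        escaper_fitness=0.0,
        generations=g,
        depth_pre=200_000,
        depth_post=200_000,
        n_replicates=2,
        seed=seed,
    )


def neutral_config(seed: int = 0, depth: int = 100_000) -> SimConfig:
    """All-neutral preset (every s = 0) for null calibration."""
    cfg = study_config(seed=seed)
    cfg.gene_fitness = {}
    cfg.category_fitness = {}
    cfg.design_fitness = {}
    cfg.depth_pre = depth
    cfg.depth_post = depth
    return cfg
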