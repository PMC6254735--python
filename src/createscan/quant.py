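"""Barcode quantification: match merged amplicon reads to designed cassettes.

Matching is two-tiered, mirroring the usearch-style protocol: a read is a
*reported hit* if it aligns to a cassette at >= 95% identity over >= 150
aligned bases (at most 40 candidates, sorted by identity); it is *counted*
only if its best hit covers the full cassette and exceeds 99% identity.
Identity is defined as matching columns / alignment columns on the
minimal-edit-distance alignment, so gaps count against identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pandas as pd
from Bio import SeqIO

IDENTITY_MIN = 0.95
LENGTH_MIN = 150
COUNT_IDENTITY_MIN = 0.99  # strict: identity must exceed this to be counted
MAX_HITS = 40

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class MatchHit:
    design_id: str
    identity: float
    alignment_length: int
    full_alignment: bool  # alignment spans the entire cassette


@dataclass
class CountMatrix:
    """Integer read counts per design per sample.

    ``counts`` is a DataFrame indexed by design_id with one column per
    sample; ``total_reads`` counts every read entering matching and
    ``matched_reads`` those that passed the counting tier, so per-sample
    column sums equal ``matched_reads``.
    """

    counts: pd.DataFrame
    total_reads: pd.Series
    matched_reads: pd.Series

    def validate(self) -> None:
        sums = self.counts.sum(axis=0)
        for s in self.counts.columns:
            if sums[s] != self.matched_reads[s]:
                raise ValueError(f"column {s} does not sum to matched_reads")
            if self.matched_reads[s] > self.total_reads[s]:
                raise ValueError(f"matched exceeds total for {s}")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    replicate: int
    phase: str  # 'pre' or 'post'
    reads_path: Optional[str] = None


class SampleSheet:
    """Sample metadata mapping samples to condition/replicate/phase."""

    def __init__(self, samples: Sequence[Sample]):
        self.samples = list(samples)
        keys = [(s.condition, s.replicate, s.phase) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (condition, replicate, phase)")
        for s in self.samples:
            if s.phase not in ("pre", "post"):
                raise ValueError(f"phase must be pre/post, got {s.phase}")
        for s in self.samples:
            if s.phase == "post" and self.find(s.condition, s.replicate, "pre") is None:
                raise ValueError("unpaired sample")

    def find(self, condition: str, replicate: int, phase: str) -> Optional[Sample]:
        for s in self.samples:
            if (s.condition, s.replicate, s.phase) == (condition, replicate, phase):
                return s
        return None

    def pairs(self) -> list[tuple[Sample, Sample]]:
        """(pre, post) sample pairs per condition x replicate."""
        out = []
        for s in self.samples:
            if s.phase == "post":
                pre = self.find(s.condition, s.replicate, "pre")
                out.append((pre, s))
        return out

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path)
        samples = [
            Sample(
                sample_id=str(r.sample_id),
                condition=str(r.condition),
                replicate=int(r.replicate),
                phase=str(r.phase),
                reads_path=str(r.reads_path) if "reads_path" in df.columns else None,
            )
            for r in df.itertuples()
        ]
        return cls(samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.samples])


def read_sequences(path) -> list[str]:
    """Read merged reads from FASTA or FASTQ (quality ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


class CassetteDB:
    """Cassette sequences keyed by design_id, in stable sorted order."""

    def __init__(self, seqs: Mapping[str, str]):
        if not seqs:
            raise ValueError("empty cassette database")
        self.ids = sorted(seqs)
        self.seqs = {d: seqs[d].upper() for d in self.ids}
        self._exact = {}
        for d in self.ids:
            self._exact.setdefault(self.seqs[d], d)  # first id wins ties

    @classmethod
    def from_cassettes(cls, cassettes) -> "CassetteDB":
        return cls({c.design.design_id: c.full_seq for c in cassettes})

    @classmethod
    def from_fasta(cls, path) -> "CassetteDB":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def _align(read: str, cassette: str) -> Optional[tuple[float, int, bool]]:
    """(identity, alignment columns, spans full cassette) or None."""
    res = edlib.align(read, cassette, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    identity = matches / columns if columns else 0.0
    full = start == 0 and end == len(cassette) - 1
    return identity, columns, full


def match_read(read: str, db: CassetteDB) -> Optional[MatchHit]:
    """Best cassette hit for one read, or None.

    Candidates must reach >= 95% identity over >= 150 aligned columns; at
    most 40 are retained, sorted by identity (ties: lexicographically
    smallest design_id).  The returned hit records whether the alignment
    covered the full cassette, which the counting tier requires.
    """
    read = read.upper()
    exact = db._exact.get(read)
    if exact is not None:
        return MatchHit(exact, 1.0, len(read), True)

    hits: list[MatchHit] = []
    for design_id in db.ids:
        aln = _align(read, db.seqs[design_id])
        if aln is None:
            continue
        identity, columns, full = aln
        if identity >= IDENTITY_MIN and columns >= LENGTH_MIN:
            hits.append(MatchHit(design_id, identity, columns, full))
    if not hits:
        return None
    hits.sort(key=lambda h: (-h.identity, h.design_id))
    del hits[MAX_HITS:]
    return hits[0]


def count_matches(reads: Iterable[str], db: CassetteDB) -> tuple[dict[str, int], int, int]:
    """Count reads per design under the strict tier.

    A read increments its best hit only when the alignment spans the full
    cassette and identity is strictly above 99%.  Returns (counts by
    design_id, total reads, matched reads).
    """
    counts = {d: 0 for d in db.ids}
    total = 0
    matched = 0
    for read in reads:
        total += 1
        hit = match_read(read, db)
        if hit is None:
            continue
        if hit.full_alignment and hit.identity > COUNT_IDENTITY_MIN:
            counts[hit.design_id] += 1
            matched += 1
    return counts, total, matched


def quantify(
    reads_by_sample: Mapping[str, Iterable[str]], db: CassetteDB
) -> CountMatrix:
    """Build a CountMatrix by matching each sample's reads to the database."""
    data = {}
    totals = {}
    matched = {}
    for sample_id, reads in reads_by_sample.items():
        counts, total, m = count_matches(reads, db)
        data[sample_id] = pd.Series(counts, dtype=int)
        totals[sample_id] = total
        matched[sample_id] = m
    cm = CountMatrix(
        counts=pd.DataFrame(data).reindex(db.ids).fillna(0).astype(int),
        total_reads=pd.Series(totals, dtype=int),
        matched_reads=pd.Series(matched, dtype=int),
    )
    cm.validate()
    return cm
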