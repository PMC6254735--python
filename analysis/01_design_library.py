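#!/usr/bin/env python
"""Design the synthetic saturation library.

Builds the study-scale preset library — five synthetic genes across the four
pathway categories, full codon saturation at every designable binding-shell
site — and writes the cassette FASTA and the design manifest.  Prints the
library bookkeeping: designs per gene, cassette length, synonymous designs
per site.
"""

import argparse
from pathlib import Path

import createscan as cs
from createscan.io import write_cassette_fasta

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = cs.study_config(seed=args.seed)
    lib = cs.simulate_library(cfg)

    RESULTS.mkdir(exist_ok=True)
    write_cassette_fasta(lib.cassettes, RESULTS / "cassettes.fasta")
    lib.manifest.to_csv(RESULTS / "design_manifest.csv", index=False)

    per_gene = lib.manifest.groupby("gene").size()
    print(f"library: {lib.n_designs} designs over {len(lib.genes)} genes")
    print(per_gene.to_string())
    lengths = {len(c.full_seq) for c in lib.cassettes}
    print(f"cassette lengths: {sorted(lengths)} nt")
    syn_per_site = lib.manifest.groupby(["gene", "residue"])["is_synonymous"].sum()
    print(f"synonymous designs per site: {sorted(syn_per_site.unique())}")
    print(f"wrote {RESULTS/'cassettes.fasta'} and {RESULTS/'design_manifest.csv'}")


if __name__ == "__main__":
    main()
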