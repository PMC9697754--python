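#!/usr/bin/env python
"""Sequence phylogeny: progressive MSA, p-distance NJ, bootstrap supports.

Aligns the family's sequences, builds the NJ tree from p-distances with
column-bootstrap supports (100 replicates here; 1000 is the production
default), and reports the RF distance to the generating topology and to
the structure tree from stage 02.
"""

import argparse
from pathlib import Path

from capsidphylo.phylo import (
    bootstrap_support,
    progressive_msa,
    read_newick,
    rf_distance,
    write_newick,
)
from capsidphylo.structio import read_fasta, write_fasta

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--family", type=Path, default=ROOT / "results" / "family")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--bootstrap", type=int, default=100)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    records = read_fasta(args.family / "sequences.fasta")
    msa = progressive_msa(records)
    write_fasta(msa.records, args.out / "alignment.fasta")
    tree = bootstrap_support(msa, n_reps=args.bootstrap, seed=args.seed)
    (args.out / "sequence_tree.nwk").write_text(write_newick(tree))

    sup = sorted(tree.supports().values())
    print(f"{len(records)} sequences, alignment of {msa.n_columns} columns")
    print(f"bootstrap supports ({args.bootstrap} reps): "
          f"min {sup[0]:.0f}, median {sup[len(sup)//2]:.0f}, max {sup[-1]:.0f}")
    true = read_newick((args.family / "true_tree.nwk").read_text())
    print(f"RF(sequence tree, true tree) = {rf_distance(tree, true)}")
    st_path = args.out / "structure_tree.nwk"
    if st_path.exists():
        st = read_newick(st_path.read_text())
        print(f"RF(sequence tree, structure tree) = {rf_distance(tree, st)}")


if __name__ == "__main__":
    main()
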