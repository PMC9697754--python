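#!/usr/bin/env python
"""Per-residue divergence profiles of the family against one reference.

Aligns every other structure to the reference, computes per-residue
C-alpha deviations under the global superposition, averages them into a
divergence map, and summarizes the designated loop regions — the
synthetic analogue of an averaged RMSD-per-residue map over capsid VP1
homologs, where the hypervariable surface loops should stand out.
"""

import argparse
from pathlib import Path

from capsidphylo.profile import (
    RegionSpec,
    average_profiles,
    per_residue_deviation,
    profiles_table,
    region_summary,
    write_attribute_file,
)
from capsidphylo.simdata import default_loop_segments
from capsidphylo.structio import read_ca_structure, subtract_segments, parse_segment_spec
from capsidphylo.superpose import pair_align

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--family", type=Path, default=ROOT / "results" / "family")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--reference", default="T01")
    args = ap.parse_args()

    structs = {p.stem: read_ca_structure(p) for p in sorted(args.family.glob("*.pdb"))}
    ref = structs.pop(args.reference)
    profiles = {}
    for lab, s in structs.items():
        corr, sup = pair_align(ref, s)
        profiles[lab] = per_residue_deviation(ref, s, corr, sup)
    mean_prof = average_profiles(list(profiles.values()))
    profiles_table(profiles, mean_prof).to_csv(
        args.out / "profile.tsv", sep="\t", index=False, float_format="%.4f"
    )
    write_attribute_file(mean_prof, args.out / "mean_profile.attr")

    loops = default_loop_segments(len(ref))
    chain = parse_segment_spec(f"{ref.residues[0].seq_id}-{ref.residues[-1].seq_id}")
    regions = [
        RegionSpec("loops", loops),
        RegionSpec("non-loops", subtract_segments(chain, loops)),
    ]
    table = region_summary(mean_prof, regions)
    table.to_csv(args.out / "region_summary.tsv", sep="\t", index=False)
    print(f"averaged divergence profile vs {args.reference} "
          f"({len(profiles)} structures):")
    print(table.to_string(index=False))
    lo = table.set_index("region")
    ratio = lo.loc["loops", "mean"] / lo.loc["non-loops", "mean"]
    print(f"loop/non-loop mean divergence ratio: {ratio:.2f} "
          f"(generator applies 4x noise variance in loops -> ~2x deviation)")


if __name__ == "__main__":
    main()
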