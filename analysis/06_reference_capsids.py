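#!/usr/bin/env python
"""Deposition-based comparison of CsfrRNAV and CtenRNAV II capsid proteins.

Needs the deposited coordinate files under data/reference/ (see the
README there; they are not redistributed and require network access to
obtain).  When present: aligns VP1/VP2/VP3 pairs, reports core RMSDs and
core sizes against the published values (VP1 1.544 A / 164 C-alpha,
VP2 0.900 A / 158, VP3 1.024 A / 174), profiles VP1 per residue, and
summarizes the surface-loop regions, where the E1E2 loop is expected to
peak at 7-8 A.
"""

from pathlib import Path

from capsidphylo.profile import load_regions, per_residue_deviation, region_summary
from capsidphylo.structio import motif_locate, read_ca_structure, read_fasta
from capsidphylo.superpose import core_rmsd, pair_align

ROOT = Path(__file__).resolve().parent.parent
REF = ROOT / "data" / "reference"

PUBLISHED = {"vp1": (1.544, 164), "vp2": (0.900, 158), "vp3": (1.024, 174)}


def main():
    needed = [f"{v}_{p}.pdb" for v in ("csfrrnav", "ctenrnavii")
              for p in ("vp1", "vp2", "vp3")]
    missing = [f for f in needed if not (REF / f).exists()]
    if missing:
        print("reference depositions not found; see data/reference/README.md")
        print("missing:", ", ".join(missing))
        return

    for vp, (pub_rmsd, pub_n) in PUBLISHED.items():
        a = read_ca_structure(REF / f"csfrrnav_{vp}.pdb")
        b = read_ca_structure(REF / f"ctenrnavii_{vp}.pdb")
        corr, _ = pair_align(a, b)
        rmsd, n_core, _ = core_rmsd(a, b, corr)
        print(f"{vp.upper()}: core RMSD {rmsd:.3f} A over {n_core} C-alpha "
              f"(published {pub_rmsd} A over {pub_n})")

    a = read_ca_structure(REF / "csfrrnav_vp1.pdb")
    b = read_ca_structure(REF / "ctenrnavii_vp1.pdb")
    corr, sup = pair_align(a, b)
    prof = per_residue_deviation(a, b, corr, sup)
    print(region_summary(prof, load_regions()).to_string(index=False))

    poly = REF / "csfrrnav_polyprotein.fasta"
    if poly.exists():
        rec = read_fasta(poly)[0]
        for motif in ("GRSRP", "DNV", "PSF", "DDF"):
            hits = motif_locate(rec, motif)
            print(f"motif {motif}: {hits}")


if __name__ == "__main__":
    main()
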