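# Reference depositions (not bundled)

The deposition-based integration tests and `analysis/06_reference_capsids.py`
compare this package's numbers against the published capsid models. The
coordinate files are not redistributed here; to run those checks, download
them and place single-chain PDB-format files in this directory:

- `csfrrnav_vp1.pdb`, `csfrrnav_vp2.pdb`, `csfrrnav_vp3.pdb` — the three
  capsid-protein chains of the full-particle CsfrRNAV model (PDB entry
  8B38; one chain per file).
- `ctenrnavii_vp1.pdb`, `ctenrnavii_vp2.pdb`, `ctenrnavii_vp3.pdb` — the
  corresponding chains of the CtenRNAV II capsid deposition.
- `csfrrnav_polyprotein.fasta` (optional) — the CsfrRNAV capsid
  polyprotein sequence (GenBank), used by the cleavage-motif check.

Chains can be split out with any structure tool, e.g.
`gemmi convert --select=/1/A 8b38.cif csfrrnav_vp2.pdb` (map chains to
VP1/VP2/VP3 according to the entry's annotation). When the files are
absent the corresponding tests skip; everything else in the package is
self-contained.
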