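"""Per-residue structural divergence profiles on a reference chain.

After a pair of traces has been superposed, each matched reference residue
gets the Euclidean C-alpha deviation under the single global fit (no
per-window refitting).  Profiles from several homologs against one
reference can be averaged into a divergence map, smoothed with an RMS
window, and summarized over named surface regions (CD, E1E2, EF loops).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import CaStructure, SegmentSet
from .superpose import Correspondence, Superposition


@dataclass(frozen=True)
class RegionSpec:
    """A named region (e.g. ``E1E2-Loop``) in reference residue numbering."""

    name: str
    segments: SegmentSet

    def __post_init__(self):
        if len(self.segments) == 0:
            raise ValueError(f"region {self.name!r}: empty segment set")


@dataclass
class RmsdProfile:
    """Map reference seq_id -> C-alpha deviation (A); absent = unmatched."""

    reference: str
    values: dict[int, float]
    window: int = 1

    def __post_init__(self):
        if any(v < 0 for v in self.values.values()):
            raise ValueError("profile deviations must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def per_residue_deviation(
    a: CaStructure,
    b: CaStructure,
    corr: Correspondence,
    sup: Superposition,
) -> RmsdProfile:
    """Deviation of each matched pair after applying ``sup`` to B.

    Unmatched reference residues are simply absent from the profile.
    """
    if len(corr) == 0:
        raise ValueError("empty correspondence")
    ca = a.coords[corr.idx_a]
    cb = sup.transform(b.coords[corr.idx_b])
    dev = np.linalg.norm(cb - ca, axis=1)
    seq_ids = a.seq_ids
    values = {seq_ids[i]: float(d) for i, d in zip(corr.idx_a, dev)}
    return RmsdProfile(a.label, values, window=1)


def windowed_profile(p: RmsdProfile, w: int) -> RmsdProfile:
    """RMS-smooth a per-residue profile over a centered window of width ``w``.

    The value at residue i is the root mean square of the per-residue
    deviations at matched residues within +-(w-1)/2 of i; residues whose
    window contains no matched residue stay missing.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("window width must be a positive odd integer")
    if w == 1:
        return RmsdProfile(p.reference, dict(p.values), window=1)
    half = (w - 1) // 2
    out: dict[int, float] = {}
    for sid in p.values:
        vals = [p.values[j] for j in range(sid - half, sid + half + 1) if j in p.values]
        out[sid] = float(np.sqrt(np.mean(np.square(vals))))
    return RmsdProfile(p.reference, out, window=w)


def average_profiles(profiles: list[RmsdProfile]) -> RmsdProfile:
    """Per-residue arithmetic mean over profiles sharing one reference.

    A residue is averaged over the profiles where it is present and is
    missing only if missing everywhere.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    refs = {p.reference for p in profiles}
    if len(refs) != 1:
        raise ValueError(f"profiles mix references: {sorted(refs)}")
    acc: dict[int, list[float]] = {}
    for p in profiles:
        for sid, v in p.values.items():
            acc.setdefault(sid, []).append(v)
    values = {sid: float(np.mean(vs)) for sid, vs in acc.items()}
    return RmsdProfile(profiles[0].reference, values, window=profiles[0].window)


def region_summary(p: RmsdProfile, regions: list[RegionSpec]) -> pd.DataFrame:
    """Per-region statistics (mean, max, n) over present profile values."""
    rows = []
    for reg in regions:
        vals = [v for sid, v in p.values.items() if sid in reg.segments]
        rows.append(
            {
                "region": reg.name,
                "mean": float(np.mean(vals)) if vals else np.nan,
                "max": float(np.max(vals)) if vals else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows, columns=["region", "mean", "max", "n"])


def profiles_table(
    profiles: dict[str, RmsdProfile],
    mean_profile: RmsdProfile | None = None,
) -> pd.DataFrame:
    """Wide TSV-ready table: seq_id, one deviation column per structure, mean."""
    all_ids = sorted(set().union(*[set(p.values) for p in profiles.values()]))
    data = {"seq_id": all_ids}
    for lab, p in profiles.items():
        data[lab] = [p.values.get(sid, np.nan) for sid in all_ids]
    if mean_profile is not None:
        data["mean"] = [mean_profile.values.get(sid, np.nan) for sid in all_ids]
    return pd.DataFrame(data)


def load_regions(path=None) -> list[RegionSpec]:
    """Load named regions from a TOML file of ``name = "start-end,..."``
    entries; default is the shipped CsfrRNAV VP1 surface-loop config."""
    import tomllib
    from importlib import resources

    from .structio import parse_segment_spec

    if path is None:
        ref = resources.files("capsidphylo") / "data" / "loops_csfrrnav_vp1.toml"
        raw = tomllib.loads(ref.read_text())
    else:
        from pathlib import Path

        raw = tomllib.loads(Path(path).read_text())
    return [RegionSpec(name, parse_segment_spec(spec)) for name, spec in raw.items()]


def write_attribute_file(p: RmsdProfile, path) -> None:
    """Generic ``residue<TAB>value`` file for structure-viewer coloring."""
    with open(path, "w") as fh:
        fh.write("# residue\tvalue\n")
        for sid in sorted(p.values):
            fh.write(f"{sid}\t{p.values[sid]:.4f}\n")
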