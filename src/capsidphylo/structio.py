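"""Coordinate, sequence and residue-range I/O for capsid-protein chains.

The whole pipeline operates on single-chain C-alpha traces.  This module
reads those traces from PDB-format coordinate files (experimental models or
predicted models whose temperature-factor column carries pLDDT), reads and
writes FASTA, parses the inclusive residue-range notation used for
modeled/unmodeled segment bookkeeping ("34-275,332-609"), and locates
short cleavage motifs in capsid polyprotein sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import gemmi
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

AA1 = set("ACDEFGHIKLMNPQRSTVWY")
AA1X = AA1 | {"X"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
_ONE_TO_THREE = {v: k for k, v in reversed(_THREE_TO_ONE.items())}


class FormatError(ValueError):
    """Unparseable record in a coordinate or sequence file."""


class ChainNotFoundError(KeyError):
    """Requested chain identifier absent from the file."""


class EmptyStructureError(ValueError):
    """No C-alpha atoms found for the requested chain."""


@dataclass(frozen=True)
class Residue:
    """One residue of a C-alpha trace.

    ``seq_id`` is the 1-based author residue number; ``ins_code`` the
    (usually empty) insertion code; ``aa`` the one-letter amino-acid code
    (``X`` when unknown); ``ca_xyz`` the C-alpha position in angstroms;
    ``confidence`` an optional per-residue model confidence in [0, 100]
    (pLDDT for predicted models).
    """

    seq_id: int
    aa: str
    ca_xyz: np.ndarray
    ins_code: str = ""
    confidence: Optional[float] = None

    def __post_init__(self):
        xyz = np.asarray(self.ca_xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"residue {self.seq_id}: ca_xyz must be a finite 3-vector")
        object.__setattr__(self, "ca_xyz", xyz)
        if self.confidence is not None and not (0.0 <= self.confidence <= 100.0):
            raise ValueError(f"residue {self.seq_id}: confidence {self.confidence} outside [0, 100]")

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.ins_code)


@dataclass
class CaStructure:
    """Ordered single-chain C-alpha trace."""

    label: str
    residues: list[Residue]

    def __post_init__(self):
        if not self.label:
            raise ValueError("structure label must be non-empty")
        if len(self.residues) < 1:
            raise EmptyStructureError(f"{self.label}: structure has no residues")
        keys = [r.key for r in self.residues]
        for prev, cur in zip(keys, keys[1:]):
            if cur <= prev:
                raise ValueError(
                    f"{self.label}: residues not strictly ordered at {prev} -> {cur}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) C-alpha coordinate array in storage order."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def seq_ids(self) -> list[int]:
        return [r.seq_id for r in self.residues]

    def subset(self, indices: Sequence[int], label: Optional[str] = None) -> "CaStructure":
        return CaStructure(label or self.label, [self.residues[i] for i in indices])


@dataclass(frozen=True)
class SequenceRecord:
    """A labeled amino-acid sequence."""

    label: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"{self.label}: empty sequence")


@dataclass(frozen=True)
class SegmentSet:
    """Normalized set of inclusive residue-number intervals."""

    segments: tuple[tuple[int, int], ...] = ()

    @staticmethod
    def from_intervals(intervals: Iterable[tuple[int, int]]) -> "SegmentSet":
        """Build a normalized set: sorted, adjacent/overlapping runs merged."""
        ivs = sorted((int(a), int(b)) for a, b in intervals)
        for a, b in ivs:
            if a > b:
                raise ValueError(f"segment start {a} > end {b}")
        merged: list[list[int]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return SegmentSet(tuple((a, b) for a, b in merged))

    def __len__(self) -> int:
        return len(self.segments)

    def __contains__(self, seq_id: int) -> bool:
        return any(a <= seq_id <= b for a, b in self.segments)

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    def residue_ids(self) -> list[int]:
        out: list[int] = []
        for a, b in self.segments:
            out.extend(range(a, b + 1))
        return out

    def render(self) -> str:
        return ",".join(f"{a}-{b}" for a, b in self.segments)


def parse_segment_spec(spec: str) -> SegmentSet:
    """Parse a comma-separated inclusive residue-range string.

    ``"34-275,332-609"`` -> two segments; a bare integer is a length-1
    segment; overlapping ranges are merged during normalization.
    """
    intervals = []
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        m = re.fullmatch(r"(-?\d+)(?:\s*-\s*(-?\d+))?", token)
        if m is None:
            raise ValueError(f"cannot parse segment {token!r} (expected e.g. '34-275')")
        a = int(m.group(1))
        b = int(m.group(2)) if m.group(2) is not None else a
        if a > b:
            raise ValueError(f"segment {token!r}: start {a} > end {b}")
        intervals.append((a, b))
    return SegmentSet.from_intervals(intervals)


def subtract_segments(a: SegmentSet, b: SegmentSet) -> SegmentSet:
    """Interval-set difference ``a \\ b`` (both normalized)."""
    out: list[tuple[int, int]] = []
    for start, end in a.segments:
        pieces = [(start, end)]
        for bs, be in b.segments:
            nxt: list[tuple[int, int]] = []
            for ps, pe in pieces:
                if be < ps or bs > pe:
                    nxt.append((ps, pe))
                    continue
                if ps < bs:
                    nxt.append((ps, bs - 1))
                if pe > be:
                    nxt.append((be + 1, pe))
            pieces = nxt
        out.extend(pieces)
    return SegmentSet.from_intervals(out)


def intersect_segments(a: SegmentSet, b: SegmentSet) -> SegmentSet:
    out = []
    for as_, ae in a.segments:
        for bs, be in b.segments:
            lo, hi = max(as_, bs), min(ae, be)
            if lo <= hi:
                out.append((lo, hi))
    return SegmentSet.from_intervals(out)


def count_modeled_residues(modeled: SegmentSet, unmodeled: SegmentSet) -> int:
    """Number of residues in the modeled ranges after removing unmodeled ones."""
    return subtract_segments(modeled, unmodeled).n_residues


def motif_locate(seq: SequenceRecord | str, motif: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) exact occurrences of ``motif``.

    Returns 1-based inclusive (start, end) positions in ascending order.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    m = len(motif)
    return [(i + 1, i + m) for i in range(len(s) - m + 1) if s[i : i + m] == motif]


# ---------------------------------------------------------------------------
# coordinate files


def read_ca_structure(
    path: str | Path,
    chain: Optional[str] = None,
    label: Optional[str] = None,
    predicted: bool = False,
) -> CaStructure:
    """Read a single-chain C-alpha trace from a PDB-format file.

    One :class:`Residue` is produced per residue with a CA atom; residues
    lacking CA are dropped.  Alternate locations keep the highest-occupancy
    altloc (ties broken by lexicographically smallest altloc id).  Only
    ATOM records are honored and only the first MODEL of a multi-model
    file.  When ``predicted`` is true the temperature-factor column is
    read as per-residue confidence (pLDDT); otherwise confidence is left
    unset so experimental B-factors are never mistaken for confidences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    model = st[0]
    chain_names = [ch.name for ch in model]
    if chain is None:
        if len(chain_names) != 1:
            raise ChainNotFoundError(
                f"{path}: file has chains {chain_names}; specify one"
            )
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise ChainNotFoundError(f"{path}: chain {chain!r} not among {chain_names}")

    residues: list[Residue] = []
    for res in gchain:
        if res.het_flag == "H":  # HETATM ignored
            continue
        cas = [a for a in res if a.name == "CA" and a.element != gemmi.Element("Ca")]
        if not cas:
            continue
        # altloc rule: highest occupancy, tie -> smallest altloc id
        ca = min(cas, key=lambda a: (-a.occ, a.altloc or "~"))
        aa = _THREE_TO_ONE.get(res.name.upper(), "X")
        conf = float(ca.b_iso) if predicted else None
        if conf is not None:
            conf = min(max(conf, 0.0), 100.0)
        residues.append(
            Residue(
                seq_id=res.seqid.num,
                ins_code=(res.seqid.icode or "").strip(),
                aa=aa,
                ca_xyz=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                confidence=conf,
            )
        )
    if not residues:
        raise EmptyStructureError(f"{path}: no CA atoms in chain {gchain.name!r}")
    residues.sort(key=lambda r: r.key)
    return CaStructure(label or path.stem, residues)


def write_ca_structure(s: CaStructure, path: str | Path, chain: str = "A") -> None:
    """Write a C-alpha trace as minimal PDB ATOM records (one CA per residue)."""
    lines = []
    for i, r in enumerate(s.residues, start=1):
        res3 = _ONE_TO_THREE.get(r.aa, "UNK")
        b = r.confidence if r.confidence is not None else 0.0
        x, y, z = r.ca_xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:>3s} {chain}{r.seq_id:4d}{r.ins_code or ' ':1s}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read amino-acid FASTA.  Lowercase is uppercased, ``*`` stripped;
    ``-`` is only legal when ``allow_gaps`` (aligned context)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate label {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("*", "")
        allowed = AA1X | ({"-"} if allow_gaps else set())
        bad = set(seq) - allowed
        if bad:
            raise ValueError(f"{path}: {rec.id}: illegal characters {sorted(bad)}")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write FASTA wrapped at 60 columns."""
    bio = [BioSeqRecord(Seq(r.seq), id=r.label, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# accounting report


def accounting_report(
    entries: Sequence[tuple[str, SegmentSet, SegmentSet]], path: Optional[str | Path] = None
):
    """Modeled-residue accounting: one row per (label, modeled, unmodeled).

    Columns: label, modeled_count (raw modeled ranges), unmodeled_count
    (residues removed), net (count after subtraction).  Optionally written
    as TSV.
    """
    import pandas as pd

    rows = []
    for lab, modeled, unmodeled in entries:
        net = count_modeled_residues(modeled, unmodeled)
        removed = modeled.n_residues - net
        rows.append(
            {"label": lab, "modeled_count": modeled.n_residues,
             "unmodeled_count": removed, "net": net}
        )
    df = pd.DataFrame(rows, columns=["label", "modeled_count", "unmodeled_count", "net"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
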