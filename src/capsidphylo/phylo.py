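"""Distance matrices, neighbor joining, progressive MSA, bootstrap and
tree comparison.

The structure phylogeny is built by neighbor joining (Saitou & Nei) on an
all-vs-all matrix of core C-alpha RMSDs; the sequence phylogeny by NJ on
p-distances from a progressive multiple alignment, with column-bootstrap
support values.  Trees are held in dendropy containers behind a thin
:class:`PhyloTree` wrapper that adds bipartition machinery (Robinson-
Foulds distance, host-clade monophyly).

RMSD is a metric-like but not additive distance; it need not satisfy the
triangle inequality, and nothing here assumes it does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from ._dp import gotoh_align
from .structio import AA1X, CaStructure, SequenceRecord
from .superpose import AlignParams, core_rmsd, pair_align, trim_nterm_arm

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix (A for structures, subst/site for
    sequences)."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if np.any(np.abs(self.d - self.d.T) >= 1e-9):
            raise ValueError("matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be >= 0")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def to_phylip(self) -> str:
        """PHYLIP square (lower+upper full matrix) format."""
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + "  ".join(f"{v:.9g}" for v in row))
        return "\n".join(lines) + "\n"

    @staticmethod
    def from_phylip(text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
        return DistanceMatrix(labels, np.array(rows))


def all_vs_all_matrix(
    structures: list[CaStructure],
    params: AlignParams | None = None,
    trim_boundaries: dict[str, int] | None = None,
) -> DistanceMatrix:
    """All-vs-all core-RMSD matrix over (optionally N-arm-trimmed) traces.

    Each entry d_ij is the deviation-trimmed core RMSD of the pairwise
    structural alignment; d_ii = 0 and only i < j is computed.
    """
    params = params or AlignParams()
    if len(structures) < 3:
        raise ValueError("need >= 3 structures for an all-vs-all matrix")
    labels = [s.label for s in structures]
    if len(set(labels)) != len(labels):
        raise ValueError("structure labels must be unique")
    trimmed = []
    for s in structures:
        if trim_boundaries and s.label in trim_boundaries:
            s = trim_nterm_arm(s, trim_boundaries[s.label])
        trimmed.append(s)
    n = len(trimmed)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                corr, _ = pair_align(trimmed[i], trimmed[j], params)
                rmsd, _, _ = core_rmsd(trimmed[i], trimmed[j], corr, params.core_cutoff)
            except Exception as exc:
                raise RuntimeError(
                    f"pair {labels[i]} vs {labels[j]} failed: {exc}"
                ) from exc
            d[i, j] = d[j, i] = rmsd
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# trees


class PhyloTree:
    """Unrooted leaf-labeled tree with branch lengths and optional internal
    support values, backed by a dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def _norm(self, side: frozenset[str]) -> frozenset[str]:
        # canonical side: the one NOT containing the alphabetically first leaf
        ref = min(self.leaf_labels)
        if ref in side:
            return frozenset(self.leaf_labels) - side
        return side

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (internal edges) as canonical leaf sets."""
        all_leaves = set(self.leaf_labels)
        out = set()
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(self._norm(side))
        return out

    def all_sides(self) -> set[frozenset[str]]:
        """Both sides of every edge, trivial (single-leaf) ones included."""
        all_leaves = frozenset(self.leaf_labels)
        out = set()
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 0 < len(side) < len(all_leaves):
                out.add(side)
                out.add(all_leaves - side)
        return out

    def supports(self) -> dict[frozenset[str], float]:
        """Map canonical bipartition -> support value where present."""
        out = {}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node or node.is_leaf():
                continue
            if node.label is None:
                continue
            try:
                sup = float(node.label)
            except ValueError:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            out[self._norm(side)] = sup
        return out


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string; internal node labels are read as supports."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize with supports as internal-node labels, 9-significant-digit
    branch lengths."""
    s = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".9g",
    )
    return s.strip() + "\n"


def nj_build(m: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou & Nei, with the Studier-Keppler Q criterion).

    Q_ij = (n-2) d_ij - r_i - r_j with r_i = sum_k d_ik; the minimal-Q pair
    is joined (ties: first pair in label-sorted scan order), branch lengths
    follow the rate-corrected split formula, and the reduction formula
    yields distances to the new node.  Negative branch lengths are clamped
    to zero with the deficit moved to the sibling branch.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    order = sorted(range(n), key=lambda i: m.labels[i])
    labels = [m.labels[i] for i in order]
    D = m.d[np.ix_(order, order)].copy()

    tns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # first strict minimum in row-major order == earliest label order
        i, j = divmod(int(np.argmin(Q)), k)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (k - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # reduction: distance from new node u to every other node
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        newD = np.zeros((k - 1, k - 1))
        newD[: k - 2, : k - 2] = D[np.ix_(keep, keep)]
        newD[-1, : k - 2] = newD[: k - 2, -1] = du[keep]
        D = newD
        nodes = [nodes[x] for x in keep] + [parent]

    # final trifurcation via the three-point formula
    (u, v, w) = nodes
    duv, duw, dvw = D[0, 1], D[0, 2], D[1, 2]
    root = dendropy.Node()
    for nd, ln in (
        (u, 0.5 * (duv + duw - dvw)),
        (v, 0.5 * (duv + dvw - duw)),
        (w, 0.5 * (duw + dvw - duv)),
    ):
        root.add_child(nd)
        nd.edge.length = max(float(ln), 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


def upgma_build(m: DistanceMatrix) -> PhyloTree:
    """UPGMA (average linkage) alternative to NJ, for sensitivity checks."""
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    order = sorted(range(len(m.labels)), key=lambda i: m.labels[i])
    labels = [m.labels[i] for i in order]
    D = m.d[np.ix_(order, order)]
    Z = average(squareform(D, checks=False))
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    heights = [0.0] * len(labels)
    for a, b, h, _ in Z:
        parent = dendropy.Node()
        for child in (nodes[int(a)], nodes[int(b)]):
            parent.add_child(child)
        nodes[int(a)].edge.length = h / 2 - heights[int(a)]
        nodes[int(b)].edge.length = h / 2 - heights[int(b)]
        nodes.append(parent)
        heights.append(h / 2)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[-1]
    tree.is_rooted = True
    return PhyloTree(tree)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: internal bipartitions unique to one tree."""
    if set(t1.leaf_labels) != set(t2.leaf_labels):
        raise ValueError("trees have different leaf sets")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)


def host_monophyly(tree: PhyloTree, hosts: dict[str, str]) -> pd.DataFrame:
    """Per-host clade test on the unrooted tree.

    A host is monophyletic if its leaves are exactly one side of some
    bipartition.  Purity is the host fraction of the smallest side that
    contains every leaf of the host (1.0 iff monophyletic).
    """
    leaves = set(tree.leaf_labels)
    unknown = set(hosts) - leaves
    if unknown:
        raise ValueError(f"host map contains unknown leaves: {sorted(unknown)}")
    missing = leaves - set(hosts)
    if missing:
        raise ValueError(f"host map missing leaves: {sorted(missing)}")
    sides = tree.all_sides() | {frozenset(leaves)}
    rows = []
    for host in sorted(set(hosts.values())):
        members = frozenset(l for l, h in hosts.items() if h == host)
        mono = members in sides
        containing = [s for s in sides if members <= s]
        purity = max(len(members) / len(s) for s in containing)
        rows.append(
            {"host": host, "n_leaves": len(members),
             "monophyletic": bool(mono), "purity": float(purity)}
        )
    return pd.DataFrame(rows, columns=["host", "n_leaves", "monophyletic", "purity"])


# ---------------------------------------------------------------------------
# sequence side: alignment, distances, bootstrap


@dataclass
class Msa:
    """Multiple sequence alignment: equal-length gapped rows."""

    records: list[SequenceRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("empty alignment")
        L = len(self.records[0].seq)
        if any(len(r.seq) != L for r in self.records):
            raise ValueError("alignment rows differ in length")
        labels = [r.label for r in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in alignment")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0].seq)

    def as_matrix(self) -> np.ndarray:
        return np.array([list(r.seq) for r in self.records])


_ALPHA = _BLOSUM62.alphabet


def _encode(seq: str) -> np.ndarray:
    xi = _ALPHA.index("X")
    return np.array([_ALPHA.index(c) if c in _ALPHA else xi for c in seq], dtype=int)


def _profile_score_matrix(rows_a: list[str], rows_b: list[str]) -> np.ndarray:
    """Column-vs-column mean BLOSUM62 score over non-gap residue pairs."""
    B = np.asarray(_BLOSUM62)
    gap_code = -1

    def cols(rows):
        enc = np.array(
            [[(_ALPHA.index(c) if c in _ALPHA else _ALPHA.index("X"))
              if c != "-" else gap_code for c in row] for row in rows]
        )
        return enc.T  # (n_cols, n_rows)

    ca, cb = cols(rows_a), cols(rows_b)
    na, nb = ca.shape[0], cb.shape[0]
    S = np.zeros((na, nb))
    for i in range(na):
        ai = ca[i]
        ai = ai[ai >= 0]
        if ai.size == 0:
            continue
        sub = B[ai]  # (k, alpha)
        for j in range(nb):
            bj = cb[j]
            bj = bj[bj >= 0]
            if bj.size == 0:
                continue
            S[i, j] = sub[:, bj].mean()
    return S


def progressive_msa(
    records: list[SequenceRecord],
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> Msa:
    """Progressive multiple alignment under BLOSUM62 with affine gaps.

    Guide tree: NJ on k-mer distances (k = 3); merge order: guide-tree
    postorder, aligning profile to profile with column scores averaged
    over non-gap residue pairs.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 sequences")
    for r in records:
        bad = set(r.seq) - AA1X
        if bad:
            raise ValueError(f"{r.label}: illegal characters {sorted(bad)}")
    if len(set(r.label for r in records)) != len(records):
        raise ValueError("duplicate sequence labels")

    if len(records) == 2:
        plan = [(frozenset([records[0].label]), frozenset([records[1].label]))]
    else:
        km = _kmer_distance_matrix(records)
        guide = nj_build(km)
        plan = _merge_plan(guide)

    # each active group: (ordered labels, gapped rows)
    active: dict[frozenset, tuple[list[str], list[str]]] = {
        frozenset([r.label]): ([r.label], [r.seq]) for r in records
    }
    for ga, gb in plan:
        la, rows_a = active.pop(ga)
        lb, rows_b = active.pop(gb)
        S = _profile_score_matrix(rows_a, rows_b)
        _, pairs = gotoh_align(S, gap_open, gap_extend)
        rows = _merge_rows(rows_a, rows_b, pairs)
        active[ga | gb] = (la + lb, rows)
    (labels, rows) = next(iter(active.values()))
    out = [SequenceRecord(lab, row) for lab, row in zip(labels, rows)]
    # restore input order
    order = {r.label: i for i, r in enumerate(records)}
    out.sort(key=lambda r: order[r.label])
    return Msa(out)


def _merge_rows(rows_a: list[str], rows_b: list[str], pairs: np.ndarray) -> list[str]:
    na, nb = len(rows_a[0]), len(rows_b[0])
    cols: list[tuple[int, int]] = []  # (col_a or -1, col_b or -1)
    pa, pb = 0, 0
    for ia, ib in pairs:
        while pa < ia:
            cols.append((pa, -1))
            pa += 1
        while pb < ib:
            cols.append((-1, pb))
            pb += 1
        cols.append((pa, pb))
        pa += 1
        pb += 1
    while pa < na:
        cols.append((pa, -1))
        pa += 1
    while pb < nb:
        cols.append((-1, pb))
        pb += 1
    out = []
    for row in rows_a:
        out.append("".join(row[c[0]] if c[0] >= 0 else "-" for c in cols))
    for row in rows_b:
        out.append("".join(row[c[1]] if c[1] >= 0 else "-" for c in cols))
    return out


def _kmer_distance_matrix(records: list[SequenceRecord], k: int = 3) -> DistanceMatrix:
    from collections import Counter

    counters = [Counter(r.seq[i : i + k] for i in range(max(len(r.seq) - k + 1, 0)))
                for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            denom = max(min(sum(counters[i].values()), sum(counters[j].values())), 1)
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return DistanceMatrix([r.label for r in records], d)


def _merge_plan(guide: PhyloTree) -> list[tuple[frozenset, frozenset]]:
    """Postorder pairwise-merge plan from the guide tree (multifurcations
    merged left to right)."""
    plan: list[tuple[frozenset, frozenset]] = []

    def visit(node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.taxon.label])
        children = [visit(ch) for ch in node.child_nodes()]
        acc = children[0]
        for nxt in children[1:]:
            plan.append((acc, nxt))
            acc = acc | nxt
        return acc

    visit(guide.dendropy_tree.seed_node)
    return plan


def pdistance_matrix(msa: Msa, correction: str = "p") -> DistanceMatrix:
    """Pairwise p-distances over columns where neither row is gapped.

    ``correction='poisson'`` applies d = -ln(1 - p).
    """
    M = msa.as_matrix()
    n = len(msa.records)
    gap = M == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise ValueError(
                    f"{msa.labels[i]} vs {msa.labels[j]}: no comparable columns"
                )
            p = float((M[i, ok] != M[j, ok]).mean())
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("p-distance 1.0: Poisson correction undefined")
                p = -np.log(1.0 - p)
            elif correction != "p":
                raise ValueError(f"unknown correction {correction!r}")
            d[i, j] = d[j, i] = p
    return DistanceMatrix(msa.labels, d)


def bootstrap_support(
    msa: Msa, n_reps: int = 1000, seed: int | None = None, correction: str = "p"
) -> PhyloTree:
    """NJ tree from the full alignment, with column-bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal bipartition of the full-data tree is the percentage of
    completed replicates whose NJ tree contains it.  Replicates where some
    pair has no comparable columns are skipped (with a warning) and do not
    enter the denominator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = nj_build(pdistance_matrix(msa, correction))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = msa.n_columns
    completed = 0
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = Msa(
            [SequenceRecord(r.label, "".join(r.seq[c] for c in cols))
             for r in msa.records]
        )
        try:
            rep_tree = nj_build(pdistance_matrix(rep, correction))
        except ValueError:
            skipped += 1
            continue
        completed += 1
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped:
        warnings.warn(f"bootstrap: {skipped} degenerate replicates skipped")
    if completed == 0:
        raise RuntimeError("all bootstrap replicates degenerate")
    # attach supports as internal-node labels
    tree = full.dendropy_tree
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = full._norm(side)
        if key in counts:
            node.label = f"{100.0 * counts[key] / completed:g}"
    return PhyloTree(tree)
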