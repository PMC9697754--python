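"""Synthetic homolog families with a known phylogeny.

Generates a family of single-chain C-alpha traces plus co-evolved
amino-acid sequences diverged along a random unrooted binary tree, the
ground truth against which tree-recovery of the whole pipeline is judged.

Structures evolve by a Cartesian Brownian model: along an edge of length
t every coordinate receives independent N(0, coord_sigma^2 * t * w_i)
noise, where w_i = loop_k inside designated "loop" segments (emulating
the hypervariable surface loops of capsid VP1s) and 1 elsewhere.  Every
leaf additionally gets a random rigid transform, so superposition is
always load-bearing downstream.  Sequences evolve by a Poisson
substitution process on the same tree (per edge of length t each site
substitutes with probability 1 - exp(-sub_rate * t), uniformly over the
other 19 amino acids).  Optional terminal deletions exercise trimming and
alignment-offset handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy.spatial.transform import Rotation

from .phylo import PhyloTree, write_newick
from .structio import (
    CaStructure,
    Residue,
    SegmentSet,
    SequenceRecord,
    write_ca_structure,
    write_fasta,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimParams:
    """Study conditions of a synthetic family.

    Defaults are the pipeline-recovery conditions used throughout the
    test suite: 12 taxa, 250-residue chains, coordinate noise 0.4 A per
    sqrt(unit branch length), 0.3 substitutions/site per unit branch
    length, no terminal indels.
    """

    n_taxa: int = 12
    chain_length: int = 250
    coord_sigma: float = 0.4
    sub_rate: float = 0.3
    terminal_indel_max: int = 0
    seed: int = 0
    loop_k: float = 4.0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.chain_length < 30:
            raise ValueError("chain_length must be >= 30")
        if self.coord_sigma < 0 or self.sub_rate < 0:
            raise ValueError("noise rates must be >= 0")
        if self.terminal_indel_max < 0:
            raise ValueError("terminal_indel_max must be >= 0")


@dataclass
class SimFamily:
    """A generated family: ground-truth tree, traces, sequences, hosts."""

    true_tree: PhyloTree
    structures: list[CaStructure]
    sequences: list[SequenceRecord]
    hosts: dict[str, str]
    loop_segments: SegmentSet


def sample_tree(n_taxa: int, seed: int | None = None) -> PhyloTree:
    """Random unrooted binary tree by sequential random edge attachment.

    Branch lengths are i.i.d. exponential with mean 0.1.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1:02d}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    edges = []  # nodes whose edge-to-parent is attachable
    for lab in labels[:3]:
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        root.add_child(leaf)
        edges.append(leaf)
    for lab in labels[3:]:
        target = edges[int(rng.integers(0, len(edges)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        mid.add_child(leaf)
        edges.extend([mid, leaf])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.edge.length = float(rng.exponential(0.1))
    return PhyloTree(tree)


def helix_fold(chain_length: int, label: str = "base") -> CaStructure:
    """Idealized helical C-alpha trace: rise 1.5 A, radius 2.3 A,
    100 degrees per residue."""
    residues = []
    for i in range(chain_length):
        theta = math.radians(100.0 * i)
        xyz = np.array([2.3 * math.cos(theta), 2.3 * math.sin(theta), 1.5 * i])
        residues.append(Residue(seq_id=i + 1, aa="A", ca_xyz=xyz))
    return CaStructure(label, residues)


def default_loop_segments(chain_length: int) -> SegmentSet:
    """Three "surface loop" windows at ~1/3, ~3/5 and ~5/6 of the chain."""
    L = chain_length
    return SegmentSet.from_intervals(
        [
            (int(0.30 * L) + 1, int(0.40 * L)),
            (int(0.55 * L) + 1, int(0.65 * L)),
            (int(0.80 * L) + 1, int(0.88 * L)),
        ]
    )


def _edge_iter_with_parents(tree: dendropy.Tree):
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            yield node.parent_node, node


def evolve_structures(
    tree: PhyloTree,
    base_fold: CaStructure,
    coord_sigma: float,
    seed: int | None = None,
    loop_segments: SegmentSet | None = None,
    loop_k: float = 4.0,
    rigid_transforms: bool = True,
) -> list[CaStructure]:
    """Brownian structural divergence of ``base_fold`` along ``tree``.

    The trace at the (arbitrarily rooted) seed node is the base fold; each
    edge of length t adds i.i.d. N(0, coord_sigma^2 * t * w_i) per
    coordinate with w_i = loop_k inside loop segments.  Each leaf finally
    receives a random rotation + translation.
    """
    if coord_sigma < 0:
        raise ValueError("coord_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if loop_segments is None:
        loop_segments = default_loop_segments(len(base_fold))
    w = np.array(
        [loop_k if r.seq_id in loop_segments else 1.0 for r in base_fold.residues]
    )
    dtree = tree.dendropy_tree
    coords = {id(dtree.seed_node): base_fold.coords}
    leaves: dict[str, np.ndarray] = {}
    for parent, node in _edge_iter_with_parents(dtree):
        t = node.edge.length if node.edge.length is not None else 0.0
        std = coord_sigma * np.sqrt(t * w)[:, None]
        xyz = coords[id(parent)] + rng.normal(size=(len(w), 3)) * std
        coords[id(node)] = xyz
        if node.is_leaf():
            leaves[node.taxon.label] = xyz
    out = []
    for lab in sorted(leaves):
        xyz = leaves[lab]
        if rigid_transforms:
            R = Rotation.random(random_state=rng).as_matrix()
            tvec = rng.uniform(-20.0, 20.0, size=3)
            xyz = xyz @ R.T + tvec
        residues = [
            Residue(seq_id=r.seq_id, ins_code=r.ins_code, aa=r.aa, ca_xyz=p)
            for r, p in zip(base_fold.residues, xyz)
        ]
        out.append(CaStructure(lab, residues))
    return out


def evolve_sequences(
    tree: PhyloTree,
    root_seq: str,
    sub_rate: float,
    seed: int | None = None,
) -> list[SequenceRecord]:
    """Poisson substitution process along the tree, starting from
    ``root_seq``; per edge of length t each site substitutes with
    probability 1 - exp(-sub_rate * t), uniformly over the other 19."""
    rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    seqs = {id(dtree.seed_node): np.array(list(root_seq))}
    leaves: dict[str, str] = {}
    aa = np.array(list(_AA20))
    for parent, node in _edge_iter_with_parents(dtree):
        t = node.edge.length if node.edge.length is not None else 0.0
        p_sub = 1.0 - math.exp(-sub_rate * t)
        seq = seqs[id(parent)].copy()
        hits = np.flatnonzero(rng.random(len(seq)) < p_sub)
        for i in hits:
            choices = aa[aa != seq[i]]
            seq[i] = choices[int(rng.integers(0, len(choices)))]
        seqs[id(node)] = seq
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(seq)
    return [SequenceRecord(lab, leaves[lab]) for lab in sorted(leaves)]


def assign_hosts(tree: PhyloTree) -> dict[str, str]:
    """Host = which of the three clades off the unrooted trifurcation a
    leaf belongs to.  Each host's leaves are a bipartition side, so they
    are exactly monophyletic on the true topology."""
    hosts = {}
    for i, child in enumerate(tree.dendropy_tree.seed_node.child_nodes(), start=1):
        for lf in child.leaf_iter():
            hosts[lf.taxon.label] = f"H{i}"
    return hosts


def generate_family(params: SimParams) -> SimFamily:
    """Generate a full in-memory family under ``params``."""
    ss = np.random.SeedSequence(params.seed)
    s_tree, s_struct, s_seq, s_misc = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    tree = sample_tree(params.n_taxa, s_tree)
    base = helix_fold(params.chain_length)
    loops = default_loop_segments(params.chain_length)
    structures = evolve_structures(
        tree, base, params.coord_sigma, s_struct, loops, params.loop_k
    )
    rng = np.random.default_rng(s_misc)
    root_seq = "".join(
        _AA20[i] for i in rng.integers(0, 20, size=params.chain_length)
    )
    sequences = evolve_sequences(tree, root_seq, params.sub_rate, s_seq)
    # give every structure its co-evolved sequence
    structures = [
        CaStructure(
            s.label,
            [
                Residue(seq_id=r.seq_id, ins_code=r.ins_code, aa=a, ca_xyz=r.ca_xyz)
                for r, a in zip(s.residues, seq.seq)
            ],
        )
        for s, seq in zip(structures, sequences)
    ]
    if params.terminal_indel_max > 0:
        cut = rng.integers(0, params.terminal_indel_max + 1, size=len(structures))
        structures = [
            CaStructure(s.label, s.residues[int(k):]) for s, k in zip(structures, cut)
        ]
        sequences = [
            SequenceRecord(q.label, q.seq[int(k):]) for q, k in zip(sequences, cut)
        ]
    hosts = assign_hosts(tree)
    return SimFamily(tree, structures, sequences, hosts, loops)


def emit_family(params: SimParams, outdir: str | Path) -> SimFamily:
    """Generate a family and write it to disk.

    One PDB-format file per structure, one FASTA of all sequences, the
    true tree as Newick, and a two-column hosts TSV.
    """
    fam = generate_family(params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in fam.structures:
        write_ca_structure(s, outdir / f"{s.label}.pdb")
    write_fasta(fam.sequences, outdir / "sequences.fasta")
    (outdir / "true_tree.nwk").write_text(write_newick(fam.true_tree))
    with open(outdir / "hosts.tsv", "w") as fh:
        fh.write("label\thost\n")
        for lab in sorted(fam.hosts):
            fh.write(f"{lab}\t{fam.hosts[lab]}\n")
    return fam
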