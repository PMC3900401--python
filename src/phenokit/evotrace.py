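"""Evolutionary-trace ranking of alignment columns.

The evolutionary trace (ET) scores each column of a multiple sequence
alignment by how well its residue variation follows the major
divergences of a phylogenetic tree built from the same alignment.  The
tree is cut at successive levels below the root; at level ``n`` the
leaves fall into ``n`` groups (the subalignments at "distance" n from
the root), and each group g contributes the Shannon entropy

    s_ig = - sum_a f_ia^g * ln f_ia^g

of the amino-acid frequencies ``f_ia^g`` of column i over the non-gap
rows of g.  The real-valued trace score of column i is

    rho_i = 1 + sum_{n=1}^{N-1} (1/n) * sum_{g=1}^{n} s_ig

where N is the number of sequences.  A column that is invariant within
every group at every level has rho = 1, the global minimum, and hence
the best rank; catalytic and cofactor-binding residues of an enzyme
family are expected near the top of this ranking, and their spatial
clustering on a structure is assessed with a permutation z-score.

Columns and residue numbers are 1-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from scipy.spatial.distance import pdist

from .constants import AMINO_ACIDS, GAP

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class Alignment:
    """Rectangular multiple sequence alignment (rows x columns)."""

    ids: list[str]
    residues: np.ndarray  # (N, L) array of single characters, '-' for gap

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype="<U1")
        if self.residues.ndim != 2:
            raise ValueError("residue matrix must be 2-D")
        if len(self.ids) != self.residues.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.n_sequences < 2:
            raise ValueError("an alignment needs at least 2 sequences")

    @property
    def n_sequences(self) -> int:
        return self.residues.shape[0]

    @property
    def n_columns(self) -> int:
        return self.residues.shape[1]

    def column(self, i: int) -> np.ndarray:
        """Residues of 1-based column ``i``."""
        if not 1 <= i <= self.n_columns:
            raise IndexError(f"column {i} out of range 1..{self.n_columns}")
        return self.residues[:, i - 1]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.residues):
                fh.write(f">{sid}\n{''.join(row)}\n")


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; all records must have equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(
                f"ragged alignment: sequence '{rec.id}' has length "
                f"{len(rec.seq)}, expected {length}"
            )
    ids = [rec.id for rec in records]
    matrix = np.array([list(str(rec.seq).strip().upper()) for rec in records])
    return Alignment(ids, matrix)


def _encode(aln: Alignment) -> np.ndarray:
    """Integer-encode residues: 0..19 amino acids, -1 for gap/unknown."""
    codes = np.full(aln.residues.shape, -1, dtype=np.int8)
    for aa, k in _AA_INDEX.items():
        codes[aln.residues == aa] = k
    return codes


# ---------------------------------------------------------------------------
# Distances and UPGMA tree


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # (N, N) symmetric, zero diagonal


def identity_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise 1 - fractional identity over columns where both rows are non-gap.

    A pair with no co-non-gap columns gets distance 1 (with a warning).
    """
    n = aln.n_sequences
    res = aln.residues
    nongap = res != GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            co = int(both.sum())
            if co == 0:
                logger.warning(
                    "sequences %s and %s share no co-non-gap columns; "
                    "distance set to 1",
                    aln.ids[i],
                    aln.ids[j],
                )
                dij = 1.0
            else:
                matches = int((both & (res[i] == res[j])).sum())
                dij = 1.0 - matches / co
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(aln.ids), d)


@dataclass(eq=False)
class TreeNode:
    """Node of a rooted tree; leaves sit at height 0, merges above."""

    height: float
    children: tuple = ()
    name: str | None = None
    leaves: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.children and not self.leaves:
            self.leaves = frozenset([self.name])

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def min_leaf(self) -> str:
        return min(self.leaves)


@dataclass
class PhyloTree:
    """Rooted tree over sequence ids; node heights record merge order."""

    root: TreeNode

    @property
    def leaf_names(self) -> frozenset:
        return self.root.leaves

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves)

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return out

    def to_newick(self) -> str:
        def fmt(nd: TreeNode, parent_height: float) -> str:
            bl = parent_height - nd.height
            if nd.is_leaf:
                return f"{nd.name}:{bl:.10g}"
            inner = ",".join(
                fmt(c, nd.height)
                for c in sorted(nd.children, key=lambda c: c.min_leaf)
            )
            return f"({inner}):{bl:.10g}"

        root = self.root
        if root.is_leaf:  # degenerate single-leaf tree
            return f"{root.name};"
        inner = ",".join(
            fmt(c, root.height)
            for c in sorted(root.children, key=lambda c: c.min_leaf)
        )
        return f"({inner});"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def read_tree(path) -> PhyloTree:
    """Read a newick file written by :meth:`PhyloTree.write_newick`.

    Node heights are recovered as the maximum branch-length distance to
    a descendant leaf, which inverts the writer exactly (the writer
    emits ``parent_height - child_height`` as branch lengths and every
    leaf at height 0).
    """
    import dendropy

    dtree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(height=0.0, name=dnode.taxon.label.replace(" ", "_"))
        kids = []
        height = 0.0
        for child in dnode.child_nodes():
            knode = convert(child)
            bl = child.edge.length or 0.0
            height = max(height, knode.height + bl)
            kids.append(knode)
        return TreeNode(
            height=height,
            children=tuple(kids),
            leaves=frozenset().union(*(k.leaves for k in kids)),
        )

    return PhyloTree(convert(dtree.seed_node))


def build_tree(d: DistanceMatrix, method: str = "upgma") -> PhyloTree:
    """UPGMA (average-linkage) rooted tree; merge height = distance / 2.

    Ties on the smallest pairwise distance are broken by the
    lexicographically smallest (then second-smallest) member id of the
    candidate pair, which makes the topology deterministic.
    """
    if method.lower() != "upgma":
        raise ValueError(f"unsupported tree method: {method}")
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 sequences to build a tree")
    clusters: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, name=d.ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:

        def tie_key(pair: tuple[int, int]):
            a, b = pair
            la, lb = clusters[a].min_leaf, clusters[b].min_leaf
            return (dist[pair], min(la, lb), max(la, lb))

        a, b = min(dist, key=tie_key)
        h = dist[(a, b)] / 2.0
        ca, cb = clusters.pop(a), clusters.pop(b)
        kids = tuple(sorted((ca, cb), key=lambda nd: nd.min_leaf))
        sa, sb = sizes.pop(a), sizes.pop(b)
        new_dist: dict[tuple[int, int], float] = {}
        for (i, j), v in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(i, j)] = v
        for k in clusters:
            dak = dist[(min(a, k), max(a, k))]
            dbk = dist[(min(b, k), max(b, k))]
            new_dist[(min(k, next_id), max(k, next_id))] = (
                sa * dak + sb * dbk
            ) / (sa + sb)
        dist = new_dist
        clusters[next_id] = TreeNode(height=h, children=kids, leaves=ca.leaves | cb.leaves)
        sizes[next_id] = sa + sb
        next_id += 1
    return PhyloTree(next(iter(clusters.values())))


# ---------------------------------------------------------------------------
# Partitions and trace scores


@dataclass
class Partition:
    """Leaf groups obtained by cutting the tree after its first n-1 merges."""

    level: int
    groups: list[frozenset]


def _split_highest(forest: list[TreeNode]) -> list[TreeNode]:
    """Replace the highest internal node of the forest by its children.

    Ties on height go to the node with the lexicographically smallest
    leaf id, mirroring the UPGMA tie-break.
    """
    internal = [nd for nd in forest if not nd.is_leaf]
    if not internal:
        raise ValueError("no internal node left to split")
    pick = sorted(internal, key=lambda nd: (-nd.height, nd.min_leaf))[0]
    out = [nd for nd in forest if nd is not pick]
    out.extend(pick.children)
    return out


def partition_at(tree: PhyloTree, n: int) -> Partition:
    """Groups at partition level ``n``: remove the n-1 highest nodes, root first."""
    N = tree.n_leaves
    if not 1 <= n <= N:
        raise ValueError(f"partition level {n} out of range 1..{N}")
    forest = [tree.root]
    for _ in range(n - 1):
        forest = _split_highest(forest)
    groups = sorted((nd.leaves for nd in forest), key=min)
    return Partition(level=n, groups=list(groups))


def group_frequencies(
    aln: Alignment, partition: Partition, column: int
) -> list[dict[str, float]]:
    """Per-group amino-acid frequencies ``f_ia^g`` of a 1-based column.

    Frequencies are taken over non-gap rows only; a group whose rows are
    all gaps at this column yields an empty dict (entropy 0).
    """
    col = aln.column(column)
    row_of = {sid: k for k, sid in enumerate(aln.ids)}
    out: list[dict[str, float]] = []
    for group in partition.groups:
        chars = [col[row_of[sid]] for sid in group]
        chars = [c for c in chars if c != GAP]
        freqs: dict[str, float] = {}
        if chars:
            total = len(chars)
            for c in chars:
                freqs[c] = freqs.get(c, 0.0) + 1.0
            freqs = {c: v / total for c, v in freqs.items()}
        out.append(freqs)
    return out


def _node_column_entropies(codes: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Natural-log Shannon entropy per column over the non-gap rows given."""
    sub = codes[rows]  # (m, L)
    L = codes.shape[1]
    counts = np.zeros((20, L))
    for k in range(20):
        counts[k] = (sub == k).sum(axis=0)
    tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, counts / np.where(tot > 0, tot, 1.0), 0.0)
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=0)


@dataclass
class ResidueTrace:
    """Trace scores and competition ranks, indexed by 1-based column."""

    columns: np.ndarray  # 1..L
    scores: np.ndarray  # rho_i >= 1, lower is better
    ranks: np.ndarray  # ties share the minimum applicable rank

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": self.columns, "rho": self.scores, "rank": self.ranks}
        )


def _competition_ranks(scores: np.ndarray) -> np.ndarray:
    # rank = 1 + number of strictly better (lower) scores; ties share it
    sorted_scores = np.sort(scores)
    return np.searchsorted(sorted_scores, scores, side="left") + 1


def trace_scores(aln: Alignment, tree: PhyloTree) -> ResidueTrace:
    """Real-valued ET score rho per column (see module docstring)."""
    if tree.leaf_names != frozenset(aln.ids):
        raise ValueError("tree leaves do not match alignment sequence ids")
    N = aln.n_sequences
    codes = _encode(aln)
    row_of = {sid: k for k, sid in enumerate(aln.ids)}
    ent_cache: dict[int, np.ndarray] = {}

    def node_entropy(nd: TreeNode) -> np.ndarray:
        key = id(nd)
        if key not in ent_cache:
            rows = np.fromiter((row_of[s] for s in nd.leaves), dtype=int)
            ent_cache[key] = _node_column_entropies(codes, rows)
        return ent_cache[key]

    rho = np.ones(aln.n_columns)
    forest = [tree.root]
    for n in range(1, N):
        level = np.zeros(aln.n_columns)
        for nd in forest:
            level += node_entropy(nd)
        rho += level / n
        if n < N - 1:
            forest = _split_highest(forest)
    columns = np.arange(1, aln.n_columns + 1)
    return ResidueTrace(columns=columns, scores=rho, ranks=_competition_ranks(rho))


def rank_residues(trace: ResidueTrace) -> pd.DataFrame:
    """Columns ordered by (rho, column index), best first."""
    frame = trace.to_frame()
    return frame.sort_values(["rho", "column"], kind="stable").reset_index(drop=True)


def write_trace_report(trace: ResidueTrace, aln: Alignment, path) -> None:
    """TSV report: column, consensus residue, rho, rank."""
    frame = rank_residues(trace)
    consensus = []
    for col in frame["column"]:
        chars = [c for c in aln.column(int(col)) if c != GAP]
        consensus.append(max(set(chars), key=chars.count) if chars else GAP)
    frame = frame.assign(residue=consensus)[["column", "residue", "rho", "rank"]]
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structures and spatial clustering


@dataclass
class StructureModel:
    """CA-only structural model: residue number -> 3-D coordinate (Angstrom)."""

    coords: dict[int, np.ndarray]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = {int(k): np.asarray(v, dtype=float) for k, v in self.coords.items()}
        for k, v in self.coords.items():
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"residue {k}: coordinate must be a finite 3-vector")

    @property
    def residue_numbers(self) -> list[int]:
        return sorted(self.coords)

    def to_pdb(self, path) -> None:
        with open(path, "w") as fh:
            for serial, res in enumerate(self.residue_numbers, start=1):
                x, y, z = self.coords[res]
                fh.write(
                    f"ATOM  {serial:5d}  CA  ALA {self.chain_id}{res:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("END\n")


def read_structure(path) -> StructureModel:
    """Read CA coordinates from a PDB file (first model, first chain)."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    model = next(structure.get_models())
    chain = next(model.get_chains())
    coords: dict[int, np.ndarray] = {}
    for residue in chain.get_residues():
        if "CA" not in residue:
            continue
        resnum = residue.id[1]
        if resnum in coords:
            raise ValueError(f"duplicate residue number {resnum} in structure")
        coords[resnum] = np.array(residue["CA"].coord, dtype=float)
    if not coords:
        raise ValueError("no CA atoms found in structure")
    return StructureModel(coords, chain_id=chain.id)


def map_to_structure(
    trace: ResidueTrace, structure: StructureModel, offset: int = 0
) -> pd.DataFrame:
    """Map trace columns onto structure residues: residue = column + offset.

    Columns without a structure residue are flagged ``mapped = False``.
    """
    residues = trace.columns + offset
    mapped = np.array([int(r) in structure.coords for r in residues])
    return pd.DataFrame(
        {
            "column": trace.columns,
            "residue": residues,
            "rho": trace.scores,
            "rank": trace.ranks,
            "mapped": mapped,
        }
    )


@dataclass
class ClusterStats:
    """Permutation test of spatial clustering of a residue selection."""

    observed: float
    null_mean: float
    null_sd: float
    zscore: float
    n_permutations: int
    cutoff_A: float
    seed: int


def _pair_count(coords: np.ndarray, cutoff: float) -> int:
    if len(coords) < 2:
        return 0
    return int((pdist(coords) <= cutoff).sum())


def cluster_zscore(
    structure: StructureModel,
    selected: "set[int] | list[int]",
    cutoff_A: float = 12.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterStats:
    """Z-score of the selected residues' CA-CA contact-pair count.

    The observed statistic is the number of selected residue pairs within
    ``cutoff_A``; the null draws ``n_perm`` uniform random residue sets of
    the same size from the structure.
    """
    selected = sorted(set(int(s) for s in selected))
    all_res = structure.residue_numbers
    if len(selected) < 2:
        raise ValueError("need at least 2 selected residues")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if len(selected) > len(all_res):
        raise ValueError("selection larger than the structure")
    missing = [s for s in selected if s not in structure.coords]
    if missing:
        raise ValueError(f"selected residues not in structure: {missing}")
    obs = _pair_count(np.array([structure.coords[s] for s in selected]), cutoff_A)
    rng = np.random.default_rng(seed)
    all_coords = np.array([structure.coords[r] for r in all_res])
    null = np.empty(n_perm)
    for p in range(n_perm):
        idx = rng.choice(len(all_res), size=len(selected), replace=False)
        null[p] = _pair_count(all_coords[idx], cutoff_A)
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    if sd == 0.0:
        raise ValueError("degenerate null distribution (sd = 0)")
    return ClusterStats(
        observed=float(obs),
        null_mean=mean,
        null_sd=sd,
        zscore=(obs - mean) / sd,
        n_permutations=n_perm,
        cutoff_A=cutoff_A,
        seed=seed,
    )
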