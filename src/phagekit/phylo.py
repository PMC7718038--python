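"""Distance-based phylogenetics.

p-distances from multiple sequence alignments (pairwise deletion),
Saitou-Nei neighbor joining with deterministic tie-breaking, bootstrap
support from column resampling, pairwise global identity via affine-gap
Needleman-Wunsch, and Newick serialization.

The NJ agglomeration minimizes

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

joining the minimal-Q pair at each step (ties broken by the
lexicographically smallest pair of cluster labels, which makes runs
deterministic and taxon-order invariant), with branch lengths from the
standard divergence formulas.  Negative branch lengths are clamped to 0
and flagged.  The output is an unrooted tree represented with a
trifurcating root.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "SequenceAlignment",
    "DistanceMatrix",
    "Clade",
    "PhyloTree",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "pairwise_global_identity",
    "write_newick",
    "read_newick",
]

_NT_VALID = set("ACGT")
_AA_VALID = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceAlignment:
    """Equal-length gapped rows with ids; nucleotide or amino acid."""

    ids: tuple
    rows: tuple
    alphabet: str = "nt"  # "nt" | "aa"

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        rows = tuple(r.upper() for r in self.rows)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rows", rows)
        if len(ids) != len(rows):
            raise InvalidInputError("ids and rows differ in length")
        if len(rows) < 2:
            raise InvalidInputError("an alignment needs at least 2 rows")
        if len({len(r) for r in rows}) != 1:
            raise InvalidInputError("alignment rows must all have the same length")
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate sequence ids in alignment")
        if self.alphabet not in ("nt", "aa"):
            raise InvalidInputError(f"unknown alphabet {self.alphabet!r}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng) -> "SequenceAlignment":
        """Bootstrap replicate: columns drawn with replacement."""
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        mat = np.array([list(r) for r in self.rows])
        rows = tuple("".join(row) for row in mat[:, idx])
        return SequenceAlignment(self.ids, rows, self.alphabet)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with labels."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidInputError("distance matrix shape does not match labels")
        if np.any(self.values < 0):
            raise InvalidInputError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InvalidInputError("distance matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def p_distance_matrix(aln: SequenceAlignment, gap_policy: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites per pair.

    Sites containing a gap or an ambiguity character in either row are
    excluded ("pairwise" deletion, default); "complete" deletion drops any
    column with a gap/ambiguity in any row.  A pair with zero comparable
    sites is an error naming the pair.
    """
    valid_set = _NT_VALID if aln.alphabet == "nt" else _AA_VALID
    mat = np.array([list(r) for r in aln.rows])
    valid = np.isin(mat, sorted(valid_set))
    if gap_policy == "complete":
        keep = valid.all(axis=0)
        mat = mat[:, keep]
        valid = valid[:, keep]
    elif gap_policy != "pairwise":
        raise InvalidInputError(f"unknown gap_policy {gap_policy!r}")
    n = len(aln.ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise InvalidInputError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            diff = int((mat[i][both] != mat[j][both]).sum())
            out[i, j] = out[j, i] = diff / m
    return DistanceMatrix(list(aln.ids), out)


class Clade:
    """A node of a (possibly unrooted) tree."""

    __slots__ = ("name", "branch_length", "support", "children")

    def __init__(self, name=None, branch_length=None, support=None, children=None):
        self.name = name
        self.branch_length = branch_length
        self.support = support
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


class PhyloTree:
    """Unrooted tree held as a rooted structure with a trifurcating root.

    Branch lengths are non-negative (NJ clamps and flags negatives);
    internal-node ``support`` values are bootstrap percentages in [0, 100].
    """

    def __init__(self, root: Clade, flags: Optional[list] = None):
        self.root = root
        self.flags = flags if flags is not None else []

    @property
    def leaf_names(self) -> list:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> dict:
        """Map each internal edge to its bipartition.

        Keys are canonical frozensets: the side *not* containing the
        alphabetically smallest leaf label.  Values are the child clades
        below the edge.  Trivial (leaf) edges are excluded.
        """
        all_leaves = set(self.leaf_names)
        anchor = min(all_leaves)
        out = {}
        for clade in self.root.walk():
            if clade is self.root or clade.is_leaf:
                continue
            side = frozenset(leaf.name for leaf in clade.leaves())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            key = side if anchor not in side else frozenset(all_leaves - side)
            out[key] = clade
        return out

    def path_distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths induced by the branch lengths."""
        # build undirected adjacency
        adj = {}
        index = {}

        def visit(clade):
            index.setdefault(id(clade), clade)
            for child in clade.children:
                adj.setdefault(id(clade), []).append((id(child), child.branch_length or 0.0))
                adj.setdefault(id(child), []).append((id(clade), child.branch_length or 0.0))
                visit(child)

        visit(self.root)
        leaves = list(self.root.leaves())
        labels = [leaf.name for leaf in leaves]
        n = len(leaves)
        out = np.zeros((n, n))
        for i, leaf in enumerate(leaves):
            dist = {id(leaf): 0.0}
            stack = [id(leaf)]
            while stack:
                u = stack.pop()
                for v, w in adj.get(u, []):
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, other in enumerate(leaves):
                out[i, j] = dist[id(other)]
        out = (out + out.T) / 2
        np.fill_diagonal(out, 0.0)
        return DistanceMatrix(labels, out)

    def to_newick(self) -> str:
        return write_newick(self)


def _check_nj_input(d: DistanceMatrix) -> None:
    if len(d.labels) < 3:
        raise InvalidInputError("neighbor joining needs at least 3 taxa")


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.  See the module docstring for the
    criterion, tie-break and clamping conventions."""
    _check_nj_input(d)
    labels = list(d.labels)
    mat = d.values.copy()
    nodes = [Clade(name=label) for label in labels]
    keys = list(labels)  # smallest leaf label in each cluster, for tie-breaks
    flags = []

    def clamp(x):
        if x < 0:
            if x < -1e-12:
                if "negative_branch_clamped" not in flags:
                    flags.append("negative_branch_clamped")
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = mat.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * mat[i, j] - r[i] - r[j]
                tie_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = clamp(mat[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2)))
        lj = clamp(mat[i, j] - (mat[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))))
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent = Clade(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (mat[i] + mat[j] - mat[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        new_mat = np.zeros((len(keep) + 1, len(keep) + 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_row[keep]
        new_mat[:-1, -1] = new_row[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [min(keys[i], keys[j])]
        mat = new_mat

    # resolve the final three clusters on one internal node
    a, b, c = nodes
    dab, dac, dbc = mat[0, 1], mat[0, 2], mat[1, 2]
    a.branch_length = clamp((dab + dac - dbc) / 2)
    b.branch_length = clamp((dab + dbc - dac) / 2)
    c.branch_length = clamp((dac + dbc - dab) / 2)
    order = sorted(range(3), key=lambda x: keys[x])
    root = Clade(children=[nodes[x] for x in order])
    return PhyloTree(root, flags=flags)


def bootstrap_support(
    aln: SequenceAlignment,
    n_replicates: int = 500,
    seed: Optional[int] = None,
    gap_policy: str = "pairwise",
) -> PhyloTree:
    """NJ tree from the full alignment, with internal-node supports.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it.  Replicates whose
    distance computation fails (a pair with no comparable sites) are
    skipped with a warning and excluded from the denominator.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    tree = neighbor_joining(p_distance_matrix(aln, gap_policy))
    target = tree.bipartitions()
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(n_replicates):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(p_distance_matrix(rep, gap_policy))
        except InvalidInputError:
            skipped += 1
            continue
        rep_bips = set(rep_tree.bipartitions())
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    effective = n_replicates - skipped
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicates skipped", stacklevel=2)
    for key, clade in target.items():
        clade.support = 100.0 * counts[key] / max(effective, 1)
    tree.flags.append(f"bootstrap_replicates={effective}")
    return tree


def pairwise_global_identity(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    max_length: int = 100_000,
) -> float:
    """Percent identity from a global (Needleman-Wunsch) alignment.

    Identity is identical aligned positions divided by the alignment
    length, times 100.  Up to 10 kb the alignment uses affine-gap scoring
    (defaults above, penalties positive); longer inputs, up to
    ``max_length``, are aligned with edlib's linear-memory global aligner
    (unit costs) since the quadratic-memory affine aligner is not viable
    there.  Inputs beyond ``max_length`` are refused.
    """
    a = a.upper().replace("-", "")
    b = b.upper().replace("-", "")
    if not a or not b:
        raise InvalidInputError("sequences must be non-empty")
    if max(len(a), len(b)) > max_length:
        raise InvalidInputError(
            f"sequence longer than {max_length}; raise max_length only with "
            "the linear-memory route in mind, or align externally"
        )
    if max(len(a), len(b)) > 10_000:
        import edlib

        res = edlib.align(a, b, mode="NW", task="path")
        ops = {"=": 0, "X": 0, "I": 0, "D": 0, "M": 0}
        for num, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
            ops[op] += int(num)
        # edlib emits the extended cigar ('='/'X'); if a build emits plain
        # 'M' blocks instead, substitutions are recovered from the edit
        # distance (ed = X + I + D)
        substitutions = res["editDistance"] - ops["I"] - ops["D"] - ops["X"]
        matches = ops["="] + ops["M"] - max(0, substitutions)
        total = sum(ops.values())
        return 100.0 * matches / total
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignment = aligner.align(a, b)[0]
    s1, s2 = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return 100.0 * matches / len(s1)


# ---------------------------------------------------------------------------
# Newick

def _format_length(x: Optional[float]) -> str:
    if x is None:
        return ""
    return f":{x:.6g}"


def _write_clade(clade: Clade) -> str:
    if clade.is_leaf:
        return f"{clade.name}{_format_length(clade.branch_length)}"
    inner = ",".join(_write_clade(child) for child in clade.children)
    label = "" if clade.support is None else str(int(round(clade.support)))
    return f"({inner}){label}{_format_length(clade.branch_length)}"


def write_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths (6 significant figures) and integer
    bootstrap supports as internal-node labels."""
    return _write_clade(tree.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse Newick produced by :func:`write_newick` (labels, branch
    lengths, numeric internal labels read back as supports)."""
    text = text.strip()
    if not text.endswith(";"):
        raise InvalidInputError("Newick text must end with ';'")
    pos = 0

    def parse_clade():
        nonlocal pos
        clade = Clade()
        if text[pos] == "(":
            pos += 1
            while True:
                clade.children.append(parse_clade())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise InvalidInputError(f"malformed Newick near offset {pos}")
            label = _read_token()
            if label:
                try:
                    clade.support = float(label)
                except ValueError:
                    clade.name = label
        else:
            clade.name = _read_token()
        if pos < len(text) and text[pos] == ":":
            pos += 1
            token = _read_token()
            clade.branch_length = float(token)
        return clade

    def _read_token():
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        return text[start:pos]

    root = parse_clade()
    if pos >= len(text) or text[pos] != ";":
        raise InvalidInputError("trailing characters in Newick text")
    return PhyloTree(root)
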