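"""Probabilistic haplotype tree with dynamic branch merging and six-state branching.

A per-chromosome leveled tree encodes allele transitions between consecutive
SNPs.  Level j holds nodes labelled by the allele (A or B) carried at locus
j; branches carry the conditional probability C to each child and the joint
probability J of the corresponding two-locus haplotype.  Nodes whose forward
transition distributions are statistically indistinguishable are merged
(variable-length Markov chain construction), turning the tree into a leveled
DAG whose per-level width stays small.

After merging, each binary node is branched into the six allelic states
{A-, A, A+, B-, B, B+}: deletion, single copy and amplification of either
allele.  Copy-number persistence decays exponentially with inter-SNP
distance; a long normal stretch is far more likely than a long aberrant one,
so the normal and aberrant states use different decay scales (1e8 bp and
1e5 bp by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from itertools import count as _counter

import numpy as np

from .signal_io import GenotypeMatrix, SnpMap

__all__ = [
    "AllelicState",
    "DecayParams",
    "TreeNode",
    "HaplotypeTree",
    "BranchedTree",
    "allowed_transition",
    "allowed_transitions",
    "build_binary_tree",
    "similarity_score",
    "merge_threshold",
    "merge_nodes",
    "merge_level",
    "decay",
    "branch_aberrant",
]


class AllelicState(IntEnum):
    """Single-haplotype state at a SNP: allele identity x copy-number class."""

    A_MINUS = 0  # deletion of the A allele (0 copies)
    A = 1  # one normal copy of A
    A_PLUS = 2  # amplification of A (2 copies)
    B_MINUS = 3
    B = 4
    B_PLUS = 5


#: allele index (0=A, 1=B) of each state
STATE_ALLELE = np.array([0, 0, 0, 1, 1, 1])
#: copy-number class: 0=loss, 1=normal, 2=gain
STATE_CLASS = np.array([0, 1, 2, 0, 1, 2])
#: copies of the state's own allele carried by the haplotype
STATE_COPIES = np.array([0, 1, 2, 0, 1, 2])

STATE_NAMES = ("A-", "A", "A+", "B-", "B", "B+")


def allowed_transition(x: int, y: int) -> bool:
    """Whether allelic state ``x`` may transit to ``y`` at the next locus.

    Normal states transit anywhere; gains never meet losses at adjacent loci
    (in either order), since adjacent gain and loss events are assumed rare.
    """
    cx, cy = STATE_CLASS[x], STATE_CLASS[y]
    return not ((cx == 2 and cy == 0) or (cx == 0 and cy == 2))


def allowed_transitions() -> list[tuple[int, int]]:
    """Enumerate all allowed ordered state transitions (there are 28)."""
    return [(x, y) for x in range(6) for y in range(6) if allowed_transition(x, y)]


ALLOWED = np.array([[allowed_transition(x, y) for y in range(6)] for x in range(6)])


@dataclass
class DecayParams:
    """Distance scales (bp) of copy-number persistence along the chromosome."""

    d_norm: float = 1e8  # normal-state persistence scale
    d_var: float = 1e5  # aberrant-state persistence scale

    def __post_init__(self) -> None:
        if self.d_norm <= 0 or self.d_var <= 0:
            raise ValueError("decay scales must be positive")


def decay(d: float, D: float) -> float:
    """Persistence probability exp(-d/D) for inter-locus distance ``d`` bp."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return float(np.exp(-d / D))


# ---------------------------------------------------------------------------
# binary tree


@dataclass
class Branch:
    child: "TreeNode"
    c: float  # conditional probability parent -> child
    j: float  # joint probability of the two-locus haplotype


@dataclass
class TreeNode:
    """Node at one locus; ``label`` is '' for the root, else 'A' or 'B'."""

    locus: int
    label: str
    m: float  # expected haplotype count reaching this node
    children: list[Branch] = field(default_factory=list)
    uid: int = field(default_factory=_counter().__next__)

    def child_map(self) -> dict[str, Branch]:
        out: dict[str, Branch] = {}
        for br in self.children:
            if br.child.label in out:
                raise ValueError("duplicate child label on node")
            out[br.child.label] = br
        return out

    def check_rows(self, atol: float = 1e-9) -> None:
        if self.children:
            tot = sum(br.c for br in self.children)
            if abs(tot - 1.0) > atol:
                raise ValueError(f"outgoing C sums to {tot}, not 1")


@dataclass
class HaplotypeTree:
    """Leveled DAG: ``levels[0] = [root]``, ``levels[j]`` holds locus-j nodes."""

    levels: list[list[TreeNode]]
    total_haplotypes: float

    @property
    def root(self) -> TreeNode:
        return self.levels[0][0]

    @property
    def n_loci(self) -> int:
        return len(self.levels) - 1

    def level_width(self, locus: int) -> int:
        return len(self.levels[locus])

    def marginal_c(self, locus: int) -> np.ndarray:
        """Count-weighted 2x2 allele-transition table out of ``locus``.

        Aggregates the (possibly multi-context) nodes of one level into a
        single conditional table; exact when each label holds one node.
        """
        num = np.zeros((2, 2))
        den = np.zeros(2)
        for node in self.levels[locus]:
            x = 0 if node.label == "A" else 1
            den[x] += node.m
            for br in node.children:
                y = 0 if br.child.label == "A" else 1
                num[x, y] += node.m * br.c
        c = np.full((2, 2), 0.5)
        for x in range(2):
            if den[x] > 0:
                c[x] = num[x] / den[x]
        return c

    def level_marginals(self, locus: int) -> np.ndarray:
        """Allele frequencies (f_A, f_B) at ``locus`` from node counts."""
        f = np.zeros(2)
        for node in self.levels[locus]:
            f[0 if node.label == "A" else 1] += node.m
        tot = f.sum()
        return f / tot if tot > 0 else np.array([0.5, 0.5])

    def edge_list(self) -> list[tuple[int, int, int, str, float, float, float]]:
        """Debug dump: (level, parent uid, child uid, child label, C, J, M)."""
        rows = []
        for lv, nodes in enumerate(self.levels):
            for nd in nodes:
                for br in nd.children:
                    rows.append((lv, nd.uid, br.child.uid, br.child.label, br.c, br.j, nd.m))
        return rows


def build_binary_tree(genos: GenotypeMatrix, tables) -> HaplotypeTree:
    """Build the two-allele tree from per-pair conditional tables.

    Identical-history expansions are never materialized: because the branch
    probabilities come from pairwise tables, every same-label node at a level
    would have an identical forward distribution, so each level is created
    directly with (at most) one node per allele.  ``genos`` supplies the
    cohort size and the locus-1 allele frequencies; node counts M are
    propagated as expected haplotype counts 2N x path probability.
    """
    calls = genos.calls
    L, n_samples = calls.shape
    if len(tables) != L - 1:
        raise ValueError("need one conditional table per consecutive locus pair")
    total = 2.0 * n_samples
    # allele frequency at locus 1 from genotype codes (code-1 = #B alleles)
    fB = float((calls[0] - 1).sum()) / total
    marg = np.array([1.0 - fB, fB])
    return _tree_from_tables([t.c for t in tables], marg, total)


def _tree_from_tables(cs, first_marginal, total_haplotypes) -> HaplotypeTree:
    L = len(cs) + 1
    root = TreeNode(0, "", total_haplotypes)
    levels = [[root]]
    marg = np.asarray(first_marginal, dtype=float)
    prev = []
    for x, lab in enumerate("AB"):
        node = TreeNode(1, lab, total_haplotypes * marg[x])
        root.children.append(Branch(node, marg[x], marg[x]))
        prev.append(node)
    levels.append(prev)
    for j in range(1, L):
        c = np.asarray(cs[j - 1], dtype=float)
        marg_next = marg @ c
        nxt = [TreeNode(j + 1, lab, total_haplotypes * marg_next[y]) for y, lab in enumerate("AB")]
        for x, node in enumerate(prev):
            for y in range(2):
                node.children.append(Branch(nxt[y], c[x, y], marg[x] * c[x, y]))
        levels.append(nxt)
        prev, marg = nxt, marg_next
    return HaplotypeTree(levels, total_haplotypes)


# ---------------------------------------------------------------------------
# merging


def similarity_score(u: TreeNode, v: TreeNode) -> float:
    """Maximal |C_u - C_v| over parallel descendants of two same-locus nodes."""
    if u.locus != v.locus:
        raise ValueError("nodes must sit at the same locus")
    cu, cv = u.child_map(), v.child_map()
    if set(cu) != set(cv):
        raise ValueError("mismatched descendant sets")
    if not cu:
        return 0.0
    return max(abs(cu[k].c - cv[k].c) for k in cu)


def merge_threshold(mu: float, mv: float) -> float:
    """Similarity threshold sqrt(1/Mu + 1/Mv).

    Roughly twice the standard deviation of a difference of two observed
    transition proportions near 1/2 when the transition is purely random —
    pairs scoring below it are statistically indistinguishable.
    """
    if mu < 0 or mv < 0:
        raise ValueError("counts must be non-negative")
    if mu == 0 or mv == 0:
        warnings.warn("zero haplotype count: threshold set to +inf (always mergeable)")
        return float("inf")
    return float(np.sqrt(1.0 / mu + 1.0 / mv))


def _repoint(tree: HaplotypeTree, old_nodes, new_node) -> None:
    olds = {id(n) for n in old_nodes}
    if new_node.locus >= 1:
        for parent in tree.levels[new_node.locus - 1]:
            for br in parent.children:
                if id(br.child) in olds:
                    br.child = new_node


def merge_nodes(tree: HaplotypeTree, u: TreeNode, v: TreeNode) -> TreeNode:
    """Merge two same-locus nodes; descendants merge recursively in parallel.

    The merged node's conditional probabilities are the count-weighted
    average of the originals; joint probabilities are recomputed as the
    parent-path probability times C.
    """
    if u is v:
        return u
    cu, cv = u.child_map(), v.child_map()
    if set(cu) != set(cv):
        raise ValueError("cannot merge nodes with mismatched descendant sets")
    m = u.m + v.m
    wu = u.m / m if m > 0 else 0.5
    merged = TreeNode(u.locus, u.label or v.label, m)
    level = tree.levels[u.locus]
    level[level.index(u)] = merged
    level.remove(v)
    _repoint(tree, (u, v), merged)
    reach = m / tree.total_haplotypes if tree.total_haplotypes > 0 else 0.0
    for lab in sorted(cu):
        bu, bv = cu[lab], cv[lab]
        c = wu * bu.c + (1 - wu) * bv.c
        child = bu.child if bu.child is bv.child else merge_nodes(tree, bu.child, bv.child)
        merged.children.append(Branch(child, c, reach * c))
    return merged


def merge_level(tree: HaplotypeTree, locus: int) -> HaplotypeTree:
    """Greedy smallest-score-first merging of one level.

    Only same-label pairs are compared (the label is the allele the node
    emits and must survive the merge).  Scores and thresholds are recomputed
    after every merge; iteration stops when no pair scores below its
    threshold or one node per label remains.
    """
    if not 1 <= locus <= tree.n_loci:
        raise IndexError("no such level")
    while True:
        nodes = tree.levels[locus]
        best = None
        for i in range(len(nodes)):
            for k in range(i + 1, len(nodes)):
                u, v = nodes[i], nodes[k]
                if u.label != v.label:
                    continue
                s = similarity_score(u, v)
                if s < merge_threshold(u.m, v.m) and (best is None or s < best[0]):
                    best = (s, u, v)
        if best is None:
            return tree
        merge_nodes(tree, best[1], best[2])


def merge_tree(tree: HaplotypeTree) -> HaplotypeTree:
    """Merge every level sequentially from the first locus to the last."""
    for locus in range(1, tree.n_loci + 1):
        merge_level(tree, locus)
    return tree


# ---------------------------------------------------------------------------
# six-state branching


def _class_weights(rho_norm: float, rho_var: float) -> np.ndarray:
    """3x3 class-transition weights w[cls_from, cls_to]; rows sum to 1.

    From a normal state the persistent share rho_norm stays normal and the
    rest splits equally to gain and loss; from an aberrant state rho_var
    stays aberrant and the complement returns to normal; gain<->loss is
    forbidden.  Class order: 0=loss, 1=normal, 2=gain.
    """
    w = np.zeros((3, 3))
    w[1] = [(1 - rho_norm) / 2, rho_norm, (1 - rho_norm) / 2]
    w[2] = [0.0, 1 - rho_var, rho_var]
    w[0] = [rho_var, 1 - rho_var, 0.0]
    return w


def six_state_matrix(c: np.ndarray, d: float, params: DecayParams) -> np.ndarray:
    """Expand a binary 2x2 conditional table into the 6x6 allelic-state matrix.

    T[s, s'] = C[allele(s), allele(s')] * w[class(s), class(s')]; every row
    sums to 1 and forbidden gain<->loss entries are exactly 0.
    """
    w = _class_weights(decay(d, params.d_norm), decay(d, params.d_var))
    t = np.empty((6, 6))
    for s in range(6):
        for s2 in range(6):
            t[s, s2] = c[STATE_ALLELE[s], STATE_ALLELE[s2]] * w[STATE_CLASS[s], STATE_CLASS[s2]]
    return t


@dataclass
class BranchedTree:
    """Six-state expansion of a merged tree for one chromosome.

    Contexts of a level are aggregated by haplotype-count weights into one
    allele-transition table before expansion (exact for the width-2 trees
    the pairwise estimation produces), so the decoder consumes a per-locus
    6x6 transition matrix plus an initial six-state distribution.
    """

    log_init: np.ndarray  # (6,)
    log_trans: np.ndarray  # (L-1, 6, 6)
    params: DecayParams

    @property
    def n_loci(self) -> int:
        return self.log_trans.shape[0] + 1

    def transition_matrix(self, j: int) -> np.ndarray:
        """Probability-scale 6x6 matrix for the step from locus j to j+1."""
        return np.exp(self.log_trans[j])


def branch_aberrant(
    tree: HaplotypeTree, snpmap: SnpMap, params: DecayParams | None = None
) -> BranchedTree:
    """Branch a merged binary tree into the six allelic states.

    ``snpmap`` supplies inter-locus distances (must cover exactly the tree's
    loci on a single chromosome).  The prior over copy-number classes at the
    first locus uses the chromosome's mean inter-SNP spacing as the distance
    argument of the normal-state decay.
    """
    params = params or DecayParams()
    L = tree.n_loci
    if len(snpmap) != L:
        raise ValueError("SNP map length must equal the tree's locus count")
    if len(set(snpmap.chrom)) > 1:
        raise ValueError("branching operates on a single chromosome")
    dists = np.diff(snpmap.pos).astype(float)
    log_trans = np.empty((L - 1, 6, 6))
    with np.errstate(divide="ignore"):
        for j in range(L - 1):
            log_trans[j] = np.log(six_state_matrix(tree.marginal_c(j + 1), dists[j], params))
        d_bar = float(dists.mean()) if L > 1 else params.d_var
        rho0 = decay(d_bar, params.d_norm)
        f = tree.level_marginals(1)
        cls_prior = np.array([(1 - rho0) / 2, rho0, (1 - rho0) / 2])
        init = np.array([f[STATE_ALLELE[s]] * cls_prior[STATE_CLASS[s]] for s in range(6)])
        log_init = np.log(init)
    return BranchedTree(log_init, log_trans, params)
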