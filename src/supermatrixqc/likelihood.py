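"""Small-scale amino-acid phylogenetic likelihood engine.

Implements Felsenstein pruning under the empirical models in
:mod:`supermatrixqc.models` with discrete-gamma rate mixtures, pairwise ML
distances, neighbor-joining starting trees, branch-length optimisation with
cached partials, NNI hill-climbing (optionally respecting a monophyly
constraint) and sequence simulation along a tree (the Seq-Gen role).

Trees cross the module boundary as dendropy trees or Newick strings; the
engine works on a private mutable node structure (:class:`LTree`) so NNI
rearrangements and partial-likelihood caching stay cheap.

Gaps and ``X`` are treated as fully ambiguous.  Identical alignment
columns are collapsed to weighted site patterns before any likelihood is
computed.

Branch-length optimisation visits edges in preorder, maintaining exact
"up" messages, so every one-branch optimisation is performed against the
true current likelihood surface and the per-sweep log-likelihood sequence
is non-decreasing (up to the scalar optimiser's tolerance).
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .align import (
    AA_ORDER,
    AlignedOrthogroup,
    MISSING_CODE,
    Record,
    decode_codes,
)
from .models import N_STATES, SubstitutionModel

_MIN_BL = 1e-9
_MAX_BL = 50.0
_TINY = 1e-300


# ---------------------------------------------------------------------------
# Internal tree structure
# ---------------------------------------------------------------------------

class _LNode:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label=None, length=0.0):
        self.children: list["_LNode"] = []
        self.parent: "_LNode | None" = None
        self.label = label
        self.length = length

    def add(self, child: "_LNode") -> "_LNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class LTree:
    """Rooted view of a (possibly unrooted) tree; the root may trifurcate."""

    def __init__(self, root: _LNode):
        self.root = root

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "LTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "LTree":
        def build(dnode):
            label = dnode.taxon.label if dnode.taxon is not None else None
            node = _LNode(label=label, length=dnode.edge.length or 0.0)
            for ch in dnode.child_nodes():
                node.add(build(ch))
            return node

        root = build(tree.seed_node)
        root.length = 0.0
        # suppress unifurcations (e.g. rooted newick with a knee at the root)
        while len(root.children) == 1 and root.children[0].children:
            child = root.children[0]
            for g in child.children:
                g.length += 0.0
            child.parent = None
            child.length = 0.0
            root = child
        return cls(root)

    @classmethod
    def coerce(cls, tree) -> "LTree":
        if isinstance(tree, LTree):
            return tree
        if isinstance(tree, dendropy.Tree):
            return cls.from_dendropy(tree)
        if isinstance(tree, str):
            return cls.from_newick(tree)
        raise TypeError(f"cannot interpret {type(tree).__name__} as a tree")

    def to_newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                core = _quote(node.label)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is None:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 taxon_namespace=taxon_namespace,
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)

    def copy(self) -> "LTree":
        def dup(node):
            n = _LNode(label=node.label, length=node.length)
            for c in node.children:
                n.add(dup(c))
            return n

        return LTree(dup(self.root))

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> list[_LNode]:
        out: list[_LNode] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or node.is_leaf:
                out.append(node)
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in node.children)
        return out

    def leaves(self) -> list[_LNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def below(self) -> dict[_LNode, frozenset]:
        """Leaf-label set below each node."""
        out: dict[_LNode, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.label])
            else:
                acc: set = set()
                for c in node.children:
                    acc |= out[c]
                out[node] = frozenset(acc)
        return out

    def splits(self) -> set[frozenset]:
        """Leaf-sets below every non-root node (one side of each edge)."""
        below = self.below()
        return {below[n] for n in below if n.parent is not None}

    def is_monophyletic(self, taxa) -> bool:
        """True iff some edge of the unrooted tree splits exactly ``taxa`` off."""
        taxa = frozenset(taxa)
        all_leaves = frozenset(self.leaf_labels())
        if not taxa <= all_leaves:
            raise ValueError("constraint taxa missing from tree")
        if taxa == all_leaves:
            return True
        comp = all_leaves - taxa
        return any(s == taxa or s == comp for s in self.splits())

    def scale_edges(self, factor: float) -> None:
        for n in self.postorder():
            if n.parent is not None:
                n.length *= factor


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Alignment access
# ---------------------------------------------------------------------------

def _codes_and_ids(alignment) -> tuple[np.ndarray, list[str], list[str]]:
    """(codes, sequence_ids, taxon_ids) for an orthogroup or supermatrix."""
    if hasattr(alignment, "records"):  # AlignedOrthogroup
        codes = alignment.codes()
        return codes, [r.sequence_id for r in alignment.records], \
            [r.taxon_id for r in alignment.records]
    if hasattr(alignment, "rows") and hasattr(alignment, "taxa"):  # Supermatrix
        from .align import encode_residues

        codes = np.vstack([encode_residues(row) for row in alignment.rows])
        return codes, list(alignment.taxa), list(alignment.taxa)
    raise TypeError("alignment must be an AlignedOrthogroup or Supermatrix")


def _row_for_leaf(label: str, seq_ids: list[str], taxon_ids: list[str]) -> int:
    try:
        return seq_ids.index(label)
    except ValueError:
        pass
    hits = [i for i, t in enumerate(taxon_ids) if t == label]
    if len(hits) == 1:
        return hits[0]
    raise ValueError(f"tree leaf {label!r} has no unique matching alignment row")


def _compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns: (patterns ``n_rows x n_pat``, weights)."""
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

class TreeLikelihood:
    """Pruning-algorithm likelihood for one tree/alignment/model triple.

    Owns a private copy of the tree; retrieve optimised trees via
    :attr:`tree` / :meth:`newick`.
    """

    def __init__(self, tree, alignment, model: SubstitutionModel,
                 compress: bool = True):
        self.tree = LTree.coerce(tree).copy() if isinstance(tree, LTree) else LTree.coerce(tree)
        self.model = model
        codes, seq_ids, taxon_ids = _codes_and_ids(alignment)

        leaves = self.tree.leaves()
        leaf_set = {n.label for n in leaves}
        align_ids = set(seq_ids) if len(set(seq_ids)) == len(seq_ids) else set(taxon_ids)
        if leaf_set != align_ids and leaf_set != set(taxon_ids):
            missing = leaf_set.symmetric_difference(align_ids)
            raise ValueError(f"tree leaves and alignment rows differ: {sorted(missing)[:5]}")

        order = [_row_for_leaf(n.label, seq_ids, taxon_ids) for n in leaves]
        mat = codes[order]
        if compress:
            self.patterns, self.weights = _compress(mat)
        else:
            self.patterns = mat
            self.weights = np.ones(mat.shape[1])
        self.n_patterns = self.patterns.shape[1]
        self.rates, self.cat_weights = model.rate_categories()
        self.n_cats = len(self.rates)

        eye = np.eye(N_STATES + 1, N_STATES)  # row 20 (missing) -> all ones
        eye[N_STATES] = 1.0
        self._leaf_partial = {
            leaf: np.ascontiguousarray(eye[self.patterns[i]].T)  # (20, n_pat)
            for i, leaf in enumerate(leaves)
        }
        self._D: dict = {}       # node -> (ncat, 20, npat) conditionals below node
        self._SD: dict = {}      # node -> (npat,) log scaling of D
        self._PD: dict = {}      # node -> P(t_node) @ D[node]
        self.converged = True

    # -- basic quantities ---------------------------------------------------
    def _pmats(self, t: float) -> np.ndarray:
        return np.stack([self.model.transition_matrix(t * r) for r in self.rates])

    def _set_pd(self, node) -> None:
        p = self._pmats(node.length)
        self._PD[node] = np.einsum("cij,cjp->cip", p, self._D[node])

    def _compute_down(self) -> None:
        for node in self.tree.postorder():
            if node.is_leaf:
                self._D[node] = np.broadcast_to(
                    self._leaf_partial[node], (self.n_cats, N_STATES, self.n_patterns))
                self._SD[node] = np.zeros(self.n_patterns)
            else:
                acc = None
                scale = np.zeros(self.n_patterns)
                for c in node.children:
                    acc = self._PD[c] if acc is None else acc * self._PD[c]
                    scale += self._SD[c]
                mx = np.maximum(acc.max(axis=(0, 1)), _TINY)
                self._D[node] = acc / mx
                self._SD[node] = scale + np.log(mx)
            if node.parent is not None:
                self._set_pd(node)

    def lnl(self) -> float:
        """Total log-likelihood (recomputed from scratch)."""
        self._compute_down()
        root = self.tree.root
        pi = self.model.frequencies
        site = np.einsum("c,i,cip->p", self.cat_weights, pi, self._D[root])
        return float(np.dot(self.weights, np.log(np.maximum(site, _TINY)) + self._SD[root]))

    # -- one-branch optimisation --------------------------------------------
    def _edge_lnl_fn(self, U, SU, D, SD):
        w, cw, rates = self.weights, self.cat_weights, self.rates
        base = SU + SD

        def f(t):
            site = np.zeros(self.n_patterns)
            for c in range(self.n_cats):
                p = self.model.transition_matrix(t * rates[c])
                site += cw[c] * np.einsum("ip,ip->p", U[c], p @ D[c])
            return -float(np.dot(w, np.log(np.maximum(site, _TINY)) + base))

        return f

    @staticmethod
    def _brent(f, t0, xatol):
        res = minimize_scalar(f, bounds=(_MIN_BL, _MAX_BL), method="bounded",
                              options={"xatol": xatol})
        t_new, f_new = float(res.x), float(res.fun)
        f_old = f(t0)
        return (t_new, f_new) if f_new <= f_old else (t0, f_old)

    def _optimize_sweep(self, xatol: float) -> float:
        """One exact preorder sweep of per-branch optimisation; returns lnL."""
        self._compute_down()
        pi = self.model.frequencies
        last = [None]

        def process(node, A, SA):
            for v in node.children:
                U = A.copy()
                SU = SA.copy()
                for s in node.children:
                    if s is not v:
                        U = U * self._PD[s]
                        SU = SU + self._SD[s]
                mx = np.maximum(U.max(axis=(0, 1)), _TINY)
                U /= mx
                SU = SU + np.log(mx)
                f = self._edge_lnl_fn(U, SU, self._D[v], self._SD[v])
                t_new, f_new = self._brent(f, v.length, xatol)
                v.length = t_new
                last[0] = -f_new
                self._set_pd(v)
                if not v.is_leaf:
                    p = self._pmats(v.length)
                    M = np.einsum("cij,cip->cjp", p, U)
                    process(v, M, SU)

        root = self.tree.root
        A0 = np.broadcast_to(pi[None, :, None],
                             (self.n_cats, N_STATES, self.n_patterns)).copy()
        process(root, A0, np.zeros(self.n_patterns))
        return last[0]

    def optimize_branch_lengths(self, tol: float = 1e-4, max_sweeps: int = 20,
                                xatol: float = 1e-6) -> float:
        """Iterate one-branch optimisation sweeps until lnL gain < ``tol``."""
        prev = self.lnl()
        self.converged = False
        for _ in range(max_sweeps):
            cur = self._optimize_sweep(xatol)
            if cur - prev < tol:
                self.converged = True
                prev = max(cur, prev)
                break
            prev = cur
        if not self.converged:
            warnings.warn("branch-length optimisation did not converge", RuntimeWarning)
        return prev

    # -- NNI ------------------------------------------------------------------
    def _compute_up_messages(self) -> tuple[dict, dict]:
        """Message into each node from outside its subtree (with pi absorbed)."""
        pi = self.model.frequencies
        M = {self.tree.root: np.broadcast_to(
            pi[None, :, None], (self.n_cats, N_STATES, self.n_patterns))}
        SM = {self.tree.root: np.zeros(self.n_patterns)}
        stack = [self.tree.root]
        while stack:
            node = stack.pop()
            for v in node.children:
                if v.is_leaf:
                    continue
                U = M[node].copy()
                SU = SM[node].copy()
                for s in node.children:
                    if s is not v:
                        U = U * self._PD[s]
                        SU = SU + self._SD[s]
                p = self._pmats(v.length)
                Mv = np.einsum("cij,cip->cjp", p, U)
                mx = np.maximum(Mv.max(axis=(0, 1)), _TINY)
                M[v] = Mv / mx
                SM[v] = SU + np.log(mx)
                stack.append(v)
        return M, SM

    def _nni_moves(self):
        """Yield candidate swaps (v, x, s): swap child ``x`` of ``v`` with
        p-side subtree ``s`` across the internal edge above ``v``."""
        for v in self.tree.postorder():
            p = v.parent
            if p is None or v.is_leaf or len(v.children) != 2:
                continue
            a, b = v.children
            if p is self.tree.root:
                others = [c for c in p.children if c is not v]
                for s in others:
                    yield v, a, s
                if len(others) == 1:
                    yield v, b, others[0]
            else:
                sibs = [c for c in p.children if c is not v]
                if len(sibs) != 1:
                    continue
                yield v, a, sibs[0]
                yield v, b, sibs[0]

    def _screen_nni(self, constraint=None, xatol: float = 1e-3):
        """Score all NNI moves by optimising only the central edge."""
        self._compute_down()
        M, SM = self._compute_up_messages()
        below = self.tree.below()
        all_leaves = frozenset(self.tree.leaf_labels())
        cset = frozenset(constraint) if constraint else None
        ccomp = all_leaves - cset if cset else None
        best = None
        for v, x, s in self._nni_moves():
            p = v.parent
            if cset is not None:
                new_below = (below[v] - below[x]) | below[s]
                ok = new_below in (cset, ccomp) or any(
                    below[n] in (cset, ccomp)
                    for n in below if n.parent is not None and n is not v)
                if not ok:
                    continue
            o = v.children[0] if v.children[1] is x else v.children[1]
            A = M[p].copy()
            SA = SM[p].copy()
            for c in p.children:
                if c is not v and c is not s:
                    A = A * self._PD[c]
                    SA = SA + self._SD[c]
            U = A * self._PD[x]
            SU = SA + self._SD[x]
            mx = np.maximum(U.max(axis=(0, 1)), _TINY)
            U /= mx
            SU = SU + np.log(mx)
            D_inner = self._PD[s] * self._PD[o]
            SD_inner = self._SD[s] + self._SD[o]
            f = self._edge_lnl_fn(U, SU, D_inner, SD_inner)
            t_new, f_new = self._brent(f, v.length, xatol)
            score = -f_new
            if best is None or score > best[0]:
                best = (score, v, x, s, t_new)
        return best

    def _apply_nni(self, v, x, s, t_central: float) -> None:
        p = v.parent
        v.children[v.children.index(x)] = s
        p.children[p.children.index(s)] = x
        s.parent, x.parent = v, p
        v.length = t_central
        # cached partials for v's ancestry are now stale; callers re-sweep

    def nni_search(self, constraint=None, tol: float = 1e-3,
                   max_rounds: int = 50, xatol: float = 1e-6) -> float:
        """NNI hill-climbing with per-round branch re-optimisation."""
        cur = self.optimize_branch_lengths(tol=tol, xatol=xatol, max_sweeps=8)
        for _ in range(max_rounds):
            cand = self._screen_nni(constraint=constraint)
            if cand is None or cand[0] <= cur + tol:
                break
            _, v, x, s, t_c = cand
            self._apply_nni(v, x, s, t_c)
            cur = self.optimize_branch_lengths(tol=tol, xatol=xatol, max_sweeps=8)
        return cur

    def newick(self) -> str:
        return self.tree.to_newick()


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def log_likelihood(tree, alignment, model: SubstitutionModel,
                   compress: bool = True) -> float:
    """Log-likelihood of ``alignment`` on ``tree`` under ``model``."""
    return TreeLikelihood(tree, alignment, model, compress=compress).lnl()


def estimate_distances(alignment, model: SubstitutionModel,
                       max_distance: float = 10.0):
    """Pairwise ML distances by 1-D optimisation of two-sequence likelihoods.

    Returns ``(ids, matrix)``.  Pairs with no shared unambiguous site get the
    cap ``max_distance`` with a warning.
    """
    codes, seq_ids, _ = _codes_and_ids(alignment)
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    pi = model.frequencies
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = (codes[i] < MISSING_CODE) & (codes[j] < MISSING_CODE)
            if not mask.any():
                warnings.warn(f"no shared sites for pair ({seq_ids[i]}, {seq_ids[j]}); "
                              "distance capped", RuntimeWarning)
                d[i, j] = d[j, i] = max_distance
                continue
            counts = np.zeros((N_STATES, N_STATES))
            np.add.at(counts, (codes[i][mask], codes[j][mask]), 1.0)
            if np.trace(counts) == mask.sum():
                continue  # identical over shared sites -> 0

            def neg(t, counts=counts):
                p = np.maximum(model.transition_matrix(t), _TINY)
                return -float(np.sum(counts * np.log(pi[:, None] * p)))

            res = minimize_scalar(neg, bounds=(_MIN_BL, max_distance),
                                  method="bounded", options={"xatol": 1e-8})
            d[i, j] = d[j, i] = min(float(res.x), max_distance)
    return seq_ids, d


def nj_tree(ids, distances) -> dendropy.Tree:
    """Neighbor-joining tree (scikit-bio), negative branch lengths clamped."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as _sk_nj

    dm = DistanceMatrix(np.asarray(distances, dtype=float), ids=list(ids))
    newick = str(_sk_nj(dm))
    tree = LTree.from_newick(newick)
    for node in tree.postorder():
        if node.parent is not None and node.length < 0:
            node.length = 0.0
    return tree.to_dendropy()


def optimize_branch_lengths(tree, alignment, model: SubstitutionModel,
                            tol: float = 1e-4, max_sweeps: int = 20):
    """Optimise branch lengths on a fixed topology; returns ``(tree, lnL)``."""
    tl = TreeLikelihood(tree, alignment, model)
    lnl = tl.optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps)
    return tl.tree.to_dendropy(), lnl


def _constrained_start(ids, d, constraint: frozenset) -> LTree:
    """NJ start tree with ``constraint`` grafted as a clade."""
    ids = list(ids)
    idx = {t: i for i, t in enumerate(ids)}
    cons = [t for t in ids if t in constraint]
    rest = [t for t in ids if t not in constraint]
    if len(cons) < 2:
        raise ValueError("constraint needs at least 2 taxa")
    if not rest:
        raise ValueError("constraint covers all taxa; nothing to test")

    # subtree over the constrained taxa, rooted where the outside attaches
    if len(cons) == 2:
        sub_root = _LNode()
        t = d[idx[cons[0]], idx[cons[1]]] / 2.0
        sub_root.add(_LNode(label=cons[0], length=max(t, _MIN_BL)))
        sub_root.add(_LNode(label=cons[1], length=max(t, _MIN_BL)))
    else:
        ph = "smqc.outside"
        sub_ids = cons + [ph]
        m = np.zeros((len(sub_ids), len(sub_ids)))
        for i, a in enumerate(cons):
            for j, b in enumerate(cons):
                m[i, j] = d[idx[a], idx[b]]
            m[i, -1] = m[-1, i] = np.mean([d[idx[a], idx[r]] for r in rest])
        sub = LTree.from_dendropy(nj_tree(sub_ids, m))
        sub_root = _reroot_at_leaf_parent(sub, ph)

    if len(rest) == 1:
        root = _LNode()
        root.add(_LNode(label=rest[0], length=_MIN_BL))
        sub_root.length = _MIN_BL
        root.add(sub_root)
        return LTree(root)
    ph = "smqc.clade"
    out_ids = rest + [ph]
    m = np.zeros((len(out_ids), len(out_ids)))
    for i, a in enumerate(rest):
        for j, b in enumerate(rest):
            m[i, j] = d[idx[a], idx[b]]
        m[i, -1] = m[-1, i] = np.mean([d[idx[a], idx[c]] for c in cons])
    host = LTree.from_dendropy(nj_tree(out_ids, m))
    for node in host.postorder():
        if node.is_leaf and node.label == ph:
            sub_root.length = max(node.length, _MIN_BL)
            sub_root.parent = node.parent
            node.parent.children[node.parent.children.index(node)] = sub_root
            break
    return host


def _reroot_at_leaf_parent(tree: LTree, leaf_label: str) -> _LNode:
    """Remove ``leaf_label`` and return the tree re-rooted at its attachment."""
    target = next(n for n in tree.postorder() if n.is_leaf and n.label == leaf_label)
    parent = target.parent
    parent.children.remove(target)
    # re-hang the tree from `parent`
    path = []
    node = parent
    while node is not None:
        path.append(node)
        node = node.parent
    for child, par in zip(path[:-1], path[1:]):
        par.children.remove(child)
        child.add(par)
        par.length = child.length
    parent.parent = None
    parent.length = 0.0
    # suppress a possible unifurcation left at the old root
    stack = [parent]
    while stack:
        nd = stack.pop()
        for c in list(nd.children):
            if len(c.children) == 1:
                g = c.children[0]
                g.length += c.length
                g.parent = nd
                nd.children[nd.children.index(c)] = g
                stack.append(nd)
            else:
                stack.append(c)
    return parent


def ml_search(alignment, model: SubstitutionModel, constraint=None,
              tol: float = 1e-3, starting_tree=None):
    """ML tree search: NJ start, then constraint-respecting NNI hill-climbing.

    Returns ``(dendropy.Tree, lnL)``.  With ``constraint`` (an iterable of
    taxon labels required to be monophyletic) the start tree is built with
    the constrained taxa grafted as a clade and NNI moves breaking the
    constraint are rejected.
    """
    codes, seq_ids, taxon_ids = _codes_and_ids(alignment)
    n = codes.shape[0]
    if n < 4:
        raise ValueError("tree search needs at least 4 sequences")
    cset = frozenset(constraint) if constraint is not None else None
    if cset is not None and not cset <= set(seq_ids) | set(taxon_ids):
        raise ValueError("constraint taxa missing from alignment")

    if starting_tree is not None:
        start = LTree.coerce(starting_tree)
    else:
        ids, d = estimate_distances(alignment, model)
        if cset is None:
            start = LTree.from_dendropy(nj_tree(ids, d))
        else:
            start = LTree.from_dendropy(nj_tree(ids, d))
            if not start.is_monophyletic(cset):
                start = _constrained_start(ids, d, cset)
    if cset is not None and not start.is_monophyletic(cset):
        raise RuntimeError("failed to build a constraint-compatible start tree")

    tl = TreeLikelihood(start, alignment, model)
    lnl = tl.nni_search(constraint=cset, tol=tol)
    if cset is not None and not tl.tree.is_monophyletic(cset):
        raise AssertionError("search left the constraint region")  # pragma: no cover
    return tl.tree.to_dendropy(), lnl


def select_model(alignment, candidates: list[SubstitutionModel]) -> str:
    """Best-fitting model by lnL on a shared NJ tree, branch lengths
    re-optimised per candidate; ties break by candidate order."""
    if not candidates:
        raise ValueError("empty candidate list")
    if len(candidates) == 1:
        return candidates[0].name
    ids, d = estimate_distances(alignment, candidates[0])
    base = LTree.from_dendropy(nj_tree(ids, d))
    best_name, best_lnl = None, -np.inf
    for cand in candidates:
        tl = TreeLikelihood(base.copy(), alignment, cand)
        lnl = tl.optimize_branch_lengths(tol=1e-3, max_sweeps=10)
        if lnl > best_lnl + 1e-9:
            best_name, best_lnl = cand.name, lnl
    return best_name


def simulate_along_tree(tree, model: SubstitutionModel, length: int, seed: int,
                        locus_id: str = "locus",
                        rate_multipliers: dict[str, float] | None = None,
                        taxon_models: dict[str, SubstitutionModel] | None = None,
                        delimiter: str = "|") -> AlignedOrthogroup:
    """Simulate an alignment along ``tree`` under ``model`` (Seq-Gen role).

    Root states draw from the equilibrium frequencies; each site draws a
    gamma rate category once and keeps it across the tree.  Pendant-edge
    evolution for taxa listed in ``rate_multipliers`` is accelerated by the
    given factor; taxa in ``taxon_models`` evolve their pendant edge under a
    substituted model (used for compositional bias).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    lt = LTree.coerce(tree)
    rng = np.random.default_rng(seed)
    rates, cat_w = model.rate_categories()
    cats = rng.choice(len(rates), size=length, p=cat_w)
    states = {lt.root: rng.choice(N_STATES, size=length, p=model.frequencies)}
    rate_multipliers = rate_multipliers or {}
    taxon_models = taxon_models or {}

    stack = [lt.root]
    order: list[_LNode] = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(node.children)
    for node in order:
        if node.parent is None:
            continue
        parent_states = states[node.parent]
        t = node.length
        mdl = model
        if node.is_leaf:
            taxon = node.label.split(delimiter, 1)[0]
            t *= rate_multipliers.get(taxon, 1.0)
            mdl = taxon_models.get(taxon, model)
        child = np.empty(length, dtype=np.int64)
        u = rng.random(length)
        for c in range(len(rates)):
            sel = cats == c
            if not sel.any():
                continue
            p = mdl.transition_matrix(t * rates[c])
            cum = np.cumsum(p, axis=1)
            cum[:, -1] = 1.0
            rows = cum[parent_states[sel]]
            child[sel] = (rows < u[sel, None]).sum(axis=1)
        states[node] = child

    records = [
        Record(leaf.label.split(delimiter, 1)[0], leaf.label, decode_codes(states[leaf]))
        for leaf in lt.leaves()
    ]
    return AlignedOrthogroup(locus_id, records)
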