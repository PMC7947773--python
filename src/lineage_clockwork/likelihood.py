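"""Kimura two-parameter likelihood machinery for rooted binary trees.

Implements Felsenstein's pruning algorithm under the K2P substitution model
(equal base frequencies, transition/transversion rate ratio ``kappa``), with:

* per-pattern scaling so large trees do not underflow;
* optional conditioning on site variability (an ascertainment correction for
  alignments that, by construction, contain variable sites only);
* fast coordinate-ascent optimization of free branch lengths and of node
  heights under an ultrametric (molecular-clock) constraint, using cached
  upward/downward conditional likelihoods so that each one-dimensional
  optimization costs O(patterns) rather than a full tree traversal.

Base encoding: A=0, C=1, G=2, T=3, missing=4. Transitions are A<->G, C<->T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import Node, postorder

MISSING = 4
BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T

_BL_MAX = 10.0
_TINY = 1e-300

_M_SAME = np.eye(4)
_M_TS = np.zeros((4, 4))
for _a in range(4):
    _M_TS[_a, TS_PARTNER[_a]] = 1.0
_M_TV = 1.0 - _M_SAME - _M_TS


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def k2p_transition_matrices(t: np.ndarray, kappa: float) -> np.ndarray:
    """K2P transition probability matrices for branch lengths ``t``.

    ``t`` is in expected substitutions per site; the rate matrix is normalized
    so the total substitution rate is 1 (alpha + 2*beta = 1 with
    alpha/beta = kappa).

    Returns an array of shape ``t.shape + (4, 4)``.
    """
    t = np.asarray(t, dtype=float)
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = np.exp(-4.0 * beta * t)
    e_ts = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e_tv + 0.5 * e_ts
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv
    return (
        p_same[..., None, None] * _M_SAME
        + p_ts[..., None, None] * _M_TS
        + p_tv[..., None, None] * _M_TV
    )


# ---------------------------------------------------------------------------
# Tree flattening
# ---------------------------------------------------------------------------

@dataclass
class TreeArrays:
    """Flat, index-based view of a rooted binary tree.

    Tips have indices ``0..n_tips-1`` in ``tip_names`` order; internal nodes
    follow in postorder, the root last.
    """

    n_tips: int
    tip_names: list[str]
    children: np.ndarray      # (n_nodes, 2); -1 for tips
    parent: np.ndarray        # (n_nodes,); -1 for root
    blen: np.ndarray          # (n_nodes,) length of edge above node
    post: np.ndarray = field(init=False)  # internal node indices, postorder

    def __post_init__(self) -> None:
        self.post = np.array(
            [i for i in range(self.n_nodes) if self.children[i, 0] >= 0], dtype=int
        )

    @property
    def n_nodes(self) -> int:
        return self.children.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def heights_from_blens(self) -> np.ndarray:
        """Max node-to-tip path length per node (a valid clock initialization)."""
        h = np.zeros(self.n_nodes)
        for v in self.post:
            a, b = self.children[v]
            h[v] = max(h[a] + self.blen[a], h[b] + self.blen[b])
        return h

    def blens_from_heights(self, h: np.ndarray) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        bl[mask] = h[self.parent[mask]] - h[np.where(mask)[0]]
        return np.maximum(bl, 0.0)


def tree_to_arrays(root: Node, tip_names: list[str] | None = None) -> TreeArrays:
    """Flatten a rooted binary tree into :class:`TreeArrays`."""
    nodes = list(postorder(root))
    tip_nodes = [n for n in nodes if n.is_tip]
    if tip_names is None:
        tip_names = [t.name for t in tip_nodes]
    name_to_idx = {name: i for i, name in enumerate(tip_names)}
    if len(name_to_idx) != len(tip_names):
        raise ValueError("duplicate tip names")
    n_tips = len(tip_nodes)
    internals = [n for n in nodes if not n.is_tip]
    idx: dict[int, int] = {}
    for t in tip_nodes:
        if t.name not in name_to_idx:
            raise ValueError(f"tip {t.name!r} absent from tip_names")
        idx[id(t)] = name_to_idx[t.name]
    for k, n in enumerate(internals):
        idx[id(n)] = n_tips + k
    n_nodes = n_tips + len(internals)
    children = np.full((n_nodes, 2), -1, dtype=int)
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    for n in nodes:
        i = idx[id(n)]
        blen[i] = n.length
        if n.children:
            if len(n.children) != 2:
                raise ValueError("tree must be binary")
            children[i] = [idx[id(c)] for c in n.children]
            for c in n.children:
                parent[idx[id(c)]] = i
    if parent[n_nodes - 1] != -1:
        raise ValueError("root must be the last postorder node")
    return TreeArrays(n_tips, list(tip_names), children, parent, blen)


# ---------------------------------------------------------------------------
# Site patterns
# ---------------------------------------------------------------------------

def compress_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.

    Parameters
    ----------
    matrix : (n_samples, n_sites) uint8
        Encoded alignment (0..3, 4=missing).

    Returns
    -------
    patterns : (n_patterns, n_samples) uint8
    counts : (n_patterns,) float
    """
    pats, counts = np.unique(matrix.T, axis=0, return_counts=True)
    return pats.astype(np.uint8), counts.astype(float)


def _augment_constant(patterns: np.ndarray, counts: np.ndarray):
    """Append the four monomorphic patterns (count 0) for ascertainment."""
    n = patterns.shape[1]
    const = np.repeat(np.arange(4, dtype=np.uint8)[:, None], n, axis=1)
    return np.vstack([patterns, const]), np.concatenate([counts, np.zeros(4)])


def tip_partials(patterns: np.ndarray) -> np.ndarray:
    """One-hot tip conditional likelihoods; missing bases are all-ones."""
    m, n_tips = patterns.shape
    part = np.zeros((n_tips, m, 4))
    for s in range(4):
        part[:, :, s] = (patterns.T == s) | (patterns.T == MISSING)
    return part


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Pruning likelihood and branch-length optimization on a fixed topology.

    Holds the compressed site patterns and (optionally) the four constant
    patterns used for the variable-sites ascertainment correction, plus
    reusable buffers for downward/upward conditional likelihoods.
    """

    def __init__(
        self,
        arr: TreeArrays,
        patterns: np.ndarray,
        counts: np.ndarray,
        ascertainment: bool = False,
    ):
        if patterns.shape[1] != arr.n_tips:
            raise ValueError("pattern width does not match tip count")
        self.arr = arr
        self.ascertainment = ascertainment
        if ascertainment:
            patterns, counts = _augment_constant(patterns, counts)
        self.patterns = patterns
        self.counts = counts
        self.n_sites = float(counts.sum())
        self.m = patterns.shape[0]
        self.tip_part = tip_partials(patterns)
        n = arr.n_nodes
        self.down = np.empty((n, self.m, 4))
        self.dlog = np.zeros((n, self.m))
        self.down[: arr.n_tips] = self.tip_part

    # -- core passes -------------------------------------------------------

    def _pmats(self, blens: np.ndarray, kappa: float) -> np.ndarray:
        return k2p_transition_matrices(blens, kappa)

    def down_pass(self, blens: np.ndarray, kappa: float) -> None:
        P = self._pmats(blens, kappa)
        down, dlog, ch = self.down, self.dlog, self.arr.children
        for v in self.arr.post:
            a, b = ch[v]
            val = (down[a] @ P[a].T) * (down[b] @ P[b].T)
            s = np.maximum(val.max(axis=1), _TINY)
            down[v] = val / s[:, None]
            dlog[v] = dlog[a] + dlog[b] + np.log(s)

    def _site_lnl_terms(self):
        """Per-pattern log-likelihoods at the root, after a down pass."""
        r = self.arr.root
        site = 0.25 * self.down[r].sum(axis=1)
        return np.log(np.maximum(site, _TINY)) + self.dlog[r]

    def _finish(self, loglik_per_pattern: np.ndarray) -> float:
        if self.ascertainment:
            obs, const = loglik_per_pattern[:-4], loglik_per_pattern[-4:]
            p_const = np.exp(const).sum()
            p_const = min(p_const, 1.0 - 1e-12)
            return float(
                (self.counts[:-4] * obs).sum() - self.n_sites * np.log1p(-p_const)
            )
        return float((self.counts * loglik_per_pattern).sum())

    def loglik(self, blens: np.ndarray, kappa: float) -> float:
        """Full-tree log-likelihood (recomputes all partials)."""
        self.down_pass(blens, kappa)
        return self._finish(self._site_lnl_terms())

    # -- free branch-length optimization ----------------------------------

    def optimize_free(
        self,
        blens: np.ndarray,
        kappa: float,
        max_sweeps: int = 20,
        tol: float = 1e-4,
        xatol: float = 1e-7,
    ) -> tuple[np.ndarray, float]:
        """Coordinate-ascent ML branch lengths at fixed ``kappa``.

        Each sweep refreshes the downward partials, then walks the tree
        root-to-tip optimizing one edge at a time against cached "rest of the
        tree" messages.
        """
        bl = blens.copy()
        best = self.loglik(bl, kappa)
        best_bl = bl.copy()
        for _ in range(max_sweeps):
            self.down_pass(bl, kappa)
            P = self._pmats(bl, kappa)
            self._sweep_edges(bl, kappa, P, xatol)
            cur = self.loglik(bl, kappa)
            gain = cur - best
            if cur > best:
                best, best_bl = cur, bl.copy()
            if gain < tol:
                break
        return best_bl, best

    def _sweep_edges(self, bl, kappa, P, xatol):
        arr = self.arr
        m = self.m
        down, dlog = self.down, self.dlog
        # adaptive upper bound: optima sit orders of magnitude below _BL_MAX
        ub = float(min(_BL_MAX, max(0.01, 8.0 * bl.max())))
        # A[v]: P(data outside subtree(v) | state at v) * prior, scaled
        A = np.empty((arr.n_nodes, m, 4))
        alog = np.zeros((arr.n_nodes, m))
        r = arr.root
        A[r] = 0.25
        stack = [r]
        counts = self.counts
        while stack:
            u = stack.pop()
            a, b = arr.children[u]
            for v, w in ((a, b), (b, a)):
                msg_w = down[w] @ P[w].T
                B = A[u] * msg_w
                s = np.maximum(B.max(axis=1), _TINY)
                B /= s[:, None]
                blog = alog[u] + dlog[w] + np.log(s)
                base = blog + dlog[v]
                dv = down[v]

                def obj(t: float) -> float:
                    Pt = k2p_transition_matrices(np.array(t), kappa)
                    site = (B * (dv @ Pt.T)).sum(axis=1)
                    terms = np.log(np.maximum(site, _TINY)) + base
                    return -self._finish(terms)

                res = minimize_scalar(
                    obj, bounds=(0.0, ub), method="bounded",
                    options={"xatol": max(xatol, 1e-2 * bl[v] + 1e-8)},
                )
                bl[v] = res.x
                P[v] = k2p_transition_matrices(np.array(bl[v]), kappa)
                if arr.children[v, 0] >= 0:
                    A[v] = B @ P[v]
                    s = np.maximum(A[v].max(axis=1), _TINY)
                    A[v] /= s[:, None]
                    alog[v] = blog + np.log(s)
                    stack.append(v)

    # -- clock (ultrametric) optimization ----------------------------------

    def optimize_clock(
        self,
        heights: np.ndarray,
        kappa: float,
        max_sweeps: int = 200,
        tol: float = 1e-5,
        xatol: float = 1e-9,
    ) -> tuple[np.ndarray, float]:
        """Coordinate-ascent ML node heights under the molecular clock.

        Tips sit at height 0; the edge above node ``v`` has length
        ``h[parent] - h[v]``. Each internal node's height is optimized within
        (max child height, parent height); the root is unbounded above.
        Because the per-node moves are strongly correlated (the likelihood
        surface's softest direction rescales the whole tree), each sweep ends
        with a one-dimensional line search over a global height scale factor.
        """
        arr = self.arr
        h = heights.copy()
        best = self.loglik(arr.blens_from_heights(h), kappa)
        best_h = h.copy()
        for _ in range(max_sweeps):
            self._sweep_heights(h, kappa, xatol)
            # global scale move along the softest direction
            def scale_obj(logs: float) -> float:
                return -self.loglik(arr.blens_from_heights(h * np.exp(logs)), kappa)

            res = minimize_scalar(scale_obj, bounds=(-0.7, 0.7), method="bounded",
                                  options={"xatol": 1e-4})
            if -res.fun > self.loglik(arr.blens_from_heights(h), kappa):
                h *= np.exp(res.x)
            cur = self.loglik(arr.blens_from_heights(h), kappa)
            gain = cur - best
            if cur > best:
                best, best_h = cur, h.copy()
            if gain < tol:
                break
        return best_h, best

    def _sweep_heights(self, h, kappa, xatol):
        # B[u]: P(data outside subtree(u) | state at PARENT of u), scaled;
        # it excludes the edge above u, which the objective re-applies with
        # the candidate height.
        arr = self.arr
        m = self.m
        bl = arr.blens_from_heights(h)
        self.down_pass(bl, kappa)
        down, dlog = self.down, self.dlog
        P = self._pmats(bl, kappa)
        B = np.empty((arr.n_nodes, m, 4))
        blog = np.zeros((arr.n_nodes, m))
        r = arr.root
        # process internal nodes root-first (parents before children)
        order = [r] + [v for v in self.arr.post[::-1] if v != r]
        for u in order:
            a, b = arr.children[u]
            par = arr.parent[u]
            lo = max(h[a], h[b])
            hi = h[par] if par >= 0 else max(h[u], lo) + 2.0 * max(h[r], 1e-6) + 1.0
            da, db = down[a], down[b]
            Bu = B[u] if par >= 0 else None
            base = (blog[u] if par >= 0 else 0.0) + dlog[a] + dlog[b]

            if hi - lo > 1e-12:
                if par >= 0:
                    def obj(x: float) -> float:
                        Pa = k2p_transition_matrices(np.array(x - h[a]), kappa)
                        Pb = k2p_transition_matrices(np.array(x - h[b]), kappa)
                        Pu = k2p_transition_matrices(np.array(h[par] - x), kappa)
                        D = (da @ Pa.T) * (db @ Pb.T)
                        site = (Bu * (D @ Pu.T)).sum(axis=1)
                        return -self._finish(
                            np.log(np.maximum(site, _TINY)) + base
                        )
                else:
                    def obj(x: float) -> float:
                        Pa = k2p_transition_matrices(np.array(x - h[a]), kappa)
                        Pb = k2p_transition_matrices(np.array(x - h[b]), kappa)
                        site = 0.25 * ((da @ Pa.T) * (db @ Pb.T)).sum(axis=1)
                        return -self._finish(
                            np.log(np.maximum(site, _TINY)) + base
                        )

                res = minimize_scalar(
                    obj, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
                )
                h[u] = float(res.x)
            else:
                h[u] = lo
            # refresh local transition matrices and descend messages
            for v in (a, b):
                P[v] = k2p_transition_matrices(np.array(h[u] - h[v]), kappa)
            if par >= 0:
                P[u] = k2p_transition_matrices(np.array(h[par] - h[u]), kappa)
            # A at u (inclusive of the edge above u, at its new length)
            if par >= 0:
                A_u = B[u] @ P[u]
                a_log = blog[u]
            else:
                A_u = np.full((m, 4), 0.25)
                a_log = 0.0
            for v, w in ((a, b), (b, a)):
                if arr.children[v, 0] >= 0:
                    msg = A_u * (down[w] @ P[w].T)
                    s = np.maximum(msg.max(axis=1), _TINY)
                    B[v] = msg / s[:, None]
                    blog[v] = a_log + dlog[w] + np.log(s)
        return h

    # -- kappa profiling ----------------------------------------------------

    def optimize_kappa(self, blens: np.ndarray, kappa: float) -> float:
        def obj(logk: float) -> float:
            return -self.loglik(blens, float(np.exp(logk)))

        res = minimize_scalar(
            obj, bounds=(np.log(0.05), np.log(50.0)), method="bounded",
            options={"xatol": 1e-3},
        )
        return float(np.exp(res.x))


def pruning_loglik(
    arr: TreeArrays,
    matrix: np.ndarray,
    kappa: float,
    ascertainment: bool = False,
) -> float:
    """One-shot Felsenstein pruning log-likelihood for an encoded alignment.

    ``matrix`` rows must follow ``arr.tip_names`` order.
    """
    patterns, counts = compress_patterns(matrix)
    eng = LikelihoodEngine(arr, patterns, counts, ascertainment=ascertainment)
    return eng.loglik(arr.blen, kappa)
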