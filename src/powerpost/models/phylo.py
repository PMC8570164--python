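"""GTR + discrete-gamma phylogenetic likelihood on a fixed rooted tree.

This is the application domain at desk scale: a nucleotide alignment, a
rooted binary tree with branch lengths in expected substitutions per site,
a general time-reversible (GTR) substitution process and gamma-distributed
among-site rate variation discretized into equal-probability categories
(4 by default).  The likelihood is computed with Felsenstein's pruning
algorithm over compressed site patterns; the topology is fixed (no tree
moves), so the model's free parameters are the branch lengths, the six GTR
exchangeabilities, the four stationary base frequencies and the gamma shape.

Site-partitioned evaluation (``site_partition_log_likelihood``) splits the
columns into N contiguous blocks for combined stone/likelihood parallelism.
Both routes reduce a per-site vector of log-likelihood values with the same
summation, so the partitioned result is bit-identical to the single-block
one regardless of N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from ..sampler import (
    DirichletSimplexMove,
    ParameterState,
    ScaleMove,
)

__all__ = [
    "Alignment",
    "Tree",
    "GTRParams",
    "build_rate_matrix",
    "transition_probs",
    "discrete_gamma_rates",
    "pruning_log_likelihood",
    "site_partition_log_likelihood",
    "phylo_log_prior",
    "simulate_alignment",
    "PhyloGTRModel",
    "read_alignment",
    "read_tree",
]

# IUPAC nucleotide codes as bitmasks over (A, C, G, T); gap/?/N are missing
_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8}
_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT", ".": "ACGT",
}
_CHAR_TO_MASK: dict[str, int] = dict(_STATE_BITS)
for code, bases in _AMBIGUITY.items():
    _CHAR_TO_MASK[code] = sum(_STATE_BITS[b] for b in bases)

_BASES = "ACGT"
# canonical exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class Alignment:
    """A DNA alignment with compressed site patterns.

    ``masks`` holds one IUPAC bitmask per (taxon, site); ambiguity codes and
    gaps contribute the union of their compatible states to the leaf
    partials (all-ones for fully missing data).
    """

    taxa: list[str]
    masks: np.ndarray  # (n_taxa, n_sites) uint8 bitmasks
    pattern_masks: np.ndarray = field(init=False)  # (n_taxa, n_patterns)
    pattern_weights: np.ndarray = field(init=False)
    pattern_index: np.ndarray = field(init=False)  # site -> pattern

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=np.uint8)
        if self.masks.ndim != 2 or self.masks.shape[0] != len(self.taxa):
            raise ValueError("mask matrix must have one row per taxon")
        if np.any(self.masks == 0) or np.any(self.masks > 15):
            raise ValueError("invalid state bitmask in alignment")
        cols, idx, counts = np.unique(
            self.masks, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_masks = cols
        self.pattern_weights = counts
        self.pattern_index = np.asarray(idx).ravel()

    @property
    def n_sites(self) -> int:
        return self.masks.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def site_block(self, start: int, stop: int) -> "Alignment":
        """A new alignment restricted to the contiguous columns [start, stop)."""
        if not 0 <= start < stop <= self.n_sites:
            raise ValueError(f"site range [{start}, {stop}) out of bounds")
        return Alignment(taxa=list(self.taxa), masks=self.masks[:, start:stop])

    @classmethod
    def from_sequences(cls, taxa: list[str], sequences: list[str]) -> "Alignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("all sequences must have equal length")
        masks = np.empty((len(taxa), lengths.pop()), dtype=np.uint8)
        for i, seq in enumerate(sequences):
            for j, ch in enumerate(seq.upper()):
                try:
                    masks[i, j] = _CHAR_TO_MASK[ch]
                except KeyError:
                    raise ValueError(f"unknown nucleotide code {ch!r} in {taxa[i]!r}")
        return cls(taxa=taxa, masks=masks)

    def to_fasta(self, path: str | Path) -> None:
        rev = {1: "A", 2: "C", 4: "G", 8: "T"}
        with open(path, "w") as fh:
            for i, name in enumerate(self.taxa):
                seq = "".join(rev.get(int(m), "N") for m in self.masks[i])
                fh.write(f">{name}\n{seq}\n")


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or (relaxed) PHYLIP alignment via Biopython."""
    from Bio import AlignIO

    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna", ".fst"} else None
    formats = [fmt] if fmt else ["fasta", "phylip-relaxed", "phylip"]
    last_err: Exception | None = None
    for candidate in formats:
        try:
            msa = AlignIO.read(str(path), candidate)
            return Alignment.from_sequences(
                [rec.id for rec in msa], [str(rec.seq) for rec in msa]
            )
        except Exception as err:  # try the next format
            last_err = err
    raise ValueError(f"could not parse alignment {path}: {last_err}")


class Tree:
    """A rooted binary tree with branch lengths, flattened for pruning.

    Wraps a dendropy tree; nodes are enumerated in postorder, with
    ``children[i]`` the child ids of node i and ``edge_lengths[i]`` the
    length of the branch above node i (unused for the root).
    """

    def __init__(self, dtree) -> None:
        import dendropy

        if not isinstance(dtree, dendropy.Tree):
            raise TypeError("expected a dendropy.Tree")
        self._dtree = dtree
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children: list[list[int]] = []
        self.edge_lengths = np.zeros(self.n_nodes)
        self.leaf_labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            kids = [index[id(c)] for c in nd.child_nodes()]
            if kids and len(kids) != 2:
                raise ValueError("tree must be binary (every internal node has 2 children)")
            self.children.append(kids)
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise ValueError("every non-root branch needs a length")
                if nd.edge.length < 0:
                    raise ValueError("branch lengths must be >= 0")
                self.edge_lengths[i] = float(nd.edge.length)
            if not kids:
                if nd.taxon is None:
                    raise ValueError("leaf without a taxon label")
                self.leaf_labels[i] = nd.taxon.label
        self.root = self.n_nodes - 1  # postorder puts the root last
        # edge ids: every node except the root owns the branch above it
        self.edge_nodes = [i for i in range(self.n_nodes) if i != self.root]
        if len(set(self.leaf_labels.values())) != len(self.leaf_labels):
            raise ValueError("leaf labels must be unique")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(dtree)

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def with_edge_lengths(self, lengths: np.ndarray) -> "Tree":
        """A shallow copy with the branch lengths replaced (edge order =
        ``edge_nodes``); topology arrays are shared, not re-parsed."""
        if len(lengths) != self.n_edges:
            raise ValueError("wrong number of branch lengths")
        clone = object.__new__(Tree)
        clone.__dict__.update(self.__dict__)
        clone.edge_lengths = self.edge_lengths.copy()
        clone.edge_lengths[self.edge_nodes] = np.asarray(lengths, dtype=float)
        return clone


def read_tree(path: str | Path) -> Tree:
    return Tree.from_newick(Path(path).read_text())


@dataclass
class GTRParams:
    """GTR exchangeabilities (6-simplex), base frequencies (4-simplex),
    gamma shape, and the number of discrete rate categories."""

    exchangeabilities: np.ndarray
    base_freqs: np.ndarray
    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        for name, simplex, size in (
            ("exchangeabilities", self.exchangeabilities, 6),
            ("base_freqs", self.base_freqs, 4),
        ):
            if simplex.shape != (size,):
                raise ValueError(f"{name} must have length {size}")
            if np.any(simplex <= 0):
                raise ValueError(f"{name} components must be positive")
            if abs(simplex.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 within 1e-12")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")


def build_rate_matrix(params: GTRParams) -> np.ndarray:
    """The GTR instantaneous rate matrix Q, scaled to one expected
    substitution per unit branch length.

    Off-diagonals q_ij = r_ij * pi_j with r in the canonical order
    AC, AG, AT, CG, CT, GT; rows sum to zero; -sum_i pi_i q_ii = 1.
    """
    r = params.exchangeabilities
    pi = params.base_freqs
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(r, _PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return Q / scale


def _eigen_gtr(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of Q via the similar symmetric matrix
    S = diag(sqrt(pi)) Q diag(1/sqrt(pi))."""
    sq = np.sqrt(pi)
    S = (sq[:, None] * Q) / sq[None, :]
    S = (S + S.T) / 2.0  # enforce exact symmetry against rounding
    w, U = np.linalg.eigh(S)
    right = U / sq[:, None]  # columns: right eigenvectors of Q
    left = U.T * sq[None, :]  # rows: left eigenvectors
    return w, right, left


def transition_probs(
    rate_matrix: np.ndarray,
    t: float,
    rate: float = 1.0,
    pi: np.ndarray | None = None,
    eig=None,
) -> np.ndarray:
    """P(t) = exp(rate * t * Q) via the reversible eigendecomposition.

    Rows sum to 1; entries are clipped at 0 against rounding noise.  ``pi``
    (or a precomputed ``eig`` triple) identifies the stationary frequencies
    used to symmetrize Q.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if eig is None:
        if pi is None:
            # recover pi from the stationary left null vector
            w, vl = np.linalg.eig(rate_matrix.T)
            k = int(np.argmin(np.abs(w)))
            pi = np.real(vl[:, k])
            pi = pi / pi.sum()
        eig = _eigen_gtr(rate_matrix, np.asarray(pi, dtype=float))
    w, right, left = eig
    P = (right * np.exp(w * rate * t)) @ left
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


from functools import lru_cache


@lru_cache(maxsize=4096)
def _discrete_gamma_rates_cached(shape: float, ncat: int) -> tuple[float, ...]:
    edges = gamma_dist.ppf(np.arange(ncat + 1) / ncat, a=shape, scale=1.0 / shape)
    upper = gamma_dist.cdf(edges, a=shape + 1.0, scale=1.0 / shape)
    rates = ncat * np.diff(upper)
    return tuple(rates / rates.mean())


def discrete_gamma_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Mean-of-category discretization of gamma(shape, shape) rate variation.

    The gamma(shape, rate=shape) density (mean 1) is cut at its ncat-tiles;
    each category's multiplier is the conditional mean within its slice,
    which has the closed form ncat * [F_{shape+1}(b_{j+1}) - F_{shape+1}(b_j)]
    with F the CDF of gamma(shape+1, rate=shape).  Renormalized so the
    multipliers average to exactly 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    return np.array(_discrete_gamma_rates_cached(float(shape), int(ncat)))


def _per_site_log_likelihood(
    tree: Tree, alignment: Alignment, params: GTRParams
) -> np.ndarray:
    """Per-site log-likelihood values, the common core of both evaluators.

    All pattern-axis arithmetic is elementwise (the 4-state transforms are
    unrolled), so a pattern's value does not depend on which other patterns
    share the batch — this is what makes site-partitioned evaluation
    bit-identical to the single-block one.
    """
    missing = set(tree.leaf_labels.values()) ^ set(alignment.taxa)
    if missing:
        raise ValueError(f"tree/alignment taxon mismatch: {sorted(missing)}")
    pi = params.base_freqs
    Q = build_rate_matrix(params)
    eig = _eigen_gtr(Q, pi)
    rates = discrete_gamma_rates(params.gamma_shape, params.n_categories)
    ncat = params.n_categories
    npat = alignment.pattern_masks.shape[1]
    taxon_row = {name: i for i, name in enumerate(alignment.taxa)}

    # leaf partials from bitmasks, shared across categories
    leaf_partials: dict[int, np.ndarray] = {}
    bit_table = np.array([[1, 2, 4, 8]], dtype=np.uint8)
    for node, label in tree.leaf_labels.items():
        masks = alignment.pattern_masks[taxon_row[label]][:, None]  # (npat, 1)
        leaf_partials[node] = ((masks & bit_table) != 0).astype(float)

    # all transition matrices at once: P_all[c, node] = exp(rate_c * t_node * Q)
    w, right, left = eig
    scaled_t = np.multiply.outer(rates, tree.edge_lengths)  # (ncat, n_nodes)
    expw = np.exp(scaled_t[:, :, None] * w[None, None, :])
    P_all = np.einsum("ij,cnj,jk->cnik", right, expw, left)
    np.clip(P_all, 0.0, None, out=P_all)
    P_all /= P_all.sum(axis=-1, keepdims=True)

    # partials carry a leading category axis: shape (ncat, npat, 4)
    partial: dict[int, np.ndarray] = {}
    for node in range(tree.n_nodes):
        kids = tree.children[node]
        if not kids:
            partial[node] = leaf_partials[node][None, :, :]
            continue
        prod = np.ones((ncat, npat, 4))
        for child in kids:
            P = P_all[:, child]  # (ncat, 4, 4)
            cp = partial.pop(child)
            # unrolled matrix product keeps every op elementwise per pattern
            transformed = (
                cp[:, :, 0:1] * P[:, None, :, 0]
                + cp[:, :, 1:2] * P[:, None, :, 1]
                + cp[:, :, 2:3] * P[:, None, :, 2]
                + cp[:, :, 3:4] * P[:, None, :, 3]
            )
            prod = prod * transformed
        partial[node] = prod
    root = partial[tree.root]
    per_cat = (
        root[:, :, 0] * pi[0]
        + root[:, :, 1] * pi[1]
        + root[:, :, 2] * pi[2]
        + root[:, :, 3] * pi[3]
    )
    site_lik = per_cat.sum(axis=0) / ncat
    if np.any(site_lik <= 0):
        raise FloatingPointError("site likelihood underflow; tree too deep for this scale")
    return np.log(site_lik)[alignment.pattern_index]


def pruning_log_likelihood(
    tree: Tree,
    alignment: Alignment,
    params: GTRParams,
    site_range: tuple[int, int] | None = None,
) -> float:
    """Felsenstein pruning log-likelihood, optionally over a column block.

    Sums, over (weighted) site patterns, the log of the category-averaged,
    frequency-weighted root partial.  ``site_range=(start, stop)`` restricts
    the evaluation to a contiguous block of columns.
    """
    if site_range is not None:
        alignment = alignment.site_block(*site_range)
    return float(np.sum(_per_site_log_likelihood(tree, alignment, params)))


def site_partition_log_likelihood(
    tree: Tree,
    alignment: Alignment,
    params: GTRParams,
    N: int,
    pool=None,
) -> float:
    """Log-likelihood with the columns split into N contiguous blocks.

    Blocks are evaluated independently (through ``pool.map`` when a worker
    pool is supplied) and the per-site values re-assembled in column order
    before the final reduction, so the result is bit-identical to
    ``pruning_log_likelihood`` for every N.
    """
    n_sites = alignment.n_sites
    if not 1 <= N <= n_sites:
        raise ValueError(f"N={N} must satisfy 1 <= N <= number of sites ({n_sites})")
    bounds = [round(b * n_sites / N) for b in range(N + 1)]
    blocks = [alignment.site_block(lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:])]
    if pool is not None:
        parts = pool.map(_per_site_block, [(tree, blk, params) for blk in blocks])
    else:
        parts = [_per_site_log_likelihood(tree, blk, params) for blk in blocks]
    return float(np.sum(np.concatenate(list(parts))))


def _per_site_block(args):
    tree, block, params = args
    return _per_site_log_likelihood(tree, block, params)


def phylo_log_prior(tree: Tree, params: GTRParams) -> float:
    """Log prior: iid Exp(10) branch lengths, flat Dirichlet simplexes,
    Exp(1) gamma shape."""
    blens = tree.edge_lengths[tree.edge_nodes]
    if np.any(blens < 0) or params.gamma_shape <= 0:
        return -np.inf
    lp = float(len(blens) * math.log(10.0) - 10.0 * blens.sum())
    lp += -params.gamma_shape  # Exp(1) log density (log 1 = 0)
    lp += float(gammaln(6))  # flat Dirichlet on the 6-simplex
    lp += float(gammaln(4))  # flat Dirichlet on the 4-simplex
    return lp


def simulate_alignment(
    tree: Tree, params: GTRParams, n_sites: int, seed: int
) -> Alignment:
    """Simulate an alignment under GTR + discrete gamma down the fixed tree.

    Root states are drawn from the stationary frequencies; each site picks
    one of the equal-probability rate categories; states evolve along each
    branch with the matrix exponential transition probabilities.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    pi = params.base_freqs
    Q = build_rate_matrix(params)
    eig = _eigen_gtr(Q, pi)
    rates = discrete_gamma_rates(params.gamma_shape, params.n_categories)
    cats = rng.integers(0, params.n_categories, size=n_sites)
    states = {tree.root: rng.choice(4, size=n_sites, p=pi)}
    # walk the tree root -> leaves (reverse postorder is a valid preorder)
    for node in range(tree.n_nodes - 1, -1, -1):
        for child in tree.children[node]:
            P_by_cat = [
                transition_probs(Q, tree.edge_lengths[child], r, eig=eig) for r in rates
            ]
            parent_states = states[node]
            child_states = np.empty(n_sites, dtype=np.int64)
            u = rng.random(n_sites)
            for s in range(n_sites):
                probs = P_by_cat[cats[s]][parent_states[s]]
                child_states[s] = int(np.searchsorted(np.cumsum(probs), u[s]))
            states[child] = np.clip(child_states, 0, 3)
    taxa = sorted(tree.leaf_labels.values())
    leaf_by_name = {v: k for k, v in tree.leaf_labels.items()}
    masks = np.empty((len(taxa), n_sites), dtype=np.uint8)
    bit = np.array([1, 2, 4, 8], dtype=np.uint8)
    for row, name in enumerate(taxa):
        masks[row] = bit[states[leaf_by_name[name]]]
    return Alignment(taxa=taxa, masks=masks)


class PhyloGTRModel:
    """GTR + discrete-gamma model on a fixed topology, for the MCMC engine.

    Parameters: one branch length per edge (scale moves), the gamma shape
    (scale move), and the two simplexes (Dirichlet moves).  The likelihood
    can optionally be evaluated over N site partitions via a worker pool.
    """

    def __init__(
        self,
        tree: Tree,
        alignment: Alignment,
        n_categories: int = 4,
        N: int = 1,
        pool=None,
    ) -> None:
        self.tree = tree
        self.alignment = alignment
        self.n_categories = n_categories
        self.N = N
        self._pool = pool
        self._moves = []
        for e, node in enumerate(tree.edge_nodes):
            self._moves.append(ScaleMove(f"blen_{e}", lam=0.6))
        self._moves.append(ScaleMove("gamma_shape", lam=0.5))
        self._moves.append(DirichletSimplexMove("exchangeabilities", concentration=300.0))
        self._moves.append(DirichletSimplexMove("base_freqs", concentration=300.0))

    # pools are process-local; never pickle them with the model
    def __getstate__(self):
        state = dict(self.__dict__)
        state["_pool"] = None
        return state

    def _unpack(self, values: dict) -> tuple[Tree, GTRParams]:
        blens = np.array([values[f"blen_{e}"] for e in range(self.tree.n_edges)])
        tree = self.tree.with_edge_lengths(blens)
        params = GTRParams(
            exchangeabilities=np.asarray(values["exchangeabilities"]),
            base_freqs=np.asarray(values["base_freqs"]),
            gamma_shape=float(values["gamma_shape"]),
            n_categories=self.n_categories,
        )
        return tree, params

    def log_prior(self, values: dict) -> float:
        blens = np.array([values[f"blen_{e}"] for e in range(self.tree.n_edges)])
        shape = float(values["gamma_shape"])
        if np.any(blens <= 0) or shape <= 0:
            return -np.inf
        lp = float(self.tree.n_edges * math.log(10.0) - 10.0 * blens.sum()) - shape
        lp += float(gammaln(6) + gammaln(4))
        return lp

    def log_likelihood(self, values: dict) -> float:
        tree, params = self._unpack(values)
        if self.N > 1:
            return site_partition_log_likelihood(
                tree, self.alignment, params, self.N, pool=self._pool
            )
        return pruning_log_likelihood(tree, self.alignment, params)

    @property
    def moves(self):
        return self._moves

    def initial_state(self, rng: np.random.Generator) -> ParameterState:
        values: dict = {
            f"blen_{e}": float(rng.exponential(1.0 / 10.0)) for e in range(self.tree.n_edges)
        }
        values["gamma_shape"] = float(rng.exponential(1.0))
        values["exchangeabilities"] = rng.dirichlet(np.ones(6))
        values["base_freqs"] = rng.dirichlet(np.ones(4))
        return ParameterState(values=values)
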