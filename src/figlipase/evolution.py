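"""Birth-death model of gene family size evolution on a species tree.

Each gene copy in a family is gained or lost at the same rate ``lambda``
per unit branch length (a linear birth-death process with equal birth and
death rates).  With ``alpha = lambda * t / (1 + lambda * t)`` the transition
probability from a parent count ``s`` to a child count ``c`` over a branch
of length ``t`` is

    P(c | s, t) = sum_{j=0}^{min(s, c)} C(s, j) C(s + c - j - 1, s - 1)
                  alpha^(s + c - 2 j) (1 - 2 alpha)^j

with the zero state absorbing.  On a rooted species tree this yields, by the
standard pruning (sum-product) recursion over count states ``0..M``:

* the log-likelihood of observed leaf counts (root prior uniform on
  ``1..M``: a family had at least one member at the root),
* a maximum-likelihood estimate of ``lambda`` over many families
  (golden-section search),
* a joint max-product reconstruction of ancestral counts with per-branch
  net changes and two-sided tail probabilities, and
* a forward simulator used for parameter-recovery checks.

Counts are truncated at a cap ``M`` (default 100); observed counts above
the cap are an error rather than silently squeezed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.special import gammaln

__all__ = [
    "BDModel",
    "AncestralReport",
    "BranchChange",
    "load_tree",
    "bd_transition_prob",
    "transition_matrix",
    "tree_loglik",
    "estimate_lambda",
    "reconstruct_ancestral",
    "simulate_counts",
]

DEFAULT_CAP = 100


@dataclass(frozen=True)
class BDModel:
    """Gain/loss rate and the state-space truncation bound."""

    lam: float
    cap: int = DEFAULT_CAP

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.cap < 1:
            raise ValueError("cap must be at least 1")

    def alpha(self, t: float) -> float:
        """alpha(t) = lambda t / (1 + lambda t), in [0, 1)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        return self.lam * t / (1.0 + self.lam * t)


@dataclass(frozen=True)
class BranchChange:
    parent: str
    child: str
    parent_count: int
    child_count: int
    net_change: int
    pvalue: float
    significant: bool


@dataclass(frozen=True)
class AncestralReport:
    node_counts: dict[str, int]  # node label -> reconstructed count (leaves included)
    branches: tuple[BranchChange, ...]
    log_score: float  # log of the joint max-product score


def load_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick species tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            raise ValueError("every non-root branch needs a positive length")
    return tree


def bd_transition_prob(s: int, c: int, model: BDModel, t: float) -> float:
    """P(child count = c | parent count = s) over a branch of length t."""
    if s < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if t < 0:
        raise ValueError("branch length must be non-negative")
    row = _kernel_row(s, model.alpha(t), c)
    return float(row[c])


def transition_matrix(model: BDModel, t: float, cap: int | None = None) -> np.ndarray:
    """Dense (cap+1) x (cap+1) kernel; rows = parent count, cols = child count."""
    m = model.cap if cap is None else cap
    return _transition_matrix_cached(model.alpha(t), m)


@lru_cache(maxsize=1024)
def _transition_matrix_cached(alpha: float, m: int) -> np.ndarray:
    out = np.empty((m + 1, m + 1))
    for s in range(m + 1):
        out[s] = _kernel_row(s, alpha, m)
    out.setflags(write=False)  # shared through the cache
    return out


def _kernel_row(s: int, alpha: float, cmax: int) -> np.ndarray:
    """Transition probabilities from parent count s to child counts 0..cmax."""
    c = np.arange(cmax + 1)
    if s == 0:  # extinction is absorbing
        row = np.zeros(cmax + 1)
        row[0] = 1.0
        return row
    if alpha == 0.0:  # zero-length branch: identity
        row = np.zeros(cmax + 1)
        if s <= cmax:
            row[s] = 1.0
        return row
    j = np.arange(s + 1)[:, None]  # (s+1, 1)
    cc = c[None, :]  # (1, cmax+1)
    # log C(s, j) + log C(s + c - j - 1, s - 1), guarded against invalid combos
    with np.errstate(invalid="ignore"):
        log_comb1 = gammaln(s + 1) - gammaln(j + 1) - gammaln(s - j + 1)
        top = s + cc - j - 1
        log_comb2 = gammaln(top + 1) - gammaln(s) - gammaln(top - (s - 1) + 1)
    power = s + cc - 2 * j
    one_minus = 1.0 - 2.0 * alpha  # may be negative for lambda*t > 1
    if one_minus == 0.0:
        j_term = np.where(j == 0, 0.0, -np.inf)  # 0^0 = 1, 0^j = 0
        sign = np.ones_like(j, dtype=float)
    else:
        j_term = j * np.log(abs(one_minus))
        sign = np.where((j % 2 == 1) & (one_minus < 0), -1.0, 1.0)
    terms = sign * np.exp(log_comb1 + log_comb2 + power * np.log(alpha) + j_term)
    valid = (j <= np.minimum(s, cc)) & (top >= s - 1)
    terms = np.where(valid, terms, 0.0)
    row = terms.sum(axis=0)
    # c = 0 reduces to the extinction probability alpha^s exactly
    row[0] = alpha**s
    return np.clip(row, 0.0, 1.0)


def _check_counts(tree: dendropy.Tree, leaf_counts: Mapping[str, int], cap: int) -> None:
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = taxa - set(leaf_counts)
    if missing:
        raise ValueError(f"missing counts for leaves: {sorted(missing)}")
    for name, count in leaf_counts.items():
        if count < 0:
            raise ValueError(f"negative count for {name!r}")
        if count > cap:
            raise ValueError(f"count {count} for {name!r} exceeds the cap {cap}")


def _branch_kernels(tree: dendropy.Tree, model: BDModel) -> dict[int, np.ndarray]:
    """Kernel per edge (keyed by id of the head node), shared across families."""
    kernels: dict[int, np.ndarray] = {}
    by_length: dict[float, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = float(node.edge.length)
        if t not in by_length:
            by_length[t] = transition_matrix(model, t)
        kernels[id(node)] = by_length[t]
    return kernels


def _pruning(tree, counts_matrix: np.ndarray, leaf_order: dict[str, int], model: BDModel):
    """Sum-product over states for all families at once.

    ``counts_matrix`` is (n_families, n_leaves); returns per-family
    log-likelihoods under a root prior uniform on 1..cap.
    """
    m = model.cap
    kernels = _branch_kernels(tree, model)
    n_fam = counts_matrix.shape[0]
    messages: dict[int, np.ndarray] = {}  # node id -> (cap+1, n_fam)
    log_scale = np.zeros(n_fam)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts = counts_matrix[:, leaf_order[node.taxon.label]]
            msg = np.zeros((m + 1, n_fam))
            msg[counts, np.arange(n_fam)] = 1.0
        else:
            msg = np.ones((m + 1, n_fam))
            for child in node.child_nodes():
                msg *= kernels[id(child)] @ messages.pop(id(child))
            peak = msg.max(axis=0)
            peak[peak == 0] = 1.0  # impossible family: leave zeros, log later
            msg /= peak
            log_scale += np.log(peak)
        messages[id(node)] = msg
    root_msg = messages[id(tree.seed_node)]
    with np.errstate(divide="ignore"):
        return np.log(root_msg[1:].sum(axis=0) / m) + log_scale


def tree_loglik(
    tree: dendropy.Tree, leaf_counts: Mapping[str, int], model: BDModel
) -> float:
    """Log-likelihood of one family's leaf counts under the model."""
    _check_counts(tree, leaf_counts, model.cap)
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    order = {name: i for i, name in enumerate(leaves)}
    matrix = np.array([[leaf_counts[name] for name in leaves]])
    return float(_pruning(tree, matrix, order, model)[0])


def estimate_lambda(
    tree: dendropy.Tree,
    families: Sequence[Mapping[str, int]],
    cap: int = DEFAULT_CAP,
    bounds: tuple[float, float] = (1e-6, 1.0),
    rel_tol: float = 1e-6,
) -> float:
    """Maximum-likelihood lambda over a set of families, by golden section.

    The search is deterministic; with degenerate data (no observed change)
    the estimate collapses to the lower bound.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError("bounds must satisfy 0 < lo < hi")
    if not families:
        raise ValueError("need at least one family")
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    order = {name: i for i, name in enumerate(leaves)}
    for fam in families:
        _check_counts(tree, fam, cap)
    matrix = np.array([[fam[name] for name in leaves] for fam in families])

    def objective(lam: float) -> float:
        ll = _pruning(tree, matrix, order, BDModel(lam=lam, cap=cap))
        total = float(ll.sum())
        if not np.isfinite(total):
            raise ValueError(f"non-finite likelihood at lambda={lam}")
        return total

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = objective(c), objective(d)
    while (b - a) > rel_tol * max(abs(a), abs(b), 1e-12):
        if fc > fd:  # maximize
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = objective(d)
    return (a + b) / 2.0


def reconstruct_ancestral(
    tree: dendropy.Tree,
    leaf_counts: Mapping[str, int],
    model: BDModel,
    significance: float = 0.05,
) -> AncestralReport:
    """Joint max-product reconstruction of ancestral counts.

    Ties break toward the smaller count.  Each branch gets a two-sided tail
    probability under the fitted kernel: the total kernel mass on child
    counts at least as far from the parent count as the one reconstructed.
    """
    _check_counts(tree, leaf_counts, model.cap)
    m = model.cap
    kernels = _branch_kernels(tree, model)
    states = np.arange(m + 1)

    log_msgs: dict[int, np.ndarray] = {}
    backptr: dict[int, np.ndarray] = {}  # child node id -> best child state per parent state
    with np.errstate(divide="ignore"):
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                msg = np.full(m + 1, -np.inf)
                msg[leaf_counts[node.taxon.label]] = 0.0
                log_msgs[id(node)] = msg
                continue
            total = np.zeros(m + 1)
            for child in node.child_nodes():
                scores = np.log(kernels[id(child)]) + log_msgs[id(child)][None, :]
                # argmax returns the first (smallest) index on ties
                best = scores.argmax(axis=1)
                backptr[id(child)] = best
                total += scores[states, best]
            log_msgs[id(node)] = total

    root = tree.seed_node
    root_scores = log_msgs[id(root)].copy()
    root_scores[0] = -np.inf  # uniform root prior on 1..cap
    root_state = int(root_scores.argmax())
    log_score = float(root_scores[root_state]) - np.log(m)

    node_counts: dict[str, int] = {}
    chosen: dict[int, int] = {id(root): root_state}
    node_counts[_label(root)] = root_state
    branches: list[BranchChange] = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = chosen[id(node.parent_node)]
        state = int(backptr[id(node)][parent_state])
        chosen[id(node)] = state
        node_counts[_label(node)] = state
        kernel_row = kernels[id(node)][parent_state]
        p = float(kernel_row[np.abs(states - parent_state) >= abs(state - parent_state)].sum())
        branches.append(
            BranchChange(
                parent=_label(node.parent_node),
                child=_label(node),
                parent_count=parent_state,
                child_count=state,
                net_change=state - parent_state,
                pvalue=p,
                significant=p < significance,
            )
        )
    return AncestralReport(node_counts, tuple(branches), log_score)


def _label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    # stable synthetic label from the sorted leaf set under the node
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "mrca(" + ",".join(leaves) + ")"


def simulate_counts(
    tree: dendropy.Tree,
    root_count: int,
    model: BDModel,
    seed: int | np.random.Generator,
) -> dict[str, int]:
    """Sample leaf counts by walking the tree branch by branch."""
    if root_count < 1:
        raise ValueError("root count must be at least 1")
    if root_count > model.cap:
        raise ValueError("root count exceeds the cap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kernels = _branch_kernels(tree, model)
    m = model.cap
    states: dict[int, int] = {id(tree.seed_node): root_count}
    out: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[id(node.parent_node)]
        row = kernels[id(node)][parent]
        total = row.sum()
        if not 0 < total:
            raise ValueError("degenerate kernel row")
        state = int(rng.choice(m + 1, p=row / total))
        states[id(node)] = state
        if node.is_leaf():
            out[node.taxon.label] = state
    return out
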