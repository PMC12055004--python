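"""Synthetic coevolving gene-tree and protein-alignment generator.

The mirrortree statistic asks whether two gene families' evolutionary
rates covary across the branches of a shared species history.  This module
generates data with exactly that structure, with the strength of the
covariation exposed as a single dial:

1. a pure-birth (Yule) species tree with branch lengths in expected
   substitutions per site;
2. a pair of gene trees that share the species topology but whose branch
   lengths are perturbed by per-branch lognormal rate multipliers; the log
   multipliers of the two genes on the same branch are bivariate normal
   with standard deviation ``rate_sd`` and correlation ``rho``.  ``rho = 0``
   gives independently evolving rates (the null of the mirrortree test,
   though the shared topology alone already induces positive correlation
   between the patristic matrices); ``rho = 1`` makes the two gene trees
   identical up to the shared noise;
3. protein alignments evolved along a gene tree under the JTT model with
   uniform site rates (no rate heterogeneity, no indels).

The lognormal multipliers are mean-corrected (``exp(eps - rate_sd**2/2)``)
so the expected branch length equals the species-tree branch length at any
``rate_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .alignment import ProteinAlignment
from .errors import InvalidParameterError, InvalidTreeError, MissingBranchLengthError
from .jtt import AMINO_ACIDS, JTTModel, jtt_model


@dataclass(frozen=True)
class CoevolutionParams:
    """Parameters of the coevolving gene-tree pair generator.

    rho : between-gene correlation of per-branch log rate multipliers, in [0, 1].
    rate_sd : standard deviation of the log multipliers (>= 0); 0 disables noise.
    n_sites : alignment length for downstream sequence evolution (>= 1).
    seed : integer seed; every draw is reproducible under it.
    """

    rho: float
    rate_sd: float = 0.5
    n_sites: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidParameterError(f"rho must be in [0, 1], got {self.rho}")
        if self.rate_sd < 0:
            raise InvalidParameterError(f"rate_sd must be >= 0, got {self.rate_sd}")
        if self.n_sites < 1:
            raise InvalidParameterError(f"n_sites must be >= 1, got {self.n_sites}")


@dataclass(frozen=True)
class GeneTreePair:
    """Two gene trees on a shared topology plus the noise that made them.

    ``log_rate_noise`` has one row per branch (preorder, root excluded) and
    two columns: the bivariate-normal log-rate draws for gene A and gene B.
    It is retained so the realized noise correlation can be inspected.
    """

    tree_a: TreeNode
    tree_b: TreeNode
    log_rate_noise: np.ndarray


def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0,
                          seed: int = 0) -> TreeNode:
    """Simulate a pure-birth (Yule) species tree with ``n_taxa`` leaves.

    Starting from the root split (two lineages), each of the k extant
    lineages splits after an Exp(k * birth_rate) waiting time, the splitting
    lineage chosen uniformly.  After the (n-1)-th split a final
    Exp(n * birth_rate) interval elapses, so every pendant branch has
    positive length.  Leaves are labeled ``t001`` .. ``tNNN`` in preorder.
    Branch lengths are in expected substitutions per site.
    """
    if n_taxa < 3:
        raise InvalidParameterError(f"n_taxa must be >= 3, got {n_taxa}")
    if birth_rate <= 0:
        raise InvalidParameterError(f"birth_rate must be > 0, got {birth_rate}")
    rng = np.random.default_rng(seed)

    root = TreeNode()
    first = [TreeNode(), TreeNode()]
    root.extend(first)
    active: list[TreeNode] = list(first)
    birth_time = {id(n): 0.0 for n in active}
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.length = t - birth_time.pop(id(parent))
        kids = [TreeNode(), TreeNode()]
        parent.extend(kids)
        for kid in kids:
            birth_time[id(kid)] = t
            active.append(kid)
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    for node in active:
        node.length = t - birth_time[id(node)]

    width = max(3, len(str(n_taxa)))
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"t{i:0{width}d}"
    return root


def simulate_coevolving_gene_trees(species: TreeNode,
                                   params: CoevolutionParams) -> GeneTreePair:
    """Derive two gene trees from a species tree with correlated rate noise.

    For every branch b with species-tree length L_b, gene g receives length
    ``L_b * exp(eps_gb - rate_sd**2 / 2)`` where (eps_1b, eps_2b) are
    bivariate normal with sd ``rate_sd`` and correlation ``rho``.  With
    ``rho = 1`` the two draws are the identical shared draw, so the trees
    are branch-for-branch equal; with ``rate_sd = 0`` both equal the
    species tree.
    """
    branches = [n for n in species.traverse(include_self=False)]
    for node in branches:
        if node.length is None:
            raise MissingBranchLengthError(str(node.name or "internal node"))
        if not np.isfinite(node.length) or node.length < 0:
            raise InvalidTreeError(f"invalid species branch length {node.length!r}")

    rng = np.random.default_rng(params.seed)
    sd, rho = params.rate_sd, params.rho
    z = rng.standard_normal((len(branches), 2))
    eps = np.empty_like(z)
    eps[:, 0] = sd * z[:, 0]
    eps[:, 1] = sd * (rho * z[:, 0] + np.sqrt(1.0 - rho ** 2) * z[:, 1])

    tree_a, tree_b = species.copy(), species.copy()
    for k, (na, nb) in enumerate(zip(tree_a.traverse(include_self=False),
                                     tree_b.traverse(include_self=False))):
        correction = sd ** 2 / 2.0
        na.length = na.length * float(np.exp(eps[k, 0] - correction))
        nb.length = nb.length * float(np.exp(eps[k, 1] - correction))
    return GeneTreePair(tree_a=tree_a, tree_b=tree_b, log_rate_noise=eps)


def evolve_alignment(tree: TreeNode, model: JTTModel | None = None,
                     n_sites: int = 200, seed: int = 0) -> ProteinAlignment:
    """Evolve an ungapped protein alignment along ``tree`` under ``model``.

    Root states are drawn from the model's equilibrium frequencies; each
    branch applies the transition matrix exp(Q * L) independently per site
    (uniform rates).  Returns one sequence of length ``n_sites`` per leaf.
    """
    if n_sites < 1:
        raise InvalidParameterError(f"n_sites must be >= 1, got {n_sites}")
    model = model or jtt_model()
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise MissingBranchLengthError(str(node.name or "internal node"))
        if not np.isfinite(node.length) or node.length < 0:
            raise InvalidTreeError(f"invalid branch length {node.length!r}")

    rng = np.random.default_rng(seed)
    pi = model.frequencies
    states: dict[int, np.ndarray] = {
        id(tree): rng.choice(len(pi), size=n_sites, p=pi)}
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    records = []
    for node in tree.preorder(include_self=False):
        cum = np.cumsum(model.transition_matrix(node.length), axis=1)
        u = rng.random(n_sites)
        child_states = (u[:, None] > cum[states[id(node.parent)]]).sum(axis=1)
        states[id(node)] = child_states
        if node.is_tip():
            records.append((node.name, alphabet[child_states].tobytes().decode()))
    order = {tip.name: i for i, tip in enumerate(tree.tips())}
    records.sort(key=lambda rec: order[rec[0]])
    return ProteinAlignment(tuple(records))
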