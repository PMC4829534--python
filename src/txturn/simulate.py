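"""Synthetic transcriptome-turnover datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: ten murid taxa on a fixed ultrametric phylogeny (splits from a
few thousand years to ~10.6 Myr), a conserved highly-expressed core of
windows transcribed in every taxon, and a turnover fraction whose
presence/absence state evolves along the tree as a two-state
continuous-time Markov chain with gain rate g and loss rate l per Myr.
Expression levels per transcribed window are log-normal and shared across
taxa; sequencing is Poisson sampling of fragments at a configurable depth
per tissue and replicate.  Genomic coverage for common-genome masking is
simulated with an independent per-taxon window dropout.

Every draw is reproducible from the model seed; the true tree, true
presence states and core labels are returned alongside the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .windows import CountMatrix, make_windows

#: taxon codes of the ten-taxon study design
DEFAULT_TAXA = ("DOM_CB", "DOM_MC", "DOM_AH", "MUS_KH", "MUS_VI",
                "CAS", "SPI", "SPR", "MAT", "APO")

#: ultrametric ten-taxon topology, branch lengths in Myr: three western
#: house-mouse populations (splits 3-12 kyr), two eastern populations
#: (10 kyr), then castaneus (0.4), the domesticus/musculus split (0.5),
#: M. spicilegus (1.2), M. spretus (1.7), M. mattheyi (6.6) and the
#: Apodemus outgroup (10.6).
DEFAULT_TREE_NEWICK = (
    "(((((((DOM_CB:0.003,DOM_MC:0.003):0.009,DOM_AH:0.012):0.488,"
    "((MUS_KH:0.01,MUS_VI:0.01):0.39,CAS:0.4):0.1):0.7,SPI:1.2):0.5,"
    "SPR:1.7):4.9,MAT:6.6):4.0,APO:10.6);"
)

DEFAULT_TISSUES = ("liver", "brain", "testis")


def default_tree() -> TreeNode:
    return TreeNode.read([DEFAULT_TREE_NEWICK], convert_underscores=False)


@dataclass
class TurnoverModel:
    """Generative parameters for a turnover dataset.

    Parameters
    ----------
    tree : skbio.TreeNode, optional
        Taxon phylogeny with branch lengths in Myr (default: the ten-taxon
        study tree).
    gain_rate, loss_rate : float
        CTMC rates g and l per Myr for 0->1 and 1->0 transitions of the
        transcription state of a turnover window.
    root_presence : float or None
        Root state probability; None means the stationary g/(g+l).
    core_fraction : float
        Fraction of windows in the conserved core (transcribed in every
        taxon, loss-immune), with expression multiplier ``core_multiplier``.
    lognorm_mu, lognorm_sigma : float
        Parameters of the log-normal expression level per transcribed
        window (shared across taxa).
    depth : float
        Depth scaling: expected fragments per sample for a window with
        expression level 1.
    background_noise : float
        Optional per-sample probability of a spurious single fragment in a
        non-transcribed window (exercises singleton analyses; 0 by default).
    """

    tree: TreeNode | None = None
    gain_rate: float = 0.21
    loss_rate: float = 0.39
    root_presence: float | None = None
    core_fraction: float = 0.2
    core_multiplier: float = 10.0
    lognorm_mu: float = float(np.log(2.0))
    lognorm_sigma: float = 0.8
    depth: float = 3.0
    background_noise: float = 0.0
    n_windows: int = 10_000
    n_tissues: int = 3
    n_replicates: int = 1
    window_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree is None:
            self.tree = default_tree()
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.core_fraction <= 1:
            raise ValueError("core_fraction must be in [0, 1]")

    @property
    def taxa(self) -> list:
        return [t.name for t in self.tree.tips()]

    @property
    def stationary_presence(self) -> float:
        tot = self.gain_rate + self.loss_rate
        if tot == 0:
            return self.root_presence if self.root_presence is not None else 0.5
        return self.gain_rate / tot

    def with_seed(self, seed: int) -> "TurnoverModel":
        return replace(self, seed=seed)


@dataclass
class SimulatedDataset:
    """Counts plus full ground truth for a simulated turnover experiment."""

    model: TurnoverModel
    windows: pd.DataFrame
    counts: CountMatrix                  # all tissues/replicates as columns
    true_presence: pd.DataFrame          # windows x taxa, 0/1
    true_tree: TreeNode
    is_core: np.ndarray
    expression: np.ndarray               # lambda per window (0 if never used)


def _transition_sample(parent_states: np.ndarray, t: float, g: float,
                       l: float, rng: np.random.Generator) -> np.ndarray:
    """One CTMC step for a vector of binary states along a branch of
    length t: P(0->1) = pi1*(1-e^{-(g+l)t}), P(1->0) = pi0*(1-e^{-(g+l)t})."""
    tot = g + l
    if tot == 0 or t == 0:
        return parent_states.copy()
    pi1 = g / tot
    relax = 1.0 - np.exp(-tot * t)
    p_gain = pi1 * relax
    p_loss = (1.0 - pi1) * relax
    u = rng.random(parent_states.shape)
    child = parent_states.copy()
    child[(parent_states == 0) & (u < p_gain)] = 1
    child[(parent_states == 1) & (u < p_loss)] = 0
    return child


def evolve_presence(model: TurnoverModel, rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Evolve per-window presence states down the tree.

    Root states are Bernoulli(root_presence or stationary); each branch
    applies the two-state CTMC transition.  Core windows (a seeded random
    subset of ``core_fraction``) are fixed present in all taxa.

    Returns (presence windows x taxa DataFrame, is_core bool array).
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = model.n_windows
    pi_root = model.root_presence
    if pi_root is None:
        pi_root = model.stationary_presence
    is_core = np.zeros(n, dtype=bool)
    n_core = int(round(model.core_fraction * n))
    if n_core:
        is_core[rng.choice(n, size=n_core, replace=False)] = True
    root_state = (rng.random(n) < pi_root).astype(np.int8)
    states: dict = {}

    def _descend(node: TreeNode, state: np.ndarray) -> None:
        for child in node.children:
            s = _transition_sample(state, float(child.length or 0.0),
                                   model.gain_rate, model.loss_rate, rng)
            if child.is_tip():
                states[child.name] = s
            else:
                _descend(child, s)

    _descend(model.tree, root_state)
    presence = pd.DataFrame(states)[model.taxa]
    presence.loc[is_core, :] = 1
    return presence, is_core


def sample_counts(presence: pd.DataFrame, model: TurnoverModel,
                  is_core: np.ndarray | None = None,
                  rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Poisson fragment sampling on top of the true presence states.

    Each transcribed window draws one log-normal expression level lambda,
    shared across taxa (core windows scaled by ``core_multiplier``); each
    sample (taxon x tissue x replicate) then draws
    count ~ Poisson(lambda * depth) where the taxon's state is present,
    else 0 (plus optional uniform background singletons).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([model.seed, 1]))
    if is_core is None:
        is_core = np.zeros(model.n_windows, dtype=bool)
    n = model.n_windows
    lam = rng.lognormal(model.lognorm_mu, model.lognorm_sigma, size=n)
    lam = np.where(is_core, lam * model.core_multiplier, lam)
    windows = make_windows({"chr1": n * model.window_size}, model.window_size)
    cols = {}
    meta = []
    for taxon in presence.columns:
        state = presence[taxon].to_numpy()
        mean = lam * model.depth * state
        for ti in range(model.n_tissues):
            tissue = DEFAULT_TISSUES[ti % len(DEFAULT_TISSUES)] \
                if ti < len(DEFAULT_TISSUES) else f"tissue{ti}"
            for rep in range(model.n_replicates):
                sid = f"{taxon}_{tissue}_{rep}"
                c = rng.poisson(mean)
                if model.background_noise > 0:
                    noise = (rng.random(n) < model.background_noise) & (state == 0)
                    c = c + noise.astype(np.int64)
                cols[sid] = c
                meta.append({"sample_id": sid, "taxon": taxon,
                             "tissue": tissue, "replicate": rep})
    counts = CountMatrix(
        counts=pd.DataFrame(cols, index=windows["index"]),
        samples=pd.DataFrame(meta).set_index("sample_id"),
    )
    return SimulatedDataset(model=model, windows=windows, counts=counts,
                            true_presence=presence, true_tree=model.tree,
                            is_core=is_core,
                            expression=np.where(lam > 0, lam, 0.0))


def simulate_dataset(model: TurnoverModel) -> SimulatedDataset:
    """Full generative run: evolve presence states, then sample counts."""
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 0]))
    presence, is_core = evolve_presence(model, rng=rng)
    rng2 = np.random.default_rng(np.random.SeedSequence([model.seed, 1]))
    return sample_counts(presence, model, is_core=is_core, rng=rng2)


def simulate_genomic_coverage(model: TurnoverModel, dropout: float = 0.05,
                              taxa: list | None = None,
                              mean_depth: float = 3.0,
                              seed: int | None = None) -> CountMatrix:
    """Genomic-read counts for common-genome masking.

    Each taxon covers each window independently with probability
    1 - dropout; covered windows get a positive Poisson(mean_depth) count
    (shifted to be >= 1).  Masks built from this matrix are strictly
    smaller than the grid whenever dropout > 0.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    if taxa is None:
        taxa = model.taxa
    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed if seed is None else seed, 2]))
    n = model.n_windows
    cols = {}
    meta = []
    for taxon in taxa:
        covered = rng.random(n) >= dropout
        c = (1 + rng.poisson(mean_depth, size=n)) * covered
        sid = f"{taxon}_genomic"
        cols[sid] = c.astype(np.int64)
        meta.append({"sample_id": sid, "taxon": taxon, "tissue": "genomic",
                     "replicate": 0})
    return CountMatrix(
        counts=pd.DataFrame(cols, index=pd.RangeIndex(n)),
        samples=pd.DataFrame(meta).set_index("sample_id"),
    )
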