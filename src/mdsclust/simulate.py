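"""Synthetic four-cluster OTU datasets under two generative scenarios.

Scenario "dm": per cluster, a Dirichlet-multinomial — sample proportions
pi_i ~ Dirichlet(pi (1-theta)/theta), counts X_i ~ Multinomial(pi_i, N_i).
Scenario "ln": per cluster, a logistic-normal multinomial — logit-scale
y_i ~ N(mu, Sigma) with the last OTU as reference, proportions by the
additive-logistic inverse, counts multinomial.

Cluster structure is sparse by design: the four clusters share a long-tailed
baseline composition and differ only on a small OTU subset (all OTUs of the
three most- or least-abundant of 20 abundance groups, or 20 OTUs from each
of three random groups), scaled by a signal-strength multiplier.  Sequencing
depths follow a truncated normal on [2000, 50000] with mean 10000 and sd
15000.  A random binary phylogeny places group-mates as neighbouring
leaves so "lineage" subsets are phylogenetically coherent.

Clusters 2-4 are made mutually distinguishable as follows: in the lineage
modes they share the subset but apply the multiplier with exponents
+1, -1 and +2 respectively; in random mode each draws its own subset.
All randomness flows from the design's master seed through named
SeedSequence spawns, so a SimResult is a pure function of its SimDesign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import softmax
from scipy.stats import truncnorm
from skbio import TreeNode

from .io import LabelVector, OtuTable

__all__ = [
    "DmParams",
    "LnParams",
    "SimDesign",
    "SimResult",
    "sample_depths",
    "baseline_dm_params",
    "baseline_ln_params",
    "choose_subset",
    "perturb_dm",
    "perturb_ln",
    "simulate_dm",
    "simulate_ln",
    "simulate",
    "random_tree",
]

# lineage-mode multiplier exponents for clusters 2, 3 and 4
_CLUSTER_EXPONENTS = (1.0, -1.0, 2.0)


@dataclass(frozen=True)
class DmParams:
    """Dirichlet-multinomial cluster parameters: proportions and dispersion."""

    pi: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be strictly positive and sum to 1")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must lie in [0, 1)")

    @property
    def concentration(self) -> np.ndarray:
        """Dirichlet concentration alpha = pi (1-theta)/theta."""
        if self.theta == 0:
            raise ValueError("theta = 0 has no Dirichlet representation")
        return self.pi * (1.0 - self.theta) / self.theta


@dataclass(frozen=True)
class LnParams:
    """Logistic-normal cluster parameters on the logit scale.

    mu and sigma have dimension P-1; the last OTU is the additive-logistic
    reference.
    """

    mu: np.ndarray
    sigma: np.ndarray
    reference: int = -1

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if sigma.shape != (mu.size, mu.size):
            raise ValueError("sigma must be (P-1) x (P-1)")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        eigmin = np.linalg.eigvalsh(sigma).min() if mu.size else 0.0
        if eigmin < -1e-8:
            raise ValueError("sigma must be positive semi-definite")


@dataclass(frozen=True)
class SimDesign:
    """Full specification of one synthetic dataset."""

    scenario: str = "dm"  # dm | ln
    n_clusters: int = 4
    per_cluster_n: int = 100
    P: int = 856
    n_groups: int = 20
    subset_type: str = "random"  # common_lineage | rare_lineage | random
    subset_per_group: int = 20  # random mode: OTUs drawn per chosen group
    signal_strength: float = 1.4  # dm multiplier
    mean_factor: Optional[float] = None  # ln multiplier; default by subset type
    theta: float = 0.001
    abundance_sigma: float = 0.5  # log-normal spread of the baseline profile
    ln_tau: float = 2.0  # logit-scale marginal sd
    ln_rho: float = 0.2  # logit-scale AR(1) correlation
    depth_mean: float = 10_000.0
    depth_sd: float = 15_000.0
    depth_lower: float = 2_000.0
    depth_upper: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("dm", "ln"):
            raise ValueError("scenario must be 'dm' or 'ln'")
        if self.subset_type not in ("common_lineage", "rare_lineage", "random"):
            raise ValueError("unknown subset_type")
        if self.signal_strength <= 0:
            raise ValueError("signal_strength must be positive")
        if self.depth_lower >= self.depth_upper:
            raise ValueError("depth_lower must be below depth_upper")

    @property
    def n_samples(self) -> int:
        return self.n_clusters * self.per_cluster_n

    def resolved_mean_factor(self) -> float:
        """LN logit-mean multiplier; defaults depend on the subset type."""
        if self.mean_factor is not None:
            return self.mean_factor
        return {"common_lineage": 2.75, "rare_lineage": 5.8, "random": 3.6}[self.subset_type]


@dataclass(frozen=True)
class SimResult:
    """A generated dataset: counts, truth, phylogeny and the parameters used."""

    table: OtuTable
    truth: LabelVector
    tree: TreeNode
    design: SimDesign
    cluster_params: tuple
    groups: np.ndarray  # abundance-group id (1..n_groups) per OTU
    subsets: tuple  # OTU index arrays used for clusters 2..n_clusters


def sample_depths(n, mean, sd, lower, upper, seed) -> np.ndarray:
    """Integer sequencing depths from a truncated normal (inverse-CDF)."""
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sd <= 0:
        depth = int(np.rint(np.clip(mean, lower, upper)))
        return np.full(n, depth, dtype=np.int64)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    draws = truncnorm.ppf(rng.random(n), a, b, loc=mean, scale=sd)
    return np.rint(draws).astype(np.int64)


def baseline_dm_params(P, n_groups, seed, abundance_sigma: float = 0.5, theta: float = 0.001):
    """Long-tailed baseline composition plus rank-based abundance groups.

    OTU magnitudes are log-normal (median 1, log-sd ``abundance_sigma``),
    closed to proportions.  OTUs are ranked by abundance and split into
    ``n_groups`` contiguous rank bins; group 1 holds the most abundant
    OTUs, group ``n_groups`` the least.
    """
    if n_groups > P:
        raise ValueError("more groups than OTUs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mags = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=P)
    pi = mags / mags.sum()
    order = np.argsort(-pi, kind="stable")
    groups = np.empty(P, dtype=int)
    edges = np.linspace(0, P, n_groups + 1).round().astype(int)
    for g in range(n_groups):
        groups[order[edges[g] : edges[g + 1]]] = g + 1
    return DmParams(pi=pi, theta=theta), groups


def choose_subset(groups, subset_type, rng, per_group: int = 20, n_pick: int = 3) -> np.ndarray:
    """Select the OTU indices carrying the cluster-differentiation signal."""
    groups = np.asarray(groups)
    n_groups = groups.max()
    if subset_type == "common_lineage":
        return np.flatnonzero(np.isin(groups, [1, 2, 3]))
    if subset_type == "rare_lineage":
        tail = [n_groups - 2, n_groups - 1, n_groups]
        return np.flatnonzero(np.isin(groups, tail))
    if subset_type != "random":
        raise ValueError(f"unknown subset_type {subset_type!r}")
    chosen_groups = rng.choice(np.arange(1, n_groups + 1), size=n_pick, replace=False)
    picks = []
    for g in chosen_groups:
        members = np.flatnonzero(groups == g)
        if members.size < per_group:
            import warnings

            warnings.warn(f"group {g} has only {members.size} OTUs; taking all", stacklevel=2)
            picks.append(members)
        else:
            picks.append(rng.choice(members, size=per_group, replace=False))
    return np.sort(np.concatenate(picks))


def perturb_dm(base: DmParams, subset, signal_strength: float) -> DmParams:
    """Scale pi on the subset by the signal strength and re-close; theta kept."""
    if signal_strength <= 0:
        raise ValueError("signal_strength must be positive")
    pi = base.pi.copy()
    pi[np.asarray(subset)] *= signal_strength
    return DmParams(pi=pi / pi.sum(), theta=base.theta)


def perturb_ln(base: LnParams, subset, factor: float) -> LnParams:
    """Multiply the logit-scale mean on the subset by ``factor``.

    A subset index equal to the reference OTU has no logit coordinate and
    is ignored.
    """
    mu = base.mu.copy()
    idx = np.asarray(subset)
    idx = idx[idx < mu.size]
    mu[idx] = mu[idx] * factor
    return LnParams(mu=mu, sigma=base.sigma, reference=base.reference)


def baseline_ln_params(pi, tau: float, rho: float) -> LnParams:
    """Logit-scale baseline from a composition: mu_p = ln(pi_p / pi_P).

    Sigma is stationary AR(1): tau^2 rho^|p-q|, a diagonal-dominant
    stand-in for the dependence structure of real logit-transformed
    abundances.
    """
    pi = np.asarray(pi, dtype=float)
    mu = np.log(pi[:-1] / pi[-1])
    idx = np.arange(mu.size)
    sigma = tau**2 * rho ** np.abs(idx[:, None] - idx[None, :])
    return LnParams(mu=mu, sigma=sigma)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _ids(design: SimDesign) -> tuple[list[str], list[str]]:
    samples = [f"s{i:04d}" for i in range(design.n_samples)]
    otus = [f"otu{p:04d}" for p in range(design.P)]
    return samples, otus


def _cluster_subsets(design: SimDesign, groups: np.ndarray, rng) -> list[np.ndarray]:
    """One subset per non-baseline cluster (shared in lineage modes)."""
    if design.subset_type == "random":
        return [
            choose_subset(groups, "random", rng, per_group=design.subset_per_group)
            for _ in range(design.n_clusters - 1)
        ]
    shared = choose_subset(groups, design.subset_type, rng)
    return [shared] * (design.n_clusters - 1)


def simulate_dm(design: SimDesign) -> SimResult:
    """Generate counts under the Dirichlet-multinomial scenario."""
    if design.scenario != "dm":
        raise ValueError("design.scenario must be 'dm'")
    rng_base, rng_subset, rng_depth, rng_count, rng_tree = _spawn_rngs(design.seed, 5)
    base, groups = baseline_dm_params(
        design.P, design.n_groups, rng_base, design.abundance_sigma, design.theta
    )
    subsets = _cluster_subsets(design, groups, rng_subset)
    params = [base]
    for c, subset in enumerate(subsets):
        if design.subset_type == "random":
            strength = design.signal_strength
        else:
            strength = design.signal_strength ** _CLUSTER_EXPONENTS[c % 3]
        params.append(perturb_dm(base, subset, strength))
    depths = sample_depths(
        design.n_samples,
        design.depth_mean,
        design.depth_sd,
        design.depth_lower,
        design.depth_upper,
        rng_depth,
    )
    counts = np.empty((design.n_samples, design.P), dtype=np.int64)
    labels = np.empty(design.n_samples, dtype=int)
    for c, par in enumerate(params):
        rows = slice(c * design.per_cluster_n, (c + 1) * design.per_cluster_n)
        labels[rows] = c + 1
        if par.theta == 0:
            probs = np.tile(par.pi, (design.per_cluster_n, 1))
        else:
            probs = rng_count.dirichlet(par.concentration, size=design.per_cluster_n)
        counts[rows] = rng_count.multinomial(depths[rows], probs)
    samples, otus = _ids(design)
    table = OtuTable(sample_ids=samples, otu_ids=otus, values=counts.astype(float))
    truth = LabelVector(sample_ids=samples, labels=labels)
    tree = random_tree(otus, rng_tree, groups=groups)
    return SimResult(table, truth, tree, design, tuple(params), groups, tuple(subsets))


def simulate_ln(design: SimDesign) -> SimResult:
    """Generate counts under the logistic-normal multinomial scenario."""
    if design.scenario != "ln":
        raise ValueError("design.scenario must be 'ln'")
    rng_base, rng_subset, rng_depth, rng_count, rng_tree = _spawn_rngs(design.seed, 5)
    base_dm, groups = baseline_dm_params(
        design.P, design.n_groups, rng_base, design.abundance_sigma, design.theta
    )
    base = baseline_ln_params(base_dm.pi, design.ln_tau, design.ln_rho)
    subsets = _cluster_subsets(design, groups, rng_subset)
    factor = design.resolved_mean_factor()
    params = [base]
    for c, subset in enumerate(subsets):
        f = factor if design.subset_type == "random" else factor ** _CLUSTER_EXPONENTS[c % 3]
        params.append(perturb_ln(base, subset, f))
    depths = sample_depths(
        design.n_samples,
        design.depth_mean,
        design.depth_sd,
        design.depth_lower,
        design.depth_upper,
        rng_depth,
    )
    chol = np.linalg.cholesky(base.sigma + 1e-10 * np.eye(design.P - 1))
    counts = np.empty((design.n_samples, design.P), dtype=np.int64)
    labels = np.empty(design.n_samples, dtype=int)
    for c, par in enumerate(params):
        rows = slice(c * design.per_cluster_n, (c + 1) * design.per_cluster_n)
        labels[rows] = c + 1
        z = rng_count.standard_normal((design.per_cluster_n, design.P - 1))
        y = par.mu + z @ chol.T
        # additive-logistic inverse via a stable softmax over (y, 0)
        probs = softmax(np.hstack([y, np.zeros((y.shape[0], 1))]), axis=1)
        counts[rows] = rng_count.multinomial(depths[rows], probs)
    samples, otus = _ids(design)
    table = OtuTable(sample_ids=samples, otu_ids=otus, values=counts.astype(float))
    truth = LabelVector(sample_ids=samples, labels=labels)
    tree = random_tree(otus, rng_tree, groups=groups)
    return SimResult(table, truth, tree, design, tuple(params), groups, tuple(subsets))


def simulate(design: SimDesign) -> SimResult:
    """Dispatch on the design's scenario."""
    return simulate_dm(design) if design.scenario == "dm" else simulate_ln(design)


def random_tree(otu_ids: Sequence[str], seed, groups=None) -> TreeNode:
    """Random rooted binary tree with Exponential(1) branch lengths.

    When abundance ``groups`` are given, each group's OTUs are first joined
    into their own random subtree and the group subtrees are then joined,
    so group-mates are phylogenetically adjacent (coherent "lineages").
    """
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTUs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if groups is None:
        pools = [list(otu_ids)]
    else:
        groups = np.asarray(groups)
        pools = [
            [otu_ids[i] for i in np.flatnonzero(groups == g)]
            for g in range(1, groups.max() + 1)
        ]
        pools = [p for p in pools if p]
    subtrees = []
    for pool in pools:
        nodes = [TreeNode(name=name, length=float(rng.exponential())) for name in pool]
        subtrees.append(_join_random(nodes, rng))
    root = _join_random(subtrees, rng)
    root.length = None
    return root


def _join_random(nodes: list[TreeNode], rng) -> TreeNode:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential()))
        parent.append(a)
        parent.append(b)
        nodes.append(parent)
    return nodes[0]
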