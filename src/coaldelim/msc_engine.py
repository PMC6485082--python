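"""Two-population multispecies-coalescent inference core.

The model: two populations A and B diverged at time tau from a root
population, all times and the mutation-scaled population sizes theta measured
in expected substitutions per site.  Looking backward, lineages within A (or
B) coalesce at pair rate 2/theta_A (2/theta_B) until tau, at which point the
survivors enter the root population (theta_root).  Sequences evolve along the
resulting gene tree under JC69.  Inverse-gamma priors are placed on tau and
the thetas.

Three samplers are exposed:

* :func:`run_a00` -- parameter estimation on the fixed two-population model
  (Metropolis-within-Gibbs over gene-tree ages/topology and parameters, with
  conjugate inverse-gamma Gibbs updates for the thetas);
* :func:`run_delimitation` -- reversible-jump MCMC between the merged
  (one-theta, no-tau) and split models, yielding the posterior probability of
  the split;
* :func:`convergence_check` -- across-run R-hat / ESS diagnostics.

The heavy kernels (Felsenstein pruning under JC69, coalescent sufficient
statistics) are JIT-compiled with numba.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy import stats as _sps
from scipy.special import ndtri

from .io_formats import AlignedLocus, PopulationMap
from .priors import InverseGammaPrior, PriorSet

__all__ = [
    "MSCPairModel",
    "GeneTree",
    "MCMCSettings",
    "PosteriorTrace",
    "DelimitationResult",
    "ConvergenceDiagnostics",
    "coalescent_log_density",
    "jc69_log_likelihood",
    "run_a00",
    "run_delimitation",
    "convergence_check",
]

logger = logging.getLogger(__name__)

# IUPAC symbol -> compatible states among (A, C, G, T)
AMBIGUITY = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3), "-": (0, 1, 2, 3),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSCPairModel:
    """Parameter vector of the two-population MSC (fixed topology ((A,B))).

    The split model carries all four parameters; the merged (one-population)
    model is represented with ``tau = theta_a = theta_b = None`` and the
    single theta stored in ``theta_root``.
    """

    tau: float | None
    theta_a: float | None
    theta_b: float | None
    theta_root: float

    def __post_init__(self) -> None:
        if self.theta_root <= 0:
            raise ValueError("theta_root must be positive")
        if self.is_split:
            if self.tau is None or self.tau <= 0:
                raise ValueError("split model requires tau > 0")
            if self.theta_a is None or self.theta_a <= 0 or \
               self.theta_b is None or self.theta_b <= 0:
                raise ValueError("split model requires positive theta_a, theta_b")

    @property
    def is_split(self) -> bool:
        return not (self.tau is None and self.theta_a is None and self.theta_b is None)

    @classmethod
    def merged(cls, theta: float) -> "MSCPairModel":
        return cls(tau=None, theta_a=None, theta_b=None, theta_root=theta)


@dataclass
class GeneTree:
    """Rooted binary ultrametric gene tree over ``samples``.

    Nodes ``0 .. n-1`` are tips (in ``samples`` order, age 0); nodes
    ``n .. 2n-2`` are coalescences.  ``parent`` is -1 at the root; ``left`` /
    ``right`` are -1 at tips.  Ages are in expected substitutions per site.
    """

    samples: tuple[str, ...]
    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    age: np.ndarray
    root: int

    @property
    def n_tips(self) -> int:
        return len(self.samples)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def validate(self) -> None:
        n, m = self.n_tips, self.n_nodes
        if not (len(self.parent) == len(self.age) == m):
            raise ValueError("gene tree array lengths inconsistent")
        if self.parent[self.root] != -1:
            raise ValueError("root must have parent -1")
        for v in range(m):
            if v < n:
                if self.age[v] != 0.0:
                    raise ValueError("tip ages must be 0")
            else:
                for c in (self.left[v], self.right[v]):
                    if self.parent[c] != v:
                        raise ValueError("parent/child arrays inconsistent")
                    if not self.age[c] < self.age[v]:
                        raise ValueError("child age must be below parent age")

    def newick(self) -> str:
        def rec(v: int) -> str:
            if v < self.n_tips:
                lab = self.samples[v]
            else:
                lab = ""
            if v >= self.n_tips:
                inner = f"({rec(self.left[v])},{rec(self.right[v])})"
            else:
                inner = lab
            p = self.parent[v]
            if p == -1:
                return inner + ";"
            bl = self.age[p] - self.age[v]
            return f"{inner}:{bl:.10g}"

        return rec(self.root)

    def tip_populations(self, popmap: PopulationMap) -> np.ndarray:
        """0/1 codes against ``popmap.populations`` order (max 2 pops)."""
        pops = popmap.populations
        if len(pops) > 2:
            raise ValueError("pair engine supports at most 2 populations")
        code = {p: i for i, p in enumerate(pops)}
        return np.array(
            [code[popmap.population_of(s)] for s in self.samples], dtype=np.int64
        )


@dataclass(frozen=True)
class MCMCSettings:
    """Chain-length settings: recorded samples, burn-in sweeps, thinning."""

    samples: int = 100_000
    burnin: int = 10_000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.samples < 1 or self.burnin < 0 or self.thin < 1:
            raise ValueError("require samples >= 1, burnin >= 0, thin >= 1")

    @property
    def total_sweeps(self) -> int:
        return self.burnin + self.samples * self.thin


@dataclass
class PosteriorTrace:
    """Recorded MCMC draws of the MSC parameters for one run."""

    draws: dict[str, np.ndarray]
    settings: MCMCSettings
    seed: int
    run_id: int
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        n = self.settings.samples
        for k, v in self.draws.items():
            if len(v) != n:
                raise ValueError(f"trace column {k!r} has {len(v)} draws, expected {n}")
            if k not in ("loglik", "model"):
                if np.any(np.asarray(v) <= 0):
                    raise ValueError(f"non-positive draws in column {k!r}")

    def __len__(self) -> int:
        return self.settings.samples

    def __getattr__(self, name: str):
        draws = object.__getattribute__(self, "draws")
        if name in draws:
            return draws[name]
        raise AttributeError(name)

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(k for k in self.draws if k not in ("loglik", "model"))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.draws)


@dataclass(frozen=True)
class DelimitationResult:
    """Split-vs-merge model choice: posterior probability and support band."""

    pp_split: float
    support_band: str
    per_run_pp: tuple[float, ...]
    convergence_warning: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.pp_split <= 1.0:
            raise ValueError("pp_split must lie in [0, 1]")


def support_band(pp: float) -> str:
    """BPP-style bands: high (pp >= 0.95), moderate (0.90 <= pp < 0.95), weak."""
    if pp >= 0.95:
        return "high"
    if pp >= 0.90:
        return "moderate"
    return "weak"


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _jc69_loglik_kernel(root, left, right, age, tip_partials, weights):
    n_tips, P, _ = tip_partials.shape
    n_nodes = 2 * n_tips - 1
    partial = np.empty((n_nodes, P, 4))
    for i in range(n_tips):
        partial[i] = tip_partials[i]
    logscale = np.zeros(P)
    # iterative postorder over internal nodes
    stack = np.empty(2 * n_nodes, np.int64)
    state = np.empty(2 * n_nodes, np.int64)
    order = np.empty(n_tips - 1, np.int64)
    sp = 0
    stack[0] = root
    state[0] = 0
    sp = 1
    no = 0
    while sp > 0:
        node = stack[sp - 1]
        st = state[sp - 1]
        if node < n_tips or st == 1:
            sp -= 1
            if node >= n_tips:
                order[no] = node
                no += 1
        else:
            state[sp - 1] = 1
            stack[sp] = left[node]
            state[sp] = 0
            sp += 1
            stack[sp] = right[node]
            state[sp] = 0
            sp += 1
    contrib = np.empty((2, 4))
    for idx in range(no):
        node = order[idx]
        c0 = left[node]
        c1 = right[node]
        t0 = age[node] - age[c0]
        t1 = age[node] - age[c1]
        e0 = math.exp(-4.0 * t0 / 3.0)
        e1 = math.exp(-4.0 * t1 / 3.0)
        for p in range(P):
            tot0 = 0.0
            tot1 = 0.0
            for s in range(4):
                tot0 += partial[c0, p, s]
                tot1 += partial[c1, p, s]
            m = 0.0
            for s in range(4):
                a = 0.25 * (1.0 - e0) * tot0 + e0 * partial[c0, p, s]
                b = 0.25 * (1.0 - e1) * tot1 + e1 * partial[c1, p, s]
                v = a * b
                partial[node, p, s] = v
                if v > m:
                    m = v
            for s in range(4):
                partial[node, p, s] /= m
            logscale[p] += math.log(m)
    ll = 0.0
    for p in range(P):
        lik = 0.0
        for s in range(4):
            lik += partial[root, p, s]
        ll += weights[p] * (math.log(0.25 * lik) + logscale[p])
    return ll


@njit(cache=False)
def _coal_stats_kernel(ages, masks, tau, n_a, n_b, merged):
    """Coalescent sufficient statistics per population.

    Returns (valid, c_a, S_a, c_b, S_b, c_r, S_r) where c is the coalescence
    count and S the integral of k(k-1) dt in that population; the gene-tree
    density given thetas is  prod_pop (2/theta)^c * exp(-S/theta).
    """
    n_int = ages.shape[0]
    idx = np.argsort(ages)
    c_a = 0
    c_b = 0
    c_r = 0
    S_a = 0.0
    S_b = 0.0
    S_r = 0.0
    if merged:
        k = n_a + n_b
        t_prev = 0.0
        for ii in range(n_int):
            t = ages[idx[ii]]
            S_r += k * (k - 1) * (t - t_prev)
            k -= 1
            t_prev = t
            c_r += 1
        return True, c_a, S_a, c_b, S_b, c_r, S_r
    # split model: A and B truncated at tau, survivors enter root
    kA = n_a
    kB = n_b
    tA = 0.0
    tB = 0.0
    for ii in range(n_int):
        i = idx[ii]
        t = ages[i]
        if t < tau:
            if masks[i] == 3:
                return False, 0, 0.0, 0, 0.0, 0, 0.0
            if masks[i] == 1:
                S_a += kA * (kA - 1) * (t - tA)
                kA -= 1
                tA = t
                c_a += 1
            else:
                S_b += kB * (kB - 1) * (t - tB)
                kB -= 1
                tB = t
                c_b += 1
    S_a += kA * (kA - 1) * (tau - tA)
    S_b += kB * (kB - 1) * (tau - tB)
    k = kA + kB
    t_prev = tau
    for ii in range(n_int):
        i = idx[ii]
        t = ages[i]
        if t >= tau:
            S_r += k * (k - 1) * (t - t_prev)
            k -= 1
            t_prev = t
            c_r += 1
    return True, c_a, S_a, c_b, S_b, c_r, S_r


def _coal_logdens_from_stats(stats, tau, th_a, th_b, th_r, merged) -> float:
    valid, c_a, S_a, c_b, S_b, c_r, S_r = stats
    if not valid:
        return -np.inf
    if merged:
        return c_r * math.log(2.0 / th_r) - S_r / th_r
    return (
        c_a * math.log(2.0 / th_a) - S_a / th_a
        + c_b * math.log(2.0 / th_b) - S_b / th_b
        + c_r * math.log(2.0 / th_r) - S_r / th_r
    )


# ---------------------------------------------------------------------------
# Public density / likelihood functions
# ---------------------------------------------------------------------------


def _subtree_masks(tree_left, tree_right, root, n_tips, tip_pop) -> np.ndarray:
    """Bitmask per node: 1 = contains A tips, 2 = contains B tips."""
    n_nodes = 2 * n_tips - 1
    mask = np.zeros(n_nodes, dtype=np.int64)
    stack = [(root, False)]
    while stack:
        v, done = stack.pop()
        if v < n_tips:
            mask[v] = 1 << int(tip_pop[v])
        elif done:
            mask[v] = mask[tree_left[v]] | mask[tree_right[v]]
        else:
            stack.append((v, True))
            stack.append((tree_left[v], False))
            stack.append((tree_right[v], False))
    return mask


class TauConstraintViolation(ValueError):
    """A cross-population coalescence occurs below the divergence time tau."""

    def __init__(self, node: int, age: float, tau: float):
        self.node, self.age, self.tau = node, age, tau
        super().__init__(
            f"gene-tree node {node} joins lineages of both populations at age "
            f"{age:.6g} < tau = {tau:.6g}"
        )


def coalescent_log_density(
    genetree: GeneTree, model: MSCPairModel, popmap: PopulationMap
) -> float:
    """Log-density of ``genetree`` under the (split or merged) MSC.

    Within each population with k lineages each pair coalesces at rate
    2/theta (aggregate k(k-1)/theta); within-A and within-B coalescents are
    truncated at tau, after which surviving lineages coalesce in the root
    population.  A gene tree that joins lineages of A and B below tau has
    density zero; ``-inf`` is returned and a structured
    :class:`TauConstraintViolation` is attached in the log.
    """
    genetree.validate()
    tip_pop = genetree.tip_populations(popmap)
    n = genetree.n_tips
    n_a = int((tip_pop == 0).sum())
    n_b = int((tip_pop == 1).sum())
    mask = _subtree_masks(genetree.left, genetree.right, genetree.root, n, tip_pop)
    ages = genetree.age[n:]
    masks = mask[n:]
    merged = not model.is_split
    tau = 0.0 if merged else float(model.tau)
    st = _coal_stats_kernel(
        np.ascontiguousarray(ages), np.ascontiguousarray(masks),
        tau, n_a, n_b, merged,
    )
    if not st[0]:
        bad = np.where((masks == 3) & (ages < tau))[0]
        v = int(bad[0]) + n
        logger.warning("%s", TauConstraintViolation(v, float(genetree.age[v]), tau))
        return -np.inf
    return _coal_logdens_from_stats(
        st, tau, model.theta_a, model.theta_b, model.theta_root, merged
    )


def _tip_partials(locus: AlignedLocus, samples: Sequence[str]):
    """Pattern-compressed per-tip partial likelihoods (n_tips, P, 4)."""
    seqs = [locus.sequence_of(s) for s in samples]
    n, L = len(seqs), len(seqs[0])
    sym = sorted(AMBIGUITY)
    code = {c: i for i, c in enumerate(sym)}
    mat = np.array([[code[c] for c in s] for s in seqs], dtype=np.int8)
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    table = np.zeros((len(sym), 4))
    for c, i in code.items():
        for s in AMBIGUITY[c]:
            table[i, s] = 1.0
    tp = table[patterns]  # (n, P, 4)
    return np.ascontiguousarray(tp), weights.astype(np.float64)


def jc69_log_likelihood(genetree: GeneTree, locus: AlignedLocus) -> float:
    """Felsenstein-pruning log-likelihood under JC69 (frequencies 1/4).

    Ambiguity codes contribute partial likelihood one over their compatible
    states; per-site rescaling keeps the computation stable; by reversibility
    the root placement does not affect the value.
    """
    if set(genetree.samples) != set(locus.samples):
        raise ValueError("gene-tree tips and alignment samples differ")
    tp, w = _tip_partials(locus, genetree.samples)
    return float(
        _jc69_loglik_kernel(
            genetree.root, genetree.left, genetree.right, genetree.age, tp, w
        )
    )


# ---------------------------------------------------------------------------
# Gene-tree simulation on arrays (shared with synthetic_data)
# ---------------------------------------------------------------------------


def _simulate_genetree_arrays(
    rng: np.random.Generator,
    tip_pop: np.ndarray,
    tau: float,
    theta_a: float,
    theta_b: float,
    theta_root: float,
):
    """Structured-coalescent simulation; returns (parent, left, right, age, root).

    ``tau = inf`` with a single population code simulates the plain coalescent.
    """
    n = len(tip_pop)
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    age = np.zeros(m)
    nxt = n

    def coalesce_phase(lineages: list[int], theta: float, t0: float, t_end: float):
        nonlocal nxt
        t = t0
        while len(lineages) >= 2:
            k = len(lineages)
            rate = k * (k - 1) / theta
            t_next = t + rng.exponential(1.0 / rate)
            if t_next >= t_end:
                return lineages, t_end
            t = t_next
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            v = nxt
            nxt += 1
            parent[a] = parent[b] = v
            left[v], right[v] = a, b
            age[v] = t
            lineages = [x for x in lineages if x not in (a, b)] + [v]
        return lineages, t_end

    la = [i for i in range(n) if tip_pop[i] == 0]
    lb = [i for i in range(n) if tip_pop[i] == 1]
    if math.isinf(tau):
        if lb:
            raise ValueError("merged simulation expects a single population code")
        la, _ = coalesce_phase(la, theta_a, 0.0, np.inf)
        root = la[0]
        return parent, left, right, age, root
    la, _ = coalesce_phase(la, theta_a, 0.0, tau) if la else (la, tau)
    lb, _ = coalesce_phase(lb, theta_b, 0.0, tau) if lb else (lb, tau)
    lin = la + lb
    lin, _ = coalesce_phase(lin, theta_root, tau, np.inf)
    root = lin[0]
    return parent, left, right, age, root


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

SPLIT, MERGED = 1, 0


class _PairSampler:
    """Metropolis-within-Gibbs sampler for the two-population MSC.

    Moves per sweep: per-node age slides, fixed-height subtree regrafts,
    a whole-tree independence refresh from the coalescent prior, conjugate
    inverse-gamma Gibbs updates for the thetas, multiplicative random-walk
    updates for tau, one joint rescale (mixing) move, and -- in trans-model
    mode -- one reversible-jump switch between the merged and split models
    with all new parameters proposed from their priors.
    """

    def __init__(
        self,
        tip_pop: np.ndarray,
        priors: PriorSet,
        rng: np.random.Generator,
        tip_partials=None,
        weights=None,
        prior_only: bool = False,
        trans_model: bool = False,
        fixed_tree: GeneTree | None = None,
    ):
        self.rng = rng
        self.tip_pop = np.asarray(tip_pop, dtype=np.int64)
        self.n_tips = len(tip_pop)
        self.n_a = int((self.tip_pop == 0).sum())
        self.n_b = int((self.tip_pop == 1).sum())
        self.single_pop = self.n_b == 0
        self.priors = priors
        self.prior_only = prior_only or tip_partials is None
        self.trans_model = trans_model and not self.single_pop
        self.tip_partials = tip_partials
        self.pattern_w = weights
        self.fixed_tree = fixed_tree is not None

        tp, taup = priors.theta_prior, priors.tau_prior
        self.th_a = tp.sample(rng)
        self.th_b = tp.sample(rng)
        self.th_r = tp.sample(rng)
        self.th_m = tp.sample(rng)
        self.tau = taup.sample(rng)
        self.model = MERGED if self.single_pop else SPLIT
        if self.trans_model:
            self.model = SPLIT if rng.random() < 0.5 else MERGED

        if fixed_tree is not None:
            self.parent = fixed_tree.parent.copy()
            self.left = fixed_tree.left.copy()
            self.right = fixed_tree.right.copy()
            self.age = fixed_tree.age.copy()
            self.root = fixed_tree.root
            # tau must sit below any cross-population coalescence
            self._refresh_mask()
            if not self.single_pop:
                mixed = self.age[self.n_tips:][self.mask[self.n_tips:] == 3]
                if mixed.size and self.tau >= mixed.min():
                    self.tau = 0.5 * float(mixed.min())
        else:
            self._resimulate_tree()
        self._refresh_mask()
        self.loglik = self._loglik()

        # tuned proposal step sizes (frozen after burn-in)
        scale = (taup.beta / taup.alpha) + (tp.beta / tp.alpha)
        self.age_delta = max(scale, 1e-6)
        self.root_eps = 1.0
        self.tau_eps = 1.0
        self.mix_eps = 0.4
        self._acc = np.zeros(4)
        self._try = np.zeros(4)
        self.tuning = True

    # -- state helpers ------------------------------------------------------

    def _cur_tau_thetas(self):
        if self.model == SPLIT and not self.single_pop:
            return self.tau, self.th_a, self.th_b, self.th_r, False
        th = self.th_a if self.single_pop else self.th_m
        return 0.0, 1.0, 1.0, th, True

    def _resimulate_tree(self):
        tau, tha, thb, thr, merged = self._cur_tau_thetas()
        if merged:
            pop = np.zeros_like(self.tip_pop)
            p, l, r, a, root = _simulate_genetree_arrays(
                self.rng, pop, np.inf, thr, thr, thr
            )
        else:
            p, l, r, a, root = _simulate_genetree_arrays(
                self.rng, self.tip_pop, tau, tha, thb, thr
            )
        self.parent, self.left, self.right, self.age, self.root = p, l, r, a, root

    def _refresh_mask(self):
        self.mask = _subtree_masks(
            self.left, self.right, self.root, self.n_tips, self.tip_pop
        )

    def _coal_stats(self, tau: float, merged: bool):
        return _coal_stats_kernel(
            np.ascontiguousarray(self.age[self.n_tips:]),
            np.ascontiguousarray(self.mask[self.n_tips:]),
            tau, self.n_a, self.n_b, merged,
        )

    def _coal_logdens(self) -> float:
        tau, tha, thb, thr, merged = self._cur_tau_thetas()
        return _coal_logdens_from_stats(
            self._coal_stats(tau, merged), tau, tha, thb, thr, merged
        )

    def _loglik(self) -> float:
        if self.prior_only:
            return 0.0
        return float(
            _jc69_loglik_kernel(
                self.root, self.left, self.right, self.age,
                self.tip_partials, self.pattern_w,
            )
        )

    def _log_prior_params(self) -> float:
        tp, taup = self.priors.theta_prior, self.priors.tau_prior
        if self.model == SPLIT and not self.single_pop:
            return (
                tp.log_pdf(self.th_a) + tp.log_pdf(self.th_b)
                + tp.log_pdf(self.th_r) + taup.log_pdf(self.tau)
            )
        th = self.th_a if self.single_pop else self.th_m
        return tp.log_pdf(th)

    def log_posterior(self) -> float:
        return self._log_prior_params() + self._coal_logdens() + self.loglik

    # -- moves --------------------------------------------------------------

    def _move_age(self, v: int):
        rng = self.rng
        lo = max(self.age[self.left[v]], self.age[self.right[v]])
        if self.model == SPLIT and not self.single_pop and self.mask[v] == 3:
            lo = max(lo, self.tau)
        p = self.parent[v]
        old_cd = self._coal_logdens()
        old_age = self.age[v]
        is_root = p == -1
        if is_root:
            # root: multiplicative proposal on the offset above lo
            y = old_age - lo
            c = math.exp(self.root_eps * (rng.random() - 0.5))
            new_age = lo + y * c
            log_hastings = math.log(c)
        else:
            hi = self.age[p]
            d = self.age_delta
            a0, b0 = max(lo, old_age - d), min(hi, old_age + d)
            new_age = rng.uniform(a0, b0)
            a1, b1 = max(lo, new_age - d), min(hi, new_age + d)
            log_hastings = math.log((b0 - a0) / (b1 - a1))
        self.age[v] = new_age
        new_cd = self._coal_logdens()
        new_ll = self._loglik()
        log_r = (new_cd + new_ll) - (old_cd + self.loglik) + log_hastings
        ctr = 1 if is_root else 0
        self._try[ctr] += 1
        if math.log(rng.random() + 1e-300) < log_r:
            self.loglik = new_ll
            self._acc[ctr] += 1
        else:
            self.age[v] = old_age

    def _descendants(self, v: int) -> set[int]:
        out, stack = set(), [v]
        while stack:
            x = stack.pop()
            out.add(x)
            if x >= self.n_tips:
                stack.extend((self.left[x], self.right[x]))
        return out

    def _move_regraft(self):
        """Detach a subtree and reattach at the same height; Hastings ratio 1.

        The coalescent density is invariant (event ages and residences are
        unchanged), so acceptance depends on the sequence likelihood only.
        """
        rng = self.rng
        n = self.n_tips
        internal = [v for v in range(n, 2 * n - 1)]
        v = internal[rng.integers(len(internal))]
        s = self.left[v] if rng.random() < 0.5 else self.right[v]
        o = self.right[v] if s == self.left[v] else self.left[v]
        t_v = self.age[v]
        sub = self._descendants(s)
        g = self.parent[v]
        # prune: v disappears, o takes its place
        if g == -1:
            pruned_root = o
        else:
            pruned_root = self.root
        split_mode = self.model == SPLIT and not self.single_pop
        cands = []
        for w in range(2 * n - 1):
            if w in sub or w == v:
                continue
            if self.age[w] >= t_v:
                continue
            pw = self.parent[w]
            if pw == v:
                pw = g  # o's effective parent after pruning
            if pw != -1 and self.age[pw] <= t_v and pw != v:
                continue
            if pw == -1 and w != pruned_root and w != o:
                continue
            if split_mode and t_v < self.tau and self.mask[w] != self.mask[s]:
                continue
            cands.append(w)
        if not cands:
            return
        w = cands[rng.integers(len(cands))]
        if w == o:
            return  # same attachment, tree unchanged
        old = (
            self.parent.copy(), self.left.copy(), self.right.copy(),
            self.root, self.mask.copy(),
        )
        # detach s / remove v
        if g == -1:
            self.root = o
            self.parent[o] = -1
        else:
            if self.left[g] == v:
                self.left[g] = o
            else:
                self.right[g] = o
            self.parent[o] = g
        # reattach: v joins s and w at height t_v
        pw = self.parent[w]
        if pw == -1:
            self.root = v
            self.parent[v] = -1
        else:
            if self.left[pw] == w:
                self.left[pw] = v
            else:
                self.right[pw] = v
            self.parent[v] = pw
        self.left[v], self.right[v] = s, w
        self.parent[s] = self.parent[w] = v
        self._refresh_mask()
        new_ll = self._loglik()
        if math.log(rng.random() + 1e-300) < new_ll - self.loglik:
            self.loglik = new_ll
        else:
            self.parent, self.left, self.right, self.root, self.mask = old

    def _move_tree_refresh(self):
        """Independence proposal: new gene tree from the coalescent prior."""
        old = (
            self.parent, self.left, self.right, self.age, self.root, self.mask,
        )
        self._resimulate_tree()
        self._refresh_mask()
        new_ll = self._loglik()
        if math.log(self.rng.random() + 1e-300) < new_ll - self.loglik:
            self.loglik = new_ll
        else:
            (self.parent, self.left, self.right, self.age, self.root,
             self.mask) = old

    def _gibbs_theta(self):
        tp = self.priors.theta_prior
        tau, _, _, _, merged = self._cur_tau_thetas()
        st = self._coal_stats(tau, merged)
        if not st[0]:
            return
        _, c_a, S_a, c_b, S_b, c_r, S_r = st

        def draw(c, S):
            return (tp.beta + S) / self.rng.gamma(tp.alpha + c)

        if merged:
            th = draw(c_r, S_r)
            if self.single_pop:
                self.th_a = th
            else:
                self.th_m = th
        else:
            self.th_a = draw(c_a, S_a)
            self.th_b = draw(c_b, S_b)
            self.th_r = draw(c_r, S_r)

    def _move_tau(self):
        if self.model != SPLIT or self.single_pop:
            return
        rng = self.rng
        taup = self.priors.tau_prior
        old_tau = self.tau
        old_cd = self._coal_logdens()
        c = math.exp(self.tau_eps * (rng.random() - 0.5))
        self.tau = old_tau * c
        new_cd = self._coal_logdens()
        log_r = (
            new_cd - old_cd
            + taup.log_pdf(self.tau) - taup.log_pdf(old_tau)
            + math.log(c)
        )
        self._try[2] += 1
        if math.log(rng.random() + 1e-300) < log_r:
            self._acc[2] += 1
        else:
            self.tau = old_tau

    def _move_tau_prior_draw(self):
        """Independence update of tau from its prior (prior terms cancel)."""
        if self.model != SPLIT or self.single_pop:
            return
        old_tau = self.tau
        old_cd = self._coal_logdens()
        self.tau = self.priors.tau_prior.sample(self.rng)
        new_cd = self._coal_logdens()
        if math.log(self.rng.random() + 1e-300) >= new_cd - old_cd:
            self.tau = old_tau

    def _move_rescale(self):
        """Joint multiplicative rescale of all ages and parameters."""
        rng = self.rng
        tp, taup = self.priors.theta_prior, self.priors.tau_prior
        c = math.exp(self.mix_eps * (rng.random() - 0.5))
        old_lp = self.log_posterior()
        old_age = self.age.copy()
        state = (self.tau, self.th_a, self.th_b, self.th_r, self.th_m)
        self.age = self.age * c
        n_scaled = self.n_tips - 1
        if self.model == SPLIT and not self.single_pop:
            self.tau *= c
            self.th_a *= c
            self.th_b *= c
            self.th_r *= c
            n_scaled += 4
        elif self.single_pop:
            self.th_a *= c
            n_scaled += 1
        else:
            self.th_m *= c
            n_scaled += 1
        new_ll = self._loglik()
        old_ll, self.loglik = self.loglik, new_ll
        new_lp = self.log_posterior()
        log_r = new_lp - old_lp + n_scaled * math.log(c)
        self._try[3] += 1
        if math.log(rng.random() + 1e-300) < log_r:
            self._acc[3] += 1
        else:
            self.age = old_age
            self.tau, self.th_a, self.th_b, self.th_r, self.th_m = state
            self.loglik = old_ll

    def _min_mixed_age(self) -> float:
        n = self.n_tips
        mixed = self.age[n:][self.mask[n:] == 3]
        return float(mixed.min())

    def _move_model_jump(self):
        """rjMCMC switch merged <-> split (equal model prior probabilities).

        The gene tree is untouched, so the sequence likelihood cancels.  The
        auxiliary tau is proposed uniformly on (0, M) where M is the smallest
        cross-population coalescence age of the current gene tree -- the
        largest tau the tree can support; its inverse-gamma prior density
        enters the acceptance ratio explicitly.  The root theta maps
        one-to-one onto the merged theta; the two daughter thetas are drawn
        from (and, reversed, absorbed back into) their priors, so those terms
        cancel.
        """
        rng = self.rng
        tp, taup = self.priors.theta_prior, self.priors.tau_prior
        old_cd = self._coal_logdens()
        M = self._min_mixed_age()
        if self.model == MERGED:
            saved = (self.tau, self.th_a, self.th_b, self.th_r)
            self.tau = rng.uniform(0.0, M)
            self.th_a = tp.sample(rng)
            self.th_b = tp.sample(rng)
            self.th_r = self.th_m
            self.model = SPLIT
            new_cd = self._coal_logdens()
            log_r = new_cd - old_cd + taup.log_pdf(self.tau) + math.log(M)
            if self.tau > 0 and math.log(rng.random() + 1e-300) < log_r:
                return
            self.model = MERGED
            self.tau, self.th_a, self.th_b, self.th_r = saved
        else:
            saved_m = self.th_m
            self.th_m = self.th_r
            self.model = MERGED
            new_cd = self._coal_logdens()
            log_r = new_cd - old_cd - taup.log_pdf(self.tau) - math.log(M)
            if math.log(rng.random() + 1e-300) < log_r:
                return
            self.model = SPLIT
            self.th_m = saved_m

    # -- sweep and tuning ---------------------------------------------------

    def sweep(self):
        n = self.n_tips
        if not self.fixed_tree:
            for v in self.rng.permutation(np.arange(n, 2 * n - 1)):
                self._move_age(int(v))
            if n > 2:
                for _ in range(max(1, (n - 1) // 2)):
                    self._move_regraft()
            self._move_tree_refresh()
        self._gibbs_theta()
        for _ in range(5):
            self._move_tau()
        for _ in range(2):
            self._move_tau_prior_draw()
        if not self.fixed_tree:
            self._move_rescale()
        if self.trans_model:
            self._move_model_jump()

    def tune(self):
        """Adjust step sizes toward acceptance 0.2-0.4 (burn-in only)."""
        for i, attr in enumerate(("age_delta", "root_eps", "tau_eps", "mix_eps")):
            if self._try[i] == 0:
                continue
            r = self._acc[i] / self._try[i]
            cur = getattr(self, attr)
            if r > 0.4:
                setattr(self, attr, cur * 1.3)
            elif r < 0.2:
                setattr(self, attr, cur * 0.75)
        self._acc[:] = 0
        self._try[:] = 0

    def record(self) -> dict[str, float]:
        if self.single_pop:
            return {"theta": self.th_a, "loglik": self.loglik}
        if self.trans_model:
            return {"model": float(self.model), "loglik": self.loglik}
        return {
            "tau": self.tau,
            "theta_a": self.th_a,
            "theta_b": self.th_b,
            "theta_root": self.th_r,
            "loglik": self.loglik,
        }


def _prepare(locus, popmap, require_pair: bool):
    popmap.validate_against(locus)
    pops = popmap.populations
    if len(pops) not in (1, 2):
        raise ValueError("pair engine requires 1 or 2 populations after selection")
    if require_pair and len(pops) != 2:
        raise ValueError("exactly 2 populations are required")
    samples = tuple(locus.samples)
    code = {p: i for i, p in enumerate(pops)}
    tip_pop = np.array([code[popmap.population_of(s)] for s in samples], np.int64)
    for p in pops:
        if (tip_pop == code[p]).sum() < 1:
            raise ValueError(f"population {p!r} has no sequences")
    return samples, tip_pop, pops


def _run_chain(sampler: _PairSampler, settings: MCMCSettings) -> dict[str, np.ndarray]:
    out: dict[str, list] = {}
    for sweep_i in range(settings.total_sweeps):
        sampler.sweep()
        if sampler.tuning and sweep_i < settings.burnin:
            if sweep_i and sweep_i % 50 == 0:
                sampler.tune()
        elif sampler.tuning:
            sampler.tuning = False
        if sweep_i >= settings.burnin:
            if (sweep_i - settings.burnin) % settings.thin == 0:
                for k, v in sampler.record().items():
                    out.setdefault(k, []).append(v)
    return {k: np.asarray(v) for k, v in out.items()}


def run_a00(
    locus: AlignedLocus | None,
    popmap: PopulationMap,
    priors: PriorSet,
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    n_runs: int = 4,
    prior_only: bool = False,
    fixed_tree: GeneTree | None = None,
) -> list[PosteriorTrace]:
    """Posterior sampling of (tau, theta_A, theta_B, theta_root) on a fixed pair.

    Runs ``n_runs`` independent chains with seeds ``seed + run_index``.  With
    ``prior_only=True`` the sequence likelihood is disabled so the chain
    samples the joint prior (the prior-vs-posterior sanity check).  With a
    single population in ``popmap`` the model reduces to a one-theta
    coalescent; ``fixed_tree`` freezes the gene tree (used by the conjugate
    closed-form oracle).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if locus is None and not prior_only:
        raise ValueError("a locus is required unless prior_only=True")
    if locus is not None:
        samples, tip_pop, pops = _prepare(locus, popmap, require_pair=False)
    else:
        pops = popmap.populations
        code = {p: i for i, p in enumerate(pops)}
        tip_pop = np.array(
            [code[p] for p in popmap.assignments.values()], np.int64
        )
    if prior_only or locus is None:
        tp = w = None
    else:
        tp, w = _tip_partials(locus, samples)
    traces = []
    for run in range(n_runs):
        run_seed = int(seed) + run
        rng = np.random.default_rng(run_seed)
        sampler = _PairSampler(
            tip_pop, priors, rng, tip_partials=tp, weights=w,
            prior_only=prior_only, fixed_tree=fixed_tree,
        )
        draws = _run_chain(sampler, settings)
        traces.append(
            PosteriorTrace(
                draws=draws, settings=settings, seed=run_seed,
                run_id=run, populations=tuple(pops),
            )
        )
    return traces


def run_delimitation(
    locus: AlignedLocus | None,
    popmap: PopulationMap,
    priors: PriorSet,
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    n_runs: int = 4,
    prior_only: bool = False,
    run_spread_tol: float = 0.05,
) -> DelimitationResult:
    """Posterior probability of the split (two-species) model via rjMCMC.

    The merged and split models get equal prior probability; the jump move
    proposes all parameters of the target model from their priors, so the
    acceptance ratio reduces to the coalescent-density ratio.  Disagreement
    among runs beyond ``run_spread_tol`` raises a convergence warning (never
    a failure).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if locus is not None:
        samples, tip_pop, pops = _prepare(locus, popmap, require_pair=True)
        if prior_only:
            tp = w = None
        else:
            tp, w = _tip_partials(locus, samples)
    else:
        if not prior_only:
            raise ValueError("a locus is required unless prior_only=True")
        pops = popmap.populations
        code = {p: i for i, p in enumerate(pops)}
        tip_pop = np.array([code[p] for p in popmap.assignments.values()], np.int64)
        tp = w = None
    pps = []
    for run in range(n_runs):
        rng = np.random.default_rng(int(seed) + run)
        sampler = _PairSampler(
            tip_pop, priors, rng, tip_partials=tp, weights=w,
            prior_only=prior_only, trans_model=True,
        )
        draws = _run_chain(sampler, settings)
        pps.append(float(draws["model"].mean()))
    spread = max(pps) - min(pps)
    warn = spread > run_spread_tol
    if warn:
        msg = (
            f"delimitation runs disagree: pp_split spread {spread:.3f} "
            f"exceeds {run_spread_tol}"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    pp = float(np.mean(pps))
    return DelimitationResult(
        pp_split=pp,
        support_band=support_band(pp),
        per_run_pp=tuple(pps),
        convergence_warning=warn,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvergenceDiagnostics:
    """Across-run diagnostics: rank-normalized R-hat, ESS, mean spread."""

    rhat: dict[str, float]
    ess: dict[str, float]
    mean_spread: dict[str, float]
    flags: tuple[str, ...]

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


def _rank_normalized_rhat(chains: np.ndarray) -> float:
    """Across-chain potential scale reduction on rank-normalized draws.

    Chains are compared whole (not split): the statistic targets the
    consistency of independent runs, following the convergence protocol of
    comparing posterior distributions across runs.  Values below 1 (possible
    when between-run variance is 0) are floored at 1.
    """
    m, n = chains.shape
    flat = chains.ravel()
    ranks = _sps.rankdata(flat).reshape(m, n)
    z = ndtri((ranks - 0.375) / (m * n + 0.25))
    W = z.var(axis=1, ddof=1).mean()
    B = n * z.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return max(1.0, math.sqrt(var_plus / W))


def convergence_check(
    traces: Sequence[PosteriorTrace],
    rhat_threshold: float = 1.05,
    ess_threshold: float = 200.0,
) -> ConvergenceDiagnostics:
    """Compare independent runs: R-hat, effective sample size, mean spread."""
    if len(traces) < 2:
        raise ValueError("need >= 2 traces to assess convergence")
    s0 = traces[0].settings
    if any(t.settings != s0 for t in traces):
        raise ValueError("traces were produced under unequal MCMC settings")
    params = traces[0].parameters
    import arviz as az

    rhat, ess, spread, flags = {}, {}, {}, []
    for p in params:
        chains = np.stack([np.asarray(t.draws[p], dtype=float) for t in traces])
        r = _rank_normalized_rhat(chains)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e = float(az.ess(az.convert_to_dataset(chains))["x"])
        means = chains.mean(axis=1)
        rhat[p] = float(r)
        ess[p] = e
        spread[p] = float(means.max() - means.min())
        if r > rhat_threshold:
            flags.append(f"{p}: rhat {r:.3f} > {rhat_threshold}")
        if e < ess_threshold:
            flags.append(f"{p}: ess {e:.0f} < {ess_threshold:.0f}")
    return ConvergenceDiagnostics(
        rhat=rhat, ess=ess, mean_spread=spread, flags=tuple(flags)
    )
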