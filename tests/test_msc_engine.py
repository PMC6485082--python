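import itertools
import math

import numpy as np
import pytest

from coaldelim.io_formats import AlignedLocus, PopulationMap
from coaldelim.msc_engine import (
    AMBIGUITY,
    GeneTree,
    MCMCSettings,
    MSCPairModel,
    PosteriorTrace,
    coalescent_log_density,
    convergence_check,
    jc69_log_likelihood,
    run_a00,
    run_delimitation,
    support_band,
)
from coaldelim.priors import InverseGammaPrior
from coaldelim.synthetic_data import SimulationSpec, simulate_gene_tree


def build_tree(samples, merges):
    """Manual gene tree: ``merges`` is a list of (child, child, age) tuples
    creating internal nodes n, n+1, ... in order."""
    n = len(samples)
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    age = np.zeros(m)
    for k, (a, b, t) in enumerate(merges):
        v = n + k
        parent[a] = parent[b] = v
        left[v], right[v] = a, b
        age[v] = t
    tree = GeneTree(tuple(samples), parent, left, right, age, root=m - 1)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Coalescent density
# ---------------------------------------------------------------------------


class TestCoalescentDensity:
    def test_single_pair_closed_form(self):
        # one population, theta=0.01, coalescence at t=0.005:
        # density (2/theta) exp(-2t/theta) = 200 e^-1
        tree = build_tree(["s1", "s2"], [(0, 1, 0.005)])
        pm = PopulationMap({"s1": "A", "s2": "A"})
        model = MSCPairModel.merged(0.01)
        got = coalescent_log_density(tree, model, pm)
        assert got == pytest.approx(math.log(200.0 * math.exp(-1.0)), abs=1e-12)

    def test_split_density_factorizes(self):
        # within-A at t1, within-B at t2 (both < tau), cross at t3 > tau
        t1, t2, t3, tau = 0.003, 0.004, 0.03, 0.02
        tree = build_tree(
            ["a1", "a2", "b1", "b2"],
            [(0, 1, t1), (2, 3, t2), (4, 5, t3)],
        )
        pm = PopulationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        model = MSCPairModel(tau, 0.002, 0.004, 0.01)
        expected = (
            math.log(2 / 0.002) - 2 * t1 / 0.002
            + math.log(2 / 0.004) - 2 * t2 / 0.004
            + math.log(2 / 0.01) - 2 * (t3 - tau) / 0.01
        )
        assert coalescent_log_density(tree, model, pm) == pytest.approx(
            expected, abs=1e-12
        )

    def test_cross_coalescence_below_tau_is_invalid(self):
        tree = build_tree(["a1", "b1"], [(0, 1, 0.005)])
        pm = PopulationMap({"a1": "A", "b1": "B"})
        model = MSCPairModel(0.02, 0.002, 0.002, 0.002)
        assert coalescent_log_density(tree, model, pm) == -np.inf

    def test_pure_lineage_may_coalesce_in_root(self):
        # both A lineages fail to coalesce by tau and meet in the root pop
        tree = build_tree(
            ["a1", "a2", "b1"], [(0, 1, 0.03), (3, 2, 0.05)]
        )
        pm = PopulationMap({"a1": "A", "a2": "A", "b1": "B"})
        tau = 0.02
        model = MSCPairModel(tau, 0.002, 0.003, 0.01)
        expected = (
            -2 * tau / 0.002  # A: two lineages all the way to tau
            + math.log(2 / 0.01) - 6 * (0.03 - tau) / 0.01  # k=3 entering root
            + math.log(2 / 0.01) - 2 * (0.05 - 0.03) / 0.01
        )
        assert coalescent_log_density(tree, model, pm) == pytest.approx(
            expected, abs=1e-12
        )


# ---------------------------------------------------------------------------
# JC69 likelihood
# ---------------------------------------------------------------------------


def jc69_transition(x, s, t):
    e = math.exp(-4.0 * t / 3.0)
    return 0.25 + 0.75 * e if x == s else 0.25 * (1.0 - e)


def brute_force_jc69(tree: GeneTree, locus: AlignedLocus) -> float:
    """Explicit summation over all node-state assignments (tiny trees only)."""
    n = tree.n_tips
    m = tree.n_nodes
    seqs = [locus.sequence_of(s) for s in tree.samples]
    total_ll = 0.0
    for site in range(locus.length):
        site_lik = 0.0
        for assign in itertools.product(range(4), repeat=m):
            # tip states must be compatible with the observed symbol
            ok = all(
                assign[i] in AMBIGUITY[seqs[i][site]] for i in range(n)
            )
            if not ok:
                continue
            p = 0.25  # uniform root state
            for v in range(m):
                pa = tree.parent[v]
                if pa == -1:
                    continue
                t = tree.age[pa] - tree.age[v]
                p *= jc69_transition(assign[v], assign[pa], t)
            site_lik += p
        total_ll += math.log(site_lik)
    return total_ll


class TestJC69Likelihood:
    def test_identical_sequences_zero_branches(self):
        tree = build_tree(["s1", "s2"], [(0, 1, 0.01)])
        tree.age[2] = 0.0  # all branch lengths zero
        locus = AlignedLocus("x", ("s1", "s2"), ("ACGTA", "ACGTA"))
        ll = jc69_log_likelihood(tree, locus)
        assert ll == pytest.approx(-5 * math.log(4.0), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_pruning_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(1, 3))
        n_b = int(rng.integers(1, 5 - n_a))
        spec = SimulationSpec(
            tau=0.02, theta_a=0.01, theta_b=0.01, theta_root=0.02,
            n_a=n_a, n_b=n_b, length=5, seed=seed,
        )
        tree = simulate_gene_tree(spec)
        symbols = list("ACGT") * 3 + ["N", "-", "R", "Y"]
        seqs = tuple(
            "".join(rng.choice(symbols, size=5)) for _ in range(tree.n_tips)
        )
        locus = AlignedLocus("x", tree.samples, seqs)
        got = jc69_log_likelihood(tree, locus)
        expected = brute_force_jc69(tree, locus)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_tip_mismatch_rejected(self, tiny_locus):
        tree = build_tree(["s1", "s2"], [(0, 1, 0.01)])
        with pytest.raises(ValueError, match="samples"):
            jc69_log_likelihood(tree, tiny_locus)


# ---------------------------------------------------------------------------
# Joint density invariance
# ---------------------------------------------------------------------------


def test_joint_density_reproducible(split_dataset):
    locus, popmap, _ = split_dataset
    spec = SimulationSpec(tau=0.01, seed=11)
    tree = simulate_gene_tree(spec)
    model = MSCPairModel(0.01, 0.002, 0.002, 0.002)
    prior = InverseGammaPrior(3, 0.002)

    def joint():
        return (
            prior.log_pdf(model.theta_a)
            + coalescent_log_density(tree, model, popmap)
            + jc69_log_likelihood(tree, locus)
        )

    v1, v2 = joint(), joint()
    assert np.isfinite(v1)
    assert abs(v1 - v2) < 1e-10


# ---------------------------------------------------------------------------
# Samplers: interface and reproducibility (statistical checks live in
# test_acceptance.py)
# ---------------------------------------------------------------------------


class TestRunA00:
    def test_trace_shape_and_reproducibility(
        self, split_dataset, default_priors, short_settings
    ):
        locus, popmap, _ = split_dataset
        t1 = run_a00(locus, popmap, default_priors, short_settings, seed=3, n_runs=2)
        assert len(t1) == 2
        for tr in t1:
            assert len(tr) == short_settings.samples
            for k in ("tau", "theta_a", "theta_b", "theta_root"):
                assert np.all(tr.draws[k] > 0)
        t2 = run_a00(locus, popmap, default_priors, short_settings, seed=3, n_runs=2)
        assert np.array_equal(t1[0].tau, t2[0].tau)
        assert t1[0].seed != t1[1].seed
        assert not np.array_equal(t1[0].tau, t1[1].tau)

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            MCMCSettings(samples=0)
        with pytest.raises(ValueError):
            MCMCSettings(samples=10, burnin=-1)
        with pytest.raises(ValueError):
            MCMCSettings(samples=10, thin=0)

    def test_requires_locus_unless_prior_only(self, tiny_popmap, default_priors):
        with pytest.raises(ValueError, match="prior_only"):
            run_a00(None, tiny_popmap, default_priors, MCMCSettings(10, 0, 1), seed=1)


class TestDelimitation:
    def test_result_bands(self):
        assert support_band(0.99) == "high"
        assert support_band(0.95) == "high"
        assert support_band(0.92) == "moderate"
        assert support_band(0.90) == "moderate"
        assert support_band(0.46) == "weak"

    def test_reproducible(self, split_dataset, default_priors, short_settings):
        locus, popmap, _ = split_dataset
        r1 = run_delimitation(
            locus, popmap, default_priors, short_settings, seed=5, n_runs=1
        )
        r2 = run_delimitation(
            locus, popmap, default_priors, short_settings, seed=5, n_runs=1
        )
        assert r1.pp_split == r2.pp_split
        assert 0.0 <= r1.pp_split <= 1.0


class TestConvergenceCheck:
    @staticmethod
    def _trace(values, run_id=0, samples=None):
        values = np.asarray(values, dtype=float)
        settings = MCMCSettings(samples or len(values), 0, 1)
        return PosteriorTrace(
            draws={"tau": values},
            settings=settings,
            seed=run_id,
            run_id=run_id,
            populations=("A", "B"),
        )

    def test_identical_traces_rhat_one(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, size=2000)
        diag = convergence_check([self._trace(x, 0), self._trace(x, 1)])
        assert diag.rhat["tau"] == 1.0
        assert not any("rhat" in f for f in diag.flags)

    def test_disjoint_supports_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 0.01, size=1000) + 10
        b = rng.normal(1.0, 0.01, size=1000) + 20
        diag = convergence_check([self._trace(a, 0), self._trace(b, 1)])
        assert diag.rhat["tau"] > 1.05
        assert diag.flagged

    def test_white_noise_ess_near_nominal(self):
        rng = np.random.default_rng(2)
        chains = [rng.normal(loc=10.0, size=5000) for _ in range(2)]
        diag = convergence_check([self._trace(c, i) for i, c in enumerate(chains)])
        assert diag.ess["tau"] == pytest.approx(10_000, rel=0.2)

    def test_unequal_settings_rejected(self):
        a = self._trace(np.ones(10) * 2, 0)
        b = PosteriorTrace(
            draws={"tau": np.ones(20) * 2},
            settings=MCMCSettings(20, 0, 1),
            seed=1, run_id=1, populations=("A", "B"),
        )
        with pytest.raises(ValueError, match="settings"):
            convergence_check([a, b])

    def test_needs_two_traces(self):
        with pytest.raises(ValueError):
            convergence_check([self._trace(np.ones(10), 0)])


class TestModelTypes:
    def test_split_model_requires_positive_params(self):
        with pytest.raises(ValueError):
            MSCPairModel(0.0, 0.002, 0.002, 0.002)
        with pytest.raises(ValueError):
            MSCPairModel(0.01, -1, 0.002, 0.002)
        merged = MSCPairModel.merged(0.002)
        assert not merged.is_split

    def test_gene_tree_validation(self):
        tree = build_tree(["s1", "s2"], [(0, 1, 0.01)])
        tree.age[2] = -0.5
        with pytest.raises(ValueError):
            tree.validate()
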