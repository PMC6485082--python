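"""Coalescent synthetic-data generator for end-to-end testing.

Generates single-locus, gap-free haploid datasets with the statistical
structure the delimitation analysis assumes: two populations that diverged at
time tau with within-population sizes theta_A/theta_B and ancestral size
theta_root (all in expected substitutions per site), gene trees drawn from the
two-population structured coalescent, and sequences evolved site-by-site under
JC69 from a uniform root state.  Defaults mirror the scale of a single-locus
mitochondrial study: 10 samples per population, 1000 bp, tau and theta of
order 1e-3 to 1e-2.

Setting ``tau = 0`` produces the panmictic null (one population of size
``theta_root``), used for calibration experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_formats import AlignedLocus, PopulationMap, write_fasta_alignment, write_imap
from .msc_engine import GeneTree, _simulate_genetree_arrays

__all__ = [
    "SimulationSpec",
    "simulate_gene_tree",
    "simulate_alignment",
    "simulate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Truth parameters and sampling design for one synthetic dataset."""

    tau: float = 0.005
    theta_a: float = 0.002
    theta_b: float = 0.002
    theta_root: float = 0.002
    n_a: int = 10
    n_b: int = 10
    length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("need at least one sample per population")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0 (0 = panmixia)")
        for name in ("theta_a", "theta_b", "theta_root"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(
            [f"a{i}" for i in range(self.n_a)] + [f"b{i}" for i in range(self.n_b)]
        )

    def population_map(self) -> PopulationMap:
        return PopulationMap(
            {s: ("A" if s.startswith("a") else "B") for s in self.sample_names}
        )


def simulate_gene_tree(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> GeneTree:
    """Draw one gene tree from the two-population structured coalescent.

    Within-A and within-B coalescents (pair rate 2/theta) run on [0, tau];
    survivors merge into the root population.  With ``tau = 0`` everything
    coalesces in a single population of size theta_root.
    """
    rng = rng or np.random.default_rng(spec.seed)
    tip_pop = np.array([0] * spec.n_a + [1] * spec.n_b, dtype=np.int64)
    if spec.tau == 0.0:
        parent, left, right, age, root = _simulate_genetree_arrays(
            rng, np.zeros_like(tip_pop), np.inf,
            spec.theta_root, spec.theta_root, spec.theta_root,
        )
    else:
        parent, left, right, age, root = _simulate_genetree_arrays(
            rng, tip_pop, spec.tau, spec.theta_a, spec.theta_b, spec.theta_root
        )
    tree = GeneTree(
        samples=spec.sample_names,
        parent=parent, left=left, right=right, age=age, root=root,
    )
    tree.validate()
    return tree


def simulate_alignment(
    genetree: GeneTree,
    length: int,
    seed: int | np.random.Generator,
    name: str = "sim",
) -> AlignedLocus:
    """Evolve i.i.d. sites under JC69 down ``genetree`` from a uniform root state.

    Under JC69 a branch of length t keeps the parental state with probability
    1/4 + 3/4 exp(-4t/3) and otherwise draws uniformly among the three others;
    equivalently, with probability 1 - exp(-4t/3) the state is redrawn
    uniformly from all four.  Output is gap-free.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = genetree.n_tips
    states = np.empty((genetree.n_nodes, length), dtype=np.int8)
    states[genetree.root] = rng.integers(0, 4, size=length)
    # preorder traversal
    stack = [genetree.root]
    while stack:
        v = stack.pop()
        if v < n:
            continue
        for c in (genetree.left[v], genetree.right[v]):
            t = genetree.age[v] - genetree.age[c]
            p_redraw = 1.0 - np.exp(-4.0 * t / 3.0)
            redraw = rng.random(length) < p_redraw
            child = states[v].copy()
            child[redraw] = rng.integers(0, 4, size=int(redraw.sum()))
            states[c] = child
            stack.append(c)
    bases = np.array(list("ACGT"))
    seqs = tuple("".join(bases[states[i]]) for i in range(n))
    return AlignedLocus(name=name, samples=genetree.samples, sequences=seqs)


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[AlignedLocus, PopulationMap, dict]:
    """Bundle a gene tree, alignment, population map and truth record.

    The gene-tree and mutation processes consume independent streams spawned
    from ``spec.seed`` so the same tree can be re-used across sequence
    lengths.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_tree, rng_seq = (np.random.default_rng(s) for s in ss.spawn(2))
    tree = simulate_gene_tree(spec, rng_tree)
    locus = simulate_alignment(tree, spec.length, rng_seq, name=f"sim_seed{spec.seed}")
    truth = dict(asdict(spec), newick=tree.newick(), root_age=float(tree.age[tree.root]))
    return locus, spec.population_map(), truth


def write_dataset(spec: SimulationSpec, outdir: str | Path) -> dict:
    """Write FASTA + imap + a JSON truth sidecar; returns the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    locus, popmap, truth = simulate_dataset(spec)
    write_fasta_alignment(locus, outdir / "alignment.fasta")
    write_imap(popmap, outdir / "imap.txt")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
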