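"""Inverse-gamma priors on theta and tau: sensitivity grid and empirical calibration.

Both MSC parameters are given inverse-gamma IG(alpha, beta) priors with mean
m = beta/(alpha-1) for alpha > 2.  Two construction routes are provided:

* a fixed 10-row sensitivity grid spanning two orders of magnitude in the
  prior mean, with alpha = 3 as a diffuse shape and alpha = 21 as an
  informative shape;
* empirical calibration, where the prior mean for theta is set to the average
  within-population nucleotide diversity (pi, computed as mean pairwise
  p-distance with pairwise deletion) and the prior mean for tau to the focal
  pair's MRCA height on an ultrametric guide tree.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distance_screen import p_distance
from .io_formats import AlignedLocus, GuideTree, PopulationMap

__all__ = [
    "InverseGammaPrior",
    "PriorSet",
    "DegeneratePriorError",
    "prior_grid",
    "beta_from_mean",
    "nucleotide_diversity",
    "empirical_theta_prior",
    "empirical_tau_prior",
    "empirical_prior_set",
    "sample_prior",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 3.0  # diffuse shape; 21 is the informative alternative


class DegeneratePriorError(ValueError):
    """Raised when an empirical prior mean is zero or undefined."""


@dataclass(frozen=True)
class InverseGammaPrior:
    """IG(alpha, beta) prior; mean beta/(alpha-1) exists for alpha > 2.

    ``beta`` carries the units of the parameter (expected substitutions/site).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("inverse-gamma requires alpha > 0 and beta > 0")

    @property
    def mean(self) -> float:
        if self.alpha <= 2:
            raise DegeneratePriorError(
                f"IG mean beta/(alpha-1) requires alpha > 2 for a usable prior; "
                f"alpha={self.alpha}"
            )
        return self.beta / (self.alpha - 1.0)

    def dist(self):
        """The matching frozen :mod:`scipy.stats` distribution."""
        return stats.invgamma(self.alpha, scale=self.beta)

    def log_pdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        a, b = self.alpha, self.beta
        from scipy.special import gammaln

        return a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x

    def sample(self, rng: np.random.Generator, size=None):
        # X = beta / Gamma(alpha, 1)
        return self.beta / rng.gamma(self.alpha, size=size)

    def label(self) -> str:
        return f"IG({self.alpha:g}, {self.beta:g})"


@dataclass(frozen=True)
class PriorSet:
    """One (theta prior, tau prior) combination with a grid-row label."""

    theta_prior: InverseGammaPrior
    tau_prior: InverseGammaPrior
    label: str


def prior_grid() -> list[PriorSet]:
    """The 10-row prior-sensitivity grid.

    Five rows vary the theta prior at fixed tau = IG(3, 0.004); five vary the
    tau prior at fixed theta = IG(3, 0.002).  Means span two orders of
    magnitude; alpha = 3 rows are diffuse, alpha = 21 informative.
    """
    theta_rows = [(3, 0.0002), (3, 0.002), (3, 0.02), (21, 0.02), (21, 0.2)]
    tau_rows = [(3, 0.0004), (3, 0.04), (21, 0.004), (21, 0.04), (21, 0.4)]
    base_tau = InverseGammaPrior(3, 0.004)
    base_theta = InverseGammaPrior(3, 0.002)
    out: list[PriorSet] = []
    for a, b in theta_rows:
        th = InverseGammaPrior(a, b)
        out.append(PriorSet(th, base_tau, f"{th.label()}|{base_tau.label()}"))
    for a, b in tau_rows:
        tau = InverseGammaPrior(a, b)
        out.append(PriorSet(base_theta, tau, f"{base_theta.label()}|{tau.label()}"))
    return out


def beta_from_mean(alpha: float, m: float) -> float:
    """Invert m = beta/(alpha-1); requires alpha > 2 and m > 0."""
    if alpha <= 2:
        raise DegeneratePriorError(
            f"prior mean undefined for alpha={alpha} (need alpha > 2)"
        )
    if m <= 0:
        raise DegeneratePriorError(f"prior mean must be positive, got {m}")
    return m * (alpha - 1.0)


def nucleotide_diversity(locus: AlignedLocus, samples) -> float:
    """Mean pairwise p-distance (pairwise deletion) among ``samples``."""
    seqs = [locus.sequence_of(s) for s in samples]
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    ds = [p_distance(x, y)[0] for x, y in itertools.combinations(seqs, 2)]
    return float(np.mean(ds))


def empirical_theta_prior(
    locus: AlignedLocus,
    popmap: PopulationMap,
    alpha: float = DEFAULT_ALPHA,
    fallback: InverseGammaPrior | None = None,
) -> InverseGammaPrior:
    """Empirical theta prior: mean = average within-population diversity.

    Populations with fewer than 2 samples carry no information about theta and
    are skipped.  If every population is a singleton the configured
    ``fallback`` prior is returned with a logged warning; with no fallback a
    :class:`DegeneratePriorError` is raised.
    """
    popmap.validate_against(locus)
    pis = []
    for pop in popmap.populations:
        samples = [s for s in popmap.samples_of(pop) if s in locus.samples]
        if len(samples) >= 2:
            pis.append(nucleotide_diversity(locus, samples))
    if not pis:
        if fallback is not None:
            msg = "all populations are singletons; falling back to default theta prior"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            return fallback
        raise DegeneratePriorError(
            "cannot calibrate theta prior: every population is a singleton"
        )
    m = float(np.mean(pis))
    return InverseGammaPrior(alpha, beta_from_mean(alpha, m))


def empirical_tau_prior(
    tree: GuideTree,
    pair: tuple[str, str],
    alpha: float = DEFAULT_ALPHA,
) -> InverseGammaPrior:
    """Empirical tau prior: mean = MRCA height of the focal pair."""
    m = tree.mrca_height(*pair)
    if m <= 0:
        raise DegeneratePriorError(
            f"MRCA height of pair {pair} is zero; tau prior degenerate"
        )
    return InverseGammaPrior(alpha, beta_from_mean(alpha, m))


def empirical_prior_set(
    locus: AlignedLocus,
    popmap: PopulationMap,
    tree: GuideTree,
    pair: tuple[str, str],
    alpha: float = DEFAULT_ALPHA,
    theta_fallback: InverseGammaPrior | None = None,
) -> PriorSet:
    """Bundle the two empirical priors for one candidate pair."""
    return PriorSet(
        theta_prior=empirical_theta_prior(locus, popmap, alpha, theta_fallback),
        tau_prior=empirical_tau_prior(tree, pair, alpha),
        label="empirical",
    )


def sample_prior(
    prior: InverseGammaPrior, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` reproducible inverse-gamma variates."""
    if n < 1:
        raise ValueError("need n >= 1 draws")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return prior.sample(rng, size=n)
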