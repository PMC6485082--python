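"""Pipeline orchestration: screen -> priors -> MSC inference -> gdi -> reports.

Each candidate pair flagged by the distance screen is analysed independently:
the alignment is subset to the pair, priors are constructed (empirical,
explicit, or the 10-row sensitivity grid), the split-vs-merge posterior
probability and the A00 parameter posteriors are sampled, gdi is computed in
both directions, and a mechanical evidence verdict is assigned.  Runs are
reproducible: per-pair seeds derive deterministically from the configured seed
and the pair labels, so results do not depend on execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .distance_screen import CandidatePair, pairwise_matrix, screen_candidates
from .gdi import GdiResult, gdi_from_trace
from .io_formats import (
    AlignedLocus,
    PopulationMap,
    read_fasta_alignment,
    read_guide_tree,
    read_imap,
    write_report,
)
from .msc_engine import (
    MCMCSettings,
    convergence_check,
    run_a00,
    run_delimitation,
    support_band,
)
from .priors import InverseGammaPrior, PriorSet, empirical_prior_set, prior_grid

__all__ = ["RunConfig", "PairSummary", "run_pipeline", "summarize_evidence"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one pipeline invocation."""

    fasta: str
    imap: str
    taxonomy: str
    outdir: str
    guide_tree: str | None = None
    lower: float = 3.0
    upper: float = 5.0
    prior_source: str = "empirical"  # empirical | grid | explicit
    theta_prior: tuple[float, float] = (3.0, 0.002)
    tau_prior: tuple[float, float] = (3.0, 0.004)
    samples: int = 100_000
    burnin: int = 10_000
    thin: int = 5
    n_runs: int = 4
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"require lower < upper, got {self.lower} >= {self.upper}")
        if self.prior_source not in ("empirical", "grid", "explicit"):
            raise ValueError(f"unknown prior source {self.prior_source!r}")
        MCMCSettings(self.samples, self.burnin, self.thin)  # validates
        if self.prior_source == "empirical" and self.guide_tree is None:
            raise ValueError("empirical priors require a guide tree")

    @property
    def settings(self) -> MCMCSettings:
        return MCMCSettings(self.samples, self.burnin, self.thin)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` config file; kwargs override."""
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (x.strip() for x in line.split("=", 1))
            raw[k] = v
        kw: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for k, v in raw.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            typ = fields[k].type
            if k in ("theta_prior", "tau_prior"):
                a, b = (float(x) for x in v.split(","))
                kw[k] = (a, b)
            elif typ in ("float", float):
                kw[k] = float(v)
            elif typ in ("int", int):
                kw[k] = int(v)
            else:
                kw[k] = v
        kw.update(overrides)
        return cls(**kw)

    def write(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PairSummary:
    """All evidence collected for one candidate pair."""

    pair: tuple[str, str]
    candidate: CandidatePair
    pp_split: float
    support_band: str
    per_prior_pp: dict[str, float]
    gdi_a: GdiResult
    gdi_b: GdiResult
    verdict: str = field(default="")
    convergence_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.verdict:
            self.verdict = summarize_evidence(self)


def summarize_evidence(pair: PairSummary) -> str:
    """Mechanical joint reading of the BPP-style support and both gdi directions.

    "split supported" iff the split posterior probability is in the high band
    (pp >= 0.95) and at least one gdi direction classifies the populations as
    distinct; "lump supported" iff support is weak (pp < 0.90) and both gdi
    directions classify them as the same species; otherwise "ambiguous".
    Pairs where the two directions disagree in classification keep the
    ambiguous/flagged reading.
    """
    if pair.gdi_a is None or pair.gdi_b is None or pair.pp_split is None:
        raise ValueError("missing evidence: need pp_split and both gdi directions")
    band = support_band(pair.pp_split)
    cls = (pair.gdi_a.classification, pair.gdi_b.classification)
    if band == "high" and "distinct" in cls:
        return "split supported"
    if band == "weak" and cls == ("same", "same"):
        return "lump supported"
    return "ambiguous"


def _pair_seed(base_seed: int, a: str, b: str) -> int:
    tag = "|".join(sorted((a, b)))
    return int((int(base_seed) + zlib.crc32(tag.encode())) % (2**31 - 1))


def _read_taxonomy(path: str | Path) -> dict[frozenset, bool]:
    out: dict[frozenset, bool] = {}
    truthy = {"1", "true", "yes", "conspecific"}
    falsy = {"0", "false", "no", "heterospecific"}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'pop_a pop_b conspecific'")
        flag = parts[2].lower()
        if flag not in truthy | falsy:
            raise ValueError(f"{path}:{lineno}: bad conspecific flag {parts[2]!r}")
        out[frozenset(parts[:2])] = flag in truthy
    return out


def analyse_pair(
    locus: AlignedLocus,
    popmap: PopulationMap,
    candidate: CandidatePair,
    prior_sets: list[PriorSet],
    headline: PriorSet,
    settings: MCMCSettings,
    seed: int,
    n_runs: int,
) -> PairSummary:
    """Run delimitation + A00 + gdi for one pair with the given prior sets."""
    a, b = candidate.population_a, candidate.population_b
    pair_map = popmap.subset([a, b])
    pair_locus = locus.subset(
        [s for s in locus.samples if s in pair_map.assignments], name=f"{a}_{b}"
    )
    per_prior_pp: dict[str, float] = {}
    for i, ps in enumerate(prior_sets):
        res = run_delimitation(
            pair_locus, pair_map, ps, settings, seed=seed + 1000 + i, n_runs=1
        )
        per_prior_pp[ps.label] = res.pp_split
    delim = run_delimitation(
        pair_locus, pair_map, headline, settings, seed=seed, n_runs=n_runs
    )
    per_prior_pp[headline.label] = delim.pp_split
    traces = run_a00(
        pair_locus, pair_map, headline, settings, seed=seed + 500, n_runs=n_runs
    )
    diag = convergence_check(traces) if len(traces) >= 2 else None
    combined = traces[0]
    if len(traces) > 1:
        from .msc_engine import PosteriorTrace

        keys = traces[0].draws.keys()
        merged_draws = {
            k: np.concatenate([t.draws[k] for t in traces]) for k in keys
        }
        combined = PosteriorTrace(
            draws=merged_draws,
            settings=MCMCSettings(
                settings.samples * len(traces), settings.burnin, settings.thin
            ),
            seed=traces[0].seed,
            run_id=-1,
            populations=traces[0].populations,
        )
    gdi_a = gdi_from_trace(combined, "a_vs_b")
    gdi_b = gdi_from_trace(combined, "b_vs_a")
    flags = diag.flags if diag is not None else ()
    if delim.convergence_warning:
        flags = flags + ("delimitation: run pp spread > tolerance",)
    return PairSummary(
        pair=(a, b),
        candidate=candidate,
        pp_split=delim.pp_split,
        support_band=delim.support_band,
        per_prior_pp=per_prior_pp,
        gdi_a=gdi_a,
        gdi_b=gdi_b,
        convergence_flags=tuple(flags),
    )


def run_pipeline(config: RunConfig) -> list[PairSummary]:
    """Execute the full analysis and write tables, traces, and a run log.

    A failure in one pair aborts that pair with a logged reason; remaining
    pairs continue.  Outputs under ``config.outdir``: ``candidates.tsv``,
    ``prior_sensitivity.tsv``, ``evidence.tsv``, per-pair trace TSVs, the
    resolved config, and a JSON-lines log with seeds and versions.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(event: str, **kw):
        rec = {"event": event, **kw}
        log_fh.write(json.dumps(rec, sort_keys=True) + "\n")

    log("start", version=_pkg_version, seed=config.seed)
    config.write(outdir / "resolved_config.cfg")

    locus = read_fasta_alignment(config.fasta)
    popmap = read_imap(config.imap)
    popmap.validate_against(locus)
    taxonomy = _read_taxonomy(config.taxonomy)
    tree = read_guide_tree(config.guide_tree) if config.guide_tree else None

    matrix = pairwise_matrix(locus)
    candidates = screen_candidates(
        matrix, popmap, taxonomy, lower=config.lower, upper=config.upper
    )
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("pop_a\tpop_b\tconspecific\td_min\td_max\td_mean\tcategory\n")
        for c in candidates:
            fh.write(
                f"{c.population_a}\t{c.population_b}\t{int(c.conspecific)}\t"
                f"{c.d_min:.2f}\t{c.d_max:.2f}\t{c.d_mean:.2f}\t{c.category}\n"
            )
    flagged = [c for c in candidates if c.category != "none"]
    log("screen", n_pairs=len(candidates), n_flagged=len(flagged))

    summaries: list[PairSummary] = []
    settings = config.settings
    for cand in flagged:
        a, b = cand.population_a, cand.population_b
        t0 = time.perf_counter()
        try:
            prior_sets: list[PriorSet] = []
            if config.prior_source == "grid":
                prior_sets = prior_grid()
                headline = prior_sets[1]  # theta IG(3,0.002), tau IG(3,0.004)
            elif config.prior_source == "empirical":
                headline = empirical_prior_set(
                    locus, popmap, tree, (a, b),
                    theta_fallback=InverseGammaPrior(*config.theta_prior),
                )
            else:
                headline = PriorSet(
                    InverseGammaPrior(*config.theta_prior),
                    InverseGammaPrior(*config.tau_prior),
                    "explicit",
                )
            seed = _pair_seed(config.seed, a, b)
            summary = analyse_pair(
                locus, popmap, cand, prior_sets, headline,
                settings, seed, config.n_runs,
            )
            summaries.append(summary)
            for warn in summary.convergence_flags:
                log("warning", pair=f"{a}/{b}", message=warn)
            log(
                "pair_done", pair=f"{a}/{b}", seed=seed,
                pp_split=summary.pp_split, verdict=summary.verdict,
                wall_s=round(time.perf_counter() - t0, 3),
            )
        except Exception as exc:  # keep going on other pairs
            logger.exception("pair %s/%s failed", a, b)
            log("pair_failed", pair=f"{a}/{b}", reason=str(exc))

    if summaries:
        write_report(summaries, outdir / "evidence.tsv")
        labels: list[str] = []
        for s in summaries:
            for lab in s.per_prior_pp:
                if lab not in labels:
                    labels.append(lab)
        with open(outdir / "prior_sensitivity.tsv", "w") as fh:
            fh.write("prior_set\t" + "\t".join("/".join(s.pair) for s in summaries) + "\n")
            for lab in labels:
                row = [
                    f"{s.per_prior_pp[lab]:.2f}" if lab in s.per_prior_pp else ""
                    for s in summaries
                ]
                fh.write(lab + "\t" + "\t".join(row) + "\n")
    log("end", n_summaries=len(summaries))
    log_fh.close()
    return summaries
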