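"""Readers and writers for the files the delimitation pipeline touches.

The pipeline consumes an aligned single-locus FASTA (mitochondrial 16S in the
motivating use case), a two-column "imap" file assigning each sample to a
population, optionally an ultrametric guide tree in newick (heights in expected
substitutions per site), and emits tab-separated evidence tables.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "AlignedLocus",
    "PopulationMap",
    "GuideTree",
    "AlignmentError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_imap",
    "write_imap",
    "read_guide_tree",
    "write_report",
]

#: IUPAC nucleotide symbols accepted in alignments (after uppercasing).
IUPAC_SYMBOLS = frozenset("ACGTURYSWKMBDHVN-?")

#: Unambiguous bases; only these count as comparable sites in p-distances.
CANONICAL_BASES = frozenset("ACGT")

ULTRAMETRIC_TOL = 1e-8


class AlignmentError(ValueError):
    """Raised for malformed alignments, maps, or trees."""


def _normalize_sequence(seq: str, sample: str) -> str:
    """Uppercase, map U->T and ?->N, and reject non-IUPAC symbols."""
    up = seq.upper().replace("U", "T").replace("?", "N")
    bad = set(up) - IUPAC_SYMBOLS
    if bad:
        raise AlignmentError(
            f"sample {sample!r}: non-IUPAC symbol(s) {sorted(bad)!r} in sequence"
        )
    return up


@dataclass(frozen=True)
class AlignedLocus:
    """An aligned sequence matrix for one locus.

    Sequences are stored uppercase with ``U`` normalized to ``T`` and ``?`` to
    ``N``.  All sequences have identical length and sample identifiers are
    unique; violations raise :class:`AlignmentError` at construction.
    """

    name: str
    samples: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.sequences):
            raise AlignmentError("samples and sequences differ in count")
        if not self.samples:
            raise AlignmentError("empty alignment")
        seen: set[str] = set()
        for s in self.samples:
            if not s:
                raise AlignmentError("empty sample identifier")
            if s in seen:
                raise AlignmentError(f"duplicate sample identifier {s!r}")
            seen.add(s)
        norm = tuple(
            _normalize_sequence(q, s) for s, q in zip(self.samples, self.sequences)
        )
        object.__setattr__(self, "sequences", norm)
        length = len(norm[0])
        if length < 1:
            raise AlignmentError("alignment has zero sites")
        for s, q in zip(self.samples, norm):
            if len(q) != length:
                raise AlignmentError(
                    f"ragged alignment: sample {s!r} has length {len(q)}, "
                    f"expected {length}"
                )

    @property
    def length(self) -> int:
        """Number of aligned sites (bp)."""
        return len(self.sequences[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sequence_of(self, sample: str) -> str:
        try:
            return self.sequences[self.samples.index(sample)]
        except ValueError:
            raise KeyError(f"sample {sample!r} not in alignment") from None

    def subset(self, samples: Sequence[str], name: str | None = None) -> "AlignedLocus":
        """Restrict the alignment to ``samples`` (kept in the given order)."""
        return AlignedLocus(
            name=name or self.name,
            samples=tuple(samples),
            sequences=tuple(self.sequence_of(s) for s in samples),
        )


@dataclass(frozen=True)
class PopulationMap:
    """Sample -> population assignment (the role of BPP's imap file)."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        for s, p in self.assignments.items():
            if not s or not p:
                raise AlignmentError("empty sample or population label in map")

    @property
    def populations(self) -> tuple[str, ...]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return tuple(seen)

    def samples_of(self, population: str) -> tuple[str, ...]:
        out = tuple(s for s, p in self.assignments.items() if p == population)
        if not out:
            raise KeyError(f"population {population!r} not in map")
        return out

    def population_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in population map") from None

    def validate_against(self, locus: AlignedLocus) -> None:
        """Every sample of ``locus`` must appear exactly once in the map."""
        missing = [s for s in locus.samples if s not in self.assignments]
        if missing:
            raise AlignmentError(f"samples missing from population map: {missing}")

    def subset(self, populations: Sequence[str]) -> "PopulationMap":
        keep = set(populations)
        return PopulationMap(
            {s: p for s, p in self.assignments.items() if p in keep}
        )


@dataclass(frozen=True)
class GuideTree:
    """Rooted ultrametric tree over population labels.

    Node heights are in expected substitutions per site, the same unit as the
    MSC divergence-time parameter tau; no calendar-time conversion is applied.
    """

    tree: dendropy.Tree

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t.taxon.label for t in self.tree.leaf_node_iter())

    def mrca_height(self, a: str, b: str) -> float:
        """Height of the most recent common ancestor of tips ``a`` and ``b``."""
        labels = set(self.taxa)
        for lab in (a, b):
            if lab not in labels:
                raise KeyError(f"label {lab!r} not in guide tree")
        node = self.tree.mrca(taxon_labels=[a, b])
        return float(node.height)  # type: ignore[attr-defined]

    @property
    def root_height(self) -> float:
        return float(self.tree.seed_node.height)  # type: ignore[attr-defined]


def read_fasta_alignment(path: str | Path, name: str | None = None) -> AlignedLocus:
    """Read an aligned FASTA file into an :class:`AlignedLocus`.

    Input sample order is preserved.  Raises :class:`AlignmentError` on ragged
    alignments, duplicate headers, or non-IUPAC symbols.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    samples = tuple(r.id for r in records)
    seqs = tuple(str(r.seq) for r in records)
    return AlignedLocus(name=name or path.stem, samples=samples, sequences=seqs)


def write_fasta_alignment(locus: AlignedLocus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, q in zip(locus.samples, locus.sequences):
            fh.write(f">{s}\n{q}\n")


def read_imap(path: str | Path) -> PopulationMap:
    """Read a whitespace-delimited two-column sample/population file.

    Blank lines and ``#`` comments are ignored.  A sample listed twice with
    conflicting labels raises :class:`AlignmentError`.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AlignmentError(
                    f"{path}:{lineno}: expected 'sample population', got {raw.strip()!r}"
                )
            sample, pop = parts[0], parts[1]
            if sample in assignments and assignments[sample] != pop:
                raise AlignmentError(
                    f"{path}:{lineno}: sample {sample!r} assigned to both "
                    f"{assignments[sample]!r} and {pop!r}"
                )
            assignments[sample] = pop
    if not assignments:
        raise AlignmentError(f"{path}: empty population map")
    return PopulationMap(assignments)


def write_imap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.assignments.items():
            fh.write(f"{s}\t{p}\n")


def read_guide_tree(path_or_newick: str | Path) -> GuideTree:
    """Read a rooted newick tree with branch lengths and validate ultrametricity.

    Accepts a file path or a literal newick string.  All tip heights must agree
    within ``1e-8``; heights are computed as distance below the root.
    """
    text: str
    p = Path(str(path_or_newick))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_newick)
    if "(" not in text:
        raise AlignmentError(f"not a newick tree: {text!r}")
    tree = dendropy.Tree.get(
        data=text, schema="newick", rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise AlignmentError("newick tree missing branch lengths")
        if edge.length is not None and edge.length < 0:
            raise AlignmentError("negative branch length in guide tree")
    # depth from root; height = max_depth - depth must match across tips
    depths: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    tip_depths = [depths[t] for t in tree.leaf_node_iter()]
    max_depth = max(tip_depths)
    if max(tip_depths) - min(tip_depths) > ULTRAMETRIC_TOL:
        raise AlignmentError(
            "guide tree is not ultrametric: tip depths span "
            f"[{min(tip_depths):.10g}, {max(tip_depths):.10g}]"
        )
    for node in tree.preorder_node_iter():
        node.height = max_depth - depths[node]
        if node.height < -ULTRAMETRIC_TOL:
            raise AlignmentError("negative node height in guide tree")
        node.height = max(node.height, 0.0)
    return GuideTree(tree=tree)


# ---------------------------------------------------------------------------
# Evidence report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "pair",
    "divergence_pct",
    "pp_split",
    "support",
    "gdi_a",
    "gdi_b",
    "classification",
)


def _fmt_range(d_min: float, d_max: float) -> str:
    if math.isclose(d_min, d_max, abs_tol=5e-3):
        return f"{d_min:.2f}"
    return f"{d_min:.2f}-{d_max:.2f}"


def write_report(results: Iterable, path: str | Path) -> None:
    """Write per-pair evidence rows as a tab-separated UTF-8 table.

    ``results`` is an iterable of objects exposing the fields assembled by the
    pipeline (see :class:`coaldelim.pipeline.PairSummary`) or plain dicts with
    the ``REPORT_COLUMNS`` keys.  Mirrors the layout
    ``Mitochondrial divergence | BPP support | gdi (mean +/- SD)``.
    """
    rows = list(results)
    if not rows:
        raise ValueError("write_report: empty result list")
    buf = io.StringIO()
    buf.write("\t".join(REPORT_COLUMNS) + "\n")
    for r in rows:
        if isinstance(r, dict):
            vals = [str(r[c]) for c in REPORT_COLUMNS]
        else:
            vals = [
                f"{r.pair[0]}/{r.pair[1]}",
                _fmt_range(r.candidate.d_min, r.candidate.d_max),
                f"{r.pp_split:.2f}",
                r.support_band,
                f"{r.gdi_a.mean:.2f} +/- {r.gdi_a.sd:.2f}",
                f"{r.gdi_b.mean:.2f} +/- {r.gdi_b.sd:.2f}",
                r.verdict,
            ]
        buf.write("\t".join(vals) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
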