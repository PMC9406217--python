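"""Weighted gene-set candidate scoring.

Candidate genes are cross-referenced against four phenotype databases —
mitotic G2-G2/M phases, the human kinome, the matrisome, and cell
adhesion — and receive an additive score over their memberships
(defaults +2, +1, +0.5, +0.5). Genes scoring at least the selection
threshold (default 2) are selected; genes carrying clustered binding
motifs bypass the threshold entirely, mirroring the screen's
high-stringency arm.

Gene identifiers are matched exactly after uppercasing; no alias
resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DEFAULT_WEIGHTS",
    "GeneSetCollection",
    "CandidateScore",
    "read_gmt",
    "score_gene",
    "assemble_candidates",
    "bundled_gene_sets",
]

#: Database weights of the selection score.
DEFAULT_WEIGHTS: dict[str, float] = {
    "G2M": 2.0,
    "kinome": 1.0,
    "matrisome": 0.5,
    "adhesion": 0.5,
}

#: Selection threshold for non-clustered candidates.
DEFAULT_THRESHOLD = 2.0

#: Candidate provenance tags, in collapse priority order.
SOURCES = ("clustered_motif", "top100_up", "top100_down", "motif_pool")


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line (name, description, members)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
            name = fields[0]
            sets[name] = {g.strip().upper() for g in fields[2:] if g.strip()}
    return sets


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with strictly positive selection weights."""

    sets: dict[str, frozenset[str]]
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        norm = {name: frozenset(g.upper() for g in members)
                for name, members in self.sets.items()}
        object.__setattr__(self, "sets", norm)
        for name in norm:
            if name not in self.weights:
                raise ValueError(f"no weight assigned to gene set {name!r}")
        for name, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"weight for {name!r} must be strictly positive")

    @classmethod
    def from_gmt_files(
        cls,
        paths: Mapping[str, "str | Path"],
        weights: Mapping[str, float] | None = None,
    ) -> "GeneSetCollection":
        """Load one GMT file per set name (first set of each file)."""
        sets = {}
        for name, path in paths.items():
            parsed = read_gmt(path)
            if name in parsed:
                sets[name] = frozenset(parsed[name])
            else:
                sets[name] = frozenset(next(iter(parsed.values())))
        w = dict(DEFAULT_WEIGHTS) if weights is None else dict(weights)
        return cls(sets=sets, weights=w)

    @classmethod
    def from_gmt_dir(
        cls, directory, weights: Mapping[str, float] | None = None
    ) -> "GeneSetCollection":
        """Load every set from every ``*.gmt`` file in a directory.

        Set names must match weight keys (default weights cover G2M,
        kinome, matrisome, adhesion).
        """
        sets: dict[str, frozenset[str]] = {}
        for path in sorted(Path(directory).glob("*.gmt")):
            for name, members in read_gmt(path).items():
                sets[name] = frozenset(members)
        if not sets:
            raise FileNotFoundError(f"no .gmt files found in {directory}")
        w = dict(DEFAULT_WEIGHTS) if weights is None else dict(weights)
        return cls(sets=sets, weights=w)

    def memberships(self, gene_id: str) -> tuple[str, ...]:
        g = gene_id.upper()
        return tuple(sorted(name for name, s in self.sets.items() if g in s))


def bundled_gene_sets() -> GeneSetCollection:
    """Small synthetic example snapshots of the four databases.

    Bundled for tests and worked examples only; real analyses should
    supply current database exports (the snapshots drift over time).
    """
    ref = resources.files("foxscreen.data").joinpath("example_sets.gmt")
    with resources.as_file(ref) as path:
        sets = read_gmt(path)
    return GeneSetCollection(sets={k: frozenset(v) for k, v in sets.items()})


@dataclass(frozen=True)
class CandidateScore:
    """A gene's database memberships and weighted selection score."""

    gene_id: str
    memberships: tuple[str, ...]
    score: float
    selected: bool
    source: str | None = None


def score_gene(
    gene_id: str,
    sets: GeneSetCollection,
    threshold: float = DEFAULT_THRESHOLD,
    source: str | None = None,
) -> CandidateScore:
    """Score one gene: additive weights over memberships.

    A gene absent from every set scores 0. ``selected`` is True when
    the score reaches the threshold, or unconditionally for
    clustered-motif candidates.
    """
    memberships = sets.memberships(gene_id)
    score = sum(sets.weights[m] for m in memberships)
    selected = (score >= threshold) or (source == "clustered_motif")
    return CandidateScore(
        gene_id=gene_id.upper(), memberships=memberships,
        score=score, selected=selected, source=source,
    )


def assemble_candidates(
    top_up: Iterable[str],
    top_down: Iterable[str],
    motif_pool: Iterable[str],
    clustered: Iterable[str],
    sets: GeneSetCollection,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Score all candidate pools and apply the selection rule.

    The candidate list is the union of (i) genes from the top-up,
    top-down and motif pools whose score reaches the threshold and
    (ii) every clustered-motif gene, which bypasses the threshold.
    Duplicate genes collapse to a single record; the clustered_motif
    source tag wins any collapse. Output is a DataFrame over all input
    genes (``selected`` flags the candidates), sorted by score
    descending then gene_id, invariant to input order.
    """
    pools = {
        "top100_up": top_up,
        "top100_down": top_down,
        "motif_pool": motif_pool,
        "clustered_motif": clustered,
    }
    source_of: dict[str, str] = {}
    for tag in reversed(SOURCES):  # ascending priority; clustered wins last
        for g in pools[tag]:
            source_of[g.upper()] = tag

    records = [
        score_gene(g, sets, threshold=threshold, source=tag)
        for g, tag in source_of.items()
    ]
    df = pd.DataFrame({
        "gene_id": [r.gene_id for r in records],
        "memberships": [",".join(r.memberships) for r in records],
        "score": [r.score for r in records],
        "selected": [r.selected for r in records],
        "source": [r.source for r in records],
    })
    return df.sort_values(
        by=["score", "gene_id"], ascending=[False, True], kind="mergesort",
    ).reset_index(drop=True)
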