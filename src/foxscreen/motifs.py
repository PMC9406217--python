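"""PWM scanning of promoter windows with a deficit cutoff, and
clustered-motif detection.

A position frequency matrix (JASPAR text format) is converted to a
log-odds scoring matrix. A window of sequence is reported as a hit iff

* every *core* position (information content >= a threshold, default
  1 bit) matches the consensus base exactly, and
* the range-normalised score shortfall, the *deficit*
  ``(S_max - S) / (S_max - S_min)``, is at most the cutoff
  (default 0.15, i.e. 15% tolerance for mismatches outside the core).

Two or more hits in one promoter whose starts chain together within a
distance window (default 100 bp, inclusive) form a motif cluster —
homotypic site clustering being the signature of direct transcriptional
control the screen keys on.

Coordinates are 0-based half-open throughout; reverse-strand hits are
reported with forward-strand window-start coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PFM",
    "PWM",
    "MotifHit",
    "MotifCluster",
    "read_jaspar",
    "build_pwm",
    "scan_sequence",
    "find_clusters",
    "promoter_window",
]

_ALPHABET = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: base counts per position.

    ``counts`` has shape (4, width), rows in A, C, G, T order.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, width)")
        if counts.shape[1] < 4:
            raise ValueError("matrix width must be >= 4")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        bg = np.asarray(self.background, dtype=float)
        if abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
            raise ValueError("background must be positive and sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


def read_jaspar(path, pseudocount: float = 0.5) -> PFM:
    """Read the first matrix from a JASPAR-format text file."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in _ALPHABET], dtype=float)
    return PFM(name=motif.name or "matrix", counts=counts, pseudocount=pseudocount)


@dataclass(frozen=True)
class PWM:
    """Log-odds scoring matrix derived from a :class:`PFM`.

    ``logodds`` has shape (4, width); ``s_max``/``s_min`` are the best
    and worst achievable window scores; ``core_mask`` marks positions
    whose information content reaches the core threshold, at which no
    mismatch from the consensus is tolerated.
    """

    name: str
    logodds: np.ndarray
    s_max: float
    s_min: float
    consensus: str
    consensus_idx: np.ndarray
    core_mask: np.ndarray
    info_content: np.ndarray

    @property
    def width(self) -> int:
        return self.logodds.shape[1]

    def score(self, word: str) -> float:
        """Score a single word of matrix width (forward strand)."""
        if len(word) != self.width:
            raise ValueError("word length must equal matrix width")
        idx = _encode(word)
        if (idx < 0).any():
            raise ValueError("word contains non-ACGT characters")
        return float(self.logodds[idx, np.arange(self.width)].sum())

    def deficit(self, score: float) -> float:
        rng = self.s_max - self.s_min
        if rng <= 0:
            return 0.0
        return (self.s_max - score) / rng


def build_pwm(pfm: PFM, core_ic: float = 1.0) -> PWM:
    """Build a log-odds PWM with consensus and core mask from counts.

    Per-position probabilities are ``(count + pseudocount) /
    (column_total + 4 * pseudocount)``; log-odds are log2 against the
    background. Information content is computed against a uniform
    background (2 bits maximum per position).
    """
    totals = pfm.counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("matrix has a zero-total column")
    probs = (pfm.counts + pfm.pseudocount) / (totals + 4 * pfm.pseudocount)
    bg = np.asarray(pfm.background, dtype=float)[:, None]
    logodds = np.log2(probs / bg)
    s_max = float(logodds.max(axis=0).sum())
    s_min = float(logodds.min(axis=0).sum())
    consensus_idx = np.argmax(probs, axis=0)
    consensus = "".join(_ALPHABET[i] for i in consensus_idx)
    ic = 2.0 + (probs * np.log2(probs)).sum(axis=0)
    core_mask = ic >= core_ic
    return PWM(
        name=pfm.name, logodds=logodds, s_max=s_max, s_min=s_min,
        consensus=consensus, consensus_idx=consensus_idx,
        core_mask=core_mask, info_content=ic,
    )


@dataclass(frozen=True)
class MotifHit:
    """One retained PWM match within a promoter window."""

    promoter_id: str
    start: int
    strand: str
    score: float
    deficit: float


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_ALPHABET):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def _scan_one_strand(idx: np.ndarray, pwm: PWM, cutoff: float) -> list[tuple[int, float, float]]:
    w = pwm.width
    n_win = len(idx) - w + 1
    if n_win <= 0:
        return []
    win = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win < 0, 0, win)
    cols = np.arange(w)
    scores = pwm.logodds[safe, cols].sum(axis=1)
    core = pwm.core_mask
    if core.any():
        core_ok = (safe[:, core] == pwm.consensus_idx[core]).all(axis=1)
    else:
        core_ok = np.ones(n_win, dtype=bool)
    rng = pwm.s_max - pwm.s_min
    if rng > 0:
        deficit = (pwm.s_max - scores) / rng
    else:
        deficit = np.zeros(n_win)
    keep = valid & core_ok & (deficit <= cutoff + 1e-12)
    return [(int(p), float(scores[p]), float(max(deficit[p], 0.0)))
            for p in np.nonzero(keep)[0]]


def scan_sequence(
    seq: str,
    pwm: PWM,
    deficit_cutoff: float = 0.15,
    both_strands: bool = True,
    promoter_id: str = "",
) -> list[MotifHit]:
    """Scan one sequence for PWM matches under the deficit cutoff.

    Windows containing any non-ACGT character are skipped. Reverse-
    strand matches are scored on the reverse complement and reported at
    the forward coordinate of the window start. A sequence shorter than
    the matrix width yields no hits. Hits are sorted by (start, strand).
    """
    idx = _encode(seq)
    L = len(idx)
    w = pwm.width
    hits = [
        MotifHit(promoter_id, start, "+", score, deficit)
        for start, score, deficit in _scan_one_strand(idx, pwm, deficit_cutoff)
    ]
    if both_strands:
        rc = _encode_revcomp(idx)
        for p_rc, score, deficit in _scan_one_strand(rc, pwm, deficit_cutoff):
            hits.append(MotifHit(promoter_id, L - w - p_rc, "-", score, deficit))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _encode_revcomp(idx: np.ndarray) -> np.ndarray:
    rc = idx[::-1].copy()
    pos = rc >= 0
    rc[pos] = 3 - rc[pos]
    return rc


@dataclass(frozen=True)
class MotifCluster:
    """Two or more hits in one promoter chained within the distance window."""

    promoter_id: str
    starts: tuple[int, ...]
    span: int  # max pairwise start distance, bp

    def __post_init__(self) -> None:
        if len(self.starts) < 2:
            raise ValueError("a cluster needs at least 2 members")


def find_clusters(
    hits: list[MotifHit],
    window: int = 100,
    measure: str = "start",
    motif_width: int | None = None,
) -> list[MotifCluster]:
    """Single-linkage chaining of hits from one promoter.

    Consecutive starts within ``window`` (inclusive) join one cluster;
    clusters with >= 2 members are reported. ``measure="start"``
    (default) uses start-to-start distance; ``measure="edge"`` uses the
    gap between one hit's end and the next hit's start and requires
    ``motif_width``. Hits at the same start on both strands count as
    distinct members at distance 0.
    """
    if measure not in ("start", "edge"):
        raise ValueError("measure must be 'start' or 'edge'")
    if measure == "edge" and motif_width is None:
        raise ValueError("edge measure requires motif_width")
    if not hits:
        return []
    prom_ids = {h.promoter_id for h in hits}
    if len(prom_ids) > 1:
        raise ValueError("find_clusters expects hits from a single promoter")
    promoter_id = prom_ids.pop()

    starts = sorted(h.start for h in hits)
    offset = 0 if measure == "start" else motif_width
    clusters: list[MotifCluster] = []
    chain = [starts[0]]
    for s in starts[1:]:
        if s - (chain[-1] + offset) <= window:
            chain.append(s)
        else:
            if len(chain) >= 2:
                clusters.append(MotifCluster(promoter_id, tuple(chain),
                                             chain[-1] - chain[0]))
            chain = [s]
    if len(chain) >= 2:
        clusters.append(MotifCluster(promoter_id, tuple(chain),
                                     chain[-1] - chain[0]))
    return clusters


def promoter_window(
    tss: int,
    upstream: int = 1500,
    downstream: int = 500,
    strand: str = "+",
) -> tuple[int, int]:
    """0-based half-open promoter interval around a TSS, strand-oriented.

    On the + strand the window is [tss - upstream, tss + downstream);
    on the - strand it is mirrored. A window that would extend past
    coordinate 0 is truncated with a warning.
    """
    if tss < 0:
        raise ValueError("tss must be non-negative")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    if start < 0:
        warnings.warn(
            f"promoter window for tss={tss} truncated at sequence start",
            stacklevel=2)
        start = 0
    return start, end
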