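"""PWM construction, deficit scanning, clustering, promoter windows."""

import itertools

import numpy as np
import pytest

from foxscreen import motifs
from foxscreen.motifs import (
    PFM,
    MotifHit,
    build_pwm,
    find_clusters,
    promoter_window,
    scan_sequence,
)

from conftest import random_dna

BASES = "ACGT"


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_hits(seq, pwm, cutoff=0.15, both_strands=True):
    """Naive per-window rescoring, independent of the vectorized scanner."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    w = pwm.width
    rng_score = pwm.s_max - pwm.s_min
    hits = []

    def word_hit(word):
        if any(b not in BASES for b in word):
            return None
        for j in range(w):
            if pwm.core_mask[j] and word[j] != pwm.consensus[j]:
                return None
        score = sum(pwm.logodds[BASES.index(word[j]), j] for j in range(w))
        deficit = 0.0 if rng_score <= 0 else (pwm.s_max - score) / rng_score
        if deficit <= cutoff + 1e-12:
            return score, max(deficit, 0.0)
        return None

    for start in range(len(seq) - w + 1):
        word = seq[start:start + w]
        res = word_hit(word)
        if res is not None:
            hits.append((start, "+", round(res[1], 9)))
        if both_strands:
            rc = "".join(comp[b] for b in reversed(word))
            res = word_hit(rc)
            if res is not None:
                hits.append((start, "-", round(res[1], 9)))
    return sorted(hits)


def transitive_closure_clusters(starts, window):
    """O(n^2) all-pairs chaining oracle for cluster membership."""
    starts = sorted(starts)
    n = len(starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(starts[i] - starts[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(starts[i])
    return sorted(tuple(sorted(g)) for g in groups.values() if len(g) >= 2)


# ---------------------------------------------------------------------------
# PWM construction
# ---------------------------------------------------------------------------

def test_uniform_pfm_gives_flat_scores():
    pfm = PFM(name="flat", counts=np.full((4, 6), 25.0))
    pwm = build_pwm(pfm)
    assert np.allclose(pwm.logodds, 0.0)
    assert pwm.s_max == pwm.s_min == 0.0
    assert not pwm.core_mask.any()
    assert pwm.deficit(0.0) == 0.0


def test_single_base_columns_define_consensus():
    counts = np.zeros((4, 5))
    word = "ACGTA"
    for j, b in enumerate(word):
        counts[BASES.index(b), j] = 100.0
    pwm = build_pwm(PFM(name="w", counts=counts))
    assert pwm.consensus == word
    assert pwm.core_mask.all()


def test_smax_matches_exhaustive_word_enumeration(rng):
    counts = rng.integers(0, 60, size=(4, 8)).astype(float)
    counts[0] += 1  # avoid zero columns
    pwm = build_pwm(PFM(name="r", counts=counts))
    best = max(
        sum(pwm.logodds[BASES.index(b), j] for j, b in enumerate(word))
        for word in itertools.product(BASES, repeat=8)
    )
    assert pwm.s_max == pytest.approx(best, abs=1e-9)
    assert pwm.score(pwm.consensus) == pytest.approx(pwm.s_max, abs=1e-9)


def test_zero_column_rejected():
    counts = np.full((4, 4), 10.0)
    counts[:, 2] = 0.0
    with pytest.raises(ValueError, match="zero"):
        build_pwm(PFM(name="z", counts=counts))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_planted_consensus_scores_zero_deficit(forkhead_pwm, rng):
    seq = random_dna(rng, 400)
    seq = seq[:150] + forkhead_pwm.consensus + seq[150 + forkhead_pwm.width:]
    hits = scan_sequence(seq, forkhead_pwm)
    planted = [h for h in hits if h.start == 150 and h.strand == "+"]
    assert len(planted) == 1
    assert planted[0].deficit == pytest.approx(0.0, abs=1e-12)


def test_core_mismatch_kills_hit_regardless_of_deficit(forkhead_pwm, rng):
    core_pos = int(np.flatnonzero(forkhead_pwm.core_mask)[0])
    word = list(forkhead_pwm.consensus)
    word[core_pos] = "C" if word[core_pos] != "C" else "A"
    seq = random_dna(rng, 200)
    seq = seq[:80] + "".join(word) + seq[80 + forkhead_pwm.width:]
    hits = scan_sequence(seq, forkhead_pwm, deficit_cutoff=1.0)
    assert not any(h.start == 80 and h.strand == "+" for h in hits)


def test_short_sequence_yields_no_hits(forkhead_pwm):
    assert scan_sequence("ACGT", forkhead_pwm) == []


def test_windows_containing_n_are_skipped(forkhead_pwm):
    seq = forkhead_pwm.consensus.replace(forkhead_pwm.consensus[0], "N", 1)
    assert scan_sequence(seq, forkhead_pwm) == []


@pytest.mark.parametrize("gc", [0.3, 0.5, 0.7])
def test_scanner_equals_brute_force_oracle(forkhead_pwm, gc):
    rng = np.random.default_rng(hash(gc) % 2**31)
    for _ in range(8):
        seq = random_dna(rng, 600, gc=gc)
        # embed near-consensus variants to populate the boundary
        for off in (50, 200, 400):
            word = list(forkhead_pwm.consensus)
            j = int(np.flatnonzero(~forkhead_pwm.core_mask)[0])
            word[j] = rng.choice(list("ACGT"))
            seq = seq[:off] + "".join(word) + seq[off + len(word):]
        got = sorted((h.start, h.strand, round(h.deficit, 9))
                     for h in scan_sequence(seq, forkhead_pwm))
        assert got == brute_force_hits(seq, forkhead_pwm)


def test_reverse_complement_symmetry(forkhead_pwm, rng):
    comp = str.maketrans("ACGT", "TGCA")
    seq = random_dna(rng, 500)
    seq = seq[:100] + forkhead_pwm.consensus + seq[100 + forkhead_pwm.width:]
    rc = seq.translate(comp)[::-1]
    fwd = {(h.start, h.strand) for h in scan_sequence(seq, forkhead_pwm)}
    L, w = len(seq), forkhead_pwm.width
    flipped = {(L - w - s, "-" if st == "+" else "+")
               for s, st in {(h.start, h.strand)
                             for h in scan_sequence(rc, forkhead_pwm)}}
    assert fwd == flipped


def test_deficit_invariant_to_column_offsets(forkhead_pwm, rng):
    """Adding a constant to every entry of a column shifts all scores
    equally, leaving the range-normalised deficit unchanged."""
    shifted = motifs.PWM(
        name="shifted",
        logodds=forkhead_pwm.logodds + 0.7,
        s_max=forkhead_pwm.s_max + 0.7 * forkhead_pwm.width,
        s_min=forkhead_pwm.s_min + 0.7 * forkhead_pwm.width,
        consensus=forkhead_pwm.consensus,
        consensus_idx=forkhead_pwm.consensus_idx,
        core_mask=forkhead_pwm.core_mask,
        info_content=forkhead_pwm.info_content,
    )
    seq = random_dna(rng, 800)
    a = [(h.start, h.strand, round(h.deficit, 9))
         for h in scan_sequence(seq, forkhead_pwm)]
    b = [(h.start, h.strand, round(h.deficit, 9))
         for h in scan_sequence(seq, shifted)]
    assert a == b


def test_planted_recall_is_total_at_default_cutoff(forkhead_pwm):
    """Every planted consensus instance is recovered at cutoff 0.15."""
    from foxscreen.simulate import SynthPromoterConfig, generate_promoters

    planted = tuple((i, 40 * i + 17, "+" if i % 2 else "-") for i in range(50))
    cfg = SynthPromoterConfig(n_promoters=50, planted=planted, seed=11)
    records, truth = generate_promoters(cfg, forkhead_pwm)
    found = 0
    for (pid, seq), (_, row) in zip(records, truth.iterrows()):
        hits = scan_sequence(seq, forkhead_pwm, promoter_id=pid)
        assert any(h.start == row["offset"] and h.strand == row["strand"]
                   for h in hits)
        found += 1
    assert found == 50


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _hits(starts, pid="p"):
    return [MotifHit(pid, s, "+", 0.0, 0.0) for s in starts]


def test_cluster_distance_boundary_inclusive():
    assert len(find_clusters(_hits([10, 110]), window=100)) == 1
    assert find_clusters(_hits([10, 111]), window=100) == []


def test_clusters_match_transitive_closure_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(0, 12))
        starts = sorted(int(s) for s in rng.integers(0, 1500, n))
        got = sorted(tuple(c.starts) for c in find_clusters(_hits(starts)))
        assert got == transitive_closure_clusters(starts, 100)


def test_cluster_span_is_max_pairwise_distance():
    (cluster,) = find_clusters(_hits([5, 80, 160]), window=100)
    assert cluster.starts == (5, 80, 160)
    assert cluster.span == 155


def test_edge_measure_uses_gap_between_hits():
    # starts 0 and 110 with width 12: gap 98 <= 100 clusters under edge
    # measure but start-to-start distance 110 does not
    hits = _hits([0, 110])
    assert find_clusters(hits, window=100, measure="start") == []
    assert len(find_clusters(hits, window=100, measure="edge",
                             motif_width=12)) == 1


def test_mixed_promoters_rejected():
    hits = _hits([0], "a") + _hits([10], "b")
    with pytest.raises(ValueError, match="single promoter"):
        find_clusters(hits)


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "tss, strand, expected",
    [(5000, "+", (3500, 5500)), (5000, "-", (4500, 6500))],
)
def test_promoter_window_orientation(tss, strand, expected):
    assert promoter_window(tss, strand=strand) == expected


def test_promoter_window_truncates_with_warning():
    with pytest.warns(UserWarning, match="truncated"):
        assert promoter_window(1000) == (0, 1500)
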