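"""Synthetic inputs with ground truth for every stage of the screen.

Each generator emulates one class of raw data the screen consumes —
differential-expression tables, promoter FASTA with planted binding
sites, DNA-content cytometry events, dose-response plates, and
three-channel (Hoechst / Calcein / EthD1) fluorescence images — and
returns, next to the data, a truth table sufficient to score the
corresponding analysis stage without re-deriving labels.

All randomness flows through ``numpy.random.default_rng(seed)``;
identical configuration and seed give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SynthDEConfig",
    "SynthPromoterConfig",
    "SynthCytometryConfig",
    "SynthPlateConfig",
    "SynthImageConfig",
    "generate_de_table",
    "generate_promoters",
    "generate_cytometry_events",
    "generate_plate",
    "generate_images",
    "generate_gene_sets",
    "reference_image_config",
    "REFERENCE_IMAGES_PER_CONDITION",
    "write_fasta",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthDEConfig:
    """Configuration of a synthetic differential-expression table.

    The table emulates the output of a two-condition Wald-test DE fit:
    per-gene fold change (knockout contrast, parental over null), log2
    fold change, raw and adjusted p-values, with a stated fraction of
    rows lacking an adjusted p-value (independent-filtering casualties).
    """

    n_genes: int = 1000
    frac_differential: float = 0.3
    frac_missing_padj: float = 0.05
    lfc_sd: float = 2.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        _check_fraction("frac_differential", self.frac_differential)
        _check_fraction("frac_missing_padj", self.frac_missing_padj)
        if self.lfc_sd <= 0:
            raise ConfigurationError("lfc_sd must be positive")


def generate_de_table(cfg: SynthDEConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a DE table and its truth labels.

    Returns ``(table, truth)``. ``table`` has columns ``gene_id``,
    ``fold_change``, ``log_fold_change``, ``p``, ``p_adj`` (NaN = missing);
    exactly ``round(frac_missing_padj * n_genes)`` rows have missing
    ``p_adj``. ``truth`` records the intended status/direction per gene:
    adjusted p-values are placed on the correct side of ``alpha`` by
    construction, so downstream classification can be scored exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_missing = int(round(cfg.frac_missing_padj * n))
    n_diff = min(int(round(cfg.frac_differential * n)), n - n_missing)

    status = np.array(["equal"] * n, dtype=object)
    order = rng.permutation(n)
    status[order[:n_missing]] = "uninterpretable"
    status[order[n_missing:n_missing + n_diff]] = "differential"

    lfc = np.zeros(n)
    p_adj = np.full(n, np.nan)
    direction = np.array(["none"] * n, dtype=object)

    diff = status == "differential"
    eq = status == "equal"
    miss = status == "uninterpretable"

    # differential genes: |lfc| bounded away from 0 so direction is defined
    n_d = int(diff.sum())
    mag = np.abs(rng.normal(0.0, cfg.lfc_sd, n_d)) + 0.25
    sign = rng.choice([-1.0, 1.0], n_d)
    lfc[diff] = sign * mag
    p_adj[diff] = rng.uniform(0.0, cfg.alpha, n_d)
    direction[diff] = np.where(sign > 0, "up", "down")

    n_e = int(eq.sum())
    lfc[eq] = rng.normal(0.0, cfg.lfc_sd / 4.0, n_e)
    p_adj[eq] = rng.uniform(cfg.alpha + 1e-6, 1.0, n_e)

    lfc[miss] = rng.normal(0.0, cfg.lfc_sd / 4.0, int(miss.sum()))

    p = np.where(np.isnan(p_adj), rng.uniform(0.0, 1.0, n),
                 p_adj * rng.uniform(0.05, 1.0, n))

    gene_id = np.array([f"GENE{i:05d}" for i in range(n)])
    table = pd.DataFrame({
        "gene_id": gene_id,
        "fold_change": np.exp2(lfc),
        "log_fold_change": lfc,
        "p": p,
        "p_adj": p_adj,
    })
    truth = pd.DataFrame({
        "gene_id": gene_id,
        "true_status": status,
        "true_direction": direction,
    })
    return table, truth


# ---------------------------------------------------------------------------
# Promoters with planted motif instances
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthPromoterConfig:
    """Synthetic promoter windows (i.i.d. background, configurable GC).

    ``planted`` lists (promoter index, 0-based start offset, strand) of
    motif instances to embed; each instance is the matrix consensus
    (deficit 0 by construction) unless ``mutation_rate`` > 0, in which
    case non-core positions are mutated independently at that rate.
    """

    n_promoters: int = 10
    window_upstream: int = 1500
    window_downstream: int = 500
    gc_content: float = 0.45
    planted: tuple[tuple[int, int, str], ...] = ()
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_fraction("gc_content", self.gc_content)
        _check_fraction("mutation_rate", self.mutation_rate)
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise ConfigurationError("window sizes must be non-negative")
        if self.window_upstream + self.window_downstream < 1:
            raise ConfigurationError("window must have positive length")

    @property
    def length(self) -> int:
        return self.window_upstream + self.window_downstream


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def generate_promoters(
    cfg: SynthPromoterConfig,
    pwm,
    ids: Sequence[str] | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate promoter sequences with planted motif instances.

    ``pwm`` is a :class:`foxscreen.motifs.PWM` (supplies consensus and
    core mask). Returns ``(records, truth)`` where ``records`` is a list
    of ``(id, sequence)`` pairs (headers default to ``promoter_<i>``)
    and ``truth`` lists every planted site (promoter_id, offset, strand).
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length
    width = pwm.width
    if width > L:
        raise ConfigurationError("matrix width exceeds the promoter window")
    for prom, off, strand in cfg.planted:
        if not (0 <= prom < cfg.n_promoters):
            raise ConfigurationError(f"planted promoter index {prom} out of range")
        if not (0 <= off <= L - width):
            raise ConfigurationError(
                f"planted offset {off} outside window of length {L}")
        if strand not in "+-":
            raise ConfigurationError(f"invalid strand {strand!r}")

    if ids is None:
        ids = [f"promoter_{i}" for i in range(cfg.n_promoters)]
    elif len(ids) != cfg.n_promoters:
        raise ConfigurationError("ids length must equal n_promoters")

    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = [
        "".join(rng.choice(_BASES, size=L, p=probs)) for _ in range(cfg.n_promoters)
    ]

    consensus = pwm.consensus
    core = np.asarray(pwm.core_mask, dtype=bool)
    rows = []
    for prom, off, strand in cfg.planted:
        site = list(consensus)
        if cfg.mutation_rate > 0:
            for j in range(width):
                if not core[j] and rng.random() < cfg.mutation_rate:
                    site[j] = rng.choice([b for b in "ACGT" if b != site[j]])
        word = "".join(site)
        if strand == "-":
            word = _revcomp(word)
        s = seqs[prom]
        seqs[prom] = s[:off] + word + s[off + width:]
        rows.append({"promoter_id": ids[prom], "offset": off, "strand": strand})

    truth = pd.DataFrame(rows, columns=["promoter_id", "offset", "strand"])
    return list(zip(ids, seqs)), truth


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (60-column wrapping)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# DNA-content cytometry events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthCytometryConfig:
    """Gaussian-mixture DNA-content model.

    G1 events ~ Normal(g1_mean, cv*g1_mean); G2/M events ~
    Normal(2*g1_mean, cv*2*g1_mean) (constant coefficient of variation,
    as for DNA stains); S events uniform on (g1_mean, 2*g1_mean).
    """

    n_events: int = 10_000
    g1_mean: float = 100.0
    cv: float = 0.03
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g1_mean <= 0:
            raise ConfigurationError("g1_mean must be positive")
        if self.cv < 0:
            raise ConfigurationError("cv must be non-negative")
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        for f in self.fractions:
            _check_fraction("phase fraction", f)
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError("fractions must sum to 1")


def generate_cytometry_events(
    cfg: SynthCytometryConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-event DNA content. Returns ``(events, labels)``.

    Phase counts are multinomial in the configured fractions; the two
    arrays are aligned and shuffled together.
    """
    rng = np.random.default_rng(cfg.seed)
    n_g1, n_s, n_g2 = rng.multinomial(cfg.n_events, cfg.fractions)
    m = cfg.g1_mean
    g1 = rng.normal(m, cfg.cv * m, n_g1)
    s = rng.uniform(m, 2 * m, n_s)
    g2 = rng.normal(2 * m, cfg.cv * 2 * m, n_g2)
    events = np.concatenate([g1, s, g2])
    labels = np.array(["g1"] * n_g1 + ["s"] * n_s + ["g2m"] * n_g2, dtype=object)
    perm = rng.permutation(cfg.n_events)
    return events[perm], labels[perm]


# ---------------------------------------------------------------------------
# Dose-response plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthPlateConfig:
    """Hill-curve dose-response plate with Poisson well counts.

    Expected total per well is ``vehicle_mean * (1 - emax * d^h /
    (d^h + ec50^h))``; dead counts are binomial in a per-dose death
    rate (flat ``base_death`` plus an optional Hill term for genuinely
    toxic compounds). Dose 0 wells are the vehicle controls.
    """

    compound: str = "compound"
    vehicle_mean: float = 2000.0
    doses: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    ec50: float = 2.0
    hill: float = 2.0
    emax: float = 0.5
    base_death: float = 0.03
    death_emax: float = 0.0
    death_ec50: float = 4.0
    death_hill: float = 2.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vehicle_mean <= 0:
            raise ConfigurationError("vehicle_mean must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        _check_fraction("emax", self.emax)
        _check_fraction("base_death", self.base_death)
        _check_fraction("death_emax", self.death_emax)
        if any(d < 0 for d in self.doses):
            raise ConfigurationError("doses must be non-negative")


def _hill(d: float, emax: float, ec50: float, h: float) -> float:
    if d <= 0 or emax == 0:
        return 0.0
    return emax * d ** h / (d ** h + ec50 ** h)


def generate_plate(cfg: SynthPlateConfig) -> pd.DataFrame:
    """Simulate a plate in long format.

    Columns: compound, dose, replicate, total, dead. Vehicle wells are
    included as dose 0.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for dose in (0.0, *cfg.doses):
        mean = cfg.vehicle_mean * (1.0 - _hill(dose, cfg.emax, cfg.ec50, cfg.hill))
        death = min(1.0, cfg.base_death
                    + _hill(dose, cfg.death_emax, cfg.death_ec50, cfg.death_hill))
        for rep in range(cfg.n_replicates):
            total = int(rng.poisson(mean))
            dead = int(rng.binomial(total, death)) if total > 0 else 0
            rows.append({
                "compound": cfg.compound, "dose": dose, "replicate": rep,
                "total": total, "dead": dead,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Three-channel 3D-culture images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthImageConfig:
    """Disk-based nucleus/colony image model.

    One Calcein blob per colony; one blurred Hoechst disk per nucleus
    (fragmented nuclei drawn as 2-3 small disks, each <= 30% of the
    parent area, inside the parent footprint); EthD1 marks dead
    colonies; anuclear colonies carry no Hoechst signal. Channels are
    Gaussian-blurred then Poisson-sampled, 16-bit.
    """

    shape: tuple[int, int] = (512, 512)
    n_colonies: int = 10
    colony_radius_mean: float = 42.0
    colony_radius_sd: float = 6.0
    nuclei_per_colony_mean: float = 7.0
    nucleus_area_mean: float = 120.0
    nucleus_area_sd: float = 35.0
    frac_fragmented: float = 0.05
    frac_anuclear: float = 0.05
    frac_dead: float = 0.1
    blur_sigma: float = 1.0
    poisson_gain: float = 1.0
    bg_level: float = 100.0
    nucleus_level: float = 3000.0
    colony_level: float = 1500.0
    dead_level: float = 2500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_fragmented", "frac_anuclear", "frac_dead"):
            _check_fraction(name, getattr(self, name))
        if self.n_colonies < 0:
            raise ConfigurationError("n_colonies must be >= 0")
        if min(self.shape) < 32:
            raise ConfigurationError("image must be at least 32x32")
        if self.nucleus_area_mean <= 0:
            raise ConfigurationError("nucleus_area_mean must be positive")


#: Fields of view per condition in the default reference evaluation
#: configuration (chosen so each condition yields well over 500
#: segmentable nuclei, the per-condition scale of the source assays).
REFERENCE_IMAGES_PER_CONDITION = 10


def reference_image_config(seed: int, nucleus_area_mean: float = 120.0) -> SynthImageConfig:
    """Default image configuration for end-to-end imaging evaluation."""
    return SynthImageConfig(seed=seed, nucleus_area_mean=nucleus_area_mean)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _place(rng, existing, cx_lo, cx_hi, cy_lo, cy_hi, radius, gap, tries=200):
    """Rejection-sample a disk centre keeping ``gap`` clearance to others."""
    for _ in range(tries):
        cy = rng.uniform(cy_lo, cy_hi)
        cx = rng.uniform(cx_lo, cx_hi)
        ok = all((cy - y) ** 2 + (cx - x) ** 2 >= (radius + r + gap) ** 2
                 for y, x, r in existing)
        if ok:
            return cy, cx
    return None


def _place_in_circle(rng, existing, cy0, cx0, lim, radius, gap, tries=100):
    """Rejection-sample a centre uniformly inside a circle of radius
    ``lim`` around (cy0, cx0), keeping ``gap`` clearance to others.

    Sampling stays in-circle on every try so acceptance is independent
    of the placed disk's own radius (no size-biased dropout).
    """
    for _ in range(tries):
        rho = lim * math.sqrt(rng.random())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        cy = cy0 + rho * math.sin(theta)
        cx = cx0 + rho * math.cos(theta)
        ok = all((cy - y) ** 2 + (cx - x) ** 2 >= (radius + r + gap) ** 2
                 for y, x, r in existing)
        if ok:
            return cy, cx
    return None


def _draw_disk(canvas: np.ndarray, cy: float, cx: float, r: float, level: float):
    from skimage.draw import disk

    rr, cc = disk((cy, cx), r, shape=canvas.shape)
    canvas[rr, cc] = np.maximum(canvas[rr, cc], level)
    return len(rr)


def generate_images(cfg: SynthImageConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one field of view. Returns ``(stack, truth)``.

    ``stack`` is a ``(3, H, W)`` uint16 array in channel order Hoechst,
    Calcein, EthD1. ``truth`` has one row per drawn object (colonies and
    individual nucleus disks — fragments count as separate objects) with
    its class, drawn pixel area, and parentage.
    """
    from scipy import ndimage as ndi

    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.shape
    hoechst = np.zeros((H, W))
    calcein = np.zeros((H, W))
    ethd1 = np.zeros((H, W))

    mu_a, sig_a = _lognormal_params(cfg.nucleus_area_mean, cfg.nucleus_area_sd)

    colonies: list[tuple[float, float, float]] = []
    rows = []
    nucleus_id = 0
    for colony_id in range(cfg.n_colonies):
        r_col = max(10.0, rng.normal(cfg.colony_radius_mean, cfg.colony_radius_sd))
        pos = _place(rng, colonies, r_col + 2, W - r_col - 2,
                     r_col + 2, H - r_col - 2, r_col, gap=6.0)
        if pos is None:
            continue
        cy, cx = pos
        colonies.append((cy, cx, r_col))
        dead = rng.random() < cfg.frac_dead
        anuclear = rng.random() < cfg.frac_anuclear
        area_col = _draw_disk(calcein, cy, cx, r_col, cfg.colony_level)
        if dead:
            _draw_disk(ethd1, cy, cx, r_col, cfg.dead_level)
        rows.append({
            "object": "colony", "object_id": f"c{colony_id}",
            "colony_id": colony_id, "parent_id": "",
            "area": area_col, "cy": cy, "cx": cx,
            "dead": dead, "anuclear": anuclear, "fragmented": False,
        })
        if anuclear:
            continue

        n_nuc = max(1, int(rng.poisson(cfg.nuclei_per_colony_mean)))
        placed: list[tuple[float, float, float]] = []
        for _ in range(n_nuc):
            area = rng.lognormal(mu_a, sig_a)
            r_nuc = math.sqrt(area / math.pi)
            lim = r_col - r_nuc - 2
            if lim <= 0:
                continue
            pos_n = _place_in_circle(rng, placed, cy, cx, lim, r_nuc, gap=4.0)
            if pos_n is None:
                continue
            ny, nx = pos_n
            placed.append((ny, nx, r_nuc))
            fragmented = rng.random() < cfg.frac_fragmented
            if not fragmented:
                drawn = _draw_disk(hoechst, ny, nx, r_nuc, cfg.nucleus_level)
                rows.append({
                    "object": "nucleus", "object_id": f"n{nucleus_id}",
                    "colony_id": colony_id, "parent_id": "",
                    "area": drawn, "cy": ny, "cx": nx,
                    "dead": dead, "anuclear": False, "fragmented": False,
                })
                nucleus_id += 1
            else:
                parent = f"n{nucleus_id}"
                nucleus_id += 1
                n_frag = int(rng.integers(2, 4))  # 2 or 3 fragments
                frags: list[tuple[float, float, float]] = []
                for _ in range(n_frag):
                    # well below the 30%-of-parent envelope, so fragments
                    # stay separable from small intact nuclei
                    fa = rng.uniform(0.10, 0.25) * area
                    fr = math.sqrt(fa / math.pi)
                    fpos = _place(rng, frags, nx - 1.5 * r_nuc, nx + 1.5 * r_nuc,
                                  ny - 1.5 * r_nuc, ny + 1.5 * r_nuc,
                                  fr, gap=3.0, tries=60)
                    if fpos is None:
                        continue
                    fy, fx = fpos
                    frags.append((fy, fx, fr))
                    drawn = _draw_disk(hoechst, fy, fx, fr, cfg.nucleus_level)
                    rows.append({
                        "object": "nucleus", "object_id": f"n{nucleus_id}",
                        "colony_id": colony_id, "parent_id": parent,
                        "area": drawn, "cy": fy, "cx": fx,
                        "dead": dead, "anuclear": False, "fragmented": True,
                    })
                    nucleus_id += 1

    stack = np.empty((3, H, W), dtype=np.uint16)
    for i, canvas in enumerate((hoechst, calcein, ethd1)):
        img = ndi.gaussian_filter(canvas, cfg.blur_sigma) + cfg.bg_level
        if cfg.poisson_gain > 0:
            img = rng.poisson(img / cfg.poisson_gain) * cfg.poisson_gain
        stack[i] = np.clip(img, 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(rows, columns=[
        "object", "object_id", "colony_id", "parent_id", "area",
        "cy", "cx", "dead", "anuclear", "fragmented",
    ])
    return stack, truth


# ---------------------------------------------------------------------------
# Synthetic gene-set memberships
# ---------------------------------------------------------------------------

def generate_gene_sets(
    gene_ids: Sequence[str],
    probs: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Assign genes to named sets independently with per-set probability.

    Emulates the phenotype-database snapshots the scoring stage consumes;
    returns ``{set_name: {gene_id, ...}}`` with known (planted) truth.
    """
    if probs is None:
        probs = {"G2M": 0.05, "kinome": 0.05, "matrisome": 0.05, "adhesion": 0.05}
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    for name, p in probs.items():
        _check_fraction(f"membership probability for {name}", p)
        mask = rng.random(len(gene_ids)) < p
        sets[name] = {g.upper() for g, m in zip(gene_ids, mask) if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "synthetic") -> None:
    """Write gene sets in GMT format (name, description, members)."""
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
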