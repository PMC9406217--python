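"""End-to-end orchestration: simulate -> de-filter -> scan -> score.

A single :class:`RunConfig` carries every stage parameter (defaults are
the screen's published constants: alpha 0.05, deficit 0.15, cluster
window 100 bp, promoter window 1500/500, weights 2/1/0.5/0.5,
threshold 2, top-k 100) plus stage toggles and a seed. ``run_screen``
executes the enabled stages in dependency order, writes per-stage TSVs
and a JSON manifest with SHA-256 hashes of every output, and logs the
record counts at each step of the selection funnel. Identical config
and seed reproduce identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, motifs, scoring, simulate

__all__ = ["RunConfig", "PipelineError", "run_screen"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage's upstream requirement is missing."""


@dataclass
class RunConfig:
    """Global configuration of a screen run; round-trips via YAML."""

    seed: int = 0
    out_dir: str = "foxscreen_run"

    # stage toggles
    simulate: bool = True
    de_filter: bool = True
    scan: bool = True
    score: bool = True

    # analysis parameters (defaults: published values)
    alpha: float = 0.05
    top_k: int = 100
    deficit_cutoff: float = 0.15
    cluster_window: int = 100
    window_upstream: int = 1500
    window_downstream: int = 500
    score_threshold: float = 2.0
    weights: dict = field(default_factory=lambda: dict(scoring.DEFAULT_WEIGHTS))

    # synthetic-data parameters
    n_genes: int = 2000
    frac_differential: float = 0.3
    frac_missing_padj: float = 0.05
    lfc_sd: float = 2.0
    n_promoters: int = 40
    gc_content: float = 0.45
    n_clustered_promoters: int = 8
    n_single_promoters: int = 12
    membership_probs: dict = field(default_factory=lambda: {
        "G2M": 0.05, "kinome": 0.05, "matrisome": 0.05, "adhesion": 0.05})

    # external inputs (used when simulation is disabled)
    de_table: str | None = None
    promoters_fasta: str | None = None
    gmt_dir: str | None = None
    pfm_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_pwm(cfg: RunConfig) -> motifs.PWM:
    if cfg.pfm_path:
        pfm = motifs.read_jaspar(cfg.pfm_path)
    else:
        ref = resources.files("foxscreen.data").joinpath("synthetic_forkhead.pfm")
        with resources.as_file(ref) as path:
            pfm = motifs.read_jaspar(path)
    return motifs.build_pwm(pfm)


def _read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def run_screen(cfg: RunConfig) -> dict:
    """Run the enabled stages and return the manifest (also written).

    Raises :class:`PipelineError` naming the stage whose upstream
    output is unavailable.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("foxscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2 ** 31)
    outputs: dict[str, str] = {}
    funnel: dict[str, int] = {}
    pwm = _load_pwm(cfg)

    def write(name: str, df: pd.DataFrame) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = _sha256(path)
        return path

    try:
        # ---- simulate -------------------------------------------------
        if cfg.simulate:
            de_cfg = simulate.SynthDEConfig(
                n_genes=cfg.n_genes, frac_differential=cfg.frac_differential,
                frac_missing_padj=cfg.frac_missing_padj, lfc_sd=cfg.lfc_sd,
                alpha=cfg.alpha, seed=int(seeds[0]))
            table, truth = simulate.generate_de_table(de_cfg)
            write("de_table.tsv", table)
            write("de_truth.tsv", truth)

            rng = np.random.default_rng(int(seeds[1]))
            diff_genes = truth.loc[truth["true_status"] == "differential",
                                   "gene_id"].tolist()
            prom_genes = list(diff_genes[:cfg.n_promoters])
            planted: list[tuple[int, int, str]] = []
            L = cfg.window_upstream + cfg.window_downstream
            w = pwm.width
            for i in range(min(cfg.n_clustered_promoters, len(prom_genes))):
                start = int(rng.integers(0, L - w - 80))
                planted.append((i, start, "+"))
                planted.append((i, start + 60, "+"))  # within the cluster window
            for i in range(cfg.n_clustered_promoters,
                           min(cfg.n_clustered_promoters + cfg.n_single_promoters,
                               len(prom_genes))):
                planted.append((i, int(rng.integers(0, L - w)), "+"))
            prom_cfg = simulate.SynthPromoterConfig(
                n_promoters=len(prom_genes),
                window_upstream=cfg.window_upstream,
                window_downstream=cfg.window_downstream,
                gc_content=cfg.gc_content, planted=tuple(planted),
                seed=int(seeds[2]))
            records, prom_truth = simulate.generate_promoters(
                prom_cfg, pwm, ids=prom_genes)
            fasta_path = out / "promoters.fa"
            simulate.write_fasta(records, fasta_path)
            outputs["promoters.fa"] = _sha256(fasta_path)
            write("promoter_truth.tsv", prom_truth)

            gene_sets = simulate.generate_gene_sets(
                table["gene_id"].tolist(), cfg.membership_probs,
                seed=int(seeds[3]))
            gmt_path = out / "gene_sets.gmt"
            simulate.write_gmt(gene_sets, gmt_path)
            outputs["gene_sets.gmt"] = _sha256(gmt_path)
            log.info("simulate: %d genes, %d promoters, %d planted sites",
                     cfg.n_genes, len(prom_genes), len(planted))

        # ---- de-filter ------------------------------------------------
        top_up = top_down = None
        if cfg.de_filter:
            if cfg.simulate:
                table_path = out / "de_table.tsv"
            elif cfg.de_table:
                table_path = Path(cfg.de_table)
            else:
                raise PipelineError(
                    "stage 'de_filter' requires a DE table: enable simulation "
                    "or set de_table")
            table = pd.read_csv(table_path, sep="\t")
            classified = de.classify_de(table, alpha=cfg.alpha)
            write("de_classified.tsv", classified)
            top_up = de.top_ranked(classified, k=cfg.top_k, direction="up")
            top_down = de.top_ranked(classified, k=cfg.top_k, direction="down")
            write("top_up.tsv", top_up)
            write("top_down.tsv", top_down)
            funnel["differential"] = int((classified["status"] == "differential").sum())
            funnel["top_up"] = len(top_up)
            funnel["top_down"] = len(top_down)
            log.info("de_filter: %d differential, top %d up / %d down",
                     funnel["differential"], len(top_up), len(top_down))

        # ---- scan -----------------------------------------------------
        motif_genes: list[str] = []
        clustered_genes: list[str] = []
        if cfg.scan:
            if cfg.simulate:
                fasta = out / "promoters.fa"
            elif cfg.promoters_fasta:
                fasta = Path(cfg.promoters_fasta)
            else:
                raise PipelineError(
                    "stage 'scan' requires promoter FASTA: enable simulation "
                    "or set promoters_fasta")
            hit_rows, cluster_rows = [], []
            for prom_id, seq in _read_fasta(fasta):
                hits = motifs.scan_sequence(
                    seq, pwm, deficit_cutoff=cfg.deficit_cutoff,
                    promoter_id=prom_id)
                if hits:
                    motif_genes.append(prom_id)
                for h in hits:
                    hit_rows.append({
                        "promoter_id": h.promoter_id, "start": h.start,
                        "end": h.start + pwm.width, "name": pwm.name,
                        "deficit": round(h.deficit, 6), "strand": h.strand,
                    })
                for cl in motifs.find_clusters(hits, window=cfg.cluster_window):
                    cluster_rows.append({
                        "promoter_id": cl.promoter_id,
                        "starts": ",".join(map(str, cl.starts)),
                        "span": cl.span,
                    })
                    clustered_genes.append(cl.promoter_id)
            clustered_genes = sorted(set(clustered_genes))
            write("hits.tsv", pd.DataFrame(
                hit_rows, columns=["promoter_id", "start", "end", "name",
                                   "deficit", "strand"]))
            write("clusters.tsv", pd.DataFrame(
                cluster_rows, columns=["promoter_id", "starts", "span"]))
            funnel["motif_genes"] = len(motif_genes)
            funnel["clustered_genes"] = len(clustered_genes)
            log.info("scan: %d hits, %d genes with motifs, %d clustered",
                     len(hit_rows), len(motif_genes), len(clustered_genes))

        # ---- score ----------------------------------------------------
        if cfg.score:
            if top_up is None:
                raise PipelineError(
                    "stage 'score' requires de_filter outputs: enable de_filter")
            if cfg.simulate:
                sets = scoring.GeneSetCollection(
                    sets={k: frozenset(v) for k, v in
                          scoring.read_gmt(out / "gene_sets.gmt").items()},
                    weights=dict(cfg.weights))
            elif cfg.gmt_dir:
                sets = scoring.GeneSetCollection.from_gmt_dir(
                    cfg.gmt_dir, weights=cfg.weights)
            else:
                raise PipelineError(
                    "stage 'score' requires gene sets: enable simulation "
                    "or set gmt_dir")
            pool = [g for g in motif_genes if g not in set(clustered_genes)]
            candidates = scoring.assemble_candidates(
                top_up["gene_id"], top_down["gene_id"], pool, clustered_genes,
                sets, threshold=cfg.score_threshold)
            write("candidates.tsv", candidates)
            funnel["candidates"] = int(candidates["selected"].sum())
            log.info("score: %d scored, %d selected candidates",
                     len(candidates), funnel["candidates"])

        manifest = {
            "config": dataclasses.asdict(cfg),
            "funnel": funnel,
            "outputs": outputs,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
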