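# foxscreen

Candidate target discovery downstream of a transcription factor, with the
phenotype-validation quantifications needed to test the candidates —
built for knockout-contrast experiments such as a clear cell renal cell
carcinoma line versus its FOXD1-null derivative, where the phenotype of
interest is a delayed G2/M cell-cycle transition.

The package is aimed at computational biologists running (or auditing)
this kind of screen: it turns a differential-expression table, promoter
sequences, a binding-site matrix and gene-set files into a ranked,
scored candidate list with an actionability call per candidate, and it
quantifies the downstream validation assays (dose-response toxicity
plates, DNA-content cell-cycle histograms, 3-channel 3D-culture
images). Every input has a seeded synthetic generator with ground-truth
labels, so the whole pipeline is testable end to end at desk scale.

## The model

**Selection funnel.** Genes with adjusted p ≤ 0.05 are *differential*
(missing adjusted p ⇒ *uninterpretable*, excluded). The top 100 genes
per direction by |log₂ fold change| join genes whose promoter windows
(−1.5 kb/+0.5 kb of the TSS) carry predicted binding sites. A window is
a site when its core positions (information content ≥ 1 bit) match the
consensus and its score deficit

    deficit = (S_max − S) / (S_max − S_min) ≤ 0.15

Two or more sites within 100 bp (start-to-start, inclusive) form a
*clustered* motif — the signature of direct transcriptional control.
Candidates are scored against four phenotype gene sets with weights

    G2/M = +2,  kinome = +1,  matrisome = +0.5,  adhesion = +0.5

and selected when the sum reaches 2; clustered-motif genes are selected
unconditionally. A decision tree then assigns each selected candidate a
required action (inhibit if the gene is down in the knockout, lfc > 0;
activate otherwise) and a compound modality, and refines the panel.

**Validation.** Dose-response summaries (percent growth / inhibition /
viability, one-sided toxicity test, optimal non-toxic dose); cell-cycle
gating anchored on a synchronized G1 control with the G2/M gate centred
at exactly 2× the fitted G1 mean; colony and nucleus segmentation of
Hoechst/Calcein/EthD1 images with anuclear, fragmentation, size-fold and
count statistics. See `docs/methods.md` for assumptions and defaults.

## Worked example

Run the full synthetic screen (simulate → classify → scan → score) from
one seed:

```sh
foxscreen run --config run.yaml   # or: python -m foxscreen.cli run ...
```

with `run.yaml` containing just `seed: 1` and an `out_dir`. The manifest
prints the funnel:

```json
{"differential": 600, "top_up": 100, "top_down": 100,
 "motif_genes": 35, "clustered_genes": 13, "candidates": 19}
```

Of 2000 simulated genes, 600 are differential; the top 100 per
direction plus 35 motif-bearing promoters enter scoring; 13 promoters
carry clustered sites and bypass the score threshold; 19 candidates are
selected. The head of `candidates.tsv`:

```
  gene_id  memberships  score  selected          source
GENE00013 G2M,adhesion    2.5      True clustered_motif
GENE00521          G2M    2.0      True       top100_up
GENE01235          G2M    2.0      True     top100_down
```

Each stage is also available alone — for example, the bundled
18-compound reference panel through the actionability tree:

```sh
$ foxscreen classify-targets --out panel/
12 inhibit, 6 activate, 0 excluded
```

and scanning user promoters with a real JASPAR matrix:

```sh
foxscreen scan --fasta promoters.fa --pfm MA0031.pfm --deficit 0.15 \
    --cluster-window 100 --out hits/
```

The bundled matrix (`data/synthetic_forkhead.pfm`) and gene sets
(`data/example_sets.gmt`) are synthetic stand-ins for tests and
examples; supply real database exports for actual analyses.

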