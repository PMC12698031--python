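# fdassembly

Trait-based community-assembly analysis for sample × species survey data:
functional-diversity metrics and community-weighted means over a mixed
ordinal/categorical trait space, constrained null models, standardized
effect sizes (SES), and assembly-rule classification (habitat filtering vs.
limiting similarity, trait convergence vs. divergence) along a
total-phosphorus (TP) eutrophication gradient. A synthetic-data generator
reproduces a fishpond-style survey design (9 ponds, monthly March–September
incidence sampling, July–September biomass sampling, 59-species pool,
17-category trait codebook) with a *known* assembly regime, so the whole
pipeline can be exercised and validated without any external data.

## Layout

| module | contents |
| --- | --- |
| `fdassembly.core_data` | domain types (community / trait / environment tables, trait codebook), CSV I/O and cross-validation, Hellinger transform, trophic-state classification |
| `fdassembly.trait_space` | Gower dissimilarity with Podani tie-corrected ordinal handling; PCoA embedding (square-root correction by default); axis-count selection |
| `fdassembly.diversity_metrics` | S, Simpson D, FRic (hull volume), FEve (MST), FDiv, FDis, RaoQ, FRed = 1 − RaoQ/D, the FD composite, and CWM; a single `MetricEngine` evaluates observed and null communities identically |
| `fdassembly.null_models` | `c0` / `c0_samp` column-permutation randomizers, null ensembles, SES, Shapiro-branched one-sample tests, assembly-rule labels, Spearman SES–log10(TP) trends |
| `fdassembly.synthetic_community` | seeded generator with `neutral`, `filtering` (Gaussian TP-tolerance kernel) and `limiting_similarity` (Gower-distance rejection) regimes |
| `fdassembly.pipeline` / `fdassembly.cli` | end-to-end orchestration, YAML config, run manifest |

## CLI

```sh
# write a synthetic dataset (3 input CSVs + truth.json)
fdassembly simulate --regime filtering --seed 1 --out data/

# full pipeline on those inputs
fdassembly run --community data/community_incidence.csv \
               --biomass data/community_biomass.csv \
               --traits data/traits.csv --env data/environment.csv \
               --n-iter 999 --seed 1 --out results/

# or simulate + run in one go / via a YAML config
fdassembly run --synthetic --regime neutral --seed 1 --out results/
fdassembly run --config run.yaml

# individual stages
fdassembly metrics  --community ... --traits ... --env ... --mode biomass --out m/
fdassembly null     --community ... --traits ... --env ... --mode incidence \
                    --n-iter 999 --seed 1 --out ses.csv
fdassembly classify --ses ses.csv --env data/environment.csv --out calls.csv
```

`run` writes `fd_metrics.csv`, `cwm.csv`, `ses.csv`, `assembly_calls.csv`,
`trends.csv`, the Gower matrix and trait-space coordinates, and a
`manifest.json` with per-stage row counts and wall times. Identical
configuration + seed ⇒ byte-identical outputs.

## Conventions

- Incidence-based indices weight every present species 1/S; biomass-based
  FD indices use Hellinger-transformed rows renormalized to sum 1, while
  CWM uses raw relative biomass.
- Simpson's D is computed on the same weights as RaoQ, so
  FRed = 1 − RaoQ/D holds row-wise and stays in [0, 1].
- RaoQ uses the raw Gower dissimilarities (a d²/2 convention is available
  via `rao_convention="d2half"`).
- Trophic states: eutrophic [40, 100), hypereutrophic [100, 300), highly
  hypereutrophic [300, ∞) µg L⁻¹ TP (half-open, lower-inclusive).
- The trait space is built once over the full species pool and held fixed
  for observed and null communities (SES comparability). Hull/MST metrics
  use the first m = min(4, s_min − 1, #positive axes) axes; FDis uses all
  positive axes.

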