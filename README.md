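# spnblur

Quantitative analysis of cell-type vulnerability in the striatum for
single-nucleus RNA-seq, centered on the loss of transcriptomic identity of
spiny projection neuron (SPN) subtypes in Huntington's disease (HD) models.

Striatal SPNs are organized along two multiplexed axes: the
striosome-matrix (S-M) compartments and the direct/indirect (D1/D2)
dopamine-receptor pathways, yielding the subtypes M-D1, S-D1, M-D2, S-D2
plus a small atypical "outlier D2" (O-D2) population. `spnblur` implements
the statistics needed to ask, from labelled gene × cell count matrices,
whether and how disease erodes these identities:

- **Pseudobulk differential expression.** Counts are summed per
  (sample, subtype), normalized to log₂ CPM with a prior count, and tested
  per gene by (optionally variance-weighted) least squares with
  Benjamini-Hochberg FDR control. Significance uses |log₂FC| > 0.1 and
  FDR-adjusted p < 0.001 (configurable; a stricter 0.2 variant is provided).
  A bootstrap over samples and cells reports per-gene sign consistency.
- **Marker catalogs.** Compartment markers are genes separating S from M
  within the D1 and/or D2 populations of control cells (*universal* when
  both defining contrasts agree, *selective* otherwise); pathway markers
  are defined symmetrically. Conservation across datasets is summarized as
  Venn overlaps, signed-log₂FC quadrant concordance and a hyper-conserved
  list, via explicit one-to-one ortholog maps.
- **Jensen-Shannon identity distance.** Each (subtype, phenotype) group is
  reduced to a probability vector over genes; the JS distance
  √(½KL(P‖M) + ½KL(Q‖M)), M = ½(P+Q), with base-2 logs lies in [0, 1]. The
  per-pair *loss of distinction* is d(disease) − d(control): negative
  values mean two subtypes became more alike. A regression of loss on the
  endogenous control distance flags pairs above/below the 99% CI band.
- **Dysregulation directionality and severity.** Genes are classified as
  *unidirectional* (one sign of log₂FC across the four canonical subtypes)
  or *bidirectional* (cell-type-dependent signs), given significance in at
  least one subtype; per-subtype severity (mean |log₂FC|) is compared by
  one-way ANOVA with Tukey-Kramer post-hoc tests and across disease models
  by Kendall rank concordance.
- **Synthetic data with ground truth.** A negative-binomial generator
  emulates the assumed statistical structure — marker fold-change structure
  on both axes, symmetric identity blurring scaled by a per-subtype severity
  gradient, cell-type-nonspecific shifts, sample-level replicates,
  library-size/mitochondrial variation and optional subtype depletion — and
  records every injected effect for parameter-recovery testing.

## Worked example

```python
from spnblur import syndata, qc, dge, identity, dysreg

cfg = syndata.SimConfig(seed=1)          # blur_sm=0.5, blur_d1d2=0.1
adata, truth = syndata.generate_dataset(cfg)
adata, report = qc.filter_cells(adata, qc.QcThresholds(species="mouse"))
print(f"retained {report.n_retained}/{report.n_input} cells")

pb = dge.aggregate_pseudobulk(adata)
hd = {t: dge.dge_hd_vs_control(pb, t) for t in cfg.subtypes}

profiles = {ph: {t: identity.subtype_profile(adata, t, ph)
                 for t in cfg.subtypes} for ph in ("control", "HD")}
losses = identity.distance_loss(profiles["control"], profiles["HD"])
print("mean S-M loss:  %.4f"
      % losses.loc[losses.pair_axis == "S-M", "loss"].mean())
print("mean D1-D2 loss: %.4f"
      % losses.loc[losses.pair_axis == "D1-D2", "loss"].mean())

records = dysreg.classify_directionality(hd)
sev = dysreg.severity_by_celltype(records, list(cfg.subtypes),
                                  directionality="bidirectional")
print(sev.means.round(3))
```

Output:

```
retained 5642/6000 cells
mean S-M loss:  -0.0578
mean D1-D2 loss: -0.0169
          mean  ci_low  ci_high   n
subtype
M-D1     0.244   0.211    0.276  77
S-D1     0.319   0.282    0.356  77
M-D2     0.305   0.275    0.336  77
S-D2     0.474   0.424    0.524  77
O-D2     0.607   0.543    0.670  77
```

Every subtype pair drew closer in the disease phenotype, and the S-M axis
lost over three times more distinction than the D1-D2 axis — the generator's
blurring coefficients (0.5 vs 0.1) read back through the full pipeline. The
bidirectional (cell-type-specific) severity table recovers the injected
gradient: O-D2 most dysregulated, then S-D2.

The same analyses run end-to-end from a YAML config:

```sh
spnblur run --config run.yaml --out results/
spnblur simulate --seed 1 --out data/
spnblur qc data/matrix.mtx data/cells.tsv data/genes.tsv \
    --species mouse --min-genes 500 --out qc_out/
```

`run` writes per-stage TSV/JSON tables plus `manifest.json` recording
versions, seeds, thresholds and per-stage row counts; replaying the same
config and seed reproduces every numeric output byte for byte.

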