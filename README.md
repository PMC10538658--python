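# circadian-gate

Genome-wide analysis of **circadian gating of acute cold responses**
from two-condition circadian RNA-seq time courses, with hexaploid-wheat
subgenome/triad resolution and a ground-truthed synthetic-data
generator.

The circadian clock can modulate how strongly a gene responds to an
acute stimulus: the same 3 h cold treatment given at different times of
day elicits responses of different magnitude. This package takes a
gene-level count matrix from the corresponding experimental design —
six treatment end-points (ZT28–ZT48, every 4 h under free run), cold
and contemporaneous control samples, replicated — and answers, per
gene:

1. **Is the cold response gated by the clock?** The cold-sensitivity
   signal is ΔCPM(ZT) = mean cold CPM − mean control CPM; subtracting
   the contemporaneous control removes the underlying abundance rhythm,
   so a gate appears as a ~24 h oscillation of ΔCPM. A gene is called
   gated when it is expressed (average CPM > 1 in either condition),
   differentially expressed at least once (moderated t on log₂-CPM,
   BH FDR < 0.05 and |log₂FC| > 0.5), and its ΔCPM profile is rhythmic
   (p < 0.05, period window 20–28 h).
2. **In which direction, and when?** On the mean-normalized scale
   (each gene's CPM divided by its grand mean over all 12
   condition × timepoint cells), mean Δmean-normCPM > 0.5 is a gated
   induction, < −0.5 a gated reduction, and the band between marks a
   displacement of transcript cycling. The estimated time of maximum
   cold responsiveness (ETMR) is the phase of the ΔCPM rhythm (trough
   phase via the inverted profile for reductions), binned into six 4 h
   groups.
3. **Was the transcript held during the treatment?** The adjusted
   difference Adj.ΔCPM(ZTx) = cold CPM(ZTx+4) − control CPM(ZTx) pairs
   each control value with the cold value one interval later; the
   displacement ratio mean|Adj.ΔCPM| / mean|ΔCPM| (over ZT28–44) is
   < 1 when abundance was stabilized for the treatment duration.
4. **Which subgenome carries the response?** Gene identifiers
   (TraesCS1A02G123456 style) are parsed to A/B/D subgenomes; for
   1:1:1 homoeolog triads, each member's share of the summed
   ΔCPM_ETMR = (ΔCPM(ZT_lower) + ΔCPM(ZT_upper))/2 gives ternary
   coordinates of triad expression balance.

The statistical engines are scikit-learn-style estimators
(`CosinorRhythmTest`, `ModeratedTTest`, `GatingAnalysis`,
`DisplacementAnalysis`) with module-level convenience functions, plus a
`circadian-gate` CLI for shell use.

## Worked example

No real dataset ships with the package; the `simulate` module generates
count matrices with the full statistical structure (rhythmic baselines,
five cold-response archetypes, NB noise, triads) and per-gene ground
truth:

```python
import circadian_gate as cg

ds = cg.generate_dataset(cg.SimulationConfig(seed=1))       # 2,000 genes
res = cg.run_analysis(ds.counts, ds.design, triads=ds.triads)
print(res["funnel"].to_string(index=False))
print(res["gating_summary"])
m = cg.validate_against_truth(res, ds.truth_frame())
```

prints

```
               stage  n_genes
               input     2000
           expressed     2000
   deg_at_least_once      694
  rhythmic_delta_cpm      404
after_anomaly_filter      384

etmr_group    <4 h  4-8 h  8-12 h  12-16 h  16-20 h  >20 h
direction                                                 
induction       26     57      38       39       38     32
displacement     2     18      15       15       19      7
reduction       10     17      12       10       13     16
```

The funnel is the filtering cascade: of 2,000 simulated genes, 694 are
differentially expressed at least once, 404 of those have a rhythmic
ΔCPM profile, and 384 survive the edge-bin anomaly filter as
circadian-gated calls. The matrix is the direction × ETMR summary
(counts of gated genes per class and 4 h phase bin). Against the known
simulation truth, `validate_against_truth` reports induction
precision/recall 0.996/0.954, mean absolute ETMR error 1.1 h (97.4%
within one 4 h bin), and median displacement ratios 0.59 for stabilized
genes vs 1.00 for phase-aligned gated genes — the separation the ratio
is designed to detect.

Equivalent CLI:

```
circadian-gate simulate --out data/ --seed 1
circadian-gate run --config config.yaml     # paths + thresholds in YAML
```

Real data enter through `load_counts(counts.tsv, design.tsv)` (TSV/CSV,
plus an XLSX reader for supplementary-style workbooks) and
`load_triads(triads.csv)`.

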