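# cernakit

Competing-endogenous-RNA (ceRNA) network inference and circRNA junction
calling for two-group whole-transcriptome studies, with a synthetic-data
generator that makes every stage testable against planted truth.

The package targets the analysis layout of a two-breed skin transcriptome
comparison — e.g. a black-coated meat breed versus a white cashmere breed,
3 pooled libraries per group, four RNA classes (mRNA, lncRNA, circRNA,
miRNA) — and implements the full downstream chain for anyone who needs
these stages as reusable, tested library code rather than a fixed vendor
pipeline:

1. **Differential expression** — negative-binomial Wald test on
   median-of-ratios-normalized counts: log2FC = log2((μ_B+c)/(μ_A+c)),
   method-of-moments dispersion stabilized through a mean-dispersion
   trend, two-sided normal p, Benjamini-Hochberg FDR.
2. **miRNA-target links** — exact intersection of two predictor tables
   (high-confidence set), then negative co-expression filtering with
   Spearman rank correlation, retaining SCC < −0.7 among DE features.
3. **ceRNA screen** — for each (sponge, mRNA) candidate sharing k miRNAs
   out of a universe of size M, the one-sided hypergeometric tail
   p = P(X ≥ k), X ~ Hypergeom(M, |T_sponge|, |T_mrna|); pairs pass with
   k > 3, p < 0.05, FDR < 0.05 and sponge–mRNA Pearson r > 0.8, and
   expand into sponge–miRNA–mRNA triplets exported as SIF/GraphML/TSV.
4. **Back-splice calling** — scan SAM alignments for chiastic clip
   signatures (`xS yM` / `xM yS` / `xS yM zS`), exact re-match of the
   clipped segment, paired-end mate containment, strand-aware GT-AG/AT-AC
   splice signals, exon-boundary annotation filter, ≥ 2 supporting reads.
5. **Assays** — 2^−ΔΔCT relative qPCR expression, OLS melanin working
   curve with inversion to mg/g fiber, follicle density per mm², and the
   two-group Student t with mean ± SD reporting.

## Worked example

```python
from cernakit import SimConfig, run_pipeline

summary = run_pipeline(SimConfig(seed=1), "out/")
print(summary["n_cerna_pairs"], summary["triplet_recall"])
```

On the default study (seed 1) the pipeline prints, stage by stage (see
`examples/` for the runnable scripts):

```
mRNA      52 significant (50/50 planted recovered)
lncRNA    13 significant (12/12 planted recovered)
circRNA    9 significant (9/9 planted recovered)
miRNA     54 significant (50/50 planted recovered)
intersection: 100 high-confidence pairs (planted: 100)
ceRNA pairs passing all thresholds: 10
triplets: 50 recall=1.00 precision=1.00
planted junctions: 20, called: 20, recall=1.00, false calls=0
```

meaning: the DE stage flags the 121 planted differential features (plus a
calibrated ~5% of nulls), predictor intersection strips all tool-specific
decoys, the hypergeometric screen retains exactly the 10 planted
sponge–mRNA pairs and all 50 planted triplets, and the junction caller
recovers each planted back-splice at exact coordinates with no calls from
the 2,000 linear background reads.

Each stage is equally usable on real data in the same formats: counts and
prediction tables as TSV, genome as FASTA, annotation as GTF, alignments
as SAM. A thin CLI mirrors the library (`cernakit simulate|de|targets|
cerna|backsplice|assays|pipeline`; see `--help`).

## Layout

- `src/cernakit/simulate.py` — synthetic study generator (counts, target
  tables, toy genome/GTF/SAM with planted back-splices, assay tables)
- `src/cernakit/expression.py` — size factors, FPKM, filters, BH, NB Wald DE
- `src/cernakit/targets.py` — predictor intersection, SCC filtering
- `src/cernakit/cerna.py` — hypergeometric screen, triplets, network export
- `src/cernakit/backsplice.py` — clip-signature junction caller
- `src/cernakit/assays.py` — ΔΔCT, melanin curve, follicle density, t-test
- `src/cernakit/pipeline.py` — end-to-end orchestration
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameter choices, and limitations
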