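# oncomap

Comparative oncogenomics of spontaneous canine mammary tumors (CMTs) — the
dog's counterpart of human breast cancer — as a tested, reusable Python
pipeline. Cohort studies in this space combine several analyses that are
usually scattered across ad hoc scripts:

- somatic-mutation post-filtering (alignment-error rule on AS/XS read
  scores, six-class consequence mapping, recurrent genes, germline
  candidate cascade) and tumor mutation burden with purity correction,
  hypermutation calling, and a dN/dS selection surrogate;
- 96-channel trinucleotide spectra, de novo signature deconvolution by
  KL-loss NMF, cosine catalog matching, and NNLS exposure fitting;
- GC-corrected read-depth ratios, circular binary segmentation (CBS),
  altered-genome fraction, and simplified G-score recurrence peaks;
- cross-species projection of copy-number profiles through UCSC chain
  files (e.g. canFam3 → hg19), re-segmentation, and cohort-level
  amplification/deletion concordance;
- consensus-NMF expression subtyping with cophenetic rank selection,
  preranked GSEA, up/down signature scoring, and Kaplan–Meier / log-rank
  survival comparison;
- the exact cohort statistics used throughout (two-sided Fisher with the
  minimum-likelihood rule, exact Mann–Whitney U, multi-group log-rank,
  one-way ANOVA, Benjamini–Hochberg FDR, Fisher pathway enrichment).

A first-class synthetic-cohort module (`oncomap.synthetic`) generates every
input with planted ground truth — driver frequencies by histology,
signature mixtures, purity-diluted VAFs, planted copy segments with GC
bias, toy two-genome chains with an exact per-base map, and expression
clusters with differing hazards — so the whole pipeline is testable
without sequencing data. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

```python
import oncomap
from oncomap import synthetic, mutsig, stats

# a 2x2 histology-restriction test: mutated/not in 0/78 vs 8/44 samples
res = stats.fisher_exact_2x2([[0, 78], [8, 36]])
print(f"p = {res.pvalue:.3g}")                # p = 0.000184

# synthetic cohort: 20 samples, 25% benign, C>T-dominated signature mixture
genome = synthetic.GenomeSpec(chrom_lengths={"chr1": 60_000}, bin_size=1_000)
reference = synthetic.generate_reference(genome, seed=11)
catalog = synthetic.default_catalog(n_signatures=4)
spec = synthetic.CohortSpec(
    n_samples=20, benign_fraction=0.25,
    driver_freqs={"PIK3CA": (0.55, 0.38), "TP53": (0.0, 0.2)},
    signature_weights=(0.7, 0.1, 0.1, 0.1), tmb_rate=30, seed=7,
)
variants, metadata = synthetic.generate_mutation_cohort(spec, genome, reference, catalog)
print(metadata["histology"].value_counts().to_dict())
# {'malignant': 15, 'benign': 5}

spectra = mutsig.build_spectrum(variants, reference)
sol = mutsig.fit_exposures(spectra.sum(axis=0).to_numpy(float), catalog)
print(sol.proportions.round(3).to_dict())
# {'SYN1': 0.682, 'SYN2': 0.102, 'SYN3': 0.102, 'SYN4': 0.114}
```

The fitted exposure proportions recover the planted (0.7, 0.1, 0.1, 0.1)
signature mixture from ~600 mutations; the Fisher p is the two-sided
minimum-likelihood exact value for the printed contingency table.

A CLI mirrors the library (`oncomap simulate`, `oncomap variants
filter-as-xs`, `oncomap burden`, `oncomap sig spectrum|denovo|fit`,
`oncomap scna segment|fraction`, `oncomap crossmap project`,
`oncomap subtype nmf`, `oncomap stats fisher|pathway`); run
`oncomap --help` for the full tree.

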