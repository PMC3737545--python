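# g4scan

Putative G-quadruplex sequence (PQS) analysis around gene boundaries,
plus a quantitative model of how far away a transcription event can
still induce G-quadruplex folding.

Guanine-rich DNA with four or more tandem G-tracts can fold into a
four-stranded G-quadruplex (G4). Negative supercoiling generated behind
a moving RNA polymerase propagates along the double helix and can induce
G4 folding at PQS motifs located upstream of a transcription start site
(TSS), even thousands of base pairs away. `g4scan` provides the
computational side of that story for genomicists and nucleic-acid
biochemists:

* **PQS scanning** with the exact semantics of the backtracking pattern
  `G{3,}(.{1,7}?G{3,}){3,}` — the motif grammar
  G≥3(N1–7G≥3)≥3 with greedy tracts, lazy loops and a greedy
  tract+loop repeat, leftmost non-overlapping matches, on one or both
  strands. An independent exhaustive oracle (`oracle_scan`) validates
  the production scanner.
* **Gene-boundary metaprofiles**: TSS/TES flank extraction from a
  genome + annotation (or a BioMart-style flank FASTA dialect),
  anchor-relative coordinates, windowed occurrence frequencies per 100
  sequences, strand-split 20-nt profiles downstream of the TES,
  cumulative PQS-positive-gene curves, per-species summaries and the
  G3/1-nt-loop subclass count.
* **Distance-decay model**: %qDNA (the fraction of DNA molecules
  carrying a quadruplex) as a function of the promoter-to-motif
  separation X, fitted to the single-phase exponential

  ```
  Y = max · exp(−k·X) + plateau,      D½ = ln 2 / k
  ```

  exposed statsmodels-style (`ExponentialDecayModel(...).fit()` →
  `DecayFitResults` with estimates, standard errors and `summary()`).
* **Synthetic data with exact ground truth**: G/C-run-free background
  flanks with motif instances planted at a configurable density (a
  five-fold TSS-proximal step over background by default), on either
  strand and either gene orientation, so every pipeline stage can be
  validated end to end without genome downloads.

## Worked example

```python
import numpy as np
from g4scan import (SyntheticConfig, generate_flank_set, scan_both_strands,
                    anchor_matches, frequency_profile, percent_positive,
                    generate_decay_dataset, ExponentialDecayModel)

cfg = SyntheticConfig(n_genes=2000, sides=("upstream",), seed=1)
flanks, truth = generate_flank_set(cfg)
anchored = [a for f in flanks
            for a in anchor_matches(f, scan_both_strands(f.seq, None, f.gene_id))]

prof = frequency_profile(anchored, n_sequences=len(flanks))
near = prof.frequencies[prof.window_starts >= -1000].mean()
far = prof.frequencies[prof.window_starts <= -1100].mean()
print(f"matches: {len(anchored)}  (planted: {len(truth)})")
print(f"near-TSS/background frequency ratio: {near/far:.2f}")
print(f"% genes with >=1 PQS within 5 kb: "
      f"{percent_positive(anchored, [f.gene_id for f in flanks]):.1f}")

data = generate_decay_dataset(max_=59, d_half=489, plateau=40,
                              distances=np.arange(0, 2501, 100), noise_sd=0)[0]
print(ExponentialDecayModel(data.x, data.y).fit().summary())
```

prints

```
matches: 1743  (planted: 1743)
near-TSS/background frequency ratio: 4.63
% genes with >=1 PQS within 5 kb: 59.4
Single-phase exponential decay  Y = max*exp(-k*X) + plateau
  n observations : 26
  max (amplitude):    59.0000 %
  k (decay rate) : 0.00141748 1/bp
  plateau        :    40.0000 %
  D_1/2 = ln2/k  :   489.0000 bp
  residual SSE   : 4.54384e-28
  std. errors    : max 3.179e-15, k 2.106e-19, plateau 2.437e-15
```

Every planted motif is recovered at its exact anchored coordinate (the
G/C-run-free background guarantees zero false positives), the
configured five-fold promoter-proximal enrichment step shows up in the
window profile, ~59% of genes are PQS-positive within 5 kb under the
default density, and the decay fit recovers the generating parameters
(max = 59%, plateau = 40%, D½ = 489 bp) to machine precision on
noiseless data.

The same operations are available from the shell:

```bash
g4scan simulate --n-genes 1000 --seed 1 --out-fasta flanks.fa --out-truth truth.tsv
g4scan profile flanks.fa -o profile.tsv
g4scan cumulative flanks.fa -o curve.tsv
g4scan fit-decay decay.tsv
```

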