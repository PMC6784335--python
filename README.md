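# jointmds

Joint 3D chromosome structure inference and comparison from paired Hi-C
contact matrices.

## The problem

Hi-C measures how often every pair of genomic loci touches in the nucleus.
A single contact matrix can be embedded into a 3D "consensus structure" of a
chromosome, but comparing two conditions (cell types, treatments, disease
states) by embedding each matrix separately is unreliable: metric MDS has
many near-equivalent local optima, so two runs on even the *same* data land
in different configurations, and any post-hoc superposition confuses that
stochasticity with real biology.

`jointmds` embeds **both** matrices at once with a similarity-penalized
SMACOF algorithm. The penalty ties the two structures together locus by
locus, so they fall into the same local optimum and the same frame; what
remains different between them is the signal. The package then:

* quantifies per-locus **relocalization** (the Euclidean distance between a
  locus's position in the two aligned structures),
* computes **A/B compartment scores** (PC1 of the observed/expected
  correlation matrix, scaled to [-1, 1]) and fits the 3D **compartment
  axis** (linear SVR of score on coordinates),
* decomposes relocalization into its component along the compartment axis
  versus the two orthogonal directions (fractions normalized by axis length,
  compared with a two-sided t test),
* calls relocalization **peaks** by continuous-wavelet-transform ridge
  detection (widths 1–10 bins) and filters/splits them by compartment-score
  difference,
* and provides the independent-inference baseline (two separate embeddings +
  Kabsch superposition) for comparison, plus virtual 4C extraction and
  interval coverage enrichment.

## The model

Given two target-distance matrices D1, D2 over the same N loci (derived
from contacts by d = c^(-1/4) after mean normalization and a small
distance-decay prior), the algorithm minimizes the joint stress

    sigma(X1, X2) = sum_{i<j} (d_ij(X1) - delta_ij1)^2
                  + sum_{i<j} (d_ij(X2) - delta_ij2)^2
                  + sum_i w_i d_i^2(X1, X2)

over two N x 3 coordinate matrices, where d_i(X1, X2) is the per-locus
distance between the embeddings and w is the similarity weight (uniform in
practice). Pairs with delta = 0 are missing and ignored. Each iteration
applies the penalized majorization update

    X1 <- (W + I)^(-1) [W X2 + B(X1) X1 / N]

(and symmetrically for X2), where B is the standard SMACOF majorizing
matrix; w = 0 reduces exactly to two independent SMACOF embeddings. The
right similarity weight is chosen by running the fit repeatedly at a grid
of weights and taking the smallest weight at which run-to-run
reproducibility of the relocalization profile plateaus — weights around
0.02–0.1 typically suffice.

## Worked example

Simulate a 40-locus chromosome pair in which locus 20 relocates between
conditions, then fit:

```sh
$ jointmds simulate reloc --out demo --seed 1 --n-loci 40
wrote demo/A.tsv, demo/B.tsv, demo/truth.json (resolution 100000)
$ jointmds run demo/A.tsv demo/B.tsv --res 100000 --weight 0.05 --seed 3 --out demo/fit
wrote demo/fit_* (joint mode)
```

The top of the relocalization profile (`demo/fit_reloc.tsv`, sorted by
magnitude) and the optimizer log:

```
 chrom   start     end  magnitude
chrSim 2000000 2100000   0.893510
chrSim 3700000 3800000   0.084807
chrSim 1900000 2000000   0.072407
final stress: 6.8647 | iterations: 72
```

The planted locus (bin 20 = 2.0–2.1 Mb) relocalizes by 0.89 embedding
units, an order of magnitude above every other locus; the fit converged in
72 majorization iterations. Relocalization is unitless — distances inherit
the arbitrary scale of the normalized contacts — so magnitudes are
interpreted relative to the profile's own background, here via CWT peak
calling (`jointmds peaks`).

The same objects are available as a library, with the core exposed as a
scikit-learn-style estimator:

```python
from jointmds import JointMDS, prepare_pair, read_contacts

a = read_contacts("demo/A.tsv", resolution=100_000)
b = read_contacts("demo/B.tsv", resolution=100_000)
d1, d2 = prepare_pair(a, b)                      # normalize, prior, d = c**-0.25
est = JointMDS(similarity_weight=0.05, random_state=3).fit(d1.delta, d2.delta)
est.embedding1_, est.embedding2_, est.stress_    # aligned coordinates + stress
```

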