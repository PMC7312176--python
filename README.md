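# pcnv — positional correlation natural vectors for alignment-free genome comparison

`pcnv` maps a DNA sequence to an 18-dimensional numerical descriptor and
compares genomes through those descriptors instead of aligning them. It is
aimed at viral genotyping and bacterial phylogenetics, where sequences run
from kilobases to megabases and multiple sequence alignment is either too
slow or (because of horizontal gene transfer) actively misleading. The
whole pipeline — vectorize, distance matrix, neighbor-joining tree,
1-nearest-neighbor genotype classification — runs in seconds on datasets
that alignment-based methods need hours or days for.

## The vector

For a sequence *S* = *s*₁…*s_N* and each nucleotide α ∈ {A, C, G, T} with
occurrence positions *p*₁ < … < *p_n* (1-based, with *p*₀ = 0 by
convention), define the **positional distribution** *U*<sub>α</sub> — a
step function constant between consecutive occurrences:

```
U_α(i) = p_j / (p_{j+1} − p_j)    for p_j ≤ i < p_{j+1}
U_α(i) = p_n / (N − (p_n − 1))    for p_n ≤ i ≤ N
```

Its block sums telescope, so Σᵢ *U*<sub>α</sub>(i) = Σⱼ *p*ⱼ. From it,

- κ<sub>α</sub> = Σᵢ *U*<sub>α</sub>(i) / *n*<sub>α</sub> — the mean occurrence position,
- cov(α, β) = Σᵢ (*U*<sub>α</sub>(i) − Ū<sub>α</sub>)(*U*<sub>β</sub>(i) − Ū<sub>β</sub>) / (*n*<sub>α</sub>·*n*<sub>β</sub>), with Ū<sub>α</sub> = Σᵢ *U*<sub>α</sub>(i)/N,
- D²<sub>α</sub> = cov(α, α).

The 18 components, in fixed order:

```
(n_A, n_C, n_G, n_T,  κ_A, κ_C, κ_G, κ_T,  D²_A, D²_C, D²_G, D²_T,
 cov(A,C), cov(A,G), cov(A,T), cov(C,G), cov(C,T), cov(G,T))
```

Sequences are compared by plain Euclidean distance between their vectors;
trees are built with Saitou–Nei neighbor joining and genotypes assigned by
leave-one-out 1-nearest-neighbor.

## Worked example

The sequence `ACTGGCAAT` (N = 9) is small enough to check by hand.
Nucleotide A occurs at positions 1, 7, 8, C at 2, 6, so

```python
>>> from pcnv import SequenceRecord, compute_pcnv, COMPONENT_NAMES
>>> v = compute_pcnv(SequenceRecord("ex", "ACTGGCAAT"))
>>> dict(zip(COMPONENT_NAMES, [round(x, 4) for x in v.components]))
{'nA': 3.0, 'nC': 2.0, 'nG': 2.0, 'nT': 2.0,
 'kA': 5.3333, 'kC': 4.0, 'kG': 4.5, 'kT': 6.0,
 'D2A': 5.858, 'D2C': 0.7222, 'D2G': 3.0, 'D2T': 16.625,
 'covAC': 1.4769, 'covAG': 0.0, 'covAT': 3.4167,
 'covCG': 0.125, 'covCT': 1.4583, 'covGT': 0.25}
```

`kA` is (1+7+8)/3 = 16/3; `covAC` is the exact rational 319/216 ≈ 1.4769.
A positive `covAC` says A and C drift in the same direction along this
sequence; `D2T` = 16.625 is large because the two Ts sit at opposite ends.

## Command line

```bash
pcnv simulate --clusters 4 --per-cluster 10 --length 5000 --rate 0.01 --seed 42 -o sim/
pcnv vectorize sim/sequences.fasta -o vectors.tsv
pcnv dist vectors.tsv -o distmat.phy
pcnv tree sim/sequences.fasta -o tree.nwk
pcnv classify sim/sequences.fasta --labels sim/labels.tsv -o report.tsv --json-output report.json
```

`simulate` writes a clustered synthetic dataset (random ancestors, point-
mutated descendants); `classify` prints a per-genotype table of
sensitivity, specificity, and accuracy. On the dataset above every class
scores 100.0 in all three columns: at a 1% per-site substitution rate,
descendants stay far closer in vector space to their own cluster than to
any other. Real datasets are handled the same way — supply your own FASTA
(optionally gzipped) and a two-column id→genotype table.

Exit codes: 0 on success, 2 on invalid input, 1 on unexpected failure.

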