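# ecdose

Thermodynamic modeling and dose-response classification of
hormone-regulated transcription, built around the ecdysone system of
insect imaginal discs: the steroid 20-hydroxy-ecdysone (20E) acting
through its nuclear receptor EcR, which represses target genes when
bound by a corepressor and activates them when bound by hormone.

The package is for quantitative biologists who want to (i) explore how
constitutive enhancers and silencers reshape a nuclear-receptor dose
response, (ii) fit that model jointly to multi-construct reporter
fluorescence data, and (iii) classify genome-wide dose-response RNA-seq
profiles into response archetypes, with a fully synthetic,
ground-truth-labeled data generator standing in for real measurements.

## The model

A gene carries `n` hormone response elements (EREs), each occupied by a
receptor that is free (weight 1), corepressor-bound (weight κ̄_R,
promoter-affinity factor C_ER < 1) or hormone-bound (weight E/K_E,
factor C_EA > 1). The transcriptional machinery binds the promoter with
basal weight κ_P, multiplied by a constitutive-element coefficient C_T
(enhancer > 1, silencer < 1) and by the factor of every DNA-bound
receptor. The receptor state probabilities are first-order Hill forms

    P_act(E) = (E/K_E) / (1 + κ̄_R + E/K_E),
    P_rep(E) = κ̄_R / (1 + κ̄_R + E/K_E),

and for a single ERE the normalized activity has the closed form

    A(E)/A_max = (χ/C_EA) · (1 + κ_P C_T C_EA) / (1 + κ_P C_T χ),
    χ(E) = 1 + (C_ER − 1) P_rep(E) + (C_EA − 1) P_act(E).

χ(E) is the average statistical weight a DNA-bound receptor contributes
to the machinery-bound state; the dose at which χ crosses 1 is the
derepression threshold. A brute-force partition-function enumeration
over all joint states serves as an independent oracle for every closed
form, including multi-ERE promoters with pairwise cooperativity ω and a
"sponge" variant in which a non-DNA-binding receptor fragment titrates
the corepressor or hormone pool.

Downstream, the RNA-seq pipeline reimplements the study-style analysis:
median-of-ratios size factors, a low-count filter (total of the four
per-dose mean counts ≥ 500), strict monotonicity over the first three
doses (0, 20, 200 nM), per-gene max-normalization, k-medoids (PAM)
clustering with elbow selection of k, the δ(2000−20)/δ(20−0) vs
fold-change response map, and a 50,000-gene Gaussian virtual-gene null
pushed through the identical filter code path.

## Worked example

`examples/02_fit_reporters.py` simulates noisy fluorescence dose
responses (10% multiplicative noise, 3 replicates, 6 doses) for four
reporter constructs — a minimal ERE reporter, enhancer + ERE,
silencer + ERE, and the enhancer's mutated-ERE control — and jointly
fits the shared parameters plus one C_T per constitutive element:

```
parameter        truth      fitted
kappa_P           0.03      0.0296
K_E                 65        68.2
C_ER               0.1       0.143
C_EA                13        13.5
k_T                131         129
C_T[enhancer]       2        2.03
C_T[silencer]     0.1       0.103

objective (sum sq. relative residuals): 0.0340
derepression threshold: 4.66 nM
```

The fit recovers the generating values; the enhancer-bound activator
(C_T ≈ 2) is far weaker than the hormone-bound receptor (C_EA ≈ 13),
and repression is lifted at a few nM of hormone. The other examples
print the archetype curves (`01`), the end-to-end classification of a
synthetic count matrix (`03`: k = 3 selected by the elbow, cluster
medoids from high-baseline to high-threshold, positive fold-change/δ
correlation), and the virtual-gene null (`04`: 1/6 of genes survive the
filters, near-zero correlation).

A thin CLI mirrors the library:

```bash
ecdose make-synthetic --seed 1 --out data/
ecdose classify --counts data/counts.tsv --samples data/samples.tsv --out results/
ecdose fit --data data/reporters.tsv --out fit.json
ecdose run-all --seed 1 --out results/
```

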