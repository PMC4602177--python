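# pdlrs

Bayesian analysis of extended gene families — genes together with their
pseudogenes — inside a dated species tree. `pdlrs` implements a
generative model in which a gene lineage evolving over the species tree
is exposed to duplication (rate δ), loss (rate μ) and irreversible
gene-to-pseudogene conversion (rate ψ), with branch lengths from a
relaxed molecular clock (independent Gamma edge rates, mean *m*, CV *c*)
and sequences from dual codon substitution models: a selective mode for
genes (dN/dS = ω over the 61 sense codons) and a neutral mode for
pseudogenes (ω = 1 over all 64 codons, premature stops allowed). Given a
codon alignment, a gene/pseudogene classification of its sequences, and
a dated species tree, an MCMC sampler reconstructs the gene tree, the
set of pseudogenization vertices Ψ and their *dates*, jointly with all
model parameters.

It is aimed at researchers studying pseudogene evolution — e.g. asking
whether a family's pseudogenes arose recently and independently or
descend from one ancient conversion — and at methods developers who need
a reference implementation of the duplication–loss–rates–sequence family
of models with pseudogenization.

The core quantities:

* the gene-tree prior `p(G, l | θ, Ψ, S)` by dynamic programming over a
  discretized species tree, with extinction and 1-to-1 probabilities of
  the two-type linear birth–death process in closed form;
* the sequence likelihood `P(D | G, l, Ψ)` by pruning with a model
  switch at Ψ vertices;
* posterior *realizations* mapping gene-tree vertices to dated points,
  which date each pseudogenization;
* roof/shade distances between pseudogenization configurations
  (topological `D_a`, `D_m` and temporal `T_a`, `T_m`) for comparing an
  inferred posterior against a reference configuration.

See `docs/methods.md` for the model, algorithms and design choices.

## Worked example

Simulate one family on a small three-species tree, run fixed-tree
inference, and measure how well the pseudogenization events are
recovered:

```
$ echo "((A:0.5,B:0.5):0.5,C:1):0.1;" > sp.nwk
$ pdlrs simulate --species-tree sp.nwk --codons 120 --seed 7 --out sim
wrote 1 families to sim
$ grep -v "^#" sim/family01.truth.tsv
clade   time        omega  kappa  n_redraws
B_1P    0.49349758  0.5    2.0    0
C_3P    0.65159648  0.5    2.0    0
```

The truth file says this family carries two pseudogenes, one per clade,
whose conversions happened at times 0.49 and 0.65 (in units of the tree
depth 1.1). Now infer, holding the true topology fixed, and compare the
posterior against the truth:

```
$ pdlrs infer --alignment sim/family01.fasta --map sim/family01.map.tsv \
    --species-tree sp.nwk --fixed-tree sim/family01.true.nwk \
    --iterations 4000 --burnin 1000 --thinning 20 --seed 7 --out inf
wrote trace with 150 samples to inf
$ pdlrs distances --truth sim/family01.true.nwk --map sim/family01.map.tsv \
    --trace inf/trace.tsv --mode temporal \
    --truth-times sim/family01.truth.tsv --realizations inf/realizations.tsv \
    --out dist.tsv
E_Da  M_Da  E_Dm  M_Dm  E_Ta      M_Ta      E_Tm      M_Tm      n_used  n_excluded
0     0     0     0     0.149315  0.292162  0.208438  0.492217  150     0
```

All 150 posterior samples place the pseudogenization vertices on the
correct edges (topological distances 0), and the posterior-average
temporal error of the inferred conversion dates is ≈0.15 time units
(`E_Ta`), i.e. the sampled dates sit close to the true 0.49 and 0.65.

For free-topology inference omit `--fixed-tree`; `pdlrs simulate --grid`
writes the full 25-family ω×κ synthetic study layout.

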