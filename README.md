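# fisim — alignment-free DNA comparison by fuzzy-integral similarity

`fisim` compares DNA sequences without aligning them, for phylogenetic
and clustering analyses where alignment is impractical: whole genomes,
large rDNA collections, highly divergent taxa. It is a library first
(importable API plus `examples/`), with a thin `fisim` command-line
wrapper for shell use.

## Method

Each sequence is summarised by the transition matrix of a first-order
Markov chain over the states S = (A, T, G, C): from the counts
N(s_i, s_j) of adjacent nucleotide pairs,

    p_ij = N(s_i, s_j) / Σ_j N(s_i, s_j),

and the k-step matrix P^k follows from Chapman–Kolmogorov. Two sequences
with k-step matrices P1 and P2 are scored per matrix cell by an evidence
function h = 1 − |P1 − P2| and a fuzzy density μ = max(P1, P2) (the
conservation level of that pair). Within each row i the densities induce
a Sugeno λ-fuzzy measure, with λ_i > −1 solved from the normalisation

    1 + λ_i = Π_j (1 + λ_i μ_ij),

and the row is aggregated by the Sugeno integral
max_j min(h_(j), μ(A_ij)) with h sorted descending. The similarity I is
the maximum over the four rows; the distance is D = 1 − I. The step k is
chosen automatically: k is increased until the all-pairs distance matrix
stops changing (root-mean-square difference between consecutive steps
below a tolerance, default 1e-6). Trees are built from the distance
matrix by UPGMA (default) or neighbor joining, and can be evaluated by
Robinson–Foulds distance against a reference tree or by ROC/AUC against
a taxon grouping.

A Markov-chain simulator (`fisim.synthetic`) generates sequences from
explicit chains and evolves families along guide trees, so the whole
pipeline is testable without downloading genomes.

## Worked example

```
python examples/04_simulation_study.py
```

simulates five 8-leaf families (20 kb sequences) from the bundled
benchmark, runs automatic step selection plus UPGMA, and prints:

```
seed 1: optimal k = 6, RF = 0
seed 2: optimal k = 6, RF = 0
seed 3: optimal k = 6, RF = 0
seed 4: optimal k = 5, RF = 0
seed 5: optimal k = 6, RF = 0

recovered the guide topology in 5/5 replicates
```

`optimal k` is the smallest step at which the distance matrix has
converged (here 5–6: the matrices are essentially stationary), and
`RF = 0` means the inferred tree matches every clade of the guide tree
that generated the data. The other examples walk through matrix
estimation, pairwise similarity, the end-to-end FASTA→PHYLIP→Newick run
and the evaluation metrics.

Command-line equivalents:

```
fisim simulate --seed 1 --mode family -o family.fasta
fisim dist family.fasta -o family.phy --report run.json
fisim tree family.phy -o family.nwk --method upgma
fisim eval --tree family.nwk --ref-tree guide.nwk
```

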