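# varcog

Quantifying how fast protein families evolve within a clade of genomes —
without building a phylogeny per family.

`varcog` is a library and command-line toolkit for comparative genomics of
prokaryotic pangenomes. Starting from per-family protein alignments, gene
trees and ancestral presence/absence reconstructions, it computes a
clade-normalized *relative variability* for every family of orthologous
proteins (csCOG, clade-specific Cluster of Orthologous Genes), and the
supporting quantities around it:

* **Column homogeneity** `h`: for an alignment column with residues `a_i`
  and weights `w_i = 1/N`, each candidate amino acid `x` scores
  `Q_x = Σ_i w_i S(a_i, x)` under a substitution matrix `S` (BLOSUM62 by
  default). With consensus `c = argmax_x Q_x` and random-assortment baseline
  `Q_R = Σ_b f_b Q_b` over background frequencies `f_b`,
  `h = max((Q_c − Q_R)/(S_cc − Q_R), 0)` — 1 for an invariant column, 0 for a
  column no better than chance.
* **Relative variability** `v_C = (1 − h_C) h_T / ((1 − h_T) h_C)`, where
  `h_C` is the family's mean homogeneity and `h_T` the clade-wide mean.
  `v = 1` means "average for this clade"; `v < 0.5` is conserved, `v > 2`
  variable. The same transform classifies individual alignment positions.
* **Homogeneity-distribution geometry**: profiles smoothed with a Gaussian
  kernel (bandwidth 20 positions), converted to densities on a 101-point
  grid over [0, 1], compared by Hellinger distance, and embedded in 2-D by
  classical (Torgerson) multidimensional scaling.
* **csCOG extraction**: genome-labeled gene trees are split into orthologous
  groups by iteratively removing the clade maximizing the coverage-paralogy
  tradeoff index `S_C²/(P_C·S)` (`P_C` leaves from `S_C` of `S` genomes).
* **Gain/loss histories**: per-node ancestral-presence posteriors are
  interpreted into discrete gain/loss events (|Δposterior| ≥ 0.5 along an
  edge), continuous gain/loss totals (sums of signed differences), and
  ancestrality calls (root posterior ≥ 0.5).
* **Microsatellite-like regions (MSR)**: k-mer recurrences (k = 1..6) in
  protein-coding nucleotide sequences flagged by a binomial tail test
  (`p = 4^-k`, trials = window − k + 1, P < 10⁻⁶), chained at start-to-start
  intervals ≤ k and merged into per-gene coverage fractions.

A synthetic-fixture module generates all of these inputs with known ground
truth (families at controlled divergence, gene trees with planted
duplications, presence histories, planted tandem repeats), so the whole
pipeline is testable offline.

## Worked example

Simulate five families at increasing divergence and rank them:

```sh
python - <<'EOF'
from pathlib import Path
from varcog.simulate import SimulationSpec, simulate_family_alignment
d = Path("alignments"); d.mkdir()
for i, theta in enumerate([0.05, 0.1, 0.2, 0.35, 0.5]):
    aln, _ = simulate_family_alignment(
        SimulationSpec(seed=100 + i, theta=theta, n_sequences=10, n_columns=120),
        family_id=f"fam{i}")
    with open(d / f"fam{i}.fasta", "w") as fh:
        for sid, gid, res in aln.rows:
            fh.write(f">{sid} genome={gid}\n{res}\n")
EOF
varcog variability --alignments alignments --out variability.tsv
```

`variability.tsv` (abridged):

```
family_id  h_C     h_T     v_C     class         f_conserved  f_intermediate  f_variable
fam0       0.9476  0.7623  0.1772  conserved     0.900        0.100           0.000
fam2       0.7955  0.7623  0.8243  intermediate  0.383        0.508           0.108
fam4       0.5080  0.7623  3.1063  variable      0.008        0.250           0.742
```

The family simulated at the lowest divergence (`fam0`, per-site substitution
probability 0.05) has mean homogeneity 0.95 and relative variability 0.18 —
conserved; the most diverged one (`fam4`, 0.5) lands at `v = 3.1` —
variable. `h_T = 0.762` is the clade mean pooled over all scored columns,
and the three `f_*` columns are the fractions of conserved / intermediate /
variable alignment positions.

Splitting a gene tree in which two genomes each carry two paralogs:

```sh
echo "((a|g1,b|g2),(c|g1,d|g2));" > tree.nwk
varcog split-tree tree.nwk --out members.tsv
```

yields two csCOGs, each covering both genomes — the two sub-clades score
index 2²/(2·2) = 1, beating the root's 2²/(4·2) = 0.5:

```
cscog_id   sequence_id  genome_id
cscog0000  a|g1         g1
cscog0000  b|g2         g2
cscog0001  c|g1         g1
cscog0001  d|g2         g2
```

Other subcommands: `varcog homogeneity`, `varcog embed`, `varcog gainloss`,
`varcog msr`, `varcog simulate` — see `varcog --help`.

## Layout

```
src/varcog/scoring.py      score model, column homogeneity, family filter
src/varcog/variability.py  clade baseline, relative variability, classes, bins
src/varcog/geometry.py     smoothing, densities, Hellinger, classical MDS
src/varcog/cscog.py        gene-tree splitting by the tradeoff index
src/varcog/gainloss.py     posterior -> gain/loss events and ancestrality
src/varcog/msr.py          binomial k-mer recurrence scanner
src/varcog/simulate.py     synthetic fixtures with ground truth
src/varcog/io.py, cli.py   formats, config, umbrella CLI
```

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
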