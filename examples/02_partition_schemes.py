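"""Build the six partition schemes compared in the study.

Data blocks are (gene, codon-position-class) pairs: positions 1+2 pooled
and position 3 separate, giving 2 blocks per gene.  Schemes:

  C    one concatenated partition
  CP   two partitions: all pos-12 blocks, all pos-3 blocks
  G    one partition per gene
  GCP  one partition per block (gene x position class)
  PF   greedy BIC merging of blocks (PartitionFinder-style)
  CS   k-medoids/gap-statistic clustering of per-block branch lengths
"""

import numpy as np

from clockpart import (
    RateDriftConfig,
    SubstModelConfig,
    build_reference_timetree,
    concatenate_alignments,
    conserved_gene_model,
    fixed_scheme,
    fit_branch_lengths,
    gap_statistic_cluster,
    make_blocks,
    sbsd_min_distance,
    simulate_alignment,
    simulate_gene_trees,
)
from clockpart.partitioning import bic_greedy_merge, sbsd_distance_matrix

tree = build_reference_timetree()
rng = np.random.default_rng(7)
genes = simulate_gene_trees(tree, RateDriftConfig(sigma2=0.25, n_genes=4), rng)
model = conserved_gene_model(n_codons=80)
aln = concatenate_alignments(
    [simulate_alignment(g, model, tree, rng) for g in genes]
)

blocks = make_blocks(aln)
print(f"{len(blocks)} data blocks from {aln.n_cols} columns")
for label in ("C", "CP", "G", "GCP"):
    scheme = fixed_scheme(label, n_genes=4)
    print(f"  {label:3}: {scheme.n_partitions:2d} partitions, assignment {scheme.assignment}")

# PF: greedy BIC merging under a linked proportional-branch-length model
subst = SubstModelConfig()
pf = bic_greedy_merge(blocks, aln, tree, config=subst)
print(f"  PF : {pf.n_partitions:2d} partitions, assignment {pf.assignment}")

# CS: cluster blocks by the scale-free sBSD distance between their fitted
# branch-length vectors
bl = np.stack(
    [fit_branch_lengths(aln.columns(b.columns), tree, subst).bhat for b in blocks]
)
print(
    "\nsBSD(block0, block1) =",
    round(sbsd_min_distance(bl[0], bl[1]), 4),
    "(0 would mean identical up to scale)",
)
cs = gap_statistic_cluster(sbsd_distance_matrix(bl), rng=rng)
print(f"  CS : {cs.n_partitions:2d} partitions, assignment {cs.assignment}")
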