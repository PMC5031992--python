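"""Clade support by chromosome subsampling, and majority-rule collapsing.

The tree for a patient is rebuilt from random subsets of autosomes (by
default 15 of the 22, 30 iterations, drawn without replacement within an
iteration); a clade's support is the fraction of replicate trees containing
it.  Replicates are rebuilt with :func:`~cnaphylo.phylogeny.build_tree` only
and re-rooted at the diploid pseudo-leaf; a clade that a replicate resolves
into a polytomy counts as absent (conservative).  Clades with support below
0.5 (strict) are collapsed into their nearest surviving ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .io_segments import FragmentedMatrix, chromosome_sort_key
from .phylogeny import PhyloTree, build_tree, clade_bipartitions, _remove_internal

DEFAULT_N_ITER = 30
DEFAULT_N_CHROM = 15
DEFAULT_THRESHOLD = 0.5


@dataclass
class ConfidenceReport:
    support: dict[frozenset[str], float]
    n_iterations: int
    n_chromosomes: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": ",".join(sorted(clade)), "support": sup,
             "n_iter": self.n_iterations, "n_chrom": self.n_chromosomes,
             "seed": self.seed}
            for clade, sup in sorted(
                self.support.items(), key=lambda kv: (-kv[1], ",".join(sorted(kv[0])))
            )
        ]
        return pd.DataFrame(rows, columns=["clade", "support", "n_iter", "n_chrom", "seed"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def subsample_confidence(
    matrix: FragmentedMatrix,
    n_iter: int = DEFAULT_N_ITER,
    n_chrom: int = DEFAULT_N_CHROM,
    seed: int = 0,
    source_tree: PhyloTree | None = None,
) -> ConfidenceReport:
    """Support for every clade of the source tree over chromosome subsamples.

    One master seed spawns an independent RNG per iteration, so iterations
    are individually replayable and the result does not depend on sample
    order in ``matrix``.
    """
    chroms = sorted(matrix.chromosomes, key=chromosome_sort_key)
    if len(chroms) < n_chrom:
        raise UsageError(
            f"matrix spans {len(chroms)} autosomes, fewer than n_chrom={n_chrom}"
        )
    if source_tree is None:
        source_tree = build_tree(matrix)
    source_clades = clade_bipartitions(source_tree)

    counts = {clade: 0 for clade in source_clades}
    seeds = np.random.SeedSequence(seed).spawn(n_iter)
    for it_seed in seeds:
        rng = np.random.default_rng(it_seed)
        chosen = rng.choice(len(chroms), size=n_chrom, replace=False)
        sub = matrix.subset_chromosomes([chroms[i] for i in chosen])
        replicate = build_tree(sub)
        present = clade_bipartitions(replicate)
        for clade in counts:
            if clade in present:
                counts[clade] += 1

    support = {clade: c / n_iter for clade, c in counts.items()}
    return ConfidenceReport(support, n_iter, n_chrom, seed)


def annotate_support(tree: PhyloTree, report: ConfidenceReport) -> PhyloTree:
    """Attach supports to the tree's internal nodes by matching leaf sets."""
    for node in tree.internal_nodes():
        clade = tree.leaves_under(node)
        if clade in report.support:
            tree.clade_support[node] = report.support[clade]
    return tree


def collapse_low_confidence(
    tree: PhyloTree, report: ConfidenceReport, threshold: float = DEFAULT_THRESHOLD
) -> PhyloTree:
    """Collapse internal nodes with support < threshold (strict) bottom-up.

    Children of a collapsed node re-attach to its parent (polytomy); the leaf
    set is never changed and surviving nodes keep their support annotation.
    """
    out = tree.copy()
    annotate_support(out, report)
    for node in out.postorder():
        if node == out.root or out.is_leaf(node) or node not in out.parent:
            continue
        clade = out.leaves_under(node)
        support = report.support.get(clade)
        if support is not None and support < threshold:
            _remove_internal(out, node)
    return out
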