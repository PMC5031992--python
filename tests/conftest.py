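import numpy as np
import pytest

from cnaphylo.io_segments import (
    CNProfile,
    FragmentedMatrix,
    GenomicSegment,
    filter_fragments,
    unify_breakpoints,
)
from cnaphylo.phylogeny import build_tree, reconstruct_ancestors
from cnaphylo.synthetic_data import SimConfig, simulate_genome, simulate_patient


def make_profile(sample_id, rows, **kw):
    """rows: (chrom, start, end, cn) tuples."""
    return CNProfile(
        sample_id=sample_id,
        segments=[(GenomicSegment(c, s, e), cn) for c, s, e, cn in rows],
        **kw,
    )


def toy_matrix(values, n_chrom=None, sample_ids=None, categories=None,
               ploidies=None, patient_ids=None, frag_len=1_000_000):
    """One fragment per chromosome (or as given); values: (samples, frags)."""
    values = np.asarray(values)
    n_frag = values.shape[1]
    n_chrom = n_chrom or n_frag
    per = n_frag // n_chrom
    frags = [
        GenomicSegment(str(i // per + 1), (i % per) * frag_len, (i % per + 1) * frag_len)
        for i in range(n_frag)
    ]
    n = values.shape[0]
    sample_ids = sample_ids or [chr(ord("A") + i) for i in range(n)]
    return FragmentedMatrix(
        frags,
        values,
        sample_ids,
        patient_ids or ["P"] * n,
        categories or ["central"] * n,
        np.asarray(ploidies if ploidies is not None else [2.0] * n, dtype=float),
    )


@pytest.fixture(scope="session")
def noiseless_patient():
    """A noiseless diploid lymph-node-scenario patient with its truth."""
    config = SimConfig(seed=42, noise_sd=0.0, triploid_fraction=0.0)
    clones, profiles = simulate_patient(config, "lymph_from_epe", 0)
    genome = simulate_genome(config)
    matrix = filter_fragments(unify_breakpoints(profiles))
    tree = reconstruct_ancestors(build_tree(matrix), matrix)
    return {
        "config": config, "clones": clones, "profiles": profiles,
        "genome": genome, "matrix": matrix, "tree": tree,
    }
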