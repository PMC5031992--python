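"""Category centroids, leave-one-patient-out distances and classical MDS.

Ploidy-adjusted profiles belonging to the same histo-pathological category
(or the same transition) are averaged into centroid vectors; Euclidean
distances between centroids summarise genome-wide relatedness of the
disease states.  Robustness is assessed by recomputing the distance matrix
with each patient left out in turn (a cohort of 7 patients yields 7
leave-one-out matrices).  Classical (Torgerson) multidimensional scaling
embeds a distance matrix by double-centering its squared entries and taking
the top eigenvectors scaled by root eigenvalues; axis orientation is fixed
deterministically by making each axis's largest-magnitude coordinate
positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import UsageError
from .io_segments import FragmentedMatrix, GenomicSegment, ploidy_adjust
from .transition_analysis import TRANSITIONS, TransitionProfile

logger = logging.getLogger("cnaphylo")

_EXCLUDED_CATEGORIES = {"benign", ""}


@dataclass
class CategoryCentroid:
    category: str
    vector: np.ndarray
    fragments: list[GenomicSegment]


def _centroids_from_matrix(
    matrix: FragmentedMatrix, exclude_patients: set[str] = frozenset()
) -> list[CategoryCentroid]:
    adjusted = ploidy_adjust(matrix)
    keep = [i for i, p in enumerate(matrix.patient_ids) if p not in exclude_patients]
    out = []
    categories = sorted(
        {matrix.categories[i] for i in keep} - _EXCLUDED_CATEGORIES
    )
    for category in categories:
        idx = [i for i in keep if matrix.categories[i] == category]
        out.append(
            CategoryCentroid(category, adjusted[idx].mean(axis=0), list(matrix.fragments))
        )
    return out


def _centroids_from_transitions(
    profiles: list[TransitionProfile], exclude_patients: set[str] = frozenset()
) -> list[CategoryCentroid]:
    out = []
    for transition in TRANSITIONS:
        members = [
            tp for tp in profiles
            if tp.transition == transition and tp.patient_id not in exclude_patients
        ]
        if not members:
            continue
        out.append(
            CategoryCentroid(
                transition,
                np.mean([tp.values for tp in members], axis=0),
                list(members[0].fragments),
            )
        )
    return out


def category_centroids(
    source: FragmentedMatrix | list[TransitionProfile],
    by: str = "sample_profiles",
) -> list[CategoryCentroid]:
    """Mean (ploidy-adjusted) profile per category or per transition."""
    if by == "sample_profiles":
        if not isinstance(source, FragmentedMatrix):
            raise UsageError("by='sample_profiles' needs a FragmentedMatrix")
        cents = _centroids_from_matrix(source)
    elif by == "transition_profiles":
        if isinstance(source, FragmentedMatrix):
            raise UsageError("by='transition_profiles' needs transition profiles")
        cents = _centroids_from_transitions(source)
    else:
        raise UsageError(f"unknown mode {by!r}")
    if not cents:
        raise UsageError("no non-empty categories to average")
    return cents


def _distance_frame(cents: list[CategoryCentroid]) -> pd.DataFrame:
    labels = [c.category for c in cents]
    mat = squareform(pdist(np.vstack([c.vector for c in cents]), metric="euclidean"))
    return pd.DataFrame(mat, index=labels, columns=labels)


def distance_matrices(
    source: FragmentedMatrix | list[TransitionProfile],
    by: str = "sample_profiles",
    leave_one_out: bool = True,
) -> list[tuple[str, pd.DataFrame]]:
    """Full-data centroid distance matrix plus one per left-out patient."""
    full = _distance_frame(category_centroids(source, by))
    out = [("all", full)]
    if not leave_one_out:
        return out
    if isinstance(source, FragmentedMatrix):
        patients = sorted(set(source.patient_ids))
        builder = lambda p: _centroids_from_matrix(source, {p})  # noqa: E731
    else:
        patients = sorted({tp.patient_id for tp in source})
        builder = lambda p: _centroids_from_transitions(source, {p})  # noqa: E731
    if len(patients) < 2:
        raise UsageError("leave-one-out needs at least two patients")
    for patient in patients:
        cents = builder(patient)
        if len(cents) < len(full):
            missing = set(full.index) - {c.category for c in cents}
            logger.warning(
                "leave-one-out without %s empties categories %s", patient, sorted(missing)
            )
        out.append((f"without_{patient}", _distance_frame(cents)))
    return out


def classical_mds(dist, dims: int = 2) -> np.ndarray:
    """Torgerson MDS: double-center -D^2/2, eigendecompose, scale by sqrt(eig).

    Negative eigenvalues are truncated at zero; the output is centred at the
    origin with a deterministic sign convention per axis.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise UsageError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise UsageError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise UsageError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if dims < 1:
        raise UsageError("dims must be >= 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)[None, :]
    if coords.shape[1] < dims:
        coords = np.pad(coords, ((0, 0), (0, dims - coords.shape[1])))
    coords -= coords.mean(axis=0)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


def mds_frame(dist: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    coords = classical_mds(dist.to_numpy(), dims)
    return pd.DataFrame(
        coords, index=dist.index, columns=[f"dim{i + 1}" for i in range(dims)]
    )
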