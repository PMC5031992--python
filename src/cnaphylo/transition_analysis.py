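"""Category representatives, transition CNA profiles and per-fragment tests.

For each patient's tree a *representative ancestor* is chosen per
histo-pathological category: the internal node whose leaf descendants best
match the category's sampled clones (maximum F1, ties resolved toward the
root).  Subtracting consecutive representatives (ploidy-adjusted) yields one
increase/decrease profile per patient and transition:

    diploid -> central -> extraprostatic -> lymph node
                    \\________ (central or EPE) -> bone

The bone transition's parent is whichever of the patient's central/EPE
representatives is the nearest ancestor of its bone representative.  The
profiles are harmonised across patients (union of breakpoints, then the
>500 kb filter) and each fragment is tested for differences across the four
transitions with a one-way ANOVA; p-values are FDR-adjusted (Benjamini-
Hochberg step-up by default, Benjamini-Yekutieli optional) and rows below
the reporting threshold (default 0.25) are returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CnaPhyloError, UsageError
from .io_segments import (
    CNProfile,
    FragmentedMatrix,
    GenomicSegment,
    filter_fragments,
    unify_breakpoints,
)
from .phylogeny import PhyloTree

logger = logging.getLogger("cnaphylo")

TRANSITIONS = (
    "diploid_to_central",
    "central_to_extraprostatic",
    "extraprostatic_to_lymph",
    "primary_to_bone",
)

#: transition -> (child category, default parent category)
_TRANSITION_PAIRS = {
    "diploid_to_central": ("central", "diploid"),
    "central_to_extraprostatic": ("extraprostatic", "central"),
    "extraprostatic_to_lymph": ("lymph_node", "extraprostatic"),
    "primary_to_bone": ("bone", None),  # parent resolved per patient
}

DEFAULT_REPORT_THRESHOLD = 0.25


class CategoryMissing(CnaPhyloError):
    """The requested category has no sampled leaves in this patient."""


@dataclass
class TransitionProfile:
    patient_id: str
    transition: str
    values: np.ndarray
    fragments: list[GenomicSegment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.fragments):
            raise UsageError("transition profile length must match its fragments")


@dataclass
class TransitionTestRow:
    fragment: GenomicSegment
    group_means: dict[str, float]
    F_stat: float
    p: float
    p_adj: float = float("nan")
    note: str = ""


# ---------------------------------------------------------------------------
# Representatives
# ---------------------------------------------------------------------------

def representative_ancestor(
    tree: PhyloTree, category: str, categories: dict[str, str]
) -> str:
    """Internal node maximising F1 against the category's leaf set.

    Ties break toward the node closer to the root.  The diploid root
    represents the "diploid" category.
    """
    if category == "diploid":
        return tree.root
    target = {leaf for leaf in tree.leaves() if categories.get(leaf) == category}
    if not target:
        raise CategoryMissing(f"no sampled leaves of category {category!r}")
    best: tuple[float, int, int] | None = None
    best_node = None
    for rank, node in enumerate(tree.preorder()):
        if tree.is_leaf(node) and node != tree.root:
            continue
        clade = tree.leaves_under(node)
        inter = len(clade & target)
        f1 = 2 * inter / (len(clade) + len(target))
        cand = (-f1, tree.depth(node), rank)
        if best is None or cand < best:
            best = cand
            best_node = node
    assert best_node is not None
    return best_node


def _node_profile_as_cnprofile(
    tree: PhyloTree, node: str, matrix: FragmentedMatrix, sample_id: str
) -> CNProfile:
    values = tree.ancestral_profiles[node].as_array()
    segments: list[tuple[GenomicSegment, int]] = []
    for frag, cn in zip(matrix.fragments, values):
        cn = int(cn)
        if (
            segments
            and segments[-1][0].chromosome == frag.chromosome
            and segments[-1][1] == cn
        ):
            prev, _ = segments[-1]
            segments[-1] = (GenomicSegment(prev.chromosome, prev.start, frag.end), cn)
        else:
            segments.append((frag, cn))
    lengths = np.array([len(s) for s, _ in segments], dtype=float)
    cns = np.array([c for _, c in segments], dtype=float)
    ploidy = float(np.round(np.average(cns, weights=lengths)))
    return CNProfile(sample_id=sample_id, segments=segments, ploidy=ploidy)


def _bone_parent_category(
    tree: PhyloTree, reps: dict[str, str], patient: str
) -> str:
    """Nearest ancestral representative (central or EPE) of the bone node."""
    node = reps["bone"]
    candidates = {reps[c]: c for c in ("extraprostatic", "central") if c in reps}
    cur = tree.parent.get(node)
    while cur is not None:
        if cur in candidates:
            return candidates[cur]
        cur = tree.parent.get(cur)
    fallback = "extraprostatic" if "extraprostatic" in reps else "central"
    logger.warning(
        "patient %s: bone representative has no category representative among "
        "its ancestors; using %s", patient, fallback,
    )
    return fallback


# ---------------------------------------------------------------------------
# Transition profiles
# ---------------------------------------------------------------------------

def transition_profiles(
    trees: dict[str, PhyloTree],
    matrices: dict[str, FragmentedMatrix],
    min_fragment_len: int = 500_000,
) -> list[TransitionProfile]:
    """Per-patient ploidy-adjusted child-minus-parent representative profiles,
    on fragments harmonised across all patients."""
    rep_profiles: list[CNProfile] = []
    rep_ploidy: dict[str, float] = {}
    patient_reps: dict[str, dict[str, str]] = {}
    for patient, tree in trees.items():
        matrix = matrices[patient]
        if not tree.ancestral_profiles:
            raise UsageError(f"patient {patient}: tree has no ancestral profiles")
        categories = dict(zip(matrix.sample_ids, matrix.categories))
        reps: dict[str, str] = {"diploid": tree.root}
        for category in ("central", "extraprostatic", "lymph_node", "bone"):
            try:
                reps[category] = representative_ancestor(tree, category, categories)
            except CategoryMissing:
                continue
        patient_reps[patient] = reps
        for category, node in reps.items():
            sid = f"{patient}|{category}"
            prof = _node_profile_as_cnprofile(tree, node, matrix, sid)
            rep_profiles.append(prof)
            rep_ploidy[sid] = prof.ploidy

    harmonised = filter_fragments(unify_breakpoints(rep_profiles), min_fragment_len)

    out: list[TransitionProfile] = []
    for transition in TRANSITIONS:
        child_cat, parent_cat = _TRANSITION_PAIRS[transition]
        found = False
        for patient, reps in patient_reps.items():
            if child_cat not in reps:
                continue
            parent = parent_cat
            if transition == "primary_to_bone":
                parent = _bone_parent_category(trees[patient], reps, patient)
            if parent != "diploid" and parent not in reps:
                logger.warning(
                    "patient %s: %s skipped (missing %s representative)",
                    patient, transition, parent,
                )
                continue
            child_id = f"{patient}|{child_cat}"
            parent_id = f"{patient}|{parent}"
            child_row = harmonised.values[harmonised.sample_index(child_id)].astype(float)
            parent_row = harmonised.values[harmonised.sample_index(parent_id)].astype(float)
            values = (child_row - rep_ploidy[child_id]) - (parent_row - rep_ploidy[parent_id])
            out.append(
                TransitionProfile(patient, transition, values, list(harmonised.fragments))
            )
            found = True
        if not found:
            logger.warning("no patient provides transition %s", transition)
    return out


# ---------------------------------------------------------------------------
# Per-fragment ANOVA with FDR
# ---------------------------------------------------------------------------

def fdr_adjust(pvals, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (default) or Benjamini-Yekutieli adjusted p-values,
    in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise UsageError("fdr_adjust needs at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise UsageError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method.lower())
    if key is None:
        raise UsageError(f"unknown FDR method {method!r}; use 'bh' or 'by'")
    return multipletests(p, method=key)[1]


def cross_patient_anova(
    profiles: list[TransitionProfile],
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
    fdr_method: str = "bh",
) -> list[TransitionTestRow]:
    """One-way ANOVA per fragment with transition as the group factor.

    Observations are per-patient values; fragments whose total variance is
    zero get p = 1 and a flag.  Returns rows with adjusted p below
    ``report_threshold``, sorted by raw p.
    """
    if not profiles:
        raise UsageError("no transition profiles given")
    fragments = profiles[0].fragments
    n_frag = len(fragments)
    if any(len(tp.values) != n_frag for tp in profiles):
        raise UsageError("transition profiles are not harmonised to common fragments")

    groups: dict[str, list[np.ndarray]] = {}
    for tp in profiles:
        groups.setdefault(tp.transition, []).append(tp.values)
    arrays = {t: np.vstack(v) for t, v in groups.items() if len(v) >= 2}
    if len(arrays) < 2:
        raise UsageError("need at least two transition groups with >=2 observations")

    ordered = [t for t in TRANSITIONS if t in arrays]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*[arrays[t] for t in ordered], axis=0)
    f_stat = np.asarray(f_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate] = 1.0

    p_adj = fdr_adjust(p, method=fdr_method)
    rows = []
    for i in range(n_frag):
        means = {
            t: float(np.mean(arrays[t][:, i])) if t in arrays else float("nan")
            for t in TRANSITIONS
        }
        rows.append(
            TransitionTestRow(
                fragment=fragments[i],
                group_means=means,
                F_stat=float(f_stat[i]) if not degenerate[i] else float("nan"),
                p=float(p[i]),
                p_adj=float(p_adj[i]),
                note="zero_variance" if degenerate[i] else "",
            )
        )
    reported = [r for r in rows if r.p_adj < report_threshold]
    reported.sort(key=lambda r: (r.p, r.fragment.label))
    return reported


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: list[TransitionProfile]) -> pd.DataFrame:
    rows = []
    for tp in profiles:
        for frag, value in zip(tp.fragments, tp.values):
            rows.append(
                {"patient": tp.patient_id, "transition": tp.transition,
                 "fragment": frag.label, "value": value}
            )
    return pd.DataFrame(rows)


def report_to_frame(rows: list[TransitionTestRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment": r.fragment.label,
                **{f"mean_{t}": r.group_means.get(t, float("nan")) for t in TRANSITIONS},
                "F": r.F_stat,
                "p": r.p,
                "p_adj": r.p_adj,
                "note": r.note,
            }
            for r in rows
        ]
    )
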