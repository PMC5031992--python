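"""Concordance of array-derived branch CN changes with MLPA intensities.

MLPA probe intensities carry a technical trend with probe length.  The trend
is estimated by a least-squares line on the benign control sample(s) — whose
copy number is uniformly 2, so the fit is uncontaminated by CNAs — and
divided out of every sample.  Tumour/control intensity ratios per gene then
estimate cn/2, and a gene's copy-number call uses thresholds shifted for
tumour ploidy:

    adjusted_ratio = ratio - (ploidy - 2) / 2
    loss if adjusted < t_lo (0.75), gain if adjusted > t_hi (1.25)

For every branch of a patient's tree, probes whose array-derived direction
changes along the branch are *informative*; concordance between the MLPA
call and the array call in each descendant sample is scored by a two-sided
exact binomial test against a null success probability of 0.33 (three
possible outcomes: decrease, increase, no change), and p-values are
FDR-adjusted across branches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError
from .io_segments import FragmentedMatrix, GenomicSegment
from .phylogeny import PhyloTree, node_ploidy
from .transition_analysis import fdr_adjust

logger = logging.getLogger("cnaphylo")

DEFAULT_T_LO = 0.75
DEFAULT_T_HI = 1.25
DEFAULT_NULL_P = 0.33


@dataclass(frozen=True)
class MLPAProbe:
    probe_id: str
    gene: str
    probe_length: int
    fragment: GenomicSegment

    def __post_init__(self) -> None:
        if self.probe_length <= 0:
            raise UsageError(f"probe {self.probe_id}: probe_length must be positive")


@dataclass
class MLPACall:
    sample_id: str
    gene: str
    ratio: float
    adjusted_ratio: float
    call: str  # loss | neutral | gain


@dataclass
class MLPAValidationRow:
    patient: str
    node: str
    descendants: str
    n_informative: int
    k_agree: int
    percent: float
    p: float
    p_adj: float = float("nan")
    note: str = ""


# ---------------------------------------------------------------------------
# Normalisation and calling
# ---------------------------------------------------------------------------

def normalize_probe_length(
    intensities: pd.DataFrame,
    probes: list[MLPAProbe] | None = None,
    control_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Divide out the probe-length trend (least-squares slope correction).

    The line is fitted on the control samples' points when given (preferred:
    their uniform CN 2 leaves the trend uncontaminated), otherwise per
    sample.  Returns a copy with a ``normalized`` column.
    """
    df = intensities.copy()
    required = {"sample", "probe_id", "probe_length", "intensity"}
    if not required <= set(df.columns):
        raise UsageError(f"intensity table must have columns {sorted(required)}")
    if df["probe_length"].nunique() == 1:
        logger.warning("all probe lengths equal; length normalisation skipped")
        df["normalized"] = df["intensity"]
        return df

    if control_samples:
        ctrl = df[df["sample"].isin(control_samples)]
        if ctrl.empty:
            raise UsageError(f"control samples {control_samples} absent from table")
        slope, intercept = np.polyfit(ctrl["probe_length"], ctrl["intensity"], 1)
        fitted = intercept + slope * df["probe_length"].to_numpy(dtype=float)
        if np.any(fitted <= 0):
            raise UsageError("fitted length trend is non-positive; data unusable")
        df["normalized"] = df["intensity"].to_numpy() / fitted
    else:
        out = np.empty(len(df))
        for _, idx in df.groupby("sample").indices.items():
            sub = df.iloc[idx]
            slope, intercept = np.polyfit(sub["probe_length"], sub["intensity"], 1)
            fitted = intercept + slope * sub["probe_length"].to_numpy(dtype=float)
            if np.any(fitted <= 0):
                raise UsageError("fitted length trend is non-positive; data unusable")
            out[idx] = sub["intensity"].to_numpy() / fitted
        df["normalized"] = out
    return df


def gene_ratios(
    normalized: pd.DataFrame, control_samples: list[str]
) -> pd.DataFrame:
    """Per-gene tumour/control ratios (probe ratios averaged within gene)."""
    if "normalized" not in normalized.columns:
        raise UsageError("run normalize_probe_length first")
    if not control_samples:
        raise UsageError("at least one control sample is required")
    ctrl_mean = (
        normalized[normalized["sample"].isin(control_samples)]
        .groupby("probe_id")["normalized"].mean()
    )
    if ctrl_mean.empty:
        raise UsageError(f"control samples {control_samples} absent from table")
    df = normalized[~normalized["sample"].isin(control_samples)].copy()
    df["ratio"] = df["normalized"] / df["probe_id"].map(ctrl_mean)
    return df.pivot_table(index="sample", columns="gene", values="ratio", aggfunc="mean")


def call_copy_number(
    ratio: float,
    ploidy: float,
    t_lo: float = DEFAULT_T_LO,
    t_hi: float = DEFAULT_T_HI,
    sample_id: str = "",
    gene: str = "",
) -> MLPACall:
    """Ploidy-adjusted gain/neutral/loss call from a tumour/control ratio."""
    if ploidy <= 0:
        raise UsageError("ploidy must be positive")
    if ratio <= 0:
        raise UsageError("ratio must be positive")
    adjusted = ratio - (ploidy - 2.0) / 2.0
    if adjusted < t_lo:
        call = "loss"
    elif adjusted > t_hi:
        call = "gain"
    else:
        call = "neutral"
    return MLPACall(sample_id, gene, float(ratio), float(adjusted), call)


def make_calls(
    ratios: pd.DataFrame,
    ploidies: dict[str, float],
    t_lo: float = DEFAULT_T_LO,
    t_hi: float = DEFAULT_T_HI,
) -> list[MLPACall]:
    calls = []
    for sample in ratios.index:
        ploidy = ploidies.get(sample, 2.0)
        for gene in ratios.columns:
            ratio = ratios.loc[sample, gene]
            if np.isnan(ratio):
                continue
            calls.append(call_copy_number(ratio, ploidy, t_lo, t_hi, sample, gene))
    return calls


# ---------------------------------------------------------------------------
# Branch concordance
# ---------------------------------------------------------------------------

_DIRECTION = {"loss": -1, "neutral": 0, "gain": 1}


def _fragment_index(matrix: FragmentedMatrix, probe: MLPAProbe) -> int | None:
    pos = (probe.fragment.start + probe.fragment.end) // 2
    for i, frag in enumerate(matrix.fragments):
        if frag.chromosome == probe.fragment.chromosome and frag.start <= pos < frag.end:
            return i
    return None


def _node_direction(tree: PhyloTree, node: str, frag_idx: int, lengths: np.ndarray) -> int:
    profile = tree.ancestral_profiles[node].as_array()
    baseline = int(round(node_ploidy(tree, node, lengths)))
    return int(np.sign(profile[frag_idx] - baseline))


def branch_concordance(
    tree: PhyloTree,
    node: str,
    probes: list[MLPAProbe],
    matrix: FragmentedMatrix,
    mlpa_calls: list[MLPACall],
    null_p: float = DEFAULT_NULL_P,
) -> MLPAValidationRow:
    """Concordance row for the branch into ``node``.

    Trials are (informative probe, descendant sample with MLPA data) pairs;
    a trial succeeds when the MLPA call direction equals the sample's own
    array-derived direction.  p is the two-sided exact binomial tail.
    """
    if node == tree.root or node not in tree.parent:
        raise UsageError(f"{node!r} is not a branch endpoint of this tree")
    parent = tree.parent[node]
    lengths = matrix.fragment_lengths().astype(float)
    call_map = {(c.sample_id, c.gene): _DIRECTION[c.call] for c in mlpa_calls}
    mlpa_samples = {c.sample_id for c in mlpa_calls}
    descendants = sorted(tree.leaves_under(node) & mlpa_samples)

    n = k = 0
    for probe in probes:
        fi = _fragment_index(matrix, probe)
        if fi is None:
            continue
        if _node_direction(tree, node, fi, lengths) == _node_direction(tree, parent, fi, lengths):
            continue  # not informative for this branch
        for sample in descendants:
            if (sample, probe.gene) not in call_map:
                continue
            si = matrix.sample_index(sample)
            baseline = int(round(matrix.ploidies[si])) if not np.isnan(matrix.ploidies[si]) else 2
            array_dir = int(np.sign(matrix.values[si, fi] - baseline))
            n += 1
            if call_map[(sample, probe.gene)] == array_dir:
                k += 1

    patient = matrix.patient_ids[0] if matrix.patient_ids else ""
    kids = "; ".join(tree.children.get(node, []))
    if n == 0:
        return MLPAValidationRow(patient, node, kids, 0, 0, float("nan"), 1.0,
                                 note="no informative probes")
    p = stats.binomtest(k, n, null_p).pvalue
    return MLPAValidationRow(patient, node, kids, n, k, round(100.0 * k / n, 1), float(p))


def validation_report(
    rows: list[MLPAValidationRow], fdr_method: str = "bh"
) -> list[MLPAValidationRow]:
    """Attach FDR-adjusted p-values across branches."""
    if not rows:
        raise UsageError("no validation rows")
    adj = fdr_adjust([r.p for r in rows], method=fdr_method)
    for row, a in zip(rows, adj):
        row.p_adj = float(a)
    return rows


def report_to_frame(rows: list[MLPAValidationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient": r.patient, "node": r.node, "descendants": r.descendants,
             "n_informative": r.n_informative, "k_agree": r.k_agree,
             "percent_validated": r.percent, "p": r.p, "p_adj": r.p_adj,
             "note": r.note}
            for r in rows
        ]
    )


def validate_patient(
    tree: PhyloTree,
    matrix: FragmentedMatrix,
    intensities: pd.DataFrame,
    probes: list[MLPAProbe],
    control_samples: list[str],
    t_lo: float = DEFAULT_T_LO,
    t_hi: float = DEFAULT_T_HI,
    null_p: float = DEFAULT_NULL_P,
    fdr_method: str = "bh",
) -> list[MLPAValidationRow]:
    """Full per-patient pipeline: normalise, call, score every branch."""
    norm = normalize_probe_length(intensities, probes, control_samples)
    ratios = gene_ratios(norm, control_samples)
    ploidies = {
        s: float(p) for s, p in zip(matrix.sample_ids, matrix.ploidies) if not np.isnan(p)
    }
    calls = make_calls(ratios, ploidies, t_lo, t_hi)
    rows = [
        branch_concordance(tree, node, probes, matrix, calls, null_p)
        for node in tree.internal_nodes()
    ]
    if not rows:  # star tree: score the root's child branches into leaves
        rows = [
            branch_concordance(tree, leaf, probes, matrix, calls, null_p)
            for leaf in tree.leaves()
        ]
    return validation_report(rows, fdr_method)
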