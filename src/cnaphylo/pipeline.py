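"""End-to-end orchestration: configuration and the staged cohort analysis.

Stages per patient: breakpoint harmonisation -> >500 kb fragment filter ->
diploid-rooted NJ tree -> chromosome-subsampling clade confidence ->
majority-rule collapse -> ancestral reconstruction.  Cohort-level stages:
transition profiles and per-fragment ANOVA/FDR, MLPA branch validation
(when intensities are given), and centroid distance / MDS geometry.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clade_confidence import ConfidenceReport, collapse_low_confidence, subsample_confidence
from .category_geometry import distance_matrices, mds_frame
from .errors import UsageError
from .io_segments import CNProfile, FragmentedMatrix, filter_fragments, unify_breakpoints
from .mlpa_validation import MLPAProbe, report_to_frame as mlpa_frame, validate_patient
from .phylogeny import PhyloTree, build_tree, reconstruct_ancestors, write_ancestral_profiles
from .transition_analysis import (
    TransitionProfile,
    cross_patient_anova,
    profiles_to_frame,
    report_to_frame,
    transition_profiles,
)

logger = logging.getLogger("cnaphylo")


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline (defaults are the study's)."""

    min_fragment_len: int = 500_000
    conf_iterations: int = 30
    conf_chromosomes: int = 15
    conf_threshold: float = 0.5
    fdr_method: str = "bh"
    report_threshold: float = 0.25
    binom_null: float = 0.33
    mlpa_t_lo: float = 0.75
    mlpa_t_hi: float = 1.25
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.min_fragment_len < 0:
            raise UsageError("min_fragment_len must be >= 0")
        if not 1 <= self.conf_chromosomes <= 22:
            raise UsageError("conf_chromosomes must lie in 1..22")
        if self.conf_iterations < 1:
            raise UsageError("conf_iterations must be >= 1")
        if not 0 <= self.conf_threshold <= 1:
            raise UsageError("conf_threshold must lie in [0, 1]")
        if self.fdr_method.lower() not in ("bh", "by"):
            raise UsageError("fdr_method must be 'bh' or 'by'")
        if not 0 < self.binom_null < 1:
            raise UsageError("binom_null must lie in (0, 1)")
        if not 0 < self.mlpa_t_lo < self.mlpa_t_hi:
            raise UsageError("need 0 < mlpa_t_lo < mlpa_t_hi")
        return self

    def echo(self) -> str:
        return " ".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Plain key=value config file; '#' starts a comment."""
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict[str, object] = {}
        unknown = []
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise UsageError(f"bad config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                unknown.append(key)
                continue
            caster = int if known[key] == "int" else (str if known[key] == "str" else float)
            values[key] = caster(value)
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values).validate()  # type: ignore[arg-type]


@dataclass
class PatientResult:
    patient_id: str
    matrix: FragmentedMatrix
    tree: PhyloTree
    confidence: ConfidenceReport
    collapsed: PhyloTree


@dataclass
class CohortResult:
    patients: dict[str, PatientResult]
    transitions: list[TransitionProfile] = field(default_factory=list)
    anova_rows: list = field(default_factory=list)
    mlpa_rows: dict[str, list] = field(default_factory=dict)


def analyse_patient(
    profiles: list[CNProfile], config: PipelineConfig
) -> PatientResult:
    tumour = [p for p in profiles if p.category != "benign"]
    if len(tumour) < 3:
        raise UsageError(
            f"patient {profiles[0].patient_id or '?'}: need >=3 tumour samples"
        )
    matrix = filter_fragments(unify_breakpoints(tumour), config.min_fragment_len)
    tree = build_tree(matrix)
    reconstruct_ancestors(tree, matrix)
    report = subsample_confidence(
        matrix,
        n_iter=config.conf_iterations,
        n_chrom=config.conf_chromosomes,
        seed=config.seed,
        source_tree=tree,
    )
    collapsed = collapse_low_confidence(tree, report, config.conf_threshold)
    reconstruct_ancestors(collapsed, matrix)
    return PatientResult(tumour[0].patient_id, matrix, tree, report, collapsed)


def analyse_cohort(
    profiles: list[CNProfile],
    config: PipelineConfig,
    mlpa: dict[str, tuple[pd.DataFrame, list[MLPAProbe], list[str]]] | None = None,
) -> CohortResult:
    """Run every stage on a cohort of SEG profiles (benign samples are used
    only as MLPA controls, never in trees)."""
    config.validate()
    by_patient: dict[str, list[CNProfile]] = {}
    for p in profiles:
        if not p.category:
            raise UsageError(f"sample {p.sample_id}: missing category label")
        by_patient.setdefault(p.patient_id or p.sample_id, []).append(p)

    patients = {
        pid: analyse_patient(plist, config) for pid, plist in sorted(by_patient.items())
    }
    result = CohortResult(patients)

    trees = {pid: r.collapsed for pid, r in patients.items()}
    matrices = {pid: r.matrix for pid, r in patients.items()}
    result.transitions = transition_profiles(trees, matrices, config.min_fragment_len)
    if result.transitions:
        groups = {tp.transition for tp in result.transitions}
        counts = {g: sum(tp.transition == g for tp in result.transitions) for g in groups}
        if sum(c >= 2 for c in counts.values()) >= 2:
            result.anova_rows = cross_patient_anova(
                result.transitions, config.report_threshold, config.fdr_method
            )

    if mlpa:
        for pid, (table, probes, controls) in mlpa.items():
            if pid not in patients:
                logger.warning("MLPA table for unknown patient %s ignored", pid)
                continue
            result.mlpa_rows[pid] = validate_patient(
                patients[pid].collapsed, patients[pid].matrix, table, probes,
                controls, config.mlpa_t_lo, config.mlpa_t_hi, config.binom_null,
                config.fdr_method,
            )
    return result


def _write_with_header(df: pd.DataFrame, path: Path, config: PipelineConfig,
                       index: bool = False, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cnaphylo {config.echo()}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def write_outputs(result: CohortResult, out_dir: str | Path,
                  config: PipelineConfig, profiles: list[CNProfile] | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, pr in result.patients.items():
        with open(out / f"{pid}.tree.nwk", "w") as fh:
            fh.write(pr.tree.newick() + "\n")
        with open(out / f"{pid}.collapsed.nwk", "w") as fh:
            fh.write(pr.collapsed.newick(include_support=True) + "\n")
        _write_with_header(pr.confidence.to_frame(), out / f"{pid}.confidence.tsv", config)
        write_ancestral_profiles(pr.collapsed, pr.matrix, out / f"{pid}.ancestors.tsv")
    if result.transitions:
        _write_with_header(
            profiles_to_frame(result.transitions), out / "transitions.tsv", config
        )
    if result.anova_rows:
        _write_with_header(
            report_to_frame(result.anova_rows), out / "transition_anova.tsv", config
        )
    for pid, rows in result.mlpa_rows.items():
        _write_with_header(mlpa_frame(rows), out / f"{pid}.mlpa_validation.tsv", config)
    if result.transitions:
        mats = distance_matrices(result.transitions, by="transition_profiles")
        for label, df in mats:
            _write_with_header(
                df, out / f"distances_{label}.tsv", config, index=True, index_label="category"
            )
        full = mats[0][1]
        if len(full) >= 2:
            _write_with_header(
                mds_frame(full, dims=2), out / "mds.tsv", config,
                index=True, index_label="category",
            )
    if profiles is not None:
        samples = [p for p in profiles if p.category != "benign"]
        cohort = filter_fragments(unify_breakpoints(samples), config.min_fragment_len)
        for label, df in distance_matrices(cohort, by="sample_profiles"):
            _write_with_header(
                df, out / f"sample_distances_{label}.tsv", config,
                index=True, index_label="category",
            )
    return out


# ---------------------------------------------------------------------------
# MLPA table I/O (probe coordinates travel with the intensity table)
# ---------------------------------------------------------------------------

def write_mlpa_tsv(table: pd.DataFrame, probes: list[MLPAProbe],
                   control_samples: list[str], path: str | Path) -> None:
    coords = {
        p.probe_id: (p.fragment.chromosome, p.fragment.start, p.fragment.end)
        for p in probes
    }
    df = table.copy()
    df["chromosome"] = df["probe_id"].map(lambda x: coords[x][0])
    df["start"] = df["probe_id"].map(lambda x: coords[x][1])
    df["end"] = df["probe_id"].map(lambda x: coords[x][2])
    df["is_control"] = df["sample"].isin(control_samples)
    df.to_csv(path, sep="\t", index=False)


def read_mlpa_tsv(path: str | Path):
    from .io_segments import GenomicSegment

    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "sample": str})
    needed = {"sample", "probe_id", "gene", "probe_length", "intensity",
              "chromosome", "start", "end"}
    if not needed <= set(df.columns):
        raise UsageError(f"MLPA table must have columns {sorted(needed)}")
    probes = [
        MLPAProbe(r.probe_id, r.gene, int(r.probe_length),
                  GenomicSegment(r.chromosome, int(r.start), int(r.end)))
        for r in df.drop_duplicates("probe_id").itertuples()
    ]
    controls = sorted(df.loc[df.get("is_control", False) == True, "sample"].unique())  # noqa: E712
    table = df[["sample", "probe_id", "gene", "probe_length", "intensity"]]
    return table, probes, controls
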