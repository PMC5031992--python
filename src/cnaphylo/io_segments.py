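"""Segmented copy-number I/O, breakpoint harmonisation and ploidy adjustment.

Profiles arrive as SEG-like TSV (one row per segment, 1-based inclusive
coordinates on disk) and are held internally with 0-based half-open
coordinates.  Only autosomes "1".."22" are analysed; sex-chromosome rows are
dropped on load.  To compare samples, all breakpoints are unioned into a
common set of *fragments* so that every sample has exactly one integer copy
number per fragment; fragments shorter than a minimum length (default
500 kb, strict) are then discarded.  Ploidy adjustment subtracts each
sample's average genome copy number so that 0 means "no change relative to
that genome's baseline" (a triploid sample at CN 3 everywhere is as neutral
as a diploid one at CN 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError, UsageError
from .med_distance import CNVector, cn_vector

logger = logging.getLogger("cnaphylo")

AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))
SEX_CHROMOSOMES = frozenset({"X", "Y", "23", "24", "XY", "MT", "M"})
CATEGORIES = ("central", "extraprostatic", "lymph_node", "bone", "benign")

DEFAULT_MIN_FRAGMENT_LEN = 500_000


def chromosome_sort_key(chromosome: str) -> int:
    return int(chromosome)


@dataclass(frozen=True)
class GenomicSegment:
    """An autosomal interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.chromosome not in AUTOSOMES:
            raise FormatError(f"chromosome {self.chromosome!r} is not an autosome 1..22")
        if not self.start < self.end:
            raise FormatError(
                f"segment {self.chromosome}:{self.start}-{self.end} has start >= end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


def segment_from_label(label: str) -> GenomicSegment:
    chrom, span = label.split(":")
    start, end = span.split("-")
    return GenomicSegment(chrom, int(start), int(end))


@dataclass
class CNProfile:
    """One sample's ordered copy-number segments plus metadata."""

    sample_id: str
    segments: list[tuple[GenomicSegment, int]]
    patient_id: str = ""
    category: str = ""
    ploidy: float = float("nan")
    purity: float = float("nan")

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments,
            key=lambda sc: (chromosome_sort_key(sc[0].chromosome), sc[0].start),
        )
        prev: GenomicSegment | None = None
        for seg, cn in self.segments:
            if cn < 0:
                raise FormatError(
                    f"sample {self.sample_id}: negative copy number at {seg.label}"
                )
            if prev is not None and prev.chromosome == seg.chromosome and seg.start < prev.end:
                raise FormatError(
                    f"sample {self.sample_id}: overlapping segments "
                    f"{prev.label} and {seg.label}"
                )
            prev = seg

    @property
    def chromosomes(self) -> list[str]:
        return sorted({s.chromosome for s, _ in self.segments}, key=chromosome_sort_key)


@dataclass
class FragmentedMatrix:
    """Samples x common-fragments integer copy-number matrix."""

    fragments: list[GenomicSegment]
    values: np.ndarray  # (n_samples, n_fragments) int
    sample_ids: list[str]
    patient_ids: list[str]
    categories: list[str]
    ploidies: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.ploidies is None:
            self.ploidies = np.full(len(self.sample_ids), np.nan)
        self.ploidies = np.asarray(self.ploidies, dtype=float)
        n_s, n_f = self.values.shape
        if not (
            n_s == len(self.sample_ids) == len(self.patient_ids) == len(self.categories)
            and n_f == len(self.fragments)
        ):
            raise UsageError("matrix dimensions and metadata lengths disagree")
        prev: GenomicSegment | None = None
        for frag in self.fragments:
            if prev is not None:
                key = (chromosome_sort_key(frag.chromosome), frag.start)
                if key < (chromosome_sort_key(prev.chromosome), prev.start):
                    raise UsageError("fragments must be sorted by (chromosome, start)")
                if prev.chromosome == frag.chromosome and frag.start < prev.end:
                    raise UsageError(f"fragments overlap at {frag.label}")
            prev = frag

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.values.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        return sorted({f.chromosome for f in self.fragments}, key=chromosome_sort_key)

    def chromosome_breaks(self) -> tuple[int, ...]:
        breaks = []
        for i in range(1, len(self.fragments)):
            if self.fragments[i].chromosome != self.fragments[i - 1].chromosome:
                breaks.append(i)
        return tuple(breaks)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise UsageError(f"unknown sample {sample_id!r}") from None

    def cn_vector(self, sample_id: str) -> CNVector:
        return cn_vector(self.values[self.sample_index(sample_id)], self.chromosome_breaks())

    def fragment_lengths(self) -> np.ndarray:
        return np.array([len(f) for f in self.fragments], dtype=np.int64)

    def subset_chromosomes(self, chromosomes: Iterable[str]) -> "FragmentedMatrix":
        keep = set(chromosomes)
        idx = [i for i, f in enumerate(self.fragments) if f.chromosome in keep]
        if not idx:
            raise UsageError("no fragments on the requested chromosomes")
        return FragmentedMatrix(
            [self.fragments[i] for i in idx],
            self.values[:, idx],
            list(self.sample_ids),
            list(self.patient_ids),
            list(self.categories),
            self.ploidies.copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FragmentedMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return FragmentedMatrix(
            list(self.fragments),
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            [self.patient_ids[i] for i in idx],
            [self.categories[i] for i in idx],
            self.ploidies[idx],
        )

    def to_frame(self, values: np.ndarray | None = None) -> pd.DataFrame:
        vals = self.values if values is None else values
        return pd.DataFrame(
            vals, index=self.sample_ids, columns=[f.label for f in self.fragments]
        )

    def write_tsv(self, path: str | Path, values: np.ndarray | None = None,
                  header_comment: str | None = None) -> None:
        df = self.to_frame(values)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# SEG-like TSV reading / writing
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("sample", "chromosome", "start", "end", "total_cn")


def read_profiles(path: str | Path, format: str = "seg_tsv") -> list[CNProfile]:
    """Read one :class:`CNProfile` per distinct sample from a SEG-like TSV.

    On-disk coordinates are 1-based inclusive and converted to 0-based
    half-open.  Sex-chromosome rows are dropped (count logged).
    """
    if format != "seg_tsv":
        raise UsageError(f"unknown format {format!r}")
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str, "sample": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["chromosome"] = df["chromosome"].str.removeprefix("chr")
    sex = df["chromosome"].isin(SEX_CHROMOSOMES)
    if sex.any():
        logger.warning("%s: dropped %d sex-chromosome rows", path.name, int(sex.sum()))
        df = df[~sex]
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        segments = [
            (GenomicSegment(r.chromosome, int(r.start) - 1, int(r.end)), int(r.total_cn))
            for r in grp.itertuples()
        ]
        first = grp.iloc[0]
        profiles.append(
            CNProfile(
                sample_id=str(sample),
                segments=segments,
                patient_id=str(first["patient"]) if "patient" in grp else "",
                category=str(first["category"]) if "category" in grp else "",
                ploidy=float(first["ploidy"]) if "ploidy" in grp else float("nan"),
                purity=float(first["purity"]) if "purity" in grp else float("nan"),
            )
        )
    return profiles


def write_profiles(profiles: Sequence[CNProfile], path: str | Path) -> None:
    """Write profiles back to the SEG-like TSV (1-based inclusive on disk)."""
    rows = []
    for p in profiles:
        for seg, cn in p.segments:
            rows.append(
                {
                    "sample": p.sample_id,
                    "chromosome": seg.chromosome,
                    "start": seg.start + 1,
                    "end": seg.end,
                    "total_cn": cn,
                    "ploidy": p.ploidy,
                    "purity": p.purity,
                    "patient": p.patient_id,
                    "category": p.category,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Breakpoint harmonisation
# ---------------------------------------------------------------------------

def unify_breakpoints(profiles: Sequence[CNProfile]) -> FragmentedMatrix:
    """Union all samples' breakpoints into common fragments.

    Regions a sample does not cover (interior gaps in toy input, or a whole
    missing chromosome) are filled with that sample's ploidy rounded to the
    nearest integer — the sample's neutral state — and logged.
    """
    if not profiles:
        raise UsageError("unify_breakpoints requires at least one profile")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise UsageError("duplicate sample ids in input profiles")

    chroms = sorted({c for p in profiles for c in p.chromosomes}, key=chromosome_sort_key)
    fragments: list[GenomicSegment] = []
    per_chrom_bounds: dict[str, np.ndarray] = {}
    for chrom in chroms:
        points: set[int] = set()
        for p in profiles:
            for seg, _ in p.segments:
                if seg.chromosome == chrom:
                    points.add(seg.start)
                    points.add(seg.end)
        bounds = np.array(sorted(points), dtype=np.int64)
        per_chrom_bounds[chrom] = bounds
        fragments.extend(
            GenomicSegment(chrom, int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])
        )

    values = np.zeros((len(profiles), len(fragments)), dtype=np.int64)
    frag_offset: dict[str, int] = {}
    off = 0
    for chrom in chroms:
        frag_offset[chrom] = off
        off += len(per_chrom_bounds[chrom]) - 1

    for si, p in enumerate(profiles):
        fill = 2 if np.isnan(p.ploidy) else int(round(p.ploidy))
        n_filled = 0
        for chrom in chroms:
            bounds = per_chrom_bounds[chrom]
            n_frag = len(bounds) - 1
            row = np.full(n_frag, -1, dtype=np.int64)
            for seg, cn in p.segments:
                if seg.chromosome != chrom:
                    continue
                lo = int(np.searchsorted(bounds, seg.start))
                hi = int(np.searchsorted(bounds, seg.end))
                row[lo:hi] = cn
            gap = row < 0
            if gap.any():
                n_filled += int(gap.sum())
                row[gap] = fill
            values[si, frag_offset[chrom] : frag_offset[chrom] + n_frag] = row
        if n_filled:
            logger.warning(
                "sample %s: filled %d uncovered fragments with rounded ploidy %d",
                p.sample_id, n_filled, fill,
            )

    return FragmentedMatrix(
        fragments,
        values,
        ids,
        [p.patient_id for p in profiles],
        [p.category for p in profiles],
        np.array([p.ploidy for p in profiles], dtype=float),
    )


def filter_fragments(
    matrix: FragmentedMatrix, min_len: int = DEFAULT_MIN_FRAGMENT_LEN
) -> FragmentedMatrix:
    """Keep only fragments strictly longer than ``min_len`` base pairs."""
    idx = [i for i, f in enumerate(matrix.fragments) if len(f) > min_len]
    if not idx:
        raise EmptyResultError(
            f"no fragment longer than {min_len} bp; use a smaller min_len"
        )
    return FragmentedMatrix(
        [matrix.fragments[i] for i in idx],
        matrix.values[:, idx],
        list(matrix.sample_ids),
        list(matrix.patient_ids),
        list(matrix.categories),
        matrix.ploidies.copy(),
    )


def ploidy_adjust(matrix: FragmentedMatrix) -> np.ndarray:
    """Subtract each sample's ploidy: 0 = no change vs that genome's baseline."""
    if np.isnan(matrix.ploidies).any():
        bad = [s for s, p in zip(matrix.sample_ids, matrix.ploidies) if np.isnan(p)]
        raise UsageError(f"missing ploidy for samples: {bad}")
    return matrix.values.astype(float) - matrix.ploidies[:, None]


def matrix_to_profiles(matrix: FragmentedMatrix) -> list[CNProfile]:
    """Per-sample segments recovered by merging equal-CN adjacent fragments."""
    profiles = []
    for si, sample in enumerate(matrix.sample_ids):
        segments: list[tuple[GenomicSegment, int]] = []
        for fi, frag in enumerate(matrix.fragments):
            cn = int(matrix.values[si, fi])
            if (
                segments
                and segments[-1][0].chromosome == frag.chromosome
                and segments[-1][0].end == frag.start
                and segments[-1][1] == cn
            ):
                prev_seg, _ = segments[-1]
                segments[-1] = (replace(prev_seg, end=frag.end), cn)
            else:
                segments.append((frag, cn))
        profiles.append(
            CNProfile(
                sample_id=sample,
                segments=segments,
                patient_id=matrix.patient_ids[si],
                category=matrix.categories[si],
                ploidy=float(matrix.ploidies[si]),
            )
        )
    return profiles
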