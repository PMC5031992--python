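"""Clonal-evolution simulator for copy-number phylogeny analyses.

Generates, per patient, a rooted clone tree whose histo-pathological
categories follow the lineage constraints under study (lymph-node clones
descend from extraprostatic clones; bone clones descend from central or
extraprostatic clones), applies segmental +/-1 copy-number events along each
edge, and emits the sampled leaf profiles as SEG-style data plus MLPA-like
probe intensities with a probe-length slope artefact.

Event model (matches the strict minimum-event distance): each event covers a
contiguous run of at most ``max_event_run`` fragments on one chromosome and
adds +1 or -1 to every covered fragment; events never cover a fragment whose
current copy number is 0, so copies lost to 0 are never regained.  Events on
one edge are placed on distinct chromosomes, which makes the strict directed
event distance from parent to child equal the number of events applied — the
central oracle linking simulator and distance.

Defaults emulate the study conditions: 6 patients with 5-9 sampled clones
each, diploid genomes with roughly a fifth of samples whole-genome doubled,
and fragment lengths of 0.6-10 Mb so every fragment passes the >500 kb
filter.  A positive ``noise_sd`` additionally jitters observed segment
boundaries by up to 10 kb, exercising breakpoint harmonisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .io_segments import AUTOSOMES, CNProfile, GenomicSegment
from .mlpa_validation import MLPAProbe
from .transition_analysis import TRANSITIONS, TransitionProfile

SCENARIOS = ("lymph_from_epe", "bone_from_central", "bone_from_epe")

#: Clone categories along each scenario's ancestor chain, root excluded.
_SCENARIO_CHAIN = {
    "lymph_from_epe": ("central", "extraprostatic", "lymph_node"),
    "bone_from_central": ("central", "bone"),
    "bone_from_epe": ("central", "extraprostatic", "bone"),
}

_CATEGORY_PREFIX = {
    "central": "C", "extraprostatic": "E", "lymph_node": "L", "bone": "B",
}

_JITTER_BP = 10_000


@dataclass
class SimConfig:
    n_patients: int = 6
    clones_per_patient: int = 7
    n_fragments_per_chromosome: int = 10
    event_rate_per_edge: float = 3.0
    max_event_run: int = 4
    triploid_fraction: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0
    #: place every event on a run disjoint (with a one-fragment margin) from
    #: all other events in the patient, so each edge's signal is private and
    #: pairwise distances stay additive on the clone tree; set False to allow
    #: recurrent/overlapping events (homoplasy).
    private_events: bool = True

    def __post_init__(self) -> None:
        if min(self.n_patients, self.clones_per_patient,
               self.n_fragments_per_chromosome, self.max_event_run) <= 0:
            raise UsageError("all simulator counts must be positive")
        if self.event_rate_per_edge <= 0:
            raise UsageError("event_rate_per_edge must be positive (>=1 event per edge)")
        if not 0 <= self.triploid_fraction <= 1:
            raise UsageError("triploid_fraction must lie in [0, 1]")


@dataclass
class SimClone:
    clone_id: str
    parent_id: str | None
    category: str
    true_profile: np.ndarray = field(repr=False)
    sampled: bool = False
    n_events_from_parent: int = 0


# ---------------------------------------------------------------------------
# Genome and events
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> list[GenomicSegment]:
    """Fixed fragment grid over 22 autosomes, shared by the whole cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    fragments = []
    for chrom in AUTOSOMES:
        lengths = rng.integers(600_000, 10_000_000, size=config.n_fragments_per_chromosome)
        pos = 0
        for length in lengths:
            fragments.append(GenomicSegment(chrom, pos, pos + int(length)))
            pos += int(length)
    return fragments


def _chromosome_spans(fragments: list[GenomicSegment]) -> dict[str, tuple[int, int]]:
    spans: dict[str, list[int]] = {}
    for i, f in enumerate(fragments):
        if f.chromosome not in spans:
            spans[f.chromosome] = [i, i]
        spans[f.chromosome][1] = i
    return {c: (a, b) for c, (a, b) in spans.items()}


def _apply_edge_events(
    profile: np.ndarray,
    n_events: int,
    spans: dict[str, tuple[int, int]],
    max_run: int,
    rng: np.random.Generator,
    used: set[int] | None = None,
) -> tuple[np.ndarray, int]:
    """Apply up to ``n_events`` strict-model events on distinct chromosomes.

    When ``used`` is given, runs must avoid (with a one-fragment margin) all
    fragments already hit by earlier events in this patient, keeping every
    event private to its edge.  Returns (child profile, events placed).
    """
    child = profile.copy()
    chroms = list(spans)
    if n_events > len(chroms):
        n_events = len(chroms)
    order = rng.permutation(len(chroms))
    placed = 0
    for ci in order:
        if placed == n_events:
            break
        lo, hi = spans[chroms[ci]]
        for _ in range(200):  # rejection: avoid CN-0 fragments (and used runs)
            run_len = int(rng.integers(1, max_run + 1))
            start = int(rng.integers(lo, hi + 1))
            stop = min(start + run_len, hi + 1)
            touched = range(max(lo, start - 1), min(hi + 1, stop + 1))
            if used is not None and any(i in used for i in touched):
                continue
            if np.all(child[start:stop] > 0):
                sign = 1 if rng.random() < 0.5 else -1
                child[start:stop] += sign
                if used is not None:
                    used.update(touched)
                placed += 1
                break
    if placed == 0:
        raise UsageError("could not place any event (genome saturated)")
    return child, placed


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------

def _leaf_allocation(m: int, n_categories: int) -> list[int]:
    counts = [1] * n_categories
    for k in range(m - n_categories):
        counts[k % n_categories] += 1
    return counts


def simulate_patient(
    config: SimConfig, scenario: str, patient_index: int = 0
) -> tuple[list[SimClone], list[CNProfile]]:
    """One patient's clone tree and observed sample profiles.

    The clone tree is an ancestor chain following the scenario's category
    order, with sampled leaf clones hanging off each ancestor; every edge
    carries at least one event.
    """
    if scenario not in SCENARIOS:
        raise UsageError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    chain = _SCENARIO_CHAIN[scenario]
    m = config.clones_per_patient
    if m < len(chain) + 1:
        raise UsageError(
            f"scenario {scenario} needs at least {len(chain) + 1} clones, got {m}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, patient_index]))
    fragments = simulate_genome(config)
    spans = _chromosome_spans(fragments)
    patient_id = f"P{patient_index + 1}"

    def n_events() -> int:
        return max(1, int(rng.poisson(config.event_rate_per_edge)))

    used: set[int] | None = set() if config.private_events else None
    clones: list[SimClone] = []
    root = SimClone(f"{patient_id}_root", None, "benign",
                    np.full(len(fragments), 2, dtype=np.int64))
    clones.append(root)

    ancestors: dict[str, SimClone] = {}
    parent = root
    for category in chain:
        profile, placed = _apply_edge_events(
            parent.true_profile, n_events(), spans, config.max_event_run, rng, used
        )
        anc = SimClone(
            f"{patient_id}_anc_{_CATEGORY_PREFIX[category]}",
            parent.clone_id, category, profile, n_events_from_parent=placed,
        )
        ancestors[category] = anc
        clones.append(anc)
        parent = anc

    counts = _leaf_allocation(m, len(chain))
    leaves: list[SimClone] = []
    for category, count in zip(chain, counts):
        anc = ancestors[category]
        for i in range(count):
            profile, placed = _apply_edge_events(
                anc.true_profile, n_events(), spans, config.max_event_run, rng, used
            )
            leaf = SimClone(
                f"{patient_id}_{_CATEGORY_PREFIX[category]}{i + 1}",
                anc.clone_id, category, profile,
                sampled=True, n_events_from_parent=placed,
            )
            leaves.append(leaf)
            clones.append(leaf)

    profiles = [
        _observe(leaf, fragments, config, rng, patient_id) for leaf in leaves
    ]
    return clones, profiles


def _observe(
    leaf: SimClone,
    fragments: list[GenomicSegment],
    config: SimConfig,
    rng: np.random.Generator,
    patient_id: str,
) -> CNProfile:
    values = leaf.true_profile.copy()
    doubled = rng.random() < config.triploid_fraction
    if doubled:
        values = values * 2

    # Observed segmentation: merge equal-CN runs, then jitter interior
    # breakpoints (only when noise is on), as array segmentation would.
    segments: list[tuple[GenomicSegment, int]] = []
    jitter = _JITTER_BP if config.noise_sd > 0 else 0
    i = 0
    while i < len(fragments):
        chrom = fragments[i].chromosome
        j = i
        while (
            j + 1 < len(fragments)
            and fragments[j + 1].chromosome == chrom
            and values[j + 1] == values[i]
        ):
            j += 1
        start, end = fragments[i].start, fragments[j].end
        segments.append((GenomicSegment(chrom, start, end), int(values[i])))
        i = j + 1
    if jitter:
        moved: list[tuple[GenomicSegment, int]] = []
        for k, (seg, cn) in enumerate(segments):
            start, end = seg.start, seg.end
            prev = segments[k - 1][0] if k > 0 else None
            if prev is not None and prev.chromosome == seg.chromosome:
                start = moved[-1][0].end
            nxt = segments[k + 1][0] if k + 1 < len(segments) else None
            if nxt is not None and nxt.chromosome == seg.chromosome:
                end = end + int(rng.integers(-jitter, jitter + 1))
            moved.append((GenomicSegment(seg.chromosome, start, end), cn))
        segments = moved

    lengths = np.array([len(s) for s, _ in segments], dtype=float)
    cns = np.array([c for _, c in segments], dtype=float)
    ploidy = float(np.average(cns, weights=lengths))
    return CNProfile(
        sample_id=leaf.clone_id,
        segments=segments,
        patient_id=patient_id,
        category=leaf.category,
        ploidy=ploidy,
        purity=float(rng.uniform(0.5, 0.95)),
    )


def simulate_cohort(
    config: SimConfig, scenarios: list[str] | None = None
) -> tuple[dict[str, list[SimClone]], dict[str, list[CNProfile]]]:
    """Whole-cohort simulation; scenario pattern mirrors the study design
    (three lymph-node patients, two bone-from-central, one bone-from-EPE)."""
    if scenarios is None:
        pattern = ["lymph_from_epe"] * 3 + ["bone_from_central"] * 2 + ["bone_from_epe"]
        scenarios = [pattern[i % len(pattern)] for i in range(config.n_patients)]
    if len(scenarios) != config.n_patients:
        raise UsageError("scenarios list must match n_patients")
    size_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**21]))
    clones_by_patient: dict[str, list[SimClone]] = {}
    profiles_by_patient: dict[str, list[CNProfile]] = {}
    for idx, scenario in enumerate(scenarios):
        lo = max(len(_SCENARIO_CHAIN[scenario]) + 1, config.clones_per_patient - 2)
        hi = config.clones_per_patient + 2
        m = int(size_rng.integers(lo, hi + 1))
        patient_config = SimConfig(**{**config.__dict__, "clones_per_patient": m})
        clones, profiles = simulate_patient(patient_config, scenario, idx)
        patient_id = f"P{idx + 1}"
        clones_by_patient[patient_id] = clones
        profiles_by_patient[patient_id] = profiles
    return clones_by_patient, profiles_by_patient


# ---------------------------------------------------------------------------
# Truth helpers (used as oracles in tests)
# ---------------------------------------------------------------------------

def true_clades(clones: list[SimClone]) -> set[frozenset[str]]:
    """Sampled-leaf sets under each true ancestor (non-trivial ones only)."""
    children: dict[str, list[str]] = {}
    by_id = {c.clone_id: c for c in clones}
    for c in clones:
        if c.parent_id is not None:
            children.setdefault(c.parent_id, []).append(c.clone_id)

    def sampled_under(cid: str) -> frozenset[str]:
        acc = set()
        stack = [cid]
        while stack:
            cur = stack.pop()
            if by_id[cur].sampled:
                acc.add(cur)
            stack.extend(children.get(cur, []))
        return frozenset(acc)

    all_sampled = sampled_under(next(c.clone_id for c in clones if c.parent_id is None))
    out = set()
    for c in clones:
        if c.clone_id in children:  # internal
            clade = sampled_under(c.clone_id)
            if 1 < len(clade) < len(all_sampled):
                out.add(clade)
    return out


def project_profile(
    values: np.ndarray,
    genome_fragments: list[GenomicSegment],
    target_fragments: list[GenomicSegment],
) -> np.ndarray:
    """A truth profile, re-expressed on a coarser harmonised fragment grid
    (each target fragment's value is the covering genome fragment's CN at
    its midpoint)."""
    out = np.empty(len(target_fragments), dtype=np.int64)
    for i, frag in enumerate(target_fragments):
        pos = (frag.start + frag.end) // 2
        for gf, v in zip(genome_fragments, values):
            if gf.chromosome == frag.chromosome and gf.start <= pos < gf.end:
                out[i] = v
                break
        else:
            raise UsageError(f"fragment {frag.label} outside the simulated genome")
    return out


def true_tree_newick(clones: list[SimClone]) -> str:
    children: dict[str, list[str]] = {}
    root = None
    for c in clones:
        if c.parent_id is None:
            root = c.clone_id
        else:
            children.setdefault(c.parent_id, []).append(c.clone_id)

    def fmt(cid: str) -> str:
        kids = children.get(cid, [])
        return f"({','.join(fmt(k) for k in kids)}){cid}" if kids else cid

    assert root is not None
    return fmt(root) + ";"


def write_truth(clones: list[SimClone], fragments: list[GenomicSegment],
                newick_path, profiles_path) -> None:
    with open(newick_path, "w") as fh:
        fh.write(true_tree_newick(clones) + "\n")
    df = pd.DataFrame(
        {c.clone_id: c.true_profile for c in clones}, index=[f.label for f in fragments]
    ).T
    df.to_csv(profiles_path, sep="\t", index_label="clone")


def category_paths_valid(clones: list[SimClone]) -> bool:
    """Check the lineage constraints: lymph under EPE, bone under central/EPE,
    and the benign -> central -> ... ordering along every root-to-leaf path."""
    order = {"benign": 0, "central": 1, "extraprostatic": 2, "lymph_node": 3, "bone": 3}
    by_id = {c.clone_id: c for c in clones}
    for c in clones:
        path = []
        cur: SimClone | None = c
        while cur is not None:
            path.append(cur.category)
            cur = by_id.get(cur.parent_id) if cur.parent_id else None
        path = path[::-1]  # root first
        ranks = [order[cat] for cat in path]
        if ranks != sorted(ranks):
            return False
        if c.category == "lymph_node" and "extraprostatic" not in path[:-1]:
            return False
        if c.category == "bone" and "central" not in path[:-1]:
            return False
    return True


# ---------------------------------------------------------------------------
# MLPA intensities
# ---------------------------------------------------------------------------

def simulate_mlpa(
    profiles: list[CNProfile],
    n_probes: int = 58,
    slope: float = 0.002,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_controls: int = 1,
    n_genes: int = 39,
) -> tuple[pd.DataFrame, list[MLPAProbe], list[str]]:
    """Probe intensity table for the given samples plus benign control(s).

    intensity = base_signal * (cn / 2) * (1 + slope * probe_length)
                * (1 + Normal(0, noise_sd))

    with a per-probe base signal, so the raw tumour/control ratio is exactly
    cn/2 in the absence of noise (the length term cancels).
    """
    if n_controls < 1:
        raise UsageError("at least one benign control sample is required")
    if not profiles:
        raise UsageError("no profiles given")
    rng = np.random.default_rng(seed)

    template = profiles[0]
    controls: list[CNProfile] = [p for p in profiles if p.category == "benign"]
    extra = []
    for i in range(max(0, n_controls - len(controls))):
        ctrl_segments = []
        for chrom in template.chromosomes:
            segs = [s for s, _ in template.segments if s.chromosome == chrom]
            ctrl_segments.append(
                (GenomicSegment(chrom, segs[0].start, segs[-1].end), 2)
            )
        ctrl = CNProfile(
            sample_id=f"{template.patient_id or 'sim'}_ctrl{i + 1}",
            segments=ctrl_segments,
            patient_id=template.patient_id,
            category="benign",
            ploidy=2.0,
        )
        controls.append(ctrl)
        extra.append(ctrl)
    all_profiles = list(profiles) + extra

    # One genomic fragment per gene; a gene's probes share its fragment.
    # Like a cancer CNA panel, most genes sit on regions that are aberrant in
    # at least one sample; the rest are spread at random.
    gene_of_probe = [(i * n_genes) // n_probes for i in range(n_probes)]
    all_fragments = [s for s, _ in template.segments]
    aberrant = []
    for p in profiles:
        baseline = 2 if np.isnan(p.ploidy) else int(round(p.ploidy))
        for seg, cn in p.segments:
            if cn != baseline:
                aberrant.append(seg)
    aberrant = sorted(set(aberrant), key=lambda s: (int(s.chromosome), s.start))
    gene_fragments = {}
    for g in range(n_genes):
        pool = aberrant if (aberrant and rng.random() < 0.7) else all_fragments
        gene_fragments[g] = pool[int(rng.integers(0, len(pool)))]

    probes = []
    for i in range(n_probes):
        g = gene_of_probe[i]
        frag = gene_fragments[g]
        probes.append(
            MLPAProbe(
                probe_id=f"probe{i + 1:03d}",
                gene=f"GENE{g + 1:02d}",
                probe_length=int(rng.integers(70, 501)),
                fragment=frag,
            )
        )
    base_signal = rng.uniform(0.8, 1.2, size=n_probes)

    def cn_at(profile: CNProfile, frag: GenomicSegment) -> int:
        pos = (frag.start + frag.end) // 2
        for seg, cn in profile.segments:
            if seg.chromosome == frag.chromosome and seg.start <= pos < seg.end:
                return cn
        return 2  # uncovered -> neutral

    rows = []
    for p in all_profiles:
        for i, probe in enumerate(probes):
            cn = cn_at(p, probe.fragment)
            noise = 1.0 + rng.normal(0.0, noise_sd) if noise_sd > 0 else 1.0
            intensity = (
                base_signal[i] * (cn / 2.0)
                * (1.0 + slope * probe.probe_length) * noise
            )
            rows.append(
                {"sample": p.sample_id, "probe_id": probe.probe_id,
                 "gene": probe.gene, "probe_length": probe.probe_length,
                 "intensity": intensity}
            )
    table = pd.DataFrame(rows)
    return table, probes, [c.sample_id for c in controls]


# ---------------------------------------------------------------------------
# Null / planted transition profiles (for test calibration)
# ---------------------------------------------------------------------------

def simulate_transition_null(
    n_patients: int = 6,
    n_fragments: int = 40,
    noise_sd: float = 0.5,
    seed: int = 0,
    planted_fragment: int | None = None,
    planted_effect: float = -2.0,
    planted_transition: str = "extraprostatic_to_lymph",
) -> list[TransitionProfile]:
    """Transition profiles with no category effect, optionally with one
    planted transition-specific shift on a single fragment.

    Patients alternate the study's two designs (lymph-node vs bone), giving
    unbalanced but realistic group sizes across the four transitions.
    """
    rng = np.random.default_rng(seed)
    per_chrom = max(1, n_fragments // 22)
    fragments = [
        GenomicSegment(AUTOSOMES[min(i // per_chrom, 21)],
                       (i % per_chrom) * 1_000_000, (i % per_chrom + 1) * 1_000_000)
        for i in range(n_fragments)
    ]
    lymph_design = (TRANSITIONS[0], TRANSITIONS[1], TRANSITIONS[2])
    bone_design = (TRANSITIONS[0], TRANSITIONS[1], TRANSITIONS[3])
    out = []
    for p in range(n_patients):
        design = lymph_design if p % 2 == 0 else bone_design
        for transition in design:
            values = rng.normal(0.0, noise_sd, size=n_fragments)
            if planted_fragment is not None and transition == planted_transition:
                values[planted_fragment] += planted_effect
            out.append(
                TransitionProfile(f"P{p + 1}", transition, values, fragments)
            )
    return out
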