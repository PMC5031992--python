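"""Simulator contracts: determinism, lineage constraints, event-distance link."""

import numpy as np
import pytest

from cnaphylo.errors import UsageError
from cnaphylo.med_distance import cn_vector, directed_event_count
from cnaphylo.synthetic_data import (
    SimConfig,
    category_paths_valid,
    simulate_cohort,
    simulate_genome,
    simulate_mlpa,
    simulate_patient,
)


def test_fixed_seed_is_deterministic():
    config = SimConfig(seed=3, noise_sd=0.1)
    c1, p1 = simulate_patient(config, "lymph_from_epe", 0)
    c2, p2 = simulate_patient(config, "lymph_from_epe", 0)
    for a, b in zip(c1, c2):
        assert a.clone_id == b.clone_id and np.array_equal(a.true_profile, b.true_profile)
    assert [p.segments for p in p1] == [p.segments for p in p2]


def test_patients_are_independent_streams():
    config = SimConfig(seed=3)
    _, pa = simulate_patient(config, "lymph_from_epe", 0)
    _, pb = simulate_patient(config, "lymph_from_epe", 1)
    assert [p.segments for p in pa] != [p.segments for p in pb]


def test_invalid_configs_rejected():
    with pytest.raises(UsageError):
        SimConfig(event_rate_per_edge=0.0)  # would allow 0-event edges
    with pytest.raises(UsageError):
        SimConfig(clones_per_patient=0)
    with pytest.raises(UsageError):
        simulate_patient(SimConfig(clones_per_patient=3), "lymph_from_epe", 0)


def test_genome_fragments_pass_length_filter():
    genome = simulate_genome(SimConfig(seed=0))
    assert len(genome) == 22 * 10
    assert all(600_000 <= len(f) <= 10_000_000 for f in genome)


@pytest.mark.parametrize("scenario", ["lymph_from_epe", "bone_from_central", "bone_from_epe"])
def test_category_constraints_hold_across_seeds(scenario):
    for seed in range(100):
        config = SimConfig(seed=seed, clones_per_patient=5)
        clones, _ = simulate_patient(config, scenario, 0)
        assert category_paths_valid(clones)
        cats = {c.category for c in clones if c.sampled}
        if scenario == "lymph_from_epe":
            assert "lymph_node" in cats and "extraprostatic" in cats
        else:
            assert "bone" in cats


def test_edge_event_counts_equal_strict_distance():
    """The central oracle linking simulator and distance."""
    for seed in range(25):
        config = SimConfig(seed=seed)
        clones, _ = simulate_patient(config, "bone_from_epe", 0)
        breaks = tuple(range(10, 220, 10))
        by_id = {c.clone_id: c for c in clones}
        for c in clones:
            if c.parent_id is None:
                continue
            parent = by_id[c.parent_id]
            d = directed_event_count(
                cn_vector(parent.true_profile, breaks),
                cn_vector(c.true_profile, breaks),
            )
            assert d == c.n_events_from_parent
            assert c.n_events_from_parent >= 1


def test_root_is_diploid_and_floors_at_zero():
    for seed in range(10):
        clones, _ = simulate_patient(SimConfig(seed=seed), "lymph_from_epe", 0)
        root = next(c for c in clones if c.parent_id is None)
        assert np.all(root.true_profile == 2)
        for c in clones:
            assert c.true_profile.min() >= 0


def test_whole_genome_doubling_fraction():
    config = SimConfig(seed=1, triploid_fraction=1.0)
    _, profiles = simulate_patient(config, "lymph_from_epe", 0)
    assert all(p.ploidy > 3.0 for p in profiles)
    config0 = SimConfig(seed=1, triploid_fraction=0.0)
    _, profiles0 = simulate_patient(config0, "lymph_from_epe", 0)
    assert all(p.ploidy < 3.0 for p in profiles0)


def test_cohort_sizes_and_scenarios():
    clones_by_p, profiles_by_p = simulate_cohort(SimConfig(seed=0))
    assert len(profiles_by_p) == 6
    for pid, profiles in profiles_by_p.items():
        assert 5 <= len(profiles) <= 9
        assert len({p.sample_id for p in profiles}) == len(profiles)


class TestSimulateMlpa:
    def test_noiseless_raw_ratio_is_cn_over_two(self):
        _, profiles = simulate_patient(SimConfig(seed=2, triploid_fraction=0.0),
                                       "lymph_from_epe", 0)
        table, probes, controls = simulate_mlpa(profiles, slope=0.0, noise_sd=0.0, seed=4)
        piv = table.pivot_table(index="sample", columns="probe_id", values="intensity")
        ctrl = piv.loc[controls[0]]
        for p in profiles:
            ratios = piv.loc[p.sample_id] / ctrl
            assert np.allclose(ratios * 2, np.round(ratios * 2))

    def test_slope_cancels_in_raw_ratio_but_correlates_with_length(self):
        _, profiles = simulate_patient(SimConfig(seed=2, triploid_fraction=0.0),
                                       "lymph_from_epe", 0)
        t0, probes, controls = simulate_mlpa(profiles, slope=0.0, noise_sd=0.0, seed=4)
        t1, _, _ = simulate_mlpa(profiles, slope=0.003, noise_sd=0.0, seed=4)
        p0 = t0.pivot_table(index="sample", columns="probe_id", values="intensity")
        p1 = t1.pivot_table(index="sample", columns="probe_id", values="intensity")
        r0 = (p0 / p0.loc[controls[0]]).drop(index=controls[0])
        r1 = (p1 / p1.loc[controls[0]]).drop(index=controls[0])
        assert np.allclose(r0.to_numpy(), r1.to_numpy())
        lengths = t1.drop_duplicates("probe_id").set_index("probe_id")["probe_length"]
        ctrl_int = p1.loc[controls[0], lengths.index]
        assert np.corrcoef(lengths, ctrl_int)[0, 1] > 0.5

    def test_fixed_seed_identical_table(self):
        _, profiles = simulate_patient(SimConfig(seed=2), "lymph_from_epe", 0)
        t1, _, _ = simulate_mlpa(profiles, seed=9, noise_sd=0.1)
        t2, _, _ = simulate_mlpa(profiles, seed=9, noise_sd=0.1)
        assert t1.equals(t2)

    def test_control_always_present_and_required(self):
        _, profiles = simulate_patient(SimConfig(seed=2), "lymph_from_epe", 0)
        table, _, controls = simulate_mlpa(profiles, seed=1)
        assert controls and set(controls) <= set(table["sample"])
        with pytest.raises(UsageError):
            simulate_mlpa(profiles, n_controls=0, seed=1)

    def test_probe_lengths_in_stated_range(self):
        _, profiles = simulate_patient(SimConfig(seed=2), "lymph_from_epe", 0)
        _, probes, _ = simulate_mlpa(profiles, seed=1)
        assert all(70 <= p.probe_length <= 500 for p in probes)
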