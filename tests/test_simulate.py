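from collections import Counter

import numpy as np
import pytest

from r2ribozyme import (
    RibozymeDescriptor,
    SimConfig,
    build_target_ref,
    fold_search,
    reconstruct_read,
    simulate_heteroduplex,
    simulate_microhomology,
    simulate_p1_shift,
    validate_fold,
)
from r2ribozyme.simulate import PlantConfig, generate_ribozyme


def test_zero_reads_gives_empty_outputs(ref28s, element):
    for fn, k in ((simulate_heteroduplex, -28), (simulate_microhomology, 0)):
        res = fn(SimConfig(model="heteroduplex" if k else "microhomology",
                           cleavage_offset=k, n_reads=0, seed=1))
        assert res.reads == [] and res.truth == []


def test_heteroduplex_without_dup_path_is_all_precise(ref28s, element):
    cfg = SimConfig(model="heteroduplex", cleavage_offset=-28, n_reads=50,
                    dup_path_prob=0.0, seed=5)
    res = simulate_heteroduplex(cfg)
    precise = ref28s.upstream + element.five_prime_seq
    assert all(seq == precise for _, seq in res.reads)
    assert all(t.category == "canonical" for t in res.truth)


def test_heteroduplex_duplications_have_cleavage_offset_length(ref28s, element):
    cfg = SimConfig(model="heteroduplex", cleavage_offset=-13, n_reads=400,
                    dup_path_prob=0.3, substitution_rate=0.02, seed=2)
    res = simulate_heteroduplex(cfg)
    dups = [t for t in res.truth if t.duplication is not None]
    assert dups, "expected some duplication-path reads"
    assert all(t.duplication.length == 13 for t in dups)
    assert all(t.duplication.source == "upstream" for t in dups)


def test_heteroduplex_requires_upstream_cleavage():
    with pytest.raises(ValueError):
        simulate_heteroduplex(SimConfig(model="heteroduplex",
                                        cleavage_offset=0, n_reads=1, seed=0))
    with pytest.raises(ValueError):
        simulate_heteroduplex(SimConfig(model="heteroduplex",
                                        cleavage_offset=-90, n_reads=1, seed=0))


def test_microhomology_requires_boundary_cleavage():
    with pytest.raises(ValueError):
        simulate_microhomology(SimConfig(model="microhomology",
                                         cleavage_offset=-5, n_reads=1, seed=0))


def test_microhomology_produces_variable_junctions(ref28s, element):
    cfg = SimConfig(model="microhomology", cleavage_offset=0, n_reads=100,
                    seed=4)
    res = simulate_microhomology(cfg)
    assert len({t.junction_tuple() for t in res.truth}) > 1


def test_every_emitted_read_satisfies_reconstruction(ref28s, element):
    for model, k in (("heteroduplex", -28), ("microhomology", 0)):
        cfg = SimConfig(model=model, cleavage_offset=k, n_reads=150,
                        dup_path_prob=0.3, substitution_rate=0.05, seed=8)
        res = (simulate_heteroduplex if k else simulate_microhomology)(cfg)
        for (rid, seq), truth in zip(res.reads, res.truth):
            assert reconstruct_read(truth, ref28s, element) == seq


def test_seeded_determinism_byte_identical(ref28s, element):
    cfg = SimConfig(model="microhomology", cleavage_offset=0, n_reads=80,
                    seed=33)
    a = simulate_microhomology(cfg)
    b = simulate_microhomology(cfg)
    assert a.reads == b.reads and a.truth == b.truth


def test_microhomology_deletion_distribution_matches_enumeration(
        flower_ref, element):
    """With no tail, priming sites are enumerable and weights are exact.

    The tiny flank offers two sites (match runs 4 and 3); with
    length-proportional weighting the implied deletions 10 and 4 must
    appear in 4:7 / 3:7 proportion up to binomial noise.
    """
    n = 2000
    cfg = SimConfig(model="microhomology", cleavage_offset=0, n_reads=n,
                    nontemplated_geom_p=1.0, min_microhomology=3, seed=5)
    res = simulate_microhomology(cfg, flower_ref, element)
    counts = Counter(t.deletion_len for t in res.truth)
    assert set(counts) == {10, 4}
    p = 4 / 7
    sd = (p * (1 - p) / n) ** 0.5
    assert abs(counts[10] / n - p) <= 3 * sd
    assert all(t.nontemplated == "" for t in res.truth)


def test_nontemplated_insert_lengths_are_geometric(ref28s, element):
    cfg = SimConfig(model="heteroduplex", cleavage_offset=-13, n_reads=4000,
                    dup_path_prob=0.3, substitution_rate=0.0,
                    nontemplated_geom_p=0.3, seed=17)
    res = simulate_heteroduplex(cfg)
    lens = [len(t.nontemplated) for t in res.truth if t.duplication]
    mean = np.mean(lens)
    exp_mean = 0.7 / 0.3
    sd_mean = np.sqrt(0.7 / 0.3 ** 2 / len(lens))
    assert abs(mean - exp_mean) <= 4 * sd_mean


# --- planted ribozymes -------------------------------------------------------

def test_generate_ribozyme_deterministic():
    a = generate_ribozyme(PlantConfig(seed=1))
    b = generate_ribozyme(PlantConfig(seed=1))
    assert a.sequence == b.sequence and a.truth == b.truth


def test_planted_p1_length_in_default_choices():
    for seed in range(8):
        pr = generate_ribozyme(PlantConfig(seed=seed))
        assert pr.truth.p1_len in (6, 7)


def test_planted_truth_validates_across_offsets(planted_set):
    for pr in planted_set:
        assert validate_fold(pr.truth, RibozymeDescriptor(), pr.ref) == []


def test_planted_recovery_sample():
    for seed in range(25):
        pr = generate_ribozyme(PlantConfig(seed=seed))
        top = fold_search(pr.sequence, pr.ref, max_results=1)[0]
        assert top.segments == pr.truth.segments


def test_plant_rejects_impossible_config():
    with pytest.raises(ValueError):
        generate_ribozyme(PlantConfig(seed=0, cleavage_offset=10))
    with pytest.raises(ValueError):
        generate_ribozyme(PlantConfig(seed=0, gap_len_range=(2, 2)))


# --- duplication-driven cleavage-site shift ----------------------------------

def test_p1_shift_trajectory_preferences():
    states = {s.state: s for s in simulate_p1_shift(dup_len=28, seed=2)}
    assert states["a"].expected_preference == "tie"
    assert states["a"].candidates[0].score == states["a"].candidates[1].score
    assert states["b"].preferred_offset == -28
    assert states["c"].preferred_offset == -28
    assert states["d"].preferred_offset == 0
    assert states["e"].preferred_offset == 0
    # state b: the internal candidate is still foldable, just weaker
    offs = [c.cleavage_offset for c in states["b"].candidates]
    assert 0 in offs
    # state e: any surviving upstream placement is degraded (mismatched
    # and strictly below the internal candidate)
    top_e = states["e"].candidates[0]
    for c in states["e"].candidates:
        if c.cleavage_offset == -28:
            assert c.score < top_e.score and c.mismatch_count >= 1


def test_p1_shift_rejects_short_duplication():
    with pytest.raises(ValueError):
        simulate_p1_shift(dup_len=3, seed=0)
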