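import pytest

from r2ribozyme import (
    ClassifyParams,
    SimConfig,
    classify_junction,
    correlate_cleavage_with_junctions,
    reconstruct_read,
    simulate_heteroduplex,
    simulate_microhomology,
    summarize_junctions,
)


def _read(ref, elem, deletion=0, dup=None, nontemp=""):
    parts = [ref.upstream[: ref.insertion_index - deletion]]
    if dup:
        parts.append(dup)
    parts.append(nontemp)
    parts.append(elem.five_prime_seq)
    return "".join(parts)


def test_canonical_identity_junction(ref28s, element):
    call = classify_junction(_read(ref28s, element), ref28s, element)
    assert call.category == "canonical"
    assert call.deletion_len == 0 and call.duplication is None
    assert call.nontemplated == ""
    assert call.element_start_in_read == ref28s.insertion_index


def test_seven_bp_deletion_is_called(ref28s, element):
    call = classify_junction(_read(ref28s, element, deletion=7), ref28s, element)
    assert call.category == "deletion" and call.deletion_len == 7


def test_upstream_tandem_duplication_with_substitutions(ref28s, element):
    src = ref28s.upstream[-24:]
    copy = src[:5] + ("A" if src[5] != "A" else "G") + src[6:]  # 1 substitution
    call = classify_junction(_read(ref28s, element, dup=copy), ref28s, element)
    assert call.category == "dup_upstream"
    d = call.duplication
    assert (d.length, d.substitutions, d.copy_count) == (24, 1, 2)


def test_downstream_duplication_with_three_substitutions(ref28s, element):
    src = ref28s.downstream[:22]
    copy = list(src)
    for i in (3, 10, 17):
        copy[i] = "A" if copy[i] != "A" else "G"
    call = classify_junction(_read(ref28s, element, dup="".join(copy)),
                             ref28s, element)
    assert call.category == "dup_downstream"
    d = call.duplication
    assert (d.length, d.substitutions) == (22, 3)


def test_mixed_junction_deletion_plus_duplication(ref28s, element):
    P = ref28s.insertion_index - 4
    src = ref28s.upstream[P - 24:P]
    call = classify_junction(_read(ref28s, element, deletion=4, dup=src),
                             ref28s, element)
    assert call.category == "mixed"
    assert call.deletion_len == 4 and call.duplication.length == 24


def test_triple_tandem_repeat_counts_three_copies(ref28s, element):
    src = ref28s.upstream[-13:]
    call = classify_junction(_read(ref28s, element, dup=src * 2), ref28s, element)
    assert call.duplication.copy_count == 3
    assert call.duplication.length == 13


def test_no_element_anchor_is_unclassified(ref28s, element):
    call = classify_junction("A" * 40, ref28s, element)
    assert call.category == "unclassified" and "anchor" in call.note


def test_reconstruction_invariant_on_handmade_junctions(ref28s, element):
    for kwargs in ({}, {"deletion": 3}, {"nontemp": "TTACG"},
                   {"dup": ref28s.upstream[-13:]},
                   {"deletion": 2, "nontemp": "GG"}):
        read = _read(ref28s, element, **kwargs)
        call = classify_junction(read, ref28s, element)
        assert reconstruct_read(call, ref28s, element) == read


def test_classification_equals_simulator_truth_both_models(ref28s, element):
    for model, fn in (("heteroduplex", simulate_heteroduplex),
                      ("microhomology", simulate_microhomology)):
        cfg = SimConfig(model=model,
                        cleavage_offset=-28 if model == "heteroduplex" else 0,
                        n_reads=300, dup_path_prob=0.2,
                        substitution_rate=0.0, seed=21)
        res = fn(cfg)
        for (rid, seq), truth in zip(res.reads, res.truth):
            assert classify_junction(seq, ref28s, element, read_id=rid) == truth


def test_classification_is_deterministic(ref28s, element):
    read = _read(ref28s, element, dup=ref28s.upstream[-13:], nontemp="TT")
    calls = {classify_junction(read, ref28s, element) for _ in range(5)}
    assert len(calls) == 1


# --- summaries and correlation ----------------------------------------------

def test_single_call_summary_is_uniform(ref28s, element):
    call = classify_junction(_read(ref28s, element), ref28s, element)
    s = summarize_junctions([call])
    assert s.modal_junction_fraction == 1.0 and s.is_uniform


def test_nine_of_ten_shared_duplication_gives_modal_fraction_090(ref28s, element):
    src = ref28s.upstream[-21:]
    reads = [_read(ref28s, element, dup=src)] * 9 + [_read(ref28s, element)]
    calls = [classify_junction(r, ref28s, element, read_id=f"r{i}")
             for i, r in enumerate(reads)]
    s = summarize_junctions(calls)
    assert s.modal_junction_fraction == pytest.approx(0.9)
    assert s.is_uniform
    assert s.duplication_length_mode == 21


def test_summary_rejects_empty_input():
    with pytest.raises(ValueError):
        summarize_junctions([])


def test_duplication_fraction_tracks_simulation_probability(ref28s, element):
    n = 3000
    cfg = SimConfig(model="heteroduplex", cleavage_offset=-13, n_reads=n,
                    dup_path_prob=0.05, substitution_rate=0.0, seed=7)
    res = simulate_heteroduplex(cfg)
    calls = [classify_junction(s, ref28s, element, read_id=r)
             for r, s in res.reads]
    dup = sum(1 for c in calls if c.duplication is not None)
    sd = (0.05 * 0.95 / n) ** 0.5
    assert abs(dup / n - 0.05) <= 3 * sd
    assert all(c.duplication.length == 13 for c in calls if c.duplication)


def test_correlation_duplication_length_matches_offset(ref28s, element):
    src = ref28s.upstream[-13:]
    calls = [classify_junction(_read(ref28s, element, dup=src), ref28s,
                               element, read_id=f"r{i}") for i in range(3)]
    calls += [classify_junction(_read(ref28s, element), ref28s, element,
                                read_id=f"c{i}") for i in range(57)]
    rep = correlate_cleavage_with_junctions(summarize_junctions(calls), -13)
    assert rep.duplication_length_equals_offset_magnitude is True
    assert rep.uniformity_matches_model is True


def test_correlation_variable_junctions_fit_boundary_cleavage(ref28s, element):
    cfg = SimConfig(model="microhomology", cleavage_offset=0, n_reads=150,
                    seed=9)
    res = simulate_microhomology(cfg)
    calls = [classify_junction(s, ref28s, element, read_id=r)
             for r, s in res.reads]
    rep = correlate_cleavage_with_junctions(summarize_junctions(calls), 0)
    assert rep.expected_uniform is False
    assert rep.uniformity_matches_model is True
    assert rep.duplication_length_equals_offset_magnitude is None


def test_params_validation():
    with pytest.raises(ValueError):
        ClassifyParams(min_element_anchor=0)
    with pytest.raises(ValueError):
        ClassifyParams(max_substitution_fraction=1.5)
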