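import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from r2ribozyme import (
    FoldError,
    RibozymeDescriptor,
    build_target_ref,
    compare_p1_candidates,
    count_repeats,
    fold_search,
    predict_cleavage,
    predict_cleavage_fragments,
    refold_with_mutation,
    t7_transcript,
    validate_fold,
)
from r2ribozyme.descriptor import FoldScoreConfig
from r2ribozyme.oracle import brute_force_best_fold
from r2ribozyme.simulate import PlantConfig, generate_ribozyme

DESC = RibozymeDescriptor()


def test_planted_fold_is_recovered_exactly(planted):
    folds = fold_search(planted.sequence, planted.ref)
    assert folds, "no fold found on a planted sequence"
    assert folds[0].segments == planted.truth.segments
    assert folds[0].score == planted.truth.score


def test_every_returned_fold_passes_the_validator(planted):
    for fold in fold_search(planted.sequence, planted.ref):
        assert validate_fold(fold, DESC, planted.ref) == []


def test_ranking_is_deterministic_and_sorted(planted):
    folds = fold_search(planted.sequence, planted.ref)
    keys = [f.sort_key() for f in folds]
    assert keys == sorted(keys)
    again = fold_search(planted.sequence, planted.ref)
    assert [f.segments for f in again] == [f.segments for f in folds]


def test_homopolymer_yields_no_fold():
    ref = build_target_ref("A" * 150, 75)
    assert fold_search("A" * 300, ref) == []


def test_too_short_sequence_raises():
    ref = build_target_ref("ACGT" * 5, 10)
    with pytest.raises(FoldError):
        fold_search("ACGT" * 5, ref)


def test_predict_cleavage_matches_planted_offset(planted_set):
    for pr in planted_set:
        top = fold_search(pr.sequence, pr.ref, max_results=1)[0]
        assert predict_cleavage(top, pr.ref) == pr.truth.cleavage_offset


def test_predict_cleavage_rejects_mismatched_reference(planted):
    top = fold_search(planted.sequence, planted.ref, max_results=1)[0]
    other = build_target_ref(planted.sequence, planted.ref.insertion_index - 3)
    with pytest.raises(FoldError):
        predict_cleavage(top, other)


def test_fold_at_element_boundary_has_offset_zero():
    pr = generate_ribozyme(PlantConfig(seed=4, cleavage_offset=0))
    top = fold_search(pr.sequence, pr.ref, max_results=1)[0]
    assert top.cleavage_offset == 0


@pytest.mark.parametrize("target,base", [("catalytic_c", "T"), ("l3_g", "A")])
def test_invariant_knockouts_empty_the_fold_list(planted, target, base):
    """C->U at the catalytic position or G->A in L3 abolish all folds."""
    pos = (planted.truth.catalytic_c if target == "catalytic_c"
           else planted.truth.segments["L3"][1] - 1)
    assert refold_with_mutation(planted.sequence, planted.ref,
                                pos=pos, base=base) == []


def test_knockout_retained_under_penalize_policy(planted):
    """Penalize policy keeps the fold, flagged, instead of rejecting it."""
    cfg = FoldScoreConfig(invariant_policy="penalize")
    pos = planted.truth.catalytic_c
    folds = refold_with_mutation(planted.sequence, planted.ref,
                                 scorecfg=cfg, pos=pos, base="T")
    assert folds and folds[0].invariant_violations


def test_refold_equals_search_on_substituted_sequence(planted):
    pos = planted.truth.segments["J1/2"][0] + 5
    base = "G" if planted.sequence[pos] != "G" else "C"
    mutated = planted.sequence[:pos] + base + planted.sequence[pos + 1:]
    direct = fold_search(mutated, planted.ref)
    via = refold_with_mutation(planted.sequence, planted.ref, pos=pos, base=base)
    assert [f.segments for f in direct] == [f.segments for f in via]


def test_substitution_in_unpaired_j12_keeps_top_fold(planted):
    pos = planted.truth.segments["J1/2"][0] + 7
    folds = refold_with_mutation(planted.sequence, planted.ref, pos=pos,
                                 base="T")
    assert folds[0].segments == planted.truth.segments


def test_refold_argument_validation(planted):
    with pytest.raises(ValueError):
        refold_with_mutation(planted.sequence, planted.ref, pos=-1, base="A")
    with pytest.raises(ValueError):
        refold_with_mutation(planted.sequence, planted.ref, pos=0,
                             base=planted.sequence[0])


def test_search_agrees_with_enumerator_on_a_planted_case():
    desc = RibozymeDescriptor(j1_2_len_range=(15, 60))
    pr = generate_ribozyme(PlantConfig(seed=7))
    top = fold_search(pr.sequence, pr.ref, desc)[0]
    ora = brute_force_best_fold(pr.sequence, pr.ref, desc)
    assert top.segments == ora.segments and top.score == ora.score


def test_compare_p1_candidates_on_perfect_duplication():
    from r2ribozyme.simulate import simulate_p1_shift

    states = {s.state: s for s in simulate_p1_shift(dup_len=28, seed=2)}
    a = states["a"]
    assert a.candidates[0].score == a.candidates[1].score
    assert {a.candidates[0].cleavage_offset,
            a.candidates[1].cleavage_offset} == {-28, 0}
    assert a.preferred_offset == -28  # tie broken toward upstream


def test_compare_p1_candidates_requires_a_fold():
    ref = build_target_ref("A" * 100, 50)
    with pytest.raises(FoldError):
        compare_p1_candidates("A" * 200, ref)


# --- fragment arithmetic -----------------------------------------------------

def test_fragment_lengths():
    assert predict_cleavage_fragments(100, 30) == (30, 70)
    assert predict_cleavage_fragments(10, 0) == (0, 10)


def test_fragment_out_of_range():
    with pytest.raises(ValueError):
        predict_cleavage_fragments(100, 101)


@given(L=st.integers(0, 10_000), c=st.integers(0, 10_000))
@settings(max_examples=100, deadline=None)
def test_fragments_are_nonnegative_and_sum(L, c):
    if c > L:
        return
    up, down = predict_cleavage_fragments(L, c)
    assert up >= 0 and down >= 0 and up + down == L


DONG_PRIMER = ("TAATACGACTCACTATAGGG"
               "TAATAATAATAATAATAATAA"
               "GCTCCCTAAAATCCTACC")


def test_dong_cotranscript_upstream_fragment_has_seven_taa_repeats():
    """Cut at the element 5' end leaves a 7x TAA upstream product."""
    transcript = t7_transcript(DONG_PRIMER)
    cut = transcript.index("GCTCCCTAAAATCCTACC")
    up, down = predict_cleavage_fragments(len(transcript), cut)
    assert up + down == len(transcript)
    assert count_repeats(transcript[:cut], "TAA") == 7


def test_t7_requires_promoter():
    with pytest.raises(ValueError):
        t7_transcript("ACGTACGTACGT")
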