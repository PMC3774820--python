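"""How a target-site duplication can shift the self-cleavage site.

Walks the five states of the duplication/mutation trajectory: a junction
with a perfect tandem duplication offers two equivalent P1 segments (a);
a mutation in the internal copy biases cleavage upstream (b, c); a
compensatory change in P1' flips the preference to the internal copy
(d, e), i.e. cleavage shifts to the element 5' end and the duplication
becomes a 5' extension of the element.
"""

from r2ribozyme import simulate_p1_shift

for st in simulate_p1_shift(dup_len=28, seed=2):
    cands = ", ".join(
        f"(offset {c.cleavage_offset}: P1 {c.p1_length} bp, "
        f"{c.mismatch_count} mm, score {c.score})"
        for c in st.candidates[:2])
    print(f"state ({st.state}) {st.description}")
    print(f"    expected {st.expected_preference:8s} "
          f"preferred offset {st.preferred_offset}")
    print(f"    top candidates: {cands}")
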