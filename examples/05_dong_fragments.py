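"""The co-transcription worked example: fragment lengths from a T7 template.

The Dong element (a ribozyme-bearing relative of R2) cleaves at its own 5'
end.  Its assay template pairs a T7 promoter with seven TAA repeats ahead
of the Dong 5' sequence; cutting the transcript at the element boundary
must therefore leave an upstream product consisting of the G-run plus
exactly seven TAA repeats -- the short product seen on the assay gel.
"""

from r2ribozyme import count_repeats, predict_cleavage_fragments, t7_transcript

PRIMER = ("TAATACGACTCACTATAGGG"        # T7 promoter (+ transcribed G run)
          "TAATAATAATAATAATAATAA"       # 7x TAA
          "GCTCCCTAAAATCCTACC")         # Dong 5' end

transcript = t7_transcript(PRIMER)
cut = transcript.index("GCTCCCTAAAATCCTACC")  # element 5' boundary
up, down = predict_cleavage_fragments(len(transcript), cut)

print(f"transcript ({len(transcript)} nt): {transcript}")
print(f"cut at element boundary: index {cut}")
print(f"upstream fragment  : {transcript[:up]} ({up} nt)")
print(f"downstream fragment: {transcript[up:]} ({down} nt)")
print(f"TAA repeats in upstream fragment: {count_repeats(transcript[:up])}")
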