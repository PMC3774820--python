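"""Fold a junction RNA with a known (planted) ribozyme and predict cleavage.

Generates a sequence containing a descriptor-conformant HDV-like ribozyme
whose P1 stem begins 28 nt upstream of the element boundary, runs the
descriptor search, and prints the predicted cleavage offset, the fold
score and the pseudoknotted dot-bracket structure.
"""

from r2ribozyme import fold_search, predict_cleavage, to_dotbracket
from r2ribozyme.simulate import PlantConfig, generate_ribozyme

planted = generate_ribozyme(PlantConfig(seed=1, cleavage_offset=-28))
folds = fold_search(planted.sequence, planted.ref)
top = folds[0]

print(f"sequence length     : {len(planted.sequence)} nt")
print(f"planted offset      : {planted.truth.cleavage_offset}")
print(f"predicted offset    : {predict_cleavage(top, planted.ref)}")
print(f"fold score          : {top.score}")
print(f"P1 length           : {top.p1_len} bp")
start, end = top.span
print(f"fold span           : [{start}, {end})")
print(planted.sequence[start:end])
print(to_dotbracket(top))
print()
print("A negative offset means the ribozyme cleaves inside the 28S rRNA,")
print("leaving that many 28S nucleotides on the element-containing fragment.")
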