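"""Decompose endogenous-style 5'-junction reads into their parts.

Builds three junction reads against the synthetic 28S reference -- a
canonical junction, a 7-bp 28S deletion, and a 22-bp duplication of
downstream 28S sequence carrying 3 substitutions (the kinds of junctions
seen in real R2 surveys) -- and prints the classifier's calls.
"""

from r2ribozyme import classify_junction, default_element, default_target_ref

ref = default_target_ref()
elem = default_element()

canonical = ref.upstream + elem.five_prime_seq
deletion7 = ref.upstream[:-7] + elem.five_prime_seq
dup = list(ref.downstream[:22])
for i in (3, 10, 17):
    dup[i] = "A" if dup[i] != "A" else "G"
dup22 = ref.upstream + "".join(dup) + elem.five_prime_seq

for name, read in (("canonical", canonical), ("deletion-7", deletion7),
                   ("downstream-dup-22", dup22)):
    call = classify_junction(read, ref, elem, read_id=name)
    d = call.duplication
    print(f"{name:18s} category={call.category:15s} "
          f"deletion={call.deletion_len} "
          f"dup={'-' if d is None else f'{d.source}/{d.length}bp/{d.substitutions}sub'} "
          f"nontemplated={call.nontemplated or '-'}")

print()
print("Each call reconstructs the read exactly from: 28S prefix (minus the")
print("deletion) + duplication copies + non-templated insert + element 5' end.")
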