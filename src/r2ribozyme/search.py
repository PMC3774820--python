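"""Descriptor-constrained folding of 28S/element junction RNA.

The search anchors on candidate P3/L3 cores (the most constrained part of
the structure: the conserved L3 'G', its reverse-wobble 'U' partner and the
P3 helix), extends outward to P1b/P1.1b, enumerates P1a placements inside
the signed cleavage-site window, and finally closes the P2 pseudoknot.
Every candidate that satisfies all descriptor constraints is scored and the
list is returned in deterministic rank order.

Because P1a may sit upstream of the element boundary, structures routinely
incorporate 28S rRNA sequence into the 5' side of the P1 stem -- which is
exactly how upstream self-cleavage sites (e.g. -28) arise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import TargetSiteRef, can_pair, normalize_sequence
from .descriptor import (
    FoldError,
    FoldScoreConfig,
    REGIONS,
    RibozymeDescriptor,
    RibozymeFold,
    build_fold,
)

__all__ = [
    "fold_search", "predict_cleavage", "refold_with_mutation",
    "compare_p1_candidates", "P1Candidate", "predict_cleavage_fragments",
    "t7_transcript", "count_repeats", "fold_summary_row",
]


def _canonical_split(
    seq: str,
    j14_start: int,
    p2b_start: int,
    desc: RibozymeDescriptor,
    require_c: bool,
) -> tuple[int, int, int] | None:
    """Partition the J1/4+P4+J4/2 gap deterministically.

    Among all admissible ``(j14, p4, j42)`` partitions of the gap, returns
    the lexicographically smallest ``(j14, p4)`` whose J4/2 window contains
    a C (the catalytic residue).  When ``require_c`` is False (penalize
    policy) a partition without a C is acceptable as a fallback.
    """
    gap = p2b_start - j14_start
    fallback = None
    for j14 in range(desc.j1_4_len_range[0], desc.j1_4_len_range[1] + 1):
        for p4 in range(desc.p4_span_range[0], desc.p4_span_range[1] + 1):
            j42 = gap - j14 - p4
            if j42 < desc.j4_2_len_range[0]:
                break  # larger p4 only shrinks j42 further
            if j42 > desc.j4_2_len_range[1]:
                continue
            if seq.rfind("C", p2b_start - j42, p2b_start) >= 0:
                return (j14, p4, j42)
            if fallback is None:
                fallback = (j14, p4, j42)
    return None if require_c else fallback


def fold_search(
    seq: str,
    ref: TargetSiteRef,
    desc: RibozymeDescriptor | None = None,
    scorecfg: FoldScoreConfig | None = None,
    max_results: int = 20,
) -> list[RibozymeFold]:
    """All descriptor-conformant folds of ``seq``, best first.

    ``seq`` is the junction RNA in the same coordinate frame as ``ref``:
    positions before ``ref.insertion_index`` are upstream 28S, the rest is
    element (the element 5' region must be long enough to close P2).  The
    ranking is deterministic: score, then longer P1, then more-upstream
    cleavage offset, then smallest segment layout.  An empty list means no
    candidate satisfies the descriptor -- notably when an invariant position
    (catalytic C, conserved L3 G) is absent under the default reject policy.
    """
    seq, _ = normalize_sequence(seq)
    desc = desc or RibozymeDescriptor()
    cfg = scorecfg or FoldScoreConfig()
    L = len(seq)
    if L < desc.min_span():
        raise FoldError(
            f"sequence length {L} below minimal descriptor span {desc.min_span()}")
    ins = ref.insertion_index
    a1_lo = max(0, ins + desc.search_window[0])
    a1_hi = min(L - 1, ins + desc.search_window[1])
    if a1_lo > a1_hi:
        raise FoldError("search window lies outside the sequence")

    reject = cfg.invariant_policy == "reject"
    p1lo, p1hi = desc.p1_len_range
    p2lo, p2hi = desc.p2_len_range
    p3lo, p3hi = desc.p3_len_range
    l3lo, l3hi = desc.l3_len_range
    j12lo, j12hi = desc.j1_2_len_range
    gap_lo = desc.j1_4_len_range[0] + desc.p4_span_range[0] + desc.j4_2_len_range[0]
    gap_hi = desc.j1_4_len_range[1] + desc.p4_span_range[1] + desc.j4_2_len_range[1]

    out: list[RibozymeFold] = []

    for s3 in range(a1_lo + p1lo + j12lo + p2lo, L):
        for p3 in range(p3lo, p3hi + 1):
            for l3len in range(l3lo, l3hi + 1):
                l3s = s3 + p3
                l3e = l3s + l3len
                p3b_e = l3e + p3
                if p3b_e + p1lo + 2 + gap_lo + p2lo > L:
                    break
                if reject:
                    if seq[l3e - 1] != "G":
                        continue
                    if "T" not in seq[l3s + 2:l3e - 1]:
                        continue
                mm3 = sum(
                    not can_pair(seq[s3 + i], seq[p3b_e - 1 - i])
                    for i in range(p3))
                if mm3 > desc.p3_max_mismatch:
                    continue

                for p1 in range(p1lo, p1hi + 1):
                    p1b_e = p3b_e + p1
                    if p1b_e + 2 + gap_lo + p2lo > L:
                        break
                    mm11 = ((not can_pair(seq[l3s], seq[p1b_e + 1]))
                            + (not can_pair(seq[l3s + 1], seq[p1b_e])))
                    if mm11 > desc.p1_1_max_disruptions:
                        continue
                    p11e = p1b_e + 2

                    # P1a placements inside the cleavage-site window
                    a1s = []
                    lowest_mm = (p1 + 1) // 2  # mismatches allowed above here
                    for a1 in range(a1_lo, min(a1_hi, s3 - p2lo - j12lo - p1) + 1):
                        mm = 0
                        ok = True
                        for i in range(p1):
                            if can_pair(seq[a1 + i], seq[p3b_e + p1 - 1 - i]):
                                continue
                            if i < lowest_mm or mm >= desc.p1_max_mismatch:
                                ok = False
                                break
                            mm += 1
                        if ok:
                            a1s.append(a1)
                    if not a1s:
                        continue

                    for p2 in range(p2lo, p2hi + 1):
                        b2 = s3 - p2
                        if b2 < 0:
                            break
                        hi = min(p11e + gap_hi, L - p2)
                        for p2b_s in range(p11e + gap_lo, hi + 1):
                            mmf = 0
                            ok = True
                            for i in range(p2 - 1, -1, -1):  # core-proximal first
                                if can_pair(seq[b2 + i], seq[p2b_s + p2 - 1 - i]):
                                    continue
                                if i >= p2 - 5:
                                    mmf += 1
                                    if mmf > desc.p2_max_mismatch_first5:
                                        ok = False
                                        break
                            if not ok:
                                continue
                            split = _canonical_split(seq, p11e, p2b_s, desc, reject)
                            if split is None:
                                continue
                            j14, p4, j42 = split
                            for a1 in a1s:
                                j12 = b2 - (a1 + p1)
                                if not j12lo <= j12 <= j12hi:
                                    continue
                                segs = {
                                    "P1a": (a1, a1 + p1),
                                    "J1/2": (a1 + p1, b2),
                                    "P2a": (b2, s3),
                                    "P3a": (s3, l3s),
                                    "L3": (l3s, l3e),
                                    "P3b": (l3e, p3b_e),
                                    "P1b": (p3b_e, p1b_e),
                                    "P1.1b": (p1b_e, p11e),
                                    "J1/4": (p11e, p11e + j14),
                                    "P4": (p11e + j14, p11e + j14 + p4),
                                    "J4/2": (p2b_s - j42, p2b_s),
                                    "P2b": (p2b_s, p2b_s + p2),
                                }
                                fold = build_fold(seq, ref, segs, desc, cfg)
                                if reject and fold.invariant_violations:
                                    continue
                                out.append(fold)

    out.sort(key=RibozymeFold.sort_key)
    return out[:max_results]


def predict_cleavage(fold: RibozymeFold, ref: TargetSiteRef) -> int:
    """Signed offset of the self-cleavage bond (5' edge of P1a).

    Negative values mean that many 28S nucleotides remain attached to the
    downstream, element-containing RNA fragment after self-cleavage.
    """
    off = fold.segments["P1a"][0] - ref.insertion_index
    if off != fold.cleavage_offset:
        raise FoldError(
            f"fold cleavage_offset {fold.cleavage_offset} inconsistent with "
            f"reference insertion point (expected {off})")
    return off


def refold_with_mutation(
    seq: str,
    ref: TargetSiteRef,
    desc: RibozymeDescriptor | None = None,
    scorecfg: FoldScoreConfig | None = None,
    pos: int = 0,
    base: str = "A",
    max_results: int = 20,
) -> list[RibozymeFold]:
    """Fold search on the point-substituted sequence.

    Mirrors the mutational assays used to pin down catalytic residues:
    substituting the catalytic C (or the conserved L3 G) must empty the
    fold list under the default reject policy.
    """
    seq, _ = normalize_sequence(seq)
    if not 0 <= pos < len(seq):
        raise ValueError(f"position {pos} out of bounds")
    base = base.upper().replace("U", "T")
    if base not in "ACGTN":
        raise ValueError(f"invalid base {base!r}")
    if seq[pos] == base:
        raise ValueError(f"sequence already has {base} at position {pos}")
    mutated = seq[:pos] + base + seq[pos + 1:]
    return fold_search(mutated, ref, desc, scorecfg, max_results=max_results)


@dataclass(frozen=True)
class P1Candidate:
    """One alternative P1a placement against a shared downstream core."""

    cleavage_offset: int
    p1_length: int
    mismatch_count: int
    score: float


def compare_p1_candidates(
    seq: str,
    ref: TargetSiteRef,
    desc: RibozymeDescriptor | None = None,
    scorecfg: FoldScoreConfig | None = None,
) -> list[P1Candidate]:
    """Rank alternative P1a placements over the best fold's downstream core.

    A junction carrying a tandem duplication of the target site offers two
    (or more) sequences that can serve as the 5' strand of P1; self-cleavage
    can occur at either, and relative stem stability decides which
    predominates.  Entries are sorted by score with the package's standard
    deterministic tie-breaking.
    """
    folds = fold_search(seq, ref, desc, scorecfg, max_results=10_000)
    if not folds:
        raise FoldError("no descriptor-conformant fold found")

    def core_key(f: RibozymeFold):
        return tuple(f.segments[r] for r in ("P2a", "P3a", "L3", "P3b"))

    top_core = core_key(folds[0])
    best_by_p1a: dict[tuple[int, int], RibozymeFold] = {}
    for f in folds:
        if core_key(f) != top_core:
            continue
        key = f.segments["P1a"]
        cur = best_by_p1a.get(key)
        if cur is None or f.sort_key() < cur.sort_key():
            best_by_p1a[key] = f
    ranked = sorted(best_by_p1a.values(), key=RibozymeFold.sort_key)
    return [
        P1Candidate(
            cleavage_offset=f.cleavage_offset,
            p1_length=f.p1_len,
            mismatch_count=f.stem_mismatches("P1"),
            score=f.score,
        )
        for f in ranked
    ]


def predict_cleavage_fragments(
    template_length: int, cut_index: int
) -> tuple[int, int]:
    """Lengths of the upstream and downstream products of one cut.

    This is the arithmetic behind reading a denaturing gel of a
    co-transcription/self-cleavage assay: an RNA of ``template_length``
    cut at ``cut_index`` yields fragments whose lengths sum to the input.
    """
    if template_length < 0:
        raise ValueError("template_length must be non-negative")
    if not 0 <= cut_index <= template_length:
        raise ValueError(
            f"cut_index {cut_index} outside [0, {template_length}]")
    return cut_index, template_length - cut_index


T7_PROMOTER_CORE = "TAATACGACTCACTATA"


def t7_transcript(template_top_strand: str) -> str:
    """RNA-equivalent transcript (as DNA) from a T7 template top strand.

    Transcription starts immediately after the 17-nt T7 promoter core, so
    the G-run engineered after the promoter is the transcript 5' end.
    """
    seq, _ = normalize_sequence(template_top_strand)
    idx = seq.find(T7_PROMOTER_CORE)
    if idx < 0:
        raise ValueError("no T7 promoter core in template")
    return seq[idx + len(T7_PROMOTER_CORE):]


def count_repeats(seq: str, unit: str = "TAA") -> int:
    """Non-overlapping occurrences of ``unit`` (e.g. TAA repeats on a gel)."""
    seq, _ = normalize_sequence(seq)
    unit, _ = normalize_sequence(unit)
    return seq.count(unit)


def fold_summary_row(fold: RibozymeFold) -> dict:
    """Flat TSV-friendly summary of one fold."""
    row = {
        "cleavage_offset": fold.cleavage_offset,
        "score": fold.score,
        "catalytic_c": fold.catalytic_c,
    }
    for stem, (a, _b) in (("P1", ("P1a", "P1b")), ("P1.1", ("P1.1b",) * 2),
                          ("P2", ("P2a", "P2b")), ("P3", ("P3a", "P3b"))):
        s, e = fold.segments[a]
        row[f"{stem}_len"] = e - s
        row[f"{stem}_mismatches"] = fold.stem_mismatches(stem)
    s, e = fold.segments["J1/2"]
    row["J1/2_len"] = e - s
    return row
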