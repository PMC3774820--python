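"""Reference enumerator for the descriptor search.

A deliberately plain, exhaustive implementation: iterate every segment
layout (P1a placement, stem lengths, loop lengths, gap partition), check
each descriptor constraint inline, score inline, and keep the best layout
under the package's standard tie-break.  It shares only the base-pairing
primitive and the fold container with the production search, so it serves
as an independent cross-check on small inputs (practical for sequences up
to a few hundred nt with J1/2 capped at tens of nt).
"""

from __future__ import annotations

from .core import TargetSiteRef, can_pair, is_gu, normalize_sequence
from .descriptor import (
    FoldScoreConfig,
    RibozymeDescriptor,
    RibozymeFold,
    build_fold,
)


def _weight(cfg: FoldScoreConfig, a: str, b: str) -> float:
    if is_gu(a, b):
        return cfg.gu_weight
    if {a, b} == {"G", "C"}:
        return cfg.gc_weight
    return cfg.au_weight


def brute_force_best_fold(
    seq: str,
    ref: TargetSiteRef,
    desc: RibozymeDescriptor | None = None,
    scorecfg: FoldScoreConfig | None = None,
) -> RibozymeFold | None:
    """Best descriptor-conformant fold by exhaustive enumeration, or None.

    Only the default reject policy is supported (the enumeration skips
    layouts missing an invariant position outright).
    """
    seq, _ = normalize_sequence(seq)
    desc = desc or RibozymeDescriptor()
    cfg = scorecfg or FoldScoreConfig()
    if cfg.invariant_policy != "reject":
        raise ValueError("the reference enumerator assumes the reject policy")

    L = len(seq)
    ins = ref.insertion_index
    a1_lo = max(0, ins + desc.search_window[0])
    a1_hi = min(L - 1, ins + desc.search_window[1])
    p1lo, p1hi = desc.p1_len_range
    p2lo, p2hi = desc.p2_len_range
    p3lo, p3hi = desc.p3_len_range
    l3lo, l3hi = desc.l3_len_range
    j12lo, j12hi = desc.j1_2_len_range
    j14lo, j14hi = desc.j1_4_len_range
    p4lo, p4hi = desc.p4_span_range
    j42lo, j42hi = desc.j4_2_len_range
    half = lambda p1: (p1 + 1) // 2

    best_key = None
    best_segs = None
    best_score = None

    for a1 in range(a1_lo, a1_hi + 1):
        for p1 in range(p1lo, p1hi + 1):
            for j12 in range(j12lo, j12hi + 1):
                b2 = a1 + p1 + j12
                for p2 in range(p2lo, p2hi + 1):
                    s3 = b2 + p2
                    for p3 in range(p3lo, p3hi + 1):
                        for l3len in range(l3lo, l3hi + 1):
                            l3s = s3 + p3
                            l3e = l3s + l3len
                            p3b_e = l3e + p3
                            p11e = p3b_e + p1 + 2
                            if p11e + j14lo + p4lo + j42lo + p2 > L:
                                break
                            # invariant L3 positions
                            if seq[l3e - 1] != "G":
                                continue
                            if "T" not in seq[l3s + 2:l3e - 1]:
                                continue
                            # P3 helix
                            if sum(not can_pair(seq[s3 + i], seq[p3b_e - 1 - i])
                                   for i in range(p3)) > desc.p3_max_mismatch:
                                continue
                            # P1 helix: mismatches only in the distal half
                            mm1 = 0
                            ok = True
                            for i in range(p1):
                                if can_pair(seq[a1 + i], seq[p3b_e + p1 - 1 - i]):
                                    continue
                                if i < half(p1):
                                    ok = False
                                    break
                                mm1 += 1
                            if not ok or mm1 > desc.p1_max_mismatch:
                                continue
                            # P1.1 pseudoknot
                            p1b_e = p3b_e + p1
                            if ((not can_pair(seq[l3s], seq[p1b_e + 1]))
                                    + (not can_pair(seq[l3s + 1], seq[p1b_e]))
                                    > desc.p1_1_max_disruptions):
                                continue
                            for gap in range(j14lo + p4lo + j42lo,
                                             j14hi + p4hi + j42hi + 1):
                                p2b_s = p11e + gap
                                if p2b_s + p2 > L:
                                    break
                                # P2 pseudoknot: <=1 mismatch in 5 core pairs
                                mmf = 0
                                ok = True
                                for i in range(p2 - 1, -1, -1):
                                    if can_pair(seq[b2 + i],
                                                seq[p2b_s + p2 - 1 - i]):
                                        continue
                                    if i >= p2 - 5:
                                        mmf += 1
                                        if mmf > desc.p2_max_mismatch_first5:
                                            ok = False
                                            break
                                if not ok:
                                    continue
                                for j14 in range(j14lo, j14hi + 1):
                                    for p4 in range(p4lo, p4hi + 1):
                                        j42 = gap - j14 - p4
                                        if j42 < j42lo:
                                            break
                                        if j42 > j42hi:
                                            continue
                                        if seq.rfind("C", p2b_s - j42,
                                                     p2b_s) < 0:
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
                                            "P4": (p11e + j14,
                                                   p11e + j14 + p4),
                                            "J4/2": (p2b_s - j42, p2b_s),
                                            "P2b": (p2b_s, p2b_s + p2),
                                        }
                                        score = _score(seq, segs, desc, cfg)
                                        key = (
                                            -score, -p1, a1 - ins,
                                            tuple(segs[r] for r in (
                                                "P1a", "J1/2", "P2a", "P3a",
                                                "L3", "P3b", "P1b", "P1.1b",
                                                "J1/4", "P4", "J4/2", "P2b")),
                                        )
                                        if best_key is None or key < best_key:
                                            best_key = key
                                            best_segs = segs
                                            best_score = score

    if best_segs is None:
        return None
    fold = build_fold(seq, ref, best_segs, desc, cfg)
    if abs(fold.score - best_score) > 1e-9:
        raise AssertionError(
            f"scoring disagreement: enumerator {best_score}, "
            f"package {fold.score}")
    return fold


def _score(seq: str, segs: dict[str, tuple[int, int]],
           desc: RibozymeDescriptor, cfg: FoldScoreConfig) -> float:
    """Inline re-derivation of the fold score for a complete layout."""
    score = 0.0
    stems = (
        (segs["P1a"], segs["P1b"]),
        ((segs["L3"][0], segs["L3"][0] + 2), segs["P1.1b"]),
        (segs["P2a"], segs["P2b"]),
        (segs["P3a"], segs["P3b"]),
    )
    for (sa, ea), (sb, eb) in stems:
        for i in range(ea - sa):
            a, b = seq[sa + i], seq[eb - 1 - i]
            if can_pair(a, b):
                score += _weight(cfg, a, b)
            else:
                score -= cfg.mismatch_penalty
    for region, idx, base in desc.consensus_pattern:
        s, e = segs[region]
        if s + idx < e and seq[s + idx] == base:
            score += cfg.consensus_bonus
    j12len = segs["J1/2"][1] - segs["J1/2"][0]
    if j12len > cfg.loop_free_len:
        score -= cfg.loop_penalty_per_nt * (j12len - cfg.loop_free_len)
    return score
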