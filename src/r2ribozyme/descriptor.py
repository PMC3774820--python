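"""The HDV-like double-pseudoknot descriptor and fold representation.

The R2 ribozyme, like the hepatitis delta virus (HDV) ribozyme, folds into
five paired segments (P1, P1.1, P2, P3, P4) arranged as a double pseudoknot.
On the RNA strand, 5'->3', the regions appear in the order::

    P1a  J1/2  P2a  P3a  L3  P3b  P1b  P1.1b  J1/4  P4  J4/2  P2b

P1a pairs P1b; P3a pairs P3b; the first two L3 bases (P1.1a) pair the two
bases immediately 3' of P1b (P1.1b); and P2a pairs P2b at the far 3' end --
the two helices that cross the nesting order (P2 and P1.1) are the
pseudoknots.  Self-cleavage occurs at the bond immediately 5' of P1a, so the
location of P1a relative to the 28S/element boundary *is* the predicted
cleavage offset.

The descriptor encodes the structural constraints observed across R2
ribozymes: stem length ranges, mismatch budgets, the conserved L3 'G' (which
forms a reverse-wobble pair with a 'U' elsewhere in L3) and the catalytic
'C' in J4/2.  The conserved positions are *invariant*: under the default
policy a candidate that lacks them is rejected outright, mirroring the
observation that a single G->A change in L3 or a C->U change at the
catalytic position abolishes self-cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .core import TargetSiteRef, can_pair, is_gu

#: 5'->3' region order of a complete fold.
REGIONS = (
    "P1a", "J1/2", "P2a", "P3a", "L3", "P3b",
    "P1b", "P1.1b", "J1/4", "P4", "J4/2", "P2b",
)

STEMS = ("P1", "P1.1", "P2", "P3")


class FoldError(ValueError):
    """Raised for a structurally inconsistent fold."""


def _check_range(name: str, rng: tuple[int, int]) -> None:
    lo, hi = rng
    if lo > hi:
        raise ValueError(f"{name} range {rng} is empty")
    if lo < 0:
        raise ValueError(f"{name} range {rng} is negative")


@dataclass(frozen=True)
class RibozymeDescriptor:
    """Constraint set for the double-pseudoknot search.

    Defaults reflect the spread observed across R2 elements: P1 of 4-7 bp
    (typically 6-7, down to 4 in the jewel wasp Nv) with mismatches tolerated
    only in the distal ("top") half of the stem; P2 of at least 5 bp with at
    most one mismatch among the five core-proximal pairs; P3 of 4-8 bp with
    at most one mismatch; L3 of 6-14 nt carrying the conserved G/U
    reverse-wobble partners; an optional, highly variable P4 region; and a
    J1/2 joiner that ranges from tens to hundreds of nucleotides.
    """

    p1_len_range: tuple[int, int] = (4, 7)
    p1_max_mismatch: int = 2
    p1_1_len: int = 2
    p1_1_max_disruptions: int = 1
    p2_len_range: tuple[int, int] = (5, 12)
    p2_max_mismatch_first5: int = 1
    p3_len_range: tuple[int, int] = (4, 8)
    p3_max_mismatch: int = 1
    l3_len_range: tuple[int, int] = (6, 14)
    p4_span_range: tuple[int, int] = (4, 60)
    j1_2_len_range: tuple[int, int] = (15, 800)
    j1_4_len_range: tuple[int, int] = (0, 2)
    j4_2_len_range: tuple[int, int] = (2, 12)
    #: candidate cleavage sites, as signed offsets around the insertion point
    search_window: tuple[int, int] = (-45, 5)
    #: consensus (bonus, non-invariant) positions: (region, index, base).
    #: Default: the two P1.1a cytosines of the consensus active site.
    consensus_pattern: tuple[tuple[str, int, str], ...] = (
        ("L3", 0, "C"),
        ("L3", 1, "C"),
    )

    def __post_init__(self) -> None:
        for name in ("p1_len_range", "p2_len_range", "p3_len_range",
                     "l3_len_range", "p4_span_range", "j1_2_len_range",
                     "j1_4_len_range", "j4_2_len_range"):
            _check_range(name, getattr(self, name))
        if self.search_window[0] > self.search_window[1]:
            raise ValueError("search_window is empty")
        if self.p1_1_len != 2:
            raise ValueError("P1.1 is a fixed 2-bp pseudoknot helix")
        if self.l3_len_range[0] < 4:
            raise ValueError("L3 must hold P1.1a (2 nt) plus the G/U anchors")

    def min_span(self) -> int:
        """Smallest sequence length a complete fold can occupy."""
        return (self.p1_len_range[0] * 2 + self.j1_2_len_range[0]
                + self.p2_len_range[0] * 2 + self.p3_len_range[0] * 2
                + self.l3_len_range[0] + 2 + self.j1_4_len_range[0]
                + self.p4_span_range[0] + self.j4_2_len_range[0])


def p1_mismatch_positions(p1_len: int) -> range:
    """P1a indices (0 = cleavage-proximal) where mismatches are tolerated.

    "Top of the stem" is taken as the distal half, away from the cleavage
    site and adjacent to J1/2.
    """
    return range((p1_len + 1) // 2, p1_len)


@dataclass(frozen=True)
class FoldScoreConfig:
    """Ranking weights for descriptor-conformant folds.

    The underlying survey ranks structures qualitatively; these weights are
    package defaults, exposed for configuration: GC=3 / AU=2 / GU=1 per
    pair, -2 per tolerated mismatch, +2 per matched consensus position.
    Invariant violations are rejected by default (``policy='reject'``) or
    penalized by ``invariant_penalty`` each (``policy='penalize'``).
    """

    gc_weight: float = 3.0
    au_weight: float = 2.0
    gu_weight: float = 1.0
    mismatch_penalty: float = 2.0
    consensus_bonus: float = 2.0
    loop_penalty_per_nt: float = 0.0  # applied to J1/2 beyond loop_free_len
    loop_free_len: int = 800
    invariant_policy: str = "reject"  # or "penalize"
    invariant_penalty: float = 10.0

    def __post_init__(self) -> None:
        if self.invariant_policy not in ("reject", "penalize"):
            raise ValueError("invariant_policy must be 'reject' or 'penalize'")

    def pair_weight(self, a: str, b: str) -> float:
        if is_gu(a, b):
            return self.gu_weight
        if {a, b} == {"G", "C"}:
            return self.gc_weight
        return self.au_weight


@dataclass(frozen=True)
class RibozymeFold:
    """One descriptor-conformant fold of a junction RNA.

    ``segments`` maps each region name of :data:`REGIONS` to a half-open
    interval on ``sequence``; the intervals tile the fold span contiguously.
    ``pair_tables`` lists, per stem, ``(i, j, is_mismatch)`` with ``i < j``
    absolute positions.  ``cleavage_offset`` is the signed position of the
    bond 5' of P1a relative to the insertion point (0 = element 5' end,
    negative = upstream in 28S).
    """

    sequence: str
    segments: dict[str, tuple[int, int]]
    catalytic_c: int | None
    cleavage_offset: int
    pair_tables: dict[str, tuple[tuple[int, int, bool], ...]]
    score: float
    conservation_hits: tuple[tuple[str, bool], ...]
    invariant_violations: tuple[str, ...] = ()

    def region(self, name: str) -> str:
        s, e = self.segments[name]
        return self.sequence[s:e]

    @property
    def p1_len(self) -> int:
        s, e = self.segments["P1a"]
        return e - s

    @property
    def span(self) -> tuple[int, int]:
        return self.segments["P1a"][0], self.segments["P2b"][1]

    def segment_tuple(self) -> tuple[tuple[int, int], ...]:
        """Segments in strand order -- the deterministic tie-break key."""
        return tuple(self.segments[r] for r in REGIONS)

    def sort_key(self) -> tuple:
        """Higher score, longer P1, more-upstream cleavage, smallest layout."""
        return (-self.score, -self.p1_len, self.cleavage_offset,
                self.segment_tuple())

    def stem_mismatches(self, stem: str) -> int:
        return sum(1 for *_ij, mm in self.pair_tables[stem] if mm)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "segments": {k: list(v) for k, v in self.segments.items()},
            "catalytic_c": self.catalytic_c,
            "cleavage_offset": self.cleavage_offset,
            "pair_tables": {k: [list(p) for p in v]
                            for k, v in self.pair_tables.items()},
            "score": self.score,
            "conservation_hits": [list(h) for h in self.conservation_hits],
            "invariant_violations": list(self.invariant_violations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RibozymeFold":
        return cls(
            sequence=d["sequence"],
            segments={k: tuple(v) for k, v in d["segments"].items()},
            catalytic_c=d["catalytic_c"],
            cleavage_offset=d["cleavage_offset"],
            pair_tables={k: tuple(tuple(p) for p in v)
                         for k, v in d["pair_tables"].items()},
            score=d["score"],
            conservation_hits=tuple(tuple(h) for h in d["conservation_hits"]),
            invariant_violations=tuple(d.get("invariant_violations", ())),
        )


def find_catalytic_c(seq: str, j42: tuple[int, int]) -> int | None:
    """The catalytic cytosine: the 3'-most C in J4/2 (closest to P2b)."""
    s, e = j42
    idx = seq.rfind("C", s, e)
    return idx if idx >= 0 else None


def score_segments(
    seq: str,
    segments: dict[str, tuple[int, int]],
    desc: RibozymeDescriptor,
    cfg: FoldScoreConfig,
) -> tuple[float, dict[str, tuple[tuple[int, int, bool], ...]],
           tuple[tuple[str, bool], ...], int | None, tuple[str, ...]]:
    """Score a segment layout; the single scoring authority for the package.

    Returns ``(score, pair_tables, conservation_hits, catalytic_c,
    invariant_violations)``.  Does not enforce descriptor ranges -- that is
    :func:`validate_fold`'s job -- but does evaluate invariant positions.
    """
    def stem_pairs(a: tuple[int, int], b: tuple[int, int]):
        (sa, ea), (sb, eb) = a, b
        n = ea - sa
        out = []
        for i in range(n):
            x, y = sa + i, eb - 1 - i
            out.append((x, y, not can_pair(seq[x], seq[y])))
        return tuple(out)

    tables = {
        "P1": stem_pairs(segments["P1a"], segments["P1b"]),
        "P1.1": stem_pairs((segments["L3"][0], segments["L3"][0] + 2),
                           segments["P1.1b"]),
        "P2": stem_pairs(segments["P2a"], segments["P2b"]),
        "P3": stem_pairs(segments["P3a"], segments["P3b"]),
    }

    score = 0.0
    for pairs in tables.values():
        for x, y, mm in pairs:
            if mm:
                score -= cfg.mismatch_penalty
            else:
                score += cfg.pair_weight(seq[x], seq[y])

    l3s, l3e = segments["L3"]
    l3 = seq[l3s:l3e]
    catalytic = find_catalytic_c(seq, segments["J4/2"])

    violations = []
    inv = [
        ("L3_G", l3[-1] == "G"),
        ("L3_U", "T" in l3[2:-1]),
        ("catalytic_C", catalytic is not None),
    ]
    for name, ok in inv:
        if not ok:
            violations.append(name)
            score -= cfg.invariant_penalty

    hits = list(inv)
    for region, idx, base in desc.consensus_pattern:
        s, e = segments[region]
        ok = s + idx < e and seq[s + idx] == base
        hits.append((f"{region}[{idx}]={base}", ok))
        if ok:
            score += cfg.consensus_bonus

    j12len = segments["J1/2"][1] - segments["J1/2"][0]
    if j12len > cfg.loop_free_len:
        score -= cfg.loop_penalty_per_nt * (j12len - cfg.loop_free_len)

    return score, tables, tuple(hits), catalytic, tuple(violations)


def build_fold(
    seq: str,
    ref: TargetSiteRef,
    segments: dict[str, tuple[int, int]],
    desc: RibozymeDescriptor,
    cfg: FoldScoreConfig,
) -> RibozymeFold:
    """Assemble and score a fold from a complete segment layout."""
    score, tables, hits, catalytic, violations = score_segments(
        seq, segments, desc, cfg)
    return RibozymeFold(
        sequence=seq,
        segments=dict(segments),
        catalytic_c=catalytic,
        cleavage_offset=segments["P1a"][0] - ref.insertion_index,
        pair_tables=tables,
        score=score,
        conservation_hits=hits,
        invariant_violations=violations,
    )


def validate_fold(
    fold: RibozymeFold,
    desc: RibozymeDescriptor,
    ref: TargetSiteRef | None = None,
    allow_invariant_violations: bool = False,
) -> list[str]:
    """Recheck every descriptor constraint on a fold; [] means conformant.

    Written as a flat constraint list, independent of the constructive
    search, so tests can use it as a second opinion.
    """
    errs: list[str] = []
    seq = fold.sequence
    seg = fold.segments

    missing = [r for r in REGIONS if r not in seg]
    if missing:
        return [f"missing regions: {missing}"]

    # strand order: contiguous, strictly ordered tiling
    prev = None
    for r in REGIONS:
        s, e = seg[r]
        if s > e or s < 0 or e > len(seq):
            errs.append(f"{r} interval {seg[r]} out of bounds")
        if prev is not None and s != prev:
            errs.append(f"{r} does not abut previous region ({s} != {prev})")
        prev = e

    def ln(r):
        return seg[r][1] - seg[r][0]

    def in_range(val, rng):
        return rng[0] <= val <= rng[1]

    p1 = ln("P1a")
    if ln("P1b") != p1:
        errs.append("P1a and P1b lengths differ")
    if not in_range(p1, desc.p1_len_range):
        errs.append(f"P1 length {p1} outside {desc.p1_len_range}")
    if ln("P2a") != ln("P2b") or not in_range(ln("P2a"), desc.p2_len_range):
        errs.append(f"P2 length {ln('P2a')}/{ln('P2b')} invalid")
    if ln("P3a") != ln("P3b") or not in_range(ln("P3a"), desc.p3_len_range):
        errs.append(f"P3 length {ln('P3a')}/{ln('P3b')} invalid")
    if not in_range(ln("L3"), desc.l3_len_range):
        errs.append(f"L3 length {ln('L3')} outside {desc.l3_len_range}")
    if ln("P1.1b") != 2:
        errs.append("P1.1b must be exactly 2 nt")
    if not in_range(ln("J1/2"), desc.j1_2_len_range):
        errs.append(f"J1/2 length {ln('J1/2')} outside {desc.j1_2_len_range}")
    if not in_range(ln("J1/4"), desc.j1_4_len_range):
        errs.append(f"J1/4 length {ln('J1/4')} outside {desc.j1_4_len_range}")
    if not in_range(ln("P4"), desc.p4_span_range):
        errs.append(f"P4 span {ln('P4')} outside {desc.p4_span_range}")
    if not in_range(ln("J4/2"), desc.j4_2_len_range):
        errs.append(f"J4/2 length {ln('J4/2')} outside {desc.j4_2_len_range}")

    # mismatch budgets and placement
    p1_mm = [i for i, (x, y, mm) in enumerate(fold.pair_tables["P1"]) if mm]
    allowed = set(p1_mismatch_positions(p1))
    if len(p1_mm) > desc.p1_max_mismatch:
        errs.append(f"P1 has {len(p1_mm)} mismatches > {desc.p1_max_mismatch}")
    if any(i not in allowed for i in p1_mm):
        errs.append("P1 mismatch outside the top of the stem")

    if fold.stem_mismatches("P1.1") > desc.p1_1_max_disruptions:
        errs.append("P1.1 disruptions exceed budget")

    p2 = ln("P2a")
    first5 = sum(1 for i, (x, y, mm) in enumerate(fold.pair_tables["P2"])
                 if mm and i >= p2 - 5)
    if first5 > desc.p2_max_mismatch_first5:
        errs.append(f"P2 has {first5} mismatches in the first 5 pairs")

    if fold.stem_mismatches("P3") > desc.p3_max_mismatch:
        errs.append("P3 mismatches exceed budget")

    # pair tables consistent with segment layout
    for stem, (a, b) in (("P1", ("P1a", "P1b")), ("P2", ("P2a", "P2b")),
                         ("P3", ("P3a", "P3b"))):
        (sa, ea), (sb, eb) = seg[a], seg[b]
        expect = [(sa + i, eb - 1 - i) for i in range(ea - sa)]
        if [(x, y) for x, y, _ in fold.pair_tables[stem]] != expect:
            errs.append(f"{stem} pair table inconsistent with segments")
    l3s = seg["L3"][0]
    sb, eb = seg["P1.1b"]
    if [(x, y) for x, y, _ in fold.pair_tables["P1.1"]] != \
            [(l3s, eb - 1), (l3s + 1, eb - 2)]:
        errs.append("P1.1 pair table inconsistent with segments")
    for stem, pairs in fold.pair_tables.items():
        for x, y, mm in pairs:
            if mm != (not can_pair(seq[x], seq[y])):
                errs.append(f"{stem} mismatch flag wrong at ({x},{y})")

    if not allow_invariant_violations:
        l3 = fold.region("L3")
        if l3[-1] != "G":
            errs.append("conserved L3 'G' absent")
        if "T" not in l3[2:-1]:
            errs.append("L3 reverse-wobble 'U' partner absent")
        if find_catalytic_c(seq, seg["J4/2"]) is None:
            errs.append("catalytic 'C' absent from J4/2")

    if ref is not None:
        if fold.cleavage_offset != seg["P1a"][0] - ref.insertion_index:
            errs.append("cleavage_offset inconsistent with reference")
        lo, hi = desc.search_window
        if not lo <= fold.cleavage_offset <= hi:
            errs.append(f"cleavage offset {fold.cleavage_offset} outside window")

    return errs


# --- annotation: optional internal P4 stem ----------------------------------

def annotate_p4_stem(fold: RibozymeFold, min_stem: int = 2,
                     min_loop: int = 3) -> tuple[tuple[int, int, bool], ...]:
    """Best internal hairpin within the P4 region, as an annotation only.

    The P4 region is highly variable across R2 elements -- absent in all
    silkmoths, extensively paired in others -- so the descriptor accepts the
    span with or without a stem and the score ignores it.  This helper
    reports the longest perfect internal stem (5'-most on ties) for display.
    """
    s, e = fold.segments["P4"]
    seq = fold.sequence
    best: list[tuple[int, int]] = []
    n = e - s
    for i in range(n):
        for j in range(n - 1, i + min_loop + 2 * min_stem - 2, -1):
            k = 0
            while (i + k < j - k - min_loop
                   and can_pair(seq[s + i + k], seq[s + j - k])):
                k += 1
            if k >= min_stem and k > len(best):
                best = [(s + i + t, s + j - t) for t in range(k)]
    return tuple((x, y, False) for x, y in best)


# --- dot-bracket with pseudoknot layers --------------------------------------

_LAYERS = {"P1": "()", "P3": "()", "P2": "[]", "P1.1": "{}"}


def to_dotbracket(fold: RibozymeFold) -> str:
    """Dot-bracket string over the fold span.

    Nested helices (P1, P3) use ``()``; the pseudoknotted stems use extra
    layers: ``[]`` for P2 and ``{}`` for P1.1.  Mismatched positions are
    left unpaired (dots).  String length equals the fold span.
    """
    start, end = fold.span
    chars = ["."] * (end - start)
    for stem, pairs in fold.pair_tables.items():
        op, cl = _LAYERS[stem]
        for x, y, mm in pairs:
            if mm:
                continue
            chars[x - start] = op
            chars[y - start] = cl
    return "".join(chars)


def parse_dotbracket(s: str) -> set[tuple[int, int]]:
    """Parse a (possibly pseudoknotted) dot-bracket string to a pair set."""
    stacks: dict[str, list[int]] = {"(": [], "[": [], "{": [], "<": []}
    close = {")": "(", "]": "[", "}": "{", ">": "<"}
    pairs = set()
    for i, ch in enumerate(s):
        if ch in stacks:
            stacks[ch].append(i)
        elif ch in close:
            st = stacks[close[ch]]
            if not st:
                raise ValueError(f"unbalanced bracket at {i}")
            pairs.add((st.pop(), i))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} at {i}")
    for op, st in stacks.items():
        if st:
            raise ValueError(f"unclosed {op!r} bracket")
    return pairs


def fold_pairs(fold: RibozymeFold, relative: bool = True) -> set[tuple[int, int]]:
    """Non-mismatch pairs of a fold, optionally relative to the fold span."""
    start = fold.span[0] if relative else 0
    return {(x - start, y - start)
            for pairs in fold.pair_tables.values()
            for x, y, mm in pairs if not mm}
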