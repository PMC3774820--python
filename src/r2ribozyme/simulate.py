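"""Synthetic data: junction populations, planted ribozymes, P1-shift states.

Everything the pipeline consumes can be generated here, seeded and
deterministic.  Two read generators emulate the competing models for how
second-strand DNA synthesis is primed during target-primed reverse
transcription:

* **heteroduplex** -- the ribozyme cleaved upstream in the 28S gene
  (offset k < 0), so the cDNA carries |k| nt of 28S that anneal to the
  target and prime precisely.  Most reads are the exact junction; with a
  small probability the integration instead uses the cDNA 5' end,
  producing a tandem duplication of the |k| upstream bases (with
  substitutions and an optional non-templated insert).
* **microhomology** -- cleavage at the element 5' end (offset 0), so
  priming relies on chance matches between the cDNA terminus (including
  run-off non-templated additions) and upstream target DNA, yielding
  variable 28S deletions and retained non-templated bases.

Reads that would be ambiguous to *any* maximum-templated-coverage parser
(e.g. a non-templated tail that happens to extend a templated match or to
mimic a duplication source) are resampled: such reads are inherently
unattributable, so the emitted truth tables describe exactly the unique
most-parsimonious decomposition of every read.

The planted-ribozyme generator writes a descriptor-conformant fold into an
otherwise pairing-inert background (loops and flanks are adenosine-rich;
stems are G/C), so the planted structure is the unique optimum and
recovery by the search is a sharp test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ElementRef, TargetSiteRef, build_target_ref
from .classify import ClassifyParams, Duplication, JunctionCall, mismatches
from .descriptor import (
    FoldScoreConfig,
    RibozymeDescriptor,
    RibozymeFold,
    build_fold,
    validate_fold,
)
from .search import P1Candidate, compare_p1_candidates

BASES = "ACGT"

# Synthetic 28S target-site context.  The 3'-most 32 nt of the upstream
# flank follow the conserved junction context printed for endogenous R2
# sites; the rest is synthetic padding.  The downstream side and the
# element 5' end are synthetic, chosen to be non-repetitive.
DEFAULT_28S_UPSTREAM = "CGTAACGGGA" + "TGACTCTCGGCGGGAGTAACTATGACTCTCTT"
DEFAULT_28S_DOWNSTREAM = (
    "AGGTCAGGTTCGAATCCAACGTGCCTTAGCATCAATTGGACCGTAGGCTTAACGGATCCA"
)
DEFAULT_ELEMENT_5P = (
    "GGTAGCACGGTCTTCAATGGATCGGTACCAGAAGCTTGATCCGTTCACCGGATAACTGGC"
)


def default_target_ref() -> TargetSiteRef:
    """Synthetic 28S reference with the insertion point after the flank."""
    return build_target_ref(
        DEFAULT_28S_UPSTREAM + DEFAULT_28S_DOWNSTREAM,
        len(DEFAULT_28S_UPSTREAM),
        id="synthetic_28S",
    )


def default_element() -> ElementRef:
    return ElementRef(id="synthetic_R2", five_prime_seq=DEFAULT_ELEMENT_5P)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a priming-model simulation."""

    model: str = "heteroduplex"
    cleavage_offset: int = -28
    n_reads: int = 100
    dup_path_prob: float = 0.05  # heteroduplex only
    nontemplated_geom_p: float = 0.3
    substitution_rate: float = 0.05  # per duplicated base
    min_microhomology: int = 4  # microhomology only
    dup_deletion_prob: float = 0.0
    site_weighting: str = "length"  # or "uniform"
    seed: int = 0
    max_resamples: int = 200

    def __post_init__(self) -> None:
        if self.model not in ("heteroduplex", "microhomology"):
            raise ValueError(f"unknown model {self.model!r}")
        for p in ("dup_path_prob", "substitution_rate", "dup_deletion_prob"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must be in [0, 1]")
        if not 0.0 < self.nontemplated_geom_p <= 1.0:
            raise ValueError("nontemplated_geom_p must be in (0, 1]")
        if self.min_microhomology < 1:
            raise ValueError("min_microhomology must be >= 1")
        if self.site_weighting not in ("length", "uniform"):
            raise ValueError("site_weighting must be 'length' or 'uniform'")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass
class SimResult:
    reads: list[tuple[str, str]]
    truth: list[JunctionCall]
    skipped: int
    config: SimConfig


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _geom_len(rng: np.random.Generator, p: float) -> int:
    """Geometric insert length with support starting at 0 (mean (1-p)/p)."""
    return int(rng.geometric(p)) - 1


def _substitute(rng: np.random.Generator, s: str, rate: float) -> str:
    if rate <= 0.0:
        return s
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


# --- uniqueness of the most-parsimonious decomposition -----------------------

def _parse_values(read: str, ref: TargetSiteRef, elem_seq: str,
                  params: ClassifyParams) -> list[tuple[int, tuple]]:
    """All (value, parse) decompositions of a read, for ambiguity checks.

    A parse is ``(P, source, length, copy_count, substitutions,
    nontemplated)`` with ``P`` the 28S prefix length; value is the
    templated coverage.  Kept separate from the classifier on purpose.
    """
    upstream, downstream = ref.upstream, ref.downstream
    U = ref.insertion_index
    frac = params.max_substitution_fraction

    lp = 0
    for L in range(min(len(read), len(elem_seq)), params.min_element_anchor - 1, -1):
        if read[len(read) - L:] == elem_seq[:L]:
            lp = L
            break
    if lp == 0:
        return []
    elem_start = len(read) - lp

    lcp = 0
    max_p = min(U, elem_start)
    while lcp < max_p and read[lcp] == upstream[lcp] and upstream[lcp] != "N":
        lcp += 1

    out = []
    for P in range(params.min_28s_anchor, lcp + 1):
        mid = read[P:elem_start]
        out.append((P + lp, (P, None, 0, 0, 0, mid)))
        for source in ("upstream", "downstream"):
            max_l = min(len(mid),
                        P if source == "upstream"
                        else min(params.downstream_search_span, len(downstream)))
            for ell in range(params.min_duplication_match, max_l + 1):
                src = (upstream[P - ell:P] if source == "upstream"
                       else downstream[:ell])
                budget = int(frac * ell)
                s0 = mismatches(mid[:ell], src, budget)
                if s0 > budget:
                    continue
                subs = [s0]
                pos = ell
                while pos + ell <= len(mid):
                    s = mismatches(mid[pos:pos + ell], src, budget)
                    if s > budget:
                        break
                    subs.append(s)
                    pos += ell
                value = P + sum(ell - s for s in subs) + lp
                out.append((value, (P, source, ell, 1 + len(subs),
                                    sum(subs), mid[pos:])))
    return out


def _truth_parse(call: JunctionCall, U: int) -> tuple:
    d = call.duplication
    return (U - call.deletion_len,
            d.source if d else None,
            d.length if d else 0,
            d.copy_count if d else 0,
            d.substitutions if d else 0,
            call.nontemplated)


def _is_unambiguous(read: str, call: JunctionCall, ref: TargetSiteRef,
                    elem: ElementRef, params: ClassifyParams) -> bool:
    """True when the truth is the strict, unique maximum-coverage parse."""
    if U_prefix := ref.insertion_index - call.deletion_len:
        if U_prefix < params.min_28s_anchor:
            return False
    else:
        return False
    values = _parse_values(read, ref, elem.five_prime_seq, params)
    if not values:
        return False
    truth = _truth_parse(call, ref.insertion_index)
    vmax = max(v for v, _ in values)
    top = [p for v, p in values if v == vmax]
    return len(top) == 1 and top[0] == truth


# --- priming-model read generators -------------------------------------------

def simulate_heteroduplex(
    cfg: SimConfig,
    ref: TargetSiteRef | None = None,
    elem: ElementRef | None = None,
    params: ClassifyParams | None = None,
) -> SimResult:
    """Junction reads under heteroduplex-primed second-strand synthesis.

    With probability ``1 - dup_path_prob`` a read is the precise junction
    (full upstream flank + element 5' end); with probability
    ``dup_path_prob`` the read instead carries a tandem duplication of the
    ``|cleavage_offset|`` upstream bases, with per-base substitutions and an
    optional geometric non-templated insert between duplication and element.
    """
    ref = ref or default_target_ref()
    elem = elem or default_element()
    params = params or ClassifyParams()
    k = cfg.cleavage_offset
    if k >= 0:
        raise ValueError("heteroduplex priming requires upstream cleavage (k < 0)")
    K = -k
    U = ref.insertion_index
    if K > U:
        raise ValueError(f"|k|={K} exceeds upstream flank length {U}")
    rng = np.random.default_rng(cfg.seed)
    E = len(elem.five_prime_seq)

    reads: list[tuple[str, str]] = []
    truth: list[JunctionCall] = []
    skipped = 0
    for i in range(cfg.n_reads):
        rid = f"het{i:05d}"
        for _attempt in range(cfg.max_resamples):
            if rng.random() >= cfg.dup_path_prob:
                read = ref.upstream + elem.five_prime_seq
                call = JunctionCall(rid, U, E, 0, None, "", "canonical")
            else:
                d = 0
                if cfg.dup_deletion_prob > 0 and rng.random() < cfg.dup_deletion_prob:
                    d = 1 + _geom_len(rng, 0.5)
                P = U - d
                if P - K < 0:
                    continue
                src = ref.upstream[P - K:P]
                copy = _substitute(rng, src, cfg.substitution_rate)
                insert = _rand_bases(rng, _geom_len(rng, cfg.nontemplated_geom_p))
                read = ref.upstream[:P] + copy + insert + elem.five_prime_seq
                dup = Duplication("upstream", K, mismatches(copy, src), 2,
                                  (copy,))
                call = JunctionCall(
                    rid, P + K + len(insert), E, d, dup, insert,
                    _cat(d, dup, insert))
            if _is_unambiguous(read, call, ref, elem, params):
                reads.append((rid, read))
                truth.append(call)
                break
        else:
            skipped += 1
    return SimResult(reads, truth, skipped, cfg)


def _cat(deletion: int, dup, nontemplated: str) -> str:
    feats = ([] if deletion == 0 else ["deletion"])
    if dup is not None:
        feats.append(f"dup_{dup.source}")
    if nontemplated:
        feats.append("nontemplated")
    if not feats:
        return "canonical"
    return feats[0] if len(feats) == 1 else "mixed"


def simulate_microhomology(
    cfg: SimConfig,
    ref: TargetSiteRef | None = None,
    elem: ElementRef | None = None,
    params: ClassifyParams | None = None,
) -> SimResult:
    """Junction reads under chance-microhomology second-strand priming.

    Per read: draw a geometric non-templated tail of random bases (the
    run-off additions on the cDNA, written 5' of the element on the top
    strand), enumerate upstream-28S positions where the tail+element
    string matches at least ``min_microhomology`` consecutive bases,
    sample a priming site (weighted by match length by default) and emit
    the junction with the implied 28S deletion and any retained
    non-templated bases.  Reads with no candidate site after bounded
    resampling are counted in ``skipped``.
    """
    ref = ref or default_target_ref()
    elem = elem or default_element()
    params = params or ClassifyParams()
    if cfg.cleavage_offset != 0:
        raise ValueError(
            "microhomology priming applies when cleavage is at the element "
            "5' end (offset 0)")
    m = cfg.min_microhomology
    U = ref.insertion_index
    upstream = ref.upstream
    rng = np.random.default_rng(cfg.seed)
    E = len(elem.five_prime_seq)

    reads: list[tuple[str, str]] = []
    truth: list[JunctionCall] = []
    skipped = 0
    for i in range(cfg.n_reads):
        rid = f"mh{i:05d}"
        for _attempt in range(cfg.max_resamples):
            g = _geom_len(rng, cfg.nontemplated_geom_p)
            tail = _rand_bases(rng, g)
            X = tail + elem.five_prime_seq
            sites = []
            for t in range(U):
                ell = 0
                while (t + ell < U and ell < len(X)
                       and X[ell] == upstream[t + ell]):
                    ell += 1
                if ell >= m:
                    sites.append((t, ell))
            if not sites:
                continue
            if cfg.site_weighting == "length":
                w = np.array([ell for _, ell in sites], dtype=float)
            else:
                w = np.ones(len(sites))
            t, ell = sites[int(rng.choice(len(sites), p=w / w.sum()))]
            q = t + ell
            if ell <= g:
                read = upstream[:q] + X[ell:]
                call = JunctionCall(
                    rid, q + (g - ell), E, U - q, None, tail[ell:],
                    _cat(U - q, None, tail[ell:]))
            else:
                # the match consumed tail plus the element's first ell-g
                # bases; those element bases coincide with 28S sequence
                read = upstream[:q] + elem.five_prime_seq[ell - g:]
                P = q - (ell - g)
                call = JunctionCall(
                    rid, P, E, U - P, None, "", _cat(U - P, None, ""))
            if _is_unambiguous(read, call, ref, elem, params):
                reads.append((rid, read))
                truth.append(call)
                break
        else:
            skipped += 1
    return SimResult(reads, truth, skipped, cfg)


def simulate(cfg: SimConfig, ref: TargetSiteRef | None = None,
             elem: ElementRef | None = None) -> SimResult:
    """Dispatch on ``cfg.model``."""
    fn = (simulate_heteroduplex if cfg.model == "heteroduplex"
          else simulate_microhomology)
    return fn(cfg, ref, elem)


# --- planted ribozymes -------------------------------------------------------

@dataclass(frozen=True)
class PlantConfig:
    """Recipe for a sequence containing one planted, known fold.

    Stems are drawn uniformly over G-C pairings (the natural P1 region at
    -28..-22 is itself GC-rich); loops, joiners and flanking sequence are
    adenosine, which pairs with nothing present outside the stems, so the
    planted structure is the unique pairing solution and its segments are
    an exact truth table.
    """

    seed: int = 0
    cleavage_offset: int = -28
    p1_len_choices: tuple[int, ...] = (6, 7)
    p2_len_range: tuple[int, int] = (5, 9)
    p3_len_range: tuple[int, int] = (4, 8)
    l3_len_range: tuple[int, int] = (6, 10)
    j1_2_len_range: tuple[int, int] = (30, 60)
    gap_len_range: tuple[int, int] = (9, 30)  # J1/4 + P4 + J4/2 combined
    upstream_pad: int = 12
    trailing: int = 6
    descriptor: RibozymeDescriptor = field(default_factory=RibozymeDescriptor)


@dataclass(frozen=True)
class PlantedRibozyme:
    sequence: str
    ref: TargetSiteRef
    truth: RibozymeFold


def _gc_stem(rng: np.random.Generator, n: int,
             forced: str | None = None) -> tuple[str, str]:
    """A perfect n-bp stem (5' strand, 3' strand) from G-C pairs."""
    a = forced if forced is not None else \
        "".join("CG"[i] for i in rng.integers(0, 2, size=n))
    comp = {"C": "G", "G": "C", "A": "T", "T": "A"}
    b = "".join(comp[c] for c in reversed(a))
    return a, b


def _sample(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def generate_ribozyme(cfg: PlantConfig,
                      forced_p1a: str | None = None) -> PlantedRibozyme:
    """Sequence with a planted descriptor-conformant ribozyme and its truth.

    Same seed, same config -> byte-identical output.  The truth fold is
    checked against the descriptor validator before being returned.
    """
    desc = cfg.descriptor
    rng = np.random.default_rng(cfg.seed)
    K = -cfg.cleavage_offset
    if cfg.cleavage_offset > 0:
        raise ValueError("planted cleavage offset must be <= 0")

    p1 = int(rng.choice(cfg.p1_len_choices))
    if not desc.p1_len_range[0] <= p1 <= desc.p1_len_range[1]:
        raise ValueError(f"planted P1 length {p1} outside descriptor range")
    p2 = _sample(rng, *cfg.p2_len_range)
    # L3 and P3 jointly: the region downstream of the reverse-wobble U that
    # could re-anchor an alternative L3 'G' must be covered by the C-strand
    # of P3, so the planted conserved G stays structurally unique
    l3len = _sample(rng, *cfg.l3_len_range)
    p3_lo = max(cfg.p3_len_range[0], 14 - l3len)
    if p3_lo > cfg.p3_len_range[1]:
        raise ValueError("l3/p3 ranges cannot keep the L3 anchor unique")
    p3 = _sample(rng, p3_lo, cfg.p3_len_range[1])
    j12_lo = max(cfg.j1_2_len_range[0], desc.j1_2_len_range[0], K - p1 + 1)
    if j12_lo > cfg.j1_2_len_range[1]:
        raise ValueError("J1/2 range cannot reach past the upstream flank")
    j12 = _sample(rng, j12_lo, cfg.j1_2_len_range[1])
    gap_lo = max(cfg.gap_len_range[0],
                 desc.j1_4_len_range[0] + desc.p4_span_range[0] + 3)
    gap_hi = min(cfg.gap_len_range[1],
                 desc.j1_4_len_range[1] + desc.p4_span_range[1]
                 + desc.j4_2_len_range[1])
    if gap_lo > gap_hi:
        raise ValueError("gap range admits no structure")
    gap = _sample(rng, gap_lo, gap_hi)

    # Stem orientation is deliberate: P3 and P2 are planted as homogeneous
    # G-strand/C-strand helices and P1a starts with C, which leaves exactly
    # one catalytic C and one wobble U reachable by any candidate core --
    # point knockouts of either invariant then empty the search, as they
    # abolish cleavage in the molecule.
    p1a, p1b = _gc_stem(rng, p1, forced_p1a)
    if forced_p1a is None:
        p1a, p1b = _gc_stem(rng, p1, "C" + p1a[1:])
    p2a, p2b = "C" * p2, "G" * p2
    p3a, p3b = "G" * p3, "C" * p3
    l3 = "CCT" + "A" * (l3len - 4) + "G"
    gap_fill = "A" * (gap - 3) + "CAA"  # catalytic C, 2 nt before P2b

    pad = cfg.upstream_pad
    seq = ("A" * pad + p1a + "A" * j12 + p2a + p3a + l3 + p3b + p1b + "GG"
           + gap_fill + p2b + "A" * cfg.trailing)
    ins = pad + K

    a1 = pad
    b2 = a1 + p1 + j12
    s3 = b2 + p2
    l3s = s3 + p3
    l3e = l3s + l3len
    p3b_e = l3e + p3
    p1b_e = p3b_e + p1
    p11e = p1b_e + 2
    # canonical gap partition: smallest J1/4, then smallest P4 whose J4/2
    # window (which must contain the planted C) fits the descriptor
    t_j14 = desc.j1_4_len_range[0]
    t_p4 = max(desc.p4_span_range[0], gap - t_j14 - desc.j4_2_len_range[1])
    t_j42 = gap - t_j14 - t_p4
    p2b_s = p11e + gap
    segs = {
        "P1a": (a1, a1 + p1),
        "J1/2": (a1 + p1, b2),
        "P2a": (b2, s3),
        "P3a": (s3, l3s),
        "L3": (l3s, l3e),
        "P3b": (l3e, p3b_e),
        "P1b": (p3b_e, p1b_e),
        "P1.1b": (p1b_e, p11e),
        "J1/4": (p11e, p11e + t_j14),
        "P4": (p11e + t_j14, p11e + t_j14 + t_p4),
        "J4/2": (p2b_s - t_j42, p2b_s),
        "P2b": (p2b_s, p2b_s + p2),
    }
    ref = build_target_ref(seq, ins, id=f"planted_seed{cfg.seed}")
    truth = build_fold(seq, ref, segs, desc, FoldScoreConfig())
    problems = validate_fold(truth, desc, ref)
    if problems:
        raise RuntimeError(f"planted fold fails its own descriptor: {problems}")
    return PlantedRibozyme(sequence=seq, ref=ref, truth=truth)


# --- Fig-8-style duplication / cleavage-site-shift trajectory ----------------

@dataclass(frozen=True)
class TrajectoryState:
    state: str
    description: str
    sequence: str
    ref: TargetSiteRef
    expected_preference: str  # "tie" | "upstream" | "internal"
    candidates: tuple[P1Candidate, ...]
    preferred_offset: int


def simulate_p1_shift(dup_len: int = 28, seed: int = 0,
                      plant: PlantConfig | None = None) -> list[TrajectoryState]:
    """The five states of the duplication-driven cleavage-site shift.

    Starting from a junction that tandem-duplicates the ``dup_len``
    upstream bases (which include the P1a segment), the trajectory walks
    through: (a) perfect duplication -- self-cleavage equally likely at
    the upstream or the internal P1; (b) a mutation in the internal copy
    biases cleavage upstream; (c) further decay of the duplicated copy
    keeps it there; (d) a compensatory change in P1' flips the preference
    to the internal copy; (e) additional compensatory changes leave only
    the internal P1, i.e. cleavage has shifted to the element 5' end.
    Preferences are computed, not asserted, via ``compare_p1_candidates``.
    """
    cfg = plant or PlantConfig(seed=seed, cleavage_offset=-dup_len)
    if cfg.cleavage_offset != -dup_len:
        cfg = replace(cfg, cleavage_offset=-dup_len)
    p1_probe = max(cfg.p1_len_choices)
    if dup_len < p1_probe:
        raise ValueError("duplication must cover a full P1a segment")

    rng = np.random.default_rng(cfg.seed)
    p1 = int(rng.choice(cfg.p1_len_choices))
    forced = "C" + "".join("CG"[i] for i in rng.integers(0, 2, size=p1 - 2)) + "G"
    base = generate_ribozyme(replace(cfg, seed=cfg.seed), forced_p1a=forced)
    seq0, ins = base.sequence, base.ref.insertion_index
    desc = cfg.descriptor

    flank, element = seq0[:ins], seq0[ins:]
    dup = seq0[ins - dup_len:ins]
    p1b_s0 = base.truth.segments["P1b"][0]
    p1b_sA = p1b_s0 + dup_len  # everything >= ins shifts by dup_len

    def with_muts(muts: dict[int, str]) -> str:
        s = list(flank + dup + element)
        for pos, b in muts.items():
            s[pos] = b
        return "".join(s)

    states = []
    plan = [
        ("a", "perfect tandem duplication: two equivalent P1 segments",
         {}, "tie"),
        ("b", "mutation in the internal (duplicated) P1 copy",
         {ins + p1 - 1: "A"}, "upstream"),
        ("c", "internal-copy mutation plus decay of the duplicated segment",
         {ins + p1 - 1: "A",
          **({ins + p1: "T", ins + p1 + 2: "G"} if dup_len > p1 + 2 else {})},
         "upstream"),
        ("d", "compensatory substitution in P1' matches the internal copy",
         {ins + p1 - 1: "A", p1b_sA: "T"}, "internal"),
        ("e", "further compensation: only the internal P1 remains pairable",
         {ins + p1 - 1: "A", p1b_sA: "T",
          ins: "A", p1b_sA + p1 - 1: "T"}, "internal"),
    ]
    for name, descr, muts, expect in plan:
        seq = with_muts(muts)
        ref = build_target_ref(seq, ins, id=f"p1shift_{name}")
        cands = tuple(compare_p1_candidates(seq, ref, desc))
        states.append(TrajectoryState(
            state=name, description=descr, sequence=seq, ref=ref,
            expected_preference=expect, candidates=cands,
            preferred_offset=cands[0].cleavage_offset))
    return states
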