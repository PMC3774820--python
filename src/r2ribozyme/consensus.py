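"""Comparative layer: active-site signatures and consensus structures.

Folds from different elements are compared region-by-region (P1.1a first
pair = column 1, and so on) rather than by sequence alignment: the regions
have fixed structural roles and vary in length only within narrow bounds.
Variable-length regions are aligned flush to their conserved anchors --
for L3, the P1.1a dinucleotide at the 5' end and the reverse-wobble 'G' at
the 3' end -- with gap columns excluded from frequency denominators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .descriptor import FoldError, RibozymeFold

#: regions entering the active-site signature, in fixed order.
SIGNATURE_REGIONS = ("P1.1a", "P1.1b", "P3a", "P3b", "L3", "J4/2c")

#: regions entering the consensus, with their alignment rule.
#: "left" = flush to the 5' anchor, "right" = flush to the 3' anchor,
#: "l3" = both anchors (2 left, 1 right, middle left-flushed).
CONSENSUS_REGIONS = (
    ("P1a", "left"), ("P1b", "right"),
    ("P2a", "right"), ("P2b", "left"),
    ("P3a", "right"), ("P3b", "left"),
    ("P1.1a", "left"), ("P1.1b", "left"),
    ("L3", "l3"), ("J1/4", "left"), ("J4/2c", "left"),
)

GAP = "-"


def _extract_regions(fold: RibozymeFold) -> dict[str, str]:
    seq = fold.sequence
    seg = fold.segments
    out = {}
    for name in ("P1a", "P1b", "P2a", "P2b", "P3a", "P3b", "P1.1b", "J1/4", "L3"):
        s, e = seg[name]
        out[name] = seq[s:e]
    l3s = seg["L3"][0]
    out["P1.1a"] = seq[l3s:l3s + 2]
    c = fold.catalytic_c
    if c is None:
        raise FoldError("fold has no catalytic C; signature undefined")
    left = seq[c - 1] if c - 1 >= seg["J4/2"][0] else GAP
    right = seq[c + 1] if c + 1 < seg["J4/2"][1] else GAP
    out["J4/2c"] = left + seq[c] + right
    return out


@dataclass(frozen=True)
class ActiveSiteSignature:
    """Ordered bases of the catalytic core (P1.1 + P3 + L3 + C context)."""

    regions: tuple[tuple[str, str], ...]

    def layout(self) -> tuple[tuple[str, int], ...]:
        return tuple((name, len(bases)) for name, bases in self.regions)

    def flat(self) -> str:
        return "".join(bases for _, bases in self.regions)

    def __len__(self) -> int:
        return len(self.flat())


def active_site_signature(fold: RibozymeFold) -> ActiveSiteSignature:
    """Extract the active-site core of a fold in fixed region order.

    The P1.1, P3 and L3 regions carry essentially all of the conserved
    active-site sequence; the catalytic C is reported with one base of
    context on each side.  Folds differing only outside these regions
    (e.g. anywhere in J1/2) have identical signatures.
    """
    regions = _extract_regions(fold)
    missing = [r for r in SIGNATURE_REGIONS if r not in regions or not regions[r]]
    if missing:
        raise FoldError(f"fold missing signature regions: {missing}")
    return ActiveSiteSignature(
        tuple((name, regions[name]) for name in SIGNATURE_REGIONS))


def signature_diff(
    sig: ActiveSiteSignature, reference: ActiveSiteSignature
) -> list[tuple[str, int, str, str]]:
    """Positions where two signatures differ: (region, index, ref, alt).

    Requires identical region layouts; the result is empty iff the
    signatures are identical, and symmetric in length under argument swap.
    """
    if sig.layout() != reference.layout():
        raise FoldError(
            f"signature layouts differ: {sig.layout()} vs {reference.layout()}")
    diffs = []
    for (name, alt), (_, refb) in zip(sig.regions, reference.regions):
        for i, (a, r) in enumerate(zip(alt, refb)):
            if a != r:
                diffs.append((name, i, r, a))
    return diffs


def _aligned_columns(bases: str, width: int, rule: str) -> list[str]:
    """Place a region's bases into ``width`` columns per its anchor rule."""
    n = len(bases)
    pad = width - n
    if rule == "left":
        return list(bases) + [GAP] * pad
    if rule == "right":
        return [GAP] * pad + list(bases)
    if rule == "l3":
        # 2 columns flush left (P1.1a), 1 flush right (conserved G),
        # middle left-flushed
        mid = bases[2:-1]
        mid_width = width - 3
        return (list(bases[:2]) + list(mid) + [GAP] * (mid_width - len(mid))
                + [bases[-1]])
    raise ValueError(f"unknown alignment rule {rule!r}")


@dataclass(frozen=True)
class ConsensusStructure:
    """Per-column base frequencies and >=threshold consensus calls.

    ``frequencies[region][col]`` maps base -> fraction among folds with a
    base in that column (gaps excluded from the denominator).  A position
    enters ``consensus`` when its modal base reaches ``threshold``; it is
    ``invariant`` when every fold has the same base there (no gaps), so
    the invariant set is always a subset of the consensus set.
    """

    n_folds: int
    threshold: float
    widths: dict[str, int]
    frequencies: dict[str, list[dict[str, float]]]
    coverage: dict[str, list[int]]
    consensus: dict[tuple[str, int], str]
    invariant: dict[tuple[str, int], str]
    stem_stats: dict[str, dict[str, dict[int, int]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region, cols in sorted(self.frequencies.items()):
            for col, freqs in enumerate(cols):
                for base, f in sorted(freqs.items()):
                    rows.append({
                        "region": region, "column": col, "base": base,
                        "frequency": f,
                        "coverage": self.coverage[region][col],
                        "consensus": self.consensus.get((region, col), ""),
                        "invariant": (region, col) in self.invariant,
                    })
        return pd.DataFrame(
            rows, columns=["region", "column", "base", "frequency",
                           "coverage", "consensus", "invariant"])

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "threshold": self.threshold,
            "widths": dict(self.widths),
            "consensus": {f"{r}:{c}": b for (r, c), b in
                          sorted(self.consensus.items())},
            "invariant": {f"{r}:{c}": b for (r, c), b in
                          sorted(self.invariant.items())},
            "stem_stats": self.stem_stats,
        }


def build_consensus(folds: list[RibozymeFold],
                    threshold: float = 0.75) -> ConsensusStructure:
    """Region-aligned consensus over a set of folds.

    Mirrors how a multi-element consensus structure is drawn: count each
    base at each structurally equivalent position, call the consensus
    where the modal base reaches ``threshold`` (default 0.75), and mark
    positions shared by every fold as invariant.
    """
    if len(folds) < 2:
        raise ValueError("need at least two folds for a consensus")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")

    extracts = [_extract_regions(f) for f in folds]
    region_names = [name for name, _ in CONSENSUS_REGIONS]
    for ex in extracts:
        missing = [r for r in region_names if r not in ex]
        if missing:
            raise FoldError(f"fold missing regions {missing}: incompatible layout")

    widths = {name: max(len(ex[name]) for ex in extracts)
              for name, _ in CONSENSUS_REGIONS}
    counts: dict[str, list[Counter]] = {
        name: [Counter() for _ in range(widths[name])]
        for name, _ in CONSENSUS_REGIONS}
    for ex in extracts:
        for name, rule in CONSENSUS_REGIONS:
            for col, base in enumerate(
                    _aligned_columns(ex[name], widths[name], rule)):
                if base != GAP:
                    counts[name][col][base] += 1

    n = len(folds)
    frequencies: dict[str, list[dict[str, float]]] = {}
    coverage: dict[str, list[int]] = {}
    consensus: dict[tuple[str, int], str] = {}
    invariant: dict[tuple[str, int], str] = {}
    for name, cols in counts.items():
        frequencies[name] = []
        coverage[name] = []
        for col, cnt in enumerate(cols):
            tot = sum(cnt.values())
            coverage[name].append(tot)
            if tot == 0:
                frequencies[name].append({})
                continue
            freqs = {b: c / tot for b, c in sorted(cnt.items())}
            frequencies[name].append(freqs)
            modal_base, modal_n = sorted(
                cnt.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if modal_n / tot >= threshold:
                consensus[(name, col)] = modal_base
            if tot == n and modal_n == n:
                invariant[(name, col)] = modal_base

    stem_stats = {}
    for stem in ("P1", "P1.1", "P2", "P3"):
        lengths = Counter(len(f.pair_tables[stem]) for f in folds)
        mm = Counter(f.stem_mismatches(stem) for f in folds)
        stem_stats[stem] = {
            "lengths": dict(sorted(lengths.items())),
            "mismatches": dict(sorted(mm.items())),
        }

    return ConsensusStructure(
        n_folds=n, threshold=threshold, widths=widths,
        frequencies=frequencies, coverage=coverage,
        consensus=consensus, invariant=invariant, stem_stats=stem_stats)
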