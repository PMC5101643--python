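"""NAHR breakpoint analysis: repeat discovery and junction painting.

A recombinant junction created by NAHR between two near-identical repeats
carries a chimeric repeat copy.  Each paralogous sequence variant (PSV)
in that copy can be assigned to the left (L) or right (R) parental repeat,
and the ordered call vector localizes the strand exchange to the interval
between the last call of one parent and the first call of the other:
L→R for deletion junctions, R→L for the reciprocal tandem-duplication
junctions.  Isolated opposite calls inside an otherwise monotone vector
are discontinuous gene-conversion tracks and are masked before the switch
is located.  The double-strand-break region inferred from both junction
classes together is the union span of their switch intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

from athcnv.locus import GenomicInterval, LcrPair, psv_intervals

__all__ = [
    "RepeatHit",
    "JunctionPainting",
    "PaintingError",
    "find_repeats",
    "paint_junction",
    "locate_breakpoint",
    "detect_conversions",
    "minimal_flip_bruteforce",
    "infer_dsb_region",
    "detect_microhomology",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PaintingError(ValueError):
    """Too few PSVs could be called to paint the junction."""


@dataclass(frozen=True)
class RepeatHit:
    """A pair of similar intervals found by self-comparison."""

    interval_a: GenomicInterval
    interval_b: GenomicInterval
    percent_identity: float
    orientation: str  # "direct" | "inverted"

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity must be within [0, 100]")
        if self.interval_a.start > self.interval_b.start:
            raise ValueError("interval_a must precede interval_b")


@dataclass
class JunctionPainting:
    """Per-PSV parental-origin calls for one junction sequence.

    ``calls`` is a string over {L, R, X} with one character per PSV;
    ``flank_upstream``/``flank_downstream`` record which parental repeat
    the sequence directly outside the chimeric copy matches (informative
    when all PSVs come from one parent).
    """

    junction_id: str
    calls: str
    junction_type: str | None = None  # "deletion" | "duplication"
    flank_upstream: str | None = None  # "L" | "R" | None
    flank_downstream: str | None = None
    switch_interval: tuple[int, int] | None = None
    conversion_sites: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(c not in "LRX" for c in self.calls):
            raise ValueError("calls must be a string over {L, R, X}")


# ---------------------------------------------------------------------------
# repeat discovery
# ---------------------------------------------------------------------------

def _chain_diagonal(
    starts: list[int], k: int, max_seed_gap: int
) -> list[tuple[int, int]]:
    """Group seed start positions on one diagonal into chained spans."""
    spans = []
    starts = sorted(starts)
    lo = prev = starts[0]
    for s in starts[1:]:
        if s - prev > max_seed_gap:
            spans.append((lo, prev + k - 1))
            lo = s
        prev = s
    spans.append((lo, prev + k - 1))
    return spans


def _extend_exact(seq_a: str, seq_b: str, a0: int, a1: int, b0: int):
    """Extend an ungapped match outward while bases agree exactly."""
    off = b0 - a0
    while a0 > 0 and off + a0 - 1 >= 0 and seq_a[a0 - 1] == seq_b[a0 - 1 + off]:
        a0 -= 1
    n_a, n_b = len(seq_a), len(seq_b)
    while a1 + 1 < n_a and a1 + 1 + off < n_b and seq_a[a1 + 1] == seq_b[a1 + 1 + off]:
        a1 += 1
    return a0, a1


def find_repeats(
    sequence: str,
    window: int = 1000,
    min_identity: float = 0.9,
    min_length: int = 500,
    k: int = 16,
    max_seed_gap: int = 400,
    chrom: str = "seq",
    origin: int = 1,
    search_inverted: bool = True,
) -> list[RepeatHit]:
    """Self-comparison repeat search by k-mer seeding and chaining.

    Exact k-mers occurring more than once seed ungapped matches; seeds
    sharing a diagonal (direct) or anti-diagonal (inverted) are chained
    when closer than ``max_seed_gap``, spans are extended outward over
    exact matches, and kept when at least ``min_length`` long at
    ``min_identity`` (fractional) identity.  Coordinates are reported
    1-based relative to ``origin``.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < window:
        warnings.warn(
            "sequence shorter than one window; no repeat search performed",
            stacklevel=2,
        )
        return []

    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer_pos.setdefault(sequence[i: i + k], []).append(i)

    hits: list[RepeatHit] = []

    # direct repeats: seeds grouped by diagonal (p2 - p1)
    diagonals: dict[int, list[int]] = {}
    for positions in kmer_pos.values():
        if len(positions) < 2:
            continue
        for p1, p2 in combinations(positions, 2):
            diagonals.setdefault(p2 - p1, []).append(p1)
    for diag, starts in diagonals.items():
        for a0, a1 in _chain_diagonal(starts, k, max_seed_gap):
            a0, a1 = _extend_exact(sequence, sequence, a0, a1, a0 + diag)
            length = a1 - a0 + 1
            if length < min_length or length > diag:
                # overlapping copies are not a valid direct repeat pair
                continue
            sub_a = sequence[a0: a1 + 1]
            sub_b = sequence[a0 + diag: a1 + diag + 1]
            ident = sum(x == y for x, y in zip(sub_a, sub_b)) / length
            if ident >= min_identity:
                hits.append(RepeatHit(
                    GenomicInterval(chrom, origin + a0, origin + a1),
                    GenomicInterval(
                        chrom, origin + a0 + diag, origin + a1 + diag
                    ),
                    percent_identity=100.0 * ident,
                    orientation="direct",
                ))

    if search_inverted:
        anti: dict[int, list[int]] = {}
        for kmer, positions in kmer_pos.items():
            rc = _revcomp(kmer)
            if rc <= kmer:  # visit each kmer/rc pair once
                continue
            for p1 in positions:
                for p2 in kmer_pos.get(rc, ()):
                    lo, hi = min(p1, p2), max(p1, p2)
                    if hi - lo < k:  # self-overlapping palindrome seed
                        continue
                    anti.setdefault(lo + hi, []).append(lo)
        for s, starts in anti.items():
            for a0, a1 in _chain_diagonal(starts, k, max_seed_gap):
                length = a1 - a0 + 1
                if length < min_length:
                    continue
                b1 = s - a0 + k - 1
                b0 = b1 - length + 1
                if b0 <= a1:
                    continue
                sub_a = sequence[a0: a1 + 1]
                sub_b = _revcomp(sequence[b0: b1 + 1])
                ident = sum(x == y for x, y in zip(sub_a, sub_b)) / length
                if ident >= min_identity:
                    hits.append(RepeatHit(
                        GenomicInterval(chrom, origin + a0, origin + a1),
                        GenomicInterval(chrom, origin + b0, origin + b1),
                        percent_identity=100.0 * ident,
                        orientation="inverted",
                    ))

    # de-duplicate: keep the longest hit among mutually overlapping ones
    hits.sort(
        key=lambda h: h.interval_a.length, reverse=True
    )
    kept: list[RepeatHit] = []
    for h in hits:
        redundant = any(
            h.orientation == g.orientation
            and h.interval_a.overlaps(g.interval_a)
            and h.interval_b.overlaps(g.interval_b)
            for g in kept
        )
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.interval_a.start, h.interval_b.start))
    return kept


# ---------------------------------------------------------------------------
# junction painting
# ---------------------------------------------------------------------------

def _find_with_mismatches(
    haystack: str, pattern: str, must_match: set[int], max_mm: int = 1
) -> int:
    """Count sliding-window matches of pattern with <= max_mm mismatches.

    Positions in ``must_match`` (pattern-relative) must match exactly.
    """
    m = len(pattern)
    count = 0
    for i in range(len(haystack) - m + 1):
        mm = 0
        ok = True
        for j in range(m):
            if haystack[i + j] != pattern[j]:
                if j in must_match:
                    ok = False
                    break
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            count += 1
    return count


def paint_junction(
    junction_seq: str,
    lcr: LcrPair,
    context_k: int = 7,
    junction_id: str = "junction",
    junction_type: str | None = None,
    flank_upstream_seqs: tuple[str, str] | None = None,
    flank_downstream_seqs: tuple[str, str] | None = None,
) -> JunctionPainting:
    """Call each PSV of a junction sequence as left- or right-derived.

    Every PSV is anchored by its exact flanking context (``context_k``
    bases each side, identical between the parental repeats); the base at
    the anchored position decides L or R.  When exact anchoring fails
    (scattered substitutions near breakpoints are common), a fallback
    accepts one mismatch anywhere in the context while requiring the PSV
    base itself to match.  Fewer than 50% callable PSVs raises
    :class:`PaintingError`.

    ``flank_upstream_seqs``/``flank_downstream_seqs`` optionally give the
    reference sequences directly outside the (left, right) repeat copies;
    when provided, the junction's own flanks are classified the same way
    and recorded on the painting.
    """
    junction_seq = junction_seq.upper()
    backbone = lcr.left_seq().upper()
    L = lcr.alignment_length
    k = context_k
    calls = []
    for p, la, ra in zip(
        lcr.psv_positions, lcr.left_alleles, lcr.right_alleles
    ):
        lo = max(p - 1 - k, 0)
        hi = min(p + k, L)
        ctx_l = backbone[lo: p - 1]
        ctx_r = backbone[p: hi]
        psv_j = len(ctx_l)  # PSV offset within the pattern
        pat = {
            "L": ctx_l + la + ctx_r,
            "R": ctx_l + ra + ctx_r,
        }
        n = {allele: junction_seq.count(q) for allele, q in pat.items()}
        if n["L"] + n["R"] == 1:
            calls.append("L" if n["L"] else "R")
            continue
        # fallback: tolerate one substitution outside the PSV base
        n = {
            allele: _find_with_mismatches(junction_seq, q, {psv_j})
            for allele, q in pat.items()
        }
        if n["L"] + n["R"] == 1:
            calls.append("L" if n["L"] else "R")
        else:
            calls.append("X")

    callable_frac = sum(c != "X" for c in calls) / len(calls)
    if callable_frac < 0.5:
        raise PaintingError(
            f"only {callable_frac:.0%} of PSVs callable; painting failed"
        )

    def flank_state(flanks, upstream: bool):
        if flanks is None:
            return None
        left_f, right_f = flanks
        if upstream:
            pats = {
                "L": left_f[-k:].upper() + backbone[:k],
                "R": right_f[-k:].upper() + backbone[:k],
            }
        else:
            pats = {
                "L": backbone[-k:] + left_f[:k].upper(),
                "R": backbone[-k:] + right_f[:k].upper(),
            }
        found = {a: junction_seq.count(q) for a, q in pats.items()}
        if found["L"] + found["R"] == 1:
            return "L" if found["L"] else "R"
        return None

    return JunctionPainting(
        junction_id=junction_id,
        calls="".join(calls),
        junction_type=junction_type,
        flank_upstream=flank_state(flank_upstream_seqs, upstream=True),
        flank_downstream=flank_state(flank_downstream_seqs, upstream=False),
    )


# ---------------------------------------------------------------------------
# switch localization and conversions
# ---------------------------------------------------------------------------

def _first_parent(junction_type: str) -> str:
    if junction_type == "deletion":
        return "L"
    if junction_type == "duplication":
        return "R"
    raise ValueError(f"unknown junction type {junction_type!r}")


def detect_conversions(
    painting: JunctionPainting,
    junction_type: str | None = None,
) -> tuple[int, ...]:
    """Minimal set of PSV flips rendering the call vector a single switch.

    A deletion junction should read L...L R...R (duplication the
    reverse); sites breaking that monotone pattern are gene-conversion
    events.  Among equal-size minimal flip sets the one whose sites lie
    nearest the resulting switch is reported.  X calls are ignored.
    """
    jt = junction_type or painting.junction_type
    informative = [
        (i + 1, c) for i, c in enumerate(painting.calls) if c != "X"
    ]
    if not informative:
        return ()
    m = len(informative)
    directions = [jt] if jt else ["deletion", "duplication"]
    best: tuple[int, float, tuple[int, ...]] | None = None
    for d in directions:
        first = _first_parent(d)
        second = "R" if first == "L" else "L"
        for cut in range(m + 1):
            flips = [
                site for j, (site, call) in enumerate(informative)
                if call != (first if j < cut else second)
            ]
            cost = len(flips)
            # tie-break: total distance of flipped sites to the cut
            dist = sum(abs(j + 0.5 - cut) for j, (site, call) in
                       enumerate(informative) if site in flips)
            cand = (cost, dist, tuple(flips))
            if best is None or cand < best:
                best = cand
    return best[2]


def minimal_flip_bruteforce(
    calls: str, junction_type: str | None = None
) -> int:
    """Exhaustive minimal flip count (oracle; exponential in |calls|)."""
    informative = [c for c in calls if c != "X"]
    m = len(informative)
    directions = (
        [junction_type] if junction_type else ["deletion", "duplication"]
    )

    def monotone(vec, d):
        first = _first_parent(d)
        seen_second = False
        for c in vec:
            if c != first:
                seen_second = True
            elif seen_second:
                return False
        return True

    for size in range(m + 1):
        for subset in combinations(range(m), size):
            vec = [
                ("R" if c == "L" else "L") if i in subset else c
                for i, c in enumerate(informative)
            ]
            if any(monotone(vec, d) for d in directions):
                return size
    return m


def locate_breakpoint(
    painting: JunctionPainting,
    lcr: LcrPair,
) -> tuple[int, int]:
    """Localize the strand exchange to a PSV-delimited interval.

    Conversion sites are masked first; the switch interval then runs from
    the alignment offset of the last first-parent call (or 1, when the
    junction enters on the first-parent flank) to the offset of the first
    second-parent call (or the alignment end).  The result is also stored
    on the painting, together with the interval's index among the
    PSV-delimited bins.
    """
    jt = painting.junction_type
    if jt is None:
        raise ValueError("junction_type must be set to locate a breakpoint")
    first = _first_parent(jt)
    second = "R" if first == "L" else "L"

    conversions = set(detect_conversions(painting, jt))
    effective = []
    for i, (p, c) in enumerate(
        zip(lcr.psv_positions, painting.calls), start=1
    ):
        if c == "X":
            continue
        if i in conversions:
            c = "R" if c == "L" else "L"
        effective.append((p, c))

    # flank states act as pseudo-calls at the alignment bounds
    bound_lo = painting.flank_upstream
    bound_hi = painting.flank_downstream

    seq = []
    if bound_lo is not None:
        seq.append((0, bound_lo))
    seq.extend(effective)
    if bound_hi is not None:
        seq.append((lcr.alignment_length + 1, bound_hi))

    firsts = [p for p, c in seq if c == first]
    seconds = [p for p, c in seq if c == second]
    if not seconds or not firsts:
        raise ValueError(
            "no recombinant junction: calls and flanks are all "
            "one parental type"
        )
    last_first = max(firsts)
    first_second = min(seconds)
    if first_second < last_first:
        raise ValueError("complex junction: multiple switches remain")
    lo = 1 if last_first == 0 else last_first
    hi = (
        lcr.alignment_length
        if first_second == lcr.alignment_length + 1
        else first_second
    )
    painting.switch_interval = (lo, hi)
    painting.conversion_sites = tuple(sorted(conversions))
    return lo, hi


def switch_interval_index(
    interval: tuple[int, int], lcr: LcrPair
) -> int | None:
    """Index (1-based) of a switch interval among the PSV-delimited bins."""
    for i, (lo, hi) in enumerate(psv_intervals(lcr), start=1):
        if interval == (lo, hi):
            return i
    return None


def infer_dsb_region(
    del_intervals: list[tuple[int, int]],
    dup_intervals: list[tuple[int, int]],
    lcr: LcrPair | None = None,
) -> tuple[int, int]:
    """Region containing the initiating double-strand break.

    Under double-Holliday-junction resolution the DSB lies between the
    exchange points seen in deletion and duplication junctions; the union
    span from the leftmost deletion-junction bound to the rightmost
    duplication-junction bound brackets it.
    """
    if not del_intervals or not dup_intervals:
        raise ValueError("need at least one interval from each junction class")
    lo = min(iv[0] for iv in del_intervals)
    hi = max(iv[1] for iv in dup_intervals)
    return lo, hi


def detect_microhomology(
    seq_a_end: str, seq_b_start: str, max_k: int = 20
) -> int:
    """Longest exact suffix(seq_a)/prefix(seq_b) match up to ``max_k``.

    Microhomology at a junction: the 3' end of the first fragment and the
    5' start of the resumed template share this many bases, making the
    exact joining point ambiguous and hinting at a microhomology-mediated
    repair step.
    """
    if len(seq_a_end) < max_k or len(seq_b_start) < max_k:
        raise ValueError(f"both sequences must be at least {max_k} bp")
    a = seq_a_end.upper()
    b = seq_b_start.upper()
    for k in range(max_k, 0, -1):
        if a[-k:] == b[:k]:
            return k
    return 0
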