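"""Multipath intervals: representations for sets of paths between two
coordinates.

Two compact forms are provided, trading expressive power against
conciseness:

* :class:`CriticalSubpathsInterval` — denotes every start-to-end path that
  traverses all of a set of *critical subpaths* (contiguously).  An empty
  critical set is the fully implicit form: all paths between the
  endpoints.
* :class:`FuzzyPathInterval` — denotes every path whose edit distance to a
  *central* single-path interval is strictly below a threshold, under
  either global edit distance or the maximum of local (per-diverging-
  segment) edit distances.

``contains`` is the scalable membership API; ``expand_multipath`` fully
enumerates the denoted set and is meant for desk-scale verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .coordinates import Position, RegionPathPartition, parse_offset
from .errors import (
    EndpointMismatchError,
    ParseError,
    PathOverflowError,
    ValidationError,
)
from .graph import enumerate_paths
from .intervals import (
    SinglePathInterval,
    _end_blocks,
    _start_blocks,
    from_block_path,
    make_interval,
)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit-cost insert/delete/substitute."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class CriticalSubpathsInterval:
    """Denotes all start-to-end paths traversing every critical subpath.

    Critical subpaths are ordered region-path-id lists that must appear
    contiguously (as sublists) in a member's full-form region-path list.
    """

    start: Position
    end: Position
    critical_subpaths: frozenset
    partition: RegionPathPartition = field(compare=False, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "critical_subpaths", frozenset(tuple(cs) for cs in self.critical_subpaths)
        )
        for cs in self.critical_subpaths:
            if not cs:
                raise ValidationError("critical subpath must be non-empty")
            for rp in cs:
                if rp not in self.partition.region_paths:
                    raise ValidationError(f"critical subpath names unknown region path {rp!r}")


@dataclass(frozen=True)
class FuzzyPathInterval:
    """Denotes all paths strictly closer than ``threshold`` edit operations
    to a central single-path interval.

    ``distance_mode`` is ``"global"`` (edit distance between the full
    concatenated sequences) or ``"max_local"`` (maximum edit distance over
    maximal diverging segments, delimited by the region paths shared with
    the central path).  The central path itself (distance 0) is always a
    member.
    """

    central: SinglePathInterval
    threshold: int
    distance_mode: str = "global"

    def __post_init__(self):
        if self.threshold < 1:
            raise ValidationError("fuzzy threshold must be a positive integer")
        if self.distance_mode not in ("global", "max_local"):
            raise ValidationError(f"unknown distance mode {self.distance_mode!r}")

    @property
    def start(self) -> Position:
        return self.central.start

    @property
    def end(self) -> Position:
        return self.central.end

    @property
    def partition(self) -> RegionPathPartition:
        return self.central.partition


MultipathInterval = Union[CriticalSubpathsInterval, FuzzyPathInterval]


# ---------------------------------------------------------------------------
# membership
# ---------------------------------------------------------------------------


def _is_sublist(sub: Sequence, seq: Sequence) -> bool:
    n, m = len(sub), len(seq)
    if n == 0:
        return True
    return any(tuple(seq[i:i + n]) == tuple(sub) for i in range(m - n + 1))


def _check_endpoints(m: MultipathInterval, i: SinglePathInterval):
    if i.start != m.start or i.end != m.end:
        raise EndpointMismatchError(
            f"interval endpoints ({i.start}, {i.end}) do not match the "
            f"multipath interval's ({m.start}, {m.end})"
        )


def _fuzzy_distance(m: FuzzyPathInterval, i: SinglePathInterval) -> int:
    if tuple(i.block_path) == tuple(m.central.block_path):
        return 0
    if m.distance_mode == "global":
        return edit_distance(i.sequence(), m.central.sequence())
    return _max_local_distance(i, m.central)


def _rp_runs(interval: SinglePathInterval):
    p = interval.partition
    runs = []
    for b in interval.block_path:
        rp = p.rp_of_block(b)
        if runs and runs[-1][0] == rp:
            runs[-1][1].append(b)
        else:
            runs.append((rp, [b]))
    return runs


def _lcs_pairs(xs, ys):
    """Index pairs of one longest common subsequence of two id lists."""
    n, m = len(xs), len(ys)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for a in range(n - 1, -1, -1):
        for b in range(m - 1, -1, -1):
            if xs[a] == ys[b]:
                dp[a][b] = dp[a + 1][b + 1] + 1
            else:
                dp[a][b] = max(dp[a + 1][b], dp[a][b + 1])
    pairs = []
    a = b = 0
    while a < n and b < m:
        if xs[a] == ys[b]:
            pairs.append((a, b))
            a += 1
            b += 1
        elif dp[a + 1][b] >= dp[a][b + 1]:
            a += 1
        else:
            b += 1
    return pairs


def _max_local_distance(i: SinglePathInterval, central: SinglePathInterval) -> int:
    """Maximum edit distance over maximal diverging segments.

    The two region-path run lists are anchored on the region paths they
    share (a longest common subsequence, endpoints always included);
    between consecutive anchors, each side's diverging blocks are spelled
    out and compared.
    """
    runs_i = _rp_runs(i)
    runs_c = _rp_runs(central)
    g = i.graph
    pairs = _lcs_pairs([r[0] for r in runs_i], [r[0] for r in runs_c])
    if not pairs or pairs[0] != (0, 0):
        pairs = [(0, 0)] + pairs
    last = (len(runs_i) - 1, len(runs_c) - 1)
    if pairs[-1] != last:
        pairs = pairs + [last]

    def spell(runs, lo, hi):
        return "".join(
            g.blocks[b].sequence
            for _, blocks in runs[lo + 1:hi]
            for b in blocks
        )

    best = 0
    for (a0, b0), (a1, b1) in zip(pairs, pairs[1:]):
        if a1 - a0 <= 1 and b1 - b0 <= 1:
            continue
        best = max(best, edit_distance(spell(runs_i, a0, a1), spell(runs_c, b0, b1)))
    return best


def contains(m: MultipathInterval, i: SinglePathInterval) -> bool:
    """Membership of a single-path interval in a multipath interval.

    The interval must share the multipath interval's endpoints
    (:class:`EndpointMismatchError` otherwise).
    """
    _check_endpoints(m, i)
    if isinstance(m, CriticalSubpathsInterval):
        return all(_is_sublist(cs, i.region_path_ids) for cs in m.critical_subpaths)
    return _fuzzy_distance(m, i) < m.threshold


# ---------------------------------------------------------------------------
# expansion and equality
# ---------------------------------------------------------------------------


def all_single_paths(
    start: Position,
    end: Position,
    p: RegionPathPartition,
    max_paths: int = 10000,
) -> list:
    """Every single-path interval between two coordinates (the implicit
    multipath representation, expanded)."""
    out = []
    seen = set()
    for sb in _start_blocks(p, start):
      for eb in _end_blocks(p, end):
        for path in enumerate_paths(p.graph, sb, eb, max_paths=max_paths):
            try:
                ival = from_block_path(p, path, start, end)
            except ValidationError:
                continue
            if ival.block_path not in seen:
                seen.add(ival.block_path)
                out.append(ival)
    return out


def expand_multipath(
    m: MultipathInterval,
    p: RegionPathPartition,
    max_paths: int = 10000,
) -> frozenset:
    """The exact set of single-path intervals denoted by ``m``.

    Raises :class:`PathOverflowError` past ``max_paths``; use
    :func:`contains` on graphs too large to enumerate.
    """
    return frozenset(
        i for i in all_single_paths(m.start, m.end, p, max_paths=max_paths) if contains(m, i)
    )


@dataclass(frozen=True)
class EqualityResult:
    """Outcome of a multipath equality check.

    ``method`` records the provenance: ``"expansion"`` (extensional,
    decided by enumerating both path sets) or ``"canonical"`` (fallback
    comparison of the representations when enumeration overflowed).
    Truthiness follows ``equal``.
    """

    equal: bool
    method: str

    def __bool__(self):
        return self.equal


def multipath_equal(
    a: MultipathInterval,
    b: MultipathInterval,
    p: RegionPathPartition,
    max_paths: int = 10000,
) -> EqualityResult:
    """Whether two multipath intervals denote the same set of single-path
    intervals.

    Decided by expansion when the graph is enumerable within
    ``max_paths``; otherwise falls back to canonical representation
    equality (same endpoints plus equal critical sets, or equal central
    path, threshold and mode), flagged in the result's ``method``.
    """
    if (a.start, a.end) != (b.start, b.end):
        return EqualityResult(False, "endpoints")
    try:
        ea = expand_multipath(a, p, max_paths=max_paths)
        eb = expand_multipath(b, p, max_paths=max_paths)
        return EqualityResult(ea == eb, "expansion")
    except PathOverflowError:
        if type(a) is not type(b):
            return EqualityResult(False, "canonical")
        if isinstance(a, CriticalSubpathsInterval):
            return EqualityResult(a.critical_subpaths == b.critical_subpaths, "canonical")
        same = (
            tuple(a.central.block_path) == tuple(b.central.block_path)
            and a.threshold == b.threshold
            and a.distance_mode == b.distance_mode
        )
        return EqualityResult(same, "canonical")


# ---------------------------------------------------------------------------
# text form (this package's own dialect)
# ---------------------------------------------------------------------------


def format_multipath(m: MultipathInterval) -> str:
    """Text form: ``(A:0 E:0 critical=C|B,D)`` or
    ``(A:0 E:0 fuzzy=B,C t=2 mode=global)``."""
    head = f"{m.start} {m.end}"
    if isinstance(m, CriticalSubpathsInterval):
        subs = "|".join(",".join(cs) for cs in sorted(m.critical_subpaths))
        return f"({head} critical={subs})"
    inner = ",".join(m.central.region_path_ids[1:-1])
    return f"({head} fuzzy={inner} t={m.threshold} mode={m.distance_mode})"


def parse_multipath(text: str, p: RegionPathPartition) -> MultipathInterval:
    """Inverse of :func:`format_multipath`."""
    s = text.strip()
    if s.startswith("(") and s.endswith(")"):
        s = s[1:-1]
    toks = s.split()
    if len(toks) < 3:
        raise ParseError(f"cannot parse multipath interval {text!r}")

    def parse_pos(tok):
        name, _, off = tok.rpartition(":")
        if not name:
            raise ParseError(f"cannot parse coordinate {tok!r}")
        return Position(name, parse_offset(off))

    start, end = parse_pos(toks[0]), parse_pos(toks[1])
    kv = {}
    for tok in toks[2:]:
        if "=" not in tok:
            raise ParseError(f"unexpected token {tok!r} in {text!r}")
        k, _, v = tok.partition("=")
        kv[k] = v
    if "critical" in kv:
        subs = frozenset(
            tuple(part.split(",")) for part in kv["critical"].split("|") if part
        )
        return CriticalSubpathsInterval(start, end, subs, p)
    if "fuzzy" in kv:
        via = [x for x in kv["fuzzy"].split(",") if x]
        central = make_interval(start, end, via, p)
        return FuzzyPathInterval(
            central,
            int(kv.get("t", "1")),
            kv.get("mode", "global"),
        )
    raise ParseError(f"multipath interval {text!r} has neither critical= nor fuzzy=")
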