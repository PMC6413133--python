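"""Exhaustive short-motif scanning in site-relative regions.

This is the counting core of the package: every k-mer (3-8 nt by default)
observed inside a region of the 400-nt windows is tallied under one of three
modes and ranked by the fraction of windows that contain it.

Scanning modes
--------------
``overlap``
    every match start counts.
``gap``
    greedy left-to-right; after accepting a match at start ``p`` the next
    acceptable start is ``p + gap + 1``.  With ``gap = k - 1`` (the default)
    this is the standard non-overlapping count: e.g. ATATAT occurs once, not
    twice, in ...ATATATAT... at gap 5.
``once``
    at most one occurrence per window - the one whose start position is
    closest to the poly(A) site (ties across the site break upstream).

A match belongs to a region only if the full k-mer lies inside it, which
keeps counts additive over disjoint regions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .seqio import (
    PolyasigError,
    Region,
    SiteWindow,
    index_to_pos,
    to_dna,
    to_rna,
)

MODES = ("overlap", "gap", "once")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of one region scan.

    ``gap=None`` means motif-length-dependent ``k - 1`` (non-overlapping).
    """

    region: Region
    k_min: int = 3
    k_max: int = 8
    mode: str = "gap"
    gap: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.k_min <= self.k_max:
            raise PolyasigError(f"need 1 <= k_min <= k_max, got {self.k_min},{self.k_max}")
        if self.mode not in MODES:
            raise PolyasigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.gap is not None and self.gap < 0:
            raise PolyasigError(f"gap must be >= 0, got {self.gap}")

    def gap_for(self, k: int) -> int:
        return k - 1 if self.gap is None else self.gap


def _normalize_motif(motif: str) -> str:
    m = to_dna(motif)
    if not m or not set(m) <= _VALID:
        raise PolyasigError(f"invalid motif {motif!r}: must be non-empty over A,C,G,U/T")
    return m


def find_starts(seq: str, motif: str) -> list[int]:
    """All (overlapping) 0-based match starts of ``motif`` in ``seq``."""
    starts = []
    i = seq.find(motif)
    while i != -1:
        starts.append(i)
        i = seq.find(motif, i + 1)
    return starts


def _greedy(starts: Sequence[int], gap: int) -> list[int]:
    accepted: list[int] = []
    nxt = 0  # smallest acceptable start
    for p in starts:
        if p >= nxt:
            accepted.append(p)
            nxt = p + gap + 1
    return accepted


def _closest_to_site(starts: Sequence[int], positions: Sequence[int]) -> int:
    # upstream wins ties across the site: |-p| vs |+p| -> upstream
    return min(starts, key=lambda p: (abs(positions[p]), positions[p] > 0))


def count_occurrences(
    seq: str,
    motif: str,
    mode: str = "gap",
    gap: Optional[int] = None,
    site_positions: Optional[Sequence[int]] = None,
) -> tuple[int, list[int]]:
    """Count matches of ``motif`` in ``seq`` under a scanning mode.

    Returns ``(count, starts)`` with 0-based accepted start offsets.  For
    ``once`` mode, ``site_positions`` (site-relative position of each seq
    offset) selects the match closest to the poly(A) site; without it the
    rightmost match is kept (correct for purely upstream sequences).
    A motif longer than the sequence simply has count 0.
    """
    motif = _normalize_motif(motif)
    if mode not in MODES:
        raise PolyasigError(f"mode must be one of {MODES}, got {mode!r}")
    if len(motif) > len(seq):
        return 0, []
    starts = find_starts(seq, motif)
    if mode == "overlap":
        return len(starts), starts
    if mode == "gap":
        g = len(motif) - 1 if gap is None else gap
        if g < 0:
            raise PolyasigError(f"gap must be >= 0, got {g}")
        accepted = _greedy(starts, g)
        return len(accepted), accepted
    # once
    if not starts:
        return 0, []
    if site_positions is None:
        return 1, [starts[-1]]
    return 1, [_closest_to_site(starts, site_positions)]


@dataclass
class MotifTable:
    """Per-region k-mer counts over a window set.

    One row per observed k-mer (RNA alphabet): number of windows with at
    least one in-region occurrence, that number as a percentage of all
    windows, and total occurrences under the scan mode.
    """

    config: ScanConfig
    n_windows: int
    frame: pd.DataFrame = field(repr=False)

    def motifs(self, k: Optional[int] = None) -> pd.DataFrame:
        if k is None:
            return self.frame
        return self.frame[self.frame["k"] == k]

    def frequency(self, motif: str) -> float:
        """frequency_pct of a motif, 0.0 if unobserved."""
        m = to_rna(_normalize_motif(motif))
        rows = self.frame.loc[self.frame["motif"] == m, "frequency_pct"]
        return float(rows.iloc[0]) if len(rows) else 0.0

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _region_kmer_starts(
    window: SiteWindow, region: Region, k: int
) -> dict[str, list[int]]:
    """0-based in-region start offsets per k-mer (N-containing k-mers skipped)."""
    sub = window.slice(region)
    out: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sub) - k + 1):
        kmer = sub[i : i + k]
        if "N" not in kmer:
            out[kmer].append(i)
    return out


def scan_region(windows: Sequence[SiteWindow], config: ScanConfig) -> MotifTable:
    """Exhaustively tally all k-mers of the configured sizes in the region.

    Only observed k-mers are enumerated (hash counting); results are
    identical to enumerating all 4^k strings.
    """
    if not windows:
        raise PolyasigError("scan_region requires at least one window")
    region = config.region
    i0, _ = region.index_span()
    region_positions = [index_to_pos(i0 + off) for off in range(len(region))]

    n_seqs: Counter[str] = Counter()
    total: Counter[str] = Counter()
    for w in windows:
        for k in range(config.k_min, config.k_max + 1):
            if k > len(region):
                continue
            for kmer, starts in _region_kmer_starts(w, region, k).items():
                if config.mode == "overlap":
                    acc = starts
                elif config.mode == "gap":
                    acc = _greedy(starts, config.gap_for(k))
                else:  # once
                    acc = [_closest_to_site(starts, region_positions)]
                if acc:
                    n_seqs[kmer] += 1
                    total[kmer] += len(acc)

    n = len(windows)
    rows = [
        {
            "motif": to_rna(kmer),
            "k": len(kmer),
            "n_seqs_with_hit": n_seqs[kmer],
            "frequency_pct": 100.0 * n_seqs[kmer] / n,
            "total_occurrences": total[kmer],
        }
        for kmer in n_seqs
    ]
    frame = pd.DataFrame(
        rows,
        columns=["motif", "k", "n_seqs_with_hit", "frequency_pct", "total_occurrences"],
    )
    frame = frame.sort_values(
        ["k", "frequency_pct", "total_occurrences", "motif"],
        ascending=[True, False, False, True],
    ).reset_index(drop=True)
    return MotifTable(config=config, n_windows=n, frame=frame)


def top_motifs(table: MotifTable, n: int, k: int) -> pd.DataFrame:
    """Top-``n`` motifs of length ``k`` with 1-based ranks.

    Order: frequency_pct desc, total_occurrences desc, then lexicographic.
    """
    if n < 1:
        raise PolyasigError(f"n must be >= 1, got {n}")
    sub = table.motifs(k).sort_values(
        ["frequency_pct", "total_occurrences", "motif"],
        ascending=[False, False, True],
    )
    out = sub.head(n).reset_index(drop=True).copy()
    out["rank"] = range(1, len(out) + 1)
    return out


@dataclass
class PositionalDistribution:
    """Occurrence counts of one motif by site-relative start position."""

    motif: str
    counts: dict[int, int]
    mode: str

    def total(self) -> int:
        return sum(self.counts.values())

    def positions(self) -> list[int]:
        return sorted(self.counts, key=lambda p: (p > 0, p))

    def to_series(self) -> pd.Series:
        idx = self.positions()
        return pd.Series([self.counts[p] for p in idx], index=idx, name=self.motif)


def positional_distribution(
    windows: Iterable[SiteWindow],
    motif: str,
    mode: str = "gap",
    gap: Optional[int] = None,
    region: Optional[Region] = None,
) -> PositionalDistribution:
    """Where in the window (or region) a motif starts, summed over windows.

    With a ``region``, matches are restricted to it and counted under the
    same mode, so the counts sum to ``scan_region``'s total for that motif.
    """
    m = _normalize_motif(motif)
    region = region or Region("window", -300, 100)
    i0, _ = region.index_span()
    positions = [index_to_pos(i0 + off) for off in range(len(region))]
    counts: dict[int, int] = {}
    for w in windows:
        _, starts = count_occurrences(
            w.slice(region), m, mode=mode, gap=gap, site_positions=positions
        )
        for s in starts:
            p = positions[s]
            counts[p] = counts.get(p, 0) + 1
    return PositionalDistribution(motif=to_rna(m), counts=counts, mode=mode)
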