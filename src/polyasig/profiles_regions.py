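"""Positional nucleotide profiles and data-driven cis-element regions.

The three cis-elements of plant-style poly(A) signals are located relative
to the cleavage site (position -1):

* NUE (near upstream element): bounded by the A/U profile crossings near
  -30 and -10, where signals like AAUAAA and UGUAA concentrate;
* FUE (far upstream element): the diffuse U- or G-rich stretch immediately
  upstream of the NUE, its 5' limit set by where G or U becomes the
  dominant base (fallback -200 when no dominance is seen);
* CE (cleavage element): fixed at -10..+10, carrying the conserved YA/BA
  dinucleotide at -2/-1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .motif_scan import PositionalDistribution
from .seqio import (
    CE_DEFAULT,
    PolyasigError,
    Region,
    SiteWindow,
    WINDOW_LENGTH,
    index_to_pos,
    pos_to_index,
)

PROFILE_BASES = "ACGU"  # row order; internal T reported as U
_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class NucleotideProfile:
    """Per-position base frequencies across a window set.

    ``freq`` is 4 x 400 (rows A, C, G, U; columns positions -300..+100).
    Columns with N calls exclude them from the denominator; each column
    otherwise sums to 1.
    """

    freq: np.ndarray
    n_windows: int

    def base(self, base: str) -> np.ndarray:
        b = base.upper().replace("U", "T")
        return self.freq[_BASE_ROW[b]]

    def column(self, pos: int) -> np.ndarray:
        return self.freq[:, pos_to_index(pos)]

    def to_dataframe(self) -> pd.DataFrame:
        positions = [index_to_pos(i) for i in range(WINDOW_LENGTH)]
        return pd.DataFrame(
            {
                "position": positions,
                "fA": self.freq[0],
                "fC": self.freq[1],
                "fG": self.freq[2],
                "fU": self.freq[3],
            }
        )


def nucleotide_profile(windows: Sequence[SiteWindow]) -> NucleotideProfile:
    """Empirical single-nucleotide profile of a window set."""
    if not windows:
        raise PolyasigError("nucleotide_profile requires at least one window")
    counts = np.zeros((4, WINDOW_LENGTH), dtype=np.int64)
    arr = np.frombuffer(
        "".join(w.sequence for w in windows).encode(), dtype=np.uint8
    ).reshape(len(windows), WINDOW_LENGTH)
    for base, row in _BASE_ROW.items():
        counts[row] = (arr == ord(base)).sum(axis=0)
    denom = counts.sum(axis=0).astype(float)  # excludes N automatically
    denom[denom == 0] = np.nan
    return NucleotideProfile(freq=counts / denom, n_windows=len(windows))


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation (width 1 = identity)."""
    if width <= 1:
        return values
    kernel = np.ones(width)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def find_au_crossings(
    profile: NucleotideProfile,
    search_range: Region,
    smooth: int = 1,
    min_delta: float = 0.0,
    confirm_window: int = 3,
) -> list[int]:
    """Positions where the A and U frequency curves cross, 5'->3'.

    A crossing is reported at position p when fA - fU is exactly zero at p,
    or changes sign between p and the next position.  ``min_delta`` > 0
    demands that the difference reach at least that magnitude with opposite
    signs within ``confirm_window`` positions on each side, which suppresses
    the spurious sign flips of a noisy, nearly flat profile.
    """
    d = _smooth(profile.base("A") - profile.base("U"), smooth)
    i_lo, i_hi = search_range.index_span()
    out = []
    for i in range(i_lo, i_hi + 1):
        here = d[i]
        if here == 0.0:
            is_crossing = True
        elif i + 1 < WINDOW_LENGTH and here * d[i + 1] < 0:
            is_crossing = True
        else:
            is_crossing = False
        if not is_crossing:
            continue
        if min_delta > 0.0:
            before = d[max(i - confirm_window, 0) : i + 1]
            after = d[i : min(i + confirm_window, WINDOW_LENGTH - 1) + 1]
            lo = min(before.min(), after.min())
            hi = max(before.max(), after.max())
            if not (lo <= -min_delta and hi >= min_delta):
                continue
        out.append(index_to_pos(i))
    return out


@dataclass
class RegionSet:
    """The three cis-element regions plus how they were obtained."""

    fue: Region
    nue: Region
    ce: Region
    provenance: str = "auto"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": ["FUE", "NUE", "CE"],
                "start": [self.fue.start, self.nue.start, self.ce.start],
                "end": [self.fue.end, self.nue.end, self.ce.end],
                "provenance": [self.provenance] * 3,
            }
        )


def manual_regions(fue: tuple[int, int], nue: tuple[int, int]) -> RegionSet:
    return RegionSet(
        fue=Region("FUE", *fue),
        nue=Region("NUE", *nue),
        ce=CE_DEFAULT,
        provenance="manual",
    )


def _dominant_mask(profile: NucleotideProfile, margin: float) -> np.ndarray:
    """True where G or U exceeds every other base frequency by >= margin."""
    f = profile.freq
    mask = np.zeros(WINDOW_LENGTH, dtype=bool)
    for row in (2, 3):  # G, U
        others = np.delete(f, row, axis=0).max(axis=0)
        mask |= f[row] - others >= margin
    return mask


def infer_regions(
    profile: NucleotideProfile,
    motif_distribution: Optional[PositionalDistribution] = None,
    *,
    min_windows: int = 50,
    nue_start_search: tuple[int, int] = (-45, -20),
    nue_end_search: tuple[int, int] = (-20, -5),
    nue_fallback: tuple[int, int] = (-30, -10),
    smooth: int = 5,
    min_delta: float = 0.05,
    dominance_margin: float = 0.05,
    dominance_run: int = 20,
    fue_fallback_start: int = -200,
    coverage: float = 0.9,
) -> RegionSet:
    """Infer FUE/NUE/CE from a nucleotide profile.

    NUE start is the first A/U crossing found in ``nue_start_search`` and
    NUE end the last one in ``nue_end_search`` (fallbacks -30 / -10 when no
    crossing qualifies).  Crossing detection runs on a smoothed profile with
    a magnitude confirmation; dominance for the FUE start is judged on the
    raw profile: the 5'-most run of >= ``dominance_run`` consecutive
    positions where G or U leads every other base by >= ``dominance_margin``,
    else the -200 fallback.  When a motif positional distribution is given,
    the NUE is widened until it covers at least ``coverage`` of that motif's
    occurrences.  Raises when the profile comes from fewer than
    ``min_windows`` windows (use :func:`manual_regions` instead).
    """
    if profile.n_windows < min_windows:
        raise PolyasigError(
            f"profile built from {profile.n_windows} windows < {min_windows}; "
            "supply manual regions instead"
        )
    starts = find_au_crossings(
        profile, Region("nue-start", *nue_start_search), smooth, min_delta
    )
    ends = find_au_crossings(
        profile, Region("nue-end", *nue_end_search), smooth, min_delta
    )
    nue_start = starts[0] if starts else nue_fallback[0]
    nue_end = ends[-1] if ends else nue_fallback[1]

    if motif_distribution is not None and motif_distribution.total() > 0:
        k = len(motif_distribution.motif)
        occ_starts = sorted(
            itertools.chain.from_iterable(
                [p] * c for p, c in motif_distribution.counts.items()
            )
        )
        tail = (1.0 - coverage) / 2.0
        n = len(occ_starts)
        lo = occ_starts[int(tail * n)]
        hi_start = occ_starts[min(int((1.0 - tail) * n), n - 1)]
        hi = index_to_pos(min(pos_to_index(hi_start) + k - 1, WINDOW_LENGTH - 1))
        nue_start = min(nue_start, lo)
        nue_end = max(nue_end, hi)

    if nue_end <= nue_start:
        nue_end = nue_fallback[1]
    nue = Region("NUE", nue_start, nue_end)

    fue_end_idx = pos_to_index(nue_start) - 1
    mask = _dominant_mask(profile, dominance_margin)[: fue_end_idx + 1]
    fue_start = None
    run = 0
    for i, ok in enumerate(mask):
        run = run + 1 if ok else 0
        if run >= dominance_run:
            fue_start = index_to_pos(i - run + 1)
            break
    if fue_start is None:
        fue_start = fue_fallback_start
    fue = Region("FUE", fue_start, index_to_pos(fue_end_idx))
    return RegionSet(fue=fue, nue=nue, ce=CE_DEFAULT, provenance="auto")


@dataclass
class DinucleotideTable:
    """Frequencies of the 16 dinucleotides at positions (-2, -1).

    ``ya`` = UA + CA; ``ba`` = UA + CA + GA.  Windows with an N at either
    position are excluded from the denominator (``n_excluded``).
    """

    counts: dict[str, int]
    frequencies: dict[str, float]
    ya: float
    ba: float
    n_windows: int
    n_excluded: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"dinucleotide": d, "count": self.counts[d], "frequency": self.frequencies[d]}
            for d in sorted(self.counts)
        ]
        return pd.DataFrame(rows)


def cleavage_dinucleotide(windows: Sequence[SiteWindow]) -> DinucleotideTable:
    """Tally the dinucleotide spanning the cleavage site (-2, -1)."""
    if not windows:
        raise PolyasigError("cleavage_dinucleotide requires at least one window")
    i2, i1 = pos_to_index(-2), pos_to_index(-1)
    raw: dict[str, int] = {}
    excluded = 0
    for w in windows:
        d = w.sequence[i2] + w.sequence[i1]
        if "N" in d:
            excluded += 1
            continue
        raw[d] = raw.get(d, 0) + 1
    n_valid = len(windows) - excluded
    if n_valid == 0:
        raise PolyasigError("all windows have N at the cleavage dinucleotide")
    dinucs = ["".join(p).replace("T", "U") for p in itertools.product("ACGU", repeat=2)]
    counts = {d: raw.get(d.replace("U", "T"), 0) for d in dinucs}
    freqs = {d: c / n_valid for d, c in counts.items()}
    ya = freqs["UA"] + freqs["CA"]
    ba = ya + freqs["GA"]
    return DinucleotideTable(
        counts=counts,
        frequencies=freqs,
        ya=ya,
        ba=ba,
        n_windows=len(windows),
        n_excluded=excluded,
    )
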