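"""Internal-priming filtering and site deduplication.

Oligo(dT) priming inside a genomic adenine run produces a cDNA whose apparent
poly(A) tail is templated, so the mapped "cleavage site" is an artifact.  A
window is flagged as internal priming when the genomic sequence covering
site-relative positions -10..+10 (20 bases; there is no position 0) either

* contains a run of >= 6 consecutive A, or
* has any 10-nt sliding window (11 of them, step 1) with >= 7 A.

N counts as non-A, which errs on the side of retaining sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqio import PolyASite, Region, SiteWindow

PRIMING_REGION = Region("priming", -10, 10)
_RUN_LEN = 6
_WIN_LEN = 10
_WIN_A = 7


def is_internal_priming(window: SiteWindow) -> tuple[bool, Optional[str]]:
    """Return (flag, reason) for one window.

    ``reason`` is ``"run6"`` when a >=6-base A-run fires, ``"win7of10"`` when
    only the 7-of-10 rule fires, ``None`` when the window is clean.  The run
    may straddle the cleavage site.
    """
    seg = window.slice(PRIMING_REGION)
    run = best = 0
    for c in seg:
        run = run + 1 if c == "A" else 0
        best = max(best, run)
    if best >= _RUN_LEN:
        return True, "run6"
    a = [c == "A" for c in seg]
    count = sum(a[:_WIN_LEN])
    if count >= _WIN_A:
        return True, "win7of10"
    for i in range(_WIN_LEN, len(a)):
        count += a[i] - a[i - _WIN_LEN]
        if count >= _WIN_A:
            return True, "win7of10"
    return False, None


def dedupe_sites(sites: Iterable[PolyASite]) -> list[PolyASite]:
    """Collapse sites identical in (contig, coord, strand), summing support.

    Output is sorted by (contig, coord, strand) for determinism.
    """
    merged: dict[tuple[str, int, str], int] = {}
    for s in sites:
        merged[s.key] = merged.get(s.key, 0) + s.support
    return [
        PolyASite(contig, coord, strand, support)
        for (contig, coord, strand), support in sorted(merged.items())
    ]


@dataclass
class FilterReport:
    """Fate accounting for a filtering pass; every input site gets exactly
    one fate, so the four outcome counts sum to ``n_input``."""

    n_input: int = 0
    n_internal_priming: int = 0
    n_duplicates_collapsed: int = 0
    n_out_of_bounds: int = 0
    n_retained: int = 0

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_internal_priming
            + self.n_out_of_bounds
            + self.n_duplicates_collapsed
        )
        if total != self.n_input:
            raise AssertionError(
                f"filter report does not conserve counts: {total} != {self.n_input}"
            )


def filter_windows(
    windows: Sequence[SiteWindow],
    n_duplicates_collapsed: int = 0,
    n_out_of_bounds: int = 0,
) -> tuple[list[SiteWindow], FilterReport]:
    """Drop internal-priming windows, preserving input order.

    ``n_duplicates_collapsed`` / ``n_out_of_bounds`` fold counts from earlier
    pipeline stages into the report so the conservation identity covers the
    whole run, not just this call.
    """
    retained = [w for w in windows if not is_internal_priming(w)[0]]
    report = FilterReport(
        n_input=len(windows) + n_duplicates_collapsed + n_out_of_bounds,
        n_internal_priming=len(windows) - len(retained),
        n_duplicates_collapsed=n_duplicates_collapsed,
        n_out_of_bounds=n_out_of_bounds,
        n_retained=len(retained),
    )
    report.check()
    return retained, report
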