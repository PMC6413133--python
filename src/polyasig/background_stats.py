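"""Markov background models and Z-scores for motif over-representation.

The expected count of a word w in the scanned region is modeled with an
order-m Markov chain fitted to the same sequences: E = T * P(w) with T the
number of possible start positions, P(w) the chain probability of w, and the
binomial standard deviation sd = sqrt(T * P(w) * (1 - P(w))).  The reported
score is z = (observed - E) / sd, with observed counted in overlap mode so
that it matches the all-start-positions expectation.

Order and significance cutoff follow motif length: triplets and tetramers
are too short to support a high-order chain, so they use an order-1 model
with cutoff z >= 5; pentamers through octamers use an order-3 model with
cutoff z >= 3.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .motif_scan import ScanConfig, _normalize_motif, scan_region
from .seqio import PolyasigError, Region, SiteWindow, to_rna

BASES = "ACGT"
DEFAULT_PSEUDOCOUNT = 0.25


@dataclass
class MarkovBackground:
    """Order-m chain: stationary m-mer distribution plus transition rows.

    Probabilities are maximum-likelihood frequencies over all N-free
    in-region (m+1)-mers, with an add-``pseudocount`` cell prior so unseen
    contexts stay usable; every transition row sums to 1 and the initial
    distribution covers all 4^m contexts.
    """

    order: int
    initial: dict[str, float]
    transitions: dict[str, dict[str, float]]
    trained_on: str
    n_train_positions: int
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def word_probability(self, motif: str) -> float:
        """Chain probability of a word: P(prefix) * prod P(next | context)."""
        w = _normalize_motif(motif)
        m = self.order
        if len(w) < m + 1:
            raise PolyasigError(
                f"motif {motif!r} shorter than order+1 = {m + 1}"
            )
        p = self.initial[w[:m]] if m else 1.0
        for j in range(m, len(w)):
            p *= self.transitions[w[j - m : j]][w[j]]
        return p


def fit_markov(
    windows: Sequence[SiteWindow],
    region: Region,
    order: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MarkovBackground:
    """Fit an order-m background to the in-region sequence of every window."""
    if order < 0:
        raise PolyasigError(f"order must be >= 0, got {order}")
    if len(region) < order + 1:
        raise PolyasigError(
            f"region {region.label} (length {len(region)}) too short for order {order}"
        )
    m = order
    ctx_counts: dict[str, float] = {}
    trans_counts: dict[str, dict[str, float]] = {}
    n_positions = 0
    for w in windows:
        sub = w.slice(region)
        for i in range(len(sub) - m):
            word = sub[i : i + m + 1]
            if "N" in word:
                continue
            ctx, nxt = word[:m], word[m]
            ctx_counts[ctx] = ctx_counts.get(ctx, 0.0) + 1.0
            trans_counts.setdefault(ctx, {})[nxt] = (
                trans_counts.get(ctx, {}).get(nxt, 0.0) + 1.0
            )
            n_positions += 1
    if n_positions == 0:
        raise PolyasigError("no N-free training positions in region")

    contexts = ["".join(c) for c in itertools.product(BASES, repeat=m)]
    total = n_positions + pseudocount * len(contexts)
    initial = {c: (ctx_counts.get(c, 0.0) + pseudocount) / total for c in contexts}
    transitions = {}
    for c in contexts:
        row = trans_counts.get(c, {})
        row_total = sum(row.values()) + pseudocount * 4
        transitions[c] = {
            b: (row.get(b, 0.0) + pseudocount) / row_total for b in BASES
        }
    return MarkovBackground(
        order=order,
        initial=initial,
        transitions=transitions,
        trained_on=f"{region.label}:{region.start}..{region.end}",
        n_train_positions=n_positions,
        pseudocount=pseudocount,
    )


def word_probability(bg: MarkovBackground, motif: str) -> float:
    return bg.word_probability(motif)


def significance_policy(k: int) -> tuple[int, float]:
    """Markov order and Z cutoff by motif length: {3,4} -> (1, 5.0);
    {5..8} -> (3, 3.0)."""
    if k in (3, 4):
        return 1, 5.0
    if 5 <= k <= 8:
        return 3, 3.0
    raise PolyasigError(f"motif length {k} outside supported range 3..8")


@dataclass
class ZScoreResult:
    motif: str
    observed: int
    expected: float
    sd: float
    z: float
    order_used: int
    cutoff: float
    significant: bool


def zscore_from_counts(
    observed: int,
    p: float,
    total_positions: int,
    *,
    motif: str = "",
    order: int = 0,
    cutoff: float = 3.0,
) -> ZScoreResult:
    """Binomial z from an observed count, word probability and position count."""
    expected = total_positions * p
    var = total_positions * p * (1.0 - p)
    if var <= 0.0:
        raise PolyasigError(f"degenerate background for motif {motif!r} (sd = 0)")
    sd = math.sqrt(var)
    z = (observed - expected) / sd
    return ZScoreResult(
        motif=motif,
        observed=observed,
        expected=expected,
        sd=sd,
        z=z,
        order_used=order,
        cutoff=cutoff,
        significant=z >= cutoff,
    )


def total_start_positions(windows: Sequence[SiteWindow], region: Region, k: int) -> int:
    """Number of possible k-mer start positions across windows' region."""
    per_window = max(len(region) - k + 1, 0)
    return per_window * len(windows)


def zscore(
    observed: int,
    bg: MarkovBackground,
    motif: str,
    windows: Sequence[SiteWindow],
    region: Region,
    cutoff: Optional[float] = None,
) -> ZScoreResult:
    """Z-score of an overlap-mode observed count against a fitted background.

    The cutoff defaults to the length policy (5.0 for k<=4, 3.0 for k>=5).
    """
    w = _normalize_motif(motif)
    k = len(w)
    if cutoff is None:
        _, cutoff = significance_policy(k)
    T = total_start_positions(windows, region, k)
    p = bg.word_probability(w)
    res = zscore_from_counts(
        observed, p, T, motif=to_rna(w), order=bg.order, cutoff=cutoff
    )
    return res


def zscore_scan(
    windows: Sequence[SiteWindow],
    region: Region,
    k_min: int = 3,
    k_max: int = 8,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    train_region: Optional[Region] = None,
) -> pd.DataFrame:
    """Score every observed k-mer in a region against the policy background.

    Observed counts use overlap mode; one background per motif length is
    fitted on ``train_region`` (default: the scanned region itself).
    Returns a DataFrame with columns motif, k, observed, expected, sd, z,
    order, cutoff, significant.
    """
    train_region = train_region or region
    counts = scan_region(
        windows, ScanConfig(region=region, k_min=k_min, k_max=k_max, mode="overlap")
    )
    backgrounds: dict[int, MarkovBackground] = {}
    rows = []
    for rec in counts.frame.itertuples(index=False):
        k = rec.k
        order, cutoff = significance_policy(k)
        if order not in backgrounds:
            backgrounds[order] = fit_markov(
                windows, train_region, order, pseudocount=pseudocount
            )
        res = zscore(
            rec.total_occurrences,
            backgrounds[order],
            rec.motif,
            windows,
            region,
            cutoff=cutoff,
        )
        rows.append(
            {
                "motif": res.motif,
                "k": k,
                "observed": res.observed,
                "expected": res.expected,
                "sd": res.sd,
                "z": res.z,
                "order": res.order_used,
                "cutoff": res.cutoff,
                "significant": res.significant,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "motif", "k", "observed", "expected", "sd", "z",
            "order", "cutoff", "significant",
        ],
    )
    return frame.sort_values(["k", "z"], ascending=[True, False]).reset_index(drop=True)
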