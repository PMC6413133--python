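"""Canonical-signal variant groups, position frequency matrices and PSSMs.

A canonical poly(A) signal (UGUAA, AAUAAA, ...) rarely acts alone: its
single-nucleotide variants carry substantial signal mass.  This module
enumerates the Hamming-distance-1 neighborhood of a canonical signal, pulls
the variants that appear among the top-ranked k-mers of a motif table into a
group with the canonical, and summarizes the group as a frequency-weighted
position frequency matrix (PFM) and its log-odds scoring matrix (PSSM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .motif_scan import MotifTable, ScanConfig, _normalize_motif, scan_region, top_motifs
from .seqio import PolyasigError, Region, SiteWindow, to_rna

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"
_ROW = {b: i for i, b in enumerate(RNA_BASES)}

#: Fixed scan regions used for cross-species canonical-signal comparisons.
CANONICAL_COMPARE_REGIONS = {
    "UGUAA": Region("UGUAA-compare", -80, -15),
    "AAUAAA": Region("AAUAAA-compare", -50, -15),
}


def enumerate_snv(canonical: str) -> list[str]:
    """All 3k motifs at Hamming distance exactly 1, lexicographic, RNA."""
    c = to_rna(_normalize_motif(canonical))
    variants = {
        c[:i] + b + c[i + 1 :]
        for i in range(len(c))
        for b in RNA_BASES
        if b != c[i]
    }
    return sorted(variants)


@dataclass
class VariantGroup:
    """A canonical signal with its observed single-nucleotide variants.

    ``combined_frequency_pct`` is the plain sum of member per-transcript
    frequencies; a window carrying two members is counted in both, so the
    sum is a signal-mass tabulation, not a per-window detection rate.
    """

    canonical: str
    members: list[tuple[str, float]]
    combined_frequency_pct: float
    source_top_n: int

    def member_frequency(self, motif: str) -> float:
        for m, f in self.members:
            if m == motif:
                return f
        return 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.members, columns=["motif", "frequency_pct"])


def compile_variant_group(
    table: MotifTable, canonical: str, top_n: int = 100
) -> VariantGroup:
    """Collect the canonical plus its SNVs found in the table's top ranks.

    The canonical is always a member (frequency 0 with a warning when it is
    absent from the table); variants contribute only when they rank within
    ``top_n`` among same-length motifs.
    """
    c = to_rna(_normalize_motif(canonical))
    k = len(c)
    ranked = top_motifs(table, top_n, k)
    in_top = dict(zip(ranked["motif"], ranked["frequency_pct"]))
    canon_freq = table.frequency(c)
    if canon_freq == 0.0:
        logger.warning("canonical signal %s absent from motif table", c)
    members = [(c, canon_freq)]
    for v in enumerate_snv(c):
        if v in in_top:
            members.append((v, float(in_top[v])))
    return VariantGroup(
        canonical=c,
        members=members,
        combined_frequency_pct=float(sum(f for _, f in members)),
        source_top_n=top_n,
    )


@dataclass
class PositionFrequencyMatrix:
    """4 x k base frequencies per motif column (rows A, C, G, U)."""

    matrix: np.ndarray
    motif_length: int

    def consensus(self) -> str:
        return "".join(RNA_BASES[i] for i in self.matrix.argmax(axis=0))

    def column_max(self) -> np.ndarray:
        """Per-column conservation: the dominant base's frequency."""
        return self.matrix.max(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=list(RNA_BASES),
            columns=[f"pos{j + 1}" for j in range(self.motif_length)],
        )


def build_pfm(group: VariantGroup) -> PositionFrequencyMatrix:
    """Frequency-weighted base distribution per motif column over members."""
    weights = [f for _, f in group.members]
    if sum(weights) <= 0:
        raise PolyasigError(
            f"variant group {group.canonical} has no positive member frequencies"
        )
    k = len(group.canonical)
    m = np.zeros((4, k))
    for motif, f in group.members:
        for j, b in enumerate(motif):
            m[_ROW[b], j] += f
    m /= m.sum(axis=0, keepdims=True)
    return PositionFrequencyMatrix(matrix=m, motif_length=k)


@dataclass
class PSSM:
    """Log2-odds of PFM frequencies (with pseudocount) over a background."""

    matrix: np.ndarray
    motif_length: int
    background: np.ndarray

    def score(self, kmer: str) -> float:
        s = to_rna(_normalize_motif(kmer))
        if len(s) != self.motif_length:
            raise PolyasigError(
                f"k-mer {kmer!r} length {len(s)} != PSSM length {self.motif_length}"
            )
        return float(sum(self.matrix[_ROW[b], j] for j, b in enumerate(s)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=list(RNA_BASES),
            columns=[f"pos{j + 1}" for j in range(self.motif_length)],
        )


def build_pssm(
    pfm: PositionFrequencyMatrix,
    background: Optional[Sequence[float]] = None,
    pseudocount: float = 0.01,
) -> PSSM:
    """Log-odds matrix: log2((pfm + pseudocount, renormalized) / background)."""
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6) or (bg <= 0).any():
        raise PolyasigError("background must be 4 positive frequencies summing to 1")
    p = pfm.matrix + pseudocount
    p /= p.sum(axis=0, keepdims=True)
    return PSSM(
        matrix=np.log2(p / bg[:, None]),
        motif_length=pfm.motif_length,
        background=bg,
    )


def pssm_score(pssm: PSSM, seq_kmer: str) -> float:
    return pssm.score(seq_kmer)


def canonical_signal_frequencies(
    windows: Sequence[SiteWindow],
    signals: Optional[dict[str, Region]] = None,
    mode: str = "gap",
) -> pd.DataFrame:
    """Per-transcript frequency of each canonical signal in its fixed
    comparison region (UGUAA in -80..-15, AAUAAA in -50..-15 by default).

    These are the coordinates used to place species on a UGUAA-vs-AAUAAA
    frequency plane.
    """
    signals = signals or CANONICAL_COMPARE_REGIONS
    rows = []
    for sig, region in signals.items():
        k = len(sig)
        table = scan_region(
            windows, ScanConfig(region=region, k_min=k, k_max=k, mode=mode)
        )
        rows.append(
            {
                "signal": to_rna(sig),
                "region_start": region.start,
                "region_end": region.end,
                "frequency_pct": table.frequency(sig),
            }
        )
    return pd.DataFrame(rows)
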