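"""Seeded generator of genomes, poly(A) sites and windows with known truth.

The generator emulates the statistical architecture the analysis assumes: a
400-nt window whose segments have distinct base compositions (uniform far
upstream, a U-rich FUE, an A-rich NUE, a U-rich CE, uniform downstream), a
signal motif planted at a random position of a stated interval with
probability pi, a cleavage dinucleotide written at -2/-1 with probability
rho, internal-priming decoys (a 6-base A-run inside -10..+10) with
probability q, and duplicate site rows for deduplication testing.  Every
emitted window is embedded in a contig with full flanks so that extraction
is exercised without truncation, and a truth table records per-site ground
truth.  Output is bit-reproducible for a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import (
    GenomeSequence,
    PolyASite,
    PolyasigError,
    Region,
    SiteWindow,
    WINDOW_LENGTH,
    extract_windows,
    index_to_pos,
    pos_to_index,
    to_dna,
)

DNA_BASES = "ACGT"

#: Default per-segment compositions (A, C, G, T).  The FUE/NUE boundary
#: composition flip (U-rich to A-rich at -32/-31) puts the A/U profile
#: crossings at -32 and -12; mirrored margins (|fA - fU| = 0.3 on both
#: sides) keep the crossing positions stable under profile smoothing.
DEFAULT_SEGMENTS: dict[str, tuple[Region, tuple[float, float, float, float]]] = {
    "upstream": (Region("upstream", -300, -181), (0.25, 0.25, 0.25, 0.25)),
    "fue": (Region("fue", -180, -32), (0.15, 0.20, 0.20, 0.45)),
    "nue": (Region("nue", -31, -12), (0.45, 0.20, 0.20, 0.15)),
    "ce": (Region("ce", -11, 10), (0.15, 0.20, 0.20, 0.45)),
    "downstream": (Region("downstream", 11, 100), (0.25, 0.25, 0.25, 0.25)),
}

PRIMING_REGION = Region("priming", -10, 10)
_DECOY = "A" * 6


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise PolyasigError(f"{name} must be in [0,1], got {value}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated site set.

    ``segments`` maps labels to (region, composition) pairs that must tile
    -300..+100; ``plant_interval`` must admit the full motif.
    """

    n_sites: int = 2000
    seed: int = 0
    segments: dict[str, tuple[Region, tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS)
    )
    planted_motif: str = "UGUAA"
    plant_prob: float = 0.5
    plant_interval: Region = Region("plant", -30, -15)
    ce_dinucleotide: str = "CA"
    ce_dinucleotide_prob: float = 0.7
    priming_decoy_prob: float = 0.0
    duplicate_site_rate: float = 0.0
    contig_id: str = "sim1"
    spacing: int = 100

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise PolyasigError(f"n_sites must be >= 1, got {self.n_sites}")
        for name in ("plant_prob", "ce_dinucleotide_prob", "priming_decoy_prob",
                     "duplicate_site_rate"):
            _check_probability(name, getattr(self, name))
        covered = sorted(
            i for region, _ in self.segments.values()
            for i in range(*region.index_span())
        )
        indices = {
            i for region, comp in self.segments.values()
            for i in range(region.index_span()[0], region.index_span()[1] + 1)
        }
        if indices != set(range(WINDOW_LENGTH)):
            raise PolyasigError("segment regions must tile -300..+100 exactly")
        if len(covered) != WINDOW_LENGTH - len(self.segments):
            raise PolyasigError("segment regions overlap")
        for _, comp in self.segments.values():
            if len(comp) != 4 or abs(sum(comp) - 1.0) > 1e-9 or min(comp) < 0:
                raise PolyasigError("each composition needs 4 probabilities summing to 1")
        motif = to_dna(self.planted_motif)
        if len(motif) > len(self.plant_interval):
            raise PolyasigError(
                f"motif {self.planted_motif!r} does not fit interval "
                f"{self.plant_interval.start}..{self.plant_interval.end}"
            )

    def composition_by_index(self) -> np.ndarray:
        """400 x 4 matrix of per-position base probabilities."""
        out = np.empty((WINDOW_LENGTH, 4))
        for region, comp in self.segments.values():
            i0, i1 = region.index_span()
            out[i0 : i1 + 1] = comp
        return out


@dataclass
class SimResult:
    genomes: dict[str, GenomeSequence]
    sites: list[PolyASite]
    truth: pd.DataFrame


def _plant_starts(config: SimConfig) -> list[int]:
    """Window indices where the planted motif fits fully inside the interval."""
    i0, i1 = config.plant_interval.index_span()
    k = len(to_dna(config.planted_motif))
    return list(range(i0, i1 - k + 2))


def simulate(config: SimConfig) -> SimResult:
    """Generate (genome, site table, truth table) under the configured
    conditions; identical config and seed give identical output."""
    rng = np.random.default_rng(config.seed)
    comp = config.composition_by_index()
    motif = to_dna(config.planted_motif)
    plant_starts = _plant_starts(config)
    dinuc = to_dna(config.ce_dinucleotide)
    i_dinuc = pos_to_index(-2)
    decoy_i0, decoy_i1 = PRIMING_REGION.index_span()
    decoy_starts = list(range(decoy_i0, decoy_i1 - len(_DECOY) + 2))

    base_arr = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8)
    cum = comp.cumsum(axis=1)

    windows_seq: list[str] = []
    truth_rows = []
    for i in range(config.n_sites):
        u = rng.random((WINDOW_LENGTH, 1))
        draw = (u < cum).argmax(axis=1)
        w = bytearray(base_arr[draw].tobytes())

        planted = rng.random() < config.plant_prob
        plant_idx = -1
        if planted:
            plant_idx = int(rng.choice(plant_starts))
            w[plant_idx : plant_idx + len(motif)] = motif.encode()

        if rng.random() < config.ce_dinucleotide_prob:
            w[i_dinuc : i_dinuc + len(dinuc)] = dinuc.encode()

        decoy = rng.random() < config.priming_decoy_prob
        decoy_idx = -1
        if decoy:
            decoy_idx = int(rng.choice(decoy_starts))
            w[decoy_idx : decoy_idx + len(_DECOY)] = _DECOY.encode()

        windows_seq.append(w.decode())
        truth_rows.append(
            {
                "site_index": i,
                "planted": planted,
                "plant_pos": _index_to_pos_safe(plant_idx),
                "decoy": decoy,
                "decoy_pos": _index_to_pos_safe(decoy_idx),
                "duplicate_of": -1,
            }
        )

    # assemble one contig: [pad][win0][pad][win1]...[pad]
    pad = config.spacing
    pieces = []
    sites = []
    for i, seq in enumerate(windows_seq):
        gap = "".join(rng.choice(list(DNA_BASES), size=pad))
        pieces.append(gap)
        offset = len(gap) + sum(len(p) for p in pieces[:-1])  # 0-based window start
        pieces.append(seq)
        coord = offset + 300  # 1-based coordinate of the base at position -1
        sites.append(PolyASite(config.contig_id, coord, "+", 1))
    pieces.append("".join(rng.choice(list(DNA_BASES), size=pad)))
    contig = GenomeSequence(config.contig_id, "".join(pieces))

    # duplicate site rows (same key; dedupe_sites should fold them back)
    all_sites = []
    for i, s in enumerate(sites):
        all_sites.append(s)
        if rng.random() < config.duplicate_site_rate:
            all_sites.append(s)
            truth_rows.append(
                {
                    "site_index": len(truth_rows),
                    "planted": truth_rows[i]["planted"],
                    "plant_pos": truth_rows[i]["plant_pos"],
                    "decoy": truth_rows[i]["decoy"],
                    "decoy_pos": truth_rows[i]["decoy_pos"],
                    "duplicate_of": i,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["site_index", "planted", "plant_pos", "decoy", "decoy_pos",
                 "duplicate_of"],
    )
    return SimResult(genomes={contig.contig_id: contig}, sites=all_sites, truth=truth)


def _index_to_pos_safe(idx: int) -> int:
    return index_to_pos(idx) if idx >= 0 else 0  # 0 = "not applicable"


def simulate_windows(config: SimConfig) -> tuple[list[SiteWindow], pd.DataFrame]:
    """Convenience: simulate and extract the unique-site windows.

    Duplicate site rows are folded away (first occurrence kept) and the
    returned truth table is row-aligned with the windows.
    """
    res = simulate(config)
    seen: set = set()
    originals = []
    for s in res.sites:
        if s.key not in seen:
            seen.add(s.key)
            originals.append(s)
    windows, log = extract_windows(res.genomes, originals)
    if log.n_dropped:
        raise AssertionError("generator geometry must never truncate windows")
    truth = res.truth[res.truth["duplicate_of"] == -1].reset_index(drop=True)
    assert len(windows) == len(truth)
    return windows, truth


def expected_frequency(config: SimConfig, region: Optional[Region] = None) -> float:
    """Analytic per-window detection probability of the planted motif.

    pi + (1 - pi) * P(background hit), where the background term is the
    complement-product over every start position in ``region`` (default:
    the plant interval's segment geometry, i.e. the NUE segment) of the
    position-specific word probability.  Background hits inside planted
    windows are ignored, making this a slight underestimate; fine within
    sampling tolerances.
    """
    motif = to_dna(config.planted_motif)
    k = len(motif)
    region = region or config.segments["nue"][0]
    comp = config.composition_by_index()
    i0, i1 = region.index_span()
    miss = 1.0
    col = {b: j for j, b in enumerate(DNA_BASES)}
    for start in range(i0, i1 - k + 2):
        p = 1.0
        for j, b in enumerate(motif):
            p *= comp[start + j, col[b]]
        miss *= 1.0 - p
    return config.plant_prob + (1.0 - config.plant_prob) * (1.0 - miss)
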