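"""Shared fixtures: hand-built windows and seeded generator outputs."""

from __future__ import annotations

import pytest

from polyasig import PolyASite, SimConfig, SiteWindow, pos_to_index, simulate_windows

DUMMY_SITE = PolyASite("chrT", 1000, "+")


def make_window(sequence: str = None, fill: str = "C", patches: dict[int, str] = None) -> SiteWindow:
    """Build a 400-nt window from a fill base with site-relative patches.

    ``patches`` maps a site-relative position to a string written starting
    there (e.g. {-30: "TGTAA"} plants TGTAA with its first base at -30).
    """
    if sequence is None:
        seq = bytearray(fill.encode() * 400)
        for pos, text in (patches or {}).items():
            i = pos_to_index(pos)
            seq[i : i + len(text)] = text.encode()
        sequence = seq.decode()
    return SiteWindow(DUMMY_SITE, sequence)


@pytest.fixture(scope="session")
def default_sim():
    """The generator's stated architecture at full study size (n=2000):
    U-rich FUE to -32, A-rich NUE -31..-12, UGUAA planted in -30..-15 with
    probability 0.5, CA dinucleotide at -2/-1 with probability 0.7."""
    cfg = SimConfig(n_sites=2000, seed=11)
    windows, truth = simulate_windows(cfg)
    return cfg, windows, truth


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(n_sites=300, seed=7)
    windows, truth = simulate_windows(cfg)
    return cfg, windows, truth
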