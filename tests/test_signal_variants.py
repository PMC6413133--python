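"""Variant enumeration, group compilation, PFM construction and PSSM scoring."""

import math

import numpy as np
import pytest

from polyasig import (
    PolyasigError,
    Region,
    ScanConfig,
    SimConfig,
    VariantGroup,
    build_pfm,
    build_pssm,
    canonical_signal_frequencies,
    compile_variant_group,
    enumerate_snv,
    pssm_score,
    scan_region,
    simulate,
    simulate_windows,
)
from polyasig.seqio import extract_windows, pos_to_index
from tests.conftest import make_window


class TestEnumerateSnv:
    @pytest.mark.parametrize(
        "canonical,expected_count,must_contain",
        [
            ("UGUAA", 15, {"UGCAA", "UUUAA", "UGUAU"}),
            ("AAUAAA", 18, {"AUUAAA", "UAUAAA", "AGUAAA"}),
            ("AA", 6, set()),
        ],
    )
    def test_counts_and_members(self, canonical, expected_count, must_contain):
        variants = enumerate_snv(canonical)
        assert len(variants) == expected_count == 3 * len(canonical)
        assert must_contain <= set(variants)
        assert variants == sorted(variants)
        assert len(set(variants)) == len(variants)
        for v in variants:
            assert sum(a != b for a, b in zip(v, canonical)) == 1

    def test_dna_input_normalized_to_rna(self):
        assert "UGCAA" in enumerate_snv("TGTAA")

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(PolyasigError):
            enumerate_snv("UGXAA")


class TestCompileVariantGroup:
    def _table(self, windows):
        return scan_region(
            windows, ScanConfig(region=Region("NUE", -30, -10), k_min=5, k_max=5)
        )

    def test_combined_is_sum_of_members(self):
        # 10 windows: 3 canonical, 1 UGCAA, 1 unrelated
        windows = (
            [make_window(patches={-25: "TGTAA"}) for _ in range(3)]
            + [make_window(patches={-25: "TGCAA"})]
            + [make_window(patches={-25: "AAAAA"}) for _ in range(6)]
        )
        group = compile_variant_group(self._table(windows), "UGUAA", top_n=100)
        assert group.member_frequency("UGUAA") == 30.0
        assert group.member_frequency("UGCAA") == 10.0
        assert math.isclose(group.combined_frequency_pct, 40.0)

    def test_variants_outside_top_n_excluded(self):
        windows = [make_window(patches={-25: "TGTAA"})] + [
            make_window(patches={-25: m})
            for m in ("AAAAA", "CCCCC", "GGGGG", "TTTTT", "TGCAA")
        ]
        group = compile_variant_group(self._table(windows), "UGUAA", top_n=1)
        assert [m for m, _ in group.members] == ["UGUAA"]
        assert group.combined_frequency_pct == group.member_frequency("UGUAA")

    def test_absent_canonical_warns_and_scores_zero(self, caplog):
        windows = [make_window(patches={-25: "AAAAA"})]
        with caplog.at_level("WARNING"):
            group = compile_variant_group(self._table(windows), "UGUAA")
        assert group.member_frequency("UGUAA") == 0.0
        assert any("absent" in r.message for r in caplog.records)

    def test_recovers_planted_canonical_and_variant(self):
        """Windows planted with UGUAA (50%) or UGCAA (6%): group frequencies
        land within 2 points of the analytic expectation (n=5000)."""
        cfg = SimConfig(n_sites=5000, seed=21, plant_prob=0.0)
        windows, _ = simulate_windows(cfg)
        rng = np.random.default_rng(99)
        i0, i1 = cfg.plant_interval.index_span()
        starts = list(range(i0, i1 - 4 + 1))
        planted = {"TGTAA": 0.0, "TGCAA": 0.0}
        out = []
        for w in windows:
            u = rng.random()
            seq = w.sequence
            if u < 0.5:
                motif = "TGTAA"
            elif u < 0.56:
                motif = "TGCAA"
            else:
                out.append(w)
                continue
            s = int(rng.choice(starts))
            seq = seq[:s] + motif + seq[s + 5 :]
            planted[motif] += 1
            out.append(type(w)(w.site, seq))
        group = compile_variant_group(self._table(out), "UGUAA", top_n=100)
        n = len(out)
        comp = cfg.composition_by_index()
        scan_i0, scan_i1 = Region("NUE", -30, -10).index_span()
        col = {b: j for j, b in enumerate("ACGT")}
        for motif, key in (("UGUAA", "TGTAA"), ("UGCAA", "TGCAA")):
            # analytic background-hit probability in the scanned region
            miss = 1.0
            for s in range(scan_i0, scan_i1 - 4 + 1):
                p = 1.0
                for j, b in enumerate(key):
                    p *= comp[s + j, col[b]]
                miss *= 1.0 - p
            planted_frac = planted[key] / n
            expected_pct = 100.0 * (planted_frac + (1 - planted_frac) * (1 - miss))
            assert abs(group.member_frequency(motif) - expected_pct) < 2.0, motif


class TestPfm:
    def test_single_member_unit_columns(self):
        group = VariantGroup("UGUAA", [("UGUAA", 30.0)], 30.0, 100)
        pfm = build_pfm(group)
        assert pfm.consensus() == "UGUAA"
        assert np.allclose(pfm.column_max(), 1.0)
        assert np.allclose(pfm.matrix.sum(axis=0), 1.0)

    def test_uaaa_core_most_conserved(self):
        """With variant mass on positions 1-2 (the observed pattern for the
        high-frequency canonical hexamer group), PFM columns 3-6 (UAAA)
        stay perfectly conserved while 1-2 degenerate."""
        group = VariantGroup(
            "AAUAAA",
            [("AAUAAA", 64.92), ("AUUAAA", 16.68), ("UAUAAA", 4.30),
             ("AGUAAA", 3.76)],
            89.66,
            100,
        )
        pfm = build_pfm(group)
        conservation = pfm.column_max()
        assert min(conservation[2:]) > max(conservation[:2])
        assert np.allclose(conservation[2:], 1.0)
        assert pfm.consensus() == "AAUAAA"

    def test_all_zero_frequencies_rejected(self):
        group = VariantGroup("UGUAA", [("UGUAA", 0.0)], 0.0, 100)
        with pytest.raises(PolyasigError):
            build_pfm(group)


class TestPssm:
    def test_canonical_scores_about_two_bits_per_position(self):
        group = VariantGroup("UGUAA", [("UGUAA", 30.0)], 30.0, 100)
        pssm = build_pssm(build_pfm(group))
        score = pssm_score(pssm, "UGUAA")
        assert 0.9 * 2 * 5 < score <= 2 * 5  # k * log2(1/0.25), minus pseudocount

    def test_unsupported_kmer_scores_negative(self):
        group = VariantGroup("UGUAA", [("UGUAA", 30.0)], 30.0, 100)
        pssm = build_pssm(build_pfm(group))
        assert pssm_score(pssm, "CCCCC") < 0

    def test_score_additive_over_positions(self):
        group = VariantGroup(
            "UGUAA", [("UGUAA", 30.0), ("UGCAA", 10.0)], 40.0, 100
        )
        pssm = build_pssm(build_pfm(group))
        total = pssm_score(pssm, "UGCAA")
        manual = sum(pssm.matrix["ACGU".index(b), j] for j, b in enumerate("UGCAA"))
        assert math.isclose(total, manual, rel_tol=1e-12)

    def test_length_mismatch_rejected(self):
        group = VariantGroup("UGUAA", [("UGUAA", 30.0)], 30.0, 100)
        pssm = build_pssm(build_pfm(group))
        with pytest.raises(PolyasigError):
            pssm_score(pssm, "UGUA")

    def test_argmax_recovers_consensus_when_majority(self):
        group = VariantGroup(
            "UGUAA",
            [("UGUAA", 30.0), ("AGUAA", 10.0), ("UCUAA", 5.0)],
            45.0,
            100,
        )
        pssm = build_pssm(build_pfm(group))
        consensus = "".join("ACGU"[i] for i in pssm.matrix.argmax(axis=0))
        assert consensus == "UGUAA"


class TestCanonicalComparison:
    def test_fixed_region_coordinates(self, small_sim):
        _, windows, _ = small_sim
        frame = canonical_signal_frequencies(windows).set_index("signal")
        assert (frame.loc["UGUAA", ["region_start", "region_end"]].tolist()
                == [-80, -15])
        assert (frame.loc["AAUAAA", ["region_start", "region_end"]].tolist()
                == [-50, -15])
        # the planted pentamer must be seen in at least the planting fraction
        assert frame.loc["UGUAA", "frequency_pct"] > 40.0
        assert frame.loc["AAUAAA", "frequency_pct"] < 20.0
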