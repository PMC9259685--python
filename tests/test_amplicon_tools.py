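"""amplicon_tools: primer logic, sentinel breakpoints, homopolymer anomalies."""

from __future__ import annotations

import numpy as np
import pytest

from paralocus import synthetic_data as sd
from paralocus.amplicon_tools import (
    AmpliconEvidence,
    InconsistentEvidenceError,
    NoBreakpointError,
    RunDepthMatrix,
    SentinelCalls,
    classify_allele_from_primers,
    detect_homopolymer_variants,
    filter_variants_by_gq,
    locate_cnl_breakpoint,
)

G, P, N = "GENE", "PSEUDO", "NOCALL"


# ---------------------------------------------------------------------------
# primer-pair classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "amplified,expected",
    [
        ((True, False, False), "WT_or_conversion"),
        ((False, True, False), "CNL"),
        ((True, False, True), "CNG"),
        ((True, True, False), "MIXED"),
        ((True, True, True), "CNG"),  # pair 3 with pair 1 present dominates
    ],
)
def test_primer_classification(amplified, expected):
    assert classify_allele_from_primers(AmpliconEvidence("s", amplified)) == expected


def test_primer_inconsistency_raises():
    with pytest.raises(InconsistentEvidenceError):
        classify_allele_from_primers(AmpliconEvidence("s", (False, False, True)))
    with pytest.raises(ValueError):
        AmpliconEvidence("s", (False, False, False))


# ---------------------------------------------------------------------------
# sentinel breakpoint localization
# ---------------------------------------------------------------------------


def test_sentinel_interval_skips_nocall():
    bi = locate_cnl_breakpoint(SentinelCalls(((1, G), (2, G), (3, N), (4, P), (5, P))))
    assert (bi.site_id_left, bi.site_id_right) == (2, 4)
    assert not bi.non_canonical


def test_sentinel_non_canonical_reports_all_transitions():
    bi = locate_cnl_breakpoint(SentinelCalls(((1, G), (2, P), (3, G), (4, P))))
    assert bi.non_canonical
    assert bi.transitions == ((1, 2), (3, 4))


def test_sentinel_uniform_raises():
    for status in (G, P):
        with pytest.raises(NoBreakpointError):
            locate_cnl_breakpoint(SentinelCalls(((1, status), (2, status))))


def test_sentinel_calls_invariants():
    with pytest.raises(ValueError):
        SentinelCalls(((2, G), (1, P)))  # unordered
    with pytest.raises(ValueError):
        SentinelCalls(((1, "X"),))


# ---------------------------------------------------------------------------
# homopolymer depth anomaly detection
# ---------------------------------------------------------------------------


def _constructed_run(n=24, n_pos=2, anomaly=None, seed=0):
    rng = np.random.default_rng(seed)
    flank = np.full((n, n_pos), 500.0)
    depth = flank * (1 + 0.03 * rng.standard_normal((n, n_pos)))
    if anomaly:
        (s, p), factor = anomaly
        depth[s, p] *= factor
    return RunDepthMatrix([f"S{i}" for i in range(n)], list(range(n_pos)), depth, flank)


def test_halved_depth_flagged_deletion_others_none():
    # [DERIVED] z computed directly: 0.5x against a 3% MAD is far beyond 5 MADs
    m = _constructed_run(anomaly=((5, 0), 0.5))
    flags = {(f.sample_id, f.position): f for f in detect_homopolymer_variants(m)}
    assert flags[("S5", 0)].flag == "DELETION"
    assert abs(flags[("S5", 0)].z) > 5
    others = [f for k, f in flags.items() if k != ("S5", 0)]
    assert all(f.flag == "NONE" for f in others)


def test_increased_depth_flagged_snv():
    m = _constructed_run(anomaly=((7, 1), 1.5))
    flags = {(f.sample_id, f.position): f.flag for f in detect_homopolymer_variants(m)}
    assert flags[("S7", 1)] == "SNV"


def test_mad_zero_fallback():
    n = 6
    depth = np.full((n, 1), 100.0)
    depth[2, 0] = 130.0  # +30% against identical others
    m = RunDepthMatrix([f"S{i}" for i in range(n)], [0], depth, np.full((n, 1), 100.0))
    flags = {f.sample_id: f for f in detect_homopolymer_variants(m)}
    assert flags["S2"].flag == "SNV" and flags["S2"].fallback_used


def test_simulated_run_recovers_truth():
    m, truth = sd.simulate_run_depths(24, {(3, 0): 0.5, (7, 1): 1.5}, seed=11)
    got = {
        (m.sample_ids.index(f.sample_id), f.position): f.flag
        for f in detect_homopolymer_variants(m)
        if f.flag != "NONE"
    }
    want = {k: v for k, v in truth.items() if v != "NONE"}
    assert got == want


def test_run_matrix_validation():
    with pytest.raises(ValueError):
        RunDepthMatrix(["a", "b"], [0], np.ones((2, 1)), np.ones((2, 1)))  # < 3 samples
    with pytest.raises(ValueError):
        RunDepthMatrix(["a", "b", "c"], [0], np.ones((3, 1)), np.zeros((3, 1)))


def test_run_matrix_tsv_round_trip(tmp_path):
    m, _ = sd.simulate_run_depths(5, {}, seed=2)
    m2 = RunDepthMatrix.from_tsv(m.to_tsv(tmp_path / "run.tsv"))
    assert m2.sample_ids == m.sample_ids and m2.positions == m.positions
    assert np.allclose(m2.depth, m.depth, atol=1e-4)
    assert np.allclose(m2.flank_depth, m.flank_depth, atol=1e-4)


# ---------------------------------------------------------------------------
# GQ filtering
# ---------------------------------------------------------------------------


def test_gq_filter_threshold_and_missing():
    calls = [
        {"id": 1, "GQ": 650},
        {"id": 2, "GQ": 649.9},
        {"id": 3},
        {"id": 4, "GQ": 1000},
    ]
    kept, log = filter_variants_by_gq(calls)
    assert [c["id"] for c in kept] == [1, 3, 4]
    assert log == {"kept": 3, "removed": 1, "missing_score": 1}
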