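"""coverage_cn: depth extraction, GC correction, normalization, GMM calling."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from paralocus import synthetic_data as sd
from paralocus.coverage_cn import (
    CopyNumberCall,
    DepthBin,
    DepthProfile,
    NormalizedDepth,
    call_total_cn,
    cnv_class_of,
    extract_depth,
    fit_sigma0,
    gc_correct,
    mixture_posteriors,
    normalize,
)
from paralocus.region_model import GenomicInterval


def _bin(start, depth, gc, contig="mini1"):
    return DepthBin(GenomicInterval(contig, start, start + 500), depth, gc)


# ---------------------------------------------------------------------------
# mixture model against an independent brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_posteriors(d, max_cn, sigma0):
    # [DERIVED] direct normal-density enumeration, independent implementation
    dens = []
    for k in range(max_cn + 1):
        sd_k = sigma0 * math.sqrt(max(k, 1))
        dens.append(
            math.exp(-0.5 * ((d - k) / sd_k) ** 2) / (sd_k * math.sqrt(2 * math.pi))
        )
    total = sum(dens)
    return [x / total for x in dens]


def test_mixture_posteriors_match_oracle():
    for d in [0.0, 0.4, 1.0, 1.9, 2.0, 2.5, 3.3, 7.7, 10.0]:
        got = mixture_posteriors(d, max_cn=10, sigma0=0.12)
        want = _oracle_posteriors(d, 10, 0.12)
        assert np.allclose(got, want, atol=1e-12)
        assert abs(got.sum() - 1.0) < 1e-12


def test_call_total_cn_rounds_clean_depths():
    # [DERIVED] for d near an integer the MAP component is round(d);
    # d is on the unique-region scale (diploid expectation 2.0)
    for d in [0.95, 2.0, 2.08, 3.9, 6.05]:
        call = call_total_cn(NormalizedDepth(d=d, n_bins_used=20))
        assert call.cn_unique == round(d)
        assert call.cn_total == round(d) + 2
        assert not call.no_call


def test_call_total_cn_no_call_between_components():
    call = call_total_cn(NormalizedDepth(d=2.5, n_bins_used=20))
    assert call.no_call
    assert call.posterior < 0.95


def test_cnv_class_thresholds():
    # [TRIVIAL] CNL <= 1 gene copy, NONE = 2, CNG >= 3
    assert cnv_class_of(0) == "CNL" and cnv_class_of(1) == "CNL"
    assert cnv_class_of(2) == "NONE"
    assert cnv_class_of(3) == "CNG" and cnv_class_of(8) == "CNG"
    with pytest.raises(ValueError):
        CopyNumberCall(cn_unique=2, cn_total=4, posterior=0.99, cnv_class="CNG", no_call=False)


def test_fit_sigma0_recovers_injected_spread():
    rng = np.random.default_rng(5)
    ds = list(2 + 0.08 * rng.standard_normal(4000))
    est = fit_sigma0(ds)
    assert abs(est - 0.08 / math.sqrt(2)) < 0.01  # sigma_k = sigma0*sqrt(k)


# ---------------------------------------------------------------------------
# normalization and GC correction on constructed profiles
# ---------------------------------------------------------------------------


def test_normalize_trimmed_mean():
    # [DERIVED] hand-computed: 5% trim drops the outlier bin entirely with 21
    # bins of identical depth 30 plus one at 300
    base = [_bin(1000 * i, 30.0, 0.5) for i in range(21)] + [_bin(30000, 300.0, 0.5)]
    uniq = [_bin(50000 + 1000 * i, 30.0, 0.5) for i in range(10)]
    nd = normalize(DepthProfile(bins=uniq, baseline_bins=base))
    d_expected = 2 * 30.0 / float(stats.trim_mean([30.0] * 21 + [300.0], 0.05))
    assert abs(nd.d - d_expected) < 1e-9


def test_gc_correct_removes_injected_slope(mini_ref, mini_fasta, sim_cache, workdir):
    cfg = sd.SimulationConfig(seed=902, gc_bias_slope=-1.5)
    bam, _ = sd.simulate_sample(mini_ref, ([], []), cfg, workdir / "gcbias")
    profile = extract_depth(bam, mini_ref.model, mini_fasta)
    corrected = gc_correct(profile)

    def slope(bins):
        g = np.array([b.gc_fraction for b in bins])
        d = np.array([b.raw_depth for b in bins])
        return np.polyfit(g, d / d.mean(), 1)[0]

    assert abs(slope(corrected.baseline_bins)) < 0.35 * abs(slope(profile.baseline_bins))
    nd = normalize(corrected)
    call = call_total_cn(nd)
    assert call.cn_total == 4 and call.cnv_class == "NONE"


def test_gc_correct_skips_with_few_bins():
    profile = DepthProfile(
        bins=[_bin(0, 30, 0.5)], baseline_bins=[_bin(1000, 30, 0.5)] * 5
    )
    out = gc_correct(profile)
    assert any("gc_correction_skipped" in w for w in out.warnings)
    assert [b.raw_depth for b in out.bins] == [b.raw_depth for b in profile.bins]


def test_extract_depth_bins_cover_regions(mini_ref, mini_fasta, sim_cache):
    bam, _ = sim_cache("WT")
    profile = extract_depth(bam, mini_ref.model, mini_fasta)
    u = mini_ref.model.unique_cn_region
    assert profile.bins and profile.baseline_bins
    for b in profile.bins:
        assert u.contains(b.interval.start)
        assert 0.0 <= b.gc_fraction <= 1.0
    nd = normalize(gc_correct(profile))
    assert 1.7 < nd.d < 2.3  # WT diploid


def test_depth_calls_match_truth_across_classes(mini_ref, mini_fasta, sim_cache):
    for cls, want in [("WT", "NONE"), ("RecNciI_CNL", "CNL"), ("CNG", "CNG")]:
        bam, truth = sim_cache(cls)
        profile = gc_correct(extract_depth(bam, mini_ref.model, mini_fasta))
        call = call_total_cn(normalize(profile))
        assert call.cnv_class == want
        assert call.cn_total == truth["cn_total"]


def test_to_bedgraph(tmp_path):
    profile = DepthProfile(bins=[_bin(0, 30, 0.5)], baseline_bins=[_bin(1000, 31, 0.4)])
    p = profile.to_bedgraph(tmp_path / "d.bedgraph")
    lines = p.read_text().strip().split("\n")
    assert len(lines) == 2 and lines[0].split("\t")[1] == "0"
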