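"""site_cn: pooled counting, binomial CN estimation, transition detection."""

from __future__ import annotations

import math

import numpy as np
import pytest

from paralocus.site_cn import (
    BreakpointCall,
    SiteCNSeries,
    SiteCounts,
    build_site_cn_series,
    classify_cnl_pathogenicity,
    count_site_bases,
    detect_cn_transitions,
    estimate_site_cn,
    site_cn_log_likelihoods,
    site_counts_to_tsv,
)


# ---------------------------------------------------------------------------
# binomial estimator against an independent enumeration oracle
# ---------------------------------------------------------------------------


def _oracle_map_cn(k_gene, depth, cn_total, epsilon=0.01):
    # [DERIVED] direct log-binomial enumeration with math.comb
    best, best_ll = None, -math.inf
    for c in range(cn_total + 1):
        p = min(max(c / cn_total, epsilon), 1 - epsilon)
        ll = (
            math.log(math.comb(depth, k_gene))
            + k_gene * math.log(p)
            + (depth - k_gene) * math.log(1 - p)
        )
        if ll > best_ll:
            best, best_ll = c, ll
    return best


def test_estimate_site_cn_matches_enumeration_oracle():
    rng = np.random.default_rng(21)
    for _ in range(300):
        cn_total = int(rng.integers(1, 9))
        depth = int(rng.integers(10, 120))
        k_gene = int(rng.integers(0, depth + 1))
        got = estimate_site_cn(SiteCounts(1, k_gene, depth - k_gene, 0), cn_total)
        assert got is not None
        assert got[0] == _oracle_map_cn(k_gene, depth, cn_total)
        assert 0 < got[1] <= 1


def test_estimate_site_cn_below_depth_returns_none():
    assert estimate_site_cn(SiteCounts(1, 4, 5, 0), 4) is None
    assert estimate_site_cn(SiteCounts(1, 5, 5, 0), 4) is not None


def test_log_likelihood_epsilon_clamps_extremes():
    ll = site_cn_log_likelihoods(0, 50, 4)
    assert np.isfinite(ll).all()
    assert np.argmax(ll) == 0


# ---------------------------------------------------------------------------
# pooled counting on simulated data
# ---------------------------------------------------------------------------


def test_wt_site_counts_balanced(mini_ref, sim_cache):
    bam, _ = sim_cache("WT")
    counts = count_site_bases(bam, mini_ref.model)
    assert len(counts) == len(mini_ref.model.sites)
    series = build_site_cn_series(counts, cn_total=4)
    vals = series.cn_values
    assert sum(v == 2 for v in vals) / len(vals) > 0.9
    frac_other = sum(c.k_other for c in counts) / sum(c.depth for c in counts)
    assert frac_other < 0.05


def test_cnl_sample_gene_cn_drops_after_breakpoint(mini_ref, sim_cache):
    bam, truth = sim_cache("RecNciI_CNL")
    counts = count_site_bases(bam, mini_ref.model)
    series = build_site_cn_series(counts, cn_total=truth["cn_total"])
    bp_pos = truth["breakpoints"][0]
    before = [cn for sid, cn, _ in series.entries
              if mini_ref.model.site_by_id(sid).gene_pos < bp_pos]
    after = [cn for sid, cn, _ in series.entries
             if mini_ref.model.site_by_id(sid).gene_pos > bp_pos]
    assert np.median(before) == 2 and np.median(after) == 1


def test_counts_tsv(mini_ref, sim_cache, tmp_path):
    bam, _ = sim_cache("WT")
    counts = count_site_bases(bam, mini_ref.model)
    p = site_counts_to_tsv(counts, mini_ref.model, tmp_path / "c.tsv")
    lines = p.read_text().strip().split("\n")
    assert len(lines) == len(counts) + 1
    assert lines[0].split("\t")[0] == "site_id"


# ---------------------------------------------------------------------------
# transition detection on constructed series
# ---------------------------------------------------------------------------


def _series(model, cn_by_index, cn_total=4, post=0.99):
    sites = model.sites
    entries = [
        (sites[i].site_id, cn, post) for i, cn in enumerate(cn_by_index)
    ]
    return SiteCNSeries(entries=entries, cn_total=cn_total)


def test_detect_cnl_step(mini_ref):
    model = mini_ref.model
    n = len(model.sites)
    cut = n // 2
    series = _series(model, [2] * cut + [1] * (n - cut), cn_total=3)
    bps = detect_cn_transitions(series, model)
    assert [b.kind for b in bps] == ["CNL"]
    b = bps[0]
    assert b.site_id_left == model.sites[cut - 1].site_id
    assert b.site_id_right == model.sites[cut].site_id
    assert b.cn_before == 2 and b.cn_after == 1


def test_detect_conversion_pair(mini_ref):
    model = mini_ref.model
    n = len(model.sites)
    vals = [2] * n
    for i in range(n - 6, n - 2):
        vals[i] = 1
    bps = detect_cn_transitions(_series(model, vals), model)
    kinds = [b.kind for b in bps]
    assert kinds == ["CONVERSION_START", "CONVERSION_END"]


def test_isolated_flicker_removed_by_median_filter(mini_ref):
    model = mini_ref.model
    vals = [2] * len(model.sites)
    vals[10] = 3  # single-site flicker, not a real transition
    assert detect_cn_transitions(_series(model, vals), model) == []


def test_low_posterior_sites_masked(mini_ref):
    model = mini_ref.model
    n = len(model.sites)
    entries = [(s.site_id, 2, 0.99) for s in model.sites]
    # a confident-looking step built entirely from low-posterior calls
    entries[n // 2:] = [(s.site_id, 1, 0.5) for s in model.sites[n // 2:]]
    series = SiteCNSeries(entries=entries, cn_total=4)
    assert detect_cn_transitions(series, model) == []


def test_pathogenicity_open_interval(mini_ref):
    model = mini_ref.model
    coding = model.coding_region
    contig = model.gene.contig

    def bp(left, right):
        return BreakpointCall(
            kind="CNL", site_id_left=1, site_id_right=2,
            pos_left=left, pos_right=right, contig=contig,
            cn_before=2, cn_after=1,
        )

    assert classify_cnl_pathogenicity(bp(coding.start + 10, coding.start + 50), model)
    assert not classify_cnl_pathogenicity(bp(coding.end + 10, coding.end + 500), model)
    # interval straddling the coding 3' boundary: breakpoint may lie inside
    assert classify_cnl_pathogenicity(bp(coding.end - 10, coding.end + 500), model)
    with pytest.raises(ValueError):
        classify_cnl_pathogenicity(
            BreakpointCall(
                kind="CNG", site_id_left=1, site_id_right=2,
                pos_left=coding.start, pos_right=coding.start + 10,
                contig=contig, cn_before=2, cn_after=3,
            ),
            model,
        )
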