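"""recombinant_phaser: assembly, haplotype CN, scenarios, classification."""

from __future__ import annotations

import itertools

import numpy as np
import pysam
import pytest

from paralocus.recombinant_phaser import (
    Haplotype,
    HaplotypeFragment,
    ScenarioCall,
    assemble_haplotypes,
    call_haplotype_cn,
    compare_scenarios,
    extract_fragments,
    haplotype_origin,
)


def _fragments(model, patterns):
    """Build fragments from '.'-padded allele strings over the phasing sites."""
    sids = [s.site_id for s in model.phasing_sites]
    out = []
    for n, pat in enumerate(patterns):
        alleles = tuple(
            (sid, a) for sid, a in zip(sids, pat) if a != "."
        )
        out.append(HaplotypeFragment(read_name=f"r{n}", alleles=alleles))
    return out


def test_fragment_invariants():
    with pytest.raises(ValueError):
        HaplotypeFragment("r", ())
    with pytest.raises(ValueError):
        HaplotypeFragment("r", ((2, "G"), (1, "P")))  # out of order


def test_assemble_two_clean_haplotypes(mini_ref):
    model = mini_ref.model
    frags = _fragments(
        model,
        ["GGGGG.....", ".....GGGGG", "GG........", "........GG"] * 3
        + ["PPPPP.....", ".....PPPPP", "..PPP.....", ".......PPP"] * 3,
    )
    haps = assemble_haplotypes(frags, model, cn_total=4)
    strings = sorted(h.allele_string for h in haps)
    assert strings == ["GGGGGGGGGG", "PPPPPPPPPP"]
    assert all(h.support >= 3 for h in haps)


def test_assemble_recovers_hybrid_suffix(mini_ref):
    # [DERIVED] hand-built fragment set: wild type, pseudogene, and a
    # RecNciI-like hybrid linked through overlapping fragments
    model = mini_ref.model
    frags = _fragments(
        model,
        ["GGGGGGGGGG"] * 5
        + ["PPPPPPPPPP"] * 8
        + ["GGGGGG.P..", "......GPPP", "....GGGP..", ".....GGPPP", "......GP.."],
    )
    haps = assemble_haplotypes(frags, model, cn_total=4)
    assert "GGGGGGGPPP" in {h.allele_string for h in haps}


def test_assembly_does_not_merge_decoy_into_wildtype(mini_ref):
    # [PUBLISHED] reverse-converted GBAP1 (gene base at one site on a pseudo
    # haplotype) must assemble as a distinct hybrid, not join the GBA wt
    model = mini_ref.model
    decoy = "PPPPPPPGPP"
    frags = _fragments(
        model,
        ["GGGGGGGGGG"] * 8
        + [decoy] * 4
        + ["PPPPPPP.PP"] * 3
        + ["......PG..", ".....PPGP.", "......PGPP"],
    )
    haps = assemble_haplotypes(frags, model, cn_total=4)
    strings = {h.allele_string for h in haps}
    assert decoy in strings
    assert haplotype_origin(decoy, model) == "HYBRID_PSEUDO"


def test_assembly_respects_min_support(mini_ref):
    model = mini_ref.model
    frags = _fragments(model, ["GGGGGGGGGG"] * 2)  # below min_hap_support=3
    assert assemble_haplotypes(frags, model, cn_total=4) == []


def test_assembly_caps_at_cn_total(mini_ref):
    model = mini_ref.model
    frags = _fragments(
        model, ["GGGGGGGGGG"] * 5 + ["PPPPPPPPPP"] * 5 + ["GGGGGPPPPP"] * 5
    )
    haps = assemble_haplotypes(frags, model, cn_total=2)
    assert len(haps) <= 2


# ---------------------------------------------------------------------------
# haplotype copy number: exhaustive-enumeration oracle
# ---------------------------------------------------------------------------


def _oracle_best_composition(hap_sets, cn_total, n_haps):
    # [DERIVED] independent brute force over all compositions
    best, best_ll = None, -np.inf
    for comp in itertools.product(range(1, cn_total + 1), repeat=n_haps):
        if sum(comp) != cn_total:
            continue
        ll = sum(
            np.log(sum(comp[i] for i in s) / cn_total) for s in hap_sets
        )
        if ll > best_ll + 1e-12 or (abs(ll - best_ll) <= 1e-12 and comp < best):
            best, best_ll = comp, ll
    return best


def test_call_haplotype_cn_matches_oracle(mini_ref):
    model = mini_ref.model
    wt, ps = "GGGGGGGGGG", "PPPPPPPPPP"
    # pseudogene present at twice the wild-type dose
    frags = _fragments(model, [wt] * 20 + [ps] * 41)
    haps = [Haplotype(wt, 20), Haplotype(ps, 41)]
    haps = call_haplotype_cn(haps, frags, cn_total=3, model=model)
    sets = [frozenset({0})] * 20 + [frozenset({1})] * 41
    want = _oracle_best_composition(sets, 3, 2)
    assert tuple(h.cn for h in haps) == want == (1, 2)


def test_call_haplotype_cn_cng(mini_ref):
    model = mini_ref.model
    wt, ps = "GGGGGGGGGG", "PPPPPPPPPP"
    frags = _fragments(model, [wt] * 90 + [ps] * 30)
    haps = call_haplotype_cn(
        [Haplotype(wt, 90), Haplotype(ps, 30)], frags, cn_total=8, model=model
    )
    assert [h.cn for h in haps] == [6, 2]


# ---------------------------------------------------------------------------
# scenario comparison and origin classification
# ---------------------------------------------------------------------------


def test_compare_scenarios_wt(mini_ref):
    haps = [Haplotype("GGGGGGGGGG", 100, cn=2), Haplotype("PPPPPPPPPP", 100, cn=2)]
    sc = compare_scenarios(haps, mini_ref.model)
    assert sc.genotype == "WT"
    assert sc.wildtype_gba_copies >= 2
    assert sc.log_likelihood_ratio > 0


def test_compare_scenarios_het(mini_ref):
    haps = [
        Haplotype("GGGGGGGGGG", 50, cn=1),
        Haplotype("GGGGGGGPPP", 50, cn=1),
        Haplotype("PPPPPPPPPP", 100, cn=2),
    ]
    sc = compare_scenarios(haps, mini_ref.model)
    assert sc.genotype == "HET" and sc.wildtype_gba_copies == 1


def test_compare_scenarios_hom(mini_ref):
    # no wild-type haplotype; gene-base CN 0 at the p.L483P site
    haps = [
        Haplotype("GGGGGGGPPP", 100, cn=2),
        Haplotype("PPPPPPPPPP", 100, cn=2),
    ]
    sc = compare_scenarios(haps, mini_ref.model)
    assert sc.genotype == "HOM"


def test_compare_scenarios_compound_het(mini_ref):
    haps = [
        Haplotype("GGGGGGPGGG", 50, cn=1),
        Haplotype("GGGGGGGPGG", 50, cn=1),
        Haplotype("PPPPPPPPPP", 100, cn=2),
    ]
    sc = compare_scenarios(haps, mini_ref.model)
    assert sc.genotype == "COMPOUND_HET"


def test_scenario_invariant():
    with pytest.raises(ValueError):
        ScenarioCall(2, 0.0, "HET")


def test_haplotype_origin_table(mini_ref):
    model = mini_ref.model
    assert haplotype_origin("GGGGGGGGGG", model) == "GBA"
    assert haplotype_origin("PPPPPPPPPP", model) == "GBAP1"
    assert haplotype_origin("GGGGGGGPPP", model) == "HYBRID_GENE"  # RecNciI
    assert haplotype_origin("GGGGGPPPPP", model) == "HYBRID_GENE"  # c.1263del+RecTL
    assert haplotype_origin("PPPPPPPGPP", model) == "HYBRID_PSEUDO"  # decoy
    assert haplotype_origin("GGPGGGGGGG", model) == "UNCLASSIFIED"


# ---------------------------------------------------------------------------
# fragment extraction from simulated reads
# ---------------------------------------------------------------------------


def test_extract_fragments_simulated_wt(mini_ref, sim_cache):
    bam, _ = sim_cache("WT")
    frags = extract_fragments(bam, mini_ref.model)
    assert len(frags) > 100
    sids = {s.site_id for s in mini_ref.model.phasing_sites}
    pure = 0
    for f in frags:
        assert {s for s, _ in f.alleles} <= sids
        alleles = {a for _, a in f.alleles if a in "GP"}
        pure += len(alleles) == 1
    assert pure / len(frags) > 0.95  # WT fragments are G-pure or P-pure


def test_mate_pairs_merge_into_one_fragment(mini_ref, sim_cache):
    bam, _ = sim_cache("WT")
    names = [r.query_name for r in pysam.AlignmentFile(str(bam)).fetch()]
    frags = extract_fragments(bam, mini_ref.model)
    fnames = [f.read_name for f in frags]
    assert len(fnames) == len(set(fnames))  # one fragment per template name
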