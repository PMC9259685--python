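"""Phasing of the ten homology-region sites and recombinant classification.

Pathogenic gene variants whose alternate allele equals the pseudogene base
(p.L483P, RecNciI and friends) cannot be called from per-site counts
alone: a pseudogene haplotype partially converted toward the gene (a
"reverse conversion") produces the same pooled allele imbalance as a real
gene variant.  What separates them is linkage: on a real recombinant the
pseudogene-derived bases sit on an otherwise gene haplotype (G...GPP...P),
while the decoy is a pseudogene haplotype with a few gene bases
(PP.G.PPP).  This module assembles haplotypes over the ten phasing sites
from read/read-pair linkage, assigns each an integer copy number under a
multinomial model, compares the one-vs-two wild-type-copy scenarios, and
maps hybrid gene-origin haplotypes to named recombinants.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from paralocus.region_model import ParalogModel
from paralocus.site_cn import MIN_BASE_QUALITY, collect_site_observations

__all__ = [
    "HaplotypeFragment",
    "Haplotype",
    "ScenarioCall",
    "RecombinantCall",
    "SampleReport",
    "extract_fragments",
    "assemble_haplotypes",
    "call_haplotype_cn",
    "compare_scenarios",
    "classify_recombinant",
    "haplotype_origin",
]

MIN_HAP_SUPPORT = 3
_WT = "G"


@dataclass(frozen=True)
class HaplotypeFragment:
    """One sequencing fragment's partial observation of the phasing sites."""

    read_name: str
    alleles: tuple[tuple[int, str], ...]  # (site_id, 'G'|'P'|'O'), site-sorted

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("fragment must cover >= 1 phasing site")
        sids = [s for s, _ in self.alleles]
        if sorted(set(sids)) != sids:
            raise ValueError("one entry per site, in site order")

    @property
    def allele_map(self) -> dict[int, str]:
        return dict(self.alleles)


@dataclass
class Haplotype:
    allele_string: str  # over {G, P}, one char per phasing site, 5'->3'
    support: int
    cn: int | None = None
    origin: str | None = None  # GBA | GBAP1 | HYBRID

    @property
    def p_sites(self) -> frozenset[int]:
        raise AttributeError("use p_site_ids(model) — needs site ids")

    def p_site_ids(self, model: ParalogModel) -> frozenset[int]:
        ph = model.phasing_sites
        return frozenset(
            s.site_id for s, a in zip(ph, self.allele_string) if a == "P"
        )


@dataclass(frozen=True)
class ScenarioCall:
    wildtype_gba_copies: int  # 1 or 2
    log_likelihood_ratio: float  # L(wt>=2) - L(wt=1)
    genotype: str  # WT | HET | HOM | COMPOUND_HET
    no_call: bool = False

    def __post_init__(self) -> None:
        if self.genotype == "HET" and self.wildtype_gba_copies != 1:
            raise ValueError("HET requires exactly one wild-type copy")


@dataclass(frozen=True)
class RecombinantCall:
    label: str  # named recombinant / variant label, or site list
    genotype: str  # HET | HOM
    mechanism: str  # SNV | CONVERSION | CNL | CNG-linked
    flags: tuple[str, ...] = ()


@dataclass
class SampleReport:
    sample_id: str
    cn_call: "object" = None  # CopyNumberCall
    breakpoints: list = field(default_factory=list)
    recombinant_calls: list[RecombinantCall] = field(default_factory=list)
    targeted_variant_calls: list = field(default_factory=list)
    scenario: ScenarioCall | None = None
    haplotypes: list[Haplotype] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "cn_unique": self.cn_call.cn_unique if self.cn_call else None,
            "cn_total": self.cn_call.cn_total if self.cn_call else None,
            "cnv_class": self.cn_call.cnv_class if self.cn_call else None,
            "cn_no_call": self.cn_call.no_call if self.cn_call else None,
            "breakpoints": [
                {
                    "kind": b.kind,
                    "site_id_left": b.site_id_left,
                    "site_id_right": b.site_id_right,
                    "pos_left": b.pos_left,
                    "pos_right": b.pos_right,
                    "pathogenic": b.pathogenic,
                    "flags": list(b.flags),
                }
                for b in self.breakpoints
            ],
            "recombinant_calls": [
                {
                    "label": c.label,
                    "genotype": c.genotype,
                    "mechanism": c.mechanism,
                    "flags": list(c.flags),
                }
                for c in self.recombinant_calls
            ],
            "targeted_variant_calls": [
                {"label": v[0], "genotype": v[1], "posterior": v[2]}
                for v in self.targeted_variant_calls
            ],
            "genotype": self.scenario.genotype if self.scenario else None,
            "haplotypes": [
                {"alleles": h.allele_string, "support": h.support, "cn": h.cn,
                 "origin": h.origin}
                for h in self.haplotypes
            ],
            "warnings": list(self.warnings),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    def to_tsv_rows(self) -> list[str]:
        rows = []
        for c in self.recombinant_calls:
            rows.append(
                f"{self.sample_id}\t{c.label}\t{c.genotype}\t{c.mechanism}"
            )
        for label, gt, post in self.targeted_variant_calls:
            rows.append(f"{self.sample_id}\t{label}\t{gt}\tSNV_targeted")
        return rows


# ---------------------------------------------------------------------------
# fragment extraction
# ---------------------------------------------------------------------------


def extract_fragments(
    alignments: str | Path | pysam.AlignmentFile,
    model: ParalogModel,
    min_base_quality: int = MIN_BASE_QUALITY,
) -> list[HaplotypeFragment]:
    """Per-fragment phasing-site observations, pooled over both paralogs.

    Mate pairs are merged by read name; a pair observing the same site with
    conflicting alleles drops that site (handled in the shared observation
    collector).
    """
    phasing = model.phasing_sites
    obs = collect_site_observations(
        alignments, model, min_base_quality, sites=phasing
    )
    per_read: dict[str, dict[int, str]] = {}
    for sid, by_name in obs.items():
        for name, cls in by_name.items():
            per_read.setdefault(name, {})[sid] = cls
    out = []
    for name, amap in sorted(per_read.items()):
        alleles = tuple(sorted(amap.items()))
        out.append(HaplotypeFragment(read_name=name, alleles=alleles))
    return out


# ---------------------------------------------------------------------------
# greedy haplotype assembly
# ---------------------------------------------------------------------------


def _consistent(amap: dict[int, str], partial: dict[int, str]) -> bool:
    """Fragment agrees with the partial haplotype wherever they overlap."""
    shared = amap.keys() & partial.keys()
    return all(amap[s] == partial[s] for s in shared)


def _overlaps(amap: dict[int, str], partial: dict[int, str]) -> bool:
    return bool(amap.keys() & partial.keys())


def assemble_haplotypes(
    fragments: list[HaplotypeFragment],
    model: ParalogModel,
    cn_total: int = 4,
    min_hap_support: int = MIN_HAP_SUPPORT,
    warnings: list[str] | None = None,
) -> list[Haplotype]:
    """Greedy seed-and-extend assembly over the ten phasing sites.

    Seed with the most-supported full-agreement fragment cluster, extend
    site by site by majority linkage (a voting fragment must span both the
    new site and the nearest covered site and agree with the partial
    haplotype everywhere), commit, then repeat on fragments not explained
    by any committed haplotype until fewer than ``min_hap_support`` remain
    or ``cn_total`` haplotypes exist.  Ambiguous extensions tie-break
    toward the gene base (then lexicographically) with a warning.
    """
    site_ids = [s.site_id for s in model.phasing_sites]
    frag_maps = [
        {s: a for s, a in f.alleles if a in ("G", "P")} for f in fragments
    ]
    frag_maps = [m for m in frag_maps if m]
    # total fragment depth per site across ALL fragments (not just the
    # unexplained pool); used to scale the evidence required for an
    # extension to switch alleles away from the continuation
    depth_all = {
        s: sum(1 for m in frag_maps if s in m) for s in site_ids
    }
    haps: list[Haplotype] = []
    committed: list[dict[int, str]] = []
    remaining = list(range(len(frag_maps)))

    while len(haps) < cn_total:
        if len(remaining) < min_hap_support:
            if remaining and warnings is not None:
                warnings.append(f"{len(remaining)} fragments unexplained")
            break
        # seed: the pattern with the most full-agreement fragments among the
        # remaining set (fragments that overlap it and agree at every shared
        # site); ties toward gene bases, then lexicographic
        best = None
        for i in remaining:
            m = frag_maps[i]
            n = sum(
                1
                for j in remaining
                if _overlaps(frag_maps[j], m) and _consistent(frag_maps[j], m)
            )
            key = (-n, -list(m.values()).count("G"), tuple(sorted(m.items())))
            if best is None or key < best[0]:
                best = (key, i, n)
        _, seed_idx, seed_n = best
        if seed_n < min_hap_support:
            if warnings is not None:
                warnings.append("no seed cluster reaches min_hap_support")
            break
        partial = dict(frag_maps[seed_idx])

        # extend over missing sites, nearest-to-covered first
        while len(partial) < len(site_ids):
            covered_idx = [k for k, s in enumerate(site_ids) if s in partial]
            missing = [
                (min(abs(k - c) for c in covered_idx), k)
                for k, s in enumerate(site_ids)
                if s not in partial
            ]
            missing.sort()
            _, k = missing[0]
            sid = site_ids[k]
            # majority linkage: a voting fragment must cover the new site
            # plus at least one already-covered site (true read-level
            # linkage, not mere compatibility) and agree with the partial
            # haplotype everywhere it overlaps.  Among eligible voters only
            # those with the deepest overlap with the partial count: a
            # fragment spanning several covered sites is far less likely to
            # originate from a co-occurring haplotype that merely agrees at
            # a single shared site.
            voters: list[tuple[int, str]] = []
            for i in remaining:
                m = frag_maps[i]
                if sid in m and m[sid] in ("G", "P") and _consistent(m, partial):
                    depth = sum(1 for s in partial if s in m)
                    if depth >= 1:
                        voters.append((depth, m[sid]))
            votes = {"G": 0, "P": 0}
            if voters:
                alleles = {a for _, a in voters}
                if len(alleles) == 1:
                    # unanimous voters: count them all
                    votes[alleles.pop()] = len(voters)
                else:
                    # conflicting voters: only the deepest-linked ones are
                    # trusted to arbitrate
                    deepest = max(d for d, _ in voters)
                    for d, a in voters:
                        if d == deepest:
                            votes[a] += 1
            # continuation source: the allele of the nearest covered site,
            # plus whether that source is an allele island (every covered
            # neighbor disagrees with it)
            nearest = min(
                (abs(k - c), c) for c, s in enumerate(site_ids) if s in partial
            )[1]
            cont = partial[site_ids[nearest]]
            left = [c for c in covered_idx if c < nearest]
            right = [c for c in covered_idx if c > nearest]
            neighbors = ([max(left)] if left else []) + (
                [min(right)] if right else []
            )
            island = bool(neighbors) and all(
                partial[site_ids[c]] != cont for c in neighbors
            )
            # evidence required for a vote to switch alleles away from the
            # continuation: the unexplained pool contains only fragments no
            # committed haplotype accounts for, so at sites where the true
            # novel haplotype matches a committed one its real reads have
            # been absorbed and a couple of same-site sequencing errors can
            # vote unopposed.  A genuine novel allele at a site contributes
            # on the order of depth/cn_total fragments, so demand ~15% of
            # that before accepting a switch.
            switch_min = max(
                2, -(-3 * depth_all[sid]) // (20 * max(cn_total, 1))
            )
            lone = len(voters) == 1 and voters[0][0] >= 2
            if lone and (voters[0][1] == cont or island):
                # a single uncontradicted voter firmly linked to the
                # partial (two or more shared covered sites) is accepted
                # when it agrees with the continuation or when the
                # continuation source is an island; a lone voter asking
                # for an allele switch on an otherwise uniform stretch is
                # indistinguishable from a sequencing error and falls
                # through to the continuation below
                allele = voters[0][1]
            elif max(votes.values()) < 2:
                # no clear linkage majority: continue the allele of the
                # nearest covered site — haplotypes are contiguous DNA, so
                # absent evidence of a switch none is assumed.  Exception:
                # when the source site is an island, extrapolating it would
                # invent a switch out of nothing, so a surviving deepest
                # voter is trusted instead if one exists.
                if island and max(votes.values()) == 1:
                    allele = next(a for a, v in votes.items() if v == 1)
                else:
                    allele = cont
            elif votes["G"] == votes["P"]:
                if warnings is not None:
                    warnings.append(f"ambiguous extension at site {sid}")
                allele = "G"  # deterministic tie-break toward the gene base
            else:
                winner = "G" if votes["G"] > votes["P"] else "P"
                if winner != cont and votes[winner] < switch_min and not island:
                    allele = cont
                else:
                    allele = winner
            partial[sid] = allele

        string = "".join(partial[s] for s in site_ids)
        support_idx = [
            i for i in remaining if _consistent(frag_maps[i], partial)
        ]
        support = len(support_idx)
        if support < min_hap_support:
            break
        # commit-time separation check: the candidate must differ from every
        # committed haplotype at one or more sites covered by enough of its
        # supporting fragments (a consistent fragment covering a site
        # necessarily carries the candidate's allele there).  Late rounds
        # run on the leftover pool, which is dominated by fragments carrying
        # sequencing errors; a real novel allele at a site contributes on
        # the order of depth/cn_total fragments, whereas even two
        # independent same-site errors stay far below that, so the required
        # evidence scales with total site depth exactly like the extension
        # switch threshold.
        separated = all(
            any(
                sum(1 for i in support_idx if s in frag_maps[i])
                >= max(2, -(-3 * depth_all[s]) // (20 * max(cn_total, 1)))
                for s in site_ids
                if c[s] != partial[s]
            )
            for c in committed
        )
        if not separated:
            if warnings is not None:
                warnings.append(
                    f"discarded weakly separated haplotype {string}"
                )
            drop = set(support_idx)
            remaining = [i for i in remaining if i not in drop]
            continue
        haps.append(Haplotype(allele_string=string, support=support))
        committed.append(dict(partial))
        remaining = [
            i
            for i in remaining
            if not any(_consistent(frag_maps[i], c) for c in committed)
        ]

    for h in haps:
        h.origin = (
            "GBA"
            if set(h.allele_string) == {"G"}
            else ("GBAP1" if set(h.allele_string) == {"P"} else "HYBRID")
        )
    return haps


# ---------------------------------------------------------------------------
# haplotype copy number
# ---------------------------------------------------------------------------


def _consistency_sets(
    haplotypes: list[Haplotype],
    fragments: list[HaplotypeFragment],
    model: ParalogModel,
) -> list[frozenset[int]]:
    site_ids = [s.site_id for s in model.phasing_sites]
    hap_maps = [
        dict(zip(site_ids, h.allele_string)) for h in haplotypes
    ]
    sets = []
    for f in fragments:
        amap = {s: a for s, a in f.alleles if a in ("G", "P")}
        if not amap:
            continue
        s = frozenset(
            i for i, hm in enumerate(hap_maps) if _consistent(amap, hm)
        )
        if s:
            sets.append(s)
    return sets


def _compositions(total: int, parts: int, minimum: int = 1):
    """All integer vectors of length ``parts`` summing to total, each >= min."""
    if parts == 0:
        if total == 0:
            yield ()
        return
    for first in range(minimum, total - minimum * (parts - 1) + 1):
        for rest in _compositions(total - first, parts - 1, minimum):
            yield (first,) + rest


def _log_likelihood(cn: tuple[int, ...], sets: list[frozenset[int]]) -> float:
    tot = sum(cn)
    ll = 0.0
    for s in sets:
        p = sum(cn[i] for i in s) / tot
        ll += np.log(max(p, 1e-300))
    return ll


def call_haplotype_cn(
    haplotypes: list[Haplotype],
    fragments: list[HaplotypeFragment],
    cn_total: int,
    model: ParalogModel,
) -> list[Haplotype]:
    """Integer CN per haplotype maximizing the fragment mixture likelihood.

    Each fragment contributes the summed proportion of the haplotypes it is
    consistent with; the composition (c_1..c_H, sum = cn_total, each >= 1)
    is found by exhaustive enumeration.  Zero-support haplotypes are
    removed beforehand.
    """
    haps = [h for h in haplotypes if h.support > 0]
    if not haps:
        return []
    if len(haps) > cn_total:
        haps = sorted(haps, key=lambda h: -h.support)[:cn_total]
    sets = _consistency_sets(haps, fragments, model)
    best, best_ll = None, -np.inf
    for comp in _compositions(cn_total, len(haps)):
        ll = _log_likelihood(comp, sets)
        if ll > best_ll + 1e-12 or (
            abs(ll - best_ll) <= 1e-12 and (best is None or comp < best)
        ):
            best, best_ll = comp, ll
    for h, c in zip(haps, best):
        h.cn = int(c)
    return haps


# ---------------------------------------------------------------------------
# scenario comparison and classification
# ---------------------------------------------------------------------------


def _suffix_sets(model: ParalogModel) -> dict[frozenset[int], str]:
    """Named recombinants by their exact pseudo-site set."""
    return {r.required_pseudo_sites: r.label for r in model.recombinants}


def haplotype_origin(allele_string: str, model: ParalogModel) -> str:
    """GBA (all gene), GBAP1 (all pseudo), HYBRID_GENE (gene haplotype with
    pseudogene-derived alleles: a real recombinant), HYBRID_PSEUDO (a
    pseudogene haplotype with gene alleles: the false-positive decoy), or
    UNCLASSIFIED."""
    ph = model.phasing_sites
    if set(allele_string) == {"G"}:
        return "GBA"
    if set(allele_string) == {"P"}:
        return "GBAP1"
    psites = frozenset(
        s.site_id for s, a in zip(ph, allele_string) if a == "P"
    )
    if psites in _suffix_sets(model):
        return "HYBRID_GENE"
    # contiguous 3' suffix of P -> recombination toward the pseudogene
    n = len(ph)
    k = allele_string.index("P")
    if allele_string[k:] == "P" * (n - k):
        return "HYBRID_GENE"
    np_ = allele_string.count("P")
    if np_ > n - np_:
        return "HYBRID_PSEUDO"
    return "UNCLASSIFIED"


def compare_scenarios(
    haplotypes: list[Haplotype],
    model: ParalogModel,
    tolerance: float = 1e-9,
) -> ScenarioCall:
    """One vs two wild-type gene copies, from haplotype support counts.

    The likelihood is multinomial over haplotypes with expected proportions
    c_h / cn_total; the wild-type CN is fixed at 1 and at >= 2 while the
    others are re-optimized (profile likelihood).  Genotype rules: two or
    more wild-type copies -> WT; one -> HET; gene-base CN 0 at a variant
    site -> HOM; more than one distinct gene-origin variant haplotype and
    no all-G haplotype -> COMPOUND_HET.
    """
    if not haplotypes or any(h.cn is None for h in haplotypes):
        raise ValueError("need CN-annotated haplotypes")
    cn_total = sum(h.cn for h in haplotypes)
    counts = [h.support for h in haplotypes]
    wt_idx = next(
        (i for i, h in enumerate(haplotypes) if set(h.allele_string) == {"G"}),
        None,
    )

    def profile(wt_constraint) -> float:
        best = -np.inf
        n = len(haplotypes)
        for comp in _compositions(cn_total, n):
            c_wt = comp[wt_idx] if wt_idx is not None else 0
            if not wt_constraint(c_wt):
                continue
            ll = sum(
                k * np.log(c / cn_total) for k, c in zip(counts, comp) if k > 0
            )
            best = max(best, ll)
        return best

    if wt_idx is None:
        l1, l2 = 0.0, -np.inf  # no wild-type haplotype at all
    else:
        l1 = profile(lambda c: c == 1)
        l2 = profile(lambda c: c >= 2)
    llr = l2 - l1

    gene_variant_haps = [
        h
        for h in haplotypes
        if haplotype_origin(h.allele_string, model) == "HYBRID_GENE" and h.cn >= 1
    ]
    wt_cn = haplotypes[wt_idx].cn if wt_idx is not None else 0

    # gene-base CN per phasing site, to detect homozygosity
    ph = model.phasing_sites
    hom_site = False
    for k, s in enumerate(ph):
        g_cn = sum(h.cn for h in haplotypes if h.allele_string[k] == "G")
        p_is_variant = any(
            v.gbap1_like and v.gene_pos == s.gene_pos for v in model.variants
        )
        if g_cn == 0 and p_is_variant:
            hom_site = True

    if len(gene_variant_haps) > 1 and wt_cn == 0:
        return ScenarioCall(1, llr, "COMPOUND_HET")
    if hom_site and wt_cn == 0 and gene_variant_haps:
        return ScenarioCall(1, llr, "HOM")
    if np.isfinite(llr) and abs(llr) <= tolerance:
        return ScenarioCall(1, 0.0, "HET", no_call=True)
    if llr > 0:
        return ScenarioCall(max(2, wt_cn), llr, "WT")
    if gene_variant_haps:
        return ScenarioCall(1, llr, "HET")
    return ScenarioCall(max(wt_cn, 1) if wt_cn >= 2 else 1, llr,
                        "WT" if wt_cn >= 2 else "HET",
                        no_call=wt_cn < 2)


def classify_recombinant(
    scenario: ScenarioCall,
    haplotypes: list[Haplotype],
    breakpoints: list,
    cn_call,
    model: ParalogModel,
    sample_id: str = "sample",
) -> SampleReport:
    """Map hybrid gene-origin haplotypes to named recombinant calls.

    Each gene-origin haplotype whose P-sites exactly match a named
    recombinant is reported under that label; unmatched suffix patterns
    are reported as the list of individual site variants.  Mechanism: CNL
    class with a CNL breakpoint 5' of the P-sites -> fusion (CNL);
    otherwise conversion (or SNV for a single site).  Pseudogene-side
    hybrids (the reverse-conversion decoys) produce no variant call.  CNG
    findings are never merged with variant calls.
    """
    report = SampleReport(
        sample_id=sample_id,
        cn_call=cn_call,
        breakpoints=list(breakpoints),
        scenario=scenario,
        haplotypes=list(haplotypes),
    )
    named = _suffix_sets(model)
    ph = model.phasing_sites
    site_label = {
        s.site_id: (s.label or f"site{s.site_id}") for s in ph
    }
    cnv = cn_call.cnv_class if cn_call is not None else "NONE"
    wt_cn = sum(
        h.cn or 0 for h in haplotypes if set(h.allele_string) == {"G"}
    )

    # decoy guard: a clean diploid with two wild-type gene copies cannot
    # carry a gene variant in the phasing region
    suppress = cnv == "NONE" and wt_cn >= 2

    cnl_bp = [b for b in breakpoints if b.kind == "CNL"]
    for h in haplotypes:
        origin = haplotype_origin(h.allele_string, model)
        if origin in ("GBA", "GBAP1"):
            continue
        if origin == "HYBRID_PSEUDO":
            report.warnings.append(
                f"pseudogene-side hybrid {h.allele_string} (no call)"
            )
            continue
        if suppress:
            report.warnings.append(
                f"gene-origin hybrid {h.allele_string} suppressed: "
                "two wild-type copies and no CNV"
            )
            continue
        if origin == "UNCLASSIFIED":
            report.recombinant_calls.append(
                RecombinantCall(
                    label=h.allele_string,
                    genotype="HET" if (h.cn or 1) == 1 else "HOM",
                    mechanism="CONVERSION",
                    flags=("UNCLASSIFIED",),
                )
            )
            continue
        psites = h.p_site_ids(model)
        label = named.get(psites)
        flags: tuple[str, ...] = ()
        if label is None:
            label = "+".join(site_label[s] for s in sorted(psites))
            flags = ("unnamed_combination",)
        n_p = len(psites)
        if cnv == "CNL" and cnl_bp:
            # the hybrid is the fusion haplotype: its P-suffix continues
            # into the pseudogene across the deletion junction
            mechanism = "CNL"
        elif n_p == 1:
            mechanism = "SNV"
        else:
            mechanism = "CONVERSION"
        genotype = "HET" if (h.cn or 1) == 1 else "HOM"
        if scenario is not None and scenario.genotype == "HOM":
            genotype = "HOM"
        report.recombinant_calls.append(
            RecombinantCall(label=label, genotype=genotype,
                            mechanism=mechanism, flags=flags)
        )
    return report
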