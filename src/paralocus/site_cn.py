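"""Gene copy number at every differentiating site; breakpoints as CN steps.

Reads from the homology region land on either paralog more or less at
random, so no per-site quantity that depends on placement can be trusted.
What IS conserved is the pooled count: at each differentiating site the
reads covering its gene position plus those covering its pseudogene
position together sample all cn_total copies, and the fraction carrying
the gene base estimates cn_gene / cn_total.  A fusion deletion (CNL)
removes the gene base 3' of its breakpoint (cn_gene 2 -> 1), a duplication
(CNG) adds gene-side copies 5' of its breakpoint (2 -> 2+e), and a gene
conversion dips to 1 and back within a diploid sample, so CNV breakpoints
appear as steps in the site-CN series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from scipy import stats

from paralocus.region_model import (
    DifferentiatingSite,
    GenomicInterval,
    ParalogModel,
)

__all__ = [
    "SiteCounts",
    "SiteCNSeries",
    "BreakpointCall",
    "count_site_bases",
    "estimate_site_cn",
    "build_site_cn_series",
    "detect_cn_transitions",
    "classify_cnl_pathogenicity",
    "site_counts_to_tsv",
]

EPSILON = 0.01  # error-rate floor on the binomial success probability
MIN_SITE_DEPTH = 10
MIN_BASE_QUALITY = 13
_INDEL_SLACK = 5  # bp tolerance on indel event placement


@dataclass(frozen=True)
class SiteCounts:
    site_id: int
    k_gene: int
    k_pseudo: int
    k_other: int
    uncovered: bool = False

    def __post_init__(self) -> None:
        if min(self.k_gene, self.k_pseudo, self.k_other) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def depth(self) -> int:
        return self.k_gene + self.k_pseudo


@dataclass(frozen=True)
class BreakpointCall:
    """CN step between two adjacent called sites; open interval (left, right)."""

    kind: str  # CNL | CNG | CONVERSION_START | CONVERSION_END | UNRESOLVED
    site_id_left: int
    site_id_right: int
    pos_left: int  # gene_pos of the left site
    pos_right: int
    contig: str
    cn_before: int
    cn_after: int
    pathogenic: bool | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.site_id_left >= self.site_id_right:
            raise ValueError("site_id_left must precede site_id_right")

    @property
    def span(self) -> GenomicInterval:
        """Genomic span of the open interval, as half-open coordinates."""
        return GenomicInterval(self.contig, self.pos_left + 1, self.pos_right)

    def contains(self, pos: int) -> bool:
        return self.pos_left < pos < self.pos_right


@dataclass
class SiteCNSeries:
    """Ordered (site_id, cn_gene, posterior) for sites passing depth."""

    entries: list[tuple[int, int, float]]
    cn_total: int

    def __post_init__(self) -> None:
        for sid, cn, _ in self.entries:
            if not 0 <= cn <= self.cn_total:
                raise ValueError(f"cn_gene {cn} outside [0, cn_total] at site {sid}")

    @property
    def site_ids(self) -> list[int]:
        return [e[0] for e in self.entries]

    @property
    def cn_values(self) -> list[int]:
        return [e[1] for e in self.entries]


def _base_calls_for_read(
    read: pysam.AlignedSegment,
    pos_to_site: dict[int, tuple[int, str]],
    positions: np.ndarray,
    min_bq: int,
) -> list[tuple[int, str]]:
    """(site_id, observed base) for every SNV site this read covers."""
    out = []
    seq = read.query_sequence
    quals = read.query_qualities
    cig = read.cigartuples
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        r0 = read.reference_start
        lo = np.searchsorted(positions, r0)
        hi = np.searchsorted(positions, r0 + cig[0][1])
        for p in positions[lo:hi]:
            q = p - r0
            if quals is None or quals[q] >= min_bq:
                out.append((pos_to_site[int(p)][0], seq[q]))
        return out
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        hit = pos_to_site.get(rpos)
        if hit is not None and (quals is None or quals[qpos] >= min_bq):
            out.append((hit[0], seq[qpos]))
    return out


def _indel_allele(read: pysam.AlignedSegment, site: DifferentiatingSite, frame: str) -> str | None:
    """Type one read at an indel differentiating site.

    Both frames are anchored at the event start so their acceptance windows
    are identical (otherwise the CN estimate at this site is biased).  A
    read must cover the anchor with >= 2 bp on each side.  Gene frame: the
    insertion exists in the reference, so alignment through the anchor
    carries the gene allele and a matching deletion the pseudogene allele.
    Pseudogene frame: contiguous alignment across pseudo_pos carries the
    pseudogene allele, a matching insertion the gene allele.
    """
    L = site.indel_length
    anchor = site.gene_pos if frame == "gene" else site.pseudo_pos
    end = read.reference_end
    if read.reference_start > anchor - 2 or end is None or end < anchor + 2:
        return None
    ref = read.reference_start
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            ref += ln
        elif op == 2:  # D
            if (
                frame == "gene"
                and ln >= L - _INDEL_SLACK
                and abs(ref - anchor) <= _INDEL_SLACK
            ):
                return "P"
            ref += ln
        elif op == 1:  # I
            if (
                frame == "pseudo"
                and ln >= L - _INDEL_SLACK
                and abs(ref - anchor) <= _INDEL_SLACK
            ):
                return "G"
        elif op == 3:
            ref += ln
    return "G" if frame == "gene" else "P"


def _read_ok(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_duplicate
        or read.is_secondary
        or read.is_supplementary
        or read.is_unmapped
    )


def collect_site_observations(
    alignments: str | Path | pysam.AlignmentFile,
    model: ParalogModel,
    min_base_quality: int = MIN_BASE_QUALITY,
    sites: list[DifferentiatingSite] | None = None,
) -> dict[int, dict[str, str]]:
    """Per-site observed allele class per read name, pooled over paralogs.

    Returns {site_id: {read_name: 'G'|'P'|'O'}}.  Reads are pooled over the
    gene and pseudogene positions of each site; a read pair observing the
    same site twice (directly or via its paralog copy) counts once, and
    conflicting mate observations drop the site for that pair.  No mapping
    quality filter is applied — homology-region reads legitimately carry
    MAPQ 0.
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    bam = pysam.AlignmentFile(str(alignments)) if own else alignments
    if sites is None:
        sites = model.sites
    snv_sites = [s for s in sites if not s.is_indel]
    indel_sites = [s for s in sites if s.is_indel]

    pos_to_site: dict[int, tuple[int, str]] = {}
    alleles: dict[int, tuple[str, str]] = {}
    for s in snv_sites:
        pos_to_site[s.gene_pos] = (s.site_id, "gene")
        pos_to_site[s.pseudo_pos] = (s.site_id, "pseudo")
        alleles[s.site_id] = (s.gene_base, s.pseudo_base)
    positions = np.array(sorted(pos_to_site), dtype=np.int64)

    obs: dict[int, dict[str, str]] = {s.site_id: {} for s in sites}
    conflicted: dict[int, set[str]] = {s.site_id: set() for s in sites}

    def record(sid: int, name: str, cls: str) -> None:
        prev = obs[sid].get(name)
        if prev is None:
            obs[sid][name] = cls
        elif prev != cls:
            conflicted[sid].add(name)

    contig = model.gene.contig
    regions = [
        (model.gene.start - 200, model.gene.end + 200),
        (model.pseudogene.start - 200, model.pseudogene.end + 200),
    ]
    seen: set[tuple[str, int, bool]] = set()
    try:
        for lo, hi in regions:
            for read in bam.fetch(contig, max(0, lo), hi):
                if not _read_ok(read):
                    continue
                key = (read.query_name, read.reference_start, read.is_read1)
                if key in seen:
                    continue  # regions may overlap
                seen.add(key)
                for sid, base in _base_calls_for_read(
                    read, pos_to_site, positions, min_base_quality
                ):
                    g, p = alleles[sid]
                    cls = "G" if base == g else ("P" if base == p else "O")
                    record(sid, read.query_name, cls)
                for s in indel_sites:
                    for frame, pos in (("gene", s.gene_pos), ("pseudo", s.pseudo_pos)):
                        if read.reference_start <= pos <= (read.reference_end or -1):
                            a = _indel_allele(read, s, frame)
                            if a is not None:
                                record(s.site_id, read.query_name, a)
                            break
    finally:
        if own:
            bam.close()
    for sid, names in conflicted.items():
        for name in names:
            obs[sid].pop(name, None)
    return obs


def count_site_bases(
    alignments: str | Path | pysam.AlignmentFile,
    model: ParalogModel,
    min_base_quality: int = MIN_BASE_QUALITY,
) -> list[SiteCounts]:
    """Pooled gene/pseudogene allele counts at every differentiating site."""
    obs = collect_site_observations(alignments, model, min_base_quality)
    out = []
    for s in model.sites:
        classes = list(obs[s.site_id].values())
        kg = classes.count("G")
        kp = classes.count("P")
        ko = classes.count("O")
        out.append(
            SiteCounts(s.site_id, kg, kp, ko, uncovered=(kg + kp + ko) == 0)
        )
    return out


def site_cn_log_likelihoods(
    k_gene: int, depth: int, cn_total: int, epsilon: float = EPSILON
) -> np.ndarray:
    c = np.arange(cn_total + 1)
    p = np.clip(c / cn_total, epsilon, 1 - epsilon)
    return stats.binom.logpmf(k_gene, depth, p)


def estimate_site_cn(
    counts: SiteCounts,
    cn_total: int,
    min_site_depth: int = MIN_SITE_DEPTH,
    epsilon: float = EPSILON,
) -> tuple[int, float] | None:
    """MAP gene CN at one site; None when pooled depth is below threshold."""
    if cn_total < 1:
        raise ValueError("cn_total must be >= 1")
    n = counts.depth
    if n < min_site_depth:
        return None
    ll = site_cn_log_likelihoods(counts.k_gene, n, cn_total, epsilon)
    post = np.exp(ll - ll.max())
    post /= post.sum()
    c = int(np.argmax(post))
    return c, float(post[c])


def build_site_cn_series(
    counts: list[SiteCounts],
    cn_total: int,
    min_site_depth: int = MIN_SITE_DEPTH,
    epsilon: float = EPSILON,
) -> SiteCNSeries:
    entries = []
    for sc in counts:
        est = estimate_site_cn(sc, cn_total, min_site_depth, epsilon)
        if est is not None:
            entries.append((sc.site_id, est[0], est[1]))
    return SiteCNSeries(entries=entries, cn_total=cn_total)


def _median_filter3(values: list[int]) -> list[int]:
    """Window-3 median filter keeping the endpoints unfiltered."""
    if len(values) < 3:
        return list(values)
    out = list(values)
    for i in range(1, len(values) - 1):
        out[i] = int(np.median(values[i - 1 : i + 2]))
    return out


def detect_cn_transitions(
    series: SiteCNSeries, model: ParalogModel, min_posterior: float = 0.9
) -> list[BreakpointCall]:
    """CN steps in the (masked, median-filtered) site series, typed by class.

    Sites whose CN posterior is below ``min_posterior`` are masked before
    scanning (they sit between integer allele fractions and flip freely);
    the remaining series is median-filtered (window 3) to suppress
    single-site flips.  With cn_total 3 a 2->1 drop is a CNL breakpoint;
    with cn_total >= 5 a 2->3(+) rise is a CNG breakpoint; with cn_total 4
    a dip and recovery bracket a gene-conversion segment.  Steps
    inconsistent with that pattern are reported with kind UNRESOLVED rather
    than raised.
    """
    entries = [e for e in series.entries if e[2] >= min_posterior]
    if len(entries) < 2:
        return []
    from paralocus.coverage_cn import cnv_class_of

    cnv_class = cnv_class_of(series.cn_total - 2)
    pos = {s.site_id: s.gene_pos for s in model.sites}
    contig = model.gene.contig
    sids = [e[0] for e in entries]
    values = _median_filter3([e[1] for e in entries])

    calls: list[BreakpointCall] = []
    open_conversion = False
    for i in range(1, len(values)):
        c0, c1 = values[i - 1], values[i]
        if c0 == c1:
            continue
        kind = "UNRESOLVED"
        flags: tuple[str, ...] = ()
        if cnv_class == "CNL" and c1 < c0:
            kind = "CNL"
        elif cnv_class == "CNG" and c1 > c0:
            kind = "CNG"
        elif cnv_class == "NONE" and c1 < c0:
            kind = "CONVERSION_START"
            open_conversion = True
        elif cnv_class == "NONE" and c1 > c0:
            if open_conversion:
                kind = "CONVERSION_END"
                open_conversion = False
            else:
                flags = ("rise_without_dip",)
        calls.append(
            BreakpointCall(
                kind=kind,
                site_id_left=sids[i - 1],
                site_id_right=sids[i],
                pos_left=pos[sids[i - 1]],
                pos_right=pos[sids[i]],
                contig=contig,
                cn_before=c0,
                cn_after=c1,
                flags=flags,
            )
        )
    if open_conversion:
        # CN dropped with cnv_class NONE and never returned
        last = calls[-1]
        calls[-1] = BreakpointCall(
            kind="UNRESOLVED",
            site_id_left=last.site_id_left,
            site_id_right=last.site_id_right,
            pos_left=last.pos_left,
            pos_right=last.pos_right,
            contig=last.contig,
            cn_before=last.cn_before,
            cn_after=last.cn_after,
            flags=last.flags + ("unterminated_conversion",),
        )
    return calls


def classify_cnl_pathogenicity(bp: BreakpointCall, model: ParalogModel) -> bool:
    """A CNL is pathogenic iff its breakpoint interval can touch coding gene.

    The open interval between the bracketing sites is intersected with the
    gene coding region; intervals straddling the coding 3' boundary count
    as pathogenic (the breakpoint may lie inside).
    """
    if bp.kind != "CNL":
        raise ValueError("pathogenicity applies to CNL breakpoints only")
    span = bp.span
    coding = model.coding_region
    return max(span.start, coding.start) < min(span.end, coding.end)


def site_counts_to_tsv(
    counts: list[SiteCounts],
    model: ParalogModel,
    path: str | Path,
    series: SiteCNSeries | None = None,
) -> Path:
    path = Path(path)
    cn = dict((sid, (c, p)) for sid, c, p in (series.entries if series else []))
    with open(path, "w") as fh:
        fh.write("site_id\tgene_pos\tpseudo_pos\tk_gene\tk_pseudo\tk_other\tcn_gene\tposterior\n")
        site = {s.site_id: s for s in model.sites}
        for sc in counts:
            s = site[sc.site_id]
            c, p = cn.get(sc.site_id, ("NA", "NA"))
            post = f"{p:.4f}" if isinstance(p, float) else p
            fh.write(
                f"{sc.site_id}\t{s.gene_pos + 1}\t{s.pseudo_pos + 1}\t"
                f"{sc.k_gene}\t{sc.k_pseudo}\t{sc.k_other}\t{c}\t{post}\n"
            )
    return path
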