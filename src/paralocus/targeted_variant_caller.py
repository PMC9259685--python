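"""Direct genotyping of known target variants outside the homology region.

Outside the gene/pseudogene homology region alignments are trustworthy,
so known variants (p.N409S, c.84dupG, ...) are genotyped directly from
read support with a conventional MAPQ filter, using the same
integer-copy-number binomial as the site-level caller: the variant copy
number is the argmax over c in {0..local_cn} of Binomial(k_alt; k_alt +
k_ref, c/local_cn).  Indel support is taken from CIGAR-declared events
overlapping the locus with a small positional slack, since aligners
left/right-shift indels differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from scipy import stats

from paralocus.region_model import ParalogModel, TargetVariant

__all__ = ["VariantObservation", "call_known_variants", "genotype_from_counts"]

MIN_DEPTH = 10
MIN_MAPQ = 20
EPSILON = 0.01
_INDEL_SLACK = 2


@dataclass(frozen=True)
class VariantObservation:
    variant: str  # TargetVariant label
    k_alt: int
    k_ref: int
    k_other: int
    local_cn: int = 2

    def __post_init__(self) -> None:
        if min(self.k_alt, self.k_ref, self.k_other) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def depth(self) -> int:
        return self.k_alt + self.k_ref


def genotype_from_counts(
    obs: VariantObservation, epsilon: float = EPSILON
) -> tuple[str, float] | None:
    """(genotype, posterior) from one observation; None below min depth."""
    n = obs.depth
    if n < MIN_DEPTH:
        return None
    c = np.arange(obs.local_cn + 1)
    p = np.clip(c / obs.local_cn, epsilon, 1 - epsilon)
    ll = stats.binom.logpmf(obs.k_alt, n, p)
    post = np.exp(ll - ll.max())
    post /= post.sum()
    best = int(np.argmax(post))
    genotype = "ABSENT" if best == 0 else ("HOM" if best == obs.local_cn else "HET")
    return genotype, float(post[best])


def _observe_snv(
    bam: pysam.AlignmentFile,
    v: TargetVariant,
    contig: str,
    min_mapq: int,
    min_bq: int,
) -> VariantObservation:
    seen: dict[str, str] = {}
    for read in bam.fetch(contig, v.gene_pos, v.gene_pos + 1):
        if read.mapping_quality < min_mapq or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if rpos == v.gene_pos:
                if read.query_qualities is None or read.query_qualities[qpos] >= min_bq:
                    base = read.query_sequence[qpos]
                    prev = seen.get(read.query_name)
                    if prev is None:
                        seen[read.query_name] = base
                    elif prev != base:
                        seen[read.query_name] = "_conflict_"
                break
    k_alt = sum(1 for b in seen.values() if b == v.alt_allele)
    k_ref = sum(1 for b in seen.values() if b == v.ref_allele)
    k_other = sum(
        1 for b in seen.values() if b not in (v.alt_allele, v.ref_allele)
    )
    return VariantObservation(v.label, k_alt, k_ref, k_other)


def _observe_insertion(
    bam: pysam.AlignmentFile, v: TargetVariant, contig: str, min_mapq: int
) -> VariantObservation:
    """Duplication/insertion-type variant: alt longer than ref (c.84dupG)."""
    ins_len = len(v.alt_allele) - len(v.ref_allele)
    locus = v.gene_pos + len(v.ref_allele)  # insertions placed after ref base
    seen: dict[str, str] = {}
    for read in bam.fetch(contig, max(0, v.gene_pos - 5), v.gene_pos + 6):
        if read.mapping_quality < min_mapq or read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        if read.reference_start > v.gene_pos - 2 or (
            read.reference_end or 0
        ) < v.gene_pos + 3:
            continue  # must bridge the locus with margin
        allele = "ref"
        ref = read.reference_start
        for op, ln in read.cigartuples:
            if op in (0, 7, 8):
                ref += ln
            elif op == 1:
                if ln == ins_len and abs(ref - locus) <= _INDEL_SLACK:
                    allele = "alt"
            elif op in (2, 3):
                ref += ln
        prev = seen.get(read.query_name)
        if prev is None:
            seen[read.query_name] = allele
        elif prev != allele:
            seen[read.query_name] = "_conflict_"
    k_alt = sum(1 for a in seen.values() if a == "alt")
    k_ref = sum(1 for a in seen.values() if a == "ref")
    return VariantObservation(v.label, k_alt, k_ref, 0)


def call_known_variants(
    alignments: str | Path | pysam.AlignmentFile,
    model: ParalogModel,
    local_cn: int = 2,
    min_mapq: int = MIN_MAPQ,
    min_base_quality: int = 13,
) -> list[tuple[str, str, float]]:
    """Genotypes of all target variants flagged outside the homology region.

    Returns (label, genotype in {ABSENT, HET, HOM}, posterior); variants
    whose locus has fewer than 10 informative reads are reported with
    genotype NO_CALL and posterior 0.
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    bam = pysam.AlignmentFile(str(alignments)) if own else alignments
    contig = model.gene.contig
    out = []
    try:
        for v in model.variants:
            if v.in_homology_region:
                continue
            if len(v.alt_allele) > len(v.ref_allele):
                obs = _observe_insertion(bam, v, contig, min_mapq)
            else:
                obs = _observe_snv(bam, v, contig, min_mapq, min_base_quality)
            obs = VariantObservation(
                obs.variant, obs.k_alt, obs.k_ref, obs.k_other, local_cn
            )
            res = genotype_from_counts(obs)
            if res is None:
                out.append((v.label, "NO_CALL", 0.0))
            else:
                out.append((v.label, res[0], res[1]))
    finally:
        if own:
            bam.close()
    return out
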