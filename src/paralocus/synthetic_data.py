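"""Miniature gene/pseudogene reference and paired-end read simulator.

Builds a ~52 kb single-contig reference emulating the salient features of
the GBA/GBAP1 locus: a ~9 kb gene, a 10 kb unique spacer, a ~9 kb
pseudogene copy at ~96% identity overall rising to ~98% in the 3' homology
block, ten clustered phasing sites 14-315 bp apart (one of them a 55 bp
gene-only insertion, the c.1263del55 analogue), two coding homopolymer
runs, and flanking baseline sequence for depth normalization.

Reads are simulated from explicitly constructed haplotypes (wild-type,
SNV, conversion, fusion-deletion, duplication) and then *placed* by a
paralog-ambiguity rule: each read overlapping the paralogs is aligned
against both homologous locations and assigned to the fewer-mismatch one,
with ties going to the gene position at mapping quality 0.  This
reproduces the one property of real aligners that matters downstream —
homology-region reads land on either paralog more or less arbitrarily —
so the pooled counting in the caller can be tested against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pysam

from paralocus.region_model import (
    DELETION_ALLELE,
    DifferentiatingSite,
    GenomicInterval,
    NamedRecombinant,
    ParalogModel,
    TargetVariant,
)

CONTIG = "mini1"
FLANK = 12000
GENE_CORE = 9000  # aligned gene length, excluding the 55 bp insertion
INDEL_LEN = 55
SPACER = 10000

# gene-relative layout
_INDEL_REL = 7199  # assigned during construction; see _phasing_positions
_CODING_REL = (800, 8000)
_BLOCK_REL_START = 6500  # start of the high-identity 3' block
_HOMOPOLYMERS_REL = ((3000, 3006, "G"), (3200, 3205, "C"))
_VARIANT_REL = {"c.84dupG": 900, "p.E365K": 6100, "p.N409S": 6300}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _seq_to_str(a: np.ndarray) -> str:
    return a.tobytes().decode()


def _other_base(rng: np.random.Generator, base: int) -> int:
    choices = _BASES[_BASES != base]
    return int(rng.choice(choices))


@dataclass
class MiniReference:
    """A synthetic paralog locus: the contig sequence plus its region model."""

    sequence: np.ndarray  # uint8 ASCII
    model: ParalogModel
    homology_block: GenomicInterval  # recombination-competent 3' block
    gene_offset: int = FLANK
    pseudo_offset: int = FLANK + GENE_CORE + INDEL_LEN + SPACER
    indel_rel: int = _INDEL_REL

    @property
    def contig(self) -> str:
        return CONTIG

    @property
    def sequence_str(self) -> str:
        return _seq_to_str(self.sequence)

    @property
    def indel_abs(self) -> tuple[int, int]:
        start = self.gene_offset + self.indel_rel
        return start, start + INDEL_LEN

    def gene_to_pseudo(self, pos: int) -> int:
        """Homologous pseudogene coordinate of a gene-frame position.

        Extends linearly a short way beyond the gene edges so that reads
        overhanging the gene can still be scored at the pseudogene."""
        rel = pos - self.gene_offset
        i0, i1 = self.indel_abs
        if i0 <= pos < i1:
            raise ValueError(f"position {pos} inside the gene-only insertion")
        if rel >= self.indel_rel + INDEL_LEN:
            rel -= INDEL_LEN
        return self.pseudo_offset + rel

    def pseudo_to_gene(self, pos: int) -> int:
        rel = pos - self.pseudo_offset
        if rel >= self.indel_rel:
            rel += INDEL_LEN
        return self.gene_offset + rel

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f">{CONTIG}\n")
            s = self.sequence_str
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
        pysam.faidx(str(path))
        return path


def build_mini_reference(
    seed: int,
    identity_overall: float = 0.96,
    identity_homology: float = 0.98,
) -> MiniReference:
    """Construct the synthetic locus.  Deterministic given ``seed``.

    ``identity_overall`` is the gene/pseudogene identity over the whole
    aligned gene; ``identity_homology`` the identity within the 3' block.
    Every substitution is recorded as a differentiating site; ten clustered
    sites inside the block (gaps 14-315 bp) form the phasing set, the sixth
    being the 55 bp gene-only insertion.
    """
    for ident in (identity_overall, identity_homology):
        if not 0.9 < ident < 1.0:
            raise ValueError(f"identity {ident} outside (0.9, 1.0)")
    rng = np.random.default_rng(seed)

    total_len = FLANK + GENE_CORE + INDEL_LEN + SPACER + GENE_CORE + FLANK
    gene_off = FLANK
    pseudo_off = FLANK + GENE_CORE + INDEL_LEN + SPACER

    # background sequence in 1 kb blocks of varying GC so that GC strata exist
    seq = np.empty(total_len, dtype=np.uint8)
    for start in range(0, total_len, 1000):
        end = min(start + 1000, total_len)
        gc = rng.uniform(0.35, 0.65)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq[start:end] = rng.choice(_BASES, size=end - start, p=p)

    # homopolymer runs (gene-relative)
    for h0, h1, base in _HOMOPOLYMERS_REL:
        seq[gene_off + h0 : gene_off + h1] = ord(base)

    # --- phasing-set positions (gene-relative, before the insertion shift) --
    gaps = rng.integers(14, 120, size=9)
    gaps[5] = INDEL_LEN + int(rng.integers(14, 65))  # room for the insertion
    phasing_rel = [6850]
    for g in gaps:
        phasing_rel.append(phasing_rel[-1] + int(g))
    indel_rel = phasing_rel[5]
    hom_rel = (phasing_rel[0] - 7, phasing_rel[-1] + 8)

    # --- choose substitution positions -------------------------------------
    n_block = round((1 - identity_homology) * (GENE_CORE - _BLOCK_REL_START)) - 9
    n_outside = (
        round((1 - identity_overall) * GENE_CORE) - n_block - 10
    )  # 10 = 9 phasing SNVs + the indel column

    forbidden = set(phasing_rel)
    forbidden.update(range(indel_rel - 2, indel_rel + INDEL_LEN + 2))
    forbidden.update(range(hom_rel[0], hom_rel[1]))
    for h0, h1, _ in _HOMOPOLYMERS_REL:
        forbidden.update(range(h0 - 1, h1 + 1))
    forbidden.update(_VARIANT_REL.values())

    def _draw(lo: int, hi: int, n: int) -> list[int]:
        pool = np.array(sorted(set(range(lo, hi)) - forbidden))
        pos = rng.choice(pool, size=n, replace=False)
        forbidden.update(int(p) for p in pos)
        return sorted(int(p) for p in pos)

    block_subs = _draw(_BLOCK_REL_START, GENE_CORE, n_block)
    outside_subs = _draw(0, _BLOCK_REL_START, n_outside)

    # --- build the gene (already in seq) and the pseudogene copy -----------
    # pseudogene = gene core without the 55 bp insertion, pseudo bases at sites
    # NOTE: seq currently has independent random sequence at the pseudogene
    # location; overwrite it with the homologous copy.
    def rel_to_abs_gene(rel: int) -> int:
        return gene_off + rel + (INDEL_LEN if rel >= indel_rel else 0)

    gene_core_idx = np.array(
        [rel_to_abs_gene(rel) for rel in range(GENE_CORE)], dtype=np.int64
    )
    seq[pseudo_off : pseudo_off + GENE_CORE] = seq[gene_core_idx]

    sub_rels = sorted(outside_subs + block_subs + [r for r in phasing_rel if r != indel_rel])
    sites: list[DifferentiatingSite] = []
    site_id = 0
    all_rels = sorted(sub_rels + [indel_rel])
    phasing_ids: dict[int, int] = {}
    labels_by_rel = {
        phasing_rel[5]: "c.1263del55",
        phasing_rel[6]: "p.D448H",
        phasing_rel[7]: "p.L483P",
        phasing_rel[8]: "p.A495P",
        phasing_rel[9]: "p.Val499=",
    }
    for rel in all_rels:
        site_id += 1
        gene_pos = rel_to_abs_gene(rel)
        pseudo_pos = pseudo_off + rel
        in_phasing = rel in phasing_rel
        sentinel = rel >= _BLOCK_REL_START
        if rel == indel_rel:
            # the insertion starts at the unshifted coordinate; aligned
            # positions >= indel_rel sit 55 bp further 3'
            gene_pos = gene_off + rel
            gene_allele = _seq_to_str(seq[gene_pos : gene_pos + INDEL_LEN])
            pseudo_allele = DELETION_ALLELE
        else:
            gb = int(seq[gene_pos])
            pb = _other_base(rng, gb)
            seq[pseudo_pos] = pb
            gene_allele, pseudo_allele = chr(gb), chr(pb)
        sites.append(
            DifferentiatingSite(
                site_id=site_id,
                gene_pos=gene_pos,
                pseudo_pos=pseudo_pos,
                gene_base=gene_allele,
                pseudo_base=pseudo_allele,
                in_phasing_set=in_phasing,
                is_sentinel=sentinel,
                label=labels_by_rel.get(rel),
            )
        )
        if in_phasing:
            phasing_ids[phasing_rel.index(rel)] = site_id

    ps = [phasing_ids[i] for i in range(10)]

    # --- intervals ----------------------------------------------------------
    gene = GenomicInterval(CONTIG, gene_off, gene_off + GENE_CORE + INDEL_LEN)
    pseudo = GenomicInterval(CONTIG, pseudo_off, pseudo_off + GENE_CORE)
    unique = GenomicInterval(CONTIG, gene.end + 500, pseudo.start - 500)
    homology = GenomicInterval(
        CONTIG, rel_to_abs_gene(hom_rel[0]), rel_to_abs_gene(hom_rel[1] - 1) + 1
    )
    coding = GenomicInterval(
        CONTIG, rel_to_abs_gene(_CODING_REL[0]), rel_to_abs_gene(_CODING_REL[1])
    )
    homopolymers = [
        GenomicInterval(CONTIG, rel_to_abs_gene(h0), rel_to_abs_gene(h1 - 1) + 1)
        for h0, h1, _ in _HOMOPOLYMERS_REL
    ]

    # --- target variants ----------------------------------------------------
    site_by_id = {s.site_id: s for s in sites}

    def _phasing_variant(label: str, idx: int, severity: str) -> TargetVariant:
        s = site_by_id[ps[idx]]
        return TargetVariant(
            label=label,
            gene_pos=s.gene_pos,
            ref_allele=s.gene_base,
            alt_allele=s.pseudo_base,
            gbap1_like=True,
            in_homology_region=True,
            severity=severity,
        )

    dup_rel = _VARIANT_REL["c.84dupG"]
    seq[gene_off + dup_rel] = ord("G")
    n409_rel = _VARIANT_REL["p.N409S"]
    e365_rel = _VARIANT_REL["p.E365K"]
    variants = [
        TargetVariant(
            "c.84dupG", rel_to_abs_gene(dup_rel), "G", "GG", severity="severe"
        ),
        TargetVariant(
            "p.E365K",
            rel_to_abs_gene(e365_rel),
            chr(int(seq[rel_to_abs_gene(e365_rel)])),
            chr(_other_base(rng, int(seq[rel_to_abs_gene(e365_rel)]))),
            severity="risk",
        ),
        TargetVariant(
            "p.N409S",
            rel_to_abs_gene(n409_rel),
            chr(int(seq[rel_to_abs_gene(n409_rel)])),
            chr(_other_base(rng, int(seq[rel_to_abs_gene(n409_rel)]))),
            severity="mild",
        ),
        _phasing_variant("c.1263del55", 5, "severe"),
        _phasing_variant("p.D448H", 6, "severe"),
        _phasing_variant("p.L483P", 7, "severe"),
        _phasing_variant("p.A495P", 8, "unknown"),
    ]

    recombinants = [
        NamedRecombinant("p.L483P", frozenset({ps[7]})),
        NamedRecombinant("p.D448H", frozenset({ps[6]})),
        NamedRecombinant("c.1263del55", frozenset({ps[5]})),
        NamedRecombinant("RecNciI", frozenset(ps[7:])),
        NamedRecombinant("RecTL", frozenset(ps[6:])),
        NamedRecombinant("c.1263del+RecTL", frozenset(ps[5:])),
    ]

    model = ParalogModel(
        gene=gene,
        pseudogene=pseudo,
        unique_cn_region=unique,
        homology_region=homology,
        coding_region=coding,
        sites=sites,
        variants=variants,
        recombinants=recombinants,
        homopolymers=homopolymers,
    )
    block = GenomicInterval(CONTIG, rel_to_abs_gene(_BLOCK_REL_START), gene.end)
    return MiniReference(
        sequence=seq, model=model, homology_block=block, indel_rel=indel_rel
    )


# ---------------------------------------------------------------------------
# allele specifications and haplotype construction
# ---------------------------------------------------------------------------

_KINDS = ("WT", "SNV", "CONVERSION", "CNL", "CNG", "PSEUDO_CONVERSION")


@dataclass
class AlleleSpec:
    """One event on one parental chromosome.

    kind:
      WT                  no change
      SNV                 known target variant, by label
      CONVERSION          gene segment replaced by pseudogene alleles over an
                          inclusive site-id range (non-reciprocal recombination)
      CNL                 fusion deletion with breakpoint at ``breakpoint_pos``
                          (gene-frame, inside the homology block)
      CNG                 duplication of the inter-homology unit,
                          ``extra_copies`` in 1..6
      PSEUDO_CONVERSION   pseudogene sites carrying gene alleles (the
                          reverse-conversion decoys of real GBAP1 haplotypes)
    """

    kind: str
    label: str | None = None
    start_site: int | None = None
    end_site: int | None = None
    breakpoint_pos: int | None = None
    extra_copies: int | None = None
    sites: tuple[int, ...] = ()

    def validate(self, ref: MiniReference) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown allele kind {self.kind}")
        if self.kind in ("CNL", "CNG"):
            bp = self.breakpoint_pos
            if bp is None or not ref.homology_block.contains(bp):
                raise ValueError("breakpoint must lie inside the homology block")
            i0, i1 = ref.indel_abs
            if i0 <= bp < i1 + 1:
                raise ValueError("breakpoint inside the gene-only insertion")
        if self.kind == "CNG" and not 1 <= int(self.extra_copies or 0) <= 6:
            raise ValueError("extra_copies must be in 1..6")
        if self.kind == "SNV" and self.label is None:
            raise ValueError("SNV spec needs a variant label")
        if self.kind == "CONVERSION" and (
            self.start_site is None or self.end_site is None
        ):
            raise ValueError("conversion spec needs start_site/end_site")


@dataclass
class SimulationConfig:
    seed: int
    depth: float = 30.0
    read_len: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 60.0
    error_rate: float = 0.002
    gc_bias_slope: float = 0.0  # depth multiplier change per 10% GC

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("depth", "read_len", "insert_mean", "insert_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate out of range")


def build_haplotype(
    ref: MiniReference, specs: list[AlleleSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """Construct one chromosome: (sequence, origin) arrays.

    ``origin[i]`` is the reference coordinate each haplotype base derives
    from (-1 for inserted bases).  Structural events are applied first, then
    point edits; at most one structural event per chromosome.
    """
    for sp in specs:
        sp.validate(ref)
    structural = [sp for sp in specs if sp.kind in ("CNL", "CNG")]
    if len(structural) > 1:
        raise ValueError("at most one structural event per chromosome")

    seq = ref.sequence.copy()
    orig = np.arange(len(seq), dtype=np.int64)

    if structural:
        sp = structural[0]
        bp = int(sp.breakpoint_pos)
        pbp = ref.gene_to_pseudo(bp)
        if sp.kind == "CNL":
            seq = np.concatenate([seq[:bp], seq[pbp:]])
            orig = np.concatenate([orig[:bp], orig[pbp:]])
        else:  # CNG
            e = int(sp.extra_copies)
            seq = np.concatenate(
                [seq[:bp]] + [seq[bp:pbp]] * (e + 1) + [seq[pbp:]]
            )
            orig = np.concatenate(
                [orig[:bp]] + [orig[bp:pbp]] * (e + 1) + [orig[pbp:]]
            )

    site_by_id = {s.site_id: s for s in ref.model.sites}
    variant_by_label = {v.label: v for v in ref.model.variants}

    deletions: list[tuple[int, int]] = []  # reference intervals to remove
    insertions: list[tuple[int, str]] = []  # (reference pos, seq inserted before it)

    def set_base(ref_pos: int, base: str) -> None:
        seq[orig == ref_pos] = ord(base)

    for sp in specs:
        if sp.kind == "SNV":
            v = variant_by_label.get(sp.label)
            if v is None:
                raise ValueError(f"unknown variant label {sp.label}")
            if v.alt_allele == DELETION_ALLELE or len(v.ref_allele) > 1:
                deletions.append((v.gene_pos, v.gene_pos + len(v.ref_allele)))
            elif len(v.alt_allele) > len(v.ref_allele):
                # duplication-style insertion: extra bases after the ref base
                insertions.append((v.gene_pos + 1, v.alt_allele[len(v.ref_allele) :]))
            else:
                set_base(v.gene_pos, v.alt_allele)
        elif sp.kind == "CONVERSION":
            for sid in range(sp.start_site, sp.end_site + 1):
                s = site_by_id.get(sid)
                if s is None:
                    continue
                if s.is_indel:
                    deletions.append((s.gene_pos, s.gene_pos + s.indel_length))
                else:
                    set_base(s.gene_pos, s.pseudo_base)
        elif sp.kind == "PSEUDO_CONVERSION":
            for sid in sp.sites:
                s = site_by_id[sid]
                if s.is_indel:
                    insertions.append((s.pseudo_pos, s.gene_base))
                else:
                    seq[orig == s.pseudo_pos] = ord(s.gene_base)

    if deletions:
        keep = np.ones(len(seq), dtype=bool)
        for d0, d1 in deletions:
            keep &= ~((orig >= d0) & (orig < d1))
        seq, orig = seq[keep], orig[keep]
    for ref_pos, ins in sorted(insertions, reverse=True):
        idx = np.nonzero(orig == ref_pos)[0]
        for i in idx[::-1]:
            seq = np.insert(seq, i, np.frombuffer(ins.encode(), np.uint8))
            orig = np.insert(orig, i, np.full(len(ins), -1, dtype=np.int64))
    return seq, orig


# ---------------------------------------------------------------------------
# read simulation and paralog-ambiguity placement
# ---------------------------------------------------------------------------


@dataclass
class _Read:
    name: str
    pos: int
    mapq: int
    cigar: list[tuple[int, int]]
    seq: str
    is_read1: bool
    mate_pos: int = 0


def _edlib_cigar(cig: str) -> list[tuple[int, int]]:
    """Convert an edlib cigar string to pysam tuples (=/X folded into M)."""
    out: list[tuple[int, int]] = []
    n = ""
    op_codes = {"M": 0, "I": 1, "D": 2, "=": 7, "X": 8}
    for ch in cig:
        if ch.isdigit():
            n += ch
        else:
            code = op_codes[ch]
            if code in (7, 8):
                code = 0
            if out and out[-1][0] == code:
                out[-1] = (code, out[-1][1] + int(n))
            else:
                out.append((code, int(n)))
            n = ""
    return out


class _Placer:
    """Places reads on the reference by the fewer-mismatch rule."""

    PAD = 60

    def __init__(self, ref: MiniReference):
        self.ref = ref
        self.ref_str = ref.sequence_str
        self.n = len(ref.sequence)
        g, p = ref.model.gene, ref.model.pseudogene
        self.gene_lo, self.gene_hi = g.start, g.end
        self.pseudo_lo, self.pseudo_hi = p.start, p.end

    def _near_paralog(self, lo: int, hi: int) -> bool:
        return (lo < self.gene_hi + 150 and hi > self.gene_lo - 150) or (
            lo < self.pseudo_hi + 150 and hi > self.pseudo_lo - 150
        )

    def _candidates(self, r0: int) -> tuple[int | None, int | None]:
        """Gene-frame and pseudo-frame start coordinates for a read whose
        first base derives from reference position r0."""
        ref = self.ref
        if r0 >= self.pseudo_lo - 200:
            ps = r0 if r0 >= self.pseudo_lo - 200 else None
            rel = r0 - ref.pseudo_offset
            gs = ref.gene_offset + rel + (INDEL_LEN if rel >= ref.indel_rel else 0)
        else:
            gs = r0
            rel = r0 - ref.gene_offset
            i0, _ = ref.indel_abs
            if rel >= ref.indel_rel + INDEL_LEN:
                rel -= INDEL_LEN
            elif r0 >= i0:
                rel = ref.indel_rel  # inside the insertion: anchor at its locus
            ps = ref.pseudo_offset + rel
        gs = gs if 0 <= gs < self.n else None
        ps = ps if self.pseudo_lo - 200 <= (ps or -1) < self.n else None
        return gs, ps

    def _window(self, start: int, length: int) -> tuple[int, str]:
        lo = max(0, start - self.PAD)
        hi = min(self.n, start + length + self.PAD)
        return lo, self.ref_str[lo:hi]

    def place(self, read_seq: str, origs: np.ndarray) -> tuple[int, int, list]:
        """Return (pos, mapq, cigar) for one read."""
        L = len(read_seq)
        valid = origs[origs >= 0]
        r0 = int(valid[0]) if len(valid) else 0
        r1 = int(valid[-1]) if len(valid) else r0
        contiguous = len(valid) == L and (r1 - r0) == L - 1

        if contiguous and not self._near_paralog(r0, r0 + L):
            return r0, 60, [(0, L)]

        gs, ps = self._candidates(r0)
        results = []
        for cand in (gs, ps):
            if cand is None:
                results.append(None)
                continue
            lo, window = self._window(cand, L)
            aln = edlib.align(read_seq, window, mode="HW", task="distance")
            results.append((aln["editDistance"], lo))
        dg = results[0][0] if results[0] else None
        dp = results[1][0] if results[1] else None

        if dg is not None and (dp is None or dg < dp):
            choice, mapq = 0, 60
        elif dp is not None and (dg is None or dp < dg):
            choice, mapq = 1, 60
        else:
            choice, mapq = 0, 0  # tie -> gene frame, MAPQ 0
        lo, window = self._window((gs, ps)[choice], L)
        aln = edlib.align(read_seq, window, mode="HW", task="path")
        start = lo + aln["locations"][0][0]
        cigar = _edlib_cigar(aln["cigar"])
        return start, mapq, cigar


def simulate_sample(
    ref: MiniReference,
    alleles: tuple[list[AlleleSpec], list[AlleleSpec]],
    cfg: SimulationConfig,
    out_prefix: str | Path,
) -> tuple[Path, dict]:
    """Simulate a diploid sample; write sorted+indexed BAM and truth JSON.

    Returns (bam_path, truth record).  The truth record carries the true
    unique-region copy number, CNV class, structural breakpoints
    (gene-frame) and the expected variant calls.
    """
    rng = np.random.default_rng(cfg.seed)
    out_prefix = Path(out_prefix)
    haps = [build_haplotype(ref, specs) for specs in alleles]

    reads: list[_Read] = []
    read_len = cfg.read_len
    placer = _Placer(ref)
    for h_idx, (hseq, horig) in enumerate(haps):
        L = len(hseq)
        n_frag = int(round(L * cfg.depth / 2.0 / (2 * read_len)))
        flen = np.clip(
            rng.normal(cfg.insert_mean, cfg.insert_sd, n_frag).astype(int),
            read_len,
            L - 1,
        )
        starts = rng.integers(0, L - flen + 1)
        if cfg.gc_bias_slope != 0.0:
            is_gc = (hseq == ord("G")) | (hseq == ord("C"))
            cum = np.concatenate([[0], np.cumsum(is_gc)])
            gc = (cum[starts + flen] - cum[starts]) / flen
            w = np.clip(1.0 + cfg.gc_bias_slope * (gc - 0.5) / 0.1, 0.02, None)
            keep = rng.random(n_frag) < w / w.max()
            starts, flen = starts[keep], flen[keep]

        for f_idx, (s, fl) in enumerate(zip(starts, flen)):
            name = f"frag_{h_idx}_{f_idx}"
            spans = [(int(s), int(s) + read_len, True)]
            if fl > read_len:
                spans.append((int(s + fl) - read_len, int(s + fl), False))
            placed = []
            for a, b, is_r1 in spans:
                b = min(b, L)
                rseq = hseq[a:b].copy()
                nerr = rng.binomial(b - a, cfg.error_rate)
                if nerr:
                    idx = rng.integers(0, b - a, nerr)
                    for i in idx:
                        rseq[i] = _other_base(rng, int(rseq[i]))
                pos, mapq, cigar = placer.place(_seq_to_str(rseq), horig[a:b])
                placed.append(_Read(name, pos, mapq, cigar, _seq_to_str(rseq), is_r1))
            if len(placed) == 2:
                placed[0].mate_pos = placed[1].pos
                placed[1].mate_pos = placed[0].pos
            reads.extend(placed)

    bam_path = out_prefix.with_suffix(".bam")
    _write_bam(bam_path, reads, len(ref.sequence))

    truth = _truth_record(ref, alleles, haps)
    truth_path = out_prefix.with_suffix(".truth.json")
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return bam_path, truth


def _write_bam(path: Path, reads: list[_Read], ref_len: int) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CONTIG, "LN": ref_len}],
    }
    reads = sorted(reads, key=lambda r: r.pos)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigartuples = r.cigar
            a.flag = (0x1 | 0x2 | 0x40 | 0x20) if r.is_read1 else (0x1 | 0x2 | 0x80 | 0x10)
            a.next_reference_id = 0
            a.next_reference_start = r.mate_pos
            a.template_length = 0
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            bam.write(a)
    pysam.index(str(path))


def _truth_record(
    ref: MiniReference,
    alleles: tuple[list[AlleleSpec], list[AlleleSpec]],
    haps,
) -> dict:
    model = ref.model
    u = model.unique_cn_region
    cn_unique = 0
    for _, orig in haps:
        inside = ((orig >= u.start) & (orig < u.end)).sum()
        cn_unique += int(round(inside / len(u)))
    cnv_class = "CNL" if cn_unique <= 1 else ("CNG" if cn_unique >= 3 else "NONE")

    breakpoints = []
    variants = []
    pathogenic_cnl = None
    site_by_id = {s.site_id: s for s in model.sites}
    for specs in alleles:
        for sp in specs:
            if sp.kind in ("CNL", "CNG"):
                breakpoints.append(int(sp.breakpoint_pos))
                if sp.kind == "CNL":
                    pathogenic_cnl = model.coding_region.contains(
                        int(sp.breakpoint_pos)
                    )
                    # a fusion allele carries the pseudogene base at every
                    # phasing site 3' of the breakpoint
                    sids = frozenset(
                        s.site_id
                        for s in model.phasing_sites
                        if s.gene_pos > int(sp.breakpoint_pos)
                    )
                    if sids:
                        label = None
                        for rec in model.recombinants:
                            if rec.required_pseudo_sites == sids:
                                label = rec.label
                        variants.append(
                            {
                                "label": label
                                or "+".join(str(s) for s in sorted(sids)),
                                "mechanism": "CNL",
                            }
                        )
            elif sp.kind == "SNV":
                variants.append({"label": sp.label, "mechanism": "SNV"})
            elif sp.kind == "CONVERSION":
                sids = frozenset(
                    sid
                    for sid in range(sp.start_site, sp.end_site + 1)
                    if sid in site_by_id
                )
                label = None
                for rec in model.recombinants:
                    if rec.required_pseudo_sites == sids:
                        label = rec.label
                variants.append(
                    {
                        "label": label or "+".join(str(s) for s in sorted(sids)),
                        "mechanism": "CONVERSION",
                    }
                )
    return {
        "cn_unique": cn_unique,
        "cn_total": cn_unique + 2,
        "cnv_class": cnv_class,
        "breakpoints": breakpoints,
        "pathogenic_cnl": pathogenic_cnl,
        "variants": variants,
    }


# ---------------------------------------------------------------------------
# canonical sample classes (ground truth for end-to-end recovery suites)
# ---------------------------------------------------------------------------

SAMPLE_CLASSES = (
    "WT",
    "L483P_het",
    "RecNciI_conversion",
    "RecNciI_CNL",
    "CNL_nonpathogenic",
    "CNG",
    "CNG_L483P",
    "c1263del_RecTL_conversion",
    "compound_het",
)


def class_allele_specs(
    ref: MiniReference, class_name: str, rng: np.random.Generator
) -> tuple[list[AlleleSpec], list[AlleleSpec]]:
    """Allele specs (two parental chromosomes) for a named sample class.

    Breakpoints are drawn uniformly within the genomic stretch that realizes
    the class (e.g. a RecNciI fusion needs its breakpoint between the
    p.D448H and p.L483P sites); ``CNG`` draws 1-6 extra copies.
    """
    model = ref.model
    ps = [s.site_id for s in model.phasing_sites]
    site = {s.site_id: s for s in model.sites}
    wt: list[AlleleSpec] = []

    def rint(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi))

    if class_name == "WT":
        return wt, []
    if class_name == "L483P_het":
        return [AlleleSpec("SNV", label="p.L483P")], wt
    if class_name == "RecNciI_conversion":
        return [AlleleSpec("CONVERSION", start_site=ps[7], end_site=ps[9])], wt
    if class_name == "RecNciI_CNL":
        bp = rint(site[ps[6]].gene_pos + 2, site[ps[7]].gene_pos - 1)
        return [AlleleSpec("CNL", breakpoint_pos=bp)], wt
    if class_name == "CNL_nonpathogenic":
        lo = model.coding_region.end + 20
        hi = max(s.gene_pos for s in model.sites) - 20
        return [AlleleSpec("CNL", breakpoint_pos=rint(lo, hi))], wt
    if class_name in ("CNG", "CNG_L483P"):
        lo = ref.homology_block.start + 30
        hi = model.homology_region.start - 30
        extra = rint(1, 7)
        cng = [AlleleSpec("CNG", breakpoint_pos=rint(lo, hi), extra_copies=extra)]
        other = [AlleleSpec("SNV", label="p.L483P")] if class_name == "CNG_L483P" else wt
        return cng, other
    if class_name == "c1263del_RecTL_conversion":
        return [AlleleSpec("CONVERSION", start_site=ps[5], end_site=ps[9])], wt
    if class_name == "compound_het":
        return (
            [AlleleSpec("SNV", label="p.L483P")],
            [AlleleSpec("SNV", label="p.D448H")],
        )
    if class_name == "decoy_reverse_L483P":
        return [AlleleSpec("PSEUDO_CONVERSION", sites=(ps[7],))], wt
    if class_name == "decoy_reverse_c1263del":
        return [AlleleSpec("PSEUDO_CONVERSION", sites=(ps[5],))], wt
    raise ValueError(f"unknown sample class {class_name}")


# ---------------------------------------------------------------------------
# amplicon run-depth simulation
# ---------------------------------------------------------------------------


def simulate_run_depths(
    n_samples: int,
    anomaly_spec: dict[tuple[int, int], float],
    seed: int,
    n_positions: int = 11,
    base_depth: tuple[float, float] = (400.0, 700.0),
    noise_sd: float = 0.03,
):
    """Simulate per-sample homopolymer depths for one sequencing run.

    ``anomaly_spec`` maps (sample_index, position_index) to a multiplicative
    depth factor (0.5 emulates a single-base deletion collapsing reads, 1.5
    an SNV splitting the homopolymer).  Returns (RunDepthMatrix, truth) where
    truth maps the anomalous cells to "DELETION"/"SNV"/"NONE".
    """
    from paralocus.amplicon_tools import RunDepthMatrix

    if n_samples < 3:
        raise ValueError("need at least 3 samples per run for MAD statistics")
    rng = np.random.default_rng(seed)
    base = rng.uniform(*base_depth, size=n_samples)
    flank = base[:, None] * (1 + rng.normal(0, noise_sd / 3, (n_samples, n_positions)))
    depth = flank * (1 + rng.normal(0, noise_sd, (n_samples, n_positions)))
    truth = {}
    for (s, p), factor in anomaly_spec.items():
        depth[s, p] *= factor
        truth[(s, p)] = "NONE" if factor == 1.0 else ("DELETION" if factor < 1 else "SNV")
    m = RunDepthMatrix(
        sample_ids=[f"S{i + 1}" for i in range(n_samples)],
        positions=list(range(n_positions)),
        depth=depth,
        flank_depth=flank,
    )
    return m, truth
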