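"""Total gene+pseudogene copy number from depth in the unique region.

The only uniquely mappable ground truth at a paralog locus is the spacer
between the two copies: reciprocal recombination deletes it (CNL) or
duplicates it (CNG) together with the intervening unit.  Depth there,
normalized against baseline windows and corrected for GC content, is
therefore a direct readout of the number of spacer copies; adding the two
copies that every chromosome pair contributes on each side gives the
combined gene+pseudogene copy number used by all site-level calling.

The integer copy number is called from a Gaussian mixture with components
centered at 0..max_cn and SD growing with the square root of the copy
number (depth noise is roughly Poisson), flat prior, MAP rule, with a
posterior threshold guarding against half-integer depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from paralocus.region_model import GenomicInterval, ParalogModel

__all__ = [
    "DepthBin",
    "DepthProfile",
    "NormalizedDepth",
    "CopyNumberCall",
    "extract_depth",
    "gc_correct",
    "normalize",
    "call_total_cn",
    "fit_sigma0",
    "cnv_class_of",
]

_GC_STRATUM_WIDTH = 0.02


class DegenerateInputError(ValueError):
    """Alignments provide no usable depth signal."""


@dataclass(frozen=True)
class DepthBin:
    interval: GenomicInterval
    raw_depth: float  # mean reads per bp
    gc_fraction: float

    def __post_init__(self) -> None:
        if self.raw_depth < 0:
            raise ValueError("raw_depth must be >= 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction outside [0, 1]")


@dataclass
class DepthProfile:
    bins: list[DepthBin]  # unique-region bins
    baseline_bins: list[DepthBin]
    gc_corrected: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_bedgraph(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for b in sorted(
                self.bins + self.baseline_bins, key=lambda b: b.interval.start
            ):
                iv = b.interval
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{b.raw_depth:.4f}\n")
        return path


@dataclass(frozen=True)
class NormalizedDepth:
    d: float  # copy-number scaled; diploid expectation 2.0
    n_bins_used: int

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("normalized depth must be >= 0")


@dataclass(frozen=True)
class CopyNumberCall:
    cn_unique: int
    cn_total: int
    posterior: float
    cnv_class: str  # CNL | NONE | CNG
    no_call: bool

    def __post_init__(self) -> None:
        if self.cn_total != self.cn_unique + 2:
            raise ValueError("cn_total must equal cn_unique + 2")
        if self.cnv_class != cnv_class_of(self.cn_unique):
            raise ValueError("cnv_class inconsistent with cn_unique")


def cnv_class_of(cn_unique: int) -> str:
    if cn_unique <= 1:
        return "CNL"
    return "NONE" if cn_unique == 2 else "CNG"


def _read_ok(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_duplicate
        or read.is_secondary
        or read.is_supplementary
        or read.is_unmapped
    )


def _mean_depth(bam: pysam.AlignmentFile, iv: GenomicInterval) -> float:
    cov = bam.count_coverage(
        iv.contig, iv.start, iv.end, quality_threshold=0, read_callback=_read_ok
    )
    return float(np.asarray(cov).sum(axis=0).mean())


def _gc_fraction(fasta: pysam.FastaFile, iv: GenomicInterval) -> float:
    seq = fasta.fetch(iv.contig, iv.start, iv.end).upper()
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def default_baseline_windows(
    model: ParalogModel, contig_length: int, margin: int = 200
) -> list[GenomicInterval]:
    """Everything on the contig outside gene/pseudogene/unique regions."""
    contig = model.gene.contig
    blocked = sorted(
        (model.gene, model.pseudogene, model.unique_cn_region),
        key=lambda iv: iv.start,
    )
    windows = []
    cursor = 0
    for iv in blocked:
        if iv.start - margin > cursor:
            windows.append(GenomicInterval(contig, cursor, iv.start - margin))
        cursor = max(cursor, iv.end + margin)
    if contig_length > cursor:
        windows.append(GenomicInterval(contig, cursor, contig_length))
    return windows


def extract_depth(
    alignments: str | Path | pysam.AlignmentFile,
    model: ParalogModel,
    fasta: str | Path | pysam.FastaFile,
    bin_size: int = 500,
    baseline_windows: list[GenomicInterval] | None = None,
) -> DepthProfile:
    """Mean depth and GC per bin over the unique region and baseline windows.

    Duplicate, secondary, supplementary and unmapped reads are excluded; no
    MAPQ filter is applied (the unique region is uniquely mappable by
    construction).  Raises DegenerateInputError when the baseline carries no
    coverage at all (e.g. an empty BAM).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    own_bam = not isinstance(alignments, pysam.AlignmentFile)
    bam = pysam.AlignmentFile(str(alignments)) if own_bam else alignments
    own_fa = not isinstance(fasta, pysam.FastaFile)
    fa = pysam.FastaFile(str(fasta)) if own_fa else fasta
    try:
        contig_length = fa.get_reference_length(model.gene.contig)
        if baseline_windows is None:
            baseline_windows = default_baseline_windows(model, contig_length)

        def bins_of(iv: GenomicInterval) -> list[DepthBin]:
            out = []
            for s in range(iv.start, iv.end, bin_size):
                e = min(s + bin_size, iv.end)
                if e - s < bin_size // 2:
                    continue  # avoid noisy stub bins
                sub = GenomicInterval(iv.contig, s, e)
                out.append(DepthBin(sub, _mean_depth(bam, sub), _gc_fraction(fa, sub)))
            return out

        unique_bins = bins_of(model.unique_cn_region)
        baseline_bins = [b for w in baseline_windows for b in bins_of(w)]
    finally:
        if own_bam:
            bam.close()
        if own_fa:
            fa.close()

    if not baseline_bins or all(b.raw_depth == 0 for b in baseline_bins):
        raise DegenerateInputError("no baseline coverage in alignments")
    return DepthProfile(bins=unique_bins, baseline_bins=baseline_bins)


def _stratum(gc: float) -> int:
    return min(int(gc / _GC_STRATUM_WIDTH), int(1.0 / _GC_STRATUM_WIDTH) - 1)


def gc_correct(profile: DepthProfile, min_baseline_bins: int = 20) -> DepthProfile:
    """Divide each bin by the median baseline depth of its 2%-wide GC stratum.

    Empty strata borrow the nearest populated stratum; afterwards all depths
    are rescaled so the baseline median is unchanged.  If the baseline spans
    fewer than 3 strata (or has too few bins to stratify), correction is
    skipped and a warning flag recorded.
    """
    base = profile.baseline_bins
    strata: dict[int, list[float]] = {}
    for b in base:
        strata.setdefault(_stratum(b.gc_fraction), []).append(b.raw_depth)
    if len(base) < min_baseline_bins or len(strata) < 3:
        out = replace(profile)
        out.warnings = profile.warnings + ["gc_correction_skipped"]
        return out

    med = {k: float(np.median(v)) for k, v in strata.items()}
    populated = sorted(k for k in med if med[k] > 0)
    if len(populated) < 3:
        out = replace(profile)
        out.warnings = profile.warnings + ["gc_correction_skipped"]
        return out

    def factor(gc: float) -> float:
        k = _stratum(gc)
        kk = min(populated, key=lambda p: (abs(p - k), p))
        return med[kk]

    def corrected(bins: list[DepthBin]) -> list[DepthBin]:
        return [
            DepthBin(b.interval, b.raw_depth / factor(b.gc_fraction), b.gc_fraction)
            for b in bins
        ]

    new_base = corrected(base)
    old_med = float(np.median([b.raw_depth for b in base]))
    new_med = float(np.median([b.raw_depth for b in new_base]))
    scale = old_med / new_med if new_med > 0 else 1.0

    def rescale(bins: list[DepthBin]) -> list[DepthBin]:
        return [
            DepthBin(b.interval, b.raw_depth * scale, b.gc_fraction) for b in bins
        ]

    return DepthProfile(
        bins=rescale(corrected(profile.bins)),
        baseline_bins=rescale(new_base),
        gc_corrected=True,
        warnings=list(profile.warnings),
    )


def _trimmed_mean(values: list[float], trim: float = 0.05) -> float:
    arr = np.sort(np.asarray(values, dtype=float))
    k = int(len(arr) * trim)
    arr = arr[k : len(arr) - k] if k > 0 else arr
    return float(arr.mean())


def normalize(profile: DepthProfile) -> NormalizedDepth:
    """d = 2 x trimmed-mean unique depth / trimmed-mean baseline depth."""
    if not profile.bins or not profile.baseline_bins:
        raise ValueError("profile has empty bin lists")
    base = _trimmed_mean([b.raw_depth for b in profile.baseline_bins])
    if base <= 0:
        raise DegenerateInputError("baseline trimmed mean is zero")
    uniq = _trimmed_mean([b.raw_depth for b in profile.bins])
    return NormalizedDepth(d=2.0 * uniq / base, n_bins_used=len(profile.bins))


def mixture_posteriors(d: float, max_cn: int, sigma0: float) -> np.ndarray:
    """Posterior over components 0..max_cn for one normalized depth value."""
    k = np.arange(max_cn + 1)
    sd = sigma0 * np.sqrt(np.maximum(k, 1))
    log_dens = -0.5 * ((d - k) / sd) ** 2 - np.log(sd)
    log_dens -= log_dens.max()
    dens = np.exp(log_dens)
    return dens / dens.sum()


def call_total_cn(
    nd: NormalizedDepth,
    max_cn: int = 10,
    posterior_threshold: float = 0.95,
    sigma0: float = 0.12,
) -> CopyNumberCall:
    """MAP integer copy number of the unique region (and cn_total = +2)."""
    if max_cn < 8:
        raise ValueError("max_cn must be >= 8")
    if not np.isfinite(nd.d):
        raise ValueError("normalized depth must be finite")
    post = mixture_posteriors(nd.d, max_cn, sigma0)
    cn = int(np.argmax(post))
    p = float(post[cn])
    return CopyNumberCall(
        cn_unique=cn,
        cn_total=cn + 2,
        posterior=p,
        cnv_class=cnv_class_of(cn),
        no_call=p < posterior_threshold,
    )


def fit_sigma0(ds: list[float], max_cn: int = 10) -> float:
    """Batch re-estimation of sigma0 from many samples' normalized depths.

    Assigns each depth to its nearest integer component and returns the MLE
    of the shared scale under the sqrt-CN variance model.
    """
    ds = np.asarray(ds, dtype=float)
    if len(ds) < 2:
        raise ValueError("need at least 2 samples")
    k = np.clip(np.round(ds), 0, max_cn)
    resid = (ds - k) / np.sqrt(np.maximum(k, 1))
    return float(np.sqrt(np.mean(resid**2)))
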