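"""End-to-end per-sample calling: BAM + region model -> SampleReport."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import pysam

from paralocus.region_model import ParalogModel
from paralocus import coverage_cn as _cov
from paralocus import site_cn as _site
from paralocus import recombinant_phaser as _ph
from paralocus import targeted_variant_caller as _tv

__all__ = ["call_sample"]


def call_sample(
    alignments: str | Path,
    model: ParalogModel,
    fasta: str | Path,
    sample_id: str = "sample",
    bin_size: int = 500,
    sigma0: float = 0.12,
    posterior_threshold: float = 0.95,
    min_hap_support: int = _ph.MIN_HAP_SUPPORT,
) -> _ph.SampleReport:
    """Run the full short-read caller on one sample.

    Stages: normalized-depth copy number in the unique region; per-site
    gene CN and CN-transition breakpoints; haplotype phasing and
    recombinant classification over the homology region; targeted variants
    outside it.  A copy-number no_call falls back to the diploid baseline
    with a warning, so downstream stages still run.
    """
    warnings: list[str] = []
    with pysam.AlignmentFile(str(alignments)) as bam:
        profile = _cov.extract_depth(bam, model, fasta, bin_size=bin_size)
        profile = _cov.gc_correct(profile)
        warnings.extend(profile.warnings)
        nd = _cov.normalize(profile)
        cn_call = _cov.call_total_cn(
            nd, posterior_threshold=posterior_threshold, sigma0=sigma0
        )
        if cn_call.no_call:
            warnings.append(
                f"copy-number posterior {cn_call.posterior:.3f} below "
                f"threshold at d={nd.d:.3f}; downstream calls use the MAP "
                "copy number"
            )
        cn_total = cn_call.cn_total

        counts = _site.count_site_bases(bam, model)
        series = _site.build_site_cn_series(counts, cn_total)
        breakpoints = _site.detect_cn_transitions(series, model)
        breakpoints = [
            replace(bp, pathogenic=_site.classify_cnl_pathogenicity(bp, model))
            if bp.kind == "CNL"
            else bp
            for bp in breakpoints
        ]

        fragments = _ph.extract_fragments(bam, model)
        haps = _ph.assemble_haplotypes(
            fragments, model, cn_total, min_hap_support, warnings=warnings
        )
        if haps:
            haps = _ph.call_haplotype_cn(haps, fragments, cn_total, model)
            scenario = _ph.compare_scenarios(haps, model)
        else:
            scenario = None
            warnings.append("no haplotypes assembled in the phasing region")
        report = _ph.classify_recombinant(
            scenario, haps, breakpoints, cn_call, model, sample_id=sample_id
        )
        report.targeted_variant_calls = [
            t for t in _tv.call_known_variants(bam, model) if t[1] not in ("ABSENT",)
        ]
    report.warnings = warnings + report.warnings
    return report
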