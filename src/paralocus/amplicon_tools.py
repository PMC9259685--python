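"""Long-read amplicon downstream procedures.

Four small, self-contained analyses applied to long-read amplicon data
after external basecalling/alignment/variant calling:

* primer-pair presence/absence -> coarse allele class (an amplicon that
  only forms across the fusion junction proves a CNL, one across the
  duplication junction a CNG);
* sentinel differentiating sites along a fusion amplicon -> breakpoint
  bracketing (the recombination breakpoint lies 3' of the last gene-base
  sentinel and 5' of the first pseudogene-base sentinel);
* flank-adjusted depth anomalies at homopolymer runs, judged against the
  other samples of the same sequencing run with a median/MAD rule
  (variant callers are unreliable inside homopolymers, but a deletion
  collapses depth and an SNV splits it);
* genotype-quality filtering of small-variant calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AmpliconEvidence",
    "SentinelCalls",
    "BreakpointInterval",
    "RunDepthMatrix",
    "HomopolymerFlag",
    "classify_allele_from_primers",
    "locate_cnl_breakpoint",
    "detect_homopolymer_variants",
    "filter_variants_by_gq",
]

MAD_SCALE = 1.4826  # normal-consistency constant
DEFAULT_TAU_MAD = 5.0
FALLBACK_REL_THRESHOLD = 0.20
DEFAULT_GQ_THRESHOLD = 650.0


class InconsistentEvidenceError(ValueError):
    """Primer amplification pattern that no allele configuration produces."""


class NoBreakpointError(ValueError):
    """Sentinel calls contain no gene->pseudogene transition."""


@dataclass(frozen=True)
class AmpliconEvidence:
    sample_id: str
    amplified: tuple[bool, bool, bool]  # primer pairs 1 (gene), 2 (CNL), 3 (CNG)

    def __post_init__(self) -> None:
        if not any(self.amplified):
            raise ValueError("at least one primer pair must amplify")


def classify_allele_from_primers(ev: AmpliconEvidence) -> str:
    """WT_or_conversion | CNL | CNG | MIXED from primer-pair presence.

    Pair 1 spans the intact gene, pair 2 the CNL fusion junction, pair 3
    the CNG hybrid junction.  A pair-3 product without a pair-1 product is
    impossible (every CNG retains an intact gene copy) and raises.
    """
    p1, p2, p3 = ev.amplified
    if p3 and not p1:
        raise InconsistentEvidenceError(
            "pair 3 (CNG junction) without pair 1 (intact gene)"
        )
    if p2 and not p1:
        return "CNL"
    if p1 and p3:
        return "CNG"
    if p1 and p2:
        return "MIXED"
    return "WT_or_conversion"


@dataclass(frozen=True)
class SentinelCalls:
    """Sentinel-site statuses along the fusion amplicon, 5'->3' in gene order."""

    calls: tuple[tuple[int, str], ...]  # (site_id, GENE|PSEUDO|NOCALL)

    def __post_init__(self) -> None:
        sids = [s for s, _ in self.calls]
        if sorted(sids) != sids or len(set(sids)) != len(sids):
            raise ValueError("sentinel calls must be unique and site-ordered")
        for _, st in self.calls:
            if st not in ("GENE", "PSEUDO", "NOCALL"):
                raise ValueError(f"bad status {st}")


@dataclass(frozen=True)
class BreakpointInterval:
    site_id_left: int  # last GENE sentinel
    site_id_right: int  # first PSEUDO sentinel
    non_canonical: bool = False
    transitions: tuple[tuple[int, int], ...] = ()


def locate_cnl_breakpoint(calls: SentinelCalls) -> BreakpointInterval:
    """Open interval bracketing the fusion breakpoint from sentinel calls.

    NOCALL sites are skipped.  The breakpoint lies 3' of the last sentinel
    showing the gene base and 5' of the first showing the pseudogene base;
    if the PSEUDO calls do not form one contiguous 3' suffix, every
    GENE->PSEUDO transition is reported and the interval flagged
    NON_CANONICAL (first transition returned as the nominal interval).
    """
    informative = [(s, st) for s, st in calls.calls if st != "NOCALL"]
    statuses = {st for _, st in informative}
    if statuses in ({"GENE"}, {"PSEUDO"}, set()):
        raise NoBreakpointError(
            "sentinels are uniformly "
            + (next(iter(statuses)) if statuses else "NOCALL")
            + "; no gene->pseudogene transition "
            + "(uniform PSEUDO suggests the wrong amplicon)"
        )
    transitions = [
        (informative[i][0], informative[i + 1][0])
        for i in range(len(informative) - 1)
        if informative[i][1] == "GENE" and informative[i + 1][1] == "PSEUDO"
    ]
    if not transitions:
        raise NoBreakpointError("no GENE followed by PSEUDO in sentinel calls")
    first_pseudo = next(i for i, (_, st) in enumerate(informative) if st == "PSEUDO")
    canonical = all(st == "PSEUDO" for _, st in informative[first_pseudo:]) and all(
        st == "GENE" for _, st in informative[:first_pseudo]
    )
    left, right = transitions[0]
    return BreakpointInterval(
        site_id_left=left,
        site_id_right=right,
        non_canonical=not canonical,
        transitions=tuple(transitions),
    )


@dataclass
class RunDepthMatrix:
    """Per-sample depth at homopolymer loci within one sequencing run."""

    sample_ids: list[str]
    positions: list[int]
    depth: np.ndarray  # samples x positions
    flank_depth: np.ndarray  # mean depth over the 100 flanking positions
    flank_width: int = 100

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.flank_depth = np.asarray(self.flank_depth, dtype=float)
        s, p = len(self.sample_ids), len(self.positions)
        if self.depth.shape != (s, p) or self.flank_depth.shape != (s, p):
            raise ValueError("matrix shapes must be (samples, positions)")
        if s < 3:
            raise ValueError("need >= 3 samples per run for MAD statistics")
        if np.any(self.flank_depth <= 0):
            raise ValueError("flanking depth must be positive")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(f"pos_{p}" for p in self.positions))
            fh.write("\t" + "\t".join(f"flank_{p}" for p in self.positions) + "\n")
            for i, sid in enumerate(self.sample_ids):
                row = [sid]
                row += [f"{v:.4f}" for v in self.depth[i]]
                row += [f"{v:.4f}" for v in self.flank_depth[i]]
                fh.write("\t".join(row) + "\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RunDepthMatrix":
        lines = Path(path).read_text().strip().split("\n")
        header = lines[0].split("\t")[1:]
        n_pos = sum(1 for h in header if h.startswith("pos_"))
        positions = [int(h[4:]) for h in header[:n_pos]]
        sample_ids, depth, flank = [], [], []
        for line in lines[1:]:
            parts = line.split("\t")
            sample_ids.append(parts[0])
            vals = [float(x) for x in parts[1:]]
            depth.append(vals[:n_pos])
            flank.append(vals[n_pos:])
        return cls(sample_ids, positions, np.array(depth), np.array(flank))


@dataclass(frozen=True)
class HomopolymerFlag:
    sample_id: str
    position: int
    flag: str  # DELETION | SNV | NONE
    z: float
    fallback_used: bool = False


def detect_homopolymer_variants(
    m: RunDepthMatrix, tau_mad: float = DEFAULT_TAU_MAD
) -> list[HomopolymerFlag]:
    """Flank-adjusted depth anomalies vs the other samples of the run.

    a(s,p) = depth(s,p) / flank_depth(s,p); for each cell, z is the
    deviation from the median of the OTHER samples at that position in
    units of their MAD (scaled by 1.4826).  |z| > tau_mad flags DELETION
    (below the median) or SNV (above).  When the MAD is zero the rule
    falls back to a 20% relative-deviation threshold.
    """
    a = m.depth / m.flank_depth
    out = []
    n = len(m.sample_ids)
    for p_idx, pos in enumerate(m.positions):
        col = a[:, p_idx]
        for s_idx, sid in enumerate(m.sample_ids):
            others = np.delete(col, s_idx)
            med = float(np.median(others))
            mad = float(np.median(np.abs(others - med))) * MAD_SCALE
            fallback = mad == 0.0
            if fallback:
                rel = (col[s_idx] - med) / med if med else 0.0
                z = np.inf * np.sign(rel) if abs(rel) > FALLBACK_REL_THRESHOLD else 0.0
                anomalous = abs(rel) > FALLBACK_REL_THRESHOLD
            else:
                z = (col[s_idx] - med) / mad
                anomalous = abs(z) > tau_mad
            if anomalous:
                flag = "DELETION" if col[s_idx] < med else "SNV"
            else:
                flag = "NONE"
            out.append(HomopolymerFlag(sid, pos, flag, float(z), fallback))
    return out


def filter_variants_by_gq(
    calls: list[dict],
    threshold: float = DEFAULT_GQ_THRESHOLD,
    gq_key: str = "GQ",
) -> tuple[list[dict], dict]:
    """Keep records whose genotype-quality score is >= threshold.

    ``calls`` are mapping-like records (e.g. parsed VCF rows).  Records
    missing the score pass through with a warning counted in the log.
    Returns (kept records, log dict with kept/removed/missing counts).
    """
    kept, removed, missing = [], 0, 0
    for rec in calls:
        gq = rec.get(gq_key)
        if gq is None:
            missing += 1
            kept.append(rec)
        elif float(gq) >= threshold:
            kept.append(rec)
        else:
            removed += 1
    log = {"kept": len(kept), "removed": removed, "missing_score": missing}
    return kept, log
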