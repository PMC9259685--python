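"""Coordinate model of a gene/pseudogene paralog pair.

A :class:`ParalogModel` describes everything the caller needs to know about
the locus: the gene and pseudogene intervals, the unique copy-number-calling
region between them, the homology region whose differentiating sites are
phased, the gene coding interval (used to classify fusion breakpoints as
pathogenic or not), the ordered list of paralog-differentiating sites, the
known target variants and the named recombinant haplotypes.

Internally every coordinate is 0-based half-open.  Model files (JSON) use
1-based inclusive point positions, the VCF convention, and are converted on
load; interval ``end`` values are identical in both conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


class ModelError(ValueError):
    """A region-model file is malformed or violates a model invariant."""


class NoMappingError(LookupError):
    """A gene position has no homologous pseudogene position (or vice versa)."""


DELETION_ALLELE = "-"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ModelError("interval contig must be non-empty")
        if not self.start < self.end:
            raise ModelError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class DifferentiatingSite:
    """A position where gene and pseudogene sequences differ.

    ``gene_base``/``pseudo_base`` are single bases for substitution-type
    sites.  An indel-type site (the c.1263del55 analogue) is represented as a
    single site whose gene allele is the inserted sequence and whose
    pseudogene allele is the deletion marker ``"-"``.
    """

    site_id: int
    gene_pos: int
    pseudo_pos: int
    gene_base: str
    pseudo_base: str
    in_phasing_set: bool = False
    is_sentinel: bool = False
    reliable: bool = True
    label: str | None = None

    def __post_init__(self) -> None:
        if self.gene_base == self.pseudo_base:
            raise ModelError(
                f"site {self.site_id}: gene and pseudogene alleles are identical"
            )

    @property
    def is_indel(self) -> bool:
        return self.pseudo_base == DELETION_ALLELE or len(self.gene_base) > 1

    @property
    def indel_length(self) -> int:
        """Length of the gene-only insertion (0 for substitution sites)."""
        return len(self.gene_base) if self.is_indel else 0


@dataclass
class TargetVariant:
    """A known (ClinVar-style) target variant on the gene."""

    label: str
    gene_pos: int
    ref_allele: str
    alt_allele: str
    gbap1_like: bool = False
    in_homology_region: bool = False
    severity: str = "unknown"  # severe | mild | risk | unknown

    _SEVERITIES = ("severe", "mild", "risk", "unknown")

    def __post_init__(self) -> None:
        if self.severity not in self._SEVERITIES:
            raise ModelError(
                f"variant {self.label}: severity {self.severity!r} not one of "
                f"{self._SEVERITIES}"
            )


@dataclass
class NamedRecombinant:
    """A named recombinant haplotype defined by its pseudogene-derived sites.

    RecNciI comprises the pseudogene alleles of p.L483P, p.A495P and
    p.Val499=; RecTL adds p.D448H; c.1263del+RecTL adds the 55 bp deletion.
    """

    label: str
    required_pseudo_sites: frozenset[int]

    def __post_init__(self) -> None:
        self.required_pseudo_sites = frozenset(self.required_pseudo_sites)
        if not self.required_pseudo_sites:
            raise ModelError(f"recombinant {self.label}: empty site set")


@dataclass
class ParalogModel:
    gene: GenomicInterval
    pseudogene: GenomicInterval
    unique_cn_region: GenomicInterval
    homology_region: GenomicInterval
    coding_region: GenomicInterval
    sites: list[DifferentiatingSite] = field(default_factory=list)
    variants: list[TargetVariant] = field(default_factory=list)
    recombinants: list[NamedRecombinant] = field(default_factory=list)
    homopolymers: list[GenomicInterval] = field(default_factory=list)
    diploid_cn_baseline: int = 4
    # free-form annotations carried through save/load unchanged (e.g. the
    # long-read amplicon span and primer coordinates of a bundled model)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ----------------------------------------------------

    @property
    def phasing_sites(self) -> list[DifferentiatingSite]:
        return [s for s in self.sites if s.in_phasing_set]

    @property
    def sentinel_sites(self) -> list[DifferentiatingSite]:
        return [s for s in self.sites if s.is_sentinel]

    def site_by_id(self, site_id: int) -> DifferentiatingSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"no site with id {site_id}")

    def recombinant_by_label(self, label: str) -> NamedRecombinant:
        for r in self.recombinants:
            if r.label == label:
                return r
        raise KeyError(f"no recombinant named {label}")

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        g, p, u = self.gene, self.pseudogene, self.unique_cn_region
        lo, hi = (g, p) if g.start <= p.start else (p, g)
        if not (lo.end <= u.start and u.end <= hi.start):
            raise ModelError(
                "unique_cn_region must lie strictly between the gene and "
                "pseudogene intervals and overlap neither"
            )
        if g.overlaps(p):
            raise ModelError("gene and pseudogene intervals overlap")

        last_pos = None
        last_id = None
        for s in self.sites:
            if last_id is not None and s.site_id <= last_id:
                raise ModelError(f"site ids not strictly increasing at {s.site_id}")
            if last_pos is not None and s.gene_pos <= last_pos:
                raise ModelError(
                    f"site gene positions not strictly increasing at site {s.site_id}"
                )
            last_pos, last_id = s.gene_pos, s.site_id
            if not g.contains(s.gene_pos):
                raise ModelError(f"site {s.site_id}: gene_pos outside gene interval")
            if not p.contains(s.pseudo_pos):
                raise ModelError(
                    f"site {s.site_id}: pseudo_pos outside pseudogene interval"
                )
            in_hom = self.homology_region.contains(s.gene_pos)
            if s.in_phasing_set and not in_hom:
                raise ModelError(
                    f"site {s.site_id}: phasing site outside homology_region"
                )
            if in_hom and not s.in_phasing_set:
                raise ModelError(
                    f"site {s.site_id}: non-phasing site inside homology_region"
                )

        by_pos = {s.gene_pos: s for s in self.sites}
        for v in self.variants:
            if v.gbap1_like:
                s = by_pos.get(v.gene_pos)
                if s is None or v.alt_allele != s.pseudo_base:
                    raise ModelError(
                        f"variant {v.label}: flagged GBAP1-like but its alt allele "
                        "does not match the pseudogene base of a differentiating "
                        "site at the same position"
                    )

        by_label = {r.label: r for r in self.recombinants}
        for sub, sup in (("RecNciI", "RecTL"), ("RecTL", "c.1263del+RecTL")):
            if sub in by_label and sup in by_label:
                if not by_label[sub].required_pseudo_sites <= by_label[
                    sup
                ].required_pseudo_sites:
                    raise ModelError(
                        f"recombinant {sup}: site set must be a superset of {sub}'s"
                    )


# -- serialization ---------------------------------------------------------

_INTERVAL_FIELDS = (
    "gene",
    "pseudogene",
    "unique_cn_region",
    "homology_region",
    "coding_region",
)


def _interval_to_json(iv: GenomicInterval) -> dict:
    # file convention: 1-based inclusive start, end unchanged
    return {"contig": iv.contig, "start": iv.start + 1, "end": iv.end}


def _interval_from_json(d: dict, where: str) -> GenomicInterval:
    try:
        return GenomicInterval(d["contig"], int(d["start"]) - 1, int(d["end"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelError(f"malformed interval in {where}: {exc}") from exc


def save_model(model: ParalogModel, path: str | Path) -> None:
    """Write a model as a canonical JSON document (1-based point positions)."""
    doc = {
        "format": "paralocus-region-model-v1",
        "diploid_cn_baseline": model.diploid_cn_baseline,
        "intervals": {
            name: _interval_to_json(getattr(model, name)) for name in _INTERVAL_FIELDS
        },
        "homopolymers": [_interval_to_json(iv) for iv in model.homopolymers],
        "sites": [
            {
                "site_id": s.site_id,
                "gene_pos": s.gene_pos + 1,
                "pseudo_pos": s.pseudo_pos + 1,
                "gene_base": s.gene_base,
                "pseudo_base": s.pseudo_base,
                "in_phasing_set": s.in_phasing_set,
                "is_sentinel": s.is_sentinel,
                "reliable": s.reliable,
                "label": s.label,
            }
            for s in model.sites
        ],
        "variants": [asdict(v) | {"gene_pos": v.gene_pos + 1} for v in model.variants],
        "recombinants": [
            {"label": r.label, "required_pseudo_sites": sorted(r.required_pseudo_sites)}
            for r in model.recombinants
        ],
    }
    if model.metadata:
        doc["metadata"] = model.metadata
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path) -> ParalogModel:
    """Load and validate a region-model JSON file.

    Raises :class:`ModelError` naming the offending field on malformed input
    or invariant violation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"{path}: not valid JSON at line {exc.lineno}") from exc

    try:
        intervals = {
            name: _interval_from_json(doc["intervals"][name], name)
            for name in _INTERVAL_FIELDS
        }
        sites = [
            DifferentiatingSite(
                site_id=int(s["site_id"]),
                gene_pos=int(s["gene_pos"]) - 1,
                pseudo_pos=int(s["pseudo_pos"]) - 1,
                gene_base=s["gene_base"],
                pseudo_base=s["pseudo_base"],
                in_phasing_set=bool(s.get("in_phasing_set", False)),
                is_sentinel=bool(s.get("is_sentinel", False)),
                reliable=bool(s.get("reliable", True)),
                label=s.get("label"),
            )
            for s in doc.get("sites", [])
        ]
        variants = [
            TargetVariant(
                label=v["label"],
                gene_pos=int(v["gene_pos"]) - 1,
                ref_allele=v["ref_allele"],
                alt_allele=v["alt_allele"],
                gbap1_like=bool(v.get("gbap1_like", False)),
                in_homology_region=bool(v.get("in_homology_region", False)),
                severity=v.get("severity", "unknown"),
            )
            for v in doc.get("variants", [])
        ]
        recombinants = [
            NamedRecombinant(r["label"], frozenset(r["required_pseudo_sites"]))
            for r in doc.get("recombinants", [])
        ]
        homopolymers = [
            _interval_from_json(d, "homopolymers") for d in doc.get("homopolymers", [])
        ]
        baseline = int(doc.get("diploid_cn_baseline", 4))
    except (KeyError, TypeError) as exc:
        raise ModelError(f"{path}: missing or malformed field {exc}") from exc

    return ParalogModel(
        sites=sites,
        variants=variants,
        recombinants=recombinants,
        homopolymers=homopolymers,
        diploid_cn_baseline=baseline,
        metadata=doc.get("metadata", {}),
        **intervals,
    )


def load_bundled_model(name: str = "gba_hg38") -> ParalogModel:
    """Load a model shipped with the package (``data/<name>.json``).

    The bundled ``gba_hg38`` model carries the GBA/GBAP1 regions in hg38
    coordinates.  Its named anchors (unique CN-calling region, homopolymer
    runs, amplicon span, key variant positions) are real; unlisted site
    positions are evenly spaced placeholders, so the file demonstrates
    real-coordinate operation but is not a clinical-grade site list.
    """
    from importlib import resources

    ref = resources.files("paralocus").joinpath(f"data/{name}.json")
    with resources.as_file(ref) as path:
        if not path.exists():
            raise FileNotFoundError(f"no bundled model named {name}")
        return load_model(path)


def export_bed(model: ParalogModel, path: str | Path) -> None:
    """Write the model's named intervals as a BED file for browser inspection."""
    lines = []
    for name in _INTERVAL_FIELDS:
        iv = getattr(model, name)
        lines.append(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}")
    for i, iv in enumerate(model.homopolymers):
        lines.append(f"{iv.contig}\t{iv.start}\t{iv.end}\thomopolymer_{i + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- gene <-> pseudogene coordinate mapping --------------------------------


def _anchors(model: ParalogModel) -> list[tuple[int, int]]:
    """(gene_pos, pseudo_pos) anchor pairs; an indel site contributes the
    anchor at the 3' edge of the gene-only insertion."""
    anchors: list[tuple[int, int]] = []
    for s in model.sites:
        if s.is_indel:
            anchors.append((s.gene_pos + s.indel_length, s.pseudo_pos))
        else:
            anchors.append((s.gene_pos, s.pseudo_pos))
    return anchors


def map_gene_to_pseudo(model: ParalogModel, pos: int) -> int:
    """Map a gene position to its homologous pseudogene position.

    Piecewise-linear interpolation anchored at the differentiating sites.
    Positions inside a gene-only insertion (or outside the anchored span, or
    between anchors whose gene/pseudogene gaps disagree) raise
    :class:`NoMappingError`.
    """
    anchors = _anchors(model)
    if not anchors:
        raise NoMappingError("model has no differentiating sites to anchor on")
    for s in model.sites:
        if s.is_indel and s.gene_pos <= pos < s.gene_pos + s.indel_length:
            raise NoMappingError(
                f"gene position {pos} lies inside a gene-only insertion"
            )
    if pos < anchors[0][0] or pos > anchors[-1][0]:
        raise NoMappingError(f"gene position {pos} outside the anchored span")
    for (g0, p0), (g1, p1) in zip(anchors, anchors[1:]):
        if g0 <= pos <= g1:
            if pos == g0:
                return p0
            if pos == g1:
                return p1
            if g1 - g0 != p1 - p0:
                raise NoMappingError(
                    f"gene position {pos} lies in an unanchored indel segment"
                )
            return p0 + (pos - g0)
    return anchors[-1][1]


def map_pseudo_to_gene(model: ParalogModel, pos: int) -> int:
    """Inverse of :func:`map_gene_to_pseudo` (the mapping is strictly monotone)."""
    anchors = _anchors(model)
    if not anchors:
        raise NoMappingError("model has no differentiating sites to anchor on")
    if pos < anchors[0][1] or pos > anchors[-1][1]:
        raise NoMappingError(f"pseudogene position {pos} outside the anchored span")
    for (g0, p0), (g1, p1) in zip(anchors, anchors[1:]):
        if p0 <= pos <= p1:
            if pos == p0:
                return g0
            if pos == p1:
                return g1
            if g1 - g0 != p1 - p0:
                raise NoMappingError(
                    f"pseudogene position {pos} lies in an unanchored indel segment"
                )
            return g0 + (pos - p0)
    return anchors[-1][0]
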