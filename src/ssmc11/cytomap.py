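"""Chromosome-11 cytoband and FISH-probe coordinate registry (GRCh37).

Resolves parsed karyotype evidence — array intervals, gained probe signals,
band spans — into a single maximal demonstrated trisomy interval per case.

The cytoband fixture is the standard UCSC hg19 ideogram table for chromosome
11, stored on disk in the UCSC cytoBand text format (0-based half-open) and
converted to 1-based inclusive coordinates on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .iscn import ParsedKaryotype
from .types import GenomicInterval, hull

__all__ = [
    "CytobandMap",
    "ProbeRegistry",
    "BandLookupError",
    "ResolutionError",
    "load_cytobands",
    "default_probe_registry",
    "resolve_extent",
]


class BandLookupError(KeyError):
    pass


class ResolutionError(ValueError):
    pass


@dataclass
class CytobandMap:
    """Ordered band → interval map for one chromosome of one build."""

    chrom: str
    build: str
    bands: list[tuple[str, GenomicInterval, str]]  # (label, interval, stain)

    def __post_init__(self) -> None:
        labels = [b[0] for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("band labels must be unique")
        for (_, a, _), (_, b, _) in zip(self.bands, self.bands[1:]):
            if b.start != a.end + 1:
                raise ValueError(f"bands must tile without gaps/overlaps: {a} / {b}")

    @property
    def centromere_anchor(self) -> GenomicInterval:
        """Union of the acen (centromeric heterochromatin) bands."""
        acen = [iv for _, iv, stain in self.bands if stain == "acen"]
        if not acen:
            raise ValueError("no acen bands in map")
        return hull(acen)

    def band_to_interval(self, band: str) -> GenomicInterval:
        """Full GRCh37 interval of a band label.

        A coarse label resolves to the union of its stored sub-bands (e.g.
        ``p11.1`` → p11.11 ∪ p11.12 when only sub-bands are stored).
        """
        band = band.strip()
        exact = {label: iv for label, iv, _ in self.bands}
        if band in exact:
            return exact[band]
        subs = [iv for label, iv, _ in self.bands if label.startswith(band)]
        if subs:
            return hull(subs)
        near = sorted(exact, key=lambda l: (not l.startswith(band[:2]), l))[:5]
        raise BandLookupError(
            f"unknown band {band!r} on chr{self.chrom}; nearest labels: {near}"
        )


@dataclass
class ProbeRegistry:
    """FISH probe name → genomic span. User probes may be added via config."""

    probes: dict[str, GenomicInterval] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.probes

    def __getitem__(self, name: str) -> GenomicInterval:
        return self.probes[name]

    def add(self, name: str, interval: GenomicInterval) -> None:
        self.probes[name] = interval


def load_cytobands(path=None) -> CytobandMap:
    """Load the packaged (or a user-supplied) UCSC-format cytoband table."""
    if path is None:
        ref = resources.files("ssmc11.data").joinpath("cytoBand_chr11_GRCh37.txt")
        lines = ref.read_text().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    bands = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, start, end, label, stain = line.split("\t")
        chrom = chrom.removeprefix("chr")
        # UCSC on-disk convention is 0-based half-open
        bands.append((label, GenomicInterval(chrom, int(start) + 1, int(end)), stain))
    return CytobandMap(chrom="11", build="GRCh37", bands=bands)


def default_probe_registry(extra: Optional[dict[str, GenomicInterval]] = None) -> ProbeRegistry:
    """The packaged three-probe registry.

    D11Z1 is the centromeric alpha-satellite probe; its registered span is the
    operational acen region 51,600,000-55,700,000 in the printed-coordinate
    convention, so that probe-resolved extents match published case tables
    verbatim. The two BAC probes carry their published hg19 spans.
    """
    ref = resources.files("ssmc11.data").joinpath("probes.tsv")
    reg = ProbeRegistry()
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, chrom, start, end = line.split("\t")
        reg.add(name, GenomicInterval(chrom, int(start), int(end)))
    if extra:
        for name, iv in extra.items():
            reg.add(name, iv)
    return reg


def _gained_probe_calls(pk: ParsedKaryotype) -> list[str]:
    """Probe names whose calls demonstrate gained material.

    On a supernumerary marker any positive signal (``+`` or ``++``) shows the
    probe's target is present on the extra chromosome. On an intrachromosomal
    derivative (46-chromosome dup/der karyotype) a single ``+`` is the normal
    two-copy signal; only a doubled ``++`` signal demonstrates gain.
    """
    gained_calls = ("+", "++") if pk.is_marker_case else ("++",)
    return [n for n, c in pk.probe_calls.items() if c in gained_calls]


def resolve_extent(
    pk: ParsedKaryotype,
    registry: ProbeRegistry,
    bands: CytobandMap,
) -> tuple[GenomicInterval, list[str]]:
    """Outermost demonstrated trisomy extent for one parsed karyotype.

    Contributing evidence, in order of reliability: (a) a canonical-build array
    interval, (b) the full spans of gained probe signals. Band-span extents are
    a fallback used only when neither is available — published case intervals
    are probe/array anchored, and band edges would otherwise overrule
    finer-grained evidence. The p boundary is the minimum start and the q
    boundary the maximum end over contributing evidence.

    Negative probe calls act as validators: when the resolved extent overlaps a
    ``-`` probe's span a consistency warning is attached (the extent is NOT
    truncated). Returns (extent, warnings).
    """
    warnings: list[str] = []
    contributions: list[GenomicInterval] = []

    iv = pk.array_interval
    if iv is not None:
        if iv.chrom != "11":
            raise ResolutionError(f"array evidence on chr{iv.chrom}, expected chr11")
        contributions.append(iv)
    for ac in pk.array_calls:
        if not ac.canonical and ac.interval.chrom == "11":
            warnings.append(
                f"array interval {ac.interval} needs build conversion; ignored"
            )

    for name in _gained_probe_calls(pk):
        if name in registry:
            span = registry[name]
            if span.chrom != "11":
                raise ResolutionError(f"probe {name} maps to chr{span.chrom}")
            contributions.append(span)
        else:
            warnings.append(f"unknown probe {name!r}; not contributing")

    if not contributions and pk.band_span is not None:
        for label in pk.band_span:
            try:
                contributions.append(bands.band_to_interval(label))
            except BandLookupError:
                warnings.append(f"band {label!r} not resolvable; skipped")

    if not contributions:
        raise ResolutionError("no usable evidence (no array, gained probe, or band)")

    extent = hull(contributions)
    for name, call in pk.probe_calls.items():
        if call == "-" and name in registry and extent.overlaps(registry[name]):
            warnings.append(
                f"extent {extent} overlaps negative probe {name}; check evidence"
            )
    return extent, warnings
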