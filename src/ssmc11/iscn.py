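"""Permissive parser for the ISCN-like karyotype dialect of sSMC case reports.

The strings this module handles are transcriptions of diagnostic karyotypes:
mosaic clone lists with bracketed cell counts or percentages, ``.ish`` clauses
with marker shape and FISH probe calls, ``arr[build]`` array stanzas, and a lot
of appended free text. The grammar is a deliberately permissive subset of ISCN
2020: everything recognizable is structured, everything else degrades to a
remark — never a crash — because real case tables contain free-text rows.

Both the unicode arrow ``→`` and ASCII ``->`` are accepted; ``::`` ring
junction marks are tolerated and ignored for extent purposes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .types import GenomicInterval, Inheritance, Sex, Shape, normalize_build

__all__ = [
    "KaryotypeParseError",
    "ArrayCall",
    "ShapeCall",
    "Clone",
    "ParsedKaryotype",
    "parse_karyotype",
    "parse_arr",
    "emit_karyotype",
    "mosaic_fraction",
]


class KaryotypeParseError(ValueError):
    """Unparseable karyotype; carries the character offset of the failure."""

    def __init__(self, message: str, offset: int = 0):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass
class Clone:
    chrom_count: int
    sex_token: Optional[str] = None
    marker_terms: list[str] = field(default_factory=list)
    cell_count: Optional[int] = None
    cell_percent: Optional[float] = None
    raw: str = ""

    @property
    def has_marker(self) -> bool:
        """True when the clone carries the supernumerary marker / duplication."""
        if self.marker_terms:
            return True
        return bool(re.search(r"\b(?:dup|ins)\(", self.raw))


@dataclass
class ShapeCall:
    shape: Shape
    chroms: tuple[str, ...] = ("11",)
    band_span: Optional[tuple[str, str]] = None
    cell_count: Optional[int] = None


@dataclass
class ArrayCall:
    interval: GenomicInterval
    copy_number: int = 3
    #: False when the stanza's build is not hg19/GRCh37 (needs conversion;
    #: the record is kept but the interval is non-canonical).
    canonical: bool = True


@dataclass
class ParsedKaryotype:
    clones: list[Clone] = field(default_factory=list)
    shapes: list[ShapeCall] = field(default_factory=list)
    band_span: Optional[tuple[str, str]] = None
    probe_calls: dict[str, str] = field(default_factory=dict)
    array_calls: list[ArrayCall] = field(default_factory=list)
    inheritance: Inheritance = Inheritance.unknown
    #: the ISCN "mos" designator was present
    has_mos: bool = False
    remark: str = ""

    # -- derived views ---------------------------------------------------

    @property
    def array_interval(self) -> Optional[GenomicInterval]:
        """First canonical-build (GRCh37) chromosome-11 array interval."""
        for ac in self.array_calls:
            if ac.canonical and ac.interval.chrom == "11":
                return ac.interval
        return None

    @property
    def sex(self) -> Sex:
        for c in self.clones:
            if c.sex_token in ("XY",):
                return Sex.male
            if c.sex_token in ("XX",):
                return Sex.female
        return Sex.unknown

    @property
    def is_marker_case(self) -> bool:
        """Supernumerary-marker karyotype (vs. intrachromosomal der/dup)."""
        return any(
            c.chrom_count >= 47 or any(t.startswith("+") for t in c.marker_terms)
            for c in self.clones
        )

    @property
    def mosaic(self) -> bool:
        """Mosaic iff a clone without the marker coexists, or the karyotype
        carries the ISCN ``mos`` designator (multi-marker carriers can be
        mosaic for each marker without any fully marker-free clone)."""
        if self.has_mos:
            return True
        if len(self.clones) < 2:
            return False
        return any(not c.has_marker for c in self.clones)

    @property
    def predominant_shape(self) -> Shape:
        """Shape of the clone with the largest cell count; first-listed on ties
        or when no counts are attached."""
        calls = [s for s in self.shapes if "11" in s.chroms]
        if not calls:
            return Shape.unknown
        counted = [s for s in calls if s.cell_count is not None]
        if counted:
            best = max(counted, key=lambda s: s.cell_count)
            return best.shape
        return calls[0].shape

    def signature(self) -> tuple:
        """Semantic content used for round-trip equality."""
        return (
            tuple(
                (c.chrom_count, c.sex_token, c.has_marker, c.cell_count, c.cell_percent)
                for c in self.clones
            ),
            tuple((s.shape, s.band_span, s.cell_count) for s in self.shapes if "11" in s.chroms),
            self.band_span,
            tuple(sorted(self.probe_calls.items())),
            tuple(
                (a.interval.chrom, a.interval.start, a.interval.end, a.interval.build, a.copy_number)
                for a in self.array_calls
            ),
            self.inheritance,
            self.mosaic,
        )


# ----------------------------------------------------------------------
# token patterns
# ----------------------------------------------------------------------

_ARROW = "→"

# clone stanza start: a plausible chromosome count followed by a comma that is
# not a thousands separator (guard: not digit-adjacent, not followed by a
# 3-digit group as in "51,095,992")
_CLONE_START = re.compile(
    r"(?<![\d,.])(?P<count>4[4-9]|5[0-3])(?:\s*[-–]\s*\d{2})?\s*,(?!\s*\d{3}\b)"
)

# where a clone stanza certainly ends (evidence clauses / free-text openers)
_CLONE_STOP = re.compile(
    r"/|\.(?:ish|rev|arr|seq)\b|\brev\s+ish\b|(?<![a-z.])\bish\b|\barr\s*[\[\(]"
    r"|\bseq\[|\bmar\s?\d\s*[=:]|#\d|\bsecond sSMC|\bfinal karyotype|\baCGH\b"
    r"|\bLSI\b|\bno clear\b|\bno data\b|\bmost likely\b|\bacc\. to\b|\bin [∼~]?\d+%"
)

_BRACKET = re.compile(r"\[([^\]]{1,16})\]")
_SEX = re.compile(r"^\s*(X[XYN])\b")
_MARKER_TERM = re.compile(r"\+\s*([0-9]?(?:inv\s+dup|min|mar|r|der|i|dic)[\w-]*(?:\([^()]*\))*)")
_INHERIT = re.compile(r"\b(mat|pat|dn)\b")

_ARR = re.compile(
    r"\barr\s*[\[\(]\s*(?P<build>[A-Za-z0-9]+)\s*[\]\)]\s*"
    r"(?P<locus>[0-9XY][0-9XYpq.,~∼\-–? ]*?)?"
    r"\(\s*(?P<a>[\d][\d,. ]*?)\s*[_\-–]\s*(?P<b>[\d][\d,. ]*?)\s*\)"
    r"\s*(?:x(?P<cn>\d+))?"
)
_ARR_ANY = re.compile(r"\barr\s*[\[\(]")

_SHAPE = re.compile(
    r"(?<![\w])(?P<shape>inv\s+dup|min(?:\s+or\s+r)?|r)\s*"
    r"\(\s*(?P<chroms>[0-9XY]{1,2}(?:\s*;\s*[0-9XY]{1,2})*)\s*\)\s*"
    r"(?P<desc>\([^()]*\))?\s*(?:\[(?P<cnt>\d+)\])?"
)

_BAND_TOKEN = re.compile(r"(?:\b(?P<chrom>\d{1,2})(?=[pq]))?(?P<band>[pq](?:ter|[\d][\d.?]*))")

_PROBE_GROUP = re.compile(r"\(([^()]+)\)")
_PROBE_CALL = re.compile(r"^([A-Za-z][A-Za-z0-9OI._/-]*?)(\+\+|\+|[-−])$")


def _to_int(num: str) -> int:
    """Strip thousands separators (including the occasional '.' typo)."""
    return int(re.sub(r"[,. ]", "", num))


def _chrom_of_locus(locus: Optional[str]) -> str:
    if not locus:
        return "11"
    m = re.match(r"\s*([0-9]{1,2}|[XY])", locus)
    return m.group(1) if m else "11"


def _parse_bracket(content: str) -> tuple[Optional[int], Optional[float]]:
    content = content.strip()
    if not content or content in ("?", "?%") or "majority" in content:
        return None, None
    m = re.match(r"^(\d+(?:\.\d+)?)\s*%", content)
    if m:
        return None, float(m.group(1))
    if re.fullmatch(r"\d+", content):
        return int(content), None
    m = re.match(r"^(\d+)", content)  # ranges like "60%-90%"
    if m and "%" in content:
        return None, float(m.group(1))
    return None, None


def _parse_clones(text: str) -> list[Clone]:
    starts = [m for m in _CLONE_START.finditer(text)]
    clones: list[Clone] = []
    for i, m in enumerate(starts):
        body_start = m.end()
        # clone body runs to the next clone start or the first stop token
        limit = starts[i + 1].start() if i + 1 < len(starts) else len(text)
        stop = _CLONE_STOP.search(text, body_start, limit)
        body_end = stop.start() if stop else limit
        body = text[body_start:body_end].strip().rstrip(",;")
        count = int(m.group("count"))
        sex_m = _SEX.match(body)
        sex_token = sex_m.group(1) if sex_m else None
        terms = ["+" + t.strip() for t in _MARKER_TERM.findall(body)]
        cell_count = cell_percent = None
        br = _BRACKET.search(body)
        if br:
            cell_count, cell_percent = _parse_bracket(br.group(1))
        clones.append(
            Clone(
                chrom_count=count,
                sex_token=sex_token,
                marker_terms=terms,
                cell_count=cell_count,
                cell_percent=cell_percent,
                raw=text[m.start():body_end],
            )
        )
    return clones


def _parse_band_span(desc: str) -> Optional[tuple[str, str]]:
    """Extract the outermost chromosome-11 band pair from a shape descriptor."""
    tokens: list[str] = []
    for segment in re.split(r"::", desc.strip("()")):
        seg_tokens = list(_BAND_TOKEN.finditer(segment))
        if not seg_tokens:
            continue
        # drop segments that clearly belong to another chromosome
        prefixes = {t.group("chrom") for t in seg_tokens if t.group("chrom")}
        if prefixes and "11" not in prefixes:
            continue
        tokens.extend(t.group("band") for t in seg_tokens)
    if not tokens:
        return None
    return tokens[0], tokens[-1]


def _parse_shapes(text: str) -> list[ShapeCall]:
    calls: list[ShapeCall] = []
    for m in _SHAPE.finditer(text):
        raw_shape = re.sub(r"\s+", " ", m.group("shape"))
        chroms = tuple(c.strip() for c in m.group("chroms").split(";"))
        desc = m.group("desc")
        band_span = _parse_band_span(desc) if desc else None
        cnt = int(m.group("cnt")) if m.group("cnt") else None
        if raw_shape == "min or r":
            for s in (Shape.min, Shape.r):
                calls.append(ShapeCall(s, chroms, band_span, cnt))
        else:
            shape = {"inv dup": Shape.inv_dup, "min": Shape.min, "r": Shape.r}[raw_shape]
            calls.append(ShapeCall(shape, chroms, band_span, cnt))
    return calls


def _parse_probes(text: str) -> dict[str, str]:
    calls: dict[str, str] = {}
    for group in _PROBE_GROUP.findall(text):
        pieces = [p.strip() for p in group.split(",")]
        parsed = []
        for piece in pieces:
            pm = _PROBE_CALL.match(piece)
            if pm:
                parsed.append((pm.group(1), pm.group(2).replace("−", "-")))
        # only accept groups where every comma piece is a probe call, so band
        # descriptors and locus lists are not mistaken for probe panels
        if parsed and len(parsed) == len(pieces):
            for name, call in parsed:
                calls[name] = call
    return calls


def _parse_arrays(text: str) -> list[ArrayCall]:
    out = []
    for m in _ARR.finditer(text):
        build = normalize_build(m.group("build"))
        chrom = _chrom_of_locus(m.group("locus"))
        start, end = _to_int(m.group("a")), _to_int(m.group("b"))
        if end < start:
            continue  # not a coordinate pair (e.g. a band list)
        cn = int(m.group("cn")) if m.group("cn") else 3
        out.append(
            ArrayCall(
                interval=GenomicInterval(chrom, start, end, build),
                copy_number=cn,
                canonical=(build == "GRCh37"),
            )
        )
    return out


def parse_karyotype(text: str) -> ParsedKaryotype:
    """Parse one karyotype string into structured evidence.

    Clones are split on ``/``; bracketed integers become cell counts and
    bracketed percentages cell percents; shape/band/probe/array stanzas are
    located anywhere in the string (case tables append them as free text);
    ``mat``/``pat``/``dn`` tokens set the inheritance. Unrecognized trailing
    text is preserved as a remark.
    """
    if not text or not text.strip():
        raise KaryotypeParseError("empty karyotype string", 0)
    text = text.replace("->", _ARROW).strip()
    clones = _parse_clones(text)
    if not clones:
        raise KaryotypeParseError(
            "no recognizable clone stanza", _first_nonspace(text)
        )
    inheritance = Inheritance.unknown
    for c in clones:
        im = _INHERIT.search(c.raw)
        if im:
            inheritance = {
                "mat": Inheritance.maternal,
                "pat": Inheritance.paternal,
                "dn": Inheritance.de_novo,
            }[im.group(1)]
            break
    shapes = _parse_shapes(text)
    band_span = next((s.band_span for s in shapes if "11" in s.chroms and s.band_span), None)
    pk = ParsedKaryotype(
        clones=clones,
        shapes=shapes,
        band_span=band_span,
        probe_calls=_parse_probes(text),
        array_calls=_parse_arrays(text),
        inheritance=inheritance,
        has_mos=bool(re.search(r"\bmos\b", text)),
        remark=text,
    )
    # clone-term shape fallback (e.g. "+min[15%]" with no ish clause)
    if not any("11" in s.chroms for s in pk.shapes):
        for c in clones:
            for t in c.marker_terms:
                for tok, shape in (("inv dup", Shape.inv_dup), ("min", Shape.min), ("r", Shape.r)):
                    if re.match(rf"\+{tok}\b", t):
                        pk.shapes.append(ShapeCall(shape))
                        break
                else:
                    continue
                break
    return pk


def _first_nonspace(text: str) -> int:
    return len(text) - len(text.lstrip())


def parse_arr(text: str) -> ArrayCall:
    """Parse a single ``arr[build] locus(start_end)xN`` stanza.

    Coordinates are split on ``_`` (or ``-``) with thousands separators
    stripped; a build other than hg19/GRCh37 is kept but flagged non-canonical
    (needs conversion). A malformed coordinate pair is a parse error.
    """
    if not _ARR_ANY.search(text):
        raise KaryotypeParseError("no arr[...] stanza", 0)
    calls = _parse_arrays(text)
    if not calls:
        m = _ARR_ANY.search(text)
        raise KaryotypeParseError("malformed arr coordinate pair", m.start())
    return calls[0]


def mosaic_fraction(pk: ParsedKaryotype) -> Optional[float]:
    """Fraction of counted cells carrying the marker, in [0, 1].

    Uses clone cell counts when present, percentages otherwise; mixing the two
    notations across clones is inconsistent and yields ``None``.
    """
    counts = [c.cell_count for c in pk.clones if c.cell_count is not None]
    percents = [(c.cell_percent, c.has_marker) for c in pk.clones if c.cell_percent is not None]
    if counts and percents:
        return None
    if counts:
        if len(counts) < len(pk.clones):
            return None
        total = sum(counts)
        marker = sum(c.cell_count for c in pk.clones if c.has_marker)
        return marker / total if total else None
    if percents:
        marker_pct = sum(p for p, has in percents if has)
        return min(marker_pct / 100.0, 1.0)
    return None


# ----------------------------------------------------------------------
# serializer
# ----------------------------------------------------------------------

def emit_karyotype(pk: ParsedKaryotype) -> str:
    """Serialize to a canonical string that re-parses to an equal structure."""
    parts = []
    clone_strs = []
    inherit_tok = {
        Inheritance.maternal: " mat",
        Inheritance.paternal: " pat",
        Inheritance.de_novo: " dn",
    }.get(pk.inheritance, "")
    for i, c in enumerate(pk.clones):
        s = f"{c.chrom_count},"
        if c.sex_token:
            s += c.sex_token
        if c.has_marker:
            s += ",+mar"
        if i == 0 and inherit_tok:
            s += inherit_tok
        if c.cell_count is not None:
            s += f"[{c.cell_count}]"
        elif c.cell_percent is not None:
            pct = c.cell_percent
            s += f"[{int(pct) if pct == int(pct) else pct}%]"
        clone_strs.append(s)
    prefix = "mos " if pk.mosaic else ""
    parts.append(prefix + "/".join(clone_strs))

    shape_strs = []
    for sc in pk.shapes:
        if "11" not in sc.chroms:
            continue
        s = f"{sc.shape.value}({';'.join(sc.chroms)})"
        if sc.band_span:
            s += f"(:{sc.band_span[0]}{_ARROW}{sc.band_span[1]}:)"
        if sc.cell_count is not None:
            s += f"[{sc.cell_count}]"
        shape_strs.append(s)
    ish = ""
    if shape_strs:
        ish = ".ish " + "/".join(shape_strs)
    if pk.probe_calls:
        calls = ",".join(f"{n}{c}" for n, c in sorted(pk.probe_calls.items()))
        ish = (ish or ".ish mar(11)") + f"({calls})"
    if ish:
        parts.append(ish)

    for ac in pk.array_calls:
        iv = ac.interval
        build = iv.build if iv.build != "GRCh37" else "hg19"
        parts.append(f".arr[{build}] {iv.chrom}({iv.start:,}_{iv.end:,})x{ac.copy_number}")
    return "".join(parts)
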