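"""Data model and file I/O for genetic maps, STR genotypes, and cohort tables.

Three small text dialects are supported:

* **MAP** — whitespace-delimited marker map: ``chromosome name cM [bp] [het]``.
  The focal variant is carried as a pseudo-locus row whose chromosome label
  ends in ``*``. Lines starting with ``#`` are comments. A fourth column
  containing a decimal point is read as heterozygosity, otherwise as a
  physical position in bp.
* **PED** — whitespace-delimited genotypes: ``family individual carrier``
  followed by two allele columns (fragment sizes in bp) per map marker, in
  map order. Missing alleles are coded ``0``; both slots of a genotype must
  be missing or both present.
* **Cohort** — tab-delimited phenotype table with a header row naming the
  :class:`PhenotypeRecord` fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Marker",
    "GeneticMap",
    "GenotypeRecord",
    "PhenotypeRecord",
    "ParseError",
    "MissingFocalVariantError",
    "MarkerOrderError",
    "DuplicateMarkerError",
    "MalformedFieldError",
    "AlleleColumnError",
    "HalfMissingGenotypeError",
    "UnknownSexError",
    "DuplicateIndividualError",
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_cohort",
    "write_cohort",
]

MISSING_ALLELE = 0

PHENOTYPE_FLAGS = ("taad", "arterial_other", "cardio_other", "connective")


class ParseError(ValueError):
    """Base class for file-format errors; carries path and line context."""

    def __init__(self, message: str, path: str | Path | None = None, line: int | None = None):
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)


class MissingFocalVariantError(ParseError):
    """MAP file lacks a row flagged (chromosome suffix ``*``) as the focal variant."""


class MarkerOrderError(ParseError):
    """Marker cM positions are not strictly increasing (unsorted rows or ties)."""


class DuplicateMarkerError(ParseError):
    """Two map rows share a marker name."""


class MalformedFieldError(ParseError):
    """A numeric field failed to parse."""


class AlleleColumnError(ParseError):
    """PED row has the wrong number of allele columns for the map."""


class HalfMissingGenotypeError(ParseError):
    """Exactly one of the two allele slots at a marker is the missing code."""


class UnknownSexError(ParseError):
    """Cohort sex code outside {male, female} (m/f accepted)."""


class DuplicateIndividualError(ParseError):
    """Cohort individual_id repeated within a family."""


@dataclass(frozen=True)
class Marker:
    """One STR locus: genetic (cM) and optional physical (bp) coordinates.

    ``het`` is the locus's expected heterozygosity 1 − Σp², if known.
    """

    name: str
    chromosome: str
    pos_cM: float
    pos_bp: int | None = None
    het: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be nonempty")
        if self.pos_cM < 0:
            raise ValueError(f"marker {self.name}: pos_cM must be >= 0")
        if self.het is not None and not (0.0 < self.het < 1.0):
            raise ValueError(f"marker {self.name}: het must lie in (0,1)")


@dataclass(frozen=True)
class GeneticMap:
    """Ordered STR marker panel bracketing a focal variant.

    Markers are strictly sorted by ``pos_cM`` (ties forbidden). The focal
    variant is a named position, normally strictly inside the marker span;
    a variant at or beyond the ends is allowed but flagged ``terminal``.
    """

    markers: tuple[Marker, ...]
    variant_name: str
    variant_cM: float
    variant_bp: int | None = None
    terminal: bool = field(default=False)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        cms = [m.pos_cM for m in self.markers]
        if any(b <= a for a, b in zip(cms, cms[1:])):
            raise ValueError("markers must be strictly sorted by pos_cM")
        if self.markers:
            inside = cms[0] < self.variant_cM < cms[-1]
            if not inside and not self.terminal:
                object.__setattr__(self, "terminal", True)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def index(self, name: str) -> int:
        return self.marker_names.index(name)

    def marker(self, name: str) -> Marker:
        return self.markers[self.index(name)]

    @property
    def variant_left_index(self) -> int:
        """Index of the last marker strictly left of the variant (-1 if none)."""
        i = -1
        for j, m in enumerate(self.markers):
            if m.pos_cM < self.variant_cM:
                i = j
        return i

    def span_cM(self) -> float:
        return self.markers[-1].pos_cM - self.markers[0].pos_cM


@dataclass(frozen=True)
class GenotypeRecord:
    """Unphased diploid STR genotypes of one individual, in map marker order.

    ``alleles[i]`` is the unordered allele pair (fragment sizes, bp) at the
    i-th map marker; ``(0, 0)`` means missing.
    """

    individual_id: str
    family_id: str
    carrier: bool
    alleles: tuple[tuple[int, int], ...]

    def allele_set(self, i: int) -> frozenset[int]:
        """Observed alleles at marker index *i*; empty if missing."""
        a, b = self.alleles[i]
        if a == MISSING_ALLELE:
            return frozenset()
        return frozenset((a, b))

    @property
    def fully_missing(self) -> bool:
        return all(a == MISSING_ALLELE for a, _ in self.alleles)


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-individual phenotype flags for penetrance tabulation.

    Categories are not mutually exclusive; "unaffected" means all four
    flags are false. ``reported_z`` is free-text annotation for published
    aortic Z-scores and is never computed on.
    """

    individual_id: str
    family_id: str
    sex: str  # "male" | "female"
    taad: bool
    arterial_other: bool
    cardio_other: bool
    connective: bool
    age: float | None = None
    reported_z: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be >= 0")

    @property
    def unaffected(self) -> bool:
        return not (self.taad or self.arterial_other or self.cardio_other or self.connective)


# ---------------------------------------------------------------------------
# MAP dialect


def _parse_float(tok: str, what: str, path, lineno) -> float:
    try:
        return float(tok)
    except ValueError:
        raise MalformedFieldError(f"malformed {what}: {tok!r}", path, lineno) from None


def _parse_int(tok: str, what: str, path, lineno) -> int:
    try:
        return int(tok)
    except ValueError:
        raise MalformedFieldError(f"malformed {what}: {tok!r}", path, lineno) from None


def read_map(path: str | Path) -> GeneticMap:
    """Read a MAP-dialect file into a :class:`GeneticMap`.

    Raises :class:`MissingFocalVariantError`, :class:`MarkerOrderError`,
    :class:`DuplicateMarkerError` or :class:`MalformedFieldError` on the
    corresponding defects.
    """
    path = Path(path)
    markers: list[Marker] = []
    variant: tuple[str, float, int | None] | None = None
    prev_cM: float | None = None
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) < 3:
                raise MalformedFieldError(f"expected >=3 columns, got {len(toks)}", path, lineno)
            chrom, name = toks[0], toks[1]
            is_variant = chrom.endswith("*")
            chrom = chrom.rstrip("*")
            cm = _parse_float(toks[2], "cM position", path, lineno)
            bp: int | None = None
            het: float | None = None
            rest = [t for t in toks[3:] if t not in (".", "NA", "na")]
            if len(rest) == 1:
                if "." in rest[0]:
                    het = _parse_float(rest[0], "heterozygosity", path, lineno)
                else:
                    bp = _parse_int(rest[0], "bp position", path, lineno)
            elif len(rest) == 2:
                bp = _parse_int(rest[0], "bp position", path, lineno)
                het = _parse_float(rest[1], "heterozygosity", path, lineno)
            elif len(rest) > 2:
                raise MalformedFieldError(f"too many columns ({len(toks)})", path, lineno)
            if prev_cM is not None and cm <= prev_cM:
                raise MarkerOrderError(
                    f"positions not strictly increasing at {name} ({cm} after {prev_cM})",
                    path, lineno,
                )
            prev_cM = cm
            if is_variant:
                if variant is not None:
                    raise ParseError("more than one focal-variant row", path, lineno)
                variant = (name, cm, bp)
                continue
            if name in seen:
                raise DuplicateMarkerError(f"duplicate marker name {name}", path, lineno)
            seen.add(name)
            try:
                markers.append(Marker(name, chrom, cm, bp, het))
            except ValueError as exc:
                raise MalformedFieldError(str(exc), path, lineno) from None
    if variant is None:
        raise MissingFocalVariantError("no focal-variant row (chromosome suffix '*')", path)
    vname, vcm, vbp = variant
    return GeneticMap(tuple(markers), vname, vcm, vbp)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    """Write a GeneticMap back to the MAP dialect (cM to 6 decimals)."""
    rows = []
    for m in gmap.markers:
        rows.append((m.chromosome, m.name, m.pos_cM, m.pos_bp, m.het))
    chrom = gmap.markers[0].chromosome if gmap.markers else "?"
    rows.append((chrom + "*", gmap.variant_name, gmap.variant_cM, gmap.variant_bp, None))
    rows.sort(key=lambda r: r[2])
    with open(path, "w") as fh:
        fh.write("# chromosome name cM bp het   ('*' flags the focal variant)\n")
        for chrom, name, cm, bp, het in rows:
            cols = [chrom, name, f"{cm:.6f}"]
            cols.append(str(bp) if bp is not None else ".")
            if het is not None:
                cols.append(f"{het:.6f}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PED dialect


def read_genotypes(path: str | Path, gmap: GeneticMap) -> list[GenotypeRecord]:
    """Read PED-dialect genotype rows, validated against *gmap*.

    One record per input row, order preserved. Raises
    :class:`AlleleColumnError` on a shape mismatch,
    :class:`MalformedFieldError` on non-integer alleles and
    :class:`HalfMissingGenotypeError` when exactly one slot of a pair is 0.
    """
    path = Path(path)
    n = len(gmap.markers)
    records: list[GenotypeRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 3 + 2 * n:
                raise AlleleColumnError(
                    f"expected {3 + 2 * n} columns ({n} markers), got {len(toks)}",
                    path, lineno,
                )
            fam, ind, flag = toks[0], toks[1], toks[2]
            if flag not in ("0", "1"):
                raise MalformedFieldError(f"carrier flag must be 0/1, got {flag!r}", path, lineno)
            pairs = []
            for k in range(n):
                a = _parse_int(toks[3 + 2 * k], "allele", path, lineno)
                b = _parse_int(toks[4 + 2 * k], "allele", path, lineno)
                if a < 0 or b < 0:
                    raise MalformedFieldError(f"negative allele {a}/{b}", path, lineno)
                if (a == MISSING_ALLELE) != (b == MISSING_ALLELE):
                    raise HalfMissingGenotypeError(
                        f"half-missing genotype {a}/{b} at marker {gmap.markers[k].name}",
                        path, lineno,
                    )
                pairs.append((min(a, b), max(a, b)))
            records.append(GenotypeRecord(ind, fam, flag == "1", tuple(pairs)))
    return records


def write_genotypes(records: Iterable[GenotypeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.family_id, r.individual_id, "1" if r.carrier else "0"]
            for a, b in r.alleles:
                cols += [str(a), str(b)]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Cohort table

_SEX = {"m": "male", "male": "male", "f": "female", "female": "female"}
_COHORT_COLUMNS = ("individual_id", "family_id", "sex", "age") + PHENOTYPE_FLAGS + ("reported_z",)


def read_cohort(path: str | Path) -> list[PhenotypeRecord]:
    """Read a tab-delimited cohort phenotype table (header row required)."""
    path = Path(path)
    records: list[PhenotypeRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return []
        cols = header.split("\t")
        missing = [c for c in ("individual_id", "family_id", "sex") + PHENOTYPE_FLAGS if c not in cols]
        if missing:
            raise ParseError(f"cohort table missing columns {missing}", path, 1)
        idx = {c: i for i, c in enumerate(cols)}
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            toks = raw.rstrip("\n").split("\t")
            if len(toks) != len(cols):
                raise ParseError(f"expected {len(cols)} fields, got {len(toks)}", path, lineno)

            def get(c: str) -> str:
                return toks[idx[c]].strip() if c in idx else ""

            sex_tok = get("sex").lower()
            if sex_tok not in _SEX:
                raise UnknownSexError(f"unknown sex code {get('sex')!r}", path, lineno)
            key = (get("family_id"), get("individual_id"))
            if key in seen:
                raise DuplicateIndividualError(
                    f"duplicate individual {key[1]!r} in family {key[0]!r}", path, lineno
                )
            seen.add(key)
            age_tok = get("age")
            age = None if age_tok in ("", ".", "NA", "na") else _parse_float(age_tok, "age", path, lineno)
            flags = {}
            for f in PHENOTYPE_FLAGS:
                tok = get(f)
                if tok not in ("0", "1"):
                    raise MalformedFieldError(f"flag {f} must be 0/1, got {tok!r}", path, lineno)
                flags[f] = tok == "1"
            records.append(
                PhenotypeRecord(
                    individual_id=key[1], family_id=key[0], sex=_SEX[sex_tok],
                    age=age, reported_z=get("reported_z"), **flags,
                )
            )
    return records


def write_cohort(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COHORT_COLUMNS) + "\n")
        for r in records:
            row = [
                r.individual_id, r.family_id, r.sex,
                "" if r.age is None else (f"{r.age:g}"),
                *["1" if getattr(r, f) else "0" for f in PHENOTYPE_FLAGS],
                r.reported_z,
            ]
            fh.write("\t".join(row) + "\n")
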