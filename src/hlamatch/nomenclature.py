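"""WHO HLA allele nomenclature: parsing, validation and normalisation.

Allele names follow the colon-delimited WHO convention
``LOCUS*FF:FF[:FF[:FF]][SUFFIX]`` where the first field designates the
antigen-level (serology-like) group, the second the specific protein, and the
optional third/fourth fields synonymous or non-coding variation.  A trailing
letter marks an expression variant; ``N`` means the allele is not expressed
(a *null* allele).

Registry analyses work at two-field ("high") resolution: higher-resolution
names are truncated to two fields, and a subject carrying a null allele is
treated as homozygous for the partner allele at that locus, because the null
product cannot present peptide or be an alloantigen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

SUPPORTED_LOCI: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQB1", "DPB1")

CLASS_I_LOCI: frozenset[str] = frozenset({"A", "B", "C"})
CLASS_II_LOCI: frozenset[str] = frozenset({"DRB1", "DQB1", "DPB1"})

#: The five loci entering the x/10 match grade used for donor selection.
MAIN_LOCI: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQB1")

_EXPRESSION_SUFFIXES = frozenset("NLSQCA")
_NULL_SUFFIXES = frozenset("N")

_ALLELE_RE = re.compile(
    r"""^\s*
        (?P<locus>[A-Za-z][A-Za-z0-9]{0,4})
        \*
        (?P<fields>\d+(?::\d+){0,3})
        (?P<suffix>[NLSQCAnlsqca])?
        \s*$""",
    re.VERBOSE,
)


class AlleleParseError(ValueError):
    """Raised when an allele string does not follow WHO nomenclature."""


class GenotypeError(ValueError):
    """Raised for genotypes that cannot be normalised (e.g. two null alleles)."""


@dataclass(frozen=True)
class Allele:
    """A parsed HLA allele at up to two-field resolution.

    ``field1``/``field2`` keep their zero-padded string form so that the
    canonical serialisation round-trips exactly; equality compares numeric
    values, so ``A*01:01`` == ``A*1:1``.
    """

    locus: str
    field1: str
    field2: Optional[str]
    suffix: str = ""
    raw: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.locus not in SUPPORTED_LOCI:
            raise AlleleParseError(f"unsupported locus {self.locus!r}")

    @property
    def resolution(self) -> int:
        """Number of fields retained (1 or 2)."""
        return 1 if self.field2 is None else 2

    @property
    def is_null(self) -> bool:
        return self.suffix in _NULL_SUFFIXES

    @property
    def key(self) -> tuple[str, int, int]:
        """Numeric two-field identity used for matching comparisons."""
        f2 = -1 if self.field2 is None else int(self.field2)
        return (self.locus, int(self.field1), f2)

    @property
    def name(self) -> str:
        """Canonical two-field name, e.g. ``"C*03:04"`` (suffix included)."""
        if self.field2 is None:
            return f"{self.locus}*{self.field1}{self.suffix}"
        return f"{self.locus}*{self.field1}:{self.field2}{self.suffix}"

    @property
    def first_field_name(self) -> str:
        """Locus-qualified antigen-level token, e.g. ``"B*35"``."""
        return f"{self.locus}*{self.field1}"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Allele):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __lt__(self, other: "Allele") -> bool:
        return self.key < other.key


def parse_allele(text: str, locus: Optional[str] = None) -> Allele:
    """Parse a WHO allele name into an :class:`Allele`.

    Names with three or four fields are truncated to two fields and flagged
    (``truncated=True``).  One-field names are accepted (``resolution == 1``)
    so that callers can decide whether low-resolution typing is admissible.

    Parameters
    ----------
    text:
        Allele string such as ``"DRB1*14:54"`` or ``"C*03:04:01:02"``.
    locus:
        If given, the parsed locus must agree (case-insensitive).

    Raises
    ------
    AlleleParseError
        On empty input, missing ``*`` separator, non-numeric fields or an
        unknown locus.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele string")
    m = _ALLELE_RE.match(text)
    if m is None:
        raise AlleleParseError(f"malformed allele string {text!r}")
    loc = m.group("locus").upper()
    if loc not in SUPPORTED_LOCI:
        raise AlleleParseError(f"unknown locus {m.group('locus')!r} in {text!r}")
    if locus is not None and loc != locus.upper():
        raise AlleleParseError(
            f"allele {text!r} has locus {loc}, expected {locus.upper()}"
        )
    fields = m.group("fields").split(":")
    suffix = (m.group("suffix") or "").upper()
    return Allele(
        locus=loc,
        field1=fields[0],
        field2=fields[1] if len(fields) > 1 else None,
        suffix=suffix,
        raw=text.strip(),
        truncated=len(fields) > 2,
    )


def first_field(allele: Allele) -> str:
    """Return the locus-qualified antigen-level token, e.g. ``"B*35"``.

    Two alleles with equal first fields are *antigen-level matched* ("low
    resolution matched") even when their second fields differ.
    """
    return allele.first_field_name


@dataclass(frozen=True)
class LocusGenotype:
    """Two alleles of one subject at one locus, after null-allele handling."""

    locus: str
    allele_a: Allele
    allele_b: Allele
    effectively_homozygous: bool = False
    had_null: bool = False

    def __post_init__(self) -> None:
        if self.allele_a.locus != self.locus or self.allele_b.locus != self.locus:
            raise GenotypeError(
                f"alleles {self.allele_a.name}/{self.allele_b.name} do not match "
                f"locus {self.locus}"
            )

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return (self.allele_a, self.allele_b)

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.allele_a.name}+{self.allele_b.name}"


def normalize_genotype(locus: str, text_a: str, text_b: str) -> LocusGenotype:
    """Build a :class:`LocusGenotype` applying the null-allele rule.

    A subject carrying a null allele is considered homozygous for the partner
    (expressed) allele at that locus.  The result is symmetric in the two
    inputs; ``effectively_homozygous`` is set whenever the two retained
    alleles are equal at two-field resolution.

    Raises
    ------
    GenotypeError
        If both alleles are null: the genotype expresses nothing at this
        locus and cannot be classified.
    """
    locus = locus.upper()
    a = parse_allele(text_a, locus=locus)
    b = parse_allele(text_b, locus=locus)
    had_null = a.is_null or b.is_null
    if a.is_null and b.is_null:
        raise GenotypeError(
            f"both alleles null at {locus} ({a.name}, {b.name}): "
            "genotype unclassifiable"
        )
    if a.is_null:
        a = b
    elif b.is_null:
        b = a
    return LocusGenotype(
        locus=locus,
        allele_a=a,
        allele_b=b,
        effectively_homozygous=(a == b),
        had_null=had_null,
    )
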