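"""Per-pair mismatch enumeration, direction vectors and match grades.

A patient-donor pair carries two alleles per subject at each of the six loci
HLA-A, -B, -C, -DRB1, -DQB1 and -DPB1.  The mismatch count at a locus is
``2 - m`` where ``m`` is the size of a maximum matching between the two
2-element allele multisets under two-field equality.  Unshared alleles give
the mismatch its direction:

* **GvH vector** -- patient alleles absent from the donor genotype (targets
  of the graft's alloresponse);
* **HvG vector** -- donor alleles absent from the patient genotype (targets
  of rejection);
* **bidirectional** when both vectors are non-empty.

The x/10 match grade counts matched alleles over the five main loci used for
donor selection (A, B, C, DRB1, DQB1); the x/12 grade adds DPB1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from hlamatch.nomenclature import (
    Allele,
    CLASS_I_LOCI,
    GenotypeError,
    LocusGenotype,
    MAIN_LOCI,
    SUPPORTED_LOCI,
    normalize_genotype,
)

ERAS: tuple[str, ...] = ("pre-2011", "2011-2015", "2016-2020", "2021-2022")

CATEGORIES: tuple[str, ...] = ("10/10", "9/10", "8/10", "<8/10")


@dataclass(frozen=True)
class MismatchRecord:
    """Mismatch structure at one locus of one pair.

    ``pairings`` lists the (patient allele, donor allele) couples of unshared
    alleles produced by the matching step; resolution labels refer to these
    pairings.  The direction vectors apply set semantics: an allele appears
    in a vector only if it is absent from the other subject's genotype, so a
    homozygous-vs-heterozygous constellation can yield a single-direction
    mismatch.
    """

    locus: str
    count: int
    unmatched_patient: tuple[Allele, ...]
    unmatched_donor: tuple[Allele, ...]
    pairings: tuple[tuple[Allele, Allele], ...]

    @property
    def direction(self) -> str:
        if self.unmatched_patient and self.unmatched_donor:
            return "bidirectional"
        if self.unmatched_patient:
            return "GvH"
        if self.unmatched_donor:
            return "HvG"
        return "none"

    @property
    def is_mismatched(self) -> bool:
        return self.count > 0


def locus_mismatch(patient: LocusGenotype, donor: LocusGenotype) -> MismatchRecord:
    """Enumerate the mismatch at one locus of a patient-donor pair.

    The two possible pairings of the 2-element allele multisets are compared
    and the one sharing more alleles wins (maximum matching).  On ties the
    pairing aligning identical first fields is preferred, then the
    lexicographically ordered one, so unmatched-pair assignment is
    deterministic.
    """
    if patient.locus != donor.locus:
        raise GenotypeError(
            f"locus mismatch: patient {patient.locus} vs donor {donor.locus}"
        )
    p = patient.alleles
    d = donor.alleles

    def score(pairing: Sequence[tuple[Allele, Allele]]) -> tuple[int, int, tuple]:
        shared = sum(a == b for a, b in pairing)
        # tie-break 1: align identical first fields; tie-break 2: lexicographic
        first_field_hits = sum(
            a.field1 == b.field1 for a, b in pairing if a != b
        )
        sort_key = tuple((a.key, b.key) for a, b in pairing)
        return (-shared, -first_field_hits, sort_key)

    pairing_1 = ((p[0], d[0]), (p[1], d[1]))
    pairing_2 = ((p[0], d[1]), (p[1], d[0]))
    best = min((pairing_1, pairing_2), key=score)

    unpaired = tuple((a, b) for a, b in best if a != b)
    donor_set = set(d)
    patient_set = set(p)
    gvh = tuple(a for a, _ in unpaired if a not in donor_set)
    hvg = tuple(b for _, b in unpaired if b not in patient_set)
    return MismatchRecord(
        locus=patient.locus,
        count=len(unpaired),
        unmatched_patient=gvh,
        unmatched_donor=hvg,
        pairings=unpaired,
    )


def classify_resolution(record: MismatchRecord) -> str:
    """Resolution of a single mismatch: antigen-level matched or not.

    A single allelic mismatch whose two unshared alleles share their first
    field is *low-resolution matched* ("allelic-only"); otherwise the
    mismatch extends to the antigen level ("antigenic").

    Raises
    ------
    ValueError
        For matched records (``count == 0``) where resolution is undefined.
    """
    if record.count == 0:
        raise ValueError("resolution undefined for a matched locus")
    labels = pairing_resolutions(record)
    return labels[0] if record.count == 1 else ";".join(labels)


def pairing_resolutions(record: MismatchRecord) -> tuple[str, ...]:
    """Per-pairing resolution labels (``"allelic-only"`` / ``"antigenic"``)."""
    return tuple(
        "allelic-only" if a.field1 == b.field1 else "antigenic"
        for a, b in record.pairings
    )


@dataclass(frozen=True)
class MatchGrade:
    """x/10 and x/12 match grades of a pair with DPB1 status and class mix."""

    grade10: int
    grade12: int
    dpb1_status: str  # matched | single mismatch | double mismatch
    category: str  # 10/10 | 9/10 | 8/10 | <8/10
    mismatched_loci: tuple[str, ...]  # main loci, with multiplicity
    mismatch_class: str  # none | class I | class II | mixed


@dataclass(frozen=True)
class PairGenotype:
    """Six-locus genotypes of a patient-donor pair plus clinical metadata."""

    pair_id: str
    patient: dict[str, LocusGenotype]
    donor: dict[str, LocusGenotype]
    transplant_year: int
    months_dx_to_tx: Optional[float] = None
    ptcy: str = "missing"  # yes | no | missing

    def __post_init__(self) -> None:
        for role, genotypes in (("patient", self.patient), ("donor", self.donor)):
            missing = [loc for loc in SUPPORTED_LOCI if loc not in genotypes]
            if missing:
                raise GenotypeError(
                    f"pair {self.pair_id}: {role} missing loci {missing}"
                )

    def mismatches(self) -> dict[str, MismatchRecord]:
        return {
            locus: locus_mismatch(self.patient[locus], self.donor[locus])
            for locus in SUPPORTED_LOCI
        }


def match_grade(
    pair_or_records: Union[PairGenotype, dict[str, MismatchRecord]]
) -> MatchGrade:
    """Compute the x/10 and x/12 grades of a pair (or its mismatch records)."""
    if isinstance(pair_or_records, PairGenotype):
        records = pair_or_records.mismatches()
    else:
        records = pair_or_records
    main_counts = {loc: records[loc].count for loc in MAIN_LOCI}
    total_main = sum(main_counts.values())
    grade10 = 10 - total_main
    dpb1_count = records["DPB1"].count
    grade12 = grade10 + (2 - dpb1_count)
    if grade10 == 10:
        category = "10/10"
    elif grade10 == 9:
        category = "9/10"
    elif grade10 == 8:
        category = "8/10"
    else:
        category = "<8/10"
    dpb1_status = {0: "matched", 1: "single mismatch", 2: "double mismatch"}[
        dpb1_count
    ]
    mismatched = tuple(
        loc for loc in MAIN_LOCI for _ in range(main_counts[loc])
    )
    classes = {("I" if loc in CLASS_I_LOCI else "II") for loc in mismatched}
    if not classes:
        mm_class = "none"
    elif classes == {"I"}:
        mm_class = "class I"
    elif classes == {"II"}:
        mm_class = "class II"
    else:
        mm_class = "mixed"
    return MatchGrade(
        grade10=grade10,
        grade12=grade12,
        dpb1_status=dpb1_status,
        category=category,
        mismatched_loci=mismatched,
        mismatch_class=mm_class,
    )


def era_of(year: int) -> str:
    """Transplant era bucket of a calendar year.

    Buckets: ``pre-2011``, ``2011-2015``, ``2016-2020``, ``2021-2022``.
    Years after 2022 (the cohort's end) raise.
    """
    year = int(year)
    if year < 1950:
        raise ValueError(f"implausible transplant year {year}")
    if year < 2011:
        return "pre-2011"
    if year <= 2015:
        return "2011-2015"
    if year <= 2020:
        return "2016-2020"
    if year <= 2022:
        return "2021-2022"
    raise ValueError(f"transplant year {year} after the last era (2022)")


# ---------------------------------------------------------------------------
# Cohort TSV dialect
# ---------------------------------------------------------------------------

def cohort_columns() -> list[str]:
    """Column names of the cohort TSV dialect (one row per pair)."""
    cols = ["pair_id", "year", "months_dx_to_tx", "ptcy"]
    for role in ("patient", "donor"):
        for locus in SUPPORTED_LOCI:
            for i in (1, 2):
                cols.append(f"{role}_{locus}_{i}")
    return cols


@dataclass
class CohortLoadResult:
    """Pairs retained at load plus the audit trail of exclusions."""

    pairs: list[PairGenotype]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (pair_id, reason)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _parse_row(row: pd.Series) -> PairGenotype:
    genotypes: dict[str, dict[str, LocusGenotype]] = {"patient": {}, "donor": {}}
    for role in ("patient", "donor"):
        for locus in SUPPORTED_LOCI:
            a = row.get(f"{role}_{locus}_1")
            b = row.get(f"{role}_{locus}_2")
            if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
                raise GenotypeError(f"missing {role} typing at {locus}")
            geno = normalize_genotype(locus, str(a), str(b))
            if geno.allele_a.resolution < 2 or geno.allele_b.resolution < 2:
                raise GenotypeError(f"low-resolution {role} typing at {locus}")
            genotypes[role][locus] = geno
    months = row.get("months_dx_to_tx")
    months_val = None if pd.isna(months) else float(months)
    if months_val is not None and months_val < 0:
        raise GenotypeError("negative diagnosis-to-transplant time")
    ptcy = str(row.get("ptcy", "missing")).strip().lower()
    if ptcy not in {"yes", "no", "missing"}:
        ptcy = "missing"
    return PairGenotype(
        pair_id=str(row["pair_id"]),
        patient=genotypes["patient"],
        donor=genotypes["donor"],
        transplant_year=int(row["year"]),
        months_dx_to_tx=months_val,
        ptcy=ptcy,
    )


def read_cohort(
    source: Union[str, Path, pd.DataFrame], strict: bool = False
) -> CohortLoadResult:
    """Read a cohort TSV (or DataFrame) into :class:`PairGenotype` records.

    Rows with incomplete or low-resolution typing are excluded and recorded
    with a reason, mirroring the availability filter that defines registry
    cohorts; with ``strict=True`` the first bad row raises instead.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    pairs: list[PairGenotype] = []
    excluded: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        pid = str(row.get("pair_id", "?"))
        try:
            pairs.append(_parse_row(row))
        except (GenotypeError, ValueError) as exc:
            if strict:
                raise
            excluded.append((pid, str(exc)))
    return CohortLoadResult(pairs=pairs, excluded=excluded)


def write_cohort(pairs: Iterable[PairGenotype], path: Union[str, Path]) -> None:
    """Write pairs back out in the cohort TSV dialect."""
    rows = []
    for pair in pairs:
        row: dict[str, object] = {
            "pair_id": pair.pair_id,
            "year": pair.transplant_year,
            "months_dx_to_tx": (
                "" if pair.months_dx_to_tx is None else pair.months_dx_to_tx
            ),
            "ptcy": pair.ptcy,
        }
        for role_name, genos in (("patient", pair.patient), ("donor", pair.donor)):
            for locus in SUPPORTED_LOCI:
                g = genos[locus]
                row[f"{role_name}_{locus}_1"] = g.allele_a.name
                row[f"{role_name}_{locus}_2"] = g.allele_b.name
        rows.append(row)
    pd.DataFrame(rows, columns=cohort_columns()).to_csv(path, sep="\t", index=False)
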