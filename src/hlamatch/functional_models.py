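"""The seven functional matching models for allele-mismatched pairs.

Allelic identity is a conservative proxy for functional identity.  These
models grade how *functionally* different the mismatched allotypes are:

* **ARD matching** -- mismatched alleles in the same P-group encode the same
  antigen-recognition domain and are functionally equivalent.
* **PBM-GvH matching** (single class I / DRB1 mismatches) -- the patient's
  allotypes are peptide-binding-motif covered by the donor's, so the graft
  sees no novel motif in the GvH direction.
* **B-leader matching** (single HLA-B mismatches) -- the mismatched alleles
  carry the same -21 M/T leader residue.
* **TCE matching** (HLA-DPB1) -- the bidirectional T-cell epitope model:
  each subject's most immunogenic group is the minimum TCE group over their
  two alleles; equal minima = permissive, patient lower = non-permissive
  GvH, donor lower = non-permissive HvG.
* **Core/non-core TCE3** -- permissive mismatches subdivided by whether the
  mismatched TCE group-3 alleles are "core" (structurally homogeneous)
  alleles, with direction for the non-core ones.
* **Expression model** (single DPB1 mismatches with a GvH vector) -- risk
  stratification by the patient's mismatched allele being linked to the
  high- (rs9277534-G) or low- (A) expression 3'UTR haplotype.
* **TPHE** -- TCE-permissive and high-expression combined.

Unknown lookups always propagate to explicit NA/unknown verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import pandas as pd

from hlamatch.nomenclature import Allele, LocusGenotype, MAIN_LOCI, SUPPORTED_LOCI
from hlamatch.pair_matching import (
    MatchGrade,
    MismatchRecord,
    PairGenotype,
    classify_resolution,
    era_of,
    locus_mismatch,
    match_grade,
)
from hlamatch.reference_tables import (
    ModelTables,
    PGroupTable,
    UNKNOWN,
    lookup_model,
)

#: Stable TCE category vocabulary (directional model).
TCE_CATEGORIES: tuple[str, ...] = (
    "allele-matched",
    "core permissive",
    "non-core permissive HvG",
    "non-core permissive GvH",
    "other permissive",
    "non-permissive HvG",
    "non-permissive GvH",
    "unknown",
)

PERMISSIVE_CATEGORIES = frozenset(
    {
        "core permissive",
        "non-core permissive HvG",
        "non-core permissive GvH",
        "other permissive",
        "permissive",
    }
)


class ModelUsageError(ValueError):
    """Raised when a model is applied outside its domain of definition."""


def ard_match(record: MismatchRecord, table: PGroupTable) -> str:
    """ARD verdict of a mismatched main locus: ``matched``/``mismatched``.

    Matched iff every unshared allele pairing lies within one P-group.
    """
    if record.locus not in MAIN_LOCI:
        raise ModelUsageError(f"ARD matching not defined at {record.locus}")
    if record.count == 0:
        raise ModelUsageError("ARD matching requires a mismatched locus")
    return (
        "matched"
        if all(table.same_group(a, b) for a, b in record.pairings)
        else "mismatched"
    )


def pbm_gvh_match(
    patient: LocusGenotype, donor: LocusGenotype, tables: ModelTables
) -> str:
    """PBM verdict in the GvH direction: ``matched``/``mismatched``/``NA``.

    Defined for single mismatches at A, B, C or DRB1.  Matched iff every
    patient allotype's PBM group occurs among the donor's PBM groups, i.e.
    the graft encounters no motif it does not carry itself.  NA whenever any
    of the four allotypes lacks a PBM assignment.
    """
    if patient.locus not in {"A", "B", "C", "DRB1"}:
        raise ModelUsageError(f"PBM-GvH matching not defined at {patient.locus}")
    record = locus_mismatch(patient, donor)
    if record.count != 1:
        raise ModelUsageError("PBM-GvH matching requires a single mismatch")
    groups = {
        al: lookup_model(al, "pbm_group", tables)
        for al in (*patient.alleles, *donor.alleles)
    }
    if UNKNOWN in groups.values():
        return "NA"
    donor_groups = {groups[al] for al in donor.alleles}
    return (
        "matched"
        if all(groups[al] in donor_groups for al in patient.alleles)
        else "mismatched"
    )


def b_leader_classify(
    patient: LocusGenotype, donor: LocusGenotype, tables: ModelTables
) -> tuple[str, str]:
    """B-leader verdict and genotype string for a single HLA-B mismatch.

    Returns ``(verdict, genotype)`` where verdict is ``matched`` iff the two
    unshared alleles carry the same -21 residue, and genotype concatenates
    (shared-allele residue, patient mismatched residue, donor mismatched
    residue), e.g. ``"TTT"``.  ``("NA", "")`` when any residue is unknown.
    """
    if patient.locus != "B" or donor.locus != "B":
        raise ModelUsageError("B-leader matching is defined at HLA-B only")
    record = locus_mismatch(patient, donor)
    if record.count != 1:
        raise ModelUsageError("B-leader matching requires a single B mismatch")
    mm_patient, mm_donor = record.pairings[0]
    # the shared allele: the patient allele paired successfully with the donor
    shared_candidates = [al for al in patient.alleles if al != mm_patient]
    shared = shared_candidates[0] if shared_candidates else patient.alleles[0]
    residues = {
        "shared": lookup_model(shared, "leader", tables),
        "patient": lookup_model(mm_patient, "leader", tables),
        "donor": lookup_model(mm_donor, "leader", tables),
    }
    if UNKNOWN in residues.values():
        return "NA", ""
    genotype = residues["shared"] + residues["patient"] + residues["donor"]
    verdict = "matched" if residues["patient"] == residues["donor"] else "mismatched"
    return verdict, genotype


def _min_tce_group(genotype: LocusGenotype, tables: ModelTables) -> Optional[int]:
    groups = [lookup_model(al, "tce_group", tables) for al in genotype.alleles]
    if UNKNOWN in groups:
        return None
    return min(int(g) for g in groups)


def tce_classify(
    patient: LocusGenotype, donor: LocusGenotype, tables: ModelTables
) -> str:
    """Bidirectional TCE verdict for the DPB1 genotypes of a pair.

    ``allele-matched`` when the DPB1 genotypes carry no mismatch; otherwise
    each subject's most immunogenic group is ``m = min(TCE group)`` over
    their alleles and the verdict is ``permissive`` (equal minima),
    ``non-permissive GvH`` (patient's lower) or ``non-permissive HvG``
    (donor's lower); ``unknown`` when any allele lacks a TCE group.
    """
    if patient.locus != "DPB1" or donor.locus != "DPB1":
        raise ModelUsageError("TCE matching is defined at HLA-DPB1 only")
    record = locus_mismatch(patient, donor)
    if record.count == 0:
        return "allele-matched"
    m_patient = _min_tce_group(patient, tables)
    m_donor = _min_tce_group(donor, tables)
    if m_patient is None or m_donor is None:
        return "unknown"
    if m_patient == m_donor:
        return "permissive"
    return "non-permissive GvH" if m_patient < m_donor else "non-permissive HvG"


def tce_core_subclassify(
    patient: LocusGenotype, donor: LocusGenotype, tables: ModelTables
) -> str:
    """Subdivide a permissive DPB1 mismatch into core/non-core categories.

    Considering the unshared (mismatched) alleles on each side:

    * ``core permissive`` -- all mismatched alleles are core TCE3 alleles;
    * ``non-core permissive GvH`` -- the patient's mismatched alleles
      include a non-core TCE3 allele (the graft faces it) and the donor's
      do not;
    * ``non-core permissive HvG`` -- symmetric for the donor;
    * ``other permissive`` -- the residual: non-core alleles on both sides,
      or a permissive mismatch that is not TCE3-vs-TCE3;
    * ``unknown`` -- a mismatched TCE3 allele without core/non-core status.

    Raises
    ------
    ModelUsageError
        When the pair is not permissively mismatched.
    """
    verdict = tce_classify(patient, donor, tables)
    if verdict not in ("permissive",):
        raise ModelUsageError(
            f"core/non-core subclassification requires a permissive mismatch, "
            f"got {verdict!r}"
        )
    record = locus_mismatch(patient, donor)
    sides: dict[str, list[Allele]] = {
        "patient": [a for a, _ in record.pairings],
        "donor": [b for _, b in record.pairings],
    }
    all_tce3 = True
    core_status: dict[str, set[str]] = {"patient": set(), "donor": set()}
    for side, alleles in sides.items():
        for al in alleles:
            if lookup_model(al, "tce_group", tables) != "3":
                all_tce3 = False
                continue
            core_status[side].add(lookup_model(al, "core_tce3", tables))
    if not all_tce3:
        return "other permissive"
    if UNKNOWN in core_status["patient"] | core_status["donor"]:
        return "unknown"
    patient_noncore = "non-core" in core_status["patient"]
    donor_noncore = "non-core" in core_status["donor"]
    if not patient_noncore and not donor_noncore:
        return "core permissive"
    if patient_noncore and donor_noncore:
        return "other permissive"
    return "non-core permissive GvH" if patient_noncore else "non-core permissive HvG"


def expression_classify(
    patient: LocusGenotype, donor: LocusGenotype, tables: ModelTables
) -> str:
    """Expression-model verdict: ``high``/``low``/``NA``.

    Applicable to pairs with a single DPB1 mismatch possessing a GvH vector;
    the verdict is the rs9277534 expression linkage of the patient's
    mismatched (GvH) allele.  ``NA`` for allele-matched pairs, double
    mismatches, single mismatches without a GvH vector, or unknown linkage.
    """
    if patient.locus != "DPB1" or donor.locus != "DPB1":
        raise ModelUsageError("the expression model is defined at HLA-DPB1 only")
    record = locus_mismatch(patient, donor)
    if record.count != 1 or len(record.unmatched_patient) != 1:
        return "NA"
    verdict = lookup_model(record.unmatched_patient[0], "expression", tables)
    return "NA" if verdict == UNKNOWN else verdict


def tphe_classify(tce_verdict: str, expression_verdict: str) -> str:
    """Combine TCE and expression verdicts: ``TPHE``/``other``/``NA``.

    TPHE (TCE-permissive, high-expression) iff the TCE verdict is permissive
    (any permissive subcategory) and the expression verdict is high; ``NA``
    when either input is NA/unknown.
    """
    if tce_verdict in ("unknown",) or expression_verdict in ("NA", UNKNOWN):
        return "NA"
    if tce_verdict in PERMISSIVE_CATEGORIES and expression_verdict == "high":
        return "TPHE"
    return "other"


@dataclass(frozen=True)
class FunctionalAnnotation:
    """All model verdicts for one pair, plus grade and mismatch structure."""

    pair_id: str
    grade: MatchGrade
    records: dict[str, MismatchRecord]
    ard: dict[str, str]  # per mismatched main locus
    pbm_gvh: str  # matched | mismatched | NA | "" (not applicable)
    b_leader: str  # matched | mismatched | NA | ""
    b_leader_genotype: str
    tce: str  # one of TCE_CATEGORIES
    dpb1_expression: str  # high | low | NA
    tphe: str  # TPHE | other | NA


def annotate_pair(
    pair: PairGenotype, pgroups: PGroupTable, tables: ModelTables
) -> FunctionalAnnotation:
    """Apply every applicable functional model to one pair.

    Single-mismatch models (PBM-GvH, B-leader) are evaluated only on pairs
    whose sole mismatch over the five main loci sits at the relevant locus,
    mirroring how single-mismatch subsets are defined in registry analyses.
    """
    records = pair.mismatches()
    grade = match_grade(records)
    ard = {
        locus: ard_match(records[locus], pgroups)
        for locus in MAIN_LOCI
        if records[locus].count > 0
    }
    single_locus = (
        grade.mismatched_loci[0]
        if grade.grade10 == 9 and len(grade.mismatched_loci) == 1
        else None
    )
    pbm = ""
    if single_locus in {"A", "B", "C", "DRB1"}:
        pbm = pbm_gvh_match(
            pair.patient[single_locus], pair.donor[single_locus], tables
        )
        # P-group identity implies an identical antigen-recognition domain,
        # hence identical peptide-binding motifs: ARD match => PBM match.
        if ard.get(single_locus) == "matched":
            pbm = "matched"
    b_leader, b_genotype = "", ""
    if single_locus == "B":
        b_leader, b_genotype = b_leader_classify(
            pair.patient["B"], pair.donor["B"], tables
        )
    tce = tce_classify(pair.patient["DPB1"], pair.donor["DPB1"], tables)
    if tce == "permissive":
        tce = tce_core_subclassify(pair.patient["DPB1"], pair.donor["DPB1"], tables)
    expression = expression_classify(pair.patient["DPB1"], pair.donor["DPB1"], tables)
    tphe = tphe_classify(tce, expression)
    return FunctionalAnnotation(
        pair_id=pair.pair_id,
        grade=grade,
        records=records,
        ard=ard,
        pbm_gvh=pbm,
        b_leader=b_leader,
        b_leader_genotype=b_genotype,
        tce=tce,
        dpb1_expression=expression,
        tphe=tphe,
    )


def annotation_row(pair: PairGenotype, ann: FunctionalAnnotation) -> dict:
    """Flatten one pair's annotation into a table row."""
    records = ann.records
    grade = ann.grade
    single_locus = (
        grade.mismatched_loci[0]
        if grade.grade10 == 9 and len(grade.mismatched_loci) == 1
        else ""
    )
    lowres = ""
    if single_locus:
        lowres = (
            "low-res matched"
            if classify_resolution(records[single_locus]) == "allelic-only"
            else "low-res mismatched"
        )
    row: dict[str, object] = {
        "pair_id": pair.pair_id,
        "year": pair.transplant_year,
        "era": era_of(pair.transplant_year),
        "months_dx_to_tx": pair.months_dx_to_tx,
        "ptcy": pair.ptcy,
        "grade10": grade.grade10,
        "grade12": grade.grade12,
        "category": grade.category,
        "mismatch_class": grade.mismatch_class,
        "dpb1_status": grade.dpb1_status,
        "single_mm_locus": single_locus,
        "resolution": lowres,
        "ard": ann.ard.get(single_locus, "") if single_locus else "",
        "pbm_gvh": ann.pbm_gvh,
        "b_leader": ann.b_leader,
        "b_leader_genotype": ann.b_leader_genotype,
        "tce": ann.tce,
        "dpb1_expression": ann.dpb1_expression,
        "tphe": ann.tphe,
    }
    for locus in SUPPORTED_LOCI:
        rec = records[locus]
        row[f"mm_{locus}"] = rec.count
        row[f"dir_{locus}"] = rec.direction
        row[f"mm_{locus}_patient"] = "/".join(a.name for a in rec.unmatched_patient)
        row[f"mm_{locus}_donor"] = "/".join(a.name for a in rec.unmatched_donor)
        # unmatched allele pairings, patient>donor, for landscape tables
        row[f"mm_{locus}_pairings"] = ";".join(
            f"{a.name}>{b.name}" for a, b in rec.pairings
        )
    return row


def annotate_cohort(
    pairs: Iterable[PairGenotype], pgroups: PGroupTable, tables: ModelTables
) -> pd.DataFrame:
    """Annotate every pair and return the per-pair annotation table."""
    rows = [annotation_row(p, annotate_pair(p, pgroups, tables)) for p in pairs]
    return pd.DataFrame(rows)
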