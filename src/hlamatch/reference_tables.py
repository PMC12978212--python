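"""Reference lookup tables behind the functional matching models.

Five kinds of curated immunogenetic knowledge are served here:

* **P-groups** -- IPD-IMGT/HLA groups of alleles encoding an identical
  protein sequence over the antigen-recognition domain (exons 2+3 for class
  I, exon 2 for class II).  Loaded from a file in the ``hla_nom_p.txt``
  dialect, so the genuine IPD-IMGT/HLA release file can be dropped in.
* **TCE groups** -- HLA-DPB1 T-cell epitope groups 1-3 (1 = most
  immunogenic) underlying the permissive/non-permissive mismatch model.
* **Core TCE3** -- the subset of structurally similar TCE group-3 alleles
  ("core") versus the remaining ("non-core") TCE3 alleles.
* **Expression linkage** -- high versus low HLA-DPB1 expression predicted
  from linkage with the 3'UTR rs9277534 G/A polymorphism (G -> high,
  A -> low).
* **B-leader residues** -- the methionine/threonine dimorphism at position
  -21 of the HLA-B leader peptide.
* **PBM groups** -- peptide-binding-motif clusters of class I and DRB1
  allotypes with overlapping immunopeptidomes.

The packaged tables are a curated subset of the published assignments,
covering the alleles used by the synthetic cohorts and the test suite; every
loader accepts a path so users can substitute complete tables.  An allele
absent from a model table yields ``"unknown"``, which downstream classifiers
propagate to an explicit NA category -- lookups never silently default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

from hlamatch.nomenclature import (
    Allele,
    SUPPORTED_LOCI,
    parse_allele,
)

UNKNOWN = "unknown"

#: model name -> loci it applies to
MODEL_LOCI: Mapping[str, frozenset[str]] = {
    "tce_group": frozenset({"DPB1"}),
    "core_tce3": frozenset({"DPB1"}),
    "expression": frozenset({"DPB1"}),
    "leader": frozenset({"B"}),
    "pbm_group": frozenset({"A", "B", "C", "DRB1"}),
}


class ReferenceTableError(ValueError):
    """Raised on malformed reference-table input."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hlamatch").joinpath("data", name)))


@dataclass(frozen=True)
class PGroupTable:
    """Mapping from two-field allele to its P-group identifier.

    Group identifiers are locus-qualified (``"DRB1*14:01P"``).  Alleles not
    listed in any group are their own singleton group: ``p_group_of`` then
    returns the allele's own two-field name, so the mapping is total.
    """

    groups: Mapping[tuple[str, int, int], str] = field(default_factory=dict)
    source: str = ""

    def group_of(self, allele: Allele) -> str:
        return self.groups.get(allele.key, allele.name)

    def same_group(self, a: Allele, b: Allele) -> bool:
        return self.group_of(a) == self.group_of(b)

    def __len__(self) -> int:
        return len(self.groups)


def load_p_groups(source: Union[str, Path, None] = None) -> PGroupTable:
    """Load a P-group table from a file in the ``hla_nom_p.txt`` dialect.

    Each data line reads ``LOCUS*;allele[/allele...];[GROUP]`` where allele
    names omit the locus prefix and may carry 1-4 fields plus an expression
    suffix; lines starting with ``#`` are comments.  An empty third field
    marks a singleton allele (its own group).  Names are reduced to two
    fields; loci other than the six supported ones are skipped.

    With no argument, the curated table shipped with the package is loaded.
    """
    path = _data_path("p_groups.curated.txt") if source is None else Path(source)
    groups: dict[tuple[str, int, int], str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(";")
            if len(parts) != 3 or not parts[0].endswith("*"):
                raise ReferenceTableError(
                    f"{path.name}:{lineno}: malformed hla_nom_p line {line!r}"
                )
            locus = parts[0][:-1].upper()
            if locus not in SUPPORTED_LOCI:
                continue
            group_name = parts[2].strip()
            try:
                alleles = [
                    parse_allele(f"{locus}*{tok}") for tok in parts[1].split("/") if tok
                ]
            except ValueError as exc:
                raise ReferenceTableError(f"{path.name}:{lineno}: {exc}") from exc
            if not alleles:
                raise ReferenceTableError(
                    f"{path.name}:{lineno}: no alleles in {line!r}"
                )
            if not group_name:
                # singleton: allele maps to itself (leave unlisted)
                continue
            qualified = f"{locus}*{group_name}"
            for al in alleles:
                if al.resolution < 2:
                    raise ReferenceTableError(
                        f"{path.name}:{lineno}: one-field allele {al.raw!r}"
                    )
                prev = groups.get(al.key)
                if prev is not None and prev != qualified:
                    raise ReferenceTableError(
                        f"{path.name}:{lineno}: {al.name} assigned to both "
                        f"{prev} and {qualified}"
                    )
                groups[al.key] = qualified
    return PGroupTable(groups=groups, source=str(path))


def p_group_of(allele: Allele, table: PGroupTable) -> str:
    """P-group identifier of ``allele``; its own name when unlisted."""
    return table.group_of(allele)


@dataclass(frozen=True)
class ModelTables:
    """The five functional-model lookup tables, keyed by two-field allele."""

    tce_group: Mapping[tuple[str, int, int], str] = field(default_factory=dict)
    core_tce3: Mapping[tuple[str, int, int], str] = field(default_factory=dict)
    expression: Mapping[tuple[str, int, int], str] = field(default_factory=dict)
    leader: Mapping[tuple[str, int, int], str] = field(default_factory=dict)
    pbm_group: Mapping[tuple[str, int, int], str] = field(default_factory=dict)

    def _table(self, model: str) -> Mapping[tuple[str, int, int], str]:
        try:
            return getattr(self, model)
        except AttributeError:
            raise ReferenceTableError(f"unknown model {model!r}") from None


_MODEL_FILES = {
    "tce_group": "dpb1_tce_groups.tsv",
    "core_tce3": "dpb1_core_tce3.tsv",
    "expression": "dpb1_expression.tsv",
    "leader": "b_leader.tsv",
    "pbm_group": "pbm_groups.tsv",
}

_MODEL_VERDICTS = {
    "tce_group": {"1", "2", "3"},
    "core_tce3": {"core", "non-core"},
    "expression": {"high", "low"},
    "leader": {"M", "T"},
    "pbm_group": None,  # free-form group ids
}


def _load_model_file(model: str, path: Path) -> dict[tuple[str, int, int], str]:
    allowed = _MODEL_VERDICTS[model]
    loci = MODEL_LOCI[model]
    out: dict[tuple[str, int, int], str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("allele\t"):
                continue
            try:
                allele_txt, verdict = line.split("\t")
            except ValueError:
                raise ReferenceTableError(
                    f"{path.name}:{lineno}: expected two tab-separated columns"
                ) from None
            allele = parse_allele(allele_txt)
            if allele.locus not in loci:
                raise ReferenceTableError(
                    f"{path.name}:{lineno}: locus {allele.locus} invalid for "
                    f"model {model}"
                )
            verdict = verdict.strip()
            if allowed is not None and verdict not in allowed:
                raise ReferenceTableError(
                    f"{path.name}:{lineno}: verdict {verdict!r} invalid for "
                    f"model {model}"
                )
            out[allele.key] = verdict
    return out


def load_model_tables(directory: Union[str, Path, None] = None) -> ModelTables:
    """Load the five model tables from TSV files (columns: allele, verdict).

    With no argument the curated tables shipped with the package are used.
    A directory must contain ``dpb1_tce_groups.tsv``, ``dpb1_core_tce3.tsv``,
    ``dpb1_expression.tsv``, ``b_leader.tsv`` and ``pbm_groups.tsv``.
    """
    loaded = {}
    for model, fname in _MODEL_FILES.items():
        path = _data_path(fname) if directory is None else Path(directory) / fname
        loaded[model] = _load_model_file(model, path)
    tables = ModelTables(**loaded)
    # core-TCE3 status only makes sense for TCE group-3 alleles
    for key in tables.core_tce3:
        if tables.tce_group.get(key) != "3":
            raise ReferenceTableError(
                f"core_tce3 lists {key} which is not TCE group 3"
            )
    return tables


def lookup_model(allele: Allele, model: str, tables: ModelTables) -> str:
    """Look up ``allele`` in one model table; ``"unknown"`` when absent.

    Raises
    ------
    ReferenceTableError
        When the model name is unknown or the allele's locus is outside the
        model's domain (e.g. leader lookup on a DRB1 allele).
    """
    if model not in MODEL_LOCI:
        raise ReferenceTableError(f"unknown model {model!r}")
    if allele.locus not in MODEL_LOCI[model]:
        raise ReferenceTableError(
            f"model {model!r} does not apply to locus {allele.locus}"
        )
    return tables._table(model).get(allele.key, UNKNOWN)
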