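"""Shared fixtures: reference tables and pair-construction helpers."""

from __future__ import annotations

import pytest

from hlamatch import (
    PairGenotype,
    load_model_tables,
    load_p_groups,
    normalize_genotype,
)
from hlamatch.nomenclature import SUPPORTED_LOCI

# identical patient/donor background so tests can mismatch one locus at a time
BACKGROUND = {
    "A": ("A*01:01", "A*01:01"),
    "B": ("B*08:01", "B*08:01"),
    "C": ("C*07:01", "C*07:01"),
    "DRB1": ("DRB1*03:01", "DRB1*03:01"),
    "DQB1": ("DQB1*02:01", "DQB1*02:01"),
    "DPB1": ("DPB1*04:01", "DPB1*04:01"),
}


@pytest.fixture(scope="session")
def pgroups():
    return load_p_groups()


@pytest.fixture(scope="session")
def tables():
    return load_model_tables()


def make_pair(
    patient: dict[str, tuple[str, str]] | None = None,
    donor: dict[str, tuple[str, str]] | None = None,
    pair_id: str = "pair1",
    year: int = 2018,
    months: float | None = 8.0,
    ptcy: str = "no",
) -> PairGenotype:
    """Build a six-locus pair from per-locus overrides over a matched background."""
    patient = {**BACKGROUND, **(patient or {})}
    donor = {**BACKGROUND, **(donor or {})}
    return PairGenotype(
        pair_id=pair_id,
        patient={
            loc: normalize_genotype(loc, *patient[loc]) for loc in SUPPORTED_LOCI
        },
        donor={loc: normalize_genotype(loc, *donor[loc]) for loc in SUPPORTED_LOCI},
        transplant_year=year,
        months_dx_to_tx=months,
        ptcy=ptcy,
    )


@pytest.fixture
def pair_factory():
    return make_pair
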