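"""Cohort-level frequency analytics and summary tables.

Builds, from a per-pair annotation table, the quantities registry analyses
report: direct-counting allele frequencies, mismatch-combination landscapes
(the chord-diagram data of which allele faced which), representation ratios
of alleles among mismatches versus the cohort, era-stratified matching
proportions, and the functional-model summary tables.

Percentages follow the registry-table convention: half-up rounding to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from hlamatch.nomenclature import CLASS_I_LOCI, MAIN_LOCI, SUPPORTED_LOCI
from hlamatch.pair_matching import CATEGORIES, ERAS, PairGenotype
from hlamatch.functional_models import TCE_CATEGORIES


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quant, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage with half-up rounding; NaN on a zero denominator."""
    if not denominator:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# Allele frequencies and representation ratios
# ---------------------------------------------------------------------------

def allele_frequencies(
    pairs: Iterable[PairGenotype], role: str, locus: str
) -> pd.DataFrame:
    """Direct-counting allele frequencies at one locus for one role.

    Each subject contributes two chromosomes (homozygotes count twice).
    Returns a DataFrame indexed by allele name with ``count`` and ``freq``
    columns, sorted by descending frequency.
    """
    if role not in {"patient", "donor"}:
        raise ValueError(f"role must be 'patient' or 'donor', got {role!r}")
    counts: dict[str, int] = {}
    for pair in pairs:
        genotype = getattr(pair, role)[locus]
        for allele in genotype.alleles:
            counts[allele.name] = counts.get(allele.name, 0) + 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {"count": pd.Series(counts, dtype=int)}
    ).sort_values("count", ascending=False)
    df["freq"] = df["count"] / total if total else np.nan
    df.index.name = "allele"
    return df


def representation_ratio(
    locus: str, allele_name: str, pairs: Sequence[PairGenotype]
) -> float:
    """Frequency of an allele among mismatched alleles over its cohort frequency.

    The numerator counts the allele among the unshared alleles (both sides
    of every unmatched pairing) of pairs mismatched at ``locus``; the
    denominator is its direct-counting frequency over all patient and donor
    chromosomes.  Values below 1 mean the allele is underrepresented among
    mismatches -- the signature of donor-selection pressure on common
    alleles.

    Raises
    ------
    ValueError
        If the allele does not occur in the cohort at all.
    """
    from hlamatch.pair_matching import locus_mismatch

    cohort_count = 0
    cohort_total = 0
    mm_count = 0
    mm_total = 0
    for pair in pairs:
        for genos in (pair.patient, pair.donor):
            for al in genos[locus].alleles:
                cohort_total += 1
                if al.name == allele_name:
                    cohort_count += 1
        record = locus_mismatch(pair.patient[locus], pair.donor[locus])
        for a, b in record.pairings:
            for al in (a, b):
                mm_total += 1
                if al.name == allele_name:
                    mm_count += 1
    if cohort_count == 0:
        raise ValueError(f"{allele_name} absent from the cohort at {locus}")
    cohort_freq = cohort_count / cohort_total
    mm_freq = (mm_count / mm_total) if mm_total else 0.0
    return mm_freq / cohort_freq


# ---------------------------------------------------------------------------
# Mismatch combination landscapes
# ---------------------------------------------------------------------------

@dataclass
class CombinationTable:
    """Ordered (donor allele, patient allele) mismatch combination counts.

    ``denominator`` is the number of single-mismatch pairs contributing, so
    frequencies sum to 1 over the entries.
    """

    locus: str
    stratum: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def denominator(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus": self.locus,
                "stratum": self.stratum,
                "donor_allele": d,
                "patient_allele": p,
                "count": c,
                "freq": c / self.denominator if self.denominator else np.nan,
            }
            for (d, p), c in sorted(
                self.counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "locus",
                "stratum",
                "donor_allele",
                "patient_allele",
                "count",
                "freq",
            ],
        )

    def top_k(self, k: int) -> pd.DataFrame:
        return self.to_frame().head(k)

    def unordered(self) -> dict[frozenset, int]:
        """Direction-free view: (donor, patient) merged with its reverse."""
        merged: dict[frozenset, int] = {}
        for (d, p), c in self.counts.items():
            key = frozenset((d, p))
            merged[key] = merged.get(key, 0) + c
        return merged

    def combination_share(self, combinations: Iterable[tuple[str, str]]) -> float:
        """Summed frequency of the given combinations, either direction."""
        merged = self.unordered()
        wanted = {frozenset(c) for c in combinations}
        total = sum(c for key, c in merged.items() if key in wanted)
        return total / self.denominator if self.denominator else float("nan")

    def entropy(self) -> float:
        """Shannon entropy (nats) of the combination frequency distribution."""
        n = self.denominator
        if not n:
            return float("nan")
        freqs = np.array([c / n for c in self.counts.values()])
        return float(-(freqs * np.log(freqs)).sum())


def mismatch_combination_table(
    annotations: pd.DataFrame, locus: str, stratum: Optional[str] = None
) -> CombinationTable:
    """Tabulate single-mismatch (donor, patient) allele combinations.

    For the five main loci the contributing pairs are those whose *sole*
    mismatch over the main loci sits at ``locus`` (9/10 single-mismatch
    pairs).  For DPB1 the pairs are single DPB1 mismatches within a grade
    stratum (``"10/10"`` or ``"9/10"``), matching how DPB1 landscapes are
    stratified.
    """
    df = annotations
    if locus == "DPB1":
        if stratum not in {"10/10", "9/10"}:
            raise ValueError("DPB1 landscapes require stratum '10/10' or '9/10'")
        mask = (df["category"] == stratum) & (df["mm_DPB1"] == 1)
    else:
        if locus not in MAIN_LOCI:
            raise ValueError(f"unknown landscape locus {locus!r}")
        mask = df["single_mm_locus"] == locus
        if stratum is not None:
            mask &= df["category"] == stratum
    counts: dict[tuple[str, str], int] = {}
    for pairing_str in df.loc[mask, f"mm_{locus}_pairings"]:
        if not isinstance(pairing_str, str) or not pairing_str:
            continue
        first = pairing_str.split(";")[0]
        patient_allele, donor_allele = first.split(">")
        key = (donor_allele, patient_allele)
        counts[key] = counts.get(key, 0) + 1
    return CombinationTable(
        locus=locus, stratum=stratum or "9/10", counts=counts
    )


# ---------------------------------------------------------------------------
# Rate aggregation (class- and cohort-level rates from locus-level rates)
# ---------------------------------------------------------------------------

def aggregate_rates(
    rates: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Count-weighted average of locus-level rates.

    This is the computation behind class-level and overall figures: a class
    rate equals the weighted mean of its locus rates with the locus
    mismatch counts as weights.
    """
    keys = [k for k in rates if k in weights and weights[k]]
    total_weight = sum(weights[k] for k in keys)
    if not total_weight:
        return float("nan")
    return sum(rates[k] * weights[k] for k in keys) / total_weight


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """All cohort-level summary tables derived from an annotation table."""

    n_pairs: int
    matching: Optional[pd.DataFrame] = None  # category counts + pct
    era_matching: Optional[pd.DataFrame] = None  # era x matching proportions
    pbm_table: Optional[pd.DataFrame] = None  # locus x PBM verdict
    tce_table: Optional[pd.DataFrame] = None  # TCE category x grade category
    tce_cohort: Optional[pd.Series] = None  # whole-cohort TCE splits
    lowres: Optional[pd.DataFrame] = None  # low-resolution rates
    ard: Optional[pd.DataFrame] = None  # ARD match rates
    dpb1: Optional[pd.DataFrame] = None  # DPB1 mismatch burden by stratum
    b_leader: Optional[pd.Series] = None
    directions: Optional[pd.DataFrame] = None  # bidirectional fractions
    eight_of_ten: Optional[pd.Series] = None
    expression: Optional[pd.Series] = None

    def tables(self) -> dict[str, Union[pd.DataFrame, pd.Series]]:
        out = {}
        for name in (
            "matching",
            "era_matching",
            "pbm_table",
            "tce_table",
            "tce_cohort",
            "lowres",
            "ard",
            "dpb1",
            "b_leader",
            "directions",
            "eight_of_ten",
            "expression",
        ):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out


def _has(df: pd.DataFrame, *cols: str) -> bool:
    return all(c in df.columns for c in cols)


def summarize_cohort(annotations: pd.DataFrame) -> CohortSummary:
    """Compute every summary table the annotation columns support.

    Blocks whose input columns are absent are skipped (left ``None``), so
    partially annotated tables -- e.g. category counts only -- can still be
    summarised.
    """
    df = annotations
    n = len(df)
    summary = CohortSummary(n_pairs=n)
    if n == 0:
        return summary

    if _has(df, "category"):
        counts = df["category"].value_counts()
        summary.matching = pd.DataFrame(
            {
                "count": [int(counts.get(c, 0)) for c in CATEGORIES],
                "pct": [pct(counts.get(c, 0), n) for c in CATEGORIES],
            },
            index=pd.Index(CATEGORIES, name="category"),
        )

    if _has(df, "category", "era", "grade12", "mm_DPB1", "mismatch_class"):
        rows = []
        for era in ERAS:
            sub = df[df["era"] == era]
            n_era = len(sub)
            ten = sub["category"] == "10/10"
            rows.append(
                {
                    "era": era,
                    "n": n_era,
                    "pct_10of10": pct((ten).sum(), n_era),
                    "pct_12of12": pct((sub["grade12"] == 12).sum(), n_era),
                    "pct_dpb1_matched": pct((sub["mm_DPB1"] == 0).sum(), n_era),
                    "pct_dpb1_matched_in_10of10": pct(
                        (ten & (sub["mm_DPB1"] == 0)).sum(), ten.sum()
                    ),
                    "pct_9of10_classI": pct(
                        (
                            (sub["category"] == "9/10")
                            & (sub["mismatch_class"] == "class I")
                        ).sum(),
                        n_era,
                    ),
                    "pct_9of10_classII": pct(
                        (
                            (sub["category"] == "9/10")
                            & (sub["mismatch_class"] == "class II")
                        ).sum(),
                        n_era,
                    ),
                }
            )
        summary.era_matching = pd.DataFrame(rows).set_index("era")

    if _has(df, "single_mm_locus", "pbm_gvh"):
        rows = []
        for locus in ("A", "B", "C", "DRB1"):
            sub = df[df["single_mm_locus"] == locus]
            n_loc = len(sub)
            for verdict in ("matched", "mismatched", "NA"):
                c = (sub["pbm_gvh"] == verdict).sum()
                rows.append(
                    {
                        "locus": locus,
                        "verdict": verdict,
                        "count": int(c),
                        "pct": pct(c, n_loc),
                    }
                )
        summary.pbm_table = pd.DataFrame(rows)

    if _has(df, "category", "tce"):
        rows = []
        for cat in TCE_CATEGORIES:
            row: dict[str, object] = {"tce": cat}
            for grade_cat in CATEGORIES:
                sub = df[df["category"] == grade_cat]
                c = (sub["tce"] == cat).sum()
                row[f"n_{grade_cat}"] = int(c)
                row[f"pct_{grade_cat}"] = pct(c, len(sub))
            rows.append(row)
        summary.tce_table = pd.DataFrame(rows).set_index("tce")

        tce = df["tce"]
        permissive = tce.isin(
            {
                "core permissive",
                "non-core permissive HvG",
                "non-core permissive GvH",
                "other permissive",
            }
        )
        nonperm = tce.isin({"non-permissive HvG", "non-permissive GvH"})
        core = (tce == "core permissive").sum()
        noncore = tce.isin(
            {"non-core permissive HvG", "non-core permissive GvH"}
        ).sum()
        summary.tce_cohort = pd.Series(
            {
                "pct_allele_matched": pct((tce == "allele-matched").sum(), n),
                "pct_permissive": pct(permissive.sum(), n),
                "pct_non_permissive": pct(nonperm.sum(), n),
                "pct_unknown": pct((tce == "unknown").sum(), n),
                "pct_core_of_directional_permissive": pct(core, core + noncore),
                "pct_noncore_gvh_of_cohort": pct(
                    (tce == "non-core permissive GvH").sum(), n
                ),
            }
        )

    if _has(df, "single_mm_locus", "resolution"):
        summary.lowres = _single_mm_rate_table(
            df, "resolution", "low-res matched", "pct_lowres_matched"
        )

    if _has(df, "single_mm_locus", "ard"):
        summary.ard = _single_mm_rate_table(df, "ard", "matched", "pct_ard_matched")

    if _has(df, "category", "dpb1_status"):
        rows = []
        for grade_cat in ("10/10", "9/10"):
            sub = df[df["category"] == grade_cat]
            n_cat = len(sub)
            rows.append(
                {
                    "stratum": grade_cat,
                    "n": n_cat,
                    "pct_matched": pct((sub["dpb1_status"] == "matched").sum(), n_cat),
                    "pct_single": pct(
                        (sub["dpb1_status"] == "single mismatch").sum(), n_cat
                    ),
                    "pct_double": pct(
                        (sub["dpb1_status"] == "double mismatch").sum(), n_cat
                    ),
                }
            )
        summary.dpb1 = pd.DataFrame(rows).set_index("stratum")

    if _has(df, "b_leader", "b_leader_genotype"):
        sub = df[df["b_leader"].isin(["matched", "mismatched"])]
        n_b = len(sub)
        genotype_counts = sub["b_leader_genotype"].value_counts()
        data = {
            "n_single_B_mismatch": n_b,
            "pct_leader_mismatched": pct((sub["b_leader"] == "mismatched").sum(), n_b),
        }
        for genotype, c in genotype_counts.items():
            data[f"pct_genotype_{genotype}"] = pct(c, n_b)
        summary.b_leader = pd.Series(data)

    if _has(df, "single_mm_locus", *(f"dir_{l}" for l in MAIN_LOCI)):
        rows = []
        for locus in MAIN_LOCI:
            sub = df[df["single_mm_locus"] == locus]
            rows.append(
                {
                    "locus": locus,
                    "n": len(sub),
                    "pct_bidirectional": pct(
                        (sub[f"dir_{locus}"] == "bidirectional").sum(), len(sub)
                    ),
                }
            )
        summary.directions = pd.DataFrame(rows).set_index("locus")

    if _has(df, "category", *(f"mm_{l}" for l in MAIN_LOCI)):
        sub = df[df["category"] == "8/10"]
        if len(sub):
            mm = sub[[f"mm_{l}" for l in MAIN_LOCI]]
            n_loci_hit = (mm > 0).sum(axis=1)
            two_loci = (n_loci_hit == 2).sum()
            one_locus_double = (n_loci_hit == 1).sum()
            summary.eight_of_ten = pd.Series(
                {
                    "n": len(sub),
                    "pct_two_loci": pct(two_loci, len(sub)),
                    "pct_single_locus_double": pct(one_locus_double, len(sub)),
                    "pct_classI_only": pct(
                        (sub["mismatch_class"] == "class I").sum(), len(sub)
                    )
                    if "mismatch_class" in sub
                    else float("nan"),
                    "pct_classII_only": pct(
                        (sub["mismatch_class"] == "class II").sum(), len(sub)
                    )
                    if "mismatch_class" in sub
                    else float("nan"),
                    "pct_mixed": pct((sub["mismatch_class"] == "mixed").sum(), len(sub))
                    if "mismatch_class" in sub
                    else float("nan"),
                }
            )

    if _has(df, "dpb1_expression"):
        applicable = df["dpb1_expression"].isin(["high", "low"])
        summary.expression = pd.Series(
            {
                "n_applicable": int(applicable.sum()),
                "pct_applicable": pct(applicable.sum(), n),
                "n_high": int((df["dpb1_expression"] == "high").sum()),
                "n_low": int((df["dpb1_expression"] == "low").sum()),
            }
        )

    return summary


def _single_mm_rate_table(
    df: pd.DataFrame, column: str, positive: str, rate_name: str
) -> pd.DataFrame:
    """Per-locus, per-class and overall rate of ``column == positive`` among
    9/10 single-mismatch pairs."""
    rows = []
    locus_rates: dict[str, float] = {}
    locus_ns: dict[str, int] = {}
    for locus in MAIN_LOCI:
        sub = df[df["single_mm_locus"] == locus]
        n_loc = len(sub)
        c = (sub[column] == positive).sum()
        raw_rate = 100.0 * c / n_loc if n_loc else float("nan")
        locus_rates[locus] = raw_rate
        locus_ns[locus] = n_loc
        rows.append(
            {"group": locus, "n": n_loc, rate_name: pct(c, n_loc)}
        )
    class_i = [l for l in MAIN_LOCI if l in CLASS_I_LOCI]
    class_ii = [l for l in MAIN_LOCI if l not in CLASS_I_LOCI]
    for label, loci in (("class I", class_i), ("class II", class_ii), ("all", list(MAIN_LOCI))):
        agg = aggregate_rates(
            {l: locus_rates[l] for l in loci if locus_ns[l]},
            {l: locus_ns[l] for l in loci},
        )
        rows.append(
            {
                "group": label,
                "n": sum(locus_ns[l] for l in loci),
                rate_name: round_half_up(agg, 1) if not np.isnan(agg) else agg,
            }
        )
    return pd.DataFrame(rows).set_index("group")
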