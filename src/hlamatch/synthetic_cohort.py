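"""Registry-like synthetic cohort generation.

Real registry cohorts are shaped by three forces: the allele frequencies at
each locus, the linkage disequilibrium (LD) between loci -- genotypes are
drawn as whole haplotypes, not independent alleles -- and donor-selection
pressure, which preferentially pairs patients with their best available
match and thereby depletes common alleles from the mismatch landscape.

The generator emulates all three: patients are two haplotypes drawn from a
frequency-weighted pool (Hardy-Weinberg at the haplotype level), the donor
is chosen among a simulated registry search of independently drawn
genotypes according to a selection policy, transplant year follows
configurable era weights, PTCy adoption rises by era, and
diagnosis-to-transplant time is log-normal with a median that depends on
matching status and era (mismatched pairs wait longer, with the gap
narrowing in recent eras).

All randomness flows from a single seeded generator, so a fixed seed yields
a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from hlamatch.nomenclature import MAIN_LOCI, SUPPORTED_LOCI
from hlamatch.pair_matching import ERAS, cohort_columns

_ERA_YEARS = {
    "pre-2011": (2003, 2010),
    "2011-2015": (2011, 2015),
    "2016-2020": (2016, 2020),
    "2021-2022": (2021, 2022),
}


@dataclass(frozen=True)
class HaplotypePool:
    """Six-locus haplotypes with frequencies.

    ``haplotypes`` maps each haplotype to one allele name per locus.  With
    ``marginal_mode=True`` the LD structure is discarded: each locus is
    sampled independently from its marginal allele distribution (the null
    model for LD-driven effects).
    """

    name: str
    haplotypes: tuple[Mapping[str, str], ...]
    frequencies: tuple[float, ...]
    marginal_mode: bool = False

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        if not self.haplotypes:
            raise ValueError("empty haplotype pool")
        freqs = np.asarray(self.frequencies, dtype=float)
        if (freqs <= 0).any():
            raise ValueError("haplotype frequencies must be positive")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {freqs.sum()}, not 1")
        for hap in self.haplotypes:
            missing = [l for l in SUPPORTED_LOCI if l not in hap]
            if missing:
                raise ValueError(f"haplotype missing loci {missing}")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def alleles_at(self, locus: str) -> list[str]:
        return [hap[locus] for hap in self.haplotypes]

    def marginal(self, locus: str) -> dict[str, float]:
        """Marginal allele frequency distribution at one locus."""
        out: dict[str, float] = {}
        for hap, f in zip(self.haplotypes, self.frequencies):
            out[hap[locus]] = out.get(hap[locus], 0.0) + f
        return out

    def without_ld(self) -> "HaplotypePool":
        return replace(self, marginal_mode=True, name=f"{self.name}-marginal")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated cohort.

    ``time_medians`` maps (status, era) -> median months from diagnosis to
    transplant, status being ``"10/10"`` or ``"<10/10"``; times are drawn
    log-normally around that median with shape ``time_sigma``.
    """

    pool: HaplotypePool
    # a deep default search emulates real registries, where most patients
    # find a 10/10 donor (about three quarters of transplants)
    registry_size: int = 200
    # recombination hotspot between HLA-DQ and HLA-DP: per transmitted
    # chromosome, the DPB1 allele is decoupled from the extended haplotype
    # and redrawn from the locus marginal with this probability; this is why
    # most otherwise 10/10-matched real pairs are DPB1 mismatched
    dpb1_recombination: float = 0.8
    selection: str = "best-grade"  # best-grade | random | grade-threshold
    grade_threshold: int = 9
    era_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "pre-2011": 0.09,
            "2011-2015": 0.18,
            "2016-2020": 0.49,
            "2021-2022": 0.24,
        }
    )
    ptcy_rate_by_era: Mapping[str, float] = field(
        default_factory=lambda: {
            "pre-2011": 0.0,
            "2011-2015": 0.03,
            "2016-2020": 0.12,
            "2021-2022": 0.25,
        }
    )
    time_medians: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("10/10", "pre-2011"): 11.3,
            ("<10/10", "pre-2011"): 14.9,
            ("10/10", "2011-2015"): 9.8,
            ("<10/10", "2011-2015"): 12.0,
            ("10/10", "2016-2020"): 8.0,
            ("<10/10", "2016-2020"): 9.2,
            ("10/10", "2021-2022"): 7.4,
            ("<10/10", "2021-2022"): 8.1,
        }
    )
    time_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection not in {"best-grade", "random", "grade-threshold"}:
            raise ValueError(f"unknown selection policy {self.selection!r}")
        if self.registry_size < 1:
            raise ValueError("registry_size must be >= 1")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            "pool": {
                "name": self.pool.name,
                "marginal_mode": self.pool.marginal_mode,
                "haplotypes": [
                    {"frequency": float(f), **{l: h[l] for l in SUPPORTED_LOCI}}
                    for h, f in zip(self.pool.haplotypes, self.pool.frequencies)
                ],
            },
            "registry_size": self.registry_size,
            "selection": self.selection,
            "grade_threshold": self.grade_threshold,
            "era_weights": dict(self.era_weights),
            "ptcy_rate_by_era": dict(self.ptcy_rate_by_era),
            "time_medians": {
                f"{status}|{era}": float(v)
                for (status, era), v in self.time_medians.items()
            },
            "time_sigma": self.time_sigma,
            "seed": self.seed,
        }
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        haps = tuple(
            {l: row[l] for l in SUPPORTED_LOCI} for row in data["pool"]["haplotypes"]
        )
        freqs = tuple(float(row["frequency"]) for row in data["pool"]["haplotypes"])
        pool = HaplotypePool(
            name=data["pool"]["name"],
            haplotypes=haps,
            frequencies=freqs,
            marginal_mode=bool(data["pool"].get("marginal_mode", False)),
        )
        medians = {
            tuple(key.split("|")): float(v)
            for key, v in data.get("time_medians", {}).items()
        }
        kwargs = {
            k: data[k]
            for k in (
                "registry_size",
                "selection",
                "grade_threshold",
                "time_sigma",
                "seed",
            )
            if k in data
        }
        if medians:
            kwargs["time_medians"] = medians
        if data.get("era_weights"):
            kwargs["era_weights"] = data["era_weights"]
        if data.get("ptcy_rate_by_era"):
            kwargs["ptcy_rate_by_era"] = data["ptcy_rate_by_era"]
        return cls(pool=pool, **kwargs)


# ---------------------------------------------------------------------------
# Sampling machinery
# ---------------------------------------------------------------------------

def _locus_codes(pool: HaplotypePool) -> dict[str, np.ndarray]:
    """Integer allele codes per locus for each haplotype (for fast grading)."""
    codes = {}
    for locus in SUPPORTED_LOCI:
        alleles = pool.alleles_at(locus)
        mapping = {name: i for i, name in enumerate(dict.fromkeys(alleles))}
        codes[locus] = np.array([mapping[a] for a in alleles], dtype=np.int32)
    return codes


def _match_counts(
    pa: np.ndarray, pb: np.ndarray, da: np.ndarray, db: np.ndarray
) -> np.ndarray:
    """Matched-allele count (0-2) between genotype multisets, vectorised."""
    s1 = (pa == da).astype(np.int8) + (pb == db).astype(np.int8)
    s2 = (pa == db).astype(np.int8) + (pb == da).astype(np.int8)
    return np.maximum(s1, s2)


def _sample_genotypes(
    pool: HaplotypePool, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Sample n genotypes as (n, 2) haplotype indices (Hardy-Weinberg)."""
    freqs = np.asarray(pool.frequencies, dtype=float)
    return rng.choice(pool.n_haplotypes, size=(n, 2), p=freqs)


def sample_cohort(config: SimulationConfig, n_pairs: int) -> pd.DataFrame:
    """Simulate a cohort; returns a table in the cohort TSV dialect.

    Each patient is two haplotypes from the pool; the donor is drawn from a
    simulated registry search of ``registry_size`` independent genotypes
    according to the selection policy (``best-grade`` maximises the x/10
    then x/12 grade, ties resolved by draw order; ``grade-threshold`` takes
    the first candidate reaching the configured x/10 grade, falling back to
    the best; ``random`` takes the first candidate).  Year, PTCy flag and
    diagnosis-to-transplant time follow the configured era and time models.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    pool = config.pool
    rng = np.random.default_rng(config.seed)
    codes = _locus_codes(pool)

    if pool.marginal_mode:
        # LD off: draw each locus independently from its marginal
        def draw_genotypes(n: int) -> dict[str, np.ndarray]:
            out = {}
            for locus in SUPPORTED_LOCI:
                marg = pool.marginal(locus)
                names = list(marg)
                p = np.asarray([marg[a] for a in names], dtype=float)
                p = p / p.sum()
                idx = rng.choice(len(names), size=(n, 2), p=p)
                out[locus] = np.asarray(names, dtype=object)[idx]
            return out

        patient_alleles = draw_genotypes(n_pairs)
        registry_alleles = draw_genotypes(n_pairs * config.registry_size)
        reg = {
            locus: arr.reshape(n_pairs, config.registry_size, 2)
            for locus, arr in registry_alleles.items()
        }
        # integer codes for grading
        def codes_of(arr_by_locus, shape):
            coded = {}
            for locus in SUPPORTED_LOCI:
                names = list(dict.fromkeys(pool.alleles_at(locus)))
                mapping = {a: i for i, a in enumerate(names)}
                coded[locus] = np.vectorize(mapping.__getitem__, otypes=[np.int32])(
                    arr_by_locus[locus]
                )
            return coded

        pat_codes = codes_of(patient_alleles, None)
        reg_codes = codes_of(reg, None)
        match_per_locus = {
            locus: _match_counts(
                pat_codes[locus][:, None, 0],
                pat_codes[locus][:, None, 1],
                reg_codes[locus][:, :, 0],
                reg_codes[locus][:, :, 1],
            )
            for locus in SUPPORTED_LOCI
        }
        get_patient_allele = lambda locus, i, j: patient_alleles[locus][i, j]
        get_donor_allele = lambda locus, i, k, j: reg[locus][i, k, j]
    else:
        patients = _sample_genotypes(pool, rng, n_pairs)  # (n, 2)
        registry = _sample_genotypes(pool, rng, n_pairs * config.registry_size)
        registry = registry.reshape(n_pairs, config.registry_size, 2)
        hap_alleles = {
            locus: np.asarray(pool.alleles_at(locus), dtype=object)
            for locus in SUPPORTED_LOCI
        }
        # DQ-DP recombination hotspot: decouple DPB1 from the haplotype on a
        # per-chromosome basis
        dp_marg = pool.marginal("DPB1")
        dp_names = np.asarray(list(dp_marg), dtype=object)
        dp_p = np.asarray([dp_marg[a] for a in dp_names], dtype=float)
        dp_p = dp_p / dp_p.sum()

        def _recombine(hap_idx: np.ndarray) -> np.ndarray:
            alleles = hap_alleles["DPB1"][hap_idx]
            mask = rng.random(hap_idx.shape) < config.dpb1_recombination
            redraw = dp_names[
                rng.choice(len(dp_names), size=hap_idx.shape, p=dp_p)
            ]
            return np.where(mask, redraw, alleles)

        patient_dpb1 = _recombine(patients)  # (n, 2) allele names
        registry_dpb1 = _recombine(registry)  # (n, reg, 2) allele names
        dp_code_map = {a: i for i, a in enumerate(dp_names)}
        _code = np.vectorize(dp_code_map.__getitem__, otypes=[np.int32])
        pat_dp_codes = _code(patient_dpb1)
        reg_dp_codes = _code(registry_dpb1)

        match_per_locus = {
            locus: _match_counts(
                codes[locus][patients[:, None, 0]],
                codes[locus][patients[:, None, 1]],
                codes[locus][registry[:, :, 0]],
                codes[locus][registry[:, :, 1]],
            )
            for locus in MAIN_LOCI
        }
        match_per_locus["DPB1"] = _match_counts(
            pat_dp_codes[:, None, 0],
            pat_dp_codes[:, None, 1],
            reg_dp_codes[:, :, 0],
            reg_dp_codes[:, :, 1],
        )

        def get_patient_allele(locus, i, j):
            if locus == "DPB1":
                return patient_dpb1[i, j]
            return hap_alleles[locus][patients[i, j]]

        def get_donor_allele(locus, i, k, j):
            if locus == "DPB1":
                return registry_dpb1[i, k, j]
            return hap_alleles[locus][registry[i, k, j]]

    grade10 = sum(match_per_locus[l] for l in MAIN_LOCI)  # (n, registry)
    grade12 = grade10 + match_per_locus["DPB1"]

    if config.selection == "best-grade":
        # maximise grade10 then grade12; ties -> first drawn candidate
        order = grade10.astype(np.int64) * 16 + grade12.astype(np.int64)
        chosen = np.argmax(order, axis=1)
    elif config.selection == "grade-threshold":
        meets = grade10 >= config.grade_threshold
        first_ok = np.argmax(meets, axis=1)
        any_ok = meets.any(axis=1)
        order = grade10.astype(np.int64) * 16 + grade12.astype(np.int64)
        best = np.argmax(order, axis=1)
        chosen = np.where(any_ok, first_ok, best)
    else:  # random
        chosen = np.zeros(n_pairs, dtype=int)

    chosen_grade10 = grade10[np.arange(n_pairs), chosen]
    matched = chosen_grade10 == 10

    eras = list(config.era_weights)
    era_p = np.asarray([config.era_weights[e] for e in eras], dtype=float)
    era_p = era_p / era_p.sum()
    era_idx = rng.choice(len(eras), size=n_pairs, p=era_p)
    years = np.empty(n_pairs, dtype=int)
    for i, e_i in enumerate(era_idx):
        lo, hi = _ERA_YEARS[eras[e_i]]
        years[i] = rng.integers(lo, hi + 1)

    ptcy_p = np.asarray(
        [config.ptcy_rate_by_era.get(eras[e], 0.0) for e in era_idx], dtype=float
    )
    ptcy = np.where(rng.random(n_pairs) < ptcy_p, "yes", "no")

    status = np.where(matched, "10/10", "<10/10")
    medians = np.asarray(
        [
            config.time_medians[(status[i], eras[era_idx[i]])]
            for i in range(n_pairs)
        ],
        dtype=float,
    )
    months = np.exp(
        np.log(medians) + config.time_sigma * rng.standard_normal(n_pairs)
    )

    rows = []
    for i in range(n_pairs):
        row: dict[str, object] = {
            "pair_id": f"sim{i:06d}",
            "year": int(years[i]),
            "months_dx_to_tx": round(float(months[i]), 2),
            "ptcy": str(ptcy[i]),
        }
        k = int(chosen[i])
        for locus in SUPPORTED_LOCI:
            row[f"patient_{locus}_1"] = get_patient_allele(locus, i, 0)
            row[f"patient_{locus}_2"] = get_patient_allele(locus, i, 1)
            row[f"donor_{locus}_1"] = get_donor_allele(locus, i, k, 0)
            row[f"donor_{locus}_2"] = get_donor_allele(locus, i, k, 1)
        rows.append(row)
    return pd.DataFrame(rows, columns=cohort_columns())


# ---------------------------------------------------------------------------
# Preset pools
# ---------------------------------------------------------------------------

def preset_pools() -> dict[str, HaplotypePool]:
    """Named curated haplotype pools.

    * ``euro-toy`` -- 17 haplotypes mirroring common European extended
      haplotypes (e.g. the A*01:01-B*08:01-C*07:01-DRB1*03:01-DQB1*02:01
      ancestral haplotype) with strong LD; allele pairs that dominate real
      mismatch landscapes (DRB1*14:01/14:54, C*03:03/03:04, DRB1*11:01/11:04,
      DRB1*04:01/04:04) ride on similar backgrounds so their mismatches are
      enriched.
    * ``uniform`` -- four equifrequent haplotypes with locus-wise distinct
      alleles; the analytically tractable null pool.
    * ``dpb1-skewed`` -- a pool whose DPB1 marginal concentrates most mass
      in the six ubiquitous alleles (01:01, 02:01, 03:01, 04:01, 04:02,
      05:01), as in real registries.

    Every allele carries entries in the packaged reference tables where the
    corresponding model applies.
    """

    def hap(a, b, c, drb1, dqb1, dpb1):
        return {
            "A": f"A*{a}",
            "B": f"B*{b}",
            "C": f"C*{c}",
            "DRB1": f"DRB1*{drb1}",
            "DQB1": f"DQB1*{dqb1}",
            "DPB1": f"DPB1*{dpb1}",
        }

    euro = HaplotypePool(
        name="euro-toy",
        haplotypes=(
            hap("01:01", "08:01", "07:01", "03:01", "02:01", "04:01"),
            hap("02:01", "07:02", "07:02", "15:01", "06:02", "04:01"),
            hap("03:01", "07:02", "07:02", "15:01", "06:02", "04:02"),
            hap("02:01", "44:02", "05:01", "04:01", "03:02", "04:01"),
            hap("02:01", "15:01", "03:03", "04:01", "03:02", "04:02"),
            hap("02:01", "15:01", "03:04", "04:04", "03:02", "02:01"),
            hap("24:02", "35:01", "04:01", "11:01", "03:01", "02:01"),
            hap("11:01", "35:03", "04:01", "11:04", "03:01", "02:01"),
            hap("03:01", "35:02", "04:01", "01:01", "05:01", "04:02"),
            hap("02:01", "18:01", "07:01", "11:04", "03:01", "03:01"),
            hap("01:01", "57:01", "06:02", "07:01", "03:03", "01:01"),
            hap("24:02", "51:01", "01:02", "14:01", "05:02", "05:01"),
            hap("11:01", "51:01", "02:02", "14:54", "05:02", "05:01"),
            hap("01:01", "13:02", "06:02", "07:01", "02:02", "17:01"),
            hap("02:01", "27:05", "01:02", "13:01", "06:03", "09:01"),
            hap("03:01", "40:01", "03:04", "13:02", "06:04", "03:01"),
            hap("24:02", "44:03", "07:01", "07:01", "02:02", "14:01"),
        ),
        frequencies=(
            0.13,
            0.11,
            0.08,
            0.08,
            0.07,
            0.06,
            0.06,
            0.05,
            0.05,
            0.05,
            0.05,
            0.04,
            0.04,
            0.04,
            0.03,
            0.03,
            0.03,
        ),
    )

    uniform = HaplotypePool(
        name="uniform",
        haplotypes=(
            hap("01:01", "08:01", "07:01", "03:01", "02:01", "01:01"),
            hap("02:01", "07:02", "07:02", "15:01", "06:02", "02:01"),
            hap("03:01", "35:01", "04:01", "11:01", "03:01", "03:01"),
            hap("24:02", "44:02", "05:01", "04:01", "03:02", "04:01"),
        ),
        frequencies=(0.25, 0.25, 0.25, 0.25),
    )

    dpb1_skewed = HaplotypePool(
        name="dpb1-skewed",
        haplotypes=(
            hap("01:01", "08:01", "07:01", "03:01", "02:01", "04:01"),
            hap("01:01", "08:01", "07:01", "03:01", "02:01", "02:01"),
            hap("02:01", "07:02", "07:02", "15:01", "06:02", "04:02"),
            hap("02:01", "07:02", "07:02", "15:01", "06:02", "01:01"),
            hap("02:01", "07:02", "07:02", "15:01", "06:02", "03:01"),
            hap("01:01", "08:01", "07:01", "03:01", "02:01", "05:01"),
            hap("02:01", "07:02", "07:02", "15:01", "06:02", "09:01"),
            hap("01:01", "08:01", "07:01", "03:01", "02:01", "17:01"),
            hap("02:01", "07:02", "07:02", "15:01", "06:02", "13:01"),
            hap("01:01", "08:01", "07:01", "03:01", "02:01", "11:01"),
        ),
        frequencies=(0.22, 0.17, 0.15, 0.12, 0.10, 0.08, 0.05, 0.04, 0.04, 0.03),
    )

    return {"euro-toy": euro, "uniform": uniform, "dpb1-skewed": dpb1_skewed}
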