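"""Core data containers for the candidate-SNP obesity panel analysis.

The analysis operates on three aligned objects:

* a SNP panel (one :class:`SnpRecord` per marker: gene, position, alleles,
  tag flag),
* a :class:`GenotypeMatrix` of per-individual allele counts coded 0/1/2
  for a designated *count allele* (``NaN`` = missing call), and
* a phenotype table (pandas ``DataFrame``) with BMI, age, sex, cohort and
  a type-2-diabetes flag.

Conventions: counts are stored for the cohort-minor allele unless a panel
dictates otherwise; positions are 1-based; the obesity flag is derived as
BMI >= 30 kg/m^2 and never stored independently of BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Required columns of a phenotype table.
PHENOTYPE_COLUMNS = ("individual_id", "cohort", "age", "sex", "bmi", "dm2")

#: BMI cut-point (kg/m^2) defining obesity.
OBESITY_BMI_THRESHOLD = 30.0


class PanelError(ValueError):
    """Raised when a SNP panel or genotype/phenotype input is inconsistent."""


@dataclass(frozen=True)
class SnpRecord:
    """Annotation for one biallelic SNP.

    ``allele_a1`` is the designated effect/minor allele; ``allele_a2`` the
    other allele. ``chromosome`` is an autosome label ("1".."22") or "X".
    """

    snp_id: str
    gene: str
    chromosome: str
    position: int
    allele_a1: str
    allele_a2: str
    is_tag: bool = True

    def __post_init__(self) -> None:
        if self.allele_a1 == self.allele_a2:
            raise PanelError(f"{self.snp_id}: alleles must differ")
        for a in (self.allele_a1, self.allele_a2):
            if a not in VALID_ALLELES:
                raise PanelError(f"{self.snp_id}: invalid allele {a!r}")
        if self.position <= 0:
            raise PanelError(f"{self.snp_id}: position must be positive")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.allele_a1, self.allele_a2))

    @property
    def is_x(self) -> bool:
        return self.chromosome.upper() == "X"

    @property
    def strand_ambiguous(self) -> bool:
        """A/T and C/G SNPs cannot be disambiguated across strand flips."""
        return self.alleles in (frozenset("AT"), frozenset("CG"))


class SnpPanel:
    """Ordered collection of :class:`SnpRecord` with unique ids."""

    def __init__(self, records: Iterable[SnpRecord]):
        self.records = list(records)
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate snp_id in panel")
        self._by_id = {r.snp_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def __getitem__(self, snp_id: str) -> SnpRecord:
        return self._by_id[snp_id]

    @property
    def snp_ids(self) -> list:
        return [r.snp_id for r in self.records]

    def subset(self, snp_ids: Iterable[str]) -> "SnpPanel":
        return SnpPanel(self._by_id[s] for s in snp_ids)

    def sorted_by_position(self) -> "SnpPanel":
        chrom_key = lambda r: (
            (int(r.chromosome), r.position) if r.chromosome.isdigit() else (99, r.position)
        )
        return SnpPanel(sorted(self.records, key=chrom_key))

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in fields(SnpRecord)]
        return pd.DataFrame([[getattr(r, c) for c in cols] for r in self.records], columns=cols)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of designated-allele counts.

    ``counts`` is a float array with entries in {0, 1, 2} and ``NaN`` for
    missing calls. ``count_allele[s]`` names the allele whose copies are
    counted at SNP ``s``; ``other_allele[s]`` is its partner. ``cohort``
    labels each individual.
    """

    individual_ids: list
    snp_ids: list
    counts: np.ndarray
    count_allele: dict
    other_allele: dict
    cohort: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, m = self.counts.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise PanelError("genotype matrix dimensions inconsistent with ids")
        ok = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.counts[~ok])
            raise PanelError(f"genotype counts outside {{0,1,2,NaN}}: {bad}")
        for s in self.snp_ids:
            if s not in self.count_allele:
                raise PanelError(f"no count allele recorded for {s}")
        if self.cohort is None:
            self.cohort = np.array(["all"] * n, dtype=object)
        else:
            self.cohort = np.asarray(self.cohort, dtype=object)
            if len(self.cohort) != n:
                raise PanelError("cohort labels do not match individuals")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def column(self, snp_id: str) -> np.ndarray:
        return self.counts[:, self.snp_index(snp_id)]

    def snp_call_rates(self) -> pd.Series:
        rates = 1.0 - np.isnan(self.counts).mean(axis=0)
        return pd.Series(rates, index=self.snp_ids)

    def individual_call_rates(self) -> pd.Series:
        rates = 1.0 - np.isnan(self.counts).mean(axis=1)
        return pd.Series(rates, index=self.individual_ids)

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individual/SNP ids."""
        ind = list(self.individual_ids) if individuals is None else list(individuals)
        snp = list(self.snp_ids) if snps is None else list(snps)
        ind_idx = [self.individual_ids.index(i) for i in ind]
        snp_idx = [self.snp_ids.index(s) for s in snp]
        return GenotypeMatrix(
            individual_ids=ind,
            snp_ids=snp,
            counts=self.counts[np.ix_(ind_idx, snp_idx)].copy(),
            count_allele={s: self.count_allele[s] for s in snp},
            other_allele={s: self.other_allele[s] for s in snp},
            cohort=self.cohort[ind_idx].copy(),
        )

    def oriented_column(self, snp_id: str, allele: str) -> np.ndarray:
        """Counts of ``allele`` at ``snp_id``, flipping 0/1/2 if needed.

        For X-linked male codings where the per-individual maximum is 1,
        the flip is still 2-x on the stored scale; callers handling
        hemizygous males must re-orient before storage instead.
        """
        j = self.snp_index(snp_id)
        if allele == self.count_allele[snp_id]:
            return self.counts[:, j]
        if allele == self.other_allele[snp_id]:
            return 2.0 - self.counts[:, j]
        raise PanelError(
            f"{snp_id}: allele {allele} not in "
            f"({self.count_allele[snp_id]}, {self.other_allele[snp_id]})"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.individual_ids, columns=self.snp_ids)


@dataclass
class StudyConfig:
    """Thresholds and conventions of one analysis run."""

    min_call_rate_snp: float = 0.95
    min_call_rate_individual: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 0.001
    alpha: float = 0.05
    n_independent_tests: int = 26
    grs_rounding: str = "half_away_from_zero"
    grs_missing: str = "impute"  # or "drop"
    x_male_coding: str = "0-1"  # or "0-2"
    adjust_dm2: bool = False
    pooled_cohort_covariate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_call_rate_snp", "min_call_rate_individual", "min_maf",
                     "min_hwe_p", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise PanelError(f"{name} must be in (0, 1], got {v}")
        if self.n_independent_tests < 1:
            raise PanelError("n_independent_tests must be >= 1")
        if self.x_male_coding not in ("0-1", "0-2"):
            raise PanelError("x_male_coding must be '0-1' or '0-2'")
        if self.grs_missing not in ("impute", "drop"):
            raise PanelError("grs_missing must be 'impute' or 'drop'")


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table and derive the obesity flag.

    Returns a copy with ``obesity`` recomputed as ``bmi >= 30``. ``sex``
    must be coded "male"/"female".
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise PanelError(f"phenotype table lacks columns: {missing}")
    out = pheno.copy()
    if out["individual_id"].duplicated().any():
        raise PanelError("duplicate individual_id in phenotype table")
    bad_sex = set(out["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise PanelError(f"sex must be 'male'/'female', got {sorted(bad_sex)}")
    if (out["bmi"] <= 0).any():
        raise PanelError("bmi must be positive")
    out["dm2"] = out["dm2"].astype(bool)
    out["obesity"] = out["bmi"] >= OBESITY_BMI_THRESHOLD
    return out
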