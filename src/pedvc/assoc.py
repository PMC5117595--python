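"""Measured-genotype association and allele-level statistics.

A coded genotype (carrier indicator or risk-allele count) enters the
pedigree mixed model as a fixed effect; the drop in the additive variance
relative to the base model, and the closed-form variance contributed by the
locus under Hardy-Weinberg proportions, quantify how much of the genetic
variance the locus explains.  Also provides allele frequencies, a
Hardy-Weinberg goodness-of-fit test and the transmission disequilibrium
test (TDT), which is robust to population stratification because it only
uses transmissions from heterozygous parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from .kinship import RelationshipMatrix
from .pedio import GenotypeTable, Pedigree, PhenotypeTable
from .vcmodel import UnivariateVarianceComponents, _as_frame

__all__ = [
    "GenotypeCoding",
    "AssociationResult",
    "MeasuredGenotypeAssociation",
    "code_genotype",
    "measured_genotype_association",
    "variance_explained",
    "allele_frequencies",
    "hwe_test",
    "tdt",
]


@dataclass(frozen=True)
class GenotypeCoding:
    """How a locus enters the model as a covariate.

    ``carrier``: 1 if any copy of the risk allele, else 0.
    ``additive``: count of risk alleles (0, 1, 2).
    """

    locus: str
    risk_allele: str
    scheme: str = "carrier"

    def __post_init__(self):
        if self.scheme not in ("carrier", "additive"):
            raise ValueError(f"unknown coding scheme {self.scheme!r}")

    @property
    def column(self) -> str:
        return f"{self.locus}_{self.risk_allele}_{self.scheme}"


def code_genotype(genos: GenotypeTable, coding: GenotypeCoding) -> pd.Series:
    """Numeric covariate per individual; missing genotypes become NaN."""
    if coding.locus not in genos.loci:
        raise KeyError(f"locus {coding.locus!r} not in genotype table")
    locus = genos.loci[coding.locus]
    if coding.risk_allele not in locus.alleles:
        raise ValueError(
            f"risk allele {coding.risk_allele!r} not in allele set of {locus.name}"
        )
    values = {}
    seen = set()
    for iid in genos.ids:
        call = genos.get(iid, coding.locus)
        if call is None:
            values[iid] = np.nan
            continue
        count = sum(a == coding.risk_allele for a in call)
        seen.add(count)
        values[iid] = float(count >= 1) if coding.scheme == "carrier" else float(count)
    non_missing = [v for v in values.values() if not np.isnan(v)]
    if non_missing and len(set(non_missing)) < 2:
        raise ValueError(f"no variation at locus {coding.locus!r}")
    return pd.Series(values, name=coding.column)


@dataclass
class AssociationResult:
    locus: str
    scheme: str
    trait: str
    beta: float
    ase: float
    p: float
    n_by_genotype: dict
    va_base: float
    va_with_locus: float
    variance_explained: float
    explained_capped: bool
    fit: object = field(repr=False, default=None)
    fit_base: object = field(repr=False, default=None)


class MeasuredGenotypeAssociation(BaseEstimator):
    """Measured-genotype test inside the variance-components model.

    Fits the base polygenic model for ``trait`` and the same model with the
    coded genotype added as a fixed effect; exposes the genotype effect
    (Wald test) and the share of the base additive variance attributable to
    the locus.
    """

    def __init__(
        self,
        trait: str = "y",
        fixed_effects: tuple = (),
        coding: GenotypeCoding | None = None,
        method: str = "reml",
    ):
        self.trait = trait
        self.fixed_effects = fixed_effects
        self.coding = coding
        self.method = method

    def fit(self, data, relationship: RelationshipMatrix, genos: GenotypeTable):
        if self.coding is None:
            raise ValueError("a GenotypeCoding is required")
        coding = self.coding
        covariate = code_genotype(genos, coding)
        df = _as_frame(data).copy()
        df[coding.column] = covariate.reindex(df.index)
        # restrict both fits to genotyped rows so V_A is comparable
        df = df[df[coding.column].notna()]

        base = UnivariateVarianceComponents(
            trait=self.trait,
            fixed_effects=tuple(self.fixed_effects),
            method=self.method,
        ).fit(df, relationship)
        full = UnivariateVarianceComponents(
            trait=self.trait,
            fixed_effects=tuple(self.fixed_effects) + (coding.column,),
            method=self.method,
        ).fit(df, relationship)

        beta = float(full.beta_[coding.column])
        ase = float(full.beta_se_[coding.column])
        p = 2.0 * float(norm.sf(abs(beta / ase))) if ase > 0 else float("nan")
        counts = (
            df.loc[full.ids_used_, coding.column].value_counts().sort_index()
        )
        n_by_genotype = {int(k): int(v) for k, v in counts.items()}

        freq = allele_frequencies(genos, coding.locus)[coding.risk_allele]
        if base.VA_ > 0:
            prop, capped = variance_explained(beta, coding, freq, base.VA_)
        else:
            prop, capped = float("nan"), False

        self.result_ = AssociationResult(
            locus=coding.locus,
            scheme=coding.scheme,
            trait=self.trait,
            beta=beta,
            ase=ase,
            p=p,
            n_by_genotype=n_by_genotype,
            va_base=base.VA_,
            va_with_locus=full.VA_,
            variance_explained=prop,
            explained_capped=capped,
            fit=full,
            fit_base=base,
        )
        return self


def measured_genotype_association(
    data,
    relationship: RelationshipMatrix,
    genos: GenotypeTable,
    coding: GenotypeCoding,
    trait: str,
    fixed_effects=(),
    method: str = "reml",
) -> AssociationResult:
    """Add a coded genotype to the polygenic model and test its effect."""
    est = MeasuredGenotypeAssociation(
        trait=trait,
        fixed_effects=tuple(fixed_effects),
        coding=coding,
        method=method,
    ).fit(data, relationship, genos)
    return est.result_


def variance_explained(
    beta: float, coding: GenotypeCoding, allele_freq: float, va_base: float
) -> tuple[float, bool]:
    """Share of the base additive variance due to one locus, under HWE.

    additive: Var = 2 p (1-p) beta^2;
    carrier:  Var = c (1-c) beta^2 with carrier frequency c = 1 - (1-p)^2.

    Returns (proportion, capped_flag); the proportion is capped at 1 with
    the flag set when the locus variance exceeds the base V_A.
    """
    if not 0.0 < allele_freq < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    if va_base <= 0:
        raise ValueError("base additive variance must be positive")
    p = allele_freq
    if coding.scheme == "additive":
        var_locus = 2.0 * p * (1.0 - p) * beta**2
    else:
        c = 1.0 - (1.0 - p) ** 2
        var_locus = c * (1.0 - c) * beta**2
    prop = var_locus / va_base
    if prop >= 1.0:
        return 1.0, True
    return float(prop), False


def allele_frequencies(
    genos: GenotypeTable,
    locus: str,
    ped: Pedigree | None = None,
    founders_only: bool = False,
) -> dict[str, float]:
    """Allele-count frequencies at a locus.

    By default over all genotyped individuals; with ``founders_only`` the
    count is restricted to pedigree founders (avoids double-counting
    transmitted alleles).
    """
    if locus not in genos.loci:
        raise KeyError(f"locus {locus!r} not in genotype table")
    ids = genos.genotyped_ids(locus)
    if founders_only:
        if ped is None:
            raise ValueError("founders_only requires a pedigree")
        founder_ids = {ind.id for ind in ped.founders}
        ids = [iid for iid in ids if iid in founder_ids]
    counts: dict[str, int] = {}
    for iid in ids:
        for a in genos.get(iid, locus):
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no non-missing genotypes at locus {locus!r}")
    return {a: c / total for a, c in sorted(counts.items())}


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> dict:
    """1-df chi-square goodness of fit against Hardy-Weinberg proportions.

    Counts are (hom for allele 1, het, hom for allele 2); expectations are
    p^2, 2pq, q^2 at the sample allele frequency.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative genotype count")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p**2, 2 * p * q, q**2])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    return {"chi2": stat, "p": float(chi2.sf(stat, df=1))}


def tdt(ped: Pedigree, genos: GenotypeTable, locus: str, risk_allele: str) -> dict:
    """Transmission disequilibrium test over heterozygous parents.

    Counts transmissions of the risk allele (``b``) versus the other allele
    (``c``) from heterozygous genotyped parents to genotyped offspring
    (both parents must be genotyped so transmissions are resolvable) and
    forms the McNemar statistic ``(b - c)^2 / (b + c)`` on 1 df.
    """
    if locus not in genos.loci:
        raise KeyError(f"locus {locus!r} not in genotype table")
    b = 0
    c = 0
    for ind in ped.individuals:
        if ind.father_id is None or ind.mother_id is None:
            continue
        child = genos.get(ind.id, locus)
        father = genos.get(ind.father_id, locus)
        mother = genos.get(ind.mother_id, locus)
        if child is None or father is None or mother is None:
            continue
        # informative parents carry exactly one copy of the risk allele;
        # parents with two copies must transmit it, with none cannot
        risk_copies = [sum(a == risk_allele for a in g) for g in (father, mother)]
        n_het = sum(1 for k in risk_copies if k == 1)
        if n_het == 0:
            continue
        risk_in_child = sum(a == risk_allele for a in child)
        from_obligate = sum(1 for k in risk_copies if k == 2)
        from_het = risk_in_child - from_obligate
        if from_het < 0 or from_het > n_het:
            raise ValueError(
                f"Mendelian inconsistency at locus {locus} for child {ind.id!r}"
            )
        b += from_het
        c += n_het - from_het
    if b + c == 0:
        raise ValueError(
            "TDT not computable: no informative heterozygous-parent transmissions"
        )
    stat = (b - c) ** 2 / (b + c)
    return {"b": b, "c": c, "chi2": float(stat), "p": float(chi2.sf(stat, df=1))}
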