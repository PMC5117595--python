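import io

import numpy as np
import pytest

from pedvc import (
    GenotypeCoding,
    Pedigree,
    SimulationConfig,
    TraitModel,
    additive_relationship,
    code_genotype,
    generate_pedigree,
    generate_study_like_dataset,
    read_pedigree,
)
from pedvc.pedio import Individual


TRIO_TEXT = "F1 dad 0 0 1\nF1 mum 0 0 2\nF1 kid dad mum 1\n"


@pytest.fixture
def trio():
    ped, _ = read_pedigree(io.StringIO(TRIO_TEXT))
    return ped


@pytest.fixture
def fullsib_pedigree():
    """Two founders, two full sibs, and an offspring of the sib mating."""
    return Pedigree(
        [
            Individual("p1", "F", sex="male"),
            Individual("p2", "F", sex="female"),
            Individual("s1", "F", "p1", "p2", "male"),
            Individual("s2", "F", "p1", "p2", "female"),
            Individual("c", "F", "s1", "s2", "male"),
        ]
    )


def random_pedigree(rng, n_max=12, mate_prob=0.6):
    """Random valid pedigree of at most ``n_max`` members: each new member
    takes two distinct earlier members as parents with some probability."""
    n = int(rng.integers(1, n_max + 1))
    inds = []
    for k in range(n):
        iid = f"i{k}"
        father = mother = None
        if k >= 2 and rng.random() < mate_prob:
            a, b = rng.choice(k, size=2, replace=False)
            father, mother = f"i{a}", f"i{b}"
        sex = "male" if rng.random() < 0.5 else "female"
        inds.append(Individual(iid, "F1", father, mother, sex))
    return Pedigree(inds)


def univariate_config(
    va=0.5, ve=0.5, n_families=60, offspring=3, loci=(), seedless_trait="y"
):
    """Single-trait nuclear-family simulation config used across tests."""
    tm = TraitModel(
        traits=(seedless_trait,),
        G=np.array([[va]]),
        E=np.array([[ve]]),
        intercepts={seedless_trait: 0.0},
        betas={seedless_trait: {}},
    )
    return SimulationConfig(
        n_families=n_families,
        offspring_fixed=offspring,
        extend_prob=0.0,
        max_generations=2,
        phenotyping_fraction=1.0,
        loci=tuple(loci),
        trait_model=tm,
    )


def study_frame(study):
    """Phenotype frame with coded-genotype covariates appended, mirroring a
    measured-genotype analysis."""
    df = study.phenotypes.data.copy()
    for locus in study.truth["loci"]:
        coding = GenotypeCoding(locus["name"], locus["risk_allele"], locus["scheme"])
        df[coding.column] = code_genotype(study.genotypes, coding).reindex(df.index)
    return df


STUDY_FIXED = ("age", "sex", "weight", "ACE_D_carrier", "TP53_P_additive")


@pytest.fixture(scope="session")
def study():
    return generate_study_like_dataset(20250101)


@pytest.fixture(scope="session")
def study_relationship(study):
    return additive_relationship(study.pedigree)
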