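"""Pedigree, phenotype and genotype I/O.

Pedigrees are read and written in the pre-makeped LINKAGE/PED dialect:
whitespace- or tab-delimited columns ``family id father mother sex`` with
``0`` denoting a missing parent or unknown sex (1 = male, 2 = female), and
optionally two allele tokens per locus after the sex column (``0 0`` =
missing genotype).  Phenotypes are delimited tables with a header row and
one row per individual.

Identifiers are opaque strings throughout: matching across files is exact
string match, and nothing assumes integer ids.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "Locus",
    "GenotypeTable",
    "PhenotypeTable",
    "PedigreeError",
    "PhenotypeError",
    "Finding",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "validate_pedigree",
]

MISSING = "0"

_SEX_FROM_CODE = {"1": "male", "2": "female", "0": "unknown"}
_CODE_FROM_SEX = {"male": "1", "female": "2", "unknown": "0"}

# physical lower bounds for trait columns (exclusive)
TRAIT_BOUNDS = {
    "uacr": 0.0,
    "sbp": 0.0,
    "dbp": 0.0,
    "fpg": 0.0,
    "creatinine": 0.0,
    "age": 0.0,
    "weight": 0.0,
    "height": 0.0,
}


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or object."""


class PhenotypeError(ValueError):
    """Structural problem in a phenotype table."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for missing parents; an
    individual is a founder iff both are ``None``.
    """

    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class Finding:
    """A structured validation finding (not an error)."""

    kind: str
    individual_id: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.message}"


class Pedigree:
    """A set of individuals with parent links forming a DAG.

    Construction validates that ids are unique, that parent references
    resolve within the pedigree, and that the parent->offspring graph is
    acyclic.  Softer problems (sex-inconsistent parents, half-specified
    parent pairs, ...) are reported by :func:`validate_pedigree` instead.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicated individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown parent {pid!r}"
                    )
        self._check_acyclic()

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        ind = self._by_id[iid]
        return ind.father_id, ind.mother_id

    def children(self, iid: str) -> list[str]:
        return [
            ind.id
            for ind in self.individuals
            if iid in (ind.father_id, ind.mother_id)
        ]

    def graph(self) -> nx.DiGraph:
        """Parent -> offspring directed graph."""
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    g.add_edge(pid, ind.id)
        return g

    def _check_acyclic(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise PedigreeError(f"cyclic ancestry: {path}")

    def topological_order(self) -> list[str]:
        """Ids with both parents placed before each offspring.

        Stable: ties are broken by file order.
        """
        placed: set[str] = set()
        order: list[str] = []
        pending = list(self.individuals)
        while pending:
            progressed = False
            remaining = []
            for ind in pending:
                ready = all(
                    pid is None or pid in placed
                    for pid in (ind.father_id, ind.mother_id)
                )
                if ready:
                    order.append(ind.id)
                    placed.add(ind.id)
                    progressed = True
                else:
                    remaining.append(ind)
            if not progressed:  # pragma: no cover - excluded at construction
                raise PedigreeError("no topological order exists (cycle)")
            pending = remaining
        return order

    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.family_id, None)
        return list(seen)

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ind in self.individuals:
            out.setdefault(ind.family_id, []).append(ind.id)
        return out

    def generation_depth(self) -> int:
        """Number of generations spanned by the deepest lineage."""
        depth: dict[str, int] = {}
        for iid in self.topological_order():
            f, m = self.parents(iid)
            parent_depths = [depth[p] for p in (f, m) if p is not None]
            depth[iid] = 1 + max(parent_depths, default=0)
        return max(depth.values(), default=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self.individuals == other.individuals

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Pedigree({len(self)} individuals, "
            f"{len(self.families())} families, {len(self.founders)} founders)"
        )


@dataclass(frozen=True)
class Locus:
    """Metadata for one biallelic (or collapsed multiallelic) locus."""

    name: str
    alleles: tuple[str, ...]
    risk_allele: str | None = None

    def __post_init__(self) -> None:
        if self.risk_allele is not None and self.risk_allele not in self.alleles:
            raise ValueError(
                f"risk allele {self.risk_allele!r} not in allele set of {self.name}"
            )


class GenotypeTable:
    """Unordered allele pairs per individual and locus."""

    def __init__(self, loci: Sequence[Locus]):
        self.loci: dict[str, Locus] = {loc.name: loc for loc in loci}
        if len(self.loci) != len(loci):
            raise ValueError("duplicate locus names")
        self._calls: dict[str, dict[str, tuple[str, str]]] = {
            name: {} for name in self.loci
        }
        self._ids: dict[str, None] = {}

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def add_individual(self, iid: str) -> None:
        self._ids.setdefault(iid, None)

    def set(self, iid: str, locus: str, alleles: tuple[str, str] | None) -> None:
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        self._ids.setdefault(iid, None)
        if alleles is None:
            self._calls[locus].pop(iid, None)
            return
        declared = self.loci[locus].alleles
        for a in alleles:
            if a not in declared:
                raise ValueError(
                    f"allele {a!r} not in declared set {declared} of locus {locus}"
                )
        self._calls[locus][iid] = tuple(sorted(alleles))  # type: ignore[assignment]

    def get(self, iid: str, locus: str) -> tuple[str, str] | None:
        return self._calls[locus].get(iid)

    def genotyped_ids(self, locus: str) -> list[str]:
        calls = self._calls[locus]
        return [iid for iid in self._ids if iid in calls]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.loci == other.loci
            and self._calls == other._calls
            and list(self._ids) == list(other._ids)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeTable({len(self._ids)} individuals, {len(self.loci)} loci)"


class PhenotypeTable:
    """Per-individual trait values and covariates, indexed by id.

    Thin wrapper over a :class:`pandas.DataFrame`; missing values are NaN.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise PhenotypeError(f"duplicate ids: {dups}")
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        self._check_bounds()

    def _check_bounds(self) -> None:
        for col, low in TRAIT_BOUNDS.items():
            if col in self.data.columns:
                vals = pd.to_numeric(self.data[col], errors="coerce")
                bad = self.data.index[vals.notna() & (vals <= low)].tolist()
                if bad:
                    raise PhenotypeError(
                        f"column {col!r} violates physical bound > {low} "
                        f"for ids {bad}"
                    )

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> pd.Series:
        return self.data[col]

    def check_ids_in(self, ped: Pedigree) -> None:
        missing = [iid for iid in self.data.index if iid not in ped]
        if missing:
            raise PhenotypeError(
                f"phenotype rows do not resolve to pedigree individuals: {missing}"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhenotypeTable({len(self)} rows x {self.data.shape[1]} columns)"


# ---------------------------------------------------------------------------
# readers / writers


def _parse_sex(token: str) -> str:
    if token not in _SEX_FROM_CODE:
        raise PedigreeError(f"unparseable sex code {token!r}")
    return _SEX_FROM_CODE[token]


def read_pedigree(
    path: str | Path | io.TextIOBase,
    loci: Sequence[Locus] = (),
) -> tuple[Pedigree, GenotypeTable | None]:
    """Read a pre-makeped LINKAGE/PED file.

    Parameters
    ----------
    path:
        File path or open text handle.
    loci:
        Metadata for the genotype columns, in file order.  If the file has
        genotype columns, ``loci`` must describe all of them.

    Returns
    -------
    (Pedigree, GenotypeTable or None)
        The genotype table is ``None`` when the file carries no genotype
        columns.
    """
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            lines = fh.read().splitlines()
    else:
        lines = path.read().splitlines()

    individuals: list[Individual] = []
    geno_rows: list[tuple[str, list[str]]] = []
    n_geno_cols: int | None = None
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 5:
            raise PedigreeError(f"line {lineno}: expected >= 5 columns, got {len(tokens)}")
        fam, iid, fid, mid, sex = tokens[:5]
        extra = tokens[5:]
        if n_geno_cols is None:
            n_geno_cols = len(extra)
        elif len(extra) != n_geno_cols:
            raise PedigreeError(
                f"line {lineno}: inconsistent number of genotype columns"
            )
        individuals.append(
            Individual(
                id=iid,
                family_id=fam,
                father_id=None if fid == MISSING else fid,
                mother_id=None if mid == MISSING else mid,
                sex=_parse_sex(sex),
            )
        )
        geno_rows.append((iid, extra))

    ped = Pedigree(individuals)

    if not n_geno_cols:
        return ped, None
    if n_geno_cols % 2:
        raise PedigreeError("odd number of genotype allele columns")
    n_loci = n_geno_cols // 2
    if not loci:
        # no metadata declared: infer allele sets from the observed tokens
        inferred = []
        for k in range(n_loci):
            alleles = sorted(
                {
                    tok
                    for _, extra in geno_rows
                    for tok in extra[2 * k : 2 * k + 2]
                    if tok != MISSING
                }
            )
            inferred.append(Locus(f"locus{k + 1}", tuple(alleles)))
        loci = inferred
    if len(loci) != n_loci:
        raise PedigreeError(
            f"file has {n_loci} genotype column pairs but {len(loci)} loci declared"
        )
    genos = GenotypeTable(loci)
    for iid, extra in geno_rows:
        genos.add_individual(iid)
        for k, locus in enumerate(loci):
            a1, a2 = extra[2 * k], extra[2 * k + 1]
            if MISSING in (a1, a2):
                genos.set(iid, locus.name, None)
            else:
                genos.set(iid, locus.name, (a1, a2))
    return ped, genos


def write_pedigree(
    ped: Pedigree,
    path: str | Path | io.TextIOBase,
    genos: GenotypeTable | None = None,
) -> None:
    """Write the PED dialect :func:`read_pedigree` accepts (write∘read = id)."""
    lines = []
    loci = list(genos.loci.values()) if genos is not None else []
    for ind in ped.individuals:
        row = [
            ind.family_id,
            ind.id,
            ind.father_id or MISSING,
            ind.mother_id or MISSING,
            _CODE_FROM_SEX[ind.sex],
        ]
        for locus in loci:
            call = genos.get(ind.id, locus.name)  # type: ignore[union-attr]
            row.extend(call if call is not None else (MISSING, MISSING))
        lines.append(" ".join(row))
    text = "\n".join(lines)
    if lines:
        text += "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


def read_phenotypes(
    path: str | Path | io.TextIOBase,
    schema: Mapping[str, str] | None = None,
    id_column: str = "id",
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a delimited phenotype table.

    Parameters
    ----------
    schema:
        Maps file column names to canonical names (e.g. ``{"ACR": "uacr"}``).
        Unmapped columns are kept under their file names.
    id_column:
        Name of the id column *in the file* (before schema renaming).
    sep:
        Field separator; by default inferred from the extension
        (``.tsv`` -> tab, otherwise comma).
    """
    if sep is None:
        name = str(path) if isinstance(path, (str, Path)) else ""
        sep = "\t" if name.endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, dtype={id_column: str})
    if id_column not in df.columns:
        raise PhenotypeError(f"id column {id_column!r} absent")
    if schema:
        df = df.rename(columns=dict(schema))
        id_column = dict(schema).get(id_column, id_column)
    df = df.set_index(id_column)
    # coerce non-id columns to numeric where possible; unparseable -> NaN
    n_coerced = 0
    for col in df.columns:
        if col == "sex":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.notna().sum() or df[col].isna().all():
            n_coerced += int((coerced.isna() & df[col].notna()).sum())
            df[col] = coerced
    table = PhenotypeTable(df)
    table.n_unparseable_cells = n_coerced  # type: ignore[attr-defined]
    return table


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    table.data.to_csv(path, sep=sep, index_label="id")


# ---------------------------------------------------------------------------
# validation findings


def validate_pedigree(ped: Pedigree) -> list[Finding]:
    """Report soft structural problems as findings (never raises).

    Checks: fathers coded non-male / mothers coded non-female, individuals
    with exactly one specified parent, isolated individuals (no parents and
    no offspring), and families split across multiple graph components.
    """
    findings: list[Finding] = []
    has_child: set[str] = set()
    for ind in ped.individuals:
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                has_child.add(pid)
        if ind.father_id is not None and ped[ind.father_id].sex != "male":
            findings.append(
                Finding(
                    "sex_inconsistent_parent",
                    ind.id,
                    f"father {ind.father_id!r} of {ind.id!r} is coded "
                    f"{ped[ind.father_id].sex}",
                )
            )
        if ind.mother_id is not None and ped[ind.mother_id].sex != "female":
            findings.append(
                Finding(
                    "sex_inconsistent_parent",
                    ind.id,
                    f"mother {ind.mother_id!r} of {ind.id!r} is coded "
                    f"{ped[ind.mother_id].sex}",
                )
            )
        if (ind.father_id is None) != (ind.mother_id is None):
            findings.append(
                Finding(
                    "half_parentage",
                    ind.id,
                    f"individual {ind.id!r} has exactly one specified parent",
                )
            )
    for ind in ped.individuals:
        if ind.is_founder and ind.id not in has_child:
            findings.append(
                Finding(
                    "isolated_individual",
                    ind.id,
                    f"individual {ind.id!r} has no parents and no offspring",
                )
            )
    # family label vs graph component structure
    g = ped.graph().to_undirected()
    for fam, members in ped.families().items():
        sub = g.subgraph(members)
        n_comp = nx.number_connected_components(sub) if members else 0
        if n_comp > 1:
            findings.append(
                Finding(
                    "multiple_components",
                    None,
                    f"family {fam!r} splits into {n_comp} graph components",
                )
            )
    return findings
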