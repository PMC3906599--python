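"""Containers and readers for longitudinal family phenotype, pedigree and genotype data.

The analysis dataset is a long-format table of person-visits nested in
families, linked to a pedigree and (optionally) to SNP genotypes.  Repeated
measures of HDL cholesterol are the response, weekly alcohol consumption the
interacting exposure, and age, sex, BMI and anti-lipid medication use the
common covariates.  The per-family cell ordering established here
(visit-major, then members in pedigree order) is the contract every
covariance builder relies on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PedigreeMember",
    "PhenotypeRecord",
    "GenotypeTable",
    "LongitudinalFamilyDataset",
    "read_phenotypes",
    "read_phenotype_table",
    "read_genotypes_ped",
    "read_dosage_tsv",
    "build_dataset",
    "subset_visits",
    "write_phenotype_csv",
    "write_ped_map",
    "DataError",
    "ParseError",
    "SchemaError",
    "LinkageError",
    "PedigreeError",
    "ConfigurationError",
]

PHENO_COLUMNS = (
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "visit",
    "age",
    "bmi",
    "alcohol",
    "med_use",
    "hdlc",
)

#: covariates that must be observed for a person-visit to enter the analysis
COMPLETE_CASE_FIELDS = ("hdlc", "alcohol", "age", "bmi", "med_use")


class DataError(ValueError):
    """Base class for data-layer failures."""


class ParseError(DataError):
    pass


class SchemaError(DataError):
    pass


class LinkageError(DataError):
    pass


class PedigreeError(DataError):
    pass


class ConfigurationError(DataError):
    pass


@dataclass(frozen=True)
class PedigreeMember:
    """One pedigree entry; a member with neither parent listed is a founder."""

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class PhenotypeRecord:
    """A single person-visit; numeric fields use NaN for missing."""

    family_id: str
    individual_id: str
    visit: int
    age: float
    sex: str
    bmi: float
    alcohol: float
    med_use: float
    hdlc: float

    def is_complete_case(self) -> bool:
        return not any(
            _isna(getattr(self, f)) for f in COMPLETE_CASE_FIELDS
        )


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


class GenotypeTable:
    """Additive minor-allele dosages (0/1/2, NaN missing) per individual x SNP."""

    def __init__(self, dosages: pd.DataFrame):
        if dosages.columns.duplicated().any():
            raise DataError("duplicate SNP ids in genotype table")
        if dosages.index.duplicated().any():
            raise DataError("duplicate individual ids in genotype table")
        vals = dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise DataError("dosages must be 0, 1, 2 or missing")
        self.dosages = dosages.astype(float)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.dosages.index)

    def dosage(self, snp_id: str) -> pd.Series:
        return self.dosages[snp_id]

    def maf(self, snp_id: str) -> float:
        d = self.dosages[snp_id].dropna()
        if len(d) == 0:
            return np.nan
        return float(d.sum() / (2 * len(d)))

    def __len__(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class FamilyLayout:
    """Observed cells of one family, visit-major then pedigree member order.

    ``cells`` holds (visit_pos, member_pos) pairs; ``full_indices`` maps each
    observed cell to its position ``visit_pos * n_members + member_pos`` in
    the complete T x n grid, which is the ordering a Kronecker product
    ``Sigma_visit (x) Omega_family`` produces.
    """

    family_id: str
    member_ids: tuple[str, ...]
    cells: tuple[tuple[int, int], ...]
    records: tuple[PhenotypeRecord, ...]

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def full_indices(self) -> np.ndarray:
        n = self.n_members
        return np.array([t * n + i for t, i in self.cells], dtype=np.intp)


class LongitudinalFamilyDataset:
    """Cross-referenced pedigree + complete-case phenotype records on a visit grid."""

    def __init__(
        self,
        members: Sequence[PedigreeMember],
        records: Sequence[PhenotypeRecord],
        visit_grid: Sequence[int],
    ):
        self.members = list(members)
        self.visit_grid = tuple(visit_grid)
        self.records = list(records)
        self._validate_pedigree()
        self.families = self._build_layouts()

    # -- construction -----------------------------------------------------
    def _validate_pedigree(self) -> None:
        by_id: dict[str, PedigreeMember] = {}
        fam_members: dict[str, set[str]] = {}
        for m in self.members:
            if m.individual_id in by_id:
                raise PedigreeError(f"duplicate individual id {m.individual_id!r}")
            by_id[m.individual_id] = m
            fam_members.setdefault(m.family_id, set()).add(m.individual_id)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in fam_members.get(m.family_id, ()):
                    raise PedigreeError(
                        f"parent {pid!r} of {m.individual_id!r} not in family {m.family_id!r}"
                    )
        # no individual is its own ancestor
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            state[iid] = 1
            m = by_id[iid]
            for pid in (m.father_id, m.mother_id):
                if pid is None:
                    continue
                if state.get(pid) == 1:
                    raise PedigreeError(f"pedigree cycle involving {pid!r}")
                if pid not in state:
                    visit(pid)
            state[iid] = 2

        for iid in by_id:
            if iid not in state:
                visit(iid)
        self._members_by_id = by_id

    def _build_layouts(self) -> dict[str, FamilyLayout]:
        grid_pos = {v: i for i, v in enumerate(self.visit_grid)}
        fam_member_order: dict[str, list[str]] = {}
        for m in self.members:
            fam_member_order.setdefault(m.family_id, []).append(m.individual_id)

        seen: set[tuple[str, int]] = set()
        per_fam: dict[str, dict[tuple[int, int], PhenotypeRecord]] = {}
        for r in self.records:
            if r.individual_id not in self._members_by_id:
                raise LinkageError(f"record individual {r.individual_id!r} absent from pedigree")
            if self._members_by_id[r.individual_id].family_id != r.family_id:
                raise LinkageError(
                    f"record family {r.family_id!r} disagrees with pedigree for {r.individual_id!r}"
                )
            if r.visit not in grid_pos:
                raise DataError(f"visit {r.visit} outside grid {self.visit_grid}")
            key = (r.individual_id, r.visit)
            if key in seen:
                raise DataError(f"duplicate record for individual {key[0]!r} visit {key[1]}")
            seen.add(key)
            if not r.is_complete_case():
                continue
            t = grid_pos[r.visit]
            i = fam_member_order[r.family_id].index(r.individual_id)
            per_fam.setdefault(r.family_id, {})[(t, i)] = r

        layouts: dict[str, FamilyLayout] = {}
        for fam_id in fam_member_order:  # deterministic pedigree order
            if fam_id not in per_fam:
                continue
            cellmap = per_fam[fam_id]
            cells = tuple(sorted(cellmap))  # visit-major, then member order
            layouts[fam_id] = FamilyLayout(
                family_id=fam_id,
                member_ids=tuple(fam_member_order[fam_id]),
                cells=cells,
                records=tuple(cellmap[c] for c in cells),
            )
        return layouts

    # -- summaries --------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return sum(f.n_cells for f in self.families.values())

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_individuals(self) -> int:
        ids = {r.individual_id for f in self.families.values() for r in f.records}
        return len(ids)

    @property
    def n_visits(self) -> int:
        return len(self.visit_grid)

    def member(self, individual_id: str) -> PedigreeMember:
        return self._members_by_id[individual_id]

    # -- derived datasets -------------------------------------------------
    def drop_individuals(self, individual_ids: Iterable[str]) -> "LongitudinalFamilyDataset":
        """Return a dataset without the given individuals' records (pedigree kept)."""
        drop = set(individual_ids)
        recs = [r for r in self.records if r.individual_id not in drop]
        return LongitudinalFamilyDataset(self.members, recs, self.visit_grid)

    def subset_visits(self, mode: str) -> "LongitudinalFamilyDataset":
        return subset_visits(self, mode)


def subset_visits(dataset: LongitudinalFamilyDataset, mode: str) -> LongitudinalFamilyDataset:
    """Build the 1-, 3- or 5-visit analysis dataset from a 5-visit one.

    ``last1`` keeps the most recent grid visit; ``alternate3`` keeps grid
    visits 1, 3 and 5 (1-based), dropping the alternates; ``all5`` is the
    identity.
    """
    grid = dataset.visit_grid
    if mode == "last1":
        keep = (grid[-1],)
    elif mode == "alternate3":
        if len(grid) != 5:
            raise ConfigurationError("alternate3 requires a 5-visit grid")
        keep = (grid[0], grid[2], grid[4])
    elif mode == "all5":
        if len(grid) != 5:
            raise ConfigurationError("all5 requires a 5-visit grid")
        return dataset
    else:
        raise ConfigurationError(f"unknown visit mode {mode!r}")
    recs = [r for r in dataset.records if r.visit in keep]
    return LongitudinalFamilyDataset(dataset.members, recs, keep)


def build_dataset(
    members: Sequence[PedigreeMember],
    records: Sequence[PhenotypeRecord],
    genotypes: GenotypeTable | None = None,
    visit_grid: Sequence[int] | None = None,
) -> LongitudinalFamilyDataset:
    """Cross-reference pedigree, records and (optionally) genotypes.

    The visit grid defaults to the sorted distinct visits present in the
    records.  Complete-case filtering over {response, exposure, common
    covariates} happens inside the dataset; genotype-missing individuals are
    only dropped per SNP at scan time.
    """
    if visit_grid is None:
        visit_grid = sorted({r.visit for r in records})
    ds = LongitudinalFamilyDataset(members, records, visit_grid)
    if genotypes is not None:
        known = {m.individual_id for m in members}
        stray = [i for i in genotypes.individual_ids if i not in known]
        if stray:
            raise LinkageError(f"genotyped individuals absent from pedigree: {stray[:5]}")
    return ds


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _opt_id(x) -> str | None:
    if x is None:
        return None
    s = str(x).strip()
    if s == "" or s == "0" or s.lower() == "nan":
        return None
    return s


def _sex(x, where: str) -> str:
    s = str(x).strip().lower()
    if s in ("male", "m", "1"):
        return "male"
    if s in ("female", "f", "2"):
        return "female"
    raise ParseError(f"unrecognised sex {x!r} at {where}")


def read_phenotype_table(
    path, visit_grid: Sequence[int] | None = None
) -> tuple[list[PedigreeMember], list[PhenotypeRecord]]:
    """Read the long-format phenotype CSV, returning pedigree members and records.

    Pedigree links (father_id/mother_id/sex) ride along on every row; the
    pedigree is the deduplicated set of (individual, parents, sex) entries in
    first-appearance order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype CSV missing columns: {missing}")
    extra = [c for c in df.columns if c not in PHENO_COLUMNS]
    if extra:
        raise SchemaError(f"unknown phenotype CSV columns: {extra}")

    members: list[PedigreeMember] = []
    seen: dict[str, PedigreeMember] = {}
    records: list[PhenotypeRecord] = []
    grid = set(visit_grid) if visit_grid is not None else None
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        where = f"line {pos}"
        try:
            visit = int(row.visit)
        except ValueError as e:
            raise ParseError(f"bad visit {row.visit!r} at {where}") from e
        if grid is not None and visit not in grid:
            raise DataError(f"visit {visit} outside grid at {where}")
        sex = _sex(row.sex, where)
        m = PedigreeMember(
            family_id=str(row.family_id),
            individual_id=str(row.individual_id),
            father_id=_opt_id(row.father_id),
            mother_id=_opt_id(row.mother_id),
            sex=sex,
        )
        prev = seen.get(m.individual_id)
        if prev is None:
            seen[m.individual_id] = m
            members.append(m)
        elif prev != m:
            raise ParseError(f"inconsistent pedigree entry for {m.individual_id!r} at {where}")

        def num(v, name):
            s = str(v).strip()
            if s == "" or s.lower() in ("na", "nan"):
                return float("nan")
            try:
                return float(s)
            except ValueError as e:
                raise ParseError(f"bad {name} {v!r} at {where}") from e

        rec = PhenotypeRecord(
            family_id=m.family_id,
            individual_id=m.individual_id,
            visit=visit,
            age=num(row.age, "age"),
            sex=sex,
            bmi=num(row.bmi, "bmi"),
            alcohol=num(row.alcohol, "alcohol"),
            med_use=num(row.med_use, "med_use"),
            hdlc=num(row.hdlc, "hdlc"),
        )
        if not _isna(rec.alcohol) and rec.alcohol < 0:
            raise DataError(f"negative alcohol at {where}")
        if not _isna(rec.bmi) and rec.bmi <= 0:
            raise DataError(f"non-positive BMI at {where}")
        records.append(rec)
    return members, records


def read_phenotypes(path, visit_grid: Sequence[int] | None = None) -> list[PhenotypeRecord]:
    """Records-only view of :func:`read_phenotype_table`."""
    return read_phenotype_table(path, visit_grid=visit_grid)[1]


def write_phenotype_csv(path, members: Sequence[PedigreeMember], records: Sequence[PhenotypeRecord]) -> None:
    by_id = {m.individual_id: m for m in members}
    rows = []
    for r in records:
        m = by_id[r.individual_id]
        rows.append(
            {
                "family_id": r.family_id,
                "individual_id": r.individual_id,
                "father_id": m.father_id or "",
                "mother_id": m.mother_id or "",
                "sex": r.sex,
                "visit": r.visit,
                "age": _fmt(r.age),
                "bmi": _fmt(r.bmi),
                "alcohol": _fmt(r.alcohol),
                "med_use": _fmt(r.med_use),
                "hdlc": _fmt(r.hdlc),
            }
        )
    pd.DataFrame(rows, columns=list(PHENO_COLUMNS)).to_csv(path, index=False)


def _fmt(x: float) -> str:
    if _isna(x):
        return ""
    return repr(float(x))


def read_genotypes_ped(ped_path, map_path) -> GenotypeTable:
    """Read PLINK text PED/MAP into additive minor-allele dosages.

    The minor allele is determined per SNP from the sample; ``0 0`` encodes a
    missing genotype.  More than two distinct alleles at a SNP is an error;
    a monomorphic SNP yields all-zero dosages with a logged warning.
    """
    snp_ids: list[str] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ParseError(f"MAP line {lineno}: expected >=2 columns")
            snp_ids.append(parts[1])
    n_snps = len(snp_ids)

    iids: list[str] = []
    alleles: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"PED line {lineno}: {len(parts)} fields, expected {6 + 2 * n_snps} "
                    f"for {n_snps} SNPs"
                )
            iids.append(parts[1])
            alleles.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)]
            )

    data = np.full((len(iids), n_snps), np.nan)
    for j, snp in enumerate(snp_ids):
        counts: dict[str, int] = {}
        for row in alleles:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise DataError(f"SNP {snp!r} has >2 alleles: {sorted(counts)}")
        if len(counts) == 0:
            warnings.warn(f"SNP {snp!r} entirely missing")
            continue
        if len(counts) == 1:
            warnings.warn(f"SNP {snp!r} is monomorphic")
            minor = None  # all non-missing dosages are 0
        else:
            (a1, c1), (a2, c2) = sorted(counts.items())
            # ties broken toward the lexicographically later allele
            minor = a2 if c2 <= c1 else a1
        for i, row in enumerate(alleles):
            x, y = row[j]
            if x == "0" or y == "0":
                continue
            data[i, j] = 0.0 if minor is None else float((x == minor) + (y == minor))
    df = pd.DataFrame(data, index=iids, columns=snp_ids)
    return GenotypeTable(df)


def write_ped_map(
    ped_path,
    map_path,
    genotypes: GenotypeTable,
    members: Sequence[PedigreeMember] | None = None,
) -> None:
    """Write dosages as PLINK text PED/MAP using synthetic alleles A (major) / B (minor)."""
    by_id = {m.individual_id: m for m in members} if members else {}
    with open(map_path, "w") as fh:
        for i, snp in enumerate(genotypes.snp_ids, start=1):
            fh.write(f"1\t{snp}\t0\t{i}\n")
    code = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}
    with open(ped_path, "w") as fh:
        for iid in genotypes.individual_ids:
            m = by_id.get(iid)
            fam = m.family_id if m else iid
            fat = (m.father_id or "0") if m else "0"
            mot = (m.mother_id or "0") if m else "0"
            sex = {"male": "1", "female": "2"}.get(m.sex, "0") if m else "0"
            fields = [fam, iid, fat, mot, sex, "-9"]
            for snp in genotypes.snp_ids:
                d = genotypes.dosages.at[iid, snp]
                fields.extend(("0", "0") if np.isnan(d) else code[d])
            fh.write(" ".join(fields) + "\n")


def read_dosage_tsv(path) -> GenotypeTable:
    """Read a dosage TSV: rows = individuals, columns = SNP ids, cells 0/1/2/NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    return GenotypeTable(df)
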