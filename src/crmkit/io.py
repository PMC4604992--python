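"""Genotype, pedigree, phenotype and relationship-matrix containers and file I/O.

The canonical interchange format for genotypes and square matrices is a
whitespace/tab-delimited text table; PLINK ``.raw`` and VCF are import-only
dialects.  Genotypes are coded as alternate-allele dosages 0/1/2 with ``-9``
as the internal missing sentinel (encoded as the character ``'3'`` in byte
strings fed to the compressor, keeping the alphabet small and unambiguous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -9
MISSING_CHAR = "3"

_VALID_CALLS = frozenset({0, 1, 2, MISSING})


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A container invariant was violated."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Animals x loci integer dosage matrix.

    Parameters
    ----------
    animal_ids : sequence of str
        Unique row identifiers.
    locus_ids : sequence of str
        Unique column identifiers.
    calls : ndarray of shape (n_animals, n_loci)
        Integer codes in {0, 1, 2} with :data:`MISSING` for no-calls.
    locus_map : DataFrame, optional
        One row per locus with columns ``chrom`` and ``pos`` (1-based);
        positions must be non-decreasing within a chromosome.
    """

    animal_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    locus_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D array")
        n, m = self.calls.shape
        if n != len(self.animal_ids) or m != len(self.locus_ids):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.locus_ids)} loci"
            )
        if len(set(self.animal_ids)) != n:
            raise ValidationError("animal_ids are not unique")
        if len(set(self.locus_ids)) != m:
            raise ValidationError("locus_ids are not unique")
        bad = ~np.isin(self.calls, list(_VALID_CALLS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype code {self.calls[i, j]} for animal "
                f"{self.animal_ids[i]} at locus {self.locus_ids[j]}"
            )
        if self.locus_map is not None:
            lm = self.locus_map
            if len(lm) != m:
                raise ValidationError("locus_map must have one entry per locus")
            for chrom, grp in lm.groupby("chrom", sort=False):
                if not np.all(np.diff(grp["pos"].to_numpy()) >= 0):
                    raise ValidationError(
                        f"positions on chromosome {chrom} are not non-decreasing"
                    )

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def row(self, animal: str | int) -> np.ndarray:
        """Return one animal's dosage vector (by id or positional index)."""
        if isinstance(animal, str):
            animal = self.animal_ids.index(animal)
        return self.calls[animal]

    def subset_loci(self, index: slice | Sequence[int]) -> "GenotypeMatrix":
        idx = np.arange(self.n_loci)[index]
        lm = self.locus_map.iloc[idx].reset_index(drop=True) if self.locus_map is not None else None
        return GenotypeMatrix(
            self.animal_ids,
            [self.locus_ids[i] for i in idx],
            self.calls[:, idx],
            locus_map=lm,
        )


@dataclass
class PedigreeTable:
    """Three-column pedigree (animal, sire, dam); ``None`` marks unknown parents."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=["animal", "sire", "dam"]).copy()
        for col in df.columns:
            df[col] = df[col].map(_norm_parent)
        if df["animal"].isna().any():
            raise ValidationError("pedigree contains a record with no animal id")
        if df["animal"].duplicated().any():
            dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
            raise ValidationError(f"duplicate pedigree record for animal {dup}")
        self.records = df
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            r.animal: tuple(p for p in (r.sire, r.dam) if p is not None)
            for r in self.records.itertuples()
        }
        WHITE, GREY, BLACK = 0, 1, 2
        state = {a: WHITE for a in parents}
        for start in parents:
            if state[start] != WHITE:
                continue
            stack = [(start, iter(parents.get(start, ())))]
            state[start] = GREY
            path = [start]
            while stack:
                node, it = stack[-1]
                for parent in it:
                    if parent not in parents:
                        continue
                    if state[parent] == GREY:
                        chain = " -> ".join(path + [parent])
                        raise ValidationError(f"pedigree cycle: {chain}")
                    if state[parent] == WHITE:
                        state[parent] = GREY
                        stack.append((parent, iter(parents.get(parent, ()))))
                        path.append(parent)
                        break
                else:
                    state[node] = BLACK
                    stack.pop()
                    path.pop()

    def animals(self) -> list[str]:
        return list(self.records["animal"])

    def parents_of(self, animal: str) -> tuple[str | None, str | None]:
        row = self.records.loc[self.records["animal"] == animal]
        if row.empty:
            return (None, None)
        r = row.iloc[0]
        return (r["sire"], r["dam"])

    def topological_order(self) -> list[str]:
        """All animals (including parents without records), parents first."""
        parents = {
            r.animal: (r.sire, r.dam) for r in self.records.itertuples()
        }
        order: list[str] = []
        seen: set[str] = set()

        def visit(a: str) -> None:
            if a in seen:
                return
            seen.add(a)
            for p in parents.get(a, (None, None)):
                if p is not None:
                    visit(p)
            order.append(a)

        for a in parents:
            visit(a)
        return order


def _norm_parent(v):
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    s = str(v).strip()
    if s in {"0", "", ".", "NA", "nan"}:
        return None
    return s


@dataclass
class PhenotypeTable:
    """One record per animal: trait value plus fixed-effect covariates."""

    data: pd.DataFrame
    trait: str = "trait"
    id_col: str = "animal"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        if self.id_col not in df.columns or self.trait not in df.columns:
            raise ValidationError(
                f"phenotype table needs columns {self.id_col!r} and {self.trait!r}"
            )
        df[self.id_col] = df[self.id_col].astype(str)
        if df[self.id_col].duplicated().any():
            raise ValidationError("more than one phenotype record per animal")
        observed = df[self.trait].notna()
        covars = [c for c in df.columns if c not in (self.id_col, self.trait)]
        if covars and df.loc[observed, covars].isna().any().any():
            raise ValidationError("covariates incomplete for phenotyped animals")
        self.data = df

    def animals(self) -> list[str]:
        return list(self.data[self.id_col])

    def values(self) -> np.ndarray:
        return self.data[self.trait].to_numpy(dtype=float)


SYMMETRY_TOL = 1e-10

MATRIX_KINDS = ("NRM", "GRM", "CRM1", "CRM2", "CRM3")


@dataclass
class RelationshipMatrix:
    """Square symmetric animal x animal similarity with a provenance tag."""

    animal_ids: list[str]
    values: np.ndarray
    kind: str = "GRM"

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} animal ids"
            )
        finite = np.isfinite(self.values)
        both = finite & finite.T
        if not np.allclose(
            self.values[both], self.values.T[both], atol=SYMMETRY_TOL, rtol=0.0
        ) or not (finite == finite.T).all():
            raise ValidationError("relationship matrix is not symmetric")

    def loc(self, a: str, b: str) -> float:
        i = self.animal_ids.index(a)
        j = self.animal_ids.index(b)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    missing_code: str | int = "NA",
) -> GenotypeMatrix:
    """Read genotypes from matrix TSV, PLINK ``.raw`` or VCF.

    VCF genotypes are converted to alternate-allele dosage (``0/1`` -> 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "matrix-TSV"):
        return _read_matrix_tsv(path, missing_code)
    if format in ("raw", "plink-raw"):
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _parse_call(token: str, missing_code: str, path: Path, lineno: int) -> int:
    if token == missing_code or token == str(MISSING):
        return MISSING
    if token in ("0", "1", "2"):
        return int(token)
    raise ValidationError(
        f"{path}:{lineno}: genotype code {token!r} is not 0/1/2 or missing"
    )


def _read_matrix_tsv(path: Path, missing_code: str | int) -> GenotypeMatrix:
    missing_code = str(missing_code)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    first = lines[0].split()
    # Header is optional: detect it by non-genotype tokens after the id column.
    has_header = any(
        tok not in ("0", "1", "2", missing_code, str(MISSING)) for tok in first[1:]
    )
    if has_header and len(lines) == 1:
        # a single line of bad codes is data, not a header
        has_header = False
    if has_header:
        locus_ids = first[1:]
        body = lines[1:]
    else:
        locus_ids = [f"L{i + 1}" for i in range(len(first) - 1)]
        body = lines
    animal_ids, rows = [], []
    width = len(locus_ids)
    for offset, line in enumerate(body):
        toks = line.split()
        lineno = offset + (2 if has_header else 1)
        if len(toks) - 1 != width:
            raise ParseError(
                f"{path}:{lineno}: expected {width} genotypes, found {len(toks) - 1}"
            )
        animal_ids.append(toks[0])
        rows.append([_parse_call(t, missing_code, path, lineno) for t in toks[1:]])
    return GenotypeMatrix(animal_ids, locus_ids, np.array(rows, dtype=np.int16))


_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing_meta = [c for c in _PLINK_META if c not in df.columns]
    if missing_meta:
        raise ParseError(f"{path}: not a PLINK .raw file (missing {missing_meta})")
    locus_ids = [c for c in df.columns if c not in _PLINK_META]
    calls = df[locus_ids].to_numpy()
    out = np.full(calls.shape, MISSING, dtype=np.int16)
    for code in ("0", "1", "2"):
        out[calls == code] = int(code)
    bad = ~(pd.isna(calls) | (calls == "NA") | np.isin(calls, ["0", "1", "2"]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: dosage {calls[i, j]!r} at {locus_ids[j]} is not 0/1/2/NA"
        )
    return GenotypeMatrix(list(df["IID"]), locus_ids, out)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    animal_ids = list(vcf.samples)
    locus_ids, rows, chroms, poss = [], [], [], []
    for var in vcf:
        locus_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gts012: 0/1/2 = dosage of the alternate allele, 3 = unknown
        gt = np.asarray(var.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING
        rows.append(gt)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    calls = np.array(rows, dtype=np.int16).T
    locus_map = pd.DataFrame({"chrom": chroms, "pos": poss})
    return GenotypeMatrix(animal_ids, locus_ids, calls, locus_map=locus_map)


def write_genotypes(g: GenotypeMatrix, path: str | Path, missing_code: str = "NA") -> None:
    """Write the canonical genotype TSV (header of locus ids, one row per animal)."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(g.locus_ids) + "\n")
        for i, aid in enumerate(g.animal_ids):
            toks = [missing_code if c == MISSING else str(c) for c in g.calls[i]]
            fh.write(aid + "\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# pedigree / phenotype / matrix tables
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> PedigreeTable:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, header=None, comment="#")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: pedigree needs three columns (animal sire dam)")
    first = df.iloc[0]
    if list(first[:3]) == ["animal", "sire", "dam"]:
        df = df.iloc[1:]
    df = df.iloc[:, :3]
    df.columns = ["animal", "sire", "dam"]
    return PedigreeTable(df.reset_index(drop=True))


def write_pedigree(p: PedigreeTable, path: str | Path) -> None:
    df = p.records.fillna("0")
    df.to_csv(path, sep="\t", index=False, header=False)


def read_phenotypes(path: str | Path, trait: str = "trait", id_col: str = "animal") -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable(df, trait=trait, id_col=id_col)


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    p.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_matrix(m: RelationshipMatrix, path: str | Path) -> None:
    """Write a square TSV with id header row/column at full (round-trip) precision."""
    try:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(m.animal_ids) + "\n")
            for aid, row in zip(m.animal_ids, m.values):
                fh.write(aid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write relationship matrix to {path}: {exc}") from exc


def read_matrix(path: str | Path, kind: str = "GRM") -> RelationshipMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        ids = header[1:]
        rows, row_ids = [], []
        for lineno, line in enumerate(fh, start=2):
            toks = line.split()
            if not toks:
                continue
            if len(toks) - 1 != len(ids):
                raise ParseError(f"{path}:{lineno}: ragged matrix row")
            row_ids.append(toks[0])
            rows.append([float(t) for t in toks[1:]])
    if row_ids != ids:
        raise ParseError(f"{path}: row ids do not match column ids")
    return RelationshipMatrix(ids, np.array(rows), kind=kind)


# ---------------------------------------------------------------------------
# byte encoding and the printed 5 x 30 toy example
# ---------------------------------------------------------------------------


def encode_genotype_string(row: np.ndarray, sentinel: str = MISSING_CHAR) -> bytes:
    """Encode one animal's dosages as one byte per locus ('0'/'1'/'2').

    Missing calls become ``sentinel`` so string length always equals locus
    count and compression stays deterministic.
    """
    row = np.asarray(row)
    chars = row.astype("U1").tolist() if row.size else []
    out = []
    for c, v in zip(chars, row.tolist()):
        out.append(sentinel if v == MISSING else c)
    return "".join(out).encode("ascii")


_TOY_STRINGS = {
    "1": "0" * 10 + "1" * 10 + "2" * 10,
    "2": "2" * 3 + "0" * 10 + "1" * 10 + "2" * 7,
    "3": ("0" * 3 + "1" * 3 + "2" * 3) * 3 + "012",
    "4": ("0" * 3 + "1" * 2 + "2" * 3 + "1") * 3 + "012",
    "5": "012" * 10,
}

_TOY_PEDIGREE = [
    # U1 and U2 are un-genotyped; Animal 1 is the product of a
    # parent-offspring mating (dam U1 is also the dam of its sire, Animal 2).
    ("U1", None, None),
    ("U2", None, None),
    ("2", None, "U1"),
    ("1", "2", "U1"),
    ("3", None, "U2"),
    ("4", None, "U2"),
    ("5", None, None),
]


def toy_fixture(pedigree: list[tuple] | None = None) -> tuple[GenotypeMatrix, PedigreeTable]:
    """The worked 5-animal, 30-SNP example, expanded from its run-length form.

    Animal 1 is 10 homozygous-reference calls, 10 heterozygous, 10 homozygous
    alternate; animal 5 alternates ``0,1,2`` ten times; animals 2-4 are
    run-length variations in between.  A plausible toy pedigree accompanies it
    (override via ``pedigree``).
    """
    calls = np.array([[int(c) for c in _TOY_STRINGS[a]] for a in "12345"], dtype=np.int16)
    g = GenotypeMatrix(list("12345"), [f"L{i + 1}" for i in range(30)], calls)
    ped = PedigreeTable(pd.DataFrame(pedigree or _TOY_PEDIGREE, columns=["animal", "sire", "dam"]))
    return g, ped
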