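"""Relationship matrices: pedigree NRM, marker GRM, and compression CRM1/2/3.

The GRM follows VanRaden: ``ZZ' / (2 * sum p(1-p))`` with genotypes centered
column-wise by twice the sample B-allele frequency.  Centering is what makes
negative entries (pairs less alike than random HWE draws) possible and scales
the diagonal to average ~1 on an outbred population.

The CRMs convert compression distance into similarity three ways:

* CRM1 — Shepard's universal distance-to-similarity law ``s = a * exp(-b d)``
  with a = 2.5, b = 5 (chosen so similarities span the 0-1 range of
  correlations on real SNP data).
* CRM2 — a linear rescaling: diagonal ``mean(d_self) / d_self`` (averaging to
  1 with a spread that reflects inbreeding), off-diagonal
  ``1.75 * [1 - (d - min d) / (max d - min d)]``.
* CRM3 — correlation of per-window compression-efficiency profiles, an
  NCD-free route to relatedness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compress import CompressorConfig, NCDMatrix, compressed_size, compression_efficiency
from .io import (
    MISSING,
    GenotypeMatrix,
    PedigreeTable,
    RelationshipMatrix,
    ValidationError,
    encode_genotype_string,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele frequencies and the GRM
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencies:
    """Per-locus B-allele frequency and heterozygosity weight p(1-p)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValidationError("allele frequencies must lie in [0, 1]")

    @property
    def het_weight(self) -> np.ndarray:
        return self.p * (1.0 - self.p)

    @property
    def denominator(self) -> float:
        """The VanRaden scaling constant 2 * sum p(1-p)."""
        return float(2.0 * self.het_weight.sum())


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Sample B-allele frequencies: half the mean non-missing dosage per locus."""
    calls = g.calls.astype(float)
    mask = g.calls != MISSING
    n_obs = mask.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmin(n_obs))
        raise ValidationError(f"locus {g.locus_ids[j]} has no non-missing calls")
    calls[~mask] = 0.0
    p = calls.sum(axis=0) / n_obs / 2.0
    return AlleleFrequencies(p)


def grm(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix ``ZZ' / (2 sum p(1-p))``.

    Missing calls are replaced by the locus mean dosage (they contribute
    zero after centering).  Monomorphic loci contribute zero to both the
    numerator and the denominator and are retained.
    """
    if g.n_animals < 2:
        raise ValueError("GRM needs at least two animals")
    af = allele_frequencies(g)
    den = af.denominator
    if den == 0.0:
        raise ValidationError("all loci are monomorphic; GRM denominator is zero")
    z = g.calls.astype(float)
    z[g.calls == MISSING] = np.nan
    z = z - 2.0 * af.p
    z = np.nan_to_num(z, nan=0.0)
    values = z @ z.T / den
    values = 0.5 * (values + values.T)  # exact symmetry against fp round-off
    return RelationshipMatrix(list(g.animal_ids), values, kind="GRM")


# ---------------------------------------------------------------------------
# pedigree NRM (tabular method)
# ---------------------------------------------------------------------------


def nrm(
    pedigree: PedigreeTable,
    max_generations: int | None = None,
    animals: list[str] | None = None,
) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    ``a_jj = 1 + a(sire, dam)/2`` and ``a_ij = (a(i, sire_j) + a(i, dam_j))/2``
    processed in an order where parents precede offspring.  With
    ``max_generations`` the pedigree is truncated: ancestors more than that
    many generations above a recorded animal are treated as unknown founders
    (a study choice, not part of the method; default traces everything).
    ``animals`` restricts the returned matrix (all ancestors still contribute).
    """
    order = pedigree.topological_order()
    parent_of = {r.animal: [r.sire, r.dam] for r in pedigree.records.itertuples()}

    if max_generations is not None:
        # Generations above: an animal at height >= max_generations from the
        # youngest descendants becomes a founder.
        height: dict[str, int] = {a: 0 for a in order}
        for a in reversed(order):
            for p in parent_of.get(a, (None, None)):
                if p is not None:
                    height[p] = max(height[p], height[a] + 1)
        for a in order:
            if height.get(a, 0) >= max_generations:
                parent_of[a] = [None, None]

    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    a_mat = np.zeros((n, n))
    for j, animal in enumerate(order):
        sire, dam = (parent_of.get(animal) or [None, None])[:2]
        si = idx.get(sire) if sire is not None else None
        di = idx.get(dam) if dam is not None else None
        for i in range(j):
            val = 0.0
            if si is not None:
                val += 0.5 * a_mat[i, si]
            if di is not None:
                val += 0.5 * a_mat[i, di]
            a_mat[i, j] = a_mat[j, i] = val
        inb = 0.5 * a_mat[si, di] if (si is not None and di is not None) else 0.0
        a_mat[j, j] = 1.0 + inb
    full = RelationshipMatrix(order, a_mat, kind="NRM")
    if animals is None:
        return full
    sel = [idx[a] for a in animals]
    return RelationshipMatrix(animals, a_mat[np.ix_(sel, sel)], kind="NRM")


# ---------------------------------------------------------------------------
# compression relationship matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Crm1Config:
    """Shepard transform parameters ``s = scale * exp(-rate * d)``."""

    scale: float = 2.5
    rate: float = 5.0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.rate <= 0:
            raise ValueError("Shepard parameters must be positive")


def crm1(d: NCDMatrix, cfg: Crm1Config | None = None) -> RelationshipMatrix:
    """CRM1: element-wise Shepard similarity ``2.5 exp(-5 d)`` of the NCD matrix."""
    cfg = cfg or Crm1Config()
    values = cfg.scale * np.exp(-cfg.rate * d.d)
    return RelationshipMatrix(list(d.animal_ids), values, kind="CRM1")


@dataclass(frozen=True)
class Crm2Config:
    """Linear rescaling parameters for CRM2.

    ``range_scope`` picks the pairs over which Min(d)/Max(d) are taken:
    ``"all"`` (diagonal included; keeps off-diagonal values within 0-0.75 on
    real data because self-self distances are the smallest) or ``"offdiag"``.
    """

    c: float = 1.75
    range_scope: str = "all"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("off-diagonal coefficient must be positive")
        if self.range_scope not in ("all", "offdiag"):
            raise ValueError("range_scope must be 'all' or 'offdiag'")


def crm2(d: NCDMatrix, cfg: Crm2Config | None = None) -> RelationshipMatrix:
    """CRM2: mean-scaled diagonal, linearly rescaled off-diagonal.

    Diagonal entries are ``mean(d_self) / d_self`` — averaging exactly 1, with
    spread that reflects inbreeding.  Off-diagonal entries are
    ``c * [1 - (d - Min) / (Max - Min)]``.
    """
    cfg = cfg or Crm2Config()
    n = len(d.animal_ids)
    if n < 2:
        raise ValueError("CRM2 needs at least two animals")
    diag = np.diag(d.d)
    off_mask = ~np.eye(n, dtype=bool)
    scope = d.d if cfg.range_scope == "all" else d.d[off_mask]
    d_min, d_max = float(np.min(scope)), float(np.max(scope))
    if d_max == d_min:
        raise ValidationError("degenerate NCD range: Max(d) equals Min(d)")
    values = cfg.c * (1.0 - (d.d - d_min) / (d_max - d_min))
    with np.errstate(divide="ignore"):
        values[np.diag_indices(n)] = np.mean(diag) / diag
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(list(d.animal_ids), values, kind="CRM2")


def window_ce_matrix(
    g: GenotypeMatrix,
    window_size: int = 50,
    cfg: CompressorConfig | None = None,
) -> np.ndarray:
    """Animals x windows matrix of per-window compression efficiency.

    Windows are consecutive, non-overlapping blocks of ``window_size`` SNPs;
    the final partial window is retained.
    """
    if window_size < 2:
        raise ValueError("window_size must be at least 2")
    cfg = cfg or CompressorConfig()
    n_win = -(-g.n_loci // window_size)
    out = np.empty((g.n_animals, n_win))
    for w in range(n_win):
        block = g.calls[:, w * window_size : (w + 1) * window_size]
        for i in range(g.n_animals):
            enc = encode_genotype_string(block[i])
            res = compressed_size(enc, cfg)
            s_a = res.net_compressed_size if cfg.net_overhead else res.compressed_size
            out[i, w] = compression_efficiency(res.raw_size, s_a)
    return out


def crm3(
    g: GenotypeMatrix,
    window_size: int = 50,
    cfg: CompressorConfig | None = None,
    method: str = "pearson",
) -> RelationshipMatrix:
    """CRM3: correlation of per-window CE profiles between animals.

    Animals whose windows all compress equally well (constant profile) have no
    defined correlation; their pairwise entries are NaN and logged.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    ce = window_ce_matrix(g, window_size, cfg)
    if ce.shape[1] < 2:
        raise ValueError("CRM3 needs at least two windows")
    prof = ce
    if method == "spearman":
        from scipy.stats import rankdata

        prof = np.apply_along_axis(rankdata, 1, ce)
    sd = prof.std(axis=1)
    flagged = [g.animal_ids[i] for i in np.flatnonzero(sd == 0)]
    if flagged:
        logger.warning("CRM3 undefined for constant-CE animals: %s", flagged)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.corrcoef(prof)
    values[np.diag_indices_from(values)] = 1.0
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(list(g.animal_ids), values, kind="CRM3")


# ---------------------------------------------------------------------------
# pedigree-class summaries
# ---------------------------------------------------------------------------


def summarize_by_pedigree_class(
    nrm_matrix: RelationshipMatrix,
    other: RelationshipMatrix,
    decimals: int = 6,
) -> pd.DataFrame:
    """Summarise another matrix's entries by distinct pedigree relationship.

    For every distinct NRM value (1, 0.5, 0.25, ...; rounded to ``decimals``)
    the count of pairs and the mean/SD/min/max of the corresponding entries of
    ``other`` are reported, diagonal included as the self-self class.
    """
    if nrm_matrix.animal_ids != other.animal_ids:
        raise ValidationError("matrices cover different animals")
    n = len(nrm_matrix.animal_ids)
    iu = np.triu_indices(n)
    classes = np.round(nrm_matrix.values[iu], decimals)
    vals = other.values[iu]
    df = pd.DataFrame({"nrm_value": classes, "value": vals})
    g = df.groupby("nrm_value")["value"]
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean": g.mean(),
            "sd": g.std(ddof=1).fillna(0.0),
            "min": g.min(),
            "max": g.max(),
        }
    ).reset_index()
    return out.sort_values("nrm_value", ascending=True, ignore_index=True)
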