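"""Synthetic data with the statistical structure the methods assume.

Three generators, all fully determined by their seed:

* pedigreed populations — Hardy-Weinberg founders and Mendelian gene-dropping
  through full-sib / half-sib family designs, so marker relatedness has the
  classical expectations (0.5 full sibs, 0.25 half sibs);
* two diverged populations — Balding-Nichols frequency draws at a target FST,
  optionally with a localised sweep (one region driven toward fixation in
  population A, the classic hard-sweep footprint of lost diversity);
* phenotypes — ``y = X b + u + e`` with the genetic values drawn from a given
  relationship-matrix covariance (or from causal loci when genotypes are
  supplied), at a chosen heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PedigreeTable, PhenotypeTable, RelationshipMatrix
from .mixedmodel import bend_psd


@dataclass
class SimConfig:
    """Shared generator settings (the study conditions, not tuning dials)."""

    seed: int | None = None
    n_loci: int = 5000
    freq_range: tuple[float, float] = (0.05, 0.95)
    # family design
    n_halfsib_families: int = 0
    halfsib_size: int = 0
    n_fullsib_families: int = 0
    fullsib_size: int = 0
    n_unrelated: int = 0
    # probability of recombination between adjacent loci at meiosis;
    # 0.5 means unlinked (the default), small values give long IBD segments
    recomb_fraction: float = 0.5
    # founder haplotype structure: with a finite ancestral pool each founder
    # haplotype is a block mosaic of `ancestral_haplotypes` ancestral ones
    # (simple linkage disequilibrium); None draws alleles independently
    ancestral_haplotypes: int | None = None
    ancestral_switch: float = 0.005
    # two-population mode
    n_per_pop: int = 100
    fst: float = 0.2
    sweep_span: tuple[int, int] | None = None
    sweep_intensity: float = 0.9
    # trait architecture
    h2: float = 0.4
    sigma2_p: float = 100.0
    n_causal: int = 100
    n_groups: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.sweep_span is not None:
            a, b = self.sweep_span
            if not (0 <= a < b <= self.n_loci):
                raise ValueError("sweep span outside the locus range")


def _founder_freqs(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    lo, hi = cfg.freq_range
    return rng.uniform(lo, hi, size=cfg.n_loci)


def _hwe_genotypes(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    return (rng.random((n, p.size)) < p).astype(np.int16) + (
        rng.random((n, p.size)) < p
    ).astype(np.int16)


def _hwe_haplotypes(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """Two phased haplotypes (rows) for one founder."""
    return (rng.random((2, p.size)) < p).astype(np.int16)


class _FounderSampler:
    """Draws founder haplotypes, either independent-locus or as block
    mosaics of a finite ancestral haplotype pool (simple LD)."""

    def __init__(self, rng: np.random.Generator, p: np.ndarray, cfg: "SimConfig"):
        self.rng = rng
        self.p = p
        self.cfg = cfg
        self.pool = (
            (rng.random((cfg.ancestral_haplotypes, p.size)) < p).astype(np.int16)
            if cfg.ancestral_haplotypes
            else None
        )

    def haplotypes(self) -> np.ndarray:
        if self.pool is None:
            return _hwe_haplotypes(self.rng, self.p)
        out = np.empty((2, self.p.size), dtype=np.int16)
        k = self.pool.shape[0]
        for h in range(2):
            switch = self.rng.random(self.p.size) < self.cfg.ancestral_switch
            switch[0] = True
            # ancestral source index per block
            src = self.rng.integers(k, size=int(switch.sum()))
            idx = np.repeat(src, np.diff(np.append(np.flatnonzero(switch), self.p.size)))
            out[h] = self.pool[idx, np.arange(self.p.size)]
        return out


def _meiosis(rng: np.random.Generator, haps: np.ndarray, c: float) -> np.ndarray:
    """One gamete: a recombination mosaic of the parent's two haplotypes.

    ``c`` is the per-interval recombination fraction; 0.5 reduces to an
    independent coin flip per locus (unlinked loci).
    """
    m = haps.shape[1]
    switch = rng.random(m) < c
    switch[0] = rng.random() < 0.5
    phase = np.cumsum(switch) % 2
    return haps[phase, np.arange(m)]


def simulate_pedigree_population(cfg: SimConfig) -> tuple[GenotypeMatrix, PedigreeTable]:
    """Founders in HWE plus gene-dropped half-sib and full-sib families.

    A half-sib family is one sire mated to ``halfsib_size`` unrelated dams,
    one offspring each; a full-sib family is one sire-dam pair with
    ``fullsib_size`` offspring.  Loci are unlinked (the 0.5/0.25 relatedness
    expectations hold either way, and unlinked loci minimise Monte-Carlo
    variance).  Genotypes are returned for offspring and founders alike; the
    pedigree records exactly the matings performed.
    """
    if cfg.n_halfsib_families * cfg.halfsib_size == 0 and (
        cfg.n_fullsib_families * cfg.fullsib_size == 0
    ) and cfg.n_unrelated == 0:
        raise ValueError("empty family design")
    rng = np.random.default_rng(cfg.seed)
    p = _founder_freqs(rng, cfg)
    sampler = _FounderSampler(rng, p, cfg)
    ids: list[str] = []
    haps: dict[str, np.ndarray] = {}
    records: list[tuple[str, str | None, str | None]] = []

    def add_founder(tag: str) -> str:
        aid = f"{tag}{len(ids) + 1}"
        ids.append(aid)
        haps[aid] = sampler.haplotypes()
        records.append((aid, None, None))
        return aid

    def add_offspring(tag: str, sire: str, dam: str) -> str:
        aid = f"{tag}{len(ids) + 1}"
        ids.append(aid)
        haps[aid] = np.vstack(
            [
                _meiosis(rng, haps[sire], cfg.recomb_fraction),
                _meiosis(rng, haps[dam], cfg.recomb_fraction),
            ]
        )
        records.append((aid, sire, dam))
        return aid

    for _ in range(cfg.n_halfsib_families):
        sire = add_founder("S")
        for _ in range(cfg.halfsib_size):
            dam = add_founder("D")
            add_offspring("H", sire, dam)
    for _ in range(cfg.n_fullsib_families):
        sire = add_founder("S")
        dam = add_founder("D")
        for _ in range(cfg.fullsib_size):
            add_offspring("F", sire, dam)
    for _ in range(cfg.n_unrelated):
        add_founder("U")

    g = GenotypeMatrix(
        ids, [f"L{j + 1}" for j in range(cfg.n_loci)], np.array([haps[a].sum(axis=0) for a in ids])
    )
    ped = PedigreeTable(pd.DataFrame(records, columns=["animal", "sire", "dam"]))
    return g, ped


def halfsib_pairs(ped: PedigreeTable) -> list[tuple[str, str]]:
    """All pairs of recorded offspring sharing exactly one parent."""
    return _sib_pairs(ped, shared=1)


def fullsib_pairs(ped: PedigreeTable) -> list[tuple[str, str]]:
    """All pairs of recorded offspring sharing both parents."""
    return _sib_pairs(ped, shared=2)


def _sib_pairs(ped: PedigreeTable, shared: int) -> list[tuple[str, str]]:
    import itertools

    kids = [
        (r.animal, frozenset(p for p in (r.sire, r.dam) if p is not None))
        for r in ped.records.itertuples()
        if r.sire is not None or r.dam is not None
    ]
    out = []
    for (a, pa), (b, pb) in itertools.combinations(kids, 2):
        if len(pa & pb) == shared and a != b:
            out.append((a, b))
    return out


def simulate_two_populations(cfg: SimConfig) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Two populations diverged to a target FST, optionally with a sweep in A.

    Shared ancestral frequencies are drawn uniformly from ``freq_range``;
    each population's frequencies then follow the Balding-Nichols model,
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, whose between-population variance
    matches the target FST.  Within ``sweep_span`` population A's frequencies
    are pushed toward fixation of the locally major allele by
    ``sweep_intensity``, producing the regional loss of diversity of a hard
    sweep.
    """
    rng = np.random.default_rng(cfg.seed)
    p_anc = _founder_freqs(rng, cfg)
    if cfg.fst > 0:
        f = cfg.fst
        shape1 = p_anc * (1.0 - f) / f
        shape2 = (1.0 - p_anc) * (1.0 - f) / f
        pa = rng.beta(shape1, shape2)
        pb = rng.beta(shape1, shape2)
    else:
        pa, pb = p_anc.copy(), p_anc.copy()
    if cfg.sweep_span is not None:
        lo, hi = cfg.sweep_span
        target = (pa[lo:hi] > 0.5).astype(float)
        pa[lo:hi] = (1.0 - cfg.sweep_intensity) * pa[lo:hi] + cfg.sweep_intensity * target
    locus_ids = [f"L{j + 1}" for j in range(cfg.n_loci)]
    g_a = GenotypeMatrix(
        [f"A{i + 1}" for i in range(cfg.n_per_pop)], locus_ids, _hwe_genotypes(rng, pa, cfg.n_per_pop)
    )
    g_b = GenotypeMatrix(
        [f"B{i + 1}" for i in range(cfg.n_per_pop)], locus_ids, _hwe_genotypes(rng, pb, cfg.n_per_pop)
    )
    return g_a, g_b


def simulate_phenotype(
    source: RelationshipMatrix | GenotypeMatrix,
    cfg: SimConfig,
) -> tuple[PhenotypeTable, dict]:
    """Phenotypes ``y = X b + u + e`` at heritability ``h2``.

    With a relationship matrix, genetic values are multivariate normal with
    covariance ``C s2_u`` (non-PSD C is bent first); with genotypes, they are
    sums of ``n_causal`` random additive locus effects rescaled to the target
    genetic variance.  Fixed effects are an intercept plus one
    ``n_groups``-level contemporary group, exercising the usual
    fixed-effect-absorption path.  The realised components are returned for
    oracle checks.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma2_u = cfg.h2 * cfg.sigma2_p
    sigma2_e = (1.0 - cfg.h2) * cfg.sigma2_p
    if isinstance(source, RelationshipMatrix):
        ids = list(source.animal_ids)
        n = len(ids)
        C, _ = bend_psd(source.values, 1e-8)
        w, U = np.linalg.eigh(0.5 * (C + C.T))
        L = U * np.sqrt(np.maximum(w, 0.0))
        u = L @ rng.standard_normal(n) * np.sqrt(sigma2_u)
    else:
        ids = list(source.animal_ids)
        n = len(ids)
        causal = rng.choice(source.n_loci, size=min(cfg.n_causal, source.n_loci), replace=False)
        effects = rng.standard_normal(causal.size)
        raw = source.calls[:, causal].astype(float) @ effects
        raw = raw - raw.mean()
        sd = raw.std(ddof=1)
        u = raw / sd * np.sqrt(sigma2_u) if sd > 0 else np.zeros(n)
    groups = rng.integers(cfg.n_groups, size=n)
    beta = np.concatenate([[50.0], rng.normal(0.0, 5.0, size=cfg.n_groups - 1)])
    X = np.column_stack(
        [np.ones(n)] + [(groups == k + 1).astype(float) for k in range(cfg.n_groups - 1)]
    )
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=n)
    y = X @ beta + u + e
    pheno = PhenotypeTable(
        pd.DataFrame({"animal": ids, "trait": y, "cg": [f"g{k}" for k in groups]})
    )
    truth = {
        "u": u,
        "e": e,
        "beta": beta,
        "X": X,
        "sigma2_u": sigma2_u,
        "sigma2_e": sigma2_e,
        "h2": cfg.h2,
    }
    return pheno, truth
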