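"""Selection-signature scan: per-window population CEh and per-SNP FST.

The genome is partitioned into non-overlapping windows of consecutive SNPs
(default 50).  For each window and each of two populations the pooled
genotype string (animals concatenated in id order) is compressed, its CE
divided by the window's mean observed heterozygosity (CEh), and the
between-population CEh difference reported next to the window-average FST.
Swept regions — a haplotype driven toward fixation in one population —
show up as extreme CEh differences and elevated FST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compress import CompressorConfig, compressed_size, compression_efficiency
from .io import MISSING, GenotypeMatrix, encode_genotype_string

logger = logging.getLogger(__name__)

FST_ESTIMATORS = ("weir-cockerham", "hudson", "nei")


@dataclass(frozen=True)
class Window:
    """Half-open locus-index interval [start, stop)."""

    index: int
    start: int
    stop: int

    @property
    def size(self) -> int:
        return self.stop - self.start


def partition_windows(locus_count: int, window_size: int = 50) -> list[Window]:
    """Disjoint consecutive windows covering all loci; the last may be partial."""
    if window_size < 2:
        raise ValueError("window_size must be at least 2")
    if locus_count < 1:
        raise ValueError("need at least one locus")
    return [
        Window(i, s, min(s + window_size, locus_count))
        for i, s in enumerate(range(0, locus_count, window_size))
    ]


def _window_het(block: np.ndarray) -> float:
    """Mean over animals of the proportion of heterozygous non-missing calls."""
    mask = block != MISSING
    counts = mask.sum(axis=1)
    het = np.zeros(block.shape[0])
    ok = counts > 0
    het[ok] = (block == 1).sum(axis=1)[ok] / counts[ok]
    return float(het[ok].mean()) if ok.any() else 0.0


def population_window_ceh(
    g_pop: GenotypeMatrix,
    window: Window,
    cfg: CompressorConfig | None = None,
) -> tuple[float, bool]:
    """Population-level CEh of one window.

    The window's calls from every animal (in id order, animal-major) are
    concatenated into one byte string, compressed, and the CE divided by the
    window's mean heterozygosity.  Returns ``(value, flagged)``; a window with
    zero heterozygosity is flagged undefined (NaN), never silently zero —
    the heterozygosity correction is what keeps runs of homozygosity from
    dominating the statistic, so it cannot be skipped.
    """
    cfg = cfg or CompressorConfig()
    block = g_pop.calls[:, window.start : window.stop]
    pooled = b"".join(encode_genotype_string(block[i]) for i in range(block.shape[0]))
    res = compressed_size(pooled, cfg)
    s_a = res.net_compressed_size if cfg.net_overhead else res.compressed_size
    ce = compression_efficiency(res.raw_size, s_a)
    het = _window_het(block)
    if het == 0.0:
        return float("nan"), True
    return ce / het, False


def _freq_and_n(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP alternate-allele frequency and diploid sample size."""
    mask = block != MISSING
    n = mask.sum(axis=0)
    calls = np.where(mask, block, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = calls.sum(axis=0) / (2.0 * n)
    return p, n


def fst_snp(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    estimator: str = "weir-cockerham",
    h1: float | None = None,
    h2: float | None = None,
) -> tuple[float, bool]:
    """Two-population per-SNP FST.

    ``p`` are B-allele frequencies and ``n`` diploid sample sizes.  The
    default is the Weir–Cockerham variance-components estimator (``h`` are
    the observed heterozygote proportions; Hardy-Weinberg expectations are
    used when not supplied).  Negative estimates are retained, not truncated.
    Returns ``(value, flagged)``: a SNP monomorphic for the same allele in
    both populations is defined as 0 and flagged.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be at least 2")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if estimator not in FST_ESTIMATORS:
        raise ValueError(f"unknown FST estimator {estimator!r}")
    if estimator == "weir-cockerham":
        if h1 is None:
            h1 = 2.0 * p1 * (1.0 - p1)
        if h2 is None:
            h2 = 2.0 * p2 * (1.0 - p2)
        num, den = _wc_components(p1, p2, n1, n2, h1, h2)
        if den == 0.0:
            return 0.0, True
        return num / den, False
    if estimator == "hudson":
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den == 0.0:
            return 0.0, True
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        return num / den, False
    # Nei Gst
    p_bar = 0.5 * (p1 + p2)
    ht = 2.0 * p_bar * (1.0 - p_bar)
    if ht == 0.0:
        return 0.0, True
    hs = p1 * (1 - p1) + p2 * (1 - p2)
    return (ht - hs) / ht, False


def _wc_components(p1, p2, n1, n2, h1, h2):
    """Weir & Cockerham (1984) a and a+b+c for two populations, one SNP."""
    r = 2.0
    n_bar = (n1 + n2) / r
    nc = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / nc) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - s2 * (r - 1.0) / r
        - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, a + b + c


def window_fst(values: np.ndarray, flags: np.ndarray | None = None) -> tuple[float, bool]:
    """Window FST: the arithmetic mean of the usable per-SNP values."""
    values = np.asarray(values, dtype=float)
    keep = np.ones(values.size, dtype=bool) if flags is None else ~np.asarray(flags, bool)
    if not keep.any():
        return float("nan"), True
    return float(values[keep].mean()), False


def multilocus_fst(
    g_a: GenotypeMatrix,
    g_b: GenotypeMatrix,
) -> float:
    """Genome-wide Weir-Cockerham FST as the ratio of summed components.

    Summing the variance components across loci before taking the ratio is
    the standard multi-locus combination; averaging per-SNP ratios instead is
    biased toward zero and is used here only within windows, where the paper
    prescribes it.
    """
    pa, na = _freq_and_n(g_a.calls)
    pb, nb = _freq_and_n(g_b.calls)
    ha = (g_a.calls == 1).sum(axis=0) / np.maximum((g_a.calls != MISSING).sum(axis=0), 1)
    hb = (g_b.calls == 1).sum(axis=0) / np.maximum((g_b.calls != MISSING).sum(axis=0), 1)
    num = den = 0.0
    for j in range(g_a.n_loci):
        a, abc = _wc_components(pa[j], pb[j], int(na[j]), int(nb[j]), float(ha[j]), float(hb[j]))
        num += a
        den += abc
    if den == 0.0:
        return 0.0
    return num / den


def sweep_scan(
    g_a: GenotypeMatrix,
    g_b: GenotypeMatrix,
    window_size: int = 50,
    cfg: CompressorConfig | None = None,
    estimator: str = "weir-cockerham",
    diff: str = "a-b",
) -> pd.DataFrame:
    """Full two-population scan: per-window CEh for each population, the CEh
    difference, the window-average FST and its rank (1 = largest FST).

    Windows where either population's CEh is undefined (zero heterozygosity)
    are flagged and excluded from ranking.  ``diff`` selects the sign
    convention (``"a-b"`` or ``"b-a"``).
    """
    if g_a.locus_ids != g_b.locus_ids:
        raise ValueError("populations are genotyped at different loci")
    if diff not in ("a-b", "b-a"):
        raise ValueError("diff must be 'a-b' or 'b-a'")
    cfg = cfg or CompressorConfig()
    windows = partition_windows(g_a.n_loci, window_size)

    pa, na = _freq_and_n(g_a.calls)
    pb, nb = _freq_and_n(g_b.calls)
    # Observed heterozygote proportions feed the WC estimator.
    ha = (g_a.calls == 1).sum(axis=0) / np.maximum((g_a.calls != MISSING).sum(axis=0), 1)
    hb = (g_b.calls == 1).sum(axis=0) / np.maximum((g_b.calls != MISSING).sum(axis=0), 1)
    snp_fst = np.empty(g_a.n_loci)
    snp_flag = np.zeros(g_a.n_loci, dtype=bool)
    for j in range(g_a.n_loci):
        snp_fst[j], snp_flag[j] = fst_snp(
            pa[j], pb[j], int(na[j]), int(nb[j]), estimator, h1=float(ha[j]), h2=float(hb[j])
        )

    rows = []
    for w in windows:
        ceh_a, flag_a = population_window_ceh(g_a, w, cfg)
        ceh_b, flag_b = population_window_ceh(g_b, w, cfg)
        wf, wf_flag = window_fst(snp_fst[w.start : w.stop], snp_flag[w.start : w.stop])
        d = (ceh_a - ceh_b) if diff == "a-b" else (ceh_b - ceh_a)
        row = {
            "window": w.index,
            "start": w.start,
            "stop": w.stop,
            "partial": w.size < window_size,
            "ceh_a": ceh_a,
            "ceh_b": ceh_b,
            "ceh_diff": d,
            "fst": wf,
            "flagged": flag_a or flag_b or wf_flag,
        }
        if g_a.locus_map is not None:
            lm = g_a.locus_map.iloc[w.start : w.stop]
            row["chrom"] = lm["chrom"].iloc[0]
            row["pos_start"] = int(lm["pos"].iloc[0])
            row["pos_stop"] = int(lm["pos"].iloc[-1])
        rows.append(row)
    table = pd.DataFrame(rows)
    ranked = table.loc[~table["flagged"], "fst"]
    ranks = ranked.rank(ascending=False, method="first")
    table["fst_rank"] = np.nan
    table.loc[ranks.index, "fst_rank"] = ranks
    return table


def rank_outliers(table: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """The ``top_k`` un-flagged windows by |CEh difference|, ties in genomic order."""
    usable = table[~table["flagged"]].copy()
    usable["abs_diff"] = usable["ceh_diff"].abs()
    usable = usable.sort_values(
        ["abs_diff", "window"], ascending=[False, True], kind="mergesort"
    )
    return usable.head(top_k).drop(columns="abs_diff").reset_index(drop=True)
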