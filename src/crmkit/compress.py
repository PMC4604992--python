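"""Compression statistics on genotype strings: CE, CEh and NCD.

All statistics are driven by a DEFLATE compressor (the algorithm behind
gzip).  The compressed size of a genotype byte string approximates its
algorithmic information content: regular strings (runs of homozygosity,
repeated haplotype motifs) compress well, irregular ones do not.

* CE, compression efficiency: ``(S_B - S_A) / S_B`` — the fractional size
  reduction of a string under lossless compression.
* CEh: CE divided by genome-wide heterozygosity, de-emphasising
  compressibility that is driven purely by runs of homozygosity.
* NCD, normalised compression distance:
  ``(Z(xy) - min{Z(x), Z(y)}) / max{Z(x), Z(y)}``, where ``Z`` is compressed
  size and ``xy`` the concatenation — small when the information in one
  string describes the other.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import MISSING, GenotypeMatrix, ValidationError, encode_genotype_string

logger = logging.getLogger(__name__)

__all__ = [
    "CompressorConfig",
    "CompressionResult",
    "NCDMatrix",
    "compressed_size",
    "compression_efficiency",
    "heterozygosity",
    "ceh_individual",
    "ncd",
    "ncd_matrix",
]


@dataclass(frozen=True)
class CompressorConfig:
    """Deterministic DEFLATE settings.

    ``container`` selects the stream framing: ``"gzip"`` writes a gzip header
    and CRC trailer with no filename or timestamp (sizes are therefore
    machine-independent), ``"raw"`` is a bare DEFLATE stream.  With
    ``net_overhead`` the size of compressing the empty string under the same
    settings is subtracted, which matters for toy-scale inputs where the
    container would otherwise dominate.
    """

    level: int = 6
    container: str = "gzip"
    net_overhead: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 9:
            raise ValueError("compression level must be in 1..9")
        if self.container not in ("gzip", "raw"):
            raise ValueError("container must be 'gzip' or 'raw'")

    @property
    def _wbits(self) -> int:
        return 31 if self.container == "gzip" else -15


@dataclass(frozen=True)
class CompressionResult:
    raw_size: int
    compressed_size: int
    net_compressed_size: int

    def __post_init__(self) -> None:
        if self.raw_size < 0 or self.compressed_size <= 0:
            raise ValidationError("sizes must be positive")


def _deflate_size(data: bytes, cfg: CompressorConfig) -> int:
    co = zlib.compressobj(cfg.level, zlib.DEFLATED, cfg._wbits)
    return len(co.compress(data) + co.flush())


@lru_cache(maxsize=None)
def _overhead(cfg: CompressorConfig) -> int:
    return _deflate_size(b"", cfg)


def compressed_size(data: bytes, cfg: CompressorConfig | None = None) -> CompressionResult:
    """Compress ``data`` and report raw, compressed and overhead-net sizes."""
    cfg = cfg or CompressorConfig()
    s_a = _deflate_size(bytes(data), cfg)
    net = max(0, s_a - _overhead(cfg))
    return CompressionResult(len(data), s_a, net)


def compression_efficiency(s_b: float, s_a: float) -> float:
    """CE = (S_B - S_A) / S_B, the fractional size reduction."""
    if s_b <= 0:
        raise ValueError("uncompressed size S_B must be positive")
    return (s_b - s_a) / s_b


def heterozygosity(row: np.ndarray) -> float:
    """Proportion of non-missing calls that are heterozygous (code 1)."""
    row = np.asarray(row)
    ok = row != MISSING
    if not ok.any():
        raise ValueError("heterozygosity is undefined for an all-missing row")
    return float(np.mean(row[ok] == 1))


def _row_ce(row: np.ndarray, cfg: CompressorConfig) -> float:
    enc = encode_genotype_string(row)
    res = compressed_size(enc, cfg)
    s_a = res.net_compressed_size if cfg.net_overhead else res.compressed_size
    return compression_efficiency(res.raw_size, s_a)


def ceh_individual(row: np.ndarray, cfg: CompressorConfig | None = None) -> float:
    """Heterozygosity-corrected compression efficiency of one genotype row.

    Returns NaN (flagged undefined, never silently zero) when the row has no
    heterozygous calls, since CE/Het is then a division by zero.
    """
    cfg = cfg or CompressorConfig()
    het = heterozygosity(np.asarray(row))
    if het == 0.0:
        logger.warning("CEh undefined: row has zero heterozygosity")
        return float("nan")
    return _row_ce(np.asarray(row), cfg) / het


def ncd(x: bytes, y: bytes, cfg: CompressorConfig | None = None, symmetrize: bool = True) -> float:
    """Normalised compression distance between two byte strings.

    Uses raw compressed sizes (container included), as the distance formula
    prescribes.  DEFLATE is order-sensitive on concatenation, so by default
    the two concatenation orders are averaged.
    """
    if not x or not y:
        raise ValueError("NCD requires non-empty sequences")
    cfg = cfg or CompressorConfig()
    z_x = compressed_size(x, cfg).compressed_size
    z_y = compressed_size(y, cfg).compressed_size
    z_xy = compressed_size(x + y, cfg).compressed_size
    if symmetrize:
        z_xy = 0.5 * (z_xy + compressed_size(y + x, cfg).compressed_size)
    return (z_xy - min(z_x, z_y)) / max(z_x, z_y)


@dataclass
class NCDMatrix:
    """All pairwise NCD values, including the self-self diagonal.

    For non-degenerate genotype data the diagonal (an animal against itself)
    is the smallest entry in its row: nothing describes a string better than
    the string itself.
    """

    animal_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.animal_ids)
        if self.d.shape != (n, n):
            raise ValidationError("NCD matrix shape does not match animal ids")
        if (self.d < 0).any():
            raise ValidationError("NCD values must be non-negative")

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.animal_ids), dtype=bool)
        return self.d[mask]


def ncd_matrix(
    g: GenotypeMatrix,
    cfg: CompressorConfig | None = None,
    symmetrize: bool = True,
) -> NCDMatrix:
    """Pairwise NCD across a genotyped population (self-self pairs included)."""
    if g.n_animals < 2:
        raise ValueError("NCD matrix needs at least two animals")
    cfg = cfg or CompressorConfig()
    enc = [encode_genotype_string(g.calls[i]) for i in range(g.n_animals)]
    z = np.array([compressed_size(e, cfg).compressed_size for e in enc], dtype=float)
    n = g.n_animals
    d = np.zeros((n, n))
    for i in range(n):
        # Self-self: Z(xx) with the same compressor; small but positive.
        z_ii = compressed_size(enc[i] + enc[i], cfg).compressed_size
        d[i, i] = (z_ii - z[i]) / z[i]
    for i, j in itertools.combinations(range(n), 2):
        z_xy = compressed_size(enc[i] + enc[j], cfg).compressed_size
        if symmetrize:
            z_xy = 0.5 * (z_xy + compressed_size(enc[j] + enc[i], cfg).compressed_size)
        val = (z_xy - min(z[i], z[j])) / max(z[i], z[j])
        d[i, j] = d[j, i] = val
    d[d < 0] = 0.0  # DEFLATE can shave a byte below min(Z); clamp at the metric floor
    return NCDMatrix(list(g.animal_ids), d)
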