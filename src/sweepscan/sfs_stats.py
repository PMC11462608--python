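"""Site-frequency-spectrum statistics in sliding windows.

Estimators: pairwise diversity (theta-pi), Watterson's theta (S/a1), the
homozygosity-weighted theta-H, Tajima's D and Fay & Wu's H.  D uses all
biallelic sites; H is restricted to polarized (ancestral-known) sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeMatrix, Polarity


@dataclass(frozen=True)
class TajimaConstants:
    """Sample-size constants for the variance of theta-pi minus theta-W."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Constants a1..e2 for a sample of ``n`` haplotypes (n >= 4)."""
    if n < 4:
        raise ValueError(f"need n >= 4 haplotypes for D, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass(frozen=True)
class WindowSpec:
    """Half-open genomic interval [start, end) in bp."""

    chrom: str | None
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SFSWindowResult:
    window: WindowSpec
    n_snps: int
    S: int
    pi: float
    theta_w: float
    theta_h: float
    tajima_d: float  # NaN when undefined
    faywu_h: float  # NaN when undefined
    n_polarized_sites: int

    @property
    def pi_per_bp(self) -> float:
        return self.pi / self.window.length if self.window.length else math.nan


def window_sfs_stats(
    m: HaplotypeMatrix,
    window: WindowSpec | None = None,
    min_snps: int = 0,
) -> SFSWindowResult:
    """SFS statistics over the sites of ``m`` (already restricted to a window).

    With x_j the derived (or ALT, when unpolarized) count at site j and n
    haplotypes:

    * theta-pi = sum_j x_j (n - x_j) / C(n, 2)
    * theta-W = S / a1
    * D = (theta-pi - theta-W) / sqrt(e1 S + e2 S (S - 1)), NaN when S = 0
      or the window holds fewer than ``min_snps`` sites
    * theta-H = sum over polarized j of 2 x_j^2 / (n (n - 1))
    * H = theta-pi(polarized sites only) - theta-H, NaN with no polarized site
    """
    n = m.n_haplotypes
    if n < 4:
        raise ValueError(f"need n >= 4 haplotypes, got {n}")
    if window is None:
        lo = int(m.positions[0]) if m.n_sites else 0
        hi = int(m.positions[-1]) + 1 if m.n_sites else 1
        window = WindowSpec(chrom=m.chrom, start=lo, end=hi)

    x = m.derived_counts.astype(np.float64)
    pairs = n * (n - 1) / 2.0
    pi = float(np.sum(x * (n - x)) / pairs)
    seg = (x > 0) & (x < n)
    S = int(seg.sum())

    const = tajima_constants(n)
    theta_w = S / const.a1
    if S == 0 or m.n_sites < min_snps:
        tajima_d = math.nan
    else:
        var = const.e1 * S + const.e2 * S * (S - 1)
        tajima_d = (pi - theta_w) / math.sqrt(var)

    pol = np.array([s.polarity is not Polarity.UNPOLARIZED for s in m.sites], dtype=bool)
    n_pol = int(pol.sum())
    if n_pol == 0 or m.n_sites < min_snps:
        theta_h = 0.0 if n_pol == 0 else math.nan
        faywu_h = math.nan
        if n_pol:
            theta_h = float(np.sum(2.0 * x[pol] ** 2) / (n * (n - 1)))
    else:
        xp = x[pol]
        theta_h = float(np.sum(2.0 * xp**2) / (n * (n - 1)))
        pi_pol = float(np.sum(xp * (n - xp)) / pairs)
        faywu_h = pi_pol - theta_h

    return SFSWindowResult(
        window=window,
        n_snps=m.n_sites,
        S=S,
        pi=pi,
        theta_w=theta_w,
        theta_h=theta_h,
        tajima_d=tajima_d,
        faywu_h=faywu_h,
        n_polarized_sites=n_pol,
    )


def iter_windows(
    positions: np.ndarray, window_bp: int, step_bp: int
) -> Iterator[tuple[int, int]]:
    """Half-open window starts anchored at floor(min_pos / step) * step."""
    if len(positions) == 0:
        return
    first = (int(positions[0]) // step_bp) * step_bp
    last = int(positions[-1])
    start = first
    while start <= last:
        yield start, start + window_bp
        start += step_bp


def sliding_scan(
    m: HaplotypeMatrix,
    window_bp: int = 5000,
    step_bp: int = 1000,
    min_snps: int = 3,
) -> list[SFSWindowResult]:
    """SFS statistics in sliding windows of ``window_bp`` at ``step_bp``.

    Windows with fewer than ``min_snps`` sites still report S and pi but
    leave D and H undefined.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window_bp >= step_bp >= 1")
    results = []
    for start, end in iter_windows(m.positions, window_bp, step_bp):
        sub = m.window(start, end)
        spec = WindowSpec(chrom=m.chrom, start=start, end=end)
        results.append(window_sfs_stats(sub, window=spec, min_snps=min_snps))
    return results


def results_to_frame(results: list[SFSWindowResult]) -> pd.DataFrame:
    """Tabulate window results for TSV export (NaN rendered as NA downstream)."""
    return pd.DataFrame(
        {
            "chrom": [r.window.chrom for r in results],
            "start": [r.window.start for r in results],
            "end": [r.window.end for r in results],
            "n_snps": [r.n_snps for r in results],
            "S": [r.S for r in results],
            "pi": [r.pi for r in results],
            "pi_per_bp": [r.pi_per_bp for r in results],
            "theta_w": [r.theta_w for r in results],
            "tajima_d": [r.tajima_d for r in results],
            "faywu_h": [r.faywu_h for r in results],
        }
    )
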