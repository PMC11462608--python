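"""Population differentiation: Hudson FST, the population branch statistic
(PBS) and pairwise LD r-squared on phased haplotypes."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeMatrix, PopulationPanel

log = logging.getLogger(__name__)


def hudson_fst_site(
    p1: float, n1: int, p2: float, n2: int
) -> tuple[float, float, float]:
    """Hudson's FST estimator at one site, with finite-sample correction.

    numerator  = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    Returns (numerator, denominator, fst); fst is NaN when the denominator
    is zero.  ``n1``/``n2`` are haplotype counts.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 haplotypes per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    fst = num / den if den != 0 else math.nan
    return num, den, fst


def fst_window(
    numerators: np.ndarray | list[float], denominators: np.ndarray | list[float]
) -> float:
    """Multi-site FST as the ratio of averages: sum(num) / sum(den).

    NaN when every denominator is zero.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    total_den = float(np.nansum(den))
    if total_den == 0:
        return math.nan
    return float(np.nansum(num) / total_den)


@dataclass(frozen=True)
class PBSResult:
    """Per-site PBS for focal population A against references B and C."""

    variant_id: str | None
    pos: int
    p_focal: float
    p_ref1: float
    p_ref2: float
    fst_ab: float
    fst_ac: float
    fst_bc: float
    t_ab: float
    t_ac: float
    t_bc: float
    pbs: float


def _branch_length(fst: float, clamp_eps: float) -> float:
    clamped = min(max(fst, 0.0), 1.0 - clamp_eps)
    return -math.log(1.0 - clamped)


def pbs_from_fst(
    fst_ab: float, fst_ac: float, fst_bc: float, clamp_eps: float = 1e-8
) -> tuple[float, float, float, float]:
    """Branch lengths and PBS from three pairwise FST values.

    Each FST is clamped into [0, 1 - clamp_eps], transformed to
    T = -ln(1 - FST), and pbs = (t_ab + t_ac - t_bc) / 2.  Returns
    (t_ab, t_ac, t_bc, pbs); NaN propagates from any undefined input.
    """
    if any(not math.isfinite(f) for f in (fst_ab, fst_ac, fst_bc)):
        return math.nan, math.nan, math.nan, math.nan
    t_ab = _branch_length(fst_ab, clamp_eps)
    t_ac = _branch_length(fst_ac, clamp_eps)
    t_bc = _branch_length(fst_bc, clamp_eps)
    return t_ab, t_ac, t_bc, (t_ab + t_ac - t_bc) / 2.0


def pbs_scan(
    m: HaplotypeMatrix,
    panel: PopulationPanel,
    focal: str,
    ref1: str,
    ref2: str,
    clamp_eps: float = 1e-8,
) -> list[PBSResult]:
    """Per-site PBS for ``focal`` against reference populations ``ref1``/``ref2``.

    Sites monomorphic in the pooled three populations, or with an undefined
    FST in any pair, are skipped (counts logged).  Population codes may be
    populations or superpopulations but must be disjoint.
    """
    groups = {}
    for code in (focal, ref1, ref2):
        samples = panel.samples_in(code)
        if not samples:
            raise ValueError(f"population code {code!r} unknown to panel")
        groups[code] = samples
    for a, b in ((focal, ref1), (focal, ref2), (ref1, ref2)):
        overlap = set(groups[a]) & set(groups[b])
        if overlap:
            raise ValueError(f"populations {a!r} and {b!r} overlap: {sorted(overlap)[:3]}")

    subs = {code: m.take_samples(groups[code]) for code in groups}
    counts = {code: subs[code].derived_counts for code in groups}
    sizes = {code: subs[code].n_haplotypes for code in groups}

    results: list[PBSResult] = []
    n_skipped = 0
    pooled = sum(counts.values())
    pooled_n = sum(sizes.values())
    for j, site in enumerate(m.sites):
        if pooled[j] == 0 or pooled[j] == pooled_n:
            n_skipped += 1
            continue
        p = {code: counts[code][j] / sizes[code] for code in groups}
        _, _, fab = hudson_fst_site(p[focal], sizes[focal], p[ref1], sizes[ref1])
        _, _, fac = hudson_fst_site(p[focal], sizes[focal], p[ref2], sizes[ref2])
        _, _, fbc = hudson_fst_site(p[ref1], sizes[ref1], p[ref2], sizes[ref2])
        if any(not math.isfinite(f) for f in (fab, fac, fbc)):
            n_skipped += 1
            continue
        t_ab, t_ac, t_bc, pbs = pbs_from_fst(fab, fac, fbc, clamp_eps=clamp_eps)
        results.append(
            PBSResult(
                variant_id=site.variant_id,
                pos=site.pos,
                p_focal=float(p[focal]),
                p_ref1=float(p[ref1]),
                p_ref2=float(p[ref2]),
                fst_ab=fab,
                fst_ac=fac,
                fst_bc=fbc,
                t_ab=t_ab,
                t_ac=t_ac,
                t_bc=t_bc,
                pbs=pbs,
            )
        )
    if n_skipped:
        log.info("pbs_scan: skipped %d sites (monomorphic or undefined FST)", n_skipped)
    return results


def ld_r2(
    m: HaplotypeMatrix | np.ndarray, site_i: int, site_j: int
) -> float:
    """Haplotype LD r^2 between two polymorphic sites.

    r^2 = D^2 / (p_i (1 - p_i) p_j (1 - p_j)) with D = p_ij - p_i p_j,
    estimated directly from phased haplotype frequencies.  ``m`` may be a
    HaplotypeMatrix or a raw 0/1 haplotype-by-site array.
    """
    calls = m.calls if isinstance(m, HaplotypeMatrix) else np.asarray(m)
    ci = calls[:, site_i].astype(float)
    cj = calls[:, site_j].astype(float)
    p_i, p_j = ci.mean(), cj.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise ValueError("both sites must be polymorphic in the matrix")
    p_ij = float(np.mean(ci * cj))
    d = p_ij - p_i * p_j
    return float(d * d / (p_i * (1 - p_i) * p_j * (1 - p_j)))


def pbs_to_frame(results: list[PBSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "pos": [r.pos for r in results],
            "p_focal": [r.p_focal for r in results],
            "p_ref1": [r.p_ref1 for r in results],
            "p_ref2": [r.p_ref2 for r in results],
            "fst_ab": [r.fst_ab for r in results],
            "fst_ac": [r.fst_ac for r in results],
            "fst_bc": [r.fst_bc for r in results],
            "pbs": [r.pbs for r in results],
        }
    )
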