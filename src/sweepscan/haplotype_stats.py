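"""Extended haplotype homozygosity and the per-SNP iHS / nSL statistics.

EHH at a distance from a core SNP is the probability that two random
haplotypes carrying the same core allele are identical over the whole
interval.  iHS integrates EHH over physical distance on the ancestral and
derived backgrounds; nSL does the analogous computation in units of
segregating sites.  Raw log-ratios are standardized within derived-allele
frequency bins.

Sign convention: unstd = ln(iHH_ancestral / iHH_derived), so a sweep on the
derived background yields negative scores.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeMatrix, Polarity

log = logging.getLogger(__name__)


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class AlleleClass(enum.Enum):
    ANCESTRAL = "ancestral"
    DERIVED = "derived"


class ScoreStatus(enum.Enum):
    OK = "ok"
    EDGE_TRUNCATED = "edge_truncated"
    GAP_SKIPPED = "gap_skipped"
    MAF_FILTERED = "maf_filtered"


@dataclass(frozen=True)
class EHHCurve:
    """EHH decay outward from a core SNP for one allele class and side."""

    core_index: int
    side: Side
    allele_class: AlleleClass
    distances: np.ndarray  # bp from core, starting at 0
    ehh: np.ndarray  # values in [0, 1], ehh[0] == 1
    truncated: bool = False  # hit data end / max extension with ehh >= cutoff
    gap_aborted: bool = False  # an inter-SNP gap exceeded max_gap_bp

    def __post_init__(self) -> None:
        if len(self.distances) != len(self.ehh) or len(self.ehh) == 0:
            raise ValueError("curve needs matching, non-empty distance/ehh arrays")
        if self.ehh[0] != 1.0:
            raise ValueError("EHH at distance 0 must be 1")


@dataclass
class HaplotypeScore:
    """Per-core-SNP haplotype-homozygosity score (iHS or nSL)."""

    core_index: int
    variant_id: str | None
    pos: int
    derived_freq: float
    statistic: str  # "ihs" or "nsl"
    anc_stat: float = math.nan  # iHH_A or SL_A
    der_stat: float = math.nan  # iHH_D or SL_D
    unstd: float = math.nan
    std: float = math.nan
    status: ScoreStatus = ScoreStatus.OK


@dataclass(frozen=True)
class StandardizationTable:
    """Per-frequency-bin mean/sd used to standardize raw scores."""

    n_bins: int
    bin_edges: np.ndarray  # length n_bins + 1, partition of (0, 1)
    means: np.ndarray  # NaN for unpopulated bins
    sds: np.ndarray
    counts: np.ndarray


def _ehh_from_labels(labels: np.ndarray, n_pairs: float) -> float:
    counts = np.bincount(labels)
    same = np.sum(counts * (counts - 1)) / 2.0
    return float(same / n_pairs)


def ehh_curve(
    m: HaplotypeMatrix,
    core: int,
    allele_class: AlleleClass,
    side: Side,
    cutoff: float = 0.05,
    max_extend_bp: int = 1_000_000,
    max_gap_bp: int = 200_000,
) -> EHHCurve:
    """EHH decay curve from a core SNP, walking SNP by SNP outward.

    The curve starts at (0, 1), includes the first point with EHH below
    ``cutoff`` (its truncation point) and stops there.  Reaching the data
    end or ``max_extend_bp`` with EHH still >= cutoff marks the curve
    truncated; an inter-SNP gap > ``max_gap_bp`` marks it gap-aborted.
    """
    target = 1 if allele_class is AlleleClass.DERIVED else 0
    carriers = np.flatnonzero(m.calls[:, core] == target)
    c = len(carriers)
    if c < 2:
        raise ValueError(
            f"allele class {allele_class.value} has {c} carriers at core {core}; need >= 2"
        )
    n_pairs = c * (c - 1) / 2.0
    pos = m.positions
    step = 1 if side is Side.RIGHT else -1
    labels = np.zeros(c, dtype=np.int64)
    distances = [0.0]
    ehh_vals = [1.0]
    truncated = False
    gap_aborted = False

    j = core + step
    prev_pos = pos[core]
    while 0 <= j < m.n_sites:
        gap = abs(int(pos[j]) - int(prev_pos))
        if gap > max_gap_bp:
            gap_aborted = True
            break
        dist = abs(int(pos[j]) - int(pos[core]))
        if dist > max_extend_bp:
            truncated = True
            break
        key = labels * 2 + m.calls[carriers, j]
        _, labels = np.unique(key, return_inverse=True)
        e = _ehh_from_labels(labels, n_pairs)
        distances.append(float(dist))
        ehh_vals.append(e)
        if e < cutoff:
            break
        prev_pos = pos[j]
        j += step
    else:
        # ran off the chromosome with EHH still at or above cutoff
        if ehh_vals[-1] >= cutoff:
            truncated = True

    return EHHCurve(
        core_index=core,
        side=side,
        allele_class=allele_class,
        distances=np.asarray(distances),
        ehh=np.asarray(ehh_vals),
        truncated=truncated,
        gap_aborted=gap_aborted,
    )


def integrate_ihh(curve: EHHCurve, gap_scale_bp: int = 20_000) -> float:
    """Trapezoidal area under the EHH curve from the core to its truncation.

    A segment spanning a gap g > ``gap_scale_bp`` contributes its trapezoid
    area scaled by gap_scale_bp / g (the selscan gap penalty).
    """
    d, e = curve.distances, curve.ehh
    area = 0.0
    for k in range(1, len(d)):
        g = d[k] - d[k - 1]
        seg = (e[k] + e[k - 1]) / 2.0 * g
        if g > gap_scale_bp:
            seg *= gap_scale_bp / g
        area += seg
    return area


def _class_sizes(m: HaplotypeMatrix, core: int) -> tuple[int, int]:
    n_der = int(m.derived_counts[core])
    return m.n_haplotypes - n_der, n_der


def ihs_scan(
    m: HaplotypeMatrix,
    maf_min: float = 0.05,
    cutoff: float = 0.05,
    max_extend_bp: int = 1_000_000,
    max_gap_bp: int = 200_000,
    gap_scale_bp: int = 20_000,
    trunc_ok: bool = False,
) -> list[HaplotypeScore]:
    """Unstandardized iHS for every polarized core SNP passing the MAF filter.

    Cores with min(p, 1-p) <= maf_min are emitted with status MAF_FILTERED
    and no score.  Cores whose EHH reaches the data end (or max extension)
    before dropping below ``cutoff`` are skipped as EDGE_TRUNCATED unless
    ``trunc_ok``, in which case the integral up to the truncation point is
    used.  A gap larger than ``max_gap_bp`` skips the core (GAP_SKIPPED).
    """
    scores: list[HaplotypeScore] = []
    n = m.n_haplotypes
    n_unpolarized = 0
    for core, site in enumerate(m.sites):
        if site.polarity is Polarity.UNPOLARIZED:
            n_unpolarized += 1
            continue
        p = m.derived_counts[core] / n
        score = HaplotypeScore(
            core_index=core,
            variant_id=site.variant_id,
            pos=site.pos,
            derived_freq=float(p),
            statistic="ihs",
        )
        n_anc, n_der = _class_sizes(m, core)
        if min(p, 1 - p) <= maf_min or min(n_anc, n_der) < 2:
            score.status = ScoreStatus.MAF_FILTERED
            scores.append(score)
            continue
        curves = [
            ehh_curve(m, core, ac, side, cutoff=cutoff,
                      max_extend_bp=max_extend_bp, max_gap_bp=max_gap_bp)
            for ac in (AlleleClass.ANCESTRAL, AlleleClass.DERIVED)
            for side in (Side.LEFT, Side.RIGHT)
        ]
        if any(c.gap_aborted for c in curves):
            score.status = ScoreStatus.GAP_SKIPPED
            scores.append(score)
            continue
        if any(c.truncated for c in curves) and not trunc_ok:
            score.status = ScoreStatus.EDGE_TRUNCATED
            scores.append(score)
            continue
        ihh_a = sum(integrate_ihh(c, gap_scale_bp) for c in curves[:2])
        ihh_d = sum(integrate_ihh(c, gap_scale_bp) for c in curves[2:])
        if ihh_a <= 0 or ihh_d <= 0:
            score.status = ScoreStatus.EDGE_TRUNCATED
            scores.append(score)
            continue
        score.anc_stat = ihh_a
        score.der_stat = ihh_d
        score.unstd = math.log(ihh_a / ihh_d)
        scores.append(score)
    if n_unpolarized:
        log.info("ihs_scan: skipped %d unpolarized sites", n_unpolarized)
    return scores


def _sl_class(m: HaplotypeMatrix, core: int, target: int, cap: int) -> float:
    """Mean, over carrier pairs, of the SNP count of the maximal identity
    interval containing the core (capped at ``cap`` SNPs per side).

    Uses the identity  mean L = 1 + sum_d EHH_left(d) + sum_d EHH_right(d),
    with d in SNP steps, since a pair extends past step d on a side exactly
    when it is still in one identity group there.
    """
    carriers = np.flatnonzero(m.calls[:, core] == target)
    c = len(carriers)
    if c < 2:
        raise ValueError(f"allele class has {c} carriers at core {core}; need >= 2")
    n_pairs = c * (c - 1) / 2.0
    total = 1.0
    for step in (-1, 1):
        labels = np.zeros(c, dtype=np.int64)
        j = core + step
        taken = 0
        while 0 <= j < m.n_sites and taken < cap:
            key = labels * 2 + m.calls[carriers, j]
            _, labels = np.unique(key, return_inverse=True)
            e = _ehh_from_labels(labels, n_pairs)
            if e == 0.0:
                break
            total += e
            taken += 1
            j += step
    return total


def nsl_scan(
    m: HaplotypeMatrix,
    maf_min: float = 0.05,
    max_extend_snps: int = 100,
) -> list[HaplotypeScore]:
    """Unstandardized nSL for every polarized core SNP passing the MAF filter.

    SL for an allele class is the mean, over carrier pairs, of the number of
    consecutive SNPs in the maximal interval containing the core over which
    the pair is identical, capped at ``max_extend_snps`` per side;
    unstd = ln(SL_A / SL_D).
    """
    scores: list[HaplotypeScore] = []
    n = m.n_haplotypes
    for core, site in enumerate(m.sites):
        if site.polarity is Polarity.UNPOLARIZED:
            continue
        p = m.derived_counts[core] / n
        score = HaplotypeScore(
            core_index=core,
            variant_id=site.variant_id,
            pos=site.pos,
            derived_freq=float(p),
            statistic="nsl",
        )
        n_anc, n_der = _class_sizes(m, core)
        if min(p, 1 - p) <= maf_min or min(n_anc, n_der) < 2:
            score.status = ScoreStatus.MAF_FILTERED
            scores.append(score)
            continue
        sl_a = _sl_class(m, core, 0, max_extend_snps)
        sl_d = _sl_class(m, core, 1, max_extend_snps)
        score.anc_stat = sl_a
        score.der_stat = sl_d
        score.unstd = math.log(sl_a / sl_d)
        scores.append(score)
    return scores


def standardize_scores(
    scores: list[HaplotypeScore], n_bins: int = 100
) -> tuple[list[HaplotypeScore], StandardizationTable]:
    """Standardize OK scores within equal-width derived-frequency bins.

    Within each populated bin, std = (unstd - bin mean) / bin sd, with the
    population sd (denominator = bin count).  Bins with fewer than 2 scores
    or zero sd leave std undefined.
    """
    ok = [s for s in scores if s.status is ScoreStatus.OK and math.isfinite(s.unstd)]
    if len(ok) < 2:
        raise ValueError("need at least 2 OK scores to standardize")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    freqs = np.array([s.derived_freq for s in ok])
    vals = np.array([s.unstd for s in ok])
    bins = np.minimum((freqs * n_bins).astype(np.int64), n_bins - 1)

    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = vals[bins == b]
        counts[b] = len(sel)
        if len(sel) >= 2:
            means[b] = sel.mean()
            sds[b] = sel.std(ddof=0)

    out = [replace(s) for s in scores]
    ok_out = [s for s in out if s.status is ScoreStatus.OK and math.isfinite(s.unstd)]
    for s, b in zip(ok_out, bins):
        if counts[b] >= 2 and sds[b] > 0:
            s.std = (s.unstd - means[b]) / sds[b]
    table = StandardizationTable(
        n_bins=n_bins, bin_edges=edges, means=means, sds=sds, counts=counts
    )
    return out, table


def scores_to_frame(scores: list[HaplotypeScore]) -> pd.DataFrame:
    """Tabulate scores for TSV export; column names follow the statistic."""
    stat = scores[0].statistic if scores else "ihs"
    a_col, d_col = ("ihh_a", "ihh_d") if stat == "ihs" else ("sl_a", "sl_d")
    return pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in scores],
            "pos": [s.pos for s in scores],
            "derived_freq": [s.derived_freq for s in scores],
            a_col: [s.anc_stat for s in scores],
            d_col: [s.der_stat for s in scores],
            "unstd": [s.unstd for s in scores],
            "std": [s.std for s in scores],
            "status": [s.status.value for s in scores],
        }
    )
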