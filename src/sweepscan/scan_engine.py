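"""Genome-wide empirical distributions, outlier p-values, top-quantile
cutoffs, allele-frequency reports and region summaries.

An empirical p-value is the proportion of genome-wide values as or more
extreme than the observed one; ties count, so p >= 1/N whenever the
observed value belongs to the set.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeMatrix, Polarity, PopulationPanel


class Tail(enum.Enum):
    LOWER = "lower"
    UPPER = "upper"
    TWO_SIDED_ABS = "two_sided_abs"


#: default tail per statistic (sweep signatures); overridable everywhere
DEFAULT_TAILS: dict[str, Tail] = {
    "pi": Tail.LOWER,
    "tajima_d": Tail.LOWER,
    "faywu_h": Tail.LOWER,
    "ihs": Tail.TWO_SIDED_ABS,
    "nsl": Tail.TWO_SIDED_ABS,
    "pbs": Tail.UPPER,
}


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Immutable genome-wide collection of statistic values (NA excluded)."""

    name: str
    tail: Tail
    values: np.ndarray = field(repr=False)  # sorted ascending; finite

    @classmethod
    def from_values(
        cls, values: Iterable[float], tail: Tail, name: str = ""
    ) -> "EmpiricalDistribution":
        arr = np.asarray(list(values), dtype=float)
        arr = np.sort(arr[np.isfinite(arr)])
        if len(arr) == 0:
            raise ValueError("empirical distribution needs at least one finite value")
        return cls(name=name, tail=tail, values=arr)

    @property
    def n(self) -> int:
        return len(self.values)


def empirical_pvalue(dist: EmpiricalDistribution, observed: float) -> float:
    """Proportion of the distribution as or more extreme than ``observed``."""
    if not math.isfinite(observed):
        raise ValueError("observed value must be finite")
    v = dist.values
    n = len(v)
    if dist.tail is Tail.UPPER:
        count = n - int(np.searchsorted(v, observed, side="left"))
    elif dist.tail is Tail.LOWER:
        count = int(np.searchsorted(v, observed, side="right"))
    else:
        a = np.sort(np.abs(v))
        count = n - int(np.searchsorted(a, abs(observed), side="left"))
    return count / n


def top_cutoffs(
    dist: EmpiricalDistribution, fractions: Sequence[float] = (0.05, 0.01)
) -> dict[float, float]:
    """Threshold value per tail fraction: the ceil(f*N)-th most extreme value.

    A value is flagged when it is as or more extreme than the threshold.
    """
    out: dict[float, float] = {}
    n = dist.n
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError(f"fraction must be in (0, 1), got {f}")
        k = math.ceil(f * n)
        if k < 1 or f * n < 1:
            raise ValueError(f"cannot resolve fraction {f} with N={n}")
        if dist.tail is Tail.UPPER:
            out[f] = float(dist.values[n - k])
        elif dist.tail is Tail.LOWER:
            out[f] = float(dist.values[k - 1])
        else:
            a = np.sort(np.abs(dist.values))
            out[f] = float(a[n - k])
    return out


def is_extreme(dist: EmpiricalDistribution, value: float, threshold: float) -> bool:
    """Whether ``value`` is as or more extreme than ``threshold`` per the tail."""
    if dist.tail is Tail.UPPER:
        return value >= threshold
    if dist.tail is Tail.LOWER:
        return value <= threshold
    return abs(value) >= threshold


def make_report(
    dist: EmpiricalDistribution,
    observed: Sequence[float],
    fractions: Sequence[float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Per-value empirical p and top-fraction flags against ``dist``.

    Non-finite observed values get NA p-values and False flags.
    """
    cuts = top_cutoffs(dist, fractions)
    rows = []
    for v in observed:
        if not math.isfinite(v):
            rows.append({"value": v, "empirical_p": math.nan,
                         **{f"top{int(f * 100)}": False for f in fractions}})
            continue
        row = {"value": v, "empirical_p": empirical_pvalue(dist, v)}
        for f in fractions:
            row[f"top{int(f * 100)}"] = is_extreme(dist, v, cuts[f])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele-frequency report
# ---------------------------------------------------------------------------


def _allele_call_value(site, allele: str) -> int | None:
    """Map an allele request onto the 0/1 call coding of a site.

    ``allele`` may be REF, ALT, DERIVED, ANCESTRAL or a literal base.  After
    polarization a REF_IS_DERIVED column codes the REF allele as 1.  Returns
    None when the request cannot be resolved for this site.
    """
    a = allele.upper()
    ref_call = 1 if site.polarity is Polarity.REF_IS_DERIVED else 0
    if a == "REF":
        return ref_call
    if a == "ALT":
        return 1 - ref_call
    if a == "DERIVED":
        return 1 if site.polarity is not Polarity.UNPOLARIZED else None
    if a == "ANCESTRAL":
        return 0 if site.polarity is not Polarity.UNPOLARIZED else None
    if a == site.ref:
        return ref_call
    if a == site.alt:
        return 1 - ref_call
    return None


def allele_frequency_report(
    m: HaplotypeMatrix,
    panel: PopulationPanel,
    variants: Sequence[str | int],
    allele: str = "DERIVED",
    by: str = "super_pop",
) -> pd.DataFrame:
    """Per-group frequency of the requested allele at selected variants.

    ``variants`` holds variant ids (str) or positions (int); a variant
    absent from the matrix yields NA rows rather than an error.  ``by`` is
    ``super_pop``, ``pop`` or ``both``.
    """
    if by not in ("super_pop", "pop", "both"):
        raise ValueError(f"by must be super_pop|pop|both, got {by!r}")
    group_cols = {"super_pop": ["super_pop"], "pop": ["pop"], "both": ["super_pop", "pop"]}[by]
    sample_set = set(m.sample_ids)
    t = panel.table[panel.table["sample"].isin(sample_set)]
    rows = []
    for want in variants:
        try:
            j = m.site_index(variant_id=want) if isinstance(want, str) else m.site_index(pos=want)
        except KeyError:
            for _, grp in t.groupby(group_cols, sort=True):
                rows.append({"variant": want, "group": "/".join(grp.iloc[0][c] for c in group_cols),
                             "allele": allele, "count": np.nan, "total": np.nan,
                             "frequency": np.nan})
            continue
        site = m.sites[j]
        call_value = _allele_call_value(site, allele)
        col = m.calls[:, j]
        sample_rows = {s: i for i, s in enumerate(m.sample_ids)}
        for _, grp in t.groupby(group_cols, sort=True):
            hap_idx = np.concatenate(
                [[2 * sample_rows[s], 2 * sample_rows[s] + 1] for s in grp["sample"]]
            )
            total = len(hap_idx)
            if call_value is None:
                count, freq = np.nan, np.nan
            else:
                count = int(np.sum(col[hap_idx] == call_value))
                freq = count / total
            rows.append({"variant": want,
                         "group": "/".join(grp.iloc[0][c] for c in group_cols),
                         "allele": allele, "count": count, "total": total,
                         "frequency": freq})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# region report
# ---------------------------------------------------------------------------


def region_report(
    tracks: Sequence[pd.DataFrame],
    region: tuple[str, int, int] | None = None,
    distributions: Mapping[str, EmpiricalDistribution] | None = None,
    fractions: Sequence[float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Inner-join statistic tracks on their shared coordinates and flag outliers.

    Tracks must share a coordinate convention: per-variant (``pos``) or
    per-window (``start``/``end``).  ``distributions`` maps statistic column
    names to genome-wide backgrounds; matched columns gain ``<col>_p`` and
    top-fraction flag columns.
    """
    if not tracks:
        raise ValueError("need at least one track")
    per_window = "start" in tracks[0].columns
    keys = ["chrom", "start", "end"] if per_window else ["chrom", "pos"]
    for t in tracks:
        missing = [k for k in keys if k not in t.columns and k != "chrom"]
        if missing:
            raise ValueError(f"track missing coordinate columns {missing}")
    chroms = set()
    for t in tracks:
        if "chrom" in t.columns:
            chroms |= set(t["chrom"].dropna().unique())
    if len(chroms) > 1:
        raise ValueError(f"tracks span mismatched chromosomes: {sorted(chroms)}")
    join_keys = [k for k in keys if all(k in t.columns for t in tracks)]
    merged = tracks[0]
    for t in tracks[1:]:
        merged = merged.merge(t, on=join_keys, how="inner")
    if region is not None:
        chrom, lo, hi = region
        if chroms and chrom not in chroms:
            raise ValueError(f"region chromosome {chrom!r} does not match tracks")
        coord = merged["start"] if per_window else merged["pos"]
        merged = merged[(coord >= lo) & (coord < hi)].reset_index(drop=True)
    if distributions:
        for col, dist in distributions.items():
            if col not in merged.columns:
                continue
            rep = make_report(dist, merged[col].tolist(), fractions)
            merged[f"{col}_p"] = rep["empirical_p"].values
            for f in fractions:
                merged[f"{col}_top{int(f * 100)}"] = rep[f"top{int(f * 100)}"].values
    return merged


def to_bed(frame: pd.DataFrame, score_col: str) -> pd.DataFrame:
    """BED3+score view of a track (0-based half-open starts)."""
    if "start" in frame.columns:
        start = frame["start"].astype(int) - 1
        end = frame["end"].astype(int) - 1
    else:
        start = frame["pos"].astype(int) - 1
        end = frame["pos"].astype(int)
    return pd.DataFrame(
        {
            "chrom": frame["chrom"] if "chrom" in frame.columns else ".",
            "start": start.clip(lower=0),
            "end": end,
            "score": frame[score_col],
        }
    )
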