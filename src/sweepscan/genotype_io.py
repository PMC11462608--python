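"""Phased-VCF and sample-panel input, allele polarization, subsetting.

The in-memory substrate for every statistic in this package is a
:class:`HaplotypeMatrix`: phased binary haplotypes over ordered biallelic
SNPs.  Calls are ALT-coded as read from a VCF (1 = ALT allele) and become
derived-coded (1 = derived allele) after :func:`polarize`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class Polarity(enum.Enum):
    """Orientation of a site's 0/1 call coding relative to ancestral state."""

    ALT_IS_DERIVED = "alt_is_derived"
    REF_IS_DERIVED = "ref_is_derived"
    UNPOLARIZED = "unpolarized"


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP: coordinates, alleles and polarization state."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str | None = None
    ancestral: str | None = None
    polarity: Polarity = Polarity.UNPOLARIZED

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if allele not in _BASES:
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not a single base"
                )
        if self.polarity is not Polarity.UNPOLARIZED:
            if self.ancestral is None or self.ancestral.upper() not in (
                self.ref,
                self.alt,
            ):
                raise ValueError(
                    f"polarized site {self.chrom}:{self.pos} needs ancestral == ref or alt"
                )

    @property
    def derived_allele(self) -> str | None:
        if self.polarity is Polarity.ALT_IS_DERIVED:
            return self.alt
        if self.polarity is Polarity.REF_IS_DERIVED:
            return self.ref
        return None


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes (rows) over ordered SNP sites (columns).

    ``calls[i, j]`` is the allele of haplotype ``i`` at site ``j``; two
    consecutive rows belong to one sample.  No missing calls are allowed.
    """

    sites: list[SiteRecord]
    calls: np.ndarray
    sample_ids: list[str]
    _positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (haplotypes x sites)")
        n_hap, n_sites = self.calls.shape
        if n_sites != len(self.sites):
            raise ValueError(f"{len(self.sites)} sites but {n_sites} call columns")
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError(
                f"{n_hap} haplotype rows do not pair into {len(self.sample_ids)} samples"
            )
        bad = (self.calls != 0) & (self.calls != 1)
        if bad.any():
            raise ValueError("calls must be 0/1 with no missing values")
        chroms = {s.chrom for s in self.sites}
        if len(chroms) > 1:
            raise ValueError(f"matrix must span a single chromosome, got {sorted(chroms)}")
        pos = np.array([s.pos for s in self.sites], dtype=np.int64)
        if n_sites > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("site positions must be strictly increasing")
        self._positions = pos

    # -- basic views ---------------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self._positions

    @property
    def chrom(self) -> str | None:
        return self.sites[0].chrom if self.sites else None

    @property
    def derived_counts(self) -> np.ndarray:
        """Per-site count of 1-calls (derived after polarization, else ALT)."""
        return self.calls.sum(axis=0, dtype=np.int64)

    @property
    def derived_freqs(self) -> np.ndarray:
        return self.derived_counts / self.n_haplotypes

    def take_sites(self, index: Sequence[int] | np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index, dtype=np.int64)
        return HaplotypeMatrix(
            sites=[self.sites[i] for i in index],
            calls=self.calls[:, index],
            sample_ids=list(self.sample_ids),
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "HaplotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        rows = np.concatenate(
            [[2 * lookup[s], 2 * lookup[s] + 1] for s in sample_ids]
        ) if sample_ids else np.empty(0, dtype=np.int64)
        return HaplotypeMatrix(
            sites=list(self.sites),
            calls=self.calls[rows.astype(np.int64)],
            sample_ids=list(sample_ids),
        )

    def window(self, start: int, end: int) -> "HaplotypeMatrix":
        """Restrict to sites with start <= pos < end (half-open, bp)."""
        lo = int(np.searchsorted(self._positions, start, side="left"))
        hi = int(np.searchsorted(self._positions, end, side="left"))
        return self.take_sites(np.arange(lo, hi))

    def site_index(self, variant_id: str | None = None, pos: int | None = None) -> int:
        """Locate a site by id or position; raises KeyError when absent."""
        if variant_id is not None:
            for j, s in enumerate(self.sites):
                if s.variant_id == variant_id:
                    return j
            raise KeyError(f"variant {variant_id!r} not in matrix")
        if pos is not None:
            j = int(np.searchsorted(self._positions, pos))
            if j < self.n_sites and self._positions[j] == pos:
                return j
            raise KeyError(f"position {pos} not in matrix")
        raise ValueError("need variant_id or pos")


@dataclass
class PopulationPanel:
    """sample -> (population, superpopulation) mapping."""

    table: pd.DataFrame  # columns: sample, pop, super_pop

    def __post_init__(self) -> None:
        required = {"sample", "pop", "super_pop"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicated sample in panel: {dup}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["pop"].unique())

    @property
    def superpopulations(self) -> list[str]:
        return sorted(self.table["super_pop"].unique())

    def samples_in(self, code: str) -> list[str]:
        """Samples belonging to a population or superpopulation code."""
        t = self.table
        mask = (t["pop"] == code) | (t["super_pop"] == code)
        return t.loc[mask, "sample"].tolist()

    def n_samples(self, code: str | None = None) -> int:
        if code is None:
            return len(self.table)
        return len(self.samples_in(code))

    def has_code(self, code: str) -> bool:
        return bool(len(self.samples_in(code)))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, 2**62
    lo, _, hi = span.partition("-")
    return chrom, int(lo), int(hi)


def parse_ancestral(raw: object, strict_uppercase: bool = False) -> str | None:
    """Extract the ancestral base from a VCF AA INFO value.

    Takes the first ``|``-delimited token; lowercase (low-confidence) calls
    are accepted unless ``strict_uppercase``; anything that is not a single
    A/C/G/T returns None.
    """
    if raw is None:
        return None
    token = str(raw).split("|", 1)[0].strip()
    if strict_uppercase and token != token.upper():
        return None
    token = token.upper()
    return token if token in _BASES else None


def read_vcf(
    path: str | Path,
    region: str | None = None,
    strict_uppercase: bool = False,
) -> HaplotypeMatrix:
    """Read phased biallelic SNPs from a VCF 4.x file.

    Retains only biallelic single-base SNPs with fully phased, non-missing
    genotypes.  Multiallelic sites, indels and sites with missing calls are
    dropped (counts logged); an unphased genotype or a duplicated position is
    an error.  The ancestral allele is parsed from the INFO key ``AA``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    want = _parse_region(region) if region else None

    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    dropped = {"multiallelic_or_indel": 0, "missing_genotype": 0, "non_acgt": 0}
    last_pos: int | None = None
    chrom_seen: str | None = None

    for v in vcf:
        if want is not None:
            if v.CHROM != want[0] or not (want[1] <= v.POS <= want[2]):
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped["multiallelic_or_indel"] += 1
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if ref not in _BASES or alt not in _BASES:
            dropped["non_acgt"] += 1
            continue
        gts = v.genotypes  # [allele_a, allele_b, phased] per sample
        alleles = np.empty(2 * len(gts), dtype=np.int8)
        missing = False
        for i, g in enumerate(gts):
            a, b, phased = g[0], g[-2], g[-1]
            if a < 0 or b < 0:
                missing = True
                break
            if not phased:
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS} (sample {samples[i]})"
                )
            alleles[2 * i] = a
            alleles[2 * i + 1] = b
        if missing:
            dropped["missing_genotype"] += 1
            continue
        if chrom_seen is None:
            chrom_seen = v.CHROM
        elif v.CHROM != chrom_seen:
            raise ValueError(
                f"multiple chromosomes in one matrix ({chrom_seen}, {v.CHROM}); "
                "use the region argument"
            )
        if last_pos is not None and v.POS == last_pos:
            raise ValueError(f"duplicate position {v.CHROM}:{v.POS}")
        last_pos = v.POS
        aa = parse_ancestral(v.INFO.get("AA"), strict_uppercase=strict_uppercase)
        vid = v.ID if v.ID not in (None, ".") else None
        sites.append(
            SiteRecord(chrom=v.CHROM, pos=v.POS, ref=ref, alt=alt, variant_id=vid,
                       ancestral=aa)
        )
        columns.append(alleles)

    if any(dropped.values()):
        log.info("read_vcf dropped sites: %s", dropped)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    return HaplotypeMatrix(sites=sites, calls=calls, sample_ids=samples)


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a 1000 Genomes-style integrated sample panel (TSV with header).

    Requires columns ``sample``, ``pop`` and ``super_pop``; extra columns
    (e.g. ``gender``) are kept but ignored.
    """
    table = pd.read_csv(path, sep=r"\s+", dtype=str)
    return PopulationPanel(table=table)


# ---------------------------------------------------------------------------
# polarization and filtering
# ---------------------------------------------------------------------------


def polarize(m: HaplotypeMatrix, drop_unpolarized: bool = True) -> HaplotypeMatrix:
    """Orient calls so that 1 = derived allele, using each site's ancestral base.

    AA == REF leaves the column unchanged (ALT is derived); AA == ALT flips
    the column (REF is derived).  Sites whose AA is missing or matches
    neither allele are dropped when ``drop_unpolarized`` and otherwise kept
    with polarity UNPOLARIZED.
    """
    keep: list[int] = []
    new_sites: list[SiteRecord] = []
    calls = m.calls.copy()
    n_flipped = n_dropped = 0
    for j, s in enumerate(m.sites):
        aa = s.ancestral.upper() if s.ancestral else None
        if aa == s.ref:
            new_sites.append(replace(s, polarity=Polarity.ALT_IS_DERIVED))
            keep.append(j)
        elif aa == s.alt:
            calls[:, j] = 1 - calls[:, j]
            new_sites.append(replace(s, polarity=Polarity.REF_IS_DERIVED))
            keep.append(j)
            n_flipped += 1
        elif drop_unpolarized:
            n_dropped += 1
        else:
            new_sites.append(replace(s, polarity=Polarity.UNPOLARIZED))
            keep.append(j)
    if n_flipped or n_dropped:
        log.info("polarize: flipped %d columns, dropped %d sites", n_flipped, n_dropped)
    return HaplotypeMatrix(
        sites=new_sites, calls=calls[:, keep], sample_ids=list(m.sample_ids)
    )


def subset_and_filter(
    m: HaplotypeMatrix,
    panel: PopulationPanel | None = None,
    pop: str | None = None,
    maf_min: float = 0.0,
    drop_monomorphic: bool = False,
) -> HaplotypeMatrix:
    """Subset haplotypes to one population and filter sites by frequency.

    MAF filtering is strict: a site is retained only when
    ``min(p, 1 - p) > maf_min`` (so a site exactly at the threshold drops).
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if pop is not None:
        if panel is None:
            raise ValueError("pop given without a panel")
        samples = panel.samples_in(pop)
        if not samples:
            raise ValueError(f"population code {pop!r} unknown to panel")
        m = m.take_samples(samples)
    counts = m.derived_counts
    n = m.n_haplotypes
    keep = np.ones(m.n_sites, dtype=bool)
    if drop_monomorphic:
        keep &= (counts > 0) & (counts < n)
    if maf_min > 0:
        p = counts / n
        keep &= np.minimum(p, 1 - p) > maf_min
    if not keep.all():
        log.info("subset_and_filter: dropped %d of %d sites", int((~keep).sum()), m.n_sites)
    return m.take_sites(np.flatnonzero(keep))
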