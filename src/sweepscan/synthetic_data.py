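"""Synthetic haplotype fixtures with known ground truth.

Three generators feed the test pyramid:

* :func:`simulate_neutral` — Kingman coalescent with infinite-sites
  mutations (E[S] = theta * a1), no recombination;
* :func:`simulate_structured` — independent sites with Balding–Nichols
  per-population frequencies at a controlled drift parameter F;
* :func:`inject_sweep` — a star-like shared haplotype copied over a span
  around a new focal SNP, as a positive control for the scan.

:func:`write_fixture` round-trips matrices through VCF + panel text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genotype_io import (
    HaplotypeMatrix,
    Polarity,
    PopulationPanel,
    SiteRecord,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class NeutralSimConfig:
    n: int  # haplotypes (must be even to pair into diploid samples)
    theta: float  # 4*N*mu per locus
    length_bp: int
    reps: int = 1
    seed: int = 0
    flip_fraction: float = 0.0  # fraction of sites emitted with AA == ALT

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2:
            raise ValueError("n must be an even integer >= 2")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 <= self.flip_fraction <= 1:
            raise ValueError("flip_fraction must be in [0, 1]")


@dataclass(frozen=True)
class StructuredSimConfig:
    n_pops: int
    fst: tuple[float, ...]  # Balding-Nichols F per population, in [0, 1)
    n_diploids: int  # per population
    n_sites: int
    length_bp: int = 1_000_000
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fst) != self.n_pops:
            raise ValueError("need one F per population")
        if any(not 0 <= f < 1 for f in self.fst):
            raise ValueError("each F must be in [0, 1)")


@dataclass(frozen=True)
class SweepConfig:
    focal_pos: int
    p_derived: float  # sweep frequency p_s in (0, 1)
    span_bp: int  # total shared-haplotype length, centered on focal_pos
    background: NeutralSimConfig
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_derived < 1:
            raise ValueError("p_derived must be in (0, 1)")
        half = self.span_bp // 2
        if self.focal_pos - half < 1 or self.focal_pos + half > self.background.length_bp:
            raise ValueError("sweep span exceeds the simulated locus")


def _random_ref_alt(rng: np.random.Generator) -> tuple[str, str]:
    i = rng.integers(0, 4)
    j = (i + 1 + rng.integers(0, 3)) % 4
    return str(_BASES[i]), str(_BASES[j])


def _draw_positions(k: int, length_bp: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct positions uniform on [1, length_bp], sorted (collision redraw)."""
    if k > length_bp:
        raise ValueError("more mutations than available positions")
    pos: set[int] = set()
    while len(pos) < k:
        draw = rng.integers(1, length_bp + 1, size=k - len(pos))
        pos.update(int(p) for p in draw)
    return np.sort(np.fromiter(pos, dtype=np.int64))


def _coalescent_segments(
    n: int, rng: np.random.Generator
) -> list[tuple[tuple[int, ...], float]]:
    """(leaf set, branch length) pieces of one Kingman genealogy.

    While k lineages remain, the inter-coalescence time is Exponential with
    rate k(k-1)/2 (units of 2N generations) and a uniform pair merges.
    """
    lineages: list[tuple[int, ...]] = [(i,) for i in range(n)]
    segments: list[tuple[tuple[int, ...], float]] = []
    k = n
    while k > 1:
        t = float(rng.exponential(2.0 / (k * (k - 1))))
        for leaves in lineages:
            segments.append((leaves, t))
        i, j = rng.choice(k, size=2, replace=False)
        merged = tuple(sorted(lineages[i] + lineages[j]))
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        k -= 1
    return segments


def _sites_from_carriers(
    carriers_per_site: list[np.ndarray],
    positions: np.ndarray,
    n: int,
    rng: np.random.Generator,
    flip_fraction: float,
    chrom: str,
) -> HaplotypeMatrix:
    """Assemble a derived-coded matrix; optionally emit some sites AA==ALT."""
    m = len(positions)
    calls = np.zeros((n, m), dtype=np.int8)
    sites: list[SiteRecord] = []
    flip = rng.random(m) < flip_fraction
    for j in range(m):
        calls[carriers_per_site[j], j] = 1
        ref, alt = _random_ref_alt(rng)
        if flip[j]:
            # encode the derived allele as REF in the emitted VCF
            sites.append(
                SiteRecord(chrom=chrom, pos=int(positions[j]), ref=ref, alt=alt,
                           variant_id=f"sim_{int(positions[j])}", ancestral=alt,
                           polarity=Polarity.REF_IS_DERIVED)
            )
        else:
            sites.append(
                SiteRecord(chrom=chrom, pos=int(positions[j]), ref=ref, alt=alt,
                           variant_id=f"sim_{int(positions[j])}", ancestral=ref,
                           polarity=Polarity.ALT_IS_DERIVED)
            )
    sample_ids = [f"sim{(i):04d}" for i in range(n // 2)]
    return HaplotypeMatrix(sites=sites, calls=calls, sample_ids=sample_ids)


def simulate_neutral(cfg: NeutralSimConfig) -> list[HaplotypeMatrix]:
    """Neutral coalescent replicates, derived-coded (1 = derived allele).

    Mutations are Poisson(theta/2 * total branch length) placed uniformly on
    branches under infinite sites; the carriers of a mutation are the leaves
    below its branch.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[HaplotypeMatrix] = []
    for rep in range(cfg.reps):
        segments = _coalescent_segments(cfg.n, rng)
        lengths = np.array([t for _, t in segments])
        total = float(lengths.sum())
        n_mut = int(rng.poisson(cfg.theta / 2.0 * total)) if cfg.theta > 0 else 0
        carriers: list[np.ndarray] = []
        if n_mut:
            which = rng.choice(len(segments), size=n_mut, p=lengths / total)
            carriers = [np.asarray(segments[w][0], dtype=np.int64) for w in which]
        positions = _draw_positions(n_mut, cfg.length_bp, rng)
        out.append(
            _sites_from_carriers(
                carriers, positions, cfg.n, rng, cfg.flip_fraction, chrom=f"sim{rep + 1}"
            )
        )
    return out


def simulate_structured(
    cfg: StructuredSimConfig,
) -> tuple[HaplotypeMatrix, PopulationPanel]:
    """Independent sites with Balding–Nichols population frequencies.

    Per site: ancestral frequency p ~ Uniform(anc_freq_range), then per
    population p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (p_k = p when F = 0), and
    haplotype alleles ~ Bernoulli(p_k).  Sites monomorphic in the pooled
    sample are dropped.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    n_hap_pop = 2 * cfg.n_diploids
    n_hap = cfg.n_pops * n_hap_pop

    lo, hi = cfg.anc_freq_range
    anc = rng.uniform(lo, hi, size=cfg.n_sites)
    calls = np.zeros((n_hap, cfg.n_sites), dtype=np.int8)
    for k, f in enumerate(cfg.fst):
        if f == 0:
            p_k = anc
        else:
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f
            p_k = rng.beta(a, b)
        block = rng.random((n_hap_pop, cfg.n_sites)) < p_k
        calls[k * n_hap_pop : (k + 1) * n_hap_pop] = block.astype(np.int8)

    pooled = calls.sum(axis=0)
    keep = np.flatnonzero((pooled > 0) & (pooled < n_hap))
    positions = _draw_positions(cfg.n_sites, cfg.length_bp, rng)

    sites: list[SiteRecord] = []
    for j in keep:
        ref, alt = _random_ref_alt(rng)
        sites.append(
            SiteRecord(chrom="sim1", pos=int(positions[j]), ref=ref, alt=alt,
                       variant_id=f"sim_{int(positions[j])}", ancestral=ref,
                       polarity=Polarity.ALT_IS_DERIVED)
        )
    sample_ids = [
        f"P{k + 1}_{i:04d}" for k in range(cfg.n_pops) for i in range(cfg.n_diploids)
    ]
    matrix = HaplotypeMatrix(sites=sites, calls=calls[:, keep], sample_ids=sample_ids)
    panel = PopulationPanel(
        table=pd.DataFrame(
            {
                "sample": sample_ids,
                "pop": [s.split("_")[0] for s in sample_ids],
                "super_pop": [s.split("_")[0] for s in sample_ids],
                "gender": "unknown",
            }
        )
    )
    return matrix, panel


def inject_sweep(m: HaplotypeMatrix, cfg: SweepConfig) -> HaplotypeMatrix:
    """Overwrite a carrier subset with one shared haplotype around a new
    focal SNP (star-like genealogy); non-carriers are untouched."""
    rng = np.random.default_rng(cfg.seed)
    n = m.n_haplotypes
    n_car = round(cfg.p_derived * n)
    if not 0 < n_car < n:
        raise ValueError("sweep frequency leaves no carriers or no non-carriers")
    carriers = np.sort(rng.choice(n, size=n_car, replace=False))
    half = cfg.span_bp // 2
    lo, hi = cfg.focal_pos - half, cfg.focal_pos + half

    calls = m.calls.copy()
    span_cols = np.flatnonzero((m.positions >= lo) & (m.positions < hi))
    if len(span_cols):
        template = calls[carriers[0], span_cols].copy()
        calls[np.ix_(carriers, span_cols)] = template

    focal_pos = int(cfg.focal_pos)
    insert_at = int(np.searchsorted(m.positions, focal_pos))
    while insert_at < m.n_sites and m.positions[insert_at] == focal_pos:
        focal_pos += 1  # avoid position collision with a background SNP
        insert_at = int(np.searchsorted(m.positions, focal_pos))
    focal_col = np.zeros((n, 1), dtype=np.int8)
    focal_col[carriers] = 1
    calls = np.concatenate(
        [calls[:, :insert_at], focal_col, calls[:, insert_at:]], axis=1
    )
    ref, alt = _random_ref_alt(rng)
    focal_site = SiteRecord(
        chrom=m.chrom or "sim1", pos=focal_pos, ref=ref, alt=alt,
        variant_id="sweep_focal", ancestral=ref, polarity=Polarity.ALT_IS_DERIVED,
    )
    sites = list(m.sites[:insert_at]) + [focal_site] + list(m.sites[insert_at:])
    return HaplotypeMatrix(sites=sites, calls=calls, sample_ids=list(m.sample_ids))


def uniform_panel(
    sample_ids: list[str], pop: str = "P1", super_pop: str = "P1"
) -> PopulationPanel:
    """Single-population panel covering the given samples."""
    import pandas as pd

    return PopulationPanel(
        table=pd.DataFrame(
            {"sample": sample_ids, "pop": pop, "super_pop": super_pop,
             "gender": "unknown"}
        )
    )


def write_fixture(
    m: HaplotypeMatrix,
    panel: PopulationPanel,
    out_dir: str | Path,
    prefix: str = "fixture",
) -> tuple[Path, Path]:
    """Write a matrix as VCF 4.2 (phased GT, INFO AA) plus a panel TSV.

    GT columns are emitted in REF/ALT coding: a derived-coded call at a
    REF_IS_DERIVED site is complemented on output, so read_vcf + polarize
    round-trips bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{prefix}.vcf"
    panel_path = out_dir / f"{prefix}.panel"

    contigs = sorted({s.chrom for s in m.sites})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(m.sample_ids),
    ]
    for j, site in enumerate(m.sites):
        col = m.calls[:, j]
        if site.polarity is Polarity.REF_IS_DERIVED:
            col = 1 - col
        gts = "\t".join(
            f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(m.n_samples)
        )
        info = f"AA={site.ancestral}" if site.ancestral else "."
        vid = site.variant_id or "."
        lines.append(
            f"{site.chrom}\t{site.pos}\t{vid}\t{site.ref}\t{site.alt}\t.\tPASS\t{info}\tGT\t{gts}"
        )
    vcf_path.write_text("\n".join(lines) + "\n")

    cols = ["sample", "pop", "super_pop"]
    extra = [c for c in panel.table.columns if c not in cols]
    panel.table[cols + extra].to_csv(panel_path, sep="\t", index=False)
    return vcf_path, panel_path
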