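"""Synthetic inputs with the statistical structure the analyses assume.

Generators for every pipeline input: Hardy-Weinberg cohort genotypes at
common SNP sites, rare-variant call sets with optional regional enrichment,
tumor-islet call sets sharing a founding ("root") clone, gene annotations
with gene-set memberships, and per-case IHC nuclear intensity scores.

Defaults emulate the study conditions: a 2 Mb region, cohorts of 33
individuals, 30 tumor islets sharing 750 root variants at >= 90% presence,
a rare-variant rate of 1.05e-5 per bp per individual (a per-sample median of
about 21 rare variants over 2 Mb), and percent-3+ IHC scores of benign
mean 3 / sd 4 versus HGSOC mean 14 / sd 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomicInterval, VARIANT_COLUMNS, empty_variant_table, sort_variants

_BASES = np.array(["A", "C", "G", "T"])

#: per-bp per-individual rare-variant rate reproducing a per-sample median of
#: ~21 rare variants over a 2 Mb region
DEFAULT_RARE_RATE = 1.05e-5

DEFAULT_REGION = GenomicInterval("chr3", 180_429_714, 182_429_713)  # 2 Mb


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# population model: common SNPs + rare variants
# ---------------------------------------------------------------------------


@dataclass
class PopulationModel:
    """Allele-frequency structure of a genomic region.

    Parameters
    ----------
    region : GenomicInterval
        1-based inclusive interval the model covers.
    common_sites : list of (position, maf)
        Panel SNPs with minor allele frequency in (0.05, 0.5].
    rare_site_rate : float
        Expected rare variants per bp per individual (each carrier event is
        an independent singleton).
    enrichment_windows : list of (GenomicInterval, fold)
        Regions whose rare-variant rate is multiplied by ``fold`` (>= 1).
    seed : int
        Default seed for generators that take this model.
    """

    region: GenomicInterval = DEFAULT_REGION
    common_sites: list[tuple[int, float]] = field(default_factory=list)
    rare_site_rate: float = DEFAULT_RARE_RATE
    enrichment_windows: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rare_site_rate < 0:
            raise ValueError("rare_site_rate must be >= 0")
        for pos, maf in self.common_sites:
            if not self.region.contains(self.region.chrom, pos):
                raise ValueError(f"common site {pos} outside region {self.region}")
            if not (0.05 < maf <= 0.5):
                raise ValueError(f"common-site MAF must be in (0.05, 0.5], got {maf}")
        for window, fold in self.enrichment_windows:
            if fold < 1:
                raise ValueError("enrichment fold must be >= 1")
            if window.chrom != self.region.chrom or window.start < self.region.start or window.end > self.region.end:
                raise ValueError(f"enrichment window {window} outside region {self.region}")

    @property
    def common_positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.common_sites], dtype=np.int64)

    @property
    def common_mafs(self) -> np.ndarray:
        return np.array([m for _, m in self.common_sites], dtype=float)

    def panel(self) -> pd.DataFrame:
        """The model's common sites as an allele-frequency panel table."""
        pos = self.common_positions
        df = pd.DataFrame(
            {
                "chrom": self.region.chrom,
                "pos": pos,
                "ref": _ref_base(pos),
                "alt": _alt_base(pos),
                "maf": self.common_mafs,
            }
        )
        return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def random_common_sites(
    region: GenomicInterval, n_sites: int, seed=None, maf_range: tuple[float, float] = (0.05, 0.5)
) -> list[tuple[int, float]]:
    """Place ``n_sites`` common SNPs uniformly with MAF ~ U(maf_range]."""
    rng = _rng(seed)
    pos = np.sort(rng.choice(np.arange(region.start, region.end + 1), size=n_sites, replace=False))
    lo, hi = maf_range
    # draw in (lo, hi]: uniform on (lo, hi] via 1 - U[0,1) scaled
    mafs = hi - rng.random(n_sites) * (hi - lo)
    return list(zip(pos.tolist(), mafs.tolist()))


def simulate_cohort_genotypes(model_or_mafs, n_individuals: int, seed=None) -> np.ndarray:
    """Draw Hardy-Weinberg genotypes for a cohort, sites independent (no LD).

    Per site with alternate-allele frequency p, each individual's genotype is
    Binomial(2, p): probabilities (1-p)^2, 2p(1-p), p^2 for 0/1/2 copies.

    Parameters
    ----------
    model_or_mafs : PopulationModel or array-like of float
        Either a population model (its common-site MAFs are used) or an
        explicit vector of allele frequencies in [0, 1].
    n_individuals : int
    seed : int or numpy.random.Generator

    Returns
    -------
    numpy.ndarray of shape (n_individuals, n_sites), values 0/1/2.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if isinstance(model_or_mafs, PopulationModel):
        mafs = model_or_mafs.common_mafs
    else:
        mafs = np.asarray(model_or_mafs, dtype=float)
    if mafs.ndim != 1:
        raise ValueError("allele frequencies must be a 1-D vector")
    if len(mafs) and (np.min(mafs) < 0 or np.max(mafs) > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rng = _rng(seed)
    return rng.binomial(2, mafs, size=(int(n_individuals), len(mafs))).astype(np.int8)


def _ref_base(pos: np.ndarray) -> np.ndarray:
    """Deterministic reference base per position (recurrent sites agree)."""
    return _BASES[np.asarray(pos, dtype=np.int64) % 4]


def _alt_base(pos: np.ndarray) -> np.ndarray:
    pos = np.asarray(pos, dtype=np.int64)
    # deterministic alternate, always != ref
    return _BASES[(pos + 1 + (pos // 7) % 3) % 4]


def _variant_frame(chrom: str, pos: np.ndarray, sample_id, genotype: int = 1,
                   quality_flag: str = "pass", somatic_status: str = "unknown") -> pd.DataFrame:
    pos = np.asarray(pos, dtype=np.int64)
    alt = _alt_base(pos)
    ref = _ref_base(pos)
    clash = alt == ref
    if clash.any():  # defensive; the base maps are constructed to differ
        alt = alt.copy()
        alt[clash] = _BASES[(pos[clash] + 2) % 4]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "sample_id": sample_id,
            "genotype": np.int64(genotype),
            "quality_flag": quality_flag,
            "somatic_status": somatic_status,
        }
    )


def simulate_rare_variant_cohort(model: PopulationModel, n_individuals: int, seed=None) -> pd.DataFrame:
    """Simulate per-individual rare singleton variants over the model region.

    Each individual receives a Poisson(rate * length) number of background
    variants placed uniformly, plus Poisson(rate * (fold-1) * window_length)
    extra variants inside each enrichment window.  Positions never coincide
    with the model's common sites.  Carriers are heterozygous; flags are
    "pass".
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = _rng(seed if seed is not None else model.seed)
    region = model.region
    common = set(model.common_positions.tolist())
    frames = []
    for i in range(int(n_individuals)):
        sample = f"S{i + 1:03d}"
        positions: list[np.ndarray] = []
        n_bg = rng.poisson(model.rare_site_rate * region.length)
        if n_bg:
            positions.append(rng.integers(region.start, region.end + 1, size=n_bg))
        for window, fold in model.enrichment_windows:
            n_extra = rng.poisson(model.rare_site_rate * (fold - 1.0) * window.length)
            if n_extra:
                positions.append(rng.integers(window.start, window.end + 1, size=n_extra))
        if not positions:
            continue
        pos = np.concatenate(positions)
        if common:
            keep = np.array([p not in common for p in pos.tolist()], dtype=bool)
            pos = pos[keep]
        if len(pos):
            frames.append(_variant_frame(region.chrom, pos, sample))
    if not frames:
        return empty_variant_table()
    return sort_variants(pd.concat(frames, ignore_index=True)[VARIANT_COLUMNS])


# ---------------------------------------------------------------------------
# tumor-islet call sets
# ---------------------------------------------------------------------------


@dataclass
class IsletModel:
    """Clonal structure of microdissected tumor-islet call sets.

    ``root_variants`` founding-clone mutations are each carried by a
    Bernoulli(``root_presence``) subset of the ``n_islets`` islets;
    ``germline_variants`` are shared by every islet and the matched normal;
    private variants (Poisson(``private_rate``) per islet) are unique to one
    islet.
    """

    n_islets: int = 30
    root_variants: int = 750
    root_presence: float = 0.97
    private_rate: float = 25.0
    germline_variants: int = 200
    region: GenomicInterval = DEFAULT_REGION

    def __post_init__(self) -> None:
        if self.n_islets < 1:
            raise ValueError("n_islets must be >= 1")
        if not (0 < self.root_presence <= 1):
            raise ValueError("root_presence must be in (0, 1]")
        if min(self.root_variants, self.germline_variants) < 0 or self.private_rate < 0:
            raise ValueError("counts and rates must be >= 0")


def simulate_islet_callsets(model: IsletModel, seed=None) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Generate per-islet variant tables plus the matched-normal table.

    Returns
    -------
    (islet_tables, normal_table)
        ``islet_tables`` is a list of ``n_islets`` variant tables with sample
        ids ``islet01`` ...; the normal carries exactly the germline variants.
    """
    rng = _rng(seed)
    region = model.region
    n_positions = model.root_variants + model.germline_variants
    # distinct positions for root and germline variants; private ones drawn
    # uniformly afterwards (collisions with these are re-drawn)
    fixed = rng.choice(np.arange(region.start, region.end + 1), size=n_positions, replace=False)
    root_pos = np.sort(fixed[: model.root_variants])
    germ_pos = np.sort(fixed[model.root_variants:])
    taken = set(fixed.tolist())

    presence = rng.random((model.root_variants, model.n_islets)) < model.root_presence

    islets = []
    for j in range(model.n_islets):
        sample = f"islet{j + 1:02d}"
        parts = []
        if model.germline_variants:
            parts.append(_variant_frame(region.chrom, germ_pos, sample, somatic_status="germline"))
        carried = root_pos[presence[:, j]]
        if len(carried):
            parts.append(_variant_frame(region.chrom, carried, sample, somatic_status="somatic"))
        n_private = rng.poisson(model.private_rate)
        if n_private:
            priv = []
            while len(priv) < n_private:
                p = int(rng.integers(region.start, region.end + 1))
                if p not in taken:
                    taken.add(p)
                    priv.append(p)
            parts.append(_variant_frame(region.chrom, np.array(priv), sample, somatic_status="somatic"))
        islets.append(
            sort_variants(pd.concat(parts, ignore_index=True)) if parts else empty_variant_table()
        )
    if model.germline_variants:
        normal = sort_variants(_variant_frame(region.chrom, germ_pos, "normal", somatic_status="germline"))
    else:
        normal = empty_variant_table()
    return islets, normal


# ---------------------------------------------------------------------------
# gene annotation substrate
# ---------------------------------------------------------------------------


def simulate_gene_annotation(
    n_genes: int,
    region_length: int,
    ontology_sizes: list[int] | None = None,
    seed=None,
    chrom: str = "chr3",
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Random gene layout plus gene-set memberships.

    TSS positions are uniform without replacement over ``[1, region_length]``
    and returned sorted; strands are random; one gene set of each requested
    size is sampled without replacement from the genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    ontology_sizes = ontology_sizes or []
    for size in ontology_sizes:
        if size > n_genes:
            raise ValueError(f"ontology size {size} exceeds n_genes {n_genes}")
    rng = _rng(seed)
    tss = np.sort(rng.choice(np.arange(1, region_length + 1), size=n_genes, replace=False))
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:04d}" for i in range(n_genes)],
            "chrom": chrom,
            "tss": tss.astype(np.int64),
            "strand": strands,
        }
    )
    gene_sets = {
        f"SET{k + 1:02d}": set(rng.choice(genes["gene_id"].to_numpy(), size=size, replace=False).tolist())
        for k, size in enumerate(ontology_sizes)
    }
    return genes, gene_sets


# ---------------------------------------------------------------------------
# IHC nuclear-score simulator
# ---------------------------------------------------------------------------


@dataclass
class IHCModel:
    """Group-level distribution of percent-3+ nuclei.

    ``groups`` maps a group label to (mean, sd, n_cases) of the percentage of
    nuclei scored 3+.  Scores are normal draws censored to [0, 100]
    (clipping; a real scanner reports 0% for cases whose latent score falls
    below zero, so the benign group carries a point mass at 0).  The
    remaining percentage mass is split randomly over the 0/1+/2+ bins.
    """

    groups: dict[str, tuple[float, float, int]] = field(
        default_factory=lambda: {"benign": (3.0, 4.0, 40), "hgsoc": (14.0, 10.0, 40)}
    )
    bounds: tuple[float, float] = (0.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (mean, sd, n) in self.groups.items():
            if sd < 0:
                raise ValueError(f"group {name!r}: sd must be >= 0")
            if n < 2:
                raise ValueError(f"group {name!r}: need n >= 2 cases")


def simulate_ihc_scores(model: IHCModel, seed=None) -> pd.DataFrame:
    """Per-case IHC intensity-bin percentages (columns pct0..pct3 sum to 100)."""
    rng = _rng(seed if seed is not None else model.seed)
    lo, hi = model.bounds
    frames = []
    for group in sorted(model.groups):
        mean, sd, n = model.groups[group]
        p3 = np.clip(rng.normal(mean, sd, size=n), lo, hi) if sd > 0 else np.full(n, float(mean))
        remainder = 100.0 - p3
        weights = rng.dirichlet(np.ones(3), size=n)
        p0 = remainder * weights[:, 0]
        p1 = remainder * weights[:, 1]
        p2 = remainder - p0 - p1  # force exact conservation
        frames.append(
            pd.DataFrame(
                {
                    "case_id": [f"{group}_{i + 1:03d}" for i in range(n)],
                    "group": group,
                    "pct0": p0,
                    "pct1": p1,
                    "pct2": p2,
                    "pct3": p3,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
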