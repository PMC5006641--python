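"""Sliding-window regional rare-variant enrichment scan.

The scan asks whether rare single-nucleotide substitutions observed in a
case cohort cluster anywhere in a target region.  Overlapping fixed-width
windows (default 40 kb every 100 bp) are scored with the ratio

    observed rare variants in cases / expected common-SNP density,

where the expectation is the mean, over Monte-Carlo cohorts drawn from panel
minor-allele frequencies under Hardy-Weinberg equilibrium (no LD), of the
number of non-reference genotype calls per window.  Two nulls calibrate the
statistic: an order-statistic p-value from resampled control-cohort subsets,
and an analytic Poisson upper tail under a uniform variant-occurrence rate
estimated from the whole region.

``RegionalBurdenScan`` bundles the steps into a fit-once model object; each
step is also exposed as a plain function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import (
    ALLOWED_QUALITY_FLAGS,
    GenomicInterval,
    VARIANT_KEY,
    distinct_variants,
    panel_index,
    validate_variants,
)


@dataclass(frozen=True)
class RareVariantFilterConfig:
    """Rare-variant definition.

    A variant is rare when it is carried by fewer than ``max_samples``
    distinct samples (exclusive: exactly ``max_samples`` carriers fails),
    absent from the reference panel, and flagged with an allowed quality
    flag.
    """

    max_samples: int = 5
    allowed_flags: tuple[str, ...] = ALLOWED_QUALITY_FLAGS

    def __post_init__(self) -> None:
        if self.max_samples < 1:
            raise ValueError("max_samples must be >= 1")


@dataclass(frozen=True)
class WindowScanConfig:
    window_size: int = 40_000
    step: int = 100
    n_sim: int = 1000
    cohort_size: int = 33
    n_control_subsets: int = 100
    count_mode: str = "carriers"  # or "sites": segregating sites per window
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step >= 1):
            raise ValueError("need window_size >= step >= 1")
        if self.n_sim < 1 or self.n_control_subsets < 1 or self.cohort_size < 1:
            raise ValueError("n_sim, n_control_subsets and cohort_size must be >= 1")
        if self.count_mode not in ("carriers", "sites"):
            raise ValueError("count_mode must be 'carriers' or 'sites'")


# ---------------------------------------------------------------------------
# rare-variant filter
# ---------------------------------------------------------------------------


def filter_rare_variants(
    variants: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    config: RareVariantFilterConfig = RareVariantFilterConfig(),
) -> pd.DataFrame:
    """Apply the rare-variant filter to a long carrier table.

    Keeps single-nucleotide substitutions that are (i) present in fewer than
    ``config.max_samples`` distinct samples of the input table, (ii) absent
    from ``panel`` (matched on chrom, pos, ref, alt), and (iii) flagged with
    one of ``config.allowed_flags``.
    """
    validate_variants(variants)
    if len(variants) == 0:
        return variants.copy()
    keys = pd.MultiIndex.from_frame(variants[VARIANT_KEY])
    counts = variants.groupby(VARIANT_KEY, sort=False)["sample_id"].nunique()
    recurrence = counts.reindex(keys).to_numpy()
    keep = recurrence < config.max_samples
    keep &= variants["quality_flag"].isin(config.allowed_flags).to_numpy()
    if panel is not None and len(panel):
        keep &= ~keys.isin(panel_index(panel))
    return variants[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def enumerate_windows(
    region: GenomicInterval, config: WindowScanConfig | None = None, *,
    window_size: int | None = None, step: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping fixed-width windows covering a region.

    The first window starts at the region start; starts advance by ``step``;
    the last window ends at or before the region end.  The number of windows
    is floor((L - window_size) / step) + 1.

    Returns ``(starts, ends)`` as 1-based inclusive coordinate arrays.
    """
    config = config or WindowScanConfig()
    w = window_size if window_size is not None else config.window_size
    s = step if step is not None else config.step
    if region.length < w:
        raise ValueError(f"region length {region.length} shorter than window {w}")
    n = (region.length - w) // s + 1
    starts = region.start + s * np.arange(n, dtype=np.int64)
    return starts, starts + w - 1


def count_in_windows(positions, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Count sorted-or-not positions falling in each (inclusive) window."""
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    return (np.searchsorted(pos, ends, side="right") - np.searchsorted(pos, starts, side="left")).astype(np.int64)


def count_rare_in_windows(variants: pd.DataFrame, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Distinct rare variants (not carrier events) per window."""
    return count_in_windows(distinct_variants(variants)["pos"].to_numpy(), starts, ends)


# ---------------------------------------------------------------------------
# expected common-SNP density under HWE
# ---------------------------------------------------------------------------


def expected_common_density(
    panel: pd.DataFrame,
    region: GenomicInterval,
    config: WindowScanConfig = WindowScanConfig(),
    seed=None,
    windows: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo expected common-SNP calls per window.

    For each of ``config.n_sim`` simulated cohorts of ``config.cohort_size``
    individuals, genotypes at each panel site with MAF > 0.05 in the region
    are drawn under HWE; the per-window count is the number of heterozygous
    or alternate-homozygous genotype calls summed over individuals
    (``count_mode='carriers'``), or the number of sites with at least one
    carrier (``count_mode='sites'``).

    Returns
    -------
    (expected, sd) : per-window mean and standard deviation over simulations.
        An empty common-site stratum yields all-zero expectation (warned).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts, ends = windows if windows is not None else enumerate_windows(region, config)
    in_region = (
        (panel["chrom"] == region.chrom)
        & (panel["pos"] >= region.start)
        & (panel["pos"] <= region.end)
        & (panel["maf"] > 0.05)
    )
    sites = panel.loc[in_region, ["pos", "maf"]].sort_values("pos")
    n_windows = len(starts)
    if len(sites) == 0:
        warnings.warn("no common panel sites (MAF > 0.05) in region; expectation is zero everywhere")
        return np.zeros(n_windows), np.zeros(n_windows)
    pos = sites["pos"].to_numpy()
    p = sites["maf"].to_numpy()
    q = 1.0 - (1.0 - p) ** 2  # P(an individual carries >= 1 alternate allele)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    total = np.zeros(n_windows)
    total_sq = np.zeros(n_windows)
    chunk = max(1, min(config.n_sim, int(5e6 // max(n_windows, 1))))
    done = 0
    while done < config.n_sim:
        m = min(chunk, config.n_sim - done)
        if config.count_mode == "carriers":
            site_counts = rng.binomial(config.cohort_size, q, size=(m, len(pos)))
        else:
            site_counts = (rng.random((m, len(pos))) < 1.0 - (1.0 - q) ** config.cohort_size).astype(np.int64)
        cum = np.zeros((m, len(pos) + 1))
        np.cumsum(site_counts, axis=1, out=cum[:, 1:])
        win = cum[:, hi] - cum[:, lo]
        total += win.sum(axis=0)
        total_sq += (win * win).sum(axis=0)
        done += m
    mean = total / config.n_sim
    var = np.maximum(total_sq / config.n_sim - mean**2, 0.0)
    return mean, np.sqrt(var)


def expected_common_density_closed_form(
    panel: pd.DataFrame, region: GenomicInterval, config: WindowScanConfig = WindowScanConfig(),
    windows: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Analytic limit of :func:`expected_common_density` (carriers mode):
    sum over in-window sites of cohort_size * (2p(1-p) + p^2)."""
    starts, ends = windows if windows is not None else enumerate_windows(region, config)
    in_region = (
        (panel["chrom"] == region.chrom)
        & (panel["pos"] >= region.start)
        & (panel["pos"] <= region.end)
        & (panel["maf"] > 0.05)
    )
    sites = panel.loc[in_region, ["pos", "maf"]].sort_values("pos")
    pos = sites["pos"].to_numpy()
    p = sites["maf"].to_numpy()
    per_site = config.cohort_size * (1.0 - (1.0 - p) ** 2)
    cum = np.concatenate([[0.0], np.cumsum(per_site)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    return cum[hi] - cum[lo]


# ---------------------------------------------------------------------------
# window statistic and nulls
# ---------------------------------------------------------------------------


def window_statistic(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Per-window ratio statistic: observed rare / expected common.

    Zero observed gives 0.  Zero expected with positive observed gives +inf
    (a warning is issued); such windows are reported but excluded from
    ranking.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected window vectors differ in length")
    ratio = np.zeros_like(observed)
    pos = observed > 0
    undef = pos & (expected == 0)
    if undef.any():
        warnings.warn(f"{int(undef.sum())} window(s) have observed > 0 with zero expectation")
        ratio[undef] = np.inf
    ok = pos & ~undef
    ratio[ok] = observed[ok] / expected[ok]
    return ratio


def poisson_tail(observed: np.ndarray, lam: float) -> np.ndarray:
    """P(X >= observed) for X ~ Poisson(lam); observed 0 gives 1."""
    return stats.poisson.sf(np.asarray(observed) - 1, lam)


def poisson_local_enrichment(
    variants: pd.DataFrame,
    region: GenomicInterval,
    config: WindowScanConfig = WindowScanConfig(),
    windows: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-window Poisson upper-tail probabilities under a uniform rate.

    The null rate is the global rate over the region (total distinct
    variants / region length); each window's rate parameter is
    rate * window_size and the p-value is P(X >= observed).
    """
    starts, ends = windows if windows is not None else enumerate_windows(region, config)
    dv = distinct_variants(variants)
    dv = dv[(dv["chrom"] == region.chrom) & (dv["pos"] >= region.start) & (dv["pos"] <= region.end)]
    total = len(dv)
    if total < 1:
        raise ValueError("need at least one variant in the region to estimate the global rate")
    window_size = int(ends[0] - starts[0] + 1)
    lam = total / region.length * window_size
    observed = count_in_windows(dv["pos"].to_numpy(), starts, ends)
    return pd.DataFrame(
        {
            "start": starts,
            "end": ends,
            "observed": observed,
            "poisson_p": poisson_tail(observed, lam),
        }
    )


def control_order_statistic_p(
    observed_stat: np.ndarray,
    control_variants: pd.DataFrame,
    expected: np.ndarray,
    windows: tuple[np.ndarray, np.ndarray],
    panel: pd.DataFrame | None = None,
    filter_config: RareVariantFilterConfig = RareVariantFilterConfig(),
    config: WindowScanConfig = WindowScanConfig(),
    seed=None,
) -> np.ndarray:
    """Order-statistic p-value per window from resampled control subsets.

    ``config.n_control_subsets`` subsets of ``config.cohort_size`` distinct
    control individuals are drawn (without replacement within a subset,
    independently across subsets); each subset is passed through the same
    rare-variant filter and window ratio statistic.  The p-value is the
    fraction of subsets whose statistic is >= the observed one (ties count
    against significance).  A value of exactly 0 means "< 1/N"; see
    :func:`format_order_p`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts, ends = windows
    observed_stat = np.asarray(observed_stat, dtype=float)
    samples = pd.unique(control_variants["sample_id"])
    if len(samples) < config.cohort_size:
        raise ValueError(
            f"control cohort has {len(samples)} individuals < cohort_size {config.cohort_size}"
        )
    exceed = np.zeros(len(starts), dtype=np.int64)
    for _ in range(config.n_control_subsets):
        chosen = rng.choice(samples, size=config.cohort_size, replace=False)
        sub = control_variants[control_variants["sample_id"].isin(chosen)]
        rare = filter_rare_variants(sub, panel, filter_config)
        counts = count_rare_in_windows(rare, starts, ends) if len(rare) else np.zeros(len(starts))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = window_statistic(counts, expected)
        exceed += stat >= observed_stat
    return exceed / config.n_control_subsets


def format_order_p(p: float, n_subsets: int) -> str:
    """Render an order-statistic p-value, using the '< 1/N' sentinel at 0."""
    if p == 0:
        return f"< {1.0 / n_subsets:g}"
    return f"{p:g}"


# ---------------------------------------------------------------------------
# regulatory-track overlap annotation
# ---------------------------------------------------------------------------


def annotate_regulatory_overlap(
    variants: pd.DataFrame, tracks: dict[str, pd.DataFrame]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag variants overlapping named interval tracks (1-based inclusive).

    Returns the variant table with one boolean column per track plus an
    ``in_any_track`` column, and a summary dict of distinct-variant overlap
    counts per track (key ``any``: variants overlapping >= 1 track).
    """
    out = variants.copy()
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, intervals in tracks.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, sub in intervals.groupby("chrom"):
            tree = IntervalTree()
            for s, e in zip(sub["start"], sub["end"]):
                tree.addi(int(s), int(e) + 1)  # inclusive end
            per_chrom[str(chrom)] = tree
        trees[name] = per_chrom
    any_hit = np.zeros(len(out), dtype=bool)
    for name, per_chrom in trees.items():
        hits = np.array(
            [
                bool(per_chrom.get(c, IntervalTree())[p])
                for c, p in zip(out["chrom"], out["pos"])
            ],
            dtype=bool,
        )
        out[f"in_{name}"] = hits
        any_hit |= hits
    out["in_any_track"] = any_hit
    dv = out.drop_duplicates(VARIANT_KEY)
    summary = {name: int(dv[f"in_{name}"].sum()) for name in tracks}
    summary["any"] = int(dv["in_any_track"].sum())
    return out, summary


# ---------------------------------------------------------------------------
# cohort carrier summary
# ---------------------------------------------------------------------------


def percent(k: int, n: int, decimals: int = 1) -> float:
    """Percentage rounded to the printed precision (one decimal by default)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, decimals)


def carrier_summary(variants: pd.DataFrame, region: GenomicInterval | None = None, n_cohort: int | None = None) -> dict:
    """Summarise how many cohort samples carry variants in a region.

    Returns distinct variant and carrier counts, the percentage of the
    cohort carrying any variant, and the same restricted to records labeled
    somatic.  ``n_cohort`` defaults to the number of distinct samples in the
    table.
    """
    sub = variants
    if region is not None:
        sub = sub[(sub["chrom"] == region.chrom) & (sub["pos"] >= region.start) & (sub["pos"] <= region.end)]
    n = int(n_cohort) if n_cohort is not None else sub["sample_id"].nunique()
    somatic = sub[sub["somatic_status"] == "somatic"]
    n_carriers = sub["sample_id"].nunique()
    n_somatic_carriers = somatic["sample_id"].nunique()
    return {
        "n_cohort": n,
        "n_variants": len(distinct_variants(sub)),
        "n_carriers": int(n_carriers),
        "pct_carriers": percent(int(n_carriers), n),
        "n_somatic_variants": len(distinct_variants(somatic)),
        "n_somatic_carriers": int(n_somatic_carriers),
        "pct_somatic_carriers": percent(int(n_somatic_carriers), n),
    }


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class RegionalBurdenScan:
    """Sliding-window rare-variant burden scan over one region.

    Parameters
    ----------
    case_variants : long carrier table for the case cohort
    region : GenomicInterval
    panel : allele-frequency panel (filtering and the HWE expectation)
    control_variants : optional control-cohort carrier table for the
        order-statistic null
    filter_config, config : stage configurations

    ``fit`` runs: rare filter -> window enumeration -> Monte-Carlo expected
    density -> ratio statistic -> Poisson tail -> (optional) order-statistic
    p-values, and returns a :class:`RegionalBurdenScanResults`.
    """

    def __init__(
        self,
        case_variants: pd.DataFrame,
        region: GenomicInterval,
        panel: pd.DataFrame,
        control_variants: pd.DataFrame | None = None,
        filter_config: RareVariantFilterConfig = RareVariantFilterConfig(),
        config: WindowScanConfig = WindowScanConfig(),
    ) -> None:
        self.case_variants = validate_variants(case_variants)
        self.region = region
        self.panel = panel
        self.control_variants = control_variants
        self.filter_config = filter_config
        self.config = config

    def fit(self, seed=None) -> "RegionalBurdenScanResults":
        seed = seed if seed is not None else self.config.seed
        ss = np.random.SeedSequence(seed)
        rng_sim, rng_ctrl = (np.random.default_rng(s) for s in ss.spawn(2))

        rare = filter_rare_variants(self.case_variants, self.panel, self.filter_config)
        windows = enumerate_windows(self.region, self.config)
        starts, ends = windows
        observed = count_rare_in_windows(rare, starts, ends)
        expected, expected_sd = expected_common_density(
            self.panel, self.region, self.config, seed=rng_sim, windows=windows
        )
        ratio = window_statistic(observed, expected)
        pois = poisson_local_enrichment(rare, self.region, self.config, windows=windows)

        frame = pd.DataFrame(
            {
                "chrom": self.region.chrom,
                "start": starts,
                "end": ends,
                "observed": observed,
                "expected": expected,
                "expected_sd": expected_sd,
                "ratio": ratio,
                "poisson_p": pois["poisson_p"].to_numpy(),
            }
        )
        if self.control_variants is not None:
            order_p = control_order_statistic_p(
                ratio,
                self.control_variants,
                expected,
                windows,
                panel=self.panel,
                filter_config=self.filter_config,
                config=self.config,
                seed=rng_ctrl,
            )
            frame["order_p"] = order_p
            frame["order_p_label"] = [
                format_order_p(p, self.config.n_control_subsets) for p in order_p
            ]
        return RegionalBurdenScanResults(frame, self, rare)


class RegionalBurdenScanResults:
    """Results of a :class:`RegionalBurdenScan` fit."""

    def __init__(self, frame: pd.DataFrame, model: RegionalBurdenScan, rare_variants: pd.DataFrame) -> None:
        self.frame = frame
        self.model = model
        self.rare_variants = rare_variants
        self.n_rare = len(distinct_variants(rare_variants))
        self.global_rate = self.n_rare / model.region.length

    def top_windows(self, n: int = 10, by: str = "ratio") -> pd.DataFrame:
        """Best windows ranked by the chosen column (infinite ratios are
        reported in ``frame`` but excluded from ranking)."""
        frame = self.frame[np.isfinite(self.frame["ratio"])]
        ascending = by in ("poisson_p", "order_p")
        return frame.sort_values(by, ascending=ascending, kind="mergesort").head(n)

    def to_bed(self, path, n: int = 10, by: str = "ratio") -> None:
        from .io import write_bed

        top = self.top_windows(n=n, by=by).copy()
        top["name"] = [f"window_{i}" for i in range(len(top))]
        write_bed(top[["chrom", "start", "end", "name"]], path)

    def summary(self) -> str:
        model = self.model
        lines = [
            "Regional rare-variant burden scan",
            "=================================",
            f"region:            {model.region} ({model.region.length:,} bp)",
            f"windows:           {len(self.frame):,} x {model.config.window_size:,} bp "
            f"(step {model.config.step} bp)",
            f"rare variants:     {self.n_rare} distinct "
            f"(global rate {self.global_rate * 1e6:.2f} per Mb)",
            f"expectation:       mean of {model.config.n_sim} HWE cohort simulations "
            f"(cohort size {model.config.cohort_size}, {model.config.count_mode})",
        ]
        if "order_p" in self.frame.columns:
            lines.append(
                f"order-statistic:   {model.config.n_control_subsets} control subsets"
            )
        lines.append("")
        cols = ["start", "end", "observed", "expected", "ratio", "poisson_p"]
        if "order_p_label" in self.frame.columns:
            cols.append("order_p_label")
        top = self.top_windows(5)[cols]
        lines.append("top windows by ratio statistic:")
        lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append(
            "note: p-values are reported per window without multiple-testing "
            "correction across overlapping windows."
        )
        return "\n".join(lines)
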