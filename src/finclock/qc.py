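"""Quality control of per-site methylation read counts.

Filters mirror the enzymatic-conversion RADseq workflow: sites that cannot be
genotyped in the untreated library portion or that look like C/T (G/A on the
reverse strand) polymorphisms are dropped first, then shallowly sequenced
individuals, then sites with poor presence across individuals, then sites
whose exact binomial confidence intervals are too wide in too many
individuals. Percent methylation is the methylated-read fraction with a
Clopper-Pearson 95% interval per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import logger

# provenance codes for PercentMethylationMatrix cells
MISSING, OBSERVED, IMPUTED = 0, 1, 2

_SITE_COLUMNS = ["site_id", "chromosome", "position", "strand"]


@dataclass
class MethylationCountMatrix:
    """Per (fish, site) methylated/total read counts plus metadata.

    ``meth`` and ``total`` are integer arrays of shape (n_fish, n_sites);
    ``total == 0`` encodes a missing cell. ``sites`` is a DataFrame with
    columns site_id, chromosome, position (1-based), strand; site keys must be
    unique on (chromosome, position, strand).
    """

    fish_ids: list[str]
    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        n_fish, n_sites = len(self.fish_ids), len(self.sites)
        if self.meth.shape != (n_fish, n_sites) or self.total.shape != (n_fish, n_sites):
            raise ValueError(
                f"count arrays must be (n_fish={n_fish}, n_sites={n_sites}); "
                f"got meth {self.meth.shape}, total {self.total.shape}"
            )
        if not np.issubdtype(self.meth.dtype, np.integer):
            raise ValueError("meth must be an integer array")
        if not np.issubdtype(self.total.dtype, np.integer):
            raise ValueError("total must be an integer array")
        bad = (self.meth > self.total) | (self.meth < 0)
        if bad.any():
            f, s = map(int, np.argwhere(bad)[0])
            raise ValueError(
                "meth > total (or negative) at cell "
                f"(fish={self.fish_ids[f]}, site={self.sites['site_id'].iloc[s]})"
            )
        missing_cols = [c for c in _SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"site table missing columns {missing_cols}")
        keys = self.sites[["chromosome", "position", "strand"]]
        if keys.duplicated().any():
            raise ValueError("duplicate site keys on (chromosome, position, strand)")
        if pd.Index(self.sites["site_id"]).has_duplicates:
            raise ValueError("duplicate site_id values")
        self.sites = self.sites.reset_index(drop=True)

    # ---- basic geometry ---------------------------------------------------
    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])

    def observed(self) -> np.ndarray:
        """Boolean (fish x site) mask of cells with at least one read."""
        return self.total > 0

    def subset_sites(self, keep: np.ndarray) -> "MethylationCountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MethylationCountMatrix(
            fish_ids=list(self.fish_ids),
            sites=self.sites.iloc[keep].reset_index(drop=True),
            meth=self.meth[:, keep],
            total=self.total[:, keep],
        )

    def subset_fish(self, keep: np.ndarray) -> "MethylationCountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MethylationCountMatrix(
            fish_ids=[self.fish_ids[i] for i in keep],
            sites=self.sites,
            meth=self.meth[keep],
            total=self.total[keep],
        )


@dataclass
class PercentMethylationMatrix:
    """Per-cell methylation fraction with 95% bounds and provenance flags.

    ``p`` is (n_fish, n_sites) with NaN at missing cells; ``provenance`` uses
    the module codes MISSING/OBSERVED/IMPUTED. Imputed cells carry no CI.
    """

    fish_ids: list[str]
    sites: pd.DataFrame
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    provenance: np.ndarray

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])

    def ci_width(self) -> np.ndarray:
        return self.ci_high - self.ci_low

    def to_frame(self) -> pd.DataFrame:
        """Fish x site DataFrame of methylation fractions."""
        return pd.DataFrame(self.p, index=self.fish_ids, columns=self.site_ids)

    def copy(self) -> "PercentMethylationMatrix":
        return PercentMethylationMatrix(
            fish_ids=list(self.fish_ids),
            sites=self.sites.copy(),
            p=self.p.copy(),
            ci_low=self.ci_low.copy(),
            ci_high=self.ci_high.copy(),
            provenance=self.provenance.copy(),
        )


def clopper_pearson_interval(x, n, conf: float = 0.95):
    """Exact (Clopper-Pearson) binomial confidence interval.

    ``low = BetaQuantile(alpha/2; x, n-x+1)`` (0 when x = 0) and
    ``high = BetaQuantile(1-alpha/2; x+1, n-x)`` (1 when x = n). Accepts
    scalars or arrays; returns (low, high) of the broadcast shape.
    """
    x_arr = np.asarray(x)
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    if np.any((x_arr < 0) | (x_arr > n_arr)):
        raise ValueError("need 0 <= x <= n")
    alpha = 1.0 - conf
    with np.errstate(invalid="ignore"):
        low = stats.beta.ppf(alpha / 2.0, x_arr, n_arr - x_arr + 1)
        high = stats.beta.ppf(1.0 - alpha / 2.0, x_arr + 1, n_arr - x_arr)
    low = np.where(x_arr == 0, 0.0, low)
    high = np.where(x_arr == n_arr, 1.0, high)
    if np.isscalar(x) and np.isscalar(n):
        return float(low), float(high)
    return low, high


def drop_ungenotyped_and_snp_sites(
    matrix: MethylationCountMatrix,
    substitution_table: pd.DataFrame,
    threshold: float = 0.05,
) -> MethylationCountMatrix:
    """Remove sites not genotyped in the untreated libraries or SNP-suspect.

    ``substitution_table`` has columns site_id, untreated_reads,
    substituted_reads, pooled across individuals. A site absent from the table
    or with untreated_reads == 0 is ungenotyped; a site whose pooled
    substitution fraction is strictly greater than ``threshold`` (default 5%)
    is a potential polymorphism. Both are dropped.
    """
    tab = substitution_table.set_index("site_id")
    ungenotyped = np.zeros(matrix.n_sites, dtype=bool)
    snp = np.zeros(matrix.n_sites, dtype=bool)
    for j, site_id in enumerate(matrix.site_ids):
        if site_id not in tab.index:
            ungenotyped[j] = True
            continue
        row = tab.loc[site_id]
        untreated = float(row["untreated_reads"])
        if untreated <= 0:
            ungenotyped[j] = True
            continue
        if float(row["substituted_reads"]) / untreated > threshold:
            snp[j] = True
    keep = ~(ungenotyped | snp)
    logger.info(
        "genotype/SNP filter: %d ungenotyped, %d SNP-suspect removed, %d retained",
        int(ungenotyped.sum()), int(snp.sum()), int(keep.sum()),
    )
    return matrix.subset_sites(keep)


def drop_low_coverage_individuals(
    matrix: MethylationCountMatrix, min_sites: int = 400_000
) -> MethylationCountMatrix:
    """Remove fish observed (total > 0) at fewer than ``min_sites`` sites."""
    n_observed = (matrix.total > 0).sum(axis=1)
    keep = n_observed >= min_sites
    if not keep.any():
        raise ValueError(
            f"low-coverage filter would remove every fish (min_sites={min_sites}); "
            "review the threshold for this dataset's scale"
        )
    logger.info(
        "coverage filter: %d fish removed (< %d observed sites), %d retained",
        int((~keep).sum()), min_sites, int(keep.sum()),
    )
    return matrix.subset_fish(keep)


def drop_low_presence_sites(
    matrix: MethylationCountMatrix, min_frac: float = 0.80
) -> MethylationCountMatrix:
    """Retain sites observed in at least ``min_frac`` of retained fish."""
    if matrix.n_fish == 0 or matrix.n_sites == 0:
        raise ValueError("empty matrix")
    presence = (matrix.total > 0).mean(axis=0)
    keep = presence >= min_frac
    logger.info(
        "presence filter: %d sites removed (< %.0f%% of fish), %d retained",
        int((~keep).sum()), 100 * min_frac, int(keep.sum()),
    )
    return matrix.subset_sites(keep)


def drop_wide_ci_sites(
    matrix: MethylationCountMatrix,
    max_width: float = 0.85,
    min_frac: float = 0.80,
    conf: float = 0.95,
) -> MethylationCountMatrix:
    """Retain sites whose CI width is < ``max_width`` in >= ``min_frac`` of
    fish with observed cells (a depth filter: width < 0.85 corresponds
    roughly to a mean of 16 reads)."""
    obs = matrix.total > 0
    width = np.ones_like(matrix.meth, dtype=float)  # unobserved -> ignored below
    if obs.any():
        low, high = clopper_pearson_interval(matrix.meth[obs], matrix.total[obs], conf)
        width[obs] = high - low
    narrow = (width < max_width) & obs
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac_narrow = np.where(n_obs > 0, narrow.sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    keep = frac_narrow >= min_frac
    logger.info(
        "CI-width filter: %d sites removed (width >= %.2f in > %.0f%% of fish), %d retained",
        int((~keep).sum()), max_width, 100 * (1 - min_frac), int(keep.sum()),
    )
    return matrix.subset_sites(keep)


def percent_methylation(matrix: MethylationCountMatrix, conf: float = 0.95) -> PercentMethylationMatrix:
    """Methylated / total per observed cell, with Clopper-Pearson bounds."""
    obs = matrix.total > 0
    p = np.full(matrix.meth.shape, np.nan)
    ci_low = np.full(matrix.meth.shape, np.nan)
    ci_high = np.full(matrix.meth.shape, np.nan)
    if obs.any():
        p[obs] = matrix.meth[obs] / matrix.total[obs]
        low, high = clopper_pearson_interval(matrix.meth[obs], matrix.total[obs], conf)
        ci_low[obs] = low
        ci_high[obs] = high
    provenance = np.where(obs, OBSERVED, MISSING).astype(np.uint8)
    return PercentMethylationMatrix(
        fish_ids=list(matrix.fish_ids),
        sites=matrix.sites.copy(),
        p=p,
        ci_low=ci_low,
        ci_high=ci_high,
        provenance=provenance,
    )


def global_methylation_summary(pmatrix: PercentMethylationMatrix) -> tuple[float, float]:
    """(mean, SD) across sites of the per-site mean methylation fraction."""
    if pmatrix.p.shape[1] < 1:
        raise ValueError("need at least one site")
    site_means = np.nanmean(pmatrix.p, axis=0)
    mean = float(np.mean(site_means))
    sd = float(np.std(site_means, ddof=1)) if site_means.size > 1 else 0.0
    return mean, sd


def apply_qc(
    matrix: MethylationCountMatrix,
    substitution_table: pd.DataFrame,
    snp_threshold: float = 0.05,
    min_sites: int = 400_000,
    presence_frac: float = 0.80,
    ci_max_width: float = 0.85,
    ci_min_frac: float = 0.80,
) -> tuple[MethylationCountMatrix, dict]:
    """Run the four QC filters in order and return (matrix, accounting).

    Order follows the workflow's prose: genotype/SNP sites, then low-coverage
    individuals, then site presence, then CI width. The accounting dict
    reconciles: sites_in = removed (per reason) + sites_out.
    """
    acct: dict[str, int] = {"sites_in": matrix.n_sites, "fish_in": matrix.n_fish}
    m1 = drop_ungenotyped_and_snp_sites(matrix, substitution_table, snp_threshold)
    acct["sites_removed_genotype_snp"] = matrix.n_sites - m1.n_sites
    m2 = drop_low_coverage_individuals(m1, min_sites)
    acct["fish_removed_low_coverage"] = m1.n_fish - m2.n_fish
    m3 = drop_low_presence_sites(m2, presence_frac)
    acct["sites_removed_presence"] = m2.n_sites - m3.n_sites
    m4 = drop_wide_ci_sites(m3, ci_max_width, ci_min_frac)
    acct["sites_removed_ci_width"] = m3.n_sites - m4.n_sites
    acct["sites_out"] = m4.n_sites
    acct["fish_out"] = m4.n_fish
    return m4, acct
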