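"""Synthetic methylation cohorts with known per-site ground truth.

The generator emulates the per-site count summaries an enzymatic-conversion
RADseq workflow produces after mapping: per (fish, CpG site) methylated/total
read counts, an untreated-library substitution summary for genotype/SNP
filtering, and a fish metadata table with otolith readings. Site classes:

- ``age_linear``     log-odds of methylation change linearly with age;
- ``env_linear``     log-odds shift by water body, no age effect;
- ``age_by_env``     age slope differs by water body (age-by-environment);
- ``snp_confounded`` apparent methylation is genotype-driven (Hardy-Weinberg
  genotypes at an underlying C/T polymorphism) and the untreated libraries
  show a > 5% substitution fraction;
- ``neutral``        no age or environment effect.

Every random draw flows from ``config.seed``, so a fixed configuration gives
bit-identical integer count matrices across runs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .aging import FishRecord
from .qc import MethylationCountMatrix

SITE_CLASSES = ("age_linear", "env_linear", "age_by_env", "snp_confounded", "neutral")


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated cohort.

    Defaults describe the reference cohort used throughout the test suite:
    150 fish aged ~1-13 years from two water bodies, 2,400 CpG sites with 300
    age-informative sites (|beta1| in [0.05, 0.3] logit/yr), 100
    environment-confounded sites, negative-binomial depth with mean 30, and a
    baseline methylation level centred near 80%.
    """

    n_fish: int = 150
    age_range: tuple[float, float] = (1.0, 13.0)
    n_water_bodies: int = 2
    water_body_sizes: tuple[int, ...] | None = None
    n_sites_by_class: dict[str, int] = field(
        default_factory=lambda: {
            "age_linear": 300,
            "env_linear": 50,
            "age_by_env": 50,
            "snp_confounded": 100,
            "neutral": 1900,
        }
    )
    beta1_range: tuple[float, float] = (0.05, 0.3)  # logit-units / year, sign random
    env_effect_range: tuple[float, float] = (0.5, 1.5)  # logit-units
    slope_interaction_range: tuple[float, float] = (0.05, 0.15)  # logit/yr between WBs
    beta0_mean: float = float(logit(0.8))
    beta0_sd: float = 0.3
    depth_mean: float = 30.0
    depth_dispersion: float = 8.0
    missing_cell_rate: float = 0.05
    fish_random_intercept_sd: float = 0.3
    ungenotyped_rate: float = 0.02
    capture_year: int = 2024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish <= 0:
            raise ValueError("n_fish must be > 0")
        lo, hi = self.age_range
        if not lo < hi or lo < 0:
            raise ValueError("age_range must satisfy 0 <= min < max")
        if self.n_water_bodies <= 0:
            raise ValueError("n_water_bodies must be > 0")
        unknown = set(self.n_sites_by_class) - set(SITE_CLASSES)
        if unknown:
            raise ValueError(f"unknown site classes {sorted(unknown)}")
        if any(v < 0 for v in self.n_sites_by_class.values()):
            raise ValueError("site class counts must be >= 0")
        if sum(self.n_sites_by_class.values()) == 0:
            raise ValueError("at least one site class count must be > 0")
        for name in ("missing_cell_rate", "ungenotyped_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.water_body_sizes is not None:
            if len(self.water_body_sizes) != self.n_water_bodies:
                raise ValueError("water_body_sizes length must equal n_water_bodies")
            if sum(self.water_body_sizes) != self.n_fish:
                raise ValueError("water_body_sizes must sum to n_fish")

    @property
    def water_body_labels(self) -> list[str]:
        return [f"waterbody_{i + 1}" for i in range(self.n_water_bodies)]

    @property
    def n_sites(self) -> int:
        return sum(self.n_sites_by_class.values())


@dataclass
class SiteTruth:
    """Generative ground truth for one site (water-body effects keyed by label).

    ``slope_by_env`` holds per-water-body deviations added to ``beta1`` at
    age-by-environment sites; it is all-zero for every other class.
    """

    site_id: str
    site_class: str
    beta0: float
    beta1: float
    env_effects: dict[str, float]
    slope_by_env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.site_class == "neutral":
            assert self.beta1 == 0 and all(v == 0 for v in self.env_effects.values())
        if self.site_class == "age_linear":
            assert all(v == 0 for v in self.env_effects.values())


def site_methylation_probability(
    truth: SiteTruth, age: float, water_body: str, fish_intercept: float = 0.0
) -> float:
    """Inverse-logit of beta0 + (beta1 + slope_dev[wb]) * age + env[wb] + u_fish."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if water_body not in truth.env_effects:
        raise ValueError(
            f"unknown water body {water_body!r}; configured: {sorted(truth.env_effects)}"
        )
    slope = truth.beta1 + truth.slope_by_env.get(water_body, 0.0)
    eta = truth.beta0 + slope * age + truth.env_effects[water_body] + fish_intercept
    return float(expit(eta))


def _draw_site_truths(config: SyntheticConfig, rng: np.random.Generator) -> list[SiteTruth]:
    labels = config.water_body_labels
    classes = np.repeat(
        [c for c in SITE_CLASSES if config.n_sites_by_class.get(c, 0) > 0],
        [config.n_sites_by_class[c] for c in SITE_CLASSES if config.n_sites_by_class.get(c, 0) > 0],
    )
    rng.shuffle(classes)
    mean_age = 0.5 * (config.age_range[0] + config.age_range[1])
    truths: list[SiteTruth] = []
    for j, cls in enumerate(classes):
        site_id = f"s{j:06d}"
        base0 = rng.normal(config.beta0_mean, config.beta0_sd)
        beta1 = 0.0
        env = {lab: 0.0 for lab in labels}
        slope_dev = {lab: 0.0 for lab in labels}
        if cls in ("age_linear", "age_by_env"):
            beta1 = rng.uniform(*config.beta1_range) * rng.choice([-1.0, 1.0])
            # centre so methylation sits near the baseline at the cohort's mid age
            base0 -= beta1 * mean_age
        if cls == "env_linear":
            amp = rng.uniform(*config.env_effect_range)
            raw = rng.uniform(-amp, amp, size=len(labels))
            raw -= raw.mean()
            env = dict(zip(labels, raw))
        if cls == "age_by_env":
            amp = rng.uniform(*config.slope_interaction_range)
            raw = rng.uniform(-amp, amp, size=len(labels))
            raw -= raw.mean()
            slope_dev = dict(zip(labels, raw))
            base0 -= 0.0  # main effects stay zero; separation grows with age
        truths.append(
            SiteTruth(
                site_id=site_id,
                site_class=str(cls),
                beta0=float(base0),
                beta1=float(beta1),
                env_effects=env,
                slope_by_env=slope_dev,
            )
        )
    return truths


def _draw_fish(config: SyntheticConfig, rng: np.random.Generator) -> list[FishRecord]:
    labels = config.water_body_labels
    if config.water_body_sizes is not None:
        sizes = list(config.water_body_sizes)
    else:
        base = config.n_fish // config.n_water_bodies
        sizes = [base] * config.n_water_bodies
        for i in range(config.n_fish - base * config.n_water_bodies):
            sizes[i] += 1
    assignments = np.repeat(labels, sizes)
    ages = rng.uniform(*config.age_range, size=config.n_fish)
    records = []
    birthday = _dt.date(config.capture_year, 3, 15)
    for i in range(config.n_fish):
        zones = int(np.floor(ages[i]))
        days = int(np.clip(np.floor((ages[i] - zones) * 365), 0, 364))
        capture = birthday + _dt.timedelta(days=days)
        # crude von-Bertalanffy-flavoured morphometrics, for realism only
        length = 600 * (1 - np.exp(-0.35 * (ages[i] + 0.5))) * rng.normal(1, 0.05)
        weight = 1e-5 * length**3 * rng.normal(1, 0.1)
        records.append(
            FishRecord(
                fish_id=f"F{i + 1:04d}",
                water_body=str(assignments[i]),
                capture_date=capture,
                reader1_zones=zones,
                reader2_zones=zones,
                total_length=round(float(length), 1),
                weight=round(float(weight), 1),
                extra={"true_age": float(ages[i])},
            )
        )
    return records


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[MethylationCountMatrix, list[FishRecord], list[SiteTruth]]:
    """Draw a full cohort: counts, fish records and per-site ground truth.

    Per-cell total reads are negative-binomial (over-dispersed RADseq
    coverage); methylated reads are binomial given the site's methylation
    probability; cells are independently missing (total = 0) at
    ``missing_cell_rate``. Fish share one random intercept across sites.
    """
    rng = np.random.default_rng(config.seed)
    truths = _draw_site_truths(config, rng)
    fish = _draw_fish(config, rng)
    n_fish, n_sites = config.n_fish, len(truths)
    labels = config.water_body_labels
    wb_index = {lab: k for k, lab in enumerate(labels)}

    ages = np.array([rec.extra["true_age"] for rec in fish])
    wb = np.array([wb_index[rec.water_body] for rec in fish])
    u_fish = rng.normal(0.0, config.fish_random_intercept_sd, size=n_fish)

    beta0 = np.array([t.beta0 for t in truths])
    beta1 = np.array([t.beta1 for t in truths])
    env = np.array([[t.env_effects[lab] for lab in labels] for t in truths])  # site x wb
    slope_dev = np.array([[t.slope_by_env.get(lab, 0.0) for lab in labels] for t in truths])

    slopes = beta1[None, :] + slope_dev.T[wb]  # fish x site
    eta = beta0[None, :] + slopes * ages[:, None] + env.T[wb] + u_fish[:, None]

    # genotype-driven signal at SNP-confounded sites
    snp_cols = [j for j, t in enumerate(truths) if t.site_class == "snp_confounded"]
    for j in snp_cols:
        maf = rng.uniform(0.1, 0.5)
        geno = rng.binomial(2, maf, size=n_fish)  # copies of the T allele
        eta[:, j] = beta0[j] + (geno - 1) * 2.5 + u_fish

    p = expit(eta)
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)
    total = rng.negative_binomial(nb_n, nb_p, size=(n_fish, n_sites))
    missing = rng.random(size=(n_fish, n_sites)) < config.missing_cell_rate
    total[missing] = 0
    meth = rng.binomial(total, p)
    meth[total == 0] = 0

    sites = pd.DataFrame(
        {
            "site_id": [t.site_id for t in truths],
            "chromosome": "chr1",
            "position": np.arange(1, n_sites + 1) * 100,
            "strand": "+",
        }
    )
    matrix = MethylationCountMatrix(
        fish_ids=[rec.fish_id for rec in fish],
        sites=sites,
        meth=meth.astype(np.int64),
        total=total.astype(np.int64),
    )
    return matrix, fish, truths


def simulate_untreated_substitutions(
    config: SyntheticConfig, truths: list[SiteTruth]
) -> pd.DataFrame:
    """Pooled untreated-library substitution summary per site.

    SNP-confounded sites get substitution fractions strictly above 5% (drawn
    in (0.05, 0.5]); all other sites stay at or below 5%. A random
    ``ungenotyped_rate`` fraction of sites receives zero untreated reads.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for t in truths:
        untreated = int(rng.poisson(config.depth_mean * config.n_fish))
        untreated = max(untreated, 40)
        if t.site_class == "snp_confounded":
            frac = rng.uniform(0.05, 0.5)
            substituted = int(np.floor(frac * untreated)) + 1  # keep strictly > 5%
            while substituted / untreated <= 0.05:
                substituted += 1
        else:
            frac = rng.uniform(0.0, 0.05)
            substituted = int(np.floor(frac * untreated))  # ratio stays <= 5%
        if rng.random() < config.ungenotyped_rate:
            untreated, substituted = 0, 0
        rows.append((t.site_id, untreated, substituted))
    return pd.DataFrame(rows, columns=["site_id", "untreated_reads", "substituted_reads"])


def truths_to_frame(truths: list[SiteTruth]) -> pd.DataFrame:
    """Site-truth table with JSON-encoded per-water-body effects."""
    import json

    return pd.DataFrame(
        {
            "site_id": [t.site_id for t in truths],
            "class": [t.site_class for t in truths],
            "beta0": [t.beta0 for t in truths],
            "beta1": [t.beta1 for t in truths],
            "env_effects": [json.dumps(t.env_effects) for t in truths],
            "slope_by_env": [json.dumps(t.slope_by_env) for t in truths],
        }
    )
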