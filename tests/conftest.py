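"""Shared fixtures: the reference synthetic cohort and one full pipeline run.

The heavy artifacts (QC'd cohort, imputed matrix, full pipeline output) are
session-scoped so the acceptance tests and the accounting tests share a
single computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from finclock import io, qc, screen, synth
from finclock.aging import select_agreement_subset
from finclock.config import PipelineConfig
from finclock.pipeline import run_pipeline

logging.getLogger("finclock").setLevel(logging.ERROR)

REFERENCE_SEED = 2026


@pytest.fixture(scope="session")
def reference_cohort():
    """Reference synthetic cohort: counts, fish, truths, substitutions."""
    cfg = synth.SyntheticConfig(seed=REFERENCE_SEED)
    matrix, fish, truths = synth.simulate_cohort(cfg)
    subs = synth.simulate_untreated_substitutions(cfg, truths)
    return cfg, matrix, fish, truths, subs


@pytest.fixture(scope="session")
def qc_cohort(reference_cohort):
    """Reference cohort after QC, with aligned age/water-body vectors."""
    _, matrix, fish, truths, subs = reference_cohort
    agreed = select_agreement_subset(fish)
    by_id = {r.fish_id: r for r in agreed}
    filtered, acct = qc.apply_qc(matrix, subs, min_sites=50)
    ages_frac = np.array([by_id[f].fractional_age for f in filtered.fish_ids])
    ages_int = np.array([by_id[f].integer_age for f in filtered.fish_ids])
    water = np.array([by_id[f].water_body for f in filtered.fish_ids])
    return filtered, acct, ages_frac, ages_int, water, truths


@pytest.fixture(scope="session")
def imputed_frame(qc_cohort):
    """Complete (imputed) percent-methylation DataFrame for the QC'd cohort."""
    filtered, _, _, ages_int, water, truths = qc_cohort
    pm = qc.percent_methylation(filtered)
    pmi = screen.impute_missing_cells(pm, ages_int)
    return pmi.to_frame(), water, truths


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, reference_cohort):
    """One full pipeline run on the reference cohort (shared, ~5 min)."""
    _, matrix, fish, truths, subs = reference_cohort
    tmp = tmp_path_factory.mktemp("pipeline")
    io.write_count_matrix(matrix, tmp / "meth.tsv", tmp / "total.tsv")
    io.write_substitution_table(subs, tmp / "subs.tsv")
    io.write_fish_metadata(fish, tmp / "fish.csv")
    cfg = PipelineConfig(min_sites=50, iterations=200, subset_size=50, seed=REFERENCE_SEED)
    manifest = run_pipeline(
        cfg, tmp / "meth.tsv", tmp / "total.tsv", tmp / "subs.tsv",
        tmp / "fish.csv", tmp / "out",
    )
    return manifest, tmp / "out", fish, truths
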