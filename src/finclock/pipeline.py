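"""End-to-end driver: QC -> age screen -> environment removal -> clock -> scores.

Every stage writes its tabular artifact into the output directory, and a
manifest records the configuration hash, per-stage seeds and the site/fish
accounting so a run can be audited and reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clock as clockmod
from . import envfilter, evaluate, qc, screen
from ._utils import logger, stage_seed
from .aging import select_agreement_subset
from .config import PipelineConfig
from .io import read_count_data, read_fish_metadata, read_substitution_table


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def run_pipeline(
    config: PipelineConfig,
    meth_path,
    total_path,
    substitutions_path,
    fish_path,
    outdir,
) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seeds": {
            s: stage_seed(config.seed, s)
            for s in ("screen", "envfilter", "partition", "clock")
        },
        "counts": {},
        "metrics": {},
    }

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(stage, exc) from exc

    # ---- load -------------------------------------------------------------
    try:
        matrix = read_count_data(meth_path, total_path)
        substitutions = read_substitution_table(substitutions_path)
        records = read_fish_metadata(fish_path)
    except Exception as exc:  # noqa: BLE001
        fail("load", exc)

    # ---- ages -------------------------------------------------------------
    try:
        agreed = select_agreement_subset(records)
        by_id = {r.fish_id: r for r in agreed}
        keep = [i for i, f in enumerate(matrix.fish_ids) if f in by_id]
        matrix = matrix.subset_fish(np.array(keep, dtype=int))
        manifest["counts"]["fish_reader_agreement"] = len(matrix.fish_ids)
    except Exception as exc:  # noqa: BLE001
        fail("aging", exc)

    # ---- qc ---------------------------------------------------------------
    try:
        filtered, acct = qc.apply_qc(
            matrix, substitutions,
            snp_threshold=config.snp_threshold,
            min_sites=config.min_sites,
            presence_frac=config.presence_frac,
            ci_max_width=config.ci_max_width,
            ci_min_frac=config.ci_min_frac,
        )
        manifest["counts"].update(acct)
        pm = qc.percent_methylation(filtered)
        gmean, gsd = qc.global_methylation_summary(pm)
        manifest["metrics"]["global_mean_methylation"] = gmean
        manifest["metrics"]["global_sd_methylation"] = gsd
        pm.to_frame().to_csv(outdir / "percent_methylation.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        fail("qc", exc)

    ages_frac = np.array([by_id[f].fractional_age for f in filtered.fish_ids])
    ages_int = np.array([by_id[f].integer_age for f in filtered.fish_ids])
    water = np.array([by_id[f].water_body for f in filtered.fish_ids])

    # ---- screen -----------------------------------------------------------
    try:
        models = screen.fit_age_screen(
            filtered, ages_frac, engine=config.screen_engine,
            seed=stage_seed(config.seed, "screen"), progress=True,
        )
        screen.screen_results_frame(models).to_csv(
            outdir / "screen_results.tsv", sep="\t", index=False
        )
        significant = screen.select_age_sites(models)
        manifest["counts"]["significant_sites"] = len(significant)
        if not significant:
            raise ValueError("no site shows significant age-correlated methylation")
        sig_idx = np.array([s in set(significant) for s in filtered.site_ids])
        sig_matrix = filtered.subset_sites(sig_idx)
        sig_pm = qc.percent_methylation(sig_matrix)
        sig_pm = screen.mask_overdispersed_cells(
            sig_pm, significant, max_width=config.mask_max_width
        )
        sig_pm = screen.impute_missing_cells(sig_pm, ages_int)
        frame = sig_pm.to_frame()
    except Exception as exc:  # noqa: BLE001
        fail("screen", exc)

    # ---- environment removal ---------------------------------------------
    try:
        focal = config.focal_water_bodies
        if focal is None:
            counts = pd.Series(water).value_counts()
            focal = list(counts.index[:2])
        focal_mask = np.isin(water, focal)
        retained, removed, audit = envfilter.iterative_env_site_removal(
            frame.loc[focal_mask], water[focal_mask],
            removal_fraction=config.removal_fraction,
            alpha=config.alpha,
            max_iter=config.max_removal_iter,
            n_perm=config.n_perm,
            max_pcs=config.max_pcs,
            cv_reps=config.cv_reps,
            holdout=config.holdout,
            seed=stage_seed(config.seed, "envfilter"),
        )
        audit.to_csv(outdir / "env_removal_audit.tsv", sep="\t", index=False)
        pd.Series(removed, name="site_id").to_csv(
            outdir / "env_removed_sites.tsv", sep="\t", index=False
        )
        manifest["counts"]["env_removed_sites"] = len(removed)
        manifest["counts"]["retained_after_env"] = len(retained)
        if not retained:
            raise ValueError("environment removal left no sites")
        frame = frame[retained]
    except Exception as exc:  # noqa: BLE001
        fail("envfilter", exc)

    # ---- clock ------------------------------------------------------------
    try:
        part = clockmod.partition_train_test(
            filtered.fish_ids, ages_int,
            train_frac=config.train_frac,
            stratify_by_age_bin=config.stratify_by_age_bin,
            seed=stage_seed(config.seed, "partition"),
        )
        manifest["counts"]["train_fish"] = len(part.train_ids)
        manifest["counts"]["test_fish"] = len(part.test_ids)
        age_by_fish = pd.Series(ages_frac, index=filtered.fish_ids)
        x_train = frame.loc[part.train_ids]
        top_sites = clockmod.pearson_prefilter(
            x_train, age_by_fish[part.train_ids], top_k=config.top_k
        )
        manifest["counts"]["prefilter_sites"] = len(top_sites)
        model = clockmod.subset_search(
            x_train[top_sites],
            np.log(age_by_fish[part.train_ids].to_numpy()),
            subset_size=min(config.subset_size, len(top_sites)),
            iterations=config.iterations,
            seed=stage_seed(config.seed, "clock"),
            n_folds=config.n_folds,
            n_lambda=config.n_lambda,
            objective=config.cv_objective,
        )
        model.save(outdir / "clock_model.tsv")
        manifest["counts"]["model_sites"] = model.n_nonzero
        pred_train = clockmod.predict_age(model, x_train)
        pred_test = clockmod.predict_age(model, frame.loc[part.test_ids])
        preds = pd.concat([pred_train, pred_test]).rename_axis("fish_id")
        preds.to_frame().assign(
            dataset=["train"] * len(pred_train) + ["test"] * len(pred_test)
        ).to_csv(outdir / "predictions.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        fail("clock", exc)

    # ---- evaluate ---------------------------------------------------------
    try:
        rows = []
        for name, pred in (("train", pred_train), ("test", pred_test)):
            true = age_by_fish[pred.index].to_numpy()
            ev = evaluate.evaluate(pred.to_numpy(), true)
            rows.append(
                dict(dataset=name, n=len(pred), r2=ev.r2, r2_identity=ev.r2_identity,
                     mdae_years=ev.mdae_years, mae_years=ev.mae_years)
            )
            manifest["metrics"][f"{name}_r2"] = ev.r2
            manifest["metrics"][f"{name}_mae_years"] = ev.mae_years
            manifest["metrics"][f"{name}_mdae_years"] = ev.mdae_years
        slope, pval, trend_r2 = evaluate.relative_error_trend(
            pred_test.to_numpy(), age_by_fish[pred_test.index].to_numpy()
        )
        manifest["metrics"]["relative_error_slope"] = slope
        manifest["metrics"]["relative_error_p"] = pval
        manifest["metrics"]["relative_error_r2"] = trend_r2
        pd.DataFrame(rows).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("evaluate", exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", outdir / "manifest.json")
    return manifest
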