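"""End-to-end orchestration: simulate -> process -> correct -> bias ->
featurize -> train -> evaluate -> downsample -> disease demo.

Every stage writes versioned outputs into the run directory; each TSV
carries the config hash in a leading comment line and each JSON in a
``config_hash`` field, and readers refuse to mix artifacts from different
hashes.  Reruns with the same configuration reproduce the metric tables
byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import clinical, features, models, outcomes, recombination, simulate
from .config import RunConfig, save_config

logger = logging.getLogger(__name__)


def write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_tsv(path: Path, expected_hash: str | None = None) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# config_hash="):
            raise ValueError(f"{path}: missing config hash header")
        found = header.split("=", 1)[1]
        if expected_hash is not None and found != expected_hash:
            raise ValueError(
                f"{path}: config hash {found} does not match expected {expected_hash}"
            )
        return pd.read_csv(fh, sep="\t")


def write_json(obj: dict, path: Path, config_hash: str) -> None:
    obj = dict(obj)
    obj["config_hash"] = config_hash
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_end_to_end(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline under one configuration.

    Returns a dict of in-memory artifacts (library, rate matrices, bias
    report, model, metric tables); files are written under ``outdir``.
    A configuration that retains no guides (e.g. an extreme read filter)
    produces an empty report rather than an error.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    save_config(config, outdir / "config.yaml")
    write_json({"stages": []}, outdir / "run_metadata.json", h)
    artifacts: dict = {"config_hash": h}
    seed = config.seed

    def stage(name):
        logger.info("stage: %s", name)

    # --- simulate -----------------------------------------------------
    stage("simulate")
    try:
        library = simulate.generate_guide_library(
            config.library.n_guides,
            seed=seed,
            force_g=config.library.force_g,
            upstream_context=config.library.upstream_context,
            editor_label=config.library.editor_label,
        )
        truth = config.truth
        result = simulate.simulate_screen(
            library, truth, n_samples=config.screen.n_samples, seed=seed + 1
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e
    lib_index = {g.guide_id: g for g in library}
    write_tsv(simulate.library_to_frame(library), outdir / "library.tsv", h)
    (outdir / "library.fasta").write_text(simulate.library_to_fasta(library))
    write_tsv(
        outcomes.profiles_to_frame(result.profiles), outdir / "profiles.tsv", h
    )
    artifacts["library"] = library
    artifacts["screen"] = result

    # --- match stats / correction ------------------------------------
    stage("correct")
    try:
        if config.screen.use_alignment_match_stats:
            assay = simulate.simulate_match_assay(
                library,
                truth,
                reads_per_guide=config.screen.match_assay_reads_per_guide,
                seed=seed + 2,
            )
            stats = recombination.match_stats_from_reads(
                assay,
                spacers={g.guide_id: g.spacer for g in library},
                targets={g.guide_id: g.target_construct for g in library},
                threshold=config.alignment.match_threshold,
            )
        else:
            stats = {
                gid: recombination.MatchStats(
                    gid, result.assigned_reads[gid], result.matched_reads[gid]
                )
                for gid in result.assigned_reads
            }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("correct", e) from e
    write_tsv(
        recombination.match_stats_to_frame(stats), outdir / "match_stats.tsv", h
    )
    artifacts["match_stats"] = stats

    # --- filter + pool + rates ---------------------------------------
    stage("process")
    try:
        retained = outcomes.filter_low_coverage(
            result.profiles, min_reads=config.filters.min_reads
        )
        by_guide: dict[str, list] = {}
        for p in result.profiles:
            if p.guide_id in retained:
                by_guide.setdefault(p.guide_id, []).append(p)
        matrices: dict[str, outcomes.RateMatrix] = {}
        for gid, profs in by_guide.items():
            pooled = outcomes.pool_samples(profs)
            st = stats.get(gid)
            if st is None or not st.match_rate > 0:
                logger.warning("guide %s excluded: no usable match rate", gid)
                continue
            matrices[gid] = recombination.correct_profile(pooled, st)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("process", e) from e
    logger.info("%d guides retained after filtering", len(matrices))
    artifacts["rate_matrices"] = matrices
    write_tsv(
        outcomes.rates_to_frame(list(matrices.values())), outdir / "rates.tsv", h
    )
    if not matrices:
        write_json(
            {"n_guides_retained": 0, "note": "no guides passed filters"},
            outdir / "empty_report.json",
            h,
        )
        artifacts["empty"] = True
        return artifacts

    # --- bias report --------------------------------------------------
    stage("bias")
    try:
        report = bias_mod.build_bias_report(
            matrices,
            lib_index,
            editor=truth.editor,
            n_boot=config.bias.n_boot,
            seed=seed + 3,
            min_stratum=config.bias.min_stratum,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("bias", e) from e
    write_json(report.to_json_dict(), outdir / "bias_report.json", h)
    write_tsv(
        bias_mod.context_effect_table(report), outdir / "context_effects.tsv", h
    )
    artifacts["bias_report"] = report

    # --- featurize + standardize + split ------------------------------
    stage("featurize")
    try:
        table = features.rates_to_position_table(
            matrices, lib_index, editor=truth.editor
        )
        # drop degenerate positions (too few guides or no variance)
        keep_cols = []
        for col in table.columns:
            vals = table[col].dropna()
            if len(vals) >= config.model.min_training_rows and vals.std() > 0:
                keep_cols.append(col)
        table = table[keep_cols]
        if not keep_cols:
            raise ValueError("no position with enough usable guides")
        gids = list(table.index)
        train_ids, test_ids = features.split_train_test(
            gids, train_frac=config.model.train_frac, seed=seed + 4
        )
        split = {g: "train" for g in train_ids}
        split.update({g: "test" for g in test_ids})
        scaler = features.PositionStandardizer(dataset_id="sim")
        train_table = table.loc[train_ids]
        scaler.fit(train_table)
        ztable = scaler.transform(table)
        feat = features.GuideFeaturizer().transform(
            [lib_index[g].spacer for g in gids]
        )
        dataset = features.build_position_dataset(
            feat, gids, ztable, dataset_id="sim", split=split
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("featurize", e) from e
    write_tsv(dataset, outdir / "dataset.tsv", h)
    artifacts["dataset"] = dataset
    artifacts["standardizer"] = scaler

    # --- train + evaluate ---------------------------------------------
    stage("train")
    try:
        model = models.train_model_set(
            dataset,
            hyperparams={
                "n_estimators": config.model.n_estimators,
                "max_depth": config.model.max_depth,
                "min_samples_leaf": config.model.min_samples_leaf,
                "learning_rate": config.model.learning_rate,
            },
            seed=seed + 5,
            min_training_rows=config.model.min_training_rows,
        )
        metrics = models.evaluate(model, dataset, split="test")
        importances = model.feature_importance_table()
    except Exception as e:  # noqa: BLE001
        raise PipelineError("train", e) from e
    model.save(outdir / "model.joblib", metadata={"config_hash": h})
    write_tsv(metrics, outdir / "metrics.tsv", h)
    write_tsv(importances, outdir / "importances.tsv", h)
    artifacts["model"] = model
    artifacts["metrics"] = metrics

    # --- downsample ----------------------------------------------------
    stage("downsample")
    try:
        ds_pos = config.downsample.position
        if ds_pos not in model.positions_:
            ds_pos = model.positions_[0]
        curves = models.downsample_experiment(
            dataset,
            ds_pos,
            fractions=config.downsample.fractions,
            n_reps=config.downsample.n_reps,
            seed=seed + 6,
            hyperparams={
                "n_estimators": config.model.n_estimators,
                "max_depth": config.model.max_depth,
                "min_samples_leaf": config.model.min_samples_leaf,
                "learning_rate": config.model.learning_rate,
            },
            min_training_rows=config.model.min_training_rows,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("downsample", e) from e
    write_tsv(curves, outdir / "downsample.tsv", h)
    artifacts["downsample"] = curves

    # --- disease demo ---------------------------------------------------
    stage("disease")
    try:
        editable = simulate.intended_substitution(truth.editor)[0]
        rows = []
        for gid in test_ids:
            spacer = lib_index[gid].spacer
            cands = [
                p for p in clinical.MODELED_RANGE if spacer[p - 1] == editable
            ]
            if not cands:
                continue
            snp = min(cands, key=lambda p: abs(p - 6))
            rows.append((gid, spacer, snp))
        guide_table = pd.DataFrame(rows, columns=["guide_id", "spacer", "snp_position"])
        scal = clinical.AnchoredScaling(
            anchor_mean=config.scaling.anchor_mean,
            anchor_sd=config.scaling.anchor_sd,
            scaling=dict(config.scaling.scaling),
        )
        if guide_table.empty:
            disease = pd.DataFrame()
        else:
            disease = clinical.evaluate_disease_guides(
                guide_table, model, scal, editable_base=editable
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("disease", e) from e
    write_tsv(disease, outdir / "disease.tsv", h)
    if not disease.empty:
        write_tsv(disease[disease["shortlisted"]], outdir / "shortlist.tsv", h)
    artifacts["disease"] = disease

    write_json(
        {
            "n_guides_simulated": len(library),
            "n_guides_retained": len(matrices),
            "stages": [
                "simulate", "correct", "process", "bias", "featurize",
                "train", "downsample", "disease",
            ],
        },
        outdir / "run_metadata.json",
        h,
    )
    return artifacts
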