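"""End-to-end pipeline run: generate -> cross-validate -> measure -> report.

Each stage writes its outputs under a run directory together with a manifest
carrying the seed and a hash of the configuration, so a rerun with the same
config reproduces every CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biostats import build_report, refraction_group, spherical_equivalent
from .config import PipelineConfig, config_hash, config_to_dict
from .geometry import measure_biometry
from .io import read_label_map, read_scan
from .phantom import generate_cohort
from .segmentation import LabelledSubject, cross_validate

log = logging.getLogger("oculomri")


def measure_cohort(
    label_maps,
    sphericity_threshold: float = 0.005,
    swap_sphericity_labels: bool = False,
    sides: tuple[str, ...] = ("right", "left"),
) -> pd.DataFrame:
    """Per-eye biometry rows for every label map in a cohort."""
    rows = []
    for lm in label_maps:
        for side in sides:
            bio = measure_biometry(
                lm, side,
                sphericity_threshold=sphericity_threshold,
                swap_sphericity_labels=swap_sphericity_labels,
            )
            row = {"subject_id": lm.subject_id}
            row.update(bio.as_row())
            rows.append(row)
    return pd.DataFrame(rows)


def derive_refraction_columns(
    cohort: pd.DataFrame,
    myopia_cutoff: float = -0.5,
    hyperopia_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Add SE, AL/CR ratio and refraction group to a cohort table."""
    out = cohort.copy()
    if {"sphere", "cylinder"}.issubset(out.columns):
        out["se"] = [
            spherical_equivalent(s, c)
            for s, c in zip(out["sphere"], out["cylinder"])
        ]
    if {"al_biometry", "cr"}.issubset(out.columns):
        out["al_cr_ratio"] = out["al_biometry"] / out["cr"]
    if "se" in out.columns:
        out["group"] = [
            refraction_group(se, myopia_cutoff, hyperopia_cutoff)
            for se in out["se"]
        ]
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all four stages; returns the run directory.

    Halts with the failing stage named.  Stage outputs:
    ``cohort/`` (scans, labels, cohort.csv), ``crossval_dice.csv``,
    ``biometry.csv``, ``report_*.csv`` and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config_to_dict(config),
        "stages": {},
        "warnings": [],
    }

    def fail(stage: str, exc: Exception) -> RuntimeError:
        return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")

    # 1. generate ----------------------------------------------------------
    try:
        cohort_dir = out_dir / "cohort"
        gen_manifest = generate_cohort(
            config.cohort, cohort_dir, rng, config.n_subjects,
            grid=config.grid, seed=config.seed,
        )
        manifest["stages"]["generate"] = {"n": config.n_subjects,
                                          "dir": str(cohort_dir)}
    except Exception as exc:
        raise fail("generate", exc) from exc

    subjects = []
    for entry in gen_manifest["subjects"]:
        scan = read_scan(cohort_dir / entry["scan"])
        labels = read_label_map(cohort_dir / entry["labels"])
        scan.subject_id = labels.subject_id = entry["subject_id"]
        subjects.append(LabelledSubject(entry["subject_id"], scan, labels))

    # 2. cross-validated segmentation -------------------------------------
    try:
        if config.k_folds > len(subjects):
            raise ValueError(
                f"k={config.k_folds} exceeds n={len(subjects)} subjects"
            )
        report = cross_validate(
            subjects, config.k_folds, config.segmentation,
            np.random.default_rng(config.seed),
        )
        dice_csv = out_dir / "crossval_dice.csv"
        report.per_subject.to_csv(dice_csv, index=False)
        summary = report.summary()
        manifest["stages"]["crossval"] = {
            "k": config.k_folds,
            "dice_mean": summary["mean"].to_dict(),
        }
        log.info("cross-validation Dice:\n%s", summary)
    except Exception as exc:
        raise fail("crossval", exc) from exc

    # 3. measure -----------------------------------------------------------
    try:
        biometry = measure_cohort(
            [s.labels for s in subjects],
            sphericity_threshold=config.sphericity_threshold,
            swap_sphericity_labels=config.swap_sphericity_labels,
        )
        biometry.to_csv(out_dir / "biometry.csv", index=False)
        manifest["stages"]["measure"] = {"rows": len(biometry)}
    except Exception as exc:
        raise fail("measure", exc) from exc

    # 4. report ------------------------------------------------------------
    try:
        cohort_csv = pd.read_csv(cohort_dir / "cohort.csv")
        right = biometry[biometry["side"] == "right"]
        merged = cohort_csv.merge(right, on="subject_id", how="left")
        merged = derive_refraction_columns(
            merged, config.myopia_cutoff, config.hyperopia_cutoff
        )
        tables = build_report(merged)
        for name, table in tables.items():
            table.to_csv(out_dir / f"report_{name}.csv",
                         index=name == "correlations")
        manifest["stages"]["report"] = {
            "tables": sorted(tables),
            "n_rows": len(merged),
        }
    except Exception as exc:
        raise fail("report", exc) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
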