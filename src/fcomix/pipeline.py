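"""End-to-end orchestration: read -> align -> QC -> estimate -> compare ->
sensitivity -> report, with a machine-readable run manifest.

Cohorts are defined by the ``study`` column of the sample sheet (a single
unnamed cohort when absent). Reruns with identical inputs and seed
reproduce all numeric outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import comparison, deconvolution, io, sensitivity

logger = logging.getLogger("fcomix")

STAGES = ("estimate", "compare", "sensitivity")


@dataclass
class RunConfig:
    """Inputs and parameters of a full pipeline run."""

    betas: str
    library: str
    sample_sheet: str
    out_dir: str
    dialect: str = "plain_tsv"
    min_present: int = 25
    covariates: tuple[str, ...] = comparison.DEFAULT_COVARIATES
    permutations: int = comparison.DEFAULT_PERMUTATIONS
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        for path in (self.betas, self.library, self.sample_sheet):
            if not Path(path).exists():
                raise io.FcomixError(f"input file not found: {path}")
        if self.permutations < 1:
            raise io.FcomixError("permutations must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise io.FcomixError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the result bundle.

    Outputs in ``config.out_dir``: ``estimates.tsv`` (per-sample FCO, in
    percent), ``qc_excluded.tsv``, ``comparison.tsv`` (per-cohort three-way
    tests), ``iqr_screen.tsv`` / ``correlations.tsv`` (sensitivity), and
    ``manifest.json`` echoing the config, seed, library hash and warnings.
    Returns an in-memory summary dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    manifest: dict = {
        "config": {**asdict(config),
                   "covariates": list(config.covariates),
                   "stages": list(config.stages)},
        "seed": config.seed,
        "library_sha256": _sha256(config.library),
        "stages_completed": [],
        "warnings": warnings,
    }
    summary: dict = {}

    stage = "read"
    try:
        lib = io.read_library(config.library)
        betas = io.read_beta_matrix(config.betas, dialect=config.dialect)
        sheet = io.read_sample_sheet(config.sample_sheet)
        if config.min_present > len(lib):
            raise io.FcomixError(
                f"min_present={config.min_present} exceeds library size {len(lib)}"
            )
        aligned = io.align_to_library(betas, lib)
        kept, excluded = io.qc_filter_samples(aligned, config.min_present)
        excluded.to_csv(out / "qc_excluded.tsv", sep="\t", index=False)
        logger.info("pipeline: %d samples read, %d excluded by QC, %d/%d "
                    "library probes present", betas.shape[1], len(excluded),
                    int(aligned.notna().any(axis=1).sum()), len(lib))
        summary["n_samples"] = betas.shape[1]
        summary["n_excluded"] = len(excluded)

        estimates = None
        if "estimate" in config.stages:
            stage = "estimate"
            estimates = deconvolution.estimate_fco(kept, lib)
            deconvolution.estimates_to_table(estimates).to_csv(
                out / "estimates.tsv", sep="\t", index=False,
            )
            summary["estimates"] = estimates

        if "compare" in config.stages:
            stage = "compare"
            if estimates is None:
                raise io.FcomixError("compare stage requires estimate stage")
            results = compare_by_study(
                estimates, sheet, covariates=config.covariates,
                B=config.permutations, seed=config.seed,
            )
            comparison.comparison_table(results).to_csv(
                out / "comparison.tsv", sep="\t", index=False,
            )
            summary["comparisons"] = results

        if "sensitivity" in config.stages:
            stage = "sensitivity"
            if estimates is None:
                raise io.FcomixError("sensitivity stage requires estimate stage")
            sens = sensitivity_tables(estimates, sheet)
            sens["iqr_screen"].to_csv(out / "iqr_screen.tsv", sep="\t", index=False)
            sens["correlations"].to_csv(out / "correlations.tsv", sep="\t",
                                        index=False)
            summary["sensitivity"] = sens

        manifest["stages_completed"] = ["read"] + [
            s for s in STAGES if s in config.stages
        ]
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise io.FcomixError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["output_sha256"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    summary["manifest"] = manifest
    return summary


def compare_by_study(
    estimates: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: Sequence[str] = comparison.DEFAULT_COVARIATES,
    B: int = comparison.DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> list[comparison.ComparisonResult]:
    """Per-cohort three-way comparison, one result per ``study`` level."""
    fco = estimates.set_index("sample_id")["fco_fraction"]
    studies = (
        sorted(sheet["study"].dropna().unique())
        if "study" in sheet.columns else [""]
    )
    results = []
    for i, study in enumerate(studies):
        members = (
            sheet.index[sheet["study"] == study] if study else sheet.index
        )
        sub = fco.reindex([s for s in members if s in fco.index]).dropna()
        results.append(
            comparison.compare_groups(
                sub, sheet, requested=covariates, B=B,
                seed=seed + i, study=study,
            )
        )
    return results


def sensitivity_tables(estimates: pd.DataFrame, sheet: pd.DataFrame) -> dict:
    """IQR screen plus FCO correlations with available numeric covariates."""
    fco = estimates.set_index("sample_id")["fco_fraction"]
    df = estimates.copy()
    df["study"] = df["sample_id"].map(
        sheet["study"] if "study" in sheet.columns else pd.Series(dtype=object)
    ).fillna("")
    screen = sensitivity.iqr_screen(df)
    corr_rows = []
    for var in ("age", "purity", "monocyte_pct", "lymphocyte_pct",
                "neutrophil_pct"):
        if var not in sheet.columns:
            continue
        cov = sheet[var].reindex(fco.index)
        if cov.notna().sum() < 3 or fco.notna().sum() < 3:
            continue
        for method in ("spearman", "pearson"):
            res = sensitivity.correlate_fco(fco, cov, method=method, variable=var)
            corr_rows.append(
                {"variable": var, "method": method, "r": res.r, "p": res.p,
                 "n": res.n, "zero_variance": res.zero_variance}
            )
    correlations = pd.DataFrame(
        corr_rows, columns=["variable", "method", "r", "p", "n", "zero_variance"]
    )
    return {"iqr_screen": screen, "correlations": correlations}


def render_report(summary: dict) -> str:
    """Human-readable per-cohort summary of a completed run.

    One line per cohort with group sizes, mean FCO (%) per group and the
    three p-values; floored permutation p-values render as "<1/B" and NA
    cohorts as "NA". Formatting is deterministic.
    """
    missing = [k for k in ("comparisons", "manifest") if k not in summary]
    if missing:
        raise io.FcomixError(f"incomplete result bundle, missing: {missing}")
    lines = [
        "study\tn_tumor\tn_nontumor\tmean_fco_tumor_pct\tmean_fco_nontumor_pct"
        "\twilcoxon_p\tlm_p\tperm_p"
    ]
    for r in summary["comparisons"]:
        mt = "NA" if r.mean_fco_tumor is None else f"{100 * r.mean_fco_tumor:.1f}"
        mn = (
            "NA" if r.mean_fco_nontumor is None
            else f"{100 * r.mean_fco_nontumor:.1f}"
        )
        lines.append(
            "\t".join(
                [
                    r.study or "(all)",
                    str(r.n_tumor),
                    str(r.n_nontumor),
                    mt,
                    mn,
                    comparison.format_pvalue(r.wilcoxon_p),
                    comparison.format_pvalue(r.lm_p),
                    comparison.format_pvalue(r.perm_p, r.perm_floor, r.B),
                ]
            )
        )
    return "\n".join(lines) + "\n"
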