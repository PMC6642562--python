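"""Synthetic reference libraries and cohorts with known FCO ground truth.

The generator emulates the statistical structure of two-group 450K-style
methylation cohorts: each sample is a convex mixture of a fetal and an
adult reference profile at a true fraction drawn from a group-specific
truncated normal, observed through per-probe logit-scale Gaussian noise
with independent per-cell missingness, alongside demographic covariates.
Defaults follow the observed direction of effect (nontumor mean FCO above
tumor mean) so both null and alternative regimes are easy to set up.

One global seed drives a hierarchy of per-component substreams
(``numpy.random.SeedSequence``), so the library, truth draws, noise,
missingness and covariates are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .io import (
    FcomixError,
    ReferenceLibrary,
    write_beta_matrix,
    write_library,
    write_sample_sheet,
)

#: Betas exactly 0/1 are nudged by this amount before the logit transform.
LOGIT_EPS = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic two-group cohort.

    ``fco_dist_*`` are (mean, sd) of the truncated-to-[0,1] normal from
    which true fetal fractions are drawn per group; ``noise_sd`` is the
    per-probe Gaussian noise sd on the logit scale; ``missing_rate`` the
    independent per-cell masking probability; ``covariate_effects`` an
    optional map covariate -> linear effect on the true fraction per unit
    of the standardized covariate.
    """

    n_probes: int = 27
    delta: float = 0.5
    n_tumor: int = 50
    n_nontumor: int = 50
    fco_dist_tumor: tuple[float, float] = (0.05, 0.05)
    fco_dist_nontumor: tuple[float, float] = (0.20, 0.10)
    noise_sd: float = 0.05
    missing_rate: float = 0.01
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    noise_model: str = "logit"      # "logit" or "additive" (clipped)
    gender_freq: float = 0.5        # P(male)
    study: str = "SYNTH"
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 2:
            raise FcomixError("n_probes must be >= 2")
        if not 0 < self.delta <= 1:
            raise FcomixError("delta must be in (0, 1]")
        if self.n_tumor < 1 or self.n_nontumor < 1:
            raise FcomixError("group sizes must be >= 1")
        if not 0 <= self.missing_rate <= 1:
            raise FcomixError("missing_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise FcomixError("noise_sd must be >= 0")
        if self.noise_model not in ("logit", "additive"):
            raise FcomixError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class SyntheticCohort:
    library: ReferenceLibrary
    betas: pd.DataFrame          # probes x samples, NaN = missing
    sheet: pd.DataFrame          # indexed by sample_id
    truth: pd.Series             # per-sample true fetal fraction


def simulate_reference(n_probes: int = 27, delta: float = 0.5,
                       seed: int = 0) -> ReferenceLibrary:
    """Draw a fetal/adult reference panel with mean |fetal - adult| ~ delta.

    Per-probe separations are jittered uniformly around ``delta`` (within
    the room the unit interval allows) and the direction of methylation
    alternates by probe parity, so at delta = 1 the profiles are strictly
    alternating 0/1.
    """
    if n_probes < 2:
        raise FcomixError("n_probes must be >= 2")
    if not 0 < delta <= 1:
        raise FcomixError("delta must be in (0, 1] (0 is degenerate)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11B]))
    half = min(0.1, delta / 2, 1 - delta)
    sep = rng.uniform(delta - half, delta + half, size=n_probes)
    lo = rng.uniform(0, 1 - sep)
    fetal = np.where(np.arange(n_probes) % 2 == 0, lo + sep, lo)
    adult = np.where(np.arange(n_probes) % 2 == 0, lo, lo + sep)
    probe_ids = tuple(f"cg{90000000 + i:08d}" for i in range(n_probes))
    return ReferenceLibrary(probe_ids=probe_ids, fetal=fetal, adult=adult)


def _truncated_normal(mean: float, sd: float, size: int,
                      rng: np.random.Generator,
                      lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a two-group cohort with known per-sample FCO truth.

    Observed betas are inverse-logit(logit(mixture) + noise) under the
    default logit noise model, keeping values strictly inside [0, 1]; the
    alternative "additive" model adds Gaussian noise on the beta scale and
    clips. Cells are masked independently at ``missing_rate``. Covariates:
    age ~ Normal(62, 13) truncated to [18, 95]; gender and race categorical.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0xC0F0])
    r_lib, r_truth, r_noise, r_miss, r_cov = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    lib = simulate_reference(config.n_probes, config.delta, seed=config.seed)

    n = config.n_tumor + config.n_nontumor
    groups = np.array(["tumor"] * config.n_tumor + ["nontumor"] * config.n_nontumor)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    age = _truncated_normal(62.0, 13.0, n, r_cov, lo=18.0, hi=95.0)
    gender = np.where(r_cov.random(n) < config.gender_freq, "male", "female")
    race = r_cov.choice(["white", "black", "asian", "other"], size=n,
                        p=[0.80, 0.11, 0.08, 0.01])
    vital = np.where(r_cov.random(n) < 0.7, "alive", "dead")

    mt, st = config.fco_dist_tumor
    mn, sn = config.fco_dist_nontumor
    truth = np.empty(n)
    tum = groups == "tumor"
    truth[tum] = _truncated_normal(mt, st, int(tum.sum()), r_truth)
    truth[~tum] = _truncated_normal(mn, sn, int((~tum).sum()), r_truth)
    for name, effect in config.covariate_effects.items():
        if name == "age":
            truth = truth + effect * (age - 62.0) / 13.0
        elif name == "gender":
            truth = truth + effect * (gender == "male")
        else:
            raise FcomixError(f"unsupported covariate effect {name!r}")
    truth = np.clip(truth, 0.0, 1.0)

    mix = np.outer(lib.fetal, truth) + np.outer(lib.adult, 1.0 - truth)
    if config.noise_model == "logit":
        mix = np.clip(mix, LOGIT_EPS, 1.0 - LOGIT_EPS)
        eps = r_noise.normal(0.0, config.noise_sd, size=mix.shape)
        obs = expit(logit(mix) + eps)
    else:
        obs = np.clip(mix + r_noise.normal(0.0, config.noise_sd, size=mix.shape),
                      0.0, 1.0)
    if config.missing_rate > 0:
        obs = np.where(r_miss.random(obs.shape) < config.missing_rate, np.nan, obs)

    betas = pd.DataFrame(obs, index=list(lib.probe_ids), columns=sample_ids)
    betas.index.name = "probe_id"
    sheet = pd.DataFrame(
        {
            "group": groups,
            "age": np.round(age, 1),
            "gender": gender,
            "race": race,
            "vital_status": vital,
            "study": config.study,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_s = pd.Series(truth, index=sample_ids, name="true_fco")
    return SyntheticCohort(library=lib, betas=betas, sheet=sheet, truth=truth_s)


def null_config(seed: int = 0, n_per_group: int = 20,
                **overrides) -> SimulationConfig:
    """A cohort with identical FCO distributions in both groups (no effect)."""
    cfg = SimulationConfig(
        n_tumor=n_per_group, n_nontumor=n_per_group,
        fco_dist_tumor=(0.15, 0.10), fco_dist_nontumor=(0.15, 0.10),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small canonical fixture set to ``out_dir``.

    Files: reference library, the cohort beta matrix in the plain and
    series-matrix dialects, sample sheet and ground-truth table. The same
    seed reproduces byte-identical files. Returns name -> path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(SimulationConfig(
        n_tumor=12, n_nontumor=12, missing_rate=0.02, seed=seed,
    ))
    paths = {
        "library": out / "library.tsv",
        "betas_plain": out / "betas_plain.tsv",
        "betas_series_matrix": out / "betas_series_matrix.txt",
        "sample_sheet": out / "sample_sheet.tsv",
        "truth": out / "truth.tsv",
    }
    write_library(cohort.library, paths["library"])
    betas = cohort.betas.round(6)
    write_beta_matrix(betas, paths["betas_plain"])
    with open(paths["betas_series_matrix"], "w") as fh:
        fh.write("!Series_title\tsynthetic fixture cohort\n")
        fh.write(f"!Series_seed\t{seed}\n")
        fh.write("!series_matrix_table_begin\n")
        header = "\t".join(["ID_REF"] + [f'"{s}"' for s in betas.columns])
        fh.write(header + "\n")
        for probe, row in betas.iterrows():
            cells = ["NA" if pd.isna(v) else f"{v:.6f}" for v in row]
            fh.write("\t".join([str(probe)] + cells) + "\n")
        fh.write("!series_matrix_table_end\n")
    write_sample_sheet(cohort.sheet, paths["sample_sheet"])
    cohort.truth.round(6).rename("true_fco").to_frame().rename_axis(
        "sample_id"
    ).to_csv(paths["truth"], sep="\t")
    return paths
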