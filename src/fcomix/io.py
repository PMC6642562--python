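"""Reading, validation and alignment of FCO analysis inputs.

Three artifacts are consumed here:

* a **reference library**: a small panel of CpG probes (canonically 27) with
  mean beta values for a fetal-derived and an adult-derived methylation
  profile — the basis of the mixture deconvolution;
* **beta matrices**: probes x samples tables of methylation fractions in
  [0, 1] with explicit missingness, in TCGA level-3-like or GEO
  series-matrix-like tab-separated dialects;
* a **sample sheet**: per-sample group label (tumor / nontumor) plus optional
  covariates (age, gender, race, vital status, tumor purity, leukocyte
  infiltration percentages, stage, study).

Beta matrices are represented as :class:`pandas.DataFrame` (index = probe
IDs, columns = sample IDs, ``NaN`` = missing); the sample sheet as a
DataFrame indexed by sample ID.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fcomix")

#: Strings mapped to the missing-value sentinel on read.
NA_STRINGS = ("NA", "na", "NaN", "nan", "")

#: Recognised beta-matrix file dialects.
DIALECTS = ("plain_tsv", "tcga_level3", "series_matrix")

#: Sample-sheet columns with a defined meaning; extra columns are preserved.
SHEET_COLUMNS = (
    "sample_id", "group", "age", "gender", "race", "vital_status",
    "purity", "monocyte_pct", "lymphocyte_pct", "neutrophil_pct",
    "stage", "study",
)


class FcomixError(ValueError):
    """Raised on invalid input data."""


@dataclass(frozen=True)
class ReferenceLibrary:
    """A fetal/adult methylation reference panel.

    Parameters
    ----------
    probe_ids : sequence of str
        Unique CpG identifiers (e.g. ``"cg10338787"``), order preserved.
    fetal : ndarray
        Mean beta of the fetal profile per probe, in [0, 1].
    adult : ndarray
        Mean beta of the adult profile per probe, in [0, 1].
    gene : sequence of str, optional
        Gene annotation per probe ("" when unannotated).
    """

    probe_ids: tuple[str, ...]
    fetal: np.ndarray
    adult: np.ndarray
    gene: tuple[str, ...] = field(default=())

    def __post_init__(self):
        probe_ids = tuple(str(p) for p in self.probe_ids)
        fetal = np.asarray(self.fetal, dtype=float)
        adult = np.asarray(self.adult, dtype=float)
        gene = tuple(self.gene) if len(self.gene) else ("",) * len(probe_ids)
        object.__setattr__(self, "probe_ids", probe_ids)
        object.__setattr__(self, "fetal", fetal)
        object.__setattr__(self, "adult", adult)
        object.__setattr__(self, "gene", gene)
        n = len(probe_ids)
        if n < 2:
            raise FcomixError(f"reference library needs >= 2 probes, got {n}")
        if fetal.shape != (n,) or adult.shape != (n,) or len(gene) != n:
            raise FcomixError("reference library fields have inconsistent lengths")
        seen: set[str] = set()
        for p in probe_ids:
            if p in seen:
                raise FcomixError(f"duplicate probe in reference library: {p!r}")
            seen.add(p)
        for name, arr in (("fetal", fetal), ("adult", adult)):
            bad = np.where(~np.isfinite(arr) | (arr < 0) | (arr > 1))[0]
            if bad.size:
                raise FcomixError(
                    f"{name} beta outside [0,1] at row {bad[0] + 1} "
                    f"(probe {probe_ids[bad[0]]!r})"
                )
        if np.all(fetal == adult):
            raise FcomixError(
                "degenerate library: fetal and adult profiles are identical"
            )

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": list(self.probe_ids),
                "fetal_beta": self.fetal,
                "adult_beta": self.adult,
                "gene": list(self.gene),
            }
        )

    def subset(self, index: Sequence[int]) -> "ReferenceLibrary":
        """Library restricted to the given probe positions (order kept)."""
        idx = list(index)
        return ReferenceLibrary(
            probe_ids=tuple(self.probe_ids[i] for i in idx),
            fetal=self.fetal[idx],
            adult=self.adult[idx],
            gene=tuple(self.gene[i] for i in idx),
        )


# ---------------------------------------------------------------------------
# Reference library I/O
# ---------------------------------------------------------------------------

def read_library(path: str | Path) -> ReferenceLibrary:
    """Read a tab-separated reference library.

    Expected header: ``probe_id  fetal_beta  adult_beta  [gene]``.
    Row order is preserved. Duplicate probes, betas outside [0, 1] and a
    fetal profile identical to the adult one are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "fetal_beta", "adult_beta"):
        if col not in df.columns:
            raise FcomixError(f"library file missing column {col!r}")

    def _num(col: str) -> np.ndarray:
        try:
            return df[col].astype(float).to_numpy()
        except ValueError as exc:
            raise FcomixError(f"non-numeric value in library column {col!r}: {exc}")

    gene = (
        tuple(df["gene"].astype(str)) if "gene" in df.columns
        else ("",) * len(df)
    )
    return ReferenceLibrary(
        probe_ids=tuple(df["probe_id"].astype(str)),
        fetal=_num("fetal_beta"),
        adult=_num("adult_beta"),
        gene=gene,
    )


def write_library(lib: ReferenceLibrary, path: str | Path) -> None:
    lib.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Beta matrix I/O
# ---------------------------------------------------------------------------

def _validate_betas(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FcomixError(f"duplicate probe row in {source}: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FcomixError(f"duplicate sample column in {source}: {dup!r}")
    values = df.to_numpy()
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FcomixError(
            f"beta value {values[i, j]!r} outside [0,1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r} in {source}"
        )
    return df


def read_beta_matrix(path: str | Path, dialect: str = "plain_tsv") -> pd.DataFrame:
    """Read a probes x samples beta matrix.

    Parameters
    ----------
    path : path
        Tab-separated file; first column = probe ID, one column per sample.
    dialect : {"plain_tsv", "tcga_level3", "series_matrix"}
        ``tcga_level3`` additionally skips a secondary
        ``Composite Element REF`` header row; ``series_matrix`` drops
        ``!``-prefixed metadata lines (including the terminal
        ``!series_matrix_table_end``) and strips double quotes.

    "NA"/"NaN"/empty cells become ``NaN``; any non-missing value outside
    [0, 1] is a hard error naming the probe and sample.
    """
    if dialect not in DIALECTS:
        raise FcomixError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    text = path.read_text()
    if dialect == "series_matrix":
        lines = [
            ln.replace('"', "")
            for ln in text.splitlines()
            if ln and not ln.startswith("!")
        ]
        text = "\n".join(lines)
    elif dialect == "tcga_level3":
        lines = text.splitlines()
        if len(lines) > 1 and lines[1].split("\t")[0] == "Composite Element REF":
            lines = [lines[0]] + lines[2:]
        text = "\n".join(lines)
    df = pd.read_csv(
        _io.StringIO(text), sep="\t", index_col=0,
        na_values=list(NA_STRINGS), keep_default_na=False,
        float_precision="round_trip",
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FcomixError(f"non-numeric beta value in {path.name}: {exc}")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    df.columns = df.columns.astype(str)
    return _validate_betas(df, path.name)


def write_beta_matrix(betas: pd.DataFrame, path: str | Path,
                      probe_col: str = "probe_id") -> None:
    """Write a beta matrix in the plain tab-separated dialect.

    ``repr`` round-trip float formatting is used so that a write/read cycle
    reproduces values bit-exactly; missing cells are written as ``NA``.
    """
    out = betas.copy()
    out.index.name = probe_col
    # shortest round-trip decimal form so write/read is bit-exact
    out.to_csv(path, sep="\t", na_rep="NA",
               float_format=lambda v: np.format_float_positional(v, unique=True))


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated sample sheet into a sample-ID-indexed DataFrame.

    Numeric columns (age, purity, infiltration percentages, stage) are
    coerced; bounds on purity ([0, 1]) and infiltration percentages
    ([0, 100]) are enforced when present. Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=list(NA_STRINGS))
    if "sample_id" not in df.columns:
        raise FcomixError("sample sheet missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FcomixError(f"duplicate sample_id in sample sheet: {dup!r}")
    df = df.set_index("sample_id")
    for col in ("age", "purity", "monocyte_pct", "lymphocyte_pct",
                "neutrophil_pct", "stage"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    if "purity" in df.columns:
        bad = df["purity"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise FcomixError("purity outside [0,1] in sample sheet")
    for col in ("monocyte_pct", "lymphocyte_pct", "neutrophil_pct"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise FcomixError(f"{col} outside [0,100] in sample sheet")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Alignment and QC
# ---------------------------------------------------------------------------

def align_to_library(betas: pd.DataFrame, lib: ReferenceLibrary) -> pd.DataFrame:
    """Restrict a beta matrix to the library probes, in library order.

    Library probes absent from the input are kept as all-missing rows so the
    QC denominator stays at the library size (mirroring "25 of 27"
    accounting on platforms where probes were masked). Probe IDs are matched
    exactly and case-sensitively. Raises if no library probe is present.
    """
    present = [p for p in lib.probe_ids if p in betas.index]
    if not present:
        raise FcomixError("no overlap with library: zero library probes found")
    aligned = betas.reindex(list(lib.probe_ids))
    aligned.index.name = betas.index.name
    logger.info(
        "align_to_library: %d/%d library probes found in input matrix",
        len(present), len(lib),
    )
    return aligned


def qc_filter_samples(
    betas: pd.DataFrame, min_present: int = 25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples with fewer than ``min_present`` non-missing library probes.

    The input must already be aligned to a library (rows = library probes).
    Returns the retained matrix (values untouched) and an exclusion table
    with one row per removed sample and its present-probe count.
    """
    n_probes = betas.shape[0]
    if min_present > n_probes:
        raise FcomixError(
            f"min_present={min_present} exceeds library size {n_probes}"
        )
    counts = betas.notna().sum(axis=0)
    keep = counts >= min_present
    excluded = pd.DataFrame(
        {"sample_id": counts.index[~keep], "probes_present": counts[~keep].to_numpy()}
    ).reset_index(drop=True)
    if len(excluded):
        logger.info("qc_filter_samples: excluded %d sample(s) with < %d present probes",
                    len(excluded), min_present)
    return betas.loc[:, keep], excluded
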