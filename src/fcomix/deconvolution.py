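"""Constrained projection of beta profiles onto the fetal/adult reference.

Each sample's methylation profile over the library probes is modelled as a
convex-ish mixture of the fetal and adult reference profiles:

    y_j ≈ w_F * fetal_j + w_A * adult_j        (over non-missing probes j)

with weights estimated by constrained least squares

    minimize  sum_j (y_j - w_F fetal_j - w_A adult_j)^2
    subject to  w_F >= 0,  w_A >= 0,  w_F + w_A <= 1.

``w_F`` is the fetal-cell-origin (FCO) fraction. The sum<=1 (rather than
=1) constraint leaves room for cell states matching neither reference
profile; the unexplained remainder is implicitly 1 - w_F - w_A.

The two-variable quadratic program is solved exactly by active-set
enumeration: the unconstrained least-squares solution is accepted when
feasible, otherwise the constrained optimum lies on one of the three
boundary segments, each a clipped one-dimensional least-squares problem.
This is deterministic and has no iterative tolerance. A brute-force grid
oracle and a leave-k-probes-out stability analysis are provided for
verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .io import FcomixError, ReferenceLibrary

#: Feasibility slack allowed before clipping reported fractions to [0, 1].
FEASIBILITY_TOL = 1e-8

#: Dropout analysis enumerates subsets exhaustively up to this count,
#: beyond it a seeded random sample of subsets is used.
DROPOUT_SUBSET_CAP = 10_000


@dataclass(frozen=True)
class MixtureEstimate:
    """Result of projecting one sample onto the reference profiles.

    ``fco_fraction`` and ``adult_fraction`` are fractions in [0, 1]
    (reported externally as percent); ``probes_used`` counts the
    non-missing library probes entering the fit; ``rss`` is the residual
    sum of squares at the optimum.
    """

    sample_id: str
    fco_fraction: float
    adult_fraction: float
    probes_used: int
    rss: float


def _clipped_1d(y: np.ndarray, x: np.ndarray) -> float:
    """argmin_{w in [0,1]} ||y - w x||^2 (x not all zero handled by caller)."""
    denom = float(x @ x)
    if denom == 0.0:
        return 0.0
    return float(np.clip((x @ y) / denom, 0.0, 1.0))


def project_sample(
    y: np.ndarray, lib: ReferenceLibrary, sample_id: str = ""
) -> MixtureEstimate:
    """Estimate (w_F, w_A) for one beta vector over the library probes.

    ``y`` is aligned to ``lib`` (same length, NaN = missing); missing
    probes are dropped before fitting. Requires >= 2 usable probes on which
    the fetal and adult profiles differ somewhere, otherwise the mixture is
    unidentifiable.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (len(lib),):
        raise FcomixError(
            f"beta vector length {y.shape} does not match library size {len(lib)}"
        )
    use = np.isfinite(y)
    if use.sum() < 2:
        raise FcomixError(
            f"sample {sample_id!r}: fewer than 2 usable library probes"
        )
    yy = y[use]
    f = lib.fetal[use]
    a = lib.adult[use]
    if np.all(f == a):
        raise FcomixError(
            f"sample {sample_id!r}: unidentifiable mixture "
            "(fetal = adult on all usable probes)"
        )

    candidates: list[tuple[float, float]] = []
    # Interior: unconstrained normal equations, kept only when feasible.
    X = np.column_stack([f, a])
    gram = X.T @ X
    if np.linalg.matrix_rank(gram) == 2:
        wf, wa = np.linalg.solve(gram, X.T @ yy)
        if wf >= -FEASIBILITY_TOL and wa >= -FEASIBILITY_TOL and wf + wa <= 1 + FEASIBILITY_TOL:
            candidates.append((float(wf), float(wa)))
    # Boundary segments (each includes its vertices after clipping).
    candidates.append((_clipped_1d(yy, f), 0.0))            # w_A = 0
    candidates.append((0.0, _clipped_1d(yy, a)))            # w_F = 0
    t = _clipped_1d(yy - a, f - a)                          # w_F + w_A = 1
    candidates.append((t, 1.0 - t))

    def rss_of(w: tuple[float, float]) -> float:
        r = yy - w[0] * f - w[1] * a
        return float(r @ r)

    # Minimum RSS; ties broken by smaller w_F then smaller w_A.
    best = min(candidates, key=lambda w: (rss_of(w), w[0], w[1]))
    wf = float(np.clip(best[0], 0.0, 1.0))
    wa = float(np.clip(best[1], 0.0, 1.0))
    return MixtureEstimate(
        sample_id=sample_id,
        fco_fraction=wf,
        adult_fraction=wa,
        probes_used=int(use.sum()),
        rss=rss_of(best),
    )


def estimate_fco(betas: pd.DataFrame, lib: ReferenceLibrary) -> pd.DataFrame:
    """Per-sample FCO estimates for an aligned (and QC'd) beta matrix.

    Missing probes are dropped per sample (pairwise deletion), so
    ``probes_used`` varies by sample. Returns a DataFrame in input sample
    order with columns ``sample_id, fco_fraction, adult_fraction,
    probes_used, rss``.
    """
    rows = []
    for sample in betas.columns:
        try:
            est = project_sample(betas[sample].to_numpy(), lib, sample_id=sample)
        except FcomixError as exc:
            raise FcomixError(f"sample {sample!r}: {exc}") from exc
        rows.append(est)
    return pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in rows],
            "fco_fraction": [e.fco_fraction for e in rows],
            "adult_fraction": [e.adult_fraction for e in rows],
            "probes_used": [e.probes_used for e in rows],
            "rss": [e.rss for e in rows],
        }
    )


def estimates_to_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """External reporting form: percent with one decimal."""
    out = pd.DataFrame(
        {
            "sample_id": estimates["sample_id"],
            "fco_pct": (estimates["fco_fraction"] * 100).round(1),
            "adult_pct": (estimates["adult_fraction"] * 100).round(1),
            "probes_used": estimates["probes_used"],
            "rss": estimates["rss"],
        }
    )
    return out


def brute_force_oracle(
    y: np.ndarray, lib: ReferenceLibrary, step: float = 1e-3
) -> tuple[float, float, float]:
    """Exhaustive grid search over the feasible triangle.

    Evaluates every (w_F, w_A) with both weights on the grid
    {0, step, 2 step, ..., 1} and w_F + w_A <= 1, returning the RSS
    minimizer; ties broken by smaller w_F then smaller w_A. Test oracle —
    independent of :func:`project_sample`.
    """
    if not 0 < step <= 0.5:
        raise FcomixError(f"step must be in (0, 0.5], got {step}")
    y = np.asarray(y, dtype=float)
    use = np.isfinite(y)
    yy, f, a = y[use], lib.fetal[use], lib.adult[use]
    grid = np.arange(0.0, 1.0 + step / 2, step)
    WF, WA = np.meshgrid(grid, grid, indexing="ij")
    feas = WF + WA <= 1 + 1e-12
    wf = WF[feas]
    wa = WA[feas]
    # rss expanded: ||y||^2 - 2 wf y.f - 2 wa y.a + wf^2 f.f + wa^2 a.a + 2 wf wa f.a
    rss = (
        float(yy @ yy)
        - 2 * wf * float(yy @ f) - 2 * wa * float(yy @ a)
        + wf**2 * float(f @ f) + wa**2 * float(a @ a)
        + 2 * wf * wa * float(f @ a)
    )
    # lexicographic tie-break: rss, then w_F, then w_A
    order = np.lexsort((wa, wf, rss))
    j = order[0]
    r = yy - wf[j] * f - wa[j] * a
    return float(wf[j]), float(wa[j]), float(r @ r)


def stability_probe_dropout(
    y: np.ndarray,
    lib: ReferenceLibrary,
    max_drop: int = 5,
    subset_cap: int = DROPOUT_SUBSET_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-k-probes-out stability of the FCO estimate.

    For each k in 1..``max_drop``, re-estimates w_F with every k-subset of
    library probes removed (or a seeded random sample of ``subset_cap``
    subsets when C(L, k) exceeds the cap) and summarises the absolute
    deviation from the full-library estimate. Estimation error grows with
    the number of probes removed, but remains small for small k when the
    profiles stay well separated.

    Returns a DataFrame with columns
    ``k, n_subsets, exhaustive, max_abs_dev, mean_abs_dev``.
    """
    L = len(lib)
    if max_drop >= L - 1:
        raise FcomixError(
            f"max_drop={max_drop} leaves fewer than 2 probes of {L}"
        )
    full = project_sample(y, lib).fco_fraction
    rng = np.random.default_rng(seed)
    records = []
    for k in range(1, max_drop + 1):
        total = comb(L, k)
        if total <= subset_cap:
            subsets = combinations(range(L), k)
            n_subsets, exhaustive = total, True
        else:
            subsets = (
                tuple(rng.choice(L, size=k, replace=False))
                for _ in range(subset_cap)
            )
            n_subsets, exhaustive = subset_cap, False
        devs = np.empty(n_subsets)
        for i, drop in enumerate(subsets):
            keep = [j for j in range(L) if j not in set(drop)]
            est = project_sample(
                np.asarray(y, dtype=float)[keep], lib.subset(keep)
            ).fco_fraction
            devs[i] = abs(est - full)
        records.append(
            {
                "k": k,
                "n_subsets": n_subsets,
                "exhaustive": exhaustive,
                "max_abs_dev": float(devs.max()),
                "mean_abs_dev": float(devs.mean()),
            }
        )
    return pd.DataFrame(records)
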