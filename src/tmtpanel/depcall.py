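"""Empirical fold-change thresholding and differential-expression calling.

The fold-change cutoff is not fixed a priori: it is read off the empirical
distribution of the normalized mutant/WT ratios pooled over all mutants and
replicates.  If at least a fraction ``1 - q`` of ratio magnitudes
``max(r, 1/r)`` fall below a candidate threshold ``t``, then calling changes
beyond ``t`` carries an estimated false-discovery rate of at most ``q``
(the bulk of the distribution is assumed null).  The study convention this
mirrors: ~95.5% of normalized ratios below 1.3, hence a 1.3-fold cutoff with
estimated FDR < 5%.

DEPs are then called by a conjunctive dual filter: two-sided one-sample
Student's t-test of the per-replicate log2 ratios against 0 at level alpha,
and replicate-aggregated fold change beyond the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantio import RatioMatrix

#: Candidate grid for FDR-targeted threshold search (2-decimal resolution).
THRESHOLD_GRID = np.round(np.arange(1.01, 3.001, 0.01), 2)


@dataclass(frozen=True)
class ThresholdReport:
    """Empirical exceedance of a fold-change threshold and the implied FDR."""

    threshold: float
    fraction_below: float
    estimated_fdr: float
    n_ratios: int
    per_replicate: pd.DataFrame = field(repr=False)  # replicate, fraction_below

    def __post_init__(self) -> None:
        assert 0.0 <= self.fraction_below <= 1.0
        assert abs(self.estimated_fdr - (1.0 - self.fraction_below)) < 1e-12

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "fraction_below": self.fraction_below,
            "estimated_fdr": self.estimated_fdr,
            "n_ratios": self.n_ratios,
            "per_replicate": self.per_replicate.to_dict(orient="records"),
        }


def _magnitudes(ratios: np.ndarray) -> np.ndarray:
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    return np.maximum(r, 1.0 / r)


def derive_threshold(
    rm: RatioMatrix | np.ndarray | Sequence[float],
    mode: Literal["given_t", "given_fdr"] = "given_t",
    value: float = 1.3,
    signed: bool = False,
) -> ThresholdReport:
    """Empirical threshold/FDR duality on the normalized-ratio distribution.

    ``given_t``: report the fraction of fold-change magnitudes below ``value``
    and the implied estimated FDR (their complement).  ``given_fdr``: return
    the smallest grid threshold whose exceedance is at most ``value``.

    By default magnitudes ``max(r, 1/r)`` are thresholded, so 2-fold changes
    in either direction count equally; ``signed=True`` instead counts raw
    ratios below ``t`` (the literal reading of "ratios smaller than t").
    """
    if isinstance(rm, RatioMatrix):
        per_rep_pools = [
            rm.ratios[:, :, rep].ravel() for rep in range(rm.n_replicates)
        ]
        pool = rm.ratios.ravel()
    else:
        pool = np.asarray(rm, dtype=float).ravel()
        per_rep_pools = [pool]
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("no ratios to threshold")

    def frac_below(values: np.ndarray, t: float) -> float:
        values = values[np.isfinite(values)]
        if values.size == 0:
            return np.nan
        if signed:
            return float(np.mean(values < t))
        return float(np.mean(_magnitudes(values) < t))

    if mode == "given_t":
        t = float(value)
        if t <= 1.0:
            raise ValueError("threshold must exceed 1")
    elif mode == "given_fdr":
        q = float(value)
        if not (0.0 < q < 1.0):
            raise ValueError("target FDR must lie in (0, 1)")
        mags = _magnitudes(pool) if not signed else pool
        # exceedance is non-increasing in t: take the smallest qualifying t
        exceed = np.array([np.mean(mags >= t) for t in THRESHOLD_GRID])
        ok = np.nonzero(exceed <= q)[0]
        if ok.size == 0:
            raise ValueError(
                f"no grid threshold up to {THRESHOLD_GRID[-1]} achieves FDR {q}"
            )
        t = float(THRESHOLD_GRID[ok[0]])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fb = frac_below(pool, t)
    per_rep = pd.DataFrame(
        {
            "replicate": range(len(per_rep_pools)),
            "fraction_below": [frac_below(p, t) for p in per_rep_pools],
        }
    )
    return ThresholdReport(
        threshold=t,
        fraction_below=fb,
        estimated_fdr=1.0 - fb,
        n_ratios=int(pool.size),
        per_replicate=per_rep,
    )


def call_deps(
    rm: RatioMatrix,
    alpha: float = 0.05,
    t: float = 1.3,
    min_coverage: int = 2,
    aggregate: Literal["mean", "median"] = "mean",
    bh: bool = False,
) -> pd.DataFrame:
    """Dual-filter DEP calls per protein and mutant.

    For every protein with at least ``min_coverage`` replicate ratios in a
    mutant, a two-sided one-sample Student's t-test of the log2 normalized
    ratios against 0 gives the p-value; the replicate-aggregated fold change
    must additionally satisfy ``max(FC, 1/FC) > t``.  Proteins below the
    coverage rule are reported untested (``tested=False``), never "not
    significant".  ``bh=True`` applies Benjamini-Hochberg within each mutant
    before the alpha filter (off by default).

    Returns a tidy table: protein, mutant, n, log2fc, p_value, direction,
    tested, is_dep.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if t <= 1.0:
        raise ValueError("fold-change threshold must exceed 1")
    if min_coverage < 2:
        raise ValueError("the t-test needs at least 2 replicates")
    log2r = rm.log2()  # (n, m, r)
    n_obs = rm.coverage()  # (n, m)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(log2r, axis=2)
        sd = np.nanstd(log2r, axis=2, ddof=1)
        agg = mean if aggregate == "mean" else np.nanmedian(log2r, axis=2)

    tested = n_obs >= min_coverage
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n_obs))
    df = n_obs - 1.0
    p = np.full(mean.shape, np.nan)
    ok = tested & (sd > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df[ok])
    # zero-variance guard: identical replicates -> p = 1 if mean 0 else 0
    degen = tested & (sd == 0)
    p[degen] = np.where(mean[degen] == 0.0, 1.0, 0.0)

    if bh:
        for mi in range(p.shape[1]):
            col = p[:, mi]
            mask = ~np.isnan(col)
            if mask.any():
                col[mask] = stats.false_discovery_control(col[mask], method="bh")
            p[:, mi] = col

    fc_mag = np.exp2(np.abs(agg))
    is_dep = tested & (p < alpha) & (fc_mag > t)
    direction = np.where(agg > 0, "up", np.where(agg < 0, "down", "flat"))

    n_prot, n_mut = mean.shape
    prot_idx, mut_idx = np.meshgrid(np.arange(n_prot), np.arange(n_mut), indexing="ij")
    out = pd.DataFrame(
        {
            "protein": np.asarray(rm.proteins)[prot_idx.ravel()],
            "mutant": np.asarray(rm.mutants)[mut_idx.ravel()],
            "n": n_obs.ravel().astype(int),
            "log2fc": agg.ravel(),
            "p_value": p.ravel(),
            "direction": direction.ravel(),
            "tested": tested.ravel(),
            "is_dep": is_dep.ravel(),
        }
    )
    return out


def dep_sets(calls: pd.DataFrame, direction: str | None = None) -> dict[str, set[str]]:
    """Mutant -> set of DEP proteins, optionally restricted to one direction."""
    sub = calls[calls["is_dep"]]
    if direction is not None:
        sub = sub[sub["direction"] == direction]
    return {
        m: set(g["protein"]) for m, g in sub.groupby("mutant", observed=True)
    } | {m: set() for m in calls["mutant"].unique() if m not in set(sub["mutant"])}
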