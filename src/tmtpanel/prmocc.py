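"""PRM quantification and two-condition phosphosite-occupancy estimation.

Targeted parallel-reaction-monitoring (PRM) quantification sums the peak
areas of up to six fragment-ion transitions per peptide; fold changes between
conditions are ratios of condition means with a two-sample Student's t-test
over replicates.

Site occupancy (stoichiometry) for one phosphosite in two conditions A and B
is solved from three measurable ratios.  With occupancies a, b and total
protein levels P_A, P_B, the measurement model is

    x = phospho ratio        = a P_A / (b P_B)
    y = non-phospho ratio    = (1-a) P_A / ((1-b) P_B)
    z = total protein ratio  = P_A / P_B            (externally supplied)

whose unique algebraic inverse (derivation in docs/methods.md) is

    b = (y - z) / (y - x),       a = (x / z) * b.

The non-phosphorylated counterpart peptides (including miscleavage forms)
serve as the internal control: their summed areas form y.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MAX_TRANSITIONS = 6
DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class OccupancyEstimate:
    """Occupancy in each condition, clipped to [0, 1] with pre-clip flags."""

    a: float
    b: float
    a_in_range: bool
    b_in_range: bool
    a_sd: float | None = None
    b_sd: float | None = None

    @property
    def in_range(self) -> bool:
        return self.a_in_range and self.b_in_range


def sum_transitions(areas: Sequence[float] | pd.DataFrame) -> float:
    """Peptide-level abundance: the summed peak area of its transitions."""
    if isinstance(areas, pd.DataFrame):
        areas = areas["area"].to_numpy()
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("transition list is empty")
    if areas.size > MAX_TRANSITIONS:
        raise ValueError(f"at most {MAX_TRANSITIONS} transitions per peptide")
    if np.any(~np.isfinite(areas)) or np.any(areas < 0):
        raise ValueError("areas must be finite and non-negative")
    return float(areas.sum())


def peptide_abundances(
    prm: pd.DataFrame, phospho: bool | None = None, peptide: str | None = None
) -> pd.DataFrame:
    """Summed transition areas per condition x replicate.

    Rows may be restricted to one peptide or to the phospho / non-phospho
    class; within each condition x replicate, areas are summed over all
    matching peptides (miscleavage forms pooled) and their transitions.
    """
    sub = prm
    if peptide is not None:
        sub = sub[sub["peptide"] == peptide]
    if phospho is not None:
        sub = sub[sub["phospho"] == phospho]
    if sub.empty:
        raise ValueError("no PRM rows match the selection")
    out = (
        sub.groupby(["condition", "replicate"], observed=True)["area"]
        .sum()
        .reset_index(name="abundance")
    )
    return out


def peptide_fold_change(
    abundances: pd.DataFrame, cond_a: str, cond_b: str
) -> dict[str, float]:
    """Ratio of condition means with a two-sample Student's t-test.

    ``abundances`` is the condition x replicate table from
    :func:`peptide_abundances`.  Returns ratio (A over B), the two-sided
    equal-variance t-test p-value over replicates, and per-condition SDs.
    Identical constant groups give ratio 1 and p = 1 (zero-variance guard).
    """
    ga = abundances.loc[abundances["condition"] == cond_a, "abundance"].to_numpy()
    gb = abundances.loc[abundances["condition"] == cond_b, "abundance"].to_numpy()
    if ga.size < 2 or gb.size < 2:
        raise ValueError("need at least 2 replicates per condition")
    mb = gb.mean()
    if mb == 0:
        raise ValueError("zero mean abundance in the denominator condition")
    if ga.std(ddof=1) == 0 and gb.std(ddof=1) == 0:
        p = 1.0 if ga.mean() == mb else 0.0
    else:
        p = float(stats.ttest_ind(ga, gb, equal_var=True).pvalue)
    return {
        "ratio": float(ga.mean() / mb),
        "p_value": p,
        "sd_a": float(ga.std(ddof=1)),
        "sd_b": float(gb.std(ddof=1)),
        "n_a": int(ga.size),
        "n_b": int(gb.size),
    }


def solve_occupancy(x: float, y: float, z: float) -> tuple[float, float]:
    """Invert the two-condition measurement model (raw, unclipped).

    x: phosphopeptide ratio A/B; y: pooled non-phospho counterpart ratio
    A/B; z: total-protein ratio A/B.  Returns (a, b), the occupancies in
    conditions A and B.  Degenerate when y == x (the site carries no
    contrast between conditions).
    """
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite ratio")
    if abs(y - x) <= DEGENERACY_TOL * max(abs(x), abs(y)):
        raise ValueError("y == x: occupancy unidentifiable (degenerate inputs)")
    b = (y - z) / (y - x)
    a = (x / z) * b
    return float(a), float(b)


def forward_model(a: float, b: float, z: float = 1.0) -> tuple[float, float]:
    """Measurement ratios (x, y) implied by occupancies (a, b) and protein ratio z."""
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError("occupancies must lie in [0, 1]")
    if b == 0.0 or b == 1.0:
        raise ValueError("forward ratios undefined at boundary occupancy in B")
    return a / b * z, (1.0 - a) / (1.0 - b) * z


def estimate_occupancy(
    prm: pd.DataFrame,
    protein_ratio: float,
    cond_a: str = "A",
    cond_b: str = "B",
    per_replicate: bool = True,
) -> OccupancyEstimate:
    """Occupancy estimate from a PRM transition table and a protein ratio.

    Phospho and pooled non-phospho abundances are summed per condition and
    replicate; with matched replicate counts the occupancies are solved per
    replicate pair and summarized as mean +/- SD (the error-bar convention),
    otherwise from the ratio of condition means.  Estimates are clipped to
    [0, 1]; the pre-clip range check is preserved in the flags.
    """
    ph = peptide_abundances(prm, phospho=True)
    nonph = peptide_abundances(prm, phospho=False)

    def cond_vals(tab: pd.DataFrame, cond: str) -> np.ndarray:
        sub = tab[tab["condition"] == cond].sort_values("replicate")
        return sub["abundance"].to_numpy()

    pa, pb = cond_vals(ph, cond_a), cond_vals(ph, cond_b)
    na, nb = cond_vals(nonph, cond_a), cond_vals(nonph, cond_b)
    if per_replicate and len(pa) == len(pb) == len(na) == len(nb) and len(pa) >= 2:
        est = np.array(
            [
                solve_occupancy(pa[i] / pb[i], na[i] / nb[i], protein_ratio)
                for i in range(len(pa))
            ]
        )
        a_vals, b_vals = est[:, 0], est[:, 1]
        a_raw, b_raw = float(a_vals.mean()), float(b_vals.mean())
        a_sd = float(a_vals.std(ddof=1))
        b_sd = float(b_vals.std(ddof=1))
    else:
        a_raw, b_raw = solve_occupancy(
            pa.mean() / pb.mean(), na.mean() / nb.mean(), protein_ratio
        )
        a_sd = b_sd = None
    return OccupancyEstimate(
        a=float(np.clip(a_raw, 0.0, 1.0)),
        b=float(np.clip(b_raw, 0.0, 1.0)),
        a_in_range=bool(0.0 <= a_raw <= 1.0),
        b_in_range=bool(0.0 <= b_raw <= 1.0),
        a_sd=a_sd,
        b_sd=b_sd,
    )


def read_prm(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "phospho", "charge", "transition", "area",
                "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing PRM columns {sorted(missing)}")
    if df["area"].lt(0).any():
        raise ValueError("negative transition areas")
    if df["phospho"].dtype == object:
        df["phospho"] = df["phospho"].astype(str).str.lower().isin(("true", "1", "+"))
    return df


def write_occupancy(
    est: OccupancyEstimate, pair: tuple[str, str], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "condition_a": pair[0],
                "condition_b": pair[1],
                "occupancy_a": est.a,
                "occupancy_b": est.b,
                "sd_a": est.a_sd,
                "sd_b": est.b_sd,
                "in_range": est.in_range,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
    return path
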