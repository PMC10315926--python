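"""Reading, filtering and normalization of reporter-ion quantification tables.

Implements the quantification arm of the analysis: parse MaxQuant
``proteinGroups``-dialect tables (one per biological replicate), drop decoy
and contaminant rows, keep proteins quantified in at least *k* replicates,
form per-replicate mutant/WT ratios normalized so each replicate-by-mutant
slice has mean 1, and aggregate to log2 fold changes with per-protein
z-scores for heat-map display and clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthgen import N_CHANNELS, QuantExperiment

REQUIRED_COLUMNS = (
    "Protein IDs",
    *[f"Reporter intensity corrected {c}" for c in range(N_CHANNELS)],
    "Reverse",
    "Potential contaminant",
)


class FormatError(ValueError):
    """A quantification table does not conform to the expected dialect."""


class DesignError(ValueError):
    """The labeling design is inconsistent with the tables."""


@dataclass
class RatioMatrix:
    """Normalized mutant/WT ratios: protein x mutant x replicate, NaN = missing.

    Within every replicate-by-mutant slice the arithmetic mean of the
    non-missing ratios is 1 (the samples were mixed at equal ratio, so the
    bulk ratio is recentred to 1).
    """

    proteins: tuple[str, ...]
    mutants: tuple[str, ...]
    ratios: np.ndarray  # (n_proteins, n_mutants, n_replicates), > 0 or NaN

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            if np.any(self.ratios <= 0):
                raise ValueError("ratios must be positive (use NaN for missing)")

    @property
    def n_replicates(self) -> int:
        return self.ratios.shape[2]

    def coverage(self) -> np.ndarray:
        """(n_proteins, n_mutants) count of replicates with a ratio."""
        return np.sum(~np.isnan(self.ratios), axis=2)

    def log2(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.log2(self.ratios)

    def to_tidy(self) -> pd.DataFrame:
        n, m, r = self.ratios.shape
        prot, mut, rep = np.meshgrid(
            np.arange(n), np.arange(m), np.arange(r), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "protein": np.asarray(self.proteins)[prot.ravel()],
                "mutant": np.asarray(self.mutants)[mut.ravel()],
                "replicate": rep.ravel(),
                "ratio": self.ratios.ravel(),
            }
        )
        return df.dropna(subset=["ratio"]).reset_index(drop=True)


@dataclass
class FoldChangeMatrix:
    """Replicate-aggregated log2 fold changes and per-protein z-scores.

    ``log2fc`` is protein x mutant; ``zscores`` is the protein x
    (mutant x replicate) matrix of log2 ratios z-scored within each protein
    row (the heat-map convention), with columns named ``mutant:replicate``.
    """

    proteins: tuple[str, ...]
    mutants: tuple[str, ...]
    log2fc: pd.DataFrame  # index protein, columns mutants
    zscores: pd.DataFrame  # index protein, columns "mutant:rep"


def read_protein_groups(
    paths: Sequence[str | Path],
    design: Mapping[int, Mapping[int, str]],
) -> QuantExperiment:
    """Assemble a QuantExperiment from per-replicate proteinGroups tables.

    ``design`` maps replicate index -> channel -> strain and must cover every
    file (replicates are taken in the order of ``paths``).  Rows flagged
    ``Reverse`` or ``Potential contaminant`` are kept but marked so that
    downstream ratio computation excludes them.
    """
    if len(paths) != len(design):
        raise DesignError(
            f"{len(paths)} table(s) but design covers {len(design)} replicate(s)"
        )
    frames = []
    for rep, path in enumerate(paths):
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"Reverse": str, "Potential contaminant": str},
            float_precision="round_trip",
        )
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        strains = sorted(design[rep].values())
        if len(set(strains)) != N_CHANNELS:
            raise DesignError(f"replicate {rep}: design must map each strain once")
        frames.append(df.set_index("Protein IDs"))
    proteins = tuple(frames[0].index)
    for rep, df in enumerate(frames[1:], start=1):
        if tuple(df.index) != proteins:
            # align on the union, missing rows become zero intensity
            proteins = tuple(sorted(set(proteins) | set(df.index)))
    intensities = np.zeros((len(proteins), len(frames), N_CHANNELS))
    reverse = np.zeros(len(proteins), dtype=bool)
    contaminant = np.zeros(len(proteins), dtype=bool)
    index = {p: i for i, p in enumerate(proteins)}
    for rep, df in enumerate(frames):
        rows = [index[p] for p in df.index]
        for ch in range(N_CHANNELS):
            intensities[rows, rep, ch] = df[f"Reporter intensity corrected {ch}"].to_numpy()
        reverse[rows] |= df["Reverse"].fillna("").eq("+").to_numpy()
        contaminant[rows] |= df["Potential contaminant"].fillna("").eq("+").to_numpy()
    flags = pd.DataFrame(
        {"reverse": reverse, "contaminant": contaminant}, index=list(proteins)
    )
    return QuantExperiment(
        proteins=proteins, intensities=intensities, design=dict(design), flags=flags
    )


def read_design(path: str | Path) -> dict[int, dict[int, str]]:
    """Parse a design TSV with columns replicate, channel, strain."""
    df = pd.read_csv(path, sep="\t")
    for col in ("replicate", "channel", "strain"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing design column {col!r}")
    design: dict[int, dict[int, str]] = {}
    for row in df.itertuples(index=False):
        design.setdefault(int(row.replicate), {})[int(row.channel)] = str(row.strain)
    return design


def filter_min_replicates(exp: QuantExperiment, k: int = 2) -> tuple[str, ...]:
    """Proteins quantifiable (WT > 0 and >= 1 mutant > 0) in >= k replicates.

    Decoy (reverse) and contaminant rows are never retained.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > exp.n_replicates:
        raise ValueError(f"k={k} exceeds the {exp.n_replicates} replicates")
    wt_intensity = exp.strain_intensity(exp.wt_strain())
    mutant_any = np.zeros_like(wt_intensity, dtype=bool)
    for strain in exp.strains:
        if strain == exp.wt_strain():
            continue
        mutant_any |= exp.strain_intensity(strain) > 0
    ok = (wt_intensity > 0) & mutant_any  # (n_proteins, n_replicates)
    retained = ok.sum(axis=1) >= k
    excluded = exp.flags["reverse"].to_numpy() | exp.flags["contaminant"].to_numpy()
    retained &= ~excluded
    return tuple(p for p, keep in zip(exp.proteins, retained) if keep)


def compute_normalized_ratios(
    exp: QuantExperiment, retained: Sequence[str]
) -> RatioMatrix:
    """Per-replicate mutant/WT ratios, mean-normalized within each slice.

    The raw ratio is mutant channel / WT channel.  Each replicate-by-mutant
    vector is then divided by its arithmetic mean (expected close to 1 since
    the six samples were mixed at equal ratio), which recentres the slice at
    exactly 1.  A zero WT or mutant intensity yields a missing cell.
    """
    if len(retained) == 0:
        raise ValueError("retained protein set is empty")
    wt = exp.wt_strain()
    mutants = tuple(s for s in sorted(exp.strains) if s != wt)
    index = {p: i for i, p in enumerate(exp.proteins)}
    sel = np.array([index[p] for p in retained])
    wt_i = exp.strain_intensity(wt)[sel]  # (n_sel, n_reps)
    ratios = np.full((len(retained), len(mutants), exp.n_replicates), np.nan)
    for mi, m in enumerate(mutants):
        mut_i = exp.strain_intensity(m)[sel]
        valid = (wt_i > 0) & (mut_i > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(valid, mut_i / np.where(wt_i > 0, wt_i, np.nan), np.nan)
        ratios[:, mi, :] = raw
    # normalize each replicate x mutant slice by its arithmetic mean
    slice_mean = np.nanmean(ratios, axis=0, keepdims=True)  # (1, n_mut, n_rep)
    ratios = ratios / slice_mean
    return RatioMatrix(proteins=tuple(retained), mutants=mutants, ratios=ratios)


def replicate_correlation(
    exp: QuantExperiment,
    retained: Sequence[str] | None = None,
    on: Literal["log_intensity", "log_ratio"] = "log_intensity",
) -> pd.DataFrame:
    """Squared Pearson correlation (R^2) for every replicate pair, per strain.

    Computed on log2 intensities of each strain (default) or on log2
    mutant/WT ratios, over proteins quantified in both replicates of a pair.
    Pairs sharing fewer than 3 proteins are reported as NaN.
    """
    if exp.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    index = {p: i for i, p in enumerate(exp.proteins)}
    sel = (
        np.array([index[p] for p in retained])
        if retained is not None
        else np.arange(len(exp.proteins))
    )
    wt = exp.wt_strain()
    rows = []
    for strain in exp.strains:
        if on == "log_ratio" and strain == wt:
            continue
        mat = exp.strain_intensity(strain)[sel].astype(float)
        if on == "log_ratio":
            wt_mat = exp.strain_intensity(wt)[sel].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                mat = np.where((mat > 0) & (wt_mat > 0), mat / wt_mat, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            logmat = np.where(mat > 0, np.log2(np.where(mat > 0, mat, np.nan)), np.nan)
        for a in range(exp.n_replicates):
            for b in range(a + 1, exp.n_replicates):
                both = ~np.isnan(logmat[:, a]) & ~np.isnan(logmat[:, b])
                if both.sum() < 3:
                    r2 = np.nan
                else:
                    r = np.corrcoef(logmat[both, a], logmat[both, b])[0, 1]
                    r2 = float(r**2)
                rows.append(
                    {"strain": strain, "rep_a": a, "rep_b": b, "r2": r2,
                     "n_shared": int(both.sum())}
                )
    return pd.DataFrame(rows)


def fold_changes_and_zscores(
    rm: RatioMatrix,
    min_coverage: int = 2,
    aggregate: Literal["mean", "median"] = "mean",
    zscore_axis: Literal["protein", "sample"] = "protein",
) -> FoldChangeMatrix:
    """Aggregate replicate ratios to log2 fold changes and z-score.

    log2 fold change is the mean (default; geometric mean on the linear
    scale) or median of the available per-replicate log2 ratios; cells with
    coverage below ``min_coverage`` are NaN.  z-scores are computed on the
    protein x (mutant x replicate) log2-ratio matrix, by default within each
    protein row (heat-map convention), optionally within each sample column.
    """
    log2r = rm.log2()  # (n, m, r)
    cov = rm.coverage()
    agg = np.nanmean if aggregate == "mean" else np.nanmedian
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fc = agg(log2r, axis=2)
    fc = np.where(cov >= min_coverage, fc, np.nan)
    log2fc = pd.DataFrame(fc, index=list(rm.proteins), columns=list(rm.mutants))

    n, m, r = log2r.shape
    flat = log2r.reshape(n, m * r)
    cols = [f"{mut}:{rep}" for mut in rm.mutants for rep in range(r)]
    axis = 1 if zscore_axis == "protein" else 0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(flat, axis=axis, keepdims=True)
        sd = np.nanstd(flat, axis=axis, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (flat - mean) / sd, np.nan)
    zscores = pd.DataFrame(z, index=list(rm.proteins), columns=cols)
    return FoldChangeMatrix(
        proteins=rm.proteins, mutants=rm.mutants, log2fc=log2fc, zscores=zscores
    )


def sample_profiles(
    exp: QuantExperiment,
    retained: Sequence[str],
    proteins: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Z-scored log2 intensity matrix over all strain x replicate samples.

    Each replicate channel is first scaled to equal mean intensity over the
    retained proteins (equal-loading normalization), log2-transformed, and
    each protein row is z-scored across the 6 x n_replicates sample columns.
    Rows with any missing value or zero variance are dropped.  ``proteins``
    optionally restricts the rows (e.g. to the DEP union before clustering).
    """
    index = {p: i for i, p in enumerate(exp.proteins)}
    universe = [p for p in retained if proteins is None or p in set(proteins)]
    if not universe:
        raise ValueError("no proteins to profile")
    sel = np.array([index[p] for p in universe])
    cols = {}
    ret_sel = np.array([index[p] for p in retained])
    for strain in exp.strains:
        mat = exp.strain_intensity(strain)
        for rep in range(exp.n_replicates):
            col = mat[:, rep].astype(float)
            scale = col[ret_sel][col[ret_sel] > 0].mean()
            with np.errstate(divide="ignore"):
                logged = np.where(col > 0, np.log2(col / scale), np.nan)
            cols[f"{strain}:{rep}"] = logged[sel]
    df = pd.DataFrame(cols, index=universe).dropna(axis=0)
    sd = df.std(axis=1, ddof=0)
    df = df.loc[sd > 0]
    z = df.sub(df.mean(axis=1), axis=0).div(sd.loc[df.index], axis=0)
    return z


def write_tidy(df: pd.DataFrame | RatioMatrix, path: str | Path) -> Path:
    """Write a RatioMatrix (as tidy protein/mutant/replicate/ratio) or DataFrame."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(df, RatioMatrix):
        df = df.to_tidy()
    df.to_csv(path, sep="\t", index=False)
    return path
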