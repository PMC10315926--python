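"""Synthetic 6-plex TMT and PRM data with known ground truth.

Emulates a six-strain (wild type + five knockout mutants) by three-replicate
isobaric-labeling experiment: log-normally distributed protein abundances,
planted differentially expressed proteins (DEPs) with a prescribed Venn
overlap structure across mutants, multiplicative log-normal reporter noise,
and co-isolation interference modeled as convex mixing of each channel with
the channel mean.  A companion generator produces parallel-reaction-
monitoring (PRM) transition tables for a phosphopeptide and its
non-phosphorylated counterparts with known phosphosite occupancy.

All randomness flows from a single integer seed through named substreams, so
every table is reproducible independently of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

N_CHANNELS = 6

#: Null log2 mutant/WT ratio spread implied by the study's threshold
#: statistic: 95.5% of normalized ratio magnitudes below 1.3 under a
#: centred normal law gives sd = log2(1.3) / z_{0.9775} ~ 0.1888.
NULL_RATIO_SIGMA_LOG2 = float(np.log2(1.3) / 2.004654)

#: Channel-level reporter noise calibrated so that the mutant/WT ratio of a
#: null protein (difference of two independent channel noises) has the
#: spread above: sigma_channel = sigma_ratio / sqrt(2).
DEFAULT_NOISE_SIGMA = float(NULL_RATIO_SIGMA_LOG2 / np.sqrt(2.0))

#: Strain order of the study: wild type first, then the five regulator knockouts.
DEFAULT_STRAINS = ("WT", "hik31", "hik8", "rre37", "sigE", "slr6041")

#: Default planted Venn skeleton: one set shared by all five mutants plus a
#: mutant-specific set each (counts follow the study design being emulated).
DEFAULT_DEP_PLAN: dict[tuple[str, ...], int] = {
    ("hik31", "hik8", "rre37", "sigE", "slr6041"): 4,
    ("hik31",): 11,
    ("hik8",): 60,
    ("rre37",): 14,
    ("sigE",): 25,
    ("slr6041",): 97,
}

DEFAULT_CATEGORIES = (
    "central carbon metabolism",
    "photosynthesis and respiration",
    "amino acid biosynthesis",
    "translation",
    "transport and binding",
    "regulatory functions",
    "cell envelope",
    "hypothetical",
)


@dataclass(frozen=True)
class FoldChangeLaw:
    """Distribution of true DEP effect sizes.

    log2 magnitudes are uniform on [lo, hi]; a fraction ``p_up`` of planted
    proteins are upregulated, the rest downregulated.
    """

    log2_lo: float = 1.0
    log2_hi: float = 2.5
    p_up: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.log2_lo <= self.log2_hi):
            raise ValueError("fold-change law requires 0 < log2_lo <= log2_hi")
        if not (0.0 <= self.p_up <= 1.0):
            raise ValueError("p_up must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic TMT/PRM experiment.

    Defaults reproduce the study conditions being emulated: ~2000 quantified
    proteins, 6 strains x 3 replicates, a planted overlap skeleton of
    4 shared + 11/60/14/25/97 mutant-specific DEPs, reporter noise calibrated
    to the observed null normalized-ratio spread (~95.5% of fold-change
    magnitudes below 1.3), and no co-isolation interference (compression is
    exercised explicitly by varying ``interference_f``).
    """

    n_proteins: int = 2000
    strains: tuple[str, ...] = DEFAULT_STRAINS
    n_replicates: int = 3
    dep_plan: Mapping[tuple[str, ...], int] = field(
        default_factory=lambda: dict(DEFAULT_DEP_PLAN)
    )
    fc_law: FoldChangeLaw = field(default_factory=FoldChangeLaw)
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    interference_f: float = 0.0
    #: (mean, sd) of log2 protein abundance; 2^20 ~ 1e6 mimics MaxQuant
    #: corrected reporter intensities, sd 2 gives a ~4 orders-of-magnitude range.
    base_intensity_law: tuple[float, float] = (20.0, 2.0)
    n_categories: int = len(DEFAULT_CATEGORIES)
    dropout_p: float = 0.0
    # PRM scenario: phosphosite occupancy in condition A (mutant) and B (WT),
    # total-protein ratio A/B, and transition-level coefficient of variation.
    occupancy_a: float = 0.70
    occupancy_b: float = 0.04
    protein_ratio: float = 1.5
    prm_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_replicates < 2:
            raise ValueError("at least 2 replicates are required")
        if len(self.strains) != N_CHANNELS:
            raise ValueError(f"exactly {N_CHANNELS} strains (one per TMT channel)")
        if not (0.0 <= self.interference_f < 1.0):
            raise ValueError("interference_f must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        for cond, occ in (("A", self.occupancy_a), ("B", self.occupancy_b)):
            if not (0.0 <= occ <= 1.0):
                raise ValueError(f"occupancy in condition {cond} must be in [0, 1]")
        mutants = set(self.strains[1:])
        total = 0
        for region, count in self.dep_plan.items():
            if count < 0:
                raise ValueError("dep_plan counts must be non-negative")
            if not set(region) <= mutants:
                raise ValueError(f"dep_plan region {region!r} names unknown mutants")
            total += count
        if total > self.n_proteins:
            raise ValueError(
                f"dep_plan assigns {total} proteins but only {self.n_proteins} exist"
            )

    @property
    def wt(self) -> str:
        return self.strains[0]

    @property
    def mutants(self) -> tuple[str, ...]:
        return self.strains[1:]

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream derived from the global seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage_key,))
        )


@dataclass(frozen=True)
class ProteinCatalog:
    """Protein identifiers with one functional category and term annotations each."""

    proteins: tuple[str, ...]
    categories: Mapping[str, str]  # protein -> category
    terms: Mapping[str, tuple[str, ...]]  # protein -> annotation terms

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth: signed true fold changes, occupancies, labeling design."""

    true_dep: Mapping[str, Mapping[str, float]]  # mutant -> protein -> signed log2 FC
    true_occupancy: Mapping[str, float]  # condition -> occupancy in [0, 1]
    labeling_design: Mapping[int, Mapping[int, str]]  # replicate -> channel -> strain

    def dep_sets(self) -> dict[str, set[str]]:
        return {m: set(d) for m, d in self.true_dep.items()}

    def region_of(self, protein: str) -> tuple[str, ...]:
        return tuple(sorted(m for m, d in self.true_dep.items() if protein in d))


@dataclass
class QuantExperiment:
    """Reporter intensities (protein x replicate x channel) plus labeling design."""

    proteins: tuple[str, ...]
    intensities: np.ndarray  # (n_proteins, n_replicates, N_CHANNELS), >= 0
    design: Mapping[int, Mapping[int, str]]  # replicate -> channel -> strain
    flags: pd.DataFrame  # index protein, columns: reverse, contaminant (bool)

    def __post_init__(self) -> None:
        n, r, c = self.intensities.shape
        if n != len(self.proteins):
            raise ValueError("intensity rows do not match protein list")
        if c != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {c}")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")
        for rep in range(r):
            strains = sorted(self.design[rep].values())
            if len(set(strains)) != N_CHANNELS:
                raise ValueError(f"replicate {rep}: each strain must appear exactly once")

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[1]

    @property
    def strains(self) -> tuple[str, ...]:
        ch0 = self.design[0]
        return tuple(ch0[c] for c in sorted(ch0))

    def wt_strain(self) -> str:
        """The reference strain: 'WT' if present, else the channel-0 strain."""
        return "WT" if "WT" in self.strains else self.strains[0]

    def channel_of(self, replicate: int, strain: str) -> int:
        for channel, s in self.design[replicate].items():
            if s == strain:
                return channel
        raise KeyError(f"strain {strain!r} absent from replicate {replicate} design")

    def strain_intensity(self, strain: str) -> np.ndarray:
        """(n_proteins, n_replicates) intensities of one strain across replicates."""
        cols = [
            self.intensities[:, rep, self.channel_of(rep, strain)]
            for rep in range(self.n_replicates)
        ]
        return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# Proteome and planted truth
# ---------------------------------------------------------------------------


def make_proteome(config: SimConfig) -> ProteinCatalog:
    """Synthetic protein catalog: ids, one functional category each, terms.

    Ids follow the sll/slr locus-tag style of the organism being emulated.
    Categories partition the proteome; each category contributes one
    annotation term ("GO:"-style) so enrichment analysis has a flat,
    non-overlapping term universe plus a handful of broader multi-category
    terms for realism.
    """
    if config.n_proteins < 10:
        raise ValueError("need at least 10 proteins for a meaningful proteome")
    if config.n_categories < 2:
        raise ValueError("need at least 2 functional categories")
    rng = config.rng("proteome")
    proteins = tuple(f"ssl{i:04d}" for i in range(config.n_proteins))
    names = [
        DEFAULT_CATEGORIES[i % len(DEFAULT_CATEGORIES)] if i < len(DEFAULT_CATEGORIES)
        else f"category {i}"
        for i in range(config.n_categories)
    ]
    # near-equal category sizes, membership randomized by permutation
    assignment = list(names) * (config.n_proteins // config.n_categories + 1)
    cat_idx = rng.permutation(config.n_proteins)
    categories = {proteins[j]: assignment[i] for i, j in enumerate(cat_idx)}
    terms: dict[str, tuple[str, ...]] = {}
    for p in proteins:
        t = [f"GO:{names.index(categories[p]):07d}"]
        # a second, broader term shared by ~20% of the proteome
        if rng.random() < 0.2:
            t.append("GO:9999999")
        terms[p] = tuple(t)
    return ProteinCatalog(proteins=proteins, categories=categories, terms=terms)


def plan_truth(catalog: ProteinCatalog, config: SimConfig) -> GroundTruth:
    """Assign planted DEPs to the requested Venn regions with signed effects.

    Each region of the plan (a tuple of mutant names) receives exactly the
    requested number of proteins, drawn without replacement; proteins outside
    every region are true nulls.  Within a multi-mutant region the sign of a
    protein's effect is shared across mutants (consistent direction), while
    magnitudes are drawn per mutant from the fold-change law.
    """
    mutants = config.mutants
    law = config.fc_law
    rng = config.rng("truth")
    regions = sorted(config.dep_plan.items(), key=lambda kv: kv[0])
    n_dep = sum(c for _, c in regions)
    if n_dep > len(catalog):
        raise ValueError("infeasible plan: more planted DEPs than proteins")
    chosen = rng.choice(len(catalog), size=n_dep, replace=False)
    true_dep: dict[str, dict[str, float]] = {m: {} for m in mutants}
    pos = 0
    for region, count in regions:
        for j in chosen[pos : pos + count]:
            protein = catalog.proteins[j]
            sign = 1.0 if rng.random() < law.p_up else -1.0
            for m in region:
                mag = rng.uniform(law.log2_lo, law.log2_hi)
                true_dep[m][protein] = sign * mag
        pos += count
    design = {
        rep: {ch: config.strains[(ch - rep) % N_CHANNELS] for ch in range(N_CHANNELS)}
        for rep in range(config.n_replicates)
    }
    occupancy = {"A": config.occupancy_a, "B": config.occupancy_b}
    return GroundTruth(true_dep=true_dep, true_occupancy=occupancy, labeling_design=design)


# ---------------------------------------------------------------------------
# TMT reporter-intensity simulation
# ---------------------------------------------------------------------------


def simulate_tmt(truth: GroundTruth, config: SimConfig,
                 catalog: ProteinCatalog | None = None) -> QuantExperiment:
    """Reporter intensities under the noise + co-isolation interference model.

    Per protein and replicate, the clean channel signal is
    ``base * 2**(true log2 FC of the channel's strain) * 2**noise`` with
    noise ~ N(0, noise_sigma^2).  Co-isolation then mixes each channel with
    the pooled background (the channel mean of the same spectrum):

        observed_c = (1 - f) * signal_c + f * mean_c(signal)

    a convex recombination, so total per-spectrum signal is conserved and the
    observed mutant/WT ratio is compressed monotonically toward 1 as f grows.
    """
    if catalog is None:
        proteins = tuple(sorted({p for d in truth.true_dep.values() for p in d}))
        if not proteins:
            raise ValueError("pass a catalog when the truth plants no DEPs")
    else:
        proteins = catalog.proteins
    n = len(proteins)
    idx = {p: i for i, p in enumerate(proteins)}
    mu, sd = config.base_intensity_law
    rng = config.rng("tmt")
    base = np.exp2(rng.normal(mu, sd, size=n))

    # per-strain true log2 fold change (WT = 0 everywhere)
    log2fc = np.zeros((n, N_CHANNELS))
    for s, strain in enumerate(config.strains):
        for protein, eff in truth.true_dep.get(strain, {}).items():
            log2fc[idx[protein], s] = eff

    f = config.interference_f
    intensities = np.empty((n, config.n_replicates, N_CHANNELS))
    for rep in range(config.n_replicates):
        noise = rng.normal(0.0, config.noise_sigma, size=(n, N_CHANNELS))
        chan_strain = [truth.labeling_design[rep][ch] for ch in range(N_CHANNELS)]
        strain_col = [config.strains.index(s) for s in chan_strain]
        signal = base[:, None] * np.exp2(log2fc[:, strain_col] + noise)
        observed = (1.0 - f) * signal + f * signal.mean(axis=1, keepdims=True)
        intensities[:, rep, :] = observed
    if config.dropout_p > 0:
        drop = config.rng("dropout").random((n, config.n_replicates)) < config.dropout_p
        intensities[drop, :] = 0.0
    flags = pd.DataFrame(
        {"reverse": False, "contaminant": False}, index=list(proteins)
    )
    return QuantExperiment(
        proteins=proteins,
        intensities=intensities,
        design=truth.labeling_design,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# PRM transition-table simulation
# ---------------------------------------------------------------------------

#: Target peptides of the default PRM scenario: the phosphopeptide and its two
#: non-phosphorylated counterparts (full and miscleaved forms).
PRM_PHOSPHOPEPTIDE = "YRGS[ph]EYTVEFLQK"
PRM_COUNTERPARTS = ("GSEYTVEFLQK", "YRGSEYTVEFLQK")


def simulate_prm(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """PRM transition areas for phospho/non-phospho peptides in two conditions.

    Per condition, the phosphopeptide pool is ``occupancy * protein_level``
    and the non-phospho pool ``(1 - occupancy) * protein_level`` (split over
    the counterpart forms), each spread over 6 transitions with fixed
    fractions and multiplied by log-normal noise of coefficient of variation
    ``prm_cv``.  Condition A protein level is ``protein_ratio`` times B.

    Returns a tidy table: peptide, phospho, charge, transition, area,
    condition, replicate.
    """
    rng = config.rng("prm")
    occ = truth.true_occupancy
    levels = {"A": config.protein_ratio * 1e6, "B": 1e6}
    # fixed, unequal transition fractions (top-6 fragment ions)
    frac = np.array([0.30, 0.25, 0.18, 0.12, 0.09, 0.06])
    counterpart_split = np.array([0.6, 0.4])
    sigma = np.sqrt(np.log1p(config.prm_cv**2))  # log-normal sd for given CV
    rows: list[dict] = []
    for cond in ("A", "B"):
        a = occ[cond]
        pools = [(PRM_PHOSPHOPEPTIDE, True, a * levels[cond])]
        for pep, split in zip(PRM_COUNTERPARTS, counterpart_split):
            pools.append((pep, False, (1.0 - a) * levels[cond] * split))
        for rep in range(config.n_replicates):
            for pep, is_ph, pool in pools:
                noise = (
                    np.exp(rng.normal(-0.5 * sigma**2, sigma, size=frac.size))
                    if sigma > 0
                    else np.ones(frac.size)
                )
                areas = pool * frac * noise
                for t, area in enumerate(areas):
                    rows.append(
                        {
                            "peptide": pep,
                            "phospho": is_ph,
                            "charge": 2,
                            "transition": f"y{t + 3}",
                            "area": float(area),
                            "condition": cond,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers (MaxQuant proteinGroups dialect + design/annotation/PRM TSVs)
# ---------------------------------------------------------------------------


def write_experiment(exp: QuantExperiment, outdir: str | Path) -> list[Path]:
    """One proteinGroups-dialect TSV per replicate plus the labeling design."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rep in range(exp.n_replicates):
        df = pd.DataFrame({"Protein IDs": list(exp.proteins)})
        for ch in range(N_CHANNELS):
            df[f"Reporter intensity corrected {ch}"] = exp.intensities[:, rep, ch]
        df["Reverse"] = np.where(exp.flags["reverse"].to_numpy(), "+", "")
        df["Potential contaminant"] = np.where(
            exp.flags["contaminant"].to_numpy(), "+", ""
        )
        path = outdir / f"proteinGroups_rep{rep}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    design_rows = [
        {"replicate": rep, "channel": ch, "strain": strain}
        for rep, chmap in exp.design.items()
        for ch, strain in chmap.items()
    ]
    design_path = outdir / "design.tsv"
    pd.DataFrame(design_rows).to_csv(design_path, sep="\t", index=False)
    paths.append(design_path)
    return paths


def write_annotation(catalog: ProteinCatalog, path: str | Path) -> Path:
    """Two-column protein -> term TSV (one row per protein-term pair)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"protein": p, "term": t} for p in catalog.proteins for t in catalog.terms[p]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_prm(prm: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    prm.to_csv(path, sep="\t", index=False)
    return path


def write_config(config: SimConfig, path: str | Path) -> Path:
    """Flat key-value YAML dump of the simulation parameters."""
    import yaml

    d = dataclasses.asdict(config)
    d["strains"] = list(config.strains)
    d["dep_plan"] = {",".join(k): v for k, v in config.dep_plan.items()}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path
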