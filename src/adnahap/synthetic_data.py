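"""Synthetic cohorts and neutral genome-wide backgrounds.

The generator reproduces the statistical structure the estimators assume,
so the whole pipeline is testable without any sequence data:

* per time bin, individuals draw a genotype (copies of the adaptive
  haplotype) from Binomial(2, p_bin) — Hardy–Weinberg at the bin's true
  frequency;
* per panel SNP, read depth is Poisson with a per-individual mean, and each
  read supports the adaptive allele with probability 1-eps, 1/2 or eps for
  genotypes 2/1/0 (an extra ``damage_delta`` is added on transition SNPs
  when enabled, a symmetric stand-in for C->T/G->A deamination);
* background SNPs start at a Uniform(0.05, 0.95) frequency and drift
  between bins by Wright–Fisher binomial resampling of 2Ne gametes per
  generation; individuals are then sampled per bin exactly as for the
  focal panel but with a single-SNP "panel".

A single seed feeds a splittable ``numpy`` SeedSequence with one child
stream per individual (and separate streams for the panel and background),
so any subset of individuals is reproducible regardless of ordering, and
identical configurations produce byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .panel_io import (
    MODERN,
    AlleleCounts,
    CohortMetadata,
    SNPPanel,
    load_counts,
    load_metadata,
    load_panel,
    write_counts,
    write_metadata,
    write_panel,
)

__all__ = [
    "BinSpec",
    "BackgroundSpec",
    "SimulationConfig",
    "SimulationTruth",
    "study_config",
    "simulate_cohort",
    "simulate_neutral_background",
    "write_fixture",
    "load_fixture",
]

#: years per generation used to convert bin-date gaps into drift generations
DEFAULT_GENERATION_TIME = 29.0


@dataclass(frozen=True)
class BinSpec:
    """One time bin of the simulated study design."""

    label: str
    newest_bp: float
    oldest_bp: float
    n_individuals: int
    true_frequency: float
    modern: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_frequency <= 1.0:
            raise ValueError(f"true_frequency outside [0,1]: {self.true_frequency}")
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if not self.modern and self.oldest_bp < self.newest_bp:
            raise ValueError(f"bin {self.label!r}: oldest_bp < newest_bp")


@dataclass(frozen=True)
class BackgroundSpec:
    """Neutral genome-wide background: M SNPs drifting under Wright–Fisher."""

    n_snps: int = 500
    ne: float = 10_000.0
    generations_between_bins: tuple[int, ...] | None = None
    init_freq_low: float = 0.05
    init_freq_high: float = 0.95

    def __post_init__(self) -> None:
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        if self.ne < 1:
            raise ValueError("ne must be >= 1")
        if not 0.0 <= self.init_freq_low <= self.init_freq_high <= 1.0:
            raise ValueError("invalid initial-frequency range")


@dataclass(frozen=True)
class SimulationConfig:
    bins: tuple[BinSpec, ...]
    panel_size: int = 20
    coverage_lambda: Union[float, tuple[float, float]] = 1.0
    epsilon_true: float = 0.01
    damage_delta: float = 0.0
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    seed: int = 0
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        if self.panel_size < 0:
            raise ValueError("panel_size must be >= 0")
        lam = self.coverage_lambda
        if isinstance(lam, (tuple, list)):
            if len(lam) != 2 or not 0 <= lam[0] <= lam[1]:
                raise ValueError("coverage_lambda range must be (low, high), 0<=low<=high")
        elif lam < 0:
            raise ValueError("coverage_lambda must be >= 0")
        if not 0.0 <= self.epsilon_true < 0.5:
            raise ValueError("epsilon_true must be in [0, 0.5)")
        if self.damage_delta < 0 or self.epsilon_true + self.damage_delta >= 0.5:
            raise ValueError("epsilon_true + damage_delta must stay below 0.5")


def study_config(seed: int = 0) -> SimulationConfig:
    """The published study design as a simulation.

    Bin sizes and generating frequencies follow the reported cohort:
    19 individuals older than 2500 B.P. at frequency 0.36, 24 at 2400–1900
    B.P. (0.47), 37 at 1600–700 B.P. (0.59) and 33 present-day individuals
    (0.86). Mean depth per individual is log-uniform on 0.05–5x, matching
    the order-of-magnitude spread of shotgun-capture aDNA coverage.
    """
    bins = (
        BinSpec("older_2500", 2500.0, 5100.0, 19, 0.36),
        BinSpec("2400_1900", 1900.0, 2400.0, 24, 0.47),
        BinSpec("1600_700", 700.0, 1600.0, 37, 0.59),
        BinSpec("modern", 0.0, 0.0, 33, 0.86, modern=True),
    )
    return SimulationConfig(
        bins=bins,
        panel_size=20,
        coverage_lambda=(0.05, 5.0),
        epsilon_true=0.01,
        seed=seed,
    )


@dataclass
class SimulationTruth:
    """Generating truth: genotypes, bin frequencies, background paths."""

    individuals: pd.DataFrame  # individual_id, bin, genotype, mean_depth
    bin_frequencies: dict[str, float]
    background_paths: pd.DataFrame | None = None  # snp_id, bin, frequency

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationTruth):
            return NotImplemented
        same_bg = (
            (self.background_paths is None) == (other.background_paths is None)
            and (
                self.background_paths is None
                or self.background_paths.equals(other.background_paths)
            )
        )
        return (
            self.individuals.equals(other.individuals)
            and self.bin_frequencies == other.bin_frequencies
            and same_bg
        )


# ---------------------------------------------------------------------------
# cohort simulation

_BASES = np.array(list("ACGT"))
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _make_panel(rng: np.random.Generator, panel_size: int) -> SNPPanel:
    """A synthetic focal panel: fully linked SNPs on one chromosome arm."""
    refs = _BASES[rng.integers(0, 4, size=panel_size)]
    is_transition = rng.random(panel_size) < 0.5
    alts = []
    for ref, ti in zip(refs, is_transition):
        if ti:
            alts.append(_TRANSITION_PARTNER[ref])
        else:
            choices = [b for b in "ACGT" if b != ref and b != _TRANSITION_PARTNER[ref]]
            alts.append(choices[rng.integers(0, len(choices))])
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:02d}" for i in range(panel_size)],
            "chrom": "2",
            "pos": 46_550_000 + 2000 * np.arange(panel_size),
            "ref": refs,
            "alt": alts,
            "adaptive": alts,  # the adaptive haplotype carries the derived allele
            "is_transition": is_transition,
        }
    )
    return SNPPanel(df)


def _read_support_prob(genotype: int, eps_eff: np.ndarray) -> np.ndarray:
    """P(read supports adaptive allele | genotype), per SNP."""
    if genotype == 2:
        return 1.0 - eps_eff
    if genotype == 1:
        return np.full_like(eps_eff, 0.5)
    return eps_eff


def _individual_lambda(
    rng: np.random.Generator, coverage_lambda: Union[float, tuple[float, float]]
) -> float:
    if isinstance(coverage_lambda, (tuple, list)):
        lo, hi = coverage_lambda
        if lo == hi:
            return float(lo)
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(coverage_lambda)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[AlleleCounts, CohortMetadata, SNPPanel, SimulationTruth]:
    """Simulate read counts, metadata and panel for a time-binned cohort."""
    root = np.random.SeedSequence(config.seed)
    panel_ss, cohort_ss, _background_ss = root.spawn(3)
    panel = _make_panel(np.random.default_rng(panel_ss), config.panel_size)
    eps_eff = np.where(
        panel.df["is_transition"].to_numpy(),
        config.epsilon_true + config.damage_delta,
        config.epsilon_true,
    )

    total_n = sum(b.n_individuals for b in config.bins)
    child_streams = cohort_ss.spawn(total_n) if total_n else []
    count_rows, meta_rows, truth_rows = [], [], []
    idx = 0
    for b in config.bins:
        for j in range(b.n_individuals):
            rng = np.random.default_rng(child_streams[idx])
            ind = f"{b.label}_ind{j + 1:03d}"
            genotype = int(rng.binomial(2, b.true_frequency))
            lam = _individual_lambda(rng, config.coverage_lambda)
            depths = rng.poisson(lam, size=config.panel_size)
            support = _read_support_prob(genotype, eps_eff)
            n_adaptive = rng.binomial(depths, support)
            for snp_id, t, r in zip(panel.snp_ids, depths, n_adaptive):
                if t > 0:
                    count_rows.append(
                        {
                            "individual_id": ind,
                            "snp_id": snp_id,
                            "n_adaptive": int(r),
                            "n_total": int(t),
                        }
                    )
            date: object
            if b.modern:
                date = MODERN
            else:
                date = round(float(rng.uniform(b.newest_bp, b.oldest_bp)), 1)
            meta_rows.append(
                {
                    "individual_id": ind,
                    "date_bp": date,
                    "group": b.label,
                    "region": "simulated",
                }
            )
            truth_rows.append(
                {
                    "individual_id": ind,
                    "bin": b.label,
                    "genotype": genotype,
                    "mean_depth": lam,
                }
            )
            idx += 1

    counts = AlleleCounts(
        pd.DataFrame(count_rows, columns=["individual_id", "snp_id", "n_adaptive", "n_total"]),
        panel=panel,
    )
    meta = CohortMetadata(
        pd.DataFrame(meta_rows, columns=["individual_id", "date_bp", "group", "region"])
    )
    truth = SimulationTruth(
        individuals=pd.DataFrame(
            truth_rows, columns=["individual_id", "bin", "genotype", "mean_depth"]
        ),
        bin_frequencies={b.label: b.true_frequency for b in config.bins},
    )
    return counts, meta, panel, truth


# ---------------------------------------------------------------------------
# neutral background simulation


def _generations_between_bins(config: SimulationConfig) -> list[int]:
    """Drift generations separating consecutive bins (oldest first)."""
    bg = config.background
    n_gaps = max(len(config.bins) - 1, 0)
    if bg.generations_between_bins is not None:
        gens = list(bg.generations_between_bins)
        if len(gens) != n_gaps:
            raise ValueError(
                f"need {n_gaps} generation gaps, got {len(gens)}"
            )
        return gens
    gens = []
    for older, newer in zip(config.bins, config.bins[1:]):
        mid_old = older.newest_bp if older.oldest_bp == math.inf else 0.5 * (
            older.newest_bp + older.oldest_bp
        )
        mid_new = 0.0 if newer.modern else 0.5 * (newer.newest_bp + newer.oldest_bp)
        gens.append(max(int(round((mid_old - mid_new) / config.generation_time)), 0))
    return gens


def _wright_fisher_step(
    rng: np.random.Generator, freqs: np.ndarray, ne: float, generations: int
) -> np.ndarray:
    """Binomial resampling of 2Ne gametes per generation; 0/1 are absorbing."""
    two_ne = max(int(round(2 * ne)), 2)
    f = freqs.copy()
    for _ in range(generations):
        f = rng.binomial(two_ne, f) / two_ne
    return f


def simulate_neutral_background(config: SimulationConfig):
    """Drift-only background SNP counts for the resampling null.

    Returns ``(r, t, snp_ids, bin_labels, truth)`` where ``r`` and ``t``
    are (M, B, N_max) arrays of per-SNP, per-bin, per-individual read
    counts (bins with fewer individuals are zero-padded and accompanied by
    the per-bin sizes in ``truth.individuals.attrs['bin_sizes']``). The
    same individuals are used across all SNPs within a bin, mirroring the
    focal analysis design.
    """
    from .selection_test import BackgroundCounts  # local import, no cycle at runtime

    root = np.random.SeedSequence(config.seed)
    _panel_ss, _cohort_ss, background_ss = root.spawn(3)
    rng = np.random.default_rng(background_ss)
    bg = config.background
    m = bg.n_snps
    bins = config.bins
    n_bins = len(bins)
    n_max = max((b.n_individuals for b in bins), default=0)

    init = rng.uniform(bg.init_freq_low, bg.init_freq_high, size=m)
    gens = _generations_between_bins(config)
    paths = np.empty((m, n_bins))
    f = init
    for bi in range(n_bins):
        if bi > 0:
            f = _wright_fisher_step(rng, f, bg.ne, gens[bi - 1])
        paths[:, bi] = f

    r = np.zeros((m, n_bins, n_max), dtype=np.int64)
    t = np.zeros((m, n_bins, n_max), dtype=np.int64)
    for bi, b in enumerate(bins):
        n = b.n_individuals
        if n == 0 or m == 0:
            continue
        genotypes = rng.binomial(2, paths[:, bi][:, None], size=(m, n))
        if isinstance(config.coverage_lambda, (tuple, list)):
            lo, hi = config.coverage_lambda
            lam = (
                np.full(n, float(lo))
                if lo == hi
                else np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
            )
        else:
            lam = np.full(n, float(config.coverage_lambda))
        depth = rng.poisson(lam[None, :], size=(m, n))
        support = np.choose(genotypes, [
            np.full((m, n), config.epsilon_true),
            np.full((m, n), 0.5),
            np.full((m, n), 1.0 - config.epsilon_true),
        ])
        reads = rng.binomial(depth, support)
        r[:, bi, :n] = reads
        t[:, bi, :n] = depth

    snp_ids = [f"bg{i + 1:05d}" for i in range(m)]
    bin_labels = [b.label for b in bins]
    truth = SimulationTruth(
        individuals=pd.DataFrame(
            {"bin": bin_labels, "n_individuals": [b.n_individuals for b in bins]}
        ),
        bin_frequencies={b.label: b.true_frequency for b in bins},
        background_paths=pd.DataFrame(
            {
                "snp_id": np.repeat(snp_ids, n_bins),
                "bin": bin_labels * m,
                "frequency": paths.reshape(-1),
            }
        ),
    )
    background = BackgroundCounts(
        snp_ids=tuple(snp_ids),
        bin_labels=tuple(bin_labels),
        bin_sizes=tuple(b.n_individuals for b in bins),
        r=r,
        t=t,
    )
    return background, truth


# ---------------------------------------------------------------------------
# fixture round-trip


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(d["coverage_lambda"], tuple):
        d["coverage_lambda"] = list(d["coverage_lambda"])
    d["bins"] = [dict(b) if isinstance(b, dict) else dataclasses.asdict(b) for b in d["bins"]]
    if d["background"]["generations_between_bins"] is not None:
        d["background"]["generations_between_bins"] = list(
            d["background"]["generations_between_bins"]
        )
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    bins = tuple(BinSpec(**b) for b in d["bins"])
    bg = BackgroundSpec(**{
        **d.get("background", {}),
        "generations_between_bins": (
            tuple(d["background"]["generations_between_bins"])
            if d.get("background", {}).get("generations_between_bins") is not None
            else None
        ),
    }) if "background" in d else BackgroundSpec()
    lam = d.get("coverage_lambda", 1.0)
    if isinstance(lam, list):
        lam = tuple(lam)
    return SimulationConfig(
        bins=bins,
        panel_size=d.get("panel_size", 20),
        coverage_lambda=lam,
        epsilon_true=d.get("epsilon_true", 0.01),
        damage_delta=d.get("damage_delta", 0.0),
        background=bg,
        seed=d.get("seed", 0),
        generation_time=d.get("generation_time", DEFAULT_GENERATION_TIME),
    )


def write_fixture(
    config: SimulationConfig,
    directory: Union[str, Path],
    include_background: bool = False,
) -> Path:
    """Simulate and write a self-describing fixture directory.

    Layout: ``panel.tsv``, ``counts.tsv``, ``meta.tsv``, ``truth.tsv``,
    ``config.yaml`` (echo; re-running it reproduces the fixture exactly)
    and optionally ``background_counts.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts, meta, panel, truth = simulate_cohort(config)
    write_panel(panel, directory / "panel.tsv")
    write_counts(counts, directory / "counts.tsv")
    write_metadata(meta, directory / "meta.tsv")
    truth.individuals.to_csv(directory / "truth.tsv", sep="\t", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
    if include_background:
        background, bg_truth = simulate_neutral_background(config)
        background.to_frame().to_csv(
            directory / "background_counts.tsv", sep="\t", index=False
        )
        bg_truth.background_paths.to_csv(
            directory / "background_truth.tsv", sep="\t", index=False
        )
    return directory


def load_fixture(directory: Union[str, Path]):
    """Reload a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    panel = load_panel(directory / "panel.tsv")
    counts = load_counts(directory / "counts.tsv", panel)
    meta = load_metadata(directory / "meta.tsv")
    truth_df = pd.read_csv(directory / "truth.tsv", sep="\t")
    with open(directory / "config.yaml") as fh:
        config = config_from_dict(yaml.safe_load(fh))
    truth = SimulationTruth(
        individuals=truth_df,
        bin_frequencies={b.label: b.true_frequency for b in config.bins},
    )
    return counts, meta, panel, truth, config
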