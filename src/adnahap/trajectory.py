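"""Time-binned haplotype-frequency trajectories.

Individuals are assigned to closed date intervals in calibrated years B.P.
(present = 1950 CE); present-day individuals carry the sentinel date
``modern`` and fall into an optional modern bin. The default preset follows
the published study design for the plateau cohort — an oldest bin for
individuals older than 2500 B.P., bins at 2400–1900 and 1600–700 B.P., and
a modern bin. The preset bins are deliberately non-contiguous: dates in the
gaps (2500–2400, 1900–1600) are excluded and reported, never snapped to a
neighbouring bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .genotype_model import ErrorModel, aggregate_cohort
from .frequency_model import FrequencyEstimate, ci_frequency
from .panel_io import MODERN, AlleleCounts, CohortMetadata, SNPPanel

__all__ = [
    "TimeBin",
    "TimeBins",
    "BinAssignment",
    "TrajectoryPoint",
    "Trajectory",
    "study_bins",
    "bin_individuals",
    "estimate_trajectory",
    "frequency_change",
]


@dataclass(frozen=True)
class TimeBin:
    """Closed interval [newest_bp, oldest_bp] in cal B.P., or a modern bin."""

    label: str
    newest_bp: float = 0.0
    oldest_bp: float = 0.0
    modern: bool = False

    def __post_init__(self) -> None:
        if not self.modern and self.oldest_bp < self.newest_bp:
            raise ValueError(
                f"bin {self.label!r}: oldest_bp < newest_bp "
                f"({self.oldest_bp} < {self.newest_bp})"
            )

    def contains(self, date_bp) -> bool:
        if date_bp == MODERN:
            return self.modern
        if self.modern:
            return False
        return self.newest_bp <= float(date_bp) <= self.oldest_bp


@dataclass(frozen=True)
class TimeBins:
    bins: tuple[TimeBin, ...]

    def __post_init__(self) -> None:
        labels = [b.label for b in self.bins]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate bin labels: {labels}")
        if sum(b.modern for b in self.bins) > 1:
            raise ValueError("at most one modern bin allowed")
        dated = sorted(
            (b for b in self.bins if not b.modern), key=lambda b: b.newest_bp
        )
        for a, b in zip(dated, dated[1:]):
            if b.newest_bp <= a.oldest_bp:  # closed intervals share a point
                raise ValueError(f"bins {a.label!r} and {b.label!r} overlap")

    def __iter__(self):
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    def __getitem__(self, label: str) -> TimeBin:
        for b in self.bins:
            if b.label == label:
                return b
        raise KeyError(label)


def study_bins(include_modern: bool = True) -> TimeBins:
    """The published four-group preset (oldest to newest)."""
    bins = [
        TimeBin("older_2500", newest_bp=2500.0, oldest_bp=math.inf),
        TimeBin("2400_1900", newest_bp=1900.0, oldest_bp=2400.0),
        TimeBin("1600_700", newest_bp=700.0, oldest_bp=1600.0),
    ]
    if include_modern:
        bins.append(TimeBin("modern", modern=True))
    return TimeBins(tuple(bins))


@dataclass(frozen=True)
class BinAssignment:
    """Bin -> individuals mapping plus the explicit exclusion report."""

    assigned: dict[str, tuple[str, ...]]
    excluded: tuple[str, ...]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def bin_individuals(meta: CohortMetadata, bins: TimeBins) -> BinAssignment:
    """Assign each individual to the unique bin containing its date.

    Individuals whose dates fall in no bin (e.g. the preset's inter-bin
    gaps) are listed in the exclusion report rather than silently dropped.
    """
    assigned: dict[str, list[str]] = {b.label: [] for b in bins}
    excluded: list[str] = []
    for row in meta.df.itertuples(index=False):
        hits = [b.label for b in bins if b.contains(row.date_bp)]
        if len(hits) > 1:  # unreachable given TimeBins validation
            raise ValueError(f"individual {row.individual_id} matches bins {hits}")
        if hits:
            assigned[hits[0]].append(row.individual_id)
        else:
            excluded.append(row.individual_id)
    return BinAssignment(
        assigned={k: tuple(v) for k, v in assigned.items()},
        excluded=tuple(excluded),
    )


@dataclass(frozen=True)
class TrajectoryPoint:
    label: str
    estimate: FrequencyEstimate | None
    individual_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.individual_ids)


@dataclass(frozen=True)
class Trajectory:
    points: tuple[TrajectoryPoint, ...]
    excluded: tuple[str, ...] = field(default=())

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, label: str) -> TrajectoryPoint:
        for pt in self.points:
            if pt.label == label:
                return pt
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            est = pt.estimate
            rows.append(
                {
                    "bin": pt.label,
                    "p_hat": est.p_hat if est else float("nan"),
                    "ci_low": est.ci_low if est else float("nan"),
                    "ci_high": est.ci_high if est else float("nan"),
                    "level": est.level if est else float("nan"),
                    "n": pt.n,
                    "method": est.method if est else "",
                    "epsilon": est.epsilon if est else float("nan"),
                    "degenerate": est.degenerate if est else True,
                }
            )
        return pd.DataFrame(rows)


def estimate_trajectory(
    counts: AlleleCounts,
    meta: CohortMetadata,
    panel: SNPPanel,
    bins: TimeBins,
    error: ErrorModel,
    level: float = 0.95,
    ci_method: str = "profile",
    seed: int | None = None,
) -> Trajectory:
    """Per-bin ML frequency estimates with confidence intervals.

    Empty bins are retained with n = 0 and no estimate. Estimates depend
    only on bin membership, so they are invariant to row order in either
    input table.
    """
    assignment = bin_individuals(meta, bins)
    points = []
    for b in bins:
        ids = tuple(sorted(assignment.assigned[b.label]))
        if not ids:
            points.append(TrajectoryPoint(b.label, None, ids))
            continue
        cohort = aggregate_cohort(counts, panel, ids)
        est = ci_frequency(cohort, error, level=level, method=ci_method, seed=seed)
        points.append(TrajectoryPoint(b.label, est, ids))
    return Trajectory(tuple(points), excluded=assignment.excluded)


def frequency_change(traj: Trajectory, bin_a: str, bin_b: str) -> float:
    """p_hat(bin_b) - p_hat(bin_a); pass the older bin first.

    Raises ``KeyError`` for unknown bins and ``ValueError`` when either
    bin lacks an estimate.
    """
    pa, pb = traj[bin_a], traj[bin_b]
    for pt in (pa, pb):
        if pt.estimate is None or pt.estimate.degenerate:
            raise ValueError(f"bin {pt.label!r} has no usable estimate")
    return pb.estimate.p_hat - pa.estimate.p_hat


def plot_trajectory(traj: Trajectory, path=None, order: Sequence[str] | None = None):
    """Point-and-interval trajectory figure (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(order) if order else [pt.label for pt in traj]
    xs, ys, lo, hi = [], [], [], []
    for i, label in enumerate(labels):
        pt = traj[label]
        if pt.estimate is None or pt.estimate.degenerate:
            continue
        xs.append(i)
        ys.append(pt.estimate.p_hat)
        lo.append(pt.estimate.p_hat - pt.estimate.ci_low)
        hi.append(pt.estimate.ci_high - pt.estimate.p_hat)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(xs, ys, yerr=[lo, hi], fmt="o-", capsize=3)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylabel("adaptive-haplotype frequency")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
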