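"""Domain types for multi-surveyor detection surveys of sessile organisms.

The detection unit is an immobile individual (for overwintering butterfly
larvae, one hibernaculum = one individual). An *occasion* is one surveyor's
complete independent search of a plot; occasions replace the time steps of
classical capture-mark-recapture. Within a plot each surveyor searches at
most once, so the occasion axis is indexed by surveyor identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

EXPERIENCE_LEVELS = ("expert", "novice")
SPECIES_LEVELS = ("reducta", "camilla", "unknown")
OCCUPANCY_LEVELS = ("full", "empty", "unknown")


class DatasetError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class SurveyorInfo:
    """One surveyor: identity, experience level, and the plots they searched."""

    surveyor_id: str
    experience: str
    plots_searched: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.experience not in EXPERIENCE_LEVELS:
            raise DatasetError(
                f"surveyor {self.surveyor_id!r}: experience must be one of "
                f"{EXPERIENCE_LEVELS}, got {self.experience!r}"
            )
        object.__setattr__(self, "plots_searched", frozenset(self.plots_searched))


@dataclass(frozen=True)
class PlotInfo:
    """Survey plot metadata: area in square metres, optional host-plant count."""

    plot_id: str
    area: float
    host_plants: int | None = None

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise DatasetError(f"plot {self.plot_id!r}: area must be > 0, got {self.area}")
        if self.host_plants is not None and self.host_plants < 0:
            raise DatasetError(f"plot {self.plot_id!r}: host_plants must be >= 0")


@dataclass(frozen=True)
class IndividualRecord:
    """One detection unit (hibernaculum) with species/occupancy/loss labels.

    ``lost`` marks individuals that disappeared during the study; they break
    the closure assumption and are removed by :func:`filter_closure` rather
    than at read time, so mortality summaries can still see them.
    """

    hibernaculum_id: str
    plot_id: str
    species: str = "unknown"
    occupancy: str = "unknown"
    lost: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES_LEVELS:
            raise DatasetError(
                f"individual {self.hibernaculum_id!r}: species must be one of "
                f"{SPECIES_LEVELS}, got {self.species!r}"
            )
        if self.occupancy not in OCCUPANCY_LEVELS:
            raise DatasetError(
                f"individual {self.hibernaculum_id!r}: occupancy must be one of "
                f"{OCCUPANCY_LEVELS}, got {self.occupancy!r}"
            )


@dataclass
class DetectionDataset:
    """Per-plot binary detection matrices plus surveyor/plot/individual metadata.

    Parameters
    ----------
    surveyors
        Registry ``surveyor_id -> SurveyorInfo``.
    plots
        Registry ``plot_id -> PlotInfo``.
    individuals
        Registry ``plot_id -> list of IndividualRecord`` (row order of the
        matrix).
    occasions
        ``plot_id -> ordered list of surveyor_ids`` (temporal search order).
    matrices
        ``plot_id -> (n_individuals, n_occasions) array`` of 0/1 detections.
    ground_truth
        Optional simulation ground truth: ``plot_id -> {"true_n": int,
        "detectability": array, "n_undetected": int}``. When present, the
        every-individual-detected invariant is not enforced (real field data
        can only contain detected individuals; simulated data may not).
    """

    surveyors: dict[str, SurveyorInfo]
    plots: dict[str, PlotInfo]
    individuals: dict[str, list[IndividualRecord]]
    occasions: dict[str, list[str]]
    matrices: dict[str, np.ndarray]
    ground_truth: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        self.matrices = {p: np.asarray(m, dtype=np.int8) for p, m in self.matrices.items()}
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def plot_ids(self) -> list[str]:
        return list(self.occasions)

    def matrix(self, plot_id: str) -> np.ndarray:
        self._require_plot(plot_id)
        return self.matrices[plot_id]

    def occasion_surveyors(self, plot_id: str) -> list[str]:
        self._require_plot(plot_id)
        return list(self.occasions[plot_id])

    def _require_plot(self, plot_id: str) -> None:
        if plot_id not in self.occasions:
            raise KeyError(f"unknown plot id {plot_id!r}; have {sorted(self.occasions)}")

    def validate(self) -> None:
        for plot_id, order in self.occasions.items():
            if len(set(order)) != len(order):
                raise DatasetError(f"plot {plot_id!r}: duplicate surveyor in occasion order")
            for sid in order:
                if sid not in self.surveyors:
                    raise DatasetError(f"plot {plot_id!r}: unknown surveyor {sid!r} in occasions")
            m = self.matrices.get(plot_id)
            if m is None:
                raise DatasetError(f"plot {plot_id!r}: no detection matrix")
            if m.ndim != 2 or m.shape[1] != len(order):
                raise DatasetError(
                    f"plot {plot_id!r}: matrix shape {m.shape} does not match "
                    f"{len(order)} occasions"
                )
            if not np.isin(m, (0, 1)).all():
                bad = np.argwhere(~np.isin(m, (0, 1)))[0]
                raise DatasetError(
                    f"plot {plot_id!r}: non-binary detection value at "
                    f"individual row {bad[0]}, occasion {bad[1] + 1}"
                )
            recs = self.individuals.get(plot_id, [])
            if len(recs) != m.shape[0]:
                raise DatasetError(
                    f"plot {plot_id!r}: {len(recs)} individual records but "
                    f"{m.shape[0]} matrix rows"
                )
            ids = [r.hibernaculum_id for r in recs]
            if len(set(ids)) != len(ids):
                raise DatasetError(f"plot {plot_id!r}: duplicate hibernaculum ids")
            if self.ground_truth is None and m.shape[0] and not (m.sum(axis=1) >= 1).all():
                row = int(np.flatnonzero(m.sum(axis=1) == 0)[0])
                raise DatasetError(
                    f"plot {plot_id!r}: individual {ids[row]!r} has no detection "
                    "(real data contains only detected individuals)"
                )

    # -- views -------------------------------------------------------------

    def subset_occasions(self, plot_id: str, surveyor_ids: Iterable[str]) -> "DetectionDataset":
        """Single-plot view restricted to the given occasions.

        Keeps the original within-plot search order and drops individuals
        never detected by the retained surveyors.
        """
        self._require_plot(plot_id)
        keep = [s for s in self.occasions[plot_id] if s in set(surveyor_ids)]
        if not keep:
            raise DatasetError(f"plot {plot_id!r}: empty occasion subset")
        cols = [self.occasions[plot_id].index(s) for s in keep]
        m = self.matrices[plot_id][:, cols]
        rows = np.flatnonzero(m.sum(axis=1) >= 1)
        recs = [self.individuals[plot_id][i] for i in rows]
        return DetectionDataset(
            surveyors={s: self.surveyors[s] for s in keep},
            plots={plot_id: self.plots[plot_id]},
            individuals={plot_id: recs},
            occasions={plot_id: keep},
            matrices={plot_id: m[rows]},
        )

    def all_individuals(self) -> list[IndividualRecord]:
        return [r for recs in self.individuals.values() for r in recs]


def filter_closure(ds: DetectionDataset) -> tuple[DetectionDataset, int]:
    """Drop individuals that disappeared during the study (closure violation).

    Returns the filtered copy and the number of individuals removed.
    Idempotent: re-filtering removes nothing further.
    """
    individuals: dict[str, list[IndividualRecord]] = {}
    matrices: dict[str, np.ndarray] = {}
    removed = 0
    for plot_id in ds.plot_ids:
        recs = ds.individuals[plot_id]
        keep = [i for i, r in enumerate(recs) if not r.lost]
        removed += len(recs) - len(keep)
        individuals[plot_id] = [recs[i] for i in keep]
        matrices[plot_id] = ds.matrices[plot_id][keep]
    out = DetectionDataset(
        surveyors=dict(ds.surveyors),
        plots=dict(ds.plots),
        individuals=individuals,
        occasions={p: list(o) for p, o in ds.occasions.items()},
        matrices=matrices,
        ground_truth=ds.ground_truth,
    )
    return out, removed


def mln(ds: DetectionDataset, plot_id: str) -> int:
    """Minimum larva number: distinct individuals with >=1 detection in a plot.

    A direct lower bound on abundance, read straight off the field data.
    """
    m = ds.matrix(plot_id)
    if m.size == 0:
        return 0
    return int((m.sum(axis=1) >= 1).sum())


def experts_of(ds: DetectionDataset, plot_id: str) -> list[str]:
    """Expert surveyors of a plot, in search order."""
    return [
        s for s in ds.occasion_surveyors(plot_id) if ds.surveyors[s].experience == "expert"
    ]
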