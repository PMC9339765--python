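"""Ecological summaries derived from abundance estimates and labels:
larval densities, hibernaculum occupancy (overwinter mortality proxy), and
adult recruitment arithmetic."""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import DetectionDataset, PlotInfo


@dataclass(frozen=True)
class DensitySummary:
    plot_id: str
    larvae_per_100m2: float
    larvae_per_100_hostplants: float | None
    species_adjusted: bool


def density(n_hat: float, plot: PlotInfo, species_fraction: float = 1.0) -> DensitySummary:
    """Larval density per 100 m² (and per 100 host plants when known).

    ``species_fraction`` apportions the estimate to the focal species when
    a sister species co-occurs; 1.0 reports all hibernacula.
    """
    if not 0.0 <= species_fraction <= 1.0:
        raise ValueError("species_fraction must be in [0, 1]")
    n_adj = n_hat * species_fraction
    per_plants = None
    if plot.host_plants:
        per_plants = n_adj / plot.host_plants * 100.0
    return DensitySummary(
        plot_id=plot.plot_id,
        larvae_per_100m2=n_adj / plot.area * 100.0,
        larvae_per_100_hostplants=per_plants,
        species_adjusted=species_fraction != 1.0,
    )


def species_fraction(ds: DetectionDataset, plot_id: str | None = None) -> float:
    """Share of the focal species among identified individuals.

    Empty hibernacula (species unknown) are apportioned by this same
    fraction when it multiplies an abundance estimate.
    """
    recs = ds.individuals[plot_id] if plot_id else ds.all_individuals()
    reducta = sum(1 for r in recs if r.species == "reducta")
    camilla = sum(1 for r in recs if r.species == "camilla")
    if reducta + camilla == 0:
        raise ValueError("no individuals with identified species")
    return reducta / (reducta + camilla)


def empty_fraction(ds: DetectionDataset, plot_id: str | None = None) -> float:
    """Fraction of empty hibernacula among occupancy-labelled individuals —
    a proxy for larval mortality during hibernation."""
    recs = ds.individuals[plot_id] if plot_id else ds.all_individuals()
    empty = sum(1 for r in recs if r.occupancy == "empty")
    full = sum(1 for r in recs if r.occupancy == "full")
    if empty + full == 0:
        raise ValueError("no individuals with occupancy labels")
    return empty / (empty + full)


def recruitment(n_hat: float, survival: float) -> float:
    """Expected adults emerging from ``n_hat`` larvae at a given survival
    rate through the remaining life stages."""
    if not 0.0 <= survival <= 1.0:
        raise ValueError("survival must be in [0, 1]")
    return n_hat * survival
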