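"""Equal-detectability diagnostic for multi-surveyor surveys.

Closed-population models assume every individual is equally detectable.
With immobile individuals that assumption is testable: fixing the population
size at the full-effort abundance estimate and each surveyor's haul at the
number of individuals they actually found, repeated simple random draws
produce the distribution of per-individual detection counts expected under
equal detectability. Comparing the observed frequency of individuals found
0, 1, 2, … times against the simulated median and 95% envelope flags
heterogeneity: too many never/rarely-found plus too many often-found
individuals pushes the tails outside the bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import DetectionDataset, mln


@dataclass
class FrequencyBands:
    """Simulated per-k detection-count frequencies under equal detection.

    Index k runs 0..T (T = number of occasions). Every simulation replicate
    distributes exactly ``n_assumed`` individuals over the k bins.
    """

    n_assumed: int
    occasion_counts: np.ndarray
    sim_median: np.ndarray
    sim_ci95: np.ndarray  # (T+1, 2)
    n_sim: int
    seed: int | None

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_counts)


@dataclass
class DetectabilityComparison:
    """Observed per-k frequencies against the simulated bands."""

    observed: np.ndarray
    bands: FrequencyBands
    inside: np.ndarray  # bool per k

    @property
    def fraction_inside(self) -> float:
        return float(self.inside.mean())


def simulate_equal_detection(
    n: int,
    occasion_counts,
    n_sim: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FrequencyBands:
    """Simulate detection-count frequencies under equal detectability.

    Per replicate and occasion j, a uniform simple random sample of size
    n_j is drawn *without replacement* from the n individuals (surveyor j
    found exactly n_j distinct individuals); per-individual totals are then
    tallied into a frequency table over k = 0..T. Bands are the per-k median
    and 2.5/97.5 percentiles across replicates.
    """
    occasion_counts = np.asarray(occasion_counts, dtype=int)
    if np.any(occasion_counts > n):
        bad = int(np.flatnonzero(occasion_counts > n)[0])
        raise ValueError(
            f"occasion {bad + 1}: count {occasion_counts[bad]} exceeds population size {n}"
        )
    if np.any(occasion_counts < 0):
        raise ValueError("occasion counts must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    T = len(occasion_counts)

    counts = np.zeros((n_sim, n), dtype=np.int16)
    for n_j in occasion_counts:
        if n_j == 0:
            continue
        # rank trick: the n_j smallest uniforms mark a uniform SRS w/o replacement
        u = rng.random((n_sim, n))
        idx = np.argpartition(u, n_j - 1, axis=1)[:, :n_j]
        inc = np.zeros((n_sim, n), dtype=np.int16)
        np.put_along_axis(inc, idx, 1, axis=1)
        counts += inc

    offsets = counts + (T + 1) * np.arange(n_sim)[:, None]
    freq = np.bincount(offsets.ravel(), minlength=n_sim * (T + 1)).reshape(n_sim, T + 1)
    med = np.median(freq, axis=0)
    lo, hi = np.percentile(freq, [2.5, 97.5], axis=0)
    return FrequencyBands(
        n_assumed=int(n),
        occasion_counts=occasion_counts,
        sim_median=med.astype(float),
        sim_ci95=np.column_stack([lo, hi]).astype(float),
        n_sim=n_sim,
        seed=seed,
    )


def observed_frequencies(ds: DetectionDataset, plot_id: str, n_assumed: int) -> np.ndarray:
    """Observed per-k frequency table, with k=0 set to n_assumed − MLN."""
    m = ds.matrix(plot_id)
    T = m.shape[1]
    per_ind = m.sum(axis=1)
    freq = np.bincount(per_ind, minlength=T + 1)[: T + 1].astype(float)
    n_seen = mln(ds, plot_id)
    if n_assumed < n_seen:
        raise ValueError(
            f"assumed population {n_assumed} below the {n_seen} individuals observed"
        )
    freq[0] = n_assumed - n_seen
    return freq


def bands_for_plot(
    ds: DetectionDataset,
    plot_id: str,
    n_assumed: float,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> FrequencyBands:
    """Bands for one plot, conditioning on each surveyor's observed haul.

    ``n_assumed`` is typically the full-effort CMR abundance estimate; it is
    rounded to the nearest integer since draws need an integer population.
    """
    occ_counts = ds.matrix(plot_id).sum(axis=0)
    return simulate_equal_detection(int(round(n_assumed)), occ_counts, n_sim=n_sim, seed=seed)


def compare_observed(
    ds: DetectionDataset, plot_id: str, bands: FrequencyBands
) -> DetectabilityComparison:
    """Flag, per detection count k, whether the observed frequency lies
    inside the simulated 95% envelope."""
    obs = observed_frequencies(ds, plot_id, bands.n_assumed)
    inside = (obs >= bands.sim_ci95[:, 0]) & (obs <= bands.sim_ci95[:, 1])
    return DetectabilityComparison(observed=obs, bands=bands, inside=inside)


def plot_bands(comparison: DetectabilityComparison, path, title: str = "") -> None:
    """Dots-and-bars figure: observed frequencies over the simulated bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    b = comparison.bands
    k = np.arange(len(b.sim_median))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(k, b.sim_median, color="0.8", label="simulated median")
    yerr = np.abs(b.sim_ci95.T - b.sim_median)
    ax.errorbar(k, b.sim_median, yerr=yerr, fmt="none", ecolor="0.4", capsize=3)
    ax.plot(k, comparison.observed, "o", color="tab:blue", label="observed")
    ax.set_xlabel("number of detections per individual")
    ax.set_ylabel("frequency")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
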