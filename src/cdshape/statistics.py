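"""Ensemble-level statistics over per-frame descriptor tables.

Given the tidy metrics table produced by
:func:`cdshape.descriptors.metrics_table`, this module computes

* the 2-D free-energy surface over (d1, d2) by Boltzmann inversion of
  the pooled pair histogram, F(x, y) = -kB T log P(x, y);
* flip-state populations (percentage of frames with 0, 1, 2, ... glucose
  units flipped, i.e. adjacent-pair angles above 90 deg);
* cavity self-closure statistics from the per-HP d4 < 3 A criterion;
* circularity mean +/- standard deviation and the Rg distribution;
* a per-temperature summary table for replica-exchange output.

All percentages are kept at full precision here; rounding happens only
at report time.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KB_KCAL_MOL_K


class StatisticsError(ValueError):
    """Raised for statistically undefined requests (empty input, no HP)."""


def _vector_columns(metrics: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in metrics.columns if c.startswith(prefix + "_")]
    return sorted(cols, key=lambda c: int(c.rsplit("_", 1)[1]))


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FESGrid:
    """Binned 2-D probability and Boltzmann-inverted free-energy surface.

    ``probability`` sums to 1 over occupied bins; ``free_energy`` is
    -kB T log P in kcal/mol on occupied bins and NaN (undefined) on
    empty ones, optionally shifted so its minimum is zero.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray  # (nx, ny)
    free_energy: np.ndarray  # (nx, ny); NaN where probability == 0
    temperature: float
    kB: float = KB_KCAL_MOL_K

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: bin centres, probability and F (occupied bins)."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        ix, iy = np.nonzero(self.probability > 0)
        return pd.DataFrame(
            {
                "d1_center": xc[ix],
                "d2_center": yc[iy],
                "probability": self.probability[ix, iy],
                "free_energy": self.free_energy[ix, iy],
            }
        )


def pooled_pair_samples(metrics: pd.DataFrame) -> np.ndarray:
    """All (d1(i), d2(i)) pairs of every frame, shape (n_frames*n_units, 2).

    The surface is pooled over the n_units adjacent pairs and over
    frames, preserving per-unit order within each frame.
    """
    if len(metrics) == 0:
        raise StatisticsError("empty metrics table")
    d1 = metrics[_vector_columns(metrics, "d1")].to_numpy(float)
    d2 = metrics[_vector_columns(metrics, "d2")].to_numpy(float)
    return np.column_stack([d1.ravel(), d2.ravel()])


def free_energy_surface(
    samples: np.ndarray,
    temperature: float,
    bin_width: float = 0.1,
    x_range: tuple[float, float] = (2.0, 8.0),
    y_range: tuple[float, float] | None = None,
    shift_min_to_zero: bool = True,
) -> FESGrid:
    """Boltzmann inversion of the 2-D histogram of paired samples.

    Bins of ``bin_width`` (A) tile ``x_range`` x ``y_range`` (default
    2-8 A on both axes); samples outside the window are dropped and the
    probability renormalised over the retained ones.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise StatisticsError("no samples for free-energy surface")
    if temperature <= 0 or bin_width <= 0:
        raise StatisticsError("temperature and bin width must be positive")
    if y_range is None:
        y_range = x_range
    nx = int(np.ceil((x_range[1] - x_range[0]) / bin_width))
    ny = int(np.ceil((y_range[1] - y_range[0]) / bin_width))
    counts, x_edges, y_edges = np.histogram2d(
        samples[:, 0], samples[:, 1], bins=(nx, ny), range=(x_range, y_range)
    )
    total = counts.sum()
    if total == 0:
        raise StatisticsError("all samples fall outside the histogram window")
    prob = counts / total
    with np.errstate(divide="ignore"):
        free = -KB_KCAL_MOL_K * temperature * np.log(prob)
    free[prob == 0] = np.nan
    if shift_min_to_zero:
        free -= np.nanmin(free)
    return FESGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        probability=prob,
        free_energy=free,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# Flip populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlipPopulation:
    """Percentage of frames by number of flipped glucose units."""

    percentages: Mapping[int, float]  # flip count -> % of frames

    def percentage(self, n_flips: int) -> float:
        """Percentage for a flip count; 0 beyond the observed maximum."""
        return float(self.percentages.get(n_flips, 0.0))


def classify_flips(theta: np.ndarray, threshold: float = 90.0) -> int:
    """Number of adjacent-pair angles strictly above ``threshold`` degrees."""
    return int(np.sum(np.asarray(theta, dtype=float) > threshold))


def flip_population(metrics: pd.DataFrame) -> FlipPopulation:
    """Distribution of per-frame flip counts as percentages of frames."""
    if len(metrics) == 0:
        raise StatisticsError("empty metrics table")
    counts = metrics["n_flips"].value_counts().sort_index()
    pct = {int(k): 100.0 * v / len(metrics) for k, v in counts.items()}
    return FlipPopulation(percentages=pct)


# ---------------------------------------------------------------------------
# Cavity self-closure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelfClosureSummary:
    """Distribution of inserted-HP counts and the overall closure percentage.

    A frame shows cavity self-closure when at least one HP group's
    centre of mass sits within the insertion cutoff of the ring's centre
    of mass (n_inserted > 0).
    """

    probability_by_n_inserted: Mapping[int, float]  # k -> % of frames
    closure_percentage: float


def n_hp_inserted(d4: np.ndarray, cutoff: float = 3.0) -> int:
    """Number of HP groups with ring-to-HP COM distance strictly below cutoff."""
    if cutoff <= 0:
        raise StatisticsError("insertion cutoff must be positive")
    return int(np.sum(np.asarray(d4, dtype=float) < cutoff))


def self_closure_summary(metrics: pd.DataFrame) -> SelfClosureSummary:
    """Self-closure statistics over frames; requires an HP-substituted topology."""
    if len(metrics) == 0:
        raise StatisticsError("empty metrics table")
    if not any(c.startswith("d4_") for c in metrics.columns):
        raise StatisticsError("self-closure undefined for unsubstituted CD (no HP groups)")
    counts = metrics["n_inserted"].value_counts().sort_index()
    pct = {int(k): 100.0 * v / len(metrics) for k, v in counts.items()}
    closure = 100.0 - pct.get(0, 0.0)
    return SelfClosureSummary(probability_by_n_inserted=pct, closure_percentage=closure)


# ---------------------------------------------------------------------------
# Scalar-descriptor statistics
# ---------------------------------------------------------------------------

def circularity_stats(metrics: pd.DataFrame, ddof: int = 0) -> tuple[float, float]:
    """Mean and standard deviation of per-frame circularity.

    The default is the population standard deviation (ddof=0), the usual
    ensemble-statistics convention.
    """
    if len(metrics) == 0:
        raise StatisticsError("empty metrics table")
    c = metrics["circularity"].to_numpy(float)
    return float(c.mean()), float(c.std(ddof=ddof))


def rg_distribution(
    metrics: pd.DataFrame, bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalised histogram of the radius of gyration and its mean.

    Returns ``(edges, probability, mean)``; the probabilities sum to 1.
    """
    if len(metrics) == 0:
        raise StatisticsError("empty metrics table")
    if bin_width <= 0:
        raise StatisticsError("bin width must be positive")
    rg = metrics["rg"].to_numpy(float)
    lo = np.floor(rg.min() / bin_width) * bin_width
    hi = np.ceil(rg.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(rg, bins=nbins, range=(lo, lo + nbins * bin_width))
    return edges, counts / counts.sum(), float(rg.mean())


# ---------------------------------------------------------------------------
# Aggregate summaries
# ---------------------------------------------------------------------------

def summarize(metrics: pd.DataFrame, temperature: float = 300.0) -> dict:
    """Aggregate one ensemble's metrics into a JSON-ready summary document."""
    pop = flip_population(metrics)
    c_mean, c_sd = circularity_stats(metrics)
    _, _, rg_mean = rg_distribution(metrics)
    summary: dict = {
        "temperature_K": temperature,
        "n_frames": int(len(metrics)),
        "flip_population_pct": {str(k): v for k, v in sorted(pop.percentages.items())},
        "circularity_mean": c_mean,
        "circularity_sd": c_sd,
        "rg_mean_A": rg_mean,
    }
    if any(c.startswith("d4_") for c in metrics.columns):
        closure = self_closure_summary(metrics)
        summary["self_closure"] = {
            "probability_by_n_inserted_pct": {
                str(k): v for k, v in sorted(closure.probability_by_n_inserted.items())
            },
            "closure_percentage": closure.closure_percentage,
        }
    else:
        summary["self_closure"] = None  # not applicable without HP groups
    return summary


def temperature_sweep(metrics_by_temperature: Mapping[float, pd.DataFrame]) -> pd.DataFrame:
    """Per-temperature summary table, rows sorted by ascending temperature.

    ``metrics_by_temperature`` maps kelvin to a metrics table (e.g. the
    demultiplexed output of the toy replica-exchange sampler).  Columns:
    temperature, flip percentages for 0/1/2 flips, circularity mean/sd,
    Rg mean, and closure percentage (NaN when no HP groups exist).
    """
    temps = list(metrics_by_temperature)
    if len(temps) < 2:
        raise StatisticsError("temperature sweep needs at least 2 temperatures")
    if len(set(temps)) != len(temps):
        raise StatisticsError("duplicate temperatures in sweep")
    rows = []
    for t in sorted(temps):
        metrics = metrics_by_temperature[t]
        pop = flip_population(metrics)
        c_mean, c_sd = circularity_stats(metrics)
        _, _, rg_mean = rg_distribution(metrics)
        has_hp = any(c.startswith("d4_") for c in metrics.columns)
        closure = self_closure_summary(metrics).closure_percentage if has_hp else np.nan
        rows.append(
            {
                "temperature_K": t,
                "pct_no_flip": pop.percentage(0),
                "pct_one_flip": pop.percentage(1),
                "pct_two_flips": pop.percentage(2),
                "circularity_mean": c_mean,
                "circularity_sd": c_sd,
                "rg_mean_A": rg_mean,
                "closure_pct": closure,
            }
        )
    return pd.DataFrame(rows)
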