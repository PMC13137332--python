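"""Spatial pattern metrics for colony snapshots.

Quantifies the range-expansion patterns the model produces: radial profiles
of detoxifier relative abundance from the inoculum edge to the expansion
frontier, the composition and fine-scale intermixing of the frontier band,
the ratio of instantaneous growth rates between strains, and a rule-based
classifier of the succession pattern (simultaneous vs detoxifier-first vs
consumer-first expansion).

All abundances are count-based (not biomass-weighted), matching how
pixel-fraction quantification of two-color fluorescence images works.  The
intermixing index is the cyclic species-transition density of the frontier
band: band cells are ordered by polar angle around the colony centroid and
the number of species changes between angular neighbours (including the
wrap-around) is divided by the band size, giving 0 for a single-species or
fully demixed band and 1 for perfect alternation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .engine import Snapshot, Trajectory

__all__ = [
    "RadialProfile",
    "FrontierBand",
    "SuccessionPattern",
    "UndefinedRatioError",
    "radial_abundance_profile",
    "frontier_band",
    "frontier_fraction",
    "intermixing_index",
    "growth_rate_ratio",
    "classify_succession",
]

#: default frontier band width: 4 cell diameters (birth diameter = 0.7 length units)
DEFAULT_BAND_WIDTH = 2.8


class SuccessionPattern(str, Enum):
    SIMULTANEOUS = "simultaneous"
    DETOXIFIER_FIRST = "detoxifier_first"
    CONSUMER_FIRST = "consumer_first"


class UndefinedRatioError(ValueError):
    """Growth-rate ratio undefined (non-positive consumer mean); carries the pair."""

    def __init__(self, pair):
        self.pair = pair
        super().__init__(
            f"growth-rate ratio undefined for mean rates {pair}; "
            "use the signed pair instead"
        )


def _cells_frame(snapshot) -> tuple[pd.DataFrame, tuple[float, float], float]:
    if isinstance(snapshot, Snapshot):
        return snapshot.cells, snapshot.centroid, snapshot.inoculum_radius
    raise TypeError("expected a Snapshot")


def _alive(cells: pd.DataFrame) -> pd.DataFrame:
    return cells[cells["alive"]] if "alive" in cells else cells


@dataclass
class RadialProfile:
    """Detoxifier relative abundance in annular bins from inoculum edge outward."""

    bin_centers: np.ndarray
    detox_fraction: np.ndarray  # NaN where a bin holds no cells
    counts: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius": self.bin_centers,
                "detox_fraction": self.detox_fraction,
                "n_cells": self.counts,
            }
        )


@dataclass
class FrontierBand:
    """Cells within ``width`` of the expansion frontier radius."""

    width: float
    cell_ids: np.ndarray
    detox_fraction: float
    intermixing: float


def radial_abundance_profile(snapshot, bin_width: float = 2.0) -> RadialProfile:
    """Per-annulus detoxifier fraction from the inoculum edge to the frontier.

    The centroid is the biomass-weighted centre of the initial inoculum
    (carried on the snapshot); bins of ``bin_width`` start at the inoculum
    radius r0, and cells inside r0 (the original inoculum footprint, not part
    of the expansion zone) are excluded.  Empty bins report NaN abundance and
    a zero count rather than being interpolated.
    """
    cells, centroid, r0 = _cells_frame(snapshot)
    cells = _alive(cells)
    if len(cells) == 0:
        raise ValueError("empty snapshot")
    r_all = np.hypot(cells["x"] - centroid[0], cells["y"] - centroid[1]).to_numpy()
    detox_all = (cells["species"] == "detoxifier").to_numpy()
    outside = r_all >= r0
    r, is_detox = r_all[outside], detox_all[outside]
    if len(r) == 0:
        # colony has not yet expanded past the inoculum edge: one empty bin
        return RadialProfile(
            bin_centers=np.array([r0 + bin_width / 2.0]),
            detox_fraction=np.array([np.nan]),
            counts=np.array([0]),
        )
    R = r.max()
    n_bins = max(1, int(np.ceil(max(R - r0, bin_width) / bin_width)))
    edges = r0 + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    detox_counts = np.bincount(idx, weights=is_detox.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, detox_counts / np.maximum(counts, 1), np.nan)
    centers = edges[:-1] + bin_width / 2.0
    return RadialProfile(bin_centers=centers, detox_fraction=frac, counts=counts)


def _band_mask(cells: pd.DataFrame, centroid, width: float) -> np.ndarray:
    """Members of the frontier band: within ``width`` of the frontier radius."""
    r = np.hypot(
        cells["x"].to_numpy() - centroid[0], cells["y"].to_numpy() - centroid[1]
    )
    return r >= r.max() - width


def frontier_band(snapshot, width: float = DEFAULT_BAND_WIDTH) -> FrontierBand:
    """The outermost annulus of the colony and its composition metrics."""
    cells, centroid, _ = _cells_frame(snapshot)
    cells = _alive(cells)
    if len(cells) == 0:
        raise ValueError("empty snapshot")
    band = cells[_band_mask(cells, centroid, width)]
    frac = float((band["species"] == "detoxifier").mean())
    mix = _intermixing_of_band(band, centroid) if len(band) >= 2 else 0.0
    return FrontierBand(
        width=width,
        cell_ids=band["cell_id"].to_numpy(),
        detox_fraction=frac,
        intermixing=mix,
    )


def frontier_fraction(snapshot, width: float = DEFAULT_BAND_WIDTH) -> float:
    """Detoxifier share among cells within ``width`` of the frontier radius."""
    band = frontier_band(snapshot, width)
    if len(band.cell_ids) == 0:
        raise ValueError("no cells in the frontier band")
    return band.detox_fraction


def _intermixing_of_band(band: pd.DataFrame, centroid) -> float:
    angles = np.arctan2(
        band["y"].to_numpy() - centroid[1], band["x"].to_numpy() - centroid[0]
    )
    order = np.argsort(angles, kind="stable")
    labels = (band["species"].to_numpy() == "detoxifier")[order]
    if labels.all() or not labels.any():
        return 0.0
    transitions = int(np.sum(labels != np.roll(labels, 1)))
    return transitions / len(labels)


def intermixing_index(snapshot, width: float = DEFAULT_BAND_WIDTH) -> float:
    """Cyclic species-transition density along the frontier band, in [0, 1].

    Label-symmetric; 0 for a single-species band, 1 for perfect alternation.
    Requires at least two band cells.
    """
    cells, centroid, _ = _cells_frame(snapshot)
    cells = _alive(cells)
    if len(cells) == 0:
        raise ValueError("empty snapshot")
    band = cells[_band_mask(cells, centroid, width)]
    if len(band) < 2:
        raise ValueError("intermixing index needs at least 2 cells in the band")
    return _intermixing_of_band(band, centroid)


def growth_rate_ratio(snapshot) -> float:
    """Mean detoxifier growth rate divided by mean consumer growth rate.

    Raises :class:`UndefinedRatioError` (carrying the signed pair) when the
    consumer mean is not positive, and ``ValueError`` when a species is
    absent.
    """
    cells, _, _ = _cells_frame(snapshot)
    cells = _alive(cells)
    for name in ("detoxifier", "consumer"):
        if not (cells["species"] == name).any():
            raise ValueError(f"species absent from snapshot: {name}")
    g_det = float(cells.loc[cells["species"] == "detoxifier", "growth_rate"].mean())
    g_con = float(cells.loc[cells["species"] == "consumer", "growth_rate"].mean())
    if g_con <= 0:
        raise UndefinedRatioError((g_det, g_con))
    return g_det / g_con


def inoculum_edge_fraction(snapshot, bin_width: float = 2.0) -> float:
    """Detoxifier fraction in the first occupied radial bin at the inoculum edge."""
    prof = radial_abundance_profile(snapshot, bin_width=bin_width)
    occ = prof.occupied
    if not occ.any():
        raise ValueError("no occupied radial bins")
    return float(prof.detox_fraction[occ][0])


def classify_succession(
    trajectory: Trajectory,
    band_width: float = DEFAULT_BAND_WIDTH,
    rise_threshold: float = 0.15,
    high_level: float = 0.65,
    sustained_fraction: float = 0.2,
) -> SuccessionPattern:
    """Classify the expansion pattern of a finished run.

    ``detoxifier_first`` requires both (a) the final frontier detoxifier
    fraction to exceed the lowest well-populated bin of the final radial
    profile by more than ``rise_threshold`` — the profile rises toward the
    frontier, the spatial signature of succession; a colony that is
    detoxifier-rich at *every* radius (dominance from the start, e.g. from
    a plain growth-rate advantage) shows no rise and is not a succession —
    and (b) the frontier fraction to have exceeded ``high_level`` in at
    least ``sustained_fraction`` of the expansion-phase snapshots.
    ``consumer_first`` is the mirror-image rule (fall from the highest bin,
    sustained below ``1 - high_level``); anything else is ``simultaneous``.
    Invariant to uniform rescaling of snapshot times.

    A toxic substrate can impose a long pre-expansion lag during which the
    colony detoxifies its surroundings without advancing; the sustained
    criterion (b) is therefore evaluated from the snapshot where the
    frontier first moves past the inoculum edge by one band width (from the
    first snapshot, if it never does), since the claim under test concerns
    the pattern of the range expansion itself.
    """
    snaps = trajectory.snapshots
    if len(snaps) < 5:
        raise ValueError("classification needs a trajectory with >= 5 snapshots")
    radii = np.array([s.frontier_radius for s in snaps])
    r0 = snaps[-1].inoculum_radius
    moving = radii > r0 + band_width
    start = int(np.argmax(moving)) if moving.any() else 0
    if len(snaps) - start < 2:
        start = 0
    series = np.array([frontier_fraction(s, band_width) for s in snaps[start:]])
    final_frontier = series[-1]

    prof = radial_abundance_profile(snaps[-1])
    dense = prof.counts >= 25  # sparse bins are too noisy to anchor the rise
    if not dense.any():
        dense = prof.occupied
    lo_bin = float(np.nanmin(prof.detox_fraction[dense]))
    hi_bin = float(np.nanmax(prof.detox_fraction[dense]))

    high = float(np.mean(series > high_level))
    low = float(np.mean(series < 1.0 - high_level))
    if final_frontier - lo_bin > rise_threshold and high >= sustained_fraction:
        return SuccessionPattern.DETOXIFIER_FIRST
    if hi_bin - final_frontier > rise_threshold and low >= sustained_fraction:
        return SuccessionPattern.CONSUMER_FIRST
    return SuccessionPattern.SIMULTANEOUS


def trajectory_metrics(
    trajectory: Trajectory, band_width: float = DEFAULT_BAND_WIDTH
) -> pd.DataFrame:
    """Per-snapshot metric table (time, frontier fraction, intermixing, ratio)."""
    rows = []
    for snap in trajectory.snapshots:
        row = {"time": snap.time, "frontier_radius": snap.frontier_radius}
        try:
            row["frontier_fraction"] = frontier_fraction(snap, band_width)
        except ValueError:
            row["frontier_fraction"] = np.nan
        try:
            row["intermixing_index"] = intermixing_index(snap, band_width)
        except ValueError:
            row["intermixing_index"] = np.nan
        try:
            row["growth_rate_ratio"] = growth_rate_ratio(snap)
        except (UndefinedRatioError, ValueError):
            row["growth_rate_ratio"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
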