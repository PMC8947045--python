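"""Fixed-grid attenuation histograms of the vertebral bone-marrow space.

Marrow attenuation samples (Hounsfield units, HU) are binned on a fixed
5 HU grid anchored at integer multiples of 5, so every bin center ends in
.5 (e.g. -212.5).  Values below -1000 HU arise from calcium suppression of
densely calcified structures (cortical bone, bone islands) that contain no
marrow; they are excluded from the histogram mass but their count is kept.

Normalization "to a standard volume" is implemented as unit total mass:
any constant standard volume is a scalar relabeling of the ordinate that
cancels in every downstream statistic (overlap, quantiles), so the physical
volume is retained only as metadata.

The consistency statistic between two unit-mass histograms is the histogram
intersection sum_i min(h1_i, h2_i), which equals 1 - L1/2 and is 1 exactly
for identical histograms and 0 for disjoint supports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BIN_WIDTH = 5.0
LOWER_CUTOFF = -1000.0

__all__ = [
    "AttenuationHistogram",
    "HistogramSummary",
    "compute_histogram",
    "normalize",
    "overlap",
    "average_histograms",
    "histogram_statistics",
    "save_histogram",
    "load_histogram",
    "BIN_WIDTH",
    "LOWER_CUTOFF",
]


@dataclass(frozen=True)
class HistogramSummary:
    """Bin-center quantile summary of a marrow attenuation histogram.

    Quantiles are reported as the center of the first bin in which the
    cumulative mass reaches the requested fraction; no within-bin
    interpolation is performed, so every value ends in .5 on the 5 HU grid.
    ``mode`` is the center of the maximal bin (ties broken toward lower HU).
    """

    median: float
    q1: float
    q3: float
    p95: float
    mode: float

    def as_dict(self) -> dict[str, float]:
        return {
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "p95": self.p95,
            "mode": self.mode,
        }


@dataclass
class AttenuationHistogram:
    """Attenuation histogram on the fixed 5 HU grid.

    Attributes
    ----------
    bin_edges:
        Monotone edges at integer multiples of the bin width; bins are
        half-open ``[lower, upper)``.
    counts:
        Per-bin counts (raw state) or masses (unit-mass state).
    excluded:
        Number of input values below the lower cutoff; never part of the
        histogram mass.
    volume_mm3:
        Physical volume of the sampled voxels (metadata only).
    normalized:
        True once the counts have been scaled to unit total mass.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    excluded: int = 0
    volume_mm3: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("bin_edges and counts must be 1-D")
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        widths = np.diff(self.bin_edges)
        if self.counts.size and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("negative bin counts")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def is_empty(self) -> bool:
        return self.total == 0.0


def compute_histogram(
    sample: Sequence[float] | np.ndarray,
    lower_cutoff: float = LOWER_CUTOFF,
    bin_width: float = BIN_WIDTH,
    volume_mm3: float = 0.0,
) -> AttenuationHistogram:
    """Bin a marrow attenuation sample onto the fixed HU grid.

    Values strictly below ``lower_cutoff`` are counted in ``excluded`` only
    (the cutoff itself is included).  Each remaining value lands in the
    half-open bin ``[k*w, (k+1)*w)`` that contains it.  An empty sample
    yields an all-zero histogram, not an error.
    """
    values = np.asarray(sample, dtype=float).ravel()
    if values.size and not np.all(np.isfinite(values)):
        raise ValueError("attenuation sample contains non-finite values")
    excluded = int(np.count_nonzero(values < lower_cutoff))
    kept = values[values >= lower_cutoff]
    if kept.size == 0:
        edges = np.array([0.0, bin_width])
        return AttenuationHistogram(edges, np.zeros(1), excluded, volume_mm3)
    k = np.floor(kept / bin_width).astype(np.int64)
    lo, hi = int(k.min()), int(k.max())
    counts = np.bincount(k - lo, minlength=hi - lo + 1).astype(float)
    edges = np.arange(lo, hi + 2, dtype=float) * bin_width
    return AttenuationHistogram(edges, counts, excluded, volume_mm3)


def normalize(h: AttenuationHistogram) -> AttenuationHistogram:
    """Scale counts to unit total mass (idempotent).

    The excluded count never participates in the mass; an all-zero
    histogram cannot be normalized.
    """
    total = h.total
    if total <= 0:
        raise ValueError("cannot normalize an all-zero histogram")
    if h.normalized and abs(total - 1.0) < 1e-9:
        return replace(h, counts=h.counts.copy())
    return replace(h, counts=h.counts / total, normalized=True)


def _align(hs: Sequence[AttenuationHistogram]) -> tuple[np.ndarray, np.ndarray]:
    """Place histograms on a common grid, zero-padding missing support.

    Returns (edges, stacked counts) where rows follow the input order.
    Grids must share the bin width and the multiples-of-width anchor.
    """
    width = hs[0].bin_width
    for h in hs[1:]:
        if not np.isclose(h.bin_width, width):
            raise ValueError("histograms have different bin widths")
    ks = [np.rint(h.bin_edges[0] / width).astype(int) for h in hs]
    for h, k in zip(hs, ks):
        if not np.isclose(h.bin_edges[0], k * width):
            raise ValueError("bin grid is not anchored at multiples of the width")
    lo = min(int(k) for k in ks)
    hi = max(int(k) + h.counts.size for k, h in zip(ks, hs))
    stacked = np.zeros((len(hs), hi - lo))
    for row, (h, k) in enumerate(zip(hs, ks)):
        start = int(k) - lo
        stacked[row, start : start + h.counts.size] = h.counts
    edges = np.arange(lo, hi + 1, dtype=float) * width
    return edges, stacked


def overlap(h1: AttenuationHistogram, h2: AttenuationHistogram) -> float:
    """Histogram intersection sum_i min(h1_i, h2_i) of two unit-mass histograms.

    Both inputs must already be normalized; silently renormalizing here
    would hide volume bookkeeping errors upstream, so raw input is rejected.
    """
    for h in (h1, h2):
        if not h.normalized:
            raise ValueError("overlap requires unit-mass histograms; call normalize() first")
    _, stacked = _align([h1, h2])
    return float(np.minimum(stacked[0], stacked[1]).sum())


def average_histograms(hs: Iterable[AttenuationHistogram]) -> AttenuationHistogram:
    """Equal-weight per-bin mean of unit-mass histograms (order-invariant)."""
    hs = list(hs)
    if not hs:
        raise ValueError("cannot average an empty list of histograms")
    for h in hs:
        if not h.normalized:
            raise ValueError("average requires unit-mass histograms")
    edges, stacked = _align(hs)
    mean = stacked.mean(axis=0)
    return AttenuationHistogram(
        edges,
        mean,
        excluded=sum(h.excluded for h in hs),
        volume_mm3=float(sum(h.volume_mm3 for h in hs)),
        normalized=True,
    )


def histogram_statistics(h: AttenuationHistogram) -> HistogramSummary:
    """Median, quartiles, 95th percentile and mode location of a histogram.

    Quantile q is the center of the first bin where the cumulative mass
    reaches >= q.  Works on raw or unit-mass histograms with positive total.
    """
    total = h.total
    if total <= 0:
        raise ValueError("cannot summarize an empty histogram")
    mass = h.counts / total
    cum = np.cumsum(mass)
    centers = h.centers

    def quantile(q: float) -> float:
        idx = int(np.searchsorted(cum, q - 1e-12, side="left"))
        return float(centers[min(idx, centers.size - 1)])

    mode = float(centers[int(np.argmax(h.counts))])  # argmax ties -> lower HU
    return HistogramSummary(
        median=quantile(0.5),
        q1=quantile(0.25),
        q3=quantile(0.75),
        p95=quantile(0.95),
        mode=mode,
    )


def save_histogram(h: AttenuationHistogram, csv_path: str | Path) -> Path:
    """Write bins to CSV and metadata to a JSON sidecar next to it."""
    csv_path = Path(csv_path)
    lines = ["bin_lower,bin_upper,mass"]
    for lo, up, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
        lines.append(f"{lo:.1f},{up:.1f},{float(c)!r}")
    csv_path.write_text("\n".join(lines) + "\n")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "excluded": h.excluded,
                "volume_mm3": h.volume_mm3,
                "normalized": h.normalized,
                "bin_width": h.bin_width,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return csv_path


def load_histogram(csv_path: str | Path) -> AttenuationHistogram:
    """Read a histogram written by :func:`save_histogram`."""
    csv_path = Path(csv_path)
    rows = csv_path.read_text().strip().splitlines()[1:]
    lowers, uppers, masses = [], [], []
    for row in rows:
        lo, up, c = row.split(",")
        lowers.append(float(lo))
        uppers.append(float(up))
        masses.append(float(c))
    edges = np.array(lowers + [uppers[-1]])
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return AttenuationHistogram(
        edges,
        np.array(masses),
        excluded=int(meta["excluded"]),
        volume_mm3=float(meta["volume_mm3"]),
        normalized=bool(meta["normalized"]),
    )
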