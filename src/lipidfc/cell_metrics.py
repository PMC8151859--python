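"""Cell-count and cell-size summaries from automated-counter histograms.

The counter reports binned diameters (e.g. 3.1 million cells between 4 and
9 µm).  The mean diameter of a flask is the count-weighted mean of the bin
centers, a bin center being the arithmetic midpoint of its edges (the 4–9 µm
bin contributes 6.5 µm).  Variability across culture replicates is the
standard error of the mean.  Drug-induced mortality is summarized as the
percent reduction of the mean treated cell count relative to the matched
vehicle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SizeHistogram",
    "weighted_mean_diameter",
    "replicate_sem",
    "cell_number_reduction",
    "size_summary",
]


@dataclass(frozen=True)
class SizeHistogram:
    """Binned cell-diameter counts for one flask.

    ``bins`` are (lower µm, upper µm, count) triples; bins must be
    non-overlapping with lower < upper and counts >= 0.  Open-ended top bins
    are not accepted.
    """

    flask_id: str
    bins: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        ordered = sorted(self.bins)
        for lo, hi, n in ordered:
            if not lo < hi:
                raise ValueError(f"{self.flask_id}: bin [{lo}, {hi}) needs lower < upper")
            if n < 0:
                raise ValueError(f"{self.flask_id}: negative count in bin [{lo}, {hi})")
        for (_, hi_a, _), (lo_b, _, _) in zip(ordered, ordered[1:]):
            if lo_b < hi_a:
                raise ValueError(f"{self.flask_id}: overlapping bins")
        object.__setattr__(self, "bins", tuple(ordered))

    @property
    def total_count(self) -> float:
        return sum(n for _, _, n in self.bins)


def weighted_mean_diameter(histogram: SizeHistogram) -> float:
    """Count-weighted mean of bin centers, in µm.

    center_i = (lower_i + upper_i)/2; mean = Σ center_i n_i / Σ n_i.
    """
    total = histogram.total_count
    if total <= 0:
        raise ValueError(f"{histogram.flask_id}: histogram has no cells")
    return sum((lo + hi) / 2 * n for lo, hi, n in histogram.bins) / total


def replicate_sem(values: Sequence[float]) -> float:
    """Standard error of the mean across culture replicates: sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM needs at least 2 replicates")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def cell_number_reduction(treated_counts: Sequence[float],
                          vehicle_counts: Sequence[float]) -> float:
    """Percent reduction in cell number: 100 × (1 − mean treated / mean vehicle)."""
    t = float(np.mean(np.asarray(treated_counts, dtype=float)))
    v = float(np.mean(np.asarray(vehicle_counts, dtype=float)))
    if v <= 0:
        raise ValueError("vehicle mean cell count must be > 0")
    return 100.0 * (1.0 - t / v)


def size_summary(histograms: Sequence[SizeHistogram],
                 groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-flask weighted mean diameter, optionally with group mean and SEM.

    ``groups`` maps flask_id → group label (e.g. "SNU449/DOX").  Returns a
    per-flask table; when groups are given, columns ``group_mean`` and
    ``group_sem`` are attached per flask's group.
    """
    rows = [dict(flask_id=h.flask_id, mean_diameter_um=weighted_mean_diameter(h),
                 total_cells=h.total_count) for h in histograms]
    out = pd.DataFrame(rows).set_index("flask_id")
    if groups is not None:
        out["group"] = groups.reindex(out.index)
        g = out.groupby("group")["mean_diameter_um"]
        out["group_mean"] = out["group"].map(g.mean())
        out["group_sem"] = out["group"].map(g.apply(lambda v: replicate_sem(v.to_numpy())))
    return out.reset_index()
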