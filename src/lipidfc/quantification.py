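"""Per-cell normalization, lipid-family aggregation and QC-pool dispersion flags.

Peak areas are divided by the number of cells extracted from each flask, so
all downstream fold changes compare per-cell lipid amounts and are invariant
to a global rescaling of the counts.  Family-level signal is the sum of the
normalized signal over the member species of each family.  Censored (missing)
member values contribute 0 to a family sum computed before imputation; sums
are dominated by detected members and the censored imputation is defined per
lipid, not per family — run imputation first if the alternative is wanted.
QC-pool injections monitor instrument stability; features whose coefficient
of variation across QC injections exceeds a threshold are flagged, advisory
only.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_by_cells",
    "rank1_family_map",
    "family_sum",
    "family_censored_counts",
    "qc_dispersion_flags",
]


def normalize_by_cells(areas: pd.DataFrame, cell_counts: pd.Series) -> pd.DataFrame:
    """Divide each sample column by that sample's extracted cell count.

    ``areas`` is lipid × sample; missing (censored) values stay missing.
    Raises if any sample lacks a positive cell count, naming the sample.
    """
    for sample in areas.columns:
        if sample not in cell_counts.index or pd.isna(cell_counts[sample]):
            raise ValueError(f"no cell count for sample {sample!r}")
        if cell_counts[sample] <= 0:
            raise ValueError(f"non-positive cell count for sample {sample!r}")
    return areas.div(cell_counts[areas.columns], axis=1)


def rank1_family_map(annotations: pd.DataFrame) -> pd.Series:
    """feature_id → family from rank-1 annotations.

    Rejects a feature annotated to two distinct families at rank 1.
    """
    r1 = annotations[annotations["rank"] == 1]
    fams = r1.groupby("feature_id")["family"].unique()
    bad = fams[fams.str.len() > 1]
    if len(bad):
        fid = bad.index[0]
        raise ValueError(
            f"feature {fid!r} maps to multiple families at rank 1: "
            f"{sorted(bad.iloc[0])}"
        )
    return fams.str[0]


def family_sum(normalized: pd.DataFrame, family_map: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Sum normalized signal over the member features of each family.

    Features absent from ``family_map`` (unannotated) are excluded.  Missing
    member values contribute 0; use :func:`family_censored_counts` to record
    how many were censored per cell.
    """
    fmap = pd.Series(dict(family_map)) if not isinstance(family_map, pd.Series) else family_map
    members = normalized.loc[normalized.index.intersection(fmap.index)]
    return members.fillna(0.0).groupby(fmap.loc[members.index]).sum()


def family_censored_counts(normalized: pd.DataFrame,
                           family_map: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Per family × sample, the number of censored member values."""
    fmap = pd.Series(dict(family_map)) if not isinstance(family_map, pd.Series) else family_map
    members = normalized.loc[normalized.index.intersection(fmap.index)]
    return members.isna().astype(int).groupby(fmap.loc[members.index]).sum()


def qc_dispersion_flags(
    normalized: pd.DataFrame,
    qc_sample_ids: Sequence[str],
    cv_threshold: float = 0.30,
) -> pd.Series:
    """Flag features whose QC-injection coefficient of variation exceeds a threshold.

    Returns a per-feature Series: ``True``/``False`` flags, or the string
    ``"not evaluated"`` for every feature when fewer than 3 QC injections are
    available.  Flags are advisory; nothing is excluded.
    """
    qc = [s for s in qc_sample_ids if s in normalized.columns]
    if len(qc) < 3:
        return pd.Series("not evaluated", index=normalized.index, name="qc_flag")
    vals = normalized[qc]
    cv = vals.std(axis=1, ddof=1) / vals.mean(axis=1)
    return pd.Series(cv > cv_threshold, index=normalized.index, name="qc_flag")
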