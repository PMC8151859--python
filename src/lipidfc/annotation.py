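"""Feature annotation: m/z matching at ppm tolerance, MS2 acyl assignment, FA isomers.

A feature (an m/z–retention-time peak with per-sample areas) is matched
against every (species, adduct) row of the theoretical library whose m/z lies
within the ppm gate.  All in-tolerance candidates are retained, ranked by
|ppm| (rank 1 = smallest deviance); downstream stages use rank 1.  The ppm
sign convention is ``1e6 × (observed − theoretical) / theoretical``.

Where MS2 spectra are available, diacyl glycerophospholipid annotations at
sum-composition resolution are refined to an acyl combination by looking for
the two fatty-acyl carboxylate anions ``[FA−H]−`` among the fragments; the
chain pair whose fragments carry the highest summed intensity wins, reported
unordered (no sn-position claim).  Free fatty acid isomers that co-elute in
separate peaks are labelled by an abundance prior: the most abundant peak of
a composition receives the canonical mammalian isomer (e.g. the dominant
FA(18:1) is oleic acid, FA(18:1n-9)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lipid_library import (
    LipidSpecies,
    PROTON_MASS,
    fatty_acid_formula,
    monoisotopic_mass,
)

__all__ = [
    "MS2Spectrum",
    "match_features",
    "unannotated_features",
    "assign_acyl_combination",
    "assign_isomer",
    "ISOMER_PRIORS",
    "DIACYL_GPL_FAMILIES",
]

DIACYL_GPL_FAMILIES = ("PC", "PE", "PG", "PI", "PS")

#: canonical mammalian isomer for the most abundant peak of a composition
ISOMER_PRIORS: dict[tuple[int, int], str] = {
    (18, 1): "n-9",   # oleic
    (18, 2): "n-6",   # linoleic
    (20, 3): "n-6",   # dihomo-gamma-linolenic
    (20, 4): "n-6",   # arachidonic
    (20, 5): "n-3",   # eicosapentaenoic
    (22, 6): "n-3",   # docosahexaenoic
}


@dataclass(frozen=True)
class MS2Spectrum:
    """Fragment list of one precursor feature."""

    precursor_id: str
    fragment_mz: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self):
        if len(self.fragment_mz) != len(self.intensity):
            raise ValueError("fragment_mz and intensity must have equal length")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be >= 0")


def match_features(
    features: pd.DataFrame,
    library: pd.DataFrame,
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Match observed features to library (species, adduct) rows within ``tol_ppm``.

    Parameters
    ----------
    features
        Must carry columns ``feature_id, mz, polarity``.
    library
        As produced by :func:`lipidfc.lipid_library.build_library`.
    tol_ppm
        Maximum absolute m/z deviance accepted, in parts per million.

    Returns
    -------
    DataFrame with one row per accepted candidate:
    ``feature_id, shorthand, family, adduct, ppm, rank, resolution`` where
    rank 1 has the smallest |ppm| for that feature.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    rows = []
    for pol, feats in features.groupby("polarity"):
        lib = library[library["polarity"] == pol]
        if lib.empty:
            continue
        lib = lib.sort_values("mz").reset_index(drop=True)
        theo = lib["mz"].to_numpy()
        obs = feats["mz"].to_numpy()
        # |obs - theo| / theo <= tol  <=>  theo in [obs/(1+tol), obs/(1-tol)]
        lo = np.searchsorted(theo, obs / (1 + tol_ppm * 1e-6), side="left")
        hi = np.searchsorted(theo, obs / (1 - tol_ppm * 1e-6), side="right")
        for (_, feat), i0, i1 in zip(feats.iterrows(), lo, hi):
            for j in range(i0, i1):
                ppm = 1e6 * (feat["mz"] - theo[j]) / theo[j]
                if abs(ppm) <= tol_ppm:
                    rows.append(
                        dict(feature_id=feat["feature_id"],
                             shorthand=lib.at[j, "shorthand"],
                             family=lib.at[j, "family"],
                             adduct=lib.at[j, "adduct"],
                             ppm=ppm)
                    )
    ann = pd.DataFrame(rows, columns=["feature_id", "shorthand", "family",
                                      "adduct", "ppm"])
    if not ann.empty:
        ann["rank"] = (
            ann["ppm"].abs().groupby(ann["feature_id"]).rank(method="first")
            .astype(int)
        )
        ann = ann.sort_values(["feature_id", "rank"]).reset_index(drop=True)
    else:
        ann["rank"] = pd.Series(dtype=int)
    ann["resolution"] = "sum-composition"
    return ann


def unannotated_features(features: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Features with no in-tolerance library candidate."""
    matched = set(annotations["feature_id"]) if not annotations.empty else set()
    return features[~features["feature_id"].isin(matched)].copy()


def _carboxylate_mz(carbons: int, double_bonds: int) -> float:
    """[FA−H]− anion m/z of an acyl chain."""
    return monoisotopic_mass(fatty_acid_formula(carbons, double_bonds)) - PROTON_MASS


def _candidate_pairs(total_c: int, total_d: int,
                     c_range=(10, 26), d_max=6) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    pairs = []
    for c1 in range(c_range[0], min(c_range[1], total_c - c_range[0]) + 1):
        c2 = total_c - c1
        if not (c_range[0] <= c2 <= c_range[1]):
            continue
        for d1 in range(0, min(d_max, total_d) + 1):
            d2 = total_d - d1
            if not (0 <= d2 <= d_max):
                continue
            a, b = sorted([(c1, d1), (c2, d2)])
            if (a, b) not in pairs:
                pairs.append((a, b))
    return pairs


def assign_acyl_combination(
    species: LipidSpecies,
    ms2: MS2Spectrum,
    frag_tol_ppm: float = 15.0,
) -> tuple[str, str] | None:
    """Resolve a sum-composition diacyl GPL to its main acyl pair from MS2.

    For every chain pair summing to the annotated carbons/double bonds, the
    two carboxylate anion m/z are predicted; a pair is a candidate only if
    both fragments are observed within ``frag_tol_ppm``.  Among candidates,
    the pair with the highest summed matched intensity wins.  Returns the
    unordered pair as shorthand strings, or ``None`` ("unresolved") if no
    pair has both fragments.
    """
    if species.family not in DIACYL_GPL_FAMILIES:
        raise ValueError(
            f"acyl assignment applies to diacyl glycerophospholipids, "
            f"not {species.family}"
        )
    frag_mz = np.asarray(ms2.fragment_mz, dtype=float)
    frag_int = np.asarray(ms2.intensity, dtype=float)
    if frag_mz.size == 0:
        return None

    def matched_intensity(mz: float) -> float | None:
        dev = np.abs(frag_mz - mz) / mz * 1e6
        hits = dev <= frag_tol_ppm
        if not hits.any():
            return None
        return float(frag_int[hits].max())

    best, best_score = None, -np.inf
    for (c1, d1), (c2, d2) in _candidate_pairs(
        species.total_carbons, species.total_double_bonds
    ):
        i1 = matched_intensity(_carboxylate_mz(c1, d1))
        i2 = matched_intensity(_carboxylate_mz(c2, d2))
        if i1 is None or i2 is None:
            continue
        score = i1 + i2
        if score > best_score:
            best, best_score = (f"{c1}:{d1}", f"{c2}:{d2}"), score
    return best


def assign_isomer(
    fa_features: Sequence[tuple[str, float]],
    carbons: int,
    double_bonds: int,
) -> dict[str, str]:
    """Label chromatographically separated FA isomer peaks by abundance prior.

    Parameters
    ----------
    fa_features
        ``(feature_id, mean_area)`` pairs sharing the same carbons and double
        bonds.
    carbons, double_bonds
        The shared sum composition.

    Returns
    -------
    feature_id → shorthand.  The most abundant feature receives the prior
    isomer label (e.g. ``FA(18:1n-9)``) when the composition is in the prior
    table; all others (and every feature of an unlisted composition) keep the
    sum-composition name.
    """
    if len(fa_features) == 0:
        raise ValueError("empty isomer group")
    base = f"FA({carbons}:{double_bonds})"
    labels = {fid: base for fid, _ in fa_features}
    prior = ISOMER_PRIORS.get((carbons, double_bonds))
    if prior is not None:
        top = max(fa_features, key=lambda t: t[1])[0]
        labels[top] = f"FA({carbons}:{double_bonds}{prior})"
    return labels
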