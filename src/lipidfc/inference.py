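"""Left-censored imputation and bootstrap log-fold-change estimation.

For each (cell line, drug) the treated group is compared against its
DMSO-matched vehicle group.  Per lipid:

* values under the limit of detection (LOD) are left-censored.  Comparisons
  where any group has more than one censored value are discarded.
* a single censored value per group is imputed by fitting a normal
  distribution to the detected peak areas of that lipid within the comparison
  and drawing from it truncated below the minimum detected signal (and above
  zero).  The normal is fitted on raw (not log) areas; truncation to the
  positive axis absorbs any mass below zero.
* the log fold change is ln(mean treated / mean vehicle).  Its sampling
  distribution is estimated by B bootstrap resamples (default 10,000), each
  resampling both groups with replacement at their own sizes.  The central
  value is the mean of the resampled statistics and the confidence interval
  is their 2.5th and 97.5th percentiles.

Imputation happens once per comparison, before bootstrapping; re-drawing the
imputed values inside every bootstrap iteration (which propagates imputation
uncertainty into the interval) is available via ``impute_per_draw``.

No p-values are computed anywhere: effects are reported as interval
estimates only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantification import family_censored_counts, family_sum

__all__ = [
    "CensoringFit",
    "FoldChangeResult",
    "censor_discard_rule",
    "fit_censoring_model",
    "impute_censored",
    "bootstrap_log_fc",
    "run_comparisons",
]


@dataclass(frozen=True)
class CensoringFit:
    """Normal fit to a lipid's detected areas, with its detection limit."""

    mean: float
    sd: float
    lod: float
    n_detected: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class FoldChangeResult:
    """Bootstrap log-fold-change estimate for one lipid or family."""

    name: str
    level: str  # 'species' | 'family'
    central: float | None
    ci_low: float | None
    ci_high: float | None
    B: int
    censored_treated: int
    censored_control: int
    status: str  # 'estimated' | 'discarded'


def censor_discard_rule(censored_counts_per_group: Iterable[int]) -> bool:
    """Keep a comparison only if every group has at most one censored value."""
    counts = list(censored_counts_per_group)
    if any(c < 0 for c in counts):
        raise ValueError("censored counts must be >= 0")
    return all(c <= 1 for c in counts)


def fit_censoring_model(values: Sequence[float],
                        detected: Sequence[bool] | None = None) -> CensoringFit:
    """Fit the imputation normal to the detected values of one lipid.

    ``detected`` defaults to the non-missing mask of ``values``.  The mean
    and SD are the sample moments of the detected values; the detection limit
    is their minimum.
    """
    v = np.asarray(values, dtype=float)
    det = ~np.isnan(v) if detected is None else np.asarray(detected, dtype=bool)
    d = v[det]
    if d.size < 2:
        raise ValueError("need at least 2 detected values to fit the censoring model")
    return CensoringFit(mean=float(d.mean()), sd=float(d.std(ddof=1)),
                        lod=float(d.min()), n_detected=int(d.size))


def impute_censored(fit: CensoringFit, n_missing: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw imputed values from the fitted normal truncated to (0, LOD)."""
    if n_missing < 1:
        raise ValueError("n_missing must be >= 1")
    if fit.lod <= 0:
        raise ValueError("detection limit must be > 0")
    if fit.sd == 0:
        # degenerate fit: all detected values equal; collapse to the mean
        val = min(fit.mean, np.nextafter(fit.lod, 0.0))
        return np.full(n_missing, max(val, np.nextafter(0.0, 1.0)))
    a = (0.0 - fit.mean) / fit.sd
    b = (fit.lod - fit.mean) / fit.sd
    draws = stats.truncnorm.rvs(a, b, loc=fit.mean, scale=fit.sd,
                                size=n_missing, random_state=rng)
    return np.asarray(draws)


def bootstrap_log_fc(
    treated: Sequence[float],
    control: Sequence[float],
    B: int = 10_000,
    rng: np.random.Generator | None = None,
    percentiles: tuple[float, float] = (2.5, 97.5),
    name: str = "",
    level: str = "species",
) -> FoldChangeResult:
    """Percentile-bootstrap estimate of ln(mean treated / mean control).

    Each of the B resamples draws both groups with replacement at their own
    sizes and recomputes the statistic; the central value is the mean of the
    resamples and the interval their ``percentiles``.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.any(t <= 0) or np.any(c <= 0) or np.any(np.isnan(t)) or np.any(np.isnan(c)):
        raise ValueError("log fold change requires strictly positive, complete groups")
    if rng is None:
        rng = np.random.default_rng()
    mt = t[rng.integers(0, t.size, size=(B, t.size))].mean(axis=1)
    mc = c[rng.integers(0, c.size, size=(B, c.size))].mean(axis=1)
    draws = np.log(mt / mc)
    lo, hi = np.percentile(draws, percentiles)
    return FoldChangeResult(name=name, level=level, central=float(draws.mean()),
                            ci_low=float(lo), ci_high=float(hi), B=B,
                            censored_treated=0, censored_control=0,
                            status="estimated")


def _comparison_groups(metadata: pd.DataFrame) -> list[dict]:
    """Enumerate (cell line, drug) treated-vs-vehicle comparisons."""
    comps = []
    study = metadata[~metadata["treatment"].isin(["QC-pool"])]
    drugs = sorted(set(study["treatment"]) - {"untreated"}
                   - {t for t in study["treatment"] if t.startswith("vehicle-")})
    for line in sorted(study["cell_line"].unique()):
        sub = study[study["cell_line"] == line]
        for drug in drugs:
            treated = sub.index[sub["treatment"] == drug].tolist()
            control = sub.index[sub["treatment"] == f"vehicle-{drug}"].tolist()
            if not treated:
                continue
            if len(control) < 2 or len(treated) < 2:
                raise ValueError(
                    f"treatment group {line}/{drug} lacks a matched vehicle "
                    f"group of size >= 2"
                )
            comps.append(dict(cell_line=line, drug=drug,
                              treated=treated, control=control))
    return comps


def _impute_comparison(values: pd.Series, treated: list, control: list,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int, int] | None:
    """Apply the discard rule and impute at most one censored value per group.

    Returns (treated values, control values, n censored treated, n censored
    control), or None when the comparison is discarded.
    """
    tv = values[treated].to_numpy(dtype=float)
    cv = values[control].to_numpy(dtype=float)
    n_ct, n_cc = int(np.isnan(tv).sum()), int(np.isnan(cv).sum())
    if not censor_discard_rule([n_ct, n_cc]):
        return None
    if n_ct or n_cc:
        fit = fit_censoring_model(np.concatenate([tv, cv]))
        if n_ct:
            tv[np.isnan(tv)] = impute_censored(fit, n_ct, rng)
        if n_cc:
            cv[np.isnan(cv)] = impute_censored(fit, n_cc, rng)
    return tv, cv, n_ct, n_cc


def run_comparisons(
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
    family_map: Mapping[str, str] | pd.Series | None = None,
    B: int = 10_000,
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
    levels: tuple[str, ...] = ("species", "family"),
    impute_per_draw: bool = False,
    impute_members: bool = True,
) -> pd.DataFrame:
    """Bootstrap log fold changes for every (cell line, drug) vs matched vehicle.

    Parameters
    ----------
    normalized
        Lipid × sample matrix of per-cell normalized signal, NaN = censored.
    metadata
        Indexed by sample id with columns ``cell_line`` and ``treatment``
        (treatments: drug labels, ``vehicle-<drug>``, ``untreated``,
        ``QC-pool``).
    family_map
        lipid → family; required for the family level.
    impute_per_draw
        Re-draw imputed values inside each bootstrap iteration instead of
        once per comparison (propagates imputation uncertainty).
    impute_members
        Impute censored member values before family summation (default).
        With ``False`` censored members contribute 0 to family sums.

    Returns
    -------
    Long DataFrame: cell_line, drug, level, name, central, ci_low, ci_high,
    B, censored_treated, censored_control, status.  Discarded species rows
    are retained with status ``discarded`` and empty estimates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for comp in _comparison_groups(metadata):
        treated, control = comp["treated"], comp["control"]
        if "species" in levels:
            for name, values in normalized.iterrows():
                imp = _impute_comparison(values, treated, control, rng)
                if imp is None:
                    tv = values[treated]
                    cv = values[control]
                    rows.append(dict(cell_line=comp["cell_line"], drug=comp["drug"],
                                     level="species", name=name, central=np.nan,
                                     ci_low=np.nan, ci_high=np.nan, B=B,
                                     censored_treated=int(tv.isna().sum()),
                                     censored_control=int(cv.isna().sum()),
                                     status="discarded"))
                    continue
                tv, cv, n_ct, n_cc = imp
                if impute_per_draw and (n_ct or n_cc):
                    res = _bootstrap_impute_per_draw(
                        values, treated, control, B, rng, percentiles)
                else:
                    res = bootstrap_log_fc(tv, cv, B=B, rng=rng,
                                           percentiles=percentiles)
                rows.append(dict(cell_line=comp["cell_line"], drug=comp["drug"],
                                 level="species", name=name, central=res.central,
                                 ci_low=res.ci_low, ci_high=res.ci_high, B=B,
                                 censored_treated=n_ct, censored_control=n_cc,
                                 status="estimated"))
        if "family" in levels and family_map is not None:
            cols = treated + control
            sub = normalized[cols]
            if impute_members:
                # impute censored member values (per comparison) before
                # summing, so family sums are not dragged down by zeros;
                # members with <2 detected values fall back to 0
                sub = sub.copy()
                for name in sub.index[sub.isna().any(axis=1)]:
                    vals = sub.loc[name].to_numpy(dtype=float)
                    miss = np.isnan(vals)
                    if (~miss).sum() >= 2:
                        fit = fit_censoring_model(vals)
                        vals[miss] = impute_censored(fit, int(miss.sum()), rng)
                        sub.loc[name] = vals
            fam = family_sum(sub, family_map)
            cens = family_censored_counts(normalized[cols], family_map)
            for name, values in fam.iterrows():
                if (values[treated + control] <= 0).any():
                    # every member censored in some sample: no log-signal
                    rows.append(dict(cell_line=comp["cell_line"], drug=comp["drug"],
                                     level="family", name=name, central=np.nan,
                                     ci_low=np.nan, ci_high=np.nan, B=B,
                                     censored_treated=int(cens.loc[name, treated].sum()),
                                     censored_control=int(cens.loc[name, control].sum()),
                                     status="discarded"))
                    continue
                res = bootstrap_log_fc(values[treated], values[control], B=B,
                                       rng=rng, percentiles=percentiles)
                rows.append(dict(cell_line=comp["cell_line"], drug=comp["drug"],
                                 level="family", name=name, central=res.central,
                                 ci_low=res.ci_low, ci_high=res.ci_high, B=B,
                                 censored_treated=int(cens.loc[name, treated].sum()),
                                 censored_control=int(cens.loc[name, control].sum()),
                                 status="estimated"))
    return pd.DataFrame(rows)


def _bootstrap_impute_per_draw(values: pd.Series, treated: list, control: list,
                               B: int, rng: np.random.Generator,
                               percentiles: tuple[float, float]) -> FoldChangeResult:
    """Variant propagating imputation uncertainty: fresh draws per iteration."""
    tv = values[treated].to_numpy(dtype=float)
    cv = values[control].to_numpy(dtype=float)
    fit = fit_censoring_model(np.concatenate([tv, cv]))
    draws = np.empty(B)
    for b in range(B):
        t = tv.copy()
        c = cv.copy()
        if np.isnan(t).any():
            t[np.isnan(t)] = impute_censored(fit, int(np.isnan(t).sum()), rng)
        if np.isnan(c).any():
            c[np.isnan(c)] = impute_censored(fit, int(np.isnan(c).sum()), rng)
        t = t[rng.integers(0, t.size, t.size)]
        c = c[rng.integers(0, c.size, c.size)]
        draws[b] = np.log(t.mean() / c.mean())
    lo, hi = np.percentile(draws, percentiles)
    return FoldChangeResult(name="", level="species", central=float(draws.mean()),
                            ci_low=float(lo), ci_high=float(hi), B=B,
                            censored_treated=0, censored_control=0,
                            status="estimated")
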