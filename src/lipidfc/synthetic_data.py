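"""Synthetic study generator with known ground truth.

Emulates the design of the cell-culture experiment the pipeline analyzes:
three primary liver cancer cell lines (HepG2, Huh7, SNU449) each treated for
48 h with two anthracyclins (DOX, IDA) at concentrations causing >50%
mortality, with DMSO-matched vehicle controls and an untreated control, in
three culture replicates.  A pooled QC extract is injected every fifth
injection.  The simulated lipidome spans 18 lipid families (~451 species by
default); measurement noise is multiplicative log-normal on peak areas, each
species has a per-species detection limit realized as a quantile of its own
areas (values below it are emitted as missing and flagged censored), and
feature m/z carry Gaussian relative errors of a few ppm, as a Q-ToF-class
instrument would produce.

Raw peak areas scale with the number of cells extracted from the flask
(fewer surviving treated cells yield proportionally less signal); dividing
by the extracted cell count recovers the per-cell lipidome, which is where
the injected true effects live.  Ground truth (species identities, true log
fold changes, the censoring mask) is returned alongside the tables so every
downstream stage can be checked against it.

All randomness derives from one master seed; each stage draws from an
independent substream keyed by a fixed label, so stages are reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cell_metrics import SizeHistogram
from .lipid_library import (
    ADDUCTS,
    DEFAULT_FAMILY_ADDUCTS,
    Chain,
    FAMILIES,
    LipidSpecies,
    build_library,
)

__all__ = [
    "DEFAULT_FAMILY_COUNTS",
    "StudyDesign",
    "TrueEffects",
    "SimulatedStudy",
    "generate_lipidome",
    "simulate_study",
    "simulate_size_histograms",
]

#: per-family species counts; totals 451. The etherPC (1 species,
#: PC(O-16:0/18:1)), etherPE (6, all PUFA-containing) and free-sterol (1)
#: counts match the detected lipidome described for these cells; the rest is
#: a plausible hepatocyte split.
DEFAULT_FAMILY_COUNTS: dict[str, int] = {
    "FA": 25, "LPC": 25, "PC": 90, "etherPC": 1, "LPE": 12, "PE": 45,
    "etherPE": 6, "PG": 20, "LPI": 6, "PI": 30, "LPS": 4, "PS": 20,
    "DG": 25, "TG": 90, "sterol": 1, "CE": 15, "Cer": 16, "SM": 20,
}

_SUBSTREAMS = {"baselines": 1, "counts": 2, "areas": 3, "mz": 4,
               "ms2": 5, "qc": 6, "injection": 7, "sizes": 8, "effects": 9}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS[label],))
    )


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of the simulated study; defaults mirror the experiment design."""

    cell_lines: tuple[str, ...] = ("HepG2", "Huh7", "SNU449")
    drugs: tuple[str, ...] = ("DOX", "IDA")
    replicates_per_group: int = 3
    n_species_per_family: Mapping[str, int] | None = None
    lod_quantile: float = 0.05
    noise_sigma_log: float = 0.2
    mortality_fraction: float = 0.6
    seed: int = 0
    baseline_cells: float = 4e6          # cells seeded per T75 flask
    count_cv_log: float = 0.08           # flask-to-flask log-scale count spread
    mz_error_ppm: float = 3.0            # SD of relative m/z error
    qc_noise_sigma: float = 0.05
    qc_every: int = 5                    # one QC injection per this many samples
    size_mean_um: tuple[float, ...] = (11.0, 12.0, 13.0)
    size_sd_um: float = 2.5
    size_shift_um: float = 2.0           # treatment-induced shift, last cell line only
    size_bins_um: tuple[float, float, float] = (4.0, 25.0, 1.0)
    cells_per_size_histogram: int = 1_000_000

    def __post_init__(self):
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if not 0.5 < self.mortality_fraction < 1:
            raise ValueError("mortality_fraction must be in (0.5, 1): the design "
                             "requires >50% mortality at 48 h")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if self.noise_sigma_log < 0:
            raise ValueError("noise_sigma_log must be >= 0")
        for fam in self.family_counts:
            if fam not in FAMILIES:
                raise ValueError(f"unknown lipid family {fam!r}")

    @property
    def family_counts(self) -> dict[str, int]:
        if self.n_species_per_family is None:
            return dict(DEFAULT_FAMILY_COUNTS)
        return {f: int(n) for f, n in self.n_species_per_family.items() if n > 0}


# ---------------------------------------------------------------------------
# lipidome enumeration

_ACYL_POOL = [(16, 0), (18, 1), (18, 0), (16, 1), (18, 2), (20, 4), (20, 5),
              (20, 3), (22, 6), (14, 0), (22, 5), (22, 4), (18, 3), (20, 0),
              (22, 0), (24, 0), (24, 1), (12, 0), (15, 0), (17, 0), (26, 0),
              (20, 1), (20, 2), (22, 1), (14, 1)]
_TG_POOL = _ACYL_POOL[:10]
_ETHER_ALKYL = [(16, 0), (18, 0), (18, 1), (16, 1), (20, 0)]
_ETHER_PUFA = [(20, 4), (22, 6), (20, 5), (22, 5), (20, 3)]
_ETHER_OTHER = [(18, 1), (16, 0), (18, 2), (18, 0)]


def _fa_pool() -> list[tuple[int, int]]:
    def dmax(c):
        return 1 if c < 16 else 2 if c < 18 else 4 if c < 20 else 6
    pool = [(c, d) for d in range(0, 7) for c in range(12, 27)
            if d <= dmax(c)]
    # abundance-ordered: common chains first
    pool.sort(key=lambda cd: (cd not in _ACYL_POOL,
                              _ACYL_POOL.index(cd) if cd in _ACYL_POOL else 0,
                              cd))
    return pool


def _combos(pool, k):
    """Unordered k-multisets of the pool, in deterministic pool order."""
    if k == 1:
        return [(p,) for p in pool]
    out = []
    idx = range(len(pool))
    if k == 2:
        for i in idx:
            for j in idx[i:]:
                out.append((pool[i], pool[j]))
    else:
        for i in idx:
            for j in idx[i:]:
                for l in idx[j:]:
                    out.append((pool[i], pool[j], pool[l]))
    return out


def _species_for_family(family: str, n: int) -> list[LipidSpecies]:
    if n <= 0:
        return []
    if family == "sterol":
        templates = [LipidSpecies("sterol", 27, 1)]
    elif family == "FA":
        templates = [LipidSpecies("FA", c, d, chains=(Chain(c, d),))
                     for c, d in _fa_pool()]
    elif family in ("LPC", "LPE", "LPI", "LPS", "CE"):
        templates = [LipidSpecies(family, c, d, chains=(Chain(c, d),))
                     for c, d in _ACYL_POOL]
    elif family in ("Cer", "SM"):
        templates = [LipidSpecies(family, 18 + c, 1 + d,
                                  chains=(Chain(18, 1, "sphingoid"), Chain(c, d)))
                     for c, d in _ACYL_POOL]
    elif family in ("PC", "PE", "PG", "PI", "PS", "DG"):
        pool = _TG_POOL if family == "DG" else _ACYL_POOL[:14]
        templates = [LipidSpecies(family, a[0] + b[0], a[1] + b[1],
                                  chains=(Chain(*a), Chain(*b)))
                     for a, b in _combos(pool, 2)]
    elif family == "TG":
        templates = [LipidSpecies("TG", a[0] + b[0] + c[0], a[1] + b[1] + c[1],
                                  chains=(Chain(*a), Chain(*b), Chain(*c)))
                     for a, b, c in _combos(_TG_POOL, 3)]
    elif family in ("etherPC", "etherPE"):
        acyls = _ETHER_PUFA if family == "etherPE" else _ETHER_OTHER
        templates = [LipidSpecies(family, alk[0] + ac[0], alk[1] + ac[1],
                                  linkage="plasmanyl",
                                  chains=(Chain(*alk, "alkyl"), Chain(*ac)))
                     for ac in acyls for alk in _ETHER_ALKYL]
    else:  # pragma: no cover
        raise ValueError(f"unknown lipid family {family!r}")
    # dedupe by shorthand, keep order
    seen, uniq = set(), []
    for sp in templates:
        if sp.shorthand not in seen:
            seen.add(sp.shorthand)
            uniq.append(sp)
    if n > len(uniq):
        raise ValueError(
            f"family {family!r}: {n} species requested but only "
            f"{len(uniq)} distinct templates available"
        )
    return uniq[:n]


def generate_lipidome(design: StudyDesign) -> list[LipidSpecies]:
    """Enumerate the simulated lipidome: Σ n_species_per_family species.

    Enumeration is deterministic (abundance-ordered chain pools), so the same
    design always yields the identical species list.  Unknown family labels
    are rejected by :class:`StudyDesign` validation.
    """
    species: list[LipidSpecies] = []
    for fam in FAMILIES:  # fixed family order
        n = design.family_counts.get(fam, 0)
        species.extend(_species_for_family(fam, n))
    return species


# ---------------------------------------------------------------------------
# true effects

@dataclass(frozen=True)
class TrueEffects:
    """Ground-truth log fold changes per (species shorthand, cell line, drug).

    Vehicle-vs-untreated effects are zero by construction: effects apply to
    drug-treated samples only.
    """

    effects: Mapping[tuple[str, str, str], float]
    family_means: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.effects.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite effect for {k}")

    def effect(self, shorthand: str, cell_line: str, drug: str) -> float:
        return self.effects.get((shorthand, cell_line, drug), 0.0)

    @classmethod
    def zero(cls) -> "TrueEffects":
        return cls(effects={})

    @classmethod
    def from_family_means(
        cls,
        lipidome: list[LipidSpecies],
        design: StudyDesign,
        family_means: Mapping[str, float],
        family_spread: float = 0.0,
        pufa_only: bool = True,
    ) -> "TrueEffects":
        """Assign each species its family's mean effect (plus optional spread).

        With ``pufa_only``, the etherPE and FA family effects apply only to
        PUFA-containing species, mirroring the biology being emulated.
        """
        rng = _rng(design.seed, "effects")
        eff = {}
        for sp in lipidome:
            mu = family_means.get(sp.family, 0.0)
            if mu and pufa_only and sp.family in ("etherPE", "FA") \
                    and not sp.is_pufa_containing():
                mu = 0.0
            for line in design.cell_lines:
                for drug in design.drugs:
                    e = mu + (rng.normal(0, family_spread) if family_spread else 0.0)
                    eff[(sp.shorthand, line, drug)] = e
        return cls(effects=eff, family_means=dict(family_means))

    @classmethod
    def default(cls, lipidome: list[LipidSpecies], design: StudyDesign) -> "TrueEffects":
        """The study's headline ground truth: etherPE-with-PUFA and free-PUFA
        lipids increase by a factor 1.5 under both drugs in every cell line."""
        return cls.from_family_means(
            lipidome, design,
            {"etherPE": math.log(1.5), "FA": math.log(1.5)},
        )


# ---------------------------------------------------------------------------
# study simulation

@dataclass
class SimulatedStudy:
    """All generated tables plus ground truth."""

    features: pd.DataFrame        # feature_id, mz, rt, polarity, <sample areas>
    metadata: pd.DataFrame        # indexed by sample_id
    ms2: pd.DataFrame             # precursor_id, fragment_mz, intensity
    censored: pd.DataFrame        # feature × sample boolean ground-truth mask
    truth: pd.DataFrame           # feature_id → shorthand, family, adduct
    effects: TrueEffects
    library: pd.DataFrame
    design: StudyDesign

    def sample_columns(self) -> list[str]:
        return list(self.metadata.index)

    def study_samples(self) -> list[str]:
        return list(self.metadata.index[self.metadata["treatment"] != "QC-pool"])


def _sample_table(design: StudyDesign) -> pd.DataFrame:
    treatments = list(design.drugs) + [f"vehicle-{d}" for d in design.drugs] + ["untreated"]
    rows = []
    for line in design.cell_lines:
        for tr in treatments:
            for rep in range(1, design.replicates_per_group + 1):
                rows.append(dict(sample_id=f"{line}_{tr}_r{rep}", cell_line=line,
                                 treatment=tr, replicate=rep))
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_study(design: StudyDesign,
                   effects: TrueEffects | None = None) -> SimulatedStudy:
    """Generate the feature table, metadata, MS2 lists and ground truth.

    The model: raw area of species *s* in sample *j* is

        baseline_per_cell[s] × cell_count[j] × exp(effect) × exp(N(0, σ_log)),

    the effect applying only to drug-treated samples.  Treated flasks carry
    on average (1 − mortality_fraction) of the vehicle cell count.  Each
    species' detection limit is the ``lod_quantile`` quantile of its areas
    across study samples; areas strictly below it are emitted as missing.
    Observed feature m/z = theoretical adduct m/z × (1 + ε), ε ~ N(0, ppm·1e-6).
    """
    if design.baseline_cells <= 0:
        raise ValueError("baseline_cells must be > 0")
    lipidome = generate_lipidome(design)
    if effects is None:
        effects = TrueEffects.default(lipidome, design)
    library = build_library(lipidome)
    meta = _sample_table(design)

    # cell counts: vehicle/untreated at baseline, treated reduced by mortality
    rng_counts = _rng(design.seed, "counts")
    counts = []
    for sid, row in meta.iterrows():
        base = design.baseline_cells * math.exp(
            rng_counts.normal(0, design.count_cv_log))
        if row["treatment"] in design.drugs:
            base *= (1 - design.mortality_fraction) * math.exp(
                rng_counts.normal(0, design.count_cv_log))
        counts.append(round(base))
    meta["cell_count"] = counts

    # per-cell baselines (log10-normal across species)
    rng_base = _rng(design.seed, "baselines")
    baseline = 10.0 ** rng_base.normal(0.0, 0.4, size=len(lipidome))

    rng_areas = _rng(design.seed, "areas")
    n_sp, n_sa = len(lipidome), len(meta)
    noise = (rng_areas.normal(0.0, design.noise_sigma_log, size=(n_sp, n_sa))
             if design.noise_sigma_log > 0 else np.zeros((n_sp, n_sa)))
    eff_m = np.zeros((n_sp, n_sa))
    for j, (sid, row) in enumerate(meta.iterrows()):
        if row["treatment"] in design.drugs:
            for i, sp in enumerate(lipidome):
                eff_m[i, j] = effects.effect(sp.shorthand, row["cell_line"],
                                             row["treatment"])
    areas = (baseline[:, None] * meta["cell_count"].to_numpy()[None, :]
             * np.exp(eff_m) * np.exp(noise))

    # per-species LOD at a quantile of that species' per-cell signal.
    # Censoring on the per-cell scale keeps missingness a function of
    # measurement noise rather than of treatment-induced cell loss, so the
    # below-minimum imputation downstream faces the censoring mechanism it
    # models.
    percell = areas / meta["cell_count"].to_numpy()[None, :]
    if design.lod_quantile > 0:
        lod = np.quantile(percell, design.lod_quantile, axis=1)
    else:
        lod = np.full(n_sp, -np.inf)
    censored = percell < lod[:, None]
    areas = np.where(censored, np.nan, areas)

    # QC pool: mean per-cell lipidome at a reference cell count, low noise
    rng_qc = _rng(design.seed, "qc")
    ref_count = round(float(meta["cell_count"].mean()))
    n_qc = max(3, n_sa // design.qc_every)
    qc_ids = [f"QC_{i + 1}" for i in range(n_qc)]
    qc_areas = (baseline[:, None] * ref_count
                * np.exp(rng_qc.normal(0, design.qc_noise_sigma, (n_sp, n_qc))))

    # injection order: shuffled study samples with a QC every qc_every slots
    rng_inj = _rng(design.seed, "injection")
    order = list(meta.index)
    rng_inj.shuffle(order)
    sequence: list[str] = []
    qi = iter(qc_ids)
    for k, sid in enumerate(order):
        if k % design.qc_every == 0:
            nxt = next(qi, None)
            if nxt:
                sequence.append(nxt)
        sequence.append(sid)
    for q in qi:
        sequence.append(q)

    qc_meta = pd.DataFrame(
        dict(cell_line="QC", treatment="QC-pool",
             replicate=range(1, n_qc + 1), cell_count=ref_count),
        index=pd.Index(qc_ids, name="sample_id"),
    )
    meta = pd.concat([meta, qc_meta])
    meta["injection_order"] = pd.Series(
        {sid: k + 1 for k, sid in enumerate(sequence)})
    meta = meta.sort_values("injection_order")

    # features: one per species at the family's primary adduct
    rng_mz = _rng(design.seed, "mz")
    prim = library.groupby("shorthand", sort=False).first()
    feat_ids = [f"F{i + 1:04d}" for i in range(n_sp)]
    shorthands = [sp.shorthand for sp in lipidome]
    theo_mz = prim.loc[shorthands, "mz"].to_numpy()
    obs_mz = theo_mz * (1 + rng_mz.normal(0, design.mz_error_ppm * 1e-6, n_sp))
    fam_index = {f: i for i, f in enumerate(FAMILIES)}
    rt = np.array([1.0 + 0.9 * fam_index[sp.family] for sp in lipidome])
    rt = rt + 0.02 * np.arange(n_sp) % 0.8 + rng_mz.normal(0, 0.01, n_sp)

    all_areas = np.concatenate([areas, qc_areas], axis=1)
    all_ids = list(_sample_table(design).index) + qc_ids
    features = pd.DataFrame(
        dict(feature_id=feat_ids, mz=obs_mz, rt=np.round(rt, 3),
             polarity=[prim.loc[s, "polarity"] for s in shorthands]))
    features = pd.concat(
        [features, pd.DataFrame(all_areas, columns=all_ids)], axis=1)
    # column order follows injection order for the sample block
    features = features[["feature_id", "mz", "rt", "polarity"] + list(meta.index)]

    cens = pd.DataFrame(False, index=feat_ids, columns=all_ids)
    cens.loc[:, _sample_table(design).index] = censored
    cens = cens[list(meta.index)]
    cens.index.name = "feature_id"

    truth = pd.DataFrame(
        dict(feature_id=feat_ids, shorthand=shorthands,
             family=[sp.family for sp in lipidome],
             adduct=[prim.loc[s, "adduct"] for s in shorthands]))

    # MS2: carboxylate anions for diacyl GPL species with known chains
    rng_ms2 = _rng(design.seed, "ms2")
    ms2_rows = []
    from .annotation import DIACYL_GPL_FAMILIES
    from .lipid_library import PROTON_MASS, fatty_acid_formula, monoisotopic_mass
    for fid, sp in zip(feat_ids, lipidome):
        if sp.family not in DIACYL_GPL_FAMILIES or sp.chains is None:
            continue
        for ch in sp.chains:
            if ch.link != "acyl":
                continue
            mzf = monoisotopic_mass(fatty_acid_formula(ch.carbons, ch.double_bonds)) \
                - PROTON_MASS
            ms2_rows.append(dict(
                precursor_id=fid,
                fragment_mz=mzf * (1 + rng_ms2.normal(0, 5e-6)),
                intensity=float(1000 * math.exp(rng_ms2.normal(0, 0.3)))))
        # one low-intensity noise peak
        ms2_rows.append(dict(precursor_id=fid,
                             fragment_mz=float(rng_ms2.uniform(100, 200)),
                             intensity=float(rng_ms2.uniform(1, 20))))
    ms2 = pd.DataFrame(ms2_rows, columns=["precursor_id", "fragment_mz", "intensity"])

    return SimulatedStudy(features=features, metadata=meta, ms2=ms2,
                          censored=cens, truth=truth, effects=effects,
                          library=library, design=design)


def simulate_size_histograms(design: StudyDesign) -> list[SizeHistogram]:
    """Binned cell-diameter counts per study flask.

    Diameters are normal per cell line (means ``size_mean_um``, SD
    ``size_sd_um``), binned over 4–25 µm.  Drug treatment shifts the mean of
    the last cell line (SNU449-like) by ``size_shift_um``; the other lines
    and all vehicle/untreated flasks are unshifted.  Bin counts are one
    multinomial draw of ``cells_per_size_histogram`` cells over the binned
    normal probabilities.
    """
    rng = _rng(design.seed, "sizes")
    lo, hi, w = design.size_bins_um
    edges = np.arange(lo, hi + w / 2, w)
    meta = _sample_table(design)
    means = {line: design.size_mean_um[i % len(design.size_mean_um)]
             for i, line in enumerate(design.cell_lines)}
    shifted_line = design.cell_lines[-1]
    out = []
    for sid, row in meta.iterrows():
        mu = means[row["cell_line"]]
        if row["cell_line"] == shifted_line and row["treatment"] in design.drugs:
            mu += design.size_shift_um
        p = np.diff(stats.norm.cdf(edges, loc=mu, scale=design.size_sd_um))
        p = p / p.sum()
        counts = rng.multinomial(design.cells_per_size_histogram, p)
        bins = tuple((float(a), float(b), int(n))
                     for a, b, n in zip(edges[:-1], edges[1:], counts))
        out.append(SizeHistogram(flask_id=sid, bins=bins))
    return out


# ---------------------------------------------------------------------------
# file export

def write_study(study: SimulatedStudy, outdir, seed: int | None = None) -> dict[str, str]:
    """Write the generated tables as commented TSV/CSV files; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    seed = study.design.seed if seed is None else seed
    header = f"# lipidfc synthetic study seed={seed} generator=0.1.0\n"
    paths = {}

    def _write(name, df, sep, index):
        p = os.path.join(outdir, name)
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep=sep, index=index)
        paths[name] = p

    _write("features.tsv", study.features, "\t", False)
    _write("metadata.csv", study.metadata, ",", True)
    _write("ms2.csv", study.ms2, ",", False)
    _write("censored.tsv", study.censored.astype(int), "\t", True)
    _write("truth.tsv", study.truth, "\t", False)
    from .lipid_library import write_library
    write_library(study.library, os.path.join(outdir, "library.tsv"), seed=seed)
    paths["library.tsv"] = os.path.join(outdir, "library.tsv")

    hists = simulate_size_histograms(study.design)
    rows = [dict(flask_id=h.flask_id, bin_lower_um=lo, bin_upper_um=hi, cell_count=n)
            for h in hists for lo, hi, n in h.bins]
    _write("sizes.csv", pd.DataFrame(rows), ",", False)
    return paths
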