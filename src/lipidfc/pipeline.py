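"""End-to-end orchestration: simulate → annotate → normalize → infer → cell metrics.

Each stage reads/writes plain TSV/CSV with a comment header recording the
seed; a JSON manifest records versions, the seed, stage status and SHA-256
hashes of every output so a run can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    DIACYL_GPL_FAMILIES,
    MS2Spectrum,
    assign_acyl_combination,
    assign_isomer,
    match_features,
    unannotated_features,
)
from .lipid_library import parse_shorthand
from .cell_metrics import SizeHistogram, size_summary, cell_number_reduction
from .inference import run_comparisons
from .quantification import (
    normalize_by_cells,
    qc_dispersion_flags,
    rank1_family_map,
)
from .synthetic_data import (
    SimulatedStudy,
    StudyDesign,
    simulate_size_histograms,
    simulate_study,
    write_study,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; flags win over config, config over defaults."""

    outdir: str = "lipidfc_out"
    seed: int = 0
    tol_ppm: float = 10.0
    bootstrap: int = 10_000
    percentiles: tuple[float, float] = (2.5, 97.5)
    level: str = "both"  # species | family | both
    cv_threshold: float = 0.30
    impute_per_draw: bool = False
    # input paths; when absent the generator runs with `design`
    features: str | None = None
    metadata: str | None = None
    ms2: str | None = None
    sizes: str | None = None
    library: str | None = None
    design: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "percentiles" in raw:
            raw["percentiles"] = tuple(raw["percentiles"])
        return cls(**raw)

    def levels(self) -> tuple[str, ...]:
        return ("species", "family") if self.level == "both" else (self.level,)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_table(path: str, sep: str, index_col=None) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def _write(df: pd.DataFrame, path: str, seed: int, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# lipidfc {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _refine_annotations(annotations: pd.DataFrame, features: pd.DataFrame,
                        ms2: pd.DataFrame | None,
                        sample_cols: list[str]) -> pd.DataFrame:
    """MS2 acyl refinement for diacyl GPLs and abundance-prior FA isomer labels."""
    if annotations.empty:
        return annotations
    ann = annotations.copy()
    ann["acyl_combination"] = ""
    r1 = ann["rank"] == 1
    if ms2 is not None and not ms2.empty:
        spectra = {fid: MS2Spectrum(fid, tuple(g["fragment_mz"]),
                                    tuple(g["intensity"]))
                   for fid, g in ms2.groupby("precursor_id")}
        for i in ann.index[r1 & ann["family"].isin(DIACYL_GPL_FAMILIES)]:
            spec = spectra.get(ann.at[i, "feature_id"])
            if spec is None:
                continue
            sp = parse_shorthand(ann.at[i, "shorthand"])
            sum_comp = parse_shorthand(
                f"{sp.family}({sp.total_carbons}:{sp.total_double_bonds})")
            pair = assign_acyl_combination(sum_comp, spec)
            if pair is not None:
                ann.at[i, "acyl_combination"] = "/".join(pair)
                ann.at[i, "resolution"] = "acyl-combination"
                # isobaric chain combinations share a sum composition; the
                # fragments name the actual pair
                ann.at[i, "shorthand"] = f"{sp.family}({'/'.join(pair)})"
    # FA isomer labels: the most abundant feature of a composition gets the
    # prior isomer name
    fa = ann[r1 & (ann["family"] == "FA")]
    if not fa.empty:
        mean_area = features.set_index("feature_id")[sample_cols].mean(axis=1)
        comp = {i: parse_shorthand(ann.at[i, "shorthand"]) for i in fa.index}
        groups: dict[tuple[int, int], list] = {}
        for i, sp in comp.items():
            groups.setdefault(
                (sp.total_carbons, sp.total_double_bonds), []).append(i)
        for (c, d), idxs in groups.items():
            members = [(ann.at[i, "feature_id"],
                        float(mean_area.get(ann.at[i, "feature_id"], 0.0)))
                       for i in idxs]
            labels = assign_isomer(members, c, d)
            for i in idxs:
                label = labels[ann.at[i, "feature_id"]]
                if label != ann.at[i, "shorthand"]:
                    ann.at[i, "shorthand"] = label
                    ann.at[i, "resolution"] = "isomer"
    return ann


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict[str, Any] = dict(
        package="lipidfc", version=__version__, seed=config.seed, stages=[], outputs={},
    )

    def stage(name):
        manifest["stages"].append(dict(name=name, status="succeeded"))

    # ---- stage 1: simulate or load -------------------------------------
    if config.features is None:
        design = StudyDesign(seed=config.seed, **config.design)
        study = simulate_study(design)
        write_study(study, config.outdir)
        features = study.features
        metadata = study.metadata
        library = study.library
        ms2 = study.ms2
        hists = simulate_size_histograms(design)
        stage("simulate")
    else:
        features = _read_table(config.features, "\t")
        metadata = _read_table(config.metadata, ",", index_col="sample_id")
        from .lipid_library import read_library
        if config.library is None:
            raise FileNotFoundError("a library path is required when features are given")
        library = read_library(config.library)
        ms2 = _read_table(config.ms2, ",") if config.ms2 else None
        hists = None
        if config.sizes:
            raw = _read_table(config.sizes, ",")
            hists = [
                SizeHistogram(fid, tuple(sub[["bin_lower_um", "bin_upper_um",
                                              "cell_count"]].itertuples(index=False,
                                                                        name=None)))
                for fid, sub in raw.groupby("flask_id")
            ]
        stage("load")

    sample_cols = [c for c in features.columns if c in set(metadata.index)]

    # ---- stage 2: annotate ---------------------------------------------
    annotations = match_features(features, library, tol_ppm=config.tol_ppm)
    annotations = _refine_annotations(annotations, features, ms2, sample_cols)
    _write(annotations, os.path.join(config.outdir, "annotations.tsv"), config.seed)
    _write(unannotated_features(features[["feature_id", "mz", "rt", "polarity"]],
                                annotations),
           os.path.join(config.outdir, "unannotated.tsv"), config.seed)
    stage("annotate")

    # ---- stage 3: quantify ---------------------------------------------
    areas = features.set_index("feature_id")[sample_cols]
    normalized = normalize_by_cells(areas, metadata["cell_count"])
    r1 = annotations[annotations["rank"] == 1].set_index("feature_id")
    # collapse features to species via rank-1 annotation (sum multiple adduct
    # features of the same species)
    species_matrix = (normalized.loc[normalized.index.intersection(r1.index)]
                      .groupby(r1["shorthand"]).sum(min_count=1))
    fam_map = r1.drop_duplicates("shorthand").set_index("shorthand")["family"]
    qc_ids = list(metadata.index[metadata["treatment"] == "QC-pool"])
    qc_flags = qc_dispersion_flags(normalized, qc_ids, config.cv_threshold)
    _write(species_matrix, os.path.join(config.outdir, "normalized.tsv"),
           config.seed, index=True)
    _write(species_matrix.isna().astype(int),
           os.path.join(config.outdir, "censored_flags.tsv"), config.seed, index=True)
    _write(qc_flags.rename("qc_flag").to_frame(),
           os.path.join(config.outdir, "qc_flags.tsv"), config.seed, index=True)
    stage("quantify")

    # ---- stage 4: infer -------------------------------------------------
    results = run_comparisons(
        species_matrix, metadata, family_map=fam_map, B=config.bootstrap,
        seed=config.seed, percentiles=config.percentiles,
        levels=config.levels(), impute_per_draw=config.impute_per_draw,
    )
    _write(results, os.path.join(config.outdir, "foldchanges.tsv"), config.seed)
    stage("infer")

    # ---- stage 5: cell metrics ------------------------------------------
    study_meta = metadata[metadata["treatment"] != "QC-pool"]
    red_rows = []
    for line in sorted(study_meta["cell_line"].unique()):
        sub = study_meta[study_meta["cell_line"] == line]
        for drug in sorted(t for t in sub["treatment"].unique()
                           if not t.startswith("vehicle") and t != "untreated"):
            t = sub.loc[sub["treatment"] == drug, "cell_count"]
            v = sub.loc[sub["treatment"] == f"vehicle-{drug}", "cell_count"]
            red_rows.append(dict(cell_line=line, drug=drug,
                                 reduction_pct=cell_number_reduction(t, v)))
    _write(pd.DataFrame(red_rows),
           os.path.join(config.outdir, "cell_counts.tsv"), config.seed)
    if hists:
        groups = (study_meta["cell_line"] + "/" + study_meta["treatment"])
        _write(size_summary(hists, groups),
               os.path.join(config.outdir, "cell_sizes.tsv"), config.seed)
    stage("cellsize")

    for fname in sorted(os.listdir(config.outdir)):
        p = os.path.join(config.outdir, fname)
        if os.path.isfile(p) and fname != "manifest.json":
            manifest["outputs"][fname] = _sha256(p)
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def fixture_design(seed: int = 1) -> StudyDesign:
    """A ≤50-species, 2-cell-line mini-study that runs in seconds."""
    return StudyDesign(
        cell_lines=("HepG2", "Huh7"),
        seed=seed,
        n_species_per_family={"PC": 10, "PE": 8, "etherPE": 4, "FA": 8,
                              "TG": 10, "Cer": 5, "LPC": 5},
        lod_quantile=0.08,
    )


def make_fixtures(seed: int = 1, outdir: str = "fixtures") -> SimulatedStudy:
    """Generate and write the mini-study used by the test suite.

    Guarantees at least one species triggering the censor-discard rule by
    forcing two values of the first feature to missing in one treated group.
    """
    study = simulate_study(fixture_design(seed))
    meta = study.metadata
    line, drug = study.design.cell_lines[0], study.design.drugs[0]
    grp = meta.index[(meta["cell_line"] == line) & (meta["treatment"] == drug)][:2]
    fid = study.features["feature_id"].iloc[0]
    mask = study.features["feature_id"] == fid
    study.features.loc[mask, list(grp)] = np.nan
    study.censored.loc[fid, list(grp)] = True
    write_study(study, outdir)
    return study
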