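"""Ground-truth fidelity, determinism and realism of the study generator."""

import math

import numpy as np
import pandas as pd
import pytest

from lipidfc.quantification import normalize_by_cells
from lipidfc.synthetic_data import (
    DEFAULT_FAMILY_COUNTS,
    StudyDesign,
    TrueEffects,
    generate_lipidome,
    simulate_size_histograms,
    simulate_study,
)


class TestDesignValidation:
    def test_defaults_valid(self):
        StudyDesign()

    def test_unknown_family_rejected_by_name(self):
        with pytest.raises(ValueError, match="XX"):
            StudyDesign(n_species_per_family={"XX": 3})

    def test_low_mortality_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(mortality_fraction=0.4)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(replicates_per_group=1)


class TestGenerateLipidome:
    def test_default_counts_sum_to_451(self):
        assert sum(DEFAULT_FAMILY_COUNTS.values()) == 451
        lip = generate_lipidome(StudyDesign())
        assert len(lip) == 451

    def test_per_family_counts_respected(self):
        lip = generate_lipidome(StudyDesign(n_species_per_family={"PC": 1}))
        assert len(lip) == 1 and lip[0].family == "PC"

    def test_unique_shorthands(self):
        lip = generate_lipidome(StudyDesign())
        names = [sp.shorthand for sp in lip]
        assert len(names) == len(set(names))

    def test_deterministic(self):
        a = generate_lipidome(StudyDesign(seed=3))
        b = generate_lipidome(StudyDesign(seed=3))
        assert [sp.shorthand for sp in a] == [sp.shorthand for sp in b]

    def test_ether_pe_species_all_pufa(self):
        lip = generate_lipidome(StudyDesign())
        ethers = [sp for sp in lip if sp.family == "etherPE"]
        assert len(ethers) == 6
        assert all(sp.is_pufa_containing() for sp in ethers)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="sterol"):
            generate_lipidome(StudyDesign(n_species_per_family={"sterol": 5}))


class TestSimulateStudy:
    def test_same_seed_byte_identical(self):
        a = simulate_study(StudyDesign(seed=9))
        b = simulate_study(StudyDesign(seed=9))
        pd.testing.assert_frame_equal(a.features, b.features)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.ms2, b.ms2)

    def test_zero_noise_normalized_logfc_equals_truth_exactly(self):
        """Without noise or censoring the per-cell log fold change of every
        species equals its ground-truth entry."""
        design = StudyDesign(seed=2, noise_sigma_log=0.0, lod_quantile=0.0,
                             n_species_per_family={"PC": 3, "etherPE": 2,
                                                   "FA": 2})
        study = simulate_study(design)
        areas = study.features.set_index("feature_id")[study.study_samples()]
        meta = study.metadata.loc[study.study_samples()]
        norm = normalize_by_cells(areas, meta["cell_count"])
        truth = study.truth.set_index("feature_id")
        for line in design.cell_lines:
            for drug in design.drugs:
                t = meta.index[(meta.cell_line == line) & (meta.treatment == drug)]
                v = meta.index[(meta.cell_line == line)
                               & (meta.treatment == f"vehicle-{drug}")]
                lfc = np.log(norm[t].mean(axis=1) / norm[v].mean(axis=1))
                for fid, val in lfc.items():
                    want = study.effects.effect(truth.loc[fid, "shorthand"],
                                                line, drug)
                    assert val == pytest.approx(want, abs=1e-12)

    def test_zero_noise_zero_effect_treated_equals_vehicle_per_cell(self):
        design = StudyDesign(seed=2, noise_sigma_log=0.0, lod_quantile=0.0,
                             n_species_per_family={"PC": 3})
        study = simulate_study(design, effects=TrueEffects.zero())
        areas = study.features.set_index("feature_id")[study.study_samples()]
        meta = study.metadata.loc[study.study_samples()]
        norm = normalize_by_cells(areas, meta["cell_count"])
        assert np.allclose(norm.to_numpy(),
                           norm.to_numpy()[:, [0]], rtol=1e-12)

    def test_censored_fraction_tracks_lod_quantile(self, default_study):
        frac = default_study.censored[default_study.study_samples()] \
            .to_numpy().mean()
        assert abs(frac - default_study.design.lod_quantile) <= 0.02

    def test_censoring_monotone_in_lod_quantile(self):
        n_at = {}
        for q in (0.05, 0.20):
            s = simulate_study(StudyDesign(
                seed=4, lod_quantile=q,
                n_species_per_family={"PC": 20, "FA": 10}))
            n_at[q] = int(s.censored.to_numpy().sum())
        assert n_at[0.20] >= n_at[0.05]

    def test_mortality_ratio_below_half(self, default_study):
        m = default_study.metadata
        t = m.loc[m.treatment.isin(default_study.design.drugs), "cell_count"].mean()
        v = m.loc[m.treatment.str.startswith("vehicle"), "cell_count"].mean()
        assert t / v < 0.5

    def test_mz_errors_within_annotation_gate(self, default_study):
        lib = default_study.library.groupby("shorthand").first()
        truth = default_study.truth.set_index("feature_id")
        obs = default_study.features.set_index("feature_id")["mz"]
        theo = lib.loc[truth["shorthand"], "mz"].to_numpy()
        ppm = 1e6 * (obs.to_numpy() - theo) / theo
        assert ppm.std() == pytest.approx(3.0, abs=1.0)
        assert np.abs(ppm).max() <= 12.0  # essentially all inside the gate

    def test_qc_samples_injected_every_fifth_position(self, default_study):
        m = default_study.metadata.sort_values("injection_order")
        qc_pos = np.flatnonzero((m.treatment == "QC-pool").to_numpy())
        assert qc_pos[0] == 0
        assert (np.diff(qc_pos[:-1]) == 6).all()

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError):
            simulate_study(StudyDesign(baseline_cells=0,
                                       n_species_per_family={"PC": 1}))


class TestSizeHistograms:
    def test_same_seed_identical(self):
        d = StudyDesign(seed=5, cells_per_size_histogram=10_000)
        a = simulate_size_histograms(d)
        b = simulate_size_histograms(d)
        assert [h.bins for h in a] == [h.bins for h in b]

    def test_bins_cover_4_to_25_um(self):
        d = StudyDesign(seed=5, cells_per_size_histogram=10_000)
        h = simulate_size_histograms(d)[0]
        assert h.bins[0][0] == 4.0 and h.bins[-1][1] == 25.0

    def test_zero_shift_groups_agree(self):
        from lipidfc.cell_metrics import weighted_mean_diameter
        d = StudyDesign(seed=6, size_shift_um=0.0)
        means = _group_size_means(d)
        for line in d.cell_lines:
            for drug in d.drugs:
                assert means[(line, drug)] == pytest.approx(
                    means[(line, f"vehicle-{drug}")], abs=0.05)

    def test_two_micron_shift_recovered(self):
        """Monte-Carlo at 1e6 cells/flask: the treated−vehicle weighted-mean
        difference in the shifted cell line is ≈ the injected 2 µm."""
        d = StudyDesign(seed=7)  # defaults: shift 2 µm in the last cell line
        means = _group_size_means(d)
        line = d.cell_lines[-1]
        for drug in d.drugs:
            diff = means[(line, drug)] - means[(line, f"vehicle-{drug}")]
            assert diff == pytest.approx(2.0, abs=0.1)
        other = d.cell_lines[0]
        assert means[(other, "DOX")] == pytest.approx(
            means[(other, "vehicle-DOX")], abs=0.05)


def _group_size_means(design):
    from lipidfc.cell_metrics import weighted_mean_diameter
    hists = simulate_size_histograms(design)
    out = {}
    for h in hists:
        line, treatment, _ = h.flask_id.rsplit("_", 2)[0], \
            h.flask_id.split("_")[1], None
        # flask ids look like "SNU449_vehicle-DOX_r1"
        line, treatment = h.flask_id.split("_")[0], h.flask_id.split("_")[1]
        out.setdefault((line, treatment), []).append(weighted_mean_diameter(h))
    return {k: float(np.mean(v)) for k, v in out.items()}
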