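"""Seeded generators: determinism, closed-form truth and feature spectra."""

import numpy as np
import pandas as pd
import pytest

from lipidkit.annotation import match_features
from lipidkit.quantify import quantify_table
from lipidkit.simulate import (
    VLCFA_THRESHOLDS,
    SimulationParams,
    class_rt_centers,
    make_design,
    simulate_feature_spectra,
    simulate_study,
    simulation_species,
    true_effect_log2,
    well_separated_panel,
)

LN2 = np.log(2.0)


SMALL_META = pd.DataFrame(
    {
        "class_code": ["PC", "CE", "TG"],
        "C": [30, 34, 70],
        "db": [0, 1, 2],
        "n_chains": [2, 1, 3],
    },
    index=["PC(30:0)", "CE(34:1)", "TG(70:2)"],
)


def test_make_design_shape_and_labels():
    params = SimulationParams(n_control_lines=2, n_ald_lines=3, replicates=2,
                              timepoints=(50, 100))
    design = make_design(params)
    frame = design.frame
    assert len(frame) == 5 * 2 * 2
    assert frame["line_id"].nunique() == 5
    assert set(frame.loc[frame["genotype"] == "CTRL", "line_id"]) == {"CTRL_1", "CTRL_2"}
    assert set(frame["timepoint"]) == {50, 100}


def test_simulation_params_validation():
    with pytest.raises(ValueError):
        SimulationParams(sigma_e=-0.1)
    with pytest.raises(ValueError):
        SimulationParams(replicates=0)


def test_true_effect_log2_closed_form():
    assert true_effect_log2(36, 1, 0.1, VLCFA_THRESHOLDS) == pytest.approx(1.0)
    assert true_effect_log2(26, 1, 0.1, VLCFA_THRESHOLDS) == 0.0
    assert true_effect_log2(20, 1, 0.1, VLCFA_THRESHOLDS) == 0.0
    assert true_effect_log2(50, 2, 0.1, VLCFA_THRESHOLDS) == pytest.approx(0.4)
    assert true_effect_log2(70, 3, 0.1, VLCFA_THRESHOLDS) == pytest.approx(0.8)
    assert true_effect_log2(70, 4, 0.1, VLCFA_THRESHOLDS) == 0.0  # no threshold


def test_simulate_study_is_deterministic():
    params = SimulationParams(seed=42, n_control_lines=2, n_ald_lines=2,
                              replicates=2, timepoints=(50, 100))
    t1, _, truth1 = simulate_study(params, species_meta=SMALL_META)
    t2, _, truth2 = simulate_study(params, species_meta=SMALL_META)
    assert t1.values.equals(t2.values)
    assert truth1.line_intercepts.equals(truth2.line_intercepts)
    t3, _, _ = simulate_study(
        SimulationParams(seed=43, n_control_lines=2, n_ald_lines=2,
                         replicates=2, timepoints=(50, 100)),
        species_meta=SMALL_META,
    )
    assert not t1.values.equals(t3.values)


def test_noiseless_null_study_is_flat():
    params = SimulationParams(
        seed=1, n_control_lines=2, n_ald_lines=2, replicates=2,
        timepoints=(50, 100), sigma_line=0.0, sigma_e=0.0, vlcfa_effect=0.0,
        class_trajectories={},
    )
    table, _, truth = simulate_study(params, species_meta=SMALL_META)
    # every sample identical per species, equal to 2**baseline
    for sp in table.species:
        row = table.values.loc[sp].to_numpy()
        assert np.ptp(row) == 0.0
        assert row[0] == pytest.approx(2.0 ** truth.baseline_log2[sp], rel=1e-12)


def test_noiseless_study_matches_generative_formula():
    params = SimulationParams(
        seed=2, n_control_lines=2, n_ald_lines=2, replicates=1,
        timepoints=(50, 200), sigma_line=0.0, sigma_e=0.0,
    )
    table, design, truth = simulate_study(params, species_meta=SMALL_META)
    frame = design.frame.set_index("sample_id")
    for sp in table.species:
        cls = SMALL_META.loc[sp, "class_code"]
        eff = truth.species_effect_log2[sp]
        for s in table.values.columns:
            tp = int(frame.loc[s, "timepoint"])
            is_ald = frame.loc[s, "genotype"] == "ALD"
            expected_log2 = (
                truth.baseline_log2[sp]
                + truth.class_trajectories.get(cls, {}).get(tp, 0.0)
                + (eff if is_ald else 0.0)
            )
            assert np.log2(table.values.loc[sp, s]) == pytest.approx(
                expected_log2, abs=1e-10
            )


def test_empirical_fold_change_matches_truth_over_replicates():
    # single-chain species 10 carbons past C0: true genotype log2 FC = 1.0
    meta = pd.DataFrame(
        {"class_code": ["CE"], "C": [36], "db": [1], "n_chains": [1]},
        index=["CE(36:1)"],
    )
    fcs = []
    for r in range(200):
        params = SimulationParams(
            seed=20_000 + r, n_control_lines=3, n_ald_lines=3, replicates=1,
            timepoints=(50,),
        )
        table, design, _ = simulate_study(params, species_meta=meta)
        frame = design.frame
        ctrl = frame.loc[frame["genotype"] == "CTRL", "sample_id"]
        ald = frame.loc[frame["genotype"] == "ALD", "sample_id"]
        row = table.values.loc["CE(36:1)"]
        fcs.append(np.log2(row[ald].mean() / row[ctrl].mean()))
    assert np.mean(fcs) == pytest.approx(1.0, abs=0.05)


def test_well_separated_panel_drops_ether_classes(classes):
    panel = well_separated_panel(classes)
    codes = {d.class_code for d in panel}
    assert not any("[O]" in c or "[P]" in c for c in codes)
    assert {"PC", "PE", "TG", "CE"} <= codes


def test_class_rt_centers_are_separated(classes):
    centers = class_rt_centers(classes, spacing=1.0)
    vals = sorted(centers.values())
    assert len(centers) == len(classes)
    assert min(np.diff(vals)) == pytest.approx(1.0)


def test_feature_spectra_truth_and_determinism(sep_db):
    design = make_design(
        SimulationParams(n_control_lines=1, n_ald_lines=1, replicates=1, timepoints=(50,))
    )
    f1, t1 = simulate_feature_spectra(sep_db, design, ppm_sigma=2.0, seed=7)
    f2, t2 = simulate_feature_spectra(sep_db, design, ppm_sigma=2.0, seed=7)
    assert t1 == t2
    assert [(f.feature_id, f.mz, f.rt) for f in f1] == [(f.feature_id, f.mz, f.rt) for f in f2]
    assert {f.feature_id for f in f1} == set(t1)


def test_feature_spectra_zero_ppm_gives_exact_masses(sep_db):
    design = make_design(
        SimulationParams(n_control_lines=1, n_ald_lines=1, replicates=1, timepoints=(50,))
    )
    features, truth = simulate_feature_spectra(sep_db, design, ppm_sigma=0.0, seed=1)
    by_key = {(e.species.name, e.adduct.name): e.mz for e in sep_db.entries()}
    for f in features:
        assert f.mz == by_key[truth[f.feature_id]]


def test_decoys_stay_away_from_candidates(sep_db):
    design = make_design(
        SimulationParams(n_control_lines=1, n_ald_lines=1, replicates=1, timepoints=(50,))
    )
    features, truth = simulate_feature_spectra(
        sep_db, design, ppm_sigma=2.0, decoy_rate=0.2, seed=4, avoid_ppm=15.0
    )
    decoys = [f for f in features if truth[f.feature_id] == ("decoy", "")]
    n_true = len(features) - len(decoys)
    assert len(decoys) == round(0.2 / 0.8 * n_true)
    for f in decoys:
        mzs = np.array([e.mz for e in sep_db.entries(f.polarity)])
        assert np.min(np.abs(mzs - f.mz)) / f.mz * 1e6 > 15.0


def test_feature_spectra_parameter_validation(sep_db):
    design = make_design(
        SimulationParams(n_control_lines=1, n_ald_lines=1, replicates=1, timepoints=(50,))
    )
    with pytest.raises(ValueError):
        simulate_feature_spectra(sep_db, design, ppm_sigma=-1.0)
    with pytest.raises(ValueError):
        simulate_feature_spectra(sep_db, design, decoy_rate=1.0)


def test_end_to_end_zero_noise_log_correlation(classes, full_db, rt_windows, standards, class_to_std):
    """simulate -> spectra -> annotate -> quantify recovers the study exactly."""
    mix, _ = standards
    meta = simulation_species(classes, max_per_class=4)
    meta = meta.drop(index=[s for s in meta.index if s in mix.amounts], errors="ignore")
    params = SimulationParams(
        seed=3, n_control_lines=2, n_ald_lines=2, replicates=1, timepoints=(50,),
        sigma_line=0.0, sigma_e=0.0,
    )
    table, design, _ = simulate_study(params, species_meta=meta)
    features, truth = simulate_feature_spectra(
        full_db, design, ppm_sigma=0.0, seed=3, is_mix=mix, abundances=table,
        class_to_standard=class_to_std, drift_sd=0.2,
        rt_centers=class_rt_centers(classes), rt_jitter=0.0,
    )
    annotations, unmatched = match_features(features, full_db, tol_ppm=5.0, rt_windows=rt_windows)
    assert unmatched == []
    recovered = quantify_table(annotations, features, design, mix, class_to_std)
    shared = recovered.values.index.intersection(table.values.index)
    assert len(shared) == len(table.values.index)
    a = np.log(recovered.values.loc[shared, design.sample_ids].to_numpy(float))
    b = np.log(table.values.loc[shared, design.sample_ids].to_numpy(float))
    assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.99
    assert np.max(np.abs(a - b)) < 1e-10
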