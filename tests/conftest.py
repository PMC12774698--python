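"""Shared fixtures: shipped configs and candidate databases, built once."""

import pytest

from lipidkit.annotation import build_database
from lipidkit.chem import expand_class
from lipidkit.io import (
    class_to_standard_map,
    load_default_adducts,
    load_default_classes,
    load_default_standards,
    standard_extra_species,
)
from lipidkit.simulate import class_rt_centers, well_separated_panel


@pytest.fixture(scope="session")
def classes():
    return load_default_classes()


@pytest.fixture(scope="session")
def adducts():
    return load_default_adducts()


@pytest.fixture(scope="session")
def standards():
    """(StandardsMix, {name: ElementalFormula})."""
    return load_default_standards()


@pytest.fixture(scope="session")
def class_to_std(classes):
    return class_to_standard_map(classes)


def make_database(classes, adducts, std_formulas):
    grid = frozenset(sp.name for d in classes for sp in expand_class(d))
    extra = standard_extra_species(classes, std_formulas, grid)
    return build_database(classes, adducts, extra_species=extra)


@pytest.fixture(scope="session")
def full_db(classes, adducts, standards):
    _, std_formulas = standards
    return make_database(classes, adducts, std_formulas)


@pytest.fixture(scope="session")
def sep_classes(classes):
    return well_separated_panel(classes)


@pytest.fixture(scope="session")
def sep_db(sep_classes, adducts, standards):
    _, std_formulas = standards
    return make_database(sep_classes, adducts, std_formulas)


@pytest.fixture(scope="session")
def rt_windows(classes):
    centers = class_rt_centers(classes)
    return {code: (t - 0.45, t + 0.45) for code, t in centers.items()}


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory, classes, full_db, standards, class_to_std):
    """A small on-disk simulated study: features.tsv + design.csv."""
    from lipidkit.io import write_design, write_feature_table
    from lipidkit.simulate import (
        SimulationParams,
        simulate_feature_spectra,
        simulate_study,
        simulation_species,
    )

    mix, _ = standards
    out = tmp_path_factory.mktemp("sim_dataset")
    meta = simulation_species(classes, max_per_class=4)
    meta = meta.drop(index=[s for s in meta.index if s in mix.amounts], errors="ignore")
    params = SimulationParams(
        seed=11, n_control_lines=2, n_ald_lines=3, replicates=2, timepoints=(50, 100)
    )
    table, design, truth = simulate_study(params, species_meta=meta)
    features, feat_truth = simulate_feature_spectra(
        full_db,
        design,
        ppm_sigma=2.0,
        seed=11,
        is_mix=mix,
        abundances=table,
        class_to_standard=class_to_std,
        rt_centers=class_rt_centers(classes),
        rt_jitter=0.05,
    )
    write_feature_table(features, out / "features.tsv", samples=design.sample_ids)
    write_design(design, out / "design.csv")
    return {
        "dir": out,
        "features": out / "features.tsv",
        "design": out / "design.csv",
        "table": table,
        "truth": truth,
        "feature_truth": feat_truth,
    }
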