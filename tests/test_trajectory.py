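"""Class Z-scores, LOESS smoothing, chain-property FC curves and PCA."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from lipidkit.quantify import AbundanceTable, StudyDesign
from lipidkit.trajectory import class_zscores, fc_by_chain_property, loess_smooth, pca_scores


def _design(sample_ids, line_ids=None, genotypes=None, timepoints=None):
    n = len(sample_ids)
    return StudyDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "line_id": line_ids or [f"CTRL_{i + 1}" for i in range(n)],
                "genotype": genotypes or ["CTRL"] * n,
                "region": ["hCO"] * n,
                "timepoint": timepoints or [50] * n,
                "replicate": list(range(1, n + 1)) if timepoints is None else [1] * n,
            }
        )
    )


def _table(values, **design_kw):
    design = _design(list(values.columns), **design_kw)
    return AbundanceTable(values=values, design=design)


# ---------------------------------------------------------------- Z-scores


def test_class_zscores_basic():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0]], index=["PC(30:0)"], columns=["s1", "s2", "s3"]
    )
    design = _design(["s1", "s2", "s3"], line_ids=["L1", "L1", "L1"],
                     timepoints=[50, 100, 150])
    traj = class_zscores(AbundanceTable(values=values, design=design), {"PC(30:0)": "PC"})
    z = traj.z_matrix.loc["PC"].to_numpy()
    assert np.allclose(z, [-1.0, 0.0, 1.0])
    assert traj.z_matrix.loc["PC"].mean() == pytest.approx(0.0, abs=1e-12)
    assert traj.z_matrix.loc["PC"].std(ddof=1) == pytest.approx(1.0)


def test_class_zscores_sums_species_within_class():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [5.0, 1.0, 9.0]],
        index=["PC(30:0)", "PC(32:1)", "TG(50:2)"],
        columns=["s1", "s2", "s3"],
    )
    design = _design(["s1", "s2", "s3"], line_ids=["L1", "L1", "L1"],
                     timepoints=[50, 100, 150])
    cmap = {"PC(30:0)": "PC", "PC(32:1)": "PC", "TG(50:2)": "TG"}
    traj = class_zscores(AbundanceTable(values=values, design=design), cmap)
    # PC sums to (4, 4, 4): constant, flagged and zeroed
    assert traj.constant_classes == ["PC"]
    assert np.allclose(traj.z_matrix.loc["PC"], 0.0)
    assert np.allclose(traj.abundance.loc["TG"], [5.0, 1.0, 9.0])


def test_class_zscores_affine_invariance():
    rng = np.random.default_rng(4)
    cols = [f"s{i}" for i in range(6)]
    base = pd.DataFrame(rng.lognormal(0, 1, (2, 6)),
                        index=["PC(30:0)", "TG(50:2)"], columns=cols)
    design = _design(cols, line_ids=["L1"] * 6, timepoints=[10, 20, 30, 40, 50, 60])
    cmap = {"PC(30:0)": "PC", "TG(50:2)": "TG"}
    z1 = class_zscores(AbundanceTable(values=base, design=design), cmap).z_matrix
    z2 = class_zscores(AbundanceTable(values=base * 7.5, design=design), cmap).z_matrix
    assert np.allclose(z1.to_numpy(), z2.to_numpy())


# ------------------------------------------------------------------- LOESS


def test_loess_reproduces_polynomials():
    x = np.linspace(0, 10, 40)
    for coeffs in ([2.0], [1.0, -0.5], [0.3, 1.2, -0.1]):
        y = np.polyval(coeffs[::-1], x)
        xe, fit = loess_smooth(x, y, span=0.5, degree=2)
        assert np.max(np.abs(fit - np.polyval(coeffs[::-1], xe))) < 1e-8


def test_loess_constant_input():
    x = np.arange(20.0)
    _, fit = loess_smooth(x, np.full(20, 3.25), span=0.6, degree=2)
    assert np.allclose(fit, 3.25)


def test_loess_matches_statsmodels_reference():
    rng = np.random.default_rng(8)
    x = np.sort(rng.uniform(0, 10, 120))
    y = np.sin(x) + rng.normal(0, 0.1, x.size)
    for span in (0.3, 0.5, 0.75):
        xe, fit = loess_smooth(x, y, span=span, degree=1)
        ref = sm_lowess(y, x, frac=span, it=0, return_sorted=True)
        assert np.allclose(xe, ref[:, 0])
        assert np.max(np.abs(fit - ref[:, 1])) < 1e-6


def test_loess_input_validation():
    x = np.arange(10.0)
    y = x.copy()
    with pytest.raises(ValueError):
        loess_smooth(x, y[:-1])
    with pytest.raises(ValueError):
        loess_smooth(x, y, span=0.0)
    with pytest.raises(ValueError):
        loess_smooth(x, y, span=1.5)
    with pytest.raises(ValueError):
        loess_smooth(np.array([1.0, 1.0, 2.0]), np.zeros(3))


def test_loess_evaluation_grid():
    x = np.linspace(0, 10, 30)
    y = 2.0 * x + 1.0
    grid = np.array([2.5, 5.0, 7.5])
    xe, fit = loess_smooth(x, y, x_eval=grid, degree=1)
    assert np.allclose(xe, grid)
    assert np.allclose(fit, 2.0 * grid + 1.0, atol=1e-8)


# --------------------------------------------------------------- FC curves


def _fc_fixture(ratio=4.0):
    """Noiseless two-genotype table where ALD = ratio x CTRL everywhere."""
    species = [f"PC({c}:0)" for c in range(30, 44, 2)]
    meta = pd.DataFrame(
        {
            "class_code": "PC",
            "C": [int(s.split("(")[1].split(":")[0]) for s in species],
            "db": 0,
            "n_chains": 2,
        },
        index=species,
    )
    cols = ["c1", "c2", "a1", "a2"]
    design = _design(
        cols,
        line_ids=["CTRL_1", "CTRL_2", "ALD_1", "ALD_2"],
        genotypes=["CTRL", "CTRL", "ALD", "ALD"],
        timepoints=[50, 50, 50, 50],
    )
    rng = np.random.default_rng(2)
    base = rng.lognormal(0, 1, (len(species), 2))
    values = pd.DataFrame(
        np.hstack([base, base * ratio]), index=species, columns=cols
    )
    return AbundanceTable(values=values, design=design, species_meta=meta)


def test_fc_curve_recovers_exact_ratio():
    table = _fc_fixture(ratio=4.0)
    (curve,) = fc_by_chain_property(
        table, "total_carbons", ("genotype", "CTRL", "ALD"), chain_counts=(2,)
    )
    assert np.allclose(curve.mean_log2_fc, 2.0, atol=1e-12)
    assert np.allclose(curve.loess_fit, 2.0, atol=1e-8)


def test_fc_curve_identity_contrast_is_zero():
    table = _fc_fixture()
    (curve,) = fc_by_chain_property(
        table, "total_carbons", ("genotype", "CTRL", "CTRL"), chain_counts=(2,)
    )
    assert np.allclose(curve.mean_log2_fc, 0.0, atol=1e-12)


def test_fc_curve_swap_negates_exactly():
    table = _fc_fixture()
    rng_vals = table.values * np.exp(
        np.random.default_rng(9).normal(0, 0.3, table.values.shape)
    )
    table = AbundanceTable(values=rng_vals, design=table.design, species_meta=table.species_meta)
    (fwd,) = fc_by_chain_property(
        table, "total_carbons", ("genotype", "CTRL", "ALD"), chain_counts=(2,)
    )
    (rev,) = fc_by_chain_property(
        table, "total_carbons", ("genotype", "ALD", "CTRL"), chain_counts=(2,)
    )
    assert np.allclose(fwd.mean_log2_fc + rev.mean_log2_fc, 0.0, atol=1e-12)
    assert np.allclose(fwd.loess_fit + rev.loess_fit, 0.0, atol=1e-9)


def test_fc_curve_requires_species_meta():
    table = _fc_fixture()
    table.species_meta = None
    with pytest.raises(ValueError, match="species_meta"):
        fc_by_chain_property(table, "total_carbons", ("genotype", "CTRL", "ALD"))


def test_fc_curve_rejects_empty_contrast_group():
    table = _fc_fixture()
    with pytest.raises(ValueError, match="empty contrast group"):
        fc_by_chain_property(table, "total_carbons", ("genotype", "CTRL", "KO"))


# --------------------------------------------------------------------- PCA


def test_pca_single_axis_of_variation():
    cols = [f"s{i}" for i in range(6)]
    rng = np.random.default_rng(3)
    base = np.tile(rng.lognormal(0, 0.5, (5, 1)), (1, 6))
    base[0, 3:] *= 50.0  # one species separates two sample groups
    values = pd.DataFrame(base, index=[f"PC({30 + 2 * i}:0)" for i in range(5)], columns=cols)
    design = _design(cols, line_ids=["L1"] * 6, timepoints=[1, 2, 3, 4, 5, 6])
    res = pca_scores(AbundanceTable(values=values, design=design))
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
    pc1 = res.scores["PC1"].to_numpy()
    assert np.ptp(np.sign(pc1[:3])) == 0 and np.ptp(np.sign(pc1[3:])) == 0
    assert np.sign(pc1[0]) != np.sign(pc1[-1])


def test_pca_rejects_constant_matrix():
    cols = ["s1", "s2", "s3"]
    values = pd.DataFrame(np.ones((3, 3)), index=["a", "b", "c"], columns=cols)
    design = _design(cols, line_ids=["L1"] * 3, timepoints=[1, 2, 3])
    with pytest.raises(ValueError, match="constant"):
        pca_scores(AbundanceTable(values=values, design=design))


def test_pca_component_cap():
    cols = [f"s{i}" for i in range(4)]
    rng = np.random.default_rng(6)
    values = pd.DataFrame(
        rng.lognormal(0, 1, (10, 4)), index=[f"x{i}(30:0)" for i in range(10)], columns=cols
    )
    design = _design(cols, line_ids=["L1"] * 4, timepoints=[1, 2, 3, 4])
    res = pca_scores(AbundanceTable(values=values, design=design), n_components=99)
    assert res.scores.shape == (4, 3)  # rank limited to n_samples - 1
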