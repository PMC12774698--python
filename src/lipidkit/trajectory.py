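"""Descriptive trajectory analyses: class Z-scores, chain-property fold-change
curves with LOESS smoothing, and PCA of lipid profiles.

These operate on (typically line-median) abundance tables and mirror the
standard exploratory views of a longitudinal lipidomics study: per-class
standardized trajectories over maturation timepoints, log2 fold change as a
function of total acyl carbons or double bonds stratified by the number of
radyl chains, and sample-level ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .quantify import AbundanceTable

__all__ = [
    "ClassTrajectory",
    "TrajectoryCurve",
    "PcaResult",
    "class_zscores",
    "fc_by_chain_property",
    "loess_smooth",
    "pca_scores",
]

log = logging.getLogger(__name__)

DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2


@dataclass
class ClassTrajectory:
    """Class x sample abundance sums and their per-class Z-scores."""

    abundance: pd.DataFrame
    z_matrix: pd.DataFrame
    constant_classes: List[str]


@dataclass
class TrajectoryCurve:
    """Mean log2 fold change vs a chain property, with a LOESS fit."""

    n_chains: int
    property_name: str
    x: np.ndarray
    mean_log2_fc: np.ndarray
    loess_x: np.ndarray
    loess_fit: np.ndarray
    comparison: str


@dataclass
class PcaResult:
    scores: pd.DataFrame           # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame         # species x components


def class_zscores(table: AbundanceTable, class_map: Mapping[str, str]) -> ClassTrajectory:
    """Sum species into classes and Z-score each class across all samples.

    Z uses the sample SD (n-1).  A class with constant abundance across all
    cells gets an all-zero row and is flagged.
    """
    if table.values.shape[1] < 2:
        raise ValueError("need at least two samples to Z-score")
    classes = pd.Series({sp: class_map.get(sp) for sp in table.species}, name="class")
    keep = classes.dropna()
    sums = table.values.loc[keep.index].groupby(keep).sum()
    mean = sums.mean(axis=1)
    sd = sums.std(axis=1, ddof=1)
    constant = sd <= 0
    z = sums.sub(mean, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    const_classes = list(sums.index[constant])
    if const_classes:
        log.warning("constant classes in Z-scoring: %s", const_classes)
    return ClassTrajectory(abundance=sums, z_matrix=z, constant_classes=const_classes)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_smooth(
    x: Sequence[float],
    y: Sequence[float],
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    x_eval: Optional[Sequence[float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Locally weighted polynomial regression with tricube weights.

    For each evaluation point the ``k = floor(span * n)`` nearest inputs are
    weighted by tricube of distance scaled to the neighborhood radius and a
    weighted polynomial of the given degree is fitted.  Returns
    (x_eval sorted, fitted values).  Deterministic; no robustness iterations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    n = x.size
    if np.unique(x).size < max(4, degree + 2):
        raise ValueError(f"need at least {max(4, degree + 2)} distinct x values")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if x_eval is None:
        xe = xs.copy()
    else:
        xe = np.sort(np.asarray(x_eval, float))
    k = int(span * n)
    k = min(max(k, degree + 1), n)
    fitted = np.empty_like(xe)
    for i, x0 in enumerate(xe):
        d = np.abs(xs - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            fitted[i] = ys[d == 0].mean()
            continue
        w = _tricube(d / h)
        idx = w > 0
        if idx.sum() <= degree:
            # not enough support for the full polynomial; weighted mean
            fitted[i] = np.average(ys[w > 0], weights=w[w > 0])
            continue
        # weighted least squares on centered x for numerical stability
        xc = xs[idx] - x0
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w[idx])
        beta, *_ = np.linalg.lstsq(design * sw[:, None], ys[idx] * sw, rcond=None)
        fitted[i] = beta[0]
    return xe, fitted


def fc_by_chain_property(
    table: AbundanceTable,
    property_name: str,
    contrast: Tuple[str, object, object],
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    chain_counts: Sequence[int] = (1, 2, 3),
) -> List[TrajectoryCurve]:
    """Per-species log2 FC between two sample groups, binned by chain property.

    ``property_name`` is ``"total_carbons"`` or ``"double_bonds"``;
    ``contrast = (design_column, reference_value, comparison_value)``, e.g.
    ``("timepoint", 50, 200)`` or ``("genotype", "CTRL", "ALD")``.  Species
    are grouped by the chain count of their class; per (n_chains, x) bin the
    mean log2 FC is reported together with a LOESS fit over the bins.
    Requires ``table.species_meta`` with columns class_code, C, db, n_chains.
    """
    meta = table.species_meta
    if meta is None:
        raise ValueError("table.species_meta is required (class_code, C, db, n_chains)")
    prop_col = {"total_carbons": "C", "double_bonds": "db"}[property_name]
    col, ref_val, cmp_val = contrast
    design = table.design.frame
    ref_samples = design.loc[design[col] == ref_val, "sample_id"]
    cmp_samples = design.loc[design[col] == cmp_val, "sample_id"]
    if len(ref_samples) == 0 or len(cmp_samples) == 0:
        raise ValueError(f"empty contrast group for {col}: {ref_val!r} vs {cmp_val!r}")
    ref_mean = table.values[list(ref_samples)].mean(axis=1)
    cmp_mean = table.values[list(cmp_samples)].mean(axis=1)
    ok = (ref_mean > 0) & (cmp_mean > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("excluding %d species with zero group mean from FC curves", n_excluded)
    log2_fc = np.log2(cmp_mean[ok] / ref_mean[ok])
    meta_ok = meta.loc[meta.index.intersection(log2_fc.index)]
    label = f"{col}:{cmp_val} vs {ref_val}"
    curves: List[TrajectoryCurve] = []
    for nc in chain_counts:
        sp = meta_ok.index[meta_ok["n_chains"] == nc]
        if len(sp) == 0:
            continue
        sub = pd.DataFrame({"x": meta_ok.loc[sp, prop_col], "fc": log2_fc[sp]})
        binned = sub.groupby("x")["fc"].mean().sort_index()
        xs = binned.index.to_numpy(float)
        ys = binned.to_numpy(float)
        if np.unique(xs).size >= max(4, degree + 2):
            lx, lf = loess_smooth(xs, ys, span=span, degree=degree)
        else:
            lx, lf = xs, ys
        curves.append(
            TrajectoryCurve(
                n_chains=nc,
                property_name=property_name,
                x=xs,
                mean_log2_fc=ys,
                loess_x=lx,
                loess_fit=lf,
                comparison=label,
            )
        )
    return curves


def pca_scores(
    table: AbundanceTable,
    log_transform: bool = True,
    n_components: Optional[int] = None,
    scale: bool = False,
) -> PcaResult:
    """PCA of (log-transformed) lipid profiles; samples are observations.

    Zeros are replaced per species by half its smallest nonzero value before
    the log.  Data are species-centered (and optionally scaled to unit SD).
    """
    X = table.values.T  # samples x species
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 species")
    if log_transform:
        vals = X.to_numpy(float).copy()
        for j in range(vals.shape[1]):
            col = vals[:, j]
            nz = col[col > 0]
            fill = nz.min() / 2.0 if nz.size else 1.0
            col[col <= 0] = fill
            vals[:, j] = np.log(col)
        X = pd.DataFrame(vals, index=X.index, columns=X.columns)
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1).replace(0.0, 1.0)
        Xc = Xc / sd
    if Xc.to_numpy().std() == 0:
        raise ValueError("constant matrix: PCA undefined")
    max_rank = min(Xc.shape[0] - 1, Xc.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xc.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=X.columns, columns=comp_names),
    )
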