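"""Per-lipid mixed-effects differential testing with FDR control.

The model follows the study design of donor-line replicates measured over
maturation timepoints: for each lipid species, log abundance is modelled with
a fixed genotype effect (ALD vs CTRL) and a random intercept per donor line,

    per-timepoint mode:  log(y) ~ genotype,                  within one timepoint
    overall mode:        log(y) ~ genotype + C(timepoint),   all timepoints

fitted by REML with a Wald z test on the genotype coefficient.  Effects are
on the natural-log scale; log2 equivalents are reported for plotting.  The
Benjamini-Hochberg step-up correction is applied per contrast across all
species tested.

Exposed statsmodels-style: build a :class:`LipidMixedModel` from an abundance
table, ``fit()`` it, and read estimates, p-values, FDR and diagnostics off the
returned :class:`LipidDifferentialResults` (``summary()`` gives a table).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as scipy_stats
from statsmodels.stats.multitest import multipletests

from .quantify import AbundanceTable, StudyDesign

__all__ = [
    "LipidMixedModel",
    "LipidDifferentialResults",
    "fit_lmm",
    "bh_fdr",
    "volcano_table",
    "bubble_table",
]

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

RESULT_COLUMNS = [
    "species",
    "class_code",
    "C",
    "db",
    "contrast",
    "effect_ln",
    "log2_fc",
    "p",
    "fdr",
    "mode",
    "fit_flag",
    "n_obs",
]


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fill_and_log(values: pd.Series) -> Optional[pd.Series]:
    """Missing-value policy: zeros/NaN -> half the smallest positive value."""
    v = values.astype(float).copy()
    pos = v[v > 0]
    if pos.empty:
        return None
    v[(v <= 0) | v.isna()] = pos.min() / 2.0
    return np.log(v)


def fit_lmm(
    values: pd.Series,
    design: StudyDesign,
    mode: str = "per-timepoint",
    timepoint: Optional[int] = None,
) -> Tuple[float, float, str, int]:
    """Fit the genotype LMM for one lipid; returns (effect_ln, p, flag, n_obs).

    ``values`` is indexed by sample_id.  In ``per-timepoint`` mode the fit is
    restricted to ``timepoint``; in ``overall`` mode timepoint enters as a
    categorical fixed effect.  On a singular or non-converging mixed fit the
    model falls back to fixed-effects OLS and flags the row "ols_fallback".
    """
    frame = design.frame.copy()
    if mode == "per-timepoint":
        if timepoint is None:
            raise ValueError("per-timepoint mode requires a timepoint")
        frame = frame[frame["timepoint"] == timepoint]
    elif mode != "overall":
        raise ValueError(f"unknown mode {mode!r}")
    frame = frame[frame["sample_id"].isin(values.index)]
    for g in ("CTRL", "ALD"):
        if frame.loc[frame["genotype"] == g, "line_id"].nunique() < 2:
            raise ValueError(f"need at least 2 lines per genotype (missing {g})")
    logy = _fill_and_log(values.loc[frame["sample_id"]])
    if logy is None:
        raise ValueError("all-zero lipid; nothing to fit")
    if float(np.ptp(logy.to_numpy())) == 0.0:
        raise ValueError("constant lipid (e.g. an internal standard); nothing to test")
    data = frame.assign(logy=logy.to_numpy())
    fixed = "logy ~ C(genotype, Treatment('CTRL'))"
    if mode == "overall" and data["timepoint"].nunique() > 1:
        fixed += " + C(timepoint)"
    term = "C(genotype, Treatment('CTRL'))[T.ALD]"
    n_lines = data["line_id"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(fixed, data, groups=data["line_id"])
            res = model.fit(reml=True)
            if not res.converged:
                res = model.fit(reml=True, method="lbfgs")
            effect = float(res.fe_params[term])
            se = float(res.bse[term])
            if not (res.converged and np.isfinite(effect) and np.isfinite(se) and se > 0):
                raise ValueError("mixed fit did not converge")
            # Wald statistic referred to t with between-line (containment) df:
            # the genotype contrast is estimated between donor lines, so the
            # asymptotic z reference is anti-conservative at a dozen lines.
            df = max(n_lines - 2, 1)
            p = float(2.0 * scipy_stats.t.sf(abs(effect / se), df=df))
            flag = "ok"
        except Exception:
            res = smf.ols(fixed, data).fit()
            effect = float(res.params[term])
            p = float(res.pvalues[term])
            flag = "ols_fallback"
    return effect, p, flag, len(data)


@dataclass
class LipidDifferentialResults:
    """Result table of per-lipid genotype contrasts with BH-FDR.

    ``frame`` has one row per (species, contrast); FDR is corrected within
    each contrast across all species.
    """

    frame: pd.DataFrame
    mode: str
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        cols = [c for c in RESULT_COLUMNS if c in self.frame.columns]
        return self.frame[cols].sort_values(["contrast", "fdr", "species"]).reset_index(drop=True)

    def significant(self, threshold: Optional[float] = None) -> pd.DataFrame:
        thr = self.alpha if threshold is None else threshold
        return self.frame[self.frame["fdr"] <= thr]

    def volcano_table(self) -> pd.DataFrame:
        return volcano_table(self.frame)

    def bubble_table(
        self, classes: Sequence[str] = ("CE", "PC", "TG"), contrast: Optional[str] = None
    ) -> pd.DataFrame:
        return bubble_table(self.frame, classes=classes, contrast=contrast)


class LipidMixedModel:
    """Per-lipid genotype mixed model over an abundance table.

    Parameters
    ----------
    table:
        Abundance table (replicate-level or line-median) with study design
        and optionally ``species_meta`` (class_code, C, db).
    mode:
        "per-timepoint" (one contrast per timepoint) or "overall" (single
        group contrast with timepoint as categorical covariate).
    """

    def __init__(self, table: AbundanceTable, mode: str = "per-timepoint") -> None:
        if mode not in ("per-timepoint", "overall"):
            raise ValueError(f"unknown mode {mode!r}")
        self.table = table
        self.mode = mode

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        design: StudyDesign,
        species_meta: Optional[pd.DataFrame] = None,
        mode: str = "per-timepoint",
    ) -> "LipidMixedModel":
        return cls(AbundanceTable(values=values, design=design, species_meta=species_meta), mode)

    def fit(self, species: Optional[Sequence[str]] = None) -> LipidDifferentialResults:
        table = self.table
        names = list(species) if species is not None else table.species
        meta = table.species_meta
        design = table.design
        timepoints = sorted(design.frame["timepoint"].unique())
        contrasts: List[Tuple[str, Optional[int]]]
        if self.mode == "per-timepoint":
            contrasts = [(f"ALD vs CTRL @ day {tp}", tp) for tp in timepoints]
        else:
            contrasts = [("ALD vs CTRL overall", None)]
        rows = []
        for label, tp in contrasts:
            for name in names:
                values = table.values.loc[name]
                try:
                    effect, p, flag, n_obs = fit_lmm(
                        values, design, mode=self.mode, timepoint=tp
                    )
                except ValueError as exc:
                    log.debug("skipping %s (%s): %s", name, label, exc)
                    continue
                row = {
                    "species": name,
                    "contrast": label,
                    "timepoint": tp,
                    "effect_ln": effect,
                    "log2_fc": effect / LN2,
                    "p": p,
                    "mode": self.mode,
                    "fit_flag": flag,
                    "n_obs": n_obs,
                }
                if meta is not None and name in meta.index:
                    row["class_code"] = meta.loc[name, "class_code"]
                    row["C"] = int(meta.loc[name, "C"])
                    row["db"] = int(meta.loc[name, "db"])
                rows.append(row)
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame["fdr"] = np.nan
            for label in frame["contrast"].unique():
                mask = frame["contrast"] == label
                frame.loc[mask, "fdr"] = bh_fdr(frame.loc[mask, "p"].to_numpy())
        return LipidDifferentialResults(frame=frame, mode=self.mode)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(species, contrast) rows of log2 FC vs -log10 p, class attached."""
    out = results.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    cols = ["species", "contrast", "log2_fc", "neg_log10_p", "p", "fdr"]
    if "class_code" in out.columns:
        cols.append("class_code")
    return out[cols].reset_index(drop=True)


def bubble_table(
    results: pd.DataFrame,
    classes: Sequence[str] = ("CE", "PC", "TG"),
    contrast: Optional[str] = None,
) -> pd.DataFrame:
    """Per-(class, C, db) rows with log2 FC and -log10 p for bubble plots."""
    if "class_code" not in results.columns:
        raise ValueError("results lack species metadata (class_code, C, db)")
    known = set(results["class_code"].dropna())
    for cls in classes:
        if cls not in known:
            log.warning("no tested species for requested class %r", cls)
    sub = results[results["class_code"].isin(classes)].copy()
    if contrast is not None:
        sub = sub[sub["contrast"] == contrast]
    with np.errstate(divide="ignore"):
        sub["neg_log10_p"] = -np.log10(sub["p"])
    cols = ["class_code", "C", "db", "contrast", "log2_fc", "neg_log10_p", "fdr"]
    return sub[cols].sort_values(["class_code", "C", "db"]).reset_index(drop=True)
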