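"""End-to-end pipeline: build-db -> annotate -> normalize -> trajectory -> stats.

A :class:`PipelineConfig` is validated on load (unknown keys rejected) and the
run writes every result table plus a machine-readable manifest.  All stages
are deterministic for fixed inputs and seed, so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import match_features
from .differential import LipidMixedModel
from .io import (
    class_to_standard_map,
    load_default_adducts,
    load_default_classes,
    load_default_standards,
    read_adducts,
    read_class_definitions,
    read_design,
    read_feature_table,
    read_standards,
    species_meta_from_classes,
    standard_extra_species,
    write_abundance_table,
    write_annotations,
)
from .annotation import build_database
from .chem import expand_class
from .quantify import median_by_line, quantify_table
from .trajectory import class_zscores, fc_by_chain_property, pca_scores

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    feature_file: str
    design_file: str
    out_dir: str
    class_file: Optional[str] = None
    adduct_file: Optional[str] = None
    standards_file: Optional[str] = None
    tol_ppm: float = 5.0
    loess_span: float = 0.75
    loess_degree: int = 2
    lmm_mode: str = "per-timepoint"
    lmm_level: str = "replicate"  # or "line-median"
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if not (0 < self.loess_span <= 1):
            raise ValueError("loess_span must be in (0, 1]")
        if self.loess_degree < 0:
            raise ValueError("loess_degree must be non-negative")
        if self.lmm_mode not in ("per-timepoint", "overall"):
            raise ValueError(f"unknown lmm_mode {self.lmm_mode!r}")
        if self.lmm_level not in ("replicate", "line-median"):
            raise ValueError(f"unknown lmm_level {self.lmm_level!r}")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Artifacts: annotations.tsv, unmatched.tsv, abundance.tsv,
    line_medians.tsv, class_zscores.tsv, fc_curves.tsv, pca_scores.tsv,
    differential.tsv, manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "tool": "lipidkit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }

    # stage 1: build-db
    stage = "build-db"
    try:
        classes = (
            read_class_definitions(config.class_file)
            if config.class_file
            else load_default_classes()
        )
        adducts = (
            read_adducts(config.adduct_file)
            if config.adduct_file
            else load_default_adducts()
        )
        mix, std_formulas = (
            read_standards(config.standards_file)
            if config.standards_file
            else load_default_standards()
        )
        grid_names = frozenset(
            sp.name for defn in classes for sp in expand_class(defn)
        )
        extra = standard_extra_species(classes, std_formulas, grid_names)
        db = build_database(classes, adducts, extra_species=extra)
        manifest["stages"].append({"name": stage, "n_candidates": len(db)})
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # stage 2: annotate
    stage = "annotate"
    try:
        features = read_feature_table(config.feature_file)
        design = read_design(config.design_file)
        annotations, unmatched = match_features(features, db, tol_ppm=config.tol_ppm)
        annotations.sort(key=lambda a: a.feature_id)
        write_annotations(annotations, out / "annotations.tsv")
        pd.DataFrame({"feature_id": sorted(f.feature_id for f in unmatched)}).to_csv(
            out / "unmatched.tsv", sep="\t", index=False
        )
        manifest["stages"].append(
            {"name": stage, "n_features": len(features), "n_annotated": len(annotations)}
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # stage 3: normalize
    stage = "normalize"
    try:
        cls_to_std = class_to_standard_map(classes)
        n_chain_of = species_meta_from_classes(classes)
        meta_rows = {}
        for a in annotations:
            meta_rows[a.species_name] = {
                "class_code": a.class_code,
                "C": a.total_carbons,
                "db": a.total_double_bonds,
                "n_chains": n_chain_of.get(a.class_code, 0),
            }
        species_meta = pd.DataFrame.from_dict(meta_rows, orient="index").sort_index()
        species_meta.index.name = "species"
        table = quantify_table(
            annotations, features, design, mix, cls_to_std, species_meta=species_meta
        )
        table.values = table.values.sort_index()
        write_abundance_table(table, out / "abundance.tsv")
        medians = median_by_line(table)
        write_abundance_table(medians, out / "line_medians.tsv")
        manifest["stages"].append({"name": stage, "n_species": len(table.species)})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # stage 4: trajectory
    stage = "trajectory"
    try:
        class_map = dict(zip(species_meta.index, species_meta["class_code"]))
        traj = class_zscores(medians, class_map)
        traj.z_matrix.sort_index().to_csv(out / "class_zscores.tsv", sep="\t", float_format="%.10g")

        tps = sorted(medians.design.frame["timepoint"].unique())
        curve_rows: List[Dict] = []
        contrasts: List[Tuple[str, object, object]] = [
            ("timepoint", tps[0], tp) for tp in tps[1:]
        ]
        genos = set(medians.design.frame["genotype"])
        if {"CTRL", "ALD"} <= genos:
            contrasts.append(("genotype", "CTRL", "ALD"))
        for contrast in contrasts:
            for prop in ("total_carbons", "double_bonds"):
                curves = fc_by_chain_property(
                    medians, prop, contrast,
                    span=config.loess_span, degree=config.loess_degree,
                )
                for c in curves:
                    for x, y in zip(c.x, c.mean_log2_fc):
                        curve_rows.append(
                            {"comparison": c.comparison, "property": prop,
                             "n_chains": c.n_chains, "kind": "bin", "x": x, "value": y}
                        )
                    for x, y in zip(c.loess_x, c.loess_fit):
                        curve_rows.append(
                            {"comparison": c.comparison, "property": prop,
                             "n_chains": c.n_chains, "kind": "loess", "x": x, "value": y}
                        )
        pd.DataFrame(curve_rows).to_csv(
            out / "fc_curves.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pca = pca_scores(medians)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.10g")
        manifest["stages"].append(
            {"name": stage, "n_classes": int(traj.z_matrix.shape[0]),
             "pc1_var": round(float(pca.explained_variance_ratio[0]), 6)}
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # stage 5: stats
    stage = "stats"
    try:
        level_table = table if config.lmm_level == "replicate" else medians
        genos = {
            g: level_table.design.frame.loc[
                level_table.design.frame["genotype"] == g, "line_id"
            ].nunique()
            for g in ("CTRL", "ALD")
        }
        if min(genos.values()) >= 2:
            model = LipidMixedModel(level_table, mode=config.lmm_mode)
            results = model.fit()
            results.summary().to_csv(
                out / "differential.tsv", sep="\t", index=False, float_format="%.10g"
            )
            n_sig = int((results.frame["fdr"] <= config.fdr_threshold).sum())
            manifest["stages"].append(
                {"name": stage, "n_tests": int(len(results.frame)), "n_significant": n_sig}
            )
        else:
            (out / "differential.tsv").write_text(
                "\t".join(["species", "contrast", "effect_ln", "log2_fc", "p", "fdr"]) + "\n"
            )
            manifest["stages"].append(
                {"name": stage, "skipped": "fewer than 2 lines per genotype"}
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
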