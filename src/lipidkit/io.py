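"""Readers and writers for the package's tabular formats and shipped configs.

All tables are UTF-8, tab-separated, '.' decimal.  Class definitions, the
adduct table and the internal-standard mix ship as editable TSV files under
``lipidkit/data`` and can be overridden per analysis.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .annotation import Annotation, Feature
from .chem import (
    AdductSpec,
    ElementalFormula,
    LipidClassDefinition,
    LipidSpecies,
    DEFAULT_MASS_TABLE,
    parse_formula,
    parse_species_name,
)
from .quantify import AbundanceTable, StandardsMix, StudyDesign, DESIGN_COLUMNS

__all__ = [
    "read_class_definitions",
    "load_default_classes",
    "read_adducts",
    "load_default_adducts",
    "read_standards",
    "load_default_standards",
    "standard_extra_species",
    "class_to_standard_map",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "write_design",
    "write_abundance_table",
    "read_abundance_table",
    "write_annotations",
    "species_meta_from_classes",
]

PathLike = Union[str, Path]


def _data_path(name: str):
    return resources.files("lipidkit.data").joinpath(name)


# ---------------------------------------------------------------- configs


def _split_adducts(cell) -> Tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return ()
    return tuple(s.strip() for s in str(cell).split(",") if s.strip())


def read_class_definitions(path: PathLike) -> List[LipidClassDefinition]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {
        "class_code", "base_formula", "n_chains", "c_min", "c_max",
        "db_min", "db_max", "adducts_pos", "adducts_neg", "internal_standard",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"class file missing columns: {sorted(missing)}")
    defs = []
    for _, row in frame.iterrows():
        base = (
            parse_formula(row["base_formula"])
            if row["base_formula"].strip()
            else ElementalFormula({})
        )
        defs.append(
            LipidClassDefinition(
                class_code=row["class_code"],
                base_formula=base,
                n_chains=int(row["n_chains"]),
                carbon_range=(int(row["c_min"]), int(row["c_max"])),
                db_range=(int(row["db_min"]), int(row["db_max"])),
                adducts_pos=_split_adducts(row["adducts_pos"]),
                adducts_neg=_split_adducts(row["adducts_neg"]),
                internal_standard=row["internal_standard"].strip() or None,
            )
        )
    codes = [d.class_code for d in defs]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate class codes in class file")
    return defs


def load_default_classes() -> List[LipidClassDefinition]:
    with resources.as_file(_data_path("lipid_classes.tsv")) as p:
        return read_class_definitions(p)


def read_adducts(path: PathLike) -> Dict[str, AdductSpec]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, AdductSpec] = {}
    for _, row in frame.iterrows():
        delta_text = str(row["delta_formula"]).strip()
        delta = ElementalFormula({}) if delta_text in ("", "-") else parse_formula(delta_text)
        out[row["name"]] = AdductSpec(
            name=row["name"],
            delta_formula=delta,
            sign=int(row["sign"]),
            z=int(row["z"]),
            n_M=int(row["n_M"]),
        )
    return out


def load_default_adducts() -> Dict[str, AdductSpec]:
    with resources.as_file(_data_path("adducts.tsv")) as p:
        return read_adducts(p)


def read_standards(path: PathLike) -> Tuple[StandardsMix, Dict[str, ElementalFormula]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    amounts, formulas = {}, {}
    for _, row in frame.iterrows():
        amounts[row["name"]] = float(row["nmol"])
        formulas[row["name"]] = parse_formula(row["formula"])
    return StandardsMix(amounts), formulas


def load_default_standards() -> Tuple[StandardsMix, Dict[str, ElementalFormula]]:
    with resources.as_file(_data_path("standards.tsv")) as p:
        return read_standards(p)


def class_to_standard_map(classes: Sequence[LipidClassDefinition]) -> Dict[str, str]:
    return {
        d.class_code: d.internal_standard
        for d in classes
        if d.internal_standard is not None
    }


def standard_extra_species(
    classes: Sequence[LipidClassDefinition],
    standard_formulas: Mapping[str, ElementalFormula],
    grid_names: frozenset,
) -> List[Tuple[LipidSpecies, Tuple[str, ...]]]:
    """Standards absent from the enumeration grid, as extra DB species.

    Each such standard (e.g. the deuterated cholesteryl ester) is attached to
    the adduct set of the class it normalizes.
    """
    std_class: Dict[str, LipidClassDefinition] = {}
    for d in classes:
        if d.internal_standard is not None:
            std_class.setdefault(d.internal_standard, d)
    extra = []
    for name, formula in standard_formulas.items():
        if name in grid_names:
            continue
        defn = std_class.get(name)
        if defn is None:
            continue
        try:
            _, c, db = parse_species_name(name.split("-d")[0])
        except ValueError:
            c, db = 0, 0
        sp = LipidSpecies(
            class_code=defn.class_code,
            total_carbons=c,
            total_double_bonds=db,
            neutral_formula=formula,
            neutral_mass=DEFAULT_MASS_TABLE.mass(formula),
            name_override=name,
        )
        extra.append((sp, tuple(defn.adducts_pos) + tuple(defn.adducts_neg)))
    return extra


def species_meta_from_classes(classes: Sequence[LipidClassDefinition]) -> Dict[str, int]:
    """class_code -> n_chains lookup."""
    return {d.class_code: d.n_chains for d in classes}


# ---------------------------------------------------------------- features


def read_feature_table(path: PathLike) -> List[Feature]:
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    required = ["feature_id", "mz", "polarity", "rt"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if frame["feature_id"].duplicated().any():
        dup = frame.loc[frame["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"duplicate feature_id {dup!r}")
    sample_cols = [c for c in frame.columns if c not in required]
    mz = pd.to_numeric(frame["mz"], errors="coerce")
    if mz.isna().any():
        bad = frame.loc[mz.isna(), "feature_id"].iloc[0]
        raise ValueError(f"non-numeric m/z for feature {bad!r}")
    features = []
    for _, row in frame.iterrows():
        features.append(
            Feature(
                feature_id=str(row["feature_id"]),
                mz=float(row["mz"]),
                polarity=str(row["polarity"]),
                rt=float(row["rt"]),
                areas={s: float(row[s]) for s in sample_cols},
            )
        )
    return features


def write_feature_table(
    features: Sequence[Feature], path: PathLike, samples: Optional[Sequence[str]] = None
) -> None:
    if samples is None:
        samples = sorted({s for f in features for s in f.areas})
    rows = []
    for f in features:
        row = {
            "feature_id": f.feature_id,
            "mz": f.mz,
            "polarity": f.polarity,
            "rt": f.rt,
        }
        row.update({s: f.areas.get(s, 0.0) for s in samples})
        rows.append(row)
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------- design


def read_design(path: PathLike) -> StudyDesign:
    sep = "," if str(path).endswith(".csv") else "\t"
    return StudyDesign(pd.read_csv(path, sep=sep))


def write_design(design: StudyDesign, path: PathLike) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    design.frame.to_csv(path, sep=sep, index=False)


# ------------------------------------------------------------- abundances


def write_abundance_table(table: AbundanceTable, path: PathLike) -> None:
    """TSV with the design embedded as a '#design:' header block (lossless)."""
    buf = _io.StringIO()
    design_csv = table.design.frame.to_csv(sep=";", index=False).strip().split("\n")
    for line in design_csv:
        buf.write(f"#design:{line}\n")
    table.values.to_csv(buf, sep="\t", float_format="%.12g")
    Path(path).write_text(buf.getvalue())


def read_abundance_table(
    path: PathLike, species_meta: Optional[pd.DataFrame] = None
) -> AbundanceTable:
    design_lines, body = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#design:"):
            design_lines.append(line[len("#design:"):])
        else:
            body.append(line)
    if not design_lines:
        raise ValueError(f"{path}: missing '#design:' header block")
    design = StudyDesign(pd.read_csv(_io.StringIO("\n".join(design_lines)), sep=";"))
    values = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", index_col=0)
    return AbundanceTable(values=values, design=design, species_meta=species_meta)


# ------------------------------------------------------------ annotations


def write_annotations(annotations: Sequence[Annotation], path: PathLike) -> None:
    rows = [
        {
            "feature_id": a.feature_id,
            "species": a.species_name,
            "adduct": a.adduct_name,
            "class_code": a.class_code,
            "C": a.total_carbons,
            "db": a.total_double_bonds,
            "theoretical_mz": a.theoretical_mz,
            "ppm_error": a.ppm_error,
            "ambiguity_count": a.ambiguity_count,
            "rt_pass": "" if a.rt_pass is None else str(a.rt_pass),
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
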