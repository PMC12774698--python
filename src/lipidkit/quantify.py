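"""Internal-standard semi-quantification and replicate aggregation.

Peak areas are converted to arbitrary units (A.U.) by dividing the analyte
response by the response of the class's internal standard in the same sample
and multiplying by the spiked amount (nmol).  Values are therefore invariant
to any per-sample detector drift that scales analyte and standard alike.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import Annotation, Feature

__all__ = [
    "StandardsMix",
    "StudyDesign",
    "AbundanceTable",
    "normalize_to_standard",
    "quantify_table",
    "median_by_line",
]

log = logging.getLogger(__name__)

DESIGN_COLUMNS = ["sample_id", "line_id", "genotype", "region", "timepoint", "replicate"]
GENOTYPES = ("CTRL", "ALD")


@dataclass(frozen=True)
class StandardsMix:
    """Internal-standard species -> amount spiked per sample (nmol)."""

    amounts: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, amt in self.amounts.items():
            if amt <= 0:
                raise ValueError(f"standard {name!r}: amount must be positive")

    def amount(self, name: str) -> float:
        return self.amounts[name]

    def __contains__(self, name: str) -> bool:
        return name in self.amounts


class StudyDesign:
    """Sample -> (donor line, genotype, region, timepoint, replicate) table."""

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"design is missing columns: {missing}")
        frame = frame[DESIGN_COLUMNS].copy()
        frame["timepoint"] = frame["timepoint"].astype(int)
        frame["replicate"] = frame["replicate"].astype(int)
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in design")
        key = frame[["line_id", "region", "timepoint", "replicate"]]
        if key.duplicated().any():
            raise ValueError("duplicate (line, region, timepoint, replicate) in design")
        bad = set(frame["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype values: {sorted(bad)}")
        per_line = frame.groupby("line_id")["genotype"].nunique()
        if (per_line > 1).any():
            raise ValueError("genotype must be constant within a donor line")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.frame["sample_id"])

    def subset(self, mask: pd.Series) -> "StudyDesign":
        return StudyDesign(self.frame[mask.values].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class AbundanceTable:
    """Species x sample matrix of semi-quantitative values plus the design.

    ``values`` is indexed by canonical species name with one column per
    sample_id; every column must appear in the design.
    """

    values: pd.DataFrame
    design: StudyDesign
    species_meta: Optional[pd.DataFrame] = None  # index species, cols class_code, C, db, n_chains

    def __post_init__(self) -> None:
        known = set(self.design.sample_ids)
        extra = [c for c in self.values.columns if c not in known]
        if extra:
            raise ValueError(f"samples absent from design: {extra[:5]}")
        if (self.values.values < 0).any():
            raise ValueError("abundances must be non-negative")
        self.values = self.values.loc[:, [s for s in self.design.sample_ids if s in self.values.columns]]

    @property
    def species(self) -> List[str]:
        return list(self.values.index)

    def long_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per (species, sample) with design columns."""
        long = self.values.reset_index(names="species").melt(
            id_vars="species", var_name="sample_id", value_name="value"
        )
        return long.merge(self.design.frame, on="sample_id", how="left")


def normalize_to_standard(analyte_area: float, is_area: float, is_amount: float) -> float:
    """analyte_area / is_area * is_amount, in A.U."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if is_amount <= 0:
        raise ValueError("internal-standard amount must be positive")
    if analyte_area < 0:
        raise ValueError("analyte area must be non-negative")
    return analyte_area / is_area * is_amount


def _best_feature_per_species(
    annotations: Sequence[Annotation], features: Mapping[str, Feature]
) -> Dict[str, Feature]:
    """Per species, the annotated feature with the smallest |ppm error|."""
    best: Dict[str, Annotation] = {}
    for a in annotations:
        cur = best.get(a.species_name)
        if cur is None or (abs(a.ppm_error), a.feature_id) < (abs(cur.ppm_error), cur.feature_id):
            best[a.species_name] = a
    return {name: features[a.feature_id] for name, a in best.items()}


def quantify_table(
    annotations: Sequence[Annotation],
    features: Sequence[Feature],
    design: StudyDesign,
    mix: StandardsMix,
    class_to_standard: Mapping[str, str],
    species_meta: Optional[pd.DataFrame] = None,
) -> AbundanceTable:
    """Convert annotated peak areas to A.U. against each class's standard.

    Classes whose standard was not itself annotated among the features are
    dropped with a warning.  A sample in which the standard's area is zero
    gets NaN for every species of that class (recorded, not fatal).
    """
    feat_by_id = {f.feature_id: f for f in features}
    species_feature = _best_feature_per_species(annotations, feat_by_id)
    samples = design.sample_ids

    std_areas: Dict[str, np.ndarray] = {}
    for std_name in set(class_to_standard.values()):
        f = species_feature.get(std_name)
        if f is None:
            continue
        std_areas[std_name] = np.array([f.areas.get(s, 0.0) for s in samples], float)

    ann_by_species = {a.species_name: a for a in annotations}
    rows: Dict[str, np.ndarray] = {}
    dropped_classes = set()
    for name, f in sorted(species_feature.items()):
        cls = ann_by_species[name].class_code
        std_name = class_to_standard.get(cls)
        if std_name is None or std_name not in std_areas:
            dropped_classes.add(cls)
            continue
        is_area = std_areas[std_name]
        amount = mix.amount(std_name)
        areas = np.array([f.areas.get(s, 0.0) for s in samples], float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(is_area > 0, areas / np.where(is_area > 0, is_area, 1.0) * amount, np.nan)
        rows[name] = vals
    if dropped_classes:
        log.warning(
            "dropped classes without an annotated internal standard: %s",
            sorted(dropped_classes),
        )
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    values.index.name = "species"
    if species_meta is not None:
        species_meta = species_meta.loc[species_meta.index.intersection(values.index)]
    return AbundanceTable(values=values, design=design, species_meta=species_meta)


def median_by_line(table: AbundanceTable) -> AbundanceTable:
    """Collapse replicates to one profile per (line, region, timepoint).

    Element-wise median; with an even replicate count this is the mean of the
    central pair (numpy convention).  The collapsed design keeps one pseudo-
    sample per group with replicate index 0.
    """
    design = table.design.frame
    groups = design.groupby(["line_id", "region", "timepoint"], sort=True)
    new_cols = {}
    new_design_rows = []
    for (line, region, tp), sub in groups:
        sample_ids = [s for s in sub["sample_id"] if s in table.values.columns]
        if not sample_ids:
            continue
        label = f"{line}_{region}_d{tp}"
        new_cols[label] = table.values[sample_ids].median(axis=1)
        new_design_rows.append(
            {
                "sample_id": label,
                "line_id": line,
                "genotype": sub["genotype"].iloc[0],
                "region": region,
                "timepoint": tp,
                "replicate": 0,
            }
        )
    values = pd.DataFrame(new_cols)
    values.index.name = "species"
    new_design = StudyDesign(pd.DataFrame(new_design_rows))
    return AbundanceTable(values=values, design=new_design, species_meta=table.species_meta)
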