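"""Candidate m/z database construction and accurate-mass feature annotation.

The database holds one entry per (species, adduct) combination, sorted by
theoretical m/z within each polarity so tolerance windows become binary
searches.  Features are matched to the candidate with the smallest absolute
ppm error inside the tolerance; ties break on (class_code, adduct name) and
every in-tolerance candidate is counted in ``ambiguity_count``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .chem import (
    DEFAULT_MASS_TABLE,
    AdductSpec,
    ElementalFormula,
    IsotopeMassTable,
    LipidClassDefinition,
    LipidSpecies,
    adduct_mz,
    expand_class,
    default_max_db,
)

__all__ = [
    "CandidateEntry",
    "CandidateDB",
    "Feature",
    "Annotation",
    "build_database",
    "ppm_error",
    "match_features",
]

DEFAULT_TOL_PPM = 5.0  # Orbitrap-class accuracy


@dataclass(frozen=True)
class CandidateEntry:
    species: LipidSpecies
    adduct: AdductSpec
    mz: float

    @property
    def polarity(self) -> str:
        return self.adduct.polarity


@dataclass(frozen=True)
class Feature:
    """One picked LC-MS feature with per-sample peak areas."""

    feature_id: str
    mz: float
    polarity: str
    rt: float
    areas: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: m/z must be positive")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: polarity must be '+' or '-'")


@dataclass(frozen=True)
class Annotation:
    feature_id: str
    species_name: str
    adduct_name: str
    class_code: str
    total_carbons: int
    total_double_bonds: int
    theoretical_mz: float
    ppm_error: float
    ambiguity_count: int
    rt_pass: Optional[bool] = None  # None = not evaluated


class CandidateDB:
    """Sorted per-polarity index over candidate (species, adduct) m/z values."""

    def __init__(self, entries: Iterable[CandidateEntry]) -> None:
        self._by_polarity: Dict[str, List[CandidateEntry]] = {"+": [], "-": []}
        seen = set()
        for e in entries:
            key = (e.species.name, e.adduct.name)
            if key in seen:
                raise ValueError(f"duplicate candidate entry {key}")
            seen.add(key)
            self._by_polarity[e.polarity].append(e)
        for pol in self._by_polarity:
            self._by_polarity[pol].sort(key=lambda e: (e.mz, e.species.class_code, e.adduct.name))
        self._mz_index = {
            pol: [e.mz for e in lst] for pol, lst in self._by_polarity.items()
        }

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_polarity.values())

    def entries(self, polarity: Optional[str] = None) -> List[CandidateEntry]:
        if polarity is None:
            return self._by_polarity["+"] + self._by_polarity["-"]
        return list(self._by_polarity[polarity])

    def query_window(self, polarity: str, lo: float, hi: float) -> List[CandidateEntry]:
        """All candidates with lo <= m/z <= hi in one polarity (binary search)."""
        mzs = self._mz_index[polarity]
        i = bisect.bisect_left(mzs, lo)
        j = bisect.bisect_right(mzs, hi)
        return self._by_polarity[polarity][i:j]

    def query_ppm(self, polarity: str, mz: float, tol_ppm: float) -> List[CandidateEntry]:
        """Candidates whose |ppm_error| relative to ``mz`` is <= tol_ppm."""
        half = mz * tol_ppm * 1e-6 / (1.0 - tol_ppm * 1e-6)
        window = self.query_window(polarity, mz - half - 1e-9, mz + half + 1e-9)
        return [c for c in window if abs(ppm_error(mz, c.mz)) <= tol_ppm]


def build_database(
    classes: Sequence[LipidClassDefinition],
    adducts: Mapping[str, AdductSpec],
    constraint=default_max_db,
    extra_species: Sequence[Tuple[LipidSpecies, Sequence[str]]] = (),
    table: IsotopeMassTable = DEFAULT_MASS_TABLE,
) -> CandidateDB:
    """Expand every class and emit one entry per (species, adduct).

    ``extra_species`` carries molecules outside the enumeration grid (e.g. a
    deuterated internal standard) as (species, adduct-name list) pairs.
    """
    codes = [c.class_code for c in classes]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate class codes in class list")
    entries: List[CandidateEntry] = []
    for defn in classes:
        species = expand_class(defn, constraint=constraint, table=table)
        names = list(defn.adducts_pos) + list(defn.adducts_neg)
        for sp in species:
            for an in names:
                a = adducts[an]
                entries.append(CandidateEntry(sp, a, adduct_mz(sp.neutral_mass, a, table)))
    for sp, adduct_names in extra_species:
        for an in adduct_names:
            a = adducts[an]
            entries.append(CandidateEntry(sp, a, adduct_mz(sp.neutral_mass, a, table)))
    return CandidateDB(entries)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def match_features(
    features: Sequence[Feature],
    db: CandidateDB,
    tol_ppm: float = DEFAULT_TOL_PPM,
    rt_windows: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> Tuple[List[Annotation], List[Feature]]:
    """Annotate features by accurate mass; returns (annotations, unmatched).

    Each feature receives the in-tolerance candidate with the smallest
    |ppm error|; exact ties break lexicographically on (class_code, adduct
    name).  When ``rt_windows`` is given, candidates of classes whose window
    excludes the feature's retention time are rejected and ``rt_pass`` is
    reported on the annotation.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    annotated: List[Annotation] = []
    unmatched: List[Feature] = []
    for f in features:
        cands = db.query_ppm(f.polarity, f.mz, tol_ppm)
        rt_pass: Optional[bool] = None
        if rt_windows is not None:
            kept = []
            for c in cands:
                win = rt_windows.get(c.species.class_code)
                if win is None or (win[0] <= f.rt <= win[1]):
                    kept.append(c)
            rt_pass = bool(kept) if cands else None
            cands = kept
        if not cands:
            unmatched.append(f)
            continue
        best = min(
            cands,
            key=lambda c: (
                abs(ppm_error(f.mz, c.mz)),
                c.species.class_code,
                c.adduct.name,
            ),
        )
        annotated.append(
            Annotation(
                feature_id=f.feature_id,
                species_name=best.species.name,
                adduct_name=best.adduct.name,
                class_code=best.species.class_code,
                total_carbons=best.species.total_carbons,
                total_double_bonds=best.species.total_double_bonds,
                theoretical_mz=best.mz,
                ppm_error=ppm_error(f.mz, best.mz),
                ambiguity_count=len(cands),
                rt_pass=rt_pass,
            )
        )
    return annotated, unmatched
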