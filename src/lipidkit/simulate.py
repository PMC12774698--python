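"""Seeded generators emulating the study's design with a known ground truth.

Two levels are provided:

* :func:`simulate_study` draws a species x sample abundance table with the
  longitudinal structure the differential model assumes: per-class timepoint
  trajectories, donor-line random intercepts, lognormal residual noise, and a
  genotype effect that grows linearly with total radyl carbons above a
  chain-count-specific threshold (the very long-chain fatty acid signature).
* :func:`simulate_feature_spectra` turns abundances into a raw-like picked
  feature table against a candidate database: accurate masses perturbed at
  ppm scale, internal-standard features, per-sample detector drift, and
  optional decoy features placed away from every candidate.

Every draw comes from one seeded generator, so truth objects plus the seed
reproduce any table bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import CandidateDB, CandidateEntry, Feature
from .chem import LipidClassDefinition, LipidSpecies, expand_class
from .quantify import AbundanceTable, StandardsMix, StudyDesign

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "make_design",
    "simulation_species",
    "simulate_study",
    "simulate_lipid",
    "simulate_feature_spectra",
    "well_separated_panel",
    "class_rt_centers",
    "true_effect_log2",
    "DEFAULT_TRAJECTORIES",
    "VLCFA_THRESHOLDS",
]

LN2 = float(np.log(2.0))

# Chain-length thresholds (total radyl carbons) above which the genotype
# effect accrues, per chain count: single-chain species beyond C26,
# two-chain beyond C46, three-chain beyond C62.
VLCFA_THRESHOLDS: Dict[int, int] = {1: 26, 2: 46, 3: 62}

# Qualitative per-class log2 trajectories relative to day 50: storage lipids
# decline with maturation while sphingolipids, sulfatides and gangliosides
# accumulate.  Config-driven; any class absent here stays flat.
DEFAULT_TRAJECTORIES: Dict[str, Dict[int, float]] = {
    "TG": {50: 0.0, 100: -0.4, 150: -0.9, 200: -1.2},
    "DG": {50: 0.0, 100: -0.3, 150: -0.7, 200: -0.9},
    "PC": {50: 0.3, 100: 0.1, 150: 0.0, 200: 0.0},
    "PE": {50: 0.3, 100: 0.1, 150: 0.0, 200: 0.0},
    "LPC": {50: -0.2, 100: 0.4, 150: 0.3, 200: 0.2},
    "LPE": {50: -0.2, 100: 0.4, 150: 0.3, 200: 0.2},
    "SM[d]": {50: -0.6, 100: 0.2, 150: 0.7, 200: 0.8},
    "Cer[d]": {50: -0.6, 100: 0.2, 150: 0.7, 200: 0.8},
    "Hex2Cer[d]": {50: -0.5, 100: 0.1, 150: 0.6, 200: 0.8},
    "SM4[d]": {50: -0.8, 100: 0.0, 150: 0.7, 200: 0.9},
    "SM4[t]": {50: -0.8, 100: 0.0, 150: 0.7, 200: 0.9},
    "GM1[d]": {50: -0.7, 100: 0.0, 150: 0.6, 200: 0.8},
    "GM2[d]": {50: -0.7, 100: 0.0, 150: 0.6, 200: 0.8},
    "GM3[d]": {50: -0.7, 100: 0.0, 150: 0.6, 200: 0.8},
}


@dataclass
class SimulationParams:
    """Study-shaped simulation settings (defaults mirror the organoid design)."""

    n_control_lines: int = 3
    n_ald_lines: int = 9
    replicates: int = 3
    timepoints: Tuple[int, ...] = (50, 100, 150, 200)
    region: str = "hCO"
    sigma_line: float = 0.2      # donor random-intercept SD, natural-log scale
    sigma_e: float = 0.3         # residual SD, natural-log scale
    vlcfa_effect: float = 0.1    # genotype log2 FC per carbon above threshold
    vlcfa_thresholds: Mapping[int, int] = field(default_factory=lambda: dict(VLCFA_THRESHOLDS))
    class_trajectories: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAJECTORIES.items()}
    )
    baseline_sd_log2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_line < 0 or self.sigma_e < 0:
            raise ValueError("noise SDs must be non-negative")
        if min(self.n_control_lines, self.n_ald_lines, self.replicates) < 1:
            raise ValueError("counts must be at least 1")


@dataclass
class SimulationTruth:
    """Everything needed to recompute expected values of a simulated study."""

    species_effect_log2: pd.Series          # per-species true genotype log2 FC
    baseline_log2: pd.Series                # per-species baseline (CTRL, day ref)
    class_trajectories: Dict[str, Dict[int, float]]
    line_intercepts: pd.Series              # natural-log per-line offsets
    seed: int


def make_design(params: SimulationParams) -> StudyDesign:
    rows = []
    lines = [(f"CTRL_{i + 1}", "CTRL") for i in range(params.n_control_lines)]
    lines += [(f"ALD_{i + 1}", "ALD") for i in range(params.n_ald_lines)]
    for (line, geno), tp, rep in itertools.product(
        lines, params.timepoints, range(1, params.replicates + 1)
    ):
        rows.append(
            {
                "sample_id": f"{line}_{params.region}_d{tp}_r{rep}",
                "line_id": line,
                "genotype": geno,
                "region": params.region,
                "timepoint": tp,
                "replicate": rep,
            }
        )
    return StudyDesign(pd.DataFrame(rows))


def simulation_species(
    classes: Sequence[LipidClassDefinition],
    max_per_class: int = 24,
) -> pd.DataFrame:
    """Deterministic species panel: an evenly spaced subset of each class grid.

    Returns a species_meta frame (index = species name) with class_code, C,
    db, n_chains and neutral mass.
    """
    rows = []
    for defn in classes:
        species = expand_class(defn)
        if not species:
            continue
        idx = np.unique(np.linspace(0, len(species) - 1, min(max_per_class, len(species))).astype(int))
        for i in idx:
            sp = species[i]
            rows.append(
                {
                    "species": sp.name,
                    "class_code": sp.class_code,
                    "C": sp.total_carbons,
                    "db": sp.total_double_bonds,
                    "n_chains": defn.n_chains,
                    "neutral_mass": sp.neutral_mass,
                }
            )
    return pd.DataFrame(rows).set_index("species")


def true_effect_log2(
    c: int, n_chains: int, vlcfa_effect: float, thresholds: Mapping[int, int]
) -> float:
    """Genotype log2 FC: slope x carbons above the chain-count threshold."""
    c0 = thresholds.get(n_chains)
    if c0 is None:
        return 0.0
    return vlcfa_effect * max(0, c - c0)


def simulate_study(
    params: SimulationParams,
    species_meta: Optional[pd.DataFrame] = None,
) -> Tuple[AbundanceTable, StudyDesign, SimulationTruth]:
    """Draw an abundance table under the longitudinal mixed model.

    log y = ln2*(baseline + trajectory(class, t) + effect_log2 * 1[ALD])
            + line_intercept + eps,   eps ~ N(0, sigma_e^2)

    exponentiated to A.U.  ``species_meta`` defaults to the shipped class
    panel via :func:`simulation_species`.
    """
    if species_meta is None:
        from .io import load_default_classes

        species_meta = simulation_species(load_default_classes())
    rng = np.random.default_rng(params.seed)
    design = make_design(params)
    frame = design.frame
    species = list(species_meta.index)

    class_codes = sorted(set(species_meta["class_code"]))
    class_base = pd.Series(
        rng.normal(0.0, 1.0, len(class_codes)), index=class_codes
    )
    baseline = pd.Series(
        class_base[species_meta["class_code"]].to_numpy()
        + rng.normal(0.0, params.baseline_sd_log2, len(species)),
        index=species,
    )
    effects = pd.Series(
        [
            true_effect_log2(
                int(species_meta.loc[s, "C"]),
                int(species_meta.loc[s, "n_chains"]),
                params.vlcfa_effect,
                params.vlcfa_thresholds,
            )
            for s in species
        ],
        index=species,
    )
    lines = sorted(frame["line_id"].unique())
    intercepts = pd.Series(rng.normal(0.0, params.sigma_line, len(lines)), index=lines)

    traj = {k: dict(v) for k, v in params.class_trajectories.items()}
    traj_log2 = np.array(
        [
            [
                traj.get(species_meta.loc[s, "class_code"], {}).get(int(tp), 0.0)
                for tp in frame["timepoint"]
            ]
            for s in species
        ]
    )
    is_ald = (frame["genotype"] == "ALD").to_numpy(float)
    log_mu = (
        LN2 * (baseline.to_numpy()[:, None] + traj_log2 + np.outer(effects.to_numpy(), is_ald))
        + intercepts[frame["line_id"]].to_numpy()[None, :]
    )
    eps = rng.normal(0.0, params.sigma_e, log_mu.shape)
    values = pd.DataFrame(
        np.exp(log_mu + eps), index=species, columns=list(frame["sample_id"])
    )
    values.index.name = "species"
    table = AbundanceTable(values=values, design=design, species_meta=species_meta)
    truth = SimulationTruth(
        species_effect_log2=effects,
        baseline_log2=baseline,
        class_trajectories=traj,
        line_intercepts=intercepts,
        seed=params.seed,
    )
    return table, design, truth


def simulate_lipid(
    beta_ln: float,
    rng: np.random.Generator,
    n_control_lines: int = 3,
    n_ald_lines: int = 9,
    replicates: int = 3,
    sigma_line: float = 0.2,
    sigma_e: float = 0.3,
    baseline_ln: float = 0.0,
) -> Tuple[pd.Series, StudyDesign]:
    """One lipid at one timepoint: log y = baseline + beta*1[ALD] + line + eps.

    Returns (values in A.U. indexed by sample, design).  Used for estimator
    calibration at a known natural-log effect size.
    """
    params = SimulationParams(
        n_control_lines=n_control_lines,
        n_ald_lines=n_ald_lines,
        replicates=replicates,
        timepoints=(50,),
    )
    design = make_design(params)
    frame = design.frame
    lines = sorted(frame["line_id"].unique())
    intercepts = dict(zip(lines, rng.normal(0.0, sigma_line, len(lines))))
    logy = (
        baseline_ln
        + beta_ln * (frame["genotype"] == "ALD").to_numpy(float)
        + np.array([intercepts[l] for l in frame["line_id"]])
        + rng.normal(0.0, sigma_e, len(frame))
    )
    return pd.Series(np.exp(logy), index=list(frame["sample_id"])), design


def well_separated_panel(
    classes: Sequence[LipidClassDefinition],
) -> List[LipidClassDefinition]:
    """Classes distinguishable by accurate mass alone.

    Ether ([O]) and plasmalogen ([P]) glycerophospholipids are exact sum-
    composition isobars of their lyso/diacyl counterparts (an ether class at
    (C:db) shares the formula of the lyso class at (C:db), and a plasmalogen
    is an ether with one more formal double bond); only retention time can
    separate them, so they are excluded from mass-only round-trip panels.
    """
    return [
        d
        for d in classes
        if "[O]" not in d.class_code and "[P]" not in d.class_code
    ]


def class_rt_centers(
    classes: Sequence[LipidClassDefinition], spacing: float = 1.0
) -> Dict[str, float]:
    """Deterministic per-class retention-time centers, one per ``spacing`` min.

    Centers are spaced far enough apart that non-overlapping per-class RT
    windows (half-width < spacing/2) can separate exact mass isobars.
    """
    codes = sorted(d.class_code for d in classes)
    return {code: 1.5 + spacing * i for i, code in enumerate(codes)}


def _primary_entry(entries: List[CandidateEntry]) -> CandidateEntry:
    """Deterministic primary adduct: prefer positive mode, then adduct name."""
    return min(entries, key=lambda e: (e.polarity != "+", e.adduct.name))


def simulate_feature_spectra(
    db: CandidateDB,
    design: StudyDesign,
    ppm_sigma: float = 2.0,
    decoy_rate: float = 0.0,
    is_mix: Optional[StandardsMix] = None,
    seed: int = 0,
    abundances: Optional[AbundanceTable] = None,
    class_to_standard: Optional[Mapping[str, str]] = None,
    is_base_area: float = 1.0e6,
    drift_sd: float = 0.1,
    avoid_ppm: float = 15.0,
    rt_centers: Optional[Mapping[str, float]] = None,
    rt_jitter: float = 0.1,
) -> Tuple[List[Feature], Dict[str, Tuple[str, str]]]:
    """Raw-like feature table for the species of a candidate database.

    One feature per species at its primary adduct, observed m/z = theoretical
    x (1 + e), e ~ N(0, ppm_sigma*1e-6).  Internal-standard features carry a
    per-sample base area times a lognormal detector drift shared with the
    analytes of the same sample, so normalization recovers ``abundances``
    exactly when given.  Decoy features are uniform in m/z but kept at least
    ``avoid_ppm`` away from every candidate.  Returns (features, truth) with
    truth[feature_id] = (species name, adduct name); decoys map to
    ("decoy", "").
    """
    if ppm_sigma < 0:
        raise ValueError("ppm_sigma must be non-negative")
    if not (0 <= decoy_rate < 1):
        raise ValueError("decoy_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = design.sample_ids
    drift = np.exp(rng.normal(0.0, drift_sd, len(samples)))
    is_area = {s: is_base_area * d for s, d in zip(samples, drift)}

    by_species: Dict[str, List[CandidateEntry]] = {}
    for e in db.entries():
        by_species.setdefault(e.species.name, []).append(e)

    std_names = set(is_mix.amounts) if is_mix is not None else set()
    target_species = list(abundances.values.index) if abundances is not None else list(by_species)
    features: List[Feature] = []
    truth: Dict[str, Tuple[str, str]] = {}
    fid = 0
    for name in sorted(set(target_species) | std_names):
        entries = by_species.get(name)
        if entries is None:
            continue
        entry = _primary_entry(entries)
        mz = entry.mz * (1.0 + rng.normal(0.0, ppm_sigma * 1e-6))
        if name in std_names and is_mix is not None:
            areas = {s: is_area[s] for s in samples}
        elif abundances is not None and name in abundances.values.index:
            if is_mix is None:
                raise ValueError("abundances given without an internal-standard mix")
            row = abundances.values.loc[name]
            # invert the quantification rule: area = A.U. / amount * IS area
            amount = 1.0
            if class_to_standard is not None:
                cls = entry.species.class_code
                std = class_to_standard.get(cls)
                if std is not None and is_mix is not None and std in is_mix:
                    amount = float(is_mix.amount(std))
            areas = {s: float(row[s]) / amount * is_area[s] for s in samples}
        else:
            base = float(np.exp(rng.normal(np.log(1e5), 1.0)))
            areas = {s: base * d for s, d in zip(samples, drift)}
        fid += 1
        if rt_centers is not None:
            center = rt_centers.get(entry.species.class_code, 8.0)
            rt = float(center + rng.normal(0.0, rt_jitter))
        else:
            rt = float(rng.uniform(0.5, 15.0))
        f = Feature(
            feature_id=f"F{fid:06d}",
            mz=mz,
            polarity=entry.polarity,
            rt=rt,
            areas=areas,
        )
        features.append(f)
        truth[f.feature_id] = (name, entry.adduct.name)

    if decoy_rate > 0:
        n_true = len(features)
        n_decoys = int(round(decoy_rate / (1.0 - decoy_rate) * n_true))
        for pol in ("+", "-"):
            cand_mz = np.array([e.mz for e in db.entries(pol)])
            n_pol = n_decoys // 2 if pol == "+" else n_decoys - n_decoys // 2
            made = 0
            while made < n_pol:
                mz = float(rng.uniform(200.0, 1400.0))
                if cand_mz.size:
                    d = np.min(np.abs(cand_mz - mz)) / mz * 1e6
                    if d <= avoid_ppm:
                        continue
                fid += 1
                base = float(np.exp(rng.normal(np.log(1e4), 1.0)))
                f = Feature(
                    feature_id=f"F{fid:06d}",
                    mz=mz,
                    polarity=pol,
                    rt=float(rng.uniform(0.5, 15.0)),
                    areas={s: base * d_ for s, d_ in zip(samples, drift)},
                )
                features.append(f)
                truth[f.feature_id] = ("decoy", "")
                made += 1
    return features, truth
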