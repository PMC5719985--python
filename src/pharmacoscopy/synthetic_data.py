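"""Synthetic screen, cohort, and clinical-outcome generators.

These generators produce data with the statistical structure the analysis
assumes, plus the ground truth needed to test it:

* a 384-well drug screen: per-well marker-positive/negative viable counts
  under configurable on- and off-target kill probabilities, with
  beta-binomial seeding noise and Hill-type concentration scaling;
* a two-class AML-like cohort over the 125-point three-drug combination
  matrix (responders with strong on-target effects, non-responders near
  null, optionally one null-response outlier in the responder class);
* paired clinical outcomes (prior vs guided progression-free survival
  with a configurable hazard ratio, ordinal responses linked to i-PCY).

All samplers are seed-deterministic: the same config and seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aml_classifier import NON_RESPONDER, RESPONDER, DrugMatrixProfile
from .outcomes import ClinicalRecord
from .screen_core import CONTROL_DRUG, WellRecord


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Screen simulation


@dataclass
class ScreenSimConfig:
    """Geometry and effect model of one simulated patient screen.

    ``on_target_effect`` / ``off_target_effect`` map drug name to the
    maximal kill probability of marker-positive / -negative cells; unlisted
    drugs have no effect.  ``overdispersion`` inflates the beta-binomial
    variance of the seeded blast fraction (0 = pure binomial).
    """

    n_drugs: int = 139
    n_concentrations: int = 2
    n_replicates: int = 5
    n_control_wells: int = 16
    cells_per_well: float = 2000.0
    blast_fraction: float = 0.5
    on_target_effect: dict[str, float] = field(default_factory=dict)
    off_target_effect: dict[str, float] = field(default_factory=dict)
    overdispersion: float = 0.002
    concentration_range_um: tuple[float, float] = (0.1, 10.0)
    marker: str = "CD34"
    patient_id: str = "P1"
    seed: int = 0

    def __post_init__(self) -> None:
        for eff in (self.on_target_effect, self.off_target_effect):
            for drug, k in eff.items():
                if not 0.0 <= k <= 1.0:
                    raise ConfigError(f"kill probability for {drug} outside [0,1]: {k}")
        if not 0.0 <= self.blast_fraction <= 1.0:
            raise ConfigError("blast_fraction must be in [0,1]")
        if self.overdispersion < 0:
            raise ConfigError("overdispersion must be >= 0")

    @property
    def drugs(self) -> list[str]:
        return [f"drug_{i:03d}" for i in range(1, self.n_drugs + 1)]

    @property
    def concentrations(self) -> np.ndarray:
        lo, hi = self.concentration_range_um
        return np.geomspace(lo, hi, self.n_concentrations)

    @property
    def ec50_um(self) -> float:
        lo, hi = self.concentration_range_um
        return math.sqrt(lo * hi)


def preset_screen_config(name: str, **overrides) -> ScreenSimConfig:
    """Named screen geometries.

    ``prospective139x2x5``: 139 drugs, two concentrations, five technical
    replicates.  ``aml_matrix_25x5x4``: the 125-combination matrix laid out
    as 125 pseudo-drugs at a single concentration in four replicates (the
    full per-drug dose structure lives in :func:`simulate_aml_cohort`).
    """
    presets = {
        "prospective139x2x5": dict(n_drugs=139, n_concentrations=2, n_replicates=5),
        "aml_matrix_25x5x4": dict(n_drugs=125, n_concentrations=1, n_replicates=4),
    }
    if name not in presets:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return ScreenSimConfig(**{**presets[name], **overrides})


def hill_kill(kill_max: float, conc_um: float, ec50_um: float, h: float = 1.0) -> float:
    """Hill-scaled kill probability: kill_max * c^h / (c^h + EC50^h)."""
    if conc_um <= 0:
        return 0.0
    ch = conc_um**h
    return kill_max * ch / (ch + ec50_um**h)


def expected_rbf(blast_fraction: float, kill_on: float, kill_off: float) -> float:
    """Closed-form expected RBF under binomial survival.

    With seeded blast fraction f, on-target survival s+ = 1 - kill_on and
    off-target survival s- = 1 - kill_off, the treated marker-positive
    fraction is f s+ / (f s+ + (1-f) s-), and the control fraction is f, so

        E[RBF] = s+ / (f s+ + (1-f) s-)

    Proportional killing (kill_on == kill_off) gives exactly 1.
    """
    f = blast_fraction
    s_on, s_off = 1.0 - kill_on, 1.0 - kill_off
    denom = f * s_on + (1.0 - f) * s_off
    if denom == 0:
        return float("nan")
    return s_on / denom


def _sample_blast_counts(
    rng: np.random.Generator, n_cells: np.ndarray, f: float, overdispersion: float
) -> np.ndarray:
    """Marker-positive seed counts: binomial or beta-binomial around f."""
    if f in (0.0, 1.0) or overdispersion == 0:
        return rng.binomial(n_cells, f)
    s = 1.0 / overdispersion  # beta concentration
    p = rng.beta(f * s, (1.0 - f) * s, size=len(n_cells))
    return rng.binomial(n_cells, p)


def _well_name(i: int) -> str:
    return f"{chr(ord('A') + (i // 24) % 16)}{i % 24 + 1:02d}"


def simulate_screen(config: ScreenSimConfig) -> tuple[list[WellRecord], pd.DataFrame]:
    """Simulate one patient's screen; returns well records plus a truth table.

    Per well: total seeded cells ~ Poisson(cells_per_well); the
    marker-positive share is beta-binomial around ``blast_fraction``;
    survival is binomial with the drug's Hill-scaled on-/off-target kill
    probabilities.  Controls (DMSO, concentration 0) see no kill.  The
    truth table stores the analytic expected RBF per drug x concentration.
    """
    rng = np.random.default_rng(config.seed)
    f = config.blast_fraction
    wells: list[WellRecord] = []
    truth_rows = []

    capacity = 384 - config.n_control_wells
    layout: list[tuple[str, float]] = [(CONTROL_DRUG, 0.0)] * config.n_control_wells
    for drug in config.drugs:
        for conc in config.concentrations:
            for _ in range(config.n_replicates):
                layout.append((drug, float(conc)))
    # controls on every plate: re-insert a control block at each plate boundary
    plate_wells: list[list[tuple[str, float]]] = []
    drug_part = layout[config.n_control_wells:]
    for start in range(0, len(drug_part), capacity):
        plate = [(CONTROL_DRUG, 0.0)] * config.n_control_wells + drug_part[
            start : start + capacity
        ]
        plate_wells.append(plate)

    rep_counter: dict[tuple[str, float], int] = {}
    for plate_no, plate in enumerate(plate_wells, start=1):
        plate_id = f"{config.patient_id}_plate{plate_no}"
        for i, (drug, conc) in enumerate(plate):
            n_cells = int(rng.poisson(config.cells_per_well))
            n_pos = int(
                _sample_blast_counts(
                    rng, np.array([n_cells]), f, config.overdispersion
                )[0]
            )
            n_neg = n_cells - n_pos
            if drug == CONTROL_DRUG:
                k_on = k_off = 0.0
            else:
                k_on = hill_kill(config.on_target_effect.get(drug, 0.0), conc, config.ec50_um)
                k_off = hill_kill(config.off_target_effect.get(drug, 0.0), conc, config.ec50_um)
            surv_pos = int(rng.binomial(n_pos, 1.0 - k_on))
            surv_neg = int(rng.binomial(n_neg, 1.0 - k_off))
            rep = rep_counter[(drug, conc)] = rep_counter.get((drug, conc), 0) + 1
            wells.append(
                WellRecord(
                    patient_id=config.patient_id,
                    plate_id=plate_id,
                    well=_well_name(i),
                    drug=drug,
                    concentration_um=conc,
                    replicate=rep if drug != CONTROL_DRUG else ((rep - 1) % config.n_control_wells) + 1,
                    n_viable_marker_pos={config.marker: surv_pos},
                    n_viable_marker_neg={config.marker: surv_neg},
                    n_total_cells=n_cells,
                )
            )

    for drug in config.drugs:
        for conc in config.concentrations:
            k_on = hill_kill(config.on_target_effect.get(drug, 0.0), conc, config.ec50_um)
            k_off = hill_kill(config.off_target_effect.get(drug, 0.0), conc, config.ec50_um)
            truth_rows.append(
                {
                    "drug": drug,
                    "concentration_um": float(conc),
                    "kill_on": k_on,
                    "kill_off": k_off,
                    "expected_rbf": expected_rbf(f, k_on, k_off),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return wells, truth


# ---------------------------------------------------------------------------
# AML cohort over the combination matrix


@dataclass
class CohortSimConfig:
    """Two-class cohort over the three-drug, 5x5x5 combination matrix."""

    n_responders: int = 10
    n_nonresponders: int = 10
    effect_gap: float = 0.5           # on-target kill_max gap between classes
    blast_fraction_range: tuple[float, float] = (0.3, 0.95)
    n_conc_per_drug: int = 5
    n_replicates: int = 4
    cells_per_well: float = 2000.0
    n_control_wells: int = 16
    nonspecific_scale: float = 0.25   # exp-scale of patient x point toxicity noise
    patient_toxicity_scale: float = 0.4  # exp-scale of per-patient global drug toxicity
    off_target_ratio: float = 0.4     # off-target kill_max as share of on-target
    include_outlier: bool = False     # one null-response responder ("patient 10")
    overdispersion: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_gap < 0:
            raise ConfigError("effect_gap must be >= 0")
        lo, hi = self.blast_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("blast_fraction_range must be within (0,1)")

    @property
    def n_points(self) -> int:
        return self.n_conc_per_drug**3


def simulate_aml_cohort(
    config: CohortSimConfig,
) -> tuple[list[DrugMatrixProfile], dict[str, str]]:
    """Simulate per-patient drug-matrix profiles with known class structure.

    Responders carry an on-target kill effect monotone in every drug's
    concentration; non-responders are near-null.  Non-specific toxicity —
    a per-patient global drug-sensitivity factor (how hard the whole
    sample is hit by any insult) times per-point noise — kills both
    populations equally in drug wells: it cancels in the RBF but shifts a
    patient's entire total-cell and total-blast profile, reproducing the
    motivation for population-relative scoring.  Returns the profiles and
    a patient -> label truth map.
    """
    rng = np.random.default_rng(config.seed)
    concs = np.geomspace(0.1, 10.0, config.n_conc_per_drug)
    ec50 = math.sqrt(0.1 * 10.0)
    # matrix points: all combinations of 3 drug concentrations, ids 1..125
    grid = np.array(
        [(a, b, c) for a in concs for b in concs for c in concs]
    )  # (n_points, 3)
    hill = grid / (grid + ec50)  # per-drug Hill factor at each point
    point_ids = np.arange(1, config.n_points + 1)

    profiles: list[DrugMatrixProfile] = []
    labels: dict[str, str] = {}
    plan = [(RESPONDER, i) for i in range(config.n_responders)] + [
        (NON_RESPONDER, i) for i in range(config.n_nonresponders)
    ]
    for label, i in plan:
        pid = f"{'CR' if label == RESPONDER else 'NR'}{i + 1:02d}"
        f = rng.uniform(*config.blast_fraction_range)
        base = rng.normal(0.05, 0.03, 3)
        if label == RESPONDER:
            kmax = np.clip(base + config.effect_gap, 0.0, 0.95)
        else:
            kmax = np.clip(base, 0.0, 0.95)
        if config.include_outlier and label == RESPONDER and i == config.n_responders - 1:
            kmax = np.zeros(3)  # clinical responder with no ex-vivo response
        kill_on = 1.0 - np.prod(1.0 - kmax * hill, axis=1)
        kill_off = 1.0 - np.prod(1.0 - config.off_target_ratio * kmax * hill, axis=1)
        patient_tox = math.exp(-rng.exponential(config.patient_toxicity_scale))
        nonspecific = patient_tox * np.exp(
            -rng.exponential(config.nonspecific_scale, config.n_points)
        )

        # control wells
        n_ctrl = rng.poisson(config.cells_per_well, config.n_control_wells)
        ctrl_pos = _sample_blast_counts(rng, n_ctrl, f, config.overdispersion)
        ctrl_neg = n_ctrl - ctrl_pos
        ctrl_frac = (ctrl_pos / n_ctrl).mean()
        ctrl_total = float((ctrl_pos + ctrl_neg).mean())
        ctrl_blasts = float(ctrl_pos.mean())

        shape = (config.n_points, config.n_replicates)
        n_cells = rng.poisson(config.cells_per_well, shape)
        n_pos = _sample_blast_counts(
            rng, n_cells.ravel(), f, config.overdispersion
        ).reshape(shape)
        n_neg = n_cells - n_pos
        s_on = (1.0 - kill_on)[:, None] * nonspecific[:, None]
        s_off = (1.0 - kill_off)[:, None] * nonspecific[:, None]
        surv_pos = rng.binomial(n_pos, s_on)
        surv_neg = rng.binomial(n_neg, s_off)
        viable = surv_pos + surv_neg
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(viable > 0, surv_pos / np.maximum(viable, 1), np.nan)
        values = {
            "rbf": pd.DataFrame(frac / ctrl_frac, index=point_ids),
            "total_cells_rel": pd.DataFrame(viable / ctrl_total, index=point_ids),
            "total_blasts_rel": pd.DataFrame(surv_pos / ctrl_blasts, index=point_ids),
        }
        profiles.append(DrugMatrixProfile(patient_id=pid, label=label, values=values))
        labels[pid] = label
    return profiles, labels


# ---------------------------------------------------------------------------
# Clinical outcome simulation


def simulate_clinical(
    n: int,
    seed: int,
    hazard_ratio: float = 1.0,
    median_prior_weeks: float = 6.0,
    censor_weeks: float = 52.0,
    ipcy_link: float = 1.0,
) -> list[ClinicalRecord]:
    """Simulate paired prior/guided outcomes for *n* patients.

    Prior PFS is exponential with the given median; guided PFS is
    exponential with hazard reduced by ``hazard_ratio``.  Guided times past
    ``censor_weeks`` are administratively censored (ongoing response); a
    non-positive ``censor_weeks`` censors every record at its drawn time.
    Ordinal responses are drawn from an ordered-logistic link on a
    simulated i-PCY score with slope ``ipcy_link``.
    """
    rng = np.random.default_rng(seed)
    scale_prior = median_prior_weeks / math.log(2)
    prior_t = rng.exponential(scale_prior, n)
    guided_t = rng.exponential(scale_prior * hazard_ratio, n)

    i_pcy = rng.normal(0.5, 2.0, n)
    latent = ipcy_link * i_pcy + rng.logistic(0.0, 1.0, n)
    ordinal = np.digitize(latent, [-2.0, 0.0, 2.0]) + 1  # 1..4
    resp_label = {1: "PD", 2: "SD", 3: "PR", 4: "CR"}

    records = []
    for i in range(n):
        if censor_weeks > 0 and guided_t[i] > censor_weeks:
            pfs, ongoing = censor_weeks, True
        elif censor_weeks <= 0:
            pfs, ongoing = guided_t[i], True
        else:
            pfs, ongoing = guided_t[i], False
        records.append(
            ClinicalRecord(
                patient_id=f"S{i + 1:03d}",
                diagnosis="simulated",
                overall_response=resp_label[int(ordinal[i])],
                pfs_weeks=float(max(pfs, 1e-6)),
                ongoing=bool(ongoing),
                previous_treatment_lines=int(rng.integers(1, 8)),
                prior_response="responder" if rng.random() < 0.25 else "non-responder",
                prior_pfs_weeks=float(max(prior_t[i], 1e-6)),
                i_pcy=float(i_pcy[i]),
            )
        )
    return records
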