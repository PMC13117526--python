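"""Seed-reproducible synthetic piglet trials.

The animal data behind the study are not publicly deposited, so this module
generates trials with the statistical structure the downstream analyses
assume:

* two arms (vehicle / treated) of ~12 animals each, with sex and weight;
* per-voxel log10 Lac/NAA that is Gaussian on the log10 scale (the analyses
  log-transform first; SD defaults to 0.4 as in the study's sizing);
* hourly aEEG background scores over 60 h from a bounded latent-drift
  process: deep post-insult suppression, then stochastic recovery, rounded
  and clipped to the integer 0-4 scale, which reproduces the plateaus at 0
  and 4 seen in such data;
* regional immunohistochemistry densities for 8 brain regions × markers,
  correlated within animal through a single animal-level random effect and
  thinned completely at random to emulate missing cells;
* plasma drug concentrations from the two-compartment infusion model with
  proportional error at the study's sampling times (2, 25, 49 h);
* serial blood counts (neutrophils, monocytes, lymphocytes, platelets).

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dataclasses_replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import pk as pkmod
from .scores import REGIONS

__all__ = [
    "TrialConfig",
    "TrialDataset",
    "MARKERS",
    "generate_trial",
    "generate_eeg_series",
    "generate_pk_samples",
    "generate_pk_population",
    "PK_VALIDATION_TIMES",
    "write_csvs",
    "read_csvs",
]

#: immunohistochemistry markers carried by the default panel
MARKERS = ("NeuN", "TUNEL", "Iba1", "OLIG2")

#: marker-level baseline density (cells/mm²) and between-animal SD
_MARKER_BASE = {"NeuN": (500.0, 100.0), "TUNEL": (60.0, 25.0),
                "Iba1": (200.0, 60.0), "OLIG2": (300.0, 80.0)}

#: default treatment shifts (cells/mm², applied to every region of the
#: marker) emulating the study's direction of effect: more surviving
#: neurons and microglia under treatment, cell death and oligodendrocytes
#: essentially unchanged
_DEFAULT_IHC_EFFECTS = {"NeuN": 40.0, "TUNEL": 0.0, "Iba1": 25.0, "OLIG2": -8.0}

_BLOOD_TIMEPOINTS = (0.0, 6.0, 24.0, 48.0, 60.0)


@dataclass(frozen=True)
class TrialConfig:
    """Knobs of one synthetic trial; defaults emulate the study conditions."""

    n_per_arm: int = 12
    effect_lacnaa: float = -0.143     # log10-unit treated-vehicle difference
    sd_lacnaa: float = 0.4            # log10-unit SD (study sizing value)
    eeg_recovery_shift: float = 0.012  # score/h extra recovery under treatment
    eeg_recovery_rate: float = 0.055   # score/h baseline recovery (vehicle)
    eeg_noise_sd: float = 0.35         # latent per-hour innovation SD
    eeg_hours: int = 60
    ihc_effects: Optional[dict] = None  # (marker -> shift) or (marker, region) -> shift
    ihc_region_rho: float = 0.5        # between-region correlation (animal effect share)
    missing_rate: float = 0.05
    sex_ratio: float = 0.5
    mean_lacnaa: float = 0.1           # vehicle-arm mean log10 Lac/NAA after IA-HI
    pk_params: pkmod.PKParams = field(default_factory=lambda: pkmod.REFERENCE_PARAMS)
    pk_times: tuple = (2.0, 25.0, 49.0)
    weight_mean_kg: float = 2.0
    weight_sd_kg: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError(f"n_per_arm must be >= 2, got {self.n_per_arm}")
        if self.sd_lacnaa <= 0:
            raise ValueError(f"sd_lacnaa must be > 0, got {self.sd_lacnaa}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        if not 0 <= self.ihc_region_rho < 1:
            raise ValueError(f"ihc_region_rho must be in [0, 1), got {self.ihc_region_rho}")
        if self.eeg_hours < 6:
            raise ValueError(f"eeg_hours must be >= 6, got {self.eeg_hours}")


@dataclass
class TrialDataset:
    """Tidy per-animal tables for one (synthetic) study."""

    animals: pd.DataFrame  # animal_id, arm, sex, weight_kg
    mrs: pd.DataFrame      # animal_id, voxel in {BGT, WM}, log10_lacnaa
    eeg: pd.DataFrame      # animal_id, hour, score
    ihc: pd.DataFrame      # animal_id, region, marker, density (NaN = missing)
    pk: pd.DataFrame       # subject_id, time_h, conc_mg_per_L (treated arm)
    blood: pd.DataFrame    # animal_id, timepoint_h, neutrophils, monocytes, lymphocytes, platelets

    TABLES = ("animals", "mrs", "eeg", "ihc", "pk", "blood")


def _ihc_shift(effects: dict, marker: str, region: str) -> float:
    if (marker, region) in effects:
        return float(effects[(marker, region)])
    return float(effects.get(marker, 0.0))


def generate_eeg_series(
    start_score: float,
    recovery_rate: float,
    hours: int,
    rng: np.random.Generator | int,
    noise_sd: float = 0.35,
) -> np.ndarray:
    """One animal's hourly background-score trajectory.

    A latent state starts at ``start_score``, drifts upward at
    ``recovery_rate`` per hour with Gaussian innovations, and is clipped to
    [0, 4]; the reported score is the rounded latent state.  With zero
    rate and noise the trajectory is constant, and a latent state at the
    boundary stays there (score plateaus).
    """
    if hours < 6:
        raise ValueError(f"need >= 6 h to form one epoch, got {hours}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    latent = np.empty(hours)
    x = float(start_score)
    for h in range(hours):
        x = np.clip(x + recovery_rate + rng.normal(0.0, noise_sd), 0.0, 4.0)
        latent[h] = x
    return np.clip(np.round(latent), 0, 4).astype(int)


def generate_pk_samples(
    params: pkmod.PKParams,
    regimen: pkmod.DoseRegimen,
    times: Sequence[float],
    cv_prop: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Noisy concentration observations: pred × (1 + eps), eps ~ N(0, cv²).

    Zero model concentrations (before the first dose) stay exactly zero;
    multiplicative noise cannot create drug where there is none.  Negative
    draws are truncated at zero.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("sampling times must be >= 0")
    if cv_prop < 0:
        raise ValueError("cv_prop must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pred = np.atleast_1d(pkmod.concentration(t, regimen, params))
    eps = rng.normal(0.0, cv_prop, size=pred.shape) if cv_prop > 0 else np.zeros_like(pred)
    return np.maximum(pred * (1.0 + eps), 0.0)


#: rich sampling schedule for PK estimator-validation studies: spans the
#: terminal phase (the drug's half-life exceeds the bedside study window,
#: so within-window sampling alone cannot identify clearance)
PK_VALIDATION_TIMES = (2.0, 6.0, 24.5, 25.0, 30.0, 48.5, 49.0, 60.0, 72.0, 96.0, 120.0)


def generate_pk_population(
    params: pkmod.PKParams,
    regimen: pkmod.DoseRegimen,
    times: Sequence[float],
    n_subjects: int,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Tidy population PK dataset with lognormal between-subject variability.

    Each subject's parameters are the population values times
    exp(eta), eta ~ N(0, omega²) for every parameter named in
    ``params.omega``; observations carry proportional error ``params.cv_prop``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for i in range(n_subjects):
        kw = {
            name: getattr(params, name) * np.exp(rng.normal(0.0, om))
            for name, om in params.omega.items()
        }
        subj = dataclasses_replace(params, omega={}, **kw)
        obs = generate_pk_samples(subj, regimen, times, params.cv_prop, rng)
        rows += [
            {"subject_id": f"S{i + 1:02d}", "time_h": float(t), "conc_mg_per_L": float(max(c, 1e-6))}
            for t, c in zip(times, obs)
        ]
    return pd.DataFrame(rows)


def generate_trial(config: TrialConfig) -> TrialDataset:
    """Generate a full synthetic trial; identical config ⇒ identical dataset."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_arm
    ids = [f"P{i + 1:02d}" for i in range(2 * n)]
    arms = ["vehicle"] * n + ["treated"] * n
    sex = np.where(rng.random(2 * n) < config.sex_ratio, "M", "F")
    weight = rng.normal(config.weight_mean_kg, config.weight_sd_kg, 2 * n).clip(1.2)
    animals = pd.DataFrame(
        {"animal_id": ids, "arm": arms, "sex": sex, "weight_kg": np.round(weight, 3)}
    )

    # MRS: Gaussian directly on the log10 scale; a small fixed sex offset
    # makes sex adjustment non-degenerate
    rows = []
    for aid, arm, sx in zip(ids, arms, sex):
        shift = config.effect_lacnaa if arm == "treated" else 0.0
        sex_off = 0.03 if sx == "M" else 0.0
        for voxel in ("BGT", "WM"):
            rows.append(
                {
                    "animal_id": aid,
                    "voxel": voxel,
                    "log10_lacnaa": rng.normal(
                        config.mean_lacnaa + shift + sex_off, config.sd_lacnaa
                    ),
                }
            )
    mrs = pd.DataFrame(rows)

    # aEEG: suppressed start, stochastic recovery; treated arm recovers faster
    rows = []
    for aid, arm in zip(ids, arms):
        rate = config.eeg_recovery_rate + (
            config.eeg_recovery_shift if arm == "treated" else 0.0
        )
        start = rng.uniform(0.0, 0.8)
        series = generate_eeg_series(
            start, rate, config.eeg_hours, rng, noise_sd=config.eeg_noise_sd
        )
        rows += [
            {"animal_id": aid, "hour": h, "score": int(s)} for h, s in enumerate(series)
        ]
    eeg = pd.DataFrame(rows)

    # IHC: density = marker base + animal effect (shared across regions,
    # giving exchangeable between-region correlation rho) + residual
    effects = dict(_DEFAULT_IHC_EFFECTS if config.ihc_effects is None else config.ihc_effects)
    rho = config.ihc_region_rho
    rows = []
    for aid, arm in zip(ids, arms):
        for marker in MARKERS:
            base, sd = _MARKER_BASE[marker]
            animal_eff = rng.normal(0.0, sd * np.sqrt(rho))
            for region in REGIONS:
                shift = _ihc_shift(effects, marker, region) if arm == "treated" else 0.0
                d = base + shift + animal_eff + rng.normal(0.0, sd * np.sqrt(1.0 - rho))
                rows.append(
                    {
                        "animal_id": aid,
                        "region": region,
                        "marker": marker,
                        "density": max(d, 0.0),
                    }
                )
    ihc = pd.DataFrame(rows)
    if config.missing_rate > 0:
        drop = rng.random(len(ihc)) < config.missing_rate
        ihc.loc[drop, "density"] = np.nan

    # PK: treated animals only, proportional-error samples at the study times
    rows = []
    for aid, arm, w in zip(ids, arms, weight):
        if arm != "treated":
            continue
        regimen = pkmod.study_regimen(weight_kg=float(w))
        obs = generate_pk_samples(
            config.pk_params, regimen, config.pk_times, config.pk_params.cv_prop, rng
        )
        rows += [
            {"subject_id": aid, "time_h": t, "conc_mg_per_L": float(c)}
            for t, c in zip(config.pk_times, obs)
        ]
    pk = pd.DataFrame(rows, columns=["subject_id", "time_h", "conc_mg_per_L"])

    # blood counts: lognormal-ish positive series; treated arm gets a lower
    # systemic inflammatory response from 24 h and more platelets late
    rows = []
    for aid, arm in zip(ids, arms):
        frailty = rng.normal(0.0, 0.2)  # animal-level log-scale random effect
        for tp in _BLOOD_TIMEPOINTS:
            infl = 1.0 + 1.5 * np.exp(-((tp - 6.0) ** 2) / 200.0)  # peaks post-insult
            treat = arm == "treated"
            neut = rng.lognormal(np.log(6.0 * infl) + frailty - (0.25 if treat and tp >= 24 else 0.0), 0.3)
            mono = rng.lognormal(np.log(1.0 * infl) + frailty - (0.20 if treat and tp >= 24 else 0.0), 0.3)
            lymp = rng.lognormal(np.log(3.5) + frailty, 0.25)
            plat = rng.normal(350.0 + (60.0 if treat and tp >= 48 else 0.0), 70.0)
            rows.append(
                {
                    "animal_id": aid,
                    "timepoint_h": tp,
                    "neutrophils": round(neut, 3),
                    "monocytes": round(mono, 3),
                    "lymphocytes": round(lymp, 3),
                    "platelets": round(max(plat, 20.0), 1),
                }
            )
    blood = pd.DataFrame(rows)

    return TrialDataset(animals=animals, mrs=mrs, eeg=eeg, ihc=ihc, pk=pk, blood=blood)


def write_csvs(dataset: TrialDataset, outdir: str | Path) -> dict:
    """Write the canonical tidy CSVs; returns {table: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TrialDataset.TABLES:
        p = outdir / f"{name}.csv"
        getattr(dataset, name).to_csv(p, index=False)
        paths[name] = p
    return paths


def read_csvs(indir: str | Path) -> TrialDataset:
    """Read a dataset previously written by :func:`write_csvs`."""
    indir = Path(indir)
    tables = {}
    for name in TrialDataset.TABLES:
        p = indir / f"{name}.csv"
        if not p.exists():
            raise FileNotFoundError(f"missing input table: {p}")
        tables[name] = pd.read_csv(p)
    return TrialDataset(**tables)
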