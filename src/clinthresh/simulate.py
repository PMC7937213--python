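"""Synthetic shoulder-trial cohorts with known ground truth.

The real trial data behind the published thresholds are not public, so
every estimator here is exercised against generated cohorts that emulate
the study's structure: ~193 patients in three arms (two surgical, one
exercise), pain VAS instruments at 6/12/24 months, function instruments
(Constant-Murley, Simple Shoulder Test) at 6/24 months only, a shared
5-level GRC anchor per patient x timepoint, and item-level missingness
producing unequal pair counts per instrument x timepoint.

Generative model
----------------
A standard-normal latent recovery ``u`` per patient x timepoint (with
within-patient correlation) drives everything.  Each instrument's true
improvement is ``effect_mean + effect_sd * u`` plus instrument-specific
measurement noise; the post score is baseline +/- that change, clipped to
the scale (and rounded for integer instruments).  The anchor is an
ordinal cut of

    z = (1 - w) * u + w * post_wellbeing_std + anchor noise

at thresholds ``tau_1 > tau_2 > tau_3 > tau_4``; ``w`` is a recall-bias
weight — at ``w > 0`` patients rate how they feel now rather than how much
they changed, which is exactly the mechanism that makes GRC-post
correlations exceed GRC-change correlations.

Because the generator knows ``u`` and the cuts, it can report the implied
true thresholds on each instrument's own scale (the planted MID at the
improved/no-change cut when ``w = 0``; the planted PASS post-score
threshold at the satisfied cut when ``w = 1``), enabling parameter-recovery
tests.  Default numeric parameters are synthetic: chosen to be clinically
plausible for subacromial pain and to reproduce the qualitative pattern of
the published analysis (strong activity-pain/function anchors, a weak
rest-pain anchor), not to equal the non-public trial's distributions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_INSTRUMENTS,
    AnchoredOutcomeTable,
    InstrumentSpec,
    compute_changes,
)


@dataclass(frozen=True)
class InstrumentSimParams:
    """Generative parameters for one instrument (instrument scale units).

    ``anchor_coupling`` is the share of the improvement's systematic
    variance that tracks the satisfaction latent ``u``; the rest follows an
    instrument-specific recovery component independent of satisfaction.
    Coupling 1 plants an exact GRC threshold on the improvement scale;
    coupling < 1 models an outcome that is not what drives how satisfied
    patients feel (rest pain, in this condition).
    """

    baseline_mean: float
    baseline_sd: float
    effect_mean: float  # mean latent improvement
    effect_sd: float    # SD of latent improvement across patients
    noise_sd: float     # measurement noise on the change
    timepoints: tuple = (6, 12, 24)
    anchor_coupling: float = 1.0


DEFAULT_SIM_PARAMS: dict[str, InstrumentSimParams] = {
    # weak anchor by design: rest pain is rarely the driving symptom, so its
    # improvement is only half-coupled to satisfaction
    "pain_rest": InstrumentSimParams(35.0, 18.0, 15.0, 16.0, 24.0, (6, 12, 24), 0.5),
    "pain_activity": InstrumentSimParams(70.0, 15.0, 30.0, 20.0, 9.0, (6, 12, 24)),
    "cs": InstrumentSimParams(52.0, 13.0, 22.0, 14.0, 5.0, (6, 24)),
    "sst": InstrumentSimParams(6.0, 2.5, 3.2, 2.6, 1.0, (6, 24)),
}

#: ordinal cuts on z: > tau_1 -> GRC 1 (very satisfied) ... <= tau_4 -> GRC 5
DEFAULT_TAUS = (0.84, 0.0, -0.67, -1.64)


@dataclass(frozen=True)
class TrialSimConfig:
    n_patients: int = 193
    groups: tuple = ("ASD", "DA", "ET")
    allocation: tuple = (1, 1, 1)
    instruments: Mapping[str, InstrumentSimParams] = field(
        default_factory=lambda: dict(DEFAULT_SIM_PARAMS)
    )
    taus: tuple = DEFAULT_TAUS
    anchor_noise_sd: float = 0.25
    #: anchor noise multiplier per timepoint (e.g. shrink with follow-up)
    anchor_noise_by_timepoint: Mapping[int, float] | None = None
    recall_bias_weight: float = 0.0  # w in [0, 1]
    #: drive the anchor's post component from one instrument only
    anchor_post_instrument: str | None = None
    patient_corr: float = 0.5  # within-patient correlation of u across timepoints
    #: correlation of wellbeing-aligned baselines across instruments: a
    #: shared severity factor raises pain baselines and lowers function ones
    baseline_corr: float = 0.6
    missing_post: float = 0.03
    missing_grc: float = 0.02
    missing_baseline: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        t = self.taus
        if not (len(t) == 4 and t[0] > t[1] > t[2] > t[3]):
            raise ValueError(f"taus must be 4 strictly decreasing cuts, got {t}")
        if not 0.0 <= self.recall_bias_weight <= 1.0:
            raise ValueError("recall_bias_weight must be in [0, 1]")
        if len(self.groups) != len(self.allocation):
            raise ValueError("groups and allocation lengths differ")

    def digest(self) -> str:
        payload = json.dumps(
            {
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in self.__dict__.items()
            },
            default=lambda o: o.__dict__,
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class GroundTruth:
    """What the generator knows that the estimators must recover."""

    latent: pd.DataFrame  # patient_id, timepoint, u, z, grc (pre-missingness)
    mid_thresholds: dict  # instrument -> improvement at the GRC 3/4 cut (w=0)
    pass_thresholds: dict  # instrument -> {"GRC 1": post cut, "GRC 1+2": post cut}
    taus: tuple
    seed: int | None


def _post_moments(spec: InstrumentSpec, p: InstrumentSimParams) -> tuple[float, float]:
    """Theoretical mean/SD of the post score, ignoring clipping."""
    sign = 1.0 if spec.increase_is_better else -1.0
    mean = p.baseline_mean + sign * p.effect_mean
    sd = float(np.sqrt(p.baseline_sd**2 + p.effect_sd**2 + p.noise_sd**2))
    return mean, sd


def implied_mid_threshold(p: InstrumentSimParams, taus: tuple) -> float:
    """Improvement at the improved/no-change cut (tau_3), instrument scale.

    Defined only for fully anchor-coupled instruments: at coupling < 1 the
    anchor is not a function of this instrument's improvement, so no exact
    threshold exists on its scale (NaN).
    """
    if p.anchor_coupling < 1.0:
        return float("nan")
    return p.effect_mean + p.effect_sd * taus[2]


def implied_pass_threshold(
    spec: InstrumentSpec, p: InstrumentSimParams, tau: float
) -> float:
    """Post score at a satisfied cut, instrument scale (valid when w = 1)."""
    mean, sd = _post_moments(spec, p)
    # wellbeing_std = sign * (post - mean) / sd crosses tau
    return mean + sd * tau if spec.increase_is_better else mean - sd * tau


def generate_trial(
    config: TrialSimConfig, seed: int | None = None
) -> tuple[AnchoredOutcomeTable, GroundTruth]:
    """Draw one cohort; deterministic under (config, seed).

    ``seed`` overrides ``config.seed`` when given.  Returns the table with
    change scores attached, plus the ground truth.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    specs = {k: DEFAULT_INSTRUMENTS[k] for k in config.instruments}

    n = config.n_patients
    alloc = np.array(config.allocation, dtype=float)
    group_of = rng.choice(
        list(config.groups), size=n, p=alloc / alloc.sum()
    )
    pids = np.array([f"P{i:04d}" for i in range(1, n + 1)])

    all_tp = sorted({t for p in config.instruments.values() for t in p.timepoints})
    rho = config.patient_corr
    a = rng.normal(size=n)  # patient-level recovery propensity
    u = {  # shared latent per timepoint, Var = 1
        t: np.sqrt(rho) * a + np.sqrt(1.0 - rho) * rng.normal(size=n) for t in all_tp
    }

    # per-instrument baseline and improvement
    severity = rng.normal(size=n)  # shared across instruments; higher = worse
    lam = config.baseline_corr
    base: dict[str, np.ndarray] = {}
    post: dict[str, dict[int, np.ndarray]] = {}
    for name, p in config.instruments.items():
        spec = specs[name]
        sign = 1.0 if spec.increase_is_better else -1.0
        sev_load = -sign * np.sqrt(lam)  # severity lowers function, raises pain
        b = p.baseline_mean + p.baseline_sd * (
            sev_load * severity + np.sqrt(1.0 - lam) * rng.normal(size=n)
        )
        b = np.clip(b, spec.scale_min, spec.scale_max)
        if spec.integer_valued:
            b = np.round(b)
        base[name] = b
        post[name] = {}
        kappa = p.anchor_coupling
        for t in p.timepoints:
            systematic = kappa * u[t]
            if kappa < 1.0:
                systematic = systematic + np.sqrt(1.0 - kappa**2) * rng.normal(size=n)
            improvement = p.effect_mean + p.effect_sd * systematic
            if p.noise_sd > 0:
                improvement = improvement + rng.normal(0, p.noise_sd, size=n)
            raw_post = b + sign * improvement
            raw_post = np.clip(raw_post, spec.scale_min, spec.scale_max)
            if spec.integer_valued:
                raw_post = np.round(raw_post)
            post[name][t] = raw_post

    # anchor: ordinal cut of (1-w) u + w post_wellbeing_std + noise
    w = config.recall_bias_weight
    grc: dict[int, np.ndarray] = {}
    zs: dict[int, np.ndarray] = {}
    for t in all_tp:
        if w > 0:
            comps = []
            for name, p in config.instruments.items():
                if t not in p.timepoints:
                    continue
                if (
                    config.anchor_post_instrument is not None
                    and name != config.anchor_post_instrument
                ):
                    continue
                spec = specs[name]
                mean, sd = _post_moments(spec, p)
                std = (post[name][t] - mean) / sd
                comps.append(std if spec.increase_is_better else -std)
            post_wb = np.mean(comps, axis=0)
        else:
            post_wb = 0.0
        noise_sd = config.anchor_noise_sd
        if config.anchor_noise_by_timepoint is not None:
            noise_sd = noise_sd * config.anchor_noise_by_timepoint.get(t, 1.0)
        z = (1.0 - w) * u[t] + w * post_wb
        if noise_sd > 0:
            z = z + rng.normal(0, noise_sd, size=n)
        t1, t2, t3, t4 = config.taus
        g = np.select([z > t1, z > t2, z > t3, z > t4], [1, 2, 3, 4], default=5)
        grc[t], zs[t] = g, z

    # assemble long-format rows, then knock out items at random
    rows = []
    for name, p in config.instruments.items():
        for t in p.timepoints:
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pids,
                        "group": group_of,
                        "timepoint": t,
                        "instrument": name,
                        "baseline_score": base[name],
                        "post_score": post[name][t],
                        "grc": grc[t].astype(float),
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    m = len(df)
    if config.missing_baseline > 0:
        df.loc[rng.random(m) < config.missing_baseline, "baseline_score"] = np.nan
    if config.missing_post > 0:
        df.loc[rng.random(m) < config.missing_post, "post_score"] = np.nan
    if config.missing_grc > 0:
        df.loc[rng.random(m) < config.missing_grc, "grc"] = np.nan

    table = compute_changes(AnchoredOutcomeTable(df, specs))

    latent = pd.concat(
        [
            pd.DataFrame(
                {"patient_id": pids, "timepoint": t, "u": u[t], "z": zs[t], "grc": grc[t]}
            )
            for t in all_tp
        ],
        ignore_index=True,
    )
    mid_thr = {
        name: implied_mid_threshold(p, config.taus) if w == 0 else float("nan")
        for name, p in config.instruments.items()
    }
    pass_thr = {}
    for name, p in config.instruments.items():
        valid = w == 1.0 and config.anchor_post_instrument in (None, name)
        if valid and config.anchor_post_instrument is None and len(config.instruments) > 1:
            valid = False  # averaged anchor has no single-instrument cut
        pass_thr[name] = {
            "GRC 1": implied_pass_threshold(specs[name], p, config.taus[0])
            if valid
            else float("nan"),
            "GRC 1+2": implied_pass_threshold(specs[name], p, config.taus[1])
            if valid
            else float("nan"),
        }
    truth = GroundTruth(latent, mid_thr, pass_thr, config.taus, seed)
    return table, truth


#: noise-free conditions with planted thresholds kept clear of the scale
#: boundaries, so floor/ceiling censoring cannot blur the planted cuts
#: (censoring under the default conditions is exercised separately)
PERFECT_ANCHOR_PARAMS: dict[str, InstrumentSimParams] = {
    "pain_rest": InstrumentSimParams(60.0, 8.0, 15.0, 8.0, 0.0, (6, 12, 24)),
    "pain_activity": InstrumentSimParams(70.0, 10.0, 30.0, 10.0, 0.0, (6, 12, 24)),
    "cs": InstrumentSimParams(50.0, 8.0, 20.0, 8.0, 0.0, (6, 24)),
    # effect chosen so the planted cut (2.5) sits between integers: rounding
    # to the 0-12 integer scale then cannot mix the two anchor classes
    "sst": InstrumentSimParams(4.0, 1.5, 3.505, 1.5, 0.0, (6, 24)),
}


def scenario_library() -> dict[str, TrialSimConfig]:
    """Named study conditions used throughout the tests and analyses."""
    base = TrialSimConfig()
    noise_free = dict(PERFECT_ANCHOR_PARAMS)
    pass_params = {
        "pain_activity": DEFAULT_SIM_PARAMS["pain_activity"],
    }
    return {
        # default conditions: strong activity-pain/CS/SST anchors, weak rest-pain
        "fimpact-like": base,
        # deterministic anchor, no measurement noise or missingness
        "perfect-anchor": replace(
            base,
            instruments=noise_free,
            anchor_noise_sd=0.0,
            missing_post=0.0,
            missing_grc=0.0,
            missing_baseline=0.0,
        ),
        # anchor independent of outcomes; cuts scaled with the noise so the
        # five GRC categories keep realistic proportions
        "worthless-anchor": replace(
            base,
            anchor_noise_sd=1000.0,
            taus=tuple(t * 1000.0 for t in DEFAULT_TAUS),
        ),
        # patients rate current state, not change
        "recall-biased": replace(base, recall_bias_weight=0.7),
        # anchor driven purely by activity-pain post score: planted PASS cut
        "planted-pass": replace(
            base,
            instruments=pass_params,
            recall_bias_weight=1.0,
            anchor_post_instrument="pain_activity",
            anchor_noise_sd=0.0,
            missing_post=0.0,
            missing_grc=0.0,
            missing_baseline=0.0,
        ),
    }


def get_scenario(name: str) -> TrialSimConfig:
    lib = scenario_library()
    if name not in lib:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(lib)}")
    return lib[name]
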