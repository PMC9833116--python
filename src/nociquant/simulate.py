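"""Synthetic cohorts with known ground truth.

Four generators emulate the data types of a burn-injury lipid-mediator
study so that every downstream stage can be exercised against planted
truth:

* a paired burn/control microdialysate time course (30-min fractions from
  -30 to 180 min) with planted features following an increase-then-plateau
  profile in burn samples only;
* a biopsy lipidomics cohort with per-sample tissue weights, interleaved
  pooled-QC injections and planted fold changes;
* Fura-2 ratio traces with drug-application pulses, a terminal
  depolarising KCl pulse and per-class response labels (including dead
  cells that fail the viability gate);
* heat-ramp traces (32 -> 55 degC linear) whose log-signal is piecewise
  linear in reciprocal absolute temperature, breaking at a per-cell
  threshold drawn from a Gaussian mixture.

Noise models: multiplicative log-normal (unit mean) for LC-MS intensities,
additive Gaussian for ratio traces.  Each generator draws from a single
``numpy.random.Generator`` stream in a fixed, documented order, so one
integer seed reproduces a cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calcium import ApplicationWindow, Trace
from .tables import FeatureTable

__all__ = [
    "MetabolomicsTruth",
    "TraceTruth",
    "gen_metabolomics_timecourse",
    "gen_lipidomics_cohort",
    "gen_calcium_traces",
    "gen_heat_ramp_cohort",
    "DEFAULT_FRACTIONS_MIN",
    "DEFAULT_THRESHOLD_MEANS_C",
]

#: microdialysate fraction start times, minutes relative to injury
DEFAULT_FRACTIONS_MIN = (-30, 0, 30, 60, 90, 120, 150, 180)

#: peak temperatures of the four heat-threshold populations, degC
DEFAULT_THRESHOLD_MEANS_C = (33.9, 39.8, 44.4, 52.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv < 0:
        raise ValueError("noise CV must be non-negative")
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# microdialysate time course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetabolomicsTruth:
    """Ground truth for a planted microdialysate time course."""

    planted_feature_ids: frozenset
    temporal_profile: tuple  # multiplicative burn effect per fraction, >= 1
    effect_onset_fraction: int
    noise_cv: float

    def __post_init__(self) -> None:
        p = np.asarray(self.temporal_profile, dtype=float)
        if np.any(p < 1.0) or np.any(np.diff(p) < -1e-12):
            raise ValueError("temporal profile must be >=1 and non-decreasing")


def temporal_profile(n_fractions: int, effect_size: float,
                     onset: int = 1, rise: int = 3) -> np.ndarray:
    """Increase-then-plateau burn profile: 1 before ``onset``, linear rise
    over ``rise`` fractions, then constant at ``effect_size``."""
    p = np.ones(n_fractions)
    for i in range(onset, n_fractions):
        step = min(i - onset + 1, rise) / rise
        p[i] = 1.0 + (effect_size - 1.0) * step
    return p


def gen_metabolomics_timecourse(
    n_subjects: int,
    n_features: int,
    n_planted: int,
    fractions: tuple = DEFAULT_FRACTIONS_MIN,
    noise_cv: float = 0.2,
    effect_size: float = 3.0,
    effect_onset_fraction: int = 1,
    ion_mode: str = "+",
    seed: int = 0,
) -> tuple[FeatureTable, MetabolomicsTruth]:
    """Paired burn/control microdialysate fractions with planted features.

    Each subject contributes one burn and one control sample per fraction.
    Planted features are multiplied by the temporal profile in burn samples
    from the effect onset; the pre-injury fraction is always unaffected.

    Draw order: feature m/z, feature RT, feature baselines, planted ids,
    then one noise value per (sample, feature) cell.
    """
    if n_subjects <= 0 or n_features <= 0 or n_planted < 0:
        raise ValueError("counts must be positive")
    if n_planted > n_features:
        raise ValueError("cannot plant more features than exist")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    n_frac = len(fractions)

    fids = [f"F{i:05d}" for i in range(n_features)]
    features = pd.DataFrame(
        {
            "mz": rng.uniform(100, 1200, n_features),
            "rt_s": rng.uniform(30, 700, n_features),
            "ion_mode": ion_mode,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    base = rng.lognormal(mean=np.log(1e4), sigma=1.0, size=n_features)
    planted = rng.choice(n_features, size=n_planted, replace=False)
    planted_mask = np.zeros(n_features, dtype=bool)
    planted_mask[planted] = True

    profile = temporal_profile(n_frac, effect_size, onset=effect_onset_fraction)

    rows, sample_ids, meta = [], [], []
    for s in range(n_subjects):
        for fi in range(n_frac):
            for cond in ("burn", "control"):
                mult = np.ones(n_features)
                if cond == "burn":
                    mult[planted_mask] = profile[fi]
                noise = _lognormal_factor(rng, noise_cv, n_features)
                rows.append(base * mult * noise)
                sample_ids.append(f"sub{s:02d}_{cond}_f{fi}")
                meta.append((f"sub{s:02d}", cond, fi, False, np.nan))

    samples = pd.DataFrame(
        meta, columns=["subject", "condition", "fraction", "is_qc", "weight_mg"],
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = FeatureTable(
        intensities=pd.DataFrame(np.array(rows), index=samples.index, columns=features.index),
        features=features,
        samples=samples,
    )
    truth = MetabolomicsTruth(
        planted_feature_ids=frozenset(fids[i] for i in planted),
        temporal_profile=tuple(profile),
        effect_onset_fraction=effect_onset_fraction,
        noise_cv=noise_cv,
    )
    return table, truth


# ---------------------------------------------------------------------------
# biopsy lipidomics cohort
# ---------------------------------------------------------------------------

def gen_lipidomics_cohort(
    n_pairs: int,
    n_features: int,
    planted_fc: dict | None = None,
    qc_every: int = 5,
    weights_mg: tuple[float, float] = (10.0, 2.0),
    noise_cv: float = 0.2,
    instrument_cv: float = 0.05,
    seed: int = 0,
) -> FeatureTable:
    """Burn/control biopsy pairs with tissue weights and interleaved QCs.

    ``planted_fc`` maps feature id (``"L0000"``-style) to a fold change
    applied to burn samples.  Intensities scale with tissue weight (so the
    weight-normalisation step has something to undo).  A pooled QC sample --
    the arithmetic mean of all biological samples, times instrument noise of
    CV ``instrument_cv`` -- is injected after every ``qc_every`` biological
    samples.

    Draw order: feature m/z, RT, baselines, per-sample weights, biological
    noise (per sample), QC instrument noise (per QC).
    """
    if n_pairs <= 0 or n_features <= 0:
        raise ValueError("counts must be positive")
    if qc_every < 1:
        raise ValueError("qc_every must be >= 1")
    w_mean, w_sd = weights_mg
    if w_mean <= 0 or w_sd < 0:
        raise ValueError("weight distribution must have positive mean and non-negative sd")
    planted_fc = dict(planted_fc or {})
    rng = np.random.default_rng(seed)

    fids = [f"L{i:04d}" for i in range(n_features)]
    unknown = set(planted_fc) - set(fids)
    if unknown:
        raise ValueError(f"planted_fc refers to unknown features: {sorted(unknown)}")
    features = pd.DataFrame(
        {
            "mz": rng.uniform(400, 900, n_features),
            "rt_s": rng.uniform(60, 1100, n_features),
            "ion_mode": "+",
        },
        index=pd.Index(fids, name="feature_id"),
    )
    base = rng.lognormal(mean=np.log(1e5), sigma=1.0, size=n_features)
    fc = np.ones(n_features)
    for f, v in planted_fc.items():
        fc[fids.index(f)] = v

    n_bio = 2 * n_pairs
    weights = np.abs(rng.normal(w_mean, w_sd, n_bio))
    weights[weights == 0] = w_mean  # degenerate draw guard

    bio_rows, bio_ids, bio_meta = [], [], []
    k = 0
    for p in range(n_pairs):
        for cond in ("burn", "control"):
            mult = fc if cond == "burn" else np.ones(n_features)
            noise = _lognormal_factor(rng, noise_cv, n_features)
            bio_rows.append(base * mult * (weights[k] / w_mean) * noise)
            bio_ids.append(f"pat{p:02d}_{cond}")
            bio_meta.append((f"pat{p:02d}", cond, np.nan, False, weights[k]))
            k += 1

    bio = np.array(bio_rows)
    qc_template = bio.mean(axis=0)
    n_qc = n_bio // qc_every

    rows, ids, meta = [], [], []
    qi = 0
    for i in range(n_bio):
        rows.append(bio[i]); ids.append(bio_ids[i]); meta.append(bio_meta[i])
        if (i + 1) % qc_every == 0:
            rows.append(qc_template * _lognormal_factor(rng, instrument_cv, n_features))
            ids.append(f"QC{qi:02d}")
            meta.append(("QC", None, np.nan, True, np.nan))
            qi += 1
    assert qi == n_qc

    samples = pd.DataFrame(
        meta, columns=["subject", "condition", "fraction", "is_qc", "weight_mg"],
        index=pd.Index(ids, name="sample_id"),
    )
    return FeatureTable(
        intensities=pd.DataFrame(np.array(rows), index=samples.index, columns=features.index),
        features=features,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceTruth:
    """Planted labels for one synthetic cell."""

    cell_id: str
    cell_class: str
    responded_windows: tuple = ()
    true_amplitude: float | None = None
    true_threshold_C: float | None = None
    component_index: int | None = None
    onset_lag_s: float = 0.0

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "cell_class": self.cell_class,
            "responded_windows": list(self.responded_windows),
            "true_amplitude": self.true_amplitude,
            "true_threshold_C": self.true_threshold_C,
            "component_index": self.component_index,
            "onset_lag_s": self.onset_lag_s,
        }


#: which (non-KCl) window labels each cell class responds to; every class
#: except "dead" also responds to the depolarising pulse
CLASS_RESPONDS = {
    "responder": lambda label: True,
    "capsaicin_only": lambda label: "capsaicin" in label.lower(),
    "kcl_only": lambda label: False,
    "dead": lambda label: False,
}

DEFAULT_CLASS_MIX = {
    "responder": 0.20,
    "capsaicin_only": 0.30,
    "kcl_only": 0.40,
    "dead": 0.10,
}


def default_windows() -> list[ApplicationWindow]:
    return [
        ApplicationWindow("LPC 30uM", 60.0, 90.0),
        ApplicationWindow("capsaicin 500nM", 160.0, 190.0),
        ApplicationWindow("KCl 60mM", 260.0, 290.0, is_depolarising=True),
    ]


def gen_calcium_traces(
    n_cells: int,
    class_mix: dict | None = None,
    windows: list[ApplicationWindow] | None = None,
    dt_s: float = 2.0,
    baseline_mean: float = 0.5,
    baseline_sd: float = 0.01,
    amplitude_mean: float = 0.3,
    amplitude_sd: float = 0.05,
    decay_tau_s: float = 25.0,
    onset_lag_max_s: float = 6.0,
    seed: int = 0,
) -> tuple[list[Trace], list[TraceTruth]]:
    """Responder / capsaicin-only / KCl-only / dead Fura-2 traces.

    Responding windows get an instantaneous-rise, mono-exponential-decay
    transient whose amplitude is drawn from N(amplitude_mean, amplitude_sd)
    truncated at 5x ``baseline_sd``; dead cells stay flat through KCl.
    Gaussian noise of SD ``baseline_sd`` is added everywhere.

    Draw order per cell: class, then per responding window (amplitude,
    onset lag), then the trace noise vector.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    labels = list(mix)
    probs = np.array([mix[c] for c in labels], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    unknown = set(labels) - set(CLASS_RESPONDS)
    if unknown:
        raise ValueError(f"unknown cell classes: {sorted(unknown)}")
    windows = list(windows) if windows is not None else default_windows()
    if not windows or not windows[-1].is_depolarising:
        raise ValueError("last window must be the depolarising stimulus")

    rng = np.random.default_rng(seed)
    t_end = windows[-1].end_s + windows[-1].onset_lag_s + 30.0
    t = np.arange(0.0, t_end, dt_s)

    traces, truths = [], []
    for i in range(n_cells):
        cls = labels[rng.choice(len(labels), p=probs)]
        ratio = np.full_like(t, baseline_mean)
        responded, amps, lag_used = [], [], 0.0
        for w in windows:
            if w.is_depolarising:
                hit = cls != "dead"
            else:
                hit = CLASS_RESPONDS[cls](w.label)
            if not hit:
                continue
            amp = max(float(rng.normal(amplitude_mean, amplitude_sd)), 5.0 * baseline_sd)
            lag = float(rng.uniform(0.0, onset_lag_max_s))
            onset = w.start_s + lag
            m = t >= onset
            ratio[m] += amp * np.exp(-(t[m] - onset) / decay_tau_s)
            responded.append(w.label)
            amps.append(amp)
            lag_used = lag
        ratio = ratio + rng.normal(0.0, baseline_sd, t.size)
        cid = f"cell{i:04d}"
        traces.append(Trace(cell_id=cid, t=t.copy(), ratio=ratio, windows=windows))
        truths.append(
            TraceTruth(
                cell_id=cid,
                cell_class=cls,
                responded_windows=tuple(responded),
                true_amplitude=float(np.mean(amps)) if amps else None,
                onset_lag_s=lag_used,
            )
        )
    return traces, truths


# ---------------------------------------------------------------------------
# heat-ramp cohort
# ---------------------------------------------------------------------------

def gen_heat_ramp_cohort(
    n_cells: int,
    component_means_C: tuple = DEFAULT_THRESHOLD_MEANS_C,
    component_sds_C: tuple = (1.5, 1.5, 1.5, 1.5),
    component_weights: tuple | None = None,
    ramp: tuple[float, float] = (32.0, 55.0),
    ramp_duration_s: float = 230.0,
    hold_s: float = 30.0,
    dt_s: float = 2.0,
    baseline_mean: float = 0.5,
    baseline_sd: float = 0.005,
    sub_slope: float = 2.0,
    supra_gain: float = 5.0,
    signal_floor: float = 0.02,
    seed: int = 0,
) -> tuple[list[Trace], list[TraceTruth]]:
    """Heat-responsive cells on a linear 32 -> 55 degC ramp.

    The recording opens with a ``hold_s``-second resting segment at the
    ramp's start temperature (no heat-evoked signal), from which the
    analysis estimates the resting ratio, then ramps linearly.  Each cell's
    threshold is drawn from a Gaussian mixture over the population
    components (redrawn in the rare case it falls outside the ramp
    interior).  In Arrhenius coordinates (x = 1000/T_K vs log10 of the
    baseline-subtracted signal) the noiseless ramp is piecewise linear:
    slope ``sub_slope`` below the threshold and ``sub_slope * supra_gain``
    above it, continuous at the breakpoint.

    Draw order per cell: component, threshold, noise vector.
    """
    means = np.asarray(component_means_C, dtype=float)
    sds = np.asarray(component_sds_C, dtype=float)
    if means.shape != sds.shape:
        raise ValueError("means and sds must have equal length")
    lo, hi = ramp
    if np.any(means < lo) or np.any(means > hi):
        raise ValueError("component means must lie within the ramp range")
    if component_weights is None:
        w = np.full(means.size, 1.0 / means.size)
    else:
        w = np.asarray(component_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
    if supra_gain <= 1.0:
        raise ValueError("supra_gain must exceed 1 (no detectable acceleration)")
    if np.any(sds < 0):
        raise ValueError("component sds must be non-negative")

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, hold_s + ramp_duration_s + dt_s / 2, dt_s)
    on_ramp = t > hold_s
    temp = np.full_like(t, lo)
    temp[on_ramp] = lo + (hi - lo) * (t[on_ramp] - hold_s) / ramp_duration_s
    x = 1000.0 / (temp + 273.15)
    x_start = x[on_ramp][0]

    traces, truths = [], []
    for i in range(n_cells):
        comp = int(rng.choice(means.size, p=w))
        theta = float(rng.normal(means[comp], sds[comp]))
        while not (lo + 0.3 < theta < hi - 0.3):
            theta = float(rng.normal(means[comp], sds[comp]))
        x_star = 1000.0 / (theta + 273.15)
        y0 = np.log10(signal_floor)
        y = np.where(
            x >= x_star,
            y0 + sub_slope * (x_start - x),
            y0 + sub_slope * (x_start - x_star) + sub_slope * supra_gain * (x_star - x),
        )
        signal = np.where(on_ramp, 10.0 ** y, 0.0)
        ratio = baseline_mean + signal + rng.normal(0.0, baseline_sd, t.size)
        cid = f"heat{i:04d}"
        traces.append(Trace(cell_id=cid, t=t.copy(), ratio=ratio, temp_C=temp.copy(), windows=[]))
        truths.append(
            TraceTruth(cell_id=cid, cell_class="heat", true_threshold_C=theta,
                       component_index=comp)
        )
    return traces, truths
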