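"""Ratiometric calcium-imaging traces: response calling and pooling.

A Fura-2 loaded cell reports intracellular calcium as the F355/F380
excitation ratio, sampled on a uniform grid (typically every 2 s).  Drug
applications are annotated as time windows; the last window is a
depolarising high-potassium (KCl) pulse used as a viability gate.

A transient counts as a response to a window when its amplitude exceeds
three times the standard deviation of the pre-application baseline *and*
its onset falls inside the window (plus a short perfusion lag).  Cells that
fail the terminal KCl gate are excluded from all counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ApplicationWindow",
    "Trace",
    "ResponseCall",
    "BaselineError",
    "baseline_stats",
    "call_response",
    "call_all",
    "viability_filter",
    "pool_counts",
    "save_traces",
    "load_traces",
]

#: default pre-application baseline length, seconds
BASELINE_S = 30.0
#: minimum number of samples required in the baseline interval
MIN_BASELINE_SAMPLES = 10


class BaselineError(ValueError):
    """Baseline interval unusable (truncated by an earlier window)."""


@dataclass(frozen=True)
class ApplicationWindow:
    """A drug-application interval.

    ``onset_lag_s`` extends the interval in which a transient onset is
    accepted, absorbing the dead time of the gravity perfusion system.
    """

    label: str
    start_s: float
    end_s: float
    is_depolarising: bool = False
    onset_lag_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"window {self.label!r}: start must precede end")


@dataclass
class Trace:
    """Per-cell ratiometric time series with application windows."""

    cell_id: str
    t: np.ndarray
    ratio: np.ndarray
    windows: list[ApplicationWindow] = field(default_factory=list)
    temp_C: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temp_C is not None:
            self.temp_C = np.asarray(self.temp_C, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.ratio.shape:
            raise ValueError("t and ratio must be 1-D arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if not np.all(np.isfinite(self.ratio)):
            raise ValueError("ratio must be finite")
        starts = [w.start_s for w in self.windows]
        if starts != sorted(starts):
            raise ValueError("windows must be time-ordered")
        for a, b in zip(self.windows, self.windows[1:]):
            if b.start_s < a.end_s:
                raise ValueError(f"windows {a.label!r} and {b.label!r} overlap")

    @property
    def depolarising_window(self) -> ApplicationWindow:
        dep = [w for w in self.windows if w.is_depolarising]
        if len(dep) != 1:
            raise ValueError(f"cell {self.cell_id}: expected exactly one depolarising window")
        return dep[0]


@dataclass(frozen=True)
class ResponseCall:
    """Outcome of the 3-sigma response test for one (cell, window) pair."""

    cell_id: str
    window: str
    responded: bool
    baseline_mean: float
    baseline_sd: float
    amplitude: float
    auc: float
    onset_s: float | None
    degenerate: bool = False  # flat trace with zero baseline SD


def baseline_stats(trace: Trace, window: ApplicationWindow,
                   baseline_s: float = BASELINE_S) -> tuple[float, float]:
    """Mean and sample SD of the baseline preceding ``window``.

    The baseline is the ``baseline_s`` seconds immediately before the window
    start, clipped so it never reaches into an earlier application window.
    Raises :class:`BaselineError` when fewer than ``MIN_BASELINE_SAMPLES``
    samples remain after clipping.
    """
    lo = window.start_s - baseline_s
    for w in trace.windows:
        if w is not window and w.end_s <= window.start_s:
            lo = max(lo, w.end_s)
    mask = (trace.t >= lo) & (trace.t < window.start_s)
    n = int(mask.sum())
    if n < MIN_BASELINE_SAMPLES:
        raise BaselineError(
            f"cell {trace.cell_id}, window {window.label!r}: only {n} baseline samples"
        )
    seg = trace.ratio[mask]
    return float(seg.mean()), float(seg.std(ddof=1))


def call_response(trace: Trace, window: ApplicationWindow,
                  baseline_s: float = BASELINE_S) -> ResponseCall:
    """Apply the 3-sigma amplitude rule with temporal correspondence.

    ``responded`` requires *strictly* ``amplitude > 3 * baseline_sd`` and an
    onset (first sample exceeding mean + 3 SD) inside
    ``[start, end + onset_lag]``.  AUC is the baseline-subtracted trapezoid
    integral over the same interval and is reported even for non-responders.
    """
    mu, sd = baseline_stats(trace, window, baseline_s=baseline_s)
    hi = window.end_s + window.onset_lag_s
    mask = (trace.t >= window.start_s) & (trace.t <= hi)
    if not mask.any():
        raise ValueError(f"window {window.label!r} contains no samples")
    seg = trace.ratio[mask]
    tseg = trace.t[mask]
    amplitude = float(seg.max() - mu)
    auc = float(np.trapezoid(seg - mu, tseg))
    above = tseg[seg > mu + 3.0 * sd]
    onset = float(above[0]) if above.size else None
    degenerate = sd == 0.0 and amplitude <= 0.0
    responded = (amplitude > 3.0 * sd) and onset is not None and not degenerate
    return ResponseCall(
        cell_id=trace.cell_id,
        window=window.label,
        responded=bool(responded),
        baseline_mean=mu,
        baseline_sd=sd,
        amplitude=amplitude,
        auc=auc,
        onset_s=onset,
        degenerate=degenerate,
    )


def call_all(traces: list[Trace], baseline_s: float = BASELINE_S) -> pd.DataFrame:
    """Response calls for every (cell, window) pair, as a tidy frame."""
    rows = []
    for tr in traces:
        for w in tr.windows:
            c = call_response(tr, w, baseline_s=baseline_s)
            rows.append(
                dict(cell_id=c.cell_id, window=c.window,
                     is_depolarising=w.is_depolarising, responded=c.responded,
                     baseline_mean=c.baseline_mean, baseline_sd=c.baseline_sd,
                     amplitude=c.amplitude, auc=c.auc, onset_s=c.onset_s)
            )
    return pd.DataFrame(rows)


def viability_filter(calls: pd.DataFrame) -> list[str]:
    """Cell ids that responded to their depolarising (KCl) window."""
    dep = calls[calls["is_depolarising"]]
    all_cells = calls["cell_id"].unique()
    missing = set(all_cells) - set(dep["cell_id"])
    if missing:
        raise ValueError(f"cells without a depolarising call: {sorted(missing)}")
    return dep.loc[dep["responded"], "cell_id"].tolist()


def pool_counts(calls: pd.DataFrame, labels: list[str] | None = None,
                cross: list[tuple[str, str]] | None = None) -> dict:
    """Responder counts per window label on the viable-cell subset.

    Returns a dict with ``per_label`` (label -> (responders, total)) and
    ``cross`` ((label_a, label_b) -> cells responding to both).  The viability
    gate is applied here: only cells passing the KCl test are counted and the
    depolarising window itself is not reported as a stimulus.
    """
    viable = set(viability_filter(calls))
    sub = calls[calls["cell_id"].isin(viable) & ~calls["is_depolarising"]]
    if labels is None:
        labels = list(dict.fromkeys(sub["window"]))
    per_label: dict[str, tuple[int, int]] = {}
    responders: dict[str, set] = {}
    for lab in labels:
        grp = sub[sub["window"] == lab]
        if grp.empty:
            raise ValueError(f"window label {lab!r} absent from all traces")
        responders[lab] = set(grp.loc[grp["responded"], "cell_id"])
        per_label[lab] = (len(responders[lab]), int(grp["cell_id"].nunique()))
    out = {"per_label": per_label, "n_viable": len(viable)}
    if cross:
        out["cross"] = {
            (a, b): len(responders[a] & responders[b]) for a, b in cross
        }
    return out


# -- I/O -------------------------------------------------------------------

def save_traces(traces: list[Trace], csv_path: str | Path, sidecar_path: str | Path,
                truth: list[dict] | None = None) -> None:
    """Write a cohort as one long CSV plus a JSON window/truth sidecar."""
    frames = []
    for tr in traces:
        df = pd.DataFrame({"cell_id": tr.cell_id, "t_s": tr.t, "ratio": tr.ratio})
        df["temp_C"] = tr.temp_C if tr.temp_C is not None else np.nan
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    side = {
        "windows": {
            tr.cell_id: [
                dict(label=w.label, start_s=w.start_s, end_s=w.end_s,
                     is_depolarising=w.is_depolarising, onset_lag_s=w.onset_lag_s)
                for w in tr.windows
            ]
            for tr in traces
        }
    }
    if truth is not None:
        side["truth"] = truth
    Path(sidecar_path).write_text(json.dumps(side, indent=1))


def load_traces(csv_path: str | Path, sidecar_path: str | Path) -> tuple[list[Trace], list[dict] | None]:
    df = pd.read_csv(csv_path)
    side = json.loads(Path(sidecar_path).read_text())
    traces = []
    for cid, grp in df.groupby("cell_id", sort=False):
        temp = grp["temp_C"].to_numpy()
        traces.append(
            Trace(
                cell_id=str(cid),
                t=grp["t_s"].to_numpy(),
                ratio=grp["ratio"].to_numpy(),
                temp_C=None if np.isnan(temp).all() else temp,
                windows=[ApplicationWindow(**w) for w in side["windows"][str(cid)]],
            )
        )
    return traces, side.get("truth")
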