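"""Readers and writers for the pipeline's tabular artifacts.

All tables are plain CSV with documented columns; metadata rides in JSON
sidecars so every output is self-describing and reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import PiecewiseSPRF, SPRFLaw
from .fs_model import FSModelParams, NeuronTrace, SpikeTrain
from .pipeline import SPRFCurve, SPRFSample

TRACE_COLUMNS = ["time_ms", "v_mV"]
SAMPLE_COLUMNS = ["phi_cycles", "dphi_cycles", "tp_ms", "tn_ms", "T_ms",
                  "ge_nS", "gi_nS", "F_hz"]


# -- neuron traces ----------------------------------------------------------

def write_trace_csv(trace: NeuronTrace, path):
    df = pd.DataFrame({"time_ms": trace.t_ms, "v_mV": trace.v_mV})
    for name, series in trace.currents_pA.items():
        df[f"i_{name}_pA"] = series
    df.to_csv(path, index=False)


def read_trace_csv(path) -> NeuronTrace:
    df = pd.read_csv(path)
    currents = {c[2:-3]: df[c].to_numpy()
                for c in df.columns if c.startswith("i_") and c.endswith("_pA")}
    t = df["time_ms"].to_numpy()
    return NeuronTrace(t_ms=t, v_mV=df["v_mV"].to_numpy(),
                       currents_pA=currents, gates={},
                       dt_ms=float(t[1] - t[0]))


# -- spike trains -----------------------------------------------------------

def write_spikes_csv(train: SpikeTrain, path):
    path = Path(path)
    pd.DataFrame({"times_ms": train.times_ms}).to_csv(path, index=False)
    meta = {"threshold_mV": train.threshold_mV, "source": train.source,
            "min_separation_ms": train.min_separation_ms}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_spikes_csv(path) -> SpikeTrain:
    path = Path(path)
    times = pd.read_csv(path)["times_ms"].to_numpy()
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    return SpikeTrain(times_ms=times,
                      threshold_mV=meta.get("threshold_mV", np.nan),
                      source=meta.get("source", ""),
                      min_separation_ms=meta.get("min_separation_ms", 2.0))


# -- SPRF samples -----------------------------------------------------------

def write_samples_csv(curve: SPRFCurve, path, meta_path=None):
    path = Path(path)
    curve.to_frame().to_csv(path, index=False)
    meta = dict(curve.meta)
    meta.update({"ge_nS": curve.g_e_nS, "gi_nS": curve.g_i_nS,
                 "F_hz": curve.F_hz, "T_ms": curve.T_ms})
    target = Path(meta_path) if meta_path else path.with_suffix(".json")
    target.write_text(json.dumps(meta, indent=1, default=float))


def read_samples_csv(path) -> SPRFCurve:
    path = Path(path)
    df = pd.read_csv(path)
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    g_e = float(df["ge_nS"].iloc[0])
    g_i = float(df["gi_nS"].iloc[0])
    F = float(df["F_hz"].iloc[0])
    samples = [SPRFSample(t_p_ms=r.tp_ms, t_n_ms=r.tn_ms, T_ms=r.T_ms,
                          g_e_nS=g_e, g_i_nS=g_i, F_hz=F)
               for r in df.itertuples()]
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    return SPRFCurve(samples=samples, g_e_nS=g_e, g_i_nS=g_i, F_hz=F,
                     T_ms=float(df["T_ms"].iloc[0]), meta=meta)


# -- fits and the law -------------------------------------------------------

def fit_to_dict(fit: PiecewiseSPRF, diag=None) -> dict:
    out = {"alpha": fit.alpha, "beta": fit.beta, "phi_c": fit.phi_c,
           "units": {"alpha": "cycles/cycle", "beta": "cycles/cycle",
                     "phi_c": "cycles"}}
    if diag is not None:
        out.update({
            "sse": diag.sse,
            "n_removed": int(diag.removed_idx.size),
            "removed_indices": diag.removed_idx.tolist(),
            "chi2": diag.chi2, "chi2_red": diag.chi2_red, "p": diag.p_value,
        })
    return out


def write_fit_json(fit: PiecewiseSPRF, path, diag=None):
    Path(path).write_text(json.dumps(fit_to_dict(fit, diag), indent=1,
                                     default=float))


def read_fit_json(path) -> PiecewiseSPRF:
    d = json.loads(Path(path).read_text())
    return PiecewiseSPRF(alpha=d["alpha"], beta=d["beta"], phi_c=d["phi_c"])


def write_law_json(law: SPRFLaw, path):
    d = dataclasses.asdict(law)
    d["units"] = {"a": "1/nS", "b": "1/nS", "c": "cycles", "d": "cycles/nS"}
    Path(path).write_text(json.dumps(d, indent=1))


def read_law_json(path) -> SPRFLaw:
    d = json.loads(Path(path).read_text())
    return SPRFLaw(a=d["a"], b=d["b"], c=d["c"], d=d["d"])


# -- model parameters -------------------------------------------------------

def write_params(params: FSModelParams, path):
    Path(path).write_text(json.dumps(dataclasses.asdict(params), indent=1))


def read_params(path) -> FSModelParams:
    return FSModelParams(**json.loads(Path(path).read_text()))


# -- tongues ----------------------------------------------------------------

def write_tongue(t, path, summary_path=None):
    """Tongue grid as long-format CSV plus a JSON summary (area and
    per-row band boundaries)."""
    path = Path(path)
    a, r = np.meshgrid(t.axis_values, t.r_values, indexing="ij")
    pd.DataFrame({t.axis_name: a.ravel(), "r": r.ravel(),
                  "entrained": t.entrained.ravel().astype(int)}
                 ).to_csv(path, index=False)
    summary = {
        "axis_name": t.axis_name, "sigma": t.sigma, "fixed": t.fixed,
        "n_bins": t.n_bins, "area": t.area, "cell_area": t.cell_area,
        "law": dataclasses.asdict(t.law),
        "boundaries": {
            f"{v:g}": t.boundary(i)
            for i, v in enumerate(t.axis_values)
        },
    }
    target = Path(summary_path) if summary_path else path.with_suffix(".json")
    target.write_text(json.dumps(summary, indent=1, default=float))
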