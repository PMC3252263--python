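"""CSV/JSON readers and writers for PRC samples, models and circuits."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .prc import PRCMeasurementSet, PRCModel
from .locking import CircuitSpec

__all__ = [
    "read_samples_csv", "write_samples_csv",
    "read_model_json", "write_model_json",
    "read_circuit_json", "write_circuit_json",
    "write_sweep_csv", "write_spikes_csv", "write_lags_csv",
    "write_histogram_csv", "write_summary_json",
]


def read_samples_csv(path, coupling_sign: str,
                     intrinsic_period: float = 100.0) -> PRCMeasurementSet:
    df = pd.read_csv(path)
    if not {"phase", "resetting"} <= set(df.columns):
        raise ValueError(f"{path}: need columns phase,resetting")
    return PRCMeasurementSet(df["phase"].to_numpy(), df["resetting"].to_numpy(),
                             coupling_sign, intrinsic_period)


def write_samples_csv(path, samples: PRCMeasurementSet) -> None:
    pd.DataFrame({"phase": samples.phases, "resetting": samples.resettings}
                 ).to_csv(path, index=False)


def read_model_json(path) -> PRCModel:
    return PRCModel.from_dict(json.loads(Path(path).read_text()))


def write_model_json(path, model: PRCModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def write_circuit_json(path, spec: CircuitSpec) -> None:
    d = {
        "period_a_ms": spec.period_1,
        "period_b_ms": spec.period_2,
        "delay_ab_ms": spec.delay_12,
        "delay_ba_ms": spec.delay_21,
        "coupling_sign": spec.coupling_sign,
        "prc_a": spec.prc_1.to_dict(),
        "prc_b": spec.prc_2.to_dict(),
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_circuit_json(path) -> CircuitSpec:
    d = json.loads(Path(path).read_text())
    return CircuitSpec(
        period_1=d["period_a_ms"], period_2=d["period_b_ms"],
        prc_1=PRCModel.from_dict(d["prc_a"]), prc_2=PRCModel.from_dict(d["prc_b"]),
        delay_12=d["delay_ab_ms"], delay_21=d["delay_ba_ms"],
    )


def write_sweep_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_spikes_csv(path, spike_log: dict) -> None:
    rows = [(n, t) for n, arr in spike_log.items() for t in np.asarray(arr)]
    pd.DataFrame(rows, columns=["neuron", "spike_time_ms"]
                 ).sort_values("spike_time_ms").to_csv(path, index=False)


def write_lags_csv(path, series) -> None:
    n = len(series)  # the two directions can differ by one at the edges
    pd.DataFrame({
        "cycle": np.arange(n),
        "tl1_ms": series.tl_1[:n],
        "tl2_ms": series.tl_2[:n],
    }).to_csv(path, index=False)


def write_histogram_csv(path, centers, density) -> None:
    pd.DataFrame({"bin_center": centers, "density": density}
                 ).to_csv(path, index=False)


def write_summary_json(path, summary) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
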