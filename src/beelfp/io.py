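"""Delimited-text formats for traces, trials and spectra.

All tables are comma-separated UTF-8 with a header row; missing values are
empty fields.  A trace is stored as two columns (time_s, amplitude_uv) with
a JSON sidecar (same path with ``.json`` appended) carrying the sampling
rate, state label and provenance — the sidecar is authoritative for the
rate, so a truncated time column cannot silently change it.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TrialRecord
from .spectral import AveragePSD, PSDEstimate
from .traces import SignalTrace

TRIAL_COLUMNS = [
    "stim_freq_hz", "stim_voltage_v", "duty_ratio", "polarity",
    "stim_duration_s", "initiated", "flap_freq_hz", "flap_dur_ms",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_signal(trace: SignalTrace, path: str | Path) -> None:
    """Write a trace as (time_s, amplitude_uv) CSV plus a JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame({
        "time_s": trace.times,
        "amplitude_uv": trace.samples,
    })
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "sampling_rate": trace.sampling_rate,
        "state": trace.state_label,
        "n_samples": int(trace.samples.size),
        "meta": _jsonable(trace.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_signal(path: str | Path) -> SignalTrace:
    """Read a trace written by :func:`write_signal`.

    The sampling rate comes from the sidecar; a missing sidecar is an
    error (the CSV alone does not define the rate authoritatively).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar}; cannot determine the sampling rate"
        )
    info = json.loads(sidecar.read_text())
    frame = pd.read_csv(path, float_precision="round_trip")
    if "amplitude_uv" not in frame.columns:
        raise ValueError(f"{path}: expected an 'amplitude_uv' column")
    return SignalTrace(
        samples=frame["amplitude_uv"].to_numpy(dtype=float),
        sampling_rate=float(info["sampling_rate"]),
        state_label=info.get("state", "unknown"),
        meta=info.get("meta", {}),
    )


def write_trials(trials: list[TrialRecord], path: str | Path) -> None:
    """Write a trial table as CSV with the canonical header."""
    rows = []
    for t in trials:
        rows.append({
            "stim_freq_hz": t.stim_freq,
            "stim_voltage_v": t.stim_voltage,
            "duty_ratio": t.duty_ratio,
            "polarity": t.polarity,
            "stim_duration_s": t.stim_duration,
            "initiated": t.initiated,
            "flap_freq_hz": t.flap_freq,
            "flap_dur_ms": t.flap_dur,
        })
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trial table, validating each row.

    A header-only file yields an empty list.  Malformed rows (missing
    stimulus fields, or responses on a non-initiated trial) raise with the
    1-based data line number.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    trials: list[TrialRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            initiated = _parse_bool(row.initiated)
            flap_freq = None if pd.isna(row.flap_freq_hz) else float(row.flap_freq_hz)
            flap_dur = None if pd.isna(row.flap_dur_ms) else float(row.flap_dur_ms)
            trials.append(TrialRecord(
                stim_freq=float(row.stim_freq_hz),
                stim_voltage=float(row.stim_voltage_v),
                duty_ratio=float(row.duty_ratio),
                polarity=str(row.polarity),
                stim_duration=float(row.stim_duration_s),
                initiated=initiated,
                flap_freq=flap_freq,
                flap_dur=flap_dur,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: invalid trial at data line {i}: {exc}") from exc
    return trials


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def write_psd(psd: PSDEstimate | AveragePSD, path: str | Path) -> None:
    """Write a PSD (frequency_hz, power[, error]) table."""
    if isinstance(psd, AveragePSD):
        frame = pd.DataFrame({
            "frequency_hz": psd.frequencies,
            "power": psd.mean_power,
            "error": psd.error,
        })
    else:
        frame = pd.DataFrame({
            "frequency_hz": psd.frequencies,
            "power": psd.power,
        })
    frame.to_csv(path, index=False, float_format="%.17g")


def read_psd(path: str | Path) -> PSDEstimate:
    """Read a single-record PSD table written by :func:`write_psd`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    freqs = frame["frequency_hz"].to_numpy(dtype=float)
    return PSDEstimate(
        frequencies=freqs,
        power=frame["power"].to_numpy(dtype=float),
        nfft=2 * (freqs.size - 1),
    )


def read_average_psd(path: str | Path) -> AveragePSD:
    """Read an averaged PSD table (frequency_hz, power, error)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    err = (frame["error"].to_numpy(dtype=float)
           if "error" in frame.columns else None)
    freqs = frame["frequency_hz"].to_numpy(dtype=float)
    power = frame["power"].to_numpy(dtype=float)
    if err is None:
        err = np.zeros_like(power)
    return AveragePSD(frequencies=freqs, mean_power=power, error=err,
                      n_samples=0, error_kind="SD")


def write_imfs(imfs: list[np.ndarray], residue: np.ndarray,
               path: str | Path) -> None:
    """Write an EMD decomposition as columns imf_1..imf_k, residue."""
    data = {f"imf_{i + 1}": c for i, c in enumerate(imfs)}
    data["residue"] = residue
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
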