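"""File formats and round-trip readers/writers.

Tabular artifacts are TSV with ``# key=value`` header lines (full float
precision, so write->read is lossless); image stacks are TIFF; configs
are YAML; fit reports and threshold maps are JSON.  Every writer embeds
enough metadata (bin width, axis origin, seed, normalization mode) to
regenerate or reinterpret the artifact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fcs_core import CorrelationCurve, FcsFitResult, PhotonTrace
from .profiles import SpatialProfile
from .gradient_mapping import GradientMeasurement, ThresholdMap

__all__ = [
    "read_header", "write_tsv", "read_tsv",
    "write_trace", "read_trace", "write_curve", "read_curve",
    "write_profile", "read_profile",
    "write_measurements", "read_measurements",
    "write_fit_report", "write_threshold_map",
    "write_stack", "read_stack", "load_config", "save_config",
]


class HeaderParseError(ValueError):
    pass


def _format_value(v):
    if isinstance(v, (np.floating, float)):
        return repr(float(v))
    return str(v)


def write_tsv(path, df: pd.DataFrame, header: dict | None = None):
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={_format_value(v)}\n")
        # pandas' default float repr is shortest-roundtrip: lossless
        df.to_csv(fh, sep="\t", index=False)


def read_header(path) -> dict:
    header = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                raise HeaderParseError(
                    f"{path}: malformed header at line {lineno}: {line!r}")
            k, v = body.split("=", 1)
            header[k.strip()] = v.strip()
    return header


def read_tsv(path, required=()):
    header = read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df, header


# -- traces ------------------------------------------------------------------

def write_trace(path, trace: PhotonTrace):
    t = np.arange(len(trace.counts)) * trace.bin_width
    write_tsv(path, pd.DataFrame({"time_s": t, "counts": trace.counts}),
              {"bin_width": trace.bin_width, "label": trace.label})


def read_trace(path) -> PhotonTrace:
    df, header = read_tsv(path, required=("time_s", "counts"))
    return PhotonTrace(float(header["bin_width"]),
                       df["counts"].to_numpy(dtype=np.int64),
                       header.get("label", ""))


# -- correlation curves ------------------------------------------------------

def write_curve(path, curve: CorrelationCurve, extra: dict | None = None):
    cols = {"lag_s": curve.lags, "g": curve.g}
    if curve.weights is not None:
        cols["weight"] = curve.weights
    head = {"n_repetitions": curve.n_repetitions}
    head.update(extra or {})
    write_tsv(path, pd.DataFrame(cols), head)


def read_curve(path) -> CorrelationCurve:
    df, header = read_tsv(path, required=("lag_s", "g"))
    w = df["weight"].to_numpy() if "weight" in df.columns else None
    return CorrelationCurve(df["lag_s"].to_numpy(), df["g"].to_numpy(), w,
                            int(header.get("n_repetitions", 1)))


# -- spatial profiles --------------------------------------------------------

def write_profile(path, profile: SpatialProfile):
    n_samples, n_bins = profile.per_sample.shape
    cols = {"bin_left_um": profile.bin_edges[:-1],
            "bin_right_um": profile.bin_edges[1:],
            "mean": profile.mean, "sd": profile.sd}
    for i in range(n_samples):
        cols[f"sample_{i}"] = profile.per_sample[i]
    write_tsv(path, pd.DataFrame(cols), {
        "bin_width_um": profile.bin_edges[1] - profile.bin_edges[0],
        "normalization": profile.normalization,
        "n_samples": n_samples,
        "n_excluded": profile.n_excluded,
        "axis_origin": "embryonic margin",
    })


def read_profile(path) -> SpatialProfile:
    df, header = read_tsv(path, required=("bin_left_um", "bin_right_um"))
    edges = np.append(df["bin_left_um"].to_numpy(),
                      df["bin_right_um"].iloc[-1])
    n_samples = int(header.get("n_samples", 0))
    if n_samples:
        mat = np.stack([df[f"sample_{i}"].to_numpy()
                        for i in range(n_samples)])
    else:
        mat = df["mean"].to_numpy()[None, :]
    return SpatialProfile(edges, mat, header.get("normalization", "none"),
                          int(header.get("n_excluded", 0)))


# -- positioned measurements -------------------------------------------------

def write_measurements(path, measurements):
    df = pd.DataFrame([{
        "sample_id": m.sample_id, "condition": m.condition,
        "distance_um": m.distance_um, "count_rate_khz": m.count_rate_khz,
    } for m in measurements])
    write_tsv(path, df, {"format": "fcs-gradient-measurements"})


def read_measurements(path):
    df, _ = read_tsv(path, required=("sample_id", "distance_um",
                                     "count_rate_khz"))
    return [GradientMeasurement(r.distance_um, r.count_rate_khz,
                                str(r.sample_id),
                                getattr(r, "condition", "control"))
            for r in df.itertuples(index=False)]


# -- JSON reports ------------------------------------------------------------

def write_fit_report(path, fit: FcsFitResult, extra: dict | None = None):
    d = fit.to_dict()
    d.update(extra or {})
    Path(path).write_text(json.dumps(d, indent=2, default=float) + "\n")


def write_threshold_map(path, tmap: ThresholdMap, extra: dict | None = None):
    d = {"features": tmap.to_dict()}
    d.update(extra or {})
    Path(path).write_text(json.dumps(d, indent=2, default=float) + "\n")


# -- images and configs ------------------------------------------------------

def write_stack(path, stack: np.ndarray, voxel_um):
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     metadata={"voxel_um": list(voxel_um)})


def read_stack(path):
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata
        voxel = None
        if meta and "voxel_um" in meta[0]:
            voxel = tuple(meta[0]["voxel_um"])
    return stack, voxel


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, config: dict):
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
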