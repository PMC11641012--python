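"""File formats: CSV traces, an HDF5 per-cycle container, tabular inputs
for EMSA/CFU data, and plain-text key = value configuration files.

The canonical trace interchange is a CSV with header columns ``time_s``,
``force_pN``, ``extension_nm`` (units asserted from the column names) and
an optional ``# sampling_rate_hz = ...`` comment line.  The container
format mirrors common tweezers exports: one HDF5 group per cycle with
``time``/``force``/``extension`` datasets and ``sampling_rate_hz`` /
``trap_stiffness_pN_per_nm`` attributes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from synaptrap.pipeline import ForceExtensionTrace
from synaptrap.stats import BindingSeries

__all__ = [
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "read_container",
    "write_container",
    "read_binding_series",
    "read_cfu_table",
    "parse_keyvalue",
    "write_keyvalue",
]

TRACE_COLUMNS = ("time_s", "force_pN", "extension_nm")


class TraceFormatError(ValueError):
    """Raised when a trace file violates the format contract."""


def write_trace(trace: ForceExtensionTrace, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz = {trace.sampling_rate!r}\n")
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        np.savetxt(fh, np.column_stack([trace.time, trace.force,
                                        trace.extension]),
                   delimiter=",", fmt="%.10g")


def read_trace(path) -> ForceExtensionTrace:
    """Read a CSV trace; header columns carry the unit contract."""
    path = Path(path)
    rate = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "sampling_rate_hz" in first:
        rate = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(
                f"{path.name}: missing required column {col!r} "
                f"(found {list(df.columns)})")
    time = df["time_s"].to_numpy(float)
    if rate is None:
        if len(time) < 2:
            raise TraceFormatError(f"{path.name}: cannot infer sampling rate")
        rate = 1.0 / float(np.median(np.diff(time)))
    return ForceExtensionTrace(time, df["force_pN"].to_numpy(float),
                               df["extension_nm"].to_numpy(float), rate)


def write_container(path, traces, trap_stiffness: float | None = None,
                    attrs: dict | None = None) -> None:
    """Write per-cycle traces into an HDF5 container."""
    with h5py.File(path, "w") as h5:
        if attrs:
            for key, val in attrs.items():
                h5.attrs[key] = val
        for i, trace in enumerate(traces):
            grp = h5.create_group(f"cycle_{i:04d}")
            grp.create_dataset("time", data=trace.time)
            grp.create_dataset("force", data=trace.force)
            grp.create_dataset("extension", data=trace.extension)
            grp.attrs["sampling_rate_hz"] = trace.sampling_rate
            if trap_stiffness is not None:
                grp.attrs["trap_stiffness_pN_per_nm"] = trap_stiffness


def read_container(path) -> tuple[list[ForceExtensionTrace], dict]:
    """Read an HDF5 container; returns per-cycle traces and file attributes."""
    traces: list[ForceExtensionTrace] = []
    with h5py.File(path, "r") as h5:
        attrs = dict(h5.attrs)
        for name in sorted(h5.keys()):
            grp = h5[name]
            try:
                rate = float(grp.attrs["sampling_rate_hz"])
                traces.append(ForceExtensionTrace(
                    grp["time"][:], grp["force"][:], grp["extension"][:],
                    rate))
            except KeyError as exc:
                raise TraceFormatError(
                    f"group {name!r}: missing {exc.args[0]!r}") from exc
    return traces, attrs


def read_binding_series(path) -> BindingSeries:
    """Read an EMSA CSV: concentration_nM, I_bound, I_unbound."""
    df = pd.read_csv(path, comment="#")
    for col in ("concentration_nM", "I_bound", "I_unbound"):
        if col not in df.columns:
            raise TraceFormatError(f"missing required column {col!r}")
    return BindingSeries(df["concentration_nM"].to_numpy(float),
                         df["I_bound"].to_numpy(float),
                         df["I_unbound"].to_numpy(float))


def read_cfu_table(path) -> pd.DataFrame:
    """Read a CFU CSV: replicate, recombinant_cfu, recipient_cfu."""
    df = pd.read_csv(path, comment="#")
    for col in ("recombinant_cfu", "recipient_cfu"):
        if col not in df.columns:
            raise TraceFormatError(f"missing required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# key = value configuration files
# ---------------------------------------------------------------------------

def _coerce(raw: str):
    raw = raw.strip()
    if "," in raw:
        return tuple(_coerce(part) for part in raw.split(","))
    lowered = raw.lower()
    if lowered in ("true", "false"):
        return lowered == "true"
    try:
        as_int = int(raw)
        return as_int
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def parse_keyvalue(path) -> dict:
    """Parse a plain-text ``key = value`` configuration file.

    Values are coerced to int/float/bool where possible; comma-separated
    values become tuples; ``#`` starts a comment.
    """
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, raw = line.split("=", 1)
        out[key.strip()] = _coerce(raw)
    return out


def write_keyvalue(mapping: dict, path) -> None:
    lines = []
    for key, val in mapping.items():
        if isinstance(val, (tuple, list)):
            val = ",".join(str(v) for v in val)
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")
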