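"""Single-column CSV reading/writing for observation vectors.

Dialect: comma-separated, '.' decimal, one value per line, optional single
header line, '#'-prefixed comment lines ignored (fixtures carry their metadata
that way).  Missing or non-numeric values are rejected with the offending line
number; negative values are rejected because the delta-gamma law is supported
on [0, inf).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["InputError", "read_observations", "write_observations"]


class InputError(ValueError):
    """A problem with an input file (bad path, format, or values)."""


def read_observations(path) -> np.ndarray:
    """Read one non-negative observation vector from a single-column CSV."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as err:
        raise InputError(f"cannot read {path}: {err}") from err

    values = []
    first_data_line = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        field = line.split(",")[0].strip()
        if field == "":
            raise InputError(f"{path}:{lineno}: missing value")
        try:
            v = float(field)
        except ValueError:
            if first_data_line:  # a single header line is allowed
                first_data_line = False
                continue
            raise InputError(
                f"{path}:{lineno}: not a number: {field!r}"
            ) from None
        first_data_line = False
        if np.isnan(v):
            raise InputError(f"{path}:{lineno}: missing value (NaN)")
        if v < 0:
            raise InputError(f"{path}:{lineno}: negative observation {v}")
        values.append(v)

    if not values:
        raise InputError(f"{path}: no observations found")
    return np.asarray(values, dtype=float)


def write_observations(path, observations, metadata: dict | None = None) -> None:
    """Write an observation vector as single-column CSV with '#' metadata lines."""
    path = Path(path)
    lines = []
    if metadata:
        lines.append("# " + json.dumps(metadata, sort_keys=True))
    lines.append("value")
    lines.extend(repr(float(v)) for v in np.asarray(observations, dtype=float))
    path.write_text("\n".join(lines) + "\n")
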