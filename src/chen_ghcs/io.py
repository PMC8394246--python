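"""Data I/O: lifetime files and the packaged electrical-appliance dataset.

Lifetimes are read from a one-column CSV (header ``time``) or plain
whitespace-separated text; values must be positive decimals in consistent
units.  The packaged fixture is the classical set of 60 electrical-appliance
failure times (in thousands of cycles), long used as a bathtub-hazard
benchmark.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["read_lifetimes", "write_lifetimes", "load_electrical"]


def read_lifetimes(path) -> np.ndarray:
    """Read, validate and sort lifetimes from CSV or whitespace text.

    Raises ``ValueError`` naming the offending line for non-numeric or
    non-positive entries, and for empty files.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    values: list[float] = []
    start = 0
    if lines and lines[0].strip().lower() == "time":
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        for tok in line.replace(",", " ").split():
            try:
                val = float(tok)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric entry {tok!r}") from None
            if val <= 0:
                raise ValueError(f"{path}:{lineno}: lifetimes must be positive, got {val}")
            values.append(val)
    if not values:
        raise ValueError(f"{path}: no lifetimes found")
    return np.sort(np.asarray(values, dtype=float))


def write_lifetimes(path, times) -> None:
    """Write lifetimes as a one-column CSV at full decimal precision."""
    times = np.asarray(times, dtype=float)
    with open(path, "w") as fh:
        fh.write("time\n")
        for val in times:
            fh.write(f"{val:.17g}\n")


def load_electrical() -> np.ndarray:
    """The 60 packaged electrical-appliance failure times, sorted."""
    with resources.as_file(resources.files("chen_ghcs").joinpath("data/electrical.csv")) as p:
        return read_lifetimes(p)
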