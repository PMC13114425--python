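"""Packaged example datasets and plain-text sample I/O.

Two classical bounded-reliability datasets ship with the package: 30 tensile
strengths of polyester fibers (fraction of nominal maximum stress at failure)
and 21 normalised computing times of the P3 algorithm.  Both live strictly
inside (0, 1) and are stored digit-for-digit as published.
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .distribution import UnitSample, sample as draw_sample

__all__ = ["NamedDataset", "load_builtin", "read_sample", "write_sample", "generate_fixture"]

_TENSILE_STRENGTH = (
    0.023, 0.032, 0.054, 0.069, 0.081, 0.094, 0.105, 0.127, 0.148, 0.169,
    0.188, 0.216, 0.255, 0.277, 0.311, 0.361, 0.376, 0.395, 0.432, 0.463,
    0.481, 0.519, 0.529, 0.567, 0.642, 0.674, 0.752, 0.823, 0.887, 0.926,
)
_P3_TIMES = (
    0.853, 0.759, 0.874, 0.800, 0.716, 0.557, 0.503, 0.399, 0.334, 0.207,
    0.118, 0.097, 0.078, 0.067, 0.056, 0.044, 0.036, 0.026, 0.019, 0.014,
    0.010,
)

_BUILTINS = {
    "tensile-strength": (_TENSILE_STRENGTH, "tensile strength of 30 polyester fibers"),
    "p3-times": (_P3_TIMES, "computing times of 21 P3 algorithm runs"),
}


@dataclass(frozen=True)
class NamedDataset:
    name: str
    values: UnitSample
    source: str

    @property
    def checksum(self) -> str:
        return hashlib.sha256(",".join(f"{v:.3f}" for v in self.values.values).encode()).hexdigest()[:12]


def load_builtin(name: str) -> NamedDataset:
    """Load a packaged dataset by name ('tensile-strength' or 'p3-times')."""
    try:
        values, source = _BUILTINS[name]
    except KeyError:
        raise KeyError(f"unknown dataset {name!r}; available: {sorted(_BUILTINS)}") from None
    return NamedDataset(name=name, values=UnitSample(values), source=source)


_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_sample(path: Union[str, Path], fmt: str = "auto") -> UnitSample:
    """Read a univariate unit sample from plain text or single-column CSV.

    One value per line or whitespace/comma separated; a non-numeric first
    line is treated as a header; '#' lines are comments.  Out-of-range or
    non-numeric values are reported with their row number.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    values = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = re.split(r"[\s,;]+", stripped)
        for tok in tokens:
            if not tok:
                continue
            if not _NUM_RE.match(tok):
                if lineno == 1:  # header row
                    break
                raise ValueError(f"{path}:{lineno}: non-numeric value {tok!r}")
            values.append((lineno, float(tok)))
    if not values:
        raise ValueError(f"{path}: no numeric data found")
    bad = [(ln, v) for ln, v in values if not 0.0 < v < 1.0]
    if bad:
        locs = ", ".join(f"row {ln}: {v}" for ln, v in bad[:5])
        raise ValueError(f"{path}: values outside the open unit interval ({locs})")
    return UnitSample([v for _, v in values])


def write_sample(samp: UnitSample, path: Union[str, Path], header: str = "") -> None:
    """Write one observation per line, full double precision, optional comment."""
    path = Path(path)
    buf = io.StringIO()
    if header:
        for line in header.splitlines():
            buf.write(f"# {line}\n")
    for v in samp.values:
        buf.write(format(float(v), ".17g") + "\n")
    path.write_text(buf.getvalue())


def generate_fixture(zeta: float, n: int, seed: int, path: Union[str, Path]) -> UnitSample:
    """Write a reproducible synthetic sample with a provenance comment header
    recording (zeta, n, seed); identical inputs give identical file bytes."""
    samp = UnitSample(draw_sample(n, zeta, seed))
    write_sample(samp, path, header=f"uasrd synthetic fixture\nzeta={zeta} n={n} seed={seed}")
    return samp


def parse_fixture_provenance(path: Union[str, Path]) -> dict:
    """Recover (zeta, n, seed) from a fixture's comment header."""
    for line in Path(path).read_text().splitlines():
        m = re.match(r"#\s*zeta=([\d.eE+-]+)\s+n=(\d+)\s+seed=(\d+)", line)
        if m:
            return dict(zeta=float(m.group(1)), n=int(m.group(2)), seed=int(m.group(3)))
    raise ValueError(f"{path}: no provenance header found")
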