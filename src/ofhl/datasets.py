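"""Packaged example datasets and sample I/O.

Two published lifetime datasets ship with the package:

* ``covid_mexico`` — 108 daily COVID-19 mortality rates for Mexico,
  4 March to 20 July 2020.
* ``chemo_survival`` — survival times in years of patients treated with
  chemotherapy alone.  The source describes 46 patients but prints 45
  values; the 45 printed values are shipped (they reproduce the published
  fits to the printed precision).

Samples are read from one-column plain-text/CSV files (optional header);
values must be strictly positive.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .estimation import Sample

__all__ = ["FIXTURES", "load_fixture", "read_sample", "write_sample", "write_report"]

COVID_MEXICO = (
    8.826, 6.105, 10.383, 7.267, 13.220, 6.015, 10.855, 6.122, 10.685, 10.035,
    5.242, 7.630, 14.604, 7.903, 6.327, 9.391, 14.962, 4.730, 3.215, 16.498,
    11.665, 9.284, 12.878, 6.656, 3.440, 5.854, 8.813, 10.043, 7.260, 5.985,
    4.424, 4.344, 5.143, 9.935, 7.840, 9.550, 6.968, 6.370, 3.537, 3.286,
    10.158, 8.108, 6.697, 7.151, 6.560, 2.988, 3.336, 6.814, 8.325, 7.854,
    8.551, 3.228, 3.499, 3.751, 7.486, 6.625, 6.140, 4.909, 4.661, 1.867,
    2.838, 5.392, 12.042, 8.696, 6.412, 3.395, 1.815, 3.327, 5.406, 6.182,
    4.949, 4.089, 3.359, 2.070, 3.298, 5.317, 5.442, 4.557, 4.292, 2.500,
    6.535, 4.648, 4.697, 5.459, 4.120, 3.922, 3.219, 1.402, 2.438, 3.257,
    3.632, 3.233, 3.027, 2.352, 1.205, 2.077, 3.778, 3.218, 2.926, 2.601,
    2.065, 1.041, 1.800, 3.029, 2.058, 2.326, 2.506, 1.923,
)

CHEMO_SURVIVAL = (
    0.047, 0.115, 0.121, 0.132, 0.164, 0.197, 0.203, 0.260, 0.282, 0.296,
    0.334, 0.395, 0.458, 0.466, 0.501, 0.507, 0.529, 0.534, 0.540, 0.641,
    0.644, 0.696, 0.841, 0.863, 1.099, 1.219, 1.271, 1.326, 1.447, 1.485,
    1.553, 1.581, 1.589, 2.178, 2.343, 2.416, 2.444, 2.825, 2.830, 3.578,
    3.658, 3.743, 3.978, 4.003, 4.033,
)

FIXTURES = {
    "covid_mexico": (COVID_MEXICO, "COVID-19 mortality rate, Mexico, 108 days (Mar 4 - Jul 20, 2020)"),
    "chemo_survival": (CHEMO_SURVIVAL, "Survival times (years) of chemotherapy-only patients"),
}
_ALIASES = {"covid": "covid_mexico", "survival": "chemo_survival"}


def load_fixture(name: str) -> Sample:
    """Return a packaged dataset as a sorted :class:`Sample`."""
    key = _ALIASES.get(name, name)
    if key not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)} "
            f"(aliases: {sorted(_ALIASES)})"
        )
    values, citation = FIXTURES[key]
    return Sample(np.asarray(values), label=f"{key}: {citation}")


def read_sample(path, label: str | None = None) -> Sample:
    """Parse a one-column numeric text/CSV file into a Sample.

    An optional single header line is tolerated; any other non-numeric row
    or a non-positive value raises with the offending 1-based line numbers.
    """
    path = Path(path)
    values: list[float] = []
    bad_lines: list[int] = []
    nonpos_lines: list[int] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            cells = [c.strip() for c in row if c.strip()]
            if not cells:
                continue
            try:
                v = float(cells[0])
            except ValueError:
                if lineno == 1:  # header
                    continue
                bad_lines.append(lineno)
                continue
            if not np.isfinite(v) or v <= 0.0:
                nonpos_lines.append(lineno)
            else:
                values.append(v)
    problems = []
    if bad_lines:
        problems.append(f"non-numeric rows at lines {bad_lines}")
    if nonpos_lines:
        problems.append(f"non-positive values at lines {nonpos_lines}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    if not values:
        raise ValueError(f"{path}: no numeric values found")
    return Sample(np.asarray(values), label=label or path.name)


def write_sample(sample: Sample, path) -> None:
    np.savetxt(path, sample.values, fmt="%.12g")


def write_report(report, path, fmt: str = "json") -> None:
    """Serialize a report (anything with to_dict, a dict, or a DataFrame)."""
    path = Path(path)
    obj = report.to_dict() if hasattr(report, "to_dict") else report
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=float)
            fh.write("\n")
    elif fmt == "csv":
        import pandas as pd

        pd.DataFrame([obj] if isinstance(obj, dict) else obj).to_csv(path, index=False)
    else:
        raise ValueError("fmt must be 'json' or 'csv'")
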