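"""PHQ-9 <-> HDRS score conversion via a monotone crosswalk table.

Primary-care records measure depression severity with the self-report PHQ-9
(0-27) while most antidepressant trials use the clinician-rated HDRS (0-52).
Predictions made on one scale are mapped onto the other through an
equipercentile-style crosswalk: a lookup table covering the whole 0-27 PHQ-9
grid with HDRS values that never decrease. Forward conversion interpolates
linearly between grid points; reverse conversion inverts the monotone map,
returning the midpoint of the pre-image interval over flat segments.

The package ships ``data/crosswalk_synthetic.csv``, a *synthetic* stand-in
with the right shape; users with access to a published linking table supply
it as a CSV with columns ``phq9,hdrs`` on the same format.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError, MonotonicityError

PHQ9_MAX = 27
HDRS_MAX = 52

__all__ = ["CrosswalkTable", "load_crosswalk", "default_crosswalk", "convert_score"]


@dataclass(frozen=True)
class CrosswalkTable:
    """Validated monotone lookup from the full PHQ-9 grid to HDRS values."""

    phq9: np.ndarray  # 0..27, complete
    hdrs: np.ndarray  # non-decreasing

    def __post_init__(self):
        phq9 = np.asarray(self.phq9, dtype=float)
        hdrs = np.asarray(self.hdrs, dtype=float)
        object.__setattr__(self, "phq9", phq9)
        object.__setattr__(self, "hdrs", hdrs)
        if phq9.shape != hdrs.shape:
            raise FormatError("phq9 and hdrs columns differ in length")
        expected = np.arange(PHQ9_MAX + 1, dtype=float)
        if phq9.shape != expected.shape or not np.array_equal(np.sort(phq9), expected):
            missing = sorted(set(expected) - set(phq9))
            raise FormatError(f"crosswalk must cover the full 0-{PHQ9_MAX} PHQ-9 grid; "
                              f"missing rows: {missing}")
        order = np.argsort(phq9)
        object.__setattr__(self, "phq9", phq9[order])
        object.__setattr__(self, "hdrs", hdrs[order])
        if np.any(np.diff(self.hdrs) < 0):
            bad = int(np.argmax(np.diff(self.hdrs) < 0)) + 1
            raise MonotonicityError(f"hdrs decreases at phq9={int(self.phq9[bad])}")
        if self.hdrs.min() < 0:
            raise FormatError("hdrs values must be >= 0")

    @property
    def strictly_increasing(self) -> bool:
        return bool(np.all(np.diff(self.hdrs) > 0))


def load_crosswalk(path: str | Path) -> CrosswalkTable:
    """Load and validate a crosswalk CSV with header ``phq9,hdrs``."""
    df = pd.read_csv(path)
    cols = {c.strip().lower() for c in df.columns}
    if not {"phq9", "hdrs"} <= cols:
        raise FormatError(f"crosswalk CSV needs columns phq9,hdrs; got {sorted(df.columns)}")
    df.columns = [c.strip().lower() for c in df.columns]
    return CrosswalkTable(phq9=df["phq9"].to_numpy(), hdrs=df["hdrs"].to_numpy())


def default_crosswalk() -> CrosswalkTable:
    """The bundled synthetic crosswalk (shape-correct stand-in, not published values)."""
    with resources.as_file(resources.files("petrushka.data") / "crosswalk_synthetic.csv") as p:
        return load_crosswalk(p)


def convert_score(x: float, table: CrosswalkTable, direction: str = "phq9_to_hdrs") -> float:
    """Convert a score between scales through the crosswalk.

    Forward (``phq9_to_hdrs``): table lookup with linear interpolation for
    non-integer inputs. Reverse (``hdrs_to_phq9``): monotone inverse; an HDRS
    value attained on a flat run of the table maps to the midpoint of that
    run's PHQ-9 interval. HDRS inputs outside the table's range (but within
    0-52) are clamped to the table's endpoints before inversion.
    """
    if direction in ("phq9_to_hdrs", "phq9->hdrs"):
        if not 0 <= x <= PHQ9_MAX:
            raise InvalidArgumentError(f"PHQ-9 score {x} outside [0, {PHQ9_MAX}]")
        return float(np.interp(x, table.phq9, table.hdrs))
    if direction in ("hdrs_to_phq9", "hdrs->phq9"):
        hi = max(HDRS_MAX, float(table.hdrs[-1]))
        if not 0 <= x <= hi:
            raise InvalidArgumentError(f"HDRS score {x} outside [0, {hi}]")
        h = float(np.clip(x, table.hdrs[0], table.hdrs[-1]))
        H = table.hdrs
        exact = np.flatnonzero(H == h)
        if exact.size:
            return float(table.phq9[exact].mean())  # midpoint of the pre-image run
        j = int(np.searchsorted(H, h)) - 1  # H[j] < h < H[j+1], strictly increasing here
        frac = (h - H[j]) / (H[j + 1] - H[j])
        return float(table.phq9[j] + frac * (table.phq9[j + 1] - table.phq9[j]))
    raise InvalidArgumentError(f"unknown direction {direction!r}")
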