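"""Bundled reference dataset from the invasive validation cohort.

Published per-vessel distal pressures for eight human coronary segments:
the wire-measured value, the four simulation variants (rigid/deformable
wall x steady/pulsatile flow), the velocity-profile parametric study,
and the two mesh-sensitivity ladders (lumen under rigid walls; wall
under the deformable assumption).  These numbers are inputs to the
statistics module; nothing in this package recomputes patient data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_APPROACH_COLS = {
    "fsi_transient": "fsi_transient_mmhg",
    "rigid_transient": "rigid_transient_mmhg",
    "fsi_steady": "fsi_steady_mmhg",
    "rigid_steady": "rigid_steady_mmhg",
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("coroflow.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def cohort_pressures() -> pd.DataFrame:
    """Measured and simulated distal pressures (mmHg) per vessel."""
    return _load("cohort_pressures.csv")


def velocity_ratio_pressures() -> pd.DataFrame:
    """Steady distal pressures under the three velocity-ratio scenarios."""
    return _load("velocity_ratio_pressures.csv")


def mesh_sensitivity_lumen() -> pd.DataFrame:
    """Lumen mesh ladder (rigid wall): element count, pressure, WSS."""
    return _load("mesh_sensitivity_lumen.csv")


def mesh_sensitivity_wall() -> pd.DataFrame:
    """Wall mesh ladder (deformable wall): element count, pressure, WSS."""
    return _load("mesh_sensitivity_wall.csv")


def approach_column(approach: str) -> str:
    try:
        return _APPROACH_COLS[approach]
    except KeyError:
        raise KeyError(
            f"unknown approach {approach!r}; expected one of "
            f"{sorted(_APPROACH_COLS)}"
        ) from None
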