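"""Agreement statistics and study protocols.

The comparison machinery used to validate simulated distal pressure
against wire measurements: ordinary-least-squares regression,
Bland-Altman limits of agreement, relative differences, the
mesh-sensitivity selection rule (< 5% wall-shear-stress change vs the
finest mesh), the four-approach experiment (rigid/deformable wall x
steady/pulsatile flow) and the velocity-ratio parametric study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .flow import (BloodProperties, FlowBC, solve_steady, solve_transient,
                   outlet_pressure_waveform)
from .waveforms import Waveform, cycle_mean


@dataclass
class PairedSeries:
    """Measured (reference) vs computed (test) pressures on one grid."""

    reference: np.ndarray  # mmHg
    test: np.ndarray       # mmHg
    times: Optional[np.ndarray] = None

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if self.reference.shape != self.test.shape:
            raise ValueError("reference and test must have equal length")
        if len(self.reference) < 3:
            raise ValueError("paired series needs at least 3 points")
        if not (np.all(np.isfinite(self.reference))
                and np.all(np.isfinite(self.test))):
            raise ValueError("paired series must be finite")

    @classmethod
    def from_waveforms(cls, reference: Waveform,
                       computed: Waveform) -> "PairedSeries":
        """Align a computed series onto the reference grid by resampling."""
        comp = np.interp(reference.times - reference.times[0],
                         computed.times - computed.times[0], computed.values)
        return cls(reference.values, comp, reference.times)


@dataclass
class RegressionResult:
    slope: float
    intercept: float  # mmHg
    r_squared: float


@dataclass
class BlandAltmanResult:
    mean_difference: float  # mmHg, test - reference
    sd_difference: float
    loa_low: float
    loa_high: float
    fraction_within: float


@dataclass
class SensitivityRow:
    label: str
    elements: int
    outlet_pressure_mmhg: float
    wss_pa: float


@dataclass
class SensitivityTable:
    """Mesh ladder ordered coarse -> fine; differences are vs the finest."""

    rows: List[SensitivityRow]
    selected: Optional[int] = None

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("sensitivity table needs at least 2 rows")

    def wss_differences(self) -> np.ndarray:
        ref = self.rows[-1].wss_pa
        return np.array([relative_difference(r.wss_pa, ref)
                         for r in self.rows[:-1]])

    def pressure_differences(self) -> np.ndarray:
        ref = self.rows[-1].outlet_pressure_mmhg
        return np.array(
            [relative_difference(r.outlet_pressure_mmhg, ref)
             for r in self.rows[:-1]])


@dataclass
class StudyReport:
    """Four computed pressures per vessel plus the measured reference."""

    vessels: List[str]
    pressures: Dict[str, Dict[str, float]]  # vessel -> approach -> mmHg
    measured: Dict[str, float]
    errors: Dict[str, Dict[str, str]] = field(default_factory=dict)

    APPROACHES = ("fsi_transient", "rigid_transient", "fsi_steady",
                  "rigid_steady")


def linear_regression(ps: PairedSeries) -> RegressionResult:
    """Ordinary least squares of computed on measured values."""
    if np.ptp(ps.reference) == 0:
        raise ValueError("reference series has zero variance")
    res = sps.linregress(ps.reference, ps.test)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2))


def bland_altman(ps: PairedSeries) -> BlandAltmanResult:
    """Mean bias and 1.96*SD limits of agreement (SD with n-1)."""
    d = ps.test - ps.reference
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanResult(mean, sd, lo, hi, within)


def relative_difference(x: float, reference: float) -> float:
    """|x - reference| / |reference| in percent."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return abs(x - reference) / abs(reference) * 100.0


def sensitivity_select(table: SensitivityTable,
                       wss_threshold: float = 5.0) -> Optional[int]:
    """Coarsest row whose WSS differs < threshold % from the finest.

    Returns the row index, or None with the table marked as needing
    further refinement when no row qualifies (the finest row itself is
    never selected).
    """
    diffs = table.wss_differences()
    for i, d in enumerate(diffs):
        if d < wss_threshold:
            table.selected = i
            return i
    table.selected = None
    return None


def cohort_mean_relative_difference(report: StudyReport,
                                    pair: Tuple[str, str]) -> float:
    """Mean per-vessel |a - b|/|b| * 100 over the cohort.

    ``pair`` names two approaches; the second is the denominator.
    """
    a, b = pair
    diffs = []
    for v in report.vessels:
        row = report.pressures.get(v, {})
        if a not in row or b not in row:
            raise ValueError(f"vessel {v} lacks approach {a!r} or {b!r}")
        diffs.append(relative_difference(row[a], row[b]))
    return float(np.mean(diffs))


def report_from_dataframe(df) -> StudyReport:
    """Build a StudyReport from a cohort table of published pressures."""
    from .reference_data import approach_column

    vessels = list(df["vessel"])
    pressures = {
        v: {ap: float(df.loc[df.vessel == v, approach_column(ap)].iloc[0])
            for ap in StudyReport.APPROACHES}
        for v in vessels
    }
    measured = {v: float(df.loc[df.vessel == v, "measured_mmhg"].iloc[0])
                for v in vessels}
    return StudyReport(vessels=vessels, pressures=pressures,
                       measured=measured)


def velocity_ratio_study(mesh, blood: BloodProperties, bc: FlowBC,
                         ratios: Sequence[float] = (1.0, 0.76, 0.5),
                         tol: float = 1e-6) -> Dict[float, float]:
    """Steady rigid outlet pressure for each velocity-ratio scenario."""
    out = {}
    for r in ratios:
        bcr = FlowBC(bc.inlet_pressure, bc.outlet_velocity_measured, r,
                     bc.outlet_profile, bc.profile_normalize)
        out[r] = solve_steady(mesh, blood, bcr, tol=tol).outlet_pressure_mmhg
    return out


def run_four_way_study(vessels, waveforms, config) -> StudyReport:
    """Run the four simulation approaches on each synthetic vessel.

    ``vessels``: dict name -> (FluidMesh, WallMesh); ``waveforms``:
    (pressure Waveform, velocity Waveform); ``config``: a StudyConfig
    carrying blood/wall/coupling settings.  Solver failures are recorded
    per cell and the study continues.
    """
    from .fsi import couple_steady, couple_transient

    pw, vw = waveforms
    blood = config.blood
    params = config.wall_params
    coupling = config.coupling
    bc_t = FlowBC(pw, vw, config.velocity_ratio)
    bc_s = FlowBC(cycle_mean(pw), cycle_mean(vw), config.velocity_ratio)

    report = StudyReport(vessels=list(vessels), pressures={}, measured={})
    for name, (fmesh, wmesh) in vessels.items():
        row, errs = {}, {}

        def record(ap, fn):
            try:
                row[ap] = fn()
            except Exception as exc:  # per-cell failure, study continues
                errs[ap] = f"{type(exc).__name__}: {exc}"

        record("rigid_steady",
               lambda: solve_steady(fmesh, blood, bc_s).outlet_pressure_mmhg)
        record("rigid_transient", lambda: cycle_mean(outlet_pressure_waveform(
            solve_transient(fmesh, blood, bc_t, dt=coupling.dt))))
        record("fsi_steady", lambda: couple_steady(
            fmesh, wmesh, blood, params, bc_s,
            coupling)[0].outlet_pressure_mmhg)

        def _fsi_transient(fm=fmesh, wm=wmesh):
            res = couple_transient(fm, wm, blood, params, bc_t, coupling)
            t = np.array([s.time for s, _ in res])
            p = np.array([s.outlet_pressure_mmhg for s, _ in res])
            return cycle_mean(Waveform(t, p, pw.period, "pressure"))

        record("fsi_transient", _fsi_transient)
        report.pressures[name] = row
        if errs:
            report.errors[name] = errs
    return report


def regression_plot(ps: PairedSeries, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reg = linear_regression(ps)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(ps.reference, ps.test, "o", ms=4)
    xx = np.array([ps.reference.min(), ps.reference.max()])
    ax.plot(xx, reg.slope * xx + reg.intercept, "-",
            label=f"y={reg.slope:.3f}x+{reg.intercept:.2f}, "
                  f"$r^2$={reg.r_squared:.4f}")
    ax.set_xlabel("measured pressure (mmHg)")
    ax.set_ylabel("computed pressure (mmHg)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(ps: PairedSeries, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(ps)
    mean_vals = 0.5 * (ps.reference + ps.test)
    d = ps.test - ps.reference
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(mean_vals, d, "o", ms=4)
    for y, ls in ((ba.mean_difference, "-"), (ba.loa_low, "--"),
                  (ba.loa_high, "--")):
        ax.axhline(y, color="k", ls=ls, lw=1)
    ax.set_xlabel("mean of measured and computed (mmHg)")
    ax.set_ylabel("computed - measured (mmHg)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
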