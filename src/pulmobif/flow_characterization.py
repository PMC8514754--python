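"""Flow-rate extraction, cohort waveform averaging, flow splits, and the
dimensionless characterization (Reynolds, Womersley, Dean) of pulsatile
pulmonary-artery flow.

Units: flow rate ml/s, areas mm^2, velocities m/s; the dimensionless-number
helpers take SI lengths (metres).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import VoxelFlowSeries


@dataclass
class FlowWaveform:
    """One-cycle flow-rate waveform Q(t) in ml/s."""

    t: np.ndarray  # s, in [0, period_T)
    Q: np.ndarray  # ml/s
    period_T: float

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.Q = np.asarray(self.Q, float)
        if len(self.t) < 16:
            raise ValueError("need at least 16 samples per cycle")
        if self.t.min() < 0 or self.t.max() > self.period_T:
            raise ValueError("t must lie within [0, period_T]")

    def resample(self, t_query):
        """Periodic linear interpolation at arbitrary times."""
        tq = np.mod(np.atleast_1d(t_query), self.period_T)
        tp = np.concatenate([self.t, [self.t[0] + self.period_T]])
        Qp = np.concatenate([self.Q, [self.Q[0]]])
        return np.interp(tq, tp, Qp)

    def net_volume_ml(self) -> float:
        """Forward minus backward volume over one cycle (trapezoid,
        periodic closure)."""
        return _net_volume(self.t, self.Q, self.period_T)

    def forward_backward_volumes_ml(self):
        tp = np.concatenate([self.t, [self.t[0] + self.period_T]])
        Qp = np.concatenate([self.Q, [self.Q[0]]])
        pos = np.trapezoid(np.clip(Qp, 0.0, None), tp)
        neg = -np.trapezoid(np.clip(Qp, None, 0.0), tp)
        return float(pos), float(neg)


def _net_volume(t, Q, T):
    tp = np.concatenate([t, [t[0] + T]])
    Qp = np.concatenate([Q, [Q[0]]])
    pos = np.trapezoid(np.clip(Qp, 0.0, None), tp)
    neg = np.trapezoid(np.clip(Qp, None, 0.0), tp)
    return float(pos + neg)


@dataclass
class CohortWaveform:
    t_norm: np.ndarray
    Q_mean: np.ndarray  # ml/s
    Q_sd: np.ndarray
    Qm_star: float  # cycle mean of the averaged waveform, ml/s

    @property
    def Q_mean_normalized(self):
        return self.Q_mean / self.Qm_star


@dataclass
class FlowSplit:
    pct_RPA: float
    pct_LPA: float

    def __post_init__(self):
        if abs(self.pct_RPA + self.pct_LPA - 100.0) > 1e-9:
            raise ValueError("flow split percentages must sum to 100")


@dataclass
class FluidProperties:
    """Blood modelled as Newtonian: rho = 1060 kg/m^3, mu = 0.004 Pa s."""

    rho: float = 1060.0
    mu: float = 0.004

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass
class DimensionlessNumbers:
    Re_mean: dict  # branch -> value
    Re_max: dict
    Wo: float
    De_max: dict  # daughter -> value


@dataclass
class TurbulenceInflowSpec:
    I: float
    k: float  # m^2/s^2
    L_scale: float  # m
    omega: float  # 1/s


# --------------------------------------------------------------------------
# voxel series -> waveform


def flow_rate_from_voxels(series: VoxelFlowSeries):
    """Q(frame) = sum(v * pixel_area) over the mask (ml/s) and
    A(frame) = count * pixel_area (mm^2)."""
    if series.n_frames == 0:
        raise ValueError("empty voxel series")
    mask = series.in_mask
    # v [m/s] * area [mm^2] integrates to ml/s
    Q = series.v_mps[:, mask].sum(axis=1) * series.pixel_area_mm2
    A = np.full(series.n_frames, float(mask.sum()) * series.pixel_area_mm2)
    period = float(series.t_s[-1] + (series.t_s[1] - series.t_s[0])) if series.n_frames > 1 else float(series.t_s[-1])
    wf = FlowWaveform(t=series.t_s, Q=Q, period_T=period)
    return wf, A


def mean_velocity_series(Q_mls, A_mm2):
    """U(t) = Q/A in m/s; A = 0 is only allowed where Q = 0."""
    Q = np.asarray(Q_mls, float)
    A = np.asarray(A_mm2, float)
    U = np.zeros_like(Q)
    zero = A == 0.0
    if np.any(zero & (Q != 0.0)):
        raise ValueError("zero area with nonzero flow rate")
    U[~zero] = Q[~zero] / A[~zero]  # ml/s per mm^2 == m/s
    return U


# --------------------------------------------------------------------------
# cohort waveform averaging


def cohort_average_waveform(waveforms, n_grid: int = 100) -> CohortWaveform:
    """Average waveforms on a normalized-time grid after dividing each
    patient's time axis by its own cycle period."""
    if not waveforms:
        raise ValueError("no waveforms to average")
    grid = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    vals = np.stack([wf.resample(grid * wf.period_T) for wf in waveforms])
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if len(waveforms) > 1 else np.zeros_like(mean)
    qm_star = float(mean.mean())
    return CohortWaveform(t_norm=grid, Q_mean=mean, Q_sd=sd, Qm_star=qm_star)


# --------------------------------------------------------------------------
# flow splits


def flow_split_from_net_volumes(wf_rpa: FlowWaveform, wf_lpa: FlowWaveform) -> FlowSplit:
    """Split from net (forward minus backward) volumes over the cycle."""
    net_r = wf_rpa.net_volume_ml()
    net_l = wf_lpa.net_volume_ml()
    if net_r <= 0 or net_l <= 0:
        raise ValueError("net branch volume non-positive: fully regurgitant "
                         "branch unsupported")
    pct_r = 100.0 * net_r / (net_r + net_l)
    return FlowSplit(pct_RPA=pct_r, pct_LPA=100.0 - pct_r)


def estimate_missing_flow_split(
    avg_split: FlowSplit,
    R_RPA_target: float,
    R_LPA_target: float,
    R_RPA_av: float,
    R_LPA_av: float,
) -> FlowSplit:
    """Scale a cohort-average split to a patient without branch flow data,
    using the squared ratio of branch radii:

    Q_R/Q_L = (Q_R_av/Q_L_av) * ((R_R/R_L) * (R_L_av/R_R_av))^2
    """
    for r in (R_RPA_target, R_LPA_target, R_RPA_av, R_LPA_av):
        if r <= 0:
            raise ValueError("radii must be positive")
    ratio = (avg_split.pct_RPA / avg_split.pct_LPA) * (
        (R_RPA_target / R_LPA_target) * (R_LPA_av / R_RPA_av)
    ) ** 2
    pct_r = 100.0 * ratio / (1.0 + ratio)
    return FlowSplit(pct_RPA=pct_r, pct_LPA=100.0 - pct_r)


# --------------------------------------------------------------------------
# dimensionless numbers


def reynolds(U_mps: float, D_m: float, props: FluidProperties) -> float:
    return U_mps * D_m / props.nu


def womersley(D_m: float, T_s: float, props: FluidProperties) -> float:
    """Wo = (D/2) sqrt(2 pi / (nu T)) at the inlet."""
    if D_m <= 0 or T_s <= 0:
        raise ValueError("D and T must be positive")
    return 0.5 * D_m * np.sqrt(2.0 * np.pi / (props.nu * T_s))


def dean_max(
    Re_max_mpa: float, split_fraction: float, D_daughter_m: float, kappa_per_m: float
) -> float:
    """De_max = Re_max(MPA) * split * sqrt(D / (2R)), R = 1/kappa.

    kappa = 0 (straight branch) gives De = 0.
    """
    if kappa_per_m == 0.0:
        return 0.0
    return Re_max_mpa * split_fraction * np.sqrt(0.5 * D_daughter_m * kappa_per_m)


def dean_along_centerline(Re_max_mpa, split_fraction, D_daughter_m, kappa_per_m_arr):
    kap = np.asarray(kappa_per_m_arr, float)
    return Re_max_mpa * split_fraction * np.sqrt(0.5 * D_daughter_m * np.clip(kap, 0, None))


def dimensionless_numbers(
    U_mean: dict,
    U_max: dict,
    D: dict,
    T_s: float,
    props: FluidProperties,
    split: FlowSplit,
    kappa_max: dict,
) -> DimensionlessNumbers:
    """Per-branch Re (mean and max), inlet Wo, and daughter De_max.

    ``U_mean``/``U_max`` m/s and ``D`` m keyed by branch; ``kappa_max`` in
    1/mm keyed by daughter (converted to 1/m internally).
    """
    re_mean = {b: reynolds(U_mean[b], D[b], props) for b in U_mean}
    re_max = {b: reynolds(U_max[b], D[b], props) for b in U_max}
    wo = womersley(D["MPA"], T_s, props)
    frac = {"RPA": split.pct_RPA / 100.0, "LPA": split.pct_LPA / 100.0}
    de = {
        b: dean_max(re_max["MPA"], frac[b], D[b], kappa_max[b] * 1e3)
        for b in ("RPA", "LPA")
        if b in kappa_max
    }
    return DimensionlessNumbers(Re_mean=re_mean, Re_max=re_max, Wo=float(wo), De_max=de)


def turbulence_inflow_spec(
    Re: float, U_mean: float, D_m: float, literal_omega: bool = False
) -> TurbulenceInflowSpec:
    """k-omega SST inflow values: I = 0.16 Re^(-1/8), k = 1.5 (U I)^2,
    L = 0.07 D, omega = sqrt(k) / (0.09^(1/4) L).

    ``literal_omega=True`` selects the dimensionally inconsistent reading
    omega = k / (0.09 L) occasionally seen in print.
    """
    if Re <= 0:
        raise ValueError("Re must be positive")
    I = 0.16 * Re ** (-1.0 / 8.0)
    k = 1.5 * (U_mean * I) ** 2
    L = 0.07 * D_m
    if literal_omega:
        omega = k / (0.09 * L)
    else:
        omega = np.sqrt(k) / (0.09**0.25 * L)
    return TurbulenceInflowSpec(I=float(I), k=float(k), L_scale=float(L),
                                omega=float(omega))


# --------------------------------------------------------------------------
# cohort tables


def aggregate_cohort_table(
    df: pd.DataFrame, decimals: dict | None = None, label_col: str = "model"
) -> pd.DataFrame:
    """Append an arithmetic "Mean value" row over the numeric columns.

    ``decimals`` maps column -> display precision; raw means are kept and a
    rounded copy is returned alongside when requested.
    """
    if len(df) == 0:
        raise ValueError("empty cohort table")
    out = df.copy()
    num = out.select_dtypes(include=[np.number]).columns.drop(
        label_col, errors="ignore"
    )
    mean_row = {c: out[c].mean() for c in num}
    mean_row[label_col] = "Mean value"
    out = pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)
    if decimals:
        disp = out.copy()
        for c, d in decimals.items():
            if c in disp.columns:
                disp[c] = disp[c].astype(float).round(d)
        return disp
    return out
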