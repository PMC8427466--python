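"""Digital rodent-liver phantom and forward simulators.

Everything the analysis chain consumes can be generated here with known
ground truth: inversion-recovery image series for FAIR ASL (global and
slice-selective inversion modes), phase-contrast cine studies of the two
caval stations, respiratory traces and segmented k-space acquisition
timetables, and whole cohorts of animals with sham/BDL parameter
distributions.  All simulators are pure functions of their inputs and an
explicit seed, so every downstream stage has a strict recovery oracle.

The signal model is the three-parameter inversion-recovery curve

    Mz(TI) = M0 * (1 - alpha * exp(-TI / T1*)),

with the apparent relaxation time tied to the tissue T1 through the
Look-Locker small-angle relation T1 = T1* * (alpha - 1).  The simulator
generates data with T1* = T1 / (alpha - 1) so the standard fitting and
correction chain is exactly invertible.  For the slice-selective inversion
the effective T1 is shortened by perfusion: inflowing non-inverted blood
accelerates the apparent recovery, and the shortened T1 is obtained by
inverting the perfusion equation (see :func:`t1_slice_selective_from_perfusion`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .units import perfusion_unit_scale

INVERSION_MODES = ("global", "slice_selective")
LOBES = ("right", "middle", "left")
VESSELS = ("infra_IVC", "supra_IVC")


# --------------------------------------------------------------------------
# Protocol metadata
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FairProtocol:
    """Look-Locker FAIR readout settings (9.4 T rodent protocol defaults)."""

    ti_spacing_ms: float = 110.0
    n_readouts: int = 50
    tr_rf_ms: float = 2.3
    flip_deg: float = 8.0
    tr_inversion_ms: float = 13_000.0
    matrix: int = 128
    fov_mm: float = 60.0
    slice_mm: float = 2.0
    lines_per_segment: int = 4

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def tis_ms(self) -> np.ndarray:
        """Inversion times: evenly spaced, first readout one spacing after inversion."""
        return self.ti_spacing_ms * np.arange(1, self.n_readouts + 1, dtype=float)


@dataclass(frozen=True)
class PCProtocol:
    """Cardiac-gated cine phase-contrast protocol (caval stations)."""

    matrix: int = 192
    fov_mm: float = 40.0
    slice_mm: float = 2.0
    n_phases: int = 13
    venc_infra_cm_s: float = 33.0
    venc_supra_cm_s: float = 66.0

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix

    def venc_for(self, vessel_label: str) -> float:
        if vessel_label == "infra_IVC":
            return self.venc_infra_cm_s
        if vessel_label == "supra_IVC":
            return self.venc_supra_cm_s
        raise ValueError(f"unknown vessel label {vessel_label!r}")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselSpec:
    """A caval station modelled as a circular vessel with parabolic flow."""

    label: str
    centre_mm: tuple[float, float]  # (row, col) offset from image centre
    radius_mm: float
    peak_velocity_cm_s: float  # spatial peak of the time-averaged profile


@dataclass
class PhantomSpec:
    """Ground-truth digital animal for a single axial liver slice.

    Tissue parameters are piecewise constant over named regions: a body
    ellipse, a liver ellipse split into right/middle/left lobes, and
    zero-signal background.  Perfusion is defined per lobe (ml/min/100 g);
    vessel geometry lives on the separate phase-contrast slices.
    """

    grid_shape: tuple[int, int]
    pixel_size_mm: float
    liver_mask: np.ndarray
    lobe_masks: dict[str, np.ndarray]
    body_mask: np.ndarray
    vessels: dict[str, VesselSpec]
    tissue_t1_ms: dict[str, float]          # {"liver": ..., "body": ...}
    tissue_m0: dict[str, float]
    perfusion_true: dict[str, float]        # per lobe, ml/min/100 g
    alpha_true: dict[str, float]            # per inversion mode
    t1_blood_ms: float = 1900.0
    lambda_ml_g: float = 0.95
    liver_weight_g: float = 14.0
    heart_rate_bpm: float = 350.0
    pulsatility_fraction: float = 0.2
    resp_period_s: float = 1.0
    quiescent_fraction: float = 0.6
    cohort: str = "sham"
    seed: int = 0
    animal_id: str = "animal0"
    lost_post_lps: bool = False
    perfusion_shift: float = 0.0            # additive post-LPS change
    t1_shift_ms: float = 0.0
    tlbf_true: float | None = None          # ml/min/100 g; None -> mean perfusion
    pc_pixel_mm: float = 40.0 / 192.0       # phase-contrast slice resolution

    def validate(self) -> None:
        if any(p < 0 for p in self.perfusion_true.values()):
            raise ValueError("perfusion must be non-negative")
        for mode, a in self.alpha_true.items():
            if not (1.0 < a <= 2.0):
                raise ValueError(f"alpha_true[{mode}] must lie in (1, 2]")
        if self.liver_weight_g <= 0:
            raise ValueError("liver weight must be positive")
        if not (0.0 < self.quiescent_fraction <= 1.0):
            raise ValueError("quiescent_fraction must lie in (0, 1]")
        if self.heart_rate_bpm <= 0 or self.resp_period_s <= 0:
            raise ValueError("heart rate and respiratory period must be positive")
        for v in self.vessels.values():
            if v.radius_mm <= self.pc_pixel_mm:
                raise ValueError("vessel radius must exceed the PC pixel size")
        if any(t <= 0 for t in self.tissue_t1_ms.values()):
            raise ValueError("tissue T1 values must be positive")

    # -- derived ground truth -------------------------------------------------

    @property
    def mean_perfusion_true(self) -> float:
        return float(np.mean([self.perfusion_true[l] for l in LOBES]))

    def tlbf_ground_truth(self) -> float:
        """True total liver blood flow in ml/min/100 g."""
        if self.tlbf_true is not None:
            return float(self.tlbf_true)
        return self.mean_perfusion_true

    def true_m0_map(self) -> np.ndarray:
        m0 = np.zeros(self.grid_shape)
        m0[self.body_mask] = self.tissue_m0["body"]
        m0[self.liver_mask] = self.tissue_m0["liver"]
        return m0

    def true_t1_map(self, mode: str) -> np.ndarray:
        """Effective T1 map for an inversion mode (ms; NaN outside tissue)."""
        if mode not in INVERSION_MODES:
            raise ValueError(f"unknown inversion mode {mode!r}")
        t1 = np.full(self.grid_shape, np.nan)
        t1[self.body_mask] = self.tissue_t1_ms["body"]
        t1[self.liver_mask] = self.tissue_t1_ms["liver"]
        if mode == "slice_selective":
            for lobe in LOBES:
                t1[self.lobe_masks[lobe]] = t1_slice_selective_from_perfusion(
                    self.tissue_t1_ms["liver"], self.perfusion_true[lobe],
                    self.lambda_ml_g, self.t1_blood_ms)
        return t1

    def apply_lps(self) -> "PhantomSpec":
        """Return the post-LPS state: additive perfusion/T1 shifts, same anatomy."""
        new_perf = {l: max(0.0, p + self.perfusion_shift)
                    for l, p in self.perfusion_true.items()}
        new_t1 = dict(self.tissue_t1_ms)
        new_t1["liver"] = self.tissue_t1_ms["liver"] + self.t1_shift_ms
        return replace(self, perfusion_true=new_perf, tissue_t1_ms=new_t1)


@dataclass
class InversionRecoverySeries:
    """A 50-TI Look-Locker inversion-recovery image stack."""

    images: np.ndarray          # (n_TI, rows, cols), signed signal by default
    tis_ms: np.ndarray
    inversion_mode: str
    protocol: FairProtocol

    def validate(self) -> None:
        tis = np.asarray(self.tis_ms, float)
        if not np.all(np.diff(tis) > 0):
            raise ValueError("inversion times must be strictly increasing")
        if len(tis) != self.protocol.n_readouts:
            raise ValueError("number of TIs must equal the protocol readout count")
        if self.images.shape[0] != len(tis):
            raise ValueError("image count must equal the number of TIs")
        if self.inversion_mode not in INVERSION_MODES:
            raise ValueError(f"unknown inversion mode {self.inversion_mode!r}")


@dataclass(frozen=True)
class RespiratoryTrace:
    """Respiratory cycle boundaries and quiescent (end-expiration) windows, seconds."""

    cycle_boundaries_s: np.ndarray
    quiescent_windows_s: np.ndarray  # (n, 2) closed intervals [start, end]

    def validate(self) -> None:
        w = np.asarray(self.quiescent_windows_s, float)
        if w.ndim != 2 or w.shape[1] != 2:
            raise ValueError("windows must be an (n, 2) array")
        if np.any(w[:, 1] < w[:, 0]):
            raise ValueError("window end before start")
        if np.any(w[1:, 0] < w[:-1, 1]):
            raise ValueError("windows must be non-overlapping and increasing")

    def is_quiescent(self, times_s: np.ndarray, margin_s: float = 0.0) -> np.ndarray:
        """True where [t - margin, t + margin] intersects a quiescent window.

        Windows are closed intervals, so a time exactly on a boundary (at
        margin 0) counts as quiescent.
        """
        if margin_s < 0:
            raise ValueError("margin must be non-negative")
        t = np.atleast_1d(np.asarray(times_s, float))
        w = np.asarray(self.quiescent_windows_s, float)
        lo = t[:, None] - margin_s
        hi = t[:, None] + margin_s
        hit = (w[None, :, 0] <= hi) & (w[None, :, 1] >= lo)
        return hit.any(axis=1)


@dataclass
class AcquisitionTimetable:
    """One record per acquired k-space line of the segmented FAIR readout."""

    lines: pd.DataFrame  # columns: ti_index, kspace_row, segment_index, time_s

    def __len__(self) -> int:
        return len(self.lines)

    def validate(self, protocol: FairProtocol) -> None:
        df = self.lines
        counts = df.groupby(["segment_index", "ti_index"]).size()
        if not (counts == protocol.lines_per_segment).all():
            raise ValueError("each segment must acquire the protocol's lines per readout")
        for _, seg in df.groupby("segment_index"):
            if not seg["time_s"].is_monotonic_increasing:
                raise ValueError("times must increase within a segment")


@dataclass
class VelocityCine:
    """Cine phase-contrast acquisition of one vessel (phase images, radians)."""

    frames: np.ndarray            # (n_phases, rows, cols) wrapped phase in (-pi, pi]
    venc_cm_s: float
    frame_times_ms: np.ndarray
    voxel_area_mm2: float
    vessel_label: str
    heart_rate_bpm: float
    vessel_centre_px: tuple[float, float]
    vessel_radius_px: float

    @property
    def n_phases(self) -> int:
        return self.frames.shape[0]

    def validate(self) -> None:
        if not (12 <= self.n_phases <= 15):
            raise ValueError("cine must have 12-15 cardiac phases")
        if self.venc_cm_s <= 0:
            raise ValueError("venc must be positive")
        if np.any(self.frames <= -np.pi) or np.any(self.frames > np.pi):
            raise ValueError("phase values must lie in (-pi, pi]")


# --------------------------------------------------------------------------
# Perfusion <-> slice-selective T1
# --------------------------------------------------------------------------

def t1_slice_selective_from_perfusion(t1_global_ms, perfusion_ml_min_100g,
                                      lambda_ml_g: float = 0.95,
                                      t1_blood_ms: float = 1900.0):
    """Slice-selective (perfusion-shortened) T1 for a given tissue perfusion.

    Inverts P = scale * (T1_global / T1_ss - 1), where scale converts the
    ratio term to ml/min/100 g (3000 at the default lambda and blood T1), so
    that the perfusion-map computation applied to (T1_global, result)
    returns P exactly.
    """
    t1g = np.asarray(t1_global_ms, float)
    p = np.asarray(perfusion_ml_min_100g, float)
    if np.any(t1g <= 0):
        raise ValueError("T1_global must be positive")
    if np.any(p < 0):
        raise ValueError("perfusion must be non-negative")
    scale = perfusion_unit_scale(lambda_ml_g, t1_blood_ms)
    out = t1g / (1.0 + p / scale)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Phantom construction
# --------------------------------------------------------------------------

def _ellipse_mask(shape, centre_frac, semi_frac) -> np.ndarray:
    rows, cols = shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    cr, cc = centre_frac[0] * rows, centre_frac[1] * cols
    ar, ac = semi_frac[0] * rows, semi_frac[1] * cols
    return ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0


def parabolic_flow_ml_min(radius_mm: float, vmax_cm_s: float) -> float:
    """Closed-form flow of a parabolic profile: integral v dA = pi R^2 vmax / 2."""
    return 0.5 * math.pi * radius_mm ** 2 * vmax_cm_s * 0.6  # mm^2*cm/s -> ml/min


def make_phantom(matrix: int = 128, fov_mm: float = 60.0, *,
                 liver_t1_ms: float = 1256.0, body_t1_ms: float = 900.0,
                 liver_m0: float = 1000.0, body_m0: float = 800.0,
                 perfusion_ml_min_100g: float = 316.0,
                 perfusion_by_lobe: dict[str, float] | None = None,
                 alpha: float = 1.95, t1_blood_ms: float = 1900.0,
                 lambda_ml_g: float = 0.95, liver_weight_g: float = 14.0,
                 tlbf_ml_min_100g: float | None = None,
                 infra_peak_velocity_cm_s: float = 12.0,
                 vessel_radius_mm: float = 1.75,
                 heart_rate_bpm: float = 350.0, pulsatility_fraction: float = 0.2,
                 resp_period_s: float = 1.0, quiescent_fraction: float = 0.6,
                 cohort: str = "sham", seed: int = 0,
                 animal_id: str = "animal0",
                 perfusion_shift: float = 0.0, t1_shift_ms: float = 0.0,
                 lost_post_lps: bool = False) -> PhantomSpec:
    """Build a single-slice rodent liver phantom with consistent vessel flows.

    The supra-hepatic IVC peak velocity is chosen so that the difference
    between supra- and infra-hepatic caval flows equals the requested TLBF
    (default: the mean tissue perfusion), making caval subtraction an exact
    oracle up to discretisation.

    Vessel diameter defaults to 3.5 mm, within the 3-4 mm caval range.
    """
    shape = (matrix, matrix)
    body = _ellipse_mask(shape, (0.50, 0.50), (0.42, 0.45))
    liver = _ellipse_mask(shape, (0.46, 0.50), (0.28, 0.40)) & body
    # split the liver into left/middle/right thirds by column
    cc = 0.50 * matrix
    ac = 0.40 * matrix
    cols = np.arange(matrix)[None, :] * np.ones((matrix, 1))
    lobes = {
        "right": liver & (cols < cc - ac / 3),
        "middle": liver & (cols >= cc - ac / 3) & (cols <= cc + ac / 3),
        "left": liver & (cols > cc + ac / 3),
    }

    perf = dict(perfusion_by_lobe) if perfusion_by_lobe is not None else \
        {l: float(perfusion_ml_min_100g) for l in LOBES}

    tlbf = float(np.mean([perf[l] for l in LOBES])) if tlbf_ml_min_100g is None \
        else float(tlbf_ml_min_100g)
    hepatic_inflow_ml_min = tlbf * liver_weight_g / 100.0
    # invert the parabolic closed form for the supra-caval velocity increment
    dvmax = hepatic_inflow_ml_min / (0.5 * math.pi * vessel_radius_mm ** 2 * 0.6)
    vessels = {
        "infra_IVC": VesselSpec("infra_IVC", (0.0, 0.0), vessel_radius_mm,
                                infra_peak_velocity_cm_s),
        "supra_IVC": VesselSpec("supra_IVC", (0.0, 0.0), vessel_radius_mm,
                                infra_peak_velocity_cm_s + dvmax),
    }

    spec = PhantomSpec(
        grid_shape=shape, pixel_size_mm=fov_mm / matrix,
        liver_mask=liver, lobe_masks=lobes, body_mask=body, vessels=vessels,
        tissue_t1_ms={"liver": liver_t1_ms, "body": body_t1_ms},
        tissue_m0={"liver": liver_m0, "body": body_m0},
        perfusion_true=perf,
        alpha_true={m: alpha for m in INVERSION_MODES},
        t1_blood_ms=t1_blood_ms, lambda_ml_g=lambda_ml_g,
        liver_weight_g=liver_weight_g, heart_rate_bpm=heart_rate_bpm,
        pulsatility_fraction=pulsatility_fraction, resp_period_s=resp_period_s,
        quiescent_fraction=quiescent_fraction, cohort=cohort, seed=seed,
        animal_id=animal_id, perfusion_shift=perfusion_shift,
        t1_shift_ms=t1_shift_ms, lost_post_lps=lost_post_lps,
        tlbf_true=tlbf,
    )
    spec.validate()
    return spec


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Per-group parameter distributions for the simulated study.

    Group means are the literature baseline values; SDs are the reported
    standard errors scaled by sqrt(n) (n = 10 sham, 9 BDL at baseline and
    7 BDL for the post-LPS change, reflecting attrition).  The true TLBF of
    each animal is its perfusion plus an offset distributed like the
    observed between-method disagreement, so that agreement statistics have
    realistic structure.
    """

    n_sham: int = 10
    n_bdl: int = 9
    sham_perfusion_mean: float = 316.0
    sham_perfusion_sd: float = 75.9      # 24 * sqrt(10)
    bdl_perfusion_mean: float = 199.0
    bdl_perfusion_sd: float = 96.0       # 32 * 3
    sham_t1_mean: float = 1256.0
    sham_t1_sd: float = 56.9             # 18 * sqrt(10)
    bdl_t1_mean: float = 1533.0
    bdl_t1_sd: float = 150.0             # 50 * 3
    sham_weight_mean: float = 14.0
    sham_weight_sd: float = 3.16         # 1 * sqrt(10)
    bdl_weight_mean: float = 30.0
    bdl_weight_sd: float = 6.0           # 2 * 3
    sham_lps_perfusion_shift_mean: float = 78.0
    sham_lps_perfusion_shift_sd: float = 104.4   # 33 * sqrt(10)
    bdl_lps_perfusion_shift_mean: float = -49.0
    bdl_lps_perfusion_shift_sd: float = 105.8    # 40 * sqrt(7)
    sham_lps_t1_shift_mean: float = 0.2
    sham_lps_t1_shift_sd: float = 28.5           # 9 * sqrt(10)
    bdl_lps_t1_shift_mean: float = 14.0
    bdl_lps_t1_shift_sd: float = 29.1            # 11 * sqrt(7)
    tlbf_offset_mean: float = 51.0
    tlbf_offset_sd: float = 131.6        # limits-of-agreement 258 / 1.96
    attrition_probability_bdl: float = 2.0 / 9.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sham < 1 or self.n_bdl < 1:
            raise ValueError("group sizes must be at least 1")
        for name, val in self.__dict__.items():
            if name.endswith("_sd") and val < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.attrition_probability_bdl <= 1.0):
            raise ValueError("attrition probability must lie in [0, 1]")


def build_cohort(config: CohortConfig, seed: int | None = None,
                 matrix: int = 128, fov_mm: float = 60.0) -> list[PhantomSpec]:
    """Draw a cohort of phantoms from the configured group distributions.

    BDL animals are flagged ``lost_post_lps`` with the configured attrition
    probability; generation is reproducible under a fixed seed.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    phantoms: list[PhantomSpec] = []
    groups = [("sham", config.n_sham), ("bdl", config.n_bdl)]
    for group, n in groups:
        pm = getattr(config, f"{group}_perfusion_mean")
        ps = getattr(config, f"{group}_perfusion_sd")
        tm = getattr(config, f"{group}_t1_mean")
        ts = getattr(config, f"{group}_t1_sd")
        wm = getattr(config, f"{group}_weight_mean")
        ws = getattr(config, f"{group}_weight_sd")
        dm = getattr(config, f"{group}_lps_perfusion_shift_mean")
        ds = getattr(config, f"{group}_lps_perfusion_shift_sd")
        tm2 = getattr(config, f"{group}_lps_t1_shift_mean")
        ts2 = getattr(config, f"{group}_lps_t1_shift_sd")
        for i in range(n):
            perf = max(0.0, float(rng.normal(pm, ps)))
            t1 = max(200.0, float(rng.normal(tm, ts)))
            weight = max(1.0, float(rng.normal(wm, ws)))
            shift = float(rng.normal(dm, ds))
            t1_shift = float(rng.normal(tm2, ts2))
            tlbf = max(5.0, perf + float(rng.normal(config.tlbf_offset_mean,
                                                    config.tlbf_offset_sd)))
            hr = float(rng.uniform(300.0, 400.0))
            lost = bool(group == "bdl" and
                        rng.random() < config.attrition_probability_bdl)
            phantoms.append(make_phantom(
                matrix=matrix, fov_mm=fov_mm,
                liver_t1_ms=t1, perfusion_ml_min_100g=perf,
                liver_weight_g=weight, tlbf_ml_min_100g=tlbf,
                heart_rate_bpm=hr, cohort=group,
                seed=int(rng.integers(0, 2**31 - 1)),
                animal_id=f"{group}{i + 1:02d}",
                perfusion_shift=shift, t1_shift_ms=t1_shift,
                lost_post_lps=lost))
    return phantoms


# --------------------------------------------------------------------------
# FAIR series simulation
# --------------------------------------------------------------------------

def ir_signal(m0, alpha, t1_star_ms, tis_ms):
    """Inversion-recovery signal Mz(TI) = M0 (1 - alpha exp(-TI / T1*))."""
    return m0 * (1.0 - alpha * np.exp(-np.asarray(tis_ms, float) / t1_star_ms))


def simulate_fair_series(phantom: PhantomSpec, mode: str,
                         noise_sd: float = 0.0, seed: int = 0,
                         protocol: FairProtocol | None = None,
                         noise_model: str = "gaussian") -> InversionRecoverySeries:
    """Forward-simulate a Look-Locker FAIR inversion-recovery series.

    For the global inversion the effective T1 is the tissue T1; for the
    slice-selective inversion it is the perfusion-shortened T1.  Noise is
    zero-mean Gaussian added to the signed signal by default; the
    ``rician`` model instead returns the magnitude of the complex signal
    with Gaussian noise on both channels.
    """
    if mode not in INVERSION_MODES:
        raise ValueError(f"unknown inversion mode {mode!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    phantom.validate()
    if protocol is None:
        protocol = FairProtocol(matrix=phantom.grid_shape[0],
                                fov_mm=phantom.pixel_size_mm * phantom.grid_shape[0])
    tis = protocol.tis_ms
    m0 = phantom.true_m0_map()
    t1 = phantom.true_t1_map(mode)
    alpha = phantom.alpha_true[mode]

    images = np.zeros((len(tis),) + phantom.grid_shape)
    tissue = np.isfinite(t1) & (m0 > 0)
    t1_star = t1[tissue] / (alpha - 1.0)
    images[:, tissue] = m0[tissue][None, :] * (
        1.0 - alpha * np.exp(-tis[:, None] / t1_star[None, :]))

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            images = images + rng.normal(0.0, noise_sd, images.shape)
        elif noise_model == "rician":
            images = np.abs(images + rng.normal(0.0, noise_sd, images.shape)
                            + 1j * rng.normal(0.0, noise_sd, images.shape))
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")

    series = InversionRecoverySeries(images=images, tis_ms=tis,
                                     inversion_mode=mode, protocol=protocol)
    series.validate()
    return series


# --------------------------------------------------------------------------
# Phase-contrast cine simulation
# --------------------------------------------------------------------------

def wrap_phase(phase):
    """Wrap phase into (-pi, pi]."""
    w = np.mod(np.asarray(phase, float) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def simulate_pc_cine(phantom: PhantomSpec, vessel_label: str,
                     venc_cm_s: float | None = None, noise_sd_rad: float = 0.0,
                     seed: int = 0, protocol: PCProtocol | None = None,
                     n_phases: int | None = None) -> VelocityCine:
    """Simulate a cardiac cine phase-contrast study of one caval station.

    The through-plane velocity is parabolic across the vessel disc,
    v(r, t) = vmax(t) (1 - (r/R)^2), with vmax modulated by a single-harmonic
    zero-mean pulsatility waveform over the cardiac cycle.  Velocity is
    encoded as phase = pi * v / venc, wrapped into (-pi, pi]; static tissue
    contributes zero phase plus noise.
    """
    if vessel_label not in phantom.vessels:
        raise ValueError(f"vessel {vessel_label!r} not in phantom")
    if protocol is None:
        protocol = PCProtocol()
    if venc_cm_s is None:
        venc_cm_s = protocol.venc_for(vessel_label)
    if venc_cm_s <= 0:
        raise ValueError("venc must be positive")
    n = protocol.n_phases if n_phases is None else int(n_phases)
    if not (12 <= n <= 15):
        raise ValueError("cine must have 12-15 cardiac phases")

    vessel = phantom.vessels[vessel_label]
    m = protocol.matrix
    px = protocol.pixel_mm
    r = (np.arange(m) - (m - 1) / 2.0) * px
    rr = r[:, None] - vessel.centre_mm[0]
    cc = r[None, :] - vessel.centre_mm[1]
    dist = np.hypot(rr, cc)
    disc = dist <= vessel.radius_mm
    profile = np.where(disc, 1.0 - (dist / vessel.radius_mm) ** 2, 0.0)

    period_ms = 60_000.0 / phantom.heart_rate_bpm
    times = period_ms * np.arange(n) / n
    waveform = np.sin(2.0 * np.pi * times / period_ms)   # zero-mean over the cycle
    vmax_t = vessel.peak_velocity_cm_s * (1.0 + phantom.pulsatility_fraction * waveform)

    frames = np.empty((n, m, m))
    rng = np.random.default_rng(seed)
    for k in range(n):
        velocity = vmax_t[k] * profile
        phase = np.pi * velocity / venc_cm_s
        if noise_sd_rad > 0:
            phase = phase + rng.normal(0.0, noise_sd_rad, phase.shape)
        frames[k] = wrap_phase(phase)

    cine = VelocityCine(frames=frames, venc_cm_s=venc_cm_s, frame_times_ms=times,
                        voxel_area_mm2=px * px, vessel_label=vessel_label,
                        heart_rate_bpm=phantom.heart_rate_bpm,
                        vessel_centre_px=((m - 1) / 2.0 + vessel.centre_mm[0] / px,
                                          (m - 1) / 2.0 + vessel.centre_mm[1] / px),
                        vessel_radius_px=vessel.radius_mm / px)
    cine.validate()
    return cine


# --------------------------------------------------------------------------
# Respiration and segmented acquisition timetable
# --------------------------------------------------------------------------

def simulate_respiration_and_timetable(
        phantom: PhantomSpec, protocol: FairProtocol | None = None,
        seed: int = 0, period_jitter: float = 0.03,
) -> tuple[RespiratoryTrace, AcquisitionTimetable]:
    """Simulate a respiratory trace and the end-expiration triggered schedule.

    Each respiratory cycle ends with a quiescent (end-expiration) window
    covering ``quiescent_fraction`` of the cycle.  Segments of
    ``lines_per_segment`` k-space lines are triggered at the start of the
    first quiescent window after the previous inversion has fully relaxed
    (TR_inversion); each segment then reads all TIs, so late readouts
    inevitably overrun into non-quiescent periods and retrospective gating
    has work to do.  The timetable covers all TIs x all k-space rows.
    """
    phantom.validate()
    if protocol is None:
        protocol = FairProtocol(matrix=phantom.grid_shape[0],
                                fov_mm=phantom.pixel_size_mm * phantom.grid_shape[0])
    rng = np.random.default_rng(seed)
    n_segments = protocol.matrix // protocol.lines_per_segment
    tis_s = protocol.tis_ms / 1000.0
    tr_rf_s = protocol.tr_rf_ms / 1000.0
    tr_inv_s = protocol.tr_inversion_ms / 1000.0
    segment_span_s = tis_s[-1] + protocol.lines_per_segment * tr_rf_s

    total_s = n_segments * (tr_inv_s + segment_span_s + 3 * phantom.resp_period_s) + 10
    n_cycles = int(np.ceil(total_s / phantom.resp_period_s)) + 2
    durations = phantom.resp_period_s * (
        1.0 + period_jitter * rng.standard_normal(n_cycles))
    durations = np.clip(durations, 0.5 * phantom.resp_period_s,
                        1.5 * phantom.resp_period_s)
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    q = phantom.quiescent_fraction
    windows = np.column_stack([boundaries[:-1] + (1.0 - q) * durations,
                               boundaries[1:]])
    trace = RespiratoryTrace(cycle_boundaries_s=boundaries,
                             quiescent_windows_s=windows)
    trace.validate()

    records = []
    t_ready = 0.0
    for seg in range(n_segments):
        starts = windows[:, 0]
        idx = np.searchsorted(starts, t_ready, side="left")
        if idx >= len(starts):
            raise RuntimeError("respiratory trace too short for the schedule")
        seg_start = float(starts[idx])
        for k in range(protocol.n_readouts):
            for j in range(protocol.lines_per_segment):
                records.append((k, seg * protocol.lines_per_segment + j, seg,
                                seg_start + tis_s[k] + j * tr_rf_s))
        t_ready = seg_start + tr_inv_s
    df = pd.DataFrame(records,
                      columns=["ti_index", "kspace_row", "segment_index", "time_s"])
    timetable = AcquisitionTimetable(lines=df)
    timetable.validate(protocol)
    return trace, timetable
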