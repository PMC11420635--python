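"""Synthetic DCE phantoms and survival cohorts with known ground truth.

The phantom emulates the acquisition the pipeline is built for: a spoiled
gradient echo (SPGR) dynamic series at 4.95 s temporal resolution plus two
pre-contrast variable-flip-angle scans at 6 and 16 degrees. Contrast arrival
is driven by a gamma-variate arterial input function

    C_aif(t) = A * ((t - t0)/tau)^k * exp(k * (1 - (t - t0)/tau)),  t > t0

which peaks at t0 + tau with amplitude A. Tumor voxels follow a delayed,
amplitude-scaled copy of the AIF with exponential washout — a deliberately
simple curve family (AUC60 is model-free, so no pharmacokinetic model is
implied) that still yields heterogeneous AUC60 maps. Signal noise is
Gaussian on signal intensity, where acquisition noise lives.

Survival cohorts draw exponential event times from a proportional-hazards
model with a dichotomised continuous biomarker (and optional extra
covariates), random exponential censoring and an administrative follow-up
cap, emulating a five-year head-and-neck radiotherapy cohort.

All randomness is driven by mandatory integer seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .containers import DynamicSeries, VFAScanPair
from .perfusion import AUC60_WINDOW_S, _windowed_integral
from .relaxometry import signal_spgr

__all__ = [
    "GammaVariateAIF",
    "TissueCurveParams",
    "PhantomSpec",
    "GroundTruth",
    "CovariateSpec",
    "CohortSpec",
    "generate_dce_phantom",
    "inject_edge_artifacts",
    "generate_survival_cohort",
    "generate_clinical_table",
]


@dataclass(frozen=True)
class GammaVariateAIF:
    """Gamma-variate arterial input function.

    peak concentration ``amplitude`` (mmol/L) at time ``onset_s + scale_s``.
    """

    amplitude: float = 6.0       # mmol/L at the peak
    onset_s: float = 22.0        # bolus arrival delay
    shape: float = 3.0           # k: larger -> narrower bolus
    scale_s: float = 8.0         # tau: time from onset to peak

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = (t - self.onset_s) / self.scale_s
        with np.errstate(invalid="ignore"):
            c = self.amplitude * np.power(np.clip(u, 0, None), self.shape) * np.exp(
                self.shape * (1.0 - u)
            )
        return np.where(u > 0, c, 0.0)

    @property
    def peak_time_s(self) -> float:
        return self.onset_s + self.scale_s


@dataclass(frozen=True)
class TissueCurveParams:
    """Tumor tissue curve: delayed, scaled AIF with exponential washout.

    Per-voxel amplitude fractions are drawn uniformly from
    ``amp_fraction * (1 -+ amp_spread)``, giving a heterogeneous but fully
    known AUC60 map.
    """

    amp_fraction: float = 0.25   # mean tissue amplitude as a fraction of the AIF
    amp_spread: float = 0.5      # relative half-width of the per-voxel uniform draw
    delay_s: float = 5.0         # tissue arrival delay after the AIF
    washout_rate: float = 0.005  # 1/s, exponential decay past tissue onset


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic DCE acquisition."""

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    dt_s: float = 4.95
    n_frames: int = 24
    n_baseline_frames: int = 4
    tr_s: float = 0.005
    flip_angles_deg: tuple[float, float] = (6.0, 16.0)
    dyn_flip_deg: float = 16.0
    aif_params: GammaVariateAIF = field(default_factory=GammaVariateAIF)
    tumor_center: tuple[float, float, float] | None = None   # default: grid center
    tumor_radii: tuple[float, float, float] = (6.0, 5.0, 4.0)
    tissue_curve_params: TissueCurveParams = field(default_factory=TissueCurveParams)
    t1_tumor_s: float = 1.2
    t1_background_s: float = 0.9
    t1_blood_s: float = 1.6
    m0: float = 1000.0
    noise_sd: float = 0.0
    artifact_fraction: float = 0.0
    artifact_magnitude: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.n_baseline_frames < 3:
            raise ValueError("need at least 3 baseline frames")
        if not 0 <= self.artifact_fraction < 1:
            raise ValueError("artifact_fraction must lie in [0, 1)")
        if self.aif_params.onset_s <= (self.n_baseline_frames - 1) * self.dt_s:
            raise ValueError("AIF onset must come after the baseline frames")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_s

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class GroundTruth:
    """Everything the phantom knows: the recovery oracle for the pipeline.

    ``auc60_map`` is the exact integral of the (piecewise-linear interpolant
    of the) true sampled concentration over the true 60 s window, so a
    noiseless run of the pipeline must reproduce it to rounding error.
    """

    t1_map_s: np.ndarray
    m0_map: np.ndarray
    conc: np.ndarray              # (x, y, z, t) true concentration, mmol/L
    times_s: np.ndarray
    auc60_map: np.ndarray
    window_start_index: int
    tumor_mask: np.ndarray
    aif_mask: np.ndarray
    artifact_mask: np.ndarray
    aif_curve: np.ndarray         # true AIF samples, mmol/L


def _ellipsoid_mask(grid_shape, center, radii) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    d = sum(((idx[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d <= 1.0


def tissue_curve_integral(aif: GammaVariateAIF, params: TissueCurveParams,
                          amp: float, t_from: float, t_to: float) -> float:
    """Closed-form integral of the tissue curve between two times.

    The tissue curve is amp * C_aif(t - delay) * exp(-w * (t - delay - t0)),
    a gamma-density-shaped integrand whose antiderivative is a regularised
    lower incomplete gamma function. Used as an independent oracle against
    the sampled trapezoidal integral.
    """
    k, tau, t0 = aif.shape, aif.scale_s, aif.onset_s + params.delay_s
    lam = k / tau + params.washout_rate

    def antideriv(t):
        u = max(t - t0, 0.0)
        return special.gammainc(k + 1, lam * u)

    norm = amp * aif.amplitude * np.exp(k) * special.gamma(k + 1) / (
        tau ** k * lam ** (k + 1)
    )
    return float(norm * (antideriv(t_to) - antideriv(t_from)))


def generate_dce_phantom(spec: PhantomSpec) -> tuple[DynamicSeries, VFAScanPair, GroundTruth]:
    """Build a DCE phantom via the SPGR forward model, with full ground truth.

    Returns the dynamic signal series, the two-flip-angle pre-contrast pair
    and a :class:`GroundTruth` carrying the true T1 map, concentration,
    AUC60 map and masks. Raises if the acquisition cannot cover a 60 s
    window starting one frame before the AIF peak.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    times = spec.times_s
    shape = tuple(spec.grid_shape)

    aif_samples = spec.aif_params(times)
    peak = int(np.argmax(aif_samples))
    if peak < 1:
        raise ValueError("AIF peaks at frame 0; increase onset_s or baseline frames")
    start = peak - 1
    end_time = times[start] + AUC60_WINDOW_S
    if times[-1] < end_time:
        need = int(np.ceil((end_time) / spec.dt_s)) + 1
        raise ValueError(
            f"acquisition too short: the 60 s window ends at {end_time:.2f} s "
            f"but the last frame is at {times[-1]:.2f} s; need n_frames >= {need}"
        )

    center = spec.tumor_center or tuple((s - 1) / 2.0 for s in shape)
    tumor = _ellipsoid_mask(shape, center, spec.tumor_radii)
    aif_mask = np.zeros(shape, dtype=bool)
    aif_mask[1:3, 1:3, shape[2] // 2 - 1:shape[2] // 2 + 1] = True
    if np.any(aif_mask & tumor):
        raise ValueError("tumor overlaps the artery region; shrink tumor_radii")

    # true T1 / M0 maps
    t1 = np.full(shape, spec.t1_background_s)
    t1[tumor] = spec.t1_tumor_s
    t1[aif_mask] = spec.t1_blood_s
    m0 = np.full(shape, spec.m0)

    # true concentration: artery carries the AIF; tumor a delayed scaled copy
    tc = spec.tissue_curve_params
    conc = np.zeros(shape + (len(times),))
    conc[aif_mask] = aif_samples
    n_tumor = int(np.count_nonzero(tumor))
    amp = tc.amp_fraction * (
        1.0 + tc.amp_spread * (2.0 * rng.random(n_tumor) - 1.0)
    )
    t0_tis = spec.aif_params.onset_s + tc.delay_s
    washout = np.exp(-tc.washout_rate * np.clip(times - t0_tis, 0, None))
    tissue_base = spec.aif_params(times - tc.delay_s) * washout
    conc[tumor] = amp[:, None] * tissue_base[None, :]

    # true AUC60: exact integral of the sampled curves over the true window
    auc_true = np.full(shape, np.nan)
    vox_conc = conc[tumor]
    auc_true[tumor] = _windowed_integral(vox_conc, times, start, end_time)

    # SPGR forward model: R1(t) = 1/T1 + r1*C -> signal
    from .relaxometry import DEFAULT_R1_RELAXIVITY

    r1_t = 1.0 / t1[..., None] + DEFAULT_R1_RELAXIVITY * conc
    signal = signal_spgr(m0[..., None], 1.0 / r1_t, spec.tr_s, spec.dyn_flip_deg)
    vfa = tuple(
        signal_spgr(m0, t1, spec.tr_s, a) for a in spec.flip_angles_deg
    )

    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
        vfa = tuple(v + rng.normal(0.0, spec.noise_sd, v.shape) for v in vfa)

    series = DynamicSeries(data=signal, times_s=times, affine=spec.affine)
    pair = VFAScanPair(
        volumes=vfa, flip_angles_deg=spec.flip_angles_deg,
        tr_s=spec.tr_s, affine=spec.affine,
    )
    truth = GroundTruth(
        t1_map_s=t1, m0_map=m0, conc=conc, times_s=times,
        auc60_map=auc_true, window_start_index=start,
        tumor_mask=tumor, aif_mask=aif_mask,
        artifact_mask=np.zeros(shape, dtype=bool),
        aif_curve=aif_samples,
    )
    if spec.artifact_fraction > 0:
        series = inject_edge_artifacts(
            series, truth, spec.artifact_fraction, spec.artifact_magnitude,
            seed=spec.seed + 1,
        )
    return series, pair, truth


def boundary_voxels(tumor_mask: np.ndarray) -> np.ndarray:
    """Tumor voxels with a non-tumor 6-neighbor."""
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(tumor_mask, structure=struct)
    return tumor_mask & ~eroded


def inject_edge_artifacts(
    series: DynamicSeries,
    truth: GroundTruth,
    fraction: float,
    magnitude: float = 5.0,
    seed: int = 0,
) -> DynamicSeries:
    """Corrupt a seeded random subset of tumor-boundary voxels.

    Emulates residual-motion artifacts at tumor edges bordering air or
    cartilage: each selected voxel gets, at 1-3 random post-baseline frames,
    either a signal spike (x ``magnitude``) or a signal drop to 20% of
    baseline (which converts to a strongly negative concentration).
    Updates ``truth.artifact_mask`` in place; deterministic given the seed.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if not np.any(truth.tumor_mask):
        raise ValueError("tumor mask is empty")
    if fraction == 0:
        return series

    rng = np.random.default_rng(seed)
    boundary = np.argwhere(boundary_voxels(truth.tumor_mask))
    n_pick = int(np.floor(fraction * len(boundary)))
    if n_pick == 0:
        return series
    pick = boundary[rng.choice(len(boundary), size=n_pick, replace=False)]

    data = series.data.copy()
    n_frames = series.n_frames
    first_dyn = max(3, int(np.argmax(truth.aif_curve > 0)))
    for (x, y, z) in pick:
        n_hits = rng.integers(1, 4)
        frames = rng.choice(np.arange(first_dyn, n_frames), size=n_hits, replace=False)
        for f in frames:
            if rng.random() < 0.5:
                data[x, y, z, f] *= magnitude
            else:
                data[x, y, z, f] = 0.2 * data[x, y, z, :3].mean()
        truth.artifact_mask[x, y, z] = True
    return DynamicSeries(data=data, times_s=series.times_s, affine=series.affine)


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """An extra cohort covariate with a known log hazard ratio."""

    name: str
    kind: str = "binary"          # "binary", "normal" or "uniform"
    params: tuple = (0.5,)        # binary: p; normal: (mean, sd); uniform: (lo, hi)
    log_hr: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Survival cohort with a dichotomised continuous biomarker effect.

    Defaults emulate a five-year head-and-neck radiotherapy cohort in which
    high tumor perfusion (biomarker above the cutpoint) is protective.
    """

    n_patients: int = 89
    biomarker_mean: float = 40.0       # mmol.s/L, AUC60_p95-like
    biomarker_sd: float = 12.0
    biomarker_dist: str = "normal"     # "normal", "lognormal" or "uniform"
    true_cutpoint: float = 31.7
    log_hr: float = -1.4               # high-vs-low group effect on the hazard
    baseline_hazard: float = 0.0094    # events per month in the low group
    censor_rate: float = 0.003         # random (loss-to-follow-up) censoring, 1/month
    horizon_months: float = 60.0       # administrative cap
    covariates: tuple[CovariateSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.horizon_months <= 0:
            raise ValueError("horizon must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor rate must be non-negative")


def _draw_biomarker(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.biomarker_dist == "normal":
        return rng.normal(spec.biomarker_mean, spec.biomarker_sd, spec.n_patients)
    if spec.biomarker_dist == "lognormal":
        mu = np.log(spec.biomarker_mean**2 / np.sqrt(spec.biomarker_mean**2 + spec.biomarker_sd**2))
        sig = np.sqrt(np.log(1 + (spec.biomarker_sd / spec.biomarker_mean) ** 2))
        return rng.lognormal(mu, sig, spec.n_patients)
    if spec.biomarker_dist == "uniform":
        half = np.sqrt(3.0) * spec.biomarker_sd
        return rng.uniform(spec.biomarker_mean - half, spec.biomarker_mean + half,
                           spec.n_patients)
    raise ValueError(f"unknown biomarker distribution {spec.biomarker_dist!r}")


def _draw_covariate(cov: CovariateSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if cov.kind == "binary":
        return (rng.random(n) < cov.params[0]).astype(float)
    if cov.kind == "normal":
        return rng.normal(cov.params[0], cov.params[1], n)
    if cov.kind == "uniform":
        return rng.uniform(cov.params[0], cov.params[1], n)
    raise ValueError(f"unknown covariate kind {cov.kind!r}")


def generate_survival_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one endpoint under exponential proportional hazards.

    Event times are exponential with per-patient hazard
    ``baseline_hazard * exp(log_hr * 1[biomarker > cutpoint] + sum(beta_c * x_c))``;
    censoring is the minimum of an exponential loss-to-follow-up time and
    the administrative horizon (event=False at the cap). Returns a tidy
    DataFrame with columns patient_id, time_months, event, biomarker,
    biomarker_high and one column per extra covariate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    biomarker = _draw_biomarker(spec, rng)
    high = (biomarker > spec.true_cutpoint).astype(float)
    lin = spec.log_hr * high
    cov_cols = {}
    for cov in spec.covariates:
        x = _draw_covariate(cov, spec.n_patients, rng)
        cov_cols[cov.name] = x
        lin = lin + cov.log_hr * x
    hazard = spec.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, spec.n_patients)
    else:
        t_cens = np.full(spec.n_patients, np.inf)
    t_cens = np.minimum(t_cens, spec.horizon_months)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    time = np.maximum(time, 1e-6)  # times must be strictly positive
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(spec.n_patients)],
            "time_months": time,
            "event": event,
            "biomarker": biomarker,
            "biomarker_high": high.astype(bool),
        }
    )
    for name, x in cov_cols.items():
        df[name] = x
    return df


def generate_clinical_table(
    spec: CohortSpec,
    endpoint_hazards: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Multi-endpoint clinical table sharing one biomarker/covariate draw.

    ``endpoint_hazards`` maps endpoint names (e.g. LC, DC, OS) to baseline
    hazards; each endpoint's event times are simulated independently given
    the shared covariates. Columns: time_<ep>, event_<ep> per endpoint plus
    the shared biomarker/covariate columns.
    """
    if endpoint_hazards is None:
        # five-year rates of roughly 81/70/57% -> monthly exponential rates
        endpoint_hazards = {"LC": 0.0035, "DC": 0.0059, "OS": 0.0094}
    base = generate_survival_cohort(replace(spec, seed=spec.seed))
    out = base[["patient_id", "biomarker", "biomarker_high"]].copy()
    for cov in spec.covariates:
        out[cov.name] = base[cov.name]
    for i, (name, hz) in enumerate(sorted(endpoint_hazards.items())):
        # shared biomarker/covariate draw; the endpoint seed drives only the
        # event- and censor-time draws
        rng = np.random.default_rng(spec.seed + 2000 + i)
        lin = spec.log_hr * base["biomarker_high"].to_numpy(dtype=float)
        for cov in spec.covariates:
            lin = lin + cov.log_hr * base[cov.name].to_numpy(dtype=float)
        hazard = hz * np.exp(lin)
        t_event = rng.exponential(1.0 / hazard)
        if spec.censor_rate > 0:
            t_cens = rng.exponential(1.0 / spec.censor_rate, spec.n_patients)
        else:
            t_cens = np.full(spec.n_patients, np.inf)
        t_cens = np.minimum(t_cens, spec.horizon_months)
        out[f"time_{name}"] = np.maximum(np.minimum(t_event, t_cens), 1e-6)
        out[f"event_{name}"] = t_event <= t_cens
    return out
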