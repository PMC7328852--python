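"""Phantom generators with known ground truth for every instrument modality.

The generators emulate the three measurement channels of a biofilm
disinfection experiment so the full quantification chain can be exercised
and validated without raw instrument data:

- layered OCT B-scan pairs: background / low-intensity disrupted stratum /
  high-intensity coherent stratum above a substrate line, with multiplicative
  speckle and smooth column-wise height variation, in the recessed-well
  geometry (nominal 250 um biofilm thickness);
- stress-relaxation curves: a four-arm Prony series under 20% strain with
  additive Gaussian noise and a linear evaporation drift, plus the matching
  blank reference trace;
- three-channel confocal stacks with prescribed live/dead/EPS voxel
  fractions of the biomass.

Group-level generation (:func:`generate_study`) realizes a time x volume
factorial: per-sample true values are drawn around the group means and can
be calibrated so their *sample* moments equal the target statistics exactly
(``calibrate="sample"``), which is how recovery of published group values
is tested without seed luck in the truth draw.

A modelling constraint worth knowing: the percentage stress relaxation of a
Prony series is pinned to its slow-arm importances,
``R = 100 * (1 - sum_i p_i exp(-100 / tau_i))``. Per-sample R truths are
therefore *derived* from the drawn importance vectors, with the EPS and
bacteria time constants solved at group level so the realized mean R equals
the requested group mean. Drawing R independently of the importances would
ask for physically impossible curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from chemoassay.clsm_quant import CLSMStack
from chemoassay.llct_visco import (
    EvaporationReference,
    MaxwellModel,
    RelaxationRecord,
)
from chemoassay.oct_quant import BScan

__all__ = [
    "GroupDesign",
    "OCTPhantomParams",
    "RelaxationPhantomParams",
    "CLSMPhantomParams",
    "OCTPairTruth",
    "CLSMTruth",
    "generate_oct_pair",
    "generate_relaxation_curve",
    "generate_clsm_stack",
    "sample_group_truths",
    "generate_study",
    "oct_reference_group",
    "llct_reference_group",
    "OCT_REFERENCE_STATS",
    "LLCT_REFERENCE_STATS",
]

# ---------------------------------------------------------------------------
# reference group statistics of the disinfection study the phantoms emulate
# (exposure-time marginals for the OCT outcomes; volume marginals for the
# viscoelastic outcomes). Keys: time in s / volume in uL.

#: (dissolution mean, dissolution SD, disruption mean, disruption SD) in %
OCT_REFERENCE_STATS: dict[int, tuple[float, float, float, float]] = {
    60: (16.5, 41.8, 25.3, 24.1),
    120: (34.5, 46.4, 44.8, 33.7),
    300: (81.3, 24.0, 72.6, 25.3),
}

#: (R mean, R SD, free-water importance mean, SD, bacteria importance mean, SD) in %
LLCT_REFERENCE_STATS: dict[int, tuple[float, float, float, float, float, float]] = {
    20: (44.5, 20.6, 26.8, 16.3, 53.4, 21.2),
    40: (64.3, 16.2, 44.2, 18.2, 35.2, 16.3),
}

_SD_KEYS = (
    "dissolution",
    "disruption",
    "importance_free_water",
    "importance_bacteria",
    "fractions",
)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class GroupDesign:
    """One cell of the factorial design plus its ground-truth group means.

    ``between_sample_sd`` is either one scalar spread applied to every
    outcome or a mapping with keys ``dissolution``, ``disruption``,
    ``importance_free_water``, ``importance_bacteria`` and ``fractions``
    (outcomes have different published spreads, so a single scalar is
    usually too coarse).

    ``calibrate="sample"`` standardizes the drawn per-sample truths to the
    exact sample mean/SD targets inside their valid ranges;
    ``"population"`` leaves them as plain truncated draws.
    """

    time_s: int
    volume_ul: int
    n: int = 10
    true_dissolution_pct: float = 50.0
    true_disruption_pct: float = 40.0
    # consistent with the default importances: a Prony series retaining the
    # bacteria arm (45%) nearly undecayed relaxes by roughly 100 - 45 = 55-60%
    true_R_pct: float = 60.0
    true_importance_pct: tuple[float, float, float, float] = (35.0, 10.0, 10.0, 45.0)
    true_fractions_pct: tuple[float, float, float] = (40.0, 20.0, 40.0)
    between_sample_sd: float | Mapping[str, float] = 10.0
    allow_negative_dissolution: bool = False
    calibrate: str = "population"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        imp = np.asarray(self.true_importance_pct, dtype=float)
        frac = np.asarray(self.true_fractions_pct, dtype=float)
        if imp.shape != (4,) or abs(imp.sum() - 100.0) > 1e-9:
            raise ValueError("true_importance_pct must be a 4-vector summing to 100")
        if frac.shape != (3,) or abs(frac.sum() - 100.0) > 1e-9:
            raise ValueError("true_fractions_pct must be a 3-vector summing to 100")
        if np.any(imp < 0) or np.any(frac < 0):
            raise ValueError("importances and fractions must be non-negative")
        for name in ("true_dissolution_pct", "true_R_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if not (-100.0 <= self.true_disruption_pct <= 1000.0):
            raise ValueError("true_disruption_pct must lie in [-100, 1000]")
        if self.calibrate not in ("sample", "population"):
            raise ValueError("calibrate must be 'sample' or 'population'")

    def sd(self, key: str) -> float:
        if key not in _SD_KEYS:
            raise KeyError(f"unknown spread key '{key}'; expected one of {_SD_KEYS}")
        if isinstance(self.between_sample_sd, Mapping):
            if key not in self.between_sample_sd:
                raise KeyError(
                    f"between_sample_sd mapping lacks key '{key}'")
            return float(self.between_sample_sd[key])
        return float(self.between_sample_sd)


@dataclass(frozen=True)
class OCTPhantomParams:
    """Geometry, optics and noise of the layered B-scan phantom.

    Defaults mirror the study conditions: 250 um nominal biofilm thickness
    in the recessed well, 2 um pixel pitch (already corrected for the
    refraction index), and strictly increasing stratum intensities
    background < disrupted < coherent.
    """

    width_px: int = 256
    height_px: int = 420
    pixel_pitch_um: float = 2.0
    substrate_row: int = 370
    nominal_thickness_um: float = 250.0
    disrupted_fraction: float = 0.2
    mean_intensities: tuple[float, float, float] = (10.0, 80.0, 200.0)
    speckle_sd: float = 0.05
    roughness_um: float = 8.0
    seed: int | None = None

    def __post_init__(self) -> None:
        bg, dis, coh = self.mean_intensities
        if not (0 <= bg < dis < coh):
            raise ValueError(
                "mean_intensities must be strictly increasing "
                "(background < disrupted < coherent) and non-negative")
        if not (0.0 <= self.disrupted_fraction <= 1.0):
            raise ValueError("disrupted_fraction must lie in [0, 1]")
        if self.nominal_thickness_um <= 0:
            raise ValueError("nominal_thickness_um must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if not (0 < self.substrate_row <= self.height_px):
            raise ValueError("substrate_row must lie inside the image")
        if self.speckle_sd < 0 or self.roughness_um < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class RelaxationPhantomParams:
    """Four-arm Prony-series forward model of one LLCT measurement."""

    E_true: tuple[float, float, float, float]
    tau_true: tuple[float, float, float, float]
    strain: float = 0.2
    duration_s: float = 100.0
    sample_rate_hz: float = 100.0
    noise_sd: float = 0.0
    evap_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        E = np.asarray(self.E_true, dtype=float)
        tau = np.asarray(self.tau_true, dtype=float)
        if E.shape != (4,) or tau.shape != (4,):
            raise ValueError("E_true and tau_true must be 4-vectors")
        if np.any(E < 0):
            raise ValueError("E_true must be non-negative elementwise")
        if np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
            raise ValueError("tau_true must be positive and strictly increasing")
        # component bins: free water / bound water / EPS / bacteria
        if not (tau[0] < 0.5 < tau[1] < 3.0 < tau[2] < 100.0 < tau[3]):
            raise ValueError(
                "tau_true must respect the component bins "
                "tau1 < 0.5 < tau2 < 3 < tau3 < 100 < tau4")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 < self.strain < 1.0):
            raise ValueError("strain must be in (0, 1)")


@dataclass(frozen=True)
class CLSMPhantomParams:
    """Three-channel confocal stack phantom with prescribed biomass split."""

    shape_vox: tuple[int, int, int] = (16, 64, 64)
    voxel_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    fractions_pct: tuple[float, float, float] = (40.0, 20.0, 40.0)
    biomass_fill: float = 0.4
    intensity_snr: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions_pct, dtype=float)
        if frac.shape != (3,) or abs(frac.sum() - 100.0) > 1e-9:
            raise ValueError("fractions_pct must be a 3-vector summing to 100")
        if np.any(frac < 0):
            raise ValueError("fractions_pct must be non-negative")
        if not (0.0 < self.biomass_fill <= 1.0):
            raise ValueError("biomass_fill must lie in (0, 1]")
        if len(self.shape_vox) != 3 or any(s < 1 for s in self.shape_vox):
            raise ValueError("shape_vox must be three positive dimensions")
        if self.intensity_snr <= 0:
            raise ValueError("intensity_snr must be positive")


# ---------------------------------------------------------------------------
# OCT phantom


@dataclass(frozen=True)
class OCTPairTruth:
    """Ground truth attached to a generated pre/post B-scan pair."""

    dissolution_pct: float
    disruption_pct: float
    pre_coherent_um: float
    pre_disrupted_um: float
    post_coherent_um: float
    post_disrupted_um: float
    pre_mask: np.ndarray
    post_mask: np.ndarray


def _rng_from(params_seed: int | None, rng: np.random.Generator | None
              ) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(params_seed)


def _roughness_profile(n: int, scale_um: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean column-wise height variation with SD ``scale_um``."""
    if scale_um == 0:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.standard_normal(n), sigma=6.0, mode="wrap")
    raw -= raw.mean()
    sd = raw.std()
    return raw / sd * scale_um if sd > 0 else np.zeros(n)


def _render_bscan(coh_px: np.ndarray, dis_px: np.ndarray,
                  params: OCTPhantomParams,
                  rng: np.random.Generator) -> tuple[BScan, np.ndarray]:
    """Rasterize column-wise layer heights into a speckled uint16 B-scan."""
    H, W = params.height_px, params.width_px
    sub = params.substrate_row
    bg, dis_i, coh_i = params.mean_intensities

    rows = np.arange(H)[:, None]
    coh_mask = (rows >= sub - coh_px[None, :]) & (rows < sub)
    dis_mask = (rows >= sub - coh_px[None, :] - dis_px[None, :]) & (
        rows < sub - coh_px[None, :])
    labels = np.zeros((H, W), dtype=np.uint8)
    labels[dis_mask] = 1
    labels[coh_mask] = 2

    img = np.full((H, W), float(bg))
    img[dis_mask] = dis_i
    img[coh_mask] = coh_i
    if params.speckle_sd > 0:
        s = params.speckle_sd
        img = img * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=img.shape)
    # bright substrate band below the biofilm
    img[sub:min(sub + 3, H), :] = coh_i * 1.1
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    scan = BScan(pixels=img, pixel_pitch_um=params.pixel_pitch_um,
                 substrate_row=sub)
    return scan, labels


def generate_oct_pair(params: OCTPhantomParams,
                      dissolution_pct: float,
                      disruption_pct: float,
                      rng: np.random.Generator | None = None,
                      allow_negative: bool = False,
                      ) -> tuple[BScan, BScan, OCTPairTruth]:
    """Generate a pre/post-treatment B-scan pair with known outcome truth.

    The pre-treatment coherent stratum has mean thickness
    ``nominal * (1 - disrupted_fraction)`` and the disrupted stratum
    ``nominal * disrupted_fraction``; one smooth roughness profile per
    stratum is shared by both scans (it is the same physical sample). The
    post scan shrinks every coherent column by ``dissolution_pct`` per cent
    and grows the disrupted stratum by ``disruption_pct`` per cent of the
    realized pre-treatment total thickness, so the generator and the
    analyzer share one metric convention.

    ``allow_negative=True`` admits negative dissolution (swelling: the
    coherent stratum grows), which real samples do exhibit; by default
    values outside [0, 100] are rejected.
    """
    lo = -100.0 if allow_negative else 0.0
    if not (lo <= dissolution_pct <= 100.0):
        raise ValueError(
            f"dissolution_pct must lie in [{lo:g}, 100], got {dissolution_pct}")
    rng = _rng_from(params.seed, rng)
    pitch = params.pixel_pitch_um
    W = params.width_px

    pre_coh_mean = params.nominal_thickness_um * (1.0 - params.disrupted_fraction)
    pre_dis_mean = params.nominal_thickness_um * params.disrupted_fraction
    coh_col = np.clip(pre_coh_mean + _roughness_profile(W, params.roughness_um, rng),
                      0.0, None)
    dis_col = np.clip(pre_dis_mean + _roughness_profile(W, params.roughness_um, rng),
                      0.0, None)
    realized_total = float(coh_col.mean() + dis_col.mean())
    if realized_total <= 0:
        raise ValueError("pre-treatment phantom has zero total thickness")

    post_coh_col = coh_col * (1.0 - dissolution_pct / 100.0)
    delta_dis = disruption_pct / 100.0 * realized_total
    post_dis_col = np.clip(dis_col + delta_dis, 0.0, None)

    max_um = params.substrate_row * pitch
    for name, cols in (("pre", coh_col + dis_col),
                       ("post", post_coh_col + post_dis_col)):
        if np.any(cols > max_um):
            raise ValueError(
                f"{name}-treatment strata ({cols.max():.0f} um) exceed the "
                f"{max_um:.0f} um available above the substrate; enlarge the image")

    to_px = lambda um: np.rint(um / pitch).astype(int)
    pre_scan, pre_mask = _render_bscan(to_px(coh_col), to_px(dis_col), params, rng)
    post_scan, post_mask = _render_bscan(to_px(post_coh_col), to_px(post_dis_col),
                                         params, rng)
    truth = OCTPairTruth(
        dissolution_pct=float(dissolution_pct),
        disruption_pct=float(disruption_pct),
        pre_coherent_um=float(coh_col.mean()),
        pre_disrupted_um=float(dis_col.mean()),
        post_coherent_um=float(post_coh_col.mean()),
        post_disrupted_um=float(post_dis_col.mean()),
        pre_mask=pre_mask,
        post_mask=post_mask,
    )
    return pre_scan, post_scan, truth


# ---------------------------------------------------------------------------
# LLCT phantom


def generate_relaxation_curve(params: RelaxationPhantomParams,
                              rng: np.random.Generator | None = None,
                              ) -> tuple[RelaxationRecord, MaxwellModel,
                                         EvaporationReference]:
    """One noisy stress-relaxation trace plus its ground truth and blank.

    ``stress(t) = strain * sum_i E_i exp(-t/tau_i) + evap_rate * t + noise``.
    The returned :class:`EvaporationReference` is the matching drift-only
    blank trace, so reference subtraction removes the drift exactly.
    """
    rng = _rng_from(params.seed, rng)
    n = int(round(params.duration_s * params.sample_rate_hz)) + 1
    t = np.arange(n) / params.sample_rate_hz
    E = np.asarray(params.E_true, dtype=float)
    tau = np.asarray(params.tau_true, dtype=float)
    stress = params.strain * (np.exp(-t[:, None] / tau) @ E)
    stress = stress + params.evap_rate * t
    if params.noise_sd > 0:
        stress = stress + rng.normal(0.0, params.noise_sd, size=n)
    record = RelaxationRecord(time_s=t, stress_pa=stress,
                              strain=params.strain, duration_s=params.duration_s)
    truth = MaxwellModel(E=E, tau=tau, sse=0.0)
    ref = EvaporationReference(time_s=t, stress_pa=params.evap_rate * t)
    return record, truth, ref


# ---------------------------------------------------------------------------
# CLSM phantom


@dataclass(frozen=True)
class CLSMTruth:
    """Ground truth attached to a generated confocal stack."""

    fractions_pct: np.ndarray
    counts: tuple[int, int, int]
    masks: tuple[np.ndarray, np.ndarray, np.ndarray]


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``targets`` (sums exactly)."""
    raw = targets / targets.sum() * total if targets.sum() > 0 else np.zeros_like(targets)
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base

_CLSM_BG_MEAN = 30.0
_CLSM_BG_SD = 2.0
_CLSM_FG_SD = 8.0


def generate_clsm_stack(params: CLSMPhantomParams,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[CLSMStack, CLSMTruth]:
    """Three-channel stack realizing the requested biomass fractions.

    ``round(biomass_fill * n_voxels)`` biomass voxels are placed uniformly
    at random and split between the live/dead/EPS channels by largest-
    remainder rounding of ``fractions_pct`` (channel counts land within one
    voxel of their targets). Foreground intensity is
    ``bg + intensity_snr * sd_fg`` with a wider spread than the tight
    dark-noise background, emulating Poisson-like signal noise.
    """
    rng = _rng_from(params.seed, rng)
    shape = tuple(params.shape_vox)
    n_vox = int(np.prod(shape))
    n_bio = int(round(params.biomass_fill * n_vox))
    counts = _largest_remainder(np.asarray(params.fractions_pct, dtype=float), n_bio)
    chosen = rng.choice(n_vox, size=n_bio, replace=False)
    splits = np.split(chosen, np.cumsum(counts)[:-1])

    fg_mean = _CLSM_BG_MEAN + params.intensity_snr * _CLSM_FG_SD
    channels = []
    masks = []
    for idx in splits:
        vol = rng.normal(_CLSM_BG_MEAN, _CLSM_BG_SD, size=n_vox)
        vol[idx] = rng.normal(fg_mean, _CLSM_FG_SD, size=idx.size)
        mask = np.zeros(n_vox, dtype=bool)
        mask[idx] = True
        channels.append(np.clip(vol, 0.0, None).reshape(shape).astype(np.float32))
        masks.append(mask.reshape(shape))
    stack = CLSMStack(live=channels[0], dead=channels[1], eps=channels[2],
                      voxel_um=params.voxel_um)
    frac_true = (100.0 * counts / n_bio) if n_bio > 0 else np.zeros(3)
    truth = CLSMTruth(fractions_pct=frac_true,
                      counts=tuple(int(c) for c in counts),
                      masks=tuple(masks))
    return stack, truth


# ---------------------------------------------------------------------------
# group-level truth sampling


def _match_sample_moments(x: np.ndarray, mean: float, sd: float,
                          lo: float, hi: float,
                          iters: int = 400, tol: float = 1e-8) -> np.ndarray:
    """Standardize draws to exact sample moments inside [lo, hi].

    Alternates exact mean/SD standardization with clipping; converges when
    the target moments are attainable on the interval (sd must stay below
    the Bhatia-Davis bound ``sqrt((mean-lo)*(hi-mean))``).
    """
    x = np.asarray(x, dtype=float).copy()
    if x.size < 2 or sd == 0:
        return np.clip(np.full_like(x, mean), lo, hi)
    if not (lo < mean < hi):
        raise ValueError(f"target mean {mean} outside ({lo}, {hi})")
    bd = math.sqrt((mean - lo) * (hi - mean))
    if sd >= bd:
        raise ValueError(
            f"target SD {sd} unattainable on [{lo}, {hi}] with mean {mean} "
            f"(Bhatia-Davis bound {bd:.3g})")
    for _ in range(iters):
        m, s = x.mean(), x.std(ddof=1)
        if s == 0:
            x = x + np.linspace(-sd, sd, x.size)
            continue
        x = mean + (x - m) * (sd / s)
        np.clip(x, lo, hi, out=x)
        if (abs(x.mean() - mean) < tol
                and abs(x.std(ddof=1) - sd) < tol):
            return x
    warnings.warn(
        f"sample-moment calibration stopped at mean {x.mean():.4f} "
        f"(target {mean}), SD {x.std(ddof=1):.4f} (target {sd})",
        stacklevel=2)
    return x


def _draw_calibrated(rng: np.random.Generator, n: int, mean: float, sd: float,
                     lo: float, hi: float, calibrate: str) -> np.ndarray:
    z = rng.standard_normal(n)
    x = mean + sd * z
    if calibrate == "sample":
        return _match_sample_moments(x, mean, sd, lo, hi)
    return np.clip(x, lo, hi)


def _draw_importances(rng: np.random.Generator, design: GroupDesign
                      ) -> np.ndarray:
    """Per-sample importance 4-vectors (%, rows sum to 100).

    Free-water and bacteria importances carry the published between-sample
    spread (negatively correlated: a curve that retains more slow-arm
    stiffness has less fast-arm stiffness); bound water and EPS share the
    remaining mass in the design's target ratio.
    """
    n = design.n
    mean_f, mean_b = design.true_importance_pct[0], design.true_importance_pct[3]
    sd_f, sd_b = design.sd("importance_free_water"), design.sd("importance_bacteria")
    rho = -0.4
    cov = np.array([[sd_f ** 2, rho * sd_f * sd_b],
                    [rho * sd_f * sd_b, sd_b ** 2]])
    fb = rng.multivariate_normal([mean_f, mean_b], cov, size=n,
                                 method="cholesky")
    f, b = fb[:, 0], fb[:, 1]

    def _project(f: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = np.clip(f, 0.5, 98.0)
        b = np.clip(b, 0.5, 98.0)
        tot = f + b
        over = tot > 98.0
        scale = np.where(over, 98.0 / tot, 1.0)
        return f * scale, b * scale

    if design.calibrate == "sample" and n >= 2:
        for _ in range(400):
            for arr, mean, sd in ((f, mean_f, sd_f), (b, mean_b, sd_b)):
                m, s = arr.mean(), arr.std(ddof=1)
                if s > 0:
                    arr *= sd / s
                    arr += mean - arr.mean()
            f, b = _project(f, b)
            if (abs(f.mean() - mean_f) < 1e-8 and abs(f.std(ddof=1) - sd_f) < 1e-8
                    and abs(b.mean() - mean_b) < 1e-8
                    and abs(b.std(ddof=1) - sd_b) < 1e-8):
                break
        else:
            warnings.warn(
                "importance calibration did not reach exact sample moments: "
                f"free {f.mean():.3f}/{f.std(ddof=1):.3f}, "
                f"bacteria {b.mean():.3f}/{b.std(ddof=1):.3f}", stacklevel=2)
    else:
        f, b = _project(f, b)

    rem = 100.0 - f - b
    w_bound_eps = np.asarray(design.true_importance_pct[1:3], dtype=float)
    w = w_bound_eps / w_bound_eps.sum() if w_bound_eps.sum() > 0 else np.array([0.5, 0.5])
    p = np.column_stack([f, rem * w[0], rem * w[1], b])
    return p


_TAU_FAST = (0.15, 1.2)  # log-midpoints of the free/bound water bins, s


def _solve_group_taus(p_pct: np.ndarray, R_target: float,
                      duration_s: float = 100.0) -> np.ndarray:
    """Solve (tau3, tau4) so the realized mean R equals ``R_target``.

    With the fast arms fully relaxed over the hold, the retained stress
    fraction is ``p3 * exp(-D/tau3) + p4 * exp(-D/tau4)``; tau4 starts at a
    preferred slow value and tau3 absorbs the residual, falling back to
    adjusting tau4 when tau3 hits its bin bounds. Warns when the target is
    infeasible within the bins (the nearest feasible R is then realized).
    """
    pbar = p_pct.mean(axis=0) / 100.0
    D = duration_s
    x_fast = pbar[0] * math.exp(-D / _TAU_FAST[0]) + pbar[1] * math.exp(-D / _TAU_FAST[1])
    retained = 1.0 - R_target / 100.0 - x_fast

    x3_lo, x3_hi = math.exp(-D / 3.2), math.exp(-D / 95.0)
    x4_lo, x4_hi = math.exp(-D / 110.0), math.exp(-D / 9.5e3)

    x4 = math.exp(-D / 3000.0)
    x3 = (retained - pbar[3] * x4) / pbar[2] if pbar[2] > 0 else x3_lo
    if not (x3_lo <= x3 <= x3_hi):
        x3 = min(max(x3, x3_lo), x3_hi)
        if pbar[3] > 0:
            x4 = (retained - pbar[2] * x3) / pbar[3]
        if not (x4_lo <= x4 <= x4_hi):
            x4 = min(max(x4, x4_lo), x4_hi)
            realized_R = 100.0 * (1.0 - x_fast - pbar[2] * x3 - pbar[3] * x4)
            warnings.warn(
                f"group mean R {R_target:.1f}% infeasible within the component "
                f"bins for these importances; realizing {realized_R:.1f}%",
                stacklevel=2)
    tau3 = -D / math.log(x3)
    tau4 = -D / math.log(x4)
    return np.array([_TAU_FAST[0], _TAU_FAST[1], tau3, tau4])


def _derived_R(p_pct: np.ndarray, tau: np.ndarray,
               duration_s: float = 100.0) -> np.ndarray:
    x = np.exp(-duration_s / tau)
    return 100.0 * (1.0 - (p_pct / 100.0) @ x)


def sample_group_truths(design: GroupDesign,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-sample ground-truth outcome values for one design cell.

    Returns one row per sample with the OCT outcome truths, the importance
    vector, the derived true R, the shared group time constants, the total
    modulus ``E_total`` (log-normal around 1 kPa) and the per-sample noise
    scale (1% of the initial stress).
    """
    n = design.n
    lo_diss = -100.0 if design.allow_negative_dissolution else 0.0
    diss = _draw_calibrated(rng, n, design.true_dissolution_pct,
                            design.sd("dissolution"), lo_diss, 100.0,
                            design.calibrate)
    disr = _draw_calibrated(rng, n, design.true_disruption_pct,
                            design.sd("disruption"), -100.0, 1000.0,
                            design.calibrate)
    p = _draw_importances(rng, design)
    tau = _solve_group_taus(p, design.true_R_pct)
    R = _derived_R(p, tau)

    sd_frac = design.sd("fractions")
    frac = np.clip(
        np.asarray(design.true_fractions_pct)[None, :]
        + sd_frac * rng.standard_normal((n, 3)),
        0.5, None)
    frac = 100.0 * frac / frac.sum(axis=1, keepdims=True)

    e_total = np.exp(rng.normal(np.log(1000.0), 0.3, size=n))

    df = pd.DataFrame({
        "time_s": design.time_s,
        "volume_ul": design.volume_ul,
        "true_dissolution_pct": diss,
        "true_disruption_pct": disr,
        "true_R_pct": R,
        "true_imp_free_water": p[:, 0],
        "true_imp_bound_water": p[:, 1],
        "true_imp_eps": p[:, 2],
        "true_imp_bacteria": p[:, 3],
        "true_frac_live": frac[:, 0],
        "true_frac_dead": frac[:, 1],
        "true_frac_eps": frac[:, 2],
        "tau1_s": tau[0], "tau2_s": tau[1], "tau3_s": tau[2], "tau4_s": tau[3],
        "E_total_pa": e_total,
    })
    return df


# ---------------------------------------------------------------------------
# full factorial study on disk


def oct_reference_group(time_s: int, volume_ul: int = 40, n: int = 30,
                        calibrate: str = "sample") -> GroupDesign:
    """Design cell calibrated to the published OCT time-marginal statistics."""
    if time_s not in OCT_REFERENCE_STATS:
        raise KeyError(f"no reference statistics for time {time_s} s")
    d_mean, d_sd, r_mean, r_sd = OCT_REFERENCE_STATS[time_s]
    return GroupDesign(
        time_s=time_s, volume_ul=volume_ul, n=n,
        true_dissolution_pct=d_mean, true_disruption_pct=r_mean,
        between_sample_sd={
            "dissolution": d_sd, "disruption": r_sd,
            "importance_free_water": 15.0, "importance_bacteria": 15.0,
            "fractions": 8.0,
        },
        # published SDs exceed the mean at the short exposures: real samples
        # include swelling (negative dissolution), so the draws must too
        allow_negative_dissolution=True,
        calibrate=calibrate,
    )


def llct_reference_group(volume_ul: int, time_s: int = 120, n: int = 20,
                         calibrate: str = "sample") -> GroupDesign:
    """Design cell calibrated to the published viscoelastic volume-marginal stats."""
    if volume_ul not in LLCT_REFERENCE_STATS:
        raise KeyError(f"no reference statistics for volume {volume_ul} uL")
    r_mean, _r_sd, f_mean, f_sd, b_mean, b_sd = LLCT_REFERENCE_STATS[volume_ul]
    rest = 100.0 - f_mean - b_mean
    return GroupDesign(
        time_s=time_s, volume_ul=volume_ul, n=n,
        true_R_pct=r_mean,
        true_importance_pct=(f_mean, rest / 2.0, rest / 2.0, b_mean),
        between_sample_sd={
            "dissolution": 20.0, "disruption": 20.0,
            "importance_free_water": f_sd, "importance_bacteria": b_sd,
            "fractions": 8.0,
        },
        calibrate=calibrate,
    )


def generate_study(groups: Sequence[GroupDesign], out_dir: str | Path,
                   seed: int, force: bool = False,
                   oct_params: OCTPhantomParams | None = None,
                   clsm_params: CLSMPhantomParams | None = None,
                   sample_rate_hz: float = 100.0,
                   evap_rate_pa_per_s: float = -0.1,
                   ) -> pd.DataFrame:
    """Write a full phantom study to disk and return its manifest.

    One folder per sample holding the pre/post B-scans (16-bit TIFF + YAML
    sidecar), the relaxation trace and its evaporation blank (CSV), and the
    confocal stack (multipage TIFF, channel order live/dead/EPS); a
    ``manifest.csv`` at the root maps samples to factor levels, file paths
    and ground truth. Fully reproducible from ``seed``; refuses to
    overwrite an existing manifest unless ``force=True``.
    """
    from chemoassay import io as cio  # deferred: io imports this module's types

    if not groups:
        raise ValueError("need at least one group")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    oct_params = oct_params or OCTPhantomParams()
    clsm_params = clsm_params or CLSMPhantomParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    for design in groups:
        truths = sample_group_truths(design, rng)
        for i, truth in truths.iterrows():
            sample_id = f"t{design.time_s}_v{design.volume_ul}_s{i:03d}"
            sdir = out_dir / sample_id
            sdir.mkdir(exist_ok=True)

            pre, post, _ = generate_oct_pair(
                oct_params, truth["true_dissolution_pct"],
                truth["true_disruption_pct"], rng=rng,
                allow_negative=design.allow_negative_dissolution)
            cio.write_bscan(sdir / "oct_pre.tif", pre)
            cio.write_bscan(sdir / "oct_post.tif", post)

            tau = tuple(truth[[f"tau{k}_s" for k in range(1, 5)]])
            p = np.array(truth[["true_imp_free_water", "true_imp_bound_water",
                                "true_imp_eps", "true_imp_bacteria"]],
                         dtype=float)
            e_total = float(truth["E_total_pa"])
            rparams = RelaxationPhantomParams(
                E_true=tuple(e_total * p / 100.0), tau_true=tau,
                sample_rate_hz=sample_rate_hz,
                noise_sd=0.01 * 0.2 * e_total,
                evap_rate=evap_rate_pa_per_s)
            record, _, ref = generate_relaxation_curve(rparams, rng=rng)
            cio.write_relaxation_csv(sdir / "relaxation.csv", record)
            cio.write_reference_csv(sdir / "evaporation_ref.csv", ref)

            cparams = CLSMPhantomParams(
                shape_vox=clsm_params.shape_vox, voxel_um=clsm_params.voxel_um,
                fractions_pct=tuple(truth[["true_frac_live", "true_frac_dead",
                                           "true_frac_eps"]]),
                biomass_fill=clsm_params.biomass_fill,
                intensity_snr=clsm_params.intensity_snr)
            stack, _ = generate_clsm_stack(cparams, rng=rng)
            cio.write_clsm_stack(sdir / "clsm.tif", stack)

            row = {"sample_id": sample_id,
                   "time_s": design.time_s, "volume_ul": design.volume_ul,
                   "oct_pre": f"{sample_id}/oct_pre.tif",
                   "oct_post": f"{sample_id}/oct_post.tif",
                   "relaxation": f"{sample_id}/relaxation.csv",
                   "evaporation_ref": f"{sample_id}/evaporation_ref.csv",
                   "clsm": f"{sample_id}/clsm.tif"}
            row.update({k: truth[k] for k in truths.columns
                        if k.startswith(("true_", "tau", "E_total"))})
            rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest
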