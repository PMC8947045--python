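"""Synthetic phantom cohorts for the VNCa marrow pipeline.

Clinical VNCa data cannot be redistributed, so every stage of the pipeline
is exercised on simulated exams: stacked vertebral bodies (axis-aligned
boxes with a cortical shell) on a regular voxel grid, marrow interiors
whose attenuation values are drawn from a parametric distribution
calibrated to a target (Q1, median, Q3, P95) quantile quadruple, optional
densely calcified inclusions that produce sub--1000 HU VNCa values, and
repeat exams of the same simulated patient that differ only in sampling
noise (plus an optional additive drift).

The marrow distribution family is a two-component normal mixture in HU —
the smallest family that can match four quantiles with skew.  Calibration
is a deterministic least-squares fit of the model quantiles to the targets.
Physiological marrow never samples below the -1000 HU cutoff (draws are
truncated there); sub-cutoff values come exclusively from calcified
structures, mirroring their origin in calcium-suppressed reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtr

from .grids import LabelMap, VncaVolume
from .histogram import LOWER_CUTOFF, compute_histogram, histogram_statistics
from .reference import AGE_BANDS, LEVELS, ExamRecord, ReferenceTable

__all__ = [
    "MarrowDistributionParams",
    "PhantomSpec",
    "GroundTruth",
    "GroupPlan",
    "SimulatedExam",
    "CalibrationError",
    "InfeasibleTargetError",
    "calibrate_distribution",
    "generate_phantom",
    "generate_cohort",
]


class InfeasibleTargetError(ValueError):
    """Target quantiles are not strictly increasing."""


class CalibrationError(RuntimeError):
    """The optimizer could not match the target quantiles to tolerance."""


@dataclass(frozen=True)
class MarrowDistributionParams:
    """Two-component normal mixture over HU values.

    ``weight`` is the mass of the first component; both standard deviations
    must be positive.
    """

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    weight: float
    family: str = "two-component-normal-mixture"

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("mixture weight must lie in [0, 1]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component standard deviations must be positive")

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.weight * ndtr((x - self.mu1) / self.sigma1) + (
            1.0 - self.weight
        ) * ndtr((x - self.mu2) / self.sigma2)

    def ppf_vec(self, probs) -> np.ndarray:
        """Quantile function by bisection (the mixture CDF has no closed inverse)."""
        probs = np.asarray(probs, dtype=float)
        lo = np.full(probs.shape, min(self.mu1 - 12 * self.sigma1, self.mu2 - 12 * self.sigma2))
        hi = np.full(probs.shape, max(self.mu1 + 12 * self.sigma1, self.mu2 + 12 * self.sigma2))
        for _ in range(60):  # (hi-lo)/2^60 is far below any HU tolerance
            mid = 0.5 * (lo + hi)
            below = self.cdf(mid) < probs
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)

    def ppf(self, q: float) -> float:
        return float(self.ppf_vec(np.array([q]))[0])

    def ppf_truncated(self, probs, lower: float = LOWER_CUTOFF) -> np.ndarray:
        """Quantiles of the mixture conditioned on X >= ``lower``.

        This is the distribution the pipeline actually measures: values
        below the cutoff are excluded from the histogram mass, and
        physiological marrow is sampled truncated at the same floor.
        """
        probs = np.asarray(probs, dtype=float)
        base = float(self.cdf(lower))
        return self.ppf_vec(base + probs * (1.0 - base))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pick = rng.random(n) < self.weight
        out = np.where(
            pick,
            rng.normal(self.mu1, self.sigma1, n),
            rng.normal(self.mu2, self.sigma2, n),
        )
        return out

    def rvs_truncated(
        self, n: int, rng: np.random.Generator, lower: float = LOWER_CUTOFF
    ) -> np.ndarray:
        """Draw n values, resampling any below ``lower`` (physiological marrow)."""
        out = self.rvs(n, rng)
        bad = out < lower
        while bad.any():
            out[bad] = self.rvs(int(bad.sum()), rng)
            bad = out < lower
        return out


_CALIBRATION_PROBS = np.array([0.25, 0.50, 0.75, 0.95])
_CALIBRATION_TOL_HU = 2.0  # max quantile residual accepted; half a bin is 2.5


def _params_from_theta(theta: np.ndarray) -> MarrowDistributionParams:
    mu1, log_s1, mu2, log_s2, logit_w = theta
    return MarrowDistributionParams(
        mu1=float(mu1),
        sigma1=float(np.exp(log_s1)),
        mu2=float(mu2),
        sigma2=float(np.exp(log_s2)),
        weight=float(1.0 / (1.0 + np.exp(-logit_w))),
    )


def calibrate_distribution(
    target: Sequence[float] | Mapping[str, float],
    family: str = "two-component-normal-mixture",
) -> MarrowDistributionParams:
    """Fit mixture parameters whose quantiles match a reference summary.

    ``target`` is (q1, median, q3, p95) in HU, or a mapping with those
    keys; the quadruple must be strictly increasing.  The fit minimizes the
    squared quantile residuals (model quantile minus target, in HU) with a
    weak regularizer that keeps the under-determined five-parameter family
    at a reproducible solution; starting values are derived from the target
    itself, so the calibration is deterministic.  A fit whose largest
    quantile residual exceeds 2 HU is rejected with the achieved residuals.
    """
    if family != "two-component-normal-mixture":
        raise ValueError(f"unknown distribution family {family!r}")
    if isinstance(target, Mapping):
        quad = (target["q1"], target["median"], target["q3"], target["p95"])
    else:
        quad = tuple(float(v) for v in target)
    if len(quad) != 4:
        raise ValueError("target must supply (q1, median, q3, p95)")
    q1, med, q3, p95 = quad
    if not (q1 < med < q3 < p95):
        raise InfeasibleTargetError(
            f"target quantiles must be strictly increasing, got q1={q1}, "
            f"median={med}, q3={q3}, p95={p95}"
        )
    targets = np.array(quad)
    iqr = q3 - q1
    s0 = iqr / 1.349  # normal-matched scale
    x0 = np.array(
        [med, np.log(s0), q1 - 0.75 * iqr, np.log(s0), np.log(0.75 / 0.25)]
    )

    def residuals(truncated: bool):
        def fun(theta: np.ndarray) -> np.ndarray:
            params = _params_from_theta(theta)
            model_q = (
                params.ppf_truncated(_CALIBRATION_PROBS)
                if truncated
                else params.ppf_vec(_CALIBRATION_PROBS)
            )
            reg = 0.05 * (theta - x0)[[1, 3, 4]]  # pin scales and weight softly
            return np.concatenate([model_q - targets, reg])

        return fun

    # stage 1 fits the plain mixture quantiles (smooth, converges from the
    # moment-based start); stage 2 refines against the cutoff-truncated
    # quantiles, which are what the measured histograms actually realize
    warm = optimize.least_squares(residuals(False), x0, method="trf", xtol=1e-10, ftol=1e-10)
    fit = optimize.least_squares(residuals(True), warm.x, method="trf", xtol=1e-10, ftol=1e-10)
    params = _params_from_theta(fit.x)
    resid = params.ppf_truncated(_CALIBRATION_PROBS) - targets
    if np.max(np.abs(resid)) > _CALIBRATION_TOL_HU:
        raise CalibrationError(
            f"calibration residuals {np.round(resid, 3).tolist()} HU exceed "
            f"{_CALIBRATION_TOL_HU} HU for target {quad}"
        )
    return params


@dataclass
class PhantomSpec:
    """Geometry and attenuation plan of one simulated exam.

    Vertebral bodies are axis-aligned boxes of ``body_size_mm`` stacked
    along the inferior->superior (third) axis with ``gap_mm`` between them;
    each body consists of a cortical shell of ``shell_mm`` around a marrow
    interior.  Every body axis must exceed 2 x (shell + 3 mm) so a
    non-empty marrow VOI survives the pipeline's margin erosion.

    The grid defaults to 1 mm isotropic voxels; ``anisotropic_preset``
    returns the 2 mm slice / 1 mm increment through-plane grid of the
    emulated reconstructions.
    """

    n_vertebrae: int = 17
    body_size_mm: tuple[float, float, float] = (30.0, 30.0, 20.0)
    gap_mm: float = 4.0
    shell_mm: float = 1.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    marrow: dict[str, MarrowDistributionParams] = field(default_factory=dict)
    n_islands: int = 0
    island_hu: float = -1500.0
    cortical_vnca_hu: float = -1200.0
    cortical_hu: float | None = 1200.0
    lesion_vertebrae: tuple[int, ...] = ()
    lesion_shift_hu: float = 0.0
    padding_mm: float = 3.0
    seed: int = 0

    MIN_CLEARANCE_MM = 3.0  # the pipeline's margin erosion

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("need at least one vertebra")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.gap_mm < 0 or self.shell_mm < 0 or self.padding_mm < 0:
            raise ValueError("gap, shell and padding must be >= 0")
        need = 2 * (self.shell_mm + self.MIN_CLEARANCE_MM)
        if any(s <= need for s in self.body_size_mm):
            raise ValueError(
                f"every body axis must exceed {need} mm "
                f"(2 x (shell {self.shell_mm} mm + {self.MIN_CLEARANCE_MM} mm margin)) "
                f"so the marrow VOI survives erosion; got {self.body_size_mm}"
            )
        if self.island_hu >= LOWER_CUTOFF:
            raise ValueError("calcified-island VNCa value must be below -1000 HU")
        bad = [i for i in self.lesion_vertebrae if not 1 <= i <= self.n_vertebrae]
        if bad:
            raise ValueError(f"lesion vertebra indices out of range: {bad}")

    def with_anisotropic_preset(self) -> "PhantomSpec":
        """2 mm slices reconstructed at a 1 mm increment through-plane."""
        return replace(self, spacing=(self.spacing[0], self.spacing[1], 1.0))

    def levels(self) -> tuple[str, ...]:
        return tuple(self.marrow.keys())


@dataclass
class GroundTruth:
    """Generator-side truth for one phantom exam."""

    marrow_masks: dict[int, np.ndarray]  # label -> boolean grid of marrow interior
    marrow_values: dict[str, np.ndarray]  # level -> draws over the union marrow, scan order
    island_indices: np.ndarray  # (k, 3) voxel coordinates of calcified inclusions
    lesion_vertebrae: tuple[int, ...]
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    def marrow_union(self) -> np.ndarray:
        out = None
        for m in self.marrow_masks.values():
            out = m.copy() if out is None else (out | m)
        return out


def _mm_to_vox(mm: float, spacing: float) -> int:
    return max(int(round(mm / spacing)), 0)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[LabelMap, dict[str, VncaVolume], GroundTruth]:
    """Rasterize one phantom exam.

    Returns the vertebra label map (labels 1..n from the bottom), one VNCa
    volume per suppression level in ``spec.marrow``, and the ground truth.
    Identical specs (including seed) produce bit-identical volumes.
    """
    if not spec.marrow:
        raise ValueError("spec.marrow must provide at least one suppression level")
    sx, sy, sz = spec.spacing
    bx = _mm_to_vox(spec.body_size_mm[0], sx)
    by = _mm_to_vox(spec.body_size_mm[1], sy)
    bz = _mm_to_vox(spec.body_size_mm[2], sz)
    gap = _mm_to_vox(spec.gap_mm, sz)
    padx, pady, padz = (_mm_to_vox(spec.padding_mm, s) for s in spec.spacing)
    shell_vox = tuple(max(int(np.ceil(spec.shell_mm / s)), 0) for s in spec.spacing)
    if min(bx, by, bz) < 1:
        raise ValueError("voxel spacing too coarse for the requested body size")
    inner = (bx - 2 * shell_vox[0], by - 2 * shell_vox[1], bz - 2 * shell_vox[2])
    if min(inner) < 1:
        raise ValueError("cortical shell leaves no marrow interior at this spacing")

    nx = bx + 2 * padx
    ny = by + 2 * pady
    nz = spec.n_vertebrae * bz + (spec.n_vertebrae - 1) * gap + 2 * padz
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    marrow_masks: dict[int, np.ndarray] = {}
    for i in range(spec.n_vertebrae):
        z0 = padz + i * (bz + gap)
        lab = i + 1  # label 1 is the most inferior body
        labels[padx : padx + bx, pady : pady + by, z0 : z0 + bz] = lab
        m = np.zeros_like(labels, dtype=bool)
        m[
            padx + shell_vox[0] : padx + bx - shell_vox[0],
            pady + shell_vox[1] : pady + by - shell_vox[1],
            z0 + shell_vox[2] : z0 + bz - shell_vox[2],
        ] = True
        marrow_masks[lab] = m

    marrow_union = np.zeros_like(labels, dtype=bool)
    for m in marrow_masks.values():
        marrow_union |= m
    shell = (labels > 0) & ~marrow_union
    n_marrow = int(marrow_union.sum())

    lesion_mask_flat = None
    if spec.lesion_vertebrae and spec.lesion_shift_hu != 0.0:
        lesion_union = np.zeros_like(marrow_union)
        for lab in spec.lesion_vertebrae:
            lesion_union |= marrow_masks[lab]
        lesion_mask_flat = lesion_union[marrow_union]

    rng = np.random.default_rng(spec.seed)
    # islands: placed once, shared across suppression levels (they are the
    # same physical calcification seen through each reconstruction)
    island_idx = np.empty((0, 3), dtype=int)
    if spec.n_islands > 0:
        coords = np.argwhere(marrow_union)
        pick = rng.choice(coords.shape[0], size=min(spec.n_islands, coords.shape[0]), replace=False)
        island_idx = coords[pick]

    volumes: dict[str, VncaVolume] = {}
    values_per_level: dict[str, np.ndarray] = {}
    summaries: dict[str, dict[str, float]] = {}
    for level, params in spec.marrow.items():
        draws = params.rvs_truncated(n_marrow, rng)
        if lesion_mask_flat is not None:
            draws = draws + spec.lesion_shift_hu * lesion_mask_flat
        grid = np.zeros(labels.shape, dtype=float)
        grid[shell] = spec.cortical_vnca_hu
        grid[marrow_union] = draws
        if island_idx.size:
            grid[island_idx[:, 0], island_idx[:, 1], island_idx[:, 2]] = spec.island_hu
        volumes[level] = VncaVolume(grid, spec.spacing, level=level)
        values_per_level[level] = draws
        summaries[level] = histogram_statistics(compute_histogram(draws)).as_dict()

    label_map = LabelMap(labels, spec.spacing, superior_axis=2, superior_sign=1)
    truth = GroundTruth(
        marrow_masks=marrow_masks,
        marrow_values=values_per_level,
        island_indices=island_idx,
        lesion_vertebrae=spec.lesion_vertebrae,
        summaries=summaries,
    )
    return label_map, volumes, truth


@dataclass(frozen=True)
class GroupPlan:
    """One stratum of a simulated cohort."""

    sex: str
    age_band: str
    n_patients: int
    exams_per_patient: int


@dataclass
class SimulatedExam:
    """An exam record plus (optionally) its rendered volumes."""

    record: ExamRecord
    label_map: LabelMap | None = None
    volumes: dict[str, VncaVolume] | None = None
    truth: GroundTruth | None = None


_AGE_RANGES = {"21-40": (21, 40), "41-60": (41, 60), "61-80": (61, 80), ">80": (81, 95)}
_EXAM_INTERVAL_DAYS = 185  # typical interval between consecutive exams


def _calibrated_levels(
    reference: ReferenceTable, sex: str, band: str, levels: Sequence[str]
) -> dict[str, MarrowDistributionParams]:
    out = {}
    for level in levels:
        e = reference.get(sex, band, level)
        out[level] = calibrate_distribution((e.q1, e.median, e.q3, e.p95))
    return out


def generate_cohort(
    plan: Sequence[GroupPlan],
    base_spec: PhantomSpec,
    reference: ReferenceTable,
    seed: int,
    levels: Sequence[str] = LEVELS,
    render_volumes: bool = True,
    n_voxels: int | None = None,
    drift_sd_hu: float = 0.0,
) -> list[SimulatedExam]:
    """Simulate a cohort of repeat exams calibrated to a reference table.

    Each stratum's marrow distributions are calibrated once from the
    reference; a patient's repeat exams reuse those parameters with fresh
    sampling noise (plus an optional N(0, ``drift_sd_hu``) additive shift
    per follow-up exam, emulating slow physiological change).  Ages are
    drawn uniformly within the band and exam dates are spaced by a typical
    follow-up interval.

    With ``render_volumes`` the full label map and VNCa grids are
    rasterized per exam; without it, marrow values are sampled directly
    (``n_voxels`` per exam, default: the spec geometry's marrow voxel
    count) and only the histograms are built — statistically identical and
    much cheaper for cohort-scale statistics.
    """
    if not plan:
        raise ValueError("cohort plan is empty")
    for g in plan:
        if g.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {g.age_band!r}")
        reference.get(g.sex, g.age_band, levels[0])  # raises KeyError if absent
    rng = np.random.default_rng(seed)
    exams: list[SimulatedExam] = []
    params_cache: dict[tuple[str, str], dict[str, MarrowDistributionParams]] = {}
    if n_voxels is None:
        inner = [
            _mm_to_vox(b, s) - 2 * max(int(np.ceil(base_spec.shell_mm / s)), 0)
            for b, s in zip(base_spec.body_size_mm, base_spec.spacing)
        ]
        n_voxels = int(np.prod(inner)) * base_spec.n_vertebrae
    for g in plan:
        key = (g.sex, g.age_band)
        if key not in params_cache:
            params_cache[key] = _calibrated_levels(reference, g.sex, g.age_band, levels)
        group_params = params_cache[key]
        lo, hi = _AGE_RANGES[g.age_band]
        for p in range(g.n_patients):
            patient_id = f"{g.sex[0].upper()}{g.age_band.replace('>', 'gt')}-{p:03d}"
            age = int(rng.integers(lo, hi + 1))
            for e in range(g.exams_per_patient):
                drift = float(rng.normal(0.0, drift_sd_hu)) if (drift_sd_hu > 0 and e > 0) else 0.0
                params = {
                    lvl: replace(pp, mu1=pp.mu1 + drift, mu2=pp.mu2 + drift)
                    for lvl, pp in group_params.items()
                }
                exam_date = f"day{e * _EXAM_INTERVAL_DAYS:05d}"
                exam_seed = int(rng.integers(0, 2**31 - 1))
                if render_volumes:
                    spec = replace(base_spec, marrow=params, seed=exam_seed)
                    label_map, volumes, truth = generate_phantom(spec)
                    hists = {
                        lvl: compute_histogram(
                            truth.marrow_values[lvl],
                            volume_mm3=float(truth.marrow_union().sum())
                            * label_map.voxel_volume_mm3,
                        )
                        for lvl in params
                    }
                    exams.append(
                        SimulatedExam(
                            record=ExamRecord(
                                patient_id=patient_id,
                                sex=g.sex,
                                age=age,
                                exam_date=exam_date,
                                histograms=hists,
                                n_vertebrae_retained=min(base_spec.n_vertebrae, 17),
                                n_vertebrae_segmented=base_spec.n_vertebrae,
                            ),
                            label_map=label_map,
                            volumes=volumes,
                            truth=truth,
                        )
                    )
                else:
                    exam_rng = np.random.default_rng(exam_seed)
                    voxel_vol = float(np.prod(base_spec.spacing))
                    hists = {
                        lvl: compute_histogram(
                            pp.rvs_truncated(n_voxels, exam_rng),
                            volume_mm3=n_voxels * voxel_vol,
                        )
                        for lvl, pp in params.items()
                    }
                    exams.append(
                        SimulatedExam(
                            record=ExamRecord(
                                patient_id=patient_id,
                                sex=g.sex,
                                age=age,
                                exam_date=exam_date,
                                histograms=hists,
                                n_vertebrae_retained=min(base_spec.n_vertebrae, 17),
                                n_vertebrae_segmented=base_spec.n_vertebrae,
                            )
                        )
                    )
    return exams
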