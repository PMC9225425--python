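"""Digital phantom: synthetic multi-echo, DCE and histology data with known truth.

The phantom emulates a small-animal contrast-enhanced MRI study: each
simulated animal is scanned at three visits (Baseline, Day1, Day7) and each
scan session yields a multi-echo T2-weighted stack and an 11-frame dynamic
contrast-enhanced (DCE) series over a labelled ROI volume that includes a
muscle reference compartment.  Group structure is a 2x2x3 design
(Injury x Sex x Day) with a per-animal lognormal random effect on tissue
enhancement and a per-session injection-efficiency multiplier that hits
every tissue including muscle (and therefore cancels under muscle
normalization).  Magnitude images carry Rician noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ROI_NAMES",
    "BRAIN_ROIS",
    "TissueSpec",
    "AcquisitionSpec",
    "DesignSpec",
    "RoiMaskSet",
    "MultiEchoStack",
    "DceSeries",
    "PlacementError",
    "default_tissues",
    "make_label_volume",
    "simulate_multi_echo",
    "simulate_dce",
    "simulate_cohort",
    "simulate_histology_image",
    "expected_group_hedges_g",
    "Cohort",
    "Session",
]

#: Canonical ROI names.  ``meninges`` is the thin dura/arachnoid shell whose
#: post-injury contrast enhancement is the primary outcome; ``muscle`` is the
#: extracranial normalization reference; the rest are brain parenchyma ROIs
#: including the visual-pathway structures (optic tract, lateral geniculate
#: nucleus, superior colliculus).
ROI_NAMES: Tuple[str, ...] = (
    "meninges",
    "cortex",
    "muscle",
    "brainstem",
    "cerebellum",
    "corpus_callosum",
    "dorsal_hippocampus",
    "optic_tract",
    "lgn",
    "superior_colliculus",
)

#: ROIs subject to the per-animal biological random effect (everything inside
#: the head; the muscle reference only sees injection-level variation).
BRAIN_ROIS: Tuple[str, ...] = tuple(r for r in ROI_NAMES if r != "muscle")

DAYS: Tuple[str, str, str] = ("Baseline", "Day1", "Day7")
SEXES: Tuple[str, str] = ("M", "F")
INJURY_GROUPS: Tuple[str, str] = ("CHIMERA", "Sham")


class PlacementError(ValueError):
    """Raised when the matrix is too small to place a tissue compartment."""


@dataclass(frozen=True)
class TissueSpec:
    """Ground-truth MR properties of one tissue compartment.

    Parameters
    ----------
    label : str
        ROI name (one of :data:`ROI_NAMES`).
    s0 : float
        Proton-density signal amplitude (arbitrary units, > 0).
    t2_ms : float
        Transverse relaxation time in milliseconds (> 0).
    enhancement_amp : float
        Peak relative DCE enhancement (dimensionless, >= 0).
    uptake_rate : float
        Exponential uptake rate constant in 1/min (> 0).
    """

    label: str
    s0: float
    t2_ms: float
    enhancement_amp: float = 0.0
    uptake_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError(f"s0 must be > 0 for tissue {self.label!r}")
        if self.t2_ms <= 0:
            raise ValueError(f"t2_ms must be > 0 for tissue {self.label!r}")
        if self.enhancement_amp < 0:
            raise ValueError(f"enhancement_amp must be >= 0 for {self.label!r}")
        if self.uptake_rate <= 0:
            raise ValueError(f"uptake_rate must be > 0 for {self.label!r}")


def default_tissues() -> List[TissueSpec]:
    """Default tissue table.

    T2 values sit in the physiologic 30-80 ms range for mouse brain at 7 T
    (muscle shorter); enhancement amplitudes make the meninges and muscle the
    strongly-enhancing compartments while intact blood-brain-barrier
    parenchyma enhances weakly, with the optic tract intermediate.
    """
    return [
        TissueSpec("meninges", s0=90.0, t2_ms=60.0, enhancement_amp=0.50, uptake_rate=1.2),
        TissueSpec("cortex", s0=100.0, t2_ms=45.0, enhancement_amp=0.10, uptake_rate=1.0),
        TissueSpec("muscle", s0=80.0, t2_ms=30.0, enhancement_amp=0.80, uptake_rate=0.9),
        TissueSpec("brainstem", s0=95.0, t2_ms=40.0, enhancement_amp=0.08, uptake_rate=1.0),
        TissueSpec("cerebellum", s0=98.0, t2_ms=48.0, enhancement_amp=0.09, uptake_rate=1.0),
        TissueSpec("corpus_callosum", s0=85.0, t2_ms=38.0, enhancement_amp=0.06, uptake_rate=1.0),
        TissueSpec("dorsal_hippocampus", s0=100.0, t2_ms=50.0, enhancement_amp=0.10, uptake_rate=1.0),
        TissueSpec("optic_tract", s0=88.0, t2_ms=42.0, enhancement_amp=0.30, uptake_rate=1.1),
        TissueSpec("lgn", s0=96.0, t2_ms=46.0, enhancement_amp=0.12, uptake_rate=1.0),
        TissueSpec("superior_colliculus", s0=97.0, t2_ms=47.0, enhancement_amp=0.12, uptake_rate=1.0),
    ]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and timing.

    Defaults follow a multi-echo RARE T2 protocol with TE = 10..110 ms and an
    11-frame, 11-minute FLASH DCE series with contrast injection commencing
    2 minutes into the acquisition; voxels are 150 x 150 um in-plane with
    1000 um (or 500 um) slices.
    """

    echo_times_ms: Tuple[float, ...] = (10.0, 30.0, 50.0, 70.0, 90.0, 110.0)
    n_frames: int = 11
    frame_duration_min: float = 1.0
    injection_start_min: float = 2.0
    voxel_size_um: Tuple[float, float, float] = (150.0, 150.0, 1000.0)
    matrix: Tuple[int, int, int] = (92, 92, 25)

    def __post_init__(self) -> None:
        if len(self.echo_times_ms) < 3:
            raise ValueError("need at least 3 echo times")
        if any(b <= a for a, b in zip(self.echo_times_ms, self.echo_times_ms[1:])):
            raise ValueError("echo_times_ms must be strictly increasing")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_duration_min <= 0:
            raise ValueError("frame_duration_min must be > 0")
        if not (0 <= self.injection_start_min < self.duration_min):
            raise ValueError("injection_start_min must fall inside the acquisition")

    @property
    def duration_min(self) -> float:
        return self.n_frames * self.frame_duration_min

    @property
    def frame_midpoints_min(self) -> np.ndarray:
        """Midpoint time of each frame; frame i (0-based) spans [i*d, (i+1)*d]."""
        d = self.frame_duration_min
        return (np.arange(self.n_frames) + 0.5) * d

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_um[0] / 1000.0,
                       self.voxel_size_um[1] / 1000.0,
                       self.voxel_size_um[2] / 1000.0, 1.0])
        return aff


@dataclass(frozen=True)
class DesignSpec:
    """Cohort design: a 2x2 between-animal layout (Injury x Sex) scanned on
    three visits, with variance components.

    ``injury_effects`` maps ``(roi, day)`` to a multiplicative shift applied
    to injured animals' enhancement amplitude (e.g. ``{("meninges", "Day1"):
    2.0}`` doubles meningeal enhancement the day of injury); ``sex_effects``
    is the analogue for males.  ``between_animal_sd`` is the SD of the
    per-animal random intercept on log enhancement (brain tissues);
    ``injection_sd`` is the SD of a per-session lognormal injection-efficiency
    multiplier applied to every tissue including muscle.  ``noise_sigma`` is
    the Rician noise scale in signal units (default ~ SNR 30 in brain).
    """

    n_per_cell: int = 10
    days: Tuple[str, ...] = DAYS
    injury_effects: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: {("meninges", "Day1"): 2.0}
    )
    sex_effects: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    between_animal_sd: float = 0.4
    injection_sd: float = 0.2
    noise_sigma: float = 3.3
    seed: int = 0
    regimen: str = "1x"

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if tuple(self.days) != DAYS:
            raise ValueError(f"days must be exactly {DAYS}")
        if self.between_animal_sd < 0 or self.injection_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class RoiMaskSet:
    """Integer label volume with a name -> label mapping (0 = background)."""

    labels: np.ndarray
    label_map: Dict[str, int]

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_map[name]

    def counts(self) -> Dict[str, int]:
        return {name: int((self.labels == lab).sum()) for name, lab in self.label_map.items()}

    @property
    def names(self) -> List[str]:
        return list(self.label_map)


@dataclass
class MultiEchoStack:
    """4D (x, y, z, echo) magnitude stack with its echo times in ms."""

    data: np.ndarray
    echo_times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if self.data.shape[-1] != self.echo_times_ms.size:
            raise ValueError("last axis must match number of echoes")


@dataclass
class DceSeries:
    """4D (x, y, z, frame) dynamic series with frame timing metadata.

    ``frame_times_min`` are the frame midpoints; ``injection_start_min`` is
    the time contrast uptake begins.
    """

    data: np.ndarray
    frame_times_min: np.ndarray
    frame_duration_min: float
    injection_start_min: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_min = np.asarray(self.frame_times_min, dtype=float)
        if self.data.shape[-1] != self.frame_times_min.size:
            raise ValueError("last axis must match number of frames")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_label_volume(acq: AcquisitionSpec, tissues: Sequence[TissueSpec]) -> RoiMaskSet:
    """Build the phantom label volume.

    Layout (x = left-right, y = ventral-dorsal, z = slices): bilateral muscle
    slabs at the two x faces, a skull gap, then the head: a 1-voxel-thick
    meninges shell at the dorsal surface of the brain, a cortex band directly
    beneath it, and the remaining deep tissue partitioned into blocks along x
    for the other ROIs.  Raises :class:`PlacementError` naming the first
    tissue that does not fit.
    """
    names = [t.label for t in tissues]
    if len(set(names)) != len(names):
        raise ValueError("tissue labels must be unique")
    nx, ny, nz = acq.matrix
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    label_map = {name: i + 1 for i, name in enumerate(names)}

    def region_or_fail(sl, name):
        sub = labels[sl]
        if sub.size == 0:
            raise PlacementError(f"matrix {acq.matrix} too small to place {name!r}")
        return sl

    if "muscle" in label_map:
        labels[:2, :, :] = label_map["muscle"]
        labels[max(nx - 2, 2):, :, :] = label_map["muscle"]

    # head occupies x in [4, nx-4), y in [2, ny-2); 2-voxel skull/background gap
    x0, x1 = 4, nx - 4
    y0, y1 = 2, ny - 2
    if "meninges" in label_map:
        sl = region_or_fail(np.s_[x0:x1, y0:y0 + 1, :], "meninges")
        labels[sl] = label_map["meninges"]
    cortex_thk = max(2, ny // 8)
    if "cortex" in label_map:
        sl = region_or_fail(np.s_[x0:x1, y0 + 1:y0 + 1 + cortex_thk, :], "cortex")
        labels[sl] = label_map["cortex"]

    deep = [t.label for t in tissues if t.label not in ("meninges", "cortex", "muscle")]
    if deep:
        yd0 = y0 + 1 + cortex_thk
        if yd0 >= y1:
            raise PlacementError(f"matrix {acq.matrix} too small to place {deep[0]!r}")
        width = (x1 - x0) // len(deep)
        if width < 1:
            raise PlacementError(f"matrix {acq.matrix} too small to place {deep[0]!r}")
        for i, name in enumerate(deep):
            xa = x0 + i * width
            xb = x1 if i == len(deep) - 1 else xa + width
            sl = region_or_fail(np.s_[xa:xb, yd0:y1, :], name)
            labels[sl] = label_map[name]

    counts = {name: int((labels == lab).sum()) for name, lab in label_map.items()}
    for name, c in counts.items():
        if c == 0:
            raise PlacementError(f"matrix {acq.matrix} too small to place {name!r}")
    return RoiMaskSet(labels=labels, label_map=label_map)


# ---------------------------------------------------------------------------
# Signal models
# ---------------------------------------------------------------------------

def rician(mu: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI (Rician) sample: sqrt((mu+e1)^2 + e2^2), e ~ N(0, sigma^2).

    With ``sigma == 0`` this is exactly ``mu`` (no RNG draw), so noiseless
    simulations are closed-form reproducible.
    """
    mu = np.asarray(mu, dtype=float)
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return mu.copy()
    e1 = rng.normal(0.0, sigma, size=mu.shape)
    e2 = rng.normal(0.0, sigma, size=mu.shape)
    return np.hypot(mu + e1, e2)


def _tissue_maps(labels: RoiMaskSet, tissues: Sequence[TissueSpec]):
    """Per-voxel (s0, t2) lookup arrays; background has s0=0."""
    max_lab = max(labels.label_map.values(), default=0)
    s0_lut = np.zeros(max_lab + 1)
    t2_lut = np.full(max_lab + 1, np.inf)
    by_name = {t.label: t for t in tissues}
    for name, lab in labels.label_map.items():
        t = by_name[name]
        s0_lut[lab] = t.s0
        t2_lut[lab] = t.t2_ms
    return s0_lut[labels.labels], t2_lut[labels.labels]


def simulate_multi_echo(
    labels: RoiMaskSet,
    tissues: Sequence[TissueSpec],
    acq: AcquisitionSpec,
    noise_sigma: float,
    seed: int,
) -> MultiEchoStack:
    """Simulate a multi-echo T2-weighted stack.

    Noiseless signal per voxel is ``S(TE) = S0 * exp(-TE / T2)``; the returned
    magnitude is Rician with scale ``noise_sigma``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    s0_map, t2_map = _tissue_maps(labels, tissues)
    tes = np.asarray(acq.echo_times_ms, dtype=float)
    mu = s0_map[..., None] * np.exp(-tes / t2_map[..., None])
    rng = np.random.default_rng(seed)
    return MultiEchoStack(data=rician(mu, noise_sigma, rng), echo_times_ms=tes)


def uptake_curve(t_min: np.ndarray, amp: float, rate: float, t0: float) -> np.ndarray:
    """Relative enhancement E(t): 0 before injection at t0, then a saturating
    mono-exponential ``amp * (1 - exp(-rate * (t - t0)))``."""
    t = np.asarray(t_min, dtype=float)
    e = np.where(t < t0, 0.0, amp * -np.expm1(-rate * np.clip(t - t0, 0.0, None)))
    return e


def simulate_dce(
    labels: RoiMaskSet,
    tissues: Sequence[TissueSpec],
    acq: AcquisitionSpec,
    amp_scale: Optional[Mapping[str, float]] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DceSeries:
    """Simulate a DCE frame series.

    ``amp_scale`` maps tissue name to a multiplier on its enhancement
    amplitude (per-animal/session effects).  The baseline (pre-contrast)
    FLASH signal of a tissue is taken as its proton-density amplitude ``s0``;
    frame signal is ``baseline * (1 + E(t_mid))`` plus Rician noise, where t
    is evaluated at frame midpoints.  The muscle compartment must be present
    so downstream normalization is exercised.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if "muscle" not in labels.label_map:
        raise ValueError("DCE simulation requires a muscle compartment")
    mids = acq.frame_midpoints_min
    if acq.injection_start_min >= mids[-1]:
        raise ValueError("frame times must cover the injection start")
    amp_scale = dict(amp_scale or {})
    by_name = {t.label: t for t in tissues}

    base = np.zeros(labels.labels.shape)
    series = np.zeros(labels.labels.shape + (acq.n_frames,))
    for name, lab in labels.label_map.items():
        t = by_name[name]
        m = labels.labels == lab
        amp = t.enhancement_amp * amp_scale.get(name, 1.0)
        e = uptake_curve(mids, amp, t.uptake_rate, acq.injection_start_min)
        base[m] = t.s0
        series[m, :] = t.s0 * (1.0 + e)
    rng = np.random.default_rng(seed)
    data = rician(series, noise_sigma, rng)
    return DceSeries(
        data=data,
        frame_times_min=mids,
        frame_duration_min=acq.frame_duration_min,
        injection_start_min=acq.injection_start_min,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """One animal-visit: its images, label volume and identifying factors."""

    animal_id: str
    sex: str
    injury: str
    regimen: str
    day: str
    labels: RoiMaskSet
    multi_echo: Optional[MultiEchoStack]
    dce: DceSeries


class Cohort:
    """Lazily-generated cohort of animal-visit image sets with ground truth.

    ``animals`` is the roster (one row per animal); ``truth`` records every
    drawn parameter, one row per (animal, day, roi).  ``iter_sessions()``
    regenerates each session's images deterministically from the design seed,
    so the full cohort never needs to be held in memory.
    """

    def __init__(self, design: DesignSpec, acq: AcquisitionSpec,
                 tissues: Optional[Sequence[TissueSpec]] = None):
        self.design = design
        self.acq = acq
        self.tissues = list(tissues) if tissues is not None else default_tissues()
        self.labels = make_label_volume(acq, self.tissues)
        self._build_truth()

    def _build_truth(self) -> None:
        d = self.design
        rng = np.random.default_rng(np.random.SeedSequence([d.seed, 0]))
        animals = []
        idx = 0
        for injury, sex in itertools.product(INJURY_GROUPS, SEXES):
            for _ in range(d.n_per_cell):
                animals.append(
                    dict(animal_id=f"a{idx:03d}", injury=injury, sex=sex,
                         regimen=d.regimen,
                         animal_mult=float(np.exp(rng.normal(0.0, d.between_animal_sd))))
                )
                idx += 1
        self.animals = pd.DataFrame(animals)

        from .dce import trapezoid_weights  # local import to avoid cycle at import time

        mids = self.acq.frame_midpoints_min
        window = (self.acq.injection_start_min, self.acq.duration_min)
        w = trapezoid_weights(mids, window)
        by_name = {t.label: t for t in self.tissues}

        rows = []
        for a in animals:
            for j, day in enumerate(d.days):
                injection_mult = float(np.exp(rng.normal(0.0, d.injection_sd)))
                for name in self.labels.label_map:
                    t = by_name[name]
                    mult = injection_mult
                    if name != "muscle":
                        mult *= a["animal_mult"]
                    if a["injury"] == "CHIMERA":
                        mult *= d.injury_effects.get((name, day), 1.0)
                    if a["sex"] == "M":
                        mult *= d.sex_effects.get((name, day), 1.0)
                    amp_true = t.enhancement_amp * mult
                    e = uptake_curve(mids, amp_true, t.uptake_rate,
                                     self.acq.injection_start_min)
                    rows.append(
                        dict(animal_id=a["animal_id"], sex=a["sex"],
                             injury=a["injury"], regimen=a["regimen"], day=day,
                             roi=name, amp_true=amp_true,
                             uptake_rate=t.uptake_rate, t2_ms=t.t2_ms, s0=t.s0,
                             animal_mult=a["animal_mult"],
                             injection_mult=injection_mult,
                             auc_true=float(w @ e))
                    )
        truth = pd.DataFrame(rows)
        muscle = truth[truth.roi == "muscle"].set_index(["animal_id", "day"])["auc_true"]
        denom = truth.set_index(["animal_id", "day"]).index.map(muscle)
        with np.errstate(divide="ignore", invalid="ignore"):
            truth["auc_norm_true"] = np.where(
                np.asarray(denom) > 0, truth["auc_true"] / np.asarray(denom), np.nan)
        self.truth = truth

    def _session_amp_scale(self, animal_id: str, day: str) -> Dict[str, float]:
        t = self.truth
        sel = t[(t.animal_id == animal_id) & (t.day == day)]
        by_name = {x.label: x for x in self.tissues}
        return {
            r.roi: (r.amp_true / by_name[r.roi].enhancement_amp
                    if by_name[r.roi].enhancement_amp > 0 else 1.0)
            for r in sel.itertuples()
        }

    def iter_sessions(self, multi_echo: bool = True) -> Iterator[Session]:
        """Yield sessions in roster order; set ``multi_echo=False`` to skip
        generating the T2-weighted stacks (DCE-only analyses)."""
        d = self.design
        for ai, a in enumerate(self.animals.itertuples()):
            for di, day in enumerate(d.days):
                seed_me = np.random.SeedSequence([d.seed, 1, ai, di])
                seed_dce = np.random.SeedSequence([d.seed, 2, ai, di])
                me = None
                if multi_echo:
                    me = simulate_multi_echo(self.labels, self.tissues, self.acq,
                                             d.noise_sigma,
                                             seed=seed_me)  # type: ignore[arg-type]
                dce = simulate_dce(self.labels, self.tissues, self.acq,
                                   amp_scale=self._session_amp_scale(a.animal_id, day),
                                   noise_sigma=d.noise_sigma,
                                   seed=seed_dce)  # type: ignore[arg-type]
                yield Session(animal_id=a.animal_id, sex=a.sex, injury=a.injury,
                              regimen=a.regimen, day=day, labels=self.labels,
                              multi_echo=me, dce=dce)

    def __len__(self) -> int:
        return len(self.animals) * len(self.design.days)


def simulate_cohort(design: DesignSpec, acq: AcquisitionSpec,
                    tissues: Optional[Sequence[TissueSpec]] = None) -> Cohort:
    """Simulate the full 2x2x3 cohort; see :class:`Cohort`."""
    return Cohort(design, acq, tissues)


# ---------------------------------------------------------------------------
# Histology
# ---------------------------------------------------------------------------

def simulate_histology_image(stained_fraction: float, shape: Tuple[int, int],
                             seed: int) -> np.ndarray:
    """Binary stained/unstained image with an exact stained-pixel count.

    Exactly ``round(stained_fraction * rows * cols)`` pixels are stained,
    placed by thresholding a smoothed Gaussian random field so staining is
    spatially clumped like immunohistochemistry signal rather than salt-and-
    pepper noise.
    """
    if not (0.0 <= stained_fraction <= 1.0):
        raise ValueError("stained_fraction must lie in [0, 1]")
    rows, cols = shape
    n = rows * cols
    k = int(round(stained_fraction * n))
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(size=(rows, cols)),
                                    sigma=max(1.0, min(rows, cols) / 20.0))
    flat = field.ravel()
    img = np.zeros(n, dtype=bool)
    if k > 0:
        img[np.argpartition(flat, -k)[-k:]] = True
    return img.reshape(rows, cols)


# ---------------------------------------------------------------------------
# Analytic expectations
# ---------------------------------------------------------------------------

def expected_group_hedges_g(
    design: DesignSpec,
    acq: AcquisitionSpec,
    tissues: Optional[Sequence[TissueSpec]] = None,
    roi: str = "meninges",
    day: str = "Day1",
    n_baseline_frames: int = 2,
) -> float:
    """Analytic expectation of the injured-vs-sham Hedges' g on muscle-
    normalized AUC at one (roi, day), sexes pooled.

    Propagates (a) the lognormal per-animal amplitude multiplier and (b) the
    Rician measurement noise of ROI-mean enhancement through the midpoint-
    trapezoid AUC and the muscle ratio (delta method).  The session-level
    injection multiplier cancels exactly in the ratio and does not enter.
    """
    from .dce import trapezoid_weights

    tissues = list(tissues) if tissues is not None else default_tissues()
    by_name = {t.label: t for t in tissues}
    labels = make_label_volume(acq, tissues)
    counts = labels.counts()
    mids = acq.frame_midpoints_min
    w = trapezoid_weights(mids, (acq.injection_start_min, acq.duration_min))

    def auc_true(t: TissueSpec, amp_mult: float = 1.0) -> float:
        e = uptake_curve(mids, t.enhancement_amp * amp_mult, t.uptake_rate,
                         acq.injection_start_min)
        return float(w @ e)

    def noise_var_auc(t: TissueSpec, n_vox: int) -> float:
        # var of ROI-mean relative enhancement per frame ~ sigma^2/(V*S0^2),
        # baseline averaged over n_baseline_frames frames and shared across
        # the trapezoid sum; independent of the enhancement amplitude.
        s = design.noise_sigma
        v = (s ** 2) / (n_vox * t.s0 ** 2)
        return v * (float(w @ w) + float(w.sum()) ** 2 / n_baseline_frames)

    t_roi, t_mus = by_name[roi], by_name["muscle"]
    mult = design.injury_effects.get((roi, day), 1.0)
    tau2 = design.between_animal_sd ** 2
    e_m, var_m = np.exp(tau2 / 2.0), np.exp(tau2) * np.expm1(tau2)

    a_mus = auc_true(t_mus)
    s_roi = noise_var_auc(t_roi, counts[roi])
    s_mus = noise_var_auc(t_mus, counts["muscle"])

    def group_moments(amp_mult: float):
        # X = (a*m + eps_roi) / (a_mus + eps_mus), m lognormal; delta method.
        a = auc_true(t_roi, amp_mult)
        mean = a * e_m / a_mus
        var = ((a / a_mus) ** 2 * var_m
               + s_roi / a_mus ** 2
               + (a * e_m) ** 2 * s_mus / a_mus ** 4)
        return mean, var

    m1, v1 = group_moments(mult)
    m0, v0 = group_moments(1.0)
    n = 2 * design.n_per_cell  # per group, sexes pooled
    j = 1.0 - 3.0 / (4.0 * (2 * n - 2) - 1.0)
    return float(j * (m1 - m0) / np.sqrt((v1 + v0) / 2.0))
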