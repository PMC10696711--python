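"""Seeded synthetic neonatal lung-ultrasound (LUS) phantoms.

Clinical LUS frames for the six neonatal pathology classes (Normal, TTN,
PTX, RDS, CLD, CON) are restricted by ethics and data-sharing policy, so
this module renders the morphologies a sonographer reads — pleural line,
A-lines, separate/coalescent B-lines, consolidation, double lung point —
on a multiplicative speckle background, together with class-dependent
clinical covariates (gestational age, cumulative gestational age at time
of scan, days of life).

The default per-class specs follow the standard morphology-by-pathology
grid: e.g. TTN shows separate B-lines and the double lung point on a
normal pleura; RDS and CLD show a thick irregular pleura with coalescent
B-lines; CON shows a hypoechoic consolidation with a bright irregular
rim.  All randomness flows from an explicit integer seed, and
``(spec, seed)`` fully determines the rendered image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

CLASS_LABELS = ("Normal", "TTN", "PTX", "RDS", "CLD", "CON")
LUNG_REGIONS = ("R1", "R2", "R3", "L1", "L2", "L3")

#: canvas size before geometric normalization (rows, cols)
DEFAULT_CANVAS = (520, 420)


# ---------------------------------------------------------------------------
# Spec dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PleuraSpec:
    """Pleural-line morphology: a bright horizontal band near the top."""

    style: str = "normal"            # normal | thick | irregular
    depth_px: float = 64.0           # row of the band centre
    thickness_px: float = 4.0        # Gaussian sigma-ish vertical extent
    brightness: float = 170.0
    #: amplitude of the slow depth undulation used for ``irregular`` style
    irregularity_px: float = 0.0

    def validate(self) -> None:
        if self.style not in ("normal", "thick", "irregular"):
            raise ValueError(f"unknown pleura style {self.style!r}")
        if self.thickness_px <= 0 or self.depth_px <= 0:
            raise ValueError("pleura geometry must be positive")


@dataclass(frozen=True)
class BlineSpec:
    """Vertical bright bands from the pleural line to the image bottom."""

    mode: str = "none"               # none | separate | coalescent | mixed
    count: int = 0                   # number of separate B-lines
    width_px: float = 9.0            # half-width of a separate B-line
    coalescent_width_px: float = 130.0
    brightness: float = 95.0

    def validate(self) -> None:
        if self.mode not in ("none", "separate", "coalescent", "mixed"):
            raise ValueError(f"unknown B-line mode {self.mode!r}")
        if self.mode != "none" and (self.width_px <= 0 or self.count < 0):
            raise ValueError("B-line geometry must be positive")


@dataclass(frozen=True)
class ConsolidationSpec:
    """Hypoechoic blob with a bright irregular rim (non-aerated lung)."""

    present: bool = False
    center_rel: tuple[float, float] = (0.45, 0.5)   # (row, col) fractions
    axes_px: tuple[float, float] = (70.0, 95.0)     # ellipse semi-axes
    interior_gain: float = 0.40                     # darkening factor
    rim_brightness: float = 120.0
    rim_width_rel: float = 0.14

    def validate(self) -> None:
        if self.present and (self.axes_px[0] <= 0 or self.axes_px[1] <= 0):
            raise ValueError("consolidation axes must be positive")


@dataclass(frozen=True)
class SpeckleSpec:
    """Multiplicative Rayleigh speckle, lightly blurred then mean-normalized."""

    scale: float = 1.0      # Rayleigh scale of the raw field
    blur_sigma: float = 1.2
    floor: float = 0.05     # lower clip on the multiplicative field

    def validate(self) -> None:
        if self.scale <= 0 or self.blur_sigma < 0:
            raise ValueError("speckle parameters must be positive")


@dataclass(frozen=True)
class ClinicalModel:
    """Per-class uniform sampling ranges for the clinical covariates.

    CGATS is derived as GA + DOL/7 (weeks), so prematurity and postnatal
    age stay mutually consistent.
    """

    ga_weeks: tuple[float, float] = (24.0, 41.0)
    dol_days: tuple[float, float] = (0.0, 28.0)

    def sample(self, rng: np.random.Generator) -> tuple[float, float, float]:
        ga = rng.uniform(*self.ga_weeks)
        dol = rng.uniform(*self.dol_days)
        return ga, ga + dol / 7.0, dol


@dataclass(frozen=True)
class PhantomSpec:
    """Full morphology + covariate recipe for one pathology class."""

    class_label: str
    pleura: PleuraSpec = field(default_factory=PleuraSpec)
    aline_count: int = 0
    aline_spacing_px: float = 70.0
    aline_brightness: float = 80.0
    aline_decay: float = 0.70        # per-line brightness decay factor
    bline: BlineSpec = field(default_factory=BlineSpec)
    consolidation: ConsolidationSpec = field(default_factory=ConsolidationSpec)
    double_lung_point: bool = False
    speckle: SpeckleSpec = field(default_factory=SpeckleSpec)
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    background_level: float = 14.0

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.aline_count < 0 or self.aline_spacing_px <= 0:
            raise ValueError("A-line geometry must be positive")
        self.pleura.validate()
        self.bline.validate()
        self.consolidation.validate()
        self.speckle.validate()
        # morphology/label consistency with the pathology grid
        label = self.class_label
        if label == "Normal" and (self.bline.mode != "none" or self.aline_count == 0):
            raise ValueError("Normal spec must have A-lines and no B-lines")
        if label == "CON" and not self.consolidation.present:
            raise ValueError("CON spec must include a consolidation")
        if label == "TTN" and self.bline.mode not in ("separate", "mixed"):
            raise ValueError("TTN spec must include separate B-lines")
        if label == "TTN" and self.consolidation.present:
            raise ValueError("TTN spec must not include a consolidation")
        if label in ("RDS", "CLD") and self.pleura.style == "normal":
            raise ValueError(f"{label} spec requires a thick/irregular pleura")


def default_class_specs() -> dict[str, PhantomSpec]:
    """Default spec per pathology class (the study conditions).

    Morphology content follows the clinical grid; Normal/PTX differ by
    A-line conspicuity (PTX enhances the reverberation pattern), and the
    clinical covariate ranges make CLD (preterm, weeks old) separable
    from RDS (preterm, first days) and TTN (late preterm/term, first
    days) while keeping Normal/PTX/CON covariates uninformative.
    """
    return {
        "Normal": PhantomSpec(
            class_label="Normal",
            pleura=PleuraSpec(style="normal", thickness_px=4.0, brightness=170.0),
            aline_count=4,
            aline_brightness=70.0,
            bline=BlineSpec(mode="none"),
            clinical_model=ClinicalModel((24.0, 41.0), (0.0, 28.0)),
        ),
        "TTN": PhantomSpec(
            class_label="TTN",
            pleura=PleuraSpec(style="normal", thickness_px=4.0, brightness=165.0),
            aline_count=3,
            aline_brightness=60.0,
            bline=BlineSpec(mode="separate", count=4, width_px=9.0, brightness=95.0),
            double_lung_point=True,
            clinical_model=ClinicalModel((34.0, 41.0), (0.0, 3.0)),
        ),
        "PTX": PhantomSpec(
            class_label="PTX",
            pleura=PleuraSpec(style="normal", thickness_px=5.0, brightness=210.0),
            aline_count=5,
            aline_brightness=120.0,
            aline_decay=0.85,
            bline=BlineSpec(mode="none"),
            clinical_model=ClinicalModel((24.0, 41.0), (0.0, 28.0)),
        ),
        "RDS": PhantomSpec(
            class_label="RDS",
            pleura=PleuraSpec(style="irregular", thickness_px=8.0,
                              brightness=150.0, irregularity_px=6.0),
            aline_count=0,
            bline=BlineSpec(mode="coalescent", count=2, width_px=10.0,
                            coalescent_width_px=150.0, brightness=85.0),
            consolidation=ConsolidationSpec(present=True, center_rel=(0.40, 0.30),
                                            axes_px=(45.0, 60.0)),
            clinical_model=ClinicalModel((24.0, 32.0), (0.0, 7.0)),
        ),
        "CLD": PhantomSpec(
            class_label="CLD",
            pleura=PleuraSpec(style="irregular", thickness_px=9.0,
                              brightness=155.0, irregularity_px=9.0),
            aline_count=0,
            bline=BlineSpec(mode="mixed", count=3, width_px=10.0,
                            coalescent_width_px=110.0, brightness=80.0),
            clinical_model=ClinicalModel((24.0, 28.0), (28.0, 90.0)),
        ),
        "CON": PhantomSpec(
            class_label="CON",
            pleura=PleuraSpec(style="thick", thickness_px=9.0, brightness=140.0),
            aline_count=0,
            bline=BlineSpec(mode="separate", count=2, width_px=9.0, brightness=70.0),
            consolidation=ConsolidationSpec(present=True, center_rel=(0.45, 0.5),
                                            axes_px=(80.0, 105.0)),
            clinical_model=ClinicalModel((24.0, 41.0), (0.0, 28.0)),
        ),
    }


@dataclass(frozen=True)
class SampleMeta:
    """Identity and covariates of one generated frame."""

    subject_id: str
    video_id: str
    frame_index: int
    class_label: str
    lung_region: str
    ga_weeks: float
    cgats_weeks: float
    dol_days: float

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.lung_region not in LUNG_REGIONS:
            raise ValueError(f"unknown lung region {self.lung_region!r}")
        if self.frame_index < 0 or self.dol_days < 0:
            raise ValueError("frame_index and dol_days must be >= 0")
        if self.cgats_weeks < self.ga_weeks - 1e-9:
            raise ValueError("CGATS must be >= GA")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _horizontal_band(height: int, width: int, center_rows: np.ndarray,
                     sigma: float, amplitude: float,
                     cols: slice = slice(None)) -> np.ndarray:
    """Additive band with Gaussian vertical profile; per-column centres."""
    out = np.zeros((height, width))
    rows = np.arange(height)[:, None]
    prof = amplitude * np.exp(-0.5 * ((rows - center_rows[None, :]) / sigma) ** 2)
    out[:, cols] = prof[:, cols]
    return out


def _pleura_centers(spec: PleuraSpec, width: int,
                    rng: np.random.Generator) -> np.ndarray:
    centers = np.full(width, float(spec.depth_px))
    if spec.style == "irregular" and spec.irregularity_px > 0:
        # smooth random undulation of the pleural depth
        rough = rng.standard_normal(width)
        smooth = gaussian_filter(rough, sigma=18.0, mode="reflect")
        smooth *= spec.irregularity_px / (np.std(smooth) + 1e-12)
        centers = centers + smooth
    return centers


def render_phantom(spec: PhantomSpec, height: int = DEFAULT_CANVAS[0],
                   width: int = DEFAULT_CANVAS[1], seed: int = 0) -> np.ndarray:
    """Render one synthetic LUS frame.

    Returns a non-negative float array of shape ``(height, width)`` on the
    native 8-bit scale (values in [0, 255]).  Identical ``(spec, seed)``
    yield bit-identical output.
    """
    if height < 64 or width < 64:
        raise ValueError("canvas must be at least 64x64")
    spec.validate()
    rng = np.random.default_rng(seed)

    echo = np.full((height, width), float(spec.background_level))

    # --- pleural line -----------------------------------------------------
    pl = spec.pleura
    centers = _pleura_centers(pl, width, rng)
    pleura_row = float(np.mean(centers))
    amp = pl.brightness
    if pl.style == "irregular":
        # patchy brightness along the line
        gain = 1.0 + 0.35 * np.tanh(gaussian_filter(
            rng.standard_normal(width), sigma=25.0, mode="reflect") * 3.0)
        band = _horizontal_band(height, width, centers, pl.thickness_px, amp)
        band *= gain[None, :]
    else:
        band = _horizontal_band(height, width, centers, pl.thickness_px, amp)
    echo += band

    # column ranges for the double lung point (A-zone | B-zone)
    half = width // 2
    a_cols = slice(0, half) if spec.double_lung_point else slice(None)
    b_cols = slice(half, width) if spec.double_lung_point else slice(None)

    # --- A-lines: equidistant horizontal echoes of decaying brightness ----
    for k in range(1, spec.aline_count + 1):
        row = centers + k * spec.aline_spacing_px
        a_amp = spec.aline_brightness * spec.aline_decay ** (k - 1)
        echo += _horizontal_band(height, width, row,
                                 pl.thickness_px * 0.9, a_amp, cols=a_cols)

    # --- B-lines: vertical bands from the pleural row to the bottom -------
    bl = spec.bline
    below = (np.arange(height)[:, None] >=
             centers[None, :] - pl.thickness_px)  # start at the pleura
    cols_idx = np.arange(width)
    if bl.mode in ("separate", "mixed") and bl.count > 0:
        lo = b_cols.start if b_cols.start is not None else 0
        hi = b_cols.stop if b_cols.stop is not None else width
        span = hi - lo
        centers_x = lo + (np.arange(bl.count) + 0.5) * span / bl.count
        centers_x = centers_x + rng.uniform(-0.08, 0.08, size=bl.count) * span / bl.count
        prof = np.zeros(width)
        for cx in centers_x:
            prof = np.maximum(
                prof, np.exp(-0.5 * ((cols_idx - cx) / bl.width_px) ** 2))
        echo += below * (bl.brightness * prof)[None, :]
    if bl.mode in ("coalescent", "mixed"):
        lo = b_cols.start if b_cols.start is not None else 0
        hi = b_cols.stop if b_cols.stop is not None else width
        cx = 0.5 * (lo + hi) + rng.uniform(-0.05, 0.05) * (hi - lo)
        sig = bl.coalescent_width_px / 2.0
        prof = np.exp(-0.5 * ((cols_idx - cx) / sig) ** 2)
        echo += below * (bl.brightness * prof)[None, :]

    # --- consolidation: hypoechoic blob with a bright irregular rim -------
    con = spec.consolidation
    if con.present:
        cr = con.center_rel[0] * height
        cc = con.center_rel[1] * width
        rr = np.arange(height)[:, None] - cr
        ccols = np.arange(width)[None, :] - cc
        theta = np.arctan2(rr, ccols)
        # angular irregularity of the rim radius
        wob = (1.0 + 0.10 * np.sin(3 * theta + rng.uniform(0, 2 * np.pi))
               + 0.06 * np.sin(5 * theta + rng.uniform(0, 2 * np.pi)))
        dist = np.sqrt((rr / con.axes_px[0]) ** 2 + (ccols / con.axes_px[1]) ** 2) / wob
        interior = dist < 1.0
        rim = (dist >= 1.0) & (dist < 1.0 + con.rim_width_rel)
        echo = np.where(interior, spec.background_level
                        + con.interior_gain * (echo - spec.background_level), echo)
        echo = echo + rim * con.rim_brightness

    # --- multiplicative speckle -------------------------------------------
    sp = spec.speckle
    field_ = rng.rayleigh(scale=sp.scale, size=(height, width))
    if sp.blur_sigma > 0:
        field_ = gaussian_filter(field_, sigma=sp.blur_sigma, mode="reflect")
    field_ /= field_.mean()
    img = echo * np.clip(field_, sp.floor, None)
    return np.clip(img, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Subject-level perturbation: same morphology, varied geometry."""
    def u(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    pleura = replace(
        spec.pleura,
        depth_px=spec.pleura.depth_px + u(-4, 4),
        thickness_px=spec.pleura.thickness_px * u(0.9, 1.1),
        brightness=spec.pleura.brightness * u(0.93, 1.07),
    )
    bline = replace(
        spec.bline,
        width_px=spec.bline.width_px * u(0.9, 1.1),
        coalescent_width_px=spec.bline.coalescent_width_px * u(0.9, 1.1),
        brightness=spec.bline.brightness * u(0.92, 1.08),
    )
    con = spec.consolidation
    if con.present:
        con = replace(
            con,
            axes_px=(con.axes_px[0] * u(0.9, 1.1), con.axes_px[1] * u(0.9, 1.1)),
            center_rel=(con.center_rel[0] + u(-0.03, 0.03),
                        con.center_rel[1] + u(-0.03, 0.03)),
        )
    return replace(
        spec,
        pleura=pleura,
        bline=bline,
        consolidation=con,
        aline_spacing_px=spec.aline_spacing_px + u(-3, 3),
        aline_brightness=spec.aline_brightness * u(0.92, 1.08),
    )


def _frame_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Intra-video jitter: +/-2 px translation via the depth parameter."""
    dy = float(rng.integers(-2, 3))
    return replace(spec, pleura=replace(spec.pleura,
                                        depth_px=spec.pleura.depth_px + dy))


def generate_cohort(n_subjects_per_class: int, videos_per_subject: int,
                    frames_per_video: int, seed: int,
                    height: int = DEFAULT_CANVAS[0],
                    width: int = DEFAULT_CANVAS[1],
                    class_specs: dict[str, PhantomSpec] | None = None,
                    ) -> tuple[list[np.ndarray], list[SampleMeta]]:
    """Generate a balanced multi-class phantom cohort.

    Subjects within a class share a jittered copy of the class spec;
    frames within a video share the subject spec with a small translation
    and fresh speckle.  ``(4, 6, 5, seed)`` yields the balanced study
    design: 24 subjects, 144 videos, 720 images.
    """
    if min(n_subjects_per_class, videos_per_subject, frames_per_video) < 1:
        raise ValueError("all cohort counts must be >= 1")
    if class_specs is None:
        class_specs = default_class_specs()

    root = np.random.SeedSequence(seed)
    images: list[np.ndarray] = []
    metas: list[SampleMeta] = []
    for ci, label in enumerate(CLASS_LABELS):
        base = class_specs[label]
        for s in range(n_subjects_per_class):
            sub_rng = np.random.default_rng(np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(ci, s)))
            subject_id = f"{label}-S{s + 1:02d}"
            spec = _jitter_spec(base, sub_rng)
            ga, cgats, dol = base.clinical_model.sample(sub_rng)
            for v in range(videos_per_subject):
                region = LUNG_REGIONS[v % len(LUNG_REGIONS)]
                video_id = f"{subject_id}-V{v + 1:02d}"
                vid_rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(ci, s, v)))
                for f in range(frames_per_video):
                    fspec = _frame_spec(spec, vid_rng)
                    frame_seed = int(vid_rng.integers(0, 2**31 - 1))
                    images.append(render_phantom(fspec, height, width,
                                                 seed=frame_seed))
                    metas.append(SampleMeta(
                        subject_id=subject_id, video_id=video_id,
                        frame_index=f, class_label=label, lung_region=region,
                        ga_weeks=round(ga, 2), cgats_weeks=round(cgats, 2),
                        dol_days=round(dol, 1)))
    return images, metas
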