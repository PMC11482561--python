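"""Ground-truthed synthetic chip fields and simulated counting measurements.

Every downstream stage of the pipeline (detection, gating, quantification,
validation statistics) is exercised against data from this module, which
emulates what the counting instrument photographs: circular WBCs bright in
the green-fluorescence (GF) channel, circular RBCs bright in the
cyan/far-red (CF) channel, both faintly visible in bright field, with
Poisson cell numbers per imaged volume, optional debris artifacts, additive
Gaussian camera noise, and optional cell overlap.

It also simulates replicate measurements from the three counting modalities
(chip imager, Neubauer hemocytometer, bead-calibrated flow cytometer) so the
validation and comparison statistics can be studied without clinical data.

The default field geometry — 488 x 488 px at 1.0 µm/px over a 100 µm deep
channel — images 488^2 x 100 µm^3 = 23.8144 nL per field, the instrument's
volume per image.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .detect import FieldImage
from .quantify import (
    ChipSpec,
    DilutionSpec,
    InvalidMeasurementError,
    flowcount_concentration,
    microscanner_concentration,
    neubauer_concentration,
    stain_dilution_factor,
)

__all__ = [
    "ClassIntensity",
    "IntensityModel",
    "FieldSpec",
    "GroundTruth",
    "MeasurementModel",
    "MeasurementResult",
    "render_field",
    "render_fields",
    "simulate_measurement",
    "save_field",
]

WBC = "WBC"
RBC = "RBC"
ARTIFACT = "ARTIFACT"


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassIntensity:
    """Log-normal signal amplitude for one cell class in one channel.

    ``median`` is the median peak amplitude above background (0 disables the
    channel for that class); ``log_sd`` the SD of log amplitude.
    """

    median: float
    log_sd: float = 0.2

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.median <= 0:
            return np.zeros(n)
        return self.median * np.exp(rng.normal(0.0, self.log_sd, size=n))


@dataclass(frozen=True)
class IntensityModel:
    """Per-class channel amplitudes: WBCs signal in GF, RBCs in CF."""

    wbc_gf: ClassIntensity = ClassIntensity(900.0)
    wbc_cf: ClassIntensity = ClassIntensity(0.0)
    rbc_gf: ClassIntensity = ClassIntensity(0.0)
    rbc_cf: ClassIntensity = ClassIntensity(900.0)
    bf_amplitude: float = 80.0  # faint bright-field signature, both classes


@dataclass(frozen=True)
class FieldSpec:
    """Everything needed to render one chip field reproducibly.

    Concentrations are in cells x 10^6/L (= cells/µL) of the fluid in the
    chip channel; radius intervals are closed, in µm.
    """

    width_px: int = 488
    height_px: int = 488
    pixel_size_um: float = 1.0
    depth_um: float = 100.0
    wbc_conc: float = 0.0
    rbc_conc: float = 0.0
    wbc_radius_um: tuple[float, float] = (3.5, 6.0)
    rbc_radius_um: tuple[float, float] = (2.5, 4.0)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    background_level: float = 100.0
    noise_sd: float = 5.0
    artifact_rate: float = 0.0
    overlap_allowed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "depth_um", "wbc_conc", "rbc_conc",
                     "background_level", "noise_sd", "artifact_rate"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_size_um <= 0 or self.depth_um <= 0:
            raise ValueError("pixel_size_um and depth_um must be positive")
        if self.wbc_conc < 0 or self.rbc_conc < 0 or self.artifact_rate < 0:
            raise ValueError("concentrations and artifact_rate must be >= 0")
        for iv in (self.wbc_radius_um, self.rbc_radius_um):
            if not (iv[0] <= iv[1] and iv[0] > 0):
                raise ValueError(f"invalid radius interval {iv}")
        if not math.isfinite(self.volume_nl) or self.volume_nl <= 0:
            raise ValueError("imaged volume must be positive and finite")

    @property
    def volume_nl(self) -> float:
        return (self.width_px * self.height_px * self.pixel_size_um**2
                * self.depth_um * 1e-6)

    @property
    def volume_ul(self) -> float:
        return self.volume_nl * 1e-3


@dataclass
class GroundTruth:
    """Exact cell inventory of a rendered field.

    ``cells`` holds (class, center_x_px, center_y_px, radius_px) tuples;
    counts are per class.
    """

    cells: list[tuple[str, float, float, float]]
    true_wbc_count: int
    true_rbc_count: int

    @property
    def true_artifact_count(self) -> int:
        return sum(1 for c in self.cells if c[0] == ARTIFACT)

    def __post_init__(self) -> None:
        if self.true_wbc_count != sum(1 for c in self.cells if c[0] == WBC):
            raise ValueError("true_wbc_count inconsistent with cell list")
        if self.true_rbc_count != sum(1 for c in self.cells if c[0] == RBC):
            raise ValueError("true_rbc_count inconsistent with cell list")


# --------------------------------------------------------------------------
# Field rendering
# --------------------------------------------------------------------------

def _place(rng, w, h, r_px, placed, overlap_allowed, max_tries=500):
    """Uniform position with the disc fully interior; rejection-sample
    against existing discs unless overlap is allowed (density here is low
    enough that placement virtually never exhausts its tries)."""
    margin = r_px + 1.0
    for _ in range(max_tries):
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if overlap_allowed or all(
            (x - px) ** 2 + (y - py) ** 2 > (r_px + pr + 1.0) ** 2
            for px, py, pr in placed
        ):
            return x, y
    return x, y  # accept the overlap rather than distort the Poisson count


def _paint_disc(img: np.ndarray, x: float, y: float, r: float, amp: float):
    """Filled disc with a 1-px linear edge falloff (keeps Hough gradients
    well defined without claiming optics fidelity)."""
    if amp == 0.0:
        return
    h, w = img.shape
    x0, x1 = max(0, int(x - r - 2)), min(w, int(x + r + 3))
    y0, y1 = max(0, int(y - r - 2)), min(h, int(y + r + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - y, xx - x)
    img[y0:y1, x0:x1] += amp * np.clip(r + 0.5 - d, 0.0, 1.0)


def render_field(spec: FieldSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one field and return the image with its exact ground truth.

    Cell numbers per class are Poisson with mean ``conc x imaged volume``;
    identical spec (including seed) gives a bit-identical image and truth.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width_px, spec.height_px
    im = spec.intensity_model

    n_wbc = int(rng.poisson(spec.wbc_conc * spec.volume_ul))
    n_rbc = int(rng.poisson(spec.rbc_conc * spec.volume_ul))
    n_art = int(rng.poisson(spec.artifact_rate))

    bf = np.full((h, w), float(spec.background_level))
    gf = np.full((h, w), float(spec.background_level))
    cf = np.full((h, w), float(spec.background_level))

    cells: list[tuple[str, float, float, float]] = []
    placed: list[tuple[float, float, float]] = []

    for cls, n, rad_iv, gf_amp, cf_amp in (
        (WBC, n_wbc, spec.wbc_radius_um, im.wbc_gf, im.wbc_cf),
        (RBC, n_rbc, spec.rbc_radius_um, im.rbc_gf, im.rbc_cf),
    ):
        radii_um = rng.uniform(rad_iv[0], rad_iv[1], size=n)
        a_gf = gf_amp.draw(rng, n)
        a_cf = cf_amp.draw(rng, n)
        for i in range(n):
            r_px = radii_um[i] / spec.pixel_size_um
            x, y = _place(rng, w, h, r_px, placed, spec.overlap_allowed)
            placed.append((x, y, r_px))
            cells.append((cls, x, y, r_px))
            _paint_disc(gf, x, y, r_px, a_gf[i])
            _paint_disc(cf, x, y, r_px, a_cf[i])
            _paint_disc(bf, x, y, r_px, im.bf_amplitude)

    # Debris / aggregates: specks below the cell size range or oversized
    # blobs, with atypical (often dual-channel) intensity.
    min_cell = min(spec.wbc_radius_um[0], spec.rbc_radius_um[0])
    max_cell = max(spec.wbc_radius_um[1], spec.rbc_radius_um[1])
    for _ in range(n_art):
        if rng.random() < 0.5:
            r_um = rng.uniform(0.4 * min_cell, 0.8 * min_cell)
        else:
            r_um = rng.uniform(1.8 * max_cell, 2.5 * max_cell)
        r_px = r_um / spec.pixel_size_um
        x, y = _place(rng, w, h, r_px, placed, spec.overlap_allowed)
        placed.append((x, y, r_px))
        cells.append((ARTIFACT, x, y, r_px))
        amp = 600.0 * np.exp(rng.normal(0.0, 0.4))
        _paint_disc(gf, x, y, r_px, amp * rng.uniform(0.3, 1.0))
        _paint_disc(cf, x, y, r_px, amp * rng.uniform(0.3, 1.0))
        _paint_disc(bf, x, y, r_px, im.bf_amplitude)

    if spec.noise_sd > 0:
        for ch in (bf, gf, cf):
            ch += rng.normal(0.0, spec.noise_sd, size=ch.shape)
            np.clip(ch, 0.0, None, out=ch)

    image = FieldImage(
        bf=bf, gf=gf, cf=cf,
        pixel_size_um=spec.pixel_size_um, depth_um=spec.depth_um,
        field_id=f"field_{spec.seed}",
    )
    truth = GroundTruth(cells=cells, true_wbc_count=n_wbc,
                        true_rbc_count=n_rbc)
    return image, truth


def render_fields(
    spec: FieldSpec, n_fields: int, master_seed: int
) -> list[tuple[FieldImage, GroundTruth]]:
    """Render ``n_fields`` fields with independent per-field streams.

    Field *i* uses seed sequence ``[master_seed, i]``, so generation order
    (or parallelism) cannot change any field's content.
    """
    from dataclasses import replace as _replace

    out = []
    for i in range(n_fields):
        rng_seed = np.random.SeedSequence([master_seed, i]).generate_state(1)[0]
        fs = _replace(spec, seed=int(rng_seed) % (2**31))
        img, truth = render_field(fs)
        img.field_id = f"field_{master_seed}_{i:04d}"
        out.append((img, truth))
    return out


# --------------------------------------------------------------------------
# Measurement simulation (three counting modalities)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementModel:
    """Stochastic model of one counting modality.

    modality ``"neubauer"``: Poisson counts in ``squares_counted x
    square_volume_ul`` per read, ``duplicates`` reads averaged, then a
    mean-one log-normal examiner factor with CV ``examiner_cv`` (hand counts
    are dominated by examiner variability, which a single multiplicative
    parameter reproduces).

    modality ``"microscanner"``: Poisson count over ``n_images`` fields of
    ``chip.volume_per_image_nl`` holding stained sample (diluted by the
    stain and any pre-dilution factor), pushed through the chip concentration
    formula; an optional mean-one log-normal instrument factor with CV
    ``instrument_cv``; measurements whose raw event count falls below
    ``min_count`` report 0, emulating the instrument's rejection of sparse
    event sets as artifacts.

    modality ``"flow"``: Poisson bead and cell event draws pushed through the
    counting-bead formula (cells/beads x bead concentration x dilution).
    """

    modality: str = "microscanner"
    # neubauer
    squares_counted: int = 4
    square_volume_ul: float = 0.1  # 1 mm x 1 mm x 0.1 mm large square
    examiner_cv: float = 0.0
    duplicates: int = 2
    # flow
    bead_concentration: float = 1000.0  # beads/µL assay concentration
    bead_events_expected: float = 5000.0
    flow_dilution_factor: float = 1.0
    # microscanner
    n_images: int = 42
    chip: ChipSpec = field(default_factory=ChipSpec)
    dilution: DilutionSpec = field(default_factory=DilutionSpec)
    instrument_cv: float = 0.0
    min_count: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("neubauer", "flow", "microscanner"):
            raise ValueError(f"unknown modality {self.modality!r}")
        for name in ("square_volume_ul", "bead_concentration",
                     "bead_events_expected", "flow_dilution_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.examiner_cv < 0 or self.instrument_cv < 0:
            raise ValueError("CV parameters must be >= 0")
        if self.squares_counted < 1 or self.duplicates < 1:
            raise ValueError("squares_counted and duplicates must be >= 1")
        if self.n_images < 1 or self.min_count < 0:
            raise ValueError("n_images must be >= 1 and min_count >= 0")


@dataclass
class MeasurementResult:
    """Measured (WBC, RBC) concentrations plus the raw draws behind them.

    Unpacks as ``(measured_wbc, measured_rbc)``; ``raw`` keeps the logged
    intermediate counts so any value can be recomputed by hand.
    """

    measured_wbc: float
    measured_rbc: float
    valid: bool = True
    raw: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.measured_wbc, self.measured_rbc))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    s2 = math.log1p(cv * cv)
    return math.exp(rng.normal(-0.5 * s2, math.sqrt(s2)))


def simulate_measurement(
    true_wbc: float, true_rbc: float, model: MeasurementModel, seed: int
) -> MeasurementResult:
    """Simulate one replicate measurement of a sample by one modality.

    With all extra-Poisson noise disabled (``examiner_cv = instrument_cv = 0``,
    ``min_count = 0``) every modality is unbiased: the mean measured value
    over many seeds converges to the true concentration.
    """
    if true_wbc < 0 or true_rbc < 0:
        raise ValueError("true concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    raw: dict = {}

    if model.modality == "neubauer":
        v = model.squares_counted * model.square_volume_ul
        out = []
        for cls, true in (("wbc", true_wbc), ("rbc", true_rbc)):
            reads = []
            for _ in range(model.duplicates):
                cells = int(rng.poisson(true * v))
                reads.append(
                    neubauer_concentration(
                        cells, model.squares_counted, model.square_volume_ul
                    ).value
                )
                raw.setdefault(f"{cls}_cells", []).append(cells)
            f = _lognormal_factor(rng, model.examiner_cv)
            raw[f"{cls}_examiner_factor"] = f
            out.append(float(np.mean(reads)) * f)
        return MeasurementResult(out[0], out[1], raw=raw)

    if model.modality == "flow":
        out = []
        valid = True
        for cls, true in (("wbc", true_wbc), ("rbc", true_rbc)):
            beads = int(rng.poisson(model.bead_events_expected))
            lam = (model.bead_events_expected * true
                   / (model.bead_concentration * model.flow_dilution_factor))
            cells = int(rng.poisson(lam))
            raw[f"{cls}_cells"] = cells
            raw[f"{cls}_beads"] = beads
            if beads == 0:
                valid = False
                out.append(float("nan"))
                continue
            out.append(
                flowcount_concentration(
                    cells, beads, model.bead_concentration,
                    model.flow_dilution_factor,
                ).value
            )
        return MeasurementResult(out[0], out[1], valid=valid, raw=raw)

    # microscanner
    sdf = stain_dilution_factor(model.dilution)
    total_factor = sdf * model.dilution.sample_dilution_factor
    imaged_ul = model.chip.volume_per_image_nl * model.n_images * 1e-3
    out = []
    for cls, true in (("wbc", true_wbc), ("rbc", true_rbc)):
        lam = true / total_factor * imaged_ul
        count = int(rng.poisson(lam))
        raw[f"{cls}_count"] = count
        if count < model.min_count:
            out.append(0.0)
            continue
        chip = ChipSpec(
            volume_per_image_nl=model.chip.volume_per_image_nl,
            n_images=model.n_images,
        )
        value = microscanner_concentration(count, chip, model.dilution).value
        out.append(value * _lognormal_factor(rng, model.instrument_cv))
    return MeasurementResult(out[0], out[1], raw=raw)


# --------------------------------------------------------------------------
# File output
# --------------------------------------------------------------------------

def save_field(
    image: FieldImage,
    truth: GroundTruth,
    spec: FieldSpec,
    path: str | Path,
) -> Path:
    """Write a field as a 3-page 16-bit TIFF (BF, GF, CF) + JSON sidecar."""
    import tifffile

    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_suffix(".tiff")
    stack = np.stack(
        [np.clip(np.rint(ch), 0, 65535).astype(np.uint16)
         for ch in (image.bf, image.gf, image.cf)]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "field_spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
            if not isinstance(v, dict)
        } | {"intensity_model": asdict(spec.intensity_model)},
        "ground_truth": {
            "cells": [list(c) for c in truth.cells],
            "true_wbc_count": truth.true_wbc_count,
            "true_rbc_count": truth.true_rbc_count,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path
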