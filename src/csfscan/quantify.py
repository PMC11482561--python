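"""Absolute concentrations from counts, for all three counting modalities.

All results are in cells x 10^6/L, numerically identical to cells/µL.
Volumes are carried explicitly in nL or µL — conversion constants appear in
the formulas, never implicitly.  Values are stored at full precision; any
rounding (2 dp) belongs to the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ChipSpec",
    "DilutionSpec",
    "BeadSpec",
    "ConcentrationResult",
    "InvalidMeasurementError",
    "stain_dilution_factor",
    "microscanner_concentration",
    "neubauer_concentration",
    "trucount_concentration",
    "flowcount_concentration",
]


class InvalidMeasurementError(ValueError):
    """A measurement that must be flagged invalid (e.g. zero counted beads)."""


@dataclass(frozen=True)
class ChipSpec:
    """Imaging-chip geometry: volume per captured image and images taken.

    The default 23.8144 nL is the instrument's volume per image
    (a 488 x 488 µm field over a 100 µm deep channel).
    """

    volume_per_image_nl: float = 23.8144
    n_images: int = 42

    def __post_init__(self) -> None:
        if self.volume_per_image_nl <= 0 or self.n_images <= 0:
            raise ValueError("chip volume and image count must be positive")

    @property
    def imaged_volume_ul(self) -> float:
        return self.volume_per_image_nl * self.n_images * 1e-3


@dataclass(frozen=True)
class DilutionSpec:
    """Staining/dilution bookkeeping for the chip workflow.

    Defaults follow the assay: 40 µL of CSF stained up to 84 µL total, a
    stain dilution factor of 84/40 = 2.1.  ``sample_dilution_factor`` covers
    any additional pre-dilution of the sample itself.
    """

    stained_total_ul: float = 84.0
    sample_ul: float = 40.0
    sample_dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sample_ul <= 0:
            raise ValueError("sample volume must be positive")
        if self.stained_total_ul < self.sample_ul:
            raise ValueError("stained_total_ul must be >= sample_ul")
        if self.sample_dilution_factor < 1:
            raise ValueError("sample_dilution_factor must be >= 1")


@dataclass(frozen=True)
class BeadSpec:
    """Counting-bead standard for absolute flow-cytometric counts."""

    bead_concentration: float  # beads/µL
    sample_volume_ul: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if (self.bead_concentration <= 0 or self.sample_volume_ul <= 0
                or self.dilution_factor < 1):
            raise ValueError("bead spec values must be positive (dilution >= 1)")


@dataclass
class ConcentrationResult:
    """An absolute count with the bookkeeping that produced it."""

    value: float  # cells x 10^6/L == cells/µL
    modality: str
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("concentration cannot be negative")


def stain_dilution_factor(dilution: DilutionSpec) -> float:
    """Total stained volume over sample volume; 84/40 -> 2.1."""
    return dilution.stained_total_ul / dilution.sample_ul


def microscanner_concentration(
    total_count: int, chip: ChipSpec, dilution: DilutionSpec
) -> ConcentrationResult:
    """Chip-imager concentration.

    value = total_count x 1000 / (volume_per_image_nl x n_images)
            x sample_dilution_factor x stain_dilution_factor

    The factor 1000 converts the counted-cells-per-nL ratio into cells/µL.
    """
    if total_count < 0:
        raise ValueError("total_count must be >= 0")
    sdf = stain_dilution_factor(dilution)
    value = (total_count * 1000.0
             / (chip.volume_per_image_nl * chip.n_images)
             * dilution.sample_dilution_factor * sdf)
    return ConcentrationResult(
        value=value,
        modality="microscanner",
        inputs={
            "total_count": total_count,
            "volume_per_image_nl": chip.volume_per_image_nl,
            "n_images": chip.n_images,
            "sample_dilution_factor": dilution.sample_dilution_factor,
            "stain_dilution_factor": sdf,
        },
    )


def neubauer_concentration(
    cells_counted: int,
    squares_counted: int,
    square_volume_ul: float,
    replicate_values: list[float] | None = None,
) -> ConcentrationResult:
    """Hemocytometer concentration.

    A single read is ``cells / (squares x square volume)`` with the standard
    large-square volume of 0.1 µL (1 mm x 1 mm x 0.1 mm).  When duplicate
    read values are supplied the reported value is their arithmetic mean
    (each sample is read twice and averaged).
    """
    if squares_counted < 1:
        raise ValueError("squares_counted must be >= 1")
    if square_volume_ul <= 0:
        raise ValueError("square_volume_ul must be positive")
    if cells_counted < 0:
        raise ValueError("cells_counted must be >= 0")
    single = cells_counted / (squares_counted * square_volume_ul)
    if replicate_values:
        for v in replicate_values:
            if not math.isfinite(v) or v < 0:
                raise ValueError("replicate values must be finite and >= 0")
        value = float(sum(replicate_values)) / len(replicate_values)
    else:
        value = single
    return ConcentrationResult(
        value=value,
        modality="neubauer",
        inputs={
            "cells_counted": cells_counted,
            "squares_counted": squares_counted,
            "square_volume_ul": square_volume_ul,
            "single_read": single,
            "replicate_values": list(replicate_values or []),
        },
    )


def trucount_concentration(
    cells: int, beads: int, bead_spec: BeadSpec
) -> ConcentrationResult:
    """Absolute count from a known-bead-count tube.

    value = (cells / beads) x (bead concentration / tested sample volume)
            x sample dilution factor

    Note the bead concentration is divided by the tested sample volume; the
    conventional kit formula instead uses beads per tube — this follows the
    assay write-up as stated (see docs/methods.md).
    """
    if beads < 1:
        raise InvalidMeasurementError("zero counted beads: measurement invalid")
    if cells < 0:
        raise ValueError("cells must be >= 0")
    value = ((cells / beads)
             * (bead_spec.bead_concentration / bead_spec.sample_volume_ul)
             * bead_spec.dilution_factor)
    return ConcentrationResult(
        value=value, modality="trucount",
        inputs={"cells": cells, "beads": beads, **bead_spec.__dict__},
    )


def flowcount_concentration(
    cells: int, beads: int, bead_assay_concentration: float,
    dilution_factor: float = 1.0,
) -> ConcentrationResult:
    """Absolute count from counting fluorospheres.

    value = (cells / beads) x bead assay concentration x dilution factor
    """
    if beads < 1:
        raise InvalidMeasurementError("zero counted beads: measurement invalid")
    if cells < 0:
        raise ValueError("cells must be >= 0")
    if bead_assay_concentration <= 0:
        raise ValueError("bead_assay_concentration must be positive")
    value = (cells / beads) * bead_assay_concentration * dilution_factor
    return ConcentrationResult(
        value=value, modality="flowcount",
        inputs={"cells": cells, "beads": beads,
                "bead_assay_concentration": bead_assay_concentration,
                "dilution_factor": dilution_factor},
    )
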