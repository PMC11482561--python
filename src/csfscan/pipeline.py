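"""End-to-end plumbing: configuration, the count pipeline, and the
validation/comparison report runners.

``run_count`` chains detection → gating → quantification over a set of
fields belonging to one sample and reports an absolute concentration for
each cell class.  ``run_validate`` and ``run_compare`` turn replicate /
paired CSV tables into validation and method-comparison reports shaped like
the tables of a verification study.

Reports are plain dicts serialised as JSON (deterministic: sorted keys, no
timestamps); numeric rounding happens only here (2 dp for concentrations,
4 dp for correlations), never inside the statistics modules.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as cmp_mod
from . import validate as val_mod
from .detect import (
    DetectorConfig,
    FieldImage,
    detect_circles,
    filter_by_size,
    load_field,
    measure_intensities,
)
from .gate import GateThresholds, SizeRules, gate_events
from .quantify import ChipSpec, DilutionSpec, microscanner_concentration

__all__ = ["RunConfig", "run_count", "run_validate", "run_compare"]

logger = logging.getLogger("csfscan")
if not logger.handlers:  # stderr logging, configurable via verbosity
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s csfscan: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)


@dataclass(frozen=True)
class RunConfig:
    """One serialisable object holding every pipeline knob.

    Round-trips through a human-readable JSON file; unknown keys in a config
    file are rejected rather than ignored.
    """

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    gate_mode: str = "fixed"  # "fixed" or "auto"
    gf_cut: float = 150.0
    cf_cut: float = 150.0
    size_rules: SizeRules = field(default_factory=SizeRules)
    chip: ChipSpec = field(default_factory=ChipSpec)
    dilution: DilutionSpec = field(default_factory=DilutionSpec)
    lob_percentile: float = 95.0
    subrange_reference: str = "A"
    seed: int = 0
    output_dir: str | None = None
    verbosity: str = "WARNING"

    @property
    def cell_radius_range_um(self) -> tuple[float, float]:
        """Accepted-cell size window: the union of the two class ranges up
        to the doublet cutoff, padded by the radius-measurement tolerance."""
        return (self.size_rules.union_min_um - self.size_rules.tolerance_um,
                self.size_rules.doublet_cutoff_um
                + self.size_rules.tolerance_um)

    def thresholds(self) -> GateThresholds | None:
        if self.gate_mode == "auto":
            return None
        return GateThresholds(gf_cut=self.gf_cut, cf_cut=self.cf_cut,
                              mode="fixed")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        sub = {"detector": DetectorConfig, "size_rules": SizeRules,
               "chip": ChipSpec, "dilution": DilutionSpec}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, typ in sub.items():
            if name in d:
                sd = dict(d.pop(name))
                sub_names = {f.name for f in dataclasses.fields(typ)}
                bad = set(sd) - sub_names
                if bad:
                    raise ValueError(
                        f"unknown config keys in {name}: {sorted(bad)}")
                for k, v in sd.items():
                    if isinstance(v, list):
                        sd[k] = tuple(v)
                kwargs[name] = typ(**sd)
        kwargs.update(d)
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# Counting pipeline
# --------------------------------------------------------------------------

def count_field(image: FieldImage, config: RunConfig):
    """Detect, size-filter, measure and gate a single field.

    Detection runs on the summed fluorescence raster (each cell class is
    bright in exactly one channel, so the sum shows both).
    """
    combined = image.gf + image.cf
    dets = detect_circles(combined, config.detector)
    dets = filter_by_size(dets, config.cell_radius_range_um,
                          image.pixel_size_um)
    dets = measure_intensities(dets, image.gf, image.cf)
    for d in dets:
        d.field_id = image.field_id
    rules = dataclasses.replace(config.size_rules,
                                pixel_size_um=image.pixel_size_um)
    gres = gate_events(dets, config.thresholds(), rules)
    return dets, gres


def run_count(
    images: list, config: RunConfig = RunConfig()
) -> dict:
    """Count one sample from its field images.

    ``images`` may mix :class:`FieldImage` objects and TIFF paths.  Fields
    that fail to load or process are reported per-file and skipped (the
    batch continues); ``report["errors"]`` is non-empty in that case and the
    concentration uses only the processed fields.
    """
    level = getattr(logging, str(config.verbosity).upper(), logging.WARNING)
    logger.setLevel(level)

    per_field = []
    detections_rows = []
    errors = []
    total_wbc = total_rbc = total_artifact = 0
    n_ok = 0
    volume_nl = config.chip.volume_per_image_nl
    for idx, item in enumerate(images):
        try:
            image = item if isinstance(item, FieldImage) else load_field(item)
            dets, gres = count_field(image, config)
        except Exception as exc:  # noqa: BLE001 - per-file error reporting
            errors.append({"field": str(item), "error": str(exc)})
            logger.error("field %s failed: %s", item, exc)
            continue
        n_ok += 1
        volume_nl = image.volume_nl
        total_wbc += gres.adjusted_wbc
        total_rbc += gres.adjusted_rbc
        total_artifact += gres.artifact_count
        logger.debug(
            "field %s: %d detections, wbc=%d rbc=%d artifacts=%d",
            image.field_id, len(dets), gres.adjusted_wbc,
            gres.adjusted_rbc, gres.artifact_count,
        )
        per_field.append({
            "field_id": image.field_id,
            "n_detections": len(dets),
            "wbc": gres.adjusted_wbc,
            "rbc": gres.adjusted_rbc,
            "artifacts": gres.artifact_count,
            "doublets": gres.doublet_count,
        })
        for d in dets:
            detections_rows.append({
                "field_id": d.field_id, "x": d.center_x_px,
                "y": d.center_y_px, "radius_px": d.radius_px,
                "gf": d.gf_intensity, "cf": d.cf_intensity,
                "flags": ";".join(d.flags),
            })

    report: dict = {
        "n_fields": n_ok,
        "per_field": per_field,
        "errors": errors,
        "totals": {"wbc": total_wbc, "rbc": total_rbc,
                   "artifacts": total_artifact},
    }
    if n_ok > 0:
        chip = ChipSpec(volume_per_image_nl=volume_nl, n_images=n_ok)
        for cls, total in (("wbc", total_wbc), ("rbc", total_rbc)):
            res = microscanner_concentration(total, chip, config.dilution)
            report[f"{cls}_concentration"] = {
                "value": round(res.value, 2),
                "value_full": res.value,
                "inputs": res.inputs,
            }
        logger.info(
            "sample: %d fields, WBC %.2f, RBC %.2f cells x 10^6/L",
            n_ok, report["wbc_concentration"]["value_full"],
            report["rbc_concentration"]["value_full"],
        )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            detections_rows,
            columns=["field_id", "x", "y", "radius_px", "gf", "cf", "flags"],
        ).to_csv(out / "detections.csv", index=False)
        pd.DataFrame(per_field).to_csv(out / "per_field.csv", index=False)
        (out / "count_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
    return report


# --------------------------------------------------------------------------
# Validation / comparison runners
# --------------------------------------------------------------------------

_VALIDATE_COLS = ["level_label", "expected", "replicate_index", "value"]


def _load_table(source, required: list[str]) -> pd.DataFrame:
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing columns: {missing}")
    return df


def run_validate(source, config: RunConfig = RunConfig()) -> dict:
    """Analytical-performance report from a replicate table.

    Expects columns ``level_label, expected, replicate_index, value``.
    Levels with expected = 0 are the blanks (pooled for the LOB); the
    non-zero levels feed linearity, LOD and precision.
    """
    df = _load_table(source, _VALIDATE_COLS)
    levels = []
    for (label, expected), grp in sorted(
        df.groupby(["level_label", "expected"]),
        key=lambda kv: (kv[0][1], str(kv[0][0])),
    ):
        levels.append(val_mod.ReplicateSet(
            level_label=str(label),
            expected_concentration=float(expected),
            measurements=tuple(grp.sort_values("replicate_index")["value"]),
        ))
    report: dict = {"n_levels": len(levels)}

    lin = val_mod.linearity(levels)
    report["linearity"] = {
        "r": round(lin.r, 4), "r_squared": round(lin.r_squared, 4),
        "levels": lin.levels,
    }

    blanks = [m for l in levels if l.expected_concentration == 0
              for m in l.measurements]
    nonzero = [l for l in levels if l.expected_concentration > 0]
    if blanks:
        lob = val_mod.limit_of_blank(blanks, config.lob_percentile)
        lodres = val_mod.limit_of_detection(nonzero, lob)
        report["lob"] = lob
        report["lod"] = lodres.lod
        report["lod_exceedance"] = lodres.exceedance

    prec = val_mod.precision(levels)
    report["precision"] = [
        {**row, "cv_percent": (round(row["cv_percent"], 2)
                               if row["cv_percent"] is not None else None)}
        for row in prec.levels
    ]
    return report


def run_compare(
    source,
    config: RunConfig = RunConfig(),
    value_range: tuple[float, float] | None = None,
) -> dict:
    """Method-comparison report from a paired table (columns ``x, y``).

    With ``value_range`` the statistics are additionally re-run on the
    subrange of pairs whose reference value (``config.subrange_reference``)
    falls inside the window.
    """
    df = _load_table(source, ["x", "y"])
    labels = {"label_x": str(df["label_x"].iloc[0]) if "label_x" in df else "method A",
              "label_y": str(df["label_y"].iloc[0]) if "label_y" in df else "method B"}
    pairs = cmp_mod.PairedMeasurements(df["x"], df["y"], **labels)

    def stats_block(p: cmp_mod.PairedMeasurements) -> dict:
        r, r2 = cmp_mod.pearson(p)
        pb = cmp_mod.passing_bablok(p)
        ba = cmp_mod.bland_altman(p)
        return {
            "n": p.n,
            "r": round(r, 4),
            "r_squared": round(r2, 4),
            "passing_bablok": {
                "slope": round(pb.slope, 4),
                "slope_ci": [round(v, 4) for v in pb.slope_ci],
                "intercept": round(pb.intercept, 4),
                "intercept_ci": [round(v, 4) for v in pb.intercept_ci],
            },
            "bland_altman": {
                "mean_bias": round(ba.mean_bias, 4),
                "bias_ci": [round(v, 4) for v in ba.bias_ci],
                "sd_diff": round(ba.sd_diff, 4),
                "loa": [round(ba.loa_low, 4), round(ba.loa_high, 4)],
            },
        }

    report = {"methods": labels, "all": stats_block(pairs)}
    if value_range is not None:
        sub = cmp_mod.subrange(pairs, value_range[0], value_range[1],
                               config.subrange_reference)
        report["subrange"] = {
            "range": list(value_range),
            "reference": config.subrange_reference,
            **stats_block(sub),
        }
    return report
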