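"""Ordered-pipeline runner over a project.

Processing steps live in a name→operation registry; a pipeline is an
ordered list of (step name, parameter map). The runner pushes every input
file through every step in order, persisting and recording each per-step
output in the project manifest, so the output of a prior step is the input
of the next. Steps come in three modes:

* ``map`` — applied to each current file independently (trim, bandpass…);
* ``batch`` — sees all current files at once but emits one output per input
  (alignment, which builds its reference from one of the inputs);
* ``reduce`` — consumes the whole current file set and emits a single file
  (concatenation, evoked averaging, correlation matrices).

New steps register with :func:`register_step` without touching the runner.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from . import connectivity, coords, register, temporal
from .project import FileRecord, Manipulation, ProjectManifest, record_step
from .stack import ImageStack

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A step failed; carries step name, input name and cause."""


@dataclass
class PipelineConfig:
    """Ordered list of (step name, parameter map)."""

    steps: list[tuple[str, dict[str, Any]]] = field(default_factory=list)

    def validate(self) -> None:
        for name, _ in self.steps:
            if name not in REGISTRY:
                raise KeyError(
                    f"unknown pipeline step {name!r}; "
                    f"registered: {sorted(REGISTRY)}"
                )

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Load from JSON or YAML: a list of {"step": name, "params": {…}}
        entries (bare step-name strings are accepted)."""
        path = os.fspath(path)
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml

                raw = yaml.safe_load(fh)
            else:
                raw = json.load(fh)
        steps: list[tuple[str, dict]] = []
        for entry in raw:
            if isinstance(entry, str):
                steps.append((entry, {}))
            else:
                steps.append((entry["step"], dict(entry.get("params", {}))))
        return cls(steps=steps)


@dataclass
class StepContext:
    """What a step function may see besides its input stacks."""

    manifest: ProjectManifest
    records: list[FileRecord]
    params: dict[str, Any]


StepFunc = Callable[[list[ImageStack], StepContext], list[ImageStack]]


@dataclass
class StepDef:
    name: str
    func: StepFunc
    mode: str = "map"  # map | batch | reduce
    type_tag: str | None = None


REGISTRY: dict[str, StepDef] = {}


def register_step(name: str, mode: str = "map", type_tag: str | None = None):
    """Decorator adding an operation to the step registry."""
    if mode not in ("map", "batch", "reduce"):
        raise ValueError(f"unknown step mode {mode!r}")

    def wrap(func: StepFunc) -> StepFunc:
        REGISTRY[name] = StepDef(name=name, func=func, mode=mode, type_tag=type_tag)
        return func

    return wrap


def run_pipeline(
    manifest: ProjectManifest,
    config: PipelineConfig,
    inputs: Sequence[str],
) -> list[FileRecord]:
    """Push every input through every step of the pipeline in order.

    Returns the records of all files the run created. Map/batch steps emit
    one output per current file; reduce steps fan the whole current set into
    one file. The first failing step aborts with step name, input name and
    cause; outputs of earlier steps remain on disk.
    """
    config.validate()
    for name in inputs:
        manifest.find(name)
    current: list[str] = list(inputs)
    created: list[FileRecord] = []
    for step_name, params in config.steps:
        sd = REGISTRY[step_name]
        t0 = time.perf_counter()
        records = [manifest.find(n) for n in current]
        if sd.mode == "map":
            # load one file at a time so memory stays bounded
            outs: list[ImageStack] = []
            for name, rec in zip(current, records):
                one_ctx = StepContext(
                    manifest=manifest, records=[rec], params=dict(params)
                )
                try:
                    (out,) = sd.func([manifest.load(name)], one_ctx)
                except Exception as exc:
                    raise PipelineError(
                        f"step {step_name!r} failed on {name!r}: {exc}"
                    ) from exc
                outs.append(out)
        else:
            stacks = [manifest.load(n) for n in current]
            ctx = StepContext(manifest=manifest, records=records, params=dict(params))
            try:
                outs = sd.func(stacks, ctx)
            except Exception as exc:
                raise PipelineError(
                    f"step {step_name!r} failed on {current!r}: {exc}"
                ) from exc
        step = Manipulation(step_name, dict(params))
        if sd.mode == "reduce":
            if len(outs) != 1:
                raise PipelineError(
                    f"reduce step {step_name!r} must emit exactly one output"
                )
            rec = record_step(
                manifest,
                current[0],
                step,
                outs[0],
                out_name=manifest.unique_name(step_name),
                type_tag=sd.type_tag,
            )
            created.append(rec)
            current = [rec.name]
        else:
            if len(outs) != len(current):
                raise PipelineError(
                    f"step {step_name!r} emitted {len(outs)} outputs for "
                    f"{len(current)} inputs"
                )
            next_names: list[str] = []
            for name, out in zip(current, outs):
                rec = record_step(manifest, name, step, out, type_tag=sd.type_tag)
                created.append(rec)
                next_names.append(rec.name)
            current = next_names
        logger.info(
            "step %-12s %4d file(s)  %6.2f s",
            step_name,
            len(outs),
            time.perf_counter() - t0,
        )
    return created


def reference_pipeline(
    seed_px: tuple[int, int],
    crop_polygons: list | None = None,
    n_front: int = 20,
    ref_start: int = 400,
    ref_end: int = 500,
) -> PipelineConfig:
    """The reference preprocessing chain for spontaneous-activity stacks.

    Order: trim → align → crop → bandpass → ΔF/F0 → GSR → concatenate →
    seed-pixel correlation map. Correlation matrices are computed from the
    per-trial post-GSR files (see :func:`run_pipeline` callers), since they
    summarise across trials rather than across the concatenation.
    """
    steps: list[tuple[str, dict]] = [
        ("trim", {"n_front": n_front}),
        ("align", {"ref_start": ref_start, "ref_end": ref_end}),
    ]
    if crop_polygons is not None:
        steps.append(("crop", {"polygons": crop_polygons}))
    steps += [
        ("bandpass", {}),
        ("dff", {}),
        ("gsr", {}),
        ("concat", {}),
        ("spc", {"seed_px": list(seed_px)}),
    ]
    return PipelineConfig(steps=steps)


# ---------------------------------------------------------------------------
# registered steps


@register_step("trim")
def _step_trim(stacks, ctx):
    p = ctx.params
    return [
        temporal.trim_frames(
            s, n_front=int(p.get("n_front", 20)), n_back=int(p.get("n_back", 0))
        )
        for s in stacks
    ]


@register_step("unsharp")
def _step_unsharp(stacks, ctx):
    k = int(ctx.params.get("kernel_size", 8))
    return [register.unsharp_filter(s, k) for s in stacks]


@register_step("align", mode="batch")
def _step_align(stacks, ctx):
    p = ctx.params
    ref_index = 0
    if "reference_name" in p:
        names = [r.name for r in ctx.records]
        ref_index = names.index(p["reference_name"])
    aligned, _ = register.align_stacks(
        stacks,
        reference_index=ref_index,
        sharpen_kernel=int(p.get("sharpen_kernel", 8)),
        ref_start=int(p.get("ref_start", 400)),
        ref_end=int(p.get("ref_end", 500)),
        frame_index=int(p.get("frame_index", 0)),
    )
    return aligned


def _load_polygons(params: dict) -> list[coords.PolygonRoI]:
    if "polygons_file" in params:
        with open(params["polygons_file"]) as fh:
            raw = json.load(fh)
    else:
        raw = params["polygons"]
    polys = []
    for i, entry in enumerate(raw):
        if isinstance(entry, dict):
            polys.append(coords.PolygonRoI(entry.get("name", f"poly_{i}"), entry["vertices"]))
        else:
            polys.append(coords.PolygonRoI(f"poly_{i}", entry))
    return polys


@register_step("crop")
def _step_crop(stacks, ctx):
    polys = _load_polygons(ctx.params)
    return [coords.polygon_mask(s, polys) for s in stacks]


@register_step("bandpass")
def _step_bandpass(stacks, ctx):
    p = ctx.params
    spec = temporal.FilterSpec(
        low_hz=float(p.get("low", 0.3)),
        high_hz=float(p.get("high", 3.0)),
        order=int(p.get("order", 4)),
        ripple_db=float(p.get("ripple", 0.1)),
    )
    return [temporal.cheby_bandpass(s, spec) for s in stacks]


@register_step("dff")
def _step_dff(stacks, ctx):
    return [temporal.dff(s) for s in stacks]


@register_step("gsr")
def _step_gsr(stacks, ctx):
    return [temporal.gsr(s) for s in stacks]


@register_step("concat", mode="reduce")
def _step_concat(stacks, ctx):
    return [temporal.concat_stacks(stacks)]


@register_step("divide")
def _step_divide(stacks, ctx):
    den = ctx.manifest.load(ctx.params["denominator"])
    return [temporal.divide_stacks(s, den) for s in stacks]


@register_step("evoked_avg", mode="reduce")
def _step_evoked(stacks, ctx):
    return [
        temporal.evoked_average(
            stacks, truncate_to_shortest=bool(ctx.params.get("truncate_to_shortest", False))
        )
    ]


@register_step("stdev_map", type_tag="stdev_map")
def _step_stdev(stacks, ctx):
    return [ImageStack(temporal.stdev_map(s)[None], s.fps) for s in stacks]


def _coordinate_system(ctx: StepContext) -> coords.CoordinateSystem:
    m = ctx.manifest
    if m.origin is None or m.um_per_px is None:
        raise ValueError("project origin and um_per_px must be set first")
    return coords.CoordinateSystem(origin=m.origin, um_per_px=m.um_per_px)


@register_step("spc", type_tag="spc_map")
def _step_spc(stacks, ctx):
    """Seed-pixel correlation map; seed given in pixels (``seed_px``) or as
    a named RoI from a CSV (``roi_csv`` + ``roi_name``)."""
    p = ctx.params
    if "seed_px" in p:
        seed = (int(p["seed_px"][0]), int(p["seed_px"][1]))
    else:
        cs = _coordinate_system(ctx)
        rois = {r.name: r for r in coords.import_roi_csv(p["roi_csv"])}
        roi = rois[p["roi_name"]]
        (seed,) = coords.seed_pixels(
            coords.SeedRoI(roi.name, roi.x_um, roi.y_um, length=1),
            cs,
            stacks[0].frame_shape,
        )
    out = []
    for s, rec in zip(stacks, ctx.records):
        m = connectivity.spc_map(s, seed, provenance=[mm.name for mm in rec.manipulations])
        out.append(ImageStack(m.values[None], s.fps))
    return out


@register_step("corrmat", mode="reduce", type_tag="corr_matrix")
def _step_corrmat(stacks, ctx):
    """Cross-trial RoI correlation matrices. Emits a 2×k×k stack (mean on
    frame 0, std on frame 1) and writes mean/std CSVs beside the project."""
    import pandas as pd

    cs = _coordinate_system(ctx)
    rois = coords.import_roi_csv(ctx.params["roi_csv"])
    length = ctx.params.get("length")
    if length is not None:
        rois = [coords.SeedRoI(r.name, r.x_um, r.y_um, int(length)) for r in rois]
    res = connectivity.correlation_matrix(stacks, rois, cs)
    base = os.path.join(ctx.manifest.project_dir, ctx.params.get("out_base", "corrmat"))
    pd.DataFrame(res.mean_r, index=res.roi_names, columns=res.roi_names).to_csv(
        base + "_mean.csv"
    )
    pd.DataFrame(res.std_r, index=res.roi_names, columns=res.roi_names).to_csv(
        base + "_std.csv"
    )
    return [ImageStack(np.stack([res.mean_r, res.std_r]), stacks[0].fps)]


@register_step("shift_origin")
def _step_shift_origin(stacks, ctx):
    """Shift stacks so their bregma lands on a target origin (pooling data
    from different animals onto one coordinate system). A per-stack origin
    overrides the project origin when present."""
    target = tuple(ctx.params["target"])
    out = []
    for s, rec in zip(stacks, ctx.records):
        own = rec.origin or ctx.manifest.origin
        if own is None:
            raise ValueError(f"no origin known for {rec.name!r}")
        out.append(coords.shift_to_common_origin(s, own, target))
    return out
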