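"""JSON-backed project manifest.

A project is a single flat directory holding every imported and derived
stack (as NPY files) plus one JSON manifest recording, for each file, its
origin, frame rate, type tag and the ordered list of manipulations it has
gone through. Because the manifest refers to files by bare name and allows
no subfolders, the whole directory can be copied to another machine and
opened there with all state intact.

Manifest writes are atomic (write-temp-then-rename) so a crashed processing
step cannot corrupt the project.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Any, Sequence

from .stack import ImageStack
from .stackio import RawSpec, load_stack, persist_stack, read_raw_stack, read_tiff_stack

MANIFEST_NAME = "mesoconn_project.json"
MANIFEST_VERSION = 1


@dataclass
class Manipulation:
    """One processing step a file has gone through: name plus parameters."""

    name: str
    params: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {"name": self.name, "params": self.params}

    @classmethod
    def from_json(cls, d: dict) -> "Manipulation":
        return cls(name=d["name"], params=dict(d.get("params", {})))


@dataclass
class FileRecord:
    """Registry entry for one stack file in the project directory."""

    path: str  # file name within the project directory (no subfolders)
    name: str
    source_stack: str | None = None
    type: str = "stack"
    fps: float = 30.0
    origin: tuple[float, float] | None = None  # per-stack origin, optional
    manipulations: list[Manipulation] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "path": self.path,
            "name": self.name,
            "source_stack": self.source_stack,
            "type": self.type,
            "fps": self.fps,
            "origin": list(self.origin) if self.origin is not None else None,
            "manipulations": [m.to_json() for m in self.manipulations],
        }

    @classmethod
    def from_json(cls, d: dict) -> "FileRecord":
        origin = d.get("origin")
        return cls(
            path=d["path"],
            name=d["name"],
            source_stack=d.get("source_stack"),
            type=d.get("type", "stack"),
            fps=float(d.get("fps", 30.0)),
            origin=tuple(origin) if origin is not None else None,
            manipulations=[Manipulation.from_json(m) for m in d.get("manipulations", [])],
        )


@dataclass
class ProjectManifest:
    """The project's registry of files, origin and pixel width."""

    project_dir: str
    um_per_px: float | None = None
    origin: tuple[float, float] | None = None
    files: list[FileRecord] = field(default_factory=list)

    # -- lookup ------------------------------------------------------------
    def find(self, name: str) -> FileRecord:
        for rec in self.files:
            if rec.name == name:
                return rec
        raise KeyError(f"no file named {name!r} in project {self.project_dir}")

    def has(self, name: str) -> bool:
        return any(rec.name == name for rec in self.files)

    def file_path(self, name: str) -> str:
        return os.path.join(self.project_dir, self.find(name).path)

    def load(self, name: str) -> ImageStack:
        rec = self.find(name)
        return load_stack(os.path.join(self.project_dir, rec.path), fps=rec.fps)

    def unique_name(self, base: str) -> str:
        if not self.has(base):
            return base
        i = 2
        while self.has(f"{base}_{i}"):
            i += 1
        return f"{base}_{i}"

    # -- persistence -------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "version": MANIFEST_VERSION,
            "um_per_px": self.um_per_px,
            "origin": list(self.origin) if self.origin is not None else None,
            "files": [rec.to_json() for rec in self.files],
        }

    def save(self) -> None:
        """Atomically rewrite the manifest JSON (write-temp-then-rename)."""
        target = os.path.join(self.project_dir, MANIFEST_NAME)
        fd, tmp = tempfile.mkstemp(
            dir=self.project_dir, prefix=".manifest-", suffix=".tmp"
        )
        try:
            with os.fdopen(fd, "w") as fh:
                json.dump(self.to_json(), fh, indent=1)
            os.replace(tmp, target)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def create_project(project_dir: str | os.PathLike) -> ProjectManifest:
    """Create (or re-open empty) a project directory with a fresh manifest."""
    project_dir = os.fspath(project_dir)
    if os.path.exists(project_dir) and not os.path.isdir(project_dir):
        raise NotADirectoryError(f"{project_dir} exists and is not a directory")
    os.makedirs(project_dir, exist_ok=True)
    manifest = ProjectManifest(project_dir=project_dir)
    manifest.save()
    return manifest


def open_project(project_dir: str | os.PathLike) -> ProjectManifest:
    """Open an existing project from its manifest JSON.

    The manifest is self-contained, so a project folder copied wholesale to
    another machine opens with all files and histories intact.
    """
    project_dir = os.fspath(project_dir)
    path = os.path.join(project_dir, MANIFEST_NAME)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no project manifest at {path}")
    with open(path) as fh:
        d = json.load(fh)
    origin = d.get("origin")
    return ProjectManifest(
        project_dir=project_dir,
        um_per_px=d.get("um_per_px"),
        origin=tuple(origin) if origin is not None else None,
        files=[FileRecord.from_json(f) for f in d.get("files", [])],
    )


def _register_import(
    manifest: ProjectManifest,
    stack: ImageStack,
    name: str,
    params: dict[str, Any],
    type_tag: str = "stack",
) -> FileRecord:
    name = manifest.unique_name(name)
    persist_stack(stack, os.path.join(manifest.project_dir, name + ".npy"))
    rec = FileRecord(
        path=name + ".npy",
        name=name,
        source_stack=name,
        type=type_tag,
        fps=stack.fps,
        manipulations=[Manipulation("import", params)],
    )
    manifest.files.append(rec)
    manifest.save()
    return rec


def import_raw(
    manifest: ProjectManifest,
    path: str | os.PathLike,
    spec: RawSpec,
    fps: float,
    name: str | None = None,
) -> FileRecord:
    """Import one channel of a RAW stack file into the project (NPY)."""
    stack = read_raw_stack(path, spec, fps)
    base = name or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return _register_import(
        manifest,
        stack,
        base,
        {
            "format": "raw",
            "source": os.path.basename(os.fspath(path)),
            "width": spec.width,
            "height": spec.height,
            "n_channels": spec.n_channels,
            "dtype": spec.dtype,
            "channel_index": spec.channel_index,
            "fps": fps,
        },
    )


def import_tiff(
    manifest: ProjectManifest,
    path: str | os.PathLike,
    channel_index: int | None = None,
    fps: float = 30.0,
    name: str | None = None,
) -> FileRecord:
    """Import a multipage TIFF stack into the project (NPY)."""
    stack = read_tiff_stack(path, channel_index=channel_index, fps=fps)
    base = name or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return _register_import(
        manifest,
        stack,
        base,
        {
            "format": "tiff",
            "source": os.path.basename(os.fspath(path)),
            "channel_index": channel_index,
            "fps": fps,
        },
    )


def record_step(
    manifest: ProjectManifest,
    in_name: str,
    step: tuple[str, dict[str, Any]] | Manipulation,
    out_stack: ImageStack,
    out_name: str | None = None,
    type_tag: str | None = None,
) -> FileRecord:
    """Persist a derived stack and record its provenance.

    The new record's manipulation list extends its source's by exactly the
    one step; the manifest is rewritten atomically.
    """
    src = manifest.find(in_name)  # KeyError for unregistered inputs
    if not isinstance(step, Manipulation):
        step = Manipulation(step[0], dict(step[1]))
    out_name = manifest.unique_name(out_name or f"{in_name}_{step.name}")
    persist_stack(out_stack, os.path.join(manifest.project_dir, out_name + ".npy"))
    rec = FileRecord(
        path=out_name + ".npy",
        name=out_name,
        source_stack=src.name,
        type=type_tag or src.type,
        fps=out_stack.fps,
        origin=src.origin,
        manipulations=src.manipulations + [step],
    )
    manifest.files.append(rec)
    manifest.save()
    return rec


def filter_files(manifest: ProjectManifest, manipulation: str) -> list[FileRecord]:
    """Files that have gone through a given manipulation, in insertion order."""
    return [
        rec
        for rec in manifest.files
        if any(m.name == manipulation for m in rec.manipulations)
    ]
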