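"""Patch descriptor files, reports, and seeded fixture generation.

The on-disk format is versioned JSON: a list of patch descriptors
``{"center": [x, y, z], "radius": R, "vertices": [[...] x3],
"sigma": [s1, s2, s3]}`` and/or a mesh block ``{"vertices": [...],
"faces": [[i, j, k], ...], "sigma": [per-vertex]}`` whose faces are
expanded to patches on load.  Angles are radians, vertex directions unit
vectors in the sphere's local frame, densities charge/length^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import SphericalTriangle

__all__ = [
    "Patch",
    "PatchFileError",
    "FixtureSpec",
    "read_patches",
    "write_patches",
    "write_report",
    "generate_fixtures",
]

SCHEMA = "sphpatch-patch/1"


class PatchFileError(ValueError):
    """Malformed patch file, with a field-level diagnostic."""


@dataclass(frozen=True)
class Patch:
    """A spherical-triangle patch with its three vertex densities."""

    tri: SphericalTriangle
    sigma: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (3,) or not np.all(np.isfinite(s)):
            raise PatchFileError("sigma must be three finite values")
        object.__setattr__(self, "sigma", s)

    def to_dict(self) -> dict:
        return {
            "center": list(self.tri.center),
            "radius": self.tri.radius,
            "vertices": [list(self.tri.v1), list(self.tri.v2), list(self.tri.v3)],
            "sigma": list(self.sigma),
        }


def _load_patch(entry: dict, where: str) -> Patch:
    for key in ("vertices", "sigma"):
        if key not in entry:
            raise PatchFileError(f"{where}: missing field {key!r}")
    verts = np.asarray(entry["vertices"], dtype=float)
    if verts.shape != (3, 3):
        raise PatchFileError(f"{where}: vertices must be 3 x 3")
    for i, v in enumerate(verts):
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise PatchFileError(
                f"{where}: vertex {i + 1} is not a unit vector "
                f"(|v| = {np.linalg.norm(v):.12g})"
            )
        # renormalize residual rounding for downstream strict checks
        verts[i] = v / np.linalg.norm(v)
    try:
        tri = SphericalTriangle(
            verts[0], verts[1], verts[2],
            center=np.asarray(entry.get("center", (0.0, 0.0, 0.0)), dtype=float),
            radius=float(entry.get("radius", 1.0)),
        )
    except ValueError as exc:
        raise PatchFileError(f"{where}: {exc}") from exc
    return Patch(tri=tri, sigma=np.asarray(entry["sigma"], dtype=float))


def read_patches(path) -> list[Patch]:
    """Load all patches (explicit descriptors plus expanded mesh faces)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != SCHEMA:
        raise PatchFileError(
            f"unsupported schema {doc.get('schema')!r}; expected {SCHEMA!r}"
        )
    patches = [
        _load_patch(entry, f"patches[{i}]")
        for i, entry in enumerate(doc.get("patches", []))
    ]
    if "mesh" in doc:
        mesh = doc["mesh"]
        verts = np.asarray(mesh["vertices"], dtype=float)
        faces = np.asarray(mesh["faces"], dtype=int)
        sig = np.asarray(mesh["sigma"], dtype=float)
        if sig.shape != (len(verts),):
            raise PatchFileError("mesh: sigma must have one value per vertex")
        if faces.min() < 0 or faces.max() >= len(verts):
            raise PatchFileError("mesh: face index out of range")
        for fi, (a, b, c) in enumerate(faces):
            patches.append(
                _load_patch(
                    {
                        "vertices": [verts[a], verts[b], verts[c]],
                        "sigma": [sig[a], sig[b], sig[c]],
                    },
                    f"mesh.faces[{fi}]",
                )
            )
    return patches


def write_patches(patches: list[Patch], path) -> None:
    doc = {"schema": SCHEMA, "patches": [p.to_dict() for p in patches]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_report(results, path) -> None:
    """JSON report writer (dict of plain values/arrays)."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, default=default)


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded random-patch generator settings (series-regime fixtures)."""

    seed: int
    n: int
    arc_range: tuple[float, float] = (0.02, 0.3)
    sigma_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self):
        lo, hi = self.arc_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("arc_range must satisfy 0 < min <= max < 0.5")


def _random_rotation(rng) -> np.ndarray:
    m = rng.standard_normal((3, 3))
    qmat, r = np.linalg.qr(m)
    qmat *= np.sign(np.diag(r))
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] *= -1.0
    return qmat


def generate_fixtures(spec: FixtureSpec) -> list[Patch]:
    """Deterministic random patches with all three side arcs in
    ``arc_range`` and uniform random vertex densities, in general
    orientation."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.arc_range
    out = []
    while len(out) < spec.n:
        b2, b3 = rng.uniform(lo, hi, size=2)
        al = rng.uniform(0.25, math.pi - 0.25)
        b1 = math.acos(
            math.cos(b2) * math.cos(b3)
            + math.sin(b2) * math.sin(b3) * math.cos(al)
        )
        if not (lo <= b1 <= hi):
            continue
        v1 = np.array([0.0, 0.0, 1.0])
        v2 = np.array([math.sin(b3), 0.0, math.cos(b3)])
        v3 = np.array(
            [
                math.sin(b2) * math.cos(al),
                math.sin(b2) * math.sin(al),
                math.cos(b2),
            ]
        )
        rot = _random_rotation(rng)
        sig = rng.uniform(*spec.sigma_range, size=3)
        out.append(
            Patch(
                tri=SphericalTriangle(rot @ v1, rot @ v2, rot @ v3),
                sigma=sig,
            )
        )
    return out
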