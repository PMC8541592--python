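"""Synthetic cell-like counting scenes with controllable domain shift.

Renders fluorescence-microscopy-style images of blob "cells" whose appearance
(colour, size, optional cytoplasm-like halo) and count range are free
parameters.  A source/target pair of :class:`SceneSpec` objects therefore
encodes the two failure axes a counting model meets in practice:

* **covariate shift** — the target scenes *look* different (colour, cell size,
  halo) while counts stay in the source range;
* **label gap** — the target count range contains values the source never
  produced (e.g. source counts in [20, 50] vs target counts in [35, 90]).

Blobs are Gaussian-profile discs placed by rejection sampling without overlap,
so the stored count is exactly the number of connected foreground components
of the noise-free render — a property the test-suite checks with an
independent connected-component labelling oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SceneSpec",
    "LabeledImageSample",
    "SceneTooCrowdedError",
    "render_scene",
    "render_clean",
    "generate_samples",
    "generate_dataset",
    "load_dataset",
    "make_shifted_pair",
    "spec_to_yaml_dict",
    "spec_from_yaml_dict",
]

SPLITS = ("train", "val", "test")

# ring radius multiplier when the cytoplasm-like halo is enabled
HALO_FACTOR = 1.5
# maximal allowed packing density of effective blob discs (area fraction)
MAX_PACKING = 0.5
BACKGROUND_LEVEL = 0.04


class SceneTooCrowdedError(RuntimeError):
    """Raised when non-overlapping blob placement fails within the retry cap."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one scene distribution (a "domain")."""

    image_size: int = 64
    count_range: tuple[int, int] = (20, 50)
    blob_radius_range: tuple[float, float] = (2.0, 3.0)
    blob_color: tuple[float, float, float] = (0.15, 0.25, 0.85)
    color_jitter: float = 0.05
    halo: bool = False
    background_noise_std: float = 0.02
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.count_range
        if not (0 <= lo <= hi):
            raise ValueError(f"count_range must satisfy 0 <= lo <= hi, got {self.count_range}")
        rmin, rmax = self.blob_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError(f"blob_radius_range must be positive, got {self.blob_radius_range}")
        if self.image_size < 8:
            raise ValueError("image_size too small")
        if not self.allow_overlap:
            # packing bound: `hi` effective discs of max radius must fit
            reff = self.effective_radius(rmax)
            if hi * np.pi * reff ** 2 > MAX_PACKING * self.image_size ** 2:
                raise ValueError(
                    f"packing bound violated: {hi} blobs of effective radius {reff:.1f} "
                    f"cannot fit in a {self.image_size}x{self.image_size} image without overlap"
                )

    def effective_radius(self, r: float) -> float:
        return r * HALO_FACTOR if self.halo else r


@dataclass
class LabeledImageSample:
    """An image, its integer count label and domain tag."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    count: int
    domain: str  # "source" | "target"
    id: str


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _place_blobs(spec: SceneSpec, count: int, rng: np.random.Generator,
                 max_tries: int = 2000):
    """Rejection-sample non-overlapping (cx, cy, r) triples."""
    rmin, rmax = spec.blob_radius_range
    placed: list[tuple[float, float, float]] = []
    for _ in range(count):
        for attempt in range(max_tries):
            r = rng.uniform(rmin, rmax)
            reff = spec.effective_radius(r)
            margin = reff + 1.0
            if 2 * margin >= spec.image_size:
                raise SceneTooCrowdedError("blob larger than image")
            cx = rng.uniform(margin, spec.image_size - margin)
            cy = rng.uniform(margin, spec.image_size - margin)
            if spec.allow_overlap:
                placed.append((cx, cy, r))
                break
            ok = True
            for px, py, pr in placed:
                mind = reff + spec.effective_radius(pr) + 1.0
                if (cx - px) ** 2 + (cy - py) ** 2 < mind ** 2:
                    ok = False
                    break
            if ok:
                placed.append((cx, cy, r))
                break
        else:
            raise SceneTooCrowdedError(
                f"could not place blob {len(placed) + 1}/{count} after {max_tries} tries"
            )
    return placed


def _draw(spec: SceneSpec, blobs, rng: np.random.Generator):
    """Render placed blobs; returns (clean image, boolean foreground mask)."""
    n = spec.image_size
    img = np.full((n, n, 3), BACKGROUND_LEVEL, dtype=np.float64)
    mask = np.zeros((n, n), dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n]
    base = np.asarray(spec.blob_color, dtype=np.float64)
    for cx, cy, r in blobs:
        color = np.clip(base + rng.normal(0.0, spec.color_jitter, 3), 0.05, 1.0)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        core = d2 <= r ** 2
        profile = np.exp(-d2 / (2.0 * (0.55 * r) ** 2))
        img[core] += color * profile[core, None]
        mask |= core
        if spec.halo:
            ring = (d2 > r ** 2) & (d2 <= (HALO_FACTOR * r) ** 2)
            halo_color = 0.35 * color + 0.15  # paler cytoplasm ring
            falloff = np.exp(-(np.sqrt(d2) - r) / (0.5 * r + 1e-9))
            img[ring] += halo_color * falloff[ring, None] * 0.6
            mask |= ring
    return np.clip(img, 0.0, 1.0), mask


def render_clean(spec: SceneSpec, count: int, seed: int):
    """Noise-free render plus its exact foreground mask (for label audits)."""
    lo, hi = spec.count_range
    if not (lo <= count <= hi):
        raise ValueError(f"count {count} outside count_range {spec.count_range}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), spec.seed, 7]))
    blobs = _place_blobs(spec, count, rng)
    img, mask = _draw(spec, blobs, rng)
    return img, mask


def render_scene(spec: SceneSpec, count: int, seed: int) -> LabeledImageSample:
    """Render one scene with exactly ``count`` blobs.

    Identical ``(spec, count, seed)`` triples give bit-identical images.
    """
    img, _ = render_clean(spec, count, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), spec.seed, 11]))
    if spec.background_noise_std > 0:
        img = img + rng.normal(0.0, spec.background_noise_std, img.shape)
    img = np.clip(img, 0.0, 1.0)
    # quantise to 8 bits so in-memory and PNG-round-tripped datasets agree
    img = np.round(img * 255.0) / 255.0
    return LabeledImageSample(image=img.astype(np.float32), count=int(count),
                              domain="source", id=f"img{seed:010d}")


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _apportion(n: int, fracs) -> list[int]:
    """Largest-remainder apportionment of n items over the split fractions."""
    fr = np.asarray(fracs, dtype=float)
    if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("split fractions must be non-negative and sum to 1")
    quota = n * fr
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    # ties broken by split order (train before val before test)
    for idx in sorted(range(len(fr)), key=lambda i: (-rem[i], i))[: n - counts.sum()]:
        counts[idx] += 1
    return counts.tolist()


def generate_samples(spec: SceneSpec, n: int,
                     split_fracs=(0.55, 0.20, 0.25),
                     domain: str = "source"):
    """Generate ``n`` samples in memory with seeded splits.

    Counts are drawn uniformly from ``spec.count_range``.  Returns a list of
    (:class:`LabeledImageSample`, split) pairs; regeneration from the same
    spec is bit-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    per_split = _apportion(n, split_fracs)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    lo, hi = spec.count_range
    counts = rng.integers(lo, hi + 1, size=n)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    order = rng.permutation(n)
    split_of = np.empty(n, dtype=object)
    start = 0
    for split, k in zip(SPLITS, per_split):
        split_of[order[start:start + k]] = split
        start += k
    out = []
    for i in range(n):
        s = render_scene(spec, int(counts[i]), int(seeds[i]))
        s.domain = domain
        s.id = f"{domain}_{i:05d}"
        out.append((s, str(split_of[i])))
    return out


def generate_dataset(spec: SceneSpec, n: int, split_fracs=(0.55, 0.20, 0.25),
                     out_dir: str | Path = ".", domain: str = "source") -> pd.DataFrame:
    """Write ``n`` PNG images plus a ``manifest.csv`` to ``out_dir``.

    The manifest has columns ``id,path,count,split`` with paths relative to
    ``out_dir``.  Returns the manifest as a DataFrame.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for sample, split in generate_samples(spec, n, split_fracs, domain=domain):
        rel = f"images/{sample.id}.png"
        arr = np.round(sample.image * 255.0).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / rel)
        rows.append({"id": sample.id, "path": rel, "count": sample.count, "split": split})
    manifest = pd.DataFrame(rows, columns=["id", "path", "count", "split"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path: str | Path, domain: str = "source"):
    """Read a manifest written by :func:`generate_dataset` back into samples."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.csv"
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    out = []
    for row in manifest.itertuples(index=False):
        arr = np.asarray(Image.open(root / row.path), dtype=np.float32) / 255.0
        out.append((LabeledImageSample(arr, int(row.count), domain, str(row.id)),
                    str(row.split)))
    return out


# ---------------------------------------------------------------------------
# domain-shift construction
# ---------------------------------------------------------------------------

_APPEARANCE_KEYS = {"blob_color", "color_jitter", "blob_radius_range", "halo"}
_LABEL_GAP_KEYS = {"count_range", "blob_radius_range"}


def make_shifted_pair(source_spec: SceneSpec,
                      appearance_shift: dict | None = None,
                      label_gap_shift: dict | None = None):
    """Build a (source, target) spec pair differing only in the given shifts.

    ``appearance_shift`` may set colour/jitter/radius/halo (covariate shift);
    ``label_gap_shift`` may replace the count range (and radius, since denser
    scenes usually need smaller cells).  Empty shifts return an identical
    target spec.
    """
    changes: dict = {}
    for shift, allowed, name in ((appearance_shift, _APPEARANCE_KEYS, "appearance_shift"),
                                 (label_gap_shift, _LABEL_GAP_KEYS, "label_gap_shift")):
        for key, val in (shift or {}).items():
            if key not in allowed:
                raise ValueError(f"{name} does not accept key {key!r}")
            changes[key] = tuple(val) if isinstance(val, list) else val
    target = dataclasses.replace(source_spec, **changes)  # re-validates invariants
    return source_spec, target


# ---------------------------------------------------------------------------
# YAML plumbing
# ---------------------------------------------------------------------------

def spec_to_yaml_dict(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["count_range"] = list(d["count_range"])
    d["blob_radius_range"] = list(d["blob_radius_range"])
    d["blob_color"] = list(d["blob_color"])
    return d


def spec_from_yaml_dict(d: dict) -> SceneSpec:
    fields = {f.name for f in dataclasses.fields(SceneSpec)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown SceneSpec keys: {sorted(unknown)}")
    missing = {"count_range"} - set(d)
    if missing:
        raise ValueError(f"missing SceneSpec keys: {sorted(missing)}")
    kw = dict(d)
    for key in ("count_range", "blob_radius_range", "blob_color"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return SceneSpec(**kw)
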