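"""Synthetic standardized embryo-like images with term-linked patterns.

Real embryo in-situ images arrive pre-scaled and pre-aligned on a common
canvas, with expression confined to reproducible anatomical locations; a
controlled-vocabulary term then names each localized structure. This module
emulates exactly that statistical structure so the whole annotation/retrieval
pipeline is testable without any external image collection:

* a fixed-size 8-bit canvas holding an elliptical "embryo" mask (background
  is exactly 0 outside the ellipse);
* hard-edged expression patterns (stripes, bands, spots, gradients) placed in
  embryo-normalized coordinates, so a pattern keeps its meaning relative to
  the spatial pooling grid across every image;
* a one-to-one term-to-pattern mapping: a group is labelled with a term iff
  its images render that term's pattern;
* optional per-image positional jitter and additive Gaussian noise standing
  in for biological and imaging variability.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

DEFAULT_CANVAS = (192, 96)  # (width, height): embryo-like 2:1 aspect
DEFAULT_AXES = (88.0, 40.0)  # (semi-major, semi-minor) in pixels
BASE_INTENSITY = 40.0
PATTERN_INTENSITY = 150.0

PATTERN_KINDS = frozenset({"stripe", "band", "spot", "gradient"})


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of one expression pattern, in embryo-normalized [0,1]² coords.

    kind:
      stripe   — ``n`` vertical stripes of width ``width``, evenly placed at
                 (i+0.5)/n unless explicit ``positions`` are given
      band     — one broad region: |coord(axis) − center| < width/2
      spot     — disk in normalized coords: (nx−cx)² + (ny−cy)² < radius²
      gradient — smooth ramp along ``axis`` (intensity ∝ coordinate)
    """

    kind: str
    n: int = 3
    width: float = 0.08
    positions: tuple[float, ...] | None = None
    axis: str = "x"
    center: tuple[float, float] | float = 0.5
    radius: float = 0.1

    def __post_init__(self):
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")

    def stripe_positions(self) -> tuple[float, ...]:
        if self.positions is not None:
            return self.positions
        return tuple((i + 0.5) / self.n for i in range(self.n))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic image collection."""

    canvas_width: int = DEFAULT_CANVAS[0]
    canvas_height: int = DEFAULT_CANVAS[1]
    embryo_axes: tuple[float, float] = DEFAULT_AXES
    patterns: Mapping[str, PatternSpec] = field(default_factory=dict)
    noise_sd: float = 0.0
    jitter_sd: float = 0.0  # per-image positional jitter, normalized units
    base_intensity: float = BASE_INTENSITY
    pattern_intensity: float = PATTERN_INTENSITY
    seed: int = 0

    def __post_init__(self):
        a, b = self.embryo_axes
        if 2 * a > self.canvas_width or 2 * b > self.canvas_height:
            raise ValueError("embryo ellipse does not fit the canvas")
        if self.canvas_width < 32 or self.canvas_height < 32:
            raise ValueError("canvas too small for downstream patches")


@dataclass
class LabeledGroupSet:
    """Image groups with their multi-term labels.

    groups: list of (group_id, list of images); every group has >= 1 image
    and all images share the canvas dimensions. labels maps group_id to the
    set of term names its images carry.
    """

    groups: list[tuple[str, list[np.ndarray]]]
    labels: dict[str, set[str]]

    @property
    def term_frequencies(self) -> dict[str, int]:
        freq: dict[str, int] = {}
        for terms in self.labels.values():
            for t in terms:
                freq[t] = freq.get(t, 0) + 1
        return freq

    @property
    def group_ids(self) -> list[str]:
        return [gid for gid, _ in self.groups]


def default_term_catalog() -> dict[str, PatternSpec]:
    """Four spatially localized patterns, one per synthetic term.

    The locations are chosen to occupy distinct regions of the embryo so that
    a spatial pooling grid can in principle separate them.
    """
    return {
        "stripes3": PatternSpec(kind="stripe", n=3, width=0.07),
        "anterior_spot": PatternSpec(kind="spot", center=(0.18, 0.5), radius=0.12),
        "posterior_band": PatternSpec(kind="band", axis="x", center=0.82, width=0.16),
        "dorsal_band": PatternSpec(kind="band", axis="y", center=0.22, width=0.20),
    }


def retrieval_term_catalog() -> dict[str, PatternSpec]:
    """Five distinct single-pattern classes for retrieval evaluation."""
    cat = default_term_catalog()
    cat["ventral_band"] = PatternSpec(kind="band", axis="y", center=0.78, width=0.20)
    return cat


def _embryo_geometry(spec: SyntheticSpec):
    w, h = spec.canvas_width, spec.canvas_height
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a, b = spec.embryo_axes
    x = np.arange(w)[None, :]
    y = np.arange(h)[:, None]
    mask = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
    # normalized coords over the embryo bounding box
    nx = (x - (cx - a)) / (2.0 * a) * np.ones_like(y, dtype=float)
    ny = (y - (cy - b)) / (2.0 * b) * np.ones_like(x, dtype=float)
    return mask, nx, ny


def _render_pattern(p: PatternSpec, nx, ny, offset=(0.0, 0.0)) -> np.ndarray:
    """Pattern activation in [0,1] on the normalized-coordinate grid."""
    ox, oy = offset
    if p.kind == "stripe":
        out = np.zeros_like(nx)
        for pos in p.stripe_positions():
            out = np.maximum(out, (np.abs(nx - (pos + ox)) < p.width / 2).astype(float))
        return out
    if p.kind == "band":
        coord, off = (nx, ox) if p.axis == "x" else (ny, oy)
        c = p.center if np.isscalar(p.center) else p.center[0]
        return (np.abs(coord - (c + off)) < p.width / 2).astype(float)
    if p.kind == "spot":
        cx, cy = p.center
        return ((nx - (cx + ox)) ** 2 + (ny - (cy + oy)) ** 2 < p.radius ** 2).astype(float)
    if p.kind == "gradient":
        coord = nx if p.axis == "x" else ny
        return np.clip(coord + (ox if p.axis == "x" else oy), 0.0, 1.0)
    raise ValueError(f"unknown pattern kind {p.kind!r}")  # pragma: no cover


def generate_image(spec: SyntheticSpec, active_terms: Sequence[str] | set,
                   seed: int | None = None) -> np.ndarray:
    """Render one 8-bit grayscale image with the given terms' patterns.

    Background outside the embryo ellipse is exactly 0; inside, intensity is
    ``base_intensity`` plus ``pattern_intensity`` times the maximum active
    pattern activation, plus clipped Gaussian noise (inside the mask only).
    """
    for t in active_terms:
        if t not in spec.patterns:
            raise ValueError(f"unknown term {t!r}: not in the configured pattern catalog")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask, nx, ny = _embryo_geometry(spec)

    activation = np.zeros_like(nx)
    for t in sorted(active_terms):  # sorted: seed-stable jitter draw order
        off = (0.0, 0.0)
        if spec.jitter_sd > 0:
            off = tuple(rng.normal(0.0, spec.jitter_sd, size=2))
        activation = np.maximum(activation, _render_pattern(spec.patterns[t], nx, ny, off))

    img = (spec.base_intensity + spec.pattern_intensity * activation) * mask
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape) * mask
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_group_set(
    spec: SyntheticSpec,
    n_groups: int,
    images_per_group: int,
    term_catalog: Sequence[str],
    prevalence: Mapping[str, float],
    seed: int,
) -> LabeledGroupSet:
    """Draw each group's term set independently per term, then render images.

    All images of a group share the group's term set (differing only by
    noise/jitter). Deterministic under a fixed seed.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups (downstream splits are impossible otherwise)")
    if images_per_group < 1:
        raise ValueError("images_per_group must be >= 1")
    for t in term_catalog:
        p = prevalence[t]
        if not (0.0 < p <= 1.0):
            raise ValueError(f"prevalence for {t!r} must be in (0, 1], got {p}")

    rng = np.random.default_rng(seed)
    groups: list[tuple[str, list[np.ndarray]]] = []
    labels: dict[str, set[str]] = {}
    width = len(str(n_groups - 1))
    for g in range(n_groups):
        gid = f"g{g:0{width}d}"
        terms = {t for t in term_catalog if rng.random() < prevalence[t]}
        imgs = [
            generate_image(spec, terms, seed=int(rng.integers(2 ** 31)))
            for _ in range(images_per_group)
        ]
        groups.append((gid, imgs))
        labels[gid] = terms
    return LabeledGroupSet(groups=groups, labels=labels)


def generate_pattern_clusters(
    spec: SyntheticSpec,
    terms: Sequence[str],
    images_per_cluster: int,
    seed: int,
) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Flat image set of single-pattern clusters, for retrieval evaluation.

    Returns (images, image_ids, cluster_term_per_image). Every image in a
    cluster renders the same single term, varying only by jitter and noise.
    """
    rng = np.random.default_rng(seed)
    images, ids, cluster = [], [], []
    for t in terms:
        if t not in spec.patterns:
            raise ValueError(f"unknown term {t!r}: not in the configured pattern catalog")
        for i in range(images_per_cluster):
            images.append(generate_image(spec, {t}, seed=int(rng.integers(2 ** 31))))
            ids.append(f"{t}_{i:03d}")
            cluster.append(t)
    return images, ids, cluster


def write_group_set(group_set: LabeledGroupSet, outdir: str | Path) -> None:
    """PNG per image under <outdir>/<group_id>/<idx>.png, plus labels.csv
    with one (group_id, term) row per label."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gid, imgs in group_set.groups:
        gdir = outdir / gid
        gdir.mkdir(exist_ok=True)
        for i, img in enumerate(imgs):
            Image.fromarray(img, mode="L").save(gdir / f"{i}.png")
    with open(outdir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_id", "term"])
        for gid, _ in group_set.groups:
            for t in sorted(group_set.labels[gid]):
                writer.writerow([gid, t])


def load_group_set(indir: str | Path) -> LabeledGroupSet:
    """Inverse of :func:`write_group_set` (images read as 8-bit grayscale)."""
    indir = Path(indir)
    labels: dict[str, set[str]] = {}
    with open(indir / "labels.csv", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["group_id", "term"]:
            raise ValueError("labels.csv must have columns group_id,term")
        for gid, term in reader:
            labels.setdefault(gid, set()).add(term)
    groups = []
    for gdir in sorted(p for p in indir.iterdir() if p.is_dir()):
        imgs = [
            np.asarray(Image.open(p).convert("L"))
            for p in sorted(gdir.glob("*.png"), key=lambda p: int(p.stem))
        ]
        if imgs:
            groups.append((gdir.name, imgs))
            labels.setdefault(gdir.name, set())
    return LabeledGroupSet(groups=groups, labels=labels)


def with_noise(spec: SyntheticSpec, noise_sd: float) -> SyntheticSpec:
    return replace(spec, noise_sd=noise_sd)
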