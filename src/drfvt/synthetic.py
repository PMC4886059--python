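"""Synthetic silhouette generation for benchmarks and tests.

Organ-like categories are defined as harmonic signatures of a radial
outline function

    r(phi) = r0 * (1 + sum_h a_h cos(h*phi + psi_h)),

rasterized as filled silhouettes.  Six templates stand in for labelled
categories of closed organ silhouettes (body, heart, lung, ovary, kidney,
liver); models within a category share the template with seeded jitter of
the harmonic amplitudes and phases, so category members are correlated in
their low harmonics but individually distinct.  Perturbations emulate the
sketch distortions a retrieval method must tolerate: anisotropic
"widening", a boundary "cut" (notch), and smooth radial jitter.

All randomness flows through explicitly seeded ``numpy`` generators; the
same spec and seed always reproduce identical image bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .contour import trace_outline
from .images import save_silhouette

__all__ = [
    "ShapeSpec",
    "CATEGORY_TEMPLATES",
    "generate_shape",
    "perturb",
    "generate_benchmark",
]

#: Harmonic signatures (harmonic, amplitude, phase) per category.  Chosen
#: so every radius function stays positive (amplitudes sum < 1), templates
#: are mutually well separated, and each shape has a unique global radius
#: minimum (no left-right symmetric double minimum — freehand outlines are
#: never perfectly symmetric either).  The body template stacks harmonics
#: whose minima all align on the vertical image axis, producing a single
#: sharp notch there like the crotch/neck region of an upright figure:
#: horizontal widening leaves that minimum-radius anchor in place, and
#: the notch keeps the anchor stable under redraw noise, as for a real
#: body outline.
CATEGORY_TEMPLATES: dict[str, tuple[tuple[int, float, float], ...]] = {
    "body": ((2, 0.22, 0.0), (3, 0.12, 4.71), (5, 0.07, 1.57), (7, 0.04, 4.71)),
    "heart": ((2, 0.18, 1.3), (3, 0.20, 0.5)),
    "lung": ((2, 0.35, 0.0), (4, 0.10, 0.7)),
    "ovary": ((2, 0.05, 0.0),),
    "kidney": ((1, 0.22, 0.0), (2, 0.10, 2.2), (4, 0.08, 1.0)),
    "liver": ((2, 0.08, 5.2), (3, 0.22, 4.0), (4, 0.15, 2.0)),
}
# Every template carries an h=2 (ellipticity) component: the radial h=2
# harmonic is what feeds the Z_{-1} outline coefficient, whose phase
# anchors the start-point normalization; a template without it would
# leave that phase reference to rasterization noise.  Real organ
# silhouettes are never ellipticity-free.

#: Default perturbation magnitudes (anisotropic widening factor - 1, and
#: boundary fraction covered by a cut).
DEFAULT_WIDEN_MAGNITUDE = 0.2
DEFAULT_CUT_MAGNITUDE = 0.1

#: A "cut" clips outline radii inside its wedge to this fraction of the
#: wedge's maximum radius: it truncates a protruding part of the
#: silhouette (an arm, a lobe) rather than gouging below the shape's
#: natural minimum radius, which is what cutting a drawn figure does.
_CUT_CLIP_FRACTION = 0.75

#: Outline sampling density used for rasterization.
_OUTLINE_SAMPLES = 720


@dataclass
class ShapeSpec:
    """Recipe for one synthetic silhouette.

    ``family`` is one of ``circle``, ``ellipse``, ``superellipse``,
    ``fourier_blob`` or ``body_like``; ``params`` carries the family
    parameters (radii, aspect, harmonics, jitter); ``size`` is the square
    image side in pixels (>= 32); ``seed`` drives the jitter RNG.
    """

    family: str
    params: dict = field(default_factory=dict)
    size: int = 128
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("image side must be >= 32 pixels")


def _radius_function(spec: ShapeSpec, phi: np.ndarray) -> np.ndarray:
    p = spec.params
    if spec.family == "circle":
        return np.full_like(phi, float(p.get("radius", spec.size * 0.3)))
    if spec.family == "ellipse":
        a = float(p.get("a", spec.size * 0.35))
        b = float(p.get("b", spec.size * 0.22))
        return (a * b) / np.hypot(b * np.cos(phi), a * np.sin(phi))
    if spec.family == "superellipse":
        a = float(p.get("a", spec.size * 0.35))
        b = float(p.get("b", spec.size * 0.25))
        e = float(p.get("exponent", 4.0))
        return (np.abs(np.cos(phi) / a) ** e
                + np.abs(np.sin(phi) / b) ** e) ** (-1.0 / e)
    if spec.family in ("fourier_blob", "body_like"):
        r0 = float(p.get("r0", spec.size * 0.3))
        harmonics = p.get("harmonics")
        if harmonics is None:
            harmonics = CATEGORY_TEMPLATES["body"]
        jitter = float(p.get("jitter", 0.0))
        harmonics = [(int(h), float(a), float(psi)) for h, a, psi in harmonics]
        if jitter > 0.0:
            rng = np.random.default_rng(spec.seed)
            harmonics = [
                (h, a * (1.0 + jitter * rng.standard_normal()),
                 psi + jitter * rng.standard_normal())
                for h, a, psi in harmonics
            ]
        r = np.full_like(phi, 1.0)
        for h, a, psi in harmonics:
            r += a * np.cos(h * phi + psi)
        r *= r0
        if np.min(r) <= 0.0:
            raise ValueError("harmonic amplitudes drive r(phi) <= 0; "
                             "the outline would not be a simple closed curve")
        return r
    raise ValueError(f"unknown shape family: {spec.family!r}")


def continuous_outline(spec: ShapeSpec,
                       n_samples: int = _OUTLINE_SAMPLES) -> np.ndarray:
    """Exact (pre-rasterization) outline samples as ``x + i*y``.

    Points are centred at the pixel-grid centre ``(size-1)/2`` and listed
    counterclockwise in plane coordinates.
    """
    phi = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    r = _radius_function(spec, phi)
    centre = (spec.size - 1) / 2.0
    return (centre + r * np.cos(phi)) + 1j * (centre + r * np.sin(phi))


def _rasterize(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    img = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(points.imag, points.real, shape=shape)
    img[rr, cc] = True
    return img


def generate_shape(spec: ShapeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a spec into a filled silhouette.

    Returns ``(image, outline)``: the boolean mask and the exact
    continuous outline samples used to draw it (for rasterization-free
    invariance tests).  Deterministic given ``spec.seed``.
    """
    outline = continuous_outline(spec)
    return _rasterize(outline, (spec.size, spec.size)), outline


def _outline_of(source) -> tuple[np.ndarray, tuple[int, int]]:
    """Outline points and canvas shape for a spec or a binary image."""
    if isinstance(source, ShapeSpec):
        return continuous_outline(source), (source.size, source.size)
    img = np.asarray(source, dtype=bool)
    return trace_outline(img).as_complex(), img.shape


def _cut_wedge(rel: np.ndarray, wedge: np.ndarray) -> np.ndarray:
    """Truncate centred outline points inside an angular wedge.

    Radii in the wedge are clipped to ``_CUT_CLIP_FRACTION`` of the
    wedge's maximum radius, removing the protruding outer part.
    """
    if not wedge.any():
        return rel
    rad = np.abs(rel)
    cap = _CUT_CLIP_FRACTION * rad[wedge].max()
    scale = np.ones_like(rad)
    outer = wedge & (rad > cap)
    scale[outer] = cap / rad[outer]
    return rel * scale


def _smooth_radial_noise(phi: np.ndarray, rng: np.random.Generator,
                         n_harmonics: int = 6) -> np.ndarray:
    """Unit-scale smooth noise as a random low-order harmonic series."""
    noise = np.zeros_like(phi)
    amps = rng.standard_normal(n_harmonics) / np.sqrt(n_harmonics)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_harmonics)
    for h in range(1, n_harmonics + 1):
        noise += amps[h - 1] * np.cos(h * phi + phases[h - 1])
    return noise


def perturb(source, mode: str, magnitude: float,
            seed: int | None = None) -> np.ndarray:
    """Produce a perturbed silhouette image.

    ``source`` is a :class:`ShapeSpec` (perturbation applied to the exact
    outline) or a binary image (outline traced first).  Modes:

    ``widen``
        Anisotropic horizontal scaling by ``1 + magnitude`` about the
        centroid; the canvas widens to fit.
    ``cut``
        Truncation of a boundary-adjacent sector: inside an angular
        wedge covering ``magnitude`` of the boundary, outline radii are
        clipped to 75% of the wedge's maximum radius, cutting off the
        protruding outer part (wedge centre seeded).
    ``jitter``
        Smooth multiplicative radial noise of relative amplitude
        ``magnitude`` (random low-order harmonic series, seeded).

    ``magnitude`` must lie in ``(0, 0.5]``; results are deterministic
    given ``seed``.
    """
    if not 0.0 < magnitude <= 0.5:
        raise ValueError("magnitude must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    points, (h, w) = _outline_of(source)
    centroid = points.mean()
    rel = points - centroid

    if mode == "widen":
        rel = rel.real * (1.0 + magnitude) + 1j * rel.imag
        new_w = int(np.ceil(w * (1.0 + magnitude))) + 2
        centre = complex((new_w - 1) / 2.0, (h - 1) / 2.0)
        return _rasterize(centre + rel, (h, new_w))

    phi = np.angle(rel)
    if mode == "cut":
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        diff = np.angle(np.exp(1j * (phi - phi0)))
        rel = _cut_wedge(rel, np.abs(diff) <= np.pi * magnitude)
    elif mode == "jitter":
        rel = rel * (1.0 + magnitude * _smooth_radial_noise(phi, rng))
    else:
        raise ValueError(f"unknown perturbation mode: {mode!r}")
    return _rasterize(centroid + rel, (h, w))


#: Perturbation mode applied to view v (cycled): none, widen, cut.
_VIEW_MODES = (None, "widen", "cut")


def _render_view(spec: ShapeSpec, noise: float, mode: str | None,
                 rng: np.random.Generator) -> np.ndarray:
    """Rasterize one benchmark view of a base shape.

    A view emulates how the same object re-enters the system as a sketch
    or another projection: the base outline is rotated by a random angle
    about its centroid, its radii perturbed by smooth jitter of amplitude
    ``noise``, and optionally widened or cut at the default magnitudes.
    """
    outline = continuous_outline(spec)
    centroid = outline.mean()
    rel = (outline - centroid) * np.exp(1j * rng.uniform(0.0, 2.0 * np.pi))
    phi = np.angle(rel)
    rel = rel * (1.0 + noise * _smooth_radial_noise(phi, rng))
    if mode == "widen":
        rel = rel.real * (1.0 + DEFAULT_WIDEN_MAGNITUDE) + 1j * rel.imag
    elif mode == "cut":
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        diff = np.angle(np.exp(1j * (np.angle(rel) - phi0)))
        rel = _cut_wedge(rel, np.abs(diff) <= np.pi * DEFAULT_CUT_MAGNITUDE)
    return _rasterize(centroid + rel, (spec.size, spec.size))


def generate_benchmark(out_dir, n_categories: int = 6, n_models: int = 5,
                       n_views: int = 3, noise: float = 0.05, seed: int = 0,
                       size: int = 128, model_jitter: float = 0.08) -> Path:
    """Write a labelled silhouette benchmark and its manifest CSV.

    Creates ``n_categories * n_models * n_views`` PNG silhouettes under
    ``out_dir`` plus ``manifest.csv`` with columns ``model_id, category,
    view_id, image_path`` (paths relative to the manifest).  With
    ``noise > 0``, views of one model are randomly rotated, radially
    jittered (amplitude ``noise``) variants of the same base shape, and
    the second and third view of each model additionally carry the
    default widening and cutting distortions (cycled for further views);
    ``noise = 0`` disables all view-level variation, making all views of
    a model identical (the separable, noise-free setting).
    ``model_jitter`` sets the within-category template jitter.
    Deterministic given ``seed``; returns the manifest path.
    """
    if n_categories < 2 or n_models < 2:
        raise ValueError("need at least 2 categories and 2 models each")
    if n_categories > len(CATEGORY_TEMPLATES):
        raise ValueError(f"at most {len(CATEGORY_TEMPLATES)} categories available")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    categories = list(CATEGORY_TEMPLATES)[:n_categories]
    rows = []
    for ci, cat in enumerate(categories):
        for mi in range(n_models):
            model_seed = int(
                np.random.SeedSequence([seed, ci, mi]).generate_state(1)[0]
                % (2 ** 31))
            # r0 = size/4 leaves headroom for rotation plus widening
            # (max radius ~ 0.25 * 1.43 * 1.2 = 0.43 of the side).
            spec = ShapeSpec(
                "fourier_blob",
                {"r0": 0.25 * size, "harmonics": CATEGORY_TEMPLATES[cat],
                 "jitter": model_jitter},
                size=size, seed=model_seed)
            model_id = f"{cat}_{mi:02d}"
            for vi in range(n_views):
                if noise == 0.0:
                    img, _ = generate_shape(spec)
                else:
                    view_seed = int(
                        np.random.SeedSequence([seed, ci, mi, vi])
                        .generate_state(1)[0] % (2 ** 31))
                    img = _render_view(spec, noise,
                                       _VIEW_MODES[vi % len(_VIEW_MODES)],
                                       np.random.default_rng(view_seed))
                name = f"{model_id}_v{vi}.png"
                save_silhouette(img, out_dir / name)
                rows.append({"model_id": model_id, "category": cat,
                             "view_id": f"v{vi}", "image_path": name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
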