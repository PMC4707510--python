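"""Synthetic brightfield spheroid phantoms with analytic ground truth.

Real spheroid micrographs come without volumetric ground truth, so every
stage of the pipeline is validated on phantoms: solids of revolution with
closed-form volumes (sphere, prolate ellipsoid, two-sphere union, sphere
with a surface bud) rendered with the appearance of a brightfield image —
dark roughly convex body, darker core, thin bright halo at the boundary,
uniform bright background, additive Gaussian noise, and an optional linear
illumination gradient.

Rasterization rule
------------------
A pixel belongs to the truth mask iff its *center* lies inside the
continuous silhouette. Pixel centers sit at integer ``(row, col)``
coordinates; physical coordinates are measured from the image center in μm.

Determinism
-----------
An identical ``PhantomSpec`` (including its ``seed``) produces bit-identical
images. Plate fixtures derive one RNG stream per well from
``(plate seed, well index)`` so wells are independent and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import BinaryMask, GrayImage, SpheromorphError

__all__ = [
    "PhantomError",
    "Appearance",
    "PhantomSpec",
    "Phantom",
    "lens_volume",
    "sphere_volume",
    "ellipsoid_volume",
    "make_phantom",
    "render_brightfield",
    "make_plate_fixture",
    "make_planted_plate",
    "PLATE_WELLS",
]

KINDS = ("sphere", "ellipsoid", "twolobe", "budding")

#: Canonical 96-well coordinates in row-major (A1 ... H12) order.
PLATE_WELLS: tuple[str, ...] = tuple(
    f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)
)


class PhantomError(SpheromorphError):
    pass


# ---------------------------------------------------------------------------
# analytic volumes
# ---------------------------------------------------------------------------

def sphere_volume(r: float) -> float:
    """Volume of a sphere of radius ``r`` (same cubed unit as ``r``)."""
    return 4.0 / 3.0 * math.pi * r**3


def ellipsoid_volume(a: float, b: float) -> float:
    """Prolate ellipsoid of revolution about the major axis: V = 4/3·π·a·b²."""
    return 4.0 / 3.0 * math.pi * a * b * b


def lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection (lens) of two spheres.

    Spheres of radii ``r1`` and ``r2`` with centers ``d`` apart. Handles the
    disjoint (``d ≥ r1+r2``) and contained (``d ≤ |r1−r2|``) limits.
    """
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return sphere_volume(min(r1, r2))
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
        / (12.0 * d)
    )


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Appearance:
    """Brightfield rendering levels on an 8-bit scale.

    Defaults make Otsu-style segmentation nontrivial but reliable: bright
    background (230), dark body (110), darker core (60), a thin bright halo
    (+20 tapering over 3 px just outside the boundary), additive Gaussian
    noise (SD 6) and an optional linear illumination gradient
    (intensity units per pixel along the column axis).
    """

    background: float = 230.0
    body: float = 110.0
    core: float = 60.0
    core_fraction: float = 0.5
    halo_width: float = 3.0
    halo_gain: float = 20.0
    noise_sd: float = 6.0
    gradient_slope: float = 0.0

    def validate(self) -> None:
        if not (self.core <= self.body < self.background):
            raise PhantomError("invalid spec: levels must order core <= body < background")
        if not (0.0 <= self.core_fraction < 1.0):
            raise PhantomError("invalid spec: core_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.halo_width < 0:
            raise PhantomError("invalid spec: negative noise or halo width")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry (μm) + appearance + raster parameters for one phantom.

    Geometry fields by ``kind``:

    * ``sphere``   — ``radius``
    * ``ellipsoid``— ``semi_major`` (a), ``semi_minor`` (b ≤ a), ``angle``
      (in-plane orientation of the major axis, radians)
    * ``twolobe``  — ``r1``, ``r2``, ``center_distance`` with
      ``|r1−r2| < center_distance < r1+r2``
    * ``budding``  — ``body_radius``, ``bud_radius ≤ 0.35·body_radius``;
      the bud center lies on the body surface at ``bud_angle``.
    """

    kind: str
    pixel_size: float = 4.4
    side: int = 256
    seed: int = 0
    appearance: Appearance = field(default_factory=Appearance)
    radius: float | None = None
    semi_major: float | None = None
    semi_minor: float | None = None
    angle: float = 0.0
    r1: float | None = None
    r2: float | None = None
    center_distance: float | None = None
    body_radius: float | None = None
    bud_radius: float | None = None
    bud_angle: float = 0.0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.kind not in KINDS:
            raise PhantomError(f"invalid spec: unknown kind {self.kind!r}")
        if self.pixel_size <= 0 or not math.isfinite(self.pixel_size):
            raise PhantomError("invalid spec: pixel_size must be positive")
        if self.side < 16:
            raise PhantomError("invalid spec: image side too small")
        self.appearance.validate()
        for name in self._required_fields():
            v = getattr(self, name)
            if v is None or v <= 0 or not math.isfinite(v):
                raise PhantomError(f"invalid spec: {name} must be positive")
        if self.kind == "ellipsoid" and self.semi_minor > self.semi_major:  # type: ignore[operator]
            raise PhantomError("invalid spec: require semi_major >= semi_minor")
        if self.kind == "twolobe":
            r1, r2, c = self.r1, self.r2, self.center_distance
            if not (abs(r1 - r2) < c < r1 + r2):  # type: ignore[operator]
                raise PhantomError("invalid spec: require |r1-r2| < center_distance < r1+r2")
        if self.kind == "budding" and self.bud_radius > 0.35 * self.body_radius:  # type: ignore[operator]
            raise PhantomError("invalid spec: bud_radius must be <= 0.35*body_radius")
        # silhouette must fit with a 5-pixel margin
        half_extent_px = self._half_extent_um() / self.pixel_size
        if half_extent_px > (self.side - 1) / 2.0 - 5.0:
            raise PhantomError("frame overflow")

    def _required_fields(self) -> tuple[str, ...]:
        return {
            "sphere": ("radius",),
            "ellipsoid": ("semi_major", "semi_minor"),
            "twolobe": ("r1", "r2", "center_distance"),
            "budding": ("body_radius", "bud_radius"),
        }[self.kind]

    # -- geometry -----------------------------------------------------------
    def _centers_radii(self) -> list[tuple[float, float, float]]:
        """Disk components of the silhouette as (x_um, y_um, radius_um).

        The compound shapes are recentered so the union bounding box is
        centered on the image. Only meaningful for non-ellipsoid kinds.
        """
        if self.kind == "sphere":
            return [(0.0, 0.0, float(self.radius))]
        if self.kind == "twolobe":
            r1, r2, c = float(self.r1), float(self.r2), float(self.center_distance)
            shift = (r2 - r1) / 2.0  # center the x bounding interval
            return [(-c / 2.0 - shift, 0.0, r1), (c / 2.0 - shift, 0.0, r2)]
        if self.kind == "budding":
            R, rb = float(self.body_radius), float(self.bud_radius)
            bx = R * math.cos(self.bud_angle)
            by = R * math.sin(self.bud_angle)
            xs = [-R, R, bx - rb, bx + rb]
            ys = [-R, R, by - rb, by + rb]
            sx = (max(xs) + min(xs)) / 2.0
            sy = (max(ys) + min(ys)) / 2.0
            return [(-sx, -sy, R), (bx - sx, by - sy, rb)]
        raise PhantomError("ellipsoid has no disk decomposition")

    def _half_extent_um(self) -> float:
        if self.kind == "ellipsoid":
            return float(self.semi_major)
        return max(math.hypot(x, y) + r for x, y, r in self._centers_radii())

    def _inside(self, x: np.ndarray, y: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Pixel-center membership in the (optionally shrunken) silhouette."""
        if self.kind == "ellipsoid":
            a = float(self.semi_major) * scale
            b = float(self.semi_minor) * scale
            ca, sa = math.cos(self.angle), math.sin(self.angle)
            u = (x * ca + y * sa) / a
            v = (-x * sa + y * ca) / b
            return u * u + v * v <= 1.0
        out = np.zeros(x.shape, dtype=bool)
        for cx, cy, r in self._centers_radii():
            out |= (x - cx) ** 2 + (y - cy) ** 2 <= (r * scale) ** 2
        return out

    def rasterize(self, scale: float = 1.0) -> np.ndarray:
        """Boolean silhouette mask with the pixel-center-in-region rule."""
        n = self.side
        half = (n - 1) / 2.0
        idx = (np.arange(n) - half) * self.pixel_size
        x, y = np.meshgrid(idx, idx)  # x along columns, y along rows
        return self._inside(x, y, scale)

    # -- truth --------------------------------------------------------------
    def analytic_volume(self) -> float:
        """Closed-form volume (μm³) of the 3D geometry."""
        if self.kind == "sphere":
            return sphere_volume(float(self.radius))
        if self.kind == "ellipsoid":
            return ellipsoid_volume(float(self.semi_major), float(self.semi_minor))
        if self.kind == "twolobe":
            r1, r2, c = float(self.r1), float(self.r2), float(self.center_distance)
            return sphere_volume(r1) + sphere_volume(r2) - lens_volume(r1, r2, c)
        R, rb = float(self.body_radius), float(self.bud_radius)
        return sphere_volume(R) + sphere_volume(rb) - lens_volume(R, rb, R)

    @property
    def truth_class(self) -> str:
        return {
            "sphere": "spherical",
            "ellipsoid": "ellipsoidal",
            "twolobe": "figure8",
            "budding": "irregular",
        }[self.kind]


@dataclass
class Phantom:
    """A rendered phantom with its exact mask and analytic truth."""

    image: GrayImage
    truth_mask: BinaryMask
    truth_volume: float  # μm³
    truth_class: str
    spec: PhantomSpec

    @property
    def truth_volume_mm3(self) -> float:
        return self.truth_volume * 1e-9


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_brightfield(
    mask: np.ndarray,
    appearance: Appearance,
    seed: int,
    pixel_size: float,
    core_mask: np.ndarray | None = None,
) -> GrayImage:
    """Render a brightfield-style image of a silhouette mask.

    Background at ``appearance.background``, interior at ``appearance.body``,
    an (optional) darker core, a bright halo tapering linearly over
    ``halo_width`` px just outside the boundary, then an illumination
    gradient along columns and additive Gaussian noise. Deterministic per
    ``seed``.
    """
    appearance.validate()
    mask = np.asarray(mask, dtype=bool)
    img = np.full(mask.shape, float(appearance.background))
    if appearance.halo_gain != 0 and appearance.halo_width > 0:
        dist = ndimage.distance_transform_edt(~mask)
        taper = np.clip(1.0 - (dist - 1.0) / appearance.halo_width, 0.0, 1.0)
        ring = (~mask) & (dist <= appearance.halo_width + 1.0)
        img[ring] += appearance.halo_gain * taper[ring]
    img[mask] = appearance.body
    if core_mask is not None:
        img[np.asarray(core_mask, dtype=bool)] = appearance.core
    if appearance.gradient_slope != 0.0:
        cols = np.arange(mask.shape[1]) - (mask.shape[1] - 1) / 2.0
        img += appearance.gradient_slope * cols[None, :]
    if appearance.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, appearance.noise_sd, size=mask.shape)
    return GrayImage(img, pixel_size, source=f"phantom(seed={seed})")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build a phantom: exact truth mask, rendered image, analytic volume."""
    spec.validate()
    mask = spec.rasterize()
    core = None
    app = spec.appearance
    if app.core_fraction > 0 and app.core < app.body:
        core = spec.rasterize(scale=app.core_fraction)
    image = render_brightfield(mask, app, spec.seed, spec.pixel_size, core_mask=core)
    return Phantom(
        image=image,
        truth_mask=BinaryMask(mask, spec.pixel_size),
        truth_volume=spec.analytic_volume(),
        truth_class=spec.truth_class,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# plate fixtures
# ---------------------------------------------------------------------------

# study conditions: ~70% of colonies spheroidize into the spherical class;
# selected populations sit around 0.112 mm³
DEFAULT_CLASS_MIX = {"sphere": 0.7, "ellipsoid": 0.1, "twolobe": 0.1, "budding": 0.1}
DEFAULT_VOLUME_DISTRIBUTION = ("lognormal", math.log(0.112), 0.3)

# unit-volume coefficients for compound shapes (r = (V / u)^(1/3))
_TWOLOBE_SEP = 1.95  # center distance in lobe radii; thin neck, separable by opening
_BUD_FRACTION = 0.25  # bud radius in body radii
_U_TWOLOBE = 2.0 * sphere_volume(1.0) - lens_volume(1.0, 1.0, _TWOLOBE_SEP)
_U_BUDDING = (
    sphere_volume(1.0) + sphere_volume(_BUD_FRACTION) - lens_volume(1.0, _BUD_FRACTION, 1.0)
)


def make_planted_plate(
    seed: int = 0,
    volume_mm3: float = 0.112,
    n_in_band: int = 40,
    n_out_band: int = 26,
    n_nonspherical: int = 30,
    pixel_size: float = 4.4,
    appearance: Appearance | None = None,
) -> tuple[dict[str, Phantom], pd.DataFrame]:
    """Build a plate with a *known* homogeneous sub-population planted in it.

    ``n_in_band`` spheres sit within ±5% of ``volume_mm3`` (well inside a
    ±15% selection band), ``n_out_band`` spheres sit far outside it
    (≤ 0.65× or ≥ 1.35×), and ``n_nonspherical`` twolobe/ellipsoid phantoms
    carry in-band volumes but sphericity below the SI ≥ 0.90 cutoff. The
    truth table gains a boolean ``planted_in_band`` column: exactly the
    wells a correct volume + sphericity selection must recover.
    """
    total = n_in_band + n_out_band + n_nonspherical
    if total > 96:
        raise PhantomError("plate overflow")
    appearance = appearance or Appearance()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 424242]))
    roles = (
        ["in"] * n_in_band + ["out"] * n_out_band + ["non"] * n_nonspherical
    )
    roles = [roles[i] for i in rng.permutation(total)]
    phantoms: dict[str, Phantom] = {}
    rows = []
    for idx, role in enumerate(roles):
        well = PLATE_WELLS[idx]
        wrng = np.random.default_rng(np.random.SeedSequence([int(seed), 424242, idx]))
        noise_seed = int(wrng.integers(0, 2**31))
        if role == "in":
            kind = "sphere"
            v = volume_mm3 * (1.0 + wrng.uniform(-0.05, 0.05))
        elif role == "out":
            kind = "sphere"
            v = volume_mm3 * (
                wrng.uniform(1.35, 1.6) if idx % 2 == 0 else wrng.uniform(0.45, 0.65)
            )
        else:
            kind = "twolobe" if idx % 2 == 0 else "ellipsoid"
            v = volume_mm3 * (1.0 + wrng.uniform(-0.05, 0.05))
        geom = _geometry_for(kind, v * 1e9, wrng)
        probe = PhantomSpec(kind=kind, pixel_size=pixel_size, side=64, **geom)
        side = 2 * int(math.ceil(probe._half_extent_um() / pixel_size)) + 31
        spec = PhantomSpec(
            kind=kind,
            pixel_size=pixel_size,
            side=side,
            seed=noise_seed,
            appearance=appearance,
            **geom,
        )
        phantoms[well] = make_phantom(spec)
        rows.append(
            {
                "well": well,
                "class": spec.truth_class,
                "volume_um3": spec.analytic_volume(),
                "pixel_size_um": pixel_size,
                "planted_in_band": role == "in",
            }
        )
    return phantoms, pd.DataFrame(rows)


def _geometry_for(kind: str, volume_um3: float, rng: np.random.Generator) -> dict:
    if kind == "sphere":
        return {"radius": (volume_um3 / sphere_volume(1.0)) ** (1.0 / 3.0)}
    if kind == "ellipsoid":
        b = (3.0 * volume_um3 / (8.0 * math.pi)) ** (1.0 / 3.0)  # a = 2b
        return {"semi_major": 2.0 * b, "semi_minor": b, "angle": float(rng.uniform(0.0, math.pi))}
    if kind == "twolobe":
        r = (volume_um3 / _U_TWOLOBE) ** (1.0 / 3.0)
        return {"r1": r, "r2": r, "center_distance": _TWOLOBE_SEP * r}
    r = (volume_um3 / _U_BUDDING) ** (1.0 / 3.0)
    return {
        "body_radius": r,
        "bud_radius": _BUD_FRACTION * r,
        "bud_angle": float(rng.uniform(0.0, 2.0 * math.pi)),
    }


def _class_counts(class_mix: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n wells to classes."""
    total = sum(class_mix.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise PhantomError("invalid spec: class_mix proportions must sum to 1")
    kinds = sorted(class_mix)
    quotas = {k: class_mix[k] * n for k in kinds}
    counts = {k: int(math.floor(quotas[k])) for k in kinds}
    remainder = n - sum(counts.values())
    by_frac = sorted(kinds, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def make_plate_fixture(
    n_wells: int = 96,
    class_mix: dict[str, float] | None = None,
    volume_distribution: tuple | None = None,
    seed: int = 0,
    pixel_size: float = 4.4,
    appearance: Appearance | None = None,
) -> tuple[dict[str, Phantom], pd.DataFrame]:
    """Generate one phantom per well plus an analytic truth table.

    Parameters
    ----------
    n_wells : int
        Number of wells to fill, in A1…H12 row-major order (≤ 96).
    class_mix : dict
        Proportions per phantom kind (must sum to 1). Wells are assigned by
        deterministic largest-remainder counts, shuffled by the plate RNG.
    volume_distribution : tuple
        ``("fixed", v_mm3)`` or ``("lognormal", mu, sigma)`` where the
        volume in mm³ is ``exp(N(mu, sigma))``.
    seed : int
        Plate seed. Each well derives its own stream from
        ``(seed, well index)``.

    Returns
    -------
    (phantoms, truth) : dict[str, Phantom], DataFrame
        ``truth`` has columns ``well, class, volume_um3, pixel_size_um``.
    """
    if n_wells > 96:
        raise PhantomError("plate overflow")
    if n_wells < 1:
        raise PhantomError("invalid spec: need at least one well")
    class_mix = dict(class_mix or DEFAULT_CLASS_MIX)
    unknown = set(class_mix) - set(KINDS)
    if unknown:
        raise PhantomError(f"invalid spec: unknown classes {sorted(unknown)}")
    volume_distribution = volume_distribution or DEFAULT_VOLUME_DISTRIBUTION
    appearance = appearance or Appearance()

    counts = _class_counts(class_mix, n_wells)
    labels = [k for k in sorted(counts) for _ in range(counts[k])]
    plate_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 96]))
    order = plate_rng.permutation(n_wells)
    assignment = [labels[i] for i in np.argsort(order, kind="stable")]

    phantoms: dict[str, Phantom] = {}
    rows = []
    for idx in range(n_wells):
        well = PLATE_WELLS[idx]
        ss = np.random.SeedSequence([int(seed), idx])
        draw_ss, noise_ss = ss.spawn(2)
        rng = np.random.default_rng(draw_ss)
        if volume_distribution[0] == "fixed":
            v_mm3 = float(volume_distribution[1])
        elif volume_distribution[0] == "lognormal":
            _, mu, sigma = volume_distribution
            v_mm3 = float(np.exp(rng.normal(mu, sigma)))
        else:
            raise PhantomError("invalid spec: unknown volume_distribution")
        kind = assignment[idx]
        geom = _geometry_for(kind, v_mm3 * 1e9, rng)
        probe = PhantomSpec(kind=kind, pixel_size=pixel_size, side=64, **geom)
        side = 2 * int(math.ceil(probe._half_extent_um() / pixel_size)) + 31
        spec = PhantomSpec(
            kind=kind,
            pixel_size=pixel_size,
            side=side,
            seed=int(noise_ss.generate_state(1, np.uint32)[0]) % (2**31),
            appearance=appearance,
            **geom,
        )
        phantoms[well] = make_phantom(spec)
        rows.append(
            {
                "well": well,
                "class": spec.truth_class,
                "volume_um3": spec.analytic_volume(),
                "pixel_size_um": pixel_size,
            }
        )
    return phantoms, pd.DataFrame(rows)
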