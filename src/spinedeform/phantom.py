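"""Synthetic loaded-spine phantom with analytic ground-truth deformation.

The phantom emulates a sagittal T2-like acquisition of the lumbar spine
(bright nucleus pulposus, darker annulus fibrosus, dark vertebral bodies)
in an unloaded state and under axial compression.  The compressive
deformation is built in closed form so that every downstream stage
(registration, Jacobian mapping, regional analysis) can be validated
against exact truth.

Deformation model
-----------------
A purely axial displacement with in-plane strain gradients.  The axial
strain at world point ``(x, y, z)`` is a sum of per-disc Gaussian lobes

    eps(x, y, z) = sum_d [ (c_d - 1) + w_d (y - y_c) + a_d (x - x_c) ]
                   * exp(-(z - z_d)^2 / (2 sigma_d^2))

where ``c_d`` is the disc's axial compression factor (< 1 compresses),
``w_d`` an anterior–posterior wedge gradient (1/mm), ``a_d`` a lateral
gradient, and ``sigma_d`` the axial width of the lobe.  The displacement
is its integral from the caudal edge (feet fixed, head moves down),

    u_z(x, y, z) = integral_0^z eps dt ,

which has an error-function closed form.  Because ``u_x = u_y = 0`` the
forward Jacobian determinant is exactly ``1 + eps``, and the deformation
value in the compression-positive reporting convention is
``D = 1 / (1 + eps)``.

The loaded image is the unloaded analytic scene pulled back through the
exact inverse warp (Newton-inverted per voxel), so no interpolation error
enters the ground truth.  Rician noise is added to both images
independently, mimicking two separate acquisitions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .grid import ImageVolume, world_meshgrid

DEFAULT_LEVELS = ("L1/L2", "L2/L3", "L3/L4", "L4/L5", "L5/S1")

_SQRT2 = np.sqrt(2.0)
_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


def wedge_for_angle(angle_deg: float, sigma: float) -> float:
    """AP strain gradient ``w`` (1/mm) producing a given endplate wedge.

    ``angle_deg`` is the asymptotic rotation (degrees) of material planes
    far cranial of the disc relative to planes far caudal of it; ``sigma``
    is the axial width of the strain lobe in mm.  Derived from
    ``tan(theta) = w * integral of the Gaussian = w * sigma * sqrt(2 pi)``.
    """
    return float(np.tan(np.deg2rad(angle_deg)) / (sigma * np.sqrt(2.0 * np.pi)))


@dataclass
class PhantomSpec:
    """Full description of a synthetic loaded-spine acquisition.

    Defaults are the package's standard validation phantom: five lumbar
    discs (L1/L2 .. L5/S1) on a 96 x 64 x 160 grid at 1.5 mm, graded
    compression increasing caudally (c = 0.98 .. 0.88), a graded
    anterior–posterior wedge spanning -2 to +2 degrees, and Rician noise
    sigma = 5 on intensities (background/bone/annulus/nucleus =
    20/60/100/200).
    """

    grid_shape: tuple[int, int, int] = (96, 64, 160)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    levels: tuple[str, ...] = DEFAULT_LEVELS
    # per-disc geometry (mm); caudal-most level has the lowest z centre
    disc_centers_z: tuple[float, ...] = (204.0, 168.0, 132.0, 96.0, 60.0)
    disc_ap_extent: float = 32.0
    disc_lr_extent: float = 44.0
    disc_height: float = 10.0
    vertebra_height: float = 24.0
    # intensities (arbitrary units, T2-like contrast)
    intensity_background: float = 20.0
    intensity_bone: float = 60.0
    intensity_annulus: float = 100.0
    intensity_nucleus: float = 200.0
    edge_width: float = 0.8  # mm, soft tissue-boundary width
    # smooth intra-tissue signal texture (random-phase cosine field),
    # material-attached so it deforms with the tissue; real T2 tissue is
    # never homogeneous, and interior deformation is only identifiable to
    # an intensity-based registration if the interior carries structure
    texture_amplitude: float = 0.12  # relative intensity modulation
    texture_wavelength: float = 12.0  # mm, dominant correlation length
    texture_n_waves: int = 48
    # deformation parameters, one per disc (L1/L2 first)
    compression_factors: tuple[float, ...] = (0.98, 0.96, 0.93, 0.90, 0.88)
    wedge_angles_deg: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    lateral_gradients: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    blend_sigma: float = 6.0  # mm, axial width of each strain lobe
    noise_sigma: float = 5.0  # Rician sigma, intensity units
    pfirrmann: tuple[int, ...] = (2, 2, 3, 3, 4)
    seed: int = 42

    @property
    def n_discs(self) -> int:
        return len(self.levels)

    def wedge_gradients(self) -> np.ndarray:
        """Per-disc AP strain gradients w_d (1/mm) from the wedge angles."""
        return np.array(
            [wedge_for_angle(a, self.blend_sigma) for a in self.wedge_angles_deg]
        )

    def validate(self) -> None:
        n = self.n_discs
        for name in (
            "disc_centers_z",
            "compression_factors",
            "wedge_angles_deg",
            "lateral_gradients",
            "pfirrmann",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per disc ({n})")
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("spacing must be positive")
        if np.any(np.asarray(self.compression_factors) <= 0) or np.any(
            np.asarray(self.compression_factors) > 1.2
        ):
            raise ValueError("compression factors must lie in (0, 1.2]")
        if self.blend_sigma <= 0:
            raise ValueError("blend_sigma must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        for k, v in kwargs.items():
            if isinstance(v, list):
                kwargs[k] = tuple(v)
        return cls(**kwargs)

    # -- geometry helpers --------------------------------------------------

    def grid(self) -> ImageVolume:
        """Empty float volume carrying the phantom grid geometry."""
        return ImageVolume(
            np.zeros(self.grid_shape, dtype=np.float64), np.asarray(self.spacing)
        )

    def column_center(self) -> tuple[float, float]:
        """In-plane (x, y) centre of the spinal column, mm."""
        shape = np.asarray(self.grid_shape, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float)
        c = (shape - 1.0) * spacing / 2.0
        return float(c[0]), float(c[1])


class StrainField:
    """Closed-form strain / displacement / deformation evaluation."""

    def __init__(self, spec: PhantomSpec):
        spec.validate()
        self.spec = spec
        self.xc, self.yc = spec.column_center()
        self.zd = np.asarray(spec.disc_centers_z, dtype=float)
        self.cd = np.asarray(spec.compression_factors, dtype=float)
        self.wd = spec.wedge_gradients()
        self.ad = np.asarray(spec.lateral_gradients, dtype=float)
        self.sigma = float(spec.blend_sigma)

    def _inplane(self, x, y):
        """Per-disc in-plane strain amplitude, stacked on a new last axis."""
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        return (self.cd - 1.0) + self.wd * (y - self.yc) + self.ad * (x - self.xc)

    def strain(self, x, y, z):
        """Axial strain eps at world points (broadcastable arrays, mm)."""
        z = np.asarray(z, dtype=float)[..., None]
        lobes = np.exp(-((z - self.zd) ** 2) / (2.0 * self.sigma**2))
        return np.sum(self._inplane(x, y) * lobes, axis=-1)

    def displacement_z(self, x, y, z):
        """Axial displacement u_z = integral_0^z eps dt (closed form, mm)."""
        z = np.asarray(z, dtype=float)[..., None]
        s = self.sigma * _SQRT2
        integ = (
            self.sigma
            * _SQRT_HALF_PI
            * (special.erf((z - self.zd) / s) - special.erf((0.0 - self.zd) / s))
        )
        return np.sum(self._inplane(x, y) * integ, axis=-1)

    def deformation(self, x, y, z):
        """Ground-truth deformation value D = 1 / (1 + eps)."""
        return 1.0 / (1.0 + self.strain(x, y, z))

    def forward_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the forward warp phi(p) = p + u(p) to ``(..., 3)`` points."""
        pts = np.asarray(points, dtype=float).copy()
        pts[..., 2] += self.displacement_z(pts[..., 0], pts[..., 1], pts[..., 2])
        return pts

    def inverse_z(self, x, y, z, tol: float = 1e-10, max_iter: int = 50):
        """Solve phi_z(x, y, p) = z for p by Newton iteration.

        Converges globally here because phi_z is strictly increasing in p
        (1 + eps > 0 is enforced at generation time).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        p = z.copy().astype(float)
        for _ in range(max_iter):
            f = p + self.displacement_z(x, y, p) - z
            if np.max(np.abs(f)) < tol:
                break
            p = p - f / (1.0 + self.strain(x, y, p))
        return p

    def inverse_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).copy()
        pts[..., 2] = self.inverse_z(pts[..., 0], pts[..., 1], pts[..., 2])
        return pts


@dataclass
class GroundTruth:
    """Analytic truth accompanying a generated phantom pair.

    All gridded fields live on the unloaded grid.  ``displacement`` holds
    the forward (unloaded -> loaded) displacement in mm with component
    order (x, y, z) on the last axis; ``d_map`` is ``1/(1+eps)`` so that
    values above 1 mark compression.
    """

    spec: PhantomSpec
    field: StrainField
    displacement: np.ndarray  # shape + (3,)
    strain: np.ndarray
    d_map: ImageVolume
    masks_unloaded: ImageVolume  # integer labels, 1 = most cranial disc
    masks_loaded: ImageVolume
    landmarks_unloaded: pd.DataFrame
    landmarks_loaded: pd.DataFrame
    true_mean_d: np.ndarray  # per disc, cranial -> caudal

    def deformation_at(self, point) -> float:
        """Closed-form D at a world point; the oracle for gridded maps."""
        point = np.asarray(point, dtype=float)
        low, high = self.d_map.world_extent()
        if np.any(point < low) or np.any(point > high):
            raise ValueError(f"point {point} outside the phantom grid")
        return float(self.field.deformation(point[0], point[1], point[2]))


def _soft_step(t: np.ndarray, width: float) -> np.ndarray:
    """Smooth 0 -> 1 transition of the signed distance ``t`` (mm)."""
    return special.expit(t / width)


class _TextureField:
    """Band-limited random-phase cosine field, analytic at any point.

    ``t(p) = 1 + amp * sum_k cos(k_j . p + phi_j) / sqrt(K)`` with wave
    vectors of magnitude ``2 pi / wavelength`` in random directions.
    Evaluated in material (unloaded) coordinates, so the texture advects
    exactly with the deforming tissue.
    """

    def __init__(self, spec: PhantomSpec):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
        k = spec.texture_n_waves
        dirs = rng.normal(size=(k, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        mags = (2.0 * np.pi / spec.texture_wavelength) * rng.uniform(
            0.5, 1.5, size=(k, 1)
        )
        self.wavevec = dirs * mags
        self.phase = rng.uniform(0.0, 2.0 * np.pi, size=k)
        self.amp = spec.texture_amplitude / np.sqrt(k)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        acc = np.zeros(pts.shape[:-1])
        for kv, ph in zip(self.wavevec, self.phase):
            acc += np.cos(pts @ kv + ph)
        return 1.0 + self.amp * acc


def _render_scene(
    spec: PhantomSpec, pts: np.ndarray, texture: "_TextureField | None" = None
) -> np.ndarray:
    """Evaluate the analytic unloaded-scene intensity at world points.

    ``pts`` has shape ``(..., 3)`` and is given in material (unloaded)
    coordinates.  The scene is a stack of soft-edged elliptic-cylinder
    vertebral bodies and discs; each disc carries an inner nucleus
    ellipsoid at higher signal.  The intra-tissue texture modulates the
    signal above background.
    """
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    xc, yc = spec.column_center()
    ax = spec.disc_lr_extent / 2.0
    ay = spec.disc_ap_extent / 2.0
    w = spec.edge_width

    # radial soft mask of the elliptic column (approximate signed distance)
    q = np.sqrt(((x - xc) / ax) ** 2 + ((y - yc) / ay) ** 2)
    radial = _soft_step((1.0 - q) * min(ax, ay), w)

    out = np.full(pts.shape[:-1], spec.intensity_background, dtype=np.float64)

    # vertebral bodies: between consecutive discs, plus one below the most
    # caudal and one above the most cranial disc
    zd = np.sort(np.asarray(spec.disc_centers_z, dtype=float))
    half_h = spec.disc_height / 2.0
    gap = 1.0  # mm cartilage endplate between disc surface and bone
    vert_centers = list((zd[:-1] + zd[1:]) / 2.0)
    vert_centers.append(zd[0] - half_h - gap - spec.vertebra_height / 2.0)
    vert_centers.append(zd[-1] + half_h + gap + spec.vertebra_height / 2.0)
    for vz in vert_centers:
        axial = _soft_step(spec.vertebra_height / 2.0 - np.abs(z - vz), w)
        out += (spec.intensity_bone - spec.intensity_background) * radial * axial

    for dz in zd:
        axial = _soft_step(half_h - np.abs(z - dz), w)
        out += (spec.intensity_annulus - spec.intensity_background) * radial * axial
        # nucleus pulposus: inner ellipsoid, bright on T2
        qn = np.sqrt(
            ((x - xc) / (0.55 * ax)) ** 2
            + ((y - yc) / (0.55 * ay)) ** 2
            + ((z - dz) / (0.75 * half_h)) ** 2
        )
        nucleus = _soft_step((1.0 - qn) * 0.55 * min(ax, ay, half_h / 0.55), w)
        out += (spec.intensity_nucleus - spec.intensity_annulus) * nucleus
    if texture is not None:
        out = spec.intensity_background + (
            out - spec.intensity_background
        ) * texture(pts)
    return out


def _disc_labels(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Integer disc labels (1 = most cranial level) at world points."""
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    xc, yc = spec.column_center()
    ax = spec.disc_lr_extent / 2.0
    ay = spec.disc_ap_extent / 2.0
    inside_col = ((x - xc) / ax) ** 2 + ((y - yc) / ay) ** 2 <= 1.0
    labels = np.zeros(pts.shape[:-1], dtype=np.int16)
    for d, dz in enumerate(spec.disc_centers_z):
        sel = inside_col & (np.abs(z - dz) <= spec.disc_height / 2.0)
        labels[sel] = d + 1
    return labels


def _landmarks(spec: PhantomSpec, warp: StrainField | None) -> pd.DataFrame:
    """Endplate landmark segments in the mid-sagittal plane (mm).

    Two endpoints per endplate at the anterior/posterior extremes of the
    disc.  If ``warp`` is given the unloaded-space points are pushed
    through the forward map, yielding loaded-space landmarks.
    """
    xc, yc = spec.column_center()
    ay = spec.disc_ap_extent / 2.0
    half_h = spec.disc_height / 2.0
    rows = []

    def seg(disc_id, structure, zlevel):
        p1 = np.array([xc, yc - ay, zlevel])
        p2 = np.array([xc, yc + ay, zlevel])
        if warp is not None:
            p1, p2 = warp.forward_points(p1), warp.forward_points(p2)
        rows.append(
            {
                "disc_id": disc_id,
                "structure": structure,
                "x1": p1[0], "y1": p1[1], "z1": p1[2],
                "x2": p2[0], "y2": p2[1], "z2": p2[2],
            }
        )

    # reference plane: superior endplate of L1 (top of the most cranial body)
    z_top = (
        max(spec.disc_centers_z)
        + half_h
        + 1.0
        + spec.vertebra_height
    )
    seg(0, "superior_endplate_L1", z_top)
    for d, dz in enumerate(spec.disc_centers_z):
        seg(d + 1, "inferior_endplate_upper", dz + half_h)
        seg(d + 1, "superior_endplate_lower", dz - half_h)
    return pd.DataFrame(rows)


def _add_rician_noise(
    data: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    if sigma <= 0:
        return data
    n1 = rng.normal(0.0, sigma, size=data.shape)
    n2 = rng.normal(0.0, sigma, size=data.shape)
    return np.sqrt((data + n1) ** 2 + n2**2)


def generate_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[ImageVolume, ImageVolume, GroundTruth, pd.DataFrame]:
    """Generate a paired unloaded/loaded phantom with analytic truth.

    Returns ``(unloaded, loaded, truth, metadata)`` where ``metadata`` is
    the per-disc table (disc_id, level, pfirrmann, compression factor,
    true mean deformation, landmark coordinates).

    Raises
    ------
    ValueError
        If the spec folds (``1 + eps <= 0`` anywhere on the grid) or has
        non-positive spacing.
    """
    if spec is None:
        spec = PhantomSpec()
    spec.validate()
    warp = StrainField(spec)
    grid = spec.grid()
    pts = world_meshgrid(grid)

    strain = warp.strain(pts[..., 0], pts[..., 1], pts[..., 2])
    min_det = float(1.0 + strain.min())
    if min_det <= 1e-3:
        raise ValueError(
            "phantom spec folds: min(1 + eps) = "
            f"{min_det:.4f} <= 0 on the grid; reduce compression/wedge"
        )

    texture = _TextureField(spec) if spec.texture_amplitude > 0 else None
    unloaded_clean = _render_scene(spec, pts, texture)
    back_pts = warp.inverse_points(pts)
    loaded_clean = _render_scene(spec, back_pts, texture)

    rng = np.random.default_rng(spec.seed)
    unloaded = ImageVolume(
        _add_rician_noise(unloaded_clean, spec.noise_sigma, rng),
        grid.spacing, grid.origin,
    )
    loaded = ImageVolume(
        _add_rician_noise(loaded_clean, spec.noise_sigma, rng),
        grid.spacing, grid.origin,
    )

    uz = warp.displacement_z(pts[..., 0], pts[..., 1], pts[..., 2])
    displacement = np.zeros(grid.shape + (3,))
    displacement[..., 2] = uz
    d_map = ImageVolume(1.0 / (1.0 + strain), grid.spacing, grid.origin)

    masks_unloaded = ImageVolume(
        _disc_labels(spec, pts), grid.spacing, grid.origin
    )
    masks_loaded = ImageVolume(
        _disc_labels(spec, back_pts), grid.spacing, grid.origin
    )

    true_mean_d = np.array(
        [
            float(d_map.data[masks_unloaded.data == d + 1].mean())
            for d in range(spec.n_discs)
        ]
    )

    lm_unloaded = _landmarks(spec, warp=None)
    lm_loaded = _landmarks(spec, warp=warp)

    truth = GroundTruth(
        spec=spec,
        field=warp,
        displacement=displacement,
        strain=strain,
        d_map=d_map,
        masks_unloaded=masks_unloaded,
        masks_loaded=masks_loaded,
        landmarks_unloaded=lm_unloaded,
        landmarks_loaded=lm_loaded,
        true_mean_d=true_mean_d,
    )

    metadata = pd.DataFrame(
        {
            "disc_id": np.arange(1, spec.n_discs + 1),
            "level": list(spec.levels),
            "pfirrmann": list(spec.pfirrmann),
            "compression_factor": list(spec.compression_factors),
            "wedge_angle_deg": list(spec.wedge_angles_deg),
            "true_mean_D": true_mean_d,
        }
    )
    return unloaded, loaded, truth, metadata


def analytic_deformation(truth: GroundTruth, point) -> float:
    """Closed-form deformation value D = 1/(1+eps) at a world point (mm)."""
    return truth.deformation_at(point)


def write_phantom(
    unloaded: ImageVolume,
    loaded: ImageVolume,
    truth: GroundTruth,
    metadata: pd.DataFrame,
    outdir,
) -> dict[str, str]:
    """Write phantom volumes, truth fields and tables; returns the file map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def _save(vol: ImageVolume, name: str):
        path = outdir / name
        vol.save(path)
        files[name] = str(path)

    _save(unloaded, "unloaded.nii.gz")
    _save(loaded, "loaded.nii.gz")
    _save(truth.masks_unloaded, "masks_unloaded.nii.gz")
    _save(truth.masks_loaded, "masks_loaded.nii.gz")
    _save(truth.d_map, "true_deformation.nii.gz")
    for a, name in enumerate("xyz"):
        _save(
            ImageVolume(
                truth.displacement[..., a], unloaded.spacing, unloaded.origin
            ),
            f"true_displacement_{name}.nii.gz",
        )
    spec_path = outdir / "phantom_spec.json"
    spec_path.write_text(truth.spec.to_json())
    files["phantom_spec.json"] = str(spec_path)

    meta = metadata.copy()
    meta_path = outdir / "discs.csv"
    meta.to_csv(meta_path, index=False)
    files["discs.csv"] = str(meta_path)
    lm_path = outdir / "landmarks_unloaded.csv"
    truth.landmarks_unloaded.to_csv(lm_path, index=False)
    files["landmarks_unloaded.csv"] = str(lm_path)
    lm_path = outdir / "landmarks_loaded.csv"
    truth.landmarks_loaded.to_csv(lm_path, index=False)
    files["landmarks_loaded.csv"] = str(lm_path)
    return files
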