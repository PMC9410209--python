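"""Voxel-wise Jacobian analysis of a deformation field.

The registration maps unloaded-space coordinates ``x`` to loaded-space
coordinates ``T(x) = x + u(x)``.  The Jacobian of the full mapping is
``J = I + grad(u)`` (gradients in world mm); its determinant is the local
volume-change ratio of the unloaded -> loaded mapping, which is *below* 1
where tissue is compressed by the load.  Reported deformation values use
the compression-positive convention ``D = 1 / det(J)``, so D > 1 marks
compression and D < 1 expansion; the raw determinant is kept alongside.

Derivatives are second-order central differences in world units, with
second-order one-sided stencils at the grid boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["JacobianMap", "jacobian_map", "deformation_in_mask", "render_heatmap"]


@dataclass
class JacobianMap:
    """Per-voxel Jacobian of a dense mapping on a regular grid.

    ``jacobian`` has shape ``grid + (3, 3)`` with ``J[..., i, j] =
    dT_i/dx_j``; ``det`` is its determinant (forward convention) and ``d``
    the reciprocal compression-positive deformation value.
    """

    jacobian: np.ndarray
    det: np.ndarray
    d: np.ndarray
    spacing: np.ndarray

    @property
    def shape(self):
        return self.det.shape


def jacobian_map(field: np.ndarray, spacing) -> JacobianMap:
    """Jacobian matrix, determinant and deformation value of a field.

    Parameters
    ----------
    field
        Displacement ``u`` in mm, shape ``(nx, ny, nz, 3)``, on a regular
        grid with the given ``spacing`` (mm per axis).
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValueError(f"expected displacement of shape (nx,ny,nz,3), got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    spacing = np.asarray(spacing, dtype=float)

    jac = np.empty(field.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = np.gradient(
                field[..., i], spacing[j], axis=j, edge_order=2
            )
        jac[..., i, i] += 1.0

    a = jac
    det = (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )
    with np.errstate(divide="ignore"):
        d = 1.0 / det
    return JacobianMap(jacobian=jac, det=det, d=d, spacing=spacing)


@dataclass
class MaskDeformation:
    mean: float
    std: float
    count: int
    values: np.ndarray


def deformation_in_mask(jmap: JacobianMap, mask: np.ndarray) -> MaskDeformation:
    """Mean deformation value D over a boolean (or label > 0) mask.

    Returns the arithmetic mean together with the standard deviation,
    voxel count and the voxelwise values themselves.
    """
    mask = np.asarray(mask)
    if mask.shape != jmap.shape:
        raise ValueError("mask and Jacobian map are on different grids")
    sel = mask > 0
    if not sel.any():
        raise ValueError("empty mask")
    vals = jmap.d[sel]
    return MaskDeformation(
        mean=float(vals.mean()), std=float(vals.std()),
        count=int(sel.sum()), values=vals,
    )


def render_heatmap(
    jmap: JacobianMap,
    masks: np.ndarray,
    path,
    projection: str = "sagittal",
) -> str:
    """Write a disc-deformation heatmap PNG and return its path.

    ``projection="sagittal"`` averages D across the left-right axis within
    disc voxels (anterior-posterior on the horizontal axis, caudal-cranial
    vertical); ``"head-feet"`` averages along the head-feet axis.  The
    colormap diverges around D = 1 so compression (> 1) and expansion
    (< 1) read as opposite hues.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    masks = np.asarray(masks)
    if masks.shape != jmap.shape:
        raise ValueError("masks and Jacobian map are on different grids")
    if not (masks > 0).any():
        raise ValueError("empty masks")
    masked = np.where(masks > 0, jmap.d, np.nan)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        if projection == "sagittal":
            img = np.nanmean(masked, axis=0).T  # (z, y)
            origin = "lower"
            xlabel, ylabel = "anterior → posterior", "caudal → cranial"
        elif projection in ("head-feet", "head_feet"):
            img = np.nanmean(masked, axis=2).T  # (y, x)
            origin = "lower"
            xlabel, ylabel = "left → right", "anterior → posterior"
        else:
            raise ValueError(f"unknown projection {projection!r}")

    finite = img[np.isfinite(img)]
    span = max(float(np.abs(finite - 1.0).max()), 1e-3) if finite.size else 0.1
    norm = TwoSlopeNorm(vcenter=1.0, vmin=1.0 - span, vmax=1.0 + span)
    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.imshow(img, cmap="RdBu_r", norm=norm, origin=origin, aspect="equal")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"Intradiscal deformation ({projection})")
    fig.colorbar(im, ax=ax, label="D  (>1 compression, <1 expansion)")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
    return str(path)
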