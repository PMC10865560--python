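"""Preprocessing: bias-field correction, template alignment, resampling.

The original pipeline relies on N4 inhomogeneity correction and ANTs
non-linear registration to the MNI template.  Reproducing those numerics
is out of scope here; this module ships the same *contracts* at desk
scale:

* ``correct_bias`` — log-domain smooth-field estimation: a low-order
  polynomial field is fit by least squares, alternating with a 1-D
  k-means tissue model so that anatomy is not absorbed into the field.
  The estimated field has unit geometric mean over the mask.
* ``register_to_template`` — identity, moment-matching affine, or affine
  plus a coarse B-spline free-form refinement.  A plug-in hook accepts
  externally computed transforms.
* ``resample_labels_to_native`` — nearest-neighbour back-transform.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage, optimize
from sklearn.cluster import KMeans

from .volumes import LabelMap, Patch, Volume3D

__all__ = [
    "TransformPair",
    "correct_bias",
    "register_to_template",
    "resample_labels_to_native",
    "zscore_patch",
    "DegenerateInputError",
    "RegistrationError",
]

log = logging.getLogger(__name__)

SD_EPS = 1e-8  # guard for constant patches


class DegenerateInputError(ValueError):
    pass


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

@dataclass
class TransformPair:
    """Invertible world-coordinate mapping between native and template space.

    The forward map sends native world coordinates to template world
    coordinates via ``x_tpl = M @ x_nat + t``; an optional B-spline
    displacement field (defined on a coarse control grid in template
    space, ``control_spacing`` mm) refines the inverse lookup.
    ``forward`` resamples a native volume onto the template grid;
    ``inverse`` resamples a template-space volume/label map back onto the
    native grid.
    """

    kind: str                       # identity | affine | affine+bspline
    matrix: np.ndarray              # 3x3
    translation: np.ndarray         # (3,)
    native_affine: np.ndarray
    native_shape: tuple[int, int, int]
    template_affine: np.ndarray
    template_shape: tuple[int, int, int]
    spacing_native: tuple[float, float, float]
    spacing_template: tuple[float, float, float]
    control_spacing: float = 2.0
    bspline_disp: Optional[np.ndarray] = None   # (3, cx, cy, cz) world-mm displacement

    # -- internal helpers -------------------------------------------------
    def _template_world(self) -> np.ndarray:
        idx = np.indices(self.template_shape, dtype=float).reshape(3, -1)
        A, t = self.template_affine[:3, :3], self.template_affine[:3, 3]
        return A @ idx + t[:, None]

    def _native_world(self) -> np.ndarray:
        idx = np.indices(self.native_shape, dtype=float).reshape(3, -1)
        A, t = self.native_affine[:3, :3], self.native_affine[:3, 3]
        return A @ idx + t[:, None]

    def _disp_at(self, world_tpl: np.ndarray) -> np.ndarray:
        """Evaluate the B-spline displacement (native-world mm) at template
        world points by interpolating the control grid."""
        if self.bspline_disp is None:
            return np.zeros_like(world_tpl)
        lo = self.template_affine[:3, 3]
        cs = self.control_spacing
        cont = (world_tpl - lo[:, None]) / cs
        out = np.empty_like(world_tpl)
        for ax in range(3):
            out[ax] = ndimage.map_coordinates(
                self.bspline_disp[ax], cont, order=3, mode="nearest")
        return out

    def forward(self, vol: Volume3D, order: int = 1) -> Volume3D:
        """Resample a native-space volume onto the template grid."""
        if self.kind == "identity" and self._grids_equal():
            return Volume3D(vol.data.copy(), self.spacing_template,
                            self.template_affine.copy(), "template")
        w_tpl = self._template_world()
        Minv = np.linalg.inv(self.matrix)
        w_nat = Minv @ (w_tpl - self.translation[:, None])
        w_nat = w_nat + self._disp_at(w_tpl)
        Ainv = np.linalg.inv(self.native_affine)
        vox = Ainv[:3, :3] @ w_nat + Ainv[:3, 3][:, None]
        data = ndimage.map_coordinates(
            np.asarray(vol.data, dtype=np.float32), vox, order=order,
            mode="constant", cval=0.0).reshape(self.template_shape)
        return Volume3D(data, self.spacing_template,
                        self.template_affine.copy(), "template")

    def inverse(self, obj, order: Optional[int] = None):
        """Resample a template-space Volume3D/LabelMap onto the native grid.

        Labels use nearest-neighbour interpolation; intensities default to
        linear.
        """
        is_labels = isinstance(obj, LabelMap)
        if order is None:
            order = 0 if is_labels else 1
        if self.kind == "identity" and self._grids_equal():
            data = obj.data.copy()
        else:
            w_nat = self._native_world()
            w_tpl = self.matrix @ w_nat + self.translation[:, None]
            if self.bspline_disp is not None:
                # one fixed-point step inverts the (small, smooth) refinement
                w_tpl = self.matrix @ (w_nat - self._disp_at(w_tpl)) \
                    + self.translation[:, None]
            Ainv = np.linalg.inv(self.template_affine)
            vox = Ainv[:3, :3] @ w_tpl + Ainv[:3, 3][:, None]
            data = ndimage.map_coordinates(
                np.asarray(obj.data, dtype=np.float32), vox, order=order,
                mode="constant", cval=0.0).reshape(self.native_shape)
        if is_labels:
            return LabelMap(np.rint(data).astype(np.int16), self.spacing_native,
                            self.native_affine.copy(), "native")
        return Volume3D(data, self.spacing_native, self.native_affine.copy(),
                        "native")

    def _grids_equal(self) -> bool:
        return (self.native_shape == self.template_shape
                and np.allclose(self.native_affine, self.template_affine))

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "native_affine": self.native_affine.tolist(),
            "native_shape": list(self.native_shape),
            "template_affine": self.template_affine.tolist(),
            "template_shape": list(self.template_shape),
            "spacing_native": list(self.spacing_native),
            "spacing_template": list(self.spacing_template),
            "control_spacing": self.control_spacing,
            "bspline_disp": None if self.bspline_disp is None
            else {"shape": list(self.bspline_disp.shape),
                  "values": self.bspline_disp.ravel().tolist()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TransformPair":
        with open(path) as fh:
            p = json.load(fh)
        disp = p.pop("bspline_disp")
        t = cls(
            kind=p["kind"],
            matrix=np.asarray(p["matrix"]),
            translation=np.asarray(p["translation"]),
            native_affine=np.asarray(p["native_affine"]),
            native_shape=tuple(p["native_shape"]),
            template_affine=np.asarray(p["template_affine"]),
            template_shape=tuple(p["template_shape"]),
            spacing_native=tuple(p["spacing_native"]),
            spacing_template=tuple(p["spacing_template"]),
            control_spacing=p["control_spacing"],
        )
        if disp is not None:
            t.bspline_disp = np.asarray(disp["values"]).reshape(disp["shape"])
        return t


def _intensity_moments(vol: Volume3D):
    """Weighted world-space centroid and per-axis sd of the intensity mass."""
    w = np.asarray(vol.data, dtype=np.float64)
    w = w - w.min()
    tot = w.sum()
    if tot <= 0:
        raise RegistrationError("volume has no intensity mass")
    wx, wy, wz = vol.world_coords()
    c = np.array([float((w * a).sum() / tot) for a in (wx, wy, wz)])
    s = np.array([float(np.sqrt((w * (a - ci) ** 2).sum() / tot))
                  for a, ci in zip((wx, wy, wz), c)])
    return c, s


def register_to_template(
    v: Volume3D,
    template: Volume3D,
    kind: str = "affine",
    refine: bool = False,
    control_spacing: float = 2.0,
    bspline_iters: int = 0,
    external: Optional[Callable[[Volume3D, Volume3D], TransformPair]] = None,
):
    """Align ``v`` to the template grid; returns ``(resampled, TransformPair)``.

    ``external`` is the plug-in hook: a callable producing a
    :class:`TransformPair` (e.g. wrapping a precomputed ANTs warp); when
    given it replaces the built-in estimation entirely.

    The built-in affine is estimated by intensity moment matching
    (translation from centroids, axis-aligned scaling from second
    moments), optionally polished by a Powell search on subsampled SSD
    (``refine=True``).  ``kind='affine+bspline'`` adds a coarse free-form
    displacement on a ``control_spacing`` mm control grid, fit by a few
    gradient steps on SSD (``bspline_iters``).
    """
    base = dict(
        native_affine=v.affine, native_shape=v.shape,
        template_affine=template.affine, template_shape=template.shape,
        spacing_native=v.spacing, spacing_template=template.spacing,
        control_spacing=control_spacing,
    )
    if external is not None:
        t = external(v, template)
        return t.forward(v), t

    if kind == "identity":
        t = TransformPair(kind="identity", matrix=np.eye(3),
                          translation=np.zeros(3), **base)
        return t.forward(v), t
    if kind not in ("affine", "affine+bspline"):
        raise ValueError(f"unsupported registration kind {kind!r}")

    c_v, s_v = _intensity_moments(v)
    c_t, s_t = _intensity_moments(template)
    scale = np.clip(s_t / np.maximum(s_v, 1e-6), 0.5, 2.0)
    M = np.diag(scale)
    trans = c_t - M @ c_v
    t = TransformPair(kind="affine", matrix=M, translation=trans, **base)

    # sanity: the mapped native field of view must overlap the template's
    corners = np.array(np.meshgrid([0, v.shape[0] - 1], [0, v.shape[1] - 1],
                                   [0, v.shape[2] - 1])).reshape(3, -1).astype(float)
    A, off = v.affine[:3, :3], v.affine[:3, 3]
    mapped = M @ (A @ corners + off[:, None]) + trans[:, None]
    tw = t._template_world()
    lo, hi = tw.min(axis=1), tw.max(axis=1)
    if np.any(mapped.max(axis=1) < lo) or np.any(mapped.min(axis=1) > hi):
        raise RegistrationError("fields of view do not overlap after affine init")

    if refine:
        tpl = np.asarray(template.data, dtype=np.float32)[::2, ::2, ::2]

        def cost(p):
            t.matrix = np.diag(p[3:6])
            t.translation = p[:3]
            res = t.forward(v).data[::2, ::2, ::2]
            return float(np.mean((res - tpl) ** 2))

        p0 = np.concatenate([trans, scale])
        res = optimize.minimize(cost, p0, method="Powell",
                                options={"maxiter": 40, "xtol": 1e-3})
        t.translation, t.matrix = res.x[:3], np.diag(res.x[3:6])

    if kind == "affine+bspline":
        t.kind = "affine+bspline"
        _fit_bspline_refinement(t, v, template, n_iters=max(bspline_iters, 3))

    return t.forward(v), t


def _fit_bspline_refinement(t: TransformPair, v: Volume3D, template: Volume3D,
                            n_iters: int = 3, step: float = 0.5) -> None:
    """Coarse FFD: gradient descent on SSD over control-point displacements.

    Forces are the SSD residual times the moving-image gradient, averaged
    over each control cell — the classic demons/FFD update restricted to a
    handful of iterations.  Intended as a refinement contract, not an
    ANTs replacement.
    """
    tw = t._template_world()
    lo = t.template_affine[:3, 3]
    extent = tw.max(axis=1) - lo
    cshape = tuple(int(np.floor(e / t.control_spacing)) + 1 for e in extent)
    t.bspline_disp = np.zeros((3,) + cshape, dtype=np.float64)
    tpl = np.asarray(template.data, dtype=np.float64)
    for _ in range(n_iters):
        warped = t.forward(v).data.astype(np.float64)
        resid = warped - tpl
        grads = np.gradient(warped, *t.spacing_template)
        cont = [(tw[ax].reshape(t.template_shape) - lo[ax]) / t.control_spacing
                for ax in range(3)]
        cont_idx = tuple(np.clip(np.rint(c).astype(int), 0, s - 1)
                         for c, s in zip(cont, cshape))
        denom = np.maximum(np.bincount(
            np.ravel_multi_index(cont_idx, cshape).ravel(),
            minlength=int(np.prod(cshape))), 1).reshape(cshape)
        for ax in range(3):
            force = -resid * grads[ax]
            accum = np.bincount(
                np.ravel_multi_index(cont_idx, cshape).ravel(),
                weights=force.ravel(), minlength=int(np.prod(cshape)),
            ).reshape(cshape) / denom
            scale = np.abs(accum).max()
            if scale > 0:
                t.bspline_disp[ax] += step * accum / scale


def resample_labels_to_native(labels: LabelMap, t: TransformPair) -> LabelMap:
    """Nearest-neighbour back-transform of a template-space label map."""
    if labels.space_tag != "template":
        raise ValueError("resample_labels_to_native expects template-space labels")
    if tuple(labels.shape) != tuple(t.template_shape):
        raise ValueError("label grid does not match the transform's template grid")
    out = t.inverse(labels, order=0)
    assert set(np.unique(out.data)) <= set(np.unique(labels.data)), \
        "nearest-neighbour resampling cannot invent label codes"
    return out


# ---------------------------------------------------------------------------
# bias correction
# ---------------------------------------------------------------------------

def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design matrix in normalized coordinates up to ``order``."""
    x, y, z = coords
    cols = [np.ones_like(x)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            for j in range(total - i + 1):
                k = total - i - j
                cols.append(x**i * y**j * z**k)
    return np.stack(cols, axis=-1)


def correct_bias(v: Volume3D, mask: Optional[LabelMap] = None,
                 order: int = 3, iterations: int = 3,
                 n_classes: int = 4, subsample: int = 30000,
                 seed: int = 0) -> Volume3D:
    """Divide out a smooth multiplicative intensity field.

    Alternates (a) a 1-D k-means tissue model of the log-corrected
    intensities with (b) a least-squares polynomial fit (degree
    ``order``) to the log-residual.  The estimated log-field is centred
    to zero mean over the mask, i.e. the field has unit geometric mean.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if np.all(data <= 0):
        raise DegenerateInputError("bias correction needs a non-zero, non-negative image")
    if np.any(data < 0):
        raise DegenerateInputError("bias correction expects non-negative intensities")
    m = (data > 0) if mask is None else (np.asarray(mask.data) > 0) & (data > 0)
    if not m.any():
        raise DegenerateInputError("empty mask")

    def unit(c):
        c = c - c[m].mean()
        return c / (np.abs(c[m]).max() + 1e-12)

    wx, wy, wz = v.world_coords()
    coords = np.stack([unit(wx)[m], unit(wy)[m], unit(wz)[m]])
    logv = np.log(data[m])

    rng = np.random.default_rng(seed)
    nm = logv.size
    sel = rng.choice(nm, size=min(subsample, nm), replace=False)
    design_s = _poly_design(coords[:, sel], order)

    field_log = np.zeros(nm)
    for _ in range(max(iterations, 1)):
        corrected = logv - field_log
        km = KMeans(n_clusters=min(n_classes, np.unique(corrected[sel]).size),
                    n_init=3, random_state=seed)
        km.fit(corrected[sel, None])
        centers = np.sort(km.cluster_centers_.ravel())
        anatomy = centers[np.argmin(np.abs(corrected[:, None] - centers[None, :]),
                                    axis=1)]
        resid = (logv - anatomy)[sel]
        coef, *_ = np.linalg.lstsq(design_s, resid, rcond=None)
        field_log = _poly_design(coords, order) @ coef
        field_log -= field_log.mean()   # unit geometric mean over the mask

    out = data.copy()
    out[m] = data[m] / np.exp(field_log)
    res = v.with_data(out.astype(np.float32))
    return res


# ---------------------------------------------------------------------------
# patch-level intensity normalization
# ---------------------------------------------------------------------------

def zscore_array(data: np.ndarray, pad_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Z-score a 3-D array over its non-padding voxels (see zscore_patch)."""
    data = np.asarray(data, dtype=np.float32).copy()
    valid = np.ones(data.shape[:3], dtype=bool) if pad_mask is None else ~pad_mask
    vals = data[valid]
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd < SD_EPS:
        warnings.warn("constant patch encountered; z-score returns all zeros",
                      stacklevel=2)
        return np.zeros_like(data)
    data = (data - mu) / sd
    data[~valid] = 0.0
    return data


def zscore_patch(p: Patch) -> Patch:
    """Z-score a patch over its non-padding voxels.

    A constant patch is mapped to all zeros (with a warning): there is no
    information to normalize.
    """
    data = np.asarray(p.data, dtype=np.float32).copy()
    valid = ~p.pad_mask
    vals = data[valid] if data.ndim == 3 else data[valid, :]
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd < SD_EPS:
        warnings.warn("constant patch encountered; z-score returns all zeros",
                      stacklevel=2)
        return Patch(np.zeros_like(data), p.origin, p.pad_mask)
    data = (data - mu) / sd
    if data.ndim == 3:
        data[~valid] = 0.0
    else:
        data[~valid, :] = 0.0
    return Patch(data, p.origin, p.pad_mask)
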