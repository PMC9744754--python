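"""Desk-scale 2D registration: affine + B-spline free-form deformation.

The pipeline needs three things from registration: (i) a rough affine
alignment of white-matter masks across subjects, (ii) a smooth nonrigid
deformation estimated on the axon-density channel, and (iii) composable
dense displacement fields so that adjacent-slice registrations can be
chained outward from a reference slice and applied in one resampling.

The nonrigid model is a cubic B-spline free-form deformation optimized by
gradient descent on a masked sum-of-squared-differences objective with a
Laplacian penalty on control-point displacements, run over a
multiresolution pyramid.  Displacement fields use the *pull* convention:
``warped(x) = moving(x + v(x))`` with ``v`` defined on the fixed grid, so
composing fields is sampling the inner field at the outer-displaced
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .images import SENTINEL


# ---------------------------------------------------------------------------
# displacement fields

@dataclass
class DisplacementField:
    """Dense 2D vector field on the fixed grid, shape (H, W, 2) = (drow, dcol)."""

    vectors: np.ndarray
    pixel_size_um: float = 50.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 3 or v.shape[2] != 2:
            raise ValueError("vectors must have shape (H, W, 2)")
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement field must be finite everywhere")
        self.vectors = v

    @classmethod
    def identity(cls, shape: tuple[int, int], pixel_size_um: float = 50.0):
        return cls(np.zeros((*shape, 2)), pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])


def _sample_coords(field: DisplacementField) -> np.ndarray:
    h, w = field.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    return np.stack([rows + field.vectors[..., 0], cols + field.vectors[..., 1]])


def apply_field(
    field: DisplacementField,
    image: np.ndarray,
    interpolation: str = "linear",
    cval: float | None = None,
) -> np.ndarray:
    """Warp ``image`` by ``field``: out(x) = image(x + v(x)).

    ``linear`` interpolation is used for metric channels, ``nearest`` for
    label images.  Out-of-grid samples take ``cval`` (defaults: NaN for
    float images, 0 for integer label images).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    image = np.asarray(image)
    if image.shape != field.shape:
        raise ValueError("image and field grids differ")
    order = 1 if interpolation == "linear" else 0
    is_int = np.issubdtype(image.dtype, np.integer)
    if cval is None:
        cval = 0 if is_int else SENTINEL
    coords = _sample_coords(field)
    if is_int or not np.isnan(np.asarray(image, dtype=float)).any():
        out = ndimage.map_coordinates(
            image.astype(float), coords, order=order, mode="constant", cval=cval
        )
        return out.astype(image.dtype) if is_int else out
    # NaN-aware resampling: interpolate values and validity separately so
    # undefined pixels neither bleed into the mask nor shrink it
    valid = np.isfinite(image)
    filled = np.where(valid, image, 0.0)
    out = ndimage.map_coordinates(filled, coords, order=order, mode="constant", cval=0.0)
    wval = ndimage.map_coordinates(
        valid.astype(float), coords, order=order, mode="constant", cval=0.0
    )
    with np.errstate(invalid="ignore"):
        return np.where(wval >= 0.5, out / np.maximum(wval, 1e-12), SENTINEL)


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Field equivalent to warping by ``inner`` first, then ``outer``.

    ``warp(compose(outer, inner), img) == warp(outer, warp(inner, img))``
    up to interpolation error: v(x) = outer(x) + inner(x + outer(x)).
    """
    if outer.shape != inner.shape:
        raise ValueError("cannot compose fields on different grids")
    coords = _sample_coords(outer)
    sampled = np.stack(
        [
            ndimage.map_coordinates(inner.vectors[..., k], coords, order=1, mode="nearest")
            for k in (0, 1)
        ],
        axis=-1,
    )
    return DisplacementField(outer.vectors + sampled, outer.pixel_size_um)


# ---------------------------------------------------------------------------
# affine registration

@dataclass(frozen=True)
class AffineTransform:
    """Maps fixed-grid coordinates into moving-image coordinates."""

    matrix: np.ndarray      # 2x2
    translation: np.ndarray  # (2,)

    @classmethod
    def identity(cls):
        return cls(np.eye(2), np.zeros(2))

    def as_field(self, shape: tuple[int, int]) -> DisplacementField:
        h, w = shape
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        pts = np.stack([rows, cols], axis=-1)
        mapped = pts @ self.matrix.T + self.translation
        return DisplacementField(mapped - pts)


def _fill(img: np.ndarray) -> np.ndarray:
    out = np.asarray(img, dtype=float).copy()
    out[~np.isfinite(out)] = 0.0
    return out


def _moments(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    total = img.sum()
    if total <= 0:
        raise ValueError("empty mask: image has no positive intensity")
    h, w = img.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cy = (img * rows).sum() / total
    cx = (img * cols).sum() / total
    var = np.array(
        [(img * (rows - cy) ** 2).sum() / total, (img * (cols - cx) ** 2).sum() / total]
    )
    return np.array([cy, cx]), var


def estimate_affine(fixed: np.ndarray, moving: np.ndarray) -> AffineTransform:
    """Estimate an affine transform aligning ``moving`` onto ``fixed``.

    Initialized from intensity centroids and second moments (translation +
    per-axis scale), then refined by Powell minimization of the SSD.  Never
    worse than the identity transform on the SSD objective.
    """
    from scipy.optimize import minimize

    f = _fill(fixed)
    m = _fill(moving)
    if f.shape != m.shape:
        raise ValueError("fixed and moving grids differ")
    cf, vf = _moments(f)
    cm, vm = _moments(m)
    scale = np.sqrt(vm / np.maximum(vf, 1e-12))

    def params_to_tf(p):
        mat = np.array([[p[0], p[1]], [p[2], p[3]]])
        return AffineTransform(mat, np.array([p[4], p[5]]))

    # moving_coord = S (fixed_coord - cf) + cm
    init = np.array(
        [scale[0], 0.0, 0.0, scale[1], *(cm - np.array([scale[0], scale[1]]) * cf)]
    )
    ident = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])

    def ssd(p):
        tf = params_to_tf(p)
        warped = ndimage.affine_transform(
            m, tf.matrix, offset=tf.translation, order=1, mode="constant", cval=0.0
        )
        return float(((warped - f) ** 2).sum())

    best_p, best_v = ident, ssd(ident)
    for start in (init, ident):
        res = minimize(ssd, start, method="Powell", options={"xtol": 1e-3, "maxiter": 40})
        if res.fun < best_v:
            best_p, best_v = res.x, res.fun
    return params_to_tf(best_p)


def apply_affine(
    tf: AffineTransform,
    image: np.ndarray,
    interpolation: str = "linear",
    cval: float | None = None,
) -> np.ndarray:
    """Resample ``image`` through an affine transform (same conventions as
    :func:`apply_field`)."""
    return apply_field(tf.as_field(np.asarray(image).shape), image, interpolation, cval)


# ---------------------------------------------------------------------------
# nonrigid B-spline registration

@dataclass(frozen=True)
class RegistrationConfig:
    """Settings for the B-spline free-form deformation registration."""

    metric: str = "ssd"
    control_spacing: float = 8.0   # pixels, at full resolution
    levels: int = 3
    smooth_weight: float = 0.5     # Laplacian penalty on control displacements
                                   # (images are intensity-normalized first,
                                   # so the weight is scale-invariant)
    max_iter: int = 200
    tol: float = 1e-4              # relative SSD improvement threshold
    step: float = 1.0              # initial gradient step (pixels)
    #: estimate a global translation by phase correlation before the
    #: B-spline refinement (the free-form stage cannot see rigid motion of
    #: texture-free regions)
    pre_translate: bool = True
    #: chain direction: "toward_reference" registers slice s+1 onto slice s
    #: moving outward from the reference; "away" uses the inverse pairing
    chain_direction: str = "toward_reference"

    def __post_init__(self) -> None:
        if self.metric != "ssd":
            raise ValueError(f"unknown similarity metric {self.metric!r}")
        if self.control_spacing < 2:
            raise ValueError("control spacing must be >= 2 pixels")
        if self.levels < 1:
            raise ValueError("need at least one resolution level")
        if self.chain_direction not in ("toward_reference", "away"):
            raise ValueError(f"unknown chain direction {self.chain_direction!r}")


def _bspline_basis(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis values B0..B3 for local parameter t in [0,1)."""
    return np.stack(
        [
            (1 - t) ** 3 / 6,
            (3 * t**3 - 6 * t**2 + 4) / 6,
            (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6,
            t**3 / 6,
        ],
        axis=-1,
    )


def _weight_matrix(n: int, spacing: float) -> np.ndarray:
    """Dense (n, n_ctrl) cubic B-spline interpolation matrix for one axis."""
    x = np.arange(n, dtype=float) / spacing
    i = np.floor(x).astype(int)
    t = x - i
    n_ctrl = int(np.floor((n - 1) / spacing)) + 4
    w = np.zeros((n, n_ctrl))
    basis = _bspline_basis(t)
    for k in range(4):
        idx = np.clip(i + k, 0, n_ctrl - 1)  # control index offset by one
        np.add.at(w, (np.arange(n), idx), basis[:, k])
    return w


def _laplacian_penalty(c: np.ndarray) -> tuple[float, np.ndarray]:
    """Second-difference smoothness penalty on a control grid (Gy, Gx, 2)."""
    val = 0.0
    grad = np.zeros_like(c)
    for axis in (0, 1):
        if c.shape[axis] < 3:
            continue
        d2 = np.diff(c, n=2, axis=axis)
        val += float((d2**2).sum())
        lap = np.zeros_like(c)
        sl = [slice(None)] * c.ndim
        sl[axis] = slice(1, -1)
        lap[tuple(sl)] += 2 * d2
        sl[axis] = slice(None, -2)
        lap[tuple(sl)] -= d2
        sl[axis] = slice(2, None)
        lap[tuple(sl)] -= d2
        grad += lap
    return val, 2 * grad


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    return ndimage.zoom(img, 1.0 / factor, order=1, grid_mode=True, mode="nearest")


def _resize_field(vectors: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resample a dense field onto a new grid, rescaling vector magnitudes."""
    if vectors.shape[:2] == tuple(shape):
        return vectors
    scale = np.array(shape, dtype=float) / vectors.shape[:2]
    out = np.stack(
        [
            ndimage.zoom(
                vectors[..., k],
                scale,
                order=1,
                mode="nearest",
                grid_mode=True,
            )
            * scale[k]
            for k in (0, 1)
        ],
        axis=-1,
    )
    return out[: shape[0], : shape[1]]


def estimate_nonrigid(
    fixed: np.ndarray, moving: np.ndarray, cfg: RegistrationConfig | None = None
) -> DisplacementField:
    """Estimate a smooth displacement field warping ``moving`` onto ``fixed``.

    Pixels that are NaN in *both* images are excluded from the objective;
    the returned field never increases the masked SSD relative to the
    identity (guaranteed by monotone line search plus a final check).
    """
    cfg = cfg or RegistrationConfig()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving grids differ")
    weight_full = (np.isfinite(fixed) | np.isfinite(moving)).astype(float)
    f_full, m_full = _fill(fixed), _fill(moving)
    # normalize intensities so the data term and the smoothness penalty are
    # on comparable scales regardless of the metric's units
    span = max(np.ptp(f_full), np.ptp(m_full))
    if span > 0:
        f_full = f_full / span
        m_full = m_full / span
    h, w = fixed.shape

    translation = np.zeros(2)
    if cfg.pre_translate:
        from skimage.registration import phase_cross_correlation

        shift, _, _ = phase_cross_correlation(f_full, m_full, upsample_factor=10)
        translation = -np.asarray(shift, dtype=float)  # pull convention

    factors = [2 ** (cfg.levels - 1 - i) for i in range(cfg.levels)]
    factors = [f for f in factors if min(h, w) // f >= 8] or [1]
    accum: np.ndarray | None = None  # dense field at the current level's grid
    for factor in factors:
        f = _downsample(f_full, factor)
        m = _downsample(m_full, factor)
        wgt = _downsample(weight_full, factor)
        if accum is None:
            base = np.broadcast_to(translation / factor, (*f.shape, 2)).copy()
        else:
            base = _resize_field(accum, f.shape)
        base_df = DisplacementField(base)
        m_warped = apply_field(base_df, m, "linear", cval=0.0)
        inc = _optimize_level(f, m_warped, wgt, cfg, factor)
        # warping by base then by inc == warping once by compose(inc, base)
        accum = compose(DisplacementField(inc), base_df).vectors

    field = _resize_field(accum, (h, w))
    df = DisplacementField(field)
    # monotone-improvement guarantee
    if _masked_ssd(f_full, m_full, weight_full, df) > _masked_ssd(
        f_full, m_full, weight_full, DisplacementField.identity((h, w))
    ):
        return DisplacementField.identity((h, w))
    return df


def _masked_ssd(f, m, wgt, field: DisplacementField) -> float:
    warped = apply_field(field, m, "linear", cval=0.0)
    return float((wgt * (warped - f) ** 2).sum())


def _optimize_level(f, m, wgt, cfg: RegistrationConfig, factor: int) -> np.ndarray:
    """Gradient descent on control-point displacements at one pyramid level.

    ``m`` is the moving image already warped through the coarser levels'
    accumulated field; the returned dense increment refines that alignment.
    """
    h, w = f.shape
    spacing = max(cfg.control_spacing / factor, 2.0)
    wy = _weight_matrix(h, spacing)
    wx = _weight_matrix(w, spacing)
    c = np.zeros((wy.shape[1], wx.shape[1], 2))

    grad_m = np.stack(np.gradient(m), axis=0)

    def dense(cc):
        return np.stack([wy @ cc[..., k] @ wx.T for k in (0, 1)], axis=-1)

    def loss_and_grad(cc):
        fld = DisplacementField(dense(cc))
        coords = _sample_coords(fld)
        warped = ndimage.map_coordinates(m, coords, order=1, mode="constant", cval=0.0)
        resid = wgt * (warped - f)
        data = float((resid * (warped - f)).sum())
        g_at = np.stack(
            [
                ndimage.map_coordinates(grad_m[k], coords, order=1, mode="nearest")
                for k in (0, 1)
            ],
            axis=-1,
        )
        dense_grad = 2 * resid[..., None] * g_at
        ctrl_grad = np.stack(
            [wy.T @ dense_grad[..., k] @ wx for k in (0, 1)], axis=-1
        )
        pen, pen_grad = _laplacian_penalty(cc)
        return data + cfg.smooth_weight * pen, ctrl_grad + cfg.smooth_weight * pen_grad

    from scipy.optimize import minimize

    shape_c = c.shape

    def fun(flat):
        loss, grad = loss_and_grad(flat.reshape(shape_c))
        return loss, grad.ravel()

    loss0 = loss_and_grad(c)[0]
    res = minimize(
        fun,
        c.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol * 1e-3, "gtol": 1e-8},
    )
    # L-BFGS line searches are monotone, but guard against any numerical
    # regression: keep the increment only if it lowered the objective
    if res.fun <= loss0:
        c = res.x.reshape(shape_c)
    return dense(c)


# ---------------------------------------------------------------------------
# stepwise chained registration

@dataclass
class RegistrationChain:
    """Per-slice fields mapping each slice into the reference slice's space."""

    ref_index: int
    fields: list[DisplacementField] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("empty registration chain")
        if not 0 <= self.ref_index < len(self.fields):
            raise ValueError("reference index outside the chain")
        if self.fields[self.ref_index].magnitude().max() > 1e-9:
            raise ValueError("reference slice must map by the identity")


def stepwise_chain(
    slices: list[np.ndarray], ref_index: int, cfg: RegistrationConfig | None = None
) -> RegistrationChain:
    """Chain adjacent-pair registrations outward from a reference slice.

    Each slice is nonrigidly registered to its neighbor on the reference
    side; pairwise fields are composed so that the stored field for slice
    ``s`` maps it directly into the reference slice's space.  Registration
    is driven by a single channel (the axon-density map, by convention).
    """
    if not slices:
        raise ValueError("empty slice list")
    if not 0 <= ref_index < len(slices):
        raise ValueError("invalid reference index")
    cfg = cfg or RegistrationConfig()
    shape = np.asarray(slices[ref_index]).shape
    fields: list[DisplacementField | None] = [None] * len(slices)
    fields[ref_index] = DisplacementField.identity(shape)

    def pair(fixed_idx: int, moving_idx: int) -> DisplacementField:
        if cfg.chain_direction == "toward_reference":
            return estimate_nonrigid(slices[fixed_idx], slices[moving_idx], cfg)
        # inverse convention: estimate the opposite direction, then negate
        # (small-deformation approximate inverse)
        fld = estimate_nonrigid(slices[moving_idx], slices[fixed_idx], cfg)
        return DisplacementField(-fld.vectors, fld.pixel_size_um)

    for s in range(ref_index + 1, len(slices)):
        f_pair = pair(s - 1, s)  # maps slice s onto slice s-1
        fields[s] = compose(fields[s - 1], f_pair)
    for s in range(ref_index - 1, -1, -1):
        f_pair = pair(s + 1, s)
        fields[s] = compose(fields[s + 1], f_pair)
    return RegistrationChain(ref_index, [f for f in fields])
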