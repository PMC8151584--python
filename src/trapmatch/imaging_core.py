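"""Grayscale conversion, border padding and normalized cross-correlation.

The similarity measure is the mean-centered normalized cross-correlation
(NCC, Pearson form): both the template and each template-sized image window
are mean-subtracted and scaled to unit sum of squares before taking their
dot product, so every coefficient lies in [-1, 1] and is invariant to affine
changes of window intensity (``a * I + b`` with ``a > 0``).  This invariance
is what makes the score robust to the trap's uneven top illumination.

Two evaluation paths are provided: :func:`match_template_naive`, a literal
double loop over all placements used as the reference, and
:func:`match_template`, an algebraically identical vectorized path (direct
or FFT cross-correlation for the numerator, exact integral-image window sums
for the denominator).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import DegeneratePatchError, DegenerateTemplateError

#: ITU-R BT.601 luma weights for RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Patches whose centered energy (sum of squared deviations) falls below this
#: are treated as constant.  8-bit imagery has integer-valued intensities, so
#: any real structure sits far above this floor.
FLAT_ENERGY_TOL = 1e-12

#: Problem sizes (map cells x template pixels) below this use direct
#: correlation for the numerator; larger ones use the FFT.
_DIRECT_OP_LIMIT = 2_000_000


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit gray or RGB image to a float64 grayscale array.

    Single-channel input passes through unchanged (as float64).  RGB input is
    reduced with BT.601 luma weights; an RGBA alpha channel is ignored.

    Raises
    ------
    ValueError
        If the array is not 2-D or 3-D with 3 or 4 channels.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[:, :, :3] @ LUMA_WEIGHTS
    raise ValueError(
        f"unsupported image shape {arr.shape}: expected HxW or HxWx3/4"
    )


def pad_image(
    image: np.ndarray,
    template: np.ndarray,
    fill: str | float = "median",
) -> np.ndarray:
    """Enlarge ``image`` by the template's width and height.

    The output is ``(height + H) x (width + W)`` with the original image in
    the centered sub-window at offset ``(H // 2, W // 2)``; border pixels are
    filled per ``fill``: ``"median"`` (the image's median intensity, which
    approximates the dark-cloth background), ``"edge"`` (replicate border
    rows/columns) or a numeric constant.

    Padding gives targets near the image boundary full correlation support:
    without it no template placement can center on them and they are missed.
    """
    img = np.asarray(image, dtype=np.float64)
    th, tw = np.asarray(template).shape[:2]
    if th > img.shape[0] or tw > img.shape[1]:
        raise ValueError("template does not fit within image")
    pads = ((th // 2, th - th // 2), (tw // 2, tw - tw // 2))
    if isinstance(fill, str):
        if fill == "median":
            return np.pad(img, pads, mode="constant",
                          constant_values=float(np.median(img)))
        if fill == "edge":
            return np.pad(img, pads, mode="edge")
        raise ValueError(f"unknown pad fill policy {fill!r}")
    return np.pad(img, pads, mode="constant", constant_values=float(fill))


def pad_offsets(template: np.ndarray) -> tuple[int, int]:
    """(x, y) offset of the original image inside its padded version."""
    th, tw = np.asarray(template).shape[:2]
    return tw // 2, th // 2


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Mean-center a patch and scale it to unit sum of squares.

    Returns ``(p - mean(p)) / sqrt(sum((p - mean(p))**2))``, so the output
    sums to zero and has unit energy.  The dot product of two patches
    normalized this way is their correlation coefficient.

    Raises
    ------
    DegeneratePatchError
        If the patch is constant (zero variance).
    """
    p = np.asarray(patch, dtype=np.float64)
    if p.size < 2:
        raise ValueError("patch must contain at least 2 pixels")
    centered = p - p.mean()
    energy = float(np.sum(centered * centered))
    if energy <= FLAT_ENERGY_TOL:
        raise DegeneratePatchError("constant patch has no normalized form")
    return centered / np.sqrt(energy)


def ncc_at(
    image: np.ndarray,
    template: np.ndarray,
    x: int,
    y: int,
    degenerate_value: float = 0.0,
) -> float:
    """Correlation of ``template`` with the window whose top-left is (x, y).

    A constant window carries no match evidence; it scores
    ``degenerate_value`` (default 0, below any sensible threshold) instead of
    NaN.  A constant template raises :class:`DegenerateTemplateError`.
    """
    img = np.asarray(image, dtype=np.float64)
    tpl = np.asarray(template, dtype=np.float64)
    th, tw = tpl.shape
    if not (0 <= x <= img.shape[1] - tw and 0 <= y <= img.shape[0] - th):
        raise ValueError(f"window at ({x}, {y}) extends outside the image")
    try:
        tn = normalize_patch(tpl)
    except DegeneratePatchError as exc:
        raise DegenerateTemplateError(str(exc)) from exc
    try:
        wn = normalize_patch(img[y:y + th, x:x + tw])
    except DegeneratePatchError:
        return degenerate_value
    return float(np.sum(tn * wn))


def match_template_naive(
    image: np.ndarray,
    template: np.ndarray,
    degenerate_value: float = 0.0,
) -> np.ndarray:
    """Reference correlation map: an explicit loop over every placement.

    Raster order follows the sliding procedure — the template moves one pixel
    right until the far right, then one pixel down and back to the far left.
    Quadratic in image size; intended for small inputs and as the oracle the
    fast path is verified against.
    """
    img = np.asarray(image, dtype=np.float64)
    tpl = np.asarray(template, dtype=np.float64)
    th, tw = tpl.shape
    out = np.empty((img.shape[0] - th + 1, img.shape[1] - tw + 1))
    for yy in range(out.shape[0]):
        for xx in range(out.shape[1]):
            out[yy, xx] = ncc_at(img, tpl, xx, yy, degenerate_value)
    return out


def _window_sums(img: np.ndarray, th: int, tw: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window sums of ``img`` and ``img**2`` via integral images.

    Cumulative sums of 8-bit-scale intensities stay well below 2**53, so
    these sums are exact in double precision — important because the window
    variance is a difference of large near-equal terms.
    """
    def integral(a: np.ndarray) -> np.ndarray:
        ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
        np.cumsum(a, axis=0, out=ii[1:, 1:])
        np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
        return ii

    i1 = integral(img)
    i2 = integral(img * img)

    def box(ii: np.ndarray) -> np.ndarray:
        return (ii[th:, tw:] - ii[:-th, tw:] - ii[th:, :-tw] + ii[:-th, :-tw])

    return box(i1), box(i2)


def match_template(
    image: np.ndarray,
    template: np.ndarray,
    degenerate_value: float = 0.0,
) -> np.ndarray:
    """Full correlation map of ``template`` over ``image``.

    The value at map position (row y, column x) is :func:`ncc_at` for the
    template placed with its top-left corner at image pixel (x, y); the map
    has shape ``(height - H + 1, width - W + 1)``.

    The numerator ``sum(T_c * window)`` (``T_c`` the mean-centered template)
    is a cross-correlation, computed directly for small problems and via FFT
    for large ones; per-window means and energies come from exact
    integral-image sums.  Windows with zero variance receive
    ``degenerate_value``.
    """
    img = np.asarray(image, dtype=np.float64)
    tpl = np.asarray(template, dtype=np.float64)
    th, tw = tpl.shape
    if th > img.shape[0] or tw > img.shape[1]:
        raise ValueError("template does not fit within image")

    tc = tpl - tpl.mean()
    t_energy = float(np.sum(tc * tc))
    if t_energy <= FLAT_ENERGY_TOL:
        raise DegenerateTemplateError("constant template")
    t_norm = np.sqrt(t_energy)

    n_map = (img.shape[0] - th + 1) * (img.shape[1] - tw + 1)
    method = "direct" if n_map * th * tw <= _DIRECT_OP_LIMIT else "fft"
    # correlate(img, tc) == sum(tc * window); subtracting the window mean is
    # unnecessary in the numerator because sum(T_c) == 0.
    num = signal.correlate(img, tc, mode="valid", method=method)

    s1, s2 = _window_sums(img, th, tw)
    w_energy = s2 - s1 * s1 / (th * tw)
    # Relative flatness cutoff so the test scales with intensity units (a
    # window rescaled by a > 0 stays flat or non-flat either way); for 8-bit
    # content the smallest non-zero window energy is ~1, far above it.
    flat = w_energy <= np.maximum(FLAT_ENERGY_TOL, 1e-9 * s2)
    denom = t_norm * np.sqrt(np.where(flat, 1.0, w_energy))
    out = num / denom
    out[flat] = degenerate_value
    return out
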