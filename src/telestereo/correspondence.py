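"""Temporal-correlation correspondence search.

Structured illumination gives every surface point a distinctive intensity
time series over the pattern sequence.  Two pixels (one per camera) that
watch the same surface point record the same series up to gain, offset and
noise, so the zero-mean normalized cross-correlation (NCC) over *time* is
the match score — no spatial windows, no assumptions about local texture.

Pixel coordinates here follow the camera convention: centered, (0, 0) at
the image center, u rightward (columns), v downward (rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import ImageStack

__all__ = [
    "Correspondence",
    "CorrespondenceSet",
    "ZeroVarianceError",
    "temporal_ncc",
    "find_correspondences",
]


class ZeroVarianceError(ValueError):
    """A time series has no temporal variance; its NCC is undefined."""


@dataclass(frozen=True)
class Correspondence:
    """A subpixel pixel pair across the two cameras with its NCC score."""

    u1: float
    v1: float
    u2: float
    v2: float
    score: float


@dataclass
class CorrespondenceSet:
    """Column-oriented container for many correspondences."""

    u1: np.ndarray
    v1: np.ndarray
    u2: np.ndarray
    v2: np.ndarray
    score: np.ndarray

    def __post_init__(self):
        for name in ("u1", "v1", "u2", "v2", "score"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())

    def __len__(self) -> int:
        return len(self.u1)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            return Correspondence(
                self.u1[i], self.v1[i], self.u2[i], self.v2[i], self.score[i]
            )
        return CorrespondenceSet(
            self.u1[i], self.v1[i], self.u2[i], self.v2[i], self.score[i]
        )

    @property
    def p1(self) -> np.ndarray:
        return np.column_stack([self.u1, self.v1])

    @property
    def p2(self) -> np.ndarray:
        return np.column_stack([self.u2, self.v2])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("u1,v1,u2,v2,score\n")
            for a, b, c, d, s in zip(self.u1, self.v1, self.u2, self.v2, self.score):
                fh.write(f"{a:.6f},{b:.6f},{c:.6f},{d:.6f},{s:.6f}\n")

    @classmethod
    def from_csv(cls, path) -> "CorrespondenceSet":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.size == 0:
            data = np.empty((0, 5))
        return cls(data[:, 0], data[:, 1], data[:, 2], data[:, 3], data[:, 4])

    @classmethod
    def empty(cls) -> "CorrespondenceSet":
        z = np.empty(0)
        return cls(z, z, z, z, z)


def temporal_ncc(series_a, series_b) -> float:
    """Zero-mean normalized cross-correlation of two time series.

    Raises :class:`ZeroVarianceError` if either series is constant; the
    caller should treat that pixel as unmatched.
    """
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("series must share a length of at least 2")
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ZeroVarianceError("temporal NCC undefined for constant series")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def _normalize_stack(frames: np.ndarray, min_modulation: float = 0.0):
    """Per-pixel unit-normalized time series, (H, W, T) float32.

    Returns (Z, valid); invalid pixels (constant, or temporal std below
    ``min_modulation``) are zeroed and excluded from matching.  The
    modulation floor is the structured-light staple that keeps unlit
    pixels — whose only temporal variation is sensor noise — from
    winning spurious correlations.
    """
    T = frames.shape[0]
    z = np.transpose(frames, (1, 2, 0)).astype(np.float32, copy=True)
    z -= z.mean(axis=2, keepdims=True)
    norm = np.sqrt((z * z).sum(axis=2, keepdims=True))
    floor = max(1e-7, 1e-6 * np.sqrt(T), min_modulation * np.sqrt(T))
    valid = norm[..., 0] > floor
    z /= np.where(norm > 0, norm, 1.0)
    z[~valid] = 0.0
    return z, valid


# Scores within single-precision rounding of 1.0 are exact matches (the
# correlation is accumulated in float32); refinement can only move away
# from a perfect peak.  Any genuinely fractional displacement of a
# band-limited pattern depresses the peak far below this.
_PERFECT_SCORE = 1.0 - 1e-5


def _paraboloid_peak(patch3x3: np.ndarray, valid3x3: np.ndarray | None = None):
    """Subpixel offset of the correlation peak inside a 3x3 patch.

    Axis-separable paraboloid on the cross stencil: a three-point
    parabola through the middle row gives dx, through the middle column
    gives dy.  The separable form noticeably outperforms the full
    9-point least-squares paraboloid on band-limited random patterns
    (the cross term mostly injects the neighborhood's autocorrelation
    asymmetry into the estimate).  Each offset is clamped to
    [-0.5, 0.5] and zeroed where the curvature is not concave.

    ``valid3x3`` marks neighbours that carry a real correlation value;
    an axis whose flanking neighbours are invalid (e.g. unlit pixels
    next to a thin bright structure) keeps the integer position instead
    of discarding the whole match.
    """
    c = patch3x3[1, 1]
    okx = valid3x3 is None or (valid3x3[1, 0] and valid3x3[1, 2])
    oky = valid3x3 is None or (valid3x3[0, 1] and valid3x3[2, 1])
    dx = dy = 0.0
    if okx:
        dxd = patch3x3[1, 0] - 2.0 * c + patch3x3[1, 2]
        if dxd < 0:
            dx = 0.5 * (patch3x3[1, 0] - patch3x3[1, 2]) / dxd
    if oky:
        dyd = patch3x3[0, 1] - 2.0 * c + patch3x3[2, 1]
        if dyd < 0:
            dy = 0.5 * (patch3x3[0, 1] - patch3x3[2, 1]) / dyd
    return float(np.clip(dx, -0.5, 0.5)), float(np.clip(dy, -0.5, 0.5))


def _centered_axes(W: int, H: int):
    return np.arange(W) - (W - 1) / 2.0, np.arange(H) - (H - 1) / 2.0


def find_correspondences(
    stack1: ImageStack,
    stack2: ImageStack,
    search: str = "full",
    F: np.ndarray | None = None,
    band_half_width: float = 2.0,
    min_score: float = 0.3,
    subpixel: bool = True,
    stride: int = 1,
    mutual: bool = False,
    min_modulation: float = 0.05,
) -> CorrespondenceSet:
    """Match camera-1 pixels to camera-2 pixels by temporal NCC.

    Parameters
    ----------
    search:
        ``"full"`` scans the whole second image for every sampled pixel
        (use a coarse ``stride`` — this is the calibration phase).
        ``"epipolar_band"`` restricts the scan to a band of
        ``band_half_width`` pixels around the epipolar line from ``F``
        (the dense reconstruction phase).
    min_score:
        Pairs scoring below this NCC threshold are dropped.
    subpixel:
        Refine the integer peak with a paraboloid fit to the 3x3 NCC
        neighborhood (clamped to ±0.5 px).  Peaks on the border of the
        search region are discarded, not refined.
    stride:
        Sample every ``stride``-th pixel of camera 1 (both axes).
    mutual:
        Optional left-right consistency check: keep a pair only when the
        best camera-1 match of its camera-2 peak lies within 1 px of the
        starting pixel.
    min_modulation:
        Minimum temporal standard deviation (intensity units, full scale
        1.0) a pixel must show to take part.  Pixels not reached by the
        projected pattern vary only by sensor noise and would otherwise
        produce random matches; 0.05 (5% of full scale) separates lit
        from unlit pixels for any realistic pattern contrast.  Set to 0
        to disable.
    """
    if stack1.n_frames != stack2.n_frames:
        raise ValueError("stacks must share n_frames")
    if not (-1.0 <= min_score <= 1.0):
        raise ValueError("min_score must lie in [-1, 1]")
    if search not in ("full", "epipolar_band"):
        raise ValueError(f"unknown search mode: {search!r}")
    if search == "epipolar_band" and F is None:
        raise ValueError("epipolar_band search requires the fundamental matrix F")

    Z1, valid1 = _normalize_stack(stack1.frames, min_modulation)
    Z2, valid2 = _normalize_stack(stack2.frames, min_modulation)
    H1, W1, T = Z1.shape
    H2, W2, _ = Z2.shape
    ucol2, vrow2 = _centered_axes(W2, H2)

    rows1 = np.arange(0, H1, stride)
    cols1 = np.arange(0, W1, stride)
    if len(rows1) == 0 or len(cols1) == 0:
        raise ValueError("empty search grid")

    out_u1, out_v1, out_u2, out_v2, out_s = [], [], [], [], []
    Z2_flat = Z2.reshape(H2 * W2, T)

    for r1 in rows1:
        sel = cols1[valid1[r1, cols1]]
        if len(sel) == 0:
            continue
        zrow = Z1[r1, sel]  # (n, T)
        v1c = r1 - (H1 - 1) / 2.0
        u1c = sel - (W1 - 1) / 2.0

        if search == "full":
            scores = zrow @ Z2_flat.T  # (n, H2*W2)
            scores[:, ~valid2.ravel()] = -2.0
            flat = np.argmax(scores, axis=1)
            pr, pc = np.unravel_index(flat, (H2, W2))
            for i in range(len(sel)):
                rr, cc = pr[i], pc[i]
                if rr == 0 or rr == H2 - 1 or cc == 0 or cc == W2 - 1:
                    continue
                s_int = float(scores[i, flat[i]])
                if s_int < min_score or s_int < -1.5:
                    continue
                du = dv = 0.0
                if subpixel and s_int < _PERFECT_SCORE:
                    # a perfect correlation admits no refinement
                    patch = scores[i].reshape(H2, W2)[rr - 1:rr + 2, cc - 1:cc + 2]
                    vpatch = valid2[rr - 1:rr + 2, cc - 1:cc + 2]
                    du, dv = _paraboloid_peak(np.asarray(patch, dtype=float),
                                              vpatch)
                out_u1.append(u1c[i]); out_v1.append(v1c)
                out_u2.append(ucol2[cc] + du); out_v2.append(vrow2[rr] + dv)
                out_s.append(min(s_int, 1.0))
        else:
            # Affine F: epipolar lines have constant direction; for each
            # cam-1 pixel the line is a*u2 + b*v2 + c(u1, v1) = 0.
            a, b = float(F[0, 2]), float(F[1, 2])
            if abs(b) < 1e-12 * max(abs(a), 1.0):
                raise ValueError("epipolar lines vertical; band search assumes "
                                 "|F[1,2]| > 0 (rotate inputs by 90 deg)")
            cconst = F[2, 0] * u1c + F[2, 1] * v1c + F[2, 2]
            # v2(u2) per pixel; collect the row window covering the whole band
            v2_at = (-(a * ucol2[None, :]) - cconst[:, None]) / b  # (n, W2)
            margin = band_half_width * np.hypot(a, b) / abs(b)
            lo = v2_at.min() - margin
            hi = v2_at.max() + margin
            r_lo = max(int(np.floor(lo + (H2 - 1) / 2.0)), 0)
            r_hi = min(int(np.ceil(hi + (H2 - 1) / 2.0)) + 1, H2)
            if r_hi <= r_lo:
                continue
            block = Z2[r_lo:r_hi].reshape(-1, T)  # (nr*W2, T)
            nr = r_hi - r_lo
            scores = (zrow @ block.T).reshape(len(sel), nr, W2)
            vband = vrow2[r_lo:r_hi]
            # mask: outside band, or invalid pixel
            dist = np.abs(
                a * ucol2[None, None, :] + b * vband[None, :, None]
                + cconst[:, None, None]
            ) / np.hypot(a, b)
            in_band = dist <= band_half_width
            ok = in_band & valid2[r_lo:r_hi][None, :, :]
            scores = np.where(ok, scores, -2.0)
            flat = scores.reshape(len(sel), -1).argmax(axis=1)
            pr, pc = np.unravel_index(flat, (nr, W2))
            for i in range(len(sel)):
                rr, cc = pr[i], pc[i]
                s_int = float(scores[i, rr, cc])
                if s_int < min_score or s_int < -1.5:
                    continue
                if cc == 0 or cc == W2 - 1 or rr == 0 or rr == nr - 1:
                    continue
                # border of the *band* along the epipolar direction: the
                # in-line neighbours must be inside the search region
                if not (in_band[i, rr, cc - 1] and in_band[i, rr, cc + 1]):
                    continue
                du = dv = 0.0
                if subpixel and s_int < _PERFECT_SCORE:
                    patch = scores[i, rr - 1:rr + 2, cc - 1:cc + 2]
                    du, dv = _paraboloid_peak(np.asarray(patch, dtype=float),
                                              ok[i, rr - 1:rr + 2,
                                                 cc - 1:cc + 2])
                out_u1.append(u1c[i]); out_v1.append(v1c)
                out_u2.append(ucol2[cc] + du); out_v2.append(vband[rr] + dv)
                out_s.append(min(s_int, 1.0))

    cs = CorrespondenceSet(
        np.array(out_u1), np.array(out_v1),
        np.array(out_u2), np.array(out_v2), np.array(out_s),
    )
    if mutual and len(cs):
        keep = _mutual_mask(cs, Z1, Z2, valid1)
        cs = cs[keep]
    return cs


def _mutual_mask(cs: CorrespondenceSet, Z1, Z2, valid1, tol: float = 1.0):
    """Reverse full-image match of each camera-2 peak; keep if it lands
    within ``tol`` px of the originating camera-1 pixel."""
    H1, W1, T = Z1.shape
    H2, W2, _ = Z2.shape
    r2 = np.clip(np.rint(cs.v2 + (H2 - 1) / 2.0).astype(int), 0, H2 - 1)
    c2 = np.clip(np.rint(cs.u2 + (W2 - 1) / 2.0).astype(int), 0, W2 - 1)
    z = Z2[r2, c2]  # (n, T)
    scores = z @ Z1.reshape(H1 * W1, T).T
    scores[:, ~valid1.ravel()] = -2.0
    flat = scores.argmax(axis=1)
    rr, cc = np.unravel_index(flat, (H1, W1))
    u1b = cc - (W1 - 1) / 2.0
    v1b = rr - (H1 - 1) / 2.0
    return (np.abs(u1b - cs.u1) <= tol) & (np.abs(v1b - cs.v1) <= tol)
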