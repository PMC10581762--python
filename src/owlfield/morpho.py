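"""Elliptic Fourier outline morphometrics.

Closed binocular-field outlines are resampled by arc length, decomposed into
elliptic Fourier harmonics (four coefficients per harmonic: cosine and sine
amplitudes of the x- and y-series), truncated by a cumulative harmonic-power
rule, and embedded in a PCA shape space over the coefficient matrix.

Normalisation removes translation (the offset terms are dropped) and scale
(all coefficients are divided by the semi-major axis of the first-harmonic
ellipse, i.e. the largest singular value of the first-harmonic matrix, which
is rotation invariant).  Rotation alignment is *optional* and off by
default: a binocular field has a biologically meaningful vertical axis, and
aligning every outline to its first ellipse would destroy the up/down
anatomy.  Set ``align_rotation=True`` for the fully rotation-invariant shape
definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

__all__ = [
    "EFTCoefficients",
    "HarmonicPower",
    "resample_outline",
    "eft_forward",
    "eft_inverse",
    "harmonic_power",
    "reconstruction_errors",
    "coefficient_matrix",
    "ShapePCA",
    "pca_shapes",
    "shape_at_pc",
]


def _as_closed(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("outline must be an (n, 2) array with n >= 3")
    if not np.allclose(pts[0], pts[-1]):
        raise ValueError("outline must be closed (first point equal to last)")
    return pts


def _dedupe(pts: np.ndarray) -> np.ndarray:
    """Open vertex list of a closed outline, consecutive duplicates removed."""
    open_pts = pts[:-1]
    d = np.linalg.norm(np.diff(np.vstack([open_pts, open_pts[:1]]), axis=0), axis=1)
    keep = d > 1e-12 * max(d.sum(), 1e-300)
    return open_pts[keep]


def resample_outline(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a closed outline to ``k`` points equally spaced by arc length.

    The start point is standardised to the topmost vertex (largest y, ties
    broken toward the smallest x), which removes the parameterisation phase
    without any rotation alignment.  Returns a closed array of ``k + 1``
    rows (first point repeated).
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    pts = _dedupe(_as_closed(points))
    if pts.shape[0] < 3:
        raise ValueError("degenerate outline (fewer than 3 distinct points)")
    # rotate vertex order so the topmost point comes first
    order = np.lexsort((pts[:, 0], -pts[:, 1]))
    start = order[0]
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("zero-perimeter outline")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    s = total * np.arange(k) / k
    x = np.interp(s, t, closed[:, 0])
    y = np.interp(s, t, closed[:, 1])
    out = np.column_stack([x, y])
    return np.vstack([out, out[:1]])


@dataclass
class EFTCoefficients:
    """Elliptic Fourier coefficients of one closed outline.

    ``a, b`` are the cosine/sine amplitudes of the x-series and ``c, d``
    those of the y-series, harmonics ``1..N``.  ``a0, c0`` are the outline
    centroid (zero after normalisation); ``scale`` records the first-ellipse
    semi-major axis divided out.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    a0: float = 0.0
    c0: float = 0.0
    scale: float = 1.0
    normalized: bool = False
    rotation_aligned: bool = False

    def __post_init__(self):
        self.a, self.b = np.asarray(self.a, float), np.asarray(self.b, float)
        self.c, self.d = np.asarray(self.c, float), np.asarray(self.d, float)
        if not (self.a.size == self.b.size == self.c.size == self.d.size >= 1):
            raise ValueError("coefficient arrays must share a length >= 1")

    @property
    def n_harmonics(self) -> int:
        return int(self.a.size)

    def amplitudes(self) -> np.ndarray:
        return np.sqrt(self.a**2 + self.b**2 + self.c**2 + self.d**2)

    def first_ellipse_axes(self) -> tuple[float, float]:
        m = np.array([[self.a[0], self.b[0]], [self.c[0], self.d[0]]])
        sv = np.linalg.svd(m, compute_uv=False)
        return float(sv[0]), float(sv[1])

    def truncated(self, n: int) -> "EFTCoefficients":
        if not 1 <= n <= self.n_harmonics:
            raise ValueError("invalid harmonic count")
        return EFTCoefficients(
            self.a[:n], self.b[:n], self.c[:n], self.d[:n],
            self.a0, self.c0, self.scale, self.normalized, self.rotation_aligned,
        )

    def to_vector(self) -> np.ndarray:
        """Flat layout ``[a_1..a_N, b_1..b_N, c_1..c_N, d_1..d_N]`` (4N)."""
        return np.concatenate([self.a, self.b, self.c, self.d])

    @classmethod
    def from_vector(cls, vec: np.ndarray, normalized: bool = True,
                    rotation_aligned: bool = False) -> "EFTCoefficients":
        vec = np.asarray(vec, float)
        if vec.size % 4:
            raise ValueError("coefficient vector length must be a multiple of 4")
        n = vec.size // 4
        return cls(vec[:n], vec[n:2 * n], vec[2 * n:3 * n], vec[3 * n:],
                   normalized=normalized, rotation_aligned=rotation_aligned)


def eft_forward(outline: np.ndarray, n_harmonics: int,
                normalize: bool = True, align_rotation: bool = False,
                param: np.ndarray | None = None) -> EFTCoefficients:
    """Piecewise-linear elliptic Fourier decomposition of a closed outline.

    Exact integrals over the polygonal chain (Kuhl--Giardina form): with
    chord lengths ``dt_i``, cumulative parameter ``t_i`` and total ``T``,

        a_n = T / (2 pi^2 n^2) * sum_i (dx_i/dt_i) (cos phi_i - cos phi_{i-1})

    and analogously for ``b, c, d`` with sine and the y-increments.

    ``param`` optionally supplies the cumulative parameter values of the
    points (length n, strictly increasing, closing increment implied by the
    last entry); the default is the natural chord-length parameterisation.
    An analytically parameterised curve (e.g. an ellipse traversed at
    uniform angular parameter, whose coordinates are exactly sinusoidal)
    is recovered by passing its own parameter.
    """
    if param is not None:
        closed = _as_closed(outline)
        pts = closed[:-1]
    else:
        pts = _dedupe(_as_closed(outline))
        closed = np.vstack([pts, pts[:1]])
    dxy = np.diff(closed, axis=0)
    if param is not None:
        t = np.asarray(param, dtype=float)
        if t.size != closed.shape[0] or np.any(np.diff(t) <= 0):
            raise ValueError("param must be strictly increasing with one value "
                             "per point of the closed outline")
        dt = np.diff(t)
        t = t - t[0]
    else:
        dt = np.linalg.norm(dxy, axis=1)
        t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValueError("zero-perimeter outline")
    N = int(n_harmonics)
    if N < 1:
        raise ValueError("n_harmonics must be >= 1")
    n = np.arange(1, N + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :] / T
    dcos = np.diff(np.cos(phi), axis=1)
    dsin = np.diff(np.sin(phi), axis=1)
    slope = dxy / dt[:, None]
    coef = T / (2.0 * np.pi**2 * n.ravel() ** 2)
    a = coef * (dcos @ slope[:, 0])
    b = coef * (dsin @ slope[:, 0])
    c = coef * (dcos @ slope[:, 1])
    d = coef * (dsin @ slope[:, 1])
    a0 = float(((closed[:-1, 0] + closed[1:, 0]) / 2.0 * dt).sum() / T)
    c0 = float(((closed[:-1, 1] + closed[1:, 1]) / 2.0 * dt).sum() / T)
    out = EFTCoefficients(a, b, c, d, a0, c0)
    if align_rotation:
        out = _align_first_ellipse(out)
    if normalize:
        s1, _ = out.first_ellipse_axes()
        if s1 <= 0:
            raise ValueError("degenerate first harmonic; cannot normalise scale")
        out = EFTCoefficients(out.a / s1, out.b / s1, out.c / s1, out.d / s1,
                              0.0, 0.0, scale=s1, normalized=True,
                              rotation_aligned=out.rotation_aligned)
    return out


def _align_first_ellipse(coeffs: EFTCoefficients) -> EFTCoefficients:
    """Kuhl--Giardina phase and rotation alignment to the first ellipse."""
    a1, b1, c1, d1 = coeffs.a[0], coeffs.b[0], coeffs.c[0], coeffs.d[0]
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                             a1**2 + c1**2 - b1**2 - d1**2)
    N = coeffs.n_harmonics
    a = coeffs.a.copy(); b = coeffs.b.copy()
    c = coeffs.c.copy(); d = coeffs.d.copy()
    for i in range(N):
        nt = (i + 1) * theta
        rot = np.array([[np.cos(nt), -np.sin(nt)], [np.sin(nt), np.cos(nt)]])
        m = np.array([[a[i], b[i]], [c[i], d[i]]]) @ rot
        a[i], b[i], c[i], d[i] = m[0, 0], m[0, 1], m[1, 0], m[1, 1]
    psi = np.arctan2(c[0], a[0])
    R = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for i in range(N):
        m = R @ np.array([[a[i], b[i]], [c[i], d[i]]])
        a[i], b[i], c[i], d[i] = m[0, 0], m[0, 1], m[1, 0], m[1, 1]
    if a[0] < 0:  # half-period phase flip keeps the convention a1 > 0
        signs = np.array([(-1.0) ** (i + 1) for i in range(N)])
        a *= signs; b *= signs; c *= signs; d *= signs
    return EFTCoefficients(a, b, c, d, coeffs.a0, coeffs.c0, coeffs.scale,
                           coeffs.normalized, rotation_aligned=True)


def eft_inverse(coeffs: EFTCoefficients, k: int = 256) -> np.ndarray:
    """Evaluate the harmonic sums at ``k`` equally spaced parameter values.

    Returns a closed outline of ``k + 1`` rows.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    t = np.arange(k + 1) / k
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    ph = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(ph), np.sin(ph)
    x = coeffs.a0 + coeffs.a @ cos + coeffs.b @ sin
    y = coeffs.c0 + coeffs.c @ cos + coeffs.d @ sin
    return np.column_stack([x, y])


@dataclass
class HarmonicPower:
    power: np.ndarray
    cumulative_fraction: np.ndarray
    selected: int
    threshold: float


def harmonic_power(coeffs: EFTCoefficients, threshold: float = 0.99) -> HarmonicPower:
    """Cumulative harmonic power and the smallest N reaching ``threshold``.

    ``power(n) = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    p = (coeffs.a**2 + coeffs.b**2 + coeffs.c**2 + coeffs.d**2) / 2.0
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total harmonic power")
    cum = np.cumsum(p) / total
    sel = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    sel = min(sel, coeffs.n_harmonics)
    return HarmonicPower(p, cum, sel, threshold)


def reconstruction_errors(outline: np.ndarray, n_max: int, k: int = 256,
                          normalize: bool = False) -> np.ndarray:
    """RMS distance of the N-harmonic reconstruction to the best (N=n_max) one.

    Evaluated pointwise at shared parameter values; non-increasing in N by
    Parseval's identity.
    """
    full = eft_forward(outline, n_max, normalize=normalize)
    best = eft_inverse(full, k)
    errs = []
    for n in range(1, n_max + 1):
        rec = eft_inverse(full.truncated(n), k)
        errs.append(np.sqrt(np.mean(np.sum((rec - best) ** 2, axis=1))))
    return np.asarray(errs)


def coefficient_matrix(coeff_list) -> np.ndarray:
    """Stack coefficient vectors of equally sized, equally normalised EFTs."""
    if len(coeff_list) < 1:
        raise ValueError("empty coefficient list")
    n = coeff_list[0].n_harmonics
    norm = (coeff_list[0].normalized, coeff_list[0].rotation_aligned)
    for cc in coeff_list:
        if cc.n_harmonics != n:
            raise ValueError("all coefficient sets must share the harmonic count")
        if (cc.normalized, cc.rotation_aligned) != norm:
            raise ValueError("all coefficient sets must share the normalisation")
    return np.vstack([cc.to_vector() for cc in coeff_list])


class ShapePCA(BaseEstimator):
    """PCA shape space over elliptic Fourier coefficient vectors.

    Covariance PCA of the column-centred coefficient matrix (coefficients
    share units after normalisation, so no correlation scaling).  Columns
    with zero variance — e.g. the first-harmonic entries fixed by a full
    normalisation — are dropped with a warning and reinstated as constants
    by :meth:`inverse_transform`.

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_ : column means over the kept columns
    components_ : principal axes (components x kept columns)
    explained_variance_ : eigenvalues of the coefficient covariance
    explained_variance_ratio_ : proportions of variance (sum to 1)
    scores_ : PC scores of the fitted outlines
    degenerate_ : True when the input carries no shape variation
    """

    def __init__(self, n_components=None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 outlines")
        self.n_features_in_ = X.shape[1]
        ptp = X.max(axis=0) - X.min(axis=0)
        scale = max(np.abs(X).max(), 1.0)
        keep = ptp > 1e-12 * scale
        self.kept_columns_ = np.flatnonzero(keep)
        self.dropped_columns_ = np.flatnonzero(~keep)
        self.column_means_ = X.mean(axis=0)
        if self.dropped_columns_.size:
            warnings.warn(
                f"dropping {self.dropped_columns_.size} zero-variance "
                "coefficient columns before PCA", RuntimeWarning)
        if self.kept_columns_.size == 0:
            self.degenerate_ = True
            warnings.warn("identical shapes: shape space is degenerate", RuntimeWarning)
            self.components_ = np.zeros((0, 0))
            self.explained_variance_ = np.zeros(0)
            self.explained_variance_ratio_ = np.zeros(0)
            self.scores_ = np.zeros((X.shape[0], 0))
            self.mean_ = np.zeros(0)
            return self
        self.degenerate_ = False
        Xk = X[:, self.kept_columns_]
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self.scores_ = self._pca.fit_transform(Xk)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_
        self.explained_variance_ = self._pca.explained_variance_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.degenerate_:
            return np.zeros((X.shape[0], 0))
        return (X[:, self.kept_columns_] - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_

    def inverse_transform(self, scores):
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        out = np.tile(self.column_means_, (scores.shape[0], 1))
        if not self.degenerate_:
            k = min(scores.shape[1], self.components_.shape[0])
            rec = self.mean_ + scores[:, :k] @ self.components_[:k]
            out[:, self.kept_columns_] = rec
        return out


def pca_shapes(coefficient_mat: np.ndarray, n_components=None) -> ShapePCA:
    """Fit a :class:`ShapePCA` on a coefficient matrix (thin wrapper)."""
    return ShapePCA(n_components=n_components).fit(np.asarray(coefficient_mat))


def shape_at_pc(space: ShapePCA, pc: int, score: float, k: int = 256,
                rotation_aligned: bool = False) -> np.ndarray:
    """Outline of the mean shape displaced along one principal component."""
    if space.degenerate_:
        raise ValueError("degenerate shape space")
    if not 0 <= pc < space.components_.shape[0]:
        raise ValueError("pc outside the computed components")
    s = np.zeros((1, space.components_.shape[0]))
    s[0, pc] = score
    vec = space.inverse_transform(s)[0]
    coeffs = EFTCoefficients.from_vector(vec, normalized=True,
                                         rotation_aligned=rotation_aligned)
    return eft_inverse(coeffs, k)
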