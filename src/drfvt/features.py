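"""Radial feature vectors, the FVT cyclic shift, and the MAXC baseline.

A shape is summarized by the distances from ``M`` outline points to their
centroid ``(x_0, y_0)``:

    r_t = sqrt((x_t - x_0)^2 + (y_t - y_0)^2),   R = (r_1, ..., r_M).

The feature vector transformation (FVT) makes the signature robust to
noise-induced misalignment of the starting point: with
``r_k = min(r_1, ..., r_M)`` the vector is cyclically rotated to
``R' = (r_k, r_{k+1}, ..., r_M, r_1, ..., r_{k-1})``, anchoring every
vector at its minimum-radius point.  Ties go to the smallest index, so
the transform is deterministic and idempotent.

The MAXC baseline replaces the low-frequency reconstruction with the
``M`` boundary points of highest discrete curvature (k-cosine turning
angle), keeping boundary order; its output feeds the same radial feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour

__all__ = ["FeatureVector", "radial_feature", "fvt", "maxc_select"]


@dataclass
class FeatureVector:
    """Radial-distance shape signature.

    ``r`` holds the nonnegative distances in traversal order; ``centroid``
    is the ``(x_0, y_0)`` they are measured from.  When ``fvt_applied`` is
    True the vector starts at its minimum and ``k`` records the 1-based
    position (in the pre-shift vector) of the element moved to the front.
    """

    r: np.ndarray
    centroid: tuple[float, float]
    fvt_applied: bool = False
    k: int | None = None

    def __len__(self) -> int:
        return len(self.r)


def radial_feature(points: np.ndarray) -> FeatureVector:
    """Distances from outline points to their centroid, in traversal order."""
    z = np.asarray(points, dtype=complex)
    if len(z) < 3:
        raise ValueError("need at least 3 outline points")
    c = z.mean()
    return FeatureVector(r=np.abs(z - c), centroid=(float(c.real), float(c.imag)))


def fvt(feature: FeatureVector) -> FeatureVector:
    """Cyclically rotate a feature vector so it starts at its minimum.

    The rotation permutes, never alters, the values; with a tied minimum
    the smallest index wins.  Applying the transform twice is a no-op.
    """
    r = np.asarray(feature.r, dtype=float)
    if len(r) == 0:
        raise ValueError("empty feature vector")
    k = int(np.argmin(r))  # argmin takes the first of tied minima
    return FeatureVector(r=np.roll(r, -k), centroid=feature.centroid,
                         fvt_applied=True, k=k + 1)


def maxc_select(contour: Contour, m_points: int) -> np.ndarray:
    """Keep the ``m_points`` boundary points of highest curvature.

    Curvature at each boundary point is scored with the k-cosine turning
    angle: with window ``k = max(2, n // 50)`` the score is ``pi`` minus
    the interior angle between the chords to the points ``k`` steps back
    and ahead (cyclically).  The selected points are returned in boundary
    order as a complex sequence usable by :func:`radial_feature`.  Ties in
    curvature are broken toward earlier boundary positions.
    """
    if not contour.closed:
        raise ValueError("MAXC selection requires a closed contour")
    z = contour.as_complex()
    n = len(z)
    if m_points > n:
        raise ValueError(f"M={m_points} exceeds contour length {n}")
    k = max(2, n // 50)
    back = np.roll(z, k) - z
    ahead = np.roll(z, -k) - z
    norms = np.abs(back) * np.abs(ahead)
    cosang = np.ones(n)  # zero-length chord: treat as straight (score 0)
    ok = norms > 0
    cosang[ok] = np.clip((back[ok] * ahead[ok].conj()).real / norms[ok], -1.0, 1.0)
    score = np.pi - np.arccos(cosang)
    order = np.argsort(-score, kind="stable")[:m_points]
    return z[np.sort(order)]
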